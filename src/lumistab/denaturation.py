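"""Equilibrium chemical denaturation: two-state linear-extrapolation global fits.

Urea-induced unfolding monitored by intrinsic fluorescence is analysed with the
two-state (folded <-> unfolded) model and the linear extrapolation method (LEM):
the unfolding free energy is assumed linear in denaturant,

    dG([D]) = dG_H2O - m * [D],       K_U([D]) = exp(-dG([D]) / (R*T)),

so the observed signal is the population-weighted average of two linear
baselines,

    y([D]) = [(a_f + b_f*[D]) + (a_u + b_u*[D]) * K_U] / (1 + K_U).

``dG_H2O`` (kcal/mol) is the stability in water, the ``m``-value
(kcal/mol/M) its denaturant dependence (unfolding cooperativity), and
``Cmid = dG_H2O / m`` the midpoint concentration. Replicate curves are fit
globally: dG_H2O and m are shared across replicates while each replicate keeps
its own four baseline parameters, so instrument-level baseline drift does not
bias the thermodynamic parameters. Differences between conditions
(``delta_delta_g``) carry quadrature-propagated errors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import lmfit
import numpy as np
import pandas as pd

from .thermal import StabilityDelta

__all__ = [
    "GAS_CONSTANT_KCAL",
    "DEFAULT_TEMPERATURE_K",
    "DenaturationCurve",
    "TwoStateFit",
    "ReagentSpec",
    "two_state_signal",
    "fraction_unfolded",
    "fit_two_state_global",
    "cmid",
    "delta_delta_g",
    "concentration_from_absorbance",
    "read_denaturation_curves",
]

#: kcal mol-1 K-1
GAS_CONSTANT_KCAL = 1.987e-3
#: 20 degrees C, the fluorescence acquisition temperature
DEFAULT_TEMPERATURE_K = 293.15

MIN_DENAT_POINTS = 8


@dataclass(frozen=True)
class DenaturationCurve:
    """One replicate urea-denaturation curve (molar urea vs fluorescence, AU)."""

    denaturant: np.ndarray
    signal: np.ndarray
    replicate_id: str = "rep1"
    condition: str = "reducing"
    ca_state: str = "depleted"

    def __post_init__(self) -> None:
        d = np.asarray(self.denaturant, dtype=float)
        s = np.asarray(self.signal, dtype=float)
        object.__setattr__(self, "denaturant", d)
        object.__setattr__(self, "signal", s)
        if d.ndim != 1 or s.ndim != 1 or d.size != s.size:
            raise ValueError("denaturant and signal must be 1-D and equal length")
        if d.size < MIN_DENAT_POINTS:
            raise ValueError(f"need >= {MIN_DENAT_POINTS} points, got {d.size}")
        if np.any(d < 0):
            raise ValueError("denaturant concentrations must be >= 0")
        if not np.all(np.diff(d) > 0):
            raise ValueError("denaturant must be strictly increasing within a replicate")
        if not (np.all(np.isfinite(d)) and np.all(np.isfinite(s))):
            raise ValueError("non-finite values in denaturation curve")


@dataclass(frozen=True)
class ReagentSpec:
    """Beer-Lambert reagent description for concentration-from-absorbance."""

    name: str
    extinction_coefficient: float  # per (concentration unit) per cm
    wavelength_nm: float
    units: str = "mM"  # concentration unit implied by 1/epsilon

    def __post_init__(self) -> None:
        if self.extinction_coefficient <= 0:
            raise ValueError("extinction coefficient must be positive")


#: GSNO quantified at 335 nm (epsilon in mM-1 cm-1)
GSNO = ReagentSpec("GSNO", 0.92, 335.0, units="mM")
#: wild-type STIM2 luminal domain at 280 nm (epsilon in mg mL-1 cm-1)
STIM2_WT = ReagentSpec("STIM2 15-217 WT", 1.2944, 280.0, units="mg/mL")


@dataclass(frozen=True)
class TwoStateFit:
    """Global two-state/LEM fit result.

    ``dg_h2o`` and ``m_value`` are shared across replicates; ``baselines`` holds
    one ``(a_f, b_f, a_u, b_u)`` tuple per replicate. ``se_mode`` records whether
    the reported standard errors come from the global-fit covariance
    ("global_covariance") or from the SEM of independent per-replicate fits
    ("replicate_sem").
    """

    dg_h2o: float
    m_value: float
    se_dg: float
    se_m: float
    baselines: tuple[tuple[float, float, float, float], ...]
    residual_ss: float
    n_points: int
    n_replicates: int
    temperature: float = DEFAULT_TEMPERATURE_K
    gas_constant: float = GAS_CONSTANT_KCAL
    se_mode: str = "global_covariance"
    post_transition_ok: bool = True
    condition: str = ""
    ca_state: str = ""

    @property
    def cmid(self) -> float:
        """Midpoint denaturant concentration, dG_H2O / m (M)."""
        return self.dg_h2o / self.m_value

    def as_row(self) -> dict:
        return {
            "condition": self.condition,
            "ca_state": self.ca_state,
            "dg_h2o_kcal_mol": self.dg_h2o,
            "se_dg_kcal_mol": self.se_dg,
            "cmid_M": self.cmid,
            "m_value_kcal_mol_M": self.m_value,
            "se_m_kcal_mol_M": self.se_m,
            "n_replicates": self.n_replicates,
            "se_mode": self.se_mode,
            "rss": self.residual_ss,
        }


def _k_unfold(d, dg, m, temperature):
    rt = GAS_CONSTANT_KCAL * temperature
    expo = np.clip(-(dg - m * np.asarray(d, dtype=float)) / rt, -700.0, 700.0)
    return np.exp(expo)


def two_state_signal(
    d,
    dg: float,
    m: float,
    baselines: Sequence[float] = (1.0, 0.0, 0.0, 0.0),
    temperature: float = DEFAULT_TEMPERATURE_K,
):
    """Observed two-state signal at denaturant concentration(s) ``d`` (M).

    ``baselines`` is ``(a_f, b_f, a_u, b_u)``: folded/unfolded intercepts and
    slopes. Stable for unfolding free energies up to ~400 kcal/mol (the exponent
    is clipped at +/-700).
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive (K)")
    vals = [dg, m, temperature, *baselines]
    if not np.all(np.isfinite(vals)):
        raise ValueError("non-finite model parameters")
    d = np.asarray(d, dtype=float)
    if not np.all(np.isfinite(d)):
        raise ValueError("non-finite denaturant values")
    a_f, b_f, a_u, b_u = baselines
    ku = _k_unfold(d, dg, m, temperature)
    out = ((a_f + b_f * d) + (a_u + b_u * d) * ku) / (1.0 + ku)
    return out if out.ndim else float(out)


def fraction_unfolded(d, dg: float, m: float, temperature: float = DEFAULT_TEMPERATURE_K):
    """Unfolded population K_U/(1+K_U) at denaturant concentration(s) ``d``."""
    if temperature <= 0:
        raise ValueError("temperature must be positive (K)")
    ku = _k_unfold(d, dg, m, temperature)
    out = ku / (1.0 + ku)
    return out if out.ndim else float(out)


# multi-start grid over the thermodynamic parameters
_DG_STARTS = (1.0, 3.0, 5.0, 8.0)
_M_STARTS = (1.0, 2.0, 3.0)


def _baseline_guess(curve: DenaturationCurve) -> tuple[float, float, float, float]:
    d, s = curve.denaturant, curve.signal
    k = max(3, d.size // 5)
    return float(np.mean(s[:k])), 0.0, float(np.mean(s[-k:])), 0.0


def _global_residual(params, curves, temperature):
    dg = params["dg"].value
    m = params["m"].value
    res = []
    for i, c in enumerate(curves):
        bl = (
            params[f"af_{i}"].value,
            params[f"bf_{i}"].value,
            params[f"au_{i}"].value,
            params[f"bu_{i}"].value,
        )
        res.append(c.signal - two_state_signal(c.denaturant, dg, m, bl, temperature))
    return np.concatenate(res)


def fit_two_state_global(
    replicates: Sequence[DenaturationCurve],
    temperature: float = DEFAULT_TEMPERATURE_K,
    shared_baselines: bool = False,
    se_mode: str = "global_covariance",
) -> TwoStateFit:
    """Globally fit the two-state/LEM model to replicate denaturation curves.

    dG_H2O and the m-value are shared across all replicates; baselines are per
    replicate unless ``shared_baselines`` is set. The optimisation is multi-start
    over a coarse (dG, m) grid, keeping the solution with the lowest total sum of
    squared residuals.

    ``se_mode``:

    * ``"global_covariance"`` (default) — standard errors of dG and m from the
      covariance matrix of the global fit.
    * ``"replicate_sem"`` — SEM of dG and m over independent single-replicate
      fits (requires >= 2 replicates); the shared point estimates still come
      from the global fit.
    """
    curves = list(replicates)
    if not curves:
        raise ValueError("need at least one replicate")
    if se_mode not in ("global_covariance", "replicate_sem"):
        raise ValueError(f"unknown se_mode {se_mode!r}")
    conditions = {(c.condition, c.ca_state) for c in curves}
    if len(conditions) > 1:
        raise ValueError(f"replicates mix conditions: {sorted(conditions)}")

    guesses = [_baseline_guess(c) for c in curves]

    best = None
    best_ssr = np.inf
    for dg0 in _DG_STARTS:
        for m0 in _M_STARTS:
            params = lmfit.Parameters()
            params.add("dg", value=dg0)
            params.add("m", value=m0, min=1e-6)
            for i, (af, bf, au, bu) in enumerate(guesses):
                if shared_baselines and i > 0:
                    for nm in ("af", "bf", "au", "bu"):
                        params.add(f"{nm}_{i}", expr=f"{nm}_0")
                else:
                    params.add(f"af_{i}", value=af)
                    params.add(f"bf_{i}", value=bf)
                    params.add(f"au_{i}", value=au)
                    params.add(f"bu_{i}", value=bu)
            try:
                out = lmfit.minimize(
                    _global_residual, params, args=(curves, temperature),
                    method="leastsq",
                )
            except Exception:
                continue
            if out.success and out.chisqr < best_ssr:
                best, best_ssr = out, out.chisqr

    if best is None:
        raise RuntimeError("two-state global fit failed to converge from any start")

    p = best.params
    dg = float(p["dg"].value)
    m = float(p["m"].value)
    se_dg = float(p["dg"].stderr) if p["dg"].stderr is not None else float("nan")
    se_m = float(p["m"].stderr) if p["m"].stderr is not None else float("nan")

    if se_mode == "replicate_sem":
        if len(curves) < 2:
            raise ValueError("replicate_sem requires >= 2 replicates")
        dgs, ms = [], []
        for c in curves:
            single = fit_two_state_global([c], temperature=temperature)
            dgs.append(single.dg_h2o)
            ms.append(single.m_value)
        se_dg = float(np.std(dgs, ddof=1) / np.sqrt(len(dgs)))
        se_m = float(np.std(ms, ddof=1) / np.sqrt(len(ms)))

    # warn if no replicate reaches past the fitted midpoint
    est_cmid = dg / m
    post_ok = any(c.denaturant[-1] > est_cmid for c in curves)
    if not post_ok:
        warnings.warn(
            "no replicate extends past the estimated midpoint "
            f"({est_cmid:.2f} M); unfolded baseline is extrapolated",
            stacklevel=2,
        )

    baselines = tuple(
        (
            float(p[f"af_{i}"].value),
            float(p[f"bf_{i}"].value),
            float(p[f"au_{i}"].value),
            float(p[f"bu_{i}"].value),
        )
        for i in range(len(curves))
    )
    cond, ca = next(iter(conditions))
    return TwoStateFit(
        dg_h2o=dg,
        m_value=m,
        se_dg=se_dg,
        se_m=se_m,
        baselines=baselines,
        residual_ss=float(best_ssr),
        n_points=int(sum(c.denaturant.size for c in curves)),
        n_replicates=len(curves),
        temperature=temperature,
        se_mode=se_mode,
        post_transition_ok=post_ok,
        condition=cond,
        ca_state=ca,
    )


def cmid(fit) -> float:
    """Midpoint concentration dG_H2O / m (M); accepts a fit or a (dg, m) pair."""
    if isinstance(fit, TwoStateFit):
        dg, m = fit.dg_h2o, fit.m_value
    else:
        dg, m = fit
    if m <= 0:
        raise ValueError("m-value must be positive")
    return dg / m


def _dg_se(obj) -> tuple[float, float]:
    if isinstance(obj, TwoStateFit):
        return obj.dg_h2o, obj.se_dg
    dg, se = obj
    return float(dg), float(se)


def delta_delta_g(reference, modified) -> StabilityDelta:
    """ddG_H2O (modified - reference) with quadrature-propagated error.

    Accepts :class:`TwoStateFit` objects or plain ``(dg, se)`` tuples.
    """
    dg_r, se_r = _dg_se(reference)
    dg_m, se_m = _dg_se(modified)
    if se_r < 0 or se_m < 0:
        raise ValueError("standard errors must be non-negative")
    return StabilityDelta(
        value=dg_m - dg_r,
        error=float(np.hypot(se_r, se_m)),
        reference_label=getattr(reference, "condition", "") or "reference",
        modified_label=getattr(modified, "condition", "") or "modified",
    )


def concentration_from_absorbance(
    absorbance: float, reagent: ReagentSpec, path_cm: float = 1.0
) -> float:
    """Beer-Lambert concentration A / (epsilon * l), in 1/epsilon units."""
    if absorbance < 0:
        raise ValueError("absorbance must be non-negative")
    if path_cm <= 0:
        raise ValueError("path length must be positive")
    return absorbance / (reagent.extinction_coefficient * path_cm)


def read_denaturation_curves(
    path: str | Path,
    condition: str = "reducing",
    ca_state: str = "depleted",
) -> list[DenaturationCurve]:
    """Read replicate curves from delimited text with columns urea_M, fluorescence_au, replicate."""
    df = pd.read_csv(path, sep=None, engine="python")
    cols = {c.lower().strip(): c for c in df.columns}
    try:
        urea_c, sig_c = cols["urea_m"], cols["fluorescence_au"]
    except KeyError as exc:
        raise ValueError(
            f"{path}: expected columns urea_M, fluorescence_au[, replicate]"
        ) from exc
    rep_c = cols.get("replicate")
    groups = df.groupby(rep_c, sort=True) if rep_c else [("rep1", df)]
    return [
        DenaturationCurve(
            g[urea_c].to_numpy(float),
            g[sig_c].to_numpy(float),
            replicate_id=str(rep),
            condition=condition,
            ca_state=ca_state,
        )
        for rep, g in groups
    ]
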