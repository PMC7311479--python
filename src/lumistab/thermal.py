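"""Thermal-melt analysis: Boltzmann sigmoid fits of far-UV CD denaturation curves.

A thermal melt monitors ellipticity (mdeg, here at the 225 nm minimum) while the
temperature is scanned. The transition is summarised by the apparent melting
midpoint ``Tm`` of the four-parameter Boltzmann sigmoid

    theta(T) = theta_post + (theta_pre - theta_post) / (1 + exp((T - Tm)/slope))

where ``theta_pre``/``theta_post`` are the folded/unfolded plateaus and ``slope``
(in degrees C) sets the transition width. Because protein thermal denaturation is
typically irreversible, the midpoint is an *apparent* Tm, a comparative readout
rather than an equilibrium thermodynamic quantity; differences between conditions
(``delta_tm``) carry quadrature-propagated standard errors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import lmfit
import numpy as np
import pandas as pd

__all__ = [
    "MeltCurve",
    "BoltzmannFit",
    "StabilityDelta",
    "boltzmann",
    "fit_boltzmann",
    "predict_boltzmann",
    "delta_tm",
    "read_melt_curve",
]

MIN_MELT_POINTS = 10


@dataclass(frozen=True)
class MeltCurve:
    """A single thermal-melt scan (temperature in degrees C vs ellipticity in mdeg)."""

    temperature: np.ndarray
    ellipticity: np.ndarray
    protein_id: str = ""
    condition: str = "reducing"  # "reducing" (DTT) or "nitrosylating" (GSNO)
    ca_state: str = "loaded"  # "loaded" or "depleted"

    def __post_init__(self) -> None:
        t = np.asarray(self.temperature, dtype=float)
        e = np.asarray(self.ellipticity, dtype=float)
        object.__setattr__(self, "temperature", t)
        object.__setattr__(self, "ellipticity", e)
        if t.ndim != 1 or e.ndim != 1 or t.size != e.size:
            raise ValueError("temperature and ellipticity must be 1-D and equal length")
        if t.size < MIN_MELT_POINTS:
            raise ValueError(
                f"melt curve needs >= {MIN_MELT_POINTS} points, got {t.size}"
            )
        if not np.all(np.diff(t) > 0):
            raise ValueError("temperature must be strictly increasing")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(e))):
            raise ValueError("non-finite values in melt curve")


@dataclass(frozen=True)
class BoltzmannFit:
    """Result of a Boltzmann sigmoid fit to one melt curve."""

    tm: float
    slope: float
    pre_baseline: float
    post_baseline: float
    se_tm: float
    residual_ss: float
    n_points: int
    tm_in_range: bool = True
    protein_id: str = ""
    condition: str = ""
    ca_state: str = ""

    def as_row(self) -> dict:
        """Report row with the midpoint labelled apparent (melts are irreversible)."""
        return {
            "protein": self.protein_id,
            "condition": self.condition,
            "ca_state": self.ca_state,
            "apparent_tm_C": self.tm,
            "se_tm_C": self.se_tm,
            "slope_C": self.slope,
            "pre_baseline_mdeg": self.pre_baseline,
            "post_baseline_mdeg": self.post_baseline,
            "rss_mdeg2": self.residual_ss,
            "n_points": self.n_points,
        }


@dataclass(frozen=True)
class StabilityDelta:
    """Difference of a fitted stability quantity, modified minus reference.

    ``error`` is the standard error of the difference, propagated in quadrature:
    sqrt(se_ref**2 + se_mod**2).
    """

    value: float
    error: float
    reference_label: str = "reference"
    modified_label: str = "modified"

    def __post_init__(self) -> None:
        if self.error < 0:
            raise ValueError("propagated error cannot be negative")


def boltzmann(
    t: np.ndarray | float,
    tm: float,
    slope: float,
    pre: float,
    post: float,
    pre_slope: float = 0.0,
    post_slope: float = 0.0,
) -> np.ndarray | float:
    """Boltzmann sigmoid with optionally sloped plateaus.

    With ``pre_slope = post_slope = 0`` this is the standard 4-parameter model.
    The exponent is clipped to +/-700 to stay finite in double precision.
    """
    t = np.asarray(t, dtype=float)
    z = np.clip((t - tm) / slope, -700.0, 700.0)
    frac_folded = 1.0 / (1.0 + np.exp(z))
    lo = pre + pre_slope * (t - tm)
    hi = post + post_slope * (t - tm)
    return hi + (lo - hi) * frac_folded


def _fit_once(
    t: np.ndarray,
    y: np.ndarray,
    tm0: float,
    slope0: float,
    pre0: float,
    post0: float,
    linear_baselines: bool,
) -> lmfit.minimizer.MinimizerResult | None:
    params = lmfit.Parameters()
    params.add("tm", value=tm0)
    params.add("slope", value=slope0, min=1e-6)
    params.add("pre", value=pre0)
    params.add("post", value=post0)
    params.add("pre_slope", value=0.0, vary=linear_baselines)
    params.add("post_slope", value=0.0, vary=linear_baselines)

    def resid(p):
        return y - boltzmann(
            t, p["tm"].value, p["slope"].value, p["pre"].value, p["post"].value,
            p["pre_slope"].value, p["post_slope"].value,
        )

    try:
        out = lmfit.minimize(resid, params, method="leastsq")
    except Exception:
        return None
    return out if out.success else None


def fit_boltzmann(
    curve: MeltCurve,
    init: dict | None = None,
    linear_baselines: bool = False,
) -> BoltzmannFit:
    """Fit the Boltzmann sigmoid to a melt curve and extract the apparent Tm.

    Multi-start least squares: unless explicit initial guesses are given, the fit
    is started from Tm at the 25/50/75% quantiles of the temperature range and the
    lowest sum of squared residuals wins (ties broken by lower Tm). ``se_tm`` comes
    from the parameter covariance of the winning fit.

    Parameters
    ----------
    curve
        Input melt scan (validated by :class:`MeltCurve`).
    init
        Optional dict overriding initial values (keys tm, slope, pre, post).
    linear_baselines
        If True, allow linearly sloping pre/post plateaus instead of flat ones.

    Raises
    ------
    RuntimeError
        If no start converges.
    """
    t, y = curve.temperature, curve.ellipticity
    t_lo, t_hi = t[0], t[-1]
    span = t_hi - t_lo

    pre0 = float(np.mean(y[: max(3, t.size // 10)]))
    post0 = float(np.mean(y[-max(3, t.size // 10):]))
    slope0 = span / 20.0
    if init is not None:
        pre0 = init.get("pre", pre0)
        post0 = init.get("post", post0)
        slope0 = init.get("slope", slope0)

    if init is not None and "tm" in init:
        tm_starts = [float(init["tm"])]
    else:
        tm_starts = [t_lo + f * span for f in (0.25, 0.50, 0.75)]

    best = None
    best_key = (np.inf, np.inf)
    for tm0 in tm_starts:
        out = _fit_once(t, y, tm0, slope0, pre0, post0, linear_baselines)
        if out is None:
            continue
        key = (out.chisqr, out.params["tm"].value)
        if key < best_key:
            best, best_key = out, key

    if best is None:
        raise RuntimeError("Boltzmann fit failed to converge from any start")

    p = best.params
    tm = float(p["tm"].value)
    se_tm = float(p["tm"].stderr) if p["tm"].stderr is not None else float("nan")
    in_range = bool(t_lo <= tm <= t_hi)
    if not in_range:
        warnings.warn(
            f"fitted Tm {tm:.2f} C lies outside the scanned range "
            f"[{t_lo:.1f}, {t_hi:.1f}] C; treat as extrapolated",
            stacklevel=2,
        )
    return BoltzmannFit(
        tm=tm,
        slope=float(p["slope"].value),
        pre_baseline=float(p["pre"].value),
        post_baseline=float(p["post"].value),
        se_tm=se_tm,
        residual_ss=float(best.chisqr),
        n_points=int(t.size),
        tm_in_range=in_range,
        protein_id=curve.protein_id,
        condition=curve.condition,
        ca_state=curve.ca_state,
    )


def predict_boltzmann(fit: BoltzmannFit, temperatures: Sequence[float]) -> np.ndarray:
    """Evaluate a fitted Boltzmann model at the given temperatures (degrees C)."""
    return np.asarray(
        boltzmann(
            np.asarray(temperatures, dtype=float),
            fit.tm, fit.slope, fit.pre_baseline, fit.post_baseline,
        )
    )


def _tm_se(obj) -> tuple[float, float]:
    if isinstance(obj, BoltzmannFit):
        return obj.tm, obj.se_tm
    tm, se = obj
    return float(tm), float(se)


def delta_tm(reference, modified) -> StabilityDelta:
    """Tm difference (modified - reference) with quadrature-propagated error.

    Accepts :class:`BoltzmannFit` objects or plain ``(tm, se)`` tuples, mirroring
    how a stability table reports dTm = Tm(+GSNO) - Tm(-GSNO).
    """
    tm_r, se_r = _tm_se(reference)
    tm_m, se_m = _tm_se(modified)
    if se_r < 0 or se_m < 0:
        raise ValueError("standard errors must be non-negative")
    ref_label = getattr(reference, "condition", "") or "reference"
    mod_label = getattr(modified, "condition", "") or "modified"
    return StabilityDelta(
        value=tm_m - tm_r,
        error=float(np.hypot(se_r, se_m)),
        reference_label=ref_label,
        modified_label=mod_label,
    )


def read_melt_curve(
    path: str | Path,
    protein_id: str = "",
    condition: str = "reducing",
    ca_state: str = "loaded",
) -> MeltCurve:
    """Read a melt curve from delimited text with columns temperature_C, ellipticity_mdeg."""
    df = pd.read_csv(path, sep=None, engine="python")
    cols = {c.lower().strip(): c for c in df.columns}
    try:
        t = df[cols["temperature_c"]].to_numpy(float)
        e = df[cols["ellipticity_mdeg"]].to_numpy(float)
    except KeyError as exc:
        raise ValueError(
            f"{path}: expected columns temperature_C, ellipticity_mdeg"
        ) from exc
    return MeltCurve(t, e, protein_id=protein_id, condition=condition, ca_state=ca_state)
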