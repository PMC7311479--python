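"""Fura-2 ratiometric Ca2+ trace processing.

Fura-2 is excited alternately at 340 and 380 nm; the emission ratio
R = F340/F380 reports free cytosolic Ca2+ via the ratiometric calibration

    [Ca2+] = Kd * beta * (R - Rmin) / (Rmax - R)

with Kd the dye's Ca2+ dissociation constant (225 nM here), Rmin/Rmax the
ratios at zero and saturating Ca2+, and beta the F380 scaling between the
Ca2+-free and Ca2+-bound dye.

Two acquisition protocols are supported, differing in how the baseline F0 is
defined and how basal and store-operated Ca2+ entry (SOCE) are summarised:

* ``suspension`` (cuvette): traces are normalised to F/F0 with F0 the mean
  ratio over the 50 s before thapsigargin (TG); basal Ca2+ is calibrated to nM
  from the pre-EGTA ratio; peak SOCE is the mean F/F0 in a window (450-550 s)
  after Ca2+ addback.
* ``plate`` (adherent cells): no nM calibration; F0 is the mean ratio over the
  80 s after EGTA / before TG, relative basal is Fbasal - F0 (Fbasal the mean
  ratio 30 s before EGTA) and relative SOCE is F_SOCE - F0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_KD_NM",
    "FuraTrace",
    "CalibrationParams",
    "CaMeasurement",
    "compute_ratio",
    "normalize_f_over_f0",
    "calibrate_concentration",
    "ratio_for_concentration",
    "basal_concentration",
    "relative_basal",
    "peak_soce",
    "derive_calibration",
    "analyze_trace",
    "read_fura_trace",
]

#: Fura-2 Ca2+ equilibrium dissociation constant (nM)
DEFAULT_KD_NM = 225.0

SUSPENSION_BASELINE_S = 50.0  # pre-TG F0 window, cuvette protocol
PLATE_BASELINE_S = 80.0       # post-EGTA/pre-TG F0 window, plate protocol
BASAL_WINDOW_S = 30.0         # pre-EGTA window for (relative) basal
SOCE_WINDOW_S = (450.0, 550.0)


@dataclass(frozen=True)
class FuraTrace:
    """A ratiometric time series plus the reagent-addition schedule."""

    time: np.ndarray
    f340: np.ndarray
    f380: np.ndarray
    events: dict  # keys egta_add, tg_add, ca_addback (seconds)
    protocol: str = "suspension"  # or "plate"

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        a = np.asarray(self.f340, dtype=float)
        b = np.asarray(self.f380, dtype=float)
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "f340", a)
        object.__setattr__(self, "f380", b)
        if not (t.size == a.size == b.size):
            raise ValueError("time, f340, f380 must be equal length")
        if not np.all(np.diff(t) > 0):
            raise ValueError("time must be strictly increasing")
        bad = np.nonzero(b <= 0)[0]
        if bad.size:
            raise ValueError(f"f380 must be positive everywhere; first bad index {bad[0]}")
        if self.protocol not in ("suspension", "plate"):
            raise ValueError(f"unknown protocol {self.protocol!r}")
        ev = self.events
        required = ("egta_add", "tg_add", "ca_addback")
        if any(k not in ev for k in required):
            raise ValueError(f"events must contain {required}")
        e, g, c = (float(ev[k]) for k in required)
        if not (e < g < c):
            raise ValueError("events must be ordered egta_add < tg_add < ca_addback")
        if not (t[0] <= e and c <= t[-1]):
            raise ValueError("event times must lie within the record")


@dataclass(frozen=True)
class CalibrationParams:
    """Ratiometric calibration constants."""

    kd: float = DEFAULT_KD_NM
    r_min: float = 0.3
    r_max: float = 6.0
    beta: float = 1.0

    def __post_init__(self) -> None:
        if not (self.r_max > self.r_min > 0):
            raise ValueError("need r_max > r_min > 0")
        if self.kd <= 0 or self.beta <= 0:
            raise ValueError("kd and beta must be positive")


@dataclass(frozen=True)
class CaMeasurement:
    """Summary statistics of one trace under its protocol."""

    protocol: str
    f0: float
    basal_nM: float | None = None        # suspension only
    relative_basal: float | None = None  # plate only
    peak_soce: float | None = None
    baseline_window: tuple[float, float] = (0.0, 0.0)
    soce_window: tuple[float, float] = SOCE_WINDOW_S

    def as_row(self) -> dict:
        return {
            "protocol": self.protocol,
            "f0": self.f0,
            "basal_nM": self.basal_nM,
            "relative_basal": self.relative_basal,
            "peak_soce": self.peak_soce,
            "baseline_start_s": self.baseline_window[0],
            "baseline_end_s": self.baseline_window[1],
            "soce_start_s": self.soce_window[0],
            "soce_end_s": self.soce_window[1],
        }


def compute_ratio(trace: FuraTrace) -> np.ndarray:
    """Element-wise excitation ratio R(t) = F340/F380."""
    return trace.f340 / trace.f380


def _window_mean(time: np.ndarray, series: np.ndarray, start: float, stop: float) -> float:
    """Mean of samples with start <= t < stop (stop-exclusive so a window ending
    exactly at an addition does not include the post-addition sample)."""
    mask = (time >= start) & (time < stop)
    if not mask.any():
        raise ValueError(f"no samples in window [{start}, {stop}) s")
    return float(series[mask].mean())


def normalize_f_over_f0(
    ratio: np.ndarray,
    trace: FuraTrace,
    baseline_s: float | None = None,
) -> tuple[np.ndarray, float]:
    """Baseline the ratio trace; returns (normalised-or-raw series, f0).

    Suspension protocol: f0 = mean R over the ``baseline_s`` (default 50 s)
    window immediately before TG; returns (R/f0, f0). Plate protocol: f0 =
    mean R over the 80 s before TG (i.e. the EGTA-present baseline); returns
    (R unchanged, f0) — plate summaries are ratio *differences*, not quotients.
    """
    tg = float(trace.events["tg_add"])
    if baseline_s is None:
        baseline_s = (SUSPENSION_BASELINE_S if trace.protocol == "suspension"
                      else PLATE_BASELINE_S)
    start = tg - baseline_s
    if start < trace.time[0]:
        raise ValueError(
            f"baseline window [{start:.0f}, {tg:.0f}) s starts before the record"
        )
    f0 = _window_mean(trace.time, ratio, start, tg)
    if trace.protocol == "suspension":
        return ratio / f0, f0
    return ratio, f0


def calibrate_concentration(ratio, calib: CalibrationParams):
    """Ratiometric ratio -> [Ca2+] in nM: Kd * beta * (R - Rmin)/(Rmax - R).

    Scalar or array input. R >= Rmax is a saturation error; R < Rmin is clamped
    to 0 nM with a warning (sub-Rmin ratios are noise below the Ca2+-free limit).
    """
    r = np.asarray(ratio, dtype=float)
    if np.any(r >= calib.r_max):
        raise ValueError(
            f"ratio >= r_max ({calib.r_max}); dye saturated, cannot calibrate"
        )
    below = r < calib.r_min
    if np.any(below):
        warnings.warn("ratio below r_min clamped to 0 nM", stacklevel=2)
        r = np.where(below, calib.r_min, r)
    conc = calib.kd * calib.beta * (r - calib.r_min) / (calib.r_max - r)
    return conc if conc.ndim else float(conc)


def ratio_for_concentration(conc_nM, calib: CalibrationParams):
    """Exact algebraic inverse of :func:`calibrate_concentration`."""
    x = np.asarray(conc_nM, dtype=float) / (calib.kd * calib.beta)
    r = (calib.r_min + x * calib.r_max) / (1.0 + x)
    return r if r.ndim else float(r)


def basal_concentration(
    trace: FuraTrace,
    calib: CalibrationParams,
    basal_s: float = BASAL_WINDOW_S,
) -> float:
    """Resting cytosolic [Ca2+] (nM): mean pre-EGTA ratio, then calibrated."""
    egta = float(trace.events["egta_add"])
    start = egta - basal_s
    if start < trace.time[0]:
        raise ValueError("basal window starts before the record")
    r_mean = _window_mean(trace.time, compute_ratio(trace), start, egta)
    return float(calibrate_concentration(r_mean, calib))


def relative_basal(trace: FuraTrace, basal_s: float = BASAL_WINDOW_S) -> float:
    """Plate protocol relative basal: Fbasal (30 s pre-EGTA) - F0 (80 s pre-TG)."""
    if trace.protocol != "plate":
        raise ValueError("relative_basal is defined for the plate protocol")
    ratio = compute_ratio(trace)
    egta = float(trace.events["egta_add"])
    start = egta - basal_s
    if start < trace.time[0]:
        raise ValueError("basal window starts before the record")
    f_basal = _window_mean(trace.time, ratio, start, egta)
    _, f0 = normalize_f_over_f0(ratio, trace)
    return f_basal - f0


def peak_soce(
    trace: FuraTrace,
    window_s: tuple[float, float] = SOCE_WINDOW_S,
) -> float:
    """Peak store-operated Ca2+ entry.

    Suspension: mean F/F0 over the window (fold change over baseline). Plate:
    mean ratio over the window minus F0 (ratio difference F_SOCE - F0).
    """
    start, stop = window_s
    if start < float(trace.events["ca_addback"]):
        raise ValueError("SOCE window must start after the Ca2+ addback")
    if stop > trace.time[-1]:
        raise ValueError("SOCE window extends past the record")
    ratio = compute_ratio(trace)
    series, f0 = normalize_f_over_f0(ratio, trace)
    mean = _window_mean(trace.time, series, start, stop)
    if trace.protocol == "suspension":
        return mean
    return mean - f0


def derive_calibration(
    triton_ratio: np.ndarray,
    egta_ratio: np.ndarray,
    triton_f380: np.ndarray | None = None,
    egta_f380: np.ndarray | None = None,
    kd: float = DEFAULT_KD_NM,
) -> CalibrationParams:
    """Calibration constants from end-of-run Triton (saturating) and EGTA
    (Ca2+-free) segments.

    r_max/r_min are the segment mean ratios; beta is the mean F380 in the
    Ca2+-free segment over the mean F380 in the saturated segment. Without F380
    segments beta defaults to 1 with a warning (common simplification).
    """
    triton_ratio = np.asarray(triton_ratio, dtype=float)
    egta_ratio = np.asarray(egta_ratio, dtype=float)
    if triton_ratio.size == 0 or egta_ratio.size == 0:
        raise ValueError("calibration segments must be non-empty")
    r_max = float(triton_ratio.mean())
    r_min = float(egta_ratio.mean())
    if r_max <= r_min:
        raise ValueError(
            f"saturated ratio ({r_max:.3g}) must exceed Ca2+-free ratio "
            f"({r_min:.3g}); segments swapped?"
        )
    if triton_f380 is None or egta_f380 is None:
        warnings.warn("no F380 calibration segments; beta set to 1", stacklevel=2)
        beta = 1.0
    else:
        beta = float(np.mean(egta_f380) / np.mean(triton_f380))
    return CalibrationParams(kd=kd, r_min=r_min, r_max=r_max, beta=beta)


def analyze_trace(
    trace: FuraTrace,
    calib: CalibrationParams | None = None,
    soce_window_s: tuple[float, float] = SOCE_WINDOW_S,
) -> CaMeasurement:
    """Full per-trace summary under the trace's protocol."""
    ratio = compute_ratio(trace)
    _, f0 = normalize_f_over_f0(ratio, trace)
    tg = float(trace.events["tg_add"])
    if trace.protocol == "suspension":
        baseline = (tg - SUSPENSION_BASELINE_S, tg)
        basal = basal_concentration(trace, calib) if calib is not None else None
        return CaMeasurement(
            protocol="suspension",
            f0=f0,
            basal_nM=basal,
            peak_soce=peak_soce(trace, soce_window_s),
            baseline_window=baseline,
            soce_window=soce_window_s,
        )
    baseline = (tg - PLATE_BASELINE_S, tg)
    return CaMeasurement(
        protocol="plate",
        f0=f0,
        relative_basal=relative_basal(trace),
        peak_soce=peak_soce(trace, soce_window_s),
        baseline_window=baseline,
        soce_window=soce_window_s,
    )


def read_fura_trace(
    path: str | Path,
    events: dict,
    protocol: str = "suspension",
) -> FuraTrace:
    """Read a trace from delimited text with columns time_s, f340, f380."""
    df = pd.read_csv(path, sep=None, engine="python")
    cols = {c.lower().strip(): c for c in df.columns}
    try:
        t, a, b = cols["time_s"], cols["f340"], cols["f380"]
    except KeyError as exc:
        raise ValueError(f"{path}: expected columns time_s, f340, f380") from exc
    return FuraTrace(
        df[t].to_numpy(float), df[a].to_numpy(float), df[b].to_numpy(float),
        events=dict(events), protocol=protocol,
    )
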