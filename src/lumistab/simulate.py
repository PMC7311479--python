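"""Synthetic-data generators with known ground truth for every analysis arm.

The study's raw curves were never deposited, so each input type — CD thermal
melts, urea denaturation replicates, HSQC peak-list pairs and Fura-2 traces —
is emulated here from an explicit ground-truth record. Generators are pure
functions of ``(truth, seed)``: the same inputs give bit-identical outputs.
Default truths mirror the published study conditions (20-90 C melt scans at
1 C steps; 25-point 0-6 M urea grids with n = 3 replicates at ~1% multiplicative
noise; EF-SAM-numbered amide peak lists with two perturbed helix spans; 600-s
Fura-2 records at 1-s sampling with EGTA/TG/Ca2+-addback events so the
450-550 s SOCE window is live).

Noise models: additive Gaussian on the CD signal and on each Fura-2
fluorescence channel; multiplicative (fractional) Gaussian on denaturation
fluorescence — matching how those instruments actually misbehave.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .csp import Peak, PeakList
from .denaturation import DenaturationCurve, two_state_signal
from .fura import CalibrationParams, FuraTrace, ratio_for_concentration
from .thermal import MeltCurve, boltzmann

__all__ = [
    "MeltTruth",
    "DenatTruth",
    "CspTruth",
    "FuraTruth",
    "gen_melt_curve",
    "gen_denaturation_replicates",
    "gen_peaklist_pair",
    "gen_fura_trace",
]


def _rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class MeltTruth:
    """Ground truth for one thermal melt (defaults: the wild-type Ca2+-loaded
    reducing-condition midpoint)."""

    tm: float = 63.2
    slope: float = 2.0
    pre_baseline: float = -10.0
    post_baseline: float = -2.0
    noise_sd: float = 0.1  # mdeg
    t_start: float = 20.0
    t_stop: float = 90.0
    t_step: float = 1.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def gen_melt_curve(
    truth: MeltTruth,
    seed: int,
    protein_id: str = "synthetic",
    condition: str = "reducing",
    ca_state: str = "loaded",
) -> MeltCurve:
    """Boltzmann signal on the truth's temperature grid plus additive noise."""
    rng = _rng(seed)
    t = np.arange(truth.t_start, truth.t_stop + truth.t_step / 2, truth.t_step)
    y = boltzmann(t, truth.tm, truth.slope, truth.pre_baseline, truth.post_baseline)
    y = y + rng.normal(0.0, truth.noise_sd, size=t.size)
    return MeltCurve(t, y, protein_id=protein_id, condition=condition, ca_state=ca_state)


@dataclass(frozen=True)
class DenatTruth:
    """Ground truth for a set of replicate urea curves (defaults: the wild-type
    Ca2+-depleted reducing-condition stability)."""

    dg: float = 4.82  # kcal/mol
    m: float = 1.69   # kcal/mol/M
    baselines: tuple[tuple[float, float, float, float], ...] = (
        (1.00, -0.010, 0.30, 0.012),
        (0.97, -0.008, 0.33, 0.010),
        (1.03, -0.012, 0.28, 0.014),
    )
    noise_fraction: float = 0.01  # of the folded-unfolded amplitude
    n_points: int = 25
    urea_max: float = 6.0
    temperature: float = 293.15

    def __post_init__(self) -> None:
        if self.noise_fraction < 0:
            raise ValueError("noise_fraction must be >= 0")
        if not self.baselines:
            raise ValueError("need at least one replicate baseline set")


def gen_denaturation_replicates(
    truth: DenatTruth,
    seed: int,
    condition: str = "reducing",
    ca_state: str = "depleted",
) -> list[DenaturationCurve]:
    """Replicate two-state curves sharing (dG, m) with per-replicate baselines.

    Noise is multiplicative: each point is scaled by ``1 + N(0, noise_fraction)``.
    """
    rng = _rng(seed)
    d = np.linspace(0.0, truth.urea_max, truth.n_points)
    out = []
    for i, bl in enumerate(truth.baselines):
        y = two_state_signal(d, truth.dg, truth.m, bl, truth.temperature)
        y = y * (1.0 + rng.normal(0.0, truth.noise_fraction, size=d.size))
        out.append(
            DenaturationCurve(d, y, replicate_id=f"rep{i + 1}",
                              condition=condition, ca_state=ca_state)
        )
    return out


@dataclass(frozen=True)
class CspTruth:
    """Ground truth for a reference/modified HSQC peak-list pair.

    Default residue range follows the assigned EF-SAM core (62-205 in the
    construct's native numbering); the two default perturbed spans emulate the
    entering helix of the canonical EF-hand and the non-canonical EF-hand exit
    helix / SAM linker region where the published perturbations cluster.
    """

    first_residue: int = 62
    last_residue: int = 205
    h_range: tuple[float, float] = (6.5, 11.0)
    n_range: tuple[float, float] = (105.0, 130.0)
    # (start, end, delta_h, delta_n) per perturbed span
    perturbed_spans: tuple[tuple[int, int, float, float], ...] = (
        (68, 76, 0.08, 0.8),    # alpha1-like span
        (130, 142, 0.10, 1.0),  # alpha4/alpha5-like span
    )
    jitter_h: float = 0.0  # sd of unrelated shift jitter on the modified list
    jitter_n: float = 0.0
    missing_in_modified: tuple[int, ...] = ()  # residues vanishing on modification
    extra_unassigned: int = 0  # unassigned peaks added to the modified list

    def __post_init__(self) -> None:
        for s, e, _, _ in self.perturbed_spans:
            if not (self.first_residue <= s <= e <= self.last_residue):
                raise ValueError(
                    f"perturbed span ({s}, {e}) outside residue range "
                    f"[{self.first_residue}, {self.last_residue}]"
                )
        if self.jitter_h < 0 or self.jitter_n < 0:
            raise ValueError("jitter must be >= 0")


_AA = "ACDEFGHIKLMNPQRSTVWY"


def gen_peaklist_pair(truth: CspTruth, seed: int) -> tuple[PeakList, PeakList]:
    """Reference and modified peak lists with declared perturbations.

    Reference shifts are uniform in the amide windows; the modified list applies
    the span's (dH, dN) to perturbed residues, optional Gaussian jitter
    everywhere, drops ``missing_in_modified`` residues and appends
    ``extra_unassigned`` peaks.
    """
    rng = _rng(seed)
    residues = np.arange(truth.first_residue, truth.last_residue + 1)
    h = rng.uniform(*truth.h_range, size=residues.size)
    n = rng.uniform(*truth.n_range, size=residues.size)
    aa = rng.choice(list(_AA), size=residues.size)

    delta_h = np.zeros(residues.size)
    delta_n = np.zeros(residues.size)
    for s, e, dh, dn in truth.perturbed_spans:
        mask = (residues >= s) & (residues <= e)
        delta_h[mask] = dh
        delta_n[mask] = dn
    if truth.jitter_h > 0:
        delta_h = delta_h + rng.normal(0.0, truth.jitter_h, size=residues.size)
    if truth.jitter_n > 0:
        delta_n = delta_n + rng.normal(0.0, truth.jitter_n, size=residues.size)

    ref_peaks, mod_peaks = [], []
    for i, r in enumerate(residues):
        label = f"{aa[i]}{r}N-H"
        ref_peaks.append(Peak(int(r), label, float(h[i]), float(n[i])))
        if int(r) in truth.missing_in_modified:
            continue
        mod_peaks.append(
            Peak(int(r), label, float(h[i] + delta_h[i]), float(n[i] + delta_n[i]))
        )
    for _ in range(truth.extra_unassigned):
        mod_peaks.append(
            Peak(None, "?-?",
                 float(rng.uniform(*truth.h_range)),
                 float(rng.uniform(*truth.n_range)))
        )
    return (
        PeakList(tuple(ref_peaks), spectrum_label="reference"),
        PeakList(tuple(mod_peaks), spectrum_label="modified"),
    )


@dataclass(frozen=True)
class FuraTruth:
    """Ground truth for one Fura-2 record.

    The event schedule leaves the 450-550 s SOCE window after the Ca2+ addback
    inside a 600-s record sampled at 1 s. ``basal_nM`` defaults to the control
    resting level; ``soce_ff0`` is the suspension-protocol plateau fold change,
    ``soce_delta`` the plate-protocol ratio difference.
    """

    calib: CalibrationParams = field(default_factory=CalibrationParams)
    basal_nM: float = 118.0
    egta_drop: float = 0.05      # ratio-unit step down on EGTA
    tg_amplitude: float = 0.30   # ratio-unit store-release transient
    tg_decay_s: float = 40.0
    soce_ff0: float = 2.5        # suspension plateau, F/F0
    soce_delta: float = 1.0      # plate plateau, ratio units over F0
    soce_rise_s: float = 8.0
    egta_s: float = 100.0
    tg_s: float = 200.0
    addback_s: float = 400.0
    duration_s: float = 600.0
    dt_s: float = 1.0
    f380_level: float = 500.0    # AU, saturated-dye reference level
    noise_sd: float = 0.5        # AU, per fluorescence channel
    calib_segment_n: int = 30

    def __post_init__(self) -> None:
        if not (0 <= self.egta_s < self.tg_s < self.addback_s <= self.duration_s):
            raise ValueError("events must satisfy 0 <= egta < tg < addback <= end")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _true_ratio(truth: FuraTruth, t: np.ndarray, protocol: str) -> np.ndarray:
    r_basal = ratio_for_concentration(truth.basal_nM, truth.calib)
    r0 = r_basal - truth.egta_drop  # post-EGTA baseline
    r = np.full(t.size, r_basal)

    after_egta = t >= truth.egta_s
    r[after_egta] = r0

    after_tg = t >= truth.tg_s
    r[after_tg] = r0 + truth.tg_amplitude * np.exp(
        -(t[after_tg] - truth.tg_s) / truth.tg_decay_s
    )

    plateau = truth.soce_ff0 * r0 if protocol == "suspension" else r0 + truth.soce_delta
    after_add = t >= truth.addback_s
    rise = 1.0 - np.exp(-(t[after_add] - truth.addback_s) / truth.soce_rise_s)
    r[after_add] = r[after_add] + (plateau - r[after_add]) * rise
    return r


def gen_fura_trace(
    truth: FuraTruth,
    seed: int,
    protocol: str = "suspension",
) -> tuple[FuraTrace, dict]:
    """One ratiometric record plus end-of-run calibration segments.

    The basal ratio comes from algebraically inverting the ratiometric
    calibration at the truth's basal nM; EGTA steps the ratio down, TG adds a
    decaying store-release transient, and the Ca2+ addback rises to the SOCE
    plateau. F340/F380 are decomposed so that the Ca2+-free dye carries
    ``beta``-fold the saturated F380, and each channel gets additive noise.

    Returns ``(trace, segments)`` where ``segments`` holds ``triton_ratio``,
    ``egta_ratio``, ``triton_f380`` and ``egta_f380`` arrays for
    :func:`lumistab.fura.derive_calibration`.
    """
    rng = _rng(seed)
    t = np.arange(0.0, truth.duration_s + truth.dt_s / 2, truth.dt_s)
    r = _true_ratio(truth, t, protocol)

    # F380 interpolates between the saturated level and beta-fold that level as
    # the dye moves from Ca2+-bound (high ratio) toward Ca2+-free (low ratio).
    calib = truth.calib
    frac_free = (calib.r_max - r) / (calib.r_max - calib.r_min)
    f380 = truth.f380_level * (1.0 + (calib.beta - 1.0) * frac_free)
    f340 = r * f380
    f340 = f340 + rng.normal(0.0, truth.noise_sd, size=t.size)
    f380 = f380 + rng.normal(0.0, truth.noise_sd, size=t.size)

    trace = FuraTrace(
        t, f340, f380,
        events={"egta_add": truth.egta_s, "tg_add": truth.tg_s,
                "ca_addback": truth.addback_s},
        protocol=protocol,
    )

    k = truth.calib_segment_n
    sat_f380 = truth.f380_level + rng.normal(0.0, truth.noise_sd, size=k)
    free_f380 = calib.beta * truth.f380_level + rng.normal(0.0, truth.noise_sd, size=k)
    sat_f340 = calib.r_max * truth.f380_level + rng.normal(0.0, truth.noise_sd, size=k)
    free_f340 = calib.r_min * calib.beta * truth.f380_level + rng.normal(
        0.0, truth.noise_sd, size=k
    )
    segments = {
        "triton_ratio": sat_f340 / sat_f380,
        "egta_ratio": free_f340 / free_f380,
        "triton_f380": sat_f380,
        "egta_f380": free_f380,
    }
    return trace, segments
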