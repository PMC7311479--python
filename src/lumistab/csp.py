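"""Chemical-shift perturbation (CSP) analysis of paired 1H-15N HSQC peak lists.

Two peak lists — a reference condition and a modified condition — are matched
per residue (or by distance for unassigned data) and the combined amide
perturbation is computed with the standard nitrogen down-weighting

    CSP = sqrt( (dH)^2 + (w * dN)^2 ),   w = 0.14 by default,

which rescales the wider 15N ppm range onto the 1H scale. Residues whose CSP
exceeds a threshold (by default an iteratively trimmed mean + 1 SD) are grouped
into sequence clusters, and per-residue values can be written into the B-factor
column of a PDB file for colouring on a structure.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from io import StringIO
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_NITROGEN_WEIGHT",
    "Peak",
    "PeakList",
    "CSPProfile",
    "CSPCluster",
    "MatchResult",
    "read_peaklist",
    "match_peaks",
    "compute_csp",
    "csp_threshold",
    "detect_clusters",
    "map_to_structure",
]

DEFAULT_NITROGEN_WEIGHT = 0.14

# amide shift sanity windows (soft check only)
_H_RANGE = (5.0, 12.0)
_N_RANGE = (100.0, 135.0)


@dataclass(frozen=True)
class Peak:
    residue_number: int | None
    assignment_label: str
    h_shift: float
    n_shift: float


@dataclass(frozen=True)
class PeakList:
    """An assigned (or partially assigned) 1H-15N peak list."""

    peaks: tuple[Peak, ...]
    spectrum_label: str = ""

    def __post_init__(self) -> None:
        seen: dict[int, int] = {}
        dupes = []
        for p in self.peaks:
            if not (np.isfinite(p.h_shift) and np.isfinite(p.n_shift)):
                raise ValueError(f"non-finite shift in peak {p.assignment_label!r}")
            if p.residue_number is not None:
                if p.residue_number in seen:
                    dupes.append(p.residue_number)
                seen[p.residue_number] = 1
        if dupes:
            raise ValueError(f"duplicate residue numbers in peak list: {sorted(set(dupes))}")
        h = [p.h_shift for p in self.peaks]
        n = [p.n_shift for p in self.peaks]
        if h and (min(h) < _H_RANGE[0] or max(h) > _H_RANGE[1]
                  or min(n) < _N_RANGE[0] or max(n) > _N_RANGE[1]):
            warnings.warn(
                "shifts outside typical amide windows "
                f"(1H {_H_RANGE}, 15N {_N_RANGE} ppm); check axis order",
                stacklevel=3,
            )

    def __len__(self) -> int:
        return len(self.peaks)

    @property
    def assigned(self) -> dict[int, Peak]:
        return {p.residue_number: p for p in self.peaks if p.residue_number is not None}

    @property
    def unassigned(self) -> tuple[Peak, ...]:
        return tuple(p for p in self.peaks if p.residue_number is None)


_ASSIGNMENT_RE = re.compile(r"^[A-Za-z]{1,3}(\d+)")


def _residue_from_label(label: str) -> int | None:
    m = _ASSIGNMENT_RE.match(label.strip())
    return int(m.group(1)) if m else None


def read_peaklist(path: str | Path, spectrum_label: str | None = None) -> PeakList:
    """Read a Sparky-style whitespace table or a residue,h_ppm,n_ppm CSV.

    Sparky convention for a 15N-HSQC list: columns ``Assignment  w1  w2`` with
    w1 the 15N shift and w2 the 1H shift; assignments like ``G109N-H`` yield
    residue number 109. Peaks whose assignment cannot be parsed (e.g. ``?-?``)
    are kept as unassigned records with a warning.
    """
    path = Path(path)
    text = path.read_text()
    label = spectrum_label if spectrum_label is not None else path.stem

    first = next((ln for ln in text.splitlines() if ln.strip()), "")
    if "," in first:
        df = pd.read_csv(StringIO(text))
        cols = {c.lower().strip(): c for c in df.columns}
        try:
            res_c, h_c, n_c = cols["residue"], cols["h_ppm"], cols["n_ppm"]
        except KeyError as exc:
            raise ValueError(f"{path}: expected CSV columns residue,h_ppm,n_ppm") from exc
        peaks = tuple(
            Peak(int(r[res_c]), str(r.get("assignment", r[res_c])),
                 float(r[h_c]), float(r[n_c]))
            for _, r in df.iterrows()
        )
        return PeakList(peaks, spectrum_label=label)

    peaks = []
    n_skipped = 0
    for line in text.splitlines():
        line = line.strip()
        if not line or line.lower().startswith("assignment"):
            continue
        parts = line.split()
        if len(parts) < 3:
            n_skipped += 1
            continue
        label_s, w1, w2 = parts[0], parts[1], parts[2]
        try:
            n_shift, h_shift = float(w1), float(w2)  # w1 = 15N, w2 = 1H
        except ValueError:
            n_skipped += 1
            continue
        resnum = _residue_from_label(label_s)
        if resnum is None and label_s not in ("?-?", "?"):
            warnings.warn(f"unparseable assignment {label_s!r}; kept unassigned",
                          stacklevel=2)
        peaks.append(Peak(resnum, label_s, h_shift, n_shift))
    if n_skipped:
        warnings.warn(f"{path}: skipped {n_skipped} malformed line(s)", stacklevel=2)
    return PeakList(tuple(peaks), spectrum_label=label)


def weighted_distance(p: Peak, q: Peak, nitrogen_weight: float = DEFAULT_NITROGEN_WEIGHT) -> float:
    """Weighted ppm distance between two peaks (the CSP metric)."""
    return float(np.hypot(p.h_shift - q.h_shift, nitrogen_weight * (p.n_shift - q.n_shift)))


@dataclass(frozen=True)
class MatchResult:
    pairs: tuple[tuple[Peak, Peak], ...]
    unmatched_reference: tuple[Peak, ...]
    unmatched_modified: tuple[Peak, ...]


def match_peaks(
    reference: PeakList,
    modified: PeakList,
    cutoff: float = 0.2,
    by_assignment: bool = True,
    nitrogen_weight: float = DEFAULT_NITROGEN_WEIGHT,
) -> MatchResult:
    """Pair peaks between two conditions.

    By default pairing is by residue number (assignments transferred between
    spectra). With ``by_assignment=False`` a greedy minimum-distance pairing in
    weighted shift space is used instead, accepting pairs with distance <=
    ``cutoff`` (weighted ppm); each peak is used at most once. Unmatched peaks
    on either side are reported, never dropped silently.
    """
    if len(reference) == 0 or len(modified) == 0:
        raise ValueError("peak lists must be non-empty")

    if by_assignment:
        ref_map, mod_map = reference.assigned, modified.assigned
        common = sorted(set(ref_map) & set(mod_map))
        pairs = tuple((ref_map[r], mod_map[r]) for r in common)
        un_ref = tuple(p for p in reference.peaks
                       if p.residue_number not in common)
        un_mod = tuple(p for p in modified.peaks
                       if p.residue_number not in common)
        return MatchResult(pairs, un_ref, un_mod)

    # greedy: repeatedly take the globally closest remaining pair
    ref_left = list(reference.peaks)
    mod_left = list(modified.peaks)
    dist = np.array(
        [[weighted_distance(p, q, nitrogen_weight) for q in mod_left] for p in ref_left]
    )
    pairs = []
    while ref_left and mod_left and dist.size:
        i, j = np.unravel_index(np.argmin(dist), dist.shape)
        if dist[i, j] > cutoff:
            break
        pairs.append((ref_left[i], mod_left[j]))
        ref_left.pop(i)
        mod_left.pop(j)
        dist = np.delete(np.delete(dist, i, axis=0), j, axis=1)
    return MatchResult(tuple(pairs), tuple(ref_left), tuple(mod_left))


@dataclass(frozen=True)
class CSPProfile:
    """Per-residue weighted chemical-shift perturbations."""

    csp: dict[int, float]
    nitrogen_weight: float = DEFAULT_NITROGEN_WEIGHT
    matched: int = 0
    unmatched_reference: tuple[str, ...] = ()
    unmatched_modified: tuple[str, ...] = ()
    threshold: float | None = None

    def __post_init__(self) -> None:
        if self.nitrogen_weight <= 0:
            raise ValueError("nitrogen weight must be positive")
        if any(v < 0 for v in self.csp.values()):
            raise ValueError("CSP values cannot be negative")

    def residues(self) -> list[int]:
        return sorted(self.csp)

    def values(self) -> np.ndarray:
        return np.array([self.csp[r] for r in self.residues()])

    def with_threshold(self, threshold: float) -> "CSPProfile":
        return CSPProfile(
            dict(self.csp), self.nitrogen_weight, self.matched,
            self.unmatched_reference, self.unmatched_modified, threshold,
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"residue": self.residues(), "csp_ppm": self.values()}
        )
        if self.threshold is not None:
            df["above_threshold"] = df["csp_ppm"] > self.threshold
        return df


def compute_csp(
    pairs: MatchResult | Iterable[tuple[Peak, Peak]],
    nitrogen_weight: float = DEFAULT_NITROGEN_WEIGHT,
) -> CSPProfile:
    """Weighted CSP per residue: sqrt(dH^2 + (w*dN)^2).

    Pairs whose reference peak is unassigned contribute to the match count but
    not to the per-residue profile.
    """
    if isinstance(pairs, MatchResult):
        pair_list = pairs.pairs
        un_ref = tuple(p.assignment_label for p in pairs.unmatched_reference)
        un_mod = tuple(p.assignment_label for p in pairs.unmatched_modified)
    else:
        pair_list = tuple(pairs)
        un_ref = un_mod = ()
    csp = {
        p.residue_number: weighted_distance(p, q, nitrogen_weight)
        for p, q in pair_list
        if p.residue_number is not None
    }
    return CSPProfile(
        csp=csp,
        nitrogen_weight=nitrogen_weight,
        matched=len(pair_list),
        unmatched_reference=un_ref,
        unmatched_modified=un_mod,
    )


def csp_threshold(
    profile: CSPProfile,
    method: str = "trimmed_mean_sd",
    fixed_value: float | None = None,
) -> float:
    """Significance threshold for a CSP profile.

    ``"trimmed_mean_sd"`` (default, standard CSP practice): iteratively exclude
    values above mean + 3*SD until stable, then return mean + 1*SD of the kept
    values. ``"fixed"``: return ``fixed_value`` unchanged.
    """
    if method == "fixed":
        if fixed_value is None:
            raise ValueError("fixed method requires fixed_value")
        return float(fixed_value)
    if method != "trimmed_mean_sd":
        raise ValueError(f"unknown threshold method {method!r}")
    vals = profile.values()
    if vals.size < 5:
        raise ValueError("need >= 5 residues with CSP values for a threshold")
    kept = vals.copy()
    while True:
        mu, sd = kept.mean(), kept.std(ddof=0)
        mask = kept <= mu + 3.0 * sd
        if mask.all():
            break
        kept = kept[mask]
    return float(kept.mean() + kept.std(ddof=0))


@dataclass(frozen=True)
class CSPCluster:
    """A contiguous stretch of significantly perturbed residues."""

    start_residue: int
    end_residue: int
    mean_csp: float
    max_csp: float
    n_above: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.start_residue > self.end_residue:
            raise ValueError("cluster start must be <= end")


def detect_clusters(
    profile: CSPProfile,
    threshold: float | None = None,
    min_length: int = 3,
    max_gap: int = 1,
) -> list[CSPCluster]:
    """Find sequence clusters of perturbation.

    A cluster is a maximal run of residues with CSP > ``threshold``, allowing up
    to ``max_gap`` consecutive below-threshold or missing residues inside the
    run. Runs spanning fewer than ``min_length`` residues are discarded.
    Clusters are returned ordered by start residue.
    """
    if threshold is None:
        threshold = profile.threshold
    if threshold is None:
        threshold = csp_threshold(profile)
    if threshold <= 0:
        raise ValueError("threshold must be positive")

    above = sorted(r for r, v in profile.csp.items() if v > threshold)
    clusters: list[CSPCluster] = []
    if not above:
        return clusters

    run = [above[0]]
    for r in above[1:]:
        if r - run[-1] <= max_gap + 1:
            run.append(r)
        else:
            clusters.append(_make_cluster(run, profile))
            run = [r]
    clusters.append(_make_cluster(run, profile))
    return [c for c in clusters if c.end_residue - c.start_residue + 1 >= min_length]


def _make_cluster(run: list[int], profile: CSPProfile) -> CSPCluster:
    vals = [profile.csp[r] for r in run]
    return CSPCluster(
        start_residue=run[0],
        end_residue=run[-1],
        mean_csp=float(np.mean(vals)),
        max_csp=float(np.max(vals)),
        n_above=len(run),
    )


def map_to_structure(
    profile: CSPProfile,
    pdb_path: str | Path,
    chain: str = "A",
    out_pdb: str | Path | None = None,
    out_tsv: str | Path | None = None,
    threshold: float | None = None,
) -> pd.DataFrame:
    """Write per-residue CSPs into a PDB B-factor column for structure colouring.

    The temperature-factor of every atom in ``chain`` is replaced by
    ``100 * CSP`` (capped at 999.99 for the fixed-width column); residues with
    no CSP get 0. Also returns (and optionally writes as TSV) the per-residue
    table with an above-threshold flag and a ``mapped`` flag; profile residues
    absent from the structure appear in the table with ``mapped=False`` rather
    than raising.
    """
    from Bio.PDB import PDBParser, PDBIO

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("input", str(pdb_path))
    model = next(structure.get_models())
    if chain not in [c.id for c in model]:
        raise ValueError(
            f"chain {chain!r} not in structure (has {[c.id for c in model]})"
        )
    struct_residues = {
        res.id[1] for res in model[chain] if res.id[0] == " "
    }
    prof_residues = set(profile.csp)
    if not (struct_residues & prof_residues):
        raise ValueError(
            "no residue-number overlap between profile "
            f"[{min(prof_residues)}-{max(prof_residues)}] and chain {chain} "
            f"[{min(struct_residues)}-{max(struct_residues)}]"
        )

    for res in model[chain]:
        val = profile.csp.get(res.id[1], 0.0)
        b = min(100.0 * val, 999.99)
        for atom in res:
            atom.set_bfactor(b)

    if out_pdb is not None:
        io = PDBIO()
        io.set_structure(structure)
        io.save(str(out_pdb))

    if threshold is None:
        threshold = profile.threshold
    rows = []
    for r in sorted(prof_residues | struct_residues):
        val = profile.csp.get(r)
        rows.append({
            "residue": r,
            "csp_ppm": val if val is not None else 0.0,
            "above_threshold": (val is not None and threshold is not None
                                and val > threshold),
            "mapped": r in struct_residues,
            "observed": r in prof_residues,
        })
    table = pd.DataFrame(rows)
    if out_tsv is not None:
        table.to_csv(out_tsv, sep="\t", index=False)
    return table
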