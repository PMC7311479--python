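"""CSP engine: parsing, matching, the weighted formula, clustering, mapping."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lumistab.csp import (
    CSPProfile,
    Peak,
    PeakList,
    compute_csp,
    csp_threshold,
    detect_clusters,
    map_to_structure,
    match_peaks,
    read_peaklist,
    weighted_distance,
)
from lumistab.simulate import CspTruth, gen_peaklist_pair


class TestReadPeaklist:
    def test_sparky_three_lines(self, sparky_file):
        pl = read_peaklist(sparky_file)
        assert len(pl) == 3
        by_res = pl.assigned
        assert by_res[109].h_shift == pytest.approx(8.456)
        assert by_res[109].n_shift == pytest.approx(110.123)

    def test_duplicate_residue_named_in_error(self, tmp_path):
        p = tmp_path / "dup.list"
        p.write_text(
            "Assignment w1 w2\nA42N-H 118.0 7.9\nG42N-H 119.0 8.1\n"
        )
        with pytest.raises(ValueError, match="42"):
            read_peaklist(p)

    def test_csv_and_sparky_dialects_agree(self, tmp_path, sparky_file):
        csv = tmp_path / "same.csv"
        csv.write_text(
            "residue,h_ppm,n_ppm\n109,8.456,110.123\n42,7.900,118.500\n"
            "205,10.220,125.010\n"
        )
        a, b = read_peaklist(sparky_file), read_peaklist(csv)
        assert {(p.residue_number, p.h_shift, p.n_shift) for p in a.peaks} == \
               {(p.residue_number, p.h_shift, p.n_shift) for p in b.peaks}

    def test_unparseable_assignment_kept_unassigned(self, tmp_path):
        p = tmp_path / "un.list"
        p.write_text("A42N-H 118.0 7.9\n?-? 120.0 8.5\n")
        pl = read_peaklist(p)
        assert len(pl.unassigned) == 1
        assert len(pl.assigned) == 1


def brute_force_min_assignment(ref, mod, weight=0.14):
    """Exhaustive minimum-total-distance pairing oracle (n <= 8)."""
    best = (np.inf, None)
    for perm in itertools.permutations(range(len(mod.peaks))):
        total = sum(
            weighted_distance(ref.peaks[i], mod.peaks[j], weight)
            for i, j in enumerate(perm)
        )
        if total < best[0]:
            best = (total, perm)
    return best


class TestMatchPeaks:
    def test_identical_lists_all_matched(self):
        ref, _ = gen_peaklist_pair(CspTruth(), seed=0)
        res = match_peaks(ref, ref)
        assert len(res.pairs) == len(ref)
        assert not res.unmatched_reference and not res.unmatched_modified

    def test_uniform_proton_shift_distance_matching(self):
        # well-separated grid so nearest neighbours are unambiguous
        ref = PeakList(tuple(
            Peak(i + 1, f"A{i + 1}N-H", 6.5 + 0.4 * i, 108.0 + 2.0 * i)
            for i in range(10)
        ))
        shifted = PeakList(
            tuple(Peak(p.residue_number, p.assignment_label,
                       p.h_shift + 0.05, p.n_shift) for p in ref.peaks)
        )
        res = match_peaks(ref, shifted, cutoff=0.2, by_assignment=False)
        assert len(res.pairs) == len(ref)
        for p, q in res.pairs:
            assert weighted_distance(p, q) == pytest.approx(0.05)
            assert p.residue_number == q.residue_number

    def test_greedy_equals_exhaustive_on_separated_peaks(self, rng):
        # perturbations far smaller than peak separation: the greedy pairing
        # must coincide with the exhaustive minimum-total-distance assignment
        for trial in range(5):
            n = 7
            h = rng.uniform(6.5, 11.0, n)
            nn = rng.uniform(105.0, 130.0, n)
            ref = PeakList(tuple(
                Peak(i + 1, f"A{i + 1}N-H", float(h[i]), float(nn[i]))
                for i in range(n)
            ))
            mod = PeakList(tuple(
                Peak(i + 1, f"A{i + 1}N-H",
                     float(h[i] + rng.normal(0, 0.005)),
                     float(nn[i] + rng.normal(0, 0.05)))
                for i in range(n)
            ))
            res = match_peaks(ref, mod, cutoff=0.2, by_assignment=False)
            total_greedy = sum(weighted_distance(p, q) for p, q in res.pairs)
            total_opt, perm = brute_force_min_assignment(ref, mod)
            assert len(res.pairs) == n
            assert total_greedy == pytest.approx(total_opt, abs=1e-12)

    def test_unmatched_reported(self):
        truth = CspTruth(missing_in_modified=(70, 71), extra_unassigned=2)
        ref, mod = gen_peaklist_pair(truth, seed=4)
        res = match_peaks(ref, mod)
        assert {p.residue_number for p in res.unmatched_reference} == {70, 71}
        assert len(res.unmatched_modified) == 2


class TestComputeCsp:
    @pytest.mark.parametrize(
        "dh, dn, want",
        [
            (0.1, 0.0, 0.1),     # pure proton
            (0.0, 1.0, 0.14),    # the nitrogen weight itself
            (0.03, 0.5, 0.07616),  # sqrt(0.0009 + 0.0049), hand arithmetic
        ],
    )
    def test_weighted_formula(self, dh, dn, want):
        ref = Peak(10, "A10N-H", 8.0, 120.0)
        mod = Peak(10, "A10N-H", 8.0 + dh, 120.0 + dn)
        prof = compute_csp([(ref, mod)])
        assert prof.csp[10] == pytest.approx(want, abs=5e-5)

    def test_symmetric_under_condition_swap(self):
        ref, mod = gen_peaklist_pair(CspTruth(), seed=5)
        fwd = compute_csp(match_peaks(ref, mod))
        rev = compute_csp(match_peaks(mod, ref))
        assert fwd.csp == pytest.approx(rev.csp)

    def test_invariant_to_global_referencing_offset(self):
        ref, mod = gen_peaklist_pair(CspTruth(), seed=6)
        off_h, off_n = 0.13, 1.7
        shift = lambda pl: PeakList(tuple(
            Peak(p.residue_number, p.assignment_label,
                 p.h_shift + off_h, p.n_shift + off_n) for p in pl.peaks
        ))
        a = compute_csp(match_peaks(ref, mod))
        b = compute_csp(match_peaks(shift(ref), shift(mod)))
        assert a.csp == pytest.approx(b.csp)

    def test_unit_weight_is_euclidean(self):
        ref = Peak(1, "A1N-H", 8.0, 120.0)
        mod = Peak(1, "A1N-H", 8.3, 120.4)
        prof = compute_csp([(ref, mod)], nitrogen_weight=1.0)
        assert prof.csp[1] == pytest.approx(np.hypot(0.3, 0.4))

    def test_no_perturbation_all_zero(self):
        ref, mod = gen_peaklist_pair(CspTruth(perturbed_spans=()), seed=7)
        prof = compute_csp(match_peaks(ref, mod))
        assert all(v == 0.0 for v in prof.csp.values())


def trimmed_mean_sd_oracle(values):
    """Spreadsheet-style recomputation of the iterative 3-SD trimmed mean + SD."""
    vals = list(values)
    while True:
        mu = sum(vals) / len(vals)
        sd = (sum((v - mu) ** 2 for v in vals) / len(vals)) ** 0.5
        kept = [v for v in vals if v <= mu + 3 * sd]
        if len(kept) == len(vals):
            return mu + sd
        vals = kept


class TestThreshold:
    def test_constant_profile(self):
        prof = CSPProfile({i: 0.07 for i in range(1, 9)})
        assert csp_threshold(prof) == pytest.approx(0.07)

    def test_against_arithmetic_oracle(self):
        vals = {1: 0.0, 2: 0.0, 3: 0.0, 4: 0.0, 5: 1.0}
        prof = CSPProfile(vals)
        assert csp_threshold(prof) == pytest.approx(
            trimmed_mean_sd_oracle(vals.values())
        )

    def test_oracle_on_realistic_profile(self, rng):
        vals = {i: float(v) for i, v in enumerate(np.abs(rng.normal(0.01, 0.01, 50)))}
        vals[20], vals[21] = 0.5, 0.6  # outliers that the trim must exclude
        prof = CSPProfile(vals)
        assert csp_threshold(prof) == pytest.approx(
            trimmed_mean_sd_oracle(vals.values())
        )

    def test_fixed_method(self):
        prof = CSPProfile({i: 0.1 for i in range(6)})
        assert csp_threshold(prof, method="fixed", fixed_value=0.05) == 0.05

    def test_small_profile_rejected(self):
        with pytest.raises(ValueError):
            csp_threshold(CSPProfile({1: 0.1, 2: 0.2}))


def enumerate_clusters_oracle(csp_map, threshold, min_length, max_gap):
    """Brute-force run enumeration: scan residues in order, splitting whenever
    the gap between consecutive above-threshold residues exceeds max_gap."""
    above = sorted(r for r, v in csp_map.items() if v > threshold)
    runs, cur = [], []
    for r in above:
        if cur and r - cur[-1] > max_gap + 1:
            runs.append(cur)
            cur = []
        cur.append(r)
    if cur:
        runs.append(cur)
    return [
        (run[0], run[-1]) for run in runs
        if run[-1] - run[0] + 1 >= min_length
    ]


class TestClusters:
    def test_single_run(self):
        vals = {r: 0.01 for r in range(1, 31)}
        for r in range(10, 15):
            vals[r] = 0.3
        prof = CSPProfile(vals)
        out = detect_clusters(prof, threshold=0.1)
        assert [(c.start_residue, c.end_residue) for c in out] == [(10, 14)]

    def test_two_published_style_clusters(self):
        ref, mod = gen_peaklist_pair(CspTruth(), seed=12)
        prof = compute_csp(match_peaks(ref, mod))
        thr = csp_threshold(prof)
        out = detect_clusters(prof, thr)
        assert len(out) == 2
        spans = [(c.start_residue, c.end_residue) for c in out]
        assert spans == [(68, 76), (130, 142)]

    def test_matches_enumeration_oracle_random(self, rng):
        for trial in range(10):
            vals = {int(r): float(abs(v)) for r, v in
                    zip(rng.choice(np.arange(1, 31), 25, replace=False),
                        rng.normal(0.05, 0.05, 25))}
            prof = CSPProfile(vals)
            got = [(c.start_residue, c.end_residue)
                   for c in detect_clusters(prof, threshold=0.08)]
            want = enumerate_clusters_oracle(vals, 0.08, 3, 1)
            assert got == want

    def test_order_invariance(self):
        vals = {r: (0.3 if 10 <= r <= 14 else 0.01) for r in range(1, 31)}
        shuffled = dict(sorted(vals.items(), key=lambda kv: -kv[0]))
        a = detect_clusters(CSPProfile(vals), threshold=0.1)
        b = detect_clusters(CSPProfile(shuffled), threshold=0.1)
        assert a == b


class TestStructureMapping:
    def test_bfactor_written_and_round_trip(self, toy_pdb, tmp_path):
        prof = CSPProfile({1: 0.1})
        out_pdb = tmp_path / "mapped.pdb"
        table = map_to_structure(prof, toy_pdb, chain="A", out_pdb=out_pdb)
        assert table.loc[table.residue == 1, "csp_ppm"].item() == pytest.approx(0.1)

        # parse-back oracle: fixed-width B-factor column, 2 decimals
        bvals = {}
        for line in out_pdb.read_text().splitlines():
            if line.startswith("ATOM"):
                bvals.setdefault(int(line[22:26]), float(line[60:66]))
        assert bvals[1] == pytest.approx(10.00, abs=0.005)
        assert bvals[2] == bvals[3] == 0.0

    def test_unmapped_residue_reported_not_error(self, toy_pdb):
        prof = CSPProfile({1: 0.1, 99: 0.5})
        table = map_to_structure(prof, toy_pdb, chain="A")
        row = table[table.residue == 99]
        assert not row.mapped.item() and row.observed.item()

    def test_zero_overlap_is_error(self, toy_pdb):
        with pytest.raises(ValueError, match="overlap"):
            map_to_structure(CSPProfile({50: 0.1, 51: 0.2}), toy_pdb, chain="A")

    def test_cap_at_format_limit(self, toy_pdb, tmp_path):
        out_pdb = tmp_path / "cap.pdb"
        map_to_structure(CSPProfile({1: 55.0}), toy_pdb, chain="A", out_pdb=out_pdb)
        line = next(l for l in out_pdb.read_text().splitlines() if l.startswith("ATOM"))
        assert float(line[60:66]) == pytest.approx(999.99)
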