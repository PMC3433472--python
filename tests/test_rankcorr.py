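import itertools
import math

import numpy as np
import pytest
from scipy import stats as scistats

from selexkit.distfam import Family
from selexkit.errors import InputError
from selexkit.rankcorr import (
    CandidateSet, EnrichmentProfile, compare_candidate_sets,
    correlate_internalization, find_orphans, fold_enrichment,
    normalize_read_counts, rate_enrichment, rising_score, round_totals,
    score_windows, select_family_representatives, select_representatives,
    spearman_correlation, window_rounds,
)

from conftest import make_record


def profile(abundance, reads=None, total=None, seq_id=1):
    reads = reads or {r: int(a * 1000) for r, a in abundance.items()}
    return EnrichmentProfile(
        sequence_id=seq_id, abundance=abundance, reads=reads,
        total_reads=total if total is not None else sum(reads.values()))


class TestNormalization:
    def test_plain_fraction(self):
        recs = [make_record(1, "AAAA", {1: 10}), make_record(2, "CCCC", {1: 990})]
        profs = normalize_read_counts(recs, [1])
        assert profs[1].abundance[1] == pytest.approx(0.01)

    def test_zero_count_substitution(self):
        recs = [make_record(1, "AAAA", {1: 0, 2: 5}), make_record(2, "CCCC", {1: 1000, 2: 5})]
        profs = normalize_read_counts(recs, [1, 2])
        assert profs[1].abundance[1] == pytest.approx(1 / 1000)

    def test_sole_sequence_has_abundance_one(self):
        recs = [make_record(1, "AAAA", {1: 500})]
        profs = normalize_read_counts(recs, [1])
        assert profs[1].abundance[1] == 1.0

    def test_totals_from_full_database(self):
        full = [make_record(1, "AAAA", {1: 10}), make_record(2, "CCCC", {1: 90})]
        subset = full[:1]
        profs = normalize_read_counts(subset, [1], totals=round_totals(full))
        assert profs[1].abundance[1] == pytest.approx(0.1)

    def test_empty_round_raises(self):
        with pytest.raises(Exception):
            normalize_read_counts([make_record(1, "AAAA", {1: 5})], [1, 2])


class TestWindowScores:
    def test_fold_enrichment_ratio(self):
        p = profile({1: 0.004, 8: 0.016})
        assert fold_enrichment(p, 1, 8) == pytest.approx(4.0)

    def test_equal_abundance_fe_one(self):
        p = profile({1: 0.01, 8: 0.01})
        assert fold_enrichment(p, 1, 8) == 1.0

    def test_zero_substituted_path_is_finite(self):
        recs = [make_record(1, "AAAA", {1: 0, 8: 100}),
                make_record(2, "CCCC", {1: 1000, 8: 900})]
        profs = normalize_read_counts(recs, [1, 8])
        fe = fold_enrichment(profs[1], 1, 8)
        assert math.isfinite(fe) and fe > 1

    def test_rate_enrichment_rpm_per_round(self):
        p = profile({3: 10 / 1e6, 8: 100 / 1e6})
        assert rate_enrichment(p, 3, 8) == pytest.approx(18.0)

    def test_rate_enrichment_signs(self):
        assert rate_enrichment(profile({1: 0.01, 2: 0.01}), 1, 2) == 0.0
        assert rate_enrichment(profile({1: 0.02, 2: 0.01}), 1, 2) < 0

    def test_rising_linear_trends(self):
        up = profile({1: 0.001, 2: 0.002, 3: 0.003, 4: 0.004})
        down = profile({1: 0.004, 2: 0.003, 3: 0.002, 4: 0.001})
        flat = profile({1: 0.002, 2: 0.002, 3: 0.002})
        assert rising_score(up, [1, 2, 3, 4]) == pytest.approx(1.0)
        assert rising_score(down, [1, 2, 3, 4]) == pytest.approx(-1.0)
        assert rising_score(flat, [1, 2, 3]) == 0.0

    def test_rising_needs_three_rounds(self):
        assert rising_score(profile({1: 0.1, 2: 0.2}), [1, 2]) is None

    def test_rising_in_unit_interval(self, rng):
        for _ in range(20):
            ab = {r: float(a) for r, a in
                  enumerate(rng.uniform(1e-4, 1e-2, size=5), start=1)}
            rho = rising_score(profile(ab), list(ab))
            assert -1.0 <= rho <= 1.0

    def test_fe_scale_invariance(self, rng):
        counts = {1: 7, 3: 19, 5: 40}
        others = {1: 993, 3: 981, 5: 960}
        for scale in (1, 10, 137):
            recs = [make_record(1, "AAAA", {r: c * scale for r, c in counts.items()}),
                    make_record(2, "CCCC", {r: c * scale for r, c in others.items()})]
            profs = normalize_read_counts(recs, [1, 3, 5])
            assert fold_enrichment(profs[1], 1, 5) == pytest.approx(
                (40 / 1000) / (7 / 1000))

    def test_window_uses_only_sequenced_rounds(self):
        # window 1-3 with round 2 unsequenced uses rounds {1, 3}
        assert window_rounds((1, 3), [0, 1, 3, 5, 6, 7, 8]) == [1, 3]
        assert window_rounds((6, 8), [0, 1, 3, 5, 6, 7, 8]) == [6, 7, 8]


class TestRepresentatives:
    def _profiles(self):
        w = (1, 8)
        pa = profile({1: 0.001, 8: 0.01}, seq_id=1)
        pb = profile({1: 0.005, 8: 0.01}, seq_id=2)
        for p in (pa, pb):
            p.fold_enrichment[w] = fold_enrichment(p, 1, 8)
            p.rate_enrichment[w] = rate_enrichment(p, 1, 8)
        return {1: pa, 2: pb}, w

    def test_highest_fe_wins(self):
        profs, w = self._profiles()
        fam = Family("sequence", 1, [1, 2])
        assert select_family_representatives([fam], profs, [w]) == [1]

    def test_fe_tie_broken_by_rate(self):
        profs, w = self._profiles()
        profs[1].fold_enrichment[w] = 2.0
        profs[2].fold_enrichment[w] = 2.0
        profs[1].rate_enrichment[w] = 5.0
        profs[2].rate_enrichment[w] = 9.0
        fam = Family("sequence", 1, [1, 2])
        assert select_family_representatives([fam], profs, [w]) == [2]

    def test_selection_invariant_to_member_order(self):
        profs, w = self._profiles()
        a = select_family_representatives([Family("sequence", 1, [1, 2])], profs, [w])
        b = select_family_representatives([Family("sequence", 1, [2, 1])], profs, [w])
        assert a == b

    def test_orphan_detection(self):
        recs = [make_record(1, "AAAA", {1: 506}), make_record(2, "CCCC", {1: 50})]
        recs[0].sequence_family = None
        assert find_orphans(recs) == [1]
        recs[0].sequence_family = "I"
        assert find_orphans(recs) == []

    def test_candidate_set_assembly_marks_representatives(self):
        recs = [make_record(1, "AAAAAAAAAA", {1: 100, 8: 400}),
                make_record(2, "AAAAAAAAAC", {1: 100, 8: 200}),
                make_record(3, "GGGGGGGGGG", {1: 200, 8: 200})]
        profs = normalize_read_counts(recs, [1, 8])
        score_windows(profs, [(1, 8)], [1, 8])
        fams = [Family("sequence", 1, [1, 2], label="I")]
        recs[0].sequence_family = recs[1].sequence_family = "I"
        cand = select_representatives(recs, fams, [], profs, windows=[(1, 8)])
        assert cand.edit_representatives == [1]
        assert 3 in cand.orphans
        assert recs[0].representative and not recs[1].representative


class TestVenn:
    @pytest.mark.parametrize("e,t,expected", [
        ({1, 2, 3}, {2, 3, 4}, (1, 2, 1)),
        ({1, 2}, {1, 2}, (0, 2, 0)),
        ({1, 2}, {3, 4, 5}, (2, 0, 3)),
    ])
    def test_counts(self, e, t, expected):
        venn = compare_candidate_sets(e, t)
        assert venn == expected
        assert sum(venn) == len(e | t)


class TestSpearman:
    def test_perfect_monotone(self):
        res = spearman_correlation([1, 2, 3, 4, 5], [10, 20, 25, 40, 100])
        assert res.r == pytest.approx(1.0)

    def test_reversed(self):
        res = spearman_correlation([1, 2, 3, 4, 5], [5, 4, 3, 2, 1])
        assert res.r == pytest.approx(-1.0)

    def test_matches_scipy_with_ties(self, rng):
        x = [1.0, 2.0, 2.0, 3.0, 4.0, 5.0, 5.0, 7.0, 8.0, 9.0, 10.0, 12.0]
        y = list(rng.normal(size=len(x)))
        res = spearman_correlation(x, y)
        ref = scistats.spearmanr(x, y)
        assert res.r == pytest.approx(ref.statistic)
        assert res.p == pytest.approx(ref.pvalue, rel=0.05)

    def test_closed_form_tie_free(self, rng):
        x = list(rng.permutation(10).astype(float))
        y = list(rng.permutation(10).astype(float))
        res = spearman_correlation(x, y)
        rx = scistats.rankdata(x)
        ry = scistats.rankdata(y)
        d2 = float(np.sum((rx - ry) ** 2))
        n = len(x)
        assert res.r == pytest.approx(1 - 6 * d2 / (n * (n * n - 1)))

    def test_exact_permutation_p_matches_enumeration(self, rng):
        x = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        y = list(rng.normal(size=6))
        res = spearman_correlation(x, y)
        rx, ry = scistats.rankdata(x), scistats.rankdata(y)
        obs = abs(np.corrcoef(rx, ry)[0, 1])
        count = sum(
            1 for perm in itertools.permutations(ry)
            if abs(np.corrcoef(rx, perm)[0, 1]) >= obs - 1e-12)
        assert res.p == pytest.approx(count / math.factorial(6))

    def test_input_validation(self):
        with pytest.raises(InputError):
            spearman_correlation([1, 2], [3, 4])
        with pytest.raises(InputError):
            spearman_correlation([1, 1, 1], [1, 2, 3])


class TestCorrelationGrid:
    def _profiles(self, rng, n=33, monotone=False):
        profs = {}
        internal = {}
        for i in range(1, n + 1):
            a1 = float(rng.uniform(1e-5, 1e-3))
            fe = float(rng.uniform(0.5, 50))
            ab = {1: a1, 3: a1 * fe ** 0.5, 8: a1 * fe}
            p = profile(ab, seq_id=i)
            profs[i] = p
            internal[i] = fe if monotone else float(rng.uniform(1, 20))
        score_windows(profs, [(1, 8)], [1, 3, 8])
        return profs, internal

    def test_monotone_metrics_give_r_one(self, rng):
        profs, internal = self._profiles(rng, monotone=True)
        grid = correlate_internalization(profs, internal, windows=[(1, 8)])
        fe_row = grid[grid.metric == "fold_enrichment"].iloc[0]
        assert fe_row.r == pytest.approx(1.0)

    def test_null_internalization_rarely_significant(self, rng):
        significant = 0
        for _ in range(100):
            profs, internal = self._profiles(rng, monotone=False)
            grid = correlate_internalization(profs, internal, windows=[(1, 8)])
            fe_row = grid[grid.metric == "fold_enrichment"].iloc[0]
            assert abs(fe_row.r) <= 1
            if fe_row.p < 0.05:
                significant += 1
        assert significant <= 10  # |r| small, p > 0.05 in >= 90% of replicates

    def test_grid_shape(self, rng):
        profs, internal = self._profiles(rng)
        score_windows(profs, [(1, 8)], [1, 3, 8])
        grid = correlate_internalization(
            profs, internal, windows=[(1, 8)], rounds=[1, 3, 8])
        # 3 metrics x 1 window (all three rounds fall in it) + 3 rounds + 1 total
        assert len(grid) == 3 * 1 + 3 + 1

    def test_two_round_window_has_no_rising_cell(self, rng):
        profs, internal = self._profiles(rng)
        score_windows(profs, [(1, 3)], [1, 3, 8])
        grid = correlate_internalization(profs, internal, windows=[(1, 3)])
        assert set(grid.metric) == {"fold_enrichment", "rate_enrichment"}

    def test_missing_measurements_excluded(self, rng):
        profs, internal = self._profiles(rng, n=10)
        internal.pop(1)
        grid = correlate_internalization(profs, internal, windows=[(1, 8)])
        assert int(grid.iloc[0].n) == 9
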