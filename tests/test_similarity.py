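"""Overlap likelihoods, log-odds, and the similarity matrix.

The enumeration oracle sums over every assignment of overlap positions
to locus classes, phase configurations and match/mismatch outcomes, so
it is an independent check of the closed-form combinatorial sums.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from clonesift.locus_filter import FilterParams, select_informative_loci
from clonesift.similarity import (
    LOG_FLOOR,
    SimilarityParams,
    build_similarity_matrix,
    log_prob_diff,
    log_prob_same,
    overlap_counts,
    pair_kernels,
    pair_log_odds,
)
from conftest import make_pileup

P = SimilarityParams()  # theta=0.05, h=0.5, epsilon=0.01


# ---------------------------------------------------------------------------
# Enumeration oracle
# ---------------------------------------------------------------------------


def enum_same(xs: int, xd: int, p: SimilarityParams) -> float:
    K = pair_kernels(p.theta)
    L = xs + xd
    w_het, w_hom = 1 - p.h - p.epsilon / 2, p.h + p.epsilon / 2
    total = 0.0
    for types in itertools.product([0, 1], repeat=L):  # 0 het, 1 hom
        tw = np.prod([w_het if t == 0 else w_hom for t in types]) if L else 1.0
        for phase in (0, 1):  # same / opposite haplotype
            for outcome in itertools.product([0, 1], repeat=L):  # 0 match
                if outcome.count(0) != xs:
                    continue
                pr = 1.0
                for t, o in zip(types, outcome):
                    if t == 1 or phase == 0:
                        pr *= K.p_ss if o == 0 else K.p_sd
                    else:
                        pr *= K.p_ds if o == 0 else K.p_dd
                total += 0.5 * tw * pr
    return total


def enum_diff(xs: int, xd: int, p: SimilarityParams) -> float:
    K = pair_kernels(p.theta)
    L = xs + xd
    weights = [1 - p.h - p.epsilon, p.h, p.epsilon]  # het, hom-same, mutated
    total = 0.0
    for types in itertools.product([0, 1, 2], repeat=L):
        tw = np.prod([weights[t] for t in types]) if L else 1.0
        for phase in (0, 1):
            for outcome in itertools.product([0, 1], repeat=L):
                if outcome.count(0) != xs:
                    continue
                pr = 1.0
                for t, o in zip(types, outcome):
                    if t == 1:
                        pr *= K.p_ss if o == 0 else K.p_sd
                    elif t == 2:
                        pr *= (
                            0.5 * (K.p_ss + K.p_ds)
                            if o == 0
                            else 0.5 * (K.p_sd + K.p_dd)
                        )
                    elif phase == 0:
                        pr *= K.p_ss if o == 0 else K.p_sd
                    else:
                        pr *= K.p_ds if o == 0 else K.p_dd
                total += 0.5 * tw * pr
    return total


class TestKernels:
    def test_error_free_limit(self):
        K = pair_kernels(0.0)
        assert K.p_ss == 1.0 and K.p_ds == 0.0

    def test_closed_form_at_default_theta(self):
        K = pair_kernels(0.05)
        assert K.p_ss == pytest.approx(0.95**2 + 0.05**2 / 3, rel=1e-14)
        assert K.p_ds == pytest.approx(
            2 * 0.95 * 0.05 / 3 + 2 * 0.05**2 / 9, rel=1e-14
        )

    @pytest.mark.parametrize("theta", [0.0, 0.01, 0.05, 0.3, 0.9])
    def test_complements_sum_to_one(self, theta):
        K = pair_kernels(theta)
        assert K.p_ss + K.p_sd == pytest.approx(1.0, abs=1e-15)
        assert K.p_ds + K.p_dd == pytest.approx(1.0, abs=1e-15)


class TestOverlapLikelihoods:
    def test_empty_overlap_is_log_one(self):
        assert log_prob_same(0, 0, P) == 0.0
        assert log_prob_diff(0, 0, P) == 0.0

    def test_negative_counts_raise(self):
        with pytest.raises(ValueError):
            log_prob_same(-1, 0, P)
        with pytest.raises(ValueError):
            log_prob_diff(0, -1, P)

    @pytest.mark.parametrize("L", range(1, 13))
    def test_same_genotype_distribution_normalizes(self, L):
        total = sum(np.exp(log_prob_same(x, L - x, P)) for x in range(L + 1))
        assert total == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("L", range(1, 11))
    def test_diff_genotype_distribution_normalizes(self, L):
        total = sum(np.exp(log_prob_diff(x, L - x, P)) for x in range(L + 1))
        assert total == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize(
        "xs,xd",
        [(x, d) for x in range(7) for d in range(7) if 1 <= x + d <= 6],
    )
    def test_enumeration_oracle_equivalence(self, xs, xd):
        a = np.exp(log_prob_same(xs, xd, P))
        b = enum_same(xs, xd, P)
        assert abs(a - b) / b < 1e-10
        c = np.exp(log_prob_diff(xs, xd, P))
        d = enum_diff(xs, xd, P)
        assert abs(c - d) / d < 1e-10

    def test_single_match_hand_expansion(self):
        K = pair_kernels(P.theta)
        expected = (1 - P.h - P.epsilon / 2) * 0.5 * (K.p_ss + K.p_ds) + (
            P.h + P.epsilon / 2
        ) * K.p_ss
        assert log_prob_same(1, 0, P) == pytest.approx(np.log(expected), rel=1e-12)

    def test_error_free_homozygous_identical_limit(self):
        params = SimilarityParams(theta=0.0, h=1.0, epsilon=0.0)
        for L in range(1, 6):
            assert log_prob_same(L, 0, params) == pytest.approx(0.0, abs=1e-12)
            assert log_prob_same(L - 1, 1, params) <= LOG_FLOOR / 2


class TestPairLogOdds:
    def test_empty_overlap_is_zero(self):
        assert pair_log_odds(0, 0, P) == 0.0

    def test_pure_matches_increasingly_favor_same_genotype(self):
        vals = [pair_log_odds(L, 0, P) for L in range(1, 11)]
        assert all(b > a for a, b in zip(vals, vals[1:]))
        assert vals[0] > 0

    def test_mixed_overlaps_strongest_different_evidence(self):
        # pure mismatches can be explained by opposite phase; a mix cannot
        assert pair_log_odds(2, 2, P) < pair_log_odds(0, 4, P)


class TestOverlapCounts:
    def test_matches_and_mismatches(self):
        fi = {10: 0, 20: 1, 30: 2}
        fj = {10: 0, 20: 1, 30: 3}
        assert overlap_counts(fi, fj) == (2, 1)

    def test_disjoint_loci_give_none(self):
        assert overlap_counts({1: 0}, {2: 0}) is None

    def test_identical_fragments(self):
        f = {i: i % 4 for i in range(5)}
        assert overlap_counts(f, f) == (5, 0)

    def test_restriction_to_informative_loci(self):
        fi = {10: 0, 20: 1}
        fj = {10: 0, 20: 2}
        assert overlap_counts(fi, fj, informative_loci={10}) == (1, 0)


class TestSimilarityMatrix:
    def _pileup_and_info(self, rows, n_cells, params=None):
        pileup = make_pileup(rows, n_cells=n_cells)
        info, _ = select_informative_loci(
            pileup,
            params
            or FilterParams(K=1.0, min_top3=0, min_nonref=0,
                            coverage_sd_limit=1e9),
        )
        return pileup, info

    def test_no_shared_loci_gives_zero(self):
        rows = [(10, 0, 0, "A", 37), (10, 2, 0, "C", 37),
                (50, 1, 0, "A", 37), (50, 2, 1, "C", 37)]
        pileup, info = self._pileup_and_info(rows, n_cells=3)
        S = build_similarity_matrix(pileup, info, P)
        assert S.matrix[0, 1] == 0.0

    def test_single_overlap_equals_pair_log_odds(self):
        # two cells, one fragment each, overlapping at 3 loci: 2 match, 1 not
        rows = [
            (10, 0, 0, "A", 37), (10, 1, 0, "A", 37),
            (20, 0, 0, "C", 37), (20, 1, 0, "C", 37),
            (30, 0, 0, "G", 37), (30, 1, 0, "T", 37),
            # extra cells keep every locus polymorphic with c1 > 1.5 c2
            (10, 2, 0, "C", 37), (20, 2, 0, "A", 37),
            (30, 3, 0, "G", 37), (30, 4, 0, "G", 37),
        ]
        pileup, info = self._pileup_and_info(rows, n_cells=5)
        assert len(info) == 3
        S = build_similarity_matrix(pileup, info, P)
        # the cell0-cell1 fragment pair shares all three loci: (xs, xd) = (2, 1)
        assert S.matrix[0, 1] == pytest.approx(pair_log_odds(2, 1, P), rel=1e-12)

    def test_symmetry_and_zero_diagonal(self, small_two_clone):
        _, _, pileup = small_two_clone
        info, _ = select_informative_loci(pileup, FilterParams())
        S = build_similarity_matrix(pileup, info, P)
        assert np.array_equal(S.matrix, S.matrix.T)
        assert np.all(np.diag(S.matrix) == 0.0)
        assert np.all(np.isfinite(S.matrix))

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(0)
        rows = []
        for locus in range(30):
            for cell in rng.choice(8, size=4, replace=False):
                rows.append(
                    (locus * 10, int(cell), 0, "ACGT"[rng.integers(4)], 37)
                )
        pileup, info = self._pileup_and_info(rows, n_cells=8)
        S = build_similarity_matrix(pileup, info, P)
        perm = rng.permutation(8)
        rows_p = [(g, int(perm[c]), f, b, q) for g, c, f, b, q in rows]
        pileup_p, info_p = self._pileup_and_info(rows_p, n_cells=8)
        S_p = build_similarity_matrix(pileup_p, info_p, P)
        assert np.allclose(S_p.matrix[np.ix_(perm, perm)], S.matrix, atol=1e-12)

    def test_within_clone_similarity_exceeds_between(self, small_two_clone):
        _, result, pileup = small_two_clone
        info, _ = select_informative_loci(pileup, FilterParams())
        S = build_similarity_matrix(pileup, info, P)
        labels = result.truth.labels()
        iu = np.triu_indices(len(labels), 1)
        same = labels[iu[0]] == labels[iu[1]]
        assert S.matrix[iu][same].mean() > S.matrix[iu][~same].mean()

    def test_cell_universe_mismatch_raises(self):
        rows = [(10, 0, 0, "A", 37), (10, 1, 0, "C", 37)]
        pileup, info = self._pileup_and_info(rows, n_cells=2)
        with pytest.raises(ValueError):
            build_similarity_matrix(pileup, info, P, cells=[0, 5])
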