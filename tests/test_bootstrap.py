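"""Bootstrap resampling, the signed-rank statistic W, p-values, Hochberg."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import rankdata

from bsmselect import (
    bootstrap_resample,
    bsm_select,
    gene_pvalues,
    hochberg_adjust,
    null_moments,
    rank_scores,
    signed_rank_statistic,
)
from bsmselect.bootstrap import BootstrapRanking, _positions_from_sd
from conftest import random_dataset


class TestBootstrapResample:
    def test_shape_and_labels_preserved(self, small_sim):
        ds, _ = small_sim
        boot = bootstrap_resample(ds, seed=0)
        assert boot.M == ds.M and boot.N == ds.N
        assert boot.M1 >= 2 and boot.M2 >= 2

    def test_seed_determinism(self, small_sim):
        ds, _ = small_sim
        a, b = bootstrap_resample(ds, seed=5), bootstrap_resample(ds, seed=5)
        np.testing.assert_array_equal(a.values, b.values)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_distinct_subject_count_matches_closed_form(self):
        """E[# distinct subjects] = M (1 - (1 - 1/M)^M) for an M-draw
        bootstrap; check the empirical mean within 3 SE."""
        rng = np.random.default_rng(123)
        ds = random_dataset(rng, N=3, M1=5, M2=5)
        M = ds.M
        n_rep = 2000
        counts = np.empty(n_rep)
        for r in range(n_rep):
            boot = bootstrap_resample(ds, seed=10_000 + r)
            # recover drawn subject via the id prefix before '#'
            originals = {s.split("#")[0] for s in boot.sample_ids}
            counts[r] = len(originals)
        expected = M * (1 - (1 - 1 / M) ** M)
        se = counts.std(ddof=1) / np.sqrt(n_rep)
        assert abs(counts.mean() - expected) < 3 * se


class TestRankScores:
    @pytest.mark.parametrize(
        "P,expected",
        [
            (np.arange(1, 11), None),          # checked below
            (np.array([1, 2, 3, 4]), [1, 0.75, 0.5, 0.25]),
        ],
    )
    def test_formula(self, P, expected):
        R = rank_scores(P)
        if expected is not None:
            np.testing.assert_allclose(R, expected)
        assert R[np.argmin(P)] == pytest.approx(1.0)     # top gene
        assert R[np.argmax(P)] == pytest.approx(1 / len(P))  # bottom gene

    def test_non_permutation_rejected(self):
        with pytest.raises(ValueError):
            rank_scores(np.array([1, 2, 2, 4]))

    def test_row_scores_are_exact_grid(self):
        rng = np.random.default_rng(0)
        P = np.vstack([rng.permutation(20) + 1 for _ in range(5)])
        ranking = BootstrapRanking(positions=P)
        for row in ranking.rank_scores:
            np.testing.assert_allclose(np.sort(row), np.arange(1, 21) / 20)


class TestSignedRankStatistic:
    def test_enumerated_example(self):
        """R=(0.9,0.8,0.1): deviations (+.15,+.05,-.65), |dev| ranks
        (2,1,3), positives contribute 2+1 -> W=3."""
        assert signed_rank_statistic(np.array([0.9, 0.8, 0.1])) == 3.0

    def test_extremes(self):
        B = 7
        assert signed_rank_statistic(np.full(B, 0.5)) == 0.0
        assert signed_rank_statistic(np.linspace(0.76, 1.0, B)) == B * (B + 1) / 2

    @given(st.integers(0, 99999))
    @settings(deadline=None, derandomize=True, max_examples=25)
    def test_bounds_and_replicate_permutation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        R = rng.random(int(rng.integers(1, 50)))
        W = signed_rank_statistic(R)
        B = R.size
        assert 0 <= W <= B * (B + 1) / 2
        assert signed_rank_statistic(rng.permutation(R)) == pytest.approx(W)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            signed_rank_statistic(np.array([]))


class TestNullMoments:
    @pytest.mark.parametrize("B,mean,var", [
        (200, 5025.0, 503756.25),
        (1, 0.25, 0.1875),
        (4, 2.5, 5.625),
    ])
    def test_closed_forms(self, B, mean, var):
        assert null_moments(B) == (mean, var)

    def test_invalid_B(self):
        with pytest.raises(ValueError):
            null_moments(0)

    def test_monte_carlo_under_stated_null(self):
        """Z_b iid Bernoulli(1/4) with fixed ranks r_b = b: the MC mean
        and variance of W = sum b Z_b match the closed forms within 3 SE."""
        B, n_rep = 50, 100_000
        rng = np.random.default_rng(99)
        Z = rng.random((n_rep, B)) < 0.25
        W = Z @ np.arange(1, B + 1)
        mean, var = null_moments(B)
        se_mean = W.std(ddof=1) / np.sqrt(n_rep)
        assert abs(W.mean() - mean) < 3 * se_mean
        se_var = W.var(ddof=1) * np.sqrt(2 / (n_rep - 1))
        assert abs(W.var(ddof=1) - var) < 3 * se_var


class TestGenePvalues:
    def test_anchor_points_and_monotonicity(self):
        B = 200
        mean, var = null_moments(B)
        W = np.array([mean, mean + 1.959964 * np.sqrt(var), mean - 100, mean + 500])
        p = gene_pvalues(W, B)
        assert p[0] == pytest.approx(0.5)
        assert p[1] == pytest.approx(0.025, rel=1e-4)
        order = np.argsort(W)
        assert (np.diff(p[order]) < 0).all()

    def test_small_B_warns(self):
        with pytest.warns(UserWarning, match="normal approximation"):
            gene_pvalues(np.array([3.0]), B=5)


def hochberg_stepwise_decisions(p: np.ndarray, alpha: float) -> np.ndarray:
    """Brute-force step-up retain/reject: walk p_(N), p_(N-1), ... and
    reject all remaining hypotheses at the first index i (1-based from
    the largest) with p_(N-i+1) <= alpha / i."""
    N = p.size
    order = np.argsort(p)
    reject = np.zeros(N, dtype=bool)
    for step, pos in enumerate(reversed(order), start=1):  # largest first
        if p[pos] <= alpha / step:
            for q in order:
                if p[q] <= p[pos]:
                    reject[q] = True
            break
    return reject


class TestHochberg:
    def test_hand_step_up_examples(self):
        np.testing.assert_allclose(
            hochberg_adjust(np.array([0.01, 0.02, 0.04])), [0.03, 0.04, 0.04]
        )
        np.testing.assert_allclose(
            hochberg_adjust(np.array([0.05, 0.05, 0.05])), [0.05, 0.05, 0.05]
        )

    def test_single_p_unchanged(self):
        np.testing.assert_array_equal(hochberg_adjust(np.array([0.2])), [0.2])

    def test_agrees_with_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(4)
        for _ in range(20):
            p = rng.random(int(rng.integers(1, 40)))
            _, adj, _, _ = multipletests(p, method="simes-hochberg")
            np.testing.assert_allclose(hochberg_adjust(p), adj, rtol=1e-12)

    @given(st.integers(0, 99999))
    @settings(deadline=None, derandomize=True, max_examples=50)
    def test_decision_agreement_with_stepwise_algorithm(self, seed):
        """Reject at level alpha via the step-wise walk <=> adjusted
        p <= alpha, at random alphas and p-vectors."""
        rng = np.random.default_rng(seed)
        p = rng.random(int(rng.integers(1, 30)))
        adj = hochberg_adjust(p)
        alpha = float(rng.uniform(0.001, 0.999))
        np.testing.assert_array_equal(adj <= alpha,
                                      hochberg_stepwise_decisions(p, alpha))

    def test_dominates_raw_and_preserves_order(self):
        rng = np.random.default_rng(8)
        p = rng.random(25)
        adj = hochberg_adjust(p)
        assert (adj >= p - 1e-15).all()
        assert (adj <= 1.0).all()
        # ordering of adjusted p never contradicts ordering of raw p
        assert (np.diff(adj[np.argsort(p, kind="stable")]) >= -1e-15).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            hochberg_adjust(np.array([0.5, 1.5]))


class TestPositionsFromSd:
    def test_descending_with_gene_id_tiebreak(self):
        sd = np.array([0.5, 0.9, 0.5, 0.1])
        ids = np.array(["gd", "ga", "gb", "gc"])
        P = _positions_from_sd(sd, ids)
        # gb (0.5) beats gd (0.5) on id; order: ga, gb, gd, gc
        np.testing.assert_array_equal(P, [3, 1, 2, 4])


class TestBsmSelect:
    def test_fixed_seed_bit_identical(self, small_sim):
        ds, _ = small_sim
        t1 = bsm_select(ds, B=30, beta=0.5, seed=3)
        t2 = bsm_select(ds, B=30, beta=0.5, seed=3)
        assert t1.frame.equals(t2.frame)

    def test_informative_genes_float_to_top(self, small_sim):
        ds, info = small_sim
        table = bsm_select(ds, B=60, beta=0.5, seed=1)
        top = set(table.sorted()["gene_id"][: len(info)])
        assert len(top & set(info)) >= 0.8 * len(info)

    def test_auto_beta_runs_and_is_recorded(self, small_sim):
        ds, _ = small_sim
        table = bsm_select(ds, B=10, beta="auto", seed=2, n_top=15)
        assert 0.0 < table.beta < 1.0

    def test_invalid_parameters(self, small_sim):
        ds, _ = small_sim
        with pytest.raises(ValueError):
            bsm_select(ds, B=0)
        with pytest.raises(ValueError):
            bsm_select(ds, B=10, alpha=1.5)
        with pytest.raises(ValueError):
            bsm_select(ds, B=10, beta=1.2)
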