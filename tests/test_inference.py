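"""Permutation tests, tau-b, FDR/FWE control and the full inference layer."""
import itertools
import math

import numpy as np
import pandas as pd
import pytest

from dfncstates import (
    CohortConfig,
    InferenceConfig,
    chi2_entry_proportions,
    fdr_bh,
    kendall_tau_b,
    metrics_table,
    perm_fwe_signed_rank,
    perm_rank_sum,
    perm_signed_rank,
    run_full_inference,
    simulate_cohort,
    zero_vs_nonzero_ttest,
)
from dfncstates.containers import StateSequence


class TestRankSum:
    def test_identical_samples_give_p_one(self):
        with pytest.warns(UserWarning):
            res = perm_rank_sum([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        assert res.p_raw == 1.0

    def test_extreme_separation_exhaustive_p(self):
        res = perm_rank_sum([1, 2, 3], [10, 11, 12], n_perm=10_000)
        assert res.p_raw == pytest.approx(2 / math.comb(6, 3))
        assert "exhaustive" in res.notes

    def test_exchangeable_identical_multisets(self):
        res = perm_rank_sum([1, 2, 5], [5, 1, 2], n_perm=10_000)
        assert res.p_raw == 1.0

    def test_monte_carlo_p_bounded_below(self):
        rng = np.random.default_rng(0)
        x = rng.normal(3, 1, 30)
        y = rng.normal(0, 1, 30)
        res = perm_rank_sum(x, y, n_perm=999, seed=1)
        assert res.p_raw >= 1 / 1000
        assert res.p_raw < 0.01
        assert res.z_approx > 3

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            perm_rank_sum([], [1.0])

    def test_exhaustive_and_monte_carlo_agree(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0.8, 1, 5)
        y = rng.normal(0, 1, 5)
        exact = perm_rank_sum(x, y, n_perm=math.comb(10, 5)).p_raw
        mc = perm_rank_sum(x, y, n_perm=5000, seed=2).p_raw
        se = math.sqrt(exact * (1 - exact) / 5000)
        assert abs(mc - exact) < 3 * se + 1e-3


class TestSignedRank:
    def test_no_change_gives_p_one(self):
        pre = np.array([1.0, 2.0, 3.0])
        with pytest.warns(UserWarning):
            res = perm_signed_rank(pre, pre)
        assert res.p_raw == 1.0

    def test_all_positive_differences_exhaustive(self):
        pre = np.zeros(5)
        post = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        res = perm_signed_rank(pre, post, n_perm=10_000)
        assert res.p_raw == pytest.approx(2 / 32)
        assert "exhaustive" in res.notes
        assert res.z_approx > 0

    def test_zero_differences_are_dropped_and_logged(self):
        pre = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        post = np.array([1.0, 2.0, 4.0, 5.0, 6.0, 7.0])  # two zero diffs
        res = perm_signed_rank(pre, post, n_perm=10_000)
        assert "n_dropped=2" in res.notes

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            perm_signed_rank([1.0], [1.0, 2.0])


class TestKendallTauB:
    def test_perfect_concordance_and_discordance(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert kendall_tau_b(x, 2 * x).statistic == pytest.approx(1.0)
        assert kendall_tau_b(x, -x).statistic == pytest.approx(-1.0)

    def test_matches_pair_enumeration_with_ties(self):
        x = np.array([1.0, 2.0, 2.0, 3.0])
        y = np.array([4.0, 4.0, 2.0, 1.0])
        conc = disc = tx = ty = 0
        for i, j in itertools.combinations(range(4), 2):
            dx, dy = x[j] - x[i], y[j] - y[i]
            if dx == 0 and dy == 0:
                continue
            if dx == 0:
                tx += 1
            elif dy == 0:
                ty += 1
            elif dx * dy > 0:
                conc += 1
            else:
                disc += 1
        n0 = math.comb(4, 2)
        expected = (conc - disc) / math.sqrt((n0 - tx_n(x)) * (n0 - tx_n(y)))
        assert kendall_tau_b(x, y).statistic == pytest.approx(expected)

    def test_invariant_under_monotone_transforms(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=15)
        y = 0.5 * x + rng.normal(size=15)
        base = kendall_tau_b(x, y).statistic
        assert kendall_tau_b(np.exp(x), y).statistic == pytest.approx(base)
        assert kendall_tau_b(x, y**3).statistic == pytest.approx(base)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            kendall_tau_b([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


def tx_n(v):
    """Tie-pair count within one vector."""
    _, counts = np.unique(v, return_counts=True)
    return sum(math.comb(int(c), 2) for c in counts)


class TestFDR:
    def test_single_p_value_unchanged(self):
        adj, rej = fdr_bh([0.03])
        assert adj[0] == pytest.approx(0.03)
        assert rej[0]

    def test_hand_computed_step_up(self):
        adj, _ = fdr_bh([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_adjusted_monotone_in_rank_order(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(0.001, 1, 25)
        adj, _ = fdr_bh(p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)
        assert np.all(adj >= p - 1e-12)
        assert np.all(adj <= 1)

    def test_step_up_consistency_under_removal(self):
        # Dropping the largest p values never removes existing rejections.
        p = [0.001, 0.008, 0.04, 0.2, 0.9]
        _, rej_full = fdr_bh(p, alpha=0.05)
        _, rej_sub = fdr_bh(p[:3], alpha=0.05)
        for i in range(3):
            assert rej_sub[i] or not rej_full[i]

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            fdr_bh([])


class TestChi2:
    def test_equal_proportions_give_zero_statistic(self):
        res = chi2_entry_proportions(np.array([[10, 10], [5, 5]]))
        assert res.statistic == pytest.approx(0.0)
        assert res.p_raw == pytest.approx(1.0)

    def test_matches_hand_formula(self):
        table = np.array([[30, 6], [10, 16]])
        n = table.sum()
        expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / n
        stat = ((table - expected) ** 2 / expected).sum()
        res = chi2_entry_proportions(table)
        assert res.statistic == pytest.approx(stat)

    def test_row_swap_invariance(self):
        table = np.array([[30, 6], [10, 16]])
        assert chi2_entry_proportions(table).statistic == pytest.approx(
            chi2_entry_proportions(table[::-1]).statistic
        )

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError):
            chi2_entry_proportions(np.array([[5, 0], [3, 0]]))


class TestZeroVsNonzero:
    def test_identical_strata_give_t_zero(self):
        scores = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        fracs = np.array([0.0, 0.0, 0.0, 0.1, 0.2, 0.3])
        res = zero_vs_nonzero_ttest(scores, fracs)
        assert res.statistic == pytest.approx(0.0)
        assert res.p_raw == pytest.approx(1.0)
        assert res.notes == "df=4"

    def test_matches_pooled_variance_formula(self):
        zero = np.array([14.0, 17.0, 16.0])
        nonzero = np.array([9.0, 11.0, 10.0])
        scores = np.concatenate([zero, nonzero])
        fracs = np.array([0.0, 0.0, 0.0, 0.2, 0.1, 0.3])
        res = zero_vs_nonzero_ttest(scores, fracs)
        sp2 = (zero.var(ddof=1) * 2 + nonzero.var(ddof=1) * 2) / 4
        t = (zero.mean() - nonzero.mean()) / math.sqrt(sp2 * (1 / 3 + 1 / 3))
        assert res.statistic == pytest.approx(t)

    def test_tiny_stratum_rejected(self):
        with pytest.raises(ValueError):
            zero_vs_nonzero_ttest(np.arange(4.0), np.array([0.0, 0.1, 0.2, 0.3]))


class TestPermFWE:
    def _family(self, rng, n=12, effect=0.0):
        rows = []
        for cell in ("A", "B"):
            for subj in range(n):
                pre = rng.normal(0, 1)
                shift = effect if cell == "A" else 0.0
                rows.append(
                    {"cell": cell, "outcome": "o1", "subject": f"{cell}{subj}",
                     "pre": pre, "post": pre + rng.normal(shift, 1)}
                )
        return pd.DataFrame(rows)

    def test_single_test_family_fwe_equals_raw(self):
        rng = np.random.default_rng(3)
        fam = self._family(rng).query("cell == 'A'")
        out = perm_fwe_signed_rank(fam, n_perm=500, seed=0)
        assert len(out) == 1
        assert out["p_fwe"].iloc[0] == pytest.approx(out["p_raw"].iloc[0])

    def test_fwe_p_never_smaller_than_raw(self):
        rng = np.random.default_rng(4)
        out = perm_fwe_signed_rank(self._family(rng), n_perm=500, seed=1)
        assert (out["p_fwe"] >= out["p_raw"] - 1e-12).all()
        assert (out["p_raw"] >= 1 / 501).all()

    def test_bonferroni_mode(self):
        rng = np.random.default_rng(5)
        out = perm_fwe_signed_rank(self._family(rng), n_perm=500, seed=2,
                                   method="bonferroni")
        np.testing.assert_allclose(
            out["p_fwe"], np.minimum(out["p_raw"] * len(out), 1.0)
        )

    def test_planted_effect_found_only_in_its_cell(self):
        rng = np.random.default_rng(6)
        out = perm_fwe_signed_rank(self._family(rng, n=18, effect=2.0),
                                   n_perm=2000, seed=3)
        sig = out[out["p_fwe"] < 0.05]["cell"].tolist()
        assert sig == ["A"]


def truth_metrics(cohort):
    """Metrics computed from the planted ground-truth state sequences."""
    seqs = [
        StateSequence(s.truth.state_sequences[cond], subject_id=s.subject_id,
                      condition=cond)
        for s in cohort.subjects
        for cond in ("rest_pre", "brooding", "rest_post")
    ]
    return metrics_table(seqs, cohort.config.n_states)


class TestFullInference:
    @pytest.fixture(scope="class")
    def planted_result(self):
        cohort = simulate_cohort(CohortConfig(emit_timecourses=False), seed=99)
        metrics = truth_metrics(cohort)
        config = InferenceConfig(n_perm=500, seed=42)
        return cohort, run_full_inference(metrics, cohort.metadata(), config)

    def test_designated_state_flagged_with_negative_tau(self, planted_result):
        cohort, res = planted_result
        assert res.flagged_state == cohort.config.designated_state
        assert res.flagged_significant
        sub = res.results[
            (res.results["test"] == "rrs_kendall_tau_b")
            & (res.results["cell"] == "MDD")
            & (res.results["condition"] == "brooding")
            & (res.results["state"] == cohort.config.designated_state)
        ]
        assert (sub["statistic"] < 0).all()

    def test_results_table_is_complete(self, planted_result):
        _, res = planted_result
        tests = set(res.results["test"])
        assert {"group_rank_sum", "rrs_kendall_tau_b", "entry_chi2",
                "prepost_signed_rank"} <= tests
        assert (res.results["p_raw"].dropna() > 0).all()
        assert (res.results["p_raw"].dropna() <= 1).all()
        # 2 conditions x 4 states x 2 outcomes rank-sum contrasts
        assert (res.results["test"] == "group_rank_sum").sum() == 16
        # 2 groups x 2 conditions x 4 states x 2 outcomes correlations
        assert (res.results["test"] == "rrs_kendall_tau_b").sum() == 32

    def test_missing_metadata_column_is_named(self, planted_result):
        cohort, _ = planted_result
        metrics = truth_metrics(cohort)
        broken = cohort.metadata().drop(columns=["rrs_b"])
        with pytest.raises(ValueError, match="rrs_b"):
            run_full_inference(metrics, broken, InferenceConfig(n_perm=50))
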