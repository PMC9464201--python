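"""Exact tests vs enumeration oracles; mixed-model fit vs statsmodels."""

import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from hvipipe.exceptions import DegenerateSignalError, DesignError, ParameterError
from hvipipe.stats import (chi_square_2x2, fit_crossover_lmm, rank_correlation,
                           summarize_study, unpaired_t_test, wilcoxon_rank_sum,
                           wilcoxon_signed_rank)
from hvipipe.synthetic import StudyDesignParams, render_crossover_study


class TestChiSquare:
    @pytest.mark.parametrize("table, expected_p", [
        ((2, 6, 3, 5), 0.590),   # male counts by sequence group
        ((8, 0, 6, 2), 0.131),   # right-eye counts
        ((7, 1, 8, 0), 0.302),   # inferonasal vein counts
    ])
    def test_baseline_tables(self, table, expected_p):
        _, p = chi_square_2x2(*table)
        assert round(p, 3) == expected_p

    def test_identical_rows(self):
        stat, p = chi_square_2x2(4, 4, 4, 4)
        assert stat == 0.0 and p == 1.0

    def test_zero_margin_rejected(self):
        with pytest.raises(ParameterError):
            chi_square_2x2(0, 0, 3, 5)


class TestUnpairedT:
    def test_equal_means_give_p_one(self):
        assert unpaired_t_test(26, 5.1, 8, 26, 4.2, 8) == 1.0

    def test_closed_form_oracle(self):
        # pooled sd = 1, se = 1/2, t = -8, df = 14
        p = unpaired_t_test(10, 1, 8, 14, 1, 8)
        expected = 2 * sps.t.sf(8.0, 14)
        assert p == pytest.approx(expected, rel=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ParameterError):
            unpaired_t_test(1, 1, 1, 2, 1, 8)
        with pytest.raises(ParameterError):
            unpaired_t_test(1, 0, 8, 2, 1, 8)


def signed_rank_enumeration(d):
    """Two-sided exact p over all 2^n sign patterns (midranks for ties)."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    n = d.size
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = np.empty(2 ** n)
    for b in range(2 ** n):
        signs = np.array([(b >> i) & 1 for i in range(n)], dtype=bool)
        ws[b] = ranks[signs].sum()
    return min(1.0, 2 * min((ws <= w_obs + 1e-9).mean(),
                            (ws >= w_obs - 1e-9).mean()))


def rank_sum_enumeration(x, y):
    """Two-sided exact p over all C(n+m, n) group assignments."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = x.size
    ranks = sps.rankdata(np.concatenate([x, y]))
    w_obs = ranks[:n].sum()
    ws = np.array([ranks[list(c)].sum()
                   for c in combinations(range(ranks.size), n)])
    return min(1.0, 2 * min((ws <= w_obs + 1e-9).mean(),
                            (ws >= w_obs - 1e-9).mean()))


class TestWilcoxonSignedRank:
    def test_all_positive_sixteen(self):
        _, p = wilcoxon_signed_rank(np.arange(1.0, 17.0))
        assert p == pytest.approx(2 / 2 ** 16, rel=1e-12)

    def test_one_up_one_down_symmetric(self):
        _, p = wilcoxon_signed_rank([1.0, -1.0])
        assert p == 1.0

    def test_zeros_dropped(self):
        _, p_with = wilcoxon_signed_rank([0.0, 0.0, 3.0, -1.0, 2.0])
        _, p_without = wilcoxon_signed_rank([3.0, -1.0, 2.0])
        assert p_with == p_without

    def test_all_zero_degenerate(self):
        with pytest.raises(DegenerateSignalError):
            wilcoxon_signed_rank([0.0, 0.0])

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.lists(st.integers(min_value=-5, max_value=5), min_size=3,
                    max_size=8))
    def test_matches_sign_pattern_enumeration(self, d):
        d = np.asarray(d, float)
        if (d == 0).all():
            return
        _, p = wilcoxon_signed_rank(d)
        assert p == pytest.approx(signed_rank_enumeration(d), abs=1e-12)


class TestWilcoxonRankSum:
    def test_identical_samples(self):
        assert wilcoxon_rank_sum([1.0, 2, 3], [1.0, 2, 3]) == 1.0

    def test_complete_separation_eight_v_eight(self):
        p = wilcoxon_rank_sum(np.arange(9.0, 17.0), np.arange(1.0, 9.0))
        assert p == pytest.approx(2 / math.comb(16, 8), rel=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(ParameterError):
            wilcoxon_rank_sum([], [1.0])

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(st.lists(st.integers(min_value=0, max_value=8), min_size=2,
                    max_size=7),
           st.lists(st.integers(min_value=0, max_value=8), min_size=2,
                    max_size=7))
    def test_matches_subset_enumeration(self, x, y):
        p = wilcoxon_rank_sum(np.asarray(x, float), np.asarray(y, float))
        assert p == pytest.approx(rank_sum_enumeration(x, y), abs=1e-12)


def test_rank_correlation_matches_scipy():
    rng = np.random.default_rng(3)
    x, y = rng.random(16), rng.random(16)
    rho, p = rank_correlation(x, y)
    rho_ref, p_ref = sps.spearmanr(x, y)
    assert rho == pytest.approx(rho_ref) and p == pytest.approx(p_ref)


# ---------------------------------------------------------------------------
# linear mixed model


def null_study(sd=12.0):
    return StudyDesignParams(pct_change={
        "ripasudil": {"2h": (0.0, sd), "8h": (0.0, sd)},
        "latanoprost": {"2h": (0.0, sd), "8h": (0.0, sd)}})


class TestCrossoverLmm:
    def test_pure_drug_effect_recovered_exactly(self):
        """Zero within- and between-subject noise, drug effect delta:
        beta_drug = delta exactly and the residual variance is ~0."""
        delta = 17.5
        study = StudyDesignParams(
            baseline_width={"ripasudil": (60.0, 0.0), "latanoprost": (60.0, 0.0)},
            pct_change={"ripasudil": {"2h": (delta, 0.0), "8h": (delta, 0.0)},
                        "latanoprost": {"2h": (0.0, 0.0), "8h": (0.0, 0.0)}})
        table, _ = render_crossover_study(study, seed=0)
        fit = fit_crossover_lmm(table)
        assert fit.drug_effect == pytest.approx(delta, abs=1e-8)
        assert fit.sigma2 == pytest.approx(0.0, abs=1e-8)
        assert fit.drug_p == pytest.approx(0.0, abs=1e-12)

    def test_agrees_with_statsmodels_reml(self):
        import statsmodels.formula.api as smf
        table, _ = render_crossover_study(StudyDesignParams(), seed=42)
        fit = fit_crossover_lmm(table)

        from hvipipe.stats import _percent_change_outcome
        wide = _percent_change_outcome(table, "2h", "percent_change_width")
        wide = wide.assign(
            drugc=(wide.drug == "ripasudil").astype(float),
            per=(wide.period == 2).astype(float),
            seqc=pd.Categorical(wide.sequence).codes.astype(float))
        ref = smf.mixedlm("y ~ seqc + drugc + per", wide,
                          groups=wide.subject_id).fit(reml=True)
        assert fit.drug_effect == pytest.approx(ref.params["drugc"], abs=1e-4)
        assert fit.fixed_effects["drug"][1] == pytest.approx(ref.bse["drugc"],
                                                            abs=1e-4)
        assert fit.sigma2 == pytest.approx(ref.scale, rel=1e-3)
        assert fit.sigma_u2 == pytest.approx(float(ref.cov_re.iloc[0, 0]),
                                             abs=1e-3)

    def test_reduces_to_ols_when_variance_ratio_zero(self):
        import statsmodels.api as sm
        table, _ = render_crossover_study(StudyDesignParams(), seed=42)
        fit = fit_crossover_lmm(table)
        assert fit.sigma_u2 == 0.0  # this replicate profiles to the boundary

        from hvipipe.stats import _percent_change_outcome
        wide = _percent_change_outcome(table, "2h", "percent_change_width")
        x = np.column_stack([
            np.ones(len(wide)),
            pd.Categorical(wide.sequence).codes.astype(float),
            (wide.drug == "ripasudil").astype(float),
            (wide.period == 2).astype(float)])
        ols = sm.OLS(wide["y"].to_numpy(), x).fit()
        assert fit.drug_effect == pytest.approx(ols.params[2], abs=1e-6)
        assert fit.fixed_effects["drug"][1] == pytest.approx(ols.bse[2], abs=1e-6)

    def test_single_sequence_design_rejected(self):
        table, _ = render_crossover_study(StudyDesignParams(), seed=1)
        one_seq = table[table.sequence == table.sequence.iloc[0]]
        with pytest.raises(DesignError):
            fit_crossover_lmm(one_seq)

    def test_null_pvalues_are_uniform(self):
        """Under no drug effect the between-group p-values are U(0, 1):
        Kolmogorov-Smirnov not rejected at alpha = 0.01 over 500 replicates."""
        rng = np.random.default_rng(99)
        pvals = []
        for _ in range(500):
            table, _ = render_crossover_study(null_study(),
                                              seed=int(rng.integers(2 ** 31)))
            pvals.append(fit_crossover_lmm(table).drug_p)
        _, ks_p = sps.kstest(pvals, "uniform")
        assert ks_p > 0.01


class TestSummarizeStudy:
    def test_known_generator_recovered(self):
        table, _ = render_crossover_study(StudyDesignParams(n_subjects=400),
                                          seed=7)
        report = summarize_study(table)
        width = report["width"].set_index(["drug", "timepoint"])
        # 400 subjects: SE of the pct-change mean ~ 16.3/20 = 0.8
        assert width.loc[("ripasudil", "2h"), "pct_change_mean"] == pytest.approx(
            28.8, abs=3 * 16.3 / 20)
        assert width.loc[("latanoprost", "2h"), "pct_change_mean"] == pytest.approx(
            -2.5, abs=3 * 5.7 / 20)
        iop = report["iop"].set_index(["drug", "timepoint"])
        assert iop.loc[("ripasudil", "2h"), "mean"] == pytest.approx(
            10.6, abs=3 * 2.1 / 20)
        for tp in ("2h", "8h"):
            assert report["lmm"][tp].drug_p < 0.001

    def test_single_subject_flagged_sd(self):
        table, _ = render_crossover_study(StudyDesignParams(n_subjects=2), seed=3)
        one = table[table.subject_id == table.subject_id.iloc[0]]
        report = summarize_study(one)
        width = report["width"].dropna(subset=["mean"])
        assert width["sd"].isna().all()
        assert (width["n"] == 1).all()
        # between-group model is impossible with one subject -> reported None
        assert report["lmm"]["2h"] is None

    def test_missing_columns_rejected(self):
        with pytest.raises(DesignError):
            summarize_study(pd.DataFrame({"subject_id": ["a"]}))
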