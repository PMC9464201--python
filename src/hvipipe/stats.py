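"""Statistical layer for the two-sequence crossover trial.

Covers the baseline-characteristics tests (Pearson chi-square without
continuity correction, unpaired t from summary statistics, Wilcoxon rank
sum), the within-group Wilcoxon signed-rank comparisons, and the primary
between-group analysis: a linear mixed model with sequence, drug and period
as fixed effects and a random intercept for participant within sequence,
fitted by REML with a one-dimensional profile over the variance ratio.

Exact Wilcoxon p-values are computed by dynamic programming over doubled
midranks (ties allowed), which reproduces full sign-pattern / subset
enumeration without the exponential loop.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .exceptions import DegenerateSignalError, DesignError, ParameterError

__all__ = [
    "MeasurementRecord",
    "LmmFit",
    "records_to_frame",
    "chi_square_2x2",
    "unpaired_t_test",
    "wilcoxon_signed_rank",
    "wilcoxon_rank_sum",
    "rank_correlation",
    "fit_crossover_lmm",
    "summarize_study",
]

REQUIRED_COLUMNS = ("subject_id", "sequence", "period", "drug",
                    "timepoint", "width_px", "iop_mmHg")


@dataclass(frozen=True)
class MeasurementRecord:
    """One subject x period x timepoint observation."""

    subject_id: str
    sequence: str
    period: int
    drug: str
    timepoint: str
    width_px: float
    iop_mmHg: float


def records_to_frame(records: list[MeasurementRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])


@dataclass(frozen=True)
class LmmFit:
    """REML fit of the crossover linear mixed model."""

    fixed_effects: dict  # name -> (estimate, standard error)
    sigma_u2: float      # subject random-intercept variance
    sigma2: float        # residual variance
    drug_effect: float
    drug_se: float
    drug_p: float
    df: float
    df_method: str
    converged: bool
    n_obs: int
    n_subjects: int


# ---------------------------------------------------------------------------
# baseline-characteristics tests

def chi_square_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table, no continuity correction, df = 1."""
    table = np.array([[a, b], [c, d]])
    if (table < 0).any() or table.dtype.kind not in "iu":
        raise ParameterError("counts must be nonnegative integers")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ParameterError("chi-square undefined: zero row or column margin")
    if table.sum() and np.array_equal(table[0] * table[1].sum(),
                                      table[1] * table[0].sum()):
        # identical row proportions: statistic is exactly 0
        return 0.0, 1.0
    stat, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(stat), float(p)


def unpaired_t_test(mean1: float, sd1: float, n1: int,
                    mean2: float, sd2: float, n2: int) -> float:
    """Two-sided pooled-variance t-test from summary statistics."""
    if n1 < 2 or n2 < 2:
        raise ParameterError("each group needs n >= 2")
    if sd1 <= 0 or sd2 <= 0:
        raise ParameterError("SDs must be positive")
    _, p = stats.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2,
                                      equal_var=True)
    if mean1 == mean2:
        return 1.0  # t is exactly 0
    return float(p)


# ---------------------------------------------------------------------------
# exact Wilcoxon tests (doubled-midrank dynamic programming)

def _doubled_midranks(values: np.ndarray) -> np.ndarray:
    # midranks of |values|, doubled so ties (x.5 ranks) become integers
    ranks = stats.rankdata(values)
    doubled = np.rint(2 * ranks).astype(int)
    return doubled


def wilcoxon_signed_rank(differences) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zeros are dropped (classic Wilcoxon convention). For n <= 25 the exact
    two-sided p is computed over all 2^n sign patterns (via rank-sum
    counting, ties handled through midranks); larger samples use the normal
    approximation with tie correction. Returns (W+, p) where W+ is the sum
    of ranks of the positive differences.
    """
    d = np.asarray(differences, dtype=np.float64)
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise DegenerateSignalError("all differences are zero")
    d2r = _doubled_midranks(np.abs(d))
    w_plus2 = int(d2r[d > 0].sum())
    w_plus = w_plus2 / 2.0

    if n <= 25:
        total = int(d2r.sum())
        counts = np.zeros(total + 1)
        counts[0] = 1.0
        for r in d2r:
            counts[r:] = counts[r:] + counts[:total + 1 - r]
        denom = 2.0 ** n
        cdf = counts[: w_plus2 + 1].sum() / denom
        sf = counts[w_plus2:].sum() / denom
        p = min(1.0, 2.0 * min(cdf, sf))
    else:
        _, p = stats.wilcoxon(d, zero_method="wilcox", correction=False,
                              method="approx")
        p = float(p)
    return w_plus, p


def wilcoxon_rank_sum(x, y) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact by subset counting for groups of at most 10 each (ties through
    midranks); otherwise the normal approximation with tie correction.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size == 0 or y.size == 0:
        raise ParameterError("both samples must be non-empty")
    n, m = x.size, y.size
    combined = np.concatenate([x, y])
    d2r = _doubled_midranks(combined)
    w_x2 = int(d2r[:n].sum())

    if n <= 10 and m <= 10:
        total = int(d2r.sum())
        # dp[k, s]: number of k-subsets of the pooled ranks with doubled sum s
        dp = np.zeros((n + 1, total + 1))
        dp[0, 0] = 1.0
        for r in d2r:
            dp[1:, r:] = dp[1:, r:] + dp[:-1, : total + 1 - r]
        dist = dp[n]
        denom = dist.sum()  # C(n + m, n)
        cdf = dist[: w_x2 + 1].sum() / denom
        sf = dist[w_x2:].sum() / denom
        return min(1.0, 2.0 * min(cdf, sf))
    _, p = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(p)


def rank_correlation(x, y) -> tuple[float, float]:
    """Spearman rank correlation (rho, two-sided p)."""
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


# ---------------------------------------------------------------------------
# crossover linear mixed model

def _percent_change_outcome(table: pd.DataFrame, timepoint: str,
                            outcome: str) -> pd.DataFrame:
    wide = table.pivot_table(index=["subject_id", "sequence", "period", "drug"],
                             columns="timepoint", values="width_px",
                             aggfunc="first").reset_index()
    for col in ("baseline", timepoint):
        if col not in wide:
            raise DesignError(f"timepoint {col!r} missing from the table")
    missing = wide[["baseline", timepoint]].isna().any(axis=1)
    wide = wide[~missing]
    if outcome == "percent_change_width":
        wide["y"] = 100.0 * (wide[timepoint] - wide["baseline"]) / wide["baseline"]
    elif outcome == "width":
        wide["y"] = wide[timepoint]
    else:
        raise ParameterError(f"unknown outcome {outcome!r}")
    return wide


def _reml_random_intercept(y: np.ndarray, x_mat: np.ndarray,
                           groups: np.ndarray):
    """Profile-REML fit of a random-intercept model.

    Returns (beta, cov_beta, sigma_u2, sigma2, converged). The only free
    dimension is the variance ratio lambda = sigma_u^2 / sigma^2; for each
    lambda the GLS solution and the profiled residual variance are closed
    form (block-diagonal V with V_i = I + lambda J).
    """
    n_obs, p = x_mat.shape
    labels, grp = np.unique(groups, return_inverse=True)
    q = labels.size

    def pieces(lam: float):
        # V^-1 = I - (lam / (1 + n_i lam)) J within each group block
        counts = np.bincount(grp)
        shrink = lam / (1.0 + counts * lam)  # per group
        gx = np.zeros((q, p))
        gy = np.zeros(q)
        np.add.at(gx, grp, x_mat)
        np.add.at(gy, grp, y)
        xtvx = x_mat.T @ x_mat - (gx * shrink[:, None]).T @ gx
        xtvy = x_mat.T @ y - (gx * shrink[:, None]).T @ gy
        ytvy = y @ y - gy @ (shrink * gy)
        logdet_v = np.log1p(counts * lam).sum()
        return xtvx, xtvy, ytvy, logdet_v

    def neg_reml(log_lam: float) -> float:
        lam = np.exp(log_lam)
        xtvx, xtvy, ytvy, logdet_v = pieces(lam)
        try:
            beta = np.linalg.solve(xtvx, xtvy)
        except np.linalg.LinAlgError:
            return np.inf
        rss = ytvy - xtvy @ beta
        if rss <= 0:
            rss = 1e-12
        sign, logdet_x = np.linalg.slogdet(xtvx)
        if sign <= 0:
            return np.inf
        return 0.5 * ((n_obs - p) * np.log(rss / (n_obs - p))
                      + logdet_v + logdet_x)

    res = optimize.minimize_scalar(neg_reml, bounds=(-12.0, 12.0),
                                   method="bounded",
                                   options={"xatol": 1e-8})
    converged = bool(res.success)
    lam = float(np.exp(res.x))
    # compare against the lambda -> 0 boundary (plain OLS)
    if neg_reml(-30.0) <= res.fun:
        lam = 0.0
    xtvx, xtvy, ytvy, _ = pieces(lam)
    beta = np.linalg.solve(xtvx, xtvy)
    rss = max(ytvy - xtvy @ beta, 0.0)
    sigma2 = rss / (n_obs - p)
    sigma_u2 = lam * sigma2
    cov_beta = sigma2 * np.linalg.inv(xtvx)
    return beta, cov_beta, sigma_u2, sigma2, converged


def fit_crossover_lmm(
    table: pd.DataFrame | list[MeasurementRecord],
    outcome: str = "percent_change_width",
    timepoint: str = "2h",
    df_method: Literal["between-within", "normal"] = "between-within",
) -> LmmFit:
    """Fit the crossover model for the drug contrast at one timepoint.

    Model: ``y = b0 + b_seq + b_drug + b_period + u_subject + e`` with
    ``u ~ N(0, sigma_u^2)`` and ``e ~ N(0, sigma^2)``, fitted by REML via a
    1-D profile over the variance ratio.

    The drug-effect p-value defaults to the between-within (containment)
    method: a t reference with within-subject degrees of freedom and the SE
    estimated from the within-subject stratum, which is exactly calibrated
    for a balanced 2x2 crossover. ``df_method="normal"`` gives the REML Wald
    z-test instead, which is anticonservative at 16 subjects. The REML Wald
    SEs for all fixed effects are always available in ``fixed_effects``.
    """
    if not isinstance(table, pd.DataFrame):
        table = records_to_frame(table)
    missing_cols = set(REQUIRED_COLUMNS) - set(table.columns)
    if missing_cols:
        raise DesignError(f"table lacks columns: {sorted(missing_cols)}")
    if table["sequence"].nunique() < 2:
        raise DesignError("both crossover sequences must be present")
    per_seq = table.groupby("sequence")["subject_id"].nunique()
    if (per_seq < 2).any():
        raise DesignError("need at least 2 subjects per sequence")

    wide = _percent_change_outcome(table, timepoint, outcome)
    y = wide["y"].to_numpy(dtype=np.float64)
    seq_codes = pd.Categorical(wide["sequence"]).codes.astype(np.float64)
    drug_codes = (wide["drug"] == "ripasudil").astype(np.float64).to_numpy()
    period_codes = (wide["period"].to_numpy() == 2).astype(np.float64)
    x_mat = np.column_stack([np.ones_like(y), seq_codes, drug_codes, period_codes])
    names = ["intercept", "sequence", "drug", "period"]
    if np.linalg.matrix_rank(x_mat) < x_mat.shape[1]:
        raise DesignError("singular fixed-effect design")
    groups = wide["subject_id"].to_numpy()

    beta, cov, sigma_u2, sigma2, converged = _reml_random_intercept(y, x_mat, groups)
    se = np.sqrt(np.diag(cov))

    n_obs = y.size
    n_subjects = len(np.unique(groups))
    subj_means = pd.DataFrame(x_mat, index=groups).groupby(level=0).mean()
    rank_between = np.linalg.matrix_rank(subj_means.to_numpy())
    df_bw = max(n_obs - x_mat.shape[1] - (n_subjects - rank_between), 1)

    i_drug = names.index("drug")
    if df_method == "between-within":
        # containment: the drug contrast lives in the within-subject stratum,
        # so its SE comes from the within-subject residual variance. For a
        # balanced 2x2 crossover this makes the null drug-effect statistic
        # exactly t(df_bw); the pooled REML sigma^2 would leak chance
        # between-subject variation into the SE.
        subj_mean_y = pd.Series(y, index=groups).groupby(level=0).transform("mean")
        y_w = y - subj_mean_y.to_numpy()
        x_w = x_mat - subj_means.loc[groups].to_numpy()
        within_cols = [i for i in range(x_mat.shape[1])
                       if not np.allclose(x_w[:, i], 0.0)]
        if i_drug not in within_cols:
            raise DesignError("drug effect is not estimable within subjects")
        xw = x_w[:, within_cols]
        beta_w, rss_w, *_ = np.linalg.lstsq(xw, y_w, rcond=None)
        resid = y_w - xw @ beta_w
        sigma2_w = float(resid @ resid) / df_bw
        gram_inv = np.linalg.inv(xw.T @ xw)
        drug_se = float(np.sqrt(sigma2_w * gram_inv[within_cols.index(i_drug),
                                                    within_cols.index(i_drug)]))
    elif df_method == "normal":
        drug_se = float(se[i_drug])
    else:
        raise ParameterError(f"unknown df_method {df_method!r}")

    if drug_se == 0:
        p = 0.0 if beta[i_drug] != 0 else 1.0
    else:
        t_stat = beta[i_drug] / drug_se
        if df_method == "between-within":
            p = float(2.0 * stats.t.sf(abs(t_stat), df_bw))
        else:
            p = float(2.0 * stats.norm.sf(abs(t_stat)))

    return LmmFit(
        fixed_effects={nm: (float(b), float(s)) for nm, b, s in zip(names, beta, se)},
        sigma_u2=float(sigma_u2), sigma2=float(sigma2),
        drug_effect=float(beta[i_drug]), drug_se=drug_se,
        drug_p=p, df=float(df_bw if df_method == "between-within" else np.inf),
        df_method=df_method, converged=converged,
        n_obs=int(n_obs), n_subjects=int(n_subjects),
    )


# ---------------------------------------------------------------------------
# study-level report

def summarize_study(table: pd.DataFrame,
                    df_method: Literal["between-within", "normal"] = "between-within",
                    ) -> dict:
    """Per-drug summary tables and the between-group model fits.

    Returns ``{"width": DataFrame, "iop": DataFrame, "lmm": {tp: LmmFit}}``.
    The width table carries mean ± SD of the widths and of the per-subject
    percent changes, with within-group Wilcoxon signed-rank p-values against
    baseline; the iop table does the same for intraocular pressure. Missing
    cells are reported as NaN rather than raising.
    """
    missing_cols = set(REQUIRED_COLUMNS) - set(table.columns)
    if missing_cols:
        raise DesignError(f"table lacks columns: {sorted(missing_cols)}")

    def per_drug(value_col: str) -> pd.DataFrame:
        rows = []
        for drug, sub in table.groupby("drug"):
            wide = sub.pivot_table(index="subject_id", columns="timepoint",
                                   values=value_col, aggfunc="first")
            for tp in ("baseline", "2h", "8h"):
                if tp not in wide:
                    rows.append({"drug": drug, "timepoint": tp})
                    continue
                vals = wide[tp].dropna()
                row = {"drug": drug, "timepoint": tp,
                       "mean": vals.mean(),
                       "sd": vals.std(ddof=1) if len(vals) > 1 else np.nan,
                       "n": len(vals)}
                if tp != "baseline" and "baseline" in wide:
                    paired = wide[["baseline", tp]].dropna()
                    diffs = paired[tp] - paired["baseline"]
                    if value_col == "width_px":
                        pct = 100.0 * diffs / paired["baseline"]
                        row["pct_change_mean"] = pct.mean()
                        row["pct_change_sd"] = pct.std(ddof=1) if len(pct) > 1 else np.nan
                    try:
                        _, row["wilcoxon_p"] = wilcoxon_signed_rank(diffs.to_numpy())
                    except DegenerateSignalError:
                        row["wilcoxon_p"] = np.nan
                rows.append(row)
        return pd.DataFrame(rows)

    lmm_fits = {}
    for tp in ("2h", "8h"):
        try:
            lmm_fits[tp] = fit_crossover_lmm(table, timepoint=tp,
                                             df_method=df_method)
        except (DesignError, ParameterError):
            lmm_fits[tp] = None

    return {"width": per_drug("width_px"), "iop": per_drug("iop_mmHg"),
            "lmm": lmm_fits}
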