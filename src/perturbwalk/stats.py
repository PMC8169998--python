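"""Statistical battery for the group comparisons.

Covers the tests the protocol calls for: a mixed two-way repeated-measures
ANOVA (between factor: falls-history group; within factor: the Base / Pre /
Post1-8 steps), Mann-Whitney U for between-group recovery-step comparisons,
Friedman across perturbations within a group, Wilcoxon signed-rank for
paired comparisons with missing-data groups, Dunnett many-to-one and Sidak
multiple-comparison adjustments, and the effect-size / sample-size
utilities used in the power analysis.

Exact null distributions are used where samples are small (recovery-step
counts are tied integers, so the usual no-ties shortcuts do not apply):
Mann-Whitney enumerates all group labelings for n <= 8 per group; Wilcoxon
enumerates sign patterns for n <= 14 when ties are present (scipy's exact
tables otherwise, up to n = 25); beyond that, tie-corrected normal
approximations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "MixedAnovaResult",
    "mixed_anova",
    "mann_whitney_u",
    "friedman",
    "wilcoxon_signed_rank",
    "dunnett_vs_control",
    "sidak_adjust",
    "cohens_f_to_d",
    "cohens_d_to_f",
    "sample_size_rm_between",
]


# ---------------------------------------------------------------------------
# Mixed (split-plot) two-way repeated-measures ANOVA


@dataclass
class MixedAnovaResult:
    """Split-plot ANOVA table plus the exact sums-of-squares partition."""

    table: pd.DataFrame  # rows: group, step, interaction
    ss_partition: dict  # includes the two error strata and the total
    sphericity_correction: str = "none"  # "none" | "GG"
    gg_epsilon: float = 1.0
    degenerate: bool = False

    def effect(self, name: str) -> pd.Series:
        return self.table.loc[name]

    def summary(self) -> str:
        lines = ["Mixed two-way repeated-measures ANOVA"]
        if self.degenerate:
            lines.append("  DEGENERATE: zero error variance; F undefined")
        for name, row in self.table.iterrows():
            lines.append(
                f"  {name:12s} F({row['df1']:.4g}, {row['df2']:.4g}) = "
                f"{row['F']:.3f}, p = {row['p']:.4g}"
            )
        if self.sphericity_correction == "GG":
            lines.append(f"  Greenhouse-Geisser epsilon = {self.gg_epsilon:.3f}")
        return "\n".join(lines)


def _gg_epsilon(wide: np.ndarray, groups: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from the pooled within-group covariance."""
    k = wide.shape[1]
    centered = np.empty_like(wide)
    for g in np.unique(groups):
        m = groups == g
        centered[m] = wide[m] - wide[m].mean(axis=0)
    S = centered.T @ centered / max(len(wide) - len(np.unique(groups)), 1)
    C = np.eye(k) - np.ones((k, k)) / k
    M = C @ S @ C
    num = np.trace(M) ** 2
    den = (k - 1) * np.trace(M @ M)
    if den <= 0:
        return 1.0
    return float(np.clip(num / den, 1.0 / (k - 1), 1.0))


def mixed_anova(
    df: pd.DataFrame,
    dv: str = "mos",
    within: str = "step",
    between: str = "group",
    subject: str = "participant",
    correction: bool = False,
) -> MixedAnovaResult:
    """Classical mixed-design decomposition on a complete long table.

    Between stratum: group vs subjects-within-groups; within stratum: step
    and group x step vs subject x step.  Greenhouse-Geisser correction of
    the within-factor dfs is off by default (mirroring integer-df
    reporting conventions) and available via ``correction=True``.
    Missing cells raise — no imputation.
    """
    pivot = df.pivot_table(
        index=subject, columns=within, values=dv, aggfunc="mean"
    )
    if pivot.isna().any().any():
        missing = int(pivot.isna().sum().sum())
        raise ValueError(f"{missing} missing cells; mixed ANOVA needs complete data")
    counts = df.groupby(subject)[within].count()
    if counts.nunique() != 1:
        raise ValueError("unbalanced within-factor: unequal steps per participant")
    groups = df.groupby(subject)[between].first().loc[pivot.index].to_numpy()
    glabels = np.unique(groups)
    if len(glabels) < 2:
        raise ValueError("need at least 2 groups")
    if min((groups == g).sum() for g in glabels) < 2:
        raise ValueError("need at least 2 participants per group")

    y = pivot.to_numpy(dtype=float)  # subjects x steps
    n_sub, k = y.shape
    g = len(glabels)
    gm = y.mean()
    subj_means = y.mean(axis=1)
    step_means = y.mean(axis=0)  # weighted over all subjects
    ng = np.array([(groups == lab).sum() for lab in glabels])
    group_means = np.array([y[groups == lab].mean() for lab in glabels])
    cell_means = np.vstack([y[groups == lab].mean(axis=0) for lab in glabels])

    ss_total = float(((y - gm) ** 2).sum())
    ss_between_subj = float(k * ((subj_means - gm) ** 2).sum())
    ss_group = float(k * (ng * (group_means - gm) ** 2).sum())
    ss_err_between = ss_between_subj - ss_group
    ss_step = float(n_sub * ((step_means - gm) ** 2).sum())
    ss_cells_within = float(
        (ng[:, None] * (cell_means - group_means[:, None]) ** 2).sum()
    )
    ss_inter = ss_cells_within - ss_step
    ss_err_within = ss_total - ss_between_subj - ss_step - ss_inter

    df_group, df_err_b = g - 1, n_sub - g
    df_step, df_inter = k - 1, (g - 1) * (k - 1)
    df_err_w = (n_sub - g) * (k - 1)

    eps = 1.0
    corr_name = "none"
    if correction:
        eps = _gg_epsilon(y, groups)
        corr_name = "GG"

    degenerate = ss_err_between <= 1e-12 * max(ss_total, 1.0) or (
        ss_err_within <= 1e-12 * max(ss_total, 1.0)
    )

    def frow(ss_eff, df_eff, ss_err, df_err, within_stratum):
        e = eps if (correction and within_stratum) else 1.0
        if degenerate or ss_err <= 0 or df_err <= 0:
            return ss_eff, df_eff * e, df_err * e, np.nan, np.nan
        F = (ss_eff / df_eff) / (ss_err / df_err)
        p = float(sps.f.sf(F, df_eff * e, df_err * e))
        return ss_eff, df_eff * e, df_err * e, F, p

    rows = {
        "group": frow(ss_group, df_group, ss_err_between, df_err_b, False),
        "step": frow(ss_step, df_step, ss_err_within, df_err_w, True),
        "interaction": frow(ss_inter, df_inter, ss_err_within, df_err_w, True),
    }
    table = pd.DataFrame(
        rows, index=["SS", "df1", "df2", "F", "p"]
    ).T
    partition = {
        "group": ss_group,
        "error_between": ss_err_between,
        "step": ss_step,
        "interaction": ss_inter,
        "error_within": ss_err_within,
        "total": ss_total,
    }
    return MixedAnovaResult(
        table=table,
        ss_partition=partition,
        sphericity_correction=corr_name,
        gg_epsilon=eps,
        degenerate=degenerate,
    )


# ---------------------------------------------------------------------------
# Rank tests


def _u_from_ranksum(ranksum: float, n: int) -> float:
    return ranksum - n * (n + 1) / 2.0


def mann_whitney_u(x, y, exact_max: int = 8, alternative: str = "two-sided"):
    """Mann-Whitney U with U = min(U1, U2).

    Exact permutation null (full enumeration of group labelings, valid under
    ties) when both samples have at most ``exact_max`` observations;
    tie-corrected normal approximation with continuity correction otherwise.
    Returns ``(U, p)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty sample")
    n, m = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    u1 = _u_from_ranksum(ranks[:n].sum(), n)
    u2 = n * m - u1
    u = min(u1, u2)
    if max(n, m) <= exact_max:
        # enumerate all C(n+m, n) assignments of pooled values to group x
        stat_obs = u if alternative == "two-sided" else u1
        count = 0
        total = 0
        for idx in combinations(range(n + m), n):
            r = ranks[list(idx)].sum()
            pu1 = _u_from_ranksum(r, n)
            total += 1
            if alternative == "two-sided":
                if min(pu1, n * m - pu1) <= stat_obs + 1e-9:
                    count += 1
            elif alternative == "less":
                if pu1 <= stat_obs + 1e-9:
                    count += 1
            else:  # greater
                if pu1 >= stat_obs - 1e-9:
                    count += 1
        p = count / total
    else:
        res = sps.mannwhitneyu(x, y, alternative=alternative, method="asymptotic")
        p = float(res.pvalue)
    return float(u), float(min(p, 1.0))


def friedman(table, allow_incomplete: bool = False):
    """Friedman rank test over a blocks x conditions table.

    Tie-corrected chi-square: with within-block midranks r_ij and column
    rank sums R_j,

        chi2 = (k - 1) [sum R_j^2 - n^2 k (k+1)^2 / 4]
               / [sum r_ij^2 - n k (k+1)^2 / 4]

    which reduces to the textbook 12/(nk(k+1)) form without ties, and — for
    two conditions — to the sign test's (n+ - n-)^2 / n.  Incomplete blocks
    raise: the protocol's fallback for incomplete data is pairwise Wilcoxon
    tests.  Returns ``(statistic, p)``.
    """
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("need a blocks x conditions table, >= 2 each")
    if np.isnan(arr).any():
        if not allow_incomplete:
            raise ValueError(
                "incomplete blocks; drop them or use wilcoxon_signed_rank pairs"
            )
        arr = arr[~np.isnan(arr).any(axis=1)]
        if arr.shape[0] < 2:
            raise ValueError("fewer than 2 complete blocks")
    n, k = arr.shape
    ranks = np.apply_along_axis(sps.rankdata, 1, arr)
    col_sums = ranks.sum(axis=0)
    num = (k - 1) * (np.sum(col_sums ** 2) - n * n * k * (k + 1) ** 2 / 4.0)
    den = np.sum(ranks ** 2) - n * k * (k + 1) ** 2 / 4.0
    if den <= 0:  # every block fully tied: no evidence either way
        return 0.0, 1.0
    stat = num / den
    return float(stat), float(sps.chi2.sf(stat, k - 1))


@dataclass
class WilcoxonResult:
    W: float
    p: float
    degenerate: bool = False

    def __iter__(self):
        return iter((self.W, self.p))


def wilcoxon_signed_rank(
    x, y=None, exact_max: int = 25, alternative: str = "two-sided"
) -> WilcoxonResult:
    """Wilcoxon signed-rank test, W = min(W+, W-).

    Zero differences are dropped (all zeros -> degenerate flag, p = 1).
    Exact null for n <= ``exact_max`` without ties (scipy), own sign-pattern
    enumeration for tied data up to n = 14, tie-corrected normal
    approximation beyond.
    """
    x = np.asarray(x, dtype=float)
    d = x - np.asarray(y, dtype=float) if y is not None else x
    d = d[d != 0]
    n = d.size
    if n == 0:
        return WilcoxonResult(W=0.0, p=1.0, degenerate=True)
    ranks = sps.rankdata(np.abs(d))
    w_plus = ranks[d > 0].sum()
    w_minus = ranks[d < 0].sum()
    w = min(w_plus, w_minus)
    has_ties = len(np.unique(np.abs(d))) < n
    if not has_ties and n <= exact_max:
        res = sps.wilcoxon(d, alternative=alternative, method="exact")
        return WilcoxonResult(W=float(w), p=float(res.pvalue))
    if has_ties and n <= 14:
        # enumerate all 2^n sign patterns of the observed |d| ranks
        signs = ((np.arange(2 ** n)[:, None] >> np.arange(n)) & 1).astype(bool)
        wp = np.where(signs, ranks, 0.0).sum(axis=1)
        total_rank = ranks.sum()
        wmin = np.minimum(wp, total_rank - wp)
        if alternative == "two-sided":
            p = float(np.mean(wmin <= w + 1e-9))
        elif alternative == "greater":  # x tends larger: small w_minus
            p = float(np.mean(total_rank - wp <= w_minus + 1e-9))
        else:
            p = float(np.mean(wp <= w_plus + 1e-9))
        return WilcoxonResult(W=float(w), p=min(p, 1.0))
    # tie-corrected normal approximation with continuity correction
    mean = n * (n + 1) / 4.0
    ties = np.unique(np.abs(d), return_counts=True)[1]
    var = n * (n + 1) * (2 * n + 1) / 24.0 - (ties ** 3 - ties).sum() / 48.0
    if alternative == "two-sided":
        z = (w - mean + 0.5) / np.sqrt(var)
        p = float(min(1.0, 2 * sps.norm.cdf(z)))
    else:
        stat = w_minus if alternative == "greater" else w_plus
        z = (stat - mean + 0.5) / np.sqrt(var)
        p = float(sps.norm.cdf(z))
    return WilcoxonResult(W=float(w), p=p)


# ---------------------------------------------------------------------------
# Multiple comparisons


def dunnett_vs_control(
    data: pd.DataFrame,
    control: str,
    n_sim: int = 100_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Within-subject Dunnett many-to-one comparisons against a control column.

    ``data`` is wide (participants x conditions).  Each condition is compared
    to the control with a paired t statistic; the family-wise adjustment uses
    seeded Monte-Carlo quantiles of the maximum of a multivariate t whose
    correlation is estimated from the paired differences.  Adjusted p-values
    are forced to be at least the unadjusted ones.
    """
    if control not in data.columns:
        raise ValueError(f"control column {control!r} not in table")
    others = [c for c in data.columns if c != control]
    if not others:
        raise ValueError("no comparison columns")
    diffs = data[others].to_numpy(float) - data[[control]].to_numpy(float)
    n, k = diffs.shape
    if n < 2:
        raise ValueError("need at least 2 subjects")
    df_err = n - 1
    means = diffs.mean(axis=0)
    sds = diffs.std(axis=0, ddof=1)
    if np.any(sds <= 0):
        raise ValueError("a contrast has zero variance")
    tstats = means / (sds / np.sqrt(n))
    p_unadj = 2 * sps.t.sf(np.abs(tstats), df_err)
    if k == 1:
        p_adj = p_unadj.copy()
    else:
        R = np.corrcoef(diffs, rowvar=False)
        # regularize toward identity if degenerate
        jitter = 1e-8
        while True:
            try:
                L = np.linalg.cholesky(R + jitter * np.eye(k))
                break
            except np.linalg.LinAlgError:
                jitter *= 10
        rng = np.random.default_rng(seed)
        z = rng.standard_normal((n_sim, k)) @ L.T
        s = np.sqrt(rng.chisquare(df_err, size=n_sim) / df_err)
        max_t = np.max(np.abs(z) / s[:, None], axis=1)
        p_adj = np.array([np.mean(max_t >= abs(t)) for t in tstats])
        p_adj = np.maximum(p_adj, p_unadj)
    return pd.DataFrame(
        {
            "comparison": [f"{c} - {control}" for c in others],
            "mean_diff": means,
            "t": tstats,
            "df": df_err,
            "p_unadjusted": p_unadj,
            "p_adjusted": np.minimum(p_adj, 1.0),
        }
    ).set_index("comparison")


def sidak_adjust(p_values, k: int | None = None) -> np.ndarray:
    """Sidak adjustment: p_adj = 1 - (1 - p)^k, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    kk = k if k is not None else p.size
    return np.minimum(1.0, 1.0 - (1.0 - p) ** kk)


# ---------------------------------------------------------------------------
# Effect size and sample size


def cohens_f_to_d(f: float) -> float:
    """Two-group contrast: d = 2 f."""
    if f < 0:
        raise ValueError("Cohen's f must be non-negative")
    return 2.0 * f


def cohens_d_to_f(d: float) -> float:
    if d < 0:
        raise ValueError("Cohen's d must be non-negative")
    return d / 2.0


def sample_size_rm_between(
    f: float,
    alpha: float = 0.05,
    power: float = 0.8,
    n_groups: int = 2,
    n_measures: int = 1,
    rho: float = 0.5,
    max_n: int = 100_000,
):
    """Smallest total N for the between-group effect in a repeated-measures design.

    Noncentral-F power with the repeated-measures efficiency multiplier
    m / (1 + (m - 1) rho): each of the m correlated measures adds
    information inversely with their correlation.  Returns
    ``(total_n, achieved_power)`` over balanced groups.
    """
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValueError("alpha and power must lie in (0, 1)")
    if f <= 0:
        raise ValueError("effect size f must be positive")
    if not (0 <= rho < 1):
        raise ValueError("rho must lie in [0, 1)")
    if n_groups < 2 or n_measures < 1:
        raise ValueError("need >= 2 groups and >= 1 measure")
    multiplier = n_measures / (1.0 + (n_measures - 1) * rho)
    df1 = n_groups - 1
    n = 2 * n_groups
    while n <= max_n:
        df2 = n - n_groups
        lam = f * f * n * multiplier
        crit = sps.f.isf(alpha, df1, df2)
        achieved = float(sps.ncf.sf(crit, df1, df2, lam))
        if achieved >= power:
            return n, achieved
        n += n_groups
    raise ValueError(f"target power not attainable with N <= {max_n}")
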