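"""Nonparametric cohort statistics for paired imaging indices.

Paired pre/post comparisons use the Wilcoxon signed-rank test, associations
between reduction ratios use Spearman's rank correlation, and subgroup
contrasts (ISUP grade group 5 vs <5, ADT scheme) use the Mann-Whitney U
test — all two-sided at the 5% level, with no multiple-testing adjustment
(each index is reported with its unadjusted p).

Exact null distributions are used whenever feasible. scipy's ``exact``
methods assume untied ranks, so instances with midrank ties get a dedicated
exhaustive permutation enumeration here (sign flips for the signed-rank
test, group assignments for Mann-Whitney); this is the conditional exact
test given the observed tie pattern. Larger or heavily tied instances fall
back to the normal approximation with tie correction.

A cohort record is one row of a :class:`pandas.DataFrame` carrying the
clinical covariates (``patient_id``, ``isup_group``, ``isup_stratum``,
``adt_scheme``, ``psa_pre``, ``psa_post``) plus per-index ``{scope}_{index}_pre``,
``{scope}_{index}_post`` and ``rr_{scope}_{index}`` columns as produced by
:func:`psmaquant.pipeline.analyze_cohort`. Missing compartments are missing
values, and every summary reports its per-row n (pairwise deletion).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateDataError, ValidationError

#: index columns of a cohort table, in reporting order
INDEX_SCOPES = ("prostate", "node", "bone", "wb")
INDEX_NAMES = ("suvmax", "psma_tv", "psma_tl")

_EXACT_WILCOXON_N = 25  # scipy exact recursion, tie-free
_EXACT_WILCOXON_TIED_N = 20  # own sign-flip enumeration (2^n patterns)
_EXACT_MWU_MIN_N = 8
_EXACT_MWU_TIED_COMB = 300_000
_EXACT_SPEARMAN_N = 9


@dataclass
class StatResult:
    statistic: float
    p_value: float
    n: int
    method: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValidationError(f"p-value {self.p_value} outside [0, 1]")


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank


def _signflip_p(ranks: np.ndarray, w_obs: float) -> float:
    """Exact two-sided sign-flip p given midranks (distribution is symmetric)."""
    n = len(ranks)
    mu = ranks.sum() / 2.0
    patterns = (np.arange(2**n, dtype=np.int64)[:, None] >> np.arange(n)) & 1
    w = patterns.astype(np.float64) @ ranks
    return float(np.mean(np.abs(w - mu) >= abs(w_obs - mu) - 1e-9))


def wilcoxon_signed_rank(pre, post) -> StatResult:
    """Two-sided paired Wilcoxon signed-rank test of pre vs post values.

    Zero differences are dropped (classic convention). The exact permutation
    null is used for n <= 25 (tie-free, scipy's recursion) or n <= 20 with
    ties (sign-flip enumeration on midranks); otherwise the normal
    approximation with tie correction.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape:
        raise ValidationError("pre and post must have equal length")
    d = post - pre
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise DegenerateDataError("all paired differences are zero")
    ranks = sps.rankdata(np.abs(d))
    tied = len(np.unique(np.abs(d))) < n
    w_pos = float(ranks[d > 0].sum())
    w_neg = float(ranks[d < 0].sum())
    statistic = min(w_pos, w_neg)
    if not tied and n <= _EXACT_WILCOXON_N:
        p = float(sps.wilcoxon(d, method="exact").pvalue)
        method = "wilcoxon-exact"
    elif tied and n <= _EXACT_WILCOXON_TIED_N:
        p = _signflip_p(ranks, w_pos)
        method = "wilcoxon-exact-tied"
    else:
        p = float(sps.wilcoxon(d, method="approx", correction=False).pvalue)
        method = "wilcoxon-normal"
    return StatResult(statistic, min(p, 1.0), n, method)


# ---------------------------------------------------------------------------
# Mann-Whitney U


def mann_whitney_u(group_a, group_b) -> StatResult:
    """Two-sided Mann-Whitney U test between two independent groups.

    Exact enumeration when min(n_a, n_b) <= 8 (scipy's tie-free recursion,
    or a full combination enumeration when ties are present and feasible);
    otherwise the normal approximation with tie correction.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValidationError("both groups must be non-empty")
    n_a, n_b = len(a), len(b)
    pooled = np.concatenate([a, b])
    tied = len(np.unique(pooled)) < len(pooled)
    n_min = min(n_a, n_b)
    if n_min <= _EXACT_MWU_MIN_N and not tied:
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        return StatResult(float(res.statistic), float(res.pvalue), n_a + n_b, "mwu-exact")
    if n_min <= _EXACT_MWU_MIN_N and math.comb(n_a + n_b, n_min) <= _EXACT_MWU_TIED_COMB:
        ranks = sps.rankdata(pooled)
        u_obs = float(ranks[:n_a].sum() - n_a * (n_a + 1) / 2.0)
        mu = n_a * n_b / 2.0
        k = min(n_a, n_b)
        offset = k * (k + 1) / 2.0
        count = total = 0
        for comb in itertools.combinations(ranks, k):
            u = sum(comb) - offset
            if n_min != n_a:  # enumerated the smaller group; reflect to U of a
                u = n_a * n_b - u
            total += 1
            if abs(u - mu) >= abs(u_obs - mu) - 1e-9:
                count += 1
        return StatResult(u_obs, count / total, n_a + n_b, "mwu-exact-tied")
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return StatResult(float(res.statistic), float(res.pvalue), n_a + n_b, "mwu-normal")


# ---------------------------------------------------------------------------
# Spearman correlation


def spearman_correlation(x, y) -> StatResult:
    """Spearman's rho (midrank Pearson) with a two-sided p.

    Exact permutation p for n <= 9 (all n! orderings of one variable's
    ranks); Student-t approximation otherwise. Constant input has no defined
    rank correlation and raises :class:`DegenerateDataError`.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("x and y must have equal length")
    n = len(x)
    if n < 3:
        raise ValidationError("Spearman correlation needs n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise DegenerateDataError("constant input: rank correlation undefined")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= _EXACT_SPEARMAN_N:
        perms = np.array(list(itertools.permutations(ry)), dtype=float)
        rxc = rx - rx.mean()
        pc = perms - ry.mean()
        num = pc @ rxc
        den = math.sqrt(float(rxc @ rxc)) * np.sqrt((pc**2).sum(axis=1))
        rho_perm = num / den
        p = float(np.mean(np.abs(rho_perm) >= abs(rho) - 1e-12))
        method = "spearman-exact"
    else:
        p = float(sps.spearmanr(x, y).pvalue)
        method = "spearman-t"
    return StatResult(rho, min(p, 1.0), n, method)


# ---------------------------------------------------------------------------
# Cohort drivers


def _index_columns():
    for scope in INDEX_SCOPES:
        for index in INDEX_NAMES:
            yield scope, index


def _filled_post(records: pd.DataFrame, col_pre: str, col_post: str) -> pd.DataFrame:
    """Rows with a present baseline; an absent follow-up compartment counts as
    a fully regressed burden of 0 for the paired comparison."""
    sub = records.loc[records[col_pre].notna(), [col_pre, col_post]].copy()
    sub[col_post] = sub[col_post].fillna(0.0)
    return sub


def summarize_cohort(
    records: pd.DataFrame, stratify: str | None = None
) -> pd.DataFrame:
    """Mean +/- SD of every index before/after plus its reduction ratio.

    One row per (scope, index) — or per (stratum, scope, index) with
    ``stratify`` — with the per-row n after pairwise deletion of patients
    lacking that compartment. SD is reported as 0 for n = 1.
    """
    if len(records) == 0:
        raise ValidationError("need at least one cohort record")
    groups = (
        [(None, records)]
        if stratify is None
        else list(records.groupby(stratify, observed=True))
    )
    rows = []
    for stratum, sub in groups:
        for scope, index in _index_columns():
            pre_col, post_col = f"{scope}_{index}_pre", f"{scope}_{index}_post"
            rr_col = f"rr_{scope}_{index}"
            if pre_col not in sub.columns:
                continue
            pair = _filled_post(sub, pre_col, post_col)
            n = len(pair)
            if n == 0:
                continue
            rr = sub.loc[sub[pre_col].notna(), rr_col].dropna()
            row = {
                "scope": scope,
                "index": index,
                "n": n,
                "mean_pre": float(pair[pre_col].mean()),
                "sd_pre": float(pair[pre_col].std(ddof=1)) if n > 1 else 0.0,
                "mean_post": float(pair[post_col].mean()),
                "sd_post": float(pair[post_col].std(ddof=1)) if n > 1 else 0.0,
                "mean_rr": float(rr.mean()) if len(rr) else float("nan"),
                "sd_rr": float(rr.std(ddof=1)) if len(rr) > 1 else 0.0,
            }
            if stratify is not None:
                row = {stratify: stratum, **row}
            rows.append(row)
    return pd.DataFrame(rows)


def paired_index_tests(records: pd.DataFrame) -> pd.DataFrame:
    """Wilcoxon signed-rank test of every index before vs after treatment."""
    rows = []
    for scope, index in _index_columns():
        pre_col, post_col = f"{scope}_{index}_pre", f"{scope}_{index}_post"
        pair = _filled_post(records, pre_col, post_col)
        if len(pair) < 2:
            continue
        try:
            res = wilcoxon_signed_rank(pair[pre_col], pair[post_col])
        except DegenerateDataError:
            continue
        rows.append(
            {
                "scope": scope,
                "index": index,
                "n": res.n,
                "statistic": res.statistic,
                "p_value": res.p_value,
                "method": res.method,
            }
        )
    return pd.DataFrame(rows)


def compare_strata(
    records: pd.DataFrame, by: str = "isup_stratum"
) -> pd.DataFrame:
    """Subgroup contrast of every index and its reduction ratio.

    Lays out, per (scope, index), the two group means before and after
    treatment and for the reduction ratio, each with a Mann-Whitney U p —
    the layout used to contrast ISUP grade-group strata.
    """
    levels = sorted(records[by].dropna().unique())
    if len(levels) != 2:
        raise ValidationError(f"{by!r} must have exactly 2 levels, got {levels}")
    g1, g2 = levels
    rows = []
    for scope, index in _index_columns():
        pre_col, post_col = f"{scope}_{index}_pre", f"{scope}_{index}_post"
        rr_col = f"rr_{scope}_{index}"
        row: dict = {"scope": scope, "index": index}
        for phase, col in (("pre", pre_col), ("post", post_col), ("rr", rr_col)):
            if phase == "post":
                sub = _filled_post(records.assign(_g=records[by]), pre_col, post_col)
                sub["_g"] = records.loc[sub.index, by]
                a = sub.loc[sub["_g"] == g1, col]
                b = sub.loc[sub["_g"] == g2, col]
            else:
                a = records.loc[records[by] == g1, col].dropna()
                b = records.loc[records[by] == g2, col].dropna()
            if len(a) == 0 or len(b) == 0:
                row[f"mean_{phase}_{g1}"] = row[f"mean_{phase}_{g2}"] = float("nan")
                row[f"p_{phase}"] = float("nan")
                continue
            row[f"mean_{phase}_{g1}"] = float(np.mean(a))
            row[f"mean_{phase}_{g2}"] = float(np.mean(b))
            row[f"p_{phase}"] = mann_whitney_u(a, b).p_value
        rows.append(row)
    return pd.DataFrame(rows)


def correlate_with_psa(records: pd.DataFrame) -> pd.DataFrame:
    """Spearman correlation of the PSA reduction ratio with every index's."""
    if "rr_psa" not in records.columns:
        raise ValidationError("records lack an rr_psa column")
    rows = []
    for scope, index in _index_columns():
        rr_col = f"rr_{scope}_{index}"
        sub = records[["rr_psa", rr_col]].dropna()
        if len(sub) < 3:
            continue
        res = spearman_correlation(sub["rr_psa"], sub[rr_col])
        rows.append(
            {
                "scope": scope,
                "index": index,
                "n": res.n,
                "rho": res.statistic,
                "p_value": res.p_value,
                "method": res.method,
            }
        )
    return pd.DataFrame(rows)


def validate_cohort_records(records: pd.DataFrame) -> None:
    """Check the cohort-record invariants (positive baseline PSA, consistent strata)."""
    if (records["psa_pre"] <= 0).any():
        raise ValidationError("psa_pre must be > 0 for every record")
    eq5 = records["isup_stratum"] == "eq5"
    if not (eq5 == (records["isup_group"] == 5)).all():
        raise ValidationError("isup_stratum inconsistent with isup_group")
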