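"""Rank-based biomarker screening.

The central operation is a volcano screen of ~105 flow-derived immune
parameters between the composite Sepsis and No-Sepsis groups: effect size
is the log2 ratio of group medians, significance a two-tailed Mann-Whitney
test with Benjamini-Hochberg false-discovery control, and a parameter is
called when |log2FC| > 0.6 and BH-adjusted p < 0.01. Around it sit the
supporting analyses: 15-day age-bracket comparisons of developmental trends
within No-Sepsis samples, age-stratified re-screens (days 1-30 vs >30),
episode stratification by CRP rise (>10 mg/L), Kruskal-Wallis/Dunn
multi-group plasma comparisons, and mixed-model confounder adjustment with
a per-baby random intercept (REML).
"""

from __future__ import annotations

import math
import warnings
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .classify import COMPOSITE_OF
from .simulate import PARAM_PREFIX

__all__ = [
    "log2fc_medians",
    "mann_whitney_two_sided",
    "bh_adjust",
    "volcano_screen",
    "age_bracket_analysis",
    "stratified_screen",
    "crp_stratify_episodes",
    "multi_group_compare",
    "adjust_confounders",
]


def _clean(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return x[~np.isnan(x)]


def log2fc_medians(a, b, eps: float | None = None) -> float:
    """log2 fold change of group medians, ``median(a)`` over ``median(b)``.

    When either median is zero a pseudocount is added to both (by default
    half the smallest positive observed value) so that frequencies or
    counts of exactly zero remain comparable. Both medians zero returns 0
    with a warning.
    """
    a, b = _clean(a), _clean(b)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    ma, mb = float(np.median(a)), float(np.median(b))
    if ma > 0 and mb > 0:
        return float(np.log2(ma / mb))
    pooled = np.concatenate([a, b])
    positive = pooled[pooled > 0]
    if eps is None:
        if len(positive) == 0:
            warnings.warn("both medians zero and no positive values; log2FC set to 0", stacklevel=2)
            return 0.0
        eps = 0.5 * float(positive.min())
    if ma == 0 and mb == 0:
        warnings.warn("both group medians are zero; log2FC set to 0", stacklevel=2)
        return 0.0
    return float(np.log2((ma + eps) / (mb + eps)))


def mann_whitney_two_sided(a, b) -> float:
    """Two-tailed Mann-Whitney p-value.

    Exact enumeration for small samples (n_a + n_b <= 20 without ties);
    tie-corrected normal approximation otherwise.
    """
    a, b = _clean(a), _clean(b)
    if len(a) < 1 or len(b) < 1:
        raise ValueError("both groups need at least one observation")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 1.0
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (len(pooled) <= 20 and no_ties) else "asymptotic"
    p = stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue
    return float(min(1.0, p))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, original order preserved.

    NaN entries (not-evaluable tests) are passed through and do not count
    toward the number of hypotheses.
    """
    p = np.asarray(p_values, dtype=float)
    ok = ~np.isnan(p)
    if np.any((p[ok] < 0) | (p[ok] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full(p.shape, np.nan)
    if ok.sum():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def _screen_two_groups(
    group_a: pd.DataFrame,
    group_b: pd.DataFrame,
    parameters: list[str],
    fc_threshold: float,
    alpha: float,
    min_per_group: int,
) -> pd.DataFrame:
    rows = []
    for name in parameters:
        col = PARAM_PREFIX + name if PARAM_PREFIX + name in group_a.columns else name
        a = _clean(group_a[col]) if col in group_a.columns else np.array([])
        b = _clean(group_b[col]) if col in group_b.columns else np.array([])
        if len(a) < min_per_group or len(b) < min_per_group:
            rows.append((name, np.nan, np.nan, len(a), len(b), False))
            continue
        rows.append(
            (name, log2fc_medians(a, b), mann_whitney_two_sided(a, b), len(a), len(b), True)
        )
    res = pd.DataFrame(rows, columns=["parameter", "log2fc", "p_raw", "n_a", "n_b", "evaluable"])
    res["p_adj"] = bh_adjust(res["p_raw"].to_numpy())
    res["significant"] = (
        res["evaluable"]
        & (res["log2fc"].abs() > fc_threshold)
        & (res["p_adj"] < alpha)
    )
    return res[["parameter", "log2fc", "p_raw", "p_adj", "significant", "n_a", "n_b", "evaluable"]]


def volcano_screen(
    labeled: pd.DataFrame,
    parameters: list[str] | None = None,
    fc_threshold: float = 0.6,
    alpha: float = 0.01,
    min_per_group: int = 2,
) -> pd.DataFrame:
    """Sepsis vs No-Sepsis screen over all immune parameters.

    Expects classified samples (NEC and repeat-episode samples removed
    upstream). One row per parameter with log2FC, raw and BH-adjusted p,
    the per-group n actually used after QC missingness, and the
    significance call |log2FC| > ``fc_threshold`` and adjusted p < ``alpha``.
    """
    if "composite" not in labeled.columns:
        raise ValueError("samples must carry a 'composite' column; run classification first")
    if parameters is None:
        parameters = [c[len(PARAM_PREFIX):] for c in labeled.columns if c.startswith(PARAM_PREFIX)]
    sep = labeled.loc[labeled["composite"] == "Sepsis"]
    nosep = labeled.loc[labeled["composite"] == "NoSepsis"]
    return _screen_two_groups(sep, nosep, parameters, fc_threshold, alpha, min_per_group)


def age_bracket(day: int, bracket_days: int = 15) -> int:
    """1-based age bracket of a postnatal day: days 1-15 -> 1, 16-30 -> 2, ..."""
    return (int(day) - 1) // bracket_days + 1


def age_bracket_analysis(
    labeled: pd.DataFrame,
    parameters: list[str] | None = None,
    bracket_days: int = 15,
    alpha: float = 0.05,
    min_per_group: int = 2,
) -> pd.DataFrame:
    """Neighbouring 15-day age-bracket comparisons within No-Sepsis samples.

    Restricted to composite No-Sepsis rows; each parameter is compared
    between consecutive non-empty brackets with a two-sided Mann-Whitney
    test, BH-corrected across the whole parameter-by-comparison grid.
    """
    if "composite" in labeled.columns:
        df = labeled.loc[labeled["composite"] == "NoSepsis"].copy()
    else:
        df = labeled.copy()
    if parameters is None:
        parameters = [c[len(PARAM_PREFIX):] for c in df.columns if c.startswith(PARAM_PREFIX)]
    df["bracket"] = df["postnatal_day"].map(lambda d: age_bracket(d, bracket_days))
    brackets = sorted(df["bracket"].unique())
    rows = []
    for lo, hi in zip(brackets[:-1], brackets[1:]):
        if hi != lo + 1:
            continue  # a gap in coverage: not neighbours
        ga = df.loc[df["bracket"] == lo]
        gb = df.loc[df["bracket"] == hi]
        for name in parameters:
            col = PARAM_PREFIX + name if PARAM_PREFIX + name in df.columns else name
            a, b = _clean(ga[col]), _clean(gb[col])
            if len(a) < min_per_group or len(b) < min_per_group:
                rows.append((name, lo, hi, np.nan, len(a), len(b)))
                continue
            rows.append((name, lo, hi, mann_whitney_two_sided(a, b), len(a), len(b)))
    res = pd.DataFrame(rows, columns=["parameter", "bracket_a", "bracket_b", "p_raw", "n_a", "n_b"])
    res["p_adj"] = bh_adjust(res["p_raw"].to_numpy())
    res["significant"] = res["p_adj"] < alpha
    return res


def stratified_screen(
    labeled: pd.DataFrame,
    boundary_day: int = 30,
    parameters: list[str] | None = None,
    fc_threshold: float = 0.6,
    alpha: float = 0.01,
    min_per_group: int = 2,
) -> dict[str, pd.DataFrame]:
    """Volcano screen repeated within postnatal-age strata.

    Default strata are days 1-``boundary_day`` and >``boundary_day``; an
    empty stratum yields an empty result table.
    """
    early = labeled.loc[labeled["postnatal_day"] <= boundary_day]
    late = labeled.loc[labeled["postnatal_day"] > boundary_day]
    out = {}
    for key, df in ((f"1-{boundary_day}d", early), (f">{boundary_day}d", late)):
        if len(df) == 0:
            out[key] = pd.DataFrame(
                columns=["parameter", "log2fc", "p_raw", "p_adj", "significant", "n_a", "n_b", "evaluable"]
            )
        else:
            out[key] = volcano_screen(df, parameters, fc_threshold, alpha, min_per_group)
    return out


def crp_stratify_episodes(
    labeled: pd.DataFrame, cutoff: float = 10.0, crp_col: str = "crp_mg_per_L"
) -> dict[str, list[str]]:
    """Partition sepsis episodes by peak CRP during the episode.

    Strictly greater than ``cutoff`` (mg/L) counts as a rise; episodes whose
    CRP is entirely missing are flagged unclassifiable.
    """
    sepsis = labeled.loc[
        labeled["category"].isin(["MCS", "ClinSep"])
        & (labeled["episode_id"].fillna("").astype(str) != "")
    ]
    rise, no_rise, unclassifiable = [], [], []
    for ep_id, grp in sepsis.groupby("episode_id", sort=True):
        peaks = _clean(grp[crp_col])
        if len(peaks) == 0:
            unclassifiable.append(ep_id)
        elif peaks.max() > cutoff:
            rise.append(ep_id)
        else:
            no_rise.append(ep_id)
    return {"rise": rise, "no_rise": no_rise, "unclassifiable": unclassifiable}


def multi_group_compare(values, group_labels, p_adjust: str = "bonferroni") -> dict:
    """Kruskal-Wallis omnibus test with Dunn's post-hoc pairwise z-tests.

    Dunn's comparisons use pooled mean ranks with tie-corrected variance;
    pairwise p-values are Bonferroni-adjusted over the k(k-1)/2 comparisons
    (the classic Dunn correction). Empty groups are dropped with a warning;
    fewer than three groups is an error directing to a two-group test.
    """
    values = np.asarray(values, dtype=float)
    group_labels = np.asarray(group_labels)
    ok = ~np.isnan(values)
    values, group_labels = values[ok], group_labels[ok]
    groups = []
    names = []
    for g in pd.unique(group_labels):
        v = values[group_labels == g]
        if len(v) == 0:
            warnings.warn(f"group {g!r} is empty and was dropped", stacklevel=2)
            continue
        groups.append(v)
        names.append(g)
    if len(groups) < 3:
        raise ValueError("need at least three non-empty groups; use a two-group test instead")

    if all(np.array_equal(np.sort(g), np.sort(groups[0])) for g in groups[1:]):
        h_stat, p_omni = 0.0, 1.0
    else:
        h_stat, p_omni = stats.kruskal(*groups)

    pooled = np.concatenate(groups)
    n_total = len(pooled)
    ranks = stats.rankdata(pooled)
    mean_ranks, sizes = [], []
    start = 0
    for g in groups:
        mean_ranks.append(float(np.mean(ranks[start:start + len(g)])))
        sizes.append(len(g))
        start += len(g)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var_base = n_total * (n_total + 1) / 12.0
    if n_total > 1:
        var_base -= tie_term / (12.0 * (n_total - 1))

    n_comp = len(groups) * (len(groups) - 1) // 2
    rows = []
    for i, j in combinations(range(len(groups)), 2):
        se = math.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        p = 2.0 * stats.norm.sf(abs(z))
        p_adj = min(1.0, p * n_comp) if p_adjust == "bonferroni" else p
        rows.append((names[i], names[j], z, p, p_adj))
    pairwise = pd.DataFrame(rows, columns=["group_a", "group_b", "z", "p_raw", "p_adj"])
    return {"H": float(h_stat), "p": float(p_omni), "pairwise": pairwise, "groups": names}


def adjust_confounders(
    labeled: pd.DataFrame,
    trait: str,
    sepsis_col: str = "composite",
    covariates: tuple[str, ...] = ("sex", "birthweight_z", "postnatal_day", "ga_weeks"),
    group_col: str = "baby_id",
    log2_transform: bool = True,
) -> dict:
    """Sepsis fixed effect from a linear mixed model (REML).

    Fits ``trait ~ sepsis + covariates`` with a random intercept per baby
    via :class:`statsmodels.regression.mixed_linear_model.MixedLM`, REML.
    Returns the sepsis-term estimate, standard error, p-value, and a
    convergence flag (non-convergence is reported, never silently dropped).
    Positive traits are log2-transformed by default so the sepsis effect is
    a log2 fold change.
    """
    import statsmodels.api as sm

    col = PARAM_PREFIX + trait if PARAM_PREFIX + trait in labeled.columns else trait
    df = labeled.copy()
    if sepsis_col == "composite":
        df = df.loc[df["composite"].isin(["Sepsis", "NoSepsis"])]
        df["is_sepsis"] = (df["composite"] == "Sepsis").astype(float)
    else:
        df["is_sepsis"] = df[sepsis_col].astype(float)
    if "sex" in covariates and df["sex"].dtype == object:
        df["sex"] = df["sex"].map({"F": 0.0, "M": 1.0})
    df = df.dropna(subset=[col, "is_sepsis", *covariates])
    if df[group_col].nunique() < 2:
        raise ValueError("random intercept unidentifiable: need at least two babies")

    y = df[col].astype(float)
    if log2_transform:
        if (y <= 0).any():
            raise ValueError("log2 transform requires strictly positive trait values")
        y = np.log2(y)
    exog = sm.add_constant(df[["is_sepsis", *covariates]].astype(float))
    model = sm.MixedLM(y, exog, groups=df[group_col])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(reml=True)
    return {
        "trait": trait,
        "estimate": float(res.params["is_sepsis"]),
        "se": float(res.bse["is_sepsis"]),
        "p": float(res.pvalues["is_sepsis"]),
        "converged": bool(res.converged),
        "n": int(len(df)),
        "n_babies": int(df[group_col].nunique()),
    }
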