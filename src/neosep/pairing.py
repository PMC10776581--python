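"""Temporal paired analysis of sepsis episodes.

For every (deduplicated) sepsis episode, the nearest sample drawn before and
after from the same baby — within a configurable window, about two weeks —
forms a (pre, sepsis, post) triplet. Paired Wilcoxon signed-rank tests then
ask whether each immune trait falls at sepsis and rebounds: a parameter is
called "sepsis-transient" when pre-vs-sepsis and sepsis-vs-post differ
significantly while pre-vs-post does not.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .screen import bh_adjust  # noqa: F401  (re-exported convenience)
from .simulate import PARAM_PREFIX

__all__ = ["EpisodeTriplet", "match_triplets", "paired_wilcoxon", "rebound_report"]


@dataclass
class EpisodeTriplet:
    episode_id: str
    baby_id: str
    sepsis_idx: int
    sepsis_day: int
    pre_idx: int | None = None
    pre_day: int | None = None
    post_idx: int | None = None
    post_day: int | None = None
    flags: tuple[str, ...] = ()

    @property
    def gap_pre_days(self) -> int | None:
        return None if self.pre_day is None else self.sepsis_day - self.pre_day

    @property
    def gap_post_days(self) -> int | None:
        return None if self.post_day is None else self.post_day - self.sepsis_day


def match_triplets(labeled: pd.DataFrame, max_gap_days: int = 14) -> list[EpisodeTriplet]:
    """Build pre/sepsis/post triplets by temporal proximity.

    The sepsis anchor of each triplet is the (first) sample of each MCS or
    ClinSep episode. Candidate neighbours are the same baby's other samples
    outside that episode; the nearest within ``max_gap_days`` wins, with
    same-day ties resolved to the first in input order (logged in flags).
    A sample serving more than one episode, or itself belonging to another
    sepsis episode, is flagged rather than forbidden. Matching depends only
    on days, never on row order.
    """
    if "category" not in labeled.columns:
        raise ValueError("samples must be classified first")
    sepsis = labeled.loc[
        labeled["category"].isin(["MCS", "ClinSep"])
        & (labeled["episode_id"].fillna("").astype(str) != "")
    ]
    triplets: list[EpisodeTriplet] = []
    used: dict[int, int] = {}
    for ep_id, grp in sepsis.groupby("episode_id", sort=True):
        anchor = grp.sort_values(["postnatal_day"], kind="stable").iloc[0]
        a_idx = int(grp.sort_values(["postnatal_day"], kind="stable").index[0])
        day = int(anchor["postnatal_day"])
        baby = anchor["baby_id"]
        cands = labeled.loc[
            (labeled["baby_id"] == baby)
            & (labeled.index != a_idx)
            & (labeled["episode_id"].fillna("").astype(str) != ep_id)
        ]
        flags: list[str] = []

        def pick(side: str):
            if side == "pre":
                pool = cands.loc[cands["postnatal_day"] < day]
            else:
                pool = cands.loc[cands["postnatal_day"] > day]
            if len(pool) == 0:
                return None, None
            gaps = (pool["postnatal_day"] - day).abs()
            pool = pool.assign(_gap=gaps).sort_values(["_gap", "postnatal_day"], kind="stable")
            best = pool.iloc[0]
            if best["_gap"] > max_gap_days:
                return None, None
            if len(pool) > 1 and pool.iloc[1]["_gap"] == best["_gap"]:
                flags.append(f"{side}: same-day tie, first in input order kept")
            if best["category"] in ("MCS", "ClinSep"):
                flags.append(f"{side}: neighbour is itself a sepsis sample")
            return int(pool.index[0]), int(best["postnatal_day"])

        pre_idx, pre_day = pick("pre")
        post_idx, post_day = pick("post")
        for idx in (pre_idx, post_idx):
            if idx is not None:
                used[idx] = used.get(idx, 0) + 1
        triplets.append(
            EpisodeTriplet(
                episode_id=ep_id,
                baby_id=baby,
                sepsis_idx=a_idx,
                sepsis_day=day,
                pre_idx=pre_idx,
                pre_day=pre_day,
                post_idx=post_idx,
                post_day=post_day,
                flags=tuple(flags),
            )
        )
    shared = {idx for idx, n in used.items() if n > 1}
    if shared:
        for t in triplets:
            extra = tuple(
                f"{side}: sample shared across episodes"
                for side, idx in (("pre", t.pre_idx), ("post", t.post_idx))
                if idx in shared
            )
            t.flags = t.flags + extra
    return triplets


def triplet_table(triplets: list[EpisodeTriplet]) -> pd.DataFrame:
    rows = [
        {
            "episode_id": t.episode_id,
            "baby_id": t.baby_id,
            "sepsis_day": t.sepsis_day,
            "pre_day": t.pre_day,
            "post_day": t.post_day,
            "gap_pre_days": t.gap_pre_days,
            "gap_post_days": t.gap_post_days,
            "flags": "; ".join(t.flags),
        }
        for t in triplets
    ]
    return pd.DataFrame(rows)


def _exact_signed_rank_p(ranks: np.ndarray, w_pos: float) -> float:
    """Exact two-sided p for the signed-rank statistic.

    ``ranks`` are the (possibly tied, average) ranks of the non-zero
    absolute differences. Works on doubled ranks so average ranks stay
    integral, and counts sign assignments by dynamic programming — exact
    even in the presence of ties.
    """
    r2 = np.rint(ranks * 2).astype(int)
    total = int(r2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    n_assign = 2.0 ** len(r2)
    w2 = int(round(w_pos * 2))
    p_low = counts[: w2 + 1].sum() / n_assign
    p_high = counts[w2:].sum() / n_assign
    return float(min(1.0, 2.0 * min(p_low, p_high)))


def paired_wilcoxon(x, y, exact_max_n: int = 25) -> float:
    """Two-sided Wilcoxon matched-pairs signed-rank p-value.

    Pairs with a missing member are dropped; zero differences are discarded
    (the classic Wilcoxon convention). The exact null distribution is used
    for up to ``exact_max_n`` non-zero differences; beyond that, a
    tie-corrected normal approximation. All differences zero gives p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must be paired (equal length)")
    ok = ~(np.isnan(x) | np.isnan(y))
    d = x[ok] - y[ok]
    if len(d) == 0:
        raise ValueError("no complete pairs")
    d = d[d != 0.0]
    n = len(d)
    if n == 0:
        warnings.warn("all paired differences are zero; p = 1", stacklevel=2)
        return 1.0
    ranks = stats.rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    if n <= exact_max_n:
        return _exact_signed_rank_p(ranks, w_pos)
    mean = n * (n + 1) / 4.0
    _, tie_counts = np.unique(np.abs(d), return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - float(np.sum(tie_counts**3 - tie_counts)) / 48.0
    if var <= 0:
        return 1.0
    z = (w_pos - mean) / math.sqrt(var)
    return float(min(1.0, 2.0 * stats.norm.sf(abs(z))))


def rebound_report(
    triplets: list[EpisodeTriplet],
    labeled: pd.DataFrame,
    parameters: list[str] | None = None,
    min_pairs: int = 5,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-parameter paired tests across the three timepoints.

    Runs pre-vs-sepsis, sepsis-vs-post and pre-vs-post Wilcoxon tests per
    parameter, each over the triplets providing that pair of samples (an
    incomplete triplet still contributes to whichever comparisons it
    supports). A parameter is called sepsis-transient when both acute
    comparisons are significant while pre-vs-post is not; comparisons with
    fewer than ``min_pairs`` complete pairs are not evaluable (NaN).
    """
    if parameters is None:
        parameters = [c[len(PARAM_PREFIX):] for c in labeled.columns if c.startswith(PARAM_PREFIX)]
    comparisons = (
        ("p_pre_vs_sepsis", "pre_idx", "sepsis_idx"),
        ("p_sepsis_vs_post", "sepsis_idx", "post_idx"),
        ("p_pre_vs_post", "pre_idx", "post_idx"),
    )
    rows = []
    for name in parameters:
        col = PARAM_PREFIX + name if PARAM_PREFIX + name in labeled.columns else name
        vals = labeled[col]
        row: dict = {"parameter": name}
        for label, left, right in comparisons:
            xs, ys = [], []
            for t in triplets:
                i, j = getattr(t, left), getattr(t, right)
                if i is None or j is None:
                    continue
                xi, yj = vals.get(i, np.nan), vals.get(j, np.nan)
                if np.isnan(xi) or np.isnan(yj):
                    continue
                xs.append(xi)
                ys.append(yj)
            row[label.replace("p_", "n_")] = len(xs)
            row[label] = paired_wilcoxon(xs, ys) if len(xs) >= min_pairs else np.nan
        evaluable = not (np.isnan(row["p_pre_vs_sepsis"]) or np.isnan(row["p_sepsis_vs_post"]))
        row["sepsis_transient"] = bool(
            evaluable
            and row["p_pre_vs_sepsis"] < alpha
            and row["p_sepsis_vs_post"] < alpha
            and (np.isnan(row["p_pre_vs_post"]) or row["p_pre_vs_post"] >= alpha)
        )
        rows.append(row)
    return pd.DataFrame(rows)
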