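"""Volcano screen primitives and supporting analyses: effect size, rank
tests, FDR control, age brackets/strata, CRP stratification, Kruskal-Wallis
with Dunn post hoc, and mixed-model confounder adjustment."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from neosep.screen import (
    adjust_confounders,
    age_bracket,
    age_bracket_analysis,
    bh_adjust,
    crp_stratify_episodes,
    log2fc_medians,
    mann_whitney_two_sided,
    multi_group_compare,
    stratified_screen,
    volcano_screen,
)

# ---------------------------------------------------------------- log2FC


def test_log2fc_examples():
    assert log2fc_medians([8, 8, 8], [2, 2, 2]) == pytest.approx(2.0)
    assert log2fc_medians([3, 1, 2], [1, 2, 3]) == pytest.approx(0.0)
    # zero median: pseudocount 0.5 on both sides
    assert log2fc_medians([0, 0, 0], [4, 4, 4], eps=0.5) == pytest.approx(np.log2(0.5 / 4.5))
    with pytest.warns(UserWarning, match="zero"):
        assert log2fc_medians([0.0, 0.0], [0.0, 0.0]) == 0.0
    with pytest.raises(ValueError):
        log2fc_medians([], [1.0])


# ---------------------------------------------------------------- Mann-Whitney


def _mw_enumeration_p(a, b):
    """Full enumeration over all labelings (distinct values only)."""
    pooled = list(a) + list(b)
    n_a, m = len(a), len(a) * len(b)

    def u(xs, ys):
        return sum(1 for x in xs for y in ys if x > y)

    u_obs = u(a, b)
    us = []
    idx = list(range(len(pooled)))
    for comb in itertools.combinations(idx, n_a):
        cs = set(comb)
        xs = [pooled[i] for i in comb]
        ys = [pooled[i] for i in idx if i not in cs]
        us.append(u(xs, ys))
    u_hi = max(u_obs, m - u_obs)
    return min(1.0, 2.0 * sum(1 for v in us if v >= u_hi) / len(us))


def test_mann_whitney_examples():
    assert mann_whitney_two_sided([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)
    assert mann_whitney_two_sided([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)
    a = np.array([1.3, 2.1, 5.0, 0.4])
    b = np.array([2.0, 3.3, 9.1])
    assert mann_whitney_two_sided(a, b) == pytest.approx(
        mann_whitney_two_sided(np.log(a), np.log(b))
    )  # rank invariance under monotone transforms


def test_mann_whitney_matches_enumeration_oracle():
    rng = np.random.default_rng(11)
    for n_a, n_b in [(3, 3), (4, 2), (5, 4), (6, 6), (2, 7)]:
        vals = rng.permutation(np.arange(1.0, n_a + n_b + 1.0))
        a, b = vals[:n_a], vals[n_a:]
        assert mann_whitney_two_sided(a, b) == pytest.approx(_mw_enumeration_p(a, b), abs=1e-12)


# ---------------------------------------------------------------- BH


def _bh_stepup_oracle(p):
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def test_bh_examples():
    assert bh_adjust([0.03]) == pytest.approx([0.03])
    assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04, 0.04, 0.04, 0.04])
    with pytest.raises(ValueError):
        bh_adjust([0.5, 1.2])


@given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=200))
def test_bh_matches_stepup_oracle(ps):
    ours = bh_adjust(ps)
    assert np.allclose(ours, _bh_stepup_oracle(ps))
    assert np.all(ours >= np.asarray(ps) - 1e-12)  # adjusted >= raw elementwise


def test_bh_passes_nan_through():
    out = bh_adjust([0.01, np.nan, 0.04])
    assert np.isnan(out[1])
    assert np.allclose(out[[0, 2]], _bh_stepup_oracle([0.01, 0.04]))


# ---------------------------------------------------------------- screens


def test_volcano_recovers_planted_signature(cohort, flow_set):
    _, truth = cohort
    res = volcano_screen(flow_set)
    assert set(res.loc[res["significant"], "parameter"]) == set(truth["true_effect_parameters"])
    # invariance to row order
    shuffled = flow_set.sample(frac=1.0, random_state=0)
    res2 = volcano_screen(shuffled)
    pd.testing.assert_frame_equal(
        res.sort_values("parameter").reset_index(drop=True),
        res2.sort_values("parameter").reset_index(drop=True),
    )


def test_volcano_identical_groups_not_significant():
    base = pd.DataFrame({"param.x": np.arange(1.0, 21.0), "postnatal_day": np.arange(1, 21)})
    df = pd.concat(
        [base.assign(composite="Sepsis"), base.assign(composite="NoSepsis")], ignore_index=True
    )
    res = volcano_screen(df)
    assert not res["significant"].any()
    assert res["p_raw"].iloc[0] == pytest.approx(1.0, abs=0.05)


def test_age_bracket_boundaries():
    assert age_bracket(15) == 1
    assert age_bracket(16) == 2
    assert age_bracket(1) == 1
    assert age_bracket(31) == 3


def test_age_brackets_detect_only_first_transition(cohort, flow_set):
    """Rising trend over the first weeks then plateau: only the bracket 1
    vs 2 comparison should reach significance for the trended traits."""
    _, truth = cohort
    res = age_bracket_analysis(flow_set, parameters=truth["true_effect_parameters"])
    sig = res.loc[res["significant"]]
    assert len(sig) > 0
    assert set(zip(sig["bracket_a"], sig["bracket_b"])) == {(1, 2)}


def test_age_brackets_flat_trend_null():
    rng = np.random.default_rng(0)
    df = pd.DataFrame(
        {
            "postnatal_day": rng.integers(1, 90, 200),
            "param.flat": rng.lognormal(3.0, 0.3, 200),
            "composite": "NoSepsis",
        }
    )
    res = age_bracket_analysis(df)
    assert not res["significant"].any()


def test_stratified_screen_effect_only_early():
    rng = np.random.default_rng(1)
    rows = []
    for day in rng.integers(1, 31, 60):
        rows.append({"postnatal_day": int(day), "composite": "NoSepsis", "param.x": rng.lognormal(3, 0.2)})
    for day in rng.integers(1, 31, 25):
        rows.append({"postnatal_day": int(day), "composite": "Sepsis", "param.x": rng.lognormal(2, 0.2)})
    for day in rng.integers(31, 80, 60):
        rows.append({"postnatal_day": int(day), "composite": "NoSepsis", "param.x": rng.lognormal(3, 0.2)})
    for day in rng.integers(31, 80, 25):
        rows.append({"postnatal_day": int(day), "composite": "Sepsis", "param.x": rng.lognormal(3, 0.2)})
    df = pd.DataFrame(rows)
    res = stratified_screen(df, boundary_day=30)
    assert res["1-30d"]["significant"].iloc[0]
    assert not res[">30d"]["significant"].iloc[0]
    empty = stratified_screen(df.loc[df["postnatal_day"] <= 30], boundary_day=30)
    assert len(empty[">30d"]) == 0


def test_crp_stratification_boundary():
    df = pd.DataFrame(
        {
            "category": ["MCS", "MCS", "ClinSep", "ClinSep", "Stable"],
            "episode_id": ["E1", "E1", "E2", "E3", ""],
            "crp_mg_per_L": [4.0, 10.0, 10.1, np.nan, 50.0],
        }
    )
    out = crp_stratify_episodes(df, cutoff=10.0)
    assert out["no_rise"] == ["E1"]  # peak exactly 10.0 is not a rise
    assert out["rise"] == ["E2"]
    assert out["unclassifiable"] == ["E3"]


# ---------------------------------------------------------------- multi-group


def test_kruskal_dunn_identical_groups():
    g = list(np.arange(10.0))
    res = multi_group_compare(g * 3, ["a"] * 10 + ["b"] * 10 + ["c"] * 10)
    assert res["p"] == pytest.approx(1.0, abs=0.01)
    assert (res["pairwise"]["p_adj"] > 0.9).all()


def test_kruskal_dunn_shifted_group():
    rng = np.random.default_rng(2)
    vals = np.concatenate([rng.normal(0, 1, 30), rng.normal(0, 1, 30), rng.normal(4, 1, 30)])
    labels = ["a"] * 30 + ["b"] * 30 + ["c"] * 30
    res = multi_group_compare(vals, labels)
    assert res["p"] < 1e-6
    pw = res["pairwise"].set_index(["group_a", "group_b"])["p_adj"]
    assert pw.loc[("a", "c")] < 0.001 and pw.loc[("b", "c")] < 0.001
    assert pw.loc[("a", "b")] > 0.05


def test_two_groups_redirects():
    with pytest.raises(ValueError, match="two-group"):
        multi_group_compare([1, 2, 3, 4], ["a", "a", "b", "b"])


# ---------------------------------------------------------------- mixed model


def _mixed_cohort(beta, seed, n_babies=20, n_per=8):
    rng = np.random.default_rng(seed)
    rows = []
    for b in range(n_babies):
        u = rng.normal(0, 0.4)
        for _ in range(n_per):
            sep = rng.random() < 0.25
            y = 5.0 + u + beta * sep + rng.normal(0, 0.3)
            rows.append(
                {
                    "baby_id": f"B{b}",
                    "composite": "Sepsis" if sep else "NoSepsis",
                    "trait": 2.0**y,
                    "sex": "F" if rng.random() < 0.5 else "M",
                    "birthweight_z": rng.normal(),
                    "postnatal_day": int(rng.integers(1, 60)),
                    "ga_weeks": int(rng.integers(23, 30)),
                }
            )
    return pd.DataFrame(rows)


def test_mixed_model_recovers_effect():
    df = _mixed_cohort(beta=-0.8, seed=3)
    res = adjust_confounders(df, "trait")
    assert res["converged"]
    assert res["estimate"] == pytest.approx(-0.8, abs=3 * res["se"])
    assert res["p"] < 1e-6


def test_mixed_model_single_baby_errors():
    df = _mixed_cohort(beta=0.0, seed=4, n_babies=1)
    with pytest.raises(ValueError, match="two babies"):
        adjust_confounders(df, "trait")
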