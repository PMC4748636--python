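"""Rank tests against enumeration oracles and scipy cross-checks."""

import itertools

import numpy as np
import pytest
from scipy import stats as sps

from placmorph.errors import ConfigError, DegenerateDataError
from placmorph.stats import (
    compare_all_conditions,
    kruskal_dunn,
    mann_whitney,
    stars,
    wilcoxon_matched_pairs,
    wilcoxon_signed_rank_vs_ref,
)
from placmorph.synthetic.cohort import (
    CONTROL_MEDIANS,
    CohortConfig,
    condition_spec,
    simulate_cohort,
)


# --------------------------------------------------------------------------
# independent brute-force oracles (deliberately naive)


def brute_force_signed_rank_p(diffs: np.ndarray) -> float:
    d = diffs[diffs != 0]
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = [
        np.asarray(signs) @ ranks
        for signs in itertools.product([0, 1], repeat=len(d))
    ]
    ws = np.asarray(ws)
    m = len(ws)
    lower = (ws <= w_obs + 1e-9).sum() / m
    upper = (ws >= w_obs - 1e-9).sum() / m
    return min(1.0, 2 * min(lower, upper))


def brute_force_mann_whitney_p(a: np.ndarray, b: np.ndarray) -> float:
    na = len(a)
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    ua_obs = ranks[:na].sum() - na * (na + 1) / 2
    uas = []
    for subset in itertools.combinations(range(len(pooled)), na):
        uas.append(ranks[list(subset)].sum() - na * (na + 1) / 2)
    uas = np.asarray(uas)
    m = len(uas)
    lower = (uas <= ua_obs + 1e-9).sum() / m
    upper = (uas >= ua_obs - 1e-9).sum() / m
    return min(1.0, 2 * min(lower, upper))


# --------------------------------------------------------------------------
# worked micro-examples


def test_signed_rank_micro_example():
    res = wilcoxon_signed_rank_vs_ref([1, 2, 3], 0)
    assert res.statistic == 6.0
    assert res.p_value == pytest.approx(0.25)
    assert res.mode == "exact"


def test_signed_rank_symmetric_values_give_p_one():
    res = wilcoxon_signed_rank_vs_ref([7, 13, 8, 12, 9, 11], 10)
    assert res.p_value == 1.0


def test_mann_whitney_micro_example():
    res = mann_whitney([1, 2, 3], [4, 5, 6])
    assert res.statistic == 0.0
    assert res.p_value == pytest.approx(0.1)
    assert res.mode == "exact"


def test_mann_whitney_identical_groups_p_one():
    res = mann_whitney([1, 2, 3], [1, 2, 3])
    assert res.p_value == 1.0


def test_mann_whitney_symmetric_in_group_order(rng):
    a, b = rng.normal(size=6), rng.normal(size=8)
    r1, r2 = mann_whitney(a, b), mann_whitney(b, a)
    assert r1.p_value == pytest.approx(r2.p_value)
    assert r1.statistic == pytest.approx(r2.statistic)


def test_kruskal_micro_example():
    res, pairwise = kruskal_dunn([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
    assert res.statistic == pytest.approx(7.2)
    assert len(pairwise) == 3


def test_kruskal_identical_groups_not_significant():
    res, pairwise = kruskal_dunn([[1, 5, 9], [2, 6, 8], [3, 4, 7]])
    assert res.p_value > 0.5
    assert not pairwise["significant"].any()


def test_kruskal_invariant_under_monotone_transform(rng):
    groups = [rng.normal(size=5) + i for i in range(3)]
    h1, _ = kruskal_dunn(groups)
    h2, _ = kruskal_dunn([np.exp(g) for g in groups])
    assert h1.statistic == pytest.approx(h2.statistic)


def test_matched_pairs_micro_example():
    res = wilcoxon_matched_pairs([1, 2, 3, 4, 5, 6], [2, 3, 4, 5, 6, 7])
    # all six differences positive: extreme sign pattern of 2^6
    assert res.p_value == pytest.approx(2 / 64)
    assert res.mode == "exact"


def test_matched_pairs_antisymmetric(rng):
    pre, post = rng.normal(size=8), rng.normal(size=8)
    r1 = wilcoxon_matched_pairs(pre, post)
    r2 = wilcoxon_matched_pairs(post, pre)
    assert r1.statistic == pytest.approx(-r2.statistic)
    assert r1.p_value == pytest.approx(r2.p_value)


# --------------------------------------------------------------------------
# oracle equivalence and properties


def test_signed_rank_matches_enumeration_on_random_instances(rng):
    for _ in range(60):
        n = int(rng.integers(4, 11))
        x = rng.normal(size=n)
        ref = rng.normal()
        p = wilcoxon_signed_rank_vs_ref(x, ref).p_value
        assert p == pytest.approx(brute_force_signed_rank_p(x - ref), abs=1e-12)


def test_signed_rank_with_tied_magnitudes_matches_enumeration(rng):
    for _ in range(20):
        n = int(rng.integers(4, 10))
        x = rng.integers(-4, 5, size=n).astype(float)
        x = x[x != 0]
        if len(x) < 3:
            continue
        p = wilcoxon_signed_rank_vs_ref(x, 0).p_value
        assert p == pytest.approx(brute_force_signed_rank_p(x), abs=1e-12)


def test_mann_whitney_matches_enumeration_on_random_instances(rng):
    for _ in range(40):
        na, nb = int(rng.integers(3, 8)), int(rng.integers(3, 8))
        a, b = rng.normal(size=na), rng.normal(size=nb)
        p = mann_whitney(a, b).p_value
        assert p == pytest.approx(brute_force_mann_whitney_p(a, b), abs=1e-12)


def test_p_values_in_unit_interval_and_exact_mode_small_n(rng):
    for _ in range(30):
        x = rng.normal(size=int(rng.integers(4, 13)))
        res = wilcoxon_signed_rank_vs_ref(x, 0.0)
        assert 0.0 <= res.p_value <= 1.0
        assert res.mode == "exact"
    res = wilcoxon_signed_rank_vs_ref(rng.normal(size=40), 0.0)
    assert res.mode == "normal"
    assert 0.0 <= res.p_value <= 1.0


def test_normal_approximation_close_to_exact_at_boundary(rng):
    # n=12 runs exact; the approximation should agree to a few percent
    for _ in range(10):
        x = rng.normal(loc=0.5, size=12)
        exact = wilcoxon_signed_rank_vs_ref(x, 0.0).p_value
        approx = sps.wilcoxon(x, method="approx", correction=True).pvalue
        assert approx == pytest.approx(exact, abs=0.03)


# --------------------------------------------------------------------------
# degenerate inputs and contracts


def test_all_zero_differences_is_degenerate():
    with pytest.raises(DegenerateDataError):
        wilcoxon_signed_rank_vs_ref([5.0, 5.0, 5.0, 5.0], 5.0)


def test_matched_pairs_equal_arms_degenerate():
    with pytest.raises(DegenerateDataError):
        wilcoxon_matched_pairs([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])


def test_matched_pairs_length_mismatch_rejected():
    with pytest.raises(ConfigError):
        wilcoxon_matched_pairs([1, 2, 3], [1, 2])


def test_empty_group_rejected():
    with pytest.raises(ConfigError):
        mann_whitney([], [1, 2, 3])


def test_two_groups_directed_to_mann_whitney():
    with pytest.raises(ConfigError, match="mann_whitney"):
        kruskal_dunn([[1, 2], [3, 4]])


def test_stars_thresholds():
    assert stars(0.2) == ""
    assert stars(0.04) == "*"
    assert stars(0.005) == "**"
    assert stars(0.0005) == "***"


# --------------------------------------------------------------------------
# cohort battery


def _two_arm_cohort(seed, effects=None):
    cfg = CohortConfig(
        (
            condition_spec("control", 10),
            condition_spec("fgr", 10, effects or {}),
        )
    )
    return simulate_cohort(cfg, seed=seed)


def test_battery_shape_and_columns():
    df = _two_arm_cohort(0)
    res = compare_all_conditions(df)
    assert len(res) == 6  # one non-control condition x six indices
    assert set(res.columns) >= {
        "condition", "index", "test", "statistic", "p_value", "mode", "stars",
    }


def test_condition_equal_to_control_values_gets_no_stars():
    df = _two_arm_cohort(1)
    controls = df[df.condition == "control"].copy()
    clone = controls.copy()
    clone["condition"] = "clone"
    clone["sample_id"] = clone["sample_id"] + "_c"
    res = compare_all_conditions(
        __import__("pandas").concat([controls, clone], ignore_index=True)
    )
    # each index: clone differs from the control median only via the median
    # sample itself; nothing can be significant
    assert (res["stars"] == "").all()


def test_missing_index_columns_named_in_error():
    df = _two_arm_cohort(2).drop(columns=["cd45_per_1000"])
    with pytest.raises(ConfigError, match="cd45_per_1000"):
        compare_all_conditions(df)


def test_fgr_effects_detected_with_high_power():
    """SNA and avascular shifts at default FGR effects, n=10/arm."""
    hits = {"sna_per_mm2": 0, "avascular_pct": 0}
    n_rep = 100
    from placmorph.synthetic.cohort import CONDITION_EFFECTS

    for rep in range(n_rep):
        df = _two_arm_cohort(1000 + rep, CONDITION_EFFECTS["fgr"])
        res = compare_all_conditions(df)
        for idx in hits:
            p = res.loc[res["index"] == idx, "p_value"].iloc[0]
            hits[idx] += p < 0.05
    assert hits["sna_per_mm2"] / n_rep >= 0.8
    assert hits["avascular_pct"] / n_rep >= 0.8


def test_holm_adjustment_is_monotone_and_conservative():
    df = _two_arm_cohort(3)
    res = compare_all_conditions(df, holm=True)
    assert (res["p_holm"] >= res["p_value"] - 1e-12).all()
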