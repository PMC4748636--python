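"""Nonparametric comparison battery with exact small-sample p-values.

The cohort analyses use four rank tests: a one-sample Wilcoxon signed-rank
test of each condition against the healthy-control median, Mann-Whitney U
for two independent groups, Wilcoxon matched-pairs for paired designs
(pre/post perfusion), and Kruskal-Wallis with Dunn's post-hoc z tests for
multi-group comparisons.  Group sizes in this setting are 5-13, where
normal approximations are unreliable, so exact null distributions are used:
sign enumeration (2^n patterns) for the signed-rank tests at n <= 12, and
the rank-sum counting recursion for Mann-Whitney when the product of group
sizes is <= 400 and the data are tie-free.  Mid-ranks handle ties; zero
differences are dropped (classic Wilcoxon, not Pratt).  Two-sided p-values
double the smaller tail, capped at 1.  The mode actually used (exact vs
normal approximation) is recorded in every result.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ConfigError, DegenerateDataError

ALPHA_DEFAULT = 0.05
SIGNED_RANK_EXACT_N_MAX = 12
MANN_WHITNEY_EXACT_NM_MAX = 400
_EPS = 1e-9


@dataclass(frozen=True)
class TestResult:
    """Outcome of one hypothesis test."""

    test: str
    statistic: float
    p_value: float
    n: tuple[int, ...]
    mode: str                     # "exact" | "normal" | "chi2"
    alpha: float = ALPHA_DEFAULT
    detail: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0) and not np.isnan(self.p_value):
            raise ValueError(f"p-value out of range: {self.p_value}")

    @property
    def significant(self) -> bool:
        return bool(self.p_value < self.alpha)


def stars(p: float) -> str:
    """Figure-style significance stars: * <0.05, ** <0.01, *** <0.001."""
    if np.isnan(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


# --------------------------------------------------------------------------
# signed-rank machinery


@lru_cache(maxsize=512)
def _signed_rank_null(ranks_key: tuple[int, ...]) -> tuple[np.ndarray, np.ndarray]:
    """Null distribution of W+ over all sign patterns of the given ranks.

    ``ranks_key`` carries ranks doubled to integers (mid-ranks are .5
    multiples).  Returns (sorted unique W+ values, probabilities).
    """
    ranks = np.asarray(ranks_key, dtype=float) / 2.0
    n = len(ranks)
    patterns = (np.arange(2**n)[:, None] >> np.arange(n)) & 1
    w = patterns @ ranks
    values, counts = np.unique(w, return_counts=True)
    return values, counts / 2.0**n


def _two_sided_from_null(values: np.ndarray, probs: np.ndarray, observed: float) -> float:
    lower = probs[values <= observed + _EPS].sum()
    upper = probs[values >= observed - _EPS].sum()
    return float(min(1.0, 2.0 * min(lower, upper)))


def _signed_rank_core(diffs: np.ndarray, test_name: str, alpha: float) -> TestResult:
    d = np.asarray(diffs, dtype=float)
    if not np.all(np.isfinite(d)):
        raise ConfigError("differences must be finite")
    n_input = len(d)
    d = d[d != 0]  # zeros dropped (classic Wilcoxon)
    n = len(d)
    if n == 0:
        raise DegenerateDataError("all differences are zero")
    if n < 3:
        raise DegenerateDataError(
            f"need >= 3 non-zero differences, got {n}"
        )
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    if n <= SIGNED_RANK_EXACT_N_MAX:
        key = tuple(np.round(ranks * 2).astype(int))
        values, probs = _signed_rank_null(key)
        p = _two_sided_from_null(values, probs, w_plus)
        mode = "exact"
    else:
        mu = ranks.sum() / 2.0
        sigma = np.sqrt((ranks**2).sum() / 4.0)  # tie-aware: Var(W+) = sum r^2 / 4
        cc = 0.5 if w_plus != mu else 0.0
        z = (w_plus - mu - np.sign(w_plus - mu) * cc) / sigma
        p = float(min(1.0, 2.0 * sps.norm.sf(abs(z))))
        mode = "normal"
    return TestResult(
        test=test_name,
        statistic=w_plus,
        p_value=p,
        n=(n_input,),
        mode=mode,
        alpha=alpha,
        detail={
            "w_plus": w_plus,
            "w_minus": w_minus,
            "n_nonzero": n,
            "zero_handling": "drop",
            "signed_statistic": w_plus - w_minus,
        },
    )


def wilcoxon_signed_rank_vs_ref(
    values, ref_median: float, alpha: float = ALPHA_DEFAULT
) -> TestResult:
    """One-sample signed-rank test of ``values`` against a reference median.

    W+ (sum of positive signed ranks of ``values - ref_median``) with
    mid-ranks for ties; exact two-sided p by full sign enumeration for
    n <= 12 non-zero differences, tie-aware normal approximation with
    continuity correction above.
    """
    values = np.asarray(values, dtype=float)
    if not np.isfinite(ref_median):
        raise ConfigError("ref_median must be finite")
    return _signed_rank_core(values - ref_median, "wilcoxon_signed_rank", alpha)


def wilcoxon_matched_pairs(pre_values, post_values, alpha: float = ALPHA_DEFAULT) -> TestResult:
    """Paired signed-rank test on ``post - pre`` differences.

    The reported statistic is the signed rank sum W+ - W- (antisymmetric:
    swapping the arms flips its sign and leaves p unchanged); W+ itself is
    in ``detail``.
    """
    pre = np.asarray(pre_values, dtype=float)
    post = np.asarray(post_values, dtype=float)
    if pre.shape != post.shape:
        raise ConfigError(
            f"paired arms must have equal length, got {len(pre)} and {len(post)}"
        )
    result = _signed_rank_core(post - pre, "wilcoxon_matched_pairs", alpha)
    return TestResult(
        test=result.test,
        statistic=result.detail["signed_statistic"],
        p_value=result.p_value,
        n=(len(pre),),
        mode=result.mode,
        alpha=alpha,
        detail=result.detail,
    )


# --------------------------------------------------------------------------
# Mann-Whitney


@lru_cache(maxsize=256)
def _rank_sum_counts(n: int, total: int) -> np.ndarray:
    """counts[s] = number of size-``n`` subsets of ranks 1..total with sum s.

    Classic dynamic programme; identical to enumerating all C(total, n)
    assignments, but polynomial time.
    """
    max_sum = n * total
    dp = np.zeros((n + 1, max_sum + 1), dtype=float)
    dp[0, 0] = 1.0
    for item in range(1, total + 1):
        for k in range(min(n, item), 0, -1):
            dp[k, item:] += dp[k - 1, :-item]
    return dp[n]


def mann_whitney(group_a, group_b, alpha: float = ALPHA_DEFAULT) -> TestResult:
    """Mann-Whitney U test for two independent groups.

    Exact two-sided p from the rank-sum distribution when the data are
    tie-free and ``n*m <= 400``; tie-corrected normal approximation with
    continuity correction otherwise.  The reported statistic is
    ``min(U_a, U_b)``, symmetric in group order.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ConfigError("both groups must be non-empty")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ConfigError("group values must be finite")
    na, nb = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    ra = float(ranks[:na].sum())
    ua = ra - na * (na + 1) / 2.0
    ub = na * nb - ua
    u_min = min(ua, ub)
    has_ties = len(np.unique(pooled)) < len(pooled)

    if not has_ties and na * nb <= MANN_WHITNEY_EXACT_NM_MAX:
        counts = _rank_sum_counts(na, na + nb)
        total = counts.sum()
        sums = np.arange(len(counts), dtype=float)
        u_values = sums - na * (na + 1) / 2.0
        probs = counts / total
        p = _two_sided_from_null(u_values, probs, ua)
        mode = "exact"
    else:
        n_total = na + nb
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = float(((tie_counts**3 - tie_counts)).sum())
        mu = na * nb / 2.0
        var = (
            na * nb / 12.0 * ((n_total + 1) - tie_term / (n_total * (n_total - 1)))
        )
        if var <= 0:
            raise DegenerateDataError("all pooled values identical")
        cc = 0.5 if ua != mu else 0.0
        z = (ua - mu - np.sign(ua - mu) * cc) / np.sqrt(var)
        p = float(min(1.0, 2.0 * sps.norm.sf(abs(z))))
        mode = "normal"
    return TestResult(
        test="mann_whitney_u",
        statistic=float(u_min),
        p_value=p,
        n=(na, nb),
        mode=mode,
        alpha=alpha,
        detail={"u_a": float(ua), "u_b": float(ub), "ties": has_ties},
    )


# --------------------------------------------------------------------------
# Kruskal-Wallis + Dunn


def _holm(p_values: np.ndarray) -> np.ndarray:
    """Holm step-down adjustment."""
    m = len(p_values)
    order = np.argsort(p_values)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p_values[idx])
        adj[idx] = min(1.0, running)
    return adj


def kruskal_dunn(
    groups: list,
    p_adjust: str | None = None,
    alpha: float = ALPHA_DEFAULT,
) -> tuple[TestResult, pd.DataFrame]:
    """Kruskal-Wallis H test with Dunn's pairwise post-hoc z tests.

    Tie-corrected H with a chi-square p-value, then Dunn z statistics for
    every pair of groups; ``p_adjust`` is None (default), "holm" or
    "bonferroni" and is recorded in the pairwise table.
    """
    if len(groups) < 3:
        raise ConfigError(
            "kruskal_dunn needs >= 3 groups; use mann_whitney for two groups"
        )
    arrays = [np.asarray(g, dtype=float) for g in groups]
    for i, g in enumerate(arrays):
        if len(g) < 2:
            raise ConfigError(f"group {i} has fewer than 2 values")
    pooled = np.concatenate(arrays)
    n_total = len(pooled)
    ranks = sps.rankdata(pooled)
    rank_groups = np.split(ranks, np.cumsum([len(g) for g in arrays])[:-1])
    mean_ranks = np.array([rg.mean() for rg in rank_groups])
    sizes = np.array([len(g) for g in arrays])

    h = (
        12.0 / (n_total * (n_total + 1)) * float((sizes * mean_ranks**2).sum())
        - 3.0 * (n_total + 1)
    )
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float((tie_counts**3 - tie_counts).sum())
    correction = 1.0 - tie_term / (n_total**3 - n_total)
    if correction <= 0:
        raise DegenerateDataError("all pooled values identical")
    h /= correction
    df = len(groups) - 1
    p = float(sps.chi2.sf(h, df))
    omnibus = TestResult(
        test="kruskal_wallis",
        statistic=float(h),
        p_value=p,
        n=tuple(int(s) for s in sizes),
        mode="chi2",
        alpha=alpha,
        detail={"df": df, "tie_correction": correction},
    )

    var_factor = n_total * (n_total + 1) / 12.0 - tie_term / (12.0 * (n_total - 1))
    rows = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            se = np.sqrt(var_factor * (1.0 / sizes[i] + 1.0 / sizes[j]))
            z = (mean_ranks[i] - mean_ranks[j]) / se
            rows.append(
                {"group_i": i, "group_j": j, "z": float(z),
                 "p_value": float(min(1.0, 2.0 * sps.norm.sf(abs(z))))}
            )
    pairwise = pd.DataFrame(rows)
    raw = pairwise["p_value"].to_numpy()
    if p_adjust is None:
        pairwise["p_adjusted"] = raw
    elif p_adjust == "bonferroni":
        pairwise["p_adjusted"] = np.minimum(1.0, raw * len(raw))
    elif p_adjust == "holm":
        pairwise["p_adjusted"] = _holm(raw)
    else:
        raise ConfigError(f"unknown p_adjust {p_adjust!r}")
    pairwise["adjustment"] = p_adjust or "none"
    pairwise["significant"] = pairwise["p_adjusted"] < alpha
    return omnibus, pairwise


# --------------------------------------------------------------------------
# cohort battery


def compare_all_conditions(
    cohort: pd.DataFrame,
    control: str = "control",
    indices: tuple[str, ...] | None = None,
    alpha: float = ALPHA_DEFAULT,
    ref_medians: dict[str, float] | None = None,
    holm: bool = False,
) -> pd.DataFrame:
    """Signed-rank tests of every condition x index against the control median.

    For each non-control condition and each index, runs
    :func:`wilcoxon_signed_rank_vs_ref` against the control median (or the
    supplied ``ref_medians``, e.g. known population medians in calibration
    studies).  Returns a long-format table with figure-style significance
    stars.  ``holm=True`` adds Holm-adjusted p-values across the whole grid;
    no adjustment is applied by default, mirroring per-comparison reporting.
    """
    from .synthetic.cohort import INDEX_COLUMNS

    if indices is None:
        indices = INDEX_COLUMNS
    missing = [c for c in ("condition", *indices) if c not in cohort.columns]
    if missing:
        raise ConfigError(f"cohort table missing columns: {missing}")
    controls = cohort[cohort["condition"] == control]
    if len(controls) < 3:
        raise ConfigError(
            f"control group {control!r} needs >= 3 samples, found {len(controls)}"
        )
    rows = []
    for condition, sub in cohort.groupby("condition", sort=True):
        if condition == control:
            continue
        for index in indices:
            ref = (
                ref_medians[index]
                if ref_medians is not None
                else float(controls[index].median())
            )
            try:
                res = wilcoxon_signed_rank_vs_ref(
                    sub[index].to_numpy(), ref, alpha=alpha
                )
                stat, p, mode = res.statistic, res.p_value, res.mode
            except DegenerateDataError:
                stat, p, mode = np.nan, np.nan, "degenerate"
            rows.append(
                {
                    "condition": condition,
                    "index": index,
                    "test": "wilcoxon_signed_rank",
                    "statistic": stat,
                    "p_value": p,
                    "mode": mode,
                    "stars": stars(p),
                }
            )
    out = pd.DataFrame(rows)
    if holm and len(out):
        valid = out["p_value"].notna()
        adj = np.full(len(out), np.nan)
        adj[valid.to_numpy()] = _holm(out.loc[valid, "p_value"].to_numpy())
        out["p_holm"] = adj
    return out
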