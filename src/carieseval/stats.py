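"""Inferential layer of the reader study.

Pre/post improvements per annotator are tested with a paired sign-flip
permutation test (no distributional assumptions); differences in improvement
between groups use the Kruskal-Wallis H-test with Dunn's Bonferroni-adjusted
post hoc pairs; the Shapiro-Wilk test screens normality beforehand.

The permutation test enumerates all 2^n sign patterns exactly when feasible
(2^n <= 2^20) and otherwise falls back to seeded Monte Carlo with the
add-one convention, so p is always > 0 and identical seeds give identical
p-values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

EXHAUSTIVE_LIMIT = 2**20
_REL_TOL = 1e-12  # guards >= comparisons of permuted statistics against float noise


@dataclass(frozen=True)
class PermutationTestResult:
    metric_name: str
    observed_mean_delta: float
    p_value: float
    n_permutations: int
    mode: str  # "exhaustive" | "monte_carlo"
    seed: int | None


@dataclass(frozen=True)
class GroupComparisonResult:
    metric_name: str
    H_statistic: float
    kw_p_value: float
    pairwise: tuple[tuple[str, str, float], ...]


def shapiro_wilk_screen(values) -> tuple[float, float]:
    """Shapiro-Wilk W and p for 3 <= n <= 5000 (scipy-backed contract)."""
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 3:
        raise ValueError(f"Shapiro-Wilk requires a 1-d sample with n >= 3 (got n={x.size})")
    if x.size > 5000:
        raise ValueError(f"Shapiro-Wilk p-values are unreliable above n=5000 (got n={x.size})")
    if np.ptp(x) == 0:
        raise ValueError("Shapiro-Wilk is undefined for a constant sample")
    w, p = sps.shapiro(x)
    return float(w), float(p)


def _subset_sums(d: np.ndarray) -> np.ndarray:
    """All 2^n subset sums of d, by iterative doubling."""
    sums = np.zeros(1)
    for v in d:
        sums = np.concatenate([sums, sums + v])
    return sums


def paired_permutation_test(
    pre,
    post,
    n_perm: int = 10_000,
    seed: int | None = None,
    alternative: str = "two_sided",
) -> PermutationTestResult:
    """Two-sided paired sign-flip permutation test of mean(post − pre) = 0.

    The null distribution negates each annotator's delta independently; the
    statistic is the mean delta.  All 2^n sign patterns are enumerated when
    2^n <= 2^20; otherwise ``n_perm`` Monte Carlo sign vectors are drawn with
    the given seed and p uses the add-one convention (the observed pattern
    counts in numerator and denominator), so p > 0 always.
    """
    if alternative != "two_sided":
        raise ValueError("only the two-sided alternative is supported")
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape or pre.ndim != 1:
        raise ValueError(f"pre and post must be equal-length 1-d vectors (got {pre.shape} vs {post.shape})")
    n = pre.size
    if n < 2:
        raise ValueError(f"paired test requires n >= 2 pairs (got {n})")
    d = post - pre
    t_obs = float(d.mean())
    threshold = abs(t_obs) * (1 - _REL_TOL)

    if 2**n <= EXHAUSTIVE_LIMIT:
        # mean under sign pattern s: (sum(d) - 2 * sum of flipped subset) / n
        stats = (d.sum() - 2.0 * _subset_sums(d)) / n
        count = int(np.count_nonzero(np.abs(stats) >= threshold))
        return PermutationTestResult(
            metric_name="",
            observed_mean_delta=t_obs,
            p_value=count / 2**n,
            n_permutations=2**n,
            mode="exhaustive",
            seed=None,
        )

    rng = np.random.default_rng(seed)
    signs = rng.integers(0, 2, size=(n_perm, n)) * 2 - 1
    stats = signs @ d / n
    count = int(np.count_nonzero(np.abs(stats) >= threshold))
    return PermutationTestResult(
        metric_name="",
        observed_mean_delta=t_obs,
        p_value=(1 + count) / (n_perm + 1),
        n_permutations=n_perm,
        mode="monte_carlo",
        seed=seed,
    )


def _check_groups(groups) -> list[np.ndarray]:
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups")
    for i, g in enumerate(arrays):
        if g.size == 0:
            raise ValueError(f"group {i} is empty")
    if sum(g.size for g in arrays) < 3:
        raise ValueError("need at least 3 observations in total")
    return arrays


def kruskal_wallis(groups) -> tuple[float, float]:
    """Rank-based H statistic with tie correction and its chi-squared p-value
    (k−1 degrees of freedom); scipy-backed.  An all-constant pooled sample
    degenerates to H = 0, p = 1."""
    arrays = _check_groups(groups)
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        return 0.0, 1.0
    h, p = sps.kruskal(*arrays)
    return float(h), float(p)


def dunn_bonferroni(groups, labels: list[str] | None = None) -> list[tuple[str, str, float]]:
    """Dunn's post hoc pairwise z-tests on pooled ranks with tie correction;
    two-sided p-values multiplied by k(k−1)/2 and capped at 1.

    For each pair (i, j):

        z = (R̄_i − R̄_j) / sqrt((N(N+1)/12 − T)·(1/n_i + 1/n_j)),
        T = Σ(t³ − t) / (12(N − 1))  over tie groups of size t.
    """
    arrays = _check_groups(groups)
    k = len(arrays)
    if labels is None:
        labels = [f"group{i}" for i in range(k)]
    if len(labels) != k:
        raise ValueError("labels must match the number of groups")

    pooled = np.concatenate(arrays)
    n_total = pooled.size
    ranks = sps.rankdata(pooled)
    rank_means = []
    start = 0
    for g in arrays:
        rank_means.append(ranks[start : start + g.size].mean())
        start += g.size

    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (12.0 * (n_total - 1)))
    variance_scale = n_total * (n_total + 1) / 12.0 - tie_term

    n_comparisons = k * (k - 1) // 2
    out: list[tuple[str, str, float]] = []
    for i in range(k):
        for j in range(i + 1, k):
            se2 = variance_scale * (1.0 / arrays[i].size + 1.0 / arrays[j].size)
            if se2 <= 0:  # all pooled values tied
                p_adj = 1.0
            else:
                z = (rank_means[i] - rank_means[j]) / np.sqrt(se2)
                p = 2.0 * sps.norm.sf(abs(z))
                p_adj = min(1.0, p * n_comparisons)
            out.append((labels[i], labels[j], float(p_adj)))
    return out


def compare_groups(groups, labels: list[str] | None = None, metric_name: str = "") -> GroupComparisonResult:
    """Kruskal-Wallis plus Dunn-Bonferroni pairs in one result object."""
    h, p = kruskal_wallis(groups)
    pairs = dunn_bonferroni(groups, labels)
    return GroupComparisonResult(
        metric_name=metric_name,
        H_statistic=h,
        kw_p_value=p,
        pairwise=tuple(pairs),
    )
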