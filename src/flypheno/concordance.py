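"""Partition concordance: Jaccard similarity and a permutation null.

Agreement between a behavior-defined genotype group and the groups defined by
genetic-interaction profiles is scored as intersection-over-union.  Its
significance is a one-sided permutation p-value: random disjoint groups with
the same size distribution as the real interaction groups are drawn from the
gene universe (default 10,000 iterations) and p is the fraction of draws in
which the best random-group similarity strictly exceeds the best real-group
similarity.  No multiple-comparison correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: stability category edges: [0, 0.35) low, [0.35, 0.7) mid, [0.7, 1] high
STABILITY_EDGES = (0.35, 0.70)
STABILITY_LABELS = ("0-0.34", "0.35-0.69", "0.7-1")


def jaccard_sets(a, b) -> float:
    """Intersection over union of two sets."""
    a, b = set(a), set(b)
    union = a | b
    if not union:
        raise ValueError("Jaccard undefined for two empty sets")
    return len(a & b) / len(union)


@dataclass
class PermutationResult:
    observed_similarity: float
    n_iterations: int
    exceed_count: int
    p_value: float
    seed: int


def permutation_test(behavior_group, gi_groups, universe, n: int = 10000,
                     seed: int = 0, add_one: bool = False) -> PermutationResult:
    """One-sided permutation p-value for partition concordance.

    ``behavior_group`` is a set of genotypes; ``gi_groups`` a list of sets
    (the real interaction groups); ``universe`` the full gene set.  Each
    iteration draws mutually disjoint random groups from the universe with
    the same sizes as ``gi_groups`` and counts an exceedance when the best
    random similarity is strictly greater than the observed best similarity.
    ``add_one`` applies the (b+1)/(n+1) small-sample correction.
    """
    universe = sorted(set(universe))
    behavior_group = set(behavior_group)
    sizes = [len(g) for g in gi_groups]
    if sum(sizes) > len(universe):
        raise ValueError("group sizes exceed universe")
    for g in gi_groups:
        if not set(g) <= set(universe):
            raise ValueError("gi_groups must be subsets of the universe")
    if not behavior_group <= set(universe):
        raise ValueError("behavior_group must be a subset of the universe")

    observed = max(jaccard_sets(behavior_group, g) for g in gi_groups)
    rng = np.random.default_rng(seed)
    uni = np.array(universe, dtype=object)
    in_behavior = np.isin(uni, sorted(behavior_group))
    n_b = in_behavior.sum()
    offsets = np.cumsum([0] + sizes)

    # vectorized: one permutation per iteration, groups are contiguous slices
    exceed = 0
    batch = 2000
    done = 0
    while done < n:
        m = min(batch, n - done)
        order = np.argsort(rng.random((m, len(uni))), axis=1)
        member = in_behavior[order]                       # permuted membership
        best = np.zeros(m)
        for lo, hi in zip(offsets[:-1], offsets[1:]):
            inter = member[:, lo:hi].sum(axis=1)
            union = (hi - lo) + n_b - inter
            best = np.maximum(best, inter / union)
        exceed += int(np.sum(best > observed))
        done += m
    p = (exceed + 1) / (n + 1) if add_one else exceed / n
    return PermutationResult(observed_similarity=float(observed),
                             n_iterations=n, exceed_count=exceed,
                             p_value=float(p), seed=seed)


def categorize_stability(values) -> dict:
    """Bin Jaccard values into the three stability categories.

    Returns counts and percentages per category, the percentage of values at
    or above 0.35 (substantial overlap), and the per-value labels.
    """
    values = np.asarray(values, dtype=float)
    if values.size and (values.min() < 0 or values.max() > 1):
        raise ValueError("Jaccard values must lie in [0, 1]")
    lo, hi = STABILITY_EDGES
    labels = np.where(values < lo, STABILITY_LABELS[0],
                      np.where(values < hi, STABILITY_LABELS[1], STABILITY_LABELS[2]))
    counts = {lab: int(np.sum(labels == lab)) for lab in STABILITY_LABELS}
    total = max(values.size, 1)
    return {
        "counts": counts,
        "percentages": {lab: 100.0 * c / total for lab, c in counts.items()},
        "pct_substantial": 100.0 * float(np.sum(values >= lo)) / total,
        "category": labels,
    }
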