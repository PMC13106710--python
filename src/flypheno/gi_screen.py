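"""Genetic-interaction scoring from ERG depolarization amplitudes.

Amplitudes are normalized to the mean control amplitude of their experimental
batch.  Under the non-interacting (multiplicative) model the expected double
heterozygous amplitude is the product of the two normalized single-mutant
means; the interaction strength of a pair is the mean of (observed replicate
− expected).  A pair interacts only when |strength| >= 0.3: positive
strengths (phenotype milder than expected) are *alleviating*, negative
(amplitude further reduced) are *aggravating*, and anything within ±0.3 is
*none*.  Gene-by-gene strength profiles are clustered with Euclidean
distance and McQuitty linkage into two interaction groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .phenotype_clustering import Dendrogram, wpgma_linkage, cut_tree

GI_THRESHOLD = 0.3


@dataclass
class GIRecord:
    pair: tuple[str, str]
    mean_a: float
    mean_b: float
    expected: float
    observed_mean: float
    strength: float
    gi_class: str
    n_replicates: int
    replicate_strengths: np.ndarray


def normalize_to_control(erg: pd.DataFrame) -> pd.DataFrame:
    """Divide every amplitude by the mean control amplitude of its batch."""
    out = erg.copy()
    ctrl = erg[erg["is_control"]].groupby("batch")["amplitude"].mean()
    missing = set(erg["batch"]) - set(ctrl.index)
    if missing:
        raise ValueError(f"batches without control rows: {sorted(missing)}")
    out["normalized"] = out["amplitude"] / out["batch"].map(ctrl)
    return out


def expected_double(mean_a: float, mean_b: float) -> float:
    """Multiplicative non-interacting expectation for a double mutant."""
    return float(mean_a) * float(mean_b)


def gi_strength(observed: np.ndarray, expected: float) -> tuple[np.ndarray, float]:
    """Per-replicate strengths (observed − expected) and their mean."""
    observed = np.asarray(observed, dtype=float)
    strengths = observed - expected
    return strengths, float(strengths.mean())


def classify_gi(strength: float, threshold: float = GI_THRESHOLD) -> str:
    """±threshold rule: >= +t alleviating, <= −t aggravating, else none."""
    if strength >= threshold:
        return "alleviating"
    if strength <= -threshold:
        return "aggravating"
    return "none"


def enumerate_pairs(genes) -> list[tuple[str, str]]:
    """All unordered distinct pairs; n genes give n(n−1)/2 pairs."""
    genes = list(genes)
    if len(set(genes)) != len(genes):
        raise ValueError("duplicate gene labels")
    return [(a, b) for i, a in enumerate(genes) for b in genes[i + 1:]]


def _single_means(norm: pd.DataFrame) -> pd.Series:
    singles = norm[(~norm["is_control"]) &
                   ((norm["genotype_b"] == "") | norm["genotype_b"].isna())]
    return singles.groupby("genotype_a")["normalized"].mean()


def score_screen(erg: pd.DataFrame,
                 threshold: float = GI_THRESHOLD) -> list[GIRecord]:
    """Full screen: normalize, apply the multiplicative model to every pair."""
    norm = normalize_to_control(erg)
    single = _single_means(norm)
    doubles = norm[(~norm["is_control"]) &
                   (norm["genotype_b"] != "") & norm["genotype_b"].notna()]
    records = []
    for (a, b), grp in doubles.groupby(["genotype_a", "genotype_b"]):
        if a not in single.index or b not in single.index:
            raise ValueError(f"pair ({a}, {b}) references genotype without single-mutant data")
        exp = expected_double(single[a], single[b])
        reps = grp["normalized"].to_numpy()
        strengths, mean_s = gi_strength(reps, exp)
        records.append(GIRecord(
            pair=(a, b), mean_a=float(single[a]), mean_b=float(single[b]),
            expected=exp, observed_mean=float(reps.mean()), strength=mean_s,
            gi_class=classify_gi(mean_s, threshold), n_replicates=len(reps),
            replicate_strengths=strengths))
    return records


def records_table(records: list[GIRecord]) -> pd.DataFrame:
    return pd.DataFrame([{
        "gene_a": r.pair[0], "gene_b": r.pair[1], "expected": r.expected,
        "observed": r.observed_mean, "strength": r.strength,
        "class": r.gi_class, "n": r.n_replicates} for r in records])


def profile_matrix(records: list[GIRecord],
                   genes: list[str] | None = None,
                   diagonal: float = 0.0) -> pd.DataFrame:
    """Symmetric gene x gene strength matrix; untested self-pairs on the diagonal."""
    if genes is None:
        genes = sorted({g for r in records for g in r.pair})
    mat = pd.DataFrame(np.full((len(genes), len(genes)), np.nan),
                       index=genes, columns=genes)
    for r in records:
        a, b = r.pair
        mat.loc[a, b] = mat.loc[b, a] = r.strength
    np.fill_diagonal(mat.values, diagonal)
    if mat.isna().any().any():
        raise ValueError("profile matrix incomplete: missing pair strengths")
    return mat


def cluster_profiles(profiles: pd.DataFrame,
                     n_groups: int = 2) -> tuple[Dendrogram, dict[str, int]]:
    """Euclidean-distance WPGMA clustering of GI strength profiles."""
    import warnings
    values = profiles.to_numpy(dtype=float)
    if np.allclose(values, 0):
        warnings.warn("all-zero GI strengths: clustering is degenerate")
    dist = squareform(pdist(values, metric="euclidean"))
    tree = wpgma_linkage(dist, list(profiles.index), distance_name="euclidean")
    return tree, cut_tree(tree, n_groups)
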