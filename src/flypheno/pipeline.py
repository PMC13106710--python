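"""End-to-end orchestration: tracks -> features -> NMF -> genotype partition.

Runs the full behavioral stratification on a cohort (synthetic or loaded),
streaming one fly at a time so multi-day frame tables never accumulate in
memory: each track is annotated on the 10-s grid, sleep-scored, QC'd,
reduced to architecture features and a 1440-bin daily sleep vector; the
blurred vectors are factorized by NMF; genotype means of features (without
morning anticipation) and component encodings are clustered into the
behavior groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import ethogram, sleep_patterns, phenotype_clustering
from .synthetic_data import ArchetypeSpec, SimulationConfig, iter_tracks


@dataclass
class CohortResult:
    features: pd.DataFrame               # one row per fly
    M: np.ndarray                        # 1440 x l blurred sleep vectors
    fly_ids: list
    genotypes: list
    decomposition: sleep_patterns.Decomposition
    component_means: pd.DataFrame        # genotype x NMF components
    feature_matrix: pd.DataFrame         # scaled genotype x feature matrix
    tree: phenotype_clustering.Dendrogram
    groups: dict                         # genotype -> group (coarse cut)
    subgroups: dict                      # genotype -> subgroup (fine cut)
    dropped_flies: list


def process_fly(track: ethogram.FlyTrack):
    """Annotate one fly and reduce it to (features, sleep vector) or None."""
    ann, bouts, qc = ethogram.annotate_fly(track)
    retained = ethogram._retained_mask(ann, qc, track.zt0_offset)
    if not retained.any():
        return None
    feats = ethogram.extract_features(track, ann, bouts, qc)
    vec = sleep_patterns.build_vector(ann, zt0_offset=track.zt0_offset,
                                      retained=retained)
    return feats, vec


def run_cohort(config: SimulationConfig, archetypes: list[ArchetypeSpec],
               k: int = 5, n_groups: int = 2, n_subgroups: int = 5,
               nmf_restarts: int = 2, nmf_max_iter: int = 250) -> CohortResult:
    """Simulate a cohort and run the full stratification pipeline on it."""
    feats, vectors, dropped = [], {}, []
    genotype_of = {}
    for fly_id, genotype, frames in iter_tracks(config, archetypes):
        track = ethogram.FlyTrack(fly_id=fly_id, genotype=genotype,
                                  t=frames["t"].to_numpy(),
                                  x=frames["x"].to_numpy(),
                                  y=frames["y"].to_numpy(),
                                  fps=config.fps, photoperiod=config.photoperiod)
        out = process_fly(track)
        if out is None:
            dropped.append(fly_id)
            continue
        f, vec = out
        feats.append(f)
        vectors[fly_id] = vec
        genotype_of[fly_id] = genotype
    features = ethogram.features_table(feats)
    return stratify(features, vectors, genotype_of, k=k, n_groups=n_groups,
                    n_subgroups=n_subgroups, seed=config.seed,
                    nmf_restarts=nmf_restarts, nmf_max_iter=nmf_max_iter,
                    dropped=dropped)


def stratify(features: pd.DataFrame, vectors: dict, genotype_of: dict,
             k: int = 5, n_groups: int = 2, n_subgroups: int = 5, seed: int = 0,
             nmf_restarts: int = 2, nmf_max_iter: int = 250,
             dropped: list | None = None) -> CohortResult:
    """Stratification stage shared by simulated and loaded cohorts."""
    M, fly_ids, genotypes = sleep_patterns.build_matrix(vectors, genotype_of)
    k = min(k, min(M.shape), len(fly_ids))
    dec = sleep_patterns.fit_nmf(M, k=k, seed=seed, n_restarts=nmf_restarts,
                                 max_iter=nmf_max_iter)
    comp_means = sleep_patterns.genotype_component_means(dec.H, genotypes)

    numeric = features.drop(columns=["fly_id"]).groupby("genotype").mean()
    matrix = phenotype_clustering.assemble_features(numeric, comp_means)
    n_subgroups = min(n_subgroups, len(matrix))
    tree, groups, subgroups = phenotype_clustering.cluster_genotypes(
        matrix, n_groups=n_groups, n_subgroups=n_subgroups)
    return CohortResult(features=features, M=M, fly_ids=fly_ids,
                        genotypes=genotypes, decomposition=dec,
                        component_means=comp_means, feature_matrix=matrix,
                        tree=tree, groups=groups, subgroups=subgroups,
                        dropped_flies=dropped or [])


def partition_recovery(recovered: dict, planted: dict) -> float:
    """Worst-case best-match Jaccard of the planted groups in the recovered cut."""
    from .phenotype_clustering import best_match_jaccard
    scores = best_match_jaccard(planted, recovered)
    return min(scores.values())
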