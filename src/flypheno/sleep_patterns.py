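"""Daily sleep vectors and their non-negative matrix factorization.

Each fly is summarized by a 1440-entry vector (one bin per minute of the
24-h day): the fraction of annotated intervals, pooled over retained days,
whose preceding 5-min window was at least 99% immobile ("time spent
sleeping").  A Gaussian blur (default sigma = 5 bins) smooths adjacent bins.
Stacking the blurred vectors of l flies column-wise gives the non-negative
matrix M (1440 x l), which NMF factorizes as M ~ W H with W (1440 x k) the
shared temporal components and H (k x l) each fly's non-negative encoding.

Rank selection uses the explained-variance elbow (maximal curvature of the
variance-vs-k curve) and, alternatively, the Calinski-Harabasz index of the
clustering induced by each fly's dominant component.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from sklearn.decomposition import NMF
from sklearn.metrics import calinski_harabasz_score

from .ethogram import INTERVAL

N_BINS = 1440
BLUR_SIGMA = 5.0


@dataclass
class Decomposition:
    W: np.ndarray                # 1440 x k temporal components
    H: np.ndarray                # k x l fly encodings
    k: int
    explained_variance: float
    seed: int

    def __post_init__(self) -> None:
        if (self.W < 0).any() or (self.H < 0).any():
            raise ValueError("NMF factors must be non-negative")


def build_vector(annotations: pd.DataFrame, zt0_offset: float = 0.0,
                 retained: np.ndarray | None = None,
                 asleep_window: float = 300.0,
                 immobile_frac: float = 0.99) -> np.ndarray:
    """1440-bin "time spent sleeping" vector for one fly.

    For every 10-s interval the strictly preceding 5-min window is inspected;
    the interval scores 1 when >= 99% of those intervals were immobile.  Bin
    values are the mean score of the retained intervals falling in each
    clock-time minute.  Bins with no retained data are 0.
    """
    immobile = ((~annotations["moving"].to_numpy())
                & (~annotations["missing"].to_numpy())).astype(float)
    n = len(immobile)
    n_look = int(round(asleep_window / INTERVAL))
    c = np.concatenate([[0.0], np.cumsum(immobile)])
    frac = np.full(n, np.nan)
    if n > n_look:
        # strictly preceding window: intervals [i - n_look, i)
        frac[n_look:] = (c[n_look:n] - c[:n - n_look]) / n_look
    score = (frac >= immobile_frac).astype(float)

    starts = annotations["interval_start"].to_numpy()
    minute = (((starts - zt0_offset) % 86400.0) // 60.0).astype(int)
    keep = ~np.isnan(frac)
    if retained is not None:
        keep &= retained
    keep &= ~annotations["missing"].to_numpy()
    vec = np.zeros(N_BINS)
    counts = np.bincount(minute[keep], minlength=N_BINS)
    sums = np.bincount(minute[keep], weights=score[keep], minlength=N_BINS)
    nz = counts > 0
    vec[nz] = sums[nz] / counts[nz]
    return vec


def gaussian_blur(vector: np.ndarray, sigma: float = BLUR_SIGMA,
                  mode: str = "reflect") -> np.ndarray:
    """Discrete Gaussian smoothing of a 1440-bin vector.

    ``mode='wrap'`` treats clock time as periodic; sigma = 0 is the identity.
    """
    vector = np.asarray(vector, dtype=float)
    if vector.shape != (N_BINS,):
        raise ValueError(f"expected a {N_BINS}-bin vector")
    if sigma == 0:
        return vector.copy()
    return gaussian_filter1d(vector, sigma=sigma, mode=mode)


def build_matrix(vectors: dict[str, np.ndarray],
                 genotypes: dict[str, str] | None = None,
                 sigma: float = BLUR_SIGMA) -> tuple[np.ndarray, list[str], list[str]]:
    """Stack blurred per-fly vectors into M (1440 x l)."""
    fly_ids = list(vectors)
    M = np.column_stack([gaussian_blur(vectors[f], sigma) for f in fly_ids])
    labels = [genotypes.get(f, "") if genotypes else "" for f in fly_ids]
    return M, fly_ids, labels


def explained_variance(M: np.ndarray, W: np.ndarray, H: np.ndarray) -> float:
    """1 - ||M - WH||^2_F / ||M - column means||^2_F."""
    resid = float(np.linalg.norm(M - W @ H) ** 2)
    tss = float(np.linalg.norm(M - M.mean(axis=0, keepdims=True)) ** 2)
    if tss == 0:
        return 1.0 if resid == 0 else -np.inf
    return 1.0 - resid / tss


def fit_nmf(M: np.ndarray, k: int, seed: int = 0,
            n_restarts: int = 5, max_iter: int = 400) -> Decomposition:
    """Best-of-restarts NMF of the sleep-vector matrix.

    One deterministic NNDSVD-initialized fit plus ``n_restarts`` random
    restarts; the solution with the lowest reconstruction error is kept.
    Deterministic for a fixed seed.
    """
    M = np.asarray(M, dtype=float)
    if M.size == 0:
        raise ValueError("empty matrix")
    if not 1 <= k <= min(M.shape):
        raise ValueError(f"k must lie in [1, {min(M.shape)}]")
    best = None
    inits = [("nndsvda", seed)] + [("random", seed + 1 + r) for r in range(n_restarts)]
    for init, rs in inits:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = NMF(n_components=k, init=init, random_state=rs,
                        max_iter=max_iter, tol=1e-6)
            W = model.fit_transform(M)
        if best is None or model.reconstruction_err_ < best[0]:
            best = (model.reconstruction_err_, W, model.components_)
    _, W, H = best
    return Decomposition(W=W, H=H, k=k,
                         explained_variance=explained_variance(M, W, H),
                         seed=seed)


def variance_curve(M: np.ndarray, k_range: range, seed: int = 0,
                   **kw) -> dict[int, float]:
    """Explained variance of the best fit at each k (monotone in k up to restarts)."""
    return {k: fit_nmf(M, k, seed=seed, **kw).explained_variance for k in k_range}


def select_k_elbow(variances: dict[int, float],
                   min_gain: float = 0.02) -> int:
    """Rank at the elbow of the explained-variance curve.

    Returns the k with the most negative discrete second difference (maximal
    curvature).  If the curve has no concave elbow, falls back to the
    smallest k whose marginal gain drops below ``min_gain`` and warns.
    """
    ks = sorted(variances)
    if len(ks) < 3:
        raise ValueError("need variances for at least 3 consecutive k")
    v = np.array([variances[k] for k in ks])
    d2 = v[2:] - 2 * v[1:-1] + v[:-2]       # indexed by interior ks[1:-1]
    if np.ptp(d2) < 1e-12 or d2.min() >= 0:
        warnings.warn("no elbow in explained-variance curve; "
                      "falling back to marginal-gain rule")
        gains = np.diff(v)
        for i, g in enumerate(gains):
            if g < min_gain:
                return ks[i + 1]
        return ks[-1]
    return ks[1 + int(np.argmin(d2))]


def dominant_component(H: np.ndarray) -> np.ndarray:
    """Cluster label of each fly = argmax of its encoding column."""
    return np.argmax(H, axis=0)


def ch_index(H: np.ndarray) -> float:
    """Calinski-Harabasz index of the dominant-component clustering.

    Computed on the fly encoding vectors (columns of H).  Degenerate cases:
    +inf when all within-cluster dispersion vanishes, NaN when fewer than two
    clusters are occupied.
    """
    X = H.T
    labels = dominant_component(H)
    if len(np.unique(labels)) < 2:
        warnings.warn("fewer than 2 occupied clusters; CH undefined")
        return float("nan")
    within = sum(np.sum((X[labels == c] - X[labels == c].mean(axis=0)) ** 2)
                 for c in np.unique(labels))
    if within == 0:
        return float("inf")
    return float(calinski_harabasz_score(X, labels))


def genotype_component_means(H: np.ndarray, genotypes: list[str]) -> pd.DataFrame:
    """Per-genotype arithmetic mean of fly encodings (rows = genotypes)."""
    if H.shape[1] != len(genotypes):
        raise ValueError("one genotype label per fly required")
    df = pd.DataFrame(H.T, columns=[f"NMF{j}" for j in range(H.shape[0])])
    df["genotype"] = genotypes
    return df.groupby("genotype").mean()
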