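"""Bayesian re-analysis of gene-pair interactions.

For each pair the normalized single-mutant fractions alpha and beta get
scaled-Beta priors, ``alpha, beta ~ 1.05 * Beta(2, 5)`` — supported on
(0, 1.05) so minor increases above control remain possible, and skewed
toward fractions nearer 1 — and the additive interaction term iota gets a
``Normal(0, 1)`` prior.  The double-mutant mean is modeled as
``alpha * beta + iota``.  Replicates are observed with Normal noise whose
per-genotype scales carry HalfNormal(0.2) priors (weakly informative on the
normalized scale).  The posterior is explored with an affine-invariant
ensemble MCMC sampler; a pair is called interacting when 0 falls outside the
95% highest-density interval (HDI) of iota.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

BETA_A, BETA_B = 2.0, 5.0
BETA_SCALE = 1.05
IOTA_SD = 1.0
SIGMA_SCALE = 0.2
_LOG_BETA_NORM = (math.lgamma(BETA_A) + math.lgamma(BETA_B)
                  - math.lgamma(BETA_A + BETA_B))


@dataclass
class PairData:
    """Normalized replicate amplitudes for one gene pair."""

    single_a_reps: np.ndarray
    single_b_reps: np.ndarray
    double_reps: np.ndarray

    def __post_init__(self) -> None:
        for name in ("single_a_reps", "single_b_reps", "double_reps"):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if arr.size < 5:
                raise ValueError(f"{name} needs at least 5 replicates")
            if np.any(arr <= 0):
                raise ValueError(f"{name} must be strictly positive")


@dataclass
class GIPosterior:
    iota_draws: np.ndarray
    hdi_low: float
    hdi_high: float
    interacting: bool
    n_draws: int
    seed: int
    rhat: float
    iota_mean: float


class PairModel:
    """Log-posterior of (alpha, beta, iota, sigma_a, sigma_b, sigma_d).

    Vectorized over walker ensembles: accepts a (n, 6) array and returns n
    log-densities.
    """

    ndim = 6
    names = ("alpha", "beta", "iota", "sigma_a", "sigma_b", "sigma_d")

    def __init__(self, data: PairData):
        self.data = data

    @staticmethod
    def _log_scaled_beta(x: np.ndarray) -> np.ndarray:
        u = x / BETA_SCALE
        with np.errstate(divide="ignore", invalid="ignore"):
            lp = ((BETA_A - 1) * np.log(u) + (BETA_B - 1) * np.log1p(-u)
                  - _LOG_BETA_NORM - math.log(BETA_SCALE))
        return np.where((x > 0) & (x < BETA_SCALE), lp, -np.inf)

    def log_prob(self, theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(np.asarray(theta, dtype=float))
        alpha, beta, iota, sa, sb, sd = theta.T
        lp = self._log_scaled_beta(alpha) + self._log_scaled_beta(beta)
        lp = lp - 0.5 * (iota / IOTA_SD) ** 2
        for s in (sa, sb, sd):
            lp = np.where(s > 0, lp - 0.5 * (s / SIGMA_SCALE) ** 2, -np.inf)
        ok = np.isfinite(lp)
        if ok.any():
            def norm_ll(y: np.ndarray, mu: np.ndarray, s: np.ndarray) -> np.ndarray:
                s = np.where(s > 0, s, 1.0)
                return (-0.5 * ((y[None, :] - mu[:, None]) / s[:, None]) ** 2
                        - np.log(s[:, None])).sum(axis=1)

            ll = (norm_ll(self.data.single_a_reps, alpha, sa)
                  + norm_ll(self.data.single_b_reps, beta, sb)
                  + norm_ll(self.data.double_reps, alpha * beta + iota, sd))
            lp = np.where(ok, lp + ll, -np.inf)
        return lp


def build_model(data: PairData) -> PairModel:
    """Model specification for one gene pair (priors + Normal likelihood)."""
    return PairModel(data)


def _initial_ensemble(model: PairModel, n_walkers: int,
                      rng: np.random.Generator) -> np.ndarray:
    d = model.data
    a0 = float(np.clip(d.single_a_reps.mean(), 0.02, BETA_SCALE - 0.02))
    b0 = float(np.clip(d.single_b_reps.mean(), 0.02, BETA_SCALE - 0.02))
    i0 = float(d.double_reps.mean() - a0 * b0)
    s0 = [max(float(x.std()), 0.01) for x in
          (d.single_a_reps, d.single_b_reps, d.double_reps)]
    center = np.array([a0, b0, i0, *s0])
    p0 = center + rng.normal(0, 0.01, (n_walkers, model.ndim))
    p0[:, 0] = np.clip(p0[:, 0], 1e-3, BETA_SCALE - 1e-3)
    p0[:, 1] = np.clip(p0[:, 1], 1e-3, BETA_SCALE - 1e-3)
    p0[:, 3:] = np.abs(p0[:, 3:]) + 1e-3
    return p0


def sample_posterior(model: PairModel, n_draws: int = 2000, chains: int = 4,
                     seed: int = 0, warmup: int = 1000,
                     n_walkers: int = 32, hdi_mass: float = 0.95) -> GIPosterior:
    """MCMC posterior for the interaction term of one pair.

    ``n_draws`` is the number of post-warmup ensemble steps retained; with
    ``n_walkers`` walkers the pooled iota sample holds
    ``n_draws * n_walkers`` draws.  Walkers are pooled into ``chains``
    groups and split-R-hat computed across the groups (individual walker
    trajectories of an affine-invariant ensemble are strongly autocorrelated,
    so per-walker R-hat would overstate non-convergence); values above 1.01
    raise a warning.
    """
    import emcee

    rng = np.random.default_rng(seed)
    p0 = _initial_ensemble(model, n_walkers, rng)
    sampler = emcee.EnsembleSampler(n_walkers, model.ndim, model.log_prob,
                                    vectorize=True)
    init = emcee.State(p0, random_state=np.random.RandomState(seed % (2**31)).get_state())
    state = sampler.run_mcmc(init, warmup, progress=False)
    sampler.reset()
    sampler.run_mcmc(state, n_draws, progress=False)
    chain = sampler.get_chain()                 # (n_draws, n_walkers, ndim)
    iota = chain[:, :, 2]

    n_g = max(chains, 2)
    per = n_walkers // n_g
    grouped = iota[:, :n_g * per].reshape(iota.shape[0], n_g, per)
    grouped = grouped.transpose(1, 0, 2).reshape(n_g, -1)
    rhat = split_rhat(grouped)
    if not np.isfinite(rhat) or rhat > 1.01:
        warnings.warn(f"iota split-R-hat {rhat:.3f} above 1.01; "
                      "treat this pair's posterior with caution")
    draws = iota.reshape(-1)
    low, high = hdi(draws, mass=hdi_mass)
    return GIPosterior(iota_draws=draws, hdi_low=low, hdi_high=high,
                       interacting=not (low <= 0.0 <= high),
                       n_draws=draws.size, seed=seed, rhat=rhat,
                       iota_mean=float(draws.mean()))


def split_rhat(chains: np.ndarray) -> float:
    """Gelman-Rubin split-R-hat of a (n_chains, n_draws) sample array."""
    chains = np.asarray(chains, dtype=float)
    n = chains.shape[1] // 2
    halves = np.concatenate([chains[:, :n], chains[:, n:2 * n]], axis=0)
    m, n = halves.shape
    means = halves.mean(axis=1)
    B = n * means.var(ddof=1)
    W = halves.var(axis=1, ddof=1).mean()
    if W == 0:
        return 1.0
    var_hat = (n - 1) / n * W + B / n
    return float(math.sqrt(var_hat / W))


def hdi(draws: np.ndarray, mass: float = 0.95) -> tuple[float, float]:
    """Narrowest interval containing ``mass`` of the sampled posterior."""
    draws = np.sort(np.asarray(draws, dtype=float))
    n = draws.size
    if n < 2:
        return float(draws[0]), float(draws[0])
    m = max(int(math.ceil(mass * n)), 1)
    if m >= n:
        return float(draws[0]), float(draws[-1])
    widths = draws[m:] - draws[:n - m]
    i = int(np.argmin(widths))
    return float(draws[i]), float(draws[i + m])


def call_interaction(posterior: GIPosterior) -> bool:
    """True iff 0 lies outside the 95% HDI of the interaction term."""
    return not (posterior.hdi_low <= 0.0 <= posterior.hdi_high)
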