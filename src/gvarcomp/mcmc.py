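"""Gibbs sampler for the Bayesian p x i random-effects model.

Model:  ``X_pi = mu + pi_p + beta_i + eps_pi`` with
``pi_p ~ N(0, vc_p)``, ``beta_i ~ N(0, vc_i)``, ``eps_pi ~ N(0, vc_pi)``,
a flat prior on the grand mean and conjugate inverse-gamma hyperpriors on
the three variances.  The hyperprior ``tau(a, b)`` is inverse-gamma with
shape ``a`` and scale ``b``; with the default shape 2 the prior mean is
``b``, and the default scales (4, 16, 64) center the priors on the
normal-family generating components.

Full conditionals are cycled in a fixed order (mu, person effects, item
effects, the three variances); every variance full conditional is
inverse-gamma (shape + n/2, scale + SS/2), so sampled variances are
strictly positive at every iteration.  Summaries are posterior means,
posterior SDs and central 80% credible intervals of the post-burn-in,
thinned draws pooled across chains; convergence is monitored by the
split-chain potential scale reduction factor (threshold 1.1, flagged, not
fatal).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .design import MethodResult, as_matrix


@dataclass(frozen=True)
class PriorSpec:
    """Inverse-gamma hyperpriors (shape, scale) per variance component."""

    shapes: tuple = (2.0, 2.0, 2.0)
    scales: tuple = (4.0, 16.0, 64.0)
    initial_variance: float = 0.001

    def __post_init__(self) -> None:
        if any(a <= 1 for a in self.shapes):
            raise ValueError("inverse-gamma shape must exceed 1 (finite prior mean)")
        if any(b <= 0 for b in self.scales):
            raise ValueError("inverse-gamma scale must be positive")

    @classmethod
    def centered_on(cls, vc, shape: float = 2.0) -> "PriorSpec":
        """Priors whose mean equals the supplied component triple."""
        return cls(shapes=(shape,) * 3, scales=tuple(float(v) for v in vc))


@dataclass(frozen=True)
class ChainConfig:
    """MCMC run settings; the default is one chain of 11000 iterations
    with 1000 discarded as burn-in, no thinning."""

    n_iter: int = 11_000
    burn_in: int = 1_000
    thin: int = 1
    n_chains: int = 1
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.n_iter > self.burn_in >= 0:
            raise ValueError("need n_iter > burn_in >= 0")
        if self.thin < 1 or self.n_chains < 1:
            raise ValueError("thin and n_chains must be >= 1")


@dataclass
class PosteriorSummary:
    """Posterior mean/SD/central interval per component plus diagnostics."""

    mean: np.ndarray
    sd: np.ndarray
    ci: np.ndarray            # (3, 2)
    level: float
    rhat: np.ndarray
    converged: bool
    draws: np.ndarray | None = None

    def as_result(self) -> MethodResult:
        return MethodResult("mcmc", self.mean, self.sd, self.ci, self.level,
                            {"rhat": self.rhat, "converged": self.converged})


def _run_chain(x: np.ndarray, priors: PriorSpec, n_iter: int,
               rng: np.random.Generator, fix_effects_to_zero: bool) -> np.ndarray:
    """One chain; returns all sampled variance triples, shape (n_iter, 3)."""
    n_p, n_i = x.shape
    n = n_p * n_i
    a_p, a_i, a_e = priors.shapes
    b_p, b_i, b_e = priors.scales

    mu = 0.0
    pi_p = np.zeros(n_p)
    beta_i = np.zeros(n_i)
    v = np.full(3, priors.initial_variance)  # (vc_p, vc_i, vc_pi)
    out = np.empty((n_iter, 3))

    for it in range(n_iter):
        if not fix_effects_to_zero:
            # grand mean, flat prior
            resid = x - pi_p[:, None] - beta_i[None, :]
            mu = rng.normal(resid.mean(), np.sqrt(v[2] / n))
            # person effects
            prec = n_i / v[2] + 1.0 / v[0]
            mean_p = ((x - mu - beta_i[None, :]).sum(axis=1) / v[2]) / prec
            pi_p = rng.normal(mean_p, np.sqrt(1.0 / prec))
            # item effects
            prec = n_p / v[2] + 1.0 / v[1]
            mean_i = ((x - mu - pi_p[:, None]).sum(axis=0) / v[2]) / prec
            beta_i = rng.normal(mean_i, np.sqrt(1.0 / prec))
            # variance of person effects
            v[0] = 1.0 / rng.gamma(a_p + n_p / 2.0,
                                   1.0 / (b_p + 0.5 * (pi_p ** 2).sum()))
            # variance of item effects
            v[1] = 1.0 / rng.gamma(a_i + n_i / 2.0,
                                   1.0 / (b_i + 0.5 * (beta_i ** 2).sum()))
        eps = x - mu - pi_p[:, None] - beta_i[None, :]
        v[2] = 1.0 / rng.gamma(a_e + n / 2.0,
                               1.0 / (b_e + 0.5 * (eps ** 2).sum()))
        if not np.all(np.isfinite(v)):
            raise FloatingPointError(f"non-finite variance draw at iteration {it}")
        out[it] = v
    return out


def split_rhat(chains: np.ndarray) -> np.ndarray:
    """Split-chain potential scale reduction factor.

    ``chains`` has shape (n_chains, n_draws, 3); each chain is split in
    half before the between/within comparison.
    """
    n_chains, n_draws, k = chains.shape
    half = n_draws // 2
    seg = chains[:, : 2 * half].reshape(n_chains * 2, half, k)
    w = seg.var(axis=1, ddof=1).mean(axis=0)
    b = half * seg.mean(axis=1).var(axis=0, ddof=1)
    var_plus = (half - 1) / half * w + b / half
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.sqrt(var_plus / w)


def gibbs_sample(matrix, priors: PriorSpec | None = None,
                 chain: ChainConfig | None = None, seed=None,
                 level: float = 0.80, return_draws: bool = False,
                 fix_effects_to_zero: bool = False,
                 rhat_threshold: float = 1.1) -> PosteriorSummary:
    """Posterior summaries of the three variance components.

    ``fix_effects_to_zero`` clamps mu and both effect vectors to zero so
    that only the residual variance is sampled; its posterior is then the
    closed-form inverse-gamma conjugate update (diagnostic/testing mode).
    """
    x = as_matrix(matrix)
    priors = priors or PriorSpec()
    chain = chain or ChainConfig()
    if seed is None:
        seed = chain.seed
    ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed

    kept = []
    for child in ss.spawn(chain.n_chains):
        draws = _run_chain(x, priors, chain.n_iter, np.random.default_rng(child),
                           fix_effects_to_zero)
        kept.append(draws[chain.burn_in::chain.thin])
    stacked = np.stack(kept)                      # (n_chains, n_kept, 3)
    pooled = stacked.reshape(-1, 3)

    mean = pooled.mean(axis=0)
    sd = pooled.std(axis=0, ddof=1)
    lo = (1.0 - level) / 2.0
    ci = np.quantile(pooled, [lo, 1.0 - lo], axis=0).T
    rhat = split_rhat(stacked)
    converged = bool(np.all(rhat[np.isfinite(rhat)] < rhat_threshold))
    return PosteriorSummary(mean, sd, ci, level, rhat, converged,
                            pooled if return_draws else None)
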