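"""Score-matrix generators for the four study distributions.

Four families of person x item score matrices are generated under the
additive random-effects model ``X_pi = mu + pi_p + beta_i + eps_pi``:

``normal``
    Additive standard-normal effects scaled by (sigma_p, sigma_i, sigma_pi)
    = (2, 4, 8), so the population components are (4, 16, 64).

``dichotomous``
    The normal score thresholded at zero: ``Y = 1`` iff ``X >= 0``; each
    cell is Bernoulli(1/2).

``polytomous``
    ``X = 2*Bern(0.14715) + 2*Bern(0.0595) + Binom(5, 0.5917)`` with the
    first term drawn once per person, the second once per item and the
    third per cell, giving integer scores on 0..9.

``skewed``
    Additive generalized-hyperbolic (GH) effects, one draw per person, per
    item and per cell.  The GH variate is sampled as a normal variance-mean
    mixture ``X = mu + beta*W + sqrt(W)*Z`` with ``W`` generalized inverse
    Gaussian; skewness is controlled by ``beta`` (0, -1, -2 in the study).

Population (true) variance components for every family are available in
closed form through :func:`population_vc`; for the dichotomous family the
exact bivariate-normal orthant covariance (arcsine) formula is used.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special, stats

from .design import DesignSpec, VarianceComponents

FAMILIES = ("normal", "dichotomous", "polytomous", "skewed")


@dataclass(frozen=True)
class DistributionSpec:
    """Parameters of one generating family.

    Only the fields relevant to ``family`` are used.  ``sigma_p``/``sigma_i``
    /``sigma_pi`` are effect standard deviations of the underlying normal
    score (also used by the dichotomous family, which thresholds it at
    ``threshold``).  The polytomous family uses two Bernoulli terms with
    weights ``poly_a1``/``poly_a2`` and a Binomial(``poly_m``, ``poly_p3``)
    cell term.  The skewed family uses GH parameters (lam, alpha, beta,
    delta, mu) with the constraint ``alpha > |beta|``.
    """

    family: str = "normal"
    mu: float = 0.0
    sigma_p: float = 2.0
    sigma_i: float = 4.0
    sigma_pi: float = 8.0
    threshold: float = 0.0
    poly_a1: float = 2.0
    poly_p1: float = 0.14715
    poly_a2: float = 2.0
    poly_p2: float = 0.0595
    poly_m: int = 5
    poly_p3: float = 0.5917
    gh_lam: float = 1.0
    gh_alpha: float = 3.0
    gh_beta: float = 0.0
    gh_delta: float = 1.0
    gh_mu: float = 0.0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        for s in (self.sigma_p, self.sigma_i, self.sigma_pi):
            if not np.isfinite(s) or s < 0:
                raise ValueError("effect standard deviations must be finite and >= 0")
        for p in (self.poly_p1, self.poly_p2, self.poly_p3):
            if not 0 < p < 1:
                raise ValueError("binomial success probabilities must lie in (0, 1)")
        if self.family == "skewed" and not self.gh_alpha > abs(self.gh_beta):
            raise ValueError("GH density requires alpha > |beta|")

    # -- convenience constructors matching the study conditions ------------
    @classmethod
    def normal(cls, mu=0.0, sigma_p=2.0, sigma_i=4.0, sigma_pi=8.0) -> "DistributionSpec":
        return cls(family="normal", mu=mu, sigma_p=sigma_p, sigma_i=sigma_i, sigma_pi=sigma_pi)

    @classmethod
    def dichotomous(cls, mu=0.0, sigma_p=2.0, sigma_i=4.0, sigma_pi=8.0, threshold=0.0) -> "DistributionSpec":
        return cls(family="dichotomous", mu=mu, sigma_p=sigma_p, sigma_i=sigma_i,
                   sigma_pi=sigma_pi, threshold=threshold)

    @classmethod
    def polytomous(cls) -> "DistributionSpec":
        return cls(family="polytomous")

    @classmethod
    def skewed(cls, beta: float = 0.0, lam: float = 1.0, alpha: float = 3.0,
               delta: float = 1.0, mu: float = 0.0) -> "DistributionSpec":
        return cls(family="skewed", gh_lam=lam, gh_alpha=alpha, gh_beta=beta,
                   gh_delta=delta, gh_mu=mu)

    @property
    def label(self) -> str:
        if self.family == "skewed":
            return f"skewed(beta={self.gh_beta:g})"
        return self.family


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def _normal_parts(design: DesignSpec, spec: DistributionSpec, rng: np.random.Generator):
    """Raw standard-normal draws with the row/column sharing structure."""
    z_p = rng.standard_normal(design.n_p)
    z_i = rng.standard_normal(design.n_i)
    z_pi = rng.standard_normal((design.n_p, design.n_i))
    return z_p, z_i, z_pi


def gen_normal(design: DesignSpec, spec: DistributionSpec, seed=None, *, return_effects: bool = False):
    """Normal score matrix ``mu + s_p z_p + s_i z_i + s_pi z_pi``.

    ``z_p`` is shared along each row and ``z_i`` along each column.  With
    ``return_effects`` the raw draws are returned as well (used by the
    structure tests).
    """
    if spec.family not in ("normal", "dichotomous"):
        raise ValueError("gen_normal requires a normal-family spec")
    z_p, z_i, z_pi = _normal_parts(design, spec, _rng(seed))
    x = (spec.mu
         + spec.sigma_p * z_p[:, None]
         + spec.sigma_i * z_i[None, :]
         + spec.sigma_pi * z_pi)
    if return_effects:
        return x, (z_p, z_i, z_pi)
    return x


def gen_dichotomous(design: DesignSpec, spec: DistributionSpec, seed=None) -> np.ndarray:
    """Indicator of the underlying normal score reaching the threshold.

    ``Y = 1`` iff ``X >= threshold`` (the boundary is included), so with the
    default symmetric parameters each cell is Bernoulli(1/2).
    """
    if spec.family != "dichotomous":
        raise ValueError("gen_dichotomous requires family='dichotomous'")
    x = gen_normal(design, spec, seed)
    return (x >= spec.threshold).astype(float)


def gen_polytomous(design: DesignSpec, spec: DistributionSpec, seed=None) -> np.ndarray:
    """Binomial-mixture integer scores on 0..9.

    The weighted Bernoulli terms are the person and item effects (drawn
    once per person / per item); the Binomial(5, .5917) term is the cell
    effect.  This indexing reproduces the population components
    ``a^2 p(1-p)`` = (0.5020, 0.2240) and ``m p3 (1-p3)`` = 1.2080.
    """
    if spec.family != "polytomous":
        raise ValueError("gen_polytomous requires family='polytomous'")
    rng = _rng(seed)
    person = spec.poly_a1 * rng.binomial(1, spec.poly_p1, size=design.n_p)
    item = spec.poly_a2 * rng.binomial(1, spec.poly_p2, size=design.n_i)
    cell = rng.binomial(spec.poly_m, spec.poly_p3, size=(design.n_p, design.n_i))
    return person[:, None] + item[None, :] + cell.astype(float)


def sample_gh(spec: DistributionSpec, size, rng: np.random.Generator) -> np.ndarray:
    """Generalized-hyperbolic draws via the normal variance-mean mixture.

    ``X = mu + beta W + sqrt(W) Z`` with ``W ~ GIG(lam, chi=delta^2,
    psi=alpha^2 - beta^2)`` and ``Z`` standard normal.  The GIG draw uses
    :class:`scipy.stats.geninvgauss` with ``b = delta*gamma`` and scale
    ``delta/gamma`` where ``gamma = sqrt(alpha^2 - beta^2)``.
    """
    gamma = np.sqrt(spec.gh_alpha ** 2 - spec.gh_beta ** 2)
    w = stats.geninvgauss.rvs(spec.gh_lam, spec.gh_delta * gamma,
                              scale=spec.gh_delta / gamma, size=size, random_state=rng)
    z = rng.standard_normal(size)
    return spec.gh_mu + spec.gh_beta * w + np.sqrt(w) * z


def gen_skewed(design: DesignSpec, spec: DistributionSpec, seed=None) -> np.ndarray:
    """Additive GH effects: one draw per person, per item and per cell."""
    if spec.family != "skewed":
        raise ValueError("gen_skewed requires family='skewed'")
    rng = _rng(seed)
    gp = sample_gh(spec, design.n_p, rng)
    gi = sample_gh(spec, design.n_i, rng)
    gpi = sample_gh(spec, (design.n_p, design.n_i), rng)
    return spec.mu + gp[:, None] + gi[None, :] + gpi


_GENERATORS = {
    "normal": gen_normal,
    "dichotomous": gen_dichotomous,
    "polytomous": gen_polytomous,
    "skewed": gen_skewed,
}


def generate(design: DesignSpec, spec: DistributionSpec, seed=None) -> np.ndarray:
    """Dispatch to the family's generator."""
    return _GENERATORS[spec.family](design, spec, seed)


# ---------------------------------------------------------------------------
# population values
# ---------------------------------------------------------------------------

def gh_variance(spec: DistributionSpec) -> float:
    """Closed-form variance of one GH effect.

    Var(X) = E[W] + beta^2 Var(W) with GIG moments
    ``E[W^k] = (delta/gamma)^k K_{lam+k}(delta*gamma) / K_lam(delta*gamma)``.
    """
    gamma = np.sqrt(spec.gh_alpha ** 2 - spec.gh_beta ** 2)
    dg = spec.gh_delta * gamma
    k0 = special.kv(spec.gh_lam, dg)
    ew = (spec.gh_delta / gamma) * special.kv(spec.gh_lam + 1, dg) / k0
    ew2 = (spec.gh_delta / gamma) ** 2 * special.kv(spec.gh_lam + 2, dg) / k0
    return float(ew + spec.gh_beta ** 2 * (ew2 - ew ** 2))


def gh_mean(spec: DistributionSpec) -> float:
    gamma = np.sqrt(spec.gh_alpha ** 2 - spec.gh_beta ** 2)
    dg = spec.gh_delta * gamma
    ew = (spec.gh_delta / gamma) * special.kv(spec.gh_lam + 1, dg) / special.kv(spec.gh_lam, dg)
    return float(spec.gh_mu + spec.gh_beta * ew)


def _dichotomous_vc(spec: DistributionSpec) -> VarianceComponents:
    # Orthant covariance of thresholded equicorrelated normals: two cells
    # sharing only the person (item) effect have underlying correlation
    # rho = sigma^2 / sigma_total^2 and indicator covariance
    # arcsin(rho) / (2 pi); the cell variance is q(1-q) with
    # q = P(X >= threshold).  vc.pi is the remainder.
    tot = spec.sigma_p ** 2 + spec.sigma_i ** 2 + spec.sigma_pi ** 2
    if tot == 0:
        return VarianceComponents(0.0, 0.0, 0.0)
    if spec.threshold != spec.mu:
        raise NotImplementedError(
            "closed-form dichotomous components implemented for the symmetric "
            "case threshold == mu only")
    q = 0.5
    vc_p = float(np.arcsin(spec.sigma_p ** 2 / tot) / (2 * np.pi))
    vc_i = float(np.arcsin(spec.sigma_i ** 2 / tot) / (2 * np.pi))
    return VarianceComponents(vc_p, vc_i, q * (1 - q) - vc_p - vc_i)


def population_vc(spec: DistributionSpec) -> VarianceComponents:
    """Analytic (true) variance components of the generating process."""
    if spec.family == "normal":
        return VarianceComponents(spec.sigma_p ** 2, spec.sigma_i ** 2, spec.sigma_pi ** 2)
    if spec.family == "dichotomous":
        return _dichotomous_vc(spec)
    if spec.family == "polytomous":
        return VarianceComponents(
            spec.poly_a1 ** 2 * spec.poly_p1 * (1 - spec.poly_p1),
            spec.poly_a2 ** 2 * spec.poly_p2 * (1 - spec.poly_p2),
            spec.poly_m * spec.poly_p3 * (1 - spec.poly_p3),
        )
    v = gh_variance(spec)
    return VarianceComponents(v, v, v)


def population_mean(spec: DistributionSpec) -> float:
    """Grand mean of one cell under the generating process."""
    if spec.family == "normal":
        return spec.mu
    if spec.family == "dichotomous":
        return 0.5 if spec.threshold == spec.mu else float("nan")
    if spec.family == "polytomous":
        return (spec.poly_a1 * spec.poly_p1 + spec.poly_a2 * spec.poly_p2
                + spec.poly_m * spec.poly_p3)
    return spec.mu + 3 * (gh_mean(spec) - spec.gh_mu) + 3 * spec.gh_mu


def study_specs(skew_betas=(0.0, -1.0, -2.0)) -> list[DistributionSpec]:
    """The six distribution conditions of the full study."""
    specs = [DistributionSpec.normal(), DistributionSpec.dichotomous(),
             DistributionSpec.polytomous()]
    specs.extend(DistributionSpec.skewed(beta=b) for b in skew_betas)
    return specs
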