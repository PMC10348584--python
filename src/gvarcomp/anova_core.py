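"""Balanced two-way random-effects ANOVA for the p x i design.

Mean squares, the expected-mean-squares solution for the three variance
components, the normal-theory standard error with ``df + 2`` denominators,
the population (``df`` denominator) sampling standard deviation, z-based
intervals, and a Henderson Method 1 variant for a matrix with one missing
cell.

Negative component estimates are retained (not truncated to zero) so that
replication means remain unbiased; pass ``truncate=True`` where clipping at
zero is wanted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .design import DesignSpec, VarianceComponents, as_matrix


@dataclass(frozen=True)
class MeanSquares:
    """Mean squares and degrees of freedom of the balanced decomposition."""

    ms_p: float
    ms_i: float
    ms_pi: float
    df_p: int
    df_i: int
    df_pi: int

    @property
    def design(self) -> DesignSpec:
        return DesignSpec(self.df_p + 1, self.df_i + 1)

    def as_arrays(self):
        return (np.array([self.ms_p, self.ms_i, self.ms_pi]),
                np.array([self.df_p, self.df_i, self.df_pi], dtype=float))


def _ms_arrays(x: np.ndarray):
    """Mean squares over the trailing two axes; supports stacked matrices."""
    n_p, n_i = x.shape[-2], x.shape[-1]
    grand = x.mean(axis=(-2, -1), keepdims=True)
    rowm = x.mean(axis=-1, keepdims=True)
    colm = x.mean(axis=-2, keepdims=True)
    ss_p = n_i * ((rowm - grand) ** 2).sum(axis=(-2, -1))
    ss_i = n_p * ((colm - grand) ** 2).sum(axis=(-2, -1))
    ss_pi = ((x - rowm - colm + grand) ** 2).sum(axis=(-2, -1))
    return ss_p / (n_p - 1), ss_i / (n_i - 1), ss_pi / ((n_p - 1) * (n_i - 1))


def mean_squares(matrix) -> MeanSquares:
    """Balanced decomposition of a complete score matrix."""
    x = as_matrix(matrix)
    n_p, n_i = x.shape
    ms_p, ms_i, ms_pi = _ms_arrays(x)
    return MeanSquares(float(ms_p), float(ms_i), float(ms_pi),
                       n_p - 1, n_i - 1, (n_p - 1) * (n_i - 1))


def estimate_vc(ms: MeanSquares, design: DesignSpec | None = None,
                truncate: bool = False) -> VarianceComponents:
    """Solve the expected-mean-squares equations.

    ``vc.pi = MS_pi``, ``vc.p = (MS_p - MS_pi)/n_i``,
    ``vc.i = (MS_i - MS_pi)/n_p``.
    """
    design = design or ms.design
    vc = VarianceComponents(
        (ms.ms_p - ms.ms_pi) / design.n_i,
        (ms.ms_i - ms.ms_pi) / design.n_p,
        ms.ms_pi,
    )
    if truncate:
        vc = VarianceComponents(*(max(v, 0.0) for v in vc))
    return vc


def estimate_vc_batch(x: np.ndarray) -> np.ndarray:
    """Component estimates for stacked matrices ``(..., n_p, n_i)``.

    Returns an array ``(..., 3)`` ordered (p, i, pi).  Used on the hot paths
    (bootstrap resamples, replication loops), hence computed from row and
    column sums in two passes over the data instead of via centred copies.
    """
    n_p, n_i = x.shape[-2], x.shape[-1]
    r = x.sum(axis=-1)
    c = x.sum(axis=-2)
    t = r.sum(axis=-1)
    q = (x * x).sum(axis=(-2, -1))
    corr = t * t / (n_p * n_i)
    ss_p = (r * r).sum(axis=-1) / n_i - corr
    ss_i = (c * c).sum(axis=-1) / n_p - corr
    ss_pi = q - corr - ss_p - ss_i
    ms_p = ss_p / (n_p - 1)
    ms_i = ss_i / (n_i - 1)
    ms_pi = ss_pi / ((n_p - 1) * (n_i - 1))
    return np.stack([(ms_p - ms_pi) / n_i, (ms_i - ms_pi) / n_p, ms_pi], axis=-1)


def expected_mean_squares(vc: VarianceComponents, design: DesignSpec) -> np.ndarray:
    """Model-implied E[MS] = (vc.pi + n_i vc.p, vc.pi + n_p vc.i, vc.pi)."""
    return np.array([
        vc.vc_pi + design.n_i * vc.vc_p,
        vc.vc_pi + design.n_p * vc.vc_i,
        vc.vc_pi,
    ])


def _se_from_ms(ms: np.ndarray, denom: np.ndarray, design: DesignSpec) -> np.ndarray:
    # f(beta|alpha) coefficients of each MS in each component estimator
    f = np.array([
        [1.0 / design.n_i, 0.0, -1.0 / design.n_i],
        [0.0, 1.0 / design.n_p, -1.0 / design.n_p],
        [0.0, 0.0, 1.0],
    ])
    var = (2.0 * (f * ms[None, :]) ** 2 / denom[None, :]).sum(axis=1)
    return np.sqrt(var)


def traditional_se(ms: MeanSquares, design: DesignSpec | None = None) -> np.ndarray:
    """Normal-theory SE estimator with ``df + 2`` denominators.

    ``SE(alpha) = sqrt( sum_beta 2 [f(beta|alpha) MS(beta)]^2 / (df(beta)+2) )``;
    its square is unbiased for the sampling variance of the component
    estimate under normality.
    """
    design = design or ms.design
    msa, dfa = ms.as_arrays()
    return _se_from_ms(msa, dfa + 2.0, design)


def normal_theory_se(vc: VarianceComponents, design: DesignSpec) -> np.ndarray:
    """True sampling SD of the ANOVA estimates under normal score effects.

    Same structure as :func:`traditional_se` but with expected mean squares
    and plain ``df`` denominators; this generates the reference ("Parameter")
    standard deviations, e.g. (1.0287, 5.3988, 2.0869) for the 100 x 20
    design with components (4, 16, 64).
    """
    ems = expected_mean_squares(vc, design)
    df = np.array([design.n_p - 1, design.n_i - 1,
                   (design.n_p - 1) * (design.n_i - 1)], dtype=float)
    return _se_from_ms(ems, df, design)


def population_se(spec, design: DesignSpec, n_reps: int = 2000, seed: int = 20_000_101) -> np.ndarray:
    """True sampling SD of the ANOVA component estimates for a family.

    Normal family: closed form (:func:`normal_theory_se`).  Other families:
    Monte-Carlo oracle — the empirical SD of the ANOVA estimates over
    ``n_reps`` fresh replications (default 2000, fixed seed), since no
    distribution-free closed form exists.
    """
    from . import synthetic_data as sd  # local import to avoid a cycle

    if isinstance(spec, VarianceComponents):
        return normal_theory_se(spec, design)
    if spec.family == "normal":
        return normal_theory_se(sd.population_vc(spec), design)
    rng = np.random.default_rng(seed)
    est = np.empty((n_reps, 3))
    for r in range(n_reps):
        est[r] = estimate_vc_batch(sd.generate(design, spec, rng))
    return est.std(axis=0, ddof=1)


def traditional_ci(vc, se, level: float = 0.80) -> np.ndarray:
    """Normal-theory interval ``vc +/- z * SE`` (z = 1.2816 at 80%).

    Bounds are not truncated at zero.  Accepts scalars or length-3 arrays;
    returns a ``(..., 2)`` array.
    """
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    z = stats.norm.ppf(0.5 + level / 2.0)
    vc = np.atleast_1d(np.asarray(vc, dtype=float))
    se = np.atleast_1d(np.asarray(se, dtype=float))
    return np.stack([vc - z * se, vc + z * se], axis=-1)


def traditional_estimate(matrix, design: DesignSpec | None = None, level: float = 0.80):
    """Convenience wrapper: mean squares -> (vc, se, ci) in one call."""
    from .design import MethodResult

    x = as_matrix(matrix)
    design = design or DesignSpec(*x.shape)
    ms = mean_squares(x)
    vc = estimate_vc(ms, design)
    se = traditional_se(ms, design)
    ci = traditional_ci(vc.as_array(), se, level)
    return MethodResult("traditional", vc.as_array(), se, ci, level)


# ---------------------------------------------------------------------------
# single-missing-cell variant (Henderson Method 1)
# ---------------------------------------------------------------------------

def estimate_vc_missing_cell(matrix, missing: tuple[int, int] | None = None) -> VarianceComponents:
    """Analogous-ANOVA estimates with one cell deleted.

    Henderson Method 1: the quadratic forms ``T_p = sum_p y_p.^2 / r_p``,
    ``T_i``, ``T_mu = y..^2 / N`` and ``T_0 = sum y^2`` have expectations
    linear in the three components; the 3 x 3 system is solved exactly.
    With ``missing=None`` the solution coincides with the balanced ANOVA
    estimates.
    """
    x = as_matrix(matrix)
    n_p, n_i = x.shape
    mask = np.ones_like(x, dtype=bool)
    if missing is not None:
        p0, i0 = missing
        if not (0 <= p0 < n_p and 0 <= i0 < n_i):
            raise ValueError("missing cell index out of range")
        mask[p0, i0] = False

    r = mask.sum(axis=1).astype(float)   # items observed per person
    c = mask.sum(axis=0).astype(float)   # persons observed per item
    if np.any(r < 1) or np.any(c < 1):
        raise ValueError("every row and column must retain at least one cell")
    n_obs = float(mask.sum())

    xm = np.where(mask, x, 0.0)
    row_sum = xm.sum(axis=1)
    col_sum = xm.sum(axis=0)
    total = xm.sum()

    t_p = float((row_sum ** 2 / r).sum())
    t_i = float((col_sum ** 2 / c).sum())
    t_mu = total ** 2 / n_obs
    t_0 = float((xm ** 2).sum())

    sr2, sc2 = float((r ** 2).sum()), float((c ** 2).sum())
    a, b = float(n_p), float(n_i)
    coeffs = np.array([
        [n_obs - sr2 / n_obs, a - sc2 / n_obs, a - 1.0],
        [b - sr2 / n_obs, n_obs - sc2 / n_obs, b - 1.0],
        [n_obs - sr2 / n_obs, n_obs - sc2 / n_obs, n_obs - 1.0],
    ])
    rhs = np.array([t_p - t_mu, t_i - t_mu, t_0 - t_mu])
    sol = np.linalg.solve(coeffs, rhs)
    return VarianceComponents(*sol)
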