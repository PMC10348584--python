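"""The six bootstrap resampling strategies for the crossed p x i design.

A strategy name lists which of persons (p), items (i) and residuals (r) are
resampled with replacement, everything else held fixed:

========  =============================================================
boot-p    whole person rows (items and residuals travel with the row)
boot-i    whole item columns
boot-pi   rows and columns independently (crossed sub-matrix)
boot-pr   person effects and pooled residuals, item effects fixed
boot-ir   item effects and pooled residuals, person effects fixed
boot-pir  person effects, item effects and pooled residuals
========  =============================================================

The r-strategies work on the additive decomposition
``x = m + a_p + b_i + e_pi`` (:func:`effect_decompose`); un-flagged effects
are held at their estimated values and residuals are drawn iid from the
pooled n_p x n_i residual set.

Plug-in ANOVA estimates computed on a resample are biased for the original
sample's components because resampling shrinks/mixes the mean squares.  The
exact resampling expectations E*[MS*] are linear in (MS_p, MS_i, MS_pi)
with strategy-specific coefficients built from (n_p-1)/n_p and
(n_i-1)/n_i; the correction layer inverts that linear map per resample
(for boot-p it reduces to the familiar ``n_p/(n_p-1)`` scaling and
``vc.i - vc.pi/(n_p-1)`` adjustments).  Correction is on by default.

Bootstrap SE is the B-1 standard deviation of the (corrected) per-resample
estimates; the 80% interval uses their 10th and 90th percentiles (linear
interpolation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .design import MethodResult, as_matrix

STRATEGIES = ("boot-p", "boot-i", "boot-pi", "boot-pr", "boot-ir", "boot-pir")

#: which of (persons, items, residuals) each strategy resamples
RESAMPLED = {
    "boot-p": ("p",),
    "boot-i": ("i",),
    "boot-pi": ("p", "i"),
    "boot-pr": ("p", "r"),
    "boot-ir": ("i", "r"),
    "boot-pir": ("p", "i", "r"),
}


@dataclass(frozen=True)
class BootstrapConfig:
    """Settings of one bootstrap run.

    ``B`` is the number of resamples (>= 2 for an SE; >= 1000 recommended
    for percentile intervals), ``ci_level`` the nominal interval coverage,
    ``bias_correction`` toggles the per-resample correction layer.
    """

    B: int = 1000
    seed: int | None = None
    ci_level: float = 0.80
    bias_correction: bool = True

    def __post_init__(self) -> None:
        if self.B < 2:
            raise ValueError("bootstrap SE needs B >= 2")
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must lie in (0, 1)")


def effect_decompose(matrix):
    """Additive decomposition ``x = m + a_p + b_i + e_pi``.

    ``a`` and ``b`` sum to zero and the residual matrix has zero row and
    column sums; ``m + a[:, None] + b[None, :] + e`` reproduces the input
    exactly.
    """
    x = as_matrix(matrix)
    m = x.mean()
    a = x.mean(axis=1) - m
    b = x.mean(axis=0) - m
    e = x - m - a[:, None] - b[None, :]
    return float(m), a, b, e


def _resample_batch(x: np.ndarray, strategy: str, B: int,
                    rng: np.random.Generator) -> np.ndarray:
    """Stack of ``B`` resampled matrices, shape (B, n_p, n_i).

    Index streams are drawn in the fixed order persons, items, residuals
    from the supplied generator, so results are reproducible given a seed.
    """
    if strategy not in RESAMPLED:
        raise ValueError(f"unknown bootstrap strategy {strategy!r}")
    n_p, n_i = x.shape
    flags = RESAMPLED[strategy]

    if "r" not in flags:
        if strategy == "boot-p":
            idx_p = rng.integers(n_p, size=(B, n_p))
            return x[idx_p]
        if strategy == "boot-i":
            idx_i = rng.integers(n_i, size=(B, n_i))
            return np.swapaxes(x.T[idx_i], 1, 2)
        idx_p = rng.integers(n_p, size=(B, n_p))
        idx_i = rng.integers(n_i, size=(B, n_i))
        return x[idx_p[:, :, None], idx_i[:, None, :]]

    m, a, b, e = effect_decompose(x)
    if "p" in flags:
        a = a[rng.integers(n_p, size=(B, n_p))]          # (B, n_p)
    else:
        a = np.broadcast_to(a, (B, n_p))
    if "i" in flags:
        b = b[rng.integers(n_i, size=(B, n_i))]          # (B, n_i)
    else:
        b = np.broadcast_to(b, (B, n_i))
    e_star = e.ravel()[rng.integers(n_p * n_i, size=(B, n_p, n_i))]
    return m + a[:, :, None] + b[:, None, :] + e_star


def resample(matrix, strategy: str, seed=None) -> np.ndarray:
    """One resampled score matrix under the given strategy."""
    x = as_matrix(matrix)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return _resample_batch(x, strategy, 1, rng)[0]


def correction_matrix(strategy: str, n_p: int, n_i: int) -> np.ndarray:
    """3 x 3 map applied to per-resample component estimates.

    Built by inverting the exact resampling expectation
    ``E*[MS*] = T_ms MS`` in mean-square space and conjugating with the
    EMS-solve map, so that corrected estimates are resampling-unbiased for
    the original sample's components.
    """
    if strategy not in RESAMPLED:
        raise ValueError(f"unknown bootstrap strategy {strategy!r}")
    cp = (n_p - 1) / n_p
    ci = (n_i - 1) / n_i
    ce = cp * ci
    t_ms = {
        "boot-p": [[cp, 0, 0], [0, 1, cp], [0, 0, cp]],
        "boot-i": [[1, 0, ci], [0, ci, 0], [0, 0, ci]],
        "boot-pi": [[cp, 0, ce], [0, ci, ce], [0, 0, ce]],
        "boot-pr": [[cp, 0, ce], [0, 1, ce], [0, 0, ce]],
        "boot-ir": [[1, 0, ce], [0, ci, ce], [0, 0, ce]],
        "boot-pir": [[cp, 0, ce], [0, ci, ce], [0, 0, ce]],
    }[strategy]
    # vc = G ms  with the EMS-solve coefficients
    g = np.array([[1 / n_i, 0, -1 / n_i], [0, 1 / n_p, -1 / n_p], [0, 0, 1.0]])
    t_vc = g @ np.asarray(t_ms, dtype=float) @ np.linalg.inv(g)
    return np.linalg.inv(t_vc)


def bootstrap_estimate(matrix, strategy: str,
                       config: BootstrapConfig | None = None,
                       return_draws: bool = False) -> MethodResult:
    """Bootstrap mean, SE and percentile interval for all components."""
    from .anova_core import estimate_vc_batch

    config = config or BootstrapConfig()
    x = as_matrix(matrix)
    rng = np.random.default_rng(config.seed)
    draws = estimate_vc_batch(_resample_batch(x, strategy, config.B, rng))
    if config.bias_correction:
        draws = draws @ correction_matrix(strategy, *x.shape).T

    est = draws.mean(axis=0)
    se = draws.std(axis=0, ddof=1)
    lo = (1.0 - config.ci_level) / 2.0
    ci = np.quantile(draws, [lo, 1.0 - lo], axis=0).T
    extra = {"B": config.B, "strategy": strategy,
             "bias_correction": config.bias_correction}
    if return_draws:
        extra["draws"] = draws
    return MethodResult(f"bootstrap[{strategy}]", est, se, ci,
                        config.ci_level, extra)
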