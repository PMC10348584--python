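"""Shared types for the crossed p x i generalizability design.

A score matrix is an ``n_p x n_i`` :class:`numpy.ndarray` with persons on
rows and items on columns, one observation per cell (0-based indices
throughout).  The three random effects of the design are the person effect
(``p``), the item effect (``i``) and the person-by-item interaction
confounded with residual error (``pi``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

#: canonical component order used by every estimator in this package
COMPONENTS = ("p", "i", "pi")


@dataclass(frozen=True)
class DesignSpec:
    """Size of the crossed design: ``n_p`` persons by ``n_i`` items."""

    n_p: int = 100
    n_i: int = 20

    def __post_init__(self) -> None:
        if self.n_p < 2 or self.n_i < 2:
            raise ValueError("a crossed p x i design needs n_p >= 2 and n_i >= 2")

    @property
    def n_cells(self) -> int:
        return self.n_p * self.n_i


class VarianceComponents(NamedTuple):
    """The triple (vc.p, vc.i, vc.pi) in squared score units.

    Population values are non-negative; ANOVA *estimates* may be negative
    and are retained as such (see :mod:`gvarcomp.anova_core`).
    """

    vc_p: float
    vc_i: float
    vc_pi: float

    def as_array(self) -> np.ndarray:
        return np.asarray(self, dtype=float)


@dataclass
class IntervalEstimate:
    """A two-sided interval with nominal coverage ``level``."""

    lower: float
    upper: float
    level: float = 0.80

    def __post_init__(self) -> None:
        if not self.lower <= self.upper:
            raise ValueError("interval requires lower <= upper")

    def contains(self, value: float) -> bool:
        return self.lower <= value <= self.upper


@dataclass
class MethodResult:
    """Point estimates, standard errors and intervals for all components.

    ``estimate``, ``se`` are length-3 arrays in the order p, i, pi;
    ``ci`` is a (3, 2) array of interval bounds; ``extra`` carries
    method-specific diagnostics (e.g. convergence statistics).
    """

    method: str
    estimate: np.ndarray
    se: np.ndarray
    ci: np.ndarray
    level: float = 0.80
    extra: dict = field(default_factory=dict)

    def intervals(self) -> list[IntervalEstimate]:
        return [IntervalEstimate(lo, hi, self.level) for lo, hi in self.ci]

    def as_dict(self) -> dict:
        out: dict = {"method": self.method, "level": self.level}
        for k, name in enumerate(COMPONENTS):
            out[f"vc_{name}"] = float(self.estimate[k])
            out[f"se_{name}"] = float(self.se[k])
            out[f"ci_{name}"] = [float(self.ci[k, 0]), float(self.ci[k, 1])]
        out.update(self.extra)
        return out


def as_matrix(values) -> np.ndarray:
    """Validate a score matrix: 2-D, finite, at least 2 x 2."""
    x = np.asarray(values, dtype=float)
    if x.ndim != 2:
        raise ValueError("score matrix must be 2-dimensional (persons x items)")
    if x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("score matrix needs at least 2 persons and 2 items")
    if not np.all(np.isfinite(x)):
        raise ValueError("score matrix entries must be finite")
    return x
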