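"""Relative-percentage-bias evaluation and bootstrap strategy selection.

The accuracy criterion for every estimated quantity is the relative
percentage bias ``RPB = 100 (estimate - parameter) / parameter``; an
estimate is called accurate when ``|RPB| < 25`` (the boundary counts as
inaccurate).  Interval quality is judged by the RPB of the empirical
coverage against the nominal level 0.80.

:func:`build_strategy_table` reproduces the divide-and-conquer selection
for the six bootstrap strategies: per (quantity, component, distribution)
the admissible set is every strategy with ``|RPB| < 25``; a strategy is
optimal for a column when it is admissible in *all* distributions
("spanning"), ties broken by the smallest summed ``|RPB|``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

RPB_THRESHOLD = 25.0
#: quantities evaluated per component
QUANTITIES = ("vc", "se", "ci")


def rpb(estimate, parameter):
    """``100 (estimate - parameter) / parameter``; NaN when parameter == 0."""
    estimate = np.asarray(estimate, dtype=float)
    parameter = np.asarray(parameter, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = 100.0 * (estimate - parameter) / parameter
    out = np.where(parameter == 0, np.nan, out)
    return float(out) if out.ndim == 0 else out


def classify(rpb_value) -> bool:
    """True (accurate) iff ``|RPB| < 25``; NaN and the boundary are inaccurate."""
    v = float(rpb_value)
    return bool(np.isfinite(v) and abs(v) < RPB_THRESHOLD)


def coverage(intervals, truth: float) -> float:
    """Fraction of intervals with ``lower <= truth <= upper``.

    ``intervals`` is a sequence of objects with lower/upper attributes or an
    (n, 2) array.
    """
    arr = np.asarray([
        (iv.lower, iv.upper) if hasattr(iv, "lower") else tuple(iv)
        for iv in intervals
    ], dtype=float)
    if arr.size == 0:
        raise ValueError("coverage needs at least one interval")
    return float(np.mean((arr[:, 0] <= truth) & (truth <= arr[:, 1])))


def coverage_rpb(observed_coverage: float, nominal: float = 0.80) -> float:
    """RPB of empirical interval coverage against the nominal level."""
    return rpb(observed_coverage, nominal)


@dataclass(frozen=True)
class EvaluationRecord:
    """One evaluated cell of the study.

    ``quantity`` is 'vc' (point estimate), 'se' (mean estimated standard
    error) or 'ci' (empirical coverage); ``parameter`` the oracle truth
    (nominal level for 'ci'); ``strategy`` is set for bootstrap records.
    """

    distribution: str
    method: str
    component: str
    quantity: str
    estimate: float
    parameter: float
    strategy: str | None = None

    @property
    def rpb(self) -> float:
        return rpb(self.estimate, self.parameter)

    @property
    def accurate(self) -> bool:
        return classify(self.rpb)


@dataclass
class StrategyTable:
    """Admissible and optimal bootstrap strategies per (quantity, component).

    ``admissible[(quantity, component)][distribution]`` is the list of
    strategies with ``|RPB| < 25`` ordered by ``|RPB|``;
    ``optimal[(quantity, component)]`` the spanning strategy with the
    smallest summed ``|RPB|`` (None when no strategy spans).
    """

    admissible: dict
    optimal: dict


def build_strategy_table(records) -> StrategyTable:
    """Divide-and-conquer selection from bootstrap evaluation records."""
    boot = [r for r in records if r.strategy is not None and r.quantity in ("se", "ci")]
    if not boot:
        raise ValueError("no bootstrap records supplied")

    admissible: dict = {}
    sums: dict = {}
    distributions: dict = {}
    for r in boot:
        key = (r.quantity, r.component)
        distributions.setdefault(key, set()).add(r.distribution)
        cell = admissible.setdefault(key, {}).setdefault(r.distribution, [])
        if r.accurate:
            cell.append((abs(r.rpb), r.strategy))
        s = sums.setdefault(key, {}).setdefault(r.strategy, [0.0, set()])
        s[0] += abs(r.rpb)
        s[1].add(r.distribution)

    adm_out: dict = {}
    opt_out: dict = {}
    for key, per_dist in admissible.items():
        adm_out[key] = {
            dist: [name for _, name in sorted(cell)]
            for dist, cell in sorted(per_dist.items())
        }
        all_dists = distributions[key]
        spanning = [
            name for name, (total, _) in sums[key].items()
            if all(name in adm_out[key].get(d, []) for d in all_dists)
        ]
        if spanning:
            opt_out[key] = min(spanning, key=lambda nm: sums[key][nm][0])
        else:
            opt_out[key] = None
    return StrategyTable(adm_out, opt_out)


def accuracy_grid(records) -> dict:
    """Qualitative '+'/'-' grid per (distribution, method, quantity).

    A method's row is '+' when every component of the quantity is accurate;
    for the bootstrap the divide-and-conquer reading applies: a component
    counts as accurate when at least one strategy estimates it accurately.
    """
    cells: dict = {}
    for r in records:
        method = "bootstrap" if r.strategy is not None else r.method
        key = (r.distribution, method, r.quantity, r.component)
        cells.setdefault(key, []).append(r.accurate)

    grid: dict = {}
    rows: dict = {}
    for (dist, method, quantity, component), oks in cells.items():
        ok = any(oks) if method == "bootstrap" else all(oks)
        rows.setdefault((dist, method, quantity), []).append(ok)
    for key, oks in rows.items():
        grid[key] = "+" if all(oks) else "-"
    return grid
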