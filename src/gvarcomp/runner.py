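"""Orchestration of the Monte-Carlo comparison study.

For every distribution condition the runner simulates ``replications``
score matrices, applies the requested estimators (traditional ANOVA,
jackknife, the six bootstrap strategies, Gibbs/MCMC) to each, and
aggregates per (distribution x method x component): the mean point
estimate, the mean estimated standard error and the empirical coverage of
the nominal-80% intervals against the oracle truth.  Evaluation records
(relative percentage bias against the oracle parameters) and the derived
accuracy grid / bootstrap strategy table are produced from the aggregate.

Determinism: every replication's data stream is seeded by
``SeedSequence([master, dist_index, rep, purpose])``, so results are
bit-for-bit reproducible for a given master seed regardless of the order
in which cells are computed.  The MCMC method, being the only expensive
estimator, runs on the first ``mcmc_replications`` replications only
(default 200), with the same per-replication data as the other methods.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import anova_core, bootstrap, jackknife, mcmc, synthetic_data
from .design import COMPONENTS, DesignSpec
from .evaluation import EvaluationRecord, accuracy_grid, build_strategy_table

_PURPOSE_DATA, _PURPOSE_BOOT, _PURPOSE_MCMC = 0, 1000, 2000


@dataclass(frozen=True)
class StudyConfig:
    """Full study settings.

    ``scale`` shrinks ``replications``, ``bootstrap_B`` and
    ``mcmc_replications`` proportionally for smoke/scaled runs (tolerances
    must be widened accordingly by the caller).
    """

    design: DesignSpec = DesignSpec()
    distributions: tuple = ()
    replications: int = 1000
    bootstrap_B: int = 1000
    bias_correction: bool = True
    strategies: tuple = bootstrap.STRATEGIES
    methods: tuple = ("traditional", "jackknife", "bootstrap", "mcmc")
    mcmc_replications: int = 200
    chain: mcmc.ChainConfig = mcmc.ChainConfig()
    center_priors_on_truth: bool = True
    level: float = 0.80
    seed: int = 1234
    oracle_replications: int = 2000
    scale: float = 1.0
    outdir: str | None = None

    def __post_init__(self) -> None:
        if self.replications < 1 or not self.methods:
            raise ValueError("need replications >= 1 and a non-empty method list")
        if not self.distributions:
            object.__setattr__(self, "distributions",
                               tuple(synthetic_data.study_specs()))

    @property
    def eff_replications(self) -> int:
        return max(1, round(self.replications * self.scale))

    @property
    def eff_bootstrap_B(self) -> int:
        return max(2, round(self.bootstrap_B * self.scale))

    @property
    def eff_mcmc_replications(self) -> int:
        return min(self.eff_replications,
                   max(1, round(self.mcmc_replications * self.scale)))


_REP_COLUMNS = (["rep"]
                + [f"vc_{c}" for c in COMPONENTS]
                + [f"se_{c}" for c in COMPONENTS]
                + [f"{b}_{c}" for c in COMPONENTS for b in ("lo", "hi")])


def _row(rep: int, res) -> list:
    vals = [rep]
    vals += [float(v) for v in res.estimate]
    vals += [float(v) for v in res.se]
    for k in range(3):
        vals += [float(res.ci[k, 0]), float(res.ci[k, 1])]
    return vals


@dataclass
class StudyResult:
    """Result store: per-cell replication tables plus oracle parameters."""

    config: StudyConfig
    parameters: dict          # dist label -> {"vc": (3,), "se": (3,)}
    cells: dict               # (dist label, method label) -> DataFrame

    def summarize(self) -> pd.DataFrame:
        """Per (distribution, method, component) aggregate table."""
        rows = []
        for (dist, method), df in self.cells.items():
            par = self.parameters[dist]
            for k, c in enumerate(COMPONENTS):
                truth = par["vc"][k]
                cov = float(np.mean((df[f"lo_{c}"] <= truth)
                                    & (truth <= df[f"hi_{c}"])))
                rows.append({
                    "distribution": dist, "method": method, "component": c,
                    "mean_vc": float(df[f"vc_{c}"].mean()),
                    "mean_se": float(df[f"se_{c}"].mean()),
                    "coverage": cov,
                    "param_vc": float(truth),
                    "param_se": float(par["se"][k]),
                    "n_reps": int(len(df)),
                })
        return pd.DataFrame(rows)

    def records(self) -> list[EvaluationRecord]:
        """RPB evaluation records for every aggregated cell."""
        out = []
        for r in self.summarize().itertuples():
            strategy = r.method if r.method in bootstrap.STRATEGIES else None
            method = "bootstrap" if strategy else r.method
            out.append(EvaluationRecord(r.distribution, method, r.component,
                                        "vc", r.mean_vc, r.param_vc, strategy))
            out.append(EvaluationRecord(r.distribution, method, r.component,
                                        "se", r.mean_se, r.param_se, strategy))
            out.append(EvaluationRecord(r.distribution, method, r.component,
                                        "ci", r.coverage, self.config.level,
                                        strategy))
        return out


def _cell_path(outdir: str, dist: str, method: str) -> Path:
    safe = dist.replace("(", "_").replace(")", "").replace("=", "")
    return Path(outdir) / "cells" / f"{safe}__{method}.csv"


def _method_labels(config: StudyConfig) -> list[str]:
    labels = []
    for m in config.methods:
        if m == "bootstrap":
            labels.extend(config.strategies)
        else:
            labels.append(m)
    return labels


def run_study(config: StudyConfig) -> StudyResult:
    """Execute the full study described by ``config``.

    Cells already present and complete under ``outdir/cells`` are loaded
    instead of recomputed; completed cells are written as soon as they
    finish, so an interrupted run resumes where it stopped.
    """
    design = config.design
    r_total = config.eff_replications
    boot_cfg_base = dict(B=config.eff_bootstrap_B, ci_level=config.level,
                         bias_correction=config.bias_correction)

    parameters: dict = {}
    cells: dict = {}
    for d_idx, spec in enumerate(config.distributions):
        label = spec.label
        truth = synthetic_data.population_vc(spec).as_array()
        parameters[label] = {
            "vc": truth,
            "se": anova_core.population_se(spec, design,
                                           n_reps=config.oracle_replications),
        }
        labels = _method_labels(config)
        pending = {}
        for ml in labels:
            want = (config.eff_mcmc_replications if ml == "mcmc" else r_total)
            if config.outdir:
                path = _cell_path(config.outdir, label, ml)
                if path.exists():
                    df = pd.read_csv(path)
                    if len(df) == want:
                        cells[(label, ml)] = df
                        continue
            pending[ml] = ([], want)
        if not pending:
            continue

        priors = (mcmc.PriorSpec.centered_on(truth)
                  if config.center_priors_on_truth else mcmc.PriorSpec())
        for rep in range(r_total):
            x = synthetic_data.generate(
                design, spec,
                np.random.SeedSequence([config.seed, d_idx, rep, _PURPOSE_DATA]))
            if "traditional" in pending and rep < pending["traditional"][1]:
                pending["traditional"][0].append(
                    _row(rep, anova_core.traditional_estimate(x, design, config.level)))
            if "jackknife" in pending and rep < pending["jackknife"][1]:
                pending["jackknife"][0].append(
                    _row(rep, jackknife.jackknife_estimate(x, config.level)))
            for s_idx, strat in enumerate(config.strategies):
                if strat in pending and rep < pending[strat][1]:
                    cfg = bootstrap.BootstrapConfig(
                        seed=np.random.SeedSequence(
                            [config.seed, d_idx, rep, _PURPOSE_BOOT + s_idx]).generate_state(1)[0],
                        **boot_cfg_base)
                    pending[strat][0].append(
                        _row(rep, bootstrap.bootstrap_estimate(x, strat, cfg)))
            if "mcmc" in pending and rep < pending["mcmc"][1]:
                summ = mcmc.gibbs_sample(
                    x, priors, config.chain,
                    seed=np.random.SeedSequence([config.seed, d_idx, rep, _PURPOSE_MCMC]),
                    level=config.level)
                pending["mcmc"][0].append(_row(rep, summ.as_result()))

        for ml, (rows, _want) in pending.items():
            df = pd.DataFrame(rows, columns=_REP_COLUMNS)
            cells[(label, ml)] = df
            if config.outdir:
                path = _cell_path(config.outdir, label, ml)
                path.parent.mkdir(parents=True, exist_ok=True)
                df.to_csv(path, index=False)

    return StudyResult(config, parameters, cells)


# ---------------------------------------------------------------------------
# table emission
# ---------------------------------------------------------------------------

def emit_tables(result: StudyResult, outdir: str) -> dict:
    """Write the study tables; returns {name: path}.

    ``estimates.csv`` mirrors the estimates-and-variability layout
    (parameter row first per distribution), ``rpb.csv`` the RPB conversion,
    ``grid.csv`` the qualitative '+'/'-' comparison, ``strategy.csv`` /
    ``strategy_rules.json`` the divide-and-conquer table.  An empty store
    produces header-only files.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    summary = result.summarize()
    est_rows = []
    seen = []
    for dist in summary["distribution"].unique() if len(summary) else []:
        par = result.parameters[dist]
        row = {"distribution": dist, "method": "Parameter"}
        for k, c in enumerate(COMPONENTS):
            row[f"vc_{c}"] = par["vc"][k]
            row[f"se_{c}"] = par["se"][k]
            row[f"ci_{c}"] = result.config.level
        est_rows.append(row)
        sub = summary[summary["distribution"] == dist]
        for method in sub["method"].unique():
            mrow = {"distribution": dist, "method": method}
            for c in COMPONENTS:
                cell = sub[(sub["method"] == method) & (sub["component"] == c)].iloc[0]
                mrow[f"vc_{c}"] = cell["mean_vc"]
                mrow[f"se_{c}"] = cell["mean_se"]
                mrow[f"ci_{c}"] = cell["coverage"]
            est_rows.append(mrow)
    est_cols = (["distribution", "method"]
                + [f"{q}_{c}" for c in COMPONENTS for q in ("vc", "se", "ci")])
    paths["estimates"] = out / "estimates.csv"
    pd.DataFrame(est_rows, columns=est_cols).to_csv(paths["estimates"], index=False)

    records = result.records() if result.cells else []
    rpb_rows = [{
        "distribution": r.distribution,
        "method": r.strategy or r.method,
        "component": r.component, "quantity": r.quantity,
        "rpb": round(r.rpb, 4) if np.isfinite(r.rpb) else np.nan,
        "accurate": r.accurate,
    } for r in records]
    paths["rpb"] = out / "rpb.csv"
    pd.DataFrame(rpb_rows, columns=["distribution", "method", "component",
                                    "quantity", "rpb", "accurate"]
                 ).to_csv(paths["rpb"], index=False)

    grid = accuracy_grid(records) if records else {}
    grid_rows = [{"distribution": d, "method": m, "quantity": q, "grade": g}
                 for (d, m, q), g in sorted(grid.items())]
    paths["grid"] = out / "grid.csv"
    pd.DataFrame(grid_rows, columns=["distribution", "method", "quantity",
                                     "grade"]).to_csv(paths["grid"], index=False)

    strat_rows = []
    rules: dict = {}
    if any(r.strategy for r in records):
        table = build_strategy_table(records)
        for (quantity, component), per_dist in table.admissible.items():
            for dist, adm in per_dist.items():
                strat_rows.append({
                    "quantity": quantity, "component": component,
                    "distribution": dist, "admissible": ", ".join(adm),
                })
            opt = table.optimal[(quantity, component)]
            rules.setdefault(quantity, {})[component] = opt
    paths["strategy"] = out / "strategy.csv"
    pd.DataFrame(strat_rows, columns=["quantity", "component", "distribution",
                                      "admissible"]).to_csv(paths["strategy"],
                                                            index=False)
    paths["rules"] = out / "strategy_rules.json"
    paths["rules"].write_text(json.dumps(rules, indent=2))
    return paths
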