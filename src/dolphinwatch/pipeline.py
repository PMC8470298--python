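"""End-to-end pipeline: records -> Markov comparison -> avoidance models.

One call runs the full disturbance analysis on a scan table (read from CSV
or freshly simulated), writes every result table as CSV plus a single
machine-readable JSON summary, and echoes the resolved configuration.  The
JSON summary is the single source of truth; the CSVs are derived from it.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
import shutil
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import avoidance, markov, records, synth
from .records import OBSERVED_STATES, Condition

logger = logging.getLogger(__name__)

#: Minimum data for the avoidance stage to run.
MIN_AVOIDANCE_OBS = 10
MIN_AVOIDANCE_GROUPS = 2


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run.

    Either ``input_csv`` (a scan table) or ``synth_config`` must be given.
    Every analytical toggle has a recorded default and the resolved config is
    serialised into the output directory.
    """

    outdir: str | Path
    input_csv: str | Path | None = None
    synth_config: synth.SyntheticConfig | None = None
    seed: int = 0
    unit_minutes: float = records.SCAN_INTERVAL_MIN
    pi_source: str = "budget"  # "budget" or "stationary"
    budget_source: str = "transitions"  # "transitions" or "scans"
    state_order: tuple[str, ...] = OBSERVED_STATES
    fit_avoidance: bool = True
    candidate_terms: tuple[str, ...] = avoidance.TERM_ORDER
    n_residual_sim: int = 1000
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.input_csv is None and self.synth_config is None:
            raise ValueError("either input_csv or synth_config is required")
        if self.pi_source not in ("budget", "stationary"):
            raise ValueError("pi_source must be 'budget' or 'stationary'")
        if self.budget_source not in ("transitions", "scans"):
            raise ValueError("budget_source must be 'transitions' or 'scans'")

    def to_dict(self) -> dict:
        d = {k: v for k, v in dataclasses.asdict(self).items() if k != "synth_config"}
        d["outdir"] = str(self.outdir)
        d["input_csv"] = None if self.input_csv is None else str(self.input_csv)
        d["synth_config"] = (None if self.synth_config is None
                             else self.synth_config.to_dict())
        d["config_version"] = 1
        return d


def _jsonable(x):
    if isinstance(x, (np.floating, np.integer)):
        x = x.item()
    if isinstance(x, float) and not math.isfinite(x):
        return None if math.isnan(x) else ("inf" if x > 0 else "-inf")
    if isinstance(x, np.ndarray):
        return [_jsonable(v) for v in x.tolist()]
    if isinstance(x, dict):
        return {str(k): _jsonable(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_jsonable(v) for v in x]
    return x


def _chi2_dict(r: markov.ChiSquareResult) -> dict:
    return {"statistic": r.statistic, "df": r.df, "pvalue": r.pvalue,
            "cells_used": r.cells_used, "flags": list(r.flags)}


def _markov_stage(pool, follows, cfg: RunConfig, summary: dict) -> None:
    order = cfg.state_order
    counts = {c: markov.build_counts(pool.samples, c, order)
              for c in (Condition.CONTROL, Condition.IMPACT)}
    mats = {c: markov.transition_probabilities(k) for c, k in counts.items()}
    summary["markov"] = {"state_order": list(order)}
    for c in (Condition.CONTROL, Condition.IMPACT):
        summary["markov"][c.value] = {
            "counts": counts[c].counts.tolist(),
            "probabilities": mats[c].probabilities.tolist(),
            "row_totals": counts[c].row_totals.tolist(),
            "defined_rows": mats[c].defined_rows.tolist(),
        }

    if counts[Condition.CONTROL].total == 0 or counts[Condition.IMPACT].total == 0:
        missing = [c.value for c in (Condition.CONTROL, Condition.IMPACT)
                   if counts[c].total == 0]
        notice = f"insufficient {' and '.join(missing)} data: chain comparison skipped"
        summary["notices"].append(notice)
        logger.warning(notice)
        return

    glob = markov.compare_chains_global(counts[Condition.CONTROL],
                                        counts[Condition.IMPACT])
    cells = {}
    for i in order:
        for j in order:
            row_tot = (counts[Condition.CONTROL].counts[counts[Condition.CONTROL].index(i)].sum()
                       + counts[Condition.IMPACT].counts[counts[Condition.IMPACT].index(i)].sum())
            if row_tot == 0:
                continue
            cells[f"{i}->{j}"] = _chi2_dict(markov.compare_transition_cell(
                i, j, counts[Condition.CONTROL], counts[Condition.IMPACT]))
    summary["markov"]["global_test"] = _chi2_dict(glob)
    summary["markov"]["cell_tests"] = cells

    budgets = {}
    for c in (Condition.CONTROL, Condition.IMPACT):
        if cfg.budget_source == "transitions":
            budgets[c] = markov.behavioural_budget(pool.samples, c, order)
        else:
            budgets[c] = markov.scan_budget(follows, c, order)
    cmp_budget = markov.compare_budget_proportions(budgets[Condition.CONTROL],
                                                   budgets[Condition.IMPACT])
    summary["budget"] = {
        "source": cfg.budget_source,
        "control": {"proportions": budgets[Condition.CONTROL].proportions.tolist(),
                    "n": budgets[Condition.CONTROL].n},
        "impact": {"proportions": budgets[Condition.IMPACT].proportions.tolist(),
                   "n": budgets[Condition.IMPACT].n},
        "global_test": _chi2_dict(cmp_budget.global_test),
        "per_state": {s: _chi2_dict(r) for s, r in cmp_budget.per_state.items()},
    }

    bouts = {c: markov.bouts_from_matrix(mats[c], cfg.unit_minutes)
             for c in (Condition.CONTROL, Condition.IMPACT)}
    bout_rows = {}
    for s in order:
        row: dict = {}
        for c in (Condition.CONTROL, Condition.IMPACT):
            est = bouts[c].get(s)
            if est is not None:
                row[c.value] = {
                    "p_ii": est.p_ii, "n_i": est.n_i,
                    "mean_minutes": est.mean_minutes,
                    "reported_minutes": est.reported_minutes,
                    "se_minutes": est.se_minutes,
                }
        if (s in bouts[Condition.CONTROL]) and (s in bouts[Condition.IMPACT]):
            t = markov.compare_bout_lengths(bouts[Condition.CONTROL][s],
                                            bouts[Condition.IMPACT][s])
            row["t_test"] = {"statistic": t.statistic, "df": t.df,
                             "pvalue": t.pvalue, "flags": list(t.flags)}
        bout_rows[s] = row
    summary["bouts"] = bout_rows

    recov = {}
    for c in (Condition.CONTROL, Condition.IMPACT):
        if cfg.pi_source == "budget":
            pi = budgets[c].proportions
        else:
            try:
                pi = markov.stationary_distribution(mats[c])
            except ValueError as exc:
                summary["notices"].append(f"{c.value} stationary distribution: {exc}")
                continue
        table = markov.recovery_times(pi, cfg.unit_minutes, condition=c,
                                      state_order=order, pi_source=cfg.pi_source)
        recov[c.value] = {
            "pi": table.pi.tolist(),
            "minutes": table.minutes.tolist(),
            "reported_minutes": list(table.reported_minutes),
        }
    summary["recovery"] = {"pi_source": cfg.pi_source, **recov}


def _avoidance_stage(follows, cfg: RunConfig, summary: dict) -> None:
    obs = avoidance.observations_from_follows(follows)
    summary["avoidance"] = {"n_observations": int(len(obs))}
    n_groups = obs["follow_id"].nunique() if len(obs) else 0
    if len(obs) < MIN_AVOIDANCE_OBS or n_groups < MIN_AVOIDANCE_GROUPS:
        notice = (f"insufficient avoidance data ({len(obs)} obs, {n_groups} groups): "
                  "avoidance stage skipped")
        summary["notices"].append(notice)
        logger.warning(notice)
        return
    candidates = avoidance.candidate_specs(cfg.candidate_terms)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        sel = avoidance.model_selection(obs, candidates)
    summary["warnings"].extend(str(w.message) for w in caught)
    best = sel.best
    summary["avoidance"].update({
        "n_groups": int(n_groups),
        "selection": sel.table.to_dict(orient="records"),
        "best_model": {
            "description": best.spec.description,
            "k": best.spec.k,
            "coefficients": best.params.to_dict(),
            "se": None if best.se is None else best.se.to_dict(),
            "sigma": best.sigma,
            "loglik": best.loglik,
            "aicc": avoidance.aicc(best),
            "boundary": best.boundary,
            "flags": list(best.flags),
        },
    })

    grids = {}
    if "vessels" in best.spec.terms:
        vmax = int(obs["n_vessels"].max())
        grids["n_vessels"] = avoidance.prediction_grid(
            best, "n_vessels", list(range(0, vmax + 1)),
            base_profile={"compliant": 1})
    if "compliance" in best.spec.terms:
        grids["compliant"] = avoidance.prediction_grid(best, "compliant", [0, 1])
    if "size" in best.spec.terms:
        lo, hi = obs["group_size"].min(), obs["group_size"].max()
        grids["group_size"] = avoidance.prediction_grid(
            best, "group_size", list(np.linspace(lo, hi, 12).round(1)),
            base_profile={"compliant": 1})
    if "cohesion" in best.spec.terms:
        grids["cohesion"] = avoidance.prediction_grid(
            best, "cohesion", list(records.COHESION_LEVELS),
            base_profile={"compliant": 1})
    summary["avoidance"]["prediction_grids"] = {
        k: v.to_dict(orient="records") for k, v in grids.items()
    }

    diag = avoidance.simulate_scaled_residuals(best, cfg.n_residual_sim,
                                               seed=cfg.seed)
    summary["avoidance"]["residual_diagnostics"] = {
        "n_sim": diag.n_sim,
        "ks_statistic": diag.ks_statistic,
        "ks_pvalue": diag.ks_pvalue,
        "residuals": diag.residuals.tolist(),
    }


def _write_tables(outdir: Path, summary: dict) -> None:
    """Derive the CSV outputs from the JSON summary."""
    order = summary.get("markov", {}).get("state_order", list(OBSERVED_STATES))
    mk = summary.get("markov", {})
    for cond in ("control", "impact"):
        if cond in mk:
            pd.DataFrame(mk[cond]["probabilities"], index=order,
                         columns=order).to_csv(outdir / f"transition_matrix_{cond}.csv")
    if "budget" in summary:
        rows = []
        for cond in ("control", "impact"):
            b = summary["budget"][cond]
            for s, p in zip(order, b["proportions"]):
                rows.append({"condition": cond, "state": s,
                             "proportion": p, "n": b["n"]})
        pd.DataFrame(rows).to_csv(outdir / "budget.csv", index=False)
    if "bouts" in summary:
        rows = []
        for s, row in summary["bouts"].items():
            for cond in ("control", "impact"):
                if cond in row:
                    rows.append({"state": s, "condition": cond, **row[cond]})
        pd.DataFrame(rows).to_csv(outdir / "bouts.csv", index=False)
    if "recovery" in summary:
        rows = []
        for cond in ("control", "impact"):
            if cond in summary["recovery"]:
                r = summary["recovery"][cond]
                for s, pi, m, rep in zip(order, r["pi"], r["minutes"],
                                         r["reported_minutes"]):
                    rows.append({"condition": cond, "state": s, "pi": pi,
                                 "minutes": m, "reported_minutes": rep})
        pd.DataFrame(rows).to_csv(outdir / "recovery.csv", index=False)
    tests_rows = []
    if "global_test" in mk:
        g = mk["global_test"]
        tests_rows.append({"test": "chain_homogeneity", "statistic": g["statistic"],
                           "df": g["df"], "pvalue": g["pvalue"]})
        for cell, r in mk.get("cell_tests", {}).items():
            tests_rows.append({"test": f"cell {cell}", "statistic": r["statistic"],
                               "df": r["df"], "pvalue": r["pvalue"]})
    if "budget" in summary:
        g = summary["budget"]["global_test"]
        tests_rows.append({"test": "budget_global", "statistic": g["statistic"],
                           "df": g["df"], "pvalue": g["pvalue"]})
        for s, r in summary["budget"]["per_state"].items():
            tests_rows.append({"test": f"budget {s}", "statistic": r["statistic"],
                               "df": r["df"], "pvalue": r["pvalue"]})
    for s, row in summary.get("bouts", {}).items():
        if "t_test" in row:
            t = row["t_test"]
            tests_rows.append({"test": f"bout {s}", "statistic": t["statistic"],
                               "df": t["df"], "pvalue": t["pvalue"]})
    if tests_rows:
        pd.DataFrame(tests_rows).to_csv(outdir / "tests.csv", index=False)
    av = summary.get("avoidance", {})
    if "selection" in av:
        pd.DataFrame(av["selection"]).to_csv(outdir / "selection.csv", index=False)
        best = av["best_model"]
        coef = pd.DataFrame({"coefficient": best["coefficients"]})
        if best["se"]:
            coef["se"] = pd.Series(best["se"])
        coef.to_csv(outdir / "coefficients.csv")
        for name, grid in av.get("prediction_grids", {}).items():
            pd.DataFrame(grid).to_csv(outdir / f"predictions_{name}.csv", index=False)
        if "residual_diagnostics" in av:
            pd.DataFrame({"scaled_residual":
                          av["residual_diagnostics"]["residuals"]}
                         ).to_csv(outdir / "residuals.csv", index=False)


def run_pipeline(config: RunConfig) -> dict:
    """Execute records -> markov -> avoidance and write the report bundle.

    Returns the JSON summary (also written to ``summary.json``).  On error
    the partially written output directory is removed and the stage name is
    attached to the raised exception.
    """
    outdir = Path(config.outdir)
    fresh = not outdir.exists()
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"notices": [], "warnings": []}
    stage = "setup"
    try:
        stage = "records"
        if config.input_csv is not None:
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                follows = records.read_scan_table(config.input_csv)
            summary["warnings"].extend(str(w.message) for w in caught)
            summary["input"] = {"path": str(config.input_csv)}
        else:
            frame, truth = synth.simulate_dataset(config.synth_config)
            frame.to_csv(outdir / "scans.csv", index=False)
            truth.to_json(outdir / "truth.json")
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                follows = records.read_scan_table(outdir / "scans.csv")
            summary["input"] = {"path": str(outdir / "scans.csv"), "synthetic": True}
        pool = records.pool_transitions(follows)
        records.write_transitions(pool.samples, outdir / "transitions.csv")
        c = pool.counts
        summary["records"] = {
            "n_follows": len(follows),
            "n_scans": int(sum(len(f) for f in follows)),
            "n_transitions": len(pool),
            "by_condition": {k.value: v for k, v in c.items()},
            "control_fraction": pool.control_fraction,
        }

        stage = "markov"
        _markov_stage(pool, follows, config, summary)

        stage = "avoidance"
        if config.fit_avoidance:
            _avoidance_stage(follows, config, summary)
        else:
            summary["notices"].append("avoidance stage disabled by configuration")

        stage = "report"
        summary = _jsonable(summary)
        with open(outdir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
        _write_tables(outdir, summary)
        with open(outdir / "config.yaml", "w") as fh:
            yaml.safe_dump(_jsonable(config.to_dict()), fh, sort_keys=True)
        return summary
    except Exception as exc:
        if fresh:
            shutil.rmtree(outdir, ignore_errors=True)
        raise RuntimeError(f"pipeline failed in stage '{stage}': {exc}") from exc
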