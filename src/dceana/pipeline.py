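"""End-to-end pipeline: design -> simulate -> fit -> select -> report.

A run configuration (dict or YAML file) names the stages to execute and
their parameters; every stochastic stage records its seed in the output so
a configuration re-runs bit-exactly.  Result JSONs carry no timestamps;
wall-clock timings go to a separate run log.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import construct, diagnostics, eclc, io, mnl, simulate as sim
from .core import Design

__all__ = ["RunConfig", "pipeline_run", "PipelineError"]

_DEFAULTS = {
    "method": "generator",
    "overlap": 0,
    "n_sets": None,
    "seed": 0,
    "n_respondents": 500,
    "n_tasks": 21,
    "straightliner_fraction": 0.0,
    "threshold": 0.05,
    "n_boot": 0,
    "stages": ["design", "simulate", "fit-mnl", "stepwise", "rai", "report"],
}


class PipelineError(RuntimeError):
    """A pipeline stage failed; the stage name is in the message."""


@dataclass
class RunConfig:
    """Resolved pipeline parameters (defaults filled in)."""

    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        merged = dict(_DEFAULTS)
        merged.update(self.params)
        self.params = merged

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls(yaml.safe_load(Path(path).read_text()) or {})

    def __getitem__(self, key):
        return self.params[key]


def build_design(method: str, overlap: int, n_sets: int | None, seed: int) -> Design:
    """Construct a design by any of the three families."""
    if method == "generator":
        gens = (
            [construct.Generator((1, 1, 1, 2, 2)), construct.Generator((2, 2, 2, 4, 4))]
            if overlap == 0
            else [construct.Generator((1, 1, 1, 0, 0)), construct.Generator((0, 0, 2, 1, 1))]
        )
        return construct.generator_design(
            construct.orthogonal_array_25(), gens, seed=seed
        )
    if method == "fedorov":
        rng = np.random.default_rng(seed)
        pool = construct.build_candidate_set(
            overlap, limit=1000, seed=int(rng.integers(2**31)), exclude_dominated=True
        )
        return construct.modified_fedorov(pool, n_sets or 50, seed=seed, n_restarts=3)
    if method == "bayesian":
        return construct.constrained_bayesian_search(
            n_sets or 25,
            [np.zeros(20)],
            seed=seed,
            overlap_target=overlap,
            candidate_limit=500,
            max_iter=5,
        )
    raise ValueError(f"unknown design method {method!r}")


def pipeline_run(config: RunConfig | dict, outdir) -> dict:
    """Execute the configured stages in order; returns the artifact index.

    Artifacts: design.csv, efficiency.json, choices.csv (+ labels.csv),
    mnl.json, eclc.json, step_trace.json, rai.json, crosstab.csv, run_log.json.
    A stage failure aborts with the stage named; earlier artifacts remain.
    """
    if not isinstance(config, RunConfig):
        config = RunConfig(dict(config))
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = list(config["stages"])
    seed = int(config["seed"])
    artifacts: dict[str, str] = {}
    log: dict = {"seed": seed, "stages": {}}
    state: dict = {}

    def run_stage(name, fn):
        t0 = time.perf_counter()
        try:
            fn()
        except Exception as exc:
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        log["stages"][name] = {"seconds": round(time.perf_counter() - t0, 3)}

    if "design" in stages:
        def _design():
            design = build_design(
                config["method"], int(config["overlap"]), config["n_sets"], seed
            )
            io.write_design(design, outdir / "design.csv")
            rep = construct.efficiency_report(design)
            io.write_json(
                {**rep.to_dict(), "method": config["method"], "seed": seed},
                outdir / "efficiency.json",
            )
            state["design"] = design
            artifacts["design"] = "design.csv"
            artifacts["efficiency"] = "efficiency.json"
        run_stage("design", _design)

    if "simulate" in stages:
        def _simulate():
            scenario = sim.default_scenario(int(config["overlap"]), seed)
            scenario.n_respondents = int(config["n_respondents"])
            scenario.n_tasks = int(config["n_tasks"])
            scenario.straightliner_fraction = float(config["straightliner_fraction"])
            scenario.engagement = True
            if "design" in state:
                scenario.design = state["design"]
            data, labels = sim.simulate(scenario)
            io.write_choice_data(data, outdir / "choices.csv")
            labels.to_csv(outdir / "labels.csv", index=False)
            state["data"], state["labels"] = data, labels
            artifacts["choices"] = "choices.csv"
            artifacts["labels"] = "labels.csv"
        run_stage("simulate", _simulate)

    def need_data():
        if "data" not in state:
            path = config.params.get("data", outdir / "choices.csv")
            if not Path(path).exists():
                raise FileNotFoundError(f"choice data not found at {path}")
            state["data"] = io.read_choice_data(path)
        return state["data"]

    if "fit-mnl" in stages:
        def _mnl():
            fit = mnl.fit_mnl(need_data())
            out = fit.to_dict()
            out["anchored"] = dict(
                zip(fit.param_names, map(float, mnl.anchor(fit)))
            )
            io.write_json(out, outdir / "mnl.json")
            state["mnl"] = fit
            artifacts["mnl"] = "mnl.json"
        run_stage("fit-mnl", _mnl)

    if "stepwise" in stages:
        def _stepwise():
            fit, trace = eclc.stepwise_selection(
                need_data(), threshold=float(config["threshold"]), seed=seed
            )
            if int(config["n_boot"]) >= 2:
                eclc.class_prob_cis(
                    fit, need_data(), n_boot=int(config["n_boot"]), seed=seed
                )
            io.write_json(fit.to_dict(), outdir / "eclc.json")
            io.write_json(
                {
                    "threshold": float(config["threshold"]),
                    "seed": seed,
                    "steps": [
                        {
                            "step": r.step,
                            "classes": r.labels,
                            "class_probs": [float(p) for p in r.class_probs],
                            "loglik": float(r.loglik),
                            "dropped": r.dropped,
                        }
                        for r in trace
                    ],
                },
                outdir / "step_trace.json",
            )
            fit.posteriors.rename_axis("respondent_id").to_csv(
                outdir / "posteriors.csv"
            )
            state["eclc"] = fit
            artifacts["eclc"] = "eclc.json"
            artifacts["step_trace"] = "step_trace.json"
            artifacts["posteriors"] = "posteriors.csv"
        run_stage("stepwise", _stepwise)

    if "rai" in stages:
        def _rai():
            fits = {}
            if "mnl" in state:
                fits["mnl_all"] = state["mnl"].beta
            if "eclc" in state:
                fits["eclc"] = state["eclc"].beta
            if not fits:
                raise ValueError("no fitted model available for RAI")
            out = {
                name: {
                    a: float(s)
                    for a, s in diagnostics.rai(beta).to_series().items()
                }
                for name, beta in fits.items()
            }
            io.write_json(out, outdir / "rai.json")
            artifacts["rai"] = "rai.json"
        run_stage("rai", _rai)

    if "report" in stages:
        def _report():
            data = need_data()
            if "eclc" in state:
                labels = eclc.classify_respondents(state["eclc"])
            elif "labels" in state:
                labels = state["labels"].set_index("respondent_id")[
                    "attendance_group"
                ]
            else:
                raise ValueError("no attendance labels available for the report")
            tab = diagnostics.engagement_crosstab(labels, data)
            tab.table.rename_axis("metric").to_csv(outdir / "crosstab.csv")
            artifacts["crosstab"] = "crosstab.csv"
        run_stage("report", _report)

    io.write_json({"artifacts": artifacts, "seed": seed}, outdir / "manifest.json")
    log["artifacts"] = artifacts
    io.write_json(log, outdir / "run_log.json")
    return artifacts
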