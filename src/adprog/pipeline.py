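"""End-to-end pipeline: simulate/read -> validate -> window-filter ->
structural selection -> covariate screening -> final fit -> bootstrap ->
VPC -> diagnostics -> subgroup analysis.

Each stage writes its outputs before the next starts, so a failed run
retains partial results.  One master seed fans out to named substreams
(simulate / bootstrap / vpc), so enabling or disabling one stage never
shifts another stage's random draws.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import evaluation, screening, subgroup
from .data import (
    filter_modeling_window,
    read_trials,
    validate_trials,
    write_trials,
)
from .estimation import fit, select_structural
from .simulate import SimulationConfig, default_config, generate_trial_set, write_truth

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

logger = logging.getLogger(__name__)

_SUBSTREAMS = {"simulate": 0, "structural": 1, "screen": 2, "fit": 3,
               "bootstrap": 4, "vpc": 5, "subgroup": 6}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one of ``input_csv`` and ``simulate`` must be set.
    """

    out_dir: str = "run"
    input_csv: str | None = None
    simulate: SimulationConfig | None = None
    seed: int = 0
    max_weeks: float = 104.0
    structural_forms: tuple[str, ...] = ("emax", "sigmoid_emax",
                                         "exponential", "inverse_bateman")
    run_structural: bool = True
    run_screening: bool = True
    bootstrap_B: int = 200
    vpc_n_sim: int = 500
    strata: tuple[str, ...] = ("era", "add_on", "region")
    n_restarts: int = 2
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if (self.input_csv is None) == (self.simulate is None):
            raise ValueError("set exactly one of input_csv / simulate")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulate", None)
        if sim is not None:
            if sim is True or sim == {}:
                sim = default_config(seed=raw.get("seed", 0))
            else:
                sim = default_config(**sim)
        for key in ("structural_forms", "strata"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(simulate=sim, **raw)


def _seed_for(cfg: RunConfig, stage: str) -> int:
    ss = np.random.SeedSequence(cfg.seed, spawn_key=(_SUBSTREAMS[stage],))
    return int(ss.generate_state(1)[0] % (2**31))


def run_pipeline(cfg: RunConfig) -> Path:
    """Run every stage, writing numeric outputs under ``cfg.out_dir``.

    Reruns with the same config reproduce byte-identical numeric
    outputs.  Returns the run directory.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "log.jsonl"
    events = []

    def record(stage, **kw):
        events.append({"stage": stage, "wall_s": round(kw.pop("wall", 0.0), 3),
                       **kw})
        with open(log_path, "w") as fh:
            for e in events:
                fh.write(json.dumps(e) + "\n")

    def stage(name):
        class _Ctx:
            def __enter__(self):
                self.t0 = time.time()
                logger.info("stage %s", name)
                return self

            def __exit__(self, exc_type, exc, tb):
                wall = time.time() - self.t0
                if exc is not None:
                    record(name, wall=wall, error=str(exc))
                    raise PipelineError(name, exc) from exc
                record(name, wall=wall)
                return False
        return _Ctx()

    with stage("data"):
        if cfg.simulate is not None:
            sim_cfg = dataclasses.replace(cfg.simulate,
                                          seed=_seed_for(cfg, "simulate"))
            ts, truth = generate_trial_set(sim_cfg)
            write_truth(truth, out / "truth.csv")
        else:
            ts = read_trials(cfg.input_csv)
        write_trials(ts, out / "dataset.csv")

    with stage("validate"):
        report = validate_trials(ts)
        (out / "validation.json").write_text(json.dumps(
            [dataclasses.asdict(v) for v in report], indent=2))
        if report:
            raise ValueError(f"{len(report)} validation violation(s); "
                             "see validation.json")

    with stage("window"):
        ts = filter_modeling_window(ts, cfg.max_weeks)

    if cfg.run_structural:
        with stage("structural"):
            table = select_structural(ts, cfg.structural_forms,
                                      n_restarts=cfg.n_restarts,
                                      seed=_seed_for(cfg, "structural"))
            table.to_csv(out / "structural_selection.csv", index=False)

    if cfg.run_screening:
        with stage("screen"):
            sr = screening.stepwise_search(
                ts, seed=_seed_for(cfg, "screen"),
                n_restarts=cfg.n_restarts)
            with open(out / "screening_audit.jsonl", "w") as fh:
                for entry in sr.audit:
                    fh.write(json.dumps(entry, default=str) + "\n")
            final_spec = sr.final_spec
    else:
        from .estimation import final_model_spec
        final_spec = final_model_spec(ts)

    with stage("fit"):
        fr = fit(ts, final_spec, n_restarts=cfg.n_restarts,
                 seed=_seed_for(cfg, "fit"))
        fr.to_json(out / "fit.json")
        fr.parameter_table().to_csv(out / "parameter_table.csv", index=False)

    with stage("bootstrap"):
        br = evaluation.bootstrap(ts, final_spec, B=cfg.bootstrap_B,
                                  seed=_seed_for(cfg, "bootstrap"),
                                  reference_fit=fr,
                                  n_restarts=1)
        br.summary.to_csv(out / "bootstrap_summary.csv", index=False)
        br.replicates.to_csv(out / "bootstrap_replicates.csv", index=False)

    with stage("vpc"):
        vr = evaluation.vpc(ts, fr, n_sim=cfg.vpc_n_sim,
                            seed=_seed_for(cfg, "vpc"))
        vr.table.to_csv(out / "vpc.csv", index=False)

    with stage("diagnostics"):
        evaluation.diagnostics(ts, fr).to_csv(out / "diagnostics.csv",
                                              index=False)

    with stage("subgroup"):
        tab = subgroup.subgroup_table(ts, fr, strata=cfg.strata)
        tab.to_csv(out / "subgroup.csv", index=False)

    record("done", seed=cfg.seed)
    return out
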