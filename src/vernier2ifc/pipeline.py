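"""End-to-end orchestration: simulate/load -> screen -> metrics -> Bayes
factors -> observer fitting, with a manifest for reproducibility.

A :class:`PipelineConfig` (a flat, JSON-serializable declaration) fully
determines a run; a given config plus seed reproduces every table bit for
bit. Stage outputs are tidy CSVs in the output directory, listed with
content hashes in ``manifest.json``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import bayes, metrics
from .data import (
    ExclusionReport,
    collapse_to_level_summaries,
    load_trials,
    save_trials,
    screen_participants,
    trials_to_frame,
)
from .design import Task, scaled_levels
from .fitting import ParticipantData, fit_observer
from .observers import ObserverSpec, simulate_prediction_table
from .synth import default_ground_truth, generate_dataset

log = logging.getLogger("vernier2ifc")

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and the partial manifest."""

    def __init__(self, stage: str, manifest: dict, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.manifest = manifest


@dataclass
class PipelineConfig:
    """Declarative description of one pipeline run."""

    out_dir: str = "results/pipeline"
    # input: path to a trial CSV, or None to simulate synthetically
    input_csv: str | None = None
    tasks: tuple[str, ...] = ("masked",)
    # synthetic-cohort settings (used when input_csv is None)
    truth_model_id: int = 3
    truth_sigma_d: float = 0.2
    n_participants: int = 12
    # exclusion policy: "per_task" or "cross_task"
    exclusion_policy: str = "per_task"
    # observer fitting
    fit_model_ids: tuple[int, ...] = (3,)
    n_sim: int = 20_000
    cv_folds: int = 10
    cv_resamples: int = 50
    run_cv: bool = True
    # MCMC settings for the hierarchical logistic fits
    mcmc_walkers: int = 64
    mcmc_steps: int = 1500
    run_bf: bool = True
    seed: int = 0

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        raw = json.loads(Path(path).read_text())
        for key in ("tasks", "fit_model_ids"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _fit_correctness_model(cells: pd.DataFrame, cfg: PipelineConfig, seed: int):
    """Hierarchical logistic fit from a (participant, x, k, n) cell table."""
    return bayes.fit_hier_logistic(
        x=cells["x"].to_numpy(),
        k=cells["k"].to_numpy(),
        n=cells["n"].to_numpy(),
        participant=list(cells["participant"]),
        seed=seed,
        n_walkers=cfg.mcmc_walkers,
        n_steps=cfg.mcmc_steps,
    )


def _cells(summaries, value_fn) -> pd.DataFrame:
    rows = []
    for s in summaries:
        k, n = value_fn(s)
        rows.append(dict(participant=s.participant_id, x=s.level.scaled_value,
                         level=s.level.index, k=k, n=n))
    return pd.DataFrame(rows)


def _predictions(post, task: Task) -> list[tuple[float, float]]:
    return [bayes.posterior_predict(post, float(x)) for x in scaled_levels(task)]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; returns the manifest. Any stage error raises
    :class:`PipelineError` carrying the partial manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": dataclasses.asdict(config),
        "versions": _versions(),
        "outputs": {},
        "timings_s": {},
        "log": [],
    }

    def _register(name: str, path: Path) -> None:
        manifest["outputs"][name] = {"path": str(path), "sha256": _sha256(path)}

    stage = "input"
    try:
        t0 = time.time()
        trials_by_task = {}
        for i, task_name in enumerate(config.tasks):
            task = Task(task_name)
            if config.input_csv:
                trials = load_trials(config.input_csv, task_filter=task)
            else:
                truth = default_ground_truth(
                    task, config.truth_model_id, config.truth_sigma_d,
                    config.n_participants, seed=config.seed + i,
                )
                trials = generate_dataset(truth, seed=config.seed + 100 + i)
            trials_by_task[task] = trials
            path = out / f"trials_{task.value}.csv"
            save_trials(trials, path)
            _register(f"trials_{task.value}", path)
        manifest["timings_s"][stage] = round(time.time() - t0, 3)

        stage = "exclusion"
        t0 = time.time()
        reports_by_task: dict[Task, list[ExclusionReport]] = {}
        rows = []
        for task, trials in trials_by_task.items():
            reports = screen_participants(trials, task)
            reports_by_task[task] = reports
            for r in reports:
                rows.append(dict(
                    participant_id=r.participant_id, task=task.value,
                    bf_orientation_slope=r.bf_orientation_slope,
                    bf_interval_slope=r.bf_interval_slope,
                    excluded=r.excluded, triggered_by=";".join(r.triggered_by),
                ))
        excl_df = pd.DataFrame(rows)
        path = out / "exclusion_report.csv"
        excl_df.to_csv(path, index=False)
        _register("exclusion_report", path)

        if config.exclusion_policy == "cross_task":
            from .data import apply_cross_task_exclusions

            dropped = apply_cross_task_exclusions(reports_by_task)
            drop_by_task = {task: dropped for task in trials_by_task}
        elif config.exclusion_policy == "per_task":
            drop_by_task = {
                task: {r.participant_id for r in reports if r.excluded}
                for task, reports in reports_by_task.items()
            }
        else:
            raise ValueError(f"unknown exclusion policy {config.exclusion_policy!r}")
        for task in trials_by_task:
            dropped = drop_by_task[task]
            if dropped:
                manifest["log"].append(
                    f"{task.value}: excluded {sorted(dropped)}")
            trials_by_task[task] = [
                t for t in trials_by_task[task] if t.participant_id not in dropped
            ]
        manifest["timings_s"][stage] = round(time.time() - t0, 3)

        stage = "metrics"
        t0 = time.time()
        metric_frames, bias_rows = [], []
        for task, trials in trials_by_task.items():
            summaries = collapse_to_level_summaries(trials)
            series = [
                metrics.accuracy_by_level(summaries, "orientation"),
                metrics.accuracy_by_level(summaries, "interval"),
                *metrics.type2_rates(summaries),
                *metrics.conditional_accuracy(summaries),
            ]
            metric_frames.extend(s.to_frame(task) for s in series)
            ori_bias, int_bias = metrics.response_bias(
                trials, fit_bf=config.run_bf, seed=config.seed,
                mcmc_kwargs={"n_walkers": config.mcmc_walkers,
                             "n_steps": config.mcmc_steps},
            )
            for rep in (ori_bias, int_bias):
                bias_rows.append(dict(
                    task=task.value, response=rep.response,
                    mean_pct=rep.mean_pct, sd_pct=rep.sd_pct,
                    t=rep.t, df=rep.df, p=rep.p, bf10=rep.bf10,
                ))
        path = out / "metrics.csv"
        pd.concat(metric_frames, ignore_index=True).to_csv(path, index=False)
        _register("metrics", path)
        path = out / "response_bias.csv"
        pd.DataFrame(bias_rows).to_csv(path, index=False)
        _register("response_bias", path)
        manifest["timings_s"][stage] = round(time.time() - t0, 3)

        stage = "bayes_factors"
        t0 = time.time()
        if config.run_bf:
            bf_rows = []
            for ti, (task, trials) in enumerate(trials_by_task.items()):
                summaries = collapse_to_level_summaries(trials)
                seed0 = config.seed + 1000 * (ti + 1)
                bf_rows += _bf_stage(summaries, task, config, seed0)
            path = out / "bayes_factors.csv"
            pd.DataFrame(bf_rows).to_csv(path, index=False)
            _register("bayes_factors", path)
        manifest["timings_s"][stage] = round(time.time() - t0, 3)

        stage = "observer_fits"
        t0 = time.time()
        fit_rows = []
        for task, trials in trials_by_task.items():
            summaries = collapse_to_level_summaries(trials)
            by_part: dict[str, list] = {}
            for s in summaries:
                by_part.setdefault(s.participant_id, []).append(s)
            for model_id in config.fit_model_ids:
                table = simulate_prediction_table(
                    ObserverSpec(model_id), n_sim=config.n_sim,
                    seed=config.seed + model_id,
                )
                for pid in sorted(by_part):
                    pdata = ParticipantData.from_summaries(by_part[pid])
                    for variant in ("ideal", "noisy"):
                        res = fit_observer(
                            table, pdata, variant,
                            cv_folds=config.cv_folds,
                            cv_resamples=config.cv_resamples,
                            cv_seed=config.seed, run_cv=config.run_cv,
                        )
                        fit_rows.append(dict(
                            task=task.value, participant=pid,
                            model_id=model_id, variant=variant,
                            sigma_d_hat=res.sigma_d_hat, logl=res.logl,
                            bic=res.bic, cv_logl_mean=res.cv_logl_mean,
                            cv_logl_sem=res.cv_logl_sem,
                            **{f"c{l}": c for l, c in
                               zip(pdata.level_indices, res.c_hat)},
                        ))
        path = out / "observer_fits.csv"
        pd.DataFrame(fit_rows).to_csv(path, index=False)
        _register("observer_fits", path)
        manifest["timings_s"][stage] = round(time.time() - t0, 3)

        stage = "manifest"
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        return manifest
    except Exception as exc:
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise PipelineError(stage, manifest, exc) from exc


def _bf_stage(summaries, task: Task, cfg: PipelineConfig, seed0: int) -> list[dict]:
    """All level-wise Bayes-factor families for one task."""
    rows = []

    def emit(family: str, results, extra=""):
        for lev, r in enumerate(results, start=1):
            rows.append(dict(
                family=family + extra, task=task.value, level_index=lev,
                obs_mean=r.obs_mean, obs_sd=r.obs_sd,
                h1_sd=r.h1.sd, bf10=r.bf10,
            ))

    # above-chance performance: orientation and interval correctness
    for name, value_fn in (
        ("orientation", lambda s: (s.n11 + s.n10, s.n)),
        ("interval", lambda s: (s.n11 + s.n01, s.n)),
    ):
        cells = _cells(summaries, value_fn)
        post = _fit_correctness_model(cells, cfg, seed0)
        preds = _predictions(post, task)
        emit(f"above_chance_{name}",
             bayes.bf_above_chance([p[0] for p in preds], [p[1] for p in preds]))
        seed0 += 1

    # Type-2 HR vs FAR
    hr_post = _fit_correctness_model(
        _cells(summaries, lambda s: (s.n11, s.n11 + s.n10)), cfg, seed0)
    far_post = _fit_correctness_model(
        _cells(summaries, lambda s: (s.n01, s.n01 + s.n00)), cfg, seed0 + 1)
    emit("type2_HRFAR", bayes.bf_difference(
        _predictions(hr_post, task), _predictions(far_post, task), "type2_HRFAR"))

    # conditional orientation accuracy: OP chosen vs OA chosen
    op_post = _fit_correctness_model(
        _cells(summaries, lambda s: (s.n11, s.n11 + s.n01)), cfg, seed0 + 2)
    oa_post = _fit_correctness_model(
        _cells(summaries, lambda s: (s.n10, s.n10 + s.n00)), cfg, seed0 + 3)
    emit("conditional", bayes.bf_difference(
        _predictions(op_post, task), _predictions(oa_post, task), "conditional"))

    # interval-order effect on interval selection
    first_post = _fit_correctness_model(
        _cells([s.restricted("first") for s in summaries],
               lambda s: (s.n11 + s.n01, s.n)), cfg, seed0 + 4)
    second_post = _fit_correctness_model(
        _cells([s.restricted("second") for s in summaries],
               lambda s: (s.n11 + s.n01, s.n)), cfg, seed0 + 5)
    emit("interval_order", bayes.bf_difference(
        _predictions(first_post, task), _predictions(second_post, task),
        "interval_order"))
    return rows


def _versions() -> dict:
    import arviz
    import emcee
    import scipy
    import statsmodels

    import vernier2ifc

    return {
        "vernier2ifc": vernier2ifc.__version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "emcee": emcee.__version__,
        "arviz": arviz.__version__,
        "statsmodels": statsmodels.__version__,
    }
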