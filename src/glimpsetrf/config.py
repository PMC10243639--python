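"""End-to-end analysis configuration and orchestration.

A single :class:`AnalysisConfig` drives the full pipeline: build regressors,
obtain lambdas (tune, reference values, or explicit), fit the baseline model,
run feature ablations, sweep the glimpse SNR threshold, and compute latency
and anatomical statistics.  Everything is deterministic given the config and
its seed: the top-level seed is fanned out to per-stage child seeds through
``numpy.random.SeedSequence`` so stages can be rerun in isolation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import comparison, stats, synthetic, trf

log = logging.getLogger("glimpsetrf")

#: Groups whose encoding is reported; phoneme onsets are always included in
#: the model when present but never themselves reported.
_UNREPORTED = ("glimpsed_phoneme_onsets", "masked_phoneme_onsets",
               "glimpsed_phoneme_onsets_nontarget",
               "masked_phoneme_onsets_nontarget")

_STAGES = ("features", "tune", "fit", "ablate", "sweep", "latency", "anatomy")


@dataclass
class AnalysisConfig:
    """Validated, fully serializable description of one analysis run."""

    out_dir: str
    seed: int = 0
    preset: str | None = "stg_like"      # synthetic scenario name, or None
    scenario_json: str | None = None     # explicit scenario file (overrides preset)
    lambda_source: str = "tune"          # "tune" | "reference" | "explicit"
    lambdas: dict[str, float] = field(default_factory=dict)
    lags_ms: tuple[float, float] = trf.DEFAULT_LAGS_MS
    display_lags_ms: tuple[float, float] = trf.DISPLAY_LAGS_MS
    n_folds: int = 5
    thresholds_db: list[float] = field(
        default_factory=lambda: list(comparison.DEFAULT_SWEEP_GRID_DB))
    n_boot: int = 10_000
    stages: tuple[str, ...] = _STAGES

    def validate(self) -> None:
        if self.lambda_source not in ("tune", "reference", "explicit"):
            raise ValueError("lambda_source must be tune | reference | explicit")
        if self.lambda_source == "explicit" and not self.lambdas:
            raise ValueError("explicit lambda_source requires a lambdas table")
        if self.preset is None and self.scenario_json is None:
            raise ValueError("need a preset name or a scenario file")
        if self.preset is not None and self.preset not in synthetic.make_scenario_presets():
            raise ValueError(f"unknown preset {self.preset!r}")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        unknown = set(self.stages) - set(_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as f:
            raw = yaml.safe_load(f)
        cfg = cls(**raw)
        cfg.lags_ms = tuple(cfg.lags_ms)
        cfg.display_lags_ms = tuple(cfg.display_lags_ms)
        cfg.stages = tuple(cfg.stages)
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "w") as f:
            yaml.safe_dump(json.loads(json.dumps(asdict(self), default=list)), f)

    def child_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the top-level seed."""
        ss = np.random.SeedSequence([self.seed, _STAGES.index(stage)])
        return int(ss.generate_state(1)[0] % (2**31 - 1))


def resolve_lambdas(config: AnalysisConfig, bank: trf.RegressorBank,
                    responses: np.ndarray,
                    lag_frames: np.ndarray) -> dict[str, float]:
    if config.lambda_source == "explicit":
        return {g: float(config.lambdas[g]) for g in bank.names}
    if config.lambda_source == "reference":
        table = dict(trf.REFERENCE_LAMBDAS)
        out = {}
        for g in bank.names:
            key = g.removesuffix("_nontarget")
            for cand in (g, key,
                         "spectrogram" if key.startswith("spectrogram") else None):
                if cand and cand in table:
                    out[g] = table[cand]
                    break
            else:
                alias = {"glimpsed_edges_mixture": "glimpsed_edges",
                         "glimpsed_edges_target": "glimpsed_edges",
                         "masked_edges_target": "masked_edges"}
                out[g] = table.get(alias.get(key, ""), 1.0)
        return out
    return trf.tune_lambdas_sequential(bank, responses, lag_frames, config.n_folds)


def run_full_analysis(config: AnalysisConfig) -> dict:
    """Run the configured stages end to end; write a report bundle.

    Outputs (under ``config.out_dir``): the resolved config, lambda table,
    per-electrode CV scores, ablation table, threshold-sweep curve, latency
    and anatomy summaries, and a run log.  Deterministic given config + seed;
    any stage failure aborts with a stage-named error.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    report: dict = {"seed": config.seed, "versions": {"numpy": np.__version__}}
    config.to_yaml(out / "config.yaml")

    try:
        stage = "features"
        if config.scenario_json:
            scenario = synthetic.SyntheticScenario.from_json(
                Path(config.scenario_json).read_text())
        else:
            scenario = synthetic.make_scenario_presets()[config.preset]
        ds = synthetic.generate_dataset(scenario, config.child_seed("features"))
        bank = ds.bank
        lag_frames = trf.make_lag_frames(config.lags_ms, ds.frame_rate_hz)
        log.info("features: %d groups, %d frames", len(bank.names), bank.n_frames)

        stage = "tune"
        lambdas = resolve_lambdas(config, bank, ds.responses, lag_frames)
        with open(out / "lambdas.json", "w") as f:
            json.dump(lambdas, f, indent=2)
        report["lambdas"] = lambdas
        log.info("lambdas: %s", lambdas)

        stage = "fit"
        fit = None
        if "fit" in config.stages:
            fit = trf.fit_trf(bank, ds.responses, lambdas, lag_frames,
                              config.n_folds)
            pd.DataFrame({
                "subject": ds.subject_ids, "region": ds.regions,
                "mean_z": fit.mean_z,
            }).to_csv(out / "cv_scores.csv", index=False)
            report["mean_cv_z"] = float(np.nanmean(fit.mean_z))
            log.info("fit: mean CV z = %.4f", report["mean_cv_z"])

        stage = "ablate"
        ablations = {}
        if "ablate" in config.stages:
            targets = [g for g in bank.names if g not in _UNREPORTED]
            table, ablations = comparison.run_ablations(
                bank, ds.responses, targets, ds.subject_ids, ds.regions,
                lambdas=lambdas, n_boot=config.n_boot,
                seed=config.child_seed("ablate"),
                lag_frames=lag_frames, n_folds=config.n_folds)
            table.to_csv(out / "ablations.csv", index=False)
            report["ablations"] = {
                g: {"mean_delta_z": r.mean_delta_z, "t": r.t_statistic,
                    "p_boot": r.bootstrap_p}
                for g, r in ablations.items()}

        stage = "sweep"
        if "sweep" in config.stages and "glimpsed_phonetic" in bank.names:
            sweep = comparison.snr_threshold_sweep(
                lambda th: ds.bank_at(th), ds.responses, ds.subject_ids,
                np.asarray(config.thresholds_db, float),
                lambdas=lambdas, lag_frames=lag_frames,
                n_folds=config.n_folds, n_boot=config.n_boot,
                seed=config.child_seed("sweep"))
            sweep.as_frame().to_csv(out / "sweep.csv", index=False)
            report["optimal_threshold_db"] = sweep.best_threshold_db
            log.info("sweep: optimum at %.1f dB", sweep.best_threshold_db)

        stage = "latency"
        if "latency" in config.stages and fit is not None:
            display_frames = trf.make_lag_frames(config.display_lags_ms,
                                                 ds.frame_rate_hz)
            dfit = trf.fit_trf(bank, ds.responses, lambdas, display_frames,
                               n_folds=None)
            latencies = {}
            for g in bank.names:
                if g in _UNREPORTED:
                    continue
                curve, _ = stats.trf_power_timecourse(dfit.group_weights(g))
                latencies[g] = stats.encoding_latency(curve, dfit.lag_ms)
            report["latencies_ms"] = latencies
            if {"glimpsed_phonetic", "masked_phonetic"} <= set(bank.names):
                gl = stats.per_electrode_latencies(
                    dfit.group_weights("glimpsed_phonetic"), dfit.lag_ms)
                ml = stats.per_electrode_latencies(
                    dfit.group_weights("masked_phonetic"), dfit.lag_ms)
                comp = stats.latency_comparison(
                    gl, ml, paired_subject_ids=ds.subject_ids,
                    n_boot=config.n_boot, seed=config.child_seed("latency"))
                report["latency_comparison"] = asdict(comp)
            with open(out / "latency.json", "w") as f:
                json.dump(report.get("latency_comparison", {}) |
                          {"latencies_ms": latencies}, f, indent=2)

        stage = "anatomy"
        if "anatomy" in config.stages and ablations:
            anatomy = {}
            pairs = [("masked_phonetic", 0, "posterior_anterior"),
                     ("glimpsed_phonetic", 1, "boundary_distance")]
            for g, axis, label in pairs:
                if g in ablations:
                    rho, p = stats.anatomical_correlation(
                        ablations[g].delta_z, ds.coords[:, axis],
                        ds.subject_ids, n_boot=config.n_boot,
                        seed=config.child_seed("anatomy"))
                    anatomy[f"{g}_vs_{label}"] = {"rho": rho, "p_boot": p}
            report["anatomy"] = anatomy
            with open(out / "anatomy.json", "w") as f:
                json.dump(anatomy, f, indent=2)
    except Exception as err:
        log.error("stage %r failed: %s", stage, err)
        (out / "INCOMPLETE").write_text(f"failed at stage {stage}: {err}\n")
        raise RuntimeError(f"analysis failed at stage {stage!r}: {err}") from err
    finally:
        log.removeHandler(handler)
        handler.close()

    with open(out / "summary.json", "w") as f:
        json.dump(report, f, indent=2, default=float)
    return report
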