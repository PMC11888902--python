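"""One-config, seed-reproducible end-to-end runs.

``run_pipeline`` executes simulate -> preprocess -> segment -> features ->
train -> evaluate, writing each stage's outputs under its own subdirectory
and a manifest recording per-stage parameters, output-file SHA-256 hashes and
the final metrics. A single global seed is fanned out deterministically to
every stochastic stage, so rerunning an identical config reproduces identical
feature tables and eval-mode predictions.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from bcgkit.features import build_feature_table, feature_matrix, segment_recording
from bcgkit.models import MODEL_NAMES, EnsembleConfig, TrainConfig, make_model
from bcgkit.preprocess import NYQUIST_CLAMP, PreprocessConfig, preprocess_pipeline
from bcgkit.evaluation import evaluate_model, parse_scheme
from bcgkit.synthetic import SyntheticConfig, generate_dataset

logger = logging.getLogger("bcgkit.pipeline")

__all__ = ["RunConfig", "validate_config", "run_pipeline"]


@dataclass
class RunConfig:
    """Everything one pipeline run needs, from simulation to report."""

    out_dir: str = "bcg_run"
    seed: int = 0
    n_per_class: int = 30
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    window_s: float = 30.0
    model: str = "fclstm"
    train: TrainConfig | None = None
    ensemble: EnsembleConfig | None = None
    schemes: tuple = ("holdout:0.25",)
    group_aware: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kwargs = dict(raw)
        if "synthetic" in kwargs:
            kwargs["synthetic"] = SyntheticConfig(**kwargs["synthetic"])
        if "preprocess" in kwargs:
            kwargs["preprocess"] = PreprocessConfig(**kwargs["preprocess"])
        if kwargs.get("train") is not None:
            kwargs["train"] = TrainConfig(**kwargs["train"])
        if kwargs.get("ensemble") is not None:
            kwargs["ensemble"] = EnsembleConfig(**kwargs["ensemble"])
        if "schemes" in kwargs:
            kwargs["schemes"] = tuple(kwargs["schemes"])
        return cls(**kwargs)


def validate_config(cfg: RunConfig) -> list[str]:
    """Return a list of problems (empty iff the config is runnable).

    Checks filter cutoffs against Nyquist (reporting the clamp policy),
    window length against recording duration, CV fold count against the
    number of recordings, and the model name.
    """
    problems: list[str] = []
    nyq = cfg.synthetic.sampling_rate_hz / 2.0
    for name, cutoff in (("highpass", cfg.preprocess.highpass_hz),
                         ("lowpass", cfg.preprocess.lowpass_hz),
                         ("baseline", cfg.preprocess.baseline_hz)):
        if cutoff >= nyq:
            problems.append(
                f"warning: {name} cutoff {cutoff} Hz >= Nyquist {nyq} Hz; "
                f"clamped to {NYQUIST_CLAMP * nyq} Hz"
            )
    if cfg.window_s > cfg.synthetic.duration_s:
        problems.append(
            f"window {cfg.window_s} s exceeds recording duration "
            f"{cfg.synthetic.duration_s} s: no segments would be produced"
        )
    if cfg.model not in MODEL_NAMES:
        problems.append(f"unknown model {cfg.model!r}; choose from {MODEL_NAMES}")
    for scheme in cfg.schemes:
        try:
            kind, value = parse_scheme(scheme)
        except ValueError as exc:
            problems.append(str(exc))
            continue
        if kind == "cv" and cfg.group_aware and value > 2 * cfg.n_per_class:
            problems.append(
                f"{scheme}: k={value} exceeds the {2 * cfg.n_per_class} recordings"
            )
    if cfg.n_per_class < 1:
        problems.append("n_per_class must be >= 1")
    return problems


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage(manifest: dict, name: str, params: dict, outputs: list[Path]) -> None:
    manifest["stages"].append(
        {
            "stage": name,
            "params": params,
            "outputs": {str(p): _sha256(p) for p in sorted(outputs)},
        }
    )
    logger.info("stage %s done (%d outputs)", name, len(outputs))


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all six stages and return the manifest (also written to disk).

    Any stage failure aborts with the stage name attached to the exception.
    """
    hard_problems = [p for p in validate_config(cfg) if not p.startswith("warning")]
    if hard_problems:
        raise ValueError("invalid config: " + "; ".join(hard_problems))

    out = Path(cfg.out_dir)
    dirs = {name: out / name for name in
            ("raw", "preprocessed", "segments", "features", "models", "reports")}
    for d in dirs.values():
        d.mkdir(parents=True, exist_ok=True)

    # one global seed, fanned out per stage
    stage_seeds = {name: int(s.generate_state(1)[0] % (2**31))
                   for name, s in zip(("simulate", "split", "train"),
                                      np.random.SeedSequence(cfg.seed).spawn(3))}
    manifest: dict = {"config": _config_dict(cfg), "seed": cfg.seed,
                      "stage_seeds": stage_seeds, "stages": []}

    stage = "simulate"
    try:
        syn = dataclasses.replace(cfg.synthetic, seed=stage_seeds["simulate"])
        recordings = generate_dataset(syn, cfg.n_per_class)
        raw_paths = [rec.to_csv(dirs["raw"]) for rec in recordings]
        _stage(manifest, stage, {"n_per_class": cfg.n_per_class,
                                 "seed": stage_seeds["simulate"]}, raw_paths)

        stage = "preprocess"
        processed = [preprocess_pipeline(rec, cfg.preprocess) for rec in recordings]
        pre_paths = [rec.to_csv(dirs["preprocessed"]) for rec in processed]
        _stage(manifest, stage, dataclasses.asdict(cfg.preprocess), pre_paths)

        stage = "segment"
        segments = [seg for rec in processed
                    for seg in segment_recording(rec, window_s=cfg.window_s)]
        _stage(manifest, stage, {"window_s": cfg.window_s,
                                 "n_segments": len(segments)}, [])

        stage = "features"
        table = build_feature_table(segments)
        features_path = dirs["features"] / "features.csv"
        table.to_csv(features_path, index=False, float_format="%.12g")
        _stage(manifest, stage, {"n_rows": len(table)}, [features_path])

        stage = "train_evaluate"
        X, y, groups = feature_matrix(table)
        factory = lambda: make_model(cfg.model, seed=stage_seeds["train"],
                                     train_cfg=cfg.train, ensemble_cfg=cfg.ensemble)
        report_paths = []
        metrics = {}
        for scheme in cfg.schemes:
            report = evaluate_model(factory, X, y, groups, scheme=scheme,
                                    seed=stage_seeds["split"],
                                    group_aware=cfg.group_aware)
            safe = scheme.replace(":", "_")
            path = dirs["reports"] / f"{cfg.model}_{safe}.json"
            report.to_json(path)
            report.to_frame().to_csv(dirs["reports"] / f"{cfg.model}_{safe}.csv",
                                     index=False, float_format="%.6g")
            report_paths.append(path)
            metrics[scheme] = report.mean
        _stage(manifest, stage, {"model": cfg.model, "schemes": list(cfg.schemes)},
               report_paths)
        manifest["metrics"] = metrics
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, default=str))
    return manifest


def _config_dict(cfg: RunConfig) -> dict:
    d = dataclasses.asdict(cfg)
    return json.loads(json.dumps(d, default=str))
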