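"""End-to-end orchestration: simulate -> features -> grey ranking ->
GA-SVM training -> evaluation, as one reproducible seeded run.

Every stage derives its own seed from the master seed combined with a CRC of
the stage name, so stages are decoupled but the whole run is deterministic.
The grey ranking's top factor becomes the classifier's second input next to
reaction time.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import evaluate, features, gasvm, grey, synthdata

__all__ = ["RunConfig", "run_all", "load_config"]

log = logging.getLogger("fatiguelab.pipeline")


@dataclass
class RunConfig:
    seed: int = 42
    n_subjects: int = 4
    profile_mix: Mapping[str, float] = field(
        default_factory=lambda: {"male": 0.6, "female": 0.4}
    )
    sim: synthdata.SimConfig = field(default_factory=synthdata.SimConfig)
    grey: grey.GreyConfig = field(
        default_factory=lambda: grey.GreyConfig(preprocess="normalize")
    )
    ga: gasvm.GAConfig = field(default_factory=gasvm.GAConfig)
    train_n: int = 142
    test_n: int = 100
    epoch_s: float = 60.0
    rr_window_s: float = 60.0
    feature_override: str | None = None  # bypass the grey ranking if set
    fixed_specs: tuple[gasvm.SVMSpec, gasvm.SVMSpec] | None = None
    write_sessions: bool = False

    def __post_init__(self) -> None:
        if self.train_n < 3 or self.test_n < 1:
            raise ValueError("train_n/test_n too small")


def _quick(cfg: RunConfig) -> RunConfig:
    """CI-scale parameters: one small cohort, reduced GA."""
    return replace(
        cfg,
        n_subjects=2,
        sim=replace(cfg.sim, eeg_fs=64.0),
        ga=replace(cfg.ga, population=8, generations=20, cv_folds=5),
        train_n=90,
        test_n=60,
    )


def _stage_seed(master: int, stage: str) -> int:
    return int(
        np.random.SeedSequence([master, zlib.crc32(stage.encode())]).generate_state(1)[0]
    )


def load_config(path: str | Path) -> RunConfig:
    """Build a RunConfig from a YAML/JSON mapping of per-stage sections."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    kwargs = dict(raw)
    if "sim" in kwargs:
        kwargs["sim"] = synthdata.SimConfig(**kwargs["sim"])
    if "grey" in kwargs:
        kwargs["grey"] = grey.GreyConfig(**kwargs["grey"])
    if "ga" in kwargs:
        kwargs["ga"] = gasvm.GAConfig(**kwargs["ga"])
    return RunConfig(**kwargs)


def run_all(cfg: RunConfig, outdir: str | Path, quick: bool = False) -> dict:
    """Execute every stage, persisting each stage's outputs under ``outdir``.

    Returns the final report dict (also written to ``report.json``).
    """
    if quick:
        cfg = _quick(cfg)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    # -- simulate ----------------------------------------------------------
    try:
        sim_cfg = replace(cfg.sim, rng_seed=_stage_seed(cfg.seed, "simulate"))
        sessions = synthdata.simulate_cohort(
            cfg.n_subjects,
            profile_mix=dict(cfg.profile_mix),
            seed=_stage_seed(cfg.seed, "cohort"),
            base_cfg=sim_cfg,
        )
        if cfg.write_sessions:
            for s in sessions:
                synthdata.write_session(s, out / "sessions" / s.session_id)
    except Exception as exc:  # pragma: no cover - diagnostics path
        raise RuntimeError(f"stage 'simulate' failed: {exc}") from exc
    log.info("simulated %d sessions", len(sessions))

    # -- features ----------------------------------------------------------
    try:
        table = pd.concat(
            [
                features.build_feature_table(
                    s, epoch_s=cfg.epoch_s, rr_window_s=cfg.rr_window_s
                )
                for s in sessions
            ],
            ignore_index=True,
        )
        features.write_feature_table(table, out / "features.csv")
    except Exception as exc:
        raise RuntimeError(f"stage 'features' failed: {exc}") from exc
    log.info("feature table: %d rows", len(table))

    # -- grey ranking ------------------------------------------------------
    try:
        factor_seqs = {c: table[c].to_numpy() for c in features.FACTOR_COLUMNS}
        result = grey.grey_degree(
            table["reaction_time_s"].to_numpy(), factor_seqs, cfg.grey
        )
        top = grey.select_top_factor(result)
        ranking = pd.DataFrame(
            {
                "factor": result.ranking,
                "gamma": [result.gamma[f] for f in result.ranking],
                "rank": np.arange(1, len(result.ranking) + 1),
            }
        )
        ranking.to_csv(out / "grey_ranking.csv", index=False)
    except Exception as exc:
        raise RuntimeError(f"stage 'grey' failed: {exc}") from exc
    log.info("grey top factor: %s", top)

    chosen = cfg.feature_override or top
    feature_cols = ("reaction_time_s", chosen)

    # -- split & train -----------------------------------------------------
    try:
        if cfg.train_n + cfg.test_n > len(table):
            raise ValueError(
                f"split {cfg.train_n}+{cfg.test_n} exceeds available rows ({len(table)})"
            )
        rng = np.random.default_rng(_stage_seed(cfg.seed, "split"))
        order = rng.permutation(len(table))
        train = table.iloc[order[: cfg.train_n]].reset_index(drop=True)
        test = table.iloc[order[cfg.train_n : cfg.train_n + cfg.test_n]].reset_index(
            drop=True
        )

        ga_cfg = replace(cfg.ga, rng_seed=_stage_seed(cfg.seed, "ga"))
        model, details = gasvm.train_hierarchical(
            train, feature_cols=feature_cols, ga_cfg=ga_cfg, specs=cfg.fixed_specs
        )
        model.to_json(out / "model.json")
    except Exception as exc:
        raise RuntimeError(f"stage 'train' failed: {exc}") from exc

    # -- evaluate ----------------------------------------------------------
    try:
        pred = gasvm.predict(model, test)
        matrix = evaluate.confusion_matrix(test["level"].to_numpy(), pred)
        conf = evaluate.stage_metrics(matrix)
        test_accuracy = float(np.mean(pred == test["level"].to_numpy()))
    except Exception as exc:
        raise RuntimeError(f"stage 'evaluate' failed: {exc}") from exc

    report = {
        "seed": cfg.seed,
        "n_rows": int(len(table)),
        "grey_ranking": {f: result.gamma[f] for f in result.ranking},
        "top_factor": top,
        "feature_cols": list(feature_cols),
        "stage_specs": {
            "stage1": details["stage1_spec"],
            "stage2": details["stage2_spec"],
        },
        "test_accuracy": test_accuracy,
        "confusion": conf.as_dict(),
    }
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    log.info("test accuracy: %.4f", test_accuracy)
    return report
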