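"""End-to-end orchestration of the two stress analyses.

``run_traffic_model`` executes ingest → preprocess → feature extraction
→ traffic labeling → threshold grid search → logistic fit → evaluation,
and ``run_roadtype_model`` the same chain with city/highway labels and
boundary-window exclusion.  Both accept either real input files (EDA
CSV, speed CSV, segment map) or a synthetic batch, and write their
reports as CSV/JSON artifacts when an output directory is configured.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import labeling, models
from .eda_features import MODEL_FEATURES, WindowScheme, extract_features
from .errors import DegenerateLabelsError, SeparationWarning
from .io_formats import align_streams, read_e4_csv, read_segment_map, read_speed_log
from .preprocess import ANALYSIS_RATE_HZ, SMOOTH_WINDOW, preprocess_eda
from .synthetic_data import EdaModel, Study, filter_valid, make_batch, null_eda_model

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything a pipeline run needs; exactly one input source.

    ``inputs`` is a list of ``(eda_path, speed_path, segments_path)``
    triples for real drives; when it is None a synthetic batch of
    ``n_drives`` drives is generated from ``seed`` (with ``n_invalid``
    of them spoiled and filtered out, mirroring a field campaign's
    unusable days).
    """

    seed: int = 0
    inputs: list[tuple[str, str, str]] | None = None
    n_drives: int = 10
    n_invalid: int = 0
    null_signal: bool = False       # synthetic only: no stress signal in EDA
    target_rate: float = ANALYSIS_RATE_HZ
    smooth_window: int = SMOOTH_WINDOW
    smooth_enabled: bool = True
    min_prominence: float = 0.01    # µS
    window_length: float = 360.0    # s
    step: float = 60.0              # s
    feature_names: list[str] = field(default_factory=lambda: list(MODEL_FEATURES))
    eval_scheme: str = "cv10"
    include_comparison: bool = False
    drop_empty_windows: bool = False
    outdir: str | None = None


def load_studies(cfg: RunConfig) -> list[Study]:
    """Materialize the drives: read files or simulate a batch."""
    if cfg.inputs is not None:
        studies = []
        for eda_path, speed_path, seg_path in cfg.inputs:
            eda = read_e4_csv(eda_path)
            speed = read_speed_log(speed_path)
            segments = read_segment_map(seg_path)
            eda, speed, segments = align_streams(eda, speed, segments)
            studies.append(Study(eda=eda, speed=speed, segments=segments, truth={}))
        return studies
    eda_model = null_eda_model() if cfg.null_signal else EdaModel()
    batch = make_batch(
        n_drives=cfg.n_drives,
        n_invalid=cfg.n_invalid,
        seed=cfg.seed,
        eda_model=eda_model,
    )
    studies = filter_valid(batch)
    logger.info("batch: %d drives simulated, %d valid", len(batch), len(studies))
    return studies


def build_dataset(
    studies: list[Study], cfg: RunConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Feature table and speed-window table over all drives.

    Feature rows carry absolute window times and a ``drive`` index;
    speed windows likewise, so label joins work on the pooled tables.
    """
    scheme = WindowScheme(
        window_length=cfg.window_length, step=cfg.step, rate=cfg.target_rate
    )
    feats, wins = [], []
    for i, study in enumerate(studies):
        processed = preprocess_eda(
            study.eda,
            target_rate=cfg.target_rate,
            smooth_window=cfg.smooth_window,
            smooth_enabled=cfg.smooth_enabled,
        )
        f = extract_features(processed, scheme, cfg.min_prominence)
        f.insert(0, "drive", i)
        feats.append(f)
        w = labeling.speed_windows(study.speed, window=cfg.window_length)
        w.insert(0, "drive", i)
        wins.append(w)
    features = pd.concat(feats, ignore_index=True)
    if cfg.drop_empty_windows:
        features = features[~features["empty"]].reset_index(drop=True)
    windows = pd.concat(wins, ignore_index=True)
    return features, windows


def _fit_eval_in_sample(feature_names: list[str]):
    """Closure for the grid search: fit on the labeling, score in-sample."""

    def fit_eval(features: pd.DataFrame, y: np.ndarray) -> dict:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", SeparationWarning)
            model = models.fit_logistic(features[feature_names], y)
        _, pred = models.predict(model, features)
        return models.evaluate_model(y, pred)

    return fit_eval


def _model_card(model: models.LogisticModel) -> pd.DataFrame:
    rows = [
        {"predictor": name, "coefficient": coef,
         "p_value": model.p_values.get(name, np.nan)}
        for name, coef in model.coefficients.items()
    ]
    rows.append(
        {"predictor": "constant", "coefficient": model.constant,
         "p_value": model.p_values.get("constant", np.nan)}
    )
    return pd.DataFrame(rows)


def _evaluate(features, y, cfg: RunConfig) -> pd.DataFrame:
    classifiers: dict[str, object] = {"Logistic": models.LogisticClassifier()}
    if cfg.include_comparison:
        classifiers.update(models.default_comparison_classifiers(seed=cfg.seed))
    groups = features["drive"].to_numpy() if "drive" in features.columns else None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return models.evaluate_classifiers(
            features[cfg.feature_names], y, classifiers,
            scheme=cfg.eval_scheme, seed=cfg.seed, groups=groups,
        )


def _finalize(
    tag: str,
    cfg: RunConfig,
    features: pd.DataFrame,
    y: np.ndarray,
    extra: dict,
) -> dict:
    """Fit the final model on the labeled windows and assemble artifacts."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", SeparationWarning)
        model = models.fit_logistic(features[cfg.feature_names], y)
    _, pred = models.predict(model, features)
    conf = models.confusion(y, pred)
    result = {
        "model": model,
        "model_card": _model_card(model),
        "confusion": conf,
        "metrics": models.metrics(conf).as_percent(),
        "r2_cox_snell": model.r2_cox_snell,
        "r2_nagelkerke": model.r2_nagelkerke,
        "evaluation": _evaluate(features, y, cfg),
        **extra,
    }
    if cfg.outdir:
        _write_artifacts(tag, cfg, result)
    return result


def _write_artifacts(tag: str, cfg: RunConfig, result: dict) -> None:
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result["model_card"].to_csv(outdir / f"{tag}_model_card.csv", index=False)
    result["evaluation"].to_csv(outdir / f"{tag}_evaluation.csv", index=False)
    if "grid" in result:
        result["grid"].table.to_csv(outdir / f"{tag}_grid.csv", index=False)
    c = result["confusion"]
    manifest = {
        "tag": tag,
        "seed": cfg.seed,
        "metrics": result["metrics"],
        "r2_cox_snell": result["r2_cox_snell"],
        "r2_nagelkerke": result["r2_nagelkerke"],
        "confusion": {"tp": c.tp, "fp": c.fp, "tn": c.tn, "fn": c.fn},
        "counts": result.get("counts", {}),
        "config": {
            k: v for k, v in dataclasses.asdict(cfg).items()
            if k not in ("inputs",)
        },
    }
    if "selected_thresholds" in result:
        manifest["selected_thresholds"] = list(result["selected_thresholds"])
    with (outdir / f"{tag}_manifest.json").open("w") as fh:
        json.dump(manifest, fh, indent=2, default=float)


def run_traffic_model(cfg: RunConfig, studies: list[Study] | None = None) -> dict:
    """Traffic-condition analysis: grid search, final fit, evaluation.

    Returns the grid result, selected thresholds, model card, confusion
    counts, percent metrics, pseudo-R² and the classifier evaluation
    table; writes them under ``cfg.outdir`` when set.  ``studies``
    overrides the configured input source.
    """
    studies = load_studies(cfg) if studies is None else studies
    features, windows = build_dataset(studies, cfg)
    grid = labeling.grid_search(
        features, windows, _fit_eval_in_sample(cfg.feature_names),
        min_class_cases=max(12, len(cfg.feature_names) + 2),
    )
    labeled = labeling.label_traffic(windows, grid.selected)
    y_series = labeling.assign_traffic_labels(features, labeled)
    usable = y_series.notna()
    y = y_series[usable].astype(bool).to_numpy()
    used = features[usable].reset_index(drop=True)
    logger.info(
        "traffic model: %d/%d windows labeled, thresholds %s",
        usable.sum(), len(features), grid.selected,
    )
    counts = {
        "windows_total": int(len(features)),
        "windows_used": int(usable.sum()),
        "windows_unlabeled": int((~usable).sum()),
        "high_stress": int(y.sum()),
        "low_stress": int((~y).sum()),
    }
    return _finalize(
        "traffic", cfg, used, y,
        {"grid": grid, "selected_thresholds": grid.selected, "counts": counts},
    )


def run_roadtype_model(cfg: RunConfig, studies: list[Study] | None = None) -> dict:
    """Road-type analysis: city = high stress, highway = low stress.

    Windows straddling segment boundaries or touching tollgates are
    excluded and tallied.  ``studies`` overrides the configured input
    source.
    """
    studies = load_studies(cfg) if studies is None else studies
    features, _ = build_dataset(studies, cfg)
    labels = []
    for i, study in enumerate(studies):
        sub = features[features["drive"] == i]
        labels.append(labeling.label_road_type(sub, study.segments))
    road = pd.concat(labels).reindex(features.index)
    usable = road.isin(["high", "low"])
    if usable.sum() == 0:
        raise DegenerateLabelsError("every window was excluded by road type")
    y = (road[usable] == "high").to_numpy()
    used = features[usable].reset_index(drop=True)
    counts = {
        "windows_total": int(len(features)),
        "windows_used": int(usable.sum()),
        "windows_excluded": int((~usable).sum()),
        "high_stress": int(y.sum()),
        "low_stress": int((~y).sum()),
    }
    logger.info("road-type model: %s", counts)
    return _finalize("roadtype", cfg, used, y, {"counts": counts})


def run_all(cfg: RunConfig) -> dict:
    """Both analyses on one shared configuration."""
    return {
        "traffic": run_traffic_model(cfg),
        "roadtype": run_roadtype_model(cfg),
    }
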