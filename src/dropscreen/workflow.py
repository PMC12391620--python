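"""End-to-end pipeline: simulate → detect → train/apply models → stats → sort.

One master seed is fanned out to named per-stage streams, so a rerun with the
same config and seed reproduces every CSV/JSON artifact byte for byte.  Each
stage fails fast; the run manifest records the failing stage.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from ._seeds import child_rng, child_seed
from .config import BRIGHTFIELD, ExperimentConfig, config_hash
from .datasets import make_crop_dataset, make_population
from .detect import detect_droplets, extract_crops, match_rois, rois_to_frame
from .io import save_stack, write_manifest
from .models import HEADS, train_cellcount_model, train_outlier_model
from .render import render_field
from .sorting import stoichiometry_sort_experiment
from .stats import (
    DropletTimeSeries,
    baseline_viability,
    dead_target_fraction,
    killing_distribution,
    stoichiometry_histogram,
)

__all__ = ["run_pipeline", "PipelineError"]

log = logging.getLogger(__name__)

_TRAIN_OUTLIER_RATES = {"bubble": 0.08, "edge_cutoff": 0.06, "double_layer_blur": 0.06}


class PipelineError(RuntimeError):
    """A stage failure, tagged with the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            log.info("stage %s ...", name)
            try:
                return fn(*args, **kwargs)
            except Exception as e:  # noqa: BLE001 - tag and re-raise
                raise PipelineError(name, e) from e

        return wrapper

    return deco


@_stage("simulate")
def _simulate(config: ExperimentConfig, seed: int, outdir: Path):
    rc = config.render
    truths = make_population(
        config.n_droplets,
        child_seed(seed, "population"),
        config.conc_effector,
        config.conc_target,
        rc,
        config.killing,
    )
    per_field = 100
    grid = (10, 10)
    times = config.killing.time_grid
    rng = child_rng(seed, "field-render")
    annotations = []
    image_paths = []
    for t_idx, t in enumerate(times):
        for f_idx in range(0, len(truths), per_field):
            chunk = truths[f_idx : f_idx + per_field]
            stack, table = render_field(chunk, grid, rc, rng, time=float(t))
            path = outdir / f"field_t{t_idx:02d}_f{f_idx // per_field:03d}.tiff"
            save_stack(stack, path)
            table["field"] = path.name
            annotations.append(table)
            image_paths.append(path)
    ann = pd.concat(annotations, ignore_index=True)
    ann.to_csv(outdir / "annotations.csv", index=False)
    return truths, ann, image_paths


@_stage("train")
def _train_models(config: ExperimentConfig, seed: int, n_train_crops: int):
    ds = make_crop_dataset(
        n_train_crops,
        child_seed(seed, "training-data"),
        render_config=config.render,
        killing_model=config.killing,
        conc_effector=config.conc_effector,
        conc_target=config.conc_target,
        outlier_rates=_TRAIN_OUTLIER_RATES,
    )
    tc_out = type(config.training)(**{**config.training.__dict__,
                                      "seed": child_seed(seed, "outlier-model")})
    outlier_model = train_outlier_model(ds.crops, ds.outlier_labels, tc_out)
    clean = [i for i, o in enumerate(ds.outlier_labels) if not o]
    tc_cnt = type(config.training)(**{**config.training.__dict__,
                                      "seed": child_seed(seed, "count-model")})
    count_model = train_cellcount_model(
        [ds.crops[i] for i in clean], ds.counts[clean], tc_cnt
    )
    return outlier_model, count_model


@_stage("predict")
def _detect_and_predict(config: ExperimentConfig, outdir: Path, ann: pd.DataFrame,
                        image_paths, outlier_model, count_model):
    from .io import load_stack

    rc = config.render
    r_nom = rc.droplet_radius_px
    r_min, r_max = int(0.8 * r_nom), int(np.ceil(1.2 * r_nom))
    rows = []
    roi_frames = []
    for path in image_paths:
        stack = load_stack(path)
        t = stack.acquisition_time
        field_ann = ann[(ann["field"] == Path(path).name)]
        rois = detect_droplets(stack.channels[BRIGHTFIELD], r_min, r_max)
        crops = extract_crops(stack, rois, rc.crop_size, rc.background_level)
        match = match_rois(rois, field_ann)
        ref_by_roi = dict(zip(match["roi_id"], match["ref_id"]))
        outlier_scores = outlier_model.predict_scores(crops) if crops else []
        counts = count_model.predict_counts_array(crops) if crops else np.empty((0, 4))
        for roi, crop, o_score, cnt in zip(rois, crops, outlier_scores, counts):
            rows.append(
                dict(
                    droplet_id=int(ref_by_roi.get(roi.droplet_id, -1)),
                    time_h=float(t),
                    pred_eff_live=int(cnt[2]),
                    pred_eff_dead=int(cnt[3]),
                    pred_tgt_live=int(cnt[0]),
                    pred_tgt_dead=int(cnt[1]),
                    outlier_flag=bool(o_score > 0.5),
                )
            )
        rf = rois_to_frame(rois)
        rf["field"] = Path(path).name
        roi_frames.append(rf)
    counts_df = pd.DataFrame(rows).sort_values(["time_h", "droplet_id"], kind="stable")
    counts_df.to_csv(outdir / "counts.csv", index=False)
    pd.concat(roi_frames, ignore_index=True).to_csv(outdir / "rois.csv", index=False)
    return counts_df


def timeseries_from_counts(counts_df: pd.DataFrame) -> list[DropletTimeSeries]:
    """Assemble per-droplet time series from a predicted-counts table."""
    series = []
    for did, grp in counts_df[counts_df["droplet_id"] >= 0].groupby("droplet_id"):
        grp = grp.sort_values("time_h")
        grp = grp.drop_duplicates(subset="time_h", keep="first")
        counts = grp[
            ["pred_tgt_live", "pred_tgt_dead", "pred_eff_live", "pred_eff_dead"]
        ].to_numpy()
        series.append(
            DropletTimeSeries(
                droplet_id=int(did),
                times=grp["time_h"].to_numpy(),
                counts=counts,
                outlier_flag=bool(grp["outlier_flag"].any()),
            )
        )
    return series


@_stage("stats")
def compute_stats(series: list[DropletTimeSeries]) -> dict:
    """The Fig-2-style summary statistics as one JSON-ready dict."""
    joint, eff_m, tgt_m = stoichiometry_histogram(series)
    out = dict(
        stoichiometry=dict(
            joint=joint.to_numpy().tolist(),
            effector_marginal=eff_m.to_numpy().tolist(),
            target_marginal=tgt_m.to_numpy().tolist(),
        ),
    )
    try:
        out["killing_distribution"] = killing_distribution(series).to_dict()
    except ValueError:
        out["killing_distribution"] = None
    for ct in ("effector", "target"):
        try:
            out[f"baseline_viability_{ct}"] = baseline_viability(series, ct).to_dict()
        except ValueError:
            out[f"baseline_viability_{ct}"] = None
    try:
        dtf = dead_target_fraction(series)
        out["dead_target_fraction"] = dtf["dead_target_fraction"].to_dict()
        out["baseline_dead_fraction"] = dtf["baseline_dead_fraction"].to_dict()
    except ValueError:
        out["dead_target_fraction"] = None
    return out


def count_model_benchmark(
    seed: int,
    n_total: int = 9000,
    n_train: int = 8000,
    config: ExperimentConfig | None = None,
) -> dict:
    """Train the count model on generated crops and score a held-out split.

    Generates ``n_total`` labelled droplet crops under the default study
    conditions, trains the four-headed count model on the first ``n_train``
    and reports exact-count accuracy per head on the remainder (the
    synthetic analogue of scoring the counter against manually annotated
    droplets).
    """
    config = config or ExperimentConfig()
    ds = make_crop_dataset(
        n_total,
        child_seed(seed, "benchmark-data"),
        render_config=config.render,
        killing_model=config.killing,
        conc_effector=config.conc_effector,
        conc_target=config.conc_target,
    )
    tc = type(config.training)(**{**config.training.__dict__,
                                  "seed": child_seed(seed, "benchmark-model")})
    model = train_cellcount_model(ds.crops[:n_train], ds.counts[:n_train], tc)
    from .models import accuracy_report

    pred = model.predict_counts_array(ds.crops[n_train:])
    overall, stratified = accuracy_report(pred, ds.counts[n_train:], tc.c_max)
    return dict(
        per_head_accuracy=overall,
        min_head_accuracy=min(overall.values()),
        n_train=n_train,
        n_test=n_total - n_train,
        stratified=stratified.to_dict(orient="records"),
        training_log=model.training_log,
    )


def run_pipeline(
    config: ExperimentConfig,
    seed: int,
    outdir: str | Path,
    n_train_crops: int = 2000,
) -> dict:
    """Execute the full workflow and return the artifact paths.

    Stages: simulate fields over the assay time grid → Hough detection →
    train outlier/count models on freshly generated labelled crops → predict
    per-droplet counts → screening statistics → stoichiometry sort
    simulation.  Artifacts land in ``outdir``; a manifest records config
    hash, seed and stage status.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config_hash(config)
    manifest_path = outdir / "manifest.json"
    try:
        truths, ann, image_paths = _simulate(config, seed, outdir)
        outlier_model, count_model = _train_models(config, seed, n_train_crops)
        outlier_model.save(outdir / "outlier_model.npz")
        count_model.save(outdir / "count_model.npz")
        counts_df = _detect_and_predict(
            config, outdir, ann, image_paths, outlier_model, count_model
        )
        series = timeseries_from_counts(counts_df)
        stats = compute_stats(series)
        (outdir / "stats.json").write_text(json.dumps(stats, indent=2))
        sort_report = stoichiometry_sort_experiment(config, child_seed(seed, "sortsim"))
        (outdir / "sort_report.json").write_text(json.dumps(sort_report, indent=2))
    except PipelineError as e:
        write_manifest(
            manifest_path, e.stage, seed, chash, {}, {}, status=f"failed: {e.cause}"
        )
        raise
    artifacts = {
        "annotations": str(outdir / "annotations.csv"),
        "rois": str(outdir / "rois.csv"),
        "counts": str(outdir / "counts.csv"),
        "stats": str(outdir / "stats.json"),
        "sort_report": str(outdir / "sort_report.json"),
        "outlier_model": str(outdir / "outlier_model.npz"),
        "count_model": str(outdir / "count_model.npz"),
    }
    write_manifest(manifest_path, "run", seed, chash, {}, artifacts)
    return artifacts
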