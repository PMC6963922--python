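"""End-to-end experiment: simulate -> correct -> segment -> preprocess ->
select -> train (PLS-DA / SVM / CNN, full spectra and effective wavelengths)
-> report.

One global seed deterministically derives per-stage seeds, so the whole run
is reproducible from its manifest.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import evaluate, preprocess, segmentation, selection, synthetic
from .cube import Hypercube, ReferenceFrames, correct_reflectance
from .errors import HsiFruitError
from .models import (
    CNNSpec,
    SVMSpec,
    cnn_build,
    plsda_fit,
    plsda_predict,
    plsda_select_lv,
    svm_grid_search,
)

MODELS = ("plsda", "svm", "cnn")
FEATURE_SETS = ("full", "effective")


@dataclass
class RunConfig:
    """Everything a full experiment needs; scaled-down defaults."""

    n_fruits_per_class: tuple[int, int, int] = (60, 60, 60)
    seed: int = 0
    # scene
    noise_sd_additive: float = 0.02
    illumination_gain_sd: float = 0.005
    fruit_scale_sd: float = 0.03
    separation: float = 1.0
    scene_length_L: int = 150
    # segmentation
    segmentation_wavelength_nm: float = segmentation.SEGMENTATION_WAVELENGTH_NM
    min_area: int = segmentation.DEFAULT_MIN_AREA
    # preprocessing
    first_band: int = preprocess.DEFAULT_FIRST_BAND
    last_band: int = preprocess.DEFAULT_LAST_BAND
    # selection
    n_max_wavelengths: int = selection.DEFAULT_N_MAX
    min_separation_nm: float = selection.DEFAULT_MIN_SEPARATION_NM
    spread_quantile: float = selection.DEFAULT_SPREAD_QUANTILE
    sg_window: int = selection.DEFAULT_WINDOW
    sg_polyorder: int = selection.DEFAULT_POLYORDER
    fixed_wavelengths_nm: tuple[float, ...] | None = None
    # models
    pls_max_lv: int = 15
    svm_cv_folds: int = 5
    cnn_epochs: int = 100
    cnn_batch_size: int = 32
    cnn_learning_rate: float = 0.0005

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("n_fruits_per_class", "fixed_wavelengths_nm"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _stage_seeds(seed: int) -> dict[str, int]:
    names = ("scenes", "split", "svm", "cnn")
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: int(c.generate_state(1)[0]) for n, c in zip(names, children)}


def build_spectrum_table(cfg: RunConfig) -> preprocess.SpectrumTable:
    """Stages simulate -> correct -> segment -> extract -> preprocess."""
    seeds = _stage_seeds(cfg.seed)
    scene_cfg = synthetic.SceneConfig(
        n_fruits_per_class=cfg.n_fruits_per_class,
        scene_length_L=cfg.scene_length_L,
        noise_sd_additive=cfg.noise_sd_additive,
        illumination_gain_sd=cfg.illumination_gain_sd,
        fruit_scale_sd=cfg.fruit_scale_sd,
        separation=cfg.separation,
        seed=seeds["scenes"],
    )
    scenes = synthetic.generate_dataset(scene_cfg)
    fruit_pixels: list[tuple[str, int, segmentation.PixelSpectra]] = []
    axis = None
    for scene_no, (raw, dark, white, truth) in enumerate(scenes):
        refs = ReferenceFrames(dark=dark, white=white)
        refl = correct_reflectance(raw, refs)
        axis = refl.axis
        roiset = segmentation.segment_scene(
            refl,
            wavelength_nm=cfg.segmentation_wavelength_nm,
            min_area=cfg.min_area,
        )
        origins = segmentation.match_origins(roiset, truth.label_image, truth.fruit_origins)
        for pixels in segmentation.extract_pixel_spectra(refl, roiset):
            sample_id = f"scene{scene_no:03d}_fruit{pixels.fruit_id:03d}"
            fruit_pixels.append((sample_id, origins[pixels.fruit_id], pixels))
    table = preprocess.build_table(
        fruit_pixels, axis, first_band=cfg.first_band, last_band=cfg.last_band
    )
    counts = evaluate.proportional_split_counts(
        tuple(int(np.sum(table.labels == c)) for c in range(3))
    )
    split = evaluate.split_samples(table.labels, counts, seed=seeds["split"])
    table.split = split.assignment
    return table


def _fit_model(
    model_name: str, table: preprocess.SpectrumTable, cfg: RunConfig, seeds: dict[str, int]
):
    """Fit one model on the calibration split; returns ``(model, meta)``."""
    cal = table.subset_split("calibration")
    val = table.subset_split("validation")
    if model_name == "plsda":
        n_lv, loo = plsda_select_lv(cal.matrix, cal.labels, cfg.pls_max_lv)
        model = plsda_fit(cal.matrix, cal.labels, n_lv)
        return model, {"n_lv": n_lv, "loo_accuracy": loo}
    if model_name == "svm":
        spec = SVMSpec(cv_folds=cfg.svm_cv_folds, seed=seeds["svm"])
        C, g, cv_acc, model = svm_grid_search(cal.matrix, cal.labels, spec)
        return model, {"C": C, "g": g, "cv_accuracy": cv_acc}
    if model_name == "cnn":
        spec = CNNSpec(
            learning_rate=cfg.cnn_learning_rate,
            batch_size=cfg.cnn_batch_size,
            epochs=cfg.cnn_epochs,
            seed=seeds["cnn"],
        )
        net = cnn_build(spec, input_length=cal.matrix.shape[1])
        net.train(cal.matrix, cal.labels, val.matrix, val.labels)
        return net, {"epochs": cfg.cnn_epochs, "best_val_accuracy": max(net.history)}
    raise ValueError(f"unknown model {model_name!r}")


def _predictor(model_name: str, model):
    if model_name == "plsda":
        return lambda X: plsda_predict(model, X)
    return model.predict


def _train_and_predict(
    model_name: str, table: preprocess.SpectrumTable, cfg: RunConfig, seeds: dict[str, int]
) -> tuple[dict[str, evaluate.ConfusionMatrix], dict]:
    model, meta = _fit_model(model_name, table, cfg, seeds)
    predict = _predictor(model_name, model)
    matrices = {}
    for split_name in evaluate.SPLIT_NAMES:
        part = table.subset_split(split_name)
        matrices[split_name] = evaluate.confusion(
            part.labels, predict(part.matrix), split=split_name
        )
    return matrices, meta


def run_experiment(cfg: RunConfig, outdir: str | Path) -> dict:
    """Run the full experiment and write report + manifest under ``outdir``.

    Returns a dict with the spectrum table, selected wavelengths, confusion
    matrices, the tidy accuracy frame and per-model metadata.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(cfg.seed)
    t0 = time.time()
    stage = "simulate/preprocess"
    try:
        table = build_spectrum_table(cfg)
        stage = "select"
        cal = table.subset_split("calibration")
        if cfg.fixed_wavelengths_nm is not None:
            ew = selection.fixed_wavelengths(table.axis, list(cfg.fixed_wavelengths_nm))
        else:
            ew = selection.select_from_table(
                cal,
                window=cfg.sg_window,
                polyorder=cfg.sg_polyorder,
                n_max=cfg.n_max_wavelengths,
                min_separation_nm=cfg.min_separation_nm,
                spread_quantile=cfg.spread_quantile,
            )
        tables = {"full": table, "effective": selection.subset_table(table, ew)}
        results: dict[str, dict[str, dict[str, evaluate.ConfusionMatrix]]] = {}
        metas: dict[str, dict[str, dict]] = {}
        for feature_set in FEATURE_SETS:
            results[feature_set] = {}
            metas[feature_set] = {}
            for model_name in MODELS:
                stage = f"train:{feature_set}:{model_name}"
                matrices, meta = _train_and_predict(model_name, tables[feature_set], cfg, seeds)
                results[feature_set][model_name] = matrices
                metas[feature_set][model_name] = meta
        stage = "report"
        tidy = evaluate.report(results, outdir)
    except HsiFruitError as exc:
        (outdir / "FAILED").write_text(f"stage={stage}\n{exc}\n")
        raise HsiFruitError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    table.to_csv(outdir / "spectrum_table.csv")
    ew.to_json(outdir / "effective_wavelengths.json")
    manifest = {
        "config": cfg.to_dict(),
        "stage_seeds": seeds,
        "n_samples": int(table.n_samples),
        "n_effective_wavelengths": len(ew),
        "model_meta": metas,
        "runtime_s": round(time.time() - t0, 2),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return {
        "table": table,
        "effective_wavelengths": ew,
        "results": results,
        "accuracy": tidy,
        "manifest": manifest,
    }


def rerun_from_manifest(manifest_path: str | Path, outdir: str | Path) -> dict:
    """Re-execute a run from its persisted manifest."""
    manifest = json.loads(Path(manifest_path).read_text())
    cfg = RunConfig.from_dict(manifest["config"])
    return run_experiment(cfg, outdir)
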