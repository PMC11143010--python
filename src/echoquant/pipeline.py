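"""End-to-end experiment orchestration.

``run_pipeline`` drives the full chain on a synthetic cohort: generate
phantoms -> patient-level split -> train one model per requested
(view, arch) -> predict test masks -> derive clinical indices -> overlap
metrics, method-agreement statistics and quality-stratified summaries, all
written under a run directory with provenance (config hash, seed, versions).

``run_observer_simulation`` emulates the inter/intra-observer study design:
two synthetic "observers" re-read the same cines, realized as seeded smooth
boundary jitter applied to the truth masks (the intra-observer repeat uses a
smaller jitter amplitude than the second observer), and per-index ICCs are
reported.  This is a labelled stand-in for human re-annotation.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

import echoquant
from echoquant import agreement, phantom, quantify, schemes, segnet
from echoquant.data_io import preprocess_frame, read_cine, resize_mask, split_patients
from echoquant.schemes import as_view

log = logging.getLogger("echoquant")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


# ---------------------------------------------------------------------------
# dataset assembly


def load_view_arrays(cohort_dir, view, patient_ids, size: int):
    """ED/ES frames + masks of one view for the given patients, model-ready.

    Images are preprocessed (resized to ``size``, [0, 1]); masks are
    nearest-neighbour resized.  Returns (images, masks, patient_ids,
    qualities, spacings) with one entry per frame; spacings are the
    post-resize (sy, sx) mm/px pairs.
    """
    cohort_dir = Path(cohort_dir)
    view = as_view(view)
    images, masks, pids, quals, spacings = [], [], [], [], []
    for pid in patient_ids:
        cine = read_cine(cohort_dir / pid / view.value)
        for frame_idx in (cine.ed_frame, cine.es_frame):
            img, sp = preprocess_frame(cine.frames[frame_idx], cine.pixel_spacing, size=size)
            images.append(img.astype(np.float32))
            masks.append(resize_mask(cine.masks[frame_idx], size))
            pids.append(pid)
            quals.append(cine.quality_class)
            spacings.append(sp)
    return (np.stack(images), np.stack(masks), np.asarray(pids),
            np.asarray(quals), spacings)


def _truth_indices_table(cohort_dir, patient_ids) -> pd.DataFrame:
    rows = []
    for pid in patient_ids:
        cine = read_cine(Path(cohort_dir) / pid / "A2C")
        rows.append({"patient_id": pid, **cine.nominal_indices})
    return pd.DataFrame(rows).set_index("patient_id")


INDEX_COLUMNS = ["la_volume_ml", "lv_edv_ml", "lv_esv_ml", "lv_mass_g", "ef_pct"]


def predict_patient_indices(models: dict, cohort_dir, patient_ids, size: int) -> pd.DataFrame:
    """Segment ED/ES frames of each view with the trained models and quantify."""
    cohort_dir = Path(cohort_dir)
    rows = []
    for pid in patient_ids:
        mask_dict, spacing_dict = {}, {}
        for view, model in models.items():
            cine = read_cine(cohort_dir / pid / view)
            phases = [("ED", cine.ed_frame)]
            if view != "PSAX":
                phases.append(("ES", cine.es_frame))
            for phase, frame_idx in phases:
                img, sp = preprocess_frame(cine.frames[frame_idx], cine.pixel_spacing, size=size)
                mask_dict[(view, phase)] = segnet.predict_mask(model, img.astype(np.float32))
                spacing_dict[view] = sp
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            idx = quantify.compute_indices(mask_dict, spacing_dict)
        rows.append({"patient_id": pid, **{k: idx.as_dict().get(k) for k in INDEX_COLUMNS}})
    return pd.DataFrame(rows).set_index("patient_id")


def evaluate_masks(models: dict, cohort_dir, patient_ids, size: int) -> pd.DataFrame:
    """Per-case, per-structure DSC/IoU of predictions against truth masks."""
    cohort_dir = Path(cohort_dir)
    rows = []
    for view, model in models.items():
        imgs, msks, pids, quals, _ = load_view_arrays(cohort_dir, view, patient_ids, size)
        for img, truth, pid, qual in zip(imgs, msks, pids, quals):
            pred = segnet.predict_mask(model, img)
            for code in schemes.label_scheme(view):
                if code == schemes.BACKGROUND:
                    continue
                rows.append({
                    "patient_id": pid, "view": view,
                    "structure": schemes.LABEL_NAMES[code], "quality": qual,
                    "dsc": agreement.dice(pred, truth, code),
                    "iou": agreement.iou(pred, truth, code),
                })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# run_pipeline


DEFAULT_CONFIG = {
    "seed": 0,
    "cohort": {"n_patients": 20, "quality_mix": [1.0, 0.0, 0.0],
               "image_size": 64, "n_frames": 8},
    "split": {"fractions": [0.8, 0.1, 0.1]},
    "views": ["A2C"],
    "archs": ["unet"],
    "model": {"levels": 3, "base_channels": 8, "learning_rate": 3e-3,
              "epochs": 5, "batch_size": 5, "input_size": 64},
}


def _merged_config(config: dict) -> dict:
    merged = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, val in (config or {}).items():
        if isinstance(val, dict) and isinstance(merged.get(key), dict):
            merged[key].update(val)
        else:
            merged[key] = val
    for arch in merged["archs"]:
        if arch not in segnet.ARCHS:
            raise ValueError(f"unknown arch {arch!r}; expected one of {segnet.ARCHS}")
    for view in merged["views"]:
        as_view(view)
    return merged


def run_pipeline(config: dict, out_dir) -> dict:
    """Run the full experiment; returns a manifest of produced artifacts."""
    config = _merged_config(config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    artifacts = {}

    def stage(name):
        log.info("stage: %s", name)
        return name

    name = stage("phantom")
    try:
        cohort_dir = out_dir / "cohort"
        manifest = phantom.generate_cohort(
            cohort_dir, config["cohort"]["n_patients"],
            quality_mix=tuple(config["cohort"]["quality_mix"]), seed=seed,
            image_size=config["cohort"]["image_size"],
            n_frames=config["cohort"]["n_frames"],
            views=[as_view(v) for v in set(config["views"]) | {"A2C", "A4C", "PSAX"}],
        )
        artifacts["cohort_manifest"] = str(cohort_dir / "manifest.csv")

        name = stage("split")
        patients = sorted(manifest["patient_id"].unique())
        split = split_patients(patients, tuple(config["split"]["fractions"]), seed=seed)
        (out_dir / "split.json").write_text(json.dumps(split.assignment, indent=1, sort_keys=True))
        artifacts["split"] = str(out_dir / "split.json")

        size = config["model"]["input_size"]
        results = {}
        for arch in config["archs"]:
            models = {}
            for view in config["views"]:
                name = stage(f"train {view}/{arch}")
                cfg = segnet.SegModelConfig(arch=arch, view=view, seed=seed, **config["model"])
                tr = load_view_arrays(cohort_dir, view, split.subset("train"), size)
                va = load_view_arrays(cohort_dir, view, split.subset("val"), size)
                model = segnet.build_model(cfg)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    segnet.train(model, tr[0], tr[1], va[0], va[1], config=cfg)
                mpath = out_dir / "models" / f"{view}_{arch}.npz"
                mpath.parent.mkdir(exist_ok=True)
                segnet.save_model(model, mpath)
                pd.DataFrame(model.history).to_csv(
                    out_dir / "models" / f"{view}_{arch}_history.csv", index=False)
                models[view] = model

            name = stage(f"evaluate {arch}")
            test_ids = split.subset("test")
            scores = evaluate_masks(models, cohort_dir, test_ids, size)
            scores.to_csv(out_dir / f"overlap_{arch}.csv", index=False)
            artifacts[f"overlap_{arch}"] = str(out_dir / f"overlap_{arch}.csv")
            strat = agreement.stratified_eval(scores)
            strat.to_csv(out_dir / f"stratified_{arch}.csv")

            if set(models) >= {"A2C", "A4C"}:
                name = stage(f"quantify {arch}")
                pred_idx = predict_patient_indices(models, cohort_dir, test_ids, size)
                truth_idx = _truth_indices_table(cohort_dir, test_ids)
                pred_idx.to_csv(out_dir / f"indices_pred_{arch}.csv")
                truth_idx.to_csv(out_dir / f"indices_truth_{arch}.csv")
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    report = agreement.compare_methods(truth_idx, pred_idx, INDEX_COLUMNS)
                report.to_csv(out_dir / f"agreement_{arch}.csv")
                artifacts[f"agreement_{arch}"] = str(out_dir / f"agreement_{arch}.csv")
            results[arch] = {"mean_dsc": float(scores["dsc"].mean())}
    except Exception as exc:
        raise PipelineError(f"stage {name!r} failed: {exc}") from exc

    provenance = {
        "config": config,
        "config_sha256": hashlib.sha256(
            json.dumps(config, sort_keys=True).encode()).hexdigest(),
        "seed": seed,
        "versions": {"echoquant": echoquant.__version__, "numpy": np.__version__},
        "artifacts": artifacts,
        "results": results,
    }
    (out_dir / "run.json").write_text(json.dumps(provenance, indent=1, sort_keys=True))
    return provenance


# ---------------------------------------------------------------------------
# observer simulation


def perturb_mask(mask: np.ndarray, amplitude_px: float, rng: np.random.Generator,
                 smoothness_px: float = 8.0) -> np.ndarray:
    """Smooth elastic jitter of label boundaries (amplitude in pixels, RMS)."""
    if amplitude_px <= 0:
        return mask.copy()
    shape = mask.shape
    disp = []
    for _ in range(2):
        field = rng.normal(size=shape)
        field = ndimage.gaussian_filter(field, smoothness_px)
        rms = np.sqrt((field**2).mean())
        disp.append(field / rms * amplitude_px if rms > 0 else field)
    ii, jj = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    coords = np.stack([ii + disp[0], jj + disp[1]])
    return ndimage.map_coordinates(mask, coords, order=0, mode="nearest")


def _observer_indices(cohort_dir, pid, amplitude_mm: float, rng) -> dict:
    cohort_dir = Path(cohort_dir)
    mask_dict, spacing_dict = {}, {}
    for view in ("A2C", "A4C", "PSAX"):
        cine = read_cine(cohort_dir / pid / view)
        amp_px = amplitude_mm / cine.pixel_spacing
        phases = [("ED", cine.ed_frame)] + ([("ES", cine.es_frame)] if view != "PSAX" else [])
        for phase, fi in phases:
            mask_dict[(view, phase)] = perturb_mask(cine.masks[fi], amp_px, rng)
            spacing_dict[view] = (cine.pixel_spacing, cine.pixel_spacing)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        idx = quantify.compute_indices(mask_dict, spacing_dict)
    return {k: idx.as_dict().get(k) for k in INDEX_COLUMNS}


def run_observer_simulation(cohort_dir, patient_ids=None, amp_intra_mm: float = 0.8,
                            amp_inter_mm: float = 1.6, seed: int = 0) -> pd.DataFrame:
    """Simulated inter/intra-observer study on phantom truth masks.

    Observer 1 reads every cine twice (independent jitter at the intra
    amplitude); observer 2 reads once at the larger inter amplitude.  Per
    clinical index, ICC(A,1) is reported for observer1-read1 vs read2
    (intra) and observer1-read1 vs observer2 (inter).
    """
    cohort_dir = Path(cohort_dir)
    if patient_ids is None:
        manifest = pd.read_csv(cohort_dir / "manifest.csv")
        patient_ids = sorted(manifest["patient_id"].unique())
    if len(patient_ids) < 10:
        raise ValueError("observer simulation needs at least 10 patients (unstable ICC)")
    rng = np.random.default_rng(seed)
    readings = {"obs1_read1": [], "obs1_read2": [], "obs2": []}
    for pid in patient_ids:
        readings["obs1_read1"].append(_observer_indices(cohort_dir, pid, amp_intra_mm, rng))
        readings["obs1_read2"].append(_observer_indices(cohort_dir, pid, amp_intra_mm, rng))
        readings["obs2"].append(_observer_indices(cohort_dir, pid, amp_inter_mm, rng))
    tables = {k: pd.DataFrame(v, index=list(patient_ids)) for k, v in readings.items()}
    rows = []
    for col in INDEX_COLUMNS:
        for kind, (a, b) in (
            ("intra", ("obs1_read1", "obs1_read2")),
            ("inter", ("obs1_read1", "obs2")),
        ):
            pair = np.column_stack([tables[a][col].to_numpy(dtype=float),
                                    tables[b][col].to_numpy(dtype=float)])
            try:
                icc, lo, hi = agreement.icc_a1(pair)
            except agreement.ZeroVarianceError:
                icc = lo = hi = np.nan
            rows.append({"index": col, "comparison": kind, "icc": icc,
                         "icc_ci_lower": lo, "icc_ci_upper": hi})
    return pd.DataFrame(rows)
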