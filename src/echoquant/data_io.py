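"""Dataset layout, readers/writers, preprocessing, and patient-level splits.

On-disk layout (produced by :mod:`echoquant.phantom` and consumed here)::

    cohort/
      manifest.csv
      P0000/A2C/frame_000.png mask_000.png ... cine.json
      ...

Frames are 8-bit grayscale PNG, masks 8-bit indexed PNG with the view's
label codes, and ``cine.json`` carries the physical calibration
(``pixel_spacing_mm``) plus ED/ES frame indices and nominal indices.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from skimage.transform import resize

from echoquant.schemes import View, as_view, label_scheme


class SidecarError(KeyError):
    """Missing or malformed cine sidecar (e.g. no pixel_spacing_mm)."""


class LabelSchemeError(ValueError):
    """A mask contains a label code outside its view's scheme."""


@dataclass
class CineSequence:
    """Ordered grayscale frames of one view of one patient."""

    frames: np.ndarray          # (n_frames, H, W)
    pixel_spacing: float        # mm/px, isotropic as acquired
    view: View
    patient_id: str
    masks: np.ndarray | None = None   # (n_frames, H, W) integer labels, if available
    ed_frame: int | None = None
    es_frame: int | None = None
    quality_class: str | None = None
    border_visibility: float | None = None
    nominal_indices: dict | None = None

    def __post_init__(self):
        self.view = as_view(self.view)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n, H, W) stack")
        if self.pixel_spacing <= 0:
            raise ValueError("pixel spacing must be positive")


@dataclass
class SplitAssignment:
    """Patient-level train/val/test partition."""

    assignment: dict            # patient_id -> "train" | "val" | "test"
    seed: int
    fractions: tuple

    def subset(self, part: str) -> list:
        return sorted(p for p, s in self.assignment.items() if s == part)


def preprocess_frame(frame: np.ndarray, spacing, size: int = 512):
    """Resize to ``size`` x ``size`` and min-max normalize into [0, 1].

    Returns ``(array, (sy, sx))`` where the per-axis spacing is rescaled by
    original_size / size so physical measurements survive the resize.
    Bilinear interpolation; a constant frame maps to all zeros.  Idempotent
    on an already-sized, already-normalized input.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2 or frame.size == 0:
        raise ValueError("frame must be a non-empty 2-D array")
    sp = np.atleast_1d(np.asarray(spacing, dtype=float))
    sy, sx = (sp[0], sp[0]) if sp.size == 1 else (sp[0], sp[1])
    h, w = frame.shape
    if (h, w) != (size, size):
        frame = resize(frame, (size, size), order=1, mode="edge",
                       anti_aliasing=h > size, preserve_range=True)
    lo, hi = frame.min(), frame.max()
    frame = (frame - lo) / (hi - lo) if hi > lo else np.zeros_like(frame)
    return frame, (sy * h / size, sx * w / size)


def resize_mask(mask: np.ndarray, size: int) -> np.ndarray:
    """Nearest-neighbour resize of an integer label map (labels stay integer)."""
    if mask.shape == (size, size):
        return mask.copy()
    out = resize(mask, (size, size), order=0, mode="edge",
                 anti_aliasing=False, preserve_range=True)
    return out.astype(mask.dtype)


def split_patients(patient_ids, fractions=(0.8, 0.1, 0.1), seed: int = 0) -> SplitAssignment:
    """Seeded patient-level split into train/val/test.

    Val/test counts are round(fraction * n); the remainder goes to train, so
    500 ids at (0.8, 0.1, 0.1) give 400/50/50.  All cines of a patient share
    a partition by construction.
    """
    ids = list(patient_ids)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate patient ids")
    if abs(sum(fractions) - 1.0) > 1e-9 or len(fractions) != 3:
        raise ValueError("fractions must be 3 values summing to 1")
    n = len(ids)
    n_val = round(fractions[1] * n)
    n_test = round(fractions[2] * n)
    n_train = n - n_val - n_test
    if n_train < 0:
        raise ValueError("fractions leave no room for a training set")
    order = np.random.default_rng(seed).permutation(n)
    assignment = {}
    for rank, idx in enumerate(order):
        part = "train" if rank < n_train else ("val" if rank < n_train + n_val else "test")
        assignment[ids[idx]] = part
    return SplitAssignment(assignment=assignment, seed=seed, fractions=tuple(fractions))


def make_cv_folds(patient_ids, k: int, seed: int = 0) -> list[list]:
    """k disjoint, exhaustive, near-equal patient folds (seeded permutation).

    Each cross-validation round uses k-1 folds for train+val and the
    remaining fold as the test set.
    """
    ids = list(patient_ids)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate patient ids")
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(ids):
        raise ValueError("more folds than patients")
    order = np.random.default_rng(seed).permutation(len(ids))
    return [[ids[i] for i in chunk] for chunk in np.array_split(order, k)]


# ---------------------------------------------------------------------------
# readers / writers


def _load_sidecar(cine_dir: Path) -> dict:
    path = cine_dir / "cine.json"
    if not path.exists():
        raise SidecarError(f"missing sidecar {path}")
    meta = json.loads(path.read_text())
    if "pixel_spacing_mm" not in meta:
        raise SidecarError(f"sidecar {path} lacks pixel_spacing_mm")
    return meta


def validate_labels(mask: np.ndarray, view) -> np.ndarray:
    scheme = set(label_scheme(view))
    present = set(np.unique(mask).tolist())
    bad = present - scheme
    if bad:
        raise LabelSchemeError(
            f"labels {sorted(bad)} invalid for view {as_view(view).value} (scheme {sorted(scheme)})"
        )
    return mask


def read_cine(cine_dir) -> CineSequence:
    """Read one cine directory (frames + masks + sidecar) into memory."""
    cine_dir = Path(cine_dir)
    meta = _load_sidecar(cine_dir)
    view = as_view(meta["view"])
    frame_paths = sorted(cine_dir.glob("frame_*.png"))
    if not frame_paths:
        raise FileNotFoundError(f"no frames in {cine_dir}")
    frames = np.stack([np.asarray(Image.open(p).convert("L")) for p in frame_paths])
    mask_paths = sorted(cine_dir.glob("mask_*.png"))
    masks = None
    if mask_paths:
        masks = np.stack([np.asarray(Image.open(p)).astype(np.uint8) for p in mask_paths])
        validate_labels(masks, view)
    return CineSequence(
        frames=frames,
        pixel_spacing=float(meta["pixel_spacing_mm"]),
        view=view,
        patient_id=str(meta.get("patient_id", cine_dir.parent.name)),
        masks=masks,
        ed_frame=meta.get("ed_frame"),
        es_frame=meta.get("es_frame"),
        quality_class=meta.get("quality_class"),
        border_visibility=meta.get("border_visibility"),
        nominal_indices=meta.get("nominal_indices"),
    )


def write_masks(masks, out_dir, view, pixel_spacing_mm: float, prefix: str = "mask"):
    """Write integer label maps as 8-bit PNGs plus a minimal sidecar.

    Round-trip with :func:`read_masks` reproduces the arrays exactly and the
    spacing to 6 decimals.
    """
    from echoquant.phantom import _save_mask_png

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    view = as_view(view)
    for k, m in enumerate(masks):
        validate_labels(np.asarray(m), view)
        _save_mask_png(np.asarray(m), out_dir / f"{prefix}_{k:03d}.png")
    meta = {"view": view.value, "pixel_spacing_mm": round(float(pixel_spacing_mm), 6)}
    (out_dir / "cine.json").write_text(json.dumps(meta, indent=1, sort_keys=True))


def read_masks(mask_dir, prefix: str = "mask"):
    """Read masks written by :func:`write_masks`; returns (stack, view, spacing)."""
    mask_dir = Path(mask_dir)
    meta = _load_sidecar(mask_dir)
    view = as_view(meta["view"])
    paths = sorted(mask_dir.glob(f"{prefix}_*.png"))
    masks = np.stack([np.asarray(Image.open(p)).astype(np.uint8) for p in paths])
    validate_labels(masks, view)
    return masks, view, float(meta["pixel_spacing_mm"])


def read_dicom_cine(path, patient_id: str = "dicom") -> CineSequence:
    """Minimal multi-frame ultrasound DICOM reader (frames + PixelSpacing only).

    Requires pydicom (optional dependency); vendor private tags are ignored.
    """
    try:
        import pydicom
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("reading DICOM requires the optional pydicom dependency") from exc
    ds = pydicom.dcmread(str(path))
    arr = ds.pixel_array
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim == 4:  # RGB multiframe
        arr = arr.mean(axis=-1)
    spacing = None
    if hasattr(ds, "PixelSpacing"):
        spacing = float(ds.PixelSpacing[0])
    elif hasattr(ds, "SequenceOfUltrasoundRegions") and ds.SequenceOfUltrasoundRegions:
        region = ds.SequenceOfUltrasoundRegions[0]
        if hasattr(region, "PhysicalDeltaY"):
            spacing = abs(float(region.PhysicalDeltaY)) * 10.0  # cm/px -> mm/px
    if spacing is None:
        raise SidecarError("DICOM lacks pixel spacing calibration")
    view = getattr(ds, "SeriesDescription", "A4C")
    try:
        view = as_view(str(view).strip().upper())
    except Exception:
        warnings.warn(f"unrecognized view tag {view!r}; defaulting to A4C")
        view = View.A4C
    return CineSequence(frames=arr.astype(np.uint8), pixel_spacing=spacing,
                        view=view, patient_id=patient_id)
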