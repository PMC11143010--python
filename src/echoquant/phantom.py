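"""Synthetic echocardiography phantoms with exact ground truth.

Generates sector-shaped B-mode-like cines for the three standard views.  The
LV is a prolate spheroid (long semi-axis a = 2b), so its apical cross-section
is a true ellipse with area A = pi*a*b and long axis L = 2a, and the
area-length volume formula (8/3pi)*A^2/L recovers the spheroid volume
(4/3)*pi*a*b^2 exactly in the continuum limit.  The cavity cross-sectional
area varies sinusoidally over the cycle between the diastolic and systolic
targets (one ED at phase 0, one ES at phase 0.5), so frame selection has an
unambiguous ground truth.  Rendering adds multiplicative Rayleigh speckle, a
bright endocardial rim, and controllable rim dropout realizing the
good/fair/poor image-quality grades (percent endocardial border
visualization: good 67-100%, fair 34-66%, poor 0-33%).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage

from echoquant import schemes
from echoquant.quantify import ClinicalIndices, ejection_fraction, lv_mass
from echoquant.schemes import View, as_view

# field of view (vertical, cm) used to derive the default pixel spacing
FOV_CM = 20.0
# sector: vertex this far above the top edge (cm), half-opening angle (deg)
SECTOR_VERTEX_CM = 2.0
SECTOR_HALF_ANGLE_DEG = 45.0

APEX_MARGIN_CM = 1.0     # transducer-to-LV-apex offset
CHAMBER_GAP_CM = 0.5     # LV/LA (and RV/RA) vertical separation
X_LEFT_HEART_CM = {"A2C": 0.5, "A4C": 1.8}   # horizontal centre of LV/LA
X_RIGHT_HEART_CM = -2.6                       # horizontal centre of RV/RA (A4C)

# render intensities (pre-speckle)
I_TISSUE = 70.0
I_CAVITY = 25.0
I_MYO = 130.0
I_RIM = 180.0

QUALITY_BANDS = {"good": (0.67, 1.00), "fair": (0.34, 0.66), "poor": (0.00, 0.33)}


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic patient/view cine.

    Volumes are ml, wall thickness mm, pixel spacing mm/px (default: a
    20 cm field of view divided by ``image_size``).  ``border_visibility``
    is the fraction of the endocardial rim rendered visible.
    """

    patient_id: str = "phantom"
    view: View = View.A2C
    n_frames: int = 8
    image_size: int = 256
    pixel_spacing: float | None = None
    nominal_edv: float = 120.0
    nominal_esv: float = 48.0
    wall_thickness: float = 10.0
    border_visibility: float = 1.0
    rng_seed: int = 0
    nominal_lav: float | None = None

    def __post_init__(self):
        object.__setattr__(self, "view", as_view(self.view))
        if self.pixel_spacing is None:
            object.__setattr__(self, "pixel_spacing", FOV_CM * 10.0 / self.image_size)
        if self.nominal_lav is None:
            object.__setattr__(self, "nominal_lav", 0.35 * self.nominal_edv)
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.image_size < 16:
            raise ValueError("image_size too small")
        if self.pixel_spacing <= 0:
            raise ValueError("pixel_spacing must be > 0")
        if not (0.0 <= self.border_visibility <= 1.0):
            raise ValueError("border_visibility must lie in [0, 1]")
        if not (0.0 < self.nominal_esv < self.nominal_edv):
            raise ValueError("need 0 < nominal_esv < nominal_edv")
        if self.wall_thickness <= 0:
            raise ValueError("wall_thickness must be > 0")


@dataclass
class PhantomTruth:
    """Exact ground truth for one cine: masks, frame indices, nominal indices."""

    masks: list[np.ndarray]
    ed_frame: int
    es_frame: int
    indices: ClinicalIndices
    spec: PhantomSpec | None = None


# ---------------------------------------------------------------------------
# geometry


def _lv_dimensions(spec: PhantomSpec):
    """LV semi-axes (cm) and cross-sectional areas at ED/ES.

    Prolate spheroid with a = 2*b_ed fixed over the cycle; EDV fixes b_ed
    via V = (4/3)*pi*a*b^2 = (8/3)*pi*b^3.
    """
    b_ed = (3.0 * spec.nominal_edv / (8.0 * math.pi)) ** (1.0 / 3.0)
    a = 2.0 * b_ed
    b_es = math.sqrt(3.0 * spec.nominal_esv / (4.0 * math.pi * a))
    return a, b_ed, b_es


def _la_dimensions(spec: PhantomSpec):
    """LA semi-axes (cm); maximal (nominal volume) at ventricular ES."""
    b_max = (3.0 * spec.nominal_lav / (4.0 * math.pi * 1.4)) ** (1.0 / 3.0)
    a_la = 1.4 * b_max
    b_min = b_max * math.sqrt(0.55)  # LA minimum volume = 55% of maximum
    return a_la, b_max, b_min


def _area_at_phase(a_ed: float, a_es: float, phase: float, antiphase: bool = False) -> float:
    """Sinusoidal interpolation between diastolic and systolic areas."""
    w = (1.0 + math.cos(2.0 * math.pi * phase)) / 2.0
    if antiphase:
        w = 1.0 - w
    return a_es + (a_ed - a_es) * w


def _grid_cm(spec: PhantomSpec):
    """Physical pixel-centre coordinates: depth z (rows) and lateral x (cols), cm."""
    s_cm = spec.pixel_spacing / 10.0
    n = spec.image_size
    z = (np.arange(n) + 0.5) * s_cm
    x = (np.arange(n) + 0.5) * s_cm - n * s_cm / 2.0
    return z[:, None], x[None, :]


def sector_mask(image_size: int, pixel_spacing_mm: float) -> np.ndarray:
    """Boolean ultrasound-sector footprint for a square image."""
    s_cm = pixel_spacing_mm / 10.0
    n = image_size
    z = (np.arange(n) + 0.5) * s_cm
    x = (np.arange(n) + 0.5) * s_cm - n * s_cm / 2.0
    zz, xx = z[:, None], x[None, :]
    depth = zz + SECTOR_VERTEX_CM
    half_width = depth * math.tan(math.radians(SECTOR_HALF_ANGLE_DEG))
    radius = n * s_cm + SECTOR_VERTEX_CM
    return (np.abs(xx) <= half_width) & (np.sqrt(xx**2 + depth**2) <= radius)


def rasterize_ellipse(shape, center, semi_axes) -> np.ndarray:
    """Boolean ellipse mask in pixel units: center (row, col), semi_axes (a_row, a_col)."""
    ii = np.arange(shape[0])[:, None] + 0.5
    jj = np.arange(shape[1])[None, :] + 0.5
    return ((ii - center[0]) / semi_axes[0]) ** 2 + ((jj - center[1]) / semi_axes[1]) ** 2 <= 1.0


def _paint(out: np.ndarray, region: np.ndarray, label: int):
    if (out[region] != 0).any():
        raise GeometryOverlapError("phantom chambers overlap; adjust spec dimensions")
    out[region] = label


class GeometryOverlapError(RuntimeError):
    """Chamber regions collided during rasterization (spec out of layout range)."""


def generate_geometry(spec: PhantomSpec, frame_phase: float) -> np.ndarray:
    """Label map for one frame at cardiac-cycle ``frame_phase`` in [0, 1).

    A2C: LV + LA ellipses; A4C additionally RV + RA; PSAX: LV-cavity disc
    with a concentric myocardial ring of the requested wall thickness.
    Chambers are pairwise disjoint by construction (checked).
    """
    view = as_view(spec.view)
    if not (0.0 <= frame_phase < 1.0):
        raise ValueError("frame_phase must lie in [0, 1)")
    zz, xx = _grid_cm(spec)
    out = np.zeros((spec.image_size, spec.image_size), dtype=np.uint8)

    a, b_ed, b_es = _lv_dimensions(spec)
    area = _area_at_phase(math.pi * a * b_ed, math.pi * a * b_es, frame_phase)
    b = area / (math.pi * a)

    if view is View.PSAX:
        cz = spec.image_size * spec.pixel_spacing / 20.0  # image centre depth, cm
        cx = 0.0
        t = spec.wall_thickness / 10.0
        ring = ((zz - cz) ** 2 + (xx - cx) ** 2 <= (b + t) ** 2)
        cavity = ((zz - cz) ** 2 + (xx - cx) ** 2 <= b**2)
        out[ring] = schemes.MYO
        out[cavity] = schemes.LV
        return out

    x_lh = X_LEFT_HEART_CM[view.value]
    cz_lv = APEX_MARGIN_CM + a
    lv = ((zz - cz_lv) / a) ** 2 + ((xx - x_lh) / b) ** 2 <= 1.0
    _paint(out, lv, schemes.LV)

    a_la, b_la_max, b_la_min = _la_dimensions(spec)
    la_area = _area_at_phase(
        math.pi * a_la * b_la_max, math.pi * a_la * b_la_min, frame_phase, antiphase=True
    )
    b_la = la_area / (math.pi * a_la)
    cz_la = cz_lv + a + CHAMBER_GAP_CM + a_la
    la = ((zz - cz_la) / a_la) ** 2 + ((xx - x_lh) / b_la) ** 2 <= 1.0
    _paint(out, la, schemes.LA)

    if view is View.A4C:
        a_rv = 0.75 * a
        b_rv = 0.6 * b
        cz_rv = APEX_MARGIN_CM + 0.3 + a_rv
        rv = ((zz - cz_rv) / a_rv) ** 2 + ((xx - X_RIGHT_HEART_CM) / b_rv) ** 2 <= 1.0
        _paint(out, rv, schemes.RV)
        a_ra = 0.85 * a_la
        b_ra = 0.8 * b_la
        cz_ra = cz_rv + a_rv + CHAMBER_GAP_CM + a_ra
        ra = ((zz - cz_ra) / a_ra) ** 2 + ((xx - X_RIGHT_HEART_CM) / b_ra) ** 2 <= 1.0
        _paint(out, ra, schemes.RA)
    return out


# ---------------------------------------------------------------------------
# rendering


def _endocardial_boundary(mask: np.ndarray, label: int) -> np.ndarray:
    """Inner boundary pixels of ``label`` (pixels of the label with a non-label 4-neighbour)."""
    binary = mask == label
    interior = binary.copy()
    interior[1:, :] &= binary[:-1, :]
    interior[:-1, :] &= binary[1:, :]
    interior[:, 1:] &= binary[:, :-1]
    interior[:, :-1] &= binary[:, 1:]
    return binary & ~interior


def render_bmode(
    mask: np.ndarray,
    border_visibility: float,
    rng: np.random.Generator,
    pixel_spacing: float | None = None,
) -> np.ndarray:
    """Render a label map as a speckled, sector-shaped grayscale frame.

    Cavities are dark, tissue mid-gray, the myocardial ring bright, and the
    LV endocardial border is drawn as a bright rim of which a contiguous
    fraction ``1 - border_visibility`` (by boundary-pixel count, placed at a
    seeded random position) is replaced by tissue-level intensity, simulating
    endocardial dropout.  Around the dropped arc the signal-loss region
    extends ~5 mm across the border (the cavity edge fades to tissue level),
    so heavily degraded cines genuinely lose boundary definition rather than
    just the rim highlight.  Speckle is multiplicative with
    Rayleigh-distributed amplitude (unit mean).  Deterministic given the rng
    state.
    """
    if not (0.0 <= border_visibility <= 1.0):
        raise ValueError("border_visibility must lie in [0, 1]")
    n = mask.shape[0]
    if pixel_spacing is None:
        pixel_spacing = FOV_CM * 10.0 / n
    # speckle is drawn first so the same seed yields the same texture
    # regardless of the dropout settings
    speckle = rng.rayleigh(scale=math.sqrt(2.0 / math.pi), size=mask.shape)
    base = np.full(mask.shape, I_TISSUE, dtype=float)
    for lab in (schemes.LV, schemes.LA, schemes.RV, schemes.RA):
        base[mask == lab] = I_CAVITY
    base[mask == schemes.MYO] = I_MYO

    boundary = _endocardial_boundary(mask, schemes.LV)
    bidx = np.argwhere(boundary)
    if bidx.shape[0] > 0:
        base[boundary] = I_RIM
        n_drop = int(round((1.0 - border_visibility) * bidx.shape[0]))
        if n_drop > 0:
            centroid = bidx.mean(axis=0)
            theta = np.arctan2(bidx[:, 0] - centroid[0], bidx[:, 1] - centroid[1])
            order = np.argsort(theta, kind="stable")
            start = int(rng.integers(bidx.shape[0]))
            drop = order[(np.arange(n_drop) + start) % bidx.shape[0]]
            base[bidx[drop, 0], bidx[drop, 1]] = I_TISSUE
            # signal loss extends across the border: fade the surrounding
            # ~5 mm to tissue level so the edge truly disappears there
            halo_px = max(1, int(round(5.0 / pixel_spacing)))
            hole = np.zeros(mask.shape, dtype=bool)
            hole[bidx[drop, 0], bidx[drop, 1]] = True
            hole = ndimage.binary_dilation(hole, iterations=halo_px)
            base[hole] = I_TISSUE

    frame = np.clip(base * speckle, 0.0, 255.0)
    frame[~sector_mask(n, pixel_spacing)] = 0.0
    return frame.astype(np.uint8)


# ---------------------------------------------------------------------------
# cine + truth


def nominal_indices(spec: PhantomSpec) -> ClinicalIndices:
    """Closed-form clinical indices the phantom geometry was built from."""
    a, b_ed, _ = _lv_dimensions(spec)
    t = spec.wall_thickness / 10.0
    epi = math.pi * (b_ed + t) ** 2
    endo = math.pi * b_ed**2
    mass = lv_mass(epi, endo, 2.0 * a)
    return ClinicalIndices(
        la_volume=spec.nominal_lav,
        lv_edv=spec.nominal_edv,
        lv_esv=spec.nominal_esv,
        lv_mass=mass,
        ef=ejection_fraction(spec.nominal_edv, spec.nominal_esv),
    )


def generate_cine(spec: PhantomSpec) -> tuple[list[np.ndarray], PhantomTruth]:
    """Render all frames of one cine and assemble its ground truth."""
    phases = np.arange(spec.n_frames) / spec.n_frames
    masks = [generate_geometry(spec, p) for p in phases]
    rng = np.random.default_rng(spec.rng_seed)
    frames = [render_bmode(m, spec.border_visibility, rng, spec.pixel_spacing) for m in masks]
    areas = [int((m == schemes.LV).sum()) for m in masks]
    truth = PhantomTruth(
        masks=masks,
        ed_frame=int(np.argmax(areas)),
        es_frame=int(np.argmin(areas)),
        indices=nominal_indices(spec),
        spec=spec,
    )
    return frames, truth


# ---------------------------------------------------------------------------
# cohort generation


def allocate_quality(n: int, quality_mix) -> list[str]:
    """Largest-remainder allocation of n patients to good/fair/poor classes."""
    mix = np.asarray(quality_mix, dtype=float)
    if mix.shape != (3,) or (mix < 0).any() or abs(mix.sum() - 1.0) > 1e-9:
        raise ValueError("quality_mix must be 3 non-negative proportions summing to 1")
    raw = mix * n
    base = np.floor(raw).astype(int)
    rem = n - int(base.sum())
    frac_order = np.argsort(-(raw - base), kind="stable")
    for i in range(rem):
        base[frac_order[i]] += 1
    classes = ["good", "fair", "poor"]
    return [c for c, k in zip(classes, base) for _ in range(k)]


def _save_mask_png(mask: np.ndarray, path: Path):
    img = Image.fromarray(mask.astype(np.uint8), mode="P")
    palette = np.zeros((256, 3), dtype=np.uint8)
    colors = {0: (0, 0, 0), 1: (220, 40, 40), 2: (40, 100, 220), 3: (240, 200, 40),
              4: (40, 200, 120), 5: (180, 70, 200)}
    for code, rgb in colors.items():
        palette[code] = rgb
    img.putpalette(palette.ravel().tolist())
    img.save(path)


def generate_cohort(
    out_dir,
    n_patients: int,
    quality_mix=(0.5, 0.3, 0.2),
    seed: int = 0,
    image_size: int = 256,
    n_frames: int = 8,
    views=(View.A2C, View.A4C, View.PSAX),
    pixel_spacing: float | None = None,
) -> pd.DataFrame:
    """Write a synthetic cohort to disk and return its manifest.

    One cine per requested view per patient (frames + masks as PNG, a JSON
    sidecar with spacing/ED/ES/nominal indices).  Image-quality classes are
    assigned by deterministic largest-remainder allocation over
    ``quality_mix`` and shuffled across patients with the seeded rng;
    ``border_visibility`` is drawn uniformly inside the class band
    (good 0.67-1.00, fair 0.34-0.66, poor 0.00-0.33).  Per-patient physiology
    (EDV, EF, LA volume, wall thickness) is sampled around normal adult
    ranges.  Fully deterministic given ``seed``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    classes = allocate_quality(n_patients, quality_mix)
    classes = [classes[i] for i in rng.permutation(n_patients)]

    rows = []
    for p in range(n_patients):
        pid = f"P{p:04d}"
        quality = classes[p]
        lo, hi = QUALITY_BANDS[quality]
        bv = float(rng.uniform(lo, hi))
        edv = float(rng.uniform(90.0, 160.0))
        ef = float(rng.uniform(50.0, 70.0))
        esv = edv * (1.0 - ef / 100.0)
        lav = float(rng.uniform(0.25, 0.45)) * edv
        wall = float(rng.uniform(8.0, 12.0))
        for view in views:
            view = as_view(view)
            spec = PhantomSpec(
                patient_id=pid,
                view=view,
                n_frames=n_frames,
                image_size=image_size,
                pixel_spacing=pixel_spacing,
                nominal_edv=edv,
                nominal_esv=esv,
                nominal_lav=lav,
                wall_thickness=wall,
                border_visibility=bv,
                rng_seed=int(rng.integers(2**31 - 1)),
            )
            frames, truth = generate_cine(spec)
            cine_dir = out_dir / pid / view.value
            cine_dir.mkdir(parents=True, exist_ok=True)
            for k, (frame, m) in enumerate(zip(frames, truth.masks)):
                Image.fromarray(frame, mode="L").save(cine_dir / f"frame_{k:03d}.png")
                _save_mask_png(m, cine_dir / f"mask_{k:03d}.png")
            sidecar = {
                "patient_id": pid,
                "view": view.value,
                "pixel_spacing_mm": spec.pixel_spacing,
                "n_frames": spec.n_frames,
                "ed_frame": truth.ed_frame,
                "es_frame": truth.es_frame,
                "border_visibility": bv,
                "quality_class": quality,
                "nominal_indices": {
                    k: v for k, v in truth.indices.as_dict().items() if not k.startswith("flag_")
                },
            }
            (cine_dir / "cine.json").write_text(json.dumps(sidecar, indent=1, sort_keys=True))
            rows.append(
                {
                    "patient_id": pid,
                    "view": view.value,
                    "quality_class": quality,
                    "border_visibility": bv,
                    "n_frames": spec.n_frames,
                    "ed_frame": truth.ed_frame,
                    "es_frame": truth.es_frame,
                    "cine_dir": str(cine_dir.relative_to(out_dir)),
                }
            )
    manifest = pd.DataFrame(
        rows,
        columns=[
            "patient_id", "view", "quality_class", "border_visibility",
            "n_frames", "ed_frame", "es_frame", "cine_dir",
        ],
    )
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
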