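"""Clinical indices from chamber masks.

Implements the standard 2-D echo quantification chain: planar chamber area
and long-axis length from a label map, single/biplane area-length volumes

    V = (8 / 3*pi) * A1 * A2 / L        (biplane; A1 = A2 gives single-plane)

LV mass by the area-length method from PSAX endo/epicardial areas and the
apical long axis, scaled by myocardial density 1.05 g/ml, and ejection
fraction EF = 100 * (EDV - ESV) / EDV.

All areas are cm^2, lengths cm, volumes ml (= cm^3), mass g.  Masks are
integer label maps; stray disconnected pixels are discarded (largest
connected component per label) before any geometry is measured.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage import measure

from echoquant import schemes

MYOCARDIAL_DENSITY_G_PER_ML = 1.05


class GeometryError(ValueError):
    """Raised when a mask does not support the requested measurement."""


@dataclass
class ClinicalIndices:
    """The quantification report for one patient.

    ``la_volume`` ml, ``lv_edv``/``lv_esv`` ml, ``lv_mass`` g, ``ef`` percent.
    ``flags`` records degraded computations (e.g. single-plane fallback).
    """

    la_volume: float | None
    lv_edv: float | None
    lv_esv: float | None
    lv_mass: float | None
    ef: float | None
    flags: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "la_volume_ml": self.la_volume,
            "lv_edv_ml": self.lv_edv,
            "lv_esv_ml": self.lv_esv,
            "lv_mass_g": self.lv_mass,
            "ef_pct": self.ef,
            **{f"flag_{k}": v for k, v in self.flags.items()},
        }


def _spacing_yx(spacing) -> tuple[float, float]:
    """Normalize spacing (scalar or (sy, sx), mm/px) to a (sy, sx) pair."""
    arr = np.atleast_1d(np.asarray(spacing, dtype=float))
    if arr.size == 1:
        sy = sx = float(arr[0])
    elif arr.size == 2:
        sy, sx = float(arr[0]), float(arr[1])
    else:
        raise ValueError("spacing must be a scalar or a (sy, sx) pair")
    if sy <= 0 or sx <= 0:
        raise ValueError("pixel spacing must be positive")
    return sy, sx


def largest_component(mask: np.ndarray, label: int) -> np.ndarray:
    """Boolean mask of the largest connected component of ``label``.

    Returns an all-False array when the label is absent.
    """
    binary = np.asarray(mask) == label
    if not binary.any():
        return binary
    cc = measure.label(binary, connectivity=2)
    counts = np.bincount(cc.ravel())
    counts[0] = 0
    return cc == int(np.argmax(counts))


def chamber_area(mask: np.ndarray, label: int, spacing) -> float:
    """Physical area (cm^2) of the largest component of ``label`` in ``mask``."""
    sy, sx = _spacing_yx(spacing)
    comp = largest_component(mask, label)
    n = int(comp.sum())
    if n == 0:
        warnings.warn(f"label {label} absent from mask; area = 0", stacklevel=2)
        return 0.0
    return n * sy * sx / 100.0  # mm^2 -> cm^2


def long_axis_length(mask: np.ndarray, label: int, spacing) -> float:
    """Long-axis length (cm) of the largest component of ``label``.

    The principal axis is taken from the second-order moments of the pixel
    coordinates (in physical units, so anisotropic spacing is handled) and
    the length is the extent of the component projected on that axis, plus
    one pixel of extent to account for pixel footprints.
    """
    sy, sx = _spacing_yx(spacing)
    comp = largest_component(mask, label)
    coords = np.argwhere(comp).astype(float)
    if coords.shape[0] < 3:
        raise GeometryError(f"label {label}: fewer than 3 pixels, no axis defined")
    phys = coords * np.array([sy, sx])  # mm
    centered = phys - phys.mean(axis=0)
    cov = centered.T @ centered / centered.shape[0]
    eigvals, eigvecs = np.linalg.eigh(cov)
    axis = eigvecs[:, int(np.argmax(eigvals))]
    proj = centered @ axis
    # extent of one pixel along the axis direction
    pixel_extent = abs(axis[0]) * sy + abs(axis[1]) * sx
    return (proj.max() - proj.min() + pixel_extent) / 10.0  # mm -> cm


def biplane_area_length_volume(area_a2c: float, area_a4c: float, long_axis: float) -> float:
    """Biplane area-length volume (ml): V = (8/3pi) * A_a2c * A_a4c / L."""
    if long_axis <= 0:
        raise GeometryError("long axis must be positive")
    if area_a2c < 0 or area_a4c < 0:
        raise GeometryError("areas must be non-negative")
    return 8.0 / (3.0 * math.pi) * area_a2c * area_a4c / long_axis


def single_plane_area_length_volume(area: float, long_axis: float) -> float:
    """Single-plane area-length volume (ml): V = (8/3pi) * A^2 / L."""
    return biplane_area_length_volume(area, area, long_axis)


def lv_mass(epi_area: float, endo_area: float, long_axis: float) -> float:
    """LV mass (g) by the area-length method.

    ``epi_area``/``endo_area`` are the PSAX epicardial and endocardial
    cross-sectional areas (cm^2) at the papillary-muscle level, ``long_axis``
    the apical LV long axis (cm).  Mean wall thickness
    t = sqrt(epi/pi) - sqrt(endo/pi); myocardial volume
    Vm = 5/6 * [epi * (L + t) - endo * L]; mass = 1.05 * Vm.
    """
    if endo_area < 0:
        raise GeometryError("endocardial area must be non-negative")
    if epi_area <= endo_area:
        raise GeometryError("epicardial area must exceed endocardial area (non-physical ring)")
    if long_axis <= 0:
        raise GeometryError("long axis must be positive")
    t = math.sqrt(epi_area / math.pi) - math.sqrt(endo_area / math.pi)
    vm = 5.0 / 6.0 * (epi_area * (long_axis + t) - endo_area * long_axis)
    return MYOCARDIAL_DENSITY_G_PER_ML * vm


def ejection_fraction(edv: float, esv: float) -> float:
    """Ejection fraction in percent, 100 * (EDV - ESV) / EDV."""
    if edv <= 0:
        raise GeometryError("EDV must be positive")
    return 100.0 * (edv - esv) / edv


def _paired_volume(masks: dict, label: int, phase: str, spacing_of, flags: dict, flag_key: str):
    """Biplane volume from A2C+A4C masks at one phase; single-plane fallback."""
    areas, axes = {}, {}
    for view in ("A2C", "A4C"):
        m = masks.get((view, phase))
        if m is None:
            continue
        sp = spacing_of(view)
        a = chamber_area(m, label, sp)
        if a <= 0:
            continue
        try:
            axis = long_axis_length(m, label, sp)
        except GeometryError:
            # a handful of stray pixels: treat the structure as absent
            continue
        areas[view] = a
        axes[view] = axis
    if not areas:
        return None
    if len(areas) == 2:
        length = min(axes.values())
        return biplane_area_length_volume(areas["A2C"], areas["A4C"], length)
    view = next(iter(areas))
    warnings.warn(
        f"only {view} available for label {label} at {phase}; single-plane volume", stacklevel=3
    )
    flags[flag_key] = True
    return single_plane_area_length_volume(areas[view], axes[view])


def compute_indices(masks: dict, spacing) -> ClinicalIndices:
    """Assemble the clinical-index report from per-view ED/ES masks.

    Parameters
    ----------
    masks : dict
        Keys are ``(view, phase)`` pairs with view in {"A2C", "A4C", "PSAX"}
        and phase in {"ED", "ES"}; values are integer label maps.  Expected
        entries: A2C/A4C at ED and ES, PSAX at ED.  Missing apical views
        degrade to single-plane volumes (flagged); missing PSAX suppresses
        the mass.
    spacing : scalar, (sy, sx) pair, or dict view -> spacing (mm/px).

    Notes
    -----
    LV volumes use the biplane area-length method at ED and ES with
    L = min of the two views' long axes.  LA volume is measured at
    ventricular end-systole (maximal LA).  LV mass combines PSAX ED
    endo/epicardial areas with the A4C ED long axis.
    """
    if isinstance(spacing, dict):
        spacing_of = lambda view: spacing[view]  # noqa: E731
    else:
        spacing_of = lambda view: spacing  # noqa: E731

    flags: dict = {}
    edv = _paired_volume(masks, schemes.LV, "ED", spacing_of, flags, "single_plane_lv")
    esv = _paired_volume(masks, schemes.LV, "ES", spacing_of, flags, "single_plane_lv")
    lav = _paired_volume(masks, schemes.LA, "ES", spacing_of, flags, "single_plane_la")

    mass = None
    psax = masks.get(("PSAX", "ED"))
    apical_ed = masks.get(("A4C", "ED"))
    apical_view = "A4C"
    if apical_ed is None:
        apical_ed = masks.get(("A2C", "ED"))
        apical_view = "A2C"
    if psax is not None and apical_ed is not None:
        sp = spacing_of("PSAX")
        endo = chamber_area(psax, schemes.LV, sp)
        myo = chamber_area(psax, schemes.MYO, sp)
        if myo > 0 and endo >= 0:
            try:
                length = long_axis_length(apical_ed, schemes.LV, spacing_of(apical_view))
                mass = lv_mass(endo + myo, endo, length)
            except GeometryError:
                mass = None
    if mass is None:
        flags["mass_missing"] = True

    ef = None
    if edv is not None and esv is not None and edv > 0:
        ef = ejection_fraction(edv, esv)

    return ClinicalIndices(la_volume=lav, lv_edv=edv, lv_esv=esv, lv_mass=mass, ef=ef, flags=flags)
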