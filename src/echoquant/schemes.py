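"""Echocardiographic views and their integer label schemes.

Chamber label codes are global (a code means the same structure in every
view); each view exposes only the subset of structures that is visible and
annotated in that view:

* A2C: LV cavity (1), LA cavity (2)
* A4C: LV (1), LA (2), RV (3), RA (4)
* PSAX (papillary-muscle level): LV cavity (1), LV myocardium ring (5)
"""

from __future__ import annotations

import enum

BACKGROUND = 0
LV = 1
LA = 2
RV = 3
RA = 4
MYO = 5

LABEL_NAMES = {
    BACKGROUND: "background",
    LV: "lv_cavity",
    LA: "la_cavity",
    RV: "rv_cavity",
    RA: "ra_cavity",
    MYO: "lv_myocardium",
}


class View(str, enum.Enum):
    """Standard 2-D echo views handled by the pipeline."""

    A2C = "A2C"
    A4C = "A4C"
    PSAX = "PSAX"


class ViewError(ValueError):
    """Raised for an unknown or unsupported view tag."""


_SCHEMES = {
    View.A2C: (BACKGROUND, LV, LA),
    View.A4C: (BACKGROUND, LV, LA, RV, RA),
    View.PSAX: (BACKGROUND, LV, MYO),
}


def as_view(view) -> View:
    """Coerce a string or View to a View, raising ViewError if unknown."""
    try:
        return View(view)
    except ValueError as exc:
        raise ViewError(f"unknown view {view!r}; expected one of {[v.value for v in View]}") from exc


def label_scheme(view) -> tuple[int, ...]:
    """Valid label codes for ``view`` (background included), ascending."""
    return _SCHEMES[as_view(view)]


def class_codes(view) -> tuple[int, ...]:
    """Alias of :func:`label_scheme`; index in this tuple = network class channel."""
    return label_scheme(view)


def n_classes(view) -> int:
    return len(label_scheme(view))
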