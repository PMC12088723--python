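"""Tissue label codes shared by every stage.

A cross-section mask is an indexed image: each pixel carries one integer
code. The three plaque tissue classes validated against histology are
fibrotic (FT), calcific (Ca) and necrotic core (NC); lumen and background
complete the grid. Classifier outputs that report "lipid" are remapped to
NC on load (lipid detected chemically/optically is taken to correspond to
histological necrotic core).
"""

from __future__ import annotations

BACKGROUND = 0
LUMEN = 1
FT = 2
CA = 3
NC = 4
MACROPHAGE = 5

#: canonical name -> code registry for masks written by this package
DEFAULT_CODES: dict[str, int] = {
    "background": BACKGROUND,
    "lumen": LUMEN,
    "FT": FT,
    "Ca": CA,
    "NC": NC,
    "macrophage": MACROPHAGE,
}

#: fixed class order used by every confusion matrix (rows = histology)
TISSUE_CLASSES: tuple[str, ...] = ("FT", "Ca", "NC")
TISSUE_CODES: tuple[int, ...] = (FT, CA, NC)

#: tie-break priority for "predominant tissue", mirroring the histology
#: precedence rule (overlapping Ca/NC regions are classified as Ca)
PREDOMINANCE_PRIORITY: tuple[int, ...] = (CA, NC, FT)

#: alias names accepted on load and remapped to a canonical class
LOAD_ALIASES: dict[str, str] = {
    "lipid": "NC",
    "fibrotic": "FT",
    "calcific": "Ca",
    "necrotic core": "NC",
    "calcium": "Ca",
}


def code_for_class(name: str) -> int:
    """Return the canonical code for a class name (aliases accepted)."""
    canonical = LOAD_ALIASES.get(name.lower(), name)
    canonical = LOAD_ALIASES.get(canonical, canonical)
    if canonical not in DEFAULT_CODES:
        raise KeyError(f"unknown tissue class name {name!r}")
    return DEFAULT_CODES[canonical]
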