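"""Central / peripheral lung regions from a lung mask.

The central region of a sagittal lung slice is a rectangle of half the
width and half the height of the lung's bounding box, placed inside the
bounding box; the peripheral region is every lung pixel outside it.
Regional physical volumes ("pulmonary thoracic space") follow from voxel
counts and voxel geometry.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Tuple

import numpy as np

Anchor = Literal["centered", "anterior", "posterior", "superior", "inferior"]

#: row axis = superior->inferior, column axis = posterior->anterior, by
#: radiological convention for a sagittal slice stored as (row, col).
_VALID_ANCHORS = ("centered", "anterior", "posterior", "superior", "inferior")


@dataclass(frozen=True)
class RegionMasks:
    """Central/peripheral partition of a lung mask.

    Attributes
    ----------
    lung_mask, central_mask, peripheral_mask : ndarray of bool
        ``central_mask | peripheral_mask == lung_mask`` and the two
        regions are disjoint by construction.
    bounding_box : tuple
        ``(row0, col0, height, width)`` of the lung's bounding box,
        0-based, half-open.
    anchor : str
        Placement rule used for the central rectangle.
    """

    lung_mask: np.ndarray
    central_mask: np.ndarray
    peripheral_mask: np.ndarray
    bounding_box: Tuple[int, int, int, int]
    anchor: str


def _central_rect(row0: int, col0: int, h: int, w: int, anchor: str):
    """0-based half-open central rectangle of floor-half dimensions.

    For odd bounding-box sides the central side rounds down and, when
    centered, the spare margin goes to the high-index side.
    """
    ch, cw = h // 2, w // 2
    if anchor == "centered":
        r0 = row0 + (h - ch) // 2
        c0 = col0 + (w - cw) // 2
    elif anchor == "superior":  # low row index
        r0, c0 = row0, col0 + (w - cw) // 2
    elif anchor == "inferior":  # high row index
        r0, c0 = row0 + h - ch, col0 + (w - cw) // 2
    elif anchor == "posterior":  # low column index
        r0, c0 = row0 + (h - ch) // 2, col0
    elif anchor == "anterior":  # high column index
        r0, c0 = row0 + (h - ch) // 2, col0 + w - cw
    else:  # pragma: no cover - guarded by caller
        raise ValueError(f"unknown anchor {anchor!r}")
    return r0, c0, ch, cw


def define_regions(lung_mask: np.ndarray, anchor: Anchor = "centered") -> RegionMasks:
    """Partition a 2D lung mask into central and peripheral regions.

    Parameters
    ----------
    lung_mask : 2D ndarray of bool
        One connected lung per call (one sagittal slice).
    anchor : str
        Where the central rectangle sits inside the bounding box.
        ``"centered"`` (default) centres it; the directional anchors
        abut it against one edge of the bounding box.

    Returns
    -------
    RegionMasks

    Raises
    ------
    ValueError
        If the mask is empty or its bounding box smaller than 2x2.
    """
    lung_mask = np.asarray(lung_mask, dtype=bool)
    if lung_mask.ndim != 2:
        raise ValueError("lung_mask must be 2D (one sagittal slice per call)")
    if anchor not in _VALID_ANCHORS:
        raise ValueError(f"anchor must be one of {_VALID_ANCHORS}, got {anchor!r}")
    rows = np.flatnonzero(lung_mask.any(axis=1))
    cols = np.flatnonzero(lung_mask.any(axis=0))
    if rows.size == 0:
        raise ValueError("empty lung mask")
    row0, col0 = int(rows[0]), int(cols[0])
    h = int(rows[-1]) - row0 + 1
    w = int(cols[-1]) - col0 + 1
    if h < 2 or w < 2:
        raise ValueError(f"lung mask bounding box {h}x{w} smaller than 2x2")

    r0, c0, ch, cw = _central_rect(row0, col0, h, w, anchor)
    rect = np.zeros_like(lung_mask)
    rect[r0 : r0 + ch, c0 : c0 + cw] = True
    central = lung_mask & rect
    peripheral = lung_mask & ~rect
    return RegionMasks(
        lung_mask=lung_mask,
        central_mask=central,
        peripheral_mask=peripheral,
        bounding_box=(row0, col0, h, w),
        anchor=anchor,
    )


def region_volume(mask: np.ndarray, voxel_dims_mm: Tuple[float, float, float]) -> float:
    """Physical volume of a voxel mask, in litres.

    ``count(mask) * dx * dy * dz / 1e6``, with voxel dims in mm.
    """
    dx, dy, dz = voxel_dims_mm
    if dx <= 0 or dy <= 0 or dz <= 0:
        raise ValueError(f"voxel dims must be positive, got {voxel_dims_mm}")
    return float(np.count_nonzero(mask)) * dx * dy * dz / 1e6
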