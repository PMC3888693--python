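"""RNFL thickness-map reconstruction from segmented OCT B-scans.

An OCT volume samples the retina with 61–121 parallel B-scans; in each
B-scan the inner limiting membrane (ILM) and the outer nerve fiber layer
boundary (ONFL) are segmented, and their axial separation times the axial
pixel pitch gives the nerve-fiber-layer thickness in µm along that scan
line.  Because the B-scans sample only a sparse set of SLO rows, a dense
thickness raster on the SLO grid is obtained by interpolating column-wise
between scan rows (linear "bilinear" or cubic-spline interpolation — both
are exact at the scan rows themselves).  The optic-disc region contains no
RNFL and is masked out, as are rows outside the scanned band.

Segmentation itself (and its manual correction) is upstream of this package;
boundary curves are consumed as input.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

__all__ = [
    "BScanBoundaries",
    "ThicknessMap",
    "BoundaryOrderError",
    "InvalidWindowError",
    "thickness_from_boundaries",
    "interpolate_map",
    "sample_troi",
]

DEFAULT_TROI_PX = 7


class BoundaryOrderError(ValueError):
    """ONFL lies above ILM somewhere — physically impossible segmentation."""


class InvalidWindowError(ValueError):
    """A thickness sampling window touches masked (invalid) pixels."""


@dataclass
class BScanBoundaries:
    """Segmented boundary curves of one B-scan.

    ``ilm`` and ``onfl`` are per-column boundary depths in axial pixels
    (depth grows downward, so ONFL ≥ ILM everywhere); ``row_position`` is the
    SLO row the scan line crosses; ``axial_scale_um`` converts axial pixels
    to µm.  B-scan columns are assumed to align with SLO columns.
    """

    row_position: float
    ilm: np.ndarray
    onfl: np.ndarray
    axial_scale_um: float

    def __post_init__(self) -> None:
        self.ilm = np.asarray(self.ilm, dtype=float)
        self.onfl = np.asarray(self.onfl, dtype=float)
        if self.ilm.shape != self.onfl.shape or self.ilm.ndim != 1:
            raise ValueError("ilm and onfl must be 1-D arrays of equal length")
        if self.axial_scale_um <= 0:
            raise ValueError("axial_scale_um must be positive")


@dataclass
class ThicknessMap:
    """Dense RNFL thickness raster (µm) on the SLO grid with validity mask."""

    values_um: np.ndarray
    valid_mask: np.ndarray

    def __post_init__(self) -> None:
        self.values_um = np.asarray(self.values_um, dtype=float)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.values_um.shape != self.valid_mask.shape:
            raise ValueError("values and mask shapes differ")
        if np.any(self.values_um[self.valid_mask] < 0):
            raise ValueError("negative thickness inside the valid region")


def thickness_from_boundaries(b: BScanBoundaries) -> np.ndarray:
    """Per-column RNFL thickness (onfl − ilm) · axial_scale_um, in µm."""
    diff = b.onfl - b.ilm
    bad = np.flatnonzero(diff < 0)
    if bad.size:
        raise BoundaryOrderError(
            f"ONFL above ILM at columns {bad.tolist()[:20]}"
            + ("…" if bad.size > 20 else "")
        )
    return diff * b.axial_scale_um


def interpolate_map(
    scans: list[BScanBoundaries],
    slo_shape: tuple[int, int],
    method: str = "bilinear",
    od_center: tuple[float, float] | None = None,
    od_radius: float | None = None,
) -> ThicknessMap:
    """Reconstruct a dense thickness map on the SLO grid from B-scan profiles.

    Thickness profiles are stacked at their scan rows and interpolated
    column-wise across rows ("bilinear": linear in row; "spline": natural
    cubic).  Both methods reproduce the profiles exactly at the scan rows.
    Rows outside [first, last] scan row are invalid, as is the optic-disc
    disk given by ``od_center``/``od_radius`` (SLO coordinates, row/col).
    """
    if len(scans) < 2:
        raise ValueError("need at least two B-scans to interpolate between rows")
    if method not in ("bilinear", "spline"):
        raise ValueError("method must be 'bilinear' or 'spline'")
    rows = np.array([s.row_position for s in scans], dtype=float)
    if np.any(np.diff(rows) <= 0):
        raise ValueError("B-scan row positions must be strictly increasing")
    H, W = slo_shape
    if rows[0] < 0 or rows[-1] > H - 1:
        raise ValueError("B-scan rows fall outside the SLO raster")
    profiles = np.vstack([thickness_from_boundaries(s) for s in scans])
    if profiles.shape[1] != W:
        raise ValueError(
            f"boundary curves span {profiles.shape[1]} columns, SLO has {W}"
        )

    grid_rows = np.arange(H, dtype=float)
    if method == "bilinear":
        values = np.empty((H, W))
        for j in range(W):  # np.interp clamps outside; masked below anyway
            values[:, j] = np.interp(grid_rows, rows, profiles[:, j])
    else:
        values = CubicSpline(rows, profiles, axis=0, bc_type="natural")(grid_rows)
        np.clip(values, 0.0, None, out=values)

    valid = (grid_rows >= rows[0]) & (grid_rows <= rows[-1])
    valid_mask = np.repeat(valid[:, None], W, axis=1)
    if od_center is not None and od_radius is not None:
        rr, cc = np.indices((H, W))
        inside_od = (rr - od_center[0]) ** 2 + (cc - od_center[1]) ** 2 <= od_radius**2
        valid_mask &= ~inside_od
    return ThicknessMap(values, valid_mask)


def sample_troi(
    tmap: ThicknessMap,
    center: tuple[int, int],
    window_px: int = DEFAULT_TROI_PX,
) -> float:
    """Mean thickness over a square window centered at ``center`` (row, col).

    Raises :class:`InvalidWindowError` if the window leaves the raster or
    touches any invalid pixel, naming whether the optic-disc mask or the
    out-of-scan region is responsible.
    """
    if window_px % 2 == 0:
        raise ValueError("window_px must be odd")
    half = (window_px - 1) // 2
    r, c = int(round(center[0])), int(round(center[1]))
    H, W = tmap.values_um.shape
    if r - half < 0 or c - half < 0 or r + half >= H or c + half >= W:
        raise InvalidWindowError(
            f"tROI window at ({r}, {c}) exceeds the thickness raster bounds"
        )
    sl = (slice(r - half, r + half + 1), slice(c - half, c + half + 1))
    mask = tmap.valid_mask[sl]
    if not mask.all():
        raise InvalidWindowError(
            f"tROI window at ({r}, {c}) covers {int((~mask).sum())} invalid "
            "pixels (optic-disc mask or outside the scanned band)"
        )
    return float(tmap.values_um[sl].mean())
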