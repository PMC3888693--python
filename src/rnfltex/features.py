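"""First-order histogram texture features from peripapillary ROIs.

The texture of the retinal nerve fiber layer is summarized per region of
interest (ROI) by five statistics of the ROI's intensity histogram: mean µ,
standard deviation σ, Shannon entropy E (bits), skewness γ1 and excess
kurtosis γ2.  First-order statistics depend only on individual pixel values,
never on their spatial arrangement, which keeps their interpretation direct:
µ tracks reflected intensity, σ the magnitude of striation contrast, E the
shape of the intensity distribution.

ROIs are square windows (default 41 × 41 px) placed around the optic disc and
must avoid blood vessels and capillaries, whose dark profiles would otherwise
dominate every statistic; an exclusion mask enforces this.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .preprocess import ChannelImage

__all__ = [
    "FEATURE_NAMES",
    "RoiSample",
    "FeatureVector",
    "RoiRejection",
    "extract_rois",
    "histogram",
    "first_order_features",
    "propose_roi_centers",
    "FirstOrderFeatures",
]

FEATURE_NAMES = ("mu", "sigma", "entropy", "skewness", "kurtosis")

DEFAULT_ROI_PX = 41
DEFAULT_N_BINS = 256


@dataclass
class RoiSample:
    """A square ROI cut from one channel image."""

    center: tuple[int, int]  # (row, col)
    size_px: int
    channel: str
    pixels: np.ndarray
    value_range: tuple[float, float] | None = None  # intensity range for binning

    def __post_init__(self) -> None:
        if self.size_px % 2 == 0:
            raise ValueError("ROI size must be odd so the center pixel exists")
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.shape != (self.size_px, self.size_px):
            raise ValueError(
                f"pixel block {self.pixels.shape} does not match size {self.size_px}"
            )


@dataclass
class FeatureVector:
    """The five first-order features of one ROI.

    ``skewness`` and ``kurtosis`` are NaN (flagged undefined, never an
    exception) when the ROI is constant (σ = 0).  ``kurtosis`` is *excess*
    kurtosis, µ4/µ2² − 3, so a Gaussian histogram scores 0.
    """

    mu: float
    sigma: float
    entropy: float
    skewness: float
    kurtosis: float
    channel: str = ""

    def as_array(self) -> np.ndarray:
        return np.array([self.mu, self.sigma, self.entropy, self.skewness, self.kurtosis])


@dataclass
class RoiRejection:
    center: tuple[int, int]
    reason: str


def _window_bounds(center, size_px):
    half = (size_px - 1) // 2
    r, c = int(center[0]), int(center[1])
    return r - half, r + half + 1, c - half, c + half + 1


def extract_rois(
    channel: ChannelImage,
    centers,
    vessel_mask: np.ndarray | None = None,
    size_px: int = DEFAULT_ROI_PX,
) -> tuple[list[RoiSample], list[RoiRejection]]:
    """Cut square ROIs at ``centers``, dropping inadmissible ones with a reason.

    A center is admissible when its full ``size_px`` window lies inside the
    raster and, if ``vessel_mask`` is given, contains no vessel pixel.
    Returns the admissible samples and the rejections (center + reason).

    Raises
    ------
    ValueError
        If *no* center is admissible — an empty feature set is always a
        protocol error worth surfacing.
    """
    if size_px % 2 == 0:
        raise ValueError("ROI size must be odd")
    img = channel.pixels
    if vessel_mask is not None:
        vessel_mask = np.asarray(vessel_mask, dtype=bool)
        if vessel_mask.shape != img.shape:
            raise ValueError("vessel mask shape must match the channel raster")

    samples: list[RoiSample] = []
    rejected: list[RoiRejection] = []
    vrange = (0.0, channel.max_value)
    for center in centers:
        r0, r1, c0, c1 = _window_bounds(center, size_px)
        if r0 < 0 or c0 < 0 or r1 > img.shape[0] or c1 > img.shape[1]:
            rejected.append(RoiRejection(tuple(center), "window exceeds raster bounds"))
            continue
        if vessel_mask is not None and vessel_mask[r0:r1, c0:c1].any():
            rejected.append(RoiRejection(tuple(center), "window overlaps vessel mask"))
            continue
        samples.append(
            RoiSample(
                center=(int(center[0]), int(center[1])),
                size_px=size_px,
                channel=channel.channel,
                pixels=img[r0:r1, c0:c1].copy(),
                value_range=vrange,
            )
        )
    if not samples:
        raise ValueError(
            f"no admissible ROI among {len(rejected)} candidate centers "
            f"(reasons: {sorted({r.reason for r in rejected})})"
        )
    return samples, rejected


def _resolve_block(roi) -> tuple[np.ndarray, tuple[float, float] | None]:
    if isinstance(roi, RoiSample):
        return roi.pixels, roi.value_range
    return np.asarray(roi, dtype=float), None


def _quantize(block: np.ndarray, n_bins: int, value_range) -> tuple[np.ndarray, np.ndarray]:
    """Uniformly quantize intensities to ``n_bins`` gray levels.

    Levels are evenly spaced over ``value_range`` (default: the block's own
    min/max) and assignment is nearest-level, so integer data on [0, n_bins-1]
    maps each value to its own level exactly.  Returns (level index per pixel,
    representative intensity per level).
    """
    if value_range is None:
        value_range = (float(block.min()), float(block.max()))
    lo, hi = map(float, value_range)
    if hi <= lo:  # constant block / degenerate range: a single occupied level
        return np.zeros(block.size, dtype=np.intp), np.array([lo])
    levels = np.linspace(lo, hi, n_bins)
    idx = np.rint((block.ravel() - lo) / (hi - lo) * (n_bins - 1)).astype(np.intp)
    np.clip(idx, 0, n_bins - 1, out=idx)
    return idx, levels


def histogram(roi, n_bins: int = DEFAULT_N_BINS, value_range=None):
    """Probability histogram H(g) = n_g / N of a ROI's gray levels.

    Returns ``(H, levels)`` where ``H`` sums to 1 over occupied and empty bins
    alike and ``levels`` holds each bin's representative intensity g.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    block, default_range = _resolve_block(roi)
    if value_range is None:
        value_range = default_range
    idx, levels = _quantize(block, n_bins, value_range)
    counts = np.bincount(idx, minlength=len(levels))
    return counts / block.size, levels


def first_order_features(
    roi, n_bins: int = DEFAULT_N_BINS, value_range=None, channel: str = ""
) -> FeatureVector:
    """Compute µ, σ, E, γ1, γ2 from a ROI's intensity histogram.

    All five statistics are moments or functionals of H(g):

        µ  = Σ g·H(g)
        σ  = sqrt(Σ (g−µ)²·H(g))
        E  = −Σ H(g)·log2 H(g)          (0·log 0 ≡ 0)
        γ1 = µ3 / µ2^(3/2)
        γ2 = µ4 / µ2² − 3               (excess kurtosis)

    where µn = Σ (g−µ)^n H(g).  For constant ROIs σ = 0 and γ1, γ2 are
    returned as NaN.
    """
    H, g = histogram(roi, n_bins=n_bins, value_range=value_range)
    if isinstance(roi, RoiSample) and not channel:
        channel = roi.channel

    mu = float(np.dot(g, H))
    d = g - mu
    mu2 = float(np.dot(d**2, H))
    mu3 = float(np.dot(d**3, H))
    mu4 = float(np.dot(d**4, H))

    nz = H > 0
    entropy = float(-np.dot(H[nz], np.log2(H[nz])))

    if mu2 <= 0:
        skew = kurt = math.nan
    else:
        skew = mu3 / mu2**1.5
        kurt = mu4 / mu2**2 - 3.0
    return FeatureVector(mu, math.sqrt(max(mu2, 0.0)), entropy, skew, kurt, channel)


def propose_roi_centers(
    shape,
    od_center,
    od_radius: float,
    n: int,
    rng: np.random.Generator,
    vessel_mask: np.ndarray | None = None,
    size_px: int = DEFAULT_ROI_PX,
    r_min_factor: float = 1.4,
    r_max_factor: float = 4.0,
    max_tries: int = 50000,
) -> list[tuple[int, int]]:
    """Propose ROI centers in an annulus around the optic disc.

    Mirrors the manual placement protocol: windows sit in the peripapillary
    region (between ``r_min_factor``·r_od and ``r_max_factor``·r_od,
    i.e. roughly within two disc diameters), fully inside the raster and free
    of vessel pixels.  Sampling is rejection-based from ``rng``; raises if the
    annulus cannot host ``n`` windows.
    """
    from scipy import ndimage

    half = (size_px - 1) // 2
    if vessel_mask is not None:
        # a center is blocked if any vessel pixel falls in its window
        blocked = ndimage.maximum_filter(
            vessel_mask.astype(np.uint8), size=size_px, mode="constant"
        ).astype(bool)
    else:
        blocked = np.zeros(shape, dtype=bool)

    centers: list[tuple[int, int]] = []
    r_lo, r_hi = r_min_factor * od_radius, r_max_factor * od_radius
    for _ in range(max_tries):
        if len(centers) >= n:
            break
        rad = rng.uniform(r_lo, r_hi)
        ang = rng.uniform(0, 2 * np.pi)
        r = int(round(od_center[0] + rad * np.sin(ang)))
        c = int(round(od_center[1] + rad * np.cos(ang)))
        if r - half < 0 or c - half < 0 or r + half >= shape[0] or c + half >= shape[1]:
            continue
        if blocked[r, c]:
            continue
        sep = max(half // 2, 1)  # windows may overlap, but not pile up
        if any(abs(r - rr) < sep and abs(c - cc) < sep for rr, cc in centers):
            continue
        centers.append((r, c))
    if len(centers) < n:
        raise ValueError(
            f"could only place {len(centers)}/{n} vessel-free ROI windows; "
            "raster too small or annulus too crowded"
        )
    return centers


class FirstOrderFeatures(TransformerMixin, BaseEstimator):
    """Sklearn-style transformer: ROI pixel blocks → (n, 5) feature matrix.

    Parameters
    ----------
    n_bins : int
        Number of gray levels for the histogram estimate.  Entropy scales
        with binning, so comparisons are only meaningful at a fixed n_bins.
    value_range : tuple or None
        Intensity range spanned by the bins; None uses each block's own
        min/max (shift-invariant σ and E, per-block µ scale).

    The transformer is stateless; ``fit`` only validates input.  Column order
    follows :data:`FEATURE_NAMES`.
    """

    def __init__(self, n_bins: int = DEFAULT_N_BINS, value_range=None):
        self.n_bins = n_bins
        self.value_range = value_range

    @staticmethod
    def _as_blocks(X):
        if isinstance(X, np.ndarray) and X.ndim == 3:
            return list(X)
        return list(X)

    def fit(self, X, y=None):
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        blocks = self._as_blocks(X)
        if not blocks:
            raise ValueError("need at least one ROI block")
        self.n_features_in_ = 1
        return self

    def transform(self, X):
        blocks = self._as_blocks(X)
        rows = [
            first_order_features(b, n_bins=self.n_bins, value_range=self.value_range).as_array()
            for b in blocks
        ]
        return np.vstack(rows)

    def get_feature_names_out(self, input_features=None):
        return np.asarray(FEATURE_NAMES, dtype=object)
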