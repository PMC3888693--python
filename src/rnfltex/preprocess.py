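"""Fundus preprocessing: per-channel CLAHE and channel-image generation.

A color fundus photograph is split into its red (R), green (G) and blue (B)
channels, each channel is contrast-normalized with contrast-limited adaptive
histogram equalization (CLAHE), and a fourth grayscale image GB is formed as
the arithmetic mean of the enhanced G and B channels.  The GB image emulates
red-free fundus imaging (the green-blue band matches rhodopsin absorption
around 500 nm) and is the main substrate for nerve-fiber texture analysis.

All routines assume *linear* intensities, i.e. rasters decoded with linear
gamma so that pixel value is proportional to reflected light.  Texture
features extracted from gamma-compressed images relate to tissue differently;
callers working with nonlinear data must opt in explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from skimage import exposure

__all__ = ["ChannelImage", "NonlinearInputError", "clahe_enhance", "make_channels"]

#: Channel tags understood by the rest of the package.
CHANNELS = ("R", "G", "B", "GB")

DEFAULT_TILE_PX = 20  # tile edge for CLAHE; interpolated between tiles
DEFAULT_CLIP_LIMIT = 0.01  # fraction of tile pixel count


class NonlinearInputError(ValueError):
    """Raised when a gamma-compressed raster is passed without an override."""


@dataclass
class ChannelImage:
    """A single-channel 2-D intensity raster with provenance metadata.

    Parameters
    ----------
    pixels
        2-D float array; values live in ``[0, 2**bit_depth - 1]``.
    channel
        One of ``"R" | "G" | "B" | "GB"``.
    bit_depth
        Nominal bit depth of the source raster; defines the intensity range.
    linear
        True if the intensities are linear in reflected light (linear gamma).
    """

    pixels: np.ndarray
    channel: str
    bit_depth: int = 16
    linear: bool = True

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("ChannelImage.pixels must be a 2-D raster")
        if self.channel not in CHANNELS:
            raise ValueError(f"channel must be one of {CHANNELS}, got {self.channel!r}")
        if self.pixels.size and (
            self.pixels.min() < 0 or self.pixels.max() > self.max_value
        ):
            raise ValueError(
                f"pixel values outside [0, {self.max_value}] for bit depth "
                f"{self.bit_depth}"
            )

    @property
    def max_value(self) -> float:
        return float(2**self.bit_depth - 1)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


def clahe_enhance(
    channel: ChannelImage | np.ndarray,
    tile_px: int = DEFAULT_TILE_PX,
    clip_limit: float = DEFAULT_CLIP_LIMIT,
    n_bins: int = 256,
) -> ChannelImage | np.ndarray:
    """Contrast-limited adaptive histogram equalization of one channel.

    The image is partitioned into ``tile_px`` × ``tile_px`` tiles; each tile's
    histogram is equalized with clipping at ``clip_limit`` (expressed as a
    fraction of the tile pixel count), and the per-tile intensity mappings are
    bilinearly interpolated so tile boundaries leave no step artifacts.  The
    output occupies the same intensity range as the input.

    Accepts either a bare 2-D array or a :class:`ChannelImage` and returns the
    same kind.  Constant images are returned unchanged (degenerate histogram:
    there is no contrast to redistribute).
    """
    if isinstance(channel, ChannelImage):
        out = clahe_enhance(channel.pixels / channel.max_value, tile_px, clip_limit, n_bins)
        return replace(channel, pixels=np.asarray(out) * channel.max_value)

    img = np.asarray(channel, dtype=float)
    if img.ndim != 2:
        raise ValueError("clahe_enhance expects a single-channel 2-D raster")
    if tile_px < 2:
        raise ValueError("tile_px must be >= 2")
    if tile_px > min(img.shape):
        raise ValueError(
            f"tile {tile_px} px exceeds image extent {min(img.shape)} px"
        )

    lo, hi = float(img.min()), float(img.max())
    if hi == lo:  # constant image: equalization is a no-op
        return img.copy()

    # equalize_adapthist wants floats in [0, 1]; map there and back so the
    # output range equals the input range.
    norm = (img - lo) / (hi - lo)
    eq = exposure.equalize_adapthist(
        norm, kernel_size=tile_px, clip_limit=clip_limit, nbins=n_bins
    )
    return eq * (hi - lo) + lo


def make_channels(
    rgb: np.ndarray,
    tile_px: int = DEFAULT_TILE_PX,
    clip_limit: float = DEFAULT_CLIP_LIMIT,
    bit_depth: int = 16,
    linear: bool = True,
    allow_nonlinear: bool = False,
) -> dict[str, ChannelImage]:
    """Split an RGB fundus raster into CLAHE-enhanced R, G, B and GB channels.

    ``GB`` is the arithmetic mean of the *enhanced* G and B channels, kept in
    floating point (no re-quantization) so downstream histogram features lose
    nothing to rounding.  Enhancement order is fixed: CLAHE per channel first,
    GB averaging second.

    Raises
    ------
    NonlinearInputError
        If ``linear`` is False and ``allow_nonlinear`` is not set.  Texture
        features assume intensities proportional to reflected light; rasters
        must be decoded with linear gamma (or the caller must opt in).
    """
    rgb = np.asarray(rgb, dtype=float)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError("expected an RGB raster of shape (rows, cols, 3)")
    if not linear and not allow_nonlinear:
        raise NonlinearInputError(
            "input is flagged as gamma-compressed; texture analysis requires "
            "linear-gamma intensities (decode RAW with linear gamma, or pass "
            "allow_nonlinear=True to proceed anyway)"
        )

    enhanced = {}
    for idx, tag in enumerate(("R", "G", "B")):
        ch = ChannelImage(rgb[..., idx], tag, bit_depth=bit_depth, linear=linear)
        enhanced[tag] = clahe_enhance(ch, tile_px=tile_px, clip_limit=clip_limit)
    enhanced["GB"] = ChannelImage(
        (enhanced["G"].pixels + enhanced["B"].pixels) / 2.0,
        "GB",
        bit_depth=bit_depth,
        linear=linear,
    )
    return enhanced
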