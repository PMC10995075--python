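"""Detection-zone image preprocessing: masking, cropping, tiling, color spaces.

A :class:`StripImage` carries the pixel array (float64 on the 0-255 scale; 8-bit
at PNG boundaries), a per-pixel validity mask, and a color-space tag. The
preprocessing pipeline mirrors a colorimetric-assay workflow: HSV threshold
masking to discard background and reaction artifacts, a 128x64 center crop of
the detection zone, and partitioning into four 64x32 tiles so each chemical
capture yields four training samples.

All color spaces are stored remapped to a uniform [0, 255] scale per channel
(hue 0-360 deg -> 0-255, LAB a*/b* -127..127 -> 0-255, etc.) so that mask
thresholds, histogram bins and pixel features are comparable across spaces.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from PIL import Image
from skimage import color as skcolor

from .errors import ConfigurationError, DomainError, SizeError

__all__ = [
    "COLOR_SPACES",
    "StripImage",
    "MaskRanges",
    "remap_channel",
    "mask_hsv",
    "center_crop",
    "tile",
    "convert_color_space",
    "preprocess_capture",
    "load_png",
    "save_png",
]

COLOR_SPACES = ("RGB", "HSV", "LAB", "YCrCb")

# Native channel ranges before remapping to the uniform [0, 255] scale.
_NATIVE_RANGES: dict[str, tuple[tuple[float, float], ...]] = {
    "RGB": (((0.0, 255.0),) * 3),
    "HSV": ((0.0, 360.0), (0.0, 1.0), (0.0, 1.0)),
    "LAB": ((0.0, 100.0), (-127.0, 127.0), (-127.0, 127.0)),
    # Channel order Y, Cr, Cb; full 8-bit studio swing per ITU-R BT.601.
    "YCrCb": ((16.0, 235.0), (16.0, 240.0), (16.0, 240.0)),
}


@dataclass
class StripImage:
    """A 3-channel detection-zone image with validity mask.

    ``pixels`` is an H x W x 3 float array on the uniform [0, 255] scale;
    ``mask`` marks valid (non-background) pixels; ``color_space`` tags the
    encoding of the channels and always matches ``pixels``.
    """

    pixels: np.ndarray
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    color_space: str = "RGB"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise SizeError(f"expected HxWx3 pixels, got shape {self.pixels.shape}")
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise SizeError("image must have H, W >= 1")
        if self.color_space not in COLOR_SPACES:
            raise ConfigurationError(
                f"unknown color space {self.color_space!r}; expected one of {COLOR_SPACES}"
            )
        if self.mask is None:
            self.mask = np.ones(self.pixels.shape[:2], dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.pixels.shape[:2]:
                raise SizeError(
                    f"mask shape {self.mask.shape} does not match image {self.pixels.shape[:2]}"
                )

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass(frozen=True)
class MaskRanges:
    """Inclusive HSV threshold ranges on the stored 8-bit scale.

    Defaults bracket the yellow-to-orange band of the Jaffe reaction:
    hue [20, 60], saturation [150, 255], value [230, 255].
    """

    hue: tuple[float, float] = (20.0, 60.0)
    saturation: tuple[float, float] = (150.0, 255.0)
    value: tuple[float, float] = (230.0, 255.0)

    def __post_init__(self) -> None:
        for name, (lo, hi) in zip(("hue", "saturation", "value"), self):
            if lo > hi:
                raise ConfigurationError(f"{name} range has low > high: ({lo}, {hi})")

    def __iter__(self):
        return iter((self.hue, self.saturation, self.value))


def remap_channel(
    values: np.ndarray | float,
    source: tuple[float, float],
    target: tuple[float, float],
) -> np.ndarray | float:
    """Affine remap of channel values from range ``source`` to ``target``.

    T = (S - S_min) * (T_max - T_min) / (S_max - S_min) + T_min, elementwise.
    Endpoint-exact and monotone when the target range is non-degenerate.
    """
    s_min, s_max = source
    t_min, t_max = target
    if s_max <= s_min:
        raise DomainError(f"degenerate source range ({s_min}, {s_max})")
    if t_max < t_min:
        raise DomainError(f"inverted target range ({t_min}, {t_max})")
    arr = np.asarray(values, dtype=np.float64)
    out = (arr - s_min) * (t_max - t_min) / (s_max - s_min) + t_min
    return float(out) if np.isscalar(values) else out


def _to_rgb01(image: StripImage) -> np.ndarray:
    """Convert the stored (remapped) pixels back to RGB floats in [0, 1]."""
    px = image.pixels
    space = image.color_space
    if space == "RGB":
        return px / 255.0
    native = np.empty_like(px)
    for c, rng in enumerate(_NATIVE_RANGES[space]):
        native[..., c] = remap_channel(px[..., c], (0.0, 255.0), rng)
    if space == "HSV":
        hsv = native.copy()
        hsv[..., 0] /= 360.0
        return skcolor.hsv2rgb(hsv)
    if space == "LAB":
        return skcolor.lab2rgb(native)
    # YCrCb stored (Y, Cr, Cb); skimage expects (Y, Cb, Cr)
    ycbcr = native[..., [0, 2, 1]]
    return skcolor.ycbcr2rgb(ycbcr)


def _from_rgb01(rgb01: np.ndarray, space: str) -> np.ndarray:
    """Encode RGB floats in [0, 1] into ``space`` on the uniform 0-255 scale."""
    if space == "RGB":
        return rgb01 * 255.0
    if space == "HSV":
        native = skcolor.rgb2hsv(rgb01)
        native = native.copy()
        native[..., 0] *= 360.0
    elif space == "LAB":
        native = skcolor.rgb2lab(rgb01)
    elif space == "YCrCb":
        ycbcr = skcolor.rgb2ycbcr(rgb01)
        native = ycbcr[..., [0, 2, 1]]
    else:
        raise ConfigurationError(f"unknown color space {space!r}")
    out = np.empty_like(native)
    for c, rng in enumerate(_NATIVE_RANGES[space]):
        out[..., c] = remap_channel(native[..., c], rng, (0.0, 255.0))
    return out


def convert_color_space(image: StripImage, target: str) -> StripImage:
    """Return the image re-encoded in ``target`` (RGB, HSV, LAB or YCrCb).

    Channels are stored remapped to [0, 255]; the mask is carried over
    unchanged. Converting to the current space is the identity.
    """
    if target not in COLOR_SPACES:
        raise ConfigurationError(
            f"unknown color space {target!r}; expected one of {COLOR_SPACES}"
        )
    if target == image.color_space:
        return replace(image, pixels=image.pixels.copy(), mask=image.mask.copy())
    rgb01 = np.clip(_to_rgb01(image), 0.0, 1.0)
    return StripImage(
        pixels=_from_rgb01(rgb01, target), mask=image.mask.copy(), color_space=target
    )


def mask_hsv(
    image: StripImage,
    ranges: MaskRanges | None = None,
    *,
    hue_convention: str = "full255",
) -> StripImage:
    """Threshold-mask an image by HSV range membership.

    A pixel is valid iff its hue, saturation, and value each fall inclusively
    within the configured ranges, combined with any pre-existing mask. Pixel
    values are not modified. ``hue_convention`` selects the hue scale on which
    the hue thresholds are interpreted: ``"full255"`` (0-360 deg remapped to
    0-255, the default) or ``"deg179"`` (half-degrees, 0-179).
    """
    ranges = ranges or MaskRanges()
    hsv = convert_color_space(image, "HSV")
    h, s, v = hsv.pixels[..., 0], hsv.pixels[..., 1], hsv.pixels[..., 2]
    if hue_convention == "full255":
        pass
    elif hue_convention == "deg179":
        h = remap_channel(h, (0.0, 255.0), (0.0, 360.0)) / 2.0
    else:
        raise ConfigurationError(f"unknown hue convention {hue_convention!r}")
    ok = (
        (h >= ranges.hue[0]) & (h <= ranges.hue[1])
        & (s >= ranges.saturation[0]) & (s <= ranges.saturation[1])
        & (v >= ranges.value[0]) & (v <= ranges.value[1])
    )
    return replace(image, pixels=image.pixels.copy(), mask=image.mask & ok)


def center_crop(image: StripImage, height: int, width: int) -> StripImage:
    """Extract the centered height x width window (floor offsets on odd
    parity differences); the mask is cropped identically."""
    H, W = image.shape
    if height > H or width > W:
        raise SizeError(f"crop {height}x{width} exceeds image {H}x{W}")
    if height < 1 or width < 1:
        raise SizeError("crop dimensions must be >= 1")
    r0 = (H - height) // 2
    c0 = (W - width) // 2
    return replace(
        image,
        pixels=image.pixels[r0 : r0 + height, c0 : c0 + width].copy(),
        mask=image.mask[r0 : r0 + height, c0 : c0 + width].copy(),
    )


def tile(image: StripImage) -> list[StripImage]:
    """Split into four equal quadrant tiles (TL, TR, BL, BR).

    Reassembling the tiles reproduces the input pixel-exactly; dimensions must
    both be even.
    """
    H, W = image.shape
    if H % 2 or W % 2:
        raise SizeError(f"tiling requires even dimensions, got {H}x{W}")
    h, w = H // 2, W // 2
    out = []
    for r0 in (0, h):
        for c0 in (0, w):
            out.append(
                replace(
                    image,
                    pixels=image.pixels[r0 : r0 + h, c0 : c0 + w].copy(),
                    mask=image.mask[r0 : r0 + h, c0 : c0 + w].copy(),
                )
            )
    return out


def preprocess_capture(
    image: StripImage,
    ranges: MaskRanges | None = None,
    crop: tuple[int, int] = (128, 64),
    *,
    hue_convention: str = "full255",
) -> list[StripImage]:
    """Full augmentation pipeline for one capture: HSV mask -> center crop ->
    4x tiling. Returns the four tiles (in RGB if the input was RGB)."""
    masked = mask_hsv(image, ranges, hue_convention=hue_convention)
    cropped = center_crop(masked, *crop)
    return tile(cropped)


def load_png(path: str | Path) -> StripImage:
    """Read an 8-bit RGB PNG from disk as a StripImage (all pixels valid)."""
    with Image.open(path) as im:
        arr = np.asarray(im.convert("RGB"), dtype=np.float64)
    return StripImage(pixels=arr, color_space="RGB")


def save_png(image: StripImage, path: str | Path) -> None:
    """Write an RGB StripImage to an 8-bit PNG (values rounded and clipped).

    Only RGB images are written; convert first if needed. The mask is not
    persisted — masking is recomputed from thresholds on load.
    """
    if image.color_space != "RGB":
        raise ConfigurationError("PNG output requires an RGB image")
    arr = np.clip(np.rint(image.pixels), 0, 255).astype(np.uint8)
    Image.fromarray(arr, mode="RGB").save(path, format="PNG")
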