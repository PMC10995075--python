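"""Feature extraction from preprocessed tiles.

Two feature families are supported:

* **Histogram of colors (HOC)** — per-channel binned frequencies of the valid
  (non-masked) pixel values, channels concatenated. The default configuration
  uses 255 unit-width bins per channel over [0, 255), giving a 765-length
  vector for any 3-channel tile; a masked-range HSV preset with per-channel
  bin counts [40, 105, 25] matches the assay's yellow-orange thresholds.
* **Pixel values** — the raw channel-wise pixel values on the uniform
  [0, 255] scale, concatenated channel-major, with masked pixels zero-filled
  (no interpolation — a deliberate choice for faint colorimetric signals).
  A 64x32 tile yields 6144 features.

A generic channel-wise convolution operator is also provided as a tested
utility for building richer feature maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import convolve2d

from .errors import ConfigurationError, DegenerateInputError
from .imaging import StripImage

__all__ = [
    "FeatureVector",
    "HOCConfig",
    "hoc",
    "pixel_features",
    "convolve_channel",
    "extract_features",
    "FeatureConfig",
]


@dataclass(frozen=True)
class HOCConfig:
    """Per-channel sampling ranges and bin counts for the color histogram.

    Ranges are half-open ``[low, high)``; pixels outside their channel's range
    are dropped (they are mask failures by construction, never clipped).
    """

    ranges: tuple[tuple[float, float], ...] = ((0.0, 255.0),) * 3
    bins: tuple[int, ...] = (255, 255, 255)
    normalize: bool = True

    def __post_init__(self) -> None:
        if len(self.ranges) != 3 or len(self.bins) != 3:
            raise ConfigurationError("HOCConfig needs 3 ranges and 3 bin counts")
        for (lo, hi), k in zip(self.ranges, self.bins):
            if k < 1:
                raise ConfigurationError(f"bin count must be >= 1, got {k}")
            if not (0.0 <= lo < hi <= 255.0):
                raise ConfigurationError(f"range ({lo}, {hi}) not within [0, 255]")

    @classmethod
    def masked_range_hsv(cls, normalize: bool = True) -> "HOCConfig":
        """Unit-width bins over the HSV mask ranges: 40/105/25 bins."""
        return cls(
            ranges=((20.0, 60.0), (150.0, 255.0), (230.0, 255.0)),
            bins=(40, 105, 25),
            normalize=normalize,
        )

    @property
    def length(self) -> int:
        return int(sum(self.bins))


@dataclass(frozen=True)
class FeatureVector:
    values: np.ndarray
    kind: str  # "HOC" | "pixel"
    color_space: str

    def __len__(self) -> int:
        return self.values.shape[0]


def hoc(image: StripImage, config: HOCConfig | None = None) -> FeatureVector:
    """Channel-wise histogram of colors over the valid pixels.

    Counts (or, when ``config.normalize``, frequencies relative to the number
    of non-masked pixels) per bin per channel, concatenated in channel order.
    """
    config = config or HOCConfig()
    valid = image.mask
    n_valid = int(valid.sum())
    if config.normalize and n_valid == 0:
        raise DegenerateInputError("cannot normalize a histogram of zero valid pixels")
    parts = []
    for c, ((lo, hi), k) in enumerate(zip(config.ranges, config.bins)):
        vals = image.pixels[..., c][valid]
        vals = vals[(vals >= lo) & (vals < hi)]  # half-open binning
        counts, _ = np.histogram(vals, bins=k, range=(lo, hi))
        parts.append(counts.astype(np.float64))
    out = np.concatenate(parts)
    if config.normalize:
        out /= n_valid
    return FeatureVector(values=out, kind="HOC", color_space=image.color_space)


def pixel_features(image: StripImage) -> FeatureVector:
    """Channel-major flattened pixel values with masked pixels zeroed.

    Channels are already on the uniform [0, 255] scale; each channel is
    flattened row-major and the three channels concatenated, giving H*W*3
    features (6144 for a 64x32 tile).
    """
    px = image.pixels.copy()
    px[~image.mask] = 0.0
    out = np.concatenate([px[..., c].ravel() for c in range(3)])
    return FeatureVector(values=out, kind="pixel", color_space=image.color_space)


def convolve_channel(channel: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """2-D convolution of a single image channel with zero padding.

    I'(x, y) = sum_s sum_t h(s, t) * I(x - s, y - t); the kernel must have odd
    dimensions so the output aligns with the input.
    """
    kernel = np.asarray(kernel, dtype=np.float64)
    if kernel.ndim != 2 or kernel.shape[0] % 2 == 0 or kernel.shape[1] % 2 == 0:
        raise ConfigurationError(
            f"kernel must be 2-D with odd dimensions, got shape {kernel.shape}"
        )
    return convolve2d(
        np.asarray(channel, dtype=np.float64), kernel, mode="same", boundary="fill", fillvalue=0.0
    )


@dataclass(frozen=True)
class FeatureConfig:
    """End-to-end feature recipe: color space + feature kind (+ HOC config)."""

    kind: str = "HOC"  # "HOC" | "pixel"
    color_space: str = "LAB"
    hoc: HOCConfig = field(default_factory=HOCConfig)

    def __post_init__(self) -> None:
        if self.kind not in ("HOC", "pixel"):
            raise ConfigurationError(f"unknown feature kind {self.kind!r}")

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "color_space": self.color_space,
            "hoc": {
                "ranges": [list(r) for r in self.hoc.ranges],
                "bins": list(self.hoc.bins),
                "normalize": self.hoc.normalize,
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureConfig":
        h = d.get("hoc", {})
        return cls(
            kind=d.get("kind", "HOC"),
            color_space=d.get("color_space", "LAB"),
            hoc=HOCConfig(
                ranges=tuple(tuple(r) for r in h.get("ranges", ((0, 255),) * 3)),
                bins=tuple(h.get("bins", (255, 255, 255))),
                normalize=h.get("normalize", True),
            ),
        )


def extract_features(tiles: list[StripImage], config: FeatureConfig) -> np.ndarray:
    """Feature matrix (n_tiles x n_features) for a list of preprocessed tiles.

    Each tile is converted to ``config.color_space`` first; the mask travels
    with the conversion so masked pixels never enter the statistics.
    """
    from .imaging import convert_color_space

    rows = []
    for t in tiles:
        img = convert_color_space(t, config.color_space)
        fv = hoc(img, config.hoc) if config.kind == "HOC" else pixel_features(img)
        rows.append(fv.values)
    return np.vstack(rows)
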