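"""Synthetic detection-zone dataset generator.

Emulates the statistical structure of a colorimetric creatinine assay study:

* a concentration grid of 65 values over four ranges (0.0-4.0 by 0.1,
  4.5-7.5 by 0.5, 8.0-19.0 by 1.0, 20.0-60.0 by 10.0), densest where the MDRD
  equation is most sensitive;
* 3 replicate strips per concentration, each photographed at 0 (pre-reaction),
  2, 12, and 22 minutes — 780 captures in the default design;
* a cream -> yellow -> reddish-orange Jaffe-like color response whose
  progression is a saturating function of concentration scaled by reaction
  time;
* one subject per capture, drawn from the 2019 US census marginals for age
  band, sex, and African-born status.

The renderer is deliberately simple (flat reaction zone + Gaussian pixel noise
+ per-capture illumination offset); it is a statistical stand-in for lightbox
photographs, not a physical model of Jaffe kinetics or camera optics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from skimage import color as skcolor

from . import imaging
from .egfr import Subject, SeverityThresholds, evaluate_subject
from .errors import ConfigurationError, DomainError
from .imaging import MaskRanges, StripImage, preprocess_capture, save_png

__all__ = [
    "ConcentrationGrid",
    "StripSample",
    "CaptureRecord",
    "CensusDistribution",
    "TABLE1_RANGES",
    "TIME_POINTS",
    "TIME_FACTORS",
    "build_concentration_grid",
    "default_grid",
    "sample_subject",
    "render_strip_image",
    "generate_captures",
    "generate_dataset",
    "augment_dataset",
    "MANIFEST_COLUMNS",
]

#: Study concentration design: (low, high, step) in mg/dL.
TABLE1_RANGES: tuple[tuple[float, float, float], ...] = (
    (0.0, 4.0, 0.1),
    (4.5, 7.5, 0.5),
    (8.0, 19.0, 1.0),
    (20.0, 60.0, 10.0),
)

#: Capture schedule in minutes after applying the sample (0 = pre-reaction).
TIME_POINTS: tuple[int, ...] = (0, 2, 12, 22)

#: Fraction of the full color change reached at each time point; 22 min is the
#: most informative, matching the study's optimal-time finding.
TIME_FACTORS: dict[int, float] = {0: 0.0, 2: 0.55, 12: 0.85, 22: 1.0}

# Concentration -> color law: HSV (degrees, 0-1, 0-1) endpoints of the
# reaction, interpolated by progress p = time_factor * c / (c + K_SAT).
_BASE_HSV = (68.0, 0.68, 0.965)  # pre-reaction cream
_END_HSV = (32.0, 0.98, 0.935)  # saturated reddish-orange
#: Half-saturation constant (mg/dL) of the color response; the steepest part
#: of the response covers the densely sampled 0-4 mg/dL range.
K_SAT = 4.0

MANIFEST_COLUMNS = [
    "path",
    "capture_id",
    "concentration_mg_dl",
    "time_point_min",
    "replicate",
    "tile",
    "age",
    "sex",
    "african_born",
    "severity",
]


@dataclass(frozen=True)
class ConcentrationGrid:
    """Sorted creatinine concentrations (mg/dL) built from step ranges."""

    ranges: tuple[tuple[float, float, float], ...]
    concentrations: tuple[float, ...]

    def __len__(self) -> int:
        return len(self.concentrations)

    def count_in(self, low: float, high: float) -> int:
        """Number of grid values c with low <= c <= high."""
        return sum(1 for c in self.concentrations if low <= c <= high)


@dataclass
class StripSample:
    """A rendered image (capture or tile) with its ground truth."""

    image: StripImage
    concentration: float
    time_point: int
    replicate: int
    capture_id: str
    tile: int = -1  # -1 = whole capture; 0..3 = tile index


@dataclass
class CaptureRecord:
    """A capture plus the subject it was assigned to and their severity."""

    sample: StripSample
    subject: Subject
    severity: str


def build_concentration_grid(
    ranges: list[tuple[float, float, float]] | tuple[tuple[float, float, float], ...],
) -> ConcentrationGrid:
    """Enumerate ``low, low+step, ..., high`` per range, merge and sort.

    Ranges must be internally consistent (low <= high, step > 0) and must not
    overlap each other.
    """
    ranges = tuple(tuple(map(float, r)) for r in ranges)
    for low, high, step in ranges:
        if step <= 0:
            raise ConfigurationError(f"step must be > 0, got {step}")
        if low > high:
            raise ConfigurationError(f"inverted range ({low}, {high})")
    for (l1, h1, _), (l2, h2, _) in zip(sorted(ranges), sorted(ranges)[1:]):
        if l2 <= h1:
            raise ConfigurationError(
                f"overlapping ranges ({l1}, {h1}) and ({l2}, {h2})"
            )
    values: list[float] = []
    for low, high, step in ranges:
        n = int(round((high - low) / step))
        values.extend(round(low + k * step, 9) for k in range(n + 1))
    values.sort()
    return ConcentrationGrid(ranges=ranges, concentrations=tuple(values))


def default_grid() -> ConcentrationGrid:
    """The 65-concentration study grid."""
    return build_concentration_grid(TABLE1_RANGES)


@dataclass(frozen=True)
class CensusDistribution:
    """Marginal age/sex/race distribution (2019 US census by default).

    ``age_bands`` are (low, high, probability) with ages drawn uniformly
    (integer, inclusive) within the selected band. The lowest band starts at 1
    because the MDRD equation requires age >= 1. The three factors are drawn
    independently.
    """

    age_bands: tuple[tuple[int, int, float], ...] = (
        (1, 4, 0.061),
        (5, 24, 0.256),
        (25, 44, 0.265),
        (45, 64, 0.254),
        (65, 84, 0.146),
        (85, 99, 0.018),
    )
    female_p: float = 0.510
    african_p: float = 0.134

    def __post_init__(self) -> None:
        total = sum(p for _, _, p in self.age_bands)
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(f"age band probabilities sum to {total}, not 1")
        if not (0.0 <= self.female_p <= 1.0 and 0.0 <= self.african_p <= 1.0):
            raise ConfigurationError("probabilities must lie in [0, 1]")


def sample_subject(
    rng: np.random.Generator, dist: CensusDistribution | None = None
) -> Subject:
    """Draw one subject: age band, sex and race independently, age uniform
    within the band."""
    dist = dist or CensusDistribution()
    probs = np.array([p for _, _, p in dist.age_bands])
    band = dist.age_bands[rng.choice(len(dist.age_bands), p=probs)]
    age = int(rng.integers(band[0], band[1] + 1))
    sex = "female" if rng.random() < dist.female_p else "male"
    african = bool(rng.random() < dist.african_p)
    return Subject(age=age, sex=sex, african_born=african)


def _reaction_color_rgb(concentration: float, time_point: int) -> np.ndarray:
    """Noise-free reaction-zone color (RGB, 0-255 floats)."""
    progress = TIME_FACTORS[time_point] * concentration / (concentration + K_SAT)
    h = _BASE_HSV[0] + progress * (_END_HSV[0] - _BASE_HSV[0])
    s = _BASE_HSV[1] + progress * (_END_HSV[1] - _BASE_HSV[1])
    v = _BASE_HSV[2] + progress * (_END_HSV[2] - _BASE_HSV[2])
    rgb01 = skcolor.hsv2rgb(np.array([[[h / 360.0, s, v]]]))
    return rgb01[0, 0] * 255.0


def render_strip_image(
    concentration: float,
    time_point: int,
    rng: np.random.Generator,
    *,
    noise_sigma: float = 3.0,
    illum_sigma: float = 2.0,
    shape: tuple[int, int] = (256, 128),
    zone: tuple[int, int] = (160, 80),
) -> StripImage:
    """Render one detection-zone capture.

    The central ``zone`` carries the reaction color for (concentration,
    time_point); the border emulates the dark background of the imaging
    lightbox. Per-pixel Gaussian noise (``noise_sigma``, 0-255 scale) and a
    per-capture scalar illumination offset (``illum_sigma``) are added; set
    both to 0 for a noise-free render. Time point 0 shows the pre-reaction
    cream color regardless of concentration.
    """
    if concentration < 0:
        raise DomainError(f"concentration must be >= 0, got {concentration}")
    if time_point not in TIME_FACTORS:
        raise DomainError(
            f"time_point must be one of {sorted(TIME_FACTORS)}, got {time_point}"
        )
    H, W = shape
    zh, zw = zone
    if zh > H or zw > W:
        raise ConfigurationError(f"reaction zone {zone} exceeds image {shape}")
    img = np.empty((H, W, 3), dtype=np.float64)
    img[...] = np.array([25.0, 22.0, 20.0])  # background
    r0, c0 = (H - zh) // 2, (W - zw) // 2
    img[r0 : r0 + zh, c0 : c0 + zw] = _reaction_color_rgb(concentration, time_point)
    if illum_sigma > 0:
        img += rng.normal(0.0, illum_sigma)
    if noise_sigma > 0:
        img += rng.normal(0.0, noise_sigma, size=img.shape)
    return StripImage(pixels=np.clip(img, 0.0, 255.0), color_space="RGB")


def generate_captures(
    grid: ConcentrationGrid | None = None,
    replicates: int = 3,
    time_points: tuple[int, ...] = TIME_POINTS,
    seed: int = 0,
    *,
    noise_sigma: float = 3.0,
    illum_sigma: float = 2.0,
    dist: CensusDistribution | None = None,
    thresholds: SeverityThresholds | None = None,
) -> list[CaptureRecord]:
    """Render the full experimental design in memory.

    One capture per (concentration, replicate, time point), each with its own
    subject; the default design yields 65 x 3 x 4 = 780 captures. Severity is
    the MDRD class of (true concentration, subject), with the 0 mg/dL blank
    floored to 0.1 mg/dL.
    """
    if grid is None:
        grid = default_grid()
    if replicates < 1:
        raise ConfigurationError(f"replicates must be >= 1, got {replicates}")
    if len(grid) == 0:
        raise ConfigurationError("empty concentration grid")
    rng = np.random.default_rng(seed)
    records: list[CaptureRecord] = []
    for ci, conc in enumerate(grid.concentrations):
        for rep in range(replicates):
            for t in time_points:
                subject = sample_subject(rng, dist)
                capture_id = f"c{ci:03d}_r{rep}_t{t:02d}"
                image = render_strip_image(
                    conc, t, rng, noise_sigma=noise_sigma, illum_sigma=illum_sigma
                )
                res = evaluate_subject(conc, subject, thresholds, floor=True)
                records.append(
                    CaptureRecord(
                        sample=StripSample(
                            image=image,
                            concentration=conc,
                            time_point=t,
                            replicate=rep,
                            capture_id=capture_id,
                        ),
                        subject=subject,
                        severity=res.severity,
                    )
                )
    return records


def _manifest_row(rec: CaptureRecord, path: str, tile: int) -> dict:
    s = rec.sample
    return {
        "path": path,
        "capture_id": s.capture_id,
        "concentration_mg_dl": s.concentration,
        "time_point_min": s.time_point,
        "replicate": s.replicate,
        "tile": tile,
        "age": rec.subject.age,
        "sex": rec.subject.sex,
        "african_born": rec.subject.african_born,
        "severity": rec.severity,
    }


def generate_dataset(
    out_dir: str | Path,
    grid: ConcentrationGrid | None = None,
    replicates: int = 3,
    time_points: tuple[int, ...] = TIME_POINTS,
    seed: int = 0,
    *,
    noise_sigma: float = 3.0,
    illum_sigma: float = 2.0,
    dist: CensusDistribution | None = None,
    thresholds: SeverityThresholds | None = None,
) -> pd.DataFrame:
    """Render the design to disk: one PNG per capture plus ``manifest.csv``
    and the resolved ``config.json``. Returns the capture-level manifest."""
    out = Path(out_dir)
    try:
        (out / "captures").mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create dataset directory {out}: {exc}") from exc
    grid = grid or default_grid()
    records = generate_captures(
        grid,
        replicates,
        time_points,
        seed,
        noise_sigma=noise_sigma,
        illum_sigma=illum_sigma,
        dist=dist,
        thresholds=thresholds,
    )
    rows = []
    for rec in records:
        rel = f"captures/{rec.sample.capture_id}.png"
        save_png(rec.sample.image, out / rel)
        rows.append(_manifest_row(rec, rel, tile=-1))
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    manifest.to_csv(out / "manifest.csv", index=False)
    config = {
        "grid_ranges": [list(r) for r in grid.ranges],
        "replicates": replicates,
        "time_points": list(time_points),
        "noise_sigma": noise_sigma,
        "illum_sigma": illum_sigma,
        "seed": seed,
    }
    (out / "config.json").write_text(json.dumps(config, indent=2))
    return manifest


def augment_dataset(
    manifest: pd.DataFrame,
    base_dir: str | Path,
    out_dir: str | Path | None = None,
    ranges: MaskRanges | None = None,
    crop: tuple[int, int] = (128, 64),
) -> tuple[pd.DataFrame, list[StripImage]]:
    """Apply the preprocessing pipeline (HSV mask, center crop, 4x tiling) to
    every capture in a capture-level manifest.

    Returns the tile-level manifest (4 rows per capture) and the tile images
    in the same order. When ``out_dir`` is given, tile PNGs and
    ``manifest_tiles.csv`` are written there. Masks are not persisted to PNG;
    consumers re-derive them from the thresholds.
    """
    base = Path(base_dir)
    rows = []
    tiles_out: list[StripImage] = []
    if out_dir is not None:
        (Path(out_dir) / "tiles").mkdir(parents=True, exist_ok=True)
    for row in manifest.itertuples(index=False):
        image = imaging.load_png(base / row.path)
        tiles = preprocess_capture(image, ranges, crop)
        for ti, tile_img in enumerate(tiles):
            rel = f"tiles/{row.capture_id}_tile{ti}.png"
            if out_dir is not None:
                save_png(tile_img, Path(out_dir) / rel)
            d = row._asdict()
            d.update({"path": rel, "tile": ti})
            rows.append(d)
            tiles_out.append(tile_img)
    tile_manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    if out_dir is not None:
        tile_manifest.to_csv(Path(out_dir) / "manifest_tiles.csv", index=False)
    return tile_manifest, tiles_out
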