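"""Seeded synthetic HDR thermal scenes with injected warm targets.

Backgrounds are correlated Gaussian clutter fields whose brightness-
temperature sample mean and standard deviation are pinned to the survey
statistics (defaults 14.2 °C mean, 1.35 °C SD); spatial correlation is a
free smoothing length since only the marginal temperature distribution
of real canopy clutter is characterised. Temperatures are converted to
raw counts through a linear radiometric map (default 100 counts/°C with
an 8000-count offset) that keeps everything inside the 14-bit range.

Targets are warm discs with a Gaussian-tapered rim, 3–11 px in diameter,
whose *mean* excess over the local background equals the drawn contrast
exactly by construction. A configurable fraction of targets (default
40%, the full-occlusion rate observed in plantation surveys) is recorded
in the ground truth as fully occluded and not rendered at all; an
optional fraction is rendered at half contrast with a random half-disc
masked off and flagged as partially occluded.

All randomness flows from integer seed sequences fed to numpy's default
bit generator, so a given spec reproduces its dataset bit-exactly.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path

import numpy as np
from scipy import ndimage

from .frames import GroundTruthRecord, ThermalFrame, write_frame, write_ground_truth

__all__ = ["SceneSpec", "GenerationError", "generate_background",
           "inject_koalas", "generate_dataset", "write_dataset"]

FOURTEEN_BIT_MAX = 16383
_BORDER_MARGIN_PX = 12
_MIN_SEPARATION_PX = 24
_PLACEMENT_TRIES = 1000


class GenerationError(RuntimeError):
    """Raised when a scene cannot be generated under its constraints."""


@dataclasses.dataclass(frozen=True)
class SceneSpec:
    """Study conditions for one synthetic dataset."""

    n_frames: int = 10
    width: int = 640
    height: int = 512
    background_mean_C: float = 14.2
    background_sd_C: float = 1.35
    clutter_correlation_px: float = 8.0
    counts_per_C: float = 100.0
    counts_offset: float = 8000.0
    n_koalas_per_frame: int = 2
    n_unique_koalas: int | None = None
    target_diameter_px: tuple[float, float] = (3.0, 11.0)
    target_contrast_C: tuple[float, float] = (2.0, 12.0)
    fully_occluded_fraction: float = 0.40
    partially_occluded_fraction: float = 0.0
    position_jitter_px: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.fully_occluded_fraction <= 1.0:
            raise ValueError("fully_occluded_fraction must lie in [0, 1]")
        if not 0.0 <= self.partially_occluded_fraction <= 1.0:
            raise ValueError("partially_occluded_fraction must lie in [0, 1]")
        dmax = min(self.width, self.height) / 4
        if not (1.0 <= self.target_diameter_px[0] <= self.target_diameter_px[1] <= dmax):
            raise ValueError(f"target diameters must lie within [1, {dmax}]")
        if self.counts_per_C <= 0:
            raise ValueError("counts_per_C must be positive")

    @property
    def unique_koalas(self) -> int:
        return self.n_unique_koalas or self.n_koalas_per_frame


def _frame_rng(spec: SceneSpec, frame_index: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([spec.seed, frame_index, stream])


def generate_background(spec: SceneSpec, frame_index: int = 0) -> ThermalFrame:
    """Correlated Gaussian clutter with pinned sample mean and SD.

    White noise is smoothed with a Gaussian of sigma
    ``clutter_correlation_px`` and the sample is standardised, so the
    frame's temperature mean and SD equal the spec values exactly; a zero
    SD yields a constant frame at the mean. Raises
    :class:`GenerationError` if any count leaves the 14-bit range.
    """
    rng = _frame_rng(spec, frame_index, 0)
    if spec.background_sd_C == 0.0:
        temps = np.full((spec.height, spec.width), spec.background_mean_C)
    else:
        noise = rng.standard_normal((spec.height, spec.width))
        field = ndimage.gaussian_filter(noise, sigma=spec.clutter_correlation_px)
        field = (field - field.mean()) / field.std()
        temps = spec.background_mean_C + spec.background_sd_C * field
    counts = np.rint(spec.counts_offset + spec.counts_per_C * temps)
    if counts.min() < 0 or counts.max() > FOURTEEN_BIT_MAX:
        raise GenerationError(
            f"radiometric overflow: counts span [{counts.min()}, {counts.max()}], "
            f"outside [0, {FOURTEEN_BIT_MAX}]")
    return ThermalFrame(
        pixels=counts.astype(np.uint16),
        frame_id=f"frame_{frame_index:05d}",
        gain=1.0 / spec.counts_per_C,
        offset=-spec.counts_offset / spec.counts_per_C,
    )


def _sample_positions(spec: SceneSpec, n: int, rng: np.random.Generator,
                      min_sep: float = _MIN_SEPARATION_PX) -> list[tuple[float, float]]:
    margin = _BORDER_MARGIN_PX
    positions: list[tuple[float, float]] = []
    for _ in range(n):
        for _try in range(_PLACEMENT_TRIES):
            x = rng.uniform(margin, spec.width - 1 - margin)
            y = rng.uniform(margin, spec.height - 1 - margin)
            if all(math.hypot(x - px, y - py) >= min_sep for px, py in positions):
                positions.append((x, y))
                break
        else:
            raise GenerationError(
                f"could not place {n} targets >= {min_sep} px apart "
                f"in a {spec.width}x{spec.height} frame")
    return positions


def _render_target(counts: np.ndarray, x: float, y: float, diameter: float,
                   amplitude_counts: float, half_mask_dir: float | None = None) -> None:
    """Add a tapered warm disc in place.

    The taper is flat out to R - 0.5 px and falls off as a Gaussian; the
    amplitude is rescaled so the mean excess over the disc footprint
    (r <= R) equals ``amplitude_counts`` exactly. ``half_mask_dir`` (rad)
    zeroes the half-plane on that side of the centre (partial occlusion).
    """
    r_disc = diameter / 2.0
    reach = int(math.ceil(r_disc + 2.0))
    x0, x1 = int(math.floor(x)) - reach, int(math.floor(x)) + reach + 1
    y0, y1 = int(math.floor(y)) - reach, int(math.floor(y)) + reach + 1
    yy, xx = np.mgrid[y0:y1, x0:x1]
    rr = np.hypot(xx - x, yy - y)
    taper = np.where(rr <= r_disc - 0.5, 1.0,
                     np.exp(-0.5 * ((rr - (r_disc - 0.5)) / 0.6) ** 2))
    taper[rr > r_disc + 1.8] = 0.0
    inside = rr <= r_disc
    if taper[inside].sum() > 0:
        scale = amplitude_counts * inside.sum() / taper[inside].sum()
    else:
        scale = amplitude_counts
    bump = scale * taper
    if half_mask_dir is not None:
        nx, ny = math.cos(half_mask_dir), math.sin(half_mask_dir)
        bump[(xx - x) * nx + (yy - y) * ny > 0] = 0.0
    # clip windows at frame borders
    h, w = counts.shape
    sy0, sy1 = max(y0, 0), min(y1, h)
    sx0, sx1 = max(x0, 0), min(x1, w)
    patch = bump[sy0 - y0:sy1 - y0, sx0 - x0:sx1 - x0]
    region = counts[sy0:sy1, sx0:sx1]
    np.clip(region + patch, 0, 65535, out=region)


def inject_koalas(
    frame: ThermalFrame, spec: SceneSpec, rng: np.random.Generator,
    positions: list[tuple[float, float]] | None = None,
    koala_ids: list[str] | None = None,
) -> tuple[ThermalFrame, list[GroundTruthRecord]]:
    """Place warm disc targets and emit matching ground truth.

    Each target draws a diameter and contrast uniformly from the spec
    ranges. With probability ``fully_occluded_fraction`` it is recorded
    as fully occluded and not rendered; with probability
    ``partially_occluded_fraction`` it is rendered at half contrast with
    a random half-disc masked and flagged partial; otherwise it is
    rendered in full and flagged visible.
    """
    n = spec.n_koalas_per_frame
    if positions is None:
        positions = _sample_positions(spec, n, rng)
    if koala_ids is None:
        koala_ids = [f"koala_{i:03d}" for i in range(n)]
    counts = frame.pixels.astype(np.float64)
    records = []
    for (x, y), kid in zip(positions, koala_ids):
        diameter = rng.uniform(*spec.target_diameter_px)
        contrast = rng.uniform(*spec.target_contrast_C)
        u = rng.uniform()
        mask_dir = rng.uniform(0.0, 2 * math.pi)  # drawn always, for stream stability
        if u < spec.fully_occluded_fraction:
            state = "full"
        elif u < spec.fully_occluded_fraction + spec.partially_occluded_fraction:
            state = "partial"
            _render_target(counts, x, y, diameter,
                           0.5 * contrast * spec.counts_per_C, half_mask_dir=mask_dir)
        else:
            state = "visible"
            _render_target(counts, x, y, diameter, contrast * spec.counts_per_C)
        records.append(GroundTruthRecord(frame_id=frame.frame_id, koala_id=kid,
                                         x=x, y=y, occlusion_state=state))
    out = ThermalFrame(pixels=np.rint(counts).astype(np.uint16),
                       frame_id=frame.frame_id, gain=frame.gain, offset=frame.offset)
    return out, records


def generate_dataset(spec: SceneSpec) -> tuple[list[ThermalFrame], list[GroundTruthRecord]]:
    """Generate ``n_frames`` frames plus the pooled ground-truth table.

    A pool of ``unique_koalas`` animals with fixed base positions is laid
    out once; every frame re-places its animals at the base position plus
    a small jitter (emulating revisits of the same animal across
    overlapping survey frames), cycling through the pool when it is
    larger than ``n_koalas_per_frame``. Occlusion state is redrawn per
    frame and animal.
    """
    base_rng = np.random.default_rng([spec.seed, 1_000_003])
    pool = spec.unique_koalas
    sep = _MIN_SEPARATION_PX + 2 * spec.position_jitter_px
    base_positions = _sample_positions(spec, pool, base_rng, min_sep=sep)
    ids = [f"koala_{i:03d}" for i in range(pool)]

    frames: list[ThermalFrame] = []
    gts: list[GroundTruthRecord] = []
    per = spec.n_koalas_per_frame
    for i in range(spec.n_frames):
        frame = generate_background(spec, i)
        rng = _frame_rng(spec, i, 1)
        sel = [(i * per + j) % pool for j in range(min(per, pool))]
        jitter = rng.uniform(-spec.position_jitter_px, spec.position_jitter_px,
                             size=(len(sel), 2))
        positions = [(base_positions[s][0] + jitter[j, 0],
                      base_positions[s][1] + jitter[j, 1])
                     for j, s in enumerate(sel)]
        frame, records = inject_koalas(frame, spec, rng, positions=positions,
                                       koala_ids=[ids[s] for s in sel])
        frames.append(frame)
        gts.extend(records)
    return frames, gts


def write_dataset(spec: SceneSpec, out_dir: str | Path) -> Path:
    """Generate and write frames as 16-bit PNG plus ``ground_truth.csv``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    frames, gts = generate_dataset(spec)
    for frame in frames:
        write_frame(frame, out_dir / f"{frame.frame_id}.png")
    write_ground_truth(gts, out_dir / "ground_truth.csv")
    return out_dir
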