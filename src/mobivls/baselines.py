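"""Classical dim-object comparison detectors.

Seven windowed-contrast detectors widely used for small-target detection
in infrared imagery, each mapping a thermal frame to a saliency map in
[0, 1]: AAGD, IAAGD, the local-contrast-measure family (MLCM, ILCM,
HB-MLCM, MPCM) and a template-matching binary-mask detector (TMBM).

All of them slide windows over the image and compare the centre cell with
its surroundings; they differ in the statistic (mean difference, max/mean
ratio, opposing-pair products) and in pre/post-processing. Where a family
offers variants, the simplest published formulation is used:

AAGD    per inner scale, mean(inner window) - mean(outer ring); maximum
        over scales, bright responses only.
IAAGD   per inner scale, min over the 8 surrounding same-size cells of
        (inner mean - cell mean); the min suppresses straight edges,
        which always have at least one equally-bright neighbour cell.
MLCM    per scale, min over the 8 neighbour cells of L^2 / m_i where L is
        the max of the centre cell and m_i the neighbour-cell mean.
ILCM    a single coarse window (10 px, 1 px step) with the mean replacing
        the max in the MLCM ratio — the speed-oriented variant.
HB-MLCM a high-boost sharpening prefilter followed by MLCM.
MPCM    per scale, min over the four opposing-direction products
        (m0 - m_i)(m0 - m_{i+4}); positive for bright AND dark targets.
TMBM    intensity floor, constant subtraction and hard threshold produce
        a binary mask which is matched (normalised cross-correlation)
        against a bank of flat disc templates.

Windows are cropped at frame borders and means taken over the available
pixels, so every centre response is exactly reproducible by a brute-force
windowed-statistics oracle.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage
from skimage.feature import match_template

from .detector import ConfigurationError, normalize01
from .frames import ThermalFrame

__all__ = ["BaselineConfig", "baseline_map", "aagd_map", "iaagd_map",
           "lcm_family_map", "tmbm_map", "BASELINE_METHODS"]

# offsets of the 8 neighbour cells, in units of one cell size
_DIRECTIONS = [(-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1)]
# opposing pairs within _DIRECTIONS (i and i+4 are antipodal)
_OPPOSING = [(0, 4), (1, 5), (2, 6), (3, 7)]


@dataclasses.dataclass(frozen=True)
class BaselineConfig:
    """Shared settings for the comparison detectors (survey defaults)."""

    inner_scales: tuple[int, ...] = (3, 5, 7, 9, 11)
    outer_window: int = 21
    ilcm_window: int = 10
    ilcm_step: int = 1
    tmbm_subtract_c: float = 0.2
    tmbm_threshold_t: float = 0.6
    tmbm_score_threshold: float = 0.8
    tmbm_intensity_threshold: float = 0.1

    def __post_init__(self) -> None:
        if any(s >= self.outer_window for s in self.inner_scales):
            raise ConfigurationError("inner scales must be smaller than the outer window")
        for name in ("tmbm_subtract_c", "tmbm_threshold_t",
                     "tmbm_score_threshold", "tmbm_intensity_threshold"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} outside [0, 1]")


def _pixels(frame: ThermalFrame | np.ndarray) -> np.ndarray:
    px = frame.pixels if isinstance(frame, ThermalFrame) else np.asarray(frame)
    return px.astype(np.float64)


def _box_sum_count(img: np.ndarray, window: int) -> tuple[np.ndarray, np.ndarray]:
    """Sum and pixel count of a centred window of side ``window``, cropped
    at the frame borders (summed-area table)."""
    h, w = img.shape
    if window > min(h, w):
        raise ConfigurationError(f"window {window} exceeds frame shape {img.shape}")
    lo = (window - 1) // 2
    hi = window // 2
    p = np.zeros((h + 1, w + 1))
    p[1:, 1:] = img.cumsum(axis=0).cumsum(axis=1)
    i = np.arange(h)
    j = np.arange(w)
    i0 = np.clip(i - lo, 0, h)
    i1 = np.clip(i + hi + 1, 0, h)
    j0 = np.clip(j - lo, 0, w)
    j1 = np.clip(j + hi + 1, 0, w)
    s = (p[np.ix_(i1, j1)] - p[np.ix_(i0, j1)] - p[np.ix_(i1, j0)] + p[np.ix_(i0, j0)])
    count = (i1 - i0)[:, None] * (j1 - j0)[None, :]
    return s, count.astype(np.float64)


def _box_mean(img: np.ndarray, window: int) -> np.ndarray:
    s, c = _box_sum_count(img, window)
    return s / c


def _shifted(arr: np.ndarray, dy: int, dx: int) -> np.ndarray:
    """Shift by (dy, dx) with border clamping (cells clamped into frame)."""
    h, w = arr.shape
    i = np.clip(np.arange(h) + dy, 0, h - 1)
    j = np.clip(np.arange(w) + dx, 0, w - 1)
    return arr[np.ix_(i, j)]


def _neighbour_cell_means(img: np.ndarray, cell: int) -> list[np.ndarray]:
    m = _box_mean(img, cell)
    return [_shifted(m, dy * cell, dx * cell) for dy, dx in _DIRECTIONS]


def aagd_map(frame: ThermalFrame | np.ndarray,
             cfg: BaselineConfig = BaselineConfig()) -> np.ndarray:
    """Average Absolute Gray Difference: inner mean minus outer-ring mean,
    maximum over inner scales, bright responses only."""
    img = _pixels(frame)
    outer_sum, outer_cnt = _box_sum_count(img, cfg.outer_window)
    best = None
    for s in cfg.inner_scales:
        inner_sum, inner_cnt = _box_sum_count(img, s)
        ring = (outer_sum - inner_sum) / (outer_cnt - inner_cnt)
        resp = inner_sum / inner_cnt - ring
        best = resp if best is None else np.maximum(best, resp)
    return normalize01(np.maximum(best, 0.0))


def iaagd_map(frame: ThermalFrame | np.ndarray,
              cfg: BaselineConfig = BaselineConfig()) -> np.ndarray:
    """Improved AAGD: the centre cell must exceed all 8 surrounding cells,
    which suppresses straight-edge false alarms."""
    img = _pixels(frame)
    best = None
    for s in cfg.inner_scales:
        inner = _box_mean(img, s)
        diffs = [inner - m for m in _neighbour_cell_means(img, s)]
        resp = np.minimum.reduce(diffs)
        best = resp if best is None else np.maximum(best, resp)
    return normalize01(np.maximum(best, 0.0))


def _lcm_single_scale(img: np.ndarray, cell: int, centre_stat: str) -> np.ndarray:
    if centre_stat == "max":
        centre = ndimage.maximum_filter(img, size=cell, mode="nearest")
    else:
        centre = _box_mean(img, cell)
    num = centre * centre
    out = None
    for m in _neighbour_cell_means(img, cell):
        ratio = np.where(m > 0, num / np.where(m > 0, m, 1.0), num)
        out = ratio if out is None else np.minimum(out, ratio)
    return out


def lcm_family_map(frame: ThermalFrame | np.ndarray, variant: str,
                   cfg: BaselineConfig = BaselineConfig()) -> np.ndarray:
    """Local-contrast-measure family dispatcher (MLCM/ILCM/HB-MLCM/MPCM)."""
    img = _pixels(frame)
    variant = variant.upper().replace("-", "")
    if variant == "MLCM":
        raw = np.maximum.reduce(
            [_lcm_single_scale(img, s, "max") for s in cfg.inner_scales])
    elif variant == "ILCM":
        raw = _lcm_single_scale(img, cfg.ilcm_window, "mean")
    elif variant == "HBMLCM":
        boosted = np.maximum(img + (img - _box_mean(img, 5)), 0.0)
        raw = np.maximum.reduce(
            [_lcm_single_scale(boosted, s, "max") for s in cfg.inner_scales])
    elif variant == "MPCM":
        raw = np.maximum.reduce(
            [_mpcm_single_scale(img, s) for s in cfg.inner_scales])
        raw = np.maximum(raw, 0.0)
    else:
        raise ConfigurationError(f"unknown LCM variant {variant!r}")
    return normalize01(raw)


def _mpcm_single_scale(img: np.ndarray, cell: int) -> np.ndarray:
    m0 = _box_mean(img, cell)
    diffs = [m0 - m for m in _neighbour_cell_means(img, cell)]
    products = [diffs[i] * diffs[j] for i, j in _OPPOSING]
    return np.minimum.reduce(products)


def tmbm_map(frame: ThermalFrame | np.ndarray,
             cfg: BaselineConfig = BaselineConfig()) -> np.ndarray:
    """Template Matching Binary Mask.

    Counts are scaled to [0, 1] by the 16-bit container full scale so the
    absolute intensity floor is meaningful; pixels below the floor are
    zeroed, the constant is subtracted and the result hard-thresholded
    into a binary mask. The mask is correlated (normalised
    cross-correlation) with flat disc templates at each inner scale;
    scores below the scoring threshold are zeroed.
    """
    img = _pixels(frame) / 65535.0
    img = np.where(img < cfg.tmbm_intensity_threshold, 0.0, img)
    mask = ((img - cfg.tmbm_subtract_c) >= cfg.tmbm_threshold_t).astype(np.float64)
    if not mask.any():
        return np.zeros_like(img)
    best = np.zeros_like(img)
    for d in cfg.inner_scales:
        tmpl = _disc_template(d)
        if tmpl.shape[0] > min(img.shape) or tmpl.std() == 0:
            continue  # degenerate all-ones template (diameter <= 3)
        score = match_template(mask, tmpl, pad_input=True,
                               mode="constant", constant_values=0.0)
        best = np.maximum(best, np.nan_to_num(score))
    best = np.clip(best, 0.0, 1.0)
    best[best < cfg.tmbm_score_threshold] = 0.0
    return best


def _disc_template(diameter: int) -> np.ndarray:
    """Flat disc of the given diameter inside a square bounding box."""
    r = diameter / 2.0
    c = (diameter - 1) / 2.0
    yy, xx = np.mgrid[0:diameter, 0:diameter]
    return (((yy - c) ** 2 + (xx - c) ** 2) <= r * r).astype(np.float64)


def baseline_map(frame: ThermalFrame | np.ndarray, method: str,
                 cfg: BaselineConfig = BaselineConfig()) -> np.ndarray:
    """Dispatch a frame to one of the seven comparison detectors by name."""
    method = method.lower()
    if method == "aagd":
        return aagd_map(frame, cfg)
    if method == "iaagd":
        return iaagd_map(frame, cfg)
    if method in ("mlcm", "ilcm", "hbmlcm", "hb-mlcm", "mpcm"):
        return lcm_family_map(frame, method, cfg)
    if method == "tmbm":
        return tmbm_map(frame, cfg)
    raise ConfigurationError(f"unknown baseline method {method!r}")


BASELINE_METHODS = ("aagd", "iaagd", "hbmlcm", "ilcm", "mlcm", "mpcm", "tmbm")
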