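"""Multiscale Object Bio-Inspired Vision Line Scanner (MOBIVLS).

A single-image small-target detector modelled on the early visual pathway
of flying insects. Each image row (and, independently, each column) is
treated as a scan line and passed through four stages:

PRC    photoreceptor adaptation — divisive (Naka-Rushton form)
       normalisation against a causal running average of the line,
       compressing the raw 14-bit dynamic range into [0, 1).
LMC    lamina monopolar cell filtering — an antisymmetric difference-of-
       boxes along the scan direction (forward mean minus backward mean),
       removing local redundancy and leaving a signed edge code:
       positive at intensity rises, negative at falls.
RTC    rectified transient cells — half-wave rectification splitting the
       bipolar signal into non-negative ON and OFF channels.
ESTMD  elementary small-target detection — the ON channel is delayed by
       each candidate object scale and multiplied with the undelayed OFF
       channel (roles swapped for dark targets), then accumulated over
       scales. A compact bright target produces an ON lobe at its leading
       edge and an OFF lobe at its trailing edge whose separation matches
       its width, so the delay bank is size-selective for targets within
       the configured scale range.

The row-wise and column-wise response grids are combined as
``H*V + H + V`` (Hadamard product plus array addition): the product term
rewards targets compact along both axes while the sum retains
single-axis evidence. The combined map is min-max normalised to [0, 1]
and thresholded adaptively at ``mean + k*std`` to produce detections.
"""

from __future__ import annotations

import dataclasses
from typing import Literal, Sequence

import numpy as np
from scipy import ndimage, signal

from .frames import DetectionRecord, ThermalFrame

__all__ = [
    "MobivlsConfig",
    "ConfigurationError",
    "DomainError",
    "prc_adapt",
    "lmc_filter",
    "rtc_split",
    "estmd_correlate",
    "scan_direction",
    "mobivls_saliency",
    "mobivls_detect",
    "normalize01",
]


class ConfigurationError(ValueError):
    """Raised when a configuration is inconsistent with the input geometry."""


class DomainError(ValueError):
    """Raised when input values violate a stage's domain (e.g. negative counts)."""


@dataclasses.dataclass(frozen=True)
class MobivlsConfig:
    """Tunable parameters of the pipeline.

    ``scales`` are the candidate target widths in pixels (the delay bank of
    the correlation stage); ``prc_adapt_length`` the e-folding length in
    pixels of the photoreceptor running average; ``lmc_halfwidth`` the
    surround half-width of the centre-surround kernel; ``threshold_k`` the
    adaptive-threshold multiplier (mean + k*std of the saliency map);
    ``min_blob_area`` the smallest connected component kept as a detection.
    """

    scales: tuple[int, ...] = tuple(range(3, 12))
    polarity: Literal["bright", "dark", "both"] = "bright"
    prc_adapt_length: float = 25.0
    lmc_halfwidth: int = 3
    threshold_k: float = 5.0
    min_blob_area: int = 2
    scan_reverse_too: bool = False
    # spatial summation window for the cross-directional combination;
    # None uses the median of the scale bank
    pool_scale: int | None = None
    # absolute combined-response value mapped to saliency 1.0; roughly the
    # pooled response of an ideal full-contrast compact target, so real
    # targets land below saturation (see module docs)
    response_scale: float = 1.0
    # Optional asymmetric ON/OFF channel adaptation (fast attack, slow decay);
    # disabled by default because the detector operates on single images.
    rtc_fast_alpha: float | None = None
    rtc_slow_alpha: float | None = None

    def __post_init__(self) -> None:
        if not self.scales:
            raise ConfigurationError("scales must be non-empty")
        if any(s <= 0 for s in self.scales):
            raise ConfigurationError("scales must be positive")
        if list(self.scales) != sorted(self.scales):
            raise ConfigurationError("scales must be ascending")
        if self.prc_adapt_length <= 0:
            raise ConfigurationError("prc_adapt_length must be positive")
        if self.lmc_halfwidth < 1:
            raise ConfigurationError("lmc_halfwidth must be >= 1")


def normalize01(arr: np.ndarray) -> np.ndarray:
    """Min-max normalise to [0, 1]; a constant array maps to all zeros."""
    arr = np.asarray(arr, dtype=np.float64)
    lo, hi = arr.min(), arr.max()
    if hi - lo <= 0:
        return np.zeros_like(arr)
    return (arr - lo) / (hi - lo)


def _as_lines(values: np.ndarray) -> np.ndarray:
    """View 1-D input as a single scan line; pass 2-D through row-wise."""
    arr = np.asarray(values, dtype=np.float64)
    return arr[None, :] if arr.ndim == 1 else arr


def prc_adapt(line: np.ndarray, cfg: MobivlsConfig = MobivlsConfig()) -> np.ndarray:
    """Photoreceptor stage: divisive normalisation against a causal mean.

    ``out[i] = v[i] / (v[i] + vbar[i])`` where ``vbar`` is an exponential
    moving average of the line with smoothing factor
    ``1/prc_adapt_length``, initialised at the first sample. Output lies in
    [0, 1); zero input maps to zero; constant positive input maps to 0.5.
    """
    x = _as_lines(line)
    if x.size and x.min() < 0:
        raise DomainError("photoreceptor input must be non-negative raw counts")
    out = np.empty_like(x)
    alpha = 1.0 / cfg.prc_adapt_length
    b = [alpha]
    a = [1.0, -(1.0 - alpha)]
    # initial condition so that vbar[0] == x[0]
    zi = (1.0 - alpha) * x[:, :1]
    vbar, _ = signal.lfilter(b, a, x, axis=1, zi=zi)
    denom = x + vbar
    np.divide(x, denom, out=out, where=denom > 0)
    out[denom <= 0] = 0.0
    return out[0] if np.asarray(line).ndim == 1 else out


def lmc_filter(line: np.ndarray, cfg: MobivlsConfig = MobivlsConfig()) -> np.ndarray:
    """Lamina stage: antisymmetric difference-of-boxes along the line.

    ``out[i] = mean(x[i+1 .. i+h]) - mean(x[i-h .. i-1])`` with
    ``h = lmc_halfwidth``: positive at intensity rises and negative at
    falls for a left-to-right scan, zero on constant input. This signed
    edge code is what gives the downstream correlator its bright/dark
    selectivity — a bright target emits ON then OFF along the scan, a
    dark one OFF then ON, and only the first ordering survives the
    delayed-ON x OFF product. Windows are cropped at the line ends (an
    empty side falls back to the centre sample), so no border lobes are
    fabricated and every value matches a direct windowed-mean oracle.
    """
    x0 = _as_lines(line)
    h = cfg.lmc_halfwidth
    n = x0.shape[1]
    if 2 * h + 1 > n:
        raise ConfigurationError(
            f"LMC kernel width {2 * h + 1} exceeds line length {n}"
        )
    # work relative to the first sample: the filter is offset-invariant and
    # this keeps constant input at exactly zero (no cumsum round-off)
    x = x0 - x0[:, :1]
    p = np.zeros((x.shape[0], n + 1))
    np.cumsum(x, axis=1, out=p[:, 1:])
    i = np.arange(n)
    l0 = np.maximum(i - h, 0)
    left_cnt = i - l0
    left_sum = p[:, i] - p[:, l0]
    r1 = np.minimum(i + h + 1, n)
    right_cnt = r1 - (i + 1)
    right_sum = p[:, r1] - p[:, i + 1]
    left_mean = np.where(left_cnt > 0, left_sum / np.maximum(left_cnt, 1), x)
    right_mean = np.where(right_cnt > 0, right_sum / np.maximum(right_cnt, 1), x)
    out = right_mean - left_mean
    return out[0] if np.asarray(line).ndim == 1 else out


def rtc_split(line: np.ndarray, cfg: MobivlsConfig = MobivlsConfig()) -> tuple[np.ndarray, np.ndarray]:
    """Rectified transient cells: split a bipolar line into ON/OFF channels.

    ``on = max(v, 0)``, ``off = max(-v, 0)``, so ``on - off`` reconstructs
    the input exactly. Optional asymmetric smoothing (fast when a channel
    rises, slow when it falls) can be enabled through the config.
    """
    x = np.asarray(line, dtype=np.float64)
    on = np.maximum(x, 0.0)
    off = np.maximum(-x, 0.0)
    if cfg.rtc_fast_alpha is not None and cfg.rtc_slow_alpha is not None:
        on = _asymmetric_smooth(on, cfg.rtc_fast_alpha, cfg.rtc_slow_alpha)
        off = _asymmetric_smooth(off, cfg.rtc_fast_alpha, cfg.rtc_slow_alpha)
    return on, off


def _asymmetric_smooth(x: np.ndarray, fast: float, slow: float) -> np.ndarray:
    """First-order smoother with separate attack/decay rates per sample."""
    lines = _as_lines(x)
    out = np.empty_like(lines)
    out[:, 0] = lines[:, 0]
    for i in range(1, lines.shape[1]):
        prev = out[:, i - 1]
        cur = lines[:, i]
        alpha = np.where(cur >= prev, fast, slow)
        out[:, i] = prev + alpha * (cur - prev)
    return out[0] if x.ndim == 1 else out


def estmd_correlate(
    on: np.ndarray, off: np.ndarray, cfg: MobivlsConfig = MobivlsConfig()
) -> np.ndarray:
    """Delay-and-multiply correlation over the scale bank.

    For bright polarity ``response[i] = sum_s on[i-s] * off[i]``; for dark
    the channel roles are swapped; ``both`` sums the two. Out-of-range
    reads are zero. The response is non-negative.
    """
    on2 = _as_lines(on)
    off2 = _as_lines(off)
    if on2.shape != off2.shape:
        raise DomainError("ON and OFF channels must share a shape")
    n = on2.shape[1]
    if max(cfg.scales) >= n:
        raise ConfigurationError(
            f"largest scale {max(cfg.scales)} must be smaller than line length {n}"
        )

    def delayed_sum(channel: np.ndarray) -> np.ndarray:
        acc = np.zeros_like(channel)
        for s in cfg.scales:
            acc[:, s:] += channel[:, :-s]
        return acc

    if cfg.polarity == "bright":
        resp = delayed_sum(on2) * off2
    elif cfg.polarity == "dark":
        resp = delayed_sum(off2) * on2
    elif cfg.polarity == "both":
        resp = delayed_sum(on2) * off2 + delayed_sum(off2) * on2
    else:  # pragma: no cover - enum guarded by type hints
        raise ConfigurationError(f"unknown polarity {cfg.polarity!r}")
    return resp[0] if np.asarray(on).ndim == 1 else resp


def _scan_lines(lines: np.ndarray, cfg: MobivlsConfig) -> np.ndarray:
    adapted = prc_adapt(lines, cfg)
    bipolar = lmc_filter(adapted, cfg)
    on, off = rtc_split(bipolar, cfg)
    resp = estmd_correlate(on, off, cfg)
    if cfg.scan_reverse_too:
        rev = lines[:, ::-1]
        on_r, off_r = rtc_split(lmc_filter(prc_adapt(rev, cfg), cfg), cfg)
        resp = resp + estmd_correlate(on_r, off_r, cfg)[:, ::-1]
    return resp


def scan_direction(
    frame: ThermalFrame | np.ndarray,
    orientation: Literal["row", "column"],
    cfg: MobivlsConfig = MobivlsConfig(),
) -> np.ndarray:
    """Run the full 1-D pipeline along every row or every column.

    Rows are scanned left-to-right and columns top-to-bottom; the optional
    ``scan_reverse_too`` adds the reversed-direction response.
    """
    pixels = frame.pixels if isinstance(frame, ThermalFrame) else np.asarray(frame)
    pixels = pixels.astype(np.float64)
    if orientation == "row":
        return _scan_lines(pixels, cfg)
    if orientation == "column":
        return _scan_lines(pixels.T, cfg).T
    raise ConfigurationError(f"unknown orientation {orientation!r}")


def _recentre(resp: np.ndarray, axis: int, window: int) -> np.ndarray:
    """Pool a directional response over ``window`` and shift it half a
    window back along the scan axis.

    The delay-and-multiply response of a target concentrates at its
    trailing edge in the scan direction; pooling over the mid-scale and
    re-centring moves that mass onto the target centre so that the row
    and column grids coincide spatially.
    """
    pooled = ndimage.uniform_filter1d(resp, size=window, axis=axis,
                                      mode="constant", cval=0.0)
    shift = window // 2
    if shift == 0:
        return pooled
    out = np.zeros_like(pooled)
    src = [slice(None)] * pooled.ndim
    dst = [slice(None)] * pooled.ndim
    src[axis] = slice(shift, None)
    dst[axis] = slice(None, -shift)
    out[tuple(dst)] = pooled[tuple(src)]
    return out


def mobivls_saliency(
    frame: ThermalFrame | np.ndarray, cfg: MobivlsConfig = MobivlsConfig()
) -> np.ndarray:
    """Combine the two cross-directional scans into a [0, 1] saliency map.

    Each directional grid is pooled over the mid-scale and re-centred so
    the two coincide on the target body, then combined as
    ``H*V + H + V`` (Hadamard product rewards two-axis compactness, the
    sum retains single-axis evidence). The result is scaled by the fixed
    ``response_scale`` and clipped to [0, 1]: responses are kept on an
    absolute scale so maps from different frames are directly comparable
    under one global threshold (a frame with no target stays dark instead
    of having its clutter stretched to full range). A constant frame
    yields an all-zero map.
    """
    h = scan_direction(frame, "row", cfg)
    v = scan_direction(frame, "column", cfg)
    m = cfg.pool_scale or sorted(cfg.scales)[len(cfg.scales) // 2]
    hh = _recentre(h, axis=1, window=m)
    vv = _recentre(v, axis=0, window=m)
    raw = hh * vv + hh + vv
    return np.clip(raw / cfg.response_scale, 0.0, 1.0)


def mobivls_detect(
    frame: ThermalFrame | np.ndarray,
    cfg: MobivlsConfig = MobivlsConfig(),
    frame_id: str | None = None,
) -> list[DetectionRecord]:
    """Adaptive thresholding of the saliency map into detection records.

    The map is thresholded at ``mean + threshold_k * std``, above-threshold
    pixels are grouped into 8-connected components, components smaller than
    ``min_blob_area`` are discarded, and each surviving component emits one
    record at its response-weighted centroid with confidence equal to the
    component's peak map value.
    """
    if frame_id is None:
        frame_id = frame.frame_id if isinstance(frame, ThermalFrame) else ""
    sal = mobivls_saliency(frame, cfg)
    thr = sal.mean() + cfg.threshold_k * sal.std()
    return saliency_to_detections(sal, thr, frame_id, min_blob_area=cfg.min_blob_area)


_EIGHT_CONNECTED = np.ones((3, 3), dtype=bool)


def saliency_to_detections(
    saliency: np.ndarray,
    threshold: float,
    frame_id: str = "",
    min_blob_area: int = 1,
) -> list[DetectionRecord]:
    """Binarise a saliency map and emit one record per connected component."""
    mask = saliency > threshold
    labels, n = ndimage.label(mask, structure=_EIGHT_CONNECTED)
    if n == 0:
        return []
    yy, xx = np.nonzero(mask)
    lab = labels[yy, xx]
    w = saliency[yy, xx]
    areas = np.bincount(lab, minlength=n + 1)[1:]
    wsum = np.bincount(lab, weights=w, minlength=n + 1)[1:]
    xsum = np.bincount(lab, weights=w * xx, minlength=n + 1)[1:]
    ysum = np.bincount(lab, weights=w * yy, minlength=n + 1)[1:]
    peaks = ndimage.maximum(saliency, labels, np.arange(1, n + 1))
    records = []
    for i in range(n):
        if areas[i] < min_blob_area:
            continue
        records.append(
            DetectionRecord(
                frame_id=frame_id,
                x=float(xsum[i] / wsum[i]),
                y=float(ysum[i] / wsum[i]),
                confidence=float(min(peaks[i], 1.0)),
            )
        )
    return records
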