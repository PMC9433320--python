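"""Chromatin dynamics readouts: FRAP normalization/fitting and FRET ratio maps.

FRAP (fluorescence recovery after photobleaching) traces are corrected by
double normalization: the bleach-ROI signal is divided by the whole-region
signal frame by frame (cancelling acquisition bleaching) and rescaled by
the pre-bleach ratio, so the corrected curve starts at 1 before the bleach
and recovers toward the mobile fraction.  Recovery is summarized by a
bounded least-squares fit of ``N(t) = F0 + m·(1−F0)·(1−2^(−t/τ))`` with
post-bleach floor F0, mobile fraction m and half-time τ.

The FRET readout is a background-corrected, denoised FRET/CFP emission
ratio evaluated inside a nuclear mask segmented from the YFP channel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .imgio import BinaryMask, Calibration
from .segcore import gaussian_denoise, otsu_dark_mask

__all__ = [
    "FRAPSeries",
    "measure_frap_series",
    "frap_normalize",
    "frap_fit",
    "fret_ratio_map",
]


@dataclass
class FRAPSeries:
    """Raw FRAP trace: bleach-ROI, whole-region and background means per frame."""

    times: np.ndarray  # s
    roi: np.ndarray
    total: np.ndarray
    background: np.ndarray
    first_post_index: int

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.roi = np.asarray(self.roi, dtype=float)
        self.total = np.asarray(self.total, dtype=float)
        self.background = np.broadcast_to(
            np.asarray(self.background, dtype=float), self.times.shape
        ).copy()
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must increase strictly")
        if self.first_post_index < 2:
            raise ValueError("need at least 2 pre-bleach frames")


def measure_frap_series(
    frames: np.ndarray,
    roi_mask: np.ndarray,
    region_mask: np.ndarray,
    bg_mask: np.ndarray,
    time_step: float,
    first_post_index: int,
) -> FRAPSeries:
    """Extract a :class:`FRAPSeries` from a (t, y, x) image series and ROI masks."""
    frames = np.asarray(frames, dtype=float)
    times = np.arange(frames.shape[0]) * time_step
    roi = frames[:, roi_mask].mean(axis=1)
    total = frames[:, region_mask].mean(axis=1)
    bg = frames[:, bg_mask].mean(axis=1)
    return FRAPSeries(times, roi, total, bg, first_post_index)


def frap_normalize(series: FRAPSeries) -> tuple[np.ndarray, np.ndarray]:
    """Double-normalized recovery curve.

    ``N(t) = [(Iroi(t)−bg)/(Itot(t)−bg)] · [(Itot_pre−bg)/(Iroi_pre−bg)]``
    with pre-bleach values averaged over the pre-bleach frames, so that
    N ≡ 1 before the bleach by construction and acquisition bleaching
    (any common per-frame factor) cancels exactly.  Returns
    ``(post-bleach times relative to the bleach, N over all frames)``.
    """
    k = series.first_post_index
    roi = series.roi - series.background
    tot = series.total - series.background
    if np.any(tot <= 0):
        raise ValueError("whole-region signal does not exceed background")
    roi_pre = roi[:k].mean()
    tot_pre = tot[:k].mean()
    if roi_pre <= 0:
        raise ValueError("pre-bleach ROI signal does not exceed background")
    n = (roi / tot) * (tot_pre / roi_pre)
    t_post = series.times[k:] - series.times[k]
    return t_post, n


def frap_fit(
    t_post: np.ndarray, n_post: np.ndarray
) -> tuple[float, float, float]:
    """Fit ``N(t) = F0 + m·(1−F0)·(1−2^(−t/τ))`` to a normalized recovery.

    Returns ``(mobile_fraction, half_time_s, post_bleach_floor)``.  The
    fit is bounded (m ∈ [0, 1], τ > 0, F0 ∈ [0, 1]) and initialized from
    curve quantiles; a fit that fails to converge raises.
    """
    t = np.asarray(t_post, dtype=float)
    n = np.asarray(n_post, dtype=float)
    if len(t) < 10:
        raise ValueError("need at least 10 post-bleach points")
    f0_init = float(np.clip(n[: max(len(n) // 20, 1)].mean(), 0, 1))
    plateau = float(np.median(n[-max(len(n) // 5, 1) :]))
    m_init = float(np.clip((plateau - f0_init) / max(1 - f0_init, 1e-6), 0.01, 1))
    # first time the curve passes halfway between floor and plateau
    half_level = f0_init + 0.5 * (plateau - f0_init)
    above = np.nonzero(n >= half_level)[0]
    tau_init = float(t[above[0]]) if len(above) and t[above[0]] > 0 else float(t[-1] / 4 + 1e-9)

    def resid(p):
        f0, m, tau = p
        return f0 + m * (1 - f0) * (1.0 - 2.0 ** (-t / tau)) - n

    res = least_squares(
        resid,
        x0=[f0_init, m_init, max(tau_init, t[1] if len(t) > 1 else 1e-3)],
        bounds=([0.0, 0.0, 1e-6], [1.0, 1.0, np.inf]),
    )
    if not res.success:
        raise RuntimeError("FRAP fit did not converge")
    f0, m, tau = res.x
    return float(m), float(tau), float(f0)


def fret_ratio_map(
    cfp: np.ndarray,
    fret: np.ndarray,
    yfp: np.ndarray,
    bg_roi: tuple[int, int, int, int],
    calibration: Calibration | None = None,
    denoise_sigma: float = 5.0,
    clip_range: tuple[float, float] = (0.0, 1.4),
) -> tuple[np.ndarray, float, int]:
    """Background-corrected FRET/CFP ratio inside the YFP nuclear mask.

    The nuclear mask is the Otsu-dark threshold of the σ-denoised YFP
    channel.  Backgrounds for FRET and CFP are measured in the
    extracellular ``bg_roi`` (y0, y1, x0, x1); after subtraction both
    channels are σ-denoised and divided.  Pixels where CFP − bg ≤ 0 are
    excluded and counted.  Returns ``(clipped ratio map with NaN outside
    the mask for display, in-mask mean ratio, n excluded pixels)``.
    """
    cfp = np.asarray(cfp, dtype=float)
    fret = np.asarray(fret, dtype=float)
    yfp = np.asarray(yfp, dtype=float)
    y0, y1, x0, x1 = bg_roi
    bg_f = float(fret[y0:y1, x0:x1].mean())
    bg_c = float(cfp[y0:y1, x0:x1].mean())
    mask = otsu_dark_mask(gaussian_denoise(yfp, denoise_sigma)).values
    if not mask.any():
        raise ValueError("empty nuclear mask")
    num = gaussian_denoise(fret - bg_f, denoise_sigma)
    den = gaussian_denoise(cfp - bg_c, denoise_sigma)
    valid = mask & (den > 0)
    n_excluded = int(mask.sum() - valid.sum())
    ratio = np.full(cfp.shape, np.nan)
    ratio[valid] = num[valid] / den[valid]
    mean_ratio = float(np.nanmean(ratio[valid]))
    display = np.clip(np.nan_to_num(ratio, nan=0.0), *clip_range)
    display[~mask] = 0.0
    return display, mean_ratio, n_excluded
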