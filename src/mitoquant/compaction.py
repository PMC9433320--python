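"""Chromatin compaction, congression and distribution metrics.

Covers the mitotic-chromatin density readouts: the fraction of DNA
congressed to the spindle equator (band profile along the pole-to-pole
axis), mean DNA density within an Otsu chromatin mask normalized to a
control, line-peak density for single chromosomes, the pole-proximal /
pole-distal signal ratio in monopolar spindles, peripheral (pole-distal)
signal for droplet dispersal, the field coefficient of variation, and
background-corrected two-channel intensity ratios.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .imgio import BinaryMask, Calibration
from .segcore import (
    LineProfile,
    find_maxima,
    gaussian_denoise,
    line_profile,
    otsu_dark_mask,
    radial_profile,
)

__all__ = [
    "AxisSpec",
    "detect_poles",
    "congression_fraction",
    "chromatin_density",
    "density_line_peak",
    "radial_displacement_ratio",
    "peripheral_distribution",
    "condensation_cv",
    "normalized_channel_ratio",
]


@dataclass(frozen=True)
class AxisSpec:
    """Pole-to-pole measurement band: two pole positions (y, x in pixels)
    plus the band geometry in μm."""

    p1: tuple[float, float]
    p2: tuple[float, float]
    length_um: float = 22.5
    width_um: float = 7.06
    central_window_um: float = 5.0

    def __post_init__(self) -> None:
        if not self.length_um > self.central_window_um > 0:
            raise ValueError("require length > central window > 0")


def detect_poles(
    tubulin: np.ndarray,
    mode: str = "bipolar",
    min_separation_px: float = 10.0,
    denoise_sigma: float = 2.0,
    prominence_fraction: float = 0.1,
) -> list[tuple[float, float]]:
    """Spindle pole position(s) from the tubulin channel.

    Bipolar: the two highest-intensity prominence maxima of the σ=2
    denoised channel separated by at least ``min_separation_px``.
    Monopolar: the intensity centroid (centre of mass) of the channel.
    """
    img = gaussian_denoise(np.asarray(tubulin, dtype=float), denoise_sigma)
    if mode == "monopolar":
        total = img.sum()
        yy, xx = np.mgrid[0 : img.shape[0], 0 : img.shape[1]]
        return [(float((yy * img).sum() / total), float((xx * img).sum() / total))]
    if mode != "bipolar":
        raise ValueError(f"unknown mode {mode!r}")
    prom = prominence_fraction * (img.max() - img.min())
    spots = find_maxima(img, prominence=max(prom, 1e-9), exclude_edges=True)
    order = np.argsort(spots.intensities)[::-1]
    chosen: list[tuple[float, float]] = []
    for i in order:
        p = tuple(spots.positions[i])
        if all(np.hypot(p[0] - q[0], p[1] - q[1]) >= min_separation_px for q in chosen):
            chosen.append(p)
        if len(chosen) == 2:
            return chosen
    raise ValueError("fewer than two separated tubulin maxima found")


def congression_fraction(
    dna: np.ndarray,
    axis: AxisSpec,
    background: float,
    calibration: Calibration,
    z_range_um: float | None = None,
) -> float:
    """Fraction of band-integrated DNA signal in the central window.

    A band profile of ``axis.length_um × axis.width_um`` is extracted
    along the pole-to-pole axis, centred on the midpoint between the
    poles; the extracellular ``background`` is subtracted per sample with
    negatives clipped to 0, and the sum over the central
    ``axis.central_window_um`` is divided by the sum over the whole
    profile.  3D input is average-projected over ``z_range_um`` around
    the central slice first.
    """
    dna = np.asarray(dna, dtype=float)
    if dna.ndim == 3:
        if calibration.z_step is None:
            raise ValueError("3D input requires z calibration")
        half = (
            int(round((z_range_um / 2) / calibration.z_step))
            if z_range_um is not None
            else dna.shape[0]
        )
        mid = dna.shape[0] // 2
        dna = dna[max(mid - half, 0) : mid + half + 1].mean(axis=0)
    px = calibration.pixel_size_xy
    p1, p2 = np.asarray(axis.p1, float), np.asarray(axis.p2, float)
    mid = (p1 + p2) / 2.0
    u = p2 - p1
    u = u / np.hypot(*u)
    half_len_px = axis.length_um / 2 / px
    start = mid - u * half_len_px
    end = mid + u * half_len_px
    width_px = max(int(round(axis.width_um / px)), 1)
    prof = line_profile(dna, tuple(start), tuple(end), width_px=width_px, calibration=calibration)
    vals = np.clip(prof.intensities - background, 0.0, None)
    total = vals.sum()
    if total <= 0:
        raise ValueError("no DNA signal in profile after background subtraction")
    centre = axis.length_um / 2.0
    in_window = np.abs(prof.distances_um - centre) <= axis.central_window_um / 2.0
    return float(vals[in_window].sum() / total)


def chromatin_density(
    dna: np.ndarray,
    reference_mean: float = 1.0,
    denoise_sigma: float = 2.0,
    background: float = 0.0,
) -> tuple[float, BinaryMask]:
    """Mean DNA intensity within the σ-denoised Otsu chromatin mask,
    divided by ``reference_mean`` (the unperturbed-control mean).

    ``background`` (an extracellular mean, e.g. camera offset) is
    subtracted before the ratio so that density ratios between
    conditions reflect chromatin signal rather than offset.  Returns the
    normalized density and the mask used.
    """
    if reference_mean <= 0:
        raise ValueError("reference mean must be > 0")
    smoothed = gaussian_denoise(np.asarray(dna, dtype=float), denoise_sigma)
    mask = otsu_dark_mask(smoothed)
    if not mask.values.any():
        raise ValueError("empty chromatin mask")
    mean = float(np.asarray(dna, dtype=float)[mask.values].mean()) - background
    return mean / reference_mean, mask


def density_line_peak(profile: LineProfile, window_um: float = 0.2) -> float:
    """Mean intensity in a ``window_um`` interval around the profile's global peak."""
    if profile.length_um <= window_um:
        raise ValueError("profile shorter than the averaging window")
    i_peak = int(np.argmax(profile.intensities))
    centre = profile.distances_um[i_peak]
    sel = np.abs(profile.distances_um - centre) <= window_um / 2.0
    return float(profile.intensities[sel].mean())


def radial_displacement_ratio(
    h2b: np.ndarray,
    center: tuple[float, float],
    inner_fraction: float = 0.30,
    edge_quantile: float = 0.99,
    angle_deg: float = 360.0,
    orientation_deg: float = 0.0,
    calibration: Calibration | None = None,
    background: float = 0.0,
) -> float:
    """Pole-proximal over pole-distal chromatin signal in a monopolar spindle.

    The chromatin edge radius R is the smallest radius containing
    ``edge_quantile`` of the cumulative radial signal; the ratio divides
    the signal within ``inner_fraction × R`` of the pole by the signal in
    the remaining shell out to R.
    """
    # no clipping: the zero-mean residual noise then cancels in the sums
    img = np.asarray(h2b, dtype=float) - background
    px = (calibration or Calibration(1.0)).pixel_size_xy
    yy, xx = np.mgrid[0 : img.shape[0], 0 : img.shape[1]]
    dy = -(yy - center[0])
    dx = xx - center[1]
    rr = np.hypot(dy, dx)
    theta = np.degrees(np.arctan2(dy, dx))
    dtheta = (theta - orientation_deg + 180.0) % 360.0 - 180.0
    sel = np.abs(dtheta) <= angle_deg / 2.0 + 1e-12
    radii = rr[sel].ravel()
    vals = img[sel].ravel()
    order = np.argsort(radii)
    radii, vals = radii[order], vals[order]
    cum = np.cumsum(vals)
    if cum[-1] <= 0:
        raise ValueError("no signal in radial profile")
    R_idx = int(np.searchsorted(cum, edge_quantile * cum[-1]))
    R = radii[min(R_idx, len(radii) - 1)]
    if R <= 0:
        raise ValueError("degenerate radial profile: all signal at the centre")
    k_in = int(np.searchsorted(radii, inner_fraction * R, side="right"))
    inner = cum[k_in - 1] if k_in > 0 else 0.0
    outer = cum[min(R_idx, len(cum) - 1)] - inner
    if outer == 0:
        return float("inf")
    return float(inner / outer)


def peripheral_distribution(
    channel: np.ndarray,
    pole: tuple[float, float],
    cell_mask: BinaryMask,
    pole_radius_um: float = 5.0,
    background: float = 0.0,
) -> float:
    """Total cellular signal outside a ``pole_radius_um`` disc at the pole.

    Returns the background-corrected sum over the cell mask minus the sum
    over the pole disc (clipped to the cell).  Dataset normalization to
    the mean per-cell total is applied by the caller via
    :func:`mitoquant.stats_report.normalize_to_reference`.
    """
    img = np.asarray(channel, dtype=float) - background
    px = cell_mask.pixel_size
    yy, xx = np.mgrid[0 : img.shape[0], 0 : img.shape[1]]
    disc = (yy - pole[0]) ** 2 + (xx - pole[1]) ** 2 <= (pole_radius_um / px) ** 2
    disc &= cell_mask.values
    total = img[cell_mask.values].sum()
    return float(total - img[disc].sum())


def condensation_cv(field: np.ndarray) -> float:
    """Coefficient of variation (σ/μ) of the whole field — the droplet
    condensation score: a field that has de-mixed into droplets has a
    higher CV than a dispersed solution of the same material."""
    field = np.asarray(field, dtype=float)
    mu = field.mean()
    if mu == 0:
        raise ValueError("zero-mean field has no CV")
    return float(field.std() / mu)


def normalized_channel_ratio(
    numerator: np.ndarray,
    denominator: np.ndarray,
    roi: BinaryMask,
    reference: float = 1.0,
    bg_numerator: float = 0.0,
    bg_denominator: float = 0.0,
) -> float:
    """Background-corrected mean-intensity ratio of two channels in a ROI,
    divided by a reference value (e.g. the control-group mean ratio)."""
    if reference <= 0:
        raise ValueError("reference must be > 0")
    if not roi.values.any():
        raise ValueError("empty ROI")
    num = float(np.asarray(numerator, float)[roi.values].mean()) - bg_numerator
    den = float(np.asarray(denominator, float)[roi.values].mean()) - bg_denominator
    if den <= 0:
        raise ValueError("denominator non-positive after background subtraction")
    return (num / den) / reference
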