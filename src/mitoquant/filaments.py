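"""Microtubule density quantification.

Two routes to the same biological question (are microtubules excluded
from chromatin?): a fluorescence route that skeletonizes thresholded
microtubule images and compares skeleton length inside chromatin regions
against the surrounding buffer, and an electron-tomography route that
clips manually annotated microtubule polylines against a voxelized
chromatin domain and reports length per unit volume in each domain.
"""

from __future__ import annotations

import numpy as np

from .imgio import BinaryMask, Calibration
from .segcore import (
    _skeleton_length_px,
    gaussian_denoise,
    otsu_dark_mask,
    phansalkar_mask,
    regions_from_mask,
    rolling_ball_background,
    skeletonize_length,
)
from skimage.morphology import skeletonize

__all__ = ["mt_skeleton_ratio", "tomogram_mt_density"]


def mt_skeleton_ratio(
    tubulin: np.ndarray,
    chromatin: np.ndarray,
    calibration: Calibration,
    denoise_sigma: float = 2.0,
    rolling_ball_radius: int = 50,
    phansalkar_radius: int = 100,
    min_region_px: float = 5.0,
) -> dict:
    """Microtubule skeleton length in chromatin regions vs buffer.

    Pipeline on the tubulin channel: Gaussian denoise → rolling-ball
    background subtraction → Phansalkar local threshold → skeletonize.
    Chromatin ROIs come from the denoised, Otsu-thresholded chromatin
    channel with small particles removed.  Returns a dict with raw
    lengths (μm), areas (μm²) and both the raw chromatin/buffer length
    ratio and the per-unit-area density ratio.
    """
    tub = gaussian_denoise(np.asarray(tubulin, float), denoise_sigma)
    tub = rolling_ball_background(tub, rolling_ball_radius)
    mt_mask = phansalkar_mask(tub, phansalkar_radius, calibration=calibration)
    skel = skeletonize(mt_mask.values)

    chrom_mask = otsu_dark_mask(
        gaussian_denoise(np.asarray(chromatin, float), denoise_sigma)
    )
    chrom_mask = BinaryMask(chrom_mask.values, calibration, "dna")
    regions = regions_from_mask(chrom_mask, min_size_px=min_region_px)
    if regions.n_regions == 0:
        raise ValueError("no chromatin regions detected")
    chrom = regions.labels > 0
    px = calibration.pixel_size_xy
    len_in = _skeleton_length_px(skel & chrom) * px
    len_out = _skeleton_length_px(skel & ~chrom) * px
    if len_out == 0:
        raise ValueError("zero buffer skeleton length")
    area_in = float(chrom.sum()) * px**2
    area_out = float((~chrom).sum()) * px**2
    return {
        "length_in_um": len_in,
        "length_out_um": len_out,
        "area_in_um2": area_in,
        "area_out_um2": area_out,
        "length_ratio": len_in / len_out,
        "density_ratio": (len_in / area_in) / (len_out / area_out),
    }


def tomogram_mt_density(
    polylines: list[np.ndarray],
    chromatin_mask: np.ndarray,
    calibration: Calibration,
    z_window: tuple[int, int] | None = None,
    sample_pitch_factor: float = 0.25,
) -> dict:
    """Microtubule length per unit volume inside and outside chromatin.

    ``polylines`` are (n, 3) arrays of (z, y, x) points in μm;
    ``chromatin_mask`` is a boolean (z, y, x) voxel volume on the same
    frame.  ``z_window = (z0, z1)`` restricts the analysis to slice
    indices [z0, z1) — the sharp centre of a tomogram.  Polyline segments
    are clipped against the mask by uniform subsampling at
    ``sample_pitch_factor`` × the voxel pitch with midpoint membership.
    Returns per-domain lengths (μm), volumes (μm³) and densities
    (μm·μm⁻³).
    """
    mask = np.asarray(chromatin_mask, dtype=bool)
    vz = calibration.z_step if calibration.z_step is not None else calibration.pixel_size_xy
    vxy = calibration.pixel_size_xy
    nz = mask.shape[0]
    z0, z1 = z_window if z_window is not None else (0, nz)
    zlo_um, zhi_um = z0 * vz, z1 * vz
    pitch = sample_pitch_factor * min(vz, vxy)

    len_in = len_out = 0.0
    shape_arr = np.array(mask.shape) - 1
    scale = np.array([vz, vxy, vxy])
    for line in polylines:
        line = np.asarray(line, dtype=float)
        for p0, p1 in zip(line[:-1], line[1:]):
            seg = p1 - p0
            L = float(np.linalg.norm(seg))
            if L == 0:
                continue
            n = max(int(np.ceil(L / pitch)), 1)
            ts = (np.arange(n) + 0.5) / n  # sub-segment midpoints
            pts = p0[None, :] + ts[:, None] * seg[None, :]
            in_slab = (pts[:, 0] >= zlo_um) & (pts[:, 0] < zhi_um)
            idx = np.clip(np.round(pts / scale).astype(int), 0, shape_arr)
            inside = mask[idx[:, 0], idx[:, 1], idx[:, 2]]
            piece = L / n
            len_in += piece * np.count_nonzero(in_slab & inside)
            len_out += piece * np.count_nonzero(in_slab & ~inside)

    window_mask = mask[z0:z1]
    voxel_vol = vz * vxy * vxy
    vol_in = float(window_mask.sum()) * voxel_vol
    vol_out = float(window_mask.size - window_mask.sum()) * voxel_vol
    if vol_in == 0 or vol_out == 0:
        raise ValueError("empty domain volume in the analysed window")
    return {
        "length_in_um": len_in,
        "length_out_um": len_out,
        "volume_in_um3": vol_in,
        "volume_out_um3": vol_out,
        "density_chromatin": len_in / vol_in,
        "density_cytoplasm": len_out / vol_out,
    }
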