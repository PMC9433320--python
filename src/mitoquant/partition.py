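"""Partition-coefficient measurements.

The partition coefficient is the equilibrium ratio of a probe's
background-corrected mean intensity inside a compartment (mitotic
chromatin, or a chromatin droplet in vitro) to that in the surrounding
phase (cytoplasm or buffer).  Four measurement geometries are provided,
matching how the readout is taken in cells and in vitro:

``line``      — intensity ratio at fixed offsets on either side of the
                compartment boundary along a line profile crossing it;
``mask_ring`` — mean in the shrunk chromatin mask over mean in a ring
                just outside it, both background-corrected;
``circle``    — mean over chromatin regions over mean in a cytoplasmic
                disc placed clear of the chromosomes;
``droplet``   — per-field: mean over concentric discs covering a fixed
                fraction of each droplet over the buffer mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .imgio import BinaryMask, Calibration, RegionSet
from .segcore import (
    LineProfile,
    gaussian_denoise,
    morph_offset,
    otsu_dark_mask,
    ring_roi,
)

__all__ = [
    "PartitionMeasurement",
    "partition_line",
    "partition_mask_ring",
    "partition_circle",
    "partition_droplet",
]


@dataclass
class PartitionMeasurement:
    """Inside/outside means, backgrounds and the resulting coefficient."""

    inside_mean: float
    outside_mean: float
    coefficient: float
    method: str
    background: float = 0.0
    geometry: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.method not in {"line", "mask_ring", "circle", "droplet"}:
            raise ValueError(f"unknown method {self.method!r}")


def _half_max_crossings(profile: LineProfile) -> list[float]:
    """Distances (μm) where the profile crosses 50% of its max, linear interp."""
    v = profile.intensities
    half = (v.max() + v.min()) / 2.0
    above = v >= half
    out = []
    for i in range(len(v) - 1):
        if above[i] != above[i + 1]:
            t = (half - v[i]) / (v[i + 1] - v[i])
            out.append(float(profile.distances_um[i] + t * np.diff(profile.distances_um[i : i + 2])[0]))
    return out


def partition_line(
    probe_profile: LineProfile,
    reference_profile: LineProfile,
    offset_um: float = 1.0,
    background: float = 0.0,
) -> PartitionMeasurement:
    """Partition coefficient from a boundary-crossing line profile.

    The compartment boundary is located at the 50%-of-max crossing of the
    reference (DNA) profile along the same line; the side with the higher
    reference mean is "inside".  The coefficient divides the probe
    intensity ``offset_um`` inside the boundary by the intensity
    ``offset_um`` outside (linear interpolation between samples).  When
    an offset falls beyond the sampled range the nearest end value is
    used and the measurement is flagged in its geometry record.
    """
    crossings = _half_max_crossings(reference_profile)
    if not crossings:
        raise ValueError("reference profile does not cross its half-maximum")
    b = crossings[0]
    d = reference_profile.distances_um
    lo = reference_profile.intensities[d <= b]
    hi = reference_profile.intensities[d > b]
    inside_is_high_side = hi.mean() > lo.mean() if len(lo) and len(hi) else True
    sign = 1.0 if inside_is_high_side else -1.0
    pos_in = b + sign * offset_um
    pos_out = b - sign * offset_um
    length = probe_profile.length_um
    extended = not (0.0 <= pos_in <= length and 0.0 <= pos_out <= length)
    inside = probe_profile.value_at(float(np.clip(pos_in, 0, length)))
    outside = probe_profile.value_at(float(np.clip(pos_out, 0, length)))
    if outside - background <= 0:
        raise ValueError("outside intensity does not exceed background")
    return PartitionMeasurement(
        inside_mean=inside,
        outside_mean=outside,
        coefficient=(inside - background) / (outside - background),
        method="line",
        background=background,
        geometry={
            "boundary_um": b,
            "offset_um": offset_um,
            "extended_beyond_profile": extended,
        },
    )


def partition_mask_ring(
    probe: np.ndarray,
    dna: np.ndarray,
    calibration: Calibration,
    shrink_um: float = 0.2,
    extend_um: float = 1.5,
    ring_width_um: float = 0.5,
    background: float = 0.0,
    denoise_sigma: float = 2.0,
) -> PartitionMeasurement:
    """Chromatin-mask / cytoplasmic-ring partition coefficient.

    The chromatin mask (σ blur + Otsu-dark on the DNA channel) is shrunk
    by ``shrink_um``; cytoplasm is measured in a ring of
    ``ring_width_um`` obtained by extending the mask by ``extend_um``.
    The extracellular ``background`` is subtracted from both means.
    """
    probe = np.asarray(probe, dtype=float)
    mask0 = otsu_dark_mask(gaussian_denoise(np.asarray(dna, float), denoise_sigma))
    mask = BinaryMask(mask0.values, calibration, "dna")
    shrunk = morph_offset(mask, -shrink_um)
    if not shrunk.values.any():
        raise ValueError("chromatin mask empty after shrinking")
    ring = ring_roi(mask, extend_um, ring_width_um)
    if not ring.values.any():
        raise ValueError("empty cytoplasmic ring")
    inside = float(probe[shrunk.values].mean())
    outside = float(probe[ring.values].mean())
    if outside - background <= 0:
        raise ValueError("ring mean does not exceed background")
    return PartitionMeasurement(
        inside_mean=inside,
        outside_mean=outside,
        coefficient=(inside - background) / (outside - background),
        method="mask_ring",
        background=background,
        geometry={"shrink_um": shrink_um, "extend_um": extend_um, "ring_width_um": ring_width_um},
    )


def partition_circle(
    probe: np.ndarray,
    dna_regions: RegionSet,
    cell_mask: BinaryMask | None = None,
    circle_diameter_um: float = 5.0,
    min_clearance_um: float = 1.0,
    background: float = 0.0,
) -> PartitionMeasurement:
    """Chromatin-region / cytoplasmic-disc partition coefficient.

    A disc of ``circle_diameter_um`` is placed in the cytoplasm with at
    least ``min_clearance_um`` Euclidean clearance from every chromatin
    region (search on the distance transform, choosing the most distant
    valid centre); the coefficient divides the mean over the chromatin
    regions by the mean over the disc.
    """
    probe = np.asarray(probe, dtype=float)
    px = dna_regions.calibration.pixel_size_xy
    chrom = dna_regions.labels > 0
    if not chrom.any():
        raise ValueError("no chromatin regions")
    r_px = circle_diameter_um / 2.0 / px
    dist = ndimage.distance_transform_edt(~chrom) * px
    valid = dist >= (min_clearance_um + circle_diameter_um / 2.0)
    if cell_mask is not None:
        inside_cell = ndimage.distance_transform_edt(cell_mask.values) >= r_px
        valid &= inside_cell
    # keep the disc inside the image
    yy, xx = np.mgrid[0 : probe.shape[0], 0 : probe.shape[1]]
    valid &= (
        (yy >= r_px)
        & (yy <= probe.shape[0] - 1 - r_px)
        & (xx >= r_px)
        & (xx <= probe.shape[1] - 1 - r_px)
    )
    if not valid.any():
        raise ValueError("no valid cytoplasmic disc placement")
    best = np.unravel_index(np.argmax(np.where(valid, dist, -1)), dist.shape)
    disc = (yy - best[0]) ** 2 + (xx - best[1]) ** 2 <= r_px**2
    inside = float(probe[chrom].mean())
    outside = float(probe[disc].mean())
    if outside - background <= 0:
        raise ValueError("cytoplasmic disc mean does not exceed background")
    return PartitionMeasurement(
        inside_mean=inside,
        outside_mean=outside,
        coefficient=(inside - background) / (outside - background),
        method="circle",
        background=background,
        geometry={
            "circle_center": [float(best[0]), float(best[1])],
            "circle_diameter_um": circle_diameter_um,
            "min_clearance_um": min_clearance_um,
        },
    )


def partition_droplet(
    probe: np.ndarray,
    droplets: RegionSet,
    buffer_rect: tuple[int, int, int, int],
    interior_area_fraction: float = 0.25,
    background: float = 0.0,
) -> PartitionMeasurement:
    """Per-field droplet partition coefficient.

    For each segmented droplet a concentric disc covering
    ``interior_area_fraction`` of its area is measured; the field
    coefficient divides the mean over these discs by the mean in the
    droplet-free ``buffer_rect`` (y0, y1, x0, x1).
    """
    probe = np.asarray(probe, dtype=float)
    y0, y1, x0, x1 = buffer_rect
    rect = np.zeros(probe.shape, dtype=bool)
    rect[y0:y1, x0:x1] = True
    if (droplets.labels[rect] > 0).any():
        raise ValueError("buffer rectangle intersects droplets")
    if droplets.n_regions == 0:
        raise ValueError("no droplets segmented")
    yy, xx = np.mgrid[0 : probe.shape[0], 0 : probe.shape[1]]
    interior = np.zeros(probe.shape, dtype=bool)
    for rid in range(1, droplets.n_regions + 1):
        sel = droplets.labels == rid
        area = sel.sum()
        cy = (yy[sel]).mean()
        cx = (xx[sel]).mean()
        r = np.sqrt(interior_area_fraction * area / np.pi)
        interior |= ((yy - cy) ** 2 + (xx - cx) ** 2 <= r**2) & sel
    inside = float(probe[interior].mean())
    buffer_mean = float(probe[rect].mean())
    if buffer_mean - background <= 0:
        raise ValueError("buffer mean does not exceed background")
    return PartitionMeasurement(
        inside_mean=inside,
        outside_mean=buffer_mean,
        coefficient=(inside - background) / (buffer_mean - background),
        method="droplet",
        background=background,
        geometry={
            "interior_area_fraction": interior_area_fraction,
            "n_droplets": droplets.n_regions,
        },
    )
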