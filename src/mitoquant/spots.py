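"""Spot-based classification metrics.

Kinetochore displacement (fraction of centromere spots further than a
distance cut outside the chromatin mask), DNA-damage focus counting
within the chromatin mask, and the per-cell apoptotic index from marker
mean-intensity tables.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .imgio import BinaryMask, Calibration
from .segcore import (
    SpotSet,
    distance_to_mask_surface,
    find_maxima,
    gaussian_denoise,
    otsu_dark_mask,
    regions_from_mask,
)

__all__ = [
    "chromatin_mask",
    "kinetochore_displacement",
    "count_foci",
    "apoptotic_index",
    "per_cell_means",
]


def chromatin_mask(
    dna: np.ndarray, calibration: Calibration, denoise_sigma: float = 2.0
) -> BinaryMask:
    """σ-denoise then Otsu-dark threshold of the DNA channel."""
    mask = otsu_dark_mask(gaussian_denoise(np.asarray(dna, float), denoise_sigma))
    return BinaryMask(mask.values, calibration, "dna")


def kinetochore_displacement(
    cenpa: np.ndarray,
    dna: np.ndarray,
    calibration: Calibration,
    prominence: float = 100.0,
    distance_cut_um: float = 0.5,
    cenpa_denoise_sigma: float = 1.0,
    dna_denoise_sigma: float = 2.0,
) -> tuple[float, SpotSet, np.ndarray]:
    """Fraction of kinetochores displaced outside chromatin.

    Spots are prominence maxima of the σ=1 denoised centromere channel
    (edge maxima excluded); the chromatin mask is the σ=2 denoised
    Otsu-dark DNA mask.  A spot counts as outside when its signed
    distance to the mask surface exceeds ``+distance_cut_um``.  Returns
    the fraction, the spot set and the per-spot signed distances (μm).
    """
    spots = find_maxima(
        gaussian_denoise(np.asarray(cenpa, float), cenpa_denoise_sigma),
        prominence=prominence,
        exclude_edges=True,
    )
    if len(spots) == 0:
        raise ValueError("no kinetochore spots detected")
    mask = chromatin_mask(dna, calibration, dna_denoise_sigma)
    dists = distance_to_mask_surface(spots.positions, mask)
    frac = float(np.count_nonzero(dists > distance_cut_um) / len(spots))
    return frac, spots, dists


def count_foci(
    foci: np.ndarray,
    dna: np.ndarray,
    calibration: Calibration,
    prominence: float = 3000.0,
    denoise_sigma: float = 2.0,
) -> int:
    """Count prominence maxima of the focus channel inside the chromatin mask.

    The input is expected to be a maximum-intensity projection; both
    channels are σ-denoised, the DNA mask is Otsu-dark.
    """
    smoothed = gaussian_denoise(np.asarray(foci, float), denoise_sigma)
    spots = find_maxima(smoothed, prominence=prominence, exclude_edges=True)
    if len(spots) == 0:
        return 0
    mask = chromatin_mask(dna, calibration, denoise_sigma)
    idx = np.clip(
        np.round(spots.positions).astype(int), 0, np.array(mask.values.shape) - 1
    )
    return int(np.count_nonzero(mask.values[tuple(idx.T)]))


def apoptotic_index(
    cells: pd.DataFrame,
    control: pd.DataFrame,
    markers: tuple[str, ...] = ("mean_psiva", "mean_pi"),
    threshold_factor: float = 1.2,
    rule: str = "and",
) -> tuple[pd.DataFrame, float]:
    """Fraction of cells scoring positive for the apoptosis markers.

    A cell is positive for a marker when its mean intensity strictly
    exceeds ``threshold_factor`` × the median of the control population
    for that marker.  ``rule='and'`` requires positivity for all markers
    jointly (the apoptotic-index definition); ``rule='or'`` accepts any.
    Returns the table with per-marker flags and the index.
    """
    if control.empty:
        raise ValueError("empty control population")
    if rule not in ("and", "or"):
        raise ValueError("rule must be 'and' or 'or'")
    out = cells.copy()
    flags = []
    for m in markers:
        thr = threshold_factor * float(control[m].median())
        col = out[m].to_numpy(dtype=float) > thr
        out[f"{m}_positive"] = col
        flags.append(col)
    combined = np.logical_and.reduce(flags) if rule == "and" else np.logical_or.reduce(flags)
    out["positive"] = combined
    return out, float(combined.mean())


def per_cell_means(
    dna: np.ndarray,
    marker_channels: dict[str, np.ndarray],
    calibration: Calibration,
    denoise_sigma: float = 2.0,
    min_size_px: float = 50.0,
) -> pd.DataFrame:
    """Segment cells from the DNA channel (σ blur + Otsu-dark + particle
    analysis, one region per cell) and tabulate per-cell marker means."""
    mask = chromatin_mask(dna, calibration, denoise_sigma)
    regions = regions_from_mask(mask, min_size_px=min_size_px)
    rows = []
    for rid in range(1, regions.n_regions + 1):
        sel = regions.labels == rid
        row: dict[str, object] = {"cell_id": f"cell{rid}"}
        for name, chan in marker_channels.items():
            row[f"mean_{name}"] = float(np.asarray(chan, float)[sel].mean())
        rows.append(row)
    return pd.DataFrame(rows)
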