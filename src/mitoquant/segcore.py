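"""Shared segmentation and profiling primitives.

Every metric in this package is a composition of a small number of image
primitives: Gaussian denoising, global (Otsu) and local (Phansalkar)
thresholding, prominence-based maxima detection, physical-unit
morphology on the Euclidean distance transform, rolling-ball style
background removal, skeleton length measurement, and line/radial
intensity profiles.  All physical parameters are in micrometres and are
converted with the mask/stack calibration; pixel centres sit at integer
coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage.filters import threshold_otsu
from skimage.morphology import skeletonize

from .imgio import BinaryMask, Calibration, RegionSet

__all__ = [
    "SpotSet",
    "LineProfile",
    "RadialProfile",
    "gaussian_denoise",
    "otsu_dark_mask",
    "phansalkar_mask",
    "find_maxima",
    "morph_offset",
    "ring_roi",
    "rolling_ball_background",
    "skeletonize_length",
    "line_profile",
    "radial_profile",
    "regions_from_mask",
    "distance_to_mask_surface",
]


@dataclass
class SpotSet:
    """Detected local maxima: positions in pixel coordinates plus peak intensities."""

    positions: np.ndarray  # (n, 2) or (n, 3) float, (y, x) or (z, y, x)
    intensities: np.ndarray  # (n,)
    prominence: float

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        if self.positions.size == 0:
            self.positions = self.positions.reshape(0, 2)
        self.intensities = np.asarray(self.intensities, dtype=float)

    def __len__(self) -> int:
        return len(self.positions)


@dataclass
class LineProfile:
    """1D intensity sampling along a straight segment.

    ``distances_um`` start at 0 at the segment start and increase
    strictly; each intensity is the mean of ``width_px`` bilinear samples
    taken perpendicular to the segment, symmetric about it.
    """

    start: tuple[float, float]
    end: tuple[float, float]
    width_px: int
    distances_um: np.ndarray
    intensities: np.ndarray
    step_um: float

    def __post_init__(self) -> None:
        self.distances_um = np.asarray(self.distances_um, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if len(self.distances_um) != len(self.intensities):
            raise ValueError("distance/intensity length mismatch")
        if len(self.distances_um) and (
            self.distances_um[0] != 0.0 or np.any(np.diff(self.distances_um) <= 0)
        ):
            raise ValueError("distances must increase strictly from 0")

    def value_at(self, distance_um: float) -> float:
        """Linearly interpolated intensity at a physical distance from the start."""
        return float(np.interp(distance_um, self.distances_um, self.intensities))

    @property
    def length_um(self) -> float:
        return float(self.distances_um[-1]) if len(self.distances_um) else 0.0


@dataclass
class RadialProfile:
    """Per-integer-radius integrated intensity around a centre point.

    ``angle_deg`` is the full integration cone Θ: pixels whose polar
    angle lies within ±Θ/2 of ``orientation_deg`` contribute.  Θ = 360°
    integrates the full circle, Θ = 180° a half-plane.
    """

    center: tuple[float, float]
    radii_um: np.ndarray
    sums: np.ndarray
    angle_deg: float
    orientation_deg: float

    def __post_init__(self) -> None:
        self.radii_um = np.asarray(self.radii_um, dtype=float)
        self.sums = np.asarray(self.sums, dtype=float)
        if np.any(self.sums < 0):
            raise ValueError("bin intensities must be non-negative")


def gaussian_denoise(img: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian blur with std ``sigma`` in pixels; ``sigma=0`` is the identity."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    img = np.asarray(img, dtype=float)
    if sigma == 0:
        return img.copy()
    return ndimage.gaussian_filter(img, sigma=sigma, mode="nearest")


def otsu_dark_mask(
    img: np.ndarray, calibration: Calibration | None = None, nbins: int = 256
) -> BinaryMask:
    """Otsu threshold with dark background: the bright class is foreground.

    The threshold maximizes the between-class variance of the ``nbins``-bin
    intensity histogram; the mask keeps pixels strictly above it.
    """
    img = np.asarray(img, dtype=float)
    if np.all(img == img.flat[0]):
        raise ValueError("constant image has no Otsu threshold")
    t = threshold_otsu(img, nbins=nbins)
    cal = calibration or Calibration(pixel_size_xy=1.0)
    return BinaryMask(img > t, cal)


def _disk_footprint(radius: int) -> np.ndarray:
    yy, xx = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    return (yy**2 + xx**2) <= radius**2


def phansalkar_mask(
    img: np.ndarray,
    radius: int,
    k: float = 0.25,
    r: float = 0.5,
    p: float = 2.0,
    q: float = 10.0,
    calibration: Calibration | None = None,
) -> BinaryMask:
    """Phansalkar local threshold for low-contrast bright structures.

    The image is min–max rescaled to [0, 1]; a pixel is foreground iff its
    value exceeds ``m·(1 + p·exp(−q·m) + k·(s/r − 1))`` where m and s are
    the mean and (population) standard deviation over the disk-shaped
    ``radius`` neighbourhood clipped to the image.
    """
    if radius < 1:
        raise ValueError("radius must be >= 1")
    img = np.asarray(img, dtype=float)
    lo, hi = img.min(), img.max()
    scaled = np.zeros_like(img) if hi == lo else (img - lo) / (hi - lo)
    foot = _disk_footprint(int(radius)).astype(float)
    if radius <= 16:
        conv = lambda a: ndimage.convolve(a, foot, mode="constant", cval=0.0)  # noqa: E731
    else:
        from scipy.signal import fftconvolve

        conv = lambda a: fftconvolve(a, foot, mode="same")  # noqa: E731
    counts = conv(np.ones_like(scaled))
    s1 = conv(scaled)
    s2 = conv(scaled**2)
    mean = s1 / counts
    var = np.maximum(s2 / counts - mean**2, 0.0)
    sd = np.sqrt(var)
    thresh = mean * (1.0 + p * np.exp(-q * mean) + k * (sd / r - 1.0))
    cal = calibration or Calibration(pixel_size_xy=1.0)
    return BinaryMask(scaled > thresh, cal)


def find_maxima(
    img: np.ndarray, prominence: float, exclude_edges: bool = True
) -> SpotSet:
    """Local maxima whose topographic prominence is at least ``prominence``.

    Prominence is the peak height above the highest saddle connecting the
    peak to any higher region; the surviving global maximum is measured
    against the image minimum.  Equal-valued plateaus are reported once,
    at the plateau centroid; when two equal peaks merge, the one whose
    peak occurs earlier in raster order survives.  Maxima whose peak
    plateau touches the image border are removed when ``exclude_edges``.
    """
    if prominence <= 0:
        raise ValueError("prominence must be > 0")
    a = np.asarray(img, dtype=float)
    if a.ndim != 2:
        raise ValueError("find_maxima expects a 2D image")
    h, w = a.shape
    n = a.size
    flat = a.ravel()
    order = np.lexsort((np.arange(n), -flat))  # descending value, raster-stable

    parent = np.full(n, -1, dtype=np.int64)

    def find(i: int) -> int:
        root = i
        while parent[root] != root:
            root = parent[root]
        while parent[i] != root:
            parent[i], i = root, parent[i]
        return root

    # per-root peak bookkeeping
    peak_val = np.zeros(n)
    peak_first = np.zeros(n, dtype=np.int64)  # raster index of first peak pixel
    cy = np.zeros(n)
    cx = np.zeros(n)
    cn = np.zeros(n, dtype=np.int64)
    edge = np.zeros(n, dtype=bool)
    active = np.zeros(n, dtype=bool)

    results: list[tuple[float, float, float]] = []  # (y, x, peak value)

    def neighbors(idx: int):
        y, x = divmod(idx, w)
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if dy == 0 and dx == 0:
                    continue
                yy, xx = y + dy, x + dx
                if 0 <= yy < h and 0 <= xx < w:
                    yield yy * w + xx

    i = 0
    while i < n:
        v = flat[order[i]]
        j = i
        while j < n and flat[order[j]] == v:
            j += 1
        level = order[i:j]
        for p_ in level:
            parent[p_] = p_
            peak_val[p_] = v
            peak_first[p_] = p_
            y, x = divmod(int(p_), w)
            cy[p_], cx[p_], cn[p_] = y, x, 1
            edge[p_] = y in (0, h - 1) or x in (0, w - 1)
            active[p_] = True
        # union each new pixel with all active neighbours (value >= v).
        # A merge of two components both peaking at v pools a plateau; a
        # merge where the lower peak exceeds v is a prominence event.
        for p_ in level:
            for q_ in neighbors(int(p_)):
                if not active[q_]:
                    continue
                ra, rb = find(int(p_)), find(int(q_))
                if ra == rb:
                    continue
                if peak_val[ra] == peak_val[rb] == v:
                    keep, drop = (ra, rb) if peak_first[ra] <= peak_first[rb] else (rb, ra)
                    cy[keep] += cy[drop]
                    cx[keep] += cx[drop]
                    cn[keep] += cn[drop]
                    edge[keep] |= edge[drop]
                    parent[drop] = keep
                    continue
                if peak_val[ra] > peak_val[rb] or (
                    peak_val[ra] == peak_val[rb] and peak_first[ra] <= peak_first[rb]
                ):
                    keep, drop = ra, rb
                else:
                    keep, drop = rb, ra
                if peak_val[drop] - v >= prominence and not (
                    exclude_edges and edge[drop]
                ):
                    results.append(
                        (cy[drop] / cn[drop], cx[drop] / cn[drop], peak_val[drop])
                    )
                parent[drop] = keep
        i = j

    vmin = flat.min()
    roots = {find(int(k)) for k in range(n)}
    for root in roots:
        if peak_val[root] - vmin >= prominence and not (exclude_edges and edge[root]):
            results.append((cy[root] / cn[root], cx[root] / cn[root], peak_val[root]))

    if not results:
        return SpotSet(np.empty((0, 2)), np.empty(0), prominence)
    results.sort(key=lambda t: (t[0], t[1]))
    pos = np.array([(y, x) for y, x, _ in results])
    inten = np.array([val for _, _, val in results])
    return SpotSet(pos, inten, prominence)


def morph_offset(mask: BinaryMask, offset_um: float) -> BinaryMask:
    """Grow (offset > 0) or shrink (offset < 0) a mask by a Euclidean distance.

    Implemented as a threshold on the exact Euclidean distance transform,
    so the offset is isotropic in physical units regardless of pixel size.
    """
    px = mask.pixel_size
    values = mask.values
    if offset_um == 0 or not values.any():
        return BinaryMask(values.copy(), mask.calibration, mask.source_channel)
    d = abs(offset_um) / px
    if offset_um > 0:
        dist = ndimage.distance_transform_edt(~values)
        out = dist <= d
    else:
        dist = ndimage.distance_transform_edt(values)
        out = dist > d
    return BinaryMask(out, mask.calibration, mask.source_channel)


def ring_roi(mask: BinaryMask, extend_um: float, width_um: float) -> BinaryMask:
    """Ring around a mask: dilation by ``extend`` minus dilation by ``extend − width``."""
    if not (extend_um >= width_um > 0):
        raise ValueError("require extend >= width > 0")
    outer = morph_offset(mask, extend_um)
    inner = morph_offset(mask, extend_um - width_um) if extend_um > width_um else mask
    return BinaryMask(outer.values & ~inner.values, mask.calibration, mask.source_channel)


def rolling_ball_background(img: np.ndarray, radius: int) -> np.ndarray:
    """Subtract a smooth background estimated by grayscale opening with a disk.

    Structures thinner than the structuring element survive; broad
    background (including slow ramps) is removed.  Output is clipped at 0.
    A radius exceeding the image reduces the background to the global
    minimum.
    """
    if radius < 1:
        raise ValueError("radius must be >= 1")
    img = np.asarray(img, dtype=float)
    if radius >= max(img.shape):
        background = np.full_like(img, img.min())
    elif radius <= 16:
        foot = _disk_footprint(int(radius))
        background = ndimage.grey_opening(img, footprint=foot, mode="nearest")
    else:
        # large radii: opening on a block-minimum coarse grid (the
        # background is smooth at this scale), then upsample; clipped so
        # the background never exceeds the image.
        ds = max(int(radius) // 12, 2)
        h, w = img.shape
        ph, pw = (-h) % ds, (-w) % ds
        padded = np.pad(img, ((0, ph), (0, pw)), mode="edge")
        coarse = padded.reshape(
            padded.shape[0] // ds, ds, padded.shape[1] // ds, ds
        ).min(axis=(1, 3))
        foot = _disk_footprint(max(int(round(radius / ds)), 1))
        opened = ndimage.grey_opening(coarse, footprint=foot, mode="nearest")
        background = ndimage.zoom(opened, ds, order=1)[:h, :w]
        background = np.minimum(background, img)
    return np.clip(img - background, 0.0, None)


def skeletonize_length(mask: BinaryMask) -> tuple[BinaryMask, float]:
    """Thin a 2D mask to 1-px curves and measure their total length in μm.

    Length is the sum over pairs of 8-adjacent skeleton pixels of the step
    length (1 for axial, √2 for diagonal steps) times the pixel size.
    """
    if mask.values.ndim != 2:
        raise ValueError("skeletonize_length expects a 2D mask")
    skel = skeletonize(mask.values)
    length_px = _skeleton_length_px(skel)
    return BinaryMask(skel, mask.calibration, mask.source_channel), length_px * mask.pixel_size


def _skeleton_length_px(skel: np.ndarray) -> float:
    s = skel.astype(bool)
    axial = np.count_nonzero(s[:, :-1] & s[:, 1:]) + np.count_nonzero(s[:-1, :] & s[1:, :])
    diag = np.count_nonzero(s[:-1, :-1] & s[1:, 1:]) + np.count_nonzero(
        s[:-1, 1:] & s[1:, :-1]
    )
    return float(axial) + float(diag) * np.sqrt(2.0)


def line_profile(
    img: np.ndarray,
    start: tuple[float, float],
    end: tuple[float, float],
    width_px: int = 1,
    calibration: Calibration | None = None,
    step_px: float = 1.0,
) -> LineProfile:
    """Averaged intensity profile along a segment, bilinear interpolation.

    ``start`` and ``end`` are (y, x) pixel coordinates.  Each sample is
    the mean of ``width_px`` bilinear samples spaced 1 px perpendicular to
    the segment, symmetric about it.
    """
    if width_px < 1:
        raise ValueError("width_px must be >= 1")
    cal = calibration or Calibration(pixel_size_xy=1.0)
    start = np.asarray(start, dtype=float)
    end = np.asarray(end, dtype=float)
    vec = end - start
    length_px = float(np.hypot(*vec))
    if length_px == 0:
        raise ValueError("zero-length segment")
    u = vec / length_px
    perp = np.array([-u[1], u[0]])
    n_samples = int(np.floor(length_px / step_px)) + 1
    ts = np.arange(n_samples) * step_px
    offsets = (np.arange(width_px) - (width_px - 1) / 2.0)[:, None]  # (w, 1)
    centers = start[None, :] + ts[:, None] * u[None, :]  # (n, 2)
    coords = centers[None, :, :] + offsets[:, None] * perp[None, None, :]  # (w, n, 2)
    samples = ndimage.map_coordinates(
        np.asarray(img, dtype=float),
        [coords[..., 0].ravel(), coords[..., 1].ravel()],
        order=1,
        mode="nearest",
    ).reshape(width_px, n_samples)
    return LineProfile(
        start=tuple(start),
        end=tuple(end),
        width_px=width_px,
        distances_um=ts * cal.pixel_size_xy,
        intensities=samples.mean(axis=0),
        step_um=step_px * cal.pixel_size_xy,
    )


def radial_profile(
    img: np.ndarray,
    center: tuple[float, float],
    angle_deg: float = 360.0,
    orientation_deg: float = 0.0,
    calibration: Calibration | None = None,
) -> RadialProfile:
    """Integrated intensity per integer-radius bin inside an angular sector.

    A pixel at polar angle θ (measured counter-clockwise from +x, with +y
    pointing up, i.e. decreasing row index) contributes to the bin at its
    rounded radius iff the wrapped difference θ − orientation lies within
    ±``angle_deg``/2.
    """
    cal = calibration or Calibration(pixel_size_xy=1.0)
    img = np.asarray(img, dtype=float)
    cy_, cx_ = center
    yy, xx = np.mgrid[0 : img.shape[0], 0 : img.shape[1]]
    dy = -(yy - cy_)  # +y up
    dx = xx - cx_
    rr = np.hypot(dy, dx)
    theta = np.degrees(np.arctan2(dy, dx))
    dtheta = (theta - orientation_deg + 180.0) % 360.0 - 180.0
    sel = np.abs(dtheta) <= angle_deg / 2.0 + 1e-12
    rbin = np.round(rr).astype(int)
    nbins = int(rbin[sel].max()) + 1 if np.any(sel) else 1
    sums = np.bincount(rbin[sel].ravel(), weights=img[sel].ravel(), minlength=nbins)
    radii = np.arange(nbins) * cal.pixel_size_xy
    return RadialProfile(
        center=(float(cy_), float(cx_)),
        radii_um=radii,
        sums=np.maximum(sums, 0.0),
        angle_deg=angle_deg,
        orientation_deg=orientation_deg,
    )


def regions_from_mask(
    mask: BinaryMask, min_size_px: float = 0.0
) -> RegionSet:
    """8-connected components of a 2D mask, dropping regions below ``min_size_px`` pixels."""
    if min_size_px < 0:
        raise ValueError("min_size_px must be >= 0")
    structure = np.ones((3,) * mask.values.ndim, dtype=bool)
    labels, n = ndimage.label(mask.values, structure=structure)
    if n:
        counts = np.bincount(labels.ravel())
        keep = np.flatnonzero(counts >= min_size_px)
        keep = keep[keep > 0]
        remap = np.zeros(n + 1, dtype=labels.dtype)
        remap[keep] = np.arange(1, len(keep) + 1)
        labels = remap[labels]
    return RegionSet(labels, mask.calibration)


def _boundary_pixels(values: np.ndarray) -> np.ndarray:
    eroded = ndimage.binary_erosion(
        values, structure=ndimage.generate_binary_structure(values.ndim, 1),
        border_value=0,
    )
    return np.argwhere(values & ~eroded)


def distance_to_mask_surface(points: np.ndarray, mask: BinaryMask) -> np.ndarray:
    """Signed Euclidean distance (μm) from each point to the mask surface.

    Negative inside the mask, positive outside.  For 3D masks, the z axis
    is scaled by the calibration aspect before the distance is computed.
    """
    values = mask.values
    if not values.any():
        raise ValueError("empty mask has no surface")
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    boundary = _boundary_pixels(values).astype(float)
    scale = np.ones(values.ndim)
    if values.ndim == 3:
        scale[0] = mask.calibration.z_aspect
    tree = cKDTree(boundary * scale)
    d, _ = tree.query(pts * scale)
    idx = np.clip(np.round(pts).astype(int), 0, np.array(values.shape) - 1)
    inside = values[tuple(idx.T)]
    sign = np.where(inside, -1.0, 1.0)
    return sign * d * mask.pixel_size
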