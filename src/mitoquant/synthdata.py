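"""Synthetic microscopy scenes with exact ground truth.

Real inputs to these pipelines are calibrated fluorescence stacks of
mitotic cells, in vitro droplet and microtubule fields, FRAP time series
and FRET channel triplets.  This module renders statistically comparable
scenes from an explicit continuous model and records every true
parameter in a :class:`SceneTruth`, so each metric can be validated by
parameter recovery rather than against withheld raw data.

The noise model is Poisson shot noise on the noiseless expectation
followed by additive Gaussian read noise; averaging many noisy
realizations converges to the noiseless scene.  All randomness flows
through an explicit seed; no global random state is touched.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .imgio import Calibration, CalibratedStack

__all__ = [
    "NoiseParams",
    "SceneTruth",
    "make_cell_scene",
    "make_peripheral_scene",
    "make_droplet_field",
    "make_filament_field",
    "make_tomogram_fixture",
    "make_frap_series",
    "make_fret_pair",
    "make_boundary_profiles",
    "make_ratio_scene",
    "make_foci_scene",
    "make_cell_table",
]


@dataclass(frozen=True)
class NoiseParams:
    """Poisson shot noise plus Gaussian read noise (σ in intensity units)."""

    poisson: bool = True
    read_sigma: float = 20.0

    @classmethod
    def off(cls) -> "NoiseParams":
        return cls(poisson=False, read_sigma=0.0)


@dataclass
class SceneTruth:
    """Generator-side record of every true parameter of a scene."""

    scene_id: str
    geometry: str
    true_params: dict
    seed: int
    noise: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(dataclasses.asdict(self), default=_jsonable, indent=1))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "SceneTruth":
        d = json.loads(Path(path).read_text())
        return cls(**d)


def _jsonable(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.integer, np.floating)):
        return o.item()
    raise TypeError(f"not serializable: {o!r}")


def _apply_noise(expect: np.ndarray, rng: np.random.Generator, noise: NoiseParams) -> np.ndarray:
    out = rng.poisson(np.clip(expect, 0, None)).astype(float) if noise.poisson else np.array(expect, dtype=float)
    if noise.read_sigma > 0:
        out = out + rng.normal(0.0, noise.read_sigma, size=out.shape)
    return np.clip(out, 0.0, None)


def _grid(shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    return np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)


def _gaussian_blob(shape, center, sigma_px, amplitude=1.0) -> np.ndarray:
    yy, xx = _grid(shape)
    return amplitude * np.exp(
        -((yy - center[0]) ** 2 + (xx - center[1]) ** 2) / (2.0 * sigma_px**2)
    )


def _disc(shape, center, radius_px) -> np.ndarray:
    yy, xx = _grid(shape)
    return ((yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius_px**2).astype(float)


# ---------------------------------------------------------------------------
# mitotic cell scenes


def make_cell_scene(
    geometry: str = "bipolar",
    *,
    shape: tuple[int, int] = (300, 300),
    pixel_size: float = 0.1,
    central_fraction: float = 0.6,
    inner_fraction: float = 0.3,
    chromatin_layout: str = "plate",
    disc_radius_um: float = 4.0,
    annulus_radius_um: float = 6.0,
    annulus_width_um: float = 1.5,
    pole_distance_um: float = 12.0,
    band_length_um: float = 22.5,
    band_width_um: float = 7.06,
    central_window_um: float = 5.0,
    dna_amplitude: float = 2000.0,
    tubulin_amplitude: float = 4000.0,
    pole_sigma_px: float = 3.0,
    cell_radius_um: float = 12.0,
    n_kt_inside: int = 0,
    n_kt_outside: int = 0,
    kt_outside_distance_um: float = 1.0,
    kt_amplitude: float = 6000.0,
    kt_sigma_px: float = 2.0,
    probe_partition: float | None = None,
    probe_cyto_level: float = 800.0,
    ki67_shell_ratio: float | None = None,
    ki67_interior_level: float = 300.0,
    ki67_shell_sigma_um: float = 0.15,
    psf_sigma_px: float = 1.0,
    background: float = 100.0,
    noise: NoiseParams = NoiseParams(),
    seed: int = 0,
    layout_seed: int | None = None,
    scene_id: str = "cell",
) -> tuple[CalibratedStack, SceneTruth]:
    """Render a mitotic cell with bipolar or monopolar spindle geometry.

    Bipolar scenes place chromatin as Gaussian blob clusters near the
    spindle equator and near the poles; the cluster amplitudes are solved
    so that the noiseless DNA signal integrated over the central
    ``central_window_um`` of the pole-axis band divides the whole-band
    integral exactly at ``central_fraction``.  Monopolar scenes place
    chromatin as an inner blob plus an annulus around the single pole,
    solved analogously for the requested ``inner_fraction``
    (pole-proximal over pole-distal signal).  ``chromatin_layout='disc'``
    instead renders a hard-edged uniform disc — the geometry used for
    kinetochore-classification and partition scenes, where exact
    region membership must be known.

    ``layout_seed`` decouples the random chromatin/spot layout from the
    noise realization: condition pairs (e.g. a density series) share a
    layout while receiving independent noise.
    """
    rng_noise = np.random.default_rng(seed)
    rng = np.random.default_rng(seed if layout_seed is None else layout_seed)
    cal = Calibration(pixel_size_xy=pixel_size)
    cy, cx = (shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0
    center = (cy, cx)
    um = 1.0 / pixel_size  # px per μm
    channels: dict[str, np.ndarray] = {}
    truth: dict = {
        "center": [cy, cx],
        "pixel_size": pixel_size,
        "background": background,
        "cell_radius_um": cell_radius_um,
        "band_length_um": band_length_um,
        "band_width_um": band_width_um,
        "central_window_um": central_window_um,
        "bg_roi": [4, 36, 4, 36],  # y0, y1, x0, x1 — extracellular corner
    }

    if geometry == "bipolar":
        half = pole_distance_um / 2.0 * um
        poles = [(cy, cx - half), (cy, cx + half)]
        truth["pole_positions"] = [list(p) for p in poles]
        tub = sum(_gaussian_blob(shape, p, pole_sigma_px, tubulin_amplitude) for p in poles)
        if chromatin_layout == "plate":
            dna = _plate_dna(
                shape, center, um, rng, central_fraction,
                band_length_um, band_width_um, central_window_um,
            )
            truth["central_fraction"] = central_fraction
        elif chromatin_layout == "disc":
            dna = _disc(shape, center, disc_radius_um * um)
            truth["chromatin_disc"] = {"center": [cy, cx], "radius_um": disc_radius_um}
            truth["central_fraction"] = _band_fraction(
                dna, center, um, band_length_um, band_width_um, central_window_um
            )
        else:
            raise ValueError(f"unknown chromatin_layout {chromatin_layout!r}")
    elif geometry == "monopolar":
        poles = [center]
        truth["pole_positions"] = [list(center)]
        tub = _gaussian_blob(shape, center, pole_sigma_px * 2.5, tubulin_amplitude)
        if chromatin_layout == "disc":
            dna = _disc(shape, center, disc_radius_um * um)
            truth["chromatin_disc"] = {"center": [cy, cx], "radius_um": disc_radius_um}
        elif chromatin_layout == "annulus":
            rr = np.hypot(*(g - c for g, c in zip(_grid(shape), center)))
            r0 = annulus_radius_um * um
            w = annulus_width_um * um
            dna = np.exp(-((rr - r0) ** 2) / (2.0 * (w / 2.355) ** 2))
            truth["annulus"] = {
                "radius_um": annulus_radius_um,
                "width_um": annulus_width_um,
            }
        elif chromatin_layout == "radial":
            dna, achieved = _radial_dna(shape, center, um, rng, inner_fraction)
            truth["inner_fraction"] = achieved
        else:
            raise ValueError(f"unknown chromatin_layout {chromatin_layout!r}")
    else:
        raise ValueError(f"unknown geometry {geometry!r}")

    dna = dna / dna.max() * dna_amplitude
    if chromatin_layout == "disc" and psf_sigma_px > 0:
        dna_render = ndimage.gaussian_filter(dna, psf_sigma_px)
    else:
        dna_render = dna
    channels["dna"] = dna_render
    channels["tubulin"] = tub

    chrom_region = dna > 0.5 * dna_amplitude  # geometric region (pre-PSF)

    if n_kt_inside or n_kt_outside:
        if "chromatin_disc" not in truth:
            raise ValueError("kinetochore spots require the disc chromatin layout")
        R = disc_radius_um * um
        min_sep = 6.0 * kt_sigma_px  # keep spots resolvable as separate maxima
        spots, labels = [], []

        def place(r_fn, label, n):
            placed = 0
            for _ in range(1000):
                if placed == n:
                    return
                a = rng.uniform(0, 2 * np.pi)
                r = r_fn()
                pos = (cy + r * np.sin(a), cx + r * np.cos(a))
                if np.hypot(pos[0] - cy, pos[1] - cx) > cell_radius_um * um:
                    raise ValueError("kinetochore spot outside the cell")
                if all(np.hypot(pos[0] - s[0], pos[1] - s[1]) >= min_sep for s in spots):
                    spots.append(pos)
                    labels.append(label)
                    placed += 1
            raise ValueError("could not place separated kinetochore spots")

        place(
            lambda: np.sqrt(rng.uniform(0, (max(R - 0.8 * um, 1.0) / R) ** 2)) * R,
            "inside", n_kt_inside,
        )
        place(lambda: R + kt_outside_distance_um * um, "outside", n_kt_outside)
        cenpa = np.zeros(shape)
        for p in spots:
            cenpa += _gaussian_blob(shape, p, kt_sigma_px, kt_amplitude)
        channels["cenpa"] = cenpa
        truth["spots"] = [
            {"y": s[0], "x": s[1], "label": l} for s, l in zip(spots, labels)
        ]
        truth["kt_outside_distance_um"] = kt_outside_distance_um

    cell = _disc(shape, center, cell_radius_um * um)
    truth["cell_disc"] = {"center": [cy, cx], "radius_um": cell_radius_um}

    if probe_partition is not None:
        probe = probe_cyto_level * cell + (probe_partition - 1.0) * probe_cyto_level * chrom_region.astype(float)
        if psf_sigma_px > 0:
            probe = ndimage.gaussian_filter(probe, psf_sigma_px)
        channels["probe"] = probe
        truth["partition_ratio"] = probe_partition
        truth["probe_cyto_level"] = probe_cyto_level

    if ki67_shell_ratio is not None:
        d_out = ndimage.distance_transform_edt(~chrom_region)
        d_in = ndimage.distance_transform_edt(chrom_region)
        d_signed = np.where(chrom_region, -d_in, d_out) * pixel_size
        shell = ki67_interior_level * ki67_shell_ratio * np.exp(
            -(d_signed**2) / (2.0 * ki67_shell_sigma_um**2)
        )
        channels["ki67"] = shell + ki67_interior_level * chrom_region
        truth["ki67_shell_ratio"] = ki67_shell_ratio
        truth["ki67_shell_sigma_um"] = ki67_shell_sigma_um

    names = tuple(channels)
    noiseless = np.stack([channels[c] + background for c in names])
    data = np.stack([_apply_noise(plane, rng_noise, noise) for plane in noiseless])
    stack = CalibratedStack(data, "CYX", names, cal)
    return stack, SceneTruth(scene_id, geometry, truth, seed, dataclasses.asdict(noise))


def _band_fraction(dna, center, um, length_um, width_um, window_um) -> float:
    """Fraction of band-integrated signal inside the central window (x-axis band)."""
    yy, xx = _grid(dna.shape)
    band = (np.abs(xx - center[1]) <= length_um / 2 * um) & (
        np.abs(yy - center[0]) <= width_um / 2 * um
    )
    central = band & (np.abs(xx - center[1]) <= window_um / 2 * um)
    total = dna[band].sum()
    if total <= 0:
        raise ValueError("no DNA signal in band")
    return float(dna[central].sum() / total)


def _plate_dna(shape, center, um, rng, f, length_um, width_um, window_um) -> np.ndarray:
    """Central metaphase-plate blobs + pole-proximal blobs, mixed to hit f exactly."""
    cy, cx = center
    sigma = 0.35 * um
    central = np.zeros(shape)
    for dy in np.linspace(-2.0, 2.0, 5):
        for dx in np.linspace(-0.8, 0.8, 3):
            jy, jx = rng.normal(0, 0.15, 2)
            central += _gaussian_blob(
                shape, (cy + (dy + jy) * um, cx + (dx + jx) * um), sigma
            )
    peripheral = np.zeros(shape)
    for side in (-1, 1):
        for dy in np.linspace(-1.8, 1.8, 3):
            for dx in (5.0, 6.5, 8.0):
                jy, jx = rng.normal(0, 0.2, 2)
                peripheral += _gaussian_blob(
                    shape, (cy + (dy + jy) * um, cx + side * (dx + jx) * um), sigma
                )
    yy, xx = _grid(shape)
    band = (np.abs(xx - cx) <= length_um / 2 * um) & (np.abs(yy - cy) <= width_um / 2 * um)
    win = band & (np.abs(xx - cx) <= window_um / 2 * um)
    cC, tC = central[win].sum(), central[band].sum()
    cP, tP = peripheral[win].sum(), peripheral[band].sum()
    if f >= 1.0:
        return central
    if f <= cP / tP:
        raise ValueError(f"central fraction {f} not achievable with this layout")
    a = (f * tP - cP) / (cC - f * tC)
    if a < 0:
        raise ValueError(f"central fraction {f} not achievable with this layout")
    return a * central + peripheral


def _radial_dna(shape, center, um, rng, f, q=0.99):
    """Inner blob + annulus around a monopole, mixed so that the inner-30%%/outer
    signal ratio of the noiseless scene equals ``f``; returns the achieved value."""
    yy, xx = _grid(shape)
    rr = np.hypot(yy - center[0], xx - center[1])
    inner = np.exp(-(rr**2) / (2.0 * (1.0 * um) ** 2))
    r0, w = 6.0 * um, 1.2 * um
    annulus = np.exp(-((rr - r0) ** 2) / (2.0 * w**2))

    def ratio(a):
        img = a * inner + annulus
        order = np.argsort(rr.ravel())
        cum = np.cumsum(img.ravel()[order])
        R = rr.ravel()[order][np.searchsorted(cum, q * cum[-1])]
        s_in = img[rr <= 0.3 * R].sum()
        s_out = img[(rr > 0.3 * R) & (rr <= R)].sum()
        return s_in / s_out

    lo, hi = 0.0, 1.0
    while ratio(hi) < f:
        hi *= 2
        if hi > 1e6:
            raise ValueError(f"inner fraction {f} not achievable")
    for _ in range(60):
        mid = (lo + hi) / 2
        if ratio(mid) < f:
            lo = mid
        else:
            hi = mid
    a = (lo + hi) / 2
    return a * inner + annulus, float(ratio(a))


def make_peripheral_scene(
    peripheral_fraction: float = 0.8,
    *,
    shape: tuple[int, int] = (300, 300),
    pixel_size: float = 0.1,
    pole_radius_um: float = 5.0,
    cell_radius_um: float = 13.0,
    h2b_amplitude: float = 1500.0,
    tubulin_amplitude: float = 4000.0,
    background: float = 100.0,
    noise: NoiseParams = NoiseParams(),
    seed: int = 0,
    scene_id: str = "peripheral",
) -> tuple[CalibratedStack, SceneTruth]:
    """Monopolar scene with a known fraction of H2B signal outside the
    ``pole_radius_um`` disc around the spindle pole (droplet dispersal readout)."""
    rng = np.random.default_rng(seed)
    cal = Calibration(pixel_size_xy=pixel_size)
    um = 1.0 / pixel_size
    cy, cx = (shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0
    tub = _gaussian_blob(shape, (cy, cx), 4.0, tubulin_amplitude)
    polar = np.zeros(shape)
    for _ in range(8):
        a, r = rng.uniform(0, 2 * np.pi), rng.uniform(0, 0.6) * pole_radius_um * um
        polar += _gaussian_blob(shape, (cy + r * np.sin(a), cx + r * np.cos(a)), 0.35 * um)
    periph = np.zeros(shape)
    for _ in range(12):
        a = rng.uniform(0, 2 * np.pi)
        r = rng.uniform(pole_radius_um + 1.5, cell_radius_um - 1.5) * um
        periph += _gaussian_blob(shape, (cy + r * np.sin(a), cx + r * np.cos(a)), 0.35 * um)
    pole_disc = _disc(shape, (cy, cx), pole_radius_um * um).astype(bool)
    f = peripheral_fraction
    pin_p, pout_p = periph[pole_disc].sum(), periph[~pole_disc].sum()
    pin_c, pout_c = polar[pole_disc].sum(), polar[~pole_disc].sum()
    # solve a·polar + periph with out/(in+out) = f
    a = (pout_p - f * (pin_p + pout_p)) / (f * (pin_c + pout_c) - pout_c)
    if a < 0:
        raise ValueError(f"peripheral fraction {f} not achievable")
    h2b = a * polar + periph
    h2b = h2b / h2b.max() * h2b_amplitude
    names = ("h2b", "tubulin")
    noiseless = np.stack([h2b + background, tub + background])
    data = np.stack([_apply_noise(p, rng, noise) for p in noiseless])
    truth = {
        "peripheral_fraction": f,
        "pole_center": [cy, cx],
        "pole_radius_um": pole_radius_um,
        "cell_disc": {"center": [cy, cx], "radius_um": cell_radius_um},
        "background": background,
        "bg_roi": [4, 36, 4, 36],
    }
    stack = CalibratedStack(data, "CYX", names, cal)
    return stack, SceneTruth(scene_id, "monopolar", truth, seed, dataclasses.asdict(noise))


# ---------------------------------------------------------------------------
# in vitro fields


def make_droplet_field(
    *,
    shape: tuple[int, int] = (256, 256),
    pixel_size: float = 0.1,
    n_droplets: int = 20,
    radius_range_um: tuple[float, float] = (0.8, 1.5),
    dna_amplitude: float = 3000.0,
    partition_ratio: float = 5.0,
    buffer_level: float = 600.0,
    background: float = 80.0,
    psf_sigma_px: float = 1.0,
    dispersed: bool = False,
    noise: NoiseParams = NoiseParams(),
    seed: int = 0,
    scene_id: str = "droplets",
) -> tuple[CalibratedStack, SceneTruth]:
    """Field of chromatin droplets with a probe at a prescribed partition ratio.

    The probe expectation is ``background + buffer_level`` outside droplets
    and ``background + partition_ratio × buffer_level`` inside.  Droplets
    are non-overlapping and kept out of a buffer strip recorded in the
    truth as a droplet-free rectangular ROI.  ``dispersed=True`` spreads
    the same DNA mass uniformly instead (no droplets), for the
    condensation coefficient-of-variation readout.
    """
    rng = np.random.default_rng(seed)
    cal = Calibration(pixel_size_xy=pixel_size)
    um = 1.0 / pixel_size
    strip = int(60)  # rows [0, strip) stay droplet-free
    centers, radii = [], []
    if not dispersed:
        # jittered-grid placement: non-overlapping by construction, with
        # enough clearance that neighbouring droplets stay separable
        rmax = radius_range_um[1] * um
        cell = 2 * rmax + 10
        ny = int((shape[0] - strip - 4) // cell)
        nx = int((shape[1] - 4) // cell)
        if n_droplets > ny * nx:
            raise ValueError(
                f"cannot place {n_droplets} non-overlapping droplets in this field"
            )
        cells = [(i, j) for i in range(ny) for j in range(nx)]
        chosen = rng.choice(len(cells), size=n_droplets, replace=False)
        for ci in chosen:
            i, j = cells[ci]
            r = rng.uniform(*radius_range_um) * um
            slack = cell / 2 - r - 1
            y = strip + 2 + (i + 0.5) * cell + rng.uniform(-slack, slack)
            x = 2 + (j + 0.5) * cell + rng.uniform(-slack, slack)
            centers.append((y, x))
            radii.append(r)
    inside = np.zeros(shape, dtype=bool)
    for c, r in zip(centers, radii):
        inside |= _disc(shape, c, r).astype(bool)
    if dispersed:
        area_frac = 0.25
        dna = np.full(shape, dna_amplitude * area_frac)
    else:
        dna = dna_amplitude * inside.astype(float)
    probe = buffer_level + (partition_ratio - 1.0) * buffer_level * inside.astype(float)
    if psf_sigma_px > 0:
        dna = ndimage.gaussian_filter(dna, psf_sigma_px)
        probe = ndimage.gaussian_filter(probe, psf_sigma_px)
    names = ("dna", "probe")
    noiseless = np.stack([dna + background, probe + background])
    data = np.stack([_apply_noise(p, rng, noise) for p in noiseless])
    truth = {
        "partition_ratio": partition_ratio,
        "buffer_level": buffer_level,
        "background": background,
        "droplets": [
            {"y": c[0], "x": c[1], "radius_um": r / um} for c, r in zip(centers, radii)
        ],
        "buffer_rect": [4, strip - 8, 4, shape[1] - 4],  # y0, y1, x0, x1
        "pixel_size": pixel_size,
        "dispersed": dispersed,
    }
    stack = CalibratedStack(data, "CYX", names, cal)
    return stack, SceneTruth(scene_id, "droplet_field", truth, seed, dataclasses.asdict(noise))


def _segment_disc_intervals(p0, p1, center, radius):
    """Parameter interval [t0, t1] ⊂ [0, 1] of a segment inside a disc/sphere."""
    p0, p1 = np.asarray(p0, float), np.asarray(p1, float)
    d = p1 - p0
    f = p0 - np.asarray(center, float)
    a = d @ d
    if a == 0:
        return None
    b = 2 * f @ d
    c = f @ f - radius**2
    disc = b * b - 4 * a * c
    if disc <= 0:
        return None
    sq = np.sqrt(disc)
    t0, t1 = (-b - sq) / (2 * a), (-b + sq) / (2 * a)
    t0, t1 = max(t0, 0.0), min(t1, 1.0)
    return (t0, t1) if t1 > t0 else None


def make_filament_field(
    *,
    shape: tuple[int, int] = (256, 256),
    pixel_size: float = 0.1,
    n_segments: int = 120,
    length_um_range: tuple[float, float] = (1.5, 4.0),
    exclusion: bool = False,
    chromatin_centers_um: tuple[tuple[float, float], ...] = ((8.0, 8.0), (17.0, 17.0)),
    chromatin_radius_um: float = 4.0,
    tubulin_amplitude: float = 1500.0,
    dna_amplitude: float = 2000.0,
    psf_sigma_px: float = 1.0,
    background: float = 60.0,
    noise: NoiseParams = NoiseParams(),
    seed: int = 0,
    scene_id: str = "filaments",
) -> tuple[CalibratedStack, SceneTruth]:
    """Random filament segments over circular chromatin regions.

    ``exclusion=True`` removes the sub-segments falling inside chromatin
    (steric exclusion); otherwise filaments are laid down uniformly.  The
    truth records the exact total filament length inside and outside the
    chromatin discs from analytic segment–disc clipping.
    """
    rng = np.random.default_rng(seed)
    cal = Calibration(pixel_size_xy=pixel_size)
    um = 1.0 / pixel_size
    centers_px = [(c[0] * um, c[1] * um) for c in chromatin_centers_um]
    r_px = chromatin_radius_um * um
    if r_px <= 0:
        raise ValueError("zero-area chromatin region")

    # sample segment centres on an extended domain so the in-frame line
    # density is uniform (no depletion near the borders); truth lengths are
    # computed analytically within the image rectangle
    margin = length_um_range[1] / 2 * um
    segments = []
    for _ in range(n_segments):
        L = rng.uniform(*length_um_range) * um
        y = rng.uniform(-margin, shape[0] + margin)
        x = rng.uniform(-margin, shape[1] + margin)
        a = rng.uniform(0, np.pi)
        dy, dx = L / 2 * np.sin(a), L / 2 * np.cos(a)
        segments.append(((y - dy, x - dx), (y + dy, x + dx)))

    def rect_interval(p0, p1):
        """Parameter interval of the segment inside the image rectangle."""
        t0, t1 = 0.0, 1.0
        for axis, hi in ((0, shape[0] - 1.0), (1, shape[1] - 1.0)):
            d = p1[axis] - p0[axis]
            if d == 0:
                if not (0.0 <= p0[axis] <= hi):
                    return None
                continue
            ta, tb = (0.0 - p0[axis]) / d, (hi - p0[axis]) / d
            t0, t1 = max(t0, min(ta, tb)), min(t1, max(ta, tb))
        return (t0, t1) if t1 > t0 else None

    def inside_intervals(p0, p1):
        ivs = []
        for c in centers_px:
            iv = _segment_disc_intervals(p0, p1, c, r_px)
            if iv:
                ivs.append(iv)
        ivs.sort()
        merged = []
        for iv in ivs:
            if merged and iv[0] <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], iv[1]))
            else:
                merged.append(iv)
        return merged

    def overlap(iv, ivs):
        return sum(max(0.0, min(iv[1], j1) - max(iv[0], j0)) for j0, j1 in ivs)

    kept_pieces = []  # rendered (p0, p1) pieces
    len_in = len_out = 0.0
    for p0, p1 in segments:
        L = float(np.hypot(p1[0] - p0[0], p1[1] - p0[1]))
        rect = rect_interval(p0, p1)
        merged = inside_intervals(p0, p1)
        lin_rect = overlap(rect, merged) * L if rect else 0.0
        lrect = (rect[1] - rect[0]) * L if rect else 0.0
        if exclusion:
            ts = [0.0]
            for t0, t1 in merged:
                ts += [t0, t1]
            ts.append(1.0)
            for k in range(0, len(ts), 2):
                t0, t1 = ts[k], ts[k + 1]
                if t1 - t0 > 1e-9:
                    q0 = (p0[0] + t0 * (p1[0] - p0[0]), p0[1] + t0 * (p1[1] - p0[1]))
                    q1 = (p0[0] + t1 * (p1[0] - p0[0]), p0[1] + t1 * (p1[1] - p0[1]))
                    kept_pieces.append((q0, q1))
            len_out += lrect - lin_rect
        else:
            kept_pieces.append((p0, p1))
            len_in += lin_rect
            len_out += lrect - lin_rect

    tub = np.zeros(shape)
    for q0, q1 in kept_pieces:
        L = float(np.hypot(q1[0] - q0[0], q1[1] - q0[1]))
        n = max(int(L * 4), 2)
        ts = np.linspace(0, 1, n)
        ys = np.round(q0[0] + ts * (q1[0] - q0[0])).astype(int)
        xs = np.round(q0[1] + ts * (q1[1] - q0[1])).astype(int)
        ok = (ys >= 0) & (ys < shape[0]) & (xs >= 0) & (xs < shape[1])
        tub[ys[ok], xs[ok]] = 1.0
    tub = tub * tubulin_amplitude
    dna = np.zeros(shape)
    for c in centers_px:
        dna += _disc(shape, c, r_px)
    dna = np.clip(dna, 0, 1) * dna_amplitude
    if psf_sigma_px > 0:
        tub = ndimage.gaussian_filter(tub, psf_sigma_px)
        dna = ndimage.gaussian_filter(dna, psf_sigma_px)
    names = ("tubulin", "dna")
    noiseless = np.stack([tub + background, dna + background])
    data = np.stack([_apply_noise(p, rng, noise) for p in noiseless])
    chrom_area_px = float(np.clip(sum(_disc(shape, c, r_px) for c in centers_px), 0, 1).sum())
    truth = {
        "exclusion": exclusion,
        "length_in_um": len_in * pixel_size,
        "length_out_um": len_out * pixel_size,
        "chromatin_centers_um": [list(c) for c in chromatin_centers_um],
        "chromatin_radius_um": chromatin_radius_um,
        "chromatin_area_fraction": chrom_area_px / (shape[0] * shape[1]),
        "segments": [[list(map(float, p0)), list(map(float, p1))] for p0, p1 in segments],
        "pixel_size": pixel_size,
    }
    stack = CalibratedStack(data, "CYX", names, cal)
    return stack, SceneTruth(scene_id, "filament_field", truth, seed, dataclasses.asdict(noise))


def make_tomogram_fixture(
    *,
    shape_zyx: tuple[int, int, int] = (60, 96, 96),
    voxel_um: float = 0.01,
    n_polylines: int = 40,
    points_per_line: int = 4,
    segment_um: float = 0.15,
    sphere_center_um: tuple[float, float, float] | None = None,
    sphere_radius_um: float = 0.35,
    z_exclude: int = 10,
    seed: int = 0,
    scene_id: str = "tomogram",
) -> tuple[list[np.ndarray], np.ndarray, Calibration, SceneTruth]:
    """Electron-tomogram style fixture: 3D polylines plus a voxelized
    chromatin domain (a sphere), with analytic per-domain length truth.

    Returns ``(polylines, mask, calibration, truth)`` where polylines are
    (n, 3) arrays of (z, y, x) coordinates in μm and the mask is a boolean
    (z, y, x) volume.  Truth lengths are computed analytically inside the
    analysed z-window (excluding ``z_exclude`` slices top and bottom),
    clipping each straight segment against the slab and the sphere.
    """
    rng = np.random.default_rng(seed)
    nz, ny, nx = shape_zyx
    if sphere_center_um is None:
        sphere_center_um = (nz / 2 * voxel_um, ny / 2 * voxel_um, nx / 2 * voxel_um)
    c = np.asarray(sphere_center_um)
    R = sphere_radius_um
    zlo, zhi = z_exclude * voxel_um, (nz - z_exclude) * voxel_um

    polylines = []
    for _ in range(n_polylines):
        p = np.array([
            rng.uniform(2 * voxel_um, (nz - 2) * voxel_um),
            rng.uniform(2 * voxel_um, (ny - 2) * voxel_um),
            rng.uniform(2 * voxel_um, (nx - 2) * voxel_um),
        ])
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
        pts = [p]
        for _ in range(points_per_line - 1):
            d = d + rng.normal(scale=0.2, size=3)
            d /= np.linalg.norm(d)
            q = pts[-1] + d * segment_um
            q = np.clip(q, voxel_um, [(nz - 1) * voxel_um, (ny - 1) * voxel_um, (nx - 1) * voxel_um])
            pts.append(q)
        polylines.append(np.array(pts))

    len_in = len_out = 0.0
    for line in polylines:
        for p0, p1 in zip(line[:-1], line[1:]):
            d = p1 - p0
            L = float(np.linalg.norm(d))
            if L == 0:
                continue
            # slab clip on z
            if d[0] != 0:
                ta, tb = (zlo - p0[0]) / d[0], (zhi - p0[0]) / d[0]
                t0s, t1s = max(min(ta, tb), 0.0), min(max(ta, tb), 1.0)
            else:
                t0s, t1s = (0.0, 1.0) if zlo <= p0[0] <= zhi else (0.0, 0.0)
            if t1s <= t0s:
                continue
            iv = _segment_disc_intervals(p0, p1, c, R)
            if iv:
                ti0, ti1 = max(iv[0], t0s), min(iv[1], t1s)
                lin = max(ti1 - ti0, 0.0) * L
            else:
                lin = 0.0
            len_in += lin
            len_out += (t1s - t0s) * L - lin

    zz, yy, xx = np.mgrid[0:nz, 0:ny, 0:nx].astype(float) * voxel_um
    mask = (zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2 <= R**2
    window = slice(z_exclude, nz - z_exclude)
    vol_in = float(mask[window].sum()) * voxel_um**3
    vol_total = float(mask[window].size) * voxel_um**3
    cal = Calibration(pixel_size_xy=voxel_um, z_step=voxel_um)
    truth = {
        "length_in_um": len_in,
        "length_out_um": len_out,
        "volume_in_um3": vol_in,
        "volume_out_um3": vol_total - vol_in,
        "z_exclude": z_exclude,
        "voxel_um": voxel_um,
        "sphere_center_um": list(c),
        "sphere_radius_um": R,
    }
    return polylines, mask, cal, SceneTruth(scene_id, "tomogram_fixture", truth, seed, {})


# ---------------------------------------------------------------------------
# time series


def make_frap_series(
    *,
    shape: tuple[int, int] = (64, 64),
    pixel_size: float = 0.1,
    pre_level: float = 2000.0,
    bleach_depth: float = 0.8,
    mobile_fraction: float = 0.9,
    half_time_s: float = 2.0,
    acq_bleach_factor: float = 1.0,
    background: float = 100.0,
    n_pre: int = 10,
    n_post: int = 100,
    time_step: float = 0.025,
    region_radius_um: float = 2.4,
    roi_radius_um: float = 0.35,
    noise: NoiseParams = NoiseParams(),
    seed: int = 0,
    scene_id: str = "frap",
) -> tuple[CalibratedStack, SceneTruth]:
    """FRAP time series of a uniform chromatin region with a bleached spot.

    After the bleach the spot signal follows
    ``bg + β^t·pre·[(1−d) + d·m·(1−2^(−t/τ))]`` with bleach depth d,
    mobile fraction m and half-time τ; the surrounding chromatin stays at
    ``bg + β^t·pre`` (recovery drawn from the large unbleached pool), and
    β is a per-frame acquisition-bleaching factor applied to every frame.
    """
    if not 0.0 <= mobile_fraction <= 1.0:
        raise ValueError("mobile fraction must be in [0, 1]")
    if half_time_s <= 0:
        raise ValueError("half-time must be positive")
    rng = np.random.default_rng(seed)
    cal = Calibration(pixel_size_xy=pixel_size, time_step=time_step)
    um = 1.0 / pixel_size
    cy, cx = (shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0
    region = _disc(shape, (cy, cx), region_radius_um * um).astype(bool)
    roi = _disc(shape, (cy, cx), roi_radius_um * um).astype(bool)
    n_frames = n_pre + n_post
    frames = np.zeros((n_frames, 1) + shape)
    d = bleach_depth
    m = mobile_fraction
    for i in range(n_frames):
        beta = acq_bleach_factor**i
        img = np.full(shape, background)
        if i < n_pre:
            img = img + beta * pre_level * region
        else:
            t = (i - n_pre) * time_step
            s_roi = pre_level * ((1 - d) + d * m * (1.0 - 2.0 ** (-t / half_time_s)))
            img = img + beta * (pre_level * (region & ~roi) + s_roi * roi)
        frames[i, 0] = _apply_noise(img, rng, noise)
    stack = CalibratedStack(frames, "TCYX", ("h2b",), cal)
    truth = {
        "mobile_fraction": m,
        "half_time_s": half_time_s,
        "bleach_depth": d,
        "acq_bleach_factor": acq_bleach_factor,
        "pre_level": pre_level,
        "background": background,
        "n_pre": n_pre,
        "time_step": time_step,
        "region": {"center": [cy, cx], "radius_um": region_radius_um},
        "roi": {"center": [cy, cx], "radius_um": roi_radius_um},
        "bg_roi": [2, 12, 2, 12],
    }
    return stack, SceneTruth(scene_id, "frap_series", truth, seed, dataclasses.asdict(noise))


def make_fret_pair(
    *,
    shape: tuple[int, int] = (128, 128),
    pixel_size: float = 0.1,
    nucleus_radius_um: float = 3.5,
    cfp_level: float = 1200.0,
    fret_ratio: float = 0.7,
    yfp_level: float = 2000.0,
    backgrounds: tuple[float, float, float] = (60.0, 80.0, 50.0),  # cfp, fret, yfp
    noise: NoiseParams = NoiseParams(),
    seed: int = 0,
    scene_id: str = "fret",
) -> tuple[CalibratedStack, SceneTruth]:
    """CFP/FRET/YFP triplet of one nucleus with a prescribed FRET/CFP ratio.

    Inside the nucleus the FRET channel equals ``fret_ratio × CFP`` above
    the per-channel extracellular background, so the true in-mask ratio
    map is exactly ``fret_ratio``.
    """
    if fret_ratio < 0:
        raise ValueError("fret ratio must be >= 0")
    rng = np.random.default_rng(seed)
    cal = Calibration(pixel_size_xy=pixel_size)
    um = 1.0 / pixel_size
    cy, cx = (shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0
    nuc = _disc(shape, (cy, cx), nucleus_radius_um * um)
    bg_c, bg_f, bg_y = backgrounds
    cfp = bg_c + cfp_level * nuc
    fret = bg_f + fret_ratio * cfp_level * nuc
    yfp = bg_y + yfp_level * nuc
    names = ("cfp", "fret", "yfp")
    data = np.stack([_apply_noise(p, rng, noise) for p in (cfp, fret, yfp)])
    truth = {
        "fret_ratio": fret_ratio,
        "cfp_level": cfp_level,
        "yfp_level": yfp_level,
        "backgrounds": {"cfp": bg_c, "fret": bg_f, "yfp": bg_y},
        "nucleus": {"center": [cy, cx], "radius_um": nucleus_radius_um},
        "bg_roi": [4, 14, 4, 14],
        "pixel_size": pixel_size,
    }
    stack = CalibratedStack(data, "CYX", names, cal)
    return stack, SceneTruth(scene_id, "fret_pair", truth, seed, dataclasses.asdict(noise))


# ---------------------------------------------------------------------------
# profile bundles and tables


def make_boundary_profiles(
    n_profiles: int = 10,
    *,
    length_um: float = 3.0,
    step_um: float = 0.05,
    boundary_um: float = 1.2,
    jitter_um: float = 0.2,
    shell_ratio: float = 4.0,
    interior_level: float = 200.0,
    outside_level: float = 30.0,
    shell_sigma_um: float = 0.15,
    dna_plateau: float = 1000.0,
    dna_edge_sigma_um: float = 0.1,
    noise_sigma: float = 5.0,
    seed: int = 0,
):
    """Paired Ki-67 / DNA line profiles crossing a chromatid surface.

    Profiles run from the cytoplasm (distance 0) into the chromatid; the
    surface sits at ``boundary_um`` plus a per-profile jitter.  The Ki-67
    profile is an interior plateau plus a Gaussian surface shell peaking
    at ``shell_ratio × interior_level``; the DNA profile is a smoothed
    step.  Returns ``(pairs, truth)`` with pairs of
    :class:`~mitoquant.segcore.LineProfile`.
    """
    from .segcore import LineProfile

    rng = np.random.default_rng(seed)
    x = np.arange(0.0, length_um + step_um / 2, step_um)
    pairs = []
    boundaries = []
    for i in range(n_profiles):
        b = boundary_um + rng.normal(0, jitter_um)
        boundaries.append(b)
        from scipy.special import erf

        dna = dna_plateau * 0.5 * (1 + erf((x - b) / (dna_edge_sigma_um * np.sqrt(2))))
        # shell amplitude chosen so the rendered peak (shell + half-risen
        # step at the boundary) equals shell_ratio × interior exactly
        shell_amp = shell_ratio * interior_level - (outside_level + interior_level) / 2.0
        ki = (
            outside_level
            + (interior_level - outside_level)
            * 0.5 * (1 + erf((x - b) / (dna_edge_sigma_um * np.sqrt(2))))
            + shell_amp * np.exp(-((x - b) ** 2) / (2 * shell_sigma_um**2))
        )
        if noise_sigma > 0:
            dna = np.clip(dna + rng.normal(0, noise_sigma, x.shape), 0, None)
            ki = np.clip(ki + rng.normal(0, noise_sigma, x.shape), 0, None)
        mk = lambda v: LineProfile(  # noqa: E731
            start=(0.0, 0.0), end=(0.0, len(x) - 1.0), width_px=1,
            distances_um=x, intensities=v, step_um=step_um,
        )
        pairs.append((mk(ki), mk(dna)))
    truth = SceneTruth(
        "profiles", "boundary_profiles",
        {
            "shell_ratio": shell_ratio,
            "interior_level": interior_level,
            "outside_level": outside_level,
            "shell_sigma_um": shell_sigma_um,
            "boundaries_um": boundaries,
            "jitter_um": jitter_um,
        },
        seed, {"read_sigma": noise_sigma},
    )
    return pairs, truth


def make_ratio_scene(
    mark_ratio: float = 3.0,
    *,
    shape: tuple[int, int] = (128, 128),
    pixel_size: float = 0.1,
    dna_amplitude: float = 1000.0,
    mark_background: float = 120.0,
    dna_background: float = 80.0,
    radius_um: float = 3.0,
    noise: NoiseParams = NoiseParams(),
    seed: int = 0,
    scene_id: str = "ratio",
) -> tuple[CalibratedStack, SceneTruth]:
    """Two-channel scene where the mark channel is a known multiple of DNA
    within the chromatin disc, each on its own additive background."""
    rng = np.random.default_rng(seed)
    cal = Calibration(pixel_size_xy=pixel_size)
    um = 1.0 / pixel_size
    cy, cx = (shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0
    disc = _disc(shape, (cy, cx), radius_um * um)
    dna = dna_background + dna_amplitude * disc
    mark = mark_background + mark_ratio * dna_amplitude * disc
    data = np.stack([_apply_noise(p, rng, noise) for p in (dna, mark)])
    truth = {
        "mark_ratio": mark_ratio,
        "dna_background": dna_background,
        "mark_background": mark_background,
        "disc": {"center": [cy, cx], "radius_um": radius_um},
        "bg_roi": [4, 14, 4, 14],
    }
    stack = CalibratedStack(data, "CYX", ("dna", "mark"), cal)
    return stack, SceneTruth(scene_id, "ratio_scene", truth, seed, dataclasses.asdict(noise))


def make_foci_scene(
    n_inside: int = 7,
    n_outside: int = 3,
    *,
    shape: tuple[int, int] = (256, 256),
    pixel_size: float = 0.1,
    disc_radius_um: float = 5.0,
    dna_amplitude: float = 1500.0,
    focus_amplitude: float = 12000.0,
    focus_sigma_px: float = 2.0,
    background: float = 100.0,
    noise: NoiseParams = NoiseParams(),
    seed: int = 0,
    scene_id: str = "foci",
) -> tuple[CalibratedStack, SceneTruth]:
    """DNA disc with bright puncta inside and outside it (damage-focus scene)."""
    rng = np.random.default_rng(seed)
    cal = Calibration(pixel_size_xy=pixel_size)
    um = 1.0 / pixel_size
    cy, cx = (shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0
    R = disc_radius_um * um
    dna = dna_amplitude * ndimage.gaussian_filter(_disc(shape, (cy, cx), R), 1.0)
    foci = np.zeros(shape)
    spots = []
    min_sep = 8.0 * focus_sigma_px  # keep puncta resolvable

    def place(r_fn, inside, n):
        placed = 0
        for _ in range(2000):
            if placed == n:
                return
            a = rng.uniform(0, 2 * np.pi)
            r = r_fn()
            p = (cy + r * np.sin(a), cx + r * np.cos(a))
            if all(np.hypot(p[0] - s["y"], p[1] - s["x"]) >= min_sep for s in spots):
                spots.append({"y": p[0], "x": p[1], "inside": inside})
                placed += 1
        raise ValueError("could not place separated foci")

    place(lambda: np.sqrt(rng.uniform(0, ((R - 10) / R) ** 2)) * R, True, n_inside)
    place(lambda: R + rng.uniform(15, 35), False, n_outside)
    for s in spots:
        foci += _gaussian_blob(shape, (s["y"], s["x"]), focus_sigma_px, focus_amplitude)
    data = np.stack(
        [_apply_noise(p + background, rng, noise) for p in (foci, dna)]
    )
    truth = {
        "n_inside": n_inside,
        "n_outside": n_outside,
        "spots": spots,
        "disc": {"center": [cy, cx], "radius_um": disc_radius_um},
        "background": background,
    }
    stack = CalibratedStack(data, "CYX", ("foci", "dna"), cal)
    return stack, SceneTruth(scene_id, "foci_scene", truth, seed, dataclasses.asdict(noise))


def make_cell_table(
    n_control: int = 50,
    n_treated: int = 100,
    fraction_positive: float = 0.12,
    *,
    base_level: float = 100.0,
    positive_factor: float = 2.0,
    cv: float = 0.05,
    seed: int = 0,
):
    """Per-cell pSIVA / PI mean-intensity table for the apoptotic index.

    The positive treated cells carry both markers at ``positive_factor``
    times the control median.  Returns ``(control_df, treated_df, truth)``
    as pandas DataFrames with columns cell_id, mean_psiva, mean_pi.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    n_pos = int(round(fraction_positive * n_treated))

    def draw(n, factor):
        return base_level * factor * (1 + rng.normal(0, cv, n))

    control = pd.DataFrame(
        {
            "cell_id": [f"c{i}" for i in range(n_control)],
            "mean_psiva": draw(n_control, 1.0),
            "mean_pi": draw(n_control, 1.0),
        }
    )
    flags = np.zeros(n_treated, dtype=bool)
    flags[rng.choice(n_treated, size=n_pos, replace=False)] = True
    treated = pd.DataFrame(
        {
            "cell_id": [f"t{i}" for i in range(n_treated)],
            "mean_psiva": np.where(flags, draw(n_treated, positive_factor), draw(n_treated, 1.0)),
            "mean_pi": np.where(flags, draw(n_treated, positive_factor), draw(n_treated, 1.0)),
        }
    )
    truth = SceneTruth(
        "cells", "cell_table",
        {"fraction_positive": n_pos / n_treated, "n_positive": n_pos},
        seed, {"cv": cv},
    )
    return control, treated, truth
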