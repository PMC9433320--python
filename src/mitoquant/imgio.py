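"""Calibrated image stacks, masks, regions and metric records.

Every quantification in this package runs on a :class:`CalibratedStack`:
a non-negative intensity array with named channels and a physical
calibration (micrometres per pixel, micrometres per z-step, seconds per
frame).  Axes follow the canonical microscopy order ``TCZYX``; optional
axes (time, z) are simply absent.  All physical distances are computed as
index differences times the calibration, with pixel centres at integer
coordinates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

_AXIS_ORDER = "TCZYX"

__all__ = [
    "Calibration",
    "CalibratedStack",
    "BinaryMask",
    "RegionSet",
    "MetricsRecord",
    "read_stack",
    "write_stack",
    "write_metrics",
    "read_metrics",
]


@dataclass(frozen=True)
class Calibration:
    """Physical pixel calibration.

    Parameters
    ----------
    pixel_size_xy:
        Micrometres per pixel in y and x (isotropic in-plane sampling).
    z_step:
        Micrometres per z-slice; ``None`` for 2D data.
    time_step:
        Seconds per frame; ``None`` for static data.
    """

    pixel_size_xy: float
    z_step: float | None = None
    time_step: float | None = None

    def __post_init__(self) -> None:
        for name in ("pixel_size_xy", "z_step", "time_step"):
            v = getattr(self, name)
            if v is not None and not (np.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be strictly positive, got {v!r}")

    @property
    def z_aspect(self) -> float:
        """z-step expressed in units of the in-plane pixel size."""
        if self.z_step is None:
            raise ValueError("no z calibration present")
        return self.z_step / self.pixel_size_xy


@dataclass
class CalibratedStack:
    """Multi-channel intensity stack with physical calibration.

    ``data`` is indexed by ``axes``, an ordered subset of ``TCZYX`` that
    always contains ``C``, ``Y`` and ``X``.
    """

    data: np.ndarray
    axes: str
    channel_names: tuple[str, ...]
    calibration: Calibration

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.channel_names = tuple(self.channel_names)
        if sorted(self.axes, key=_AXIS_ORDER.index) != list(self.axes):
            raise ValueError(f"axes {self.axes!r} not in canonical TCZYX order")
        if not {"C", "Y", "X"}.issubset(self.axes):
            raise ValueError("axes must contain C, Y and X")
        if self.data.ndim != len(self.axes):
            raise ValueError("data dimensionality does not match axes")
        n_chan = self.data.shape[self.axes.index("C")]
        if n_chan != len(self.channel_names):
            raise ValueError(
                f"{n_chan} channel planes but {len(self.channel_names)} channel names"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")
        if not np.all(np.isfinite(self.data)) or np.any(self.data < 0):
            raise ValueError("intensities must be finite and non-negative")

    @property
    def spatial_shape(self) -> tuple[int, ...]:
        return tuple(
            self.data.shape[self.axes.index(a)] for a in "ZYX" if a in self.axes
        )

    def channel(self, name: str, t: int | None = None) -> np.ndarray:
        """One channel as a (z?, y, x) array; pick frame ``t`` if a time axis exists."""
        if name not in self.channel_names:
            raise KeyError(f"unknown channel {name!r}; have {self.channel_names}")
        arr = np.take(self.data, self.channel_names.index(name), axis=self.axes.index("C"))
        if "T" in self.axes:
            if t is None:
                raise ValueError("stack has a time axis; pass t")
            arr = np.take(arr, t, axis=self.axes.index("T"))
        return arr

    @property
    def n_frames(self) -> int:
        return self.data.shape[self.axes.index("T")] if "T" in self.axes else 1


@dataclass
class BinaryMask:
    """Boolean mask in the geometry of one source channel."""

    values: np.ndarray
    calibration: Calibration
    source_channel: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)

    @property
    def pixel_size(self) -> float:
        return self.calibration.pixel_size_xy

    def area_um2(self) -> float:
        if self.values.ndim != 2:
            raise ValueError("area defined for 2D masks")
        return float(self.values.sum()) * self.pixel_size**2


@dataclass
class RegionSet:
    """Labelled connected regions; label 0 is background, ids contiguous from 1."""

    labels: np.ndarray
    calibration: Calibration

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        ids = np.unique(self.labels)
        ids = ids[ids > 0]
        if len(ids) and not np.array_equal(ids, np.arange(1, len(ids) + 1)):
            raise ValueError("region ids must be contiguous from 1")

    @property
    def n_regions(self) -> int:
        return int(self.labels.max()) if self.labels.size else 0

    def mask(self) -> BinaryMask:
        return BinaryMask(self.labels > 0, self.calibration)

    def region_sizes(self) -> dict[int, float]:
        """Region sizes in physical units (μm² for 2D, μm³ for 3D)."""
        unit = self.calibration.pixel_size_xy ** 2
        if self.labels.ndim == 3:
            unit *= self.calibration.z_step or self.calibration.pixel_size_xy
        counts = np.bincount(self.labels.ravel())
        return {i: float(counts[i]) * unit for i in range(1, len(counts))}


@dataclass
class MetricsRecord:
    """One measured quantity, with enough context to re-trace it."""

    scene_id: str
    metric_name: str
    value: float
    units: str = ""
    parameters: Mapping[str, object] = field(default_factory=dict)
    normalization_reference: str = ""

    def __post_init__(self) -> None:
        if not np.isfinite(self.value):
            raise ValueError("metric value must be finite")
        json.dumps(dict(self.parameters))  # must be serializable


_METRIC_COLUMNS = [
    "scene_id",
    "metric_name",
    "value",
    "units",
    "normalization_reference",
    "parameters",
]


def write_metrics(records: Sequence[MetricsRecord], path: str | Path) -> Path:
    """Write metric records to CSV, one row per record, fixed column order."""
    if not records:
        raise ValueError("no records to write")
    rows = [
        {
            "scene_id": r.scene_id,
            "metric_name": r.metric_name,
            "value": repr(float(r.value)),
            "units": r.units,
            "normalization_reference": r.normalization_reference,
            "parameters": json.dumps(dict(r.parameters), sort_keys=True),
        }
        for r in records
    ]
    path = Path(path)
    pd.DataFrame(rows, columns=_METRIC_COLUMNS).to_csv(path, index=False)
    return path


def read_metrics(path: str | Path) -> list[MetricsRecord]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    return [
        MetricsRecord(
            scene_id=row["scene_id"],
            metric_name=row["metric_name"],
            value=float(row["value"]),
            units=row["units"],
            parameters=json.loads(row["parameters"]) if row["parameters"] else {},
            normalization_reference=row["normalization_reference"],
        )
        for _, row in df.iterrows()
    ]


def write_stack(stack: CalibratedStack, path: str | Path) -> Path:
    """Write a stack as ImageJ-style TIFF with calibration and channel metadata."""
    path = Path(path)
    cal = stack.calibration
    metadata = {
        "axes": stack.axes,
        "channel_names": list(stack.channel_names),
        "pixel_size_xy": cal.pixel_size_xy,
        "z_step": cal.z_step,
        "time_step": cal.time_step,
    }
    tifffile.imwrite(
        path,
        stack.data,
        metadata=metadata,
        photometric="minisblack",
        resolution=(1.0 / cal.pixel_size_xy, 1.0 / cal.pixel_size_xy),
    )
    return path


def read_stack(
    path: str | Path,
    channel_names: Sequence[str] | None = None,
    calibration: Calibration | None = None,
    axes: str | None = None,
) -> CalibratedStack:
    """Read a single- or multi-page TIFF into a :class:`CalibratedStack`.

    Metadata written by :func:`write_stack` is honoured; ``channel_names``,
    ``calibration`` and ``axes`` override or supply what the file lacks.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        meta: dict = {}
        desc = tif.pages[0].tags.get("ImageDescription")
        if desc is not None:
            try:
                meta = json.loads(desc.value)
            except (json.JSONDecodeError, TypeError):
                meta = {}
    if axes is None:
        axes = meta.get("axes")
    if channel_names is None:
        channel_names = meta.get("channel_names")
    if calibration is None:
        if "pixel_size_xy" in meta:
            calibration = Calibration(
                pixel_size_xy=meta["pixel_size_xy"],
                z_step=meta.get("z_step"),
                time_step=meta.get("time_step"),
            )
        else:
            raise ValueError(
                f"{path}: no calibration in file metadata; pass calibration="
            )
    if channel_names is None:
        raise ValueError(f"{path}: no channel names in metadata; pass channel_names=")
    if axes is None:
        # infer a plain layout: leading channel axis when page count matches
        if data.ndim == 2:
            if len(channel_names) != 1:
                raise ValueError(
                    f"{path}: 2D image but {len(channel_names)} channel names"
                )
            data = data[None]
            axes = "CYX"
        elif data.ndim == 3:
            axes = "CYX"
        else:
            raise ValueError(f"{path}: cannot infer axes for ndim={data.ndim}; pass axes=")
    return CalibratedStack(
        data=np.asarray(data),
        axes=axes,
        channel_names=tuple(channel_names),
        calibration=calibration,
    )
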