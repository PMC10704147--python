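"""Event-stream I/O: binning into fixed-width binary rasters and reading or
writing the standard event-dataset containers.

Rasters are binary, not counts: the discrete neuron dynamics consume spikes
S in {0, 1}, so multiple events falling into the same (bin, channel) cell
clip to a single 1.  Bins are half-open, ``[b*dt, (b+1)*dt)``, and events at
or beyond the horizon ``n_steps*dt`` are dropped.

Supported containers:

* HDF5 in the spiking-audio schema (``spikes/times`` in seconds,
  ``spikes/units`` channel ids, ``labels``) — used both for the public
  700-channel spoken-digit release and for synthetic datasets written by
  :func:`write_synthetic`, so one reader path serves both.
* Per-sample AER binary files (5 bytes per event: x, y, polarity bit plus a
  23-bit microsecond timestamp) as used by the saccade-converted MNIST
  event dataset; (x, y, polarity) flattens row-major with polarity fastest
  to ``(y*34 + x)*2 + p``, giving 2312 channels.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .synthetic import EventDataset, EventStream

__all__ = [
    "SpikeRaster",
    "DatasetBundle",
    "bin_events",
    "bundle_dataset",
    "read_shd_h5",
    "read_nmnist_bin",
    "write_synthetic",
    "NMNIST_SIDE",
    "NMNIST_CHANNELS",
]

NMNIST_SIDE = 34
NMNIST_CHANNELS = NMNIST_SIDE * NMNIST_SIDE * 2  # 2312


@dataclass
class SpikeRaster:
    """Binary time x channel grid at fixed dt, with its class label."""

    grid: np.ndarray  # (n_steps, n_channels), {0,1}
    dt_ms: float
    label: int

    def __post_init__(self):
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 2 or self.grid.shape[0] < 1:
            raise ValueError("grid must be (n_steps, n_channels) with n_steps >= 1")


@dataclass
class DatasetBundle:
    """A split of rasters stacked as (n_steps, n_samples, n_channels)."""

    x: np.ndarray
    labels: np.ndarray
    dt_ms: float
    n_classes: int
    split: str = "train"

    @property
    def n_samples(self) -> int:
        return self.x.shape[1]

    @property
    def n_channels(self) -> int:
        return self.x.shape[2]

    @property
    def n_steps(self) -> int:
        return self.x.shape[0]


def bin_events(stream: EventStream, dt_ms: float, n_steps: int, n_channels: int) -> SpikeRaster:
    """Bin one event stream into a binary raster.

    Bin index is ``floor(time / dt)``; an event at exactly ``b*dt`` belongs
    to bin ``b``.  Events at or after ``n_steps*dt`` are dropped (truncated
    horizon); shorter streams leave trailing all-zero rows (zero padding).
    """
    if not dt_ms > 0:
        raise ValueError("dt_ms must be positive")
    times = np.asarray(stream.times_s, dtype=float)
    if np.any(times < 0):
        raise ValueError("negative event times")
    channels = np.asarray(stream.channels, dtype=int)
    if channels.size and (channels.min() < 0 or channels.max() >= n_channels):
        raise ValueError("channel index out of range")
    bins = np.floor(times * 1000.0 / dt_ms).astype(int)
    keep = bins < n_steps
    grid = np.zeros((n_steps, n_channels), dtype=np.int8)
    grid[bins[keep], channels[keep]] = 1
    return SpikeRaster(grid, dt_ms, stream.label)


def bundle_dataset(
    dataset: EventDataset, split: str = "train", n_steps: int | None = None
) -> DatasetBundle:
    """Bin every stream of an event dataset into one stacked bundle."""
    n_steps = n_steps or dataset.n_steps
    rasters = [
        bin_events(s, dataset.dt_ms, n_steps, dataset.n_channels) for s in dataset.streams
    ]
    x = np.stack([r.grid for r in rasters], axis=1).astype(float)
    return DatasetBundle(x, dataset.labels(), dataset.dt_ms, dataset.n_classes, split)


# ---------------------------------------------------------------------------
# HDF5 (spiking-audio schema)


def read_shd_h5(
    path: str | Path, n_channels: int | None = None, n_steps: int = 100, dt_ms: float = 14.0
) -> EventDataset:
    """Read an HDF5 file with groups ``spikes/times``, ``spikes/units`` and
    ``labels`` into an :class:`EventDataset`."""
    import h5py

    with h5py.File(path, "r") as f:
        for key in ("spikes/times", "spikes/units", "labels"):
            if key not in f:
                raise ValueError(f"missing HDF5 group/dataset {key!r} in {path}")
        times = [np.asarray(t, dtype=float) for t in f["spikes/times"]]
        units = [np.asarray(u, dtype=int) for u in f["spikes/units"]]
        labels = np.asarray(f["labels"], dtype=int)
        attrs = dict(f.attrs)
    if n_channels is None:
        n_channels = int(attrs.get("n_channels", 700))
    n_classes = int(attrs.get("n_classes", labels.max() + 1 if labels.size else 1))
    n_steps = int(attrs.get("n_steps", n_steps))
    dt_ms = float(attrs.get("dt_ms", dt_ms))
    streams = []
    for t, u, y in zip(times, units, labels):
        if u.size and (u.min() < 0 or u.max() >= n_channels):
            raise ValueError(f"unit index out of range [0, {n_channels})")
        streams.append(EventStream(t, u, int(y)))
    return EventDataset(streams, n_channels, n_classes, n_steps, dt_ms)


def write_synthetic(dataset: EventDataset, path: str | Path) -> None:
    """Write an event dataset in the HDF5 schema ``read_shd_h5`` expects.

    The round trip is exact: every event time, channel and label is
    preserved bit-for-bit.
    """
    import h5py

    with h5py.File(path, "w") as f:
        spikes = f.create_group("spikes")
        vfloat = h5py.vlen_dtype(np.float64)
        vint = h5py.vlen_dtype(np.int64)
        n = len(dataset.streams)
        dt = spikes.create_dataset("times", (n,), dtype=vfloat)
        du = spikes.create_dataset("units", (n,), dtype=vint)
        for i, s in enumerate(dataset.streams):
            dt[i] = s.times_s
            du[i] = s.channels.astype(np.int64)
        f.create_dataset("labels", data=dataset.labels().astype(np.int64))
        f.attrs["n_channels"] = dataset.n_channels
        f.attrs["n_classes"] = dataset.n_classes
        f.attrs["n_steps"] = dataset.n_steps
        f.attrs["dt_ms"] = dataset.dt_ms


# ---------------------------------------------------------------------------
# AER binary (event-camera samples)


def nmnist_channel(x: int | np.ndarray, y: int | np.ndarray, polarity: int | np.ndarray):
    """Flatten (x, y, polarity) to a channel id, row-major, polarity fastest."""
    return (np.asarray(y) * NMNIST_SIDE + np.asarray(x)) * 2 + np.asarray(polarity)


def read_nmnist_bin(path: str | Path, label: int = -1) -> EventStream:
    """Decode one 5-byte-per-event AER sample file.

    Layout per event: byte 0 = x, byte 1 = y, byte 2 bit 7 = polarity and
    bits 6..0 = timestamp bits 22..16, bytes 3-4 = timestamp bits 15..0
    (microseconds).  Times are returned in seconds.
    """
    raw = np.fromfile(str(path), dtype=np.uint8)
    if raw.size % 5 != 0:
        raise ValueError(f"truncated AER record in {path}: {raw.size} bytes")
    raw = raw.reshape(-1, 5).astype(np.uint32)
    x, y = raw[:, 0], raw[:, 1]
    if x.size and (x.max() >= NMNIST_SIDE or y.max() >= NMNIST_SIDE):
        raise ValueError(f"coordinates outside {NMNIST_SIDE}x{NMNIST_SIDE} grid")
    polarity = raw[:, 2] >> 7
    t_us = ((raw[:, 2] & 0x7F) << 16) | (raw[:, 3] << 8) | raw[:, 4]
    channels = nmnist_channel(x, y, polarity)
    return EventStream(t_us.astype(float) / 1e6, channels.astype(int), label)
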