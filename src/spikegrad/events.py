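"""Event-stream containers and I/O.

An address-event stream is the native signal format of event-based vision
sensors and of the simulator in this package: a time-sorted sequence of
(time, source) pairs, where ``source`` indexes a flat presynaptic address
space.  This module provides

* :class:`EventStream`, the in-memory container used everywhere,
* a reader/writer pair for the 5-byte AER binary layout used by the
  N-MNIST dataset (34x34 DVS recordings with on/off polarity),
* Poisson rate-coding of intensity images, and
* a portable HDF5 stream format for fixtures and datasets.

Flattening convention: pixel (x, y) with polarity p on a WxH sensor maps to
``source = y*W + x + p*W*H`` -- row-major with polarity as the slowest axis,
so off-events occupy sources [0, W*H) and on-events [W*H, 2*W*H).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, NamedTuple

import numpy as np

__all__ = [
    "Event",
    "EventStream",
    "RawDVSEvent",
    "StreamFormatError",
    "StreamValidationError",
    "read_nmnist",
    "write_nmnist",
    "poisson_rates",
    "poisson_encode",
    "poisson_stream",
    "save_stream",
    "load_stream",
    "load_image",
]

_HDF5_MAGIC = "spikegrad-stream-v1"

# N-MNIST AER record: byte0=x, byte1=y, byte2 bit7=polarity,
# byte2 bits6-0 = timestamp bits 22-16, bytes3-4 = timestamp bits 15-0 (us).
_RECORD_SIZE = 5
_T_US_MAX = 1 << 23


class StreamFormatError(ValueError):
    """Malformed on-disk event data (truncated record, bad magic, ...)."""


class StreamValidationError(ValueError):
    """Event data violating a stream invariant (ordering, address range)."""


class Event(NamedTuple):
    t: float
    source: int


class RawDVSEvent(NamedTuple):
    """One undecoded DVS event as stored in an N-MNIST file."""

    x: int
    y: int
    polarity: int
    t_us: int


@dataclass
class EventStream:
    """Time-sorted address-event sequence over a flat source space.

    Parameters
    ----------
    times : array of event times in seconds, non-decreasing, >= 0.
    sources : int array of source indices in ``[0, n_sources)``.
    n_sources : size of the presynaptic address space.
    duration : presentation length in seconds; all times are <= duration.
    """

    times: np.ndarray
    sources: np.ndarray
    n_sources: int
    duration: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.float64)
        self.sources = np.asarray(self.sources, dtype=np.int64)
        self.validate()

    def validate(self) -> None:
        t, s = self.times, self.sources
        if t.shape != s.shape or t.ndim != 1:
            raise StreamValidationError("times and sources must be matching 1-D arrays")
        if t.size:
            if t[0] < 0:
                raise StreamValidationError("negative event time")
            if np.any(np.diff(t) < 0):
                raise StreamValidationError("event times are not non-decreasing")
            if t[-1] > self.duration + 1e-12:
                raise StreamValidationError(
                    f"event at t={t[-1]:g}s exceeds duration {self.duration:g}s"
                )
            if s.min() < 0 or s.max() >= self.n_sources:
                raise StreamValidationError("source index outside address space")
        if self.n_sources <= 0:
            raise StreamValidationError("n_sources must be positive")
        if self.duration < 0:
            raise StreamValidationError("duration must be non-negative")

    def __len__(self) -> int:
        return int(self.times.size)

    def __iter__(self) -> Iterator[Event]:
        for t, s in zip(self.times, self.sources):
            yield Event(float(t), int(s))

    def shifted(self, t0: float, duration: float | None = None) -> "EventStream":
        """Return a copy with all times shifted by ``-t0``."""
        t = self.times - t0
        dur = duration if duration is not None else max(self.duration - t0, 0.0)
        return EventStream(t, self.sources.copy(), self.n_sources, dur, dict(self.meta))


def _canonical_order(times: np.ndarray, sources: np.ndarray):
    """Sort by time, breaking ties by source index (the engine's canonical order)."""
    order = np.lexsort((sources, times))
    return times[order], sources[order]


# ---------------------------------------------------------------------------
# N-MNIST AER binary layout
# ---------------------------------------------------------------------------

def read_nmnist(path, width: int = 34, height: int = 34) -> EventStream:
    """Read a binary AER file in the N-MNIST 5-byte record layout.

    Polarity splits the address space into two channels: off-events map to
    sources ``[0, W*H)`` and on-events to ``[W*H, 2*W*H)``.  Timestamps are
    converted from microseconds to seconds; ``duration`` is the last
    timestamp (0 for an empty file).

    Raises
    ------
    StreamFormatError
        if the file does not contain whole 5-byte records.
    StreamValidationError
        for out-of-range coordinates or non-monotonic timestamps.
    """
    with open(path, "rb") as fh:
        raw = fh.read()
    if len(raw) % _RECORD_SIZE:
        raise StreamFormatError(
            f"truncated AER record at byte offset {len(raw) - len(raw) % _RECORD_SIZE} "
            f"({len(raw)} bytes is not a multiple of {_RECORD_SIZE})"
        )
    data = np.frombuffer(raw, dtype=np.uint8).reshape(-1, _RECORD_SIZE)
    if data.shape[0] == 0:
        return EventStream(np.empty(0), np.empty(0, dtype=np.int64),
                           2 * width * height, 0.0)
    x = data[:, 0].astype(np.int64)
    y = data[:, 1].astype(np.int64)
    pol = (data[:, 2] >> 7).astype(np.int64)
    t_us = (
        (data[:, 2].astype(np.int64) & 0x7F) << 16
        | data[:, 3].astype(np.int64) << 8
        | data[:, 4].astype(np.int64)
    )
    if np.any(x >= width) or np.any(y >= height):
        bad = int(np.flatnonzero((x >= width) | (y >= height))[0])
        raise StreamValidationError(
            f"event {bad}: coordinate ({x[bad]}, {y[bad]}) outside {width}x{height}"
        )
    if np.any(np.diff(t_us) < 0):
        bad = int(np.flatnonzero(np.diff(t_us) < 0)[0]) + 1
        raise StreamValidationError(f"non-monotonic timestamp at record {bad}")
    source = y * width + x + pol * width * height
    times = t_us.astype(np.float64) * 1e-6
    return EventStream(times, source, 2 * width * height, float(times[-1]))


def write_nmnist(stream: EventStream, path, width: int = 34, height: int = 34) -> None:
    """Write ``stream`` as an N-MNIST-layout AER binary file.

    Inverse of :func:`read_nmnist` on the representable domain; timestamps
    are quantized to 1 microsecond.
    """
    n_pix = width * height
    if stream.n_sources != 2 * n_pix:
        raise StreamValidationError(
            f"stream has {stream.n_sources} sources, expected {2 * n_pix}"
        )
    src = stream.sources
    pol = src // n_pix
    rem = src - pol * n_pix
    y, x = rem // width, rem % width
    if width > 256 or height > 256 or (len(src) and (x.max() >= 256 or y.max() >= 256)):
        raise StreamValidationError("coordinates not representable in 8-bit x/y")
    t_us = np.round(stream.times * 1e6).astype(np.int64)
    if len(t_us) and t_us.max() >= _T_US_MAX:
        raise OverflowError(
            f"timestamp {t_us.max()} us does not fit in 23 bits (max {_T_US_MAX - 1})"
        )
    rec = np.empty((len(src), _RECORD_SIZE), dtype=np.uint8)
    rec[:, 0] = x
    rec[:, 1] = y
    rec[:, 2] = (pol << 7) | ((t_us >> 16) & 0x7F)
    rec[:, 3] = (t_us >> 8) & 0xFF
    rec[:, 4] = t_us & 0xFF
    with open(path, "wb") as fh:
        fh.write(rec.tobytes())


# ---------------------------------------------------------------------------
# Poisson rate coding
# ---------------------------------------------------------------------------

def poisson_rates(image: np.ndarray, total_rate: float) -> np.ndarray:
    """Per-pixel Poisson rates: ``r_i = total_rate * I_i / sum(I)``.

    The summed rate parameter equals ``total_rate`` by construction, the
    normalization used when converting intensity images to event streams
    (5 keps total by default throughout the package).
    """
    img = np.asarray(image, dtype=np.float64).ravel()
    if np.any(img < 0):
        raise ValueError("intensities must be non-negative")
    total = img.sum()
    if total <= 0:
        raise ValueError("all-zero image: per-pixel rates are undefined")
    if total_rate <= 0:
        raise ValueError("total_rate must be positive")
    return total_rate * img / total


def poisson_stream(rates: np.ndarray, duration: float, rng: np.random.Generator,
                   n_sources: int | None = None) -> EventStream:
    """Independent Poisson processes with the given per-source rates.

    Events are drawn by exponential inter-arrival sampling per source and
    merged into canonical (time, source) order.
    """
    rates = np.asarray(rates, dtype=np.float64).ravel()
    n_src = n_sources if n_sources is not None else rates.size
    all_t, all_s = [], []
    for i in np.flatnonzero(rates > 0):
        r = rates[i]
        # draw in blocks until past the horizon
        t_acc: list[np.ndarray] = []
        last = 0.0
        block = max(8, int(r * duration * 1.5) + 1)
        while last < duration:
            gaps = rng.exponential(1.0 / r, size=block)
            ts = last + np.cumsum(gaps)
            t_acc.append(ts)
            last = ts[-1]
        ts = np.concatenate(t_acc)
        ts = ts[ts <= duration]
        if ts.size:
            all_t.append(ts)
            all_s.append(np.full(ts.size, i, dtype=np.int64))
    if all_t:
        t = np.concatenate(all_t)
        s = np.concatenate(all_s)
        t, s = _canonical_order(t, s)
    else:
        t = np.empty(0)
        s = np.empty(0, dtype=np.int64)
    return EventStream(t, s, n_src, float(duration))


def poisson_encode(image: np.ndarray, total_rate: float, duration: float,
                   seed: int | np.random.Generator) -> EventStream:
    """Encode an intensity image as a Poisson event stream.

    Each pixel is an independent Poisson process whose rate is proportional
    to its intensity, normalized so the rates sum to ``total_rate``.  Fully
    reproducible given ``seed``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rates = poisson_rates(image, total_rate)
    return poisson_stream(rates, duration, rng)


# ---------------------------------------------------------------------------
# Portable stream format (HDF5)
# ---------------------------------------------------------------------------

def save_stream(stream: EventStream, path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["magic"] = _HDF5_MAGIC
        f.attrs["n_sources"] = stream.n_sources
        f.attrs["duration"] = stream.duration
        f.create_dataset("t", data=stream.times)
        f.create_dataset("source", data=stream.sources)


def load_stream(path) -> EventStream:
    import h5py

    with h5py.File(path, "r") as f:
        if f.attrs.get("magic") != _HDF5_MAGIC:
            raise StreamFormatError(f"{path}: not a spikegrad stream file")
        return EventStream(
            np.asarray(f["t"]),
            np.asarray(f["source"]),
            int(f.attrs["n_sources"]),
            float(f.attrs["duration"]),
        )


def load_image(path) -> np.ndarray:
    """Load a grayscale image (PNG/PGM/... via Pillow, or plain numeric text)."""
    path = str(path)
    if path.endswith((".txt", ".csv")):
        return np.loadtxt(path, delimiter="," if path.endswith(".csv") else None)
    from PIL import Image

    with Image.open(path) as im:
        return np.asarray(im.convert("L"), dtype=np.float64)
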