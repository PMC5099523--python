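"""Synthetic event-stream classification tasks.

Desk-scale datasets with the statistical structure the trainer assumes:

* :func:`make_rate_task` — class-conditional Poisson rate patterns, the
  event-stream analogue of rate-coded images: each class elevates the
  rate of a disjoint subset of input sources, with the total rate
  normalized (5 keps by default, the normalization used for image
  encoding).  Background sources keep a small floor rate (5% of peak) so
  that losing neurons and the threshold-regularization paths are
  exercised.

* :func:`make_moving_task` — a spatio-temporal variant emulating
  saccade-style sensor recordings: a per-class pixel pattern translates
  across the grid in timed phases (3 by default), with on-events emitted
  at the pattern's current position and off-events at its previous one,
  flattened into two polarity channels.

* :func:`sample_event_window` — pick a fixed number of consecutive events
  at a random position, the subsampling used for training on real DVS
  streams (300 consecutive events out of ~4k per digit).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .events import EventStream, poisson_stream

__all__ = [
    "SyntheticTask",
    "make_rate_task",
    "make_moving_task",
    "sample_event_window",
]

BACKGROUND_FLOOR = 0.05  # floor rate as a fraction of the peak rate


@dataclass
class SyntheticTask:
    """A class-conditional Poisson event-stream task.

    ``rate_patterns`` holds one per-class rate vector (events/s over the
    input sources) for static tasks; moving tasks additionally carry a
    per-phase sequence of rate vectors in ``phase_patterns``.  Sample
    labels cycle through the classes round-robin so every split is
    balanced; the events of each presentation are drawn fresh from the
    class pattern via the supplied generator.
    """

    n_classes: int
    n_inputs: int
    rate_patterns: np.ndarray           # (n_classes, n_inputs) events/s
    duration: float = 0.050
    n_train: int = 80
    n_test: int = 40
    seed: int = 0
    phase_patterns: np.ndarray | None = None  # (n_classes, n_phases, n_inputs)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        pats = np.asarray(self.rate_patterns, dtype=np.float64)
        if pats.shape != (self.n_classes, self.n_inputs):
            raise ValueError("rate_patterns must be (n_classes, n_inputs)")
        if np.any(pats < 0):
            raise ValueError("rates must be non-negative")
        if any(
            np.array_equal(pats[i], pats[j])
            for i in range(self.n_classes) for j in range(i + 1, self.n_classes)
        ):
            raise ValueError("class rate patterns must be distinct")
        self.rate_patterns = pats

    # -- sampling ------------------------------------------------------

    def label(self, i: int) -> int:
        return i % self.n_classes

    def stream_for_class(self, cls: int, duration: float,
                         rng: np.random.Generator) -> EventStream:
        if self.phase_patterns is None:
            return poisson_stream(self.rate_patterns[cls], duration, rng,
                                  n_sources=self.n_inputs)
        return self._moving_stream(cls, duration, rng)

    def _moving_stream(self, cls: int, duration: float,
                       rng: np.random.Generator) -> EventStream:
        phases = self.phase_patterns[cls]
        n_ph = phases.shape[0]
        seg = duration / n_ph
        t_all, s_all = [], []
        for p in range(n_ph):
            sub = poisson_stream(phases[p], seg, rng, n_sources=self.n_inputs)
            t_all.append(sub.times + p * seg)
            s_all.append(sub.sources)
        t = np.concatenate(t_all)
        s = np.concatenate(s_all)
        order = np.lexsort((s, t))
        return EventStream(t[order], s[order], self.n_inputs, duration)

    def train_sample(self, i: int, duration: float,
                     rng: np.random.Generator):
        if not 0 <= i < self.n_train:
            raise IndexError(i)
        cls = self.label(i)
        return self.stream_for_class(cls, duration, rng), cls

    def test_sample(self, i: int, duration: float,
                    rng: np.random.Generator):
        if not 0 <= i < self.n_test:
            raise IndexError(i)
        cls = self.label(i)
        return self.stream_for_class(cls, duration, rng), cls


def make_rate_task(n_classes: int = 4, n_inputs: int = 100,
                   contrast: float = 1.0, total_rate: float = 5000.0,
                   seed: int = 0, duration: float = 0.050,
                   n_train: int = 80, n_test: int = 40) -> SyntheticTask:
    """Rate-pattern task: each class elevates a disjoint random input subset.

    ``contrast`` in (0, 1] sets how far background sources fall below the
    elevated ones (1 = maximally separable: background at the 5% floor
    only).  Every class pattern is normalized so its rates sum to
    ``total_rate``, hence the expected event count of a presentation is
    ``total_rate * duration`` for every class.
    """
    if not 0 < contrast <= 1:
        raise ValueError("contrast must lie in (0, 1]")
    if n_inputs < n_classes:
        raise ValueError("need at least one input per class")
    k = n_inputs // n_classes
    if k < 1:
        raise ValueError("infeasible per-class subset size")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_inputs)
    patterns = np.empty((n_classes, n_inputs))
    off_level = (1.0 - contrast) + BACKGROUND_FLOOR
    for c in range(n_classes):
        pat = np.full(n_inputs, off_level)
        pat[perm[c * k:(c + 1) * k]] = 1.0 + BACKGROUND_FLOOR
        patterns[c] = pat * (total_rate / pat.sum())
    return SyntheticTask(
        n_classes=n_classes, n_inputs=n_inputs, rate_patterns=patterns,
        duration=duration, n_train=n_train, n_test=n_test, seed=seed,
        meta={"contrast": contrast, "total_rate": total_rate,
              "supports": [perm[c * k:(c + 1) * k].tolist()
                           for c in range(n_classes)]},
    )


def make_moving_task(n_classes: int = 4, grid: tuple[int, int] = (12, 12),
                     n_phases: int = 3, seed: int = 0,
                     total_rate: float = 5000.0, pattern_size: int = 3,
                     duration: float = 0.150, n_train: int = 80,
                     n_test: int = 40) -> SyntheticTask:
    """Moving-pattern task with on/off polarity channels.

    Each class is a ``pattern_size``-square blob at a class-specific row
    that translates horizontally across the grid in ``n_phases`` equal
    time segments (echoing a saccade's piecewise motion).  During each
    segment, on-events fire from the pattern's current position and
    off-events (at half rate) from its previous position; sources are
    flattened with polarity as the slowest axis, off-channel first, the
    same convention as the AER file reader.  ``n_phases = 1`` degenerates
    to a static rate task on the on-channel.
    """
    H, W = grid
    if n_phases < 1:
        raise ValueError("n_phases must be >= 1")
    if pattern_size > H or pattern_size > W:
        raise ValueError("pattern larger than grid")
    if n_phases > 1 and pattern_size + n_phases - 1 > W:
        raise ValueError("pattern leaves the grid during the phase motion")
    rng = np.random.default_rng(seed)
    n_pix = H * W
    n_inputs = 2 * n_pix
    rows = rng.permutation(max(H - pattern_size + 1, 1))[:n_classes] \
        if H - pattern_size + 1 >= n_classes else \
        rng.integers(0, H - pattern_size + 1, size=n_classes)

    def blob_sources(row: int, col: int, channel: int) -> np.ndarray:
        ys, xs = np.meshgrid(np.arange(row, row + pattern_size),
                             np.arange(col, col + pattern_size), indexing="ij")
        return channel * n_pix + ys.ravel() * W + xs.ravel()

    phase_patterns = np.zeros((n_classes, n_phases, n_inputs))
    for c in range(n_classes):
        for p in range(n_phases):
            pat = np.full(n_inputs, BACKGROUND_FLOOR)
            pat[blob_sources(int(rows[c]), p, 1)] = 1.0 + BACKGROUND_FLOOR
            if p > 0:
                pat[blob_sources(int(rows[c]), p - 1, 0)] = 0.5 + BACKGROUND_FLOOR
            phase_patterns[c, p] = pat * (total_rate / pat.sum())
    mean_patterns = phase_patterns.mean(axis=1)
    return SyntheticTask(
        n_classes=n_classes, n_inputs=n_inputs, rate_patterns=mean_patterns,
        duration=duration, n_train=n_train, n_test=n_test, seed=seed,
        phase_patterns=phase_patterns,
        meta={"grid": [H, W], "n_phases": n_phases,
              "pattern_size": pattern_size, "total_rate": total_rate},
    )


def sample_event_window(stream: EventStream, n_events: int,
                        seed: int | np.random.Generator) -> EventStream:
    """Pick ``n_events`` consecutive events at a uniformly random position.

    Times are re-zeroed to the window's first event; the duration is the
    window's time span.  A stream shorter than ``n_events`` is returned
    whole with a warning.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = len(stream)
    if n < n_events:
        warnings.warn(
            f"stream has only {n} events (< {n_events}); returning it whole")
        return stream
    start = int(rng.integers(0, n - n_events + 1))
    t = stream.times[start:start + n_events]
    s = stream.sources[start:start + n_events]
    t0 = t[0] if len(t) else 0.0
    span = float(t[-1] - t0) if len(t) else 0.0
    return EventStream(t - t0, s.copy(), stream.n_sources, span)
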