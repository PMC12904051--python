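"""Shared data containers: stimulus schedules and two-channel functional movies.

Coordinate conventions used throughout the package: 0-based pixel indices,
pixel-center convention, ``x`` = column, ``y`` = row.  Geometric transforms
act about the image center.  Times are seconds, frames are sampled at
``frame_rate`` Hz starting at t = 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError


@dataclass(frozen=True)
class Epoch:
    """One stimulus application: tastant name plus onset/offset in seconds."""

    tastant: str
    onset_s: float
    offset_s: float

    def __post_init__(self):
        if self.offset_s <= self.onset_s:
            raise ParameterError(
                f"epoch for {self.tastant!r}: offset {self.offset_s} <= onset {self.onset_s}"
            )


@dataclass(frozen=True)
class StimulusSchedule:
    """Ordered, non-overlapping tastant applications with a pre-stimulus baseline.

    The default protocol applies artificial saliva for the first 20 s (the
    baseline window), then for each tastant 20 s of stimulus followed by a
    50 s washout.
    """

    epochs: tuple[Epoch, ...]
    baseline_window: tuple[float, float]
    frame_rate: float = 1.0

    def __post_init__(self):
        if self.frame_rate <= 0:
            raise ParameterError("frame_rate must be positive")
        b0, b1 = self.baseline_window
        if b1 <= b0:
            raise ParameterError("baseline window must have positive length")
        prev_end = -np.inf
        for ep in self.epochs:
            if ep.onset_s < prev_end:
                raise ParameterError("epochs must be ordered and non-overlapping")
            prev_end = ep.offset_s
        if self.epochs and b1 > self.epochs[0].onset_s:
            raise ParameterError("baseline must precede the first stimulus epoch")

    @classmethod
    def default(
        cls,
        tastants: tuple[str, ...] = ("sweet", "umami", "sour"),
        baseline_s: float = 20.0,
        stimulus_s: float = 20.0,
        washout_s: float = 50.0,
        frame_rate: float = 1.0,
    ) -> "StimulusSchedule":
        epochs = []
        t = baseline_s
        for name in tastants:
            epochs.append(Epoch(name, t, t + stimulus_s))
            t += stimulus_s + washout_s
        return cls(tuple(epochs), (0.0, baseline_s), frame_rate)

    @property
    def duration_s(self) -> float:
        return self.epochs[-1].offset_s + 50.0 if self.epochs else self.baseline_window[1]

    @property
    def tastants(self) -> tuple[str, ...]:
        return tuple(ep.tastant for ep in self.epochs)

    def n_frames(self, duration_s: float | None = None) -> int:
        return int(round((duration_s or self.duration_s) * self.frame_rate))

    def frame_slice(self, t0: float, t1: float) -> slice:
        """Frame indices covering the half-open time interval [t0, t1)."""
        lo = int(np.ceil(t0 * self.frame_rate - 1e-9))
        hi = int(np.ceil(t1 * self.frame_rate - 1e-9))
        return slice(max(lo, 0), hi)

    def epoch_slice(self, tastant: str) -> slice:
        for ep in self.epochs:
            if ep.tastant == tastant:
                return self.frame_slice(ep.onset_s, ep.offset_s)
        raise KeyError(f"no epoch for tastant {tastant!r}")

    def to_dict(self) -> dict:
        return {
            "epochs": [[e.tastant, e.onset_s, e.offset_s] for e in self.epochs],
            "baseline_window": list(self.baseline_window),
            "frame_rate": self.frame_rate,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StimulusSchedule":
        return cls(
            tuple(Epoch(str(n), float(a), float(b)) for n, a, b in d["epochs"]),
            tuple(float(v) for v in d["baseline_window"]),
            float(d.get("frame_rate", 1.0)),
        )


@dataclass
class TasteBudMovie:
    """Two-channel pseudo-volumetric calcium-imaging movie.

    ``green`` (GCaMP) and ``red`` (tdTomato) are (T, P, Y, X) arrays over
    T frames and P axial planes.  Cells live on the apical planes
    (0 .. P-2 by default); afferent-nerve signal lives on the basolateral
    plane (the last one).
    """

    green: np.ndarray
    red: np.ndarray
    schedule: StimulusSchedule
    cell_plane: int = 0
    nerve_plane: int = -1
    true_shifts: np.ndarray | None = None  # (T, 2) injected (dy, dx), ground truth
    invivo_labels: np.ndarray | None = None  # label image in the movie's frame

    def __post_init__(self):
        if self.green.shape != self.red.shape:
            raise ParameterError("green/red channel shapes differ")
        if self.green.ndim != 4:
            raise ParameterError("movie arrays must be (T, P, Y, X)")

    @property
    def n_frames(self) -> int:
        return self.green.shape[0]

    @property
    def n_planes(self) -> int:
        return self.green.shape[1]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.green.shape[2:]
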