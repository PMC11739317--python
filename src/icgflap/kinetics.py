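"""Bolus-kinetics handling: from a raw ICG-A frame stack to a plateau-phase
perfusion map.

After an intravenous indocyanine green bolus, the mean fluorescence in the
flap rises during arterial inflow, sits on a plateau while the dye
circulates, and decays during venous washout.  The perfusion map used for
flap assessment is taken from the plateau, i.e. after the arterial phase and
before the venous phase.  Phase boundaries are located on the ROI-mean
time-intensity curve with threshold fractions of its maximum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

__all__ = [
    "FrameSequence",
    "PhaseSegmentation",
    "PerfusionMap",
    "mean_roi_curve",
    "detect_phases",
    "extract_perfusion_map",
]


@dataclass
class FrameSequence:
    """An ordered stack of 2-D near-infrared intensity frames.

    Parameters
    ----------
    frames
        ``(T, H, W)`` array of non-negative intensities.
    times
        ``T`` strictly increasing acquisition times in seconds since
        injection.
    metadata
        Free-form key/value pairs (ICG dose, device tag, ...).
    """

    frames: np.ndarray
    times: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValueError("frames must be a (T, H, W) stack with T >= 1")
        if self.times.shape != (self.frames.shape[0],):
            raise ValueError(
                f"times has {self.times.size} entries for "
                f"{self.frames.shape[0]} frames"
            )
        if self.frames.shape[0] > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.frames < 0):
            raise ValueError("frame intensities must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


@dataclass(frozen=True)
class PhaseSegmentation:
    """Frame-index boundaries of the arterial / plateau / venous phases."""

    arterial_end_index: int
    venous_start_index: int

    def __post_init__(self) -> None:
        if self.arterial_end_index > self.venous_start_index:
            raise ValueError("arterial_end_index must be <= venous_start_index")

    @property
    def plateau_indices(self) -> np.ndarray:
        """Inclusive, contiguous and always nonempty plateau index range."""
        return np.arange(self.arterial_end_index, self.venous_start_index + 1)


@dataclass(frozen=True)
class PerfusionMap:
    """Single plateau-phase intensity image (absolute perfusion units)."""

    values: np.ndarray
    source_indices: tuple[int, int]
    aggregator_name: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if np.any(self.values < 0):
            raise ValueError("perfusion map values must be non-negative")


def mean_roi_curve(seq: FrameSequence, roi: np.ndarray) -> np.ndarray:
    """Mean intensity over ``roi`` for each frame.

    Parameters
    ----------
    seq
        Frame stack.
    roi
        Boolean ``(H, W)`` mask; must be nonempty and match the frame shape.

    Returns
    -------
    ndarray of shape ``(T,)``.
    """
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != seq.shape:
        raise ValueError(f"roi shape {roi.shape} != frame shape {seq.shape}")
    if not roi.any():
        raise ValueError("roi is empty")
    return seq.frames[:, roi].mean(axis=1)


def detect_phases(
    curve: np.ndarray,
    rise_fraction: float = 0.95,
    fall_fraction: float = 0.90,
) -> PhaseSegmentation:
    """Locate the plateau window on a time-intensity curve.

    The arterial phase ends at the first frame whose ROI mean reaches
    ``rise_fraction`` of the curve maximum; the venous phase starts at the
    last frame still at or above ``fall_fraction`` of the maximum.  The
    window is inclusive of both boundaries, always contains the argmax frame
    and is therefore never empty.
    """
    curve = np.asarray(curve, dtype=float)
    if curve.size < 3:
        raise ValueError("curve must have at least 3 samples")
    peak = curve.max()
    if peak <= 0:
        raise ValueError("no perfusion signal: ROI curve is identically zero")
    rise = np.flatnonzero(curve >= rise_fraction * peak)
    fall = np.flatnonzero(curve >= fall_fraction * peak)
    return PhaseSegmentation(
        arterial_end_index=int(rise[0]), venous_start_index=int(fall[-1])
    )


def extract_perfusion_map(
    seq: FrameSequence,
    seg: PhaseSegmentation,
    aggregator: Literal["median", "mean"] = "median",
) -> PerfusionMap:
    """Aggregate the plateau frames into one perfusion image.

    The default is a per-pixel median over the plateau window, which is
    robust to frame-to-frame flicker; ``mean`` is available, and a
    single-frame window reproduces a frozen-screen workflow exactly.
    """
    idx = seg.plateau_indices
    if idx[0] < 0 or idx[-1] >= seq.n_frames:
        raise ValueError("plateau indices out of range for this sequence")
    window = seq.frames[idx[0] : idx[-1] + 1]
    if aggregator == "median":
        values = np.median(window, axis=0)
    elif aggregator == "mean":
        values = window.mean(axis=0)
    else:
        raise ValueError(f"unknown aggregator {aggregator!r}")
    return PerfusionMap(
        values=values,
        source_indices=(int(idx[0]), int(idx[-1])),
        aggregator_name=aggregator,
    )
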