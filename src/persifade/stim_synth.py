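"""Random-dot matrices, the single second-order transient, and the contrast-
decay proxy stimulus.

Grey levels are floats with black = 0, white = 1 (mean grey 0.5); 8-bit
quantization happens only at export time.  The transient is a one-time
polarity flip of every pixel inside a shape mask: the two matrices are
identical elsewhere, so the stimulus carries a single second-order onset
signal and no sustained or offset signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence, Union

import numpy as np

from .decay_model import DecayParams, impulse_response
from .geometry import AnnulusSpec, DiskSpec, DisplayGeometry, shape_mask

__all__ = [
    "TransientPair",
    "FrameSchedule",
    "random_matrix",
    "apply_transient",
    "proxy_frames",
]


def random_matrix(side_px: int, seed) -> np.ndarray:
    """side_px x side_px matrix of pixels independently black (0) or white (1).

    ``seed`` may be an int or a numpy Generator; the same seed reproduces the
    same matrix.
    """
    if side_px <= 0:
        raise ValueError("side_px must be positive")
    rng = np.random.default_rng(seed)
    return rng.integers(0, 2, size=(side_px, side_px), dtype=np.uint8)


def apply_transient(m1: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Flip luminance polarity exactly on mask pixels (an involution)."""
    if m1.shape != mask.shape:
        raise ValueError(f"shape mismatch: matrix {m1.shape} vs mask {mask.shape}")
    m2 = m1.copy()
    m2[mask] = 1 - m2[mask]
    return m2


@dataclass(frozen=True)
class TransientPair:
    """Two binary matrices differing exactly on the flip mask."""

    m1: np.ndarray
    m2: np.ndarray
    mask: np.ndarray
    seed: int | None = None

    def __post_init__(self) -> None:
        if not np.array_equal(self.m1 != self.m2, self.mask.astype(bool)):
            raise ValueError("m1 and m2 must differ exactly on mask pixels")

    @classmethod
    def generate(
        cls,
        spec: Union[AnnulusSpec, DiskSpec],
        geom: DisplayGeometry,
        seed,
        *,
        allow_clip: bool = False,
    ) -> "TransientPair":
        m1 = random_matrix(geom.matrix_px, seed)
        mask = shape_mask(spec, geom, allow_clip=allow_clip)
        return cls(m1, apply_transient(m1, mask), mask,
                   seed if isinstance(seed, int) else None)


@dataclass(frozen=True)
class FrameSchedule:
    """Frame times of one stimulus sequence, all in ms since sequence start.

    The matrix transition happens at ``t_transition_ms`` (after the random
    fixation interval); the reference stimulus comes on Δt later.
    """

    frame_times_ms: tuple
    t_transition_ms: float
    delta_t_ms: float
    reference_duration_ms: float = 500.0
    fixation_interval_ms: float = 1000.0

    def __post_init__(self) -> None:
        ft = np.asarray(self.frame_times_ms, dtype=float)
        if np.any(np.diff(ft) < 0):
            raise ValueError("frame times must be non-decreasing")

    @property
    def t_reference_on_ms(self) -> float:
        return self.t_transition_ms + self.delta_t_ms

    @classmethod
    def build(
        cls,
        rng: np.random.Generator,
        delta_t_ms: float,
        *,
        frame_rate_hz: float = 100.0,
        tail_ms: float = 1500.0,
        reference_duration_ms: float = 500.0,
    ) -> "FrameSchedule":
        """Draw the 1000-1500 ms fixation interval and lay out frame times at
        the display rate; frames are stamped at their midpoints."""
        fixation = float(rng.uniform(1000.0, 1500.0))
        period = 1000.0 / frame_rate_hz
        total = fixation + tail_ms
        times = np.arange(period / 2, total, period)
        return cls(tuple(times), fixation, delta_t_ms,
                   reference_duration_ms, fixation)


def proxy_frames(
    base: np.ndarray,
    disk: DiskSpec,
    decay: DecayParams,
    frame_times_ms: Sequence[float],
    geom: DisplayGeometry,
) -> np.ndarray:
    """Render the physically fading disk as a stack of grayscale frames.

    At each frame time t (ms since the stimulus onset), pixels inside the disk
    are pulled toward mean grey by the contrast reduction f(t):

        lum(t) = 0.5 + (pixel - 0.5) * (1 - f(t))

    so f = 1 is a homogeneous grey disk and f = 0 leaves the base matrix
    untouched.  Outside the disk frames equal the base matrix; the regional
    mean luminance is unchanged at every t.  Negative frame times (before the
    onset) get f = 0.
    """
    if not decay.is_normalized:
        raise ValueError("decay must be calibrated/normalized (peak = 1)")
    base_f = np.asarray(base, dtype=float)
    mask = shape_mask(disk, geom)
    frames = np.empty((len(frame_times_ms),) + base_f.shape, dtype=float)
    for k, t_ms in enumerate(frame_times_ms):
        f = impulse_response(max(t_ms, 0.0) / 1000.0, decay) if t_ms > 0 else 0.0
        frame = base_f.copy()
        frame[mask] = 0.5 + (base_f[mask] - 0.5) * (1.0 - f)
        frames[k] = frame
    return frames
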