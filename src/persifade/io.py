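"""Trial-record CSV schema and image/animation export."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence, Union

import imageio.v3 as iio
import numpy as np
import pandas as pd

__all__ = [
    "REQUIRED_TRIAL_COLUMNS",
    "read_trials",
    "write_trials",
    "export_png",
    "export_animation",
]

REQUIRED_TRIAL_COLUMNS = (
    "subject", "experiment", "task", "delta_t_ms", "n_reps", "converged",
)

#: Δt is serialized at 0.1 ms precision (finer than any adjustment device)
_DELTA_T_DECIMALS = 1


def _check_schema(df: pd.DataFrame) -> None:
    for col in REQUIRED_TRIAL_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"trial table is missing required column {col!r}")


def write_trials(df: pd.DataFrame, path: Union[str, Path]) -> None:
    """Write trial records as UTF-8 comma-separated values, header row,
    '.' decimal; Δt rounded to 0.1 ms.  Unknown columns are preserved."""
    _check_schema(df)
    out = df.copy()
    out["delta_t_ms"] = out["delta_t_ms"].round(_DELTA_T_DECIMALS)
    out.to_csv(path, index=False, encoding="utf-8")


def read_trials(path: Union[str, Path]) -> pd.DataFrame:
    """Read trial records, validating the required schema columns."""
    df = pd.read_csv(path, encoding="utf-8")
    _check_schema(df)
    df["converged"] = df["converged"].astype(bool)
    return df


def _to_uint8(frame: np.ndarray) -> np.ndarray:
    frame = np.asarray(frame)
    if frame.dtype == bool:
        return frame.astype(np.uint8) * 255
    if np.issubdtype(frame.dtype, np.integer):
        # binary matrices use 0/1; full-range uint8 passes through untouched
        if frame.size and frame.max() <= 1:
            return frame.astype(np.uint8) * 255
        return frame.astype(np.uint8)
    # float frames use the synthesis convention black=0.0, white=1.0
    return np.clip(np.rint(frame * 255.0), 0, 255).astype(np.uint8)


def export_png(frame: np.ndarray, path: Union[str, Path]) -> None:
    """Write one matrix/mask/frame as an 8-bit grayscale PNG (0/255 for
    binary inputs)."""
    iio.imwrite(Path(path), _to_uint8(frame), extension=".png")


def export_animation(
    frames: Sequence[np.ndarray],
    path: Union[str, Path],
    frame_rate: float = 100.0,
) -> None:
    """Write a frame stack as an animated GIF (lossless grayscale palette).

    Per-frame duration is 1000 / frame_rate ms; requires at least two frames.
    """
    if len(frames) < 2:
        raise ValueError("an animation needs at least 2 frames")
    stack = np.stack([_to_uint8(f) for f in frames])
    duration_ms = 1000.0 / frame_rate
    iio.imwrite(Path(path), stack, extension=".gif",
                duration=duration_ms, loop=0)


def read_animation(path: Union[str, Path]) -> np.ndarray:
    """Read back an animated GIF as a uint8 frame stack (grayscale)."""
    frames = iio.imread(Path(path), extension=".gif", index=None)
    if frames.ndim == 4:  # palette GIFs come back RGB(A); channels are equal
        frames = frames[..., 0]
    return frames
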