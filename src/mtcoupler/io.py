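"""TIFF stack input/output and raw-movie preprocessing."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import tifffile


class FormatError(ValueError):
    """Unreadable or unsupported image file."""


def read_stack(path: str | Path) -> np.ndarray:
    """Read a (multi-page) TIFF as a (frames, y, x) array.

    Single-page files come back as a 1-frame stack.  16-bit integer and
    32-bit float files round-trip losslessly with :func:`write_stack`.
    """
    try:
        data = tifffile.imread(str(path))
    except Exception as exc:  # noqa: BLE001 - re-raise with context
        raise FormatError(f"cannot read TIFF {path}: {exc}") from exc
    data = np.asarray(data)
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise FormatError(f"{path}: expected 2-D or 3-D image data, got shape {data.shape}")
    return data


def write_stack(path: str | Path, stack: np.ndarray) -> None:
    """Write a (frames, y, x) array as a multi-page TIFF (dtype preserved)."""
    stack = np.asarray(stack)
    if stack.ndim == 2:
        stack = stack[None]
    if stack.ndim != 3:
        raise ValueError(f"expected a 2-D or 3-D array, got shape {stack.shape}")
    tifffile.imwrite(str(path), stack, photometric="minisblack")


def preprocess_dic_stack(
    stack: np.ndarray, background_frames: int = 50, block: int = 10
) -> np.ndarray:
    """Background-correct and block-average a raw transmitted-light stack.

    Subtracts the mean of the first ``background_frames`` frames (recorded
    while rapidly moving the stage, so structure averages out), then
    averages non-overlapping blocks of ``block`` consecutive frames; a
    trailing partial block is dropped.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3:
        raise ValueError("stack must be 3-D (frames, y, x)")
    if stack.shape[0] < background_frames:
        raise ValueError(
            f"stack has {stack.shape[0]} frames, fewer than {background_frames} background frames"
        )
    corrected = stack - stack[:background_frames].mean(axis=0)
    n_blocks = corrected.shape[0] // block
    if n_blocks < 1:
        raise ValueError(f"fewer frames ({corrected.shape[0]}) than one block ({block})")
    trimmed = corrected[: n_blocks * block]
    return trimmed.reshape(n_blocks, block, *stack.shape[1:]).mean(axis=1)
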