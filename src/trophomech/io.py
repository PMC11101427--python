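"""File formats at the pipeline boundaries.

Images cross the boundary as multi-page 16-bit TIFF; everything downstream
is tidy CSV (vector fields, ROI statistics, spheroid tracks) plus small
JSON sidecars for ground truth and run metadata.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

from .fields import DisplacementField, TractionField

__all__ = [
    "read_image_stack",
    "write_image_stack",
    "write_displacement_csv",
    "read_displacement_csv",
    "write_traction_csv",
    "read_traction_csv",
    "write_json",
    "read_json",
]


def read_image_stack(path: str | Path) -> np.ndarray:
    """Read a multi-page TIFF as an (n_frames, H, W) array.

    A single-page file comes back with a leading axis of length 1.  Frames
    of inconsistent shape are refused.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image stack not found: {path}")
    with tifffile.TiffFile(path) as tif:
        shapes = {page.shape for page in tif.pages}
        if len(shapes) > 1:
            raise ValueError(f"inconsistent frame shapes in {path}: {sorted(shapes)}")
        stack = tif.asarray()
    if stack.ndim == 2:
        stack = stack[None]
    return stack


def write_image_stack(path: str | Path, stack: np.ndarray) -> None:
    """Write an (n_frames, H, W) array as multi-page 16-bit TIFF.

    Float input is clipped to the uint16 range; integer input is written
    bit-exactly."""
    stack = np.asarray(stack)
    if stack.ndim == 2:
        stack = stack[None]
    if not np.issubdtype(stack.dtype, np.integer):
        stack = np.clip(np.round(stack), 0, 65535)
    tifffile.imwrite(Path(path), stack.astype(np.uint16), photometric="minisblack")


def write_displacement_csv(
    path: str | Path, fields: Sequence[DisplacementField]
) -> None:
    """Long-format CSV, one row per lattice vector per timepoint."""
    pd.concat([f.to_dataframe() for f in fields], ignore_index=True).to_csv(
        path, index=False
    )


def read_displacement_csv(path: str | Path, pixel_size: float) -> list[DisplacementField]:
    df = pd.read_csv(path)
    return [
        DisplacementField.from_dataframe(grp, pixel_size)
        for _, grp in df.groupby("time_h", dropna=False, sort=True)
    ]


def write_traction_csv(path: str | Path, fields: Sequence[TractionField]) -> None:
    pd.concat([f.to_dataframe() for f in fields], ignore_index=True).to_csv(
        path, index=False
    )


def read_traction_csv(path: str | Path, pixel_size: float) -> list[TractionField]:
    df = pd.read_csv(path)
    return [
        TractionField.from_dataframe(grp, pixel_size)
        for _, grp in df.groupby("time_h", dropna=False, sort=True)
    ]


def write_json(path: str | Path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path: str | Path):
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"file not found: {path}")
    return json.loads(path.read_text())
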