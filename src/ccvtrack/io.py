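"""TIFF / CSV / JSON input-output.

TIFF pixel data round-trips bit-exactly for integer types; CSV numeric
columns round-trip to 6 decimals.  All tables use UTF-8, a header row
and '.' decimals; coordinates are 0-based pixel-center with x = column.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

__all__ = ["read_image", "write_image", "read_table", "write_table",
           "read_json", "write_json"]

_SUPPORTED_DTYPES = ("uint8", "uint16", "int16", "float32", "float64")


def read_image(path: str | Path) -> np.ndarray:
    """Read a single- or multi-page grayscale TIFF as an array."""
    arr = tifffile.imread(str(path))
    if arr.dtype.name not in _SUPPORTED_DTYPES:
        raise ValueError(
            f"{path}: unsupported TIFF dtype {arr.dtype} "
            f"(supported: {', '.join(_SUPPORTED_DTYPES)})"
        )
    return arr


def write_image(path: str | Path, array: np.ndarray) -> None:
    """Write an array as a (multi-page) grayscale TIFF."""
    array = np.asarray(array)
    if array.dtype.name not in _SUPPORTED_DTYPES:
        if np.issubdtype(array.dtype, np.floating):
            array = array.astype(np.float32)
        else:
            raise ValueError(f"{path}: unsupported dtype {array.dtype}")
    tifffile.imwrite(str(path), array, photometric="minisblack")


def read_table(path: str | Path, required: list[str] | None = None) -> pd.DataFrame:
    """Read a CSV table, checking for required columns."""
    df = pd.read_csv(path)
    if required:
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing required column(s) {missing}")
    return df


def write_table(path: str | Path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False, float_format="%.6f")


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def write_json(path: str | Path, obj: dict) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
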