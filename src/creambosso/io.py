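"""Image and table I/O, configuration files, and bundled reference data.

Images: 8/16-bit grayscale PNG and TIFF (read/write) plus read-only DICOM
monochrome.  Tables: CSV with fixed per-schema headers — ``sweep``
(contrast/entropy vs d), ``ratings`` (Likert scores), ``metrics``
(comparison reports).  Configuration: plain-text ``key = value`` files.

The package bundles three measured sweep tables (knee, breast, wrist
radiograph series) and one expert-rating table as worked examples and
analytics fixtures; see :func:`bundled_table` / :func:`bundled_ratings`.
"""

from __future__ import annotations

import logging
from importlib import resources
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .enhance import rescale_to_8bit
from .errors import ChannelError, InvalidInputError, SchemaError
from .grid import ImageGrid
from .ratings import RatingRecord

logger = logging.getLogger("creambosso")

SCHEMAS = {
    "sweep": ["d", "contrast_cream", "contrast_bosso", "entropy_cream", "entropy_bosso"],
    "ratings": ["image_id", "d", "cream", "bosso"],
    "metrics": ["method", "contrast", "entropy_bits", "psnr_db", "snr_db", "ssim"],
}

# ITU-R BT.601 luminance weights for forced grayscale conversion
_LUMA = np.array([0.299, 0.587, 0.114])


def read_image(path, force_gray: bool = False) -> ImageGrid:
    """Read a PNG/TIFF/DICOM image as a grayscale grid with its bit depth.

    Multi-channel input is rejected unless ``force_gray`` asks for a
    luminance conversion.
    """
    path = Path(path)
    if not path.exists():
        raise InvalidInputError(f"no such file: {path}")
    if path.suffix.lower() in (".dcm", ".dicom"):
        import pydicom

        ds = pydicom.dcmread(path)
        arr = ds.pixel_array
        if arr.ndim != 2:
            raise ChannelError("only monochrome DICOM is supported")
    else:
        try:
            arr = iio.imread(path)
        except Exception as exc:  # pragma: no cover - backend specific
            raise InvalidInputError(f"cannot read {path}: {exc}") from exc
    if arr.ndim == 3:
        if not force_gray:
            raise ChannelError(
                f"{path} has {arr.shape[-1]} channels; pass force_gray for a "
                "luminance conversion"
            )
        arr = arr[..., :3].astype(np.float64) @ _LUMA
    bit_depth = 16 if np.asarray(arr).dtype.itemsize > 1 else 8
    return ImageGrid(np.asarray(arr, dtype=np.float64), bit_depth=bit_depth,
                     source=str(path))


def write_image(grid: ImageGrid, path, mode: str = "raw-residual") -> None:
    """Write a grid to PNG/TIFF.

    ``raw-residual`` rounds the float values and writes integers at the
    grid's declared bit depth (8-bit grids round-trip exactly);
    ``rescaled-8bit`` min-max rescales to [0, 255] (a constant grid is
    written as mid-gray with a logged warning).
    """
    path = Path(path)
    if mode == "raw-residual":
        dtype = np.uint8 if grid.bit_depth == 8 else np.uint16
        data = np.clip(np.rint(grid.pixels), 0, grid.nominal_max).astype(dtype)
    elif mode == "rescaled-8bit":
        if grid.pixels.max() == grid.pixels.min():
            logger.warning("constant image rescaled for export: writing mid-gray")
        data = rescale_to_8bit(grid.pixels)
    else:
        raise InvalidInputError(f"unknown write mode {mode!r}")
    iio.imwrite(path, data)


def _schema_error(path, msg: str) -> SchemaError:
    return SchemaError(f"{path}: {msg}")


def load_table(path, schema: str):
    """Load and validate a CSV table.

    ``sweep``/``metrics`` return a DataFrame; ``ratings`` returns a list
    of :class:`RatingRecord` (blank cells become missing scores).  Header
    mismatches, non-numeric cells and (for sweeps) non-increasing d raise
    :class:`SchemaError` naming the offending row or column.
    """
    if schema not in SCHEMAS:
        raise InvalidInputError(f"schema must be one of {tuple(SCHEMAS)}")
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    except pd.errors.EmptyDataError as exc:
        raise _schema_error(path, "empty file") from exc
    expected = SCHEMAS[schema]
    if list(df.columns) != expected:
        raise _schema_error(path, f"header must be {','.join(expected)}, got "
                                  f"{','.join(df.columns)}")

    if schema == "ratings":
        records = []
        for idx, row in df.iterrows():
            try:
                d = float(row["d"])
            except (TypeError, ValueError):
                raise _schema_error(path, f"row {idx}: non-numeric d {row['d']!r}")
            scores = {}
            for col in ("cream", "bosso"):
                cell = row[col]
                if cell is None or (isinstance(cell, float) and np.isnan(cell)) or str(cell).strip() == "":
                    scores[col] = None
                else:
                    try:
                        scores[col] = int(cell)
                    except ValueError:
                        raise _schema_error(path, f"row {idx}: non-integer {col} {cell!r}")
            records.append(RatingRecord(image_id=str(row["image_id"]), d=d, **scores))
        return records

    numeric_cols = expected[1:] if schema == "metrics" else expected
    out = df.copy()
    for col in numeric_cols:
        try:
            out[col] = pd.to_numeric(df[col])
        except (TypeError, ValueError):
            raise _schema_error(path, f"non-numeric cell in column {col!r}")
    if schema == "sweep":
        d = out["d"].to_numpy()
        if np.any(d <= 0):
            raise _schema_error(path, "column 'd' must be positive")
        if np.any(np.diff(d) <= 0):
            raise _schema_error(path, "column 'd' must be strictly increasing")
    return out


def save_table(df: pd.DataFrame, path) -> None:
    """Write a DataFrame to CSV without the index (deterministic layout)."""
    df.to_csv(path, index=False)


def load_config(path) -> dict[str, str]:
    """Parse a plain-text ``key = value`` configuration file.

    Blank lines and ``#`` comments are ignored; values are returned as
    strings for the caller to coerce.
    """
    out: dict[str, str] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise SchemaError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, value = line.split("=", 1)
        out[key.strip()] = value.strip()
    return out


_BUNDLED = {
    "knee": "knee_sweep.csv",
    "breast": "breast_sweep.csv",
    "wrist": "wrist_sweep.csv",
}


def bundled_table(name: str) -> pd.DataFrame:
    """A bundled measured sweep table: 'knee', 'breast' or 'wrist'."""
    if name not in _BUNDLED:
        raise InvalidInputError(f"bundled tables: {tuple(_BUNDLED)}")
    with resources.as_file(resources.files("creambosso.data") / _BUNDLED[name]) as p:
        return load_table(p, "sweep")


def bundled_ratings() -> list[RatingRecord]:
    """The bundled expert Likert-rating table."""
    with resources.as_file(resources.files("creambosso.data") / "expert_ratings.csv") as p:
        return load_table(p, "ratings")
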