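"""Reading image series and writing analysis tables.

Frames are read from single- or multi-page TIFF or per-frame PNG files.
Frame-to-time mapping comes from a manifest CSV with columns
``filename, time_min`` living next to the images (imaging cadence in these
experiments is irregular, from minutes to a day, so times are data, not a
rate).
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

__all__ = ["read_image", "read_series", "write_provenance"]


def read_image(path: str | Path) -> np.ndarray:
    """Read one grayscale image (TIFF or PNG) as a 2D array.

    A multi-page TIFF read through this function must contain one page;
    use :func:`read_series` for stacks.
    """
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    arr = np.asarray(arr)
    if arr.ndim == 3 and arr.shape[0] == 1:
        arr = arr[0]
    if arr.ndim != 2:
        raise ValueError(f"{path} is not a single 2D grayscale image")
    return arr


def read_series(
    directory: str | Path, manifest: str | Path | None = None
) -> list[tuple[float, np.ndarray]]:
    """Read an image series with its frame-time mapping.

    ``manifest`` defaults to ``<directory>/manifest.csv`` with columns
    ``filename`` (relative to the directory) and ``time_min``.  Returns
    (time_min, image) pairs sorted by time.
    """
    directory = Path(directory)
    manifest = Path(manifest) if manifest else directory / "manifest.csv"
    if not manifest.exists():
        raise FileNotFoundError(f"manifest not found: {manifest}")
    df = pd.read_csv(manifest)
    missing = {"filename", "time_min"} - set(df.columns)
    if missing:
        raise ValueError(f"manifest lacks columns: {sorted(missing)}")
    out = [
        (float(row.time_min), read_image(directory / str(row.filename)))
        for row in df.itertuples()
    ]
    out.sort(key=lambda p: p[0])
    return out


def write_provenance(path: str | Path, config: dict, seed: int | None = None) -> None:
    """Write the fully resolved run configuration as a JSON sidecar."""
    payload = dict(config)
    if seed is not None:
        payload["seed"] = seed
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=str)
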