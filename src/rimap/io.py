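"""Reading and writing the pipeline's file formats.

Localization tables travel as CSV (header
``frame,x_nm,y_nm,z_nm,photons,background,llr,converged``) or as an
equivalent HDF5 layout (one dataset per column under ``/localizations``);
image stacks as multi-page TIFF; expected molecule images as 32-bit
float TIFF.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

LOC_COLUMNS = ["frame", "x_nm", "y_nm", "z_nm", "photons", "background",
               "llr", "converged"]


def read_stack(path) -> np.ndarray:
    """Read a multi-page TIFF stack as a (frames, ny, nx) float array."""
    import tifffile

    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None]
    return arr.astype(float)


def write_stack(path, stack: np.ndarray, dtype=np.uint16) -> None:
    """Write an image stack as multi-page TIFF (clipped to the dtype)."""
    import tifffile

    arr = np.asarray(stack)
    if np.issubdtype(dtype, np.integer):
        info = np.iinfo(dtype)
        arr = np.clip(np.round(arr), info.min, info.max)
    tifffile.imwrite(path, arr.astype(dtype))


def write_image_float32(path, image: np.ndarray) -> None:
    """Write one expected molecule image as 32-bit float TIFF."""
    import tifffile

    tifffile.imwrite(path, np.asarray(image, dtype=np.float32))


def write_localizations(path, table: pd.DataFrame) -> None:
    """Write a localization table as CSV or HDF5 (by file suffix)."""
    path = Path(path)
    df = table[LOC_COLUMNS]
    if path.suffix.lower() in (".h5", ".hdf5"):
        import h5py

        with h5py.File(path, "w") as f:
            grp = f.create_group("localizations")
            for col in LOC_COLUMNS:
                data = df[col].to_numpy()
                if col == "converged":
                    data = data.astype(np.uint8)
                grp.create_dataset(col, data=data)
    else:
        df.to_csv(path, index=False)


def read_localizations(path) -> pd.DataFrame:
    """Read a localization table written by :func:`write_localizations`."""
    path = Path(path)
    if path.suffix.lower() in (".h5", ".hdf5"):
        import h5py

        with h5py.File(path, "r") as f:
            grp = f["localizations"]
            df = pd.DataFrame({col: grp[col][()] for col in LOC_COLUMNS})
    else:
        df = pd.read_csv(path)
    df["converged"] = df["converged"].astype(bool)
    return df[LOC_COLUMNS]
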