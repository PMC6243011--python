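"""Dense volume I/O: multi-page TIFF and HDF5, zyx axis order."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .errors import ValidationError


def read_volume(path) -> np.ndarray:
    """Read a 3D volume; format chosen by suffix (.tif/.tiff or .h5/.hdf5)."""
    p = Path(path)
    suffix = p.suffix.lower()
    if suffix in (".tif", ".tiff"):
        import tifffile

        arr = np.asarray(tifffile.imread(p))
    elif suffix in (".h5", ".hdf5"):
        import h5py

        with h5py.File(p, "r") as fh:
            if "data" in fh:
                arr = fh["data"][()]
            else:
                keys = list(fh.keys())
                if len(keys) != 1:
                    raise ValidationError(
                        f"{p}: expected a 'data' dataset or a single dataset, found {keys}"
                    )
                arr = fh[keys[0]][()]
    else:
        raise ValidationError(f"unsupported volume format: {p.suffix}")
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValidationError(f"{p}: expected a 3D volume, got {arr.ndim}D")
    return arr


def write_volume(path, array: np.ndarray) -> None:
    p = Path(path)
    arr = np.asarray(array)
    if arr.ndim != 3:
        raise ValidationError("volumes are 3D (z, y, x)")
    suffix = p.suffix.lower()
    if suffix in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(p, arr)
    elif suffix in (".h5", ".hdf5"):
        import h5py

        with h5py.File(p, "w") as fh:
            fh.create_dataset("data", data=arr)
    else:
        raise ValidationError(f"unsupported volume format: {p.suffix}")
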