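"""Readers and writers for the image and table formats the toolkit touches.

Rasters: PNG and TIFF, 8- or 16-bit grayscale, scaled to [0, 1] on read.
Volumes: NIfTI (float), with voxel spacing taken from the header. Plain
arrays: ``.npy`` and whitespace-delimited ``.txt``. Tables: CSV/TSV with
``group, n, events`` (contingency) or ``group, n, mean, sd`` (summaries)
columns.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np
import pandas as pd
import tifffile

from .clinical import ContingencyTable2x2, GroupSummary
from .errors import FormatError, InputError, MriToolError
from .grid import ImageGrid

RASTER_EXTS = {".png", ".tif", ".tiff"}
VOLUME_EXTS = {".nii", ".nii.gz"}
ARRAY_EXTS = {".npy", ".txt"}


class IOError_(MriToolError, OSError):
    """File could not be read or written."""


def _suffix(path: Path) -> str:
    name = path.name.lower()
    if name.endswith(".nii.gz"):
        return ".nii.gz"
    return path.suffix.lower()


def read_image(path) -> ImageGrid:
    """Read an image file into an :class:`ImageGrid`.

    Integer rasters are scaled by their bit depth to [0, 1]; NIfTI volumes
    keep their floating intensities and header spacing. Files without
    spacing information default to 1 mm with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise IOError_(f"no such image file: {path}")
    ext = _suffix(path)
    try:
        if ext in VOLUME_EXTS:
            vol = nib.load(str(path))
            values = np.asarray(vol.dataobj, dtype=float)
            spacing = tuple(float(z) for z in vol.header.get_zooms()[:values.ndim])
            return ImageGrid(values=values, spacing=spacing, modality_tag="NIfTI")
        if ext in RASTER_EXTS:
            raw = tifffile.imread(str(path)) if ext != ".png" else iio.imread(path)
        elif ext == ".npy":
            raw = np.load(path)
        elif ext == ".txt":
            raw = np.loadtxt(path)
        else:
            raise FormatError(f"unsupported image extension {ext!r} ({path})")
    except (FormatError, IOError_):
        raise
    except Exception as exc:  # unreadable / truncated file
        raise IOError_(f"failed to read image {path}: {exc}") from exc
    raw = np.asarray(raw)
    if raw.ndim not in (2, 3):
        raise FormatError(f"{path}: expected a 2-D/3-D grayscale image, "
                          f"got shape {raw.shape}")
    if raw.dtype.kind == "u":
        if raw.dtype.itemsize > 2:
            raise FormatError(f"{path}: unsupported bit depth {raw.dtype}")
        values = raw.astype(float) / float(np.iinfo(raw.dtype).max)
    elif raw.dtype.kind in "fi":
        values = raw.astype(float)
    else:
        raise FormatError(f"{path}: unsupported pixel type {raw.dtype}")
    if ext in RASTER_EXTS:
        warnings.warn(f"{path}: no spacing metadata in raster; assuming 1 mm",
                      stacklevel=2)
    return ImageGrid(values=values, modality_tag=ext.lstrip("."))


def write_image(grid: ImageGrid, path, rescale: bool = False) -> None:
    """Write an image; the format is chosen by the extension.

    PNG/TIFF are written 16-bit; values must already lie in [0, 1] unless
    ``rescale`` is set. NIfTI and ``.npy`` are written as floats, lossless.
    """
    path = Path(path)
    if not path.parent.exists():
        raise IOError_(f"parent directory does not exist: {path.parent}")
    ext = _suffix(path)
    values = grid.values
    if ext in RASTER_EXTS:
        if rescale:
            rng = values.max() - values.min()
            values = (values - values.min()) / rng if rng > 0 else values * 0.0
        elif values.max() > 1.0:
            raise InputError(
                f"values exceed 1.0; pass rescale=True to write {ext} ({path})"
            )
        raw = np.round(values * 65535.0).astype(np.uint16)
        if ext == ".png":
            iio.imwrite(path, raw)
        else:
            tifffile.imwrite(str(path), raw)
    elif ext in VOLUME_EXTS:
        affine = np.diag(list(grid.spacing) + [1.0] * (4 - grid.ndim))
        nib.save(nib.Nifti1Image(values.astype(np.float32), affine), str(path))
    elif ext == ".npy":
        np.save(path, values)
    elif ext == ".txt":
        np.savetxt(path, values if grid.ndim == 2 else values.reshape(values.shape[0], -1))
    else:
        raise FormatError(f"unsupported image extension {ext!r} ({path})")


def _read_table(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise IOError_(f"no such table file: {path}")
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep)
    df.columns = [c.strip().lower() for c in df.columns]
    return df


def read_group_summaries(path) -> list[GroupSummary]:
    """Read ``group, n, mean, sd`` rows from a CSV/TSV file."""
    df = _read_table(path)
    required = {"group", "n", "mean", "sd"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: summary table needs columns {sorted(required)}")
    return [GroupSummary(str(r.group), int(r.n), float(r.mean), float(r.sd))
            for r in df.itertuples()]


def read_contingency(path) -> ContingencyTable2x2:
    """Read a two-row ``group, n, events`` CSV/TSV into a 2x2 table."""
    df = _read_table(path)
    required = {"group", "n", "events"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: contingency table needs columns {sorted(required)}")
    if len(df) != 2:
        raise FormatError(f"{path}: expected exactly 2 group rows, got {len(df)}")
    a, b = df.itertuples()
    return ContingencyTable2x2(str(a.group), int(a.events), int(a.n),
                               str(b.group), int(b.events), int(b.n))


def sha256_of(path) -> str:
    import hashlib
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
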