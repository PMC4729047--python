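"""Image loading, intensity normalization and manifest handling.

Images are normalized to [0, 1] by dividing by the bit-depth full-scale
value (255 for 8-bit, 65535 for 16-bit), *not* by per-image min-max.
Global brightness differences between images therefore remain visible to
the feature bank; controlling batch artifacts is the job of the
validation module, not the loader.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RawImage",
    "SampleRecord",
    "load_image",
    "read_manifest",
    "MIN_IMAGE_SIZE",
]

#: Minimum height/width accepted: every feature group is defined from here up.
MIN_IMAGE_SIZE = 8


@dataclass(frozen=True)
class RawImage:
    """A single-channel image with intensities in [0, 1].

    Parameters
    ----------
    pixels
        2-D float array, values in [0, 1].
    channel_id
        Name of the acquisition channel the plane came from.
    sample_id
        Identifier of the biological sample the image belongs to.
    """

    pixels: np.ndarray
    channel_id: str = "ch0"
    sample_id: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2:
            raise ValueError(f"pixels must be 2-D, got shape {px.shape}")
        if px.shape[0] < MIN_IMAGE_SIZE or px.shape[1] < MIN_IMAGE_SIZE:
            raise ValueError(
                f"image {px.shape} smaller than minimum "
                f"{MIN_IMAGE_SIZE}x{MIN_IMAGE_SIZE}"
            )
        if not np.all(np.isfinite(px)):
            raise ValueError("pixels contain non-finite values")
        if px.min() < 0.0 or px.max() > 1.0:
            raise ValueError("pixel values must lie in [0, 1]")
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class SampleRecord:
    """Manifest row: one sample with one image path per channel."""

    sample_id: str
    channel_paths: dict[str, str] = field(default_factory=dict)
    class_label: str | None = None
    batch_id: str = ""

    def __post_init__(self) -> None:
        if not self.channel_paths:
            raise ValueError(f"sample {self.sample_id!r} has no channel paths")
        if not self.batch_id:
            self.batch_id = self.sample_id


def _full_scale(dtype: np.dtype) -> float:
    """Full-scale denominator for a raster dtype."""
    dtype = np.dtype(dtype)
    if dtype == np.uint8:
        return 255.0
    if dtype == np.uint16:
        return 65535.0
    if dtype.kind == "f":
        return 1.0  # already-normalized float rasters pass through
    raise ValueError(f"unsupported raster dtype {dtype}; expected 8- or 16-bit")


def load_image(
    path: str | os.PathLike,
    channel_index: int = 0,
    sample_id: str = "",
    channel_id: str | None = None,
) -> RawImage:
    """Load one plane of a raster image and scale it to [0, 1].

    Multi-plane rasters (multi-page TIFF, RGB/RGBA PNG or JPEG) are
    indexed by ``channel_index``; planes stored on the trailing axis
    (color images) and on the leading axis (image stacks) are both
    handled.

    Raises
    ------
    IOError
        If the file does not exist or cannot be decoded.
    IndexError
        If ``channel_index`` is out of range for the file's plane count.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise IOError(f"image file not found: {path}")
    try:
        if path.lower().endswith((".tif", ".tiff")):
            import tifffile

            arr = tifffile.imread(path)
        else:
            import imageio.v3 as iio

            arr = iio.imread(path)
    except Exception as exc:  # decoder errors are I/O errors to callers
        raise IOError(f"cannot decode image {path}: {exc}") from exc

    arr = np.asarray(arr)
    if arr.ndim == 2:
        planes = arr[None, ...]
    elif arr.ndim == 3:
        # Color rasters carry channels last; stacks carry pages first.
        if arr.shape[-1] in (3, 4) and arr.shape[0] > 4:
            planes = np.moveaxis(arr, -1, 0)
        else:
            planes = arr
    else:
        raise IOError(f"unsupported raster rank {arr.ndim} in {path}")

    if not 0 <= channel_index < planes.shape[0]:
        raise IndexError(
            f"channel_index {channel_index} out of range for "
            f"{planes.shape[0]}-plane image {path}"
        )
    plane = planes[channel_index]
    scaled = plane.astype(np.float64) / _full_scale(plane.dtype)
    return RawImage(
        pixels=np.clip(scaled, 0.0, 1.0),
        channel_id=channel_id or f"ch{channel_index}",
        sample_id=sample_id or os.path.splitext(os.path.basename(path))[0],
    )


def read_manifest(path: str | os.PathLike) -> list[SampleRecord]:
    """Read a sample manifest CSV into records.

    The manifest needs a ``sample_id`` column and at least one
    ``channel_<name>`` path column; ``class`` and ``batch`` columns are
    optional. A missing ``batch`` column defaults each sample's batch to
    its own id (every sample its own acquisition batch).
    """
    df = pd.read_csv(path, dtype=str)
    if "sample_id" not in df.columns:
        raise ValueError("manifest is missing required column 'sample_id'")
    channel_cols = [c for c in df.columns if c.startswith("channel_")]
    if not channel_cols:
        raise ValueError("manifest has no 'channel_<name>' path columns")
    if df["sample_id"].duplicated().any():
        dupes = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample_id values in manifest: {dupes}")

    records = []
    for _, row in df.iterrows():
        paths = {
            c[len("channel_"):]: row[c]
            for c in channel_cols
            if isinstance(row[c], str) and row[c]
        }
        label = row.get("class")
        batch = row.get("batch")
        records.append(
            SampleRecord(
                sample_id=row["sample_id"],
                channel_paths=paths,
                class_label=label if isinstance(label, str) and label else None,
                batch_id=batch if isinstance(batch, str) and batch else "",
            )
        )
    return records
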