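"""Image and table input/output.

All images travel as TIFF; measurements as CSV; configuration and
ground-truth sidecars as YAML/JSON.  Conventions used throughout the
package:

* coordinates are 0-based ``(row, col)`` with the origin at the top left;
* areas are reported in μm² as ``pixel_count * pixel_size_um**2``;
* the default pixel calibration is 0.133 μm/px (so that the 2-pixel
  cluster criterion corresponds to 0.266 μm), overridable everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

#: default lateral calibration, μm per pixel
DEFAULT_PIXEL_SIZE_UM = 0.133


class FieldImageError(ValueError):
    """Raised for malformed multi-channel images or calibration problems."""


@dataclass
class FieldImage:
    """A calibrated multi-channel field.

    Each channel is a 2D image ``(H, W)``, a z-stack ``(Z, H, W)`` or a
    time-lapse ``(T, H, W)``; all channels must share their trailing
    spatial dimensions.
    """

    channels: dict[str, np.ndarray]
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    z_step_um: float | None = None
    frame_interval_s: float | None = None

    def __post_init__(self) -> None:
        if not self.channels:
            raise FieldImageError("FieldImage needs at least one channel")
        if self.pixel_size_um <= 0:
            raise FieldImageError("pixel_size_um must be positive")
        shapes = {c: a.shape[-2:] for c, a in self.channels.items()}
        if len(set(shapes.values())) != 1:
            raise FieldImageError(f"channels disagree on spatial shape: {shapes}")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape[-2:]

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.channels[name]
        except KeyError:
            raise FieldImageError(
                f"no channel {name!r}; have {sorted(self.channels)}"
            ) from None


def max_project(stack: np.ndarray) -> np.ndarray:
    """Maximum-intensity projection of a z-stack along its first axis.

    A single 2D plane is returned unchanged (as a copy).  The projection
    is idempotent on its own output.
    """
    stack = np.asarray(stack)
    if stack.ndim == 2:
        return stack.copy()
    if stack.ndim != 3 or stack.shape[0] < 1:
        raise FieldImageError("max_project expects a (Z, H, W) stack with Z >= 1")
    return stack.max(axis=0)


def write_field(image: FieldImage, path: str | Path) -> Path:
    """Write all channels into one multi-channel TIFF (channel axis first)."""
    path = Path(path)
    arr = np.stack([image.channels[c] for c in image.channels])
    tifffile.imwrite(path, arr, photometric="minisblack")
    return path


def read_field(
    path: str | Path,
    channel_names: Sequence[str],
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
    z_step_um: float | None = None,
    frame_interval_s: float | None = None,
) -> FieldImage:
    """Read a multi-channel TIFF and attach names and calibration.

    ``channel_names`` gives the caller's channel order for the first
    array axis.  A 2D file is accepted when exactly one name is given.
    Integer data are preserved losslessly.
    """
    path = Path(path)
    if not path.exists():
        raise FieldImageError(f"no such file: {path}")
    try:
        arr = tifffile.imread(path)
    except Exception as exc:  # pragma: no cover - depends on tifffile internals
        raise FieldImageError(f"unreadable TIFF {path}: {exc}") from exc
    if arr.ndim == 2:
        arr = arr[None]
    n = arr.shape[0]
    if n != len(channel_names):
        raise FieldImageError(
            f"{path} has {n} channels but {len(channel_names)} names declared"
        )
    channels = {name: arr[i] for i, name in enumerate(channel_names)}
    return FieldImage(
        channels=channels,
        pixel_size_um=pixel_size_um,
        z_step_um=z_step_um,
        frame_interval_s=frame_interval_s,
    )


def write_labels(labels: np.ndarray, path: str | Path) -> Path:
    """Write a label map as an integer TIFF (0 = background)."""
    path = Path(path)
    labels = np.asarray(labels)
    if labels.min() < 0:
        raise FieldImageError("label maps must be non-negative")
    dtype = np.uint16 if labels.max() < 2**16 else np.uint32
    tifffile.imwrite(path, labels.astype(dtype))
    return path


def read_labels(path: str | Path) -> np.ndarray:
    return np.asarray(tifffile.imread(Path(path)))


def read_stack(path: str | Path) -> np.ndarray:
    """Read a plain TIFF stack (z or time series) as an array."""
    path = Path(path)
    if not path.exists():
        raise FieldImageError(f"no such file: {path}")
    try:
        return np.asarray(tifffile.imread(path))
    except Exception as exc:
        raise FieldImageError(f"unreadable TIFF {path}: {exc}") from exc


def write_measurements(
    records: Iterable[Mapping] | pd.DataFrame,
    path: str | Path,
    columns: Sequence[str] | None = None,
) -> Path:
    """Write one row per object to CSV with a stable column order.

    ``columns`` fixes the schema (required to obtain a header-only file
    from an empty record list).  Floats are written with full round-trip
    precision.
    """
    path = Path(path)
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        df = pd.DataFrame(list(records), columns=columns)
    if columns is not None:
        df = df.reindex(columns=list(columns))
    # %.17g guarantees binary round-trip for float64
    df.to_csv(path, index=False, float_format="%.17g")
    return path


def read_measurements(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(path), float_precision="round_trip")
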