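"""Image and table input/output.

Multichannel immunofluorescence images arrive as TIFF files whose three
planes carry BG4 (red), hnRNP H (green) and DAPI (blue) staining.  All
planes are normalized to [0, 1] by the full-scale value of their integer
bit depth, so that one absolute intensity threshold is meaningful across
images.  Densitometry and metadata arrive as CSV tables with fixed
schemas.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile
import yaml

logger = logging.getLogger("quadfoci")


class QuadfociError(Exception):
    """Base class for fatal input errors."""


class ImageFormatError(QuadfociError):
    pass


class SchemaError(QuadfociError):
    pass


class ConfigError(QuadfociError):
    pass


@dataclass(frozen=True)
class ChannelMap:
    """Assignment of stored plane index to semantic channel.

    The channel order is never inferred from the file; the default is the
    conventional red=0, green=1, blue=2 used when the generator writes
    fixtures.
    """

    red: int = 0
    green: int = 1
    blue: int = 2

    def __post_init__(self) -> None:
        if len({self.red, self.green, self.blue}) != 3:
            raise ConfigError("channel map must assign three distinct plane indices")


@dataclass
class MultichannelImage:
    """Three co-registered intensity planes with a physical pixel size.

    Planes are float arrays in [0, 1]; ``pixel_size_um`` is the edge
    length of one pixel in micrometres.
    """

    red: np.ndarray
    green: np.ndarray
    blue: np.ndarray
    pixel_size_um: float
    source_id: str = ""

    def __post_init__(self) -> None:
        if not (self.red.shape == self.green.shape == self.blue.shape):
            raise ImageFormatError(
                f"channel planes differ in shape: {self.red.shape}, "
                f"{self.green.shape}, {self.blue.shape}"
            )
        if self.pixel_size_um <= 0:
            raise ConfigError("pixel_size_um must be > 0")
        for name in ("red", "green", "blue"):
            plane = getattr(self, name)
            if plane.size and (plane.min() < 0 or plane.max() > 1):
                raise ImageFormatError(f"{name} plane not normalized to [0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.red.shape


def normalize_plane(plane: np.ndarray) -> np.ndarray:
    """Scale a raw plane to float in [0, 1].

    Integer planes are divided by the full-scale value of their dtype
    (255 for uint8, 65535 for uint16, ...), not by the observed maximum:
    an absolute threshold presumes a fixed scale.  Float planes already
    in [0, 1] are returned unchanged (idempotence).
    """
    if np.issubdtype(plane.dtype, np.integer):
        info = np.iinfo(plane.dtype)
        if info.min < 0:
            raise ImageFormatError(f"signed integer images unsupported ({plane.dtype})")
        return plane.astype(np.float64) / info.max
    plane = np.asarray(plane, dtype=np.float64)
    if plane.size and (plane.min() < 0 or plane.max() > 1):
        raise ImageFormatError("float image must already lie in [0, 1]")
    return plane


def _extract_planes(arr: np.ndarray) -> list[np.ndarray]:
    if arr.ndim == 2:
        raise ImageFormatError("single-plane image: three channels required")
    if arr.ndim == 3:
        # interleaved RGB(A) page
        if arr.shape[-1] in (3, 4) and arr.shape[0] not in (3, 4):
            return [arr[..., i] for i in range(3)]
        if arr.shape[0] >= 3:
            return [arr[i] for i in range(arr.shape[0])]
    raise ImageFormatError(f"cannot interpret TIFF of shape {arr.shape} as 3 channels")


def load_image(
    path,
    channel_map: ChannelMap | None = None,
    pixel_size_um: float | None = None,
    config: dict | None = None,
    source_id: str | None = None,
) -> MultichannelImage:
    """Read a multichannel TIFF and return normalized planes.

    The pixel size must be supplied directly or through the config key
    ``pixel_size_um``; there is no attempt to parse vendor metadata.
    """
    channel_map = channel_map or ChannelMap()
    if pixel_size_um is None and config is not None:
        pixel_size_um = config.get("pixel_size_um")
    if pixel_size_um is None:
        raise ConfigError(
            "pixel size unknown: pass pixel_size_um or set the "
            "'pixel_size_um' config key"
        )
    try:
        arr = tifffile.imread(str(path))
    except Exception as exc:  # noqa: BLE001 - surface as fatal input error
        raise ImageFormatError(f"{path}: not a readable TIFF ({exc})") from exc
    planes = _extract_planes(np.asarray(arr))
    for name in ("red", "green", "blue"):
        if getattr(channel_map, name) >= len(planes):
            raise ImageFormatError(
                f"{path}: missing {name} channel "
                f"(plane {getattr(channel_map, name)} of {len(planes)})"
            )
    return MultichannelImage(
        red=normalize_plane(planes[channel_map.red]),
        green=normalize_plane(planes[channel_map.green]),
        blue=normalize_plane(planes[channel_map.blue]),
        pixel_size_um=float(pixel_size_um),
        source_id=source_id if source_id is not None else str(path),
    )


def save_image(image: MultichannelImage, path, channel_map: ChannelMap | None = None) -> None:
    """Write the image as a 3-page uint16 TIFF (pages ordered per channel_map)."""
    channel_map = channel_map or ChannelMap()
    pages = [None, None, None]
    for name in ("red", "green", "blue"):
        plane = getattr(image, name)
        pages[getattr(channel_map, name)] = np.round(plane * 65535).astype(np.uint16)
    tifffile.imwrite(str(path), np.stack(pages))


# ---------------------------------------------------------------------------
# CSV table schemas

#: schema name -> (all columns, numeric columns, key columns or None)
SCHEMAS: dict[str, tuple[list[str], list[str], list[str] | None]] = {
    "bands": (
        ["sample", "group", "gene", "replicate", "incl_intensity", "excl_intensity"],
        ["incl_intensity", "excl_intensity"],
        ["sample", "gene", "replicate"],
    ),
    "fractions": (
        ["sample", "group", "replicate", "soluble", "sarkosyl_soluble", "sarkosyl_insoluble"],
        ["soluble", "sarkosyl_soluble", "sarkosyl_insoluble"],
        ["sample", "replicate"],
    ),
    "binding": (
        ["series", "protein_conc_nM", "bound_intensity", "free_intensity"],
        ["protein_conc_nM", "bound_intensity", "free_intensity"],
        None,
    ),
    "cells": (["image_id", "cell_count"], ["cell_count"], ["image_id"]),
    "metadata": (
        ["sample", "group", "disease_duration_months"],
        ["disease_duration_months"],
        ["sample"],
    ),
    "design": (["image_id", "experiment", "line", "group"], [], ["image_id"]),
}


def read_table(path, schema_name: str) -> pd.DataFrame:
    """Read and validate a CSV against a named schema.

    Rows with non-numeric values in numeric columns are reported by their
    CSV line number (header = line 1).  Duplicate key rows are fatal.
    """
    if schema_name not in SCHEMAS:
        raise SchemaError(
            f"unknown schema {schema_name!r}; known: {sorted(SCHEMAS)}"
        )
    columns, numeric, key = SCHEMAS[schema_name]
    df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing} for schema {schema_name!r}")
    for col in numeric:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            lines = ", ".join(str(i + 2) for i in bad[:10])
            raise SchemaError(
                f"{path}: non-numeric value in column {col!r} at CSV line(s) {lines}"
            )
        df[col] = coerced
    if key:
        dup = df.duplicated(subset=key)
        if dup.any():
            first = df.loc[dup.idxmax(), key].tolist()
            raise SchemaError(
                f"{path}: duplicate key {key} rows (e.g. {first})"
            )
    return df


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def load_config(path) -> dict:
    """Load a plain key/value (YAML) configuration file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if cfg is None:
        return {}
    if not isinstance(cfg, dict):
        raise ConfigError(f"{path}: config must be key: value pairs")
    return cfg
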