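"""Calibrated RGB micrograph I/O and study manifests.

Conventions used throughout the package:

* Images are row-major, origin at the top-left corner, 0-based indices.
* Pixel intensities are carried as real numbers (float64) on a 0-255 scale
  regardless of the on-disk bit depth; 16-bit inputs are rescaled by
  255/65535.  Nothing in the analysis path clips intensities — the
  high-pass stage needs signed arithmetic.
* Channels are addressed by *name* ("red", "green", "blue"), never by
  position.  Files are assumed RGB on disk; the stored order is recorded on
  the :class:`Micrograph` so a differently-ordered source can still be
  handled explicitly.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "Micrograph",
    "Manifest",
    "REGION_LABELS",
    "read_micrograph",
    "write_micrograph",
    "load_manifest",
]

logger = logging.getLogger(__name__)

#: Region labels used in the cortical fiber-density studies this package
#: targets (orbitofrontal and medial prefrontal subdivisions); "other" is the
#: catch-all for additional regions.
REGION_LABELS = frozenset(
    {"VO", "LO", "A32d", "A32v", "MO", "M2", "insula", "other"}
)

MANIFEST_REQUIRED_COLUMNS = (
    "path",
    "subject",
    "region",
    "hemisphere",
    "ap_mm",
    "pixel_size_um",
)

_KEY_COLUMNS = ("subject", "region", "hemisphere", "ap_mm")


@dataclass
class Micrograph:
    """A calibrated RGB region-of-interest image plus study metadata.

    Parameters
    ----------
    pixels
        ``(H, W, 3)`` float array of per-channel intensities on the 0-255
        scale, in the order given by ``channel_order``.
    pixel_size_um
        Physical size of one pixel in micrometres (> 0).  The conventional
        ROI is a 300x300 um^2 window sampled at 1320x1320 px, i.e. about
        0.227 um/px, but any calibration is accepted.
    subject_id
        Opaque subject identifier (blind-coded in typical studies).
    region
        One of :data:`REGION_LABELS`.
    hemisphere
        ``"left"`` or ``"right"``.
    ap_mm
        Antero-posterior level of the section, mm from Bregma.
    group_labels
        Mapping of between-subject factor name to level, e.g.
        ``{"group": "CTL"}``.
    """

    pixels: np.ndarray
    pixel_size_um: float
    subject_id: str = "unknown"
    region: str = "other"
    hemisphere: str = "left"
    ap_mm: float = 0.0
    group_labels: Mapping[str, str] = field(default_factory=dict)
    channel_order: tuple[str, str, str] = ("red", "green", "blue")

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError(
                f"micrograph must be H x W x 3, got shape {self.pixels.shape}"
            )
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ValueError("micrograph must have H >= 1 and W >= 1")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("micrograph intensities must be finite")
        if self.pixels.min() < 0 or self.pixels.max() > 255:
            raise ValueError(
                "micrograph intensities must lie within [0, 255]; got range "
                f"[{self.pixels.min():g}, {self.pixels.max():g}]"
            )
        if not (self.pixel_size_um > 0):
            raise ValueError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")
        if self.region not in REGION_LABELS:
            raise ValueError(
                f"unknown region label {self.region!r}; expected one of "
                f"{sorted(REGION_LABELS)}"
            )
        if self.hemisphere not in ("left", "right"):
            raise ValueError(f"hemisphere must be 'left' or 'right', got {self.hemisphere!r}")
        if set(self.channel_order) != {"red", "green", "blue"}:
            raise ValueError(f"channel_order must name red/green/blue, got {self.channel_order}")

    @property
    def shape(self) -> tuple[int, int]:
        """(H, W) of the image."""
        return self.pixels.shape[:2]

    def channel(self, name: str) -> np.ndarray:
        """Return one channel plane by name ('red', 'green' or 'blue')."""
        try:
            idx = self.channel_order.index(name)
        except ValueError:
            raise KeyError(f"no channel named {name!r} in order {self.channel_order}")
        return self.pixels[:, :, idx]

    def with_offset(self, offset: float) -> "Micrograph":
        """Copy of this micrograph with a constant added to every channel."""
        return replace(self, pixels=self.pixels + float(offset))


@dataclass
class Manifest:
    """Validated table of micrograph records for a study.

    ``records`` is a DataFrame with the columns of
    :data:`MANIFEST_REQUIRED_COLUMNS` plus one column per between-subject
    factor; row order is that of the source CSV.  ``factor_columns`` lists
    the between-subject factor columns in file order.
    """

    records: pd.DataFrame
    factor_columns: tuple[str, ...]
    root: Path = field(default_factory=Path)

    def __len__(self) -> int:
        return len(self.records)

    def resolve_path(self, record: Mapping) -> Path:
        p = Path(record["path"])
        return p if p.is_absolute() else self.root / p

    def iter_records(self):
        for _, row in self.records.iterrows():
            yield row


def _rescale_to_255(arr: np.ndarray) -> np.ndarray:
    """Map integer images of any bit depth onto a real-valued 0-255 scale."""
    arr = np.asarray(arr)
    if arr.dtype == np.uint8:
        return arr.astype(np.float64)
    if arr.dtype == np.uint16:
        return arr.astype(np.float64) * (255.0 / 65535.0)
    if np.issubdtype(arr.dtype, np.integer):
        info = np.iinfo(arr.dtype)
        return arr.astype(np.float64) * (255.0 / info.max)
    # float input: assume already on a 0-255 (or 0-1) scale
    arr = arr.astype(np.float64)
    if arr.size and arr.max() <= 1.0:
        return arr * 255.0
    return arr


def read_micrograph(path, meta: Mapping | None = None) -> Micrograph:
    """Read a 3-channel TIFF/PNG as a calibrated :class:`Micrograph`.

    Parameters
    ----------
    path
        Readable 8- or 16-bit RGB image (TIFF or PNG).
    meta
        Manifest record supplying ``subject``/``subject_id``, ``region``,
        ``hemisphere``, ``ap_mm``, ``pixel_size_um`` and any between-factor
        labels; metadata is copied verbatim.

    Raises
    ------
    IOError
        If the file cannot be read.
    ValueError
        If the image does not have exactly 3 channels, or the pixel size is
        not positive.
    """
    path = Path(path)
    try:
        if path.suffix.lower() in (".tif", ".tiff"):
            arr = tifffile.imread(path)
        else:
            arr = iio.imread(path)
    except FileNotFoundError:
        raise IOError(f"cannot read micrograph: file not found: {path}")
    except Exception as exc:  # pragma: no cover - backend specific
        raise IOError(f"cannot read micrograph {path}: {exc}") from exc

    arr = np.asarray(arr)
    if arr.ndim == 3 and arr.shape[2] == 4:  # drop alpha if present
        arr = arr[:, :, :3]
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(
            f"{path}: expected a 3-channel image, got shape {arr.shape}"
        )

    meta = {} if meta is None else dict(meta)
    known = {"path", "subject", "subject_id", "region", "hemisphere", "ap_mm", "pixel_size_um"}
    group_labels = meta.get("group_labels")
    if group_labels is None:
        group_labels = {k: v for k, v in meta.items() if k not in known}
    pixel_size = float(meta.get("pixel_size_um", 300.0 / 1320.0))
    return Micrograph(
        pixels=_rescale_to_255(arr),
        pixel_size_um=pixel_size,
        subject_id=str(meta.get("subject_id", meta.get("subject", "unknown"))),
        region=str(meta.get("region", "other")),
        hemisphere=str(meta.get("hemisphere", "left")),
        ap_mm=float(meta.get("ap_mm", 0.0)),
        group_labels=dict(group_labels),
    )


def write_micrograph(path, img: Micrograph) -> None:
    """Write a micrograph as an 8-bit RGB TIFF (values rounded and clipped).

    Round-trips exactly for images whose intensities are already 8-bit
    integers on the 0-255 scale.
    """
    path = Path(path)
    data = np.clip(np.rint(img.pixels), 0, 255).astype(np.uint8)
    tifffile.imwrite(path, data, photometric="rgb")


def load_manifest(path) -> Manifest:
    """Load and validate a study manifest CSV.

    Required columns: ``path, subject, region, hemisphere, ap_mm,
    pixel_size_um``; every additional column is treated as a
    between-subject factor.  The (subject, region, hemisphere, ap_mm) tuple
    must be unique per row and every referenced image file must exist
    (relative paths resolve against the manifest's directory).
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in MANIFEST_REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest {path} is missing required columns: {missing}")
    if len(df) == 0:
        warnings.warn(f"manifest {path} contains no records", stacklevel=2)

    dup = df.duplicated(subset=list(_KEY_COLUMNS), keep=False)
    if dup.any():
        dupes = df.loc[dup, list(_KEY_COLUMNS)].to_dict("records")
        raise ValueError(
            f"manifest {path} has duplicated (subject, region, hemisphere, ap_mm) keys: {dupes}"
        )
    if (df["pixel_size_um"] <= 0).any():
        raise ValueError(f"manifest {path} has non-positive pixel_size_um entries")

    root = path.parent
    unresolved = [
        str(p) for p in df["path"]
        if not (Path(p) if Path(p).is_absolute() else root / p).exists()
    ]
    if unresolved:
        raise ValueError(f"manifest {path} references missing files: {unresolved}")

    factor_cols = tuple(c for c in df.columns if c not in MANIFEST_REQUIRED_COLUMNS)
    return Manifest(records=df, factor_columns=factor_cols, root=root)
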