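"""Frame input/output and sub-pleural region-of-interest extraction.

A lung-ultrasound exam consists of one still frame per intercostal space,
twelve per patient: each hemithorax is divided into anterior, lateral and
posterior zones, each split into an upper and a lower half.  Frames are 8-bit
grayscale images acquired with a linear probe in transverse orientation, so
the pleural line appears as the dominant bright horizontal reflector near the
top of the image and B-lines as vertical bright bands beneath it.

This module reads/writes frames (PNG/TIFF), parses exam manifests, and
locates the pleural line so the segmentation stage can operate on the
sub-pleural block of the image only.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .errors import DegenerateROIError, InputError, UnsupportedFormatError

#: Closed vocabulary of the 12 standard intercostal regions
#: (zone x half x side).
REGIONS: tuple[str, ...] = tuple(
    f"{zone}_{half}_{side}"
    for zone in ("anterior", "lateral", "posterior")
    for half in ("upper", "lower")
    for side in ("left", "right")
)

#: ITU-R 601 luma weights used to collapse RGB inputs to grayscale.
_LUMA_601 = np.array([0.299, 0.587, 0.114])

#: Minimum number of analyzable rows that must remain below the pleural line.
MIN_ROI_ROWS = 8


@dataclass
class UltrasoundFrame:
    """One grayscale intercostal-space still image plus acquisition metadata."""

    pixels: np.ndarray
    patient_id: str | None = None
    region_id: str | None = None
    source_path: str | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise InputError(f"frame pixels must be 2-D, got shape {px.shape}")
        if px.shape[0] < 32 or px.shape[1] < 32:
            raise InputError(f"frame must be at least 32x32, got {px.shape}")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise InputError("frame intensities must lie in [0, 255]")
            px = px.astype(np.uint8)
        self.pixels = px
        if self.region_id is not None and self.region_id not in REGIONS:
            raise InputError(
                f"unknown region_id {self.region_id!r}; expected one of {REGIONS}"
            )

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class SubPleuralROI:
    """Sub-matrix of a frame strictly below the detected pleural line.

    ``pleural_row`` is in frame coordinates (0-based, row 0 at the skin
    surface); ``pixels`` starts at frame row ``pleural_row + offset``.
    """

    pixels: np.ndarray
    pleural_row: int
    offset: int = 2
    contrast_warning: bool = field(default=False, compare=False)

    @property
    def depth(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


def read_frame(
    path: str | os.PathLike,
    patient_id: str | None = None,
    region_id: str | None = None,
) -> UltrasoundFrame:
    """Read a PNG/TIFF still frame as an 8-bit grayscale :class:`UltrasoundFrame`.

    RGB(A) inputs are collapsed with the ITU-R 601 luma transform; 16-bit
    inputs are linearly rescaled to 0-255 (fixed 65535 -> 255 scale).
    Multi-frame containers are rejected: export stills first.
    """
    path = os.fspath(path)
    try:
        raw = iio.imread(path)
    except Exception as exc:  # imageio raises a zoo of decoder errors
        raise InputError(f"cannot read image {path!r}: {exc}") from exc
    raw = np.asarray(raw)
    if raw.size == 0:
        raise InputError(f"image {path!r} is empty")
    if raw.ndim == 4 or (raw.ndim == 3 and raw.shape[-1] not in (1, 3, 4)):
        raise UnsupportedFormatError(
            f"{path!r} looks like a multi-frame/cine container; "
            "export individual still frames and retry"
        )
    if raw.ndim == 3:
        if raw.shape[-1] == 4:  # drop alpha
            raw = raw[..., :3]
        if raw.shape[-1] == 1:
            raw = raw[..., 0]
        else:
            raw = raw @ _LUMA_601
    if np.issubdtype(raw.dtype, np.floating):
        px = np.clip(np.rint(raw), 0, 255).astype(np.uint8)
    elif raw.dtype == np.uint8:
        px = raw
    elif raw.dtype == np.uint16:
        px = np.rint(raw.astype(np.float64) * (255.0 / 65535.0)).astype(np.uint8)
    else:
        info = np.iinfo(raw.dtype)
        px = np.rint(raw.astype(np.float64) * (255.0 / info.max)).astype(np.uint8)
    return UltrasoundFrame(px, patient_id=patient_id, region_id=region_id, source_path=path)


def write_frame(frame: UltrasoundFrame, path: str | os.PathLike) -> None:
    """Write a frame as an 8-bit grayscale image (format from extension)."""
    iio.imwrite(os.fspath(path), frame.pixels)


def read_manifest(path: str | os.PathLike) -> pd.DataFrame:
    """Read an exam manifest CSV.

    Required columns: ``patient_id``, ``region_id``, ``path``.  Optional:
    ``pleural_row_override`` (blank = automatic pleural-line detection).
    """
    try:
        df = pd.read_csv(path, dtype={"patient_id": str, "region_id": str})
    except Exception as exc:
        raise InputError(f"cannot read manifest {path!r}: {exc}") from exc
    required = {"patient_id", "region_id", "path"}
    missing = required - set(df.columns)
    if missing:
        raise InputError(f"manifest missing columns: {sorted(missing)}")
    if "pleural_row_override" not in df.columns:
        df["pleural_row_override"] = np.nan
    return df


def locate_pleural_line(
    frame: UltrasoundFrame,
    search_fraction: float = 0.4,
    offset: int = 2,
    pleural_row: int | None = None,
) -> SubPleuralROI:
    """Locate the pleural line and extract the sub-pleural ROI.

    The pleural line is taken as the row with maximal mean intensity within
    the top ``search_fraction`` of the frame (ties broken toward the
    shallowest row, anchoring a thick pleural band at its top).  The ROI is
    the block of rows starting at ``pleural_row + offset`` and running to the
    bottom of the frame.  Passing ``pleural_row`` explicitly bypasses
    detection (manual per-frame override).
    """
    if not 0 < search_fraction <= 1:
        raise DegenerateROIError(f"search_fraction must be in (0, 1], got {search_fraction}")
    if offset < 0:
        raise DegenerateROIError(f"offset must be >= 0, got {offset}")
    if pleural_row is None:
        n_search = max(1, int(round(search_fraction * frame.height)))
        row_means = frame.pixels[:n_search].mean(axis=1)
        pleural_row = int(np.argmax(row_means))  # argmax keeps first of ties
    else:
        pleural_row = int(pleural_row)
        if not 0 <= pleural_row < frame.height:
            raise DegenerateROIError(f"pleural_row override {pleural_row} outside frame")
    start = pleural_row + offset
    depth = frame.height - start
    if depth < MIN_ROI_ROWS:
        raise DegenerateROIError(
            f"pleural line at row {pleural_row} leaves only {max(depth, 0)} rows "
            f"(< {MIN_ROI_ROWS}) below the pleura"
        )
    return SubPleuralROI(frame.pixels[start:], pleural_row=pleural_row, offset=offset)
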