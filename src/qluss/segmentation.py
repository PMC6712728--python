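"""QLUSS core: per-frame B-line segmentation of the sub-pleural ROI.

The automatic score measures the percentage of the pleural line affected by
B-lines.  Each still frame passes through a fixed sequence of stages:

1. percentile-clip contrast stretch of the sub-pleural ROI;
2. two-class intensity clustering (exact 1-D 2-means), the brighter cluster
   becoming the "white" foreground;
3. an alternated sequential filter (ASF) of morphological openings and
   closings with vertical (axial) line structuring elements of increasing
   length, which closes small axial gaps inside B-lines and isolates objects
   laterally;
4. a column scan flagging columns whose white fraction over the upper part of
   the ROI reaches a threshold;
5. the per-frame B-line percentage: 100 x flagged columns / total columns.

B-lines are laser-like vertical reverberation artifacts that arise at the
pleural line and extend to the bottom of the screen without fading, which is
why a column-wise white-fraction criterion identifies them.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage

from .errors import ConfigurationError, DegenerateClusteringError
from .frames_io import SubPleuralROI, UltrasoundFrame, locate_pleural_line

__all__ = [
    "SegmentationConfig",
    "BinaryMask",
    "ColumnDetection",
    "FrameResult",
    "ContrastWarning",
    "adjust_contrast",
    "kmeans_binarize",
    "asf_filter",
    "detect_bline_columns",
    "frame_bline_percent",
    "run_pipeline",
]


class ContrastWarning(UserWarning):
    """Raised (as a warning) when the contrast stage meets a constant ROI."""


@dataclass(frozen=True)
class SegmentationConfig:
    """Tunable parameters of the segmentation pipeline.

    ``asf_max_gap`` is the largest axial (vertical) black gap, in pixels,
    that the filter must close inside a B-line; the ASF schedule of odd
    element lengths 3, 5, ..., ``asf_max_gap + 1`` is derived from it unless
    ``asf_lengths`` overrides the schedule explicitly.
    """

    low_percentile: float = 1.0
    high_percentile: float = 99.0
    kmeans_k: int = 2
    asf_max_gap: int = 10
    asf_lengths: tuple[int, ...] | None = None
    white_fraction_threshold: float = 0.50
    depth_fraction: float = 0.70
    search_fraction: float = 0.4
    roi_offset: int = 2
    random_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.low_percentile < self.high_percentile <= 100:
            raise ConfigurationError(
                f"need 0 <= low < high <= 100 percentiles, got "
                f"({self.low_percentile}, {self.high_percentile})"
            )
        if self.kmeans_k != 2:
            raise ConfigurationError("the binarization stage is defined for k = 2 only")
        if not 0 < self.white_fraction_threshold <= 1:
            raise ConfigurationError("white_fraction_threshold must be in (0, 1]")
        if not 0 < self.depth_fraction <= 1:
            raise ConfigurationError("depth_fraction must be in (0, 1]")
        if self.asf_max_gap < 1:
            raise ConfigurationError("asf_max_gap must be >= 1")
        if self.asf_lengths is not None:
            object.__setattr__(self, "asf_lengths", tuple(int(n) for n in self.asf_lengths))
            if any(n < 1 or n % 2 == 0 for n in self.asf_lengths):
                raise ConfigurationError("asf_lengths must be odd positive integers")

    @property
    def schedule(self) -> tuple[int, ...]:
        """ASF element lengths, smallest to largest."""
        if self.asf_lengths is not None:
            return self.asf_lengths
        top = self.asf_max_gap + 1 if self.asf_max_gap % 2 == 0 else self.asf_max_gap + 2
        return tuple(range(3, top + 1, 2))

    def digest(self) -> str:
        """Short stable hash of the configuration (for provenance)."""
        payload = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class BinaryMask:
    """Boolean foreground mask, same shape as its source ROI."""

    pixels: np.ndarray
    stage: str  # "kmeans" | "asf"

    def __post_init__(self) -> None:
        if self.stage not in ("kmeans", "asf"):
            raise ConfigurationError(f"unknown mask stage {self.stage!r}")
        self.pixels = np.asarray(self.pixels, dtype=bool)


@dataclass
class ColumnDetection:
    """Per-column white fraction and B-line decision."""

    white_fraction: np.ndarray
    is_bline: np.ndarray

    @property
    def n_columns(self) -> int:
        return self.white_fraction.shape[0]


@dataclass
class FrameResult:
    """Per-frame B-line percentage with provenance."""

    bline_percent: float
    patient_id: str | None = None
    region_id: str | None = None
    config_digest: str | None = None
    n_columns: int | None = None
    n_flagged: int | None = None
    intermediates: dict = field(default_factory=dict, repr=False, compare=False)


def adjust_contrast(roi: SubPleuralROI, config: SegmentationConfig) -> SubPleuralROI:
    """Percentile-clip linear contrast stretch of the ROI.

    Intensities at/below the ``low_percentile`` value map to 0, at/above the
    ``high_percentile`` value to 255, linearly in between.  A constant ROI is
    returned unchanged with :class:`ContrastWarning` and the ROI's
    ``contrast_warning`` flag set — never a divide-by-zero.
    """
    px = roi.pixels
    lo, hi = np.percentile(px, [config.low_percentile, config.high_percentile])
    if hi <= lo:
        warnings.warn(
            "ROI has zero dynamic range at the configured percentiles; "
            "contrast left unchanged",
            ContrastWarning,
            stacklevel=2,
        )
        return SubPleuralROI(px.copy(), roi.pleural_row, roi.offset, contrast_warning=True)
    stretched = (px.astype(np.float64) - lo) * (255.0 / (hi - lo))
    out = np.clip(np.rint(stretched), 0, 255).astype(np.uint8)
    return SubPleuralROI(out, roi.pleural_row, roi.offset)


def _best_threshold(values: np.ndarray, counts: np.ndarray) -> int:
    """Exact 1-D 2-means on a weighted histogram.

    Returns the cut value c such that the partition {v <= c} | {v > c}
    minimizes the total within-cluster sum of squares.  For k = 2 in one
    dimension the optimal clustering is always an interval split of the
    sorted values, so scanning the distinct-value cuts is exact (no
    iterative/randomized clustering is needed, keeping the stage fully
    deterministic).  Ties favor the smallest cut value.
    """
    v = values.astype(np.float64)
    c = counts.astype(np.float64)
    cw = np.cumsum(c)
    csum = np.cumsum(c * v)
    csq = np.cumsum(c * v * v)
    n_tot, s_tot, q_tot = cw[-1], csum[-1], csq[-1]
    # within-SS of a group = sum v^2 - (sum v)^2 / n; evaluate all cuts at once
    left_ss = csq[:-1] - csum[:-1] ** 2 / cw[:-1]
    nr = n_tot - cw[:-1]
    right_ss = (q_tot - csq[:-1]) - (s_tot - csum[:-1]) ** 2 / nr
    total = left_ss + right_ss
    return int(values[np.argmin(total)])


def kmeans_binarize(roi: SubPleuralROI, config: SegmentationConfig) -> BinaryMask:
    """Split ROI pixels into two intensity classes; brighter class is white.

    One-dimensional 2-means clustering on intensity: the returned partition
    is the global minimizer of the within-cluster sum of squares (solved
    exactly on the intensity histogram), equivalent to a single intensity
    threshold.  The cluster with the higher centroid is the foreground.
    """
    values, counts = np.unique(roi.pixels, return_counts=True)
    if values.size < 2:
        raise DegenerateClusteringError(
            "ROI has a single intensity value; two-class clustering is undefined "
            "(check the contrast-adjustment stage)"
        )
    cut = _best_threshold(values, counts)
    return BinaryMask(roi.pixels > cut, stage="kmeans")


def _open_close(mask: np.ndarray, length: int) -> np.ndarray:
    """One ASF stage: opening then closing with a vertical line element.

    Out-of-image positions are ignored during erosion (treated as
    foreground) and treated as background during dilation, so the filter
    introduces no border artifacts: a full-height white column is a fixed
    point of every stage.
    """
    se = np.ones((length, 1), dtype=bool)
    opened = ndimage.binary_dilation(
        ndimage.binary_erosion(mask, se, border_value=1), se, border_value=0
    )
    closed = ndimage.binary_erosion(
        ndimage.binary_dilation(opened, se, border_value=0), se, border_value=1
    )
    return closed


def asf_filter(mask: BinaryMask, config: SegmentationConfig) -> BinaryMask:
    """Alternated sequential filter with axial line structuring elements.

    Applies opening-then-closing with vertical elements of odd lengths taken
    from ``config.schedule`` (default 3, 5, 7, 9, 11).  The terminal closing
    (length L) fills axial gaps of up to L - 1 pixels inside a column
    (default: 10-pixel gaps); the openings remove white runs shorter than the
    element and sever 1-pixel-tall horizontal bridges, isolating objects
    laterally.  Total on boolean matrices — never raises.
    """
    out = np.asarray(mask.pixels, dtype=bool)
    for length in config.schedule:
        out = _open_close(out, length)
    return BinaryMask(out, stage="asf")


def detect_bline_columns(mask: BinaryMask, config: SegmentationConfig) -> ColumnDetection:
    """Column scan: flag columns mostly white over the upper ROI depth window.

    For each column the white fraction is evaluated over the uppermost
    ``ceil(depth_fraction * depth)`` rows (B-lines arise at the pleura and
    may attenuate at depth); a column is a B-line when the fraction reaches
    ``white_fraction_threshold`` (inclusive).  Both numbers come from the
    configuration, never hard-coded.
    """
    depth = mask.pixels.shape[0]
    window = int(np.ceil(config.depth_fraction * depth))
    if window < 1:
        raise ConfigurationError(
            f"depth window of {window} rows (depth_fraction={config.depth_fraction}, "
            f"depth={depth}); nothing to scan"
        )
    white_fraction = mask.pixels[:window].mean(axis=0)
    is_bline = white_fraction >= config.white_fraction_threshold
    return ColumnDetection(white_fraction=white_fraction, is_bline=is_bline)


def frame_bline_percent(
    det: ColumnDetection,
    patient_id: str | None = None,
    region_id: str | None = None,
    config_digest: str | None = None,
) -> FrameResult:
    """Per-frame B-line percentage: 100 x flagged columns / total columns.

    Carried at full precision; rounding to two decimals happens only at
    serialization time.
    """
    n = det.n_columns
    if n < 1:
        raise ConfigurationError("column detection carries no columns")
    flagged = int(det.is_bline.sum())
    return FrameResult(
        bline_percent=100.0 * flagged / n,
        patient_id=patient_id,
        region_id=region_id,
        config_digest=config_digest,
        n_columns=n,
        n_flagged=flagged,
    )


def run_pipeline(
    frame: UltrasoundFrame,
    config: SegmentationConfig | None = None,
    pleural_row: int | None = None,
    keep_intermediates: bool = False,
) -> FrameResult:
    """Full per-frame pipeline: ROI -> contrast -> 2-means -> ASF -> column scan.

    ``pleural_row`` overrides automatic pleural-line detection.  With
    ``keep_intermediates`` the result carries the ROI, both masks and the
    column detection (the four panels of the debugging view).
    """
    config = config or SegmentationConfig()
    stage = "pleural-line"
    try:
        roi = locate_pleural_line(
            frame,
            search_fraction=config.search_fraction,
            offset=config.roi_offset,
            pleural_row=pleural_row,
        )
        stage = "contrast"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ContrastWarning)
            adj = adjust_contrast(roi, config)
        if adj.contrast_warning:
            # constant ROI: no intra-ROI contrast to cluster.  Classify the
            # constant against a frame-level 2-means cut instead: a uniformly
            # dark field carries no B-lines (0%), a uniformly bright one is
            # full-width coalescence (100%)
            values, counts = np.unique(frame.pixels, return_counts=True)
            if values.size >= 2:
                white = bool(roi.pixels.flat[0] > _best_threshold(values, counts))
            else:
                white = False
            full = np.full(adj.pixels.shape, white, dtype=bool)
            km = BinaryMask(full, stage="kmeans")
            filtered = BinaryMask(full.copy(), stage="asf")
            det = detect_bline_columns(filtered, config)
        else:
            stage = "kmeans"
            km = kmeans_binarize(adj, config)
            stage = "asf"
            filtered = asf_filter(km, config)
            stage = "column-scan"
            det = detect_bline_columns(filtered, config)
    except Exception as exc:
        exc.add_note(f"segmentation stage: {stage}")
        raise
    result = frame_bline_percent(
        det,
        patient_id=frame.patient_id,
        region_id=frame.region_id,
        config_digest=config.digest(),
    )
    if keep_intermediates:
        result.intermediates = {
            "roi": roi,
            "contrast": adj,
            "kmeans": km,
            "asf": filtered,
            "columns": det,
        }
    return result
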