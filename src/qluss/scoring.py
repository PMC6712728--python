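"""Semi-quantitative lung-ultrasound scores and patient-level aggregation.

Four scores are computed from a clinician's categorical reading of each of
the 12 intercostal regions; the fifth (the automatic B-line percentage) is
aggregated from the per-frame segmentation output:

- ``nLUSS``   — total number of B-lines over the exam, fused B-lines counted
  as one;
- ``%LUSS``   — per region, the visual percentage of the rib space filled
  with confluent B-lines divided by 10, plus any discrete B-lines seen at
  the same time; a white-lung region counts as 10; summed over regions;
- ``cLUSS``   — regional aeration-loss grade 0-3 (0: A-lines or < 2
  B-lines; 1: spaced B-lines; 2: coalescent B-lines; 3: tissue-like
  pattern), summed over regions;
- ``qLUSS``   — as cLUSS, except coalescent regions grade 1 when confluent
  B-lines occupy <= 50% of the intercostal space and 2 when > 50%;
- ``QLUSS``   — intra-patient mean of the per-frame B-line percentages.

Grading the boundary case of exactly 2 B-lines: the 0-3 scale anchors grade
0 at "< 2 B-lines" and grade 1 at ">= 3 spaced B-lines", leaving 2 B-lines
unstated; this module grades 2 spaced B-lines as 1 (aeration loss present).
The choice is isolated in :func:`cluss_region_grade` so the alternative is a
one-line change.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import IncompleteExamError, InconsistentAnnotationError, InputError
from .frames_io import REGIONS
from .segmentation import FrameResult

#: Closed vocabulary of regional patterns.
PATTERNS = ("a_lines", "spaced_blines", "coalescent", "tissue_like", "white_lung")

#: Patterns that may carry a non-zero confluent percentage.
_CONFLUENT_PATTERNS = ("coalescent", "white_lung")


@dataclass(frozen=True)
class RegionAnnotation:
    """A clinician's categorical reading of one intercostal space.

    ``bline_count`` counts every B-line with fused B-lines counted as a
    single one; ``confluent_percent`` is the visual percentage of the rib
    space filled with confluent B-lines; ``discrete_extra_blines`` counts
    additional non-confluent B-lines seen at the same time (for a purely
    spaced pattern it equals ``bline_count``).
    """

    patient_id: str
    region_id: str
    pattern: str
    bline_count: int = 0
    confluent_percent: float = 0.0
    discrete_extra_blines: int = 0

    def __post_init__(self) -> None:
        if self.pattern not in PATTERNS:
            raise InconsistentAnnotationError(
                f"unknown pattern {self.pattern!r}; expected one of {PATTERNS}"
            )
        if self.region_id not in REGIONS:
            raise InputError(f"unknown region_id {self.region_id!r}")
        if self.bline_count < 0 or self.discrete_extra_blines < 0:
            raise InconsistentAnnotationError("B-line counts cannot be negative")
        if not 0 <= self.confluent_percent <= 100:
            raise InconsistentAnnotationError("confluent_percent must be in [0, 100]")
        if self.confluent_percent > 0 and self.pattern not in _CONFLUENT_PATTERNS:
            raise InconsistentAnnotationError(
                f"pattern {self.pattern!r} cannot carry confluent_percent > 0"
            )
        if self.pattern == "white_lung" and self.confluent_percent != 100:
            raise InconsistentAnnotationError("white_lung implies confluent_percent = 100")
        if self.pattern == "a_lines" and self.bline_count > 1:
            raise InconsistentAnnotationError("a_lines pattern implies fewer than 2 B-lines")


def _check_complete(
    annotations: Iterable, regions: Sequence[str] = REGIONS
) -> dict[str, object]:
    """Map region_id -> item, requiring exactly one item per region."""
    by_region: dict[str, object] = {}
    for ann in annotations:
        rid = ann.region_id
        if rid in by_region:
            raise IncompleteExamError(f"duplicate annotation for region {rid!r}")
        by_region[rid] = ann
    missing = [r for r in regions if r not in by_region]
    if missing:
        raise IncompleteExamError(f"exam incomplete; missing regions: {missing}")
    return by_region


def score_nluss(
    annotations: Iterable[RegionAnnotation], regions: Sequence[str] = REGIONS
) -> int:
    """Total B-line count over the exam (fused B-lines count as one)."""
    by_region = _check_complete(annotations, regions)
    return int(sum(ann.bline_count for ann in by_region.values()))


def percent_luss_region(ann: RegionAnnotation) -> float:
    """%LUSS contribution of one region.

    Confluent percentage / 10 plus discrete B-lines; white lung fixed at 10.
    """
    if ann.pattern == "white_lung":
        return 10.0
    return ann.confluent_percent / 10.0 + ann.discrete_extra_blines


def score_percent_luss(
    annotations: Iterable[RegionAnnotation], regions: Sequence[str] = REGIONS
) -> float:
    """%LUSS: summed per-region B-line-equivalents."""
    by_region = _check_complete(annotations, regions)
    return float(sum(percent_luss_region(a) for a in by_region.values()))


def cluss_region_grade(ann: RegionAnnotation) -> int:
    """cLUSS aeration-loss grade (0-3) of one region.

    White lung grades as coalescent (2).  Exactly 2 spaced B-lines grades 1
    (see the module docstring); change the ``>= 2`` below to ``>= 3`` for the
    stricter alternative.
    """
    if ann.pattern == "tissue_like":
        return 3
    if ann.pattern in _CONFLUENT_PATTERNS:
        return 2
    if ann.pattern == "spaced_blines" and ann.bline_count >= 2:
        return 1
    return 0  # a_lines, or fewer than 2 B-lines


def score_cluss(
    annotations: Iterable[RegionAnnotation], regions: Sequence[str] = REGIONS
) -> int:
    """cLUSS: summed 0-3 aeration-loss grades."""
    by_region = _check_complete(annotations, regions)
    return int(sum(cluss_region_grade(a) for a in by_region.values()))


def qluss_region_grade(ann: RegionAnnotation) -> int:
    """qLUSS grade of one region.

    Identical to the cLUSS grade except coalescent regions: grade 1 when
    confluent B-lines occupy <= 50% of the space, 2 when > 50% (white lung,
    at 100%, grades 2).  Non-coalescent grades are inherited from cLUSS.
    """
    if ann.pattern == "coalescent":
        return 1 if ann.confluent_percent <= 50 else 2
    return cluss_region_grade(ann)


def score_qluss_semiquant(
    annotations: Iterable[RegionAnnotation], regions: Sequence[str] = REGIONS
) -> int:
    """qLUSS: cLUSS with the coalescence grade split at 50% involvement."""
    by_region = _check_complete(annotations, regions)
    return int(sum(qluss_region_grade(a) for a in by_region.values()))


def aggregate_qluss(
    frame_results: Iterable[FrameResult],
    regions: Sequence[str] = REGIONS,
    annotations: Iterable[RegionAnnotation] | None = None,
) -> tuple[float, bool]:
    """Patient-level QLUSS: mean per-frame B-line percentage over the exam.

    Returns ``(qluss_percent, reliability_warning)``; the warning is set when
    any region is annotated tissue-like (consolidated lung is outside the
    automatic score's validity, but its frames are still included).
    """
    by_region = _check_complete(frame_results, regions)
    mean = float(np.mean([fr.bline_percent for fr in by_region.values()]))
    warn = False
    if annotations is not None:
        warn = any(a.pattern == "tissue_like" for a in annotations)
    return mean, warn


@dataclass
class ScorePanel:
    """The five lung-ultrasound scores for one patient, plus EVLW when known."""

    patient_id: str
    nLUSS: int
    percent_LUSS: float
    cLUSS: int
    qLUSS: int
    QLUSS: float | None = None
    EVLW: float | None = None
    qluss_reliability_warning: bool = False

    def __post_init__(self) -> None:
        if self.qLUSS > self.cLUSS:
            raise InconsistentAnnotationError(
                f"qLUSS ({self.qLUSS}) cannot exceed cLUSS ({self.cLUSS})"
            )


def build_score_panel(
    annotations: Sequence[RegionAnnotation],
    frame_results: Sequence[FrameResult] | None = None,
    evlw: float | None = None,
    regions: Sequence[str] = REGIONS,
) -> ScorePanel:
    """Compute all scores for one patient from annotations (+ segmentation)."""
    by_region = _check_complete(annotations, regions)
    patient_ids = {a.patient_id for a in by_region.values()}
    if len(patient_ids) != 1:
        raise InputError(f"annotations span multiple patients: {sorted(patient_ids)}")
    qluss = warn = None
    if frame_results is not None:
        qluss, warn = aggregate_qluss(frame_results, regions, annotations)
    return ScorePanel(
        patient_id=patient_ids.pop(),
        nLUSS=score_nluss(annotations, regions),
        percent_LUSS=score_percent_luss(annotations, regions),
        cLUSS=score_cluss(annotations, regions),
        qLUSS=score_qluss_semiquant(annotations, regions),
        QLUSS=qluss,
        EVLW=evlw,
        qluss_reliability_warning=bool(warn),
    )


def read_annotations(path) -> list[RegionAnnotation]:
    """Read a region-annotation CSV.

    Columns: patient_id, region_id, pattern, bline_count, confluent_percent,
    discrete_extra_blines.
    """
    df = pd.read_csv(path, dtype={"patient_id": str, "region_id": str})
    required = {
        "patient_id", "region_id", "pattern",
        "bline_count", "confluent_percent", "discrete_extra_blines",
    }
    missing = required - set(df.columns)
    if missing:
        raise InputError(f"annotation file missing columns: {sorted(missing)}")
    return [
        RegionAnnotation(
            patient_id=row.patient_id,
            region_id=row.region_id,
            pattern=row.pattern,
            bline_count=int(row.bline_count),
            confluent_percent=float(row.confluent_percent),
            discrete_extra_blines=int(row.discrete_extra_blines),
        )
        for row in df.itertuples()
    ]


def panels_to_frame(panels: Sequence[ScorePanel]) -> pd.DataFrame:
    """Score panels as a table mirroring the per-patient score/EVLW layout.

    Percentages are rounded half-up to 2 decimals at this serialization
    boundary only; in-memory values stay at full precision.
    """
    from decimal import Decimal, ROUND_HALF_UP

    def r2(x):
        if x is None:
            return None
        return float(Decimal(repr(float(x))).quantize(Decimal("0.01"), ROUND_HALF_UP))

    return pd.DataFrame(
        {
            "Patients": [p.patient_id for p in panels],
            "QLUSS": [r2(p.QLUSS) for p in panels],
            "qLUSS": [p.qLUSS for p in panels],
            "%LUSS": [r2(p.percent_LUSS) for p in panels],
            "cLUSS": [p.cLUSS for p in panels],
            "nLUSS": [p.nLUSS for p in panels],
            "EVLW": [p.EVLW for p in panels],
        }
    )
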