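"""Synthetic ultrasound-like phantoms with known B-line ground truth.

A phantom frame emulates the geometry the segmentation pipeline relies on: a
bright horizontal pleural line near the top of the image, and vertical
hyperechoic bands (B-lines) that arise at the pleural line and extend toward
the bottom of the screen without fading, over a darker background.  Speckle
is modeled as multiplicative log-normal noise — a simple, standard stand-in
for ultrasound speckle texture; no field propagation or scan conversion is
simulated.  Overlapping or adjacent bands merge into one coalescent truth
interval, exercising the detector's behavior on merged B-lines.

The module also simulates subjects x raters score tables from a two-way
random-effects model, giving a closed-form target ICC for agreement tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .errors import ConfigurationError
from .frames_io import UltrasoundFrame
from .stats import RaterTable


@dataclass(frozen=True)
class Band:
    """One vertical B-line band: column interval, brightness, penetration."""

    center_column: int
    width_px: int
    intensity: int = 190
    depth_fraction: float = 1.0

    def columns(self) -> tuple[int, int]:
        """Half-open column interval [start, stop) covered by the band."""
        start = self.center_column - self.width_px // 2
        return start, start + self.width_px


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of a synthetic frame.

    ``gap_spec`` lists axial dropouts carved inside every band as
    ``(row_start, gap_height)`` in frame coordinates; ``speckle_sigma`` is
    the log-scale of the multiplicative noise (0 = noiseless).
    """

    height: int = 256
    width: int = 256
    pleural_row: int = 30
    bands: tuple[Band, ...] = ()
    background_intensity: int = 40
    pleural_intensity: int = 250
    speckle_sigma: float = 0.0
    gap_spec: tuple[tuple[int, int], ...] = ()
    lateral_blur_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height < 32 or self.width < 32:
            raise ConfigurationError("phantom must be at least 32x32")
        if not 0 <= self.pleural_row < self.height:
            raise ConfigurationError("pleural_row outside the frame")
        if self.speckle_sigma < 0:
            raise ConfigurationError("speckle_sigma must be >= 0")
        for band in self.bands:
            lo, hi = band.columns()
            if lo < 0 or hi > self.width or band.width_px < 1:
                raise ConfigurationError(f"band {band} does not lie inside the frame")
            if band.intensity <= self.background_intensity:
                raise ConfigurationError("band intensity must exceed the background")
            if not 0 < band.depth_fraction <= 1:
                raise ConfigurationError("band depth_fraction must be in (0, 1]")


@dataclass
class PhantomTruth:
    """Ground-truth column mask and B-line percentage of a phantom."""

    column_mask: np.ndarray
    true_bline_percent: float = field(init=False)

    def __post_init__(self) -> None:
        self.column_mask = np.asarray(self.column_mask, dtype=bool)
        self.true_bline_percent = 100.0 * self.column_mask.sum() / self.column_mask.size


def generate_frame(
    spec: PhantomSpec,
    patient_id: str | None = None,
    region_id: str | None = None,
) -> tuple[UltrasoundFrame, PhantomTruth]:
    """Render a phantom frame and its ground truth.

    Deterministic given (spec, spec.seed); the truth is computed before
    noise, so speckle never alters it.  Overlapping bands contribute the
    union of their columns to the truth (coalescence), never an error.
    """
    img = np.full((spec.height, spec.width), float(spec.background_intensity))
    column_mask = np.zeros(spec.width, dtype=bool)
    for band in spec.bands:
        lo, hi = band.columns()
        bottom = int(round(band.depth_fraction * spec.height))
        img[spec.pleural_row : bottom, lo:hi] = band.intensity
        column_mask[lo:hi] = True
        for row_start, gap_height in spec.gap_spec:
            r0 = max(row_start, spec.pleural_row)
            img[r0 : row_start + gap_height, lo:hi] = spec.background_intensity
    img[spec.pleural_row, :] = spec.pleural_intensity
    if spec.lateral_blur_sigma > 0:
        img = ndimage.gaussian_filter1d(img, spec.lateral_blur_sigma, axis=1)
    if spec.speckle_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        img = img * np.exp(rng.normal(0.0, spec.speckle_sigma, img.shape))
    pixels = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    frame = UltrasoundFrame(pixels, patient_id=patient_id, region_id=region_id)
    return frame, PhantomTruth(column_mask)


def random_spec(
    rng: np.random.Generator,
    height: int = 128,
    width: int = 128,
    max_bands: int = 4,
    speckle_sigma: float = 0.0,
) -> PhantomSpec:
    """Draw a random, always-valid phantom spec (for property tests)."""
    pleural_row = int(rng.integers(5, height // 3))
    n_bands = int(rng.integers(0, max_bands + 1))
    bands = []
    for _ in range(n_bands):
        w = int(rng.integers(6, max(7, width // 6)))
        center = int(rng.integers(w // 2 + 1, width - (w - w // 2) - 1))
        bands.append(Band(center_column=center, width_px=w))
    return PhantomSpec(
        height=height,
        width=width,
        pleural_row=pleural_row,
        bands=tuple(bands),
        speckle_sigma=speckle_sigma,
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def generate_exam(
    base_spec: PhantomSpec, seed: int = 0, patient_id: str = "phantom"
) -> list[tuple[UltrasoundFrame, PhantomTruth]]:
    """Render one phantom frame per standard intercostal region (12 frames).

    Each region reuses ``base_spec`` with a region-specific sub-seed so the
    exam is reproducible from (base_spec, seed).
    """
    from .frames_io import REGIONS

    out = []
    for i, region in enumerate(REGIONS):
        spec = replace(base_spec, seed=(seed * 1009 + i) % (2**31 - 1))
        out.append(generate_frame(spec, patient_id=patient_id, region_id=region))
    return out


def generate_rater_table(
    n_subjects: int,
    variance_components: tuple[float, float, float],
    n_raters: int = 2,
    mu: float = 10.0,
    seed: int = 0,
) -> RaterTable:
    """Simulate a subjects x raters table from a two-way random-effects model.

    score(i, j) = mu + subject_i + rater_j + error_ij with independent normal
    components of variances ``(sigma2_subject, sigma2_rater, sigma2_error)``.
    The theoretical absolute-agreement ICC,
    sigma2_subject / (sigma2_subject + sigma2_rater + sigma2_error),
    is attached to the returned table.
    """
    s2_subj, s2_rater, s2_err = variance_components
    if min(s2_subj, s2_rater, s2_err) < 0:
        raise ConfigurationError("variance components must be >= 0")
    if n_subjects < 5:
        raise ConfigurationError("need at least 5 subjects")
    rng = np.random.default_rng(seed)
    subj = rng.normal(0.0, np.sqrt(s2_subj), size=(n_subjects, 1))
    rater = rng.normal(0.0, np.sqrt(s2_rater), size=(1, n_raters))
    err = rng.normal(0.0, np.sqrt(s2_err), size=(n_subjects, n_raters))
    total = s2_subj + s2_rater + s2_err
    true_icc = s2_subj / total if total > 0 else 1.0
    return RaterTable(
        scores=mu + subj + rater + err,
        rater_names=tuple(f"rater_{j + 1}" for j in range(n_raters)),
        true_icc=float(true_icc),
    )
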