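"""Planar gamma-scintigraphy ROI quantification.

Correction chain for static planar count images of a 99mTc-labeled aerosol:
9-point smoothing, background subtraction, physical-decay correction to a
common reference time, and per-region tissue attenuation correction derived
from calibration acquisitions of known activity.  The output is a corrected
activity-equivalent count per region of interest (extrathoracic ET, thoracic
TH, optionally STOMACH) with a relative-accuracy estimate.

Decay and attenuation corrections are both multiplicative, so their order is
immaterial; the pipeline applies background subtraction first because the
background estimate is made on the raw (smoothed) image.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "TC99M_HALF_LIFE_S",
    "PlanarImage",
    "ROIMask",
    "CorrectionSet",
    "RegionalCounts",
    "smooth_9point",
    "subtract_background",
    "decay_correct",
    "attenuation_factor_from_calibration",
    "quantify_regions",
]

#: physical half-life of 99mTc in seconds (6.0067 h)
TC99M_HALF_LIFE_S: float = 6.0067 * 3600.0

ROI_LABELS = ("ET", "TH", "BACKGROUND", "CALIBRATION", "STOMACH")
#: labels quantified as deposition regions (BACKGROUND and CALIBRATION are
#: service ROIs; STOMACH is reported when present but excluded from the
#: ET/TH balance downstream)
REGION_LABELS = ("ET", "TH", "STOMACH")


@dataclass
class PlanarImage:
    """A 2-D planar count image with acquisition metadata.

    ``counts`` holds nonnegative per-pixel counts (integer for raw camera
    output, float after smoothing).  ``acquisition_start`` is the offset in
    seconds of the acquisition relative to the run reference time; ``view``
    (anterior/posterior) is metadata only and never enters the algorithm.
    """

    counts: np.ndarray
    acquisition_seconds: float
    acquisition_start: float = 0.0
    view: str = "posterior"

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 2:
            raise ValueError("counts must be a 2-D matrix")
        if np.any(c < 0):
            raise ValueError("counts must be nonnegative")
        if self.acquisition_seconds <= 0:
            raise ValueError("acquisition_seconds must be > 0")
        self.counts = c


@dataclass
class ROIMask:
    """A labeled boolean region-of-interest mask congruent with the image."""

    label: str
    mask: np.ndarray

    def __post_init__(self) -> None:
        if self.label not in ROI_LABELS:
            raise ValueError(f"unknown ROI label {self.label!r}; one of {ROI_LABELS}")
        m = np.asarray(self.mask, dtype=bool)
        if m.ndim != 2:
            raise ValueError("mask must be 2-D")
        if not m.any():
            raise ValueError(f"{self.label} mask is empty")
        self.mask = m

    @property
    def area(self) -> int:
        return int(self.mask.sum())


@dataclass
class CorrectionSet:
    """Correction parameters applied to one acquisition.

    ``attenuation_factor`` maps region label to the multiplicative tissue
    attenuation correction (>= 1 expected); missing labels default to 1.
    ``background_rate`` (counts/pixel/s) overrides estimation from a
    BACKGROUND mask when set.  ``attenuation_rel_unc`` is the relative
    uncertainty of the attenuation factors, folded into the reported
    relative accuracy.
    """

    half_life_seconds: float = TC99M_HALF_LIFE_S
    reference_time: float = 0.0
    attenuation_factor: dict[str, float] = field(default_factory=dict)
    background_rate: float | None = None
    attenuation_rel_unc: float = 0.0

    def __post_init__(self) -> None:
        if self.half_life_seconds <= 0:
            raise ValueError("half_life_seconds must be > 0")
        for label, f in self.attenuation_factor.items():
            if f <= 0:
                raise ValueError(f"attenuation factor for {label} must be > 0")
            if f < 1:
                warnings.warn(
                    f"attenuation factor {f:.3f} < 1 for {label}: accepted, "
                    "but calibration should be checked",
                    stacklevel=2,
                )


@dataclass
class RegionalCounts:
    """Quantification result for one region."""

    region: str
    raw: float
    net: float
    corrected: float
    relative_accuracy: float


def smooth_9point(img: PlanarImage, kernel: np.ndarray | None = None) -> PlanarImage:
    """Smooth with a 9-point (3x3) convolution mask.

    Default kernel is the uniform 3x3 mean; any 3x3 kernel may be supplied
    and is normalized to unit sum.  Borders are handled by reflection, which
    preserves the global sum exactly on constant images.
    """
    c = img.counts
    if c.shape[0] < 3 or c.shape[1] < 3:
        raise ValueError("image smaller than the 3x3 kernel")
    if kernel is None:
        smoothed = ndimage.uniform_filter(c.astype(float), size=3, mode="reflect")
    else:
        k = np.asarray(kernel, dtype=float)
        if k.shape != (3, 3):
            raise ValueError("kernel must be 3x3")
        if k.sum() <= 0:
            raise ValueError("kernel must have positive sum")
        smoothed = ndimage.correlate(c.astype(float), k / k.sum(), mode="reflect")
    # filtering can leave -1e-17-scale residue on empty regions
    smoothed = np.maximum(smoothed, 0.0)
    return PlanarImage(
        counts=smoothed,
        acquisition_seconds=img.acquisition_seconds,
        acquisition_start=img.acquisition_start,
        view=img.view,
    )


def subtract_background(
    counts_in_roi: float, roi_area: int, bg_rate: float, duration: float
) -> float:
    """Net ROI counts after removing the expected background contribution.

    ``bg_rate`` is in counts/pixel/s, estimated from a background ROI of the
    same image.  Clamps at zero (with a warning) when the background estimate
    exceeds the measured counts.
    """
    expected_bg = bg_rate * roi_area * duration
    net = counts_in_roi - expected_bg
    if net < 0:
        warnings.warn(
            f"background estimate ({expected_bg:.1f}) exceeds ROI counts "
            f"({counts_in_roi:.1f}); clamping net counts to 0",
            stacklevel=2,
        )
        return 0.0
    return float(net)


def decay_correct(counts: float, elapsed: float, half_life: float) -> float:
    """Correct counts for physical decay back to the reference time.

    Multiplies by 2**(elapsed/half_life), where ``elapsed`` is the time from
    the reference to the acquisition.  Negative ``elapsed`` inverts the
    correction, so decay_correct(decay_correct(x, t), -t) == x.
    """
    if half_life <= 0:
        raise ValueError("half_life must be > 0")
    return float(counts * 2.0 ** (elapsed / half_life))


def attenuation_factor_from_calibration(
    measured: RegionalCounts,
    administered_mbq: float,
    sensitivity_cps_per_mbq: float,
    duration: float,
) -> float:
    """Tissue attenuation correction factor from a calibration acquisition.

    The calibration image (known administered activity in the relevant
    tissue compartment) is quantified with the same chain *minus*
    attenuation; the factor is the ratio of expected counts
    (activity x sensitivity x duration) to the observed decay- and
    background-corrected counts.  Factors >= 1 are expected; < 1 is accepted
    with a warning.
    """
    expected = administered_mbq * sensitivity_cps_per_mbq * duration
    if measured.corrected <= 0:
        raise ValueError("calibration ROI has zero corrected counts")
    factor = expected / measured.corrected
    if factor < 1:
        warnings.warn(
            f"attenuation factor {factor:.3f} < 1: observed counts exceed "
            "expectation; check sensitivity calibration",
            stacklevel=2,
        )
    return float(factor)


def _background_rate(
    smoothed: PlanarImage, masks: dict[str, ROIMask], corr: CorrectionSet
) -> float:
    if corr.background_rate is not None:
        return corr.background_rate
    bg = masks.get("BACKGROUND")
    if bg is None:
        warnings.warn(
            "no BACKGROUND mask and no configured background rate; "
            "assuming zero background",
            stacklevel=3,
        )
        return 0.0
    return float(smoothed.counts[bg.mask].mean() / smoothed.acquisition_seconds)


def quantify_regions(
    img: PlanarImage, masks: list[ROIMask], corr: CorrectionSet
) -> list[RegionalCounts]:
    """Apply the full correction chain and return per-region activities.

    Chain: 9-point smoothing -> per-ROI raw sums -> background subtraction
    (rate from the BACKGROUND mask unless configured) -> decay correction to
    the reference time -> per-region attenuation factor.  ET and TH masks are
    mandatory; a STOMACH mask is quantified when present.

    The reported relative accuracy combines Poisson counting error on the
    net counts (1/sqrt(N)) with the attenuation-factor uncertainty in
    quadrature.
    """
    by_label: dict[str, ROIMask] = {}
    for m in masks:
        if m.mask.shape != img.counts.shape:
            raise ValueError(
                f"{m.label} mask shape {m.mask.shape} does not match image "
                f"shape {img.counts.shape}"
            )
        by_label[m.label] = m
    for required in ("ET", "TH"):
        if required not in by_label:
            raise ValueError(f"missing required {required} mask")
    if np.any(by_label["ET"].mask & by_label["TH"].mask):
        raise ValueError("ET and TH masks overlap")

    smoothed = smooth_9point(img)
    bg_rate = _background_rate(smoothed, by_label, corr)
    elapsed = img.acquisition_start - corr.reference_time

    results = []
    for label in REGION_LABELS:
        roi = by_label.get(label)
        if roi is None:
            continue
        raw = float(smoothed.counts[roi.mask].sum())
        net = subtract_background(raw, roi.area, bg_rate, img.acquisition_seconds)
        decayed = decay_correct(net, elapsed, corr.half_life_seconds)
        factor = corr.attenuation_factor.get(label, 1.0)
        corrected = decayed * factor
        if net > 0:
            rel = float(np.sqrt(1.0 / net + corr.attenuation_rel_unc**2))
        else:
            rel = float("inf")
        results.append(
            RegionalCounts(
                region=label,
                raw=raw,
                net=net,
                corrected=corrected,
                relative_accuracy=rel,
            )
        )
    return results
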