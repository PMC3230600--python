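"""Optical densitometry for enzymatic histochemistry.

Transmitted-light darkness of a stained tissue region is expressed as an
optical density against a nearby background region on the same image,

    OD = log10(I_bk / I_m),

where I_bk is the mean background intensity and I_m the mean sample
intensity, both on the 8-bit scale.  Mutant activities are normalized to a
reference (wild-type) strain, comparing only measurements from the same
glass slide, and summarized with 95% confidence intervals and two-sample
Student's t-tests.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .roi import Roi, RoiPairing, roi_mask

logger = logging.getLogger(__name__)

# Luminance weights used for RGB -> grayscale conversion (ImageJ default).
_LUMA = np.array([0.299, 0.587, 0.114])

# Mean sample intensities are floored at 1 intensity unit so that saturated
# dark regions give a large, finite OD instead of infinity.
I_M_FLOOR = 1.0


class MeasurementError(ValueError):
    """ROI cannot be measured on this image."""


class BatchError(ValueError):
    """Slide-matching constraint violated during normalization."""


@dataclass
class ODMeasurement:
    """One paired sample/background optical-density measurement."""

    strain: str
    tissue: str
    slide_id: str
    i_m: float
    i_bk: float
    od: float


@dataclass
class NormalizedActivity:
    """Mutant activity expressed relative to the reference strain.

    The confidence interval is computed on the mutant OD sample and then
    divided by the reference mean, matching per-sample error bars rather
    than a ratio-propagated interval.
    """

    strain: str
    tissue: str
    ratio: float
    n_mutant: int
    n_reference: int
    ci95: tuple[float, float]
    p_value: float


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Monochrome images pass through; RGB images are converted with
    luminance weights 0.299 R + 0.587 G + 0.114 B."""
    arr = np.asarray(image, dtype=float)
    if arr.ndim == 2:
        return arr
    if arr.ndim == 3 and arr.shape[2] in (3, 4):
        return arr[..., :3] @ _LUMA
    raise ValueError(f"unsupported image shape {arr.shape}")


def mean_intensity(image: np.ndarray, roi: Roi) -> float:
    """Arithmetic mean of the grayscale value over the ROI mask pixels."""
    gray = to_grayscale(image)
    h, w = gray.shape
    mask = roi_mask(roi, w, h)
    if not mask.any():
        raise MeasurementError(
            f"roi {roi.name!r} does not cover any pixel of the {w}x{h} image"
        )
    return float(gray[mask].mean())


def optical_density(i_bk: float, i_m: float) -> float:
    """OD = log10(i_bk / i_m), with i_m floored at 1 intensity unit."""
    if i_bk <= 0:
        raise MeasurementError(f"invalid background intensity {i_bk}")
    if i_m < I_M_FLOOR:
        logger.warning("sample intensity %.3f clamped to %.0f", i_m, I_M_FLOOR)
        i_m = I_M_FLOOR
    return math.log10(i_bk / i_m)


def measure_od(image: np.ndarray, pairing: RoiPairing, *,
               strain: str = "", tissue: str | None = None,
               slide_id: str = "") -> ODMeasurement:
    """Measure one tissue/background ROI pair on an image."""
    i_m = mean_intensity(image, pairing.tissue_roi)
    i_bk = mean_intensity(image, pairing.background_roi)
    od = optical_density(i_bk, i_m)
    if od < 0:
        logger.warning(
            "roi %r darker background than sample (OD=%.4f < 0)",
            pairing.tissue_roi.name, od,
        )
    return ODMeasurement(
        strain=strain,
        tissue=tissue if tissue is not None else pairing.tissue_roi.tissue,
        slide_id=slide_id,
        i_m=i_m,
        i_bk=i_bk,
        od=od,
    )


def normalize_to_reference(measurements: Iterable[ODMeasurement],
                           reference_strain: str) -> list[NormalizedActivity]:
    """Express per-strain, per-tissue mean OD relative to the reference.

    Only slide-matched groups enter the ratio: for every slide carrying a
    mutant measurement of a tissue, the same slide must also carry a
    reference measurement of that tissue (images are only comparable when
    stained together on one glass slide).
    """
    measurements = list(measurements)
    ref = [m for m in measurements if m.strain == reference_strain]
    if not ref:
        raise BatchError(f"no measurements for reference strain {reference_strain!r}")

    results: list[NormalizedActivity] = []
    strains = sorted({m.strain for m in measurements})
    tissues = sorted({m.tissue for m in measurements})
    for strain in strains:
        for tissue in tissues:
            mut = [m for m in measurements
                   if m.strain == strain and m.tissue == tissue]
            if not mut:
                continue
            mut_slides = {m.slide_id for m in mut}
            ref_here = [m for m in ref
                        if m.tissue == tissue and m.slide_id in mut_slides]
            ref_slides = {m.slide_id for m in ref_here}
            missing = sorted(mut_slides - ref_slides)
            if missing:
                raise BatchError(
                    f"strain {strain!r}, tissue {tissue!r}: no reference "
                    f"measurement on slide(s) {missing}"
                )
            mut_od = np.array([m.od for m in mut])
            ref_od = np.array([m.od for m in ref_here])
            ref_mean = float(ref_od.mean())
            if strain == reference_strain:
                ratio = 1.0
            else:
                ratio = float(mut_od.mean()) / ref_mean
            if len(mut_od) >= 2:
                lo, hi = confidence_interval(mut_od, 0.95)
                ci = (lo / ref_mean, hi / ref_mean)
            else:
                ci = (math.nan, math.nan)
            if len(mut_od) >= 2 and len(ref_od) >= 2 and strain != reference_strain:
                p = students_t_test(mut_od, ref_od)
            else:
                p = math.nan
            results.append(NormalizedActivity(
                strain=strain, tissue=tissue, ratio=ratio,
                n_mutant=len(mut_od), n_reference=len(ref_od),
                ci95=ci, p_value=p,
            ))
    return results


def confidence_interval(values: Sequence[float],
                        level: float = 0.95) -> tuple[float, float]:
    """Two-sided t confidence interval for the mean:
    mean +/- t_{(1+level)/2, n-1} * sd / sqrt(n)."""
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n < 2:
        raise MeasurementError("confidence interval requires n >= 2")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    mean = values.mean()
    sem = values.std(ddof=1) / math.sqrt(n)
    t_crit = stats.t.ppf((1 + level) / 2, n - 1)
    return (float(mean - t_crit * sem), float(mean + t_crit * sem))


def students_t_test(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-sided, two-sample, pooled-variance Student's t-test p-value.

    Degenerate zero-pooled-variance samples follow the documented
    convention: equal means -> p = 1.0, unequal means -> p = 0.0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise MeasurementError("t-test requires n >= 2 in each sample")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        return 1.0 if a.mean() == b.mean() else 0.0
    return float(stats.ttest_ind(a, b, equal_var=True).pvalue)


def exposure_linearity(exposure_times: Sequence[float],
                       background_intensities: Sequence[float],
                       *, warn_below: float = 0.99) -> float:
    """Pearson correlation between exposure time and background intensity,
    used as the camera-linearity check; warns when r drops below
    ``warn_below``."""
    x = np.asarray(exposure_times, dtype=float)
    y = np.asarray(background_intensities, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise MeasurementError("linearity check needs >= 3 paired points")
    if x.std() == 0 or y.std() == 0:
        raise MeasurementError("correlation undefined for zero-variance input")
    r = float(stats.pearsonr(x, y).statistic)
    if r < warn_below:
        logger.warning("exposure linearity r=%.4f below %.2f", r, warn_below)
    return r
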