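"""End-to-end per-patient analysis of a first/last fraction slice pair.

The iso-pixel threshold is established once, on the first-fraction image,
and reused verbatim for the last fraction, so that area change is measured
against a fixed HU level.  Because the threshold itself depends on a
background estimate that in turn requires a tumor contour, the first
fraction is processed in two passes:

1. a provisional iso value is formed against a crude background estimate
   (the slice median HU — dominated by lung in a lung window) and used to
   extract a provisional region;
2. the proper annular background ROI around that region supplies the final
   background mean, the iso value is recomputed, and the final region is
   extracted.

Both fractions then get their own background annulus (geometry around their
own contour) for CNR, while sharing the single iso value.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

from .image_io import ImageSlice
from .metrics import (
    FractionMeasurement,
    MuCalibration,
    ResponseRatios,
    Response,
    classify_r,
    cnr,
    compute_ratios,
    mu_max,
    region_statistics,
)
from .segmentation import (
    BackgroundROI,
    TumorRegion,
    background_roi,
    choose_iso_value,
    extract_iso_region,
)

DEFAULT_CUTOFF = 1.1


@dataclass(frozen=True)
class FractionAnalysis:
    """Segmentation products and measurements for one fraction."""

    region: TumorRegion
    background: BackgroundROI
    measurement: FractionMeasurement


@dataclass(frozen=True)
class PatientResult:
    """Full per-patient record: per-fraction measurements, ratios, call."""

    patient_id: str
    iso_value: float
    first: FractionAnalysis
    last: FractionAnalysis
    ratios: ResponseRatios
    cutoff: float
    call: Response

    def as_record(self) -> dict:
        """Flat dict for CSV/JSON serialization."""
        f, l = self.first.measurement, self.last.measurement
        return {
            "patient_id": self.patient_id,
            "iso_value": float(self.iso_value),
            "A_F": float(f.area), "A_L": float(l.area),
            "CNR_F": float(f.cnr), "CNR_L": float(l.cnr),
            "mu_F": float(f.mu_max), "mu_L": float(l.mu_max),
            "R_A": float(self.ratios.r_area), "R_CNR": float(self.ratios.r_cnr),
            "R_mu": float(self.ratios.r_mu), "R": float(self.ratios.r),
            "cutoff": float(self.cutoff), "label": self.call.value,
        }


def analyze_fraction(
    slice_: ImageSlice,
    seed: tuple[int, int],
    iso_value: float,
    fraction_label: str,
    inner_margin_px: int = 2,
    outer_margin_px: int = 10,
    calib: MuCalibration | None = None,
    smooth: bool = False,
) -> FractionAnalysis:
    """Segment one fraction at a given iso value and measure A, CNR, mu_max."""
    region = extract_iso_region(slice_, seed, iso_value)
    bg = background_roi(region, slice_, inner_margin_px, outer_margin_px)
    stats = region_statistics(slice_, region, bg)
    meas = FractionMeasurement(
        area=region.pixel_count * slice_.pixel_area_mm2,
        cnr=cnr(stats),
        mu_max=mu_max(slice_, region, calib, smooth=smooth),
        fraction_label=fraction_label,
    )
    return FractionAnalysis(region=region, background=bg, measurement=meas)


def first_fraction_iso(
    slice_: ImageSlice,
    seed: tuple[int, int],
    inner_margin_px: int = 2,
    outer_margin_px: int = 10,
) -> float:
    """Two-pass iso-value estimate on the first-fraction image."""
    crude_bg = float(np.median(slice_.pixels))
    iso0 = choose_iso_value(slice_, seed, crude_bg)
    provisional = extract_iso_region(slice_, seed, iso0)
    bg = background_roi(provisional, slice_, inner_margin_px, outer_margin_px)
    return choose_iso_value(slice_, seed, bg)


def analyze_pair(
    first: ImageSlice,
    last: ImageSlice,
    seed: tuple[int, int],
    patient_id: str = "patient",
    seed_last: tuple[int, int] | None = None,
    cutoff: float = DEFAULT_CUTOFF,
    inner_margin_px: int = 2,
    outer_margin_px: int = 10,
    calib: MuCalibration | None = None,
    smooth: bool = False,
) -> PatientResult:
    """Analyze a first/last fraction pair and classify the response.

    ``seed`` locates the tumor on both images (override with ``seed_last``
    if the tumor moved).  The iso value is computed on the first fraction
    and shared.
    """
    iso = first_fraction_iso(first, seed, inner_margin_px, outer_margin_px)
    fa = analyze_fraction(first, seed, iso, "first",
                          inner_margin_px, outer_margin_px, calib, smooth)
    la = analyze_fraction(last, seed_last or seed, iso, "last",
                          inner_margin_px, outer_margin_px, calib, smooth)
    ratios = compute_ratios(fa.measurement, la.measurement)
    return PatientResult(
        patient_id=patient_id,
        iso_value=iso,
        first=fa,
        last=la,
        ratios=ratios,
        cutoff=cutoff,
        call=classify_r(ratios.r, cutoff),
    )
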