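"""Per-fraction tumor quantities and last/first response ratios.

For one treatment fraction the tumor on the analysis slice is summarized by
three numbers:

* ``A``   — iso-contour area (mm^2),
* ``CNR`` — contrast-to-noise ratio ``|T - B| / sqrt(sigma_T^2 + sigma_B^2)``
  between the tumor (mean ``T``, SD ``sigma_T``) and its background ROI
  (mean ``B``, SD ``sigma_B``),
* ``mu_max`` — the highest linear attenuation coefficient inside the tumor,
  obtained from HU via ``mu = (1 + HU/1000) * mu_water``, representing peak
  tumor density.

Response between the first (F) and last (L) fraction is measured by the
ratios ``R_A = A_L/A_F``, ``R_CNR = CNR_L/CNR_F``, ``R_mu = mu_L/mu_F`` and
the combined metric ``R = R_A * R_CNR * R_mu``.  Growth, rising contrast or
rising density each push R above 1; a cutoff R_C (1.1 in the source cohort)
separates controlled disease (R <= R_C) from progression (R > R_C).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .image_io import ImageSlice
from .segmentation import BackgroundROI, TumorRegion

#: Linear attenuation coefficient of water, cm^-1, at a typical CT effective
#: energy.  Every ratio and classification is invariant to this value (it
#: cancels in R_mu), so it only matters for absolute mu reporting.
DEFAULT_MU_WATER = 0.195


class Response(str, enum.Enum):
    CONTROLLED = "controlled"
    PROGRESSION = "progression"


class RecistCategory(str, enum.Enum):
    PARTIAL_RESPONSE = "partial_response"
    STABLE_DISEASE = "stable_disease"
    PROGRESSIVE_DISEASE = "progressive_disease"


@dataclass(frozen=True)
class MuCalibration:
    """HU-to-attenuation conversion constant."""

    mu_water: float = DEFAULT_MU_WATER

    def __post_init__(self) -> None:
        if self.mu_water <= 0:
            raise ValueError("mu_water must be positive")


@dataclass(frozen=True)
class RegionStats:
    """Mean/SD of tumor (T, sigma_T) and background (B, sigma_B) HU."""

    T: float
    sigma_T: float
    B: float
    sigma_B: float

    def __post_init__(self) -> None:
        vals = (self.T, self.sigma_T, self.B, self.sigma_B)
        if not all(np.isfinite(vals)):
            raise ValueError("region statistics must be finite")
        if self.sigma_T < 0 or self.sigma_B < 0:
            raise ValueError("standard deviations must be non-negative")


@dataclass(frozen=True)
class FractionMeasurement:
    """A, CNR and mu_max for one treatment fraction."""

    area: float
    cnr: float
    mu_max: float
    fraction_label: str = "first"

    def __post_init__(self) -> None:
        if self.area <= 0:
            raise ValueError("area must be positive")
        if self.cnr < 0 or self.mu_max < 0:
            raise ValueError("cnr and mu_max must be non-negative")


@dataclass(frozen=True)
class ResponseRatios:
    """Last/first ratios R_A, R_CNR, R_mu and their product R."""

    r_area: float
    r_cnr: float
    r_mu: float
    r: float

    def __post_init__(self) -> None:
        if min(self.r_area, self.r_cnr, self.r_mu, self.r) <= 0:
            raise ValueError("ratios must be positive")
        expected = self.r_area * self.r_cnr * self.r_mu
        if abs(self.r - expected) > 1e-12 * max(abs(expected), 1.0):
            raise ValueError("r must equal r_area * r_cnr * r_mu")


def region_statistics(
    slice_: ImageSlice, tumor: TumorRegion, background: BackgroundROI
) -> RegionStats:
    """Mean and population SD of HU over the tumor and background masks."""
    if tumor.mask.shape != slice_.shape or background.mask.shape != slice_.shape:
        raise ValueError("mask incongruent with slice")
    if (tumor.mask & background.mask).any():
        raise ValueError("tumor and background masks overlap")
    t_px = slice_.pixels[tumor.mask]
    b_px = slice_.pixels[background.mask]
    if t_px.size < 2 or b_px.size < 2:
        raise ValueError("each mask needs >=2 pixels for a standard deviation")
    return RegionStats(
        T=float(t_px.mean()),
        sigma_T=float(t_px.std(ddof=0)),
        B=float(b_px.mean()),
        sigma_B=float(b_px.std(ddof=0)),
    )


def cnr(stats: RegionStats) -> float:
    """Contrast-to-noise ratio |T - B| / sqrt(sigma_T^2 + sigma_B^2)."""
    denom = np.hypot(stats.sigma_T, stats.sigma_B)
    if denom == 0:
        raise ValueError("noise-free CNR undefined (both SDs zero)")
    return abs(stats.T - stats.B) / denom


def hu_to_mu(hu: float, calib: MuCalibration | None = None) -> float:
    """Convert HU to linear attenuation: mu = (1 + HU/1000) * mu_water."""
    calib = calib or MuCalibration()
    if hu < -1000:
        raise ValueError("HU below -1000 implies negative attenuation")
    return (1.0 + hu / 1000.0) * calib.mu_water


def _masked_median3(pixels: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """3x3 median restricted to mask pixels; returns values at mask positions."""
    rows, cols = pixels.shape
    out = np.empty(int(mask.sum()))
    for i, (r, c) in enumerate(np.argwhere(mask)):
        window_mask = mask[max(r - 1, 0) : r + 2, max(c - 1, 0) : c + 2]
        window = pixels[max(r - 1, 0) : r + 2, max(c - 1, 0) : c + 2]
        out[i] = np.median(window[window_mask])
    return out


def mu_max(
    slice_: ImageSlice,
    tumor: TumorRegion,
    calib: MuCalibration | None = None,
    smooth: bool = False,
) -> float:
    """Peak attenuation inside the tumor region.

    With ``smooth`` a 3x3 median filter restricted to the mask suppresses
    single-pixel noise spikes before the maximum is taken.
    """
    if tumor.mask.shape != slice_.shape:
        raise ValueError("mask incongruent with slice")
    if smooth:
        hu_peak = float(_masked_median3(slice_.pixels, tumor.mask).max())
    else:
        hu_peak = float(slice_.pixels[tumor.mask].max())
    return hu_to_mu(hu_peak, calib)


def combine_ratios(r_area: float, r_cnr: float, r_mu: float) -> ResponseRatios:
    """Build :class:`ResponseRatios` from precomputed per-feature ratios."""
    return ResponseRatios(r_area=r_area, r_cnr=r_cnr, r_mu=r_mu,
                          r=r_area * r_cnr * r_mu)


def compute_ratios(
    first: FractionMeasurement, last: FractionMeasurement
) -> ResponseRatios:
    """Last/first ratios of area, CNR and peak attenuation, and their product.

    Growth-oriented: a tumor that grows, gains contrast or gains density
    between fractions yields ratios above 1.
    """
    if first.cnr <= 0 or first.mu_max <= 0:
        raise ZeroDivisionError("first-fraction CNR and mu_max must be positive")
    return combine_ratios(
        last.area / first.area, last.cnr / first.cnr, last.mu_max / first.mu_max
    )


def classify_r(r: float, cutoff: float) -> Response:
    """Controlled (response/stable) if r <= cutoff, progression otherwise."""
    if r <= 0 or cutoff <= 0:
        raise ValueError("r and cutoff must be positive")
    return Response.CONTROLLED if r <= cutoff else Response.PROGRESSION


def recist_classify(diameter_first: float, diameter_last: float) -> RecistCategory:
    """Diameter-based RECIST call: -30% partial response, +20% progression."""
    if diameter_first <= 0 or diameter_last <= 0:
        raise ValueError("diameters must be positive")
    d = diameter_last / diameter_first
    if d <= 0.7:
        return RecistCategory.PARTIAL_RESPONSE
    if d >= 1.2:
        return RecistCategory.PROGRESSIVE_DISEASE
    return RecistCategory.STABLE_DISEASE
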