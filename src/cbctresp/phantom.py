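"""Synthetic paired-fraction lung phantoms with known ground truth.

Each phantom pair emulates the imaging situation the method targets: an
elliptical soft-tissue tumor (around 0-100 HU) embedded in aerated lung
(around -800 HU) on a 0.9 mm grid, imaged at the first and last treatment
fraction.  Between the two time points the generator applies controlled
multiplicative changes:

* ``area_factor``     — ellipse area is scaled (semi-axes by its sqrt),
* ``contrast_factor`` — the tumor-to-lung contrast is scaled by shifting the
  tumor mean toward the lung mean (noise SD fixed, so the CNR ratio tracks
  this factor analytically),
* ``peak_factor``     — the height of a small dense core above the tumor
  mean is scaled, moving the peak attenuation.

Additive white Gaussian noise in HU is drawn from ``seed`` for the first
fraction and ``seed + 1`` for the last, so pairs are fully deterministic
while the two fractions carry independent noise.  CBCT streak/scatter
artifacts and respiratory blur are deliberately not simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np

from .image_io import ImageSlice
from .metrics import Response

#: Default HU levels: aerated lung background and soft-tissue tumor.
DEFAULT_LUNG_HU = -800.0
DEFAULT_TUMOR_HU = 50.0


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry, contrast and change factors for one phantom pair."""

    grid: tuple[int, int] = (128, 128)
    spacing_mm: tuple[float, float] = (0.9, 0.9)
    lung_hu: float = DEFAULT_LUNG_HU
    tumor_hu: float = DEFAULT_TUMOR_HU
    tumor_center: tuple[float, float] | None = None  # None -> grid center
    tumor_radii_px: tuple[float, float] = (15.0, 12.0)
    noise_sd_hu: float = 20.0
    area_factor: float = 1.0
    contrast_factor: float = 1.0
    peak_factor: float = 1.0
    peak_offset_hu: float = 30.0
    core_fraction: float = 0.3  # core semi-axes as a fraction of the tumor's
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.tumor_radii_px) <= 2:
            raise ValueError("tumor semi-axes must exceed 2 px")
        if self.tumor_hu <= self.lung_hu:
            raise ValueError("tumor must be denser than lung")
        if min(self.area_factor, self.contrast_factor, self.peak_factor) <= 0:
            raise ValueError("change factors must be positive")
        if self.noise_sd_hu < 0:
            raise ValueError("noise SD must be non-negative")
        if not (0 < self.core_fraction < 1):
            raise ValueError("core_fraction must lie in (0, 1)")

    @property
    def center(self) -> tuple[float, float]:
        if self.tumor_center is not None:
            return self.tumor_center
        return ((self.grid[0] - 1) / 2.0, (self.grid[1] - 1) / 2.0)


@dataclass(frozen=True)
class PhantomTruth:
    """Analytic ground truth recorded alongside a generated pair."""

    true_area_first: float
    true_area_last: float
    true_r_area: float
    true_r_cnr_nominal: float
    true_r_mu_nominal: float
    class_label: Response
    raster_area_first: float = field(default=float("nan"))
    raster_area_last: float = field(default=float("nan"))

    @property
    def raster_r_area(self) -> float:
        """Area ratio of the rasterized masks (pixel-counting truth)."""
        return self.raster_area_last / self.raster_area_first


def _ellipse_mask(
    grid: tuple[int, int], center: tuple[float, float], radii: tuple[float, float]
) -> np.ndarray:
    rr, cc = np.mgrid[0 : grid[0], 0 : grid[1]]
    return ((rr - center[0]) / radii[0]) ** 2 + ((cc - center[1]) / radii[1]) ** 2 <= 1.0


def _render_fraction(
    config: PhantomConfig,
    radii: tuple[float, float],
    tumor_hu: float,
    core_hu: float,
    noise_seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    img = np.full(config.grid, config.lung_hu, dtype=float)
    tumor = _ellipse_mask(config.grid, config.center, radii)
    core = _ellipse_mask(
        config.grid,
        config.center,
        (radii[0] * config.core_fraction, radii[1] * config.core_fraction),
    )
    img[tumor] = tumor_hu
    img[core] = core_hu
    if config.noise_sd_hu > 0:
        rng = np.random.default_rng(noise_seed)
        img += rng.normal(0.0, config.noise_sd_hu, size=config.grid)
    return img, tumor


def generate_pair(config: PhantomConfig) -> tuple[ImageSlice, ImageSlice, PhantomTruth]:
    """Render the first/last-fraction slice pair and its analytic truth.

    The last fraction scales the semi-axes by ``sqrt(area_factor)``, the
    tumor-to-lung contrast by ``contrast_factor`` and the core height above
    the tumor mean by ``peak_factor``.  Noise is independent between the two
    fractions but fully determined by ``config.seed``.
    """
    a, b = config.tumor_radii_px
    s = float(np.sqrt(config.area_factor))
    radii_last = (a * s, b * s)
    cr, cc = config.center
    rows, cols = config.grid
    max_a = max(a, radii_last[0])
    max_b = max(b, radii_last[1])
    if (
        cr - max_a < 0 or cr + max_a >= rows or cc - max_b < 0 or cc + max_b >= cols
    ):
        raise ValueError("ellipse does not fit inside the grid")

    contrast_first = config.tumor_hu - config.lung_hu
    tumor_hu_last = config.lung_hu + contrast_first * config.contrast_factor
    core_hu_first = config.tumor_hu + config.peak_offset_hu
    core_hu_last = tumor_hu_last + config.peak_offset_hu * config.peak_factor

    img_f, mask_f = _render_fraction(
        config, (a, b), config.tumor_hu, core_hu_first, config.seed
    )
    img_l, mask_l = _render_fraction(
        config, radii_last, tumor_hu_last, core_hu_last, config.seed + 1
    )

    px_area = config.spacing_mm[0] * config.spacing_mm[1]
    area_f = float(np.pi * a * b * px_area)
    area_l = float(np.pi * radii_last[0] * radii_last[1] * px_area)
    r_mu_nom = (1.0 + core_hu_last / 1000.0) / (1.0 + core_hu_first / 1000.0)
    r_nominal = config.area_factor * config.contrast_factor * r_mu_nom
    truth = PhantomTruth(
        true_area_first=area_f,
        true_area_last=area_l,
        true_r_area=config.area_factor,
        true_r_cnr_nominal=config.contrast_factor,
        true_r_mu_nominal=r_mu_nom,
        class_label=Response.PROGRESSION if r_nominal > 1.1 else Response.CONTROLLED,
        raster_area_first=float(mask_f.sum()) * px_area,
        raster_area_last=float(mask_l.sum()) * px_area,
    )
    sp = config.spacing_mm
    first = ImageSlice(img_f, sp[0], sp[1], slice_index=0,
                       meta={"fraction": "first", "seed": config.seed})
    last = ImageSlice(img_l, sp[0], sp[1], slice_index=0,
                      meta={"fraction": "last", "seed": config.seed + 1})
    return first, last, truth


@dataclass(frozen=True)
class EffectSpec:
    """Per-class uniform ranges for the three change factors.

    Defaults give a clearly separated cohort: controlled tumors shrink and
    lose contrast (factor products concentrated below 1), progressing tumors
    grow and gain density (products above 1).
    """

    controlled_area: tuple[float, float] = (0.70, 1.00)
    controlled_contrast: tuple[float, float] = (0.80, 1.05)
    controlled_peak: tuple[float, float] = (0.85, 1.05)
    progression_area: tuple[float, float] = (1.20, 1.50)
    progression_contrast: tuple[float, float] = (1.00, 1.30)
    progression_peak: tuple[float, float] = (1.00, 1.25)

    def ranges(self, label: Response) -> tuple[tuple[float, float], ...]:
        if label is Response.CONTROLLED:
            return (self.controlled_area, self.controlled_contrast, self.controlled_peak)
        return (self.progression_area, self.progression_contrast, self.progression_peak)


def generate_cohort(
    n_controlled: int = 124,
    n_progression: int = 10,
    effect: EffectSpec | None = None,
    noise_sd_hu: float = 20.0,
    base_seed: int = 0,
    base_config: PhantomConfig | None = None,
) -> Iterator[tuple[ImageSlice, ImageSlice, PhantomTruth, PhantomConfig]]:
    """Yield a labeled cohort of phantom pairs, deterministically from a seed.

    Class sizes default to 124 controlled : 10 progression, mirroring the
    prevalence the method was calibrated on.  Per-patient factors are drawn
    uniformly from the :class:`EffectSpec` ranges; per-patient noise seeds
    are derived from ``base_seed`` and stay below 2**31.
    """
    if n_controlled <= 0 or n_progression <= 0:
        raise ValueError("need at least one patient per class")
    effect = effect or EffectSpec()
    base = base_config or PhantomConfig(noise_sd_hu=noise_sd_hu)
    rng = np.random.default_rng(base_seed)
    labels = [Response.CONTROLLED] * n_controlled + [Response.PROGRESSION] * n_progression
    for label in labels:
        (a_lo, a_hi), (c_lo, c_hi), (p_lo, p_hi) = effect.ranges(label)
        cfg = replace(
            base,
            noise_sd_hu=noise_sd_hu,
            area_factor=float(rng.uniform(a_lo, a_hi)),
            contrast_factor=float(rng.uniform(c_lo, c_hi)),
            peak_factor=float(rng.uniform(p_lo, p_hi)),
            seed=int(rng.integers(0, 2**30)),
        )
        first, last, truth = generate_pair(cfg)
        truth = replace(truth, class_label=label)
        yield first, last, truth, cfg
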