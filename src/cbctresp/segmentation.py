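"""Iso-pixel tumor contouring and background ROI construction.

The tumor on a slice is delineated by a single fixed HU threshold (the
"iso-pixel" value): the tumor region is the 8-connected component of pixels
at or above the threshold that contains a user-supplied seed, with interior
holes filled.  The background is an annulus of pixels at a controlled
distance band around the tumor, optionally minus an exclusion mask for
adjacent bright anatomy (chest wall, vessels).

The same iso value is meant to be reused across treatment fractions so that
area change is measured against a fixed threshold; see
:func:`cbctresp.pipeline.analyze_pair`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .image_io import ImageSlice

_EIGHT = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class TumorRegion:
    """Iso-pixel tumor mask on one slice.

    ``mask`` is a single filled 8-connected component containing ``seed``;
    ``boundary`` is its ordered, closed outer pixel boundary (Moore trace:
    consecutive boundary pixels are 8-adjacent, first equals last).
    """

    mask: np.ndarray
    iso_value: float
    seed: tuple[int, int]
    boundary: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask, dtype=bool)
        if mask.ndim != 2 or not mask.any():
            raise ValueError("tumor mask must be a non-empty 2D boolean grid")
        if not mask[self.seed]:
            raise ValueError("seed not inside tumor mask")
        labels, n = ndimage.label(mask, structure=_EIGHT)
        if n != 1:
            raise ValueError("tumor mask must be a single connected component")
        object.__setattr__(self, "mask", mask)

    @property
    def pixel_count(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class BackgroundROI:
    """Background pixels in a distance band around the tumor boundary."""

    mask: np.ndarray
    inner_margin_px: int
    outer_margin_px: int

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask, dtype=bool)
        if mask.ndim != 2 or not mask.any():
            raise ValueError("background mask must be a non-empty 2D boolean grid")
        object.__setattr__(self, "mask", mask)

    @property
    def pixel_count(self) -> int:
        return int(self.mask.sum())


def choose_iso_value(
    slice_: ImageSlice,
    seed: tuple[int, int],
    background_sample: "BackgroundROI | float",
) -> float:
    """Midpoint iso value between the seed neighborhood and the background.

    The tumor-side level is the mean HU of the 3x3 neighborhood of ``seed``
    (clipped at image edges); the background level is either a plain mean HU
    or the mean over a :class:`BackgroundROI`.  Requires positive contrast
    (tumor brighter than background).
    """
    r, c = seed
    rows, cols = slice_.shape
    if not (0 <= r < rows and 0 <= c < cols):
        raise IndexError(f"seed {seed} outside slice bounds {slice_.shape}")
    patch = slice_.pixels[max(r - 1, 0) : r + 2, max(c - 1, 0) : c + 2]
    tumor_level = float(patch.mean())
    if isinstance(background_sample, BackgroundROI):
        bg_level = float(slice_.pixels[background_sample.mask].mean())
    else:
        bg_level = float(background_sample)
    if tumor_level <= bg_level:
        raise ValueError("tumor not brighter than background")
    return 0.5 * (tumor_level + bg_level)


def _trace_boundary(mask: np.ndarray, start: tuple[int, int]) -> list[tuple[int, int]]:
    """Moore-neighbor boundary trace, clockwise from the topmost-leftmost pixel."""
    # clockwise 8-neighborhood starting from west
    moves = [(0, -1), (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1)]
    rows, cols = mask.shape

    def on(p: tuple[int, int]) -> bool:
        return 0 <= p[0] < rows and 0 <= p[1] < cols and mask[p]

    contour = [start]
    prev_dir = 0  # came "from the west"
    cur = start
    while True:
        found = False
        for i in range(8):
            d = (prev_dir + i) % 8
            nxt = (cur[0] + moves[d][0], cur[1] + moves[d][1])
            if on(nxt):
                contour.append(nxt)
                cur = nxt
                # back up two steps so the scan restarts just past the
                # background pixel we entered from
                prev_dir = (d + 6) % 8 if d % 2 == 0 else (d + 7) % 8
                found = True
                break
        if not found:  # isolated single pixel
            break
        if cur == start and len(contour) > 1:
            break
    return contour


def extract_iso_region(
    slice_: ImageSlice, seed: tuple[int, int], iso_value: float
) -> TumorRegion:
    """Extract the filled 8-connected iso-pixel region through ``seed``.

    Pixels equal to the threshold are included (>=).  The component must be
    interior to the image: a component touching the border has no closed
    contour and is rejected.
    """
    r, c = seed
    rows, cols = slice_.shape
    if not (0 <= r < rows and 0 <= c < cols):
        raise IndexError(f"seed {seed} outside slice bounds {slice_.shape}")
    if slice_.pixels[r, c] < iso_value:
        raise ValueError("seed pixel below iso value")
    thresh = slice_.pixels >= iso_value
    labels, _ = ndimage.label(thresh, structure=_EIGHT)
    mask = labels == labels[r, c]
    if mask[0, :].any() or mask[-1, :].any() or mask[:, 0].any() or mask[:, -1].any():
        raise ValueError("component touches border; contour not closed")
    mask = ndimage.binary_fill_holes(mask)
    start_r, start_c = np.argwhere(mask)[0]
    boundary = _trace_boundary(mask, (int(start_r), int(start_c)))
    return TumorRegion(mask=mask, iso_value=float(iso_value), seed=(r, c),
                       boundary=tuple(boundary))


def region_area(region: TumorRegion, slice_: ImageSlice) -> float:
    """Tumor area A in mm^2: pixel count times pixel pitch in both axes."""
    if region.mask.shape != slice_.shape:
        raise ValueError("region mask incongruent with slice")
    return region.pixel_count * slice_.pixel_area_mm2


def background_roi(
    region: TumorRegion,
    slice_: ImageSlice,
    inner_margin_px: int = 2,
    outer_margin_px: int = 10,
    exclusion: np.ndarray | None = None,
) -> BackgroundROI:
    """Annular background ROI at distance (inner, outer] px from the tumor.

    Distances are Euclidean, measured to the nearest tumor pixel.  Pixels in
    ``exclusion`` (bright adjacent anatomy) are removed.  The annulus must
    fit inside the image and be non-empty after exclusion.
    """
    if not (0 < inner_margin_px < outer_margin_px):
        raise ValueError("need 0 < inner_margin_px < outer_margin_px")
    if region.mask.shape != slice_.shape:
        raise ValueError("region mask incongruent with slice")
    rs, cs = np.nonzero(region.mask)
    rows, cols = slice_.shape
    if (
        rs.min() - outer_margin_px < 0
        or cs.min() - outer_margin_px < 0
        or rs.max() + outer_margin_px >= rows
        or cs.max() + outer_margin_px >= cols
    ):
        raise ValueError("annulus does not fit inside the image")
    dist = ndimage.distance_transform_edt(~region.mask)
    mask = (dist > inner_margin_px) & (dist <= outer_margin_px)
    if exclusion is not None:
        mask &= ~np.asarray(exclusion, dtype=bool)
    if not mask.any():
        raise ValueError("empty background annulus after exclusion")
    return BackgroundROI(mask=mask, inner_margin_px=inner_margin_px,
                         outer_margin_px=outer_margin_px)


def save_overlay(
    slice_: ImageSlice,
    region: TumorRegion,
    path,
    background: BackgroundROI | None = None,
) -> None:
    """Write a PNG of the slice with the contour (and optional ROI) overlaid."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    ax.imshow(slice_.pixels, cmap="gray", interpolation="nearest")
    b = np.array(region.boundary)
    ax.plot(b[:, 1], b[:, 0], "r-", linewidth=1.0, label="iso contour")
    if background is not None:
        rs, cs = np.nonzero(background.mask)
        ax.plot(cs, rs, ".", color="deepskyblue", markersize=0.5, label="background ROI")
    ax.set_axis_off()
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
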