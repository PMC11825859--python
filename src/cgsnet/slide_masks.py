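"""Slide-level masks: annotation polygons, tissue detection, rasterization.

Three binary masks drive patch quality control: a *tissue* mask from Otsu
thresholding on HSV saturation with morphological clean-up, a *cancer* mask
rasterized from the pathologist (or synthetic) annotation polygons, and the
*non-cancer* mask = tissue minus cancer.  The cancer mask is annotation-
driven and is never gated by the tissue mask, so fat-tissue holes inside an
annotation stay part of the cancer class.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage import color as skcolor
from skimage import morphology
from skimage.filters import threshold_otsu

LEVEL_FACTORS = {2: 4, 3: 8}     # level-0 -> level linear divisors


@dataclass
class AnnotationSet:
    """Closed polygon rings in level-0 pixel coordinates."""

    polygons: list                      # list of (n, 2) arrays of (x, y)
    slide_id: str = ""

    def __post_init__(self):
        checked = []
        for i, poly in enumerate(self.polygons):
            arr = np.asarray(poly, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 2:
                raise ValueError(f"polygon {i} must be an (n, 2) vertex array")
            if arr.shape[0] < 3:
                raise ValueError(f"polygon {i} has fewer than 3 vertices")
            if not np.isfinite(arr).all() or (arr < 0).any():
                raise ValueError(f"polygon {i} has non-finite or negative coordinates")
            checked.append(arr)
        self.polygons = checked


@dataclass
class TissueMaskParams:
    closing_radius: int = 4
    min_hole_area: int = 16
    min_object_area: int = 16

    def __post_init__(self):
        if min(self.closing_radius, self.min_hole_area, self.min_object_area) < 0:
            raise ValueError("tissue-mask parameters must be non-negative")

    def at_level(self, level: int) -> "TissueMaskParams":
        """Defaults are stated at level 2; halve linear sizes at level 3."""
        if level == 2:
            return self
        return TissueMaskParams(closing_radius=max(self.closing_radius // 2, 1),
                                min_hole_area=max(self.min_hole_area // 2, 1),
                                min_object_area=max(self.min_object_area // 2, 1))


@dataclass
class SlideMaskSet:
    tissue: np.ndarray
    cancer: np.ndarray
    noncancer: np.ndarray
    level: int
    dims: tuple[int, int] = (0, 0)      # (height, width)

    def __post_init__(self):
        if not (self.tissue.shape == self.cancer.shape == self.noncancer.shape):
            raise ValueError("mask dims differ")
        if (self.cancer & self.noncancer).any():
            raise ValueError("cancer and non-cancer masks overlap")
        self.dims = self.tissue.shape


# ---------------------------------------------------------------- operations
def load_annotations(xml_path: str | Path, slide_id: str | None = None) -> AnnotationSet:
    """Parse ASAP-dialect annotation XML; vertices ordered by Order attribute."""
    from lxml import etree

    xml_path = Path(xml_path)
    try:
        tree = etree.parse(str(xml_path))
    except etree.XMLSyntaxError as exc:
        raise ValueError(f"malformed annotation XML {xml_path.name}: {exc}") from exc
    polygons = []
    for anno in tree.iter("Annotation"):
        verts = []
        for coord in anno.iter("Coordinate"):
            verts.append((int(coord.get("Order")),
                          float(coord.get("X")), float(coord.get("Y"))))
        if len(verts) < 3:
            raise ValueError(
                f"Annotation '{anno.get('Name')}' has fewer than 3 vertices")
        verts.sort(key=lambda t: t[0])
        polygons.append(np.array([(x, y) for _, x, y in verts]))
    return AnnotationSet(polygons=polygons,
                         slide_id=slide_id or xml_path.stem)


def rasterize_polygons(polygons, dims: tuple[int, int], factor: float) -> np.ndarray:
    """Even-odd scanline rasterization: a pixel is set iff its center
    (col + 0.5, row + 0.5) lies inside any polygon after dividing the
    level-0 coordinates by ``factor``."""
    h, w = dims
    flips = np.zeros((h, w + 1), dtype=np.int64)
    yc = np.arange(h) + 0.5
    for poly in polygons:
        pts = np.asarray(poly, dtype=float) / factor
        x1, y1 = pts[:, 0], pts[:, 1]
        x2, y2 = np.roll(x1, -1), np.roll(y1, -1)
        for ex1, ey1, ex2, ey2 in zip(x1, y1, x2, y2):
            if ey1 == ey2:
                continue
            lo, hi = (ey1, ey2) if ey1 < ey2 else (ey2, ey1)
            rows = np.nonzero((yc >= lo) & (yc < hi))[0]
            if rows.size == 0:
                continue
            t = (yc[rows] - ey1) / (ey2 - ey1)
            xc = ex1 + t * (ex2 - ex1)
            cols = np.clip(np.ceil(xc - 0.5 - 1e-12).astype(np.int64), 0, w)
            np.add.at(flips, (rows, cols), 1)
    inside = np.cumsum(flips[:, :w], axis=1) % 2
    return inside.astype(bool)


def rasterize_cancer_mask(annotations: AnnotationSet, level: int,
                          dims: tuple[int, int]) -> np.ndarray:
    if level not in LEVEL_FACTORS:
        raise ValueError(f"unsupported pyramid level {level}")
    if not annotations.polygons:
        return np.zeros(dims, dtype=bool)
    return rasterize_polygons(annotations.polygons, dims, LEVEL_FACTORS[level])


def compute_tissue_mask(rgb_image: np.ndarray,
                        params: TissueMaskParams | None = None) -> np.ndarray:
    """Otsu threshold on HSV saturation, then closing and clean-up."""
    params = params or TissueMaskParams()
    rgb_image = np.asarray(rgb_image)
    if rgb_image.ndim != 3 or rgb_image.shape[2] != 3:
        raise ValueError("expected an H x W x 3 RGB image")
    sat = skcolor.rgb2hsv(rgb_image)[:, :, 1]
    if np.ptp(sat) < 1e-9:
        warnings.warn("constant saturation: Otsu undefined, returning "
                      "all-background mask", stacklevel=2)
        return np.zeros(sat.shape, dtype=bool)
    # per-slide threshold on the full 256-bin saturation histogram
    thr = threshold_otsu(sat, nbins=256)
    mask = sat > thr
    if params.closing_radius > 0:
        mask = morphology.closing(mask, morphology.disk(params.closing_radius))
    if params.min_hole_area > 0:
        # remove holes strictly smaller than the stated area
        mask = morphology.remove_small_holes(mask, max_size=params.min_hole_area - 1)
    if params.min_object_area > 0:
        mask = morphology.remove_small_objects(mask, max_size=params.min_object_area - 1)
    return mask.astype(bool)


def derive_masks(tissue: np.ndarray, cancer: np.ndarray, level: int = 2) -> SlideMaskSet:
    """Combine tissue and cancer into the three-mask set.

    The cancer mask is kept verbatim even across tissue-mask holes; the
    non-cancer mask is tissue outside the annotations.
    """
    tissue = np.asarray(tissue, dtype=bool)
    cancer = np.asarray(cancer, dtype=bool)
    if tissue.shape != cancer.shape:
        raise ValueError(f"mask dims differ: {tissue.shape} vs {cancer.shape}")
    return SlideMaskSet(tissue=tissue, cancer=cancer,
                        noncancer=tissue & ~cancer, level=level)
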