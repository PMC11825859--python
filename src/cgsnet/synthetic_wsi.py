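"""Synthetic pyramidal H&E-like slides with cancer annotations.

The generator emulates the inputs of a whole-slide segmentation pipeline at
desk scale: pink-purple tissue blobs on bright glass background, polygonal
cancer annotations in level-0 coordinates, a two-level pyramid (level-2
detail, level-3 context, a 2x linear scale apart) and exact per-level
ground-truth masks.

The slides deliberately contain an *ambiguous-texture* zone: tissue within a
band around each cancer boundary is drawn from one shared color/texture
distribution on both sides of the boundary, so the label of those pixels is
not decidable from local appearance alone.  A wide enough band places the
discriminative cancer-core colors outside a detail patch's field of view but
inside the co-centred context patch's, which is what a context-aware model
is supposed to exploit.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .slide_masks import (AnnotationSet, SlideMaskSet, derive_masks,
                          rasterize_polygons)

LEVEL2_FACTOR = 4      # level-0 -> level-2 linear downscale
LEVEL3_FACTOR = 8      # level-0 -> level-3 linear downscale
LEVEL2_MPP = 3.89
LEVEL3_MPP = 7.8
PATCH = 224

# default color model (RGB mean, RGB std): eosin-pink tissue, bright glass,
# hematoxylin-purple cancer cores, and the shared boundary-band distribution
DEFAULT_COLORS = {
    "background": ((242.0, 240.0, 242.0), 2.5),
    "tissue": ((205.0, 140.0, 185.0), 10.0),
    "cancer": ((120.0, 70.0, 150.0), 10.0),
    "ambiguous": ((170.0, 110.0, 170.0), 10.0),
}


@dataclass
class SyntheticSlideSpec:
    level2_width: int = 1024
    level2_height: int = 1024
    tissue_blob_count: int = 3
    tissue_color_model: dict = field(default_factory=lambda: dict(DEFAULT_COLORS))
    cancer_polygons: list = field(default_factory=list)   # level-0 coordinates
    small_tumor: bool = False
    ambiguous_texture_fraction: float = 0.0
    # explicit widths (level-2 px) of the shared-appearance band around
    # cancer boundaries (inward / outward); override the quantile implied by
    # the fraction
    ambiguous_band_px: float | None = None
    ambiguous_band_out_px: float | None = None
    seed: int = 0
    slide_id: str = "synthetic"

    def __post_init__(self):
        if self.level2_width < 3 * PATCH or self.level2_height < 3 * PATCH:
            raise ValueError(
                "slide must be at least 672 px per axis at level 2 "
                f"(got {self.level2_width}x{self.level2_height})")
        if not 0.0 <= self.ambiguous_texture_fraction <= 1.0:
            raise ValueError("ambiguous_texture_fraction must be in [0, 1]")
        w0 = self.level2_width * LEVEL2_FACTOR
        h0 = self.level2_height * LEVEL2_FACTOR
        for i, poly in enumerate(self.cancer_polygons):
            arr = np.asarray(poly, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
                raise ValueError(f"polygon {i} must be a ring of >= 3 (x, y) vertices")
            if (arr < 0).any() or (arr[:, 0] > w0).any() or (arr[:, 1] > h0).any():
                raise ValueError(
                    f"polygon {i} exceeds the level-0 slide bounds {w0}x{h0}")


@dataclass
class SlidePyramid:
    level2_image: np.ndarray
    level3_image: np.ndarray
    level2_mpp: float = LEVEL2_MPP
    level3_mpp: float = LEVEL3_MPP
    slide_id: str = "synthetic"


@dataclass
class SyntheticSlide:
    """A generated slide bundled with its annotations and ground truth."""

    pyramid: SlidePyramid
    annotations: AnnotationSet
    masks: dict[int, SlideMaskSet]        # level -> ground-truth masks
    spec: SyntheticSlideSpec
    stratum: str = "noncancer"

    @property
    def slide_id(self) -> str:
        if self.pyramid is not None:
            return self.pyramid.slide_id
        return self.spec.slide_id


def box_downsample_2x(image: np.ndarray) -> np.ndarray:
    """2x2 block mean with floor rounding; odd axes are edge-padded first."""
    h, w = image.shape[:2]
    ph, pw = h % 2, w % 2
    if ph or pw:
        image = np.pad(image, ((0, ph), (0, pw), (0, 0)), mode="edge")
    blocks = image.reshape(image.shape[0] // 2, 2, image.shape[1] // 2, 2, -1)
    return (blocks.astype(np.uint32).sum(axis=(1, 3)) // 4).astype(np.uint8)


def _tissue_blobs(spec: SyntheticSlideSpec, rng: np.random.Generator) -> np.ndarray:
    """Union of smoothed random ellipses as the tissue footprint (level 2)."""
    h, w = spec.level2_height, spec.level2_width
    yy, xx = np.mgrid[0:h, 0:w]
    mask = np.zeros((h, w), dtype=bool)
    for _ in range(spec.tissue_blob_count):
        cy = rng.uniform(0.22 * h, 0.78 * h)
        cx = rng.uniform(0.22 * w, 0.78 * w)
        ry = rng.uniform(0.18, 0.34) * h
        rx = rng.uniform(0.18, 0.34) * w
        theta = rng.uniform(0, np.pi)
        dy, dx = yy - cy, xx - cx
        u = dx * np.cos(theta) + dy * np.sin(theta)
        v = -dx * np.sin(theta) + dy * np.cos(theta)
        mask |= (u / rx) ** 2 + (v / ry) ** 2 <= 1.0
    return mask


def _paint(shape, color_model, region_labels, rng):
    """Render pixel noise per region; labels: 0 bg, 1 tissue, 2 cancer, 3 ambiguous."""
    names = ["background", "tissue", "cancer", "ambiguous"]
    img = np.empty(shape + (3,), dtype=np.float32)
    for code, name in enumerate(names):
        sel = region_labels == code
        if not sel.any():
            continue
        mean, std = color_model[name]
        img[sel] = np.asarray(mean) + rng.standard_normal((sel.sum(), 3)) * std
    return np.clip(img, 0, 255).astype(np.uint8)


def generate_slide(spec: SyntheticSlideSpec):
    """Render one slide; returns (SlidePyramid, AnnotationSet, masks per level)."""
    rng = np.random.default_rng(spec.seed)
    h2, w2 = spec.level2_height, spec.level2_width
    annotations = AnnotationSet(
        polygons=[np.asarray(p, dtype=float) for p in spec.cancer_polygons],
        slide_id=spec.slide_id)

    tissue2 = _tissue_blobs(spec, rng)
    cancer2 = rasterize_polygons(annotations.polygons, (h2, w2), LEVEL2_FACTOR)
    tissue2 |= cancer2                       # annotated area is tissue by construction

    labels = np.zeros((h2, w2), dtype=np.uint8)
    labels[tissue2] = 1
    labels[cancer2] = 2
    band = spec.ambiguous_band_px
    if (spec.ambiguous_texture_fraction > 0 or band) and cancer2.any():
        # band of shared appearance around each cancer boundary, sized either
        # explicitly or by the requested quantile of boundary distance
        inside = ndimage.distance_transform_edt(cancer2)
        outside = ndimage.distance_transform_edt(~cancer2)
        dist = np.where(cancer2, inside, outside)
        if band is None:
            band = np.quantile(dist[tissue2], spec.ambiguous_texture_fraction)
        band_out = spec.ambiguous_band_out_px or band
        ambig = np.where(cancer2, dist <= band, dist <= band_out)
        labels[ambig & tissue2] = 3

    level2 = _paint((h2, w2), spec.tissue_color_model, labels, rng)
    level3 = box_downsample_2x(level2)

    masks2 = derive_masks(tissue2, cancer2, level=2)
    h3, w3 = level3.shape[:2]
    cancer3 = rasterize_polygons(annotations.polygons, (h3, w3), LEVEL3_FACTOR)
    tissue3 = _downsample_mask(tissue2, (h3, w3)) | cancer3
    masks3 = derive_masks(tissue3, cancer3, level=3)

    pyramid = SlidePyramid(level2_image=level2, level3_image=level3,
                           slide_id=spec.slide_id)
    return pyramid, annotations, {2: masks2, 3: masks3}


def _downsample_mask(mask: np.ndarray, dims: tuple[int, int]) -> np.ndarray:
    h, w = mask.shape
    ph, pw = h % 2, w % 2
    if ph or pw:
        mask = np.pad(mask, ((0, ph), (0, pw)), mode="edge")
    blocks = mask.reshape(mask.shape[0] // 2, 2, mask.shape[1] // 2, 2)
    return blocks.sum(axis=(1, 3)) >= 2


# ------------------------------------------------------------------ cohorts
def _square(cx, cy, half):
    return np.array([[cx - half, cy - half], [cx + half, cy - half],
                     [cx + half, cy + half], [cx - half, cy + half]], dtype=float)


def _blob_polygon(cx, cy, radius, rng, n_vertices=14, rad_lo=0.7):
    ang = np.sort(rng.uniform(0, 2 * np.pi, n_vertices))
    rad = radius * rng.uniform(rad_lo, 1.0, n_vertices)
    return np.stack([cx + rad * np.cos(ang), cy + rad * np.sin(ang)], axis=1)


def generate_cohort(n_noncancer: int, n_cancer: int, n_cancer_unique: int,
                    seed: int = 0, level2_size: int = 1024,
                    ambiguous_texture_fraction: float = 0.0) -> list[SyntheticSlide]:
    """Slides of the three strata: non-cancer, cancer, and cancer-unique
    (tumor bounding box fits inside a single 224 px detail patch)."""
    for name, n in (("n_noncancer", n_noncancer), ("n_cancer", n_cancer),
                    ("n_cancer_unique", n_cancer_unique)):
        if n < 0:
            raise ValueError(f"{name} must be >= 0")
    if n_noncancer + n_cancer + n_cancer_unique == 0:
        raise ValueError("empty cohort")
    rng = np.random.default_rng(seed)
    w0 = level2_size * LEVEL2_FACTOR
    slides = []
    idx = 0

    def make(stratum):
        nonlocal idx
        sub_seed = int(rng.integers(0, 2**31 - 1))
        sub = np.random.default_rng(sub_seed)
        polys = []
        small = False
        if stratum == "cancer":
            for _ in range(int(sub.integers(1, 3))):
                r = sub.uniform(0.12, 0.22) * w0
                cx = sub.uniform(0.3 * w0, 0.7 * w0)
                cy = sub.uniform(0.3 * w0, 0.7 * w0)
                polys.append(_blob_polygon(cx, cy, r, sub))
        elif stratum == "cancer_unique":
            small = True
            half = sub.uniform(0.3, 0.5) * (PATCH / 2) * LEVEL2_FACTOR
            cx = sub.uniform(0.35 * w0, 0.65 * w0)
            cy = sub.uniform(0.35 * w0, 0.65 * w0)
            polys.append(_blob_polygon(cx, cy, half, sub, n_vertices=10))
        for p in polys:
            np.clip(p, 8.0, w0 - 8.0, out=p)
        spec = SyntheticSlideSpec(
            level2_width=level2_size, level2_height=level2_size,
            cancer_polygons=polys, small_tumor=small,
            ambiguous_texture_fraction=(ambiguous_texture_fraction
                                        if stratum != "noncancer" else 0.0),
            seed=sub_seed, slide_id=f"{stratum}_{idx:03d}")
        pyramid, annotations, masks = generate_slide(spec)
        slides.append(SyntheticSlide(pyramid, annotations, masks, spec, stratum))
        idx += 1

    for _ in range(n_noncancer):
        make("noncancer")
    for _ in range(n_cancer):
        make("cancer")
    for _ in range(n_cancer_unique):
        make("cancer_unique")
    return slides


# -------------------------------------------------------------- persistence
def write_annotation_xml(polygons, path: str | Path):
    """ASAP-dialect annotation XML (level-0 coordinates)."""
    from lxml import etree

    polygons = [np.asarray(p, dtype=float) for p in polygons]
    if not polygons:
        raise ValueError("cannot write an empty annotation set")
    root = etree.Element("ASAP_Annotations")
    annos = etree.SubElement(root, "Annotations")
    for i, poly in enumerate(polygons):
        anno = etree.SubElement(annos, "Annotation", Name=f"Annotation {i}",
                                Type="Polygon", PartOfGroup="None", Color="#F4FA58")
        coords = etree.SubElement(anno, "Coordinates")
        for order, (x, y) in enumerate(poly):
            etree.SubElement(coords, "Coordinate", Order=str(order),
                             X=repr(float(x)), Y=repr(float(y)))
    etree.SubElement(root, "AnnotationGroups")
    Path(path).write_bytes(etree.tostring(root, pretty_print=True,
                                          xml_declaration=True, encoding="UTF-8"))


def write_slide(slide: SyntheticSlide, out_dir: str | Path):
    """Two-level pyramidal TIFF + annotation XML + JSON spec sidecar."""
    import tifffile

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sid = slide.slide_id
    with tifffile.TiffWriter(out_dir / f"{sid}.tif") as tw:
        tw.write(slide.pyramid.level2_image, subifds=1,
                 metadata={"mpp": LEVEL2_MPP})
        tw.write(slide.pyramid.level3_image, subfiletype=1,
                 metadata={"mpp": LEVEL3_MPP})
    if slide.annotations.polygons:
        write_annotation_xml(slide.annotations.polygons, out_dir / f"{sid}.xml")
    spec = slide.spec
    sidecar = {
        "slide_id": sid, "stratum": slide.stratum, "seed": spec.seed,
        "level2_size": [spec.level2_width, spec.level2_height],
        "small_tumor": spec.small_tumor,
        "ambiguous_texture_fraction": spec.ambiguous_texture_fraction,
        "n_polygons": len(spec.cancer_polygons),
    }
    (out_dir / f"{sid}.json").write_text(json.dumps(sidecar, indent=1))
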