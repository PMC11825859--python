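"""Five-category multi-pass patch extraction with quotas and fallbacks.

Patch centers are proposed at level 2 (224 x 224 windows, half-open
[c-112, c+112)), assessed against the slide masks, and accepted when the
category's pass criteria hold and the window overlaps every previously
accepted window on the slide by less than 50%.  Cancer and boundary
categories relax their criteria over passes as attempts accumulate; cancer
slides that still fall short of 80 cancer patches are topped up from
annotation vertices with all quality control waived (deliberate
oversampling of small cancer regions).
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np
from scipy import ndimage

from .slide_masks import SlideMaskSet, LEVEL_FACTORS
from .synthetic_wsi import SyntheticSlide, PATCH

HALF = PATCH // 2


class PatchCategory(str, Enum):
    noncancer_from_noncancer_slide = "noncancer_from_noncancer_slide"
    noncancer_from_cancer_slide = "noncancer_from_cancer_slide"
    cancer = "cancer"
    cancer_boundary = "cancer_boundary"
    noncancer_island_boundary = "noncancer_island_boundary"


BOUNDARY_CATEGORIES = (PatchCategory.cancer_boundary,
                       PatchCategory.noncancer_island_boundary)
NONCANCER_CATEGORIES = (PatchCategory.noncancer_from_noncancer_slide,
                        PatchCategory.noncancer_from_cancer_slide)


@dataclass(frozen=True)
class PassRule:
    attempt_lo: int                 # inclusive, 1-based
    attempt_hi: int                 # inclusive
    tissue_min: float               # required tissue fraction
    tissue_strict: bool             # True: frac > min; False: frac >= min
    cancer_lo: float
    cancer_hi: float


@dataclass
class PassSchedule:
    """Per-category ordered pass rules; attempt ranges partition [1, cap]."""

    rules: dict = field(default_factory=dict)

    @staticmethod
    def default(attempt_cap: int = 25_000, boundary_switch: int = 10_000,
                final_pass_start: int = 22_000) -> "PassSchedule":
        r = {
            PatchCategory.cancer: [
                PassRule(1, boundary_switch, 0.75, True, 0.75, 1.0),
                PassRule(boundary_switch + 1, attempt_cap, 0.75, True, 0.45, 1.0),
            ],
            PatchCategory.noncancer_from_noncancer_slide: [
                PassRule(1, attempt_cap, 0.75, True, 0.0, 0.0),
            ],
            PatchCategory.noncancer_from_cancer_slide: [
                PassRule(1, attempt_cap, 0.75, True, 0.0, 0.0),
            ],
        }
        for cat in BOUNDARY_CATEGORIES:
            r[cat] = [
                PassRule(1, boundary_switch, 0.75, True, 0.40, 0.75),
                PassRule(boundary_switch + 1, final_pass_start - 1, 0.50, False, 0.20, 0.75),
                PassRule(final_pass_start, attempt_cap, 0.25, False, 0.10, 0.90),
            ]
        return PassSchedule(rules=r)

    def pass_for_attempt(self, category: PatchCategory, attempt: int) -> int:
        for i, rule in enumerate(self.rules[category], start=1):
            if rule.attempt_lo <= attempt <= rule.attempt_hi:
                return i
        return len(self.rules[category])


@dataclass
class QuotaConfig:
    noncancer_per_cancer_slide: int = 50
    cancer_per_cancer_slide: int = 25
    cancer_boundary: int = 50
    island_boundary: int = 25
    noncancer_per_noncancer_slide: int = 25
    attempt_cap: int = 25_000
    boundary_band: int = 112
    min_cancer_patches: int = 80
    seed_pairs: int = 10

    def for_category(self, category: PatchCategory) -> int:
        return {
            PatchCategory.noncancer_from_noncancer_slide: self.noncancer_per_noncancer_slide,
            PatchCategory.noncancer_from_cancer_slide: self.noncancer_per_cancer_slide,
            PatchCategory.cancer: self.cancer_per_cancer_slide,
            PatchCategory.cancer_boundary: self.cancer_boundary,
            PatchCategory.noncancer_island_boundary: self.island_boundary,
        }[category]


@dataclass
class PatchRecord:
    slide_id: str
    category: PatchCategory
    center: tuple[int, int]           # (cx, cy), level-2, 0-based
    pass_index: int
    tissue_frac: float
    cancer_frac: float
    fallback: bool = False
    # accepted through the glass-boundary exemption (annotation along the
    # slide background): the cancer criterion held but the tissue one did not
    glass_exempt: bool = False
    split: str | None = None


@dataclass
class PatchPair:
    detail_image: np.ndarray          # 224 x 224 x 3
    context_image: np.ndarray         # 224 x 224 x 3
    detail_mask: np.ndarray           # 224 x 224 binary
    context_mask: np.ndarray
    record: PatchRecord


# ---------------------------------------------------------------- primitives
def window_in_bounds(center, dims) -> bool:
    cx, cy = center
    h, w = dims
    return HALF <= cx <= w - HALF and HALF <= cy <= h - HALF


def assess(center, masks: SlideMaskSet):
    """(tissue_frac, cancer_frac) of the 224 window, or None if out of bounds."""
    if masks.level != 2:
        raise ValueError("patch QC references the level-2 masks")
    if not window_in_bounds(center, masks.dims):
        return None
    cx, cy = center
    sl = np.s_[cy - HALF:cy + HALF, cx - HALF:cx + HALF]
    area = float(PATCH * PATCH)
    return (float(masks.tissue[sl].sum()) / area,
            float(masks.cancer[sl].sum()) / area)


def meets_criteria(category: PatchCategory, pass_index: int, fracs,
                   schedule: PassSchedule) -> bool:
    """Pure predicate: do the window fractions satisfy the pass rule?"""
    if category not in schedule.rules:
        raise ValueError(f"unknown category {category!r}")
    rules = schedule.rules[category]
    if not 1 <= pass_index <= len(rules):
        raise ValueError(f"pass {pass_index} invalid for {category.value}")
    rule = rules[pass_index - 1]
    tissue, cancer = fracs
    tissue_ok = tissue > rule.tissue_min if rule.tissue_strict else tissue >= rule.tissue_min
    if category in NONCANCER_CATEGORIES:
        return tissue_ok and cancer == 0.0
    return tissue_ok and rule.cancer_lo <= cancer <= rule.cancer_hi


def overlap_fraction(c1, c2) -> float:
    """Intersection of the two 224 windows over the single-window area."""
    dx = abs(c1[0] - c2[0])
    dy = abs(c1[1] - c2[1])
    return max(0, PATCH - dx) * max(0, PATCH - dy) / float(PATCH * PATCH)


def _scaled_edges(annotations, level: int = 2):
    f = LEVEL_FACTORS[level]
    edges = []
    for poly in annotations.polygons:
        pts = np.asarray(poly, dtype=float) / f
        edges.extend(zip(pts, np.roll(pts, -1, axis=0)))
    return edges


def boundary_center(annotations, rng: np.random.Generator,
                    band: int = 112) -> tuple[int, int]:
    """A level-2 center within Chebyshev distance ``band`` of a polygon edge."""
    if not annotations.polygons:
        raise ValueError("boundary sampling on a slide without annotations")
    edges = _scaled_edges(annotations)
    lengths = np.array([np.linalg.norm(b - a) for a, b in edges])
    probs = lengths / lengths.sum() if lengths.sum() > 0 else None
    a, b = edges[rng.choice(len(edges), p=probs)]
    point = a + rng.random() * (b - a)
    off = rng.uniform(-band, band, size=2)
    return int(round(point[0] + off[0])), int(round(point[1] + off[1]))


def small_tumor_seeds(annotations, rng: np.random.Generator,
                      n_seeds: int = 10) -> list[tuple[int, int]]:
    """Annotation vertices (scaled to level 2) used as guaranteed centers."""
    if not annotations.polygons:
        raise ValueError("no annotations to seed from")
    verts = np.concatenate([np.asarray(p) for p in annotations.polygons]) / LEVEL_FACTORS[2]
    idx = rng.choice(len(verts), size=n_seeds, replace=True)
    return [(int(round(x)), int(round(y))) for x, y in verts[idx]]


def _island_edges(masks: SlideMaskSet):
    """Edges of non-cancer pockets enclosed by cancer, as pixel coordinates."""
    cancer = masks.cancer
    filled = ndimage.binary_fill_holes(cancer)
    islands = filled & ~cancer
    if not islands.any():
        return None
    eroded = ndimage.binary_erosion(islands)
    border = islands & ~eroded
    ys, xs = np.nonzero(border)
    return np.stack([xs, ys], axis=1)


def _glass_edge_map(masks: SlideMaskSet, annotations, band: int = 112) -> np.ndarray:
    """Polygon-edge pixels lying within ``band`` px of non-tissue (glass)."""
    h, w = masks.dims
    edge_mask = np.zeros((h, w), dtype=bool)
    for a, b in _scaled_edges(annotations):
        n = max(int(np.ceil(np.linalg.norm(b - a))), 1)
        t = np.linspace(0.0, 1.0, n + 1)[:, None]
        pts = np.round(a + t * (b - a)).astype(int)
        ok = (pts[:, 0] >= 0) & (pts[:, 0] < w) & (pts[:, 1] >= 0) & (pts[:, 1] < h)
        edge_mask[pts[ok, 1], pts[ok, 0]] = True
    glass_dist = ndimage.distance_transform_edt(masks.tissue)
    return edge_mask & (glass_dist <= band)


# ------------------------------------------------------------------ sampling
def sample_category(slide: SyntheticSlide, category: PatchCategory,
                    quota: int, schedule: PassSchedule,
                    rng: np.random.Generator,
                    accepted_so_far: list[PatchRecord] | None = None,
                    quotas: QuotaConfig | None = None,
                    seed_centers: list | None = None) -> list[PatchRecord]:
    """Sample up to ``quota`` records of one category on one slide."""
    quotas = quotas or QuotaConfig()
    masks = slide.masks[2]
    h, w = masks.dims
    accepted = list(accepted_so_far or [])
    out: list[PatchRecord] = []

    cancer_pixels = None
    island_pts = None
    glass_edges = None
    if category == PatchCategory.cancer:
        ys, xs = np.nonzero(masks.cancer)
        if len(ys) == 0:
            return []
        cancer_pixels = (xs, ys)
    if category == PatchCategory.noncancer_island_boundary:
        island_pts = _island_edges(masks)
        if island_pts is None:
            return []
    if category in (PatchCategory.cancer,) + BOUNDARY_CATEGORIES:
        if slide.annotations.polygons:
            glass_edges = _glass_edge_map(masks, slide.annotations,
                                          quotas.boundary_band)

    seeds = list(seed_centers or [])

    def propose(attempt):
        if seeds:
            return seeds.pop(0)
        if category in NONCANCER_CATEGORIES:
            return (int(rng.integers(0, w)), int(rng.integers(0, h)))
        if category == PatchCategory.cancer:
            i = int(rng.integers(0, len(cancer_pixels[0])))
            return (int(cancer_pixels[0][i]), int(cancer_pixels[1][i]))
        if category == PatchCategory.cancer_boundary:
            return boundary_center(slide.annotations, rng, quotas.boundary_band)
        # island boundary: jitter around island-border pixels
        i = int(rng.integers(0, len(island_pts)))
        off = rng.uniform(-quotas.boundary_band, quotas.boundary_band, size=2)
        return (int(round(island_pts[i][0] + off[0])),
                int(round(island_pts[i][1] + off[1])))

    n_passes = len(schedule.rules[category])
    for attempt in range(1, quotas.attempt_cap + 1):
        if len(out) >= quota:
            break
        center = propose(attempt)
        fracs = assess(center, masks)
        if fracs is None:
            continue                    # window out of bounds: attempt consumed
        pass_index = schedule.pass_for_attempt(category, attempt)
        ok = meets_criteria(category, pass_index, fracs, schedule)
        exempt = False
        if not ok and category not in NONCANCER_CATEGORIES and pass_index == n_passes:
            # glass-boundary exemption: tissue criterion alone may fail when
            # the annotation runs along the glass edge
            rule = schedule.rules[category][pass_index - 1]
            cancer_ok = rule.cancer_lo <= fracs[1] <= rule.cancer_hi
            if cancer_ok and glass_edges is not None and _window_touches(
                    glass_edges, center):
                ok = exempt = True
        if not ok:
            continue
        if any(overlap_fraction(center, r.center) >= 0.5 for r in accepted):
            continue
        rec = PatchRecord(slide_id=slide.slide_id, category=category,
                          center=center, pass_index=pass_index,
                          tissue_frac=fracs[0], cancer_frac=fracs[1],
                          glass_exempt=exempt)
        out.append(rec)
        accepted.append(rec)
    return out


def _window_touches(mask: np.ndarray, center) -> bool:
    cx, cy = center
    h, w = mask.shape
    sl = np.s_[max(cy - HALF, 0):min(cy + HALF, h),
               max(cx - HALF, 0):min(cx + HALF, w)]
    return bool(mask[sl].any())


def deficit_reallocation(counts: dict, quotas: dict) -> dict:
    """Move unmet quota to the closest category.

    cancer_boundary <-> noncancer_island_boundary, cancer -> cancer_boundary;
    non-cancer categories are never reallocated.
    """
    adjusted = dict(quotas)
    for cat, q in quotas.items():
        if counts.get(cat, 0) > q:
            raise ValueError(f"count exceeds quota for {cat}")
    cb = PatchCategory.cancer_boundary
    ib = PatchCategory.noncancer_island_boundary
    ca = PatchCategory.cancer
    short = {c: quotas.get(c, 0) - counts.get(c, 0) for c in (ca, cb, ib)}
    if short.get(ca, 0) > 0:
        adjusted[cb] = adjusted.get(cb, 0) + short[ca]
    if short.get(cb, 0) > 0:
        adjusted[ib] = adjusted.get(ib, 0) + short[cb]
    if short.get(ib, 0) > 0:
        adjusted[cb] = adjusted.get(cb, 0) + short[ib]
    return adjusted


def cancer_fallback(slide: SyntheticSlide, existing_count: int,
                    rng: np.random.Generator,
                    floor: int = 80) -> list[PatchRecord]:
    """Top up to the cancer floor from annotation vertices, ignoring all QC."""
    if not slide.annotations.polygons:
        raise ValueError("cancer fallback requires an annotated (cancer) slide")
    if existing_count >= floor:
        return []
    masks = slide.masks[2]
    h, w = masks.dims
    verts = np.concatenate([np.asarray(p) for p in slide.annotations.polygons])
    verts = verts / LEVEL_FACTORS[2]
    out = []
    for _ in range(floor - existing_count):
        x, y = verts[int(rng.integers(0, len(verts)))]
        cx = int(np.clip(round(x), HALF, w - HALF))
        cy = int(np.clip(round(y), HALF, h - HALF))
        fr = assess((cx, cy), masks)
        out.append(PatchRecord(slide_id=slide.slide_id,
                               category=PatchCategory.cancer,
                               center=(cx, cy), pass_index=0,
                               tissue_frac=fr[0], cancer_frac=fr[1],
                               fallback=True))
    return out


# -------------------------------------------------------------- orchestration
def sample_slide(slide: SyntheticSlide, quotas: QuotaConfig | None = None,
                 schedule: PassSchedule | None = None,
                 seed: int = 0) -> list[PatchRecord]:
    """All categories for one slide, with reallocation and the cancer floor."""
    quotas = quotas or QuotaConfig()
    schedule = schedule or PassSchedule.default(quotas.attempt_cap)
    rng = np.random.default_rng((seed, _stable_hash(slide.slide_id)))
    records: list[PatchRecord] = []
    is_cancer_slide = bool(slide.annotations.polygons)

    if not is_cancer_slide:
        records += sample_category(
            slide, PatchCategory.noncancer_from_noncancer_slide,
            quotas.noncancer_per_noncancer_slide, schedule, rng, records,
            quotas)
        return records

    seeds = (small_tumor_seeds(slide.annotations, rng, quotas.seed_pairs)
             if slide.spec.small_tumor else None)
    base = {
        PatchCategory.cancer: quotas.cancer_per_cancer_slide,
        PatchCategory.cancer_boundary: quotas.cancer_boundary,
        PatchCategory.noncancer_island_boundary: quotas.island_boundary,
    }
    counts: dict = {}
    for cat, q in base.items():
        got = sample_category(slide, cat, q, schedule, rng, records, quotas,
                              seed_centers=seeds if cat == PatchCategory.cancer_boundary else None)
        records += got
        counts[cat] = len(got)
    adjusted = deficit_reallocation(counts, base)
    for cat in (PatchCategory.cancer_boundary,
                PatchCategory.noncancer_island_boundary):
        extra = adjusted[cat] - base[cat]
        if extra > 0 and counts[cat] >= base[cat]:
            records += sample_category(slide, cat, extra, schedule, rng,
                                       records, quotas)
    records += sample_category(
        slide, PatchCategory.noncancer_from_cancer_slide,
        quotas.noncancer_per_cancer_slide, schedule, rng, records, quotas)

    n_cancerous = sum(1 for r in records if r.cancer_frac > 0)
    records += cancer_fallback(slide, n_cancerous, rng,
                               quotas.min_cancer_patches)
    return records


def _stable_hash(text: str) -> int:
    import hashlib
    return int.from_bytes(hashlib.sha256(text.encode()).digest()[:4], "big")


# ----------------------------------------------------------------- extraction
def extract_pair(slide: SyntheticSlide, record: PatchRecord) -> PatchPair:
    """Co-centred detail (level-2) and context (level-3) crops with masks."""
    if record.slide_id != slide.slide_id:
        raise ValueError(f"record belongs to slide '{record.slide_id}', "
                         f"not '{slide.slide_id}'")
    cx, cy = record.center
    det = slide.pyramid.level2_image[cy - HALF:cy + HALF, cx - HALF:cx + HALF]
    det_mask = slide.masks[2].cancer[cy - HALF:cy + HALF, cx - HALF:cx + HALF]
    c3x, c3y = cx // 2, cy // 2
    ctx = _crop_edge_padded(slide.pyramid.level3_image, c3x, c3y)
    ctx_mask = _crop_edge_padded(slide.masks[3].cancer, c3x, c3y)
    return PatchPair(detail_image=det, context_image=ctx,
                     detail_mask=det_mask.astype(np.uint8),
                     context_mask=ctx_mask.astype(np.uint8), record=record)


def _crop_edge_padded(img: np.ndarray, cx: int, cy: int, size: int = PATCH):
    h, w = img.shape[:2]
    ys = np.clip(np.arange(cy - size // 2, cy + size // 2), 0, h - 1)
    xs = np.clip(np.arange(cx - size // 2, cx + size // 2), 0, w - 1)
    return img[np.ix_(ys, xs)]


# -------------------------------------------------------------------- splits
@dataclass
class DatasetManifest:
    assignments: dict[str, str]        # slide_id -> split
    strata: dict[str, str]             # slide_id -> stratum
    records: list[PatchRecord] = field(default_factory=list)

    def split_of(self, slide_id: str) -> str:
        return self.assignments[slide_id]

    def to_dataframe(self):
        import pandas as pd
        rows = [dict(slide_id=r.slide_id, split=self.assignments[r.slide_id],
                     category=r.category.value, pass_index=r.pass_index,
                     cx=r.center[0], cy=r.center[1],
                     tissue_frac=r.tissue_frac, cancer_frac=r.cancer_frac,
                     fallback=r.fallback, glass_exempt=r.glass_exempt)
                for r in self.records]
        return pd.DataFrame(rows)

    def checksum(self) -> str:
        import hashlib
        df = self.to_dataframe()
        return hashlib.sha256(df.to_csv(index=False).encode()).hexdigest()


def split_slides(cohort: list[SyntheticSlide], ratios=(0.6, 0.2, 0.2),
                 seed: int = 0) -> DatasetManifest:
    """Stratified slide-level 60/20/20 split (no patch-level leakage)."""
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError("split ratios must sum to 1")
    rng = np.random.default_rng(seed)
    assignments: dict[str, str] = {}
    strata = {s.slide_id: s.stratum for s in cohort}
    split_names = ("train", "val", "test")
    for stratum in sorted({s.stratum for s in cohort}):
        ids = sorted(s.slide_id for s in cohort if s.stratum == stratum)
        if not ids:
            raise ValueError(f"stratum '{stratum}' is empty")
        perm = rng.permutation(len(ids))
        n = len(ids)
        # largest-remainder allocation over the three splits
        raw = np.array(ratios) * n
        base = np.floor(raw).astype(int)
        rem = n - base.sum()
        order = np.argsort(-(raw - base))
        for k in range(rem):
            base[order[k]] += 1
        pos = 0
        for split, cnt in zip(split_names, base):
            for j in range(cnt):
                assignments[ids[perm[pos]]] = split
                pos += 1
    return DatasetManifest(assignments=assignments, strata=strata)


def build_dataset(cohort: list[SyntheticSlide], quotas: QuotaConfig | None = None,
                  schedule: PassSchedule | None = None, seed: int = 0,
                  ratios=(0.6, 0.2, 0.2)) -> DatasetManifest:
    """Split the cohort, sample every slide, and tag records with splits."""
    manifest = split_slides(cohort, ratios, seed)
    for slide in cohort:
        recs = sample_slide(slide, quotas, schedule, seed)
        for r in recs:
            r.split = manifest.assignments[r.slide_id]
        manifest.records.extend(recs)
    return manifest
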