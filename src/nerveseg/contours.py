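"""Contour extraction, shape filtering and polyline simplification.

Contours are closed polylines through boundary-pixel centers, traced with
the Moore-neighbor algorithm on 8-connected foreground components
(4-connected background), with hole boundaries attached to their parent.
Shapes are scored by circularity c = 4*pi*A/p^2 (1 for a circle) and
gated by vertex count and circularity before Ramer-Douglas-Peucker
simplification.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage
from shapely.geometry import LineString
from skimage import measure

from .filters import FilterParams, IntensityBand, apply_band, percentile_band
from .images import BinaryMask, GrayImage, InstanceLabelMap, clahe_equalize, fill_polygon


@dataclass
class Contour:
    """Closed polyline in pixel coordinates.

    ``points`` is an (N, 2) array of (x, y) vertices, implicitly closed.
    Orientation is normalized so the shoelace signed area is non-negative.
    ``parent`` holds the id of the enclosing contour for hole boundaries.
    """

    points: np.ndarray
    tissue_class: str = ""
    parent: Optional[int] = None
    id: int = 0
    strict: bool = True
    normalize: bool = True

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float).reshape(-1, 2)
        # drop consecutive duplicates (incl. wrap-around)
        if len(pts) > 1:
            keep = np.any(pts != np.roll(pts, 1, axis=0), axis=1)
            keep[0] = True
            pts = pts[keep]
            if len(pts) > 1 and np.array_equal(pts[0], pts[-1]):
                pts = pts[:-1]
        if self.strict and len(pts) < 3:
            raise ValueError("a contour needs at least 3 distinct points")
        if self.normalize and len(pts) >= 3 and _signed_area(pts) < 0:
            pts = pts[::-1].copy()
        self.points = pts

    @property
    def n_points(self) -> int:
        return len(self.points)

    @property
    def area(self) -> float:
        """Enclosed area under the shoelace formula (px^2)."""
        if len(self.points) < 3:
            return 0.0
        return float(abs(_signed_area(self.points)))

    @property
    def perimeter(self) -> float:
        """Euclidean length of the closed polyline (px)."""
        if len(self.points) < 2:
            return 0.0
        d = np.diff(np.vstack([self.points, self.points[:1]]), axis=0)
        return float(np.hypot(d[:, 0], d[:, 1]).sum())

    def centroid(self) -> Tuple[float, float]:
        """Area-weighted polygon centroid; vertex mean when area is 0."""
        pts = self.points
        if len(pts) < 3:
            return tuple(pts.mean(axis=0))
        x, y = pts[:, 0], pts[:, 1]
        xn, yn = np.roll(x, -1), np.roll(y, -1)
        cross = x * yn - xn * y
        a = cross.sum() / 2.0
        if abs(a) < 1e-12:
            return (float(x.mean()), float(y.mean()))
        cx = ((x + xn) * cross).sum() / (6.0 * a)
        cy = ((y + yn) * cross).sum() / (6.0 * a)
        return (float(cx), float(cy))


def _signed_area(pts: np.ndarray) -> float:
    x, y = pts[:, 0], pts[:, 1]
    return float((x * np.roll(y, -1) - np.roll(x, -1) * y).sum() / 2.0)


@dataclass
class ContourSet:
    """Contours extracted from one image, with provenance."""

    contours: List[Contour] = field(default_factory=list)
    source_image_id: str = ""
    pixel_size_um: float = 1.0

    def __post_init__(self) -> None:
        ids = [c.id for c in self.contours]
        if len(ids) != len(set(ids)):
            raise ValueError("contour ids must be unique")

    def __len__(self) -> int:
        return len(self.contours)

    def __iter__(self):
        return iter(self.contours)

    def top_level(self) -> List[Contour]:
        return [c for c in self.contours if c.parent is None]

    def holes_of(self, contour_id: int) -> List[Contour]:
        return [c for c in self.contours if c.parent == contour_id]


# ---------------------------------------------------------------------------
# boundary tracing

# clockwise Moore neighborhood in image coords (y down), starting east
_MOORE = ((0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1), (-1, 0), (-1, 1))


def _trace_boundary(region: np.ndarray, start: Tuple[int, int]) -> np.ndarray:
    """Moore-neighbor trace of one connected region's outer boundary.

    ``start`` must be the region's topmost-leftmost pixel (row-major scan
    order), which guarantees its west neighbor is background.  Returns the
    ordered boundary pixel chain as (x, y) rows.  Terminates when the
    initial (pixel, entry-direction) state recurs (Jacob's criterion).
    """
    h, w = region.shape
    sy, sx = start
    chain = [(sx, sy)]
    dir_index = {v: k for k, v in enumerate(_MOORE)}
    # backtrack direction: index into _MOORE pointing at the background
    # pixel the scan starts from; initially west (index 4), which is
    # guaranteed background for the topmost-leftmost start pixel
    cy, cx, back = sy, sx, 4
    first_move = None
    while True:
        move = None
        for k in range(1, 9):
            d = (back + k) % 8
            ny, nx = cy + _MOORE[d][0], cx + _MOORE[d][1]
            if 0 <= ny < h and 0 <= nx < w and region[ny, nx]:
                move = d
                dprev = (back + k - 1) % 8  # last examined background pixel
                break
        if move is None:  # isolated pixel
            break
        if first_move is None:
            first_move = move
        elif (cy, cx) == (sy, sx) and move == first_move:
            chain.pop()  # re-entered the initial state; drop duplicate start
            break
        by, bx = cy + _MOORE[dprev][0], cx + _MOORE[dprev][1]
        cy, cx = cy + _MOORE[move][0], cx + _MOORE[move][1]
        chain.append((cx, cy))
        # resume the clockwise scan from that background pixel, now
        # expressed as a direction relative to the new current pixel
        back = dir_index[(by - cy, bx - cx)]
        if len(chain) > 4 * region.size:
            raise RuntimeError("boundary trace failed to terminate")
    return np.asarray(chain, dtype=float)


def extract_contours(mask: BinaryMask, tissue_class: str = "",
                     start_id: int = 1) -> ContourSet:
    """Trace one contour per 8-connected foreground component.

    Hole boundaries (4-connected background regions enclosed by a
    component) are traced over the hole's own pixels and returned with
    ``parent`` pointing at the enclosing contour.  Components or holes
    whose chains have fewer than 3 distinct vertices are returned as
    non-strict degenerate contours so instance counts are preserved.
    """
    labels, n = ndimage.label(mask.pixels, structure=np.ones((3, 3), int))
    contours: List[Contour] = []
    next_id = start_id
    slices = ndimage.find_objects(labels)
    for lab in range(1, n + 1):
        sl = slices[lab - 1]
        region = labels[sl] == lab
        oy, ox = sl[0].start, sl[1].start
        ys, xs = np.nonzero(region)
        k = np.lexsort((xs, ys))[0]  # topmost-leftmost
        chain = _trace_boundary(region, (int(ys[k]), int(xs[k])))
        chain += (ox, oy)
        outer = Contour(chain, tissue_class=tissue_class, id=next_id,
                        strict=False)
        outer_id = next_id
        next_id += 1
        contours.append(outer)
        filled = ndimage.binary_fill_holes(region)
        holes = filled & ~region
        if holes.any():
            hlabels, hn = ndimage.label(holes, structure=np.array(
                [[0, 1, 0], [1, 1, 1], [0, 1, 0]]))
            for hl in range(1, hn + 1):
                hreg = hlabels == hl
                hy, hx = np.nonzero(hreg)
                hk = np.lexsort((hx, hy))[0]
                hchain = _trace_boundary(hreg, (int(hy[hk]), int(hx[hk])))
                hchain += (ox, oy)
                contours.append(Contour(hchain, tissue_class=tissue_class,
                                        parent=outer_id, id=next_id,
                                        strict=False))
                next_id += 1
    return ContourSet(contours)


# ---------------------------------------------------------------------------
# shape statistics and filtering


def circularity(contour: Contour) -> float:
    """c = 4*pi*(A/p^2); 1 for a perfect circle, 0 for a flat polygon."""
    p = contour.perimeter
    if p <= 0:
        raise ValueError("circularity undefined for zero perimeter")
    return 4.0 * np.pi * contour.area / (p * p)


def estimate_diameter(contour: Contour, pixel_size_um: float) -> float:
    """Circular-equivalent diameter: perimeter / pi, scaled to um."""
    p = contour.perimeter
    if p <= 0:
        raise ValueError("diameter undefined for zero perimeter")
    return p * pixel_size_um / np.pi


def filter_contours(cs: ContourSet, params: FilterParams) -> ContourSet:
    """Gate top-level contours by vertex count and circularity.

    Both tests use the raw traced contour.  Hole boundaries are not
    filtered independently: they are kept iff their parent survives.
    """
    kept: List[Contour] = []
    kept_ids = set()
    for c in cs.top_level():
        if not params.min_contour_points <= c.n_points <= params.max_contour_points:
            continue
        if c.perimeter <= 0:
            continue
        if circularity(c) < params.min_circularity:
            continue
        kept.append(c)
        kept_ids.add(c.id)
    for c in cs.contours:
        if c.parent is not None and c.parent in kept_ids:
            kept.append(c)
    return ContourSet(kept, cs.source_image_id, cs.pixel_size_um)


# ---------------------------------------------------------------------------
# Ramer-Douglas-Peucker


def _farthest_pair(pts: np.ndarray) -> Tuple[int, int]:
    """Indices of the two farthest-apart vertices."""
    n = len(pts)
    cand = np.arange(n)
    if n > 600:
        try:
            from scipy.spatial import ConvexHull

            cand = np.sort(ConvexHull(pts).vertices)
        except Exception:  # collinear or otherwise degenerate
            cand = np.array([int(pts[:, 0].argmin()), int(pts[:, 0].argmax()),
                             int(pts[:, 1].argmin()), int(pts[:, 1].argmax())])
    sub = pts[cand]
    d2 = ((sub[:, None, :] - sub[None, :, :]) ** 2).sum(-1)
    i, j = np.unravel_index(int(d2.argmax()), d2.shape)
    a, b = int(cand[i]), int(cand[j])
    return (a, b) if a < b else (b, a)


def simplify_rdp(contour: Contour, epsilon_frac: float) -> Contour:
    """Douglas-Peucker simplification with tolerance relative to perimeter.

    The closed contour is split at its two farthest-apart vertices and
    each open half simplified with epsilon = ``epsilon_frac`` times the
    input perimeter; output vertices are a subsequence of the input.
    """
    if epsilon_frac < 0:
        raise ValueError("epsilon_frac must be >= 0")
    pts = contour.points
    if len(pts) < 3:
        return replace(contour)
    eps = epsilon_frac * contour.perimeter
    i, j = _farthest_pair(pts)
    half1 = pts[i:j + 1]
    half2 = np.vstack([pts[j:], pts[:i + 1]])
    out = []
    for half in (half1, half2):
        if len(half) < 2:
            continue
        simplified = np.asarray(
            LineString(half).simplify(eps, preserve_topology=False).coords
        )
        out.append(simplified[:-1])  # endpoint repeats as next half's start
    merged = np.vstack(out)
    return Contour(merged, tissue_class=contour.tissue_class,
                   parent=contour.parent, id=contour.id, strict=False,
                   normalize=False)


# ---------------------------------------------------------------------------
# pipeline


@dataclass
class SegmentationResult:
    """Per-class output of the full segmentation pipeline."""

    contours: Dict[str, ContourSet]
    masks: Dict[str, BinaryMask]
    simplified: Dict[str, ContourSet]
    bands: Dict[str, IntensityBand]
    equalized: GrayImage


def segment_image(
    img: GrayImage,
    presets: Sequence[FilterParams],
    exclude_ids: Iterable[int] = (),
    clahe_tiles: Tuple[int, int] = (8, 8),
    clahe_clip: float = 2.0,
    gaussian_sigma: float = 0.0,
) -> SegmentationResult:
    """Run equalize -> band threshold -> trace -> filter -> simplify.

    One pass per preset; contour ids are unique across classes, and ids in
    ``exclude_ids`` are dropped before output (an explicit stand-in for
    manual false-positive removal).  ``gaussian_sigma`` optionally smooths
    the equalized image before thresholding (off by default).
    """
    eq = clahe_equalize(img, tiles=clahe_tiles, clip_limit=clahe_clip)
    if gaussian_sigma > 0:
        sm = ndimage.gaussian_filter(eq.pixels.astype(float), gaussian_sigma)
        eq = GrayImage(np.clip(np.round(sm), 0, 255).astype(np.uint8),
                       pixel_size_um=img.pixel_size_um, id=img.id)
    exclude = set(exclude_ids)
    contours: Dict[str, ContourSet] = {}
    masks: Dict[str, BinaryMask] = {}
    simplified: Dict[str, ContourSet] = {}
    bands: Dict[str, IntensityBand] = {}
    next_id = 1
    for p in presets:
        band = percentile_band(eq, p.lower_pct, p.upper_pct)
        mask = apply_band(eq, band)
        cs = extract_contours(mask, tissue_class=p.name, start_id=next_id)
        if cs.contours:
            next_id = max(c.id for c in cs.contours) + 1
        cs = filter_contours(cs, p)
        keep = [c for c in cs.contours
                if c.id not in exclude and c.parent not in exclude]
        cs = ContourSet(keep, img.id, img.pixel_size_um)
        contours[p.name] = cs
        masks[p.name] = mask
        bands[p.name] = band
        simplified[p.name] = ContourSet(
            [simplify_rdp(c, p.rdp_epsilon_frac) for c in cs.contours],
            img.id, img.pixel_size_um)
    return SegmentationResult(contours, masks, simplified, bands, eq)


def contours_to_instance_map(cs: ContourSet, shape: Tuple[int, int],
                             tissue_class: Optional[str] = None) -> InstanceLabelMap:
    """Rasterize top-level contours into an instance map (holes cleared)."""
    h, w = shape
    out = np.zeros((h, w), np.int32)
    class_of: Dict[int, str] = {}
    for c in cs.top_level():
        if c.n_points < 3:
            continue
        m = fill_polygon(c.points, h, w).astype(bool)
        for hole in cs.holes_of(c.id):
            if hole.n_points >= 3:
                m &= ~fill_polygon(hole.points, h, w).astype(bool)
            elif hole.n_points >= 1:
                hx = np.round(hole.points[:, 0]).astype(int)
                hy = np.round(hole.points[:, 1]).astype(int)
                m[hy, hx] = False
        out[m] = c.id
        class_of[c.id] = tissue_class if tissue_class is not None else c.tissue_class
    survivors = set(np.unique(out)) - {0}
    class_of = {i: cl for i, cl in class_of.items() if i in survivors}
    return InstanceLabelMap(out, class_of)


# ---------------------------------------------------------------------------
# serialization


def contour_set_to_json(cs: ContourSet, path, pixel_size_um: Optional[float] = None) -> None:
    ps = pixel_size_um if pixel_size_um is not None else cs.pixel_size_um
    payload = {
        "source_image_id": cs.source_image_id,
        "pixel_size_um": ps,
        "contours": [
            {
                "id": c.id,
                "class": c.tissue_class,
                "parent": c.parent,
                "points": c.points.tolist(),
                "n_points": c.n_points,
                "area_px2": c.area,
                "perimeter_px": c.perimeter,
            }
            for c in cs.contours
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def contour_set_from_json(path) -> ContourSet:
    with open(path) as fh:
        payload = json.load(fh)
    return ContourSet(
        [Contour(np.asarray(d["points"]), tissue_class=d["class"],
                 parent=d["parent"], id=d["id"], strict=False)
         for d in payload["contours"]],
        payload.get("source_image_id", ""),
        payload.get("pixel_size_um", 1.0),
    )
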