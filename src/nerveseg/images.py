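"""Raster carriers, label-file parsing and CLAHE preprocessing.

Conventions used throughout the package: coordinates are 0-based with
``x`` = column and ``y`` = row (y grows downward), pixel centers sit at
integer coordinates, and polygon rasterization counts boundary pixels as
interior.  Images are 8-bit grayscale; binary masks hold {0, 1} and are
stored on disk as {0, 255} PNG.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
from lxml import etree
from PIL import Image
from skimage import draw as _draw

#: Contour class vocabulary used by label documents.  Unknown names are
#: accepted with a warning so foreign dialect extensions do not hard-fail.
KNOWN_CLASSES = (
    "unmyelinated fiber",
    "myelinated fiber inner",
    "myelinated fiber outer",
    "fat",
    "Schwann cell",
    "blood vessel",
    "epineurium",
    "endoneurium",
    "axon",
    "myelin",
    "umf",
)


@dataclass
class GrayImage:
    """8-bit grayscale micrograph with physical pixel size.

    Parameters
    ----------
    pixels : ndarray of uint8, shape (H, W)
    pixel_size_um : float
        Micrometres per pixel; must be positive.
    id : str
        Free-text provenance tag.
    """

    pixels: np.ndarray
    pixel_size_um: float = 1.0
    id: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("GrayImage requires a non-empty 2-D array")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise ValueError("intensities must lie in [0, 255]")
            px = px.astype(np.uint8)
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")
        self.pixels = px

    @property
    def shape(self) -> Tuple[int, int]:
        return self.pixels.shape


@dataclass
class BinaryMask:
    """Per-class binary raster; values are exactly {0, 1}."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError("BinaryMask requires a 2-D array")
        if not np.isin(px, (0, 1)).all():
            raise ValueError("mask values must be 0 or 1")
        self.pixels = px.astype(np.uint8)

    @property
    def shape(self) -> Tuple[int, int]:
        return self.pixels.shape

    def __eq__(self, other: object) -> bool:
        return isinstance(other, BinaryMask) and np.array_equal(
            self.pixels, other.pixels
        )


@dataclass
class InstanceLabelMap:
    """Integer instance raster: 0 = background, k > 0 = instance k."""

    pixels: np.ndarray
    class_of_instance: Dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError("InstanceLabelMap requires a 2-D array")
        if px.min() < 0:
            raise ValueError("instance ids must be non-negative")
        self.pixels = px.astype(np.int32)
        present = set(np.unique(self.pixels)) - {0}
        missing = present - set(self.class_of_instance)
        if missing:
            raise ValueError(f"instances without a class: {sorted(missing)}")

    @property
    def shape(self) -> Tuple[int, int]:
        return self.pixels.shape

    def instance_ids(self) -> List[int]:
        ids = np.unique(self.pixels)
        return [int(i) for i in ids if i > 0]

    def restricted_to(self, tissue_class: str) -> "InstanceLabelMap":
        """Map with only the instances of one tissue class kept."""
        keep = {i for i, c in self.class_of_instance.items() if c == tissue_class}
        px = np.where(np.isin(self.pixels, list(keep)), self.pixels, 0)
        return InstanceLabelMap(px, {i: tissue_class for i in keep})


@dataclass
class LabelDocument:
    """Parsed contour label file: (class name, points, closed) triples."""

    contours: List[Tuple[str, List[Tuple[float, float]], bool]] = field(
        default_factory=list
    )

    def __post_init__(self) -> None:
        for name, points, closed in self.contours:
            if closed and len(points) < 3:
                raise ValueError(
                    f"closed contour '{name}' needs >= 3 points, got {len(points)}"
                )


# ---------------------------------------------------------------------------
# raster IO


def read_gray_image(path, pixel_size_um: float = 1.0) -> GrayImage:
    """Load a PNG/TIFF raster as 8-bit grayscale.

    RGB inputs are collapsed with standard luma weighting
    (ITU-R 601: 0.299 R + 0.587 G + 0.114 B).
    """
    with Image.open(path) as im:
        if im.mode not in ("L", "I;16", "I"):
            im = im.convert("L")
        arr = np.asarray(im)
    if arr.ndim != 2 or arr.size == 0:
        raise ValueError(f"{path}: expected a non-empty 2-D raster")
    if arr.dtype != np.uint8:
        arr = np.clip(arr, 0, 255).astype(np.uint8)
    return GrayImage(arr, pixel_size_um=pixel_size_um, id=str(path))


def write_gray_image(img: GrayImage, path) -> None:
    Image.fromarray(img.pixels).save(path)


def write_mask(mask: BinaryMask, path) -> None:
    """Write a mask as lossless 8-bit PNG with values {0, 255}."""
    Image.fromarray(mask.pixels * np.uint8(255)).save(path)


def read_mask(path) -> BinaryMask:
    with Image.open(path) as im:
        arr = np.asarray(im.convert("L"))
    return BinaryMask((arr > 127).astype(np.uint8))


def write_instance_map(ilm: InstanceLabelMap, png_path, json_path=None) -> None:
    """Instance raster as 16-bit PNG plus a JSON id->class mapping."""
    if ilm.pixels.max() > 65535:
        raise ValueError("more than 65535 instances cannot go in a 16-bit PNG")
    Image.fromarray(ilm.pixels.astype(np.uint16)).save(png_path)
    if json_path is not None:
        with open(json_path, "w") as fh:
            json.dump({str(k): v for k, v in ilm.class_of_instance.items()}, fh)


def read_instance_map(png_path, json_path=None) -> InstanceLabelMap:
    with Image.open(png_path) as im:
        arr = np.asarray(im).astype(np.int32)
    mapping: Dict[int, str] = {}
    if json_path is not None:
        with open(json_path) as fh:
            mapping = {int(k): v for k, v in json.load(fh).items()}
    else:
        mapping = {int(i): "unknown" for i in np.unique(arr) if i > 0}
    return InstanceLabelMap(arr, mapping)


# ---------------------------------------------------------------------------
# label documents


def parse_label_xml(path) -> LabelDocument:
    """Parse the documented contour-label XML dialect.

    The dialect is a root element containing ``<contour name="...">``
    elements, each holding ``<point x="..." y="..."/>`` children in pixel
    units; an optional ``closed`` attribute ("true"/"false", default true)
    marks open traces.
    """
    tree = etree.parse(str(path))
    contours = []
    for el in tree.getroot().iter("contour"):
        name = el.get("name", "")
        if name not in KNOWN_CLASSES:
            warnings.warn(f"unknown contour class {name!r}; recorded verbatim")
        closed = el.get("closed", "true").lower() != "false"
        points = [
            (float(p.get("x")), float(p.get("y"))) for p in el.iter("point")
        ]
        contours.append((name, points, closed))
    return LabelDocument(contours)


def write_label_xml(doc: LabelDocument, path) -> None:
    root = etree.Element("labels")
    for name, points, closed in doc.contours:
        el = etree.SubElement(
            root, "contour", name=name, closed="true" if closed else "false"
        )
        for x, y in points:
            etree.SubElement(el, "point", x=repr(float(x)), y=repr(float(y)))
    etree.ElementTree(root).write(str(path), pretty_print=True)


def label_document_to_json(doc: LabelDocument, path) -> None:
    payload = [
        {"class": name, "points": [[float(x), float(y)] for x, y in pts],
         "closed": closed}
        for name, pts, closed in doc.contours
    ]
    with open(path, "w") as fh:
        json.dump(payload, fh)


def label_document_from_json(path) -> LabelDocument:
    with open(path) as fh:
        payload = json.load(fh)
    return LabelDocument(
        [(d["class"], [tuple(p) for p in d["points"]], bool(d["closed"]))
         for d in payload]
    )


def fill_polygon(points: Sequence[Tuple[float, float]], height: int, width: int) -> np.ndarray:
    """Rasterize a closed polygon: even-odd interior plus boundary pixels.

    ``points`` are (x, y) pairs; returns a uint8 {0,1} array of the given
    shape.  Vertices are clipped to the canvas.
    """
    pts = np.asarray(points, dtype=float)
    xs = np.clip(pts[:, 0], 0, width - 1)
    ys = np.clip(pts[:, 1], 0, height - 1)
    out = np.zeros((height, width), dtype=np.uint8)
    rr, cc = _draw.polygon(ys, xs, shape=(height, width))
    out[rr, cc] = 1
    rr, cc = _draw.polygon_perimeter(
        np.round(ys).astype(int), np.round(xs).astype(int),
        shape=(height, width), clip=True,
    )
    out[rr, cc] = 1
    return out


def rasterize_labels(
    doc: LabelDocument,
    height: int,
    width: int,
    classes: Sequence[str],
) -> Tuple[Dict[str, BinaryMask], InstanceLabelMap]:
    """Convert a label document into per-class masks and an instance map.

    Closed contours are filled (interior + boundary).  Instances are
    numbered in document order; on overlap, later instances overwrite
    earlier ones in the instance map, while per-class masks are unions.
    """
    class_masks = {c: np.zeros((height, width), np.uint8) for c in classes}
    inst = np.zeros((height, width), np.int32)
    class_of: Dict[int, str] = {}
    present = {name for name, _, _ in doc.contours}
    for c in classes:
        if c not in present:
            warnings.warn(f"requested class {c!r} absent from document")
    next_id = 1
    for name, points, closed in doc.contours:
        if not closed:
            continue
        filled = fill_polygon(points, height, width)
        if name in class_masks:
            class_masks[name] |= filled
        inst[filled.astype(bool)] = next_id
        class_of[next_id] = name
        next_id += 1
    # instances fully overwritten by later ones drop out of the map
    survivors = set(np.unique(inst)) - {0}
    class_of = {i: c for i, c in class_of.items() if i in survivors}
    return (
        {c: BinaryMask(m) for c, m in class_masks.items()},
        InstanceLabelMap(inst, class_of),
    )


# ---------------------------------------------------------------------------
# CLAHE


def _tile_lut(tile: np.ndarray, clip_limit: float, nbins: int) -> np.ndarray:
    """Clipped-histogram CDF mapping for one tile (uint8 LUT of length 256).

    ``clip_limit`` is a multiple of the mean histogram bin height, the
    convention of the classic CLAHE formulation.  Tiles whose histogram
    occupies only a handful of discrete levels (flat regions, cartoon-like
    synthetic content) get the identity mapping: such histograms carry no
    gradation to equalize — clipping redistributes nearly all of their
    mass — and the raw CDF mapping would merely inject quantization
    offsets that vary from tile to tile.
    """
    n = tile.size
    hist, _ = np.histogram(tile, bins=nbins, range=(0, 256))
    if np.count_nonzero(hist) <= 8:
        return np.arange(256, dtype=np.uint8)
    clip = max(1.0, clip_limit * n / nbins)
    clipped = np.minimum(hist, clip)
    excess = n - clipped.sum()
    clipped = clipped + excess / nbins  # uniform redistribution
    cdf = np.cumsum(clipped) / n
    lut_bins = np.round(cdf * 255.0)
    # expand bin-level LUT to the 256 intensity levels
    idx = np.minimum((np.arange(256) * nbins) // 256, nbins - 1)
    return lut_bins[idx].astype(np.uint8)


def clahe_equalize(
    img: GrayImage,
    tiles: Tuple[int, int] = (8, 8),
    clip_limit: float = 2.0,
    nbins: int = 256,
) -> GrayImage:
    """Contrast-limited adaptive histogram equalization.

    The image is divided into a ``tiles`` grid; each tile's histogram is
    clipped at ``clip_limit`` times the mean bin height, excess mass is
    redistributed uniformly, and the per-tile CDF mappings are blended
    bilinearly between tile centers.  Defaults follow the published
    workflow: an 8x8 grid with a clip size of two bins.
    """
    ty, tx = tiles
    if ty < 1 or tx < 1:
        raise ValueError("tiles must be >= (1, 1)")
    if clip_limit <= 0:
        raise ValueError("clip_limit must be positive")
    h, w = img.shape
    if h < ty or w < tx:
        raise ValueError(f"image {h}x{w} smaller than tile grid {ty}x{tx}")

    row_edges = np.linspace(0, h, ty + 1).astype(int)
    col_edges = np.linspace(0, w, tx + 1).astype(int)
    luts = np.empty((ty, tx, 256), dtype=float)
    for i in range(ty):
        for j in range(tx):
            tile = img.pixels[row_edges[i]:row_edges[i + 1],
                              col_edges[j]:col_edges[j + 1]]
            luts[i, j] = _tile_lut(tile, clip_limit, nbins)

    centers_y = (row_edges[:-1] + row_edges[1:]) / 2.0
    centers_x = (col_edges[:-1] + col_edges[1:]) / 2.0
    # fractional tile coordinates of every pixel, clamped to the center grid
    fy = np.interp(np.arange(h), centers_y, np.arange(ty))
    fx = np.interp(np.arange(w), centers_x, np.arange(tx))
    y0 = np.floor(fy).astype(int)
    x0 = np.floor(fx).astype(int)
    y1 = np.minimum(y0 + 1, ty - 1)
    x1 = np.minimum(x0 + 1, tx - 1)
    wy = (fy - y0)[:, None]
    wx = (fx - x0)[None, :]

    v = img.pixels
    iy0 = y0[:, None]
    iy1 = y1[:, None]
    ix0 = x0[None, :]
    ix1 = x1[None, :]
    out = (
        (1 - wy) * (1 - wx) * luts[iy0, ix0, v]
        + (1 - wy) * wx * luts[iy0, ix1, v]
        + wy * (1 - wx) * luts[iy1, ix0, v]
        + wy * wx * luts[iy1, ix1, v]
    )
    return GrayImage(
        np.clip(np.round(out), 0, 255).astype(np.uint8),
        pixel_size_um=img.pixel_size_um,
        id=img.id,
    )
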