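"""Percentile band filters computed from the cumulative grayscale histogram.

Each tissue filter removes a fixed fraction of the darkest and/or brightest
pixel mass of the (equalized) image: the epineurium filter drops the
darkest 70%, the myelin filter drops the brightest 95%, and the axon
filter drops 30% from each tail.  Thresholds are per image, derived from
the cumulative histogram, so they adapt to each micrograph's exposure.
"""

from __future__ import annotations

import configparser
from dataclasses import dataclass, replace
from typing import Dict, List

import numpy as np

from .images import BinaryMask, GrayImage


@dataclass(frozen=True)
class FilterParams:
    """Tunable knobs of one tissue filter.

    ``lower_pct``/``upper_pct`` are the fractions of darkest/brightest
    pixel mass removed; the contour-point bounds and circularity minimum
    gate shape eligibility downstream; ``rdp_epsilon_frac`` is the
    polyline-simplification tolerance as a fraction of contour perimeter.
    """

    name: str
    lower_pct: float = 0.0
    upper_pct: float = 0.0
    min_contour_points: int = 100
    max_contour_points: int = 1000
    min_circularity: float = 0.1
    rdp_epsilon_frac: float = 0.001

    def __post_init__(self) -> None:
        if not (0 <= self.lower_pct and 0 <= self.upper_pct
                and self.lower_pct + self.upper_pct < 1):
            raise ValueError("need 0 <= lower_pct, upper_pct and sum < 1")
        if not (0 < self.min_contour_points <= self.max_contour_points):
            raise ValueError("need 0 < min_contour_points <= max_contour_points")
        if not 0 <= self.min_circularity <= 1:
            raise ValueError("min_circularity must lie in [0, 1]")
        if self.rdp_epsilon_frac < 0:
            raise ValueError("rdp_epsilon_frac must be >= 0")


@dataclass(frozen=True)
class IntensityBand:
    """Inclusive intensity interval [lo, hi] retained by a band filter.

    The canonical pair (255, 0) denotes the empty band: removal targets
    on a coarse (few-bin) histogram can only be met by removing every
    pixel, since partial bins cannot be split.
    """

    lo: int
    hi: int

    def __post_init__(self) -> None:
        if not (0 <= self.lo <= 255 and 0 <= self.hi <= 255):
            raise ValueError("band bounds must be 8-bit intensities")
        if self.lo > self.hi and (self.lo, self.hi) != (255, 0):
            raise ValueError("band requires lo <= hi")

    @property
    def is_empty(self) -> bool:
        return self.lo > self.hi

    @classmethod
    def empty(cls) -> "IntensityBand":
        return cls(255, 0)


def percentile_band(img: GrayImage, lower_pct: float, upper_pct: float) -> IntensityBand:
    """Thresholds from the cumulative histogram.

    ``lo`` is the smallest intensity whose strictly-below cumulative mass
    reaches ``lower_pct * N`` (so the removed-below mass is the smallest
    achievable value >= the target); ``hi`` mirrors the rule from the
    bright end.  The retained mass therefore matches the requested band to
    within one histogram bin.
    """
    if img.pixels.size == 0:
        raise ValueError("empty image")
    if not (0 <= lower_pct and 0 <= upper_pct and lower_pct + upper_pct < 1):
        raise ValueError("need 0 <= lower_pct, upper_pct and sum < 1")
    n = img.pixels.size
    hist = np.bincount(img.pixels.ravel(), minlength=256)
    below = np.concatenate(([0], np.cumsum(hist)))[:256]  # below[v] = #pixels < v
    above = n - np.cumsum(hist)                           # above[v] = #pixels > v
    lo_ok = below >= lower_pct * n
    hi_ok = above >= upper_pct * n
    lo = int(np.argmax(lo_ok)) if lo_ok.any() else 256    # smallest qualifying v
    hi = 255 - int(np.argmax(hi_ok[::-1])) if hi_ok.any() else -1  # largest
    if lo > hi:  # cuts cross: only full removal meets both targets
        return IntensityBand.empty()
    # clamp degenerate (zero-target) cuts to the observed intensity range
    nonzero = np.nonzero(hist)[0]
    lo = max(lo, int(nonzero[0]))
    hi = min(hi, int(nonzero[-1]))
    if lo > hi:  # retained interval holds no occupied bin
        return IntensityBand.empty()
    return IntensityBand(lo, hi)


def apply_band(img: GrayImage, band: IntensityBand) -> BinaryMask:
    """Mask of pixels with intensity in [band.lo, band.hi]."""
    px = img.pixels
    return BinaryMask(((px >= band.lo) & (px <= band.hi)).astype(np.uint8))


def preset_filters(umf_min_points: int = 20) -> List[FilterParams]:
    """The four published tissue filters.

    Epineurium drops the darkest 70% of pixel mass, myelin drops the
    brightest 95%, and the axon filter drops 30% from each tail; all use
    the 100-1000 contour-point window, a circularity floor of 0.1 and a
    0.1% simplification tolerance.  The unmyelinated-fiber preset shares
    the axon band but admits shorter contours (default 20 points), since
    ~1-2 um fibers trace with far fewer boundary vertices.
    """
    return [
        FilterParams("epineurium", lower_pct=0.70, upper_pct=0.0),
        FilterParams("myelin", lower_pct=0.0, upper_pct=0.95),
        FilterParams("axon", lower_pct=0.30, upper_pct=0.30),
        FilterParams("umf", lower_pct=0.30, upper_pct=0.30,
                     min_contour_points=umf_min_points,
                     max_contour_points=1000),
    ]


def get_preset(name: str) -> FilterParams:
    for p in preset_filters():
        if p.name == name:
            return p
    raise KeyError(f"no preset named {name!r}")


_FIELDS = ("lower_pct", "upper_pct", "min_contour_points",
           "max_contour_points", "min_circularity", "rdp_epsilon_frac")


def write_filter_config(params: List[FilterParams], path) -> None:
    """Plain-text config: one section per preset, one key per field."""
    cp = configparser.ConfigParser()
    for p in params:
        cp[p.name] = {f: repr(getattr(p, f)) for f in _FIELDS}
    with open(path, "w") as fh:
        cp.write(fh)


def read_filter_config(path) -> List[FilterParams]:
    """Read presets from config; unlisted fields fall back to defaults."""
    cp = configparser.ConfigParser()
    with open(path) as fh:
        cp.read_file(fh)
    out = []
    for name in cp.sections():
        base = FilterParams(name)
        kwargs: Dict[str, object] = {}
        for f in _FIELDS:
            if f in cp[name]:
                cast = int if "points" in f else float
                kwargs[f] = cast(float(cp[name][f]))
        out.append(replace(base, **kwargs))
    return out
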