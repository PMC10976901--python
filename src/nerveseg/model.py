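"""Functionalized nerve geometry, distribution-based packing, recruitment.

Segmented cross-sections become extruded 3-D nerve descriptions: each
tissue contour is a closed profile swept along a trajectory (default a
straight 1 cm segment, matching a zero-tortuosity extrusion), carrying an
isotropic conductivity; a center spline per fiber supports downstream
cable-model simulation.  Field solving and membrane dynamics are out of
scope: activation is abstracted behind a monotone predicate, and the
utilities here handle titration bookkeeping (phi_T(t) = phi * T * a(t))
and recruitment-curve computation.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
from shapely.geometry import Point, Polygon

from .contours import Contour, ContourSet, estimate_diameter

#: Isotropic tissue conductivities in S/m.
DEFAULT_CONDUCTIVITIES: Dict[str, float] = {
    "fat": 0.0673,
    "myelin": 0.0010,
    "blood & blood vessel": 0.6599,
    "saline": 1.6000,
    "epineurium": 0.1587,
    "endoneurium": 0.2651,
}

#: Classes whose contours are fibers (get a center spline). Unmyelinated
#: fiber diameters are capped at this value at export time, a limitation
#: of the unmyelinated conduction model.
FIBER_CLASSES = ("axon", "umf", "myelinated fiber", "unmyelinated fiber")
UNMYELINATED_CLASSES = ("umf", "unmyelinated fiber")
UMF_DIAMETER_CAP_UM = 1.0

#: Segmentation class names resolved onto bulk-tissue conductivities:
#: fiber interiors conduct like endoneurium in the bulk problem (their
#: membranes live in the cable model, not the FEM), the myelin filter
#: also traces Schwann cells, and myelinated-fiber outlines are sheath.
CLASS_ALIASES: Dict[str, str] = {
    "axon": "endoneurium",
    "umf": "endoneurium",
    "unmyelinated fiber": "endoneurium",
    "myelinated fiber": "myelin",
    "Schwann cell": "myelin",
    "blood vessel": "blood & blood vessel",
    "blood": "blood & blood vessel",
}

#: Stimulus metadata recorded in exports: bipolar wire electrodes and
#: balanced biphasic pulse presets (per-phase width in us).
DEFAULT_ELECTRODE = {
    "type": "bipolar",
    "wire_diameter_um": 0.127,
    "spacing_um": 500.0,
}
PULSE_PRESETS = {
    "biphasic_250us": {"shape": "balanced bipolar biphasic", "phase_us": 250.0},
    "biphasic_1000us": {"shape": "balanced bipolar biphasic", "phase_us": 1000.0},
}


@dataclass
class TissueConductivity:
    values: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CONDUCTIVITIES))

    def __post_init__(self) -> None:
        for k, v in self.values.items():
            if not v > 0:
                raise ValueError(f"conductivity for {k!r} must be positive")

    def __getitem__(self, tissue_class: str) -> float:
        if tissue_class in self.values:
            return self.values[tissue_class]
        alias = CLASS_ALIASES.get(tissue_class)
        if alias is not None and alias in self.values:
            return self.values[alias]
        raise KeyError(f"no conductivity configured for {tissue_class!r}")


def read_conductivity_config(path) -> TissueConductivity:
    """Plain-text ``class = value`` pairs; '#' starts a comment."""
    values = dict(DEFAULT_CONDUCTIVITIES)
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, val = line.partition("=")
            values[key.strip()] = float(val)
    return TissueConductivity(values)


def write_conductivity_config(cond: TissueConductivity, path) -> None:
    with open(path, "w") as fh:
        fh.write("# tissue conductivities in S/m\n")
        for k, v in cond.values.items():
            fh.write(f"{k} = {v}\n")


@dataclass
class Trajectory:
    """Ordered 3-D polyline (um) the cross-section is swept along."""

    points: np.ndarray

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if len(pts) < 2:
            raise ValueError("a trajectory needs at least 2 points")
        self.points = pts

    @property
    def length_um(self) -> float:
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())

    @classmethod
    def straight(cls, length_um: float = 10_000.0) -> "Trajectory":
        """Default: a straight 1 cm segment along z (zero tortuosity)."""
        return cls(np.array([[0.0, 0.0, 0.0], [0.0, 0.0, length_um]]))


@dataclass
class GeometryFeature:
    tissue_class: str
    profile_um: np.ndarray  # (N, 2) closed polyline, um
    conductivity_s_per_m: float


@dataclass
class FiberSpline:
    fiber_id: int
    tissue_class: str
    path_um: np.ndarray  # (N, 3) center polyline, um
    diameter_um: float


@dataclass
class NerveGeometry:
    features: List[GeometryFeature]
    fiber_splines: List[FiberSpline]
    trajectory: Trajectory
    electrode: Dict[str, object] = field(
        default_factory=lambda: dict(DEFAULT_ELECTRODE))
    pulses: Dict[str, Dict[str, object]] = field(
        default_factory=lambda: {k: dict(v) for k, v in PULSE_PRESETS.items()})


def build_geometry(
    class_contours: Dict[str, ContourSet],
    pixel_size_um: float,
    trajectory: Optional[Trajectory] = None,
    conductivities: Optional[TissueConductivity] = None,
) -> NerveGeometry:
    """Sweep per-class contours into a functionalized extruded geometry.

    Every contour is scaled to um and recorded as a closed profile with
    its class conductivity; fiber-class contours additionally get a
    center spline following the trajectory.  Unmyelinated fibers whose
    perimeter-based diameter exceeds 1 um are exported with the diameter
    capped at exactly 1 um (the raw contour is preserved).
    """
    traj = trajectory if trajectory is not None else Trajectory.straight()
    cond = conductivities if conductivities is not None else TissueConductivity()
    rel = traj.points - traj.points[0]
    features: List[GeometryFeature] = []
    splines: List[FiberSpline] = []
    for cls, cs in class_contours.items():
        try:
            sigma = cond[cls]
        except KeyError as exc:
            raise ValueError(str(exc)) from exc
        for c in cs.top_level():
            profile = np.asarray(c.points, dtype=float) * pixel_size_um
            features.append(GeometryFeature(cls, profile, sigma))
            if cls in FIBER_CLASSES and c.perimeter > 0:
                d = estimate_diameter(c, pixel_size_um)
                if cls in UNMYELINATED_CLASSES:
                    d = min(d, UMF_DIAMETER_CAP_UM)
                cx, cy = c.centroid()
                path = rel + np.array([cx * pixel_size_um,
                                       cy * pixel_size_um, 0.0])
                splines.append(FiberSpline(c.id, cls, path, d))
    return NerveGeometry(features, splines, traj)


def export_geometry_json(geom: NerveGeometry, path) -> None:
    payload = {
        "trajectory_um": geom.trajectory.points.tolist(),
        "trajectory_length_um": geom.trajectory.length_um,
        "electrode": geom.electrode,
        "pulse_presets": geom.pulses,
        "features": [
            {
                "class": f.tissue_class,
                "conductivity_s_per_m": f.conductivity_s_per_m,
                "profile_um": f.profile_um.tolist(),
            }
            for f in geom.features
        ],
        "fiber_splines": [
            {
                "fiber_id": s.fiber_id,
                "class": s.tissue_class,
                "diameter_um": s.diameter_um,
                "path_um": s.path_um.tolist(),
            }
            for s in geom.fiber_splines
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


# ---------------------------------------------------------------------------
# distribution-based nerve generation


class PackingError(RuntimeError):
    pass


@dataclass
class DistributionSpec:
    """Statistical description of a fiber population.

    Diameters are drawn per class from a normal distribution truncated
    below at ``diameter_floor_um``; myelinated fibers also draw a g-ratio
    (inner = g * outer).  ``endoneurium``/``epineurium`` are traced
    profiles in um; the DBC variant replaces them with circles of equal
    area.
    """

    n_myelinated: int = 0
    n_unmyelinated: int = 0
    myelinated_diameter_mean_um: float = 2.4
    myelinated_diameter_sd_um: float = 0.4
    unmyelinated_diameter_mean_um: float = 1.0
    unmyelinated_diameter_sd_um: float = 0.3
    g_ratio_mean: float = 0.6
    g_ratio_sd: float = 0.05
    endoneurium_um: Optional[np.ndarray] = None  # (N, 2) closed polyline
    epineurium_um: Optional[np.ndarray] = None
    circular_boundaries: bool = False  # DBC variant
    diameter_floor_um: float = 0.1
    seed: int = 0
    max_attempts: int = 10_000

    def __post_init__(self) -> None:
        if self.n_myelinated < 0 or self.n_unmyelinated < 0:
            raise ValueError("fiber counts must be >= 0")
        for sd in (self.myelinated_diameter_sd_um,
                   self.unmyelinated_diameter_sd_um, self.g_ratio_sd):
            if sd < 0:
                raise ValueError("standard deviations must be >= 0")
        if self.endoneurium_um is None:
            self.endoneurium_um = _circle_polyline((0.0, 0.0), 25.0)
        if self.epineurium_um is None:
            self.epineurium_um = _circle_polyline((0.0, 0.0), 30.0)
        self.endoneurium_um = np.asarray(self.endoneurium_um, float)
        self.epineurium_um = np.asarray(self.epineurium_um, float)
        if not Polygon(self.epineurium_um).contains(
                Polygon(self.endoneurium_um).representative_point()):
            raise ValueError("endoneurium must lie inside the epineurium")


def _circle_polyline(center: Tuple[float, float], radius: float,
                     n: int = 64) -> np.ndarray:
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.column_stack([center[0] + radius * np.cos(th),
                            center[1] + radius * np.sin(th)])


def _equal_area_circle(poly: np.ndarray) -> np.ndarray:
    shp = Polygon(poly)
    r = math.sqrt(shp.area / math.pi)
    c = shp.centroid
    return _circle_polyline((c.x, c.y), r)


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      floor: float) -> float:
    if sd == 0:
        return max(mean, floor)
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if v >= floor:
            return float(v)
    return floor


def generate_db_nerve(spec: DistributionSpec) -> Dict[str, ContourSet]:
    """Sequentially pack circular fibers drawn from the distribution.

    Each fiber draws a diameter, then a uniformly random center inside
    the endoneurium is accepted only if the disc lies strictly inside the
    endoneurium and overlaps no previously placed fiber (rejection
    sampling, seeded RNG).  Myelinated fibers place an inner circle at
    g * outer.  Raises :class:`PackingError` naming the failing fiber if
    a disc cannot be placed within ``max_attempts`` draws.
    """
    rng = np.random.default_rng(spec.seed)
    endo_poly = spec.endoneurium_um
    epi_poly = spec.epineurium_um
    if spec.circular_boundaries:
        endo_poly = _equal_area_circle(endo_poly)
        epi_poly = _equal_area_circle(epi_poly)
    endo = Polygon(endo_poly)
    minx, miny, maxx, maxy = endo.bounds
    placed: List[Tuple[float, float, float]] = []  # (x, y, r)
    classes: List[str] = []
    g_ratios: List[Optional[float]] = []
    order = (["myelinated fiber"] * spec.n_myelinated
             + ["unmyelinated fiber"] * spec.n_unmyelinated)
    for idx, cls in enumerate(order):
        if cls == "myelinated fiber":
            d = _truncated_normal(rng, spec.myelinated_diameter_mean_um,
                                  spec.myelinated_diameter_sd_um,
                                  spec.diameter_floor_um)
            g = float(np.clip(rng.normal(spec.g_ratio_mean, spec.g_ratio_sd),
                              0.05, 0.95))
        else:
            d = _truncated_normal(rng, spec.unmyelinated_diameter_mean_um,
                                  spec.unmyelinated_diameter_sd_um,
                                  spec.diameter_floor_um)
            g = None
        r = d / 2.0
        for attempt in range(spec.max_attempts):
            x = rng.uniform(minx, maxx)
            y = rng.uniform(miny, maxy)
            if not endo.contains(Point(x, y).buffer(r, quad_segs=16)):
                continue
            if any((x - px) ** 2 + (y - py) ** 2 <= (r + pr) ** 2
                   for px, py, pr in placed):
                continue
            placed.append((x, y, r))
            classes.append(cls)
            g_ratios.append(g)
            break
        else:
            raise PackingError(
                f"could not place fiber {idx} ({cls}, diameter {d:.2f} um) "
                f"after {spec.max_attempts} attempts")

    out: Dict[str, List[Contour]] = {
        "myelinated fiber": [], "unmyelinated fiber": [],
        "endoneurium": [], "epineurium": [],
    }
    next_id = 1
    for (x, y, r), cls, g in zip(placed, classes, g_ratios):
        outer = Contour(_circle_polyline((x, y), r), tissue_class=cls,
                        id=next_id)
        next_id += 1
        out[cls].append(outer)
        if g is not None:
            inner = Contour(_circle_polyline((x, y), g * r),
                            tissue_class=cls, parent=outer.id, id=next_id)
            next_id += 1
            out[cls].append(inner)
    out["endoneurium"].append(
        Contour(endo_poly, tissue_class="endoneurium", id=next_id))
    out["epineurium"].append(
        Contour(epi_poly, tissue_class="epineurium", id=next_id + 1))
    # profiles are already in um: pixel_size 1
    return {cls: ContourSet(cs, source_image_id=f"db-seed{spec.seed}",
                            pixel_size_um=1.0)
            for cls, cs in out.items()}


# ---------------------------------------------------------------------------
# titration and recruitment


def titrate(phi, T: float, a) -> np.ndarray:
    """Scaled extracellular waveform phi_T(t) = phi * T * a(t)."""
    if T < 0:
        raise ValueError("titration factor must be >= 0")
    return np.asarray(phi, float) * T * np.asarray(a, float)


def titration_search(
    fiber_fires: Callable[[float], bool],
    T_max: float,
    tol: float = 0.01,
) -> float:
    """Smallest scale T at which a fiber fires, to relative tolerance.

    The predicate must be monotone in T.  The threshold is bracketed by
    halving down from ``T_max`` and refined by bisection; returns
    ``math.inf`` when the fiber does not fire even at ``T_max``.
    """
    if not T_max > 0:
        raise ValueError("T_max must be positive")
    if not 0 < tol < 1:
        raise ValueError("tol must lie in (0, 1)")
    if not fiber_fires(T_max):
        if fiber_fires(T_max / 2.0):
            raise RuntimeError(
                "activation predicate is not monotone: fires at T_max/2 "
                "but not at T_max")
        return math.inf
    hi = T_max
    lo = 0.0
    t = T_max
    # halve down until the predicate stops firing (or t is negligible)
    while t > tol * T_max * 1e-6:
        t /= 2.0
        if fiber_fires(t):
            hi = t
        else:
            lo = t
            break
    if lo == 0.0:  # fires arbitrarily low: return the tiny lower bound
        return hi
    while hi - lo > tol * hi:
        mid = (hi + lo) / 2.0
        if fiber_fires(mid):
            hi = mid
        else:
            lo = mid
    return hi


@dataclass
class RecruitmentResult:
    amplitudes_uv: np.ndarray
    fractions: np.ndarray
    base_amplitude_uv: float
    thresholds_uv: np.ndarray
    density: Optional[np.ndarray] = None  # KDE of thresholds on the grid


def recruitment_curve(
    titration_factors: Sequence[float],
    base_amplitude_uv: float,
    grid_uv: Sequence[float],
    kde: bool = False,
    bandwidth: Optional[float] = None,
) -> RecruitmentResult:
    """Fraction of fibers activated at each amplitude.

    A fiber with titration factor T fires at threshold base * T; the
    curve reports #{thresholds <= V} / n over the sorted amplitude grid.
    With ``kde=True`` a Gaussian kernel density of the finite thresholds
    is also evaluated on the grid (Scott's rule bandwidth by default).
    """
    T = np.asarray(titration_factors, float)
    if T.size == 0:
        raise ValueError("empty titration set")
    grid = np.asarray(grid_uv, float)
    if np.any(np.diff(grid) < 0):
        raise ValueError("amplitude grid must be sorted ascending")
    thresholds = base_amplitude_uv * T
    fractions = np.array([(thresholds <= v).mean() for v in grid])
    density = None
    if kde:
        from scipy.stats import gaussian_kde

        finite = thresholds[np.isfinite(thresholds)]
        if finite.size > 1 and np.ptp(finite) > 0:
            k = gaussian_kde(finite, bw_method=bandwidth)  # None -> Scott
            density = k(grid)
    return RecruitmentResult(grid, fractions, base_amplitude_uv,
                             thresholds, density)
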