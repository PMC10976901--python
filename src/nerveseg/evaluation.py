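"""Panoptic-quality scoring and filter-parameter optimization.

Panoptic quality (PQ) scores an instance segmentation against ground
truth: predicted and true instances are matched when their IoU exceeds
0.5 (which makes the matching unique), segmentation quality (SQ) is the
mean IoU over matches, recognition quality (RQ) is the detection F-term
TP / (TP + FP/2 + FN/2), and PQ = SQ * RQ.  Filter parameters are tuned
by minimizing 1 - PQ with a COBYLA local search inside a basin-hopping
outer loop.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize as sciopt

from .contours import contours_to_instance_map, segment_image
from .filters import FilterParams
from .images import BinaryMask, GrayImage, InstanceLabelMap


@dataclass
class PQReport:
    pq: float
    sq: float
    rq: float
    tp: int
    fp: int
    fn: int
    matches: List[Tuple[int, int, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if abs(self.pq - self.sq * self.rq) > 1e-9:
            raise ValueError("PQ must equal SQ * RQ")
        if self.tp != len(self.matches):
            raise ValueError("TP must equal the number of matches")


def iou(a: BinaryMask, b: BinaryMask) -> float:
    """Intersection over union; 0 when both masks are empty."""
    if a.shape != b.shape:
        raise ValueError("mask shapes differ")
    pa = a.pixels.astype(bool)
    pb = b.pixels.astype(bool)
    union = np.logical_or(pa, pb).sum()
    if union == 0:
        return 0.0
    return float(np.logical_and(pa, pb).sum() / union)


def panoptic_quality(
    pred: InstanceLabelMap,
    truth: InstanceLabelMap,
    iou_threshold: float = 0.5,
) -> PQReport:
    """Match instances by IoU and decompose PQ = SQ * RQ.

    At the canonical threshold of 0.5 each instance can match at most one
    counterpart, so the matching is unambiguous; for lower thresholds
    (sensitivity checks) candidate pairs are taken greedily by descending
    IoU with one-to-one uniqueness enforced.
    """
    if pred.shape != truth.shape:
        raise ValueError("instance map shapes differ")
    p = pred.pixels.ravel()
    t = truth.pixels.ravel()
    pred_ids = np.array(pred.instance_ids(), dtype=np.int64)
    truth_ids = np.array(truth.instance_ids(), dtype=np.int64)
    p_area = {int(i): int(n) for i, n in
              zip(*np.unique(p[p > 0], return_counts=True))}
    t_area = {int(i): int(n) for i, n in
              zip(*np.unique(t[t > 0], return_counts=True))}
    # joint histogram of co-occurring (pred, truth) labels
    both = (p > 0) & (t > 0)
    pairs, counts = np.unique(
        np.stack([p[both], t[both]]), axis=1, return_counts=True)
    candidates = []
    for (pi, ti), inter in zip(pairs.T, counts):
        u = p_area[int(pi)] + t_area[int(ti)] - int(inter)
        val = inter / u
        if val > iou_threshold:
            candidates.append((float(val), int(pi), int(ti)))
    candidates.sort(reverse=True)
    used_p, used_t = set(), set()
    matches: List[Tuple[int, int, float]] = []
    for val, pi, ti in candidates:
        if pi in used_p or ti in used_t:
            continue
        used_p.add(pi)
        used_t.add(ti)
        matches.append((pi, ti, val))
    tp = len(matches)
    fp = len(pred_ids) - tp
    fn = len(truth_ids) - tp
    sq = float(np.mean([m[2] for m in matches])) if matches else 0.0
    denom = tp + 0.5 * fp + 0.5 * fn
    rq = tp / denom if denom > 0 else 0.0
    return PQReport(pq=sq * rq, sq=sq, rq=rq, tp=tp, fp=fp, fn=fn,
                    matches=matches)


# ---------------------------------------------------------------------------
# parameter optimization


@dataclass
class OptimizationResult:
    best_params: FilterParams
    best_pq: float
    trace: List[Tuple[FilterParams, float]]
    seed: int

    def __post_init__(self) -> None:
        if self.trace and abs(self.best_pq - max(pq for _, pq in self.trace)) > 1e-12:
            raise ValueError("best_pq must be the maximum over the trace")


# optimization operates on a normalized vector; integer bounds are relaxed
# to continuous values and rounded at evaluation time
_VEC_FIELDS = ("lower_pct", "upper_pct", "min_circularity",
               "min_contour_points", "max_contour_points")
_SCALES = (1.0, 1.0, 1.0, 1000.0, 1000.0)


def _params_to_vec(p: FilterParams) -> np.ndarray:
    return np.array([getattr(p, f) / s for f, s in zip(_VEC_FIELDS, _SCALES)])


def _vec_to_params(x: np.ndarray, template: FilterParams) -> Optional[FilterParams]:
    lower = float(x[0])
    upper = float(x[1])
    circ = float(np.clip(x[2], 0.0, 1.0))
    mn = int(round(x[3] * _SCALES[3]))
    mx = int(round(x[4] * _SCALES[4]))
    try:
        return replace(template, lower_pct=lower, upper_pct=upper,
                       min_circularity=circ, min_contour_points=max(mn, 1),
                       max_contour_points=max(mx, max(mn, 1)))
    except ValueError:
        return None


def evaluate_params(img: GrayImage, truth: InstanceLabelMap,
                    params: FilterParams, **segment_kwargs) -> float:
    """PQ of a single-filter segmentation of ``img`` against ``truth``."""
    res = segment_image(img, [params], **segment_kwargs)
    pred = contours_to_instance_map(res.contours[params.name], img.shape)
    return panoptic_quality(pred, truth).pq


def optimize_filter_params(
    img: GrayImage,
    truth: InstanceLabelMap,
    init: FilterParams,
    seed: int = 0,
    n_hops: int = 20,
    local_maxiter: int = 100,
    hop_sigma: float = 0.1,
    progress: Optional[Callable[[int, float], None]] = None,
) -> OptimizationResult:
    """Minimize 1 - PQ over filter parameters.

    A COBYLA local minimizer (derivative-free, honoring the linear
    parameter constraints) runs inside a basin-hopping loop whose hops are
    Gaussian perturbations (sigma ``hop_sigma``) on the normalized
    parameter scale, drawn from an RNG seeded with ``seed`` so runs are
    reproducible.  The returned parameters are never worse than ``init``
    because the initial evaluation is part of the trace.
    """
    _ = FilterParams(**{f: getattr(init, f) for f in
                        ("name", "lower_pct", "upper_pct", "min_contour_points",
                         "max_contour_points", "min_circularity",
                         "rdp_epsilon_frac")})  # re-validate init
    trace: List[Tuple[FilterParams, float]] = []

    def objective(x: np.ndarray) -> float:
        params = _vec_to_params(x, init)
        if params is None:
            return 1.5  # outside the feasible region
        pq = evaluate_params(img, truth, params)
        trace.append((params, pq))
        if progress is not None:
            progress(len(trace), pq)
        return 1.0 - pq

    constraints = [
        {"type": "ineq", "fun": lambda x: x[0]},                 # lower >= 0
        {"type": "ineq", "fun": lambda x: x[1]},                 # upper >= 0
        {"type": "ineq", "fun": lambda x: 0.999 - x[0] - x[1]},  # sum < 1
        {"type": "ineq", "fun": lambda x: x[2]},
        {"type": "ineq", "fun": lambda x: 1.0 - x[2]},
        {"type": "ineq", "fun": lambda x: x[3] - 1.0 / _SCALES[3]},
        {"type": "ineq", "fun": lambda x: x[4] - x[3]},
    ]
    rng = np.random.default_rng(seed)
    x0 = _params_to_vec(init)
    objective(x0)  # anchor the trace at the initial parameters

    class _Step:
        def __call__(self, x):
            return x + rng.normal(0.0, hop_sigma, size=len(x))

    sciopt.basinhopping(
        objective,
        x0,
        niter=n_hops,
        take_step=_Step(),
        minimizer_kwargs={
            "method": "COBYLA",
            "constraints": constraints,
            "options": {"maxiter": local_maxiter, "rhobeg": 0.15},
        },
        rng=np.random.default_rng(seed + 1),
    )
    best_params, best_pq = max(trace, key=lambda t: t[1])
    return OptimizationResult(best_params=best_params, best_pq=best_pq,
                              trace=trace, seed=seed)
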