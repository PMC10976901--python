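# Methods

## Pipeline model

The segmentation model assumes osmium-stained TEM-like contrast: myelin
(and Schwann-cell cytoplasm) darkest, axoplasm mid-gray, connective
tissue / epineurium brightest. Classes are separated purely by pixel-mass
percentiles of the per-image histogram, so the filters adapt to exposure
but depend on *composition*: the axon band (drop 30% of mass from each
tail) isolates axoplasm only when at least 30% of the pixel mass is
darker than every axoplasm pixel and at least 30% is brighter. This is
the regime of a densely packed fascicle; the filters are not expected to
work on images dominated by a single tissue.

### Percentile thresholds

`percentile_band` picks `lo` as the smallest intensity whose
strictly-below cumulative mass reaches `lower_pct * N`; `hi` mirrors this
from the bright end. The removed tail is therefore the smallest
achievable mass at or above the target — histogram bins are atomic, so
the retained band matches the request only to within one bin. When the
two cuts cross (possible on coarse histograms: both rules round *up*),
no non-empty band satisfies them and the canonical empty band
`(lo, hi) = (255, 0)` is returned; a constant image under the epineurium
preset, for example, yields an empty mask rather than an arbitrary one.
This rounding rule keeps band enlargement monotone (a larger requested
band never loses a retained pixel).

### CLAHE

Contrast-limited adaptive histogram equalization is applied before
thresholding: per-tile histograms (default 8x8 grid, 256 bins) are
clipped at `clip_limit` times the mean bin height (default 2), excess
mass is redistributed uniformly, and per-tile CDF mappings are blended
bilinearly between tile centers. One numerical guard departs from the
textbook formulation: a tile whose histogram occupies eight or fewer
discrete levels gets the identity mapping. Such histograms carry no
gradation to equalize — clipping redistributes essentially all of their
mass, and the raw CDF mapping would only inject a few levels of
quantization offset that differ from tile to tile, splitting a globally
constant intensity population into several adjacent levels. The guard
makes CLAHE exactly idempotent on constant and cartoon-like images
(including the noise-free synthetic fixtures) while leaving natural
images, whose noise produces continuous histograms, on the standard
path.

### Contour tracing and shape gates

Boundaries are traced with the Moore-neighbor algorithm (clockwise scan,
Gonzalez-Woods backtracking, Jacob stopping criterion) over 8-connected
foreground components; enclosed 4-connected background regions are
traced over their own pixels and attached as hole boundaries. "Contour
length" in the vertex-count gate means the raw traced chain (one vertex
per boundary pixel), not metric length — the published 100-1000 window
pairs naturally with counts. Circularity is computed before
simplification (simplification distorts the perimeter more than the
area). Hole boundaries are not gated independently; they follow their
parent. Components of fewer than three boundary pixels produce
degenerate contours that no gate can accept; they are retained
internally (instance counts stay honest) but never exported as shapes.

Ramer-Douglas-Peucker simplification interprets its 0.1% tolerance as a
fraction of each contour's own perimeter (the only dimensionally
meaningful reading). Closed contours are split at their two
farthest-apart vertices and each open half is simplified independently,
so the output is always a vertex subsequence and every input vertex
stays within epsilon of the result. The length gate runs before
simplification; running it after would couple the gate to the tolerance.

### Evaluation and optimization

Panoptic quality follows the standard instance-segmentation definition:
matches at IoU > 0.5 (unique by construction; the threshold is exposed
for sensitivity checks, with greedy one-to-one matching below 0.5),
SQ = mean matched IoU, RQ = TP / (TP + FP/2 + FN/2), PQ = SQ * RQ.
Evaluation never applies the user exclusion list — accuracy is always
reported without intervention.

`optimize_filter_params` minimizes 1 - PQ over (lower_pct, upper_pct,
min_circularity, contour-point bounds) with COBYLA inside basin-hopping.
Parameters are normalized (point counts scaled by 1000); integer bounds
are relaxed to continuous values and rounded at evaluation. Defaults are
20 hops x 100 local evaluations with Gaussian hops of sigma 0.1 on the
normalized scale and COBYLA rhobeg 0.15; all randomness flows from one
seed, and the initial parameters are evaluated first so the result can
never be worse than the start. The test suite runs reduced budgets
(2-3 hops x 15-25 evaluations), which already recover PQ > 0.95 from a
badly misplaced band on the synthetic fixture.

## Model generation

Profiles are swept along a trajectory (default straight 10,000 um — a
1 cm nerve with zero tortuosity), so cross-sectional collision checks in
the distribution-based generator are purely 2-D. Conductivities are
isotropic; defaults (S/m): fat 0.0673, myelin 0.0010, blood & blood
vessel 0.6599, saline 1.6000, epineurium 0.1587, endoneurium 0.2651.
Segmentation class names resolve onto these via aliases: fiber interiors
conduct like endoneurium in the bulk problem (membranes belong to the
cable model), myelinated-fiber outlines and Schwann cells like myelin.
Unmyelinated fibers whose perimeter-based diameter exceeds 1 um export
with the diameter capped at exactly 1 um; the contour itself is kept
raw, and morphometry tables never apply the cap.

Field solving and membrane dynamics are intentionally out of scope. The
export is a neutral JSON scene (profiles + conductivities + fiber
splines + electrode metadata: bipolar 0.127 um wires at 0.5 mm spacing,
balanced biphasic pulse presets of 250 or 1000 us per phase), and
activation is abstracted behind a monotone predicate so any simulator
can drive `titration_search` (halving bracket + bisection, default 1%
relative tolerance; infinity marker when a fiber never fires at the
search cap).

The distribution-based generator draws diameters from a normal
distribution truncated below at 0.1 um (the normal family is assumed
from mean/SD parameterization; the floor avoids non-physical draws) and
g-ratios clipped to [0.05, 0.95]. Each fiber is placed by rejection
sampling — uniform center, accepted when the disc lies strictly inside
the endoneurium ("colliding with the endoneurium" is read as containment)
and overlaps no earlier fiber — with a 10,000-attempt cap per fiber that
raises a packing error naming the failing fiber. The circular-boundary
variant replaces traced endo/epineurium outlines with equal-area circles.

## Synthetic fixtures

`generate_scene` renders three intensity populations (myelin 15,
axoplasm 128, background 230 by default) plus clipped additive Gaussian
noise, and returns exact per-class masks, a combined instance map, and
true diameters / g-ratios. Myelinated fibers (default ten, outer
diameter 3.2-3.3 um, g-ratio 0.60-0.63 at 0.05 um/px) are placed on a
jittered grid rather than by free rejection sampling: the axon preset
needs myelin to carry >= 30% of pixel mass, which corresponds to ~55%
outer-disc coverage — beyond the ~54.7% jamming limit of random
sequential placement, but trivial for a lattice, and real fascicles are
similarly close-packed. Standalone axon/unmyelinated discs fill gaps by
rejection sampling. Core diameters are sized so their traced chains fall
inside the published 100-1000 vertex window at this magnification.

What the fixture does *not* emulate: texture inside tissue classes,
staining gradients, touching or overlapping fibers, elliptical or
irregular fiber profiles, vascular and adipose structures. Passing the
end-to-end tests therefore demonstrates the correctness of the
thresholding / tracing / scoring machinery under the stated contrast
model, not segmentation accuracy on real micrographs. Two preset-level
consequences are worth noting: the myelin preset (keep the darkest 5%)
assumes myelin is a small mass fraction, so on this deliberately
myelin-rich fixture it returns an empty band; and a scene of bare
mid-gray discs on a bright background cannot be isolated by the axon
preset at all, because nothing occupies the bottom 30% of mass — which
is why the fixture's "axons" are the cores of myelinated rings.

## Problem sizes and numerical defaults

Test and acceptance runs use 216x288 px scenes with ten fibers,
200-fiber distribution packs, 200 random instance maps (<= 16x16) for
the PQ oracle, and 1000 random polylines for the simplification
properties — sizes at which every oracle is exhaustive. Sample standard
deviations use the n-1 denominator (summaries feed the distribution
generator). Polygon rasterization counts boundary pixels as interior,
uses the even-odd rule, and pixel centers sit at integer coordinates;
instance overlap during label rasterization resolves by document order
(later wins) while per-class masks are unions.

## Known limitations

- Touching fibers merge into one component; no watershed splitting.
- Thresholds are global per image; strong illumination gradients within
  an image are only partially absorbed by CLAHE.
- The optimizer's objective is piecewise constant, so derivative-free
  local search can stall on plateaus; basin hops are the escape
  mechanism and the budget may need raising for hard images.
- The XML label dialect is a minimal documented one (contour/point
  elements with pixel coordinates); proprietary tracing formats must be
  converted externally.
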