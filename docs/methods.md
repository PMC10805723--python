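# Methods

This note documents the models behind `crowdcell`: what the simulators
emulate, the aggregation and scoring procedures, the tunable parameters
with their defaults and units, the numerical conventions, and what passing
tests do and do not establish about real data.

## Scene model (`scene_sim`)

A scene is a flat list of parametric cells on a rectangular region
(default 1860 × 1396 px at 0.25 µm/px, the size of one multispectral
region of interest). Cell classes and their marker logic:

| class | nucleus | cytoplasm | markers |
|---|---|---|---|
| tumor | DAPI-bright, **ATRX-negative** | star (5 arms) | GFAP 0.5, IDH1 0.6 |
| astrocyte | DAPI, **ATRX-positive** | star (6 arms) | GFAP 0.8 |
| neuron | DAPI, ATRX-positive, larger | compact disc | no GFAP |
| endothelial | DAPI, ATRX-positive | elongated ellipse | faint GFAP, CD34 |
| immune | DAPI, ATRX | small disc | MS4A4A/CD68/CD206/CD3 |
| other | DAPI, ATRX-positive | small disc | — |

Geometry defaults assume nuclei of 8–11 µm and processes reaching ~25 µm
(nucleus radius 16 px for tumor/astrocyte, cytoplasm radius 45–55 px).
The star shape is the union of the nucleus disc and `arm_count` circular
sectors of half-angle 0.28 rad and length `cytoplasm_radius` — the
minimal parametric form of a "star-shaped" cell. Rendering is additive per
channel (nuclear channels paint the nucleus disc, ATRX only when
expressed; cytoplasmic channels paint the full footprint), plus a constant
background (default 0.05) and clipped additive Gaussian noise (default
sd 0.02). There is deliberately no autofluorescence, spectral bleed-through
or scanner model: rendered scenes are cartoons whose ground truth is exact,
not photorealistic tissue.

Cell placement is a hard-core Poisson process: per-class counts are
Poisson(density × area), centers uniform with a minimum center-to-center
spacing (default 40 px) enforced by rejection sampling (bounded retries,
explicit failure). Density defaults (~8·10⁻⁵ tumor cells/px²,
~8·10⁻⁶ astrocytes/px²) were derived once from typical per-region expert
counts (hundreds of tumor cells and a handful of astrocytes per region);
confuser classes sit at the astrocyte order of magnitude. Quantitative
marker intensities and cell-size distributions are plausible choices, not
calibrated measurements.

The nine RGB variants map channels to colors: Var1 is the crowd-facing
scheme (GFAP blue, ATRX red, DAPI white) and is fixed; Var2–Var4 re-color
or re-scale the same three channels, Var5–Var6 drop ATRX (emulating
IDH-wildtype material where ATRX loss carries no signal), Var7–Var8 add
extra markers without ATRX, Var9 shows everything. Only Var1's colors are
canonical; the others are documented defaults and every `VariantSpec` is
fully configurable.

## Worker model (`crowd_sim`)

A worker clicks each true cell of class *c* as class *a* with probability
`sensitivity[c]` (a = c) or `confusion[(c, a)]` (e.g. neuron → astrocyte),
jittered by isotropic Gaussian localization error (default sd 3 px), adds
Poisson-distributed spurious clicks (`fp_rate` per tile), and — because
the annotation interface requires at least one point per image — emits one
uniform random click when it would otherwise submit nothing. Low-effort
workers are modeled purely by low sensitivity; there is no separate
laziness, fatigue or learning process, and no dependence between workers.
Heterogeneous crowds (`sample_profiles`) draw sensitivity ~ U(0.5, 0.95)
and fp_rate ~ U(0, 3), a spread chosen to reproduce the qualitative
individual-quality range reported for paid crowds (median individual F1
well below consensus F1).

Per-worker sub-seeds are `SHA-256(master_seed ":" worker_id) mod 2³¹`, so
simulation output is independent of profile iteration order.

## Tiling (`tiling`)

Tiles form a gx × gy grid with tile width
`ceil((W + (gx−1)·overlap)/gx)` and x-starts
`round(i·(W − tile_w)/(gx−1))` (clamped); the union covers the image
exactly and adjacent tiles share at least `overlap` (default 30 px,
chosen so a cell on an internal boundary appears whole in some tile).
Reference grids: 4 × 4 (16 tiles) for the tumor task, 2 × 2 (4 tiles) for
the astrocyte task. With ceil/round arithmetic the realized overlap can
exceed the nominal value by 1 px on some seams; all geometry therefore
flows from the `TilePlan`, never from hard-coded tile sizes. Stitching
translates clicks by their tile origin and merges same-worker, same-class
clicks that fall within `dedup_radius` (default 5 px) of each other inside
a multiply-covered region.

## Aggregation (`aggregation`)

Clicks of one image and class are grouped by greedy nearest-pair
agglomeration: candidate inter-worker pairs sorted by distance (ties
broken by worker id, then coordinates) are merged when the merged cluster
keeps at most one click per worker and every member lies strictly within
`radius` (default 20 px ≈ 5 µm, about one nucleus radius) of the merged
centroid. The strict inequality makes two clicks exactly 2·radius apart
two singletons. Tests compare this greedy rule against an exhaustive
oracle over all maximal feasible groupings of small instances.

* **Majority vote** accepts a cluster iff support > n/2 of the task
  roster (strict majority; the threshold is configurable). The roster is
  every worker assigned to the task, not merely workers with a nearby
  click.
* **Weighted vote** accepts iff the members' weight sum exceeds half the
  roster's total weight; the consensus point is the weight-weighted
  centroid.
* **Worker weight** comes from a hidden ground-truth image every worker
  annotates: weight = max(0.05, 1.00 − 0.20 · wrong), where *wrong*
  counts false positives **and** missed cells of the one-to-one matching.
  Counting both is a design choice — the source formulation does not pin
  down what a "wrong cell" is — and both the penalty and the floor are
  constants of the scheme, not tunables.

## Quality control (`quality`)

Point matching is greedy one-to-one: candidate (prediction, truth) pairs
within `radius` (default 20 px, shared with clustering) sorted by distance,
accepted when both sides are unmatched. TPR = tp/(tp+fn),
PPV = tp/(tp+fp), F1 = 2tp/(2tp+fp+fn); all-zero counts define every
metric as 0, and an empty prediction set is treated as PPV 0 by the
qualification gate (conservative toward the worker). The gate passes at
pooled PPV ≥ 0.8 inclusive.

Fleiss' κ is computed on an items × {marked, not marked} table whose items
are the ground-truth cells plus clusters of purely false-positive clicks;
each roster worker rates every item by whether one of their clicks matches
it. The κ computation itself is delegated to
`statsmodels.stats.inter_rater.fleiss_kappa`, with the degenerate
expected-agreement-1 case (a single category throughout) defined as κ = 1.
A grid-occupancy item construction was considered and rejected as more
arbitrary; the candidate-cell construction keeps items interpretable.

## Point-to-box conversion (`boxes`)

Two tiers. First, background removal: the intensity histogram (256 bins,
Gaussian-smoothed, sd 2 bins) is scanned for the first local minimum above
the dominant low-intensity mode that genuinely separates two modes (valley
below half of both flanking maxima, second mode above 5% of the peak);
when no such valley exists the Otsu threshold is used and flagged. Second,
a 4-connected breadth-first flood fill from the consensus point accepts a
neighbor iff it is above the background threshold, its color distance
(Euclidean, in whatever channel space the fill runs in) to the running
region mean is ≤ `color_tolerance` (default 0.25), and it lies within
`max_radius` (default 60 px, a generous cytoplasm bound that stops leakage
through diffuse cytoplasmic background) of the seed. Fixed N/E/S/W
neighbor order and incremental mean updates make the fill deterministic; a
seed on background returns the single-pixel mask with a warning flag.

The pipeline fills on the **GFAP plane** by default (`fill_channel`): the
cytoplasmic marker is what delineates astrocyte/tumor outlines, and on an
RGB composite the nucleus-to-cytoplasm color jump would stop the fill at
the nucleus edge. The operating space is configurable because the original
procedure's channel choice and stopping criteria are not fully specified.

Because the two annotation tasks run on disjoint image pools, per-image
labels initially hold one class. Consolidation asks a pluggable
single-class `cross_detector` for the missing class (the default is the
aggregation + flood-fill pipeline on that image's cross-class annotations;
tests also use a ground-truth oracle — the original design used two
preliminary trained detectors here, which this package deliberately
replaces with an interface so the pipeline is testable without training).
Overlapping boxes with IoU > 0.5 are resolved by keeping the
higher-confidence box; crowd-derived boxes carry confidence = normalized
vote support. Labels export as YOLO text (normalized
`class cx cy w h`, six decimals, lossless round trip up to quantization)
and COCO JSON.

## Detection scoring (`detection_eval`)

Predictions below confidence 0.25 are dropped; the rest are matched
greedily in confidence order to the unmatched same-class ground-truth box
of highest IoU, requiring IoU ≥ 0.35 (a deliberately relaxed bound: cell
boxes are small and ragged-edged, so stricter IoU under-counts visually
correct detections). TP/FP/FN are pooled over the entire test set before
computing TPR/PPV/F1 — per-image averages are unstable when single images
hold very few cells of a class. AP uses all-points interpolation of the
precision envelope (exact on small sets; 101-point interpolation is not
needed at these sizes) and, by standard convention, no confidence floor;
AP@[0.5:0.05:0.95] is the unweighted mean over the IoU ladder. A class
with no ground-truth boxes has undefined AP and is excluded from means
with a warning.

## Pipeline and reproducibility

Stage order: simulate → tile → annotate → stitch → aggregate → qc → boxes
→ export → evaluate. Every stage reads only upstream artifacts and writes
its own; the manifest records the full configuration and a SHA-256 per
artifact. All randomness derives from the master seed through stable
string-keyed hashes, so identical configurations reproduce identical CSV
and label outputs.

## Problem sizes used in tests

The test suite and the acceptance script run on scaled-down scenes chosen
to keep the statistical checks well-powered while staying quick: 500 × 500
px regions with ~60 cells for the consensus-vs-individual and crowd-size
studies (100 and 50 seeded runs), 300 × 300 px noiseless scenes for
flood-fill box recovery (20 seeds), 500-instance oracle comparisons for
matching, and a 518 × 438 px simulated ground-truth image (~38 cells) for
the weighting constants. These sizes are the package's own defaults for
validation; the pipeline defaults remain full-size regions.

## Limitations

* Rendered scenes omit autofluorescence, bleed-through, staining batch
  effects and imperfect color deconvolution; passing tests show the
  pipeline's logic is correct on idealized signal, not that a real crowd
  would reach the same scores on real tissue.
* Worker profiles are stationary and independent; collusion, learning and
  compensation effects are out of scope.
* Aggregation covers majority and weighted vote only — no
  expectation-maximization truth inference or learned crowd layers.
* Box extraction claims end at bounding boxes; the flood-fill mask is not
  a segmentation-quality instance mask.
* Detector training itself is out of scope; the detector interface plus
  label export are the hand-off point.
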