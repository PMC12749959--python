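# Methods

## Scope and model of the data

`venmorph` analyzes digital neuronal reconstructions in the SWC format:
each node is a 7-tuple (id, structure code, x, y, z, radius, parent id)
with coordinates and radii in micrometers, code 1 marking the soma, 2 the
axon, 3/4 basal/apical dendrites.  A *compartment* is the frustum between a
node and its parent; the compartment's diameter is taken from the child
node, matching the convention that a section extends from its coordinates
to the next node's.  Codes 0 and 5–10 are accepted and treated as generic
neurite: they contribute to geometry but never to soma logic.

The scientific task is binary: distinguish von Economo neurons (VENs;
elongated stick-shaped soma, few stems, sparse long dendrites, basal
terminal tuft) from pyramidal neurons (isometric soma, many stems, deeper
arbors).  The package provides both routes used for this task — tabular
classification on morphometric features and image classification on 2D
projections — plus the supporting machinery: quality control, agreement
statistics, and a synthetic cohort generator so that every stage is
testable without any external download.

## Reconstruction quality control

Five checks run per reconstruction; failures are report entries, never
exceptions.  Numeric thresholds are package choices (no published values
exist) and are all configurable:

| check | criterion | default |
|---|---|---|
| soma_3d_complete | multi-node soma spans > `z_span_min` in z | 2 µm |
| soma_contour_closed | first/last contour points within `closure_tol` | 2 µm |
| all_processes_attached | every non-soma root reaches a soma node via parents | — |
| z_alignment | no edge with dz > `z_jump_max` while dxy < `xy_step_max` | 20 µm / 5 µm |
| endings_marked | all parent ids resolve; tips terminate with valid radius | — |

The Z-drift signature is deliberately conjunctive: a large z step across a
long xy step is legitimate 3D geometry, while the same z jump over an
almost-vanishing xy step indicates the microscope stage drifted between
focal planes.  The two soma-shape checks are not applicable to single-node
(spherical) somas; a report passes iff no check fails.

Conversion fidelity between two reconstructions of one cell is quantified
by node-order matching: equal parent maps ⇒ topology equal; the maximum
Euclidean node displacement and maximum radius deviation quantify
geometric distortion.

## Morphometry

Branches are maximal unbranched node paths between topological points
(soma attachment, branch point, tip).  Stems have order 1; the order
increments after every branch point (multifurcations increment once, like
bifurcations).  From this decomposition the feature vector comprises 19
named whole-cell metrics plus the soma height-to-width ratio; notable
definitions:

- *contraction* = straight-line / path length per branch, averaged;
- *fragmentation* = compartments per branch (mean and max);
- *partition asymmetry* = |n₁−n₂|/(n₁+n₂−2) over the tip counts of the two
  subtrees at each binary branch point (0 when both subtrees are single
  tips); multifurcations are excluded from this statistic and from Rall's
  ratio.  Whether the per-cell figure should be the mean or the maximum is
  genuinely open; the package reports the mean;
- *Rall's ratio* = (d₁^{3/2}+d₂^{3/2})/d_p^{3/2} at binary branch points;
- *total volume* = Σ frustum volumes (πℓ/3)(r₁²+r₁r₂+r₂²) over compartments
  plus the soma volume (sphere for single-node somas, frustum chain
  otherwise); *soma surface* analogously (4πr² or lateral frustum sum);
- *overall width/height/depth* use full min–max extents with no percentile
  trimming (some morphometry builds trim the extremes; this one does not,
  and documents the deviation);
- *height_to_width_ratio* = soma contour y-extent / x-extent for
  multi-node somas, 1.0 by convention for spherical somas — which is
  exactly why collapsing a distorted soma to a sphere is detectable in
  this feature.

Branch statistics of a soma-only tree are NaN with an explicit flag, never
silently zero.  On trees of ≤ 12 nodes every metric is validated against an
independent brute-force implementation (explicit path enumeration and tip
counting) to 1e-9 relative tolerance; translation, z-rotation and uniform
scaling laws (lengths ×s, surfaces ×s², volumes ×s³, dimensionless metrics
invariant) are asserted as property tests.

## Synthetic cohorts

The generator emulates the two-class contrast at the level the analysis
needs, not at biophysical fidelity.  Each neuron gets a closed elliptical
soma contour (12 points + closure point, z zig-zag ±1.6 µm so the 3D-soma
check is meaningful), one apical stem growing +y with a long unbranched
trunk (trunk length = `apical_trunk_factor` × `max_order` × mean branch
length) ending in a forced terminal tuft, and basal stems fanning out −y,
each growing by recursive branching with per-branch bifurcation
probability, diameter taper, and coordinate jitter kept below the Z-drift
threshold.  The forced apical tuft guarantees ≥ 1 bifurcation per cell, so
partition asymmetry and Rall's ratio are always defined on generated
cohorts.

Class presets (package choices reflecting the qualitative VEN/pyramidal
contrast; they are configuration, not ground truth): VEN — soma elongation
3.0 ± 0.4, 2 ± 0.5 stems, branch length 180 ± 30 µm, max order 3,
pronounced taper; pyramidal — elongation 1.1 ± 0.15, 6 ± 1 stems, branch
length 90 ± 20 µm, max order 5.  Every neuron draws from an RNG stream
seeded by (cohort seed, index), so cohorts are byte-identical across runs
and under parallel generation.  Generated trees pass all QC checks before
defect injection; a depth-3 decision tree separates the default presets
with ≥ 95% 5-fold accuracy at n = 100/100.

Defect injection produces the four reconstruction-error classes the
pipeline is designed to catch: `z_drift` moves one dendritic subtree up in
z while resuming at (almost) the parent's xy position — exactly the
conjunctive drift signature; `detached_process` severs one stem from the
soma; `soma_distortion` collapses the contour to a sphere
(height-to-width ratio → 1.0); `truncated_apical` removes the distal half
of the geometrically longest apical path, which strictly reduces
`max_path_distance` because the apical trunk dominates that path by
construction.

Two *signal-isolated* cohorts support the attribution experiments.  The
soma-signal cohort pairs cells across classes: each pair shares one
dendritic tree node-for-node and differs only in the soma contour, which
is stretched area-preservingly (y × √f, x ÷ √f) to the target elongation;
per-pair soma-size jitter makes soma surface and volume overlap between
classes, leaving the height-to-width ratio as the only clean separator.
The branching-signal cohort holds the soma and the stem count fixed (four
stems in both classes) and varies only branching depth.  These cohorts are
rendered at a common µm-per-pixel scale, centered on the soma, so neither
cell size nor soma position leaks class information into the image.

## Tabular analysis

**Bootstrap consensus importance.**  Classifier stacks in this domain
handle a limited number of predictors per fit, so importance is assessed
over random feature subsets: each repetition draws `subset_size` (default
10) features without replacement, splits the rows 70/30, fits every
adapter on the 70% and ranks the subset by single-pass permutation
importance on the held-out 30% (rank 1 = most important; ties share first
place as 1/t).  Permutation importance was chosen as the one importance
definition that applies uniformly to every adapter; model-specific
importances vary in scale and meaning across learners.  Default 5000
repetitions; per-feature aggregates are the first-position frequency
conditional on inclusion, the median rank, and the rank variance, overall
and per adapter.  Inter-adapter consistency is the mean ± SD Spearman
correlation of per-adapter median-rank vectors.

**Adapters.**  random_forest, gradient_boosting, xgboost, svm (RBF,
decision-function scores) and a CART decision tree standing in for
rule-based tree learners.  Bayesian additive trees and adaptive-spline
learners are accepted through the same adapter contract but not bundled —
the resampling procedure, not any specific learner, is the methodological
content.  Adapters are deterministic under a provided seed.  Undefined
feature values (flagged NaN upstream) are median-imputed at the matrix
boundary so margin-based learners accept the data.

**Balanced-subsample census.**  With heavily imbalanced classes (the
motivating repository has 706 pyramidal cells to 55 VENs), classifiers are
repeatedly retrained on balanced draws of `n_per_class` (default 50) cells
per class and evaluated on every cell outside that draw.  What
"misclassified by an algorithm" means under repeated resampling is not
standardized; the package defines it as an out-of-training-set
misclassification fraction > 0.5 (configurable).  The per-cell count of
adapters exceeding that threshold identifies consistently problematic
reconstructions; on synthetic cohorts with planted label flips, the
flipped cells collect the top counts.

**Group comparison.**  Per-feature two-sided Mann–Whitney U (smaller-U
convention, exact or normal approximation via scipy), Bonferroni-adjusted
p = min(1, m·p), and Cohen's d on the pooled SD.

## Agreement statistics

Rankings are compared three ways.  Fleiss' κ treats the variables as items
and the assigned rank values as categories, with the classical
large-sample variance for the z and p values; κ is undefined (flagged)
when all ratings fall in one category.  Spearman's ρ compares two
consensus rankings with average-rank ties.  The consistency analysis
computes, per variable, the sample variance of ranks within each rater
group (expert vs algorithm), summarizes each group as mean ± SD of those
variances, and reports the expert/algorithm ratio — the factor by which
the algorithms are more consistent.  A group of one rater has undefined
variance and is flagged rather than silently dropped.

## Rendering

Three projection styles re-implement, natively, the three visualization
conventions the image route trains on — a plain skeleton (`original`),
strokes widened proportionally to compartment diameter
(`diameter_enhanced`), and a filled soma polygon enlarged ×2
(`soma_focused`) — as xy orthographic projections without rotation, black
ink on white, auto-fitted with a 5% margin, anti-aliased by 4×
supersampling.  Reproducing the exact pixel output of any external viewer
is a non-goal; the styles capture what each viewer emphasizes.  Masks
occlude a disc of 1.5× the projected soma bounding radius around the soma
centroid (`soma_masked`) or its complement (`dendrite_masked`); the two
masks are exact complements, so their ink sums reconstruct the original
image pixel-for-pixel.  For cohort experiments the disc radius is unified
to the cohort maximum so occlusion geometry itself carries no class
signal.  ImageNet normalization ((x − [0.485, 0.456, 0.406]) / [0.229,
0.224, 0.225]) prepares images for the CNN and is exactly invertible.

## CNN profiles and training

The network stack is a compact numpy implementation authored in the
package: im2col convolution (3×3, stride 1, padding 1), batch
normalization, 2×2 max pooling with deterministic tie-breaking, dense
layers, He initialization, manual backpropagation (verified against
numerical gradients), Adam, and a cosine-annealed learning rate.  Binary
classification uses a single sigmoid logit trained with binary
cross-entropy L = −[y log p + (1−y) log(1−p)] in the numerically stable
softplus form — a one-logit head keeps the implementation aligned with
that loss, rather than a two-logit softmax.

Two profiles share this stack.  `paper_vgg16bn_pretrained` builds the
13-convolution VGG16-BN topology in five blocks with the final fully
connected layer replaced by the binary head; pretrained ImageNet weights
are not bundled, and requesting them falls back to random initialization
with a warning.  `desk_small_cnn` (three conv-pool blocks, flatten, dense
head; 64-pixel inputs) is the profile all tests and experiments run: it
trains in seconds on one CPU.  Reference protocol constants — lr 1e-4,
β = (0.9, 0.999), 10 epochs, batch 16, 224-pixel inputs — are the config
defaults; desk-scale runs use lr 1e-3–1e-2 and 20–30 epochs because tens
of images yield only a few dozen optimizer steps per epoch, far fewer than
a repository-scale run would take at the reference settings.

Evaluation is stratified k-fold (k ∈ {2, 5}) with per-fold metrics from
the same `classification_metrics` implementation the tabular route uses.
Grad-CAM weights the last convolutional layer's feature maps by their
spatially averaged gradients of the class score (the logit for VEN, its
negation for pyramidal), rectifies the weighted sum, min–max normalizes,
and upsamples bilinearly; all-zero gradients yield a flagged all-zero map.
Region summaries report mean relevance inside vs outside the projected
soma disc carried in the rendering metadata.

The masking experiment trains and evaluates under each occlusion condition
with shared seed and folds; the `none` condition reproduces the plain
cross-validation result exactly.  On the signal-isolated cohorts the
experiment recovers the construction: with a soma-only signal, accuracy
survives dendrite masking (soma visible) and collapses under soma masking;
with a branching-only signal the ordering inverts.

## Pipeline

`run_pipeline` executes synth → qc → features → selection → census →
agreement → render → cnn from a single config, with each stage seeded by a
hash of (global seed, stage name) and every artifact checksummed into a
manifest; identical configs reproduce identical manifests bit for bit.
The agreement stage, lacking real survey data, synthesizes an expert panel
as noisy permutations of the algorithm consensus — sufficient to exercise
the statistics, not a model of real experts.  Printed protocol constants
(subset size 10, 5000 repetitions, 50 per class, lr 1e-4, 10 epochs,
batch 16, 224 px) are the library defaults; the pipeline config scales
them down for desk runs.

## Problem sizes and what the tests show

The test and acceptance runs use desk-scale sizes chosen as this package's
own verification conditions: QC defect detection over 100 seeds; bootstrap
importance at 500 repetitions on a 100/100 cohort (planted-signal recovery
and its permutation null); the census at 200 repetitions, 50 per class,
4 adapters, with 4 planted label flips in a 100/100 cohort; masking
experiments on 120 images at 64 px with 2-fold evaluation.  Passing these
shows the procedures are implemented correctly and recover planted
structure under the generator's assumptions — clean, fully labeled, two
well-separated classes with independent cells.  It does not show how the
pipeline behaves on real repository data, where labels are noisy, classes
form a morphological continuum, reconstructions carry uncorrected
artifacts, and image renders come from heterogeneous viewers.

## Known limitations

- The synthetic generator produces planar-ish arbors with small z extent;
  depth-dependent metrics exercise little dynamic range.
- Exact brute-force oracle equivalence is asserted only for trees ≤ 12
  nodes; larger trees rely on the property tests.
- The two unnamed metrics of the motivating 21-metric panel are not
  reproducible from public information; the registry implements the 19
  named metrics plus the soma ratio and is extensible.
- Fleiss' κ on rank assignments treats ranks as unordered categories; an
  intraclass-correlation treatment would respect ordinality but is out of
  scope.
- The VGG16-BN profile is topology-faithful but, without pretrained
  weights, is not a practical classifier at desk scale; it exists to make
  the transfer-learning configuration explicit and testable.
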