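# venmorph

Tools for the quantitative classification of **von Economo neurons (VENs)**
against pyramidal neurons from digital morphological reconstructions.

VENs are large layer-Vb neurons of the anterior cingulate and fronto-insular
cortex with an elongated, stick-shaped soma, single apical and basal stems
without a clear somatic demarcation, and a basal terminal tuft.  Because
morphologically similar "modified pyramidal neurons" are often subsumed
under the same label, an objective, reproducible classification procedure is
needed.  `venmorph` implements such a procedure end to end:

1. **SWC I/O and quality control** (`venmorph.swc_io`) — parse/write the
   7-column SWC reconstruction format, run five reconstruction-quality
   checks (soma reconstructed in 3D, soma contour closed, all processes
   attached, no Z-drift, endings marked), and verify conversion fidelity
   between two reconstructions of the same cell.
2. **Morphometry** (`venmorph.morphometry`) — decompose a reconstruction
   into branches and compute an L-measure-style feature vector: extents,
   stem/branch counts, fragmentation, contraction, partition asymmetry
   |n₁−n₂|/(n₁+n₂−2), Rall's ratio (d₁^{3/2}+d₂^{3/2})/d_p^{3/2}, soma
   surface, frustum volumes, branch orders, and the soma height-to-width
   ratio.
3. **Synthetic morphology** (`venmorph.synthetic`) — a seeded generator of
   labeled two-class cohorts (elongated-soma, sparse-stem "VEN" preset vs
   isometric-soma, bushy "pyramidal" preset), defect injection (Z-drift,
   detached process, soma distortion, truncated apical), and
   signal-isolated cohorts for attribution experiments.
4. **Tabular machine learning** (`venmorph.tabular_ml`) — bootstrap
   consensus variable importance over random 10-feature subsets;
   a balanced-subsample misclassification census (repeatedly train on 50
   cells per class, tally which cells every classifier gets wrong);
   Mann–Whitney U group comparison with Bonferroni correction; shared
   classification metrics (accuracy, precision, recall, F1, ROC-AUC).
5. **Agreement statistics** (`venmorph.agreement`) — Fleiss' κ across
   raters, Spearman's ρ between consensus rankings, and the rank-variance
   consistency ratio between expert and algorithm rater groups.
6. **Rendering + CNN** (`venmorph.rendering`, `venmorph.cnn`) — three 2D
   projection styles (original, diameter-enhanced, soma-focused),
   soma/dendrite occlusion masks, ImageNet normalization; a numpy CNN
   stack with a desk-scale profile and a VGG16-BN-topology profile,
   trained with Adam (lr 1e-4, β₁ 0.9, β₂ 0.999), cosine annealing and
   binary cross-entropy; stratified k-fold evaluation, Grad-CAM
   attribution, and systematic masking experiments.
7. **Pipeline + CLI** (`venmorph.pipeline`, `venmorph` command) —
   configuration-driven orchestration of all stages with deterministic
   seeding and checksummed manifests.

## Worked example

```python
from venmorph.synthetic import GeneratorConfig, generate_cohort
from venmorph.morphometry import feature_table
from venmorph.swc_io import run_qc
from venmorph import tabular_ml

trees, labels = generate_cohort(GeneratorConfig(n_ven=30, n_pyr=30, seed=13))
print(sum(run_qc(t).passed for t in trees.values()), "of", len(trees), "pass QC")

table = feature_table(trees, labels)
print(table.groupby("label")[["height_to_width_ratio", "number_of_stems",
                              "average_length"]].mean().round(2))
```

prints

```
60 of 60 pass QC
           height_to_width_ratio  number_of_stems  average_length
label
VEN                         3.00             1.93          272.86
pyramidal                   1.14             5.97           99.60
```

i.e. every generated reconstruction passes the five quality checks, and the
two classes show the expected contrast: VENs have a soma roughly three
times taller than wide, two stems, and long sparsely branched dendrites,
while pyramidal cells are isometric with about six stems and shorter
branches.  A depth-3 decision tree separates the two classes with ≥ 95%
5-fold accuracy on these features.

Command-line equivalents:

```bash
venmorph synth --n-ven 55 --n-pyr 706 --seed 42 -o cohort/
venmorph qc cohort/VEN_000.swc
venmorph features cohort/ -o features.csv
venmorph census features.csv --n-per-class 50 --n-reps 200
venmorph run config.yaml      # full pipeline from a YAML config
```

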