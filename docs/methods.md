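# Methods

## The analysis model

The pipeline treats each behavioral condition as an independent small-n
study of regional activity. Per subject and region, the input is a c-Fos
cell density (cells/mm³); per condition it is a subjects × regions table.
Three layers of inference are stacked on that table:

**Regional screen.** Each region is tested with a classical fixed-effects
one-way ANOVA across conditions (between-subjects factor: condition).
Regions with a significant omnibus test get SNK step-down post hoc
comparisons: condition means are ordered, each pair's Studentized range
statistic q = |m_a − m_b| / √(MS_within / n_h) is referred to the
Studentized range distribution at (r, df_within), where r is the number of
ordered means the pair spans and n_h is the harmonic mean of the two group
sizes (groups are unbalanced, 7 vs 9, and the harmonic mean is the
standard small-sample choice). The step-down rule is enforced: any pair
nested inside a span already declared homogeneous is non-significant
regardless of its own q. The resulting relation is rendered as a compact
letter display via insert-and-absorb, which by construction satisfies
"share a letter ⇔ not significantly different". No correction is applied
across regions; the screen object carries an explicit
`multiple_testing_corrected = False` flag, and the type-I calibration test
verifies the per-region rate, not a family-wise rate. Variance homogeneity
is assumed, not tested.

**Coactivity.** Functional connectivity is the Pearson correlation of
densities across the subjects of one condition, computed pairwise-complete
with a floor of `min_pairs = 5` complete pairs (below it the pair is a NaN
sentinel and can never form an edge). Zero-variance regions are dropped
with a warning. No correlation p-values exist anywhere in the pipeline:
edge inclusion is purely threshold-based.

**Modules and networks.** Each region's coactivity profile is its full row
of the correlation matrix, diagonal included (the diagonal contributes a
constant, symmetric offset and keeps the rule simple: identical profiles ⇒
distance 0). Profiles are clustered agglomeratively on Euclidean distance.
Complete linkage is the default because its merge heights are monotone,
which makes the half-height cut well-defined; single, average and ward are
accepted alternatives. The dendrogram is cut at `cut_fraction × max merge
height` (default 0.5, per-tree normalization): merges strictly below the
cut join, a merge exactly at the cut does not (deterministic tie-break),
and `cut_fraction = 1.0` is read as cutting above the root (one module).
Unmerged leaves are singleton modules, reported as isolates. Edges then
come from the same correlation matrix at |R| > 0.5 strictly, sign
preserved.

**Node metrics.** Two per-node statistics are computed against the cut
partition (never re-derived from the graph):

- mWMDz = Σ |r_e| / (s_i − 1) over the node's within-module edges, where
  s_i is its module's size. It ranges 0–1; a node alone in its module
  scores 0 by definition. Despite the conventional name it is *not* a
  z score — no standardization is applied, deliberately: with ≤ 13 nodes
  per network a mean/variance standardization is dominated by noise. The
  classical Guimerà–Amaral within-module degree z score is intentionally
  not implemented.
- PC = 1 − Σ_s (K_is / k_i)², with K_is and k_i counting edges (both
  signs) by number, not weight. The count/weight asymmetry between the two
  metrics is deliberate and preserved. An isolated node (k_i = 0) returns
  PC = 0 with a warning rather than an error, since thresholded small-n
  networks can produce isolates even when real studies tune the threshold
  to avoid them.

## Synthetic studies

`fosnet.synthetic` generates the study conditions the pipeline assumes.
Each condition is a multivariate normal draw: the planted correlation
matrix has `rho_within` on same-module pairs and per-module-pair
`rho_between` elsewhere (default 0); draws are scaled to per-region SDs,
shifted to per-region means, and clipped at 0 (counted and warned; with
means ≥ 4 SD clipping is ≪ 0.01 % of cells). The matrix is validated
positive semi-definite at construction; minimum eigenvalues in
[−1e−10, 0) are treated as numerical noise and nudged by adding 1e−10 to
the diagonal, anything worse is rejected with the offending eigenvalue —
no silent repair. Generation is raw-scale (not log-normal) so that planted
Pearson correlations equal their targets exactly, which is what the
recovery tests check.

One master seed spawns per-condition substreams keyed by a SHA-256 hash of
the condition name, so adding or reordering conditions never perturbs
another condition's draws and every table is bit-reproducible.

The canned study (`default_paper_study`) has four conditions — control
(n = 7), partner, opposite-sex stranger, same-sex stranger (n = 9 each) —
over the 13 SDMN regions. Baseline densities sit in the 1 700–3 500
cells/mm³ range with SD = mean/6; eight regions are elevated 1.8-fold in a
condition-specific pattern (VMH in every social condition; mPOA, BNST, LS,
VP with partner and same-sex stranger; AH, MeA, VTA with the same-sex
stranger only). Correlation structure: control is broadly integrated
(three blocks, ρ_within 0.8, ρ_between 0.3); partner has one large
positively coupled 8-region module; the stranger conditions plant
anticorrelated blocks (ρ_between −0.5 / −0.55) and, for the opposite-sex
stranger, several isolates. These choices emulate the qualitative
condition differences such a study reports; they are not fit to any real
dataset.

What the generator does **not** emulate: non-normal density distributions,
hemispheric asymmetry (one value per subject-region is assumed, averaged
bilaterally upstream), missing-at-random structure tied to histology
quality, and between-region variance heterogeneity beyond the specified
SDs. Passing recovery tests therefore show the pipeline is correct under
its own model, not that real c-Fos data satisfy that model.

## Numerical and design choices

- ANOVA degenerate inputs: all values identical ⇒ F = 0, p = 1; zero
  within-group variance with distinct means ⇒ F = ∞, p = 0. MS_within = 0
  in the post hoc declares all unequal-mean pairs significant by
  convention, with a warning.
- Clustering determinism: leaves are processed in lexicographic label
  order, so the tree is a pure function of the labelled distances and
  permuting input region order changes nothing downstream.
- Thresholds are strict inequalities (|R| > 0.5; merge height < cut), so
  boundary values resolve identically on every run.
- The full pipeline writes only deterministic artifacts; the provenance
  manifest records config, seed, package version and the input's SHA-256,
  and two runs of the same config produce byte-identical files.
- Test problem sizes: recovery uses n = 200 subjects × 100 replicates and
  calibration 1 000 replicates at the study's own 7/9/9/9 group sizes —
  large enough that the binomial bands checked ([0.03, 0.07] flag rate,
  ≥ 95/100 recoveries) have comfortable margins under the planted effect
  sizes.

## Known limitations

- Pearson correlations on 7–9 subjects are extremely noisy; the module
  partitions and networks of any single real study at such n should be
  read descriptively. The package reproduces the analysis faithfully; it
  does not claim the analysis is well-powered.
- The SNK procedure does not control the family-wise error rate at α in
  the strong sense; it is implemented because it is the field's chosen
  post hoc here, with Tukey-dominance verified in tests (every
  Tukey-significant pair is SNK-significant).
- Only one-way between-subjects designs are supported; no repeated
  measures, no non-parametric alternatives, no partial correlations, no
  modularity-optimization community detection, and no cross-condition
  network statistics (conditions are compared descriptively).
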