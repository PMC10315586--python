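# Methods

## Model

A bulk methylation profile is treated as a convex combination of
cell-type-specific mean profiles. For a probe set P with reference matrix
X ∈ [0,1]^{|P|×k} (columns = cell types) and bulk vector y ∈ [0,1]^{|P|},
the proportion vector solves

    min_π ‖y − Xπ‖²  subject to  π ≥ 0 and Σπ ≤ 1 (or Σπ = 1).

This is the classical constrained-projection formulation for
reference-based cell mixture estimation on beta values. Beta values are
bounded and approximately linear in cell mass, which is what makes the
mixture model sensible; the residual absorbs measurement noise and any
cell type absent from the reference.

### Exact solver

The QP is solved exactly rather than iteratively:

- **Σπ ≤ 1**: scipy's NNLS (an exact active-set method) solves the
  nonnegativity-only problem; if its solution satisfies the sum bound it
  is the constrained optimum (the constraint is inactive at the KKT
  point). Otherwise the sum constraint is active and the equality problem
  is solved.
- **Σπ = 1**: the optimum's strictly-positive support satisfies the
  stationarity conditions of its own equality-constrained least-squares
  problem, so enumerating all 2^k − 1 supports, solving each (k+1)×(k+1)
  KKT system, and keeping the feasible candidate with the lowest
  objective finds the global optimum. k ≤ 8 throughout this package
  (seven cell types plus a nuisance column), so enumeration is cheap,
  deterministic, and exact to machine precision; a hard limit of k = 16
  guards against misuse. Singular KKT systems (duplicate reference
  columns) fall back to the minimum-norm least-squares solution, which
  attains the same objective; a rank-deficiency warning is emitted.

Negative round-off is clipped to zero after solving. Solver identity and
tolerances are recorded in output metadata.

## Hierarchy and the three-step procedure

Seven leaf cell types are arranged under three Layer-1 groups:
neuronal (GABA, GLU), glial (astrocyte, microglia, oligodendrocyte),
endothelial/stromal (endothelial, stromal). One marker library is built
for the Layer-1 node (discriminating the groups) and one per Layer-2 node
(2A endothelial/stromal, 2B glial, 2C neuronal).

1. The Layer-1 library estimates group proportions with Σπ ≤ 1; the
   shortfall from 1 is reported as `unknown` (bulk mass not captured by
   the reference, e.g. cell types outside the panel).
2. Each Layer-2 node estimates within-group coefficients on its own
   probes with Σ ≤ 1.
3. The node coefficients are renormalized to conditional proportions
   (summing to 1) and multiplied by the Layer-1 group proportion. Leaf
   proportions therefore always sum exactly to their group total, and the
   `unknown` mass carries over from Layer 1. Single-leaf groups pass the
   group proportion through unchanged.

### The complement column

A Layer-2 node's probes are chosen to discriminate *within* the group,
but the bulk sample also contains off-group cells, which contribute
baseline-level methylation on those probes. Projected onto the node's
leaf columns alone, that contamination is absorbed into the fitted
coefficients and biases the conditional split — under this package's
synthetic conditions the bias reached several percentage points of
absolute proportion (average RMSE ≈ 3.5–4% instead of < 1%), because the
contamination's projection onto between-leaf contrasts does not vanish
with tens of probes per leaf.

Each Layer-2 sub-library therefore stores a **complement profile**: the
mean methylation of all reference samples outside the node's cell types,
over the node's probes. It enters the node fit as one extra nuisance
column, making the generative bulk signal fully representable
(y ≈ X_leaves·π_leaves + complement·(1 − π_group)); its coefficient is
excluded from the conditional renormalization and reported only in
diagnostics. With it, the same pipeline recovers the synthetic validation
mixtures with average RMSE ≈ 0.15% (see `scripts/acceptance.py`). An
alternative — constraining the node's coefficient sum to the Layer-1
group estimate — was evaluated and rejected: it removes the first-order
bias only when marker baselines balance across leaf blocks, and measured
~3.5% RMSE otherwise.

### Degenerate node solutions

If a node's leaf coefficients are all zero while its Layer-1 group
proportion is positive, conditional proportions are undefined (0/0); the
package falls back to a uniform conditional split and warns. When the
group proportion itself is (near) zero the fallback is silent, since the
leaf proportions are zero regardless.

## Marker selection

Per node, candidate probes are scored one-vs-rest for each cell type:
effect = mean beta in the class minus mean beta in the rest, with a
pooled two-group residual variance per probe. Variances are moderated by
empirical Bayes: a scaled inverse-chi-square prior (d₀, s₀²) is fitted to
the per-probe variances by moment matching on log variances (digamma /
trigamma moments; trigamma inverted by Newton iteration), and the
posterior variance (d₀s₀² + d·s²)/(d₀ + d) replaces s² in the
t-statistic. This is the standard moderation scheme in differential
methylation analysis; with few reference samples per type it prevents
low-variance probes from dominating the ranking. Probes with zero
effect get t = 0; if every probe has zero residual variance (a
degenerate, noise-free panel) the prior cannot be fitted and variances
are left unmoderated.

Selection modes: `hyper` (top n by t per class), `hypo` (bottom n),
`hybrid` (union of both; default, n = 50 per direction per cell type).
Ranking ties break lexicographically on probe ID, so selection is fully
deterministic. The pooled library is the deduplicated union across
classes, sorted by probe ID. Layer 1 ranks groups over all reference
samples; each Layer-2 node ranks its leaves over only its group's
samples. Probes with any missing value in the reference cohort are
dropped before selection.

For a two-class node, effects are antisymmetric, so class A's hyper set
equals class B's hypo set and the hybrid pool holds at most 2n distinct
probes — a structural property, not a defect.

### Dispersion separability criterion

For comparing candidate libraries: over a probe subset with class
centroids c_k, global centroid c, class sizes n_k and N samples total,

    between = sqrt((1/N) Σ_k n_k ‖c_k − c‖²),
    within  = sqrt((1/N) Σ_k Σ_{i∈k} ‖x_i − c_k‖²),  DSC = between/within.

Higher is better separation. Identical within-class samples with distinct
centroids give an infinite DSC; fully degenerate data raise an error.

## Synthetic data generator

The generator emulates a purified-cell discovery panel on a two-layer
hierarchy:

- every probe draws a baseline beta uniformly from `baseline_beta_range`
  (default (0.1, 0.9));
- each Layer-1 group and each leaf type owns a disjoint block of
  `n_signal_probes_per_class` marker probes (default 20); within a block
  probes alternate direction, shifted +δ or −δ for the affected samples
  (δ_group = 0.5, δ_leaf = 0.4 by default — strong markers, as purified
  brain cell types show);
- i.i.d. Gaussian noise (sd 0.02 by default) is added and values are
  clipped to [0, 1]. Signal-probe baselines are drawn so the shifted
  value keeps headroom (margin = 0.05 + 4·noise_sd) inside [0, 1],
  preserving the designed effect sizes against clipping;
- 5 samples per leaf type by default; identical seeds give bit-identical
  panels.

Bulk mixtures follow the validation recipe: per mixture, seven
Uniform(0,1) draws normalized by their sum give the designed proportions
(equivalent to a flat Dirichlet only approximately — this is the verbatim
procedure, not a Dirichlet); per cell type, `samples_per_type_draw`
purified samples are drawn without replacement and averaged, and the
mixture column is the product of that mean matrix with the proportion
vector. Optional i.i.d. noise is added then clipped; per-probe, per-type
standard deviations across the drawn samples are returned as metadata so
users can inject realistic within-type noise. Default mixture noise is
zero: the validation design isolates estimator error from measurement
noise, and a noise-sweep test covers degradation separately.

What the generator does **not** emulate: the bimodal marginal
distribution of real beta values, probe-type chemistry differences, batch
effects, spatially correlated probes, and realistic (non-uniform) brain
cell composition. Passing tests therefore demonstrate correctness of the
estimation machinery under the designed signal structure, not performance
on real arrays.

`exact_mixture_from_library` builds bulk profiles that are exact
per-node combinations of a library's mean columns (group totals on
Layer-1 probes; absolute leaf proportions plus complement mass on each
Layer-2 node's probes). It exists to state the solver's exactness
property sharply — such mixtures are recovered to < 1e-6 at both layers —
and requires disjoint sub-library probe sets, which libraries built on
the generator's planted blocks satisfy.

## Evaluation

Per cell type over mixtures: Pearson r (R² reported as r², matching
common usage alongside correlation tests), RMSE and MAE in proportion
units (×100 for percentage points). Aggregates are unweighted means over
the seven cell types; the `unknown` column is excluded (designed mixtures
place no mass there). A cell type with constant designed proportions has
undefined r — it is flagged, warned about, and excluded from the R²
average while RMSE/MAE are still reported.

Composition summaries: GNR = (astro + micro + oligo)/(GABA + GLU),
GABA/GLU ratio, and within-glia fractions; zero denominators yield NaN
sentinels with warnings rather than errors.

## Problem sizes and defaults

The bundled validation runs at desk scale — 2,000 probes, 5 reference
samples per type, 50 mixtures — chosen so the full pipeline (and its
tests) executes in seconds while leaving the estimation problem
non-trivial: with n = 50 per direction, ~60–80% of each library is
noise-selected filler, which is exactly the regime where the complement
column matters. Library construction cost is dominated by the moderated
tests (O(probes × samples)); deconvolution cost by per-sample QPs
(milliseconds each).

Coverage rules at deconvolution: a warning below 80% of a node's library
probes present in the bulk, an error below 50%; probes missing in an
individual sample are dropped from that sample's fit only, under the same
thresholds.

## Known limitations

- The complement column models off-group contamination as a single
  average profile; if off-group composition varies wildly across bulk
  samples, its fit degrades gracefully (the residual grows) but the
  conditional split can drift.
- The `unknown` fraction is a residual-mass estimate, not a calibrated
  proportion of unprofiled cell types.
- Support enumeration in the equality-constrained QP is exponential in
  the number of cell types; fine for hierarchical nodes (≤ 8 columns),
  not intended for references with dozens of types.
- Uniform-simplex mixture truths rarely produce the extreme compositions
  of real tissue (e.g. > 90% neuronal NeuN+ sorts); pure-profile tests
  cover that corner separately.
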