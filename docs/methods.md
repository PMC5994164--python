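# Methods

## Scope and data model

The package infers a physiological response (resting metabolic rate in
mL O₂ h⁻¹ g⁻⁰·⁶⁷, or periosteal bone apposition rate in μm/day) for fossil
tips of a time-calibrated phylogeny from one histological predictor,
primary osteon density. Trees are rooted, with branch lengths in Ma on
every non-root edge; they need not be ultrametric (fossil tips end before
the present). Trait tables carry one row per species: the density (a
fraction in (0, 1)), the response (present for *training* species, absent
for *target* fossils), and the role flag. Section masks are integer label
grids: 0 background/medullary space, 1 compact bone matrix, 2 primary
osteon area (vascular canal plus lamellar infill).

## Tree handling

Newick parsing is delegated to dendropy; the canonical writer emits labels
unquoted when alphanumeric and branch lengths with up to 6 significant
digits (`precision=None` writes shortest-exact decimals so write→read is an
identity to the bit, used wherever serialisation must not perturb
numerics). Branch lengths are rounded to integer Ma with the half-up rule
(`floor(x + 0.5)`), matching everyday rounding and making the convention
deterministic; zero-length results are retained and logged rather than
clamped, because the PEM weight function already maps them to weight 0 for
steepness < 1. Fossils are added by *grafting*: the attachment edge is
split at a stated distance from its child node and a pendant tip hung
there, which provably conserves every pre-existing root-to-tip path
length. Polytomies are accepted throughout (nothing in the influence-matrix
formulation needs binary trees); binary trees are the tested main path.

## PEM construction

The influence matrix records root-to-tip path membership over edges in
preorder. Edge weights are `w = ψ·b^((1−a)/2)`; ψ is fixed at 1 by default
because the regression coefficients absorb overall scale, leaving the
steepness *a* as the single weighting parameter. The weighted influence
matrix is column-centred and decomposed by thin SVD; singular values below
`1e-10 × max(d)` are dropped as numerical rank deficiency, and each
eigenvector's first nonzero entry (in tip order) is made positive so bases
are bit-reproducible across platforms. Out-of-sample tips are scored as
`(row − column means) · V · diag(1/d)`; the training basis is built on the
full analysis tree's edge set but only the training rows, so edges private
to fossil tips have identically zero centred columns and cannot leak into
the basis — scoring is therefore invariant to the fossil's pendant branch
length, which the tests check explicitly.

## Regression, AICc, LOOCV, intervals

Both variables are log₁₀-transformed (the source datasets for RMR and
apposition rate are conventionally plotted on log₁₀ axes, and the values
span orders of magnitude); back-transformation is plain exponentiation
without bias correction, since results are reported directly in natural
units. The design is `[1, selected eigenvectors, log₁₀ density]`, fit by
OLS. Model choice uses Gaussian AICc with k counting the intercept, slopes
and residual variance; candidates whose small-sample denominator `n−k−1`
is non-positive, or whose design is rank-deficient, are rejected rather
than raised. Eigenvectors enter by forward selection in order of
decreasing singular value, stopping at the first candidate that fails to
lower AICc by more than 1e-9 (ties resolve to fewer parameters); this
selection strategy is a package choice exposed as `forward | all | none`.
The steepness is either fixed or scanned on the grid a = 0, 0.01, …, 1
with the AICc-best selected model kept.

Numerical choices: RSS below `1e-16 × max(TSS, 1)` is treated as exactly
zero before entering the AICc log, so noiseless fits stay finite and
compare by parameter count alone. The residual variance used for
intervals is the unbiased `RSS/(n−p)` with p mean parameters, and interval
critical values use `t(0.975, n−p)` — the standard OLS prediction-interval
degrees of freedom. Intervals default to *prediction* intervals
(`±t·σ·√(1 + hᵀ(XᵀX)⁻¹h)`): the fossil boxes they correspond to describe
the uncertainty of a new observation, not of the conditional mean; a flag
switches to confidence-of-mean intervals.

Report CSVs are written with a canonical float format of 12 significant
digits: report byte-identity across reruns is a contract of the pipeline,
and fixed formatting makes it hold independently of last-bit variation in
the underlying linear-algebra kernels.

LOOCV deliberately refits *everything* per fold — basis, steepness choice,
eigenvector selection — by demoting the held-out species to a target and
re-running the full procedure, so PRESS honestly reflects the whole
pipeline's out-of-sample error. Failed folds are flagged and excluded from
PRESS rather than aborting the run.

## Ancestral states

Internal-node states under Brownian motion are computed by minimising the
BM deviance `Σ (x_child − x_parent)²/b` — a sparse linear solve on the
tree's weighted Laplacian with conductance 1/b per edge. These are exactly
the GLS/ML estimates (the tests verify agreement with an explicit
node-to-tip covariance GLS oracle to 1e-8). Zero-length edges are
contracted (index-based union-find, so the contraction order is
deterministic) before the solve; contracted groups containing tips are
treated as known with the mean of their tip values. Conditional variances
are `σ²·diag(L_uu⁻¹)` with σ² the ML Brownian rate from the tips.
Reconstruction runs on the log₁₀ scale, consistent with the regression;
exports carry both log and natural values. Fossil tips enter with their
*predicted* values treated as known — prediction uncertainty is not
propagated into ancestral states, a known limitation.

## Histology measurement

Primary osteon density is an area fraction: osteon pixels divided by
osteon-plus-bone pixels, with background and medullary space excluded from
the denominator ("whole bone area" is read as the compact cortical field
including the osteons themselves). Species values average four cortical
regions of interest — the protocol that compensates for stress-related
structural differences around the cortex — and per-region values are
always retained; the arithmetic mean was chosen as the simplest unbiased
pooling where the original protocol leaves aggregation unstated. ROIs use
0-based, row-major, half-open intervals. Segmentation of raw micrographs
is out of scope: the package consumes already-labelled masks.

## Synthetic data

The generator emulates the assumed data-generating process, not real bone:

* **Trees** — pure-birth (Yule) process started from the root's two
  daughters; each of k lineages waits Exp(k·λ) before a uniform lineage
  splits, with one extra waiting time after the last split. Default
  λ = 1.0 per Ma, giving ~2.5–3.5 Ma deep 32-tip trees.
* **Traits** — `log₁₀ y = β₀ + β₁·log₁₀ density + BM(σ²_BM) + N(0, σ_e²)`,
  with log₁₀ density uniform over the density range. Defaults β₁ = 1,
  σ²_BM = 0.5 per Ma, σ_e = 0.1 are the standard conditions of the
  recovery and calibration tests; the density range 0.02–0.40 brackets
  values plausible for amniote cortical bone. With the default tree depth
  this yields log-trait spreads of order one, comparable to real
  comparative datasets. Fossil-like targets are made by withholding the
  response of known tips, so predictions have exact recorded truths.
* **Masks** — a circular bone field seeded with non-overlapping rasterised
  discs (pixel-level overlap test) until the osteon fraction first reaches
  the target; when the field jams, the sampled radius range shrinks
  geometrically so smaller discs fill interstices, making fractions up to
  ~0.5 reachable. The achieved fraction is recorded and equals the
  measured density by construction.

What the generator does **not** emulate: spatial gradients of vascularity
across the cortex, canal orientation and shape anisotropy, growth marks,
secondary remodelling, and measurement error in region placement. Passing
tests therefore demonstrate correctness of the statistical machinery under
its own assumptions, not robustness to these real-data features.

## Test and acceptance problem sizes

Property tests use 100 random trees of 2–16 tips (Brownian-limit check),
100 trees of ≤ 6 tips (ancestral GLS oracle), 20 eight-tip datasets (LOOCV
identity), 200 replicates of 32-tip datasets for slope recovery and 500
for interval calibration, and ten mask targets 0.05–0.5 at 384² pixels —
sizes at which the Monte-Carlo tolerances stated in the tests are sharp
while the whole suite stays fast. The acceptance script re-runs the same
measurements from a user seed and adds a study-scale synthetic run
(15 training tips, 8 withheld targets, grid steepness).

## Known limitations

* Prediction uncertainty of fossils is not propagated into ancestral
  states or downstream rankings.
* One global steepness; no per-edge steepness vectors or reticulations.
* A single co-predictor (density); no multi-predictor designs or model
  averaging.
* The published-dataset comparison requires the study's deposited tree and
  measurement files, which are not bundled.
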