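# Methods

This note documents the models implemented in `gwgen`, the synthetic-data
generator that the validation suite runs against, the numerical choices
made where the procedure was underdetermined, and the method's measured
limitations.  Every number quoted here is computed by the test suite or by
`scripts/acceptance.py`; nothing is asserted that the code does not
measure.

## 1. Node models and identification

Four model classes share one regression skeleton per node and sample:

| class   | response | linear regressors | product regressors | constraint |
|---------|----------|-------------------|--------------------|-----------|
| protein | `q_i`    | —                 | `q_i·q_h` per PPI partner `h` | none |
| gene    | `z_j`    | TF `p_u`, lncRNA `x_v` | `z_j·r_w` per miRNA `w` | coefficient ≤ 0 |
| lncRNA  | `f_k`    | TF, lncRNA        | `f_k·r_w`          | ≤ 0 |
| miRNA   | `b_t`    | TF, lncRNA        | `b_t·r_w`          | ≤ 0 |

plus an intercept (the **basal level** β) in every model.  Columns are laid
out in blocks — TF/protein, lncRNA, miRNA, basal — and the design matrix is
assembled literally in this product form: the response appears inside its
own miRNA/PPI regressors.  This is deliberate: the identification step fits
the model exactly as written rather than re-deriving the equivalent
rational form, and the data generator guarantees the two are consistent.

Estimation minimizes `½‖Φθ − y‖²` with box constraints `θ_c ≤ 0` on
miRNA-repression coefficients.  The solver first takes the unconstrained
(minimum-norm if rank-deficient, cutoff `σ < 1e-10·σ_max`) least-squares
solution and accepts it when it is feasible; otherwise it solves the
bounded problem with SciPy's BVLS (falling back to the trust-region
reflective solver for rank-deficient or under-determined designs).  An
active-set enumeration oracle in the test suite confirms optimality to
1e-8.

**Over-parameterized nodes.** When a node's candidate order exceeds
`N − 2`, the problem is capped before fitting at the `N − 2` regressors
whose assembled columns correlate most strongly (absolute Pearson) with
the response.  Assembly itself never truncates, so the full candidate
structure remains inspectable.

## 2. Order selection

Per node, `AIC(k) = log(RSS_k/N) + 2(k+1)/N` (natural log; the `+1` counts
the basal term).  Two searches are provided:

* **greedy** (default): fit the full constrained model, rank regressors by
  `|estimate| · sd(column)`, evaluate the nested prefix models of order
  `0..H`, keep the AIC minimizer (ties → smaller order);
* **exhaustive** (`H ≤ 15`): evaluate all subsets, order = subset size,
  deterministic tie-breaking by size then lexicographic position.  Used as
  the oracle for the greedy path.

For gene/lncRNA/miRNA nodes the per-class retained counts are read off a
single joint ranking rather than a three-dimensional grid search, which
would be exponential.  Numerical choice: inside the search, RSS is floored
at `(1e-9‖y‖)²` so that numerically perfect fits (noise-free data) compare
as ties and the order penalty decides; without the floor, float dust at
1e-25 would dominate the log term.  `aic()` itself floors only exact zero
(at 1e-300, with a warning).

Pruning runs the search independently per node ("one node at a time") and
re-fits the retained set; the real network's edge weights are the refitted
abilities, not the full-model estimates.

## 3. Synthetic data: what it emulates, what it does not

The generator produces data that satisfy the fitted equations *exactly* up
to an additive Gaussian `ε` (default sd 0.1) — this makes parameter
recovery a well-posed validation surface.  Solving each node's equation for
the response gives `value = (linear terms + β + ε)/(1 − Σ w_prod·x)`; the
sampler sweeps nodes in topological order (exogenous drivers first) and
falls back to fixed-point iteration (tol 1e-10, ≤ 100 sweeps) for cyclic
inputs.

Key conventions, fixed once:

* **Exogenous drivers.** Half of the proteins (configurable) have no
  incoming PPI edge and are sampled `Uniform(1, 3)` per sample, as is any
  node without regulators.  Expression is on an arbitrary positive linear
  scale, O(1–10), no log transform.
* **Weights** have magnitude `Uniform(0.3, 1.0)` with random sign; miRNA
  repression weights are always negative.  Basal levels are
  `Uniform(1, 3)`.
* **Spectral safety.** Weight sets feeding a node are re-drawn at
  generation time using interval arithmetic over the reachable value
  ranges so that every solved denominator stays ≥ 0.25 and values stay in
  (0.01, 50); the sampler still verifies `|denominator| ≥ 0.2` per sample
  and raises otherwise.
* **Identifiability screening.** A node without product regressors is an
  exact affine function of its parents, so an unlucky regulator draw can
  make a downstream design exactly rank-deficient at zero noise.  Each
  node's noise-free value is tracked as an affine combination over
  "nonlinear atoms" (exogenous drivers and denominator-solved nodes), and
  candidate regulator sets are re-drawn when their representations are
  linearly dependent.  With this screening, noise-free refitting recovers
  every true ability to ~1e-13 relative error.
* **Stage structure.** Stages share one weight set; a stage differs only
  through per-node basal offsets (`stage_deltas`), the generator's model of
  epigenetic modification between stages, plus fresh sampling noise.
* **Decoy injection** adds `round(fp_ratio·|true edges|)` edges drawn
  uniformly from all role-compatible non-edges, recorded in the manifest.

Not emulated: probe-level microarray artifacts, batch effects, missing
values, heteroscedastic noise, and any feedback from genes (genes are
sinks).  Passing tests therefore demonstrate correctness of the estimation
machinery under the model's own assumptions, not robustness to real
microarray noise structure.

## 4. Principal network projection

All fitted abilities are placed in the zero-padded matrix `P` with rows
ordered proteins (including receptors and TFs), genes, lncRNAs, miRNAs and
columns ordered protein/TF, lncRNA, miRNA regulators.  One shared
protein/TF column universe serves both PPI partners (protein rows) and TF
regulators (other rows); this is the only reading under which the stated
matrix dimensions are consistent.  `project()` computes the thin SVD,
eigen-expression fractions `E_m = d_m²/Σd²`, the minimal rank `A` reaching
the energy threshold (default 0.85), and per-node scores
`D_R(ω) = ‖row_ω(P)·R[:, :A]‖₂`.  Invariants verified by tests: fractions
sum to 1 (±1e-12), `A` is minimal, scores at threshold 1 equal row
2-norms (±1e-10), and scores are non-decreasing in `A`.  Core extraction
keeps the top-scoring nodes per role (per-role quota or fraction, default
30%, ties broken by node id) and induces all real-network edges among
them.

## 5. Stage comparison and basal shifts

Structural comparison is set algebra on node ids and `(source, target,
etype)` edge keys; weights are reported but never used for membership.
Basal shifts are computed from the real-network (post-pruning) fits:
`Δβ = β̂_b − β̂_a`, standardized by the pooled standard error from a
residual bootstrap per stage (resample residuals, refit, default 100
draws), flagged above a cutoff of 2.0 with direction `sign(Δβ)`.  With
`n_boot = 0` the report degrades to a raw Δβ ranking and flags nothing.

**Limitation (measured).** For nodes whose design contains the response
itself (bilinear PPI and miRNA-product columns), the basal estimate's
variability across independently sampled cohorts exceeds the
design-conditional bootstrap SE, because the regressor columns embed the
response's own noise and re-draw with the cohort.  On a planted-shift
benchmark (regulatory network with exogenous drivers, +2.0 offset on one
regulated gene, noise 0.1, N = 150, 50 seeds) the planted gene is flagged
"up" in 50/50 runs but is the top-ranked shift in only 42/50, and a
zero-shift control flags ~14% of nodes at cutoff 2.0 — dominated by nodes
with retained miRNA-product regressors.  Basal levels of endogenous
(bilinearly coupled) proteins are effectively unidentifiable at this
precision, which is why the shift benchmark drives all proteins
exogenously.  Users should treat shift scores on product-regressor nodes
as ordinal evidence, not calibrated statistics.

Over-representation of a node selection against GMT gene sets uses the
one-sided hypergeometric tail with Benjamini–Hochberg adjustment
(statsmodels).

## 6. Permutation validation

A node's model is significant when its selected-order AIC is strictly
lower than all `B` AICs from refits on response-permuted data (regulators
fixed; product columns rebuilt from the permuted response), giving the
reported bound `p < 1/(B+1)`.  Permutation is per node; what is shuffled
is the node's own response across samples, the standard exchangeable null
for a regression.  Basal-only models are annotated: permutation leaves
their AIC unchanged, so they can never be significant — a conservative
convention.  Calibration measured on 500 pure-noise nodes at `B = 19`:
significant fraction 0.044–0.066 across seeds against the nominal 0.05.

Transfer evaluation refits each node's retained support on an independent
dataset and compares that AIC with the permutation null built from the
training data at the same support, reporting the fraction of common nodes
that stay significant.  On an independent cohort simulated from the same
ground truth (demo pipeline, 60 samples/stage) the fraction is ~0.52–0.55;
it is bounded above by the fraction of nodes that retain any regulator,
since basal-only models cannot be significant.

## 7. Pipeline

`run_pipeline()` executes simulate → identify+prune (per stage) → project
→ extract core → neighboring-stage differential reports (structural diff +
basal shifts) → transfer evaluation, writing one named TSV artifact per
step plus a JSON manifest (configuration, derived seeds, sizes, warnings,
timings).  One master seed deterministically spawns every module seed
(`numpy.random.SeedSequence`); reruns are byte-identical on all tabular
artifacts.  Default stage sample sizes follow the motivating cohort's
Dukes-stage split (early 137, mid 92, late 61); the bundled demo and
validation configurations use 40–60 samples per stage and 40–60 nodes to
keep runs in the seconds-to-a-minute range.

## 8. Known limitations of the pruning step (measured)

AIC with a `2k/N` penalty is a liberal selector: a pure-noise regressor
survives with probability `P(χ²₁ > 2) ≈ 0.157` asymptotically, and ranking
inflates this for the best of several decoys.  Worse, every PPI candidate
column is `y·q_h` and *contains the response*: such a column always
explains a large share of the response's variance — including its noise —
so PPI decoys targeting weakly-explained proteins are retained at near
100%.  Under a stress benchmark (one decoy per true edge, noise 0.1,
N = 150) the measured mean decoy-removal recall is ~0.24 and true-edge
retention ~0.80.  These are properties of the selection criterion and the
bilinear model class, not of the implementation: the exhaustive-search
oracle reproduces them.  Practical consequences: treat the real network as
a data-supported superset, rely on the projection step (which weighs edges
by estimated strength) to suppress weak decoys, and use the permutation
test — which the self-regression trap also passes through — only as
evidence of fit, not of causal regulation.
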