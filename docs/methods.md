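# Methods

This note documents the model implemented by `dnecpm`, the choices made
where the design was genuinely open, and what the synthetic-data tests do
and do not demonstrate.

## Pipeline model and assumptions

The analysis assumes its input is a per-subject node-by-time matrix of
regional BOLD signals, already motion-corrected, normalised and parcellated
upstream (the package deliberately contains no image-space processing).
Motion enters only as a 6-column rigid-body parameter table per subject.

**Conditioning.**  The first `n_discard` volumes (default 4) are dropped
for magnetisation equilibration.  Nuisance regression uses ordinary least
squares against `[intercept | Friston-24 motion | optional global/CSF/WM
columns]`; residuals are exactly orthogonal to the design.  Filtering is a
4th-order Butterworth band-pass (0.01–0.10 Hz) applied forward-backward
(`sosfiltfilt`), i.e. zero-phase with a squared magnitude response.  The
default step order is discard → regress → filter; regressing before
filtering follows the usual argument that regressing *after* filtering can
reintroduce filtered-out nuisance variance.  The order is configurable and
echoed in the run report.

**Motion exclusion.**  Frame-wise displacement is the Power
backward-difference form: FD(t) = Σ|Δtranslation| + R·Σ|Δrotation| with
head radius R = 50 mm (configurable).  Subjects with *mean* FD above 1 mm
are excluded.  The mean-versus-maximum reading of the exclusion rule is
ambiguous in common usage; the mean-FD reading is implemented and the
threshold is configurable.

**Dynamic network.**  Windows of 50 time points advance 1 TR at a time:
a T-point series yields ⌊(T−50)/1⌋+1 windows — 191 for T = 240, 187 for
T = 236.  (Published descriptions of this design quote 191 windows
together with 4 discarded volumes; the two are arithmetically consistent
only if windowing the undiscarded 240-point series.  The package always
computes the count from the actual series length.)  Within each window a
Pearson correlation matrix is turned into a graph; by default the graph is
**weighted**, keeps only positive correlations, applies no sparsity
threshold, and assigns edge length 1/r.  Weighted graphs are the default
because binarising a dense correlation matrix without thresholding makes
every window's graph complete, every nodal efficiency identically 1, and
the dnE correlation undefined.  Binary mode, |r| rectification and a
proportional threshold (top fraction of edges by |weight|, ties broken by
lexicographic node-pair order for reproducibility) are available.

Nodal global efficiency is the Latora–Marchiori form
E_i = (1/(N−1)) Σ_{j≠i} 1/d(i,j), with all-pairs shortest paths computed
by dense Floyd–Warshall; unreachable pairs contribute 0.  The dnE matrix
is the node-by-node Pearson correlation of the efficiency curves.  A
zero-variance curve (possible in binary mode or on degenerate input) is
flagged in `degenerate_nodes` and its correlations set to 0 rather than
NaN, keeping the downstream feature matrix finite while making the
degeneracy auditable in the run report.

## Prediction model

The regression objective is

    min_β ‖y − xβ‖₂² + ½ λ ‖β‖₁ ,   λ = 0.08 by default,

with x the vectorised strict upper triangle of the dnE matrix.  Because a
single penalty can only act comparably across features on a common scale,
features are standardised (zero mean, unit variance; zero-variance
features dropped with a warning) and y centred **within each training
set**; the objective is solved in that standardised frame and predictions
are mapped back to the original score scale.

**Solver mapping.**  scikit-learn's Lasso/LassoLars minimise
(1/2n)‖y−Xw‖² + α‖w‖₁.  Matching terms gives α = λ/(4n) for n training
samples.  The optimality conditions of the objective above are

    |2 xₖᵀ(y − xβ)| ≤ λ/2          if βₖ = 0
     2 xₖᵀ(y − xβ) = (λ/2)·sign(βₖ)  otherwise,

hence λ_max = 4·max_k |xₖᵀ y_c|: any λ above it yields β = 0.  These
conditions are evaluated by `kkt_violation` and pinned by unit tests, so
λ = 0.08 has a precise, solver-independent meaning.  The default solver is
LassoLars (exact homotopy path; KKT residuals at machine precision);
coordinate descent is available as `solver="cd"`.  Every fit starts cold:
warm-starting across cross-validation folds is deliberately avoided
because an incompletely converged warm-started fit retains information
from the previous fold's training set — which contains the current
held-out subject — and measurably inflates cross-validated correlations.
λ = 0 is accepted for testing and solved by least squares (minimum-norm
when underdetermined).

**Evaluation.**  Leave-one-out cross-validation re-estimates the
standardisation and the fit on every fold of N−1 subjects.  Performance is
the Pearson correlation between the N held-out predictions and the true
scores (two-tailed p via the t transform, multiplied by the number of
score targets tested — two when both medication-off and medication-on are
predicted — and capped at 1) plus the mean absolute error.  Significance
uses a one-sided label-permutation test: each iteration permutes y and
reruns the *complete* LOOCV; p = (1 + #{r_null ≥ r_obs}) / (1 + n_perm),
the add-one estimator, which cannot return 0 and is exactly uniform under
the null.  At λ = 0.08 with tens of subjects the effective penalty
α = λ/(4n) is tiny, so the fits are near-interpolating; cross-validated r
consequently has high sampling variability between cohort realisations —
visible in the synthetic recovery experiments, where r varies by ±0.2
across generator seeds at a fixed effect size.

**Aggregation.**  Per-fold coefficients are recorded in the standardised
frame (the frame in which the penalty acts and weights are comparable
across features).  The fold-mean weight counts a feature unselected in a
fold as 0, preserving selection frequency.  The macro-region matrix is the
*signed* mean of weights over all node pairs connecting two regions, so
positively and negatively predictive connection classes remain
distinguishable by sign; region pairs with no features are 0 with a zero
count in the companion matrix.  Node prediction efficacy sums absolute
incident mean weights and divides by the maximum (raw scores are
non-negative, so the floor is anchored at 0); a node with no selected
incident connection scores exactly 0 and the best node scores 1.

The packaged lookup maps the 246 Brainnetome parcels (210 cortical, 36
subcortical, 123 per hemisphere) onto the atlas's 24 gyral/subcortical
macro-regions; any table with the same four-column schema can be
substituted.

## Synthetic cohorts

Two generation modes decouple testing of the prediction stage from the
graph stage.

*Direct mode* samples dnE entries in Fisher-z space, z = μ + b·s̃ + ε for
planted pairs (ε ~ N(0, σ²), s̃ the standardised subject score) and maps
them through tanh, so entries respect (−1, 1) by construction and the
planted relation stays linear in z — the population correlation between
the z-transformed entry and s̃ is b/√(b²+σ²), giving closed-form oracle
values for tests.

*Time-series mode* synthesises the relation dynamically: per planted pair,
two low-pass-filtered unit-variance latent modulators m₁, m₂ (default
cutoff 0.005 Hz — connectivity states lasting a few minutes, slower than
the 100 s analysis window, as sliding-window estimation requires); node p's
coupling amplitude to a shared community signal follows 1 + 1.5·m₁
(floored at 0.05) and node q's follows the same transform of
α·m₁ + √(1−α²)·m₂ with α = (1 + tanh(b·s̃))/2, so the synchrony of the two
nodes' efficiency fluctuations — and hence their dnE entry — increases
with the subject's score.  Ordinary nodes mix the community signal with
unique noise at static weights drawn once per subject.  Scores are drawn
uniformly over the configured range for the medication-off column;
medication-on is half of it, emulating the typical post-levodopa
improvement, so both targets carry the same standardised plant.

One cohort seed is expanded into independent substreams —
`default_rng([seed, 0])` for scores, `default_rng([seed, 1, i])` for
subject i — so any subject is reproducible in isolation and cohorts are
bit-for-bit deterministic.

What the generator does **not** emulate: hemodynamic response shape,
scanner drift and physiological noise spectra, spatial autocorrelation
between parcels, realistic motion, or between-subject anatomical
variability.  Passing recovery tests therefore shows the *pipeline*
correctly extracts a planted dynamic-connectivity signal of realistic
magnitude at realistic scan length and cohort size; it does not certify
effect sizes or significance levels attainable on real patient data.

## Problem sizes used by the test suite

Unit tests run at toy scale.  The end-to-end checks use: a full
62-subject × 246-node × 240-point cohort for structural fidelity (one
prediction target, permutations disabled there; the dnE stage dominates at
roughly three minutes on one CPU); a 60-subject × 40-node × 236-point
cohort with three planted pairs for parameter recovery (200 permutations);
and fifty 16-subject direct-mode null cohorts at 79 permutations each for
calibration of the permutation p-value.  The shortest-path implementation
is validated against a hand-written pure-Python Floyd–Warshall oracle on
200 random graphs of up to 12 nodes.

## Known limitations

- The analysis consumes extracted ROI time series only; no NIfTI/imaging
  front-end is provided.
- Scrubbing/censoring of individual high-motion frames is not implemented
  (whole-subject exclusion only).
- Tapered or adaptive windows, other dynamic graph metrics (local
  efficiency, modularity) and alternative learners (ridge, elastic net)
  are out of scope.
- λ is fixed (0.08) by default, mirroring the analysis design; no nested
  selection loop runs unless a user performs one explicitly.
- Pearson r on LOOCV predictions is a noisy criterion near the
  interpolation regime (see above); MAE and the permutation p provide the
  more stable summaries.
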