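# Methods

## The model

`dcpm` implements dynamic connectome-based predictive modeling: trial-level
prediction of behavior from instantaneous phase-synchrony connectomes.

**Dynamic connectivity.** Each node's BOLD-like signal is band-pass
filtered to 0.008–0.12 Hz with a zero-phase Butterworth filter (order 2 per
pass, applied forward–backward, so phase estimates are not lagged by the
filter). The instantaneous phase φᵢ(t) of node *i* is the angle of the
analytic signal (Hilbert transform), which is interpretable because the
input is narrowband. Phase synchrony of edge (i, j) at sample *t* is

    sᵢⱼ(t) = cos(φᵢ(t) − φⱼ(t)) ∈ [−1, 1],

1 in phase, −1 in antiphase, giving single-TR temporal resolution. Edges
are indexed in a fixed canonical order — pairs (i, j) with i < j, row-major
over the upper triangle — shared by every module and checksummed whenever
two saved artifacts are combined. For the reference 377-node parcellation
(a 368-node functional atlas plus nine stress-system nodes) the edge
universe has C(377, 2) = 70,876 edges.

**Trial connectomes.** For a trial with onset *o* (samples), the trial
connectome is the mean of each edge's synchrony over the half-open window
[o + shift, o + shift + window), defaults shift = 5 s and window = 10 s:
the forward shift stands in for the hemodynamic delay between the event and
the BOLD response. Seconds are converted to whole samples by rounding
toward zero (at the 1-s TR of the reference design the two coincide).
Trials whose shifted window would run past the end of the run are dropped,
not truncated, so the window length is homogeneous; trials with missing
behavior for the analyzed construct are excluded. The first and last
⌈1/f_low⌉ seconds of each run are flagged as low-confidence (Hilbert edge
effects); trials overlapping them are retained but logged.

**Leave-one-trial-out CPM.** Trials pool all subjects in a session/run
condition. Per fold (one held-out trial):

1. every edge's trial-averaged synchrony is Pearson-correlated with the
   behavior vector over the training trials (for the binary memory outcome
   this is the point-biserial correlation); edges with two-sided P < α
   (default 0.01) form the positive (r > 0) and negative (r < 0)
   subnetworks; constant edge columns are excluded and counted;
2. two scalar features per trial — the sum of synchrony over each
   subnetwork — enter a logistic (memory) or ordinary linear (arousal)
   regression with intercept; a config switch collapses them to the single
   difference (positive − negative) instead;
3. the held-out trial is predicted; memory predictions are thresholded at
   probability 0.5.

Performance is accuracy (memory) or Pearson r between predicted and
observed values (arousal) over all held-out predictions. Folds in which
neither subnetwork selects any edge produce no prediction; they are
excluded from the statistic and reported as reduced coverage.

**Permutation testing.** Behavior is shuffled uniformly across all retained
trials (a subject-blocked shuffle is available behind a flag) and the whole
cross-validated procedure is rerun; default 1000 iterations. The p-value
uses the add-one convention p = (1 + #{null ≥ observed}) / (1 + n_perm),
which can never be exactly 0. A permutation iteration whose performance is
undefined (no predictable folds, constant predictions) is ranked below
every defined value — the same rule is applied to the observed statistic,
preserving exchangeability and hence the uniformity of p under the null.
Degenerate-but-defined values (e.g. a correlation over very few
predictions) are kept as-is, again symmetrically.

**Consensus networks.** The predictive network of a model is the set of
edges selected on *every* leave-one-trial-out fold, kept separately per
signed subnetwork (an edge that switches sign across folds belongs to
neither consensus). Note that adjacent folds share all but one trial, so
the consensus removes few α-level chance selections: the expected consensus
precision against a planted network of k edges per sign is approximately
k / (k + α/2 · E) where E is the edge-universe size. This bound drives the
design of the recovery preset below.

**Network anatomy.** Given a partition of nodes into functional networks
(10 in the reference atlas; the node→network table is a required user
input), composition is the percentage of each functional-network pair's
possible edges (|A|·|B| across pairs, C(|A|, 2) within — self-pairs never
count) present in a predictive subnetwork. Enrichment significance is the
upper-tail hypergeometric probability P(X ≥ x) of drawing x cell edges when
the subnetwork's edges are drawn from the full universe. Overlap between
two networks reports x = |A ∩ B|, the percentage x / min(|A|, |B|) × 100,
and the upper-tail hypergeometric probability with population M (default
C(n_nodes, 2)). The upper tail is used because the question is whether the
overlap is *larger* than chance; a pointwise P(X = x) variant is available.
Overlap degrees are compared with a 2×2 chi-square test on
[[k₁, n₁−k₁], [k₂, n₂−k₂]], without continuity correction by default.

**Engagement and cofluctuation.** Network engagement at each sample is the
mean synchrony over the positive subnetwork minus the mean over the
negative subnetwork (means, not sums, so subnetworks of different sizes are
comparable; engagement then lies in [−2, 2]; a sum option exists).
Internetwork cofluctuation is the Pearson correlation over all run samples
between two networks' engagement series; edges present in both networks are
removed from both first, and the API refuses to correlate series that have
not been through shared-edge removal. Engagement is not z-scored before
correlating (Pearson r is scale-invariant). Per subject/run summaries are
exported as tidy tables for external mixed-effects modeling, which is out
of scope here.

**Generalization.** To test whether a network selected for one construct or
run predicts another: per held-out target trial, edges are selected from
the source data (with one source trial held out, paired to the target fold
by index; selection-on-all-source-trials is available as `pairing="all"`),
subnetwork-sum features are computed on the target run, a fresh model is
fit on the target training trials, and the held-out target trial is
predicted. With identical source and target this reduces exactly to the
ordinary cross-validation, which is asserted in the tests. Permutations
shuffle the target behavior only; the source selection is treated as a
fixed property of the source run.

## The synthetic-data generator

The generator emulates the reference study design — up to 26 subjects × 2
sessions × 2 runs × 40 trials at 1-s sampling with 377 nodes — and plants
known ground truth so every downstream stage has a recoverable answer.

* **Signals.** Node time series are white Gaussian noise filtered to the
  analysis band and rescaled to unit variance per node, times `noise_sd`.
* **Behavior.** One latent Gaussian per trial: the arousal rating is the
  latent discretized at the standard-normal quartiles into 1–4; the memory
  outcome is Bernoulli with log-odds `memory_slope`·latent. The slope tunes
  the correlation between constructs (≈ 0.7 at slope 3, 0 at slope 0),
  which cross-construct generalization tests need. A configurable fraction
  of behavior entries can be nulled out to exercise the missing-behavior
  exclusion rule.
* **Planted coupling.** During each trial's stimulus window a shared
  band-limited unit-variance component is added to both endpoints of every
  planted edge, with amplitude `coupling_strength`·b for positive edges and
  `coupling_strength`·(1−b) for negative edges, where b is the driving
  construct's value normalized to [0, 1]. Trial-averaged synchrony at
  planted edges therefore correlates with behavior, and nowhere else in
  expectation. Secondary planted sets driven by the *other* construct
  support two-network scenarios.
* **Timing.** Trials are laid out regularly (default 16-sample stimulus
  window, 4-sample gap, 20-sample padding at both run ends) so the
  default 5-s shift + 10-s window of the analysis falls inside the injected
  interval. The within-trial coupling profile is a boxcar — a modeling
  convenience, not a claim about real data.

What the generator does **not** emulate: hemodynamics (no HRF or balloon
model — coupling is injected directly into the band-limited signal), head
motion and physiological artifacts, spatial autocorrelation between nodes,
subject-level heterogeneity of coupling, or temporal autocorrelation beyond
the band limit. Passing recovery tests therefore demonstrate the estimator
chain is correct and calibrated on its own assumptions, not that real fMRI
effects of this size are detectable.

A subtlety worth recording: injected components perturb the phases of the
nodes they touch, so two planted networks that are edge-disjoint but share
nodes become statistically coupled even when their driving behaviors are
independent (extra injected variance at a node dilutes the phase alignment
of *all* its edges). The "independent constructs" generalization preset
therefore uses node-disjoint networks.

## Presets and problem sizes

* `design_preset_paper` — the reference design (26 × 2 × 2 × 40, 377
  nodes); used for design-count and combinatorics checks.
* `design_preset_desk` — 10 subjects, 100 nodes, 20 trials/run, 2 × 2
  conditions; the fast default for pipeline runs and null-rate checks.
* `preset_null_small` — 6 subjects, 40 nodes, 15 trials, single run, zero
  coupling; sized so a 150–200-iteration permutation test takes seconds,
  allowing ~50 repeated simulations in a calibration study.
* `preset_strong_coupling` — 14 subjects × 40 trials, 50 nodes (1225
  edges), 30 planted edges per sign, coupling 2.0: chosen, per the
  consensus-precision bound above (30 / (30 + 0.005·1225) ≈ 0.83), so that
  ≥ 0.8 precision and recall are statistically attainable; pilot runs
  across several seeds sat at precision 0.85–0.91 and recall 0.90–1.00
  for the positive consensus network before the preset was frozen.
* `preset_generalization(shared=…)` — 10 subjects × 30 trials, 40 nodes;
  either one arousal-driven network with correlated memory (ρ ≈ 0.7) or
  node-disjoint arousal- and memory-driven networks with independent
  behaviors.

## Numerical choices

* Leave-one-out correlation screens are computed for all folds at once by
  rank-one downdates of full-data cross products; per-fold regressions are
  batched (normal equations for linear, Newton/IRLS for logistic). A naive
  per-fold reference implementation lives in the test suite and must agree
  to 1e-6 on predictions.
* The logistic fit always carries a tiny ridge term (1e-6) so perfectly
  separated folds stay finite and deterministic; the linear fit carries a
  1e-10 relative ridge purely against rank deficiency (an empty subnetwork
  contributes a zero column whose coefficient is then 0).
* Correlation p-values use the exact t transform with df = n − 2;
  (near-)zero-variance columns are excluded (r = 0, p = 1) with a 1e-9
  relative variance tolerance.
* Fewer than 3 trials, or fewer than 3 surviving predictions, mark a result
  degenerate; its performance may be NaN and is never silently compared.
* `shift`/`window` truncate toward zero when converted to samples; the
  averaging window is half-open on the right. Both are conventions the
  source description leaves open; they are flagged here rather than claimed.

## Known limitations

* Phase synchrony assumes narrowband signals; feeding unfiltered data to
  `instantaneous_phase` silently degrades the phase interpretation (the
  pipeline always filters first).
* The consensus definition is strict per signed subnetwork; sign-unstable
  edges vanish from both consensus sets.
* Permutation tests treat trials as exchangeable across subjects by
  default, mirroring an unblocked shuffle; when within-subject structure
  matters, pass `subjects=` for a blocked null.
* The engagement/cofluctuation module exports summaries; it does not fit
  the mixed-effects models a full group analysis would require.
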