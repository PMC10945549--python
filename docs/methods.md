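# Methods

## The modeling problem

A kinase-inhibitor screen measures, for each of n drugs, the level of m
secreted factors (cytokines, chemokines, growth factors) released by
LPS-stimulated macrophages, expressed relative to the LPS-only control.
Each drug also has a known polypharmacology fingerprint: the residual
activity it leaves in each of p kinases (percent of uninhibited control,
0–100, measured at a single dose). Because every drug perturbs many
kinases at once, no single drug identifies a responsible kinase; the
deconvolution is statistical. `kirscreen` implements the KiR
(kinase-inhibitor regression) approach: regress each factor's response
across drugs on the drugs' kinase-inhibition fingerprints,

y_i = β₀ + Σ_j x_ij β_j + ε_i,

with an elastic-net penalty λ·[α‖β‖₁ + (1−α)/2·‖β‖₂²], since p (tens to
hundreds of kinases) far exceeds n (tens of drugs).

## Fitting protocol

* **α sweep.** Models are computed for 11 evenly spaced values of the
  L1/L2 mixing parameter α from 0 to 1 inclusive.
* **Penalty selection.** For each α, λ is chosen by leave-one-out
  cross-validation with drugs as folds, in order and unshuffled: the path
  is refit on n−1 drugs and the held-out drug predicted, for every λ in a
  grid of 100 log-spaced values from λ_max down to 10⁻³·λ_max (λ_max is the
  smallest fully sparsifying penalty on standardized predictors; α is
  floored at 0.05 inside the λ_max formula so the grid stays finite near
  ridge). The λ with the lowest LOOCV MSE wins; exact ties go to the larger
  λ (the sparser model).
* **Standardization.** Predictors are internally standardized to zero mean
  and unit population variance per training set; coefficients are reported
  back on the original residual-activity scale. Constant predictor columns
  are dropped with a logged warning and report coefficient zero.
* **Quality gate.** A model is *accepted* iff its LOOCV predictions (from
  the best-α solution, i.e. lowest LOOCV MSE over the full grid including
  α = 0) satisfy nRMSE < 0.1 **and** Pearson r > 0.85 against the measured
  responses. nRMSE normalizes the RMSE by the observed response range
  (normalization by the mean is available as an option). LOOCV predictions,
  not in-sample fits, are used deliberately: the in-sample reading of the
  gate is nearly always optimistic at n ≪ p.
* **Hit calling.** A kinase is *informative* for a factor when its
  coefficient exceeds 1e−8 in the selected solution of at least one α > 0.
  The α = 0 (pure ridge) member is always dense and never contributes.
  Positive coefficients are the biologically interpretable direction here:
  the response is secretion relative to control and predictors are residual
  activities, so β_j > 0 means inhibiting kinase j lowers secretion.
* **Aggregation gate.** Only accepted models contribute hits to the
  kinase×cytokine matrix, the pipeline's informative-kinase count and the
  benchmark statistics (`accepted_only=False` overrides). A rejected
  model's coefficients are not evidence; without this gate a no-signal
  screen still emits ~2–3 spurious kinases per factor, with it essentially
  none.
* **Prediction.** Out-of-panel responses for unscreened inhibitors use each
  accepted factor's best-α solution: ŷ = β₀ + x·β. A pseudo-drug with
  residual activity 100 everywhere predicts the model's fitted control
  level. Predicting from rejected models requires an explicit override, and
  a panel lacking a kinase that carries a nonzero coefficient is an error
  naming the kinase.

## Solver

The elastic-net path is solved by cyclic coordinate descent with
soft-thresholding on standardized predictors, warm-started along the
decreasing λ grid, with glmnet-style active-set iteration between full
passes (`_solver.py`, numba-compiled). Convergence is declared when a full
pass moves no standardized coefficient by more than `tol`. Two tolerances
are used: LOOCV path scans run at 1e−5 (coefficient error ~1e−3, far below
the MSE resolution the λ choice needs), and every reported full-data
solution is then polished at 1e−8 from the scan solution. Soft-thresholding
produces exact zeros, so sparsity patterns do not depend on the tolerance.
Pure ridge (α = 0) is solved in closed form through the SVD. In the test
suite the solver is cross-checked against scikit-learn's `enet_path`, the
analytic ridge normal equations, per-λ cold-start refits (for the LOOCV
path), and R glmnet was used during development as an external reference.

Numerical edge cases: responses with zero variance are skipped with a
logged reason, not fitted; constant predictors are dropped; a constant
response or constant LOOCV predictions make the quality score undefined and
the model is rejected with an explicit flag.

## Synthetic screens

The generator produces every surface a real study has, with a planted
sparse truth so recovery is measurable:

* **Ground truth.** Each cytokine gets exactly `k_planted` promoter kinases
  with effects drawn Uniform(0.05, 0.3) on the fraction-of-control scale;
  all other effects are exactly zero. The baseline is β₀ = 1 − Σβ so an
  uninhibited (LPS-only) pseudo-drug sits at level 1.0 exactly; when drawn
  effects sum above 0.95 they are rescaled to 0.95 to keep β₀ ≥ 0.05.
* **Drug–target matrix.** Each drug strongly inhibits a Bernoulli
  (`selectivity`, default 0.1) subset of kinases, residual ~ Uniform[0, 50);
  all other entries are Normal(100, 2) truncated to [0, 100], emulating
  assay jitter. The *screen* matrix additionally guarantees every kinase at
  least two strongly inhibiting drugs, emulating a computationally chosen
  inhibitor panel: a kinase the screen never perturbs is unidentifiable to
  the regression and, worse, a silent extrapolation hazard when the larger
  unscreened panel does perturb it. The prediction panel has no coverage
  guarantee.
* **Responses.** y = β₀ + (X/100)·β + Normal(0, `noise_sd`), clipped at 0;
  default noise_sd 0.02 on the fraction-of-control scale. Defaults follow
  the screen design the package targets: 34 screen drugs, 100 panel drugs,
  50 kinases, 10 cytokines, 5 planted kinases each.
* **Secretome replicates.** A long-format control-vs-LPS table (default 191
  factors, 3 replicates) in which a chosen subset truly shifts (half up,
  half down by `fold_change`); readouts are log-normal around the condition
  mean with coefficient of variation `cv` (default 0.15), baselines
  log-uniform over two decades.

What the generator does **not** emulate: dose–response kinetics, time
courses, bead-level assay error structure, correlated kinase inhibition
profiles within chemical scaffolds, or cross-factor correlation of
secretion. Passing recovery tests therefore shows the inference machinery
is sound under an honest linear-with-noise world, not that real screens
meet those assumptions.

## Differential secretion

Per factor, a two-sided Welch (unequal-variance) t-test compares
log(value + 1) between two conditions (the +1 offset tolerates zero
readouts and is configurable); log2 fold change is reported from the
condition means. p-values are Benjamini–Hochberg adjusted across tested
factors and a factor is significant at q < fdr (default 0.05). Factors with
fewer than two replicates in either condition are excluded with a reason.
The test choice is this package's own; the screen literature typically
states significance without naming one.

## Networks

The cytokine-centric subnetwork is the union of all minimum-total-weight
paths of at most `max_hops` (default 2) edges from each informative kinase
to the cytokine's gene on a user-supplied reference graph (e.g.
KEGG-derived), where higher edge weight means a less likely interaction
(confidence-scored inputs can be inverted on load). All tied minimum-weight
paths are kept, making the result deterministic. The hop-bounded search is
a layered Bellman–Ford sweep with full tie backtracking; under positive
weights a walk revisiting a node can never match the optimal simple path,
so the sweep is exact. Weight-threshold pruning keeps edges with weight ≤ t
and then drops nodes disconnected from the anchor; it is idempotent and
monotone in t. This is a deliberately simple, fully testable variant of
kinase-centric network construction; propagation-based scoring schemes are
out of scope.

## Ranking surfaces

Efficacy of drug d on factor c is 100·(1 − level(d,c)) with levels on the
fraction-of-control scale (negative predicted levels are clipped to 0
first, so efficacy caps at 100; potentiated factors give negative
efficacy). A drug *affects* a factor at efficacy ≥ 50% by default — a
display convention, configurable and recorded in output metadata. Drugs are
ranked by mean efficacy over the selected cytokines, ties broken by the
number of selected factors affected, then by drug id; input row order never
matters. Drug *selectivity* is the fraction of profiled kinases inhibited
below 50% residual activity. Drug *specificity* is reported as one minus
the normalized Shannon entropy of the nonnegative efficacy profile — a
declared stand-in, since no operational definition is established for these
summary tables.

## Known limitations and characterization

* **The sign-based hit rule is liberal.** On the default planted benchmark
  (34 drugs, 50 kinases, 5 planted per cytokine, noise 0.02, 25 seeds) the
  positive-coefficient rule recovers planted kinases at mean recall ≈ 0.94
  but mean precision ≈ 0.4: LOOCV MSE curves are nearly flat at this
  signal-to-noise, the selected λ sits near the bottom of the grid, and the
  selected models carry many small spurious positives. This is a property
  of the protocol, not of this implementation — R glmnet's `cv.glmnet`
  under the same folds and grid selects equally dense or denser models
  (union hit sets of 18–21 kinases per factor on the same data). True and
  false positives separate sharply by coefficient magnitude (medians ≈
  0.15 vs ≈ 0.01 per fully inhibited kinase), so magnitude-aware
  post-filtering would raise precision substantially, but the sign rule is
  kept as the field defines it.
* Single-dose linearity is assumed throughout; no interaction terms, no
  dose–response extrapolation.
* The benchmark problem sizes (25 seeds × 10 cytokines for recovery and
  null calibration, one 100-drug panel for held-out prediction, 20 random
  problems/graphs for the oracles) are the package's standard desk-scale
  battery, chosen to characterize each property with comfortable Monte
  Carlo margins.
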