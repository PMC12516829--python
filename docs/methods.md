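# Methods

`intrisol` implements a three-stage workflow for the intrinsic aqueous
solubility of drug-like, ionizable compounds: (1) derive intrinsic
solubility S0 from pH-dependent assay measurements and predicted pKa's,
(2) learn S0 together with seven related physicochemical properties with a
multi-task graph transformer, (3) reconstruct full pH 0–12 solubility
profiles from predicted S0 and pKa's.  This note records the models, the
assumptions, and the design choices made where the design was genuinely
open.

## Speciation model

For a compound with relevant acidic pKa's `a1 ≤ a2 ≤ …` and basic pKa's
`b1 ≥ b2 ≥ …`, total solubility factorizes as `S(pH) = S0 · Φ(pH)` with the
cumulative ionization expansion

    Φ(pH) = 1 + Σ_k 10^(k·pH − Σ_{j≤k} a_j) + Σ_k 10^(Σ_{j≤k} b_j − k·pH)

This reproduces the standard monoprotic/diprotic/triprotic acid and base
equations and the ordinary-ampholyte case.  Microspecies that are acid- and
base-ionized simultaneously (zwitterionic cross-terms) are not modelled;
compounds whose smallest acidic pKa is within 2 pH units of their largest
basic pKa are treated as zwitterions and removed during curation.  Φ is
evaluated in log space (log-sum-exp anchored at the largest exponent) so
that |pH − pKa| gaps of 20 or more cannot overflow; the naive summation
exists only as a test oracle.

**Relevant-pKa rule.** A pKa enters Φ only if its group's ionized fraction
at the working pH — `1/(1+10^(pKa−pH))` for acids, `1/(1+10^(pH−pKa))` for
bases — reaches a threshold, default 0.01 (boundary inclusive).  At most 3
pKa's are kept (the largest fractions win); when more than 3 are relevant
the operation is refused and callers decide: curation discards the
compound, the profiler marks the pH point undetermined.  The threshold form
was chosen because the error a mis-predicted pKa induces in S0 grows with
the extent of ionization; the fraction is the natural measure of that
exposure.  One consequence worth knowing: a group whose fraction is just
below threshold (e.g. an acid with pKa 4 evaluated at pH 2, fraction
0.0098) contributes exactly nothing, so derived values can differ from the
unfiltered closed form by up to ~`log10(1+threshold)` ≈ 0.004 log units.

**Convention.** The relevant-subset rule is applied *everywhere* solubility
is computed from pKa's — in the synthetic-data generator's forward
simulation, in curation's inversion, and in the profiler.  Using one
convention on both sides of the round trip makes noise-free pipeline
recovery exact to machine precision rather than exact up to the threshold.

## Curation rules

Inputs are assay records (log10 molar solubility at pH 2 and pH 7, with a
solid-state readout of the residual solid and censoring flags at the
0.1–600 µM dynamic range) plus per-compound pKa lists.  In order:

1. Only crystalline, uncensored records of non-salt compounds survive.
   Censored records are dropped entirely, not used as bounds.
2. Derivation condition per ionization class: acid-only → pH 2 (least
   ionized), base-only → pH 7, both types with gap > 2 → the available pH
   closest to the midpoint of min(acidic) and max(basic) pKa (ties go to
   the lower pH), gap ≤ 2 → discard (zwitterion), no pKa → the measurement
   is S0 directly.
3. The speciation map is inverted at the chosen pH with the relevant
   subset.  Replicate-derived values are merged only when their spread is
   < 0.7 log units, keeping the *smaller* solubility (assumed to reflect
   the more stable polymorph); otherwise the compound is dropped.  No-pKa
   compounds with records at both pH values are resolved by the same rule.
4. The high-quality flag marks compounds whose derivation records are
   crystalline, uncensored, and have replicate spread ≤ 0.5 log units (all
   thresholds configurable).  This subset drives stratified splitting and
   is the only population on which test-set S0 metrics are reported.

The eight-task table (S0; solubility at pH 2, pH 7, FaSSIF; logP; logD at
pH 2.6/7.4/10.5) is the outer union over per-task compound sets with an
observation mask; missing entries are never imputed.

Salt handling is an input flag only — no desalting chemistry is attempted.

## Molecular graphs

Heavy-atom graphs from SMILES via RDKit.  Node features: element one-hot
(C/N/O/S/F/Cl/Br/I/P + other), degree one-hot, formal charge, total H
count one-hot, hybridization one-hot, aromaticity, ring membership.  Edge
features: bond-order one-hot (single/double/triple/aromatic), conjugation,
ring membership, stereo flag.  Both lists are configurable so an alternate
feature vocabulary can be swapped in.  Two structural descriptors feed the
model: all-pairs BFS hop distances (∞ between disconnected fragments) and a
random-walk structural encoding — for each node the probability that a
uniform random walk returns in exactly k steps, k = 1..20, i.e. the
diagonal of powers of the degree-normalized transition matrix.

## Model

The architecture follows the hybrid local/global graph-transformer design:
each block runs, in parallel over the batch graph,

* an edge-conditioned GINE-style message-passing branch over bonds, and
* multi-head global self-attention whose post-softmax row weights are
  multiplied elementwise by the decay mask `γ^d(i,j)` (hop distance `d`, 0
  across fragments) and renormalized to sum to one,

summed onto the residual stream and followed by a feed-forward stage.
Blocks are pre-norm (LayerNorm feeds each branch; outputs add to the raw
residual): in our experiments post-norm blocks needed several-fold more
optimization steps to converge at the same learning rate.  Mask placement
is post-softmax with renormalization so rows stay convex combinations and
the two limits are exact: γ = 1 recovers unmasked attention, γ = 0 reduces
to self-only attention.  γ is fixed (default 0.6), not learned.  Mean
pooling over each molecule's nodes feeds eight independent linear heads.

Targets are standardized per task on the training observations; the scaler
is stored with the model and inverted at prediction time.

**Loss.** Homoscedastic-uncertainty weighting with learnable per-task
log-variances `s_t`:  `L = Σ_t exp(−s_t)·MSE_t + r(s_t)` over tasks with at
least one observed entry in the batch; masked entries contribute exactly
zero gradient.  The regularizer is `r(s) = s/2` by default, with a
softplus option `r(s) = log(1+e^s)` that keeps the weight penalty positive
and is less sensitive to initialization.

**Optimization.** Adam at base learning rate 0.005 with 5 warmup epochs and
cosine decay to zero at `max_epochs` (the schedule used by the graph
transformer recipes this model follows; constant lr is available).  Up to
200 epochs with early stopping after 30 epochs without validation
improvement; the best-validation weights are restored.  Defaults: 2 blocks,
hidden width 96, 4 heads, batch 16 — sized so that desk-scale CPU training
converges; all configurable.  The whole network runs on an internal NumPy
reverse-mode autodiff (float64), which makes runs bit-reproducible for a
fixed seed on one thread configuration; gradient correctness is asserted
against finite differences in the test suite.

## Evaluation protocol

70/15/15 train/validation/test split, stratified on high-quality
membership; within each stratum the validation and test counts are rounded
and the remainder goes to train, so every partition contains high-quality
compounds and test-set S0 metrics can be restricted to them.  Strata with
fewer than 3 members go entirely to train.  Metrics are RMSE and
R² = 1 − SS_res/SS_tot.  Stability is reported as mean (sample SD, n−1) of
the metrics over five trials with different split seeds.

## pH-solubility profiles

`log S(pH) = log S0 + log Φ(pH)` over a pH 0–12 grid (default step 0.1).
Grid points where more than 3 pKa's are relevant are marked undetermined
and serialized as empty fields rather than sentinel numbers.  Because the
map is linear in log S0 at fixed pKa's, two profiles of the same compound
differ by a constant equal to their S0 difference — an S0 prediction error
shifts the curve rigidly.  The cohort evaluation therefore reduces to S0
error statistics: RMSE, the 75th-percentile absolute error, and the
fraction of compounds below it.  No salt/solubility-product plateaus or
common-ion effects are modelled, so profiles keep rising beyond the range
where real formulations would plateau.

## Synthetic data generator

The generator emulates the statistical structure of a high-throughput
pH 2 / pH 7 screen so every stage is testable without proprietary data:

* **Compounds.** A class mix (defaults: 20% neutral, 30% acid, 30% base,
  10% ordinary ampholyte, 10% zwitterion) over hand-vetted drug-like
  scaffolds decorated with random acyclic fragments; every SMILES is
  RDKit-validated and unique within the cohort.  pKa's are drawn per class
  from U[2, 11] (1–2 per type, so up to 4 total), with the ampholyte gap
  constraint enforced by rejection.  pKa lists are *not* derived from the
  structures — pKa prediction is an input to the real pipeline, and the
  generator mirrors that, which is a documented limitation: passing tests
  show the pipeline arithmetic and learning machinery work, not that
  structure→pKa chemistry is captured.
* **True S0.** Mean −5, SD 1.2 log10 molar; half the variance
  (`structure_rho = 0.5`) tracks standardized heavy-atom count (larger →
  less soluble) so that learning has a recoverable structural signal, the
  rest is independent noise.
* **Measurements.** `S(pH)` from the speciation model plus N(0, σ) noise
  (default σ = 0.3 log units, between reported inter-laboratory and
  shake-flask variabilities), censored and clipped at the 0.1–600 µM
  window; replicates at a 10% duplicate rate carry their spread; amorphous
  residual-solid labels at 15%; salt forms at 5%.
* **Auxiliary tasks.** Solubility tasks follow the speciation curve (FaSSIF
  with a +0.8 solubilizing shift); logP/logD are noisy linear functions of
  S0 and molecular size — enough cross-task correlation to exercise
  multi-task learning with no claim of partitioning physics.  Per-task
  sparsity uses exact counts (`round(p·n)` observed compounds).

What the generator does *not* emulate: assay-protocol shifts between
laboratories, structure-consistent ionization chemistry, polymorphism
beyond the min-rule, and the chemical-space breadth of a real screening
library.  Results on synthetic data therefore validate correctness and
protocol, not real-data accuracy.

## Numerical choices and problem sizes

Float64 throughout.  Speciation tolerances: round-trip identity holds to
1e-10; profile constant-offset to 1e-12.  Ties in the midpoint rule go to
the lower pH.  Degenerate inputs: empty graphs are rejected; single-node
graphs run (the message-passing branch reduces to its self path); an
all-unobserved batch contributes zero loss with a warning.  Test and
acceptance runs use deliberately small cohorts — 50 compounds for the
memorization check, 150 for the five-trial protocol, 500 for curation
recovery, 810 for the profile cohort — sizes chosen so the full suite runs
comfortably on a single CPU while keeping every statistical check
well-powered for its tolerance.
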