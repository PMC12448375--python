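# Methods

## Feature extraction

A spectrum's feature vector holds the relative intensities of the ten core
Y-ions Y1..Y5 and Y1F..Y5F, computed from the PSM's peptide mass (an
explicit `peptide_mass` column wins over the sequence-derived mass; the
sequence path applies monoisotopic residue masses, water, and
carbamidomethyl-Cys as the default fixed modification). Glycan residue
constants are HexNAc 203.07937, Hex 162.05282, Fuc 146.05791 Da, proton
1.0072765 Da — standard monoisotopic values, injectable for other
conventions.

Matching and normalization choices, with rationale:

* **Tolerance**: |obs − theo|/theo ≤ 20 ppm (theoretical m/z in the
  denominator).
* **Charge states**: {1+, 2+} by default; per (ion, charge) the most intense
  peak in the window is taken (robust to centroiding jitter, unlike
  nearest-m/z), and an ion's raw intensity is the sum over charge states.
  Y-ions of intact glycopeptides commonly appear at both charges; the set is
  configurable.
* **Relative intensity**: raw intensity / base-peak intensity, clipped to
  [0, 1] (TIC denominator available). Typical log10 values of −0.8 to −1.9
  in the cohort statistics are consistent with base-peak scaling.
* **Missing ions** are zero-filled (mask false) *before* normalization;
  spectra with fewer than 3 of 10 matched ions are dropped (configurable).
* **Normalization**: Max (X∞ = x/max) or Sum (X = x/Σx). Sum is the package
  default and the pairing under which the autoencoder threshold parameter
  k = 0.4 is used.

## Trustworthy labeling

* FUT8-knockout provenance ⇒ nCF, regardless of composition: without the
  α1,6-fucosyltransferase no core fucose can be synthesized.
* Core-fucosylated high-mannose ⇒ CF: composition HexNAc2 Fuc1 Hex≥3 with no
  sialic acids *and* an explicit upstream structure call placing the fucose
  on the core. A pure-mannose glycan has no antennary fucose to migrate, so
  the observed core fucose cannot be an FM artifact. The structure call is
  consumed as a boolean/structure column from an upstream structure engine;
  this package does not re-derive glycan structures, and upstream FDR
  filtering is assumed done (an optional `id_fdr` cutoff is supported).
* Everything else is UNLABELED and only usable as untagged training data.

The Y1F/Y1 > 0.1 threshold baseline is included for comparison; it returns
UNDETERMINED when Y1 is unmatched, and its decision is invariant to the
normalization choice (it is a ratio of two components of x).

## Mapping-convergence model

Ψ1 (mapping) is a ν-one-class SVM with RBF kernel, ν = 0.05; Ψ2
(convergence) a soft-margin RBF SVM with C = 1. Both use the bandwidth
heuristic γ = 1/(10 · mean per-feature variance of P ∪ U). No
hyperparameters are prescribed for the original experiment, so mild
standard settings are used and everything is configurable. The convergence
loop moves predicted negatives of the current positive remainder into N
until an iteration finds none (guaranteed within |U| iterations; a
max_iter = 100 safety cap covers numerical edge cases). No class
rebalancing is applied during iterations — the accumulated N can grow much
larger than the remainder, matching the plain procedure; a balanced-weights
option exists but is off by default. Decision convention: positive decision
value ⇒ nCF (the tagged class).

## Autoencoder model

Fixed architecture 10-9-8-7-8-9-10, tanh on every layer including the
output (inputs lie in [0, 1], inside tanh's range, so no input rescaling).
Implemented directly in numpy (forward pass, backprop, Adam) — the network
is tiny and fully seeded. Training minimizes MSE with Adam at learning rate
1e−3, batch 256, up to 500 epochs with early stopping on a loss plateau
(patience 20); Xavier-uniform initialization. Divergence (NaN loss) raises
with the config echoed.

μ and σ for the threshold α = μ + kσ are computed over the *training*
(tagged nCF) vectors' final reconstruction errors. The decision rule is a
strict inequality: error > α ⇒ CF; error = α stays nCF. `AEModel.with_k`
rethresholds a trained network without retraining, which makes the flagged
fraction exactly monotone non-increasing in k.

Known structural property: for error distributions that are roughly
unimodal without a heavy right tail, μ + 0.4σ sits near the 70th–80th
percentile, so at k = 0.4 roughly a quarter of data distributed like the
training set is flagged. High nCF specificity at k = 0.4 therefore requires
an outlier-dominated error distribution (a bulk of near-perfect
reconstructions plus a small large-error subpopulation inflating σ) — a
regime real heterogeneous spectra plausibly produce but the synthetic
generator below does not (see Limitations).

## Cohort statistics

Per ion and cohort, log10 of the *matched* (nonzero) relative intensities
is fitted by sample mean and ddof=1 standard deviation; zeros are excluded
because log 0 is undefined and only observed peaks are histogrammed.
Between case and control fits the symmetrized Gaussian KL distance
(KL(P‖Q) + KL(Q‖P))/2 is evaluated in closed form (cross-checked against
numerical integration to 1e−6 in the tests). The published distribution
table's second entries are treated as standard deviations, not variances:
only under the σ reading do the published KL distances reproduce. The FM
ratio 100·10^(μ_YiF − μ_Yi) compares the distribution modes (10^mean for a
log10-Gaussian) of the migration-born YiF peak and its Yi parent within the
all-nCF case cohort. Ions with fewer than 30 matched values in a cohort are
reported as absent (NaN), never as zero. Plotting is out of scope; the
report is a tidy table.

## Synthetic data

The generator emulates the *statistical* structure of the real cohorts, not
the physics of fragmentation:

* Case (FUT8-KO) cohort: each ion's intensity is drawn independently as
  10^N(μᵢ, σᵢ) from the published case parameters, with dropout 0.05 on
  Y1..Y5 (core ions nearly always observed) and 0.5 on Y1F..Y5F (a
  migration-born peak exists only when FM occurred in that spectrum).
* Control cohort: a mixture of that nCF component (weight 1 − w) and a
  synthetic CF component (weight w, default 0.3). Only the control
  *marginals* are published — no pure-CF distribution exists in print — so
  the CF component is an explicit synthetic choice: Yi as in the case
  parameters, each YiF mean 0.2 decades below its Yi parent (YiF ≈ 63% of
  Yi intensity, the signature of a fucose retained on the core through
  fragmentation), σ 0.25, dropout 0.05 throughout.
* Values are clipped to (0, 1]; vectors are normalized after zero-filling;
  everything is deterministic under a fixed seed.

Toy spectra place one peak per nonzero ion at its theoretical m/z (optional
ppm jitter), a base peak of intensity 1.0 and noise peaks outside every ion
window, so extraction recovers the intended vector exactly at zero jitter.

## Problem sizes and numerical choices

The default test/benchmark sizes are 5,000 + 5,000 vectors for classifier
benchmarks, 50,000 for parameter-recovery checks, 150–1,000 for invariant
and determinism runs — sizes at which the cohort statistics are stable to
well under the assertion tolerances. Split sizes use the floor rule
(uniquely consistent with the published 19,047 / 16,057 / 22,618 training
counts); tagged and untagged cohorts are shuffled and split independently.
F1 uses CF as the positive class (the minority detection target); the
published F1 values could not be reconciled with the published per-class
accuracies and class sizes, so F1 is defined cleanly here from the
confusion matrix. UNDETERMINED baseline outputs are excluded from metric
denominators and counted separately.

## Limitations

* The generator draws ions independently given the component; real spectra
  have strongly correlated ion intensities (shared fragmentation
  efficiency, glycan abundance) and heterogeneous quality. Consequences:
  passing benchmark results show the *procedures* behave correctly under
  the published marginal statistics, not that real-data accuracies are
  reproduced; and the autoencoder's nCF specificity at k = 0.4 is
  substantially lower on this synthetic data (reconstruction errors lack
  the outlier-dominated shape discussed above) than the high specificity
  reported on real spectra.
* The synthetic CF component is not constrained by any published
  distribution; benchmark metrics depend on that documented choice.
* The ten Y-type ions are the only fragments modeled; oxonium/B/C/Z ions,
  deisotoping and isotope-envelope summation are out of scope, as is glycan
  structure elucidation itself.
* Which charge states the original experiment summed, and whether
  normalization preceded zero-filling, are unstated upstream; both are
  explicit configuration here (defaults: charges {1, 2}, zero-fill first).
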