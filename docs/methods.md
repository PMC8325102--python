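# Methods

This note documents the models implemented in `kinasecall`, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical conventions that matter for reproducing a
run exactly.

## 1. Motif model

**Model.** A phosphosite's sequence context is the ±7 flanking residues
around the acceptor (S/T/Y). From `N` training windows the per-position
residue probability is pseudocount-regularized,

    p(x,i) = (f(x,i) + c(x)) / (N + ε),   c(x) = p(x)·ε,   ε = √N,

with background `p(x)` estimated from the proteome. Weights are
`w(x,i) = log2(p(x,i)/p(x))` and a window scores `λ = Σᵢ w(qᵢ,i)`. The √N
pseudocount keeps every weight finite and shrinks towards the background at
a rate that vanishes as the training set grows: the posterior mean places
weight `N/(N+√N)` on the data.

**Acceptor position.** λ sums over the 14 flanking offsets only; the
acceptor itself (offset 0) is excluded by default because the training
windows all share an S/T/Y there and it carries no discriminative
information. `include_center=True` adds offset 0 for training sets that
constrain the acceptor.

**Terminus handling.** Sites within 7 residues of a terminus have pad
symbols in their window. At scoring time a pad contributes exactly 0 (a
neutral, background-level observation), so λ remains comparable across
sites; the number of scored positions is reported alongside λ. At training
time pads are excluded from the integer counts, and each column's pad mass
is redistributed over the alphabet in proportion to the background:

    p(x,i) = (f(x,i) + p(x)·(ε + n_pad,i)) / (N + ε).

The denominator stays `N + ε` for every column; pad-free columns reduce
exactly to the standard formula, every column sums to 1 analytically, and a
fully padded column collapses to the background (all weights 0). Columns
are never renormalized numerically — the identity is exact.

**Other conventions.** Non-standard residues (U, B, Z, X, …) are treated as
pads when scoring and skipped when training, with logged counts. A
background residue absent from the proteome receives a floor of one
pseudo-observation before renormalization, since `p(x)` appears in
denominators. Offsets are signed relative to the acceptor; protein
coordinates are 1-based, matching site names such as S1377.

**Calibration.** A PWM trained on windows drawn i.i.d. from the background
is flat up to sampling noise: the weight of a cell with background
probability `p` has standard deviation ≈ `√((1−p)/(pN))/ln 2`, about 0.06
at `p = 0.05`, `N = 10⁴`. The maximum over the 280 cells therefore sits
near 0.19 at `N = 10⁴` and falls below 0.1 only for training sets an order
of magnitude larger; the shipped null-calibration check trains on 10⁵
windows, where the expected maximum is ≈ 0.06 and the mean score of fresh
background windows is 0 within ±0.05.

## 2. BioID interactome filter

Input is a protein × sample matrix of linear MS1 intensities with bait and
control groups in ≥2 replicates (here triplicates). The cascade:

1. **Replicate presence.** Keep proteins observed in ≥2 of 3 bait
   replicates (scope configurable to either group).
2. **Imputation.** Missing values are treated as missing-not-at-random
   (below the detection limit). Per sample column, missing log2 intensities
   are drawn from `Normal(mean − 1.8·sd, (0.3·sd)²)` computed on the
   observed log2 values — the standard downshifted-normal convention for
   label-free proteomics. Both the downshift (1.8 column sd) and width (0.3
   column sd) are configuration keys, as is column-wise vs global scope.
3. **Test.** Two-tailed Welch's t-test on log2 intensities, bait vs
   control, with Welch–Satterthwaite degrees of freedom (scipy).
4. **Call.** `passed ⇔ log2_ratio ≥ log2(fc_cutoff) and p < p_cutoff`,
   with `log2_ratio = mean(log2 bait) − mean(log2 control)` (the volcano
   x-axis). Defaults: 2-fold, p < 0.05.

Proteins detected only in bait go through the same imputation path rather
than a separate "exclusive detection" rule: one uniform statistical
treatment keeps the p-values interpretable.

Two statistical caveats are worth stating. Welch's test at n = 3 vs 3 is
conservative (true size ≈ 0.03–0.04 at nominal 0.05); the null
false-positive checks in this package account for that by using a wide
binomial band. And under MNAR dropout, imputation at a column-level
downshift can fabricate group differences for proteins near the detection
limit; the fold-change cutoff, not the p-value, is the guard against such
calls. The shipped null-rate check therefore disables the detection limit
to isolate the test's own type-I error.

## 3. Perturbation phosphoproteome filter

Input is a peptide-level table of per-replicate treated/control log2
ratios with phospho-counts and localization probabilities.

1. **Monophosphopeptides only** (`phospho_count == 1`), so each ratio is
   attributable to a single site.
2. **Localization** strictly greater than 0.75 (a value of exactly 0.75 is
   excluded).
3. **Aggregation**: per site and replicate, the mean of the contributing
   peptides' log2 ratios; peptides disagreeing on site metadata are an
   input error, not silently merged.
4. **Call**: the replicate-mean log2 ratio must clear ±log2(2) with the
   sign required by the experiment (down for an inhibitor, up for an
   activator) and a two-tailed one-sample t-test of the replicate ratios
   against 0 must give p < 0.05.

The one-sample-against-zero test is the only test computable from the
stated data reduction (per-replicate ratios, averaged to sites); when
paired per-channel intensities are available a two-sample mode can be
substituted. Sites with zero replicate variance are flagged untestable and
never pass. The mono→localization→aggregate cascade is order-stable: the
two filters commute.

## 4. Integration

A site is a substrate call iff its protein is a called interactor, the
site is a called regulated site, and λ strictly exceeds the score
threshold (default 2.0; a tie fails). The evaluated universe is the set of
perturbation-quantified sites whose proteins were quantified in the BioID
matrix — the sites for which all three layers could in principle have
fired; it is configurable to all perturbation sites. The seven Venn
regions of the three flag sets are reported and must reconstruct each
filter's total exactly. A protein-level rollup marks every protein with at
least one final site. Recovery against planted truth reports sensitivity
TP/(TP+FN) over planted sites, precision TP/(TP+FP) over calls (NaN when
there are no calls), and F1.

## 5. Mutation impact

Each missense mutation is paired with every phosphosite within ±7
residues (one mutation at a time; no compound haplotypes). For a flanking
mutation, additivity gives `Δλ = w(alt,i) − w(ref,i)` exactly; the
implementation computes λ on the substituted window and asserts the
identity. Acceptor mutations (offset 0) are flagged `acceptor_loss` when
the alternate is not S/T/Y and are not Δ-scored, since the flank-only PWM
carries no weight there. Substitutions beyond ±7 never change λ.

Classification defaults (all configurable; they are conventions, since no
canonical thresholds exist for "loss vs no change"): **loss** if
Δλ ≤ −1 or the mutation pushes a passing site (λ_wt > threshold) below the
threshold; **no_change** if |Δλ| < 0.5; **gain** if Δλ ≥ +1; otherwise
**indeterminate**.

The in vitro assay statistic is
`phosphorylation ratio (%) = (1 − area_with/area_without) × 100`,
the fraction of the nonphosphopeptide consumed by the kinase reaction;
it is ≤ 100, equals 100 iff the with-kinase area is 0, and negative values
(with > without) are reported and flagged rather than clamped.

## 6. Synthetic-data generator

The generator produces every input with known ground truth. Its defaults
define the shipped reference benchmark; they are generator conventions,
stated here, not inferences about any particular experiment.

| Parameter | Default | Meaning |
|---|---|---|
| n_proteins / mean_length | 500 / 450 | i.i.d.-residue proteome, geometric lengths, min 30 |
| residue frequencies | human-like table | background for proteome and motif residuals |
| ground-truth motif | acidophilic (E/D at +1..+3, mass 0.9) | CK2-like specificity; a basophilic (R/K at −3,−2) variant is included |
| n_train_windows | 2000 | training set for the PWM |
| n_true / n_decoy | 50 / 2950 | substrate sites planted on distinct proteins / native S/T/Y decoys |
| n_extra_interactors | 50 | proximal-but-nonsubstrate proteins |
| BioID: baseline, protein sd | 25, 2 (log2) | latent protein abundances |
| BioID: effect, replicate sd | +2, 0.3 (log2) | bait-channel shift for true interactors |
| detection limit | 22 (log2) | hard MNAR truncation; values below become missing |
| perturbation: effect, noise | 1.5 (down), 0.2 (log2) | replicate ratio shift for true sites |
| peptides per site | 1 + Poisson(0.5) | missed-cleavage/modified forms |
| frac_multiphospho | 0.1 | share of peptide rows with ≥2 phosphates |
| localization probability | Beta(12, 1) | ≈97% of rows exceed 0.75 |

"Consistent truth" (default on) forces planted substrate sites onto
planted interactor proteins, so the triple intersection has a recoverable
signal; turning it off yields a negative-control scenario. True sites get
their flanking window overwritten with a fresh motif sample, so the
returned (modified) proteome is what downstream scoring must use.

**What is not emulated:** spectra, peptide-spectrum matching, protein
inference, TMT reporter-ion physics, isotope-impurity effects,
normalization artifacts, correlated peptide noise, or biological pathway
structure. Passing the benchmark therefore demonstrates that the cascade's
statistics and set algebra are correct and well calibrated under the
stated noise model — not that any particular wet-lab dataset would yield
the same operating characteristics.

## 7. Reproducibility and problem sizes

All randomness flows from one run seed through per-stage seeds derived as
`sha256(seed:stage) mod 2³¹`, so stages can be rerun in isolation and a
rerun with the same configuration is byte-identical (tables are written
with shortest-exact float formatting; the config hash excludes the output
directory). The reference benchmark (3000 sites, 500 proteins, triplicate
designs) and the calibration analyses (2000-protein and 1000-site nulls,
10⁵-window null PWM, 10⁴ imputation draws) each run in seconds on one
CPU; these sizes give binomial/SE tolerances tight enough for the
guarantees asserted in the test suite while keeping the whole suite fast.

## 8. Known limitations

- The flank-only PWM assumes positional independence; correlated motifs
  (e.g. priming-dependent kinases) are outside the model.
- Welch's test with triplicates has low power and is conservative; the
  fold-change gate does most of the filtering at this replicate count.
- Downshifted-normal imputation is a convention, not a dropout model fit;
  near-limit proteins can acquire biased ratios (see §2).
- The regulated-site test treats replicate ratios as independent normals;
  TMT ratio compression and channel correlation are not modeled.
- Mutation impact is purely sequence-based: structural effects, expression
  changes, and phosphatase/kinase network rewiring are out of scope.
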