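# Methods

`lipidiff` implements a comparative plasma-membrane lipidomics analysis for
shotgun-lipidomics concentration tables: species-level pmol amounts for a
healthy control hepatocyte line (THLE2) and a panel of hepatocellular
carcinoma (HCC) lines, untreated or treated with a Wnt-pathway modulator
(Wnt3a or Dkk1), with a few biological replicates per condition.

## Nomenclature and ontology

Species are named in Lipotype-style shorthand: a class token, an optional
`O-` ether marker, and one sn-chain token `C:D[;H]` per chain (carbons,
double bonds, hydroxylations), e.g. `Cer 18:1;2/17:0`. The ontology covers
23 classes (19 diacyl/monoacyl classes plus the ether variants `PC O-`,
`PE O-`, `LPC O-`, `LPE O-`); each class has a fixed chain arity (CL: 4,
TAG: 3, most phospholipids and sphingolipids: 2, CE and lyso-species: 1)
and maps to one of five categories: sterols, sphingolipids, glycerolipids,
glycerophospholipids, glycerophospholipid intermediates (the lyso-species).
The class → (category, arity, ether) table ships as an editable TSV
resource. The category assignment of the lyso classes and CE follows the
standard LIPID MAPS-style grouping. Parsing accepts both spaced
(`17 : 0`) and compact (`17:0`) typesetting; the canonical rendering is
compact and the parse → render round-trip is exact.

## Missingness model

A missing cell means "below the detection limit, not measurable" and is
represented explicitly (NaN), never imputed; a stored `0.0` is a measured
zero and is kept distinct. Missing values are neglected in every
computation: the mol% denominator, replicate means and the t-test use
present values only.

## Acquisition filter

For intensity-level inputs, a (lipid, sample) cell is kept only if its
signal-to-noise ratio strictly exceeds 5 **and** its signal exceeds 5×
the lipid's blank-sample intensity; both thresholds are parameters
(`FilterParams`). Delivered pmol tables are assumed pre-filtered upstream,
so the filter is exposed for synthetic/intensity data only.

## mol% normalization

Within each sample, every present concentration is divided by the sample's
present-value sum and multiplied by 100, so each non-degenerate sample sums
to exactly 100 mol%. The operation is idempotent and invariant to rescaling
a sample's raw vector by any positive constant. A sample with no positive
present value raises a degenerate-sample error naming the sample.

## Differential regulation calls

For a contrast of a test group over a reference group (cancer over healthy
control, or treated over untreated of the same line), per lipid:

* `log2fc = log2(mean_test / mean_ref)` over present replicate mol% values
  (ratio of means, not mean of ratios);
* a two-tailed two-sample Student's t-test (classical equal-variance
  pooling by default; Welch via `equal_variance=False`) on the
  per-replicate mol% values;
* a lipid enters the contrast only with ≥ `min_replicates` (default 2)
  present values in **both** groups; a group mean of exactly 0 makes
  `log2fc` undefined and excludes the lipid with a logged reason;
* a differentially regulated lipid (DRL) has `p < alpha` (default 0.05,
  uncorrected; Benjamini–Hochberg available as an explicit opt-in
  deviation), with direction Up/Down by the sign of `log2fc`.

Numerical conventions: when the standard error is below 1e-12 relative to
the group means it is treated as zero — such differences are float
rounding, not evidence — and then `p = 1` if the means agree to a relative
1e-9 and `p = 0` otherwise. This generalizes the natural zero-variance
convention (identical groups ⇒ p = 1; zero variance with distinct means ⇒
t → ∞ ⇒ p = 0) and matters only for noise-free synthetic data; measured
data never sits within float resolution.

## Interaction taxonomy

Per cell line, each lipid carries a significance-gated *cancer* direction
(untreated line vs healthy control) and *treatment* direction (treated vs
untreated), each Up/Down/none. The pair maps to five mutually exclusive,
exhaustive categories: **moderates** (directions opposite), **amplifies**
(same), **no_treatment_effect** (cancer only), **side_effect** (treatment
only), **unaffected** (neither). A lipid excluded from one contrast by the
replicate rule gets direction none there but is flagged `not_evaluable`,
keeping absence of evidence distinguishable from evidence of no effect;
count summaries are reported both inclusive and strict (fully evaluable
lipids only).

Directional DRL set overlaps use UpSet semantics: each lipid belongs to the
exact combination of sets containing it; concordant mode splits each
combination into Up/Down counts for lipids with identical direction in all
member sets, counting the rest as discordant.

## Clustering and PCA

Fold-change clustering operates on a lipids × contrasts matrix where every
cell that is not a significant DRL — missing or merely non-significant —
is replaced by zero; a provenance mask records why (`drl`,
`nonsignificant`, `missing`, `zero`). Profiles are compared by Pearson
correlation distance (1 − r) under average linkage (the pheatmap-style
default; the linkage method is a parameter). A zero-variance profile has
undefined correlation and sits at distance 1 from every other profile by
convention. PCA runs on mol%/sample profiles with samples as observations,
column-centered and unscaled (mol% values share a scale; standardization is
an option); lipids with any missing value are dropped and listed. The
per-component sign indeterminacy is fixed by making each component's
largest-magnitude loading positive, so scores are reproducible across runs
and BLAS builds.

## Synthetic data generator

The generator emulates the statistical shape of a Lipotype-style delivery
with known ground truth. Defaults, chosen once as the study conditions:

| parameter | default | rationale |
|---|---|---|
| design | THLE2 + HUH7/SNU475/Hep3B with a Wnt3a arm | the panel's Wnt3a-responsive subset |
| `n_replicates` | 3 | the study's biological replication |
| `n_lipids_per_class` | ~260 species over 21 classes | plausible membrane panel size |
| `base_log10_pmol_mean`, `sd` | 1.5, 0.8 | median ≈ 32 pmol, ~2 decades spread |
| `replicate_cv` | 0.10 | multiplicative noise typical of shotgun lipidomics |
| `detection_limit_pmol` | 3.0 | yields ~5–15% below-LOD missingness |
| `effect_log2fc_magnitude` | 2.0 | clearly regulated species (4-fold) |
| `interaction_mix` | 0.2 each | even coverage of the five categories |

Baseline abundances are lognormal; replicate noise is mean-one lognormal
with the stated CV; values below the detection limit become missing and are
flagged in the truth. All randomness derives from one seed; replicate noise
uses per-lipid child streams so truth labels do not depend on noise draws.

**Compositional closure.** mol% is a composition: if planted effects
changed a condition's summed concentration, the mol% of *every* lipid in
that condition would shift and no planted label would be recoverable, by
any method. Planted effects are therefore total-conserving: per cancer
line, effect signs are assigned greedily (largest baseline first) to keep
both condition arms' expected totals at the baseline total, and one or a
few balancer species per arm absorb the residual exactly — a moderates
lipid's cancer effect (treated-arm neutral, since its treatment effect
stays tied to −c) for the untreated arm, and a treatment-affected lipid's
treatment effect for the treated arm. Balancers keep their direction and
approximately the nominal magnitude; the truth table records the actual
planted values. In the class-coherent mode (one effect per class per line,
emulating class-level trends) conservation is not enforced and labels
recover only approximately.

**What the generator does not emulate:** class-dependent abundance scales,
correlated species, batch/acquisition drift, intensity-dependent
censoring (the limit cuts on the true pmol value), or compositional
imbalance between conditions. Passing recovery tests therefore show the
calling and classification logic is correct under the stated noise model —
not that the t-test's assumptions hold for any real lipidome, where
condition totals may genuinely differ.

## Recovery metric

Label recovery is measured on lipids evaluable in both contrasts (the
strict sense): a Down & Down species at 2⁻⁴ of baseline falls below the
detection limit in the treated arm, is excluded by the ≥ 2-replicate rule,
and its treatment label is unrecoverable from the data. Inclusive recovery
(counting such lipids as errors) is reported alongside by the tests'
helper. Measured under the default conditions (see
`scripts/acceptance.py`): strict recovery ≈ 0.95 at n = 5, CV 10%,
|log2fc| = 2; exactly 1.0 on noise-free, censoring-free data.

## Problem sizes

The test suite and acceptance script use 10,000 null lipids for the type-I
check, 500 planted lipids for recovery, 100 random fixtures for the t-test
oracle, and ≤ 6-item fixtures for the exhaustive linkage/overlap oracles —
sizes at which the exhaustive oracles are exact and the Monte-Carlo error
of the rate estimates is well inside the asserted bands.

## Known limitations

* The five-way taxonomy inherits the significance gate: with n = 3 a real
  but noisy effect lands in `unaffected`/`no_treatment_effect`; the
  categories are descriptive, not causal.
* No multiple-testing correction by default (raw P < 0.05), matching the
  analysis being reproduced; BH correction is available but changes DRL
  sets.
* Pearson-distance clustering of zero-filled matrices underweights lipids
  significant in few contrasts; the fill mask is retained so users can
  audit this.
* The t-test treats mol% replicates as independent observations; the
  compositional dependence between lipids within a sample is ignored, as
  in the original analysis.
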