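# Methods

This note documents the models, parameter choices and numerical conventions
behind `tcscore`, and what the synthetic cohorts do and do not establish
about real repertoires.

## Input model and clonotype identity

A sample is a set of productive TCR-β clonotypes `(V gene, J gene, CDR3
amino-acid sequence)` with duplicate counts; frequencies are counts over the
sample total. Identity is at the amino-acid, gene level: allele suffixes
(`*01`) are truncated, ambiguous (comma-separated) gene calls and junctions
containing stop (`*`), frameshift (`_`) or any non-standard character are
dropped with a logged count, and duplicate keys merge by summing counts.
Nucleotide-level clonotypes and paired αβ chains are out of scope.
Normalization is idempotent and writing + re-reading a sample is an exact
round trip.

## F50

Within one V–J, members are ordered by descending repertoire-level frequency
(ties broken lexicographically by CDR3 for determinism). F50 is the frequency
of the first clonotype at which the cumulative sum reaches half the V–J's own
total; the crossing is inclusive (cumulative ≥ total/2), with a 1e-12
relative slack so exact-half crossings survive floating-point rounding.
Frequencies are deliberately *not* renormalized within the V–J: only this
reading reproduces the worked example of a 0.057 top clone inside a V–J of
total 0.063 yielding F50 = 0.057. F50 is bounded by the member frequencies
and never decreases when mass moves from the smallest clone to the largest.

## CDR3 distance and chaos

The pairwise distance is a weighted Hamming distance in the TCRdist family:

- identical residues cost 0; a substitution costs `min(cap, cap − B(a,b))`
  with `B` = BLOSUM62 and `cap = 4`, so conservative substitutions are cheap
  and dissimilar ones saturate;
- a gap against a residue costs `gap_cost = 4`;
- unequal lengths are aligned by anchoring the first ⌈n/2⌉ residues of the
  shorter sequence left and the last ⌊n/2⌋ right, with one contiguous middle
  gap block — deterministic, mirroring the CDR3 middle-gap convention.

All distances are non-negative integers; the CDR3 loop is used whole (no
end-trimming) with weight 1, since a uniform rescaling cannot change either
E or V below. Matrix name, cap and gap cost are configurable.

Pairs are enumerated over *unique* CDR3 strings, unweighted by clone size.
The distance-value distribution over all unordered pairs gives
`E = −Σ p_d log2 p_d` (bits), `V` = number of distinct values, and
`chaos = E·V` by default (`E+V` and `E` alone are available as config
options). E ≤ log2 V with equality iff values are equiprobable. Profiles with
fewer than two CDR3s produce an empty distribution flagged degenerate
(E = V = chaos = 0). Profiles larger than `subsample_cap = 2000` CDR3s are
reduced to a seeded uniform subsample before pair enumeration; the cap keeps
the largest V–Js (>10⁴ CDR3s) tractable, is bit-for-bit reproducible under a
fixed seed, and recovers the exact computation whenever it is ≥ the profile
size. Internally the pairwise computation is vectorized: sequences are
grouped by length, padded per the gap rule, and costs looked up in a
precomputed 27×27 integer table.

## TCS and the feature matrix

`TCS = F50 / max(chaos, chaos_floor)` with `chaos_floor = 1.0`. The floor
guards the degenerate cases (single-clonotype or single-distance V–Js, where
chaos = 0) and makes TCS finite and non-negative everywhere; it is
configurable. TCS is strictly increasing in F50 and strictly decreasing in
chaos above the floor.

The cohort feature matrix is samples × V–J with the universe taken as the
union of V–Js observed across the cohort (an explicit universe can be
supplied, e.g. to express a test cohort on the training universe). V–Js
absent from a sample get TCS 0 — absence is absence of expansion evidence —
keeping Welch tests and classifiers well-defined; a NaN policy exists for
exploratory use. Column order is the sorted V–J key regardless of sample
order, and the whole path (simulation → TCS → matrix) is deterministic under
fixed seeds.

## Tissue/blood overlap

The overlap partition bins tissue clonotypes at a frequency threshold
(default 0.001, strict `>` for the "over" bin), splitting each bin by
presence of the clonotype key in blood and reporting counts and cumulative
tissue frequencies. Morisita–Horn similarity

`MH = 2 Σ p_i q_i / ((Σ p_i²/P² + Σ q_i²/Q²) P Q)`

is computed over rank windows (all, top 1–20, ranks 21–1000, …) defined on
each sample's own descending-frequency ranking in turn — MH itself is
symmetric, so "direction" is purely which sample defines the window. Window
frequencies are raw repertoire frequencies, not renormalized, preserving the
expansion signal; keys absent in the other sample contribute 0 and a fully
disjoint window scores 0.

## Diagnostic model

1. **Welch filter.** Per-V–J unequal-variance t-test (vectorized; the
   Welch–Satterthwaite degrees of freedom) keeping two-sided p < 0.05. The
   degenerate both-variances-zero case is resolved by rule: equal means →
   t = 0, p = 1 (dropped); different means → p = 0 (kept). A `top_n` mode
   can force an exact count, and a `min_keep` floor guarantees downstream
   stages a non-empty panel on weak cohorts.
2. **Random-forest selection.** 1000-tree forest (scikit-learn) on the
   filtered features; top 13 by impurity importance, ties broken by V–J key;
   deterministic under a fixed seed.
3. **Gaussian naive Bayes.** Class priors and per-feature class-conditional
   Gaussians (sample variances floored at 1e-9), implemented in-package so
   the model serializes to JSON and refits cheaply per CV fold; posteriors of
   the GO class are the sample scores.
4. **Evaluation.** Confusion statistics at posterior ≥ 0.5 (sensitivity and
   specificity as percentages to two decimals), ROC by threshold sweep with
   trapezoidal AUC (equal to the Mann–Whitney pair statistic with ties at ½),
   and average-linkage Euclidean clustering of samples on per-feature
   z-scored TCS with a 2-cluster cut.

LOOCV refits the naive Bayes (including priors) on each n−1 fold. By default
the feature panel is selected once on the full cohort and held fixed across
folds — the conventional order of operations for this workflow, which leaks
selection information and therefore flatters the cross-validated estimate. A
nested mode re-runs filter + selection inside every fold and is the
leak-free choice when the selection procedure itself is under evaluation.

**Permutation null.** The chance-level calibration fixes the feature panel a
priori, simulates a cohort with zero planted effect, and permutes labels
before each LOOCV. Two pitfalls this design avoids, both measured on
synthetic cohorts: (i) re-selecting features on permuted labels and then
cross-validating with them fixed reintroduces selection bias and inflates
null AUC; (ii) permuting a cohort that *does* carry planted signal leaves the
panel features strongly mutually correlated (one latent "affected" factor),
and random label imbalance over that factor widens the null AUC spread to
roughly twice the Mann–Whitney width. On null cohorts the LOOCV AUC is
mildly pessimistic (mean ≈ 0.47 rather than 0.50) because held-out extreme
values of heavy-tailed TCS features shift their own class's fitted moments —
a known small-sample LOOCV effect, accepted rather than corrected.

## Survival

GO-free survival uses the Kaplan–Meier product-limit estimator and the
standard two-group log-rank test (lifelines), with hypergeometric variance at
tied event times and censoring processed after events at the same time. The
default follow-up horizon is 18 months; times must be positive and a test
with zero events is refused.

## Synthetic cohorts

The generator emulates bulk blood TCR-β repertoires:

- **Clone sizes:** iid draws from the discrete power law with exponent 1.5
  (the standard heavy-tail model for repertoires), capped at 1000 reads per
  clone — the uncapped law has infinite mean and a single clone can swamp a
  sample, which real blood repertoires do not show. The cap means natural
  background expansions top out near frequency 1000/total, below the planted
  signal range at the default 20,000 (and the test-scale 5,000) clonotypes
  per sample.
- **Gene usage:** one Dirichlet draw per study for V (48 TRBV genes) and J
  (13 TRBJ genes); the 624-combination grid brackets a realistic observed
  universe of ~500+ V–Js. Training, test and validation cohorts of one study
  share this context (and the signal V–Js); samples differ by per-sample
  seeds derived from the master seed.
- **CDR3s:** random C…F-framed peptides of length 9–18. No VDJ recombination
  model, insertion/deletion profile, or nucleotide level — synthetic CDR3s
  are exchangeable random strings, so background V–Js have near-maximal
  chaos. Real repertoires share public clones and convergent motifs, giving
  correlated backgrounds the generator does not reproduce.
- **Signal:** the 13 most-used V–Js (present in every sample). Per signal
  V–J, with penetrance 0.9 an affected (GO) sample receives an expanded
  clone at frequency uniform in [0.01, 0.06] (raising F50) and a homology
  cluster of 30 CDR3s within ≤2 substitutions of a seed (lowering chaos);
  GH→GO progressors carry the same mechanism at 0.7× penetrance. The two
  mechanisms are independently switchable to exercise each score path.
- **Paired thyroid/blood:** the thyroid sample reuses the blood clone pool
  with the top 50 clones enriched 3–15×, half the tail retained and
  tissue-private clones added at count 1, scaled so every thyroid clone above
  frequency 0.001 is present in blood by construction.
- **Follow-up:** progressors draw gamma(shape 2) event times with
  unconditional median 6.5 months; events beyond 18 months, and all
  non-progressors, are censored at 18. Conditioning on observed events
  (< 18 months) shifts the empirical median to ≈ 6.2.

Passing tests on these cohorts demonstrates that the statistics measure what
they claim, that the pipeline recovers a strong planted panel (≥ 8 of 13
V–Js, LOOCV/test AUC ≥ 0.9 at 70/30 cohort sizes), and that the evaluation
machinery is calibrated at chance on null data. They do not establish
clinical performance: real effect sizes, inter-patient gene-usage
variability, batch effects and sequencing-depth differences are all outside
the generator.

## Problem sizes and determinism

End-to-end experiments in the test suite and the reproduction script run at
5,000 clonotypes per sample with the pairwise-distance subsample cap at
2,000 — the package's chosen desk-scale operating point; the generator
default of 20,000 clonotypes changes none of the logic. Every stochastic
stage (simulation, subsampling, forest, permutations, follow-up) takes an
explicit seed; pipeline runs write a manifest with the config hash and seeds
and are byte-reproducible under a fixed manifest.
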