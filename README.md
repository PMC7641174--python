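# tcscore

Scoring of T-cell receptor (TCR) β-chain repertoires for early prediction of
Graves' ophthalmopathy (GO) in Graves' hyperthyroidism (GH) patients, built
around **TCS** — the *TCR clonal expansion and chaos score* of a V–J gene
combination — together with the diagnostic-model workflow that turns
per-sample TCS vectors into a progression classifier, and the tissue/blood
repertoire-overlap analyses that motivate blood-based monitoring.

## Who this is for

Computational immunologists working with bulk TCR-β clonotype tables (AIRR
Rearrangement TSV: `junction_aa`, `v_call`, `j_call`, `duplicate_count`) who
want per-V–J summary statistics that capture antigen-driven T-cell activation,
and a reproducible small-cohort biomarker-panel pipeline on top of them.

## The score

For each V–J combination of a sample (clonotype frequencies are
repertoire-level, the V–J keeps its own total *F*):

- **F50** — frequency of the clonotype at which the descending cumulative
  frequency within the V–J first reaches *F*/2. A single dominant clone gives
  a large F50 (oligoclonal expansion); evenly spread clones give a tiny one.
- **Chaos (E·V)** — from the multiset of pairwise CDR3 distances inside the
  V–J (an integer weighted-Hamming/TCRdist-style distance:
  `min(cap, cap − BLOSUM62(a,b))` per substitution, gap cost 4, deterministic
  middle-gap alignment for unequal lengths), take `E` = Shannon entropy (bits)
  of the distance-value distribution and `V` = number of distinct distances;
  chaos = E·V. Homologous, antigen-focused CDR3 sets score low.
- **TCS = F50 / max(chaos, 1)** — activation raises F50 and/or lowers chaos,
  so either mechanism raises TCS.

Cohort analysis: samples × V–J TCS matrix → Welch-*t* feature shrinkage →
random-forest importance selection (1000 trees, panel of 13) → Gaussian naive
Bayes → leave-one-out cross-validation, ROC/AUC, confusion statistics,
hierarchical clustering — and, for initially-GH cohorts under follow-up,
Kaplan–Meier GO-free survival with the log-rank test. Paired thyroid/blood
samples are compared by a frequency-threshold overlap partition and the
Morisita–Horn similarity index over rank windows, in both directions.

A first-class synthetic-data module (`tcscore.simulate`) generates seeded
cohorts with heavy-tailed clone sizes, Dirichlet V/J usage over 48×13 TRBV/TRBJ
genes and class-dependent signal (planted expansions and CDR3 homology
clusters in 13 signal V–Js), so the whole pipeline is testable end to end
without any sequencing data.

## Worked example

```python
from tcscore import (VJProfile, f50, pairwise_distance_distribution,
                     ev_score, tcs_of_vj)

profile = VJProfile.from_members(
    "TRBV27", "TRBJ1-5",
    [("CASSLGETQYF", 0.057), ("CASRDRNYEQYF", 0.004), ("CAWSVGNTEAFF", 0.002)],
)
res = f50(profile)
print(f"F50 = {res.value:.3f} (crossing rank {res.crossing_index})")
dist = pairwise_distance_distribution(profile)
ev = ev_score(dist)
print(f"E = {ev.entropy_bits:.4f} bits, V = {ev.variability}, chaos = {ev.chaos:.4f}")
print(f"TCS = {tcs_of_vj(res.value, ev):.5f}")
```

prints

```
F50 = 0.057 (crossing rank 1)
E = 0.9183 bits, V = 2, chaos = 1.8366
TCS = 0.03104
```

The top clone carries 0.057 of the repertoire inside a V–J of total frequency
0.063, so it crosses 50% alone and F50 equals its frequency — strong
oligoclonal expansion. The three CDR3s produce two distinct pairwise
distances ({24: 2 pairs, 25: 1 pair}), hence V = 2 and E = 0.9183 bits;
the resulting TCS ≈ 0.031 is orders of magnitude above a diverse,
unexpanded V–J (typically < 1e-4).

A full synthetic study from the shell:

```bash
tcs run --seed 1 --out myrun/        # simulate → score → train → evaluate → survival
tcs simulate --n-go 10 --n-gh 10 --seed 3 --out cohort/   # just the data
```

`myrun/manifest.json` records the config hash, seeds and every artifact
(TCS matrices, model JSON, ROC tables, KM tables, clustering).

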