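# apexflux

Analysis pipeline for APEX2 proximity-biotinylation interactomics with a
DNA-damage (ionizing radiation, IR) perturbation, plus splice-junction
percent-spliced-in (PSI) analysis of androgen-receptor (AR) isoform
composition. It is written for proteomics/transcriptomics analysts who have
upstream quantification in hand — a MaxQuant-style protein-groups table, or
a junction-count table — and need the downstream statistics: filtering,
riBAQ quantification, flux classification, overlap/enrichment tests, and
PSI/dPSI calls.

## What it computes

**Interactome track.** From per-sample iBAQ intensities the pipeline
computes relative iBAQ, riBAQ_i = iBAQ_i / Σ_j iBAQ_j per sample, then:

1. drops decoy (`REV__`) and flagged-contaminant (`CON__`) groups;
2. omits proteins detected in the no-H2O2 **control** labeling arm
   (endogenously biotinylated / nonspecific background);
3. keeps proteins with ≥2 unique peptides detected in ≥2 replicates of an
   experimental arm (−IR or +IR), decided per arm;
4. reports each interactor's mean riBAQ per arm (mean over detected
   replicates only) with abundance ranks;
5. classifies IR flux from FC = mean riBAQ(+IR)/mean riBAQ(−IR):
   `ir_up` iff FC ≥ 1.5, `ir_down` iff FC ≤ 1/1.5, with arm-exclusive
   proteins reported separately.

Overlap between interactor lists is 100·|A∩B|/|A∪B| with an exact
hypergeometric tail test P(X ≥ |A∩B|), X ~ Hypergeom(N, |A|, |B|), and GMT
category enrichment uses the same tail with Benjamini–Hochberg q-values.
Replicate QC is PCA plus average-linkage clustering of log10 riBAQ.

**Splicing track.** PSI of a junction is inclusion/(inclusion+exclusion)
reads, where exclusion reads come from competing junctions sharing the same
donor exon; dPSI = PSI(treated) − PSI(control) on replicate-pooled counts,
with a two-sided Fisher exact test, and events are called at strict
|dPSI| > 0.2 and p < 0.05. A built-in AR junction model aggregates
junctions into isoform classes (exon2→exon3: full-length/V1/V6/V7/V9-
compatible; exon3→CE3: AR-V7-encoding; exon2→CE4: CE4-containing).

A seeded synthetic-data module plants ground truth (interactors,
control-arm contaminants, IR-responsive proteins with known fold changes,
junctions with known PSI) so every stage is testable end to end; see
`docs/methods.md` for the model and its limits.

## Worked example

```python
from apexflux import (ProteomeSimConfig, generate_proteomics,
                      quantify_interactome, classify_flux, percent_overlap)
from apexflux.simulate import evaluate_flux_recovery
from collections import Counter

rows, design, truth = generate_proteomics(ProteomeSimConfig(seed=1))
result = quantify_interactome(rows, design)
calls = classify_flux(result.records, fc_threshold=1.5)
print(dict(Counter(c.flux_class for c in calls)))
rec = evaluate_flux_recovery(truth, calls, result.removed_contaminant_ids)
print(f"sensitivity={rec.sensitivity:.3f} FDR={rec.fdr:.3f}")

res = percent_overlap({f"P{i}" for i in range(435)},
                      {f"P{i}" for i in range(13, 480)})
print(f"{res.percent_overlap:.1f}% (~{res.percent_rounded}%)")
```

prints

```
{'unchanged': 973, 'minus_ir_only': 10, 'plus_ir_only': 9, 'ir_down': 40, 'ir_up': 38}
sensitivity=0.975 FDR=0.000
87.9% (~88%)
```

The first line is the flux classification of the 1,070 proteins surviving
the filters (78 of the 80 planted IR-responsive proteins are called, all in
the right direction); the last line is the union-percent overlap of two
interactor lists of 435 and 467 proteins sharing 422 members. The scripts
in `examples/` walk through each capability (quantification, flux,
overlap/enrichment, junction PSI, QC) with printed, annotated output, and a
thin CLI wraps the same functions:

```bash
apexflux simulate --seed 17 --out sim/
apexflux quantify --protein-groups sim/protein_groups.tsv --design sim/design.tsv --out out/
apexflux psi --junctions sim/junctions.tsv --conditions sim/conditions.tsv --out out/
```

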