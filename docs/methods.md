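# Methods

## Scope and model

`apexflux` implements the computational half of an APEX2
proximity-biotinylation interactome experiment with an ionizing-radiation
(IR) perturbation, plus a splice-junction percent-spliced-in (PSI) analysis
of androgen-receptor (AR) isoform composition. The measurement model it
assumes is:

- Proteins are identified and quantified upstream (e.g. MaxQuant); the
  package consumes per-sample iBAQ intensities and unique-peptide counts,
  never raw spectra. iBAQ is treated as an arbitrary-scale abundance: all
  downstream statistics are built on **riBAQ**, the per-sample fraction
  riBAQ_i = iBAQ_i / Σ_j iBAQ_j over the proteins detected in that sample,
  which cancels any per-run global intensity scale.
- The design has three arms: a **control** labeling reaction without H2O2
  (no biotinylation, so anything detected there is endogenously biotinylated
  or bead background), and **−IR** / **+IR** bait arms, each with replicates
  (canonically 3).
- Detection is a present, strictly positive iBAQ; a zero or blank entry is
  "not detected". Nothing is imputed anywhere; per-arm means average only
  the replicates in which a protein was detected.

## Filtering and quantification

The canonical pipeline order is: decoy/flagged-contaminant removal → riBAQ
normalization → control-contaminant omission → evidence filters →
per-arm summaries. Normalization happens before contaminant omission so
riBAQ reflects each run's full detected proteome; the alternative order
would inflate the riBAQ of retained proteins by the share of the removed
background, which differs between runs. Every stage logs input, retained
and removed row counts, so input = retained + removed is checkable per run.

- **Control omission**: a protein detected (iBAQ > 0 and ≥1 unique
  peptide) in ≥1 control replicate is removed from experimental
  consideration. The threshold (`min_control_detections`) is configurable;
  1 is the default because the control arm is itself a detection experiment
  and a single confident control observation already marks a protein as
  biotinylation-independent background.
- **Evidence filters**: a protein is retained *per experimental arm* iff
  its maximum per-sample unique-peptide count is ≥2 and it is detected in
  ≥2 replicates of that arm. Group-level peptide semantics (the maximum
  over samples) follow the upstream software's group reporting.
- **Summaries**: per-arm mean riBAQ over detected replicates, replicate
  support, and per-arm abundance ranks (descending mean riBAQ; ties broken
  lexicographically by accession so ranks are reproducible).

## Flux classification

IR flux is the ratio FC = mean riBAQ(+IR) / mean riBAQ(−IR). The default
rule is inclusive at a 1.5-fold threshold: `ir_up` iff FC ≥ 1.5, `ir_down`
iff FC ≤ 1/1.5, `unchanged` otherwise; a strict mode (>, <) is available.
Proteins quantified in exactly one arm are reported as `plus_ir_only` /
`minus_ir_only` rather than being mapped onto an infinite fold change —
folding them into the thresholded classes would let a single-replicate
dropout masquerade as a maximal flux signal. No p-value accompanies the
fold-change classes by default: with 2–3 replicates per arm and no
distributional model for riBAQ, a test statistic would suggest more
inference than the design supports.

## Overlap and enrichment statistics

Percent overlap between two interactor lists defaults to the **union**
denominator, 100·|A∩B|/|A∪B| (e.g. lists of 435 and 467 proteins sharing
422 members overlap by 87.9% ≈ 88%); min-set and query-set denominators are
selectable for comparing against figures computed under other conventions.
Significance against a finite universe is the exact hypergeometric upper
tail P(X ≥ |A∩B|), X ~ Hypergeom(N = |universe|, K = |A|, n = |B|).
Category enrichment over user-supplied GMT sets uses the same tail per
category (categories intersected with the universe first; zero-overlap
categories reported at p = 1) with Benjamini–Hochberg q-values across all
tested categories. The enrichment universe defaults to all proteins
detected in any arm after decoy removal.

QC mirrors standard replicate diagnostics: PCA and average-linkage
hierarchical clustering of samples on log10 riBAQ, with missing values set
to a floor of half the smallest observed positive riBAQ (a deterministic,
data-adaptive pseudo-count) and a fixed PCA sign convention (each
component's largest-magnitude loading is positive) so coordinates are
byte-stable across runs.

## Junction PSI

PSI of a junction is inclusion/(inclusion+exclusion), where inclusion reads
are the junction's own counts and exclusion reads are the pooled counts of
the competing junctions sharing its **donor exon**. This per-donor
convention makes the two PSI values of a binary donor competition sum to
exactly 1 and matches the AR locus geometry: exon 2 splices to either exon
3 (productive; compatible with full-length AR and the V1/V6/V7/V9 variants)
or cryptic exon 4, and exon 3 splices to cryptic exon 3 (AR-V7-encoding) or
exon 4. Replicates are pooled by summation within each condition before
estimation — read depth is the information unit — and dPSI is
treated-minus-control. Significance uses a two-sided Fisher exact test on
the pooled 2×2 inclusion/exclusion table. This test is a deliberate,
documented stand-in for the internal statistics of dedicated splicing-event
annotation tools, which are neither specified in enough detail to reproduce
nor in scope here; being exact on pooled counts it is conservative
(super-uniform under the null), which the test suite checks. A
per-replicate mean-PSI mode and BH correction across events exist behind
flags for sensitivity analysis; the default event call is strict
|dPSI| > 0.2 and p < 0.05, with boundary values not called.

The AR junction model maps (donor, acceptor) exon-name pairs to isoform
classes; exon names, not genomic coordinates, are the keys, so the same
model applies to any annotation that names AR exons E1–E8 and cryptic exons
CE1–CE4.

## Synthetic data

The generator plants ground truth for every downstream stage:

- **Proteomics** (`ProteomeSimConfig`): protein base intensities are
  log-normal (`log10_mu = 6`, `log10_sigma = 0.15` protein-to-protein);
  each (protein, sample) measurement adds Normal(0,
  `replicate_log10_sigma` = 0.05) noise in log10 space (≈12% CV, a typical
  label-free repeatability) and is detected with probability `detect_prob`
  (default 0.95). Defaults plant 1,000 background interactors, 40 IR-Up at
  true FC 2.0, 40 IR-Down at FC 0.5 (both beyond the 1.5-fold threshold),
  and 50 contaminants; contaminants appear in all three arms (that is, in
  the control — the pipeline's operational definition of a contaminant),
  other proteins only in the experimental arms. Unique-peptide counts are
  1 + Poisson(`peptide_lambda` − 1), constant across a protein's samples.
  One master seed drives separate named streams for the proteomics and
  junction tables, so growing one table never perturbs the other.
- **Junctions** (`JunctionSimConfig`): per event, condition and replicate,
  inclusion counts are Binomial(depth, PSI_true) with the competing
  junction receiving the complement; defaults emulate the AR events
  (E2→E3 0.90 → 0.55 and E3→CE3 0.50 → 0.20 under knockdown) at depth 200
  × 3 replicates.

What the simulator does **not** model: batch effects, correlated dropout
(missingness is MNAR-by-abundance in real LFQ data, independent Bernoulli
here), a realistically wide protein dynamic range (the default
protein-to-protein spread is deliberately narrow so planted fold changes
are the dominant signal), peptide-level variance, isoform-shared junctions
beyond binary donor competition, and overdispersed junction counts.
Passing recovery tests therefore demonstrate that the pipeline's logic is
correct and well-calibrated under its stated assumptions — not that real
data of this type will yield the same sensitivity.

## Verification targets and known limits

Design targets checked by the test suite on fixed seeds: planted flux
recovery at sensitivity ≥0.8 and FDR ≤0.2 with ≥95% contaminant removal
under the default simulation; PSI estimates within 3 binomial standard
errors of truth for ≥99% of 200 events at depth 600; super-uniform null
p-values for the dPSI test; exact agreement of hypergeometric tails with
brute-force enumeration for universes up to size 12 (tolerance 1e−12); and
riBAQ column sums of 1 ± 1e−9.

Dataset-scale counts from the original measurements this design emulates —
numbers of interactors per arm, of IR-Up/IR-Down proteins, of
differentially expressed genes, of significant splicing events, and
cohort-level correlations — depend on raw proteomics and external
transcriptome data that this package does not ship and are **not
reproduction targets**; the synthetic property-based suites above replace
them. The one printed quantity the package does reproduce exactly is
arithmetic, not data: the 88% union overlap of two interactor lists of 435
and 467 proteins sharing 422 members.

Numerical notes: fold changes are undefined (and the protein reported
arm-exclusively) unless both arm means exist and the −IR mean is positive;
PSI is undefined at zero pooled depth and such junctions are skipped with a
warning; all identifiers are compared case-sensitively after whitespace
stripping; result tables are written with 10-significant-digit floats and a
config-hash comment line so reruns are byte-identical and traceable.
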