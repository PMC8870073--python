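# Methods

## Problem setting

A matched design: for each patient, DNA from a tumor fine-needle biopsy,
from plasma extracellular vesicles (evDNA) and from plasma cell-free DNA
(cfDNA) is panel-sequenced and annotated with a VEP-style effect predictor.
The tumor sample is treated as the reference; the question is how much of
its variant profile each liquid-biopsy analyte — or their combination —
recovers, and how stringency filtering changes that answer. Patients whose
tumor DNA fails sequencing QC contribute no reference and are excluded from
all comparative statistics (reported, never scored).

## Variant identity and deduplication

Annotators emit one row per variant–transcript combination. Identity is
collapsed with class-specific key tuples:

* SNV: (location `chrom:pos`, alt allele, gene symbol, protein position,
  amino-acid change). Chromosomes are case-folded with any `chr` prefix
  stripped; empty protein position/amino acid serialize as a fixed
  sentinel so two empties compare equal.
* indel: (location, alt allele, transcript feature). Because the feature
  is part of the key, one genomic indel may survive once per transcript;
  cross-analyte matching uses the same key, so both sides of every
  comparison stay consistent.

Among records sharing a key, the most damaging PolyPhen-2 annotation wins.
The ordering is category first (probably_damaging > possibly_damaging >
benign > no prediction), then numeric score, then first occurrence. The
category-then-score ordering is a design choice (raw-score-only ordering
would be an alternative); putting unpredicted records below `benign` means
an explicit benign prediction beats no information. Exact ties keep the
first occurrence, so runs are reproducible and survivors preserve input
order; deduplication is idempotent and order-insensitive at key level.

Coordinates are 1-based and fully closed (VCF/VEP convention). Indel
alleles are assumed pre-normalized by the annotator; no left-alignment is
performed.

## Filter cascade

All filters are pure predicates, so after the initial deduplication the
surviving set is independent of filter order (asserted by permutation
tests). Semantics and the reasoning behind the missing-value contracts:

* **Population AF ≤ 1%** (inclusive). `AF` is the population (gnomAD-style)
  frequency, not the sample variant-allele fraction: the filter's job is
  removing common polymorphisms. A *missing* AF passes — somatic variants
  are typically absent from population databases, and dropping them would
  delete the signal under study.
* **Impact**: keep MODERATE+HIGH for the standard cascade; HIGH alone as
  the high-stringency indel setting.
* **PP-2**: `damaging` keeps {possibly, probably} damaging (the union
  reading of "damaging"); `probably_damaging` keeps only the top class.
  Records without a prediction fail either setting — a prediction-based
  filter cannot pass unpredicted records. Both readings are exposed
  because the narrower one is a meaningful stringency step of its own.
* **Condel**: keep `deleterious` only; missing fails, same rationale.
* **Actionability**: gene-level matching against a COSMIC-style tier table
  (tier 1 = approved drugs … tier 4 = case studies); entries naming a
  specific amino-acid change annotate matching records (tier, drugs) but
  never gate, since the database is mainly gene-level. Tier 1+2 output is
  a subset of tier 1–4 output by construction.

The cascade runner always deduplicates first and logs the surviving count
after every step (the funnel report).

## Copy-number calling

Per panel target, expected depth arrives as data — a reference-cohort mean
supplied by the user or by the simulator — replacing any proprietary
reference set. With expected copies c (2 on autosomes, sex-dependent on
X/Y) the copy-corrected ratio is r = observed / (expected · c/2), and the
partition is exactly: r < 0.05 homozygous deletion, 0.05 ≤ r < 0.55
heterozygous deletion, r > 1.45 duplication, else no call (boundaries
0.05 / 0.55 / 1.45 behave strictly as written). Calls are per target;
when every known target of a gene carries the same class, the gene is
additionally labeled as wholly changed; genes are never merged into
segments, and no breakpoints are inferred. Sex is estimated from coverage:
male when the mean Y-target observed/expected ratio exceeds 0.3 (or, with
no Y targets, when the mean X ratio falls below 0.75). These thresholds
are plumbing, not biology — they sit far from both the diploid and haploid
expectations and are overridable parameters. A female-Y target (0 expected
copies) with observed reads is flagged as an anomaly and never called.
Out of scope by design: segmentation (CBS/HMM), GC normalization, B-allele
frequencies.

## Agreement statistics

* **Percent concordance** is recall-style: per patient,
  100·|analyte ∩ tumor| / |tumor| over identity keys after identical
  processing of both sides; the cohort value is the unweighted mean over
  patients with ≥1 tumor key. Patients with zero tumor keys after
  filtering are excluded and listed, not scored as 0 or 100. The
  patient-wise (macro) average is used rather than a pooled (micro)
  denominator: it reproduces the packaged worked example's mean and its
  "six of nine patients" structure, which a pooled denominator does not.
* **Bland–Altman** on per-patient (analyte, tumor) count pairs:
  differences analyte − tumor (under-detection ⇒ negative bias), sample
  (n−1) SD, limits of agreement bias ± 1.96·SD, outside-pairs counted
  strictly. Fewer than 3 pairs is an error (SD unstable).
* **Coincidence matrix**: rows are the distinct tumor variant keys pooled
  over all patients (the reported n), columns patient × {ev, cf, ev∪cf}
  detection flags. The combined analyte is the union of the ev and cf key
  sets, so per patient and in the mean it dominates either single
  analyte. This recall-maximizing union is a documented surrogate for
  alteration-plot tooling whose internal "maximal overlap" objective is
  not public.

## Composition and fragmentomics

Consequence percentages are per term *occurrence* (a multi-term record
contributes each term once), so shares sum to 100 while co-annotations
such as missense + NMD-transcript can both be large. Biotypes are one per
record. Fragment traces are integrated trapezoidally with linear
interpolation at window edges; short = 100–250 bp, long = 250–5500 bp,
total = 100–5500 bp, so short% + long% = 100. Instrument marker peaks
outside 100–5500 bp are excluded from the total. No peak calling or
molarity conversion.

## Synthetic cohort generator

The generator produces the statistical structure the analysis assumes —
not reads, not real annotations. Per patient, a Poisson number of tumor
variants; each is independently re-detected in ev and cf with the
configured sensitivities (an optional parameter couples the two detection
events through a shared uniform); each analyte adds Poisson-distributed
private variants. Annotation layers are coupled the way annotator output
is: moderate variants are missense in mostly protein-coding transcripts
(and carry PP-2/Condel predictions), modifier variants are
intronic/non-coding noise, a configurable fraction are common
polymorphisms (AF > 1%), and a fraction of SNVs receive a second, less
damaging transcript row to exercise deduplication. All randomness flows
from a single seed; a truth record stores every planted fact.

Defaults encode the emulated study conditions: 9 patients (the size of the
comparative cohort), ev/cf sensitivities 0.69/0.67 (the observed
single-analyte coincidence level), common-AF fraction 0.4 (the observed
unfiltered→AF-filtered reduction), indel fraction 0.28 (the observed
indel/SNV ratio), ev-like/cf-like long-fragment masses 0.55/0.32 (the
observed long-fraction percentages), depth noise CV 5%. Tumor variant
count per patient defaults to 20 — a deliberate desk-scale stand-in for
the tens of thousands of raw calls per real sample; concordance statistics
are scale-free in this count, so conclusions about the statistics carry
over, but absolute variant-count comparisons do not.

What passing simulator-based tests shows: the statistics recover planted
detection sensitivities and copy numbers under the stated noise. What it
does not show: robustness to real-data pathologies the generator omits —
sequencing artifacts, annotation disagreement between transcripts beyond
the modeled duplicate rows, correlated dropout between analytes (default
is independence, which makes the combined-analyte advantage maximal),
panel-specific target effects, GC bias in coverage.

## Numerical and interface choices

* Missing values in tables are `-` (annotator dialect); missing AF/PP-2/
  Condel parse as missing, never zero. A bare PolyPhen category without a
  score is anchored at the category's canonical score midpoint.
* The reader either raises on the first bad row (with its line number) or,
  given an error sink, collects row errors so records + errors always
  equals the data-row count — rows are never silently dropped.
* Writers are deterministic (fixed column order, `\n` newlines,
  percentages at two decimals in reports); write→read round-trips all
  fields exactly, with the reference allele carried in an extra
  `REF_ALLELE` column since the tabular annotation dialect does not
  include it. Tables lacking that column are still accepted: the variant
  class is then inferred from the alt allele with `N` placeholders for
  the reference.
* The packaged worked-example fixture encodes multi-variant annotation
  cells as separate variants (the cohort mean is robust to either
  encoding at the 0.1 percentage-point level) and follows the table, not
  the accompanying text, where the two disagree on one ATM label (L89F).
  Fixture variants receive deterministic synthetic locations so they flow
  through the same key/dedup/concordance code paths as real tables.

## Known limitations

* CNV concordance and the per-target partition depend entirely on the
  supplied expected-depth table; with a poorly matched reference cohort
  the thresholds misfire, and no within-run renormalization is attempted.
* Gene-level actionability matching cannot distinguish activating from
  inactivating variants in the same gene.
* Indel keys are transcript-scoped; comparing datasets annotated against
  different transcript sets will under-match indels.
* The cohort statistics are designed for small matched cohorts (the
  worked example has nine evaluable patients); Bland–Altman limits at
  such n are wide, and no significance testing between analytes is
  provided (out of scope).
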