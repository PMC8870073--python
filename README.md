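# lbconcord

Concordance analysis of DNA variants between tumor biopsies and liquid-biopsy
analytes — circulating cell-free DNA (cfDNA) and DNA carried by extracellular
vesicles (evDNA) — from targeted panel sequencing.

## Who this is for

Groups comparing matched tumor / evDNA / cfDNA panel-sequencing results face
the same chain of questions: after annotating calls (VEP-style), how do you
collapse redundant per-transcript rows into variants, filter down to the
tumor-relevant subset, and quantify how faithfully each liquid-biopsy analyte
reproduces the tumor's variant profile? `lbconcord` implements that chain as
a tested library plus a small CLI, together with a synthetic cohort generator
so every stage can be exercised without patient data.

## What it computes

* **Deduplication.** Variant identity for SNVs is the tuple
  (location `chrom:pos`, alt allele, gene symbol, protein position,
  amino-acid change); for indels it is (location, alt allele, transcript
  feature). Among duplicates, the record with the most damaging PolyPhen-2
  annotation survives (probably > possibly damaging > benign > unpredicted,
  ties by higher score, then first occurrence).
* **Stringency cascade.** Composable pure filters: population allele
  frequency AF ≤ 1% (missing AF passes — somatic variants are absent from
  population databases), impact ∈ {MODERATE, HIGH} (or HIGH only),
  PP-2 damaging / probably-damaging, Condel deleterious, COSMIC-style
  actionability tiers 1–4 and 1+2 (gene-level matching).
* **CNV calling.** Per panel target, with coverage ratio
  r = observed / (expected × copies/2): r < 0.05 homozygous deletion,
  r < 0.55 heterozygous deletion, r > 1.45 duplication, otherwise no call;
  sex estimated from X/Y coverage to set expected copies; whole-gene label
  when all targets of a gene agree.
* **Agreement statistics.** Per-patient percent concordance
  100·|analyte ∩ tumor| / |tumor| (recall of tumor variants), averaged
  unweighted over patients; Bland–Altman bias and limits of agreement
  (bias ± 1.96·SD of analyte − tumor count differences); a pooled
  alteration/coincidence matrix across patients with the combined ev∪cf
  analyte, which dominates either single analyte by construction.
* **Composition & fragmentomics.** Consequence-term and biotype percentage
  breakdowns; electropherogram AUC over the short (100–250 bp) and long
  (250–5500 bp) fragment windows as percentages of total DNA content.

## Worked example

The package ships the per-patient detection table of tier 1+2 actionable
SNVs (filtered at AF ≤ 1%, moderate/high impact) for a nine-patient
matched tumor/ev/cf cohort, together with severity labels and the tumor
sequencing-quality table. Running

```bash
lbconcord table4
```

prints

```
evDNA mean concordance: 42.76%
cfDNA mean concordance: 42.76%
ev+cf mean concordance: 42.76%
patients with >=1 matching tumor variant: ev 6/9, cf 6/9
analyte-private variants: ev 5 (patients 10,3,4,9), cf 3 (patients 6)
tumor sequencing quality means: coverage 955.8, sequenced reads 63.1%
```

Reading: averaged per patient, each liquid-biopsy analyte recovered ≈43% of
the tumor's tier 1+2 actionable variants, with at least one recovered
variant in six of the nine evaluable patients; evDNA additionally reported
five variants absent from the matched tumor (a BRAF L319I recurring in four
patients plus one RAD51B T107K) and cfDNA three, all in one patient —
candidate signals of tumor heterogeneity not captured by the localized
biopsy. The quality means are the column averages of the packaged
sequencing-metrics table.

A full synthetic run:

```bash
lbconcord simulate --seed 7 --out demo/cohort
lbconcord run --cohort-dir demo/cohort --out demo/report
lbconcord cnv  --coverage demo/cohort/coverage_tumor.tsv --out demo/cnv.tsv
lbconcord frag --trace demo/cohort/trace_ev.csv \
               --trace demo/cohort/trace_cf.csv --out demo/frag.tsv
```

writes per-patient concordance, Bland–Altman, coincidence, composition and
private-variant TSVs; re-running on identical inputs reproduces the reports
byte for byte.

## Layout

| module | contents |
| --- | --- |
| `lbconcord.data_model` | domain types, validation, TSV/CSV readers and writers |
| `lbconcord.dedup` | identity keys and duplicate removal |
| `lbconcord.filters` | stringency filters and the cascade runner |
| `lbconcord.cnv` | coverage-ratio CNV calling, sex estimation, gene roll-up |
| `lbconcord.concordance` | percent agreement, Bland–Altman, coincidence matrix |
| `lbconcord.composition` | consequence/biotype percentage breakdowns |
| `lbconcord.fragmentomics` | fragment-size AUC windows |
| `lbconcord.actionability` | tier stratification, severity cross-reference, packaged fixtures |
| `lbconcord.simulate` | synthetic matched-cohort generator |
| `lbconcord.cli` | `lbconcord simulate / run / cnv / frag / table4` |

See `docs/methods.md` for the model assumptions, parameter defaults and
known limitations.
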