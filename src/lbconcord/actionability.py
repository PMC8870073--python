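"""Actionable-variant stratification and the tier 1+2 worked example.

Variants that survive the stringency cascade are stratified by COSMIC-style
actionability tier (tier 1 = approved marketed drugs ... tier 4 = case
studies), cross-referenced against static ClinVar/Varsome/OncoKB-style
severity tables, and reduced to clinically interesting gene subsets
(e.g. BRCA1/BRCA2).

The module also ships, as a packaged fixture, the published per-patient
detection table of tier 1+2 actionable SNVs in filtered tumor/ev/cf
analytes of a nine-patient pancreatic-cancer cohort (plus severity labels
and the tumor sequencing quality table), so the per-patient recall,
private-variant and quality summaries are reproducible offline.  In the
fixture, multi-variant annotation cells are encoded as separate variants
and the ambiguous ATM L98F/L89F label follows the table (L89F).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .data_model import (ActionabilityEntry, Analyte, AnnotatedVariant,
                         Impact, PatientCohort, SeverityXref)
from .concordance import (COMBINED, ConcordanceResult, analyte_private_variants,
                          percent_concordance)
from .dedup import VariantKey, make_key

_AA_RE = re.compile(r"^([A-Z\*])(\d+)([A-Z\*])$")


# ---------------------------------------------------------------------------
# Tier stratification
# ---------------------------------------------------------------------------

def stratify_tiers(records: Sequence[AnnotatedVariant],
                   db: Sequence[ActionabilityEntry],
                   ) -> dict[str, list[AnnotatedVariant]]:
    """Split cascade-filtered records into tier 1–4 and tier 1+2 groups.

    Matching is gene-level; the tier 1+2 group is a subset of the tier 1–4
    group by construction.
    """
    from .filters import filter_actionable
    if not db:
        return {"tier_1_4": [], "tier_1_2": []}
    return {
        "tier_1_4": filter_actionable(list(records), db, tiers={1, 2, 3, 4}),
        "tier_1_2": filter_actionable(list(records), db, tiers={1, 2}),
    }


def per_patient_counts(records: Iterable[AnnotatedVariant]) -> dict[str, int]:
    counts: dict[str, int] = {}
    for r in records:
        counts[r.patient_id] = counts.get(r.patient_id, 0) + 1
    return counts


# ---------------------------------------------------------------------------
# Severity cross-reference
# ---------------------------------------------------------------------------

def variant_label(record: AnnotatedVariant) -> str:
    """``GENE AAchange`` label, e.g. ``PTEN Y155C``."""
    if record.amino_acid_change and record.protein_position is not None:
        ref, _, alt = record.amino_acid_change.partition("/")
        return f"{record.gene_symbol} {ref}{record.protein_position}{alt or ref}"
    return f"{record.gene_symbol} {record.location}"


def xref_severity(records: Sequence[AnnotatedVariant],
                  xref: Sequence[SeverityXref]) -> list[AnnotatedVariant]:
    """Attach ClinVar/Varsome/OncoKB labels; unmatched records get "/".

    The record set is never changed — only annotations are added.
    """
    table = {x.variant_label: x for x in xref}
    for r in records:
        entry = table.get(variant_label(r))
        r.annotations["clinvar"] = entry.clinvar_label if entry else "/"
        r.annotations["varsome"] = entry.varsome_label if entry else "/"
        r.annotations["oncokb"] = entry.oncokb_label if entry else "/"
        r.annotations["treatment"] = entry.treatment_note if entry else "/"
    return list(records)


def gene_subset(records: Iterable[AnnotatedVariant],
                genes: Iterable[str]) -> list[AnnotatedVariant]:
    """Exact gene-symbol subset (e.g. {"BRCA1", "BRCA2"})."""
    genes = set(genes)
    return [r for r in records if r.gene_symbol in genes]


# ---------------------------------------------------------------------------
# Packaged fixtures (published worked example)
# ---------------------------------------------------------------------------

def _data_path(name: str):
    return resources.files("lbconcord").joinpath("data", name)


def load_table4_detections() -> pd.DataFrame:
    """Per-patient tier 1+2 actionable-variant detection flags."""
    with resources.as_file(_data_path("table4_detections.tsv")) as p:
        return pd.read_csv(p, sep="\t", dtype={"patient_id": str})


def load_table4_xref() -> list[SeverityXref]:
    from .data_model import read_severity_xref
    with resources.as_file(_data_path("table4_xref.tsv")) as p:
        return read_severity_xref(p)


def load_table2() -> pd.DataFrame:
    """Tumor-DNA sequencing quality metrics (one QC-failed patient absent)."""
    with resources.as_file(_data_path("table2_tumor_quality.tsv")) as p:
        return pd.read_csv(p, sep="\t", dtype={"patient_id": str})


def _fixture_record(patient_id: str, analyte: Analyte, gene: str,
                    aa_change: str, pos: int) -> AnnotatedVariant:
    m = _AA_RE.match(aa_change)
    if not m:
        raise ValueError(f"malformed amino-acid label {aa_change!r}")
    ref_aa, protein_position, alt_aa = m.group(1), int(m.group(2)), m.group(3)
    return AnnotatedVariant(
        patient_id=patient_id, analyte=analyte, chrom="1", pos=pos,
        ref_allele="N", alt_allele="A", gene_symbol=gene,
        feature_id=f"ENST_{gene}", consequence_terms=("missense_variant",),
        impact=Impact.MODERATE, biotype="protein_coding",
        protein_position=protein_position,
        amino_acid_change=f"{ref_aa}/{alt_aa}")


def table4_cohort(detections: pd.DataFrame | None = None) -> PatientCohort:
    """Build a cohort of already-filtered variant records from the fixture.

    Each distinct (gene, amino-acid change) gets a deterministic synthetic
    genomic location, so the identity keys, the concordance statistics and
    the private-variant listings run through the same code paths as any
    annotated table.  A patient without tumor rows (no tumor DNA of
    sequencing quality) ends up without a tumor slot and is excluded from
    comparative statistics automatically.
    """
    df = load_table4_detections() if detections is None else detections
    labels = sorted({(row.gene, row.aa_change)
                     for row in df.itertuples(index=False)})
    pos_of = {label: 1000 + i for i, label in enumerate(labels)}
    cohort = PatientCohort()
    flag_of = {Analyte.TUMOR: "in_tumor", Analyte.EV: "in_ev",
               Analyte.CF: "in_cf"}
    for pid, sub in df.groupby("patient_id", sort=False):
        for analyte, flag in flag_of.items():
            records = [
                _fixture_record(pid, analyte, row.gene, row.aa_change,
                                pos_of[(row.gene, row.aa_change)])
                for row in sub.itertuples(index=False)
                if getattr(row, flag) == 1]
            if records:
                cohort.add_variants(pid, analyte, records)
        if not sub["in_tumor"].any():
            cohort.excluded_patients.append(pid)
    return cohort


@dataclass
class Table4Summary:
    """Tier 1+2 actionable-variant agreement of the packaged cohort."""

    ev: ConcordanceResult
    cf: ConcordanceResult
    combined: ConcordanceResult
    ev_patients_with_match: int
    cf_patients_with_match: int
    ev_private: dict[str, list[str]] = field(default_factory=dict)
    cf_private: dict[str, list[str]] = field(default_factory=dict)

    @property
    def n_ev_private(self) -> int:
        return sum(len(v) for v in self.ev_private.values())

    @property
    def n_cf_private(self) -> int:
        return sum(len(v) for v in self.cf_private.values())


def _label_map(cohort: PatientCohort) -> Mapping[VariantKey, str]:
    out: dict[VariantKey, str] = {}
    for pid in cohort.patients:
        for analyte in (Analyte.TUMOR, Analyte.EV, Analyte.CF):
            for r in cohort.get(pid, analyte):
                out[make_key(r)] = variant_label(r)
    return out


def table4_summary(cohort: PatientCohort | None = None) -> Table4Summary:
    """Recall, patients-with-match and private-variant summary.

    Uses per-patient percent concordance (tumor-count denominator,
    unweighted mean over the nine comparative patients) and the
    analyte-private set differences.
    """
    if cohort is None:
        cohort = table4_cohort()
    labels = _label_map(cohort)
    ev = percent_concordance(cohort, Analyte.EV.value)
    cf = percent_concordance(cohort, Analyte.CF.value)
    combined = percent_concordance(cohort, COMBINED)
    ev_private = {pid: [labels[k] for k in keys] for pid, keys in
                  analyte_private_variants(cohort, Analyte.EV.value).items()}
    cf_private = {pid: [labels[k] for k in keys] for pid, keys in
                  analyte_private_variants(cohort, Analyte.CF.value).items()}
    return Table4Summary(
        ev=ev, cf=cf, combined=combined,
        ev_patients_with_match=sum(1 for p in ev.per_patient if p.n_matched > 0),
        cf_patients_with_match=sum(1 for p in cf.per_patient if p.n_matched > 0),
        ev_private=ev_private, cf_private=cf_private)


def table2_means() -> dict[str, float]:
    """Column means of the tumor sequencing-quality fixture."""
    df = load_table2()
    return {
        "mapped_reads_million": float(df["mapped_reads_million"].mean()),
        "sequenced_reads_pct": float(df["sequenced_reads_pct"].mean()),
        "median_insert_size": float(df["median_insert_size"].mean()),
        "average_coverage": float(df["average_coverage"].mean()),
    }
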