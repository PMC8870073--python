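"""Domain types and tabular I/O for matched tumor / evDNA / cfDNA cohorts.

The in-memory model mirrors one row of VEP-style tabular annotation output
per variant call, carried per patient and per analyte (tumor biopsy DNA,
extracellular-vesicle DNA, circulating cell-free DNA).  Readers accept the
tab-separated dialect produced by annotators (``Location``, ``Allele``,
``SYMBOL``, ``Feature``, ``Consequence``, ``IMPACT``, ``BIOTYPE``,
``Protein_position``, ``Amino_acids``, ``AF``, ``PolyPhen``, ``Condel``);
writers round-trip every field, including missing values.
"""

from __future__ import annotations

import enum
import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("lbconcord")

#: Missing-value token used throughout the VEP tabular dialect.
MISSING = "-"

#: Separator for multi-valued consequence cells.
CONSEQUENCE_SEP = "&"

#: Number of decimals used when rendering percentages in reports.
PERCENT_DECIMALS = 2


class SchemaError(ValueError):
    """A required column is absent from an input table."""


class RowError(ValueError):
    """A single data row could not be parsed.

    Attributes
    ----------
    line_number : int
        1-based line number in the source file (header included).
    """

    def __init__(self, message: str, line_number: int):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


class ContractError(ValueError):
    """An operation was called with arguments violating its contract."""


# ---------------------------------------------------------------------------
# Enumerations
# ---------------------------------------------------------------------------

class Analyte(str, enum.Enum):
    TUMOR = "tumor"
    EV = "ev"
    CF = "cf"


class Impact(str, enum.Enum):
    HIGH = "HIGH"
    MODERATE = "MODERATE"
    LOW = "LOW"
    MODIFIER = "MODIFIER"


class PP2Category(str, enum.Enum):
    """PolyPhen-2 qualitative prediction for an amino-acid substitution."""

    BENIGN = "benign"
    POSSIBLY_DAMAGING = "possibly_damaging"
    PROBABLY_DAMAGING = "probably_damaging"
    UNKNOWN = "unknown"


class CondelLabel(str, enum.Enum):
    DELETERIOUS = "deleterious"
    NEUTRAL = "neutral"
    MISSING = "missing"


class VariantClass(str, enum.Enum):
    SNV = "snv"
    INDEL = "indel"


class Sex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"


class CnvClass(str, enum.Enum):
    DUPLICATION = "duplication"
    HETEROZYGOUS_DELETION = "heterozygous_deletion"
    HOMOZYGOUS_DELETION = "homozygous_deletion"


def normalize_chrom(chrom: str) -> str:
    """Case-fold a chromosome name and strip any ``chr`` prefix."""
    c = chrom.strip().lower()
    if c.startswith("chr"):
        c = c[3:]
    return c


def _is_base_allele(a: str) -> bool:
    return len(a) == 1 and a != MISSING


# ---------------------------------------------------------------------------
# Core variant record
# ---------------------------------------------------------------------------

@dataclass
class AnnotatedVariant:
    """One annotated SNV/indel call in one analyte of one patient.

    ``population_af`` is the population (gnomAD-style) allele frequency
    annotated by the effect predictor — not the sample variant-allele
    fraction.  ``None`` means the variant is absent from the population
    databases, which is the typical situation for somatic variants.
    """

    patient_id: str
    analyte: Analyte
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    gene_symbol: str
    feature_id: str
    consequence_terms: tuple[str, ...]
    impact: Impact
    biotype: str
    protein_position: int | None = None
    amino_acid_change: str = ""
    population_af: float | None = None
    pp2_category: PP2Category = PP2Category.UNKNOWN
    pp2_score: float | None = None
    condel_label: CondelLabel = CondelLabel.MISSING
    variant_class: VariantClass = VariantClass.SNV
    # free-form annotations attached by downstream steps (tiers, drugs,
    # severity labels); never part of variant identity
    annotations: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        self.analyte = Analyte(self.analyte)
        self.impact = Impact(self.impact)
        self.pp2_category = PP2Category(self.pp2_category)
        self.condel_label = CondelLabel(self.condel_label)
        self.variant_class = VariantClass(self.variant_class)
        self.chrom = normalize_chrom(self.chrom)
        self.consequence_terms = tuple(self.consequence_terms)
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not self.consequence_terms:
            raise ValueError("consequence_terms must be non-empty")
        for name in ("population_af", "pp2_score"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if (self.pp2_category is PP2Category.UNKNOWN) != (self.pp2_score is None):
            raise ValueError(
                "pp2_category must be 'unknown' exactly when pp2_score is missing"
            )
        is_snv = _is_base_allele(self.ref_allele) and _is_base_allele(self.alt_allele)
        if (self.variant_class is VariantClass.SNV) != is_snv:
            raise ValueError(
                f"variant_class {self.variant_class.value} inconsistent with alleles "
                f"{self.ref_allele!r}>{self.alt_allele!r}"
            )

    @property
    def location(self) -> str:
        """``chrom:pos`` text used in deduplication keys."""
        return f"{self.chrom}:{self.pos}"


# ---------------------------------------------------------------------------
# Coverage / CNV types
# ---------------------------------------------------------------------------

@dataclass
class TargetCoverage:
    """Observed vs reference-expected read depth for one panel target.

    The expected depth plays the role of the sequencing vendor's reference
    sample cohort; it is supplied explicitly as data (by the user or by the
    simulator).  ``expected_copies`` is 2 on autosomes and sex-dependent on
    X/Y (set by :func:`lbconcord.cnv.estimate_sex`).
    """

    patient_id: str
    analyte: Analyte
    chrom: str
    gene_symbol: str
    target_id: str
    observed_depth: float
    expected_depth: float
    expected_copies: int = 2

    def __post_init__(self) -> None:
        self.analyte = Analyte(self.analyte)
        self.chrom = normalize_chrom(self.chrom)
        if self.observed_depth < 0:
            raise ValueError("observed_depth must be >= 0")
        if self.expected_depth <= 0:
            raise ValueError("expected_depth must be > 0")
        if self.expected_copies not in (0, 1, 2):
            raise ValueError("expected_copies must be in {0, 1, 2}")


@dataclass
class CnvCall:
    """A duplication / deletion call for one target (or whole gene)."""

    patient_id: str
    analyte: Analyte
    gene_symbol: str
    target_id: str
    call: CnvClass
    coverage_ratio: float
    whole_gene: bool = False

    def __post_init__(self) -> None:
        self.analyte = Analyte(self.analyte)
        self.call = CnvClass(self.call)
        if self.coverage_ratio < 0:
            raise ValueError("coverage_ratio must be >= 0")


# ---------------------------------------------------------------------------
# Actionability / severity cross-reference
# ---------------------------------------------------------------------------

@dataclass
class ActionabilityEntry:
    """One gene (or gene+variant) row of a COSMIC-style actionability table."""

    gene_symbol: str
    tier: int
    specific_variant: str = ""
    drugs: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.tier not in (1, 2, 3, 4):
            raise ValueError(f"tier must be 1-4, got {self.tier}")
        self.drugs = tuple(self.drugs)


@dataclass
class SeverityXref:
    """Static ClinVar/Varsome/OncoKB-style labels for one specific variant."""

    gene_symbol: str
    variant_label: str
    clinvar_label: str = "/"
    varsome_label: str = "/"
    oncokb_label: str = "/"
    treatment_note: str = "/"


# ---------------------------------------------------------------------------
# Fragment-size trace
# ---------------------------------------------------------------------------

@dataclass
class FragmentTrace:
    """Electropherogram curve: signal as a function of fragment size (bp)."""

    sizes_bp: np.ndarray
    signal: np.ndarray

    def __post_init__(self) -> None:
        self.sizes_bp = np.asarray(self.sizes_bp, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.sizes_bp.ndim != 1 or self.sizes_bp.shape != self.signal.shape:
            raise ValueError("sizes and signal must be equal-length 1-D arrays")
        if self.sizes_bp.size < 2:
            raise ValueError("a trace needs at least 2 points")
        if np.any(self.sizes_bp <= 0):
            raise ValueError("fragment sizes must be > 0")
        if np.any(np.diff(self.sizes_bp) <= 0):
            raise ValueError("fragment sizes must be strictly increasing")
        if np.any(self.signal < 0):
            raise ValueError("signal must be >= 0")

    @property
    def points(self) -> list[tuple[float, float]]:
        return list(zip(self.sizes_bp.tolist(), self.signal.tolist()))


# ---------------------------------------------------------------------------
# Cohort container
# ---------------------------------------------------------------------------

@dataclass
class CohortIssue:
    patient_id: str
    kind: str
    message: str


@dataclass
class PatientCohort:
    """Per-patient, per-analyte variant lists plus optional coverage/traces."""

    variants: dict = field(default_factory=dict)  # pid -> {Analyte: [records]}
    coverage: dict = field(default_factory=dict)  # (pid, Analyte) -> [TargetCoverage]
    traces: dict = field(default_factory=dict)  # (pid, Analyte) -> FragmentTrace
    excluded_patients: list = field(default_factory=list)
    duplicate_slots: list = field(default_factory=list)

    def add_variants(self, patient_id: str, analyte: Analyte | str,
                     records: Sequence[AnnotatedVariant]) -> None:
        analyte = Analyte(analyte)
        for r in records:
            if r.patient_id != patient_id or r.analyte is not analyte:
                raise ContractError(
                    f"record for {r.patient_id}/{r.analyte.value} loaded into "
                    f"slot {patient_id}/{analyte.value}"
                )
        slots = self.variants.setdefault(patient_id, {})
        if analyte in slots:
            self.duplicate_slots.append((patient_id, analyte))
            slots[analyte] = list(slots[analyte]) + list(records)
        else:
            slots[analyte] = list(records)

    def get(self, patient_id: str, analyte: Analyte | str) -> list[AnnotatedVariant]:
        return self.variants.get(patient_id, {}).get(Analyte(analyte), [])

    @property
    def patients(self) -> list[str]:
        return sorted(self.variants)

    def comparative_patients(self) -> list[str]:
        """Patients eligible for tumor-vs-analyte comparison.

        A patient without a tumor analyte (no tumor DNA of sequencing
        quality) is excluded, mirroring how such patients are dropped from
        comparative analyses.
        """
        out = []
        for pid in self.patients:
            if pid in self.excluded_patients:
                continue
            if self.variants[pid].get(Analyte.TUMOR):
                out.append(pid)
        return out


def validate_cohort(cohort: PatientCohort) -> list[CohortIssue]:
    """Report (never raise) structural problems in a loaded cohort."""
    issues: list[CohortIssue] = []
    for pid, analyte in cohort.duplicate_slots:
        issues.append(CohortIssue(
            pid, "duplicate_slot",
            f"patient {pid} analyte {analyte.value} loaded more than once"))
    for pid in cohort.patients:
        slots = cohort.variants[pid]
        if not slots.get(Analyte.TUMOR):
            issues.append(CohortIssue(
                pid, "no_tumor",
                f"patient {pid} has no tumor variants; "
                "exclude from comparative analysis"))
        for analyte, records in slots.items():
            if len(records) == 0:
                issues.append(CohortIssue(
                    pid, "empty_slot",
                    f"patient {pid} analyte {analyte.value} has an empty "
                    "variant list"))
    return issues


# ---------------------------------------------------------------------------
# Variant-table reader / writer (VEP tabular dialect)
# ---------------------------------------------------------------------------

REQUIRED_COLUMNS = (
    "Location", "Allele", "SYMBOL", "Feature", "Consequence", "IMPACT",
    "BIOTYPE", "Protein_position", "Amino_acids", "AF", "PolyPhen", "Condel",
)

#: Optional extra column naming the reference allele; when absent the
#: reference allele is inferred (``N`` placeholders) from the alt allele.
REF_COLUMN = "REF_ALLELE"

_POLYPHEN_RE = re.compile(r"^\s*([a-z_]+)\s*(?:\(\s*([0-9.eE+-]+)\s*\))?\s*$")


def _cell(value) -> str:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return MISSING
    s = str(value).strip()
    return s if s else MISSING


def parse_location(text: str) -> tuple[str, int]:
    """Parse ``chrom:pos`` or ``chrom:start-end`` (start taken as pos)."""
    chrom, _, rest = text.partition(":")
    if not rest:
        raise ValueError(f"malformed location {text!r}")
    start = rest.split("-", 1)[0]
    return normalize_chrom(chrom), int(start)


def parse_polyphen(text: str) -> tuple[PP2Category, float | None]:
    """Parse ``probably_damaging(0.98)`` / bare category / missing cells."""
    cell = _cell(text)
    if cell == MISSING or cell.lower() == "unknown":
        return PP2Category.UNKNOWN, None
    m = _POLYPHEN_RE.match(cell)
    if not m:
        raise ValueError(f"malformed PolyPhen cell {cell!r}")
    category = PP2Category(m.group(1))
    score = float(m.group(2)) if m.group(2) is not None else None
    if score is None:
        # A bare category without a score still carries a prediction; anchor
        # the score at the category's canonical midpoint so the
        # category-iff-score invariant holds.
        score = {PP2Category.BENIGN: 0.0,
                 PP2Category.POSSIBLY_DAMAGING: 0.7,
                 PP2Category.PROBABLY_DAMAGING: 1.0}[category]
    return category, score


def parse_condel(text: str) -> CondelLabel:
    cell = _cell(text)
    if cell == MISSING:
        return CondelLabel.MISSING
    label = _POLYPHEN_RE.match(cell)
    if not label:
        raise ValueError(f"malformed Condel cell {cell!r}")
    return CondelLabel(label.group(1))


def _infer_alleles(allele: str, ref: str | None) -> tuple[str, str, VariantClass]:
    alt = allele
    if ref is not None and ref != "":
        pass
    elif alt == MISSING:          # deletion: removed bases unknown
        ref = "NN"
    elif len(alt) > 1:            # insertion relative to the reference
        ref = MISSING
    else:
        ref = "N"
    is_snv = _is_base_allele(ref) and _is_base_allele(alt)
    return ref, alt, VariantClass.SNV if is_snv else VariantClass.INDEL


def read_variant_table(path, analyte: Analyte | str, patient_id: str,
                       errors: list | None = None) -> list[AnnotatedVariant]:
    """Read one per-analyte annotated variant table.

    Missing AF / PolyPhen-2 / Condel cells parse as *missing*, never as
    zero.  With ``errors=None`` the first unparseable row raises
    :class:`RowError`; passing a list collects row-level errors instead so
    that ``len(records) + len(errors)`` always equals the data-row count.
    """
    analyte = Analyte(analyte)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"required column {col!r} missing from {path}")
    has_ref = REF_COLUMN in df.columns
    records: list[AnnotatedVariant] = []
    for i, row in enumerate(df.itertuples(index=False)):
        line_number = i + 2  # 1-based, after the header line
        row = dict(zip(df.columns, row))
        try:
            chrom, pos = parse_location(row["Location"])
            af_cell = _cell(row["AF"])
            try:
                af = None if af_cell == MISSING else float(af_cell)
            except ValueError as exc:
                raise ValueError(f"unparseable AF {af_cell!r}") from exc
            pp2_category, pp2_score = parse_polyphen(row["PolyPhen"])
            ref, alt, vclass = _infer_alleles(
                _cell(row["Allele"]), row.get(REF_COLUMN) if has_ref else None)
            pp_cell = _cell(row["Protein_position"])
            protein_position = (None if pp_cell == MISSING
                                else int(pp_cell.split("-", 1)[0]))
            aa_cell = _cell(row["Amino_acids"])
            records.append(AnnotatedVariant(
                patient_id=patient_id,
                analyte=analyte,
                chrom=chrom,
                pos=pos,
                ref_allele=ref,
                alt_allele=alt,
                gene_symbol=_cell(row["SYMBOL"]),
                feature_id=_cell(row["Feature"]),
                consequence_terms=tuple(
                    t for t in _cell(row["Consequence"]).split(CONSEQUENCE_SEP) if t),
                impact=Impact(_cell(row["IMPACT"])),
                biotype=_cell(row["BIOTYPE"]),
                protein_position=protein_position,
                amino_acid_change="" if aa_cell == MISSING else aa_cell,
                population_af=af,
                pp2_category=pp2_category,
                pp2_score=pp2_score,
                condel_label=parse_condel(row["Condel"]),
                variant_class=vclass,
            ))
        except (ValueError, KeyError) as exc:
            err = RowError(str(exc), line_number)
            if errors is None:
                raise err from exc
            errors.append(err)
    return records


def _format_float(v: float | None) -> str:
    return MISSING if v is None else repr(float(v))


def write_variant_table(records: Iterable[AnnotatedVariant], path) -> None:
    """Write records in the same dialect ``read_variant_table`` consumes.

    A round trip (write, read) reproduces every field exactly, missing
    values included; the reference allele travels in an extra
    ``REF_ALLELE`` column.
    """
    rows = []
    for r in records:
        if r.pp2_score is None:
            polyphen = MISSING
        else:
            polyphen = f"{r.pp2_category.value}({_format_float(r.pp2_score)})"
        rows.append({
            "Location": r.location,
            "Allele": r.alt_allele,
            REF_COLUMN: r.ref_allele,
            "SYMBOL": r.gene_symbol,
            "Feature": r.feature_id,
            "Consequence": CONSEQUENCE_SEP.join(r.consequence_terms),
            "IMPACT": r.impact.value,
            "BIOTYPE": r.biotype,
            "Protein_position": (MISSING if r.protein_position is None
                                 else str(r.protein_position)),
            "Amino_acids": r.amino_acid_change or MISSING,
            "AF": _format_float(r.population_af),
            "PolyPhen": polyphen,
            "Condel": (MISSING if r.condel_label is CondelLabel.MISSING
                       else r.condel_label.value),
        })
    columns = list(REQUIRED_COLUMNS[:2]) + [REF_COLUMN] + list(REQUIRED_COLUMNS[2:])
    pd.DataFrame(rows, columns=columns).to_csv(
        path, sep="\t", index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# Coverage / trace / lookup-table readers
# ---------------------------------------------------------------------------

def read_coverage_table(path, analyte: Analyte | str,
                        patient_id: str) -> list[TargetCoverage]:
    """Read a BED-like per-target coverage table.

    Columns: chrom, start, end, gene, target_id, observed_depth,
    expected_depth (tab-separated, with header).
    """
    analyte = Analyte(analyte)
    df = pd.read_csv(path, sep="\t")
    required = ("chrom", "gene", "target_id", "observed_depth", "expected_depth")
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"required column {col!r} missing from {path}")
    return [
        TargetCoverage(
            patient_id=patient_id, analyte=analyte,
            chrom=str(row.chrom), gene_symbol=str(row.gene),
            target_id=str(row.target_id),
            observed_depth=float(row.observed_depth),
            expected_depth=float(row.expected_depth),
        )
        for row in df.itertuples(index=False)
    ]


def write_coverage_table(coverage: Iterable[TargetCoverage], path) -> None:
    rows = [{
        "chrom": c.chrom, "start": 0, "end": 0, "gene": c.gene_symbol,
        "target_id": c.target_id, "observed_depth": c.observed_depth,
        "expected_depth": c.expected_depth,
    } for c in coverage]
    pd.DataFrame(rows, columns=["chrom", "start", "end", "gene", "target_id",
                                "observed_depth", "expected_depth"]).to_csv(
        path, sep="\t", index=False, lineterminator="\n")


def read_trace_csv(path) -> FragmentTrace:
    """Read a two-column (size_bp, signal) electropherogram CSV."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise SchemaError(f"trace CSV {path} needs 2 columns (size_bp, signal)")
    return FragmentTrace(df.iloc[:, 0].to_numpy(float),
                         df.iloc[:, 1].to_numpy(float))


def write_trace_csv(trace: FragmentTrace, path) -> None:
    pd.DataFrame({"size_bp": trace.sizes_bp, "signal": trace.signal}).to_csv(
        path, index=False, lineterminator="\n")


def read_actionability_table(path) -> list[ActionabilityEntry]:
    """Read a COSMIC-style actionability TSV: gene, tier[, variant, drugs]."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("gene", "tier"):
        if col not in df.columns:
            raise SchemaError(f"required column {col!r} missing from {path}")
    entries = []
    for row in df.itertuples(index=False):
        row = dict(zip(df.columns, row))
        drugs = tuple(d for d in _cell(row.get("drugs", "")).split(";")
                      if d and d != MISSING)
        entries.append(ActionabilityEntry(
            gene_symbol=row["gene"], tier=int(row["tier"]),
            specific_variant=_cell(row.get("variant", "")).replace(MISSING, ""),
            drugs=drugs))
    return entries


def read_severity_xref(path) -> list[SeverityXref]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("gene", "aa_change"):
        if col not in df.columns:
            raise SchemaError(f"required column {col!r} missing from {path}")
    return [SeverityXref(
        gene_symbol=row["gene"],
        variant_label=f"{row['gene']} {row['aa_change']}",
        clinvar_label=_cell(row.get("clinvar", "/")),
        varsome_label=_cell(row.get("varsome", "/")),
        oncokb_label=_cell(row.get("oncokb", "/")),
        treatment_note=_cell(row.get("treatment", "/")),
    ) for row in (dict(zip(df.columns, t)) for t in df.itertuples(index=False))]


# ---------------------------------------------------------------------------
# Generic report writer
# ---------------------------------------------------------------------------

def _as_dataframe(results) -> pd.DataFrame:
    if isinstance(results, pd.DataFrame):
        return results
    if isinstance(results, Mapping):
        return pd.DataFrame([results])
    rows = []
    for item in results:
        if isinstance(item, Mapping):
            rows.append(dict(item))
        else:  # dataclass-like
            rows.append({k: v for k, v in vars(item).items()
                         if not k.startswith("_")})
    return pd.DataFrame(rows)


def write_report(results, path, columns: Sequence[str] | None = None) -> None:
    """Write a result bundle as a deterministic TSV.

    Column order is fixed (given ``columns``, or first-seen order);
    percentage columns (name containing ``percent``/``pct``) are rendered
    with two decimals; writing the same bundle twice yields byte-identical
    files.
    """
    df = _as_dataframe(results)
    if columns is not None:
        df = df.reindex(columns=list(columns))
    df = df.copy()
    for col in df.columns:
        name = str(col).lower()
        if ("percent" in name or "pct" in name) and df[col].notna().any():
            df[col] = df[col].map(
                lambda v: "" if pd.isna(v) else f"{float(v):.{PERCENT_DECIMALS}f}")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")
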