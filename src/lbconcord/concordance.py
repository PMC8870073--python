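"""Cross-analyte agreement statistics.

The central question: of the variants detected in a patient's tumor DNA,
what fraction does a liquid-biopsy analyte (evDNA, cfDNA, or their union)
recover?  Concordance is recall-style — the denominator is the tumor
variant count — with per-patient fractions averaged unweighted over
patients that contribute at least one tumor variant.  Count-level
agreement between an analyte and the tumor is additionally summarized by
Bland–Altman bias and limits of agreement (bias ± 1.96·SD of the
analyte − tumor differences, so systematic under-detection shows up as a
negative bias).  The coincidence (alteration) matrix pools the distinct
tumor variant keys over all patients and flags, per patient and analyte,
which of them were recovered; the combined ev∪cf analyte uses the union
of both key sets and therefore can only do better than either alone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .data_model import Analyte, AnnotatedVariant, ContractError, PatientCohort, \
    VariantClass
from .dedup import KeyKind, VariantKey, deduplicate, key_set, make_key
from .filters import FilterStep, run_cascade

#: Label for the combined extracellular-vesicle + cell-free analyte.
COMBINED = "ev+cf"

#: Bland–Altman limits-of-agreement multiplier (± 1.96 standard deviations).
LOA_MULTIPLIER = 1.96


# ---------------------------------------------------------------------------
# Matching
# ---------------------------------------------------------------------------

def match_sets(tumor_keys: Iterable[VariantKey],
               analyte_keys: Iterable[VariantKey]) -> set[VariantKey]:
    """Tumor-side keys that are also present in the analyte key set."""
    tumor_keys = set(tumor_keys)
    analyte_keys = set(analyte_keys)
    kinds = {k.kind for k in tumor_keys} | {k.kind for k in analyte_keys}
    if len(kinds) > 1:
        raise ContractError(f"mixed key kinds in match: {sorted(k.value for k in kinds)}")
    return tumor_keys & analyte_keys


def _select_class(records: Sequence[AnnotatedVariant],
                  key_kind: KeyKind | str | None) -> list[AnnotatedVariant]:
    if key_kind is None:
        return list(records)
    key_kind = KeyKind(key_kind)
    wanted = (VariantClass.SNV if key_kind is KeyKind.SNV else VariantClass.INDEL)
    return [r for r in records if r.variant_class is wanted]


def _keys_for(records: Sequence[AnnotatedVariant],
              key_kind, steps: Sequence[FilterStep] | None) -> set[VariantKey]:
    records = _select_class(records, key_kind)
    if steps:
        records = run_cascade(records, steps).records
    else:
        records = deduplicate(records)
    return key_set(records)


def _label_keys(cohort: PatientCohort, pid: str, analyte_label: str,
                key_kind, steps: Sequence[FilterStep] | None) -> set[VariantKey]:
    """Key set for one analyte label; the combined label is the union of
    the ev and cf key sets (each deduplicated/filtered on its own)."""
    if analyte_label == COMBINED:
        return (_keys_for(cohort.get(pid, Analyte.EV), key_kind, steps)
                | _keys_for(cohort.get(pid, Analyte.CF), key_kind, steps))
    return _keys_for(cohort.get(pid, Analyte(analyte_label)), key_kind, steps)


# ---------------------------------------------------------------------------
# Percent concordance
# ---------------------------------------------------------------------------

@dataclass
class PatientConcordance:
    patient_id: str
    n_tumor: int
    n_matched: int
    percent: float


@dataclass
class ConcordanceResult:
    """Per-patient and mean percent agreement of one analyte with tumor."""

    analyte_label: str
    per_patient: list[PatientConcordance]
    mean_percent: float
    excluded: list[str] = field(default_factory=list)

    def as_rows(self) -> list[dict]:
        return [{"patient_id": p.patient_id, "analyte": self.analyte_label,
                 "n_tumor": p.n_tumor, "n_matched": p.n_matched,
                 "percent": p.percent} for p in self.per_patient]


def percent_concordance(cohort: PatientCohort, analyte_label: str,
                        key_kind: KeyKind | str | None = None,
                        steps: Sequence[FilterStep] | None = None,
                        ) -> ConcordanceResult:
    """Recall of tumor variant keys by an analyte, per patient and mean.

    ``analyte_label`` is ``"ev"``, ``"cf"`` or ``"ev+cf"`` (union of key
    sets).  ``key_kind`` restricts to SNVs or indels; ``steps`` is an
    optional filter cascade applied identically to both sides (plain
    deduplication otherwise).  Patients with zero tumor keys after
    filtering are excluded and listed — never scored as 0 or 100.
    """
    per_patient: list[PatientConcordance] = []
    excluded = [pid for pid in cohort.patients
                if pid not in cohort.comparative_patients()]
    for pid in cohort.comparative_patients():
        tumor_keys = _keys_for(cohort.get(pid, Analyte.TUMOR), key_kind, steps)
        if not tumor_keys:
            excluded.append(pid)
            continue
        analyte_keys = _label_keys(cohort, pid, analyte_label, key_kind, steps)
        # key identity includes the kind, so plain intersection equals
        # per-kind matching even when SNVs and indels are analyzed jointly
        matched = tumor_keys & analyte_keys
        per_patient.append(PatientConcordance(
            pid, len(tumor_keys), len(matched),
            100.0 * len(matched) / len(tumor_keys)))
    mean = (sum(p.percent for p in per_patient) / len(per_patient)
            if per_patient else float("nan"))
    return ConcordanceResult(analyte_label, per_patient, mean, excluded)


# ---------------------------------------------------------------------------
# Bland–Altman
# ---------------------------------------------------------------------------

@dataclass
class BlandAltmanResult:
    bias: float
    sd: float
    loa_low: float
    loa_high: float
    n_outside: int
    n: int


def bland_altman(pairs: Sequence[tuple[float, float]]) -> BlandAltmanResult:
    """Bland–Altman agreement of paired (analyte, tumor) counts.

    Differences are analyte − tumor, so systematic under-detection by the
    liquid-biopsy analyte appears as negative bias.  SD is the sample
    (n−1) standard deviation; limits of agreement are bias ± 1.96·SD;
    pairs strictly outside the limits are counted.
    """
    if len(pairs) < 3:
        raise ValueError("Bland–Altman needs at least 3 pairs (SD unstable)")
    diffs = [float(a) - float(t) for a, t in pairs]
    n = len(diffs)
    bias = sum(diffs) / n
    var = sum((d - bias) ** 2 for d in diffs) / (n - 1)
    sd = math.sqrt(var)
    lo, hi = bias - LOA_MULTIPLIER * sd, bias + LOA_MULTIPLIER * sd
    n_outside = sum(1 for d in diffs if d < lo or d > hi)
    return BlandAltmanResult(bias, sd, lo, hi, n_outside, n)


# ---------------------------------------------------------------------------
# Coincidence (alteration) matrix
# ---------------------------------------------------------------------------

@dataclass
class CoincidenceResult:
    """Alteration matrix plus per-analyte mean percent coincidence.

    ``matrix`` rows are the distinct tumor variant keys pooled over all
    patients (``n_variants`` = the reported n); columns are
    patient × analyte detection flags.  ``mean_percent`` maps each analyte
    label (ev, cf, ev+cf) to the unweighted mean over patients of the
    fraction of that patient's tumor keys the analyte recovered.
    """

    matrix: pd.DataFrame
    per_patient: dict  # analyte label -> {pid: percent}
    mean_percent: dict  # analyte label -> percent
    n_variants: int


def coincidence_matrix(cohort: PatientCohort,
                       steps: Sequence[FilterStep] | None = None,
                       key_kind: KeyKind | str | None = KeyKind.SNV,
                       ) -> CoincidenceResult:
    analytes = (Analyte.EV.value, Analyte.CF.value, COMBINED)
    tumor_keys: dict[str, set[VariantKey]] = {}
    detected: dict[tuple[str, str], set[VariantKey]] = {}
    for pid in cohort.comparative_patients():
        tk = _keys_for(cohort.get(pid, Analyte.TUMOR), key_kind, steps)
        if not tk:
            continue
        tumor_keys[pid] = tk
        for label in analytes:
            ak = _label_keys(cohort, pid, label, key_kind, steps)
            detected[(pid, label)] = tk & ak
    pooled = sorted({k for tk in tumor_keys.values() for k in tk},
                    key=lambda k: (k.kind.value, k.components))
    columns = [f"{pid}:{label}" for pid in sorted(tumor_keys)
               for label in analytes]
    matrix = pd.DataFrame(0, index=[str(k) for k in pooled], columns=columns,
                          dtype=int)
    for pid in sorted(tumor_keys):
        for label in analytes:
            for k in detected[(pid, label)]:
                matrix.loc[str(k), f"{pid}:{label}"] = 1
    per_patient = {label: {} for label in analytes}
    for label in analytes:
        for pid, tk in tumor_keys.items():
            per_patient[label][pid] = 100.0 * len(detected[(pid, label)]) / len(tk)
    mean_percent = {
        label: (sum(v.values()) / len(v) if v else float("nan"))
        for label, v in per_patient.items()}
    return CoincidenceResult(matrix, per_patient, mean_percent, len(pooled))


def analyte_private_variants(cohort: PatientCohort, analyte_label: str,
                             key_kind: KeyKind | str | None = None,
                             steps: Sequence[FilterStep] | None = None,
                             ) -> dict[str, list[VariantKey]]:
    """Per-patient keys detected by an analyte but absent from the tumor."""
    out: dict[str, list[VariantKey]] = {}
    for pid in cohort.comparative_patients():
        tumor_keys = _keys_for(cohort.get(pid, Analyte.TUMOR), key_kind, steps)
        analyte_keys = _label_keys(cohort, pid, analyte_label, key_kind, steps)
        private = sorted(analyte_keys - tumor_keys,
                         key=lambda k: (k.kind.value, k.components))
        if private:
            out[pid] = private
    return out
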