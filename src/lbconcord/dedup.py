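"""Duplicate removal for annotated variant calls.

Annotators emit one row per variant-transcript combination, so the same
genomic change recurs many times per table.  Identity is defined by a key
tuple that differs between SNVs and indels:

* SNV key — location (``chrom:pos``), alt allele, gene symbol, protein
  position, amino-acid change;
* indel key — location, alt allele, transcript feature.

Among records sharing a key, the one with the *most damaging* PolyPhen-2
annotation is retained (probably_damaging > possibly_damaging > benign >
unknown, ties broken by higher numeric score, then by first occurrence).
Because the indel key includes the transcript, the same genomic indel may
legitimately survive once per transcript; cross-analyte matching uses the
same key, so both sides of a comparison stay consistent.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Sequence

from .data_model import (AnnotatedVariant, ContractError, PP2Category,
                         VariantClass)

#: Serialized form of an empty protein position / amino-acid component, so
#: two empties compare equal.
EMPTY_SENTINEL = "-"


class KeyKind(str, enum.Enum):
    SNV = "snv_key"
    INDEL = "indel_key"


@dataclass(frozen=True)
class VariantKey:
    """Identity tuple used for deduplication and cross-analyte matching."""

    kind: KeyKind
    components: tuple[str, ...]

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.kind.value}({'|'.join(self.components)})"


def make_key(v: AnnotatedVariant) -> VariantKey:
    """Build the SNV or indel identity key for one record."""
    if v.variant_class is VariantClass.SNV:
        return VariantKey(KeyKind.SNV, (
            v.location,
            v.alt_allele,
            v.gene_symbol,
            str(v.protein_position) if v.protein_position is not None
            else EMPTY_SENTINEL,
            v.amino_acid_change.strip() or EMPTY_SENTINEL,
        ))
    return VariantKey(KeyKind.INDEL, (v.location, v.alt_allele, v.feature_id))


_PP2_RANK = {
    PP2Category.PROBABLY_DAMAGING: 3,
    PP2Category.POSSIBLY_DAMAGING: 2,
    PP2Category.BENIGN: 1,
    PP2Category.UNKNOWN: 0,
}


def _damage(v: AnnotatedVariant) -> tuple[int, float]:
    score = v.pp2_score if v.pp2_score is not None else -1.0
    return _PP2_RANK[v.pp2_category], score


def deduplicate(records: Sequence[AnnotatedVariant]) -> list[AnnotatedVariant]:
    """Keep exactly one record per distinct key (most damaging PP-2 wins).

    Records must all belong to one patient/analyte slot.  Survivors keep
    their input order; the operation is idempotent.
    """
    records = list(records)
    if not records:
        return []
    slots = {(r.patient_id, r.analyte) for r in records}
    if len(slots) > 1:
        raise ContractError(
            f"deduplicate() expects one patient/analyte slot, got {sorted(str(s) for s in slots)}")
    best: dict[VariantKey, tuple[tuple[int, float], int]] = {}
    for idx, r in enumerate(records):
        key = make_key(r)
        damage = _damage(r)
        if key not in best or damage > best[key][0]:
            best[key] = (damage, idx)
    keep = sorted(idx for _, idx in best.values())
    return [records[i] for i in keep]


def key_set(records: Iterable[AnnotatedVariant]) -> set[VariantKey]:
    """The set of identity keys of (typically deduplicated) records."""
    return {make_key(r) for r in records}
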