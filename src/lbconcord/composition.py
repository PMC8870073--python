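"""Consequence-term and biotype composition summaries.

Answers "what kinds of variants remain?" before and after filtering.
Consequence percentages are computed over term *occurrences* — a record
annotated ``missense_variant&NMD_transcript_variant`` contributes one
occurrence to each term — so shares always sum to 100 regardless of
multi-term records.  Biotypes are one per record.
"""

from __future__ import annotations

from collections import Counter
from typing import Iterable

from .data_model import AnnotatedVariant


def _percentages(counts: Counter) -> dict[str, float]:
    total = sum(counts.values())
    if total == 0:
        return {}
    return {term: 100.0 * n / total
            for term, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))}


def consequence_composition(records: Iterable[AnnotatedVariant]) -> dict[str, float]:
    """Percent of total consequence-term occurrences, per term."""
    counts = Counter(term for r in records for term in r.consequence_terms)
    return _percentages(counts)


def biotype_composition(records: Iterable[AnnotatedVariant]) -> dict[str, float]:
    """Percent of records per transcript biotype."""
    return _percentages(Counter(r.biotype for r in records))
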