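"""The stringency filter cascade.

Filters compose into the cascades used when comparing liquid-biopsy
analytes with tumor DNA: population allele frequency (AF ≤ 1% removes
common polymorphisms), annotation impact (moderate/high, or high only for
indels), PolyPhen-2 damaging class, Condel deleteriousness, and COSMIC-style
actionability tiers.  All filters are pure predicates — after the initial
deduplication the final surviving set does not depend on filter order.

Missing population AF passes the AF filter: somatic variants are typically
absent from population databases, and removing them would delete exactly
the signal the analysis is after.  Missing PP-2 / Condel predictions fail
the respective damaging filters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import yaml

from .data_model import (ActionabilityEntry, AnnotatedVariant, Impact,
                         PP2Category, CondelLabel, read_actionability_table)
from .dedup import deduplicate

Records = list[AnnotatedVariant]


def filter_af(records: Iterable[AnnotatedVariant],
              threshold: float = 0.01) -> Records:
    """Keep records with population AF ≤ threshold (inclusive) or missing."""
    if not (0.0 <= threshold <= 1.0):
        raise ValueError(f"AF threshold must lie in [0, 1], got {threshold}")
    return [r for r in records
            if r.population_af is None or r.population_af <= threshold]


def filter_impact(records: Iterable[AnnotatedVariant],
                  levels: Iterable[Impact | str]) -> Records:
    """Keep records whose impact class is in ``levels``."""
    levels = {Impact(lv) for lv in levels}
    if not levels:
        raise ValueError("levels must be non-empty")
    return [r for r in records if r.impact in levels]


#: Damaging PP-2 classes kept under the two stringency settings.
_PP2_KEEP = {
    "damaging": {PP2Category.POSSIBLY_DAMAGING, PP2Category.PROBABLY_DAMAGING},
    "probably_damaging": {PP2Category.PROBABLY_DAMAGING},
}


def filter_pp2(records: Iterable[AnnotatedVariant],
               minimum: str = "damaging") -> Records:
    """Keep records at or above a PP-2 damaging class.

    ``minimum="damaging"`` keeps possibly + probably damaging;
    ``minimum="probably_damaging"`` keeps probably damaging only.  Records
    without a PP-2 prediction are removed under either setting.
    """
    if minimum not in _PP2_KEEP:
        raise ValueError(f"minimum must be one of {sorted(_PP2_KEEP)}")
    keep = _PP2_KEEP[minimum]
    return [r for r in records if r.pp2_category in keep]


def filter_condel(records: Iterable[AnnotatedVariant]) -> Records:
    """Keep records with a deleterious Condel label (missing removed)."""
    return [r for r in records if r.condel_label is CondelLabel.DELETERIOUS]


def filter_actionable(records: Iterable[AnnotatedVariant],
                      db: Sequence[ActionabilityEntry],
                      tiers: Iterable[int] = (1, 2, 3, 4)) -> Records:
    """Keep records in actionable genes of the requested tiers.

    Matching is gene-level (the actionability database carries mainly
    gene-level information); a database entry for the specific amino-acid
    change additionally annotates the record with tier and drugs but never
    gates it.
    """
    if not db:
        raise ValueError("actionability database must be non-empty")
    tiers = set(tiers)
    by_gene: dict[str, list[ActionabilityEntry]] = {}
    for entry in db:
        if entry.tier in tiers:
            by_gene.setdefault(entry.gene_symbol, []).append(entry)
    out: Records = []
    for r in records:
        entries = by_gene.get(r.gene_symbol)
        if not entries:
            continue
        best = min(entries, key=lambda e: e.tier)
        r.annotations["tier"] = best.tier
        r.annotations["drugs"] = tuple(d for e in entries for d in e.drugs)
        for e in entries:
            if e.specific_variant and r.protein_position is not None and \
                    e.specific_variant == _aa_label(r):
                r.annotations["specific_variant_match"] = e.specific_variant
        out.append(r)
    return out


def _aa_label(r: AnnotatedVariant) -> str:
    """``R141H``-style label from an ``R/H`` amino-acid change."""
    if not r.amino_acid_change or r.protein_position is None:
        return ""
    ref, _, alt = r.amino_acid_change.partition("/")
    return f"{ref}{r.protein_position}{alt or ref}"


# ---------------------------------------------------------------------------
# Cascade
# ---------------------------------------------------------------------------

@dataclass
class FilterStep:
    """One named step of a cascade, with parameters."""

    name: str
    params: dict = field(default_factory=dict)


@dataclass
class CascadeResult:
    records: Records
    funnel: list[tuple[str, int]]  # (step label, surviving count), input first


_STEP_NAMES = ("dedup", "af", "impact", "pp2", "condel", "actionable")


def _apply_step(records: Records, step: FilterStep) -> Records:
    if step.name == "dedup":
        return deduplicate(records)
    if step.name == "af":
        return filter_af(records, **step.params)
    if step.name == "impact":
        return filter_impact(records, **step.params)
    if step.name == "pp2":
        return filter_pp2(records, **step.params)
    if step.name == "condel":
        return filter_condel(records, **step.params)
    if step.name == "actionable":
        return filter_actionable(records, **step.params)
    raise ValueError(f"unknown filter step {step.name!r}; "
                     f"expected one of {_STEP_NAMES}")


def run_cascade(records: Iterable[AnnotatedVariant],
                steps: Sequence[FilterStep]) -> CascadeResult:
    """Deduplicate, then apply filters in order, recording the funnel.

    Deduplication always runs first; an explicit leading ``dedup`` step is
    honored, otherwise one is prepended (unless the cascade is empty, which
    is the identity).
    """
    records = list(records)
    funnel = [("input", len(records))]
    steps = list(steps)
    if steps and steps[0].name != "dedup":
        steps.insert(0, FilterStep("dedup"))
    for step in steps:
        records = _apply_step(records, step)
        label = step.name
        if step.params:
            label += "(" + ",".join(f"{k}={_short(v)}"
                                    for k, v in sorted(step.params.items())) + ")"
        funnel.append((label, len(records)))
    return CascadeResult(records, funnel)


def _short(v) -> str:
    if isinstance(v, (list, tuple, set, frozenset)):
        return "+".join(sorted(str(getattr(x, "value", x)) for x in v))
    return str(getattr(v, "value", v))


def cascade_from_config(config, actionability_path=None) -> list[FilterStep]:
    """Build cascade steps from a YAML file path or already-parsed list.

    Config shape: a list of ``{name: ..., <param>: ...}`` mappings, e.g.::

        - name: af
          threshold: 0.01
        - name: impact
          levels: [MODERATE, HIGH]
        - name: pp2
          minimum: damaging
    """
    if isinstance(config, (str, bytes)) or hasattr(config, "read_text"):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    steps = []
    for item in config or []:
        item = dict(item)
        name = item.pop("name")
        if name == "impact" and "levels" in item:
            item["levels"] = {Impact(lv) for lv in item["levels"]}
        if name == "actionable":
            path = item.pop("db", actionability_path)
            item["db"] = read_actionability_table(path)
            if "tiers" in item:
                item["tiers"] = set(item["tiers"])
        steps.append(FilterStep(name, item))
    return steps
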