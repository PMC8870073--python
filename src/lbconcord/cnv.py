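"""Coverage-ratio copy-number calling on targeted-panel data.

Each panel target carries an observed mean depth and an expected depth
derived from a reference cohort.  With ``r`` the observed/expected ratio
(rescaled by the sex-dependent expected copy number), a target is reported
as a homozygous deletion when coverage drops below 5% of the expected
value, a heterozygous deletion below 55%, and a duplication above 145%;
anything else is no call.  Calls are made at target (exon) granularity —
no breakpoints, no segmentation; when every target of a gene carries the
same call class, the gene as a whole is additionally labeled as changed,
and adjacent fully-deleted genes are always reported individually.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .data_model import CnvCall, CnvClass, Sex, TargetCoverage

logger = logging.getLogger("lbconcord")

#: Call thresholds on the copy-corrected coverage ratio.
HOM_DEL_BELOW = 0.05
HET_DEL_BELOW = 0.55
DUP_ABOVE = 1.45

#: Sex-estimation thresholds on coverage ratios (plumbing defaults; the
#: values sit far from both the diploid and haploid expectations).
Y_RATIO_MALE_ABOVE = 0.3
X_RATIO_MALE_BELOW = 0.75


def estimate_sex(coverage: Sequence[TargetCoverage],
                 y_threshold: float = Y_RATIO_MALE_ABOVE,
                 x_threshold: float = X_RATIO_MALE_BELOW) -> Sex:
    """Estimate patient sex from sex-chromosome coverage and set copies.

    Male when the mean Y-target observed/expected ratio exceeds
    ``y_threshold``; with no Y targets, male when the mean X ratio falls
    below ``x_threshold``.  Sets ``expected_copies`` on X/Y targets in
    place (male: X=1, Y=1; female: X=2, Y=0).
    """
    y = [c for c in coverage if c.chrom == "y"]
    x = [c for c in coverage if c.chrom == "x"]
    if not y and not x:
        raise ValueError("cannot estimate sex: no X or Y targets in coverage")
    if y:
        ratio = sum(c.observed_depth / c.expected_depth for c in y) / len(y)
        sex = Sex.MALE if ratio > y_threshold else Sex.FEMALE
    else:
        ratio = sum(c.observed_depth / c.expected_depth for c in x) / len(x)
        sex = Sex.MALE if ratio < x_threshold else Sex.FEMALE
    for c in x:
        c.expected_copies = 1 if sex is Sex.MALE else 2
    for c in y:
        c.expected_copies = 1 if sex is Sex.MALE else 0
    return sex


def classify_ratio(r: float) -> CnvClass | None:
    """Map a coverage ratio to a call class (or None for no call).

    The thresholds are strict exactly as stated: r = 0.05 is a
    heterozygous deletion, r = 0.55 and r = 1.45 are no call.
    """
    if r < HOM_DEL_BELOW:
        return CnvClass.HOMOZYGOUS_DELETION
    if r < HET_DEL_BELOW:
        return CnvClass.HETEROZYGOUS_DELETION
    if r > DUP_ABOVE:
        return CnvClass.DUPLICATION
    return None


def call_cnvs(coverage: Iterable[TargetCoverage],
              anomalies: list | None = None) -> list[CnvCall]:
    """Call duplications/deletions per target from coverage ratios.

    The ratio is observed / (expected × expected_copies / 2), so a value
    of 1.0 means the expected copy number.  A target expected at 0 copies
    (female Y) with observed reads is an anomaly: it is skipped, logged,
    and appended to ``anomalies`` when a list is supplied.
    """
    calls: list[CnvCall] = []
    for c in coverage:
        if c.expected_copies == 0:
            if c.observed_depth > 0:
                logger.warning(
                    "anomalous coverage on %s/%s target %s: %.1f reads where "
                    "0 copies expected", c.patient_id, c.analyte.value,
                    c.target_id, c.observed_depth)
                if anomalies is not None:
                    anomalies.append(c)
            continue
        r = c.observed_depth / (c.expected_depth * c.expected_copies / 2.0)
        cls = classify_ratio(r)
        if cls is not None:
            calls.append(CnvCall(
                patient_id=c.patient_id, analyte=c.analyte,
                gene_symbol=c.gene_symbol, target_id=c.target_id,
                call=cls, coverage_ratio=r))
    return calls


def gene_rollup(calls: Sequence[CnvCall],
                targets_per_gene: Mapping[str, Sequence[str]]) -> list[CnvCall]:
    """Label a whole gene as changed when all its targets agree.

    When every known target of a gene carries the same call class, the
    per-target calls are replaced by a single whole-gene call (ratio =
    mean of the target ratios); otherwise per-target calls are retained.
    Genes are always reported individually, never merged into segments.
    """
    out: list[CnvCall] = []
    grouped: dict[tuple[str, str, str], list[CnvCall]] = {}
    for call in calls:
        grouped.setdefault(
            (call.patient_id, call.analyte.value, call.gene_symbol), []
        ).append(call)
    for (pid, analyte, gene), gene_calls in grouped.items():
        universe = set(targets_per_gene.get(gene, ()))
        called = {c.target_id for c in gene_calls}
        classes = {c.call for c in gene_calls}
        if universe and called >= universe and len(classes) == 1:
            ratio = sum(c.coverage_ratio for c in gene_calls) / len(gene_calls)
            out.append(CnvCall(
                patient_id=pid, analyte=analyte, gene_symbol=gene,
                target_id="*", call=classes.pop(), coverage_ratio=ratio,
                whole_gene=True))
        else:
            out.extend(gene_calls)
    return out


@dataclass
class CnvConcordance:
    per_patient: list[tuple[str, int, int, float]]  # pid, n_tumor, n_matched, pct
    mean_percent: float


def cnv_concordance(tumor_calls: Sequence[CnvCall],
                    analyte_calls: Sequence[CnvCall]) -> CnvConcordance:
    """Percent agreement of analyte CNV calls with tumor calls.

    The match unit is (gene, target, call class); per-patient percent is
    100 · matched / tumor calls, averaged unweighted over patients with at
    least one tumor call.
    """
    def by_patient(calls):
        d: dict[str, set] = {}
        for c in calls:
            d.setdefault(c.patient_id, set()).add(
                (c.gene_symbol, c.target_id, c.call))
        return d

    tumor = by_patient(tumor_calls)
    analyte = by_patient(analyte_calls)
    per_patient = []
    for pid in sorted(tumor):
        n_tumor = len(tumor[pid])
        if n_tumor == 0:
            continue
        n_matched = len(tumor[pid] & analyte.get(pid, set()))
        per_patient.append((pid, n_tumor, n_matched, 100.0 * n_matched / n_tumor))
    mean = (sum(p[3] for p in per_patient) / len(per_patient)
            if per_patient else float("nan"))
    return CnvConcordance(per_patient, mean)
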