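"""Synthetic matched tumor / evDNA / cfDNA cohorts, coverage and traces.

The generator emulates the statistical structure the analysis assumes:

* each patient carries a Poisson number of tumor variants, annotated with
  impact / consequence / biotype / PolyPhen-2 / Condel categories drawn
  from configurable mixes (impact and the annotation layers are coupled —
  moderate variants are missense in protein-coding transcripts, modifier
  variants are intronic/non-coding noise — so the filter cascade behaves
  as it does on real annotator output);
* each tumor variant is independently re-detected in evDNA and cfDNA with
  the configured analyte sensitivities (an optional correlation parameter
  couples the two detection events); each analyte additionally carries a
  Poisson number of analyte-private variants;
* a configurable fraction of variants are common polymorphisms
  (population AF > 1%), which the AF filter later removes;
* coverage profiles plant copy-number events as multiplicative depth
  shifts with a given coefficient of variation around the expected depth;
* fragment traces mix a short ~167 bp mononucleosome peak with a long
  (250–5500 bp) log-size component whose mass differs between ev-like and
  cf-like samples.

All randomness flows from ``config.seed``; identical configurations yield
identical cohorts.  A truth record stores every planted fact so expected
downstream statistics can be computed independently.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .data_model import (Analyte, AnnotatedVariant, CondelLabel, FragmentTrace,
                         Impact, PatientCohort, PP2Category, TargetCoverage,
                         VariantClass)

# Gene symbols sampled for synthetic variants (tumor-panel style).
GENE_POOL = (
    "TP53", "KRAS", "SMAD4", "CDKN2A", "BRCA1", "BRCA2", "ATM", "BRAF",
    "PTEN", "CHEK2", "ALK", "ROS1", "IDH2", "RAD51B", "NF1", "FGFR3",
    "KMT2C", "MAP2K3", "FLT3", "PRSS1", "PARP4", "GGT1", "NCOR1", "ERCC5",
    "EGFR", "ERBB2", "PIK3CA", "ARID1A", "RNF43", "GNAS",
)

_BASES = ("A", "C", "G", "T")

# Consequence terms drawn conditional on impact class.
CONSEQUENCES_BY_IMPACT = {
    Impact.HIGH: (("stop_gained", 0.6), ("splice_donor_variant", 0.4)),
    Impact.MODERATE: (("missense_variant", 0.85),
                      ("missense_variant&NMD_transcript_variant", 0.15)),
    Impact.LOW: (("synonymous_variant", 0.6), ("splice_region_variant", 0.4)),
    Impact.MODIFIER: (("intron_variant", 0.5),
                      ("non_coding_transcript_variant", 0.3),
                      ("NMD_transcript_variant", 0.2)),
}

# Biotype drawn conditional on impact group (coding-altering vs noise).
BIOTYPES_CODING = (("protein_coding", 0.94), ("nonsense_mediated_decay", 0.06))
BIOTYPES_NOISE = (("protein_coding", 0.55), ("nonsense_mediated_decay", 0.15),
                  ("retained_intron", 0.18), ("processed_transcript", 0.12))

_AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class SyntheticConfig:
    """Study-condition knobs for the synthetic cohort generator.

    Defaults emulate the matched nine-patient comparison at desk scale:
    analyte sensitivities near the observed per-patient coincidence of
    the single liquid-biopsy analytes, a common-polymorphism share near
    the observed unfiltered→AF-filtered reduction, and ev-like vs cf-like
    long-fragment masses near the published long-fraction percentages.
    """

    n_patients: int = 9
    tumor_variants_per_patient: float = 20.0
    ev_sensitivity: float = 0.69
    cf_sensitivity: float = 0.67
    shared_detection_correlation: float = 0.0
    private_rate_ev: float = 0.5
    private_rate_cf: float = 0.3
    common_af_fraction: float = 0.4
    indel_fraction: float = 0.28
    duplicate_rate: float = 0.15
    impact_mix: dict = field(default_factory=lambda: {
        Impact.MODIFIER: 0.50, Impact.LOW: 0.15,
        Impact.MODERATE: 0.30, Impact.HIGH: 0.05})
    pp2_mix: dict = field(default_factory=lambda: {
        PP2Category.UNKNOWN: 0.25, PP2Category.BENIGN: 0.30,
        PP2Category.POSSIBLY_DAMAGING: 0.25,
        PP2Category.PROBABLY_DAMAGING: 0.20})
    cnv_events: list = field(default_factory=lambda: [
        ("CDKN2A", 1), ("SMAD4", 0), ("MYC", 3)])
    background_genes: int = 10
    targets_per_gene: int = 5
    depth_mean: float = 500.0
    depth_cv: float = 0.05
    frag_long_mass_ev: float = 0.55
    frag_long_mass_cf: float = 0.32
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("ev_sensitivity", "cf_sensitivity",
                     "shared_detection_correlation", "common_af_fraction",
                     "indel_fraction", "duplicate_rate",
                     "frag_long_mass_ev", "frag_long_mass_cf"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for mix_name in ("impact_mix", "pp2_mix"):
            total = sum(getattr(self, mix_name).values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{mix_name} must sum to 1, sums to {total}")


def _choice(rng: np.random.Generator, weighted) -> str:
    items = [w[0] for w in weighted]
    probs = np.array([w[1] for w in weighted], dtype=float)
    return items[rng.choice(len(items), p=probs / probs.sum())]


def _pp2_score(rng: np.random.Generator, category: PP2Category) -> float | None:
    lo_hi = {PP2Category.BENIGN: (0.0, 0.45),
             PP2Category.POSSIBLY_DAMAGING: (0.45, 0.9),
             PP2Category.PROBABLY_DAMAGING: (0.9, 1.0)}.get(category)
    if lo_hi is None:
        return None
    return float(rng.uniform(*lo_hi))


def _make_variant(rng: np.random.Generator, config: SyntheticConfig,
                  patient_id: str, analyte: Analyte) -> AnnotatedVariant:
    """One random annotated variant (identity + annotation layers)."""
    is_indel = rng.random() < config.indel_fraction
    chrom = str(rng.integers(1, 23))
    pos = int(rng.integers(10_000, 200_000_000))
    gene = GENE_POOL[rng.integers(len(GENE_POOL))]
    impact_items = list(config.impact_mix.items())
    impact = _choice(rng, [(k, v) for k, v in impact_items])
    consequence = _choice(rng, CONSEQUENCES_BY_IMPACT[impact])
    coding = impact in (Impact.MODERATE, Impact.HIGH)
    biotype = _choice(rng, BIOTYPES_CODING if coding else BIOTYPES_NOISE)
    if is_indel:
        if rng.random() < 0.5:
            ref, alt = "NN", "-"  # deletion
        else:
            ref, alt = "-", "".join(rng.choice(_BASES, size=2))
        vclass = VariantClass.INDEL
    else:
        ref, alt = rng.choice(_BASES, size=2, replace=False)
        vclass = VariantClass.SNV
    # Population AF: common polymorphism, rare annotated, or absent.
    u = rng.random()
    if u < config.common_af_fraction:
        af = float(rng.uniform(0.02, 0.5))
    elif u < config.common_af_fraction + 0.2:
        af = float(rng.uniform(0.0, 0.01))
    else:
        af = None
    # PP-2 / Condel exist only for missense SNVs.
    missense = (not is_indel) and consequence.startswith("missense")
    if missense:
        pp2_category = PP2Category(_choice(
            rng, [(k, v) for k, v in config.pp2_mix.items()]))
        pp2_score = _pp2_score(rng, pp2_category)
        deleterious_prob = {
            PP2Category.PROBABLY_DAMAGING: 0.9,
            PP2Category.POSSIBLY_DAMAGING: 0.6,
            PP2Category.BENIGN: 0.1}.get(pp2_category)
        if deleterious_prob is None:
            condel = CondelLabel.MISSING
        else:
            condel = (CondelLabel.DELETERIOUS
                      if rng.random() < deleterious_prob
                      else CondelLabel.NEUTRAL)
    else:
        pp2_category, pp2_score = PP2Category.UNKNOWN, None
        condel = CondelLabel.MISSING
    protein_position = (int(rng.integers(1, 1200))
                        if consequence.startswith("missense") else None)
    aa_change = ""
    if protein_position is not None:
        a, b = rng.choice(len(_AA), size=2, replace=False)
        aa_change = f"{_AA[a]}/{_AA[b]}"
    return AnnotatedVariant(
        patient_id=patient_id, analyte=analyte, chrom=chrom, pos=pos,
        ref_allele=str(ref), alt_allele=str(alt), gene_symbol=gene,
        feature_id=f"ENST{rng.integers(10_000_000):08d}",
        consequence_terms=tuple(consequence.split("&")),
        impact=impact, biotype=biotype, protein_position=protein_position,
        amino_acid_change=aa_change, population_af=af,
        pp2_category=pp2_category, pp2_score=pp2_score, condel_label=condel,
        variant_class=vclass)


def _reassign(record: AnnotatedVariant, analyte: Analyte) -> AnnotatedVariant:
    return dataclasses.replace(record, analyte=analyte, annotations={})


def _duplicate_row(rng: np.random.Generator,
                   record: AnnotatedVariant) -> AnnotatedVariant:
    """A second transcript annotation row for the same SNV, with a less
    damaging PP-2 score, as annotators produce for overlapping features."""
    dup = dataclasses.replace(record, feature_id=f"ENSTDUP{rng.integers(1_000_000):07d}",
                              annotations={})
    if dup.pp2_score is not None and dup.pp2_category is not PP2Category.BENIGN:
        dup.pp2_category = PP2Category.BENIGN
        dup.pp2_score = float(rng.uniform(0.0, 0.4))
    return dup


def _correlated_detection(rng: np.random.Generator, p_ev: float, p_cf: float,
                          rho: float) -> tuple[bool, bool]:
    u_shared = rng.random()
    u_ev = u_shared if rng.random() < rho else rng.random()
    u_cf = u_shared if rng.random() < rho else rng.random()
    return u_ev < p_ev, u_cf < p_cf


def generate_cohort(config: SyntheticConfig) -> tuple[PatientCohort, dict]:
    """Generate a matched tumor/ev/cf cohort plus a planted-truth record."""
    rng = np.random.default_rng(config.seed)
    cohort = PatientCohort()
    truth: dict = {"patients": {}, "seed": config.seed}
    for i in range(config.n_patients):
        pid = f"P{i + 1:02d}"
        n_tumor = int(rng.poisson(config.tumor_variants_per_patient))
        tumor, ev, cf = [], [], []
        n_ev_det = n_cf_det = 0
        for _ in range(n_tumor):
            v = _make_variant(rng, config, pid, Analyte.TUMOR)
            tumor.append(v)
            if rng.random() < config.duplicate_rate and \
                    v.variant_class is VariantClass.SNV:
                tumor.append(_duplicate_row(rng, v))
            det_ev, det_cf = _correlated_detection(
                rng, config.ev_sensitivity, config.cf_sensitivity,
                config.shared_detection_correlation)
            if det_ev:
                ev.append(_reassign(v, Analyte.EV))
                n_ev_det += 1
            if det_cf:
                cf.append(_reassign(v, Analyte.CF))
                n_cf_det += 1
        n_ev_priv = int(rng.poisson(config.private_rate_ev))
        n_cf_priv = int(rng.poisson(config.private_rate_cf))
        ev.extend(_make_variant(rng, config, pid, Analyte.EV)
                  for _ in range(n_ev_priv))
        cf.extend(_make_variant(rng, config, pid, Analyte.CF)
                  for _ in range(n_cf_priv))
        cohort.add_variants(pid, Analyte.TUMOR, tumor)
        cohort.add_variants(pid, Analyte.EV, ev)
        cohort.add_variants(pid, Analyte.CF, cf)
        truth["patients"][pid] = {
            "n_tumor": n_tumor, "n_ev_detected": n_ev_det,
            "n_cf_detected": n_cf_det, "n_ev_private": n_ev_priv,
            "n_cf_private": n_cf_priv}
    return cohort, truth


def generate_coverage(config: SyntheticConfig, patient_id: str = "P01",
                      analyte: Analyte | str = Analyte.TUMOR,
                      ) -> tuple[list[TargetCoverage], dict]:
    """Per-target coverage with planted copy-number events plus truth.

    Every gene in ``config.cnv_events`` gets ``targets_per_gene`` targets
    at the planted copy number; ``background_genes`` additional autosomal
    genes sit at 2 copies.  Observed depth is the copy-scaled expected
    depth with multiplicative Gaussian noise of CV ``depth_cv``.
    """
    rng = np.random.default_rng(config.seed + 1)
    analyte = Analyte(analyte)
    coverage: list[TargetCoverage] = []
    truth: dict = {"targets": {}}
    genes = list(config.cnv_events) + [
        (f"BG{i:03d}", 2) for i in range(config.background_genes)]
    for gi, (gene, copies) in enumerate(genes):
        chrom = str(gi % 22 + 1)
        for t in range(config.targets_per_gene):
            target_id = f"{gene}_t{t + 1}"
            expected = float(config.depth_mean * rng.lognormal(0.0, 0.15))
            noise = 1.0 + config.depth_cv * rng.standard_normal()
            observed = max(0.0, expected * copies / 2.0 * noise)
            coverage.append(TargetCoverage(
                patient_id=patient_id, analyte=analyte, chrom=chrom,
                gene_symbol=gene, target_id=target_id,
                observed_depth=observed, expected_depth=expected))
            truth["targets"][target_id] = copies
    return coverage, truth


#: Size grid for synthetic traces: dense around the mononucleosome peak,
#: log-spaced through the long-fragment range.
def _trace_grid() -> np.ndarray:
    short = np.linspace(50.0, 320.0, 120, endpoint=False)
    long = np.geomspace(320.0, 6000.0, 140)
    return np.concatenate([short, long])


def generate_trace(config: SyntheticConfig,
                   analyte: Analyte | str) -> FragmentTrace:
    """Electropherogram mixing a ~167 bp peak with a long log-size tail.

    The long component (log-normal over roughly 250–5500 bp) carries the
    analyte's configured mass fraction; ev-like samples carry more long
    mass than cf-like ones.  Signal is area-normalized to 1 before a tiny
    seeded multiplicative noise.
    """
    analyte = Analyte(analyte)
    mass_long = {Analyte.EV: config.frag_long_mass_ev,
                 Analyte.CF: config.frag_long_mass_cf,
                 Analyte.TUMOR: 0.8}[analyte]
    rng = np.random.default_rng(config.seed + {"tumor": 2, "ev": 3, "cf": 4}[analyte.value])
    x = _trace_grid()
    short = np.exp(-0.5 * ((x - 167.0) / 15.0) ** 2) / (15.0 * np.sqrt(2 * np.pi))
    mu, sigma = np.log(1200.0), 0.75
    long = np.exp(-0.5 * ((np.log(x) - mu) / sigma) ** 2) / (
        x * sigma * np.sqrt(2 * np.pi))
    signal = (1.0 - mass_long) * short + mass_long * long
    signal = signal / np.trapezoid(signal, x)
    signal = signal * np.clip(1.0 + 0.01 * rng.standard_normal(x.size), 0.0, None)
    return FragmentTrace(x, signal)
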