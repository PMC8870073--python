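import pytest

from lbconcord import (Analyte, AnnotatedVariant, CondelLabel, Impact,
                       PP2Category, VariantClass)


def make_variant(patient_id="p1", analyte="tumor", chrom="1", pos=100,
                 ref="A", alt="G", gene="TP53", feature="ENST0001",
                 consequences=("missense_variant",), impact=Impact.MODERATE,
                 biotype="protein_coding", protein_position=10, aa="R/H",
                 af=None, pp2=(PP2Category.UNKNOWN, None),
                 condel=CondelLabel.MISSING) -> AnnotatedVariant:
    """Concise factory for one annotated variant record."""
    is_snv = len(ref) == 1 and len(alt) == 1 and ref != "-" and alt != "-"
    return AnnotatedVariant(
        patient_id=patient_id, analyte=Analyte(analyte), chrom=chrom, pos=pos,
        ref_allele=ref, alt_allele=alt, gene_symbol=gene, feature_id=feature,
        consequence_terms=tuple(consequences), impact=impact, biotype=biotype,
        protein_position=protein_position, amino_acid_change=aa,
        population_af=af, pp2_category=pp2[0], pp2_score=pp2[1],
        condel_label=condel,
        variant_class=VariantClass.SNV if is_snv else VariantClass.INDEL)


@pytest.fixture
def mkvar():
    return make_variant
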