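"""Small builders shared across test modules."""

from haystack import AnnotatedVariant, GenotypeCall, VariantKey


def het_call(sample="S1", dp=30, ad=15, dosage=1):
    return GenotypeCall(sample_id=sample, alt_dosage=dosage, read_depth=dp, alt_depth=ad)


def hom_call(sample="S1", dp=30, ad=29):
    return GenotypeCall(sample_id=sample, alt_dosage=2, read_depth=dp, alt_depth=ad)


def make_variant(
    gene="G1",
    chrom="1",
    pos=1000,
    ref="A",
    alt="T",
    consequence="frameshift_variant",
    maf=None,
    cadd=None,
    calls=(),
):
    return AnnotatedVariant(
        key=VariantKey(chrom, pos, ref, alt),
        gene=gene,
        consequence=consequence,
        population_maf=maf,
        cadd=cadd,
        calls=tuple(calls),
    )
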