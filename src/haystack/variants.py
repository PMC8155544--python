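"""Core variant and genotype domain types plus elementary classifiers.

Every downstream stage of the prioritization cascade works with these atoms:
a :class:`VariantKey` identifies one alternate allele at one site, a
:class:`GenotypeCall` carries one sample's dosage and depth evidence, and an
:class:`AnnotatedVariant` joins the key with gene/consequence/population
annotations and the per-sample calls.

Consequence terms follow Sequence Ontology spellings; a synonym table accepts
common annotation dialects (``stop-gain``, ``splice donor`` ...). The
loss-of-function (LoF) class is exactly the set {stop gained, frameshift,
splice acceptor, splice donor}.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum

from .errors import DataError, UndefinedAlleleFraction

logger = logging.getLogger(__name__)


class ConsequenceClass(str, Enum):
    """Coarse functional class of a variant consequence term."""

    LOF = "lof"
    MISSENSE = "missense"
    OTHER = "other"


#: severity ordering used when collapsing multi-transcript annotations
_SEVERITY = {ConsequenceClass.LOF: 2, ConsequenceClass.MISSENSE: 1, ConsequenceClass.OTHER: 0}

#: canonical Sequence Ontology terms per class
LOF_TERMS = frozenset(
    {"stop_gained", "frameshift_variant", "splice_acceptor_variant", "splice_donor_variant"}
)
MISSENSE_TERMS = frozenset({"missense_variant"})

#: accepted synonyms -> canonical SO term (normalized spelling, see _normalize_term)
CONSEQUENCE_SYNONYMS: dict[str, str] = {
    "stop_gain": "stop_gained",
    "stopgain": "stop_gained",
    "nonsense": "stop_gained",
    "stop": "stop_gained",
    "frameshift": "frameshift_variant",
    "frame_shift": "frameshift_variant",
    "splice_acceptor": "splice_acceptor_variant",
    "splice_donor": "splice_donor_variant",
    "missense": "missense_variant",
    "synonymous": "synonymous_variant",
}


def _normalize_term(term: str) -> str:
    return term.strip().lower().replace("-", "_").replace(" ", "_")


def classify_consequence(term: str) -> ConsequenceClass:
    """Map a consequence term to {lof, missense, other}.

    Total function: unknown terms map to ``other`` (logged at debug level),
    never an error.
    """
    if not isinstance(term, str) or not term.strip():
        return ConsequenceClass.OTHER
    norm = _normalize_term(term)
    norm = CONSEQUENCE_SYNONYMS.get(norm, norm)
    if norm in LOF_TERMS:
        return ConsequenceClass.LOF
    if norm in MISSENSE_TERMS:
        return ConsequenceClass.MISSENSE
    if norm not in {"synonymous_variant"}:
        logger.debug("unknown consequence term %r -> other", term)
    return ConsequenceClass.OTHER


def most_severe_class(classes) -> ConsequenceClass:
    """Collapse multiple transcript annotations to the most severe class."""
    classes = list(classes)
    if not classes:
        return ConsequenceClass.OTHER
    return max(classes, key=_SEVERITY.__getitem__)


class Zygosity(str, Enum):
    HOMOZYGOUS_ALT = "homozygous_alt"
    HETEROZYGOUS = "heterozygous"
    REFERENCE = "reference"
    MISSING = "missing"


@dataclass(frozen=True, order=True)
class VariantKey:
    """Identity of one alternate allele at one genomic site (1-based)."""

    chromosome: str
    position: int
    ref: str
    alt: str

    def __post_init__(self):
        if not self.chromosome:
            raise DataError("chromosome label must be non-empty")
        if self.position < 1:
            raise DataError(f"position must be >= 1, got {self.position}")
        if not self.ref or not self.alt:
            raise DataError("ref and alt alleles must be non-empty")
        if self.ref == self.alt:
            raise DataError(f"ref and alt must differ at {self.chromosome}:{self.position}")

    def __str__(self) -> str:  # chrom-pos-ref-alt, the usual variant shorthand
        return f"{self.chromosome}-{self.position}-{self.ref}-{self.alt}"


@dataclass(frozen=True)
class GenotypeCall:
    """One sample's genotype at one variant.

    ``alt_dosage`` is the number of alternate-allele copies (0/1/2) or ``None``
    for a missing call; missing calls are excluded from every filter.
    """

    sample_id: str
    alt_dosage: int | None
    read_depth: int | None = None
    alt_depth: int | None = None

    def __post_init__(self):
        if self.alt_dosage is not None and self.alt_dosage not in (0, 1, 2):
            raise DataError(f"alt_dosage must be in {{0,1,2}}, got {self.alt_dosage}")
        if self.read_depth is not None and self.read_depth < 0:
            raise DataError("read_depth must be non-negative")
        if self.alt_depth is not None and self.alt_depth < 0:
            raise DataError("alt_depth must be non-negative")
        if (
            self.read_depth is not None
            and self.alt_depth is not None
            and self.alt_depth > self.read_depth
        ):
            raise DataError(
                f"alt_depth {self.alt_depth} exceeds read_depth {self.read_depth} "
                f"for sample {self.sample_id}"
            )


def variant_allele_fraction(call: GenotypeCall) -> float:
    """AD/DP for one call; the "frequency" term of the call-quality gate."""
    if not call.read_depth:
        raise UndefinedAlleleFraction(
            f"variant allele fraction undefined at read depth 0 (sample {call.sample_id})"
        )
    if call.alt_depth is None:
        raise UndefinedAlleleFraction(f"alt depth missing for sample {call.sample_id}")
    return call.alt_depth / call.read_depth


def zygosity(call: GenotypeCall) -> Zygosity:
    if call.alt_dosage is None:
        return Zygosity.MISSING
    if call.alt_dosage == 2:
        return Zygosity.HOMOZYGOUS_ALT
    if call.alt_dosage == 1:
        return Zygosity.HETEROZYGOUS
    return Zygosity.REFERENCE


def is_x_linked(chromosome: str) -> bool:
    """True iff the label, case-insensitively and ignoring a "chr" prefix, is X."""
    label = chromosome.strip().lower()
    if label.startswith("chr"):
        label = label[3:]
    return label == "x"


@dataclass(frozen=True)
class AnnotatedVariant:
    """A variant with gene, consequence, population MAF, CADD and calls."""

    key: VariantKey
    gene: str
    consequence: str
    population_maf: float | None = None
    cadd: float | None = None
    calls: tuple[GenotypeCall, ...] = field(default_factory=tuple)

    def __post_init__(self):
        if not self.gene:
            raise DataError(f"gene symbol missing for variant {self.key}")
        if self.population_maf is not None and not 0.0 <= self.population_maf <= 1.0:
            raise DataError(
                f"population MAF must lie in [0,1], got {self.population_maf} for {self.key}"
            )
        if self.cadd is not None and self.cadd < 0:
            raise DataError(f"CADD score must be non-negative, got {self.cadd}")
        object.__setattr__(self, "calls", tuple(self.calls))

    @property
    def consequence_class(self) -> ConsequenceClass:
        return classify_consequence(self.consequence)

    def carrier_calls(self) -> tuple[GenotypeCall, ...]:
        """Calls with at least one alternate allele copy."""
        return tuple(c for c in self.calls if c.alt_dosage is not None and c.alt_dosage >= 1)
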