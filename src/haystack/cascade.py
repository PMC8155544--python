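"""Five-stage gene prioritization cascade with per-stage audit.

The cascade mirrors the discovery strategy used for the Sertoli cell-only
(SCO) cohort: starting from all annotated case variants, genes survive only if
they carry

1. a loss-of-function variant that is rare in the general population
   (MAF <= 0.01, missing MAF treated as 0 i.e. novel),
2. with a quality-passing case call (DP >= 10, AD >= 4, VAF >= 40%),
3. whose genotype-specific MAF gate holds (homozygous autosomal <= 0.01;
   heterozygous or X-linked <= 0.001),
4. in a gene whose testis expression is above 50% of its maximum across all
   tissues (strict inequality), and
5. with no quality-passing LoF call in any control individual with intact
   spermatogenesis.

Counts are audited gene-level after every stage, and candidates are binned by
the number of distinct patients carrying a qualifying variant (recurrence).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .errors import ConfigurationError, DataError, UndefinedAlleleFraction
from .variants import (
    AnnotatedVariant,
    ConsequenceClass,
    GenotypeCall,
    Zygosity,
    is_x_linked,
    variant_allele_fraction,
    zygosity,
)

logger = logging.getLogger(__name__)

STAGE_NAMES = (
    "effect_and_rarity",
    "quality",
    "genotype_maf",
    "expression",
    "control_exclusion",
)


@dataclass
class FilterConfig:
    """All cascade thresholds; defaults are the published criteria."""

    lof_maf_max: float = 0.01
    hom_maf_max: float = 0.01
    het_maf_max: float = 0.001
    x_linked_maf_max: float = 0.001
    min_read_depth: int = 10
    min_alt_depth: int = 4
    min_vaf: float = 0.40
    testis_fraction_min: float = 0.5  # strict ">" gate
    missing_maf_policy: str = "zero"

    def __post_init__(self):
        for name in ("lof_maf_max", "hom_maf_max", "het_maf_max", "x_linked_maf_max", "min_vaf", "testis_fraction_min"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0,1], got {v}")
        if self.min_read_depth < 0 or self.min_alt_depth < 0:
            raise ConfigurationError("depth thresholds must be non-negative")
        if self.missing_maf_policy != "zero":
            raise ConfigurationError(
                f"unsupported missing_maf_policy {self.missing_maf_policy!r}"
            )

    @classmethod
    def from_mapping(cls, overrides: dict | None) -> "FilterConfig":
        cfg = cls()
        for key, value in (overrides or {}).items():
            if not hasattr(cfg, key):
                raise ConfigurationError(f"unknown filter setting {key!r}")
            setattr(cfg, key, type(getattr(cfg, key))(value))
        cfg.__post_init__()
        return cfg


@dataclass(frozen=True)
class ExpressionProfile:
    """Per-gene tissue expression (TPM-like); must include testis."""

    gene: str
    expression: dict


def testis_fraction(profile: ExpressionProfile) -> float:
    """Testis expression over the maximum across all tissues (testis included).

    An all-zero profile yields 0 by convention.
    """
    testis = None
    for tissue, value in profile.expression.items():
        if tissue.lower() == "testis":
            testis = float(value)
            break
    if testis is None:
        raise ConfigurationError(f"profile for {profile.gene} lacks a testis value")
    peak = max(float(v) for v in profile.expression.values())
    if peak <= 0.0:
        return 0.0
    return testis / peak


@dataclass(frozen=True)
class QualifyingCall:
    """One (variant, carrier call) pair moving through the per-call stages."""

    variant: AnnotatedVariant
    call: GenotypeCall
    zygosity: Zygosity


@dataclass
class StageRecord:
    name: str
    genes_in: int
    genes_out: int
    removed: dict  # gene -> reason

    def __post_init__(self):
        if self.genes_out > self.genes_in:
            raise DataError(f"stage {self.name}: genes_out exceeds genes_in")


@dataclass
class StageAudit:
    """Ordered per-stage gene counts; the cascade's reproducibility ledger."""

    stages: list = field(default_factory=list)

    def append(self, record: StageRecord) -> None:
        if self.stages and record.genes_in != self.stages[-1].genes_out:
            raise DataError(
                f"stage {record.name}: genes_in {record.genes_in} does not chain "
                f"from previous genes_out {self.stages[-1].genes_out}"
            )
        self.stages.append(record)

    def to_dict(self) -> dict:
        return {
            "stages": [
                {
                    "name": s.name,
                    "genes_in": s.genes_in,
                    "genes_out": s.genes_out,
                    "removed": dict(sorted(s.removed.items())),
                }
                for s in self.stages
            ]
        }

    def to_text(self) -> str:
        lines = [f"{'stage':<20}{'genes_in':>10}{'genes_out':>11}"]
        for s in self.stages:
            lines.append(f"{s.name:<20}{s.genes_in:>10}{s.genes_out:>11}")
        return "\n".join(lines) + "\n"


@dataclass
class CandidateGene:
    """A gene surviving all stages, with its qualifying case variants."""

    gene: str
    qualifying_variants: list  # of (AnnotatedVariant, sample_id, Zygosity)
    patient_count: int


@dataclass
class RecurrenceHistogram:
    """Genes binned by the number of distinct patients carrying them."""

    total_genes: int
    bins: dict  # patient_count -> (n_genes, percentage)


def effective_maf(variant: AnnotatedVariant) -> float:
    """Population MAF with the missing-is-novel (0) policy."""
    return variant.population_maf if variant.population_maf is not None else 0.0


def stage1_effect_and_rarity(
    variants: list[AnnotatedVariant], cfg: FilterConfig
) -> list[AnnotatedVariant]:
    """Keep LoF variants rare in the general population (MAF <= lof_maf_max)."""
    return [
        v
        for v in variants
        if v.consequence_class is ConsequenceClass.LOF and effective_maf(v) <= cfg.lof_maf_max
    ]


def call_passes_quality(call: GenotypeCall, cfg: FilterConfig) -> bool:
    """DP >= 10, AD >= 4 and VAF >= 40% (all inclusive); missing evidence fails."""
    if call.read_depth is None or call.alt_depth is None:
        logger.debug("call for %s lacks DP/AD; fails quality", call.sample_id)
        return False
    try:
        vaf = variant_allele_fraction(call)
    except UndefinedAlleleFraction:
        return False
    return (
        call.read_depth >= cfg.min_read_depth
        and call.alt_depth >= cfg.min_alt_depth
        and vaf >= cfg.min_vaf
    )


def stage2_quality(
    variants: list[AnnotatedVariant], cfg: FilterConfig
) -> list[QualifyingCall]:
    """Per-call quality gate; a variant survives via its quality-passing carriers."""
    pairs = []
    for v in variants:
        for call in v.carrier_calls():
            if call_passes_quality(call, cfg):
                pairs.append(QualifyingCall(v, call, zygosity(call)))
    return pairs


def genotype_maf_passes(pair: QualifyingCall, cfg: FilterConfig) -> bool:
    maf = effective_maf(pair.variant)
    x_linked = is_x_linked(pair.variant.key.chromosome)
    if pair.zygosity is Zygosity.HOMOZYGOUS_ALT and not x_linked:
        return maf <= cfg.hom_maf_max
    if x_linked:
        return maf <= cfg.x_linked_maf_max
    return maf <= cfg.het_maf_max


def stage3_genotype_maf(
    pairs: list[QualifyingCall], cfg: FilterConfig
) -> list[QualifyingCall]:
    """Genotype-aware MAF gate: hom autosomal <= 0.01; het or X-linked <= 0.001."""
    return [p for p in pairs if genotype_maf_passes(p, cfg)]


def stage4_expression(
    genes: set[str], profiles: dict[str, ExpressionProfile], cfg: FilterConfig
) -> tuple[set[str], dict]:
    """Keep genes with testis expression strictly above half their maximum."""
    kept, removed = set(), {}
    for gene in genes:
        profile = profiles.get(gene)
        if profile is None:
            removed[gene] = "no expression profile"
        elif testis_fraction(profile) > cfg.testis_fraction_min:
            kept.add(gene)
        else:
            removed[gene] = (
                f"testis fraction {testis_fraction(profile):.3f} "
                f"not above {cfg.testis_fraction_min}"
            )
    return kept, removed


def stage5_control_exclusion(
    genes: set[str], control_variants: list[AnnotatedVariant], cfg: FilterConfig
) -> tuple[set[str], dict]:
    """Drop genes with a quality-passing LoF call in any control individual.

    No MAF gate is applied to control evidence: any LoF observed in a man with
    intact spermatogenesis disqualifies the gene, but the supporting call must
    itself pass the quality gate so genes are not excluded on sequencing noise.
    """
    lof_in_controls = set()
    for v in control_variants:
        if v.consequence_class is not ConsequenceClass.LOF or v.gene not in genes:
            continue
        if any(call_passes_quality(c, cfg) for c in v.carrier_calls()):
            lof_in_controls.add(v.gene)
    kept = genes - lof_in_controls
    removed = {g: "LoF variant in control individual" for g in lof_in_controls}
    return kept, removed


def run_cascade(
    case_variants: list[AnnotatedVariant],
    control_variants: list[AnnotatedVariant],
    profiles: dict[str, ExpressionProfile],
    cfg: FilterConfig | None = None,
) -> tuple[list[CandidateGene], StageAudit]:
    """Apply the five stages in order and return candidates plus the audit.

    Raises on an empty case cohort; an empty control cohort only turns the
    control-exclusion stage into a logged no-op.
    """
    cfg = cfg or FilterConfig()
    if not case_variants:
        raise DataError("case cohort contains no variants")
    if not control_variants:
        logger.warning("control cohort is empty; control exclusion is a no-op")

    audit = StageAudit()
    genes0 = {v.gene for v in case_variants}

    s1 = stage1_effect_and_rarity(case_variants, cfg)
    genes1 = {v.gene for v in s1}
    audit.append(
        StageRecord(
            "effect_and_rarity",
            len(genes0),
            len(genes1),
            {g: "no rare LoF variant" for g in genes0 - genes1},
        )
    )

    pairs2 = stage2_quality(s1, cfg)
    genes2 = {p.variant.gene for p in pairs2}
    audit.append(
        StageRecord(
            "quality",
            len(genes1),
            len(genes2),
            {g: "no quality-passing call" for g in genes1 - genes2},
        )
    )

    pairs3 = stage3_genotype_maf(pairs2, cfg)
    genes3 = {p.variant.gene for p in pairs3}
    audit.append(
        StageRecord(
            "genotype_maf",
            len(genes2),
            len(genes3),
            {g: "genotype-specific MAF gate" for g in genes2 - genes3},
        )
    )

    genes4, removed4 = stage4_expression(genes3, profiles, cfg)
    audit.append(StageRecord("expression", len(genes3), len(genes4), removed4))

    genes5, removed5 = stage5_control_exclusion(genes4, control_variants, cfg)
    audit.append(StageRecord("control_exclusion", len(genes4), len(genes5), removed5))

    by_gene: dict[str, list] = {}
    for p in pairs3:
        if p.variant.gene in genes5:
            by_gene.setdefault(p.variant.gene, []).append(
                (p.variant, p.call.sample_id, p.zygosity)
            )
    candidates = []
    for gene in sorted(by_gene):
        quals = sorted(by_gene[gene], key=lambda t: (t[0].key, t[1]))
        patients = {sample for _, sample, _ in quals}
        candidates.append(CandidateGene(gene, quals, len(patients)))
    return candidates, audit


def recurrence_histogram(candidates: list[CandidateGene]) -> RecurrenceHistogram:
    """Bin candidate genes by distinct-patient count, with percentages."""
    total = len(candidates)
    if total == 0:
        return RecurrenceHistogram(0, {})
    counts: dict[int, int] = {}
    for c in candidates:
        counts[c.patient_count] = counts.get(c.patient_count, 0) + 1
    bins = {
        k: (n, 100.0 * n / total) for k, n in sorted(counts.items())
    }
    return RecurrenceHistogram(total, bins)
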