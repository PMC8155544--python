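"""Screen a patient's variants against a known infertility gene panel.

A variant qualifies if it is loss-of-function, or missense with CADD >= 20,
and rare (gnomAD MAF <= 0.01 for homozygous, <= 0.001 for heterozygous
calls; missing MAF counts as 0). For recessive genes a hit additionally
requires a homozygous qualifying variant or a likely compound-heterozygous
state, i.e. two distinct qualifying variants in the same gene in the same
patient (phase is unknown).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum

from .cascade import FilterConfig, effective_maf
from .variants import AnnotatedVariant, ConsequenceClass, Zygosity, zygosity

logger = logging.getLogger(__name__)

CADD_MIN = 20.0  # missense deleteriousness gate (~top 1% of CADD)


class Inheritance(str, Enum):
    RECESSIVE = "recessive"
    NON_RECESSIVE = "non_recessive"


class HitRationale(str, Enum):
    LOF = "lof"
    MISSENSE_CADD = "missense_cadd"
    COMPOUND_HET = "compound_het"
    HOMOZYGOUS = "homozygous"


@dataclass(frozen=True)
class PanelGene:
    gene: str
    inheritance: Inheritance


@dataclass(frozen=True)
class ScreenHit:
    sample_id: str
    gene: str
    variants: tuple  # of (AnnotatedVariant, Zygosity)
    rationale: HitRationale


def variant_qualifies(variant: AnnotatedVariant, call_zygosity: Zygosity) -> bool:
    """Effect gate (LoF, or missense with CADD >= 20) plus the rarity gate."""
    cls = variant.consequence_class
    if cls is ConsequenceClass.LOF:
        effect_ok = True
    elif cls is ConsequenceClass.MISSENSE:
        if variant.cadd is None:
            logger.debug("missense %s lacks a CADD score; never qualifies", variant.key)
            effect_ok = False
        else:
            effect_ok = variant.cadd >= CADD_MIN
    else:
        effect_ok = False
    if not effect_ok:
        return False
    maf = effective_maf(variant)
    cfg = FilterConfig()
    if call_zygosity is Zygosity.HOMOZYGOUS_ALT:
        return maf <= cfg.hom_maf_max
    if call_zygosity is Zygosity.HETEROZYGOUS:
        return maf <= cfg.het_maf_max
    return False


def screen_patient(
    sample_id: str, variants: list[AnnotatedVariant], panel: list[PanelGene]
) -> list[ScreenHit]:
    """Apply qualification and inheritance rules for one patient.

    Variants in genes absent from the panel are ignored. Output ordering is
    independent of the input variant order.
    """
    modes = {p.gene: p.inheritance for p in panel}
    qualifying: dict[str, list] = {}
    for v in variants:
        mode = modes.get(v.gene)
        if mode is None:
            continue
        for call in v.calls:
            if call.sample_id != sample_id:
                continue
            zyg = zygosity(call)
            if zyg in (Zygosity.HOMOZYGOUS_ALT, Zygosity.HETEROZYGOUS) and variant_qualifies(v, zyg):
                qualifying.setdefault(v.gene, []).append((v, zyg))

    hits = []
    for gene in sorted(qualifying):
        found = sorted(set(qualifying[gene]), key=lambda t: (t[0].key, t[1].value))
        mode = modes[gene]
        zygs = [z for _, z in found]
        if mode is Inheritance.RECESSIVE:
            if Zygosity.HOMOZYGOUS_ALT in zygs:
                rationale = HitRationale.HOMOZYGOUS
            elif len({v.key for v, _ in found}) >= 2:
                rationale = HitRationale.COMPOUND_HET
            else:
                continue  # single heterozygous variant in a recessive gene: no hit
        else:
            if any(v.consequence_class is ConsequenceClass.LOF for v, _ in found):
                rationale = HitRationale.LOF
            else:
                rationale = HitRationale.MISSENSE_CADD
        hits.append(ScreenHit(sample_id, gene, tuple(found), rationale))
    return hits
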