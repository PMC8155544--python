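"""Readers for the cascade's file inputs.

Formats (all plain text):

* cohort VCF 4.2 with per-sample ``GT:DP:AD`` (read through pysam; multi-allelic
  records are split into one record per alternate allele, AD taken per allele)
* annotation sidecar: TSV with columns ``chrom pos ref alt gene consequence cadd``
* population frequency table: TSV with columns ``chrom pos ref alt af``
* expression table: TSV, first column ``gene``, one column per tissue
  ("testis" required, matched case-insensitively)
* gene panel: TSV with columns ``gene inheritance``
"""

from __future__ import annotations

import logging
import math
import os
from pathlib import Path

import pandas as pd
import pysam

from .errors import ConfigurationError, DataError
from .variants import AnnotatedVariant, GenotypeCall, VariantKey

logger = logging.getLogger(__name__)

SiteKey = tuple[str, int, str, str]


def _require_file(path) -> Path:
    p = Path(path)
    if not p.is_file():
        raise DataError(f"input file not found: {p}")
    return p


def read_cohort_vcf(path) -> tuple[list[str], list[tuple[VariantKey, list[GenotypeCall]]]]:
    """Read a multi-sample VCF into per-allele variant records.

    Returns the sample list and one ``(VariantKey, calls)`` entry per
    alternate allele of every record. Dosage is the count of that allele in
    the GT; DP/AD are taken from FORMAT, AD per allele.
    """
    p = _require_file(path)
    records: list[tuple[VariantKey, list[GenotypeCall]]] = []
    save = pysam.set_verbosity(0)  # silence missing-index chatter
    try:
        with pysam.VariantFile(os.fspath(p)) as vcf:
            samples = list(vcf.header.samples)
            for rec in vcf:
                alts = rec.alts or ()
                for ai, alt in enumerate(alts):
                    key = VariantKey(rec.chrom, rec.pos, rec.ref, alt)
                    calls = []
                    for sample in samples:
                        data = rec.samples[sample]
                        gt = data.get("GT")
                        if gt is None or any(g is None for g in gt):
                            dosage = None
                        else:
                            dosage = sum(1 for g in gt if g == ai + 1)
                        dp = data.get("DP")
                        ad = data.get("AD")
                        alt_depth = None
                        if ad is not None and len(ad) > ai + 1 and ad[ai + 1] is not None:
                            alt_depth = ad[ai + 1]
                        calls.append(GenotypeCall(sample, dosage, dp, alt_depth))
                    records.append((key, calls))
    finally:
        pysam.set_verbosity(save)
    return samples, records


def load_annotation_table(path) -> dict[SiteKey, tuple[str, str, float | None]]:
    """Sidecar table mapping variant site -> (gene, consequence, CADD or None)."""
    p = _require_file(path)
    df = pd.read_csv(p, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
    required = {"chrom", "pos", "ref", "alt", "gene", "consequence", "cadd"}
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"annotation table {p} lacks columns: {sorted(missing)}")
    table: dict[SiteKey, tuple[str, str, float | None]] = {}
    for row in df.itertuples(index=False):
        cadd = None if row.cadd is None or (isinstance(row.cadd, float) and math.isnan(row.cadd)) else float(row.cadd)
        table[(row.chrom, int(row.pos), row.ref, row.alt)] = (row.gene, row.consequence, cadd)
    return table


def load_frequency_table(path) -> dict[SiteKey, float]:
    """Population (gnomAD-like) allele frequencies keyed by variant site."""
    p = _require_file(path)
    df = pd.read_csv(p, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
    required = {"chrom", "pos", "ref", "alt", "af"}
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"frequency table {p} lacks columns: {sorted(missing)}")
    return {
        (row.chrom, int(row.pos), row.ref, row.alt): float(row.af)
        for row in df.itertuples(index=False)
    }


def load_expression_table(path) -> dict[str, "ExpressionProfile"]:
    """Gene x tissue expression (TPM-like); requires a testis column."""
    from .cascade import ExpressionProfile  # local import to avoid a cycle

    p = _require_file(path)
    df = pd.read_csv(p, sep="\t")
    if df.columns[0].lower() != "gene":
        raise DataError(f"expression table {p} must start with a 'gene' column")
    tissues = list(df.columns[1:])
    if not any(t.lower() == "testis" for t in tissues):
        raise ConfigurationError(f"expression table {p} has no testis column")
    profiles = {}
    for row in df.itertuples(index=False):
        gene = row[0]
        profiles[gene] = ExpressionProfile(
            gene=gene, expression={t: float(v) for t, v in zip(tissues, row[1:])}
        )
    return profiles


def load_panel(path):
    """Known infertility gene panel: gene -> inheritance mode."""
    from .panel import Inheritance, PanelGene

    p = _require_file(path)
    df = pd.read_csv(p, sep="\t")
    if not {"gene", "inheritance"} <= set(df.columns):
        raise DataError(f"panel table {p} needs columns gene, inheritance")
    panel = []
    seen = set()
    for row in df.itertuples(index=False):
        if row.gene in seen:
            raise DataError(f"duplicate panel gene {row.gene}")
        seen.add(row.gene)
        panel.append(PanelGene(gene=row.gene, inheritance=Inheritance(row.inheritance)))
    return panel


def annotate_cohort(
    records: list[tuple[VariantKey, list[GenotypeCall]]],
    annotations: dict[SiteKey, tuple[str, str, float | None]],
    frequencies: dict[SiteKey, float],
) -> list[AnnotatedVariant]:
    """Join VCF records with the sidecar annotations and frequency table.

    Records without an annotation entry are dropped (logged): consequences are
    consumed as annotations, never predicted in-house.
    """
    out = []
    for key, calls in records:
        site = (key.chromosome, key.position, key.ref, key.alt)
        ann = annotations.get(site)
        if ann is None:
            logger.warning("no annotation for %s; variant skipped", key)
            continue
        gene, consequence, cadd = ann
        out.append(
            AnnotatedVariant(
                key=key,
                gene=gene,
                consequence=consequence,
                population_maf=frequencies.get(site),
                cadd=cadd,
                calls=tuple(calls),
            )
        )
    return out


def load_annotated_cohort(vcf_path, annotation_path, frequency_path) -> list[AnnotatedVariant]:
    """Convenience loader: VCF + sidecar + frequency table -> AnnotatedVariants."""
    _, records = read_cohort_vcf(vcf_path)
    return annotate_cohort(
        records, load_annotation_table(annotation_path), load_frequency_table(frequency_path)
    )
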