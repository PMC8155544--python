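"""Seeded synthetic cohorts, competition read sets and dye-dilution series.

Every generator is a pure function of its config (which carries the seed):
rerunning with the same config produces byte-identical files. The cohort
generator emulates the input structure of the real study — a case cohort of
men with Sertoli cell-only phenotype, a smaller control cohort with intact
spermatogenesis, a gnomAD-like allele-frequency table and a GTEx-like tissue
expression table — with known ground truth:

* planted causal genes carry loss-of-function case variants that pass every
  cascade filter (novel, quality-passing, testis-dominant expression, absent
  from controls), recurring in a configurable number of distinct patients;
* each decoy gene violates exactly one designed filter (common MAF, low call
  quality, heterozygous-MAF gate, low testis expression, or a LoF hit in a
  control) and satisfies all the others;
* the remaining background genes carry rare missense case variants, so they
  enter the cascade and leave at the effect filter.

The competition generator grows allele classes exponentially with
class-specific cycle times, n_x(t) = n_x(0) * 2^(t/T_x), and samples read
counts multinomially from the abundance shares. The dye generator follows
mfi(t) = background + (mfi0 - background) * 2^(-t/T) with optional
multiplicative lognormal noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .assays import AlleleClassCounts, CompetitionSeries, DyeMeasurement
from .errors import ConfigurationError

CHROMOSOMES = tuple(str(i) for i in range(1, 23)) + ("X",)

GTEX_LIKE_TISSUES = (
    "testis",
    "brain",
    "heart",
    "liver",
    "lung",
    "kidney",
    "muscle",
    "skin",
    "spleen",
    "pancreas",
    "colon",
    "stomach",
    "thyroid",
)

_LOF_TEMPLATES = (
    ("stop_gained", "C", "T"),
    ("frameshift_variant", "AT", "A"),
    ("splice_acceptor_variant", "G", "A"),
    ("splice_donor_variant", "G", "T"),
)

#: decoy class -> cascade stage designed to remove it
DECOY_STAGES = {
    "common_maf": "effect_and_rarity",
    "low_quality": "quality",
    "het_maf_fail": "genotype_maf",
    "low_testis": "expression",
    "control_hit": "control_exclusion",
}


def _default_decoys() -> dict[str, int]:
    return {name: 1 for name in DECOY_STAGES}


@dataclass
class CohortSimConfig:
    """Study conditions for the synthetic prioritization cohort.

    Cohort sizes default to the real study design: 247 case exomes with the
    SCO phenotype and 89 controls with intact spermatogenesis. The gene
    universe is a scaled stand-in for the exome. Planted genes recur in 1-4
    distinct patients, cycling through ``recurrence_cycle``.
    """

    seed: int = 0
    n_cases: int = 247
    n_controls: int = 89
    n_genes: int = 120
    n_planted: int = 5
    decoys: dict = field(default_factory=_default_decoys)
    recurrence_cycle: tuple = (1, 2, 3, 4)
    background_maf_beta: tuple = (0.5, 200.0)
    depth_range: tuple = (20, 60)
    tissues: tuple = GTEX_LIKE_TISSUES

    def __post_init__(self):
        unknown = set(self.decoys) - set(DECOY_STAGES)
        if unknown:
            raise ConfigurationError(f"unknown decoy classes: {sorted(unknown)}")
        if any(n < 0 for n in self.decoys.values()) or self.n_planted < 0:
            raise ConfigurationError("planted and decoy counts must be non-negative")
        if self.n_planted + sum(self.decoys.values()) > self.n_genes:
            raise ConfigurationError("more planted + decoy genes than genes in total")
        if self.n_cases < max(self.recurrence_cycle, default=1):
            raise ConfigurationError("n_cases too small for the recurrence cycle")
        if "testis" not in {t.lower() for t in self.tissues}:
            raise ConfigurationError("tissue list must include testis")


@dataclass(frozen=True)
class SyntheticTruth:
    """Planted genes, per-decoy designed failing stage, per-gene recurrence."""

    planted: tuple
    decoy_stages: dict  # gene -> stage name
    recurrence: dict  # planted gene -> distinct case carriers

    def expected_stage_counts(self, cfg: CohortSimConfig) -> list[tuple[str, int, int]]:
        """Gene-level audit counts implied by the construction."""
        d = {name: cfg.decoys.get(name, 0) for name in DECOY_STAGES}
        n_in = cfg.n_genes
        out1 = cfg.n_planted + sum(d.values()) - d["common_maf"]
        out2 = out1 - d["low_quality"]
        out3 = out2 - d["het_maf_fail"]
        out4 = out3 - d["low_testis"]
        out5 = out4 - d["control_hit"]
        return [
            ("effect_and_rarity", n_in, out1),
            ("quality", out1, out2),
            ("genotype_maf", out2, out3),
            ("expression", out3, out4),
            ("control_exclusion", out4, out5),
        ]

    def to_json(self) -> str:
        return json.dumps(
            {
                "planted": list(self.planted),
                "decoy_stages": dict(sorted(self.decoy_stages.items())),
                "recurrence": dict(sorted(self.recurrence.items())),
            },
            indent=2,
        )


@dataclass(frozen=True)
class CohortPaths:
    case_vcf: Path
    control_vcf: Path
    annotations: Path
    frequencies: Path
    expression: Path
    truth: Path


@dataclass
class _SimVariant:
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    consequence: str
    cadd: float | None
    maf: float | None  # None = absent from the frequency table (novel)
    case_carriers: dict  # sample -> (gt, dp, ad)
    control_carriers: dict


def _write_vcf(path: Path, samples: list[str], variants: list[_SimVariant], carriers_attr: str) -> None:
    order = {c: i for i, c in enumerate(CHROMOSOMES)}
    lines = ["##fileformat=VCFv4.2", '##source=haystack-synthetic']
    for c in CHROMOSOMES:
        lines.append(f"##contig=<ID={c}>")
    lines += [
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples),
    ]
    for v in sorted(variants, key=lambda v: (order[v.chrom], v.pos, v.alt)):
        carriers = getattr(v, carriers_attr)
        fields = [v.chrom, str(v.pos), ".", v.ref, v.alt, ".", "PASS", ".", "GT:DP:AD"]
        for s in samples:
            if s in carriers:
                gt, dp, ad = carriers[s]
            else:
                gt, dp, ad = "0/0", 30, 0
            fields.append(f"{gt}:{dp}:{dp - ad},{ad}")
        lines.append("\t".join(fields))
    path.write_text("\n".join(lines) + "\n")


def simulate_prioritization_cohort(
    cfg: CohortSimConfig, out_dir
) -> tuple[CohortPaths, SyntheticTruth]:
    """Emit case/control VCFs, sidecar, frequency and expression tables + truth."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)

    cases = [f"CASE{i + 1:03d}" for i in range(cfg.n_cases)]
    controls = [f"CTRL{i + 1:03d}" for i in range(cfg.n_controls)]

    genes = [f"GENE{i + 1:04d}" for i in range(cfg.n_genes)]
    planted = tuple(genes[: cfg.n_planted])
    decoy_genes: dict[str, str] = {}
    cursor = cfg.n_planted
    for cls in DECOY_STAGES:  # fixed class order keeps the layout deterministic
        for _ in range(cfg.decoys.get(cls, 0)):
            decoy_genes[genes[cursor]] = cls
            cursor += 1
    background = genes[cursor:]

    recurrence = {
        g: int(cfg.recurrence_cycle[i % len(cfg.recurrence_cycle)])
        for i, g in enumerate(planted)
    }

    dp_lo, dp_hi = cfg.depth_range

    def good_call(gt: str = "0/1") -> tuple[str, int, int]:
        dp = int(rng.integers(dp_lo, dp_hi + 1))
        ad = max(4, int(round(dp * 0.5)))
        return (gt, dp, ad)

    def bad_quality_call() -> tuple[str, int, int]:
        dp = int(rng.integers(5, 10))  # DP < 10 fails the depth gate
        return ("0/1", dp, max(1, dp // 2))

    variants: list[_SimVariant] = []
    for i, gene in enumerate(genes):
        chrom = CHROMOSOMES[i % len(CHROMOSOMES)]
        pos = 100_000 + 10_000 * i
        if gene in planted or gene in decoy_genes:
            term, ref, alt = _LOF_TEMPLATES[int(rng.integers(len(_LOF_TEMPLATES)))]
            cls = decoy_genes.get(gene)
            maf = {"common_maf": 0.02, "het_maf_fail": 0.0047}.get(cls)
            n_carriers = recurrence.get(gene, 1)
            picked = sorted(rng.choice(cfg.n_cases, size=n_carriers, replace=False).tolist())
            if cls == "low_quality":
                case_carriers = {cases[j]: bad_quality_call() for j in picked}
            else:
                case_carriers = {cases[j]: good_call() for j in picked}
            control_carriers = {}
            if cls == "control_hit" and cfg.n_controls:
                ctrl = int(rng.integers(cfg.n_controls))
                control_carriers = {controls[ctrl]: good_call()}
            variants.append(
                _SimVariant(chrom, pos, ref, alt, gene, term, None, maf, case_carriers, control_carriers)
            )
        else:
            # background gene: one rare missense case variant
            carrier = cases[int(rng.integers(cfg.n_cases))]
            maf = float(rng.beta(*cfg.background_maf_beta))
            cadd = float(rng.uniform(0, 35))
            variants.append(
                _SimVariant(chrom, pos, "A", "G", gene, "missense_variant", cadd, maf, {carrier: good_call()}, {})
            )

    # --- expression table --------------------------------------------------
    tissues = list(cfg.tissues)
    other_tissues = [t for t in tissues if t.lower() != "testis"]
    expression_rows = []
    for gene in genes:
        others = rng.uniform(1.0, 100.0, size=len(other_tissues))
        peak = float(others.max())
        cls = decoy_genes.get(gene)
        if cls == "low_testis":
            frac = 0.4
        elif gene in planted or cls is not None:
            frac = float(rng.uniform(0.6, 0.999))
        else:
            frac = float(rng.uniform(0.05, 0.95))
        values = {"testis": frac * peak}
        values.update({t: float(v) for t, v in zip(other_tissues, others)})
        expression_rows.append((gene, [values[t] if t.lower() != "testis" else values["testis"] for t in tissues]))

    paths = CohortPaths(
        case_vcf=out / "cases.vcf",
        control_vcf=out / "controls.vcf",
        annotations=out / "annotations.tsv",
        frequencies=out / "frequencies.tsv",
        expression=out / "expression.tsv",
        truth=out / "truth.json",
    )

    _write_vcf(paths.case_vcf, cases, variants, "case_carriers")
    control_variants = [v for v in variants if v.control_carriers]
    _write_vcf(paths.control_vcf, controls, control_variants, "control_carriers")

    ann = ["chrom\tpos\tref\talt\tgene\tconsequence\tcadd"]
    for v in variants:
        cadd = "" if v.cadd is None else f"{v.cadd:.1f}"
        ann.append(f"{v.chrom}\t{v.pos}\t{v.ref}\t{v.alt}\t{v.gene}\t{v.consequence}\t{cadd}")
    paths.annotations.write_text("\n".join(ann) + "\n")

    freq = ["chrom\tpos\tref\talt\taf"]
    for v in variants:
        if v.maf is not None:
            freq.append(f"{v.chrom}\t{v.pos}\t{v.ref}\t{v.alt}\t{v.maf:.6f}")
    paths.frequencies.write_text("\n".join(freq) + "\n")

    expr = ["gene\t" + "\t".join(tissues)]
    for gene, values in expression_rows:
        expr.append(gene + "\t" + "\t".join(f"{v:.3f}" for v in values))
    paths.expression.write_text("\n".join(expr) + "\n")

    truth = SyntheticTruth(
        planted=planted,
        decoy_stages={g: DECOY_STAGES[cls] for g, cls in decoy_genes.items()},
        recurrence=recurrence,
    )
    paths.truth.write_text(truth.to_json() + "\n")
    return paths, truth


# --- growth competition -------------------------------------------------------

@dataclass
class CompetitionSimConfig:
    """1:1 wild-type vs CRISPR-mutant pool growing with class-specific cycles.

    Defaults mirror the assay design: a mixed culture sampled at days
    0/3/7/14/21, a deep-sequenced amplicon per timepoint, half the alleles
    wild type at mixing, and mutant classes cycling a few hours slower than
    the wild-type doubling time.
    """

    seed: int = 0
    initial_proportions: tuple = (0.50, 0.175, 0.325)  # wild_type, in_frame, frameshift
    cycle_hours: tuple = (38.0, 40.0, 41.94)
    timepoint_hours: tuple = (0.0, 72.0, 168.0, 336.0, 504.0)
    labels: tuple = ("d0", "d3", "d7", "d14", "d21")
    depth: int = 50_000
    cut_site: int = 100  # 0-based amplicon coordinate of the Cas9 cut

    def __post_init__(self):
        if len(self.initial_proportions) != 3 or len(self.cycle_hours) != 3:
            raise ConfigurationError("three allele classes expected")
        if abs(sum(self.initial_proportions) - 1.0) > 1e-9:
            raise ConfigurationError("initial proportions must sum to 1")
        if any(t <= 0 for t in self.cycle_hours):
            raise ConfigurationError("cycle times must be positive")
        if len(self.labels) != len(self.timepoint_hours):
            raise ConfigurationError("labels and timepoint_hours must align")


def expected_class_frequencies(cfg: CompetitionSimConfig, hours: float) -> dict[str, float]:
    """Closed-form model frequencies: n_x(t) = p_x(0) * 2^(t/T_x), normalized."""
    p0 = np.asarray(cfg.initial_proportions, dtype=float)
    cycles = np.asarray(cfg.cycle_hours, dtype=float)
    abundance = p0 * np.exp2(hours / cycles)
    share = abundance / abundance.sum()
    return dict(zip(("wild_type", "in_frame", "frameshift"), share.tolist()))


def simulate_competition_series(
    cfg: CompetitionSimConfig,
) -> tuple[CompetitionSeries, list[dict]]:
    """Multinomial read counts per timepoint plus the exact model frequencies."""
    rng = np.random.default_rng(cfg.seed)
    timepoints, truth = [], []
    for label, hours in zip(cfg.labels, cfg.timepoint_hours):
        freqs = expected_class_frequencies(cfg, hours)
        probs = [freqs["wild_type"], freqs["in_frame"], freqs["frameshift"]]
        wt, inf_, fs = rng.multinomial(cfg.depth, probs).tolist()
        timepoints.append((label, hours, AlleleClassCounts(wt, inf_, fs)))
        truth.append({"timepoint": label, "hours": hours, **freqs})
    return CompetitionSeries(timepoints), truth


def write_competition_tables(
    series: CompetitionSeries, cut_site: int, out_dir
) -> Path:
    """Emit per-timepoint indel-call tables and a manifest; returns manifest path.

    Wild-type reads carry no events, in-frame reads a -3 deletion and
    frameshift reads a +17 insertion at the cut site.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = ["timepoint\thours\tpath"]
    for label, hours, counts in series.timepoints:
        rows = ["read_id\tevents\tsubstitution_only"]
        rid = 0
        for _ in range(counts.wild_type):
            rid += 1
            rows.append(f"r{rid:07d}\t\t0")
        for _ in range(counts.in_frame):
            rid += 1
            rows.append(f"r{rid:07d}\t-3@{cut_site}\t0")
        for _ in range(counts.frameshift):
            rid += 1
            rows.append(f"r{rid:07d}\t+17@{cut_site}\t0")
        name = f"reads_{label}.tsv"
        (out / name).write_text("\n".join(rows) + "\n")
        manifest.append(f"{label}\t{hours:g}\t{name}")
    manifest_path = out / "manifest.tsv"
    manifest_path.write_text("\n".join(manifest) + "\n")
    return manifest_path


# --- dye dilution -------------------------------------------------------------

def simulate_dye_dilution(
    seed: int,
    true_cycle_hours: float,
    mfi0: float = 20_000.0,
    background: float = 150.0,
    noise_sd: float = 0.0,
    timepoint_hours: float = 96.0,
    n_replicates: int = 1,
) -> list[DyeMeasurement]:
    """Dye-dilution measurements under halving-per-division decay.

    Multiplicative lognormal noise (sd on the log scale) is applied to the
    background-subtracted signals; at noise 0 the measurement inverts exactly
    to ``true_cycle_hours`` through division_number / mean_cycle_duration.
    """
    if true_cycle_hours <= 0:
        raise ConfigurationError("true_cycle_hours must be positive")
    rng = np.random.default_rng(seed)
    signal0 = mfi0 - background
    signal_t = signal0 * 2.0 ** (-timepoint_hours / true_cycle_hours)
    out = []
    for _ in range(n_replicates):
        e0 = float(np.exp(rng.normal(0.0, noise_sd))) if noise_sd else 1.0
        et = float(np.exp(rng.normal(0.0, noise_sd))) if noise_sd else 1.0
        out.append(
            DyeMeasurement(
                mfi_day0=background + signal0 * e0,
                mfi_final=background + signal_t * et,
                mfi_unstained=background,
                elapsed_hours=timepoint_hours,
            )
        )
    return out
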