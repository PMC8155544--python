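"""Growth-competition allele-class dynamics and dye-dilution proliferation.

Competition assays: amplicon reads from a mixed wild-type / CRISPR-mutant
culture are classified per read by the net indel length inside a
quantification window around the cut site — no indel means wild type, a net
length divisible by 3 is an in-frame mutation, anything else a frameshift
(loss of function). Class frequencies per timepoint and their fold changes
summarize the relative fitness of each allele class.

Dye dilution: a proliferation dye's median fluorescence intensity (MFI)
halves with every division, so after background subtraction

    divisions = log2((MFI_day0 - MFI_unstained) / (MFI_final - MFI_unstained))

and the mean cycle duration is elapsed time over divisions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .errors import DataError

#: default half-width (bp) of the quantification window around the cut site
DEFAULT_WINDOW_HALFWIDTH = 10


@dataclass(frozen=True)
class IndelEvent:
    """One indel in amplicon coordinates: insertions positive, deletions negative."""

    position: int  # 0-based amplicon coordinate
    length: int  # signed; never zero

    def __post_init__(self):
        if self.length == 0:
            raise DataError("indel events must have non-zero signed length")
        if self.position < 0:
            raise DataError("indel position must be non-negative")

    def overlaps(self, window: tuple[int, int]) -> bool:
        start, end = window
        if self.length > 0:  # insertion sits between two reference bases
            return start <= self.position < end
        return self.position < end and self.position - self.length > start


@dataclass(frozen=True)
class ReadCall:
    """Per-read indel summary from an editing-outcome caller."""

    read_id: str
    events: tuple[IndelEvent, ...] = ()
    substitution_only: bool = False

    def __post_init__(self):
        if self.substitution_only and self.events:
            raise DataError(f"read {self.read_id}: substitution_only but indels present")
        object.__setattr__(self, "events", tuple(self.events))


def window_around(center: int, halfwidth: int = DEFAULT_WINDOW_HALFWIDTH) -> tuple[int, int]:
    """Half-open quantification window around a 0-based cut-site coordinate."""
    if halfwidth < 0:
        raise DataError("window halfwidth must be non-negative")
    return (max(0, center - halfwidth), center + halfwidth)


def net_indel_length(read: ReadCall, window: tuple[int, int]) -> int:
    """Sum of signed lengths of the read's indels overlapping the window."""
    return sum(e.length for e in read.events if e.overlaps(window))


def classify_read(read: ReadCall, window: tuple[int, int]) -> str:
    """wild_type / in_frame / frameshift by net indel length in the window.

    Substitution-only reads leave the frame intact and count as wild type.
    """
    overlapping = [e for e in read.events if e.overlaps(window)]
    if not overlapping:
        return "wild_type"
    net = sum(e.length for e in overlapping)
    return "in_frame" if net % 3 == 0 else "frameshift"


@dataclass(frozen=True)
class AlleleClassCounts:
    wild_type: int
    in_frame: int
    frameshift: int

    def __post_init__(self):
        if min(self.wild_type, self.in_frame, self.frameshift) < 0:
            raise DataError("class counts must be non-negative")

    @property
    def total_reads(self) -> int:
        return self.wild_type + self.in_frame + self.frameshift

    @classmethod
    def from_reads(cls, reads, window: tuple[int, int]) -> "AlleleClassCounts":
        tally = {"wild_type": 0, "in_frame": 0, "frameshift": 0}
        for read in reads:
            tally[classify_read(read, window)] += 1
        return cls(**tally)


def class_frequencies(counts: AlleleClassCounts) -> dict[str, float]:
    """Per-class fractions; sums to 1 within 1e-12."""
    total = counts.total_reads
    if total == 0:
        raise DataError("cannot compute class frequencies from zero reads")
    return {
        "wild_type": counts.wild_type / total,
        "in_frame": counts.in_frame / total,
        "frameshift": counts.frameshift / total,
    }


@dataclass
class CompetitionSeries:
    """Ordered timepoints (label, hours) with per-timepoint class counts."""

    timepoints: list  # of (label, hours, AlleleClassCounts)

    def __post_init__(self):
        hours = [h for _, h, _ in self.timepoints]
        if len(hours) < 2:
            raise DataError("a competition series needs at least two timepoints")
        if any(b <= a for a, b in zip(hours, hours[1:])):
            raise DataError("timepoint hours must be strictly increasing")

    def frequency_table(self) -> pd.DataFrame:
        rows = []
        for label, hours, counts in self.timepoints:
            freqs = class_frequencies(counts)
            rows.append({"timepoint": label, "hours": hours, "total_reads": counts.total_reads, **freqs})
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class FoldChange:
    ratio: float | None
    fold: int | None
    infinite: bool = False


def frequency_fold_change(f_start: float, f_end: float) -> FoldChange:
    """f_start / f_end with its nearest-integer fold; f_end = 0 flags infinity."""
    if f_start < 0 or f_end < 0:
        raise DataError("frequencies must be non-negative")
    if f_end == 0:
        return FoldChange(ratio=None, fold=None, infinite=True)
    ratio = f_start / f_end
    return FoldChange(ratio=ratio, fold=round(ratio), infinite=False)


@dataclass(frozen=True)
class DyeMeasurement:
    """Background-referenced dye MFIs bracketing one culture interval."""

    mfi_day0: float
    mfi_final: float
    mfi_unstained: float
    elapsed_hours: float

    def __post_init__(self):
        if self.elapsed_hours <= 0:
            raise DataError("elapsed_hours must be positive")
        if self.mfi_day0 <= self.mfi_unstained:
            raise DataError("day-0 MFI must exceed the unstained background")
        if self.mfi_final <= self.mfi_unstained:
            raise DataError("final MFI must exceed the unstained background")


def division_number(m: DyeMeasurement) -> float:
    """log2 of the background-subtracted MFI ratio (halving per division)."""
    return math.log2((m.mfi_day0 - m.mfi_unstained) / (m.mfi_final - m.mfi_unstained))


def mean_cycle_duration(m: DyeMeasurement) -> float:
    """Elapsed hours per division; undefined at zero divisions."""
    divisions = division_number(m)
    if divisions <= 0:
        raise DataError("cycle duration undefined for zero (or negative) divisions")
    return m.elapsed_hours / divisions


# --- plain-text input formats -------------------------------------------------

def parse_event_token(token: str) -> IndelEvent:
    """Parse one ``<signed length>@<position>`` token, e.g. ``+17@102``."""
    try:
        length_str, pos_str = token.split("@")
        return IndelEvent(position=int(pos_str), length=int(length_str))
    except (ValueError, TypeError) as exc:
        raise DataError(f"malformed indel event token {token!r}") from exc


def read_indel_call_table(path) -> list[ReadCall]:
    """TSV with columns read_id, events (semicolon-separated), substitution_only."""
    df = pd.read_csv(path, sep="\t", dtype={"read_id": str}, keep_default_na=False)
    required = {"read_id", "events", "substitution_only"}
    if not required <= set(df.columns):
        raise DataError(f"indel call table {path} needs columns {sorted(required)}")
    reads = []
    for row in df.itertuples(index=False):
        events = tuple(
            parse_event_token(tok) for tok in str(row.events).split(";") if tok.strip()
        )
        sub_only = str(row.substitution_only).strip().lower() in {"1", "true", "yes"}
        reads.append(ReadCall(row.read_id, events, sub_only))
    return reads


def read_series_manifest(path) -> list[tuple[str, float, str]]:
    """Manifest TSV: one (label, hours, per-timepoint call table path) per row."""
    df = pd.read_csv(path, sep="\t")
    if not {"timepoint", "hours", "path"} <= set(df.columns):
        raise DataError(f"manifest {path} needs columns timepoint, hours, path")
    return [(str(r.timepoint), float(r.hours), str(r.path)) for r in df.itertuples(index=False)]


def load_competition_series(manifest_path, window: tuple[int, int]) -> CompetitionSeries:
    """Build a series by classifying every timepoint's reads in the window."""
    from pathlib import Path

    base = Path(manifest_path).parent
    timepoints = []
    for label, hours, rel in read_series_manifest(manifest_path):
        table = Path(rel)
        if not table.is_absolute():
            table = base / table
        if not table.is_file():
            raise DataError(f"timepoint table not found: {table}")
        reads = read_indel_call_table(table)
        timepoints.append((label, hours, AlleleClassCounts.from_reads(reads, window)))
    return CompetitionSeries(timepoints)
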