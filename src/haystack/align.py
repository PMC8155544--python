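"""Naive global amplicon aligner for raw-read fixtures.

Production input to the competition assays is a pre-called indel table; this
aligner (match 2, mismatch -1, gap open -6, gap extend -1, global) exists so
small raw-read fixtures can be turned into :class:`~haystack.assays.ReadCall`
objects without an external editing-outcome pipeline. Indel events are
reported in reference (amplicon) coordinates; terminal gaps are ignored, so
reads are expected to span the quantification window.
"""

from __future__ import annotations

from Bio import Align

from .assays import IndelEvent, ReadCall
from .errors import DataError

MATCH, MISMATCH, GAP_OPEN, GAP_EXTEND = 2, -1, -6, -1


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = MATCH
    aligner.mismatch_score = MISMATCH
    aligner.open_gap_score = GAP_OPEN
    aligner.extend_gap_score = GAP_EXTEND
    return aligner


def call_read(read_id: str, read_seq: str, reference: str) -> ReadCall:
    """Globally align one read and summarize its indel events."""
    if not read_seq or not reference:
        raise DataError("read and reference sequences must be non-empty")
    alignment = _make_aligner().align(reference, read_seq)[0]
    ref_blocks, read_blocks = alignment.aligned
    events: list[IndelEvent] = []
    mismatches = 0
    for (rs, re_), (qs, qe) in zip(ref_blocks, read_blocks):
        mismatches += sum(1 for i, j in zip(range(rs, re_), range(qs, qe)) if reference[i] != read_seq[j])
    for k in range(1, len(ref_blocks)):
        ref_gap = ref_blocks[k][0] - ref_blocks[k - 1][1]
        read_gap = read_blocks[k][0] - read_blocks[k - 1][1]
        pos = int(ref_blocks[k - 1][1])
        if ref_gap > 0:  # reference bases absent from the read: deletion
            events.append(IndelEvent(position=pos, length=-int(ref_gap)))
        if read_gap > 0:  # extra read bases: insertion at the reference junction
            events.append(IndelEvent(position=pos, length=int(read_gap)))
    substitution_only = not events and mismatches > 0
    return ReadCall(read_id, tuple(events), substitution_only)


def call_reads(reads: dict[str, str], reference: str) -> list[ReadCall]:
    """Align a read_id -> sequence mapping against one amplicon reference."""
    return [call_read(rid, seq, reference) for rid, seq in reads.items()]
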