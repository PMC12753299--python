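"""Read recruitment: alignment ingestion, identity filtering, and pileups.

Alignments (SAM/BAM, e.g. the simulator's truth SAM or an external mapper's
output) are reduced to :class:`RecruitedRead` records carrying per-read edit
counts and alignment identity, then filtered with the study's recruitment
contract (identity >= 95%, non-discordant pairing, best match per read) and
tallied into a per-position A/C/G/T pileup — the raw material for nucleotide
diversity, depth, and breadth.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pysam
from Bio import SeqIO

from ._dna import encode
from .synthgen import Genome

__all__ = [
    "RecruitedRead",
    "PileupMatrix",
    "load_reference",
    "load_alignments",
    "alignment_identity",
    "apply_filters",
    "build_pileup",
]

# pysam CIGAR operation codes
_OP_M, _OP_I, _OP_D, _OP_N, _OP_S = 0, 1, 2, 3, 4
_OP_EQ, _OP_X = 7, 8
_ALN_OPS = (_OP_M, _OP_EQ, _OP_X)
_CIGAR_CHARS = "MIDNSHP=XB"


@dataclass(slots=True)
class RecruitedRead:
    """One aligned read, the unit of ANIr.

    ``identity`` is gap-columns identity: every inserted or deleted base
    counts as one non-matching alignment column,
    ``n_match / (n_match + n_mismatch + n_ins + n_del)``. Soft-clipped
    columns are excluded from both numerator and denominator.
    """

    read_id: str
    ref_id: str
    ref_start: int
    cigartuples: tuple[tuple[int, int], ...]
    sequence: str
    n_match: int
    n_mismatch: int
    n_ins: int
    n_del: int
    identity: float
    is_paired: bool = False
    mate_number: int = 0
    mate_unmapped: bool = True
    mate_ref_id: str | None = None

    @property
    def cigar(self) -> str:
        return "".join(f"{ln}{_CIGAR_CHARS[op]}" for op, ln in self.cigartuples)

    @property
    def paired_ok(self) -> bool:
        """False only when a mapped mate points at a different reference."""
        if not self.is_paired or self.mate_unmapped:
            return True
        return self.mate_ref_id == self.ref_id


@dataclass
class PileupMatrix:
    """Per-reference-position A/C/G/T counts (shape ``(ref_length, 4)``)."""

    ref_id: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape[1] != 4:
            raise ValueError("counts must have shape (ref_length, 4)")

    @property
    def ref_length(self) -> int:
        return self.counts.shape[0]

    @property
    def depths(self) -> np.ndarray:
        return self.counts.sum(axis=1)


def load_reference(path: str | Path, record_id: str | None = None) -> Genome:
    """Read a single reference genome from a FASTA file."""
    for rec in SeqIO.parse(str(path), "fasta"):
        if record_id is None or rec.id == record_id:
            return Genome(rec.id, str(rec.seq).upper())
    raise ValueError(f"no FASTA record {record_id!r} in {path}")


def load_alignments(path: str | Path, ref: Genome) -> list[RecruitedRead]:
    """Load primary alignments against ``ref`` from a SAM/BAM file.

    Unmapped, secondary, and supplementary records are excluded. Edit counts
    come from the CIGAR plus the NM tag when present; otherwise mismatches
    are re-derived by comparing aligned columns to the reference.
    """
    ref_codes = np.array(encode(ref.sequence))
    reads: list[RecruitedRead] = []
    with pysam.AlignmentFile(str(path), check_sq=False) as af:
        for rec in af:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            if rec.reference_name != ref.id:
                raise ValueError(
                    f"record {rec.query_name!r} maps to unknown reference "
                    f"{rec.reference_name!r} (expected {ref.id!r})"
                )
            reads.append(_to_recruited(rec, ref, ref_codes))
    return reads


def _to_recruited(rec: pysam.AlignedSegment, ref: Genome,
                  ref_codes: np.ndarray) -> RecruitedRead:
    cig = tuple(rec.cigartuples or ())
    seq = rec.query_sequence or ""
    q_span = sum(ln for op, ln in cig if op in (*_ALN_OPS, _OP_I, _OP_S))
    if q_span != len(seq):
        raise ValueError(
            f"record {rec.query_name!r}: CIGAR consumes {q_span} query bases "
            f"but sequence has {len(seq)}"
        )
    aligned = sum(ln for op, ln in cig if op in _ALN_OPS)
    n_ins = sum(ln for op, ln in cig if op == _OP_I)
    n_del = sum(ln for op, ln in cig if op in (_OP_D, _OP_N))
    n_mm = -1
    if rec.has_tag("NM"):
        nm = int(rec.get_tag("NM"))
        n_mm = nm - n_ins - n_del
    if not 0 <= n_mm <= aligned:  # absent or inconsistent NM: re-derive
        n_mm = count_mismatches(seq, cig, rec.reference_start, ref_codes)
    n_match = aligned - n_mm
    return RecruitedRead(
        read_id=rec.query_name,
        ref_id=ref.id,
        ref_start=rec.reference_start,
        cigartuples=cig,
        sequence=seq,
        n_match=n_match,
        n_mismatch=n_mm,
        n_ins=n_ins,
        n_del=n_del,
        identity=alignment_identity(n_match, n_mm, n_ins, n_del),
        is_paired=rec.is_paired,
        mate_number=(2 if rec.is_read2 else 1) if rec.is_paired else 0,
        mate_unmapped=rec.mate_is_unmapped if rec.is_paired else True,
        mate_ref_id=rec.next_reference_name if rec.is_paired else None,
    )


def count_mismatches(seq: str, cigartuples: Sequence[tuple[int, int]],
                     ref_start: int, ref_codes: np.ndarray) -> int:
    """Count mismatching aligned columns by direct reference comparison."""
    codes = encode(seq)
    q = 0
    p = ref_start
    n_mm = 0
    for op, ln in cigartuples:
        if op in _ALN_OPS:
            n_mm += int(np.count_nonzero(codes[q:q + ln] != ref_codes[p:p + ln]))
            q += ln
            p += ln
        elif op in (_OP_I, _OP_S):
            q += ln
        elif op in (_OP_D, _OP_N):
            p += ln
    return n_mm


def alignment_identity(n_match: int, n_mismatch: int, n_ins: int,
                       n_del: int) -> float:
    """Fraction of matching alignment columns (gaps count as columns)."""
    if min(n_match, n_mismatch, n_ins, n_del) < 0:
        raise ValueError("edit counts must be non-negative")
    cols = n_match + n_mismatch + n_ins + n_del
    if cols == 0:
        raise ValueError("alignment has no columns")
    return n_match / cols


def apply_filters(reads: Iterable[RecruitedRead], min_identity: float = 0.95,
                  pairing: str = "non_discordant",
                  best_match: bool = True) -> list[RecruitedRead]:
    """Apply the recruitment contract.

    Reads with identity below ``min_identity`` are dropped (boundary
    inclusive: identity == min_identity is kept). Under ``non_discordant``
    pairing a read is dropped only when its mapped mate points at a different
    reference. Under ``best_match`` a single alignment is kept per read
    (and per mate): the highest identity, ties broken by leftmost
    ``ref_start``, then lexicographic ``ref_id``. Idempotent.
    """
    if not 0.0 <= min_identity <= 1.0:
        raise ValueError("min_identity must lie in [0, 1]")
    if pairing not in ("non_discordant", "none"):
        raise ValueError("pairing must be 'non_discordant' or 'none'")
    kept = [r for r in reads if r.identity >= min_identity]
    if pairing == "non_discordant":
        kept = [r for r in kept if r.paired_ok]
    if not best_match:
        return kept
    best: dict[tuple[str, int], tuple[int, RecruitedRead]] = {}
    for idx, r in enumerate(kept):
        key = (r.read_id, r.mate_number)
        prev = best.get(key)
        if prev is None:
            best[key] = (idx, r)
            continue
        p = prev[1]
        if (-r.identity, r.ref_start, r.ref_id) < (-p.identity, p.ref_start,
                                                   p.ref_id):
            best[key] = (idx, r)
    return [r for _, r in sorted(best.values(), key=lambda t: t[0])]


def build_pileup(reads: Iterable[RecruitedRead], ref: Genome) -> PileupMatrix:
    """Tally recruited reads into per-position nucleotide counts.

    Match/mismatch CIGAR columns increment the count of the read base at the
    reference position; insertions contribute nothing; deletions leave gaps
    at the spanned positions; non-ACGT read bases are skipped.
    """
    L = ref.length
    counts = np.zeros((L, 4), dtype=np.int32)
    flat = counts.reshape(-1)
    for r in reads:
        codes = encode(r.sequence)
        q = 0
        p = r.ref_start
        for op, ln in r.cigartuples:
            if op in _ALN_OPS:
                if p + ln > L or p < 0:
                    raise ValueError(
                        f"read {r.read_id!r} overhangs the reference "
                        f"({p}..{p + ln} on length {L})"
                    )
                seg = codes[q:q + ln]
                pos = np.arange(p, p + ln)
                valid = seg < 4
                if not valid.all():
                    seg = seg[valid]
                    pos = pos[valid]
                np.add.at(flat, pos * 4 + seg, 1)
                q += ln
                p += ln
            elif op in (_OP_I, _OP_S):
                q += ln
            elif op in (_OP_D, _OP_N):
                p += ln
    return PileupMatrix(ref.id, counts)
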