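"""Synthetic strain-mixture metagenomes with parametric sequencing-error models.

This module builds the ground-truth side of the study: an ancestor genome, a
set of conspecific strains derived from it by point substitutions (pairwise
ANI >= 95%, i.e. within the species boundary), log-normally distributed strain
abundances, and shotgun reads carrying insertion/deletion/mismatch errors
drawn from a five-parameter profile. Every read is emitted together with its
true alignment to the ancestor (SAM with CIGAR and NM) and a truth table, so
downstream recruitment and diversity estimates can be validated exactly.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
from Bio import SeqIO

from ._dna import BASES, decode, encode, revcomp

__all__ = [
    "Genome",
    "StrainEdits",
    "StrainSet",
    "AbundanceProfile",
    "ErrorProfile",
    "ERROR_FREE",
    "Q20",
    "Q30",
    "SimulatedRead",
    "SimulationResult",
    "generate_ancestor",
    "derive_strain_set",
    "sample_lognormal_abundances",
    "simulate_reads",
    "simulate_metagenome",
    "shred_reads",
    "apply_edits",
]

_ACGT = frozenset("ACGT")


@dataclass(frozen=True)
class Genome:
    """A DNA sequence with a label; alphabet restricted to A/C/G/T."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        bad = set(self.sequence) - _ACGT
        if bad:
            raise ValueError(
                f"genome {self.id!r} contains non-ACGT characters: {sorted(bad)!r}"
            )
        if not self.sequence:
            raise ValueError(f"genome {self.id!r} is empty")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class StrainEdits:
    """Substitutions distinguishing one strain from the ancestor.

    ``positions`` are 0-based ancestor coordinates (sorted, unique);
    ``bases`` are the replacement base codes (uint8, A=0..T=3), each
    guaranteed to differ from the ancestor base at that position.
    """

    positions: np.ndarray
    bases: np.ndarray

    def __len__(self) -> int:
        return len(self.positions)


@dataclass(frozen=True)
class StrainSet:
    """Ancestor plus derived strains with known edit lists and pairwise ANI."""

    ancestor: Genome
    strains: list[Genome]
    edits: list[StrainEdits]
    pairwise_ani: np.ndarray

    @property
    def n_strains(self) -> int:
        return len(self.strains)


@dataclass(frozen=True)
class AbundanceProfile:
    """Relative abundances of the strains; strictly positive, summing to 1."""

    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        if w.ndim != 1 or len(w) < 1:
            raise ValueError("weights must be a non-empty 1-D array")
        if np.any(w <= 0):
            raise ValueError("all abundance weights must be > 0")
        if abs(w.sum() - 1.0) > 1e-12:
            raise ValueError("abundance weights must sum to 1 within 1e-12")

    def __len__(self) -> int:
        return len(self.weights)


@dataclass(frozen=True)
class ErrorProfile:
    """Per-base sequencing-error event probabilities.

    One categorical event is drawn per read base: insertion (one uniform base
    inserted after the position), deletion (the base is dropped), or mismatch
    (uniform over the 3 alternative bases). The elevated mismatch rates
    ``p_mm_start``/``p_mm_end`` apply only within the first ``start_window``
    and last ``end_window`` bases of the read (read orientation) and add to
    ``p_mm`` there.
    """

    p_ins: float
    p_del: float
    p_mm: float
    p_mm_start: float
    p_mm_end: float
    start_window: int = 10
    end_window: int = 10

    def __post_init__(self) -> None:
        probs = (self.p_ins, self.p_del, self.p_mm, self.p_mm_start, self.p_mm_end)
        if any(p < 0 or p >= 1 for p in probs):
            raise ValueError("event probabilities must lie in [0, 1)")
        if sum(probs) >= 1:
            raise ValueError("event probabilities must sum to < 1")
        if self.start_window < 0 or self.end_window < 0:
            raise ValueError("windows must be non-negative")

    @property
    def is_error_free(self) -> bool:
        return (self.p_ins + self.p_del + self.p_mm
                + self.p_mm_start + self.p_mm_end) == 0.0

    def mismatch_prob(self, read_length: int) -> np.ndarray:
        """Position-dependent mismatch probability along a read."""
        m = np.full(read_length, self.p_mm, dtype=float)
        m[: self.start_window] += self.p_mm_start
        if self.end_window:
            m[max(0, read_length - self.end_window):] += self.p_mm_end
        return m

    @classmethod
    def from_name(cls, name: str) -> "ErrorProfile":
        try:
            return _PRESETS[name.lower()]
        except KeyError:
            raise ValueError(
                f"unknown error profile {name!r}; choose from {sorted(_PRESETS)}"
            ) from None


ERROR_FREE = ErrorProfile(0.0, 0.0, 0.0, 0.0, 0.0)
#: roughly one error per 1,000 bp
Q20 = ErrorProfile(0.001, 0.001, 0.006, 0.001, 0.001)
#: roughly one error per 10,000 bp
Q30 = ErrorProfile(0.0001, 0.0001, 0.0006, 0.0001, 0.0001)

_PRESETS = {"none": ERROR_FREE, "error-free": ERROR_FREE, "q20": Q20, "q30": Q30}


@dataclass(slots=True)
class SimulatedRead:
    """One simulated read with full ground truth.

    ``sequence`` and ``edits`` are in read orientation (as sequenced);
    ``sam_sequence``/``cigar`` are in reference orientation. Edit tuples are
    ``(offset_in_read, kind, base)`` where *base* is the read base for
    mismatches/insertions and the dropped source base for deletions.
    Mismatch/indel counts are against the ANCESTOR (strain substitutions
    composed with sequencing errors), matching the truth SAM's NM tag.
    """

    id: str
    source_strain: str
    start: int
    strand: str
    sequence: str
    edits: list[tuple[int, str, str]]
    true_identity: float
    cigar: str
    sam_sequence: str
    n_match: int
    n_mismatch: int
    n_ins: int
    n_del: int


@dataclass(frozen=True)
class SimulationResult:
    fastq: Path
    sam: Path
    truth: Path
    n_reads: int


# ---------------------------------------------------------------------------
# genomes and communities
# ---------------------------------------------------------------------------

def generate_ancestor(length: int, gc_fraction: float = 0.5, seed: int = 0,
                      genome_id: str = "ancestor") -> Genome:
    """Generate an i.i.d. random ancestor genome.

    Bases are drawn independently with P(G) + P(C) = ``gc_fraction``,
    reproducibly under a fixed seed.
    """
    if length < 1000:
        raise ValueError("ancestor length must be >= 1000 bp")
    if not 0.0 <= gc_fraction <= 1.0:
        raise ValueError("gc_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    at, gc = (1.0 - gc_fraction) / 2.0, gc_fraction / 2.0
    codes = rng.choice(4, size=length, p=[at, gc, gc, at]).astype(np.uint8)
    return Genome(genome_id, decode(codes))


def derive_strain_set(ancestor: Genome, n_strains: int,
                      divergence_range: tuple[float, float] = (0.0, 0.0249),
                      seed: int = 0) -> StrainSet:
    """Derive conspecific strains from an ancestor by point substitutions.

    Strain 1 is the ancestor itself (divergence 0). Each further strain k
    carries ``round(d_k * L)`` substitutions at distinct uniformly sampled
    positions, with d_k drawn uniformly from ``divergence_range``. Pairwise
    ANI is computed exactly from the edit lists, not by re-alignment.
    """
    lo, hi = divergence_range
    if n_strains < 1:
        raise ValueError("n_strains must be >= 1")
    if not (0.0 <= lo <= hi):
        raise ValueError("divergence_range must satisfy 0 <= min <= max")
    if hi >= 0.05:
        raise ValueError(
            "divergence above 5% would leave the >=95% identity recruitment regime"
        )
    rng = np.random.default_rng(seed)
    L = ancestor.length
    anc = np.array(encode(ancestor.sequence))  # writable copy

    strains = [Genome(f"{ancestor.id}|strain_1", ancestor.sequence)]
    empty = np.array([], dtype=np.int64)
    edits = [StrainEdits(empty, empty.astype(np.uint8))]
    for k in range(2, n_strains + 1):
        d = rng.uniform(lo, hi)
        n_sub = int(round(d * L))
        if n_sub > L:
            raise ValueError("requested substitutions exceed genome length")
        pos = np.sort(rng.choice(L, size=n_sub, replace=False))
        shift = rng.integers(1, 4, size=n_sub, dtype=np.uint8)
        new = (anc[pos] + shift) % 4
        codes = anc.copy()
        codes[pos] = new
        strains.append(Genome(f"{ancestor.id}|strain_{k}", decode(codes)))
        edits.append(StrainEdits(pos, new.astype(np.uint8)))

    ani = np.ones((n_strains, n_strains))
    for i in range(n_strains):
        for j in range(i + 1, n_strains):
            diff = _edit_distance(edits[i], edits[j])
            ani[i, j] = ani[j, i] = 1.0 - diff / L
    return StrainSet(ancestor, strains, edits, ani)


def _edit_distance(a: StrainEdits, b: StrainEdits) -> int:
    """Hamming distance between two strains, from their ancestor edit lists."""
    common, ia, ib = np.intersect1d(a.positions, b.positions,
                                    assume_unique=True, return_indices=True)
    same = int(np.count_nonzero(a.bases[ia] == b.bases[ib]))
    return len(a) + len(b) - len(common) - same


def sample_lognormal_abundances(n_strains: int, sigma: float = 1.0,
                                seed: int = 0) -> AbundanceProfile:
    """Sample relative abundances proportional to exp(Normal(0, sigma^2))."""
    if n_strains < 1:
        raise ValueError("n_strains must be >= 1")
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    rng = np.random.default_rng(seed)
    w = np.exp(rng.normal(0.0, sigma, size=n_strains))
    return AbundanceProfile(w / w.sum())


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

_EV_NONE, _EV_INS, _EV_DEL, _EV_MM = 0, 1, 2, 3


def _iter_simulated_reads(strain_set: StrainSet, abundances: AbundanceProfile,
                          n_reads: int, read_length: int,
                          error_profile: ErrorProfile, rng: np.random.Generator,
                          per_read: bool = False,
                          batch_size: int = 20_000) -> Iterator[list[SimulatedRead]]:
    """Yield batches of simulated reads (the streaming core of the simulator)."""
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    if len(abundances) != strain_set.n_strains:
        raise ValueError("abundance profile length does not match strain count")
    L = strain_set.ancestor.length
    if any(g.length != L for g in strain_set.strains):
        raise ValueError("strains must share the ancestor length")
    if read_length > L or read_length < 1:
        raise ValueError("read_length must lie in [1, shortest strain length]")

    strain_strs = [g.sequence for g in strain_set.strains]
    strain_codes = [np.array(encode(s)) for s in strain_strs]
    strain_ids = [g.id for g in strain_set.strains]
    edit_pos = [e.positions for e in strain_set.edits]
    anc_codes = np.array(encode(strain_set.ancestor.sequence))
    rl = read_length

    mm_prob = error_profile.mismatch_prob(rl)
    t_ins = error_profile.p_ins
    t_del = t_ins + error_profile.p_del
    t_total = t_del + mm_prob  # position-dependent upper threshold
    error_free = error_profile.is_error_free

    emitted = 0
    while emitted < n_reads:
        b = min(batch_size, n_reads - emitted)
        sidx = rng.choice(strain_set.n_strains, size=b, p=abundances.weights)
        starts = rng.integers(0, L - rl + 1, size=b)
        minus = rng.integers(0, 2, size=b).astype(bool)

        if error_free:
            has_event = np.zeros(b, dtype=bool)
            u = None
        elif per_read:
            evc_rows = _per_read_events(error_profile, rl, b, rng)
            has_event = np.array([r is not None for r in evc_rows])
            u = None
        else:
            u = rng.random((b, rl))
            has_event = (u < t_total).any(axis=1)

        batch: list[SimulatedRead] = []
        for r in range(b):
            s = int(sidx[r])
            start = int(starts[r])
            strand = "-" if minus[r] else "+"
            rid = f"r{emitted + r}"
            if not has_event[r]:
                batch.append(_fast_read(rid, strain_strs[s], strain_ids[s],
                                        edit_pos[s], start, rl, strand))
                continue
            if per_read:
                evc = evc_rows[r]
            else:
                row = u[r]
                evc = np.zeros(rl, dtype=np.uint8)
                evc[row < t_total] = _EV_MM
                evc[row < t_del] = _EV_DEL
                evc[row < t_ins] = _EV_INS
            batch.append(_edited_read(rid, strain_codes[s], anc_codes,
                                      strain_ids[s], start, rl, strand, evc, rng))
        emitted += b
        yield batch


def _per_read_events(profile: ErrorProfile, rl: int, b: int,
                     rng: np.random.Generator) -> list[np.ndarray | None]:
    """Per-read interpretation: each probability is per read, one event each."""
    rows: list[np.ndarray | None] = []
    sw = min(profile.start_window, rl)
    ew = min(profile.end_window, rl)
    for _ in range(b):
        evc = np.zeros(rl, dtype=np.uint8)
        any_ev = False
        for p, code, lo, hi in (
            (profile.p_ins, _EV_INS, 0, rl),
            (profile.p_del, _EV_DEL, 0, rl),
            (profile.p_mm, _EV_MM, 0, rl),
            (profile.p_mm_start, _EV_MM, 0, sw),
            (profile.p_mm_end, _EV_MM, rl - ew, rl),
        ):
            if p > 0 and hi > lo and rng.random() < p:
                evc[int(rng.integers(lo, hi))] = code
                any_ev = True
        rows.append(evc if any_ev else None)
    return rows


def _fast_read(rid: str, strain_str: str, strain_id: str, edit_pos: np.ndarray,
               start: int, rl: int, strand: str) -> SimulatedRead:
    """Error-free read: an exact window of the strain genome."""
    window = strain_str[start:start + rl]
    lo = int(np.searchsorted(edit_pos, start))
    hi = int(np.searchsorted(edit_pos, start + rl))
    n_mm = hi - lo  # strain substitutions always differ from the ancestor
    seq = revcomp(window) if strand == "-" else window
    return SimulatedRead(
        id=rid, source_strain=strain_id, start=start, strand=strand,
        sequence=seq, edits=[], true_identity=(rl - n_mm) / rl,
        cigar=f"{rl}M", sam_sequence=window,
        n_match=rl - n_mm, n_mismatch=n_mm, n_ins=0, n_del=0,
    )


def _edited_read(rid: str, strain: np.ndarray, anc: np.ndarray, strain_id: str,
                 start: int, rl: int, strand: str, evc: np.ndarray,
                 rng: np.random.Generator) -> SimulatedRead:
    src = strain[start:start + rl]
    oriented = (3 - src[::-1]) if strand == "-" else src

    out: list[int] = []
    ops: list[list] = []  # run-merged [op, length] in read orientation
    edits: list[tuple[int, str, str]] = []

    def add_op(op: str) -> None:
        if ops and ops[-1][0] == op:
            ops[-1][1] += 1
        else:
            ops.append([op, 1])

    for i in range(rl):
        base = int(oriented[i])
        e = evc[i]
        if e == _EV_NONE:
            out.append(base)
            add_op("M")
        elif e == _EV_MM:
            nb = (base + 1 + int(rng.integers(3))) % 4
            edits.append((len(out), "mismatch", BASES[nb]))
            out.append(nb)
            add_op("M")
        elif e == _EV_INS:
            out.append(base)
            add_op("M")
            ib = int(rng.integers(4))
            edits.append((len(out), "insertion", BASES[ib]))
            out.append(ib)
            add_op("I")
        else:  # deletion
            edits.append((len(out), "deletion", BASES[base]))
            add_op("D")

    out_codes = np.array(out, dtype=np.uint8)
    if strand == "-":
        sam_codes = 3 - out_codes[::-1]
        sam_ops = ops[::-1]
    else:
        sam_codes = out_codes
        sam_ops = ops

    # count matches/mismatches against the ancestor, column by column
    anc_seg = anc[start:start + rl]
    q = p = n_mm = n_match = n_ins = n_del = 0
    for op, ln in sam_ops:
        if op == "M":
            d = int(np.count_nonzero(sam_codes[q:q + ln] != anc_seg[p:p + ln]))
            n_mm += d
            n_match += ln - d
            q += ln
            p += ln
        elif op == "I":
            n_ins += ln
            q += ln
        else:
            n_del += ln
            p += ln

    cols = n_match + n_mm + n_ins + n_del
    return SimulatedRead(
        id=rid, source_strain=strain_id, start=start, strand=strand,
        sequence=decode(out_codes), edits=edits,
        true_identity=n_match / cols,
        cigar="".join(f"{ln}{op}" for op, ln in sam_ops),
        sam_sequence=decode(sam_codes),
        n_match=n_match, n_mismatch=n_mm, n_ins=n_ins, n_del=n_del,
    )


def apply_edits(source_window: str, edits: Sequence[tuple[int, str, str]]) -> str:
    """Replay an edit list onto the (read-oriented) source window.

    This is the composition oracle: for every simulated read,
    ``apply_edits(source_window, read.edits) == read.sequence``.
    """
    out: list[str] = []
    si = 0
    for off, kind, base in edits:
        while len(out) < off:
            out.append(source_window[si])
            si += 1
        if kind == "mismatch":
            out.append(base)
            si += 1
        elif kind == "insertion":
            out.append(base)
        elif kind == "deletion":
            si += 1
        else:
            raise ValueError(f"unknown edit kind {kind!r}")
    out.append(source_window[si:])
    return "".join(out)


def simulate_reads(strain_set: StrainSet, abundances: AbundanceProfile,
                   n_reads: int, read_length: int = 150,
                   error_profile: ErrorProfile = ERROR_FREE, seed: int = 0,
                   per_read: bool = False) -> list[SimulatedRead]:
    """Simulate reads fully in memory (convenience for small runs and tests)."""
    rng = np.random.default_rng(seed)
    reads: list[SimulatedRead] = []
    for batch in _iter_simulated_reads(strain_set, abundances, n_reads,
                                       read_length, error_profile, rng,
                                       per_read=per_read):
        reads.extend(batch)
    return reads


def simulate_metagenome(strain_set: StrainSet, abundances: AbundanceProfile,
                        n_reads: int, read_length: int = 150,
                        error_profile: ErrorProfile = ERROR_FREE, seed: int = 0,
                        out_prefix: str | Path = "metagenome",
                        per_read: bool = False) -> SimulationResult:
    """Simulate a metagenome and write FASTQ, truth SAM, and truth TSV.

    The truth SAM records each read's alignment to the ANCESTOR (strain
    substitutions and sequencing errors composed into CIGAR + NM); FASTQ
    qualities are a constant placeholder ('I'). Outputs are byte-identical
    for identical inputs and seed.
    """
    prefix = Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    fq_path = prefix.with_suffix(".fastq")
    sam_path = prefix.with_suffix(".sam")
    truth_path = prefix.with_suffix(".truth.tsv")

    anc = strain_set.ancestor
    rng = np.random.default_rng(seed)
    with open(fq_path, "w") as fq, open(sam_path, "w") as sam, \
            open(truth_path, "w") as tt:
        sam.write("@HD\tVN:1.6\tSO:unsorted\n")
        sam.write(f"@SQ\tSN:{anc.id}\tLN:{anc.length}\n")
        sam.write("@PG\tID:microdepth\tPN:microdepth\n")
        tt.write("read_id\tstrain\tstart\tstrand\tn_mismatch\tn_ins\tn_del\t"
                 "true_identity\n")
        for batch in _iter_simulated_reads(strain_set, abundances, n_reads,
                                           read_length, error_profile, rng,
                                           per_read=per_read):
            fq_lines, sam_lines, tt_lines = [], [], []
            for rd in batch:
                qual = "I" * len(rd.sequence)
                fq_lines.append(f"@{rd.id}\n{rd.sequence}\n+\n{qual}\n")
                flag = 16 if rd.strand == "-" else 0
                sam_lines.append(
                    f"{rd.id}\t{flag}\t{anc.id}\t{rd.start + 1}\t60\t{rd.cigar}"
                    f"\t*\t0\t0\t{rd.sam_sequence}\t{qual}"
                    f"\tNM:i:{rd.n_mismatch + rd.n_ins + rd.n_del}\n")
                tt_lines.append(
                    f"{rd.id}\t{rd.source_strain}\t{rd.start}\t{rd.strand}\t"
                    f"{rd.n_mismatch}\t{rd.n_ins}\t{rd.n_del}\t"
                    f"{rd.true_identity:.10g}\n")
            fq.write("".join(fq_lines))
            sam.write("".join(sam_lines))
            tt.write("".join(tt_lines))
    return SimulationResult(fq_path, sam_path, truth_path, n_reads)


# ---------------------------------------------------------------------------
# long-read shredding
# ---------------------------------------------------------------------------

def shred_reads(in_fastq: str | Path, out_fastq: str | Path,
                fragment_length: int = 200, keep_terminal: bool = True) -> int:
    """Cut every read into consecutive non-overlapping fragments.

    Mirrors the common practice of shredding long reads into short fragments
    before recruitment so that short- and long-read data can be compared on
    an equal footing. Returns the number of fragments written. The terminal
    fragment shorter than ``fragment_length`` is kept unless
    ``keep_terminal=False``.
    """
    if fragment_length < 1:
        raise ValueError("fragment_length must be >= 1")
    n_out = 0
    with open(out_fastq, "w") as out:
        for rec in SeqIO.parse(str(in_fastq), "fastq"):
            seq = str(rec.seq)
            quals = rec.letter_annotations["phred_quality"]
            for k, off in enumerate(range(0, len(seq), fragment_length)):
                frag = seq[off:off + fragment_length]
                if len(frag) < fragment_length and not keep_terminal:
                    continue
                q = "".join(chr(q + 33) for q in quals[off:off + len(frag)])
                out.write(f"@{rec.id}/frag{k + 1}\n{frag}\n+\n{q}\n")
                n_out += 1
    return n_out
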