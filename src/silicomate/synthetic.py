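"""Synthetic genomes, diverged queries, shotgun reads, and truth alignments.

This module manufactures the full input side of the pipeline so every
stage can be exercised closed-loop without external data or a mapper:

* a random background genome with near-identical repeat copies planted at
  known, recorded intervals (the ambiguous-path structure that breaks
  short-read assemblies);
* a diverged "query species" derived from it by independent per-site
  substitutions and small indels, with an exact query-vs-reference
  alignment retained;
* paired-end shotgun reads shredded from the query with normal insert
  sizes, optional base errors, and recorded origins;
* a truth SAM that places every read at its true reference position with
  an indel-aware CIGAR, standing in for the external mapping step;
* a linkage-recovery score: the fraction of repeat-flanking unique-contig
  junctions spanned by at least one simulated mate pair.

Everything is reproducible byte-for-byte from its seed.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Sequence, Tuple

import numpy as np

from .io_formats import (
    AlignmentRecord,
    FastqRecord,
    SequenceRecord,
    FLAG_PAIRED,
    FLAG_READ1,
    FLAG_READ2,
    FLAG_REVERSE,
    FLAG_UNMAPPED,
    write_fastq,
    write_sam,
)
from .matesim import MatePair, LibrarySpec, parse_mate_name, reverse_complement

_LETTERS = np.frombuffer(b"ACGT", dtype=np.uint8)


def _decode(codes: np.ndarray) -> str:
    return _LETTERS[codes].tobytes().decode("ascii")


def _encode(bases: str) -> np.ndarray:
    lut = np.full(256, 4, dtype=np.uint8)
    for i, b in enumerate("ACGT"):
        lut[ord(b)] = i
    return lut[np.frombuffer(bases.encode("ascii"), dtype=np.uint8)]


@dataclass
class SyntheticGenomeSpec:
    """Parameters of one synthetic reference/query genome pair.

    Defaults describe the standard test condition: a 200 kb genome with
    ten 2 kb repeat copies at 98% identity, and a query diverged by 2%
    substitutions plus sparse short indels — divergence on the order of a
    cross-species primate mapping scenario.
    """

    length: int = 200_000
    repeat_copies: int = 10
    repeat_length: int = 2_000
    repeat_identity: float = 0.98
    snp_rate: float = 0.02
    indel_rate: float = 0.001
    indel_max: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        for rate in (self.repeat_identity, self.snp_rate, self.indel_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if self.repeat_copies * self.repeat_length >= self.length:
            raise ValueError("repeats would cover the whole genome")


@dataclass
class ShotgunRead:
    """One shredded read with its true origin on the query."""

    name: str  # includes the /1 or /2 suffix
    bases: str
    quals: str
    qpos: int  # 0-based leftmost query coordinate
    strand: str  # '+' or '-'
    mate: int  # 1 or 2


@dataclass
class SyntheticTruth:
    """Planted structure of one synthetic dataset (oracle bookkeeping)."""

    reference: SequenceRecord
    query: SequenceRecord | None = None
    repeat_intervals_ref: List[Tuple[int, int]] = field(default_factory=list)
    repeat_intervals: List[Tuple[int, int]] = field(default_factory=list)  # query coords
    mutation_table: List[tuple] = field(default_factory=list)
    align_ops: List[Tuple[str, int]] = field(default_factory=list)  # query vs reference
    read_origins: Dict[str, Tuple[int, str]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# reference simulation
# ---------------------------------------------------------------------------

def simulate_reference_with_repeats(spec: SyntheticGenomeSpec) -> SyntheticTruth:
    """Random genome with near-identical repeat copies at recorded intervals.

    One copy is placed per equal-width slot, at a random position inside
    the slot but away from its edges (10% guard margin), so copies never
    overlap and every pair of adjacent copies is separated by a unique
    segment of guaranteed minimum length.
    """
    rng = np.random.default_rng(spec.seed)
    L = spec.length
    genome = rng.integers(0, 4, size=L, dtype=np.uint8)
    element = rng.integers(0, 4, size=spec.repeat_length, dtype=np.uint8)
    intervals: List[Tuple[int, int]] = []
    if spec.repeat_copies > 0:
        slot = L // spec.repeat_copies
        guard = max(1, slot // 10)
        for i in range(spec.repeat_copies):
            lo = i * slot + guard
            hi = (i + 1) * slot - guard - spec.repeat_length
            if hi < lo:
                raise ValueError(
                    f"cannot place {spec.repeat_copies} x {spec.repeat_length} bp "
                    f"repeat copies without overlap in {L} bp"
                )
            start = int(rng.integers(lo, hi + 1))
            copy = element.copy()
            mut = rng.random(spec.repeat_length) < (1.0 - spec.repeat_identity)
            shift = rng.integers(1, 4, size=spec.repeat_length, dtype=np.uint8)
            copy[mut] = (copy[mut] + shift[mut]) % 4
            genome[start : start + spec.repeat_length] = copy
            intervals.append((start, start + spec.repeat_length))
    seq = _decode(genome)
    ref = SequenceRecord(id="synref", bases=seq)
    return SyntheticTruth(
        reference=ref,
        query=SequenceRecord(id="synquery", bases=seq),
        repeat_intervals_ref=list(intervals),
        repeat_intervals=list(intervals),
        align_ops=[("M", L)],
    )


def mask_reference(truth: SyntheticTruth) -> SequenceRecord:
    """Hard-masked reference: repeat intervals replaced by N runs."""
    arr = bytearray(truth.reference.bases, "ascii")
    for s, e in truth.repeat_intervals_ref:
        arr[s:e] = b"N" * (e - s)
    return SequenceRecord(id=truth.reference.id, bases=arr.decode("ascii"))


# ---------------------------------------------------------------------------
# divergence
# ---------------------------------------------------------------------------

def _map_ref_to_query(ops: Sequence[Tuple[str, int]], ref_pos: int) -> int:
    """Query coordinate of a reference position (next query base if deleted)."""
    q = r = 0
    for op, n in ops:
        if op == "M":
            if ref_pos < r + n:
                return q + (ref_pos - r)
            q += n
            r += n
        elif op == "I":
            q += n
        else:  # D
            if ref_pos < r + n:
                return q
            r += n
    return q


def mutate_genome(
    truth: SyntheticTruth,
    snp_rate: float | None = None,
    indel_rate: float | None = None,
    indel_max: int = 10,
    seed: int = 1,
) -> SyntheticTruth:
    """Derive the diverged query from the reference, recording every event.

    Substitutions hit each site independently (uniform choice among the
    three other bases); indel events start at sites drawn at ``indel_rate``
    and are insertions or deletions with equal probability, lengths uniform
    in [1, indel_max].  Updates *truth* in place (query, mutation_table,
    align_ops, query-coordinate repeat intervals) and returns it.

    mutation_table rows: ("SNP", query_pos, ref_base, alt_base),
    ("INS", query_pos, inserted_seq), ("DEL", query_pos, ref_pos, length).
    """
    if snp_rate is None:
        snp_rate = 0.0
    if indel_rate is None:
        indel_rate = 0.0
    rng = np.random.default_rng(seed)
    ref_codes = _encode(truth.reference.bases)
    L = len(ref_codes)
    sub_mask = (rng.random(L) < snp_rate) & (ref_codes < 4)
    shifts = rng.integers(1, 4, size=L, dtype=np.uint8)
    mut_codes = ref_codes.copy()
    mut_codes[sub_mask] = (ref_codes[sub_mask] + shifts[sub_mask]) % 4
    indel_sites = np.nonzero(rng.random(L) < indel_rate)[0]

    parts: List[str] = []
    ops: List[Tuple[str, int]] = []
    table: List[tuple] = []

    def _add_op(op: str, n: int) -> None:
        if n <= 0:
            return
        if ops and ops[-1][0] == op:
            ops[-1] = (op, ops[-1][1] + n)
        else:
            ops.append((op, n))

    qpos = 0
    pos = 0  # reference cursor

    def _emit_match(upto: int) -> None:
        nonlocal qpos, pos
        if upto <= pos:
            return
        block = mut_codes[pos:upto]
        parts.append(_decode(block))
        for off in np.nonzero(sub_mask[pos:upto])[0]:
            table.append(
                (
                    "SNP",
                    qpos + int(off),
                    "ACGT"[ref_codes[pos + off]],
                    "ACGT"[mut_codes[pos + off]],
                )
            )
        _add_op("M", upto - pos)
        qpos += upto - pos
        pos = upto

    for site in indel_sites:
        site = int(site)
        if site < pos:
            continue  # swallowed by a previous deletion
        _emit_match(site)
        k = int(rng.integers(1, indel_max + 1))
        if rng.random() < 0.5:  # insertion before reference position `site`
            ins = _decode(rng.integers(0, 4, size=k, dtype=np.uint8))
            parts.append(ins)
            table.append(("INS", qpos, ins))
            _add_op("I", k)
            qpos += k
        else:  # deletion of reference bases [site, site+k)
            k = min(k, L - site)
            table.append(("DEL", qpos, site, k))
            _add_op("D", k)
            pos = site + k
    _emit_match(L)

    truth.query = SequenceRecord(id="synquery", bases="".join(parts))
    truth.mutation_table = table
    truth.align_ops = ops
    truth.repeat_intervals = [
        (_map_ref_to_query(ops, s), _map_ref_to_query(ops, e))
        for s, e in truth.repeat_intervals_ref
    ]
    return truth


# ---------------------------------------------------------------------------
# read shredding
# ---------------------------------------------------------------------------

def shred_paired_end(
    query: SequenceRecord,
    read_length: int = 100,
    insert_mean: int = 400,
    insert_sd: float = 40.0,
    coverage: float = 30.0,
    error_rate: float = 0.0,
    seed: int = 2,
    id_prefix: str = "sr",
) -> Tuple[List[ShotgunRead], Dict[str, Tuple[int, str]]]:
    """Shred FR paired-end shotgun reads from the query, recording origins.

    Fragment starts are uniform along the query; insert lengths are normal
    (clipped to [2*read_length, len(query)]); each fragment's source strand
    is random.  ``pair count = round(coverage * L / (2 * read_length))``.
    Qualities are constant Phred 40.
    """
    if insert_mean < 2 * read_length:
        raise ValueError("insert_mean must be >= 2 * read_length")
    L = len(query.bases)
    rng = np.random.default_rng(seed)
    n_pairs = int(round(coverage * L / (2 * read_length)))
    inserts = np.clip(
        np.rint(rng.normal(insert_mean, insert_sd, size=n_pairs)).astype(np.int64),
        2 * read_length,
        L,
    )
    starts = rng.integers(0, L - inserts + 1)
    flips = rng.random(n_pairs) < 0.5
    const_quals = "I" * read_length
    reads: List[ShotgunRead] = []
    origins: Dict[str, Tuple[int, str]] = {}

    def _with_errors(bases: str) -> str:
        if error_rate <= 0:
            return bases
        n_err = rng.binomial(len(bases), error_rate)
        if n_err == 0:
            return bases
        arr = _encode(bases)
        idx = rng.choice(len(bases), size=n_err, replace=False)
        arr[idx] = (arr[idx] + rng.integers(1, 4, size=n_err, dtype=np.uint8)) % 4
        return _decode(arr)

    for i in range(n_pairs):
        s = int(starts[i])
        e = s + int(inserts[i])
        fwd = _with_errors(query.bases[s : s + read_length])
        rev = _with_errors(reverse_complement(query.bases[e - read_length : e]))
        stem = f"{id_prefix}{i}"
        if not flips[i]:
            spec1 = (fwd, s, "+")
            spec2 = (rev, e - read_length, "-")
        else:
            spec1 = (rev, e - read_length, "-")
            spec2 = (fwd, s, "+")
        for mate, (bases, qpos, strand) in ((1, spec1), (2, spec2)):
            name = f"{stem}/{mate}"
            reads.append(
                ShotgunRead(
                    name=name, bases=bases, quals=const_quals,
                    qpos=qpos, strand=strand, mate=mate,
                )
            )
            origins[name] = (qpos, strand)
    return reads, origins


def write_reads_fastq(
    reads: Sequence[ShotgunRead], path1: str | Path, path2: str | Path
) -> Tuple[int, int]:
    """Write shredded reads to a /1,/2 FASTQ pair."""
    n1 = write_fastq(
        (FastqRecord(r.name, r.bases, r.quals) for r in reads if r.mate == 1), path1
    )
    n2 = write_fastq(
        (FastqRecord(r.name, r.bases, r.quals) for r in reads if r.mate == 2), path2
    )
    return n1, n2


# ---------------------------------------------------------------------------
# truth alignments
# ---------------------------------------------------------------------------

class _OpIndex:
    """Query-interval -> (reference pos, CIGAR) lookup over the global alignment."""

    def __init__(self, ops: Sequence[Tuple[str, int]]):
        self.ops = list(ops)
        self.qstarts: List[int] = []
        self.rstarts: List[int] = []
        q = r = 0
        for op, n in self.ops:
            self.qstarts.append(q)
            self.rstarts.append(r)
            if op in "MI":
                q += n
            if op in "MD":
                r += n
        self.qlen, self.rlen = q, r

    def map_interval(self, q0: int, q1: int) -> Tuple[int, List[Tuple[str, int]]] | None:
        """0-based reference start + per-read CIGAR, or None if unalignable."""
        items: List[Tuple[str, int, int]] = []  # (op, len, rstart or -1)
        i = bisect.bisect_right(self.qstarts, q0) - 1
        i = max(i, 0)
        while i < len(self.ops):
            op, n = self.ops[i]
            qs, rs = self.qstarts[i], self.rstarts[i]
            if op in "MI":
                if qs >= q1:
                    break
                a, b = max(q0, qs), min(q1, qs + n)
                if b > a:
                    if op == "M":
                        items.append(("M", b - a, rs + (a - qs)))
                    else:
                        items.append(("I", b - a, -1))
            else:  # D: zero query extent; keep only if strictly inside the read
                if qs >= q1:
                    break
                if q0 < qs:
                    items.append(("D", n, -1))
            i += 1
        # trim edges: leading/trailing D dropped, leading/trailing I soft-clipped
        while items and items[0][0] == "D":
            items.pop(0)
        while items and items[-1][0] == "D":
            items.pop()
        if items and items[0][0] == "I":
            items[0] = ("S", items[0][1], -1)
        if items and items[-1][0] == "I":
            items[-1] = ("S", items[-1][1], -1)
        if not any(op == "M" for op, _, _ in items):
            return None
        first_m = next(item for item in items if item[0] == "M")
        merged: List[Tuple[str, int]] = []
        for op, n, _ in items:
            if merged and merged[-1][0] == op:
                merged[-1] = (op, merged[-1][1] + n)
            else:
                merged.append((op, n))
        return first_m[2], merged


def emit_truth_sam(
    reads: Sequence[ShotgunRead],
    truth: SyntheticTruth,
    path: str | Path,
) -> int:
    """Write a SAM placing each read at its true reference location.

    Stands in for the external mapping step in closed-loop tests.  Reads
    lying entirely inside a planted insertion (no reference-aligned base)
    are written as unmapped records.
    """
    index = _OpIndex(truth.align_ops)
    ref = truth.reference

    def _records() -> Iterator[AlignmentRecord]:
        for rd in reads:
            q0, q1 = rd.qpos, rd.qpos + len(rd.bases)
            mapped = index.map_interval(q0, q1)
            flag = FLAG_PAIRED | (FLAG_READ1 if rd.mate == 1 else FLAG_READ2)
            qname = rd.name.rsplit("/", 1)[0]
            if rd.strand == "-":
                seq_fwd = reverse_complement(rd.bases)
                qual_fwd = rd.quals[::-1]
                flag |= FLAG_REVERSE
            else:
                seq_fwd, qual_fwd = rd.bases, rd.quals
            if mapped is None:
                yield AlignmentRecord(
                    qname=qname, flag=flag | FLAG_UNMAPPED, rname="*", pos=0,
                    mapq=0, cigar="*", seq=seq_fwd, qual=qual_fwd,
                )
                continue
            rpos0, cig = mapped
            cigar = "".join(f"{n}{op}" for op, n in cig)
            yield AlignmentRecord(
                qname=qname, flag=flag, rname=ref.id, pos=rpos0 + 1,
                mapq=60, cigar=cigar, seq=seq_fwd, qual=qual_fwd,
            )

    return write_sam(_records(), [(ref.id, len(ref.bases))], path)


# ---------------------------------------------------------------------------
# linkage recovery
# ---------------------------------------------------------------------------

def evaluate_linkage_recovery(
    pairs: Iterable[MatePair],
    truth: SyntheticTruth,
    spec: LibrarySpec,
) -> float:
    """Fraction of repeat junctions spanned by at least one mate pair.

    The unique-sequence contigs are the reference split at the planted
    repeat intervals (mate coordinates live on the reference/consensus
    axis); junction k joins contig k and contig k+1 across repeat k.  A
    junction is recovered when some pair has read 1's footprint entirely
    inside one flanking contig and read 2's entirely inside the other.
    """
    intervals = sorted(truth.repeat_intervals_ref)
    if not intervals:
        raise ValueError("no planted repeats: the recovery fraction is undefined")
    L = len(truth.reference.bases)
    contigs: List[Tuple[int, int]] = []
    prev = 0
    for s, e in intervals:
        contigs.append((prev, s))
        prev = e
    contigs.append((prev, L))
    starts = [c[0] for c in contigs]

    def _locate(a: int, b: int) -> int | None:
        i = bisect.bisect_right(starts, a) - 1
        if i >= 0 and contigs[i][0] <= a and b <= contigs[i][1]:
            return i
        return None

    r = spec.read_length
    recovered: set[int] = set()
    for pair in pairs:
        _, _, start, insert = parse_mate_name(pair.name)
        i1 = _locate(start, start + r)
        i2 = _locate(start + insert - r, start + insert)
        if i1 is None or i2 is None:
            continue
        lo, hi = min(i1, i2), max(i1, i2)
        if hi == lo + 1:
            recovered.add(lo)
    return len(recovered) / len(intervals)
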