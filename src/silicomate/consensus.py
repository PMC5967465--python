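"""Coordinate-preserving consensus calling from reads mapped to a reference.

The consensus of the mapped query reads is built per reference sequence and
keeps the reference coordinate system: the output has exactly one base per
reference position, so fragment distances measured on the consensus equal
distances on the reference.  Positions with no (or insufficient) mapped
evidence become N, as do positions that are N (hard-masked) in the
reference itself.  Where the query carries two alleles, the consensus emits
the two-fold IUPAC ambiguity code, so allelic differences survive into the
sampled scaffolding libraries.

The caller is a deliberately simple majority/ambiguity model: a column is
called N below ``min_call_depth``; otherwise the majority base; the IUPAC
code of the top two bases is emitted when the second-ranked allele reaches
both ``min_allele_count`` reads and an ``allele_fraction`` share of the
column.  Columns where a third allele also passes those thresholds fall
back to the majority base (only two-fold codes are emitted, reflecting a
diploid query).  Indels are ignored: insertions never enter the consensus
and deleted positions are called from whatever reads still cover them —
this is what preserves the coordinate system.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Iterator, Sequence

import numpy as np

from .io_formats import (
    AlignmentRecord,
    FastqRecord,
    SequenceRecord,
    _open_text,
    parse_cigar,
)

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}

# base -> small int for vectorized counting; 255 marks non-ACGT (ignored)
_CODE_LUT = np.full(256, 255, dtype=np.uint8)
for _b, _i in _BASE_INDEX.items():
    _CODE_LUT[ord(_b)] = _i
    _CODE_LUT[ord(_b.lower())] = _i

# two-fold IUPAC ambiguity codes, indexed by the two base codes
_AMBIG = {
    frozenset("AG"): "R",
    frozenset("CT"): "Y",
    frozenset("GC"): "S",
    frozenset("AT"): "W",
    frozenset("GT"): "K",
    frozenset("AC"): "M",
}
_AMBIG_LUT = np.zeros((4, 4), dtype="U1")
for _i in range(4):
    for _j in range(4):
        if _i != _j:
            _AMBIG_LUT[_i, _j] = _AMBIG[frozenset(_BASES[_i] + _BASES[_j])]
        else:
            _AMBIG_LUT[_i, _j] = _BASES[_i]

QUAL_CAP = 40  # consensus quality = min(depth, QUAL_CAP), Phred+33


@dataclass
class ConsensusParams:
    """Filter and calling thresholds for consensus construction.

    Defaults: every mapped primary read contributes (min_mapq 0), bases
    below Phred 13 are dropped, a single read suffices to call a base, and
    a second allele needs >=2 reads making up >=25% of the column to emit
    an ambiguity code.
    """

    min_mapq: int = 0
    min_baseq: int = 13
    min_call_depth: int = 1
    allele_fraction: float = 0.25
    min_allele_count: int = 2
    keep_secondary: bool = False
    keep_supplementary: bool = False


@dataclass
class PileupColumn:
    """Read-base evidence over one reference position (0-based)."""

    ref_id: str
    ref_pos: int
    counts: Dict[str, int]

    @property
    def depth(self) -> int:
        return sum(self.counts.values())


@dataclass
class ConsensusRecord:
    """Consensus bases plus per-position depth for one reference sequence."""

    id: str
    bases: str
    depths: np.ndarray  # int array, len == len(bases)

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths, dtype=np.int64)
        if len(self.bases) != len(self.depths):
            raise ValueError(
                f"consensus {self.id!r}: {len(self.bases)} bases vs "
                f"{len(self.depths)} depths"
            )

    def __len__(self) -> int:
        return len(self.bases)


# ---------------------------------------------------------------------------
# pileup accumulation
# ---------------------------------------------------------------------------

def _record_passes(rec: AlignmentRecord, params: ConsensusParams) -> bool:
    if rec.is_unmapped:
        return False
    if rec.is_secondary and not params.keep_secondary:
        return False
    if rec.is_supplementary and not params.keep_supplementary:
        return False
    return rec.mapq >= params.min_mapq


def _add_to_counts(rec: AlignmentRecord, counts: np.ndarray, min_baseq: int) -> None:
    """Add one alignment's M/=/X bases to a (4, L) count matrix."""
    L = counts.shape[1]
    seq = np.frombuffer(rec.seq.encode("ascii"), dtype=np.uint8)
    codes = _CODE_LUT[seq]
    if rec.qual != "*":
        quals = np.frombuffer(rec.qual.encode("ascii"), dtype=np.uint8)
        qok = quals >= 33 + min_baseq
    else:
        qok = np.ones(len(seq), dtype=bool)
    rpos = rec.pos - 1
    qpos = 0
    for op, n in parse_cigar(rec.cigar):
        if op in "M=X":
            if rpos + n > L:
                raise ValueError(
                    f"alignment {rec.qname!r} extends to reference position "
                    f"{rpos + n} beyond reference length {L}"
                )
            seg = slice(qpos, qpos + n)
            mask = (codes[seg] < 4) & qok[seg]
            if mask.any():
                np.add.at(
                    counts,
                    (codes[seg][mask], np.arange(rpos, rpos + n)[mask]),
                    1,
                )
            rpos += n
            qpos += n
        elif op in "IS":
            qpos += n
        elif op in "DN":
            rpos += n


def pileup_counts(
    alignments: Iterable[AlignmentRecord],
    ref: SequenceRecord,
    params: ConsensusParams | None = None,
) -> np.ndarray:
    """Count passing read bases per reference position; shape (4, len(ref)).

    Alignments need not be sorted; the full count matrix for the reference
    is held in memory (4 ints per reference base).
    """
    params = params or ConsensusParams()
    counts = np.zeros((4, len(ref.bases)), dtype=np.int64)
    for rec in alignments:
        if rec.rname != ref.id or not _record_passes(rec, params):
            continue
        _add_to_counts(rec, counts, params.min_baseq)
    return counts


def accumulate_pileup(
    alignments: Iterable[AlignmentRecord],
    ref: SequenceRecord,
    min_mapq: int = 0,
    min_baseq: int = 13,
) -> Iterator[PileupColumn]:
    """Yield one column per reference position with at least one passing base."""
    params = ConsensusParams(min_mapq=min_mapq, min_baseq=min_baseq)
    counts = pileup_counts(alignments, ref, params)
    depth = counts.sum(axis=0)
    for pos in np.nonzero(depth)[0]:
        col = {b: int(counts[i, pos]) for b, i in _BASE_INDEX.items() if counts[i, pos]}
        yield PileupColumn(ref_id=ref.id, ref_pos=int(pos), counts=col)


# ---------------------------------------------------------------------------
# calling
# ---------------------------------------------------------------------------

def call_consensus_base(
    col: PileupColumn,
    min_call_depth: int = 1,
    allele_fraction: float = 0.25,
    min_allele_count: int = 2,
) -> str:
    """Call one column: N below min depth, else majority or two-fold IUPAC."""
    depth = col.depth
    if depth < min_call_depth or depth == 0:
        return "N"
    # stable descending sort; ties broken toward A<C<G<T
    ranked = sorted(_BASES, key=lambda b: (-col.counts.get(b, 0), b))
    top, second, third = ranked[0], ranked[1], ranked[2]

    def _passes(b: str) -> bool:
        c = col.counts.get(b, 0)
        return c >= min_allele_count and c >= allele_fraction * depth - 1e-9

    if _passes(second) and not _passes(third):
        return _AMBIG[frozenset(top + second)]
    return top


def _call_array(
    counts: np.ndarray, ref_bases: str, params: ConsensusParams
) -> str:
    """Vectorized consensus call over a whole reference sequence."""
    depth = counts.sum(axis=0)
    order = np.argsort(-counts, axis=0, kind="stable")
    top, second, third = order[0], order[1], order[2]
    ar = np.arange(counts.shape[1])
    c2 = counts[second, ar]
    c3 = counts[third, ar]
    frac_floor = params.allele_fraction * depth - 1e-9
    sec_pass = (c2 >= params.min_allele_count) & (c2 >= frac_floor)
    third_pass = (c3 >= params.min_allele_count) & (c3 >= frac_floor)
    letters = np.array(list(_BASES), dtype="U1")
    calls = np.where(sec_pass & ~third_pass, _AMBIG_LUT[top, second], letters[top])
    calls[depth < max(params.min_call_depth, 1)] = "N"
    ref_arr = np.frombuffer(ref_bases.encode("ascii"), dtype=np.uint8)
    calls[ref_arr == ord("N")] = "N"  # hard masking is preserved
    return "".join(calls)


def build_consensus(
    alignments: Iterable[AlignmentRecord],
    refs: Iterable[SequenceRecord],
    params: ConsensusParams | None = None,
) -> Iterator[ConsensusRecord]:
    """Build one ConsensusRecord per reference sequence, in reference order.

    Alignments may arrive in any order; count matrices for all references
    are held in memory simultaneously.  An alignment naming a reference not
    present in *refs* is an error.
    """
    params = params or ConsensusParams()
    ref_list = list(refs)
    by_name = {r.id: r for r in ref_list}
    matrices = {r.id: np.zeros((4, len(r.bases)), dtype=np.int64) for r in ref_list}
    for rec in alignments:
        if not _record_passes(rec, params):
            continue
        if rec.rname not in matrices:
            raise ValueError(f"alignment {rec.qname!r} maps to unknown reference {rec.rname!r}")
        _add_to_counts(rec, matrices[rec.rname], params.min_baseq)
    for ref in ref_list:
        counts = matrices[ref.id]
        bases = _call_array(counts, ref.bases.upper(), params)
        depths = counts.sum(axis=0)
        # masked / uncalled positions report their evidence depth regardless;
        # bases carry the N, depths stay the raw passing-base counts
        yield ConsensusRecord(id=ref.id, bases=bases, depths=depths)


# ---------------------------------------------------------------------------
# FASTQ / depth-track serialization
# ---------------------------------------------------------------------------

def depth_quals(depths: np.ndarray) -> str:
    """Phred+33 string encoding min(depth, 40) per position."""
    capped = np.minimum(np.asarray(depths, dtype=np.int64), QUAL_CAP) + 33
    return capped.astype(np.uint8).tobytes().decode("ascii")


def consensus_to_fastq(rec: ConsensusRecord) -> FastqRecord:
    """One FASTQ record per reference sequence; quality encodes depth."""
    return FastqRecord(id=rec.id, bases=rec.bases, quals=depth_quals(rec.depths))


def write_depth_track(records: Iterable[ConsensusRecord], path: str | Path) -> None:
    """Sidecar depth track: ref_id, 0-based position, depth (depth > 0 only)."""
    with open(path, "wt") as out:
        out.write("#ref_id\tpos0\tdepth\n")
        for rec in records:
            for pos in np.nonzero(rec.depths)[0]:
                out.write(f"{rec.id}\t{pos}\t{rec.depths[pos]}\n")


def load_consensus(
    fastq_path: str | Path, depths_path: str | Path | None = None
) -> list[ConsensusRecord]:
    """Load consensus records from FASTQ (+ optional exact depth sidecar).

    Without the sidecar, depths are decoded from the quality string and are
    therefore capped at 40; with it, exact depths are restored.
    """
    from .io_formats import read_fastq

    records: list[ConsensusRecord] = []
    index: dict[str, int] = {}
    for fq in read_fastq(fastq_path):
        depths = np.frombuffer(fq.quals.encode("ascii"), dtype=np.uint8).astype(np.int64) - 33
        index[fq.id] = len(records)
        records.append(ConsensusRecord(id=fq.id, bases=fq.bases, depths=depths))
    if depths_path is not None:
        for rec in records:
            rec.depths = np.zeros(len(rec.bases), dtype=np.int64)
        with _open_text(depths_path) as handle:
            for line in handle:
                if line.startswith("#") or not line.strip():
                    continue
                ref_id, pos, depth = line.rstrip("\n").split("\t")
                records[index[ref_id]].depths[int(pos)] = int(depth)
    return records
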