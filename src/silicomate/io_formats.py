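"""Sequence and alignment I/O: FASTA, FASTQ, SAM, and CIGAR projection.

All downstream stages consume the record types defined here.  FASTA and
FASTQ are parsed by small streaming readers that enforce the contracts the
pipeline relies on (unique ids, a declared alphabet, matching base/quality
lengths) and report parse errors with line numbers; SAM goes through pysam.

Coordinate convention: SAM fields are 1-based inclusive as the format
requires; everything internal to this package uses 0-based half-open
intervals, converted only at the SAM boundary.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Sequence, Tuple

import pysam

# IUPAC nucleotide alphabet: the four bases, N, all ambiguity codes.
IUPAC_ALPHABET = frozenset("ACGTUNRYSWKMBDHV")

# SAM flag bits used for pileup filtering.
FLAG_PAIRED = 0x1
FLAG_UNMAPPED = 0x4
FLAG_REVERSE = 0x10
FLAG_READ1 = 0x40
FLAG_READ2 = 0x80
FLAG_SECONDARY = 0x100
FLAG_SUPPLEMENTARY = 0x800

_CIGAR_OPS = set("MIDNSHP=X")
_READ_CONSUMING = set("MIS=X")
_REF_CONSUMING = set("MDN=X")


class ParseError(ValueError):
    """Malformed input file; message names the file and line where known."""


@dataclass
class SequenceRecord:
    """One FASTA record; bases stored uppercase over the IUPAC alphabet."""

    id: str
    bases: str
    description: str = ""

    def __len__(self) -> int:
        return len(self.bases)


@dataclass
class FastqRecord:
    """One FASTQ record with Phred+33 qualities."""

    id: str
    bases: str
    quals: str

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.quals):
            raise ValueError(
                f"record {self.id!r}: {len(self.bases)} bases but "
                f"{len(self.quals)} quality characters"
            )

    def __len__(self) -> int:
        return len(self.bases)


@dataclass
class AlignmentRecord:
    """One SAM alignment line (mandatory fields only)."""

    qname: str
    flag: int
    rname: str
    pos: int  # 1-based leftmost reference coordinate; 0 when unmapped
    mapq: int
    cigar: str
    seq: str
    qual: str

    @property
    def is_unmapped(self) -> bool:
        return bool(self.flag & FLAG_UNMAPPED)

    @property
    def is_secondary(self) -> bool:
        return bool(self.flag & FLAG_SECONDARY)

    @property
    def is_supplementary(self) -> bool:
        return bool(self.flag & FLAG_SUPPLEMENTARY)


def _open_text(path: str | Path) -> IO[str]:
    """Open a possibly gzip-compressed text file transparently."""
    path = Path(path)
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> Iterator[SequenceRecord]:
    """Stream records from a (possibly gzipped, wrapped) FASTA file.

    Bases are uppercased and validated against the IUPAC alphabet; duplicate
    ids and malformed headers raise :class:`ParseError` naming the line.
    """
    seen: set[str] = set()
    header: str | None = None
    header_line = 0
    chunks: list[str] = []

    def _emit() -> SequenceRecord:
        assert header is not None
        bases = "".join(chunks)
        if not bases:
            raise ParseError(f"{path}:{header_line}: record {header!r} has no sequence")
        fields = header.split(None, 1)
        rec_id = fields[0]
        desc = fields[1] if len(fields) > 1 else ""
        if rec_id in seen:
            raise ParseError(f"{path}:{header_line}: duplicate sequence id {rec_id!r}")
        seen.add(rec_id)
        return SequenceRecord(id=rec_id, bases=bases, description=desc)

    with _open_text(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\r\n")
            if not line:
                continue
            if line.startswith(">"):
                if header is not None:
                    yield _emit()
                header = line[1:].strip()
                if not header:
                    raise ParseError(f"{path}:{lineno}: empty FASTA header")
                header_line = lineno
                chunks = []
            else:
                if header is None:
                    raise ParseError(f"{path}:{lineno}: sequence before first header")
                seg = line.upper()
                bad = set(seg) - IUPAC_ALPHABET
                if bad:
                    raise ParseError(
                        f"{path}:{lineno}: illegal sequence character(s) "
                        f"{''.join(sorted(bad))!r}"
                    )
                chunks.append(seg)
        if header is not None:
            yield _emit()


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> int:
    """Write records as wrapped FASTA; returns the record count."""
    n = 0
    with open(path, "wt") as out:
        for rec in records:
            head = rec.id if not rec.description else f"{rec.id} {rec.description}"
            out.write(f">{head}\n")
            for i in range(0, len(rec.bases), width):
                out.write(rec.bases[i : i + width] + "\n")
            n += 1
    return n


# ---------------------------------------------------------------------------
# FASTQ
# ---------------------------------------------------------------------------

def read_fastq(path: str | Path) -> Iterator[FastqRecord]:
    """Stream 4-line FASTQ records (Phred+33), gzip-transparent."""
    with _open_text(path) as handle:
        lineno = 0
        while True:
            head = handle.readline()
            if not head:
                return
            lineno += 1
            head = head.rstrip("\r\n")
            if not head.startswith("@"):
                raise ParseError(f"{path}:{lineno}: expected '@' header, got {head[:20]!r}")
            bases = handle.readline().rstrip("\r\n")
            plus = handle.readline().rstrip("\r\n")
            quals = handle.readline().rstrip("\r\n")
            lineno += 3
            if not plus.startswith("+"):
                raise ParseError(f"{path}:{lineno - 1}: expected '+' separator")
            if len(bases) != len(quals):
                raise ParseError(
                    f"{path}:{lineno}: sequence/quality length mismatch for {head[1:]!r}"
                )
            if quals and not all(33 <= ord(c) <= 126 for c in quals):
                raise ParseError(f"{path}:{lineno}: quality characters outside Phred+33 range")
            yield FastqRecord(id=head[1:].split()[0], bases=bases.upper(), quals=quals)


def write_fastq(records: Iterable[FastqRecord], path: str | Path) -> int:
    n = 0
    with open(path, "wt") as out:
        for rec in records:
            out.write(f"@{rec.id}\n{rec.bases}\n+\n{rec.quals}\n")
            n += 1
    return n


def write_fastq_pair(pairs: Iterable, path1: str | Path, path2: str | Path) -> Tuple[int, int]:
    """Write mate pairs to two synchronized FASTQ files.

    Record i of *path1* is read 1 of pair i and record i of *path2* is its
    mate; ids share the pair name stem and differ only in the ``/1`` vs
    ``/2`` suffix.  Returns the (equal) record counts.
    """
    n1 = n2 = 0
    with open(path1, "wt") as out1, open(path2, "wt") as out2:
        for pair in pairs:
            r1, r2 = pair.read1, pair.read2
            if len(r1.bases) != len(r1.quals) or len(r2.bases) != len(r2.quals):
                raise ValueError(f"pair {pair.name!r}: base/quality length mismatch")
            if len(r1.bases) != len(r2.bases):
                raise ValueError(f"pair {pair.name!r}: mate length mismatch")
            out1.write(f"@{pair.name}/1\n{r1.bases}\n+\n{r1.quals}\n")
            out2.write(f"@{pair.name}/2\n{r2.bases}\n+\n{r2.quals}\n")
            n1 += 1
            n2 += 1
    return n1, n2


# ---------------------------------------------------------------------------
# SAM
# ---------------------------------------------------------------------------

def read_sam(path: str | Path) -> Iterator[AlignmentRecord]:
    """Stream alignment records from a headered SAM file via pysam."""
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for seg in sam:
            qual = (
                pysam.qualities_to_qualitystring(seg.query_qualities)
                if seg.query_qualities is not None
                else "*"
            )
            yield AlignmentRecord(
                qname=seg.query_name or "",
                flag=seg.flag,
                rname=seg.reference_name if seg.reference_name is not None else "*",
                pos=0 if seg.is_unmapped else seg.reference_start + 1,
                mapq=seg.mapping_quality,
                cigar=seg.cigarstring or "*",
                seq=seg.query_sequence or "*",
                qual=qual,
            )


def write_sam(
    records: Iterable[AlignmentRecord],
    references: Sequence[Tuple[str, int]],
    path: str | Path,
) -> int:
    """Write records as headered text SAM; *references* is [(name, length)]."""
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": name, "LN": length} for name, length in references],
    }
    ref_ids = {name: i for i, (name, _) in enumerate(references)}
    n = 0
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for rec in records:
            seg = pysam.AlignedSegment(out.header)
            seg.query_name = rec.qname
            seg.flag = rec.flag
            if rec.is_unmapped or rec.rname == "*":
                seg.reference_id = -1
                seg.reference_start = -1
            else:
                seg.reference_id = ref_ids[rec.rname]
                seg.reference_start = rec.pos - 1
                seg.cigarstring = rec.cigar if rec.cigar != "*" else None
            seg.mapping_quality = rec.mapq
            if rec.seq != "*":
                seg.query_sequence = rec.seq
                if rec.qual != "*":
                    seg.query_qualities = pysam.qualitystring_to_array(rec.qual)
            out.write(seg)
            n += 1
    return n


# ---------------------------------------------------------------------------
# CIGAR projection
# ---------------------------------------------------------------------------

def parse_cigar(cigar: str) -> list[Tuple[str, int]]:
    """Parse a CIGAR string into (op, length) tuples; '*' is rejected."""
    if cigar == "*" or not cigar:
        raise ValueError("cannot parse an absent CIGAR ('*')")
    ops: list[Tuple[str, int]] = []
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        elif ch in _CIGAR_OPS:
            if not num:
                raise ValueError(f"malformed CIGAR {cigar!r}: operation {ch!r} without length")
            ops.append((ch, int(num)))
            num = ""
        else:
            raise ValueError(f"malformed CIGAR {cigar!r}: illegal character {ch!r}")
    if num:
        raise ValueError(f"malformed CIGAR {cigar!r}: trailing number")
    return ops


def cigar_read_length(ops: Sequence[Tuple[str, int]]) -> int:
    return sum(n for op, n in ops if op in _READ_CONSUMING)


def project_alignment(rec: AlignmentRecord) -> list[Tuple[int, str, str]]:
    """Project aligned read bases onto reference coordinates.

    Returns one ``(ref_pos, base, qual)`` tuple per M/=/X base, ref_pos
    1-based; insertions and soft clips consume read only, deletions and
    skips consume reference only, hard clips and padding consume neither.
    """
    if rec.is_unmapped:
        raise ValueError(f"record {rec.qname!r} is unmapped")
    ops = parse_cigar(rec.cigar)
    if rec.seq != "*" and cigar_read_length(ops) != len(rec.seq):
        raise ValueError(
            f"record {rec.qname!r}: CIGAR consumes {cigar_read_length(ops)} read "
            f"bases but sequence has {len(rec.seq)}"
        )
    out: list[Tuple[int, str, str]] = []
    rpos = rec.pos  # 1-based
    qpos = 0
    quals = rec.qual if rec.qual != "*" else "I" * len(rec.seq)
    for op, n in ops:
        if op in "M=X":
            for k in range(n):
                out.append((rpos + k, rec.seq[qpos + k], quals[qpos + k]))
            rpos += n
            qpos += n
        elif op in "IS":
            qpos += n
        elif op in "DN":
            rpos += n
        # H and P consume neither
    return out
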