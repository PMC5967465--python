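"""Systematic in silico mate-pair sampling from a consensus sequence.

Fragments of an exact, user-chosen insert size are taken at regularly
spaced offsets along the consensus and their two ends emitted as a read
pair.  The spacing ``s = max(1, floor(2r / c))`` makes the read-base
coverage of interior positions equal the target coverage ``c`` for read
length ``r`` under systematic tiling.  A candidate fragment is emitted only
if every base of both read footprints has pileup depth >= ``min_depth``
(default 3) and is not N, so no read base ever derives from a masked or
under-covered position; the unread interior gap of the fragment is not
inspected.  Sampling is fully deterministic — there is no random number
generator anywhere in this module — and there is no upper bound on the
insert size other than the consensus length itself.

Pair names encode (library label, reference id, 0-based fragment start,
insert size) so that every emitted pair can be re-located exactly on the
consensus by string parsing alone.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence, Tuple

import numpy as np

from .consensus import ConsensusRecord, depth_quals
from .io_formats import write_fastq_pair

_COMPLEMENT = str.maketrans(
    "ACGTUNRYSWKMBDHVacgtunryswkmbdhv",
    "TGCAANYRSWMKVHDBtgcaanyrswmkvhdb",
)
_IUPAC = set("ACGTUNRYSWKMBDHV")


def reverse_complement(s: str) -> str:
    """IUPAC-aware reverse complement (R<->Y, K<->M, S/W/N self)."""
    bad = set(s.upper()) - _IUPAC
    if bad:
        raise ValueError(f"illegal base(s) for reverse complement: {''.join(sorted(bad))!r}")
    return s.translate(_COMPLEMENT)[::-1]


@dataclass
class LibrarySpec:
    """Parameters of one in silico scaffolding library.

    ``insert_size`` is the outer, end-to-end fragment length.  FR is the
    inward-pointing paired-end convention, RF the outward mate-pair one.
    """

    insert_size: int
    read_length: int
    target_coverage: float
    label: str
    orientation: str = "FR"
    min_depth: int = 3

    def __post_init__(self) -> None:
        if self.read_length < 1:
            raise ValueError("read_length must be >= 1")
        if self.insert_size < self.read_length:
            raise ValueError("insert_size must be >= read_length")
        if self.target_coverage <= 0:
            raise ValueError("target_coverage must be > 0")
        if self.orientation not in ("FR", "RF"):
            raise ValueError(f"orientation must be FR or RF, got {self.orientation!r}")
        if not self.label or any(c in self.label for c in ":/ \t"):
            raise ValueError(f"label must be non-empty without ':', '/', whitespace: {self.label!r}")
        if self.insert_size < 2 * self.read_length:
            warnings.warn(
                f"library {self.label!r}: insert {self.insert_size} < 2x read length, "
                "mates will overlap",
                stacklevel=2,
            )


@dataclass
class Read:
    bases: str
    quals: str


@dataclass
class MatePair:
    """One simulated pair; the name round-trips to its source coordinates."""

    name: str
    read1: Read
    read2: Read


def mate_name(label: str, ref_id: str, start: int, insert_size: int) -> str:
    return f"{label}:{ref_id}:{start}:{insert_size}"


def parse_mate_name(name: str) -> Tuple[str, str, int, int]:
    """Decode (label, ref_id, fragment_start, insert_size) from a pair name."""
    stem = name.rsplit("/", 1)[0] if name.endswith(("/1", "/2")) else name
    label, rest = stem.split(":", 1)
    ref_id, start, insert = rest.rsplit(":", 2)
    return label, ref_id, int(start), int(insert)


def compute_offset_step(read_length: int, target_coverage: float) -> int:
    """Fragment-start spacing achieving the target read-base coverage.

    Coverage identity: fragments every ``s`` bases put ``2r/s`` read bases
    over each interior position, so ``s = floor(2r/c)``, clamped to >= 1.
    """
    if read_length <= 0 or target_coverage <= 0:
        raise ValueError("read_length and target_coverage must be positive")
    return max(1, math.floor(2 * read_length / target_coverage))


class _FootprintIndex:
    """O(1) all-eligible queries over [i, j) via a prefix sum of bad positions."""

    def __init__(self, cons: ConsensusRecord, min_depth: int):
        bases = np.frombuffer(cons.bases.encode("ascii"), dtype=np.uint8)
        bad = (cons.depths < min_depth) | (bases == ord("N"))
        self._cum = np.concatenate(([0], np.cumsum(bad, dtype=np.int64)))

    def clean(self, start: int, end: int) -> bool:
        return self._cum[end] == self._cum[start]


def fragment_eligible(cons: ConsensusRecord, start: int, spec: LibrarySpec) -> bool:
    """True iff both read footprints avoid N and depth < min_depth positions."""
    r, I = spec.read_length, spec.insert_size
    if start < 0 or start + I > len(cons):
        raise ValueError(f"fragment [{start}, {start + I}) outside consensus of length {len(cons)}")
    idx = _FootprintIndex(cons, spec.min_depth)
    return idx.clean(start, start + r) and idx.clean(start + I - r, start + I)


def _make_pair(
    cons: ConsensusRecord, quals: str, start: int, spec: LibrarySpec
) -> MatePair:
    r, I = spec.read_length, spec.insert_size
    left_b = cons.bases[start : start + r]
    left_q = quals[start : start + r]
    right_b = cons.bases[start + I - r : start + I]
    right_q = quals[start + I - r : start + I]
    fwd = Read(left_b, left_q)
    rev = Read(reverse_complement(right_b), right_q[::-1])
    if spec.orientation == "FR":
        read1, read2 = fwd, rev
    else:  # RF: both reads point outward
        read1 = Read(reverse_complement(left_b), left_q[::-1])
        read2 = Read(right_b, right_q)
    return MatePair(name=mate_name(spec.label, cons.id, start, I), read1=read1, read2=read2)


def emit_mate_pair(cons: ConsensusRecord, start: int, spec: LibrarySpec) -> MatePair:
    """Emit the pair for one fragment start; the fragment must be eligible."""
    if not fragment_eligible(cons, start, spec):
        raise ValueError(f"fragment start {start} is not eligible for library {spec.label!r}")
    return _make_pair(cons, depth_quals(cons.depths), start, spec)


def sample_mate_pairs(cons: ConsensusRecord, spec: LibrarySpec) -> Iterator[MatePair]:
    """Systematically sample all eligible exact-insert fragments.

    Candidate starts are 0, s, 2s, ... with start + insert <= len(cons);
    each eligible candidate yields exactly one pair.  An insert longer than
    the consensus yields an empty stream.
    """
    r, I = spec.read_length, spec.insert_size
    L = len(cons)
    if I > L:
        return
    step = compute_offset_step(r, spec.target_coverage)
    idx = _FootprintIndex(cons, spec.min_depth)
    quals = depth_quals(cons.depths)
    for start in range(0, L - I + 1, step):
        if idx.clean(start, start + r) and idx.clean(start + I - r, start + I):
            yield _make_pair(cons, quals, start, spec)


def generate_libraries(
    cons_records: Iterable[ConsensusRecord],
    specs: Sequence[LibrarySpec],
    out_dir: str | Path,
) -> list[dict]:
    """Write one FASTQ pair per library spec, spanning all consensus records.

    Returns the manifest (one row per library) and writes it as
    ``manifest.tsv`` in *out_dir*.  Candidate starts restart at 0 on every
    consensus record; fragments never span record boundaries.
    """
    if not specs:
        raise ValueError("no library specs given")
    labels = [s.label for s in specs]
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate library labels: {sorted(labels)}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cons_list = list(cons_records)
    manifest: list[dict] = []
    for spec in specs:
        p1 = out_dir / f"{spec.label}_1.fastq"
        p2 = out_dir / f"{spec.label}_2.fastq"
        pairs = (p for cons in cons_list for p in sample_mate_pairs(cons, spec))
        n1, _ = write_fastq_pair(pairs, p1, p2)
        manifest.append(
            {
                "label": spec.label,
                "insert_size": spec.insert_size,
                "read_length": spec.read_length,
                "target_coverage": spec.target_coverage,
                "orientation": spec.orientation,
                "min_depth": spec.min_depth,
                "pairs": n1,
                "file1": str(p1),
                "file2": str(p2),
            }
        )
    cols = list(manifest[0].keys())
    with open(out_dir / "manifest.tsv", "wt") as out:
        out.write("\t".join(cols) + "\n")
        for row in manifest:
            # file columns as basenames so the manifest is location-independent
            vals = [
                Path(row[c]).name if c in ("file1", "file2") else str(row[c])
                for c in cols
            ]
            out.write("\t".join(vals) + "\n")
    return manifest
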