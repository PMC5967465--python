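"""Assembly contiguity statistics (N50/L50, Nx curve, length-threshold counts).

Nx is the length of the smallest sequence in the minimal descending-order
prefix whose summed length reaches x% of the assembly total; L50 is the
number of sequences in that prefix at x = 50.  A sequence whose length ties
the boundary is included.  No reference size is used (NG50 is out of scope).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, Tuple

import numpy as np

DEFAULT_NX_POINTS: Tuple[int, ...] = tuple(range(10, 100, 10))


@dataclass
class AssemblyMetrics:
    n_sequences: int
    total_length: int
    max_length: int
    n50: int
    l50: int
    nx_curve: list  # [(x, Nx)]
    n_ge_threshold: dict  # threshold bp -> count


def compute_metrics(
    lengths: Iterable[int],
    thresholds: Sequence[int] = (),
    nx_points: Sequence[int] = DEFAULT_NX_POINTS,
) -> AssemblyMetrics:
    """Contiguity summary of a sequence-length multiset (order-independent)."""
    arr = np.sort(np.asarray(list(lengths), dtype=np.int64))[::-1]
    if arr.size and arr[-1] < 1:
        raise ValueError("sequence lengths must be >= 1")
    if arr.size == 0:
        return AssemblyMetrics(0, 0, 0, 0, 0, [(x, 0) for x in nx_points], {t: 0 for t in thresholds})
    total = int(arr.sum())
    cum = np.cumsum(arr)

    def _nx(x: float) -> Tuple[int, int]:
        # smallest prefix whose sum reaches x% of total
        target = x / 100.0 * total
        idx = int(np.searchsorted(cum, target, side="left"))
        return int(arr[idx]), idx + 1

    n50, l50 = _nx(50)
    curve = [(int(x), _nx(x)[0]) for x in nx_points]
    counts = {int(t): int((arr >= t).sum()) for t in thresholds}
    return AssemblyMetrics(
        n_sequences=int(arr.size),
        total_length=total,
        max_length=int(arr[0]),
        n50=n50,
        l50=l50,
        nx_curve=curve,
        n_ge_threshold=counts,
    )


def metrics_from_fasta(path: str | Path, thresholds: Sequence[int] = ()) -> AssemblyMetrics:
    from .io_formats import read_fasta

    return compute_metrics([len(rec.bases) for rec in read_fasta(path)], thresholds)


def format_report(m: AssemblyMetrics) -> str:
    """Tab-separated key/value report."""
    lines = [
        f"n_sequences\t{m.n_sequences}",
        f"total_length\t{m.total_length}",
        f"max_length\t{m.max_length}",
        f"N50\t{m.n50}",
        f"L50\t{m.l50}",
    ]
    lines += [f"N{x}\t{nx}" for x, nx in m.nx_curve if x != 50]
    lines += [f"n_ge_{t}\t{c}" for t, c in sorted(m.n_ge_threshold.items())]
    return "\n".join(lines) + "\n"
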