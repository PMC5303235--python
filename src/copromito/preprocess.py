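"""Read preprocessing: 3'-end adapter/N/low-quality trimming and length filtering.

Single-end libraries of highly fragmented DNA frequently read through the
insert into the adapter, so the adapter appears as a 3' suffix.  Trimming
removes, in order: the longest read suffix matching a prefix of the adapter
(overlap of at least ``min_overlap``, at most one mismatch per ten aligned
bases), then any trailing run of N's or bases below the quality floor.
Reads shorter than ``min_len`` after trimming are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ParameterError
from .types import Read


@dataclass
class TrimReport:
    n_input: int = 0
    n_adapter_trimmed: int = 0
    n_quality_trimmed: int = 0
    n_discarded_short: int = 0
    n_output: int = 0


def _adapter_overlap(bases: str, adapter: str, min_overlap: int) -> int:
    """Length of the longest read suffix matching an adapter prefix.

    A suffix of length ``k`` matches when at most ``k // 10`` of its bases
    differ from ``adapter[:k]``.  Returns 0 if no acceptable overlap exists.
    """
    max_k = min(len(bases), len(adapter))
    for k in range(max_k, min_overlap - 1, -1):
        tail = bases[-k:]
        mism = sum(a != b for a, b in zip(tail, adapter[:k]))
        if mism <= k // 10:
            return k
    return 0


def trim_read(
    read: Read,
    adapter: str,
    qual_floor: int = 2,
    min_overlap: int = 3,
) -> tuple[Read, bool, bool]:
    """Trim one read's 3' end; returns (trimmed read, adapter_hit, quality_hit).

    Adapter and quality/N trimming are repeated until the read stops
    shrinking (removing one suffix can expose another), so trimming is a
    fixed point: re-trimming a trimmed read changes nothing.  The returned
    read may be empty.  Bases and qualities are trimmed in lockstep.
    """
    if not adapter:
        raise ParameterError("adapter must be non-empty")
    bases, quals = read.bases, read.quals
    adapter_hit = quality_hit = False
    while True:
        before = len(bases)
        k = _adapter_overlap(bases, adapter, min_overlap)
        if k > 0:
            adapter_hit = True
            bases, quals = bases[:-k], quals[:-k]
        end = len(bases)
        while end > 0 and (bases[end - 1] == "N" or ord(quals[end - 1]) - 33 < qual_floor):
            end -= 1
        if end < len(bases):
            quality_hit = True
            bases, quals = bases[:end], quals[:end]
        if len(bases) == before:
            break
    return Read(read.id, bases, quals), adapter_hit, quality_hit


def filter_length(reads: list[Read], min_len: int = 20) -> tuple[list[Read], TrimReport]:
    """Keep reads of length >= ``min_len`` (shorter reads are discarded)."""
    if min_len < 1:
        raise ParameterError(f"min_len must be >= 1, got {min_len}")
    report = TrimReport(n_input=len(reads))
    kept = []
    for r in reads:
        if len(r) >= min_len:
            kept.append(r)
        else:
            report.n_discarded_short += 1
    report.n_output = len(kept)
    return kept, report


def trim_pool(
    reads: list[Read],
    adapter: str,
    qual_floor: int = 2,
    min_len: int = 20,
    min_overlap: int = 3,
) -> tuple[list[Read], TrimReport]:
    """Adapter/quality-trim then length-filter a whole pool."""
    trimmed = []
    n_adapter = n_quality = 0
    for r in reads:
        t, a, q = trim_read(r, adapter, qual_floor, min_overlap)
        n_adapter += a
        n_quality += q
        trimmed.append(t)
    kept, report = filter_length(trimmed, min_len)
    report.n_input = len(reads)
    report.n_adapter_trimmed = n_adapter
    report.n_quality_trimmed = n_quality
    return kept, report
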