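"""Competitive taxonomic assignment against a mitogenome panel.

A read is credited to a genome only when it matches that genome perfectly —
full length, no mismatch or indel, on either strand, across the circular
origin if need be — and matches no other genome in the panel.  Reads with
perfect matches on two or more genomes are tallied as shared; reads with
only imperfect (but acceptable) placements as imperfect-only; the rest as
unmapped.  The four categories partition the pool exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from ._seq import revcomp
from .align import AlignerParams, IndexedGenome, align_read
from .errors import ParameterError
from .types import Read, ReferenceGenome


@dataclass
class AssignmentTable:
    """Per-genome perfect-unique counts plus the shared/imperfect/unmapped tail."""

    per_genome: dict[str, int] = field(default_factory=dict)
    n_shared: int = 0
    n_imperfect_only: int = 0
    n_unmapped: int = 0
    n_reads: int = 0

    def check_partition(self) -> bool:
        return (
            sum(self.per_genome.values())
            + self.n_shared
            + self.n_imperfect_only
            + self.n_unmapped
            == self.n_reads
        )

    def to_frame(self) -> pd.DataFrame:
        total = max(self.n_reads, 1)
        rows = [
            {"genome_id": g, "n_perfect_unique": n, "fraction": n / total}
            for g, n in sorted(self.per_genome.items(), key=lambda kv: -kv[1])
        ]
        for label, n in (
            ("__shared__", self.n_shared),
            ("__imperfect_only__", self.n_imperfect_only),
            ("__unmapped__", self.n_unmapped),
        ):
            rows.append({"genome_id": label, "n_perfect_unique": n, "fraction": n / total})
        return pd.DataFrame(rows)


class _PerfectMatcher:
    """Constant-time-ish perfect-substring tests on a (circular) genome."""

    def __init__(self, genome: ReferenceGenome, max_read_len: int = 101):
        if genome.circular:
            wrap = genome.sequence[: max_read_len - 1]
            self.haystack = genome.sequence + wrap
        else:
            self.haystack = genome.sequence

    def matches(self, bases: str) -> bool:
        return bases in self.haystack or revcomp(bases) in self.haystack


def assign_reads(
    reads: list[Read],
    panel: list[ReferenceGenome],
    params: AlignerParams = AlignerParams(),
) -> AssignmentTable:
    """Tally perfect-unique assignments of a read pool against a panel.

    Deterministic.  The imperfect-only category uses the aligner's
    edit-distance ceiling to decide whether a read maps at all.
    """
    if not panel:
        raise ParameterError("panel is empty")
    max_len = max((len(r) for r in reads), default=101)
    matchers = [(g.id, _PerfectMatcher(g, max_len)) for g in panel]
    indexed = [IndexedGenome(g) for g in panel]

    table = AssignmentTable(per_genome={g.id: 0 for g in panel}, n_reads=len(reads))
    for read in reads:
        hits = [gid for gid, m in matchers if m.matches(read.bases)]
        if len(hits) == 1:
            table.per_genome[hits[0]] += 1
        elif len(hits) > 1:
            table.n_shared += 1
        elif align_read(read, indexed, params):
            table.n_imperfect_only += 1
        else:
            table.n_unmapped += 1
    return table
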