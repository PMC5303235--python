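"""Core domain types shared across the pipeline.

Coordinates are 0-based half-open throughout the library; human-readable
reports convert to 1-based inclusive and say so in their headers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ParameterError
from ._seq import validate_dna

FEATURE_KINDS = ("CDS", "tRNA", "rRNA", "D-loop")


@dataclass(frozen=True)
class Feature:
    """An annotated interval on a reference genome.

    ``start``/``end`` are 0-based half-open; on a circular genome a feature
    may wrap the origin, in which case ``end < start`` and the feature spans
    ``[start, length) + [0, end)``.
    """

    name: str
    kind: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise ParameterError(f"unknown feature kind {self.kind!r}")
        if self.strand not in "+-":
            raise ParameterError(f"strand must be '+' or '-', got {self.strand!r}")

    def length(self, genome_length: int) -> int:
        if self.end >= self.start:
            return self.end - self.start
        return genome_length - self.start + self.end


@dataclass
class ReferenceGenome:
    """A named DNA sequence, circular by default (mitogenome convention)."""

    id: str
    sequence: str
    circular: bool = True
    features: list[Feature] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ParameterError(f"genome {self.id!r}: empty sequence")
        # N is tolerated because later assembly rounds align against partial
        # consensuses; generated panels are strictly A/C/G/T.
        self.sequence = validate_dna(self.sequence, allow_n=True, context=f"genome {self.id!r}")
        L = len(self.sequence)
        for f in self.features:
            if not (0 <= f.start < L and 0 <= f.end <= L):
                raise ParameterError(f"feature {f.name!r} outside [0, {L})")
            if f.end < f.start and not self.circular:
                raise ParameterError(f"feature {f.name!r} wraps a linear genome")

    def __len__(self) -> int:
        return len(self.sequence)

    def fragment(self, start: int, end: int) -> str:
        """Substring ``[start, end)``; wraps the origin when circular and end < start."""
        L = len(self.sequence)
        if not (0 <= start < L and 0 <= end <= L):
            raise ParameterError(f"interval ({start}, {end}) outside genome of length {L}")
        if end >= start:
            return self.sequence[start:end]
        if not self.circular:
            raise ParameterError(f"interval ({start}, {end}) wraps a linear genome")
        return self.sequence[start:] + self.sequence[:end]


@dataclass
class Read:
    """A sequencing read with Phred+33 base qualities."""

    id: str
    bases: str
    quals: str

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.quals):
            raise ParameterError(
                f"read {self.id!r}: {len(self.bases)} bases vs {len(self.quals)} quality values"
            )

    def __len__(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class RadiocarbonDate:
    """An uncalibrated radiocarbon age in years BP with 1-sigma uncertainty."""

    age: float
    sigma: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.age <= 0:
            raise ParameterError(f"age must be positive, got {self.age}")
        if self.sigma <= 0:
            raise ParameterError(f"sigma must be positive, got {self.sigma}")
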