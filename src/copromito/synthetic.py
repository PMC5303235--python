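"""Synthetic ancient-DNA data: reference panels, damaged read pools, PCR fragments.

The generator emulates a shotgun library built from an ancient faecal sample
containing DNA of two dominant organisms (the producer and its prey) plus
optional trace taxa.  Its defaults reproduce the characteristic features of
such libraries: short lognormal fragment lengths with median 48 nt truncated
to the usable 20-101 nt range, elevated G-to-A substitution toward read 3'
ends (the signature of cytosine deamination on repaired double-stranded
libraries), and a uniform sequencing-error floor.  Every simulated read is
recorded in a truth table so downstream stages can be scored exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._seq import A, C, G, N, T, decode, encode, revcomp_codes
from .errors import ParameterError
from .types import Feature, Read, ReferenceGenome

TRUTH_COLUMNS = ["read_id", "source", "start", "end", "strand", "n_damage", "n_error"]

_STOPS = ("TAA", "TAG", "AGA", "AGG")


@dataclass(frozen=True)
class DamageModel:
    """Post-mortem damage plus sequencing error, applied on the read strand.

    ``delta3`` is the G->A substitution probability at the 3'-terminal base,
    ``delta5`` the C->T probability at the 5'-terminal base; both decay
    geometrically inward (rate at distance d from the relevant end is
    ``delta * decay**d``).  ``err`` is a uniform per-base error probability
    applied after damage.
    """

    delta3: float = 0.0
    delta5: float = 0.0
    decay: float = 0.5
    err: float = 0.0

    def __post_init__(self) -> None:
        for name in ("delta3", "delta5", "err"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must be in [0,1], got {v}")
        if not 0.0 < self.decay < 1.0:
            raise ParameterError(f"decay must be in (0,1), got {self.decay}")

    def rate3(self, d: int) -> float:
        """G->A rate at distance ``d`` from the 3' end."""
        return self.delta3 * self.decay**d

    def rate5(self, d: int) -> float:
        """C->T rate at distance ``d`` from the 5' end."""
        return self.delta5 * self.decay**d


@dataclass(frozen=True)
class FragmentLengthModel:
    """Truncated-lognormal fragment lengths.

    Only the median (48 nt) and the usable range (20-101 nt) of the emulated
    library are well characterised; the lognormal family and its spread are
    modelling choices exposed here.
    """

    median: float = 48.0
    sigma: float = 0.35
    min_len: int = 20
    max_len: int = 101

    def __post_init__(self) -> None:
        if not self.min_len <= self.median <= self.max_len:
            raise ParameterError("median must lie within [min_len, max_len]")
        if self.sigma <= 0:
            raise ParameterError("sigma must be positive")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        """Draw ``n`` integer fragment lengths by rejection from the lognormal."""
        out = np.empty(n, dtype=np.int64)
        got = 0
        mu = math.log(self.median)
        while got < n:
            draw = np.rint(rng.lognormal(mu, self.sigma, size=2 * (n - got) + 16))
            keep = draw[(draw >= self.min_len) & (draw <= self.max_len)]
            take = min(len(keep), n - got)
            out[got : got + take] = keep[:take]
            got += take
        return out


@dataclass
class ReadPool:
    """Simulated reads plus the per-read truth table that generated them."""

    reads: list[Read]
    truth: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if list(self.truth.columns) != TRUTH_COLUMNS:
            raise ParameterError(f"truth table must have columns {TRUTH_COLUMNS}")
        ids = [r.id for r in self.reads]
        if sorted(ids) != sorted(self.truth["read_id"]):
            raise ParameterError("truth table and read list disagree on read ids")

    def __len__(self) -> int:
        return len(self.reads)


def _plant_cds(codes: np.ndarray, start: int, length: int) -> None:
    """Overwrite ``codes[start:start+length]`` in place with a valid CDS.

    Sets an ATG start and TAA stop and neutralises internal stop codons of
    the vertebrate mitochondrial code by editing third codon positions.
    """
    codes[start : start + 3] = encode("ATG")
    codes[start + length - 3 : start + length] = encode("TAA")
    for i in range(start + 3, start + length - 3, 3):
        codon = decode(codes[i : i + 3])
        if codon in _STOPS:
            codes[i + 2] = C  # TAA->TAC, TAG->TAC, AGA->AGC, AGG->AGC


def generate_panel(
    seed: int,
    n_genomes: int,
    length: int = 16000,
    divergence: float = 0.05,
    cds_start: int = 1200,
    cds_length: int = 300,
) -> list[ReferenceGenome]:
    """Generate a star-shaped panel of circular mitogenome-sized references.

    Genome 0 is the ancestral sequence; every other genome differs from it by
    independent per-site substitutions with probability ``divergence``.  Each
    genome carries one synthetic CDS feature with a valid start/stop codon
    and no internal stop.

    Deterministic given ``seed``.
    """
    if n_genomes < 1:
        raise ParameterError(f"n_genomes must be >= 1, got {n_genomes}")
    if not 0.0 <= divergence <= 0.25:
        raise ParameterError(f"divergence must be in [0, 0.25], got {divergence}")
    if length < 1000:
        raise ParameterError(f"length must be >= 1000, got {length}")
    if cds_length % 3 != 0 or cds_length < 9:
        raise ParameterError("cds_length must be a multiple of 3 and >= 9")
    if cds_start + cds_length > length:
        raise ParameterError("synthetic CDS does not fit in the genome")

    rng = np.random.default_rng(seed)
    ancestor = rng.integers(0, 4, size=length).astype(np.uint8)
    genomes: list[ReferenceGenome] = []
    for i in range(n_genomes):
        codes = ancestor.copy()
        if i > 0 and divergence > 0:
            hit = np.nonzero(rng.random(length) < divergence)[0]
            # substitute to one of the three other bases, uniformly
            codes[hit] = (codes[hit] + rng.integers(1, 4, size=hit.size)) % 4
        _plant_cds(codes, cds_start, cds_length)
        feat = Feature("synthetic_cds", "CDS", cds_start, cds_start + cds_length, "+")
        genomes.append(ReferenceGenome(f"genome{i}", decode(codes), circular=True, features=[feat]))
    return genomes


def _apply_damage(codes: np.ndarray, damage: DamageModel, rng: np.random.Generator) -> int:
    """Deaminate ``codes`` (read-strand orientation) in place; return event count."""
    n = len(codes)
    if n == 0 or (damage.delta3 == 0 and damage.delta5 == 0):
        return 0
    d5 = np.arange(n)
    d3 = d5[::-1]
    p = np.zeros(n)
    p[codes == G] = damage.delta3 * damage.decay ** d3[codes == G]
    p[codes == C] = damage.delta5 * damage.decay ** d5[codes == C]
    hit = rng.random(n) < p
    codes[hit & (codes == G)] = A
    codes[hit & (codes == C)] = T
    return int(hit.sum())


def _apply_error(codes: np.ndarray, err: float, rng: np.random.Generator) -> int:
    """Uniform sequencing error in place; return event count."""
    if err == 0:
        return 0
    hit = np.nonzero(rng.random(len(codes)) < err)[0]
    codes[hit] = (codes[hit] + rng.integers(1, 4, size=hit.size).astype(np.uint8)) % 4
    return int(hit.size)


def simulate_reads(
    panel: list[ReferenceGenome],
    proportions: list[float],
    total: int,
    fraglen: FragmentLengthModel | None = None,
    damage: DamageModel | None = None,
    seed: int = 0,
    duplicate_rate: float = 0.0,
    qual_char: str = "F",
) -> ReadPool:
    """Simulate an ancient single-end read pool from a genome panel.

    Each read is a fragment of its source genome (wrapping the origin when
    circular), reverse-complemented with probability 1/2, then deaminated on
    the read strand (G->A decaying from the 3' end, C->T from the 5' end)
    and finally subjected to uniform sequencing error.  With probability
    ``duplicate_rate`` a read is instead an exact copy of a previously
    emitted read (a PCR/optical duplicate).  Qualities are constant
    ``qual_char`` (Q37 by default).  Deterministic given ``seed``.
    """
    if not panel:
        raise ParameterError("panel is empty")
    props = np.asarray(proportions, dtype=float)
    if len(props) != len(panel) or props.min() < 0 or props.sum() <= 0:
        raise ParameterError("proportions must be non-negative, one per genome, with positive sum")
    if not 0.0 <= duplicate_rate < 1.0:
        raise ParameterError("duplicate_rate must be in [0,1)")
    props = props / props.sum()
    fraglen = fraglen or FragmentLengthModel()
    damage = damage or DamageModel()
    rng = np.random.default_rng(seed)

    sources = rng.choice(len(panel), size=total, p=props)
    lengths = fraglen.sample(rng, total)
    reads: list[Read] = []
    rows: list[tuple] = []
    for i in range(total):
        rid = f"read{i:07d}"
        if reads and rng.random() < duplicate_rate:
            j = int(rng.integers(0, len(reads)))
            proto = reads[j]
            reads.append(Read(rid, proto.bases, proto.quals))
            prev = rows[j]
            rows.append((rid, *prev[1:]))
            continue
        g = panel[int(sources[i])]
        L = len(g)
        flen = int(min(lengths[i], L))
        start = int(rng.integers(0, L)) if g.circular else int(rng.integers(0, L - flen + 1))
        end = (start + flen) % L if g.circular else start + flen
        if g.circular and flen == L:
            frag = g.sequence[start:] + g.sequence[:start]
        else:
            frag = g.fragment(start, end) if g.circular else g.sequence[start:end]
        codes = encode(frag)
        strand = "+"
        if rng.random() < 0.5:
            strand = "-"
            codes = revcomp_codes(codes)
        n_dmg = _apply_damage(codes, damage, rng)
        n_err = _apply_error(codes, damage.err, rng)
        reads.append(Read(rid, decode(codes), qual_char * flen))
        rows.append((rid, g.id, start, end, strand, n_dmg, n_err))
    truth = pd.DataFrame(rows, columns=TRUTH_COLUMNS)
    return ReadPool(reads=reads, truth=truth)


@dataclass(frozen=True)
class PcrFragment:
    """An error-free consensus fragment labelled with its source interval."""

    id: str
    start: int
    end: int
    sequence: str

    def __len__(self) -> int:
        return len(self.sequence)


def simulate_pcr_fragments(
    genome: ReferenceGenome, intervals: list[tuple[int, int]]
) -> list[PcrFragment]:
    """Extract error-free consensus fragments over ``intervals``.

    Intervals are 0-based half-open and may wrap the origin on circular
    genomes (``end < start``).
    """
    frags = []
    for i, (start, end) in enumerate(intervals):
        seq = genome.fragment(start, end)
        frags.append(PcrFragment(f"{genome.id}_pcr{i:03d}", start, end, seq))
    return frags
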