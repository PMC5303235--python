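"""Simultaneous iterative consensus assembly of co-occurring mitogenomes.

The core procedure: a mixed ancient-read pool is aligned simultaneously to
two (generally N) reference genomes; for each target, reads are kept only
if they map exclusively to that target (no acceptable placement on any
competitor) with sufficient mapping quality; placements are deduplicated to
unique reads; a majority consensus is called per position from at least
``min_concordant`` concordant unique sequences (Illumina reads or PCR
consensus fragments); and the pool is realigned to the provisional
consensuses until they stop changing.  Columns where more than
``dispute_frac`` of the aligned read bases disagree are flagged, and kept
only when the disagreement is explained by terminal G-to-A damage or
confirmed by PCR evidence.

Coordinates stay in the frame of the round's reference (consensus length
equals reference length); a majority-deletion column calls N rather than
contracting the frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._seq import A, C, G, T
from .align import AlignerParams, ReadAlignment, align_pool, maxdiff
from .errors import ParameterError
from .synthetic import PcrFragment
from .types import ReferenceGenome

DASH = 4  # index of '-' in pileup count vectors (A,C,G,T,-)
_BASE_ORDER = "ACGT-"

FLAG_NO_COVERAGE = "no_coverage"
FLAG_SINGLE_COVERAGE = "single_coverage"
FLAG_DISPUTED = "disputed"
FLAG_DAMAGE_EXPLAINED = "damage_explained"
FLAG_PCR_CONFIRMED = "pcr_confirmed"


@dataclass
class PileupColumn:
    """Read-friendly view of one consensus column."""

    position: int
    counts: dict[str, int]
    pcr_counts: dict[str, int]
    depth_unique: int
    consensus_base: str
    flags: frozenset[str]


@dataclass
class Pileup:
    """Per-position tallies from gated unique alignments plus PCR fragments."""

    length: int
    counts: np.ndarray  # (L, 5) read-derived counts over A,C,G,T,-
    pcr: np.ndarray  # (L, 5) PCR-fragment counts
    dmg_a_plus: np.ndarray  # (L,) A contributions from + reads near their 3' end
    dmg_t_minus: np.ndarray  # (L,) T contributions from - reads near their 3' end

    @classmethod
    def empty(cls, length: int) -> "Pileup":
        return cls(
            length=length,
            counts=np.zeros((length, 5), dtype=np.int32),
            pcr=np.zeros((length, 5), dtype=np.int32),
            dmg_a_plus=np.zeros(length, dtype=np.int32),
            dmg_t_minus=np.zeros(length, dtype=np.int32),
        )

    def add_alignment(self, aln: ReadAlignment, damage_window: int = 10) -> None:
        codes = aln.oriented_codes()
        l = len(codes)
        L = self.length
        # (read index, reference position) pairs, honouring a single split
        if aln.split is None:
            pairs = [(i, aln.start + i) for i in range(l)]
        else:
            p, s = aln.split
            if s > 0:  # s reference bases deleted from the read
                pairs = [(i, aln.start + i) for i in range(p)]
                for j in range(s):
                    pos = (aln.start + p + j) % L
                    self.counts[pos, DASH] += 1
                pairs += [(i, aln.start + s + i) for i in range(p, l)]
            else:  # -s read bases inserted relative to the reference
                g = -s
                pairs = [(i, aln.start + i) for i in range(p)]
                pairs += [(i, aln.start + s + i) for i in range(p + g, l)]
        for i, raw in pairs:
            pos = raw % L
            b = int(codes[i])
            if b > 3:  # read N contributes no evidence
                continue
            self.counts[pos, b] += 1
            d3 = (l - 1 - i) if aln.strand == "+" else i
            if d3 <= damage_window:
                if aln.strand == "+" and b == A:
                    self.dmg_a_plus[pos] += 1
                elif aln.strand == "-" and b == T:
                    self.dmg_t_minus[pos] += 1

    def add_pcr_fragment(self, frag: PcrFragment) -> None:
        from ._seq import encode

        codes = encode(frag.sequence)
        for i, b in enumerate(codes):
            if b > 3:
                continue
            pos = (frag.start + i) % self.length
            self.pcr[pos, int(b)] += 1


@dataclass
class ConsensusState:
    """Consensus sequence plus per-column evidence for one genome, one round."""

    genome_id: str
    iteration: int
    sequence: str
    pileup: Pileup = field(repr=False)
    flags: list[frozenset[str]] = field(repr=False, default_factory=list)

    @property
    def gap_report(self) -> list[tuple[int, int]]:
        """Maximal 0-based half-open runs of no-coverage N positions."""
        runs = []
        start = None
        for i, fl in enumerate(self.flags):
            if FLAG_NO_COVERAGE in fl:
                if start is None:
                    start = i
            elif start is not None:
                runs.append((start, i))
                start = None
        if start is not None:
            runs.append((start, len(self.flags)))
        return runs

    @property
    def singleton_report(self) -> list[int]:
        return [i for i, fl in enumerate(self.flags) if FLAG_SINGLE_COVERAGE in fl]

    @property
    def n_uncalled(self) -> int:
        return self.sequence.count("N")

    def columns(self) -> list[PileupColumn]:
        out = []
        for i in range(len(self.sequence)):
            out.append(
                PileupColumn(
                    position=i,
                    counts={b: int(self.pileup.counts[i, j]) for j, b in enumerate(_BASE_ORDER)},
                    pcr_counts={b: int(self.pileup.pcr[i, j]) for j, b in enumerate(_BASE_ORDER)},
                    depth_unique=int(self.pileup.counts[i].sum()),
                    consensus_base=self.sequence[i],
                    flags=self.flags[i],
                )
            )
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for col in self.columns():
            rows.append(
                {
                    "position": col.position,
                    **{f"n_{b}": col.counts[b] for b in "ACGT"},
                    "n_del": col.counts["-"],
                    "n_pcr": sum(col.pcr_counts.values()),
                    "depth_unique": col.depth_unique,
                    "consensus": col.consensus_base,
                    "flags": ",".join(sorted(col.flags)),
                }
            )
        return pd.DataFrame(rows)


def dedup_unique(alignments: list[ReadAlignment]) -> tuple[list[ReadAlignment], int]:
    """Collapse placements identical in (genome, start, strand, bases).

    Returns the unique representatives (first seen) and the number of
    collapsed duplicates.
    """
    seen: set[tuple] = set()
    unique = []
    dups = 0
    for a in alignments:
        key = (a.genome_id, a.start, a.strand, a.bases)
        if key in seen:
            dups += 1
        else:
            seen.add(key)
            unique.append(a)
    return unique, dups


def exclusivity_filter(
    alignments: list[ReadAlignment],
    target: str,
    competitor: str | list[str],
    mq_min: int = 25,
    strict: bool = False,
) -> list[ReadAlignment]:
    """Keep target placements of reads with no acceptable competitor placement.

    ``alignments`` is the flat placement list of one panel call (both
    genomes).  The mapping-quality gate is ``mapq >= mq_min`` by default
    (``strict`` switches to a strictly-greater gate).
    """
    competitors = {competitor} if isinstance(competitor, str) else set(competitor)
    excluded_reads = {a.read_id for a in alignments if a.genome_id in competitors}
    kept = []
    for a in alignments:
        if a.genome_id != target or a.read_id in excluded_reads:
            continue
        if (a.mapq > mq_min) if strict else (a.mapq >= mq_min):
            kept.append(a)
    return kept


def build_pileup(
    alignments: list[ReadAlignment],
    length: int,
    pcr_fragments: list[PcrFragment] | None = None,
    damage_window: int = 10,
) -> Pileup:
    pile = Pileup.empty(length)
    for a in alignments:
        pile.add_alignment(a, damage_window)
    for frag in pcr_fragments or []:
        pile.add_pcr_fragment(frag)
    return pile


def call_consensus(
    pileup: Pileup,
    genome_id: str = "consensus",
    iteration: int = 0,
    min_concordant: int = 2,
    dispute_frac: float = 0.25,
) -> ConsensusState:
    """Majority consensus with support, dispute and damage-explanation rules.

    Per column: the most frequent base over reads + PCR wins, provided at
    least ``min_concordant`` unique sequences agree on it; otherwise N with
    a coverage flag.  Ties call N + disputed.  If more than ``dispute_frac``
    of aligned read bases disagree with the winner the column is disputed;
    it keeps the winner only when the disagreement is entirely terminal
    G-to-A damage (damage_explained) or when a PCR fragment confirms the
    winner (pcr_confirmed); otherwise N.
    """
    L = pileup.length
    seq = []
    flags: list[frozenset[str]] = []
    total = pileup.counts + pileup.pcr
    for i in range(L):
        col = total[i]
        read_col = pileup.counts[i]
        depth_total = int(col.sum())
        fl: set[str] = set()
        top = int(col.max())
        if top < min_concordant:
            if depth_total == 0:
                fl.add(FLAG_NO_COVERAGE)
            elif depth_total == 1:
                fl.add(FLAG_SINGLE_COVERAGE)
            else:
                fl.add(FLAG_DISPUTED)  # discordant singletons
            seq.append("N")
            flags.append(frozenset(fl))
            continue
        winners = np.nonzero(col == top)[0]
        if len(winners) > 1:
            fl.add(FLAG_DISPUTED)
            seq.append("N")
            flags.append(frozenset(fl))
            continue
        b = int(winners[0])
        if b == DASH:
            # majority deletion: frame is kept fixed, column reported uncalled
            fl.add(FLAG_DISPUTED)
            seq.append("N")
            flags.append(frozenset(fl))
            continue
        if pileup.pcr[i, b] >= 1:
            fl.add(FLAG_PCR_CONFIRMED)
        read_depth = int(read_col.sum())
        disagree = read_depth - int(read_col[b])
        base = _BASE_ORDER[b]
        if read_depth > 0 and disagree / read_depth > dispute_frac:
            fl.add(FLAG_DISPUTED)
            explained = False
            if b == G:
                others = disagree - int(read_col[A])
                explained = others == 0 and read_col[A] > 0 and read_col[A] == pileup.dmg_a_plus[i]
            elif b == C:
                others = disagree - int(read_col[T])
                explained = others == 0 and read_col[T] > 0 and read_col[T] == pileup.dmg_t_minus[i]
            if explained:
                fl.add(FLAG_DAMAGE_EXPLAINED)
            elif pileup.pcr[i, b] < 1:
                base = "N"
        seq.append(base)
        flags.append(frozenset(fl))
    return ConsensusState(genome_id, iteration, "".join(seq), pileup, flags)


def propose_pcr_targets(
    state: ConsensusState,
    primer_margin: int = 25,
    max_amplicon: int = 150,
) -> list[tuple[int, int]]:
    """Amplicon intervals covering every gap and singleton position.

    Greedy left-to-right grouping: each interval is padded by
    ``primer_margin`` on both sides and kept at or under ``max_amplicon``
    where possible (a lone position always yields one interval).  Intervals
    are 0-based half-open, clamped to the genome.
    """
    flagged = sorted(
        set(p for start, end in state.gap_report for p in range(start, end))
        | set(state.singleton_report)
    )
    if not flagged:
        return []
    L = len(state.sequence)
    intervals = []
    first = last = flagged[0]
    for p in flagged[1:]:
        if (p + primer_margin + 1) - (first - primer_margin) <= max_amplicon:
            last = p
        else:
            intervals.append((max(0, first - primer_margin), min(L, last + primer_margin + 1)))
            first = last = p
    intervals.append((max(0, first - primer_margin), min(L, last + primer_margin + 1)))
    return intervals


@dataclass
class CoassemblyLog:
    """Per-round bookkeeping for an iterative co-assembly."""

    rows: pd.DataFrame
    converged: bool
    n_iterations: int

    @property
    def warning(self) -> str | None:
        if not self.converged:
            return f"did not converge within {self.n_iterations} iterations"
        return None


def _alignment_pairs(aln: ReadAlignment, L: int) -> list[tuple[int, int]]:
    """(read index, reference position) pairs of an alignment, honouring a split."""
    l = len(aln.bases)
    if aln.split is None:
        return [(i, (aln.start + i) % L) for i in range(l)]
    p, s = aln.split
    pairs = [(i, (aln.start + i) % L) for i in range(p)]
    if s > 0:
        pairs += [(i, (aln.start + s + i) % L) for i in range(p, l)]
    else:
        pairs += [(i, (aln.start + s + i) % L) for i in range(p - s, l)]
    return pairs


def _edit_vs_consensus(aln: ReadAlignment, cons: np.ndarray) -> tuple[int, int]:
    """Recompute an alignment's edit distance against an updated consensus.

    The placement is frozen; only substitution costs are re-evaluated
    (uncalled consensus positions count as mismatches), plus the original
    gap cost.  Returns ``(edit, n_uncalled_covered)`` so callers can also
    form the N-discounted edit used by the exclusivity rule.
    """
    codes = aln.oriented_codes()
    gap_cost = 0 if aln.split is None else abs(aln.split[1])
    pairs = _alignment_pairs(aln, len(cons))
    idx = np.fromiter((pos for _, pos in pairs), dtype=np.int64)
    ri = np.fromiter((i for i, _ in pairs), dtype=np.int64)
    w = cons[idx]
    q = codes[ri]
    edit = gap_cost + int(((w != q) | (w >= 4)).sum())
    return edit, int((w == 4).sum())


def _joint_refine(
    flat: list[ReadAlignment],
    refs: list[ReferenceGenome],
    ceilings: dict[str, int],
    pcr_by_genome: dict[str, list[PcrFragment]],
    iteration: int,
    mq_min: int,
    mq_strict: bool,
    min_concordant: int,
    dispute_frac: float,
    damage_window: int,
    max_inner: int = 40,
) -> tuple[list[ConsensusState], dict[str, list[ReadAlignment]]]:
    """Iterate gates -> consensus on frozen placements until nothing moves.

    Within one realignment round the placements are fixed, but the gates
    are not: calling a position N raises the recomputed edit distance of
    reads spanning it; correcting a base re-admits reads that disagreed
    with the previous reference; and either change on one genome can flip
    a read's exclusivity on the other.  All of these cascades can be
    evaluated without realignment, so acceptance, exclusivity and
    consensus calling are re-run jointly over all genomes against each new
    set of consensuses until the sequences stop changing.  The exclusivity
    test uses the N-discounted edit (an uncalled position is no evidence
    of a difference); consensus evidence requires the strict edit ceiling.
    """
    from ._seq import encode

    by_genome: dict[str, list[ReadAlignment]] = {g.id: [] for g in refs}
    for a in flat:
        by_genome[a.genome_id].append(a)
    unique_by_genome = {gid: dedup_unique(alns)[0] for gid, alns in by_genome.items()}

    # frozen placement geometry, precomputed once: (read positions,
    # reference positions, read codes, gap cost)
    geometry: dict[int, tuple[np.ndarray, np.ndarray, int]] = {}
    for gid, alns in unique_by_genome.items():
        L = len(next(g for g in refs if g.id == gid))
        for a in alns:
            pairs = _alignment_pairs(a, L)
            idx = np.fromiter((pos for _, pos in pairs), dtype=np.int64)
            q = a.oriented_codes()[[i for i, _ in pairs]]
            gap_cost = 0 if a.split is None else abs(a.split[1])
            geometry[id(a)] = (idx, q, gap_cost)

    cons = {g.id: encode(g.sequence) for g in refs}
    prev_seqs: list[str] | None = None
    states: list[ConsensusState] = []
    active_by_genome: dict[str, list[ReadAlignment]] = {}
    for _ in range(max_inner):
        # recompute strict and discounted edits for every placement
        strict: dict[int, int] = {}
        discounted: dict[int, int] = {}
        for gid, alns in unique_by_genome.items():
            c = cons[gid]
            for a in alns:
                idx, q, gap_cost = geometry[id(a)]
                w = c[idx]
                e = gap_cost + int(((w != q) | (w >= 4)).sum())
                strict[id(a)] = e
                discounted[id(a)] = e - int((w == 4).sum())
        # reads with an acceptable (discounted) placement on a genome
        mapped: dict[str, set[str]] = {
            gid: {
                a.read_id
                for a in alns
                if discounted[id(a)] <= ceilings[a.read_id]
            }
            for gid, alns in unique_by_genome.items()
        }
        states = []
        active_by_genome = {}
        for ref in refs:
            others = [g.id for g in refs if g.id != ref.id]
            excluded = set().union(*(mapped[o] for o in others)) if others else set()
            active = [
                a
                for a in unique_by_genome[ref.id]
                if a.read_id not in excluded
                and ((a.mapq > mq_min) if mq_strict else (a.mapq >= mq_min))
                and strict[id(a)] <= ceilings[a.read_id]
            ]
            pile = build_pileup(active, len(ref), pcr_by_genome.get(ref.id, []), damage_window)
            states.append(
                call_consensus(pile, ref.id, iteration, min_concordant, dispute_frac)
            )
            active_by_genome[ref.id] = active
        seqs = [s.sequence for s in states]
        if seqs == prev_seqs:
            break
        prev_seqs = seqs
        cons = {s.genome_id: encode(s.sequence) for s in states}
    return states, active_by_genome


def coassemble_pool(
    reads,
    refs: list[ReferenceGenome],
    aligner: AlignerParams = AlignerParams(),
    pcr_fragments: dict[str, list[PcrFragment]] | None = None,
    pcr_start_round: int = 1,
    mq_min: int = 25,
    mq_strict: bool = False,
    min_concordant: int = 2,
    dispute_frac: float = 0.25,
    damage_window: int = 10,
    max_iterations: int = 5,
) -> tuple[list[ConsensusState], CoassemblyLog, list[ReadAlignment]]:
    """Iteratively co-assemble N genomes from one mixed pool.

    Round 0 aligns to the external references; each later round realigns
    the full pool simultaneously to the current consensuses (uncalled N
    positions count as mismatches, so the called region can only lose read
    support monotonically and the iteration reaches a fixed point).  PCR fragments are injected as concordant
    evidence from ``pcr_start_round`` onward.  Terminates when all
    consensuses are unchanged between rounds, or at ``max_iterations`` with
    a warning recorded in the log.  Also returns the final gated unique
    alignment set of every genome (for damage profiling).
    """
    if len(refs) < 2:
        raise ParameterError("co-assembly needs at least two references")
    ids = [g.id for g in refs]
    if len(set(ids)) != len(ids):
        raise ParameterError("reference ids must be distinct")

    # retain near-ceiling placements so the within-round refinement can
    # re-gate them as the consensus drifts, instead of waiting a round
    import dataclasses

    aligner = dataclasses.replace(aligner, retain_slack=max(aligner.retain_slack, 2))

    current = refs
    prev_seqs: list[str] | None = None
    states: list[ConsensusState] = []
    final_unique: list[ReadAlignment] = []
    log_rows = []
    converged = False
    rounds_done = 0
    for it in range(max_iterations):
        hits = align_pool(reads, current, aligner)
        flat = [a for alist in hits.values() for a in alist]
        ceilings = {
            rid: maxdiff(len(alist[0].bases), aligner.err, aligner.miss_thres)
            for rid, alist in hits.items()
        }
        pcr_by = dict(pcr_fragments or {}) if it >= pcr_start_round else {}
        states, active_by = _joint_refine(
            flat, current, ceilings, pcr_by, it,
            mq_min, mq_strict, min_concordant, dispute_frac, damage_window,
        )
        final_unique = [a for alns in active_by.values() for a in alns]
        for idx, ref in enumerate(current):
            state = states[idx]
            mine = [a for a in flat if a.genome_id == ref.id]
            n_dups = dedup_unique(mine)[1]
            changed = (
                sum(a != b for a, b in zip(state.sequence, prev_seqs[idx]))
                if prev_seqs is not None
                else sum(a != b for a, b in zip(state.sequence, refs[idx].sequence))
            )
            log_rows.append(
                {
                    "iteration": it,
                    "genome_id": ref.id,
                    "n_placements": len(mine),
                    "n_unique": len(active_by[ref.id]),
                    "n_duplicates": n_dups,
                    "n_changed": changed,
                    "n_uncalled": state.n_uncalled,
                    "n_gap_positions": sum(e - s for s, e in state.gap_report),
                    "n_singletons": len(state.singleton_report),
                }
            )
        rounds_done = it + 1
        new_seqs = [s.sequence for s in states]
        if prev_seqs is not None and new_seqs == prev_seqs:
            converged = True
            break
        prev_seqs = new_seqs
        current = [
            ReferenceGenome(ref.id, s.sequence, circular=ref.circular)
            for ref, s in zip(refs, states)
        ]
    log = CoassemblyLog(pd.DataFrame(log_rows), converged, rounds_done)
    return states, log, final_unique


def iterate_coassembly(
    reads,
    ref_a: ReferenceGenome,
    ref_b: ReferenceGenome,
    aligner: AlignerParams = AlignerParams(),
    pcr_fragments: dict[str, list[PcrFragment]] | None = None,
    **kwargs,
) -> tuple[ConsensusState, ConsensusState, CoassemblyLog]:
    """Two-genome convenience wrapper around :func:`coassemble_pool`."""
    if ref_a.id == ref_b.id:
        raise ParameterError("the two references must differ")
    states, log, _ = coassemble_pool(reads, [ref_a, ref_b], aligner, pcr_fragments, **kwargs)
    return states[0], states[1], log
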