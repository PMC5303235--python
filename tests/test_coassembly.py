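"""Deduplication, exclusivity, consensus rules and the iterative co-assembly."""

import numpy as np
import pytest

import copromito as cp
from copromito.align import ReadAlignment, align_pool
from copromito.coassembly import (
    FLAG_DAMAGE_EXPLAINED,
    FLAG_DISPUTED,
    FLAG_NO_COVERAGE,
    FLAG_SINGLE_COVERAGE,
    Pileup,
    build_pileup,
    call_consensus,
    coassemble_pool,
    dedup_unique,
    exclusivity_filter,
    propose_pcr_targets,
)
from .conftest import mutate


def _aln(rid, bases, start=0, strand="+", genome="g", mapq=37, edit=0):
    return ReadAlignment(
        read_id=rid, genome_id=genome, start=start, strand=strand,
        edit_distance=edit, n_gap_opens=0, mapq=mapq, co_optimal=1, bases=bases,
    )


class TestDedupUnique:
    def test_identical_placements_collapse(self):
        a = _aln("r1", "ACGTACGTACGT")
        b = _aln("r2", "ACGTACGTACGT")
        unique, dups = dedup_unique([a, b])
        assert len(unique) == 1 and dups == 1

    def test_one_base_difference_kept(self):
        a = _aln("r1", "ACGTACGTACGT")
        b = _aln("r2", "ACGTACGTACGA")
        unique, dups = dedup_unique([a, b])
        assert len(unique) == 2 and dups == 0

    def test_simulated_duplicate_rate(self, single_genome):
        pool = cp.simulate_reads([single_genome], [1.0], 3000,
                                 damage=cp.DamageModel(), seed=30, duplicate_rate=0.2)
        hits = align_pool(pool.reads, [single_genome])
        flat = [a for al in hits.values() for a in al]
        unique, dups = dedup_unique(flat)
        mean = 1 + 2999 * 0.8
        sd = np.sqrt(2999 * 0.8 * 0.2)
        assert abs(len(unique) - mean) < 3 * sd + 10  # coincidental twins possible


class TestExclusivityFilter:
    def test_cross_mapping_read_removed(self):
        both = [_aln("r1", "A" * 30, genome="A"), _aln("r1", "A" * 30, genome="B")]
        assert exclusivity_filter(both, "A", "B") == []

    def test_unique_high_mq_read_kept(self):
        only_a = [_aln("r1", "A" * 30, genome="A", mapq=37)]
        assert len(exclusivity_filter(only_a, "A", "B")) == 1

    def test_mq_gate_removes_ambiguous_placement(self):
        low = [_aln("r1", "A" * 30, genome="A", mapq=0)]
        assert exclusivity_filter(low, "A", "B") == []

    def test_inclusive_vs_strict_gate(self):
        at_gate = [_aln("r1", "A" * 30, genome="A", mapq=25)]
        assert len(exclusivity_filter(at_gate, "A", "B", mq_min=25)) == 1
        assert exclusivity_filter(at_gate, "A", "B", mq_min=25, strict=True) == []


def _column_state(counts: dict[str, int], dmg_a=0, pcr: dict[str, int] | None = None,
                  **kwargs):
    """Build a single-column pileup by hand and call it."""
    pile = Pileup.empty(1)
    for b, n in counts.items():
        pile.counts[0, "ACGT-".index(b)] = n
    pile.dmg_a_plus[0] = dmg_a
    for b, n in (pcr or {}).items():
        pile.pcr[0, "ACGT-".index(b)] = n
    return call_consensus(pile, **kwargs)


class TestCallConsensus:
    def test_clean_majority(self):
        state = _column_state({"G": 5})
        assert state.sequence == "G" and state.flags[0] == frozenset()

    def test_single_read_not_called(self):
        state = _column_state({"G": 1})
        assert state.sequence == "N"
        assert FLAG_SINGLE_COVERAGE in state.flags[0]

    def test_no_coverage(self):
        state = _column_state({})
        assert state.sequence == "N"
        assert FLAG_NO_COVERAGE in state.flags[0]

    def test_damage_explained_dispute_keeps_majority(self):
        """G column with 3/9 terminal A disagreements stays G, flagged."""
        state = _column_state({"G": 6, "A": 3}, dmg_a=3)
        assert state.sequence == "G"
        assert {FLAG_DISPUTED, FLAG_DAMAGE_EXPLAINED} <= state.flags[0]

    def test_unexplained_dispute_without_pcr_is_n(self):
        state = _column_state({"G": 6, "A": 3}, dmg_a=0)
        assert state.sequence == "N"
        assert FLAG_DISPUTED in state.flags[0]

    def test_unexplained_dispute_with_pcr_confirmation_kept(self):
        state = _column_state({"G": 6, "A": 3}, dmg_a=0, pcr={"G": 1})
        assert state.sequence == "G"

    def test_tie_is_n_and_disputed(self):
        state = _column_state({"C": 2, "T": 2})
        assert state.sequence == "N"
        assert FLAG_DISPUTED in state.flags[0]

    def test_pcr_counts_toward_concordance(self):
        """One read plus one PCR fragment reach the two-sequence floor."""
        state = _column_state({"G": 1}, pcr={"G": 1})
        assert state.sequence == "G"

    def test_minority_below_dispute_threshold_unflagged(self):
        state = _column_state({"G": 9, "A": 2})  # 18% < 25%
        assert state.sequence == "G" and FLAG_DISPUTED not in state.flags[0]


class TestProposePcrTargets:
    def _state_with_flags(self, length, gaps=(), singles=()):
        pile = Pileup.empty(length)
        for i in range(length):
            if i in gaps:
                continue
            depth = 1 if i in singles else 3
            pile.counts[i, 0] = depth
        return call_consensus(pile)

    def test_two_separated_gaps_two_intervals(self):
        state = self._state_with_flags(1000, gaps={10, 11, 12, 500})
        targets = propose_pcr_targets(state)
        assert len(targets) == 2
        covered = set()
        for s, e in targets:
            covered.update(range(s, e))
        assert {10, 11, 12, 500} <= covered

    def test_fully_called_state_empty(self):
        state = self._state_with_flags(200)
        assert propose_pcr_targets(state) == []

    def test_many_scattered_gap_and_singleton_positions_covered(self):
        """169 gap + 144 singleton positions are all covered by the proposal."""
        rng = np.random.default_rng(17)
        flagged = rng.choice(16000, size=313, replace=False)
        gaps, singles = set(flagged[:169].tolist()), set(flagged[169:].tolist())
        state = self._state_with_flags(16000, gaps, singles)
        assert sum(e - s for s, e in state.gap_report) == 169
        assert len(state.singleton_report) == 144
        targets = propose_pcr_targets(state)
        covered = set()
        for s, e in targets:
            assert e - s <= 150 or e - s <= 2 * 25 + 1
            covered.update(range(s, e))
        assert gaps | singles <= covered


@pytest.fixture(scope="module")
def small_run():
    panel = cp.generate_panel(seed=71, n_genomes=2, length=3000, divergence=0.05)
    refs = [
        cp.ReferenceGenome("refA", mutate(panel[0].sequence, 0.01, 1)),
        cp.ReferenceGenome("refB", mutate(panel[1].sequence, 0.01, 2)),
    ]
    total = int(2 * 3000 * 25 / 48)
    pool = cp.simulate_reads(
        panel, [0.5, 0.5], total,
        damage=cp.DamageModel(delta3=0.1, delta5=0.1, decay=0.5, err=0.001),
        seed=72,
    )
    states, log, final_unique = coassemble_pool(pool.reads, refs)
    return panel, refs, pool, states, log, final_unique


class TestIterativeCoassembly:
    def test_consensus_matches_truth_over_called_positions(self, small_run):
        panel, _, _, states, _, _ = small_run
        for state, truth in zip(states, panel):
            called = [(a, b) for a, b in zip(state.sequence, truth.sequence) if a != "N"]
            acc = sum(a == b for a, b in called) / len(called)
            assert acc >= 0.999
            assert len(called) > 0.5 * len(truth)

    def test_converges_within_budget(self, small_run):
        _, _, _, _, log, _ = small_run
        assert log.converged and log.n_iterations <= 5

    def test_gap_report_matches_final_coverage_exactly(self, small_run):
        _, _, _, states, _, final_unique = small_run
        for state in states:
            depth = state.pileup.counts.sum(axis=1) + state.pileup.pcr.sum(axis=1)
            zero_runs = []
            start = None
            for i, d in enumerate(depth):
                if d == 0 and start is None:
                    start = i
                elif d > 0 and start is not None:
                    zero_runs.append((start, i))
                    start = None
            if start is not None:
                zero_runs.append((start, len(depth)))
            assert state.gap_report == zero_runs
            assert state.singleton_report == [i for i, d in enumerate(depth) if d == 1]

    def test_exclusivity_soundness(self, small_run):
        """No read in one genome's final pileup maps within the ceiling to
        the other genome's final consensus."""
        from copromito.align import IndexedGenome, maxdiff as md
        from copromito.coassembly import _edit_vs_consensus
        from copromito._seq import encode

        _, _, _, states, _, final_unique = small_run
        cons = {s.genome_id: encode(s.sequence) for s in states}
        other = {"refA": "refB", "refB": "refA"}
        ig = {s.genome_id: IndexedGenome(
            cp.ReferenceGenome(s.genome_id, s.sequence)) for s in states}
        from copromito.align import align_read
        from copromito.types import Read

        rng = np.random.default_rng(0)
        sample = rng.choice(len(final_unique), size=min(150, len(final_unique)), replace=False)
        for idx in sample:
            a = final_unique[idx]
            read = Read(a.read_id, a.bases, "F" * len(a.bases))
            hits = align_read(read, [ig[other[a.genome_id]].genome])
            assert all(h.edit_distance > 0 for h in hits)

    def test_rerun_is_deterministic(self, small_run):
        panel, refs, pool, states, _, _ = small_run
        states2, _, _ = coassemble_pool(pool.reads, refs)
        assert [s.sequence for s in states2] == [s.sequence for s in states]

    def test_absent_taxon_stays_uncalled(self, single_genome):
        pool = cp.simulate_reads([single_genome], [1.0], 800,
                                 damage=cp.DamageModel(), seed=40)
        rng = np.random.default_rng(91)
        junk = cp.ReferenceGenome(
            "junk", "".join("ACGT"[i] for i in rng.integers(0, 4, 2000)))
        states, log, _ = coassemble_pool(pool.reads, [single_genome, junk])
        present, absent = states
        assert absent.n_uncalled > 0.95 * len(junk)
        assert present.n_uncalled < 0.1 * len(single_genome)

    def test_pcr_fragments_fill_gaps_monotonically(self, single_genome):
        """Error-free fragments covering the gaps drive no_coverage to zero
        on the covered spans and never increase the N count."""
        pool = cp.simulate_reads([single_genome], [1.0], 250,
                                 damage=cp.DamageModel(), seed=41)
        rng = np.random.default_rng(92)
        junk = cp.ReferenceGenome(
            "junk", "".join("ACGT"[i] for i in rng.integers(0, 4, 2000)))
        bare, _, _ = coassemble_pool(pool.reads, [single_genome, junk])
        targets = propose_pcr_targets(bare[0])
        frags = cp.simulate_pcr_fragments(single_genome, targets)
        filled, _, _ = coassemble_pool(
            pool.reads, [single_genome, junk],
            pcr_fragments={single_genome.id: frags})
        assert filled[0].n_uncalled <= bare[0].n_uncalled
        covered = set()
        for s, e in targets:
            covered.update(range(s, e))
        gap_positions = {
            p for s, e in filled[0].gap_report for p in range(s, e)
        }
        assert not (gap_positions & covered)
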