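"""Synthetic-data generator: determinism, divergence, lengths, damage, PCR."""

import numpy as np
import pytest

import copromito as cp
from copromito.errors import ParameterError
from copromito.synthetic import FragmentLengthModel


def hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


class TestGeneratePanel:
    def test_zero_divergence_gives_identical_sequences(self):
        g = cp.generate_panel(seed=1, n_genomes=2, length=16000, divergence=0.0)
        assert g[0].sequence == g[1].sequence

    def test_divergence_matches_binomial_expectation(self):
        g = cp.generate_panel(seed=1, n_genomes=2, length=16000, divergence=0.05)
        d = hamming(g[0].sequence, g[1].sequence)
        mean, sd = 16000 * 0.05, np.sqrt(16000 * 0.05 * 0.95)
        assert abs(d - mean) < 3 * sd

    def test_large_panel_all_pairwise_distinct(self):
        g = cp.generate_panel(seed=1, n_genomes=49, length=16000, divergence=0.08)
        assert len(g) == 49
        seqs = [x.sequence for x in g]
        assert len(set(seqs)) == 49

    def test_every_genome_carries_valid_cds(self):
        from copromito.annotate import MITO_STOPS

        for g in cp.generate_panel(seed=9, n_genomes=3, length=2000, divergence=0.1):
            (feat,) = [f for f in g.features if f.kind == "CDS"]
            cds = g.sequence[feat.start : feat.end]
            assert len(cds) % 3 == 0
            assert cds[:3] == "ATG" and cds[-3:] == "TAA"
            assert not any(
                cds[i : i + 3] in MITO_STOPS for i in range(3, len(cds) - 3, 3)
            )

    def test_determinism(self):
        a = cp.generate_panel(seed=3, n_genomes=3, length=1500, divergence=0.1)
        b = cp.generate_panel(seed=3, n_genomes=3, length=1500, divergence=0.1)
        assert [g.sequence for g in a] == [g.sequence for g in b]

    @pytest.mark.parametrize("kwargs", [
        {"n_genomes": 0}, {"divergence": 0.3}, {"divergence": -0.1}, {"length": 500},
    ])
    def test_parameter_errors(self, kwargs):
        args = {"seed": 1, "n_genomes": 2, "length": 2000, "divergence": 0.05}
        args.update(kwargs)
        with pytest.raises(ParameterError):
            cp.generate_panel(**args)


class TestSimulateReads:
    def test_noise_free_reads_are_exact_substrings(self, single_genome):
        pool = cp.simulate_reads([single_genome], [1.0], 300, damage=cp.DamageModel(), seed=2)
        doubled = single_genome.sequence * 2
        from copromito._seq import revcomp

        for r in pool.reads:
            assert r.bases in doubled or revcomp(r.bases) in doubled

    def test_truth_table_is_complete_and_consistent(self, single_genome):
        pool = cp.simulate_reads([single_genome], [1.0], 200, damage=cp.DamageModel(), seed=2)
        assert len(pool.truth) == 200
        L = len(single_genome)
        for read, row in zip(pool.reads, pool.truth.itertuples()):
            assert read.id == row.read_id
            assert (row.end - row.start) % L == len(read) % L

    def test_median_read_length_near_48(self, single_genome):
        pool = cp.simulate_reads([single_genome], [1.0], 10000, damage=cp.DamageModel(), seed=3)
        med = np.median([len(r) for r in pool.reads])
        assert 46 <= med <= 50

    def test_lengths_within_usable_range(self, single_genome):
        pool = cp.simulate_reads([single_genome], [1.0], 2000, damage=cp.DamageModel(), seed=4)
        lens = [len(r) for r in pool.reads]
        assert min(lens) >= 20 and max(lens) <= 101

    def test_terminal_damage_rate_recovered(self, single_genome):
        """Empirical G->A rate at the 3'-terminal base and at distance 3
        matches delta3 * decay**d within 3 binomial sigma."""
        dm = cp.DamageModel(delta3=0.3, delta5=0.0, decay=0.5, err=0.0)
        pool = cp.simulate_reads([single_genome], [1.0], 50000, damage=dm, seed=5)
        from copromito._seq import revcomp

        hits = {0: 0, 3: 0}
        opps = {0: 0, 3: 0}
        for read, row in zip(pool.reads, pool.truth.itertuples()):
            frag = single_genome.fragment(row.start, row.end) if row.end != row.start else ""
            src = revcomp(frag) if row.strand == "-" else frag  # read-strand original
            l = len(read)
            for d in (0, 3):
                i = l - 1 - d
                if src[i] == "G":
                    opps[d] += 1
                    if read.bases[i] == "A":
                        hits[d] += 1
        for d, expected in ((0, 0.3), (3, 0.3 * 0.5**3)):
            rate = hits[d] / opps[d]
            sd = np.sqrt(expected * (1 - expected) / opps[d])
            assert abs(rate - expected) < 3 * sd, (d, rate, expected)

    def test_per_genome_proportions(self, two_genome_panel, clean_pool):
        counts = clean_pool.truth["source"].value_counts()
        n = len(clean_pool)
        for gid, p in zip([g.id for g in two_genome_panel], [0.7, 0.3]):
            sd = np.sqrt(n * p * (1 - p))
            assert abs(counts[gid] - n * p) < 3 * sd

    def test_byte_identical_given_seed(self, two_genome_panel):
        kw = dict(proportions=[0.5, 0.5], total=500, seed=11,
                  damage=cp.DamageModel(delta3=0.2, decay=0.5, err=0.01))
        a = cp.simulate_reads(two_genome_panel, **kw)
        b = cp.simulate_reads(two_genome_panel, **kw)
        assert [(r.id, r.bases, r.quals) for r in a.reads] == [
            (r.id, r.bases, r.quals) for r in b.reads
        ]
        assert a.truth.equals(b.truth)

    def test_duplicate_rate(self, single_genome):
        pool = cp.simulate_reads([single_genome], [1.0], 5000,
                                 damage=cp.DamageModel(), seed=6, duplicate_rate=0.2)
        n_fresh = 5000 - pool.truth["read_id"].duplicated().sum()
        # duplicates copy an earlier row including coordinates
        uniq = pool.truth.drop_duplicates(["source", "start", "end", "strand"])
        mean = 1 + 4999 * 0.8
        sd = np.sqrt(4999 * 0.8 * 0.2)
        assert abs(len(uniq) - mean) < 3 * sd + 5  # small slack for coincidental overlaps

    def test_parameter_errors(self, single_genome):
        with pytest.raises(ParameterError):
            cp.simulate_reads([], [1.0], 10)
        with pytest.raises(ParameterError):
            cp.simulate_reads([single_genome], [0.0], 10)


class TestPcrFragments:
    def test_plain_interval(self, single_genome):
        (frag,) = cp.simulate_pcr_fragments(single_genome, [(0, 100)])
        assert frag.sequence == single_genome.sequence[:100]

    def test_wrapping_interval(self, single_genome):
        L = len(single_genome)
        (frag,) = cp.simulate_pcr_fragments(single_genome, [(L - 10, 5)])
        assert len(frag.sequence) == 15
        assert frag.sequence == single_genome.sequence[-10:] + single_genome.sequence[:5]

    def test_sixteen_fragments_totalling_609(self, single_genome):
        """Sixteen disjoint amplicons concatenating to 609 informative bases."""
        sizes = [38] * 15 + [39]
        assert sum(sizes) == 609
        intervals, pos = [], 0
        for s in sizes:
            intervals.append((pos, pos + s))
            pos += s + 25
        frags = cp.simulate_pcr_fragments(single_genome, intervals)
        assert len(frags) == 16
        assert sum(len(f) for f in frags) == 609

    def test_out_of_range_interval(self, single_genome):
        with pytest.raises(ParameterError):
            cp.simulate_pcr_fragments(single_genome, [(0, len(single_genome) + 1)])


def test_fragment_length_model_validation():
    with pytest.raises(ParameterError):
        FragmentLengthModel(median=10)
    with pytest.raises(ParameterError):
        FragmentLengthModel(sigma=0)


def test_damage_model_validation():
    with pytest.raises(ParameterError):
        cp.DamageModel(delta3=1.5)
    with pytest.raises(ParameterError):
        cp.DamageModel(decay=1.0)
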