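# copromito

Reconstruction of two mitochondrial genomes from one mixed ancient-DNA
read pool — the computational situation posed by a carnivore coprolite,
which contains short, damaged DNA fragments of both the producer (the
carnivore) and its prey. `copromito` implements the full desk-side
workflow as a tested, reusable Python library with a CLI:

- **Competitive taxonomic assignment**: reads are credited to a panel
  mitogenome only on a perfect, full-length, single-genome match; shared
  and imperfect reads are tallied separately so the categories partition
  the pool exactly.
- **Simultaneous iterative co-assembly**: the pool is aligned to both
  candidate genomes at once; per genome, only reads mapping *exclusively*
  to it (mapping quality ≥ 25) survive, duplicates collapse to unique
  reads, and a majority consensus is called per position from ≥ 2
  concordant unique sequences; columns with > 25% disagreement are kept
  only when the conflict is explained by terminal G→A damage or confirmed
  by PCR evidence. Realignment to the provisional consensuses iterates to
  a fixed point, and uncovered/single-read positions become PCR amplicon
  proposals.
- **Damage authentication**: substitution-rate profiles by distance from
  the read ends; an elevated terminal 3' G→A (or 5' C→T) rate relative to
  the interior plateau is the ancientness hallmark.
- **Short-read alignment** with a read-length-dependent edit ceiling: the
  maximum edit distance is the smallest k with
  P(Poisson(0.02·l) > k) < 0.1 — one mismatch for 20–26 nt reads up to
  four for 88–101 nt reads — with capped gap openings and a three-tier
  uniqueness mapping quality.
- **Annotation transfer** through a banded global alignment, with CDS
  validation under the vertebrate mitochondrial genetic code.
- **Difference-count phylogenetics**: p-distances with complete deletion,
  Neighbor-Joining, and 500-replicate column bootstrap.
- **Pseudo-haploid SNP genotyping** (majority base, depth ≥ 2, third
  allele → missing), allele-sharing distances, and classical (Torgerson)
  multidimensional scaling.
- **Radiocarbon combination** of replicate measurements (truncated mean,
  quadrature sigma).
- A **synthetic ancient-read generator** (lognormal fragment lengths with
  median 48 nt, geometric terminal deamination, uniform error, truth
  tables) so that every stage is testable end-to-end without any external
  data.

## Worked example

```python
import numpy as np
import copromito as cp

# two circular 16-kb "mitogenomes" at 5% divergence: prey and producer
truthA, truthB = cp.generate_panel(seed=601, n_genomes=2, length=16000,
                                   divergence=0.05)

# an ancient library: 30x per genome, median 48 nt, terminal damage
pool = cp.simulate_reads(
    [truthA, truthB], proportions=[0.5, 0.5], total=20000,
    damage=cp.DamageModel(delta3=0.1, delta5=0.1, decay=0.5, err=0.001),
    seed=602)

# who is in the pool?
table = cp.assign_reads(pool.reads, [truthA, truthB])
print(table.to_frame().head(2).to_string(index=False))

# co-assemble both genomes starting from imperfect references
def perturb(seq, rate, seed):
    rng = np.random.default_rng(seed)
    out = list(seq)
    for i in np.nonzero(rng.random(len(out)) < rate)[0]:
        out[i] = "ACGT"[("ACGT".index(out[i]) + int(rng.integers(1, 4))) % 4]
    return "".join(out)

refA = cp.ReferenceGenome("refA", perturb(truthA.sequence, 0.01, 11))
refB = cp.ReferenceGenome("refB", perturb(truthB.sequence, 0.01, 12))
stateA, stateB, log = cp.iterate_coassembly(pool.reads, refA, refB)
called = [(a, b) for a, b in zip(stateA.sequence, truthA.sequence) if a != "N"]
print(f"converged={log.converged} after {log.n_iterations} iterations; "
      f"genome A: {len(called)} positions called, "
      f"identity {sum(a == b for a, b in called) / len(called):.4%}")

# combine two radiocarbon measurements of the dated specimen
combined = cp.combine_dates([cp.RadiocarbonDate(32316, 215),
                             cp.RadiocarbonDate(32623, 200)])
print(f"combined age: {combined.date.age:.0f} +/- {combined.date.sigma:.0f} BP")
```

Output:

```
genome_id  n_perfect_unique  fraction
  genome0              7777   0.38885
  genome1              7660   0.38300
converged=True after 3 iterations; genome A: 12729 positions called, identity 100.0000%
combined age: 32469 +/- 147 BP
```

Reading it: a large share of reads is perfect-unique for each genome (the
rest carry damage/error, fall in shared windows, or are short), the
co-assembly converges in a handful of realignment rounds, called positions
are essentially exact while ambiguous low-divergence regions stay uncalled
(N) pending PCR evidence, and the two radiocarbon replicates combine to
32,469 ± 147 BP.

## Command line

```bash
copromito simulate --seed 1 --out sim/
copromito coassemble --reads sim/reads.fastq --refs refs.fasta --out run/
copromito c14 --dates dates.tsv
copromito run --config cfg.yaml --inputs inputs.yaml --out run/
```

Subcommands: `simulate`, `preprocess`, `align`, `assign`, `coassemble`,
`authenticate`, `annotate`, `phylo`, `popgen`, `c14`, `run`. All
configuration lives in a strict YAML (`PipelineConfig`); unknown keys are
errors. Reports are plain TSV/FASTA/SAM/newick; logging goes to stderr.

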