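"""Pipeline orchestration: stages, run directory, manifest, SAM export.

Stages run in the fixed order preprocess -> assign -> coassemble ->
authenticate -> annotate -> phylo -> popgen -> radiocarbon, each skippable
via the config's stage toggles.  Every stage writes machine-readable
reports into the run directory; logging goes to stderr.  Reports use
1-based inclusive coordinates only where their headers say so; all files
written here are 0-based half-open unless stated.
"""

from __future__ import annotations

import json
import logging
import sys
from pathlib import Path

import pandas as pd

from . import __version__
from .align import AlignerParams, ReadAlignment, align_pool
from .annotate import global_align, project_features, projections_to_frame, validate_cds
from .assign import assign_reads
from .coassembly import coassemble_pool
from .config import PipelineConfig
from .damage import authenticity_verdict, profile_damage
from .errors import ConfigError
from .io import read_fasta, read_fastq, read_tsv, write_fasta, write_fastq, write_tsv
from .phylo import bootstrap_support, pairwise_differences
from .popgen import GenotypeMatrix, SNPPanel, classical_mds, genotype_sites, pairwise_allele_distance
from .preprocess import trim_pool
from .radiocarbon import combine_dates
from .synthetic import PcrFragment
from .types import Feature, RadiocarbonDate, Read, ReferenceGenome

log = logging.getLogger("copromito")

_STAGE_INPUTS = {
    "preprocess": ["reads"],
    "assign": ["reads", "panel"],
    "coassemble": ["reads", "refs"],
    "authenticate": ["reads", "refs"],
    "annotate": ["refs", "features"],
    "phylo": ["alignment"],
    "popgen": ["snp_panel", "ref_genotypes"],
    "radiocarbon": ["c14"],
}


def write_sam(path: str | Path, alignments: list[ReadAlignment], refs: list[ReferenceGenome]) -> None:
    """Minimal unsorted SAM export: POS 1-based, NM = edit distance."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for g in refs:
            fh.write(f"@SQ\tSN:{g.id}\tLN:{len(g)}\n")
        for a in alignments:
            flag = 16 if a.strand == "-" else 0
            l = len(a.bases)
            if a.split is None:
                cigar = f"{l}M"
            else:
                p, s = a.split
                if s > 0:
                    cigar = f"{p}M{s}D{l - p}M"
                else:
                    cigar = f"{p}M{-s}I{l - p + s}M"
            seq = a.bases if a.strand == "+" else a.bases  # stored as sequenced
            fh.write(
                f"{a.read_id}\t{flag}\t{a.genome_id}\t{a.start + 1}\t{a.mapq}\t{cigar}"
                f"\t*\t0\t0\t{seq}\t*\tNM:i:{a.edit_distance}\n"
            )


def _read_pcr_fragments(path: str | Path) -> dict[str, list[PcrFragment]]:
    frame = read_tsv(path)
    out: dict[str, list[PcrFragment]] = {}
    for row in frame.itertuples():
        out.setdefault(row.genome_id, []).append(
            PcrFragment(row.id, int(row.start), int(row.end), row.sequence)
        )
    return out


def _read_features(path: str | Path) -> list[Feature]:
    frame = read_tsv(path)
    return [
        Feature(r.name, r.kind, int(r.start), int(r.end), r.strand)
        for r in frame.itertuples()
    ]


def run_pipeline(config: PipelineConfig, inputs: dict[str, str], outdir: str | Path) -> Path:
    """Run the enabled stages over ``inputs``; returns the run directory.

    ``inputs`` maps logical names (reads, panel, refs, pcr, features,
    alignment, snp_panel, ref_genotypes, c14) to file paths.  Every input
    required by an enabled stage is checked before any stage runs.
    """
    logging.basicConfig(stream=sys.stderr, level=logging.INFO, format="%(name)s: %(message)s")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    enabled = [s for s in _STAGE_INPUTS if config.stages.get(s, True)]
    missing = []
    for stage in enabled:
        for key in _STAGE_INPUTS[stage]:
            if key not in inputs:
                missing.append(f"{stage} needs input {key!r}")
            elif not Path(inputs[key]).exists():
                missing.append(f"{stage}: input file {inputs[key]} not found")
    if missing:
        raise ConfigError("; ".join(missing))

    aligner = AlignerParams(
        err=config.err,
        miss_thres=config.miss_thres,
        max_gap_opens=config.max_gap_opens,
        seed_len=config.seed_len,
    )

    reads: list[Read] | None = None
    refs: list[ReferenceGenome] | None = None
    final_unique: list[ReadAlignment] = []
    consensus_states = []

    if "reads" in inputs and any(s in enabled for s in ("preprocess", "assign", "coassemble", "authenticate")):
        reads = read_fastq(inputs["reads"])

    if "preprocess" in enabled:
        log.info("preprocess: trimming %d reads", len(reads))
        reads, report = trim_pool(
            reads, config.adapter, config.qual_floor, config.min_read_len
        )
        write_tsv(outdir / "trim_report.tsv", pd.DataFrame([report.__dict__]))
        write_fastq(outdir / "trimmed.fastq", reads)

    if "assign" in enabled:
        panel = read_fasta(inputs["panel"])
        log.info("assign: %d reads vs %d genomes", len(reads), len(panel))
        table = assign_reads(reads, panel, aligner)
        write_tsv(outdir / "assignment.tsv", table.to_frame())

    if "coassemble" in enabled or "authenticate" in enabled:
        refs = read_fasta(inputs["refs"])
        pcr = _read_pcr_fragments(inputs["pcr"]) if inputs.get("pcr") else None
        log.info("coassemble: %d reads vs %d references", len(reads), len(refs))
        consensus_states, colog, final_unique = coassemble_pool(
            reads,
            refs,
            aligner,
            pcr_fragments=pcr,
            mq_min=config.mq_min,
            mq_strict=config.mq_strict,
            min_concordant=config.min_concordant,
            dispute_frac=config.dispute_frac,
            damage_window=config.damage_window,
            max_iterations=config.max_iterations,
        )
        if colog.warning:
            log.warning("coassemble: %s", colog.warning)
        write_tsv(outdir / "coassembly_log.tsv", colog.rows)
        out_genomes = [
            ReferenceGenome(s.genome_id, s.sequence, circular=r.circular)
            for s, r in zip(consensus_states, refs)
        ]
        write_fasta(outdir / "consensus.fasta", out_genomes)
        for state in consensus_states:
            write_tsv(outdir / f"columns_{state.genome_id}.tsv", state.to_frame())
            with open(outdir / f"gaps_{state.genome_id}.bed", "w") as fh:
                for s, e in state.gap_report:
                    fh.write(f"{state.genome_id}\t{s}\t{e}\tno_coverage\n")
                for p in state.singleton_report:
                    fh.write(f"{state.genome_id}\t{p}\t{p + 1}\tsingle_coverage\n")
        write_sam(outdir / "final_unique.sam", final_unique, out_genomes)

    if "authenticate" in enabled:
        state = consensus_states[0]
        mine = [a for a in final_unique if a.genome_id == state.genome_id]
        profile = profile_damage(mine, state.sequence)
        verdict = authenticity_verdict(profile, config.fold_threshold)
        write_tsv(outdir / "damage_5p.tsv", profile.to_frame("5"))
        write_tsv(outdir / "damage_3p.tsv", profile.to_frame("3"))
        write_tsv(
            outdir / "damage_summary.tsv",
            pd.DataFrame(
                [
                    {
                        "n_aligned_bases": profile.n_aligned_bases,
                        "n_mismatches": profile.n_mismatches,
                        "identity_fraction": profile.identity_fraction,
                        "median_read_length": profile.median_read_length,
                        "verdict": verdict,
                    }
                ]
            ),
        )

    if "annotate" in enabled:
        if refs is None:
            refs = read_fasta(inputs["refs"])
        features = _read_features(inputs["features"])
        target = (
            consensus_states[0].sequence if consensus_states else refs[0].sequence
        )
        aln = global_align(
            ReferenceGenome("consensus", target, circular=refs[0].circular), refs[0]
        )
        projections = project_features(aln, features)
        for p in projections:
            if p.kind == "CDS":
                p.validation = validate_cds(p, aln.rotated_consensus)
        write_tsv(outdir / "annotation.tsv", projections_to_frame(projections))

    if "phylo" in enabled:
        from .phylo import ConcatAlignment

        genomes = read_fasta(inputs["alignment"], circular=False)
        aln = ConcatAlignment([g.id for g in genomes], [g.sequence for g in genomes])
        D, sites = pairwise_differences(aln)
        write_tsv(
            outdir / "differences.tsv",
            pd.DataFrame(D, index=aln.taxa, columns=aln.taxa).reset_index(),
        )
        tree, supports = bootstrap_support(aln, config.bootstrap_reps, config.seed)
        (outdir / "tree.nwk").write_text(tree.to_newick() + "\n")

    if "popgen" in enabled:
        panel = SNPPanel(read_tsv(inputs["snp_panel"]))
        ref_gt = read_tsv(inputs["ref_genotypes"], index_col=0)
        sample_alns = [a for a in final_unique] if final_unique else []
        ref_len = len(refs[0]) if refs else int(panel.sites["pos"].max()) + 1
        row = genotype_sites(sample_alns, panel, ref_len, config.min_depth, config.mq_min)
        matrix = GenotypeMatrix(
            samples=list(ref_gt.index) + ["sample"],
            calls=pd.concat([ref_gt, pd.DataFrame([row], index=["sample"])]).to_numpy(),
        )
        D = pairwise_allele_distance(matrix, config.min_shared)
        coords, evals = classical_mds(D, k=2)
        write_tsv(
            outdir / "mds.tsv",
            pd.DataFrame(coords, columns=[f"dim{i + 1}" for i in range(coords.shape[1])]).assign(
                sample=matrix.samples
            ),
        )
        write_tsv(outdir / "genotypes.tsv", matrix.to_frame().reset_index())

    if "radiocarbon" in enabled:
        frame = read_tsv(inputs["c14"])
        dates = [
            RadiocarbonDate(float(r.age), float(r.sigma), str(r.label))
            for r in frame.itertuples()
        ]
        combined = combine_dates(dates)
        write_tsv(
            outdir / "c14_combined.tsv",
            pd.DataFrame(
                [
                    {
                        "age_bp": combined.date.age,
                        "sigma": combined.date.sigma,
                        "method": combined.method,
                        "n": combined.n,
                        "consistency_t": combined.consistency_t,
                    }
                ]
            ),
        )

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config_digest": config.digest(),
        "stages_run": enabled,
        "inputs": {k: str(v) for k, v in inputs.items()},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return outdir
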