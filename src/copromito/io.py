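"""FASTA/FASTQ/TSV readers and writers.

Format parsing is delegated to Biopython's SeqIO; this layer normalises
sequences (upper case, U rejected), converts records into the package's
domain types and turns malformed input into :class:`ParseError` naming the
offending record.  Empty files yield empty lists with a warning rather than
an error.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._seq import validate_dna
from .errors import ParseError
from .types import Read, ReferenceGenome


def read_fasta(path: str | Path, circular: bool = True) -> list[ReferenceGenome]:
    """Read a (possibly wrapped, possibly lower-case) FASTA file.

    Sequences are upper-cased; U and other non-DNA letters are rejected.
    """
    path = Path(path)
    genomes: list[ReferenceGenome] = []
    try:
        for i, rec in enumerate(SeqIO.parse(str(path), "fasta")):
            try:
                seq = validate_dna(str(rec.seq), allow_n=True, context=f"record {rec.id!r}")
            except ValueError as exc:
                raise ParseError(f"{path}: record {i + 1} ({rec.id!r}): {exc}") from exc
            if not seq:
                raise ParseError(f"{path}: record {i + 1} ({rec.id!r}) has an empty sequence")
            genomes.append(ReferenceGenome(rec.id, seq, circular=circular))
    except ValueError as exc:
        if isinstance(exc, ParseError):
            raise
        raise ParseError(f"{path}: {exc}") from exc
    if not genomes:
        warnings.warn(f"{path}: no FASTA records found", stacklevel=2)
    return genomes


def write_fasta(path: str | Path, genomes: list[ReferenceGenome], width: int = 60) -> None:
    records = [
        SeqRecord(Seq(g.sequence), id=g.id, description="") for g in genomes
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def read_fastq(path: str | Path) -> list[Read]:
    """Read Phred+33 FASTQ into :class:`Read` objects."""
    path = Path(path)
    reads: list[Read] = []
    try:
        for i, rec in enumerate(SeqIO.parse(str(path), "fastq")):
            try:
                bases = validate_dna(str(rec.seq), allow_n=True, context=f"record {rec.id!r}")
            except ValueError as exc:
                raise ParseError(f"{path}: record {i + 1} ({rec.id!r}): {exc}") from exc
            quals = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
            reads.append(Read(rec.id, bases, quals))
    except ValueError as exc:
        if isinstance(exc, ParseError):
            raise
        # Biopython reports the record at which parsing failed; FASTQ records
        # occupy 4 lines each, so name the earliest possibly-offending line.
        raise ParseError(f"{path}: near line {4 * len(reads) + 1}: {exc}") from exc
    if not reads:
        warnings.warn(f"{path}: no FASTQ records found", stacklevel=2)
    return reads


def write_fastq(path: str | Path, reads: list[Read]) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.bases}\n+\n{r.quals}\n")


def read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    """Read a tab-separated table (header row expected)."""
    try:
        return pd.read_csv(path, sep="\t", **kwargs)
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_tsv(path: str | Path, frame: pd.DataFrame) -> None:
    frame.to_csv(path, sep="\t", index=False)
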