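"""Annotation transfer: banded global alignment and feature projection.

A freshly assembled mitogenome is annotated by aligning it end-to-end
against an annotated reference of the same (mitogenome) scale, projecting
every feature boundary through the alignment, and validating coding
sequences under the vertebrate mitochondrial genetic code (AGA/AGG are
stops, ATA/GTG can initiate, and a coding sequence may end on an
incomplete T or TA stop completed by polyadenylation).

The aligner is a banded Needleman-Wunsch minimising unit-cost edit
distance; circular inputs are first rotated so a shared anchor k-mer near
the reference origin starts both sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._seq import encode
from .errors import BandExceededError, ParameterError
from .types import Feature, ReferenceGenome

MITO_STARTS = ("ATG", "ATA", "GTG")
MITO_STOPS = ("TAA", "TAG", "AGA", "AGG")

_INF = np.int32(2**30)


@dataclass
class GlobalAlignment:
    """End-to-end alignment of a consensus against an annotated reference.

    ``ref2cons[i]`` is the consensus column aligned to reference position i
    (-1 when that reference base is deleted); ``cons2ref`` is the inverse.
    Consensus coordinates are in the rotated frame; ``rotation`` is the
    offset such that ``rotated = consensus[rotation:] + consensus[:rotation]``.
    """

    edits: int
    ref2cons: np.ndarray = field(repr=False)
    cons2ref: np.ndarray = field(repr=False)
    aligned_ref: str = field(repr=False, default="")
    aligned_cons: str = field(repr=False, default="")
    rotation: int = 0
    rotated_consensus: str = field(repr=False, default="")


def _rotate_to_anchor(consensus: str, reference: str, ksize: int = 24) -> int:
    """Rotation of ``consensus`` aligning a shared anchor k-mer to the
    reference origin; 0 if no anchor is found (alignment proceeds unrotated)."""
    doubled = consensus + consensus
    for t in range(0, min(len(reference) - ksize, 2048), ksize):
        anchor = reference[t : t + ksize]
        if "N" in anchor:
            continue
        pos = doubled.find(anchor)
        if pos >= 0:
            return (pos - t) % len(consensus)
    return 0


def global_align(
    consensus: str | ReferenceGenome,
    annotated_ref: str | ReferenceGenome,
    band: int = 200,
    circular: bool | None = None,
) -> GlobalAlignment:
    """Banded global alignment of a consensus to an annotated reference.

    Raises :class:`BandExceededError` when the length difference cannot fit
    in the band (rerun with a larger band).
    """
    cons_seq = consensus.sequence if isinstance(consensus, ReferenceGenome) else consensus
    ref_seq = annotated_ref.sequence if isinstance(annotated_ref, ReferenceGenome) else annotated_ref
    if circular is None:
        circular = isinstance(consensus, ReferenceGenome) and consensus.circular and (
            not isinstance(annotated_ref, ReferenceGenome) or annotated_ref.circular
        )
    rotation = _rotate_to_anchor(cons_seq, ref_seq) if circular else 0
    rotated = cons_seq[rotation:] + cons_seq[:rotation]

    a = encode(rotated)  # consensus, columns
    b = encode(ref_seq)  # reference, rows
    n, m = len(a), len(b)
    if abs(n - m) >= band:
        raise BandExceededError(
            f"length difference {abs(n - m)} >= band {band}; increase the band"
        )
    width = 2 * band + 1
    offsets = np.arange(width)
    D = np.full((m + 1, width), _INF, dtype=np.int32)
    # row 0: D[0][j] = j, at o = j + band
    j0 = offsets - band
    valid0 = (j0 >= 0) & (j0 <= n)
    D[0, valid0] = j0[valid0]
    for i in range(1, m + 1):
        j = i + offsets - band  # consensus column for each band slot
        prev = D[i - 1]
        # diagonal: same slot in the previous row; substitution cost
        jm1 = j - 1
        ok = (jm1 >= 0) & (jm1 < n)
        sub = np.ones(width, dtype=np.int32)
        sub[ok] = (a[np.clip(jm1, 0, n - 1)] != b[i - 1])[ok]
        diag = np.where(ok, prev + sub, _INF)
        # up (reference base deleted): slot o+1 in the previous row
        up = np.concatenate([prev[1:], [_INF]]) + 1
        cand = np.minimum(diag, up)
        # left (consensus base inserted): prefix-min within the row
        row = np.minimum.accumulate(cand - offsets) + offsets
        row[(j < 0) | (j > n)] = _INF
        D[i] = np.minimum(row, _INF)
    end_o = n - m + band
    edits = int(D[m, end_o])
    if edits >= _INF:
        raise BandExceededError("no path within the band; increase the band")

    # traceback
    ref2cons = np.full(m, -1, dtype=np.int64)
    cons2ref = np.full(n, -1, dtype=np.int64)
    ar, ac = [], []
    i, j = m, n
    while i > 0 or j > 0:
        o = j - i + band
        here = D[i, o]
        if i > 0 and j > 0:
            sub = int(a[j - 1] != b[i - 1])
            if D[i - 1, o] + sub == here:
                ref2cons[i - 1] = j - 1
                cons2ref[j - 1] = i - 1
                ar.append(ref_seq[i - 1])
                ac.append(rotated[j - 1])
                i, j = i - 1, j - 1
                continue
        if i > 0 and o + 1 < width and D[i - 1, o + 1] + 1 == here:
            ar.append(ref_seq[i - 1])
            ac.append("-")
            i -= 1
            continue
        if j > 0 and o - 1 >= 0 and D[i, o - 1] + 1 == here:
            ar.append("-")
            ac.append(rotated[j - 1])
            j -= 1
            continue
        raise AssertionError("traceback failed")  # pragma: no cover
    return GlobalAlignment(
        edits=edits,
        ref2cons=ref2cons,
        cons2ref=cons2ref,
        aligned_ref="".join(reversed(ar)),
        aligned_cons="".join(reversed(ac)),
        rotation=rotation,
        rotated_consensus=rotated,
    )


@dataclass
class FeatureProjection:
    """A reference feature mapped into consensus coordinates."""

    name: str
    kind: str
    strand: str
    source_start: int
    source_end: int
    start: int
    end: int
    n_indels_within: int
    flagged: bool
    validation: frozenset[str] = frozenset()


def _map_boundary(ref2cons: np.ndarray, pos: int, direction: int) -> tuple[int, bool]:
    """Map a reference position; walk toward the feature interior if deleted."""
    m = len(ref2cons)
    p = pos
    flagged = False
    while 0 <= p < m and ref2cons[p] < 0:
        p += direction
        flagged = True
    if not 0 <= p < m:
        raise ParameterError(f"boundary {pos} cannot be mapped (feature fully deleted?)")
    return int(ref2cons[p]), flagged


def project_features(
    alignment: GlobalAlignment, features: list[Feature]
) -> list[FeatureProjection]:
    """Project reference features through a global alignment.

    Boundaries falling in deletions move to the nearest aligned column
    toward the feature interior and are flagged.  Feature order and strand
    are preserved (projection is monotone).
    """
    out = []
    r2c = alignment.ref2cons
    for f in features:
        if f.end < f.start:
            raise ParameterError(
                f"feature {f.name!r} wraps the origin; rotate the annotation first"
            )
        start, fl1 = _map_boundary(r2c, f.start, +1)
        end_in, fl2 = _map_boundary(r2c, f.end - 1, -1)
        end = end_in + 1
        span = r2c[f.start : f.end]
        n_del = int((span < 0).sum())
        inner = alignment.cons2ref[start:end]
        n_ins = int((inner < 0).sum())
        out.append(
            FeatureProjection(
                name=f.name,
                kind=f.kind,
                strand=f.strand,
                source_start=f.start,
                source_end=f.end,
                start=start,
                end=end,
                n_indels_within=n_del + n_ins,
                flagged=fl1 or fl2,
            )
        )
    return out


def _revcomp(seq: str) -> str:
    from ._seq import revcomp

    return revcomp(seq)


def validate_cds(
    projection: FeatureProjection, consensus: str
) -> frozenset[str]:
    """Validate a projected CDS under the vertebrate mitochondrial code.

    Returns the subset of {start_ok, stop_ok, no_internal_stop,
    length_multiple_of_3, flagged} that holds.  An incomplete terminal
    T/TA stop (completed by polyadenylation in vivo) passes stop_ok but is
    flagged.
    """
    if projection.kind != "CDS":
        raise ParameterError(f"feature {projection.name!r} is not a CDS")
    seq = consensus[projection.start : projection.end]
    if projection.strand == "-":
        seq = _revcomp(seq)
    flags: set[str] = set()
    if projection.flagged:
        flags.add("flagged")
    if len(seq) < 6:
        return frozenset(flags)
    if len(seq) % 3 == 0:
        flags.add("length_multiple_of_3")
    if seq[:3] in MITO_STARTS:
        flags.add("start_ok")
    rem = len(seq) % 3
    if rem == 0:
        if seq[-3:] in MITO_STOPS:
            flags.add("stop_ok")
        n_complete = len(seq) // 3 - 1  # exclude the stop codon itself
    else:
        tail = seq[-rem:]
        if (rem == 1 and tail == "T") or (rem == 2 and tail == "TA"):
            flags.add("stop_ok")
            flags.add("flagged")
        n_complete = len(seq) // 3
    internal = any(seq[3 * c : 3 * c + 3] in MITO_STOPS for c in range(1, n_complete))
    if not internal:
        flags.add("no_internal_stop")
    return frozenset(flags)


def projections_to_frame(projections: list[FeatureProjection]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "name": p.name,
                "kind": p.kind,
                "strand": p.strand,
                "source_start": p.source_start,
                "source_end": p.source_end,
                "start": p.start,
                "end": p.end,
                "n_indels_within": p.n_indels_within,
                "flagged": p.flagged,
                "validation": ",".join(sorted(p.validation)),
            }
            for p in projections
        ]
    )
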