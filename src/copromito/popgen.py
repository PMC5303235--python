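"""Low-coverage SNP genotyping, allele-sharing distances, classical MDS.

An ancient sample sequenced at low depth cannot support diploid calls; the
standard recourse is pseudo-haploid genotyping: at each panel site, the
majority base among mapped reads becomes a single-allele call, gated by a
minimum depth.  Samples are then compared by allele-sharing distance
(1 - fraction of matching calls over shared non-missing sites) and placed
in a low-dimensional space by classical (Torgerson) multidimensional
scaling on the double-centred squared-distance matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .align import ReadAlignment
from .errors import InsufficientOverlapError, ParameterError

MISSING = -1
REF = 0
ALT = 1


@dataclass
class SNPPanel:
    """Bi-allelic SNP sites on a reference: (chrom, 0-based pos, ref, alt)."""

    sites: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["chrom", "pos", "ref", "alt"]
        if list(self.sites.columns)[:4] != required:
            raise ParameterError(f"panel must have columns {required}")
        if self.sites.duplicated(["chrom", "pos"]).any():
            raise ParameterError("duplicate positions in SNP panel")
        for col in ("ref", "alt"):
            if not self.sites[col].isin(list("ACGT")).all():
                raise ParameterError(f"{col} alleles must be single bases A/C/G/T")
        if (self.sites["ref"] == self.sites["alt"]).any():
            raise ParameterError("ref and alt alleles must differ")

    def __len__(self) -> int:
        return len(self.sites)


@dataclass
class GenotypeMatrix:
    """Samples x sites pseudo-haploid calls: 0 = ref, 1 = alt, -1 = missing."""

    samples: list[str]
    calls: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.calls.shape[0] != len(self.samples):
            raise ParameterError("one row per sample required")

    @property
    def call_counts(self) -> np.ndarray:
        return (self.calls != MISSING).sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.calls, index=self.samples)


def genotype_sites(
    alignments: list[ReadAlignment],
    panel: SNPPanel,
    reference_length: int,
    min_depth: int = 2,
    mq_min: int = 25,
) -> np.ndarray:
    """Pseudo-haploid genotype row for one sample at the panel sites.

    Per site the majority of read bases matching ref or alt wins; the call
    is missing when covering depth is below ``min_depth``, the majority is
    tied, or any third allele is observed.  Calls are invariant to read
    order.  Alignments are gated at ``mapq >= mq_min``; sites are looked up
    by (chrom == genome id, position).
    """
    if min_depth < 1:
        raise ParameterError("min_depth must be >= 1")
    # per (chrom, pos): base -> count
    piles: dict[tuple[str, int], dict[str, int]] = {
        (row.chrom, int(row.pos)): {} for row in panel.sites.itertuples()
    }
    for a in alignments:
        if a.mapq < mq_min:
            continue
        codes = a.oriented_codes()
        l = len(codes)
        if a.split is None:
            pairs = [(i, a.start + i) for i in range(l)]
        else:
            p, s = a.split
            pairs = [(i, a.start + i) for i in range(p)]
            if s > 0:
                pairs += [(i, a.start + s + i) for i in range(p, l)]
            else:
                pairs += [(i, a.start + s + i) for i in range(p - s, l)]
        for i, raw in pairs:
            key = (a.genome_id, raw % reference_length)
            pile = piles.get(key)
            if pile is not None:
                b = "ACGTN"[codes[i]]
                pile[b] = pile.get(b, 0) + 1
    row = np.full(len(panel), MISSING, dtype=np.int8)
    for idx, site in enumerate(panel.sites.itertuples()):
        pile = piles[(site.chrom, int(site.pos))]
        depth = sum(pile.values())
        if depth < min_depth:
            continue
        third = {b: c for b, c in pile.items() if b not in (site.ref, site.alt)}
        if third:
            continue
        n_ref = pile.get(site.ref, 0)
        n_alt = pile.get(site.alt, 0)
        if n_ref == n_alt:
            continue
        row[idx] = REF if n_ref > n_alt else ALT
    return row


def pairwise_allele_distance(matrix: GenotypeMatrix, min_shared: int = 100) -> np.ndarray:
    """Allele-sharing distance: 1 - matches/shared over non-missing sites.

    Raises :class:`InsufficientOverlapError` naming every pair with fewer
    than ``min_shared`` shared called sites.
    """
    calls = matrix.calls
    n = len(matrix.samples)
    if n < 2:
        raise ParameterError("need at least two samples")
    D = np.zeros((n, n))
    bad = []
    for i in range(n):
        for j in range(i + 1, n):
            ok = (calls[i] != MISSING) & (calls[j] != MISSING)
            shared = int(ok.sum())
            if shared < min_shared:
                bad.append((matrix.samples[i], matrix.samples[j], shared))
                continue
            match = int((calls[i, ok] == calls[j, ok]).sum())
            D[i, j] = D[j, i] = 1.0 - match / shared
    if bad:
        detail = "; ".join(f"{a}-{b}: {s} shared" for a, b, s in bad)
        raise InsufficientOverlapError(f"pairs below min_shared={min_shared}: {detail}")
    return D


def classical_mds(distances: np.ndarray, k: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """Classical (Torgerson) MDS.

    Double-centres the squared distance matrix, eigendecomposes, and
    returns the top-``k`` coordinates scaled by the square root of their
    (positive) eigenvalues, plus the full eigenvalue spectrum in
    non-increasing order.  Negative eigenvalues (non-Euclidean input) are
    truncated; if fewer than ``k`` positive eigenvalues exist a smaller
    embedding is returned with a warning.
    """
    D = np.asarray(distances, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n) or not np.allclose(D, D.T) or (np.abs(np.diag(D)) > 1e-12).any():
        raise ParameterError("distance matrix must be square, symmetric, zero-diagonal")
    if k < 1:
        raise ParameterError("k must be >= 1")
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    n_pos = int((evals > 1e-10).sum())
    if n_pos < k:
        warnings.warn(
            f"only {n_pos} positive eigenvalues; returning a {n_pos}-dimensional embedding",
            stacklevel=2,
        )
        k = max(n_pos, 0)
    coords = evecs[:, :k] * np.sqrt(np.maximum(evals[:k], 0.0))
    return coords, evals
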