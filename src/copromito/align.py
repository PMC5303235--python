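"""Short-read alignment to small (circular) references.

The aligner reproduces, in documented form, the behaviour of a seed-and-
extend mapper configured for ancient reads: the maximum edit distance grows
with read length following a Poisson model of sequencing error (``maxdiff``),
gap openings are capped, and mapping quality expresses placement uniqueness
in three tiers (0 ambiguous / 20 near-ambiguous / 37 unique).

Candidate loci are found by exact k-mer seeding at every read offset on both
strands.  The effective seed length is ``min(seed_len, l // (k+1))`` where
``k = maxdiff(l)``: by the pigeonhole principle any placement within the
edit ceiling contains an exact run at least that long, so seeding finds
every acceptable placement — the aligner is fully sensitive within its own
model.  Candidates are scored by banded edit distance (band ±k around the
candidate diagonal) with at most ``max_gap_opens`` gap openings.  Circular
references are handled by extending the sequence across the origin;
positions are reported modulo the genome length and no placement is
reported twice.

Uncalled (N) reference positions count as mismatches, as they do in the
mappers this model reproduces: an N carries no evidence that a read
matches there.  During iterative co-assembly this makes the uncalled set
shrink read support monotonically, so the consensus iteration reaches a
fixed point instead of oscillating (reads can re-anchor across at most
``maxdiff`` uncalled positions per placement).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.stats import poisson

from ._seq import N, SENTINEL, encode, revcomp_codes
from .errors import ParameterError
from .types import Read, ReferenceGenome

_PAD = 112  # covers max read length (101) + max edit ceiling, with margin
_LEAD = 8


@dataclass(frozen=True)
class AlignerParams:
    """Alignment model parameters.

    ``err`` is the assumed per-base sequencing error; ``miss_thres`` the
    tolerated probability of missing a true alignment (together they define
    the read-length-dependent edit ceiling).  ``max_gap_opens`` caps gap
    openings per alignment; ``seed_len`` is the maximum exact-seed length.
    ``retain_slack`` additionally lists placements up to that many edits
    above the ceiling — they never influence mapping quality and exist so
    iterative consumers can re-gate them against updated consensuses.
    """

    err: float = 0.02
    miss_thres: float = 0.1
    max_gap_opens: int = 1
    seed_len: int = 12
    retain_slack: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.err < 1.0:
            raise ParameterError(f"err must be in [0,1), got {self.err}")
        if not 0.0 < self.miss_thres < 1.0:
            raise ParameterError(f"miss_thres must be in (0,1), got {self.miss_thres}")
        if self.max_gap_opens not in (0, 1, 2):
            raise ParameterError(f"max_gap_opens must be 0, 1 or 2, got {self.max_gap_opens}")
        if self.seed_len < 4:
            raise ParameterError(f"seed_len must be >= 4, got {self.seed_len}")
        if not 0 <= self.retain_slack <= 4:
            raise ParameterError(f"retain_slack must be in 0..4, got {self.retain_slack}")


@dataclass
class ReadAlignment:
    """One placement of a read on one reference genome.

    ``start`` is the 0-based reference position of the read's leftmost
    aligned base (modulo the genome length for circular references), for the
    read oriented to the reference strand.  ``bases`` holds the read as
    sequenced; for strand ``-`` the reference-oriented sequence is its
    reverse complement.  ``split`` encodes a single internal gap as
    ``(p, s)``: read positions ``< p`` align at diagonal 0; ``s > 0`` means
    ``s`` reference bases after offset ``p`` are deleted from the read,
    ``s < 0`` means ``-s`` read bases starting at ``p`` are inserted.
    ``co_optimal`` counts equally-best placements across the whole panel
    call; ``mapq`` is 0 when that count exceeds 1.
    """

    read_id: str
    genome_id: str
    start: int
    strand: str
    edit_distance: int
    n_gap_opens: int
    mapq: int
    co_optimal: int
    bases: str
    split: tuple[int, int] | None = None
    n_ref_n: int = 0  # uncalled reference positions covered (each counts as a mismatch)

    @property
    def informative_edit(self) -> int:
        """Edit distance discounting uncalled reference positions."""
        return self.edit_distance - self.n_ref_n

    def __len__(self) -> int:
        return len(self.bases)

    def oriented_codes(self) -> np.ndarray:
        """Read codes oriented to the reference strand."""
        codes = encode(self.bases)
        return revcomp_codes(codes) if self.strand == "-" else codes


@lru_cache(maxsize=None)
def maxdiff(length: int, err: float = 0.02, miss_thres: float = 0.1) -> int:
    """Maximum edit distance allowed for a read of the given length.

    The smallest k such that P(X > k) < ``miss_thres`` for
    X ~ Poisson(err * length): with more expected errors on longer reads,
    the ceiling rises (1 for 20-26 nt up to 4 for 88-101 nt at the
    defaults).  Monotone non-decreasing in length.
    """
    if length < 1:
        raise ParameterError(f"read length must be >= 1, got {length}")
    if err == 0:
        return 0
    lam = err * length
    k = 0
    while poisson.sf(k, lam) >= miss_thres:
        k += 1
    return k


class IndexedGenome:
    """A reference genome prepared for seeding and banded scoring."""

    def __init__(self, genome: ReferenceGenome):
        self.genome = genome
        self.L = len(genome)
        codes = encode(genome.sequence)
        if genome.circular:
            reps = 2 + (_PAD + self.L - 1) // self.L
            self.ext = np.tile(codes, reps)[: 2 * self.L + _PAD]
            self.origin = self.L  # canonical starts live at ext offsets [L, 2L)
        else:
            lead = np.full(_LEAD, SENTINEL, dtype=np.uint8)
            tail = np.full(_PAD, SENTINEL, dtype=np.uint8)
            self.ext = np.concatenate([lead, codes, tail])
            self.origin = _LEAD
        self.ext_bytes = self.ext.tobytes()
        self._indexes: dict[int, dict[bytes, list[int]]] = {}

    def index(self, slen: int) -> dict[bytes, list[int]]:
        idx = self._indexes.get(slen)
        if idx is None:
            idx = {}
            lo, hi = self.origin, self.origin + self.L
            if not self.genome.circular:
                hi -= slen - 1
            b = self.ext_bytes
            for p in range(lo, hi):
                idx.setdefault(b[p : p + slen], []).append(p)
            self._indexes[slen] = idx
        return idx

    def canonical(self, ext_pos: int) -> int | None:
        """Map an ext offset to a canonical start, or None if out of range."""
        if self.genome.circular:
            return self.origin + (ext_pos - self.origin) % self.L
        start = ext_pos - self.origin
        if start < 0 or start >= self.L:
            return None
        return ext_pos

    def score(
        self, q: np.ndarray, ext_start: int, k: int, max_go: int, slack: int = 0
    ) -> tuple[int, int, tuple[int, int] | None, int] | None:
        """Best banded, gap-capped edit distance of ``q`` anchored at ``ext_start``.

        Returns ``(cost, n_gap_opens, split, n_ref_n)`` for the best
        alignment whose first read base sits at ``ext_start``; ``n_ref_n``
        counts the uncalled (N) reference positions it covers, each already
        included in ``cost``.  A placement is retained when its edit
        distance *discounting* uncalled positions is within ``k``, so
        uncalled stretches neither hide nor fabricate cross-mapping.
        """
        l = len(q)
        ext = self.ext
        w0 = ext[ext_start : ext_start + l]
        isn0 = w0 == N
        mm0 = (w0 != q) | (w0 >= N)
        best_cost = int(mm0.sum())
        nw0 = int(isn0.sum())
        best: tuple[int, int, tuple[int, int] | None, int] = (best_cost, 0, None, nw0)
        if best_cost == 0 or max_go == 0 or k < 1:
            return best if best_cost - nw0 <= k + slack else None
        if max_go >= 2:
            dp = _dp_score(q, ext, ext_start, k, max_go)
            if dp is not None and dp[0] < best[0]:
                best = (dp[0], dp[1], dp[2], 0)
            return best if best[0] - best[3] <= k + slack else None
        p0 = np.concatenate([[0], np.cumsum(mm0)])
        n0 = np.concatenate([[0], np.cumsum(isn0)])
        for s in range(-k, k + 1):
            if s == 0 or ext_start + s < 0:
                continue
            ws = ext[ext_start + s : ext_start + s + l]
            isns = ws == N
            mms = (ws != q) | (ws >= N)
            cs = np.concatenate([[0], np.cumsum(mms)])
            suf = cs[l] - cs  # suf[j] = mismatches of q[j:] on diagonal s
            ns = np.concatenate([[0], np.cumsum(isns)])
            nsuf = ns[l] - ns
            if s > 0:
                if l < 2:
                    continue
                vals = p0[1:l] + suf[1:l]
                j = int(np.argmin(vals))
                cost = s + int(vals[j])
                split = (j + 1, s)
                nw = int(n0[j + 1] + nsuf[j + 1])
            else:
                g = -s
                if g + 1 > l - 1:
                    continue
                vals = p0[1 : l - g] + suf[g + 1 : l]
                j = int(np.argmin(vals))
                cost = g + int(vals[j])
                split = (j + 1, s)
                nw = int(n0[j + 1] + nsuf[j + 1 + g])
            if cost < best[0]:
                best = (cost, 1, split, nw)
        return best if best[0] - best[3] <= k + slack else None


def _dp_score(
    q: np.ndarray, ext: np.ndarray, ext_start: int, k: int, max_go: int
) -> tuple[int, int, tuple[int, int] | None] | None:
    """Banded DP allowing up to ``max_go`` gap openings (slow generic path).

    State after consuming ``i`` read bases: (diagonal, opens so far, last
    op), with ops M=0 (aligned), D=1 (reference bases skipped), I=2 (read
    bases inserted).  The first and last read bases must be aligned, so all
    gaps are internal; trailing/leading reference flanks are free.  Returns
    cost and opens; the split descriptor is not reconstructed on this path
    (multi-gap per-base placement is not needed by callers).
    """
    l = len(q)
    INF = 10**9
    M, D, I = 0, 1, 2
    cur = np.full((2 * k + 1, max_go + 1, 3), INF, dtype=np.int64)
    cur[k, 0, M] = 0 if (ext[ext_start] == q[0] and q[0] < N) else 1
    for i in range(1, l):
        # deletions between read[i-1] and read[i]: diagonal +1, ascending
        # order so runs cascade within the layer
        for d in range(-k, k):
            for o in range(max_go + 1):
                for op in (M, D, I):
                    c = cur[d + k, o, op]
                    if c >= INF:
                        continue
                    oo = o + (0 if op == D else 1)
                    if oo <= max_go and c + 1 < cur[d + 1 + k, oo, D]:
                        cur[d + 1 + k, oo, D] = c + 1
        nxt = np.full_like(cur, INF)
        for d in range(-k, k + 1):
            for o in range(max_go + 1):
                for op in (M, D, I):
                    c = cur[d + k, o, op]
                    if c >= INF:
                        continue
                    # align read[i] at diagonal d
                    pos = ext_start + d + i
                    ref = ext[pos] if pos >= 0 else SENTINEL
                    sub = 0 if (ref == q[i] and ref < N) else 1
                    if c + sub < nxt[d + k, o, M]:
                        nxt[d + k, o, M] = c + sub
                    # insert read[i] (needs an aligned base after it)
                    if i <= l - 2 and d - 1 >= -k:
                        oo = o + (0 if op == I else 1)
                        if oo <= max_go and c + 1 < nxt[d - 1 + k, oo, I]:
                            nxt[d - 1 + k, oo, I] = c + 1
        cur = nxt
    costs = cur[:, :, M]  # last read base must be aligned
    best = int(costs.min())
    if best > k:
        return None
    opens = int(np.argwhere(costs == best)[0][1])
    return best, opens, None


def align_read(
    read: Read,
    panel: list[IndexedGenome] | list[ReferenceGenome],
    params: AlignerParams = AlignerParams(),
) -> list[ReadAlignment]:
    """Align one read against a panel; returns the best stratum per genome.

    Placements with edit distance above ``maxdiff(len(read))`` are discarded.
    Mapping quality is global across the panel call: 0 when the best
    placement is tied (``co_optimal > 1``), 20 when a second-best placement
    exists at best+1, 37 otherwise.  Reads shorter than the seed length are
    recorded as unaligned (empty list), not an error.
    """
    indexed = [g if isinstance(g, IndexedGenome) else IndexedGenome(g) for g in panel]
    if not indexed:
        raise ParameterError("panel is empty")
    l = len(read)
    if l < params.seed_len:
        return []
    k = maxdiff(l, params.err, params.miss_thres)
    slen = min(params.seed_len, max(4, l // (k + 1)))

    fcodes = encode(read.bases)
    rcodes = revcomp_codes(fcodes)
    placements: list[tuple[int, str, int, int, int, tuple[int, int] | None, int]] = []
    for strand, q in (("+", fcodes), ("-", rcodes)):
        qb = q.tobytes()
        for gi, ig in enumerate(indexed):
            idx = ig.index(slen)
            cands: set[int] = set()
            for off in range(0, l - slen + 1):
                hits = idx.get(qb[off : off + slen])
                if hits:
                    for p in hits:
                        c = ig.canonical(p - off)
                        if c is not None:
                            cands.add(c)
            if k >= 1 and params.max_gap_opens >= 1:
                # a seed downstream of a gap reports a diagonal shifted by up
                # to the gap length; widen so the true first-base start is
                # always scored
                widened: set[int] = set()
                for c in cands:
                    for j in range(-k, k + 1):
                        cj = ig.canonical(c + j)
                        if cj is not None:
                            widened.add(cj)
                cands = widened
            for ext_start in cands:
                res = ig.score(q, ext_start, k, params.max_gap_opens, params.retain_slack)
                if res is not None:
                    cost, opens, split, nw = res
                    placements.append((gi, strand, ext_start, cost, opens, split, nw))
    if not placements:
        return []

    # Cluster placements into loci: same genome and strand, starts within k
    # of each other — gapped re-anchorings of one alignment must not count
    # as distinct near-optimal placements.  Each cluster is represented by
    # its cheapest member, preferring fewer gap openings on ties.
    reps: list[tuple[int, str, int, int, int, tuple[int, int] | None, int]] = []
    bykey: dict[tuple[int, str], list] = {}
    for p in placements:
        bykey.setdefault((p[0], p[1]), []).append(p)
    for (gi, strand), group in bykey.items():
        group.sort(key=lambda p: p[2])
        clusters: list[list] = [[group[0]]]
        for p in group[1:]:
            if p[2] - clusters[-1][-1][2] <= k:
                clusters[-1].append(p)
            else:
                clusters.append([p])
        if (
            indexed[gi].genome.circular
            and len(clusters) > 1
            and (clusters[0][0][2] + indexed[gi].L) - clusters[-1][-1][2] <= k
        ):
            clusters[0] = clusters.pop() + clusters[0]
        for cluster in clusters:
            reps.append(min(cluster, key=lambda p: (p[3], p[4], p[2])))

    # placements retained only through the slack never influence placement
    # confidence; they exist for iterative consumers to re-gate later.
    # Confidence ranks loci by informative (N-discounted) edit with the
    # strict edit as tie-break: an uncalled reference position is evidence
    # neither for nor against a placement's uniqueness.
    competitive = [p for p in reps if p[3] - p[6] <= k]
    if competitive:
        keys = [(p[3] - p[6], p[3]) for p in competitive]
        best_key = min(keys)
        co_optimal = keys.count(best_key)
        second = any(kk[0] == best_key[0] + 1 for kk in keys)
        mapq = 0 if co_optimal > 1 else (20 if second else 37)
    else:
        co_optimal = len(reps)
        mapq = 0

    out: list[ReadAlignment] = []
    for gi, ig in enumerate(indexed):
        mine = [p for p in reps if p[0] == gi]
        if not mine:
            continue
        gbest = min(p[3] for p in mine)
        for _, strand, ext_start, cost, opens, split, nw in mine:
            if cost != gbest:
                continue
            start = ext_start - ig.origin
            if ig.genome.circular:
                start %= ig.L
            out.append(
                ReadAlignment(
                    read_id=read.id,
                    genome_id=ig.genome.id,
                    start=start,
                    strand=strand,
                    edit_distance=cost,
                    n_gap_opens=opens,
                    mapq=mapq,
                    co_optimal=co_optimal,
                    bases=read.bases,
                    split=split,
                    n_ref_n=nw,
                )
            )
    return out


def align_pool(
    reads: list[Read],
    panel: list[ReferenceGenome],
    params: AlignerParams = AlignerParams(),
) -> dict[str, list[ReadAlignment]]:
    """Align a pool; returns read_id -> placements (empty lists omitted)."""
    indexed = [IndexedGenome(g) for g in panel]
    out: dict[str, list[ReadAlignment]] = {}
    for r in reads:
        hits = align_read(r, indexed, params)
        if hits:
            out[r.id] = hits
    return out
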