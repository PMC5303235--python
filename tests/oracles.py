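"""Independent reference implementations used as test oracles.

``exhaustive_banded_scan`` evaluates, for EVERY start offset on both
strands, a full banded dynamic program with a gap-opening cap, and returns
the best edit distance.  It shares the production aligner's alignment
model (first and last read base aligned, internal gaps only, band +-k,
uncalled/ambiguous reference positions count as mismatches) but none of
its machinery: no seeding, no candidate pruning, no single-gap shortcut.
"""

from __future__ import annotations

import numpy as np

BASES = {c: i for i, c in enumerate("ACGTN")}
SENTINEL = 5


def _encode(seq: str) -> np.ndarray:
    return np.array([BASES.get(c, 4) for c in seq], dtype=np.int64)


def _revcomp(seq: str) -> str:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    return "".join(comp[c] for c in reversed(seq))


def _scan_one_strand(q: np.ndarray, ext: np.ndarray, starts: np.ndarray, k: int, max_go: int) -> int:
    """Best cost over all anchored starts, full DP vectorised across starts."""
    INF = 10**6
    l = len(q)
    ns = len(starts)
    width = 2 * k + 1
    M, D, I = 0, 1, 2
    # cost[s, d+k, opens, last_op]
    cur = np.full((ns, width, max_go + 1, 3), INF, dtype=np.int64)
    ref0 = ext[starts]
    cur[:, k, 0, M] = np.where((ref0 == q[0]) & (q[0] < 4), 0, 1)
    for i in range(1, l):
        # deletions between read i-1 and read i: diagonal +1, cascading
        for d in range(-k, k):
            src = cur[:, d + k, :, :]
            opens_add = np.ones((max_go + 1, 3), dtype=np.int64)
            opens_add[:, D] = 0
            for o in range(max_go + 1):
                for op in (M, D, I):
                    oo = o + opens_add[o, op]
                    if oo > max_go:
                        continue
                    cand = src[:, o, op] + 1
                    tgt = cur[:, d + 1 + k, oo, D]
                    np.minimum(tgt, cand, out=tgt)
        nxt = np.full_like(cur, INF)
        for d in range(-k, k + 1):
            pos = starts + d + i
            ref = np.where((pos >= 0) & (pos < len(ext)), ext[np.clip(pos, 0, len(ext) - 1)], SENTINEL)
            sub = np.where((ref == q[i]) & (ref < 4), 0, 1)
            src = cur[:, d + k, :, :]
            base = src.min(axis=2)  # over last op
            for o in range(max_go + 1):
                np.minimum(nxt[:, d + k, o, M], base[:, o] + sub, out=nxt[:, d + k, o, M])
                if i <= l - 2 and d - 1 >= -k:
                    for op in (M, D, I):
                        oo = o + (0 if op == I else 1)
                        if oo > max_go:
                            continue
                        np.minimum(
                            nxt[:, d - 1 + k, oo, I], src[:, o, op] + 1,
                            out=nxt[:, d - 1 + k, oo, I],
                        )
        cur = nxt
    best = int(cur[:, :, :, M].min())
    return best


def exhaustive_banded_scan(read: str, genome_seq: str, circular: bool, k: int, max_go: int) -> int | None:
    """Best banded gap-capped edit distance over all offsets and strands.

    Returns None when no placement is within ``k``.
    """
    L = len(genome_seq)
    l = len(read)
    if circular:
        ext = _encode(genome_seq + genome_seq[: l + k])
    else:
        ext = np.concatenate([_encode(genome_seq), np.full(l + k, SENTINEL, dtype=np.int64)])
    starts = np.arange(L)
    best = 10**6
    for seq in (read, _revcomp(read)):
        q = _encode(seq)
        best = min(best, _scan_one_strand(q, ext, starts, k, max_go))
    return best if best <= k else None
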