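"""Low-level DNA sequence helpers shared across modules.

Sequences are handled both as upper-case Python strings over {A,C,G,T,N}
and as numpy uint8 code arrays (A=0, C=1, G=2, T=3, N=4).  Code 4 (N) is a
wildcard during alignment scoring: it never counts as a mismatch when it
appears in the reference.  Code 5 is an out-of-bounds sentinel used to pad
linear references; it mismatches everything.
"""

from __future__ import annotations

import numpy as np

A, C, G, T, N = 0, 1, 2, 3, 4
SENTINEL = 5

_CODE = np.full(256, N, dtype=np.uint8)
for _i, _b in enumerate("ACGTN"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

_BASES = np.frombuffer(b"ACGTN?", dtype=np.uint8)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# complement in code space: A<->T, C<->G, N->N, sentinel->sentinel
_CODE_COMP = np.array([T, G, C, A, N, SENTINEL], dtype=np.uint8)


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string into a uint8 code array."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    """Decode a uint8 code array back into a DNA string."""
    return _BASES[codes].tobytes().decode("ascii")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    """Reverse complement of a code array."""
    return _CODE_COMP[codes][::-1]


def validate_dna(seq: str, *, allow_n: bool = False, context: str = "sequence") -> str:
    """Upper-case ``seq`` and verify it only contains DNA letters.

    RNA (U) and gap characters are rejected outright.
    """
    s = seq.upper()
    alphabet = set("ACGTN" if allow_n else "ACGT")
    bad = set(s) - alphabet
    if bad:
        raise ValueError(f"{context} contains invalid characters: {sorted(bad)!r}")
    return s
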