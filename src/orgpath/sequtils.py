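"""Small DNA sequence helpers shared across modules."""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# byte-level base -> 2-bit code; anything non-ACGT (incl. N) maps to 4
_BASE_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_CODE[_b] = _i
for _i, _b in enumerate(b"acgt"):
    _BASE_CODE[_b] = _i

_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe, case-preserving)."""
    return seq.translate(_COMPLEMENT)[::-1]


def random_dna(rng: np.random.Generator, n: int) -> str:
    """Uniform random DNA of length n."""
    return _BASE_BYTES[rng.integers(0, 4, n, dtype=np.uint8)].tobytes().decode()


def encode_bases(seq: str) -> np.ndarray:
    """2-bit base codes (uint8); non-ACGT characters become 4."""
    return _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def canonical_kmer_codes(seq: str, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Canonical k-mer integer codes for every window of ``seq``.

    A canonical k-mer is the numeric minimum of a window's forward 2-bit
    code and the code of its reverse complement (equivalent to the
    lexicographic minimum of the two strings). Windows containing any
    non-ACGT character are dropped.

    Returns ``(codes, positions)`` where ``positions`` are the 0-based
    window start offsets of the surviving windows. Requires ``k <= 31``
    so codes fit in int64.
    """
    if not 1 <= k <= 31:
        raise ValueError(f"k must be in [1, 31], got {k}")
    a = encode_bases(seq)
    n = a.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    w = np.lib.stride_tricks.sliding_window_view(a, k).astype(np.int64)
    valid = (w < 4).all(axis=1)
    pw = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    fwd = w @ pw
    rev = (3 - w)[:, ::-1] @ pw
    canon = np.minimum(fwd, rev)
    pos = np.nonzero(valid)[0]
    return canon[valid], pos
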