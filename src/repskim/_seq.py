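"""Low-level nucleotide sequence helpers.

Sequences are numpy uint8 arrays with A=0, C=1, G=2, T=3 and N=4.  The
encoding is chosen so that the complement of a valid base b is simply 3-b.
"""
from __future__ import annotations

import numpy as np

_ALPHABET = np.frombuffer(b"ACGTN", dtype=np.uint8)
_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _c in enumerate(b"ACGT"):
    _ENCODE[_c] = _i
    _ENCODE[_c + 32] = _i  # lower case


def encode(seq: str | bytes) -> np.ndarray:
    """Encode a nucleotide string into a uint8 array (unknown chars -> N)."""
    if isinstance(seq, str):
        seq = seq.encode("ascii")
    return _ENCODE[np.frombuffer(seq, dtype=np.uint8)].copy()


def decode(arr: np.ndarray) -> str:
    return _ALPHABET[arr].tobytes().decode("ascii")


def revcomp(arr: np.ndarray) -> np.ndarray:
    """Reverse complement; N stays N."""
    out = np.where(arr < 4, 3 - arr, arr)
    return out[::-1].copy()


def revcomp_rows(mat: np.ndarray) -> np.ndarray:
    """Reverse complement every row of a 2-D read matrix."""
    out = np.where(mat < 4, 3 - mat, mat)
    return out[:, ::-1].copy()


def random_seq(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.integers(0, 4, size=n, dtype=np.uint8)


def mutate(arr: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Return a copy with independent per-base substitutions at ``rate``.

    A substituted base is always changed to one of the three other bases,
    so ``rate`` is the realized expected per-base difference from ``arr``.
    """
    out = arr.copy()
    if rate <= 0:
        return out
    hit = rng.random(arr.shape) < rate
    n_hit = int(hit.sum())
    if n_hit:
        shift = rng.integers(1, 4, size=n_hit, dtype=np.uint8)
        out[hit] = (out[hit] + shift) % 4
    return out


def hamming_identity(a: np.ndarray, b: np.ndarray) -> float:
    """Fraction of matching positions between two equal-length sequences."""
    if a.shape != b.shape:
        raise ValueError("sequences must have equal length")
    return float(np.mean((a == b) & (a < 4)))
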