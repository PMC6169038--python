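"""Low-level DNA sequence utilities shared by all modules.

Sequences are plain Python strings over the alphabet {A, C, G, T, N}.
``N`` is the hard-mask/ambiguity character: it never matches anything in an
alignment, including another ``N``. For numeric work, sequences are encoded
as ``int8`` arrays with A=0, C=1, G=2, T=3, N=4.
"""

from __future__ import annotations

import numpy as np

ALPHABET = "ACGTN"
A, C, G, T, N = range(5)

_ENCODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(ALPHABET):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i

_DECODE = np.frombuffer(ALPHABET.encode(), dtype=np.uint8)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as an int8 array (A=0, C=1, G=2, T=3, N=4).

    Raises ``ValueError`` on empty input or characters outside {A,C,G,T,N}
    (case-insensitive).
    """
    if not seq:
        raise ValueError("empty sequence")
    raw = np.frombuffer(seq.encode("ascii", errors="strict"), dtype=np.uint8)
    codes = _ENCODE[raw]
    if (codes < 0).any():
        bad = sorted({seq[i] for i in np.nonzero(codes < 0)[0][:5]})
        raise ValueError(f"invalid DNA characters: {bad!r}")
    return codes


def decode(codes: np.ndarray) -> str:
    """Inverse of :func:`encode`."""
    return _DECODE[codes].tobytes().decode("ascii")


def revcomp(seq: str) -> str:
    """Reverse complement (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def random_dna(length: int, rng: np.random.Generator) -> str:
    """A uniform random A/C/G/T string of the given length."""
    if length <= 0:
        raise ValueError("length must be positive")
    return decode(rng.integers(0, 4, size=length).astype(np.int8))


def mutate(seq: str, rate: float, rng: np.random.Generator) -> tuple[str, int]:
    """Apply i.i.d. per-site substitutions at the given rate.

    Each selected site is replaced by one of the 3 alternative bases chosen
    uniformly (a Jukes–Cantor-like process), so a mutated site never retains
    its original base. ``N`` positions are left untouched. Returns the mutated
    sequence and the realized number of substituted sites.
    """
    if not 0.0 <= rate < 0.5:
        raise ValueError(f"substitution rate must be in [0, 0.5), got {rate}")
    codes = encode(seq)
    hit = (rng.random(codes.shape[0]) < rate) & (codes < 4)
    n_sub = int(hit.sum())
    if n_sub:
        shift = rng.integers(1, 4, size=n_sub).astype(np.int8)
        codes[hit] = (codes[hit] + shift) % 4
    return decode(codes), n_sub
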