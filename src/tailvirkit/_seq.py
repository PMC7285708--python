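"""Small DNA-string helpers shared across modules."""

from __future__ import annotations

import numpy as np

DNA_ALPHABET = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def random_dna(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")


def mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Apply i.i.d. per-site substitutions, uniform over the 3 other bases.

    N positions are left untouched. No indels: identity between the input and
    output stays analytically controllable (~1 - rate * 3/4 * 4/3 = 1 - rate
    per site relative to the input).
    """
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hit = rng.random(arr.size) < rate
    hit &= arr != ord("N")
    idx = np.flatnonzero(hit)
    if idx.size:
        # shift each hit base by 1..3 within ACGT (uniform over alternatives)
        base_idx = np.searchsorted(_BASES, arr[idx])
        shift = rng.integers(1, 4, size=idx.size)
        arr[idx] = _BASES[(base_idx + shift) % 4]
    return arr.tobytes().decode("ascii")


def identity_fraction(a: str, b: str) -> float:
    """Fraction of positions with equal non-N bases (equal-length strings)."""
    if len(a) != len(b):
        raise ValueError("sequences must have equal length")
    xa = np.frombuffer(a.encode(), dtype=np.uint8)
    xb = np.frombuffer(b.encode(), dtype=np.uint8)
    ok = (xa == xb) & (xa != ord("N"))
    return float(ok.sum()) / len(a)


def pairwise_mutation_rate(target_pairwise_identity: float) -> float:
    """Per-copy substitution rate so two independent mutants of one ancestor
    show the requested pairwise identity.

    With per-site rate s in each copy, a site matches between the two copies
    with probability (1-s)^2 + s^2/3 (both untouched, or both mutated to the
    same alternative). Solve for s by the quadratic.
    """
    # (4/3) s^2 - 2 s + (1 - t) = 0
    t = target_pairwise_identity
    disc = 4.0 - 4.0 * (4.0 / 3.0) * (1.0 - t)
    s = (2.0 - disc ** 0.5) / (8.0 / 3.0)
    return s
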