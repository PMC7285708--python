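"""Seeded pairwise nucleotide alignment for ANI / alignment-fraction estimates.

The aligner finds exact k-mer anchors (k = 15 by default), groups them by
diagonal, extends each anchor cluster gaplessly in both directions with an
x-drop criterion, merges overlapping segments, and greedily selects a
non-overlapping segment set. ANI is identities over aligned columns across the
merged segments; the alignment fraction uses the shorter sequence of the pair
as denominator ("fraction of the smallest"). Both orientations are tried and
the better-scoring one kept, since assembly strand is arbitrary. N bases never
count as matches.

Sequences shorter than k fall back to full dynamic programming — inputs there
are tiny, so the O(nm) cost is irrelevant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._seq import revcomp

MATCH = 1
MISMATCH = -2
XDROP = 20
CLUSTER_GAP = 200       # nt between anchors on one diagonal before splitting
MAX_KMER_OCC = 20       # repeat masking: ignore k-mers this frequent in the subject


@dataclass(frozen=True)
class PairwiseAlignmentStat:
    """Symmetric summary of one sequence pair's merged local alignments."""
    id_a: str
    id_b: str
    ani: float          # identities / aligned columns, 0 if nothing aligns
    af_small: float     # aligned columns / length of the shorter sequence
    aligned_len: int
    score: float        # raw +1/-2 score over merged segments
    orientation: str    # "+" or "-"


def _to_bytes(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def kmer_set(seq: str, k: int = 15) -> frozenset:
    """Distinct k-mers without N, used by the cheap candidate-pair prefilter."""
    return frozenset(seq[i:i + k] for i in range(len(seq) - k + 1)
                     if "N" not in seq[i:i + k])


def _segment_counts(a: np.ndarray, b: np.ndarray, d: int,
                    j0: int, j1: int) -> tuple[int, int]:
    """(identities, columns) for the gapless span b[j0:j1] vs a[j0+d:j1+d]."""
    sa = a[j0 + d:j1 + d]
    sb = b[j0:j1]
    eq = (sa == sb) & (sa != ord("N")) & (sb != ord("N"))
    return int(eq.sum()), j1 - j0


def _xdrop_extend(a: np.ndarray, b: np.ndarray, d: int, j0: int, j1: int
                  ) -> tuple[int, int]:
    """Extend [j0, j1) on diagonal d both ways; return best-scoring endpoints."""
    n, m = len(a), len(b)
    # right
    best, run, bj = 0.0, 0.0, j1
    j = j1
    while j < m and j + d < n:
        hit = a[j + d] == b[j] and a[j + d] != ord("N") and b[j] != ord("N")
        run += MATCH if hit else MISMATCH
        if run > best:
            best, bj = run, j + 1
        elif best - run > XDROP:
            break
        j += 1
    j1 = bj
    # left
    best, run, bj = 0.0, 0.0, j0
    j = j0 - 1
    while j >= 0 and j + d >= 0:
        hit = a[j + d] == b[j] and a[j + d] != ord("N") and b[j] != ord("N")
        run += MATCH if hit else MISMATCH
        if run > best:
            best, bj = run, j
        elif best - run > XDROP:
            break
        j -= 1
    return bj, j1


def _merge_intervals(iv: list[tuple[int, int]]) -> list[tuple[int, int]]:
    iv = sorted(iv)
    out = [list(iv[0])]
    for lo, hi in iv[1:]:
        if lo <= out[-1][1]:
            out[-1][1] = max(out[-1][1], hi)
        else:
            out.append([lo, hi])
    return [tuple(x) for x in out]


def _align_oriented(seq_a: str, seq_b: str, k: int) -> tuple[int, int, float]:
    """(identities, aligned_columns, score) for one orientation of b."""
    if min(len(seq_a), len(seq_b)) < k:
        return _dp_align(seq_a, seq_b)
    a, b = _to_bytes(seq_a), _to_bytes(seq_b)
    index: dict[str, list[int]] = {}
    for i in range(len(seq_a) - k + 1):
        km = seq_a[i:i + k]
        if "N" not in km:
            index.setdefault(km, []).append(i)
    diags: dict[int, list[int]] = {}
    for j in range(len(seq_b) - k + 1):
        pos = index.get(seq_b[j:j + k])
        if pos is None or len(pos) > MAX_KMER_OCC:
            continue
        for i in pos:
            diags.setdefault(i - j, []).append(j)

    segments = []  # (score, d, j0, j1, ident, cols)
    for d, js in diags.items():
        js.sort()
        clusters, start, prev = [], js[0], js[0]
        for j in js[1:]:
            if j - prev > CLUSTER_GAP:
                clusters.append((start, prev))
                start = j
            prev = j
        clusters.append((start, prev))
        spans = [_xdrop_extend(a, b, d, j0, j1 + k) for j0, j1 in clusters]
        for j0, j1 in _merge_intervals(spans):
            if j1 <= j0:
                continue
            ident, cols = _segment_counts(a, b, d, j0, j1)
            score = MATCH * ident + MISMATCH * (cols - ident)
            if score > 0:
                segments.append((score, d, j0, j1, ident, cols))

    # greedy non-overlapping selection across diagonals (overlap in either seq)
    segments.sort(key=lambda s: (-s[0], s[1], s[2]))
    used_b: list[tuple[int, int]] = []
    used_a: list[tuple[int, int]] = []
    tot_ident = tot_cols = 0
    tot_score = 0.0
    for score, d, j0, j1, ident, cols in segments:
        a0, a1 = j0 + d, j1 + d
        if any(j0 < hi and lo < j1 for lo, hi in used_b):
            continue
        if any(a0 < hi and lo < a1 for lo, hi in used_a):
            continue
        used_b.append((j0, j1))
        used_a.append((a0, a1))
        tot_ident += ident
        tot_cols += cols
        tot_score += score
    return tot_ident, tot_cols, tot_score


def _dp_align(seq_a: str, seq_b: str, gap: int = -3) -> tuple[int, int, float]:
    """Tiny-input global alignment fallback (plain Needleman-Wunsch)."""
    n, m = len(seq_a), len(seq_b)
    score = np.zeros((n + 1, m + 1))
    ptr = np.zeros((n + 1, m + 1), dtype=np.int8)  # 0 diag, 1 up, 2 left
    score[:, 0] = np.arange(n + 1) * gap
    score[0, :] = np.arange(m + 1) * gap
    ptr[1:, 0], ptr[0, 1:] = 1, 2
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            hit = seq_a[i - 1] == seq_b[j - 1] and seq_a[i - 1] != "N"
            cand = (score[i - 1, j - 1] + (MATCH if hit else MISMATCH),
                    score[i - 1, j] + gap, score[i, j - 1] + gap)
            best = int(np.argmax(cand))
            score[i, j] = cand[best]
            ptr[i, j] = best
    ident = cols = 0
    i, j = n, m
    while i > 0 or j > 0:
        p = ptr[i, j]
        if p == 0:
            cols += 1
            if seq_a[i - 1] == seq_b[j - 1] and seq_a[i - 1] != "N":
                ident += 1
            i, j = i - 1, j - 1
        elif p == 1:
            i -= 1
        else:
            j -= 1
    return ident, cols, float(MATCH * ident + MISMATCH * (cols - ident))


def pairwise_ani(a, b, k: int = 15) -> PairwiseAlignmentStat:
    """ANI and alignment fraction between two scaffolds (objects with .id/.seq).

    Both orientations of ``b`` are aligned and the higher-scoring one kept.
    """
    fwd = _align_oriented(a.seq, b.seq, k)
    rev = _align_oriented(a.seq, revcomp(b.seq), k)
    (ident, cols, score), orient = max(
        ((fwd, "+"), (rev, "-")), key=lambda t: (t[0][2], t[1] == "+"))
    small = min(len(a.seq), len(b.seq))
    return PairwiseAlignmentStat(
        id_a=a.id, id_b=b.id,
        ani=ident / cols if cols else 0.0,
        af_small=min(cols / small, 1.0) if small else 0.0,
        aligned_len=cols, score=score, orientation=orient)
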