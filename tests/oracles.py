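"""Independent brute-force oracles used only by the tests.

These deliberately re-derive results through a different route than the
package: full-matrix textbook dynamic programming, set arithmetic on
k-mers, a literal transcription of the greedy chaining rule, and an
exhaustive scan for ungapped extensions. They must stay independent of
the implementation they check.
"""

from __future__ import annotations

from typing import Dict, List, Sequence, Set, Tuple

import numpy as np

NEG = -(10 ** 9)


# ---------------------------------------------------------------------------
# Full-matrix affine-gap DP (Gotoh), global and local
# ---------------------------------------------------------------------------

def gotoh_global_score(q: str, t: str, scorer) -> int:
    """Textbook full-matrix global alignment score with affine gaps.

    A gap of length L costs gap_open + L * gap_extend.
    """
    m, n = len(q), len(t)
    go, ge = scorer.gap_open, scorer.gap_extend
    H = np.full((m + 1, n + 1), NEG, dtype=np.int64)
    E = np.full((m + 1, n + 1), NEG, dtype=np.int64)
    F = np.full((m + 1, n + 1), NEG, dtype=np.int64)
    H[0, 0] = 0
    for j in range(1, n + 1):
        E[0, j] = -(go + j * ge)
        H[0, j] = E[0, j]
    for i in range(1, m + 1):
        F[i, 0] = -(go + i * ge)
        H[i, 0] = F[i, 0]
        for j in range(1, n + 1):
            E[i, j] = max(H[i, j - 1] - go - ge, E[i, j - 1] - ge)
            F[i, j] = max(H[i - 1, j] - go - ge, F[i - 1, j] - ge)
            H[i, j] = max(
                H[i - 1, j - 1] + scorer.score(q[i - 1], t[j - 1]),
                E[i, j], F[i, j],
            )
    return int(H[m, n])


def gotoh_local_identity(q: str, t: str, scorer) -> Tuple[int, int, int]:
    """Best local affine-gap alignment: (score, matching, columns).

    Traceback walks from the best cell back to the first zero cell,
    counting match columns and total columns (gaps included).
    """
    m, n = len(q), len(t)
    go, ge = scorer.gap_open, scorer.gap_extend
    H = np.zeros((m + 1, n + 1), dtype=np.int64)
    E = np.full((m + 1, n + 1), NEG, dtype=np.int64)
    F = np.full((m + 1, n + 1), NEG, dtype=np.int64)
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            E[i, j] = max(H[i, j - 1] - go - ge, E[i, j - 1] - ge)
            F[i, j] = max(H[i - 1, j] - go - ge, F[i - 1, j] - ge)
            H[i, j] = max(
                0,
                H[i - 1, j - 1] + scorer.score(q[i - 1], t[j - 1]),
                E[i, j], F[i, j],
            )
    best = int(H.max())
    if best == 0:
        return 0, 0, 0
    i, j = np.unravel_index(int(H.argmax()), H.shape)
    i, j = int(i), int(j)
    matching = 0
    columns = 0
    state = "H"
    while H[i, j] != 0 or state != "H":
        if state == "H":
            if H[i, j] == H[i - 1, j - 1] + scorer.score(q[i - 1], t[j - 1]):
                columns += 1
                if q[i - 1] == t[j - 1]:
                    matching += 1
                i -= 1
                j -= 1
            elif H[i, j] == E[i, j]:
                state = "E"
            else:
                state = "F"
        elif state == "E":
            columns += 1
            if E[i, j] == H[i, j - 1] - go - ge:
                state = "H"
            j -= 1
        else:
            columns += 1
            if F[i, j] == H[i - 1, j] - go - ge:
                state = "H"
            i -= 1
    return best, matching, columns


# ---------------------------------------------------------------------------
# K-mer set arithmetic
# ---------------------------------------------------------------------------

def kmer_set(residues: str, k: int, ambiguous: Set[str]) -> Set[str]:
    """All distinct ambiguity-free k-length windows, as strings."""
    out: Set[str] = set()
    for i in range(len(residues) - k + 1):
        window = residues[i:i + k]
        if not any(ch in ambiguous for ch in window):
            out.add(window)
    return out


def shared_kmer_counts(
    query: str, targets: Sequence[str], k: int, ambiguous: Set[str]
) -> Dict[int, int]:
    """Brute-force U per target id, zero-count targets omitted."""
    qset = kmer_set(query, k, ambiguous)
    out: Dict[int, int] = {}
    for tid, target in enumerate(targets):
        u = len(qset & kmer_set(target, k, ambiguous))
        if u:
            out[tid] = u
    return out


# ---------------------------------------------------------------------------
# Greedy chaining, transcribed literally
# ---------------------------------------------------------------------------

def greedy_chain(hsps: Sequence) -> List:
    """Literal greedy rule: take the highest-scoring HSP, then repeatedly
    the highest-scoring remaining HSP that is collinear with and
    non-overlapping with every selected HSP, until none can join."""

    def before(a, b):
        return a.query_end <= b.query_start and a.target_end <= b.target_start

    def ok(h, chosen):
        return all(before(h, s) or before(s, h) for s in chosen)

    remaining = list(hsps)
    chosen: List = []
    while True:
        candidates = [h for h in remaining if ok(h, chosen)]
        if not candidates:
            break
        best = min(
            candidates,
            key=lambda h: (-h.score, h.query_start, h.target_start),
        )
        chosen.append(best)
        remaining.remove(best)
    return sorted(chosen, key=lambda h: h.query_start)


# ---------------------------------------------------------------------------
# X-drop ungapped extension endpoints
# ---------------------------------------------------------------------------

def xdrop_endpoint(gains: Sequence[int], xdrop: int) -> Tuple[int, int]:
    """(best gain, best length) for one extension direction.

    Vectorised reformulation: cumulative gains, running peak, first index
    where the drop below the peak exceeds xdrop, then the earliest argmax
    of the surviving prefix (only strictly positive gains extend).
    """
    if not len(gains):
        return 0, 0
    cum = np.cumsum(np.asarray(gains, dtype=np.int64))
    peak = np.maximum.accumulate(np.maximum(cum, 0))
    broken = np.nonzero(peak - cum > xdrop)[0]
    if len(broken):
        cum = cum[: broken[0] + 1]
    best = int(cum.max())
    if best <= 0:
        return 0, 0
    return best, int(cum.argmax()) + 1
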