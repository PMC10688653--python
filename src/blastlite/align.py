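"""Pairwise alignment: seed-and-extend HSPs, greedy chaining, banded DP.

The pipeline mirrors the classic heuristic local-aligner design:

1. ``find_seeds`` locates every exact k-mer match between query and target
   and merges diagonal-adjacent matches into maximal seeds.
2. ``extend_seed`` grows each seed without gaps in both directions under an
   X-drop rule, producing an HSP (high-scoring segment pair) trimmed to its
   best-scoring endpoints.
3. ``chain_hsps`` selects a collinear, non-overlapping subset greedily:
   highest-scoring HSP first, then repeatedly the best remaining HSP that
   is compatible with everything already chosen.
4. ``banded_align`` closes the gaps between consecutive chained HSPs with
   global affine-gap dynamic programming restricted to a diagonal band.

``align_pair`` runs the whole pipeline and reports identity as matching
columns over all alignment columns (gap columns included); terminal
overhangs outside the chained region are excluded.

CIGAR operations are run-length lists over M (alignment column, match or
mismatch), I (query-only) and D (target-only).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence as TSequence, Tuple

from .alphabet import Alphabet, PairScorer, Sequence
from .index import enumerate_kmers

CigarOps = List[Tuple[str, int]]

_NEG = -(1 << 30)


# ---------------------------------------------------------------------------
# CIGAR helpers
# ---------------------------------------------------------------------------

def merge_ops(ops: TSequence[Tuple[str, int]]) -> CigarOps:
    """Coalesce adjacent runs of the same operation; drop zero-length runs."""
    out: CigarOps = []
    for op, length in ops:
        if length == 0:
            continue
        if out and out[-1][0] == op:
            out[-1] = (op, out[-1][1] + length)
        else:
            out.append((op, length))
    return out


def cigar_string(ops: TSequence[Tuple[str, int]]) -> str:
    return "".join(f"{length}{op}" for op, length in ops)


def evaluate_cigar(
    ops: TSequence[Tuple[str, int]],
    query: str,
    target: str,
    query_start: int,
    target_start: int,
    scorer: PairScorer,
) -> Tuple[int, int, int, int, int]:
    """Re-evaluate a cigar against the sequences.

    Returns (score, matching_columns, mismatches, gap_openings, columns).
    Each I or D run is one gap opening costing open + length * extend.
    """
    qi, ti = query_start, target_start
    score = 0
    matching = 0
    mismatches = 0
    gap_openings = 0
    columns = 0
    for op, length in ops:
        columns += length
        if op == "M":
            for _ in range(length):
                a, b = query[qi], target[ti]
                score += scorer.score(a, b)
                if a == b:
                    matching += 1
                else:
                    mismatches += 1
                qi += 1
                ti += 1
        elif op == "I":
            gap_openings += 1
            score -= scorer.gap_open + length * scorer.gap_extend
            qi += length
        elif op == "D":
            gap_openings += 1
            score -= scorer.gap_open + length * scorer.gap_extend
            ti += length
        else:
            raise ValueError(f"unknown cigar op {op!r}")
    return score, matching, mismatches, gap_openings, columns


def expanded_cigar(ops: TSequence[Tuple[str, int]], query: str, target: str,
                   query_start: int, target_start: int) -> str:
    """Extended =/X form: M columns split into = (match) and X (mismatch)."""
    qi, ti = query_start, target_start
    runs: List[Tuple[str, int]] = []
    for op, length in ops:
        if op == "M":
            for _ in range(length):
                sym = "=" if query[qi] == target[ti] else "X"
                runs.append((sym, 1))
                qi += 1
                ti += 1
        else:
            runs.append((op, length))
            if op == "I":
                qi += length
            else:
                ti += length
    return cigar_string(merge_ops(runs))


# ---------------------------------------------------------------------------
# Seeds and HSPs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Seed:
    """A maximal run of exact k-mer matches on one diagonal."""

    query_pos: int
    target_pos: int
    length: int

    @property
    def diagonal(self) -> int:
        return self.target_pos - self.query_pos


@dataclass(frozen=True)
class Hsp:
    """An ungapped high-scoring segment pair (0-based half-open intervals)."""

    query_start: int
    query_end: int
    target_start: int
    target_end: int
    score: int

    @property
    def ops(self) -> CigarOps:
        return [("M", self.query_end - self.query_start)]


def find_seeds(query: Sequence, target: Sequence, k: Optional[int] = None) -> List[Seed]:
    """Every exact, ambiguity-free k-length match, merged along diagonals.

    Overlapping or touching window matches on one diagonal merge into a
    single maximal seed; no match is lost by merging. Order: by diagonal
    (target_pos - query_pos), then query position.
    """
    if k is None:
        k = query.alphabet.default_k
    target_map: Dict[int, List[int]] = {}
    for pos, code in enumerate_kmers(target, k):
        target_map.setdefault(code, []).append(pos)
    matches: List[Tuple[int, int]] = []  # (diagonal, query_pos)
    for qpos, code in enumerate_kmers(query, k):
        for tpos in target_map.get(code, ()):
            matches.append((tpos - qpos, qpos))
    matches.sort()
    seeds: List[Seed] = []
    cur_diag = None
    cur_start = cur_end = 0
    for diag, qpos in matches:
        if diag == cur_diag and qpos <= cur_end:
            cur_end = max(cur_end, qpos + k)
        else:
            if cur_diag is not None:
                seeds.append(Seed(cur_start, cur_start + cur_diag, cur_end - cur_start))
            cur_diag = diag
            cur_start = qpos
            cur_end = qpos + k
    if cur_diag is not None:
        seeds.append(Seed(cur_start, cur_start + cur_diag, cur_end - cur_start))
    return seeds


def extend_seed(
    seed: Seed, query: Sequence, target: Sequence,
    scorer: PairScorer, xdrop: int,
) -> Hsp:
    """Ungapped X-drop extension of a seed in both directions.

    Extension on a side stops once the running score falls more than
    ``xdrop`` below the best score seen on that side; the HSP is trimmed
    back to the best-scoring endpoints. The seed window itself is never
    trimmed, so the HSP scores at least the bare seed window.
    """
    q, t = query.residues, target.residues
    sc = scorer.score
    qs, ts, length = seed.query_pos, seed.target_pos, seed.length
    base = sum(sc(q[qs + i], t[ts + i]) for i in range(length))

    def _extend(qi: int, ti: int, step: int, qlim: int, tlim: int) -> Tuple[int, int]:
        best_gain = 0
        best_len = 0
        run = 0
        off = 0
        while qi != qlim and ti != tlim:
            run += sc(q[qi], t[ti])
            off += 1
            if run > best_gain:
                best_gain, best_len = run, off
            elif best_gain - run > xdrop:
                break
            qi += step
            ti += step
        return best_gain, best_len

    right_gain, right_len = _extend(qs + length, ts + length, 1, len(q), len(t))
    left_gain, left_len = _extend(qs - 1, ts - 1, -1, -1, -1)
    return Hsp(
        query_start=qs - left_len,
        query_end=qs + length + right_len,
        target_start=ts - left_len,
        target_end=ts + length + right_len,
        score=base + left_gain + right_gain,
    )


def _compatible(a: Hsp, b: Hsp) -> bool:
    """Collinear and non-overlapping in both query and target coordinates."""
    return (
        (a.query_end <= b.query_start and a.target_end <= b.target_start)
        or (b.query_end <= a.query_start and b.target_end <= a.target_start)
    )


def chain_hsps(hsps: TSequence[Hsp]) -> List[Hsp]:
    """Greedy chain: best HSP first, then best compatible remainder.

    Ties break by higher score, then smaller query start, then smaller
    target start. This is the literal greedy rule, not optimal chaining.
    The result is sorted by query coordinate.
    """
    order = sorted(hsps, key=lambda h: (-h.score, h.query_start, h.target_start))
    selected: List[Hsp] = []
    for h in order:
        if all(_compatible(h, s) for s in selected):
            selected.append(h)
    return sorted(selected, key=lambda h: h.query_start)


# ---------------------------------------------------------------------------
# Banded global alignment (Gotoh affine gaps)
# ---------------------------------------------------------------------------

def banded_align(
    query_segment: str, target_segment: str,
    scorer: PairScorer, band_radius: int = 16,
) -> Tuple[CigarOps, int]:
    """Global affine-gap alignment restricted to a diagonal band.

    The band spans ``band_radius`` diagonals either side of the corridor
    between the (0,0) diagonal and its shift by the length difference, so
    a full path always exists even for segments of very different length.
    A gap of length L costs open + L * extend. Equals unrestricted global
    alignment whenever the optimal path stays inside the band.
    """
    q = query_segment.residues if isinstance(query_segment, Sequence) else query_segment
    t = target_segment.residues if isinstance(target_segment, Sequence) else target_segment
    m, n = len(q), len(t)
    if m == 0 and n == 0:
        return [], 0
    go, ge = scorer.gap_open, scorer.gap_extend
    gof = go + ge  # first residue of a gap
    lo_off = min(0, n - m) - band_radius
    hi_off = max(0, n - m) + band_radius
    sc = scorer.score

    H = [[_NEG] * (n + 1) for _ in range(m + 1)]
    E = [[_NEG] * (n + 1) for _ in range(m + 1)]  # gap in query (D, consumes target)
    F = [[_NEG] * (n + 1) for _ in range(m + 1)]  # gap in target (I, consumes query)
    H[0][0] = 0
    for j in range(1, min(n, hi_off) + 1):
        E[0][j] = -(go + j * ge)
        H[0][j] = E[0][j]
    for i in range(1, m + 1):
        jlo = max(0, i + lo_off)
        jhi = min(n, i + hi_off)
        if jlo == 0:
            F[i][0] = max(H[i - 1][0] - gof, F[i - 1][0] - ge)
            H[i][0] = F[i][0]
        row_h, row_e, row_f = H[i], E[i], F[i]
        prev_h, prev_f = H[i - 1], F[i - 1]
        qc = q[i - 1]
        for j in range(max(1, jlo), jhi + 1):
            e = max(row_h[j - 1] - gof, row_e[j - 1] - ge)
            f = max(prev_h[j] - gof, prev_f[j] - ge)
            d = prev_h[j - 1] + sc(qc, t[j - 1])
            row_e[j] = e
            row_f[j] = f
            row_h[j] = d if d >= e and d >= f else (e if e >= f else f)

    if H[m][n] <= _NEG // 2:
        raise RuntimeError("banded alignment found no in-band path")

    # Traceback (preference M > D > I, closing gaps eagerly: deterministic).
    ops_rev: List[Tuple[str, int]] = []
    i, j = m, n
    state = "H"
    while i > 0 or j > 0:
        if state == "H":
            if i > 0 and j > 0 and H[i][j] == H[i - 1][j - 1] + sc(q[i - 1], t[j - 1]):
                ops_rev.append(("M", 1))
                i -= 1
                j -= 1
            elif j > 0 and H[i][j] == E[i][j]:
                state = "E"
            else:
                state = "F"
        elif state == "E":
            ops_rev.append(("D", 1))
            closes = H[i][j - 1] - gof >= E[i][j - 1] - ge or j == 1
            j -= 1
            if closes:
                state = "H"
        else:  # F
            ops_rev.append(("I", 1))
            closes = H[i - 1][j] - gof >= F[i - 1][j] - ge or i == 1
            i -= 1
            if closes:
                state = "H"
    return merge_ops(reversed(ops_rev)), H[m][n]


# ---------------------------------------------------------------------------
# Full pipeline for one pair
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AlignmentChain:
    """Chained, gap-closed alignment of one query-target pair.

    Intervals are 0-based half-open on the sequences as aligned; the cigar
    consumes exactly query[query_start:query_end] and
    target[target_start:target_end].
    """

    query_start: int
    query_end: int
    target_start: int
    target_end: int
    ops: Tuple[Tuple[str, int], ...]
    score: int
    matching_columns: int
    alignment_length: int
    mismatches: int
    gap_openings: int

    @property
    def identity(self) -> float:
        return self.matching_columns / self.alignment_length

    @property
    def cigar(self) -> str:
        return cigar_string(self.ops)


def identity_of(chain: AlignmentChain) -> float:
    """Matching columns over all alignment columns (gaps included)."""
    return chain.identity


def align_pair(
    query: Sequence, target: Sequence,
    k: Optional[int] = None,
    scorer: Optional[PairScorer] = None,
    xdrop: Optional[int] = None,
    band_radius: int = 16,
) -> Optional[AlignmentChain]:
    """Seed, extend, chain and bridge one query-target pair.

    Returns ``None`` when the pair shares no ambiguity-free k-mer (no
    seeds). Identity covers the chained region only: terminal overhangs
    beyond the outermost HSPs are excluded from the alignment.
    """
    alphabet: Alphabet = query.alphabet
    if k is None:
        k = alphabet.default_k
    if scorer is None:
        scorer = alphabet.scorer
    if xdrop is None:
        xdrop = alphabet.default_xdrop

    seeds = find_seeds(query, target, k)
    if not seeds:
        return None
    hsps: List[Hsp] = []
    seen = set()
    for seed in seeds:
        hsp = extend_seed(seed, query, target, scorer, xdrop)
        key = (hsp.query_start, hsp.query_end, hsp.target_start, hsp.target_end)
        if key not in seen:
            seen.add(key)
            hsps.append(hsp)
    chain = chain_hsps(hsps)

    q, t = query.residues, target.residues
    ops: List[Tuple[str, int]] = []
    prev: Optional[Hsp] = None
    for hsp in chain:
        if prev is not None:
            qseg = q[prev.query_end:hsp.query_start]
            tseg = t[prev.target_end:hsp.target_start]
            bridge_ops, _ = banded_align(qseg, tseg, scorer, band_radius)
            ops.extend(bridge_ops)
        ops.extend(hsp.ops)
        prev = hsp
    ops = merge_ops(ops)

    qstart, tstart = chain[0].query_start, chain[0].target_start
    score, matching, mismatches, gap_openings, columns = evaluate_cigar(
        ops, q, t, qstart, tstart, scorer
    )
    return AlignmentChain(
        query_start=qstart,
        query_end=chain[-1].query_end,
        target_start=tstart,
        target_end=chain[-1].target_end,
        ops=tuple(ops),
        score=score,
        matching_columns=matching,
        alignment_length=columns,
        mismatches=mismatches,
        gap_openings=gap_openings,
    )
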