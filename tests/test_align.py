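"""Seed finding, X-drop extension, chaining and banded DP."""

import numpy as np
import pytest

from blastlite import (
    DNA,
    PROTEIN,
    Sequence,
    align_pair,
    banded_align,
    chain_hsps,
    extend_seed,
    find_seeds,
    identity_of,
)
from blastlite.align import Hsp, Seed, cigar_string, evaluate_cigar, expanded_cigar
from .conftest import mutate, random_dna, random_protein
from .oracles import (
    gotoh_global_score,
    gotoh_local_identity,
    greedy_chain,
    xdrop_endpoint,
)


# ---------------------------------------------------------------------------
# find_seeds
# ---------------------------------------------------------------------------

def test_find_seeds_identical_sequences_single_maximal_seed(rng):
    res = random_dna(rng, 50)
    q = Sequence("q", res)
    seeds = find_seeds(q, q, k=8)
    full = [s for s in seeds if s.length == 50 and s.diagonal == 0]
    assert len(full) == 1


def test_find_seeds_disjoint_sequences():
    q = Sequence("q", "A" * 30)
    t = Sequence("t", "C" * 30)
    assert find_seeds(q, t, k=8) == []


def test_find_seeds_implanted_shared_word(rng):
    """An implanted 12-mer produces a seed covering it on one diagonal."""
    shared = random_dna(rng, 12)
    q = Sequence("q", random_dna(rng, 20) + shared + random_dna(rng, 20))
    t = Sequence("t", random_dna(rng, 35) + shared + random_dna(rng, 5))
    seeds = find_seeds(q, t, k=8)
    # brute-force: every exact window match must be covered by some seed
    for i in range(len(q.residues) - 7):
        for j in range(len(t.residues) - 7):
            if q.residues[i:i + 8] == t.residues[j:j + 8]:
                assert any(
                    s.query_pos <= i and i + 8 <= s.query_pos + s.length
                    and s.diagonal == j - i
                    for s in seeds
                )
    assert any(
        s.diagonal == 35 - 20
        and s.query_pos <= 20 and 32 <= s.query_pos + s.length
        for s in seeds
    )


def test_find_seeds_order_by_diagonal_then_position(rng):
    q = Sequence("q", random_dna(rng, 120))
    t = Sequence("t", mutate(rng, q.residues, 10))
    seeds = find_seeds(q, t, k=8)
    keys = [(s.diagonal, s.query_pos) for s in seeds]
    assert keys == sorted(keys)


def test_find_seeds_windows_match_exactly(rng):
    q = Sequence("q", random_dna(rng, 80))
    t = Sequence("t", mutate(rng, q.residues, 6))
    for s in find_seeds(q, t, k=8):
        assert (
            q.residues[s.query_pos:s.query_pos + s.length]
            == t.residues[s.target_pos:s.target_pos + s.length]
        )


# ---------------------------------------------------------------------------
# extend_seed
# ---------------------------------------------------------------------------

def test_extend_seed_identical_sequences_spans_everything(rng):
    res = random_dna(rng, 60)
    q = Sequence("q", res)
    hsp = extend_seed(Seed(20, 20, 8), q, q, DNA.scorer, xdrop=16)
    assert (hsp.query_start, hsp.query_end) == (0, 60)
    assert hsp.score == 60 * 2


def test_extend_seed_mismatch_walls_stop_extension():
    # seed flanked by mismatch runs deeper than xdrop on both sides
    q = Sequence("q", "A" * 12 + "ACGTACGT" + "A" * 12)
    t = Sequence("t", "C" * 12 + "ACGTACGT" + "C" * 12)
    hsp = extend_seed(Seed(12, 12, 8), q, t, DNA.scorer, xdrop=5)
    assert (hsp.query_start, hsp.query_end) == (12, 20)
    assert hsp.score == 16


def test_extend_seed_matches_endpoint_oracle(rng):
    """Endpoints equal the vectorised reformulation of the X-drop scan."""
    for _ in range(50):
        res = random_dna(rng, 100)
        q = Sequence("q", res)
        t = Sequence("t", mutate(rng, res, 12))
        seeds = find_seeds(q, t, k=8)
        if not seeds:
            continue
        seed = seeds[0]
        hsp = extend_seed(seed, q, t, DNA.scorer, xdrop=20)
        sc = DNA.scorer.score
        right = [
            sc(q.residues[seed.query_pos + seed.length + o],
               t.residues[seed.target_pos + seed.length + o])
            for o in range(min(
                len(q) - seed.query_pos - seed.length,
                len(t) - seed.target_pos - seed.length,
            ))
        ]
        left = [
            sc(q.residues[seed.query_pos - 1 - o],
               t.residues[seed.target_pos - 1 - o])
            for o in range(min(seed.query_pos, seed.target_pos))
        ]
        rg, rl = xdrop_endpoint(right, 20)
        lg, ll = xdrop_endpoint(left, 20)
        assert hsp.query_start == seed.query_pos - ll
        assert hsp.query_end == seed.query_pos + seed.length + rl
        base = sum(
            sc(q.residues[seed.query_pos + i], t.residues[seed.target_pos + i])
            for i in range(seed.length)
        )
        assert hsp.score == base + lg + rg
        assert hsp.score >= base  # extension never undercuts the seed window


# ---------------------------------------------------------------------------
# chain_hsps
# ---------------------------------------------------------------------------

def _random_hsps(rng, n):
    out = []
    for _ in range(n):
        qs = int(rng.integers(0, 80))
        ts = int(rng.integers(0, 80))
        length = int(rng.integers(5, 25))
        out.append(Hsp(qs, qs + length, ts, ts + length,
                       score=int(rng.integers(1, 60))))
    return out


def test_chain_single_hsp():
    h = Hsp(0, 10, 0, 10, 20)
    assert chain_hsps([h]) == [h]


def test_chain_target_overlap_keeps_higher_score():
    a = Hsp(0, 10, 0, 10, 30)
    b = Hsp(20, 30, 5, 15, 20)  # target overlaps a
    assert chain_hsps([a, b]) == [a]


def test_chain_empty():
    assert chain_hsps([]) == []


def test_chain_matches_greedy_oracle(rng):
    for _ in range(100):
        hsps = _random_hsps(rng, 6)
        assert chain_hsps(hsps) == greedy_chain(hsps)


def test_chain_result_is_collinear(rng):
    for _ in range(30):
        chain = chain_hsps(_random_hsps(rng, 8))
        for a, b in zip(chain, chain[1:]):
            assert a.query_end <= b.query_start
            assert a.target_end <= b.target_start


# ---------------------------------------------------------------------------
# banded_align
# ---------------------------------------------------------------------------

def test_banded_align_pure_deletion():
    ops, score = banded_align("", "ACG", DNA.scorer)
    assert ops == [("D", 3)]
    assert score == -(5 + 3 * 2)


def test_banded_align_pure_insertion():
    ops, score = banded_align("ACG", "", DNA.scorer)
    assert ops == [("I", 3)]
    assert score == -(5 + 3 * 2)


def test_banded_align_identity():
    ops, score = banded_align("ACGT", "ACGT", DNA.scorer)
    assert ops == [("M", 4)]
    assert score == 8


def test_banded_align_empty_segments():
    assert banded_align("", "", DNA.scorer) == ([], 0)


def test_banded_align_matches_full_dp_small(rng):
    """Generous band reproduces full Needleman-Wunsch affine scores."""
    for _ in range(40):
        q = random_dna(rng, int(rng.integers(1, 30)))
        t = random_dna(rng, int(rng.integers(1, 30)))
        ops, score = banded_align(q, t, DNA.scorer, band_radius=30)
        assert score == gotoh_global_score(q, t, DNA.scorer)
        # cigar must re-evaluate to its own score and consume both segments
        s2, _, _, _, _ = evaluate_cigar(ops, q, t, 0, 0, DNA.scorer)
        assert s2 == score
        assert sum(l for op, l in ops if op != "D") == len(q)
        assert sum(l for op, l in ops if op != "I") == len(t)


def test_banded_align_matches_biotite(rng):
    """Independent cross-check against a C-accelerated global aligner."""
    import biotite.sequence as bseq
    import biotite.sequence.align as ba

    alph = bseq.NucleotideSequence("ACGT").alphabet
    mat = ba.SubstitutionMatrix(
        alph, alph,
        np.array([[2 if i == j else -3 for j in range(4)] for i in range(4)],
                 dtype=np.int32),
    )
    for _ in range(25):
        q = random_dna(rng, int(rng.integers(5, 80)))
        t = random_dna(rng, int(rng.integers(5, 80)))
        _, score = banded_align(q, t, DNA.scorer, band_radius=100)
        ref = ba.align_optimal(
            bseq.NucleotideSequence(q), bseq.NucleotideSequence(t), mat,
            gap_penalty=(-(5 + 2), -2), terminal_penalty=True, local=False,
        )[0].score
        assert score == ref


def test_banded_align_protein_matches_full_dp(rng):
    for _ in range(15):
        q = random_protein(rng, int(rng.integers(5, 25)))
        t = random_protein(rng, int(rng.integers(5, 25)))
        _, score = banded_align(q, t, PROTEIN.scorer, band_radius=25)
        assert score == gotoh_global_score(q, t, PROTEIN.scorer)


def test_banded_align_band_auto_widens_for_length_difference():
    q = "ACGT"
    t = "ACGT" + "A" * 50  # length difference far beyond the radius
    ops, score = banded_align(q, t, DNA.scorer, band_radius=2)
    assert sum(l for op, l in ops if op != "I") == len(t)


# ---------------------------------------------------------------------------
# align_pair and identity
# ---------------------------------------------------------------------------

def test_align_pair_identical():
    q = Sequence("q", "ACGTACGTACGTACGTACGTACGT")
    chain = align_pair(q, q, k=8)
    assert chain.identity == 1.0
    assert chain.ops == (("M", len(q)),)


def test_align_pair_single_substitution(rng):
    res = random_dna(rng, 100)
    q = Sequence("q", res)
    t = Sequence("t", mutate(rng, res, 1))
    chain = align_pair(q, t, k=8)
    assert chain.alignment_length == 100
    assert chain.identity == pytest.approx(0.99)


def test_align_pair_disjoint_returns_none():
    q = Sequence("q", "A" * 40)
    t = Sequence("t", "C" * 40)
    assert align_pair(q, t, k=8) is None


def test_align_pair_score_consistency(rng):
    """Reported score equals re-evaluation of the cigar, exactly."""
    for _ in range(20):
        res = random_dna(rng, 150)
        q = Sequence("q", res)
        t = Sequence("t", mutate(rng, res, 15))
        chain = align_pair(q, t, k=8)
        score, matching, mismatches, gaps, columns = evaluate_cigar(
            chain.ops, q.residues, t.residues,
            chain.query_start, chain.target_start, DNA.scorer,
        )
        assert score == chain.score
        assert matching == chain.matching_columns
        assert mismatches == chain.mismatches
        assert gaps == chain.gap_openings
        assert columns == chain.alignment_length


def test_align_pair_identity_close_to_local_oracle(rng):
    """Heuristic identity within 0.02 of full affine local DP identity."""
    for _ in range(8):
        res = random_dna(rng, 180)
        q = Sequence("q", res)
        t = Sequence("t", mutate(rng, res, 9))  # 5% divergence
        chain = align_pair(q, t, k=8, band_radius=32)
        _, matching, columns = gotoh_local_identity(
            q.residues, t.residues, DNA.scorer
        )
        assert chain.identity == pytest.approx(matching / columns, abs=0.02)


def test_align_pair_symmetry(rng):
    for _ in range(10):
        res = random_dna(rng, 120)
        q = Sequence("q", res)
        t = Sequence("t", mutate(rng, res, 10))
        fwd = align_pair(q, t, k=8)
        rev = align_pair(t, q, k=8)
        assert fwd.identity == rev.identity
        assert fwd.score == rev.score


def test_align_pair_monotone_degradation(rng):
    """More point mutations never increase identity (distinct positions)."""
    res = random_dna(rng, 200)
    q = Sequence("q", res)
    positions = rng.choice(200, size=20, replace=False)
    identities = []
    mutated = list(res)
    for p in positions:
        mutated[p] = "ACGT"[("ACGT".index(mutated[p]) + 1) % 4]
        chain = align_pair(q, Sequence("t", "".join(mutated)), k=8)
        identities.append(chain.identity if chain else 0.0)
    assert all(a >= b for a, b in zip(identities, identities[1:]))


def test_identity_of_recounts_cigar(rng):
    res = random_dna(rng, 150)
    q = Sequence("q", res)
    t = Sequence("t", mutate(rng, res, 7))
    chain = align_pair(q, t, k=8)
    matching = sum(
        1 for a, b in zip(
            q.residues[chain.query_start:chain.query_end],
            t.residues[chain.target_start:chain.target_end],
        ) if a == b
    ) if chain.gap_openings == 0 else chain.matching_columns
    assert identity_of(chain) == matching / chain.alignment_length


def test_expanded_cigar_splits_matches():
    q = "ACGT"
    t = "ACTT"
    assert expanded_cigar([("M", 4)], q, t, 0, 0) == "2=1X1="


def test_cigar_string_format():
    assert cigar_string([("M", 95), ("I", 2), ("M", 3)]) == "95M2I3M"
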