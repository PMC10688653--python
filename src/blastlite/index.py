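"""K-mer database index and shared-k-mer candidate counting.

Database sequences are indexed into postings lists keyed by packed k-mer
codes. A k-length window packs into a 32-bit unsigned integer using the
alphabet's per-residue bit codes, big-endian (first residue in the highest
bits). Any window containing at least one ambiguous residue maps to the
``AMBIGUOUS_KMER`` sentinel and is excluded from the index entirely —
storing every realisation of an ambiguous window would grow exponentially.

Candidate selection counts U, the number of *distinct* k-mers a query
shares with each database sequence (presence, not multiplicity), and
returns targets ordered by decreasing U with ties broken by insertion
order, which makes the downstream search fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence as TSequence, Tuple

from .alphabet import Alphabet, Sequence


class _AmbiguousKmer:
    """Sentinel code for windows containing an ambiguous residue."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "AMBIGUOUS_KMER"


AMBIGUOUS_KMER = _AmbiguousKmer()


def encode_kmer(window: str, alphabet: Alphabet):
    """Pack a k-length window into an integer code (or the sentinel).

    Big-endian packing: code = sum over i of code(residue_i) shifted by
    bits * (k - 1 - i). Returns ``AMBIGUOUS_KMER`` iff any residue is
    ambiguous.
    """
    codes = alphabet.codes
    bits = alphabet.bits_per_symbol
    value = 0
    for ch in window:
        c = codes.get(ch)
        if c is None:
            return AMBIGUOUS_KMER
        value = (value << bits) | c
    return value


def enumerate_kmers(seq: Sequence, k: int) -> List[Tuple[int, int]]:
    """All (position, code) windows of a sequence, ambiguity-free only.

    Windows overlapping an ambiguous residue are omitted (not emitted as
    sentinel entries). Uses a rolling encoding, O(len) overall.
    """
    residues = seq.residues
    n = len(residues)
    if n < k:
        return []
    codes = seq.alphabet.codes
    bits = seq.alphabet.bits_per_symbol
    mask = (1 << (bits * k)) - 1
    out: List[Tuple[int, int]] = []
    value = 0
    run = 0  # consecutive unambiguous residues ending here
    for i, ch in enumerate(residues):
        c = codes.get(ch)
        if c is None:
            run = 0
            value = 0
            continue
        value = ((value << bits) | c) & mask
        run += 1
        if run >= k:
            out.append((i - k + 1, value))
    return out


@dataclass
class DatabaseIndex:
    """Lookup tables mapping k-mer codes to the sequences containing them."""

    k: int
    alphabet: Alphabet
    sequences: List[Sequence]
    postings: Dict[int, List[int]] = field(default_factory=dict)
    unique_kmer_counts: List[int] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.sequences)


def build_index(sequences: TSequence[Sequence], k: int) -> DatabaseIndex:
    """Index database sequences; a pure function of (sequences, k).

    Sequence ids are assigned in input order; each id appears at most once
    per postings list (presence only).
    """
    seqs = list(sequences)
    if k < 1:
        raise ValueError("k must be >= 1")
    if seqs:
        alphabet = seqs[0].alphabet
        for s in seqs:
            if s.alphabet is not alphabet:
                raise ValueError("all database sequences must share one alphabet")
    else:
        from .alphabet import DNA as alphabet  # empty db: alphabet immaterial
    if k * alphabet.bits_per_symbol > 32:
        raise ValueError(
            f"k={k} exceeds the 32-bit code budget for alphabet "
            f"{alphabet.name!r} ({alphabet.bits_per_symbol} bits/residue)"
        )
    postings: Dict[int, List[int]] = {}
    counts: List[int] = []
    for sid, seq in enumerate(seqs):
        unique = {code for _, code in enumerate_kmers(seq, k)}
        counts.append(len(unique))
        for code in unique:
            postings.setdefault(code, []).append(sid)
    # ids were appended in increasing order, so postings lists are sorted
    return DatabaseIndex(
        k=k, alphabet=alphabet, sequences=seqs,
        postings=postings, unique_kmer_counts=counts,
    )


CandidateList = List[Tuple[int, int]]  # (target_id, U) sorted by U desc


def count_shared(query: Sequence, index: DatabaseIndex, k: int = None) -> CandidateList:
    """Rank database sequences by U, the number of distinct shared k-mers.

    U(t) = |unique_kmers(query) ∩ unique_kmers(t)|, accumulated through the
    postings lists. Targets with U = 0 are excluded; ties at equal U break
    by ascending target id.
    """
    if k is None:
        k = index.k
    elif k != index.k:
        raise ValueError(f"index was built with k={index.k}, not k={k}")
    if query.alphabet is not index.alphabet and index.sequences:
        raise ValueError("query alphabet differs from index alphabet")
    query_kmers = {code for _, code in enumerate_kmers(query, k)}
    shared: Dict[int, int] = {}
    postings = index.postings
    for code in query_kmers:
        for sid in postings.get(code, ()):
            shared[sid] = shared.get(sid, 0) + 1
    return sorted(shared.items(), key=lambda item: (-item[1], item[0]))
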