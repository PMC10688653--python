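"""Residue alphabets, scoring and sequence containers.

An :class:`Alphabet` bundles everything the search pipeline needs to know
about a residue type: the canonical symbol set, the bit width used to pack
k-mers into 32-bit codes, the set of ambiguity characters, and a
:class:`PairScorer` for alignment. Two alphabets are provided: ``DNA``
(2-bit codes, IUPAC ambiguity, match/mismatch scoring) and ``PROTEIN``
(5-bit codes, BLOSUM62 scoring). RNA input is handled by normalising U to T
at construction time, so a single nucleic alphabet covers both.

The design is deliberately policy-like: adding a new alphabet means
constructing another :class:`Alphabet` instance, nothing in the index or
alignment code is nucleotide-specific.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Tuple


class InvalidResidueError(ValueError):
    """A residue outside the alphabet's canonical + ambiguity sets."""

    def __init__(self, residue: str, position: int, context: str = ""):
        self.residue = residue
        self.position = position  # 1-based
        where = f" in {context}" if context else ""
        super().__init__(
            f"invalid residue {residue!r} at position {position}{where}"
        )


# ---------------------------------------------------------------------------
# Pairwise scoring
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PairScorer:
    """Symmetric substitution scores plus affine gap penalties.

    A gap of length L costs ``gap_open + L * gap_extend`` (both penalties
    are positive numbers that get subtracted from the alignment score).

    ``matrix`` maps ordered residue pairs to integer scores; pairs absent
    from the matrix fall back to ``default_score`` (used for ambiguous
    residues in the nucleic alphabet, and for the rare protein ambiguity
    letters that the BLOSUM table does not carry, which are routed through
    the X row via ``aliases``).
    """

    matrix: Mapping[Tuple[str, str], int]
    gap_open: int
    gap_extend: int
    default_score: int
    aliases: Mapping[str, str] = field(default_factory=dict)

    def score(self, a: str, b: str) -> int:
        a = self.aliases.get(a, a)
        b = self.aliases.get(b, b)
        return self.matrix.get((a, b), self.default_score)


def score_pair(a: str, b: str, scorer: PairScorer) -> int:
    """Substitution score for an ordered residue pair."""
    return scorer.score(a, b)


def _load_matrix_text(text: str) -> Dict[Tuple[str, str], int]:
    """Parse an NCBI-format substitution matrix into a pair dict."""
    matrix: Dict[Tuple[str, str], int] = {}
    columns: list[str] = []
    for line in text.splitlines():
        line = line.rstrip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if not columns:
            columns = fields
            continue
        row = fields[0]
        for col, val in zip(columns, fields[1:]):
            matrix[(row, col)] = int(val)
    return matrix


def load_blosum62() -> Dict[Tuple[str, str], int]:
    """The packaged BLOSUM62 matrix as an ordered-pair dict."""
    text = blosum62_text()
    return _load_matrix_text(text)


def blosum62_text() -> str:
    """The BLOSUM62 table verbatim, in NCBI matrix text format."""
    ref = importlib.resources.files("blastlite").joinpath("data/blosum62.txt")
    return ref.read_text()


# ---------------------------------------------------------------------------
# Alphabets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Alphabet:
    """A residue alphabet: symbols, k-mer packing policy and scorer."""

    name: str
    symbols: Tuple[str, ...]
    bits_per_symbol: int
    default_k: int
    ambiguity_set: frozenset
    scorer: PairScorer
    codes: Mapping[str, int]
    complement: Optional[Mapping[str, str]] = None
    default_xdrop: int = 16

    def __post_init__(self) -> None:
        if 2 ** self.bits_per_symbol < len(self.symbols):
            raise ValueError("bits_per_symbol too small for symbol set")
        if self.default_k * self.bits_per_symbol > 32:
            raise ValueError("default_k does not fit a 32-bit k-mer code")

    @property
    def valid_chars(self) -> frozenset:
        return frozenset(self.symbols) | self.ambiguity_set

    def is_ambiguous(self, residue: str) -> bool:
        return residue in self.ambiguity_set


_DNA_MATRIX = {
    (a, b): (2 if a == b else -3) for a in "ACGT" for b in "ACGT"
}

DNA_COMPLEMENT = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    # IUPAC ambiguity codes
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}

DNA = Alphabet(
    name="dna",
    symbols=tuple("ACGT"),
    bits_per_symbol=2,
    default_k=8,
    ambiguity_set=frozenset("RYSWKMBDHVN"),
    scorer=PairScorer(
        matrix=_DNA_MATRIX, gap_open=5, gap_extend=2, default_score=-3
    ),
    codes={"A": 0, "C": 1, "G": 2, "T": 3},
    complement=DNA_COMPLEMENT,
    default_xdrop=16,
)

_PROTEIN_SYMBOLS = tuple("ACDEFGHIKLMNPQRSTVWY")  # alphabetical one-letter

PROTEIN = Alphabet(
    name="protein",
    symbols=_PROTEIN_SYMBOLS,
    bits_per_symbol=5,
    default_k=5,
    ambiguity_set=frozenset("BZJX"),
    scorer=PairScorer(
        matrix=load_blosum62(),
        gap_open=11,
        gap_extend=1,
        default_score=-1,  # X-vs-anything fallback
        aliases={"J": "X"},  # J (I/L) is absent from BLOSUM62
    ),
    codes={s: i for i, s in enumerate(_PROTEIN_SYMBOLS)},
    default_xdrop=32,
)

ALPHABETS: Dict[str, Alphabet] = {"dna": DNA, "protein": PROTEIN}


def get_alphabet(name_or_alphabet) -> Alphabet:
    if isinstance(name_or_alphabet, Alphabet):
        return name_or_alphabet
    try:
        return ALPHABETS[str(name_or_alphabet).lower()]
    except KeyError:
        raise ValueError(f"unknown alphabet: {name_or_alphabet!r}") from None


# ---------------------------------------------------------------------------
# Sequences
# ---------------------------------------------------------------------------

def normalize(raw_text: str, alphabet: Alphabet, context: str = "") -> str:
    """Canonicalise raw residue text for an alphabet.

    Uppercases, strips all whitespace, maps U to T for nucleic input, and
    rejects any character outside the alphabet with an
    :class:`InvalidResidueError` naming the offending character and its
    1-based position (counted after whitespace removal).
    """
    stripped = "".join(raw_text.split()).upper()
    if alphabet.name == "dna":
        stripped = stripped.replace("U", "T")
    valid = alphabet.valid_chars
    for i, ch in enumerate(stripped):
        if ch not in valid:
            raise InvalidResidueError(ch, i + 1, context)
    return stripped


@dataclass(frozen=True)
class Sequence:
    """An identified residue string tagged with its alphabet.

    Residues are normalised at construction (uppercase, U->T for nucleic,
    validated); an invalid character raises :class:`InvalidResidueError`.
    """

    identifier: str
    residues: str
    alphabet: Alphabet = DNA
    description: str = ""

    def __post_init__(self) -> None:
        if not self.identifier:
            raise ValueError("sequence identifier must be non-empty")
        object.__setattr__(
            self,
            "residues",
            normalize(self.residues, self.alphabet, context=self.identifier),
        )

    def __len__(self) -> int:
        return len(self.residues)


def reverse_complement(seq: Sequence) -> Sequence:
    """Reverse-complement a nucleic sequence (IUPAC-aware); involution."""
    if seq.alphabet.complement is None:
        raise ValueError(
            f"reverse_complement undefined for alphabet {seq.alphabet.name!r}"
        )
    comp = seq.alphabet.complement
    rc = "".join(comp[ch] for ch in reversed(seq.residues))
    return Sequence(seq.identifier, rc, seq.alphabet, seq.description)
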