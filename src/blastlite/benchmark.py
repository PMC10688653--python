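"""Synthetic family-recovery benchmark generator.

Emulates the structure of a curated-family recovery protocol: each family
descends from one random ancestral root, and every member is an
independently mutated copy of that root (per-residue substitutions,
single-residue insertions and deletions, and a trickle of ambiguous N
residues so ambiguity-handling code paths run end-to-end). One member per
family is withheld as a query; the remainder form the reference database;
accuracy is the fraction of queries whose top accepted hit belongs to the
query's own family.

Roots are uniform random nucleotide strings, not biologically structured
sequences: the generator emulates the recovery *protocol*, not ncRNA
biology. All randomness derives from the single seed in the spec, so two
runs with an equal spec produce byte-identical FASTA.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Sequence as TSequence, Tuple

import numpy as np

from .alphabet import DNA, Sequence
from .io import HitRecord, write_fasta

_BASES = "ACGT"


@dataclass(frozen=True)
class FamilySpec:
    """Generator settings; defaults are the benchmark's study conditions.

    Rates are per residue of the root. ``indel`` divergence is split
    evenly between insertions and deletions; ambiguity injection replaces
    an emitted residue with N.
    """

    n_families: int = 200
    members_per_family: int = 4
    root_length: Tuple[int, int] = (150, 300)
    substitution_rate: float = 0.10
    insertion_rate: float = 0.005
    deletion_rate: float = 0.005
    ambiguity_rate: float = 0.002
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_families < 1 or self.members_per_family < 2:
            raise ValueError("need >= 1 family with >= 2 members each")
        for rate in (self.substitution_rate, self.insertion_rate,
                     self.deletion_rate, self.ambiguity_rate):
            if not (0.0 <= rate < 1.0):
                raise ValueError("rates must lie in [0, 1)")


def family_of(seq_id: str) -> str:
    """Family label encoded in a generated sequence id (``fNNNN_mK``)."""
    return seq_id.split("_", 1)[0]


def _mutate(root: str, rng: np.random.Generator, spec: FamilySpec) -> str:
    out: List[str] = []
    for ch in root:
        if rng.random() < spec.deletion_rate:
            continue
        base = ch
        if rng.random() < spec.substitution_rate:
            base = _BASES[(_BASES.index(ch) + rng.integers(1, 4)) % 4]
        if rng.random() < spec.ambiguity_rate:
            base = "N"
        out.append(base)
        if rng.random() < spec.insertion_rate:
            out.append(_BASES[rng.integers(0, 4)])
    return "".join(out) or _BASES[rng.integers(0, 4)]


def generate_families(spec: FamilySpec) -> List[Sequence]:
    """Generate all family members; ids encode family and member index.

    Member ids are ``f{family:04d}_m{member}``; every member is an
    independent mutant of its family root (the root itself is not
    emitted). Deterministic under ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.root_length
    sequences: List[Sequence] = []
    for fam in range(spec.n_families):
        length = int(rng.integers(lo, hi + 1))
        root = "".join(_BASES[c] for c in rng.integers(0, 4, size=length))
        for mem in range(spec.members_per_family):
            residues = _mutate(root, rng, spec)
            sequences.append(
                Sequence(f"f{fam:04d}_m{mem}", residues, DNA)
            )
    return sequences


@dataclass(frozen=True)
class BenchmarkSplit:
    """Query/database split with the query -> family truth map."""

    queries: Tuple[Sequence, ...]
    database: Tuple[Sequence, ...]
    truth: Dict[str, str]  # query id -> family label


def split_benchmark(
    families: TSequence[Sequence], seed: int = 0
) -> BenchmarkSplit:
    """Withhold one random member per family as the query set.

    Raises on any single-member family. Deterministic under ``seed``.
    """
    rng = np.random.default_rng(seed)
    by_family: Dict[str, List[Sequence]] = {}
    for seq in families:
        by_family.setdefault(family_of(seq.identifier), []).append(seq)
    queries: List[Sequence] = []
    database: List[Sequence] = []
    truth: Dict[str, str] = {}
    for fam in sorted(by_family):
        members = by_family[fam]
        if len(members) < 2:
            raise ValueError(f"family {fam!r} has fewer than 2 members")
        pick = int(rng.integers(0, len(members)))
        for i, seq in enumerate(members):
            if i == pick:
                queries.append(seq)
                truth[seq.identifier] = fam
            else:
                database.append(seq)
    return BenchmarkSplit(tuple(queries), tuple(database), truth)


def score_accuracy(hits: TSequence[HitRecord], truth: Dict[str, str]) -> float:
    """Fraction of queries whose top accepted hit is in their own family.

    The top hit is the first hit reported for a query (acceptance order);
    queries with no hit count as failures.
    """
    top: Dict[str, str] = {}
    for hit in hits:
        if hit.query_id not in top:
            top[hit.query_id] = hit.target_id
    if not truth:
        return 0.0
    correct = sum(
        1 for qid, fam in truth.items()
        if qid in top and family_of(top[qid]) == fam
    )
    return correct / len(truth)


def write_benchmark(split: BenchmarkSplit, directory) -> None:
    """Write queries.fasta, database.fasta and truth.tsv to a directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_fasta(split.queries, directory / "queries.fasta")
    write_fasta(split.database, directory / "database.fasta")
    with open(directory / "truth.tsv", "w", encoding="utf-8") as fh:
        fh.write("query_id\tfamily\n")
        for qid in (s.identifier for s in split.queries):
            fh.write(f"{qid}\t{split.truth[qid]}\n")
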