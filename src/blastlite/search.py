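"""The accept/reject search driver.

Candidates are examined in decreasing order of U (distinct shared k-mers).
Each candidate is aligned; identity at or above ``min_identity`` is an
accept, below is a reject, and a candidate that yields no alignment (no
seeds) also counts as a reject. The per-query loop stops at
``max_accepts`` accepts or ``max_rejects`` rejects, so at most
max_accepts + max_rejects alignments are ever computed per query.

For nucleic searches both strands can be examined: the minus strand
searches the reverse-complemented query, candidate lists from the two
orientations are merged by U, and the accept/reject budgets are shared
across strands. Minus-strand hit coordinates are mapped back onto the
original query.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import IO, List, Optional, Sequence as TSequence, Union

from .alphabet import (
    Alphabet, PairScorer, Sequence, get_alphabet, reverse_complement,
)
from .align import align_pair
from .index import DatabaseIndex, build_index, count_shared
from .io import HitRecord, read_fasta, write_hits

logger = logging.getLogger("blastlite")


@dataclass(frozen=True)
class SearchParams:
    """Search settings; defaults reproduce the benchmark protocol.

    min_identity 0.75, one accept, eight rejects; strand "both" applies to
    nucleic searches only (protein forces plus).
    """

    min_identity: float = 0.75
    max_accepts: int = 1
    max_rejects: int = 8
    strand: str = "both"
    k: Optional[int] = None
    scorer: Optional[PairScorer] = None
    xdrop: Optional[int] = None
    band_radius: int = 16

    def __post_init__(self) -> None:
        if not (0.0 < self.min_identity <= 1.0):
            raise ValueError("min_identity must be in (0, 1]")
        if self.max_accepts < 1 or self.max_rejects < 1:
            raise ValueError("max_accepts and max_rejects must be >= 1")
        if self.strand not in {"plus", "minus", "both"}:
            raise ValueError(f"bad strand {self.strand!r}")

    def resolved(self, alphabet: Alphabet) -> "SearchParams":
        """Fill alphabet-dependent defaults (k, scorer, xdrop, strand)."""
        strand = self.strand
        if alphabet.name == "protein":
            if strand != "plus":
                raise ValueError("protein searches support the plus strand only")
        return replace(
            self,
            k=self.k or alphabet.default_k,
            scorer=self.scorer or alphabet.scorer,
            xdrop=self.xdrop or alphabet.default_xdrop,
            strand=strand,
        )


@dataclass
class SearchStats:
    """Instrumentation for audits: one entry per alignment attempted."""

    alignments_per_query: List[int] = field(default_factory=list)
    examined: List[List[tuple]] = field(default_factory=list)
    # each examined entry: (target_id, U, strand, identity or None, accepted)


def _hit_from_chain(query: Sequence, target: Sequence, chain, strand: str,
                    original_query_length: int) -> HitRecord:
    qs, qe = chain.query_start + 1, chain.query_end  # 1-based inclusive
    if strand == "-":
        # chain coordinates are on the reverse-complemented query; map back
        L = original_query_length
        qs, qe = L - chain.query_end + 1, L - chain.query_start
    return HitRecord(
        query_id=query.identifier,
        target_id=target.identifier,
        identity_fraction=chain.identity,
        alignment_length=chain.alignment_length,
        mismatches=chain.mismatches,
        gap_openings=chain.gap_openings,
        query_start=qs,
        query_end=qe,
        target_start=chain.target_start + 1,
        target_end=chain.target_end,
        strand=strand,
        cigar=chain.cigar,
    )


def _candidate_stream(query: Sequence, index: DatabaseIndex, strand: str):
    """Merged candidate list: (U, target_id, strand_rank, oriented_query).

    Sorted by decreasing U, then ascending target id, then plus before
    minus — a fully deterministic examination order.
    """
    oriented = {"+": query}
    entries = []
    if strand in {"plus", "both"}:
        for tid, u in count_shared(query, index):
            entries.append((-u, tid, 0, "+"))
    if strand in {"minus", "both"}:
        rc = reverse_complement(query)
        oriented["-"] = rc
        for tid, u in count_shared(rc, index):
            entries.append((-u, tid, 1, "-"))
    entries.sort()
    return [
        (-neg_u, tid, s_char, oriented[s_char])
        for neg_u, tid, _rank, s_char in entries
    ]


def search_one(
    query: Sequence, index: DatabaseIndex, params: SearchParams,
    stats: Optional[SearchStats] = None,
) -> List[HitRecord]:
    """Search one query on the plus strand only."""
    p = replace(params, strand="plus")
    return _search_oriented(query, index, p.resolved(index.alphabet), stats)


def search_strands(
    query: Sequence, index: DatabaseIndex, params: SearchParams,
    stats: Optional[SearchStats] = None,
) -> List[HitRecord]:
    """Search one query on the configured strands with shared budgets."""
    return _search_oriented(query, index, params.resolved(index.alphabet), stats)


def _search_oriented(
    query: Sequence, index: DatabaseIndex, params: SearchParams,
    stats: Optional[SearchStats],
) -> List[HitRecord]:
    if len(query) < params.k:
        logger.warning(
            "query %s (length %d) is shorter than k=%d; no candidates",
            query.identifier, len(query), params.k,
        )
    candidates = _candidate_stream(query, index, params.strand)
    hits: List[HitRecord] = []
    accepts = 0
    rejects = 0
    n_alignments = 0
    audit: List[tuple] = []
    for u, tid, strand, oriented_query in candidates:
        if accepts >= params.max_accepts or rejects >= params.max_rejects:
            break
        target = index.sequences[tid]
        chain = align_pair(
            oriented_query, target,
            k=params.k, scorer=params.scorer,
            xdrop=params.xdrop, band_radius=params.band_radius,
        )
        n_alignments += 1
        if chain is None:
            rejects += 1
            audit.append((target.identifier, u, strand, None, False))
            continue
        if chain.identity >= params.min_identity:
            accepts += 1
            hits.append(_hit_from_chain(
                oriented_query, target, chain,
                strand if index.alphabet.name == "dna" else "n/a",
                len(query),
            ))
            audit.append((target.identifier, u, strand, chain.identity, True))
        else:
            rejects += 1
            audit.append((target.identifier, u, strand, chain.identity, False))
    if stats is not None:
        stats.alignments_per_query.append(n_alignments)
        stats.examined.append(audit)
    return hits


def search_all(
    queries: TSequence[Sequence], database: TSequence[Sequence],
    params: Optional[SearchParams] = None,
    stats: Optional[SearchStats] = None,
) -> List[HitRecord]:
    """Index the database once and search every query in order."""
    params = params or SearchParams()
    db = list(database)
    if not db:
        return []
    alphabet = db[0].alphabet
    k = params.k or alphabet.default_k
    index = build_index(db, k)
    hits: List[HitRecord] = []
    for query in queries:
        hits.extend(search_strands(query, index, params, stats))
    return hits


def blast(
    query: Union[str, Path, TSequence[Sequence]],
    database: Union[str, Path, TSequence[Sequence]],
    max_accepts: int = 1,
    max_rejects: int = 8,
    min_identity: float = 0.75,
    alphabet: Union[str, Alphabet] = "dna",
    strand: str = "both",
    output: Optional[Union[str, Path, IO[str]]] = None,
    output_dialect: str = "tsv",
    **kwargs,
) -> List[HitRecord]:
    """High-level entry point: search a query set against a database.

    ``query`` and ``database`` may be FASTA paths or sequence collections.
    If ``output`` is given, the hit table is also written there.
    """
    alpha = get_alphabet(alphabet)
    if alpha.name == "protein" and strand == "both":
        strand = "plus"
    if isinstance(query, (str, Path)):
        query = read_fasta(query, alpha)
    if isinstance(database, (str, Path)):
        database = read_fasta(database, alpha)
    params = SearchParams(
        min_identity=min_identity, max_accepts=max_accepts,
        max_rejects=max_rejects, strand=strand, **kwargs,
    )
    hits = search_all(query, database, params)
    if output is not None:
        write_hits(hits, output, output_dialect)
    return hits
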