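# blastlite

A lightweight, embeddable BLAST-like sequence similarity search for DNA,
RNA and protein sequences — a pure-Python library with a thin command-line
front end. It is aimed at people who want BLAST-style "find my sequence in
this database" functionality inside a larger Python application or
pipeline without shelling out to an external aligner installation.

## The algorithm

The search rests on the observation that a few good candidate sequences
are enough for most similarity searches:

1. **Indexing.** Every database sequence is decomposed into overlapping
   k-mers (k = 8 for nucleotides, k = 5 for proteins). Each k-mer packs
   into a 32-bit code (2 bits per nucleotide, 5 per amino acid); windows
   containing an ambiguous residue (IUPAC codes, or B/Z/J/X for proteins)
   are excluded from the index rather than expanded.
2. **Candidate filtering.** For a query, the index yields *U*, the number
   of distinct k-mers shared with each database sequence. Candidates are
   examined in decreasing order of *U*.
3. **Alignment.** Each candidate is aligned by seed-and-extend: exact
   k-mer matches are merged into maximal seeds, extended without gaps
   under an X-drop rule into HSPs (high-scoring segment pairs), chained
   greedily (best HSP first, then the best collinear non-overlapping
   remainder), and the gaps between chained HSPs are closed with banded
   affine-gap dynamic programming.
4. **Accept/reject.** Identity = matching columns / all alignment columns
   (gap columns included, terminal overhangs excluded). A candidate at or
   above the identity threshold is a hit; the per-query loop stops at
   `max_accepts` hits or `max_rejects` rejects (defaults: ≥ 75% identity,
   1 accept, 8 rejects).

Nucleotide scoring is +2 match / −3 mismatch; protein scoring uses the
BLOSUM62 matrix. Gaps are affine: a gap of length L costs
`open + L·extend` (5 + 2L for DNA, 11 + L for protein). For nucleotide
queries both strands are searched by default, with one shared
accept/reject budget across strands.

## Worked example

```sh
$ cat ex.fa
>q1
ACGTACGTACGTACGTACGTACGTACGT
$ blastlite search --query ex.fa --db ex.fa --out -
INFO blastlite: alphabet=dna strand=both k=8 min_identity=0.75 max_accepts=1 max_rejects=8 dialect=tsv
INFO blastlite: queries=1 hits=1 mean_identity=1.000
query_id  target_id  identity  alignment_length  mismatches  gap_openings  q_start  q_end  t_start  t_end  strand  cigar
q1        q1         100.0     28                0           0             1        28     1        28     +       28M
```

The log lines (standard error) echo every effective parameter and a run
summary; the data stream (standard out, or `--out FILE`) is a tabular hit
report: one row per accepted hit with percent identity, alignment length,
mismatch and gap-opening counts, 1-based inclusive coordinates on query
and target, strand (`+`/`-` for nucleotides, `n/a` for proteins) and the
alignment CIGAR. Here the query matches itself over all 28 columns at
100.0% identity.

The same search from Python:

```python
from blastlite import blast
hits = blast("queries.fa", "database.fa", min_identity=0.75)
for h in hits:
    print(h.query_id, h.target_id, h.identity_fraction)
```

A synthetic family-recovery benchmark (mutated descendants of random
ancestral roots, one member per family withheld as a query) can be
generated with `blastlite make-benchmark --out-dir bench/`.

## Scope

No E-values or bit scores, no translated searches, no optimal (DP)
chaining, no multithreading: results are sequential-deterministic — two
runs on identical inputs produce byte-identical hit tables.
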