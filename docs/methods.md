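# Methods

## Model of the search

blastlite implements heuristic local similarity search in the usearch
lineage: a cheap k-mer prefilter proposes a short, ranked list of
database candidates, and only those candidates are aligned. The method is
exact nowhere and effective because truly similar sequences share many
k-mers; its guarantees are therefore empirical (the acceptance script
measures them) rather than analytic.

### Alphabets as policy

All residue-type knowledge lives in an `Alphabet` object: canonical
symbols, per-residue bit codes, ambiguity set, complement table and a
`PairScorer`. The nucleic alphabet covers DNA and RNA (U is normalised to
T at sequence construction); the protein alphabet covers the 20 canonical
amino acids. Nothing downstream branches on residue type, so further
alphabets or scoring schemes are additions, not modifications.

Residue bit codes are A=0, C=1, G=2, T=3 (2 bits) and the amino acids
0–19 in alphabetical one-letter order (5 bits). Codes pack big-endian
into a 32-bit integer, which caps k at 16 for nucleotides and 6 for
proteins; defaults are k=8 and k=5. Larger k trades sensitivity for
speed.

### Ambiguity handling

Any k-window containing an ambiguous residue (IUPAC nucleotide codes;
B/Z/J/X for protein) is dropped from both the database index and the
query k-mer set — expanding ambiguity codes into all realisations grows
exponentially and is never worth it at these k. At alignment time
ambiguous residues score as an ordinary mismatch (−3) for nucleotides and
through the BLOSUM62 X/B/Z rows for proteins (J, absent from the
published table, is routed through the X row). Lowercase input is simply
uppercased; there is no soft-masking.

### Scoring

Nucleotides: match +2, mismatch −3, gap open 5, gap extend 2 — the
classic megablast-style defaults. Proteins: BLOSUM62 with gap open 11,
extend 1, the standard protein-BLAST configuration. A gap of length L
costs open + L·extend; penalties are positive numbers that are
subtracted. The BLOSUM62 table ships as a static NCBI-format text file
and is validated entry-for-entry against an independent copy in the test
suite.

### Candidate ranking

U(query, target) is the size of the intersection of the two *distinct*
k-mer sets — presence, not multiplicity, so internal repeats count once.
Postings lists store presence only (no positions); seed positions are
recomputed per pair at alignment time, keeping index memory linear.
Candidates are examined in strictly decreasing U; ties break by database
insertion order, and for two-strand searches the plus orientation of an
equal-(U, target) pair is examined before the minus one. These tie-break
rules exist purely to make the whole search deterministic.

### Alignment pipeline

1. *Seeds*: all exact, ambiguity-free k-mer matches between the pair;
   overlapping or touching matches on one diagonal merge into maximal
   seeds (no match is lost by merging).
2. *X-drop extension*: each seed is extended without gaps left and right;
   a side stops once the running score falls more than `xdrop` below that
   side's best, and the HSP is trimmed back to the best endpoints. The
   seed window itself is never trimmed. Defaults: xdrop 16 (nucleotide),
   32 (protein) — protein scores move in bigger steps, hence the larger
   drop allowance. HSPs with identical intervals (one per diagonal run,
   typically) are deduplicated.
3. *Greedy chaining*: highest-scoring HSP first, then repeatedly the
   highest-scoring remaining HSP that is collinear with and
   non-overlapping (in both query and target) with everything selected.
   Ties: smaller query start, then smaller target start. This is
   deliberately the greedy rule, not optimal DP chaining.
4. *Bridging*: the region between consecutive chained HSPs is aligned
   globally with banded affine-gap DP (Gotoh). The band spans
   `band_radius` (default 16) diagonals around the corridor between the
   starting diagonal and its shift by the segment length difference, so a
   path always exists; with a band at least as wide as the longer
   segment it provably equals full Needleman–Wunsch.

### Identity

Identity = matching columns / all alignment columns, gap columns
included, computed over the chained region only — terminal overhangs
beyond the outermost HSPs are excluded. This matches the BLAST tabular
convention. A consequence worth knowing: a short perfect local match
(e.g. a single shared k-mer in otherwise unrelated sequences) has
identity 1.0 over its few columns, so `min_identity` is a *local*
identity threshold. The candidate ordering by U makes this mostly moot in
practice — genuinely similar targets are examined first — but users who
need global coverage should filter hits on `alignment_length` as well.

### The accept/reject loop

Per query, candidates are aligned in ranked order. Identity at or above
`min_identity` (default 0.75) appends a hit; below it counts a reject; a
candidate with no seeds (possible through ambiguity stripping) also
counts as a reject. The loop stops at `max_accepts` (default 1) accepts
or `max_rejects` (default 8) rejects, so at most
`max_accepts + max_rejects` alignments are ever computed per query; the
budgets are per query and shared across strands. Self-hits are not
suppressed. Minus-strand hits are computed on the reverse-complemented
query; their coordinates are mapped back onto the original query (with
query_start ≤ query_end preserved) and the reported CIGAR describes the
reverse-complemented query against the target.

## The synthetic benchmark

`blastlite.benchmark` emulates a family-recovery protocol: families
descend from one uniform-random root each; every member is an independent
mutant of its root; one random member per family becomes a query and the
rest the database; accuracy is the fraction of queries whose top accepted
hit is in their own family. Defaults — 200 families × 4 members, roots
150–300 nt, 10% substitution, 0.5% + 0.5% insertion/deletion, 0.2%
N-injection — put typical query–target identity near 0.81, usefully close
to the 0.75 acceptance threshold, and the N-injection exercises the
ambiguity paths end-to-end. Indels are single-residue events; no indel
length distribution is modelled, which is enough to exercise the gap
code.

What passing this benchmark does *not* show: uniform-random roots have
none of the conserved secondary structure, repeat content or compositional
bias of real sequence families, and family members here are star-shaped
descendants of one root rather than a phylogeny. Results on it establish
the pipeline's mechanics (ranking, alignment, budgets, determinism), not
biological sensitivity at a given divergence.

All generator randomness flows from a single integer seed through one
`numpy` generator; equal specs yield byte-identical FASTA.

## Numerical and design choices

- All scores are exact integers; identity is an exact fraction
  (`matching/columns`) and only formatting rounds it (one decimal as a
  percentage in the hit table).
- DP traceback prefers match/mismatch over target-gap over query-gap and
  closes gaps eagerly at equal score — an arbitrary but fixed rule that
  keeps CIGARs deterministic.
- Degenerate inputs: an empty bridge segment aligns to a pure gap run; a
  query shorter than k yields no candidates (logged warning, empty
  result); an empty database yields an empty table.
- The benchmark problem sizes used by the tests and the acceptance script
  (200-family benchmark, 1,000-sequence self-search, a few hundred
  oracle pairs) are the package's standard desk-scale protocol; the
  pipeline itself has no size limits beyond memory.

## Known limitations

- No E-values or bit scores; the only hit criterion is identity.
- Greedy chaining can pick a locally best HSP that excludes a better
  overall chain; this is the documented behaviour, not a bug.
- The banded bridge aligner is exact only while the optimal path stays in
  band; highly indel-dense regions wider than the band may be scored
  sub-optimally.
- Single-threaded by design; determinism is part of the contract.
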