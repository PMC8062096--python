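# Methods

## Model and assumptions

The package treats a local-alignment search result as a set of
(query, subject) high-scoring pairs, each with a raw score S that is a
property of the two sequences and the scoring system alone. The expect
value attached to an HSP is a property of the *search*: under
Karlin–Altschul statistics, E = K·m′·n′·e^(−λS), where the effective
lengths m′ = m − l and n′ = n − N·l correct for the edge effect through
the length adjustment l. Everything the package does rests on two facts:

1. raw scores do not change when the database grows or is partitioned;
2. the database enters E only through its size (n, N) — via l and n′ in
   the Karlin–Altschul family, and via a multiplicative database scale
   factor in the Spouge finite-size-correction family.

Hence a result computed against part of a database can be *recalibrated*
to the whole: re-solve l and recompute E from S (Karlin–Altschul:
`blastn`, `tblastx`), or multiply E by n_total/n_part (Spouge: `blastp`,
`blastx`, `tblastn` — the finite-size "area" term depends only on the
query and the scoring system and cancels in the ratio, so the Gumbel
machinery behind it never needs to be evaluated). The additive form
E_total = E_part + K·e^(−λS)·(D_total − D_part) is also provided and
cross-tested against recomputation; recomputation is the default path.

The merge of per-part results assumes the parts are disjoint. A subject
appearing in two parts is kept once, with its better e-value, and a
warning is emitted; summing would double-count under statistics that
assume disjointness.

## Numerical choices

**Length-adjustment solver.** l is defined as the largest integer with
l ≤ f(l), f(l) = (α/λ)·ln(K(m−l)(n−N·l)) + β; since f is decreasing on
its domain this is the floor of the real fixed point. The implementation
runs a clamped fixed-point iteration (at most 20 steps, stopping when
successive iterates differ by < 1) and then pins the exact integer with a
saturation walk on the defining inequality, so agreement with the
exhaustive integer-scan oracle in the test suite is structural, not a
property of convergence luck. Clamps keep m − l ≥ 1 and n − N·l ≥ 1; a
single-residue query therefore gets l = 0 with m′ = 1. Empty databases
and other nonpositive sizes raise a domain error naming the violated
bound.

**Log-space e-values.** E-values are stored as natural logarithms and all
corrections operate on logs (the additive Karlin–Altschul form uses
log-sum-exp). Linear values appear only at serialization, where the
decimal mantissa/exponent pair is derived from log₁₀E directly — never
through a linear double — so documents faithfully carry values far below
both the double-precision floor and the e⁻¹⁸⁰ level at which standard
BLAST text output collapses to 0.0. Serialization uses 13 significant
digits; a round trip perturbs log E by < 10⁻¹², well inside every
tolerance used downstream.

**Zero-rounding guard.** An input e-value parsed as a literal 0.0 is
flagged: its magnitude is unknown, and rescaling it would silently keep
it at zero. Rescaling such a value raises an error; the recalibration
path instead regenerates it from its raw score against the part's own
search space and then applies the correction. The package's own writer
never produces 0.0 (flagged inputs that were never corrected round-trip
as "0.0" to preserve the flag).

**Ranking.** Hits are ordered by ascending e-value, ties broken by
descending raw score and then lexicographic subject id. E-values are
compared at a quantization of 10⁻⁶ in log space — far below printed
precision — so hits of equal significance computed along different
arithmetic routes (e.g. different parts of a merge) rank by the
deterministic tie-breaks rather than by floating-point round-off.

**Retention.** Merged results keep 2 × `max_target_seqs` hits, both in
storage and at merge time; a writer flag emits only `max_target_seqs` for
NCBI-compatible output. Because each truncated part can contribute
candidates another part's truncation would have hidden, the doubled pool
preserves every hit that a whole-database search would have ranked inside
`max_target_seqs`. Multi-way merges recalibrate every part against the
same union database and combine them in one k-way pass, which makes the
operation associative and commutative up to the truncation boundary.

**Growth percentages.** Reported database-growth percentages are
truncated (not rounded) to one decimal, the convention that matches how
such timelines are customarily printed; e.g. growth from a 44.5%-sized to
a 62.7%-sized snapshot reports as 40.8%.

## Parameter provenance

λ, K and H travel inside each result's own statistics block (the XML
dialect serializes them; the commented tabular dialect carries them in a
`# Statistics:` line). α and β are not serialized by BLAST and come from
a bundled tab-separated table keyed by (program, matrix or match/mismatch,
gap open, gap extend), transcribed from NCBI's published parameter tables
for the common scoring schemes; a user table can override it. For a
scoring scheme absent from the table the ungapped convention α = λ/H,
β = 0 is applied with a warning — adequate for ungapped statistics,
approximate for gapped ones, which is why the table should be extended
rather than relied on through the fallback for production scoring
schemes.

## Incremental orchestration

The record store is an embedded SQLite file whose primary key
(query-set digest, database id, program, parameter digest) enforces a
most-recent-only policy: storage is O(1) per key however often the
database grows. Query-set identity is an order-insensitive digest of the
(id, uppercased sequence) pairs, so a reformatted FASTA still matches;
changed search parameters are a different key by construction. The
database id is the stable lineage name (e.g. "nt"); the record separately
stores the snapshot (volume list and sizes) seen at search time, and
growth is detected by filename-list difference against it — not by
content-diffing volumes. Volume or size loss raises a shrinkage error,
and the orchestrator falls back to a full re-search with a warning. The
delta database is expressed as a standard BLAST alias file (.nal/.pal
with a DBLIST line), byte-stable for identical input.

The search itself is behind an executor contract —
`executor(queries, db_profile, program, params) -> XML` — satisfied by
the deterministic mock used throughout the tests and by any adapter that
shells out to the BLAST+ binaries.

The residue-balanced query partitioner shuffles queries by seed and
assigns each to the currently lightest of k partitions, bounding the
spread of per-partition residue totals by one maximum query length —
markedly better than count-balanced splitting under heavy-tailed query
length distributions.

## What the synthetic scenarios do and do not show

The generator builds database timelines (snapshots strictly nested by
volume list) and spatial partitions (pairwise disjoint volumes), with a
score model in which whether a (query, subject) pair hits, and at what
raw score, is a pure seeded hash of the two identifiers. This
partition-invariance mirrors the essential property of a real aligner —
alignment scores do not depend on what else is in the database — and is
what makes split-vs-whole comparisons meaningful. E-values and statistics
blocks in generated files are computed with the brute-force oracle
formulas (exhaustive integer scan for l, direct log-space evaluation),
independent of the solver and correction code they are used to test.

Deliberately not emulated:

* the seed-and-extend search heuristic, including the first-versus-best
  `max_target_seqs` bias of real BLAST. The suite demonstrates the
  *mechanism* by which merging over parts enlarges the candidate pool,
  but cannot reproduce any particular missed-hit rate of the real
  heuristic;
* expect-threshold filtering. The mock reports every score-model hit
  regardless of significance, so part and whole searches see identical
  hit sets and the correction mathematics is measured in isolation. Real
  per-part searches with an e-value cutoff can retain borderline hits a
  whole-database search would drop; merged output is then a superset near
  the threshold;
* biologically realistic sequences and alignments. Alignment strings are
  schematic; no operation consumes them.

Passing the fidelity suites therefore shows that the correction and merge
mathematics is exact under the stated assumptions, not that any
particular biological analysis is reproduced.

## Problem sizes

Default suite scales: scenario databases of tens of subjects across 2–7
volumes (≤ ~10⁵ residues), 3 queries per scenario, ~60 randomized
scenarios in the fidelity sweep; 1000 random instances in the
solver/oracle equivalence check; 200 random results in the round-trip
sweep. These sizes exercise every code path — including length
adjustments of the same order as real searches — while keeping the whole
suite in the single-digit seconds on one CPU. The statistics are
size-free: nothing in the correction mathematics changes character at
nt/nr scale beyond the magnitudes of n and D, which the arithmetic
handles in log space and arbitrary-precision integers respectively.

## Known limitations

* Spouge-family recalibration relies on the ratio form and therefore on
  the part result carrying a correct actual database length in its
  statistics block; results stripped of their statistics cannot be
  rescaled (the bare 12-column tabular format is such an input — parse
  succeeds, correction refuses).
* Karlin–Altschul recalibration needs raw scores; tabular inputs written
  without the score column are rejected on that path with a capability
  error.
* α/β coverage of the bundled parameter table is intentionally small;
  unknown gapped schemes fall back to the ungapped convention with a
  warning rather than failing.
* The record store identifies "the same query set" by content digest;
  queries that differ only in their identifiers hash differently even if
  the sequences match.
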