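# Methods

## Scope and model

`rmdefrag` post-processes RepeatMasker `.out` annotations. Its unit of
interest is the *copy* — one biological insertion of a transposable element —
reconstructed from the alignment *hits* that RepeatMasker reports. The
reconstruction is deliberately conservative: fragments are only merged when
their geometry is compatible with a single insertion, so very old copies
shattered by many subsequent insertions may stay split, and an inverted
segment of a copy is always reported as a separate copy (merging across
strands would hide real rearrangements). Both behaviours over-estimate copy
number rather than silently joining unrelated insertions.

## Merging rules and their parameters

Fragments of one family on one query merge pairwise when (1) strands match,
(2) the furthest extremities span `< 2·L_ref` and (3) starts and ends are
strictly ordered (containment never merges; exact duplicates never merge).
Coordinates are 1-based inclusive everywhere and span lengths are
`end − start + 1`.

* The distance bound uses a strict `<`; the alternative `--insert s` rule on
  the inter-fragment gap uses `≤ s` (so `--insert 0` merges only abutting
  fragments). The boundary cases are pinned in the test suite.
* `L_ref` during chaining is always the reference length of the fragment
  being added — for LTR families each portion chains against its own
  portion length, since portions are merged before structural assembly.
* A fragment whose element has no reference length (possible only with a
  user-restricted `.length` table) is never merged and is reported as a
  single-fragment copy.

Chaining is greedy in ascending `q_begin`. An *ambiguity* is a fragment
acceptable to ≥ 2 open chains. Candidates are ordered by separation
(`max(0, frag.start − chain.end − 1)`), ties broken toward the chain ending
rightmost; solution 0 is therefore "merge closest hits". Block-ID agreement
(the last numeric `.out` column) short-circuits every resolution mode when
exactly one candidate shares the focal fragment's ID. The default and
dry-run modes take solution 0; choice mode consults an interactive prompt or
a scripted answers file (one index per ambiguity, `len(candidates)` meaning
"leave the fragment alone"), which keeps tests non-interactive. Because the
chain grows as soon as a choice is made, one answer can cascade into later
unambiguous merges automatically.

A small exhaustive oracle in the tests enumerates every partition of a unit
into valid chains and selects the lexicographically smallest sequence of
merge distances; on units of ≤ 8 fragments the greedy path must reproduce
it exactly.

## LTR-retrotransposon assembly

Within a family unit, two LTR fragments separated by a compatible
(same-strand) internal fragment are not merged, and vice versa — the blocker
test requires the blocking fragment to lie strictly inside the candidate
gap. After chaining, portion copies are joined structurally: an LTR copy can
flank an internal copy when strands match and the gap between them is
`< L_LTR / 2` (strict; the gap may be negative for slight overlaps). Full
`LTR-I-LTR` triples are formed first, each internal copy taking its nearest
eligible LTR on each side; remaining internal copies take their nearest
remaining LTR to form `LTR-I` / `I-LTR`; leftover LTR copies are solo-LTRs
and leftover internal copies are reported as internal-only. Structure names
follow query order, not element orientation.

## Quality metrics

Per copy, `%_Div`, `%_Del` and `%_Ins` are fragment means weighted by
fragment query span. The consensus-view length is the sum of aligned
consensus spans (`r_end − r_begin + 1`), and `%_of_Ref` divides it by a
structure-dependent denominator fixed at assembly time: the element's own
length (plain and internal-only copies), `L_LTR` (solo-LTRs, so a
full-length solo-LTR scores 1.00), `L_I + L_LTR` (partial elements) or
`L_I + ΣL_LTR` over both flanks (full elements). Ratios above 1 (insertions
relative to the consensus) are reported as-is. When a denominator is
unavailable the ratio prints `NA`.

`--strict` keeps copies with consensus-view length strictly greater than
80 bp and weighted divergence strictly below 20 % — the size and identity
parts of the 80-80-80 similarity rule. It filters assembled copies, not raw
hits, because both metrics are only meaningful after merging.

## Reference lengths

Each hit implies its consensus length (`r_end + r_left`); per element the
modal implied value is used, breaking frequency ties toward the larger
length (multiple consensus versions of one element favour the most complete
one). A user `.length` file both overrides these values and restricts the
run: elements absent from it are excluded from assembly and reporting. An
LTR family missing either portion's length reports `No_ref_available` in
the copy-number table.

## Name dictionary

LTR/internal consensus names are paired by stem: role tokens `LTR`, `int`
(attached directly or by `-`/`_`) and separator-attached `I` are stripped
repeatedly from either end, separators normalise to one symbol, and a name
carrying `LTR` only internally (e.g. `DMLTR5`) counts as an LTR with the
token excised. A directly-attached single `I` is deliberately *not* a role
token — family names like `Idefix` would otherwise be mutilated. Standard
mode pairs identical stems with internal↔LTR roles. Fuzzy mode runs three
passes over still-unmatched LTR- or plain-role names — stems differing by
one letter, one digit, then any two characters (edit distance ≤ 2, via
edlib) — attaching each to its closest internal stem; an exact tie is
logged and left unmatched, since the emitted dictionary is designed to be
hand-edited and re-read anyway (one-sided lines carry an empty partner
field for that purpose). Names are sorted before pairing, so the dictionary
is independent of file traversal order.

## Quantification

`Total_Bp` is the union of the fragment query intervals of an element's
copies — each genomic base counts once per element — and `Cover` divides it
by the summed query lengths of the file (lengths recovered from
`q_end + q_left`, asserted consistent per query). The `Copies` column counts
all reconstructed copies *including* solo-LTRs, with `Solo_LTR` the subset
count; the alternative reading (copies excluding solos) is not used because
the column is described as a total. Category rollups sum their element
rows, so the all-TE coverage equals the sum of category coverages by
construction. Simple repeats, low-complexity regions, satellites and
structural RNAs are parsed but never assembled; they appear only in the
global summary rows, as do Unknown/Unspecified hits unless `--unknown`
promotes them to first-class elements.

## Synthetic data

The generator emits `.out` text (and optionally FASTA with the element
sequences planted at the annotated positions) for five fixed fragmentation
scenarios and for random genomes. Scenario coordinates are chosen so each
geometry exercises one rule exactly: the full-length element fixtures sit
at `%_of_Ref = 1.00`, the deletion fixture spans well under `2·L_ref`, the
solo-LTR fixture puts the lone LTR far beyond `L_LTR/2` of any internal
copy, and the copia fixture reproduces a published full-length insertion
span on chr2L (3,073,087–3,078,231, 5,145 bp). Random genomes default to
100 insertions with divergences uniform in 0–15 %, a 35 % share of LTR
elements, 20 % 5′-truncation of plain elements, and spacing of at least
twice the longest consensus plus jitter — the "well-separated" regime in
which exact truth recovery is required. Divergence ranges are configurable
precisely so strict-filter tests can straddle the 20 % boundary. The
generator does not emulate nested or overlapping random insertions,
sequencing-gap fragmentation, or realistic alignment scores; passing tests
therefore demonstrate correctness of the merging logic under its stated
geometric conditions, not performance on arbitrarily pathological real
annotations (the fixed scenarios cover the canonical pathological cases).

## Problem sizes and determinism

Tests and the acceptance script use fixtures of 3–6 hits for the scenario
checks, ≤ 8 fragments for oracle equivalence, and 100-insertion genomes
(~1.5 Mb implied query) for recovery and filter statistics; these sizes
characterise the behaviour fully while keeping runs fast. All randomness is
seeded (the acceptance script derives every stream from `--seed`), output
formatting is fixed at two decimals, and rows have total sort orders, so
reruns are byte-identical.

## Known limitations

* Name-based dictionary pairing only; truly dissimilar LTR/internal names
  (the `DMLTR5`/`HMSBEAGLE_I` kind) require the documented hand edit.
* No reconstruction of insertion chronology for nested elements, no
  TSD/poly(A) detection, and no age estimation — the outputs carry the
  columns (`%_Div`, `%_of_Ref`, positions) such analyses start from.
* The structural-assembly distance bound is not re-checked against the
  combined `2·(L_I + 2·L_LTR)` span after joining portions; the per-portion
  bounds and the `L_LTR/2` pairing rule already constrain the geometry.
* Copy lines in `*.transposons.csv`/`*.ltr.csv` carry the summed fragment
  score in the fragment lines only; the copy header line's first column is
  the `###`-prefixed block-ID chain.
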