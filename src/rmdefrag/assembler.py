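"""Merging RepeatMasker hits into transposable-element copies.

A single TE insertion is frequently reported as several hits: the library
splits LTR-retrotransposons into LTR and internal consensi, and large
deletions or nested insertions of other elements break one copy into
collinear fragments.  This module reverses that fragmentation.

Two hits of one family on one query are fragments of the same copy when

1. they lie on the same strand;
2. their furthest extremities span less than twice the reference element
   length (or, with the *insert* option, the sequence between their
   closest extremities is at most the given size); and
3. the second fragment starts and ends strictly after the first starts
   and ends — overlap is allowed, containment is not.

Chaining is greedy left-to-right on the query.  When more than one open
chain can accept a fragment the situation is ambiguous: solution 0 is
always the nearest chain, RepeatMasker block IDs override when they
resolve the case unequivocally, and callers may supply their own choices.

Within an LTR family the LTR and internal portions are chained
separately (a fragment of the other portion sitting in the gap blocks a
merge), then structural assembly pairs LTR copies with internal copies
that are on the same strand and separated by less than half the LTR
length — full LTR-I-LTR elements first, then partial LTR-I / I-LTR, and
whatever LTR copies remain are solo-LTRs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

from .dictionary import ElementDictionary, Family
from .lengths import LengthTable, compute_length_table
from .rmout import RMHit, QueryInfo

logger = logging.getLogger(__name__)

__all__ = [
    "SINGLE", "MERGED", "LTR_I_LTR", "LTR_I", "I_LTR", "SOLO_LTR",
    "INTERNAL_ONLY",
    "TECopy", "AmbiguityRecord", "WorkUnit", "AssemblyOptions",
    "AssemblyResult", "group_hits", "mergeable", "resolve_ambiguity",
    "assemble_copies", "assemble_ltr_elements", "strict_filter",
    "assemble_genome",
]

# structural labels
SINGLE = "single"
MERGED = "merged"
LTR_I_LTR = "LTR-I-LTR"
LTR_I = "LTR-I"
I_LTR = "I-LTR"
SOLO_LTR = "solo-LTR"
INTERNAL_ONLY = "internal-only"


@dataclass
class TECopy:
    """An assembled TE copy: ordered fragments plus structural metadata.

    ``ref_length`` is the denominator for the %_of_Ref quality ratio,
    fixed at assembly time: the element's own reference length for plain
    copies, the LTR length for solo-LTRs, and internal + one/two LTR
    lengths for partial/full LTR-retrotransposons.  ``None`` when no
    reference length is available.
    """

    fragments: list[RMHit]
    element: str
    class_family: str
    structure: str
    ref_length: int | None = None

    @property
    def query(self) -> str:
        return self.fragments[0].query

    @property
    def start(self) -> int:
        return self.fragments[0].q_begin

    @property
    def end(self) -> int:
        return max(f.q_end for f in self.fragments)

    @property
    def strand(self) -> str:
        return self.fragments[0].strand

    @property
    def num_assembled(self) -> int:
        return len(self.fragments)

    @property
    def id_chain(self) -> str:
        return "/".join(str(f.block_id) for f in self.fragments)

    @property
    def sw_score(self) -> int:
        return sum(f.sw_score for f in self.fragments)

    @property
    def consensus_view_length(self) -> int:
        """Copy length seen from the consensus: sum of aligned consensus spans."""
        return sum(f.r_span for f in self.fragments)

    def _weighted(self, attr: str) -> float:
        total = sum(f.q_span for f in self.fragments)
        return sum(getattr(f, attr) * f.q_span for f in self.fragments) / total

    @property
    def pct_div(self) -> float:
        """Mean divergence of the fragments, weighted by query-span size."""
        return self._weighted("pct_div")

    @property
    def pct_del(self) -> float:
        return self._weighted("pct_del")

    @property
    def pct_ins(self) -> float:
        return self._weighted("pct_ins")

    @property
    def pct_of_ref(self) -> float | None:
        if self.ref_length is None or self.ref_length <= 0:
            return None
        return self.consensus_view_length / self.ref_length

    @property
    def category(self) -> str:
        return self.class_family.split("/", 1)[0]


@dataclass
class _Chain:
    frags: list[RMHit]

    @property
    def start(self) -> int:
        return self.frags[0].q_begin

    @property
    def end(self) -> int:
        return max(f.q_end for f in self.frags)

    @property
    def strand(self) -> str:
        return self.frags[0].strand

    def block_ids(self) -> set[int]:
        return {f.block_id for f in self.frags}


@dataclass
class AmbiguityRecord:
    """A fragment that more than one open chain could accept.

    ``candidates`` are ordered by proximity: solution 0 merges the
    closest hits together.  The extra, implicit last solution is "leave
    the fragment alone" (index ``len(candidates)``).
    """

    query: str
    unit: str
    focal: RMHit
    candidates: list[_Chain]
    distances: list[int]
    resolution: str = "default0"
    chosen: int | None = 0

    def describe(self) -> str:
        opts = "; ".join(
            f"solution {i}: chain ending at {c.end} (gap {d} bp)"
            for i, (c, d) in enumerate(zip(self.candidates, self.distances)))
        opts += f"; solution {len(self.candidates)}: leave fragment alone"
        return (f"{self.query}:{self.focal.q_begin}-{self.focal.q_end} "
                f"{self.focal.element} — {opts} -> {self.resolution}"
                f" (solution {self.chosen if self.chosen is not None else len(self.candidates)})")


@dataclass
class WorkUnit:
    """All hits of one family unit on one query, sorted by position."""

    query: str
    family_key: str
    hits: list[RMHit]
    family: Family | None = None  # set for dictionary LTR families

    @property
    def is_ltr_family(self) -> bool:
        return self.family is not None


@dataclass
class AssemblyOptions:
    insert: int | None = None
    strict: bool = False
    mode: str = "default"  # "default" | "dry_run" | "choice"
    answers: Sequence[int] | None = None
    chooser: Callable[[AmbiguityRecord], int] | None = None
    unknown: bool = False


@dataclass
class AssemblyResult:
    copies: list[TECopy]
    records: list[AmbiguityRecord]
    hits: list[RMHit]
    queries: dict[str, QueryInfo]
    assembled_hits: list[RMHit]
    skipped_hits: list[RMHit]
    lengths: LengthTable
    unfiltered_copies: list[TECopy] = field(default_factory=list)
    options: AssemblyOptions = field(default_factory=AssemblyOptions)


def group_hits(hits: Iterable[RMHit], dictionary: ElementDictionary,
               lengths: LengthTable | None = None, unknown: bool = False,
               ) -> tuple[list[WorkUnit], list[RMHit]]:
    """Partition hits into per-(query, family unit) work units.

    The LTR and internal portions of one dictionary family form a single
    unit.  Non-TE classes (simple repeats, low complexity, satellites,
    structural RNAs) are never assembled; Unknown/Unspecified classes
    join only when *unknown* is set.  With a user-supplied length table,
    elements absent from it are excluded altogether.  Returns the units
    (sorted by query then family key) and the excluded hits.
    """
    units: dict[tuple[str, str], WorkUnit] = {}
    skipped: list[RMHit] = []
    for h in hits:
        if not (h.is_te or (unknown and h.is_unknown)):
            skipped.append(h)
            continue
        if lengths is not None and lengths.restrict and h.element not in lengths:
            skipped.append(h)
            continue
        portion = dictionary.portion_of(h.element)
        if portion is not None:
            key = portion[0]
            family = dictionary.families[key]
        else:
            key, family = h.element, None
        unit = units.get((h.query, key))
        if unit is None:
            unit = units[(h.query, key)] = WorkUnit(h.query, key, [], family)
        unit.hits.append(h)
    for unit in units.values():
        unit.hits.sort(key=lambda h: (h.q_begin, h.q_end, h.line_no))
    ordered = [units[k] for k in sorted(units)]
    return ordered, skipped


def _separation(a, b) -> int:
    """Bases strictly between two spans (0 when adjacent or overlapping)."""
    return max(0, b.start - a.end - 1) if hasattr(b, "start") else 0


def mergeable(a, b: RMHit, ref_len: int | None, insert_opt: int | None = None,
              blockers: Sequence[RMHit] = ()) -> bool:
    """Can fragment *b* extend chain/fragment *a*?

    *a* exposes ``start``/``end``/``strand`` (a chain, a copy, or a hit
    via :func:`as_span`).  ``blockers`` are fragments of the other
    portion of an LTR family: a same-strand blocker lying inside the gap
    vetoes the merge, so an internal sequence keeps two LTRs apart and
    vice versa.
    """
    b_start, b_end = b.q_begin, b.q_end
    if a.strand != b.strand:
        return False
    # condition 3: strictly ordered starts and ends (overlap yes, nesting no)
    if not (b_start > a.start and b_end > a.end):
        return False
    if insert_opt is not None:
        gap = b_start - a.end - 1
        if gap > insert_opt:
            return False
    else:
        if ref_len is None:
            return False
        if max(a.end, b_end) - min(a.start, b_start) + 1 >= 2 * ref_len:
            return False
    for blk in blockers:
        if blk.strand == a.strand and blk.q_begin > a.end and blk.q_end < b_start:
            return False
    return True


def as_span(hit: RMHit) -> _Chain:
    """Adapt a lone hit to the chain interface used by :func:`mergeable`."""
    return _Chain([hit])


def resolve_ambiguity(rec: AmbiguityRecord, mode: str = "default",
                      answer: int | None = None) -> int | None:
    """Pick a solution for an ambiguous merge; returns a candidate index
    or ``None`` for "leave the fragment alone".

    Agreement of RepeatMasker block IDs short-circuits every mode: when
    exactly one candidate chain shares the focal fragment's block ID the
    two are merged without consulting the user.  Otherwise the default
    (and dry-run) policy takes solution 0, the nearest chain.
    """
    by_block = [i for i, c in enumerate(rec.candidates)
                if rec.focal.block_id in c.block_ids()]
    if len(by_block) == 1:
        rec.resolution = "block_id"
        rec.chosen = by_block[0]
        return by_block[0]
    if mode in ("default", "dry_run"):
        rec.resolution = "default0"
        rec.chosen = 0
        return 0
    if mode == "choice":
        if answer is None:
            raise ValueError("choice mode requires an answer")
        if not 0 <= answer <= len(rec.candidates):
            raise ValueError(
                f"answer {answer} out of range 0..{len(rec.candidates)}")
        if answer == len(rec.candidates):
            rec.resolution = "none"
            rec.chosen = None
            return None
        rec.resolution = "user_choice"
        rec.chosen = answer
        return answer
    raise ValueError(f"unknown mode {mode!r}")


def _chain_fragments(frags: Sequence[RMHit], ref_of: Callable[[RMHit], int | None],
                     options: AssemblyOptions, blockers: Sequence[RMHit],
                     records: list[AmbiguityRecord], unit_name: str,
                     answer_iter) -> list[_Chain]:
    chains: list[_Chain] = []
    for frag in frags:
        cands = [c for c in chains
                 if mergeable(c, frag, ref_of(frag), options.insert, blockers)]
        if ref_of(frag) is None and options.insert is None and not cands:
            logger.debug("no reference length for %s; fragment left unmerged",
                         frag.element)
        if not cands:
            chains.append(_Chain([frag]))
            continue
        if len(cands) == 1:
            cands[0].frags.append(frag)
            continue
        ordered = sorted(cands, key=lambda c: (_separation(c, as_span(frag)), -c.end))
        rec = AmbiguityRecord(frag.query, unit_name, frag, ordered,
                              [_separation(c, as_span(frag)) for c in ordered])
        if options.mode == "choice":
            if options.chooser is not None:
                answer = options.chooser(rec)
            else:
                try:
                    answer = next(answer_iter)
                except StopIteration:
                    raise ValueError("ran out of scripted answers for "
                                     "ambiguous merges") from None
        else:
            answer = None
        idx = resolve_ambiguity(rec, options.mode, answer)
        records.append(rec)
        if idx is None:
            chains.append(_Chain([frag]))
        else:
            ordered[idx].frags.append(frag)
    return chains


def _copy_from_chain(chain: _Chain, element: str, ref_length: int | None,
                     structure: str | None = None) -> TECopy:
    frags = sorted(chain.frags, key=lambda f: (f.q_begin, f.q_end))
    if structure is None:
        structure = SINGLE if len(frags) == 1 else MERGED
    return TECopy(frags, element, frags[0].class_family, structure, ref_length)


def assemble_copies(unit: WorkUnit, lengths: LengthTable,
                    options: AssemblyOptions | None = None,
                    records: list[AmbiguityRecord] | None = None,
                    answer_iter=None) -> list[TECopy]:
    """Assemble all copies of one work unit.

    Plain elements are chained directly.  For an LTR family the two
    portions are chained separately — each against its own portion's
    reference length, with the other portion's fragments acting as
    blockers — and then joined structurally by
    :func:`assemble_ltr_elements`.
    """
    options = options or AssemblyOptions()
    if records is None:
        records = []
    if answer_iter is None:
        answer_iter = iter(options.answers or ())

    def ref_of(frag: RMHit) -> int | None:
        return lengths.get(frag.element)

    if not unit.is_ltr_family:
        chains = _chain_fragments(unit.hits, ref_of, options, (), records,
                                  unit.family_key, answer_iter)
        return [_copy_from_chain(c, unit.family_key, ref_of(c.frags[0]))
                for c in chains]

    fam = unit.family
    ltr_frags = [h for h in unit.hits if h.element in fam.ltr_names]
    int_frags = [h for h in unit.hits if h.element in fam.internal_names]
    other = [h for h in unit.hits
             if h.element not in fam.ltr_names and h.element not in fam.internal_names]
    assert not other, "unit contains hits outside its family"
    ltr_chains = _chain_fragments(ltr_frags, ref_of, options, int_frags,
                                  records, unit.family_key, answer_iter)
    int_chains = _chain_fragments(int_frags, ref_of, options, ltr_frags,
                                  records, unit.family_key, answer_iter)
    ltr_copies = [_copy_from_chain(c, unit.family_key, ref_of(c.frags[0]), SOLO_LTR)
                  for c in ltr_chains]
    int_copies = [_copy_from_chain(c, unit.family_key, ref_of(c.frags[0]),
                                   INTERNAL_ONLY) for c in int_chains]
    return assemble_ltr_elements(ltr_copies, int_copies, lengths, fam)


def _ltr_ref(copy: TECopy, lengths: LengthTable) -> int | None:
    return lengths.get(copy.fragments[0].element)


def _pair_gap(left: TECopy, right: TECopy) -> int:
    return right.start - left.end - 1


def assemble_ltr_elements(ltr_copies: list[TECopy], internal_copies: list[TECopy],
                          lengths: LengthTable, family: Family) -> list[TECopy]:
    """Join portion copies of one family into structured elements.

    An LTR copy may flank an internal copy when both are on the same
    strand and the gap between them is less than half the LTR reference
    length.  Full LTR-I-LTR elements are built first; remaining copies
    form partial LTR-I / I-LTR elements; leftover LTR copies are
    solo-LTRs and leftover internal copies stay internal-only.
    """
    ltrs = sorted(ltr_copies, key=lambda c: (c.start, c.end))
    internals = sorted(internal_copies, key=lambda c: (c.start, c.end))
    used: set[int] = set()
    assembled: list[TECopy] = []
    int_done: set[int] = set()

    def flank_candidates(icopy: TECopy, side: str) -> list[tuple[int, int]]:
        out = []
        for j, ltr in enumerate(ltrs):
            if j in used or ltr.strand != icopy.strand:
                continue
            half = _ltr_ref(ltr, lengths)
            if half is None:
                continue
            if side == "left" and ltr.start < icopy.start:
                gap = _pair_gap(ltr, icopy)
            elif side == "right" and ltr.start > icopy.start:
                gap = _pair_gap(icopy, ltr)
            else:
                continue
            if gap < half / 2:
                out.append((max(0, gap), j))
        out.sort()
        return out

    def join(parts: list[TECopy], structure: str) -> TECopy:
        frags = sorted((f for p in parts for f in p.fragments),
                       key=lambda f: (f.q_begin, f.q_end))
        internal = next(p for p in parts if p.structure == INTERNAL_ONLY)
        int_ref = _ltr_ref(internal, lengths)
        ltr_refs = [_ltr_ref(p, lengths) for p in parts if p.structure == SOLO_LTR]
        ref = None
        if int_ref is not None and all(r is not None for r in ltr_refs):
            ref = int_ref + sum(ltr_refs)
        return TECopy(frags, family.name, internal.class_family, structure, ref)

    # pass 1: full-length LTR-I-LTR elements take priority
    for i, icopy in enumerate(internals):
        left = flank_candidates(icopy, "left")
        right = flank_candidates(icopy, "right")
        if left and right:
            lj, rj = left[0][1], right[0][1]
            used.update((lj, rj))
            int_done.add(i)
            assembled.append(join([ltrs[lj], icopy, ltrs[rj]], LTR_I_LTR))

    # pass 2: partial LTR-I / I-LTR elements from what remains
    for i, icopy in enumerate(internals):
        if i in int_done:
            continue
        left = flank_candidates(icopy, "left")
        right = flank_candidates(icopy, "right")
        best = None
        if left and (not right or left[0][0] <= right[0][0]):
            best = (left[0][1], LTR_I)
        elif right:
            best = (right[0][1], I_LTR)
        if best is not None:
            j, structure = best
            used.add(j)
            int_done.add(i)
            parts = [ltrs[j], icopy] if structure == LTR_I else [icopy, ltrs[j]]
            assembled.append(join(parts, structure))

    for i, icopy in enumerate(internals):
        if i not in int_done:
            assembled.append(icopy)
    for j, ltr in enumerate(ltrs):
        if j not in used:
            assembled.append(ltr)
    assembled.sort(key=lambda c: (c.start, c.end))
    return assembled


def strict_filter(copies: Iterable[TECopy]) -> list[TECopy]:
    """Keep copies satisfying the size/identity parts of the 80-80-80 rule:
    consensus-aligned size strictly greater than 80 bp and identity to the
    reference strictly greater than 80% (weighted divergence < 20)."""
    return [c for c in copies
            if c.consensus_view_length > 80 and c.pct_div < 20.0]


def assemble_genome(hits: Sequence[RMHit], queries: dict[str, QueryInfo],
                    dictionary: ElementDictionary,
                    lengths: LengthTable | None = None,
                    options: AssemblyOptions | None = None) -> AssemblyResult:
    """Run the full assembly over parsed hits.

    Computes the length table from the hits when none is given, groups
    hits into work units, chains and structurally assembles every unit,
    and applies the strict filter when requested.  ``result.copies`` is
    the reported set; ``result.unfiltered_copies`` always holds the
    pre-filter copies.
    """
    options = options or AssemblyOptions()
    if lengths is None:
        lengths = compute_length_table(hits)
    units, skipped = group_hits(hits, dictionary, lengths, options.unknown)
    records: list[AmbiguityRecord] = []
    answer_iter = iter(options.answers or ())
    copies: list[TECopy] = []
    for unit in units:
        copies.extend(assemble_copies(unit, lengths, options, records, answer_iter))
    copies.sort(key=lambda c: (c.query, c.start, c.end, c.element))
    assembled_hits = [f for c in copies for f in c.fragments]
    reported = strict_filter(copies) if options.strict else copies
    return AssemblyResult(
        copies=reported, records=records, hits=list(hits), queries=queries,
        assembled_hits=assembled_hits, skipped_hits=skipped,
        lengths=lengths, unfiltered_copies=copies, options=options)
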