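"""Copy metrics, family summaries and the five tab-separated output files.

For every input ``.out`` file the pipeline writes, next to it:

``*.copynumber.csv``
    per-element quantification (fragments, copies, solo-LTRs, base pairs,
    percent coverage) with per-class/family ``###`` summary rows,
    per-category ``######Type:`` rows (DNA, LINE, SINE, LTR, ...) and
    global rows for all TEs, satellites, low-complexity and simple
    repeats, and unknown repeats;
``*.transposons.csv`` / ``*.ltr.csv``
    every reconstructed copy of non-LTR / LTR elements.  A copy line
    starts with ``###`` followed by the slash-joined block IDs of its
    fragments; multi-fragment copies list their fragments underneath;
``*.elem_sorted.csv``
    the union of the two previous files sorted by genomic position;
``*.log.txt``
    the screen output: per-element hit/copy counts and every ambiguous
    merge with the solutions considered.

All percentages and ratios are printed with two decimals so reruns are
byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .assembler import (AssemblyResult, SOLO_LTR, TECopy)
from .lengths import LengthTable
from .rmout import RMHit, QueryInfo

__all__ = ["CopyMetrics", "FamilySummary", "copy_metrics", "family_summary",
           "write_outputs", "SummaryReport"]

NO_REF = "No_ref_available"
NA = "NA"

COPY_COLUMNS = ["Score", "%_Div", "%_Del", "%_Ins", "Query", "Beg", "End",
                "Length", "Strand", "Element", "Family", "R_Beg", "R_End",
                "R_Left", "ID", "Num_Assembled", "%_of_Ref"]

COPYNUMBER_COLUMNS = ["Family", "Element", "Length", "Fragments", "Copies",
                      "Solo_LTR", "Total_Bp", "Cover"]


@dataclass(frozen=True)
class CopyMetrics:
    pct_div: float
    pct_del: float
    pct_ins: float
    consensus_view_length: int
    pct_of_ref: float | None


def copy_metrics(copy: TECopy, lengths: LengthTable | None = None) -> CopyMetrics:
    """Size-weighted quality metrics of an assembled copy.

    Divergence, deletion and insertion percentages are the means of the
    fragment values weighted by fragment query-span.  ``pct_of_ref``
    relates the consensus-view length to the structure's reference
    denominator (fixed at assembly time); it is ``None`` when no
    reference length is available.
    """
    ref = copy.ref_length
    if ref is None and lengths is not None and len(copy.fragments) >= 1:
        ref = lengths.get(copy.fragments[0].element)
    pct = None if not ref else copy.consensus_view_length / ref
    return CopyMetrics(copy.pct_div, copy.pct_del, copy.pct_ins,
                       copy.consensus_view_length, pct)


@dataclass
class FamilySummary:
    family: str            # class/family string, e.g. "LTR/Gypsy"
    element: str
    length: int | None     # reference bp, None -> No_ref_available
    fragments: int
    copies: int
    solo_ltr: int | None   # None -> NA (non-LTR elements)
    total_bp: int
    cover: float           # percent of the query length


@dataclass
class SummaryReport:
    elements: list[FamilySummary]
    categories: list[FamilySummary]   # per TE category (DNA, LINE, SINE, LTR...)
    class_families: list[FamilySummary]
    all_tes: FamilySummary
    others: list[FamilySummary]       # satellites, simple repeats, ...


def _union_bp(intervals: Iterable[tuple[str, int, int]]) -> int:
    """Total bases covered by 1-based inclusive intervals, per query."""
    by_query: dict[str, list[tuple[int, int]]] = {}
    for q, s, e in intervals:
        by_query.setdefault(q, []).append((s, e))
    total = 0
    for spans in by_query.values():
        spans.sort()
        cur_s, cur_e = spans[0]
        for s, e in spans[1:]:
            if s > cur_e + 1:
                total += cur_e - cur_s + 1
                cur_s, cur_e = s, e
            else:
                cur_e = max(cur_e, e)
        total += cur_e - cur_s + 1
    return total


def _family_ref_length(key: str, result: AssemblyResult, dictionary) -> int | None:
    """Reference length for a copynumber row: the element's own length, or
    internal + 2*LTR for a dictionary family (None when a portion lacks one)."""
    lengths = result.lengths
    fam = dictionary.families.get(key) if dictionary is not None else None
    if fam is None:
        return lengths.get(key)
    int_lens = [lengths.get(n) for n in sorted(fam.internal_names)]
    ltr_lens = [lengths.get(n) for n in sorted(fam.ltr_names)]
    int_len = next((v for v in int_lens if v is not None), None)
    ltr_len = next((v for v in ltr_lens if v is not None), None)
    if int_len is None or ltr_len is None:
        return None
    return int_len + 2 * ltr_len


def family_summary(result: AssemblyResult, dictionary=None) -> SummaryReport:
    """Per-element rows plus class/family, category and global rollups.

    ``total_bp`` counts each genomic base once per element (union of the
    fragment intervals of its copies); coverage is relative to the summed
    length of the query sequences of the file.
    """
    total_query = sum(q.length for q in result.queries.values()) or 1

    def fam_key(hit: RMHit) -> tuple[str, str]:
        portion = dictionary.portion_of(hit.element) if dictionary else None
        if portion is not None:
            fam = dictionary.families[portion[0]]
            cf = next((h.class_family for h in result.hits
                       if h.element in fam.internal_names), hit.class_family)
            return portion[0], cf
        return hit.element, hit.class_family

    frag_counts: dict[tuple[str, str], int] = {}
    skipped_ids = {id(h) for h in result.skipped_hits}
    for h in result.hits:
        if id(h) in skipped_ids:
            continue
        key = fam_key(h)
        frag_counts[key] = frag_counts.get(key, 0) + 1

    by_elem: dict[tuple[str, str], list[TECopy]] = {}
    for c in result.copies:
        by_elem.setdefault((c.element, c.class_family), []).append(c)

    rows: list[FamilySummary] = []
    for key in sorted(set(frag_counts) | set(by_elem)):
        element, cf = key
        copies = by_elem.get(key, [])
        category = cf.split("/", 1)[0]
        is_ltr = category == "LTR"
        solo = sum(1 for c in copies if c.structure == SOLO_LTR) if is_ltr else None
        bp = _union_bp((f.query, f.q_begin, f.q_end)
                       for c in copies for f in c.fragments)
        rows.append(FamilySummary(
            family=cf, element=element,
            length=_family_ref_length(element, result, dictionary),
            fragments=frag_counts.get(key, sum(c.num_assembled for c in copies)),
            copies=len(copies), solo_ltr=solo,
            total_bp=bp, cover=100.0 * bp / total_query))

    def rollup(name: str, subset: list[FamilySummary], is_ltr: bool) -> FamilySummary:
        return FamilySummary(
            family=name, element=NA, length=None,
            fragments=sum(r.fragments for r in subset),
            copies=sum(r.copies for r in subset),
            solo_ltr=sum(r.solo_ltr or 0 for r in subset) if is_ltr else None,
            total_bp=sum(r.total_bp for r in subset),
            cover=sum(r.cover for r in subset))

    class_rows = []
    for cf in sorted({r.family for r in rows}):
        subset = [r for r in rows if r.family == cf]
        class_rows.append(rollup(cf, subset, cf.split("/", 1)[0] == "LTR"))

    cat_rows = []
    for cat in sorted({r.family.split("/", 1)[0] for r in rows}):
        subset = [r for r in rows if r.family.split("/", 1)[0] == cat]
        cat_rows.append(rollup(cat, subset, cat == "LTR"))

    all_tes = rollup("All_TEs", rows, True)

    others = []
    other_classes = ["Satellite", "Low_complexity", "Simple_repeat", "Unknown"]
    skipped = result.skipped_hits
    for cls in other_classes:
        if cls == "Unknown":
            sub = [h for h in skipped if h.is_unknown]
        else:
            sub = [h for h in skipped if h.category == cls]
        bp = _union_bp((h.query, h.q_begin, h.q_end) for h in sub)
        others.append(FamilySummary(
            family=cls, element=NA, length=None, fragments=len(sub),
            copies=0, solo_ltr=None, total_bp=bp,
            cover=100.0 * bp / total_query))
    return SummaryReport(rows, cat_rows, class_rows, all_tes, others)


# ---------------------------------------------------------------------------
# file writing

def _fmt_len(v: int | None) -> str:
    return NO_REF if v is None else str(v)


def _fmt_solo(v: int | None) -> str:
    return NA if v is None else str(v)


def _copynumber_line(r: FamilySummary, prefix: str = "") -> str:
    # rollup rows (Element == NA) have no single reference length
    length = NA if r.element == NA else _fmt_len(r.length)
    return "\t".join([
        prefix + r.family, r.element, length, str(r.fragments),
        str(r.copies), _fmt_solo(r.solo_ltr), str(r.total_bp),
        f"{r.cover:.2f}"])


def _copynumber_text(report: SummaryReport) -> str:
    lines = ["\t".join(COPYNUMBER_COLUMNS)]
    cats = sorted({r.family.split("/", 1)[0] for r in report.elements})
    for cat in cats:
        cat_cfs = sorted({r.family for r in report.elements
                          if r.family.split("/", 1)[0] == cat})
        for cf in cat_cfs:
            for r in sorted((x for x in report.elements if x.family == cf),
                            key=lambda x: x.element):
                lines.append(_copynumber_line(r))
            cf_row = next(x for x in report.class_families if x.family == cf)
            lines.append(_copynumber_line(cf_row, prefix="###"))
        cat_row = next(x for x in report.categories if x.family == cat)
        lines.append(_copynumber_line(cat_row, prefix="######Type:"))
    lines.append(_copynumber_line(report.all_tes, prefix="######Type:"))
    for r in report.others:
        lines.append(_copynumber_line(r, prefix="######Type:"))
    return "\n".join(lines) + "\n"


def _copy_block(copy: TECopy) -> list[str]:
    r_beg = min(f.r_begin for f in copy.fragments)
    last = max(copy.fragments, key=lambda f: f.r_end)
    ratio = copy.pct_of_ref
    head = "\t".join([
        "###" + copy.id_chain,
        f"{copy.pct_div:.2f}", f"{copy.pct_del:.2f}", f"{copy.pct_ins:.2f}",
        copy.query, str(copy.start), str(copy.end),
        str(copy.consensus_view_length), copy.strand, copy.element,
        copy.class_family, str(r_beg), str(last.r_end), str(last.r_left),
        copy.id_chain, str(copy.num_assembled),
        NA if ratio is None else f"{ratio:.2f}"])
    lines = [head]
    if copy.num_assembled > 1:
        for f in copy.fragments:
            lines.append("\t".join([
                str(f.sw_score), f"{f.pct_div:.2f}", f"{f.pct_del:.2f}",
                f"{f.pct_ins:.2f}", f.query, str(f.q_begin), str(f.q_end),
                str(f.r_span), f.strand, f.element, f.class_family,
                str(f.r_begin), str(f.r_end), str(f.r_left),
                str(f.block_id), "", ""]))
    return lines


def _copies_text(copies: Sequence[TECopy]) -> str:
    lines = ["\t".join(COPY_COLUMNS)]
    for c in copies:
        lines.extend(_copy_block(c))
    return "\n".join(lines) + "\n"


def _log_text(result: AssemblyResult, report: SummaryReport) -> str:
    lines = []
    lines.append(f"Parsed {len(result.hits)} hits on "
                 f"{len(result.queries)} query sequence(s)")
    lines.append(f"Assembled {len(result.unfiltered_copies)} copies from "
                 f"{len(result.assembled_hits)} TE hits "
                 f"({len(result.skipped_hits)} hits outside copy assembly)")
    if result.options.strict:
        lines.append(f"Strict 80-80 filter kept {len(result.copies)} copies")
    for r in sorted(report.elements, key=lambda x: (x.family, x.element)):
        solo = "" if r.solo_ltr is None else f", {r.solo_ltr} solo-LTR(s)"
        lines.append(f"Element {r.element} ({r.family}): {r.fragments} hits, "
                     f"{r.copies} copies{solo}")
    lines.append(f"Ambiguous situations: {len(result.records)}")
    for rec in result.records:
        lines.append("  " + rec.describe())
    return "\n".join(lines) + "\n"


def write_outputs(result: AssemblyResult, base_path: str | Path,
                  dictionary=None, dry_run: bool = False) -> dict[str, Path]:
    """Write the output files next to *base_path* (the input ``.out`` file).

    With *dry_run* only the log file is produced.  Returns the mapping
    from file kind to path.
    """
    base = Path(base_path)
    report = family_summary(result, dictionary)
    paths = {"log": base.with_name(base.name + ".log.txt")}
    paths["log"].write_text(_log_text(result, report))
    if dry_run:
        return paths
    ltr_copies = [c for c in result.copies if c.category == "LTR"]
    other_copies = [c for c in result.copies if c.category != "LTR"]
    ordered = sorted(result.copies, key=lambda c: (c.query, c.start, c.end))
    paths["copynumber"] = base.with_name(base.name + ".copynumber.csv")
    paths["transposons"] = base.with_name(base.name + ".transposons.csv")
    paths["ltr"] = base.with_name(base.name + ".ltr.csv")
    paths["elem_sorted"] = base.with_name(base.name + ".elem_sorted.csv")
    paths["copynumber"].write_text(_copynumber_text(report))
    paths["transposons"].write_text(_copies_text(other_copies))
    paths["ltr"].write_text(_copies_text(ltr_copies))
    paths["elem_sorted"].write_text(_copies_text(ordered))
    return paths
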