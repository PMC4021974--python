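"""Reading and writing RepeatMasker ``.out`` annotation files.

A ``.out`` file carries one whitespace-separated line per alignment ("hit")
between a repeat-library consensus and the query sequence, preceded by a
two-line column banner.  Coordinates are 1-based inclusive.  For hits on the
complementary strand the three consensus-position columns are printed in
reversed order, ``(left) end begin``; parsing normalises them so that
``r_begin <= r_end`` always holds.

The "left" columns — ``q_left`` and ``r_left`` — give the number of bases
remaining after the hit's end on the query and on the consensus
respectively, so ``q_end + q_left`` is the query length and
``r_end + r_left`` the consensus length.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "RMHit",
    "QueryInfo",
    "RMOutError",
    "parse_out_file",
    "parse_out_text",
    "write_out_file",
    "format_hits",
    "consensus_length_of_hit",
    "scan_directory",
]

FORWARD = "+"
COMPLEMENT = "C"

#: repeat classes that are never assembled into TE copies; they are only
#: counted in the global summary rows
NON_TE_CLASSES = ("Simple_repeat", "Low_complexity", "Satellite", "ARTEFACT",
                  "rRNA", "snRNA", "tRNA", "scRNA", "srpRNA", "RNA", "Other")

UNKNOWN_CLASSES = ("Unknown", "Unspecified")


class RMOutError(ValueError):
    """Malformed RepeatMasker annotation (message carries the line number)."""


@dataclass(frozen=True)
class RMHit:
    """One annotation line of a RepeatMasker ``.out`` file."""

    sw_score: int
    pct_div: float
    pct_del: float
    pct_ins: float
    query: str
    q_begin: int
    q_end: int
    q_left: int
    strand: str  # "+" or "C"
    element: str
    class_family: str
    r_begin: int
    r_end: int
    r_left: int
    block_id: int
    line_no: int = 0

    def __post_init__(self) -> None:
        if self.q_begin > self.q_end:
            raise RMOutError(
                f"line {self.line_no}: query begin {self.q_begin} > end {self.q_end}")
        if self.q_begin < 1:
            raise RMOutError(f"line {self.line_no}: query begin {self.q_begin} < 1")
        if self.r_begin > self.r_end:
            raise RMOutError(
                f"line {self.line_no}: consensus begin {self.r_begin} > end {self.r_end}")
        if self.q_left < 0 or self.r_left < 0:
            raise RMOutError(f"line {self.line_no}: negative 'left' value")
        for v in (self.pct_div, self.pct_del, self.pct_ins):
            if not 0.0 <= v <= 100.0:
                raise RMOutError(f"line {self.line_no}: percentage {v} outside [0,100]")
        if self.strand not in (FORWARD, COMPLEMENT):
            raise RMOutError(f"line {self.line_no}: bad strand {self.strand!r}")

    @property
    def q_span(self) -> int:
        """Length of the hit on the query, 1-based inclusive."""
        return self.q_end - self.q_begin + 1

    @property
    def r_span(self) -> int:
        """Length of the aligned region on the consensus."""
        return self.r_end - self.r_begin + 1

    @property
    def category(self) -> str:
        """Class prefix of ``class_family`` (text before the first '/')."""
        return self.class_family.split("/", 1)[0]

    @property
    def is_unknown(self) -> bool:
        return self.category in UNKNOWN_CLASSES

    @property
    def is_te(self) -> bool:
        """True for transposable-element classes eligible for copy assembly."""
        return self.category not in NON_TE_CLASSES and not self.is_unknown


@dataclass(frozen=True)
class QueryInfo:
    """A query sequence and its length, recovered from ``q_end + q_left``."""

    query: str
    length: int


def consensus_length_of_hit(hit: RMHit) -> int:
    """Full length of the consensus a hit aligns to (``r_end + r_left``)."""
    return hit.r_end + hit.r_left


_INT_RE = re.compile(r"^-?\d+$")


def _strip_parens(token: str, line_no: int) -> str:
    if token.startswith("(") and token.endswith(")"):
        return token[1:-1]
    return token


def _to_int(token: str, line_no: int, what: str) -> int:
    try:
        return int(token)
    except ValueError:
        raise RMOutError(f"line {line_no}: non-numeric {what} {token!r}") from None


def _to_float(token: str, line_no: int, what: str) -> float:
    try:
        return float(token)
    except ValueError:
        raise RMOutError(f"line {line_no}: non-numeric {what} {token!r}") from None


def parse_out_text(text: str, unknown_mode: bool = False,
                   ) -> tuple[list[RMHit], dict[str, QueryInfo]]:
    """Parse the content of a ``.out`` file.

    Header/banner lines (any line whose first token is not an integer
    score) are skipped, which tolerates the two-line column banner as well
    as blank lines.  Hits with class/family "Unknown" or "Unspecified" are
    always retained and flagged via :attr:`RMHit.is_unknown`; whether they
    take part in copy assembly is decided downstream (``unknown_mode`` is
    accepted here for interface symmetry and does not alter parsing).

    Returns the hits in file order plus a per-query length table built
    from ``q_end + q_left``; inconsistent lengths for one query raise
    :class:`RMOutError`.
    """
    del unknown_mode
    hits: list[RMHit] = []
    queries: dict[str, QueryInfo] = {}
    for line_no, raw in enumerate(text.splitlines(), start=1):
        tokens = raw.split()
        if not tokens or not _INT_RE.match(tokens[0]):
            continue  # banner, blank or ruler line
        if tokens[-1] == "*":  # overlap marker, ignored
            tokens = tokens[:-1]
        if len(tokens) != 15:
            raise RMOutError(
                f"line {line_no}: expected 15 columns (plus optional '*'), "
                f"got {len(tokens)}")
        strand = tokens[8]
        if strand not in (FORWARD, COMPLEMENT):
            raise RMOutError(f"line {line_no}: bad strand token {strand!r}")
        if strand == FORWARD:
            rb, re_, rl = tokens[11], tokens[12], _strip_parens(tokens[13], line_no)
        else:  # complement: (left) end begin
            rl, re_, rb = _strip_parens(tokens[11], line_no), tokens[12], tokens[13]
        # block ID: the last all-numeric column (robust to dialects that
        # shift it by one)
        if not _INT_RE.match(tokens[14]):
            raise RMOutError(f"line {line_no}: non-numeric block ID {tokens[14]!r}")
        hit = RMHit(
            sw_score=_to_int(tokens[0], line_no, "score"),
            pct_div=_to_float(tokens[1], line_no, "%div"),
            pct_del=_to_float(tokens[2], line_no, "%del"),
            pct_ins=_to_float(tokens[3], line_no, "%ins"),
            query=tokens[4],
            q_begin=_to_int(tokens[5], line_no, "query begin"),
            q_end=_to_int(tokens[6], line_no, "query end"),
            q_left=_to_int(_strip_parens(tokens[7], line_no), line_no, "query left"),
            strand=strand,
            element=tokens[9],
            class_family=tokens[10],
            r_begin=_to_int(rb, line_no, "consensus begin"),
            r_end=_to_int(re_, line_no, "consensus end"),
            r_left=_to_int(rl, line_no, "consensus left"),
            block_id=_to_int(tokens[14], line_no, "block ID"),
            line_no=line_no,
        )
        hits.append(hit)
        length = hit.q_end + hit.q_left
        known = queries.get(hit.query)
        if known is None:
            queries[hit.query] = QueryInfo(hit.query, length)
        elif known.length != length:
            raise RMOutError(
                f"line {line_no}: query {hit.query} implies length {length}, "
                f"earlier hits implied {known.length}")
    return hits, queries


def parse_out_file(path: str | Path, unknown_mode: bool = False,
                   ) -> tuple[list[RMHit], dict[str, QueryInfo]]:
    """Parse one RepeatMasker ``.out`` file.  See :func:`parse_out_text`."""
    path = Path(path)
    try:
        text = path.read_text()
    except OSError as exc:
        raise RMOutError(f"cannot read {path}: {exc}") from exc
    try:
        return parse_out_text(text, unknown_mode=unknown_mode)
    except RMOutError as exc:
        raise RMOutError(f"{path}: {exc}") from None


_HEADER = (
    "   SW  perc perc perc  query     position in query       matching"
    "    repeat            position in repeat\n"
    "score  div. del. ins.  sequence  begin  end      (left)  repeat"
    "      class/family  begin  end    (left)   ID\n"
    "\n"
)


def format_hit(hit: RMHit) -> str:
    """Render one hit as a ``.out`` annotation line."""
    if hit.strand == FORWARD:
        rcols = f"{hit.r_begin} {hit.r_end} ({hit.r_left})"
    else:
        rcols = f"({hit.r_left}) {hit.r_end} {hit.r_begin}"
    return (f"{hit.sw_score} {hit.pct_div:.1f} {hit.pct_del:.1f} {hit.pct_ins:.1f} "
            f"{hit.query} {hit.q_begin} {hit.q_end} ({hit.q_left}) {hit.strand} "
            f"{hit.element} {hit.class_family} {rcols} {hit.block_id}")


def format_hits(hits: Iterable[RMHit], banner: bool = True) -> str:
    """Render hits as the text of a ``.out`` file (with column banner)."""
    body = "\n".join(format_hit(h) for h in hits)
    text = (_HEADER if banner else "") + body
    return text + "\n" if body else text


def write_out_file(hits: Sequence[RMHit], path: str | Path) -> None:
    Path(path).write_text(format_hits(hits))


def renumber(hits: Sequence[RMHit]) -> list[RMHit]:
    """Return hits with ``line_no`` set to their 1-based position."""
    return [replace(h, line_no=i) for i, h in enumerate(hits, start=1)]


def scan_directory(path: str | Path) -> list[Path]:
    """All ``*.out`` files under *path*, recursively, in lexicographic order."""
    path = Path(path)
    if not path.is_dir():
        raise RMOutError(f"not a directory: {path}")
    return sorted(p for p in path.rglob("*.out") if p.is_file())
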