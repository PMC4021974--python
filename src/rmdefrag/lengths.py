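"""Per-element reference consensus lengths.

The merging distance bound and the ``%_of_Ref`` copy-quality ratio both
need the full length of each library consensus.  The ``.out`` file does
not state it directly, but every hit implies it (``r_end + r_left``).
Because several consensus versions of one element can coexist in a
library, the table keeps the *modal* implied length per element, breaking
frequency ties toward the larger value.

A user-supplied ``.length`` file overrides computation and additionally
restricts the analysis: elements absent from it are dropped entirely.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from .rmout import RMHit, consensus_length_of_hit

__all__ = ["LengthTable", "compute_length_table", "read_length_file",
           "write_length_file"]

COMPUTED = "computed"
USER_FILE = "user_file"


@dataclass
class LengthTable:
    lengths: dict[str, int] = field(default_factory=dict)
    provenance: str = COMPUTED

    def get(self, element: str) -> int | None:
        return self.lengths.get(element)

    @property
    def restrict(self) -> bool:
        """Whether elements absent from the table must be excluded."""
        return self.provenance == USER_FILE

    def __contains__(self, element: str) -> bool:
        return element in self.lengths

    def __len__(self) -> int:
        return len(self.lengths)


def compute_length_table(hits: Iterable[RMHit]) -> LengthTable:
    """Modal consensus length per element over all hits; ties -> larger."""
    counts: dict[str, Counter] = {}
    for h in hits:
        counts.setdefault(h.element, Counter())[consensus_length_of_hit(h)] += 1
    lengths = {}
    for element, ctr in counts.items():
        best = max(ctr.items(), key=lambda kv: (kv[1], kv[0]))
        lengths[element] = best[0]
    return LengthTable(lengths, COMPUTED)


def read_length_file(path: str | Path) -> LengthTable:
    lengths: dict[str, int] = {}
    for line_no, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        if not raw.strip() or raw.lstrip().startswith("#"):
            continue
        parts = raw.split()
        if len(parts) != 2:
            raise ValueError(f"{path}: line {line_no}: expected 'element length'")
        element, length_s = parts
        try:
            length = int(length_s)
        except ValueError:
            raise ValueError(
                f"{path}: line {line_no}: non-numeric length {length_s!r}") from None
        if length <= 0:
            raise ValueError(f"{path}: line {line_no}: non-positive length {length}")
        lengths[element] = length
    return LengthTable(lengths, USER_FILE)


def write_length_file(table: LengthTable, path: str | Path) -> None:
    lines = [f"{el}\t{bp}" for el, bp in sorted(table.lengths.items())]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
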