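"""Retrieving copy sequences (optionally with flanks) from the query FASTA.

Coordinates are 1-based inclusive throughout, matching the annotation.
Copies on the complementary strand are reverse-complemented by default so
the emitted sequence reads in element orientation, which is what
downstream alignment of copies against their consensus expects; pass
``orient=False`` to keep the genomic strand.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

from pyfaidx import Fasta

from .assembler import TECopy
from .rmout import COMPLEMENT

__all__ = ["extract_copy_sequence", "write_copy_fasta", "open_fasta"]

_COMP = str.maketrans("ACGTRYKMBVDHacgtrykmbvdh", "TGCAYRMKVBHDtgcayrmkvbhd")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def open_fasta(path: str | Path) -> Fasta:
    """Open an indexed FASTA; sequence names are the first whitespace-
    delimited token of each header."""
    return Fasta(str(path))


def extract_copy_sequence(fasta: Fasta, copy: TECopy, flanking: int = 0,
                          orient: bool = True) -> tuple[str, str]:
    """Return ``(header, sequence)`` for one copy.

    The sequence covers ``[start - flanking, end + flanking]`` clipped to
    the query bounds.  The header records query, 1-based span, strand,
    element and the copy's block-ID chain.
    """
    if flanking < 0:
        raise ValueError("flanking must be >= 0")
    if copy.query not in fasta:
        raise KeyError(f"query {copy.query!r} of copy {copy.element} "
                       f"{copy.start}-{copy.end} absent from FASTA")
    record = fasta[copy.query]
    qlen = len(record)
    if copy.end > qlen:
        raise ValueError(
            f"copy {copy.element} ends at {copy.end} but {copy.query} "
            f"is only {qlen} bp: FASTA does not match the annotation")
    lo = max(1, copy.start - flanking)
    hi = min(qlen, copy.end + flanking)
    seq = str(record[lo - 1:hi])
    if orient and copy.strand == COMPLEMENT:
        seq = _revcomp(seq)
    header = (f"{copy.query}:{copy.start}-{copy.end}({copy.strand}) "
              f"{copy.element} {copy.structure} ID={copy.id_chain}"
              + (f" flanking={flanking}" if flanking else ""))
    return header, seq


def write_copy_fasta(fasta: Fasta, copies: Iterable[TECopy], path: str | Path,
                     flanking: int = 0, orient: bool = True) -> int:
    """Write one FASTA record per copy (60-column wrapped); returns count."""
    n = 0
    with open(path, "w") as fh:
        for copy in copies:
            header, seq = extract_copy_sequence(fasta, copy, flanking, orient)
            fh.write(f">{header}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")
            n += 1
    return n
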