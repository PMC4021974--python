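"""Synthetic RepeatMasker inputs with known ground truth.

Real ``.out`` files fragment TE copies in a handful of recurring ways;
the named scenarios here reproduce each geometry with full control over
coordinates so the assembler's behaviour can be verified copy by copy:

``split_ltr``
    one full-length LTR-retrotransposon annotated as three hits
    (LTR, internal, LTR) because the library stores the two portions as
    separate consensi;
``deletions``
    one copy broken into three collinear same-strand fragments by two
    internal deletions (consensus coordinates jump across the gaps);
``nested``
    an LTR-retrotransposon interrupted by a reverse-orientation DNA
    transposon that itself carries an internal deletion — six hits, two
    biological copies;
``copia_full_length``
    a full LTR-I-LTR element placed at the published chr2L coordinates
    of a complete *copia* insertion (span 5,145 bp);
``solo_ltr``
    a lone full-length LTR far from any internal copy, plus the
    internal-only copy that proves the family exists in the query.

:func:`make_random_genome` plants many insertions with configurable
divergence, truncation and spacing; in the well-separated regime
(spacing at least twice the longest consensus) every planted copy must
be recovered exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .assembler import I_LTR, INTERNAL_ONLY, LTR_I, LTR_I_LTR, MERGED, SINGLE, SOLO_LTR
from .rmout import COMPLEMENT, FORWARD, RMHit, format_hits

__all__ = ["TruthCopy", "SyntheticData", "make_scenario", "make_random_genome",
           "SCENARIOS"]

SCENARIOS = ("split_ltr", "deletions", "nested", "copia_full_length", "solo_ltr")


@dataclass(frozen=True)
class TruthCopy:
    element: str           # family name for LTR families
    query: str
    start: int
    end: int
    strand: str
    structure: str
    n_fragments: int


@dataclass
class SyntheticData:
    hits: list[RMHit]
    out_text: str
    truth: list[TruthCopy]
    ref_lengths: dict[str, int]
    query_length: dict[str, int]
    fasta_text: str | None = None
    element_seqs: dict[str, str] = field(default_factory=dict)


def _mkhit(score, div, dele, ins, query, qb, qe, qlen, strand, element, cf,
           rb, re_, rlen, block_id):
    return RMHit(score, div, dele, ins, query, qb, qe, qlen - qe, strand,
                 element, cf, rb, re_, rlen - re_, block_id)


def _random_seq(rng, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])


_COMP = str.maketrans("ACGT", "TGCA")


def _build_fasta(query: str, qlen: int, placements, rng) -> str:
    """Random genome with element sequences planted at the hit positions.

    ``placements`` is an iterable of ``(start, end, strand, seq)`` where
    *seq* is the element-oriented sequence to plant.
    """
    genome = list(_random_seq(rng, qlen))
    for start, end, strand, seq in placements:
        if strand == COMPLEMENT:
            seq = seq.translate(_COMP)[::-1]
        assert len(seq) == end - start + 1
        genome[start - 1:end] = list(seq)
    body = "".join(genome)
    lines = [f">{query}"] + [body[i:i + 60] for i in range(0, len(body), 60)]
    return "\n".join(lines) + "\n"


def make_scenario(name: str, seed: int = 0, div: float = 5.0,
                  with_fasta: bool = True) -> SyntheticData:
    """Build one named fixture scenario (see module docstring)."""
    rng = np.random.default_rng(seed)
    if name == "split_ltr":
        q, qlen = "chr_sim", 20_000
        refs = {"TIRANT_LTR": 400, "TIRANT_I": 4000}
        hits = [
            _mkhit(2000, div, 1.0, 0.5, q, 5001, 5400, qlen, FORWARD,
                   "TIRANT_LTR", "LTR/Gypsy", 1, 400, 400, 1),
            _mkhit(9000, div, 1.0, 0.5, q, 5401, 9400, qlen, FORWARD,
                   "TIRANT_I", "LTR/Gypsy", 1, 4000, 4000, 1),
            _mkhit(2000, div, 1.0, 0.5, q, 9401, 9800, qlen, FORWARD,
                   "TIRANT_LTR", "LTR/Gypsy", 1, 400, 400, 1),
        ]
        truth = [TruthCopy("TIRANT", q, 5001, 9800, FORWARD, LTR_I_LTR, 3)]
    elif name == "deletions":
        q, qlen = "chr_sim", 10_000
        refs = {"HELENA": 1200}
        hits = [
            _mkhit(1800, div, 1.0, 0.5, q, 2001, 2400, qlen, FORWARD,
                   "HELENA", "LINE/Jockey", 1, 400, 1200, 2),
            _mkhit(1700, div, 1.0, 0.5, q, 2501, 2900, qlen, FORWARD,
                   "HELENA", "LINE/Jockey", 501, 900, 1200, 3),
            _mkhit(1600, div, 1.0, 0.5, q, 3001, 3300, qlen, FORWARD,
                   "HELENA", "LINE/Jockey", 901, 1200, 1200, 4),
        ]
        truth = [TruthCopy("HELENA", q, 2001, 3300, FORWARD, MERGED, 3)]
    elif name == "nested":
        q, qlen = "chr_sim", 30_000
        refs = {"QUASIMODO_LTR": 300, "QUASIMODO_I": 3000, "HOBO": 3016}
        hits = [
            _mkhit(1500, div, 1.0, 0.5, q, 1001, 1300, qlen, FORWARD,
                   "QUASIMODO_LTR", "LTR/Gypsy", 1, 300, 300, 5),
            _mkhit(4000, div, 1.0, 0.5, q, 1301, 2800, qlen, FORWARD,
                   "QUASIMODO_I", "LTR/Gypsy", 1, 1500, 3000, 5),
            _mkhit(3000, div, 1.0, 0.5, q, 2801, 4000, qlen, COMPLEMENT,
                   "HOBO", "DNA/hAT", 1817, 3016, 3016, 6),
            _mkhit(3500, div, 1.0, 0.5, q, 4101, 5700, qlen, COMPLEMENT,
                   "HOBO", "DNA/hAT", 1, 1600, 3016, 6),
            _mkhit(4000, div, 1.0, 0.5, q, 5701, 7200, qlen, FORWARD,
                   "QUASIMODO_I", "LTR/Gypsy", 1501, 3000, 3000, 5),
            _mkhit(1500, div, 1.0, 0.5, q, 7201, 7500, qlen, FORWARD,
                   "QUASIMODO_LTR", "LTR/Gypsy", 1, 300, 300, 5),
        ]
        truth = [
            TruthCopy("QUASIMODO", q, 1001, 7500, FORWARD, LTR_I_LTR, 4),
            TruthCopy("HOBO", q, 2801, 5700, COMPLEMENT, MERGED, 2),
        ]
    elif name == "copia_full_length":
        q, qlen = "chr2L", 23_011_544
        refs = {"COPIA_LTR": 276, "COPIA_I": 4593}
        hits = [
            _mkhit(2100, div, 0.5, 0.2, q, 3_073_087, 3_073_362, qlen, FORWARD,
                   "COPIA_LTR", "LTR/Copia", 1, 276, 276, 7),
            _mkhit(30000, div, 0.5, 0.2, q, 3_073_363, 3_077_955, qlen, FORWARD,
                   "COPIA_I", "LTR/Copia", 1, 4593, 4593, 7),
            _mkhit(2100, div, 0.5, 0.2, q, 3_077_956, 3_078_231, qlen, FORWARD,
                   "COPIA_LTR", "LTR/Copia", 1, 276, 276, 7),
        ]
        truth = [TruthCopy("COPIA", q, 3_073_087, 3_078_231, FORWARD,
                           LTR_I_LTR, 3)]
        with_fasta = False  # chromosome-scale query; no sequence emitted
    elif name == "solo_ltr":
        q, qlen = "chr_sim", 30_000
        refs = {"COPIA2_LTR": 400, "COPIA2_I": 4500}
        hits = [
            _mkhit(25000, div, 1.0, 0.5, q, 1001, 5500, qlen, FORWARD,
                   "COPIA2_I", "LTR/Copia", 1, 4500, 4500, 8),
            _mkhit(2500, div, 1.0, 0.5, q, 20_001, 20_400, qlen, FORWARD,
                   "COPIA2_LTR", "LTR/Copia", 1, 400, 400, 9),
        ]
        truth = [
            TruthCopy("COPIA2", q, 1001, 5500, FORWARD, INTERNAL_ONLY, 1),
            TruthCopy("COPIA2", q, 20_001, 20_400, FORWARD, SOLO_LTR, 1),
        ]
    else:
        raise ValueError(f"unknown scenario {name!r}; choose from {SCENARIOS}")

    data = SyntheticData(
        hits=hits, out_text=format_hits(hits), truth=truth, ref_lengths=refs,
        query_length={q: qlen})
    if with_fasta:
        seqs = {el: _random_seq(rng, n) for el, n in refs.items()}
        placements = [(h.q_begin, h.q_end, h.strand,
                       seqs[h.element][h.r_begin - 1:h.r_end]) for h in hits]
        data.fasta_text = _build_fasta(q, qlen, placements, rng)
        data.element_seqs = seqs
    return data


# default element menu for random genomes: a few fly-like families
PLAIN_ELEMENTS = [
    ("HOBO", "DNA/hAT", 3016),
    ("JOCKEY", "LINE/Jockey", 5020),
    ("HELENA", "LINE/Jockey", 1200),
    ("FW", "LINE/F", 4700),
]
LTR_FAMILIES = [
    ("TIRANT", 400, 4000),
    ("COPIA", 276, 4593),
]


def make_random_genome(n_insertions: int = 100, seed: int = 0,
                       spacing: int | None = None,
                       truncation_rate: float = 0.2,
                       ltr_fraction: float = 0.35,
                       div_range: tuple[float, float] = (0.0, 15.0),
                       with_fasta: bool = False,
                       query: str = "chr_sim") -> SyntheticData:
    """Plant *n_insertions* TE copies with known truth on one query.

    Plain elements give one hit each (possibly 5'-truncated at
    *truncation_rate*); LTR families give an adjacent LTR/internal/LTR
    triple.  The default spacing keeps consecutive insertions more than
    twice the longest consensus apart, the regime in which assembly must
    recover every planted copy exactly.  Deterministic for a given seed.
    """
    rng = np.random.default_rng(seed)
    refs: dict[str, int] = {el: n for el, _, n in PLAIN_ELEMENTS}
    for fam, ltr_len, int_len in LTR_FAMILIES:
        refs[f"{fam}_LTR"] = ltr_len
        refs[f"{fam}_I"] = int_len
    if spacing is None:
        spacing = 2 * max(refs.values()) + 200

    pending: list[tuple] = []  # (score,div,qb,qe,strand,elem,cf,rb,re,rlen,bid)
    truth: list[TruthCopy] = []
    pos = 1 + int(rng.integers(500, 1500))
    for i in range(n_insertions):
        strand = FORWARD if rng.random() < 0.5 else COMPLEMENT
        div = round(float(rng.uniform(*div_range)), 1)
        bid = i + 1
        if rng.random() < ltr_fraction:
            fam, ltr_len, int_len = LTR_FAMILIES[int(rng.integers(len(LTR_FAMILIES)))]
            cf = "LTR/Copia" if fam == "COPIA" else "LTR/Gypsy"
            spans = [(f"{fam}_LTR", 1, ltr_len), (f"{fam}_I", 1, int_len),
                     (f"{fam}_LTR", 1, ltr_len)]
            start = pos
            # portions are laid out in element order; the assembler only
            # requires same-strand collinearity, so strand C is fine too
            for el, rb, re_ in spans:
                qe = pos + (re_ - rb)
                pending.append((10 * (re_ - rb + 1) // 2, div, pos, qe, strand,
                                el, cf, rb, re_, refs[el], bid))
                pos = qe + 1
            truth.append(TruthCopy(fam, query, start, pos - 1, strand,
                                   LTR_I_LTR, 3))
        else:
            el, cf, ref_len = PLAIN_ELEMENTS[int(rng.integers(len(PLAIN_ELEMENTS)))]
            if rng.random() < truncation_rate:
                frac = float(rng.uniform(0.3, 0.9))
                rb = ref_len - int(ref_len * frac) + 1
            else:
                rb = 1
            re_ = ref_len
            qe = pos + (re_ - rb)
            pending.append((10 * (re_ - rb + 1) // 2, div, pos, qe, strand,
                            el, cf, rb, re_, ref_len, bid))
            truth.append(TruthCopy(el, query, pos, qe, strand, SINGLE, 1))
            pos = qe + 1
        pos += spacing + int(rng.integers(0, spacing // 4 + 1))

    qlen = pos + 1000
    hits = [_mkhit(sc, dv, 1.0, 0.5, query, qb, qe, qlen, st, el, cf, rb, re_,
                   rlen, bid)
            for sc, dv, qb, qe, st, el, cf, rb, re_, rlen, bid in pending]
    data = SyntheticData(
        hits=hits, out_text=format_hits(hits), truth=truth, ref_lengths=refs,
        query_length={query: qlen})
    if with_fasta:
        seqs = {el: _random_seq(rng, n) for el, n in refs.items()}
        placements = [(h.q_begin, h.q_end, h.strand,
                       seqs[h.element][h.r_begin - 1:h.r_end]) for h in hits]
        data.fasta_text = _build_fasta(query, qlen, placements, rng)
        data.element_seqs = seqs
    return data
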