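"""Pairing LTR and internal consensus names into LTR-retrotransposon families.

Repeat libraries annotate an LTR-retrotransposon as two consensi: the long
terminal repeat (often ``FOO_LTR``) and the internal portion (``FOO_I`` /
``FOO-int``).  Reconstructing full-length elements requires knowing which
LTR consensus belongs with which internal consensus.  Most pairs share a
name stem and differ only by the role token; the remainder (e.g. an LTR
called ``DMLTR5`` whose internal portion is ``HMSBEAGLE_I``) cannot be
paired by name and must be fixed by hand in the emitted dictionary file.

Fuzzy matching widens the net for LTR *variants*: several diverged LTR
consensi (``MER66A`` … ``MER66D``) sharing one internal consensus
(``MER66-int``).  Three successive passes pair still-unmatched stems that
differ by a single letter, a single digit, or any two characters (edit
distance <= 2); earlier passes win and one internal stem may collect
several LTR variants.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import edlib

logger = logging.getLogger(__name__)

__all__ = [
    "Family",
    "ElementDictionary",
    "stem_name",
    "build_dictionary",
    "write_dictionary",
    "read_dictionary",
]

ROLE_LTR = "ltr"
ROLE_INTERNAL = "internal"
ROLE_PLAIN = "plain"

# role tokens; single-letter "I" only counts when set off by a separator,
# otherwise names like "Idefix" would be mutilated
_SUFFIX = re.compile(r"^(?P<base>.+?)(?:[-_](?P<tok1>ltr|int|i)|(?P<tok2>ltr|int))$",
                     re.IGNORECASE)
_PREFIX = re.compile(r"^(?:(?P<tok1>ltr|int|i)[-_]|(?P<tok2>ltr|int))(?P<base>.+)$",
                     re.IGNORECASE)

_ROLE_OF_TOKEN = {"ltr": ROLE_LTR, "int": ROLE_INTERNAL, "i": ROLE_INTERNAL}


def _normalize(base: str) -> str:
    stem = re.sub(r"[-_]+", ".", base.lower()).strip(".")
    return stem


def stem_name(name: str) -> tuple[str, str]:
    """Split a consensus name into a normalized stem and a role.

    The role token (``LTR``, ``int`` or ``I``, case-insensitive, attached
    by '-', '_' or directly) is stripped from either end, repeatedly, so
    ``HERV1_I-int`` reduces to ``herv1``.  Separators are normalised to a
    single '.'.  A name carrying ``LTR`` only in its middle (``DMLTR5``)
    is still recognised as an LTR with the token excised.  Names with no
    token keep their full stem and role "plain".
    """
    if not name:
        raise ValueError("empty consensus name")
    base = name
    role = ROLE_PLAIN
    stripped = True
    while stripped:
        stripped = False
        for pat in (_SUFFIX, _PREFIX):
            m = pat.match(base)
            if not m:
                continue
            tok = (m.group("tok1") or m.group("tok2")).lower()
            new_role = _ROLE_OF_TOKEN[tok]
            if role == ROLE_PLAIN:
                role = new_role
            elif role != new_role:
                continue  # keep the outermost role, stop conflicting strips
            base = m.group("base")
            stripped = True
            break
    if role == ROLE_PLAIN:
        low = base.lower()
        if "ltr" in low:
            i = low.index("ltr")
            base = base[:i] + base[i + 3:]
            role = ROLE_LTR
    return _normalize(base), role


def _family_label(name: str) -> str:
    """The consensus name with its outermost role token removed, original
    case and separators preserved — used as the family's display name."""
    for pat in (_SUFFIX, _PREFIX):
        m = pat.match(name)
        if m:
            return m.group("base")
    return name


@dataclass
class Family:
    """One LTR-retrotransposon family: its internal and LTR consensus names."""

    name: str
    internal_names: set[str] = field(default_factory=set)
    ltr_names: set[str] = field(default_factory=set)


@dataclass
class ElementDictionary:
    """Mapping from family names to their internal/LTR consensus names."""

    families: dict[str, Family] = field(default_factory=dict)
    unmatched: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self._portion: dict[str, tuple[str, str]] = {}
        for fam in self.families.values():
            for n in fam.internal_names:
                self._register(n, fam.name, ROLE_INTERNAL)
            for n in fam.ltr_names:
                self._register(n, fam.name, ROLE_LTR)

    def _register(self, name: str, family: str, portion: str) -> None:
        prev = self._portion.get(name)
        if prev is not None and prev[0] != family:
            raise ValueError(
                f"consensus {name!r} assigned to two families: {prev[0]!r} and {family!r}")
        self._portion[name] = (family, portion)

    def add(self, family_name: str, internal: set[str], ltr: set[str]) -> Family:
        fam = self.families.setdefault(family_name, Family(family_name))
        for n in internal:
            fam.internal_names.add(n)
            self._register(n, family_name, ROLE_INTERNAL)
        for n in ltr:
            fam.ltr_names.add(n)
            self._register(n, family_name, ROLE_LTR)
        return fam

    def portion_of(self, element: str) -> tuple[str, str] | None:
        """(family name, "ltr"|"internal") for a paired consensus, else None."""
        return self._portion.get(element)

    def __len__(self) -> int:
        return len(self.families)


def _single_edit_kind(a: str, b: str) -> str | None:
    """Classify a distance-1 edit between stems: "letter", "digit" or "other"."""
    if len(a) < len(b):
        a, b = b, a
    if len(a) == len(b):
        diff = [(x, y) for x, y in zip(a, b) if x != y]
        if len(diff) != 1:
            return None
        chars = diff[0]
    else:  # len(a) == len(b) + 1: one deletion from a
        for i in range(len(b)):
            if a[i] != b[i]:
                if a[:i] + a[i + 1:] != b:
                    return None
                chars = (a[i],)
                break
        else:
            chars = (a[-1],)
    if all(c.isalpha() for c in chars):
        return "letter"
    if all(c.isdigit() for c in chars):
        return "digit"
    return "other"


def _edit_distance(a: str, b: str) -> int:
    return edlib.align(a, b, task="distance")["editDistance"]


def _pass_accepts(pass_no: int, a: str, b: str) -> bool:
    d = _edit_distance(a, b)
    if d == 0:
        return False  # identical stems are handled by the standard pass
    if pass_no == 2:
        return d <= 2
    if d != 1:
        return False
    return _single_edit_kind(a, b) == ("letter", "digit")[pass_no]


def build_dictionary(hits, fuzzy: bool = False, unknown: bool = False,
                     ) -> ElementDictionary:
    """Associate LTR and internal consensus names seen in *hits*.

    Only names observed at least once participate.  Candidates are the
    elements of LTR classes, plus Unknown/Unspecified classes when
    *unknown* is set.  The standard pass pairs an internal-role name with
    every LTR-role name sharing the identical stem.  With *fuzzy*, three
    further passes adopt still-unmatched LTR or plain-role names whose
    stem is within the pass's edit budget of an internal stem; a candidate
    within reach of several internal stems goes to the closest, and an
    exact tie is logged and left unmatched (the printed dictionary is
    meant to be hand-checked anyway).
    """
    names: set[str] = set()
    for h in hits:
        if h.category == "LTR" or (unknown and h.is_unknown):
            names.add(h.element)
    ordered = sorted(names)
    stems = {n: stem_name(n) for n in ordered}

    internals = [n for n in ordered if stems[n][1] == ROLE_INTERNAL]
    ltrs = [n for n in ordered if stems[n][1] == ROLE_LTR]
    plains = [n for n in ordered if stems[n][1] == ROLE_PLAIN]

    d = ElementDictionary()
    matched: set[str] = set()
    fam_of_internal_stem: dict[str, str] = {}

    # standard pass: identical stems, internal <-> ltr roles only
    internals_by_stem: dict[str, list[str]] = {}
    for n in internals:
        internals_by_stem.setdefault(stems[n][0], []).append(n)
    for stem in sorted(internals_by_stem):
        owners = internals_by_stem[stem]
        fam_of_internal_stem[stem] = _family_label(owners[0])
        partners = [m for m in ltrs if stems[m][0] == stem]
        if partners:
            d.add(fam_of_internal_stem[stem], set(owners), set(partners))
            matched.update(owners)
            matched.update(partners)

    if fuzzy:
        internal_stems = sorted({stems[n][0] for n in internals})
        for pass_no in range(3):
            for cand in ltrs + plains:
                if cand in matched:
                    continue
                cstem = stems[cand][0]
                scored = [(s, _edit_distance(cstem, s)) for s in internal_stems
                          if _pass_accepts(pass_no, cstem, s)]
                if not scored:
                    continue
                best = min(dist for _, dist in scored)
                closest = [s for s, dist in scored if dist == best]
                if len(closest) > 1:
                    logger.warning(
                        "fuzzy pass %d: %s is equally close to internal stems %s; "
                        "left unmatched for manual inspection",
                        pass_no + 1, cand, ", ".join(closest))
                    continue
                stem = closest[0]
                owners = [n for n in internals if stems[n][0] == stem]
                fam = d.add(fam_of_internal_stem[stem], set(owners), {cand})
                matched.update(owners)
                matched.add(cand)

    d.unmatched = {n for n in ordered if n not in matched}
    return d


def write_dictionary(d: ElementDictionary, path_or_file) -> None:
    """Write a dictionary as tab-separated text.

    One family per line: name, comma-joined internal names, comma-joined
    LTR names.  Unmatched names follow with an empty partner field so the
    file can be completed by hand (pairing by name is known to miss some
    families) and re-read.
    """
    lines = []
    for fam in sorted(d.families.values(), key=lambda f: f.name):
        lines.append(f"{fam.name}\t{','.join(sorted(fam.internal_names))}\t"
                     f"{','.join(sorted(fam.ltr_names))}")
    for name in sorted(d.unmatched):
        _, role = stem_name(name)
        if role == ROLE_LTR:
            lines.append(f"{name}\t\t{name}")
        else:
            lines.append(f"{name}\t{name}\t")
    text = "\n".join(lines) + ("\n" if lines else "")
    if hasattr(path_or_file, "write"):
        path_or_file.write(text)
    else:
        Path(path_or_file).write_text(text)


def read_dictionary(path: str | Path) -> ElementDictionary:
    """Read a (possibly hand-edited) dictionary file.

    Lines with both partner fields filled define paired families; lines
    with one empty field are recorded as unmatched.  Blank lines and
    ``#`` comments are skipped.  A duplicated family name is an error.
    """
    d = ElementDictionary()
    seen: set[str] = set()
    for line_no, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2 or len(parts) > 3:
            raise ValueError(f"line {line_no}: expected 2-3 tab-separated fields")
        name = parts[0].strip()
        internal = {x.strip() for x in parts[1].split(",") if x.strip()}
        ltr = ({x.strip() for x in parts[2].split(",") if x.strip()}
               if len(parts) == 3 else set())
        if not name:
            raise ValueError(f"line {line_no}: empty family name")
        if name in seen:
            raise ValueError(f"line {line_no}: duplicate family name {name!r}")
        seen.add(name)
        if internal and ltr:
            d.add(name, internal, ltr)
        else:
            d.unmatched.update(internal | ltr or {name})
    return d
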