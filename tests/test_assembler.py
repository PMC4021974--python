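"""Fragment merging, ambiguity resolution, LTR assembly, strict filter."""

import numpy as np
import pytest

import rmdefrag as rd
from rmdefrag.assembler import (AssemblyOptions, LTR_I_LTR, MERGED, SINGLE,
                                SOLO_LTR, INTERNAL_ONLY, WorkUnit, as_span,
                                assemble_copies, mergeable, strict_filter)
from rmdefrag.dictionary import ElementDictionary
from rmdefrag.lengths import LengthTable
from rmdefrag.rmout import RMHit
from conftest import assemble_scenario


def hit(qb, qe, strand="+", element="E", cf="DNA/hAT", rb=1, rspan=None,
        block_id=1, div=5.0, qlen=100_000, rlen=5000):
    rspan = rspan if rspan is not None else (qe - qb + 1)
    return RMHit(100, div, 1.0, 0.5, "q", qb, qe, qlen - qe, strand, element,
                 cf, rb, rb + rspan - 1, max(0, rlen - (rb + rspan - 1)),
                 block_id)


def plain_unit(frags, element="E"):
    return WorkUnit("q", element, sorted(frags, key=lambda h: h.q_begin))


TABLE = LengthTable({"E": 500})


class TestMergeable:
    def test_opposite_strands_never_merge(self):
        a, b = hit(1, 100), hit(200, 300, strand="C")
        assert not mergeable(as_span(a), b, 500)

    def test_containment_never_merges(self):
        a, b = hit(100, 900), hit(200, 800)
        assert not mergeable(as_span(a), b, 5000)

    def test_identical_coordinates_never_merge(self):
        a = hit(100, 900)
        assert not mergeable(as_span(a), hit(100, 900), 5000)

    def test_overlap_is_allowed(self):
        a, b = hit(100, 500), hit(300, 700)
        assert mergeable(as_span(a), b, 500)

    def test_distance_bound_is_strict(self):
        # furthest extremities must span strictly less than 2*ref
        a = hit(1, 100)
        assert mergeable(as_span(a), hit(900, 999), 500)       # span 999
        assert not mergeable(as_span(a), hit(900, 1000), 500)  # span 1000 = 2*ref
        assert not mergeable(as_span(a), hit(901, 1001), 500)

    def test_insert_zero_means_adjacent_only(self):
        a = hit(1, 100)
        assert mergeable(as_span(a), hit(101, 200), None, insert_opt=0)
        assert not mergeable(as_span(a), hit(102, 200), None, insert_opt=0)

    def test_insert_bound_is_inclusive(self):
        a = hit(1, 100)
        assert mergeable(as_span(a), hit(151, 200), None, insert_opt=50)
        assert not mergeable(as_span(a), hit(152, 200), None, insert_opt=50)

    def test_missing_reference_length_blocks_merge(self):
        a = hit(1, 100)
        assert not mergeable(as_span(a), hit(200, 300), None)

    def test_blocking_fragment_of_other_portion(self):
        a, b = hit(1, 100), hit(500, 600)
        blocker = hit(200, 400)  # same strand, inside the gap
        assert mergeable(as_span(a), b, 5000)
        assert not mergeable(as_span(a), b, 5000, blockers=[blocker])
        off_strand = hit(200, 400, strand="C")
        assert mergeable(as_span(a), b, 5000, blockers=[off_strand])


class TestScenarios:
    def test_split_ltr_gives_one_full_length_copy(self):
        _, _, res = assemble_scenario("split_ltr")
        (copy,) = res.copies
        assert copy.structure == LTR_I_LTR
        assert copy.num_assembled == 3
        assert (copy.start, copy.end) == (5001, 9800)

    def test_deletion_fragments_give_one_copy_of_three(self):
        _, _, res = assemble_scenario("deletions")
        (copy,) = res.copies
        assert copy.structure == MERGED
        assert copy.num_assembled == 3
        assert copy.id_chain == "2/3/4"

    def test_nested_insertion_gives_two_copies_from_six_hits(self):
        sc, _, res = assemble_scenario("nested")
        assert len(sc.hits) == 6
        assert len(res.copies) == 2
        by_el = {c.element: c for c in res.copies}
        assert by_el["QUASIMODO"].structure == LTR_I_LTR
        assert by_el["QUASIMODO"].num_assembled == 4
        assert by_el["HOBO"].strand == "C"
        assert by_el["HOBO"].num_assembled == 2

    def test_single_isolated_hit_is_identity(self):
        unit = plain_unit([hit(100, 200)])
        (copy,) = assemble_copies(unit, TABLE)
        assert copy.structure == SINGLE and copy.fragments == unit.hits


class TestLTRAssembly:
    def _family_copies(self, ltr_positions, int_position, ltr_ref=400,
                       int_ref=4000):
        refs = LengthTable({"F_LTR": ltr_ref, "F_I": int_ref})
        d = ElementDictionary()
        d.add("F", {"F_I"}, {"F_LTR"})
        hits = [hit(s, e, element="F_LTR", cf="LTR/Gypsy", rspan=min(e - s + 1, ltr_ref),
                    rlen=ltr_ref, block_id=i + 1)
                for i, (s, e) in enumerate(ltr_positions)]
        s, e = int_position
        hits.append(hit(s, e, element="F_I", cf="LTR/Gypsy",
                        rspan=min(e - s + 1, int_ref), rlen=int_ref, block_id=9))
        unit = WorkUnit("q", "F", sorted(hits, key=lambda h: h.q_begin),
                        d.families["F"])
        return assemble_copies(unit, refs)

    def test_full_length_pairing_within_half_ltr(self):
        copies = self._family_copies([(1, 400), (4500, 4899)], (450, 4449))
        (copy,) = copies
        assert copy.structure == LTR_I_LTR
        assert copy.pct_of_ref == pytest.approx(1.0)

    def test_gap_at_half_ltr_length_is_too_far(self):
        # LTR 500 bp downstream of the internal copy: 500 >= 400/2
        copies = self._family_copies([(4901, 5300)], (1, 4400))
        assert sorted(c.structure for c in copies) == [INTERNAL_ONLY, SOLO_LTR]

    def test_gap_just_under_half_ltr_pairs(self):
        copies = self._family_copies([(4600, 4999)], (1, 4400))
        (copy,) = copies
        assert copy.structure == "I-LTR"

    def test_full_length_solo_ltr_ratio_is_one(self):
        _, _, res = assemble_scenario("solo_ltr")
        solo = next(c for c in res.copies if c.structure == SOLO_LTR)
        assert solo.pct_of_ref == pytest.approx(1.0)

    def test_full_length_triples_take_priority(self):
        # LTR - I - LTR - I: the middle LTR must complete the first triple,
        # leaving the second internal copy partial
        refs = LengthTable({"F_LTR": 400, "F_I": 2000})
        d = ElementDictionary()
        d.add("F", {"F_I"}, {"F_LTR"})
        hits = [
            hit(1, 400, element="F_LTR", cf="LTR/Gypsy", rlen=400, block_id=1),
            hit(451, 2450, element="F_I", cf="LTR/Gypsy", rlen=2000, block_id=2),
            hit(2501, 2900, element="F_LTR", cf="LTR/Gypsy", rlen=400, block_id=3),
            hit(2951, 4950, element="F_I", cf="LTR/Gypsy", rlen=2000, block_id=4),
        ]
        unit = WorkUnit("q", "F", hits, d.families["F"])
        copies = assemble_copies(unit, refs)
        assert sorted(c.structure for c in copies) == [LTR_I_LTR, INTERNAL_ONLY]


def _ambiguous_unit():
    """Chain A (100-900) contains chain B (200-800); fragment C at 950
    is reachable from both."""
    a = hit(100, 900, rspan=400, block_id=1)
    b = hit(200, 800, rspan=400, block_id=2)
    c = hit(950, 1049, rspan=100, block_id=3)
    return plain_unit([a, b, c]), (a, b, c)


class TestAmbiguity:
    def test_default_merges_with_nearest(self):
        unit, (a, b, c) = _ambiguous_unit()
        records = []
        copies = assemble_copies(unit, TABLE, AssemblyOptions(), records)
        assert len(records) == 1
        assert records[0].resolution == "default0"
        merged = next(cp for cp in copies if c in cp.fragments)
        assert a in merged.fragments  # nearest chain end wins

    def test_block_id_overrides_distance(self):
        unit, (a, b, c) = _ambiguous_unit()
        far = hit(950, 1049, rspan=100, block_id=2)  # same block as b
        unit = plain_unit([a, b, far])
        records = []
        copies = assemble_copies(unit, TABLE, AssemblyOptions(), records)
        assert records[0].resolution == "block_id"
        merged = next(cp for cp in copies if far in cp.fragments)
        assert b in merged.fragments

    def test_scripted_choice_and_leave_alone(self):
        unit, (a, b, c) = _ambiguous_unit()
        copies = assemble_copies(unit, TABLE,
                                 AssemblyOptions(mode="choice", answers=[1]))
        merged = next(cp for cp in copies if c in cp.fragments)
        assert b in merged.fragments
        copies = assemble_copies(unit, TABLE,
                                 AssemblyOptions(mode="choice", answers=[2]))
        lone = next(cp for cp in copies if c in cp.fragments)
        assert lone.num_assembled == 1

    def test_out_of_range_answer_raises(self):
        unit, _ = _ambiguous_unit()
        with pytest.raises(ValueError, match="out of range"):
            assemble_copies(unit, TABLE,
                            AssemblyOptions(mode="choice", answers=[7]))

    def test_dry_run_records_match_default(self):
        unit, _ = _ambiguous_unit()
        rec_dry, rec_def = [], []
        dry = assemble_copies(unit, TABLE, AssemblyOptions(mode="dry_run"), rec_dry)
        dflt = assemble_copies(unit, TABLE, AssemblyOptions(), rec_def)
        assert len(rec_dry) == len(rec_def) == 1
        assert [c.id_chain for c in dry] == [c.id_chain for c in dflt]


class TestStrictFilter:
    def make(self, rspan, div):
        return rd.TECopy([hit(1000, 1000 + rspan - 1, rspan=rspan, div=div)],
                         "E", "DNA/hAT", SINGLE, 5000)

    def test_boundaries_are_strict(self):
        assert strict_filter([self.make(100, 10.0)])      # kept
        assert not strict_filter([self.make(80, 10.0)])   # size 80: removed
        assert strict_filter([self.make(81, 10.0)])
        assert not strict_filter([self.make(100, 25.0)])  # identity < 80%
        assert not strict_filter([self.make(100, 20.0)])  # exactly 20% div
        assert strict_filter([self.make(100, 19.9)])

    def test_monotone_per_element(self, random_genome):
        hits, queries = rd.parse_out_text(random_genome.out_text)
        d = rd.build_dictionary(hits)
        default = rd.assemble_genome(hits, queries, d)
        strict = rd.assemble_genome(hits, queries, d,
                                    options=AssemblyOptions(strict=True))
        from collections import Counter
        c_def = Counter(c.element for c in default.copies)
        c_str = Counter(c.element for c in strict.copies)
        for el, n in c_str.items():
            assert n <= c_def[el]


class TestProperties:
    def test_hit_partition_conservation(self, random_genome,
                                        assembled_random_genome):
        res = assembled_random_genome
        assembled = [id(h) for h in res.assembled_hits]
        te_hits = [h for h in res.hits if h.is_te]
        assert len(assembled) == len(set(assembled)) == len(te_hits)
        assert {id(h) for h in te_hits} == set(assembled)

    def test_truth_recovery_on_well_separated_genome(self, random_genome,
                                                     assembled_random_genome):
        got = sorted((c.query, c.start, c.end, c.element, c.structure)
                     for c in assembled_random_genome.copies)
        want = sorted((t.query, t.start, t.end, t.element, t.structure)
                      for t in random_genome.truth)
        assert got == want

    def test_copy_count_non_increasing_in_insert_size(self):
        frags = [hit(1, 100, block_id=1), hit(151, 250, block_id=2),
                 hit(500, 600, block_id=3), hit(2000, 2100, block_id=4)]
        counts = []
        for ins in (0, 50, 300, 2000, 10_000):
            copies = assemble_copies(plain_unit(frags), TABLE,
                                     AssemblyOptions(insert=ins))
            counts.append(len(copies))
        assert counts == sorted(counts, reverse=True)

    def test_inverted_segment_stays_separate_copy(self):
        frags = [hit(1, 100, block_id=1), hit(151, 250, strand="C", block_id=2),
                 hit(301, 400, block_id=3)]
        copies = assemble_copies(plain_unit(frags), TABLE)
        assert len(copies) == 2  # + fragments chain; C fragment on its own


# --------------------------------------------------------------------------
# brute-force oracle: exhaustive enumeration of merge partitions, choosing
# the lexicographically smallest sequence of merge distances ("nearest
# first"); a voluntary new chain counts as an infinite distance.

INF = (10 ** 9,)


def oracle_partition(frags, ref_len):
    best = None

    def span(chain):
        return (frags[chain[0]].q_begin, max(frags[j].q_end for j in chain),
                frags[chain[0]].strand)

    class S:
        def __init__(self, t):
            self.start, self.end, self.strand = t

    def rec(i, chains, keys):
        nonlocal best
        if i == len(frags):
            key = tuple(keys)
            if best is None or key < best[0]:
                best = (key, [tuple(c) for c in chains])
            return
        f = frags[i]
        accepting = []
        for ci, chain in enumerate(chains):
            sp = S(span(chain))
            if mergeable(sp, f, ref_len):
                accepting.append((max(0, f.q_begin - sp.end - 1), -sp.end, ci))
        for sep, negend, ci in accepting:
            chains[ci].append(i)
            rec(i + 1, chains, keys + [(sep, negend)])
            chains[ci].pop()
        chains.append([i])
        rec(i + 1, chains, keys + [INF])
        chains.pop()

    rec(0, [], [])
    return {frozenset(c) for c in best[1]}


def random_unit(rng, n):
    frags = []
    pos = 1
    for i in range(n):
        pos += int(rng.integers(0, 400))
        length = int(rng.integers(20, 600))
        strand = "+" if rng.random() < 0.8 else "C"
        frags.append(hit(pos, pos + length - 1, strand=strand,
                         rspan=min(length, 400), block_id=100 + i, rlen=500))
        pos += int(rng.integers(0, 200))
    return sorted(frags, key=lambda h: (h.q_begin, h.q_end, h.line_no))


@pytest.mark.parametrize("seed", range(12))
def test_greedy_matches_bruteforce_oracle(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, 9))
    frags = random_unit(rng, n)
    copies = assemble_copies(plain_unit(frags), TABLE)
    got = {frozenset(frags.index(f) for f in c.fragments) for c in copies}
    assert got == oracle_partition(frags, TABLE.get("E"))
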