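import pytest

import rmdefrag as rd
from rmdefrag.synthetic import make_scenario, make_random_genome


def assemble_scenario(name, options=None, with_fasta=False, **kw):
    """Parse + dictionary + assembly for one named scenario."""
    sc = make_scenario(name, with_fasta=with_fasta, **kw)
    hits, queries = rd.parse_out_text(sc.out_text)
    d = rd.build_dictionary(hits)
    result = rd.assemble_genome(hits, queries, d, options=options)
    return sc, d, result


@pytest.fixture(scope="session")
def random_genome():
    return make_random_genome(n_insertions=60, seed=11)


@pytest.fixture(scope="session")
def assembled_random_genome(random_genome):
    hits, queries = rd.parse_out_text(random_genome.out_text)
    d = rd.build_dictionary(hits)
    return rd.assemble_genome(hits, queries, d)
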