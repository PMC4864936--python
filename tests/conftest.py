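import numpy as np
import pytest
from hypothesis import settings

from jumpscaf import Config
from jumpscaf.graph import Contig
from jumpscaf.io import MappingRecord

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def cfg():
    return Config(edge_support=1)


@pytest.fixture
def chain_graph():
    """Three unique contigs linked into a concordant chain."""
    from jumpscaf.graph import ScaffoldEdge
    contigs = {c: Contig(id=c, length=5000) for c in "ABC"}
    edges = [
        ScaffoldEdge(0, "A", 1, "B", 1, gap=100.0, sd=30.0, support=10),
        ScaffoldEdge(1, "B", 1, "C", 1, gap=200.0, sd=30.0, support=10),
    ]
    return contigs, edges


def make_same_contig_pairs(n, mu, sigma, seed, contig="big", rlen=100,
                           lib="lib", orientation="inward", contig_len=10**6):
    """Same-contig read pairs with Normal(mu, sigma) outer spans."""
    rng = np.random.default_rng(seed)
    spans = np.round(rng.normal(mu, sigma, n)).astype(int)
    starts = rng.integers(0, contig_len - int(mu + 8 * sigma), n)
    pairs = []
    for i in range(n):
        span = max(int(spans[i]), 2 * rlen)
        s = int(starts[i])
        if orientation == "inward":
            st1, st2 = "+", "-"
        elif orientation == "outward":
            st1, st2 = "-", "+"
        else:
            st1, st2 = "+", "+"
        r1 = MappingRecord(f"q{i}", 1, contig, s, st1, rlen, lib)
        r2 = MappingRecord(f"q{i}", 2, contig, s + span - rlen, st2, rlen, lib)
        pairs.append((r1, r2))
    return pairs


@pytest.fixture(scope="session")
def small_dataset():
    """A 300-kbp synthetic study, shared across pipeline tests."""
    from jumpscaf.simulate import (LibrarySpec, RepeatFamilySpec,
                                   simulate_dataset)
    return simulate_dataset(
        seed=5, genome_size=300_000,
        repeat_spec=(RepeatFamilySpec(length=8000, copies=3),),
        specs=(LibrarySpec("lib3k", 3000.0, 300.0),
               LibrarySpec("lib10k", 10000.0, 1000.0)))
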