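import pytest

from methylink.models import GeneModel, GenomeSequence, ModifiedBase
from methylink.motifs import parse_motif
from methylink.synth import SyntheticScenario, generate_linked_dataset


@pytest.fixture(scope="session")
def aggcct():
    return parse_motif("AgGCcT")


@pytest.fixture(scope="session")
def gat_motif():
    return parse_motif("GaTNNNNNGtGG")


@pytest.fixture
def small_genome():
    return GenomeSequence("c1", "AAGGCCTTACGTGATAAAAAGTGGACGT", circular=False)


@pytest.fixture
def mod(request):
    def make(position, strand="+", base="A", score=100.0, contig="c1", **kw):
        mod_type = kw.pop("mod_type", "m6A" if base == "A" else "m4C")
        return ModifiedBase(contig, position, strand, base, mod_type, score, **kw)

    return make


@pytest.fixture
def genes():
    return [
        GeneModel("g1", "c1", 1001, 2000, "+"),
        GeneModel("g2", "c1", 3001, 4000, "-"),
        GeneModel("g3", "c1", 5001, 5900, "+"),
    ]


@pytest.fixture(scope="session")
def linked_null():
    """Moderate null dataset shared across tests (no planted coupling)."""
    scenario = SyntheticScenario(
        genome_length=150_000,
        n_genes=100,
        noncanonical_density=10.0,
        coupling_strength=0.0,
        seed=42,
    )
    return generate_linked_dataset(scenario)


@pytest.fixture(scope="session")
def linked_coupled():
    """Dataset with a strong planted coupling at -80..-20."""
    scenario = SyntheticScenario(
        genome_length=300_000,
        n_genes=300,
        noncanonical_density=2.0,
        coupling_strength=0.9,
        coupling_offsets=(-80, -20),
        seed=3,
    )
    return generate_linked_dataset(scenario)
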