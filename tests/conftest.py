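import pytest

from orgpath.scoring import PLANT_MT_CORE, get_profile
from orgpath.synth import GenomeSpec, RepeatSpec, make_genome, make_graph

from helpers import build_graph


@pytest.fixture
def plant_mt_profile():
    return get_profile("plant", "mt")


@pytest.fixture
def plant_mt_genes():
    return [("mt_core", g) for g in sorted(PLANT_MT_CORE)]


@pytest.fixture
def dumbbell():
    """Two unique contigs joined through a 2-copy repeat; the classic
    repeat-mediated master-circle configuration."""
    graph = build_graph(
        [("A", 5000, 100.0, "A" * 5000), ("B", 4000, 100.0, "C" * 4000), ("R", 2000, 200.0, "G" * 2000)],
        [("A", "+", "R", "+"), ("R", "+", "A", "+"), ("B", "+", "R", "+"), ("R", "+", "B", "+")],
    )
    return graph, {"A": 1, "B": 1, "R": 2}


@pytest.fixture
def clean_plant_mt_fixture(plant_mt_genes):
    """Noise-free plant-mt instance: circle + 2 repeat families + nuclear
    background + high-depth NUMT bridge."""
    spec = GenomeSpec(
        kind="circle",
        length=60_000,
        repeats=(RepeatSpec(2000, 2), RepeatSpec(1200, 2, inverted=True)),
        n_nuclear_contigs=30,
        numt=True,
        depth_cv=0.0,
        seed=42,
    )
    truth = make_genome(spec, plant_mt_genes)
    graph, hits = make_graph(truth)
    return spec, truth, graph, hits
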