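"""Copy numbers, path priority, structure resolution, sequence spelling."""

import numpy as np
import pytest

from orgpath.resolve import (
    BfsPath,
    canonical_cycle,
    estimate_copy_numbers,
    is_feasible_path,
    path_priority,
    path_to_sequence,
    resolve_structure,
    step_string,
)
from orgpath.sequtils import random_dna, revcomp
from orgpath.synth import GenomeSpec, expected_structure, make_genome, make_graph

from helpers import build_graph, decompose_oracle, random_small_graph


@pytest.mark.parametrize("depth,expected", [(100.0, 1), (195.0, 2), (40.0, 1), (249.0, 2), (250.0, 3)])
def test_copy_number_rounding_and_floor(depth, expected):
    g = build_graph([("c", 1000, depth)], [])
    assert estimate_copy_numbers(g, ["c"], 100.0) == {"c": expected}


def _path(cyclic, length, nodes, depth, steps=(("a", "+"),)):
    usage = {}
    for cid, _ in steps:
        usage[cid] = usage.get(cid, 0) + 1
    return BfsPath(steps=tuple(steps), usage=usage, total_length=length, node_count=nodes,
                   path_depth=depth, is_cyclic=cyclic)


def test_priority_cyclic_beats_longer_linear():
    cyc = _path(True, 50_000, 5, 100.0)
    lin = _path(False, 60_000, 5, 100.0)
    assert path_priority(cyc, 100.0) < path_priority(lin, 100.0)


def test_priority_longer_cycle_wins():
    assert path_priority(_path(True, 50_000, 5, 100.0), 100.0) < path_priority(_path(True, 40_000, 5, 100.0), 100.0)


def test_priority_depth_closest_to_baseline_wins():
    a = _path(True, 50_000, 5, 95.0)
    b = _path(True, 50_000, 5, 60.0)
    assert path_priority(a, 100.0) < path_priority(b, 100.0)


def test_three_contig_simple_cycle():
    g = build_graph(
        [("a", 3000, 100.0), ("b", 2000, 100.0), ("c", 1000, 100.0)],
        [("a", "+", "b", "+"), ("b", "+", "c", "+"), ("c", "+", "a", "+")],
    )
    res = resolve_structure(g, {"a": 1, "b": 1, "c": 1}, 100.0)
    assert res.classification == "single_circular"
    assert len(res.paths) == 1 and res.paths[0].total_length == 6000
    assert res.paths[0].usage == {"a": 1, "b": 1, "c": 1}
    assert res.residual == {}


def test_dumbbell_resolves_to_master_circle(dumbbell):
    """With crossing junctions present, the repeat-mediated master circle
    (A-R-B-R) outranks the two small circles; the exhaustive oracle agrees."""
    graph, cn = dumbbell
    res = resolve_structure(graph, cn, 100.0)
    assert res.classification == "single_circular"
    assert res.paths[0].total_length == 13_000
    assert res.paths[0].usage == {"A": 1, "B": 1, "R": 2}
    oracle = decompose_oracle(graph, cn, 100.0)
    assert [p.steps for p in oracle] == [p.steps for p in res.paths]


def test_oracle_equivalence_on_random_small_graphs():
    """Beam decomposition == exhaustive enumeration on 200 seeded random
    graphs with <= 8 contigs and <= 12 total copies."""
    rng = np.random.default_rng(99)
    for _ in range(200):
        g, cn = random_small_graph(rng)
        got = resolve_structure(g, cn, 100.0)
        want = decompose_oracle(g, cn, 100.0)
        assert [(p.steps, p.total_length, p.is_cyclic) for p in got.paths] == [
            (p.steps, p.total_length, p.is_cyclic) for p in want
        ]


def test_usage_never_exceeds_copy_numbers():
    rng = np.random.default_rng(13)
    for _ in range(50):
        g, cn = random_small_graph(rng)
        res = resolve_structure(g, cn, 100.0)
        total = res.usage_total()
        assert all(total[c] <= cn[c] for c in total)
        # residual + usage accounts for every copy
        for cid, m in cn.items():
            assert total.get(cid, 0) + res.residual.get(cid, 0) <= m


def test_cyclic_path_reported_in_canonical_form():
    steps = (("b", "+"), ("c", "-"), ("a", "+"))
    canon = canonical_cycle(steps)
    # canonical form: starts at the smallest oriented step, minimal string
    assert canon[0] == ("a", "+")
    for rot in range(3):
        rotated = steps[rot:] + steps[:rot]
        assert canonical_cycle(rotated) == canon
    reflected = tuple((c, "-" if o == "+" else "+") for c, o in reversed(steps))
    assert canonical_cycle(reflected) == canon


def test_resolution_deterministic_across_reruns():
    g = build_graph(
        [("a", 3000, 100.0), ("b", 2000, 100.0), ("r", 500, 200.0)],
        [("a", "+", "r", "+"), ("r", "+", "b", "+"), ("b", "+", "r", "+"), ("r", "+", "a", "+")],
    )
    runs = [resolve_structure(g, {"a": 1, "b": 1, "r": 2}, 100.0) for _ in range(3)]
    assert all(step_string(r.paths[0].steps) == step_string(runs[0].paths[0].steps) for r in runs)


def test_single_circle_recovery_sample(plant_mt_genes):
    """Random no-repeat circles resolve single_circular with the planted
    sequence recovered up to rotation/strand (small sample; the acceptance
    suite runs 50)."""
    rng = np.random.default_rng(7)
    for rep in range(8):
        spec = GenomeSpec(
            kind="circle",
            length=int(rng.integers(20_000, 200_000)),
            n_segments=int(rng.integers(5, 21)),
            depth_cv=0.0,
            seed=500 + rep,
        )
        truth = make_genome(spec, plant_mt_genes[:4])
        graph, _ = make_graph(truth)
        cn = estimate_copy_numbers(graph, truth.organelle_ids, spec.organelle_depth)
        res = resolve_structure(graph.subgraph(truth.organelle_ids), cn, spec.organelle_depth)
        assert res.classification == "single_circular"
        seq = path_to_sequence(res.paths[0], graph)
        doubled = truth.genomes[0] * 2
        assert seq in doubled or revcomp(seq) in doubled


def test_expected_structure_matches_resolution(clean_plant_mt_fixture):
    spec, truth, graph, hits = clean_plant_mt_fixture
    sub = graph.subgraph(truth.organelle_ids)
    cn = estimate_copy_numbers(sub, truth.organelle_ids, spec.organelle_depth)
    res = resolve_structure(sub, cn, spec.organelle_depth)
    exp = expected_structure(truth)
    assert res.classification == exp.classification == "single_circular"
    assert sorted(p.steps for p in res.paths) == sorted(p.steps for p in exp.paths)
    assert is_feasible_path(sub, exp.paths[0].steps, cn, cyclic=True)


def test_residual_when_copies_cannot_be_placed():
    """An inflated copy count that no walk can consume ends up as residual
    and flips the classification to unresolved_branched."""
    g = build_graph(
        [("a", 3000, 100.0), ("b", 2000, 100.0)],
        [("a", "+", "b", "+"), ("b", "+", "a", "+")],
    )
    res = resolve_structure(g, {"a": 3, "b": 1}, 100.0)
    assert res.classification == "unresolved_branched"
    assert res.residual.get("a", 0) >= 1


def test_path_to_sequence_single_contig():
    seq = random_dna(np.random.default_rng(3), 500)
    g = build_graph([("a", 500, 100.0, seq)], [])
    p = _path(False, 500, 1, 100.0, steps=(("a", "+"),))
    assert path_to_sequence(p, g) == seq


def test_path_to_sequence_overlap_trimming():
    rng = np.random.default_rng(4)
    s1, shared, s2 = random_dna(rng, 400), random_dna(rng, 100), random_dna(rng, 300)
    g = build_graph(
        [("a", 500, 100.0, s1 + shared), ("b", 400, 100.0, shared + s2)],
        [("a", "+", "b", "+", 100)],
    )
    p = _path(False, 800, 2, 100.0, steps=(("a", "+"), ("b", "+")))
    assert path_to_sequence(p, g) == s1 + shared + s2


def test_path_to_sequence_minus_step_is_revcomp():
    seq = random_dna(np.random.default_rng(5), 200)
    g = build_graph([("a", 200, 100.0, seq)], [])
    p = _path(False, 200, 1, 100.0, steps=(("a", "-"),))
    assert path_to_sequence(p, g) == revcomp(seq)


def test_path_to_sequence_missing_sequence_names_contig():
    g = build_graph([("a", 200, 100.0)], [])
    p = _path(False, 200, 1, 100.0, steps=(("a", "+"),))
    with pytest.raises(ValueError, match="a"):
        path_to_sequence(p, g)


def test_overlap_mode_roundtrip():
    """Synthetic circles built with junction overlaps still spell back the
    planted genome exactly."""
    spec = GenomeSpec(kind="circle", length=30_000, n_segments=6, overlap=50, depth_cv=0.0, seed=17)
    truth = make_genome(spec)
    graph, _ = make_graph(truth)
    cn = estimate_copy_numbers(graph, truth.organelle_ids, spec.organelle_depth)
    res = resolve_structure(graph, cn, spec.organelle_depth)
    assert res.classification == "single_circular"
    assert res.paths[0].total_length == 30_000
    seq = path_to_sequence(res.paths[0], graph)
    doubled = truth.genomes[0] * 2
    assert seq in doubled or revcomp(seq) in doubled
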