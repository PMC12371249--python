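"""Repeat/MTPT statistics, gene content, and the assembly report."""

import numpy as np
import pytest

from orgpath.assess import (
    AssemblyReport,
    build_report,
    count_rearrangement_contigs,
    gene_content,
    mtpt_stats,
    repeat_fraction_percent,
    repeat_stats,
)
from orgpath.formats import GeneHit
from orgpath.resolve import BfsPath, StructureResult
from orgpath.scoring import get_profile
from orgpath.sequtils import random_dna, revcomp

from helpers import build_graph, repeat_covered_bp_bruteforce, shares_kmer


def _mk_result(usages, cyclic=True, lengths=None):
    paths = []
    for i, usage in enumerate(usages):
        steps = tuple((cid, "+") for cid, n in usage.items() for _ in range(n))
        paths.append(
            BfsPath(steps=steps, usage=dict(usage), total_length=(lengths or [10_000])[min(i, len(lengths or [0]) - 1)],
                    node_count=len(steps), path_depth=100.0, is_cyclic=cyclic)
        )
    cls = "single_circular" if len(paths) == 1 else "multi_circular"
    return StructureResult(paths=paths, classification=cls, residual={})


def _hit(ctg, gene, cls="mt_core"):
    return GeneHit(contig_id=ctg, gene=gene, gene_class=cls, start=1, end=60, identity=99.0, bitscore=120.0)


# --------------------------------------------------------------------------
# repeats


def test_planted_direct_duplication_counts_both_copies():
    rng = np.random.default_rng(1)
    block = random_dna(rng, 100)
    seq = random_dna(rng, 800) + block + random_dna(rng, 500) + block + random_dna(rng, 500)
    total, intervals = repeat_stats([seq])
    assert total == 200
    assert len(intervals) == 2


def test_planted_inverted_duplication_counts_both_copies():
    rng = np.random.default_rng(2)
    block = random_dna(rng, 100)
    seq = random_dna(rng, 800) + block + random_dna(rng, 500) + revcomp(block) + random_dna(rng, 500)
    total, _ = repeat_stats([seq])
    # both copies covered; chance single-base extensions at the flanks allowed
    assert 200 <= total <= 208
    assert total == repeat_covered_bp_bruteforce([seq])


def test_unique_sequence_has_no_repeats():
    # de Bruijn-ish construction: every 31-mer distinct w.h.p. in random DNA
    seq = random_dna(np.random.default_rng(3), 2000)
    assert repeat_covered_bp_bruteforce([seq]) == 0  # oracle confirms fixture
    assert repeat_stats([seq])[0] == 0


def test_repeat_shorter_than_threshold_ignored():
    rng = np.random.default_rng(4)
    block = random_dna(rng, 30)  # exactly 30 bp: not > 30
    seq = random_dna(rng, 500) + block + random_dna(rng, 400) + block + random_dna(rng, 400)
    assert repeat_stats([seq])[0] == repeat_covered_bp_bruteforce([seq])


def test_cross_sequence_repeats_detected():
    rng = np.random.default_rng(5)
    block = random_dna(rng, 60)
    s1 = random_dna(rng, 300) + block + random_dna(rng, 300)
    s2 = random_dna(rng, 200) + revcomp(block) + random_dna(rng, 200)
    total, intervals = repeat_stats([s1, s2])
    assert total == 120
    assert {iv[0] for iv in intervals} == {0, 1}


def test_repeat_stats_matches_bruteforce_oracle_sample():
    """Exact agreement with the all-pairs scanning oracle on 25 seeded
    sequences (the acceptance suite runs 100)."""
    rng = np.random.default_rng(6)
    for rep in range(25):
        n = int(rng.integers(200, 3000))
        seq = list(random_dna(rng, n))
        # plant 0-2 duplications, sometimes inverted, sometimes overlapping
        for _ in range(int(rng.integers(0, 3))):
            ln = int(rng.integers(20, 120))
            src = int(rng.integers(0, n - ln))
            dst = int(rng.integers(0, n - ln))
            block = "".join(seq[src : src + ln])
            if rng.random() < 0.5:
                block = revcomp(block)
            seq[dst : dst + ln] = list(block)
        s = "".join(seq)
        assert repeat_stats([s])[0] == repeat_covered_bp_bruteforce([s])


def test_repeat_stats_requires_input():
    with pytest.raises(ValueError):
        repeat_stats([])


# --------------------------------------------------------------------------
# MTPT


def test_mtpt_exact_containment():
    rng = np.random.default_rng(7)
    plastid = random_dna(rng, 5000)
    insert = plastid[1000:2000]
    mito = random_dna(rng, 3000) + insert + random_dna(rng, 2000)
    total, intervals = mtpt_stats(mito, plastid)
    assert total == 1000
    assert intervals == [(3000, 4000)]


def test_mtpt_zero_when_no_shared_kmer():
    rng = np.random.default_rng(8)
    mito, plastid = random_dna(rng, 4000), random_dna(rng, 4000)
    assert not shares_kmer(mito, plastid)  # oracle: fixture really is disjoint
    assert mtpt_stats(mito, plastid)[0] == 0


def test_mtpt_additive_over_disjoint_inserts():
    rng = np.random.default_rng(9)
    plastid = random_dna(rng, 8000)
    mito = (
        random_dna(rng, 2000)
        + plastid[100:400]  # 300 bp
        + random_dna(rng, 1500)
        + plastid[5000:5700]  # 700 bp
        + random_dna(rng, 1000)
    )
    total, intervals = mtpt_stats(mito, plastid)
    assert total == 1000
    assert len(intervals) == 2


def test_mtpt_position_symmetric():
    rng = np.random.default_rng(10)
    plastid = random_dna(rng, 6000)
    insert = plastid[2000:2500]
    for offset in (0, 1500, 3500):
        mito = random_dna(rng, offset) + insert + random_dna(rng, 4000 - offset)
        assert mtpt_stats(mito, plastid)[0] == 500


def test_mtpt_short_spans_dropped_and_gaps_merged():
    rng = np.random.default_rng(11)
    plastid = random_dna(rng, 6000)
    short = plastid[100:140]  # 40 bp < min_span
    mito = random_dna(rng, 1000) + short + random_dna(rng, 1000)
    assert mtpt_stats(mito, plastid)[0] == 0
    # two 200 bp blocks 80 bp apart merge into one span
    mito2 = random_dna(rng, 1000) + plastid[300:500] + random_dna(rng, 80) + plastid[800:1000] + random_dna(rng, 500)
    total, intervals = mtpt_stats(mito2, plastid)
    assert len(intervals) == 1
    assert total == 480


# --------------------------------------------------------------------------
# gene content / rearrangements / report


def test_gene_content_full_and_missing():
    prof = get_profile("animal", "mt")
    result = _mk_result([{"c1": 1, "c2": 1}])
    hits = [_hit("c1", g) for g in sorted(prof.core_genes) if g != "atp8"]
    hits.append(_hit("c3", "atp8"))  # on a contig no path uses
    present, missing = gene_content(result, hits, prof)
    assert missing == {"atp8"}
    present2, missing2 = gene_content(result, hits + [_hit("c2", "atp8")], prof)
    assert missing2 == set()
    assert present2 | missing2 == set(prof.core_genes)


def test_gene_content_empty_hits():
    prof = get_profile("animal", "mt")
    present, missing = gene_content(_mk_result([{"c1": 1}]), [], prof)
    assert present == set() and missing == set(prof.core_genes)


def test_rearrangement_contig_count():
    assert count_rearrangement_contigs(_mk_result([{"a": 1, "b": 1}])) == 0
    assert count_rearrangement_contigs(_mk_result([{"a": 1, "b": 1, "r": 2}])) == 1
    # repeat used once in each of two paths still totals 2
    assert count_rearrangement_contigs(_mk_result([{"a": 1, "r": 1}, {"b": 1, "r": 1}])) == 1


def test_repeat_fraction_worked_example():
    """82,815 bp of repeats in a 156,349 bp genome -> 53% after rounding."""
    assert repeat_fraction_percent(82_815, 156_349) == 53


def test_repeat_fraction_zero():
    assert repeat_fraction_percent(0, 10_000) == 0


def test_report_verdict_and_roundtrip():
    prof = get_profile("animal", "mt")
    g = build_graph([("c1", 8000, 100.0), ("c2", 6000, 100.0)], [])
    result = _mk_result([{"c1": 1, "c2": 1}], lengths=[14_000])
    hits = [_hit("c1", gene) for gene in sorted(prof.core_genes)]
    present, missing = gene_content(result, hits, prof)
    report = build_report(result, g, present, missing, 1000, 0, prof)
    assert report.verdict == "complete"
    assert report.repeat_fraction == repeat_fraction_percent(1000, 14_000)
    assert abs(report.repeat_fraction - 100 * report.repeat_total / report.total_length) <= 0.5
    assert AssemblyReport.from_json(report.to_json()) == report

    # missing a gene -> partial
    present2, missing2 = gene_content(result, hits[:-1], prof)
    assert build_report(result, g, present2, missing2, 0, 0, prof).verdict == "partial"
    # no genes at all -> failed
    present3, missing3 = gene_content(result, [], prof)
    assert build_report(result, g, present3, missing3, 0, 0, prof).verdict == "failed"


def test_report_mean_depth_is_length_weighted():
    prof = get_profile("animal", "mt")
    g = build_graph([("c1", 10_000, 100.0), ("c2", 30_000, 60.0)], [])
    result = _mk_result([{"c1": 1, "c2": 1}], lengths=[40_000])
    report = build_report(result, g, set(), set(prof.core_genes), 0, 0, prof)
    assert report.mean_depth == pytest.approx(70.0)
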