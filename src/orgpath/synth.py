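"""Synthetic organelle genomes, repeat-collapsed graphs, and truth labels.

The generator emulates the inputs the pipeline consumes downstream of
whole-genome assembly:

* circular (optionally multipartite) organelle genomes with planted
  direct or inverted repeats, which collapse in the graph to single
  contigs of multiplied depth;
* quadripartite plastomes (LSC + SSC + two inverted repeats);
* plastid-derived inserts (MTPT) in mitogenomes;
* low-depth nuclear background contigs, optionally one high-depth
  nuclear homolog (a collapsed NUMT/NUPT cluster) linked into the
  organelle subgraph;
* conserved core genes planted as unique 60 bp tags with exact-match
  hit rows, decoupling tests from any particular aligner.

Depth noise is multiplicative log-normal with unit mean and a
configurable coefficient of variation. Everything derives from the spec
seed, so the same spec yields byte-identical genomes, graphs and hit
tables.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .formats import GeneHit
from .graph import AssemblyGraph, Contig, Link
from .resolve import BfsPath, StructureResult, canonical_cycle
from .sequtils import random_dna, revcomp

GENE_TAG_LEN = 60


@dataclass(frozen=True)
class RepeatSpec:
    length: int
    copies: int = 2
    inverted: bool = False

    def __post_init__(self) -> None:
        if self.length < 1 or self.copies < 2:
            raise ValueError("repeat needs length >= 1 and copies >= 2")


@dataclass
class GenomeSpec:
    """Conditions for one synthetic organelle + background instance."""

    kind: str = "circle"  # circle | multi_circle | plastome_quadripartite | linear
    length: int = 100_000
    repeats: tuple[RepeatSpec, ...] = ()
    n_circles: int = 1
    n_segments: int | None = None  # unique contigs per circle (min: one per repeat copy)
    mtpt_insert: int = 0
    n_nuclear_contigs: int = 0
    nuclear_depth: float = 8.0
    organelle_depth: float = 100.0
    depth_cv: float = 0.1
    numt: bool = False
    numt_depth: float | None = None  # default 2.5x organelle depth (collapsed cluster)
    overlap: int = 0  # junction overlap; only valid without repeats
    seed: int = 0
    min_segment: int = 300

    def __post_init__(self) -> None:
        if self.kind not in ("circle", "multi_circle", "plastome_quadripartite", "linear"):
            raise ValueError(f"unknown genome kind: {self.kind}")
        if self.length < 1:
            raise ValueError("length must be >= 1")
        if self.kind != "multi_circle" and self.n_circles != 1:
            raise ValueError("n_circles > 1 requires kind='multi_circle'")
        if self.kind == "multi_circle" and self.n_circles < 2:
            raise ValueError("multi_circle needs n_circles >= 2")
        if self.overlap and self.repeats:
            raise ValueError("overlap mode only supported without repeats")
        rep_bp = sum(r.length * r.copies for r in self.repeats)
        if rep_bp >= self.length:
            raise ValueError("infeasible packing: repeats do not fit in the genome")


@dataclass
class PlantedGene:
    gene_class: str
    gene: str
    contig_id: str
    start: int  # 1-based inclusive, contig coordinates
    end: int


@dataclass
class SyntheticTruth:
    spec: GenomeSpec
    genomes: list[str]
    circles: list[list[tuple[str, str]]]  # ordered (contig id, orientation) per molecule
    contig_seqs: dict[str, str]
    copies: dict[str, int]
    genes: list[PlantedGene]
    repeat_intervals: list[tuple[int, int, int]]  # (circle, start, end) 0-based half-open
    mtpt_intervals: list[tuple[int, int, int]] = field(default_factory=list)
    plastid_seq: str | None = None

    @property
    def organelle_ids(self) -> set[str]:
        return set(self.copies)

    @property
    def total_length(self) -> int:
        return sum(len(g) for g in self.genomes)

    def to_json(self) -> str:
        d = {
            "spec": asdict(self.spec),
            "genomes": self.genomes,
            "circles": self.circles,
            "copies": self.copies,
            "genes": [asdict(g) for g in self.genes],
            "repeat_intervals": self.repeat_intervals,
            "mtpt_intervals": self.mtpt_intervals,
        }
        return json.dumps(d, indent=1, sort_keys=True)


def _split_lengths(rng: np.random.Generator, total: int, n: int, minimum: int) -> list[int]:
    """Random partition of ``total`` into n parts each >= minimum."""
    if total < n * minimum:
        raise ValueError("infeasible packing: unique sequence does not cover minimum segments")
    extra = total - n * minimum
    if extra == 0:
        return [minimum] * n
    cuts = np.sort(rng.integers(0, extra + 1, size=n - 1))
    parts = np.diff(np.concatenate(([0], cuts, [extra])))
    return [minimum + int(p) for p in parts]


def _plant_genes(
    rng: np.random.Generator,
    unique_seqs: dict[str, str],
    genes: Sequence[tuple[str, str]],
) -> list[PlantedGene]:
    """Overwrite unique 60 bp tags into unique contigs, round-robin."""
    placements: list[PlantedGene] = []
    hosts = sorted(cid for cid, s in unique_seqs.items() if len(s) >= GENE_TAG_LEN + 20)
    if genes and not hosts:
        raise ValueError("infeasible packing: no contig can host gene tags")
    taken: dict[str, list[tuple[int, int]]] = {h: [] for h in hosts}
    for i, (gclass, gname) in enumerate(genes):
        placed = False
        for attempt in range(200):
            host = hosts[(i + attempt) % len(hosts)]
            seq = unique_seqs[host]
            lo, hi = 10, len(seq) - GENE_TAG_LEN - 10
            if hi <= lo:
                continue
            start = int(rng.integers(lo, hi))
            span = (start, start + GENE_TAG_LEN)
            if any(not (span[1] <= s or span[0] >= e) for s, e in taken[host]):
                continue
            tag = random_dna(rng, GENE_TAG_LEN)
            unique_seqs[host] = seq[: span[0]] + tag + seq[span[1] :]
            taken[host].append(span)
            placements.append(
                PlantedGene(gene_class=gclass, gene=gname, contig_id=host, start=span[0] + 1, end=span[1])
            )
            placed = True
            break
        if not placed:
            raise ValueError(f"infeasible packing: cannot place gene {gname}")
    return placements


def make_genome(spec: GenomeSpec, genes: Sequence[tuple[str, str]] = ()) -> SyntheticTruth:
    """Generate genome sequence(s) plus all planted features.

    ``genes`` is a sequence of (gene_class, gene_name) pairs, e.g.
    ("mt_core", "cox1"); tags are distributed across the unique contigs
    of all molecules. Deterministic for a given spec.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.kind == "plastome_quadripartite":
        return _make_quadripartite(spec, genes, rng)

    n_circles = spec.n_circles if spec.kind == "multi_circle" else 1
    # molecule lengths: proportional random split, each >= 15% of an even share
    if n_circles == 1:
        circle_lengths = [spec.length]
    else:
        circle_lengths = _split_lengths(rng, spec.length, n_circles, max(spec.length // (4 * n_circles), 1000))

    # assign repeat families to molecules round-robin
    fams_per_circle: list[list[tuple[int, RepeatSpec]]] = [[] for _ in range(n_circles)]
    for fi, rs in enumerate(spec.repeats):
        fams_per_circle[fi % n_circles].append((fi, rs))

    unique_seqs: dict[str, str] = {}
    repeat_seqs: dict[str, str] = {}
    copies: dict[str, int] = {}
    circles: list[list[tuple[str, str]]] = []

    for ci in range(n_circles):
        fams = fams_per_circle[ci]
        rep_bp = sum(rs.length * rs.copies for _, rs in fams)
        occ: list[tuple[str, str]] = []  # (repeat contig id, orientation)
        for fi, rs in fams:
            rid = f"r{fi}"
            repeat_seqs[rid] = random_dna(rng, rs.length)
            copies[rid] = rs.copies
            for copy_i in range(rs.copies):
                orient = "-" if (rs.inverted and copy_i > 0) else "+"
                occ.append((rid, orient))
        order = rng.permutation(len(occ))
        occ = [occ[i] for i in order]
        n_occ = len(occ)
        n_unique = max(n_occ, spec.n_segments or (n_occ if n_occ else 6))
        u_total = circle_lengths[ci] - rep_bp
        u_lens = _split_lengths(rng, u_total, n_unique, spec.min_segment)
        u_ids = [f"c{ci}u{j}" for j in range(n_unique)]
        for uid, ul in zip(u_ids, u_lens):
            unique_seqs[uid] = random_dna(rng, ul)
            copies[uid] = 1
        # layout: distribute the unique contigs into n_occ blocks (>=1 each),
        # alternating block / repeat occurrence; no repeats -> all unique
        layout: list[tuple[str, str]] = []
        if n_occ == 0:
            layout = [(uid, "+") for uid in u_ids]
        else:
            block_sizes = [1] * n_occ
            for j in range(n_unique - n_occ):
                block_sizes[int(rng.integers(0, n_occ))] += 1
            k = 0
            for bi in range(n_occ):
                for _ in range(block_sizes[bi]):
                    layout.append((u_ids[k], "+"))
                    k += 1
                layout.append(occ[bi])
        circles.append(layout)

    planted_genes = _plant_genes(rng, unique_seqs, genes)

    # MTPT: copy a plastid block into the largest unique contig
    mtpt_intervals: list[tuple[int, int, int]] = []
    plastid_seq: str | None = None
    if spec.mtpt_insert > 0:
        plastid_seq = random_dna(rng, max(3 * spec.mtpt_insert, 20_000))
        host = max(unique_seqs, key=lambda cid: len(unique_seqs[cid]))
        seq = unique_seqs[host]
        if len(seq) < spec.mtpt_insert + 2 * GENE_TAG_LEN + 40:
            raise ValueError("infeasible packing: MTPT insert larger than host contig")
        p_start = int(rng.integers(0, len(plastid_seq) - spec.mtpt_insert + 1))
        insert = plastid_seq[p_start : p_start + spec.mtpt_insert]
        # place after any planted gene tags to avoid clobbering them
        gene_ends = [g.end for g in planted_genes if g.contig_id == host]
        lo = max(gene_ends) if gene_ends else 10
        hi = len(seq) - spec.mtpt_insert - 10
        if hi <= lo:
            raise ValueError("infeasible packing: no room for MTPT insert")
        m_start = int(rng.integers(lo, hi))
        unique_seqs[host] = seq[:m_start] + insert + seq[m_start + spec.mtpt_insert :]
        mtpt_intervals.append(_contig_to_genome_interval(circles, unique_seqs, repeat_seqs, host, m_start, m_start + spec.mtpt_insert))

    contig_seqs = {**unique_seqs, **repeat_seqs}
    genomes = []
    repeat_intervals: list[tuple[int, int, int]] = []
    for ci, layout in enumerate(circles):
        parts = []
        pos = 0
        for cid, orient in layout:
            s = contig_seqs[cid]
            if orient == "-":
                s = revcomp(s)
            if cid in repeat_seqs:
                repeat_intervals.append((ci, pos, pos + len(s)))
            parts.append(s)
            pos += len(s)
        genomes.append("".join(parts))

    return SyntheticTruth(
        spec=spec,
        genomes=genomes,
        circles=circles,
        contig_seqs=contig_seqs,
        copies=copies,
        genes=planted_genes,
        repeat_intervals=repeat_intervals,
        mtpt_intervals=mtpt_intervals,
        plastid_seq=plastid_seq,
    )


def _contig_to_genome_interval(circles, unique_seqs, repeat_seqs, host, s, e):
    pos = 0
    seqs = {**unique_seqs, **repeat_seqs}
    for ci, layout in enumerate(circles):
        pos = 0
        for cid, _ in layout:
            ln = len(seqs[cid])
            if cid == host:
                return (ci, pos + s, pos + e)
            pos += ln
    raise KeyError(host)


def _make_quadripartite(
    spec: GenomeSpec, genes: Sequence[tuple[str, str]], rng: np.random.Generator
) -> SyntheticTruth:
    """LSC + IRa + SSC + IRb circle; the IRs are exact reverse complements."""
    ir_len = spec.repeats[0].length if spec.repeats else max(spec.length // 8, 1000)
    rest = spec.length - 2 * ir_len
    if rest < 2 * spec.min_segment:
        raise ValueError("infeasible packing: IRs leave no room for single-copy regions")
    lsc_len = math.floor(rest * 0.8)
    ssc_len = rest - lsc_len
    unique_seqs = {"LSC": random_dna(rng, lsc_len), "SSC": random_dna(rng, ssc_len)}
    repeat_seqs = {"IR": random_dna(rng, ir_len)}
    copies = {"LSC": 1, "SSC": 1, "IR": 2}
    layout = [("LSC", "+"), ("IR", "+"), ("SSC", "+"), ("IR", "-")]
    planted = _plant_genes(rng, unique_seqs, genes)
    contig_seqs = {**unique_seqs, **repeat_seqs}
    parts = []
    pos = 0
    repeat_intervals = []
    for cid, orient in layout:
        s = contig_seqs[cid]
        if orient == "-":
            s = revcomp(s)
        if cid == "IR":
            repeat_intervals.append((0, pos, pos + len(s)))
        parts.append(s)
        pos += len(s)
    return SyntheticTruth(
        spec=spec,
        genomes=["".join(parts)],
        circles=[layout],
        contig_seqs=contig_seqs,
        copies=copies,
        genes=planted,
        repeat_intervals=repeat_intervals,
    )


def _lognormal_factor(rng: np.random.Generator, cv: float) -> float:
    """Unit-mean multiplicative noise with the given coefficient of variation."""
    if cv <= 0:
        return 1.0
    sigma2 = math.log(1.0 + cv * cv)
    return float(rng.lognormal(mean=-sigma2 / 2.0, sigma=math.sqrt(sigma2)))


def make_graph(truth: SyntheticTruth) -> tuple[AssemblyGraph, list[GeneHit]]:
    """Collapse the truth into an assembly graph plus exact-match hit rows.

    Each repeat family becomes one contig at (copies x organelle depth);
    junction links carry the true orientations. Nuclear background
    contigs are unlinked except for the optional NUMT contig, which
    shares a planted homologous block with the organelle and a link into
    its subgraph. Deterministic for a given truth (seeded off the spec).
    """
    spec = truth.spec
    rng = np.random.default_rng([spec.seed, 1])
    graph = AssemblyGraph()
    ov = spec.overlap

    # organelle contigs; in overlap mode extend each contig with the first
    # `overlap` bases of its successor so junctions genuinely share sequence
    succ_prefix: dict[str, str] = {}
    if ov:
        for layout in truth.circles:
            for i, (cid, orient) in enumerate(layout):
                nid, norient = layout[(i + 1) % len(layout)]
                nseq = truth.contig_seqs[nid]
                if norient == "-":
                    nseq = revcomp(nseq)
                succ_prefix[cid] = nseq[:ov]

    for cid in sorted(truth.copies):
        base = truth.contig_seqs[cid]
        seq = base + succ_prefix.get(cid, "") if ov else base
        depth = spec.organelle_depth * truth.copies[cid] * _lognormal_factor(rng, spec.depth_cv)
        graph.add_contig(Contig(id=cid, length=len(seq), depth=depth, sequence=seq))

    for layout in truth.circles:
        n = len(layout)
        rng_junctions = range(n) if spec.kind != "linear" else range(n - 1)
        for i in rng_junctions:
            a, ao = layout[i]
            b, bo = layout[(i + 1) % n]
            graph.add_link(Link(a, ao, b, bo, overlap=ov, support=10))

    # nuclear background
    numt_id = None
    for j in range(spec.n_nuclear_contigs):
        nid = f"n{j}"
        ln = int(rng.integers(5_000, 50_000))
        seq = random_dna(rng, ln)
        depth = spec.nuclear_depth * _lognormal_factor(rng, spec.depth_cv)
        if spec.numt and j == 0:
            numt_id = nid
            depth = (spec.numt_depth or 2.5 * spec.organelle_depth) * _lognormal_factor(rng, spec.depth_cv)
            block = truth.genomes[0][: min(2000, len(truth.genomes[0]))]
            seq = seq[: ln - len(block)] + block
        graph.add_contig(Contig(id=nid, length=len(seq), depth=depth, sequence=seq))
    if numt_id is not None:
        first = truth.circles[0][0]
        graph.add_link(Link(numt_id, "+", first[0], first[1], overlap=0, support=1))

    hits = [
        GeneHit(
            contig_id=g.contig_id,
            gene=g.gene,
            gene_class=g.gene_class,
            start=g.start,
            end=g.end,
            identity=100.0,
            bitscore=2.0 * (g.end - g.start + 1),
        )
        for g in truth.genes
    ]
    hits.sort(key=lambda h: (h.contig_id, h.start, h.end, h.gene))
    return graph, hits


def expected_structure(truth: SyntheticTruth) -> StructureResult:
    """Ground-truth decomposition in the same canonical form resolve emits."""
    paths = []
    for ci, layout in enumerate(truth.circles):
        cyclic = truth.spec.kind != "linear"
        steps = canonical_cycle(layout) if cyclic else tuple(layout)
        usage: dict[str, int] = {}
        for cid, _ in layout:
            usage[cid] = usage.get(cid, 0) + 1
        paths.append(
            BfsPath(
                steps=steps,
                usage=usage,
                total_length=len(truth.genomes[ci]),
                node_count=len(layout),
                path_depth=truth.spec.organelle_depth,
                is_cyclic=cyclic,
            )
        )
    if truth.spec.kind == "linear":
        cls = "linear"
    elif len(paths) == 1:
        cls = "single_circular"
    else:
        cls = "multi_circular"
    return StructureResult(paths=paths, classification=cls, residual={})


def simulate_reads(
    genome: str, coverage: float, read_length: int = 2000, seed: int = 0, circular: bool = True
) -> list[str]:
    """Error-free reads sampled uniformly from a (circular) genome."""
    rng = np.random.default_rng(seed)
    n_reads = math.ceil(coverage * len(genome) / read_length)
    doubled = genome + genome[: read_length - 1] if circular else genome
    max_start = len(genome) if circular else max(len(genome) - read_length, 1)
    starts = rng.integers(0, max_start, size=n_reads)
    return [doubled[s : s + read_length] for s in starts]
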