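"""Strict readers/writers for the file formats the toolkit touches.

Dialects, fixed on purpose:

* GFA 1.0, S and L records only. Segment depth is taken from the first
  available of ``dp:f`` > ``DP:f`` > ``RC:i``/length > the caller's
  default; a segment with no depth source is a hard error. Link overlap
  must be a single-operation match CIGAR (``<n>M``); link support comes
  from ``RC:i`` or ``EC:i`` and defaults to 1 (GFA has no standard
  junction-support tag).
* Gene hits: 12-column tab-separated alignment rows (the ubiquitous
  tabular output dialect: query, subject, identity, length, mismatches,
  gap opens, qstart, qend, sstart, send, evalue, bitscore) where the
  query id is ``<class>|<gene>`` with class in {mt_core, cp_core}.
  Coordinates are 1-based inclusive; minus-strand hits are normalized
  to start <= end with the strand recorded.
* Reports: JSON (machine) plus TSV (human).

Internal path arithmetic elsewhere is 0-based half-open; conversions
happen only here.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Sequence

from .graph import AssemblyGraph, Contig, Link

if TYPE_CHECKING:  # pragma: no cover
    from .assess import AssemblyReport
    from .resolve import StructureResult


class GfaError(ValueError):
    pass


class HitsError(ValueError):
    pass


@dataclass(frozen=True)
class GeneHit:
    """One conserved-gene alignment on a contig (1-based inclusive coords)."""

    contig_id: str
    gene: str
    gene_class: str  # mt_core | cp_core
    start: int
    end: int
    identity: float
    bitscore: float
    strand: str = "+"

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError(f"hit {self.gene}@{self.contig_id}: bad coordinates {self.start}..{self.end}")
        if not 0.0 <= self.identity <= 100.0:
            raise ValueError(f"hit {self.gene}@{self.contig_id}: identity {self.identity} outside [0, 100]")


# ---------------------------------------------------------------------------
# GFA


def _parse_tags(fields: Iterable[str]) -> dict[str, str]:
    tags = {}
    for f in fields:
        parts = f.split(":", 2)
        if len(parts) == 3:
            tags[f"{parts[0]}:{parts[1]}"] = parts[2]
    return tags


def _segment_depth(name: str, length: int, tags: dict[str, str], default_depth: float | None) -> float:
    if "dp:f" in tags:
        return float(tags["dp:f"])
    if "DP:f" in tags:
        return float(tags["DP:f"])
    if "RC:i" in tags:
        return int(tags["RC:i"]) / length
    if default_depth is not None:
        return default_depth
    raise GfaError(f"segment {name}: no depth tag (dp:f/DP:f/RC:i) and no default depth given")


def _parse_overlap(cigar: str, where: str) -> int:
    if not cigar.endswith("M") or not cigar[:-1].isdigit():
        raise GfaError(f"{where}: overlap CIGAR must be '<n>M', got {cigar!r}")
    return int(cigar[:-1])


def read_gfa(path: str | Path, default_depth: float | None = None) -> AssemblyGraph:
    """Load a GFA 1.0 assembly graph (S/L records)."""
    graph = AssemblyGraph()
    pending_links: list[tuple[int, Link]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            rec = fields[0]
            if rec == "S":
                if len(fields) < 3:
                    raise GfaError(f"line {lineno}: malformed S record")
                name, seq = fields[1], fields[2]
                tags = _parse_tags(fields[3:])
                if seq != "*":
                    length = len(seq)
                    sequence = seq.upper()
                elif "LN:i" in tags:
                    length = int(tags["LN:i"])
                    sequence = None
                else:
                    raise GfaError(f"segment {name}: no sequence and no LN:i tag")
                depth = _segment_depth(name, length, tags, default_depth)
                graph.add_contig(Contig(id=name, length=length, depth=depth, sequence=sequence))
            elif rec == "L":
                if len(fields) < 6:
                    raise GfaError(f"line {lineno}: malformed L record")
                overlap = _parse_overlap(fields[5], f"line {lineno}")
                tags = _parse_tags(fields[6:])
                support = int(tags.get("RC:i", tags.get("EC:i", 1)))
                pending_links.append(
                    (lineno, Link(fields[1], fields[2], fields[3], fields[4], overlap=overlap, support=support))
                )
            # H and other records are ignored
    for lineno, link in pending_links:
        try:
            graph.add_link(link)
        except ValueError as exc:
            raise GfaError(f"line {lineno}: {exc}") from None
    return graph


def write_gfa(graph: AssemblyGraph, path: str | Path) -> None:
    """Write GFA 1.0 with dp:f depth tags and RC:i link support, deterministic order."""
    with open(path, "w") as fh:
        fh.write("H\tVN:Z:1.0\n")
        for cid in sorted(graph.contigs):
            c = graph.contigs[cid]
            seq = c.sequence if c.sequence is not None else "*"
            fh.write(f"S\t{c.id}\t{seq}\tLN:i:{c.length}\tdp:f:{c.depth}\n")
        for link in sorted(graph.links, key=lambda l: (l.from_id, l.to_id, l.from_orient, l.to_orient)):
            fh.write(
                f"L\t{link.from_id}\t{link.from_orient}\t{link.to_id}\t{link.to_orient}"
                f"\t{link.overlap}M\tRC:i:{link.support}\n"
            )


# ---------------------------------------------------------------------------
# Gene hits


def read_hits(path: str | Path, min_identity: float = 60.0, max_evalue: float = 1e-5) -> list[GeneHit]:
    """Read a 12-column tabular hits file, filter, and normalize coordinates.

    Rows failing the identity/e-value filters are dropped; hits with
    sstart > send are flipped to start <= end with strand '-'. Output is
    sorted by (contig_id, start, end, gene) so it does not depend on the
    input row order.
    """
    hits: list[GeneHit] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) != 12:
                raise HitsError(f"line {lineno}: expected 12 columns, got {len(f)}")
            if "|" not in f[0]:
                raise HitsError(f"line {lineno}: query id {f[0]!r} lacks '<class>|<gene>' separator")
            gene_class, gene = f[0].split("|", 1)
            identity = float(f[2])
            evalue = float(f[10])
            if identity < min_identity or evalue > max_evalue:
                continue
            sstart, send = int(f[8]), int(f[9])
            strand = "+"
            if sstart > send:
                sstart, send = send, sstart
                strand = "-"
            hits.append(
                GeneHit(
                    contig_id=f[1],
                    gene=gene,
                    gene_class=gene_class,
                    start=sstart,
                    end=send,
                    identity=identity,
                    bitscore=float(f[11]),
                    strand=strand,
                )
            )
    hits.sort(key=lambda h: (h.contig_id, h.start, h.end, h.gene))
    return hits


def write_hits(hits: Sequence[GeneHit], path: str | Path) -> None:
    """Write hits in the same 12-column dialect read_hits consumes."""
    with open(path, "w") as fh:
        for h in hits:
            aln_len = h.end - h.start + 1
            sstart, send = (h.start, h.end) if h.strand == "+" else (h.end, h.start)
            fh.write(
                f"{h.gene_class}|{h.gene}\t{h.contig_id}\t{h.identity}\t{aln_len}\t0\t0"
                f"\t1\t{aln_len}\t{sstart}\t{send}\t0.0\t{h.bitscore}\n"
            )


# ---------------------------------------------------------------------------
# Result emission


def emit_outputs(
    result: "StructureResult",
    graph: AssemblyGraph,
    report: "AssemblyReport",
    outdir: str | Path,
) -> dict[str, Path]:
    """Write the resolved organelle genome and its quality report.

    Produces per-path FASTA (headers encode topology, length and the
    oriented step string), the organelle subgraph as GFA, a per-path
    TSV, and the report as JSON + TSV. FASTA is omitted when the graph
    carries no sequences.
    """
    from .resolve import path_to_sequence, step_string

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    used = sorted({cid for p in result.paths for cid in p.usage})
    have_seqs = used and all(graph.contigs[c].sequence is not None for c in used)

    if have_seqs:
        fasta = outdir / "paths.fasta"
        with open(fasta, "w") as fh:
            for i, p in enumerate(result.paths, 1):
                topo = "circular" if p.is_cyclic else "linear"
                seq = path_to_sequence(p, graph)
                fh.write(
                    f">path_{i:03d} topology={topo} length={p.total_length}"
                    f" nodes={p.node_count} steps={step_string(p.steps)}\n"
                )
                for j in range(0, len(seq), 80):
                    fh.write(seq[j : j + 80] + "\n")
        written["fasta"] = fasta

    if used:
        sub = graph.subgraph(used)
        gfa = outdir / "organelle.gfa"
        write_gfa(sub, gfa)
        written["gfa"] = gfa

    paths_tsv = outdir / "paths.tsv"
    with open(paths_tsv, "w") as fh:
        fh.write("path\ttopology\tlength\tnode_count\tpath_depth\tsteps\n")
        for i, p in enumerate(result.paths, 1):
            topo = "circular" if p.is_cyclic else "linear"
            fh.write(
                f"path_{i:03d}\t{topo}\t{p.total_length}\t{p.node_count}"
                f"\t{p.path_depth:.3f}\t{step_string(p.steps)}\n"
            )
    written["paths_tsv"] = paths_tsv

    report_json = outdir / "report.json"
    report_json.write_text(report.to_json())
    written["report_json"] = report_json

    report_tsv = outdir / "report.tsv"
    report_tsv.write_text(report.to_tsv())
    written["report_tsv"] = report_tsv

    if report.repeat_intervals:
        bed = outdir / "repeats.bed"
        with open(bed, "w") as fh:
            for name, start, end in report.repeat_intervals:
                fh.write(f"{name}\t{start}\t{end}\trepeat\n")
        written["repeats_bed"] = bed
    if report.mtpt_intervals:
        bed = outdir / "mtpt.bed"
        with open(bed, "w") as fh:
            for name, start, end in report.mtpt_intervals:
                fh.write(f"{name}\t{start}\t{end}\tmtpt\n")
        written["mtpt_bed"] = bed
    return written
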