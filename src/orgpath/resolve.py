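"""Repeat-aware decomposition of the organelle subgraph into genome paths.

A repeat-collapsed assembly graph represents each repeat family as a
single contig whose depth is (roughly) the per-copy depth times the copy
number. Structure resolution proceeds in two stages:

1. **Copy numbers.** Each member contig gets an integer multiplicity
   ``m(c) = max(1, round(depth(c) / baseline_depth))`` (half-up), the
   maximum number of times it may be used across all reported paths.

2. **Path search.** Repeatedly: anchor on the longest contig with
   unused copies, grow partial paths outward from both orientations of
   the anchor with a breadth-first frontier. The frontier is keyed by
   (current oriented end, usage multiset) so equivalent partial paths
   collapse, and is beam-limited per level. Extensions respect the
   remaining per-contig copy counts and a per-link capacity equal to the
   smaller endpoint copy number. A path closes cyclically when a link
   re-enters the anchor in its starting orientation, or linearly when it
   cannot extend. The best closed path under the priority order is
   committed, its contig usages are subtracted, and the loop continues.

Priority is lexicographic: cyclic beats linear, then longer total
length, then more nodes, then path depth (the minimum member depth)
closest to the baseline, with the canonical step string as the final
deterministic tie-break. This favors the single master-circle
representation of repeat-mediated multipartite genomes while remaining
fully deterministic.

Cyclic paths are reported in canonical form — rotated to start at the
lexicographically smallest oriented step, in the direction minimizing
the step string — so reruns are byte-identical regardless of where the
search happened to close the circle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .graph import AssemblyGraph, Link, flip
from .sequtils import revcomp

Step = tuple[str, str]


def estimate_copy_numbers(
    graph: AssemblyGraph, member_ids: Iterable[str], baseline_depth: float
) -> dict[str, int]:
    """Per-contig multiplicity m = max(1, round(depth / baseline)), half-up."""
    if baseline_depth <= 0:
        raise ValueError("baseline depth must be positive")
    return {
        cid: max(1, math.floor(graph.contigs[cid].depth / baseline_depth + 0.5))
        for cid in member_ids
    }


def step_string(steps: Sequence[Step]) -> str:
    return ",".join(f"{cid}{o}" for cid, o in steps)


@dataclass
class BfsPath:
    """One resolved walk through the graph."""

    steps: tuple[Step, ...]
    usage: dict[str, int]
    total_length: int
    node_count: int
    path_depth: float
    is_cyclic: bool

    def __post_init__(self) -> None:
        if self.total_length < 1:
            raise ValueError("path total_length must be >= 1")


@dataclass
class StructureResult:
    paths: list[BfsPath]
    classification: str  # single_circular | multi_circular | linear | unresolved_branched
    residual: dict[str, int] = field(default_factory=dict)

    @property
    def total_length(self) -> int:
        return sum(p.total_length for p in self.paths)

    def usage_total(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for p in self.paths:
            for cid, n in p.usage.items():
                out[cid] = out.get(cid, 0) + n
        return out


def path_priority(p: BfsPath, baseline_depth: float) -> tuple:
    """Orderable key; smaller sorts first (= higher priority).

    (linear?, -length, -nodes, |depth - baseline|, canonical step string)
    """
    return (
        0 if p.is_cyclic else 1,
        -p.total_length,
        -p.node_count,
        abs(p.path_depth - baseline_depth),
        step_string(p.steps),
    )


def canonical_cycle(steps: Sequence[Step]) -> tuple[Step, ...]:
    """Canonical rotation/reflection of a cyclic step sequence.

    Among all rotations of the cycle and of its reversed-complemented
    traversal, pick the one with the smallest step string. Link mirror
    symmetry guarantees the reflected traversal is a valid walk.
    """
    steps = tuple(steps)
    n = len(steps)
    reflected = tuple((cid, flip(o)) for cid, o in reversed(steps))
    candidates = []
    for var in (steps, reflected):
        for i in range(n):
            candidates.append(var[i:] + var[:i])
    return min(candidates, key=step_string)


def is_feasible_path(
    graph: AssemblyGraph, steps: Sequence[Step], copy_numbers: dict[str, int], cyclic: bool
) -> bool:
    """Validity predicate: consecutive steps linked, usage within copy numbers."""
    steps = list(steps)
    if not steps:
        return False
    usage: dict[str, int] = {}
    for cid, _ in steps:
        usage[cid] = usage.get(cid, 0) + 1
        if usage[cid] > copy_numbers.get(cid, 0):
            return False
    pairs = list(zip(steps, steps[1:]))
    if cyclic:
        pairs.append((steps[-1], steps[0]))
    for (a, ao), (b, bo) in pairs:
        if graph.find_link(a, ao, b, bo) is None:
            return False
    return True


# ---------------------------------------------------------------------------
# beam search


@dataclass
class _Partial:
    steps: tuple[Step, ...]
    usage: dict[str, int]
    link_usage: dict[tuple, int]
    length: int  # sum of contig lengths minus internal overlaps
    min_depth: float
    start: Step

    def key(self) -> tuple:
        return (self.steps[-1], self.start, tuple(sorted(self.usage.items())))

    def rank(self, baseline_depth: float) -> tuple:
        return (-self.length, -len(self.steps), abs(self.min_depth - baseline_depth), step_string(self.steps))


def _close_cyclic(p: _Partial, closing: Link, graph: AssemblyGraph, baseline: float) -> BfsPath:
    return BfsPath(
        steps=canonical_cycle(p.steps),
        usage=dict(p.usage),
        total_length=p.length - closing.overlap,
        node_count=len(p.steps),
        path_depth=p.min_depth,
        is_cyclic=True,
    )


def _close_linear(p: _Partial) -> BfsPath:
    return BfsPath(
        steps=p.steps,
        usage=dict(p.usage),
        total_length=p.length,
        node_count=len(p.steps),
        path_depth=p.min_depth,
        is_cyclic=False,
    )


def _search_from_anchor(
    graph: AssemblyGraph,
    anchor: str,
    remaining: dict[str, int],
    link_cap: dict[tuple, int],
    baseline_depth: float,
    beam: int,
) -> BfsPath | None:
    """Best closed path (by priority) growing forward from the anchor."""
    closed: list[BfsPath] = []
    anchor_len = graph.contigs[anchor].length
    anchor_depth = graph.contigs[anchor].depth
    frontier: dict[tuple, _Partial] = {}
    for o in ("+", "-"):
        p = _Partial(
            steps=((anchor, o),),
            usage={anchor: 1},
            link_usage={},
            length=anchor_len,
            min_depth=anchor_depth,
            start=(anchor, o),
        )
        frontier[p.key()] = p

    max_steps = sum(remaining.values())
    for _level in range(max_steps + 1):
        if not frontier:
            break
        nxt: dict[tuple, _Partial] = {}
        for p in frontier.values():
            cur_id, cur_o = p.steps[-1]
            extended = False
            for link in graph.neighbors(cur_id, cur_o):
                ekey = link.canonical_key()
                cap = link_cap.get(ekey, 0)
                used = p.link_usage.get(ekey, 0)
                if used + 1 > cap:
                    continue
                nid, no = link.to_id, link.to_orient
                if (nid, no) == p.start and len(p.steps) >= 1:
                    closed.append(_close_cyclic(p, link, graph, baseline_depth))
                if p.usage.get(nid, 0) + 1 <= remaining.get(nid, 0):
                    extended = True
                    usage = dict(p.usage)
                    usage[nid] = usage.get(nid, 0) + 1
                    lu = dict(p.link_usage)
                    lu[ekey] = used + 1
                    q = _Partial(
                        steps=p.steps + ((nid, no),),
                        usage=usage,
                        link_usage=lu,
                        length=p.length + graph.contigs[nid].length - link.overlap,
                        min_depth=min(p.min_depth, graph.contigs[nid].depth),
                        start=p.start,
                    )
                    k = q.key()
                    old = nxt.get(k)
                    if old is None or q.rank(baseline_depth) < old.rank(baseline_depth):
                        nxt[k] = q
            if not extended:
                closed.append(_close_linear(p))
        if len(nxt) > beam:
            kept = sorted(nxt.values(), key=lambda q: q.rank(baseline_depth))[:beam]
            nxt = {q.key(): q for q in kept}
        frontier = nxt

    if not closed:
        return None
    return min(closed, key=lambda bp: path_priority(bp, baseline_depth))


def resolve_structure(
    graph: AssemblyGraph,
    copy_numbers: dict[str, int],
    baseline_depth: float,
    beam: int = 64,
) -> StructureResult:
    """Greedy commit-and-subtract decomposition of the member subgraph.

    ``graph`` must already be restricted to the expansion members (the
    pipeline passes the induced member subgraph). Copies the search
    cannot place — leftover multiplicities of contigs that already
    appear in committed paths — are reported as residual rather than
    emitted as junk single-contig paths.
    """
    if not copy_numbers:
        raise ValueError("no member contigs to resolve")
    for cid in copy_numbers:
        if cid not in graph.contigs:
            raise ValueError(f"copy-number contig not in graph: {cid}")

    remaining = dict(copy_numbers)
    link_cap: dict[tuple, int] = {}
    for link in graph.links:
        k = link.canonical_key()
        link_cap[k] = min(copy_numbers.get(link.from_id, 0), copy_numbers.get(link.to_id, 0))

    paths: list[BfsPath] = []
    residual: dict[str, int] = {}
    used_ever: set[str] = set()

    while True:
        live = [cid for cid, m in remaining.items() if m > 0]
        if not live:
            break
        anchor = max(live, key=lambda cid: (graph.contigs[cid].length, cid))
        best = _search_from_anchor(graph, anchor, remaining, link_cap, baseline_depth, beam)
        if best is None:
            residual[anchor] = remaining[anchor]
            remaining[anchor] = 0
            continue
        if not best.is_cyclic and best.node_count == 1 and anchor in used_ever:
            # leftover copy of an already-placed repeat: unplaceable, not a path
            residual[anchor] = remaining[anchor]
            remaining[anchor] = 0
            continue
        for cid, n in best.usage.items():
            remaining[cid] -= n
            used_ever.add(cid)
        paths.append(best)

    if residual:
        classification = "unresolved_branched"
    elif any(not p.is_cyclic for p in paths):
        classification = "linear"
    elif len(paths) == 1:
        classification = "single_circular"
    else:
        classification = "multi_circular"
    return StructureResult(paths=paths, classification=classification, residual=residual)


# ---------------------------------------------------------------------------
# sequence reconstruction


def path_to_sequence(p: BfsPath, graph: AssemblyGraph) -> str:
    """Spell out a path's DNA, trimming link overlaps from each successor.

    For cyclic paths the closing link's overlap is trimmed from the end,
    so the returned length always equals ``p.total_length``.
    """
    parts: list[str] = []
    for i, (cid, o) in enumerate(p.steps):
        contig = graph.contigs[cid]
        if contig.sequence is None:
            raise ValueError(f"contig {cid} carries no sequence")
        seq = contig.sequence if o == "+" else revcomp(contig.sequence)
        if i > 0:
            prev_id, prev_o = p.steps[i - 1]
            link = graph.find_link(prev_id, prev_o, cid, o)
            if link is None:
                raise ValueError(f"no link between consecutive steps {prev_id}{prev_o} -> {cid}{o}")
            seq = seq[link.overlap :]
        parts.append(seq)
    out = "".join(parts)
    if p.is_cyclic:
        first_id, first_o = p.steps[0]
        last_id, last_o = p.steps[-1]
        link = graph.find_link(last_id, last_o, first_id, first_o)
        if link is None:
            raise ValueError(f"no closing link {last_id}{last_o} -> {first_id}{first_o}")
        if link.overlap:
            out = out[: -link.overlap]
    if len(out) != p.total_length:
        raise AssertionError(
            f"reconstructed length {len(out)} != declared total_length {p.total_length}"
        )
    return out
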