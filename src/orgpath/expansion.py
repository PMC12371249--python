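"""Breadth-first seed expansion of the organelle subgraph.

Starting from the ranked seed contigs, a multi-source FIFO breadth-first
traversal grows the candidate organelle subgraph. A link is traversable
only if its junction support meets the profile's minimum. Each newly
reached contig is admitted or excluded by a depth filter whose form
depends on the target:

* plastome (pt): exclude contigs whose depth falls below
  ``plastome_low_frac`` (default 0.3) times the depth of the matched
  seed — the seed whose BFS tree reached the contig first (ties broken
  toward the higher-scoring seed);
* mitogenome (mt): exclude contigs whose depth exceeds
  ``mito_high_mult`` (default 2.0) times the baseline genome depth.

Both boundaries are strict on the exclusion side ("below" / "exceeding"),
i.e. a contig sitting exactly on the threshold is retained. Excluded
contigs block traversal: the expansion never crosses them, which stops
nuclear bridges from leaking the frontier into the nuclear graph. Seeds
themselves are exempt from the filters (they define the baseline).
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

from .graph import AssemblyGraph, Contig
from .scoring import LineageProfile, SeedSet

LOW_DEPTH_PT = "low_depth_pt"
HIGH_DEPTH_MT = "high_depth_mt"
LOW_LINK_SUPPORT = "low_link_support"
UNREACHABLE = "unreachable"


@dataclass
class ExpansionResult:
    members: set[str]
    member_links: list
    matched_seed: dict[str, str]
    excluded: dict[str, str] = field(default_factory=dict)


def passes_depth_filter(
    contig: Contig,
    target: str,
    seed_depth: float,
    baseline_depth: float,
    profile: LineageProfile,
) -> tuple[bool, str | None]:
    """Apply the target-specific depth rule; returns (pass, reason-if-not)."""
    if target == "pt":
        if seed_depth <= 0:
            raise ValueError("seed depth must be positive for pt filtering")
        if contig.depth < profile.plastome_low_frac * seed_depth:
            return False, LOW_DEPTH_PT
        return True, None
    if target == "mt":
        if baseline_depth <= 0:
            raise ValueError("baseline depth must be positive for mt filtering")
        if contig.depth > profile.mito_high_mult * baseline_depth:
            return False, HIGH_DEPTH_MT
        return True, None
    raise ValueError(f"unknown target: {target}")


def bfs_expand(
    graph: AssemblyGraph,
    seeds: SeedSet,
    target: str,
    profile: LineageProfile,
) -> ExpansionResult:
    """Multi-source BFS from all seeds with depth and link-support filters.

    Seeds are enqueued in rank order, so when two seeds reach a contig at
    the same BFS depth the higher-ranked seed claims it (the documented
    "best-matching seed" tie-break).
    """
    if not seeds.ids:
        raise ValueError("seed set is empty")

    members: set[str] = set()
    matched: dict[str, str] = {}
    excluded: dict[str, str] = {}
    queue: deque[str] = deque()

    for sid in seeds.ids:
        if sid not in graph.contigs:
            raise ValueError(f"seed contig not in graph: {sid}")
        if sid not in matched:
            matched[sid] = sid
            members.add(sid)
            queue.append(sid)

    while queue:
        cid = queue.popleft()
        for orient in ("+", "-"):
            for link in graph.neighbors(cid, orient):
                if link.support < profile.min_link_support:
                    continue
                nid = link.to_id
                if nid in matched or nid in excluded:
                    continue
                seed_id = matched[cid]
                seed_depth = graph.contigs[seed_id].depth
                ok, reason = passes_depth_filter(
                    graph.contigs[nid], target, seed_depth, seeds.baseline_depth, profile
                )
                if ok:
                    matched[nid] = seed_id
                    members.add(nid)
                    queue.append(nid)
                else:
                    excluded[nid] = reason

    # classify everything the traversal never decided
    for cid in graph.contigs:
        if cid in matched or cid in excluded:
            continue
        weakly_attached = False
        for orient in ("+", "-"):
            for link in graph.neighbors(cid, orient):
                if link.support < profile.min_link_support and link.to_id in members:
                    weakly_attached = True
        excluded[cid] = LOW_LINK_SUPPORT if weakly_attached else UNREACHABLE

    member_links = [
        l
        for l in graph.links
        if l.from_id in members and l.to_id in members and l.support >= profile.min_link_support
    ]
    return ExpansionResult(
        members=members, member_links=member_links, matched_seed=matched, excluded=excluded
    )


def write_exclusions_tsv(result: ExpansionResult, graph: AssemblyGraph, path) -> None:
    """Exclusion diagnostics as TSV: contig id, depth, reason."""
    with open(path, "w") as fh:
        fh.write("contig\tdepth\treason\n")
        for cid in sorted(result.excluded):
            fh.write(f"{cid}\t{graph.contigs[cid].depth}\t{result.excluded[cid]}\n")
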