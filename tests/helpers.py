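"""Independent brute-force oracles and small graph builders for tests.

Every oracle here is deliberately written with a different algorithmic
route than the implementation it checks (string scanning instead of
k-mer hashing, exhaustive enumeration instead of beam search,
plain reachability instead of filtered BFS).
"""

from __future__ import annotations

from orgpath.graph import AssemblyGraph, Contig, Link
from orgpath.resolve import BfsPath, canonical_cycle, path_priority
from orgpath.sequtils import revcomp


def build_graph(contigs, links):
    """contigs: (id, length, depth[, seq]); links: (a, ao, b, bo[, overlap[, support]])."""
    g = AssemblyGraph()
    for c in contigs:
        cid, ln, dp = c[:3]
        seq = c[3] if len(c) > 3 else None
        g.add_contig(Contig(cid, ln, dp, sequence=seq))
    for l in links:
        a, ao, b, bo = l[:4]
        ov = l[4] if len(l) > 4 else 0
        sup = l[5] if len(l) > 5 else 1
        g.add_link(Link(a, ao, b, bo, overlap=ov, support=sup))
    return g


# ---------------------------------------------------------------------------
# repeat oracle: brute force over all substring pairs via str.count


def repeat_covered_bp_bruteforce(sequences, min_len=30):
    """Union bp covered by exact repeats > min_len, by scanning every window
    of length min_len+1 against the concatenated forward text.

    A window belongs to a qualifying repeat iff it plus its reverse
    complement occur at least twice in total; str.count does the scanning.
    """
    w = min_len + 1
    seqs = [s.upper() for s in sequences]
    text = "#".join(seqs)
    total = 0
    for s in seqs:
        covered = [False] * len(s)
        for i in range(len(s) - w + 1):
            sub = s[i : i + w]
            if "N" in sub:
                continue
            # occurrences of the window plus of its reverse complement,
            # across all forward sequences (w is odd, so sub != revcomp(sub))
            if text.count(sub) + text.count(revcomp(sub)) >= 2:
                for j in range(i, i + w):
                    covered[j] = True
        total += sum(covered)
    return total


def shares_kmer(a, b, k=31):
    """True iff a and b share any k-mer directly or via reverse complement."""
    kmers = {a[i : i + k] for i in range(len(a) - k + 1)}
    brc = revcomp(b)
    return any(b.find(km) >= 0 or brc.find(km) >= 0 for km in kmers)


# ---------------------------------------------------------------------------
# expansion oracle: plain reachability with the filter as a node predicate


def reachable_members_oracle(graph, seed_ids, node_pass, min_support=1):
    """Transitive closure over passing nodes from the seeds; seeds exempt."""
    members = set(seed_ids)
    frontier = list(seed_ids)
    while frontier:
        cid = frontier.pop()
        for orient in "+-":
            for link in graph.neighbors(cid, orient):
                if link.support < min_support:
                    continue
                n = link.to_id
                if n in members or not node_pass(n):
                    continue
                members.add(n)
                frontier.append(n)
    return members


# ---------------------------------------------------------------------------
# resolve oracle: exhaustive anchor-rooted path enumeration (no beam)


def enumerate_closed_paths(graph, anchor, remaining, link_cap, baseline):
    """All capacity-respecting closed paths growing forward from the anchor.

    Cyclic closure on re-entering the anchor's starting orientation;
    linear closure when no extension is feasible. Exhaustive DFS —
    only usable on small graphs.
    """
    results = []

    def walk(steps, usage, link_usage, length, min_depth, start):
        cur_id, cur_o = steps[-1]
        extended = False
        for link in graph.neighbors(cur_id, cur_o):
            ek = link.canonical_key()
            if link_usage.get(ek, 0) + 1 > link_cap.get(ek, 0):
                continue
            tgt = (link.to_id, link.to_orient)
            if tgt == start:
                results.append(
                    BfsPath(
                        steps=canonical_cycle(steps),
                        usage=dict(usage),
                        total_length=length - link.overlap,
                        node_count=len(steps),
                        path_depth=min_depth,
                        is_cyclic=True,
                    )
                )
            if usage.get(link.to_id, 0) + 1 <= remaining.get(link.to_id, 0):
                extended = True
                usage2 = dict(usage)
                usage2[link.to_id] = usage2.get(link.to_id, 0) + 1
                lu2 = dict(link_usage)
                lu2[ek] = lu2.get(ek, 0) + 1
                walk(
                    steps + [tgt],
                    usage2,
                    lu2,
                    length + graph.contigs[link.to_id].length - link.overlap,
                    min(min_depth, graph.contigs[link.to_id].depth),
                    start,
                )
        if not extended:
            results.append(
                BfsPath(
                    steps=tuple(steps),
                    usage=dict(usage),
                    total_length=length,
                    node_count=len(steps),
                    path_depth=min_depth,
                    is_cyclic=False,
                )
            )

    for o in "+-":
        start = (anchor, o)
        walk([start], {anchor: 1}, {}, graph.contigs[anchor].length, graph.contigs[anchor].depth, start)
    return results


def decompose_oracle(graph, copy_numbers, baseline):
    """Greedy decomposition with exhaustive (beam-free) per-step search:
    at every step the committed path is the true priority-maximal closed
    path from the longest remaining anchor."""
    remaining = dict(copy_numbers)
    link_cap = {
        l.canonical_key(): min(copy_numbers.get(l.from_id, 0), copy_numbers.get(l.to_id, 0))
        for l in graph.links
    }
    committed = []
    used_ever = set()
    while True:
        live = [c for c, m in remaining.items() if m > 0]
        if not live:
            break
        anchor = max(live, key=lambda c: (graph.contigs[c].length, c))
        cands = enumerate_closed_paths(graph, anchor, remaining, link_cap, baseline)
        if not cands:
            remaining[anchor] = 0
            continue
        best = min(cands, key=lambda p: path_priority(p, baseline))
        if not best.is_cyclic and best.node_count == 1 and anchor in used_ever:
            remaining[anchor] = 0
            continue
        for cid, n in best.usage.items():
            remaining[cid] -= n
            used_ever.add(cid)
        committed.append(best)
    return committed


def random_small_graph(rng, max_nodes=8, max_total_copies=12):
    """Random connected oriented graph with copy numbers for oracle tests."""
    n = int(rng.integers(2, max_nodes + 1))
    ids = [f"v{i}" for i in range(n)]
    copy_numbers = {}
    budget = max_total_copies - n
    for cid in ids:
        extra = int(rng.integers(0, 3)) if budget > 0 else 0
        extra = min(extra, budget)
        budget -= extra
        copy_numbers[cid] = 1 + extra
    g = AssemblyGraph()
    for cid in ids:
        ln = int(rng.integers(500, 5000))
        g.add_contig(Contig(cid, ln, 100.0 * copy_numbers[cid], sequence=None))
    # random spanning chain keeps it connected, plus extra random links
    order = list(rng.permutation(n))
    for i in range(n - 1):
        a, b = ids[order[i]], ids[order[i + 1]]
        g.add_link(Link(a, str(rng.choice(["+", "-"])), b, str(rng.choice(["+", "-"]))))
    for _ in range(int(rng.integers(0, n + 2))):
        a, b = rng.choice(ids, size=2)
        try:
            g.add_link(Link(str(a), str(rng.choice(["+", "-"])), str(b), str(rng.choice(["+", "-"]))))
        except ValueError:
            pass
    return g, copy_numbers
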