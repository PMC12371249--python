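"""Assembly-graph data model: contigs, oriented links, adjacency index.

The graph is the substrate for seed expansion and structure resolution.
Links follow GFA semantics: a link (a, x) -> (b, y) means a walk that
traverses contig ``a`` in orientation ``x`` may continue into contig
``b`` in orientation ``y``, with ``overlap`` shared bases at the
junction. Every link is traversable in reverse as (b, !y) -> (a, !x);
links are stored in a canonical form and the adjacency index synthesizes
the mirror direction, so the stored set is closed under that symmetry.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Iterator


def flip(orient: str) -> str:
    return "-" if orient == "+" else "+"


@dataclass
class Contig:
    """One assembled sequence (GFA segment).

    depth is the mean read coverage; cp_tagged flags contigs identified
    as chloroplast-derived (relevant when assembling plant mitogenomes,
    where plastid-derived inserts are common).
    """

    id: str
    length: int
    depth: float
    sequence: str | None = None
    cp_tagged: bool = False

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError(f"contig {self.id}: length must be >= 1, got {self.length}")
        if self.depth < 0:
            raise ValueError(f"contig {self.id}: depth must be >= 0, got {self.depth}")
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValueError(
                f"contig {self.id}: sequence length {len(self.sequence)} != declared length {self.length}"
            )


@dataclass(frozen=True)
class Link:
    """Oriented adjacency between two contig ends."""

    from_id: str
    from_orient: str
    to_id: str
    to_orient: str
    overlap: int = 0
    support: int = 1

    def __post_init__(self) -> None:
        if self.from_orient not in "+-" or self.to_orient not in "+-":
            raise ValueError(f"bad orientation in link {self}")
        if self.overlap < 0:
            raise ValueError(f"link {self}: overlap must be >= 0")
        if self.support < 0:
            raise ValueError(f"link {self}: support must be >= 0")

    @property
    def mirror_tuple(self) -> tuple[str, str, str, str]:
        return (self.to_id, flip(self.to_orient), self.from_id, flip(self.from_orient))

    @property
    def ends_tuple(self) -> tuple[str, str, str, str]:
        return (self.from_id, self.from_orient, self.to_id, self.to_orient)

    def canonical_key(self) -> tuple[str, str, str, str, int]:
        """Identity of the undirected edge (both traversal directions share it)."""
        return min(self.ends_tuple, self.mirror_tuple) + (self.overlap,)


class AssemblyGraph:
    """Contigs plus oriented links with a constant-time adjacency index."""

    def __init__(self) -> None:
        self.contigs: dict[str, Contig] = {}
        self._links: dict[tuple, Link] = {}
        self._adj: dict[tuple[str, str], list[Link]] = {}

    # -- construction -------------------------------------------------

    def add_contig(self, contig: Contig) -> None:
        if contig.id in self.contigs:
            raise ValueError(f"duplicate contig id: {contig.id}")
        self.contigs[contig.id] = contig

    def add_link(self, link: Link) -> None:
        for cid in (link.from_id, link.to_id):
            if cid not in self.contigs:
                raise ValueError(f"link references unknown contig: {cid}")
        key = link.canonical_key()
        if key in self._links:
            # duplicate edge (e.g. both directions present in a file): keep max support
            old = self._links[key]
            if link.support > old.support:
                self._links[key] = replace(old, support=link.support)
                self.rebuild_adjacency()
            return
        if link.ends_tuple != key[:4]:
            link = Link(*key[:4], overlap=link.overlap, support=link.support)
        self._links[key] = link
        self._index_link(link)

    def _index_link(self, link: Link) -> None:
        self._adj.setdefault((link.from_id, link.from_orient), []).append(link)
        mt = link.mirror_tuple
        if mt != link.ends_tuple:
            mirror = Link(*mt, overlap=link.overlap, support=link.support)
            self._adj.setdefault((mirror.from_id, mirror.from_orient), []).append(mirror)

    def rebuild_adjacency(self) -> None:
        """Recompute the oriented-end index from the link set."""
        self._adj = {}
        for link in self._links.values():
            self._index_link(link)

    # -- access -------------------------------------------------------

    @property
    def links(self) -> list[Link]:
        """Canonical links in deterministic order."""
        return [self._links[k] for k in sorted(self._links)]

    def neighbors(self, contig_id: str, orient: str) -> list[Link]:
        """Outgoing links from the oriented end of a contig, deterministic order."""
        out = self._adj.get((contig_id, orient), [])
        return sorted(out, key=lambda l: (l.to_id, l.to_orient))

    def find_link(self, a: str, ao: str, b: str, bo: str) -> Link | None:
        for link in self._adj.get((a, ao), []):
            if link.to_id == b and link.to_orient == bo:
                return link
        return None

    def degree(self, contig_id: str) -> int:
        return len(self._adj.get((contig_id, "+"), [])) + len(self._adj.get((contig_id, "-"), []))

    def subgraph(self, ids: Iterable[str], min_support: int = 0) -> "AssemblyGraph":
        """Induced subgraph on ``ids`` keeping links with support >= min_support."""
        keep = set(ids)
        sub = AssemblyGraph()
        for cid in sorted(keep):
            sub.add_contig(self.contigs[cid])
        for link in self.links:
            if link.from_id in keep and link.to_id in keep and link.support >= min_support:
                sub.add_link(link)
        return sub

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AssemblyGraph):
            return NotImplemented
        return self.contigs == other.contigs and self._links == other._links

    def __iter__(self) -> Iterator[Contig]:
        return iter(self.contigs.values())

    def __len__(self) -> int:
        return len(self.contigs)
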