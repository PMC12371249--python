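"""Composite contig scoring and organelle seed selection.

Each contig gets three component scores — sequencing depth, length, and
conserved-gene content — individually normalized through a sigmoid
centered on the robust location/scale of that component across all
contigs, then combined as a weighted mean. Gene content is weighted
above length so that large nuclear contigs carrying homologous sequence
do not outrank genuine organelle contigs. In plant mitogenome runs,
contigs that look chloroplast-derived (cp-core hits covering most of
the contig) have their gene component down-weighted, which suppresses
plastid and MTPT-dominated contigs without discarding them.

The depth and length components are log10-transformed before
normalization: both quantities span orders of magnitude across a
whole-genome graph, and the log scale makes the median/IQR location
estimates meaningful.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .formats import GeneHit
from .graph import AssemblyGraph


class NoSeedError(RuntimeError):
    """No contig passed the seed threshold; carries the best rejected score."""


# Core gene sets bundled per lineage. The animal set is the canonical 13
# mitochondrial protein-coding genes; fungi typically lack atp8 but carry
# rps3; the plant mitochondrial set is the 24 conserved core genes; the
# plastid set covers the universally retained photosynthesis/expression
# genes used to recognize chloroplast-derived sequence.
ANIMAL_MT_CORE = frozenset(
    ["nad1", "nad2", "nad3", "nad4", "nad4L", "nad5", "nad6", "cox1", "cox2", "cox3", "cob", "atp6", "atp8"]
)
FUNGUS_MT_CORE = (ANIMAL_MT_CORE - {"atp8"}) | {"rps3"}
PLANT_MT_CORE = frozenset(
    [
        "atp1", "atp4", "atp6", "atp8", "atp9",
        "ccmB", "ccmC", "ccmFc", "ccmFn",
        "cob", "cox1", "cox2", "cox3",
        "matR", "mttB",
        "nad1", "nad2", "nad3", "nad4", "nad4L", "nad5", "nad6", "nad7", "nad9",
    ]
)
PLANT_CP_CORE = frozenset(
    [
        "rbcL", "matK", "psaA", "psaB", "psbA", "psbB", "psbC", "psbD",
        "atpA", "atpB", "atpE", "atpF", "atpH", "atpI",
        "rpoA", "rpoB", "rpoC1", "rpoC2", "petA", "petB", "petD",
    ]
)


@dataclass(frozen=True)
class LineageProfile:
    """Scoring/expansion parameters for one lineage x target combination.

    Weights must sum to 1 with w_gene > w_length (gene content is
    prioritized over contig length). mtpt_penalty is the multiplier
    applied to the gene weight of chloroplast-tagged contigs in plant
    mitogenome runs. plastome_low_frac and mito_high_mult are the dual
    depth-filter thresholds used during seed expansion (fractions of the
    matched seed depth and of the baseline genome depth respectively).
    """

    lineage: str  # plant | animal | fungus
    target: str  # mt | pt
    core_genes: frozenset[str]
    w_depth: float
    w_length: float
    w_gene: float
    mtpt_penalty: float = 0.5
    seed_score_threshold: float = 0.6
    plastome_low_frac: float = 0.3
    mito_high_mult: float = 2.0
    min_link_support: int = 1

    def __post_init__(self) -> None:
        if self.lineage not in ("plant", "animal", "fungus"):
            raise ValueError(f"unknown lineage: {self.lineage}")
        if self.target not in ("mt", "pt"):
            raise ValueError(f"unknown target: {self.target}")
        if abs(self.w_depth + self.w_length + self.w_gene - 1.0) > 1e-9:
            raise ValueError("scoring weights must sum to 1")
        if min(self.w_depth, self.w_length, self.w_gene) < 0:
            raise ValueError("scoring weights must be non-negative")
        if not self.w_gene > self.w_length:
            raise ValueError("gene-content weight must exceed length weight")
        if not self.core_genes:
            raise ValueError("core gene set must be non-empty")
        if not 0 < self.mtpt_penalty <= 1:
            raise ValueError("mtpt_penalty must be in (0, 1]")
        if not 0 < self.seed_score_threshold < 1:
            raise ValueError("seed_score_threshold must be in (0, 1)")

    @property
    def target_class(self) -> str:
        return f"{self.target}_core"


_PRESETS: dict[tuple[str, str], tuple[frozenset[str], float, float, float]] = {
    ("plant", "mt"): (PLANT_MT_CORE, 0.30, 0.20, 0.50),
    ("plant", "pt"): (PLANT_CP_CORE, 0.35, 0.15, 0.50),
    ("animal", "mt"): (ANIMAL_MT_CORE, 0.40, 0.20, 0.40),
    ("fungus", "mt"): (FUNGUS_MT_CORE, 0.40, 0.20, 0.40),
}


def parse_profile_config(path) -> dict:
    """Read ``key = value`` profile overrides from a config file.

    Recognized keys are LineageProfile fields; ``core_genes`` takes a
    comma-separated gene list. Blank lines and '#' comments are skipped.
    """
    overrides: dict = {}
    numeric = {
        "w_depth", "w_length", "w_gene", "mtpt_penalty", "seed_score_threshold",
        "plastome_low_frac", "mito_high_mult",
    }
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, value = (part.strip() for part in line.split("=", 1))
            if key in numeric:
                overrides[key] = float(value)
            elif key == "min_link_support":
                overrides[key] = int(value)
            elif key == "core_genes":
                overrides[key] = frozenset(g.strip() for g in value.split(",") if g.strip())
            elif key in ("lineage", "target"):
                overrides[key] = value
            else:
                raise ValueError(f"{path}:{lineno}: unknown profile key {key!r}")
    return overrides


def get_profile(lineage: str, target: str, **overrides) -> LineageProfile:
    """Bundled lineage preset, optionally overridden field-by-field."""
    try:
        core, wd, wl, wg = _PRESETS[(lineage, target)]
    except KeyError:
        raise ValueError(f"no preset for lineage={lineage!r}, target={target!r}") from None
    prof = LineageProfile(lineage=lineage, target=target, core_genes=core, w_depth=wd, w_length=wl, w_gene=wg)
    return replace(prof, **overrides) if overrides else prof


@dataclass(frozen=True)
class ContigScore:
    contig_id: str
    s_depth: float
    s_length: float
    s_gene: float
    cp_tagged: bool
    composite: float
    length: int
    depth: float
    n_target_genes: int


@dataclass(frozen=True)
class SeedSet:
    """Ranked seed contigs plus the baseline organelle depth estimate.

    baseline_depth is the length-weighted mean depth of the selected
    seeds; downstream it serves as the estimated average genome depth.
    """

    seeds: tuple[ContigScore, ...]
    baseline_depth: float

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(s.contig_id for s in self.seeds)

    def composite_of(self, contig_id: str) -> float:
        for s in self.seeds:
            if s.contig_id == contig_id:
                return s.composite
        raise KeyError(contig_id)


def sigmoid_normalize(x: float, center: float, scale: float) -> float:
    """Logistic squashing 1 / (1 + exp(-(x - center)/scale)), in (0, 1)."""
    if scale <= 0:
        raise ValueError("scale must be positive")
    z = (x - center) / scale
    # guard against overflow for extreme inputs
    if z >= 0:
        return 1.0 / (1.0 + math.exp(-z))
    ez = math.exp(z)
    return ez / (1.0 + ez)


def robust_center_scale(values: np.ndarray) -> tuple[float, float]:
    """Median and IQR/1.349 (the Gaussian-consistent robust sigma).

    Falls back to max(|median|, 1) when the IQR degenerates to zero.
    """
    center = float(np.median(values))
    q75, q25 = np.percentile(values, [75, 25])
    scale = float(q75 - q25) / 1.349
    if scale <= 0:
        scale = max(abs(center), 1.0)
    return center, scale


def _covered_fraction(intervals: list[tuple[int, int]], length: int) -> float:
    """Fraction of [1, length] covered by 1-based inclusive intervals."""
    if not intervals:
        return 0.0
    intervals = sorted(intervals)
    covered = 0
    cur_s, cur_e = intervals[0]
    for s, e in intervals[1:]:
        if s <= cur_e + 1:
            cur_e = max(cur_e, e)
        else:
            covered += cur_e - cur_s + 1
            cur_s, cur_e = s, e
    covered += cur_e - cur_s + 1
    return min(covered / length, 1.0)


def score_contigs(graph: AssemblyGraph, hits: list[GeneHit], profile: LineageProfile) -> list[ContigScore]:
    """Composite scores for every contig, sorted by contig id.

    The raw gene component is (distinct target-class core genes hit) +
    (fraction of contig bases covered by such hits), so it separates
    multi-gene organelle contigs from contigs with a single short
    homologous stretch. cp_tagged is set in plant-mt runs when cp-core
    hits cover at least half of the contig.
    """
    if not graph.contigs:
        raise ValueError("empty graph: nothing to score")

    by_contig: dict[str, list[GeneHit]] = {}
    for h in hits:
        by_contig.setdefault(h.contig_id, []).append(h)

    ids = sorted(graph.contigs)
    raw_gene = np.empty(len(ids))
    raw_depth = np.empty(len(ids))
    raw_len = np.empty(len(ids))
    cp_flags: list[bool] = []
    n_genes: list[int] = []

    for i, cid in enumerate(ids):
        c = graph.contigs[cid]
        chits = by_contig.get(cid, [])
        tgt = [h for h in chits if h.gene_class == profile.target_class and h.gene in profile.core_genes]
        distinct = len({h.gene for h in tgt})
        frac = _covered_fraction([(min(h.start, c.length), min(h.end, c.length)) for h in tgt], c.length)
        raw_gene[i] = distinct + frac
        raw_depth[i] = math.log10(max(c.depth, 1e-9))
        raw_len[i] = math.log10(c.length)
        tagged = False
        if profile.lineage == "plant" and profile.target == "mt":
            cp = [h for h in chits if h.gene_class == "cp_core"]
            cp_frac = _covered_fraction([(min(h.start, c.length), min(h.end, c.length)) for h in cp], c.length)
            tagged = cp_frac >= 0.5 or c.cp_tagged
        cp_flags.append(tagged)
        n_genes.append(distinct)

    cd, sd = robust_center_scale(raw_depth)
    cl, sl = robust_center_scale(raw_len)
    cg, sg = robust_center_scale(raw_gene)

    scores = []
    for i, cid in enumerate(ids):
        s_depth = sigmoid_normalize(raw_depth[i], cd, sd)
        s_length = sigmoid_normalize(raw_len[i], cl, sl)
        s_gene = sigmoid_normalize(raw_gene[i], cg, sg)
        gene_w = profile.w_gene * (profile.mtpt_penalty if cp_flags[i] else 1.0)
        composite = profile.w_depth * s_depth + profile.w_length * s_length + gene_w * s_gene
        c = graph.contigs[cid]
        scores.append(
            ContigScore(
                contig_id=cid,
                s_depth=s_depth,
                s_length=s_length,
                s_gene=s_gene,
                cp_tagged=cp_flags[i],
                composite=composite,
                length=c.length,
                depth=c.depth,
                n_target_genes=n_genes[i],
            )
        )
    return scores


def rank_scores(scores: list[ContigScore]) -> list[ContigScore]:
    """Composite descending; ties broken by longer length then id."""
    return sorted(scores, key=lambda s: (-s.composite, -s.length, s.contig_id))


def select_seeds(scores: list[ContigScore], profile: LineageProfile, max_seeds: int = 5) -> SeedSet:
    """Top-ranked contigs passing the composite threshold and carrying
    at least one distinct target-class core gene.
    """
    if not scores:
        raise ValueError("no scores given")
    ranked = rank_scores(scores)
    qualifying = [
        s for s in ranked if s.composite >= profile.seed_score_threshold and s.n_target_genes >= 1
    ]
    if not qualifying:
        best = ranked[0]
        raise NoSeedError(
            f"no seed contigs: best candidate {best.contig_id} scored "
            f"{best.composite:.4f} (threshold {profile.seed_score_threshold}, "
            f"{best.n_target_genes} core genes)"
        )
    chosen = tuple(qualifying[:max_seeds])
    total_len = sum(s.length for s in chosen)
    baseline = sum(s.length * s.depth for s in chosen) / total_len
    return SeedSet(seeds=chosen, baseline_depth=baseline)
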