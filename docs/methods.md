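# Methods

This note documents the models and procedures implemented in `orgpath`,
the defaults and why they were chosen, what the synthetic generator does
and does not emulate, and the package's known limitations.

## Data model and formats

The assembly graph follows GFA 1.0 semantics: contigs (segments) carry a
length, a mean read depth, and optionally a sequence; links are oriented
adjacencies `(a, x) → (b, y)` with a non-negative overlap and a junction
support count. Every link is traversable in reverse as `(b, ¬y) → (a,
¬x)`; links are stored once in a canonical orientation and the adjacency
index synthesizes the mirror, so the link set is closed under that
symmetry by construction.

Dialect decisions, fixed deliberately:

* Segment depth is read from the first available of `dp:f` > `DP:f` >
  `RC:i`/length > a caller-supplied default. This ordering covers the
  tag conventions of the common long-read assemblers; first match wins.
* A segment with no depth source is a hard error, as is a link overlap
  CIGAR that is not a single `<n>M` operation, and a link naming an
  undeclared segment. Silent graph corruption is considered worse than
  a failed load.
* Link support defaults to 1 when untagged (`RC:i`/`EC:i` read when
  present); GFA has no standard junction-support tag, and defaulting to
  1 keeps the link-support filter meaningful without inventing data.
* Gene hits use the ubiquitous 12-column tabular alignment dialect with
  query ids of the form `<class>|<gene>` (`mt_core` or `cp_core`).
  Coordinates are 1-based inclusive; minus-strand hits are normalized to
  `start ≤ end` because scoring uses only gene presence and coverage.
  Internally all path arithmetic is 0-based half-open; conversions
  happen only in the format layer.

## Seed scoring

Each contig receives three component scores — depth, length, gene
content — normalized through a logistic function
`σ(x) = 1/(1 + e^{-(x-c)/s})` with `c` the median and `s` the IQR/1.349
of that component across all contigs (falling back to `max(|c|, 1)` when
the IQR is zero). Median/IQR centring is robust to the nuclear-contig
majority and to extreme outliers, which are exactly the failure mode
that motivates scoring in the first place. Depth and length are
log10-transformed first since both span orders of magnitude in a
whole-genome graph.

The raw gene component is `(# distinct core genes of the target class
on the contig) + (fraction of contig bases covered by such hits)`. The
integer part separates multi-gene organelle contigs decisively; the
fractional part breaks ties among single-gene contigs. Bit scores are
deliberately not used: they scale with alignment length and would
re-introduce the length bias the scoring is designed to suppress.

Composite: `S = w_d·σ_d + w_l·σ_l + w_g·σ_g` with weights summing to 1
and `w_g > w_l` (gene content over length). Defaults: plant-mt
(0.30, 0.20, 0.50), plant-pt (0.35, 0.15, 0.50), animal/fungus-mt
(0.40, 0.20, 0.40); all configurable. In plant mitogenome runs a contig
whose cp-core hits cover ≥ 50% of its bases is flagged
chloroplast-derived and its gene weight is multiplied by λ = 0.5
*without* renormalizing the other weights — the lost weight mass is
allocated to a zero-scored slot. This makes the penalty unconditional
(a tagged contig always scores strictly below an otherwise identical
untagged one), which a renormalized form would not guarantee.

Seeds are the top-ranked contigs (composite desc, then longer, then id)
with `S ≥ τ` (default 0.6) *and* at least one distinct target-class core
gene; up to `max_seeds` (default 5) are taken. Requiring a core gene
operationalizes conserved-gene detection as the completeness proxy at
the seed stage. The baseline organelle depth `D̂` is the length-weighted
mean depth of the selected seeds.

Bundled core gene sets: the 13 canonical animal mitochondrial
protein-coding genes (nad1–6, nad4L, cox1–3, cob, atp6, atp8); the
fungal set (animal minus atp8 plus rps3); the 24 conserved plant
mitochondrial core genes; and a 21-gene plastid recognition set. All
overridable.

## Seed expansion

Multi-source FIFO breadth-first search from all seeds simultaneously,
enqueued in rank order. A link is traversable iff its support meets the
profile minimum (default 1). A newly reached contig is judged by the
depth filter of the target:

* plastome: excluded iff `depth < 0.3 × depth(matched seed)`;
* mitogenome: excluded iff `depth > 2 × D̂`.

Both boundaries are strict on the exclusion side, so a contig exactly on
the threshold is retained. The "matched seed" is the root of the BFS
tree that reaches the contig first; when two seeds reach it at the same
BFS depth, the higher-ranked seed claims it — a deterministic, local
definition. Seeds themselves are exempt from the filters (they define
`D̂`). Excluded contigs are removed from traversal, not merely
unlabeled: this is what prevents a single nuclear bridge from leaking
the expansion into the nuclear graph. Undecided contigs after the
traversal are classified `low_link_support` if they touch a member
through an under-supported link, else `unreachable`.

A consequence worth knowing: the mitogenome filter is a *high*-depth
cap, so a low-depth nuclear homolog linked into the organelle subgraph
passes it. Only collapsed, high-copy nuclear clusters (depth above
2×`D̂`) are excludable by depth alone; raising the link-support minimum
is the remaining lever. Note also that the cap sits exactly at the
expected depth of a two-copy repeat (2×`D̂`), so under depth noise a
duplicated contig lies on the boundary; the strict "exceeding" semantics
retain it at exactly 2×`D̂` but noise above the line excludes it. This
is an inherent edge of the rule, not an implementation artifact.

## Structure resolution

Copy numbers: `m(c) = max(1, ⌊depth(c)/D̂ + 0.5⌋)` (half-up). The floor
at 1 means depth noise can never delete a member contig, only
under-multiply it.

Decomposition is greedy commit-and-subtract. While any contig has unused
copies: anchor on the longest such contig and grow partial walks from
both of its orientations with a breadth-first frontier. Frontier states
are keyed by (current oriented end, usage multiset), so partial walks
that are interchangeable for all future extensions collapse to the best
representative; each level is then truncated to the best `B` partials
(beam width, default 64). Extensions respect remaining per-contig copy
counts and a per-link capacity equal to the smaller endpoint copy number
— a conservative reading absent any link-multiplicity data. A walk
closes cyclically when a link re-enters the anchor in its starting
orientation, or linearly when no extension is feasible. Among all
closed candidates the committed path is the minimum of the priority key

    (linear?, −total_length, −node_count, |path_depth − D̂|, step string)

i.e. cyclic first, then longest, then most nodes, then path depth
(minimum member depth — a path is only as supported as its weakest
contig) closest to baseline, with the canonical step string as the final
deterministic tie-break. This ordering favors the single master-circle
representation of repeat-mediated multipartite genomes, which is the
conventional reporting form in plant mitogenomics, and on graphs small
enough for exhaustive search the committed decomposition provably
attains the priority maximum (tested against a beam-free enumerator).

Cyclic paths are canonicalized — rotated to start at the
lexicographically smallest oriented step, in the direction minimizing
the step string — so reruns are byte-identical.

Leftover copies of contigs that already appear in committed paths are
reported as *residual* rather than emitted as single-contig junk paths;
non-empty residual classifies the result `unresolved_branched`.
Classification otherwise: `linear` if any committed path is acyclic,
`single_circular` / `multi_circular` by path count. Beam exhaustion
degrades to residual, never to a crash or a wrong-length path.

Two structural consequences of these rules, both deliberate:

* Molecules that share a repeat contig are reported as the recombined
  master circle: in a collapsed graph the crossing junctions always
  exist, and the priority order prefers the longer cycle. Total length
  and copy usage are identical to the multi-circle reading; the emitted
  organelle GFA preserves the alternative configurations at the graph
  level.
* Linear paths grow forward from the anchor only, so a truly linear
  genome whose longest contig is internal fragments into more than one
  linear path. Linear organelle molecules are rare and flagged by the
  `linear` classification; two-sided extension is future work.

Sequence spelling concatenates step sequences (reverse-complemented for
`−` steps), trimming each link's overlap from the successor and, for
circles, the closing overlap from the end; the output length always
equals the declared path length (asserted).

## Assessment

* **Gene content**: a core gene is present iff at least one passing hit
  lies on a contig used by a committed path. Verdict `complete` =
  no missing core genes and a closed (single- or multi-circular)
  topology; `partial` = some genes present; `failed` otherwise.
* **Rearrangement contigs**: contigs with total usage ≥ 2 across
  committed paths — the repeat contigs mediating alternative junctions.
* **Repeats**: exact repeated substrings strictly longer than 30 bp,
  direct or inverted, within or between output sequences, reported as
  the union of occurrence bp. Computed by counting canonical
  31-mer windows that occur ≥ 2 times: a position is covered by a
  qualifying repeat iff one of its 31-windows is repeated, so the
  window union equals the maximal-repeat union exactly. Exact matching
  (no mismatches) keeps the statistic reproducible and oracle-checkable;
  near-identical repeat support is future work. The odd window length
  rules out reverse-complement palindromes, so canonical counting is
  unambiguous.
* **MTPT**: shared canonical 31-mers between the mitogenome and a
  plastome seed matches; co-linear seeds gapped ≤ 100 bp are merged and
  merged spans ≥ 50 bp are reported (union bp on the mitogenome).
  Exact k-mer chaining avoids an aligner dependency; the thresholds are
  configurable defaults.
* Mean depth is the length×usage-weighted average over path contigs;
  repeat fraction is rounded to integer percent (half-up).

## Preprocessing

Canonical k-mer counting (lexicographic min of window and reverse
complement, windows with non-ACGT skipped) with default k = 17 — small
enough for organelle-scale data in memory, large enough to be unique at
these genome sizes; k is restricted to odd values in [11, 31] so every
window has a unique canonical form and codes pack into 64-bit integers.

Genome size = (k-mer mass above an error cutoff) / (peak multiplicity).
The cutoff walks down the initial descending slope of the multiplicity
histogram — the error component — and stops at the valley; a histogram
that rises from the start has no error component and keeps everything.
The peak is the most populated multiplicity at or above the cutoff, ties
broken toward the smaller multiplicity (the conservative, larger-size
reading). Caveat: the empirical peak location is only as stable as the
histogram is smooth. Adjacent k-mer windows share reads, so multiplicity
is block-correlated along the genome; simulations in the test suite use
500 bp error-free fragments at 30×, which give enough independent
coverage blocks for the raw argmax to sit within a few percent of the
true coverage. With few long reads the argmax can wobble several units;
histogram smoothing before peak-picking would be the next refinement.

Subsampling: with a fraction `f`, each read is kept independently with
probability `f` in original order; with a base target, reads are
consumed in a seeded random permutation until the cumulative length
reaches the target. Identical inputs, parameters and seed give
byte-identical output. Read error-correction is out of scope — the
toolkit accepts HiFi or already-corrected reads.

## Synthetic data generator

`make_genome` plants, deterministically per seed: uniform random DNA;
repeat families copied verbatim (reverse-complemented copies when
inverted) separated by unique segments of at least `min_segment`
(default 300 bp); quadripartite plastomes as LSC + IR + SSC + inverted
IR (LSC:SSC = 4:1 of the non-IR length); core genes as unique 60 bp
tags at recorded positions, which decouples every test from any
aligner; and optional MTPT inserts copied from a generated plastome.

`make_graph` collapses the truth: one contig per repeat family at
`copies × organelle_depth`, junction links with true orientations
(overlap 0 by default; an overlap mode exercises junction trimming),
multiplicative log-normal depth noise with unit mean and configurable
CV (default 10% — a realistic coverage dispersion for long-read data),
plus unlinked nuclear background contigs at 8× and optionally one
NUMT-like contig sharing a 2 kb homologous block with the organelle and
a link into its subgraph. The NUMT contig defaults to 2.5× the
organelle depth, emulating a repeat-collapsed NUMT cluster — the case
the mitogenome depth cap can actually reject (see above).

What the generator does **not** emulate, and what passing tests
therefore do not show: sequencing errors and chimeric joins (contigs are
exact genome substrings), assembler-specific artifacts (bubbles, tips,
under-collapsed repeats), depth variation along a contig,
heteroplasmy, and gene families split across contigs. Results on real
graphs depend on upstream assembly quality in ways these fixtures
cannot capture. Structural end-to-end fixtures use CV = 0 so that the
2-copy-repeat/2× cap boundary interaction (see Seed expansion) does not
dominate; the statistical fixtures (copy-number recovery, seed
accuracy) keep the default 10% noise.

## Reproducibility and problem sizes

All randomness flows from explicit integer seeds; the `run.json` log of
a pipeline run records parameters, seeds, versions and per-stage counts
and suffices to reproduce a run bit-exactly. The bundled acceptance
script exercises: 50 random single circles of 20–200 kb (5–20 contigs),
a 4-molecule 180 kb multipartite fixture, 100 copy-number replicates at
10% CV, a 100 kb × 30× k-mer simulation, 100 seed-selection replicates
with 30-contig nuclear background, and one full automated run — sizes
chosen to exercise every code path at desk scale while completing in
well under a minute.

## Known limitations

* Depth is the only copy-number signal; no read-backed junction phasing
  or flow-based global optimization. Greedy commit-and-subtract matches
  the sequential search design and is near-linear per committed path,
  but is not a global optimum over all decompositions (the priority
  maximality holds per committed step).
* One representative structure is emitted per run; alternative
  recombination isomers survive only in the emitted subgraph GFA.
* Exact-match repeats and MTPTs only (no mismatches/indels).
* Low-depth nuclear bridges pass the mitogenome depth filter by design
  of the rule itself; link support is the only countermeasure.
* The quadripartite generator fixes the LSC:SSC split; real plastomes
  vary.
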