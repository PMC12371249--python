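"""Read preprocessing: k-mer histogram, genome-size estimation, subsampling.

Genome size is estimated from the canonical k-mer multiplicity
histogram: multiplicities below the first local minimum of the histogram
are treated as sequencing error, the modal multiplicity above that
cutoff is taken as the per-copy coverage peak, and the size is the
total surviving k-mer mass divided by the peak. On error-free
uniform-coverage data this is the classic total-kmers/peak-depth
estimator. Read self-correction is out of scope here — the toolkit
accepts already-corrected or HiFi reads.
"""

from __future__ import annotations

import gzip
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
from Bio import SeqIO

from .sequtils import canonical_kmer_codes


@dataclass
class KmerHistogram:
    """Distribution of canonical k-mer multiplicities.

    counts maps multiplicity m -> number of distinct canonical k-mers
    seen exactly m times; total mass sum(m * counts[m]) equals the
    number of k-mer windows emitted.
    """

    k: int
    counts: dict[int, int]

    @property
    def total_kmers(self) -> int:
        return sum(m * c for m, c in self.counts.items())

    def to_tsv(self) -> str:
        return "".join(f"{m}\t{self.counts[m]}\n" for m in sorted(self.counts))


@dataclass
class GenomeSizeEstimate:
    size_bp: int
    peak_multiplicity: int
    error_cutoff: int


def _as_sequences(reads: Iterable) -> Iterator[str]:
    for r in reads:
        yield str(getattr(r, "seq", r)).upper()


def kmer_histogram(reads: Iterable, k: int = 17) -> KmerHistogram:
    """Canonical k-mer multiplicity histogram over a read stream.

    k must be odd and in [11, 31] (odd k rules out reverse-complement
    palindromes, so every window has a unique canonical form). Windows
    containing non-ACGT characters are skipped.
    """
    if k % 2 == 0 or not 11 <= k <= 31:
        raise ValueError(f"k must be odd and in [11, 31], got {k}")
    chunks = []
    n_reads = 0
    for seq in _as_sequences(reads):
        n_reads += 1
        codes, _ = canonical_kmer_codes(seq, k)
        if codes.size:
            chunks.append(codes)
    if n_reads == 0 or not chunks:
        raise ValueError("empty input")
    cat = np.concatenate(chunks)
    _, mult = np.unique(cat, return_counts=True)
    ms, cs = np.unique(mult, return_counts=True)
    return KmerHistogram(k=k, counts={int(m): int(c) for m, c in zip(ms, cs)})


def estimate_genome_size(hist: KmerHistogram) -> GenomeSizeEstimate:
    """Total-kmer-mass / peak-depth estimator with an error cutoff.

    The cutoff is the first local minimum of counts scanning stored
    multiplicities upward (1 when the histogram is monotone); the peak
    is the multiplicity with the largest count at or above the cutoff,
    ties broken toward the smaller multiplicity (the conservative,
    larger-size reading).
    """
    if not hist.counts:
        raise ValueError("empty histogram")
    ms = sorted(hist.counts)
    # walk down the initial (error) slope; the valley where the descent
    # stops is the cutoff. A histogram that rises from the start has no
    # error component and keeps everything.
    i = 0
    while i + 1 < len(ms) and hist.counts[ms[i + 1]] < hist.counts[ms[i]]:
        i += 1
    cutoff = ms[i]
    signal = [m for m in ms if m >= cutoff]
    if not signal:
        raise ValueError("no signal peak")
    peak = max(signal, key=lambda m: (hist.counts[m], -m))
    mass = sum(m * hist.counts[m] for m in signal)
    if mass == 0:
        raise ValueError("no signal peak")
    size = math.floor(mass / peak + 0.5)
    return GenomeSizeEstimate(size_bp=size, peak_multiplicity=peak, error_cutoff=cutoff)


def subsample_reads(
    reads: Sequence,
    fraction: float | None = None,
    target_bp: int | None = None,
    seed: int = 0,
) -> list:
    """Seeded read subsampling.

    Exactly one of ``fraction`` / ``target_bp`` must be given. With a
    fraction, each read is kept independently with that probability and
    the original order is preserved. With a base target, reads are
    consumed in a seeded random order until the cumulative length
    reaches the target. Same inputs + seed -> identical output.
    """
    if (fraction is None) == (target_bp is None):
        raise ValueError("give exactly one of fraction or target_bp")
    reads = list(reads)
    rng = np.random.default_rng(seed)
    if fraction is not None:
        if not 0.0 <= fraction <= 1.0:
            raise ValueError("fraction must be in [0, 1]")
        if fraction == 1.0:
            return reads
        draws = rng.random(len(reads))
        return [r for r, u in zip(reads, draws) if u < fraction]
    if target_bp < 0:
        raise ValueError("target_bp must be >= 0")
    order = rng.permutation(len(reads))
    out = []
    acc = 0
    for idx in order:
        if acc >= target_bp:
            break
        r = reads[idx]
        out.append(r)
        acc += len(str(getattr(r, "seq", r)))
    return out


def read_reads(path: str | Path) -> list:
    """Load FASTA/FASTQ records (plain or gzip), format sniffed from the name."""
    path = Path(path)
    name = path.name[:-3] if path.name.endswith(".gz") else path.name
    fmt = "fastq" if name.endswith((".fq", ".fastq")) else "fasta"
    opener = gzip.open if path.name.endswith(".gz") else open
    with opener(path, "rt") as fh:
        return list(SeqIO.parse(fh, fmt))
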