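"""Admixture-block extraction, healing, genetic-length dating, and the
single-pulse dispersion test.

Blocks are maximal runs of consecutive windows whose posterior probability
of donor ancestry exceeds a threshold (0.95 by default).  Under a single
admixture pulse ``v`` generations ago, block lengths in Morgans are
exponential with mean 1/v, so T = 1/mean_length(Morgans) estimates the time
since admixture, and the variance of block lengths should equal the squared
mean; over-dispersion indicates ongoing or multi-pulse gene flow.

The chunk arithmetic: a present-day genome traces back to X = v*L + C
ancestral chunks ``v`` generations ago (L = map length in Morgans, C =
number of chromosomes), spread over 2^v genealogical ancestors -- hence
log2(X) - v (log-space; 2^150 overflows any float's integer range) gives the
log2 expected chunks per ancestor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .ancestry_hmm import PosteriorTrack

__all__ = [
    "AncestryBlock",
    "PulseEstimate",
    "ChunkModel",
    "call_blocks",
    "heal_blocks",
    "block_length_cm",
    "generations_since_pulse",
    "pulse_dispersion_test",
    "summarize_pulse",
    "genome_chunks",
]


@dataclass
class AncestryBlock:
    chromosome: str
    start: int
    end: int
    mean_posterior: float
    n_windows: int

    @property
    def length_bp(self) -> int:
        return self.end - self.start

    def length_morgans(self, map_length_morgans: float, genome_bp: float) -> float:
        return self.length_bp * map_length_morgans / genome_bp


@dataclass
class PulseEstimate:
    n_blocks: int
    mean_length_morgans: float
    sd_length_morgans: float
    T_generations: float
    dispersion_p: float | None = None


@dataclass
class ChunkModel:
    v: float
    L: float
    C: int
    X: float
    log2_per_ancestor: float


def call_blocks(track: PosteriorTrack, threshold: float = 0.95,
                window_bp: int = 1_000) -> list[AncestryBlock]:
    """Maximal runs of consecutive windows with posterior > threshold.

    Block coordinates are the union of the member windows' spans.  Missing
    windows never join a block (their posterior is driven by the prior, not
    data) and break runs.
    """
    blocks: list[AncestryBlock] = []
    cur = None  # [chrom, start, end, sum_post, n]
    for w, p in zip(track.windows, track.posterior_donor):
        hit = (not w.missing) and np.isfinite(p) and p > threshold
        if hit and cur is not None and w.chromosome == cur[0] and w.start == cur[2]:
            cur[2] = w.start + window_bp
            cur[3] += p
            cur[4] += 1
        elif hit:
            if cur is not None:
                blocks.append(AncestryBlock(cur[0], cur[1], cur[2], cur[3] / cur[4], cur[4]))
            cur = [w.chromosome, w.start, w.start + window_bp, p, 1]
        else:
            if cur is not None:
                blocks.append(AncestryBlock(cur[0], cur[1], cur[2], cur[3] / cur[4], cur[4]))
                cur = None
    if cur is not None:
        blocks.append(AncestryBlock(cur[0], cur[1], cur[2], cur[3] / cur[4], cur[4]))
    return blocks


def heal_blocks(blocks: list[AncestryBlock], gap_kb: int = 0) -> list[AncestryBlock]:
    """Merge successive same-chromosome blocks separated by <= gap_kb.

    Merging is transitive; the healed block spans the merged extent
    including the gaps (``span`` semantics).  ``gap_kb`` of 0 returns the
    input unchanged.  Healing is monotone: a larger gap never yields more
    blocks or less covered length.
    """
    if gap_kb == 0 or not blocks:
        return list(blocks)
    gap_bp = gap_kb * 1_000
    ordered = sorted(blocks, key=lambda b: (str(b.chromosome), b.start))
    out: list[AncestryBlock] = []
    for b in ordered:
        if out and out[-1].chromosome == b.chromosome and b.start - out[-1].end <= gap_bp:
            prev = out[-1]
            n = prev.n_windows + b.n_windows
            mp = (prev.mean_posterior * prev.n_windows + b.mean_posterior * b.n_windows) / n
            out[-1] = AncestryBlock(prev.chromosome, prev.start, max(prev.end, b.end), mp, n)
        else:
            out.append(b)
    return out


def block_length_cm(length_bp: float, map_length_cm: float = 1_470.0,
                    genome_bp: float = 2.6e8) -> float:
    """Linear bp -> cM conversion: length_bp * map_length_cM / genome_bp."""
    if map_length_cm <= 0 or genome_bp <= 0:
        raise ValueError("map length and genome size must be > 0")
    return length_bp * map_length_cm / genome_bp


def generations_since_pulse(mean_length_morgans: float) -> float:
    """T = 1 / mean block length in Morgans (single-pulse exponential model)."""
    if mean_length_morgans <= 0:
        raise ValueError("mean block length must be > 0")
    return 1.0 / mean_length_morgans


def pulse_dispersion_test(lengths_morgans: np.ndarray, n_boot: int = 1_000,
                          seed: int = 0) -> float:
    """One-sided bootstrap test of the single-pulse (exponential) model.

    Under one pulse, Var(length) = mean(length)^2.  Blocks are resampled
    with replacement ``n_boot`` times; the p-value is the proportion of
    resamples in which the variance does **not** exceed the squared mean
    (small p = over-dispersed block lengths, rejecting a single pulse).
    """
    lengths = np.asarray(lengths_morgans, dtype=float)
    if len(lengths) < 2:
        raise ValueError("need >= 2 blocks")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(lengths), size=(n_boot, len(lengths)))
    res = lengths[idx]
    means = res.mean(axis=1)
    vars_ = res.var(axis=1, ddof=1)
    n_null = int(np.sum(vars_ <= means ** 2))
    return (1 + n_null) / (n_boot + 1)


def summarize_pulse(blocks: list[AncestryBlock], map_length_morgans: float = 14.7,
                    genome_bp: float = 2.6e8, n_boot: int = 1_000,
                    seed: int = 0) -> PulseEstimate:
    """Block-length summary on the Morgan scale with pulse date T = 1/mean
    and the dispersion p-value."""
    if not blocks:
        raise ValueError("no blocks")
    lengths = np.array([b.length_morgans(map_length_morgans, genome_bp) for b in blocks])
    p = pulse_dispersion_test(lengths, n_boot=n_boot, seed=seed) if len(lengths) >= 2 else None
    return PulseEstimate(
        n_blocks=len(lengths),
        mean_length_morgans=float(lengths.mean()),
        sd_length_morgans=float(lengths.std(ddof=1)) if len(lengths) > 1 else 0.0,
        T_generations=generations_since_pulse(float(lengths.mean())),
        dispersion_p=p,
    )


def genome_chunks(v: float, L: float = 14.7, C: int = 14) -> ChunkModel:
    """Chunk model: X = v*L + C; log2 chunks per ancestor = log2(X) - v."""
    if v < 0:
        raise ValueError("v must be >= 0")
    X = v * L + C
    log2_per_ancestor = math.log2(X) - v
    return ChunkModel(v=v, L=L, C=C, X=X, log2_per_ancestor=log2_per_ancestor)
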