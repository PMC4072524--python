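"""Pairwise and windowed nucleotide diversity, block bootstrap, AFS, and
variant partitioning.

Diversity (pi) is the mean number of pairwise sequence differences per site
of a stated degeneracy class (e.g. per fourfold-degenerate site for pi_S):
for each sample pair, the denominator counts only sites co-called in both
samples and in the class, and the numerator counts mismatches at those
sites.  Windows are anchored at position 0 of each chromosome; block
bootstrap resamples 100 kb blocks with replacement to acknowledge linkage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np

from .variant_io import GenotypePanel, MISSING

__all__ = [
    "WindowStat",
    "AFS",
    "pairwise_pi",
    "windowed_pi",
    "block_bootstrap",
    "polarized_afs",
    "partition_variants",
]


@dataclass
class WindowStat:
    """Pairwise mismatch statistic over a genomic interval."""

    chromosome: str | None
    start: int
    end: int
    sample_a: str
    sample_b: str
    n_sites: int
    n_diff: int
    insufficient: bool = False

    @property
    def pi(self) -> float:
        """Mismatch fraction; NaN (undefined) when no informative sites."""
        if self.n_sites == 0:
            return float("nan")
        return self.n_diff / self.n_sites

    @property
    def defined(self) -> bool:
        return self.n_sites > 0


@dataclass
class AFS:
    """Derived-allele-count histogram over ingroup samples.

    ``counts[i]`` is the number of sites at which exactly ``i`` of the
    ``n_samples`` ingroup samples carry the derived allele (i = 0..n).
    """

    site_class: tuple | None
    n_samples: int
    counts: np.ndarray
    lo: np.ndarray | None = None
    hi: np.ndarray | None = None


def _pair_arrays(panel: GenotypePanel, a: str, b: str, site_class) -> tuple[np.ndarray, np.ndarray]:
    ia, ib = panel.sample_index(a), panel.sample_index(b)
    ca, cb = panel.calls[:, ia], panel.calls[:, ib]
    ok = (ca != MISSING) & (cb != MISSING) & panel.class_mask(site_class)
    return ok, (ca != cb)


def pairwise_pi(
    panel: GenotypePanel,
    a: str,
    b: str,
    site_class: Iterable[int] | None = None,
) -> WindowStat:
    """Genome-wide pairwise diversity between samples ``a`` and ``b``.

    Returns a :class:`WindowStat` whose ``pi`` is NaN (flagged undefined, not
    zero) when no site is co-called in the requested class.
    """
    ok, diff = _pair_arrays(panel, a, b, site_class)
    n_sites = int(ok.sum())
    n_diff = int((ok & diff).sum())
    end = int(panel.pos.max()) + 1 if panel.n_sites else 0
    return WindowStat(None, 0, end, a, b, n_sites, n_diff)


def windowed_pi(
    panel: GenotypePanel,
    a: str,
    b: str,
    site_class: Iterable[int] | None = None,
    window_bp: int = 5_000,
    slide_bp: int = 1_000,
    min_sites: int = 100,
    chrom_sizes: dict | None = None,
) -> list[WindowStat]:
    """Sliding-window pairwise diversity.

    Windows are anchored at position 0 of each chromosome, start every
    ``slide_bp`` and span ``window_bp`` (overlapping when slide < window).
    Windows with fewer than ``min_sites`` informative sites are flagged
    ``insufficient`` (callers exclude them from histograms).  The final
    partial window of each chromosome is retained if it spans at least half
    of ``window_bp``.
    """
    if window_bp < slide_bp:
        raise ValueError("window_bp must be >= slide_bp")
    ok, diff = _pair_arrays(panel, a, b, site_class)
    out: list[WindowStat] = []
    for c in panel.chromosomes():
        cmask = panel.chrom == c
        size = (chrom_sizes or {}).get(c, int(panel.pos[cmask].max()) + 1)
        pos = panel.pos[cmask]
        okc = ok[cmask]
        diffc = (diff & ok)[cmask]
        # prefix sums over informative / mismatching site counts by position
        order = np.argsort(pos, kind="stable")
        pos, okc, diffc = pos[order], okc[order], diffc[order]
        cum_ok = np.concatenate([[0], np.cumsum(okc)])
        cum_df = np.concatenate([[0], np.cumsum(diffc)])
        start = 0
        while start < size:
            end = min(start + window_bp, size)
            if end - start < window_bp and end - start < window_bp / 2:
                break
            lo = np.searchsorted(pos, start, side="left")
            hi = np.searchsorted(pos, end, side="left")
            n_sites = int(cum_ok[hi] - cum_ok[lo])
            n_diff = int(cum_df[hi] - cum_df[lo])
            out.append(WindowStat(c, start, end, a, b, n_sites, n_diff,
                                  insufficient=n_sites < min_sites))
            start += slide_bp
    return out


def block_bootstrap(
    statistic: Callable[[GenotypePanel], float],
    panel: GenotypePanel,
    block_bp: int = 100_000,
    n_boot: int = 200,
    seed: int = 0,
    max_redraws: int = 100,
) -> tuple[float, float, float]:
    """Block-bootstrap confidence interval for a panel statistic.

    The genome is partitioned into ``block_bp`` blocks; each bootstrap
    replicate resamples blocks with replacement, rebuilds a panel from the
    chosen blocks, and recomputes the statistic.  Returns
    ``(point, lo, hi)`` -- the point estimate and 2.5/97.5 percentiles.
    Resamples on which the statistic is undefined (NaN) are redrawn (up to
    ``max_redraws`` extra draws, after which NaN replicates are dropped).
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    rng = np.random.default_rng(seed)
    # block id per site
    keys = [(str(c), int(p) // block_bp) for c, p in zip(panel.chrom, panel.pos)]
    uniq = sorted(set(keys))
    key_to_block = {k: i for i, k in enumerate(uniq)}
    block_of_site = np.array([key_to_block[k] for k in keys])
    site_idx_by_block = [np.nonzero(block_of_site == b)[0] for b in range(len(uniq))]

    point = statistic(panel)
    vals = []
    redraws = 0
    while len(vals) < n_boot and redraws <= max_redraws + n_boot:
        chosen = rng.integers(0, len(uniq), size=len(uniq))
        idx = np.concatenate([site_idx_by_block[b] for b in chosen]) if len(uniq) else np.empty(0, int)
        sub = _resampled_panel(panel, idx)
        v = statistic(sub)
        redraws += 1
        if np.isnan(v):
            continue
        vals.append(v)
    arr = np.array(vals, dtype=float)
    lo, hi = np.percentile(arr, [2.5, 97.5])
    return float(point), float(lo), float(hi)


def _resampled_panel(panel: GenotypePanel, idx: np.ndarray) -> GenotypePanel:
    """Panel over resampled blocks: sites are relabelled onto a single
    pseudo-chromosome in draw order so position-sortedness is preserved."""
    alleles = None if panel.alleles is None else [panel.alleles[i] for i in idx]
    return GenotypePanel(
        samples=list(panel.samples),
        chrom=np.full(len(idx), "resample", dtype=object),
        pos=np.arange(len(idx), dtype=np.int64),
        calls=panel.calls[idx],
        alleles=alleles,
        depth=None if panel.depth is None else panel.depth[idx],
        degeneracy=panel.degeneracy[idx],
    )


def polarized_afs(
    panel: GenotypePanel,
    ingroup: Sequence[str],
    outgroup: str,
    site_class: Iterable[int] | None = None,
) -> AFS:
    """Derived allele-frequency spectrum polarized by an outgroup sample.

    The outgroup allele is labelled ancestral.  Sites are excluded when the
    outgroup call is missing, when any ingroup sample is missing, or when an
    ingroup sample carries a third allele (neither the outgroup's nor one
    alternate).  Monomorphic (all-ancestral) sites do not enter the counts.
    """
    io = panel.sample_index(outgroup)
    ii = [panel.sample_index(s) for s in ingroup]
    og = panel.calls[:, io]
    ing = panel.calls[:, ii]
    ok = (og != MISSING) & np.all(ing != MISSING, axis=1)
    ok &= panel.class_mask(site_class)
    if not ok.any():
        raise ValueError("no usable sites for the AFS")
    counts = np.zeros(len(ii) + 1, dtype=int)
    total_used = 0
    for i in np.nonzero(ok)[0]:
        anc = og[i]
        alleles = set(ing[i]) | {anc}
        if len(alleles) > 2:
            continue  # third allele among ingroup relative to outgroup
        derived = int(np.sum(ing[i] != anc))
        if derived > 0:
            counts[derived] += 1
        total_used += 1
    return AFS(site_class=None if site_class is None else tuple(site_class),
               n_samples=len(ii), counts=counts)


def partition_variants(
    panel: GenotypePanel,
    group_a: Sequence[str],
    group_b: Sequence[str],
    outgroup: str | None = None,
    site_class: Iterable[int] | None = None,
) -> dict:
    """Partition polymorphic sites into shared / private / fixed categories.

    Each site polymorphic among the union of the groups is assigned exactly
    one category: ``shared`` (polymorphic in both), ``private_a`` /
    ``private_b`` (polymorphic in one, monomorphic in the other at the same
    background allele), or ``fixed_diff`` (each group monomorphic, for
    different alleles).  Fixed differences are polarized by the outgroup
    when its call matches one side: the side carrying the non-outgroup
    allele is the derived one.
    """
    if set(group_a) & set(group_b):
        raise ValueError("groups must be disjoint")
    ia = [panel.sample_index(s) for s in group_a]
    ib = [panel.sample_index(s) for s in group_b]
    io = panel.sample_index(outgroup) if outgroup is not None else None
    out = {"shared": 0, "private_a": 0, "private_b": 0, "fixed_diff": 0,
           "fixed_derived_a": 0, "fixed_derived_b": 0, "fixed_unpolarized": 0}
    cls = panel.class_mask(site_class)
    for i in range(panel.n_sites):
        if not cls[i]:
            continue
        ca = [panel.calls[i, j] for j in ia if panel.calls[i, j] != MISSING]
        cb = [panel.calls[i, j] for j in ib if panel.calls[i, j] != MISSING]
        if not ca or not cb:
            continue
        sa, sb = set(ca), set(cb)
        if len(sa | sb) == 1:
            continue  # monomorphic overall
        poly_a, poly_b = len(sa) > 1, len(sb) > 1
        if poly_a and poly_b:
            out["shared"] += 1
        elif poly_a:
            out["private_a"] += 1
        elif poly_b:
            out["private_b"] += 1
        else:  # both fixed, different alleles
            out["fixed_diff"] += 1
            if io is not None and panel.calls[i, io] != MISSING:
                anc = panel.calls[i, io]
                if anc == next(iter(sa)):
                    out["fixed_derived_b"] += 1
                elif anc == next(iter(sb)):
                    out["fixed_derived_a"] += 1
                else:
                    out["fixed_unpolarized"] += 1
            else:
                out["fixed_unpolarized"] += 1
    return out
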