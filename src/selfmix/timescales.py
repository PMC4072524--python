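"""Closed-form timescale and selfing-rate estimators, and LD decay profiles.

Under neutrality, divergence between two populations is the sum of pairwise
diversity in their ancestor and 2*mu*tau new mutations, giving the split-time
estimator tau = (pi_between - pi_ancestral) / (2 mu).  The same scaling
pi / (2 mu) reads either as an effective number of chromosomes (coalescent
Ne*) or as a divergence time in generations.  Under the neutral coalescent a
lineage pair fails to coalesce by generation t with probability e^(-t/Ne*).

For a partially selfing population with inbreeding coefficient F, the
population-scaled recombination/mutation ratio is reduced by the factor
(1 - F) relative to an outcrossing population; with a constant selfing rate
s at equilibrium, F = s / (2 - s), i.e. s = 2F / (1 + F).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .variant_io import GenotypePanel, MISSING

__all__ = [
    "RateParams",
    "SplitEstimate",
    "SelfingEstimate",
    "LDProfile",
    "split_time",
    "pi_to_scale",
    "noncoalescence",
    "solve_N",
    "selfing_rate_from_ratios",
    "ld_profile",
]


@dataclass(frozen=True)
class RateParams:
    """Per-generation mutation rate (per bp) and generation time (years)."""

    mu: float = 1.5e-8
    generation_time: float = 1.0

    def __post_init__(self) -> None:
        if self.mu <= 0 or self.generation_time <= 0:
            raise ValueError("mu and generation_time must be > 0")


@dataclass
class SplitEstimate:
    tau_generations: float
    tau_years: float
    lo_years: float | None = None
    hi_years: float | None = None


@dataclass
class SelfingEstimate:
    one_minus_F: float
    F: float
    s: float


@dataclass
class LDProfile:
    bin_edges_bp: np.ndarray     # len n_bins + 1
    mean_r2: np.ndarray          # len n_bins, NaN for empty bins
    n_pairs: np.ndarray
    half_decay_bp: float         # smallest bin distance where the profile
                                 # has fallen halfway to its asymptote


def split_time(
    pi_between: float,
    pi_ancestral: float,
    rates: RateParams = RateParams(),
    pi_between_ci: tuple[float, float] | None = None,
) -> SplitEstimate:
    """Split time tau = (pi_between - pi_ancestral) / (2 mu).

    ``pi`` values are fractions (0.0445, not 4.45).  An optional bootstrap
    CI on pi_between is pushed through the (linear) formula to give a CI in
    years.  Raises on a negative implied time.
    """
    if pi_between < pi_ancestral:
        raise ValueError("pi_between < pi_ancestral implies negative split time")
    tau = (pi_between - pi_ancestral) / (2.0 * rates.mu)
    lo = hi = None
    if pi_between_ci is not None:
        lo = max(0.0, (pi_between_ci[0] - pi_ancestral)) / (2.0 * rates.mu) * rates.generation_time
        hi = max(0.0, (pi_between_ci[1] - pi_ancestral)) / (2.0 * rates.mu) * rates.generation_time
    return SplitEstimate(
        tau_generations=tau,
        tau_years=tau * rates.generation_time,
        lo_years=lo,
        hi_years=hi,
    )


def pi_to_scale(pi: float, rates: RateParams = RateParams()) -> float:
    """pi / (2 mu): interpretable as effective chromosomes (Ne*) when pi is
    within-population diversity, or as generations of divergence when pi is
    a pairwise divergence."""
    if pi < 0:
        raise ValueError("pi must be >= 0")
    return pi / (2.0 * rates.mu)


def noncoalescence(t: float, N: float) -> float:
    """Probability a lineage pair fails to coalesce by generation t in a
    constant population of N chromosomes: e^(-t/N)."""
    if t < 0 or N <= 0:
        raise ValueError("require t >= 0 and N > 0")
    return math.exp(-t / N)


def solve_N(t: float, p: float) -> float:
    """Population size (chromosomes) at which the non-coalescence
    probability by generation t equals p: N = t / ln(1/p)."""
    if not (0.0 < p < 1.0):
        raise ValueError("p must be in (0, 1)")
    if t < 0:
        raise ValueError("t must be >= 0")
    return t / math.log(1.0 / p)


def selfing_rate_from_ratios(ne_ratio: float, ld_ratio: float) -> SelfingEstimate:
    """Selfing rate from the ratio of Ne reduction to LD-scale expansion.

    ``ne_ratio`` is the fold-reduction in effective population size of the
    selfer relative to its outcrossing relative; ``ld_ratio`` the
    fold-expansion in the physical scale of LD decay.  Their quotient
    estimates 1 - F; F = s/(2 - s) then gives s = 2F/(1 + F).
    """
    if not (ld_ratio >= ne_ratio > 0):
        raise ValueError("require ld_ratio >= ne_ratio > 0")
    one_minus_F = ne_ratio / ld_ratio
    F = 1.0 - one_minus_F
    if not (0.0 <= F <= 1.0):
        raise ValueError("implied F outside [0, 1]")
    s = 2.0 * F / (1.0 + F)
    return SelfingEstimate(one_minus_F=one_minus_F, F=F, s=s)


def ld_profile(
    panel: GenotypePanel,
    samples: Sequence[str],
    max_dist_bp: int = 50_000,
    n_bins: int = 50,
    max_pairs_per_site: int = 200,
    tail_fraction: float = 0.1,
    seed: int = 0,
) -> LDProfile:
    """Mean r^2 between biallelic site pairs, binned by physical distance.

    Only sites polymorphic among ``samples`` (with complete data) enter.
    For each focal site, up to ``max_pairs_per_site`` downstream partners
    within ``max_dist_bp`` are used.  The half-decay distance is the
    left edge of the smallest-distance bin at which mean r^2 has dropped to
    or below the midpoint between the profile maximum (shortest-distance
    bin) and its asymptotic minimum (mean over the last ``tail_fraction``
    of bins).
    """
    idx = [panel.sample_index(s) for s in samples]
    if len(idx) < 2:
        raise ValueError("need >= 2 samples")
    calls = panel.calls[:, idx]
    complete = np.all(calls != MISSING, axis=1)
    freqs = calls.mean(axis=1)
    poly = complete & (freqs > 0) & (freqs < 1)
    if not poly.any():
        raise ValueError("monomorphic panel: no polymorphic sites for LD")
    edges = np.linspace(0, max_dist_bp, n_bins + 1)
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=int)
    for c in panel.chromosomes():
        cmask = (panel.chrom == c) & poly
        pos = panel.pos[cmask]
        g = calls[cmask].astype(float)
        n = len(pos)
        for i in range(n):
            hi = np.searchsorted(pos, pos[i] + max_dist_bp, side="right")
            js = np.arange(i + 1, hi)
            if len(js) > max_pairs_per_site:
                js = js[:max_pairs_per_site]
            if len(js) == 0:
                continue
            gi = g[i]
            gj = g[js]
            # r^2 between binary haplotype columns
            pi_ = gi.mean()
            pj = gj.mean(axis=1)
            pij = (gj * gi).mean(axis=1)
            denom = pi_ * (1 - pi_) * pj * (1 - pj)
            ok = denom > 0
            r2 = np.zeros(len(js))
            r2[ok] = (pij[ok] - pi_ * pj[ok]) ** 2 / denom[ok]
            d = pos[js] - pos[i]
            b = np.minimum(np.searchsorted(edges, d, side="right") - 1, n_bins - 1)
            np.add.at(sums, b[ok], r2[ok])
            np.add.at(counts, b[ok], 1)
    mean_r2 = np.full(n_bins, np.nan)
    nz = counts > 0
    mean_r2[nz] = sums[nz] / counts[nz]

    # half-decay: midpoint between the shortest-distance bin and the
    # asymptote (mean of the last tail_fraction of non-empty bins)
    valid = np.nonzero(nz)[0]
    top = mean_r2[valid[0]]
    k = max(1, int(len(valid) * tail_fraction))
    floor = float(np.nanmean(mean_r2[valid[-k:]]))
    mid = (top + floor) / 2.0
    half = float("nan")
    for b in valid:
        if mean_r2[b] <= mid:
            half = float(edges[b])
            break
    return LDProfile(bin_edges_bp=edges, mean_r2=mean_r2, n_pairs=counts,
                     half_decay_bp=half)
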