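"""Four-population D statistic with delete-one-chromosome jackknife, and the
single-outlier region scan for introgression into the selfing taxon.

The D statistic uses sample allele frequencies y, z, w, x from populations
Y (sympatric recipient), Z (allopatric recipient near Y), W (donor taxon)
and X (distant allopatric recipient):

    D = sum_i (y_i - z_i)(w_i - x_i) / sum_i (y_i + z_i - 2 y_i z_i)(w_i + x_i - 2 w_i x_i)

signed so that excess allele sharing between Y and W gives D > 0.
Significance comes from a weighted block jackknife dropping one chromosome
per run.

The outlier scan finds long regions (>= 20 kb) where exactly one donor-taxon
sample differs from all others (pairwise pi above a threshold while the
non-outliers remain mutually similar), then asks -- region by region --
whether the outlier is closer to a candidate source sample than the
non-outliers are; under incomplete lineage sorting that has probability
50%, tested with an exact one-sided binomial tail.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .diversity import pairwise_pi
from .variant_io import GenotypePanel, MISSING

__all__ = [
    "DStatResult",
    "OutlierRegion",
    "OutlierTestResult",
    "allele_frequencies",
    "d_statistic",
    "block_jackknife",
    "find_outlier_regions",
    "outlier_source_test",
]


@dataclass
class DStatResult:
    D: float
    se: float | None = None
    Z: float | None = None
    leave_one_out: dict = field(default_factory=dict)
    n_sites: int = 0
    undefined: bool = False


@dataclass
class OutlierRegion:
    chromosome: str
    start: int
    end: int
    outlier: str

    @property
    def length_bp(self) -> int:
        return self.end - self.start


@dataclass
class OutlierTestResult:
    k: int            # regions where the outlier is closer to the source
    n: int            # informative (untied) regions
    p: float          # one-sided exact binomial tail at 0.5


def allele_frequencies(panel: GenotypePanel, samples: Sequence[str]) -> np.ndarray:
    """Per-site frequency of allele 1 among the given samples (NaN where no
    sample has data).  Sites must be biallelic (allele codes 0/1)."""
    idx = [panel.sample_index(s) for s in samples]
    calls = panel.calls[:, idx].astype(float)
    calls[calls == MISSING] = np.nan
    with np.errstate(invalid="ignore"):
        return np.nanmean(calls, axis=1)


def d_statistic(
    y: np.ndarray, z: np.ndarray, w: np.ndarray, x: np.ndarray,
) -> DStatResult:
    """Point D statistic from aligned per-site allele frequencies.

    Sites where any frequency is undefined (NaN) are skipped.  A zero
    denominator over the remaining sites makes D undefined (flagged).
    """
    y, z, w, x = (np.asarray(a, dtype=float) for a in (y, z, w, x))
    num, den, ok = _d_terms(y, z, w, x)
    ds = float(den[ok].sum())
    if ds == 0:
        return DStatResult(D=float("nan"), n_sites=int(ok.sum()), undefined=True)
    return DStatResult(D=float(num[ok].sum()) / ds, n_sites=int(ok.sum()))


def _d_terms(y, z, w, x):
    ok = ~(np.isnan(y) | np.isnan(z) | np.isnan(w) | np.isnan(x))
    num = (y - z) * (w - x)
    den = (y + z - 2 * y * z) * (w + x - 2 * w * x)
    return num, den, ok


def block_jackknife(
    y: np.ndarray, z: np.ndarray, w: np.ndarray, x: np.ndarray,
    chromosomes: np.ndarray,
) -> DStatResult:
    """D with a delete-one-chromosome weighted jackknife.

    Per-site numerator/denominator terms are summed per chromosome; each
    jackknife replicate recomputes D without one chromosome.  The weighted
    jackknife variance uses each chromosome's share of the total denominator
    as its weight, so unequal chromosome information contents are handled.
    Requires >= 3 chromosomes with data.
    """
    y, z, w, x = (np.asarray(a, dtype=float) for a in (y, z, w, x))
    chromosomes = np.asarray(chromosomes)
    num, den, ok = _d_terms(y, z, w, x)
    labels = [c for c in dict.fromkeys(chromosomes[ok])]
    if len(labels) < 3:
        raise ValueError("need >= 3 chromosomes for the block jackknife")
    num_c = np.array([num[ok & (chromosomes == c)].sum() for c in labels])
    den_c = np.array([den[ok & (chromosomes == c)].sum() for c in labels])
    # chromosomes contributing no denominator carry no information
    informative = den_c != 0
    labels = [c for c, keep in zip(labels, informative) if keep]
    num_c, den_c = num_c[informative], den_c[informative]
    if len(labels) < 3:
        raise ValueError("need >= 3 informative chromosomes")
    N, S = num_c.sum(), den_c.sum()
    if S == 0:
        return DStatResult(D=float("nan"), undefined=True, n_sites=int(ok.sum()))
    D = N / S
    g = len(labels)
    loo = {}
    D_j = np.empty(g)
    for j, c in enumerate(labels):
        denom = S - den_c[j]
        D_j[j] = (N - num_c[j]) / denom if denom != 0 else np.nan
        loo[c] = D_j[j]
    # weighted jackknife (Busing et al. 1999): weights = block share of the
    # denominator; falls back to the unweighted formula for equal weights
    h = S / den_c  # n / m_j
    valid = np.isfinite(D_j)
    g_eff = int(valid.sum())
    if g_eff < 3:
        raise ValueError("need >= 3 informative chromosomes")
    hv, Dv = h[valid], D_j[valid]
    theta_J = g_eff * D - np.sum((1 - 1 / hv) * Dv)
    tau = hv * D - (hv - 1) * Dv  # pseudovalues
    var = np.sum((tau - theta_J) ** 2 / (hv - 1)) / g_eff
    se = float(np.sqrt(var))
    return DStatResult(D=float(D), se=se, Z=float(D / se) if se > 0 else float("inf"),
                       leave_one_out=loo, n_sites=int(ok.sum()))


# ---------------------------------------------------------------------------
# Outlier-sample introgression scan
# ---------------------------------------------------------------------------

def _window_pair_pi(panel, samples, window_bp, site_class, chrom_sizes):
    """Per-window pairwise mismatch rates among samples.

    Returns (windows, rate[win, i, j], n[win, i, j]) with windows as
    (chromosome, start) on the non-overlapping window grid.
    """
    idx = [panel.sample_index(s) for s in samples]
    cls = panel.class_mask(site_class)
    wins: list[tuple[str, int]] = []
    rates, ns = [], []
    for c in panel.chromosomes():
        cmask = panel.chrom == c
        size = (chrom_sizes or {}).get(c, int(panel.pos[cmask].max()) + 1)
        pos = panel.pos[cmask]
        n_win = int(np.ceil(size / window_bp))
        win_of = (pos // window_bp).astype(int)
        m = len(idx)
        n_mat = np.zeros((n_win, m, m), dtype=int)
        k_mat = np.zeros((n_win, m, m), dtype=int)
        for a in range(m):
            ca = panel.calls[cmask, idx[a]]
            for b in range(a + 1, m):
                cb = panel.calls[cmask, idx[b]]
                ok = (ca != MISSING) & (cb != MISSING) & cls[cmask]
                n_mat[:, a, b] = np.bincount(win_of[ok], minlength=n_win)
                k_mat[:, a, b] = np.bincount(win_of[ok & (ca != cb)], minlength=n_win)
        n_mat += np.transpose(n_mat, (0, 2, 1))
        k_mat += np.transpose(k_mat, (0, 2, 1))
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(n_mat > 0, k_mat / np.maximum(n_mat, 1), np.nan)
        for wdx in range(n_win):
            wins.append((c, wdx * window_bp))
        rates.append(r)
        ns.append(n_mat)
    return wins, np.concatenate(rates), np.concatenate(ns)


def find_outlier_regions(
    panel: GenotypePanel,
    donor_samples: Sequence[str],
    window_bp: int = 5_000,
    pi_threshold: float = 0.01,
    region_bp: int = 20_000,
    site_class: set | None = None,
    min_sites: int = 10,
    chrom_sizes: dict | None = None,
) -> list[OutlierRegion]:
    """Regions where exactly one donor-taxon sample differs from all others.

    A window is a single-outlier window for sample s when every pairwise pi
    between s and the other samples exceeds ``pi_threshold`` while all
    pairs among the others stay at or below it (mutual similarity), with at
    least ``min_sites`` co-called sites per evaluated pair.  Consecutive
    windows with the same outlier merge; regions shorter than ``region_bp``
    are dropped.
    """
    if len(donor_samples) < 3:
        raise ValueError("need >= 3 donor-taxon samples")
    wins, rate, nmat = _window_pair_pi(panel, donor_samples, window_bp,
                                       site_class, chrom_sizes)
    m = len(donor_samples)
    regions: list[OutlierRegion] = []
    cur: OutlierRegion | None = None
    for widx, (c, start) in enumerate(wins):
        outlier = None
        informative = True
        for a in range(m):
            for b in range(a + 1, m):
                if nmat[widx, a, b] < min_sites or not np.isfinite(rate[widx, a, b]):
                    informative = False
        if informative:
            for s in range(m):
                others = [t for t in range(m) if t != s]
                far = all(rate[widx, s, t] > pi_threshold for t in others)
                near = all(rate[widx, a, b] <= pi_threshold
                           for ai, a in enumerate(others) for b in others[ai + 1:])
                if far and near:
                    outlier = donor_samples[s]
                    break
        if outlier is not None and cur is not None and cur.chromosome == c \
                and cur.outlier == outlier and cur.end == start:
            cur = OutlierRegion(c, cur.start, start + window_bp, outlier)
        else:
            if cur is not None and cur.length_bp >= region_bp:
                regions.append(cur)
            cur = OutlierRegion(c, start, start + window_bp, outlier) if outlier else None
    if cur is not None and cur.length_bp >= region_bp:
        regions.append(cur)
    return regions


def outlier_source_test(
    regions: Sequence[OutlierRegion],
    panel: GenotypePanel,
    donor_samples: Sequence[str],
    candidate_source: str,
    site_class: set | None = None,
    strict: bool = False,
) -> OutlierTestResult:
    """Is the outlier closer to the candidate source than non-outliers are?

    Per region, compares pi(outlier, source) with the mean pi(non-outlier,
    source) (or, with ``strict=True``, requires the outlier to beat every
    non-outlier).  Ties and regions with undefined comparisons are dropped
    from n.  p is the exact one-sided binomial tail against 50%.
    """
    from scipy.stats import binomtest

    if not regions:
        raise ValueError("no regions to test")
    k = n = 0
    for reg in regions:
        sub = _region_panel(panel, reg)
        d_out = pairwise_pi(sub, reg.outlier, candidate_source, site_class).pi
        others = [s for s in donor_samples if s != reg.outlier]
        d_others = [pairwise_pi(sub, s, candidate_source, site_class).pi for s in others]
        d_others = [d for d in d_others if np.isfinite(d)]
        if not np.isfinite(d_out) or not d_others:
            continue
        ref = min(d_others) if strict else float(np.mean(d_others))
        if d_out == ref:
            continue  # tie: uninformative
        n += 1
        if d_out < ref:
            k += 1
    if n == 0:
        raise ValueError("no informative regions")
    p = binomtest(k, n, 0.5, alternative="greater").pvalue
    return OutlierTestResult(k=k, n=n, p=float(p))


def binomial_outlier_p(k: int, n: int) -> float:
    """Exact one-sided binomial tail P(K >= k | n, 1/2)."""
    from scipy.stats import binomtest

    return float(binomtest(k, n, 0.5, alternative="greater").pvalue)


def _region_panel(panel: GenotypePanel, reg: OutlierRegion) -> GenotypePanel:
    mask = (panel.chrom == reg.chromosome) & (panel.pos >= reg.start) & (panel.pos < reg.end)
    return panel.subset_sites(np.nonzero(mask)[0])
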