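"""Windowed recombination rates from a genetic map and their rank
correlation with windowed divergence.

A negative genome-wide correlation between the local recombination rate and
absolute interspecific divergence is the signature of selection against
introgressed ancestry: introgressed (low-divergence) tracts persist longer
where recombination frees linked neutral sites from selected donor alleles.
Raw rates are the interpolated cM difference across each 100 kb window;
each is smoothed by the mean raw rate over the surrounding 500 kb.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .diversity import WindowStat
from .variant_io import GeneticMap, interpolate_cm

__all__ = [
    "RecombWindow",
    "CorrelationResult",
    "window_recomb_rates",
    "divergence_recomb_correlation",
    "covariate_check",
]


@dataclass
class RecombWindow:
    chromosome: str
    start: int
    end: int
    rate_cm_per_mb: float
    smoothed_cm_per_mb: float


@dataclass
class CorrelationResult:
    rho: float
    p: float
    n: int
    note: str = ""


def window_recomb_rates(
    gmap: GeneticMap,
    window_bp: int = 100_000,
    smooth_bp: int = 500_000,
) -> list[RecombWindow]:
    """Per-window recombination rates (cM/Mb), smoothed over the
    surrounding ``smooth_bp`` span (the centered run of windows; edge
    windows use the neighbors that exist).  Windows outside the marker
    range of the map are excluded."""
    half = max(0, int(round(smooth_bp / window_bp)) // 2)
    out: list[RecombWindow] = []
    for c in gmap.chromosomes():
        lo, hi = gmap.span(c)
        start0 = (lo // window_bp) * window_bp
        if start0 < lo:
            start0 += window_bp  # only windows fully inside map coverage
        raw, starts = [], []
        s = start0
        while s + window_bp <= hi:
            cm0 = interpolate_cm(gmap, c, s)
            cm1 = interpolate_cm(gmap, c, s + window_bp)
            raw.append((cm1 - cm0) / (window_bp / 1e6))
            starts.append(s)
            s += window_bp
        raw_arr = np.array(raw)
        for i, s in enumerate(starts):
            j0, j1 = max(0, i - half), min(len(raw_arr), i + half + 1)
            out.append(RecombWindow(c, s, s + window_bp,
                                    float(raw_arr[i]), float(raw_arr[j0:j1].mean())))
    return out


def _join(window_stats: Sequence[WindowStat], rates: Sequence[RecombWindow],
          min_comparisons: int):
    """Align divergence windows and rate windows on (chromosome, start);
    windows failing the comparison filter are excluded."""
    rate_by_key = {(str(r.chromosome), r.start): r.smoothed_cm_per_mb for r in rates}
    div, rec = [], []
    for ws in window_stats:
        if ws.n_sites < min_comparisons or not ws.defined:
            continue
        key = (str(ws.chromosome), ws.start)
        if key in rate_by_key:
            div.append(ws.pi)
            rec.append(rate_by_key[key])
    return np.array(div), np.array(rec)


def divergence_recomb_correlation(
    window_stats: Sequence[WindowStat],
    rates: Sequence[RecombWindow],
    min_comparisons: int = 100,
) -> CorrelationResult:
    """Spearman rank correlation between windowed divergence and the local
    recombination rate, over windows with at least ``min_comparisons``
    pairwise-compared sites."""
    from scipy.stats import spearmanr

    div, rec = _join(window_stats, rates, min_comparisons)
    if len(div) < 10:
        raise ValueError("fewer than 10 joinable windows")
    rho, p = spearmanr(div, rec)
    return CorrelationResult(rho=float(rho), p=float(p), n=len(div))


def covariate_check(
    window_stats: Sequence[WindowStat],
    rates: Sequence[RecombWindow],
    covariates: dict[str, dict[tuple[str, int], float]],
    min_comparisons: int = 100,
) -> dict[str, dict[str, CorrelationResult]]:
    """Recompute the correlation controlling for per-window covariates
    (e.g. outgroup divergence as a mutation-rate proxy, or mean depth).

    Two controls per covariate: (1) rank-residualization -- Spearman
    correlation of the residuals of divergence ranks and rate ranks after
    linear regression on the covariate's ranks; (2) stratification -- the
    correlation within covariate quartile strata, combined by an
    n-weighted mean of the per-stratum rho (p from the residualized test).
    A constant covariate falls back to the plain correlation with a note.
    """
    from scipy.stats import rankdata, spearmanr

    rate_by_key = {(str(r.chromosome), r.start): r.smoothed_cm_per_mb for r in rates}
    out: dict[str, dict[str, CorrelationResult]] = {}
    for name, cov_map in covariates.items():
        div, rec, cov = [], [], []
        for ws in window_stats:
            if ws.n_sites < min_comparisons or not ws.defined:
                continue
            key = (str(ws.chromosome), ws.start)
            if key in rate_by_key and key in cov_map and np.isfinite(cov_map[key]):
                div.append(ws.pi)
                rec.append(rate_by_key[key])
                cov.append(cov_map[key])
        div, rec, cov = np.array(div), np.array(rec), np.array(cov)
        if len(div) < 10:
            raise ValueError("fewer than 10 joinable windows")
        if np.all(cov == cov[0]):
            rho, p = spearmanr(div, rec)
            res = CorrelationResult(float(rho), float(p), len(div),
                                    note="constant covariate; plain correlation")
            out[name] = {"residualized": res, "stratified": res}
            continue
        rd, rr, rc = rankdata(div), rankdata(rec), rankdata(cov)
        res_d = rd - np.polyval(np.polyfit(rc, rd, 1), rc)
        res_r = rr - np.polyval(np.polyfit(rc, rr, 1), rc)
        rho, p = spearmanr(res_d, res_r)
        residualized = CorrelationResult(float(rho), float(p), len(div))
        # quartile strata of the covariate
        qs = np.quantile(cov, [0.25, 0.5, 0.75])
        strat = np.digitize(cov, qs)
        rhos, ns = [], []
        for qidx in range(4):
            m = strat == qidx
            if m.sum() >= 10:
                r_q, _ = spearmanr(div[m], rec[m])
                if np.isfinite(r_q):
                    rhos.append(r_q)
                    ns.append(int(m.sum()))
        if ns:
            rho_strat = float(np.average(rhos, weights=ns))
            stratified = CorrelationResult(rho_strat, float(p), int(np.sum(ns)),
                                           note="n-weighted mean rho across quartiles")
        else:
            stratified = CorrelationResult(float("nan"), float("nan"), 0,
                                           note="no stratum large enough")
        out[name] = {"residualized": residualized, "stratified": stratified}
    return out
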