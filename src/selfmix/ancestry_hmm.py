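"""Two-state local-ancestry HMM for detecting donor introgression.

The observation for each non-overlapping 1 kb window of a focal recipient
genome is the *minimum* divergence to a panel of donor-taxon samples: the
mismatch count ``k_min`` to the genetically closest donor out of ``n``
co-called sites.  Windows descending from recent introgression look like
within-donor comparisons; windows of resident ancestry look like ordinary
between-taxon comparisons.  The two hidden states are therefore calibrated
empirically:

* donor state   <- the genome-wide distribution of min divergence between a
  donor sample and its closest donor relative (a conspecific comparison);
* recipient state <- the distribution of min divergence between recipient
  samples and the closest donor (a heterospecific comparison).

Each reference distribution is summarized as a weighted histogram over
per-site mismatch probabilities; the emission likelihood of an observed
``(k, n)`` is the histogram-weighted binomial mixture, which conditions on
the window's own informative-site count ``n`` (heterogeneity in data density
is thereby absorbed into the binomial sampling term).  Because a minimum
over more comparisons is stochastically smaller, reference minima taken over
fewer comparisons than the focal sample's are resampled to the focal
``m`` before binning.

Transitions are parameterized by the admixture proportion ``alpha`` and the
per-window switch rate ``r`` (recombination probability per window times
generations since admixture), constant across windows:

    t[rec,rec] = (1-r) + r(1-alpha)    t[rec,don] = r alpha
    t[don,rec] = r(1-alpha)            t[don,don] = (1-r) + r alpha

Posterior decoding uses the forward-backward algorithm with per-window
scaling for underflow control; (alpha, r) are fitted by Nelder-Mead on the
forward log-likelihood, on a logit-transformed (unconstrained) scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .variant_io import GenotypePanel, MISSING

__all__ = [
    "EmissionWindow",
    "EmissionModel",
    "HMMParams",
    "PosteriorTrack",
    "compute_emission_windows",
    "build_emission_model",
    "transition_matrix",
    "forward_backward",
    "fit_hmm",
    "admixture_fraction",
]

RECIPIENT_STATE = 0
DONOR_STATE = 1


@dataclass
class EmissionWindow:
    """Minimum-divergence observation for one non-overlapping window."""

    chromosome: str
    start: int
    n_sites: int          # co-called sites vs the closest donor
    k_min: int            # mismatches to the closest donor
    closest_donor: str | None
    missing: bool = False

    @property
    def rate(self) -> float:
        return float("nan") if self.n_sites == 0 else self.k_min / self.n_sites


@dataclass
class EmissionModel:
    """Per-state weighted histograms over per-site mismatch probabilities."""

    bin_p: np.ndarray          # (n_bins,) mismatch probability per bin
    weights: np.ndarray        # (2, n_bins), rows sum to 1 (state x bin)
    m: int                     # donor comparisons the focal minima run over

    def log_emissions(self, k: np.ndarray, n: np.ndarray, missing: np.ndarray) -> np.ndarray:
        """(T, 2) log emission likelihoods; missing windows emit 1 in both
        states (log 0.0)."""
        from scipy.stats import binom

        T = len(k)
        out = np.zeros((T, 2))
        obs = ~missing
        if obs.any():
            kk = k[obs][:, None].astype(float)
            nn = n[obs][:, None].astype(float)
            pmf = binom.pmf(kk, nn, self.bin_p[None, :])  # (T_obs, B)
            for s in range(2):
                lik = pmf @ self.weights[s]
                out[obs, s] = np.log(np.maximum(lik, 1e-300))
        return out


@dataclass
class HMMParams:
    """Admixture proportion and per-window switch rate."""

    alpha: float
    r: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha <= 1.0) or not (0.0 <= self.r <= 1.0):
            raise ValueError("alpha and r must be in [0, 1]")

    @property
    def transition(self) -> np.ndarray:
        return transition_matrix(self.alpha, self.r)

    @property
    def initial(self) -> np.ndarray:
        """Stationary distribution (1 - alpha, alpha)."""
        return np.array([1.0 - self.alpha, self.alpha])


@dataclass
class PosteriorTrack:
    windows: list[EmissionWindow]
    posterior_donor: np.ndarray     # P(donor ancestry) per window
    log_likelihood: float
    params: HMMParams | None = None


def transition_matrix(alpha: float, r: float) -> np.ndarray:
    """Row-stochastic 2x2 transition matrix (recipient=row/col 0)."""
    if not (0.0 <= alpha <= 1.0) or not (0.0 <= r <= 1.0):
        raise ValueError("alpha and r must be in [0, 1]")
    return np.array([
        [(1 - r) + r * (1 - alpha), r * alpha],
        [r * (1 - alpha), (1 - r) + r * alpha],
    ])


# ---------------------------------------------------------------------------
# Emissions
# ---------------------------------------------------------------------------

def compute_emission_windows(
    panel: GenotypePanel,
    focal: str,
    donors: Sequence[str],
    window_bp: int = 1_000,
    site_class: set | None = None,
    chrom_sizes: dict | None = None,
) -> list[EmissionWindow]:
    """Minimum divergence to the donor panel in non-overlapping windows.

    Per window and donor, counts sites co-called in focal and donor (and in
    ``site_class``, if given) and mismatches among them; records the donor
    with the lowest mismatch *rate* (ties broken toward the first donor).
    Windows with no co-called sites against any donor are flagged missing.
    """
    if not donors:
        raise ValueError("need at least one donor")
    jf = panel.sample_index(focal)
    jd = [panel.sample_index(d) for d in donors]
    cf = panel.calls[:, jf]
    cls = panel.class_mask(site_class)
    out: list[EmissionWindow] = []
    for c in panel.chromosomes():
        cmask = panel.chrom == c
        size = (chrom_sizes or {}).get(c, int(panel.pos[cmask].max()) + 1)
        pos = panel.pos[cmask]
        n_win = int(np.ceil(size / window_bp))
        win_of_site = (pos // window_bp).astype(int)
        ns = np.zeros((n_win, len(jd)), dtype=int)
        ks = np.zeros((n_win, len(jd)), dtype=int)
        f = cf[cmask]
        okf = (f != MISSING) & cls[cmask]
        for di, j in enumerate(jd):
            d = panel.calls[cmask, j]
            ok = okf & (d != MISSING)
            ns[:, di] = np.bincount(win_of_site[ok], minlength=n_win)
            mism = ok & (f != d)
            ks[:, di] = np.bincount(win_of_site[mism], minlength=n_win)
        with np.errstate(divide="ignore", invalid="ignore"):
            rates = np.where(ns > 0, ks / np.maximum(ns, 1), np.inf)
        best = np.argmin(rates, axis=1)
        for w in range(n_win):
            di = int(best[w])
            if not np.isfinite(rates[w, di]):
                out.append(EmissionWindow(c, w * window_bp, 0, 0, None, missing=True))
            else:
                out.append(EmissionWindow(
                    c, w * window_bp, int(ns[w, di]), int(ks[w, di]), donors[di]))
    return out


def _resample_minima(
    rates: np.ndarray,
    m_source: int,
    m_target: int,
    n_draws: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Emulate minima over ``m_target`` comparisons from iid minima over
    ``m_source``: each draw takes the min of j source minima, where j has
    mean m_target/m_source (fractional part randomized)."""
    ratio = m_target / m_source
    j_lo = int(math.floor(ratio))
    frac = ratio - j_lo
    out = np.empty(n_draws)
    for i in range(n_draws):
        j = j_lo + (1 if rng.random() < frac else 0)
        j = max(j, 1)
        out[i] = rates[rng.integers(0, len(rates), size=j)].min()
    return out


def build_emission_model(
    conspecific_windows: Sequence[EmissionWindow],
    heterospecific_windows: Sequence[EmissionWindow],
    m: int,
    n_bins: int = 50,
    m_conspecific: int | None = None,
    pseudocount: float = 0.5,
    n_draws: int = 10_000,
    seed: int = 0,
) -> EmissionModel:
    """Calibrate the two emission histograms from reference window sets.

    ``conspecific_windows``: min divergence of donor samples to their
    closest donor relative (donor-state reference, minima over
    ``m_conspecific`` comparisons -- defaults to ``m``).
    ``heterospecific_windows``: min divergence of recipient samples to the
    closest donor (recipient-state reference, minima over ``m``).
    """
    rng = np.random.default_rng(seed)
    con = np.array([w.rate for w in conspecific_windows if not w.missing and w.n_sites > 0])
    het = np.array([w.rate for w in heterospecific_windows if not w.missing and w.n_sites > 0])
    if len(con) == 0 or len(het) == 0:
        raise ValueError("empty reference window set")
    if m_conspecific is not None and m_conspecific != m:
        con = _resample_minima(con, m_conspecific, m, n_draws, rng)
    top = max(con.max(), het.max(), 1e-6)
    edges = np.linspace(0.0, top * (1 + 1e-9), n_bins + 1)
    centers = np.clip((edges[:-1] + edges[1:]) / 2.0, 1e-9, 1 - 1e-9)
    weights = np.empty((2, n_bins))
    for s, data in ((RECIPIENT_STATE, het), (DONOR_STATE, con)):
        h, _ = np.histogram(data, bins=edges)
        w = h + pseudocount
        weights[s] = w / w.sum()
    return EmissionModel(bin_p=centers, weights=weights, m=m)


# ---------------------------------------------------------------------------
# Forward-backward
# ---------------------------------------------------------------------------

def _by_chromosome(windows: Sequence[EmissionWindow]):
    """Yield (chromosome, index array) keeping window order."""
    order: dict[str, list[int]] = {}
    for i, w in enumerate(windows):
        order.setdefault(w.chromosome, []).append(i)
    for c, idx in order.items():
        yield c, np.array(idx)


def _scaled_forward_backward(E: np.ndarray, trans: np.ndarray, init: np.ndarray):
    """Scaled forward-backward on one chain of likelihoods E (T, 2).
    Returns (posteriors (T,2), log-likelihood)."""
    T = E.shape[0]
    a = np.empty((T, 2))
    scale = np.empty(T)
    v = init * E[0]
    scale[0] = v.sum()
    a[0] = v / scale[0]
    t00, t01, t10, t11 = trans[0, 0], trans[0, 1], trans[1, 0], trans[1, 1]
    for t in range(1, T):
        p0 = (a[t - 1, 0] * t00 + a[t - 1, 1] * t10) * E[t, 0]
        p1 = (a[t - 1, 0] * t01 + a[t - 1, 1] * t11) * E[t, 1]
        s = p0 + p1
        scale[t] = s
        a[t, 0] = p0 / s
        a[t, 1] = p1 / s
    b = np.empty((T, 2))
    b[T - 1] = 1.0
    for t in range(T - 2, -1, -1):
        x0 = t00 * E[t + 1, 0] * b[t + 1, 0] + t01 * E[t + 1, 1] * b[t + 1, 1]
        x1 = t10 * E[t + 1, 0] * b[t + 1, 0] + t11 * E[t + 1, 1] * b[t + 1, 1]
        b[t, 0] = x0 / scale[t + 1]
        b[t, 1] = x1 / scale[t + 1]
    post = a * b
    post /= post.sum(axis=1, keepdims=True)
    return post, float(np.log(scale).sum())


def _likelihood_matrix(windows: Sequence[EmissionWindow], model: EmissionModel) -> np.ndarray:
    k = np.array([w.k_min for w in windows])
    n = np.array([w.n_sites for w in windows])
    miss = np.array([w.missing or w.n_sites == 0 for w in windows])
    logE = model.log_emissions(k, n, miss)
    # per-window rescaling for numerical range; posteriors are invariant to
    # uniform per-window rescaling and the scale is restored in the loglik
    shift = logE.max(axis=1, keepdims=True)
    E = np.exp(logE - shift)
    return E, shift[:, 0]


def forward_backward(
    windows: Sequence[EmissionWindow],
    model: EmissionModel,
    params: HMMParams,
) -> PosteriorTrack:
    """Posterior donor-ancestry probabilities per window.

    Chromosomes are independent chains; missing windows emit likelihood 1 in
    both states but still advance one transition step (constant per-window r
    preserves genome geometry).  Underflow is controlled by per-window
    scaling; the total log-likelihood sums over chromosomes.
    """
    E, shift = _likelihood_matrix(windows, model)
    trans = params.transition
    init = params.initial
    post = np.full(len(windows), np.nan)
    total = 0.0
    any_chain = False
    for c, idx in _by_chromosome(windows):
        Ec = E[idx]
        if np.all([windows[i].missing for i in idx]):
            # no data anywhere on this chromosome: posterior = prior
            post[idx] = params.alpha
            continue
        p, ll = _scaled_forward_backward(Ec, trans, init)
        post[idx] = p[:, DONOR_STATE]
        total += ll + shift[idx].sum()
        any_chain = True
    if not any_chain:
        raise ValueError("all chromosomes lack data")
    return PosteriorTrack(list(windows), post, total, params)


def _forward_loglik(E: np.ndarray, shift_sum: float, chains: list[np.ndarray],
                    alpha: float, r: float) -> float:
    trans = transition_matrix(alpha, r)
    init = np.array([1.0 - alpha, alpha])
    t00, t01, t10, t11 = trans[0, 0], trans[0, 1], trans[1, 0], trans[1, 1]
    total = shift_sum
    for idx in chains:
        Ec = E[idx]
        v0 = init[0] * Ec[0, 0]
        v1 = init[1] * Ec[0, 1]
        s = v0 + v1
        ll = math.log(s)
        v0, v1 = v0 / s, v1 / s
        for t in range(1, Ec.shape[0]):
            p0 = (v0 * t00 + v1 * t10) * Ec[t, 0]
            p1 = (v0 * t01 + v1 * t11) * Ec[t, 1]
            s = p0 + p1
            ll += math.log(s)
            v0, v1 = p0 / s, p1 / s
        total += ll
    return total


def _logit(x: float) -> float:
    x = min(max(x, 1e-12), 1 - 1e-12)
    return math.log(x / (1 - x))


def _expit(y: float) -> float:
    if y >= 0:
        return 1.0 / (1.0 + math.exp(-y))
    e = math.exp(y)
    return e / (1.0 + e)


def fit_hmm(
    windows: Sequence[EmissionWindow],
    model: EmissionModel,
    init: HMMParams | None = None,
    n_restarts: int = 5,
    tol: float = 1e-8,
) -> tuple[HMMParams, PosteriorTrack, dict]:
    """Maximum-likelihood (alpha, r) by Nelder-Mead on the forward loglik.

    Optimization runs on logit(alpha), logit(r); ``n_restarts`` spread
    initial points guard against local optima (the supplied ``init``, if
    any, is always among them).  Returns the fitted parameters, the
    posterior track decoded under them, and an info dict with the fitted
    log-likelihood and convergence flag.  The fitted log-likelihood is never
    allowed below the best initial point's.
    """
    from scipy.optimize import minimize

    E, shift = _likelihood_matrix(windows, model)
    shift_sum = float(np.sum([shift[i] for i, w in enumerate(windows)]))
    chains = [idx for _, idx in _by_chromosome(windows)
              if not all(windows[i].missing for i in idx)]
    if not chains:
        raise ValueError("all chromosomes lack data")

    def neg(y):
        return -_forward_loglik(E, shift_sum, chains, _expit(y[0]), _expit(y[1]))

    starts = [(0.1, 0.01), (0.3, 0.001), (0.02, 0.05), (0.5, 0.005), (0.15, 0.0005)]
    if init is not None:
        starts = [(init.alpha, init.r)] + starts
    best = None
    converged = False
    for alpha0, r0 in starts[:max(n_restarts, 1)]:
        y0 = np.array([_logit(alpha0), _logit(r0)])
        res = minimize(neg, y0, method="Nelder-Mead",
                       options={"fatol": tol, "xatol": 1e-6, "maxiter": 500})
        if best is None or res.fun < best.fun:
            best = res
            converged = bool(res.success)
    alpha_hat, r_hat = _expit(best.x[0]), _expit(best.x[1])
    fitted = HMMParams(alpha=alpha_hat, r=r_hat)
    # optimizer contract: never worse than the supplied initial point
    if init is not None:
        ll_init = _forward_loglik(E, shift_sum, chains, init.alpha, init.r)
        if -best.fun < ll_init:
            fitted = init
    track = forward_backward(windows, model, fitted)
    return fitted, track, {"log_likelihood": -float(best.fun),
                           "converged": converged}


def admixture_fraction(track: PosteriorTrack, mode: str = "posterior-weighted",
                       threshold: float = 0.5) -> float:
    """Genome-wide donor-ancestry fraction from a posterior track.

    ``posterior-weighted``: mean posterior over non-missing windows.
    ``threshold``: fraction of non-missing windows with posterior above
    ``threshold`` (at 0.5 this is the majority vote of decoded states).
    """
    if len(track.windows) == 0:
        raise ValueError("empty track")
    obs = np.array([not w.missing for w in track.windows])
    p = track.posterior_donor[obs]
    if len(p) == 0:
        return 0.0
    if mode == "posterior-weighted":
        return float(np.mean(p))
    if mode == "threshold":
        return float(np.mean(p > threshold))
    raise ValueError(f"unknown mode {mode!r}")
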