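"""Macroscopic clonal structure from a sample's sAGP (or CCF) spectrum.

Two competing descriptions of the filtered value vector Y are fitted and
compared by BIC:

* Model-1 (uni-modal + uniform background): maximum likelihood of
  l = sum ln( A/range(Y) + (1-A) * Normal(y_i; mu, sigma) ), A, mu in (0, 1).
* Model-2: Dirichlet-process mixture of normals, fitted by a collapsed
  Chinese-restaurant Gibbs sampler with a normal-inverse-gamma base measure
  (the 1-D specialization of a normal/inverse-Wishart), a Gamma(tau1/2,
  tau2/2) prior on the base-measure precision scale k0, and a Gamma(a0, b0)
  prior on the DP concentration alpha (Escobar-West update).

BIC counts 3 free parameters for Model-1 (A, mu, sigma) and 7 for Model-2
(a0, b0, k0, nu1, psi1, tau1, tau2); smaller BIC wins.  The number of
identifiable cell populations is the number of mixture components carrying
at least ``min_weight`` of the mass at the posterior point estimate.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.stats import norm

log = logging.getLogger(__name__)

try:
    from numba import njit
except ImportError:  # pragma: no cover - numba is a hard dependency
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f


@dataclass
class DPPriorConfig:
    """Hyperparameters and chain settings for the DP mixture sampler.

    mu1/psi1 default to the data mean/variance when left None ("conservative"
    diffuse base measure); nu1 = 4 gives the inverse-gamma variance prior a
    finite mean of psi1/2.
    """
    a0: float = 1.0
    b0: float = 1.0
    mu1: float | None = None
    nu1: float = 4.0
    psi1: float | None = None
    tau1: float = 1.0
    tau2: float = 1.0
    iterations: int = 10000
    burn_in: int = 2000
    thinning: int = 5
    seed: int = 0
    alpha_init: float = 1.0
    update_alpha: bool = True   # False fixes the DP concentration at alpha_init

    def __post_init__(self):
        for name in ("a0", "b0", "nu1", "tau1", "tau2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass
class Model1Fit:
    A: float
    mu: float
    sigma: float
    loglik: float


@dataclass
class DPFit:
    clusters: list[tuple[float, float, float]]  # (weight, mean, sd)
    loglik: float
    k_posterior: Counter = field(default_factory=Counter)
    converged: bool = True


@dataclass
class ClonalModelFit:
    model: str                      # "unimodal_uniform" | "dp_mixture"
    n_peaks: int
    bic1: float
    bic2: float
    fit1: Model1Fit | None
    fit2: DPFit | None


def prepare_sagp_vector(
    segments,
    euploid_fbaf: float = 0.04,
    euploid_lrr: float = 0.16,
    min_sagp: float = 0.05,
    min_bins: int = 50,
) -> tuple[np.ndarray, bool]:
    """Filter per-bin sAGP values into the clustering vector Y.

    Bins with median folded BAF <= euploid_fbaf and |median LRR| <= euploid_lrr
    are treated as euploid (sAGP 0); bins with missing sAGP are dropped;
    values <= min_sagp are removed (short true sCNAs diluted by flanking
    euploid sequence pile up there).  Returns (Y, analyzable) where analyzable
    is False when fewer than ``min_bins`` values survive.
    """
    fbaf = segments["med_fbaf"].to_numpy(dtype=float)
    lrr = segments["med_lrr"].to_numpy(dtype=float)
    p = segments["sagp"].to_numpy(dtype=float).copy()
    euploid = (fbaf <= euploid_fbaf) & (np.abs(lrr) <= euploid_lrr)
    p[euploid] = 0.0
    p = p[~np.isnan(p)]
    y = p[p > min_sagp]
    analyzable = len(y) >= min_bins
    if not analyzable:
        log.warning("only %d values survive filtering (< %d); sample flagged "
                    "unanalyzable for clonal-structure fitting", len(y), min_bins)
    return y, analyzable


# ---------------------------------------------------------------------------
# Model-1: uniform + single Gaussian

def model1_loglik(y: np.ndarray, A: float, mu: float, sigma: float) -> float:
    rng_y = float(np.ptp(y)) or 1.0
    dens = A / rng_y + (1.0 - A) * norm.pdf(y, mu, sigma)
    return float(np.sum(np.log(np.maximum(dens, 1e-300))))


def fit_model1(y: np.ndarray, min_points: int = 50) -> Model1Fit | None:
    """Multi-start bounded ML fit of the uniform + Gaussian model."""
    if len(y) < min_points:
        raise ValueError(f"need >= {min_points} values, got {len(y)}")
    rng_y = float(np.ptp(y)) or 1.0

    def neg(params):
        a, m, ls = params
        return -model1_loglik(y, a, m, math.exp(ls))

    bounds = [(1e-6, 1 - 1e-6), (1e-6, 1 - 1e-6),
              (math.log(1e-4), math.log(2.0))]
    best = None
    sd0 = max(float(np.std(y)), 1e-3)
    for m0 in np.quantile(y, [0.25, 0.5, 0.75]):
        for a0 in (0.1, 0.5, 0.9):
            for s0 in (sd0 / 4, sd0):
                res = minimize(neg, x0=[a0, float(np.clip(m0, 1e-4, 1 - 1e-4)),
                                        math.log(s0)],
                               method="L-BFGS-B", bounds=bounds)
                if res.success and (best is None or res.fun < best.fun):
                    best = res
    if best is None:
        log.warning("Model-1 optimizer failed on all starts")
        return None
    a, m, ls = best.x
    return Model1Fit(A=float(a), mu=float(m), sigma=float(math.exp(ls)),
                     loglik=float(-best.fun))


# ---------------------------------------------------------------------------
# Model-2: DP mixture of normals, collapsed CRP Gibbs

@njit(cache=False)
def _log_t_pred(y, n, s1, s2, k0, mu1, nu1, psi1):
    """Log posterior-predictive (Student-t) of y for a cluster with stats
    (n, sum, sumsq) under the normal-inverse-gamma base measure."""
    if n > 0:
        m = s1 / n
        ss = s2 - n * m * m
        if ss < 0.0:
            ss = 0.0
        kn = k0 + n
        mun = (k0 * mu1 + s1) / kn
        nun = nu1 + n
        psin = psi1 + ss + k0 * n * (m - mu1) ** 2 / kn
    else:
        kn, mun, nun, psin = k0, mu1, nu1, psi1
    scale2 = psin * (kn + 1.0) / (kn * nun)
    z = (y - mun) ** 2 / (nun * scale2)
    return (math.lgamma((nun + 1.0) / 2.0) - math.lgamma(nun / 2.0)
            - 0.5 * math.log(nun * math.pi * scale2)
            - (nun + 1.0) / 2.0 * math.log1p(z))


@njit(cache=False)
def _crp_sweep(y, z, counts, sums, sumsqs, K, alpha, k0, mu1, nu1, psi1, u):
    """One Gibbs sweep over cluster assignments (Neal's algorithm 3).

    Mutates z and the sufficient-statistic arrays in place; returns the
    updated number of occupied clusters.
    """
    n = y.shape[0]
    logw = np.empty(n + 1)
    for i in range(n):
        yi = y[i]
        c = z[i]
        counts[c] -= 1
        sums[c] -= yi
        sumsqs[c] -= yi * yi
        if counts[c] == 0:
            last = K - 1
            if c != last:
                counts[c] = counts[last]
                sums[c] = sums[last]
                sumsqs[c] = sumsqs[last]
                for j in range(n):
                    if z[j] == last:
                        z[j] = c
            K = last
        for c2 in range(K):
            logw[c2] = math.log(counts[c2]) + _log_t_pred(
                yi, counts[c2], sums[c2], sumsqs[c2], k0, mu1, nu1, psi1)
        logw[K] = math.log(alpha) + _log_t_pred(
            yi, 0, 0.0, 0.0, k0, mu1, nu1, psi1)
        mx = logw[0]
        for c2 in range(1, K + 1):
            if logw[c2] > mx:
                mx = logw[c2]
        tot = 0.0
        for c2 in range(K + 1):
            logw[c2] = math.exp(logw[c2] - mx)
            tot += logw[c2]
        target = u[i] * tot
        acc = 0.0
        newc = K
        for c2 in range(K + 1):
            acc += logw[c2]
            if target <= acc:
                newc = c2
                break
        if newc == K:
            counts[K] = 0
            sums[K] = 0.0
            sumsqs[K] = 0.0
            K += 1
        z[i] = newc
        counts[newc] += 1
        sums[newc] += yi
        sumsqs[newc] += yi * yi
    return K


def _mixture_loglik(y: np.ndarray, clusters) -> float:
    dens = np.zeros_like(y, dtype=float)
    for w, m, sd in clusters:
        dens += w * norm.pdf(y, m, sd)
    return float(np.sum(np.log(np.maximum(dens, 1e-300))))


def fit_model2_dp(y: np.ndarray, priors: DPPriorConfig | None = None,
                  min_points: int = 50) -> DPFit:
    """Fit the DP Gaussian mixture by collapsed Gibbs sampling.

    The reported point estimate is the posterior-mode number of occupied
    clusters, then the retained sample with the highest data log-density
    among states with that cluster count.  A non-convergence warning flag is
    set when the occupied-cluster count has not stabilized over the last
    quarter of the retained chain.
    """
    if len(y) < min_points:
        raise ValueError(f"need >= {min_points} values, got {len(y)}")
    if priors is None:
        priors = DPPriorConfig()
    # sort for exchangeability: permutations of the input then yield an
    # identical chain under a fixed seed
    y = np.sort(np.asarray(y, dtype=float))
    n = len(y)
    mu1 = float(np.mean(y)) if priors.mu1 is None else priors.mu1
    psi1 = float(np.var(y)) if priors.psi1 is None else priors.psi1
    psi1 = max(psi1, 1e-8)
    rng = np.random.default_rng(priors.seed)

    z = np.zeros(n, dtype=np.int64)
    counts = np.zeros(n + 1, dtype=np.int64)
    sums = np.zeros(n + 1)
    sumsqs = np.zeros(n + 1)
    counts[0] = n
    sums[0] = y.sum()
    sumsqs[0] = float(np.sum(y * y))
    K = 1
    alpha = priors.alpha_init
    k0 = 1.0

    kept: list[tuple[int, list, float]] = []
    for it in range(priors.iterations):
        u = rng.random(n)
        K = int(_crp_sweep(y, z, counts, sums, sumsqs, K, alpha, k0,
                           mu1, priors.nu1, psi1, u))
        # conjugate draws of per-cluster (sigma^2, mu)
        params = []
        sq_term = 0.0
        for c in range(K):
            nc, s1, s2 = counts[c], sums[c], sumsqs[c]
            m = s1 / nc
            ss = max(s2 - nc * m * m, 0.0)
            kn = k0 + nc
            mun = (k0 * mu1 + s1) / kn
            nun = priors.nu1 + nc
            psin = psi1 + ss + k0 * nc * (m - mu1) ** 2 / kn
            sigma2 = (psin / 2.0) / rng.gamma(nun / 2.0)
            mu_c = rng.normal(mun, math.sqrt(sigma2 / kn))
            params.append((nc / n, mu_c, math.sqrt(sigma2)))
            sq_term += (mu_c - mu1) ** 2 / (2.0 * sigma2)
        # k0 | clusters ~ Gamma(tau1/2 + K/2, tau2/2 + sum term)
        k0 = rng.gamma(priors.tau1 / 2.0 + K / 2.0,
                       1.0 / (priors.tau2 / 2.0 + sq_term))
        k0 = max(k0, 1e-8)
        if priors.update_alpha:
            # alpha | K, n (Escobar & West 1995) with Gamma(a0, b0) prior
            eta = rng.beta(alpha + 1.0, n)
            rate = priors.b0 - math.log(eta)
            odds = (priors.a0 + K - 1) / (n * rate)
            shape = priors.a0 + K if rng.random() < odds / (1 + odds) \
                else priors.a0 + K - 1
            alpha = max(rng.gamma(max(shape, 1e-3), 1.0 / rate), 1e-8)

        if it >= priors.burn_in and (it - priors.burn_in) % priors.thinning == 0:
            kept.append((K, params, _mixture_loglik(y, params)))

    if not kept:
        raise RuntimeError("chain produced no retained samples; increase "
                           "iterations or reduce burn_in")
    k_counts = Counter(k for k, _, _ in kept)
    k_mode = k_counts.most_common(1)[0][0]
    best = max((s for s in kept if s[0] == k_mode), key=lambda s: s[2])
    clusters = sorted(best[1], key=lambda c: c[1])
    tail = [k for k, _, _ in kept[-max(len(kept) // 4, 1):]]
    converged = Counter(tail).most_common(1)[0][1] >= 0.5 * len(tail)
    if not converged:
        log.warning("occupied-cluster count not stabilized over the last "
                    "quarter of the chain")
    return DPFit(clusters=clusters, loglik=best[2], k_posterior=k_counts,
                 converged=converged)


def count_peaks(fit: DPFit, min_weight: float = 0.05, grid_n: int = 2048) -> int:
    """Number of modes of the fitted mixture density.

    Components below ``min_weight`` are ignored; overlapping components that
    merge into a single density mode count once (the DP routinely shreds one
    tight population into several co-located clusters).
    """
    keep = [(w, m, sd) for w, m, sd in fit.clusters if w >= min_weight]
    if not keep:
        return 0
    if len(keep) == 1:
        return 1
    lo = min(m - 4 * sd for _, m, sd in keep)
    hi = max(m + 4 * sd for _, m, sd in keep)
    x = np.linspace(lo, hi, grid_n)
    dens = np.zeros_like(x)
    for w, m, sd in keep:
        dens += w * norm.pdf(x, m, sd)
    interior = (dens[1:-1] > dens[:-2]) & (dens[1:-1] >= dens[2:])
    n = int(np.count_nonzero(interior))
    if dens[0] > dens[1]:
        n += 1
    if dens[-1] > dens[-2]:
        n += 1
    return max(n, 1)


def select_model(fit1: Model1Fit | None, fit2: DPFit | None, n: int,
                 min_weight: float = 0.05) -> ClonalModelFit:
    """BIC model selection: k ln(n) - 2 loglik with k = 3 vs 7; smaller wins."""
    bic1 = 3 * math.log(n) - 2 * fit1.loglik if fit1 else math.inf
    bic2 = 7 * math.log(n) - 2 * fit2.loglik if fit2 else math.inf
    if fit1 is None and fit2 is None:
        raise ValueError("both model fits unavailable")
    if fit1 is None or fit2 is None:
        log.warning("one model fit unavailable; selecting the other")
    if bic1 <= bic2:
        return ClonalModelFit("unimodal_uniform", 1, bic1, bic2, fit1, fit2)
    return ClonalModelFit("dp_mixture", count_peaks(fit2, min_weight),
                          bic1, bic2, fit1, fit2)


def infer_clonal_structure(y: np.ndarray, priors: DPPriorConfig | None = None,
                           min_weight: float = 0.05,
                           min_points: int = 50) -> ClonalModelFit:
    """Fit both models on a filtered sAGP (or CCF) vector and select by BIC."""
    fit1 = fit_model1(y, min_points)
    fit2 = fit_model2_dp(y, priors, min_points)
    return select_model(fit1, fit2, len(y), min_weight)


def model_fit_table(fit: ClonalModelFit):
    """Flatten a ClonalModelFit for model_fit.tsv."""
    import pandas as pd

    rows = [{"model": fit.model, "n_peaks": fit.n_peaks,
             "bic_model1": fit.bic1, "bic_model2": fit.bic2,
             "component": "selection", "weight": np.nan, "mean": np.nan,
             "sd": np.nan}]
    if fit.fit1 is not None:
        rows.append({"model": "unimodal_uniform", "n_peaks": 1,
                     "bic_model1": fit.bic1, "bic_model2": fit.bic2,
                     "component": "uniform+peak", "weight": 1 - fit.fit1.A,
                     "mean": fit.fit1.mu, "sd": fit.fit1.sigma})
    if fit.fit2 is not None:
        for i, (w, m, sd) in enumerate(fit.fit2.clusters):
            rows.append({"model": "dp_mixture", "n_peaks": np.nan,
                         "bic_model1": fit.bic1, "bic_model2": fit.bic2,
                         "component": f"cluster_{i}", "weight": w,
                         "mean": m, "sd": sd})
    return pd.DataFrame(rows)
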