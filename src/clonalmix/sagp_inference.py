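"""Segmental aneuploid genome proportion (sAGP) inference.

Each copy state (n_b, n_t) traces a "canonical line" in (folded-BAF, LRR)
space as its local mixing fraction p runs from 0 (pure euploid) to 1 (pure
aneuploid):

    BAF(p) = |(p*n_b + 1 - p) / (p*n_t + 2*(1 - p)) - 0.5| + x0
    LRR(p) = log2(p*n_t + 2*(1 - p)) - 1 + y0

where (x0, y0) is the sample baseline, the observed position of the balanced
diploid state.  A segment is assigned to the closest canonical line if the
residual distance clears a noise threshold (criterion a); when several lines
qualify, the one whose implied average copy number is closest to the global
ploidy and whose p is closest to the sample-wide aneuploid fraction wins
(criterion b).  Segments matching no line are declared to violate the local
two-way-mixing hypothesis and carry a missing sAGP; segments inside the
euploid noise ellipse get p = 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import gaussian_kde

log = logging.getLogger(__name__)


class CopyState(NamedTuple):
    """Allele-specific copy state: n_b minor copies out of n_t total."""
    n_b: int
    n_t: int

    @property
    def n_a(self) -> int:
        return self.n_t - self.n_b


EUPLOID = CopyState(1, 2)


def candidate_states(max_nt: int = 6) -> list[CopyState]:
    """All states with 0 <= n_b <= n_t/2 and 1 <= n_t <= max_nt, minus the
    euploid reference (1, 2)."""
    states = [CopyState(nb, nt)
              for nt in range(1, max_nt + 1)
              for nb in range(0, nt // 2 + 1)]
    return [s for s in states if s != EUPLOID]


def mean_copy(state: CopyState, p) -> float:
    """Average total copy number of a two-way euploid/aneuploid mixture."""
    return 2.0 * (1.0 - p) + state.n_t * p


@dataclass
class SampleBaseline:
    """Observed coordinates and scatter of the balanced diploid cluster."""
    x0: float
    y0: float
    sd_baf: float
    sd_lrr: float
    p_s: float = 0.0      # sample-wide aneuploid genome proportion
    ploidy: float = 2.0   # genome-average copy number

    @property
    def threshold(self) -> float:
        """Criterion-(a) distance threshold: 2 * sqrt(sd_baf^2 + sd_lrr^2)."""
        return 2.0 * float(np.hypot(self.sd_baf, self.sd_lrr))


@dataclass
class SAGPEstimate:
    state: CopyState | None
    p: float | None
    residual: float
    n_candidates: int = 0
    candidates: list = field(default_factory=list)

    @property
    def missing(self) -> bool:
        return self.state is None


class BaselineError(RuntimeError):
    """No balanced diploid cluster could be located; sample unanalyzable."""


def canonical_position(state: CopyState, p, baseline: SampleBaseline | None = None,
                       base_state: CopyState = EUPLOID):
    """Theoretical (folded BAF + x0, LRR) of ``state`` at mixing fraction p.

    ``base_state`` generalizes the reference population for the genome-doubled
    case (AABB at the origin); the default is the balanced diploid AB.
    Accepts scalar or array p.
    """
    p = np.asarray(p, dtype=float)
    nb0, nt0 = base_state.n_b, base_state.n_t
    denom = p * state.n_t + nt0 * (1.0 - p)
    if np.any(denom <= 0):
        raise ValueError("degenerate mixture: total copy number is zero")
    x0 = baseline.x0 if baseline is not None else 0.0
    y0 = baseline.y0 if baseline is not None else 0.0
    fbaf = np.abs((p * state.n_b + nb0 * (1.0 - p)) / denom - 0.5) + x0
    lrr = np.log2(denom) - np.log2(nt0) + y0
    if fbaf.ndim == 0:
        return float(fbaf), float(lrr)
    return fbaf, lrr


# ---------------------------------------------------------------------------
# baseline

def estimate_baseline(
    segments: pd.DataFrame,
    fbaf_max: float = 0.1,
    lrr_window: float = 0.1,
    min_sd_baf: float = 1e-4,
    min_sd_lrr: float = 1e-4,
) -> SampleBaseline:
    """Locate the balanced diploid cluster and quantify its scatter.

    Takes segments with med_fbaf below ``fbaf_max``, finds the densest mode of
    their med_lrr (kernel density), and uses segments within ``lrr_window`` of
    that mode as the baseline cluster: (x0, y0) are its medians, sd_baf/sd_lrr
    its MAD * 1.4826 (floored so a noiseless sample keeps a usable
    criterion-(a) threshold).  Raises :class:`BaselineError` when no balanced
    segments exist.
    """
    if len(segments) < 10:
        raise BaselineError(f"only {len(segments)} segments; need >= 10")
    near = segments[segments["med_fbaf"].notna()
                    & (segments["med_fbaf"] < fbaf_max)]
    if len(near) == 0:
        raise BaselineError("no segment with med_fbaf < %.3g; cannot anchor "
                            "the euploid baseline" % fbaf_max)
    lrr = near["med_lrr"].to_numpy(dtype=float)
    if len(lrr) < 3 or np.std(lrr) < 1e-9:
        peak = float(np.median(lrr))
    else:
        kde = gaussian_kde(lrr)
        grid = np.linspace(lrr.min(), lrr.max(), 512)
        peak = float(grid[np.argmax(kde(grid))])
    cluster = near[np.abs(near["med_lrr"] - peak) <= lrr_window]
    if len(cluster) == 0:
        cluster = near
    x0 = float(np.median(cluster["med_fbaf"]))
    y0 = float(np.median(cluster["med_lrr"]))
    sd_baf = 1.4826 * float(np.median(np.abs(cluster["med_fbaf"] - x0)))
    sd_lrr = 1.4826 * float(np.median(np.abs(cluster["med_lrr"] - y0)))
    return SampleBaseline(x0=x0, y0=y0,
                          sd_baf=max(sd_baf, min_sd_baf),
                          sd_lrr=max(sd_lrr, min_sd_lrr))


# ---------------------------------------------------------------------------
# per-segment fitting

def _fit_state(fbaf: float, lrr: float, state: CopyState,
               baseline: SampleBaseline, base_state: CopyState = EUPLOID,
               grid: int = 101, xatol: float = 1e-6) -> tuple[float, float]:
    """Closest point of one canonical line to an observed segment.

    Grid scan over p (the fold in BAF makes the distance non-convex) seeds a
    bounded 1-D refinement.  Returns (p_hat, distance).
    """
    ps = np.linspace(0.0, 1.0, grid)
    bx, by = canonical_position(state, ps, baseline, base_state)
    d2 = (bx - fbaf) ** 2 + (by - lrr) ** 2
    i = int(np.argmin(d2))
    lo, hi = ps[max(i - 1, 0)], ps[min(i + 1, grid - 1)]

    def objective(p: float) -> float:
        x, y = canonical_position(state, p, baseline, base_state)
        return (x - fbaf) ** 2 + (y - lrr) ** 2

    res = minimize_scalar(objective, bounds=(lo, hi), method="bounded",
                          options={"xatol": xatol})
    if res.fun <= d2[i]:
        return float(res.x), float(np.sqrt(res.fun))
    return float(ps[i]), float(np.sqrt(d2[i]))


def fit_sagp(
    segment,
    baseline: SampleBaseline,
    states: Sequence[CopyState] | None = None,
    p_s: float | None = None,
    ploidy: float | None = None,
    threshold_mult: float = 2.0,
    base_state: CopyState = EUPLOID,
) -> SAGPEstimate:
    """Assign one segment to a canonical line and estimate its sAGP.

    ``segment`` is anything with med_fbaf / med_lrr attributes or keys.
    Criterion (a): minimized distance <= threshold_mult*sqrt(sd_baf^2+sd_lrr^2).
    Criterion (b): among survivors, argmin |mean_copy - ploidy| + |p_s - p|.
    Segments inside the euploid noise ellipse return p = 0; segments matching
    no line return a missing estimate.
    """
    fbaf = float(segment["med_fbaf"] if isinstance(segment, (dict, pd.Series))
                 else segment.med_fbaf)
    lrr = float(segment["med_lrr"] if isinstance(segment, (dict, pd.Series))
                else segment.med_lrr)
    if np.isnan(fbaf) or np.isnan(lrr):
        return SAGPEstimate(None, None, np.nan)
    if p_s is None:
        p_s = baseline.p_s
    if ploidy is None:
        ploidy = baseline.ploidy
    threshold = threshold_mult * float(np.hypot(baseline.sd_baf, baseline.sd_lrr))
    d0 = float(np.hypot(fbaf - baseline.x0, lrr - baseline.y0))
    if d0 <= threshold:
        return SAGPEstimate(EUPLOID, 0.0, d0, 0)
    if states is None:
        states = candidate_states()
    fits = [(s, *_fit_state(fbaf, lrr, s, baseline, base_state))
            for s in states]
    survivors = [(s, p, d) for s, p, d in fits if d <= threshold]
    if not survivors:
        return SAGPEstimate(None, None, min(d for _, _, d in fits), 0,
                            candidates=[])
    def crit_b(item):
        s, p, d = item
        return (abs(mean_copy(s, p) - ploidy) + abs(p_s - p), d)
    s, p, d = min(survivors, key=crit_b)
    return SAGPEstimate(s, p, d, len(survivors), candidates=survivors)


def estimate_global_context(estimates: Sequence[SAGPEstimate],
                            lengths: Sequence[float]) -> tuple[float, float]:
    """Sample-wide AGP (p_s) and genome-average ploidy from a first sAGP pass.

    Ploidy is the length-weighted mean of each segment's average copy number
    (euploid segments contribute 2; missing segments are excluded); p_s is the
    largest kernel-density peak of the per-sCNA p-hat distribution.
    """
    weights, copies, p_values = [], [], []
    for est, length in zip(estimates, lengths):
        if est.missing:
            continue
        weights.append(length)
        copies.append(mean_copy(est.state, est.p))
        if est.state != EUPLOID and est.p > 0:
            p_values.append(est.p)
    if not p_values:
        return 0.0, 2.0
    ploidy = float(np.average(copies, weights=weights)) if weights else 2.0
    ps = np.asarray(p_values)
    if len(ps) < 3 or np.std(ps) < 1e-9:
        p_s = float(np.median(ps))
    else:
        kde = gaussian_kde(ps)
        grid = np.linspace(0.0, 1.0, 1001)
        p_s = float(grid[np.argmax(kde(grid))])
    return p_s, ploidy


def fit_all_segments(
    segments: pd.DataFrame,
    baseline: SampleBaseline | None = None,
    states: Sequence[CopyState] | None = None,
    threshold_mult: float = 2.0,
    two_pass: bool = True,
    doubling_check: bool = False,
) -> pd.DataFrame:
    """Fit sAGP for every segment, with the two-pass p_s/ploidy refinement.

    Pass 1 runs with provisional p_s = median of first-pass p-hats and
    ploidy = 2 (criterion b needs quantities that themselves depend on sAGP);
    :func:`estimate_global_context` then fixes (p_s, ploidy) and pass 2
    re-selects among the cached per-line fits.  Returns a copy of ``segments``
    with n_b, n_t, sagp, residual, n_candidates columns; the fitted baseline
    (with p_s/ploidy filled) is attached as ``df.attrs["baseline"]``.
    """
    if baseline is None:
        baseline = estimate_baseline(segments)
    if states is None:
        states = candidate_states()
    base_state = EUPLOID
    if doubling_check:
        base_state = _resolve_doubling(segments, baseline, states,
                                       threshold_mult)

    first = [fit_sagp(row, baseline, states, 0.0, 2.0, threshold_mult,
                      base_state)
             for _, row in segments.iterrows()]
    # provisional per-segment p-hat: closest line, parsimony (smallest n_t)
    # breaking the exact ties among copy states whose canonical lines overlap
    first = [_select_parsimonious(e) for e in first]
    provisional = [e.p for e in first if not e.missing and e.p > 0]
    p_s0 = float(np.median(provisional)) if provisional else 0.0
    first = _reselect(first, p_s0, 2.0)
    lengths = (segments["end"] - segments["start"]).clip(lower=1).to_numpy()
    if two_pass:
        p_s, ploidy = estimate_global_context(first, lengths)
        final = _reselect(first, p_s, ploidy)
        p_s, ploidy = estimate_global_context(final, lengths)
    else:
        final, (p_s, ploidy) = first, (p_s0, 2.0)
    baseline.p_s, baseline.ploidy = p_s, ploidy

    out = segments.copy()
    out["n_b"] = [e.state.n_b if not e.missing else np.nan for e in final]
    out["n_t"] = [e.state.n_t if not e.missing else np.nan for e in final]
    out["sagp"] = [e.p if not e.missing else np.nan for e in final]
    out["residual"] = [e.residual for e in final]
    out["n_candidates"] = [e.n_candidates for e in final]
    out.attrs["baseline"] = baseline
    return out


def _select_parsimonious(est: SAGPEstimate) -> SAGPEstimate:
    """Pick the closest line among cached candidates, preferring fewer total
    copies on near-ties (overlapping-line degeneracy of n_b = 1 states)."""
    if est.missing or not est.candidates:
        return est
    s, p, d = min(est.candidates,
                  key=lambda it: (round(it[2], 6), it[0].n_t, it[0].n_b))
    return SAGPEstimate(s, p, d, est.n_candidates, est.candidates)


def _reselect(estimates: list[SAGPEstimate], p_s: float,
              ploidy: float) -> list[SAGPEstimate]:
    """Re-apply criterion (b) using cached per-line fits (no re-optimization)."""
    out = []
    for est in estimates:
        if est.missing or not est.candidates:
            out.append(est)
            continue
        def crit_b(item):
            s, p, d = item
            return (abs(mean_copy(s, p) - ploidy) + abs(p_s - p), d)
        s, p, d = min(est.candidates, key=crit_b)
        out.append(SAGPEstimate(s, p, d, est.n_candidates, est.candidates))
    return out


def _resolve_doubling(segments, baseline, states, threshold_mult) -> CopyState:
    """Heuristic AB-vs-AABB baseline disambiguation.

    Refits all segments with the near-origin cluster reinterpreted as the
    balanced tetraploid state and keeps whichever interpretation yields the
    smaller total criterion-(a) residual.  Defaults to AB; the choice is
    logged.
    """
    totals = {}
    for base in (EUPLOID, CopyState(2, 4)):
        resid = 0.0
        for _, row in segments.iterrows():
            est = fit_sagp(row, baseline, states, 0.0, 2.0, threshold_mult,
                           base)
            resid += est.residual if np.isfinite(est.residual) else 0.0
        totals[base] = resid
    chosen = min(totals, key=totals.get)
    log.info("baseline genotype check: AB residual %.4g, AABB residual %.4g "
             "-> using %s", totals[EUPLOID], totals[CopyState(2, 4)],
             "AB" if chosen == EUPLOID else "AABB")
    return chosen
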