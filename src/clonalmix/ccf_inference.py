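"""Cancer cell fraction (CCF) estimation for somatic point mutations.

A mutation inside a somatic copy-number alteration (sCNA) relates its somatic
allele frequency f to its CCF through the local copy state (n_b, n_t), the
sCNA's cell fraction p, and the lineage scenario tying mutation and sCNA
together:

    A1: mutation first, on the chromosome the sCNA then amplified/retained
    A2: mutation first, on the other parental chromosome
    B : sCNA first, mutation in a subset of sCNA-bearing cells
    C : mutation and sCNA on independent lineages

Each scenario implies three coexisting populations (r0 mutation- and
sCNA-free, r1, r2; r0+r1+r2 = 1) and an admissible SAF interval.  Scenario
likelihoods integrate the binomial read-count likelihood over that interval
(closed form via the regularized incomplete beta function); the smallest
scenario combination reaching a probability threshold is reported, and a CCF
point estimate exists whenever all scenarios in the set share one CCF
expression.  Posterior CCF moments use a uniform prior on CCF and the
binomial likelihood at the implied SAF.

CCF counts cells physically carrying at least one mutant copy, so for states
that lost a parental chromosome (n_b = 0) scenario A2 — mutation on the
subsequently lost allele — collapses onto the B/C expression.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import betainc, gammaln

from clonalmix.sagp_inference import EUPLOID, CopyState

log = logging.getLogger(__name__)

SCENARIOS = ("A1", "A2", "B", "C")


def mean_copy_number(p: float, n_t: int) -> float:
    """Average copy number at a locus mixing euploid and n_t-copy cells."""
    return 2.0 * (1.0 - p) + n_t * p


def admissible_scenarios(state: CopyState) -> tuple[str, ...]:
    """Scenarios attainable for a copy state.

    Hemizygous deletion and heterozygous amplification support all four; for
    LOH states (n_b = 0, n_t >= 2) and balanced gains (n_b = n_t/2 > 1) the
    A2 branch is degenerate (it duplicates another scenario's population
    structure) and the admissible set is (A1, B, C).
    """
    state = CopyState(*state)
    if state == EUPLOID:
        raise ValueError("euploid state has no mutation-sCNA scenarios; "
                         "caller handles euploid separately")
    if state.n_b == 0 and state.n_t == 1:
        return SCENARIOS
    if state.n_b == 0:
        return ("A1", "B", "C")
    if 2 * state.n_b == state.n_t:
        return ("A1", "B", "C")
    return SCENARIOS


def _mutant_multiplicity(state: CopyState, scenario: str) -> int:
    """Mutant-allele copies per r2 cell (A1/A2) implied by the scenario."""
    if scenario == "A1":
        return state.n_a
    if scenario == "A2":
        return state.n_b   # 0 when the mutated allele was lost
    raise ValueError(scenario)


def ccf_expression(f: float, state: CopyState, p: float, scenario: str):
    """CCF as a function of SAF for one scenario.

    General forms (n_bar = 2(1-p) + n_t*p):
      A1:   n_bar*f - p*n_a + p
      A2:   n_bar*f - p*n_b + p  (n_b >= 1); n_bar*f when n_b = 0
      B/C:  n_bar*f
    which reduce to the per-type special cases: amplification A1
    f(2+p) - p, others f(2+p); CN-LOH A1 2f - p, others 2f; deletion f(2-p)
    for every scenario.
    """
    state = CopyState(*state)
    n_bar = mean_copy_number(p, state.n_t)
    f = np.asarray(f, dtype=float)
    if scenario == "A1":
        out = n_bar * f - p * state.n_a + p
    elif scenario == "A2" and state.n_b >= 1:
        out = n_bar * f - p * state.n_b + p
    elif scenario in ("A2", "B", "C"):
        out = n_bar * f
    else:
        raise ValueError(f"unknown scenario {scenario!r}")
    return float(out) if out.ndim == 0 else out


def saf_bounds(state: CopyState, p: float, scenario: str) -> tuple[float, float]:
    """Admissible SAF interval [f_l, f_h] for a scenario at sAGP p.

    Derived from the three-population model: with m mutant copies per
    sCNA-bearing cell, A1/A2 give f = (r1 + m*p)/n_bar with r1 in [0, 1-p];
    B gives f = r2/n_bar with r2 in [0, p]; C gives f = r1/n_bar with r1 in
    [0, 1-p].
    """
    state = CopyState(*state)
    n_bar = mean_copy_number(p, state.n_t)
    if scenario in ("A1", "A2"):
        m = _mutant_multiplicity(state, scenario)
        return (m * p / n_bar, (1.0 - p + m * p) / n_bar)
    if scenario == "B":
        return (0.0, p / n_bar)
    if scenario == "C":
        return (0.0, (1.0 - p) / n_bar)
    raise ValueError(f"unknown scenario {scenario!r}")


# ---------------------------------------------------------------------------
# probabilistic scenario identification

def _binomial_zone_mass(s: int, n: int, f_l: float, f_h: float) -> float:
    """Integral of Binomial(s | n, f) over f in [f_l, f_h], closed form.

    int_a^b C(n,s) f^s (1-f)^(n-s) df
        = [I_b(s+1, n-s+1) - I_a(s+1, n-s+1)] / (n+1).
    """
    a = np.clip(f_l, 0.0, 1.0)
    b = np.clip(f_h, 0.0, 1.0)
    if b <= a:
        return 0.0
    return float(betainc(s + 1, n - s + 1, b) - betainc(s + 1, n - s + 1, a)) \
        / (n + 1)


def scenario_probabilities(s_count: int, n_depth: int, state: CopyState,
                           p: float) -> tuple[dict[str, float], bool]:
    """Normalized scenario probabilities p~_X from observed read counts.

    Returns (probs over admissible scenarios, out_of_zone flag).  When every
    zone integral underflows to zero (observed f far outside all zones) the
    probabilities fall back to uniform and the flag is set.
    """
    if not 0 <= s_count <= n_depth or n_depth < 1:
        raise ValueError("require 0 <= S <= N and N >= 1")
    scen = admissible_scenarios(state)
    raw = {x: _binomial_zone_mass(s_count, n_depth, *saf_bounds(state, p, x))
           for x in scen}
    total = sum(raw.values())
    if total <= 0.0:
        return {x: 1.0 / len(scen) for x in scen}, True
    return {x: v / total for x, v in raw.items()}, False


def assign_scenario(probs: dict[str, float],
                    threshold: float = 0.95) -> tuple[str, ...]:
    """Smallest scenario combination whose summed probability clears threshold.

    Singles, then pairs, then triples, then the full set; within a size class
    combinations are tried in decreasing summed probability (exact ties broken
    lexicographically).  The full admissible set is the terminal fallback.
    """
    labels = sorted(probs, key=SCENARIOS.index)
    for size in range(1, len(labels)):
        combos = sorted(itertools.combinations(labels, size),
                        key=lambda c: (-sum(probs[x] for x in c), c))
        for combo in combos:
            if sum(probs[x] for x in combo) >= threshold - 1e-12:
                return combo
    return tuple(labels)


def ccf_point_estimate(f: float, state: CopyState, p: float,
                       assigned_set: tuple[str, ...]):
    """CCF point estimate for an assigned scenario set, or missing.

    Returns (ccf_clipped, ccf_pre_clip, candidates).  ccf is missing (None)
    when the set mixes scenarios with different CCF expressions; the distinct
    candidate values are then retained for QC.
    """
    if not assigned_set:
        raise ValueError("assigned_set must be non-empty")
    values = [ccf_expression(f, state, p, x) for x in assigned_set]
    uniq: list[float] = []
    for v in values:
        if not any(abs(v - u) <= 1e-9 for u in uniq):
            uniq.append(v)
    if len(uniq) > 1:
        return None, None, uniq
    raw = uniq[0]
    return float(np.clip(raw, 0.0, 1.0)), float(raw), uniq


def _implied_saf(x, state: CopyState | None, p: float, scenario: str):
    """G(x): the SAF implied by CCF = x under a scenario (clipped to [0,1])."""
    if state is None or CopyState(*state) == EUPLOID:
        return np.clip(np.asarray(x, float) / 2.0, 0.0, 1.0)
    state = CopyState(*state)
    n_bar = mean_copy_number(p, state.n_t)
    if scenario == "A1":
        c = p * (state.n_a - 1)
    elif scenario == "A2" and state.n_b >= 1:
        c = p * (state.n_b - 1)
    else:
        c = 0.0
    return np.clip((np.asarray(x, float) + c) / n_bar, 0.0, 1.0)


def ccf_posterior_moments(s_count: int, n_depth: int, state: CopyState | None,
                          p: float, scenario: str, grid_n: int = 2001):
    """Posterior mean and variance of CCF under a uniform prior on [0, 1].

    The posterior density is proportional to Binomial(S | N, G(x)) with G the
    inverse CCF expression; moments come from fixed-grid Simpson quadrature.
    Returns (exp, var, flag) where flag marks a degenerate/underflowed
    posterior (moments are then NaN).
    """
    x = np.linspace(0.0, 1.0, grid_n)
    g = _implied_saf(x, state, p, scenario)
    if np.ptp(g) <= 0.0:
        return np.nan, np.nan, True
    with np.errstate(divide="ignore", invalid="ignore"):
        loglik = s_count * np.log(g) + (n_depth - s_count) * np.log1p(-g)
    loglik = np.where(np.isfinite(loglik), loglik, -np.inf)
    m = np.max(loglik)
    if not np.isfinite(m):
        return np.nan, np.nan, True
    dens = np.exp(loglik - m)
    from scipy.integrate import simpson
    norm = simpson(dens, x=x)
    if norm <= 0:
        return np.nan, np.nan, True
    ex = simpson(dens * x, x=x) / norm
    ex2 = simpson(dens * x * x, x=x) / norm
    return float(ex), float(max(ex2 - ex ** 2, 0.0)), False


@dataclass
class CCFEstimate:
    """Per-variant CCF inference result."""
    ccf: float | None
    ccf_pre_clip: float | None
    ccf_exp: float
    ccf_var: float
    scenario_set: tuple[str, ...] | None
    probs: dict[str, float] = field(default_factory=dict)
    flag: str = ""


def estimate_ccf_for_variant(
    s_count: int,
    n_depth: int,
    state: CopyState | None,
    p: float | None,
    threshold: float = 0.95,
    grid_n: int = 2001,
) -> CCFEstimate:
    """Full per-variant CCF inference given its host segment's sAGP estimate.

    No overlapping sCNA (or p = 0): CCF = 2f, no scenario machinery.  Host
    sCNA with missing sAGP: CCF missing.  Otherwise: scenario probabilities ->
    smallest qualifying scenario set -> point estimate (missing on conflicting
    expressions) -> posterior moments for the shared expression.
    """
    f = s_count / n_depth
    if state is not None and (p is None or (isinstance(p, float) and np.isnan(p))):
        return CCFEstimate(None, None, np.nan, np.nan, None, {},
                           flag="host_sagp_missing")
    if state is None or CopyState(*state) == EUPLOID or p == 0:
        raw = 2.0 * f
        ex, var, bad = ccf_posterior_moments(s_count, n_depth, None, 0.0,
                                             "diploid", grid_n)
        return CCFEstimate(float(np.clip(raw, 0, 1)), raw, ex, var, None, {},
                           flag="euploid")
    state = CopyState(*state)
    probs, out_of_zone = scenario_probabilities(s_count, n_depth, state, p)
    if out_of_zone:
        # observed f incompatible with every zone under this (state, p):
        # report the shared B/C expression at low confidence
        raw = ccf_expression(f, state, p, "B")
        ex, var, _ = ccf_posterior_moments(s_count, n_depth, state, p, "B",
                                           grid_n)
        return CCFEstimate(float(np.clip(raw, 0, 1)), raw, ex, var,
                           tuple(probs), probs, flag="out_of_zone")
    assigned = assign_scenario(probs, threshold)
    ccf, raw, candidates = ccf_point_estimate(f, state, p, assigned)
    if ccf is None:
        return CCFEstimate(None, None, np.nan, np.nan, assigned, probs,
                           flag="conflicting_expressions")
    ex, var, bad = ccf_posterior_moments(s_count, n_depth, state, p,
                                         assigned[0], grid_n)
    return CCFEstimate(ccf, raw, ex, var, assigned, probs,
                       flag="degenerate_posterior" if bad else "")


def _segment_lookup(segments: pd.DataFrame):
    """Map (chrom, pos) to a segment row index via per-chromosome binary search."""
    by_chrom = {}
    for chrom, cdf in segments.groupby("chrom", sort=False):
        by_chrom[chrom] = (cdf["start"].to_numpy(), cdf["end"].to_numpy(),
                           cdf.index.to_numpy())

    def lookup(chrom, pos):
        if chrom not in by_chrom:
            return None
        starts, ends, idx = by_chrom[chrom]
        i = np.searchsorted(starts, pos, side="right") - 1
        if i >= 0 and pos <= ends[i]:
            return idx[i]
        return None

    return lookup


def estimate_ccf_batch(
    variants: pd.DataFrame,
    segments: pd.DataFrame,
    threshold: float = 0.95,
    min_depth: int = 0,
    min_saf: float = 0.0,
    grid_n: int = 2001,
) -> pd.DataFrame:
    """CCF inference for a variant table against fitted segments.

    ``segments`` must carry n_b / n_t / sagp columns (NaN for missing).
    Variants failing the depth/SAF filters are dropped (counted in attrs).
    """
    keep = (variants["n_depth"] >= min_depth) & (variants["saf"] >= min_saf)
    n_filtered = int((~keep).sum())
    variants = variants[keep].reset_index(drop=True)
    lookup = _segment_lookup(segments)
    rows = []
    for _, v in variants.iterrows():
        si = lookup(v["chrom"], v["pos"])
        if si is None:
            state, p = None, None
        else:
            seg = segments.loc[si]
            if np.isnan(seg["sagp"]):
                state, p = CopyState(0, 1), np.nan  # host sCNA, sAGP missing
            elif seg["sagp"] == 0 or (seg["n_b"] == 1 and seg["n_t"] == 2):
                state, p = None, None
            else:
                state = CopyState(int(seg["n_b"]), int(seg["n_t"]))
                p = float(seg["sagp"])
        est = estimate_ccf_for_variant(int(v["s_count"]), int(v["n_depth"]),
                                       state, p, threshold, grid_n)
        rows.append({
            "chrom": v["chrom"], "pos": v["pos"],
            "s_count": int(v["s_count"]), "n_depth": int(v["n_depth"]),
            "saf": float(v["saf"]),
            "scenario_set": ("|".join(est.scenario_set)
                            if est.scenario_set else "NA"),
            "p_A1": est.probs.get("A1", np.nan),
            "p_A2": est.probs.get("A2", np.nan),
            "p_B": est.probs.get("B", np.nan),
            "p_C": est.probs.get("C", np.nan),
            "ccf": est.ccf if est.ccf is not None else np.nan,
            "ccf_pre_clip": (est.ccf_pre_clip
                             if est.ccf_pre_clip is not None else np.nan),
            "ccf_exp": est.ccf_exp, "ccf_var": est.ccf_var,
            "flag": est.flag,
        })
    out = pd.DataFrame(rows)
    out.attrs["n_filtered"] = n_filtered
    return out
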