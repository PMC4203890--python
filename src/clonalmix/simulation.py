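"""Synthetic tumors for validating sAGP and CCF inference.

The generator emulates a tumor whose genome mixes euploid segments with
sCNAs carried by a dominant and a minor clone.  Segment-level observables
follow the noise model

    fBAF = |0.5 - (p*n_b + 1 - p)/n_bar| + Normal(0, sigma_BAF)
    LRR  = log2(n_bar) - 1 + Normal(0, sigma_LRR),   n_bar = 2(1-p) + n_t*p

with sigma_BAF = 0.01 and sigma_LRR = 0.04 by default (equivalent to the
per-segment standard error of roughly 36 array markers).  Somatic variants
are placed uniformly along the genome; inside an sCNA a lineage scenario is
drawn uniformly from the admissible set, the SAF uniformly from that
scenario's admissible interval, and read counts as N ~ Poisson(k) (zero
redrawn), S ~ Binomial(N, f).  Variant truth is deliberately constructed
from the *estimated* (sAGP, n_b, n_t) of the host segment, so the CCF score
isolates the read-count/scenario part of the problem the way the original
validation protocol does.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import pearsonr, spearmanr

from clonalmix.ccf_inference import (admissible_scenarios, ccf_expression,
                                     estimate_ccf_batch, saf_bounds)
from clonalmix.sagp_inference import (EUPLOID, CopyState, estimate_baseline,
                                      fit_all_segments, mean_copy)

log = logging.getLogger(__name__)


def default_state_ratios() -> dict[CopyState, float]:
    """2/7 deletion, 2/7 CN-LOH, 2/7 amplification, 1/7 balanced doubling."""
    return {CopyState(0, 1): 2 / 7, CopyState(0, 2): 2 / 7,
            CopyState(1, 3): 2 / 7, CopyState(2, 4): 1 / 7}


@dataclass
class SimulationConfig:
    p_dom: float = 0.9
    p_sub: float = 0.4
    n_euploid: int = 200
    n_scna: int = 200
    dom_count: int | None = None          # default: round(2/3 * n_scna) = 133
    state_ratios: dict = field(default_factory=default_state_ratios)
    sigma_baf: float = 0.01
    sigma_lrr: float = 0.04
    n_snv: int = 4000
    coverage: float = 50.0
    markers_per_segment: int = 36
    segment_length: int = 110_000
    seed: int = 0

    def __post_init__(self):
        if self.p_sub >= self.p_dom:
            raise ValueError("p_sub must be < p_dom")
        if abs(sum(self.state_ratios.values()) - 1.0) > 1e-9:
            raise ValueError("state_ratios must sum to 1")
        if min(self.sigma_baf, self.sigma_lrr) < 0:
            raise ValueError("sigma must be non-negative")

    @property
    def n_dom(self) -> int:
        return self.dom_count if self.dom_count is not None \
            else round(self.n_scna * 2 / 3)


def observed_segment_signal(state: CopyState, p: float, sigma_baf: float,
                            sigma_lrr: float, rng: np.random.Generator):
    """Noisy (med_fbaf, med_lrr) of one segment under the two-way model."""
    n_bar = mean_copy(state, p)
    fbaf = abs(0.5 - (p * state.n_b + 1.0 - p) / n_bar)
    lrr = np.log2(n_bar) - 1.0
    return (fbaf + rng.normal(0.0, sigma_baf) if sigma_baf > 0 else fbaf,
            lrr + rng.normal(0.0, sigma_lrr) if sigma_lrr > 0 else lrr)


def _draw_states(n: int, ratios: dict, rng: np.random.Generator):
    states = list(ratios)
    probs = np.array([ratios[s] for s in states])
    idx = rng.choice(len(states), size=n, p=probs / probs.sum())
    return [states[i] for i in idx]


def simulate_scna_dataset(config: SimulationConfig,
                          rng: np.random.Generator | None = None,
                          sagp_values: np.ndarray | None = None
                          ) -> pd.DataFrame:
    """Simulate the segment table for one tumor.

    ``sagp_values``, when given, overrides the dominant/minor clone split
    with one explicit sAGP per sCNA segment (used by the comparison
    protocol's U(0,1) draw).  Segment order along the genome is shuffled.
    Truth columns: true_nb, true_nt, true_p, clone.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    records = []
    for _ in range(config.n_euploid):
        records.append((EUPLOID, 0.0, "euploid"))
    if sagp_values is not None:
        if len(sagp_values) != config.n_scna:
            raise ValueError("need one sAGP per sCNA segment")
        states = _draw_states(config.n_scna, config.state_ratios, rng)
        for st, p in zip(states, sagp_values):
            records.append((st, float(p), "scna"))
    else:
        n_dom = config.n_dom
        states = _draw_states(config.n_scna, config.state_ratios, rng)
        for i, st in enumerate(states):
            if i < n_dom:
                records.append((st, config.p_dom, "dominant"))
            else:
                records.append((st, config.p_sub, "minor"))
    order = rng.permutation(len(records))
    rows = []
    L = config.segment_length
    for slot, i in enumerate(order):
        st, p, clone = records[i]
        fbaf, lrr = observed_segment_signal(st, p, config.sigma_baf,
                                            config.sigma_lrr, rng)
        rows.append({
            "chrom": "sim1",
            "start": slot * L + 1,
            "end": (slot + 1) * L,
            "n_snps": config.markers_per_segment,
            "n_het": config.markers_per_segment,
            "med_lrr": lrr,
            "med_fbaf": fbaf,
            "unit_kind": "scna",
            "true_nb": st.n_b, "true_nt": st.n_t, "true_p": p,
            "clone": clone,
        })
    return pd.DataFrame(rows)


def sagp_grid(step: float = 0.1) -> list[tuple[float, float]]:
    """All (p_dom, p_sub) pairs: p_dom in {step..1}, p_sub in {0..p_dom-step}."""
    n = round(1.0 / step)
    if abs(n * step - 1.0) > 1e-9:
        raise ValueError("step must divide 1")
    pairs = []
    for i in range(1, n + 1):
        p_dom = i * step
        for j in range(0, i):
            pairs.append((round(p_dom, 10), round(j * step, 10)))
    return pairs


def simulate_snv_dataset(config: SimulationConfig, fitted: pd.DataFrame,
                         rng: np.random.Generator | None = None
                         ) -> pd.DataFrame:
    """Simulate somatic variants on a fitted segment table.

    Hosts are drawn length-weighted among segments with a non-missing sAGP
    estimate.  On a segment estimated euploid (sAGP 0) the SAF is U(0, 0.5)
    and true CCF = 2f; on an estimated sCNA the scenario is uniform over the
    admissible set and the SAF uniform inside the scenario's zone.  Depth
    N ~ Poisson(coverage) with zeros redrawn; S ~ Binomial(N, f).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    eligible = fitted[fitted["sagp"].notna()].reset_index(drop=True)
    if len(eligible) == 0:
        raise ValueError("no segment with a usable sAGP estimate")
    lengths = (eligible["end"] - eligible["start"] + 1).to_numpy(dtype=float)
    hosts = rng.choice(len(eligible), size=config.n_snv,
                       p=lengths / lengths.sum())
    rows = []
    for h in hosts:
        seg = eligible.iloc[h]
        pos = int(rng.integers(seg["start"], seg["end"] + 1))
        p_hat = float(seg["sagp"])
        state = CopyState(int(seg["n_b"]), int(seg["n_t"]))
        if p_hat == 0.0 or state == EUPLOID:
            f = float(rng.uniform(0.0, 0.5))
            ccf, scenario, host_kind = 2.0 * f, "E", "euploid"
        else:
            scenario = str(rng.choice(admissible_scenarios(state)))
            f_l, f_h = saf_bounds(state, p_hat, scenario)
            f = float(rng.uniform(f_l, f_h))
            ccf = float(ccf_expression(f, state, p_hat, scenario))
            host_kind = "scna"
        n_depth = 0
        while n_depth < 1:
            n_depth = int(rng.poisson(config.coverage))
        s_count = int(rng.binomial(n_depth, min(max(f, 0.0), 1.0)))
        rows.append({
            "chrom": seg["chrom"], "pos": pos,
            "s_count": s_count, "n_depth": n_depth,
            "saf": s_count / n_depth,
            "true_scenario": scenario, "true_f": f, "true_ccf": ccf,
            "host_kind": host_kind, "host_clone": seg.get("clone", "NA"),
            "host_nb": state.n_b, "host_nt": state.n_t, "host_p": p_hat,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# scoring

def evaluate_sagp(fitted: pd.DataFrame) -> dict:
    """State-error rates and sAGP MADs, stratified dominant/minor.

    A wrong or missing (n_b, n_t) counts as a state error.  MADs are reported
    for correctly-typed segments and for all segments with an estimate.
    """
    out: dict[str, float] = {}
    scna = fitted[fitted["clone"] != "euploid"]
    for clone in ("dominant", "minor", "scna"):
        sub = scna if clone == "scna" else scna[scna["clone"] == clone]
        if len(sub) == 0:
            continue
        est_ok = sub["sagp"].notna()
        correct = est_ok & (sub["n_b"] == sub["true_nb"]) \
            & (sub["n_t"] == sub["true_nt"])
        # truly-euploid "minor" segments (p_sub = 0) count as correct when
        # estimated euploid
        if (sub["true_p"] == 0).any():
            true_eu = sub["true_p"] == 0
            correct |= true_eu & est_ok & (sub["sagp"] == 0)
        out[f"state_error_{clone}"] = float(1.0 - correct.mean())
        out[f"missing_rate_{clone}"] = float((~est_ok).mean())
        err = np.abs(sub["sagp"] - sub["true_p"])
        if correct.any():
            out[f"mad_{clone}_correct"] = float(np.median(err[correct]))
        if est_ok.any():
            out[f"mad_{clone}_all"] = float(np.median(err[est_ok]))
    eu = fitted[fitted["clone"] == "euploid"]
    if len(eu):
        ok = eu["sagp"].notna()
        out["euploid_called_zero"] = float((ok & (eu["sagp"] == 0)).mean())
    return out


def evaluate_ccf(variants: pd.DataFrame, min_stratum: int = 3) -> dict:
    """Correlations and MAD between true and estimated CCF, plus strata."""
    est = variants["ccf"].to_numpy(dtype=float)
    true = variants["true_ccf"].to_numpy(dtype=float)
    ok = ~np.isnan(est)
    out = {"n_total": int(len(variants)), "n_estimated": int(ok.sum()),
           "fraction_estimated": float(ok.mean()) if len(variants) else np.nan}

    def _score(mask, prefix):
        mask = mask & ok
        if mask.sum() < min_stratum:
            out[f"{prefix}spearman"] = np.nan
            return
        out[f"{prefix}spearman"] = float(spearmanr(true[mask], est[mask])[0])
        out[f"{prefix}pearson"] = float(pearsonr(true[mask], est[mask])[0])
        out[f"{prefix}mad"] = float(np.median(np.abs(true[mask] - est[mask])))

    _score(np.ones(len(variants), bool), "")
    host = variants["host_kind"].to_numpy()
    _score(host == "euploid", "euploid_")
    _score(host == "scna", "scna_")
    clones = variants["host_clone"].to_numpy()
    for clone in ("dominant", "minor"):
        _score((host == "scna") & (clones == clone), f"{clone}_")
    for nb, nt, name in [(0, 1, "deletion"), (0, 2, "cnloh"),
                         (1, 3, "amplification"), (2, 4, "balanced")]:
        _score((host == "scna") & (variants["host_nb"] == nb)
               & (variants["host_nt"] == nt), f"{name}_")
    return out


# ---------------------------------------------------------------------------
# naive comparison estimators (mis-specified on purpose)

def ccf_ignore_r1(variants: pd.DataFrame) -> np.ndarray:
    """Mis-specified estimator assuming mutation and sCNA always co-occur.

    Inverts f = CCF * n_a / n_bar, i.e. ignores the sCNA-free mutated
    population r1; underestimates CCF whenever the mutation predates the
    sCNA (scenarios A1/A2 with r1 > 0).
    """
    out = np.empty(len(variants))
    for i, (_, v) in enumerate(variants.iterrows()):
        f = v["saf"]
        if v["host_kind"] == "euploid":
            out[i] = np.clip(2.0 * f, 0, 1)
        else:
            n_bar = mean_copy_number_row(v)
            n_a = v["host_nt"] - v["host_nb"]
            out[i] = np.clip(n_bar * f / max(n_a, 1), 0, 1)
    return out


def ccf_force_a1(variants: pd.DataFrame) -> np.ndarray:
    """Mis-specified estimator applying the mutation-first (A1) inversion to
    every mutation regardless of its actual lineage scenario."""
    out = np.empty(len(variants))
    for i, (_, v) in enumerate(variants.iterrows()):
        f = v["saf"]
        if v["host_kind"] == "euploid":
            out[i] = np.clip(2.0 * f, 0, 1)
        else:
            st = CopyState(int(v["host_nb"]), int(v["host_nt"]))
            out[i] = np.clip(ccf_expression(f, st, v["host_p"], "A1"), 0, 1)
    return out


def mean_copy_number_row(v) -> float:
    return 2.0 * (1.0 - v["host_p"]) + v["host_nt"] * v["host_p"]


# ---------------------------------------------------------------------------
# protocols

CCF_VALIDATION_CASES = ((0.9, 0.8), (0.9, 0.4), (0.5, 0.3), (0.3, 0.1))


def run_ccf_case(p_dom: float, p_sub: float, coverage: float, seed: int,
                 n_snv: int = 4000, sigma_baf: float = 0.01,
                 sigma_lrr: float = 0.04) -> dict:
    """One CCF-validation case: simulate segments, fit sAGP, simulate and
    estimate variants, score."""
    cfg = SimulationConfig(p_dom=p_dom, p_sub=p_sub, coverage=coverage,
                           n_snv=n_snv, sigma_baf=sigma_baf,
                           sigma_lrr=sigma_lrr, seed=seed)
    rng = np.random.default_rng(seed)
    segments = simulate_scna_dataset(cfg, rng)
    fitted = fit_all_segments(segments)
    variants = simulate_snv_dataset(cfg, fitted, rng)
    est = estimate_ccf_batch(variants, fitted)
    merged = pd.concat([variants.reset_index(drop=True),
                        est[["scenario_set", "ccf", "ccf_exp", "ccf_var",
                             "flag"]].reset_index(drop=True)], axis=1)
    metrics = evaluate_ccf(merged)
    metrics.update({"p_dom": p_dom, "p_sub": p_sub, "coverage": coverage})
    metrics["sagp"] = evaluate_sagp(fitted)
    metrics["variants"] = merged
    return metrics


def run_ccf_validation(seed: int = 0, cases=CCF_VALIDATION_CASES,
                       coverages=(50, 100), n_snv: int = 4000) -> dict:
    """The full CCF-validation protocol: every case x coverage, plus the
    minimum Spearman correlation across them."""
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(cases) * len(coverages))
    results, i = [], 0
    for p_dom, p_sub in cases:
        for k in coverages:
            case_seed = int(children[i].generate_state(1)[0] % (2 ** 31))
            i += 1
            results.append(run_ccf_case(p_dom, p_sub, k, case_seed, n_snv))
    return {"cases": results,
            "min_spearman": min(r["spearman"] for r in results),
            "n_variants": sum(r["n_total"] for r in results)}


def run_comparison_protocol(seed: int = 0, n_cna: int = 200,
                            n_mut: int = 1000, coverage: float = 50.0) -> dict:
    """The three-method comparison simulation (this package's side only).

    200 CNA regions with sAGP ~ U(0,1) and states at the 2/7:2/7:2/7:1/7
    ratios, observables from the segment noise model, 1000 mutations placed
    uniformly over a genome that is ~50% euploid by length, scenario-balanced
    SAFs, reads at mean coverage 50, full-pipeline CCF estimation, plus the
    two intentionally mis-specified estimators for bias context.
    """
    rng = np.random.default_rng(seed)
    cfg = SimulationConfig(p_dom=1.0, p_sub=0.0, n_euploid=n_cna,
                           n_scna=n_cna, n_snv=n_mut, coverage=coverage,
                           seed=seed)
    sagps = rng.uniform(0.0, 1.0, size=n_cna)
    segments = simulate_scna_dataset(cfg, rng, sagp_values=sagps)
    fitted = fit_all_segments(segments)
    variants = simulate_snv_dataset(cfg, fitted, rng)
    est = estimate_ccf_batch(variants, fitted)
    merged = pd.concat([variants.reset_index(drop=True),
                        est[["scenario_set", "ccf", "ccf_exp", "ccf_var",
                             "flag"]].reset_index(drop=True)], axis=1)
    in_scna = merged[merged["host_kind"] == "scna"]
    ok = in_scna["ccf"].notna()
    r = float(pearsonr(in_scna.loc[ok, "true_ccf"],
                       in_scna.loc[ok, "ccf"])[0]) if ok.sum() >= 3 else np.nan
    strata = []
    for (nb, nt, scen), grp in in_scna.groupby(
            ["host_nb", "host_nt", "true_scenario"]):
        gok = grp["ccf"].notna()
        err = (grp.loc[gok, "ccf"] - grp.loc[gok, "true_ccf"])
        strata.append({"n_b": nb, "n_t": nt, "scenario": scen,
                       "n": int(len(grp)), "n_estimated": int(gok.sum()),
                       "bias": float(err.mean()) if gok.any() else np.nan,
                       "mad": float(np.median(np.abs(err))) if gok.any()
                       else np.nan})
    merged["ccf_ignore_r1"] = ccf_ignore_r1(merged)
    merged["ccf_force_a1"] = ccf_force_a1(merged)
    return {"variants": merged, "n_in_scna": int(len(in_scna)),
            "pearson_in_scna": r, "metrics": evaluate_ccf(merged),
            "strata": pd.DataFrame(strata), "fitted_segments": fitted}


# ---------------------------------------------------------------------------
# marker-level generators (segmentation / pipeline inputs)

def simulate_marker_series(plan, sigma_baf: float = 0.01,
                           sigma_lrr: float = 0.04,
                           rng: np.random.Generator | None = None):
    """Per-marker LRR / folded-BAF series for planted segments.

    ``plan`` is a list of (CopyState, p, n_markers); returns (lrr, fbaf,
    breakpoints) with the planted breakpoint marker indices.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    lrr, fbaf, breaks, pos = [], [], [], 0
    for state, p, n in plan:
        n_bar = mean_copy(CopyState(*state), p)
        f0 = abs(0.5 - (p * state[0] + 1 - p) / n_bar)
        l0 = np.log2(n_bar) - 1.0
        fbaf.append(f0 + rng.normal(0, sigma_baf, n))
        lrr.append(l0 + rng.normal(0, sigma_lrr, n))
        pos += n
        breaks.append(pos)
    return (np.concatenate(lrr), np.concatenate(fbaf),
            np.array(breaks[:-1], dtype=int))


def simulate_snp_level_sample(config: SimulationConfig,
                              rng: np.random.Generator | None = None,
                              markers_per_segment: int | None = None,
                              het_fraction: float = 0.7,
                              depth: float = 100.0):
    """Tumor and matched-normal allele-count tables for pipeline input.

    Produces the five-column frames :func:`clonalmix.io_formats.
    read_allele_counts` would return, with per-SNP Poisson sampling around
    the segment's theoretical allele intensities.  Returns (tumor, normal,
    truth_segments).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    segments = simulate_scna_dataset(
        SimulationConfig(**{**config.__dict__, "sigma_baf": 0.0,
                            "sigma_lrr": 0.0}), rng)
    m = markers_per_segment or config.markers_per_segment
    t_rows, n_rows, snp = [], [], 0
    for _, seg in segments.iterrows():
        state = CopyState(int(seg["true_nb"]), int(seg["true_nt"]))
        p = float(seg["true_p"])
        n_bar = mean_copy(state, p)
        tumor_total = depth * n_bar / 2.0
        q_b = (p * state.n_b + 1.0 - p) / n_bar   # tumor B fraction at hets
        step = (seg["end"] - seg["start"]) // (m + 1)
        for j in range(m):
            pos = int(seg["start"] + (j + 1) * step)
            snp += 1
            het = rng.random() < het_fraction
            if het:
                na = rng.poisson(depth / 2)
                nb = rng.poisson(depth / 2)
                flip = rng.random() < 0.5   # which parental allele is B
                tb = rng.poisson(tumor_total * (q_b if not flip else 1 - q_b))
                ta = rng.poisson(tumor_total * ((1 - q_b) if not flip else q_b))
            else:
                na, nb = rng.poisson(depth), 0
                ta, tb = rng.poisson(tumor_total), 0
            t_rows.append((f"snp{snp}", seg["chrom"], pos, float(ta), float(tb)))
            n_rows.append((f"snp{snp}", seg["chrom"], pos, float(na), float(nb)))
    cols = ["snp_id", "chrom", "pos", "a_count", "b_count"]
    return (pd.DataFrame(t_rows, columns=cols),
            pd.DataFrame(n_rows, columns=cols), segments)
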