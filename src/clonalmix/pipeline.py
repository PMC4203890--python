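"""End-to-end orchestration: read -> segment -> sAGP -> CCF -> clonal
structure -> report, plus the self-contained validation suite."""

from __future__ import annotations

import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from clonalmix import clonal_structure, io_formats, segmentation, simulation
from clonalmix.ccf_inference import estimate_ccf_batch
from clonalmix.sagp_inference import fit_all_segments

log = logging.getLogger(__name__)

DEFAULT_CONFIG: dict = {
    "paths": {"tumor_counts": None, "normal_counts": None, "variants": None,
              "segments": None, "out_dir": "results"},
    "unit_kind": None,          # None -> scna when variants given, else bin
    "seed": 0,
    "io": {"het_band": 0.2, "center_lrr": True, "tumor_sample": None},
    "segmentation": {"het_per_bin": 500, "min_markers": 5, "alpha": 0.01,
                     "n_perm": 1000, "merge_window": 5},
    "sagp": {"max_nt": 6, "threshold_mult": 2.0, "doubling_check": False},
    "ccf": {"threshold": 0.95, "min_depth": 20, "min_saf": 0.05},
    "clonal_structure": {"euploid_fbaf": 0.04, "euploid_lrr": 0.16,
                         "min_sagp": 0.05, "min_bins": 50,
                         "min_weight": 0.05,
                         "mcmc": {"iterations": 10000, "burn_in": 2000,
                                  "thinning": 5}},
    "exclude_chroms": [],
}


def _deep_update(base: dict, extra: dict) -> dict:
    out = dict(base)
    for k, v in (extra or {}).items():
        out[k] = _deep_update(base[k], v) \
            if isinstance(v, dict) and isinstance(base.get(k), dict) else v
    return out


def load_config(path: str | Path | None = None, **overrides) -> dict:
    cfg = DEFAULT_CONFIG
    if path is not None:
        with open(path) as fh:
            cfg = _deep_update(cfg, yaml.safe_load(fh) or {})
    return _deep_update(cfg, overrides)


class PipelineError(RuntimeError):
    """A hard, stage-named pipeline failure."""


def run_pipeline(config: dict) -> dict:
    """Execute all requested stages in order; returns a result bundle with
    the segment/variant/model tables, soft-error notes, and output paths."""
    t0 = time.time()
    cfg = _deep_update(DEFAULT_CONFIG, config)
    paths = cfg["paths"]
    soft_errors: list[str] = []
    rng = np.random.default_rng(cfg["seed"])

    want_ccf = paths.get("variants") is not None
    unit_kind = cfg["unit_kind"] or ("scna" if want_ccf else "bin")

    # --- stage: io
    if paths.get("segments") is not None:
        segments = pd.read_csv(paths["segments"], sep="\t")
        signals = None
    else:
        if not (paths.get("tumor_counts") and paths.get("normal_counts")):
            raise PipelineError("io_formats: tumor_counts and normal_counts "
                                "(or a precomputed segments table) required")
        tumor = io_formats.read_allele_counts(paths["tumor_counts"])
        normal = io_formats.read_allele_counts(paths["normal_counts"])
        signals = io_formats.compute_site_signals(
            tumor, normal, het_band=cfg["io"]["het_band"],
            center=cfg["io"]["center_lrr"])
        if cfg["exclude_chroms"]:
            signals = signals[~signals["chrom"].isin(cfg["exclude_chroms"])]
        log.info("io: %d sites (%d rejected tumor rows, %d normal)",
                 len(signals), tumor.attrs.get("n_rejected", 0),
                 normal.attrs.get("n_rejected", 0))
        # --- stage: segmentation
        seg_cfg = cfg["segmentation"]
        segments = segmentation.segment_genome(
            signals, unit_kind=unit_kind, het_per_bin=seg_cfg["het_per_bin"],
            min_markers=seg_cfg["min_markers"], alpha=seg_cfg["alpha"],
            n_perm=seg_cfg["n_perm"], merge_window=seg_cfg["merge_window"],
            rng=rng)
        log.info("segmentation: %d %s unit(s)", len(segments), unit_kind)

    # --- stage: sagp
    from clonalmix.sagp_inference import candidate_states
    fitted = fit_all_segments(
        segments, states=candidate_states(cfg["sagp"]["max_nt"]),
        threshold_mult=cfg["sagp"]["threshold_mult"],
        doubling_check=cfg["sagp"]["doubling_check"])
    baseline = fitted.attrs["baseline"]
    log.info("sagp: p_s=%.3f ploidy=%.3f, %d/%d segments estimable",
             baseline.p_s, baseline.ploidy,
             int(fitted["sagp"].notna().sum()), len(fitted))

    # --- stage: ccf
    variants = None
    if want_ccf:
        vpath = Path(paths["variants"])
        if not vpath.exists():
            raise PipelineError(
                f"ccf_inference: variants input {vpath} does not exist")
        raw = io_formats.read_somatic_variants(
            vpath, tumor_sample=cfg["io"]["tumor_sample"])
        variants = estimate_ccf_batch(
            raw, fitted, threshold=cfg["ccf"]["threshold"],
            min_depth=cfg["ccf"]["min_depth"], min_saf=cfg["ccf"]["min_saf"])
        if variants.attrs.get("n_filtered"):
            soft_errors.append(
                f"ccf_inference: {variants.attrs['n_filtered']} variant(s) "
                "removed by depth/SAF filters")

    # --- stage: clonal structure
    cs_cfg = cfg["clonal_structure"]
    y, analyzable = clonal_structure.prepare_sagp_vector(
        fitted, euploid_fbaf=cs_cfg["euploid_fbaf"],
        euploid_lrr=cs_cfg["euploid_lrr"], min_sagp=cs_cfg["min_sagp"],
        min_bins=cs_cfg["min_bins"])
    model_fit = None
    fit = None
    if analyzable:
        priors = clonal_structure.DPPriorConfig(
            seed=cfg["seed"], **cs_cfg["mcmc"])
        fit = clonal_structure.infer_clonal_structure(
            y, priors, min_weight=cs_cfg["min_weight"],
            min_points=cs_cfg["min_bins"])
        model_fit = clonal_structure.model_fit_table(fit)
    else:
        soft_errors.append("clonal_structure: too few filtered sAGP values; "
                           "model fitting skipped")

    out_paths = io_formats.write_results(
        paths["out_dir"], segments=fitted, variants=variants,
        model_fit=model_fit, config=cfg, seed=cfg["seed"])
    log.info("pipeline finished in %.1fs (%d soft error(s))",
             time.time() - t0, len(soft_errors))
    return {"segments": fitted, "variants": variants, "model_fit": fit,
            "baseline": baseline, "soft_errors": soft_errors,
            "paths": out_paths}


def run_validation_suite(seed: int = 0, grid_step: float | None = None,
                         n_snv: int = 4000, coverages=(50, 100)) -> dict:
    """Self-contained validation: the (p_dom, p_sub) sAGP grid (optionally a
    coarser subset), the four-case CCF validation at both coverages, and the
    comparison protocol."""
    report: dict = {}
    pairs = simulation.sagp_grid(grid_step) if grid_step \
        else simulation.sagp_grid()
    grid_rows = []
    ss = np.random.SeedSequence(seed).spawn(len(pairs))
    for (p_dom, p_sub), child in zip(pairs, ss):
        case_seed = int(child.generate_state(1)[0] % (2 ** 31))
        cfg = simulation.SimulationConfig(p_dom=p_dom, p_sub=p_sub,
                                          seed=case_seed)
        rng = np.random.default_rng(case_seed)
        segs = simulation.simulate_scna_dataset(cfg, rng)
        fitted = fit_all_segments(segs)
        row = {"p_dom": p_dom, "p_sub": p_sub}
        row.update(simulation.evaluate_sagp(fitted))
        grid_rows.append(row)
    report["sagp_grid"] = pd.DataFrame(grid_rows)
    report["ccf_validation"] = simulation.run_ccf_validation(
        seed=seed + 1, n_snv=n_snv, coverages=coverages)
    report["comparison"] = simulation.run_comparison_protocol(seed=seed + 2)
    return report
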