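"""Partition the genome into bins or copy-number segments and summarize them.

Two spatial units are supported: fixed-count heterozygous-SNP bins, and
segments from change-point detection run independently on the LRR and
folded-BAF marker series, with BAF change points that fall within a few
markers of an LRR change point discarded as redundant (het markers are
sparser, so their breakpoints are less accurately placed).

The change-point engine is a recursive binary splitter in the circular-binary-
segmentation family: the candidate split maximizing the standardized
mean-difference statistic is accepted when its permutation p-value clears
alpha, and recursion stops when no split is significant or a child segment
would fall below ``min_markers``.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# change-point detection

def _best_split(x: np.ndarray, min_markers: int) -> tuple[int, float]:
    """Most extreme standardized mean-difference split of ``x``.

    Returns (split index k, statistic); the split puts x[:k] left and x[k:]
    right.  First maximal statistic wins ties.  Statistic is 0 for constant
    series.
    """
    n = len(x)
    ks = np.arange(min_markers, n - min_markers + 1)
    if len(ks) == 0:
        return -1, 0.0
    cs = np.cumsum(x)
    total = cs[-1]
    n_l = ks.astype(float)
    n_r = n - n_l
    mean_l = cs[ks - 1] / n_l
    mean_r = (total - cs[ks - 1]) / n_r
    sd = np.std(x, ddof=1)
    if sd <= 0:
        return -1, 0.0
    t = np.abs(mean_l - mean_r) / (sd * np.sqrt(1.0 / n_l + 1.0 / n_r))
    i = int(np.argmax(t))
    return int(ks[i]), float(t[i])


def _split_pvalue(x: np.ndarray, observed: float, min_markers: int,
                  n_perm: int, rng: np.random.Generator) -> float:
    count = 0
    y = x.copy()
    for _ in range(n_perm):
        rng.shuffle(y)
        _, t = _best_split(y, min_markers)
        if t >= observed:
            count += 1
    return (1 + count) / (1 + n_perm)


def detect_changepoints(
    values: np.ndarray,
    min_markers: int = 5,
    alpha: float = 0.01,
    n_perm: int = 1000,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Recursive binary segmentation of a per-marker series.

    Returns sorted change-point indices k, meaning a boundary between
    values[k-1] and values[k].  A series shorter than 2*min_markers yields no
    change points.
    """
    values = np.asarray(values, dtype=float)
    if rng is None:
        rng = np.random.default_rng(0)
    cps: list[int] = []

    def recurse(lo: int, hi: int) -> None:
        x = values[lo:hi]
        if len(x) < 2 * min_markers:
            return
        k, t = _best_split(x, min_markers)
        if k < 0 or t <= 0:
            return
        p = _split_pvalue(x, t, min_markers, n_perm, rng)
        if p >= alpha:
            return
        cps.append(lo + k)
        recurse(lo, lo + k)
        recurse(lo + k, hi)

    recurse(0, len(values))
    return np.array(sorted(cps), dtype=int)


def merge_changepoints(lrr_cps: np.ndarray, baf_cps: np.ndarray,
                       window: int = 5) -> np.ndarray:
    """Union of LRR change points and BAF change points not within ``window``
    markers (either direction) of some LRR change point."""
    lrr_cps = np.asarray(lrr_cps, dtype=int)
    baf_cps = np.asarray(baf_cps, dtype=int)
    if len(lrr_cps) == 0:
        return np.unique(baf_cps)
    keep = [b for b in baf_cps if np.min(np.abs(lrr_cps - b)) > window]
    return np.unique(np.concatenate([lrr_cps, np.array(keep, dtype=int)]))


# ---------------------------------------------------------------------------
# binning

def make_bins(signals: pd.DataFrame, het_per_bin: int = 500) -> pd.DataFrame:
    """Bins of ``het_per_bin`` consecutive heterozygous markers per chromosome.

    All markers (het and hom) between bin boundaries belong to the bin; only
    het markers feed the folded-BAF summary.  A trailing partial bin is kept
    when it holds at least het_per_bin/2 het markers, otherwise merged into
    the previous bin.  A chromosome with fewer than het_per_bin/2 het markers
    becomes a single whole-chromosome bin (with a warning).
    """
    if het_per_bin < 50:
        raise ValueError("het_per_bin must be >= 50")
    segments = []
    for chrom, chrom_df in signals.groupby("chrom", sort=False):
        chrom_df = chrom_df.reset_index(drop=True)
        het_idx = np.flatnonzero(chrom_df["is_het"].to_numpy())
        n_het = len(het_idx)
        if n_het < het_per_bin / 2:
            log.warning("chromosome %s has only %d het markers; one bin",
                        chrom, n_het)
            segments.append(_summary_row(chrom_df, chrom, "bin"))
            continue
        n_full = n_het // het_per_bin
        trailing = n_het - n_full * het_per_bin
        # marker index one past each bin's last het marker
        bounds = [het_idx[(i + 1) * het_per_bin - 1] + 1 for i in range(n_full)]
        if trailing >= het_per_bin / 2:
            bounds.append(len(chrom_df))
        else:
            bounds[-1] = len(chrom_df)  # merge trailing markers into last bin
        lo = 0
        for hi in bounds:
            segments.append(_summary_row(chrom_df.iloc[lo:hi], chrom, "bin"))
            lo = hi
    return pd.DataFrame(segments).reset_index(drop=True)


def _summary_row(markers: pd.DataFrame, chrom, unit_kind: str) -> dict:
    het = markers[markers["is_het"]]
    med_fbaf = (float(np.median(np.abs(het["baf"] - 0.5)))
                if len(het) else np.nan)
    return {
        "chrom": chrom,
        "start": int(markers["pos"].iloc[0]),
        "end": int(markers["pos"].iloc[-1]),
        "n_snps": int(len(markers)),
        "n_het": int(len(het)),
        "med_lrr": float(np.median(markers["lrr"])),
        "med_fbaf": med_fbaf,
        "unit_kind": unit_kind,
    }


def summarize_segments(signals: pd.DataFrame,
                       changepoints_by_chrom: dict,
                       unit_kind: str = "scna") -> pd.DataFrame:
    """Summarize marker runs delimited by change points into segments.

    med_lrr is the median LRR over all markers; med_fbaf the median
    |BAF - 0.5| over het markers (missing when a segment has none, in which
    case it is excluded from sAGP fitting downstream).
    """
    rows = []
    for chrom, chrom_df in signals.groupby("chrom", sort=False):
        chrom_df = chrom_df.reset_index(drop=True)
        cps = np.asarray(changepoints_by_chrom.get(chrom, []), dtype=int)
        bounds = np.concatenate([[0], cps, [len(chrom_df)]])
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            if hi > lo:
                rows.append(_summary_row(chrom_df.iloc[lo:hi], chrom, unit_kind))
    return pd.DataFrame(rows).reset_index(drop=True)


def segment_genome(
    signals: pd.DataFrame,
    unit_kind: str = "scna",
    het_per_bin: int = 500,
    min_markers: int = 5,
    alpha: float = 0.01,
    n_perm: int = 1000,
    merge_window: int = 5,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """End-to-end segmentation: bins, or LRR+folded-BAF change points merged
    within each chromosome (the merge window never spans chromosomes)."""
    if unit_kind == "bin":
        return make_bins(signals, het_per_bin=het_per_bin)
    if unit_kind != "scna":
        raise ValueError(f"unit_kind must be 'bin' or 'scna', got {unit_kind!r}")
    if rng is None:
        rng = np.random.default_rng(0)
    cps_by_chrom = {}
    for chrom, chrom_df in signals.groupby("chrom", sort=False):
        chrom_df = chrom_df.reset_index(drop=True)
        lrr_cps = detect_changepoints(chrom_df["lrr"].to_numpy(),
                                      min_markers, alpha, n_perm, rng)
        het_mask = chrom_df["is_het"].to_numpy()
        het_positions = np.flatnonzero(het_mask)
        fbaf = np.abs(chrom_df["baf"].to_numpy()[het_positions] - 0.5)
        baf_cps_het = detect_changepoints(fbaf, min_markers, alpha, n_perm, rng)
        # map het-series indices back to genome-wide marker indices
        baf_cps = het_positions[baf_cps_het] if len(baf_cps_het) else np.array([], int)
        cps_by_chrom[chrom] = merge_changepoints(lrr_cps, baf_cps, merge_window)
    return summarize_segments(signals, cps_by_chrom, unit_kind="scna")
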