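"""Readers and writers for every external table the pipeline touches.

Allele-specific signal comes in as a five-column table (SNP ID, chromosome,
position, A-allele count, B-allele count); counts may be real-valued array
intensities.  Somatic variants come in as VCF 4.x with per-sample allele
depths, or as a four-column tabular fallback (chrom, pos, alt count, total
depth).  Results go out as tab-delimited tables with "NA" for missing values
plus a JSON run manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import re
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

ALLELE_COLUMNS = ["snp_id", "chrom", "pos", "a_count", "b_count"]

SEGMENT_COLUMNS = [
    "chrom", "start", "end", "n_snps", "n_het", "med_lrr", "med_fbaf",
    "unit_kind", "n_b", "n_t", "sagp", "residual", "n_candidates",
]

VARIANT_COLUMNS = [
    "chrom", "pos", "s_count", "n_depth", "saf", "scenario_set",
    "p_A1", "p_A2", "p_B", "p_C", "ccf", "ccf_pre_clip",
    "ccf_exp", "ccf_var", "flag",
]


class FormatError(ValueError):
    """Input file does not match the documented layout."""


def chrom_sort_key(chrom: str) -> tuple[int, int, str]:
    """Order chromosomes numerically, then X, Y, M, then lexically."""
    c = str(chrom)
    c = c[3:] if c.lower().startswith("chr") else c
    if c.isdigit():
        return (0, int(c), "")
    special = {"X": 23, "Y": 24, "M": 25, "MT": 25}
    if c.upper() in special:
        return (0, special[c.upper()], "")
    return (1, 0, c)


def _sort_by_position(df: pd.DataFrame) -> pd.DataFrame:
    key = df["chrom"].map(chrom_sort_key)
    order = sorted(range(len(df)), key=lambda i: (key.iat[i], df["pos"].iat[i]))
    return df.iloc[order].reset_index(drop=True)


def read_allele_counts(path: str | Path) -> pd.DataFrame:
    """Parse a five-column allele-count table into a coordinate-sorted frame.

    A header row is auto-detected (non-numeric count fields).  Malformed rows
    are dropped, counted in ``df.attrs["n_rejected"]`` and reported at WARNING
    level with their line numbers.  Raises :class:`FormatError` if the file
    has fewer than five columns.
    """
    path = Path(path)
    rows: list[list[str]] = []
    lines: list[int] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            rows.append(re.split(r"\s+", line.strip()))
            lines.append(lineno)
    if not rows:
        log.warning("%s: empty allele-count file", path)
        df = pd.DataFrame(columns=ALLELE_COLUMNS)
        df.attrs["n_rejected"] = 0
        return df

    def _numeric(tok: str) -> bool:
        try:
            float(tok)
            return True
        except ValueError:
            return False

    first = rows[0]
    if len(first) < 5:
        raise FormatError(f"{path}: expected 5 columns, found {len(first)}")
    if not (_numeric(first[3]) and _numeric(first[4]) and _numeric(first[2])):
        rows = rows[1:]
        lines = lines[1:]

    records, rejected = [], []
    for lineno, row in zip(lines, rows):
        if len(row) < 5:
            rejected.append(lineno)
            continue
        try:
            records.append((row[0], row[1], int(float(row[2])),
                            float(row[3]), float(row[4])))
        except ValueError:
            rejected.append(lineno)
    if rejected:
        log.warning("%s: rejected %d malformed row(s) at line(s) %s",
                    path, len(rejected), rejected[:20])
    df = pd.DataFrame.from_records(records, columns=ALLELE_COLUMNS)
    if df.duplicated(["chrom", "pos"]).any():
        n_dup = int(df.duplicated(["chrom", "pos"]).sum())
        log.warning("%s: dropping %d duplicate (chrom, pos) row(s)", path, n_dup)
        df = df.drop_duplicates(["chrom", "pos"], keep="first")
    df = _sort_by_position(df)
    df.attrs["n_rejected"] = len(rejected)
    return df


def compute_site_signals(
    tumor: pd.DataFrame,
    normal: pd.DataFrame,
    het_band: float = 0.2,
    center: bool = True,
) -> pd.DataFrame:
    """Join tumor/normal counts on (chrom, pos) and derive BAF/LRR per site.

    BAF is the tumor B-allele fraction; LRR is log2 of the tumor/normal total
    signal ratio, optionally median-centered genome-wide so the euploid mode
    sits near zero (the sample baseline later refines the offset).  A site is
    flagged heterozygous when the *normal* BAF lies within 0.5 +/- het_band.
    Sites with zero total signal in either sample are dropped and counted.
    """
    merged = tumor.merge(normal, on=["chrom", "pos"], suffixes=("_t", "_n"))
    tt = merged["a_count_t"] + merged["b_count_t"]
    nt = merged["a_count_n"] + merged["b_count_n"]
    usable = (tt > 0) & (nt > 0)
    n_dropped = int((~usable).sum())
    if n_dropped:
        log.warning("dropped %d site(s) with zero total signal", n_dropped)
    merged, tt, nt = merged[usable], tt[usable], nt[usable]
    baf = merged["b_count_t"] / tt
    lrr = np.log2(tt / nt)
    if center and len(lrr):
        lrr = lrr - np.median(lrr)
    normal_baf = merged["b_count_n"] / nt
    out = pd.DataFrame({
        "chrom": merged["chrom"].to_numpy(),
        "pos": merged["pos"].to_numpy(),
        "baf": baf.to_numpy(),
        "lrr": lrr.to_numpy(),
        "is_het": (np.abs(normal_baf - 0.5) <= het_band).to_numpy(),
    })
    out = _sort_by_position(out)
    out.attrs["n_dropped"] = n_dropped
    return out


def _read_variants_vcf(path: Path, tumor_sample: str | None,
                       skip_multiallelic: bool = True) -> pd.DataFrame:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if not samples:
        raise FormatError(f"{path}: VCF has no sample columns")
    if tumor_sample is None:
        idx = len(samples) - 1
        if len(samples) > 1:
            log.warning("tumor_sample not given; using last sample %r",
                        samples[idx])
    else:
        if tumor_sample not in samples:
            raise FormatError(
                f"{path}: sample {tumor_sample!r} not in VCF ({samples})")
        idx = samples.index(tumor_sample)

    records, n_multi, n_zero = [], 0, 0
    for v in vcf:
        if len(v.ALT) != 1:
            n_multi += 1
            continue
        try:
            ad = v.format("AD")
        except KeyError:
            ad = None
        if ad is None:
            raise FormatError(
                f"{path}: record {v.CHROM}:{v.POS} lacks per-sample allele "
                "depths (AD); unsupported format")
        ref, alt = int(ad[idx][0]), int(ad[idx][1])
        n = ref + alt
        if n <= 0:
            n_zero += 1
            continue
        records.append((v.CHROM, int(v.POS), alt, n, alt / n))
    if n_multi:
        log.warning("%s: skipped %d multi-allelic record(s)", path, n_multi)
    if n_zero:
        log.warning("%s: rejected %d record(s) with zero depth", path, n_zero)
    df = pd.DataFrame.from_records(
        records, columns=["chrom", "pos", "s_count", "n_depth", "saf"])
    df.attrs["n_rejected"] = n_zero
    df.attrs["n_multiallelic"] = n_multi
    return df


def _read_variants_tabular(path: Path) -> pd.DataFrame:
    """Tabular fallback: chrom, pos, somatic-allele count, total depth."""
    raw = pd.read_csv(path, sep=r"\s+", header=None, comment="#",
                      names=["chrom", "pos", "s_count", "n_depth"],
                      dtype={"chrom": str})
    n0 = len(raw)
    raw = raw[(raw["n_depth"] >= 1) & (raw["s_count"] >= 0)
              & (raw["s_count"] <= raw["n_depth"])].copy()
    n_rejected = n0 - len(raw)
    if n_rejected:
        log.warning("%s: rejected %d degenerate row(s)", path, n_rejected)
    raw["saf"] = raw["s_count"] / raw["n_depth"]
    raw = raw.reset_index(drop=True)
    raw.attrs["n_rejected"] = n_rejected
    return raw


def read_somatic_variants(path: str | Path,
                          tumor_sample: str | None = None) -> pd.DataFrame:
    """Read somatic variants with tumor read counts (VCF or tabular).

    Returns one row per biallelic record with columns chrom, pos, s_count
    (reads supporting the somatic allele, S), n_depth (total reads, N) and
    saf (S/N, the somatic allele frequency f).
    """
    path = Path(path)
    with open(path) as fh:
        head = fh.readline()
    if head.startswith("##fileformat=VCF") or path.suffix == ".vcf":
        df = _read_variants_vcf(path, tumor_sample)
    else:
        df = _read_variants_tabular(path)
    attrs = dict(df.attrs)
    df = _sort_by_position(df)
    df.attrs.update(attrs)
    return df


def _frame_for_output(df: pd.DataFrame | None, columns: list[str]) -> pd.DataFrame:
    if df is None:
        return pd.DataFrame(columns=columns)
    out = df.copy()
    for c in columns:
        if c not in out.columns:
            out[c] = np.nan
    return out[columns]


def write_results(
    out_dir: str | Path,
    segments: pd.DataFrame | None = None,
    variants: pd.DataFrame | None = None,
    model_fit: pd.DataFrame | None = None,
    config: dict | None = None,
    seed: int | None = None,
) -> dict[str, Path]:
    """Write segments.tsv / variants.tsv / model_fit.tsv plus a run manifest.

    Missing values are encoded "NA"; reruns with the same inputs and seed
    produce byte-identical tables.  The manifest records config, seed,
    package version and a sha256 of each table.
    """
    from clonalmix import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    tables = {
        "segments.tsv": _frame_for_output(segments, SEGMENT_COLUMNS),
        "variants.tsv": _frame_for_output(variants, VARIANT_COLUMNS),
    }
    if model_fit is not None:
        tables["model_fit.tsv"] = model_fit
    hashes = {}
    for name, table in tables.items():
        p = out_dir / name
        table.to_csv(p, sep="\t", index=False, na_rep="NA",
                     float_format="%.6g")
        hashes[name] = hashlib.sha256(p.read_bytes()).hexdigest()
        paths[name] = p
    manifest = {
        "package": "clonalmix",
        "version": __version__,
        "seed": seed,
        "config": config,
        "files": hashes,
    }
    mp = out_dir / "manifest.json"
    mp.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    paths["manifest.json"] = mp
    return paths
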