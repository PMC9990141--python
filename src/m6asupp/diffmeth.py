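"""Differential-methylation region calling between knockdown and control.

The unit of analysis is a pre-defined region set (e.g. fixed windows tiled
over transcripts) with per-replicate IP and input counts under control and
EJC-factor knockdown conditions.  Per region:

* methylation-level fold change
  log2fc = log2[(sum ip_kd / sum input_kd) / (sum ip_ctl / sum input_ctl)]
  on CPM-normalized, pseudocounted counts;
* a replicate-stratified Cochran-Mantel-Haenszel (CMH) test of the
  IP/input x condition odds ratio.  The statistic uses the unconditional
  (N^3) variance form per stratum, so a single stratum reduces exactly to
  the continuity-corrected (Yates) 2x2 chi-square; with replicate strata it
  pools evidence without mixing library depths.  A Fisher test on summed
  counts is available as a pooled fallback.
* Benjamini-Hochberg FDR across regions and classification as hyper
  (log2fc > lfc_thresh, FDR < fdr_thresh), hypo (log2fc < -lfc_thresh,
  FDR < fdr_thresh), or unchanged;
* a "novel" flag: no >= 1 nt overlap with m6A peaks from the control
  condition.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import annotation
from .annotation import CONSTANTS, TranscriptModel

log = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("region_id", "replicate", "condition", "fraction", "count")
CONDITIONS = ("ctl", "kd")
FRACTIONS = ("input", "ip")


class RegionValidationError(ValueError):
    """Region count tables or interval sets are inconsistent."""


def _count_cube(counts: pd.DataFrame, normalize: bool = True,
                pseudocount: float = 0.5):
    """Pivot long counts into an array [region, replicate, condition, fraction].

    With ``normalize`` the counts are CPM-scaled within each (condition,
    replicate, fraction) library and the pseudocount is added (in read
    units) before scaling.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in counts.columns]
    if missing:
        raise RegionValidationError(f"counts table lacks columns {missing}")
    if (counts["count"] < 0).any():
        raise RegionValidationError("negative counts")
    df = counts.copy()
    if normalize:
        lib = df.groupby(["condition", "replicate", "fraction"])["count"].transform("sum")
        df["value"] = (df["count"] + pseudocount) / lib * 1e6
    else:
        df["value"] = df["count"].astype(float)
    wide = df.pivot_table(index="region_id",
                          columns=["replicate", "condition", "fraction"],
                          values="value", aggfunc="first")
    if wide.isna().any().any():
        raise RegionValidationError(
            "unequal replicate structure across conditions/fractions")
    reps = sorted({c[0] for c in wide.columns})
    cube = np.empty((len(wide), len(reps), 2, 2))
    for ri, r in enumerate(reps):
        for ci, cond in enumerate(CONDITIONS):
            for fi, frac in enumerate(FRACTIONS):
                cube[:, ri, ci, fi] = wide[(r, cond, frac)].to_numpy()
    return wide.index.to_numpy(), cube


def region_log2fc(counts: pd.DataFrame) -> pd.Series:
    """Methylation-level log2 fold change (kd vs ctl) per region."""
    ids, cube = _count_cube(counts, normalize=True)
    tot = cube.sum(axis=1)  # sum over replicates -> [region, condition, fraction]
    ratio_ctl = tot[:, 0, 1] / tot[:, 0, 0]
    ratio_kd = tot[:, 1, 1] / tot[:, 1, 0]
    return pd.Series(np.log2(ratio_kd / ratio_ctl), index=pd.Index(ids, name="region_id"),
                     name="log2fc")


# ----------------------------------------------------------------------
# CMH test
# ----------------------------------------------------------------------

def cmh_from_tables(tables: np.ndarray) -> tuple[float, float]:
    """CMH chi-square with continuity correction on stacked 2x2 tables.

    ``tables`` has shape (n_strata, 2, 2) with layout
    [[a, b], [c, d]] = [[ip_kd, input_kd], [ip_ctl, input_ctl]].
    Strata with a zero margin are dropped; if all strata are degenerate the
    p-value is 1 with a logged warning.  The per-stratum variance is the
    unconditional form r1*r2*c1*c2/N^3, so a single stratum reproduces the
    Yates-corrected 2x2 chi-square exactly.
    """
    tables = np.asarray(tables, dtype=float)
    if tables.ndim == 2:
        tables = tables[None]
    a = tables[:, 0, 0]
    r1 = tables[:, 0, :].sum(axis=1)
    r2 = tables[:, 1, :].sum(axis=1)
    c1 = tables[:, :, 0].sum(axis=1)
    c2 = tables[:, :, 1].sum(axis=1)
    n = tables.sum(axis=(1, 2))
    ok = (r1 > 0) & (r2 > 0) & (c1 > 0) & (c2 > 0)
    if not ok.any():
        log.warning("CMH: all strata degenerate; returning p = 1")
        return 0.0, 1.0
    e = (r1 * c1 / n)[ok]
    v = (r1 * r2 * c1 * c2 / n**3)[ok]
    dev = abs(float(np.sum(a[ok] - e))) - 0.5
    stat = max(dev, 0.0) ** 2 / float(np.sum(v))
    return stat, float(stats.chi2.sf(stat, df=1))


def cmh_test(counts: pd.DataFrame) -> pd.DataFrame:
    """Replicate-stratified CMH test per region (two-sided p).

    Raw counts are used (the 2x2 odds ratio is library-size free).
    """
    ids, cube = _count_cube(counts, normalize=False)
    out = []
    for i in range(len(ids)):
        # stratum layout: rows condition (kd, ctl), cols fraction (ip, input)
        tabs = np.stack([
            np.array([[cube[i, r, 1, 1], cube[i, r, 1, 0]],
                      [cube[i, r, 0, 1], cube[i, r, 0, 0]]])
            for r in range(cube.shape[1])])
        stat, p = cmh_from_tables(tabs)
        out.append((stat, p))
    return pd.DataFrame(out, columns=["cmh_stat", "p_value"],
                        index=pd.Index(ids, name="region_id")).reset_index()


def fisher_pooled_test(counts: pd.DataFrame) -> pd.DataFrame:
    """Fallback: two-sided Fisher exact test on replicate-summed counts."""
    ids, cube = _count_cube(counts, normalize=False)
    tot = cube.sum(axis=1)
    out = []
    for i in range(len(ids)):
        table = [[tot[i, 1, 1], tot[i, 1, 0]], [tot[i, 0, 1], tot[i, 0, 0]]]
        out.append(stats.fisher_exact(np.round(table).astype(int))[1])
    return pd.DataFrame({"region_id": ids, "p_value": out})


# ----------------------------------------------------------------------
# Region calling
# ----------------------------------------------------------------------

def call_regions(counts: pd.DataFrame, fdr_thresh: float = 0.1,
                 lfc_thresh: float = 1.0, test: str = "cmh") -> pd.DataFrame:
    """Full region-level differential methylation calls.

    Returns one row per region with log2fc, p_value, fdr and class in
    {hyper, hypo, unchanged}.
    """
    if test == "cmh":
        pvals = cmh_test(counts)
    elif test == "fisher":
        pvals = fisher_pooled_test(counts)
    else:
        raise ValueError(f"unknown test {test!r}")
    lfc = region_log2fc(counts)
    res = pvals.merge(lfc.reset_index(), on="region_id", validate="one_to_one")
    _, fdr, _, _ = multipletests(res["p_value"].to_numpy(), method="fdr_bh")
    res["fdr"] = fdr
    sig = res["fdr"] < fdr_thresh
    res["class"] = np.where(sig & (res["log2fc"] > lfc_thresh), "hyper",
                    np.where(sig & (res["log2fc"] < -lfc_thresh), "hypo",
                             "unchanged"))
    return res


def overlap_peaks(regions: pd.DataFrame, peaks: pd.DataFrame) -> pd.DataFrame:
    """Flag regions with no >= 1 nt overlap with any control peak as novel.

    Both tables need ``chrom``, ``start``, ``end`` (0-based half-open).
    A complete disconnect between the two files' chromosome names (likely a
    naming-convention clash) raises a validation error.
    """
    from intervaltree import IntervalTree

    for name, df in (("regions", regions), ("peaks", peaks)):
        for col in ("chrom", "start", "end"):
            if col not in df.columns:
                raise RegionValidationError(f"{name} table lacks column {col!r}")
    rchroms, pchroms = set(regions["chrom"]), set(peaks["chrom"])
    if rchroms and pchroms and not (rchroms & pchroms):
        raise RegionValidationError(
            f"no shared chromosome names between regions {sorted(rchroms)} "
            f"and peaks {sorted(pchroms)}")
    trees = {}
    for chrom, grp in peaks.groupby("chrom"):
        t = IntervalTree()
        for s, e in zip(grp["start"], grp["end"]):
            if e > s:
                t.addi(int(s), int(e))
        trees[chrom] = t
    out = regions.copy()
    out["novel"] = [
        not trees.get(c, IntervalTree()).overlaps(int(s), int(e))
        for c, s, e in zip(regions["chrom"], regions["start"], regions["end"])]
    return out


# ----------------------------------------------------------------------
# Architecture profiling
# ----------------------------------------------------------------------

def metagene_density(coords: np.ndarray, bins_per_segment: int = 100) -> pd.DataFrame:
    """Area-normalized metagene histogram over [0,3) (density sums to 1
    after multiplying by the bin width)."""
    edges = np.linspace(0.0, 3.0, 3 * bins_per_segment + 1)
    hist, _ = np.histogram(coords, bins=edges)
    width = edges[1] - edges[0]
    total = hist.sum()
    density = hist / (total * width) if total else hist.astype(float)
    return pd.DataFrame({"bin_left": edges[:-1], "bin_right": edges[1:],
                         "count": hist, "density": density})


def architecture_profile(regions: pd.DataFrame,
                         models: Mapping[str, TranscriptModel],
                         bins_per_segment: int = 100) -> dict[str, pd.DataFrame]:
    """Architecture tables for a region set.

    Each region is represented by its midpoint in transcript coordinates
    (columns ``transcript_id``, ``tstart``, ``tend``; a missing or unknown
    transcript sends the region to the "unassigned" bucket).  Returns exon
    class counts, internal-exon length values, a metagene density table and
    a last-exon-offset histogram with the proximal (< 150 nt) fraction.
    """
    exon_counts: dict[str, int] = {}
    internal_lengths: list[int] = []
    metagene_coords: list[float] = []
    last_offsets: list[int] = []
    for rec in regions.itertuples(index=False):
        tid = getattr(rec, "transcript_id", None)
        if tid is None or tid not in models or pd.isna(tid):
            exon_counts["unassigned"] = exon_counts.get("unassigned", 0) + 1
            continue
        t = models[tid]
        mid = min((int(rec.tstart) + int(rec.tend)) // 2, t.length - 1)
        arch = annotation.classify_site(t, mid)
        exon_counts[arch.exon_class] = exon_counts.get(arch.exon_class, 0) + 1
        if arch.exon_class == "internal":
            internal_lengths.append(arch.exon_length)
        if arch.metagene_coord is not None:
            metagene_coords.append(arch.metagene_coord)
        if arch.last_exon_offset is not None:
            last_offsets.append(arch.last_exon_offset)

    offsets = np.asarray(last_offsets)
    prox = CONSTANTS.last_exon_proximal
    last_tbl = pd.DataFrame({
        "n_last_exon": [len(offsets)],
        "n_proximal": [int((offsets < prox).sum()) if len(offsets) else 0],
        "fraction_proximal": [float((offsets < prox).mean()) if len(offsets) else np.nan],
    })
    return {
        "exon_class_counts": pd.DataFrame(
            sorted(exon_counts.items()), columns=["exon_class", "n"]),
        "internal_exon_lengths": pd.DataFrame({"exon_length": internal_lengths}),
        "metagene": metagene_density(np.asarray(metagene_coords), bins_per_segment),
        "last_exon": last_tbl,
    }
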