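"""Enrichment and correlation statistics linking sites, regions and
transcript covariates.

* :func:`fisher_coloc` — colocalization of a query site set with an anchor
  set over an explicit universe, via a one-sided Fisher exact test on the
  (near anchor) x (in query) 2x2 table, with a Woolf-logit 95% CI on the
  odds ratio (Haldane-Anscombe corrected when any cell is zero).
* :func:`pcc` / :func:`binned_pcc` — Pearson correlation, raw or after
  averaging within near-equal bins of ranked x (the standard trick for
  visualizing weak transcriptome-wide correlations).
* :func:`ejc_density_vs_outcome` — correlation of per-transcript EJC
  density (CDS exons per kb) with an outcome such as mRNA half-life.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import TranscriptModel, ejc_density, NoncodingTranscriptError


class InsufficientDataError(ValueError):
    pass


class UndefinedCorrelationError(ValueError):
    """Zero variance makes the Pearson correlation undefined."""


@dataclass(frozen=True)
class ColocResult:
    """2x2 colocalization result (odds ratio with 95% CI)."""

    table: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float

    def to_dict(self) -> dict:
        return {"table": [list(r) for r in self.table],
                "odds_ratio": self.odds_ratio, "ci_low": self.ci_low,
                "ci_high": self.ci_high, "p_value": self.p_value}


def fisher_table(table) -> ColocResult:
    """One-sided Fisher exact test (enrichment) plus Woolf-logit 95% CI.

    When any cell is zero the Haldane-Anscombe correction (+0.5 to every
    cell) is applied to both the odds-ratio point estimate and the CI, so
    the estimate always lies inside its interval.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("expected a non-negative 2x2 table")
    ti = np.round(t).astype(int)
    p = stats.fisher_exact(ti, alternative="greater")[1]
    work = t + 0.5 if (t == 0).any() else t
    or_ = (work[0, 0] * work[1, 1]) / (work[0, 1] * work[1, 0])
    se = float(np.sqrt((1.0 / work).sum()))
    lo, hi = np.exp(np.log(or_) + np.array([-1.96, 1.96]) * se)
    return ColocResult(tuple(map(tuple, ti.tolist())), float(or_),
                       float(lo), float(hi), float(p))


def _near_anchor(universe: pd.DataFrame, anchors: pd.DataFrame,
                 window: int) -> np.ndarray:
    """True for universe intervals whose window-padded span overlaps an
    anchor by >= 1 nt (window 0 therefore means direct overlap)."""
    from intervaltree import IntervalTree

    trees: dict[str, IntervalTree] = {}
    for chrom, grp in anchors.groupby("chrom"):
        tree = IntervalTree()
        for s, e in zip(grp["start"], grp["end"]):
            if e > s:
                tree.addi(int(s), int(e))
        trees[chrom] = tree
    out = np.zeros(len(universe), dtype=bool)
    for i, (c, s, e) in enumerate(zip(universe["chrom"], universe["start"],
                                      universe["end"])):
        tree = trees.get(c)
        if tree is not None:
            out[i] = tree.overlaps(int(s) - window, int(e) + window)
    return out


def _interval_keys(df: pd.DataFrame) -> set[tuple]:
    return set(zip(df["chrom"], df["start"], df["end"]))


def fisher_coloc(query: pd.DataFrame, anchors: pd.DataFrame,
                 universe: pd.DataFrame, window: int = 100) -> ColocResult:
    """Enrichment of query sites near anchor sites, within the universe.

    All three are interval tables (``chrom``, ``start``, ``end``; 0-based
    half-open).  Universe sites are cross-classified by (within ``window``
    nt of an anchor) x (member of the query set); the table layout is
    [[near & query, near & not], [far & query, far & not]].  The query must
    be a subset of the universe.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    qk, uk = _interval_keys(query), _interval_keys(universe)
    if not qk <= uk:
        raise ValueError(
            f"query is not a subset of the universe ({len(qk - uk)} foreign sites)")
    near = _near_anchor(universe, anchors, window)
    keys = list(zip(universe["chrom"], universe["start"], universe["end"]))
    in_query = np.array([k in qk for k in keys])
    a = int((near & in_query).sum())
    b = int((near & ~in_query).sum())
    c = int((~near & in_query).sum())
    d = int((~near & ~in_query).sum())
    return fisher_table([[a, b], [c, d]])


# ----------------------------------------------------------------------
# Correlations
# ----------------------------------------------------------------------

def pcc(x, y) -> tuple[float, float]:
    """Pearson correlation with two-sided p (t approximation)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise InsufficientDataError(f"need n >= 3 paired values, got {len(x)}")
    if np.std(x) == 0 or np.std(y) == 0:
        raise UndefinedCorrelationError("zero variance in x or y")
    r = stats.pearsonr(x, y)
    return float(r.statistic), float(r.pvalue)


@dataclass(frozen=True)
class BinnedCorrelation:
    n_bins: int
    bin_x: np.ndarray
    bin_y: np.ndarray
    pcc: float
    p_value: float


def binned_pcc(x, y, n_bins: int = 100) -> BinnedCorrelation:
    """Pearson correlation on bin means after ranking x.

    x is ranked and split into ``n_bins`` near-equal groups (any remainder
    spread over the first bins); the correlation is computed between the
    per-bin means of x and y.  Averaging within bins suppresses independent
    per-observation noise, which is why binned correlations on noisy
    transcriptome-wide data exceed the raw ones.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < n_bins:
        raise InsufficientDataError(
            f"need n >= n_bins ({n_bins}), got {len(x)}")
    order = np.argsort(x, kind="mergesort")
    groups = np.array_split(order, n_bins)
    bx = np.array([x[g].mean() for g in groups])
    by = np.array([y[g].mean() for g in groups])
    r, p = pcc(bx, by)
    return BinnedCorrelation(n_bins, bx, by, r, p)


def ejc_density_vs_outcome(models: dict[str, TranscriptModel],
                           outcomes: pd.DataFrame,
                           outcome_col: str = "outcome",
                           n_bins: int = 100) -> pd.DataFrame:
    """Correlate per-transcript EJC density with an outcome variable.

    ``outcomes`` needs ``transcript_id`` and the outcome column.  Returns a
    one-row report with the raw and (when enough transcripts) binned PCC.
    """
    dens = {}
    for tid, t in models.items():
        try:
            dens[tid] = ejc_density(t)
        except NoncodingTranscriptError:
            continue
    joined = outcomes.assign(ejc_density=outcomes["transcript_id"].map(dens)) \
        .dropna(subset=["ejc_density", outcome_col])
    if len(joined) < 3:
        raise InsufficientDataError(
            f"only {len(joined)} transcripts joinable with outcomes")
    x = joined["ejc_density"].to_numpy()
    y = joined[outcome_col].to_numpy()
    r, p = pcc(x, y)
    row = {"n": len(joined), "pcc": r, "p_value": p,
           "binned_pcc": np.nan, "binned_p_value": np.nan}
    if len(joined) >= n_bins:
        b = binned_pcc(x, y, n_bins)
        row["binned_pcc"], row["binned_p_value"] = b.pcc, b.p_value
    return pd.DataFrame([row])
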