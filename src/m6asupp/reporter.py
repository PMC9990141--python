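"""Reporter-assay enrichment scoring and methylation calls.

The massively parallel reporter assay reads out methylation of each designed
sequence as its enrichment after m6A immunoprecipitation (IP) relative to
input, against the matched DRACH-knockout negative control:

    score = (experimental IP/input) - (control IP/input)

Counts are normalized to counts-per-million within each (replicate,
fraction) library, with a pseudocount of 0.5 reads added before ratio
formation.  Significance uses a one-sided paired test on per-replicate
log2(IP/input) of experimental versus control across replicates
(experimental > control), with Benjamini-Hochberg FDR control across the
library; a site is called methylated when FDR < alpha and the mean score is
positive.  Scores are reported on the ratio-difference scale, while the test
operates on log-ratios for variance stability — both are emitted.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

REQUIRED_COLUMNS = ("pair_id", "replicate", "fraction", "role", "count")
FRACTIONS = ("input", "ip")
ROLES = ("experimental", "control")


class NormalizationError(ValueError):
    """A sequencing library is empty and cannot be CPM-normalized."""


class PairingError(ValueError):
    """An experimental oligo lacks its control partner in some cell."""


class InsufficientReplicatesError(ValueError):
    """Fewer than two replicates were supplied."""


def _check_counts(counts: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in counts.columns]
    if missing:
        raise ValueError(f"counts table lacks columns {missing}")
    bad_frac = set(counts["fraction"]) - set(FRACTIONS)
    bad_role = set(counts["role"]) - set(ROLES)
    if bad_frac:
        raise ValueError(f"unknown fraction labels {sorted(bad_frac)}")
    if bad_role:
        raise ValueError(f"unknown role labels {sorted(bad_role)}")
    if (counts["count"] < 0).any():
        raise ValueError("negative counts")


def normalize(counts: pd.DataFrame, pseudocount: float = 0.5) -> pd.DataFrame:
    """Add CPM columns within each (replicate, fraction) library.

    ``cpm`` is the plain counts-per-million value; ``cpm_pseudo`` adds the
    pseudocount (in read units) before scaling and is the quantity used for
    ratio formation, so zero counts yield finite ratios.
    """
    _check_counts(counts)
    out = counts.copy()
    lib = out.groupby(["replicate", "fraction"])["count"].transform("sum")
    if (lib == 0).any():
        empties = out.loc[lib == 0, ["replicate", "fraction"]].drop_duplicates()
        raise NormalizationError(
            f"all-zero libraries: {empties.to_dict('records')}")
    out["cpm"] = out["count"] / lib * 1e6
    out["cpm_pseudo"] = (out["count"] + pseudocount) / lib * 1e6
    return out


def _ratio_matrix(counts: pd.DataFrame) -> pd.DataFrame:
    """Wide table: one row per pair, IP/input ratio per (role, replicate)."""
    norm = normalize(counts)
    wide = norm.pivot_table(index="pair_id", columns=["role", "fraction", "replicate"],
                            values="cpm_pseudo", aggfunc="first")
    # every experimental oligo needs its control partner in all four cells
    reps = sorted({c[2] for c in wide.columns})
    expected = [(role, frac, r) for role in ROLES for frac in FRACTIONS
                for r in reps]
    absent = [c for c in expected if c not in wide.columns]
    if absent or wide.isna().any().any():
        missing = absent + wide.columns[wide.isna().any()].tolist()
        raise PairingError(f"missing count cells (role, fraction, replicate): {missing}")
    ratios = {}
    for role in ROLES:
        for r in reps:
            ratios[(role, r)] = wide[(role, "ip", r)] / wide[(role, "input", r)]
    return pd.DataFrame(ratios)


def enrichment_scores(counts: pd.DataFrame) -> pd.DataFrame:
    """Per-replicate and mean enrichment scores for every pair.

    score_rep = (exp IP/input) - (ctl IP/input), on CPM with pseudocount.
    """
    ratios = _ratio_matrix(counts)
    reps = sorted({r for _, r in ratios.columns})
    out = pd.DataFrame(index=ratios.index)
    for r in reps:
        out[f"score_rep{r}"] = ratios[("experimental", r)] - ratios[("control", r)]
        out[f"log2fc_rep{r}"] = np.log2(ratios[("experimental", r)]) - \
            np.log2(ratios[("control", r)])
    out["mean_score"] = out[[f"score_rep{r}" for r in reps]].mean(axis=1)
    out["mean_log2fc"] = out[[f"log2fc_rep{r}" for r in reps]].mean(axis=1)
    return out.reset_index()


def spike_normalized_enrichment(ip: float, input_: float,
                                spike_ip: float, spike_input: float) -> float:
    """IP/input enrichment normalized to a known-methylated spike-in RNA.

    (ip/input) / (spike_ip/spike_input); all four values must be positive.
    """
    vals = {"ip": ip, "input": input_, "spike_ip": spike_ip, "spike_input": spike_input}
    for name, v in vals.items():
        if v <= 0:
            raise ValueError(f"{name} must be > 0, got {v}")
    return (ip / input_) / (spike_ip / spike_input)


def _paired_onesided_pvalues(diffs: np.ndarray, test: str) -> np.ndarray:
    """One-sided p-values (alternative: mean difference > 0) per row.

    Degenerate rows (zero variance across replicates) are handled by rule:
    constant positive difference -> machine-minimum p (perfect separation);
    constant zero or negative difference -> p = 1.
    """
    n = diffs.shape[1]
    tiny = float(np.finfo(float).tiny)
    if test == "ttest":
        mean = diffs.mean(axis=1)
        sd = diffs.std(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = mean / (sd / np.sqrt(n))
        p = stats.t.sf(tstat, df=n - 1)
        degenerate = sd == 0
        p[degenerate & (mean > 0)] = tiny
        p[degenerate & (mean <= 0)] = 1.0
        return p
    if test == "wilcoxon":
        p = np.ones(len(diffs))
        for i, row in enumerate(diffs):
            if np.all(row == 0):
                p[i] = 1.0
            else:
                p[i] = stats.wilcoxon(row, alternative="greater",
                                      zero_method="wilcox").pvalue
        return p
    raise ValueError(f"unknown test {test!r} (expected 'ttest' or 'wilcoxon')")


def call_methylation(counts: pd.DataFrame, alpha: float = 0.05,
                     test: str = "ttest") -> pd.DataFrame:
    """Enrichment scores, p-values, BH FDR and methylation calls per pair.

    The test is a one-sided paired comparison of per-replicate
    log2(IP/input) between experimental and control oligos (experimental >
    control); ``call`` is True iff FDR < alpha and the mean ratio-difference
    score is positive.  Requires at least two replicates.
    """
    ratios = _ratio_matrix(counts)
    reps = sorted({r for _, r in ratios.columns})
    if len(reps) < 2:
        raise InsufficientReplicatesError(
            f"need >= 2 replicates, got {len(reps)}")
    scores = enrichment_scores(counts).set_index("pair_id")
    exp = np.log2(ratios[[("experimental", r) for r in reps]].to_numpy())
    ctl = np.log2(ratios[[("control", r) for r in reps]].to_numpy())
    p = _paired_onesided_pvalues(exp - ctl, test)
    _, fdr, _, _ = multipletests(p, method="fdr_bh")
    out = scores
    out["p_value"] = p
    out["fdr"] = fdr
    out["call"] = (out["fdr"] < alpha) & (out["mean_score"] > 0)
    return out.reset_index()


SITE_CLASSES = ("confirmed", "suppressed", "context_dependent", "inert", "unknown")


def classify_suppressed(calls: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Cross endogenous status with reporter calls into site classes.

    suppressed          endogenously unmethylated, reporter-methylated
    confirmed           endogenously methylated, reporter-methylated
    context_dependent   endogenously methylated, not reporter-methylated
    inert               endogenously unmethylated, not reporter-methylated
    unknown             endogenous status unknown (kept, never dropped)

    ``meta`` needs columns ``pair_id`` and ``endogenous_status``.
    """
    merged = calls.merge(meta[["pair_id", "endogenous_status"]], on="pair_id",
                         how="left", validate="one_to_one")
    merged["endogenous_status"] = merged["endogenous_status"].fillna("unknown")

    def cls(row) -> str:
        if row.endogenous_status == "unknown":
            return "unknown"
        if row.endogenous_status == "methylated":
            return "confirmed" if row.call else "context_dependent"
        return "suppressed" if row.call else "inert"

    merged["site_class"] = [cls(r) for r in merged.itertuples(index=False)]
    return merged


def summarize_calls(classified: pd.DataFrame) -> pd.DataFrame:
    """Fraction of reporter-methylated sequences per endogenous class."""
    g = classified.groupby("endogenous_status")["call"]
    return pd.DataFrame({"n": g.size(), "n_methylated": g.sum(),
                         "fraction_methylated": g.mean()}).reset_index()
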