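"""End-to-end synthetic study and the emergent qualitative signatures.

Running the full pipeline on one seeded synthetic transcriptome reproduces
the core observations the protection model implies:

a. the reporter context (no introns, hence no EJCs) methylates endogenously
   unmethylated sites at nearly the same rate as endogenously methylated
   ones;
b. knockdown-hypermethylated regions are enriched in short (< 246 nt)
   internal exons;
c. most hypermethylated regions do not overlap control-condition m6A peaks
   ("novel" regions dominate);
d. within last exons, hypermethylation concentrates in the first 150 nt
   past the last-exon start;
e. the predicted reporter exon-length series loses suppression
   monotonically with exon length.

These functions are shared by the test suite, the acceptance script and the
``report`` CLI subcommand.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import annotation, diffmeth, oligo, reporter, simulate
from .annotation import CONSTANTS, TranscriptModel
from .association import ColocResult, fisher_table
from .ejc_model import predict_reporter_series
from .simulate import GeneratorConfig


@dataclass
class StudyBundle:
    """Everything one synthetic study produces."""

    cfg: GeneratorConfig
    models: dict[str, TranscriptModel]
    seqs: dict[str, str]
    sites: pd.DataFrame            # truth-annotated DRACH sites
    pairs_meta: pd.DataFrame       # designed oligo pairs
    oligo_counts: pd.DataFrame
    calls: pd.DataFrame            # classified reporter calls
    regions: pd.DataFrame          # tiled regions with truth fractions
    region_counts: pd.DataFrame
    region_results: pd.DataFrame   # diffmeth calls with novel flags + arch
    peaks: pd.DataFrame            # control-condition truth peaks (BED-like)


def _region_architecture(regions: pd.DataFrame,
                         models: dict[str, TranscriptModel]) -> pd.DataFrame:
    """Midpoint architecture columns for every region."""
    exon_class = []
    exon_length = []
    last_off = []
    for rec in regions.itertuples(index=False):
        t = models[rec.transcript_id]
        mid = min((int(rec.tstart) + int(rec.tend)) // 2, t.length - 1)
        arch = annotation.classify_site(t, mid)
        exon_class.append(arch.exon_class)
        exon_length.append(arch.exon_length)
        last_off.append(arch.last_exon_offset)
    out = regions.copy()
    out["exon_class"] = exon_class
    out["exon_length"] = exon_length
    out["last_exon_offset"] = last_off
    return out


def run_study(cfg: GeneratorConfig, n_lib_methylated: int = 600,
              n_lib_unmethylated: int = 300,
              alpha: float = 0.05, fdr_thresh: float = 0.1,
              lfc_thresh: float = 1.0) -> StudyBundle:
    """Generate a synthetic study and run the full pipeline on it.

    The reporter library samples endogenously methylated and unmethylated
    sites at roughly the 2:1 ratio of the real assay design.
    """
    rng = np.random.default_rng(cfg.seed)
    models, seqs0 = simulate.generate_transcriptome(cfg)
    seqs, site_tbl = simulate.plant_drach(seqs0, cfg, rng)
    sites = simulate.assign_truth(site_tbl, models, cfg.params, rng)

    # --- reporter arm -------------------------------------------------
    def sample_class(status: str, n: int) -> pd.DataFrame:
        pool = sites[sites["endogenous_status"] == status]
        n = min(n, len(pool))
        return pool.sample(n=n, random_state=int(rng.integers(2**31)))

    lib = pd.concat([sample_class("methylated", n_lib_methylated),
                     sample_class("unmethylated", n_lib_unmethylated)])
    drach_sites = [oligo.DrachSite(r.transcript_id, int(r.pos), r.motif,
                                   r.endogenous_status)
                   for r in lib.itertuples(index=False)]
    pairs, _rejects = oligo.build_library(drach_sites, seqs)
    meta = oligo.pair_metadata_table(pairs)
    oligo_counts, _otruth = simulate.simulate_oligo_counts(meta, cfg, rng)
    called = reporter.call_methylation(oligo_counts, alpha=alpha)
    calls = reporter.classify_suppressed(called, meta)

    # --- knockdown arm ------------------------------------------------
    regions = simulate.tile_regions(models, cfg.region_window)
    regions = simulate.region_truth(regions, sites, cfg, rng=rng)
    region_counts = simulate.simulate_region_counts(regions, cfg, rng)
    results = diffmeth.call_regions(region_counts, fdr_thresh=fdr_thresh,
                                    lfc_thresh=lfc_thresh)
    merged = regions.merge(results, on="region_id", validate="one_to_one")
    peaks = simulate.control_peaks(regions)
    merged = diffmeth.overlap_peaks(merged, peaks)
    merged = _region_architecture(merged, models)
    return StudyBundle(cfg, models, seqs, sites, meta, oligo_counts, calls,
                       regions, region_counts, merged, peaks)


# ----------------------------------------------------------------------
# Signature metrics
# ----------------------------------------------------------------------

def reporter_class_rates(bundle: StudyBundle) -> dict[str, float]:
    """Reporter methylation-call rate per endogenous class, and their gap
    in percentage points."""
    summary = reporter.summarize_calls(bundle.calls)
    by = summary.set_index("endogenous_status")["fraction_methylated"]
    rate_m = float(by.get("methylated", np.nan))
    rate_u = float(by.get("unmethylated", np.nan))
    return {"rate_methylated": rate_m, "rate_unmethylated": rate_u,
            "gap_pp": abs(rate_m - rate_u) * 100.0}


def hyper_short_exon_enrichment(bundle: StudyBundle,
                                length_thresh: int = CONSTANTS.long_exon_p90_reference,
                                ) -> ColocResult:
    """Fisher enrichment of hyper calls in short internal exons.

    Universe: regions whose midpoint lies in an internal exon; 2x2 of
    (hyper vs not) x (exon length < 246 nt vs >=)."""
    r = bundle.region_results
    internal = r[r["exon_class"] == "internal"]
    hyper = internal["class"] == "hyper"
    short = internal["exon_length"] < length_thresh
    table = [[int((hyper & short).sum()), int((hyper & ~short).sum())],
             [int((~hyper & short).sum()), int((~hyper & ~short).sum())]]
    return fisher_table(table)


def hyper_peak_overlap_fraction(bundle: StudyBundle) -> float:
    """Fraction of hyper calls that overlap a control-condition truth peak
    (the complement of the 'novel' fraction)."""
    hyper = bundle.region_results[bundle.region_results["class"] == "hyper"]
    if not len(hyper):
        return float("nan")
    return float(1.0 - hyper["novel"].mean())


def last_exon_density_contrast(bundle: StudyBundle,
                               proximal: int = CONSTANTS.last_exon_proximal,
                               ) -> dict[str, float]:
    """Density (hyper calls per kb) within vs beyond ``proximal`` nt past
    last-exon starts."""
    r = bundle.region_results
    last = r[r["exon_class"].isin(["last", "single_exon"]) &
             (r["class"] == "hyper")]
    offs = last["last_exon_offset"].to_numpy(dtype=float)
    n_prox = int((offs < proximal).sum())
    n_dist = int((offs >= proximal).sum())
    nt_prox = nt_dist = 0
    for t in bundle.models.values():
        L = t.exon_lengths[-1]
        nt_prox += min(L, proximal)
        nt_dist += max(L - proximal, 0)
    dens_prox = n_prox / nt_prox * 1000.0
    dens_dist = n_dist / nt_dist * 1000.0 if nt_dist else float("nan")
    return {"n_proximal": n_prox, "n_distal": n_dist,
            "density_proximal_per_kb": dens_prox,
            "density_distal_per_kb": dens_dist}


REPORTER_SERIES_LENGTHS = (102, 136, 177, 238, 300, 476, 600, 912)


def reporter_series(bundle_or_cfg) -> pd.DataFrame:
    """Predicted suppression ratio across the reporter exon-length series."""
    cfg = bundle_or_cfg.cfg if isinstance(bundle_or_cfg, StudyBundle) \
        else bundle_or_cfg
    ratios = predict_reporter_series(REPORTER_SERIES_LENGTHS, cfg.params)
    return pd.DataFrame({"exon_length": REPORTER_SERIES_LENGTHS,
                         "suppression_ratio": ratios})


def signature_report(bundle: StudyBundle) -> dict:
    """All emergent-signature statistics for one study."""
    rates = reporter_class_rates(bundle)
    enr = hyper_short_exon_enrichment(bundle)
    series = reporter_series(bundle)
    dens = last_exon_density_contrast(bundle)
    n_hyper = int((bundle.region_results["class"] == "hyper").sum())
    n_hypo = int((bundle.region_results["class"] == "hypo").sum())
    return {
        "reporter": rates,
        "n_hyper": n_hyper,
        "n_hypo": n_hypo,
        "hyper_short_exon_or": enr.odds_ratio,
        "hyper_short_exon_p": enr.p_value,
        "hyper_peak_overlap_fraction": hyper_peak_overlap_fraction(bundle),
        "last_exon": dens,
        "suppression_ratio_102": float(series["suppression_ratio"].iloc[0]),
        "suppression_ratio_476": float(
            series.set_index("exon_length")["suppression_ratio"].loc[476]),
    }
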