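"""Differential-methylation region calling."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2_contingency

from m6asupp import GeneratorConfig, call_regions, cmh_from_tables, cmh_test, \
    overlap_peaks, region_log2fc, architecture_profile, TranscriptModel
from m6asupp.diffmeth import RegionValidationError, fisher_pooled_test
from m6asupp.simulate import simulate_region_counts


def _region_counts(regions: dict, replicates=1) -> pd.DataFrame:
    """regions maps region_id -> {(condition, fraction): count}."""
    rows = []
    for rid, cells in regions.items():
        for (cond, frac), cnt in cells.items():
            for r in range(1, replicates + 1):
                c = cnt if np.isscalar(cnt) else cnt[r - 1]
                rows.append(dict(region_id=rid, replicate=r, condition=cond,
                                 fraction=frac, count=c))
    return pd.DataFrame(rows)


def _with_filler(cells: dict, total: int = 2_000_000) -> dict:
    """Add a filler region so every library has the same total depth (CPM
    then cancels and the example ratios hold exactly)."""
    return {"r": cells,
            "filler": {k: total - v for k, v in cells.items()}}


def test_log2fc_examples():
    # kd IP/input ratio 4x the ctl ratio -> log2fc = 2
    c = _region_counts(_with_filler(
        {("ctl", "input"): 40_000, ("ctl", "ip"): 10_000,
         ("kd", "input"): 20_000, ("kd", "ip"): 20_000}))
    assert region_log2fc(c).loc["r"] == pytest.approx(2.0, abs=1e-3)
    c0 = _region_counts(_with_filler(
        {("ctl", "input"): 5000, ("ctl", "ip"): 7000,
         ("kd", "input"): 5000, ("kd", "ip"): 7000}))
    assert region_log2fc(c0).loc["r"] == pytest.approx(0.0, abs=1e-9)


def test_log2fc_antisymmetric_under_condition_swap():
    c = _region_counts(_with_filler(
        {("ctl", "input"): 9000, ("ctl", "ip"): 3000,
         ("kd", "input"): 4000, ("kd", "ip"): 8000}))
    swapped = c.assign(condition=c["condition"].map({"ctl": "kd", "kd": "ctl"}))
    assert region_log2fc(c).loc["r"] == pytest.approx(
        -region_log2fc(swapped).loc["r"])


# ----------------------------------------------------------------------
# CMH test
# ----------------------------------------------------------------------

def test_cmh_single_stratum_equals_yates(rng):
    """One stratum reduces exactly to the continuity-corrected 2x2
    chi-square."""
    for _ in range(200):
        t = rng.integers(1, 60, size=(2, 2))
        stat, p = cmh_from_tables(t)
        ref = chi2_contingency(t, correction=True)
        assert abs(stat - ref.statistic) < 1e-10
        assert abs(p - ref.pvalue) < 1e-10


def test_cmh_identical_odds_ratio_one():
    t = np.array([[[50, 50], [50, 50]]] * 3)
    stat, p = cmh_from_tables(t)
    assert stat == pytest.approx(0.0, abs=1e-9)
    assert p == pytest.approx(1.0)


def test_cmh_stratum_permutation_invariance(rng):
    tabs = rng.integers(1, 80, size=(4, 2, 2))
    stat1, p1 = cmh_from_tables(tabs)
    perm = tabs[rng.permutation(4)]
    stat2, p2 = cmh_from_tables(perm)
    assert stat1 == pytest.approx(stat2)
    assert p1 == pytest.approx(p2)


def test_cmh_close_to_statsmodels(rng):
    """Dual route: the statistic matches statsmodels' classical CMH up to
    the (N-1)/N variance convention."""
    from statsmodels.stats.contingency_tables import StratifiedTable

    tabs = rng.integers(20, 200, size=(3, 2, 2))
    stat, _ = cmh_from_tables(tabs)
    sm = StratifiedTable(np.transpose(tabs, (1, 2, 0)).astype(float))
    ref = float(sm.test_null_odds(correction=True).statistic)
    assert stat == pytest.approx(ref, rel=0.02)


def test_cmh_all_degenerate_returns_one(caplog):
    with caplog.at_level("WARNING"):
        stat, p = cmh_from_tables(np.zeros((3, 2, 2)))
    assert p == 1.0


def test_cmh_null_rejection_rate():
    """1,000 generator-null regions reject at about the nominal 5% rate."""
    rng = np.random.default_rng(202)
    n = 1000
    regions = pd.DataFrame({
        "region_id": [f"r{i}" for i in range(n)], "transcript_id": "t",
        "tstart": 0, "tend": 100, "chrom": "c", "start": 0, "end": 100,
        "strand": "+", "n_sites": 0, "frac_ctl": 0.0, "frac_kd": 0.0,
        "truth_log2fc": 0.0, "expression": rng.lognormal(0, 1, n)})
    cfg = GeneratorConfig(seed=8, depth_region=200_000)
    counts = simulate_region_counts(regions, cfg, rng)
    res = cmh_test(counts)
    rate = (res["p_value"] < 0.05).mean()
    assert 0.03 <= rate <= 0.07


# ----------------------------------------------------------------------
# Region calling
# ----------------------------------------------------------------------

def _truthy_counts(rng, n=400, n_hyper=50, depth=100_000):
    frac_kd = np.zeros(n)
    frac_kd[:n_hyper] = 1.0
    regions = pd.DataFrame({
        "region_id": [f"r{i}" for i in range(n)], "transcript_id": "t",
        "tstart": 0, "tend": 100, "chrom": "c", "start": 0, "end": 100,
        "strand": "+", "n_sites": 1, "frac_ctl": 0.0, "frac_kd": frac_kd,
        "truth_log2fc": np.log2(1 + 7 * frac_kd),
        "expression": rng.lognormal(0, 1, n)})
    cfg = GeneratorConfig(seed=9, depth_region=depth)
    return regions, simulate_region_counts(regions, cfg, rng)


def test_call_regions_classes_and_threshold_monotonicity(rng):
    regions, counts = _truthy_counts(rng)
    res = call_regions(counts)
    merged = regions.merge(res, on="region_id")
    truth = merged["truth_log2fc"] > 1
    hyper = merged["class"] == "hyper"
    assert (hyper & truth).sum() / truth.sum() >= 0.9      # recall
    assert (hyper & ~truth).sum() / max(hyper.sum(), 1) <= 0.15
    # hyper/hypo invariants
    assert (merged.loc[hyper, "log2fc"] > 1).all()
    assert (merged.loc[hyper, "fdr"] < 0.1).all()
    # BH monotonicity: rejections grow with the threshold
    loose = call_regions(counts, fdr_thresh=0.3)
    tight_ids = set(res.loc[res["class"] != "unchanged", "region_id"])
    loose_ids = set(loose.loc[loose["class"] != "unchanged", "region_id"])
    assert tight_ids <= loose_ids


def test_effect_size_filter():
    # strong statistical signal but |log2fc| < 1 stays unchanged; the
    # filler region anchors the library sizes
    c = _region_counts(
        {"r": {("ctl", "input"): 50_000, ("ctl", "ip"): 50_000,
               ("kd", "input"): 50_000, ("kd", "ip"): 90_000},
         "filler": {("ctl", "input"): 10**6, ("ctl", "ip"): 10**6,
                    ("kd", "input"): 10**6, ("kd", "ip"): 10**6}},
        replicates=3)
    res = call_regions(c).set_index("region_id")
    assert res.loc["r", "fdr"] < 0.1
    assert 0 < res.loc["r", "log2fc"] < 1
    assert res.loc["r", "class"] == "unchanged"


def test_fisher_pooled_fallback(rng):
    regions, counts = _truthy_counts(rng, n=60, n_hyper=10)
    res = call_regions(counts, test="fisher")
    merged = regions.merge(res, on="region_id")
    assert (merged.loc[merged["truth_log2fc"] > 1, "class"] == "hyper").mean() > 0.8


# ----------------------------------------------------------------------
# Peak overlap
# ----------------------------------------------------------------------

def test_overlap_boundaries():
    regions = pd.DataFrame({"chrom": ["c", "c"], "start": [100, 100],
                            "end": [200, 200], "region_id": ["a", "b"]})
    peaks1 = pd.DataFrame({"chrom": ["c"], "start": [150], "end": [160]})
    peaks2 = pd.DataFrame({"chrom": ["c"], "start": [200], "end": [300]})
    assert not overlap_peaks(regions, peaks1)["novel"].iloc[0]
    # half-open: touching at the boundary is NOT an overlap
    assert overlap_peaks(regions, peaks2)["novel"].iloc[0]


def test_overlap_vs_bruteforce(rng):
    n, m = 300, 100
    regions = pd.DataFrame({
        "chrom": rng.choice(["c1", "c2"], n),
        "start": rng.integers(0, 10_000, n)})
    regions["end"] = regions["start"] + rng.integers(1, 200, n)
    peaks = pd.DataFrame({
        "chrom": rng.choice(["c1", "c2"], m),
        "start": rng.integers(0, 10_000, m)})
    peaks["end"] = peaks["start"] + rng.integers(1, 200, m)
    got = overlap_peaks(regions, peaks)["novel"].to_numpy()
    for i in range(n):
        hit = any(peaks["chrom"][j] == regions["chrom"][i]
                  and peaks["start"][j] < regions["end"][i]
                  and peaks["end"][j] > regions["start"][i]
                  for j in range(m))
        assert got[i] == (not hit)


def test_chromosome_mismatch_rejected():
    regions = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [10]})
    peaks = pd.DataFrame({"chrom": ["1"], "start": [0], "end": [10]})
    with pytest.raises(RegionValidationError, match="chr1"):
        overlap_peaks(regions, peaks)


# ----------------------------------------------------------------------
# Architecture profile
# ----------------------------------------------------------------------

def test_architecture_profile_tables():
    t = TranscriptModel("tx", "g", "c", "+",
                        ((0, 200), (300, 467), (500, 900)),
                        cds_start=50, cds_end=400)
    regions = pd.DataFrame({
        "region_id": ["a", "b", "c"], "transcript_id": ["tx", "tx", "missing"],
        "tstart": [200, 400, 0], "tend": [300, 500, 100]})
    models = {"tx": t}
    tables = architecture_profile(regions, models)
    # region "a" midpoint 250 -> internal exon of length 167
    assert 167 in tables["internal_exon_lengths"]["exon_length"].tolist()
    assert tables["exon_class_counts"].set_index("exon_class")["n"]["unassigned"] == 1
    dens = tables["metagene"]
    width = dens["bin_right"].iloc[0] - dens["bin_left"].iloc[0]
    assert (dens["density"] * width).sum() == pytest.approx(1.0)
    # region "b" midpoint 450 -> last exon, offset 83 < 150
    assert tables["last_exon"]["fraction_proximal"].iloc[0] == 1.0
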