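"""Seeded synthetic data emulating the study's inputs.

The generator produces every input the pipeline consumes:

* a transcriptome whose internal-exon lengths follow a log-normal body with
  a heavy upper tail (short-body/long-tail: ~90% of internal exons below
  ~246 nt, 10th percentile near 60 nt), with first/internal/last exons and
  a CDS ending shortly after the last-exon start (stop codons sit near the
  start of long last exons);
* DRACH sites planted at a configured density into random transcript
  sequence, then rescanned so the site list is exactly the scanner output;
* truth methylation states per site under control and EJC-knockdown
  contexts, drawn from the junction-distance protection model with a shared
  uniform per site so knockdown never demethylates (suppression of
  deposition, not demethylation);
* overdispersed IP/input sequencing counts for reporter oligos and tiled
  transcript regions.  Overdispersion is realized as a shared Gamma
  abundance per (unit, replicate, condition) with Poisson reads given the
  abundance — marginally negative binomial, while the abundance cancels in
  the IP/input odds ratio as in a matched input/IP library preparation.

All draws descend from a single integer seed; identical configs give
byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .annotation import TranscriptModel, ejc_sites
from .ejc_model import EJCModelParams, default_params
from .oligo import DRACH_MOTIFS, scan_drach

BASES = np.array(list("ACGU"))
_DRACH_LIST = sorted(DRACH_MOTIFS)


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the synthetic study, with defaults chosen to emulate
    the real transcriptome and assay geometry (lengths in nt, depths in
    reads per library)."""

    seed: int = 0
    n_genes: int = 500
    exons_per_gene: tuple[int, int] = (4, 9)          # uniform inclusive range
    # internal exon lengths: log-normal body + heavy log-normal tail
    internal_meanlog: float = math.log(110.0)
    internal_sdlog: float = 0.42
    tail_weight: float = 0.06
    tail_meanlog: float = math.log(1200.0)
    tail_sdlog: float = 0.6
    min_exon: int = 20
    first_meanlog: float = math.log(150.0)
    first_sdlog: float = 0.5
    last_meanlog: float = math.log(700.0)             # long 3'UTR-bearing last exons
    last_sdlog: float = 0.5
    intron_meanlog: float = math.log(400.0)
    intron_sdlog: float = 0.6
    min_intron: int = 60
    drach_per_kb: float = 2.0
    ejc_params: EJCModelParams | None = None          # None -> calibrated defaults
    depth_oligo: int = 1_000_000
    depth_region: int = 2_000_000
    dispersion: float = 0.1                           # NB dispersion (var = m + disp*m^2)
    ip_gain: float = 8.0                              # IP fold-enrichment of a methylated molecule
    replicates_oligo: int = 4
    replicates_region: int = 3
    region_window: int = 100
    oligo_abundance_sdlog: float = 0.3
    expression_sdlog: float = 1.0

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.drach_per_kb <= 0:
            raise ConfigError("n_genes and drach_per_kb must be positive")
        if not 0 <= self.tail_weight <= 1:
            raise ConfigError("tail_weight must be in [0,1]")
        lo, hi = self.exons_per_gene
        if not 1 <= lo <= hi:
            raise ConfigError(f"bad exons_per_gene range {self.exons_per_gene}")
        for name in ("depth_oligo", "depth_region", "dispersion", "ip_gain",
                     "replicates_oligo", "replicates_region", "region_window"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")

    @property
    def params(self) -> EJCModelParams:
        return self.ejc_params if self.ejc_params is not None else default_params()


def lognormal_quantile(q: float, meanlog: float, sdlog: float) -> float:
    """Closed-form quantile of the log-normal distribution."""
    from scipy.stats import norm
    return float(math.exp(meanlog + sdlog * norm.ppf(q)))


def sample_internal_exon_lengths(rng: np.random.Generator, n: int,
                                 cfg: GeneratorConfig) -> np.ndarray:
    """Draw internal-exon lengths from the body+tail log-normal mixture."""
    tail = rng.uniform(size=n) < cfg.tail_weight
    body = rng.lognormal(cfg.internal_meanlog, cfg.internal_sdlog, size=n)
    long_ = rng.lognormal(cfg.tail_meanlog, cfg.tail_sdlog, size=n)
    out = np.where(tail, long_, body)
    return np.maximum(np.round(out).astype(int), cfg.min_exon)


# ----------------------------------------------------------------------
# Transcriptome
# ----------------------------------------------------------------------

def generate_transcriptome(cfg: GeneratorConfig,
                           ) -> tuple[dict[str, TranscriptModel], dict[str, str]]:
    """Random gene models and transcript sequences, deterministic per seed.

    One transcript per gene, all on a single synthetic chromosome with
    alternating strands; CDS starts inside the first exon and ends shortly
    after the last-exon start.
    """
    rng = np.random.default_rng(cfg.seed)
    models: dict[str, TranscriptModel] = {}
    seqs: dict[str, str] = {}
    cursor = 1000
    lo, hi = cfg.exons_per_gene
    for gi in range(cfg.n_genes):
        n_ex = int(rng.integers(lo, hi + 1))
        if n_ex == 1:
            lengths = [max(int(round(rng.lognormal(cfg.last_meanlog, cfg.last_sdlog))),
                           300)]
        else:
            first = max(int(round(rng.lognormal(cfg.first_meanlog, cfg.first_sdlog))),
                        30)
            internals = sample_internal_exon_lengths(rng, n_ex - 2, cfg).tolist()
            last = max(int(round(rng.lognormal(cfg.last_meanlog, cfg.last_sdlog))),
                       100)
            lengths = [first] + internals + [last]
        introns = np.maximum(
            np.round(rng.lognormal(cfg.intron_meanlog, cfg.intron_sdlog,
                                   size=max(n_ex - 1, 0))).astype(int),
            cfg.min_intron)
        strand = "+" if gi % 2 == 0 else "-"
        # genomic layout 5'->3' along the genome, then orient
        g_exons = []
        g = cursor
        for i, ln in enumerate(lengths):
            g_exons.append((g, g + ln))
            g += ln
            if i < n_ex - 1:
                g += int(introns[i])
        cursor = g + 500
        exons = tuple(g_exons if strand == "+" else g_exons[::-1])
        if strand == "-":
            lengths = lengths[::-1]  # genomic-left exon is transcript-last

        tid = f"TX{gi:04d}"
        tlen = sum(e - s for s, e in exons)
        tx_lengths = [e - s for s, e in exons]
        # CDS: starts inside the first exon, ends shortly past last-exon start
        cds_start = int(rng.integers(20, max(min(tx_lengths[0] - 1, 300), 21)))
        last_tstart = tlen - tx_lengths[-1]
        stop_off = int(rng.integers(10, min(201, tx_lengths[-1] - 9)))
        cds_end = min(last_tstart + stop_off, tlen - 1)
        if cds_end <= cds_start:
            cds_end = cds_start + 3
        models[tid] = TranscriptModel(tid, f"G{gi:04d}", "chrS", strand, exons,
                                      cds_start=cds_start, cds_end=cds_end)
        seqs[tid] = "".join(rng.choice(BASES, size=tlen))
    return models, seqs


# ----------------------------------------------------------------------
# DRACH planting and truth methylation
# ----------------------------------------------------------------------

def plant_drach(seqs: dict[str, str], cfg: GeneratorConfig,
                rng: np.random.Generator | None = None,
                ) -> tuple[dict[str, str], pd.DataFrame]:
    """Plant DRACH 5-mers at the configured density, then rescan.

    Planted motifs overwrite the sequence at non-overlapping positions; the
    returned site table is exactly the scanner output (planted motifs plus
    whatever DRACH occurs by chance), with a ``planted`` flag.
    """
    rng = np.random.default_rng(cfg.seed + 1) if rng is None else rng
    new_seqs: dict[str, str] = {}
    rows = []
    for tid in sorted(seqs):
        s = list(seqs[tid])
        n_plant = int(round(cfg.drach_per_kb * len(s) / 1000.0))
        usable = len(s) - 4
        if n_plant * 5 > usable:
            raise ConfigError(
                f"{tid}: density {cfg.drach_per_kb}/kb infeasible for length {len(s)}")
        planted: set[int] = set()
        starts: list[int] = []
        tries = 0
        while len(starts) < n_plant and tries < 50 * max(n_plant, 1):
            tries += 1
            p = int(rng.integers(0, usable + 1))
            if all(abs(p - q) >= 5 for q in starts):
                starts.append(p)
        for p in sorted(starts):
            motif = _DRACH_LIST[int(rng.integers(0, len(_DRACH_LIST)))]
            s[p:p + 5] = list(motif)
            planted.add(p + 2)
        seq = "".join(s)
        new_seqs[tid] = seq
        for pos, motif in scan_drach(seq):
            rows.append({"transcript_id": tid, "pos": pos, "motif": motif,
                         "planted": pos in planted})
    return new_seqs, pd.DataFrame(rows)


def assign_truth(sites: pd.DataFrame, models: dict[str, TranscriptModel],
                 params: EJCModelParams,
                 rng: np.random.Generator | int = 2) -> pd.DataFrame:
    """Truth methylation per site under control and knockdown contexts.

    A single uniform draw per site is compared against meth_prob with and
    without EJCs, coupling the two states (kd is a superset of ctl).  Adds
    columns ``dist_nearest_ejc`` (NaN for EJC-free transcripts),
    ``meth_ctl``, ``meth_kd`` and ``endogenous_status``.
    """
    from .ejc_model import meth_prob

    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) \
        else rng
    out = sites.copy()
    dists = np.full(len(out), np.nan)
    ejc_cache: dict[str, list[int]] = {}
    tids = out["transcript_id"].to_numpy()
    poss = out["pos"].to_numpy()
    for i in range(len(out)):
        t = models[tids[i]]
        es = ejc_cache.setdefault(t.transcript_id, ejc_sites(t))
        if es:
            dists[i] = min(abs(int(poss[i]) - e) for e in es)
    u = rng.uniform(size=len(out))
    p_ctl = np.asarray(meth_prob(dists, True, params))
    out["dist_nearest_ejc"] = dists
    out["meth_ctl"] = u < p_ctl
    out["meth_kd"] = u < params.p_open
    out["endogenous_status"] = np.where(out["meth_ctl"], "methylated",
                                        "unmethylated")
    return out


# ----------------------------------------------------------------------
# Count simulation
# ----------------------------------------------------------------------

def _matched_counts(mu: np.ndarray, gain: np.ndarray, depth: float,
                    dispersion: float, rng: np.random.Generator,
                    ) -> tuple[np.ndarray, np.ndarray]:
    """One replicate library pair: shared Gamma abundance, Poisson reads.

    ``mu`` are relative abundances, ``gain`` the IP enrichment factor per
    unit.  Input and IP libraries are each scaled to the target depth.
    """
    shape = 1.0 / dispersion
    a = rng.gamma(shape, scale=mu * dispersion)
    lam_in = a / a.sum() * depth
    ag = a * gain
    lam_ip = ag / ag.sum() * depth
    return rng.poisson(lam_in), rng.poisson(lam_ip)


def simulate_oligo_counts(meta: pd.DataFrame, cfg: GeneratorConfig,
                          rng: np.random.Generator | int = 3,
                          ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Reporter-library IP/input counts.

    ``meta`` needs a ``pair_id`` column (one row per designed pair).  The
    reporter context is unprotected, so every experimental molecule is
    methylated with probability p_open and carries expected IP propensity
    1 + (ip_gain - 1) * p_open; control oligos are never methylated.
    Replicates are independent.  Returns the long counts table and the
    per-oligo truth table.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) \
        else rng
    params = cfg.params
    pair_ids = meta["pair_id"].tolist()
    n = len(pair_ids)
    mu = rng.lognormal(0.0, cfg.oligo_abundance_sdlog, size=2 * n)
    # interleave experimental/control per pair
    roles = np.tile(["experimental", "control"], n)
    ids = np.repeat(pair_ids, 2)
    p_meth = np.where(roles == "experimental", params.p_open, 0.0)
    gain = 1.0 + (cfg.ip_gain - 1.0) * p_meth
    rows = []
    for r in range(1, cfg.replicates_oligo + 1):
        c_in, c_ip = _matched_counts(mu, gain, cfg.depth_oligo,
                                     cfg.dispersion, rng)
        for frac, counts in (("input", c_in), ("ip", c_ip)):
            rows.append(pd.DataFrame({
                "pair_id": ids, "role": roles, "replicate": r,
                "fraction": frac, "count": counts}))
    truth = pd.DataFrame({"pair_id": ids, "role": roles, "p_meth": p_meth,
                          "ip_propensity": gain})
    return pd.concat(rows, ignore_index=True), truth


def tile_regions(models: dict[str, TranscriptModel],
                 window: int = 100) -> pd.DataFrame:
    """Fixed windows tiled over each transcript (stride = window).

    Genomic columns give the region's spanning interval (min/max over the
    exonic pieces of the transcript window).
    """
    rows = []
    for tid in sorted(models):
        t = models[tid]
        for ts in range(0, t.length, window):
            te = min(ts + window, t.length)
            pieces = t.transcript_interval_to_genomic(ts, te)
            rows.append({"region_id": f"{tid}:{ts}-{te}", "transcript_id": tid,
                         "tstart": ts, "tend": te, "chrom": t.chrom,
                         "start": pieces[0][0], "end": pieces[-1][1],
                         "strand": t.strand})
    return pd.DataFrame(rows)


def region_truth(regions: pd.DataFrame, truth_sites: pd.DataFrame,
                 cfg: GeneratorConfig,
                 expression: pd.Series | None = None,
                 rng: np.random.Generator | int = 4) -> pd.DataFrame:
    """Per-region methylated-site fractions and expected log2 fold change.

    The methylated fraction under each condition is the mean realized truth
    state of the DRACH sites inside the region (0 for DRACH-free regions);
    expected IP gain is 1 + (ip_gain - 1) * fraction.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) \
        else rng
    out = regions.copy()
    frac_ctl = np.zeros(len(out))
    frac_kd = np.zeros(len(out))
    n_sites = np.zeros(len(out), dtype=int)
    grouped = {tid: grp for tid, grp in truth_sites.groupby("transcript_id")}
    for i, rec in enumerate(out.itertuples(index=False)):
        grp = grouped.get(rec.transcript_id)
        if grp is None:
            continue
        inside = grp[(grp["pos"] >= rec.tstart) & (grp["pos"] < rec.tend)]
        n_sites[i] = len(inside)
        if len(inside):
            frac_ctl[i] = inside["meth_ctl"].mean()
            frac_kd[i] = inside["meth_kd"].mean()
    out["n_sites"] = n_sites
    out["frac_ctl"] = frac_ctl
    out["frac_kd"] = frac_kd
    g_ctl = 1.0 + (cfg.ip_gain - 1.0) * frac_ctl
    g_kd = 1.0 + (cfg.ip_gain - 1.0) * frac_kd
    out["truth_log2fc"] = np.log2(g_kd / g_ctl)
    if expression is None:
        expr = pd.Series(
            rng.lognormal(0.0, cfg.expression_sdlog, size=len({*out["transcript_id"]})),
            index=sorted({*out["transcript_id"]}))
    else:
        expr = expression
    out["expression"] = out["transcript_id"].map(expr)
    return out


def simulate_region_counts(regions: pd.DataFrame, cfg: GeneratorConfig,
                           rng: np.random.Generator | int = 5) -> pd.DataFrame:
    """Long IP/input count table per region under ctl and kd conditions.

    ``regions`` must carry ``frac_ctl``, ``frac_kd`` and ``expression``
    (from :func:`region_truth`).  Counts follow the matched Gamma-Poisson
    model per (region, replicate, condition).
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) \
        else rng
    mu = regions["expression"].to_numpy() * \
        (regions["tend"] - regions["tstart"]).to_numpy() / cfg.region_window
    gains = {"ctl": 1.0 + (cfg.ip_gain - 1.0) * regions["frac_ctl"].to_numpy(),
             "kd": 1.0 + (cfg.ip_gain - 1.0) * regions["frac_kd"].to_numpy()}
    ids = regions["region_id"].to_numpy()
    rows = []
    for cond in ("ctl", "kd"):
        for r in range(1, cfg.replicates_region + 1):
            c_in, c_ip = _matched_counts(mu, gains[cond], cfg.depth_region,
                                         cfg.dispersion, rng)
            for frac, counts in (("input", c_in), ("ip", c_ip)):
                rows.append(pd.DataFrame({
                    "region_id": ids, "replicate": r, "condition": cond,
                    "fraction": frac, "count": counts}))
    return pd.concat(rows, ignore_index=True)


def control_peaks(regions_with_truth: pd.DataFrame,
                  min_fraction: float = 0.5) -> pd.DataFrame:
    """Truth m6A peak set under the control condition.

    A tiled region counts as a peak when at least half of its DRACH sites
    are methylated in the control context (half-maximal stoichiometry, the
    truth analogue of a called MeRIP peak) and it contains at least one
    site.  Returned as a BED-like table.
    """
    sel = regions_with_truth[(regions_with_truth["n_sites"] > 0) &
                             (regions_with_truth["frac_ctl"] >= min_fraction)]
    return sel[["chrom", "start", "end", "region_id", "strand"]].reset_index(drop=True)


def provenance(cfg: GeneratorConfig) -> dict:
    """YAML-serializable record of the generator configuration."""
    d = asdict(cfg)
    d["ejc_params"] = asdict(cfg.params)
    return d
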