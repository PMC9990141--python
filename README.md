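# m6asupp

Analysis toolkit for studying **suppression of m⁶A deposition by exon
junction complexes (EJCs)** — for epitranscriptomics researchers who work
with m⁶A reporter assays, MeRIP-seq differential methylation, and
exon-architecture statistics.

N⁶-methyladenosine (m⁶A) is installed by METTL3–METTL14 in DRACH motifs
(D = A/G/U, R = A/G, then the methylated A, C, H = A/C/U), yet only a small
fraction of DRACH sites are methylated, with strong enrichment in long
internal exons and near stop codons. The mechanistic hypothesis this
package implements and tests is *suppression*: EJCs, deposited ~24 nt
upstream of every exon–exon junction, package proximal RNA and block the
methyltransferase, so methylation survives only where sites are far from
junctions.

## The model

A DRACH site at distance *d* (nt) from the nearest EJC is methylated with
probability

```
P(meth | d)   = p_floor + (p_open − p_floor) · (1 − π(d))
π(d)          = 1 / (1 + exp((d − d₀)/k))            (logistic protection)
P(meth | no EJC) = p_open
```

with `p_open` the unprotected (reporter / EJC-knockdown) methylation
probability, `p_floor` the residual probability under full protection,
`d₀` the protection half-range and `k` its steepness. For a site centered
in an internal exon of length *L* with both junctions spliced, the two
flanking protections combine as independent events,
`π₂ = 1 − (1 − π)(1 − π)` with `d = max(0, L/2 − 24)`. The predicted
*suppression ratio* `P(meth | L) / p_open` is calibrated so a 102-nt
internal exon is strongly suppressed and exons ≥ 476 nt are not.

Around this model the package provides:

- **annotation** — GTF transcript models, transcript↔genome coordinate
  maps, exon classes, splice-site distances, metagene coordinates
  (5′UTR/CDS/3′UTR → [0,3)), EJC positions and distances, EJC density
  (CDS exons per kb), internal-exon length percentiles;
- **oligo** — DRACH scanning, 102-nt reporter windows (51 up / 50 down),
  DRACH-knockout negative controls (central A→G, iterated to fixpoint);
- **reporter** — CPM normalization, enrichment scores
  (experimental IP/input − control IP/input), spike-in normalization,
  one-sided paired tests with Benjamini–Hochberg FDR, and site classes
  (confirmed / suppressed / context-dependent / inert);
- **diffmeth** — region-level log₂ fold changes, a replicate-stratified
  Cochran–Mantel–Haenszel test, hyper/hypo calls (FDR < 0.1, |log₂FC| > 1),
  overlap with control peaks ("novel" regions), architecture profiles;
- **ejc_model** — the protection model: likelihood fitting with
  observed-information standard errors, reporter-series prediction,
  calibration, knockdown simulation;
- **association** — Fisher colocalization with odds-ratio CIs, Pearson and
  rank-binned correlations, EJC density vs transcript outcomes;
- **simulate** — a seeded generator for transcriptomes (short-body /
  long-tail internal exon lengths), planted DRACH sites, truth methylation
  states, and overdispersed IP/input counts for oligos and regions.

## Worked example

```python
from m6asupp import GeneratorConfig, default_params, predict_reporter_series
from m6asupp.signatures import run_study, signature_report

params = default_params()
print(f"protection half-range d0 = {params.d0:.1f} nt, steepness k = {params.k:.1f} nt")
for L, r in zip((102, 238, 476, 912),
                predict_reporter_series((102, 238, 476, 912), params)):
    print(f"exon {L:4d} nt: suppression ratio {r:.3f}")

bundle = run_study(GeneratorConfig(seed=11))   # full synthetic study
rep = signature_report(bundle)
print(f"reporter call rate, endogenously methylated:   {rep['reporter']['rate_methylated']:.1%}")
print(f"reporter call rate, endogenously unmethylated: {rep['reporter']['rate_unmethylated']:.1%}")
print(f"hypermethylated regions: {rep['n_hyper']} (hypo: {rep['n_hypo']})")
print(f"enrichment in short internal exons: OR = {rep['hyper_short_exon_or']:.1f}")
print(f"novel (no control-peak overlap): {1 - rep['hyper_peak_overlap_fraction']:.1%}")
```

prints

```
protection half-range d0 = 92.8 nt, steepness k = 41.9 nt
exon  102 nt: suppression ratio 0.050
exon  238 nt: suppression ratio 0.279
exon  476 nt: suppression ratio 0.900
exon  912 nt: suppression ratio 0.999
reporter call rate, endogenously methylated:   100.0%
reporter call rate, endogenously unmethylated: 100.0%
hypermethylated regions: 2078 (hypo: 112)
enrichment in short internal exons: OR = 13.4
novel (no control-peak overlap): 99.8%
```

Reading the output: a site centered in a 102-nt internal exon keeps only 5%
of its unprotected methylation probability, and suppression is essentially
gone by 476 nt. In the synthetic study the intronless reporter context
methylates endogenously *unmethylated* sites as readily as methylated ones
(both ~100% of designed pairs are called), simulated EJC-factor knockdown
produces thousands of hypermethylated regions that concentrate in short
(< 246 nt) internal exons, and almost none of them overlap m⁶A peaks of the
control condition — the signature of sites that were suppressed, not absent.

A `m6asupp` command-line tool exposes the same pipeline as subcommands
(`simulate`, `design`, `score`, `diffmeth`, `annotate`, `fit-model`,
`coloc`, `report`), each writing a run manifest with config, seed and input
checksums.

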