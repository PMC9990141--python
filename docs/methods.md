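# Methods

## The protection model

The package's core is a generative model of m⁶A deposition as a
distance-dependent competition between the methyltransferase and EJC-made
mRNP packaging. Each DRACH site carries a latent uniform draw *u*; in a
context with protection strength π the site is methylated iff
*u* < p_floor + (p_open − p_floor)(1 − π). Assumptions:

- **Monotone, smooth protection.** π(d) decreases smoothly with distance
  *d* to the nearest EJC. The logistic kernel
  π(d) = 1/(1 + e^{(d−d₀)/k}) is used by default (an exponential
  half-range kernel is available via `kernel="exponential"`); both are
  two-parameter, monotone and identifiable from binary outcomes.
- **Nearest-EJC protection for transcript sites; independent combination
  for the centered reporter construct.** For sites on annotated
  transcripts only the nearest EJC is considered. For the reporter
  exon-length series — a site centered in an internal exon with both
  junctions spliced — the two flanking protections combine as independent
  events (complement product). Whether flanking EJCs act independently or
  cooperatively is not determined by available evidence; independence is
  the minimal assumption and the combination rule is exposed
  (`combine="independent" | "nearest"`).
- **Suppression, not demethylation.** The knockdown context never
  demethylates: the shared-uniform construction makes the knockdown
  methylation set a superset of the control set at every site.
- **Residual suppression.** EJC-factor depletion does not fully restore
  methylation; the model represents all non-EJC suppression by the single
  floor parameter p_floor rather than mechanistically.

### Parameters

| parameter | units | default | rationale |
|-----------|-------|---------|-----------|
| `p_open`  | probability | 0.95 | roughly nine of ten endogenously unmethylated DRACH sites methylate once moved into an unprotected reporter context, so the unprotected probability must be ≈0.9–0.95 |
| `p_floor` | probability | 0.02 | small nonzero residual: knockdown does not completely restore methylation |
| `d0`      | nt    | ≈92.8 (calibrated) | protection half-range |
| `k`       | nt    | ≈41.9 (calibrated) | logistic steepness |
| `ejc_offset` | nt | 24   | EJC deposition ~24 nt upstream of junctions |
| `last_exon_proximal` | nt | 150 | the m⁶A density peak near stop codons corresponds to enrichment within 150 nt past last-exon starts |

(d₀, k) are not fitted to data; they come from `ejc_model.calibrate`,
a least-squares match of the predicted reporter series to two anchor
behaviors: suppression ratio 0.05 at exon length 102 nt and 0.90 at
476 nt (a 102-nt internal exon is strongly suppressed; ≥476 nt exons are
not). The anchors encode qualitative reporter behavior, so the calibration
is labeled heuristic. The 476-nt boundary derives from a single reporter
series in one locus and is treated as a calibration anchor, not a
universal constant.

### Fitting

`ejc_model.fit` maximizes the Bernoulli likelihood over
(p_open, p_floor, d₀, k) with L-BFGS-B inside the box
p_open ∈ [10⁻³, 1−10⁻³], p_floor ∈ [10⁻⁶, 0.5], d₀ ∈ [1, 2000],
k ∈ [1, 500], with p_floor < p_open enforced by penalty. Eight starts (one
fixed, seven spread deterministically over the box) guard against local
optima. Standard errors are observed-information: the finite-difference
Hessian of the negative log-likelihood at the optimum, inverted; singular
information is flagged rather than hidden. Degenerate data are handled
explicitly: with no protected observations the model reduces to
p_open = sample frequency and d₀/k are flagged unidentifiable; data with
no methylated sites produce a boundary warning.

## Reporter scoring

Counts are normalized to counts-per-million within each
(replicate, fraction) library; a pseudocount of 0.5 reads is added before
ratio formation so zero counts yield finite ratios. The enrichment score is
reported on the ratio-difference scale, (experimental IP/input) −
(control IP/input), while significance testing operates on per-replicate
log₂(IP/input) differences for variance stability — both are emitted. The
default test is a one-sided paired t-test (experimental > control) with
Benjamini–Hochberg FDR across the library; a Wilcoxon signed-rank
alternative is selectable (`test="wilcoxon"`). Zero-variance rows are
resolved by rule: a constant positive difference gets the machine-minimum
p-value (perfect separation), constant zero or negative differences get
p = 1. A call requires FDR < α (default 0.05) *and* positive mean score.
Which QC filter the original assay applied to designed pairs is unknown;
any input-depth filtering here is the package's own and configurable.

## Differential methylation

The unit of analysis is a caller-supplied region set (the generator tiles
transcripts at 100-nt windows); de novo peak calling from coverage is out
of scope. The methylation fold change is
log₂[(Σ ip_kd/Σ input_kd)/(Σ ip_ctl/Σ input_ctl)] on CPM-normalized,
pseudocounted counts summed over replicates. Significance uses a
replicate-stratified Cochran–Mantel–Haenszel statistic on the 2×2
(fraction × condition) table per replicate, with continuity correction.
One deliberate numerical choice: the per-stratum variance uses the
unconditional form r₁r₂c₁c₂/N³ rather than the classical hypergeometric
r₁r₂c₁c₂/(N²(N−1)), so that the single-stratum statistic reduces *exactly*
to the Yates-corrected 2×2 chi-square; for the replicate-sized strata in
this application the two differ by the factor (N−1)/N ≈ 1 and the variant
is marginally conservative. A Fisher test on replicate-summed counts is
available as a pooled fallback. Calls follow fixed thresholds
(FDR < 0.1 and |log₂FC| > 1); "novel" means no ≥1-nt overlap with any
control-condition peak (half-open intervals, so touching is not
overlapping). Regions map to architecture via their midpoint — a
deterministic, strand-safe rule.

## Coordinates and architecture conventions

All internal coordinates are 0-based half-open; GTF input/output converts
to/from 1-based closed; BED stays 0-based half-open. Exons are ordered
5′→3′ in transcript orientation. "Internal exon" means neither first nor
last; for length statistics, exons shared across transcripts are
deduplicated by genomic interval to avoid isoform-weighted bias. EJC
positions are junction − 24 nt, clamped to the upstream exon start for
exons shorter than the offset. The metagene maps 5′UTR, CDS and 3′UTR each
linearly onto a unit segment of [0,3), 100 bins per segment,
area-normalized per region set; a site exactly at the CDS start maps to
1.0 and at the CDS end (first base after the stop) to 2.0 — boundary
assignments are arbitrary but fixed. Splice-site distances are reported
only where the corresponding exon boundary is a junction (absent for the
5′ edge of first exons and the 3′ edge of last exons). Isoform-aware site
assignment is out of scope: each site belongs to one caller-specified
transcript.

## Oligo design conventions

Windows are 102 nt with the central A at offset 51 (51 upstream, 50
downstream), shifted — never padded — at transcript ends so every oligo is
a real subsequence. Knockout substitutes every DRACH central A with G
simultaneously and iterates to a fixpoint: A→G preserves purine content,
provably cannot re-create a motif centered at the substituted position,
and each pass strictly decreases the A count, guaranteeing termination.
Whether the original assay mutated all motif bases or only the central A
is not documented; central-A substitution is the fixed choice here. Inputs
may be DNA- or RNA-alphabet (T→U internally); FASTA output uses the DNA
alphabet, matching synthesis practice.

## The synthetic-data generator

The generator emulates the features of the real study that the pipeline's
statistics depend on:

- **Exon architecture.** Internal exon lengths follow a log-normal body
  (median ≈110 nt, σ_log = 0.42) with a 6% heavy log-normal tail
  (median ≈1200 nt), reproducing the short-body/long-tail shape with
  10th/90th percentiles near 60/246 nt. Last exons are long
  (log-normal, median ≈700 nt) and the CDS ends 10–200 nt past the
  last-exon start, putting stop codons where they belong. One transcript
  per gene, 4–9 exons, alternating strands on one synthetic chromosome.
- **Sites and truth.** DRACH 5-mers are planted at 2/kb (plus chance
  background motifs ≈1.8% of offsets); the site list is exactly the
  scanner's output. Truth methylation uses the protection model with a
  shared uniform per site coupling control and knockdown states. With the
  default parameters the control-context methylation rate of
  junction-proximal sites lands near 5%, consistent with the observation
  that only a small fraction of DRACH sites are selected for methylation.
- **Counts.** Overdispersion is realized as a shared Gamma(1/φ, φ·μ)
  abundance per (unit, replicate, condition) with Poisson input and IP
  reads given the abundance — marginally negative binomial with
  dispersion φ = 0.1, while the abundance cancels in the IP/input odds
  ratio, as in a matched input/IP library preparation. This matched
  structure is what makes the CMH test calibrated on the generator's own
  null. IP means are scaled by 1 + (ip_gain − 1)·(methylated fraction)
  with ip_gain = 8 (an 8-fold IP enrichment of methylated molecules).
  Reporter oligos live in an intronless context: every experimental
  molecule methylates at p_open, controls never; replicates are
  independent. Default depths: 10⁶ reads per oligo library
  (4 replicates), 2×10⁶ per region library (3 replicates).

What the generator does **not** emulate — and hence what passing tests do
not show about real data: alternative isoforms and isoform-specific EJC
positioning; non-uniform base composition, GC or mappability structure;
fragment-level effects of immunoprecipitation (fragmentation, antibody
bias, peak shape); between-replicate batch effects beyond abundance noise;
site-level heterogeneity of intrinsic methylatability beyond EJC
protection (every DRACH shares one p_open); and any sequence determinant
of methylation other than the motif itself.

## Problem sizes

The default synthetic study uses 500 genes (≈19,000 DRACH sites, ≈10,000
tiled regions, a 900-pair reporter library), sizes at which every
statistical property under test is comfortably resolved while a complete
study runs in seconds. Calibration checks use 1,000 null units; parameter
recovery uses 5,000 observations; oracle-equivalence checks enumerate
10,000 random 60-mers, 1,000 knockout windows, and all 2×2 tables with
total count ≤ 30.

## Known limitations

- The protection kernel's functional form is a modeling choice; only its
  monotonicity and approximate range are constrained by the anchors.
- The CMH test treats counts as conditionally multinomial given the
  matched abundance; overdispersion that hits IP and input *differently*
  (e.g. IP-specific efficiency noise) would inflate its type-I error and
  is deliberately pushed into the fold-change filter.
- Fisher colocalization requires the caller to define the site universe
  explicitly (all DRACH sites, all tested regions, …); the default
  100-nt window is a convention, not an estimate.
- `p_floor` is a phenomenological stand-in for all non-EJC suppression;
  the model cannot attribute residual suppression to a mechanism.
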