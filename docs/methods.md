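# Methods

This note documents the models behind each stage, the defaults and why they
were chosen, what the synthetic generator does and does not emulate, and the
numerical decisions a maintainer would want to know.

## 1. Differential histone-mark enrichment

**Signal.** The per-gene signal is the arithmetic mean of replicate pile-up
values per condition (three biological replicates by default). The signed
fold enrichment is `r = mean(grafted)/mean(control)` reported as `+r` for
gains and `−1/r` for losses, so its magnitude is always ≥ 1 and a zero
difference maps to +1. Signs encode direction of change, not the identity of
the mark: a +4.3 on the repressive mark is still a *gain* (hyper).

**Null model and p-values.** Fold-change distributions of ChIP pile-ups are
approximately lognormal, so the log2 ratios of unaffected genes form an
approximately normal bulk with genuine effects in the tails. The null is
fitted robustly — median centre and MAD-scaled spread — over *all* genes, so
up to ~25% planted/true effects do not bias it. P-values are two-sided
normal tails; a p below α = 0.001 together with |signed fold| ≥ 2 yields the
hyper/hypo call. No multiple-testing correction is applied: the reference
procedure thresholds raw per-gene p-values, and α is exposed as a parameter.
Fewer than 50 genes is rejected (the null fit needs mass); identical ratios
raise a degenerate-null error rather than emitting p-values from a
zero-spread fit.

**Pseudocount.** A pseudocount (default 1.0) is added to *both* condition
means only when one of them is zero. Adding it unconditionally would distort
every ratio (10 → 21 would no longer be 2.1); adding it conditionally keeps
ordinary values exact, keeps all-zero genes finite, and preserves exact
scale invariance for positive data.

**Metagene profile.** Per-gene binned tracks (10 flank + 40 body + 10 flank
bins by default) are reversed for minus-strand genes, per-segment rescaled by
midpoint linear interpolation when bin counts differ, and averaged across
genes. The promoter-associated mark is expected to peak near the 5' end of
the body; the Polycomb-associated mark to be uniform across the body.

## 2. Conversion-as-variant methylation calling

Under bisulfite/EM-seq chemistry an unmethylated cytosine is read as
thymine on its own strand; minus-strand cytosines are kept in the
plus-strand frame (reference G, observed G when methylated / A when
unmethylated). The caller:

1. pools replicate base counts per site per condition (the libraries being
   emulated pooled three biological replicates; a per-replicate concordance
   mode was considered and rejected as under-determined at 20× depth);
2. takes the consensus allele when pooled depth ≥ 5 and the modal base
   fraction ≥ 0.9 — explicit stand-ins, since the reference procedure
   delegates variant filtering to external tools; ambiguous and
   uninformative sites are skipped, not errors (the design compares one
   cultivar against itself, so non-chemistry alleles carry no signal);
3. decodes alleles to methylation states and calls a DMP when the state
   differs between conditions: loss in grafted = hypo, gain = hyper;
4. annotates CG/CHG/CHH context from the two bases 3' of the cytosine on its
   own strand (H = any base other than G); truncated neighbourhoods are NA.

**DMG aggregation** counts hyper and hypo DMPs inside each annotated gene
body (optional flank, default 0 bp — the reference analysis says only "gene
regions", so promoter inclusion is a flag). A gene qualifies at threshold k
when either direction reaches k (default 1; 5 reproduces the stricter
selection used for term-enrichment input). Whether the stricter "|DMPs| > 5"
selection means per-direction or net counts is not derivable from the
source; the default is per-direction with a `mode="net"` alternative.
Summary strings are `+11`, `−2`, or `1 / -2` when both directions occur.

## 3. Expression classification and integration

RPKM is `count·10⁹/(length·library_total)` with per-sample totals. DEG
classes use the grafted/control RPKM ratio with an **inclusive** 2× cut —
forced by a published worked example in which a ratio of exactly 2.0
(1.9 → 3.8) is labelled "Up". The RPKM > 10 expression floor is applied to
the gene's maximum RPKM across all samples of the comparison context
(a strict per-pair floor would discard genes that are silent at one
timepoint but well expressed at the other); genes failing it are `filtered`.
A pseudocount of 0.01 enters only when the control RPKM is exactly zero.

Classification is by fold change alone — no count-based test — mirroring the
procedure being modelled. Consequently, single pooled libraries with
negative-binomial noise produce false DEG calls at realistic dispersion;
recovery of planted labels is exact only on noise-free counts, and the
scorer treats this honestly (see §5).

Mark grouping: active = {K4 hyper, DNA hypo, K27 hypo}, inactive =
{K4 hypo, DNA hyper, K27 hyper}; a gene with DMPs in both directions joins
both groups. Venn counts are exclusive region counts over 2–3 named sets and
always partition the union. Term enrichment is the one-sided hypergeometric
over-representation test per term over a user-supplied gene→term map, raw
p < 0.05 by default (no correction, matching the reference analysis; BH is a
caller-side option via `statsmodels` if needed). The gene-ontology database
itself is out of scope.

## 4. Phenotype statistics

* **2^−ΔCt**: single-delta form, ΔCt = Ct_target − Ct_reference against a
  housekeeping rRNA channel. It is strictly decreasing in Ct_target and
  halves per added cycle.
* **Exact Mann–Whitney**: all C(n, n_a) assignments of the pooled midranks
  are enumerated (n ≤ 12), giving exact p-values with or without ties. With
  3 vs 3 the two-sided floor is p = 0.1 — below any conventional α — so the
  qPCR summary reports the exact p *and* a Welch t-test side by side rather
  than picking one.
* **Survival**: recovery from the apical meristem or an axillary bud counts
  as survival; rates display as whole percents rounded half-up (9/16 =
  56.25 → "56%").
* **Chi-square**: Pearson on the 2×2 survivors/non-survivors table,
  continuity correction **off** by default — with Yates the 6/30-vs-0/30
  comparison would not reach p < 0.01, contradicting the annotated result of
  the design being reproduced; the correction is a flag. Zero marginals are
  an error, not a silent p = 1.

## 5. Synthetic data: what it emulates, and what a green test proves

The generator writes a single linear chromosome with evenly spaced,
strand-alternating gene models; every downstream input; and truth tables
sufficient to score each caller. Defaults state the emulated world:

| parameter | default | rationale |
| --- | --- | --- |
| n_replicates | 3 | three biological replicates per condition |
| chip_effect_fold | 3 | planted effects must clear the 2× call threshold |
| chip_noise_cv | 0.2 | typical replicate CV of ChIP pile-ups |
| chip_base_mean/sigma | 50 / 0.5 | lognormal per-gene baseline |
| frac_hyper / frac_hypo | 0.025 / 0.005 | gains dominate losses, sparse tails |
| methylation_rate | 0.3 | single prior blending high-CG/low-CHH plant contexts |
| dmp_rate | 0.002 | sparse state flips between conditions |
| depth_mean | 20 | Poisson per-replicate site depth (unstated upstream; explicit stand-in) |
| error_rate | 0 (0.01 in acceptance runs) | per-read uniform miscall |
| deg_fold | 4 | twice the 2× cut so NB noise does not straddle the threshold |
| nb_dispersion | 0.1 | typical biological overdispersion |
| gc_fraction | 0.38 | tomato-like genomic GC |
| cohort sizes / survival | 30:0.2, 16:0.5625, 30:0, 30:0 | the emulated drought-recovery experiment |

Noise models are the simplest with the right overdispersion: lognormal
pile-ups (mean-preserving, so CV 0 gives exact planted folds), Poisson
depth, gamma-Poisson (negative binomial) counts, Bernoulli survival.

Not emulated: read-level data (FASTQ/alignment), mappability and coverage
biases, context-dependent methylation priors, linked/correlated sites,
partial methylation (states are binary), batch effects, and library-size
confounding beyond what per-sample totals induce. A green recovery test
therefore establishes that the *decision logic* is correct and calibrated
under the stated noise models — not that the thresholds would achieve the
same operating point on real sequencing data.

## 6. Numerical and interface decisions

* Internal coordinates are 0-based half-open; GFF3 is written/read 1-based
  inclusive; site tables carry 1-based positions.
* All tabular outputs are single-header TSV with `%.6g` floats, making
  identically configured runs byte-identical (tested).
* Exact-threshold comparisons (ratio ≥ 2) use a 1e-12 relative guard against
  binary-representation jitter.
* The run manifest records seed, thresholds and per-stage row counts, and
  contains no timestamps; changing any threshold changes the manifest.
* `scipy` provides the normal/chi-square/hypergeometric distributions and
  the contingency-table statistic; the enumeration Mann–Whitney, the
  conversion-chemistry decoder, the signed-fold statistic and the robust
  null are implemented here and cross-checked against independent oracles
  (exhaustive combinatorics, `scipy.stats.mannwhitneyu(method="exact")`,
  closed-form chi-square) in the test suite.

## 7. Known limitations

* The robust normal null is an approximation for ratios of lognormal means;
  its extreme tails (beyond |z| ≈ 4) are not calibrated, which is acceptable
  at α = 0.001 (verified by simulation) but should not be pushed to
  genome-wide-significance regimes.
* Fold-change-only DEG classification has no error control; treat DEG lists
  from noisy counts as candidate sets.
* The exact Mann–Whitney is limited to total n ≤ 12 by design; larger
  designs should use the normal approximation in `scipy` directly.
* DMP calling assumes near-homozygous material; heterozygous sites surface
  as ambiguous consensus and are silently skipped (by design, logged counts
  in the outputs).
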