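# graftomics

Grafting a plant — even onto its own severed stem — triggers a wound-healing
programme that can leave lasting epigenetic traces in the scion and alter how
it responds to later stress. `graftomics` implements the analysis chain used
to characterise such grafted-vs-control experiments in tomato-style designs:

* **differential histone-mark enrichment** (H3K4me3, H3K27me3) from per-gene
  ChIP pile-up values with three biological replicates per condition;
* **conversion-as-variant DNA-methylation calling**: under bisulfite/EM-seq
  chemistry an unmethylated cytosine reads as T on its own strand (G→A on the
  opposite strand), so a site whose consensus allele changes between
  conditions is a differentially methylated position (DMP), annotated with
  its CG/CHG/CHH context and aggregated to differentially methylated genes
  (DMGs);
* **expression classification and integration**: RPKM normalisation,
  fold-change DEG classes, active/inactive mark grouping, Venn region counts,
  mark × DEG cross-tabulation, a per-gene integrated report, and
  hypergeometric term enrichment;
* **phenotype statistics**: 2^−ΔCt qPCR relative expression, exact
  Mann–Whitney tests for 3-vs-3 designs, cohort survival rates and 2×2
  chi-square tests;
* a **synthetic-data generator** that plants known truth (effect genes,
  methylation flips, DEGs, survival probabilities) so every stage can be
  scored for precision and recall without access to sequencing data.

## Core quantities

For a gene with replicate pile-ups, the signed fold enrichment is

    r = mean(grafted) / mean(control),    signed = +r if r ≥ 1 else −1/r

so +2.1 is a 2.1× gain in grafted, −2.0 a 2× loss. P-values come from a
robust normal null fitted to log2 ratios over all genes (median centre,
MAD spread); a gene is *hyper* when signed fold ≥ +2 with p < 0.001, *hypo*
when ≤ −2 with p < 0.001.

A DMP at a cytosine site is called from consensus alleles
(pooled depth ≥ 5, modal fraction ≥ 0.9):

    control C/G  and  grafted T/A  →  hypo   (methylation lost by grafting)
    control T/A  and  grafted C/G  →  hyper  (methylation gained)

Expression classes use `RPKM = count · 10⁹ / (length · library_total)` and an
inclusive 2× rule: up when grafted/control ≥ 2, down when ≤ 1/2, else nc,
with genes below an RPKM floor of 10 (max across the compared samples)
reported as `filtered`.

## Worked example

```python
>>> from graftomics import chip, methylome, phenotype as ph, expression as ex
>>> chip.fold_enrichment([10, 10, 10], [21, 21, 21])
2.1
>>> chip.classify_enrichment(2.1, 1e-4)
'hyper'
>>> ex.classify_deg(20.5, 46.4)          # 2.26x increase
'up'
>>> ph.survival_rate(16, 7, 2)           # 9 of 16 plants recovered
56.25
>>> ph.chi_square_2x2(6, 24, 9, 7)       # 20% vs 56% survival
(6.239677419354839, 0.012491922677110436)
>>> ph.mann_whitney_exact([1, 2, 3], [4, 5, 6])
(0.0, 0.1)
```

The fold enrichment of 2.1 means the grafted mean pile-up is 2.1× the
control mean; with p = 10⁻⁴ the gene is classified as hypermethylated by
grafting. The chi-square p ≈ 0.012 says the 20% vs 56% survival difference
would be surprising under independence. The exact Mann–Whitney p of 0.1 is
the *smallest* two-sided value attainable with 3 vs 3 replicates — which is
why the package reports a Welch t-test alongside it.

End-to-end on synthetic data (or via the `graftomics run-all` CLI):

```python
>>> from graftomics.config import RunConfig, SimConfig
>>> from graftomics.pipeline import run_all
>>> cfg = RunConfig(outdir="demo_run", sim=SimConfig(seed=1, error_rate=0.01))
>>> manifest = run_all(cfg)
```

which, for seed 1, recovers every planted ChIP effect and all 243 planted
methylation flips exactly (`demo_run/scores.tsv`):

```
        stage   label  tp  n_called  n_truth  precision  recall
 chip_H3K4me3   hyper   5         5        5        1.0       1
          dmp overall 243       243      243        1.0       1
          deg      up  10        20       10        0.5       1
```

DEG precision is deliberately imperfect here: classification is by fold
change alone (no count-based test), so negative-binomial noise in single
pooled libraries produces false calls — exactly the behaviour of the
procedure being modelled. On noise-free counts recovery is exact.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the entire pipeline from scratch on a seeded synthetic dataset
(simulation, enrichment, methylome, integration, phenotype statistics and
truth scoring) and writes the acceptance JSON to `--out`.

## Layout

| module | contents |
| --- | --- |
| `graftomics.simulate` | reference/GFF3 generation, planted truth, pile-ups, site tables, counts, qPCR, cohorts |
| `graftomics.chip` | fold enrichment, robust null, classification, metagene profiles |
| `graftomics.methylome` | consensus alleles, chemistry decoding, context, DMP/DMG calling |
| `graftomics.expression` | RPKM, DEG classes, mark groups, Venn, crosstab, report, term enrichment |
| `graftomics.phenotype` | 2^−ΔCt, exact Mann–Whitney, survival, chi-square |
| `graftomics.pipeline` / `graftomics.cli` | orchestration, manifest, scoring, `graftomics` CLI |

See `docs/methods.md` for the statistical models, defaults and limitations.
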