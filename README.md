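# popqtl

Ancestry-differentiated cis-eQTL discovery with downstream expression
and survival validation.

## The problem

Some diseases are markedly more prevalent in one ancestry than others
(ovarian clear-cell adenocarcinoma in the Japanese population is the
motivating case). One route to candidate susceptibility genes is a
multistep cis-eQTL funnel over a multi-ancestry reference panel:

1. **Variant QC** — drop SNPs with poor imputation accuracy
   (r² < 0.25), low minor allele frequency (MAF < 0.1), or
   Hardy–Weinberg disequilibrium (p < 10⁻⁴).
2. **Ancestry differentiation** — keep SNPs whose allele frequencies
   differ across populations (Pearson χ² on the 2×K allele-count table,
   df = K−1, p < 0.001) *and* are preferentially prevalent in the
   target ancestry (its alt-allele frequency is the strict extremum).
3. **cis association** — for each selected SNP, regress the expression
   of every gene within a genomic window (default 1 Mb to the nearer
   gene boundary; 500 kb available) on the additive dosage g ∈ {0,1,2}:
   y = α + βg + ε, with t = β̂/se(β̂) on n−2 df, and adjust all pairs of
   a run with Benjamini–Hochberg at FDR 0.05.

The surviving genes are then validated clinically: quantile
normalization, Wilcoxon rank-sum comparisons between histologies,
median-dichotomized Kaplan–Meier curves with the log-rank test, and Cox
proportional-hazards fits (Breslow ties, Newton–Raphson on the partial
likelihood).

Because the original panels (HapMap3, clinical cohorts, TCGA) cannot be
bundled, the package ships a synthetic-data generator with known ground
truth: Balding–Nichols population structure (per-SNP F_ST, one target
ancestry drifted hard at a minority of SNPs), additive cis effects on
expression, and exponential proportional-hazards survival. Every
pipeline stage is testable end-to-end against planted truth.

## Worked example

```python
from popqtl import (SimulationConfig, simulate_genotypes,
                    simulate_expression, run_funnel, FunnelConfig)

cfg = SimulationConfig(seed=7)   # 3 x 200 samples, 935 SNPs, 4 enriched in JPT
gm, panel, truth = simulate_genotypes(cfg)
em = simulate_expression(gm, cfg)
res = run_funnel(gm, panel, em, cfg.genome_map.genes,
                 FunnelConfig(target_population="JPT"))
print(res.report.to_frame().to_string(index=False))
```

```
             stage  count
candidate_genes_in      7
       snps_tested    935
   snps_passing_qc    890
 differential_snps    149
         cis_pairs    211
distinct_cis_genes      4
```

935 simulated SNPs enter; 890 clear QC; 149 are significantly
differentiated with a JPT-extremum frequency (the four planted SNPs
plus genuinely drifted background — background F_ST = 0.01 is
detectable at this sample size); 211 SNP–gene pairs fall within 1 Mb
and are regressed. The top associations:

```
    rsid       gene_id  distance      beta            p            q
rs000188 GENE_rs000188     30000  0.954492 7.842969e-62 1.654866e-59
rs000375 GENE_rs000375    120000  0.846180 1.933967e-40 2.040335e-38
```

Both are planted eQTLs (true β = 1) recovered with the right sign and
magnitude; all four planted SNPs are in the selected set for this seed.
The two planted genes placed 1.2–1.5 Mb from their SNPs fall outside
the window, demonstrating the window rule in both directions.

The package also carries the published coordinates of the four
ovarian-clear-cell susceptibility loci and their seven cis genes
(`popqtl.ovcca_example`); running the window rule on those printed rows
yields 8 pairs at 1 Mb (7 genes, 4 SNPs; rs4873815 sits 28,310 bp from
*ZNF707*) and 5 pairs at 500 kb.

A CLI mirrors the library: `popqtl simulate | qc | popdiff | pipeline |
survival | diffexp` (see `popqtl --help`).

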