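# cgimeth

Analysis toolkit for measuring **de novo DNA methyltransferase activity at
CpG islands (CGIs)** in cell-line experiments, for epigenomics researchers
working with reduced-representation bisulfite sequencing (RRBS), spike-in
ChIP-seq (ChIP-Rx) and demethylation/recovery time courses.

The package reimplements, as a tested reusable library, four bespoke
computations used to dissect which CGIs attract de novo methylation in
colorectal cancer cells:

1. **CGI methylation gain calling.** Per-CGI methylation is the
   coverage-weighted mean beta over contained CpGs (pooled methylated reads
   / pooled total reads), computed from CpGs with coverage ≥ 10 in all
   samples. A CGI gains methylation between conditions when a two-sided
   Fisher's exact test on the pooled counts survives Benjamini–Hochberg
   correction (q < 0.05) **and** the beta difference is ≥ 0.20.
2. **Re-methylation kinetics after 5-aza-2′-deoxycytidine.** Cells
   demethylated with 5-aza-dC recover methylation over ~3 weeks. If
   recovery reflected only the outgrowth of cells that escaped
   demethylation, trajectories normalised to day 0 would be identical
   across CGIs. The toolkit fits, by maximum likelihood over days 3–22,

   ```
   null:         m ~ t + (1 | CGI)           (random intercept)
   alternative:  m ~ t + (1 + t | CGI)       (random intercept + slope)
   ```

   and compares them with a likelihood-ratio test; per-CGI OLS slopes of
   the normalised trajectories are the fraction of day-0 methylation
   recovered per day, contrastable between groups (e.g. H3K36me3-marked
   vs other CGIs) with Wilcoxon rank-sum tests.
3. **Input-corrected spike-in ChIP normalisation.** Per-region signal is
   `[(c_ChIP + 0.5)·10⁷/total_ChIP] / [(c_input + 0.5)·10⁷/total_input]`;
   between-sample scaling uses the foreign-genome spike-in:
   `S_n = (dRPTM_ChIP-n / dRPTM_ChIP-ref) / (dRPTM_IN-n / dRPTM_IN-ref)`
   with dRPTM = spike-in reads per 10⁷ mapped reads. Decile ranking,
   Spearman association and a standardised linear model of one mark on
   others support occupancy analyses.
4. **CGI-mapped term enrichment.** CGIs map to genes (TSS > transcript >
   closest TSS, ties kept), gene annotations are closed over ontology
   ancestors, terms are tested one-sided with BH correction (terms with
   < 10 background CGIs excluded), and redundant significant terms are
   collapsed by Wang semantic similarity > 0.7, keeping the lowest-q term
   per group.

Every stage is exercisable without external data through the
`cgimeth.simulate` generators, which emit inputs with machine-readable
ground truth (per-CGI gainer flags and betas, true recovery slopes, true
scaling factors, planted enriched terms).

## Worked example

```python
from cgimeth import (MethSimConfig, simulate_cpg_counts, filter_cpgs,
                     cgi_weighted_methylation, call_methylation_gain,
                     KineticsSimConfig, simulate_timecourse,
                     normalise_timecourse, test_rate_heterogeneity)

# two-condition RRBS-like counts: 200 CGIs, 20% gain 0.5 methylation
sim = simulate_cpg_counts(MethSimConfig(n_cgis=200, gainer_fraction=0.2,
                                        gain_size=0.5, seed=1))
counts = filter_cpgs(sim.table_a.merge(sim.table_b, on=["chrom", "pos"]),
                     min_coverage=10)
meth = cgi_weighted_methylation(counts, sim.cgis)
calls = call_methylation_gain(meth[meth["sample"] == "A"],
                              meth[meth["sample"] == "B"])
print(f"{calls.is_gainer.sum()} of {len(calls)} CGIs gain methylation")

# recovery kinetics: is the rate genuinely heterogeneous across CGIs?
tc = simulate_timecourse(KineticsSimConfig(n_cgis=200, regime="heterogeneous",
                                           rate_sd=0.01, seed=1))
res = test_rate_heterogeneity(normalise_timecourse(tc.table))
print(f"LRT = {res.lr_statistic:.1f} (df={res.df_difference}), "
      f"p = {res.p_value:.3g} over {res.n_cgis} CGIs")
```

prints

```
40 of 200 CGIs gain methylation
LRT = 1586.4 (df=2), p = 0 over 200 CGIs
```

All 40 called CGIs are true simulated gainers (the configured 20% of 200),
and the likelihood-ratio statistic decisively rejects the outgrowth-only
null on data generated with per-CGI slope sd 0.01/day — exactly the
behaviour expected when de novo methyltransferase activity differs between
islands. On data generated under the outgrowth null the same test is
calibrated (rejection rate below the nominal 5%; the boundary chi-square
reference is conservative).

A command-line interface mirrors the library
(`cgimeth simulate|intervals|methylation|gain|kinetics|chip|enrich|run`);
`cgimeth run --seed 0 --outdir out/` executes the synthetic end-to-end
pipeline and writes TSV/JSON artifacts plus a reproducibility manifest.

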