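# tiletar

Expression calling, novel-transcript detection and comparative statistics
for whole-genome **tiling microarrays**, built around the analysis used to
identify maternally loaded transcripts in insect eggs (unfertilized vs
early fertilized eggs on a tiled two-color array).

## Who this is for

Tiling arrays interrogate a genome with overlapping probes (here 49–74 bp,
mean 54 bp, overlapping ~12 bp) rather than one probe per gene, so they can
detect transcription both inside annotated genes and in unannotated
intergenic regions. This package provides the complete analysis chain for
such data, plus a synthetic-data generator with planted ground truth so
every stage can be validated end to end without the original arrays.

## The method

1. **Normalization.** Each array channel is shifted additively (log2 scale)
   so that its mean over the *random probes* — address-less probes with
   genome-like (Markov-model) composition that measure pure background —
   equals the grand random-probe mean; then all channels are
   quantile-normalized. Replicates are summarized per probe and condition
   by the median.
2. **Empirical-null thresholding.** The detection threshold is the 99th
   percentile of the random-probe signal, so by construction only ~1% of
   null probes exceed it (a 1% false-positive rate). A probe is *positive*
   if its summarized value is strictly above the threshold.
3. **Gene expression calling.** A gene is *testable* if at least one probe
   overlaps its exons, and *expressed* if strictly more than 80% of its
   tiled exonic length is covered by positive probes. Its expression score
   is the median probe log2 signal over the random-probe background.
4. **TAR segmentation.** Positive probes are joined into transcriptionally
   active regions (TARs) when adjacent in the tiling with no intermittent
   non-positive probe (maxgap = 0) and a midpoint-to-midpoint span of at
   least 45 bp (minrun = 45, i.e. at least 3 adjacent positive probes).
   *Novel* TARs are those longer than 100 bp lying more than 100 bp from
   every annotated gene; TAR counts / 4.4 (the genome's mean exons per
   gene) estimates the number of novel genes they represent.
5. **Differential expression.** Per-replicate gene-level log2 fold changes
   (fertilized − unfertilized) are tested with a one-sample empirical-Bayes
   moderated t: s̃² = (d₀s₀² + d s²)/(d₀ + d), t̃ = mean/(s̃/√n) on d + d₀
   df, with (d₀, s₀²) fitted by method of moments on the log sample
   variances. Benjamini–Hochberg q-values and an inclusive two-fold rule
   classify genes as maternal-degraded, zygotic-activated or stable.
6. **Comparative statistics.** 1-df chi-squared goodness of fit for
   gene-list enrichment, the G-test for heterogeneity of expressed
   fractions across chromosomes, Kolmogorov–Smirnov for TAR size
   distributions, Pearson correlation of TAR counts with chromosome
   length, and the ortholog Group A/B/C classification (maternally
   expressed / fertilized-only / not expressed orthologs).

## Worked example

Run the whole pipeline on a simulated dataset (300 genes, 58.2% maternally
expressed, 12 planted intergenic TARs per condition):

```python
from tiletar.pipeline import PipelineConfig, run
from tiletar.synthetic_data import SimulationParams

cfg = PipelineConfig(
    params=SimulationParams(n_genes=300, n_random_probes=5000,
                            n_planted_tars=12, seed=4),
    seed=4, outdir="demo_run",
)
res = run(cfg)
print(res.compare.to_string(index=False))
```

prints

```
                             metric     value
         chromosome_heterogeneity_G  4.881896
        chromosome_heterogeneity_df  9.000000
         chromosome_heterogeneity_p  0.844480
                  maternal_fraction  0.580000
                  x_enrichment_chi2  1.872518
                     x_enrichment_p  0.171187
              novel_tars_fertilized 12.000000
             novel_genes_fertilized  2.000000
  tar_length_correlation_fertilized  0.683215
            novel_tars_unfertilized 12.000000
           novel_genes_unfertilized  2.000000
tar_length_correlation_unfertilized  0.555188
           unique_tars_unfertilized  6.000000
             unique_tars_fertilized  6.000000
                      tar_size_ks_k  0.250000
                      tar_size_ks_p  0.769483
                         n_de_genes 63.000000
                n_maternal_degraded 18.000000
                n_zygotic_activated 27.000000
```

Reading this: 58.0% of testable genes are called maternally expressed
(the generator planted 58.2%); expressed fractions are homogeneous across
the ten chromosomes (G-test p = 0.84, as expected — no enrichment was
planted); all 12 planted intergenic TARs per condition are recovered as
novel TARs, of which the 6 planted only in one condition are correctly
unique to it; and the two-fold/q < 0.1 classification finds the planted
degraded and zygotic-activated genes. Per-stage tables (`calls.tsv`,
`tars.bed`, `de.tsv`, `compare.tsv`, a run manifest) are written under
`demo_run/`.

The same stages are available from a shell:

```sh
tiletar simulate -o sim
tiletar normalize --matrix sim/matrix.tsv --design sim/design.tsv -o norm.tsv
tiletar call --matrix norm.tsv --design sim/design.tsv --annotation sim/annotation.gff3 -o calls
tiletar run-all -c config.yaml
```

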