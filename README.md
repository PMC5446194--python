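# methocc

DNA methylation context, MeCP2 chromatin occupancy, and the direction of
transcriptional mis-regulation — a tested, desk-scale re-implementation of
the analysis chain that links the three, exercised end-to-end on synthetic
data with planted ground truth.

MeCP2 is an abundant neuronal methyl-CpG-binding protein whose loss causes
Rett syndrome. Its genomic behaviour is unusual: ChIP coverage tracks the
Input (fragmented chromatin) profile almost everywhere, binding
concentrates on methylated CG dinucleotides and on the non-CpG
trinucleotide mCAC, occupancy is organised into broad domains rather than
sharp peaks, and knocking the protein out produces a *global* reduction of
RNA per cell that per-library normalisation cannot see. Each of those
observations needs a specific piece of statistical machinery, and this
package provides all of them as a reusable library for epigenomics
analysts:

- **`io_formats`** — FASTA, BED3/6/12, bedGraph, Bismark-style cytosine
  reports, gene-count tables; all internal coordinates 0-based half-open.
- **`meth_context`** — strand-aware cytosine context classification and the
  core methylation statistics. Per site, `m_i = mC / C` basecalls. Per
  region of length `L` with `N_CX` covered sites of context CX and mean
  level `m'_CX`, the **methylation density** is `N_CX · m'_CX / L`
  (reported per kb). Also BS−TAB resolution of 5mC vs 5hmC and spike-in
  (λ DNA) non-conversion estimation.
- **`occupancy`** — fragment binning with a configurable read shift, RPKM,
  `log2((ChIP+ψ)/(Input+ψ))` tracks, the linear Input-predictability model
  `ChIP ~ Input` with R², residual-based enriched/depleted window
  partitions, and the AT-flank binding-site comparison (runs of ≥4 A/T
  starting within ±13 bp of an isolated methylated site).
- **`summits_profiles`** — a simplified Poisson-local-background summit
  caller and anchored meta-profiles (summits ±4 kb at 20 bp, TSS ±100 kb
  at 1 kb, CGIs at 100 bp) with random-region negative controls.
- **`msr_domains`** — multiscale segmentation of the occupancy signal on a
  geometric smoothing ladder (100 bp × 2^s), signed enrichment scores,
  binomial significance, scale×score summaries, and methylation/GC
  annotation of every segment.
- **`expression_link`** — median-of-ratios size factors with a
  **global-scale correction** (the knockout's measured 15% RNA-per-cell
  reduction enters as a ×1.15 multiplier on KO size factors), a moderated
  negative-binomial Wald test, the up/down/unchanged/filtered gene
  classification (padj<0.05; padj>0.5 & |log2FC|<0.01; TPM<5), gene-level
  occupancy aggregation (body ± 100 kb), rolling-mean curves (400-gene
  windows, step 80), and occupancy–expression correlation statistics.
- **`synthetic_data`** — the generative model all tests run against:
  CG-depleted genomes with unmethylated CGIs on an isochore-like GC
  landscape, ~0.8 mCG outside islands, domain-structured mCAC, GC-biased
  Input with ChIP coupled to combined mCG+mCAC density, and NB expression
  counts whose KO fold-changes couple to occupancy on top of a global 0.85
  scale — with every planted parameter recorded for recovery tests.

## Worked example

```python
import pandas as pd
from methocc import SimConfig, simulate_all
from methocc.occupancy import bin_coverage, log2_ratio, fit_input_model, partition_outliers
from methocc.expression_link import (size_factors, apply_global_scale, nb_test,
                                     classify_genes, tpm_matrix, gene_occupancy,
                                     occupancy_expression_stats)
from methocc.synthetic_data import condition_labels

cfg = SimConfig(seed=1)                      # 2 chromosomes x 5 Mb
sim = simulate_all(cfg)

chip = bin_coverage(sim.chip_fragments, sim.genome.lengths, window=1000, shift=67)
inp = bin_coverage(sim.input_fragments, sim.genome.lengths, window=1000, shift=67)
fit = partition_outliers(fit_input_model(chip.counts, inp.counts),
                         chip.counts, inp.counts, mode="quantile")
print(f"Input model: R^2 = {fit.r_squared:.3f}, "
      f"neutral-window R^2 = {fit.neutral_r_squared:.3f}")

track = log2_ratio(chip, inp, psi=0.5)
occ = gene_occupancy(sim.genes, track, sim.genome.lengths, flank=100_000)

conds = condition_labels(sim.counts)
factors = apply_global_scale(size_factors(sim.counts), conds, "KO", 1/1.15)
de_ko = nb_test(sim.counts, factors, conds, ("WT", "KO"))
de_oe = nb_test(sim.counts, factors, conds, ("WT", "OE"))
lengths = pd.Series((sim.genes["end"] - sim.genes["start"]).to_numpy(),
                    index=sim.genes["gene_id"])
classes = classify_genes(de_ko, tpm_matrix(sim.counts, lengths))
stats = occupancy_expression_stats(occ["flank_mean"], de_ko, de_oe, classes, lengths)
print(f"KO genes at padj<0.05: up {(classes == 'up').sum()}, "
      f"down {(classes == 'down').sum()}")
print(f"Spearman occupancy vs log2FC: KO {stats['rho_ko']:+.2f}, "
      f"OE {stats['rho_oe']:+.2f}")
```

Output:

```
Input model: R^2 = 0.570, neutral-window R^2 = 0.670
KO genes at padj<0.05: up 222, down 75
Spearman occupancy vs log2FC: KO +0.19, OE -0.20
```

Reading it: on this synthetic study more than half of the ChIP window
variance is plain Input (composition) signal; after excluding residual
outliers the neutral windows are even more Input-predictable. Once the
knockout counts are rescaled for the global RNA reduction, the genes that
rise in KO are the highly occupied ones and the same genes fall under
overexpression — the positive KO and negative OE rank correlations with
occupancy recover the planted coupling.

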