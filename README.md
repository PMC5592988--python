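# mitomethyl

Analytics for studies that link **mitochondrial DNA haplotypes** to nuclear
**DNA-methylation and gene-expression phenotypes**. The motivating design is a
panel of embryonic stem cell lines sharing one chromosomal genome but carrying
divergent mtDNA (e.g. *Mus musculus*, *M. spretus*, *M. dunni*/*terricolor*,
*M. pahari* cybrids): each haplotype establishes its own methylation profile,
its own mtDNA replication behaviour during differentiation, and its own
phylogenetic depth. `mitomethyl` implements the quantitative core of that
analysis as a tested, reusable library, with synthetic-data generators that
plant known truth so every stage can be validated without any external data.

## What it computes

**MeDIP CpG-array differential methylation** (`mitomethyl.medip`).
Two-channel probes (Cy3 = input DNA, Cy5 = 5mC-immunoprecipitated fraction)
yield M = log2(Cy5/Cy3). Probes are stratified into melting-temperature
quantile bins and given Z-scores against the Gaussian of comparable probes;
the reference Gaussian is estimated robustly (median, 1.4826·MAD) so it
describes the unaffected bulk even under heavy contamination by true signal
(the classical mean/sample-SD estimator is available as
`method="classical"`). A probe is differentially methylated between groups
when |ΔM̄| > 2 (fourfold) **and** |Z| > 5 in the group driving the
difference. Probe calls aggregate to genes by CpG-island interval overlap
(majority rule, ties flagged), and genes called in exactly one line form that
line's exclusive hyper/hypomethylated sets.

**qPCR quantities** (`mitomethyl.qpcr`). Standard-curve fits
Ct = b + m·log10(N) with efficiency 10^(−1/m) − 1; absolute mtDNA copies per
cell against a β-actin diploid reference (copies/cell = 2·mtDNA/actin);
relative expression by 2^(−ΔΔCt); ChIP/MeDIP enrichment as percent of
(fraction-adjusted) input, 100·2^((Ct_input − log2(1/f)) − Ct_IP); and the
Fluidigm ΔCt matrix (Ct_gene − Ct_18S) with average-linkage euclidean
clustering of genes and samples.

**mtDNA replicative efficiency** (`mitomethyl.releff`). The composite
statistic copies-per-cell ÷ (5mC/5hmC) at the *PolgA* exon-2 CpG island —
copy number per unit of net methylation pressure at the replication-licensing
locus.

**Enzyme assays** (`mitomethyl.assays`). α-ketoglutarate from a linear
standard curve, (A − intercept)/slope; MDH2 specific activity
U = (r_A·V_cuvette)/(l·ξ·V_sample·ρ) with ξ = 37/mM/cm; initial kinetic
rates r_A from 450-nm traces via an auto-selected linear window (R² ≥ 0.99
with trailing-outlier trimming).

**mtDNA phylogenetics** (`mitomethyl.phylo`). Pairwise ML distances under a
single alignment-wide GTR(+Γ) parameterisation (5 discrete Gamma categories,
shape 0.3734 by default), neighbor-joining with deterministic tie-breaking,
nonparametric bootstrap over alignment columns (1000 replicates), and
relative-rate divergence dating anchored on the *R. norvegicus* / *M.
musculus* split (8–12 Mya calibration interval).

**Synthetic data** (`mitomethyl.synthetic`). Generators for every input
above with planted ground truth: line-specific hyper/hypomethylated genes on
arrays, Ct tables from known curves, clock-like GTR+Γ alignments from dated
trees, and linear-plus-noise kinetic traces. Same seed ⇒ byte-identical
output; zero noise ⇒ exact recovery by the matching analysis stage.

## Worked example

```python
from mitomethyl import synthetic, medip, releff

cfg = synthetic.SimConfig(n_genes=500, probes_per_gene=2, noise_sd=0.3,
                          n_replicates=3, rng_seed=1)
truth = synthetic.default_truth(cfg, n_per_line=20, seed=2)
arrays, annotation, truth_table = synthetic.gen_cpg_arrays(cfg, truth)
by_line = {ln: [arrays[(ln, r)] for r in range(cfg.n_replicates)]
           for ln in synthetic.LINES}
calls, exclusive, shared = medip.call_per_line(by_line, annotation)
for line in synthetic.LINES:
    print(f"{line:8s} exclusive: {len(exclusive[line]['hyper'])} hyper, "
          f"{len(exclusive[line]['hypo'])} hypo")
m = synthetic.evaluate_recovery(calls, truth_table, cfg.n_genes)
print(f"sensitivity={m['sensitivity']:.3f} specificity={m['specificity']:.3f}")

eff = releff.replicative_efficiency(copies_per_cell=1000.0, e5mc=2.0, e5hmc=1.0)
print(f"replicative efficiency: {eff.efficiency:.1f}")
```

prints

```
mus      exclusive: 10 hyper, 10 hypo
spretus  exclusive: 10 hyper, 10 hypo
dunni    exclusive: 10 hyper, 10 hypo
pahari   exclusive: 10 hyper, 10 hypo
sensitivity=1.000 specificity=1.000
replicative efficiency: 500.0
```

Each of the four simulated lines had 20 line-specific genes planted (10
hypermethylated, 10 hypomethylated, |log2 shift| = 3) among 500 genes at
probe noise SD 0.3; the fourfold + |Z|>5 cascade recovers every planted
(gene, line, direction) triple with no false positives, and the exclusive
sets match the plant exactly. The efficiency example reads: 1000 mtDNA
copies/cell at a 5mC/5hmC ratio of 2 give 500 copies per methylation-ratio
unit.

A command-line surface mirrors the library
(`mitomethyl simulate|medip|qpcr|releff|assay|phylo ...`); see
`mitomethyl --help`.

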