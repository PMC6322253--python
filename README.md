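# gbmeth

Gene-body CG methylation analysis from bisulfite count data, built for
studies of sparsely methylated genomes — typified by hemimetabolous insects
— where methylation concentrates in the bodies of a conserved subset of
genes and the question is whether it does anything to transcription.

Given allc-style per-cytosine count tables (chrom, 1-based position,
strand, context, methylated reads, total reads), gene/TE annotations and
RNA-seq count matrices, the package:

- computes **weighted methylation levels** (`Σmc / Σn`) per site set,
  genomic compartment (genic / TE / intergenic / genome-wide), and region;
- estimates the **bisulfite non-conversion rate** from an unmethylated
  spike-in contig, with an exact binomial 95% CI;
- pairs **CpG dyads** and quantifies strand symmetry — the signature of
  maintenance methyltransferase (Dnmt1) activity;
- classifies genes as **CG-methylated vs unmethylated** by a one-sided
  binomial test of pooled genic counts against the coding-sequence
  background `p0` (`p = P[Bin(Σn, p0) ≥ Σmc]`), Benjamini–Hochberg
  corrected, requiring ≥ 20 reads over ≥ 20 covered CG sites, with a
  false-negative drop rule; compares statuses across conditions into
  DMG / SMG / UMG classes;
- builds strand-aware **metaplots**: 20 proportional windows over gene or
  TE bodies plus 1 kb flanks, read-weighted per window;
- summarises **expression** (CPM ≥ 1 in ≥ 2 libraries filter, FPKM, group
  means, log2 fold-changes, TE locus collapsing and RPKM, one-sided
  Mann–Whitney on TE expression);
- tests **methylation–expression association**: expression by methylation
  decile, OLS of log2 FPKM on mCG level with Bonferroni flagging, per-gene
  (ΔmCG, log2FC) with Spearman correlation, and the 2×2 overlap of
  differential methylation with differential expression.

A first-class synthetic-data generator (`gbmeth.simulate`) produces
genomes, annotations, ground-truth methylomes, bisulfite count tables and
negative-binomial expression matrices with the statistical structure the
analysis assumes — bimodal genic methylation, strand-symmetric dyads, an
unmethylated spike-in observed through a small non-conversion error, a
knockdown modelled as cell-mixture dilution (every true level multiplied by
the retained fraction *f*), and configurable methylation–expression
coupling (default zero). The whole test suite runs against it.

## Worked example

Simulate a control/knockdown study (60 genes, one 250 kb contig, depth 20,
retained fraction 0.15) and run the core methylome analysis:

```python
from gbmeth import quant, workflows
from gbmeth.simulate import SimConfig, simulate_all

cfg = SimConfig(seed=42, n_chrom=1, chrom_len=250_000, n_genes=60,
                gene_len_range=(1000, 2500), depth_mean=20.0)
b = simulate_all(cfg)

ctrl = quant.compartment_levels(b.allc_control, b.genome.genes, b.genome.tes)
kd = quant.compartment_levels(b.allc_kd, b.genome.genes, b.genome.tes)
print(ctrl.round(4))

cc = workflows.call_and_compare(b.allc_control, b.allc_kd,
                                b.genome.genes, b.genome.spikein_chrom)
print("background p0 =", round(cc.p0, 4))
print("non-conversion rate =", f"{cc.nonconversion.rate:.2%}")
print("control calls:", cc.calls_control["status"].value_counts().to_dict())
print("knockdown calls:", cc.calls_kd["status"].value_counts().to_dict())
print("status classes:", cc.class_counts)
print(f"genic level kd/control = {kd.loc['genic','level']/ctrl.loc['genic','level']:.3f}")
```

prints

```
                 mc       n   level  covered_sites
compartment
genic         77565  265187  0.2925          13253
te            12543   42019  0.2985           2101
intergenic    32610  373701  0.0873          18742
genome_wide  122718  680907  0.1802          34096
background p0 = 0.2925
non-conversion rate = 0.06%
control calls: {'unmethylated': 38, 'methylated': 22}
knockdown calls: {'unmethylated': 60}
status classes: {'UMG': 38, 'DMG': 22, 'SMG': 0, 'unclassified': 0}
genic level kd/control = 0.150
```

Reading this: genic mCG sits at 0.29 in the control (bimodal across genes:
22 of 60 genes are called CG-methylated against the coding background,
matching the generative 40% class fraction up to sampling); the spike-in
recovers the ~0.05% conversion-error floor; the knockdown collapses every
methylated gene to unmethylated (22 DMGs) and the genic level ratio 0.150
recovers the simulated retained fraction f = 0.15 — an 85% loss of
gene-body methylation. With the default zero coupling, the association
suite (`workflows.run_association_suite`) then finds no methylation–
expression relationship: that separation of epigenetic and transcriptional
effects is exactly what the analysis is designed to resolve.

The same operations are available from the shell via the `gbmeth` console
script (`gbmeth sim all`, `gbmeth meth levels|call|compare|symmetry|
nonconversion|metaplot`, `gbmeth expr summarize|filter|te`,
`gbmeth assoc deciles|regress|delta|overlap`).

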