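# Methods

## Scope and model

`gbmeth` analyses CG methylation in species with sparse, gene-body-focused
methylomes (typified by hemimetabolous insects), from *count-level* bisulfite
data: per-cytosine tables of methylated and total read counts (allc-style),
plus gene/TE annotations and RNA-seq count matrices. Read alignment and
methylation calling from BAM are out of scope; so are DMR discovery,
CHG/CHH biology, and quasi-likelihood differential-expression internals
(DE significance is consumed from an external results table).

The central quantity everywhere is the **weighted methylation level** of a
site set: `Σ mc / Σ n`, the sum of methylated read counts over the sum of
total read counts. It is coverage-weighted by construction, invariant to how
the input stream is split or reordered, and *undefined* (NaN, never 0) when
no reads cover the set. All region summaries, metaplot windows, backgrounds
and gene levels use this definition, so levels pool exactly:
`level(A ∪ B) = (Σmc_A + Σmc_B) / (Σn_A + Σn_B)`.

Coordinates: allc positions are 1-based positions of the cytosine; BED6 is
0-based half-open; GFF3 1-based inclusive. All conversions live in
`gbmeth.io`; internal interval logic is 0-based half-open.

## Gene classification

A gene's CG sites are pooled into `(Σmc, Σn)` and tested one-sided against a
background level `p0` — the weighted level over all coding sequence — with
`p = P[Binomial(Σn, p0) ≥ Σmc]`. Benjamini–Hochberg correction runs across
the determinate genes only; a gene is *CG-methylated* when `q < 0.05` and it
has at least 20 reads over at least 20 covered CG sites, *indeterminate*
when coverage fails those thresholds. `p0` is floored at the estimated
non-conversion rate so an entirely unmethylated coding background cannot
produce a degenerate `p0 = 0`. Because a pooled binomial can leave highly
methylated genes unmethylated when site-level evidence is thin, unmethylated
genes whose level exceeds the lowest methylated gene's level are *dropped*
from downstream analyses. Sites inside overlapping genes count toward every
gene containing them.

**Shared background for condition comparisons.** When two conditions are
compared (`workflows.call_and_compare`), both are classified against a
single background — the control/reference coding level. This is a deliberate
design choice: classification is meant to answer "is this gene methylated
above the wild-type coding baseline?". Re-estimating the background per
condition would re-normalise away a genome-wide loss — under a uniform
dilution, gene levels and the background shrink by the same factor, and a
pooled binomial over thousands of reads would keep every originally
methylated gene significant, making the differential-methylation contrast
vacuous by construction. With the shared baseline, a strong knockdown
reclassifies formerly methylated genes as unmethylated, which is the
behaviour the contrast exists to measure. `classify_genes` itself takes
`p0` explicitly, so the per-condition convention remains available.

## Metaplots

Feature bodies are divided into `k = 20` proportional windows; the 1 kb
flanks are also divided into `k` windows each (the windowing of flanks is
genuinely open — equal-width flank windows are assumed; `k` and the flank
length are configurable). When the body length is not divisible by `k`, the
remainder is spread over the first `length mod k` windows *in feature
orientation*; minus-strand features are laid out right-to-left so window 1
is always biologically upstream. Note this means the plus- and minus-strand
tilings of the same interval coincide exactly only for divisible lengths.
Window levels are pooled (read-weighted) across features by default,
matching the weighted-level convention; an unweighted mean-of-features
variant is exposed as a flag. Features shorter than `k` bp are skipped and
counted. Flanks running past a contig end are truncated.

## Dyad symmetry and non-conversion

A CpG dyad pairs the plus-strand C at position `p` with the minus-strand C
at `p+1`. Symmetry summaries use dyads with at least `min_cov` (default 3,
raised to 10–20 for density work) reads on *each* strand; orphans (coverage
on one strand only) are excluded from symmetry but retained in pooled
levels. Concordance is the Pearson correlation of per-strand levels across
qualifying dyads (NaN, flagged, under zero variance or fewer than two
dyads). Both per-site and per-dyad level histograms are produced, since a
density plot can reasonably be drawn from either.

The non-conversion rate is the weighted level over the unmethylated
spike-in contig, with an exact Clopper–Pearson 95% CI on the pooled counts.
Its exact coverage probability at a true rate of 5e-4 and 10^6 reads is
0.951 (computed by enumeration in the test suite).

## Expression

CPM, FPKM and RPKM use the standard definitions (`count·10^6 / total`,
`count·10^9 / (length·total)`). The retention filter is CPM ≥ 1 in ≥ 2
libraries. Group means average FPKM across libraries; log2 fold-changes use
a pseudo-value of half the smallest nonzero group-mean FPKM added to zero
means. TE records of the same family that overlap or touch are collapsed
into loci; families are ranked by the number of collapsed loci of ≥ 500 bp,
and the top ten are analysed. TE RPKM is reported per locus and per family
under *both* aggregation conventions (pooled counts/length, and the mean of
per-locus RPKM), plus the length-free reads-per-million variant, because
the field uses all of these. The TE contrast is a one-sided Mann–Whitney U
(knockdown greater); a fully tied input returns p = 1 with a warning.

The bundled two-group DE test (`nb_moment_de_test`) is a **synthetic
stand-in**: a moment-based negative-binomial Wald test on CPM-normalised
group means with a pooled method-of-moments dispersion and BH correction.
It exists so simulated pipelines are self-contained and calibrated; real
analyses should supply an external DE results table (gene, log2FC, FDR),
with DEG defined as FDR < 0.05.

## Association analyses

Expression enters deciles and regression as `log2(FPKM + pseudo)`.
Methylated genes are ranked by level (ties broken by gene id for
reproducibility) and cut into ten near-equal bins, with an extra UM bin for
unmethylated genes; per-bin means carry t-based 95% CIs. The continuous
analysis is OLS of log2 expression on weighted mCG level over genes with
positive expression; the Bonferroni family size `m` is the number of
regressions executed in the invocation. The knockdown contrast reports
per-gene `ΔmCG = level_kd − level_ctrl` against log2FC, with fixed-grid 2-D
bin counts and a Spearman correlation. The overlap partition cross-tabulates
{DMG, SMG∪UMG} × {DEG, non-DEG} with row percentages (NaN for empty rows).
The relative-expression matrix divides each gene's FPKM row by its own
maximum (all-zero rows kept and flagged) and orders rows by average-linkage
hierarchical clustering on Euclidean distance.

## Synthetic data generator

The generator emulates the features of real WGBS + RNA-seq studies that the
analysis relies on, with defaults chosen once as the study conditions:

| parameter | default | meaning |
|---|---|---|
| `frac_methylated_genes` | 0.4 | fraction of genes in the methylated class (≈ the ~39% seen in gene-body-methylated insects) |
| `meth_level_beta` | (8, 2) | per-dyad Beta levels of methylated genes (mean 0.8, "highly methylated" mode) |
| `unmeth_level` | 0.0 | true level of unmethylated-class genes |
| `te_level` / `intergenic_level` | 0.3 / 0.1 | flat compartment levels of a genome-wide-methylated hemimetabolous genome |
| `nonconversion_rate` | 5e-4 | bisulfite error floor (≈ 0.05%) |
| `depth_mean` | 10 | Poisson mean reads/site/strand (≈ 9–11× mapped coverage) |
| `retained_fraction` | 0.15 | knockdown dilution factor f |
| `n_reps_per_group` | 3 | RNA-seq replicates per condition |
| `nb_dispersion` | 0.1 | NB dispersion, typical bulk RNA-seq |
| `coupling_effect` | 0.0 | planted log2FC per unit ΔmCG (0 = null) |

Structure: random uniform-composition contigs (CpG density ≈ 1/16) plus an
unmethylated spike-in contig; genes placed without overlap and at least
`2·flank_len` from contig ends (placement failure is an explicit error);
TEs dropped uniformly, free to overlap genes (compartment precedence
gene > TE > intergenic resolves truth assignment). Each CpG dyad carries one
true level shared by both strands. The knockdown multiplies every level by
`f` — the direct formalisation of passive dilution where a fraction `f` of
cells retains the wild-type methylome and the rest are fully demethylated.
Observation: per strand independently, `n ~ Poisson(depth_mean)` and
`mc ~ Binomial(n, level + (1−level)·nonconversion)`. Expression:
`NB(mean·s_r, dispersion)` with log2-uniform baseline means, lognormal
library size factors, and the knockdown group mean multiplied by
`2^(coupling·ΔmCG)`; dispersion 0 degenerates to Poisson. One RNG stream
per output kind is spawned from the master seed, so outputs are
reproducible and independent across kinds.

What the generator deliberately does **not** emulate: coverage
autocorrelation and mappability structure, sequence-composition bias in CpG
placement, partially methylated domains or per-cell heterogeneity beyond
the uniform mixture, read-level errors other than non-conversion, exon
structure (gene extent = start-to-stop interval), and batch effects in
expression. Passing tests therefore certify the *estimators and tests*
under a clean generative model, not robustness to alignment artefacts or
biological heterogeneity in real libraries.

## Numerical and test-size choices

Binomial tails use `scipy.stats.binom.sf(mc − 1, n, p0)` and are verified
against an exact rational-arithmetic oracle to 1e−12. BH comes from
`statsmodels.multipletests`, checked against a from-definition oracle.
Degenerate inputs return flagged NaNs rather than exceptions wherever a
partial result is meaningful (zero-coverage levels, zero-variance
correlations and slopes, empty overlap rows); hard errors are reserved for
invalid inputs (mc > n, unknown strands, zero-total libraries, annotations
naming unknown contigs, infeasible gene placement). Statistical suite sizes
were chosen to keep Monte-Carlo error well inside the asserted margins:
knockdown recovery uses ≥ 10^4 dyads at depth 20 (ratio SE ≈ 0.002 against
a ±0.02 band); null-association calibration uses 50 independent 100-gene
runs for the KS uniformity check and one 2000-gene run for the overlap and
Spearman checks; caller calibration uses 20 replicates of 2000 null genes.
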