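"""Synthetic genomes, methylomes, bisulfite counts and expression matrices.

The generator emulates the statistical structure the downstream analysis
assumes: a bimodal genic CG methylome (a fraction of genes highly methylated,
the rest unmethylated), strand-symmetric CpG dyads, an unmethylated spike-in
contig observed through a small bisulfite non-conversion error, a maintenance-
methyltransferase knockdown modelled as a cell-mixture dilution (a fraction
``f`` of cells retains the wild-type methylome, the rest are fully
demethylated, so every true level is multiplied by ``f``), and negative-
binomial expression counts for a two-group replicate design with configurable
(default zero) coupling between methylation change and expression change.

Randomness is organised as one child stream per output kind, all spawned from
the master seed, so e.g. adding TE families does not perturb gene-level draws.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as _io

SPIKEIN_CHROM = "lambda_spikein"

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


class PlacementError(RuntimeError):
    """Requested gene set cannot be placed without overlap on the contigs."""


@dataclass(frozen=True)
class SimConfig:
    """All knobs of the generative model, with study-condition defaults.

    Proportions are in [0, 1]; lengths in bp. ``retained_fraction`` is the
    knockdown dilution factor f (fraction of cells keeping the wild-type
    methylome). ``coupling_effect`` is the planted log2 fold-change in
    expression per unit of methylation change (0 = the null the study reports).
    """

    seed: int = 0
    n_chrom: int = 2
    chrom_len: int = 200_000
    n_genes: int = 80
    gene_len_range: tuple[int, int] = (1_000, 3_000)
    flank_len: int = 1_000
    n_te_per_family: int = 8
    te_families: tuple[str, ...] = ("Gypsy", "Jockey", "Copia", "Mariner")
    te_len_range: tuple[int, int] = (300, 1_500)
    spikein_len: int = 20_000
    frac_methylated_genes: float = 0.4
    meth_level_beta: tuple[float, float] = (8.0, 2.0)
    unmeth_level: float = 0.0
    te_level: float = 0.3
    intergenic_level: float = 0.1
    nonconversion_rate: float = 5e-4
    depth_mean: float = 10.0
    retained_fraction: float = 0.15
    n_reps_per_group: int = 3
    nb_mean_log2_range: tuple[float, float] = (2.0, 10.0)
    nb_dispersion: float = 0.1
    coupling_effect: float = 0.0

    def validate(self) -> None:
        for name in (
            "frac_methylated_genes", "unmeth_level", "te_level",
            "intergenic_level", "nonconversion_rate", "retained_fraction",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be positive")
        if self.n_reps_per_group < 2:
            raise ValueError("n_reps_per_group must be >= 2")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")

    def streams(self) -> dict[str, np.random.Generator]:
        """One independent child generator per output kind."""
        kinds = ("genome", "methylome", "counts_control", "counts_kd", "expression")
        children = np.random.SeedSequence(self.seed).spawn(len(kinds))
        return {k: np.random.default_rng(s) for k, s in zip(kinds, children)}


@dataclass
class Genome:
    """Contig sequences plus gene/TE annotations (0-based half-open)."""

    contigs: dict[str, str]
    genes: pd.DataFrame  # chrom, start, end, name, score, strand
    tes: pd.DataFrame    # chrom, start, end, strand, family
    spikein_chrom: str = SPIKEIN_CHROM

    @property
    def contig_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.contigs.items()}


@dataclass
class TrueMethylome:
    """Ground-truth per-dyad levels (shared by both strands) and gene classes.

    ``dyads``: chrom, pos (1-based plus-strand C), level, compartment, gene.
    ``genes``: gene, meth_class in {methylated, unmethylated}, mean_level.
    """

    dyads: pd.DataFrame
    genes: pd.DataFrame
    spikein_chrom: str = SPIKEIN_CHROM


def _random_seq(rng: np.random.Generator, length: int) -> str:
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    return alphabet[rng.integers(0, 4, size=length)].tobytes().decode()


def _place_intervals(rng, n, len_range, lo, hi, min_gap=1):
    """Place n non-overlapping intervals of random length inside [lo, hi).

    Lengths are uniform over ``len_range``; the leftover space is spread over
    the n+1 gaps with a Dirichlet draw. Raises PlacementError when the
    intervals cannot fit.
    """
    if n == 0:
        return np.empty(0, int), np.empty(0, int)
    lengths = rng.integers(len_range[0], len_range[1] + 1, size=n)
    slack = (hi - lo) - int(lengths.sum()) - min_gap * (n - 1)
    if slack < 0:
        raise PlacementError(
            f"cannot place {n} intervals totalling {lengths.sum()} bp "
            f"in {hi - lo} bp of usable space"
        )
    w = rng.dirichlet(np.ones(n + 1))
    gaps = np.floor(w * slack).astype(int)
    gaps[-1] += slack - gaps.sum()
    starts = np.empty(n, int)
    cur = lo
    for i in range(n):
        cur += gaps[i] + (min_gap if i > 0 else 0)
        starts[i] = cur
        cur += lengths[i]
    return starts, starts + lengths


def simulate_genome(config: SimConfig) -> Genome:
    """Random contigs (plus a spike-in), non-overlapping genes, and TEs.

    Genes stay at least ``2 * flank_len`` from contig ends so metaplot flanks
    never truncate. TEs are dropped uniformly and may overlap genes (the
    compartment precedence rule downstream resolves that). Deterministic for
    a given config.
    """
    config.validate()
    rng = config.streams()["genome"]
    chrom_names = [f"chr{i + 1}" for i in range(config.n_chrom)]
    contigs = {c: _random_seq(rng, config.chrom_len) for c in chrom_names}
    contigs[SPIKEIN_CHROM] = _random_seq(rng, config.spikein_len)

    per = np.full(config.n_chrom, config.n_genes // config.n_chrom)
    per[: config.n_genes % config.n_chrom] += 1
    gene_rows, gid = [], 0
    for c, n_here in zip(chrom_names, per):
        lo, hi = 2 * config.flank_len, config.chrom_len - 2 * config.flank_len
        if hi <= lo and n_here > 0:
            raise PlacementError(f"contig {c} too short for flank margin")
        starts, ends = _place_intervals(rng, int(n_here), config.gene_len_range, lo, hi)
        for s, e in zip(starts, ends):
            gene_rows.append(
                {
                    "chrom": c, "start": int(s), "end": int(e),
                    "name": f"gene{gid:05d}", "score": 0,
                    "strand": rng.choice(["+", "-"]),
                }
            )
            gid += 1
    genes = pd.DataFrame(gene_rows, columns=_io.BED6_COLUMNS)

    te_rows = []
    for fam in config.te_families:
        for _ in range(config.n_te_per_family):
            c = chrom_names[rng.integers(0, config.n_chrom)]
            length = int(rng.integers(config.te_len_range[0], config.te_len_range[1] + 1))
            start = int(rng.integers(0, config.chrom_len - length))
            te_rows.append(
                {
                    "chrom": c, "start": start, "end": start + length,
                    "strand": rng.choice(["+", "-"]), "family": fam,
                }
            )
    tes = pd.DataFrame(te_rows, columns=["chrom", "start", "end", "strand", "family"])
    if len(tes):
        tes = tes.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    return Genome(contigs=contigs, genes=genes, tes=tes)


def _dyad_positions(seq: str) -> np.ndarray:
    """0-based positions of the plus-strand C of every CpG dyad."""
    a = np.frombuffer(seq.encode(), dtype="S1")
    return np.where((a[:-1] == b"C") & (a[1:] == b"G"))[0]


def _membership(pos0: np.ndarray, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
    """Index of the (sorted, merged) interval containing each pos, -1 if none."""
    if starts.size == 0:
        return np.full(pos0.shape, -1)
    idx = np.searchsorted(starts, pos0, side="right") - 1
    ok = (idx >= 0) & (pos0 < ends[np.clip(idx, 0, None)])
    return np.where(ok, idx, -1)


def simulate_methylome(genome: Genome, config: SimConfig) -> TrueMethylome:
    """Assign each gene a class and each CpG dyad a true level.

    Methylated-class genes get per-dyad levels drawn from
    Beta(*meth_level_beta*); unmethylated genes sit at ``unmeth_level``
    everywhere; TE and intergenic dyads get their flat compartment levels;
    the spike-in contig is exactly 0. Precedence for overlaps is
    gene > TE > intergenic. Both strands of a dyad share the level.
    """
    config.validate()
    rng = config.streams()["methylome"]
    genes = genome.genes
    is_meth = rng.random(len(genes)) < config.frac_methylated_genes
    gene_class = pd.DataFrame(
        {
            "gene": genes["name"].values,
            "meth_class": np.where(is_meth, "methylated", "unmethylated"),
        }
    )
    a, b = config.meth_level_beta

    frames = []
    for chrom, seq in genome.contigs.items():
        pos0 = _dyad_positions(seq)
        if chrom == genome.spikein_chrom:
            lv = np.zeros(pos0.size)
            comp = np.full(pos0.size, "spikein", dtype=object)
            gene_of = np.full(pos0.size, "", dtype=object)
        else:
            g = genes[genes["chrom"] == chrom].sort_values("start")
            gidx = _membership(pos0, g["start"].values, g["end"].values)
            t = genome.tes[genome.tes["chrom"] == chrom]
            ts, te_ = _io.merge_intervals(t["start"].values, t["end"].values)
            tidx = _membership(pos0, ts, te_)
            comp = np.where(gidx >= 0, "genic", np.where(tidx >= 0, "te", "intergenic"))
            gene_of = np.where(gidx >= 0, g["name"].values[np.clip(gidx, 0, None)], "")
            lv = np.full(pos0.size, config.intergenic_level, float)
            lv[comp == "te"] = config.te_level
            in_gene = gidx >= 0
            gene_is_meth = np.zeros(pos0.size, bool)
            meth_names = set(gene_class.loc[is_meth, "gene"]) if len(genes) else set()
            gene_is_meth[in_gene] = np.isin(
                gene_of[in_gene], list(meth_names)
            )
            lv[in_gene & ~gene_is_meth] = config.unmeth_level
            n_meth_sites = int((in_gene & gene_is_meth).sum())
            lv[in_gene & gene_is_meth] = rng.beta(a, b, size=n_meth_sites)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": pos0 + 1,  # 1-based plus-strand C
                    "level": lv,
                    "compartment": comp,
                    "gene": gene_of,
                }
            )
        )
    dyads = pd.concat(frames, ignore_index=True)
    means = (
        dyads[dyads["gene"] != ""].groupby("gene")["level"].mean()
        if len(dyads) else pd.Series(dtype=float)
    )
    gene_class["mean_level"] = gene_class["gene"].map(means).fillna(np.nan)
    return TrueMethylome(dyads=dyads, genes=gene_class, spikein_chrom=genome.spikein_chrom)


def apply_knockdown(truth: TrueMethylome, f: float) -> TrueMethylome:
    """Cell-mixture dilution: every true level is multiplied by ``f``.

    A fraction f of cells retains the wild-type methylome and the remainder
    is fully demethylated by replication without maintenance, so the expected
    per-site level is f times the wild-type level.
    """
    if not (0.0 <= f <= 1.0):
        raise ValueError(f"retained fraction f={f} outside [0, 1]")
    dyads = truth.dyads.copy()
    dyads["level"] = dyads["level"] * f
    genes = truth.genes.copy()
    genes["mean_level"] = genes["mean_level"] * f
    return TrueMethylome(dyads=dyads, genes=genes, spikein_chrom=truth.spikein_chrom)


def _context_3mers(seq: str, pos0: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Strand-local 3-mer contexts for the two cytosines of each dyad.

    Plus-strand context is the 3-mer starting at the C; the minus-strand C
    (opposite the G) reads CG + complement of the base 5' of the dyad.
    """
    padded = np.frombuffer(("N" + seq + "NN").encode(), dtype="S1").astype("U1")
    plus = np.char.add(
        np.char.add(padded[pos0 + 1], padded[pos0 + 2]), padded[pos0 + 3]
    )
    before = padded[pos0]
    comp = before.copy()
    for base, partner in _COMP.items():
        comp[before == base] = partner
    minus = np.char.add("CG", comp)
    return plus, minus


def simulate_site_counts(
    genome: Genome, truth: TrueMethylome, config: SimConfig, group: str = "control"
) -> pd.DataFrame:
    """Observe the true methylome through the bisulfite count model.

    Per strand of each dyad independently: total reads ~ Poisson(depth_mean)
    and methylated reads ~ Binomial(total, pi) with
    pi = level + (1 - level) * nonconversion_rate. Returns an allc-style
    frame covering both strands (zero-coverage sites included).
    """
    config.validate()
    rng = config.streams()["counts_kd" if group == "kd" else "counts_control"]
    frames = []
    for chrom, seq in genome.contigs.items():
        d = truth.dyads[truth.dyads["chrom"] == chrom]
        if d.empty:
            continue
        pos0 = d["pos"].values - 1
        level = d["level"].values
        pi = level + (1.0 - level) * config.nonconversion_rate
        ctx_p, ctx_m = _context_3mers(seq, pos0)
        n_p = rng.poisson(config.depth_mean, size=pos0.size)
        n_m = rng.poisson(config.depth_mean, size=pos0.size)
        mc_p = rng.binomial(n_p, pi)
        mc_m = rng.binomial(n_m, pi)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": np.concatenate([pos0 + 1, pos0 + 2]),
                    "strand": np.repeat(["+", "-"], pos0.size),
                    "context": np.concatenate([ctx_p, ctx_m]),
                    "mc": np.concatenate([mc_p, mc_m]),
                    "n": np.concatenate([n_p, n_m]),
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)


@dataclass
class ExpressionSim:
    """Simulated two-group count matrix plus its generative bookkeeping."""

    counts: pd.DataFrame            # genes x libraries, integer
    groups: dict[str, str]          # library -> {control, kd}
    size_factors: dict[str, float]
    gene_lengths: pd.Series         # bp, indexed by gene
    delta_mcg: pd.Series            # true kd - control gene mean level
    true_log2fc: pd.Series          # planted coupling_effect * delta_mcg


def simulate_expression(
    genes: pd.DataFrame,
    truth_control: TrueMethylome,
    truth_kd: TrueMethylome,
    config: SimConfig,
) -> ExpressionSim:
    """Negative-binomial counts for control and knockdown replicate libraries.

    Baseline means are log2-uniform over ``nb_mean_log2_range``; the knockdown
    group mean is multiplied by ``2 ** (coupling_effect * delta_mCG)`` where
    delta_mCG is the gene's true mean level change, so ``coupling_effect=0``
    gives the null of no methylation-expression relationship. Counts are
    NB(mean * size_factor, dispersion); dispersion 0 degenerates to Poisson.
    """
    config.validate()
    rng = config.streams()["expression"]
    names = genes["name"].values
    lengths = pd.Series(
        (genes["end"] - genes["start"]).values, index=names, name="length"
    )
    lo, hi = config.nb_mean_log2_range
    base_mu = 2.0 ** rng.uniform(lo, hi, size=len(names))
    d_ctrl = truth_control.genes.set_index("gene")["mean_level"]
    d_kd = truth_kd.genes.set_index("gene")["mean_level"]
    delta = (d_kd - d_ctrl).reindex(names).fillna(0.0)
    planted = config.coupling_effect * delta
    libs = [f"{g}_{i + 1}" for g in ("control", "kd") for i in range(config.n_reps_per_group)]
    groups = {lib: lib.rsplit("_", 1)[0] for lib in libs}
    size_factors = {lib: float(rng.lognormal(0.0, 0.15)) for lib in libs}
    cols = {}
    for lib in libs:
        mu = base_mu * (2.0 ** planted.values if groups[lib] == "kd" else 1.0)
        mu = mu * size_factors[lib]
        if config.nb_dispersion < 1e-12:
            cols[lib] = rng.poisson(mu)
        else:
            r = 1.0 / config.nb_dispersion
            cols[lib] = rng.negative_binomial(r, r / (r + mu))
    counts = pd.DataFrame(cols, index=pd.Index(names, name="gene"))
    return ExpressionSim(
        counts=counts,
        groups=groups,
        size_factors=size_factors,
        gene_lengths=lengths,
        delta_mcg=delta,
        true_log2fc=pd.Series(planted.values, index=names, name="true_log2fc"),
    )


@dataclass
class SimBundle:
    """Everything one simulated study produces, ready for the analysis."""

    config: SimConfig
    genome: Genome
    truth_control: TrueMethylome
    truth_kd: TrueMethylome
    allc_control: pd.DataFrame
    allc_kd: pd.DataFrame
    expression: ExpressionSim


def simulate_all(config: SimConfig) -> SimBundle:
    """Run the full generative model: genome, methylomes, counts, expression."""
    genome = simulate_genome(config)
    truth_control = simulate_methylome(genome, config)
    truth_kd = apply_knockdown(truth_control, config.retained_fraction)
    return SimBundle(
        config=config,
        genome=genome,
        truth_control=truth_control,
        truth_kd=truth_kd,
        allc_control=simulate_site_counts(genome, truth_control, config, "control"),
        allc_kd=simulate_site_counts(genome, truth_kd, config, "kd"),
        expression=simulate_expression(genome.genes, truth_control, truth_kd, config),
    )


def write_bundle(bundle: SimBundle, outdir: str | Path) -> dict[str, Path]:
    """Write a bundle to flat files (FASTA/BED6/GFF3/allc/counts/truth TSVs)."""
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    recs = [
        SeqRecord(Seq(s), id=c, description="")
        for c, s in bundle.genome.contigs.items()
    ]
    paths["fasta"] = outdir / "genome.fa"
    SeqIO.write(recs, paths["fasta"], "fasta")
    paths["genes"] = outdir / "genes.bed"
    _io.write_bed6(bundle.genome.genes, paths["genes"])
    paths["tes"] = outdir / "tes.gff3"
    _io.write_te_gff3(bundle.genome.tes, paths["tes"])
    for tag, allc in (("control", bundle.allc_control), ("kd", bundle.allc_kd)):
        paths[f"allc_{tag}"] = outdir / f"allc_{tag}.tsv"
        _io.write_allc(allc, paths[f"allc_{tag}"])
    paths["counts"] = outdir / "counts.tsv"
    _io.write_counts(bundle.expression.counts, paths["counts"])
    truth = bundle.truth_control.genes.copy()
    truth["mean_level_kd"] = bundle.truth_kd.genes["mean_level"].values
    paths["truth"] = outdir / "truth_genes.tsv"
    truth.to_csv(paths["truth"], sep="\t", index=False)
    meta = pd.DataFrame(
        {
            "library": list(bundle.expression.groups),
            "group": list(bundle.expression.groups.values()),
            "size_factor": [
                bundle.expression.size_factors[k] for k in bundle.expression.groups
            ],
        }
    )
    paths["libraries"] = outdir / "libraries.tsv"
    meta.to_csv(paths["libraries"], sep="\t", index=False)
    lengths = bundle.expression.gene_lengths.rename("length")
    paths["gene_lengths"] = outdir / "gene_lengths.tsv"
    lengths.to_csv(paths["gene_lengths"], sep="\t", index_label="gene")
    return paths
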