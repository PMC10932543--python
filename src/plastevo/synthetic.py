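"""Synthetic three-stage expression, phenotype and two-population genotype data.

The generator emulates the structure of the staged colonization study —
a gene x sample TPM matrix over ancestral / plastic / colonized stages,
muscle-like phenotypes measured on the ancestral and colonized
individuals, and biallelic SNP genotypes for a lowland and a highland
population with gene annotation on a single pseudo-chromosome — while
planting a known ground truth (per-gene plasticity class and magnitude,
regulator signs, per-SNP divergence) so every downstream stage of the
pipeline can be validated without external data.

Expression model: each gene has an ancestral mean mu drawn log-uniformly
on the TPM scale.  Reinforcement genes rise to mu(1+m) at the plastic
stage and mu(1+2m) at the colonized stage; reversion genes rise to
mu(1+m) and then overshoot back to mu(1+m) - mu*m' with m' = 1.5 m, so
both changes exceed the classification threshold; null genes keep mu.
Per-sample values multiply the stage mean by mean-one log-normal noise
with a configurable coefficient of variation.

Genotype model: Balding-Nichols.  Each SNP draws an ancestral frequency
p ~ Uniform(0.05, 0.95) and per-population frequencies from
Beta(p(1-F)/F, (1-p)(1-F)/F); individual genotypes are Binomial(2, freq)
draws.  SNPs falling in the 2 kb flanks of candidate genes (planted
reinforcement/reversion genes) use F = ``fst_candidate_flank``; all
other SNPs use F = ``fst_background``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .expression import STAGES, ExpressionMatrix
from .popgen import FLANK_BP, GeneAnnotation, GenotypeData

SIGN_NONE = "none"


@dataclass
class SyntheticConfig:
    """Knobs of the synthetic dataset; defaults mirror the study conditions.

    Counts per stage default to 5 individuals; planted class fractions
    default to 10% reinforcement and 30% reversion at magnitude 0.8 of
    the ancestral mean with 10% log-normal noise.  The genotype block
    defaults to the study's 12 lowland and 11 highland individuals with
    a weak genome-wide background divergence and strongly elevated
    divergence in candidate-gene flanks.
    """

    n_genes: int = 1000
    n_per_stage: tuple[int, int, int] = (5, 5, 5)
    frac_reinforcement: float = 0.10
    frac_reversion: float = 0.30
    effect_magnitude: float = 0.8
    reversion_overshoot: float = 1.5
    noise_cv: float = 0.1
    tissue: str = "flight_muscle"
    mu_range: tuple[float, float] = (1.0, 100.0)

    n_phenotypes: int = 3
    regulator_fraction: float = 0.2
    coupling: float = 1.0
    regulator_latent_sd: float = 0.35
    phenotype_noise: float = 0.5  # noise sd as a fraction of the signal sd

    n_snps: int = 5000
    n_individuals_per_pop: tuple[int, int] = (12, 11)
    fst_background: float = 0.05
    fst_candidate_flank: float = 0.4
    gene_length: int = 3000
    gene_spacing: int = 10000

    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.n_snps <= 0 or self.n_phenotypes < 0:
            raise ValueError("counts must be positive")
        if any(n <= 0 for n in self.n_per_stage):
            raise ValueError("each stage needs at least one sample")
        fr, fv = self.frac_reinforcement, self.frac_reversion
        if fr < 0 or fv < 0 or fr + fv > 1:
            raise ValueError("class fractions must be non-negative and sum to <= 1")
        if not (0 < self.fst_background < 1 and 0 < self.fst_candidate_flank < 1):
            raise ValueError("fst parameters must lie in (0,1)")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.effect_magnitude < 0:
            raise ValueError("effect_magnitude must be >= 0")
        if self.reversion_overshoot * self.effect_magnitude >= 1 + self.effect_magnitude:
            raise ValueError("reversion overshoot would drive colonized means negative")
        if any(n <= 0 for n in self.n_individuals_per_pop):
            raise ValueError("both populations need individuals")

    @property
    def frac_null(self) -> float:
        return 1.0 - self.frac_reinforcement - self.frac_reversion


@dataclass
class SyntheticTruth:
    """Planted ground truth: per-gene classes/signs, per-SNP divergence."""

    genes: pd.DataFrame  # index gene; class, magnitude, regulator_sign, is_candidate
    latent_factor: pd.Series | None = None  # per-sample driver of regulator expression
    snps: pd.DataFrame | None = None  # chrom, pos(1-based), fst, in_candidate_flank

    def class_counts(self) -> pd.Series:
        return self.genes["class"].value_counts()


def _stage_mean_matrix(config: SyntheticConfig, classes: np.ndarray, mu: np.ndarray) -> np.ndarray:
    m = config.effect_magnitude
    means = np.tile(mu[:, None], (1, 3))
    rei = classes == "reinforcement"
    rev = classes == "reversion"
    means[rei, 1] = mu[rei] * (1 + m)
    means[rei, 2] = mu[rei] * (1 + 2 * m)
    means[rev, 1] = mu[rev] * (1 + m)
    means[rev, 2] = mu[rev] * (1 + m - config.reversion_overshoot * m)
    return means


def generate_expression(config: SyntheticConfig) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Generate the TPM matrix, sample design and planted gene truth.

    Deterministic given ``config.seed``.  Regulator genes (a configurable
    fraction, random +/- signs) additionally load on a per-sample latent
    factor that later drives the phenotypes, so expression-phenotype
    correlations exist by construction.
    """
    rng = np.random.default_rng(config.seed)
    genes = pd.Index([f"g{i:05d}" for i in range(config.n_genes)], name="gene_id")

    n_rei = int(round(config.frac_reinforcement * config.n_genes))
    n_rev = int(round(config.frac_reversion * config.n_genes))
    classes = np.array(
        ["reinforcement"] * n_rei
        + ["reversion"] * n_rev
        + ["none"] * (config.n_genes - n_rei - n_rev)
    )
    rng.shuffle(classes)
    magnitude = np.where(classes == "none", 0.0, config.effect_magnitude)

    lo, hi = config.mu_range
    mu = np.exp(rng.uniform(np.log(lo), np.log(hi), size=config.n_genes))
    means = _stage_mean_matrix(config, classes, mu)

    # regulator genes load on a shared latent factor
    n_reg = int(round(config.regulator_fraction * config.n_genes))
    reg_idx = rng.choice(config.n_genes, size=n_reg, replace=False)
    signs = np.full(config.n_genes, SIGN_NONE, dtype=object)
    signs[reg_idx] = rng.choice(["positive", "negative"], size=n_reg)

    sample_ids, stages = [], []
    for stage, n in zip(STAGES, config.n_per_stage):
        for k in range(n):
            sample_ids.append(f"{stage[:3]}_{k + 1:02d}")
            stages.append(stage)
    n_samples = len(sample_ids)
    u = rng.standard_normal(n_samples)  # latent phenotype driver

    if config.noise_cv > 0:
        sigma = np.sqrt(np.log1p(config.noise_cv**2))
        noise = rng.lognormal(-(sigma**2) / 2, sigma, size=(config.n_genes, n_samples))
    else:
        noise = np.ones((config.n_genes, n_samples))

    stage_of_sample = np.array([STAGES.index(s) for s in stages])
    values = means[:, stage_of_sample] * noise
    gamma = config.regulator_latent_sd
    if gamma > 0 and n_reg:
        sgn = np.where(signs[reg_idx] == "positive", 1.0, -1.0)
        loading = np.exp(sgn[:, None] * gamma * u[None, :] - (gamma**2) / 2)
        values[reg_idx] *= loading

    design = pd.DataFrame(
        {
            "stage": stages,
            "tissue": config.tissue,
            "individual": [f"ind_{s}" for s in sample_ids],
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    matrix = ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=sample_ids), design
    )
    truth = SyntheticTruth(
        genes=pd.DataFrame(
            {
                "class": classes,
                "magnitude": magnitude,
                "regulator_sign": signs,
                "is_candidate": classes != "none",
            },
            index=genes,
        ),
        latent_factor=pd.Series(u, index=matrix.samples, name="latent"),
    )
    return matrix, truth


def generate_phenotypes(
    truth: SyntheticTruth,
    matrix: ExpressionMatrix,
    config: SyntheticConfig,
    stages=("ancestral", "colonized"),
) -> pd.DataFrame:
    """Phenotypes as sign-weighted sums of standardized regulator expression.

    Each phenotype is coupling * sum(sign_g * z(expr_g)) over regulator
    genes, evaluated on the ancestral and colonized samples (phenotypes
    are not measured at the plastic stage, matching the study design),
    plus Gaussian noise scaled to ``phenotype_noise`` times the signal's
    standard deviation.  Positive regulators therefore correlate
    positively with every phenotype by construction.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    keep = matrix.design.index[matrix.design["stage"].isin(stages)]
    reg = truth.genes.index[truth.genes["regulator_sign"] != SIGN_NONE]
    if len(reg) == 0:
        raise ValueError("no regulator genes planted; raise regulator_fraction")
    X = matrix.values.loc[reg, keep].to_numpy(dtype=float)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    sd[sd == 0] = 1.0
    Z = (X - X.mean(axis=1, keepdims=True)) / sd
    sgn = np.where(truth.genes.loc[reg, "regulator_sign"] == "positive", 1.0, -1.0)
    signal = config.coupling * (sgn[None, :] @ Z).ravel()
    signal_sd = signal.std(ddof=1) if len(keep) > 1 else 1.0
    table = {}
    for k in range(config.n_phenotypes):
        eps = rng.standard_normal(len(keep)) * config.phenotype_noise * signal_sd
        table[f"phenotype_{k + 1}"] = signal + eps
    return pd.DataFrame(table, index=pd.Index(keep, name="sample_id"))


def _annotation(config: SyntheticConfig) -> GeneAnnotation:
    offset = 5000
    starts = offset + np.arange(config.n_genes) * config.gene_spacing
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    strands = rng.choice(["+", "-"], size=config.n_genes)
    genes = pd.DataFrame(
        {
            "gene": [f"g{i:05d}" for i in range(config.n_genes)],
            "chrom": "chr1",
            "start": starts,
            "end": starts + config.gene_length,
            "strand": strands,
        }
    )
    length = int(offset + config.n_genes * config.gene_spacing + FLANK_BP)
    return GeneAnnotation(genes=genes, chrom_lengths={"chr1": length})


def generate_genotypes(
    truth: SyntheticTruth,
    config: SyntheticConfig,
) -> tuple[GenotypeData, GeneAnnotation]:
    """Balding-Nichols genotypes for two populations plus gene annotation.

    Genes sit on one pseudo-chromosome with non-overlapping bodies and
    2 kb flanks; SNP positions are uniform over the chromosome.  SNPs in
    the flanks of candidate genes (planted non-null classes) receive the
    elevated divergence parameter.  Updates ``truth.snps`` in place and
    is deterministic given the config seed.
    """
    annotation = _annotation(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    length = annotation.chrom_lengths["chr1"]
    pos0 = np.sort(rng.choice(length, size=config.n_snps, replace=False))

    candidate = set(truth.genes.index[truth.genes["is_candidate"]])
    flank_iv = []
    for rec in annotation.regions(FLANK_BP).itertuples(index=False):
        if rec.gene in candidate and rec.region in ("upstream", "downstream"):
            flank_iv.append((rec.start, rec.end))
    in_flank = np.zeros(config.n_snps, dtype=bool)
    for s, e in flank_iv:
        in_flank |= (pos0 >= s) & (pos0 < e)

    F = np.where(in_flank, config.fst_candidate_flank, config.fst_background)
    p_anc = rng.uniform(0.05, 0.95, size=config.n_snps)
    alpha = p_anc * (1 - F) / F
    beta = (1 - p_anc) * (1 - F) / F
    n1, n2 = config.n_individuals_per_pop
    freq1 = rng.beta(alpha, beta)
    freq2 = rng.beta(alpha, beta)
    g1 = rng.binomial(2, freq1[:, None], size=(config.n_snps, n1))
    g2 = rng.binomial(2, freq2[:, None], size=(config.n_snps, n2))

    bases = np.array(["A", "C", "G", "T"])
    ref_i = rng.integers(0, 4, size=config.n_snps)
    alt_i = (ref_i + rng.integers(1, 4, size=config.n_snps)) % 4

    genotypes = GenotypeData(
        chrom=np.repeat("chr1", config.n_snps),
        pos=pos0 + 1,  # VCF 1-based
        ref=bases[ref_i],
        alt=bases[alt_i],
        genotypes=np.hstack([g1, g2]).astype(np.int8),
        samples=[f"low_{i + 1:02d}" for i in range(n1)]
        + [f"high_{i + 1:02d}" for i in range(n2)],
        populations=np.array(["lowland"] * n1 + ["highland"] * n2),
    )
    truth.snps = pd.DataFrame(
        {
            "chrom": "chr1",
            "pos": pos0 + 1,
            "fst": F,
            "in_candidate_flank": in_flank,
        }
    )
    return genotypes, annotation


# ---------------------------------------------------------------- writers


def write_expression_tsv(matrix: ExpressionMatrix, expr_path, sheet_path) -> None:
    df = matrix.values.copy()
    df.index.name = "gene_id"
    df.to_csv(expr_path, sep="\t")
    sheet = matrix.design.reset_index().rename(columns={"index": "sample_id"})
    sheet.to_csv(sheet_path, sep="\t", index=False)


def write_phenotypes_tsv(phenotypes: pd.DataFrame, path) -> None:
    phenotypes.to_csv(path, sep="\t")


def write_truth_tsv(truth: SyntheticTruth, path) -> None:
    truth.genes.to_csv(path, sep="\t")


def write_bed(annotation: GeneAnnotation, path) -> None:
    with open(path, "w") as fh:
        for rec in annotation.genes.itertuples(index=False):
            fh.write(
                f"{rec.chrom}\t{rec.start}\t{rec.end}\t{rec.gene}\t0\t{rec.strand}\n"
            )


def write_pop_map(genotypes: GenotypeData, path) -> None:
    with open(path, "w") as fh:
        for s, p in zip(genotypes.samples, genotypes.populations):
            fh.write(f"{s}\t{p}\n")


def write_vcf(genotypes: GenotypeData, path) -> None:
    """Write a minimal VCF v4.2 with GT-only genotype fields."""
    gt_strings = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}
    contigs = pd.unique(genotypes.chrom)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=plastevo-synthetic\n")
        for c in contigs:
            cmax = int(genotypes.pos[genotypes.chrom == c].max()) + FLANK_BP
            fh.write(f"##contig=<ID={c},length={cmax}>\n")
        fh.write('##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS mapping quality">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(genotypes.samples)
            + "\n"
        )
        for i in range(genotypes.n_snps):
            gts = "\t".join(gt_strings[int(g)] for g in genotypes.genotypes[i])
            fh.write(
                f"{genotypes.chrom[i]}\t{genotypes.pos[i]}\tsnp{i:06d}\t"
                f"{genotypes.ref[i]}\t{genotypes.alt[i]}\t60\tPASS\tMQ=60\tGT\t{gts}\n"
            )


def generate_dataset(config: SyntheticConfig, outdir) -> dict[str, Path]:
    """Generate and write the full synthetic input bundle; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    matrix, truth = generate_expression(config)
    phenotypes = generate_phenotypes(truth, matrix, config)
    genotypes, annotation = generate_genotypes(truth, config)
    paths = {
        "expression": outdir / "expression.tsv",
        "sample_sheet": outdir / "samples.tsv",
        "phenotypes": outdir / "phenotypes.tsv",
        "vcf": outdir / "variants.vcf",
        "bed": outdir / "genes.bed",
        "pop_map": outdir / "pop_map.tsv",
        "truth": outdir / "truth.tsv",
    }
    write_expression_tsv(matrix, paths["expression"], paths["sample_sheet"])
    write_phenotypes_tsv(phenotypes, paths["phenotypes"])
    write_vcf(genotypes, paths["vcf"])
    write_bed(annotation, paths["bed"])
    write_pop_map(genotypes, paths["pop_map"])
    write_truth_tsv(truth, paths["truth"])
    return paths
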