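"""Weir-Cockerham FST, gene/flank region assignment and the permutation test.

Genetic divergence between the ancestral (lowland) and colonized
(highland) populations is measured with the Weir & Cockerham (1984)
variance-component estimator theta = a / (a + b + c) per biallelic SNP,
averaged as the ratio-of-sums Sigma(a) / Sigma(a+b+c) ("weighted" FST,
the convention vcftools prints).  Candidate gene sets are compared with a
genic background by resampling: the empirical mean FST over the SNPs of
a candidate region set is compared with the distribution of mean FST
over repeated random draws of (approximately) the same number of SNPs
from the background pool.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

FLANK_BP = 2000

REGION_GENIC = "genic"
REGION_UPSTREAM = "upstream"
REGION_DOWNSTREAM = "downstream"
REGION_TYPES = (REGION_GENIC, REGION_UPSTREAM, REGION_DOWNSTREAM)


class PopgenError(ValueError):
    """Raised for malformed variant or annotation inputs."""


@dataclass
class GenotypeData:
    """Biallelic SNP dosages for two labelled populations.

    ``genotypes`` holds alt-allele dosage (0/1/2) per SNP x individual,
    with -1 for missing calls.  ``populations`` labels each individual
    column; exactly two non-empty populations are required.
    """

    chrom: np.ndarray  # str per SNP
    pos: np.ndarray  # int, 1-based as in VCF
    ref: np.ndarray
    alt: np.ndarray
    genotypes: np.ndarray  # (n_snps, n_individuals) int8 dosage, -1 missing
    samples: list[str]
    populations: np.ndarray  # str per individual
    filter_log: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        pops = pd.unique(self.populations)
        if len(pops) != 2:
            raise PopgenError(f"exactly two populations required, got {list(pops)}")
        for p in pops:
            if (self.populations == p).sum() == 0:
                raise PopgenError(f"population {p} is empty")

    @property
    def n_snps(self) -> int:
        return len(self.pos)

    @property
    def pop_names(self) -> tuple[str, str]:
        names = pd.unique(self.populations)
        return (names[0], names[1])

    def pop_columns(self, pop: str) -> np.ndarray:
        return np.flatnonzero(self.populations == pop)


@dataclass
class GeneAnnotation:
    """Gene intervals on 0-based half-open coordinates with 2 kb flanks.

    ``genes`` has columns ``gene``, ``chrom``, ``start``, ``end``,
    ``strand``.  Upstream/downstream are strand-aware 2 kb windows,
    truncated at position 0 (and at chromosome ends when lengths are
    known).
    """

    genes: pd.DataFrame
    chrom_lengths: dict[str, int] | None = None

    def __post_init__(self) -> None:
        required = {"gene", "chrom", "start", "end", "strand"}
        if not required.issubset(self.genes.columns):
            raise PopgenError(f"annotation needs columns {sorted(required)}")
        if (self.genes["end"] <= self.genes["start"]).any():
            raise PopgenError("gene end must exceed start (0-based half-open)")

    def regions(self, flank: int = FLANK_BP) -> pd.DataFrame:
        """Tidy table of (gene, region, chrom, start, end) intervals."""
        rows = []
        for rec in self.genes.itertuples(index=False):
            clen = (self.chrom_lengths or {}).get(rec.chrom)
            body = (rec.start, rec.end)
            left = (max(0, rec.start - flank), rec.start)
            right = (rec.end, rec.end + flank if clen is None else min(clen, rec.end + flank))
            if rec.strand == "-":
                up, down = right, left
            else:
                up, down = left, right
            for region, (s, e) in (
                (REGION_GENIC, body),
                (REGION_UPSTREAM, up),
                (REGION_DOWNSTREAM, down),
            ):
                if e > s:
                    rows.append((rec.gene, region, rec.chrom, int(s), int(e)))
        return pd.DataFrame(rows, columns=["gene", "region", "chrom", "start", "end"])


def read_annotation_bed(path) -> GeneAnnotation:
    """Read a BED6 file of gene bodies (chrom, start, end, name, score, strand)."""
    bed = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        names=["chrom", "start", "end", "gene", "score", "strand"],
        dtype={"chrom": str},
    )
    return GeneAnnotation(
        genes=bed[["gene", "chrom", "start", "end", "strand"]].copy()
    )


def read_pop_map(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", header=None, names=["sample_id", "population"])
    return dict(zip(df["sample_id"].astype(str), df["population"].astype(str)))


def read_variants(
    vcf_path,
    pop_map: dict[str, str],
    qual_min: float = 30.0,
    mq_min: float = 20.0,
    min_spacing: int = 5,
) -> GenotypeData:
    """Read biallelic SNPs from a VCF with site filters.

    Sites failing QUAL >= ``qual_min``, INFO/MQ >= ``mq_min`` (when MQ is
    present) or closer than ``min_spacing`` bp to the previously kept SNP
    (the first of a close pair wins) are dropped; multiallelic and
    non-SNP records are dropped and counted in ``filter_log``.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path), gts012=True)
    samples = list(vcf.samples)
    missing = set(pop_map) - set(samples)
    if missing:
        raise PopgenError(f"pop map samples absent from VCF: {sorted(missing)}")
    keep_cols = [i for i, s in enumerate(samples) if s in pop_map]
    kept_samples = [samples[i] for i in keep_cols]
    pops = np.array([pop_map[s] for s in kept_samples])

    chroms, poss, refs, alts, rows = [], [], [], [], []
    log = {"multiallelic_or_non_snp": 0, "low_qual": 0, "low_mq": 0, "spacing": 0, "kept": 0}
    last_kept: dict[str, int] = {}
    for v in vcf:
        if len(v.ALT) != 1 or not v.is_snp:
            log["multiallelic_or_non_snp"] += 1
            continue
        if v.QUAL is not None and v.QUAL < qual_min:
            log["low_qual"] += 1
            continue
        mq = v.INFO.get("MQ")
        if mq is not None and mq < mq_min:
            log["low_mq"] += 1
            continue
        prev = last_kept.get(v.CHROM)
        if prev is not None and v.POS - prev < min_spacing:
            log["spacing"] += 1
            continue
        gts = v.genotype.array()
        if gts.shape[1] - 1 != 2:  # last column is phasing flag
            raise PopgenError(f"non-diploid genotype at {v.CHROM}:{v.POS}")
        # gts012: 0,1,2 dosage; 3 = unknown
        dosage = np.asarray(v.gt_types, dtype=np.int8)[keep_cols]
        dosage[dosage == 3] = -1
        last_kept[v.CHROM] = v.POS
        chroms.append(v.CHROM)
        poss.append(v.POS)
        refs.append(v.REF)
        alts.append(v.ALT[0])
        rows.append(dosage)
        log["kept"] += 1
    if not rows:
        raise PopgenError("no SNPs passed the filters")
    return GenotypeData(
        chrom=np.array(chroms),
        pos=np.array(poss, dtype=np.int64),
        ref=np.array(refs),
        alt=np.array(alts),
        genotypes=np.vstack(rows),
        samples=kept_samples,
        populations=pops,
        filter_log=log,
    )


def wc_fst_site(p1, h1, n1, p2, h2, n2):
    """Weir-Cockerham (1984) variance components for one site, two populations.

    Parameters are per-population alt-allele frequency ``p``, observed
    heterozygote proportion ``h`` and diploid sample size ``n``.  Returns
    (a, b, c, theta) where ``a`` is the among-population component, ``b``
    among individuals within populations, ``c`` within individuals, and
    theta = a/(a+b+c).  Sites monomorphic in the pooled sample (or with an
    empty population) return NaN for all four values; callers exclude
    them from averages.  Accepts scalars or aligned arrays.
    """
    p1, h1, n1, p2, h2, n2 = (np.asarray(x, dtype=float) for x in (p1, h1, n1, p2, h2, n2))
    r = 2.0
    n_bar = (n1 + n2) / r
    with np.errstate(invalid="ignore", divide="ignore"):
        p_bar = (n1 * p1 + n2 * p2) / (r * n_bar)
        s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1.0) * n_bar)
        h_bar = (n1 * h1 + n2 * h2) / (r * n_bar)
        n_c = (r * n_bar - (n1**2 + n2**2) / (r * n_bar)) / (r - 1.0)
        a = (n_bar / n_c) * (
            s2 - (1.0 / (n_bar - 1.0)) * (p_bar * (1.0 - p_bar) - s2 * (r - 1.0) / r - h_bar / 4.0)
        )
        b = (n_bar / (n_bar - 1.0)) * (
            p_bar * (1.0 - p_bar) - s2 * (r - 1.0) / r - h_bar * (2.0 * n_bar - 1.0) / (4.0 * n_bar)
        )
        c = h_bar / 2.0
        total = a + b + c
        theta = a / total
    undefined = (n1 < 1) | (n2 < 1) | (p_bar <= 0) | (p_bar >= 1)
    a = np.where(undefined, np.nan, a)
    b = np.where(undefined, np.nan, b)
    c = np.where(undefined, np.nan, c)
    theta = np.where(undefined | ~np.isfinite(theta), np.nan, theta)
    if a.ndim == 0:
        return float(a), float(b), float(c), float(theta)
    return a, b, c, theta


def site_components(genotypes: GenotypeData):
    """Per-site WC84 components (a, b, c, theta) from dosage data.

    Missing genotypes are excluded per site from the frequency,
    heterozygosity and sample-size terms of each population.
    """
    pop1, pop2 = genotypes.pop_names
    out = []
    for pop in (pop1, pop2):
        G = genotypes.genotypes[:, genotypes.pop_columns(pop)].astype(float)
        called = G >= 0
        n = called.sum(axis=1).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(n > 0, np.where(called, G, 0).sum(axis=1) / (2.0 * n), np.nan)
            h = np.where(n > 0, np.where(called, G == 1, False).sum(axis=1) / n, np.nan)
        out.append((p, h, n))
    (p1, h1, n1), (p2, h2, n2) = out
    return wc_fst_site(p1, h1, n1, p2, h2, n2)


def mean_fst(a, b, c, method: str = "weighted") -> float:
    """Average FST over sites with defined components.

    ``weighted`` is the ratio of sums Sigma(a)/Sigma(a+b+c) (vcftools'
    weighted FST); ``mean`` averages the per-site ratios.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    c = np.asarray(c, dtype=float)
    ok = np.isfinite(a) & np.isfinite(b) & np.isfinite(c)
    if not ok.any():
        raise PopgenError("no sites with defined FST")
    if method == "weighted":
        return float(a[ok].sum() / (a[ok] + b[ok] + c[ok]).sum())
    if method == "mean":
        with np.errstate(invalid="ignore", divide="ignore"):
            theta = a[ok] / (a[ok] + b[ok] + c[ok])
        return float(np.nanmean(theta))
    raise ValueError("method must be 'weighted' or 'mean'")


def assign_regions(
    annotation: GeneAnnotation,
    genotypes: GenotypeData,
    flank: int = FLANK_BP,
) -> pd.DataFrame:
    """Map each SNP to every (gene, region) interval containing it.

    Positions are converted from the VCF's 1-based convention to 0-based
    before interval lookup; a SNP inside several genes' intervals appears
    once per hit.  Returns columns ``snp_index``, ``gene``, ``region``.
    """
    trees: dict[str, IntervalTree] = {}
    for rec in annotation.regions(flank).itertuples(index=False):
        trees.setdefault(rec.chrom, IntervalTree()).addi(
            rec.start, rec.end, (rec.gene, rec.region)
        )
    rows = []
    for i, (chrom, pos1) in enumerate(zip(genotypes.chrom, genotypes.pos)):
        tree = trees.get(str(chrom))
        if tree is None:
            continue
        for hit in tree[int(pos1) - 1]:
            gene, region = hit.data
            rows.append((i, gene, region))
    df = pd.DataFrame(rows, columns=["snp_index", "gene", "region"])
    return df.sort_values(["snp_index", "gene", "region"]).reset_index(drop=True)


@dataclass
class FstPermResult:
    """Permutation-test outcome for one candidate region set."""

    label: str
    region: str
    n_candidate: int
    empirical: float
    permuted: np.ndarray
    p: float
    significant: bool

    def to_dict(self) -> dict:
        q = np.percentile(self.permuted, [5, 50, 95])
        return {
            "label": self.label,
            "region": self.region,
            "n_candidate": self.n_candidate,
            "empirical_fst": self.empirical,
            "permuted_q05": float(q[0]),
            "permuted_median": float(q[1]),
            "permuted_q95": float(q[2]),
            "p": self.p,
            "significant": bool(self.significant),
        }


def fst_permutation_test(
    a,
    b,
    c,
    candidate_idx,
    background_idx,
    n_perm: int = 100,
    fluctuation: float = 0.05,
    seed: int = 0,
    exclude_candidates: bool = True,
    label: str = "candidate",
    region: str = "",
) -> FstPermResult:
    """Compare candidate-set mean FST with random background draws.

    Each of ``n_perm`` replicates draws N' SNPs without replacement from
    the background pool, N' uniform on [ceil((1-f)N), floor((1+f)N)]
    where N is the candidate SNP count and f the allowed fluctuation,
    and records the weighted mean FST.  The empirical p-value uses the
    add-one convention (1 + #{permuted >= empirical}) / (n_perm + 1); the
    significance flag follows the percentile rule: empirical strictly
    above the 95th percentile of the permuted distribution.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    c = np.asarray(c, dtype=float)
    candidate_idx = np.asarray(candidate_idx, dtype=int)
    background_idx = np.asarray(background_idx, dtype=int)
    if candidate_idx.size == 0:
        raise PopgenError("candidate SNP set is empty")
    pool = background_idx
    if exclude_candidates:
        pool = np.setdiff1d(pool, candidate_idx)
    n = candidate_idx.size
    lo = int(np.ceil((1.0 - fluctuation) * n))
    hi = int(np.floor((1.0 + fluctuation) * n))
    lo = max(lo, 1)
    if pool.size < hi:
        raise PopgenError(
            f"background pool ({pool.size}) smaller than the largest draw ({hi}); "
            "use fewer candidates or fluctuation=0"
        )
    empirical = mean_fst(a[candidate_idx], b[candidate_idx], c[candidate_idx])
    rng = np.random.default_rng(seed)
    permuted = np.empty(n_perm)
    for k in range(n_perm):
        size = int(rng.integers(lo, hi + 1))
        take = np.sort(rng.choice(pool, size=size, replace=False))
        permuted[k] = mean_fst(a[take], b[take], c[take])
    p = float((1 + (permuted >= empirical).sum()) / (n_perm + 1))
    significant = bool(empirical > np.percentile(permuted, 95))
    return FstPermResult(
        label=label,
        region=region,
        n_candidate=int(n),
        empirical=empirical,
        permuted=permuted,
        p=p,
        significant=significant,
    )


def fst_region_tests(
    genotypes: GenotypeData,
    annotation: GeneAnnotation,
    candidate_genes,
    n_perm: int = 100,
    fluctuation: float = 0.05,
    seed: int = 0,
    label: str = "candidate",
    flank: int = FLANK_BP,
) -> list[FstPermResult]:
    """Run the permutation test separately for genic, upstream and downstream SNPs.

    The background pool is the union of all genes' genic + flank SNPs
    (deduplicated); each region type's candidate SNPs are those falling
    in that region of any candidate gene.
    """
    a, b, c, _ = site_components(genotypes)
    mapping = assign_regions(annotation, genotypes, flank)
    background = np.unique(mapping["snp_index"].to_numpy())
    candidate_genes = set(candidate_genes)
    results = []
    for region in REGION_TYPES:
        cand = np.unique(
            mapping.loc[
                (mapping["region"] == region) & mapping["gene"].isin(candidate_genes),
                "snp_index",
            ].to_numpy()
        )
        if cand.size == 0:
            continue
        results.append(
            fst_permutation_test(
                a,
                b,
                c,
                cand,
                background,
                n_perm=n_perm,
                fluctuation=fluctuation,
                seed=seed,
                label=label,
                region=region,
            )
        )
    return results
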