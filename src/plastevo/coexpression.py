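"""Stage-associated co-expression modules, eigengenes and hub genes.

A light-weight correlation-network analysis: gene significance (GS) is the
absolute Pearson correlation between a gene's expression and a numeric
stage code; modules come from average-linkage clustering of the
1 - |r|^beta dissimilarity; each module is summarized by its eigengene
(first principal component of the per-gene standardized submatrix);
highly correlated modules are merged; modules whose eigengene tracks the
stage code are reported as stage-associated; and hub genes are the
members of stage-associated modules with GS above the first quartile and
a significant stage correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from ._stats import pearson_rows
from .expression import STAGES, ExpressionMatrix

UNASSIGNED = "unassigned"

DEFAULT_STAGE_CODING = {"ancestral": 0.0, "plastic": 1.0, "colonized": 2.0}


def _stage_codes(matrix: ExpressionMatrix, stage_coding=None) -> np.ndarray:
    coding = DEFAULT_STAGE_CODING if stage_coding is None else dict(stage_coding)
    missing = set(matrix.design["stage"]) - set(coding)
    if missing:
        raise ValueError(f"stage coding missing stages: {sorted(missing)}")
    return matrix.design["stage"].map(coding).to_numpy(dtype=float)


def gene_significance(matrix: ExpressionMatrix, stage_coding=None) -> pd.DataFrame:
    """GS = |Pearson r| between each gene and the numeric stage code.

    Zero-variance genes get GS = 0 with p = 1.  Requires >= 3 samples.
    """
    if len(matrix.samples) < 3:
        raise ValueError("gene significance needs at least 3 samples")
    codes = _stage_codes(matrix, stage_coding)
    r, p = pearson_rows(matrix.values.to_numpy(), codes)
    gs = np.abs(r)
    flat = ~np.isfinite(r)
    gs[flat] = 0.0
    p = np.where(flat, 1.0, p)
    return pd.DataFrame({"GS": gs, "p": p}, index=matrix.genes)


@dataclass
class ModuleAssignment:
    """Per-gene module labels; modules below the size minimum are unassigned."""

    labels: pd.Series  # gene -> module label or "unassigned"
    min_size: int

    @property
    def modules(self) -> list[str]:
        return sorted(
            set(self.labels) - {UNASSIGNED},
            key=lambda m: (-int((self.labels == m).sum()), m),
        )

    def members(self, module: str) -> pd.Index:
        return self.labels.index[self.labels == module]

    def sizes(self) -> pd.Series:
        return self.labels[self.labels != UNASSIGNED].value_counts()


def detect_modules(
    matrix: ExpressionMatrix,
    beta: float = 6.0,
    min_size: int = 30,
    cut_height: float = 0.25,
) -> ModuleAssignment:
    """Cluster genes by signed-free co-expression adjacency |r|^beta.

    Dissimilarity 1 - |r|^beta feeds average-linkage hierarchical
    clustering, cut at ``cut_height``; clusters smaller than ``min_size``
    are left unassigned.  ``beta`` plays the role of a soft-threshold
    power: it suppresses weak correlations so that the dendrogram's
    branches reflect strongly co-expressed sets.
    """
    if beta <= 0:
        raise ValueError("beta must be > 0")
    X = matrix.values.to_numpy(dtype=float)
    if X.shape[0] < min_size:
        raise ValueError(f"need at least min_size={min_size} genes")
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(X)
    corr = np.nan_to_num(corr, nan=0.0)  # zero-variance genes join nothing
    np.fill_diagonal(corr, 1.0)
    dissim = 1.0 - np.abs(corr) ** beta
    np.fill_diagonal(dissim, 0.0)
    dissim = (dissim + dissim.T) / 2
    Z = hierarchy.linkage(squareform(dissim, checks=False), method="average")
    flat = hierarchy.fcluster(Z, t=cut_height, criterion="distance")
    labels = pd.Series(UNASSIGNED, index=matrix.genes, dtype=object)
    sizes = pd.Series(flat).value_counts()
    kept = sizes[sizes >= min_size].sort_values(ascending=False)
    for rank, cluster_id in enumerate(kept.index, start=1):
        labels.iloc[np.flatnonzero(flat == cluster_id)] = f"M{rank}"
    return ModuleAssignment(labels=labels, min_size=min_size)


def module_eigengene(matrix: ExpressionMatrix, genes) -> pd.Series:
    """First principal component of the per-gene standardized submatrix.

    Returned as a unit-norm per-sample vector with its sign fixed so that
    it correlates non-negatively with the module's mean standardized
    profile; per-gene z-scoring makes the eigengene invariant to
    rescaling any single gene.
    """
    genes = pd.Index(genes)
    if len(genes) < 2:
        raise ValueError("a module eigengene needs >= 2 genes")
    sub = matrix.values.loc[genes].to_numpy(dtype=float)
    sd = sub.std(axis=1, ddof=1, keepdims=True)
    sd[sd == 0] = 1.0
    Z = (sub - sub.mean(axis=1, keepdims=True)) / sd
    # first left singular vector of samples x genes
    u, s, vt = np.linalg.svd(Z.T, full_matrices=False)
    eig = u[:, 0]
    mean_profile = Z.mean(axis=0)
    if float(eig @ mean_profile) < 0:
        eig = -eig
    return pd.Series(eig, index=matrix.samples, name="eigengene")


def module_eigengenes(matrix: ExpressionMatrix, modules: ModuleAssignment) -> pd.DataFrame:
    return pd.DataFrame(
        {m: module_eigengene(matrix, modules.members(m)) for m in modules.modules}
    )


@dataclass
class StageAssociation:
    """Merged modules and their eigengene-stage correlations."""

    modules: ModuleAssignment
    eigengenes: pd.DataFrame  # samples x modules
    stats: pd.DataFrame  # module -> r, p, associated

    @property
    def associated(self) -> list[str]:
        return list(self.stats.index[self.stats["associated"]])


def merge_and_associate(
    matrix: ExpressionMatrix,
    modules: ModuleAssignment,
    stage_coding=None,
    merge_p: float = 0.1,
    assoc_p: float = 0.01,
) -> StageAssociation:
    """Merge highly correlated modules, then test eigengene-stage association.

    Pairs of modules whose eigengene correlation has p < ``merge_p`` are
    merged iteratively (smallest p first, eigengenes recomputed after each
    merge).  A module is stage-associated when its eigengene's Pearson
    correlation with the stage code has p < ``assoc_p``.
    """
    codes = _stage_codes(matrix, stage_coding)
    labels = modules.labels.copy()
    current = ModuleAssignment(labels=labels, min_size=modules.min_size)

    while True:
        mods = current.modules
        if len(mods) < 2:
            break
        eig = module_eigengenes(matrix, current)
        best = None
        for i in range(len(mods)):
            for j in range(i + 1, len(mods)):
                r, p = pearson_rows(eig[mods[i]].to_numpy()[None, :], eig[mods[j]].to_numpy())
                p = float(p[0])
                if np.isfinite(p) and p < merge_p and (best is None or p < best[0]):
                    best = (p, mods[i], mods[j])
        if best is None:
            break
        _, keep, drop = best
        labels[labels == drop] = keep
        current = ModuleAssignment(labels=labels, min_size=modules.min_size)

    # relabel merged modules by size
    relabel = {m: f"M{i}" for i, m in enumerate(current.modules, start=1)}
    labels = labels.map(lambda m: relabel.get(m, UNASSIGNED))
    current = ModuleAssignment(labels=labels, min_size=modules.min_size)

    eig = module_eigengenes(matrix, current)
    rows = []
    for m in current.modules:
        r, p = pearson_rows(eig[m].to_numpy()[None, :], codes)
        rows.append({"module": m, "r": float(r[0]), "p": float(p[0])})
    stats = pd.DataFrame(rows).set_index("module") if rows else pd.DataFrame(
        columns=["r", "p"]
    )
    stats["associated"] = stats["p"] < assoc_p if len(stats) else pd.Series(dtype=bool)
    return StageAssociation(modules=current, eigengenes=eig, stats=stats)


def hub_genes(
    gs: pd.DataFrame,
    assoc: StageAssociation,
    alpha: float = 0.05,
    quartile_scope: str = "associated",
) -> pd.Index:
    """Hub genes: members of stage-associated modules with high GS.

    A hub gene has GS strictly greater than the first quartile of GS
    (linear-interpolation quartile over the scope population, by default
    the genes of the stage-associated modules) and stage-correlation
    p < ``alpha``.
    """
    assoc_modules = assoc.associated
    if not assoc_modules:
        return pd.Index([], dtype=object)
    member_idx = assoc.modules.labels.index[
        assoc.modules.labels.isin(assoc_modules)
    ]
    if quartile_scope == "associated":
        pool = gs.loc[member_idx, "GS"]
    elif quartile_scope == "all":
        pool = gs["GS"]
    else:
        raise ValueError("quartile_scope must be 'associated' or 'all'")
    q1 = float(np.quantile(pool.to_numpy(), 0.25))
    sub = gs.loc[member_idx]
    return sub.index[(sub["GS"] > q1) & (sub["p"] < alpha)]
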