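"""Phenotype-correlated regulators and adaptive/maladaptive plasticity calls.

A gene is a *positive regulator* of a muscle phenotype (e.g. capillaries
per fiber, fiber area, capillary density) when its expression correlates
positively with the phenotype across the ancestral and colonized
individuals at p < alpha, and a *negative regulator* when the correlation
is negative.  Because the measured phenotypic shifts in colonized birds
improve oxygen delivery, a plastic expression change whose direction
matches the regulator's sign expectation (up for positive regulators,
down for negative ones) is called *adaptive*; a change that opposes it is
*maladaptive*.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._stats import pearson_rows
from .expression import ExpressionMatrix
from .plasticity import binomial_excess_test

ADAPTIVE = "adaptive"
MALADAPTIVE = "maladaptive"
NONE = "none"


def phenotype_correlation(
    matrix: ExpressionMatrix,
    phenotypes: pd.DataFrame,
    samples=None,
    stages=("ancestral", "colonized"),
) -> pd.DataFrame:
    """Pearson r and two-sided p per gene x phenotype pair.

    Phenotypes were measured on the ancestral and colonized individuals,
    so the correlation is computed over those samples by default; pass
    ``samples`` to override.  Zero-variance genes or phenotypes are
    excluded from the result.
    """
    if samples is None:
        keep = matrix.design.index[matrix.design["stage"].isin(stages)]
        samples = keep.intersection(phenotypes.index)
    else:
        samples = pd.Index(samples)
    missing = pd.Index(samples).difference(phenotypes.index)
    if len(missing):
        raise ValueError(f"samples missing from phenotype table: {sorted(missing)}")
    missing = pd.Index(samples).difference(matrix.samples)
    if len(missing):
        raise ValueError(f"samples missing from expression matrix: {sorted(missing)}")
    if len(samples) < 3:
        raise ValueError("need >= 3 samples with both expression and phenotypes")

    X = matrix.values.loc[:, samples].to_numpy(dtype=float)
    rows = []
    for pheno in phenotypes.columns:
        y = phenotypes.loc[samples, pheno].to_numpy(dtype=float)
        if np.std(y) == 0:
            continue
        r, p = pearson_rows(X, y)
        ok = np.isfinite(r)
        rows.append(
            pd.DataFrame(
                {
                    "gene": matrix.genes[ok],
                    "phenotype": pheno,
                    "r": r[ok],
                    "p": p[ok],
                    "n": len(samples),
                }
            )
        )
    if not rows:
        return pd.DataFrame(columns=["gene", "phenotype", "r", "p", "n"])
    return pd.concat(rows, ignore_index=True)


def classify_regulators(correlations: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Assign a regulator sign per significant gene x phenotype pair.

    Returns the correlation table restricted to p < alpha with a ``sign``
    column ("positive"/"negative").  ``DataFrame.attrs["conflicts"]``
    lists genes significant for several phenotypes with opposite signs.
    """
    sig = correlations[correlations["p"] < alpha].copy()
    sig["sign"] = np.where(sig["r"] > 0, "positive", "negative")
    per_gene = sig.groupby("gene")["sign"].nunique()
    conflicts = list(per_gene.index[per_gene > 1])
    sig.attrs["conflicts"] = conflicts
    return sig


def regulator_summary(regulator_calls: pd.DataFrame) -> pd.DataFrame:
    """One row per regulator gene, using the phenotype with smallest p.

    Genes whose significant phenotypes disagree in sign keep the
    smallest-p call but are flagged in the ``conflict`` column.
    """
    if len(regulator_calls) == 0:
        return pd.DataFrame(columns=["phenotype", "r", "p", "sign", "conflict"])
    best = regulator_calls.sort_values(["p", "phenotype"]).groupby("gene").first()
    nsigns = regulator_calls.groupby("gene")["sign"].nunique()
    best["conflict"] = nsigns.reindex(best.index) > 1
    return best[["phenotype", "r", "p", "sign", "conflict"]]


def classify_adaptive(calls: pd.DataFrame, regulators: pd.DataFrame) -> pd.DataFrame:
    """Adaptive/maladaptive labels for regulator genes with excess plastic change.

    ``calls`` is the plasticity classification table (needs ``PC`` and
    ``excess_plastic``); ``regulators`` is a :func:`regulator_summary`
    table.  A regulator with an excess plastic change is *adaptive* when
    the change's direction matches its sign (positive & PC > 0, or
    negative & PC < 0) and *maladaptive* when it opposes it; regulators
    without an excess plastic change get "none".
    """
    merged = regulators.join(calls[["PC", "excess_plastic"]], how="inner")
    pc = merged["PC"].to_numpy(dtype=float)
    pos = (merged["sign"] == "positive").to_numpy()
    excess = merged["excess_plastic"].to_numpy(dtype=bool)
    label = np.full(len(merged), NONE, dtype=object)
    match = (pos & (pc > 0)) | (~pos & (pc < 0))
    oppose = (pos & (pc < 0)) | (~pos & (pc > 0))
    label[excess & match] = ADAPTIVE
    label[excess & oppose] = MALADAPTIVE
    merged["adaptive"] = label
    return merged


def adaptive_excess_test(adaptive_calls: pd.DataFrame, p0: float = 0.5) -> dict:
    """Binomial test of maladaptive vs adaptive counts."""
    k_mal = int((adaptive_calls["adaptive"] == MALADAPTIVE).sum())
    k_ada = int((adaptive_calls["adaptive"] == ADAPTIVE).sum())
    if k_mal + k_ada == 0:
        return {"maladaptive": 0, "adaptive": 0, "p": None}
    return {
        "maladaptive": k_mal,
        "adaptive": k_ada,
        "p": binomial_excess_test(k_mal, k_ada, p0),
    }
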