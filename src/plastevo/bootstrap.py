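"""Parametric-bootstrap support for reinforcement/reversion calls.

Stage means are estimates from few individuals, so a classification can be
an artifact of sampling error.  For each gene and each of ``n_rep``
replicates, one value per stage is drawn from a Gaussian with mean equal
to the observed stage mean and standard deviation equal to that stage's
standard error, and the replicate triple is reclassified.  A call is
*supported* when at least ``support_min`` replicates (default 950 of
1000, a p<0.05-style guard) reproduce the gene's point-estimate class.
"""

from __future__ import annotations

import zlib

import numpy as np
import pandas as pd

from .expression import GeneStageSummary
from .plasticity import CLASS_NONE, _CLASS_LABELS, _classify_arrays, classify_plasticity

#: maximum rounds of redrawing replicates whose ancestral draw is <= 0
MAX_REDRAW_ROUNDS = 100


def _gene_rng(seed: int, gene_id: str) -> np.random.Generator:
    # stable per-gene substream: independent of gene order in the table
    return np.random.default_rng([seed, zlib.crc32(str(gene_id).encode())])


def bootstrap_support(
    summary: GeneStageSummary,
    tau: float = 0.5,
    n_rep: int = 1000,
    support_min: int = 950,
    seed: int = 0,
    mode: str = "point-class",
) -> pd.DataFrame:
    """Bootstrap support counts for every gene's plasticity class.

    Parameters
    ----------
    mode
        ``"point-class"`` counts replicates reproducing the gene's exact
        point-estimate class; ``"any"`` counts replicates landing in
        either the reinforcement or the reversion class (only meaningful
        for genes whose point class is not "none").

    Returns
    -------
    DataFrame indexed by gene with columns ``class`` (point estimate),
    ``support`` and ``supported``.  Deterministic given ``seed`` and
    invariant to gene order (each gene owns a substream keyed on its id).

    Notes
    -----
    Gaussian draws can be negative; replicates are classified as drawn,
    except that an ancestral draw <= 0 leaves the relative threshold
    undefined, so such replicates are redrawn wholly (all three stages).
    Redrawing is bounded at :data:`MAX_REDRAW_ROUNDS` rounds; a replicate
    still invalid after that is counted as not reproducing the class.
    """
    if n_rep < 1:
        raise ValueError("n_rep must be >= 1")
    if support_min > n_rep:
        raise ValueError("support_min cannot exceed n_rep")
    if mode not in ("point-class", "any"):
        raise ValueError("mode must be 'point-class' or 'any'")

    point = classify_plasticity(summary, tau)
    means = summary.mean[["ancestral", "plastic", "colonized"]].to_numpy()
    ses = summary.se[["ancestral", "plastic", "colonized"]].to_numpy()
    point_cls = point["class"].to_numpy()

    support = np.zeros(len(summary.genes), dtype=int)
    for i, gene in enumerate(summary.genes):
        rng = _gene_rng(seed, gene)
        mu, sd = means[i], ses[i]
        draws = rng.normal(mu, sd, size=(n_rep, 3))
        if mu[0] > 0:
            # ancestral draws <= 0 invalidate the relative threshold
            bad = draws[:, 0] <= 0
            rounds = 0
            while bad.any() and rounds < MAX_REDRAW_ROUNDS:
                draws[bad] = rng.normal(mu, sd, size=(int(bad.sum()), 3))
                bad = draws[:, 0] <= 0
                rounds += 1
        else:
            bad = np.ones(n_rep, dtype=bool)
        cls, _, _, _ = _classify_arrays(draws[:, 0], draws[:, 1], draws[:, 2], tau)
        labels = _CLASS_LABELS[cls]
        labels[draws[:, 0] <= 0] = "invalid"
        if mode == "point-class":
            support[i] = int((labels == point_cls[i]).sum())
        else:
            support[i] = int(np.isin(labels, ("reinforcement", "reversion")).sum())

    out = pd.DataFrame(
        {
            "class": point_cls,
            "support": support,
            "supported": support >= support_min,
        },
        index=summary.genes,
    )
    out.attrs.update({"n_rep": n_rep, "support_min": support_min, "seed": seed, "tau": tau})
    return out


def merge_support(calls: pd.DataFrame, support: pd.DataFrame) -> pd.DataFrame:
    """Attach bootstrap support columns to a classification table."""
    merged = calls.join(support[["support", "supported"]])
    return merged
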