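"""Reinforcement / reversion classification of expression plasticity.

For each gene the three stage means (E_ancestral, E_plastic, E_colonized)
define two changes: the plastic change PC = E_plastic - E_ancestral and the
evolved change EC = E_colonized - E_plastic.  A gene shows an excess plastic
change when |PC| > tau * E_ancestral, and an excess evolved change when
|EC| > tau * E_ancestral (tau defaults to 0.5, i.e. 50% of the ancestral
level).  When both excesses hold, the gene is *reinforcement* if the two
changes share a direction and *reversion* if they oppose.

The magnitude of plasticity is M = min(|PC|, |EC|) / E_ancestral, the
binding constraint that guarantees both changes clear a category's lower
bound.  Genes are grouped into disjoint half-open magnitude categories
(50%,100%], (100%,150%], (150%,200%], >200% and, alternatively, into
consecutive bins of fixed width, and class imbalance within a group is
assessed with an exact two-tailed binomial test.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .expression import GeneStageSummary

CLASS_NONE = "none"
CLASS_REINFORCEMENT = "reinforcement"
CLASS_REVERSION = "reversion"

DEFAULT_TAU = 0.5
DEFAULT_BOUNDARIES = (0.5, 1.0, 1.5, 2.0)


def _classify_arrays(el, eh, ec, tau):
    """Vectorized classifier on raw stage-mean arrays.

    Returns (cls, pc, evc, mag) where cls is an int8 array with
    0 = none, 1 = reinforcement, 2 = reversion.  Entries with el <= 0
    are classified 0 (callers exclude them separately).
    """
    el = np.asarray(el, dtype=float)
    eh = np.asarray(eh, dtype=float)
    ec = np.asarray(ec, dtype=float)
    pc = eh - el
    evc = ec - eh
    with np.errstate(invalid="ignore", divide="ignore"):
        thr = tau * el
        excess = (np.abs(pc) > thr) & (np.abs(evc) > thr) & (el > 0)
        prod = np.sign(pc) * np.sign(evc)
        cls = np.zeros(el.shape, dtype=np.int8)
        cls[excess & (prod > 0)] = 1
        cls[excess & (prod < 0)] = 2
        mag = np.where(el > 0, np.minimum(np.abs(pc), np.abs(evc)) / np.where(el > 0, el, 1.0), np.nan)
    return cls, pc, evc, mag


_CLASS_LABELS = np.array([CLASS_NONE, CLASS_REINFORCEMENT, CLASS_REVERSION])


def classify_plasticity(summary: GeneStageSummary, tau: float = DEFAULT_TAU) -> pd.DataFrame:
    """Classify every gene from its stage means.

    Parameters
    ----------
    summary
        Per-stage means (SEs are ignored here; the bootstrap uses them).
    tau
        Relative excess threshold as a fraction of the ancestral mean.

    Returns
    -------
    DataFrame indexed by gene with columns ``E_ancestral``, ``E_plastic``,
    ``E_colonized``, ``PC``, ``EC``, ``rel_plastic``, ``rel_evolved``,
    ``excess_plastic``, ``excess_evolved``, ``class``, ``magnitude`` and
    ``excluded_zero_ancestral``.  Genes with zero ancestral mean cannot be
    classified with a relative threshold; they are kept with class "none",
    NaN magnitude and the exclusion flag set, and the count is stored in
    ``DataFrame.attrs["n_excluded_zero_ancestral"]``.
    """
    if tau <= 0:
        raise ValueError("tau must be > 0")
    if (summary.mean.to_numpy() < 0).any():
        raise ValueError("negative stage means are not allowed")
    el = summary.mean["ancestral"].to_numpy()
    eh = summary.mean["plastic"].to_numpy()
    ec = summary.mean["colonized"].to_numpy()
    cls, pc, evc, mag = _classify_arrays(el, eh, ec, tau)
    excluded = el <= 0
    with np.errstate(invalid="ignore", divide="ignore"):
        rel_pc = np.where(excluded, np.nan, np.abs(pc) / np.where(excluded, 1.0, el))
        rel_ec = np.where(excluded, np.nan, np.abs(evc) / np.where(excluded, 1.0, el))
    out = pd.DataFrame(
        {
            "E_ancestral": el,
            "E_plastic": eh,
            "E_colonized": ec,
            "PC": pc,
            "EC": evc,
            "rel_plastic": rel_pc,
            "rel_evolved": rel_ec,
            "excess_plastic": ~excluded & (np.abs(pc) > tau * el),
            "excess_evolved": ~excluded & (np.abs(evc) > tau * el),
            "class": _CLASS_LABELS[cls],
            "magnitude": np.where(excluded, np.nan, mag),
            "excluded_zero_ancestral": excluded,
        },
        index=summary.genes,
    )
    out.attrs["tau"] = tau
    out.attrs["n_excluded_zero_ancestral"] = int(excluded.sum())
    return out


def _format_boundary(b: float) -> str:
    pct = b * 100
    return f"{pct:g}%"


def category_labels(boundaries=DEFAULT_BOUNDARIES) -> list[str]:
    labels = [
        f"({_format_boundary(lo)},{_format_boundary(hi)}]"
        for lo, hi in zip(boundaries[:-1], boundaries[1:])
    ]
    labels.append(f">{_format_boundary(boundaries[-1])}")
    return labels


def magnitude_category(magnitude, boundaries=DEFAULT_BOUNDARIES):
    """Map magnitudes to disjoint half-open categories (b_i, b_{i+1}].

    The lowest boundary is the classification threshold itself, so every
    classified gene falls in exactly one category; the top category is
    open-ended.  Accepts a scalar or an array; NaN (unclassified) maps
    to None.
    """
    bounds = np.asarray(boundaries, dtype=float)
    if not np.all(np.diff(bounds) > 0):
        raise ValueError("boundaries must be strictly increasing")
    labels = category_labels(boundaries)
    scalar = np.isscalar(magnitude)
    m = np.atleast_1d(np.asarray(magnitude, dtype=float))
    idx = np.searchsorted(bounds, m, side="left")
    out = np.empty(m.shape, dtype=object)
    for i, (mi, ix) in enumerate(zip(m, idx)):
        if np.isnan(mi):
            out[i] = None
        elif ix == 0:
            raise ValueError(
                f"magnitude {mi} at or below the lowest boundary {bounds[0]}; "
                "classified genes always exceed it"
            )
        else:
            out[i] = labels[ix - 1]
    return out[0] if scalar else out


def assign_categories(calls: pd.DataFrame, boundaries=DEFAULT_BOUNDARIES) -> pd.DataFrame:
    """Add a ``category`` column to a classification table (None for class 'none')."""
    calls = calls.copy()
    cat = np.full(len(calls), None, dtype=object)
    classified = (calls["class"] != CLASS_NONE).to_numpy()
    if classified.any():
        cat[classified] = magnitude_category(
            calls.loc[classified, "magnitude"].to_numpy(), boundaries
        )
    calls["category"] = cat
    return calls


def bin_categories(calls: pd.DataFrame, bin_width: float, base: float = DEFAULT_TAU) -> pd.DataFrame:
    """Count reinforcement/reversion genes in consecutive magnitude bins.

    Bins are half-open intervals (base + k*w, base + (k+1)*w] starting at
    the base classification threshold; widths of 0.2, 0.4 and 0.6 probe
    the robustness of the reversion excess to the grouping scheme.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    classified = calls[calls["class"] != CLASS_NONE]
    if len(classified) == 0:
        return pd.DataFrame(columns=[CLASS_REINFORCEMENT, CLASS_REVERSION])
    m = classified["magnitude"].to_numpy()
    k = np.ceil((m - base) / bin_width - 1e-12).astype(int) - 1
    k = np.maximum(k, 0)
    n_bins = int(k.max()) + 1
    labels = [
        f"({_format_boundary(base + i * bin_width)},{_format_boundary(base + (i + 1) * bin_width)}]"
        for i in range(n_bins)
    ]
    counts = pd.DataFrame(
        0, index=labels, columns=[CLASS_REINFORCEMENT, CLASS_REVERSION]
    )
    for i, cls in zip(k, classified["class"]):
        counts.loc[labels[i], cls] += 1
    return counts


def binomial_excess_test(k_a: int, k_b: int, p0: float = 0.5) -> float:
    """Exact two-tailed binomial p-value for an imbalance between two groups.

    Tests whether k_a successes out of n = k_a + k_b departs from the
    null proportion p0, summing the probabilities of all outcomes whose
    point probability does not exceed that of the observed count
    (the "minlike" two-sided convention).
    """
    if k_a < 0 or k_b < 0:
        raise ValueError("counts must be non-negative")
    n = k_a + k_b
    if n == 0:
        raise ValueError("at least one observation required")
    if not 0 < p0 < 1:
        raise ValueError("p0 must be in (0,1)")
    return float(stats.binomtest(k_a, n, p0, alternative="two-sided").pvalue)


def class_excess_tests(
    calls: pd.DataFrame,
    boundaries=DEFAULT_BOUNDARIES,
    bin_widths=(0.2, 0.4, 0.6),
    p0: float = 0.5,
) -> dict:
    """Binomial reversion-vs-reinforcement tests overall, per category and per bin."""
    calls = assign_categories(calls, boundaries)
    out: dict = {"overall": None, "categories": {}, "bins": {}}
    def _test(sub):
        k_rev = int((sub["class"] == CLASS_REVERSION).sum())
        k_rei = int((sub["class"] == CLASS_REINFORCEMENT).sum())
        if k_rev + k_rei == 0:
            return {"reversion": 0, "reinforcement": 0, "p": None}
        return {
            "reversion": k_rev,
            "reinforcement": k_rei,
            "p": binomial_excess_test(k_rev, k_rei, p0),
        }
    classified = calls[calls["class"] != CLASS_NONE]
    out["overall"] = _test(classified)
    for label in category_labels(boundaries):
        out["categories"][label] = _test(classified[classified["category"] == label])
    for w in bin_widths:
        counts = bin_categories(calls, w)
        out["bins"][f"{w:g}"] = {
            label: {
                "reversion": int(row[CLASS_REVERSION]),
                "reinforcement": int(row[CLASS_REINFORCEMENT]),
                "p": (
                    binomial_excess_test(int(row[CLASS_REVERSION]), int(row[CLASS_REINFORCEMENT]), p0)
                    if row.sum() > 0
                    else None
                ),
            }
            for label, row in counts.iterrows()
        }
    return out
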