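"""Expression matrices, per-stage summaries, and the conserved-gene batch check.

The analysis follows genes across three stages of a high-elevation
colonization design: *ancestral* (lowland residents in situ), *plastic*
(lowland birds after hypoxia acclimation) and *colonized* (highland
residents).  Expression is measured as TPM (transcripts per million), so
all values are non-negative and within-sample normalized.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

STAGES = ("ancestral", "plastic", "colonized")


class ExpressionError(ValueError):
    """Raised for malformed expression inputs."""


@dataclass
class ExpressionMatrix:
    """Gene x sample TPM matrix with its sample design.

    Parameters
    ----------
    values
        DataFrame of TPM values, genes as rows, samples as columns.
    design
        DataFrame indexed by sample id with columns ``stage``
        (one of :data:`STAGES`), ``tissue`` and ``individual``.
    """

    values: pd.DataFrame
    design: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise ExpressionError(f"duplicate gene ids: {list(dups[:5])}")
        if (self.values.to_numpy() < 0).any():
            raise ExpressionError("negative TPM values are not allowed")
        missing = self.design.index.difference(self.values.columns)
        if len(missing):
            raise ExpressionError(
                f"samples in design absent from matrix: {sorted(missing)}"
            )
        bad = set(self.design["stage"]) - set(STAGES)
        if bad:
            raise ExpressionError(
                f"unknown stage labels {sorted(bad)}; allowed: {list(STAGES)}"
            )
        # keep only designed samples, in design order
        self.values = self.values.loc[:, self.design.index]

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.design.index

    def stage_samples(self, stage: str) -> pd.Index:
        return self.design.index[self.design["stage"] == stage]

    def subset_stages(self, stages) -> "ExpressionMatrix":
        keep = self.design.index[self.design["stage"].isin(list(stages))]
        return ExpressionMatrix(self.values.loc[:, keep], self.design.loc[keep])


@dataclass
class GeneStageSummary:
    """Per-gene, per-stage mean expression, standard error and sample count.

    ``mean`` and ``se`` are gene x stage DataFrames; ``n`` maps each stage
    to its sample count.  Stages observed with a single sample get SE = 0
    and are listed in ``degenerate_stages``.
    """

    mean: pd.DataFrame
    se: pd.DataFrame
    n: dict[str, int]
    degenerate_stages: tuple[str, ...] = field(default_factory=tuple)

    @property
    def genes(self) -> pd.Index:
        return self.mean.index


def read_expression(path, sample_sheet_path) -> ExpressionMatrix:
    """Read a TPM TSV (gene_id + one column per sample) and a sample sheet.

    The sample sheet is a TSV with columns ``sample_id``, ``stage``,
    ``tissue``, ``individual``.  Samples listed in the sheet but missing
    from the matrix raise :class:`ExpressionError`.
    """
    values = pd.read_csv(path, sep="\t", index_col=0)
    sheet = pd.read_csv(sample_sheet_path, sep="\t")
    required = {"sample_id", "stage", "tissue", "individual"}
    if not required.issubset(sheet.columns):
        raise ExpressionError(
            f"sample sheet must have columns {sorted(required)}; got {list(sheet.columns)}"
        )
    design = sheet.set_index("sample_id")[["stage", "tissue", "individual"]]
    return ExpressionMatrix(values, design)


def summarize_stages(matrix: ExpressionMatrix) -> GeneStageSummary:
    """Arithmetic mean and standard error of TPM per gene and stage.

    SE uses the n-1 sample standard deviation divided by sqrt(n) and is
    defined as 0 for stages with a single sample (flagged as degenerate).
    """
    means = {}
    ses = {}
    ns = {}
    degenerate = []
    for stage in STAGES:
        cols = matrix.stage_samples(stage)
        if len(cols) == 0:
            raise ExpressionError(f"stage {stage!r} has no samples")
        sub = matrix.values.loc[:, cols]
        n = len(cols)
        means[stage] = sub.mean(axis=1)
        if n == 1:
            ses[stage] = pd.Series(0.0, index=matrix.genes)
            degenerate.append(stage)
        else:
            ses[stage] = sub.std(axis=1, ddof=1) / np.sqrt(n)
        ns[stage] = n
    return GeneStageSummary(
        mean=pd.DataFrame(means)[list(STAGES)],
        se=pd.DataFrame(ses)[list(STAGES)],
        n=ns,
        degenerate_stages=tuple(degenerate),
    )


@dataclass
class ConservedGeneReport:
    """Result of the conserved-gene batch-effect check."""

    conserved: pd.Index
    cv: pd.Series
    sample_medians: pd.Series
    stage_medians: dict[str, float]
    pairwise_p: dict[tuple[str, str], float]

    def to_json(self, path) -> None:
        payload = {
            "n_conserved": int(len(self.conserved)),
            "stage_medians": {k: float(v) for k, v in self.stage_medians.items()},
            "pairwise_p": {f"{a}|{b}": float(p) for (a, b), p in self.pairwise_p.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def conserved_gene_check(
    matrix: ExpressionMatrix,
    cv_max: float = 0.3,
    min_mean_tpm: float = 1.0,
) -> ConservedGeneReport:
    """Identify conserved genes and compare their medians between stages.

    A gene is conserved when the coefficient of variation of its
    log2(TPM+1) values across all samples is <= ``cv_max`` and its mean
    raw TPM is >= ``min_mean_tpm``.  Stage medians are compared with the
    two-sided rank-sum (Mann-Whitney) test on per-sample medians of the
    conserved genes; similar stage medians indicate the absence of gross
    batch effects between sampling groups.
    """
    logv = np.log2(matrix.values + 1.0)
    mean_log = logv.mean(axis=1)
    # zero-mean log values (gene silent everywhere) make CV undefined
    nonzero = mean_log > 0
    cv = pd.Series(np.nan, index=matrix.genes)
    cv[nonzero] = logv.loc[nonzero].std(axis=1, ddof=1) / mean_log[nonzero]
    conserved = matrix.genes[
        nonzero & (cv <= cv_max) & (matrix.values.mean(axis=1) >= min_mean_tpm)
    ]
    if len(conserved) == 0:
        warnings.warn("conserved gene set is empty; batch check skipped")
        return ConservedGeneReport(conserved, cv, pd.Series(dtype=float), {}, {})

    sample_medians = logv.loc[conserved].median(axis=0)
    stage_medians = {}
    pairwise_p = {}
    for stage in STAGES:
        stage_medians[stage] = float(
            sample_medians[matrix.stage_samples(stage)].median()
        )
    for a, b in itertools.combinations(STAGES, 2):
        xa = sample_medians[matrix.stage_samples(a)].to_numpy()
        xb = sample_medians[matrix.stage_samples(b)].to_numpy()
        if len(xa) < 2 or len(xb) < 2:
            raise ExpressionError("conserved-gene check needs >= 2 samples per stage")
        pairwise_p[(a, b)] = float(stats.mannwhitneyu(xa, xb, alternative="two-sided").pvalue)
    return ConservedGeneReport(conserved, cv, sample_medians, stage_medians, pairwise_p)
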