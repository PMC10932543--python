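"""End-to-end orchestration: QC -> co-expression -> plasticity -> regulators -> FST.

The pipeline consumes either real input files (expression TSV + sample
sheet, phenotype TSV, VCF + BED + population map) or a synthetic block,
and writes TSV tables plus a JSON summary per stage.  All randomness is
seeded from the config, so two runs with the same config produce
byte-identical outputs.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import bootstrap as bootstrap_mod
from . import coexpression, expression, plasticity, popgen, regulators, synthetic


@dataclass
class PipelineConfig:
    """Inputs and thresholds for a full run.

    Exactly one of the two input routes must be provided: the file paths
    (``expression_path`` + ``sample_sheet_path`` at minimum) or a
    ``synthetic`` block with :class:`~plastevo.synthetic.SyntheticConfig`
    fields.
    """

    expression_path: str | None = None
    sample_sheet_path: str | None = None
    phenotypes_path: str | None = None
    vcf_path: str | None = None
    bed_path: str | None = None
    pop_map_path: str | None = None
    synthetic: dict | None = None

    tau: float = plasticity.DEFAULT_TAU
    boundaries: tuple = plasticity.DEFAULT_BOUNDARIES
    bin_widths: tuple = (0.2, 0.4, 0.6)
    p0: float = 0.5
    n_rep: int = 1000
    support_min: int = 950
    regulator_alpha: float = 0.05
    coexpr_beta: float = 6.0
    coexpr_min_size: int = 30
    coexpr_cut_height: float = 0.25
    merge_p: float = 0.1
    assoc_p: float = 0.01
    n_perm: int = 100
    fluctuation: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        has_files = self.expression_path is not None
        has_synth = self.synthetic is not None
        if not has_files and not has_synth:
            raise ValueError("provide input paths or a synthetic block")
        for name in ("tau", "n_rep", "support_min", "n_perm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("boundaries", "bin_widths"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage {stage!r} failed: {detail}")
        self.stage = stage


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run every applicable stage and write the report bundle to ``outdir``.

    Stages without their inputs (no phenotype table, no VCF/BED) are
    skipped with a warning; any in-stage failure aborts with the stage
    name.  Returns the summary dictionary that is also written to
    ``summary.json``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "plastevo_version": __version__,
        "seed": config.seed,
        "stages": {},
    }

    # ---- inputs
    phenotypes = None
    genotypes = annotation = None
    if config.synthetic is not None:
        syn = synthetic.SyntheticConfig(**{**config.synthetic, "seed": config.seed})
        matrix, truth = synthetic.generate_expression(syn)
        if syn.regulator_fraction > 0 and syn.n_phenotypes > 0:
            phenotypes = synthetic.generate_phenotypes(truth, matrix, syn)
        genotypes, annotation = synthetic.generate_genotypes(truth, syn)
        synthetic.write_truth_tsv(truth, outdir / "truth.tsv")
        summary["stages"]["simulate"] = {
            "n_genes": syn.n_genes,
            "n_snps": syn.n_snps,
            "class_counts": {
                k: int(v) for k, v in truth.class_counts().items()
            },
        }
    else:
        try:
            matrix = expression.read_expression(
                config.expression_path, config.sample_sheet_path
            )
        except Exception as exc:  # pragma: no cover - error path
            raise PipelineError("read_expression", str(exc)) from exc
        if config.phenotypes_path:
            phenotypes = pd.read_csv(config.phenotypes_path, sep="\t", index_col=0)
        if config.vcf_path and config.bed_path and config.pop_map_path:
            try:
                genotypes = popgen.read_variants(
                    config.vcf_path, popgen.read_pop_map(config.pop_map_path)
                )
                annotation = popgen.read_annotation_bed(config.bed_path)
            except Exception as exc:
                raise PipelineError("read_variants", str(exc)) from exc

    # ---- QC
    try:
        qc = expression.conserved_gene_check(matrix)
        qc.to_json(outdir / "qc.json")
        summary["stages"]["qc"] = {
            "n_conserved": int(len(qc.conserved)),
            "pairwise_p": {f"{a}|{b}": p for (a, b), p in qc.pairwise_p.items()},
        }
    except Exception as exc:
        raise PipelineError("qc", str(exc)) from exc

    # ---- co-expression
    try:
        gs = coexpression.gene_significance(matrix)
        gs.to_csv(outdir / "gene_significance.tsv", sep="\t")
        hubs = pd.Index([], dtype=object)
        if len(matrix.genes) >= config.coexpr_min_size:
            modules = coexpression.detect_modules(
                matrix,
                beta=config.coexpr_beta,
                min_size=config.coexpr_min_size,
                cut_height=config.coexpr_cut_height,
            )
            assoc = coexpression.merge_and_associate(
                matrix, modules, merge_p=config.merge_p, assoc_p=config.assoc_p
            )
            modules.labels.rename("module").to_csv(outdir / "modules.tsv", sep="\t")
            assoc.eigengenes.to_csv(outdir / "eigengenes.tsv", sep="\t")
            if len(assoc.stats):
                assoc.stats.to_csv(outdir / "module_stage_association.tsv", sep="\t")
            hubs = coexpression.hub_genes(gs, assoc, alpha=config.regulator_alpha)
            summary["stages"]["coexpression"] = {
                "n_modules": len(assoc.modules.modules),
                "n_associated": len(assoc.associated),
                "n_hub_genes": int(len(hubs)),
            }
        else:
            warnings.warn("too few genes for module detection; skipping")
            summary["stages"]["coexpression"] = {"skipped": "too few genes"}
        pd.Series(sorted(hubs), name="gene_id").to_csv(
            outdir / "hub_genes.tsv", sep="\t", index=False
        )
    except Exception as exc:
        raise PipelineError("coexpression", str(exc)) from exc

    # ---- plasticity + bootstrap
    try:
        stage_summary = expression.summarize_stages(matrix)
        calls = plasticity.classify_plasticity(stage_summary, tau=config.tau)
        n_excluded = calls.attrs["n_excluded_zero_ancestral"]
        calls = plasticity.assign_categories(calls, config.boundaries)
        support = bootstrap_mod.bootstrap_support(
            stage_summary,
            tau=config.tau,
            n_rep=config.n_rep,
            support_min=config.support_min,
            seed=config.seed,
        )
        calls = bootstrap_mod.merge_support(calls, support)
        calls.to_csv(outdir / "plasticity_calls.tsv", sep="\t")
        tests = plasticity.class_excess_tests(
            calls, config.boundaries, config.bin_widths, config.p0
        )
        _write_json(tests, outdir / "plasticity_tests.json")
        summary["stages"]["plasticity"] = {
            "n_reinforcement": int((calls["class"] == "reinforcement").sum()),
            "n_reversion": int((calls["class"] == "reversion").sum()),
            "n_excluded_zero_ancestral": n_excluded,
            "n_supported": int(calls["supported"].sum()),
            "overall_p": tests["overall"]["p"],
        }
    except Exception as exc:
        raise PipelineError("plasticity", str(exc)) from exc

    # ---- regulators
    if phenotypes is not None:
        try:
            corr = regulators.phenotype_correlation(matrix, phenotypes)
            reg_calls = regulators.classify_regulators(corr, alpha=config.regulator_alpha)
            reg_sum = regulators.regulator_summary(reg_calls)
            adaptive = regulators.classify_adaptive(calls, reg_sum)
            adaptive.to_csv(outdir / "regulators.tsv", sep="\t")
            test = regulators.adaptive_excess_test(adaptive, config.p0)
            _write_json(test, outdir / "adaptive_tests.json")
            summary["stages"]["regulators"] = {
                "n_regulators": int(len(reg_sum)),
                "n_conflicts": int(reg_sum["conflict"].sum()) if len(reg_sum) else 0,
                **{k: v for k, v in test.items()},
            }
        except Exception as exc:
            raise PipelineError("regulators", str(exc)) from exc
    else:
        warnings.warn("no phenotype table; regulator stage skipped")
        summary["stages"]["regulators"] = {"skipped": "no phenotypes"}

    # ---- FST permutation
    if genotypes is not None and annotation is not None:
        try:
            results = []
            classified = calls[calls["class"] != "none"]
            gene_sets = {"all_classified": list(classified.index)}
            for label in plasticity.category_labels(config.boundaries):
                gene_sets[f"category {label}"] = list(
                    classified.index[classified["category"] == label]
                )
            for label, genes in gene_sets.items():
                if not genes:
                    continue
                try:
                    results.extend(
                        popgen.fst_region_tests(
                            genotypes,
                            annotation,
                            genes,
                            n_perm=config.n_perm,
                            fluctuation=config.fluctuation,
                            seed=config.seed,
                            label=label,
                        )
                    )
                except popgen.PopgenError as exc:
                    warnings.warn(f"FST test skipped for {label!r}: {exc}")
            table = pd.DataFrame([r.to_dict() for r in results])
            table.to_csv(outdir / "fst_permutation.tsv", sep="\t", index=False)
            summary["stages"]["popgen"] = {
                "n_snps": genotypes.n_snps,
                "n_tests": len(results),
                "n_significant": int(sum(r.significant for r in results)),
            }
        except Exception as exc:
            raise PipelineError("popgen", str(exc)) from exc
    else:
        warnings.warn("no VCF/BED/pop-map inputs; FST stage skipped")
        summary["stages"]["popgen"] = {"skipped": "no genotype inputs"}

    _write_json(summary, outdir / "summary.json")
    return summary
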