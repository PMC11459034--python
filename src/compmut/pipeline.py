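"""End-to-end orchestration: cohort → calls → statistics → prediction.

:func:`run_pipeline` executes the full chain under one seeded configuration
and writes all stage outputs (plain TSV/JSON) plus a JSON manifest of
parameters, seeds, versions and per-stage counts into the output directory.
Per-composite-gene analyses run independently and write to per-gene
subdirectories.  Strata that are empty (no composite calls, no significant
co-genes, single-class labels) are skipped with the reason recorded in the
manifest, never a crash; genuine stage failures abort with the stage name.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .chrom_disruption import randomization_test, same_chromosome_fraction
from .composite_caller import (
    call_composites,
    composite_prevalence,
    extract_driver_events,
    partition_events,
)
from .comutation_stats import (
    EmptyStratumError,
    ZeroVarianceError,
    complementary_relationship,
    test_comutations,
)
from .io_formats import Cohort, ValidationError, load_cohort
from .predictor import (
    ModelConfig,
    SingleClassError,
    build_feature_matrices,
    shuffle_robustness,
    train_ensemble,
)
from .synthetic_data import SimConfig, generate_cohort, write_fixture_bundle

__all__ = ["RunConfig", "RunReport", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass(frozen=True)
class RunConfig:
    """One pipeline run.  ``seed`` is the single source of randomness: it is
    pushed into the simulation config and the model config."""

    out_dir: str | Path
    sim: SimConfig | None = None
    inputs: dict[str, str] | None = None  # maf, cnv, annotations, hotspots, samples, layout
    composite_genes: tuple[str, ...] = ("BRAF", "EGFR", "KRAS", "PIK3CA")
    p_threshold: float = 0.05
    background_multiplier: float = 1.04
    model: ModelConfig = field(default_factory=ModelConfig)
    n_randomization: int = 500
    run_shuffle: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.sim is None) == (self.inputs is None):
            raise ValidationError("provide exactly one of sim= or inputs=")


@dataclass
class RunReport:
    manifest: dict
    out_dir: Path
    calls: pd.DataFrame


def _write_json(obj: dict, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def run_pipeline(config: RunConfig) -> RunReport:
    """Run all stages; returns the manifest and composite calls.

    Output layout::

        out_dir/
          cohort/           simulated input bundle (simulation runs only)
          calls.tsv         composite calls
          prevalence_matrix.tsv
          chrom_histogram.tsv
          chrom_summary.json
          <gene>/           per composite gene: comutations.tsv,
                            metrics.json, roc.tsv, confusion.tsv,
                            shuffle.tsv (optional)
          manifest.json
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": {"name": "compmut", "version": __version__},
        "seed": config.seed,
        "parameters": {
            "composite_genes": list(config.composite_genes),
            "p_threshold": config.p_threshold,
            "background_multiplier": config.background_multiplier,
            "n_randomization": config.n_randomization,
            "run_shuffle": config.run_shuffle,
            "model": dataclasses.asdict(
                dataclasses.replace(config.model, seed=config.seed)
            ),
        },
        "stages": {},
        "skipped": [],
    }
    skipped: list[dict] = manifest["skipped"]

    # --- stage: cohort -------------------------------------------------------
    try:
        if config.sim is not None:
            sim = dataclasses.replace(config.sim, seed=config.seed)
            manifest["parameters"]["sim"] = sim.to_dict()
            cohort, truth = generate_cohort(sim)
            write_fixture_bundle(cohort, truth, out / "cohort")
        else:
            cohort = load_cohort(**config.inputs)
        manifest["stages"]["cohort"] = dict(cohort.summary)
    except Exception as e:  # noqa: BLE001 - surfaced with stage name
        raise PipelineError("cohort", e) from e

    # --- stage: composite calling -------------------------------------------
    try:
        events = extract_driver_events(cohort)
        calls = call_composites(events, cohort.annotations)
        _write_tsv(calls, out / "calls.tsv")
        prevalence = composite_prevalence(calls, cohort)
        matrix = prevalence.by_gene_tumor_type.reset_index()
        _write_tsv(matrix, out / "prevalence_matrix.tsv")
        manifest["stages"]["composite_calling"] = {
            "n_driver_events": int(len(events)),
            "n_composite_calls": int(len(calls)),
            "n_composite_samples": prevalence.n_composite_samples,
            "prevalence_overall": prevalence.overall,
        }
    except Exception as e:
        raise PipelineError("composite_calling", e) from e

    if len(calls) == 0:
        skipped.append(
            {"stage": "post_calling", "reason": "no composite calls in cohort"}
        )
        _write_json(manifest, out / "manifest.json")
        return RunReport(manifest=manifest, out_dir=out, calls=calls)

    # --- stage: co-mutation statistics --------------------------------------
    genes_of_interest = [
        g for g in config.composite_genes if g in set(calls["gene"])
    ]
    for g in config.composite_genes:
        if g not in set(calls["gene"]):
            skipped.append(
                {"stage": "comutation_stats", "gene": g, "reason": "no composite calls"}
            )
    tumor_types = sorted(cohort.samples["tumor_type"].unique())
    comut_by_gene: dict[str, pd.DataFrame] = {}
    try:
        for gene in genes_of_interest:
            results = []
            for tt in tumor_types:
                try:
                    results.append(
                        test_comutations(
                            cohort,
                            calls,
                            gene,
                            tt,
                            events=events,
                            alpha=config.p_threshold,
                            background_multiplier=config.background_multiplier,
                        )
                    )
                except EmptyStratumError:
                    skipped.append(
                        {
                            "stage": "comutation_stats",
                            "gene": gene,
                            "tumor_type": tt,
                            "reason": "no composite samples in stratum",
                        }
                    )
            gene_dir = out / gene
            gene_dir.mkdir(exist_ok=True)
            pooled = (
                pd.concat(results, ignore_index=True)
                if results
                else pd.DataFrame()
            )
            comut_by_gene[gene] = pooled
            _write_tsv(pooled, gene_dir / "comutations.tsv")
            stage_info: dict = {
                "n_tests": int(len(pooled)),
                "n_significant": int(pooled["significant"].sum()) if len(pooled) else 0,
            }
            if len(pooled) >= 3:
                try:
                    fit = complementary_relationship(pooled)
                    stage_info["complementary"] = {
                        "pearson_r": fit.pearson_r,
                        "p_value": fit.p_value,
                        "slope": fit.slope,
                        "n_pairs": fit.n_pairs,
                    }
                except (ValidationError, ZeroVarianceError) as err:
                    skipped.append(
                        {
                            "stage": "complementary_fit",
                            "gene": gene,
                            "reason": str(err),
                        }
                    )
            manifest["stages"].setdefault("comutation_stats", {})[gene] = stage_info
    except PipelineError:
        raise
    except Exception as e:
        raise PipelineError("comutation_stats", e) from e

    # --- stage: chromosomal disruption --------------------------------------
    try:
        partition = partition_events(cohort, calls, events=events)
        report = same_chromosome_fraction(
            calls, partition, cohort.annotations, cohort.layout
        )
        candidates = sorted(cohort.annotations["symbol"])
        stat = randomization_test(
            calls,
            partition,
            cohort.annotations,
            candidates,
            n_iterations=config.n_randomization,
            seed=config.seed,
        )
        _write_tsv(report.histogram, out / "chrom_histogram.tsv")
        _write_json(
            {
                "pooled_same_chromosome_fraction": report.pooled_fraction,
                "mean_per_gene_fraction": report.mean_per_gene_fraction,
                "per_gene": report.per_gene,
                "n_comparisons": report.n_comparisons,
                "randomization": {
                    "observed_fraction": stat.observed_fraction,
                    "empirical_p": stat.empirical_p,
                    "n_iterations": stat.n_iterations,
                    "null_mean": float(np.mean(stat.null_fractions)),
                    "seed": stat.seed,
                },
            },
            out / "chrom_summary.json",
        )
        manifest["stages"]["chrom_disruption"] = {
            "pooled_same_chromosome_fraction": report.pooled_fraction,
            "empirical_p": stat.empirical_p,
        }
    except ValidationError as e:
        skipped.append({"stage": "chrom_disruption", "reason": str(e)})
    except Exception as e:
        raise PipelineError("chrom_disruption", e) from e

    # --- stage: prediction ---------------------------------------------------
    model_config = dataclasses.replace(config.model, seed=config.seed)
    for gene in genes_of_interest:
        pooled = comut_by_gene.get(gene, pd.DataFrame())
        sig = (
            sorted(pooled.loc[pooled["significant"], "co_gene"].unique())
            if len(pooled)
            else []
        )
        if not sig:
            skipped.append(
                {
                    "stage": "prediction",
                    "gene": gene,
                    "reason": "no significant co-genes",
                }
            )
            continue
        try:
            features = build_feature_matrices(
                cohort, calls, gene, sig, events=events
            )
            result = train_ensemble(features, model_config)
        except SingleClassError as err:
            skipped.append(
                {"stage": "prediction", "gene": gene, "reason": str(err)}
            )
            continue
        except ValidationError as err:
            skipped.append(
                {"stage": "prediction", "gene": gene, "reason": str(err)}
            )
            continue
        except Exception as e:
            raise PipelineError("prediction", e) from e

        gene_dir = out / gene
        gene_dir.mkdir(exist_ok=True)
        cm, rep = result.confusion, result.report
        _write_tsv(
            pd.DataFrame(
                [{"tp": cm.tp, "fp": cm.fp, "tn": cm.tn, "fn": cm.fn}]
            ),
            gene_dir / "confusion.tsv",
        )
        _write_tsv(rep.roc_points, gene_dir / "roc.tsv")
        metrics = {
            "n_features": int(features.binary.shape[1]),
            "n_test_samples": int(len(result.y_test)),
            "accuracy": rep.accuracy,
            "balanced_accuracy": rep.balanced_accuracy,
            "precision": rep.precision,
            "tpr": rep.tpr,
            "fpr": rep.fpr,
            "specificity": rep.specificity,
            "auc": rep.auc,
        }
        _write_json(metrics, gene_dir / "metrics.json")
        manifest["stages"].setdefault("prediction", {})[gene] = metrics

        if config.run_shuffle:
            shuffle = shuffle_robustness(features, model_config)
            rows = [
                {
                    "fraction": f,
                    "auc": shuffle.reports[f].auc,
                    "accuracy": shuffle.reports[f].accuracy,
                    "balanced_accuracy": shuffle.reports[f].balanced_accuracy,
                }
                for f in shuffle.fractions
            ]
            _write_tsv(pd.DataFrame(rows), gene_dir / "shuffle.tsv")
            manifest["stages"].setdefault("shuffle", {})[gene] = {
                "auc_by_fraction": {str(f): shuffle.reports[f].auc for f in shuffle.fractions}
            }

    _write_json(manifest, out / "manifest.json")
    return RunReport(manifest=manifest, out_dir=out, calls=calls)
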