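"""End-to-end orchestration: call -> overlap -> concordance -> recurrence -> similarity.

A run is described by a JSON :class:`RunConfig`.  Every stage's tables are
written under the output directory, and ``manifest.json`` records the config
echo (defaults included, so default drift across versions is detectable),
tool version, and SHA-256 hashes of every input and output — config plus
manifest suffice to repeat a run exactly.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Literal

from pydantic import BaseModel, Field, model_validator

from . import __version__
from .concordance import (
    build_profile,
    full_core,
    genes_in_at_least,
    leave_one_out_core,
    partition_by_psg,
)
from .deg_calling import call_degs, tier_by_fold_change
from .errors import ConfigError
from .phenotype_overlap import build_overlap_matrix, recurrence_frame, recurrence_scores
from .similarity import rank_by_resemblance, summarize_counts
from .tables_io import (
    read_deg_table,
    read_gene_sets,
    sha256_of,
    write_json,
    write_report_tables,
)

logger = logging.getLogger(__name__)


class DatasetEntry(BaseModel):
    path: str
    dialect: Literal["cuffdiff", "generic"] = "generic"
    name: str
    model_type: str = ""


class GeneSetEntry(BaseModel):
    path: str
    format: Literal["gmt", "plain_list"] = "gmt"


class RunConfig(BaseModel):
    """Validated configuration of one pipeline run."""

    datasets: list[DatasetEntry]
    gene_sets: list[GeneSetEntry]
    out_dir: str
    q_threshold: float = Field(default=0.05, gt=0.0, le=1.0)
    recompute_q: bool = False
    tier_cutoffs: list[float] = [1.0, 2.0, 3.0]
    recurrence_min_count: int = Field(default=9, ge=0)
    #: genes called in at least k datasets; default n - 1
    concordance_k: int | None = None
    #: leave-one-out cores reported for each of these dataset names
    concordance_exclude: list[str] = []
    #: reference dataset for recurrence and similarity; default the first
    similarity_reference: str | None = None
    similarity_metric: str = "mean_absolute_difference"
    allow_empty_sets: bool = False
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "RunConfig":
        names = [d.name for d in self.datasets]
        if len(names) != len(set(names)):
            raise ValueError("dataset names must be unique")
        return self


def load_config(path: str | Path) -> RunConfig:
    import json

    payload = json.loads(Path(path).read_text())
    try:
        return RunConfig.model_validate(payload)
    except Exception as exc:
        raise ConfigError(f"{path}: {exc}") from exc


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and return the written manifest."""
    for entry in config.datasets + config.gene_sets:
        if not Path(entry.path).exists():
            raise ConfigError(f"input path does not exist: {entry.path}")

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    _attach_run_log(out_dir)

    input_hashes = {
        e.path: sha256_of(e.path) for e in [*config.datasets, *config.gene_sets]
    }

    logger.info("reading %d datasets", len(config.datasets))
    datasets = {
        e.name: read_deg_table(e.path, dialect=e.dialect, name=e.name, model_type=e.model_type)
        for e in config.datasets
    }
    psg_lists = []
    for entry in config.gene_sets:
        psg_lists.extend(
            read_gene_sets(entry.path, format=entry.format, allow_empty=config.allow_empty_sets)
        )

    # Stage 1: uniform-threshold DEG calling with fold-change tiers
    calls = {}
    for name, dataset in datasets.items():
        result = call_degs(dataset, config.q_threshold, recompute_q=config.recompute_q)
        tier_by_fold_change(result, dataset, config.tier_cutoffs)
        calls[name] = result
        logger.info("%s: %d DEGs (%d up / %d down)", name, len(result.deg_genes),
                    result.n_up, result.n_down)
    sets = {name: res.deg_genes for name, res in calls.items()}

    reference = config.similarity_reference or next(iter(datasets))
    if reference not in datasets:
        raise ConfigError(f"similarity_reference {reference!r} is not a dataset name")

    # Stage 2: overlap matrix
    matrix = build_overlap_matrix(sets, psg_lists, allow_empty=config.allow_empty_sets)

    # Stage 3: recurrence for the reference dataset
    recurrence = recurrence_scores(
        sets[reference], datasets[reference], psg_lists, config.recurrence_min_count
    )

    # Stage 4: concordance
    results: dict[str, object] = {
        "deg_calls": {
            name: {
                "q_threshold": res.q_threshold,
                "n_degs": len(res.deg_genes),
                "n_up": res.n_up,
                "n_down": res.n_down,
                "n_flat": res.n_flat,
                "n_infinite_lfc": res.n_infinite,
                "tier_counts": {str(k): v for k, v in res.tier_counts.items()},
            }
            for name, res in calls.items()
        },
        "overlap_matrix": matrix.to_frame(),
        "overlap_summary": matrix.summary(),
        "recurrence": recurrence_frame(recurrence),
    }
    if len(sets) >= 2:
        profile = build_profile(sets)
        k = config.concordance_k if config.concordance_k is not None else profile.n - 1
        core = full_core(profile)
        at_least_k = genes_in_at_least(profile, k)
        psg_side, non_psg_side = partition_by_psg(at_least_k, psg_lists)
        results["concordance_regions"] = profile.to_frame()
        results["concordance_core"] = {
            "dataset_order": list(profile.dataset_order),
            "core": sorted(core),
            "k": k,
            "at_least_k": sorted(at_least_k),
            "at_least_k_psg": {g: list(ph) for g, ph in sorted(psg_side.items())},
            "at_least_k_non_psg": sorted(non_psg_side),
            "leave_one_out": {
                name: sorted(leave_one_out_core(profile, name))
                for name in config.concordance_exclude
            },
        }
        # Stage 5: similarity
        report = rank_by_resemblance(matrix, reference, config.similarity_metric)
        results["similarity"] = report.to_dict()

    summary = summarize_counts({name: len(s) for name, s in sets.items()})
    results["deg_count_summary"] = {
        "counts": summary.counts,
        "mean": summary.mean,
        "mean_display": summary.mean_display,
        "median": summary.median,
    }

    output_hashes = write_report_tables(results, out_dir)
    manifest = {
        "tool": "phenoconcord",
        "version": __version__,
        "config": config.model_dump(),
        "input_hashes": input_hashes,
        "output_hashes": output_hashes,
    }
    write_json(manifest, out_dir / "manifest.json")
    logger.info("run complete: %d artifacts in %s", len(output_hashes), out_dir)
    return manifest


def _attach_run_log(out_dir: Path) -> None:
    root = logging.getLogger("phenoconcord")
    target = out_dir / "run.log"
    for handler in root.handlers:
        if isinstance(handler, logging.FileHandler) and Path(handler.baseFilename) == target:
            return
    handler = logging.FileHandler(target, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s"))
    root.addHandler(handler)
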