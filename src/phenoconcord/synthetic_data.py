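"""Ground-truth simulator for multi-study DEG tables and phenotype seed lists.

The generator emulates the structure of a cross-dataset DEG meta-analysis:
independent studies over a shared gene universe, each study a two-group
p-value mixture (null genes uniform, alternative genes Beta(a, 1) with a < 1
pushing p toward 0), BH adjustment within study, a small concordant core
planted as alternative in every study with a consistent fold-change sign,
mostly study-private remaining signal (hence poor cross-study concordance),
and phenotype seed lists with a controlled fraction of members drawn from one
designated study's true alternatives.

Defaults mirror the study conditions this pipeline targets: six datasets and
twelve phenotype lists over a ~12k-gene universe, a two-gene all-study core,
seed-list sizes spanning roughly 180-1240 genes, and ~27% seed-list
enrichment.  Beta(a, 1) alternatives give closed-form expected discovery
rates, which the property tests exploit.

A single integer seed drives a splittable stream — one substream per dataset
and per phenotype list — so adding datasets does not perturb existing ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .deg_calling import bh_adjust
from .errors import ConfigError
from .tables_io import DEGRecord, ExpressionDataset, PhenotypeSeedList

_STREAM_STRUCTURE = 0
_STREAM_DATASET = 1
_STREAM_PHENOTYPE = 2


class SimulationConfig(BaseModel):
    """Parameters of one simulated meta-analysis."""

    model_config = {"frozen": True}

    seed: int = 0
    n_genes: int = Field(default=12_000, ge=10)
    n_datasets: int = Field(default=6, ge=1)
    #: per-dataset fraction of null (non-differential) genes
    pi0: float = Field(default=0.85, ge=0.0, le=1.0)
    #: shape a of the Beta(a, 1) alternative p-value distribution
    alt_beta_a: float = Field(default=0.15, gt=0.0)
    #: genes planted as alternative in every dataset
    core_size: int = Field(default=2, ge=0)
    #: of the non-core alternative slots, fraction sampled per dataset
    private_frac: float = Field(default=0.9, ge=0.0, le=1.0)
    #: standard deviation of planted |log2fc| (folded normal)
    lfc_scale: float = Field(default=1.2, gt=0.0)
    n_phenotypes: int = Field(default=12, ge=0)
    psg_size_range: tuple[int, int] = (180, 1240)
    #: target fraction of each seed list drawn from the designated study's
    #: true alternatives
    enrichment: float = Field(default=0.27, ge=0.0, le=1.0)

    @model_validator(mode="after")
    def _check(self) -> "SimulationConfig":
        n_alt = self.n_alternative
        if self.core_size > n_alt:
            raise ValueError(
                f"core_size {self.core_size} exceeds alternative budget "
                f"(1-pi0)*n_genes = {n_alt}"
            )
        lo, hi = self.psg_size_range
        if not 1 <= lo <= hi <= self.n_genes:
            raise ValueError(f"psg_size_range {self.psg_size_range} outside [1, n_genes]")
        return self

    @property
    def n_alternative(self) -> int:
        return round((1.0 - self.pi0) * self.n_genes)


@dataclass
class SimulationTruth:
    """Ground truth written alongside every simulated run."""

    core: frozenset[str]
    shared: frozenset[str]
    per_dataset_alt: dict[str, frozenset[str]]
    phenotype_enriched: dict[str, frozenset[str]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "core": sorted(self.core),
            "shared": sorted(self.shared),
            "per_dataset_alt": {k: sorted(v) for k, v in sorted(self.per_dataset_alt.items())},
            "phenotype_enriched": {
                k: sorted(v) for k, v in sorted(self.phenotype_enriched.items())
            },
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "SimulationTruth":
        return cls(
            core=frozenset(payload["core"]),
            shared=frozenset(payload["shared"]),
            per_dataset_alt={
                k: frozenset(v) for k, v in payload["per_dataset_alt"].items()
            },
            phenotype_enriched={
                k: frozenset(v) for k, v in payload["phenotype_enriched"].items()
            },
        )


def gene_universe(n_genes: int) -> list[str]:
    """Synthetic symbols G000001... — never collide with real symbols."""
    return [f"G{i + 1:06d}" for i in range(n_genes)]


def _rng(config: SimulationConfig, stream: int, index: int = 0) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, stream, index]))


def simulate_studies(
    config: SimulationConfig,
) -> tuple[list[ExpressionDataset], SimulationTruth]:
    """Draw the per-study DEG tables and their ground truth.

    Null genes receive p ~ Uniform(0,1) and log2fc ~ Normal(0, 0.1*lfc_scale);
    alternative genes p ~ Beta(a,1) and |log2fc| ~ folded Normal(0, lfc_scale)
    with a random sign — except core genes, whose sign is drawn once and held
    consistent across datasets.  q-values are BH-adjusted within each study.
    Fully reproducible from the config seed.
    """
    genes = np.array(gene_universe(config.n_genes))
    struct = _rng(config, _STREAM_STRUCTURE)

    n_alt = config.n_alternative
    n_noncore = n_alt - config.core_size
    n_shared = round((1.0 - config.private_frac) * n_noncore)
    n_private = n_noncore - n_shared

    all_idx = np.arange(config.n_genes)
    fixed_idx = struct.choice(all_idx, size=config.core_size + n_shared, replace=False)
    core_idx = fixed_idx[: config.core_size]
    shared_idx = fixed_idx[config.core_size :]
    core_signs = struct.choice([-1.0, 1.0], size=config.core_size)
    remaining = np.setdiff1d(all_idx, fixed_idx, assume_unique=False)

    datasets: list[ExpressionDataset] = []
    per_dataset_alt: dict[str, frozenset[str]] = {}
    for d in range(config.n_datasets):
        rng = _rng(config, _STREAM_DATASET, d)
        name = f"study_{d + 1}"
        private_idx = rng.choice(remaining, size=n_private, replace=False)
        alt_idx = np.concatenate([core_idx, shared_idx, private_idx]).astype(int)
        is_alt = np.zeros(config.n_genes, dtype=bool)
        is_alt[alt_idx] = True

        p = rng.uniform(0.0, 1.0, size=config.n_genes)
        p[is_alt] = rng.beta(config.alt_beta_a, 1.0, size=is_alt.sum())
        lfc = rng.normal(0.0, 0.1 * config.lfc_scale, size=config.n_genes)
        magnitudes = np.abs(rng.normal(0.0, config.lfc_scale, size=is_alt.sum()))
        signs = rng.choice([-1.0, 1.0], size=is_alt.sum())
        lfc[is_alt] = signs * magnitudes
        lfc[core_idx] = core_signs * np.abs(lfc[core_idx])
        q = bh_adjust(p)

        records = [
            DEGRecord(gene=genes[i], log2fc=float(lfc[i]), p_value=float(p[i]), q_value=float(q[i]))
            for i in range(config.n_genes)
        ]
        datasets.append(
            ExpressionDataset.from_records(name, records, model_type="synthetic")
        )
        per_dataset_alt[name] = frozenset(genes[alt_idx])

    truth = SimulationTruth(
        core=frozenset(genes[core_idx]),
        shared=frozenset(genes[shared_idx]),
        per_dataset_alt=per_dataset_alt,
    )
    return datasets, truth


def simulate_psg_lists(
    config: SimulationConfig,
    truth: SimulationTruth,
    designated: str | None = None,
) -> list[PhenotypeSeedList]:
    """Draw phenotype seed lists with controlled DEG enrichment.

    Each list's size is uniform over ``psg_size_range``; a fraction
    ``enrichment`` of members is sampled (without replacement) from the
    designated dataset's true-alternative genes, the remainder from that
    dataset's null pool.  The planted-enriched subsets are recorded on the
    truth object.
    """
    if not truth.per_dataset_alt:
        raise ConfigError("truth carries no datasets")
    designated = designated or next(iter(truth.per_dataset_alt))
    if designated not in truth.per_dataset_alt:
        raise ConfigError(f"designated dataset {designated!r} not in truth")
    alt_pool = np.array(sorted(truth.per_dataset_alt[designated]))
    null_pool = np.array(
        sorted(set(gene_universe(config.n_genes)) - truth.per_dataset_alt[designated])
    )
    lo, hi = config.psg_size_range
    lists: list[PhenotypeSeedList] = []
    for k in range(config.n_phenotypes):
        rng = _rng(config, _STREAM_PHENOTYPE, k)
        size = int(rng.integers(lo, hi + 1))
        n_enr = round(config.enrichment * size)
        n_null = size - n_enr
        if n_enr > alt_pool.size or n_null > null_pool.size:
            raise ConfigError(
                f"phenotype list size {size} exceeds pools "
                f"(alt {alt_pool.size}, null {null_pool.size})"
            )
        enriched = rng.choice(alt_pool, size=n_enr, replace=False)
        background = rng.choice(null_pool, size=n_null, replace=False)
        phenotype = f"phenotype_{k + 1}"
        lists.append(
            PhenotypeSeedList(
                phenotype=phenotype,
                genes=frozenset(enriched) | frozenset(background),
            )
        )
        truth.phenotype_enriched[phenotype] = frozenset(enriched)
    return lists


def simulate_run(
    config: SimulationConfig,
) -> tuple[list[ExpressionDataset], list[PhenotypeSeedList], SimulationTruth]:
    """Studies plus seed lists in one call (designated dataset = the first)."""
    datasets, truth = simulate_studies(config)
    psg_lists = simulate_psg_lists(config, truth)
    return datasets, psg_lists, truth
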