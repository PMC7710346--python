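"""DEG x phenotype-seed-gene overlap matrix and multi-phenotype recurrence.

For every (dataset, phenotype) pair the overlap cell records |DEG ∩ PSG| and
two normalizations: the percentage of the seed list recovered as DEGs
(``pct_of_psg``) and the percentage of the dataset's DEGs that are seeds
(``pct_of_deg``).  Percentages are stored at full precision; display rounding
is half-up to one decimal.  Recurrence scores rank each DEG by how many
phenotype lists contain it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import DomainError
from .tables_io import ExpressionDataset, PhenotypeSeedList

DEFAULT_MIN_RECURRENCE = 9


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding (0.05 -> 0.1), as used in printed reports."""
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class OverlapCell:
    """One dataset x phenotype overlap entry."""

    dataset_name: str
    phenotype: str
    n_overlap: int
    psg_size: int
    deg_size: int
    applicable: bool = True  # False for an empty seed list explicitly allowed

    def __post_init__(self) -> None:
        if self.applicable and not 0 <= self.n_overlap <= min(self.psg_size, self.deg_size):
            raise DomainError(
                f"{self.dataset_name}/{self.phenotype}: overlap {self.n_overlap} "
                f"inconsistent with sizes {self.psg_size}/{self.deg_size}"
            )

    @property
    def pct_of_psg(self) -> float:
        """Percentage of the seed list found as DEGs, full precision."""
        return 100.0 * self.n_overlap / self.psg_size

    @property
    def pct_of_deg(self) -> float:
        """Percentage of the dataset's DEGs included in the seed list."""
        return 100.0 * self.n_overlap / self.deg_size if self.deg_size else 0.0


def overlap_cell(
    deg_genes: frozenset[str] | set[str],
    psg: PhenotypeSeedList,
    deg_size: int,
    dataset_name: str = "",
    allow_empty: bool = False,
) -> OverlapCell:
    """Exact |DEG ∩ PSG| cell.  ``deg_size`` is the full DEG count of the
    dataset (the intersection may have been taken on a subset)."""
    if not psg.genes:
        if not allow_empty:
            raise DomainError(f"empty seed list {psg.phenotype!r}: pct_of_psg undefined")
        return OverlapCell(dataset_name, psg.phenotype, 0, 0, deg_size, applicable=False)
    n = len(set(deg_genes) & psg.genes)
    return OverlapCell(dataset_name, psg.phenotype, n, len(psg.genes), deg_size)


@dataclass
class OverlapMatrix:
    """Dataset x phenotype grid of overlap cells with per-dataset summaries."""

    dataset_names: tuple[str, ...]
    phenotypes: tuple[str, ...]
    cells: dict[tuple[str, str], OverlapCell]
    #: per-dataset |DEG ∩ (∪ seed lists)| computed on sets, not summed cells
    union_counts: dict[str, int] = field(default_factory=dict)

    def cell(self, dataset: str, phenotype: str) -> OverlapCell:
        return self.cells[(dataset, phenotype)]

    def pct_of_psg_vector(self, dataset: str) -> dict[str, float]:
        return {
            ph: self.cells[(dataset, ph)].pct_of_psg
            for ph in self.phenotypes
            if self.cells[(dataset, ph)].applicable
        }

    def mean_pct_of_psg(self, dataset: str) -> float:
        vec = self.pct_of_psg_vector(dataset)
        return sum(vec.values()) / len(vec)

    def mean_pct_of_deg(self, dataset: str) -> float:
        cells = [
            self.cells[(dataset, ph)]
            for ph in self.phenotypes
            if self.cells[(dataset, ph)].applicable
        ]
        return sum(c.pct_of_deg for c in cells) / len(cells)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table, one row per (dataset, phenotype), display-rounded
        percentages alongside the exact counts."""
        rows = []
        for ds in self.dataset_names:
            for ph in self.phenotypes:
                c = self.cells[(ds, ph)]
                rows.append(
                    {
                        "dataset": ds,
                        "phenotype": ph,
                        "n_overlap": c.n_overlap,
                        "psg_size": c.psg_size,
                        "deg_size": c.deg_size,
                        "pct_of_psg": round_half_up(c.pct_of_psg) if c.applicable else None,
                        "pct_of_deg": round_half_up(c.pct_of_deg) if c.applicable else None,
                    }
                )
        return pd.DataFrame(rows)

    def summary(self) -> pd.DataFrame:
        rows = []
        for ds in self.dataset_names:
            rows.append(
                {
                    "dataset": ds,
                    "mean_pct_of_psg": round_half_up(self.mean_pct_of_psg(ds)),
                    "mean_pct_of_deg": round_half_up(self.mean_pct_of_deg(ds)),
                    "union_overlap": self.union_counts[ds],
                }
            )
        return pd.DataFrame(rows)


def build_overlap_matrix(
    deg_sets: Mapping[str, frozenset[str] | set[str]],
    psg_lists: Sequence[PhenotypeSeedList],
    deg_sizes: Mapping[str, int] | None = None,
    allow_empty: bool = False,
) -> OverlapMatrix:
    """Complete overlap grid over every dataset and seed list.

    ``deg_sizes`` overrides the per-dataset DEG totals when the supplied sets
    are a subset of the full DEG call (e.g. a published excerpt); by default
    the set sizes are used.  Per-dataset means are computed from
    full-precision percentages; union counts from set union, never by summing
    cells.
    """
    if not deg_sets or not psg_lists:
        raise DomainError("need at least one dataset and one seed list")
    deg_sizes = dict(deg_sizes or {})
    cells: dict[tuple[str, str], OverlapCell] = {}
    unions: dict[str, int] = {}
    for ds_name, genes in deg_sets.items():
        size = deg_sizes.get(ds_name, len(genes))
        if not genes:
            import logging

            logging.getLogger(__name__).warning("dataset %s has an empty DEG set", ds_name)
        for psg in psg_lists:
            cells[(ds_name, psg.phenotype)] = overlap_cell(
                genes, psg, size, dataset_name=ds_name, allow_empty=allow_empty
            )
        all_psg: set[str] = set()
        for psg in psg_lists:
            all_psg |= psg.genes
        unions[ds_name] = len(set(genes) & all_psg)
    return OverlapMatrix(
        dataset_names=tuple(deg_sets),
        phenotypes=tuple(p.phenotype for p in psg_lists),
        cells=cells,
        union_counts=unions,
    )


@dataclass(frozen=True)
class RecurrenceRecord:
    """A DEG annotated with the number of phenotype lists containing it."""

    gene: str
    n_phenotypes: int
    log2fc: float
    direction: str
    phenotypes: tuple[str, ...] = ()


def recurrence_scores(
    deg_genes: Iterable[str],
    dataset: ExpressionDataset,
    psg_lists: Sequence[PhenotypeSeedList],
    min_count: int = DEFAULT_MIN_RECURRENCE,
) -> list[RecurrenceRecord]:
    """Rank DEGs of the focal dataset by multi-phenotype recurrence.

    One record per DEG contained in at least ``min_count`` seed lists, sorted
    by recurrence descending then log2 fold change descending.  A gene counts
    once per phenotype regardless of multiplicity in the source files.
    """
    if min_count < 0:
        raise DomainError("min_count must be >= 0")
    out = []
    for gene in deg_genes:
        hits = tuple(p.phenotype for p in psg_lists if gene in p.genes)
        if len(hits) < min_count:
            continue
        rec = dataset.records[gene]
        out.append(
            RecurrenceRecord(
                gene=gene,
                n_phenotypes=len(hits),
                log2fc=rec.log2fc,
                direction=rec.direction,
                phenotypes=hits,
            )
        )
    out.sort(key=lambda r: (-r.n_phenotypes, -r.log2fc, r.gene))
    return out


def recurrence_frame(records: Sequence[RecurrenceRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene": r.gene,
                "n_phenotypes": r.n_phenotypes,
                "log2fc": r.log2fc,
                "direction": r.direction,
                "phenotypes": ";".join(r.phenotypes),
            }
            for r in records
        ],
        columns=["gene", "n_phenotypes", "log2fc", "direction", "phenotypes"],
    )
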