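"""Cross-dataset DEG concordance: membership bitmasks and Venn-region decomposition.

Each gene in the union of the per-study DEG sets gets a bitmask over a fixed
dataset order (LSB = first dataset).  The 2^n - 1 non-empty membership
patterns (Venn regions) partition the union exactly, so region counts sum to
the union size.  The region table is exponential in n; builds are guarded to
n <= 16.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import ConfigError, DomainError
from .tables_io import PhenotypeSeedList

MAX_DATASETS = 16


@dataclass
class ConcordanceProfile:
    """Per-gene membership masks across datasets plus region counts."""

    dataset_order: tuple[str, ...]
    masks: dict[str, int]
    region_counts: dict[int, int]

    @property
    def n(self) -> int:
        return len(self.dataset_order)

    @property
    def full_mask(self) -> int:
        return (1 << self.n) - 1

    def datasets_of(self, mask: int) -> tuple[str, ...]:
        return tuple(
            name for i, name in enumerate(self.dataset_order) if mask >> i & 1
        )

    def region_genes(self, mask: int) -> frozenset[str]:
        return frozenset(g for g, m in self.masks.items() if m == mask)

    def to_frame(self) -> pd.DataFrame:
        """Region table: non-empty regions plus an explicit row for the
        full-intersection region even when empty (the headline region)."""
        masks = set(self.region_counts) | {self.full_mask}
        rows = []
        for mask in sorted(masks):
            genes = sorted(self.region_genes(mask))
            rows.append(
                {
                    "mask": mask,
                    "datasets": ";".join(self.datasets_of(mask)),
                    "n_datasets": bin(mask).count("1"),
                    "count": self.region_counts.get(mask, 0),
                    "genes": ";".join(genes),
                }
            )
        return pd.DataFrame(rows, columns=["mask", "datasets", "n_datasets", "count", "genes"])


def build_profile(
    deg_sets: Mapping[str, Iterable[str]],
) -> ConcordanceProfile:
    """Exact Venn decomposition of named gene sets in their given order."""
    names = list(deg_sets)
    if len(names) != len(set(names)):
        raise ConfigError("duplicate dataset names in concordance input")
    if not 2 <= len(names) <= MAX_DATASETS:
        raise ConfigError(f"need between 2 and {MAX_DATASETS} datasets, got {len(names)}")
    masks: dict[str, int] = {}
    for bit, name in enumerate(names):
        for gene in deg_sets[name]:
            masks[gene] = masks.get(gene, 0) | (1 << bit)
    region_counts: dict[int, int] = {}
    for mask in masks.values():
        region_counts[mask] = region_counts.get(mask, 0) + 1
    return ConcordanceProfile(
        dataset_order=tuple(names), masks=masks, region_counts=region_counts
    )


def genes_in_at_least(profile: ConcordanceProfile, k: int) -> frozenset[str]:
    """Genes called DEG in at least k of the n datasets."""
    if not 1 <= k <= profile.n:
        raise DomainError(f"k must be in [1, {profile.n}], got {k}")
    return frozenset(
        g for g, m in profile.masks.items() if bin(m).count("1") >= k
    )


def full_core(profile: ConcordanceProfile) -> frozenset[str]:
    """The all-datasets intersection (the concordant core)."""
    return profile.region_genes(profile.full_mask)


def leave_one_out_core(profile: ConcordanceProfile, excluded: str) -> frozenset[str]:
    """Intersection of every dataset except ``excluded``.

    The excluded dataset's membership is ignored, not required absent, so the
    result always contains the full core.
    """
    if excluded not in profile.dataset_order:
        raise ConfigError(f"unknown dataset {excluded!r}")
    bit = profile.dataset_order.index(excluded)
    want = profile.full_mask & ~(1 << bit)
    return frozenset(g for g, m in profile.masks.items() if m & want == want)


def partition_by_psg(
    genes: Iterable[str],
    psg_lists: Sequence[PhenotypeSeedList],
) -> tuple[dict[str, tuple[str, ...]], frozenset[str]]:
    """Split genes into seed genes (annotated with their phenotypes) and the rest."""
    psg_genes: dict[str, tuple[str, ...]] = {}
    non_psg: set[str] = set()
    for gene in genes:
        hits = tuple(p.phenotype for p in psg_lists if gene in p.genes)
        if hits:
            psg_genes[gene] = hits
        else:
            non_psg.add(gene)
    return psg_genes, frozenset(non_psg)
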