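"""Benjamini-Hochberg adjustment and uniform-threshold DEG selection.

A gene is called differentially expressed when its BH-adjusted q-value falls
strictly below the threshold (default 0.05), applied uniformly to every
study.  By default the q-values shipped with each study are trusted;
``recompute_q=True`` re-derives them from the raw p-values with the step-up
rule implemented here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import DataError, DomainError
from .tables_io import ExpressionDataset

DEFAULT_Q_THRESHOLD = 0.05
DEFAULT_TIER_CUTOFFS = (1.0, 2.0, 3.0)


def bh_adjust(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    With m p-values sorted ascending, q_(i) = min_{j >= i} (m * p_(j) / j),
    clipped to 1, returned in the original input order.  Ties in p receive
    identical q (guaranteed by the running minimum).

    Raises :class:`DomainError` on NaN or values outside [0, 1].
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise DomainError("bh_adjust expects a 1-D collection")
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise DomainError("p-values must lie in [0, 1] and not be NaN")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    np.clip(q_sorted, 0.0, 1.0, out=q_sorted)
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


@dataclass
class DEGCallResult:
    """Outcome of uniform-threshold DEG selection on one dataset."""

    dataset_name: str
    q_threshold: float
    deg_genes: frozenset[str]
    n_up: int
    n_down: int
    n_flat: int
    #: genes whose log2fc is infinite: direction known, tier counting excludes them
    n_infinite: int = 0
    tier_counts: dict[float, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        assert self.n_up + self.n_down + self.n_flat == len(self.deg_genes)


def call_degs(
    dataset: ExpressionDataset,
    q_threshold: float = DEFAULT_Q_THRESHOLD,
    recompute_q: bool = False,
) -> DEGCallResult:
    """Select DEGs at ``q < q_threshold`` (strict inequality).

    With ``recompute_q`` the BH adjustment is re-run on the dataset's raw
    p-values; otherwise each record must carry an upstream q-value
    (:class:`DataError` lists offending genes if not).
    """
    if not 0.0 <= q_threshold <= 1.0:
        raise DomainError(f"q_threshold {q_threshold} outside [0, 1]")

    genes = sorted(dataset.records)
    if recompute_q:
        q = bh_adjust([dataset.records[g].p_value for g in genes])
        q_by_gene = dict(zip(genes, q))
    else:
        missing = [g for g in genes if dataset.records[g].q_value is None]
        if missing:
            raise DataError(
                "q-values absent (pass recompute_q=True) for: " + ", ".join(missing[:20])
                + ("..." if len(missing) > 20 else "")
            )
        q_by_gene = {g: dataset.records[g].q_value for g in genes}

    called = frozenset(g for g in genes if q_by_gene[g] < q_threshold)
    n_up = n_down = n_flat = n_inf = 0
    for g in called:
        rec = dataset.records[g]
        if rec.direction == "up":
            n_up += 1
        elif rec.direction == "down":
            n_down += 1
        else:
            n_flat += 1
        if not rec.finite_lfc:
            n_inf += 1
    return DEGCallResult(
        dataset_name=dataset.name,
        q_threshold=q_threshold,
        deg_genes=called,
        n_up=n_up,
        n_down=n_down,
        n_flat=n_flat,
        n_infinite=n_inf,
    )


def tier_by_fold_change(
    result: DEGCallResult,
    dataset: ExpressionDataset,
    cutoffs: Sequence[float] = DEFAULT_TIER_CUTOFFS,
) -> dict[float, int]:
    """Count called DEGs with finite |log2fc| >= cutoff, for each cutoff.

    Cutoffs are on the log2 scale (a cutoff of 1 means a 2-fold change) and
    must be positive and strictly ascending.  Records with infinite log2fc
    are excluded and reported separately via ``result.n_infinite``.
    The mapping is also stored on ``result.tier_counts``.
    """
    cutoffs = [float(c) for c in cutoffs]
    if any(c <= 0 for c in cutoffs):
        raise DomainError("tier cutoffs must be positive")
    if any(b <= a for a, b in zip(cutoffs, cutoffs[1:])):
        raise DomainError("tier cutoffs must be strictly ascending")

    abs_lfc = [
        abs(dataset.records[g].log2fc)
        for g in result.deg_genes
        if dataset.records[g].finite_lfc
    ]
    tiers = {c: sum(1 for x in abs_lfc if x >= c) for c in cutoffs}
    result.tier_counts = tiers
    return tiers


def deg_sets(call_results: Mapping[str, DEGCallResult]) -> dict[str, frozenset[str]]:
    """Convenience: dataset name -> called gene set, order preserved."""
    return {name: res.deg_genes for name, res in call_results.items()}
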