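"""Per-dataset DEG-count summaries and phenotype-profile resemblance ranking.

Resemblance between a cellular model and the reference (patient) dataset is
measured on their per-phenotype ``pct_of_psg`` vectors.  The default metric
is the mean absolute difference (MAD); Spearman rank correlation is offered
as an alternative.  Neither is canonical for this kind of comparison — the
choice is documented in every output header.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass
from typing import Mapping

from scipy import stats as scipy_stats

from .errors import AlignmentError, ConfigError, DomainError
from .phenotype_overlap import OverlapMatrix, round_half_up

METRICS = ("mean_absolute_difference", "spearman_rank")
METRIC_ALIASES = {"mad": "mean_absolute_difference", "spearman": "spearman_rank"}


@dataclass
class DatasetSummary:
    """Location summaries of per-dataset DEG counts."""

    counts: dict[str, int]
    mean: float
    median: float

    @property
    def mean_display(self) -> int:
        """Mean rounded to the nearest integer for reports (2157.33 -> 2157)."""
        return int(round_half_up(self.mean, 0))


def summarize_counts(deg_counts: Mapping[str, int]) -> DatasetSummary:
    """Mean and median of named DEG counts; even-n median averages the two
    middle order statistics."""
    if not deg_counts:
        raise DomainError("summarize_counts needs at least one count")
    values = list(deg_counts.values())
    return DatasetSummary(
        counts=dict(deg_counts),
        mean=statistics.fmean(values),
        median=statistics.median(values),
    )


def profile_distance(
    vec_a: Mapping[str, float],
    vec_b: Mapping[str, float],
    metric: str = "mean_absolute_difference",
) -> float:
    """Distance (MAD) or association (Spearman) between two keyed vectors.

    Both vectors must be keyed by the same phenotypes; values are compared
    key-wise, so ordering is irrelevant.
    """
    metric = METRIC_ALIASES.get(metric, metric)
    if metric not in METRICS:
        raise ConfigError(f"unknown metric {metric!r}; use one of {METRICS}")
    if set(vec_a) != set(vec_b):
        only_a = sorted(set(vec_a) - set(vec_b))
        only_b = sorted(set(vec_b) - set(vec_a))
        raise AlignmentError(
            f"phenotype keys differ; only in first: {only_a}, only in second: {only_b}"
        )
    keys = sorted(vec_a)
    a = [vec_a[k] for k in keys]
    b = [vec_b[k] for k in keys]
    if metric == "mean_absolute_difference":
        return sum(abs(x - y) for x, y in zip(a, b)) / len(keys)
    if len(keys) < 2:
        raise DomainError("spearman needs at least 2 phenotypes")
    rho = scipy_stats.spearmanr(a, b).statistic
    return float(rho)


@dataclass
class SimilarityReport:
    """Ranking of datasets by resemblance to a reference profile."""

    reference: str
    metric: str
    scores: dict[str, float]
    ranking: tuple[str, ...]
    tied: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "reference": self.reference,
            "metric": self.metric,
            "metric_note": (
                "resemblance metric is a package choice, not a field standard; "
                "mean_absolute_difference compares per-phenotype pct_of_psg vectors"
            ),
            "scores": {k: round(v, 6) for k, v in self.scores.items()},
            "ranking": list(self.ranking),
            "tied": list(self.tied),
        }


def rank_by_resemblance(
    matrix: OverlapMatrix,
    reference: str,
    metric: str = "mean_absolute_difference",
) -> SimilarityReport:
    """Order the non-reference datasets by profile resemblance to ``reference``.

    MAD ranks ascending (closer is more similar); Spearman ranks descending.
    Ties are broken alphabetically and flagged in the report.
    """
    metric = METRIC_ALIASES.get(metric, metric)
    if reference not in matrix.dataset_names:
        raise ConfigError(f"reference {reference!r} not in overlap matrix")
    ref_vec = matrix.pct_of_psg_vector(reference)
    scores = {
        name: profile_distance(matrix.pct_of_psg_vector(name), ref_vec, metric)
        for name in matrix.dataset_names
        if name != reference
    }
    descending = metric == "spearman_rank"
    ranking = tuple(
        sorted(scores, key=lambda n: (-scores[n] if descending else scores[n], n))
    )
    seen: dict[float, list[str]] = {}
    for name, score in scores.items():
        seen.setdefault(round(score, 12), []).append(name)
    tied = tuple(sorted(n for grp in seen.values() if len(grp) > 1 for n in grp))
    return SimilarityReport(
        reference=reference, metric=metric, scores=scores, ranking=ranking, tied=tied
    )
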