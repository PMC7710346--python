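"""Readers, writers and domain records for every external format the pipeline touches.

Three tabular dialects come in:

* Cuffdiff ``gene_exp.diff`` — the native output of the Cufflinks
  differential-expression step (tab-delimited, 14 columns, a ``status``
  column marking testable rows ``OK``);
* a generic DEG TSV with columns ``gene  log2fc  p_value  [q_value]``;
* gene-set files, either Broad-dialect GMT or plain one-symbol-per-line lists.

Gene identifiers are matched across studies by exact normalized symbol
(uppercase, surrounding whitespace stripped); no alias or ortholog mapping is
attempted.  Outputs are byte-stable TSV/JSON so re-runs diff clean.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import (
    DataError,
    EmptyInputError,
    FormatError,
    RowParseError,
)

logger = logging.getLogger(__name__)

#: Columns a Cuffdiff gene_exp.diff must carry (subset actually consumed).
CUFFDIFF_REQUIRED = ("gene", "log2(fold_change)", "p_value", "q_value", "status")

#: Canonical header of the generic dialect; q_value optional.
GENERIC_REQUIRED = ("gene", "log2fc", "p_value")

FLOAT_FMT = "%.6g"


def normalize_symbol(symbol: str) -> str:
    """Normalize a gene symbol: strip surrounding whitespace, uppercase.

    Idempotent by construction; matching across studies is by exact
    normalized symbol only.
    """
    return symbol.strip().upper()


# ---------------------------------------------------------------------------
# Domain records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DEGRecord:
    """One gene's differential-expression result.

    ``log2fc`` may be signed infinity when one condition has zero expression;
    such records keep their direction but are excluded from fold-change tier
    counting.  ``q_value`` is recorded verbatim when supplied by the upstream
    study — ``q >= p`` is deliberately not asserted.
    """

    gene: str
    log2fc: float
    p_value: float
    q_value: float | None = None

    def __post_init__(self) -> None:
        if not self.gene:
            raise DataError("DEGRecord with empty gene symbol")
        if math.isnan(self.p_value) or not 0.0 <= self.p_value <= 1.0:
            raise DataError(f"{self.gene}: p_value {self.p_value!r} outside [0, 1]")
        if self.q_value is not None and (
            math.isnan(self.q_value) or not 0.0 <= self.q_value <= 1.0
        ):
            raise DataError(f"{self.gene}: q_value {self.q_value!r} outside [0, 1]")

    @property
    def direction(self) -> str:
        """``up`` iff log2fc > 0, ``down`` iff < 0, ``flat`` at exactly 0."""
        if self.log2fc > 0:
            return "up"
        if self.log2fc < 0:
            return "down"
        return "flat"

    @property
    def finite_lfc(self) -> bool:
        return math.isfinite(self.log2fc)


@dataclass
class ParseStats:
    """Row bookkeeping for one parse; rows_in == rows_retained + rows_dropped."""

    rows_in: int = 0
    rows_retained: int = 0
    rows_dropped: int = 0
    dropped_status: int = 0      # cuffdiff rows with status != OK
    collapsed_duplicates: int = 0

    def assert_conserved(self) -> None:
        if self.rows_in != self.rows_retained + self.rows_dropped:
            raise AssertionError(
                f"row conservation violated: {self.rows_in} != "
                f"{self.rows_retained} + {self.rows_dropped}"
            )


@dataclass
class ExpressionDataset:
    """A named study's DEG records keyed by normalized gene symbol."""

    name: str
    model_type: str = ""
    records: dict[str, DEGRecord] = field(default_factory=dict)
    parse_stats: ParseStats = field(default_factory=ParseStats)

    @classmethod
    def from_records(
        cls,
        name: str,
        records: Iterable[DEGRecord],
        model_type: str = "",
        stats: ParseStats | None = None,
    ) -> "ExpressionDataset":
        """Build a dataset, collapsing duplicate gene rows.

        Of duplicate rows for one symbol the survivor is the one with the
        smallest q (missing q sorts last), then smallest p, then largest
        |log2fc|, then first occurrence.  Every collapse is logged.
        """
        stats = stats or ParseStats()
        kept: dict[str, DEGRecord] = {}
        for rec in records:
            prev = kept.get(rec.gene)
            if prev is None:
                kept[rec.gene] = rec
                continue
            stats.collapsed_duplicates += 1
            logger.info("%s: duplicate rows for %s collapsed", name, rec.gene)
            if _dedup_key(rec) < _dedup_key(prev):
                kept[rec.gene] = rec
        return cls(name=name, model_type=model_type, records=kept, parse_stats=stats)

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records.values())


def _dedup_key(rec: DEGRecord) -> tuple:
    q = rec.q_value if rec.q_value is not None else math.inf
    return (q, rec.p_value, -abs(rec.log2fc))


@dataclass(frozen=True)
class PhenotypeSeedList:
    """A named phenotype and its candidate-gene symbols (normalized)."""

    phenotype: str
    genes: frozenset[str]

    def __len__(self) -> int:
        return len(self.genes)


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def read_deg_table(
    path: str | Path,
    dialect: str = "generic",
    name: str | None = None,
    model_type: str = "",
) -> ExpressionDataset:
    """Read one study's DEG table.

    Cuffdiff rows whose ``status`` is not ``OK`` are dropped and counted;
    ``inf``/``-inf`` fold changes are preserved as signed infinities.

    Raises
    ------
    FormatError
        if a required column is missing.
    EmptyInputError
        if no row is retained.
    RowParseError
        on an unparsable numeric value, with the 1-based line number.
    """
    path = Path(path)
    if dialect not in ("cuffdiff", "generic"):
        raise ValueError(f"unknown dialect {dialect!r}")
    name = name or path.stem

    try:
        frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"{path}: empty file") from None

    required = CUFFDIFF_REQUIRED if dialect == "cuffdiff" else GENERIC_REQUIRED
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {', '.join(missing)}")

    stats = ParseStats(rows_in=len(frame))
    records: list[DEGRecord] = []
    lfc_col = "log2(fold_change)" if dialect == "cuffdiff" else "log2fc"
    has_q = dialect == "cuffdiff" or "q_value" in frame.columns

    for idx, row in enumerate(frame.itertuples(index=False)):
        line_number = idx + 2  # 1-based, after the header
        row = dict(zip(frame.columns, row))
        if dialect == "cuffdiff" and row["status"] != "OK":
            stats.rows_dropped += 1
            stats.dropped_status += 1
            continue
        try:
            rec = DEGRecord(
                gene=normalize_symbol(row["gene"]),
                log2fc=_parse_float(row[lfc_col]),
                p_value=_parse_float(row["p_value"]),
                q_value=_parse_float(row["q_value"]) if has_q and row["q_value"] != "" else None,
            )
        except (ValueError, DataError) as exc:
            raise RowParseError(str(exc), line_number) from None
        records.append(rec)
        stats.rows_retained += 1

    if not records:
        raise EmptyInputError(f"{path}: zero rows retained")
    if stats.dropped_status:
        logger.info("%s: dropped %d rows with status != OK", path, stats.dropped_status)
    stats.assert_conserved()
    return ExpressionDataset.from_records(name, records, model_type=model_type, stats=stats)


def _parse_float(text: str) -> float:
    text = text.strip()
    # Cuffdiff prints infinite fold changes as "inf"/"-inf" (sometimes "1.79769e+308")
    value = float(text)
    return value


def read_gene_sets(
    path: str | Path,
    format: str = "gmt",
    allow_empty: bool = False,
) -> list[PhenotypeSeedList]:
    """Read phenotype seed-gene lists from a GMT file or a plain list.

    GMT lines are ``name<TAB>description<TAB>gene...``; a plain list holds one
    symbol per line and takes its phenotype name from the file stem.
    Symbols are normalized and duplicates within a set collapsed.
    """
    path = Path(path)
    if format == "gmt":
        out: list[PhenotypeSeedList] = []
        with open(path) as handle:
            for line_number, line in enumerate(handle, start=1):
                line = line.rstrip("\n")
                if not line.strip():
                    continue
                fields = line.split("\t")
                if len(fields) < 3:
                    raise FormatError(
                        f"{path}: line {line_number}: GMT line has "
                        f"{len(fields)} fields, need at least 3"
                    )
                genes = frozenset(
                    normalize_symbol(g) for g in fields[2:] if g.strip()
                )
                out.append(_checked_set(fields[0].strip(), genes, allow_empty, path))
        if not out:
            raise EmptyInputError(f"{path}: no gene sets found")
        return out
    if format == "plain_list":
        with open(path) as handle:
            genes = frozenset(
                normalize_symbol(line) for line in handle if line.strip()
            )
        return [_checked_set(path.stem, genes, allow_empty, path)]
    raise ValueError(f"unknown gene-set format {format!r}")


def _checked_set(
    phenotype: str, genes: frozenset[str], allow_empty: bool, path: Path
) -> PhenotypeSeedList:
    if not genes:
        if not allow_empty:
            raise EmptyInputError(f"{path}: gene set {phenotype!r} is empty")
        logger.warning("%s: gene set %r is empty (retained)", path, phenotype)
    else:
        logger.info("gene set %s: %d symbols", phenotype, len(genes))
    return PhenotypeSeedList(phenotype=phenotype, genes=genes)


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_deg_table(dataset: ExpressionDataset, path: str | Path) -> Path:
    """Write a dataset in the generic dialect (byte-stable, genes sorted)."""
    path = Path(path)
    has_q = any(rec.q_value is not None for rec in dataset)
    lines = ["gene\tlog2fc\tp_value" + ("\tq_value" if has_q else "")]
    for gene in sorted(dataset.records):
        rec = dataset.records[gene]
        cells = [gene, _fmt(rec.log2fc), _fmt(rec.p_value)]
        if has_q:
            cells.append(_fmt(rec.q_value) if rec.q_value is not None else "")
        lines.append("\t".join(cells))
    path.write_text("\n".join(lines) + "\n")
    return path


def write_gmt(sets: Sequence[PhenotypeSeedList], path: str | Path) -> Path:
    path = Path(path)
    lines = [
        "\t".join([s.phenotype, "NA", *sorted(s.genes)]) for s in sets
    ]
    path.write_text("\n".join(lines) + "\n")
    return path


def _fmt(value: float) -> str:
    if math.isinf(value):
        return "inf" if value > 0 else "-inf"
    return FLOAT_FMT % value


def sha256_of(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_json(obj, path: str | Path) -> Path:
    """Deterministic JSON: sorted keys, fixed separators, trailing newline."""
    path = Path(path)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
    return path


def write_tsv(frame: pd.DataFrame, path: str | Path) -> Path:
    """Byte-stable TSV with fixed float formatting."""
    path = Path(path)
    frame.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT, lineterminator="\n")
    return path


def write_report_tables(results: Mapping[str, object], out_dir: str | Path) -> dict[str, str]:
    """Write a mapping of stage name -> serializable result under ``out_dir``.

    DataFrames become TSV, everything else deterministic JSON.  Returns a
    manifest ``{relative filename: sha256}``; writing the same input twice
    yields byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}
    for stage_name in sorted(results):
        payload = results[stage_name]
        if isinstance(payload, pd.DataFrame):
            target = out_dir / f"{stage_name}.tsv"
            write_tsv(payload, target)
        else:
            target = out_dir / f"{stage_name}.json"
            write_json(payload, target)
        manifest[target.name] = sha256_of(target)
    return manifest
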