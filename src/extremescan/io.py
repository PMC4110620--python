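"""Cohort input/output: expression matrices, clinical tables, annotations.

Expression data are log-scale genes x samples tables in the tab-separated
layout used by GEO series matrices (first column = probe or gene id, header
row = sample ids). Probes mapping to the same gene are collapsed by their
arithmetic mean on the log scale. Clinical tables are delimited files with a
user-supplied column-name map so that heterogeneous cohort annotations
(survival vs recurrence time, stage labels, therapy flags) all land in one
schema.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

RAW_LOG = "raw_log"
STANDARD_SCORE = "standard_score"

STAGES = ("I", "II", "III", "unknown")


@dataclass
class ExpressionMatrix:
    """Log-scale genes x samples expression table.

    ``values`` is a DataFrame indexed by unique gene symbols with unique
    sample-id columns. ``scale_tag`` records whether columns are raw log
    intensities or per-array standard scores.
    """

    values: pd.DataFrame
    scale_tag: str = RAW_LOG

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"duplicate gene ids: {list(dups[:5])}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique()
            raise ValueError(f"duplicate sample ids: {list(dups[:5])}")
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("expression matrix contains non-finite values")
        if self.scale_tag not in (RAW_LOG, STANDARD_SCORE):
            raise ValueError(f"unknown scale_tag {self.scale_tag!r}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        missing = [s for s in sample_ids if s not in self.values.columns]
        if missing:
            raise KeyError(f"samples absent from expression matrix: {missing[:5]}")
        return ExpressionMatrix(self.values.loc[:, list(sample_ids)], self.scale_tag)

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        missing = [g for g in gene_ids if g not in self.values.index]
        if missing:
            raise KeyError(f"genes absent from expression matrix: {missing[:5]}")
        return ExpressionMatrix(self.values.loc[list(gene_ids)], self.scale_tag)


@dataclass
class ClinicalRecord:
    """One case: survival/recurrence time in months plus stratification flags."""

    sample_id: str
    time: float
    event: bool
    stage: str = "unknown"
    adjuvant_therapy: bool | None = None
    subtype_flags: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError(f"negative time for {self.sample_id}: {self.time}")
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r} for {self.sample_id}")


class CohortTable:
    """Ordered collection of :class:`ClinicalRecord` with DataFrame access."""

    def __init__(self, records: Sequence[ClinicalRecord]):
        ids = [r.sample_id for r in records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample ids in cohort")
        self.records: list[ClinicalRecord] = list(records)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ClinicalRecord]:
        return iter(self.records)

    @property
    def sample_ids(self) -> list[str]:
        return [r.sample_id for r in self.records]

    def to_frame(self) -> pd.DataFrame:
        flag_names = sorted({k for r in self.records for k in r.subtype_flags})
        rows = []
        for r in self.records:
            row = {
                "sample_id": r.sample_id,
                "time": r.time,
                "event": r.event,
                "stage": r.stage,
                "adjuvant_therapy": r.adjuvant_therapy,
            }
            for name in flag_names:
                row[name] = r.subtype_flags.get(name)
            rows.append(row)
        return pd.DataFrame(rows)

    def subset(self, sample_ids: Sequence[str]) -> "CohortTable":
        wanted = set(sample_ids)
        return CohortTable([r for r in self.records if r.sample_id in wanted])


@dataclass
class JoinReport:
    matched: list[str]
    unmatched_clinical: list[str]
    unmatched_expression: list[str]


@dataclass
class LoadReport:
    n_rows_in: int
    n_genes_out: int
    n_unmapped_dropped: int


def _read_table(path: str | Path, check_header: bool = False) -> pd.DataFrame:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    if check_header:
        # pandas silently renames duplicate header fields; catch them first
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split(sep)
        seen = [h for h in header if header.count(h) > 1]
        if seen:
            raise ValueError(f"duplicate sample ids in header: {sorted(set(seen))}")
    return pd.read_csv(path, sep=sep, dtype={0: str})


def collapse_probes(values: pd.DataFrame, probe_map: Mapping[str, str]) -> tuple[pd.DataFrame, int]:
    """Average rows mapping to the same gene; drop and count unmapped probes."""
    mapped = values.index.to_series().map(dict(probe_map))
    n_unmapped = int(mapped.isna().sum())
    kept = values.loc[mapped.notna()]
    genes = mapped.dropna()
    collapsed = kept.groupby(genes.values, sort=True).mean()
    collapsed.index.name = values.index.name
    return collapsed, n_unmapped


def read_expression(
    path: str | Path,
    probe_map: Mapping[str, str] | str | Path | None = None,
) -> tuple[ExpressionMatrix, LoadReport]:
    """Read a genes-or-probes x samples log-expression table.

    ``probe_map`` may be a probe->gene mapping or a path to a two-column
    (probe, gene) TSV. When given, multi-probe genes are collapsed by the
    arithmetic mean of their log values and unmapped probes are dropped
    (counted in the returned :class:`LoadReport`).
    """
    raw = _read_table(path, check_header=True)
    id_col = raw.columns[0]
    if raw[id_col].duplicated().any() and probe_map is None:
        raise ValueError("duplicate row ids without a probe map")
    values = raw.set_index(id_col)
    bad = values.columns[values.dtypes == object]
    if len(bad):
        col = bad[0]
        row = values.index[pd.to_numeric(values[col], errors="coerce").isna()][0]
        raise ValueError(f"non-numeric cell at row {row!r}, column {col!r}")
    values = values.astype(float)

    n_in = values.shape[0]
    n_unmapped = 0
    if probe_map is not None:
        if isinstance(probe_map, (str, Path)):
            pm = _read_table(probe_map)
            probe_map = dict(zip(pm.iloc[:, 0].astype(str), pm.iloc[:, 1].astype(str)))
        values, n_unmapped = collapse_probes(values, probe_map)

    matrix = ExpressionMatrix(values, scale_tag=RAW_LOG)
    report = LoadReport(n_in, matrix.n_genes, n_unmapped)
    logger.info(
        "read_expression: %d rows -> %d genes (%d unmapped probes dropped), %d samples",
        n_in, matrix.n_genes, n_unmapped, matrix.n_samples,
    )
    return matrix, report


def write_expression(m: ExpressionMatrix, path: str | Path) -> None:
    out = m.values.copy()
    out.index.name = out.index.name or "gene"
    out.to_csv(path, sep="\t")


def scale_arrays(m: ExpressionMatrix) -> ExpressionMatrix:
    """Transform each sample column to standard scores (mean 0, sd 1, ddof=1).

    Used when arrays from several series are pooled and per-array intensity
    distributions must be made comparable.
    """
    if m.scale_tag != RAW_LOG:
        raise ValueError("scale_arrays expects raw_log input")
    arr = m.values.to_numpy()
    sd = arr.std(axis=0, ddof=1)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        raise ValueError(f"zero-variance sample column: {m.sample_ids[zero[0]]!r}")
    scaled = (arr - arr.mean(axis=0)) / sd
    return ExpressionMatrix(
        pd.DataFrame(scaled, index=m.values.index, columns=m.values.columns),
        scale_tag=STANDARD_SCORE,
    )


_TRUE = {"1", "true", "yes", "y", "t", "dead", "event", "recurrence"}
_FALSE = {"0", "false", "no", "n", "f", "alive", "censored", "none"}


def _parse_bool(value) -> bool | None:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    s = str(value).strip().lower()
    if s in _TRUE:
        return True
    if s in _FALSE:
        return False
    if s in ("", "na", "nan", "unknown"):
        return None
    raise ValueError(f"cannot parse boolean value {value!r}")


def _parse_stage(value, stage_map: Mapping[str, str] | None) -> str:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return "unknown"
    s = str(value).strip()
    if stage_map and s in stage_map:
        return stage_map[s]
    u = s.upper()
    if u in ("I", "1", "1A", "1B", "IA", "IB"):
        return "I"
    if u in ("II", "2", "2A", "2B", "IIA", "IIB"):
        return "II"
    if u in ("III", "3", "3A", "3B", "IIIA", "IIIB"):
        return "III"
    return "unknown"


def read_clinical(
    path: str | Path,
    schema: Mapping[str, str],
    expression: ExpressionMatrix | None = None,
    stage_map: Mapping[str, str] | None = None,
    flag_columns: Mapping[str, str] | None = None,
) -> tuple[CohortTable, JoinReport | None]:
    """Read a clinical table into a :class:`CohortTable`.

    ``schema`` maps the canonical field names {"id", "time", "event"} (and
    optionally "stage", "adjuvant_therapy") to the file's column names.
    ``flag_columns`` maps subtype-flag names to columns (e.g. triple-negative,
    T1, N0). When an ``expression`` matrix is supplied, a join report of
    matched/unmatched sample ids is returned — unmatched records are reported,
    never silently dropped.
    """
    for key in ("id", "time", "event"):
        if key not in schema:
            raise ValueError(f"schema missing mandatory field {key!r}")
    df = _read_table(path)
    for col in schema.values():
        if col not in df.columns:
            raise ValueError(f"clinical table missing column {col!r}")

    records = []
    for _, row in df.iterrows():
        flags = {}
        for name, col in (flag_columns or {}).items():
            flags[name] = _parse_bool(row[col])
        records.append(
            ClinicalRecord(
                sample_id=str(row[schema["id"]]),
                time=float(row[schema["time"]]),
                event=bool(_parse_bool(row[schema["event"]])),
                stage=_parse_stage(row.get(schema.get("stage", "")), stage_map),
                adjuvant_therapy=_parse_bool(row[schema["adjuvant_therapy"]])
                if "adjuvant_therapy" in schema
                else None,
                subtype_flags=flags,
            )
        )
    cohort = CohortTable(records)

    report = None
    if expression is not None:
        expr_ids = set(expression.sample_ids)
        clin_ids = set(cohort.sample_ids)
        report = JoinReport(
            matched=sorted(expr_ids & clin_ids),
            unmatched_clinical=sorted(clin_ids - expr_ids),
            unmatched_expression=sorted(expr_ids - clin_ids),
        )
        logger.info(
            "read_clinical: %d records, %d matched to arrays, %d unmatched",
            len(cohort), len(report.matched), len(report.unmatched_clinical),
        )
    return cohort, report


def write_clinical(cohort: CohortTable, path: str | Path) -> None:
    cohort.to_frame().to_csv(path, index=False)


@dataclass
class AnnotationTable:
    """gene id -> free-text description used for keyword gene-set search."""

    descriptions: pd.Series

    @classmethod
    def from_pairs(cls, pairs: Sequence[tuple[str, str]]) -> "AnnotationTable":
        df = pd.DataFrame(pairs, columns=["gene_id", "description"])
        # duplicates concatenated so every keyword hit survives the merge
        merged = df.groupby("gene_id", sort=True)["description"].agg("; ".join)
        return cls(merged)

    @classmethod
    def read(cls, path: str | Path) -> "AnnotationTable":
        df = _read_table(path)
        return cls.from_pairs(list(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str))))


def flag_genes_by_keyword(
    annotation: AnnotationTable,
    keywords: Sequence[str],
    extra_genes: Sequence[str] = (),
    universe: Sequence[str] | None = None,
) -> set[str]:
    """Case-insensitive substring search of annotation descriptions.

    Returns the union of keyword hits and ``extra_genes``, restricted to
    ``universe`` (defaults to the annotated genes) — the mechanism behind
    assembling e.g. an immune gene set from terms like "immuno" or "B-cell".
    """
    keywords = [k.strip() for k in keywords if k and k.strip()]
    if not keywords:
        raise ValueError("keyword list is empty")
    desc = annotation.descriptions.str.lower()
    hits: set[str] = set()
    for kw in keywords:
        hits |= set(desc.index[desc.str.contains(kw.lower(), regex=False)])
    allowed = set(universe) if universe is not None else set(annotation.descriptions.index)
    return (hits | set(extra_genes)) & allowed


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=str))
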