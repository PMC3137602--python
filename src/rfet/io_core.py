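"""Expression-matrix and sample-metadata data model plus text I/O.

All tabular I/O is tab-separated with a header row. Probe identifiers are
opaque strings and never parsed. Matrices are held in the canonical
genes-in-rows orientation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._errors import DataError, ConfigError

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "SampleRecord",
    "SampleTable",
    "RankedEntry",
    "RankedList",
    "read_expression_tsv",
    "write_expression_tsv",
    "read_geo_series_matrix",
    "read_sample_table",
    "write_sample_table",
    "read_ranked_list",
    "write_ranked_list",
    "align",
    "quantile_normalize",
    "log2_transform",
    "bundled_resistant_samples",
    "bundled_susceptible_samples",
]

# full round-trip precision for all float output
_FLOAT_FMT = "%.17g"


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: dict[str, int] = {}
    dups = []
    for i in ids:
        if i in seen:
            dups.append(i)
        seen[i] = 1
    if dups:
        raise DataError(f"duplicate {what} identifier(s): {sorted(set(dups))}")


@dataclass
class ExpressionMatrix:
    """Genes-by-samples matrix of normalized log-scale expression values."""

    probe_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DataError("expression values must be a 2-D array")
        if self.values.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise DataError(
                f"shape {self.values.shape} does not match "
                f"{len(self.probe_ids)} probes x {len(self.sample_ids)} samples"
            )
        _check_unique(self.probe_ids, "probe")
        _check_unique(self.sample_ids, "sample")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise DataError(
                f"non-finite expression value at probe "
                f"{self.probe_ids[bad[0]]!r}, sample {self.sample_ids[bad[1]]!r}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.probe_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def subset_probes(self, probes: Sequence[str]) -> "ExpressionMatrix":
        """Return the matrix restricted to ``probes``, in the given order."""
        index = {p: i for i, p in enumerate(self.probe_ids)}
        missing = [p for p in probes if p not in index]
        if missing:
            raise DataError(f"probes absent from matrix: {missing}")
        rows = [index[p] for p in probes]
        return ExpressionMatrix(list(probes), list(self.sample_ids), self.values[rows])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.probe_ids, columns=self.sample_ids)


@dataclass
class SampleRecord:
    sample_id: str
    group: str
    condition: str
    replicate: int
    class_label: int

    def __post_init__(self) -> None:
        if self.class_label not in (0, 1):
            raise DataError(
                f"sample {self.sample_id!r}: class_label must be 0 or 1, "
                f"got {self.class_label!r}"
            )
        if self.replicate < 1:
            raise DataError(f"sample {self.sample_id!r}: replicate must be >= 1")


@dataclass
class SampleTable:
    """Per-sample metadata with binary class labels (1/0)."""

    records: list[SampleRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        _check_unique(self.sample_ids, "sample")

    @property
    def sample_ids(self) -> list[str]:
        return [r.sample_id for r in self.records]

    @property
    def class_labels(self) -> np.ndarray:
        return np.array([r.class_label for r in self.records], dtype=int)

    def __len__(self) -> int:
        return len(self.records)

    def require_both_classes(self) -> None:
        labels = set(self.class_labels.tolist())
        if labels != {0, 1}:
            raise DataError(f"both classes required for training; labels present: {sorted(labels)}")


@dataclass
class RankedEntry:
    probe_id: str
    elimination_step: int  # 1 = first eliminated, G = last eliminated (best)
    criterion: float  # squared SVM weight at elimination time


@dataclass
class RankedList:
    """One full gene ranking: a permutation of the input probe set.

    Rank 1 is the last-eliminated (best) gene; rank G the first-eliminated.
    """

    entries: list[RankedEntry]

    def __post_init__(self) -> None:
        g = len(self.entries)
        steps = sorted(e.elimination_step for e in self.entries)
        if steps != list(range(1, g + 1)):
            raise DataError("elimination steps must be exactly 1..G with no gaps")
        _check_unique([e.probe_id for e in self.entries], "probe")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def probe_ids(self) -> list[str]:
        return [e.probe_id for e in self.entries]

    def ordered_probes(self) -> list[str]:
        """Probe ids best-to-worst (rank 1 first)."""
        g = len(self.entries)
        return [e.probe_id for e in sorted(self.entries, key=lambda e: g - e.elimination_step)]

    def ranks(self) -> dict[str, int]:
        """Map probe id -> rank (1 = best)."""
        g = len(self.entries)
        return {e.probe_id: g - e.elimination_step + 1 for e in self.entries}

    def criteria(self) -> dict[str, float]:
        return {e.probe_id: e.criterion for e in self.entries}


# ---------------------------------------------------------------------------
# expression matrix I/O


def read_expression_tsv(path: str | Path, orientation: str = "genes_in_rows") -> ExpressionMatrix:
    """Read a TSV expression table into canonical genes-in-rows form.

    The first column carries row identifiers and the header row carries
    column identifiers. ``orientation`` states what the file's rows are.
    """
    if orientation not in ("genes_in_rows", "samples_in_rows"):
        raise ConfigError(f"unknown orientation {orientation!r}")
    path = Path(path)
    if not path.exists():
        raise DataError(f"expression file not found: {path}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.index.has_duplicates:
        dups = sorted(set(df.index[df.index.duplicated()]))
        raise DataError(f"duplicate row identifier(s): {dups}")
    if df.columns.has_duplicates:
        dups = sorted(set(df.columns[df.columns.duplicated()]))
        raise DataError(f"duplicate column identifier(s): {dups}")
    try:
        values = df.to_numpy(dtype=float)
        if np.any(~np.isfinite(values)):
            raise ValueError
    except (ValueError, TypeError):
        # slow path only to locate the offending cell for the error message
        for j, col in enumerate(df.columns):
            for i, raw in enumerate(df[col]):
                if raw is None or (isinstance(raw, float) and np.isnan(raw)) or str(raw).strip() == "":
                    raise DataError(f"missing value at row {df.index[i]!r}, column {col!r}") from None
                try:
                    v = float(raw)
                except ValueError:
                    raise DataError(
                        f"non-numeric value {raw!r} at row {df.index[i]!r}, column {col!r}"
                    ) from None
                if not np.isfinite(v):
                    raise DataError(
                        f"non-finite value {raw!r} at row {df.index[i]!r}, column {col!r}"
                    ) from None
        raise DataError(f"{path}: could not parse numeric table") from None
    if orientation == "samples_in_rows":
        return ExpressionMatrix(list(df.columns), [str(i) for i in df.index], values.T)
    return ExpressionMatrix([str(i) for i in df.index], list(df.columns), values)


def write_expression_tsv(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.to_frame().to_csv(path, sep="\t", index_label="probe_id", float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# GEO series matrix

_GEO_BEGIN = "!series_matrix_table_begin"
_GEO_END = "!series_matrix_table_end"


def _geo_unquote(tok: str) -> str:
    tok = tok.strip()
    if len(tok) >= 2 and tok[0] == '"' and tok[-1] == '"':
        tok = tok[1:-1]
    return tok


def read_geo_series_matrix(path: str | Path) -> tuple[ExpressionMatrix, list[dict[str, str]]]:
    """Parse a GEO Series Matrix text file.

    Returns the expression matrix (probes x GSM samples) and one free-text
    metadata dict per sample, built from the ``!Sample_*`` header lines.
    Class labels are *not* inferred; supply them via a sample table.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"series matrix file not found: {path}")
    sample_meta_lines: dict[str, list[str]] = {}
    table_lines: list[str] = []
    in_table = False
    saw_begin = saw_end = False
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.strip() == _GEO_BEGIN:
                in_table, saw_begin = True, True
                continue
            if line.strip() == _GEO_END:
                in_table, saw_end = False, True
                continue
            if in_table:
                if line.strip():
                    table_lines.append(line)
            elif line.startswith("!Sample_"):
                key = line.split("\t", 1)[0][len("!Sample_"):]
                vals = [_geo_unquote(t) for t in line.split("\t")[1:]]
                # repeated keys (e.g. characteristics_ch1) accumulate
                if key in sample_meta_lines:
                    sample_meta_lines[key] = [
                        f"{a}; {b}" if a else b for a, b in zip(sample_meta_lines[key], vals)
                    ]
                else:
                    sample_meta_lines[key] = vals
    if not saw_begin:
        raise DataError(f"{path}: no '{_GEO_BEGIN}' marker found")
    if not saw_end:
        raise DataError(f"{path}: table block not terminated by '{_GEO_END}'")
    if not table_lines:
        raise DataError(f"{path}: empty series matrix table block")

    header = [_geo_unquote(t) for t in table_lines[0].split("\t")]
    sample_ids = header[1:]
    n_cols = len(header)
    probe_ids: list[str] = []
    rows: list[list[float]] = []
    for lineno, line in enumerate(table_lines[1:], start=2):
        toks = line.split("\t")
        if len(toks) != n_cols:
            raise DataError(
                f"{path}: ragged table row {lineno} has {len(toks)} fields, expected {n_cols}"
            )
        probe_ids.append(_geo_unquote(toks[0]))
        try:
            rows.append([float(_geo_unquote(t)) for t in toks[1:]])
        except ValueError:
            raise DataError(f"{path}: non-numeric value in table row {lineno}") from None
    matrix = ExpressionMatrix(probe_ids, sample_ids, np.array(rows, dtype=float))

    meta: list[dict[str, str]] = []
    for j, sid in enumerate(sample_ids):
        rec = {"sample_id": sid}
        for key, vals in sample_meta_lines.items():
            if j < len(vals):
                rec[key] = vals[j]
        meta.append(rec)
    return matrix, meta


# ---------------------------------------------------------------------------
# sample table I/O

_SAMPLE_COLUMNS = ["sample_id", "group", "condition", "replicate", "class_label"]


def read_sample_table(path: str | Path) -> SampleTable:
    """Read per-sample metadata (TSV with sample_id ... class_label columns)."""
    path = Path(path)
    if not path.exists():
        raise DataError(f"sample table not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in ("sample_id", "class_label") if c not in df.columns]
    if missing:
        raise DataError(f"{path}: missing required column(s) {missing}")
    records = []
    for i, row in df.iterrows():
        raw_label = str(row["class_label"]).strip()
        if raw_label not in ("0", "1"):
            raise DataError(
                f"{path}: row {i + 2} (sample {row['sample_id']!r}): "
                f"class_label must be 0 or 1, got {raw_label!r}"
            )
        rep_raw = str(row.get("replicate", "1")).strip()
        try:
            rep = int(rep_raw)
        except ValueError:
            raise DataError(f"{path}: row {i + 2}: replicate {rep_raw!r} is not an integer") from None
        records.append(
            SampleRecord(
                sample_id=str(row["sample_id"]).strip(),
                group=str(row.get("group", "")).strip(),
                condition=str(row.get("condition", "")).strip(),
                replicate=rep,
                class_label=int(raw_label),
            )
        )
    return SampleTable(records)


def write_sample_table(table: SampleTable, path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "sample_id": r.sample_id,
                "group": r.group,
                "condition": r.condition,
                "replicate": r.replicate,
                "class_label": r.class_label,
            }
            for r in table.records
        ],
        columns=_SAMPLE_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# ranked list I/O


def write_ranked_list(ranked: RankedList, path: str | Path) -> None:
    g = len(ranked)
    rows = sorted(ranked.entries, key=lambda e: g - e.elimination_step)
    df = pd.DataFrame(
        {
            "rank": [g - e.elimination_step + 1 for e in rows],
            "probe_id": [e.probe_id for e in rows],
            "elimination_step": [e.elimination_step for e in rows],
            "criterion": [e.criterion for e in rows],
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_ranked_list(path: str | Path) -> RankedList:
    path = Path(path)
    if not path.exists():
        raise DataError(f"ranked list not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str})
    required = {"probe_id", "elimination_step", "criterion"}
    if not required.issubset(df.columns):
        raise DataError(f"{path}: ranked list needs columns {sorted(required)}")
    entries = [
        RankedEntry(str(r.probe_id), int(r.elimination_step), float(r.criterion))
        for r in df.itertuples()
    ]
    return RankedList(entries)


# ---------------------------------------------------------------------------
# alignment and normalization


def align(matrix: ExpressionMatrix, samples: SampleTable) -> tuple[ExpressionMatrix, np.ndarray]:
    """Reorder matrix columns to the sample table's order.

    Returns the column-subset matrix and the aligned 0/1 label vector.
    Matrix columns not mentioned in the table are dropped (logged); table
    samples missing from the matrix are an error.
    """
    col_index = {s: j for j, s in enumerate(matrix.sample_ids)}
    missing = [s for s in samples.sample_ids if s not in col_index]
    if missing:
        raise DataError(f"sample(s) in table absent from matrix: {missing}")
    dropped = [s for s in matrix.sample_ids if s not in set(samples.sample_ids)]
    if dropped:
        logger.info("align: dropping %d matrix column(s) not in sample table: %s", len(dropped), dropped)
    cols = [col_index[s] for s in samples.sample_ids]
    out = ExpressionMatrix(list(matrix.probe_ids), list(samples.sample_ids), matrix.values[:, cols])
    return out, samples.class_labels.copy()


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Quantile-normalize columns to their common mean distribution.

    Each column is mapped onto the row-wise mean of the per-column sorted
    values; within-column ties receive the mean of the target values across
    the tied rank span.
    """
    if matrix.n_samples < 2:
        raise DataError("quantile normalization needs at least 2 samples")
    x = matrix.values
    g, n = x.shape
    order = np.argsort(x, axis=0, kind="stable")
    sorted_cols = np.take_along_axis(x, order, axis=0)
    target = sorted_cols.mean(axis=1)
    out = np.empty_like(x)
    for j in range(n):
        col = x[:, j]
        idx = order[:, j]
        vals = col[idx]
        assigned = target.copy()
        # average the target over each run of tied input values
        start = 0
        for end in range(1, g + 1):
            if end == g or vals[end] != vals[start]:
                if end - start > 1:
                    assigned[start:end] = target[start:end].mean()
                start = end
        out[idx, j] = assigned
    return ExpressionMatrix(list(matrix.probe_ids), list(matrix.sample_ids), out)


_DATA_DIR = Path(__file__).parent / "data"


def bundled_resistant_samples() -> SampleTable:
    """Sample metadata for the drought-tolerant transgenic lines (bundled)."""
    return read_sample_table(_DATA_DIR / "resistant_samples.tsv")


def bundled_susceptible_samples() -> SampleTable:
    """Sample metadata for the drought-susceptible wild-type/control lines (bundled)."""
    return read_sample_table(_DATA_DIR / "susceptible_samples.tsv")


def log2_transform(matrix: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """log2(x + pseudocount) for matrices still on the linear scale."""
    if np.any(matrix.values + pseudocount <= 0):
        raise DataError("log2 transform requires values + pseudocount > 0")
    return ExpressionMatrix(
        list(matrix.probe_ids), list(matrix.sample_ids), np.log2(matrix.values + pseudocount)
    )
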