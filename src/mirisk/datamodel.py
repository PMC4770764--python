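"""Core containers and tab-delimited readers/writers.

The interchange format is plain TSV: expression matrices carry a single
``#scale=`` metadata comment line, annotation tables use a fixed header,
prediction tables are gene-by-tool 0/1 matrices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from mirisk.errors import (
    AlignmentError,
    IdentifierError,
    ParseError,
    SchemaError,
    ValidationError,
)

logger = logging.getLogger(__name__)


class Scale(str, Enum):
    RAW = "raw"
    LOG2 = "log2"


class Group(str, Enum):
    BMPC = "BMPC"
    MGUS = "MGUS"
    MM = "MM"
    HMCL = "HMCL"


class Flag(str, Enum):
    PRESENT = "present"
    ABSENT = "absent"
    UNKNOWN = "unknown"


ABERRATION_NAMES = (
    "t4_14",
    "t11_14",
    "del17p",
    "gain1q21",
    "del13q",
    "hyperdiploid",
)

ISS_STAGES = ("I", "II", "III", "unknown")

ANNOTATION_COLUMNS = (
    "sample_id",
    "group",
    "t4_14",
    "t11_14",
    "del17p",
    "gain1q21",
    "del13q",
    "hyperdiploid",
    "iss",
    "b2m",
    "gpi",
    "uams",
    "ifm",
    "efs_time",
    "efs_event",
    "os_time",
    "os_event",
)


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen = set()
    for i in ids:
        if i in seen:
            raise IdentifierError(f"duplicate {what} id: {i!r}")
        seen.add(i)


@dataclass
class ExpressionMatrix:
    """Probe-by-sample numeric matrix with a scale tag (raw | log2)."""

    probe_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    scale: Scale = Scale.LOG2

    def __post_init__(self) -> None:
        self.probe_ids = [str(p) for p in self.probe_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.scale = Scale(self.scale)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("expression values must be a 2-D matrix")
        if self.values.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise ValidationError(
                f"shape {self.values.shape} does not match "
                f"{len(self.probe_ids)} probes x {len(self.sample_ids)} samples"
            )
        _check_unique(self.probe_ids, "probe")
        _check_unique(self.sample_ids, "sample")
        if self.scale is Scale.LOG2 and not np.all(np.isfinite(self.values)):
            raise ValidationError("log2-scale matrix contains non-finite values")

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def probe_index(self, probe_id: str) -> int:
        try:
            return self.probe_ids.index(probe_id)
        except ValueError:
            raise KeyError(probe_id) from None

    def subset_probes(self, probe_ids: Sequence[str]) -> "ExpressionMatrix":
        idx = {p: i for i, p in enumerate(self.probe_ids)}
        missing = [p for p in probe_ids if p not in idx]
        if missing:
            raise AlignmentError(f"unknown probes: {missing}")
        rows = [idx[p] for p in probe_ids]
        return ExpressionMatrix(
            list(probe_ids), list(self.sample_ids), self.values[rows, :], self.scale
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in idx]
        if missing:
            raise AlignmentError(f"unknown samples: {missing}")
        cols = [idx[s] for s in sample_ids]
        return ExpressionMatrix(
            list(self.probe_ids), list(sample_ids), self.values[:, cols], self.scale
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.probe_ids, columns=self.sample_ids)


@dataclass(frozen=True)
class SurvivalOutcome:
    """Right-censored time-to-event outcome (time in months)."""

    time: float
    event: bool

    def __post_init__(self) -> None:
        if not np.isfinite(self.time) or self.time <= 0:
            raise ValidationError(f"survival time must be positive, got {self.time}")


@dataclass
class ClinicalAnnotation:
    """Per-sample clinical record: group, aberration flags, stage, risk indices,
    and EFS/OS outcomes. Missing values are None (flags: Flag.UNKNOWN)."""

    sample_id: str
    group: Group
    aberrations: Mapping[str, Flag] = field(
        default_factory=lambda: {a: Flag.UNKNOWN for a in ABERRATION_NAMES}
    )
    iss_stage: str = "unknown"
    b2m: float | None = None
    gpi: float | None = None
    uams_score: float | None = None
    ifm_score: float | None = None
    efs: SurvivalOutcome | None = None
    os: SurvivalOutcome | None = None

    def __post_init__(self) -> None:
        self.group = Group(self.group)
        self.aberrations = {
            a: Flag(self.aberrations.get(a, Flag.UNKNOWN)) for a in ABERRATION_NAMES
        }
        if self.iss_stage not in ISS_STAGES:
            raise SchemaError(f"unknown ISS stage {self.iss_stage!r}")
        if self.b2m is not None and self.b2m < 0:
            raise ValidationError("b2m must be non-negative")


@dataclass
class PredictionTable:
    """Boolean gene-by-tool target-prediction calls (7 tools by default)."""

    gene_ids: list[str]
    tool_names: list[str]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.tool_names = [str(t) for t in self.tool_names]
        self.calls = np.asarray(self.calls, dtype=bool)
        _check_unique(self.gene_ids, "gene")
        if self.calls.shape != (len(self.gene_ids), len(self.tool_names)):
            raise ValidationError("calls shape does not match gene/tool counts")

    @property
    def n_tools(self) -> int:
        return len(self.tool_names)


# ---------------------------------------------------------------------------
# readers / writers


def read_expression(path, scale: Scale | str | None = None) -> ExpressionMatrix:
    """Read a tab-delimited expression matrix.

    First column is the probe id, the header row holds sample ids. An optional
    leading ``#scale=raw|log2`` comment declares the scale; an explicit
    ``scale`` argument overrides it (default log2).
    """
    path = str(path)
    file_scale = None
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#scale="):
            file_scale = first.strip().split("=", 1)[1]
            header_line = fh.readline()
        else:
            header_line = first
        header = header_line.rstrip("\n").split("\t")
        if len(header) < 2:
            raise SchemaError(f"{path}: expected probe_id column plus >=1 sample")
        sample_ids = header[1:]
        probe_ids: list[str] = []
        rows: list[list[float]] = []
        for lineno, line in enumerate(fh, start=3 if file_scale else 2):
            line = line.rstrip("\n")
            if not line:
                continue
            cells = line.split("\t")
            if len(cells) != len(header):
                raise ParseError(f"{path}:{lineno}: expected {len(header)} columns, got {len(cells)}")
            probe_ids.append(cells[0])
            row = []
            for col, cell in enumerate(cells[1:], start=2):
                if cell == "":
                    raise ParseError(f"{path}:{lineno}: missing value in column {col}")
                try:
                    row.append(float(cell))
                except ValueError:
                    raise ParseError(
                        f"{path}:{lineno}: non-numeric cell {cell!r} in column {col}"
                    ) from None
            rows.append(row)
    if scale is None:
        scale = file_scale if file_scale is not None else Scale.LOG2
    return ExpressionMatrix(probe_ids, sample_ids, np.array(rows, dtype=float), Scale(scale))


def write_expression(matrix: ExpressionMatrix, path) -> None:
    """Write a matrix as TSV with a ``#scale=`` metadata line.

    Values are rendered with repr-style shortest round-trip formatting, so a
    write/read cycle reproduces them bit-for-bit.
    """
    if matrix.n_probes == 0:
        raise ValidationError("refusing to write a matrix with no probes")
    path = str(path)
    with open(path, "w") as fh:
        fh.write(f"#scale={matrix.scale.value}\n")
        fh.write("probe_id\t" + "\t".join(matrix.sample_ids) + "\n")
        for i, pid in enumerate(matrix.probe_ids):
            cells = "\t".join(repr(float(v)) for v in matrix.values[i])
            fh.write(f"{pid}\t{cells}\n")


def _parse_flag(cell: str) -> Flag:
    if cell == "":
        return Flag.UNKNOWN
    low = cell.strip().lower()
    if low in ("present", "1", "yes", "true"):
        return Flag.PRESENT
    if low in ("absent", "0", "no", "false"):
        return Flag.ABSENT
    if low == "unknown":
        return Flag.UNKNOWN
    raise SchemaError(f"unknown aberration flag value {cell!r}")


def _parse_float(cell: str, what: str) -> float | None:
    if cell == "":
        return None
    try:
        return float(cell)
    except ValueError:
        raise ParseError(f"non-numeric {what}: {cell!r}") from None


def _parse_outcome(time_cell: str, event_cell: str, what: str) -> SurvivalOutcome | None:
    if time_cell == "" and event_cell == "":
        return None
    if time_cell == "" or event_cell == "":
        raise SchemaError(f"{what}: time and event must both be present or both missing")
    t = float(time_cell)
    ev = event_cell.strip().lower()
    if ev in ("1", "true", "yes"):
        event = True
    elif ev in ("0", "false", "no"):
        event = False
    else:
        raise SchemaError(f"{what}: bad event flag {event_cell!r}")
    return SurvivalOutcome(time=t, event=event)


def read_annotation(path) -> list[ClinicalAnnotation]:
    """Read the fixed-header annotation TSV (empty string = missing)."""
    path = str(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        missing_cols = [c for c in ANNOTATION_COLUMNS if c not in header]
        if missing_cols:
            raise SchemaError(f"{path}: missing mandatory columns {missing_cols}")
        col = {c: header.index(c) for c in ANNOTATION_COLUMNS}
        records: list[ClinicalAnnotation] = []
        seen: set[str] = set()
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            cells = line.split("\t")
            if len(cells) != len(header):
                raise ParseError(f"{path}:{lineno}: expected {len(header)} columns")

            def get(name: str) -> str:
                return cells[col[name]]

            sid = get("sample_id")
            if sid in seen:
                raise IdentifierError(f"{path}:{lineno}: duplicate sample id {sid!r}")
            seen.add(sid)
            group_cell = get("group")
            try:
                group = Group(group_cell)
            except ValueError:
                raise SchemaError(f"{path}:{lineno}: unknown group {group_cell!r}") from None
            iss = get("iss") or "unknown"
            if iss not in ISS_STAGES:
                raise SchemaError(f"{path}:{lineno}: unknown ISS stage {iss!r}")
            try:
                record = ClinicalAnnotation(
                    sample_id=sid,
                    group=group,
                    aberrations={a: _parse_flag(get(a)) for a in ABERRATION_NAMES},
                    iss_stage=iss,
                    b2m=_parse_float(get("b2m"), "b2m"),
                    gpi=_parse_float(get("gpi"), "gpi"),
                    uams_score=_parse_float(get("uams"), "uams"),
                    ifm_score=_parse_float(get("ifm"), "ifm"),
                    efs=_parse_outcome(get("efs_time"), get("efs_event"), "efs"),
                    os=_parse_outcome(get("os_time"), get("os_event"), "os"),
                )
            except (ValidationError, SchemaError) as exc:
                raise type(exc)(f"{path}:{lineno}: {exc}") from None
            records.append(record)
    return records


def write_annotation(records: Sequence[ClinicalAnnotation], path) -> None:
    """Write annotation records back to the fixed-header TSV."""

    def fmt(v) -> str:
        return "" if v is None else repr(float(v))

    with open(str(path), "w") as fh:
        fh.write("\t".join(ANNOTATION_COLUMNS) + "\n")
        for r in records:
            cells = [
                r.sample_id,
                r.group.value,
                *(r.aberrations[a].value for a in ABERRATION_NAMES),
                r.iss_stage,
                fmt(r.b2m),
                fmt(r.gpi),
                fmt(r.uams_score),
                fmt(r.ifm_score),
                fmt(r.efs.time) if r.efs else "",
                str(int(r.efs.event)) if r.efs else "",
                fmt(r.os.time) if r.os else "",
                str(int(r.os.event)) if r.os else "",
            ]
            fh.write("\t".join(cells) + "\n")


def read_prediction_table(path) -> PredictionTable:
    """Read a gene-by-tool 0/1 prediction TSV (header: gene_id + tool names)."""
    df = pd.read_csv(str(path), sep="\t", dtype={0: str})
    if df.columns[0] != "gene_id":
        raise SchemaError("prediction table must start with a gene_id column")
    tools = list(df.columns[1:])
    calls = df.iloc[:, 1:].to_numpy()
    if not np.isin(calls, (0, 1)).all():
        raise ParseError("prediction calls must be 0/1")
    return PredictionTable(list(df["gene_id"]), tools, calls.astype(bool))


def write_prediction_table(table: PredictionTable, path) -> None:
    with open(str(path), "w") as fh:
        fh.write("gene_id\t" + "\t".join(table.tool_names) + "\n")
        for i, g in enumerate(table.gene_ids):
            fh.write(g + "\t" + "\t".join(str(int(v)) for v in table.calls[i]) + "\n")


def align(
    matrix: ExpressionMatrix, annotations: Sequence[ClinicalAnnotation]
) -> tuple[ExpressionMatrix, list[ClinicalAnnotation]]:
    """Restrict matrix and annotations to their shared samples, in matrix
    column order. Logs any dropped ids; empty intersection is an error."""
    by_id = {a.sample_id: a for a in annotations}
    shared = [s for s in matrix.sample_ids if s in by_id]
    if not shared:
        raise AlignmentError("no samples shared between matrix and annotations")
    dropped_m = [s for s in matrix.sample_ids if s not in by_id]
    dropped_a = [s for s in by_id if s not in set(matrix.sample_ids)]
    if dropped_m:
        logger.info("align: dropped %d matrix samples without annotation: %s", len(dropped_m), dropped_m)
    if dropped_a:
        logger.info("align: dropped %d annotations without expression: %s", len(dropped_a), dropped_a)
    if not dropped_m and not dropped_a and [a.sample_id for a in annotations] == matrix.sample_ids:
        return matrix, list(annotations)
    sub = matrix if not dropped_m else matrix.subset_samples(shared)
    return sub, [replace(by_id[s]) for s in shared]
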