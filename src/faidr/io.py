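"""Domain containers and delimited-text I/O.

The unit of analysis is the intrinsically disordered region (IDR).  Feature
tables hold one row per IDR, grouped by protein; annotation tables hold one
binary label per protein and function.  IDR identifiers follow the dialect
``PROTEIN|start-end`` (1-based, inclusive amino-acid coordinates) with an
ordinal fallback ``PROTEIN|j`` for coordinate-free data.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("faidr")

FIT_FORMAT = "faidr-fit"
FIT_VERSION = 1

__all__ = [
    "IDRRecord",
    "FeatureTable",
    "AnnotationTable",
    "IDRLabelSet",
    "FaidrFit",
    "FeatureTableError",
    "AnnotationError",
    "FitFormatError",
    "read_feature_table",
    "write_feature_table",
    "read_annotation_table",
    "write_annotation_table",
    "map_sites_to_idrs",
    "read_fit",
    "write_fit",
    "read_idr_labels",
    "write_idr_labels",
]


class FeatureTableError(ValueError):
    """Malformed feature table (bad identifier, non-numeric cell, ...)."""


class AnnotationError(ValueError):
    """Malformed annotation table (non-binary cell, duplicate protein, ...)."""


class FitFormatError(ValueError):
    """Unreadable or incompatible serialized fit."""


@dataclass
class IDRRecord:
    """One disordered region: identity, optional coordinates, feature vector."""

    protein_id: str
    idr_index: int
    features: np.ndarray
    start: int | None = None
    end: int | None = None

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if self.idr_index < 1:
            raise FeatureTableError(f"idr_index must be >= 1, got {self.idr_index}")
        if (self.start is None) != (self.end is None):
            raise FeatureTableError("start and end must be given together")
        if self.start is not None and not (1 <= self.start <= self.end):
            raise FeatureTableError(
                f"invalid coordinates {self.start}-{self.end} for {self.protein_id}"
            )
        if not np.all(np.isfinite(self.features)):
            raise FeatureTableError(f"non-finite feature value in {self.idr_id}")

    @property
    def idr_id(self) -> str:
        if self.start is not None:
            return f"{self.protein_id}|{self.start}-{self.end}"
        return f"{self.protein_id}|{self.idr_index}"


class FeatureTable:
    """Per-IDR feature matrix with protein grouping.

    Rows keep file order.  ``protein_index`` maps each protein to the row
    positions of its IDRs; ``r_i = len(protein_index[p])`` is the number of
    disordered regions in protein ``p``.
    """

    def __init__(self, records: Sequence[IDRRecord], feature_names: Sequence[str]):
        feature_names = list(feature_names)
        if len(set(feature_names)) != len(feature_names):
            raise FeatureTableError("duplicate feature names")
        if not records:
            raise FeatureTableError("feature table has no rows")
        m = len(feature_names)
        seen: set[str] = set()
        index: dict[str, list[int]] = {}
        for pos, rec in enumerate(records):
            if rec.features.shape != (m,):
                raise FeatureTableError(
                    f"row {rec.idr_id} has {rec.features.size} features, expected {m}"
                )
            if rec.idr_id in seen:
                raise FeatureTableError(f"duplicate IDR identifier {rec.idr_id!r}")
            seen.add(rec.idr_id)
            index.setdefault(rec.protein_id, []).append(pos)
        self.records: list[IDRRecord] = list(records)
        self.feature_names: list[str] = feature_names
        self.protein_index: dict[str, list[int]] = index
        self.X: np.ndarray = np.vstack([r.features for r in records])
        self.idr_ids: list[str] = [r.idr_id for r in records]
        self.row_protein: list[str] = [r.protein_id for r in records]
        # integer protein label per row, in protein_index (first appearance) order
        order = {p: k for k, p in enumerate(index)}
        self.row_group: np.ndarray = np.array(
            [order[r.protein_id] for r in records], dtype=np.intp
        )

    @property
    def n_idrs(self) -> int:
        return len(self.records)

    @property
    def n_proteins(self) -> int:
        return len(self.protein_index)

    @property
    def protein_ids(self) -> list[str]:
        return list(self.protein_index)

    def r(self) -> np.ndarray:
        """Number of IDRs per protein, in ``protein_ids`` order."""
        return np.array([len(v) for v in self.protein_index.values()], dtype=np.intp)

    def subset_proteins(self, keep: Iterable[str]) -> "FeatureTable":
        keep_set = set(keep)
        recs = [r for r in self.records if r.protein_id in keep_set]
        return FeatureTable(recs, self.feature_names)


@dataclass
class AnnotationTable:
    """Protein-level binary labels, one column per function."""

    protein_ids: list[str]
    function_names: list[str]
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if len(set(self.protein_ids)) != len(self.protein_ids):
            raise AnnotationError("duplicate protein ids in annotation table")
        if self.labels.shape != (len(self.protein_ids), len(self.function_names)):
            raise AnnotationError("annotation matrix shape mismatch")
        if not np.isin(self.labels, (0, 1)).all():
            raise AnnotationError("annotation labels must be 0 or 1")

    def column(self, function: str) -> dict[str, int]:
        """Mapping protein -> label for one function."""
        try:
            j = self.function_names.index(function)
        except ValueError:
            raise AnnotationError(f"unknown function {function!r}") from None
        return {p: int(v) for p, v in zip(self.protein_ids, self.labels[:, j])}


@dataclass
class IDRLabelSet:
    """Binary IDR-level labels for one IDR-resolved function."""

    function_name: str
    idr_ids: list[str]
    labels: np.ndarray
    n_skipped_sites: int = 0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if self.labels.shape != (len(self.idr_ids),):
            raise ValueError("IDR label vector length mismatch")

    def as_dict(self) -> dict[str, int]:
        return {i: int(v) for i, v in zip(self.idr_ids, self.labels)}


@dataclass
class FaidrFit:
    """A fitted per-function model.

    ``responsibilities`` are the posterior probabilities that each IDR is the
    one responsible for its protein's annotation; they sum to one within each
    protein.  ``objective_trace`` records the penalized marginal log-likelihood
    at initialization and after every EM round.
    """

    function_name: str
    feature_names: list[str]
    coefficients: np.ndarray
    intercept: float
    idr_ids: list[str]
    responsibilities: np.ndarray
    lambda_: float
    alpha: float
    n_em_iterations: int
    objective_trace: list[float] = field(default_factory=list)
    converged: bool = True

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        self.responsibilities = np.asarray(self.responsibilities, dtype=float)
        if self.lambda_ <= 0:
            raise ValueError("lambda must be > 0")
        if not (0 < self.alpha <= 1):
            raise ValueError("alpha must be in (0, 1]")
        if self.responsibilities.size and (
            self.responsibilities.min() < -1e-12 or self.responsibilities.max() > 1 + 1e-12
        ):
            raise ValueError("responsibilities must lie in [0, 1]")

    @property
    def selected_features(self) -> list[str]:
        """Features with nonzero penalized coefficients."""
        return [n for n, b in zip(self.feature_names, self.coefficients) if b != 0.0]


_ID_RE = re.compile(r"^(?P<protein>.+)\|(?:(?P<start>\d+)-(?P<end>\d+)|(?P<ordinal>\d+))$")


def _parse_idr_id(token: str) -> tuple[str, int | None, int | None, int | None]:
    m = _ID_RE.match(token)
    if not m:
        raise FeatureTableError(
            f"cannot parse IDR identifier {token!r}; expected 'PROTEIN|start-end' or 'PROTEIN|j'"
        )
    if m.group("start") is not None:
        return m.group("protein"), int(m.group("start")), int(m.group("end")), None
    return m.group("protein"), None, None, int(m.group("ordinal"))


def _sniff_sep(path: str) -> str:
    with open(path) as fh:
        header = fh.readline()
    if "\t" in header:
        return "\t"
    if "," in header:
        return ","
    return "\t"


def read_feature_table(path: str) -> FeatureTable:
    """Read a delimited per-IDR feature table.

    First column: IDR identifier (``PROTEIN|start-end`` or ``PROTEIN|j``);
    remaining columns: numeric features named in the header.  Tab-delimited by
    default; comma auto-detected from the header line.
    """
    sep = _sniff_sep(path)
    # round_trip parsing keeps values bit-exact under write/read cycles
    df = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise FeatureTableError(f"duplicate IDR identifier {dup!r}")
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        column = df[col]
        if not pd.api.types.is_numeric_dtype(column):
            coerced = pd.to_numeric(column, errors="coerce")
            bad = coerced.isna() & ~column.isna()
            row = df.index[bad.to_numpy().nonzero()[0][0]]
            raise FeatureTableError(
                f"non-numeric ({df.loc[row, col]!r}) cell at row {row!r}, column {col!r}"
            )
        if column.isna().any():
            row = df.index[column.isna().to_numpy().nonzero()[0][0]]
            raise FeatureTableError(f"missing cell at row {row!r}, column {col!r}")
        values[:, j] = column.to_numpy(dtype=float)
    ordinals: dict[str, int] = {}
    records = []
    for i, token in enumerate(df.index):
        protein, start, end, ordinal = _parse_idr_id(str(token))
        if ordinal is None:
            ordinal = ordinals.get(protein, 0) + 1
        ordinals[protein] = ordinal
        records.append(
            IDRRecord(protein, ordinal, values[i], start=start, end=end)
        )
    return FeatureTable(records, [str(c) for c in df.columns])


def write_feature_table(table: FeatureTable, path: str) -> None:
    df = pd.DataFrame(table.X, index=table.idr_ids, columns=table.feature_names)
    df.index.name = "idr"
    # %.17g round-trips IEEE doubles exactly
    df.to_csv(path, sep="\t", float_format="%.17g")


def read_annotation_table(path: str, feature_table: FeatureTable | None = None) -> AnnotationTable:
    """Read a protein x function 0/1 table; header = function names."""
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    mat = np.empty(df.shape, dtype=np.int8)
    for j, col in enumerate(df.columns):
        for i, cell in enumerate(df[col]):
            if cell not in ("0", "1"):
                raise AnnotationError(
                    f"annotation cell at row {df.index[i]!r}, column {col!r} "
                    f"is {cell!r}; expected 0 or 1"
                )
            mat[i, j] = int(cell)
    tab = AnnotationTable([str(p) for p in df.index], [str(c) for c in df.columns], mat)
    if feature_table is not None:
        extra = set(tab.protein_ids) - set(feature_table.protein_index)
        if extra:
            logger.info(
                "%d annotated proteins have no IDR rows and are ignored in fitting",
                len(extra),
            )
    return tab


def write_annotation_table(table: AnnotationTable, path: str) -> None:
    df = pd.DataFrame(table.labels, index=table.protein_ids, columns=table.function_names)
    df.index.name = "protein"
    df.to_csv(path, sep="\t")


def map_sites_to_idrs(
    sites: Sequence[tuple[str, int]],
    idrs: FeatureTable,
    function_name: str = "site",
) -> IDRLabelSet:
    """Binarize site coordinates onto IDR intervals.

    An IDR is labeled 1 iff at least one site position ``p`` (1-based amino
    acid index) satisfies ``start <= p <= end``; every other IDR is labeled 0.
    Sites on proteins absent from the table are skipped and counted.
    """
    for rec in idrs.records:
        if rec.start is None:
            raise FeatureTableError(
                f"IDR {rec.idr_id} lacks coordinates; cannot map sites"
            )
    labels = np.zeros(idrs.n_idrs, dtype=np.int8)
    skipped = 0
    for protein, pos in sites:
        rows = idrs.protein_index.get(protein)
        if rows is None:
            skipped += 1
            continue
        for i in rows:
            rec = idrs.records[i]
            if rec.start <= pos <= rec.end:
                labels[i] = 1
    if skipped:
        logger.warning("%d sites on proteins absent from the feature table", skipped)
    return IDRLabelSet(function_name, list(idrs.idr_ids), labels, n_skipped_sites=skipped)


def write_fit(fit: FaidrFit, path: str) -> None:
    payload = {
        "format": FIT_FORMAT,
        "version": FIT_VERSION,
        "function_name": fit.function_name,
        "feature_names": fit.feature_names,
        "coefficients": [float(b) for b in fit.coefficients],
        "intercept": float(fit.intercept),
        "idr_ids": fit.idr_ids,
        "responsibilities": [float(x) for x in fit.responsibilities],
        "lambda": fit.lambda_,
        "alpha": fit.alpha,
        "n_em_iterations": fit.n_em_iterations,
        "objective_trace": [float(v) for v in fit.objective_trace],
        "converged": fit.converged,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
        fh.write("\n")


def read_fit(path: str) -> FaidrFit:
    try:
        with open(path) as fh:
            payload = json.load(fh)
    except json.JSONDecodeError as exc:
        raise FitFormatError(f"cannot parse fit file {path}: {exc}") from exc
    if not isinstance(payload, dict) or payload.get("format") != FIT_FORMAT:
        raise FitFormatError(f"{path} is not a {FIT_FORMAT} file")
    if payload.get("version") != FIT_VERSION:
        raise FitFormatError(
            f"fit file version {payload.get('version')} unsupported (expected {FIT_VERSION})"
        )
    return FaidrFit(
        function_name=payload["function_name"],
        feature_names=list(payload["feature_names"]),
        coefficients=np.asarray(payload["coefficients"], dtype=float),
        intercept=float(payload["intercept"]),
        idr_ids=list(payload["idr_ids"]),
        responsibilities=np.asarray(payload["responsibilities"], dtype=float),
        lambda_=float(payload["lambda"]),
        alpha=float(payload["alpha"]),
        n_em_iterations=int(payload["n_em_iterations"]),
        objective_trace=[float(v) for v in payload["objective_trace"]],
        converged=bool(payload["converged"]),
    )


def read_idr_labels(path: str, function_name: str = "site") -> IDRLabelSet:
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, header=None, dtype=str)
    ids = [str(v) for v in df.iloc[:, 0]]
    vals = []
    for v in df.iloc[:, 1]:
        if v not in ("0", "1"):
            raise ValueError(f"IDR label {v!r} is not 0/1")
        vals.append(int(v))
    return IDRLabelSet(function_name, ids, np.array(vals, dtype=np.int8))


def write_idr_labels(labels: IDRLabelSet, path: str) -> None:
    with open(path, "w") as fh:
        for i, v in zip(labels.idr_ids, labels.labels):
            fh.write(f"{i}\t{int(v)}\n")
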