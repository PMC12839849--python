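"""Readers and writers for the on-disk artifacts of the pipeline.

Expression matrices travel as TSV (genes in rows, samples in columns — the
GEO series-matrix convention), gene set collections as GMT, clinical tables
as CSV, and fitted models / signatures as JSON bundles with base64-encoded
numeric arrays so that provenance stays human-inspectable.
"""

from __future__ import annotations

import base64
import datetime
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

BUNDLE_VERSION = "cmsig-bundle-1"

VALID_SUBTYPES = ("CMS1", "CMS2", "CMS3", "CMS4", "NOLBL")

#: Label used for samples whose consensus subtype is unknown.
NOLBL = "NOLBL"


def _check_unique(ids, what: str) -> None:
    seen = set()
    for x in ids:
        if x in seen:
            raise ValueError(f"duplicate {what} id: {x!r}")
        seen.add(x)


@dataclass
class ExpressionMatrix:
    """Log-scale expression, genes x samples.

    Parameters
    ----------
    gene_ids, sample_ids
        Ordered, unique identifiers.
    values
        Real matrix of shape ``(len(gene_ids), len(sample_ids))``; every
        entry must be finite (no imputation is performed downstream).
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"({len(self.gene_ids)}, {len(self.sample_ids)})"
            )
        if len(self.gene_ids) < 2 or len(self.sample_ids) < 2:
            raise ValueError("expression matrix needs at least 2 genes and 2 samples")
        if not np.all(np.isfinite(self.values)):
            g, s = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite expression value for gene {self.gene_ids[g]!r}, "
                f"sample {self.sample_ids[s]!r}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ExpressionMatrix":
        return cls(list(frame.index), list(frame.columns), frame.to_numpy(dtype=float))

    def samples_frame(self) -> pd.DataFrame:
        """Samples x genes view, the orientation used for feature selection."""
        return self.to_frame().T


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT semantics): unique set names, deduplicated members."""

    sets: dict[str, tuple[str, ...]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            dedup = tuple(dict.fromkeys(members))
            if not dedup:
                raise ValueError(f"gene set {name!r} is empty after deduplication")
            self.sets[name] = dedup

    def __len__(self) -> int:
        return len(self.sets)

    def names(self) -> list[str]:
        return list(self.sets)

    def subset(self, names) -> "GeneSetCollection":
        return GeneSetCollection(
            {n: self.sets[n] for n in names},
            {n: self.descriptions.get(n, "") for n in names},
        )


@dataclass
class ClinicalTable:
    """Per-sample survival outcome plus optional subtype / cohort labels.

    ``time`` is in the declared ``time_unit`` (the upstream studies mix days
    and months, so the unit is always explicit); ``event`` is 1 for an
    observed event (recurrence/death), 0 for censoring.
    """

    sample_ids: list[str]
    time: np.ndarray
    event: np.ndarray
    subtype: np.ndarray | None = None
    cohort: np.ndarray | None = None
    time_unit: str = "months"
    n_excluded: int = 0

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        _check_unique(self.sample_ids, "sample")
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event)
        n = len(self.sample_ids)
        if self.time.shape != (n,) or self.event.shape != (n,):
            raise ValueError("time/event length does not match sample_ids")
        if np.any(~np.isfinite(self.time)) or np.any(self.time <= 0):
            bad = int(np.flatnonzero(~(np.isfinite(self.time) & (self.time > 0)))[0])
            raise ValueError(
                f"non-positive or missing survival time for sample "
                f"{self.sample_ids[bad]!r}"
            )
        ev = np.unique(self.event)
        if not set(ev.astype(float)).issubset({0.0, 1.0}):
            bad = int(np.flatnonzero(~np.isin(self.event.astype(float), (0.0, 1.0)))[0])
            raise ValueError(
                f"event indicator outside {{0,1}} for sample {self.sample_ids[bad]!r}: "
                f"{self.event[bad]!r}"
            )
        self.event = self.event.astype(int)
        if self.subtype is not None:
            self.subtype = np.asarray(self.subtype, dtype=object)
            if self.subtype.shape != (n,):
                raise ValueError("subtype length does not match sample_ids")
            bad = set(self.subtype) - set(VALID_SUBTYPES)
            if bad:
                raise ValueError(f"unknown subtype labels: {sorted(bad)}")
        if self.cohort is not None:
            self.cohort = np.asarray(self.cohort, dtype=object)
            if self.cohort.shape != (n,):
                raise ValueError("cohort length does not match sample_ids")

    def __len__(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        data = {"time": self.time, "event": self.event}
        if self.subtype is not None:
            data["subtype"] = self.subtype
        if self.cohort is not None:
            data["cohort"] = self.cohort
        return pd.DataFrame(data, index=pd.Index(self.sample_ids, name="sample_id"))

    def select(self, sample_ids) -> "ClinicalTable":
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in idx]
        if missing:
            raise KeyError(f"samples absent from clinical table: {missing[:5]}")
        take = [idx[s] for s in sample_ids]
        return ClinicalTable(
            [self.sample_ids[i] for i in take],
            self.time[take],
            self.event[take],
            None if self.subtype is None else self.subtype[take],
            None if self.cohort is None else self.cohort[take],
            self.time_unit,
        )


# ---------------------------------------------------------------------------
# expression TSV


def read_expression(
    path,
    transpose: bool = False,
    probe_map: dict[str, str] | None = None,
) -> ExpressionMatrix:
    """Read a genes x samples TSV (header = sample ids, first column = gene ids).

    ``transpose`` flips a samples-in-rows file; orientation is never guessed.
    ``probe_map`` optionally collapses probe rows to genes, keeping for each
    gene the probe with the maximum average expression.
    """
    frame = pd.read_csv(path, sep="\t", index_col=0)
    if transpose:
        frame = frame.T
    frame.index = frame.index.astype(str)
    frame.columns = frame.columns.astype(str)
    for axis, what in ((frame.index, "gene"), (frame.columns, "sample")):
        dup = axis[axis.duplicated()]
        if len(dup):
            raise ValueError(f"duplicate {what} id: {dup[0]!r}")
    for col in frame.columns:
        coerced = pd.to_numeric(frame[col], errors="coerce")
        bad = frame.index[coerced.isna() & frame[col].notna()]
        if len(bad):
            raise ValueError(
                f"non-numeric expression value at gene {bad[0]!r}, sample {col!r}"
            )
        if coerced.isna().any():
            raise ValueError(
                f"missing expression value at gene "
                f"{frame.index[coerced.isna()][0]!r}, sample {col!r}"
            )
        frame[col] = coerced
    if probe_map is not None:
        frame = _collapse_probes(frame, probe_map)
    return ExpressionMatrix.from_frame(frame)


def _collapse_probes(frame: pd.DataFrame, probe_map: dict[str, str]) -> pd.DataFrame:
    mapped = frame.loc[[p for p in frame.index if p in probe_map]].copy()
    genes = pd.Series({p: probe_map[p] for p in mapped.index})
    mean_expr = mapped.mean(axis=1)
    keep = mean_expr.groupby(genes).idxmax()
    out = mapped.loc[keep.values]
    out.index = keep.index
    return out


def write_expression(expr: ExpressionMatrix, path) -> None:
    expr.to_frame().to_csv(path, sep="\t", index_label="gene_id")


# ---------------------------------------------------------------------------
# GMT


def read_gmt(path, min_size: int = 1, max_size: int | None = None) -> GeneSetCollection:
    """Read a GMT file, dropping sets outside ``[min_size, max_size]`` after
    member deduplication. An empty file yields an empty collection."""
    sets: dict[str, tuple[str, ...]] = {}
    descriptions: dict[str, str] = {}
    n_dropped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"malformed GMT line {lineno}: expected >=3 tab-separated "
                    f"fields, got {len(fields)}"
                )
            name, desc, *members = fields
            members = tuple(dict.fromkeys(m for m in members if m))
            if name in sets:
                raise ValueError(f"duplicate gene set name: {name!r}")
            size = len(members)
            if size < min_size or (max_size is not None and size > max_size):
                n_dropped += 1
                continue
            sets[name] = members
            descriptions[name] = desc
    if n_dropped:
        logger.info("read_gmt: dropped %d sets outside size bounds", n_dropped)
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, members in collection.sets.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *members]) + "\n")


# ---------------------------------------------------------------------------
# clinical CSV


def read_clinical(
    path,
    time_col: str = "time",
    event_col: str = "event",
    subtype_col: str | None = "subtype",
    cohort_col: str | None = "cohort",
    sample_col: str | None = None,
    time_unit: str = "months",
) -> ClinicalTable:
    """Read a clinical CSV. Rows with missing time or event are excluded and
    counted (mirroring the exclusion of samples with incomplete survival
    information); invalid values in retained rows are hard errors."""
    frame = pd.read_csv(path, index_col=0 if sample_col is None else None)
    if sample_col is not None:
        frame = frame.set_index(sample_col)
    frame.index = frame.index.astype(str)
    for col in (time_col, event_col):
        if col not in frame.columns:
            raise ValueError(f"clinical table lacks required column {col!r}")
    complete = frame[time_col].notna() & frame[event_col].notna()
    n_excluded = int((~complete).sum())
    frame = frame.loc[complete]
    subtype = None
    if subtype_col is not None and subtype_col in frame.columns:
        subtype = frame[subtype_col].fillna(NOLBL).to_numpy(dtype=object)
    cohort = None
    if cohort_col is not None and cohort_col in frame.columns:
        cohort = frame[cohort_col].to_numpy(dtype=object)
    table = ClinicalTable(
        list(frame.index),
        frame[time_col].to_numpy(dtype=float),
        frame[event_col].to_numpy(),
        subtype,
        cohort,
        time_unit,
        n_excluded,
    )
    if n_excluded:
        logger.info("read_clinical: excluded %d incomplete rows", n_excluded)
    return table


def write_clinical(table: ClinicalTable, path) -> None:
    table.to_frame().to_csv(path)


# ---------------------------------------------------------------------------
# model bundles (JSON + base64 arrays)


@dataclass
class ModelBundle:
    """Serializable container for a fitted pipeline stage.

    ``params`` may hold numpy arrays, scalars and strings; arrays round-trip
    bit-exactly for integer dtypes and to full float64 precision otherwise.
    """

    stage: str
    params: dict
    metadata: dict = field(default_factory=dict)


def _encode(value):
    if isinstance(value, np.ndarray):
        return {
            "__ndarray__": base64.b64encode(np.ascontiguousarray(value).tobytes()).decode(),
            "dtype": str(value.dtype),
            "shape": list(value.shape),
        }
    if isinstance(value, (np.integer,)):
        return int(value)
    if isinstance(value, (np.floating,)):
        return float(value)
    if isinstance(value, dict):
        return {k: _encode(v) for k, v in value.items()}
    if isinstance(value, (list, tuple)):
        return [_encode(v) for v in value]
    return value


def _decode(value):
    if isinstance(value, dict):
        if "__ndarray__" in value:
            raw = base64.b64decode(value["__ndarray__"])
            return np.frombuffer(raw, dtype=value["dtype"]).reshape(value["shape"]).copy()
        return {k: _decode(v) for k, v in value.items()}
    if isinstance(value, list):
        return [_decode(v) for v in value]
    return value


def save_bundle(bundle: ModelBundle, path) -> None:
    metadata = dict(bundle.metadata)
    metadata.setdefault(
        "created", datetime.datetime.now(datetime.timezone.utc).isoformat()
    )
    doc = {
        "version": BUNDLE_VERSION,
        "stage": bundle.stage,
        "params": _encode(bundle.params),
        "metadata": _encode(metadata),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def load_bundle(path) -> ModelBundle:
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except json.JSONDecodeError as err:
        raise ValueError(f"corrupt model bundle {path}: {err}") from err
    version = doc.get("version")
    if version != BUNDLE_VERSION:
        raise ValueError(
            f"bundle version mismatch: expected {BUNDLE_VERSION!r}, found {version!r}"
        )
    return ModelBundle(doc["stage"], _decode(doc["params"]), _decode(doc["metadata"]))
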