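"""Data model and delimited-text I/O for Ct tables, count matrices and reports.

The central containers are deliberately thin wrappers around pandas objects:

``CtTable``
    Long-format, replicate-resolved cycle-threshold (Ct) measurements with
    strain / condition / timepoint labels, as exported from a qPCR run.
``CountMatrix``
    A gene x sample matrix of (raw or normalized) transcriptome counts with
    optional per-sample size factors and metadata.
``StabilityScores`` / ``StabilityReport``
    Per-gene stability values and ranks for the four algorithms plus the
    geometric-mean consensus, with provenance, serialisable to JSON + TSV.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ParseError, SchemaError, ValidationError

logger = logging.getLogger(__name__)

#: canonical column names of a long-format Ct table
CT_COLUMNS = (
    "sample",
    "gene",
    "ct",
    "tech_rep",
    "bio_rep",
    "strain",
    "condition",
    "timepoint",
)

#: Ct values outside this open/closed interval are rejected (usual qPCR
#: cycle ceiling; configurable through ``read_ct_table``).
CT_RANGE = (0.0, 45.0)

#: default technical-replicate spread (cycles) above which a well is flagged
DEFAULT_SPREAD_LIMIT = 1.0


def _infer_delimiter(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","


@dataclass
class CtTable:
    """Long-format Ct measurements.

    Parameters
    ----------
    data
        DataFrame with (at least) the columns in :data:`CT_COLUMNS`.
        One row per technical-replicate measurement.
    flags
        Optional QC metadata (e.g. replicate-spread flags) indexed like
        ``data`` after technical aggregation.
    """

    data: pd.DataFrame
    flags: pd.DataFrame | None = None

    @property
    def gene_set(self) -> list[str]:
        """Gene labels in order of first appearance."""
        return list(dict.fromkeys(self.data["gene"]))

    @property
    def samples(self) -> list[str]:
        """Sample labels in order of first appearance."""
        return list(dict.fromkeys(self.data["sample"]))

    def validate(self, ct_range: tuple[float, float] = CT_RANGE) -> "CtTable":
        missing = [c for c in CT_COLUMNS if c not in self.data.columns]
        if missing:
            raise SchemaError(f"Ct table is missing required column(s): {missing}")
        ct = pd.to_numeric(self.data["ct"], errors="coerce")
        bad = self.data.index[ct.isna() | ~np.isfinite(ct)]
        if len(bad):
            raise ValidationError(f"non-numeric or non-finite Ct in rows {list(bad)}")
        lo, hi = ct_range
        out = self.data.index[(ct <= lo) | (ct > hi)]
        if len(out):
            raise ValidationError(
                f"Ct outside ({lo}, {hi}] in rows {list(out)}: "
                f"{ct.loc[out].tolist()}"
            )
        dup = self.data.duplicated(subset=["sample", "gene", "tech_rep"], keep=False)
        if dup.any():
            pairs = self.data.loc[dup, ["sample", "gene", "tech_rep"]]
            raise ValidationError(
                "duplicate (sample, gene, tech_rep) measurements:\n"
                f"{pairs.drop_duplicates().to_string(index=False)}"
            )
        return self

    def sample_meta(self) -> pd.DataFrame:
        """Per-sample strain / condition / timepoint / bio_rep labels."""
        meta = (
            self.data[["sample", "strain", "condition", "timepoint", "bio_rep"]]
            .drop_duplicates(subset="sample")
            .set_index("sample")
        )
        return meta.loc[self.samples]

    def to_wide(self, dropna: str = "warn") -> pd.DataFrame:
        """Pivot to a complete gene x sample Ct matrix.

        Requires one measurement per (sample, gene) — i.e. technical
        replicates already aggregated. Genes with any missing Ct are handled
        per the complete-case policy: excluded with a warning (``"warn"``),
        silently (``"silent"``) or kept as NaN (``"keep"``).
        """
        if self.data.duplicated(subset=["sample", "gene"]).any():
            raise ValidationError(
                "multiple measurements per (sample, gene); aggregate technical "
                "replicates first (aggregate_technical_reps)"
            )
        wide = self.data.pivot(index="gene", columns="sample", values="ct")
        wide = wide.reindex(index=self.gene_set, columns=self.samples)
        if dropna != "keep":
            incomplete = wide.index[wide.isna().any(axis=1)]
            if len(incomplete):
                if dropna == "warn":
                    warnings.warn(
                        f"excluding {len(incomplete)} gene(s) with missing Ct "
                        f"after aggregation: {list(incomplete)}",
                        stacklevel=2,
                    )
                wide = wide.drop(index=incomplete)
        return wide

    def __eq__(self, other: object) -> bool:  # field-for-field round-trip equality
        if not isinstance(other, CtTable):
            return NotImplemented
        a = self.data[list(CT_COLUMNS)].reset_index(drop=True)
        b = other.data[list(CT_COLUMNS)].reset_index(drop=True)
        return a.equals(b)


@dataclass
class CountMatrix:
    """Gene x sample expression counts with optional size factors and metadata."""

    values: pd.DataFrame
    size_factors: pd.Series | None = None
    sample_meta: pd.DataFrame | None = None

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def validate(self) -> "CountMatrix":
        vals = self.values.to_numpy(dtype=float)
        if not np.isfinite(vals).all():
            raise ValidationError("count matrix contains non-finite values")
        if (vals < 0).any():
            genes = self.values.index[(vals < 0).any(axis=1)]
            raise ValidationError(f"negative counts for gene(s): {list(genes)}")
        if self.size_factors is not None:
            sf = np.asarray(self.size_factors, dtype=float)
            if len(sf) != self.values.shape[1]:
                raise ValidationError(
                    f"{len(sf)} size factors for {self.values.shape[1]} samples"
                )
            if not (np.isfinite(sf).all() and (sf > 0).all()):
                raise ValidationError("size factors must be positive and finite")
        return self


class EfficiencyMap(dict):
    """gene_id -> amplification efficiency E (fold increase per cycle).

    E = 2 is perfect doubling; values must lie in (1, 2]. Genes absent from
    the map fall back to the default E = 2.0 with a logged notice.
    """

    default: float = 2.0

    def __init__(self, data: Mapping[str, float] | None = None, default: float = 2.0):
        super().__init__(data or {})
        self.default = default
        for gene, e in self.items():
            if not (1.0 < float(e) <= 2.0):
                raise ValidationError(
                    f"amplification efficiency for {gene!r} must be in (1, 2], got {e}"
                )

    def get_efficiency(self, gene: str) -> float:
        if gene in self:
            return float(self[gene])
        logger.info("no efficiency for gene %r; using default E=%s", gene, self.default)
        return self.default


def read_ct_table(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    delimiter: str | None = None,
    ct_range: tuple[float, float] = CT_RANGE,
) -> CtTable:
    """Read a long-format Ct table from delimited text.

    ``dialect`` maps canonical column names (:data:`CT_COLUMNS`) to the names
    used in the file, e.g. ``{"sample": "Sample Name", "ct": "Cq"}``.
    Row-level errors report 1-based physical line numbers (header = line 1).
    """
    path = Path(path)
    sep = _infer_delimiter(path, delimiter)
    try:
        raw = pd.read_csv(path, sep=sep, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: empty file") from exc
    dialect = dict(dialect or {})
    rename = {dialect.get(c, c): c for c in CT_COLUMNS}
    missing = [dialect.get(c, c) for c in CT_COLUMNS if dialect.get(c, c) not in raw.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {missing}")
    df = raw.rename(columns=rename)[list(CT_COLUMNS)].copy()

    ct = pd.to_numeric(df["ct"], errors="coerce")
    bad = df.index[ct.isna()]
    if len(bad):
        lines = [int(i) + 2 for i in bad]  # +1 header, +1 one-based
        raise ParseError(
            f"{path}: non-numeric Ct value(s) {df.loc[bad, 'ct'].tolist()} "
            f"at line(s) {lines}"
        )
    lo, hi = ct_range
    out = df.index[(ct <= lo) | (ct > hi)]
    if len(out):
        lines = [int(i) + 2 for i in out]
        raise ParseError(
            f"{path}: Ct outside ({lo}, {hi}] at line(s) {lines}: {ct.loc[out].tolist()}"
        )
    df["ct"] = ct.astype(float)
    for col in ("tech_rep", "bio_rep"):
        reps = pd.to_numeric(df[col], errors="coerce")
        if reps.isna().any() or (reps < 1).any() or (reps != reps.round()).any():
            raise ParseError(f"{path}: column {col!r} must hold positive integers")
        df[col] = reps.astype(int)
    table = CtTable(df)
    table.validate(ct_range=ct_range)
    return table


def write_ct_table(table: CtTable, path: str | Path, delimiter: str | None = None) -> None:
    path = Path(path)
    sep = _infer_delimiter(path, delimiter)
    table.data[list(CT_COLUMNS)].to_csv(path, sep=sep, index=False)


def read_count_matrix(
    path: str | Path,
    delimiter: str | None = None,
    sample_meta: str | Path | None = None,
) -> CountMatrix:
    """Read a gene x sample count matrix (first column = gene labels)."""
    path = Path(path)
    sep = _infer_delimiter(path, delimiter)
    try:
        df = pd.read_csv(path, sep=sep, index_col=0)
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: empty file") from exc
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: ragged or malformed rows ({exc})") from exc
    if df.shape[1] == 0:
        raise ParseError(f"{path}: no sample columns found")
    try:
        values = df.astype(float)
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric count values ({exc})") from exc
    if values.isna().any().any():
        raise ParseError(f"{path}: missing values (ragged rows?)")
    meta = None
    if sample_meta is not None:
        meta_path = Path(sample_meta)
        meta = pd.read_csv(meta_path, sep=_infer_delimiter(meta_path, delimiter))
        if "sample" not in meta.columns:
            raise SchemaError(f"{meta_path}: metadata needs a 'sample' column")
        meta = meta.set_index("sample")
    cm = CountMatrix(values, sample_meta=meta)
    cm.validate()
    return cm


def write_count_matrix(cm: CountMatrix, path: str | Path, delimiter: str | None = None) -> None:
    path = Path(path)
    cm.values.to_csv(path, sep=_infer_delimiter(path, delimiter), index_label="gene")


def read_efficiencies(path: str | Path, delimiter: str | None = None) -> EfficiencyMap:
    """Read a two-column (gene, E) table into an :class:`EfficiencyMap`."""
    path = Path(path)
    df = pd.read_csv(path, sep=_infer_delimiter(path, delimiter))
    if df.shape[1] < 2:
        raise SchemaError(f"{path}: expected two columns (gene, E)")
    gene_col, e_col = df.columns[:2]
    return EfficiencyMap(dict(zip(df[gene_col].astype(str), df[e_col].astype(float))))


def aggregate_technical_reps(
    table: CtTable, spread_limit: float = DEFAULT_SPREAD_LIMIT
) -> CtTable:
    """Average technical replicates on the Ct scale.

    Returns one measurement per (sample, gene) whose Ct is the arithmetic
    mean of its technical replicates. Wells whose replicate spread
    (max - min) exceeds ``spread_limit`` cycles are flagged in the returned
    table's ``flags`` frame but never dropped.
    """
    df = table.data
    grouped = df.groupby(["sample", "gene"], sort=False)
    agg = grouped.agg(
        ct=("ct", "mean"),
        spread=("ct", lambda x: float(x.max() - x.min())),
        n_tech=("ct", "size"),
        bio_rep=("bio_rep", "first"),
        strain=("strain", "first"),
        condition=("condition", "first"),
        timepoint=("timepoint", "first"),
    ).reset_index()
    agg["tech_rep"] = 1
    flags = agg[["sample", "gene", "spread", "n_tech"]].copy()
    flags["high_spread"] = flags["spread"] > spread_limit
    if flags["high_spread"].any():
        n = int(flags["high_spread"].sum())
        logger.warning("%d well(s) exceed the replicate spread limit of %.2f cycles",
                       n, spread_limit)
    out = agg[list(CT_COLUMNS)]
    return CtTable(out, flags=flags)


@dataclass
class StabilityScores:
    """Per-gene stability values and ranks for all four methods + composite.

    ``table`` is indexed by gene with the columns
    genorm_m, genorm_rank, normfinder_rho, normfinder_rank, bestkeeper_sd,
    bestkeeper_cv_pct, bestkeeper_r, bestkeeper_rank, deltact_sd,
    deltact_rank, composite_geomean, final_rank.
    """

    table: pd.DataFrame

    COLUMNS = (
        "genorm_m",
        "genorm_rank",
        "normfinder_rho",
        "normfinder_rank",
        "bestkeeper_sd",
        "bestkeeper_cv_pct",
        "bestkeeper_r",
        "bestkeeper_rank",
        "deltact_sd",
        "deltact_rank",
        "composite_geomean",
        "final_rank",
    )

    def ranked(self) -> pd.DataFrame:
        """Rows sorted by the consensus ranking (ties by gene label)."""
        return self.table.sort_values(
            ["final_rank", "composite_geomean"], kind="mergesort"
        ).sort_values("final_rank", kind="mergesort")

    def to_dict(self) -> dict:
        return {
            "genes": list(self.table.index),
            "columns": {c: [None if pd.isna(v) else float(v)
                            for v in self.table[c]]
                        for c in self.COLUMNS},
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "StabilityScores":
        df = pd.DataFrame(
            {c: [np.nan if v is None else v for v in d["columns"][c]]
             for c in cls.COLUMNS},
            index=pd.Index(d["genes"], name="gene"),
        )
        return cls(df)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, StabilityScores):
            return NotImplemented
        return self.to_dict() == other.to_dict()


@dataclass
class StabilityReport:
    """Full stability analysis result: all-sample scores, per-subset scores,
    and provenance (config echo, seed, input digests)."""

    scores: StabilityScores
    subset_scores: dict[str, StabilityScores] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)


def file_digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_report(
    report: StabilityReport,
    json_path: str | Path,
    tsv_path: str | Path | None = None,
) -> None:
    """Serialise a report as a JSON document plus a flat ranked TSV table.

    JSON floats use Python's shortest round-trip repr, so re-reading the
    document reproduces every score bit-identically.
    """
    doc = {
        "provenance": report.provenance,
        "scores": report.scores.to_dict(),
        "subsets": {k: v.to_dict() for k, v in sorted(report.subset_scores.items())},
    }
    Path(json_path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")
    if tsv_path is not None:
        report.scores.ranked().to_csv(tsv_path, sep="\t", index_label="gene")


def read_report(json_path: str | Path) -> StabilityReport:
    doc = json.loads(Path(json_path).read_text())
    return StabilityReport(
        scores=StabilityScores.from_dict(doc["scores"]),
        subset_scores={k: StabilityScores.from_dict(v)
                       for k, v in doc.get("subsets", {}).items()},
        provenance=doc.get("provenance", {}),
    )
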