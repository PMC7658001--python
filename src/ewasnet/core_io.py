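"""Shared data model and tabular I/O for the methylation analysis pipeline.

The pipeline's universal currency is the *beta value*: the methylation
fraction of a CpG probe, in [0, 1], stored as a probes x samples matrix.
Everything else — sample phenotypes, probe annotation, per-probe association
results, cell-type reference profiles — is tabular and travels as TSV.

Canonical on-disk dialect: tab-separated, "." decimal separator, "NA" as the
missing-value token.  Readers validate invariants and fail loudly with the
location of the offending cell; writers are exact inverses of the readers on
the canonical dialect.  Probe and sample order is preserved through I/O —
nothing is ever silently sorted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "Dialect",
    "BetaMatrix",
    "ProbeManifest",
    "SampleTable",
    "EwasTable",
    "CellReference",
    "read_beta_matrix",
    "write_beta_matrix",
    "read_sample_table",
    "write_sample_table",
    "read_probe_manifest",
    "write_probe_manifest",
    "read_ewas_table",
    "write_ewas_table",
    "write_graph",
]

#: Beta values may stray outside [0, 1] by at most this much (float round-off).
BETA_TOLERANCE = 1e-9

#: Canonical fields of a sample table and their dtypes ("num", "cat", "bin").
SAMPLE_FIELDS: dict[str, str] = {
    "sample_id": "cat",
    "cohort_id": "cat",
    "diagnosis": "bin",
    "units_per_week": "num",
    "age": "num",
    "sex": "cat",
    "ancestry": "cat",
    "smoking_score": "num",
    "pack_years": "num",
    "drinks_per_day": "num",
    "years_drinking": "num",
    "cortisol": "num",
    "hippocampus_left": "num",
    "hippocampus_right": "num",
    "tissue": "cat",
    "cell_reference_id": "cat",
}

#: Numeric sample fields that must be non-negative when present.
NONNEGATIVE_FIELDS = (
    "age",
    "pack_years",
    "drinks_per_day",
    "years_drinking",
    "units_per_week",
    "hippocampus_left",
    "hippocampus_right",
)


@dataclass(frozen=True)
class Dialect:
    """On-disk conventions for delimited text artifacts."""

    sep: str = "\t"
    na_token: str = "NA"
    float_format: str = "%.10g"


CANONICAL_DIALECT = Dialect()


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------


@dataclass
class BetaMatrix:
    """Probes x samples matrix of methylation fractions in [0, 1].

    ``data`` is a float DataFrame indexed by probe ID with sample IDs as
    columns; NaN marks missing entries.  Construction validates uniqueness
    of both axes and the value range (tolerance :data:`BETA_TOLERANCE`).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        idx = self.data.index
        cols = self.data.columns
        if idx.has_duplicates:
            dup = idx[idx.duplicated()][0]
            raise ValueError(f"duplicate probe ID: {dup!r}")
        if cols.has_duplicates:
            dup = cols[cols.duplicated()][0]
            raise ValueError(f"duplicate sample ID: {dup!r}")
        vals = self.data.to_numpy(dtype=float)
        bad = (vals < -BETA_TOLERANCE) | (vals > 1.0 + BETA_TOLERANCE)
        bad &= ~np.isnan(vals)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"beta value out of [0,1]: {vals[i, j]!r} at probe "
                f"{idx[i]!r}, sample {cols[j]!r}"
            )

    @property
    def probe_ids(self) -> pd.Index:
        return self.data.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.columns

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_probes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def subset_probes(self, probe_ids: Sequence[str]) -> "BetaMatrix":
        missing = [p for p in probe_ids if p not in self.data.index]
        if missing:
            raise KeyError(f"probes absent from matrix: {missing[:5]}")
        return BetaMatrix(self.data.loc[list(probe_ids)])

    def subset_samples(self, sample_ids: Sequence[str]) -> "BetaMatrix":
        missing = [s for s in sample_ids if s not in self.data.columns]
        if missing:
            raise KeyError(f"samples absent from matrix: {missing[:5]}")
        return BetaMatrix(self.data[list(sample_ids)])


@dataclass
class ProbeManifest:
    """Per-probe annotation: gene symbols, Infinium design type, QC flags.

    ``design_type`` is "I" or "II"; ``gene_symbols`` may hold several
    semicolon-joined symbols (e.g. ``"GAS5a; SNORD47"``).
    """

    data: pd.DataFrame

    REQUIRED = ("gene_symbols", "design_type", "cross_reactive", "qc_fail")

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][0]
            raise ValueError(f"duplicate probe ID in manifest: {dup!r}")
        for col in self.REQUIRED:
            if col not in self.data.columns:
                raise ValueError(f"manifest missing required column {col!r}")
        bad = ~self.data["design_type"].isin(["I", "II"])
        if bad.any():
            probe = self.data.index[bad][0]
            raise ValueError(
                f"design_type must be 'I' or 'II'; probe {probe!r} has "
                f"{self.data.loc[probe, 'design_type']!r}"
            )

    @property
    def probe_ids(self) -> pd.Index:
        return self.data.index

    def design_types(self, probe_ids: Sequence[str]) -> pd.Series:
        return self.data["design_type"].reindex(probe_ids)


@dataclass
class SampleTable:
    """Per-sample phenotypes, covariates and outcomes.

    Canonical fields are listed in :data:`SAMPLE_FIELDS`; ``roi_bold_*``
    columns carry per-ROI BOLD eigenvariates; any other columns are kept as
    opaque annotations.  The table is indexed by ``sample_id``.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][0]
            raise ValueError(f"duplicate sample ID: {dup!r}")
        if "diagnosis" in self.data.columns:
            d = self.data["diagnosis"].dropna()
            bad = ~d.isin([0, 1, 0.0, 1.0])
            if bad.any():
                sid = d.index[bad][0]
                raise ValueError(
                    f"diagnosis must be 0/1 or missing; sample {sid!r} has "
                    f"{d[sid]!r}"
                )
        for colname in NONNEGATIVE_FIELDS:
            if colname in self.data.columns:
                col = pd.to_numeric(self.data[colname], errors="coerce")
                if (col.dropna() < 0).any():
                    sid = col.index[(col < 0).fillna(False)][0]
                    raise ValueError(
                        f"{colname} must be non-negative; sample {sid!r} has "
                        f"{col[sid]!r}"
                    )

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.index

    def roi_columns(self) -> list[str]:
        return [c for c in self.data.columns if c.startswith("roi_bold")]

    def subset(self, sample_ids: Sequence[str]) -> "SampleTable":
        return SampleTable(self.data.loc[list(sample_ids)])


@dataclass
class EwasTable:
    """Per-probe association results: effect b, SE, t, p, q, n, direction.

    A probe that could not be fit carries NaN statistics and a non-empty
    ``reason`` code instead.
    """

    data: pd.DataFrame

    COLUMNS = ("b", "se", "t", "p", "q", "n", "direction", "reason")

    def __post_init__(self) -> None:
        for col in self.COLUMNS:
            if col not in self.data.columns:
                raise ValueError(f"EWAS table missing column {col!r}")
        p = self.data["p"].dropna()
        if ((p <= 0) | (p > 1)).any():
            raise ValueError("p values must lie in (0, 1]")
        finite = self.data["b"].notna() & self.data["se"].notna()
        if (self.data.loc[finite, "se"] <= 0).any():
            raise ValueError("SE must be positive where the fit succeeded")

    @property
    def probe_ids(self) -> pd.Index:
        return self.data.index

    def significant(self, q_threshold: float) -> pd.Index:
        q = self.data["q"]
        return self.data.index[(q <= q_threshold).fillna(False)]


@dataclass
class CellReference:
    """Pure cell-type methylation profiles (cell types x probes, in [0, 1])."""

    profiles: pd.DataFrame

    def __post_init__(self) -> None:
        vals = self.profiles.to_numpy(dtype=float)
        ok = np.isnan(vals) | ((vals >= -BETA_TOLERANCE) & (vals <= 1 + BETA_TOLERANCE))
        if not ok.all():
            raise ValueError("cell reference profiles must lie in [0, 1]")
        if self.profiles.index.has_duplicates:
            raise ValueError("duplicate cell type IDs in reference")

    @property
    def cell_type_ids(self) -> pd.Index:
        return self.profiles.index

    @property
    def probe_ids(self) -> pd.Index:
        return self.profiles.columns


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def _read_table(path, dialect: Dialect) -> pd.DataFrame:
    return pd.read_csv(
        path,
        sep=dialect.sep,
        index_col=0,
        na_values=[dialect.na_token],
        keep_default_na=False,
        dtype=str,
    )


def read_beta_matrix(path, dialect: Dialect = CANONICAL_DIALECT) -> BetaMatrix:
    """Read a probes x samples beta matrix from delimited text.

    The first column holds probe IDs; every other column is one sample.
    Non-numeric cells and values outside [0, 1] are hard errors naming the
    offending probe and sample.
    """
    raw = _read_table(path, dialect)
    numeric = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=float)
    for col in raw.columns:
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = converted.isna() & raw[col].notna()
        if bad.any():
            probe = raw.index[bad][0]
            raise ValueError(
                f"non-numeric beta value {raw.loc[probe, col]!r} at probe "
                f"{probe!r}, sample {col!r}"
            )
        numeric[col] = converted
    return BetaMatrix(numeric)


def write_beta_matrix(matrix: BetaMatrix, path, dialect: Dialect = CANONICAL_DIALECT) -> None:
    matrix.data.to_csv(
        path,
        sep=dialect.sep,
        na_rep=dialect.na_token,
        float_format=dialect.float_format,
        index_label="probe_id",
    )


def read_sample_table(
    path,
    schema: Mapping[str, str] | None = None,
    dialect: Dialect = CANONICAL_DIALECT,
) -> SampleTable:
    """Read a sample sheet, mapping file columns onto canonical fields.

    ``schema`` maps file column names to canonical field names; matching is
    case-insensitive.  Columns not covered by the schema and not already
    canonical are preserved untouched as opaque annotations.  A missing
    ``sample_id`` column is a hard error.
    """
    raw = pd.read_csv(
        path, sep=dialect.sep, na_values=[dialect.na_token], keep_default_na=False
    )
    rename: dict[str, str] = {}
    schema_lower = {k.lower(): v for k, v in (schema or {}).items()}
    for col in raw.columns:
        target = schema_lower.get(col.lower())
        if target is None and col.lower() in SAMPLE_FIELDS:
            target = col.lower()
        if target is not None:
            rename[col] = target
    table = raw.rename(columns=rename)
    if "sample_id" not in table.columns:
        raise ValueError("sample table is missing the mandatory sample_id column")
    for colname, kind in SAMPLE_FIELDS.items():
        if colname in table.columns and kind in ("num", "bin") and colname != "sample_id":
            converted = pd.to_numeric(table[colname], errors="coerce")
            bad = converted.isna() & table[colname].notna()
            if bad.any():
                row = bad.idxmax()
                raise ValueError(
                    f"unparseable numeric value {table.loc[row, colname]!r} in "
                    f"column {colname!r}, row {row}"
                )
            table[colname] = converted.astype(float)
    for col in table.columns:
        if col.startswith("roi_bold"):
            table[col] = pd.to_numeric(table[col], errors="coerce")
    table = table.set_index("sample_id")
    return SampleTable(table)


def write_sample_table(
    table: SampleTable, path, dialect: Dialect = CANONICAL_DIALECT
) -> None:
    table.data.to_csv(
        path,
        sep=dialect.sep,
        na_rep=dialect.na_token,
        float_format=dialect.float_format,
        index_label="sample_id",
    )


def read_probe_manifest(path, dialect: Dialect = CANONICAL_DIALECT) -> ProbeManifest:
    raw = pd.read_csv(
        path,
        sep=dialect.sep,
        index_col=0,
        na_values=[dialect.na_token],
        keep_default_na=False,
    )
    for col in ("cross_reactive", "qc_fail"):
        if col in raw.columns:
            raw[col] = raw[col].astype(str).str.lower().isin(["true", "1", "yes"])
    if "gene_symbols" in raw.columns:
        raw["gene_symbols"] = raw["gene_symbols"].fillna("")
    return ProbeManifest(raw)


def write_probe_manifest(
    manifest: ProbeManifest, path, dialect: Dialect = CANONICAL_DIALECT
) -> None:
    manifest.data.to_csv(
        path, sep=dialect.sep, na_rep=dialect.na_token, index_label="probe_id"
    )


def read_ewas_table(path, dialect: Dialect = CANONICAL_DIALECT) -> EwasTable:
    raw = pd.read_csv(
        path,
        sep=dialect.sep,
        index_col=0,
        na_values=[dialect.na_token],
        keep_default_na=False,
    )
    for col in ("b", "se", "t", "p", "q", "n", "direction"):
        if col in raw.columns:
            raw[col] = pd.to_numeric(raw[col], errors="coerce")
    if "reason" in raw.columns:
        raw["reason"] = raw["reason"].fillna("").astype(str)
    return EwasTable(raw)


def write_ewas_table(table: EwasTable, path, dialect: Dialect = CANONICAL_DIALECT) -> None:
    out = table.data.copy()
    out["reason"] = out["reason"].replace("", np.nan)
    out.to_csv(
        path,
        sep=dialect.sep,
        na_rep=dialect.na_token,
        float_format=dialect.float_format,
        index_label="probe_id",
    )


def write_graph(graph: nx.DiGraph, path, format: str = "edge_list") -> None:
    """Write a mediation graph as a TSV edge list or GraphML.

    ``edge_list`` emits one header row plus one row per edge with every edge
    attribute as an extra column (an empty graph yields the header only).
    ``graphml`` delegates to the standard GraphML serialization, preserving
    node and edge attributes.
    """
    if format == "edge_list":
        attr_names = sorted({k for _, _, d in graph.edges(data=True) for k in d})
        rows = []
        for u, v, d in graph.edges(data=True):
            rows.append([u, v] + [d.get(a, "") for a in attr_names])
        frame = pd.DataFrame(rows, columns=["source", "target"] + attr_names)
        frame.to_csv(path, sep="\t", index=False)
    elif format == "graphml":
        nx.write_graphml(graph, path)
    else:
        raise ValueError(f"unknown graph format {format!r}; use edge_list or graphml")
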