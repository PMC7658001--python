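"""Per-probe covariate-adjusted association testing with FDR control.

Each CpG's beta value is regressed by ordinary least squares on a predictor
(diagnosis, log-transformed drinks per week, or a cumulative drink-years
dose metric) plus covariates — typically age, sex, ancestry and cell-type
proportions; optionally smoking score (sensitivity analysis) or M-value
principal components.  The per-probe output is the predictor coefficient b
(beta-scale difference per unit predictor), its classical SE, t = b/SE, the
two-sided p from the t distribution, and the FDR q value from
Benjamini–Hochberg step-up across all tested probes.

Missing data are handled complete-case per probe; a zero-variance response
yields a missing row with reason code ``zero_variance`` rather than p = 1,
distinguishing "no signal" from "no information".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import logit
from statsmodels.stats.multitest import multipletests

from .core_io import BetaMatrix, EwasTable, SampleTable

__all__ = [
    "ModelSpec",
    "dose_metric",
    "mvalue_pcs",
    "fit_probe_model",
    "run_ewas",
    "fdr_adjust",
    "sensitivity_with_smoking",
]

#: sentinel covariate name expanded to the supplied cell-proportion columns
CELLPROPS = "cellprops"


@dataclass(frozen=True)
class ModelSpec:
    """Model definition for a per-probe regression scan.

    ``predictor`` is one of ``diagnosis``, ``log_units_per_week``,
    ``dose_metric``, or any numeric sample-table column.  ``covariates`` are
    sample-table columns, ``cellprops`` (expanded to the cell-proportion
    matrix passed to the fit), or PC score columns previously merged into
    the table.  ``log_base`` controls the consumption transform: ``log1p``
    (default, defined at zero for abstainers) or ``log``.
    """

    predictor: str = "diagnosis"
    covariates: tuple[str, ...] = ("age", "sex", "ancestry", CELLPROPS)
    missing_policy: str = "complete_case"
    log_base: str = "log1p"

    def __post_init__(self) -> None:
        if self.predictor in self.covariates:
            raise ValueError("predictor must not be duplicated in covariates")
        if self.missing_policy != "complete_case":
            raise ValueError("only complete_case missing policy is implemented")
        if self.log_base not in ("log1p", "log"):
            raise ValueError("log_base must be 'log1p' or 'log'")


def dose_metric(drinks_per_day, years_drinking):
    """Lifetime exposure in drink-years: average drinks/day x years drinking.

    Works elementwise; missing in either input propagates to missing.
    Negative inputs are rejected.
    """
    d = np.asarray(drinks_per_day, dtype=float)
    y = np.asarray(years_drinking, dtype=float)
    if (d[~np.isnan(d)] < 0).any() or (y[~np.isnan(y)] < 0).any():
        raise ValueError("drinks_per_day and years_drinking must be non-negative")
    out = d * y
    if out.ndim == 0:
        return float(out)
    return out


def mvalue_pcs(matrix: BetaMatrix, n_components: int = 20) -> pd.DataFrame:
    """Principal-component scores of the M-value (logit beta) matrix.

    Betas are clipped to [0.001, 0.999] before the logit; probes are
    centered, and PC scores (samples x components) are returned as columns
    ``pc1 .. pcK`` for use as covariates.
    """
    m = logit(np.clip(matrix.values, 1e-3, 1 - 1e-3))  # probes x samples
    m = np.where(np.isnan(m), np.nanmean(m, axis=1, keepdims=True), m)
    centered = (m - m.mean(axis=1, keepdims=True)).T  # samples x probes
    n_components = min(n_components, min(centered.shape))
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    scores = centered @ vt[:n_components].T
    return pd.DataFrame(
        scores,
        index=matrix.sample_ids,
        columns=[f"pc{k + 1}" for k in range(n_components)],
    )


def _derive_predictor(samples: pd.DataFrame, spec: ModelSpec) -> pd.Series:
    if spec.predictor == "log_units_per_week":
        upw = pd.to_numeric(samples["units_per_week"], errors="coerce")
        if spec.log_base == "log1p":
            return np.log1p(upw)
        with np.errstate(divide="ignore"):
            vals = np.log(upw.to_numpy(dtype=float))
        return pd.Series(np.where(np.isfinite(vals), vals, np.nan), index=samples.index)
    if spec.predictor == "dose_metric":
        return pd.Series(
            dose_metric(samples["drinks_per_day"], samples["years_drinking"]),
            index=samples.index,
        )
    if spec.predictor not in samples.columns:
        raise KeyError(f"predictor column {spec.predictor!r} not in sample table")
    return pd.to_numeric(samples[spec.predictor], errors="coerce")


def _encode_column(samples: pd.DataFrame, name: str) -> pd.DataFrame:
    if name not in samples.columns:
        raise KeyError(f"covariate column {name!r} not in sample table")
    col = samples[name]
    if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
        levels = sorted(col.dropna().unique())
        dummies = pd.DataFrame(index=samples.index)
        for lev in levels[1:]:  # first (lexicographic) level is the reference
            dummies[f"{name}[{lev}]"] = (col == lev).astype(float)
        dummies[col.isna()] = np.nan
        return dummies
    return pd.DataFrame({name: pd.to_numeric(col, errors="coerce")})


def build_design(
    samples: SampleTable,
    spec: ModelSpec,
    cell_proportions: pd.DataFrame | None = None,
    extra_covariates: tuple[str, ...] = (),
) -> tuple[pd.Series, pd.DataFrame]:
    """Assemble (predictor, covariate design) aligned to the sample table.

    Categorical covariates are dummy-encoded against the lexicographically
    first level; ``cellprops`` expands to all but the last cell-proportion
    column (the simplex constraint makes the full set collinear with the
    intercept).
    """
    frame = samples.data
    predictor = _derive_predictor(frame, spec)
    blocks: list[pd.DataFrame] = []
    for name in tuple(spec.covariates) + tuple(extra_covariates):
        if name == CELLPROPS:
            if cell_proportions is None:
                raise ValueError("spec requests cellprops but none were supplied")
            props = cell_proportions.reindex(frame.index)
            blocks.append(props.iloc[:, :-1].astype(float))
        else:
            blocks.append(_encode_column(frame, name))
    covs = pd.concat(blocks, axis=1) if blocks else pd.DataFrame(index=frame.index)
    return predictor, covs


def _check_rank(x: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        # identify a dependent column by incremental rank growth
        dependent = []
        for j in range(1, x.shape[1]):
            if np.linalg.matrix_rank(x[:, : j + 1]) == np.linalg.matrix_rank(x[:, :j]):
                dependent.append(names[j])
        raise np.linalg.LinAlgError(
            f"design matrix is rank deficient; dependent columns: {dependent}"
        )


def _fit_single(
    y: np.ndarray, predictor: np.ndarray, covs: np.ndarray, names: list[str]
) -> dict:
    """OLS of y on [intercept, predictor, covariates] over complete cases."""
    mask = ~np.isnan(y) & ~np.isnan(predictor)
    if covs.size:
        mask &= ~np.isnan(covs).any(axis=1)
    n = int(mask.sum())
    n_cols = 2 + (covs.shape[1] if covs.size else 0)
    out = {"b": np.nan, "se": np.nan, "t": np.nan, "p": np.nan, "n": n, "reason": ""}
    if n < n_cols + 2:
        out["reason"] = "insufficient_complete_cases"
        return out
    yy = y[mask]
    if np.ptp(yy) == 0.0:
        out["reason"] = "zero_variance"
        return out
    x = np.column_stack(
        [np.ones(n), predictor[mask]] + ([covs[mask]] if covs.size else [])
    )
    _check_rank(x, ["intercept"] + names)
    fit = sm.OLS(yy, x).fit()
    out.update(
        b=float(fit.params[1]),
        se=float(fit.bse[1]),
        t=float(fit.tvalues[1]),
        p=float(fit.pvalues[1]),
    )
    return out


def fit_probe_model(
    beta_row: pd.Series,
    samples: SampleTable,
    spec: ModelSpec,
    cell_proportions: pd.DataFrame | None = None,
) -> pd.Series:
    """Fit one probe's regression; see module docstring for the model."""
    predictor, covs = build_design(samples, spec, cell_proportions)
    y = pd.to_numeric(beta_row, errors="coerce").reindex(samples.sample_ids)
    res = _fit_single(
        y.to_numpy(dtype=float),
        predictor.to_numpy(dtype=float),
        covs.to_numpy(dtype=float),
        [spec.predictor] + list(covs.columns),
    )
    res["direction"] = float(np.sign(res["b"])) if np.isfinite(res["b"]) else np.nan
    return pd.Series(res)


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up q values, missing-aware.

    Missing p values are excluded from the adjustment and re-inserted as
    missing; q_(i) = min_{j >= i} m p_(j) / j, capped at 1, mapped back to
    the input order.
    """
    p = np.asarray(p_values, dtype=float)
    q = np.full_like(p, np.nan)
    mask = ~np.isnan(p)
    if ((p[mask] <= 0) | (p[mask] > 1)).any():
        raise ValueError("p values must lie in (0, 1]")
    if mask.any():
        q[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return q


def run_ewas(
    matrix: BetaMatrix,
    samples: SampleTable,
    spec: ModelSpec,
    cell_proportions: pd.DataFrame | None = None,
    extra_covariates: tuple[str, ...] = (),
) -> EwasTable:
    """Scan every probe with the given model and append BH-FDR q values.

    Samples are aligned by ID (matrix column order is authoritative); zero
    overlap is an error.  The output has one row per matrix probe, in probe
    order, and is deterministic given the inputs.
    """
    common = [s for s in matrix.sample_ids if s in samples.sample_ids]
    if not common:
        raise ValueError("no overlapping samples between matrix and sample table")
    sub_samples = samples.subset(common)
    sub_matrix = matrix.subset_samples(common)

    predictor, covs = build_design(sub_samples, spec, cell_proportions, extra_covariates)
    pred_arr = predictor.to_numpy(dtype=float)
    cov_arr = covs.to_numpy(dtype=float)
    names = [spec.predictor] + list(covs.columns)
    values = sub_matrix.values

    rows = []
    for j in range(sub_matrix.n_probes):
        rows.append(_fit_single(values[j], pred_arr, cov_arr, names))
    table = pd.DataFrame(rows, index=sub_matrix.probe_ids)
    table["q"] = fdr_adjust(table["p"].to_numpy())
    table["direction"] = np.sign(table["b"])
    table = table[["b", "se", "t", "p", "q", "n", "direction", "reason"]]
    return EwasTable(table)


def sensitivity_with_smoking(
    matrix: BetaMatrix,
    samples: SampleTable,
    spec: ModelSpec,
    probe_set,
    cell_proportions: pd.DataFrame | None = None,
) -> EwasTable:
    """Re-fit a probe subset with smoking score added to the covariates.

    An empty probe set returns an empty (but well-formed) table.
    """
    probe_set = list(probe_set)
    if not probe_set:
        empty = pd.DataFrame(
            {c: pd.Series(dtype=float) for c in ("b", "se", "t", "p", "q", "n", "direction")}
        )
        empty["reason"] = pd.Series(dtype=str)
        empty.index.name = "probe_id"
        return EwasTable(empty)
    sub = matrix.subset_probes(probe_set)
    return run_ewas(
        sub, samples, spec, cell_proportions, extra_covariates=("smoking_score",)
    )
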