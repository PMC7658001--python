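"""Endophenotype models: methylation summaries vs cortisol, brain volume,
and ROI BOLD responses.

Two statistical routes, matching how such traits are typically analysed:

* **OLS route** (cortisol, hippocampal volume): the trait is regressed on a
  methylation summary (module eigengene or single probe) plus covariates;
  reported are the summary coefficient b +/- SE, the overall model F with
  its degrees of freedom, and the coefficient's two-sided p.
* **Rank route** (BOLD eigenvariates, whose regression residuals are
  typically non-normal): the summary is first residualized on cell-type
  proportions, then associated with each ROI score by partial Kendall
  correlation (tau-b throughout) adjusting for age, sex and ancestry, with
  p from the normal approximation.

Left and right structures are always analysed separately, never averaged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .core_io import BetaMatrix, SampleTable

__all__ = [
    "EndophenotypeResult",
    "residualize",
    "trait_regression",
    "kendall_partial",
    "bold_association",
]


@dataclass
class EndophenotypeResult:
    """One summary-trait association."""

    summary: str
    trait: str
    kind: str  # "ols_beta" or "kendall_tau"
    estimate: float
    se: float | None
    statistic: float  # model F (OLS) or z (Kendall)
    df: tuple[int, int] | int | None
    p: float
    n: int


def _encode_covariates(covariates: pd.DataFrame) -> pd.DataFrame:
    """Dummy-encode object columns against the lexicographically first level."""
    blocks = []
    for col in covariates.columns:
        series = covariates[col]
        if series.dtype == object or isinstance(series.dtype, pd.CategoricalDtype):
            levels = sorted(series.dropna().unique())
            for lev in levels[1:]:
                enc = (series == lev).astype(float)
                enc[series.isna()] = np.nan
                blocks.append(enc.rename(f"{col}[{lev}]"))
        else:
            blocks.append(pd.to_numeric(series, errors="coerce").rename(col))
    return pd.concat(blocks, axis=1) if blocks else pd.DataFrame(index=covariates.index)


def residualize(values, covariates: pd.DataFrame):
    """OLS residuals of each column of ``values`` on [intercept, covariates].

    ``values`` may be a Series or DataFrame aligned to the covariate index.
    Residuals are orthogonal to the covariate columns; a rank-deficient
    design is an error.
    """
    as_series = isinstance(values, pd.Series)
    frame = values.to_frame() if as_series else values
    covs = _encode_covariates(covariates).loc[frame.index]
    x = np.column_stack([np.ones(len(frame)), covs.to_numpy(dtype=float)])
    if np.isnan(x).any():
        raise ValueError("covariates contain missing values; drop incomplete rows first")
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise np.linalg.LinAlgError("covariate design is rank deficient")
    y = frame.to_numpy(dtype=float)
    coefs, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ coefs
    out = pd.DataFrame(resid, index=frame.index, columns=frame.columns)
    return out.iloc[:, 0] if as_series else out


def trait_regression(
    summary_scores: pd.Series,
    trait: pd.Series,
    covariates: pd.DataFrame | None = None,
    summary_name: str | None = None,
    trait_name: str | None = None,
) -> EndophenotypeResult:
    """OLS of a trait on [intercept, methylation summary, covariates].

    Complete cases only.  ``statistic`` is the overall model F with
    ``df = (k, n - k - 1)``; ``p`` is the two-sided p of the summary
    coefficient.
    """
    frames = [summary_scores.rename("summary"), trait.rename("trait")]
    covs = None
    if covariates is not None and covariates.shape[1] > 0:
        covs = _encode_covariates(covariates)
        frames.append(covs)
    data = pd.concat(frames, axis=1, join="inner").dropna()
    n = len(data)
    k = 1 + (covs.shape[1] if covs is not None else 0)
    if n < k + 3:
        raise ValueError("too few complete cases for the trait regression")
    x = np.column_stack([np.ones(n), data.iloc[:, 0].to_numpy(dtype=float)]
                        + ([data.iloc[:, 2:].to_numpy(dtype=float)] if covs is not None else []))
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise np.linalg.LinAlgError("trait regression design is rank deficient")
    fit = sm.OLS(data["trait"].to_numpy(dtype=float), x).fit()
    return EndophenotypeResult(
        summary=summary_name or str(summary_scores.name or "summary"),
        trait=trait_name or str(trait.name or "trait"),
        kind="ols_beta",
        estimate=float(fit.params[1]),
        se=float(fit.bse[1]),
        statistic=float(fit.fvalue),
        df=(int(fit.df_model), int(fit.df_resid)),
        p=float(fit.pvalues[1]),
        n=n,
    )


def _tau_b(x: np.ndarray, y: np.ndarray) -> float:
    return float(stats.kendalltau(x, y, variant="b").statistic)


def _tie_fraction(v: np.ndarray) -> float:
    n = len(v)
    _, counts = np.unique(v, return_counts=True)
    tied = (counts * (counts - 1) / 2).sum()
    return tied / (n * (n - 1) / 2)


def kendall_partial(
    x, y, adjust_set: list | tuple = (), return_z: bool = False
):
    """Partial Kendall correlation (tau-b) of x and y given the adjust set.

    For one adjuster z:
    tau_xy.z = (tau_xy - tau_xz tau_yz) / sqrt((1 - tau_xz^2)(1 - tau_yz^2));
    multiple adjusters are partialled out recursively in the given order
    (each adjuster updates all remaining pairwise taus before the next is
    applied).  The p value uses the normal approximation with the plain
    tau variance 2(2n+5) / (9n(n-1)).

    A unit-magnitude tau between an adjuster and x or y makes the
    denominator vanish and is an error; inputs where more than half of all
    pairs are tied trigger a warning.
    """
    arrays = [np.asarray(v, dtype=float) for v in (x, y, *adjust_set)]
    n = len(arrays[0])
    if any(len(a) != n for a in arrays):
        raise ValueError("all inputs must have equal length")
    if n < 4:
        raise ValueError("need at least 4 observations")
    for a in arrays:
        if _tie_fraction(a) > 0.5:
            warnings.warn("more than half of all pairs are tied; tau-b may be unstable")
    m = len(arrays)
    tau = np.eye(m)
    for i in range(m):
        for j in range(i + 1, m):
            tau[i, j] = tau[j, i] = _tau_b(arrays[i], arrays[j])
    # partial out adjusters 2..m-1 in order; after processing adjuster a,
    # tau[i, j] holds tau_ij . (adjusters up to a)
    active = list(range(m))
    for a in range(2, m):
        active.remove(a)
        new = tau.copy()
        for ii in active:
            for jj in active:
                if ii >= jj:
                    continue
                if max(abs(tau[ii, a]), abs(tau[jj, a])) >= 1 - 1e-9:
                    raise ZeroDivisionError(
                        "an adjuster is perfectly concordant with x or y"
                    )
                denom = (1 - tau[ii, a] ** 2) * (1 - tau[jj, a] ** 2)
                new[ii, jj] = new[jj, ii] = (
                    tau[ii, jj] - tau[ii, a] * tau[jj, a]
                ) / np.sqrt(denom)
        tau = new
    t_partial = float(np.clip(tau[0, 1], -1.0, 1.0))
    var = 2.0 * (2 * n + 5) / (9.0 * n * (n - 1))
    z = t_partial / np.sqrt(var)
    p = float(2 * stats.norm.sf(abs(z)))
    if return_z:
        return t_partial, p, float(z)
    return t_partial, p


def bold_association(
    summary: pd.Series,
    samples: SampleTable,
    cell_proportions: pd.DataFrame,
    covariates: tuple[str, ...] = ("age", "sex", "ancestry"),
    rois: list[str] | None = None,
) -> pd.DataFrame:
    """Partial Kendall association of a methylation summary with each ROI.

    The summary is residualized on cell-type proportions, then correlated
    with each ROI BOLD eigenvariate adjusting for the named covariates
    (categoricals are rank-encoded by lexicographic level order, a
    monotone-invariant choice for Kendall statistics).  Missing ROI columns
    are skipped with a warning; one result row per ROI.
    """
    frame = samples.data
    roi_cols = rois if rois is not None else samples.roi_columns()
    props = cell_proportions.reindex(frame.index)
    keep = summary.reindex(frame.index).notna() & props.notna().all(axis=1)
    for cov in covariates:
        keep &= frame[cov].notna()
    idx = frame.index[keep]
    resid = residualize(
        summary.reindex(idx), props.loc[idx].iloc[:, :-1]
    )
    adjusters = []
    for cov in covariates:
        col = frame.loc[idx, cov]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            levels = {lev: r for r, lev in enumerate(sorted(col.dropna().unique()))}
            adjusters.append(col.map(levels).to_numpy(dtype=float))
        else:
            adjusters.append(pd.to_numeric(col, errors="coerce").to_numpy(dtype=float))

    records = []
    for roi in roi_cols:
        if roi not in frame.columns:
            warnings.warn(f"ROI column {roi!r} missing; skipped")
            continue
        roi_vals = pd.to_numeric(frame.loc[idx, roi], errors="coerce")
        ok = roi_vals.notna().to_numpy()
        tau, p = kendall_partial(
            resid.to_numpy()[ok],
            roi_vals.to_numpy(dtype=float)[ok],
            [a[ok] for a in adjusters],
        )
        records.append({"roi": roi, "tau": tau, "p": p, "n": int(ok.sum())})
    return pd.DataFrame.from_records(records).set_index("roi") if records else pd.DataFrame(
        columns=["tau", "p", "n"]
    )
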