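"""Probe QC, between-design scale correction, quantile normalization,
beta computation, and reference-based cell-composition estimation.

Array methylation intensities come from two Infinium chemistries (type I and
type II probes) with systematically different scales.  Normalization here
follows the dasen recipe: rescale type II intensities so their per-sample
median matches the type I median, then quantile-normalize the methylated and
unmethylated matrices separately within each design-type stratum, so that
every sample shares the stratum-wise reference distribution.  Beta values
are then M / (M + U + offset) with the conventional offset of 100.

Cell-composition estimation is a reference-based constrained projection: a
sample's beta profile over a panel of cell-type-discriminating probes is
decomposed as a non-negative mixture of pure cell-type profiles (summing to
one, or to at most one), by constrained least squares.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import rankdata

from .core_io import BetaMatrix, CellReference, ProbeManifest

__all__ = [
    "filter_probes",
    "dasen_normalize",
    "quantile_normalize",
    "compute_beta",
    "select_deconvolution_probes",
    "estimate_cell_proportions",
    "DeconvolutionResult",
]


def filter_probes(matrix: BetaMatrix, manifest: ProbeManifest) -> BetaMatrix:
    """Drop cross-reactive and QC-failed probes, preserving probe order."""
    missing = matrix.probe_ids.difference(manifest.probe_ids)
    if len(missing) > 0:
        raise KeyError(
            f"{len(missing)} matrix probes absent from manifest, e.g. "
            f"{list(missing[:5])}"
        )
    flags = manifest.data.loc[matrix.probe_ids]
    keep = ~(flags["cross_reactive"].astype(bool) | flags["qc_fail"].astype(bool))
    return BetaMatrix(matrix.data.loc[keep[keep].index])


def quantile_normalize(values: np.ndarray) -> np.ndarray:
    """Quantile-normalize columns (samples) to their common mean distribution.

    Every column is mapped onto the rank-wise mean of the column-sorted
    values; ties within a column receive the average of the reference values
    at their tied ranks (deterministic).  Within-column ranks are preserved.
    """
    n_rows, n_cols = values.shape
    sorted_vals = np.sort(values, axis=0)
    reference = sorted_vals.mean(axis=1)
    out = np.empty_like(values, dtype=float)
    positions = np.arange(1, n_rows + 1, dtype=float)
    for j in range(n_cols):
        ranks = rankdata(values[:, j], method="average")
        out[:, j] = np.interp(ranks, positions, reference)
    return out


def dasen_normalize(
    methylated: pd.DataFrame,
    unmethylated: pd.DataFrame,
    design_types: pd.Series,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Scale-correct type II intensities and quantile-normalize per stratum.

    For each of the two intensity matrices independently: (1) per sample,
    multiply type II intensities by the ratio of that sample's type I median
    to its type II median (the between-design scale correction); (2) within
    each design-type stratum, quantile-normalize across samples so all
    samples share the stratum's mean empirical distribution.

    Strata with fewer than two probes are passed through with a warning.
    """
    if methylated.shape != unmethylated.shape:
        raise ValueError("methylated and unmethylated matrices differ in shape")
    if not methylated.index.equals(unmethylated.index) or not methylated.columns.equals(
        unmethylated.columns
    ):
        raise ValueError("methylated and unmethylated matrices must be aligned")
    dt = design_types.reindex(methylated.index)
    if dt.isna().any():
        raise ValueError("design type missing for some probes")

    out = []
    for mat in (methylated, unmethylated):
        vals = mat.to_numpy(dtype=float).copy()
        type1 = (dt == "I").to_numpy()
        type2 = (dt == "II").to_numpy()
        if type1.any() and type2.any():
            med1 = np.median(vals[type1], axis=0)
            med2 = np.median(vals[type2], axis=0)
            with np.errstate(divide="ignore", invalid="ignore"):
                factor = np.where(med2 > 0, med1 / med2, 1.0)
            vals[type2] *= factor[None, :]
        for stratum in ("I", "II"):
            mask = (dt == stratum).to_numpy()
            if mask.sum() == 0:
                continue
            if mask.sum() < 2:
                warnings.warn(
                    f"design-type stratum {stratum!r} has < 2 probes; passed through"
                )
                continue
            vals[mask] = quantile_normalize(vals[mask])
        out.append(pd.DataFrame(vals, index=mat.index, columns=mat.columns))
    return out[0], out[1]


def compute_beta(
    methylated: pd.DataFrame, unmethylated: pd.DataFrame, offset: float = 100.0
) -> BetaMatrix:
    """Beta = M / (M + U + offset); a zero denominator yields missing."""
    if offset < 0:
        raise ValueError("offset must be non-negative")
    m = methylated.to_numpy(dtype=float)
    u = unmethylated.to_numpy(dtype=float)
    if (m < 0).any() or (u < 0).any():
        raise ValueError("intensities must be non-negative")
    denom = m + u + offset
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(denom > 0, m / denom, np.nan)
    return BetaMatrix(
        pd.DataFrame(beta, index=methylated.index, columns=methylated.columns)
    )


def select_deconvolution_probes(reference: CellReference, k: int = 100) -> pd.Index:
    """Top-k probes by between-type dispersion of the reference profiles.

    With one profile value per cell type, the between-type F-statistic
    reduces to the variance across types; the k most type-discriminating
    probes make the projection well conditioned.
    """
    disp = reference.profiles.var(axis=0, ddof=1)
    k = min(k, len(disp))
    return disp.sort_values(ascending=False).index[:k]


@dataclass
class DeconvolutionResult:
    """Estimated cell proportions (samples x types) with per-sample squared
    -error objective values."""

    proportions: pd.DataFrame
    objectives: pd.Series


def _check_reference_rank(profiles: np.ndarray, type_ids) -> None:
    centered = profiles - profiles.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    if (norms == 0).any():
        flat = [type_ids[i] for i in np.where(norms == 0)[0]]
        raise ValueError(f"constant reference profile(s): {flat}")
    corr = (centered / norms[:, None]) @ (centered / norms[:, None]).T
    np.fill_diagonal(corr, 0.0)
    i, j = np.unravel_index(np.argmax(np.abs(corr)), corr.shape)
    if abs(corr[i, j]) > 1 - 1e-10:
        raise ValueError(
            f"collinear reference profiles: {type_ids[i]!r} and {type_ids[j]!r}"
        )


def estimate_cell_proportions(
    sample_betas: BetaMatrix,
    reference: CellReference,
    constraint: str = "simplex",
    probes: pd.Index | None = None,
    n_probes: int = 100,
) -> DeconvolutionResult:
    """Constrained projection of each sample onto pure cell-type profiles.

    Per sample, minimize ||A w - y||^2 over proportion vectors w >= 0 with
    sum(w) = 1 (``simplex``) or sum(w) <= 1 (``sub_simplex``), where A holds
    the reference profiles over the deconvolution probe panel.  The panel is
    ``probes`` if given, otherwise the ``n_probes`` most discriminating
    reference probes shared with the sample matrix.
    """
    if constraint not in ("simplex", "sub_simplex"):
        raise ValueError("constraint must be 'simplex' or 'sub_simplex'")
    if probes is None:
        shared = reference.probe_ids.intersection(sample_betas.probe_ids)
        if len(shared) == 0:
            raise ValueError("reference and samples share no probes")
        sub = CellReference(reference.profiles[shared])
        probes = select_deconvolution_probes(sub, n_probes)
    else:
        missing = [p for p in probes if p not in sample_betas.probe_ids]
        if missing:
            raise KeyError(f"deconvolution probes absent from samples: {missing[:5]}")
    a_mat = reference.profiles[list(probes)].to_numpy(dtype=float).T  # probes x types
    _check_reference_rank(a_mat.T, list(reference.cell_type_ids))
    n_types = a_mat.shape[1]
    y_all = sample_betas.data.loc[list(probes)].to_numpy(dtype=float)

    w0 = np.full(n_types, 1.0 / n_types)
    if constraint == "simplex":
        constraints = [{"type": "eq", "fun": lambda w: w.sum() - 1.0, "jac": lambda w: np.ones_like(w)}]
    else:
        constraints = [{"type": "ineq", "fun": lambda w: 1.0 - w.sum(), "jac": lambda w: -np.ones_like(w)}]
    bounds = [(0.0, 1.0)] * n_types
    ata = a_mat.T @ a_mat

    props = np.empty((sample_betas.n_samples, n_types))
    objs = np.empty(sample_betas.n_samples)
    for i in range(sample_betas.n_samples):
        y = y_all[:, i]
        mask = ~np.isnan(y)
        if mask.sum() < n_types:
            raise ValueError(
                f"sample {sample_betas.sample_ids[i]!r} has too few non-missing "
                "deconvolution probes"
            )
        a_i = a_mat[mask]
        y_i = y[mask]

        def objective(w, a_i=a_i, y_i=y_i):
            r = a_i @ w - y_i
            return r @ r

        def grad(w, a_i=a_i, y_i=y_i):
            return 2.0 * a_i.T @ (a_i @ w - y_i)

        res = optimize.minimize(
            objective,
            w0,
            jac=grad,
            method="SLSQP",
            bounds=bounds,
            constraints=constraints,
            options={"ftol": 1e-14, "maxiter": 500},
        )
        props[i] = np.clip(res.x, 0.0, None)
        objs[i] = objective(props[i])
    proportions = pd.DataFrame(
        props, index=sample_betas.sample_ids, columns=reference.cell_type_ids
    )
    return DeconvolutionResult(proportions, pd.Series(objs, index=sample_betas.sample_ids))
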