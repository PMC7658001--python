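"""Coregulation-module detection on a candidate probe set (WGCNA-style).

The network is built on unsigned soft-thresholded correlations: adjacency
a_ij = |cor(x_i, x_j)|^beta with beta chosen by the scale-free topology
criterion (smallest power whose signed fit R^2 exceeds 0.8, else the best
fitting power).  Topological overlap converts adjacency into a
shared-neighbour similarity, average-linkage hierarchical clustering on
1 - TOM with a static cut yields modules, and each module is summarized by
its eigengene — the first principal component of its standardized probes,
unit-variance, sign-oriented so its mean correlation with member probes is
positive.  Per-probe module membership (kME) is the correlation of the
probe with its module's eigengene; probes with high |kME| are hubs.

Probes are typically residualized on covariates (age, sex, ancestry) before
network construction — see :func:`ewasnet.endophenotype.residualize`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .core_io import BetaMatrix

__all__ = [
    "ModuleSet",
    "soft_adjacency",
    "pick_soft_threshold",
    "topological_overlap",
    "detect_modules",
    "module_eigengene",
    "module_trait_association",
    "build_modules",
]

#: default candidate soft powers; includes 9, the typical small-network pick
DEFAULT_POWERS = tuple(range(1, 21))


@dataclass
class ModuleSet:
    """Result of module detection on a probe submatrix.

    ``assignment`` maps each probe to a module ID (``"M1"`` largest first)
    or ``"unassigned"``; ``eigengenes`` holds one unit-variance score per
    sample per module; ``kme`` is each assigned probe's correlation with its
    own module eigengene.
    """

    power: int
    fit_table: pd.DataFrame
    assignment: pd.Series
    eigengenes: pd.DataFrame  # samples x modules
    kme: pd.Series
    variance_explained: pd.Series  # per module

    def module_probes(self, module_id: str) -> pd.Index:
        return self.assignment.index[self.assignment == module_id]


def _as_frame(data) -> pd.DataFrame:
    """Accept a BetaMatrix or a probes x samples DataFrame (e.g. covariate
    residuals, which live outside [0, 1])."""
    return data.data if isinstance(data, BetaMatrix) else data


def _probe_matrix(data) -> np.ndarray:
    frame = _as_frame(data)
    x = frame.to_numpy(dtype=float)  # probes x samples
    if np.isnan(x).any():
        raise ValueError("network construction requires complete (imputed) data")
    sds = x.std(axis=1)
    flat = sds <= 1e-12 * (1.0 + np.abs(x).max(axis=1))
    if flat.any():
        probe = frame.index[np.argmax(flat)]
        raise ValueError(f"zero-variance probe: {probe!r}")
    return x


def soft_adjacency(beta_submatrix, power: int) -> pd.DataFrame:
    """Unsigned adjacency |pearson cor|^power with zero diagonal."""
    if power < 1:
        raise ValueError("power must be >= 1")
    frame = _as_frame(beta_submatrix)
    if frame.shape[0] < 3:
        raise ValueError("need at least 3 probes")
    x = _probe_matrix(frame)
    corr = np.corrcoef(x)
    adj = np.abs(np.clip(corr, -1.0, 1.0)) ** power
    np.fill_diagonal(adj, 0.0)
    return pd.DataFrame(adj, index=frame.index, columns=frame.index)


def _scale_free_fit(connectivity: np.ndarray, n_bins: int = 10) -> float:
    """Signed R^2 of log-frequency vs log-mean-connectivity over degree bins."""
    k = connectivity[connectivity > 0]
    if len(k) < 3 or np.ptp(k) == 0:
        raise ValueError("degenerate connectivity distribution")
    edges = np.linspace(k.min(), k.max() + 1e-12, n_bins + 1)
    which = np.clip(np.digitize(k, edges) - 1, 0, n_bins - 1)
    log_k, log_f = [], []
    for b in range(n_bins):
        members = k[which == b]
        if len(members) == 0:
            continue  # empty bins dropped
        log_k.append(np.log10(members.mean()))
        log_f.append(np.log10(len(members) / len(k)))
    if len(log_k) < 3:
        return 0.0
    res = stats.linregress(log_k, log_f)
    # scale-free topology has a negative log-log slope; the signed fit index
    # is -sign(slope) * R^2 so that good scale-free fits score positively
    return float(-np.sign(res.slope) * res.rvalue**2)


def pick_soft_threshold(
    beta_submatrix,
    candidate_powers=DEFAULT_POWERS,
    r2_threshold: float = 0.8,
) -> tuple[int, pd.DataFrame]:
    """Choose the soft power by the scale-free topology criterion.

    Returns the smallest candidate whose signed R^2 exceeds
    ``r2_threshold``; if none qualifies, the candidate maximizing signed
    R^2.  The full fit table (power, signed R^2, mean connectivity) is
    returned alongside.
    """
    candidate_powers = list(candidate_powers)
    if not candidate_powers:
        raise ValueError("candidate_powers must be non-empty")
    records = []
    for power in candidate_powers:
        adj = soft_adjacency(beta_submatrix, power).to_numpy()
        k = adj.sum(axis=1)
        if np.ptp(k) == 0:
            raise ValueError("all connectivities identical; degenerate network")
        records.append(
            {"power": power, "signed_r2": _scale_free_fit(k), "mean_k": float(k.mean())}
        )
    fit = pd.DataFrame(records).set_index("power")
    passing = fit.index[fit["signed_r2"] > r2_threshold]
    chosen = int(passing[0]) if len(passing) else int(fit["signed_r2"].idxmax())
    return chosen, fit


def topological_overlap(adjacency: pd.DataFrame) -> pd.DataFrame:
    """TOM similarity: shared-neighbour overlap normalized by connectivity.

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij) for
    i != j, and TOM_ii = 1.
    """
    a = adjacency.to_numpy(dtype=float)
    if not np.allclose(a, a.T):
        raise ValueError("adjacency must be symmetric")
    if (a < 0).any() or (a > 1).any():
        raise ValueError("adjacency entries must lie in [0, 1]")
    a = a.copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    shared = a @ a
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = (shared + a) / denom
    np.fill_diagonal(tom, 1.0)
    return pd.DataFrame(tom, index=adjacency.index, columns=adjacency.columns)


def detect_modules(
    tom: pd.DataFrame, min_module_size: int = 10, cut_height: float | None = None
) -> pd.Series:
    """Average-linkage clustering of 1 - TOM with a static cut.

    ``cut_height`` is the static cut on the merge height; the default
    (``None``) places the cut in the middle of the largest gap between
    consecutive merge heights in the upper half of the dendrogram — between
    the within-module merges and the final between-module joins — which
    adapts to the TOM scale set by the soft power.  Clusters smaller than
    ``min_module_size`` become ``"unassigned"``; surviving modules are
    labelled M1, M2, ... by size descending (ties broken by first-member
    probe order, deterministically).
    """
    if min_module_size < 2:
        raise ValueError("min_module_size must be >= 2")
    dissim = 1.0 - tom.to_numpy(dtype=float)
    np.fill_diagonal(dissim, 0.0)
    condensed = squareform(dissim, checks=False)
    link = hierarchy.linkage(condensed, method="average")
    if cut_height is None:
        heights = np.sort(link[:, 2])
        upper = heights[heights >= np.median(heights)]
        gaps = np.diff(upper)
        g = int(np.argmax(gaps))
        cut_height = float((upper[g] + upper[g + 1]) / 2.0)
    raw = hierarchy.fcluster(link, t=cut_height, criterion="distance")
    labels = pd.Series(raw, index=tom.index)
    sizes = labels.value_counts()
    keep = sizes[sizes >= min_module_size]
    # order: size descending, then first appearance of the cluster
    first_pos = {c: int(np.argmax(raw == c)) for c in keep.index}
    ordered = sorted(keep.index, key=lambda c: (-keep[c], first_pos[c]))
    mapping = {c: f"M{r + 1}" for r, c in enumerate(ordered)}
    return labels.map(lambda c: mapping.get(c, "unassigned"))


def module_eigengene(
    beta_submatrix, module_probes
) -> tuple[pd.Series, pd.Series, float]:
    """First principal component summary of a module.

    Probes are standardized across samples; the eigengene is the PC1 score
    vector scaled to unit variance, sign-oriented so its mean correlation
    with member probes is positive.  Returns (eigengene, kME per probe,
    variance explained by PC1).
    """
    module_probes = list(module_probes)
    if len(module_probes) < 2:
        raise ValueError("module must have at least 2 probes")
    frame = _as_frame(beta_submatrix)
    missing = [p for p in module_probes if p not in frame.index]
    if missing:
        raise KeyError(f"module probes absent from matrix: {missing[:5]}")
    sub = frame.loc[module_probes]
    if sub.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    x = _probe_matrix(sub).T  # samples x probes
    z = (x - x.mean(axis=0)) / x.std(axis=0, ddof=1)
    u, s, _ = np.linalg.svd(z, full_matrices=False)
    scores = u[:, 0] * s[0]
    scores = scores / scores.std(ddof=1)
    var_explained = float(s[0] ** 2 / (s**2).sum())
    kme_vals = np.array([stats.pearsonr(z[:, j], scores)[0] for j in range(z.shape[1])])
    if kme_vals.mean() < 0:
        scores = -scores
        kme_vals = -kme_vals
    eigengene = pd.Series(scores, index=sub.columns, name="eigengene")
    kme = pd.Series(kme_vals, index=sub.index, name="kme")
    return eigengene, kme, var_explained


def module_trait_association(
    eigengene: pd.Series | None,
    trait: pd.Series | None = None,
    method: str = "eigengene_cor",
    kme: pd.Series | None = None,
    probe_statistic: pd.Series | None = None,
) -> tuple[float, float]:
    """Module-trait correlation under either of two published readings.

    ``eigengene_cor``: Pearson correlation of the module eigengene with a
    per-sample trait, with its t-test p.  ``mm_vs_significance``: Pearson
    correlation across probes of |kME| with a per-probe association
    statistic (the membership-vs-significance construction).
    """
    if method == "eigengene_cor":
        if eigengene is None or trait is None:
            raise ValueError("eigengene_cor requires eigengene and trait")
        aligned = pd.concat([eigengene, trait], axis=1, join="inner").dropna()
        if len(aligned) != len(eigengene):
            if len(aligned) < 3:
                raise ValueError("eigengene and trait share too few samples")
        r, p = stats.pearsonr(aligned.iloc[:, 0], aligned.iloc[:, 1])
        return float(r), float(p)
    if method == "mm_vs_significance":
        if kme is None or probe_statistic is None:
            raise ValueError("mm_vs_significance requires kme and probe_statistic")
        aligned = pd.concat([kme.abs(), probe_statistic], axis=1, join="inner").dropna()
        if len(aligned) < 3:
            raise ValueError("too few probes with both kME and statistic")
        r, p = stats.pearsonr(aligned.iloc[:, 0], aligned.iloc[:, 1])
        return float(r), float(p)
    raise ValueError("method must be 'eigengene_cor' or 'mm_vs_significance'")


def build_modules(
    beta_submatrix,
    candidate_powers=DEFAULT_POWERS,
    min_module_size: int = 10,
    cut_height: float | None = None,
    power: int | None = None,
) -> ModuleSet:
    """Full module-detection pass: power selection, TOM, clustering,
    eigengenes and kME.  Pass ``power`` to skip selection (e.g. a published
    configuration such as beta = 9)."""
    if power is None:
        power, fit = pick_soft_threshold(beta_submatrix, candidate_powers)
    else:
        _, fit = pick_soft_threshold(beta_submatrix, [power])
    adj = soft_adjacency(beta_submatrix, power)
    tom = topological_overlap(adj)
    assignment = detect_modules(tom, min_module_size, cut_height)
    eigengenes = {}
    kme_parts = []
    var_exp = {}
    for module_id in sorted(set(assignment) - {"unassigned"}):
        probes = assignment.index[assignment == module_id]
        eg, kme, ve = module_eigengene(beta_submatrix, probes)
        eigengenes[module_id] = eg
        kme_parts.append(kme)
        var_exp[module_id] = ve
    eg_frame = (
        pd.DataFrame(eigengenes)
        if eigengenes
        else pd.DataFrame(index=_as_frame(beta_submatrix).columns)
    )
    kme_all = pd.concat(kme_parts) if kme_parts else pd.Series(dtype=float)
    return ModuleSet(
        power=power,
        fit_table=fit,
        assignment=assignment,
        eigengenes=eg_frame,
        kme=kme_all,
        variance_explained=pd.Series(var_exp, dtype=float),
    )
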