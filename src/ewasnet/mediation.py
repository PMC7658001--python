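"""Mediation-network "connectedness" analysis of a coregulated module.

For a module tied to a physiological outcome (here: morning cortisol), this
procedure asks which hub loci statistically account for the outcome
associations of the other module loci.  Hubs are the loci in the top
fraction (default 30%) of module membership |kME|.  For an ordered pair
(mediator hub -> mediated locus), two OLS models are fit:

  (A)  outcome ~ mediated + covariates            -> solo p of `mediated`
  (B)  outcome ~ mediator + mediated + covariates -> conditional p of `mediated`

The pair is *connected* when the mediated locus associates alone
(solo p < alpha) but loses association once the hub enters the additive
model (conditional p >= alpha).  A hub's connectedness is its number of
connected edges; no multiple-testing correction is applied across pairs, so
the expected false-edge burden under the null is about alpha per evaluated
pair — report it alongside.

This is a significance-pattern classifier, not a causal-effect
decomposition: no indirect-effect estimate, Sobel test, or bootstrap is
involved.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
import statsmodels.api as sm

from .core_io import BetaMatrix
from .endophenotype import _encode_covariates

__all__ = [
    "select_hubs",
    "mediation_edge",
    "build_mediation_network",
    "MediationResult",
]


def select_hubs(kme: pd.Series, percentile: float = 0.30) -> list[str]:
    """Loci in the top ``percentile`` fraction of module membership |kME|.

    The hub count is ceil(percentile x module size); boundary ties are
    broken by probe-ID lexicographic order, so selection is deterministic.
    """
    if len(kme) == 0:
        raise ValueError("empty module")
    if not 0.0 < percentile <= 1.0:
        raise ValueError("percentile must lie in (0, 1]")
    count = math.ceil(percentile * len(kme))
    ranked = (
        kme.abs()
        .to_frame("abs_kme")
        .assign(probe=kme.index)
        .sort_values(["abs_kme", "probe"], ascending=[False, True], kind="mergesort")
    )
    return list(ranked.index[:count])


def _ols_pvalue(y: np.ndarray, columns: list[np.ndarray], target_col: int) -> float:
    x = np.column_stack([np.ones(len(y))] + columns)
    fit = sm.OLS(y, x).fit()
    return float(fit.pvalues[target_col])


@dataclass
class EdgeDecision:
    mediator: str
    mediated: str
    solo_p: float
    conditional_p: float
    connected: bool


def mediation_edge(
    mediator: pd.Series,
    mediated: pd.Series,
    outcome: pd.Series,
    covariates: pd.DataFrame | None = None,
    alpha: float = 0.05,
    hub_assessed_alone: bool = False,
) -> EdgeDecision:
    """Classify one ordered locus pair as connected or not.

    By default the *mediated* locus is the one assessed alone and in the
    additive model (so connectedness is a property of the hub mediator);
    ``hub_assessed_alone=True`` flips to the opposite reading, testing the
    mediator's own association before and after adding the mediated locus.
    Near-collinear pairs (|cor| > 0.999) raise rather than emit a decision.
    """
    frames = [mediator.rename("mediator"), mediated.rename("mediated"), outcome.rename("outcome")]
    if covariates is not None:
        frames.append(_encode_covariates(covariates))
    data = pd.concat(frames, axis=1, join="inner").dropna()
    if len(data) < (4 + (0 if covariates is None else covariates.shape[1])):
        raise ValueError("too few complete cases for the mediation models")
    x_med = data["mediator"].to_numpy(dtype=float)
    x_tar = data["mediated"].to_numpy(dtype=float)
    if abs(np.corrcoef(x_med, x_tar)[0, 1]) > 0.999:
        raise ValueError(
            f"collinear pair: |cor({mediator.name!r}, {mediated.name!r})| > 0.999"
        )
    y = data["outcome"].to_numpy(dtype=float)
    covs = [data[c].to_numpy(dtype=float) for c in data.columns[3:]]

    solo_x, added_x = (x_tar, x_med) if not hub_assessed_alone else (x_med, x_tar)
    solo_p = _ols_pvalue(y, [solo_x] + covs, target_col=1)
    conditional_p = _ols_pvalue(y, [solo_x, added_x] + covs, target_col=1)
    connected = solo_p < alpha and conditional_p >= alpha
    return EdgeDecision(
        mediator=str(mediator.name),
        mediated=str(mediated.name),
        solo_p=solo_p,
        conditional_p=conditional_p,
        connected=connected,
    )


@dataclass
class MediationResult:
    """Directed mediation graph plus per-hub connectedness ranking."""

    graph: nx.DiGraph
    connectedness: pd.Series  # hubs, ranked descending (ties by probe ID)
    evaluated_pairs: int
    skipped: list[tuple[str, str, str]] = field(default_factory=list)

    @property
    def top_hub(self) -> str:
        return str(self.connectedness.index[0])


def build_mediation_network(
    hubs,
    module_probes,
    beta_submatrix: BetaMatrix,
    outcome: pd.Series,
    covariates: pd.DataFrame | None = None,
    alpha: float = 0.05,
    hub_assessed_alone: bool = False,
) -> MediationResult:
    """Evaluate every (hub mediator, other module locus) ordered pair.

    Nodes carry their connectedness count (out-degree); edges carry solo and
    conditional p values.  Collinear pairs are skipped with a warning and
    recorded.  The procedure is deterministic and invariant to probe input
    ordering (edges are evaluated independently; the ranking sorts by count
    then probe ID).
    """
    hubs = list(hubs)
    module_probes = list(module_probes)
    if not set(hubs) <= set(module_probes):
        raise ValueError("hubs must be a subset of module_probes")
    data = beta_submatrix.data if isinstance(beta_submatrix, BetaMatrix) else beta_submatrix

    graph = nx.DiGraph()
    counts = {h: 0 for h in hubs}
    skipped: list[tuple[str, str, str]] = []
    evaluated = 0
    graph.add_nodes_from(hubs)
    for hub in hubs:
        for probe in module_probes:
            if probe == hub:
                continue
            try:
                decision = mediation_edge(
                    data.loc[hub],
                    data.loc[probe],
                    outcome,
                    covariates,
                    alpha=alpha,
                    hub_assessed_alone=hub_assessed_alone,
                )
            except ValueError as err:
                warnings.warn(f"skipping pair ({hub}, {probe}): {err}")
                skipped.append((hub, probe, str(err)))
                continue
            evaluated += 1
            if decision.connected:
                counts[hub] += 1
                graph.add_edge(
                    hub,
                    probe,
                    solo_p=decision.solo_p,
                    conditional_p=decision.conditional_p,
                )
    nx.set_node_attributes(
        graph, {h: {"connectedness": counts.get(h, 0)} for h in graph.nodes}
    )
    ranking = (
        pd.Series(counts, name="connectedness")
        .sort_index()
        .sort_values(ascending=False, kind="mergesort")
    )
    return MediationResult(
        graph=graph, connectedness=ranking, evaluated_pairs=evaluated, skipped=skipped
    )
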