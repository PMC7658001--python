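"""Cross-cohort replication: intersection of FDR-significant probes with
direction consistency, the chance-overlap enrichment statistic, and the
multi-cohort report table.

The replication logic is deliberately simple set algebra: a probe replicates
when it is FDR-significant in every cohort and (optionally) its effect has
the same sign everywhere.  Whether that overlap exceeds chance is judged
against an explicit background fraction — the per-probe probability that a
replication-significant probe would also be discovery-significant under
independence — with a binomial confidence interval on the overlap
proportion k/n (Wilson score by default) and a one-sided exact binomial
enrichment p value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .core_io import EwasTable, ProbeManifest

__all__ = [
    "ReplicationResult",
    "intersect_significant",
    "overlap_enrichment",
    "multi_cohort_table",
]

_CI_METHODS = {"wilson": "wilson", "normal": "normal", "clopper_pearson": "beta"}


@dataclass
class ReplicationResult:
    """Outcome of a cross-cohort intersection.

    ``n`` is the number of significant probes in the (first) replication
    cohort — the denominator of the replicated fraction k/n.
    """

    significant_per_table: list[pd.Index]
    intersection: pd.Index
    direction_consistent: pd.Index
    k: int
    n: int
    expected_probability: float | None = None
    ci_lower: float | None = None
    ci_upper: float | None = None
    p_enrichment: float | None = None


def overlap_enrichment(
    k: int,
    n: int,
    background_fraction: float,
    ci_method: str = "wilson",
) -> tuple[float, float, float, float]:
    """Chance expectation, binomial 95% CI for k/n, and enrichment p.

    ``background_fraction`` is the per-probe chance of discovery
    significance under independence; the enrichment p is the exact binomial
    upper tail P(X >= k | n, background_fraction).
    """
    if not 0 <= k <= n:
        raise ValueError("require 0 <= k <= n")
    if not 0.0 <= background_fraction <= 1.0:
        raise ValueError("background_fraction must lie in [0, 1]")
    if ci_method not in _CI_METHODS:
        raise ValueError(f"ci_method must be one of {sorted(_CI_METHODS)}")
    lo, hi = proportion_confint(k, n, alpha=0.05, method=_CI_METHODS[ci_method])
    p_enrich = float(stats.binom.sf(k - 1, n, background_fraction)) if n else 1.0
    return background_fraction, float(lo), float(hi), p_enrich


def intersect_significant(
    tables: list[EwasTable],
    q_threshold: float = 0.05,
    require_same_direction: bool = True,
    background_fraction: float | None = None,
    ci_method: str = "wilson",
) -> ReplicationResult:
    """Probes significant in every cohort, optionally direction-consistent.

    The enrichment statistics use ``background_fraction`` when given;
    otherwise the discovery table's significant fraction (significant /
    tested) stands in for the per-probe chance rate, and that default is
    recorded in the result rather than applied silently.
    """
    if len(tables) < 2:
        raise ValueError("need at least two cohort tables")
    shared = tables[0].probe_ids
    for t in tables[1:]:
        shared = shared.intersection(t.probe_ids)
    if len(shared) == 0:
        raise ValueError("cohort tables share no probes")

    sig_sets = [t.significant(q_threshold) for t in tables]
    inter = sig_sets[0]
    for s in sig_sets[1:]:
        inter = inter.intersection(s)
    inter = pd.Index([p for p in tables[0].probe_ids if p in inter])  # discovery order

    signs = np.column_stack(
        [t.data.loc[inter, "direction"].to_numpy(dtype=float) for t in tables]
    ) if len(inter) else np.empty((0, len(tables)))
    # zero or missing effects count as inconsistent with either sign
    consistent_mask = (
        (np.abs(signs) == 1).all(axis=1) & (signs == signs[:, [0]]).all(axis=1)
        if len(inter)
        else np.array([], dtype=bool)
    )
    consistent = inter[consistent_mask]

    replicated = consistent if require_same_direction else inter
    k = len(replicated)
    n = len(sig_sets[1])
    result = ReplicationResult(
        significant_per_table=sig_sets,
        intersection=inter,
        direction_consistent=consistent,
        k=k,
        n=n,
    )
    if background_fraction is None:
        tested = int(tables[0].data["p"].notna().sum())
        background_fraction = len(sig_sets[0]) / tested if tested else 0.0
    if n > 0:
        exp, lo, hi, p_enrich = overlap_enrichment(k, n, background_fraction, ci_method)
        result.expected_probability = exp
        result.ci_lower = lo
        result.ci_upper = hi
        result.p_enrichment = p_enrich
    return result


def multi_cohort_table(
    tables: dict[str, EwasTable],
    probe_set,
    manifest: ProbeManifest | None = None,
) -> pd.DataFrame:
    """Per-probe (b, SE, adjusted p) across cohorts, report-style.

    Rows are sectioned into negative then positive associations by the
    discovery (first) cohort's effect sign and ordered within section by
    the last cohort's adjusted p (missing last); probes absent from a
    cohort show missing cells.
    """
    probe_set = list(probe_set)
    if not probe_set:
        raise ValueError("probe_set must be non-empty")
    cohorts = list(tables)
    rows = {}
    for probe in probe_set:
        row: dict[str, object] = {}
        if manifest is not None and probe in manifest.probe_ids:
            row["gene"] = manifest.data.loc[probe, "gene_symbols"]
        else:
            row["gene"] = ""
        for name in cohorts:
            tab = tables[name].data
            if probe in tab.index:
                row[f"{name}_b"] = tab.loc[probe, "b"]
                row[f"{name}_se"] = tab.loc[probe, "se"]
                row[f"{name}_q"] = tab.loc[probe, "q"]
            else:
                row[f"{name}_b"] = np.nan
                row[f"{name}_se"] = np.nan
                row[f"{name}_q"] = np.nan
        rows[probe] = row
    report = pd.DataFrame.from_dict(rows, orient="index")
    report.index.name = "probe_id"
    disc_sign = report[f"{cohorts[0]}_b"].apply(
        lambda b: "negative" if b < 0 else "positive"
    )
    report["section"] = disc_sign
    sort_q = report[f"{cohorts[-1]}_q"]
    report = report.assign(_order=sort_q).sort_values(
        ["section", "_order"],
        ascending=[True, True],
        na_position="last",
        kind="mergesort",  # stable -> deterministic, byte-identical reruns
    )
    return report.drop(columns="_order")
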