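"""Per-probe regression against the closed-form OLS oracle, BH-FDR against
the exhaustive step-up oracle, scan alignment invariance, and the smoking
sensitivity analysis."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ewasnet import (
    ModelSpec,
    ModuleBlock,
    SimulationConfig,
    dose_metric,
    fdr_adjust,
    fit_probe_model,
    generate_cohort,
    run_ewas,
    sensitivity_with_smoking,
)
from ewasnet.core_io import BetaMatrix, SampleTable
from ewasnet.ewas import mvalue_pcs

from conftest import ols_oracle


class TestDoseMetric:
    def test_product(self):
        assert dose_metric(5.0, 20.0) == 100.0

    def test_zero_drinks(self):
        assert dose_metric(0.0, 35.0) == 0.0

    def test_missing_propagates(self):
        assert np.isnan(dose_metric(np.nan, 20.0))
        assert np.isnan(dose_metric(3.0, np.nan))

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            dose_metric(-1.0, 5.0)


def _toy_samples(n=200, seed=0):
    rng = np.random.default_rng(seed)
    frame = pd.DataFrame(
        {
            "diagnosis": rng.integers(0, 2, n).astype(float),
            "age": rng.uniform(25, 70, n),
            "sex": rng.choice(["F", "M"], n),
            "smoking_score": rng.poisson(2.0, n).astype(float),
        },
        index=pd.Index([f"s{i}" for i in range(n)], name="sample_id"),
    )
    return SampleTable(frame)


class TestFitProbeModel:
    def test_constant_response_gives_reason_code(self):
        samples = _toy_samples()
        row = pd.Series(0.5, index=samples.sample_ids)
        res = fit_probe_model(row, samples, ModelSpec(covariates=("age", "sex")))
        assert np.isnan(res["b"])
        assert res["reason"] == "zero_variance"

    def test_planted_effect_matches_closed_form_oracle(self):
        rng = np.random.default_rng(42)
        samples = _toy_samples(200, seed=1)
        dx = samples.data["diagnosis"].to_numpy()
        y = 0.30 + 0.05 * dx + rng.normal(0, 0.01, 200)
        row = pd.Series(y, index=samples.sample_ids)
        spec = ModelSpec(covariates=("age", "sex"))
        res = fit_probe_model(row, samples, spec)
        assert abs(res["b"] - 0.05) < 3 * res["se"]

        x = np.column_stack(
            [
                np.ones(200),
                dx,
                samples.data["age"],
                (samples.data["sex"] == "M").astype(float),
            ]
        )
        beta, se, t, p, _ = ols_oracle(x, y)
        assert res["b"] == pytest.approx(beta[1], abs=1e-10)
        assert res["se"] == pytest.approx(se[1], abs=1e-10)
        assert res["p"] == pytest.approx(p[1], abs=1e-10)

    def test_oracle_agreement_on_random_designs(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            n = int(rng.integers(15, 40))
            n_cov = int(rng.integers(0, 3))
            frame = pd.DataFrame(
                {"diagnosis": rng.integers(0, 2, n).astype(float)},
                index=pd.Index([f"s{i}" for i in range(n)], name="sample_id"),
            )
            covs = []
            for c in range(n_cov):
                frame[f"cov{c}"] = rng.normal(size=n)
                covs.append(f"cov{c}")
            samples = SampleTable(frame)
            y = rng.normal(0.4, 0.05, n)
            res = fit_probe_model(
                pd.Series(y, index=frame.index), samples, ModelSpec(covariates=tuple(covs))
            )
            x = np.column_stack(
                [np.ones(n), frame["diagnosis"]] + [frame[c] for c in covs]
            )
            beta, se, _, p, _ = ols_oracle(x, y)
            assert res["b"] == pytest.approx(beta[1], abs=1e-10)
            assert res["se"] == pytest.approx(se[1], abs=1e-10)
            assert res["p"] == pytest.approx(p[1], abs=1e-10)

    def test_orthogonal_covariate_leaves_b_unchanged(self):
        rng = np.random.default_rng(9)
        n = 100
        samples = _toy_samples(n, seed=2)
        dx = samples.data["diagnosis"].to_numpy()
        y = 0.3 + 0.02 * dx + rng.normal(0, 0.01, n)
        # build a covariate orthogonal to [1, dx, y] by projection
        raw = rng.normal(size=n)
        basis = np.column_stack([np.ones(n), dx, y])
        ortho = raw - basis @ np.linalg.lstsq(basis, raw, rcond=None)[0]
        frame = samples.data.copy()
        frame["ortho"] = ortho
        samples2 = SampleTable(frame)
        row = pd.Series(y, index=frame.index)
        b0 = fit_probe_model(row, samples2, ModelSpec(covariates=()))["b"]
        b1 = fit_probe_model(row, samples2, ModelSpec(covariates=("ortho",)))["b"]
        assert b1 == pytest.approx(b0, abs=1e-10)

    def test_rank_deficient_design_names_columns(self):
        samples = _toy_samples(50, seed=3)
        frame = samples.data.copy()
        frame["age_copy"] = frame["age"]
        samples2 = SampleTable(frame)
        row = pd.Series(np.random.default_rng(0).uniform(0.2, 0.8, 50), index=frame.index)
        with pytest.raises(np.linalg.LinAlgError, match="age_copy"):
            fit_probe_model(row, samples2, ModelSpec(covariates=("age", "age_copy")))

    def test_insufficient_complete_cases(self):
        samples = _toy_samples(6, seed=4)
        row = pd.Series([0.1, 0.2, np.nan, np.nan, np.nan, 0.3], index=samples.sample_ids)
        res = fit_probe_model(row, samples, ModelSpec(covariates=("age", "sex")))
        assert res["reason"] == "insufficient_complete_cases"


def bh_oracle(p):
    """Exhaustive min-over-suffix step-up oracle."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    for rank_pos, idx in enumerate(order):
        candidates = [
            m * p[order[j]] / (j + 1) for j in range(rank_pos, m)
        ]
        q[idx] = min(1.0, min(candidates))
    return q


class TestFdrAdjust:
    def test_hand_step_up(self):
        np.testing.assert_allclose(
            fdr_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_identity(self):
        np.testing.assert_allclose(fdr_adjust([0.05]), [0.05])

    def test_missing_reinserted(self):
        q = fdr_adjust([0.01, np.nan, 0.04])
        assert np.isnan(q[1])
        np.testing.assert_allclose(q[[0, 2]], bh_oracle([0.01, 0.04]))

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.0, 0.5])

    @settings(max_examples=200, deadline=None)
    @given(
        st.lists(
            st.floats(1e-12, 1.0, exclude_min=False), min_size=1, max_size=50
        )
    )
    def test_matches_exhaustive_oracle(self, p):
        # agreement up to multiplication-order round-off (~1 ulp)
        np.testing.assert_allclose(fdr_adjust(p), bh_oracle(p), rtol=1e-12, atol=0)

    def test_sorted_input_gives_monotone_q(self):
        rng = np.random.default_rng(1)
        p = np.sort(rng.uniform(1e-6, 1, 30))
        q = fdr_adjust(p)
        assert (np.diff(q) >= -1e-15).all()


class TestRunEwas:
    def test_alignment_invariance(self, small_cohort):
        matrix, table, _, truth = small_cohort
        spec = ModelSpec(covariates=("age", "sex", "ancestry", "cellprops"))
        res1 = run_ewas(matrix, table, spec, cell_proportions=truth.true_proportions)
        perm = np.random.default_rng(0).permutation(matrix.n_samples)
        matrix2 = BetaMatrix(matrix.data.iloc[:, perm])
        table2 = SampleTable(table.data.iloc[perm])
        res2 = run_ewas(matrix2, table2, spec, cell_proportions=truth.true_proportions)
        pd.testing.assert_frame_equal(res1.data, res2.data)

    def test_extreme_power_all_significant(self):
        cfg = SimulationConfig(
            n_samples=150, n_probes=40, n_causal=40, delta_range=(0.15, 0.2),
            module_blocks=(), composition_shift=None, smoking_comorbid=False,
            noise_sd=0.1, frac_covariate_probes=0.0, seed=5,
        )
        matrix, table, _, truth = generate_cohort(cfg)
        res = run_ewas(matrix, table, ModelSpec(covariates=("age", "sex")))
        assert (res.data["q"] < 0.05).all()

    def test_zero_sample_overlap_is_error(self, small_cohort):
        matrix, table, _, _ = small_cohort
        renamed = SampleTable(
            table.data.rename(index=lambda s: f"other_{s}")
        )
        with pytest.raises(ValueError, match="overlap"):
            run_ewas(matrix, renamed, ModelSpec(covariates=()))

    def test_null_scan_calibrated_small(self):
        cfg = SimulationConfig(
            n_samples=150, n_probes=800, n_causal=0, module_blocks=(),
            composition_shift=None, smoking_comorbid=False, seed=23,
        )
        matrix, table, _, _ = generate_cohort(cfg)
        res = run_ewas(matrix, table, ModelSpec(covariates=("age", "sex", "ancestry")))
        frac = (res.data["p"] <= 0.05).mean()
        assert frac == pytest.approx(0.05, abs=0.02)

    def test_consumption_predictor_and_pcs(self, small_cohort):
        matrix, table, _, _ = small_cohort
        pcs = mvalue_pcs(matrix, n_components=5)
        merged = SampleTable(table.data.join(pcs))
        spec = ModelSpec(
            predictor="log_units_per_week",
            covariates=("age", "sex", "pc1", "pc2", "pc3", "pc4", "pc5"),
        )
        res = run_ewas(matrix, merged, spec)
        assert res.data["p"].notna().all()
        assert (res.data["n"] == matrix.n_samples).all()


class TestSmokingSensitivity:
    def test_empty_probe_set(self, small_cohort):
        matrix, table, _, truth = small_cohort
        res = sensitivity_with_smoking(
            matrix, table, ModelSpec(covariates=("age",)), probe_set=[]
        )
        assert len(res.data) == 0

    def test_independent_smoking_barely_shifts_effects(self, small_cohort):
        # smoking_comorbid=False in the fixture: smoking is independent of
        # diagnosis, so adjusting for it moves b by well under 1 SE
        matrix, table, _, truth = small_cohort
        spec = ModelSpec(covariates=("age", "sex", "ancestry", "cellprops"))
        base = run_ewas(
            matrix.subset_probes(truth.causal_probes), table, spec,
            cell_proportions=truth.true_proportions,
        )
        adj = sensitivity_with_smoking(
            matrix, table, spec, probe_set=truth.causal_probes,
            cell_proportions=truth.true_proportions,
        )
        shift = (adj.data["b"] - base.data["b"]).abs() / base.data["se"]
        assert (shift < 1.0).all()

    def test_comorbid_smoking_confounds_and_adjustment_restores(self):
        cfg = SimulationConfig(
            n_samples=400, n_probes=600, n_causal=0, module_blocks=(),
            composition_shift=None, smoking_comorbid=True,
            frac_covariate_probes=0.3, covariate_effect_sd=0.05, seed=31,
        )
        matrix, table, _, _ = generate_cohort(cfg)
        naive = run_ewas(matrix, table, ModelSpec(covariates=("age", "sex")))
        adjusted = sensitivity_with_smoking(
            matrix, table, ModelSpec(covariates=("age", "sex")),
            probe_set=matrix.probe_ids,
        )
        frac_naive = (naive.data["p"] <= 0.05).mean()
        frac_adj = (adjusted.data["p"] <= 0.05).mean()
        mc_se = np.sqrt(0.05 * 0.95 / 600)
        assert frac_naive > 0.05 + 3 * mc_se
        assert frac_adj == pytest.approx(0.05, abs=2.5 * mc_se)
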