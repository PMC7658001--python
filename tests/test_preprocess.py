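"""QC filtering, normalization fixed points, beta arithmetic, and
deconvolution against an exhaustive active-set quadratic-programming oracle."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ewasnet.core_io import BetaMatrix, CellReference, ProbeManifest
from ewasnet.preprocess import (
    compute_beta,
    dasen_normalize,
    estimate_cell_proportions,
    filter_probes,
    quantile_normalize,
    select_deconvolution_probes,
)
from ewasnet.synthetic import default_manifest


def make_matrix(values, probes=None, samples=None):
    values = np.asarray(values, dtype=float)
    probes = probes or [f"cg{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{i}" for i in range(values.shape[1])]
    return BetaMatrix(pd.DataFrame(values, index=probes, columns=samples))


class TestFilterProbes:
    def test_flagged_probes_removed_order_preserved(self):
        mat = make_matrix(np.full((5, 2), 0.5))
        manifest = default_manifest(
            mat.probe_ids, cross_reactive=[False, True, False, False, False]
        )
        out = filter_probes(mat, manifest)
        assert list(out.probe_ids) == ["cg0", "cg2", "cg3", "cg4"]

    def test_no_flags_identity(self):
        mat = make_matrix(np.full((4, 3), 0.2))
        out = filter_probes(mat, default_manifest(mat.probe_ids))
        pd.testing.assert_frame_equal(out.data, mat.data)

    def test_random_flags_match_set_difference_oracle(self):
        rng = np.random.default_rng(17)
        mat = make_matrix(rng.uniform(size=(100, 3)))
        cross = rng.random(100) < 0.1
        qc = rng.random(100) < 0.08
        manifest = default_manifest(mat.probe_ids, cross_reactive=cross, qc_fail=qc)
        out = filter_probes(mat, manifest)
        expected = [p for p, c, q in zip(mat.probe_ids, cross, qc) if not (c or q)]
        assert list(out.probe_ids) == expected

    def test_probe_absent_from_manifest(self):
        mat = make_matrix(np.full((3, 2), 0.5))
        manifest = default_manifest(["cg0", "cg1"])
        with pytest.raises(KeyError, match="cg2"):
            filter_probes(mat, manifest)


class TestDasenNormalize:
    def test_hand_computed_single_stratum(self):
        # 3 probes x 2 samples: both samples map to rank-wise means
        frame = pd.DataFrame(
            [[1.0, 10.0], [2.0, 20.0], [3.0, 30.0]],
            index=["a", "b", "c"],
            columns=["s1", "s2"],
        )
        dt = pd.Series("II", index=frame.index)
        m, u = dasen_normalize(frame, frame, dt)
        expected = np.tile([[5.5], [11.0], [16.5]], (1, 2))
        np.testing.assert_allclose(m.to_numpy(), expected)
        np.testing.assert_allclose(u.to_numpy(), expected)

    def test_sorted_intensities_identical_across_samples_per_stratum(self):
        rng = np.random.default_rng(5)
        frame = pd.DataFrame(
            rng.gamma(3.0, 500.0, size=(60, 5)),
            index=[f"cg{i}" for i in range(60)],
        )
        dt = pd.Series(np.where(np.arange(60) % 3 == 0, "I", "II"), index=frame.index)
        m, _ = dasen_normalize(frame, frame.copy(), dt)
        for stratum in ("I", "II"):
            sub = np.sort(m.loc[dt == stratum].to_numpy(), axis=0)
            for j in range(1, sub.shape[1]):
                np.testing.assert_allclose(sub[:, j], sub[:, 0])

    def test_idempotent(self):
        rng = np.random.default_rng(6)
        frame = pd.DataFrame(
            rng.gamma(3.0, 500.0, size=(40, 4)),
            index=[f"cg{i}" for i in range(40)],
        )
        dt = pd.Series(np.where(np.arange(40) < 15, "I", "II"), index=frame.index)
        m1, u1 = dasen_normalize(frame, frame.copy(), dt)
        m2, u2 = dasen_normalize(m1, u1, dt)
        np.testing.assert_allclose(m2.to_numpy(), m1.to_numpy(), atol=1e-10)

    def test_type2_medians_matched_to_type1_before_qn(self):
        rng = np.random.default_rng(7)
        base = rng.gamma(3.0, 500.0, size=(50, 4))
        frame = pd.DataFrame(base, index=[f"cg{i}" for i in range(50)])
        dt = pd.Series(np.where(np.arange(50) < 25, "I", "II"), index=frame.index)
        inflated = frame.copy()
        inflated.loc[dt == "II"] *= 2.4  # systematic design-type scale gap
        m, _ = dasen_normalize(inflated, inflated.copy(), dt)
        med1 = np.median(m.loc[dt == "I"].to_numpy(), axis=0).mean()
        med2 = np.median(m.loc[dt == "II"].to_numpy(), axis=0).mean()
        assert med2 == pytest.approx(med1, rel=0.15)

    def test_shape_mismatch_and_tiny_stratum(self):
        frame = pd.DataFrame(np.ones((3, 2)), index=["a", "b", "c"])
        with pytest.raises(ValueError, match="shape"):
            dasen_normalize(frame, frame.iloc[:2], pd.Series("I", index=frame.index))
        dt = pd.Series(["I", "II", "II"], index=frame.index)
        with pytest.warns(UserWarning, match="stratum"):
            dasen_normalize(frame, frame.copy(), dt)


class TestComputeBeta:
    def test_arithmetic_and_boundaries(self):
        m = pd.DataFrame([[100.0], [0.0]], index=["a", "b"], columns=["s"])
        u = pd.DataFrame([[100.0], [500.0]], index=["a", "b"], columns=["s"])
        beta = compute_beta(m, u, offset=100.0)
        assert beta.data.loc["a", "s"] == pytest.approx(100 / 300)
        assert beta.data.loc["b", "s"] == 0.0

    def test_zero_denominator_is_missing(self):
        z = pd.DataFrame([[0.0]], index=["a"], columns=["s"])
        beta = compute_beta(z, z, offset=0.0)
        assert np.isnan(beta.data.loc["a", "s"])

    @settings(max_examples=50, deadline=None)
    @given(
        m=st.floats(0.0, 1e5),
        u=st.floats(0.0, 1e5),
        dm=st.floats(0.0, 100.0),
    )
    def test_monotone_in_m_and_antitone_in_u(self, m, u, dm):
        mk = lambda v: pd.DataFrame([[v]], index=["a"], columns=["s"])
        base = compute_beta(mk(m), mk(u)).data.iloc[0, 0]
        up_m = compute_beta(mk(m + dm), mk(u)).data.iloc[0, 0]
        up_u = compute_beta(mk(m), mk(u + dm)).data.iloc[0, 0]
        assert up_m >= base - 1e-12
        assert up_u <= base + 1e-12


def qp_oracle(a_mat, y, constraint):
    """Exhaustive active-set solver for min ||A w - y||^2, w >= 0 and
    sum(w) = 1 (simplex) or <= 1 (sub_simplex): enumerate every support set,
    solve the corresponding equality-constrained least squares via KKT, keep
    feasible candidates, return the best."""
    n_types = a_mat.shape[1]
    best_obj, best_w = np.inf, None
    for r in range(1, n_types + 1):
        for support in itertools.combinations(range(n_types), r):
            a_s = a_mat[:, support]
            for equality in ([True] if constraint == "simplex" else [True, False]):
                if equality:
                    # KKT: [2A'A  1; 1' 0] [w; lam] = [2A'y; 1]
                    kkt = np.zeros((r + 1, r + 1))
                    kkt[:r, :r] = 2 * a_s.T @ a_s
                    kkt[:r, r] = 1.0
                    kkt[r, :r] = 1.0
                    rhs = np.concatenate([2 * a_s.T @ y, [1.0]])
                    try:
                        sol = np.linalg.solve(kkt, rhs)
                    except np.linalg.LinAlgError:
                        continue
                    w_s = sol[:r]
                else:
                    w_s, *_ = np.linalg.lstsq(a_s, y, rcond=None)
                    if w_s.sum() > 1 + 1e-12:
                        continue
                if (w_s < -1e-10).any():
                    continue
                w = np.zeros(n_types)
                w[list(support)] = np.clip(w_s, 0, None)
                obj = float(np.sum((a_mat @ w - y) ** 2))
                if obj < best_obj - 1e-15:
                    best_obj, best_w = obj, w
    return best_w, best_obj


class TestDeconvolution:
    def _reference(self, seed=3, n_types=6, n_probes=80):
        rng = np.random.default_rng(seed)
        profiles = pd.DataFrame(
            rng.uniform(0.05, 0.95, size=(n_types, n_probes)),
            index=[f"cell{c}" for c in range(n_types)],
            columns=[f"cg{j}" for j in range(n_probes)],
        )
        return CellReference(profiles)

    def test_vertex_recovery(self):
        ref = self._reference()
        sample = BetaMatrix(ref.profiles.iloc[[0]].T.rename(columns={"cell0": "s0"}))
        res = estimate_cell_proportions(sample, ref, "simplex", probes=ref.probe_ids)
        np.testing.assert_allclose(
            res.proportions.loc["s0"], [1, 0, 0, 0, 0, 0], atol=1e-6
        )

    def test_even_mixture_recovery(self):
        ref = self._reference()
        mix = 0.5 * ref.profiles.iloc[0] + 0.5 * ref.profiles.iloc[1]
        sample = BetaMatrix(mix.to_frame("s0"))
        res = estimate_cell_proportions(sample, ref, "simplex", probes=ref.probe_ids)
        np.testing.assert_allclose(
            res.proportions.loc["s0"], [0.5, 0.5, 0, 0, 0, 0], atol=1e-6
        )

    @pytest.mark.parametrize("constraint", ["simplex", "sub_simplex"])
    def test_noisy_mixtures_match_qp_oracle(self, constraint):
        ref = self._reference(seed=9)
        rng = np.random.default_rng(31)
        n_samples = 50
        truth = rng.dirichlet(np.ones(6) * 2.0, size=n_samples)
        a_mat = ref.profiles.to_numpy().T
        obs = truth @ ref.profiles.to_numpy() + rng.normal(0, 0.02, size=(n_samples, 80))
        obs = np.clip(obs, 0, 1)
        samples = BetaMatrix(
            pd.DataFrame(obs.T, index=ref.probe_ids, columns=[f"s{i}" for i in range(n_samples)])
        )
        res = estimate_cell_proportions(samples, ref, constraint, probes=ref.probe_ids)
        rmse = np.sqrt(((res.proportions.to_numpy() - truth) ** 2).mean())
        assert rmse < 0.05
        for i in range(n_samples):
            _, oracle_obj = qp_oracle(a_mat, obs[i], constraint)
            assert res.objectives.iloc[i] <= oracle_obj + 1e-6

    def test_objective_not_worse_than_truth(self):
        ref = self._reference(seed=12)
        rng = np.random.default_rng(8)
        truth = rng.dirichlet(np.ones(6), size=10)
        obs = truth @ ref.profiles.to_numpy() + rng.normal(0, 0.02, size=(10, 80))
        obs = np.clip(obs, 0, 1)
        samples = BetaMatrix(
            pd.DataFrame(obs.T, index=ref.probe_ids, columns=[f"s{i}" for i in range(10)])
        )
        res = estimate_cell_proportions(samples, ref, "simplex", probes=ref.probe_ids)
        a_mat = ref.profiles.to_numpy().T
        for i in range(10):
            truth_obj = np.sum((a_mat @ truth[i] - obs[i]) ** 2)
            assert res.objectives.iloc[i] <= truth_obj + 1e-10

    def test_collinear_reference_rejected(self):
        ref = self._reference()
        profiles = ref.profiles.copy()
        profiles.iloc[1] = profiles.iloc[0]
        bad = CellReference(profiles)
        sample = BetaMatrix(profiles.iloc[[0]].T.rename(columns={"cell0": "s0"}))
        with pytest.raises(ValueError, match="cell0.*cell1"):
            estimate_cell_proportions(sample, bad, "simplex", probes=bad.probe_ids)

    def test_probe_panel_selection_prefers_discriminating(self):
        rng = np.random.default_rng(4)
        flat = np.full((4, 30), 0.5)
        flat[:, :10] = rng.uniform(0, 1, size=(4, 10))  # only first 10 vary
        ref = CellReference(
            pd.DataFrame(flat, index=list("abcd"), columns=[f"cg{j}" for j in range(30)])
        )
        panel = select_deconvolution_probes(ref, k=10)
        assert set(panel) == {f"cg{j}" for j in range(10)}
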