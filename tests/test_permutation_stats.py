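"""The single-subject permutation test, BH-FDR, and calibration."""
import numpy as np
import pytest

from painconn import (
    PermutationConfig,
    SimulationSpec,
    ValidationError,
    calibration_experiment,
    edge_perm_test,
    fdr_bh,
    simulate_edge_level,
    test_patient as patient_test,
)


def brute_force_perm_p(controls, patient):
    """Enumerate all n+1 label assignments directly from the definition."""
    pooled = list(controls) + [patient]
    n = len(controls)
    obs = abs(np.mean(controls) - patient)
    stats = []
    for i in range(n + 1):
        rest = pooled[:i] + pooled[i + 1:]
        stats.append(abs(np.mean(rest) - pooled[i]))
    return obs, sum(s >= obs for s in stats) / (n + 1)


def brute_force_bh(p, alpha):
    """Step-up BH from the definition: adj_i = min_{j>=i} m p_(j)/j, capped at 1."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = np.minimum.accumulate((m * p[order] / np.arange(1, m + 1))[::-1])[::-1]
    adj_sorted = np.minimum(adj_sorted, 1.0)
    adj = np.empty(m)
    adj[order] = adj_sorted
    return adj, adj <= alpha


EXACT = PermutationConfig(method="exact")


class TestEdgePermTest:
    def test_exact_enumeration_zero_controls_unit_patient(self):
        obs, p = edge_perm_test([0.0, 0.0, 0.0, 0.0], 1.0, EXACT)
        assert obs == 1.0
        assert p == pytest.approx(1 / 5)

    def test_all_values_tie_gives_p_one(self):
        obs, p = edge_perm_test([0.4, 0.4, 0.4], 0.4, EXACT)
        assert obs == 0.0
        assert p == 1.0

    def test_pooled_mean_patient_is_least_extreme(self):
        obs, p = edge_perm_test([1, 2, 3, 4, 5], 3.0, EXACT)
        assert p == 1.0

    def test_exact_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            controls = rng.normal(size=rng.integers(2, 8))
            patient = rng.normal()
            obs, p = edge_perm_test(controls, patient, EXACT)
            obs_bf, p_bf = brute_force_perm_p(list(controls), patient)
            assert obs == pytest.approx(obs_bf, abs=1e-12)
            assert p == pytest.approx(p_bf, abs=1e-12)

    def test_exact_p_lies_on_the_achievable_grid(self):
        rng = np.random.default_rng(8)
        n = 6
        for _ in range(30):
            _, p = edge_perm_test(rng.normal(size=n), rng.normal(), EXACT)
            assert p * (n + 1) == pytest.approx(round(p * (n + 1)), abs=1e-9)
            assert p >= 1 / (n + 1)

    def test_monte_carlo_converges_to_exact(self):
        """|MC - exact| < 0.01 at n_perm=100,000 on every edge of a 5-control toy."""
        rng = np.random.default_rng(12)
        cfg = PermutationConfig(n_perm=100_000, rng_seed=99)
        for edge in range(12):
            controls = rng.normal(size=5)
            patient = rng.normal() + rng.choice([0.0, 1.0])
            _, p_exact = edge_perm_test(controls, patient, EXACT)
            _, p_mc = edge_perm_test(controls, patient, cfg,
                                     rng=np.random.default_rng(1000 + edge))
            assert abs(p_mc - p_exact) < 0.01

    def test_invariant_to_control_order_and_constant_shift(self):
        controls = np.array([0.1, -0.4, 0.9, 0.3, 0.0])
        patient = 1.2
        _, p0 = edge_perm_test(controls, patient, EXACT)
        _, p1 = edge_perm_test(controls[::-1], patient, EXACT)
        _, p2 = edge_perm_test(controls + 5.0, patient + 5.0, EXACT)
        assert p0 == p1 == p2

    def test_plus_one_rule_never_returns_zero(self):
        cfg = PermutationConfig(n_perm=50, rng_seed=0, p_rule="plus_one")
        _, p = edge_perm_test(np.zeros(10) + np.arange(10), 1e6, cfg)
        assert p >= 1 / 51

    def test_too_few_controls_raises(self):
        with pytest.raises(ValidationError):
            edge_perm_test([1.0], 0.0, EXACT)


class TestFdrBH:
    def test_all_rejected_when_ps_below_steps(self):
        adj, reject = fdr_bh(np.array([0.01, 0.02, 0.03, 0.04]), alpha=0.05)
        assert reject.all()
        np.testing.assert_allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_flat_half_ps_not_rejected(self):
        adj, reject = fdr_bh(np.array([0.5, 0.5, 0.5]), alpha=0.05)
        assert not reject.any()
        np.testing.assert_allclose(adj, 0.5)

    def test_single_p_is_identity(self):
        adj, reject = fdr_bh(np.array([0.04]), alpha=0.05)
        assert adj[0] == pytest.approx(0.04)
        assert reject[0]

    def test_matches_brute_force_oracle_on_random_vectors(self):
        rng = np.random.default_rng(17)
        for _ in range(1000):
            m = rng.integers(1, 51)
            p = rng.uniform(size=m) ** rng.choice([1, 2, 4])
            adj, reject = fdr_bh(p, alpha=0.05)
            adj_bf, reject_bf = brute_force_bh(p, 0.05)
            np.testing.assert_allclose(adj, adj_bf, atol=1e-12)
            np.testing.assert_array_equal(reject, reject_bf)

    def test_adjusted_never_below_raw(self):
        rng = np.random.default_rng(18)
        p = rng.uniform(size=200)
        adj, _ = fdr_bh(p, alpha=0.05)
        assert (adj >= p - 1e-15).all()

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValidationError):
            fdr_bh(np.array([0.5, 1.5]))


def _small_cohort(delta=0.0, injected=(), seed=0, n_controls=20,
                  n_seeds=6, n_atlas=8, n_patients=1):
    spec = SimulationSpec(n_controls=n_controls, n_patients=n_patients,
                          n_seeds=n_seeds, n_atlas=n_atlas,
                          injected_edges=injected, delta=delta, rng_seed=seed)
    return simulate_edge_level(spec)


class TestTestPatient:
    def test_patient_at_control_mean_has_no_signal(self):
        from painconn import CohortStack, ConnectivityMatrix

        stack, _, _ = _small_cohort(seed=3)
        mean_patient = ConnectivityMatrix("mean", stack.values.mean(axis=0), "fisher_z")
        res = patient_test(stack, mean_patient, EXACT)
        np.testing.assert_allclose(res.observed_diff, 0.0, atol=1e-12)
        assert not res.significant.any()
        assert (res.p_raw == 1.0).all()

    def test_injected_edges_attain_minimum_achievable_p(self):
        """delta = 5 sigma_between with 20 controls: every injected edge at p = 1/21."""
        injected = ((0, 0), (1, 3), (2, 5), (3, 7), (4, 2), (5, 6), (0, 4), (1, 1), (2, 2), (3, 3))
        stack, [patient], truth = _small_cohort(delta=0.5, injected=injected, seed=5)
        res = patient_test(stack, patient, EXACT)
        for si, ai in truth.injected[patient.subject_id]:
            assert res.p_raw[si, ai] == pytest.approx(1 / 21, abs=1e-12)

    def test_fixed_seed_is_deterministic(self):
        stack, [patient], _ = _small_cohort(seed=6)
        cfg = PermutationConfig(n_perm=300, rng_seed=123)
        a = patient_test(stack, patient, cfg)
        b = patient_test(stack, patient, cfg)
        np.testing.assert_array_equal(a.p_raw, b.p_raw)
        np.testing.assert_array_equal(a.significant, b.significant)

    def test_shape_mismatch_raises(self):
        from painconn import ConnectivityMatrix

        stack, _, _ = _small_cohort(seed=7)
        bad = ConnectivityMatrix("bad", np.zeros((3, 3)), "fisher_z")
        with pytest.raises(ValidationError, match="shape"):
            patient_test(stack, bad, EXACT)

    def test_pooled_null_resolves_below_per_edge_floor(self):
        injected = ((0, 0), (5, 7))
        stack, [patient], _ = _small_cohort(delta=0.5, injected=injected, seed=8)
        pooled = PermutationConfig(method="exact", null_model="pooled_edges")
        res = patient_test(stack, patient, pooled)
        assert res.p_raw[0, 0] < 1 / 21
        assert (res.p_adj >= res.p_raw - 1e-15).all()
        assert ((res.p_adj <= 0.05) == res.significant).all()

    def test_monte_carlo_substreams_match_exact_closely(self):
        stack, [patient], _ = _small_cohort(seed=9, n_controls=5, n_seeds=3, n_atlas=4)
        exact = patient_test(stack, patient, EXACT)
        mc = patient_test(stack, patient,
                          PermutationConfig(n_perm=100_000, rng_seed=11))
        assert np.max(np.abs(mc.p_raw - exact.p_raw)) < 0.01


class TestCalibration:
    def test_null_flagged_proportion_controlled(self):
        spec = SimulationSpec(n_controls=20, n_patients=0, n_seeds=6, n_atlas=8,
                              delta=0.0, rng_seed=10)
        cfg = PermutationConfig(n_perm=200, alpha=0.05, rng_seed=1)
        report = calibration_experiment(spec, cfg, n_replicates=10)
        assert report["mean_flagged_proportion"] <= 0.05

    def test_flagged_proportion_monotone_in_alpha(self):
        spec = SimulationSpec(n_controls=8, n_patients=0, n_seeds=4, n_atlas=5,
                              delta=0.0, rng_seed=14)
        props = []
        for alpha in (0.01, 0.10):
            cfg = PermutationConfig(n_perm=200, alpha=alpha, rng_seed=2)
            props.append(calibration_experiment(spec, cfg, n_replicates=8)[
                "mean_flagged_proportion"
            ])
        assert props[0] <= props[1]

    def test_requires_null_spec(self):
        spec = SimulationSpec(n_controls=5, n_seeds=2, n_atlas=2, delta=0.3,
                              injected_edges=((0, 0),), rng_seed=0)
        with pytest.raises(ValidationError, match="delta"):
            calibration_experiment(spec, EXACT, n_replicates=2)
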