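"""The Euler–Maruyama integrator and attractor location."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

import panfate as pf
from panfate.engine import NoiseModel, em_step
from panfate.network import GENE_INDEX, N_STATE, N_TF


class TestEmStep:
    def test_zero_noise_is_forward_euler(self, kernel):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 3, N_STATE)
        drift_fn = kernel.drift
        out = em_step(x, drift_fn, NoiseModel(0.0), 0.01, rng)
        euler = np.maximum(x + kernel.drift(x[None])[0] * 0.01, 0.0)
        np.testing.assert_array_equal(out, euler)

    def test_output_nonnegative(self):
        rng = np.random.default_rng(2)
        drift_fn = lambda x: -50.0 * np.ones_like(x)
        x = np.full(N_STATE, 0.01)
        out = em_step(x, drift_fn, NoiseModel(0.1), 0.05, rng)
        assert np.all(out >= 0)

    def test_ou_stationary_variance_is_D_over_k(self):
        # pure decay (production 0, k=1) with <xi xi'> = 2 D delta:
        # stationary variance D/k; clipping disabled for the closed form
        D, dt, n_steps = 0.05, 0.01, 100_000
        rng = np.random.default_rng(7)
        drift_fn = lambda x: -x
        x = np.zeros((1, N_STATE))
        noise = NoiseModel(D)
        burn = 2_000
        acc = []
        for s in range(n_steps + burn):
            x = em_step(x, drift_fn, noise, dt, rng, clip=False)
            if s >= burn:
                acc.append(x[0, 0])
        var = np.var(acc)
        assert var == pytest.approx(D, rel=0.05)

    def test_nonfinite_drift_names_gene(self, kernel):
        rng = np.random.default_rng(0)
        bad = lambda x: np.full_like(x, np.nan)
        with pytest.raises(FloatingPointError, match="Hnf6"):
            em_step(np.zeros(N_STATE), bad, NoiseModel(0.0), 0.01, rng)


class TestSimulateCell:
    def test_constant_at_fixed_point_without_noise(self, network, params, attractors):
        tr = pf.simulate_cell(
            network, params.with_(D=0.0), initial=attractors["beta"], t_end=20.0)
        np.testing.assert_allclose(tr.states[-1, :N_TF], tr.states[0, :N_TF], atol=1e-4)

    def test_hnf6_starts_high_and_decays(self, network, params):
        tr = pf.simulate_cell(network, params, seed=11)
        h = tr.gene("Hnf6")
        assert h[0] == pytest.approx(2.2)
        assert h[-1] < 0.1 * h[0]

    def test_same_seed_is_bitwise_identical(self, network, params):
        p = params.with_(t_end=30.0)
        a = pf.simulate_cell(network, p, seed=4, t_end=30.0)
        b = pf.simulate_cell(network, p, seed=4, t_end=30.0)
        np.testing.assert_array_equal(a.states, b.states)

    def test_schedule_beyond_horizon_rejected(self, network, params):
        sched = pf.overexpress(["Ngn3"], window=(50.0, 60.0))
        with pytest.raises(ValueError):
            pf.simulate_cell(network, params, sched, t_end=40.0)

    def test_unknown_gene_in_schedule_rejected(self):
        with pytest.raises(KeyError):
            pf.knockout("NotAGene")


class TestSimulateEnsemble:
    def test_deterministic_ensemble_has_identical_members(self, network, params):
        ens = pf.simulate_ensemble(
            5, network, params.with_(D=0.0), master_seed=0, t_end=50.0)
        ref = ens.trajectories[0].states
        for tr in ens.trajectories[1:]:
            np.testing.assert_array_equal(tr.states, ref)

    def test_single_cell_ensemble_matches_simulate_cell(self, network, params):
        ens = pf.simulate_ensemble(1, network, params, master_seed=9, t_end=20.0)
        child = np.random.SeedSequence(9).spawn(1)[0]
        tr = pf.simulate_cell(network, params, seed=child, t_end=20.0)
        np.testing.assert_array_equal(ens.trajectories[0].states, tr.states)

    def test_members_share_initial_condition(self, small_ensemble):
        starts = {tuple(t.states[0]) for t in small_ensemble.trajectories}
        assert len(starts) == 1

    def test_cell_ids_unique(self, small_ensemble):
        ids = [t.cell_id for t in small_ensemble.trajectories]
        assert len(set(ids)) == len(ids)

    def test_terminal_marker_patterns_diversify(self, dev_ensemble, thresholds):
        n, _ = pf.count_attractors(dev_ensemble, thresholds)
        assert n >= 2


class TestDtConvergence:
    def test_deterministic_path_converges_to_ode_oracle(self, network, kernel, params):
        # reference: high-order adaptive integration of the same vector field
        x0 = pf.progenitor_state(params)
        rhs = lambda t, y: kernel.drift(np.maximum(y, 0.0)[None])[0]
        ref = solve_ivp(rhs, (0, 20.0), x0, rtol=1e-10, atol=1e-12, dense_output=True)
        errs = []
        for dt in (0.02, 0.005):
            p = params.with_(D=0.0, dt=dt, save_interval=1.0)
            tr = pf.simulate_cell(network, p, t_end=20.0)
            exact = ref.sol(tr.times).T
            errs.append(np.max(np.abs(tr.states[:, :N_TF] - exact[:, :N_TF])))
        assert errs[1] < errs[0]
        assert errs[1] < 0.01  # O(dt) accuracy at dt=0.005


class TestFindAttractor:
    def test_idempotent_on_converged_state(self, network, params, attractors):
        res = pf.find_attractor(network, params, attractors["beta"])
        assert res.converged and res.residual < 1e-6
        np.testing.assert_allclose(res.state[:N_TF], attractors["beta"][:N_TF], atol=1e-4)

    def test_beta_attractor_marker_logic(self, attractors, thresholds):
        beta = attractors["beta"]
        for g in ("MafA", "Pdx1", "Pax6"):
            assert beta[GENE_INDEX[g]] > thresholds[g]
        for g in ("Ptf1a", "DeltaGene", "Brn4", "Ngn3", "Pax4"):
            assert beta[GENE_INDEX[g]] < thresholds[g]

    def test_nonconvergence_is_flagged_not_raised(self, network, params):
        far = np.full(N_STATE, 3.0)
        res = pf.find_attractor(network, params, far, t_max=0.05)
        assert not res.converged


class TestTrajectoryIO:
    def test_csv_round_trip_is_lossless(self, small_ensemble, tmp_path, network, params):
        df = pf.ensemble_to_frame(small_ensemble)
        path = tmp_path / "traj.csv"
        df.to_csv(path, index=False)
        import pandas as pd

        back = pf.frame_to_ensemble(pd.read_csv(path), network, params)
        assert len(back) == len(small_ensemble)
        np.testing.assert_allclose(
            back.states_array(), small_ensemble.states_array(), rtol=0, atol=1e-12)
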