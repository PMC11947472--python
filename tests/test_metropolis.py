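"""Metropolis sampler: proposals, constraints, acceptance, trajectories."""

import numpy as np
import pytest

import cellmatch as cm
from cellmatch.energetics import params_from_gamma
from cellmatch.errors import CellMatchError, ConfigurationError, InsufficientDataError
from cellmatch.metropolis import (
    MCMCSettings,
    MCMCTrajectory,
    acceptance_probability,
    propose_move,
    run,
    steady_state_mismatch,
    step,
)


class TestProposeMove:
    def test_two_cell_rows_propose_only_middle_vertex(self):
        cfg = cm.make_tissue("all-T", 2, rng=0)
        rng = np.random.default_rng(1)
        for _ in range(200):
            row, i, _ = propose_move(cfg, rng, 0.05)
            assert i == 1 and row in (1, 2)

    def test_vertex_selection_is_uniform(self):
        """Selection frequency 1/(2(N-1)) per interior vertex (binomial 3-sigma)."""
        cfg = cm.make_tissue("TTTTSS", 6, rng=0)
        rng = np.random.default_rng(2)
        n_draw = 50_000
        counts = np.zeros((2, cfg.n_cells + 1))
        for _ in range(n_draw):
            row, i, _ = propose_move(cfg, rng, 0.05)
            counts[row - 1, i] += 1
        assert counts[:, 0].sum() == 0 and counts[:, -1].sum() == 0
        p = 1 / (2 * (cfg.n_cells - 1))
        sigma = np.sqrt(n_draw * p * (1 - p))
        interior = counts[:, 1:-1].ravel()
        assert (np.abs(interior - n_draw * p) < 3.5 * sigma).all()

    def test_displacement_std_matches_deltaX(self):
        cfg = cm.make_tissue("all-T", 4, rng=0)
        rng = np.random.default_rng(3)
        dxs = np.array([propose_move(cfg, rng, 0.05)[2] for _ in range(100_000)])
        assert abs(dxs.std() - 0.05) / 0.05 < 0.01
        assert abs(dxs.mean()) < 3 * 0.05 / np.sqrt(len(dxs))

    def test_single_cell_rows_have_no_movable_vertex(self):
        cfg = cm.make_tissue("all-T", 1, rng=0)
        with pytest.raises(CellMatchError):
            propose_move(cfg, np.random.default_rng(0), 0.05)


class TestMoveAllowed:
    def test_examples(self):
        cfg = cm.make_tissue("all-T", 4, {"T": cm.TypeLengthParams(1.0, 0.0)}, rng=0)
        assert cm.move_allowed(cfg, 1, 2, 0.0)
        assert not cm.move_allowed(cfg, 1, 2, 1.5)   # beyond right cell (length 1)
        assert not cm.move_allowed(cfg, 1, 2, -1.5)  # beyond left cell
        assert cm.move_allowed(cfg, 1, 2, 0.99)
        assert cm.move_allowed(cfg, 1, 2, 1.0)       # boundary: exactly zero-length

    def test_end_vertices_never_allowed(self):
        cfg = cm.make_tissue("all-T", 4, rng=0)
        assert not cm.move_allowed(cfg, 1, 0, 0.01)
        assert not cm.move_allowed(cfg, 1, cfg.n_cells, 0.01)


class TestAcceptanceProbability:
    def test_downhill_always_accepted(self):
        assert acceptance_probability(-1.0, 0.1) == 1.0
        assert acceptance_probability(0.0, 0.1) == 1.0

    def test_at_temperature_scale(self):
        assert acceptance_probability(0.1, 0.1) == pytest.approx(np.exp(-1))

    def test_large_barrier_vanishes(self):
        assert acceptance_probability(1e4, 0.1) < 1e-300

    def test_invalid_temperature(self):
        with pytest.raises(ConfigurationError):
            acceptance_probability(1.0, 0.0)


class TestStep:
    def test_greedy_descent_at_low_temperature(self):
        """E0 -> 0: accepted moves never raise the energy."""
        cfg = cm.make_tissue("TTTTSS", 12, rng=1)
        p = params_from_gamma(1.0)
        s = MCMCSettings(E0=1e-12, deltaX=0.05)
        rng = np.random.default_rng(5)
        e = cm.total_energy(cfg, p)
        for _ in range(3000):
            cfg, accepted = step(cfg, p, s, rng)
            if accepted:
                e_new = cm.total_energy(cfg, p)
                assert e_new <= e + 1e-9
                e = e_new

    def test_rejected_step_leaves_config_unchanged(self):
        cfg = cm.make_tissue("TTTTSS", 6, rng=1)
        p = params_from_gamma(5.0)
        s = MCMCSettings(E0=1e-12, deltaX=5.0)  # huge moves, mostly rejected
        rng = np.random.default_rng(6)
        before = cfg.vertices.copy()
        _, accepted = step(cfg, p, s, rng)
        if not accepted:
            np.testing.assert_array_equal(cfg.vertices, before)

    def test_span_and_order_preserved(self):
        cfg = cm.make_tissue("TTTTSS", 12, rng=2)
        p = params_from_gamma(0.5)
        rng = np.random.default_rng(7)
        span0 = cfg.span
        s = MCMCSettings()
        for _ in range(2000):
            cfg, _ = step(cfg, p, s, rng)
        assert cfg.span == span0
        assert (np.diff(cfg.vertices, axis=1) >= 0).all()


class TestRun:
    def test_identical_seeds_identical_trajectories(self, cv10_factory):
        cfg = cv10_factory(1)
        p = params_from_gamma(1.0)
        s = MCMCSettings(seed=42, n_steps=120_000)
        t1 = run(cfg, p, s)
        t2 = run(cfg, p, s)
        np.testing.assert_array_equal(t1.tissue_mismatch, t2.tissue_mismatch)
        np.testing.assert_array_equal(t1.final_config.vertices, t2.final_config.vertices)

    def test_input_configuration_not_mutated(self, cv10_factory):
        cfg = cv10_factory(1)
        before = cfg.vertices.copy()
        run(cfg, params_from_gamma(1.0), MCMCSettings(seed=0, n_steps=50_000))
        np.testing.assert_array_equal(cfg.vertices, before)

    def test_symmetric_single_type_stays_near_zero(self):
        """gamma = 0, zero-variance tissue: mismatch stays at the fluctuation
        scale set by deltaX over the cell length."""
        params = {"T": cm.TypeLengthParams(5.0, 0.0)}
        cfg = cm.make_tissue("all-T", 12, params, rng=0)
        p = cm.AdhesionParameters(K=1.0)
        traj = run(cfg, p, MCMCSettings(seed=1, n_steps=300_000, early_stop=False))
        # thermal scale: boundary offsets ~ sqrt(E0/2K) = 0.22 um on 5 um cells
        assert traj.tissue_mismatch.max() < 0.25
        mean, _ = steady_state_mismatch(traj)
        assert mean < 0.1

    def test_acceptance_rate_decreases_with_deltaX(self, cv10_factory):
        cfg = cv10_factory(2)
        p = params_from_gamma(1.0)
        rates = [
            run(cfg, p, MCMCSettings(seed=3, n_steps=60_000, deltaX=dx,
                                     early_stop=False)).acceptance_rate
            for dx in (0.02, 0.1, 0.5, 2.0)
        ]
        assert all(a >= b for a, b in zip(rates, rates[1:]))

    def test_recorded_energy_tracks_full_recompute(self, cv10_factory):
        """The kernel's incremental energy is validated against a full
        recomputation at the end of every run (raises on drift)."""
        cfg = cv10_factory(3)
        traj = run(cfg, params_from_gamma(2.0), MCMCSettings(seed=4, n_steps=200_000))
        assert np.isfinite(traj.total_energy).all()
        assert traj.total_energy[-1] == pytest.approx(
            cm.total_energy(traj.final_config, params_from_gamma(2.0)), abs=1e-6
        )


class TestSteadyState:
    def _traj(self, series):
        series = np.asarray(series, dtype=float)
        return MCMCTrajectory(
            steps=np.arange(len(series)), tissue_mismatch=series,
            total_energy=np.zeros_like(series), acceptance_rate=0.5,
            final_config=None, converged=True, n_steps_run=len(series),
        )

    def test_constant_series(self):
        mean, sem = steady_state_mismatch(self._traj([0.3] * 50))
        assert (mean, sem) == (0.3, 0.0)

    def test_full_tail_mean(self):
        mean, _ = steady_state_mismatch(self._traj([0.2, 0.4]), tail_fraction=1.0)
        assert mean == pytest.approx(0.3)

    def test_sem_shrinks_with_sample_size(self):
        rng = np.random.default_rng(0)
        short = steady_state_mismatch(self._traj(rng.normal(0.5, 0.05, 200)), 1.0)[1]
        long = steady_state_mismatch(self._traj(rng.normal(0.5, 0.05, 20_000)), 1.0)[1]
        assert long < short / 5  # ~ 1/sqrt(100) shrinkage for white noise

    def test_empty_trajectory_rejected(self):
        with pytest.raises((InsufficientDataError, ConfigurationError)):
            steady_state_mismatch(self._traj([]), tail_fraction=0.5)
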