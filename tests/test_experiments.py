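"""Ensemble orchestration, genotype mapping, gamma inference, defects."""

import numpy as np
import pytest

import cellmatch as cm
from cellmatch import experiments as ex
from cellmatch.errors import ConfigurationError
from cellmatch.geometry import TypeLengthParams

SMALL = {"S": TypeLengthParams(4.0, 0.4), "T": TypeLengthParams(5.0, 0.5)}
FAST = cm.MCMCSettings(n_steps=150_000)


class TestRunEnsemble:
    def test_single_replicate(self):
        fac = ex.tissue_factory("TTTTSS", 12, SMALL)
        res = ex.run_ensemble(fac, cm.params_from_gamma(1.0), FAST, n_replicates=1,
                              master_seed=5)
        assert res.n_replicates == 1
        assert res.mean == res.mismatches[0]
        assert res.sem == 0.0

    def test_seeds_disjoint_and_reproducible(self):
        fac = ex.tissue_factory("TTTTSS", 12, SMALL)
        a = ex.run_ensemble(fac, cm.params_from_gamma(1.0), FAST, 3, master_seed=9)
        b = ex.run_ensemble(fac, cm.params_from_gamma(1.0), FAST, 3, master_seed=9)
        assert len(set(a.replicate_seeds)) == 3
        np.testing.assert_array_equal(a.mismatches, b.mismatches)

    def test_gamma_zero_tracks_initial_level(self):
        """Without adhesion the steady state sits at the geometric level plus
        a small thermal broadening; it never drops below the initial value
        systematically (the energy is symmetric in the two rows)."""
        fac = ex.tissue_factory("all-T", 12, SMALL)
        res = ex.run_ensemble(fac, cm.AdhesionParameters(K=1.0),
                              cm.MCMCSettings(n_steps=400_000), 12, master_seed=3)
        init = res.initial_mismatches.mean()
        assert res.mean >= init - 2 * res.sem
        assert res.mean - init < 0.1


class TestSweepSize:
    def test_zero_variance_gives_zero_everywhere(self):
        params = {"T": TypeLengthParams(5.0, 0.0), "S": TypeLengthParams(4.0, 0.0)}
        df = ex.sweep_size([2, 6, 12], length_params=params, n_replicates=3)
        assert (df["mean"] == 0.0).all()

    def test_small_sizes_rejected(self):
        with pytest.raises(ConfigurationError):
            ex.sweep_size([1], length_params=SMALL)

    def test_n2_matches_conditional_gaussian_oracle(self):
        """The N = 2 initial mismatch agrees with an independent construction
        that replaces rejection sampling by the exact Gaussian conditional of
        row 2 given the equal-total constraint."""
        n_mc = 4000
        rng = np.random.default_rng(123)
        mu, sd = 5.0, 0.5
        vals = np.empty(n_mc)
        for k in range(n_mc):
            a = rng.normal(mu, sd, 2)
            s = a.sum()
            # b | b1+b2 = s is Gaussian: b1 ~ N(mu + (s - 2 mu)/2, sd^2/2)
            b1 = rng.normal(mu + (s - 2 * mu) / 2, sd / np.sqrt(2))
            d = abs(a[0] - b1)
            # sister-pair mismatch of the two-cell system with middle offset d
            pair1 = 0.5 * d / max(a[0], b1)
            pair2 = 0.5 * d / max(s - a[0], s - b1)
            vals[k] = 0.5 * (pair1 + pair2)
        oracle = vals.mean()
        oracle_sem = vals.std(ddof=1) / np.sqrt(n_mc)
        m = ex.initial_mismatches(2, "all-T", {"T": TypeLengthParams(mu, sd)},
                                  n_replicates=400, master_seed=1)
        sem = m.std(ddof=1) / np.sqrt(len(m))
        assert abs(m.mean() - oracle) < 3.5 * np.hypot(sem, oracle_sem)


class TestGenotypeMapping:
    def test_wildtype_sums_components(self):
        spec = ex.GenotypeSpec("WT", gamma_fas3=0.25, gamma_tenm=0.25)
        pattern, g, params = ex.genotype_to_params(spec)
        assert pattern == "TTTTSS" and g == 0.5
        assert cm.gamma(params) == pytest.approx(0.5)

    @pytest.mark.parametrize(
        "name, expected_gamma, expected_pattern",
        [
            ("svp_null", 0.0, "all-T"),
            ("double_null", 0.0, "TTTTSS"),
            ("fas3_null", 0.25, "TTTTSS"),
            ("tenm_null", 0.35, "TTTTSS"),
            ("svp_gal4_fas3_oe", 0.25, "TTTTSS"),
            ("svp_gal4_fas3_rnai", 0.6, "TTTTSS"),
        ],
    )
    def test_mutant_rules(self, name, expected_gamma, expected_pattern):
        spec = ex.GenotypeSpec(name, gamma_fas3=0.35, gamma_tenm=0.25)
        pattern, g, _ = ex.genotype_to_params(spec)
        assert g == pytest.approx(expected_gamma)
        assert pattern == expected_pattern

    def test_sum_rule(self):
        """gamma(WT) = gamma(fas3_null) + gamma(tenm_null), exactly."""
        kw = dict(gamma_fas3=0.31, gamma_tenm=0.17)
        g_wt = ex.genotype_to_params(ex.GenotypeSpec("WT", **kw))[1]
        g_f = ex.genotype_to_params(ex.GenotypeSpec("fas3_null", **kw))[1]
        g_t = ex.genotype_to_params(ex.GenotypeSpec("tenm_null", **kw))[1]
        assert g_wt == g_f + g_t

    def test_unknown_genotype(self):
        with pytest.raises(ConfigurationError):
            ex.GenotypeSpec("quadruple_null")


class TestInferGamma:
    def _curve(self):
        g = np.array([0.0, 0.25, 0.5, 1.0, 2.0])
        mean = 0.07 + 0.25 * np.exp(-g / 0.3)
        sem = np.full_like(g, 0.005)
        return ex.MasterCurve(gamma=g, mean=mean, sem=sem, mean_isotonic=mean)

    def test_roundtrip_at_grid_node(self):
        curve = self._curve()
        est = ex.infer_gamma(float(curve.mean[2]), 0.0, curve)
        assert est.value == pytest.approx(0.5)
        assert est.flag == "ok"

    def test_bracketing_between_nodes(self):
        curve = self._curve()
        target = 0.5 * (curve.mean[1] + curve.mean[2])
        est = ex.infer_gamma(float(target), 0.0, curve)
        assert 0.25 < est.value < 0.5

    def test_above_curve_clamps_to_zero(self):
        est = ex.infer_gamma(0.9, 0.0, self._curve())
        assert est.value == 0.0 and est.flag == "clamped_zero"

    def test_below_plateau_is_lower_bound(self):
        est = ex.infer_gamma(0.0, 0.0, self._curve())
        assert est.value == 2.0 and est.flag == "lower_bound"

    def test_interval_widens_with_error(self):
        curve = self._curve()
        narrow = ex.infer_gamma(float(curve.mean[2]), 0.001, curve)
        wide = ex.infer_gamma(float(curve.mean[2]), 0.02, curve)
        assert wide.upper - wide.lower > narrow.upper - narrow.lower
        assert narrow.lower <= narrow.value <= narrow.upper

    def test_isotonic_regularisation_restores_monotonicity(self):
        res = [_FakeResult(g, m) for g, m in
               [(0.0, 0.30), (0.25, 0.16), (0.5, 0.17), (1.0, 0.10), (2.0, 0.08)]]
        curve = ex.MasterCurve.from_results(res)
        assert (np.diff(curve.mean_isotonic) <= 1e-12).all()


class _FakeResult:
    def __init__(self, gamma, mean):
        self.gamma = gamma
        self.mean = mean
        self.sem = 0.01


class TestDefects:
    def test_identical_patterns_reduce_to_plain_ensemble(self):
        report = ex.defect_experiment(
            "TTTTSS", "TTTTSS", cm.params_from_gamma(0.5), FAST,
            n_cells=12, length_params=SMALL, n_replicates=2, master_seed=1,
        )
        plain = ex.run_ensemble(ex.tissue_factory("TTTTSS", 12, SMALL),
                                cm.params_from_gamma(0.5), FAST, 2, master_seed=1)
        np.testing.assert_allclose(report.ensemble.mismatches, plain.mismatches)

    def test_adhesion_closes_boundary_offsets(self):
        """A 3-vs-4 Tin sector defect: equilibration at gamma = 0.5 pulls the
        type boundaries together; the gamma = 0 control does not."""
        row1 = "TTTTSS" * 2
        row2 = "TTTSSS" + "TTTTSS"
        settings = cm.MCMCSettings(n_steps=600_000)
        adh = ex.defect_experiment(row1, row2, cm.params_from_gamma(0.5), settings,
                                   n_cells=12, length_params=SMALL,
                                   n_replicates=6, master_seed=2)
        ctrl = ex.defect_experiment(row1, row2, cm.params_from_gamma(0.0), settings,
                                    n_cells=12, length_params=SMALL,
                                    n_replicates=6, master_seed=2)
        gain_adh = adh.boundary_offsets_initial - adh.boundary_offsets_final
        gain_ctrl = ctrl.boundary_offsets_initial - ctrl.boundary_offsets_final
        assert gain_adh.mean() > 0
        assert gain_adh.mean() > gain_ctrl.mean()


class TestSweepTemperature:
    def test_high_temperature_approaches_random_level(self):
        """At E0 >> adhesion scales the steady state returns to the gamma = 0
        level; the trend in E0 is non-decreasing at fixed gamma."""
        fac = ex.tissue_factory("TTTTSS", 12, SMALL)
        p = cm.params_from_gamma(1.0)
        df = ex.sweep_temperature([0.1, 0.5, 5.0], p,
                                  settings=cm.MCMCSettings(n_steps=400_000),
                                  config_factory=fac, n_replicates=8, master_seed=4)
        assert df["mean"].is_monotonic_increasing
        rand = ex.run_ensemble(fac, cm.AdhesionParameters(K=1.0),
                               cm.MCMCSettings(n_steps=400_000, E0=5.0),
                               8, master_seed=4)
        assert abs(df["mean"].iloc[-1] - rand.mean) < 4 * np.hypot(df["sem"].iloc[-1],
                                                                   rand.sem)


class TestStiffnessSweepShape:
    def test_asymmetric_mode_reaches_minimal_state(self):
        """One compliant cell type suffices: with T cells pinned at K = 100,
        varying the S-cell stiffness by orders of magnitude still lets the
        tissue leave its initial mismatch far behind."""
        fac = ex.tissue_factory("TTTTSS", 24, SMALL)
        df = ex.sweep_stiffness([1.0, 100.0, 10_000.0], mode="asymmetric",
                                config_factory=fac, n_replicates=6, master_seed=5)
        assert (df["final_mean"] < 0.6 * df["initial_mean"]).all()

    def test_invalid_mode(self):
        with pytest.raises(ConfigurationError):
            ex.sweep_stiffness([1.0], mode="sideways")
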