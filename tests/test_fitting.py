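"""Estimator checks: chi-square weighting, protocol fits, global fits,
identifiability diagnostics, and recovery invariants."""

import numpy as np
import pytest

import tmfret as tf
from tmfret import fitting, synthetic

from conftest import (
    DONOR_TRUTH,
    INTRA_DISTANCES,
    STANDARD_VARY,
    TOTAL_COUNTS,
    generic_start,
    protocol_global_fit,
)


def _hist(counts, role="decay"):
    grid = tf.TimeGrid(0.05, len(counts))
    return tf.Histogram(grid=grid, counts=np.asarray(counts, float), role=role,
                        acquisition_duration=300.0)


class TestWeightedChiSquare:
    def test_zero_for_perfect_prediction(self):
        obs = _hist(np.arange(2, 12))
        pred = _hist(np.arange(2, 12))
        assert fitting.weighted_chi_square(obs, pred) == 0.0

    def test_single_bin_arithmetic(self):
        obs = _hist([100.0, 100.0])
        pred = _hist([110.0, 100.0])
        assert fitting.weighted_chi_square(obs, pred, window=(0, 0)) == pytest.approx(1.0)

    def test_poisson_counts_give_unit_reduced_chi_square(self):
        rng = np.random.default_rng(7)
        expected = 50.0 + 5000.0 * np.exp(-np.arange(4000) / 800.0)
        obs = _hist(rng.poisson(expected))
        pred = tf.Histogram(grid=obs.grid, counts=expected, role="decay",
                            acquisition_duration=300.0)
        chi2 = fitting.weighted_chi_square(obs, pred)
        assert 0.9 < chi2 / 4000 < 1.1

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError):
            fitting.weighted_chi_square(_hist([1, 2, 3]), _hist([1, 2]))


class TestFitBuffer:
    def test_recovers_two_component_lifetimes(self, grid):
        irf = synthetic.make_irf(grid, seed=0)
        truth = tf.BufferModel(((12000.0, 1.0), (6000.0, 6.0)))
        buf = synthetic.simulate_buffer_histogram(truth, irf, seed=1)
        assert buf.total > 9e5  # high-count regime for tight recovery
        model, fit = fitting.fit_buffer(buf, irf, 2)
        taus = sorted(t for _, t in model.components)
        assert taus[0] == pytest.approx(1.0, rel=0.05)
        assert taus[1] == pytest.approx(6.0, rel=0.05)
        assert 0.8 < fit.redchi < 1.2

    def test_noise_free_buffer_reaches_zero_chi_square(self, grid):
        irf = synthetic.make_irf(grid, seed=0)
        truth = tf.BufferModel(((12000.0, 1.0), (6000.0, 6.0)))
        from tmfret.decay_model import buffer_intensity, reconvolve

        clean = reconvolve(irf, buffer_intensity(truth, grid),
                           np.zeros(grid.n_bins), bkgr_dec=0.5)
        clean = tf.Histogram(grid=grid, counts=clean.counts, role="buffer",
                             acquisition_duration=300.0)
        _, fit = fitting.fit_buffer(clean, irf, 2)
        assert fit.redchi < 1e-3

    def test_flat_buffer_flagged_not_crashed(self, grid):
        irf = synthetic.make_irf(grid, seed=0)
        rng = np.random.default_rng(3)
        flat = tf.Histogram(grid=grid, counts=rng.poisson(20.0, grid.n_bins).astype(float),
                            role="buffer", acquisition_duration=300.0)
        model, fit = fitting.fit_buffer(flat, irf, 2)
        # the fitted exponentials must carry a negligible share of the signal
        # (the flat level goes to bkgr_dec), or the fit is flagged
        exp_counts = sum(a * t for a, t in model.components) / grid.bin_width
        assert fit.flagged or exp_counts < 0.05 * flat.total

    def test_component_count_validated(self, grid):
        irf = synthetic.make_irf(grid, seed=0)
        with pytest.raises(ValueError):
            fitting.fit_buffer(irf, irf, 5)


class TestDonorOnlyProtocol:
    def test_protocol_violation_rejected(self, grid):
        sc = synthetic.make_scenario("donor_only", seed=0, grid=grid,
                                     total_counts=1e5, conditions=[("apo", 0.0)])
        bad = tf.FretParams(f_D=1.0, vary={"R0": True, "tau_D1": True})
        with pytest.raises(ValueError, match="donor-only"):
            fitting.fit_donor_only(sc.decays["apo"], sc.irf, sc.buffer_model, bad)

    def test_recovery_and_chi_square(self, donor_recovery_fits):
        taus = np.array([f.estimates["tau_D1"] for f in donor_recovery_fits])
        alphas = np.array([f.estimates["alpha_D1"] for f in donor_recovery_fits])
        redchis = np.array([f.redchi for f in donor_recovery_fits])
        assert np.all(np.abs(taus - DONOR_TRUTH["tau_D1"]) < 0.3)
        assert np.all(np.abs(alphas - DONOR_TRUTH["alpha_D1"]) < 0.03)
        assert 0.9 < redchis.mean() < 1.1

    def test_mono_exponential_input_degenerate_but_convergent(self, grid):
        sc = synthetic.make_scenario(
            "donor_only", seed=4, grid=grid, total_counts=TOTAL_COUNTS,
            conditions=[("apo", 0.0)], overrides={"alpha_D1": 1.0},
        )
        start = tf.FretParams(
            f_D=1.0, tau_D1=15.0, alpha_D1=0.8, tau_D2=4.0, f_B=1.0, A0=1.0,
            bkgr_dec=1.0,
            vary={n: True for n in
                  ("tau_D1", "alpha_D1", "tau_D2", "shift_irf", "A0", "bkgr_dec")},
        )
        bm, _ = fitting.fit_buffer(sc.buffer_decay, sc.irf, 2)
        fit = fitting.fit_donor_only(sc.decays["apo"], sc.irf, bm, start)
        assert 0.8 < fit.redchi < 1.2
        # nested-model degeneracy: vanishing second fraction or merged lifetimes
        merged = abs(fit.estimates["tau_D1"] - fit.estimates["tau_D2"]) < 1.0
        assert fit.estimates["alpha_D1"] > 0.97 or merged

    def test_noise_free_input_reaches_zero_chi_square(self, grid):
        irf = synthetic.make_irf(grid, seed=9)
        truth = tf.FretParams(f_D=1.0, f_B=0.0, A0=2e4, bkgr_dec=0.5, **DONOR_TRUTH)
        from tmfret.decay_model import fret_intensity, reconvolve

        clean = reconvolve(irf, fret_intensity(truth, grid),
                           np.zeros(grid.n_bins), bkgr_dec=0.5)
        decay = tf.Histogram(grid=grid, counts=clean.counts, role="decay",
                             acquisition_duration=300.0)
        start = truth.replace(
            tau_D1=15.0, alpha_D1=0.8, tau_D2=4.0, A0=1.0,
            vary={n: True for n in
                  ("tau_D1", "alpha_D1", "tau_D2", "shift_irf", "A0", "bkgr_dec")},
        )
        fit = fitting.fit_donor_only(decay, irf, None, start)
        assert fit.redchi < 1e-4


class TestFitDecay:
    def test_protocol_fixing_rules_enforced(self, grid):
        sc = synthetic.make_scenario("intrasubunit", seed=0, grid=grid,
                                     total_counts=1e5, conditions=[("apo", 0.08)])
        bad = generic_start(sc.true_params["apo"])
        bad.vary["R0"] = True
        with pytest.raises(ValueError, match="donor\\+acceptor"):
            fitting.fit_decay(sc.decays["apo"], sc.irf, sc.buffer_model, bad)

    def test_fixed_parameters_never_move(self, intrasubunit_recovery_fits):
        for fit in intrasubunit_recovery_fits:
            for p in fit.params_by_dataset:
                assert p.R0 == 43.5
                assert p.tau_D1 == DONOR_TRUTH["tau_D1"]
                assert p.alpha_D1 == DONOR_TRUTH["alpha_D1"]
                assert p.f_B == 1.0
                assert p.bkgr_irf == 0.0

    def test_single_gaussian_recovery_with_f_a2_pinned(self, grid):
        # f_A2 fixed at 0 and at 1 on one-state data recovers that state
        for f_true, pin in ((0.0, 0.0), (1.0, 1.0)):
            sc = synthetic.make_scenario(
                "intrasubunit", seed=8, grid=grid, total_counts=TOTAL_COUNTS,
                conditions=[("x", f_true)],
            )
            bm, _ = fitting.fit_buffer(sc.buffer_decay, sc.irf, 2)
            vary = dict(STANDARD_VARY)
            vary["f_A2"] = False
            start = generic_start(sc.true_params["x"], vary=vary, f_A2=pin)
            fit = fitting.fit_decay(sc.decays["x"], sc.irf, bm, start)
            which = ("rbar1", "sigma1") if pin == 0.0 else ("rbar2", "sigma2")
            assert fit.estimates[which[0]] == pytest.approx(
                INTRA_DISTANCES[which[0]], abs=0.5
            )
            assert fit.estimates[which[1]] == pytest.approx(
                INTRA_DISTANCES[which[1]], abs=0.5
            )

    def test_recovery_bias_invariant(self, intrasubunit_recovery_fits):
        r1 = np.array([f.estimates["rbar1"] for f in intrasubunit_recovery_fits])
        r2 = np.array([f.estimates["rbar2"] for f in intrasubunit_recovery_fits])
        fa_apo = np.array([f.estimates["f_A2@0"] for f in intrasubunit_recovery_fits])
        fa_sat = np.array([f.estimates["f_A2@1"] for f in intrasubunit_recovery_fits])
        assert abs(r1.mean() - INTRA_DISTANCES["rbar1"]) < 0.5
        assert abs(r2.mean() - INTRA_DISTANCES["rbar2"]) < 0.5
        assert abs(fa_apo.mean() - 0.08) < 0.03
        assert abs(fa_sat.mean() - 0.96) < 0.03

    def test_cost_trace_best_so_far_decreases(self, intrasubunit_recovery_fits):
        trace = intrasubunit_recovery_fits[0].cost_trace
        best = np.minimum.accumulate(trace)
        assert np.all(np.diff(best) <= 0)
        assert best[-1] < trace[0]


class TestFitGlobal:
    def test_two_identical_replicates_match_single_fit(self, grid):
        sc = synthetic.make_scenario("intrasubunit", seed=12, grid=grid,
                                     total_counts=TOTAL_COUNTS,
                                     conditions=[("mid", 0.5)])
        bm, _ = fitting.fit_buffer(sc.buffer_decay, sc.irf, 2)
        start = generic_start(sc.true_params["mid"])
        single = fitting.fit_decay(sc.decays["mid"], sc.irf, bm, start)
        ds = fitting.Dataset(sc.decays["mid"], sc.irf, bm, start)
        spec = fitting.FitSpec(datasets=[ds, ds], sharing=tuple(STANDARD_VARY))
        both = fitting.fit_global(spec)
        for name in ("rbar1", "rbar2", "f_A2", "f_D"):
            assert both.estimates[name] == pytest.approx(
                single.estimates[name], abs=0.05
            )

    def test_requires_two_datasets(self, grid):
        sc = synthetic.make_scenario("intrasubunit", seed=0, grid=grid,
                                     total_counts=1e5, conditions=[("apo", 0.08)])
        ds = fitting.Dataset(sc.decays["apo"], sc.irf, sc.buffer_model,
                             generic_start(sc.true_params["apo"]))
        with pytest.raises(ValueError):
            fitting.fit_global(fitting.FitSpec(datasets=[ds]))

    def test_inconsistent_sharing_rejected(self, grid):
        sc = synthetic.make_scenario("intrasubunit", seed=0, grid=grid,
                                     total_counts=1e5,
                                     conditions=[("a", 0.08), ("b", 0.96)])
        p_free = generic_start(sc.true_params["a"])
        vary = dict(STANDARD_VARY)
        vary["rbar1"] = False
        p_fixed = generic_start(sc.true_params["b"], vary=vary)
        with pytest.raises(ValueError, match="shared parameter"):
            fitting.FitSpec(
                datasets=[
                    fitting.Dataset(sc.decays["a"], sc.irf, sc.buffer_model, p_free),
                    fitting.Dataset(sc.decays["b"], sc.irf, sc.buffer_model, p_fixed),
                ],
                sharing=("rbar1",),
            )

    def test_titration_f_a2_recovery(self, grid):
        truths = [0.08, 0.5, 0.8, 0.96]
        sc = synthetic.make_scenario(
            "intrasubunit", seed=21, grid=grid, total_counts=TOTAL_COUNTS,
            conditions=[(f"c{i}", f) for i, f in enumerate(truths)],
        )
        fit = protocol_global_fit(sc)
        for i, f_true in enumerate(truths):
            assert fit.estimates[f"f_A2@{i}"] == pytest.approx(f_true, abs=0.05)


class TestIdentifiability:
    def test_profile_of_fixed_parameter_rejected(self, grid):
        sc = synthetic.make_scenario("intrasubunit", seed=0, grid=grid,
                                     total_counts=1e5, conditions=[("apo", 0.08)])
        ds = fitting.Dataset(sc.decays["apo"], sc.irf, sc.buffer_model,
                             generic_start(sc.true_params["apo"]))
        spec = fitting.FitSpec(datasets=[ds])
        with pytest.raises(ValueError, match="fixed"):
            fitting.chi2_profile(spec, "R0", [43.0, 44.0])
        with pytest.raises(ValueError, match="non-empty"):
            fitting.chi2_profile(spec, "rbar1", [])

    def test_rbar_profile_convex_with_minimum_at_estimate(
        self, single_gaussian_identifiability
    ):
        from conftest import assert_unimodal_profile

        prof = single_gaussian_identifiability["profile_rbar1"]
        truth = single_gaussian_identifiability["truth"].rbar1
        step = prof.values[1] - prof.values[0]
        k = assert_unimodal_profile(prof)
        assert abs(prof.values[k] - truth) <= step + 1e-9

    def test_sigma_less_well_determined_than_rbar(
        self, single_gaussian_identifiability
    ):
        prof_r = single_gaussian_identifiability["profile_rbar1"]
        prof_s = single_gaussian_identifiability["profile_sigma1"]
        assert prof_r.curvature() / prof_s.curvature() > 1.0

    def test_sigma_fd_surface_is_tilted_valley(self, single_gaussian_identifiability):
        surf = single_gaussian_identifiability["surface"]
        z = surf.redchi
        # interior minimum
        imin = np.unravel_index(np.argmin(z), z.shape)
        assert 0 < imin[0] < z.shape[0] - 1
        assert 0 < imin[1] < z.shape[1] - 1
        # mixed partial from the central 3x3 block: nonzero correlation
        i, j = imin
        d2xy = (z[i + 1, j + 1] - z[i + 1, j - 1] - z[i - 1, j + 1] + z[i - 1, j - 1])
        d2xx = z[i + 1, j] - 2 * z[i, j] + z[i - 1, j]
        d2yy = z[i, j + 1] - 2 * z[i, j] + z[i, j - 1]
        corr = (d2xy / 4.0) / np.sqrt(d2xx * d2yy)
        assert abs(corr) > 0.05

    def test_surface_on_single_point_equals_fit_chi_square(
        self, single_gaussian_identifiability
    ):
        fit = single_gaussian_identifiability["fit"]
        spec = single_gaussian_identifiability["spec"]
        surf = fitting.chi2_surface(
            spec, ("rbar1", "sigma1"),
            [fit.estimates["rbar1"]], [fit.estimates["sigma1"]],
        )
        # one fewer free parameter per fixed axis changes dof slightly
        assert surf.redchi[0, 0] == pytest.approx(fit.redchi, rel=0.02)
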