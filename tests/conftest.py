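"""Shared fixtures: a test-scale time grid, protocol helpers, and the
expensive simulate-and-refit campaigns reused across test modules.

Test simulations use 1024 bins x 50 ps (51.2 ns window) instead of the
production default (4096 x 25 ps): the coarser binning keeps refits fast
while leaving parameter recovery at the sub-angstrom level.
"""

from __future__ import annotations

import numpy as np
import pytest

import tmfret as tf
from tmfret import fitting, synthetic

GRID = tf.TimeGrid(bin_width=0.05, n_bins=1024)

STANDARD_VARY = {
    n: True
    for n in (
        "f_D", "rbar1", "sigma1", "f_A2", "rbar2", "sigma2",
        "shift_irf", "A0", "bkgr_dec",
    )
}

# Generating truths used across recovery tests (study parameter sets).
DONOR_TRUTH = dict(tau_D1=17.6, alpha_D1=0.87, tau_D2=4.73)
INTRA_DISTANCES = dict(rbar1=41.7, sigma1=2.3, rbar2=28.8, sigma2=2.1)
HOMOTETRAMER_DISTANCES = dict(rbar1=41.6, sigma1=3.6, rbar2=29.1, sigma2=4.1)
INTERSUBUNIT_RHO2 = ((54.1, 3.0), (58.0, 5.0))
TOTAL_COUNTS = 5e6


def generic_start(truth, vary=None, **overrides):
    """Documented deterministic starting point for donor+acceptor fits:
    distances bracketing R0, f_A2 = 0.5, sigma = 3 A."""
    kwargs = dict(
        f_D=0.1, rbar1=45.0, sigma1=3.0, f_A2=0.5, rbar2=33.0, sigma2=3.0,
        shift_irf=0.0, A0=1.0, bkgr_dec=1.0,
        vary=dict(vary if vary is not None else STANDARD_VARY),
    )
    kwargs.update(overrides)
    return truth.replace(**kwargs)


def protocol_global_fit(scenario, share=("rbar1", "sigma1", "rbar2", "sigma2", "f_D")):
    """The study's protocol: fit the buffer, then globally fit all ligand
    conditions with the distance parameters shared and f_A2 free per
    condition (donor lifetimes, R0, f_B, bkgr_irf fixed throughout)."""
    buffer_model, _ = fitting.fit_buffer(scenario.buffer_decay, scenario.irf, 2)
    datasets = []
    for label, _ in scenario.conditions:
        truth = scenario.true_params[label]
        start = generic_start(truth)
        datasets.append(
            fitting.Dataset(scenario.decays[label], scenario.irf, buffer_model,
                            start, label=label)
        )
    spec = fitting.FitSpec(datasets=datasets, sharing=share)
    return fitting.fit_global(spec)


@pytest.fixture(scope="session")
def grid():
    return GRID


@pytest.fixture(scope="session")
def donor_recovery_fits():
    """20 seeded donor-only simulate-and-refit rounds at 5e6 counts."""
    results = []
    for seed in range(20):
        sc = synthetic.make_scenario(
            "donor_only", seed=seed, grid=GRID, total_counts=TOTAL_COUNTS,
            conditions=[("apo", 0.0)],
        )
        start = tf.FretParams(
            f_D=1.0, tau_D1=15.0, alpha_D1=0.8, tau_D2=4.0, f_B=1.0, A0=1.0,
            bkgr_dec=1.0,
            vary={n: True for n in
                  ("tau_D1", "alpha_D1", "tau_D2", "shift_irf", "A0", "bkgr_dec")},
        )
        buffer_model, _ = fitting.fit_buffer(sc.buffer_decay, sc.irf, 2)
        fit = fitting.fit_donor_only(sc.decays["apo"], sc.irf, buffer_model, start)
        results.append(fit)
    return results


@pytest.fixture(scope="session")
def intrasubunit_recovery_fits():
    """20 seeded apo+saturating global refits of the intrasubunit scenario."""
    results = []
    for seed in range(20):
        sc = synthetic.make_scenario(
            "intrasubunit", seed=seed, grid=GRID, total_counts=TOTAL_COUNTS,
            conditions=[("apo", 0.08), ("sat", 0.96)],
        )
        results.append(protocol_global_fit(sc))
    return results


@pytest.fixture(scope="session")
def homotetramer_recovery_fits():
    """Two-acceptor (intersubunit rho2) recovery over 3 seeds."""
    results = []
    for seed in (0, 1, 2):
        sc = synthetic.make_scenario(
            "homotetramer", seed=seed, grid=GRID, total_counts=TOTAL_COUNTS,
            conditions=[("apo", 0.25), ("sat", 0.94)],
        )
        results.append(protocol_global_fit(sc))
    return results


@pytest.fixture(scope="session")
def single_gaussian_identifiability():
    """One single-Gaussian fit plus chi-square profiles and a surface.

    Used both for profile convexity / sigma-vs-rbar curvature checks and for
    the (sigma1, f_D) correlation structure.
    """
    sc = synthetic.make_scenario(
        "intrasubunit", seed=5, grid=GRID, total_counts=TOTAL_COUNTS,
        conditions=[("apo", 0.0)],
        overrides={"f_D": 0.15},
    )
    truth = sc.true_params["apo"]
    buffer_model, _ = fitting.fit_buffer(sc.buffer_decay, sc.irf, 2)
    vary = {n: True for n in
            ("f_D", "rbar1", "sigma1", "shift_irf", "A0", "bkgr_dec")}
    start = truth.replace(
        f_D=0.1, rbar1=45.0, sigma1=3.0, shift_irf=0.0, A0=1.0, bkgr_dec=1.0,
        vary=vary,
    )
    spec = fitting.FitSpec(
        datasets=[fitting.Dataset(sc.decays["apo"], sc.irf, buffer_model, start)]
    )
    fit = fitting.fit_decay(sc.decays["apo"], sc.irf, buffer_model, start)
    r_hat = fit.estimates["rbar1"]
    s_hat = fit.estimates["sigma1"]
    f_hat = fit.estimates["f_D"]
    steps = np.linspace(-1.5, 1.5, 7)
    prof_r = fitting.chi2_profile(spec, "rbar1", r_hat + steps)
    prof_s = fitting.chi2_profile(spec, "sigma1", s_hat + steps)
    surf = fitting.chi2_surface(
        spec, ("sigma1", "f_D"),
        s_hat + np.linspace(-1.0, 1.0, 5),
        np.clip(f_hat + np.linspace(-0.06, 0.06, 5), 0.0, 1.0),
    )
    return {
        "truth": truth, "fit": fit, "spec": spec,
        "profile_rbar1": prof_r, "profile_sigma1": prof_s,
        "surface": surf,
    }


@pytest.fixture(scope="session")
def coupling_experiment():
    """Synthetic two-construct coupling experiment with a shared-distance
    global fit, mirroring the fragment-vs-full-channel comparison."""
    shared_distances = dict(rbar1=40.5, sigma1=4.1, rbar2=30.5, sigma2=3.3)
    conditions = {
        "cterm": [("apo", 0.12), ("sat", 0.96)],
        "full": [("apo", 0.41), ("sat", 0.99)],
    }
    datasets = []
    truths = {}
    for i, (construct, conds) in enumerate(conditions.items()):
        sc = synthetic.make_scenario(
            "homotetramer", seed=100 + i, grid=GRID, total_counts=TOTAL_COUNTS,
            conditions=conds, overrides=shared_distances,
        )
        buffer_model, _ = fitting.fit_buffer(sc.buffer_decay, sc.irf, 2)
        for label, f_true in conds:
            truth = sc.true_params[label]
            truths[f"{construct}:{label}"] = f_true
            datasets.append(
                fitting.Dataset(sc.decays[label], sc.irf, buffer_model,
                                generic_start(truth), label=f"{construct}:{label}")
            )
    spec = fitting.FitSpec(
        datasets=datasets, sharing=("rbar1", "sigma1", "rbar2", "sigma2", "f_D")
    )
    fit = fitting.fit_global(spec)
    labels = [ds.label for ds in datasets]
    return {"fit": fit, "labels": labels, "truths": truths,
            "shared_distances": shared_distances}


def assert_unimodal_profile(prof, eps=0.01):
    """A chi-square profile should fall to one interior minimum and rise
    again; ``eps`` absorbs re-optimization noise in reduced chi-square.
    Returns the index of the minimum."""
    z = prof.redchi
    k = int(np.argmin(z))
    assert np.all(np.diff(z[: k + 1]) <= eps), z
    assert np.all(np.diff(z[k:]) >= -eps), z
    assert prof.curvature() > 0
    return k


# ---------------------------------------------------------------------------
# independent oracles


def direct_two_acceptor_intensity(params, grid, n_r=501, times=None):
    """Brute-force two-acceptor intensity by direct 2-D quadrature.

    Evaluates the double integral over (r1, r2) of
    rho1(r1) rho2(r2) sum_i a_i exp(-t/tau_i [1 + (R0/r1)^6 + (R0/r2)^6])
    on a tensor-product trapezoid grid, without using the factorization into
    a product of 1-D integrals.  Deliberately slow and structurally
    independent of the implementation under test.
    """
    from tmfret.decay_model import distance_density

    t = grid.times if times is None else np.asarray(times)
    rho1 = params.rho1
    rho2 = params.rho2_distribution

    def axis(dist):
        lo = max(0.5, float(np.min(dist.means - 8 * dist.stdevs)))
        hi = float(np.max(dist.means + 8 * dist.stdevs))
        r = np.linspace(lo, hi, n_r)
        w = distance_density(dist, r)
        return r, w, r[1] - r[0]

    r1, w1, dr1 = axis(rho1)
    r2, w2, dr2 = axis(rho2)
    weight = np.outer(w1, w2) * dr1 * dr2
    # trapezoid end-corrections (negligible mass at +/-8 sigma, kept for form)
    weight[0, :] *= 0.5
    weight[-1, :] *= 0.5
    weight[:, 0] *= 0.5
    weight[:, -1] *= 0.5

    donor = params.donor
    g = 1.0 + np.add.outer((params.R0 / r1) ** 6, (params.R0 / r2) ** 6)
    fret = np.zeros(t.size)
    for k, ti in enumerate(t):
        acc = 0.0
        for a, tau in donor.components:
            acc += a * float(np.sum(weight * np.exp(-ti * g / tau)))
        fret[k] = acc
    donor_term = donor.fractions @ np.exp(-np.outer(1.0 / donor.lifetimes, t))
    return params.A0 * (params.f_D * donor_term + (1.0 - params.f_D) * fret)
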