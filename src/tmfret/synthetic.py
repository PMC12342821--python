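"""Synthetic TCSPC datasets with known ground truth.

Every stage of the analysis pipeline — buffer fits, donor-only fits,
single- and two-acceptor FRET fits, global fits, energetics — can be
exercised on data generated here.  The generator emulates the physics of a
cuvette TCSPC experiment: a double-exponential donor, FRET quenching through
Gaussian distance distributions, a finite-width Gaussian IRF, a
multi-exponential buffer background, a constant dark-count floor, and
independent Poisson shot noise in every bin.  It does not emulate detector
afterpulsing, pulse pile-up, or repetition-rate wrap-around.

Scenario presets carry the parameter sets of the SthK study system: the
acridonylalanine (Acd) donor (87% of 17.6 ns + 13% of 4.73 ns), the
Ru-complex acceptor with R0 = 43.5 A, and resting/active Gaussian distance
pairs for the intrasubunit, intersubunit, homotetramer and full-length
channel labelling schemes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.stats import norm

from .decay_model import (
    BufferModel,
    FretParams,
    Histogram,
    TimeGrid,
    buffer_intensity,
    fret_intensity,
    reconvolve,
)
from .energetics import DoseResponseParams, dose_response_value

__all__ = [
    "Scenario",
    "SCENARIO_NAMES",
    "default_grid",
    "make_irf",
    "simulate_histogram",
    "simulate_buffer_histogram",
    "make_scenario",
    "make_dose_series",
]

#: Default TCSPC binning: 4096 bins x 25 ps = 102.4 ns window.
DEFAULT_GRID = TimeGrid(bin_width=0.025, n_bins=4096)

# Acd donor in SthK: 87% amplitude at 17.6 ns, remainder at 4.73 ns.
_DONOR = dict(tau_D1=17.6, alpha_D1=0.87, tau_D2=4.73)
_R0 = 43.5

# Intersubunit (donor on one subunit, acceptors on neighbours) resting and
# active Gaussians, used as the fixed second-acceptor block rho2.
_INTERSUBUNIT_RHO2 = ((54.1, 3.0), (58.0, 5.0))

# (rbar1, sigma1, rbar2, sigma2, conditions, rho2)
_PRESETS = {
    "donor_only": dict(
        distances=None,
        conditions=[("apo", 0.0), ("cAMP_320uM", 0.0)],
        rho2=None,
    ),
    "intrasubunit": dict(
        distances=(41.7, 2.3, 28.8, 2.1),
        conditions=[("apo", 0.08), ("cAMP_1uM", 0.5), ("cAMP_320uM", 0.96)],
        rho2=None,
    ),
    "intersubunit": dict(
        distances=(54.1, 3.0, 58.0, 5.0),
        conditions=[("apo", 0.2), ("cAMP_320uM", 0.8)],
        rho2=None,
    ),
    "homotetramer": dict(
        distances=(41.6, 3.6, 29.1, 4.1),
        conditions=[("apo", 0.25), ("cAMP_320uM", 0.94)],
        rho2=_INTERSUBUNIT_RHO2,
    ),
    "full_length": dict(
        distances=(39.8, 4.1, 31.0, 2.7),
        conditions=[("apo", 0.41), ("cAMP_320uM", 0.99)],
        rho2=_INTERSUBUNIT_RHO2,
    ),
}

SCENARIO_NAMES = tuple(_PRESETS)

# Default nuisance levels: buffer fluorescence ~2% of the decay peak split
# over a fast and a slow component, plus 0.5 dark counts per bin.
_BUFFER_TAUS = (1.0, 6.0)
_BKGR_DEC = 0.5
_IRF_CENTER = 5.0
_IRF_FWHM = 0.4
_ACQUISITION_S = 300.0


def default_grid() -> TimeGrid:
    return DEFAULT_GRID


@dataclass
class Scenario:
    """A complete synthetic experiment bundle with its ground truth."""

    name: str
    true_params: dict            # condition label -> FretParams used to generate
    conditions: list             # (label, f_A2) pairs
    decays: dict                 # condition label -> Histogram
    irf: Histogram
    buffer_decay: Histogram
    buffer_model: BufferModel
    total_counts: float
    seed: int

    def manifest(self) -> dict:
        """Self-describing metadata (ground truth included) for the bundle."""
        truth = {}
        for label, p in self.true_params.items():
            entry = {k: float(v) for k, v in p.values().items()}
            if p.rho2 is not None:
                entry["rho2"] = [[float(m), float(s)] for m, s in p.rho2]
                entry["rho2_tied_to_f_A2"] = True
            truth[label] = entry
        return {
            "scenario": self.name,
            "seed": int(self.seed),
            "total_counts": float(self.total_counts),
            "conditions": [[label, float(f)] for label, f in self.conditions],
            "acquisition_duration_s": _ACQUISITION_S,
            "buffer_model": [[float(a), float(t)] for a, t in self.buffer_model.components],
            "truth": truth,
        }


def make_irf(
    grid: TimeGrid = DEFAULT_GRID,
    center: float = _IRF_CENTER,
    fwhm: float = _IRF_FWHM,
    total_counts: float = 2e6,
    background_rate: float = 0.0,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
) -> Histogram:
    """Poisson-sampled Gaussian instrument response plus uniform background.

    Stands in for a measured scatterer IRF.  ``fwhm`` narrower than a bin
    collapses to a single-bin spike.
    """
    if fwhm <= 0:
        raise ValueError("fwhm must be > 0")
    t = grid.times
    if not t[0] <= center <= t[-1]:
        raise ValueError(f"IRF center {center} ns outside the time window")
    rng = rng if rng is not None else np.random.default_rng(seed)
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    # integrate the pulse over each bin so sub-bin pulses land in one bin
    edges = np.concatenate([t - grid.bin_width / 2, [t[-1] + grid.bin_width / 2]])
    cdf = norm.cdf(edges, loc=center, scale=sigma)
    shape = np.diff(cdf)
    mass = shape.sum()
    if mass <= 0:
        raise ValueError("IRF pulse has no mass inside the time window")
    expected = total_counts * shape / mass + background_rate
    counts = rng.poisson(expected)
    return Histogram(
        grid=grid,
        counts=counts.astype(float),
        role="irf",
        condition_label="irf",
        metadata={"center_ns": center, "fwhm_ns": fwhm},
    )


def _expected_decay(params, irf, buffer, grid, n_nodes=301):
    intensity = fret_intensity(params, grid, n_nodes)
    buf = buffer_intensity(buffer, grid) if buffer is not None else np.zeros(grid.n_bins)
    return reconvolve(
        irf,
        intensity,
        buf,
        shift_irf=params.shift_irf,
        bkgr_irf=params.bkgr_irf,
        f_B=params.f_B,
        bkgr_dec=params.bkgr_dec,
    )


def simulate_histogram(
    params: FretParams,
    irf: Histogram,
    buffer: Optional[BufferModel],
    total_counts: float,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
    condition_label: str = "",
    rescale_a0: bool = True,
) -> Histogram:
    """Poisson-sampled decay from the noise-free reconvolution prediction.

    With ``rescale_a0`` (default) the model amplitude A0 is rescaled so the
    total *expected* counts (signal + buffer + background) equal
    ``total_counts``; the effective A0 is recorded in the metadata together
    with the full generating parameter set.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    grid = irf.grid
    expected = _expected_decay(params, irf, buffer, grid).counts
    if rescale_a0:
        # split the expectation into the A0-proportional signal and the rest
        zero_a0 = _expected_decay(params.replace(A0=0.0), irf, buffer, grid).counts
        signal = expected - zero_a0
        budget = total_counts - zero_a0.sum()
        if budget <= 0 or signal.sum() <= 0:
            raise ValueError(
                "total_counts too small for the configured buffer/background"
            )
        scale = budget / signal.sum()
        params = params.replace(A0=params.A0 * scale)
        expected = zero_a0 + scale * signal
    expected = np.clip(expected, 0.0, None)
    counts = rng.poisson(expected).astype(float)
    meta = {"truth": {k: float(v) for k, v in params.values().items()}}
    if params.rho2 is not None:
        meta["truth"]["rho2"] = [[float(m), float(s)] for m, s in params.rho2]
    return Histogram(
        grid=grid,
        counts=counts,
        role="decay",
        acquisition_duration=_ACQUISITION_S,
        condition_label=condition_label,
        metadata=meta,
    )


def simulate_buffer_histogram(
    buffer: BufferModel,
    irf: Histogram,
    bkgr_dec: float = _BKGR_DEC,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
) -> Histogram:
    """Poisson-sampled buffer-only decay (reconvolved, plus dark counts)."""
    rng = rng if rng is not None else np.random.default_rng(seed)
    grid = irf.grid
    curve = buffer_intensity(buffer, grid)
    expected = reconvolve(irf, curve, np.zeros(grid.n_bins), bkgr_dec=bkgr_dec).counts
    counts = rng.poisson(np.clip(expected, 0.0, None)).astype(float)
    return Histogram(
        grid=grid,
        counts=counts,
        role="buffer",
        acquisition_duration=_ACQUISITION_S,
        condition_label="buffer",
    )


def _scenario_params(name: str, f_A2: float, overrides: dict) -> FretParams:
    preset = _PRESETS[name]
    kwargs = dict(
        f_D=0.1 if name != "donor_only" else 1.0,
        R0=_R0,
        shift_irf=0.0,
        f_B=1.0,
        A0=1.0,
        bkgr_dec=_BKGR_DEC,
        bkgr_irf=0.0,
        **_DONOR,
    )
    if preset["distances"] is not None:
        r1, s1, r2, s2 = preset["distances"]
        kwargs.update(rbar1=r1, sigma1=s1, rbar2=r2, sigma2=s2)
    kwargs["f_A2"] = f_A2
    kwargs["rho2"] = preset["rho2"]
    kwargs.update(overrides)
    return FretParams(**kwargs)


def make_scenario(
    scenario_name: str,
    overrides: Optional[dict] = None,
    seed: int = 0,
    grid: TimeGrid = DEFAULT_GRID,
    total_counts: float = 5e6,
    conditions: Optional[list] = None,
    outdir=None,
) -> Scenario:
    """Generate a full dataset bundle (decays + IRF + buffer) for a named
    experimental scenario.

    Scenarios: ``donor_only``, ``intrasubunit``, ``intersubunit``,
    ``homotetramer``, ``full_length``.  ``overrides`` patches the generating
    :class:`FretParams` fields; ``conditions`` replaces the preset
    (label, f_A2) list.  If ``outdir`` is given the bundle is also written to
    disk in the package's histogram/manifest text formats.
    """
    if scenario_name not in _PRESETS:
        raise ValueError(
            f"unknown scenario {scenario_name!r}; choose from {SCENARIO_NAMES}"
        )
    overrides = dict(overrides or {})
    conditions = list(conditions or _PRESETS[scenario_name]["conditions"])
    if any(not 0.0 <= f <= 1.0 for _, f in conditions):
        raise ValueError("condition f_A2 values must lie in [0, 1]")
    if total_counts <= 0:
        raise ValueError("total_counts must be > 0")
    rng = np.random.default_rng(seed)
    irf = make_irf(grid, rng=rng)

    # buffer amplitudes scaled to ~2% of the (approximate) decay peak
    peak_guess = total_counts * grid.bin_width / 10.0
    buffer_model = BufferModel(
        tuple((0.01 * peak_guess, tau) for tau in _BUFFER_TAUS)
    )
    buffer_decay = simulate_buffer_histogram(buffer_model, irf, rng=rng)

    decays, true_params = {}, {}
    for label, f_A2 in conditions:
        params = _scenario_params(scenario_name, f_A2, overrides)
        h = simulate_histogram(
            params, irf, buffer_model, total_counts, rng=rng, condition_label=label
        )
        decays[label] = h
        true_params[label] = params.replace(A0=h.metadata["truth"]["A0"])

    scenario = Scenario(
        name=scenario_name,
        true_params=true_params,
        conditions=conditions,
        decays=decays,
        irf=irf,
        buffer_decay=buffer_decay,
        buffer_model=buffer_model,
        total_counts=total_counts,
        seed=seed,
    )
    if outdir is not None:
        from .io import write_scenario  # local import to avoid a cycle

        write_scenario(scenario, outdir)
    return scenario


def make_dose_series(
    dose_params: DoseResponseParams,
    concentrations,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
    noise_sd: float = 0.0,
) -> list:
    """Ground-truth (L, f_A2) pairs from the tight-binding isotherm, with
    optional additive Gaussian noise clipped to [0, 1]."""
    L = np.asarray(concentrations, dtype=float)
    if np.any(L < 0):
        raise ValueError("concentrations must be >= 0")
    f = np.atleast_1d(dose_response_value(dose_params, L))
    if noise_sd > 0:
        rng = rng if rng is not None else np.random.default_rng(seed)
        f = np.clip(f + rng.normal(0.0, noise_sd, size=f.shape), 0.0, 1.0)
    return list(zip(L.tolist(), f.tolist()))
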