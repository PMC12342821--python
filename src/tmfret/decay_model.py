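"""Forward model for time-domain tmFRET fluorescence decays.

A pulsed-excitation TCSPC measurement records a histogram of photon arrival
times.  The donor fluorophore decays with one or two exponential components;
FRET to a nearby metal-ion acceptor adds a distance-dependent rate
``(R0/r)**6 / tau_D`` to each component.  Donor-acceptor distances are not
fixed but follow a distribution ``rho(r)`` modelled as the sum of up to two
Gaussians (one per conformational state).  The measured decay is the
convolution of this intensity (plus scaled buffer fluorescence) with the
instrument response function (IRF), on top of a constant dark-count
background.

Units: time in ns (``shift_irf`` is accepted in ps and converted), distances
in angstrom, amplitudes in photon counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.signal import fftconvolve
from scipy.stats import norm

__all__ = [
    "TimeGrid",
    "Histogram",
    "DonorModel",
    "BufferModel",
    "DistanceDistribution",
    "FretParams",
    "PARAM_NAMES",
    "distance_density",
    "fret_intensity_single",
    "fret_intensity_double",
    "buffer_intensity",
    "reconvolve",
]

#: Names of the 15 scalars of the reconvolution FRET model, addressable on
#: :class:`FretParams`.
PARAM_NAMES = (
    "f_D",
    "tau_D1",
    "alpha_D1",
    "tau_D2",
    "R0",
    "rbar1",
    "sigma1",
    "f_A2",
    "rbar2",
    "sigma2",
    "shift_irf",
    "f_B",
    "A0",
    "bkgr_dec",
    "bkgr_irf",
)

# Default box bounds used when a parameter is freed in a fit.
DEFAULT_BOUNDS = {
    "f_D": (0.0, 1.0),
    "tau_D1": (0.1, 50.0),
    "alpha_D1": (0.0, 1.0),
    "tau_D2": (0.1, 50.0),
    "R0": (1.0, 200.0),
    "rbar1": (10.0, 100.0),
    "sigma1": (0.1, 20.0),
    "f_A2": (0.0, 1.0),
    "rbar2": (10.0, 100.0),
    "sigma2": (0.1, 20.0),
    "shift_irf": (-2000.0, 2000.0),
    "f_B": (0.0, np.inf),
    "A0": (0.0, np.inf),
    "bkgr_dec": (0.0, np.inf),
    "bkgr_irf": (0.0, np.inf),
}

# Distances below this (angstrom) are excluded from the quadrature support;
# the FRET rate diverges as r -> 0 but reported distributions carry no mass
# there.
_R_MIN = 0.5
# Half-width of each Gaussian component's quadrature support, in stdevs.
_SUPPORT_SIGMAS = 8.0
# Trapezoid nodes per Gaussian component.
_N_NODES = 301


class DomainError(ValueError):
    """Raised for arguments outside the model's physical domain."""


@dataclass(frozen=True)
class TimeGrid:
    """Uniform arrival-time binning; ``origin`` is the first bin center (ns)."""

    bin_width: float
    n_bins: int
    origin: float = 0.0

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise DomainError(f"bin_width must be > 0, got {self.bin_width}")
        if self.n_bins < 2:
            raise DomainError(f"n_bins must be >= 2, got {self.n_bins}")

    @property
    def times(self) -> np.ndarray:
        return self.origin + self.bin_width * np.arange(self.n_bins)

    @property
    def span(self) -> float:
        return self.bin_width * self.n_bins


@dataclass
class Histogram:
    """Photon-count record on a :class:`TimeGrid`.

    ``role`` is one of ``decay`` / ``buffer`` / ``irf``.  Counts are integers
    for measured or simulated data and reals for model predictions.
    ``acquisition_duration`` (s) is required for decay and buffer roles: their
    ratio fixes the buffer scaling f_B.
    """

    grid: TimeGrid
    counts: np.ndarray
    role: str = "decay"
    acquisition_duration: Optional[float] = None
    condition_label: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 1 or self.counts.size != self.grid.n_bins:
            raise ValueError(
                f"counts length {self.counts.size} != n_bins {self.grid.n_bins}"
            )
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.role not in ("decay", "buffer", "irf"):
            raise ValueError(f"unknown role {self.role!r}")
        if self.role in ("decay", "buffer"):
            if self.acquisition_duration is None or self.acquisition_duration <= 0:
                raise ValueError(
                    f"{self.role} histogram requires acquisition_duration > 0"
                )

    @property
    def total(self) -> float:
        return float(self.counts.sum())


@dataclass(frozen=True)
class DonorModel:
    """Donor-only fluorescence: 1-2 exponential components.

    ``components`` is a sequence of (amplitude_fraction, lifetime_ns); the
    fractions must sum to 1.
    """

    components: tuple

    def __post_init__(self) -> None:
        comps = tuple((float(a), float(t)) for a, t in self.components)
        object.__setattr__(self, "components", comps)
        if not 1 <= len(comps) <= 2:
            raise DomainError("donor model needs 1-2 exponential components")
        if any(t <= 0 for _, t in comps):
            raise DomainError("donor lifetimes must be > 0")
        if abs(sum(a for a, _ in comps) - 1.0) > 1e-8:
            raise DomainError("donor amplitude fractions must sum to 1")

    @property
    def fractions(self) -> np.ndarray:
        return np.array([a for a, _ in self.components])

    @property
    def lifetimes(self) -> np.ndarray:
        return np.array([t for _, t in self.components])


@dataclass(frozen=True)
class BufferModel:
    """Buffer-only fluorescence: up to 4 exponentials, amplitudes in counts."""

    components: tuple

    def __post_init__(self) -> None:
        comps = tuple((float(a), float(t)) for a, t in self.components)
        object.__setattr__(self, "components", comps)
        if not 1 <= len(comps) <= 4:
            raise DomainError("buffer model needs 1-4 exponential components")
        if any(t <= 0 for _, t in comps):
            raise DomainError("buffer lifetimes must be > 0")
        if any(a < 0 for a, _ in comps):
            raise DomainError("buffer amplitudes must be >= 0")


@dataclass(frozen=True)
class DistanceDistribution:
    """Donor-acceptor distance density: up to two Gaussians over r > 0.

    ``components`` is a sequence of (fraction, mean_A, stdev_A).  Each
    Gaussian is truncated at r > 0 and renormalized so the mixture integrates
    to one over positive distances.
    """

    components: tuple

    def __post_init__(self) -> None:
        comps = tuple((float(f), float(m), float(s)) for f, m, s in self.components)
        object.__setattr__(self, "components", comps)
        if not 1 <= len(comps) <= 2:
            raise DomainError("distance distribution needs 1-2 Gaussian components")
        if any(f < 0 for f, _, _ in comps):
            raise DomainError("component fractions must be >= 0")
        if abs(sum(f for f, _, _ in comps) - 1.0) > 1e-8:
            raise DomainError("component fractions must sum to 1")
        if any(m <= 0 for _, m, _ in comps):
            raise DomainError("mean distances must be > 0")
        if any(s <= 0 for _, _, s in comps):
            raise DomainError("distance stdevs must be > 0")

    @property
    def fractions(self) -> np.ndarray:
        return np.array([f for f, _, _ in self.components])

    @property
    def means(self) -> np.ndarray:
        return np.array([m for _, m, _ in self.components])

    @property
    def stdevs(self) -> np.ndarray:
        return np.array([s for _, _, s in self.components])


def distance_density(dist: DistanceDistribution, r) -> np.ndarray:
    """Probability density (1/A) of the donor-acceptor distance at ``r``.

    Each Gaussian component is truncated to r > 0 and renormalized by its
    positive-r mass; for the reported distance scales (mean/stdev > 10) the
    correction is negligible but it keeps the density proper for any valid
    parameters.
    """
    r_arr = np.asarray(r, dtype=float)
    if np.any(r_arr < 0):
        raise DomainError("distance r must be >= 0")
    out = np.zeros_like(r_arr, dtype=float)
    for f, m, s in dist.components:
        if f == 0.0:
            continue
        z = norm.cdf(m / s)  # mass of the untruncated Gaussian on r > 0
        out = out + f * norm.pdf(r_arr, loc=m, scale=s) / z
    return out if out.shape else float(out)


def _component_nodes(fraction, mean, stdev, n_nodes):
    """Trapezoid nodes/weights for one truncated Gaussian component.

    Weights are renormalized to sum exactly to ``fraction`` so the discrete
    rule preserves the mixture normalization.
    """
    lo = max(_R_MIN, mean - _SUPPORT_SIGMAS * stdev)
    hi = mean + _SUPPORT_SIGMAS * stdev
    r = np.linspace(lo, hi, n_nodes)
    w = norm.pdf(r, loc=mean, scale=stdev)
    w[0] *= 0.5
    w[-1] *= 0.5
    w *= fraction / w.sum()
    return r, w


def distance_quadrature(dist: DistanceDistribution, n_nodes: int = _N_NODES):
    """Quadrature nodes and weights for integrals against the distance density.

    Returns ``(r, w)`` with ``w.sum() == 1``; the rule is a per-component
    trapezoid on mean +/- 8 stdev (clipped at r = 0.5 A), dense enough that
    the decay integrals are accurate to well below 1e-6 relative.
    """
    rs, ws = [], []
    for f, m, s in dist.components:
        if f == 0.0:
            continue
        r, w = _component_nodes(f, m, s, n_nodes)
        rs.append(r)
        ws.append(w)
    return np.concatenate(rs), np.concatenate(ws)


@dataclass
class FretParams:
    """The 15-parameter vector of the reconvolution FRET model.

    Scalars (see :data:`PARAM_NAMES`): donor-only fraction ``f_D``; donor
    lifetimes/fraction ``tau_D1, alpha_D1, tau_D2``; Forster distance ``R0``
    (A); the two-Gaussian intrasubunit distance distribution ``rbar1, sigma1,
    f_A2, rbar2, sigma2``; IRF shift ``shift_irf`` (ps); buffer scaling
    ``f_B``; model amplitude ``A0`` (counts); backgrounds ``bkgr_dec`` and
    ``bkgr_irf`` (counts/bin).

    ``vary`` flags and ``bounds`` drive the fitting module.  ``rho2``, when
    present, is a second (intersubunit) acceptor distance distribution whose
    mixing fraction is always tied to ``f_A2``: only its component means and
    stdevs are meaningful, stored as ((mean1, sd1), (mean2, sd2)).
    """

    f_D: float = 0.0
    tau_D1: float = 17.6
    alpha_D1: float = 0.87
    tau_D2: float = 4.73
    R0: float = 43.5
    rbar1: float = 40.0
    sigma1: float = 3.0
    f_A2: float = 0.0
    rbar2: float = 30.0
    sigma2: float = 3.0
    shift_irf: float = 0.0
    f_B: float = 0.0
    A0: float = 1.0
    bkgr_dec: float = 0.0
    bkgr_irf: float = 0.0
    vary: dict = field(default_factory=dict)
    bounds: dict = field(default_factory=dict)
    rho2: Optional[tuple] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.f_D <= 1.0:
            raise DomainError("f_D must lie in [0, 1]")
        if not 0.0 <= self.f_A2 <= 1.0:
            raise DomainError("f_A2 must lie in [0, 1]")
        if self.R0 <= 0:
            raise DomainError("R0 must be > 0")
        if self.rho2 is not None:
            rho2 = tuple((float(m), float(s)) for m, s in self.rho2)
            if not 1 <= len(rho2) <= 2:
                raise DomainError("rho2 needs 1-2 (mean, stdev) pairs")
            self.rho2 = rho2
        unknown = set(self.vary) - set(PARAM_NAMES)
        if unknown:
            raise ValueError(f"unknown parameter names in vary: {sorted(unknown)}")

    @property
    def donor(self) -> DonorModel:
        if self.alpha_D1 >= 1.0 - 1e-12:
            return DonorModel(((1.0, self.tau_D1),))
        return DonorModel(
            ((self.alpha_D1, self.tau_D1), (1.0 - self.alpha_D1, self.tau_D2))
        )

    @property
    def rho1(self) -> DistanceDistribution:
        if self.f_A2 == 0.0:
            return DistanceDistribution(((1.0, self.rbar1, self.sigma1),))
        if self.f_A2 == 1.0:
            return DistanceDistribution(((1.0, self.rbar2, self.sigma2),))
        return DistanceDistribution(
            (
                (1.0 - self.f_A2, self.rbar1, self.sigma1),
                (self.f_A2, self.rbar2, self.sigma2),
            )
        )

    @property
    def rho2_distribution(self) -> DistanceDistribution:
        """Intersubunit distribution with its fraction tied to ``f_A2``."""
        if self.rho2 is None:
            raise ValueError("params carry no intersubunit rho2 block")
        if len(self.rho2) == 1:
            (m, s), = self.rho2
            return DistanceDistribution(((1.0, m, s),))
        (m1, s1), (m2, s2) = self.rho2
        if self.f_A2 == 0.0:
            return DistanceDistribution(((1.0, m1, s1),))
        if self.f_A2 == 1.0:
            return DistanceDistribution(((1.0, m2, s2),))
        return DistanceDistribution(
            ((1.0 - self.f_A2, m1, s1), (self.f_A2, m2, s2))
        )

    def values(self) -> dict:
        return {name: getattr(self, name) for name in PARAM_NAMES}

    def replace(self, **kwargs) -> "FretParams":
        return replace(self, **kwargs)

    def bound(self, name: str):
        return self.bounds.get(name, DEFAULT_BOUNDS[name])

    def is_varied(self, name: str) -> bool:
        return bool(self.vary.get(name, False))


def _fret_component_curves(donor, dist, R0, times, n_nodes):
    """Per donor component, the distance-averaged FRET survival curve.

    Returns an array (n_components, n_bins) of
    ``integral rho(r) exp(-(t/tau)(1 + (R0/r)^6)) dr``.
    """
    r, w = distance_quadrature(dist, n_nodes)
    g = 1.0 + (R0 / r) ** 6
    out = np.empty((len(donor.components), times.size))
    for i, tau in enumerate(donor.lifetimes):
        out[i] = np.exp(-np.outer(times, g / tau)) @ w
    return out


def fret_intensity_single(
    params: FretParams, grid: TimeGrid, n_nodes: int = _N_NODES
) -> np.ndarray:
    """Unconvolved donor intensity with a single FRET acceptor.

    I(t) = A0 [ f_D sum_i a_i e^{-t/tau_i}
                + (1-f_D) integral rho(r) sum_i a_i
                  e^{-t/tau_i - (t/tau_i)(R0/r)^6} dr ].
    """
    if params.rho2 is not None:
        raise ValueError("params carry rho2; use fret_intensity_double")
    t = grid.times
    donor = params.donor
    donor_term = donor.fractions @ np.exp(-np.outer(1.0 / donor.lifetimes, t))
    if params.f_D >= 1.0:
        return params.A0 * donor_term
    curves = _fret_component_curves(donor, params.rho1, params.R0, t, n_nodes)
    fret_term = donor.fractions @ curves
    return params.A0 * (params.f_D * donor_term + (1.0 - params.f_D) * fret_term)


def fret_intensity_double(
    params: FretParams, grid: TimeGrid, n_nodes: int = _N_NODES
) -> np.ndarray:
    """Unconvolved donor intensity with intra- plus intersubunit acceptors.

    The two acceptor distances are independent, so the double integral over
    (r1, r2) factorizes per donor component into the product of a
    single-acceptor curve for rho1 and a pure transfer factor
    ``integral rho2(r2) exp(-(t/tau_i)(R0/r2)^6) dr2``.
    """
    if params.rho2 is None:
        raise ValueError("params carry no rho2; use fret_intensity_single")
    t = grid.times
    donor = params.donor
    donor_term = donor.fractions @ np.exp(-np.outer(1.0 / donor.lifetimes, t))
    curves1 = _fret_component_curves(donor, params.rho1, params.R0, t, n_nodes)
    rho2 = params.rho2_distribution
    r2, w2 = distance_quadrature(rho2, n_nodes)
    g2 = (params.R0 / r2) ** 6  # transfer-only rate factor, no 1/tau decay
    fret = np.zeros_like(t)
    for i, tau in enumerate(donor.lifetimes):
        s2 = np.exp(-np.outer(t, g2 / tau)) @ w2
        fret += donor.fractions[i] * curves1[i] * s2
    return params.A0 * (params.f_D * donor_term + (1.0 - params.f_D) * fret)


def fret_intensity(params: FretParams, grid: TimeGrid, n_nodes: int = _N_NODES):
    """Dispatch to the single- or two-acceptor intensity model."""
    if params.rho2 is None:
        return fret_intensity_single(params, grid, n_nodes)
    return fret_intensity_double(params, grid, n_nodes)


def buffer_intensity(buf: BufferModel, grid: TimeGrid) -> np.ndarray:
    """Multi-exponential buffer fluorescence at the grid's bin centers."""
    t = grid.times
    out = np.zeros_like(t)
    for a, tau in buf.components:
        out += a * np.exp(-t / tau)
    return out


def _shifted_kernel(irf_counts: np.ndarray, shift_bins: float) -> np.ndarray:
    """Shift the IRF by a (possibly fractional) number of bins.

    Whole-bin shifts are exact relocations; fractional shifts linearly
    interpolate between neighbouring bins.  Mass shifted past the edges is
    dropped.
    """
    n = irf_counts.size
    idx = np.arange(n, dtype=float)
    return np.interp(idx - shift_bins, idx, irf_counts, left=0.0, right=0.0)


def reconvolve(
    irf: Histogram,
    model_intensity: np.ndarray,
    buffer_intensity: np.ndarray,
    shift_irf: float = 0.0,
    bkgr_irf: float = 0.0,
    f_B: float = 0.0,
    bkgr_dec: float = 0.0,
) -> Histogram:
    """Predicted decay: (shifted, background-free, unit-sum IRF) convolved
    with (model + f_B * buffer), plus a constant background.

    ``shift_irf`` is in ps.  The convolution is linear (zero-padded FFT)
    truncated to the grid, so signal that would arrive past the window is
    lost at the boundary rather than wrapped around.
    """
    grid = irf.grid
    model_intensity = np.asarray(model_intensity, dtype=float)
    buffer_arr = np.asarray(buffer_intensity, dtype=float)
    if model_intensity.size != grid.n_bins or buffer_arr.size != grid.n_bins:
        raise ValueError("model/buffer intensity length does not match IRF grid")
    kernel = np.clip(irf.counts - bkgr_irf, 0.0, None)
    if kernel.sum() <= 0:
        raise DomainError("IRF has no signal after background subtraction")
    shift_bins = (shift_irf * 1e-3) / grid.bin_width
    if shift_bins != 0.0:
        kernel = _shifted_kernel(kernel, shift_bins)
        if kernel.sum() <= 0:
            raise DomainError("IRF shifted entirely out of the time window")
    kernel = kernel / kernel.sum()
    signal = model_intensity + f_B * buffer_arr
    pred = fftconvolve(kernel, signal)[: grid.n_bins] + bkgr_dec
    # FFT round-off can leave tiny negative values where the signal is ~0.
    np.clip(pred, 0.0, None, out=pred)
    return Histogram(
        grid=grid,
        counts=pred,
        role="decay",
        acquisition_duration=1.0,
        condition_label="model",
    )
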