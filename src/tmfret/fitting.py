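"""Poisson-weighted chi-square fitting of TCSPC decays, singly and globally.

Decays are fit by bounded trust-region least squares on the weighted
residuals ``(obs - pred) / sqrt(max(obs, 1))`` — the shot-noise standard
deviation of a counting histogram, with a floor of one count so empty bins
do not blow up the weights.  The standard protocol mirrors common practice
for reconvolution lifetime analysis:

* the buffer-only decay is fit first and its multi-exponential model frozen;
* the donor-only sample is fit with ``f_D = 1`` to pin the donor lifetimes;
* donor+acceptor decays are then fit with the donor lifetimes, ``R0``,
  ``f_B`` (acquisition-time ratio) and ``bkgr_irf`` (0) held fixed;
* several decays measured under different ligand conditions can be fit
  globally with selected parameters constrained equal across datasets.

Identifiability is probed with chi-square profiles (fix one parameter on a
grid, re-optimize the rest) and 2-D chi-square surfaces.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import lmfit
import numpy as np

from .decay_model import (
    BufferModel,
    FretParams,
    Histogram,
    PARAM_NAMES,
    buffer_intensity,
    fret_intensity,
    reconvolve,
)

__all__ = [
    "Dataset",
    "FitSpec",
    "FitResult",
    "ProfileResult",
    "SurfaceResult",
    "weighted_chi_square",
    "default_fit_window",
    "fit_buffer",
    "fit_donor_only",
    "fit_decay",
    "fit_global",
    "chi2_profile",
    "chi2_surface",
    "initial_distance_estimate",
]

# Parameters the standard donor+acceptor protocol may free.
_PROTOCOL_FREE = {
    "f_D", "rbar1", "sigma1", "f_A2", "rbar2", "sigma2",
    "shift_irf", "A0", "bkgr_dec",
}
# Parameters the donor-only protocol may free.
_DONOR_FREE = {"tau_D1", "alpha_D1", "tau_D2", "shift_irf", "A0", "bkgr_dec"}

# Deterministic jitters applied to the distance parameters for restarts of
# two-Gaussian fits (multiplier on rbar, sigma respectively).
_RESTART_JITTERS = [
    {"rbar1": 1.05, "rbar2": 0.95, "sigma1": 1.5, "sigma2": 1.5},
    {"rbar1": 0.92, "rbar2": 1.08, "sigma1": 0.67, "sigma2": 0.67},
]
# A converged start whose reduced chi-square falls below this is accepted
# without running the jittered restarts (a correctly specified fit sits at
# 1 +/- a few times sqrt(2/dof), well under this).
_RESTART_REDCHI = 1.1


@dataclass
class Dataset:
    """One decay with its matched IRF and frozen buffer model."""

    decay: Histogram
    irf: Histogram
    buffer: Optional[BufferModel]
    params: FretParams
    label: str = ""

    def __post_init__(self) -> None:
        if self.decay.grid != self.irf.grid:
            raise ValueError("decay and IRF must share one time grid")


@dataclass
class FitSpec:
    """Datasets plus the names of parameters shared across all of them."""

    datasets: list
    sharing: Sequence[str] = ()
    fit_window: Optional[tuple] = None
    n_nodes: int = 101

    def __post_init__(self) -> None:
        if not self.datasets:
            raise ValueError("FitSpec needs at least one dataset")
        for name in self.sharing:
            if name not in PARAM_NAMES:
                raise ValueError(f"unknown shared parameter {name!r}")
        vary0 = {n: self.datasets[0].params.is_varied(n) for n in self.sharing}
        for i, ds in enumerate(self.datasets[1:], start=1):
            for name in self.sharing:
                if ds.params.is_varied(name) != vary0[name]:
                    raise ValueError(
                        f"shared parameter {name!r} is fixed in one dataset "
                        f"and free in another (dataset {i})"
                    )


@dataclass
class FitResult:
    """Estimates, fit-quality measures and predictions from one optimization."""

    estimates: dict
    stderr: dict
    params_by_dataset: list
    redchi: float
    chisqr: float
    dof: int
    residuals: list
    predictions: list
    windows: list
    success: bool
    message: str
    at_bounds: list = field(default_factory=list)
    cost_trace: np.ndarray = field(default_factory=lambda: np.empty(0))
    nfev: int = 0

    @property
    def flagged(self) -> bool:
        return (not self.success) or bool(self.at_bounds)


@dataclass
class ProfileResult:
    parameter: str
    values: np.ndarray
    redchi: np.ndarray

    def curvature(self) -> float:
        """Mean second difference of the chi-square profile (per unit^2)."""
        h = np.diff(self.values)
        if not np.allclose(h, h[0]):
            raise ValueError("curvature needs a uniform profile grid")
        d2 = np.diff(self.redchi, 2) / h[0] ** 2
        return float(d2.mean())


@dataclass
class SurfaceResult:
    parameters: tuple
    values_x: np.ndarray
    values_y: np.ndarray
    redchi: np.ndarray  # shape (len(values_x), len(values_y))


def weighted_chi_square(observed: Histogram, predicted: Histogram, window=None) -> float:
    """Shot-noise weighted chi-square over a bin window (inclusive bounds)."""
    if observed.grid != predicted.grid:
        raise ValueError("observed and predicted histograms must share a grid")
    lo, hi = window if window is not None else (0, observed.grid.n_bins - 1)
    if not 0 <= lo <= hi < observed.grid.n_bins:
        raise ValueError(f"window {(lo, hi)} outside grid bounds")
    obs = observed.counts[lo : hi + 1]
    pred = predicted.counts[lo : hi + 1]
    var = np.maximum(obs, 1.0)
    return float(np.sum((obs - pred) ** 2 / var))


def default_fit_window(decay: Histogram, irf: Histogram) -> tuple:
    """From 5 bins before the IRF peak to the last bin with >= 1 count."""
    peak = int(np.argmax(irf.counts))
    lo = max(0, peak - 5)
    nz = np.nonzero(decay.counts >= 1)[0]
    hi = int(nz[-1]) if nz.size else decay.grid.n_bins - 1
    if hi <= lo:
        raise ValueError("empty fit window: decay has no counts after IRF peak")
    return lo, hi


def initial_distance_estimate(
    decay: Histogram, irf: Histogram, params: FretParams
) -> float:
    """Deterministic starting value for the mean donor-acceptor distance.

    Inverts the amplitude-weighted mean decay time through the
    single-distance FRET relation E = 1 - tau_DA/tau_D = 1/(1+(r/R0)^6).
    Crude — it ignores the IRF width and distribution breadth — but places
    the optimizer on the right side of R0.
    """
    t = decay.grid.times
    counts = np.clip(decay.counts - np.median(decay.counts[-50:]), 0.0, None)
    t0 = t[int(np.argmax(irf.counts))]
    tail = t >= t0
    w = counts[tail]
    if w.sum() <= 0:
        return params.rbar1
    tau_obs = float(np.sum((t[tail] - t0) * w) / w.sum())
    donor = params.donor
    tau_d = float(np.sum(donor.fractions * donor.lifetimes**2)
                  / np.sum(donor.fractions * donor.lifetimes))
    eff = 1.0 - tau_obs / tau_d
    eff = min(max(eff, 0.02), 0.98)
    r = params.R0 * (1.0 / eff - 1.0) ** (1.0 / 6.0)
    lo, hi = params.bound("rbar1")
    return float(min(max(r, lo), hi))


# ---------------------------------------------------------------------------
# core optimizer plumbing


def _lmfit_name(name: str, idx: int, shared) -> str:
    return name if name in shared else f"{name}__d{idx}"


def _report_name(name: str, idx: int, shared, n_datasets: int) -> str:
    if name in shared or n_datasets == 1:
        return name
    return f"{name}@{idx}"


def _build_parameters(spec: FitSpec, start=None, extra_fixed=None):
    """Map every FretParams scalar to one lmfit parameter.

    Shared names collapse to a single parameter; everything else is
    namespaced per dataset.  ``start`` overrides starting values and
    ``extra_fixed`` pins named parameters (both keyed by lmfit name).
    """
    start = start or {}
    extra_fixed = extra_fixed or {}
    pars = lmfit.Parameters()
    shared = set(spec.sharing)
    for idx, ds in enumerate(spec.datasets):
        for name in PARAM_NAMES:
            key = _lmfit_name(name, idx, shared)
            if key in pars:
                continue
            value = start.get(key, getattr(ds.params, name))
            vary = ds.params.is_varied(name)
            lo, hi = ds.params.bound(name)
            if key in extra_fixed:
                value, vary = extra_fixed[key], False
            value = min(max(value, lo), hi)
            pars.add(key, value=value, vary=vary, min=lo, max=hi)
    # a component with zero weight contributes nothing: freeze its shape
    # parameters, otherwise their zero Jacobian columns derail the optimizer
    votes: dict = {}
    for idx, ds in enumerate(spec.datasets):
        key_f = _lmfit_name("f_A2", idx, shared)
        inert = ()
        if not pars[key_f].vary:
            if pars[key_f].value == 0.0:
                inert = ("rbar2", "sigma2")
            elif pars[key_f].value == 1.0:
                inert = ("rbar1", "sigma1")
        for name in ("rbar1", "sigma1", "rbar2", "sigma2"):
            key = _lmfit_name(name, idx, shared)
            votes.setdefault(key, []).append(name in inert)
    for key, flags in votes.items():
        if all(flags):
            pars[key].vary = False
    return pars


def _dataset_params(pars, spec: FitSpec, idx: int) -> FretParams:
    shared = set(spec.sharing)
    vals = {n: pars[_lmfit_name(n, idx, shared)].value for n in PARAM_NAMES}
    base = spec.datasets[idx].params
    return base.replace(**vals)


class _Objective:
    def __init__(self, spec: FitSpec):
        self.spec = spec
        self.windows = []
        self.obs = []
        self.weights = []
        self.buffer_curves = []
        self.cost_trace = []
        for ds in spec.datasets:
            window = spec.fit_window or default_fit_window(ds.decay, ds.irf)
            lo, hi = window
            obs = ds.decay.counts[lo : hi + 1]
            self.windows.append(window)
            self.obs.append(obs)
            self.weights.append(1.0 / np.sqrt(np.maximum(obs, 1.0)))
            if ds.buffer is not None:
                self.buffer_curves.append(buffer_intensity(ds.buffer, ds.decay.grid))
            else:
                self.buffer_curves.append(np.zeros(ds.decay.grid.n_bins))

    def predict(self, pars, idx: int) -> Histogram:
        ds = self.spec.datasets[idx]
        p = _dataset_params(pars, self.spec, idx)
        intensity = fret_intensity(p, ds.decay.grid, self.spec.n_nodes)
        return reconvolve(
            ds.irf,
            intensity,
            self.buffer_curves[idx],
            shift_irf=p.shift_irf,
            bkgr_irf=p.bkgr_irf,
            f_B=p.f_B,
            bkgr_dec=p.bkgr_dec,
        )

    def __call__(self, pars):
        res = []
        for idx in range(len(self.spec.datasets)):
            lo, hi = self.windows[idx]
            pred = self.predict(pars, idx).counts[lo : hi + 1]
            res.append((self.obs[idx] - pred) * self.weights[idx])
        out = np.concatenate(res)
        self.cost_trace.append(float(out @ out))
        return out


def _at_bounds(pars) -> list:
    names = []
    for name, p in pars.items():
        if not p.vary:
            continue
        span = (p.max - p.min) if np.isfinite(p.max - p.min) else max(abs(p.value), 1.0)
        tol = 1e-6 * span
        if (np.isfinite(p.min) and p.value - p.min < tol) or (
            np.isfinite(p.max) and p.max - p.value < tol
        ):
            names.append(name)
    return names


def _autoscale_a0(objective: _Objective, pars) -> None:
    """Start A0 so each predicted decay matches its observed total counts."""
    for idx in range(len(objective.spec.datasets)):
        key = _lmfit_name("A0", idx, set(objective.spec.sharing))
        if not pars[key].vary:
            continue
        lo, hi = objective.windows[idx]
        pred = objective.predict(pars, idx).counts[lo : hi + 1]
        p = _dataset_params(pars, objective.spec, idx)
        base = p.bkgr_dec
        num = float(np.sum(objective.obs[idx] - base))
        den = float(np.sum(pred - base))
        if den > 0 and num > 0:
            pars[key].value = min(
                max(pars[key].value * num / den, pars[key].min), pars[key].max
            )


def _minimize(spec: FitSpec, start=None, extra_fixed=None, autoscale=True):
    objective = _Objective(spec)
    pars = _build_parameters(spec, start=start, extra_fixed=extra_fixed)
    if autoscale:
        _autoscale_a0(objective, pars)
    result = lmfit.minimize(
        objective,
        pars,
        method="least_squares",
        x_scale="jac",
        diff_step=1e-4,
        ftol=1e-7,
        xtol=1e-7,
        gtol=1e-7,
        max_nfev=3000,
    )
    return result, objective


def _package_result(result, objective: _Objective, spec: FitSpec) -> FitResult:
    pars = result.params
    n_datasets = len(spec.datasets)
    shared = set(spec.sharing)
    estimates, stderr = {}, {}
    for idx in range(n_datasets):
        for name in PARAM_NAMES:
            key = _lmfit_name(name, idx, shared)
            rname = _report_name(name, idx, shared, n_datasets)
            estimates[rname] = pars[key].value
            stderr[rname] = (
                pars[key].stderr if pars[key].stderr is not None else float("nan")
            )
    params_by_dataset = [
        _dataset_params(pars, spec, idx) for idx in range(n_datasets)
    ]
    predictions, residuals = [], []
    chisq = 0.0
    nbins = 0
    for idx in range(n_datasets):
        pred = objective.predict(pars, idx)
        lo, hi = objective.windows[idx]
        r = (objective.obs[idx] - pred.counts[lo : hi + 1]) * objective.weights[idx]
        predictions.append(pred)
        residuals.append(r)
        chisq += float(r @ r)
        nbins += r.size
    dof = nbins - result.nvarys
    return FitResult(
        estimates=estimates,
        stderr=stderr,
        params_by_dataset=params_by_dataset,
        redchi=chisq / dof if dof > 0 else float("nan"),
        chisqr=chisq,
        dof=dof,
        residuals=residuals,
        predictions=predictions,
        windows=list(objective.windows),
        success=bool(result.success),
        message=str(result.message),
        at_bounds=_at_bounds(pars),
        cost_trace=np.asarray(objective.cost_trace),
        nfev=int(result.nfev),
    )


def _canonicalize(fit: FitResult, spec: FitSpec) -> FitResult:
    """Relabel Gaussian components so that rbar1 >= rbar2.

    Exchanging the two components while replacing f_A2 by 1 - f_A2 is an
    exact symmetry of the single-acceptor model, so fits can converge to
    either labelling.  The swap is applied only when it is a symmetry:
    no tied intersubunit rho2 block and f_A2 free.
    """
    if any(ds.params.rho2 is not None for ds in spec.datasets):
        return fit
    if not all(ds.params.is_varied("f_A2") for ds in spec.datasets):
        return fit
    if not all(
        ds.params.is_varied(n)
        for ds in spec.datasets
        for n in ("rbar1", "rbar2")
    ):
        return fit
    shared = set(spec.sharing)
    n = len(spec.datasets)
    est, err = dict(fit.estimates), dict(fit.stderr)
    # group datasets that share one rbar1 parameter: one swap decision each
    groups: dict = {}
    for idx in range(n):
        groups.setdefault(_report_name("rbar1", idx, shared, n), []).append(idx)
    for key_r1, members in groups.items():
        idx0 = members[0]
        if est[key_r1] >= est[_report_name("rbar2", idx0, shared, n)]:
            continue
        seen = set()
        for i in members:
            for a, b in (("rbar1", "rbar2"), ("sigma1", "sigma2")):
                ka, kb = _report_name(a, i, shared, n), _report_name(b, i, shared, n)
                if ka in seen:
                    continue
                seen.add(ka)
                est[ka], est[kb] = est[kb], est[ka]
                err[ka], err[kb] = err[kb], err[ka]
            kf = _report_name("f_A2", i, shared, n)
            if kf not in seen:
                seen.add(kf)
                est[kf] = 1.0 - est[kf]
    fit.estimates, fit.stderr = est, err
    fit.params_by_dataset = [
        p.replace(
            rbar1=est[_report_name("rbar1", i, shared, n)],
            sigma1=est[_report_name("sigma1", i, shared, n)],
            rbar2=est[_report_name("rbar2", i, shared, n)],
            sigma2=est[_report_name("sigma2", i, shared, n)],
            f_A2=est[_report_name("f_A2", i, shared, n)],
        )
        for i, p in enumerate(fit.params_by_dataset)
    ]
    return fit


def _mirror_restart(best: FitResult, spec: FitSpec) -> FitResult:
    """Re-optimize from the component-exchanged solution for rho2-tied fits.

    With a tied intersubunit block the 1<->2 exchange is *not* a symmetry,
    but the two labellings sit in separate basins of similar depth; if the
    optimizer settled in the swapped one (rbar1 < rbar2 against the
    resting/active convention of the fixed rho2 block), restart from the
    mirrored point and keep the better solution.
    """
    if not any(ds.params.rho2 is not None for ds in spec.datasets):
        return best
    shared = set(spec.sharing)
    n = len(spec.datasets)
    free = lambda name: all(ds.params.is_varied(name) for ds in spec.datasets)
    if not (free("f_A2") and free("rbar1") and free("rbar2")):
        return best
    swapped_any = False
    start = {}
    for idx in range(n):
        rname = lambda name: _report_name(name, idx, shared, n)
        kname = lambda name: _lmfit_name(name, idx, shared)
        r1, r2 = best.estimates[rname("rbar1")], best.estimates[rname("rbar2")]
        if r1 >= r2:
            for name in PARAM_NAMES:
                start.setdefault(kname(name), best.estimates[rname(name)])
            continue
        swapped_any = True
        start[kname("rbar1")] = r2
        start[kname("rbar2")] = r1
        start[kname("sigma1")] = best.estimates[rname("sigma2")]
        start[kname("sigma2")] = best.estimates[rname("sigma1")]
        start[kname("f_A2")] = 1.0 - best.estimates[rname("f_A2")]
        for name in PARAM_NAMES:
            start.setdefault(kname(name), best.estimates[rname(name)])
    if not swapped_any:
        return best
    result, objective = _minimize(spec, start=start, autoscale=False)
    cand = _package_result(result, objective, spec)
    return cand if cand.chisqr < best.chisqr else best


def _needs_multistart(spec: FitSpec) -> bool:
    """Restarts only pay off when both Gaussian components are in play."""
    ds0 = spec.datasets[0].params
    two_gauss = ds0.is_varied("f_A2") or (0.0 < ds0.f_A2 < 1.0)
    distance_free = any(
        ds.params.is_varied(n)
        for ds in spec.datasets
        for n in ("rbar1", "rbar2", "sigma1", "sigma2")
    )
    return two_gauss and distance_free


def _staged_start(spec: FitSpec) -> dict:
    """Starting values for a global fit from independent single-dataset fits.

    Each dataset is first fit on its own; shared parameters start from the
    median of the per-dataset estimates, everything else from its own fit.
    Far more robust than launching a high-dimensional global fit from cold
    heuristic starts.
    """
    shared = set(spec.sharing)
    singles = []
    for ds in spec.datasets:
        sub = FitSpec(datasets=[ds], sharing=(), fit_window=spec.fit_window,
                      n_nodes=spec.n_nodes)
        singles.append(_fit_spec(sub))
    start = {}
    for name in PARAM_NAMES:
        if name in shared:
            start[name] = float(np.median([s.estimates[name] for s in singles]))
        else:
            for i, s in enumerate(singles):
                start[f"{name}__d{i}"] = s.estimates[name]
    return start


def _fit_spec(spec: FitSpec, multistart: Optional[bool] = None) -> FitResult:
    """Run the optimization, with deterministic jittered restarts for
    two-Gaussian fits that land on a poor local minimum.

    Multi-dataset specs are staged: single-dataset fits supply the starting
    point of the joint optimization."""
    if multistart is None:
        multistart = _needs_multistart(spec)
    if len(spec.datasets) > 1:
        result, objective = _minimize(
            spec, start=_staged_start(spec), autoscale=False
        )
    else:
        result, objective = _minimize(spec)
    best = _package_result(result, objective, spec)

    def accepted(fit):
        return fit.success and fit.redchi < _RESTART_REDCHI

    if not multistart or accepted(best):
        return _canonicalize(_mirror_restart(best, spec), spec)
    shared = set(spec.sharing)
    n = len(spec.datasets)
    for jitter in _RESTART_JITTERS:
        # restart from the best solution so far with perturbed distances
        start = {}
        for idx in range(n):
            for name in PARAM_NAMES:
                key = _lmfit_name(name, idx, shared)
                value = best.estimates[_report_name(name, idx, shared, n)]
                start[key] = value * jitter.get(name, 1.0)
        result, objective = _minimize(spec, start=start, autoscale=False)
        cand = _package_result(result, objective, spec)
        if cand.chisqr < best.chisqr:
            best = cand
        if accepted(best):
            break
    return _canonicalize(_mirror_restart(best, spec), spec)


# ---------------------------------------------------------------------------
# protocol-level entry points


def _check_protocol(params: FretParams, allowed: set, label: str, override: bool):
    free = {n for n in PARAM_NAMES if params.is_varied(n)}
    extra = free - allowed
    if extra and not override:
        raise ValueError(
            f"{label} protocol does not free {sorted(extra)}; "
            "pass allow_nonstandard=True to override"
        )


def fit_buffer(
    buffer_decay: Histogram,
    irf: Histogram,
    n_components: int = 2,
    fit_window: Optional[tuple] = None,
) -> tuple:
    """Fit the buffer-only decay with up to four reconvolved exponentials.

    Returns ``(BufferModel, FitResult)``; the model is meant to be frozen and
    handed to the sample fits.  Degenerate inputs (e.g. a flat, featureless
    buffer) converge with near-zero amplitudes or lifetimes pinned at a
    bound, reported through ``FitResult.at_bounds`` / ``flagged``.
    """
    if not 1 <= n_components <= 4:
        raise ValueError("n_components must be in 1..4")
    if buffer_decay.grid != irf.grid:
        raise ValueError("buffer decay and IRF must share one time grid")
    window = fit_window or default_fit_window(buffer_decay, irf)
    lo, hi = window
    obs = buffer_decay.counts[lo : hi + 1]
    weights = 1.0 / np.sqrt(np.maximum(obs, 1.0))
    peak = max(float(buffer_decay.counts.max()), 1.0)

    pars = lmfit.Parameters()
    taus = np.geomspace(0.5, 8.0, n_components)
    for i in range(n_components):
        pars.add(f"alpha{i}", value=peak / n_components, min=0.0, max=100 * peak)
        pars.add(f"tau{i}", value=taus[i], min=0.05, max=50.0)
    pars.add("shift_irf", value=0.0, min=-2000.0, max=2000.0)
    pars.add("bkgr_dec", value=float(np.median(obs[-20:])), min=0.0, max=peak)

    grid = buffer_decay.grid
    trace = []

    def predict(p):
        model = BufferModel(
            tuple((p[f"alpha{i}"].value, p[f"tau{i}"].value) for i in range(n_components))
        )
        curve = buffer_intensity(model, grid)
        return reconvolve(
            irf, curve, np.zeros(grid.n_bins),
            shift_irf=p["shift_irf"].value, bkgr_dec=p["bkgr_dec"].value,
        )

    def residual(p):
        r = (obs - predict(p).counts[lo : hi + 1]) * weights
        trace.append(float(r @ r))
        return r

    result = lmfit.minimize(residual, pars, method="least_squares", x_scale="jac")
    p = result.params
    model = BufferModel(
        tuple((p[f"alpha{i}"].value, p[f"tau{i}"].value) for i in range(n_components))
    )
    pred = predict(p)
    r = (obs - pred.counts[lo : hi + 1]) * weights
    dof = r.size - result.nvarys
    estimates = {k: v.value for k, v in p.items()}
    stderr = {k: (v.stderr if v.stderr is not None else float("nan")) for k, v in p.items()}
    fit = FitResult(
        estimates=estimates,
        stderr=stderr,
        params_by_dataset=[],
        redchi=float(r @ r) / dof if dof > 0 else float("nan"),
        chisqr=float(r @ r),
        dof=dof,
        residuals=[r],
        predictions=[pred],
        windows=[window],
        success=bool(result.success),
        message=str(result.message),
        at_bounds=_at_bounds(p),
        cost_trace=np.asarray(trace),
        nfev=int(result.nfev),
    )
    return model, fit


def fit_donor_only(
    decay: Histogram,
    irf: Histogram,
    buffer: Optional[BufferModel],
    params: FretParams,
    fit_window: Optional[tuple] = None,
    allow_nonstandard: bool = False,
    n_nodes: int = 101,
) -> FitResult:
    """Donor-only protocol fit: ``f_D`` pinned at 1, only the donor
    lifetimes/fraction, IRF shift, amplitude and background vary.

    The recovered ``tau_D1, alpha_D1, tau_D2`` are meant to be frozen in all
    subsequent donor+acceptor fits of the same sample.
    """
    _check_protocol(params, _DONOR_FREE, "donor-only", allow_nonstandard)
    params = params.replace(f_D=1.0, bkgr_irf=0.0)
    spec = FitSpec(
        datasets=[Dataset(decay, irf, buffer, params)],
        fit_window=fit_window,
        n_nodes=n_nodes,
    )
    fit = _fit_spec(spec, multistart=False)
    # canonical labelling: component 1 carries the longer donor lifetime
    if params.is_varied("tau_D1") and params.is_varied("tau_D2"):
        est, err = fit.estimates, fit.stderr
        if est["tau_D1"] < est["tau_D2"]:
            est["tau_D1"], est["tau_D2"] = est["tau_D2"], est["tau_D1"]
            err["tau_D1"], err["tau_D2"] = err["tau_D2"], err["tau_D1"]
            est["alpha_D1"] = 1.0 - est["alpha_D1"]
            fit.params_by_dataset = [
                p.replace(
                    tau_D1=est["tau_D1"],
                    tau_D2=est["tau_D2"],
                    alpha_D1=est["alpha_D1"],
                )
                for p in fit.params_by_dataset
            ]
    return fit


def fit_decay(
    decay: Histogram,
    irf: Histogram,
    buffer: Optional[BufferModel],
    params: FretParams,
    fit_window: Optional[tuple] = None,
    allow_nonstandard: bool = False,
    n_nodes: int = 101,
    multistart: Optional[bool] = None,
) -> FitResult:
    """Donor+acceptor protocol fit of a single decay.

    Donor lifetimes, ``R0``, ``f_B`` and ``bkgr_irf`` stay fixed; any subset
    of ``f_D, rbar1, sigma1, f_A2, rbar2, sigma2, shift_irf, A0, bkgr_dec``
    may vary per ``params.vary``.  When ``params.rho2`` is present the
    two-acceptor (intersubunit) model is used with the second distribution's
    means/stdevs fixed and its mixing fraction tied to ``f_A2``.
    """
    _check_protocol(params, _PROTOCOL_FREE, "donor+acceptor", allow_nonstandard)
    params = params.replace(bkgr_irf=0.0)
    spec = FitSpec(
        datasets=[Dataset(decay, irf, buffer, params)],
        fit_window=fit_window,
        n_nodes=n_nodes,
    )
    return _fit_spec(spec, multistart=multistart)


def fit_global(spec: FitSpec, multistart: Optional[bool] = None) -> FitResult:
    """Global fit of several decays with shared parameters constrained equal.

    Sharing is by parameter name across all datasets in the spec; shared
    parameters report a single estimate, everything else one per dataset.
    """
    if len(spec.datasets) < 2:
        raise ValueError("global fit needs at least 2 datasets")
    return _fit_spec(spec, multistart=multistart)


def _profile_point(spec: FitSpec, fixed: dict, start: Optional[dict]):
    result, objective = _minimize(spec, start=start, extra_fixed=fixed, autoscale=False)
    return _package_result(result, objective, spec), result.params


def _free_lmfit_keys(spec: FitSpec, name: str) -> list:
    shared = set(spec.sharing)
    keys = []
    for idx, ds in enumerate(spec.datasets):
        key = _lmfit_name(name, idx, shared)
        if key not in keys:
            if not ds.params.is_varied(name):
                raise ValueError(f"parameter {name!r} is fixed; profile a free parameter")
            keys.append(key)
    return keys


def _optimum_start(spec: FitSpec) -> dict:
    """Starting values (by lmfit name) taken from the unconstrained fit."""
    fit = _fit_spec(spec)
    shared = set(spec.sharing)
    n = len(spec.datasets)
    start = {}
    for idx in range(n):
        for name in PARAM_NAMES:
            start[_lmfit_name(name, idx, shared)] = fit.estimates[
                _report_name(name, idx, shared, n)
            ]
    return start


def _best_profile_point(spec, fixed, starts):
    """Re-optimize the free parameters at one profile point, trying each
    candidate start and keeping the lowest chi-square."""
    best = None
    best_pars = None
    for start in starts:
        if start is None:
            continue
        fit, pars = _profile_point(spec, fixed, start)
        if best is None or fit.chisqr < best.chisqr:
            best, best_pars = fit, pars
    return best, best_pars


def chi2_profile(spec: FitSpec, parameter_name: str, values) -> ProfileResult:
    """Reduced chi-square profile: fix one parameter on a grid of values and
    re-optimize all remaining free parameters at each grid point.

    Each point is optimized from two starts — the previous grid point's
    solution and the unconstrained optimum — and keeps the better, which
    guards the profile against ratcheting into local minima along the scan.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("profile needs a non-empty grid of values")
    keys = _free_lmfit_keys(spec, parameter_name)
    base = _optimum_start(spec)
    redchi = np.empty(values.size)
    warm = None
    for i, v in enumerate(values):
        fixed = {k: float(v) for k in keys}
        fit, pars = _best_profile_point(spec, fixed, [base, warm])
        redchi[i] = fit.redchi
        warm = {k: p.value for k, p in pars.items()}
    return ProfileResult(parameter=parameter_name, values=values, redchi=redchi)


def chi2_surface(spec: FitSpec, parameter_pair, values_x, values_y) -> SurfaceResult:
    """2-D analogue of :func:`chi2_profile` over a parameter-pair grid."""
    name_x, name_y = parameter_pair
    values_x = np.asarray(values_x, dtype=float)
    values_y = np.asarray(values_y, dtype=float)
    if values_x.size == 0 or values_y.size == 0:
        raise ValueError("surface needs non-empty grids")
    keys_x = _free_lmfit_keys(spec, name_x)
    keys_y = _free_lmfit_keys(spec, name_y)
    base = _optimum_start(spec)
    redchi = np.empty((values_x.size, values_y.size))
    row_start = None
    for i, vx in enumerate(values_x):
        warm = row_start
        for j, vy in enumerate(values_y):
            fixed = {k: float(vx) for k in keys_x}
            fixed.update({k: float(vy) for k in keys_y})
            fit, pars = _best_profile_point(spec, fixed, [base, warm])
            redchi[i, j] = fit.redchi
            warm = {k: p.value for k, p in pars.items()}
            if j == 0:
                row_start = dict(warm)
    return SurfaceResult(
        parameters=(name_x, name_y), values_x=values_x, values_y=values_y, redchi=redchi
    )
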