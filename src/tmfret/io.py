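"""Plain-text file formats: histograms, scenario bundles, fit reports.

Histograms are two-column delimited text (time in ns, photon counts) with
``#``-prefixed ``key: value`` header lines carrying the role, condition
label and acquisition duration.  Bundles are a directory of histogram files
plus a YAML manifest; fit reports are JSON with the full effective
configuration, and curves/residuals go to CSV.  Proprietary instrument
binary formats are deliberately not parsed — export to text first.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .decay_model import Histogram, TimeGrid, distance_density

__all__ = [
    "ParseError",
    "read_histogram",
    "write_histogram",
    "read_manifest",
    "write_scenario",
    "load_bundle",
    "write_fit_report",
    "write_distance_curve",
]

_FORMAT_TAG = "tmfret-histogram v1"


class ParseError(ValueError):
    """Malformed histogram file; the message names the offending line."""


def write_histogram(hist: Histogram, path, dialect: str = "csv") -> Path:
    """Write a histogram as delimited text with ``#`` metadata headers."""
    sep = "," if dialect == "csv" else "\t"
    path = Path(path)
    lines = [
        f"# {_FORMAT_TAG}",
        f"# role: {hist.role}",
        f"# condition: {hist.condition_label}",
    ]
    if hist.acquisition_duration is not None:
        lines.append(f"# acquisition_duration_s: {hist.acquisition_duration!r}")
    t = hist.grid.times
    integral = np.allclose(hist.counts, np.round(hist.counts))
    for ti, ci in zip(t, hist.counts):
        c = f"{int(round(ci))}" if integral else f"{ci!r}"
        lines.append(f"{ti:.9g}{sep}{c}")
    path.write_text("\n".join(lines) + "\n")
    return path


def read_histogram(path, dialect: Optional[str] = None) -> Histogram:
    """Parse a two-column delimited histogram file.

    ``dialect`` is ``"csv"`` or ``"tsv"``; when omitted the delimiter is
    sniffed from the first data line.  Bins must be uniform to 1e-9 relative
    and counts non-negative; violations raise :class:`ParseError` naming the
    line number.
    """
    path = Path(path)
    meta: dict = {}
    times, counts = [], []
    sep = {"csv": ",", "tsv": "\t"}.get(dialect)
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line[1:].strip()
            if ":" in body:
                key, _, value = body.partition(":")
                meta[key.strip()] = value.strip()
            continue
        if sep is None:
            sep = "\t" if "\t" in line else ","
        parts = line.split(sep)
        if len(parts) != 2:
            raise ParseError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
        try:
            t = float(parts[0])
            c = float(parts[1])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-numeric value ({exc})") from None
        if c < 0:
            raise ParseError(f"{path}:{lineno}: negative count {c}")
        times.append(t)
        counts.append(c)
    if len(times) < 2:
        raise ParseError(f"{path}: fewer than 2 data rows")
    t_arr = np.asarray(times)
    dt = np.diff(t_arr)
    width = (t_arr[-1] - t_arr[0]) / (len(times) - 1)
    # snap to 12 significant digits so decimal bin widths round-trip exactly
    width = float(np.format_float_positional(width, precision=12, fractional=False))
    if width <= 0 or np.any(np.abs(dt - width) > 1e-9 * max(abs(width), 1.0)):
        bad = int(np.argmax(np.abs(dt - width))) + 2
        raise ParseError(f"{path}: non-uniform time bins near data row {bad}")
    role = meta.get("role")
    if role is None:
        raise ParseError(f"{path}: missing '# role:' metadata header")
    acq = meta.get("acquisition_duration_s")
    if role in ("decay", "buffer") and acq is None:
        raise ParseError(
            f"{path}: role {role!r} requires '# acquisition_duration_s:' metadata"
        )
    grid = TimeGrid(bin_width=width, n_bins=len(times), origin=float(t_arr[0]))
    return Histogram(
        grid=grid,
        counts=np.asarray(counts),
        role=role,
        acquisition_duration=float(acq) if acq is not None else None,
        condition_label=meta.get("condition", ""),
        metadata={k: v for k, v in meta.items() if k not in
                  ("role", "condition", "acquisition_duration_s")},
    )


def read_manifest(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def write_scenario(scenario, outdir) -> Path:
    """Write a synthetic bundle: one file per histogram plus manifest.yaml."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = scenario.manifest()
    manifest["files"] = {
        "irf": "irf.csv",
        "buffer": "buffer.csv",
        "decays": {},
    }
    write_histogram(scenario.irf, outdir / "irf.csv")
    write_histogram(scenario.buffer_decay, outdir / "buffer.csv")
    for label, hist in scenario.decays.items():
        fname = f"decay_{label}.csv"
        write_histogram(hist, outdir / fname)
        manifest["files"]["decays"][label] = fname
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return outdir


def load_bundle(bundle_dir):
    """Read a bundle directory back: (manifest, decays, irf, buffer_decay)."""
    bundle_dir = Path(bundle_dir)
    manifest = read_manifest(bundle_dir / "manifest.yaml")
    files = manifest["files"]
    irf = read_histogram(bundle_dir / files["irf"])
    buffer_decay = read_histogram(bundle_dir / files["buffer"])
    decays = {
        label: read_histogram(bundle_dir / fname)
        for label, fname in files["decays"].items()
    }
    return manifest, decays, irf, buffer_decay


def write_fit_report(fit, path, config: Optional[dict] = None) -> Path:
    """JSON fit report: estimates, uncertainties, chi-square, free/fixed map
    and the full effective configuration needed to re-run the fit."""
    path = Path(path)
    vary_maps = [dict(p.vary) for p in fit.params_by_dataset]
    report = {
        "estimates": {k: float(v) for k, v in fit.estimates.items()},
        "stderr": {k: (None if np.isnan(v) else float(v)) for k, v in fit.stderr.items()},
        "reduced_chi2": float(fit.redchi),
        "chi2": float(fit.chisqr),
        "degrees_of_freedom": int(fit.dof),
        "success": bool(fit.success),
        "message": fit.message,
        "parameters_at_bounds": list(fit.at_bounds),
        "n_function_evals": int(fit.nfev),
        "fit_windows": [list(map(int, w)) for w in fit.windows],
        "vary": vary_maps,
        "config": config or {},
    }
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(report, indent=2) + "\n")
    return path


def write_residual_tables(fit, outdir, labels=None) -> list:
    """Per-dataset CSV of time, observed, predicted, weighted residual."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for idx, pred in enumerate(fit.predictions):
        lo, hi = fit.windows[idx]
        t = pred.grid.times[lo : hi + 1]
        label = labels[idx] if labels else str(idx)
        df = pd.DataFrame(
            {
                "time_ns": t,
                "predicted": pred.counts[lo : hi + 1],
                "weighted_residual": fit.residuals[idx],
            }
        )
        p = outdir / f"residuals_{label}.csv"
        df.to_csv(p, index=False)
        paths.append(p)
    return paths


def write_distance_curve(params, path, r_min: float = 10.0, r_max: float = 80.0,
                         n: int = 701) -> Path:
    """CSV of the fitted distance density rho(r) sampled on [r_min, r_max]."""
    r = np.linspace(r_min, r_max, n)
    rho = distance_density(params.rho1, r)
    df = pd.DataFrame({"r_angstrom": r, "density_per_angstrom": rho})
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path
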