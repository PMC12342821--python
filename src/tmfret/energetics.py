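"""Conformational free energies and ligand dose-response fits.

The two Gaussian components of the fitted distance distribution represent
the resting and active conformations of the protein; the active-state
fraction ``f_A2`` is Boltzmann-related to the free energy of the
resting-to-active transition,

    dG = -R T ln( f_A2 / (1 - f_A2) ),

and the ligand effect on the equilibrium is the difference
``ddG = dG(ligand) - dG(apo)``.  Titrations of ``f_A2`` against total ligand
are fit with the quadratic tight-binding isotherm, which accounts for ligand
depletion by the protein itself (important when protein and K_D are of
comparable magnitude).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import lmfit

__all__ = [
    "GAS_CONSTANT_KCAL",
    "EnergeticsConfig",
    "DoseResponseParams",
    "delta_g",
    "delta_delta_g",
    "fraction_from_delta_g",
    "dose_response_value",
    "fit_dose_response",
]

#: Universal gas constant in kcal mol^-1 K^-1.
GAS_CONSTANT_KCAL = 1.9872e-3


@dataclass(frozen=True)
class EnergeticsConfig:
    """Thermodynamic constants: R (kcal/mol/K) and temperature (K)."""

    gas_constant: float = GAS_CONSTANT_KCAL
    temperature: float = 298.15

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0 K")

    @property
    def rt(self) -> float:
        return self.gas_constant * self.temperature


@dataclass
class DoseResponseParams:
    """Quadratic tight-binding dose-response parameters.

    K_D and concentrations in uM; ``A`` and ``B`` are the active-state
    fractions at saturating and zero ligand.
    """

    K_D: float
    P_total: float
    A: float
    B: float
    stderr: dict = field(default_factory=dict)
    redchi: float = float("nan")
    identifiable: bool = True

    def __post_init__(self) -> None:
        if self.K_D <= 0:
            raise ValueError("K_D must be > 0")
        if self.P_total < 0:
            raise ValueError("P_total must be >= 0")
        for name in ("A", "B"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


def delta_g(f_A2: float, config: EnergeticsConfig = EnergeticsConfig()) -> float:
    """Free energy (kcal/mol) of the resting-to-active transition.

    Strictly decreasing in ``f_A2`` and antisymmetric about f_A2 = 0.5;
    diverges at the endpoints, which are therefore rejected.
    """
    if not 0.0 < f_A2 < 1.0:
        raise ValueError("f_A2 must lie strictly inside (0, 1)")
    return -config.rt * np.log(f_A2 / (1.0 - f_A2))


def fraction_from_delta_g(
    dg: float, config: EnergeticsConfig = EnergeticsConfig()
) -> float:
    """Inverse of :func:`delta_g`: the active-state fraction at a given dG."""
    return 1.0 / (1.0 + np.exp(dg / config.rt))


def delta_delta_g(dg_ligand: float, dg_apo: float) -> float:
    """Ligand-induced shift of the conformational free energy (kcal/mol)."""
    if not (np.isfinite(dg_ligand) and np.isfinite(dg_apo)):
        raise ValueError("both free energies must be finite")
    return dg_ligand - dg_apo


def dose_response_value(params: DoseResponseParams, L_total) -> np.ndarray:
    """Fractional response at total ligand concentration(s) ``L_total`` (uM).

    Evaluates the quadratic tight-binding isotherm

        (A - B) * ((L+P+K) - sqrt((L+P+K)^2 - 4 P L)) / (2 P) + B

    through the algebraically equivalent form
    ``(A - B) * 2L / ((L+P+K) + sqrt((L+P+K)^2 - 4 P L)) + B``, which avoids
    catastrophic cancellation for small P and reduces smoothly to the
    hyperbolic binding curve B + (A-B) L/(L+K) as P -> 0.
    """
    L = np.asarray(L_total, dtype=float)
    if np.any(L < 0):
        raise ValueError("ligand concentrations must be >= 0")
    s = L + params.P_total + params.K_D
    disc = np.sqrt(np.clip(s * s - 4.0 * params.P_total * L, 0.0, None))
    bound = 2.0 * L / (s + disc)
    out = (params.A - params.B) * bound + params.B
    return out if out.shape else float(out)


def fit_dose_response(
    concentrations,
    f_A2_values,
    fix: dict | None = None,
    config: EnergeticsConfig = EnergeticsConfig(),
) -> DoseResponseParams:
    """Least-squares fit of the tight-binding isotherm to an f_A2 titration.

    ``fix`` maps parameter names (K_D, P_total, A, B) to fixed values.  Needs
    at least as many points as free parameters and at least 4 points overall,
    spanning zero and a near-saturating ligand concentration.  Flat data
    (no ligand dependence) are flagged via ``identifiable=False`` rather than
    raised.
    """
    L = np.asarray(concentrations, dtype=float)
    y = np.asarray(f_A2_values, dtype=float)
    if L.shape != y.shape or L.ndim != 1:
        raise ValueError("concentrations and f_A2 values must be 1-D and matched")
    fix = dict(fix or {})
    free = [n for n in ("K_D", "P_total", "A", "B") if n not in fix]
    if L.size < 4 or L.size < len(free):
        raise ValueError("need >= 4 points and at least as many points as free parameters")

    pars = lmfit.Parameters()
    span = max(L.max(), 1.0)
    pars.add("K_D", value=fix.get("K_D", np.median(L[L > 0]) if np.any(L > 0) else 1.0),
             min=1e-6, max=10 * span, vary="K_D" not in fix)
    pars.add("P_total", value=fix.get("P_total", 0.01 * span),
             min=0.0, max=10 * span, vary="P_total" not in fix)
    pars.add("A", value=fix.get("A", float(y[np.argmax(L)])), min=0.0, max=1.0,
             vary="A" not in fix)
    pars.add("B", value=fix.get("B", float(y[np.argmin(L)])), min=0.0, max=1.0,
             vary="B" not in fix)

    def residual(p):
        dr = DoseResponseParams(
            K_D=max(p["K_D"].value, 1e-12),
            P_total=p["P_total"].value,
            A=p["A"].value,
            B=p["B"].value,
        )
        return dose_response_value(dr, L) - y

    result = lmfit.minimize(residual, pars, method="least_squares")
    vals = result.params
    identifiable = True
    if abs(vals["A"].value - vals["B"].value) < 1e-3 * max(1.0, abs(vals["A"].value)):
        identifiable = False  # no ligand dependence: K_D is unconstrained
    stderr = {
        n: (vals[n].stderr if vals[n].stderr is not None else float("nan"))
        for n in ("K_D", "P_total", "A", "B")
    }
    return DoseResponseParams(
        K_D=vals["K_D"].value,
        P_total=vals["P_total"].value,
        A=min(max(vals["A"].value, 0.0), 1.0),
        B=min(max(vals["B"].value, 0.0), 1.0),
        stderr=stderr,
        redchi=float(result.redchi) if result.ndata > result.nvarys else float("nan"),
        identifiable=identifiable,
    )
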