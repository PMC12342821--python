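# tmfret

Time-domain transition metal ion FRET (tmFRET) analysis: simulate and fit
TCSPC fluorescence-decay histograms with a reconvolution FRET model whose
donor–acceptor distances follow one or two Gaussian distributions, then
convert the fitted state occupancies into conformational free energies and
ligand dose–response parameters.

## The problem

Time-correlated single photon counting (TCSPC) records a histogram of photon
arrival times after pulsed excitation of a donor fluorophore.  When a
short-R0 metal-ion acceptor (tmFRET) sits 20–60 Å away, energy transfer adds
a rate `(R0/r)^6 / τ_D` to every donor decay component, so the decay shape
encodes the *distribution* of donor–acceptor distances — and therefore the
mixture of conformational states of the labelled protein.  The package was
built around a cyclic nucleotide-binding domain (CNBD) system: an
acridonylalanine donor (lifetimes 17.6 ns / 4.73 ns, 87 % / 13 % amplitude)
paired with a Ru-complex acceptor (R0 = 43.5 Å), where the resting and
active conformations of the C-helix give two distinct Gaussian distance
components and the active-state fraction `f_A2` shifts with cAMP.

The measured decay is modelled as

    Decay(t) = [IRF(t − shift) − bkgr_irf] ⊛ [I_DA(t) + f_B·I_B(t)] + bkgr_dec

with the donor-in-presence-of-acceptor intensity

    I_DA(t) = A0 [ f_D Σᵢ αᵢ e^(−t/τᵢ)
                 + (1−f_D) ∫ ρ(r) Σᵢ αᵢ e^(−t/τᵢ − (t/τᵢ)(R0/r)^6) dr ]

where `ρ(r)` is a one- or two-Gaussian distance density (`r̄₁, σ₁, f_A2,
r̄₂, σ₂`).  For homotetramers with acceptors on neighbouring subunits, a
second independent acceptor distance `ρ₂(r₂)` multiplies in an extra
transfer factor; the double integral factorizes into a product of 1-D
integrals per donor component, with ρ₂'s mixing fraction tied to `f_A2`.

Fits minimize the Poisson-weighted χ², `Σ (obs − pred)² / max(obs, 1)`,
singly or globally across ligand conditions and protein constructs with
selected parameters shared.  Fitted occupancies map to free energies by the
Boltzmann relation

    ΔG = −RT ln( f_A2 / (1 − f_A2) ),    ΔΔG = ΔG_ligand − ΔG_apo

and titrations of `f_A2` against total ligand are fit with the quadratic
tight-binding isotherm (explicit ligand depletion by protein).

## Worked example

Simulate a two-condition intrasubunit experiment at 5×10⁶ photons per decay
and refit it with the standard protocol (donor lifetimes, R0, buffer scaling
fixed; distances shared across conditions; `f_A2` free per condition):

```python
from tmfret import TimeGrid, synthetic, fitting
from tmfret import energetics as en

grid = TimeGrid(bin_width=0.05, n_bins=1024)
scenario = synthetic.make_scenario(
    "intrasubunit", seed=3, grid=grid, total_counts=5e6,
    conditions=[("apo", 0.08), ("cAMP", 0.96)],
)
buffer_model, _ = fitting.fit_buffer(scenario.buffer_decay, scenario.irf,
                                     n_components=2)

datasets = []
for label, _ in scenario.conditions:
    start = scenario.true_params[label].replace(
        f_D=0.1, rbar1=45.0, sigma1=3.0, f_A2=0.5, rbar2=33.0, sigma2=3.0,
        A0=1.0, bkgr_dec=1.0,
        vary={n: True for n in ("f_D", "rbar1", "sigma1", "f_A2", "rbar2",
                                "sigma2", "shift_irf", "A0", "bkgr_dec")},
    )
    datasets.append(fitting.Dataset(scenario.decays[label], scenario.irf,
                                    buffer_model, start, label=label))

fit = fitting.fit_global(fitting.FitSpec(
    datasets=datasets, sharing=("rbar1", "sigma1", "rbar2", "sigma2", "f_D"),
))
f_apo, f_sat = fit.estimates["f_A2@0"], fit.estimates["f_A2@1"]
dg_apo, dg_sat = en.delta_g(f_apo), en.delta_g(f_sat)
```

Output:

```
reduced chi2  : 0.979
resting state : rbar = 41.7 A, sigma = 2.3 A
active state  : rbar = 28.8 A, sigma = 2.1 A
f_A2          : apo = 0.080, cAMP = 0.960
dG            : apo = +1.45, cAMP = -1.89 kcal/mol
ddG(cAMP)     : -3.34 kcal/mol
```

The fit recovers the generating distance parameters (41.7/2.3 Å resting,
28.8/2.1 Å active) and occupancies (0.08 apo, 0.96 at saturating cAMP) with
a reduced χ² near 1, as expected for pure shot noise.  The ΔG values say the
resting→active transition is unfavourable without ligand (+1.45 kcal/mol)
and favourable at saturating cAMP (−1.89 kcal/mol); the ΔΔG of
−3.34 kcal/mol is the ligand's energetic drive on the conformational
equilibrium.

The same pipeline is available from the shell:

```sh
tmfret simulate --scenario intrasubunit --seed 3 --out bundle/
tmfret fit-global bundle/ --out fit/
tmfret energetics fa2_table.csv --out energetics/
```

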