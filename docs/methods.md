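# Methods

## Model

A TCSPC decay is modelled as the linear convolution of the measured
instrument response function with the sum of the donor intensity and a
scaled buffer-only intensity, plus a constant dark-count background:

    Decay(t) = [IRF(t' − shift_irf) − bkgr_irf] ⊛ [I_DA + f_B·I_B](t) + bkgr_dec

The donor intensity mixes a donor-only population (fraction `f_D`, one or
two exponential components `α_Di, τ_Di` with `α_D1 + α_D2 = 1`) with a
FRET-quenched population whose donor–acceptor distance r follows a mixture
of up to two Gaussians (`f_A1 + f_A2 = 1`).  Each distance adds a transfer
rate `(R0/r)^6 / τ_Di` to component i.  The buffer intensity is a sum of up
to four exponentials with amplitudes in counts; its scaling `f_B` in the
sample fit is the ratio of sample to buffer acquisition times, since both
cuvettes see the same buffer fluorophores per unit time.

For homotetramers a donor can also transfer to acceptors on neighbouring
subunits.  This is approximated by one additional independent acceptor
distance `r₂ ~ ρ₂`, dominated by the closest of the three neighbours.
Because the two distances are independent, the double integral over
(r₁, r₂) factorizes per donor component into the product of the
single-acceptor integral over ρ₁ and a transfer-only factor over ρ₂ — this
factorized form is what the code evaluates, and a brute-force 2-D
quadrature of the unfactorized integrand is kept in the test suite as an
independent oracle.  ρ₂'s component means and widths are determined
separately (from a donor-only/acceptor-on-neighbours construct) and then
held fixed, with its mixing fraction tied to the intrasubunit `f_A2`, so
the two-acceptor fit introduces no new free parameters.

There are 15 named scalars in the parameter vector: `f_D, τ_D1, α_D1, τ_D2,
R0, r̄₁, σ₁, f_A2, r̄₂, σ₂, shift_irf, f_B, A0, bkgr_dec, bkgr_irf`.

### Assumptions

* κ² = 2/3 orientation averaging is absorbed into a fixed R0 measured
  independently from spectra; R0 never varies in a fit.
* Shot noise only: counts are independent Poisson variables per bin.
  Detector pile-up, afterpulsing and repetition-rate wrap-around are not
  modelled.
* The distance distribution is static on the fluorescence timescale (no
  diffusion-enhanced averaging within the excited-state lifetime).
* Gaussians are truncated at r > 0 and renormalized; for all reported
  parameter regimes (r̄/σ > 10) the correction is ≪ 1e-6.

## Numerics

* **Distance integrals.**  Per-component trapezoid quadrature on
  r̄ ± 8σ (clipped at r = 0.5 Å), 101 nodes per component in fits and 301 in
  the standalone forward model.  The integrand is a Gaussian times a smooth
  factor, so the trapezoid rule converges spectrally here; 101 nodes already
  agree with a 3001-node reference at machine precision.  Node weights are
  renormalized to sum exactly to the component fraction, which makes the
  discrete rule preserve the mixture normalization.
* **Convolution.**  Zero-padded FFT convolution truncated to the time
  window (no circular wrap).  The IRF kernel is background-subtracted
  (`bkgr_irf`), clipped at zero, and normalized to unit sum so that `A0`
  carries all amplitude.  `shift_irf` is specified in ps; whole-bin shifts
  relocate the kernel exactly, sub-bin shifts linearly interpolate.
* **Weights.**  χ² uses per-bin variance `max(obs, 1)` — the shot-noise
  variance with a floor of one count so empty tail bins do not dominate.
  Observed (not model) counts weight the residuals; at the photon budgets
  used here the Pearson/Neyman distinction is negligible, but it is stated
  because it changes estimates at low counts.
* **Optimizer.**  Bounded trust-region least squares (lmfit/scipy
  `least_squares`) with 2-point numeric derivatives, relative finite
  difference step 1e-4, `x_scale='jac'`, and ftol = xtol = gtol = 1e-7.
  Default bounds: `f_D, f_A2 ∈ [0,1]`, r̄ ∈ [10, 100] Å, σ ∈ [0.1, 20] Å,
  τ ∈ [0.1, 50] ns, `shift_irf ∈ ±2000 ps`.
* **Degenerate components.**  When `f_A2` is fixed at exactly 0 or 1 the
  absent component's (r̄, σ) are frozen automatically — their Jacobian
  columns would be identically zero and derail the scaled trust region.
* **Starts and restarts.**  Deterministic starts: r̄ from the
  amplitude-weighted mean decay time inverted through the single-distance
  FRET relation, σ = 3 Å, f_A2 = 0.5; `A0` is pre-scaled so predicted and
  observed totals match.  Global fits are staged: each dataset is first fit
  alone and the joint optimization starts from those estimates (shared
  parameters from their median) — cold high-dimensional starts proved
  unreliable.  Two-Gaussian fits that end unconverged or with reduced
  χ² ≥ 1.1 are restarted from deterministically jittered distance values and
  the best solution kept.
* **Component labelling.**  The single-acceptor model is exactly symmetric
  under exchanging the two Gaussians with `f_A2 → 1 − f_A2`; fits are
  relabelled post hoc so r̄₁ ≥ r̄₂ (resting/active convention).  With a tied
  ρ₂ block the exchange is *not* a symmetry but the two labellings sit in
  basins of similar depth, so a swapped solution triggers one re-optimization
  from the mirrored point and the lower-χ² labelling wins.
* **Profiles and surfaces.**  χ² profiles fix one parameter on a grid and
  re-optimize the rest, trying both the neighbouring grid point's solution
  and the unconstrained optimum as starts; this prevents the scan from
  ratcheting into local minima.  Surfaces are the 2-D analogue.
* **Fit window.**  Default from 5 bins before the IRF peak to the last bin
  with at least one count.

## Protocol

1. `fit_buffer`: buffer-only decay → up to 4 reconvolved exponentials,
   then frozen.
2. `fit_donor_only`: `f_D` pinned at 1; only `τ_D1, α_D1, τ_D2, shift_irf,
   A0, bkgr_dec` vary.  The donor lifetimes are then frozen.
3. `fit_decay` / `fit_global`: donor lifetimes, R0, `f_B` (acquisition-time
   ratio) and `bkgr_irf` (0) fixed; the free subset of
   `f_D, r̄₁, σ₁, f_A2, r̄₂, σ₂, shift_irf, A0, bkgr_dec` is estimated.
   `f_A2` is pinned to 0 or 1 for single-state fits and free otherwise.
   Global fits constrain named parameters equal across conditions or
   constructs (typically the four distance parameters and `f_D`; whether
   `f_D` is shared is configurable — it is shared per labelled protein
   sample by default).
4. When pre-fitting the intersubunit distribution from a
   donor-on-one/acceptors-on-neighbours construct, `f_A2` is fixed at 0.2
   (apo) and 0.8 (cAMP); these constants are configurable inputs of that
   protocol step rather than estimates.

## Energetics

`ΔG = −RT ln(f_A2/(1−f_A2))` with R = 1.9872×10⁻³ kcal mol⁻¹ K⁻¹ and
T = 298.15 K by default (always configurable; T enters only through RT).
ΔΔG subtracts the apo from the liganded ΔG.  Dose–response fits use the
quadratic tight-binding isotherm evaluated in the cancellation-free form
`2L/((L+P+K_D)+√((L+P+K_D)²−4PL))`, which reduces smoothly to the
hyperbola as `P_total → 0`.  Flat titrations (A ≈ B) are flagged as
unidentifiable rather than rejected.

## Synthetic data

The generator emulates a cuvette TCSPC experiment: a Gaussian IRF
(FWHM 0.4 ns centred at 5 ns, Poisson-sampled with the pulse integrated over
bins), a two-exponential buffer (1 ns and 6 ns, ~2 % of the decay peak), a
constant dark-count floor of 0.5 counts/bin, and a decay drawn bin-wise from
the noise-free reconvolution prediction rescaled so the expected total is
the requested photon budget (default 5×10⁶ per decay — large enough for
sub-Å distance recovery, small enough for seconds-scale simulation).  All
randomness flows through one seeded `numpy` generator and every bundle
embeds its full ground truth in its manifest.

Scenario presets carry the study system's parameter sets: donor
87 %/17.6 ns + 13 %/4.73 ns, R0 = 43.5 Å; intrasubunit distances
41.7/2.3 Å (resting) and 28.8/2.1 Å (active); intersubunit 54.1/3.0 and
58.0/5.0 Å; homotetramer 41.6/3.6 and 29.1/4.1 Å with the intersubunit pair
as the tied ρ₂ block; full-length 39.8/4.1 and 31.0/2.7 Å with occupancies
0.41 (apo) and 0.99 (saturating cAMP).

What passing recovery tests show — and what they do not: the pipeline is
unbiased and correctly weighted *under its own noise model*.  Real
instruments add IRF drift, pile-up at high count rates, detector afterpulses
and background structure that the generator does not produce, so recovery
bounds measured here are best-case.

Problem sizes: tests and examples run on 1024 bins × 50 ps (51.2 ns
window); the production default grid is 4096 × 25 ps.  Recovery campaigns
use 20 seeds for the donor-only and intrasubunit protocols and 3 seeds for
the two-acceptor homotetramer protocol.

## Design choices where the design was open

* The time discretization, r-integration scheme and IRF normalization are
  not dictated by the model; the choices above (unit-sum kernel, adaptive
  per-component quadrature support) were made for numerical hygiene and are
  documented precisely so fits are reproducible.
* Truncation/renormalization of ρ(r) at r > 0 is adopted for propriety of
  the density; it is numerically irrelevant for reported parameters.
* Component identity is a labelling convention, not a constraint: the
  optimizer never sees an ordering restriction, and relabelling happens
  after the fit (see above).  Intersubunit fits keep their configured
  labels because ρ₂ breaks the symmetry.
* Uncertainties are reported from the χ² curvature at the optimum
  (covariance of the trust-region solution); profile-based intervals can be
  computed with `chi2_profile` where curvature is unreliable (notably σ).

## Known limitations

* One effective intersubunit acceptor stands in for three neighbours; it
  captures the closest-acceptor-dominated transfer but not the full
  geometry of a tetramer.
* σ parameters are intrinsically shallow directions of the χ² landscape
  (the profiles show much smaller curvature than for r̄, and σ₁ correlates
  with `f_D`); interpret fitted widths cautiously.
* Near-saturating occupancies (f_A2 → 1) make ΔG exquisitely sensitive to
  f_A2; error bars on ΔG should be propagated from the f_A2 uncertainty
  rather than read from the point estimate.
* No Poisson maximum-likelihood or Bayesian fitting; weighted least squares
  is accurate above ~10 counts/bin, which the fit window and photon budgets
  ensure.
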