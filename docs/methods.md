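# Methods

## The model

`ringb` models the post-translational dynamics of the Polycomb PRC1 core:
the E3 ligase Ring1B, its partner Bmi1, the deubiquitinase USP7 and the
downstream substrate histone H2A.  Ten species are followed (twelve in the
mass-action variant): free Bmi1 (`B`) and its degradation-targeted
ubiquitinated form (`Bd`, written by SPOP/Cul-3), free Ring1B (`R`) and its
degradation-targeted form (`Rd`, written by E6-AP with canonical K48
chains), the Bmi1·Ring1B heterodimer (`Z`), its self-ubiquitinated form
(`Zub`, the strongest H2A ligase), the active (`Ra`) and weakly active
(`Ru`) self-ubiquitinated free Ring1B forms, and H2A/uH2A (`H`, `Hu`).

Thirteen reactions connect them (see the module docstring of
`ringb.model` for the full list).  Three ingredients produce the nonlinear
behaviour:

1. **Intermolecular self-ubiquitination with positive feedback.**
   Reactions 6 (on the complex) and 9 (on free Ring1B) have rate
   `(k_basal + k_auto * A) * substrate` with the catalysing activity
   `A = wZ*Zub + wRa*Ra + wRu*Ru`.  Self-ubiquitinated Ring1B ubiquitinates
   other Ring1B molecules, so active forms promote their own production.
2. **Saturable removal of the active complex.**  Reaction 7 (USP7 removing
   the activating chains from `Zub`) follows a Michaelis–Menten law
   `k7 * USP7_tot * Zub / (KM7 + Zub)`.  Near-zero-order removal plus
   autocatalytic production is the classic recipe for bistability.
3. **Competition for a single DUB pool** (`dub_competition=True`).  USP7
   binds its most abundant substrate tightly, so the free enzyme available
   to the first-order deubiquitination steps (2, 4, 10, 11) is depleted by
   the factor `KM7 / (KM7 + Zub)` — the quasi-steady-state expression for
   the free fraction of an enzyme sequestered by `Zub`.  An activity burst
   thereby throttles its own recovery reactions, which is the delayed
   negative feedback behind the relaxation oscillations and excitable
   overshoots.  With the flag off, each DUB step draws on an independent
   pool and the constants scale with `USP7_tot` alone; extensive randomized
   exploration of that independent-pool form produced robust bistability
   but never sustained oscillations, which is why the shared-pool reduction
   is the form used for the oscillatory regimes.  The mass-action variant
   resolves the same physics into elementary steps
   (`U + Zub <-> U·Zub -> U + Z`) with an explicit enzyme–substrate
   complex, and reproduces the reduced model closely in the regime where
   the complex holds a negligible share of the material (enzyme much below
   `KM7` + substrate): steady states agree to ~1% and oscillation periods
   to ~3% at the shipped MM-limit parameterization.

Units: concentrations are normalized by total Ring1B (1 unit = 100 nM);
time is in seconds.  Parameter sets may be supplied in nM; they are
converted once at the interface (second-order constants scale by the
normalizing concentration, first-order constants are unchanged).

## Calibrated parameter sets

No kinetic rates for this system have been measured, so the shipped
defaults are calibrated: free constants were tuned once so that the
hallmark behaviours hold at their canonical abundance coordinates, then
frozen.  Two Michaelis–Menten sets are provided because a single set of
this rate-law family could not be found (about 4,000 randomized candidate
sets plus continuation-guided tuning) that shows *both* the bistable
anchors and the oscillatory anchors at their respective coordinates:

* **`bistable`** (the default; independent DUB pools): at
  `USP7_tot = 1` the Bmi1 scan has saddle-node folds at 2.01 and 3.05
  (201 and 305 nM), three steady states (two stable, one unstable) at
  `Bmi1_tot = 2.5`, single stable states at 1 and 4, and matching
  hysteresis thresholds.  The high-`Rd`/low-`Zub` state is reached from
  Bmi1-depleted starts, the low-`Rd`/high-`Zub` state from Bmi1-rich
  starts.
* **`oscillatory`** (shared-USP7 competition): sustained relaxation
  oscillations at `(USP7_tot, Bmi1_tot) = (2, 3.25)` (period ≈ 510 s) and
  at `(3, 5)` with `k1 = 0.0016` (twice the default `k1 = 0.0008`);
  monostable at `(1, 1)` and `(1, 4)`.  The overall time scale of this set
  was fixed by pinning the default `k1` at 0.0008 s⁻¹ so that the doubled
  value used by the second oscillation condition is exactly 0.0016 s⁻¹.
  Its excitable operating point — a stable rest state just below the
  oscillation onset with all-or-none threshold responses — lies at
  `(USP7_tot, Bmi1_tot) = (2, 1.0)` (`ringb.EXCITABLE_POINT`); a `Zub`
  increment of 0.01 decays while 0.02 fires a full excursion.  The 40%
  `k6a` pulse-duration threshold at that point is ≈ 13 s: the duration and
  increment thresholds are tied together by the set's intrinsic rate
  scale, so they cannot be placed at arbitrary independent values.

Mass-action sources `table_s2`, `fig_s10`, `fig_s11a`, `fig_s11b` carry
the elementary-step constants; where a source corresponds to a published
figure, the constants printed in its caption are used verbatim and the
remaining ones are filled from the calibrated sets (synthetic stand-ins,
so marked in `ringb.synthetic`).

Known deviations of the calibrated behaviour from the published regime
structure, all verified rather than hidden: the excitable regime of the
oscillatory set sits at lower Bmi1 than in the published map and has a
single steady state near a Hopf bifurcation rather than the
one-stable-plus-two-unstable configuration; `Rd` oscillates roughly a
quarter cycle — not half a cycle — away from `Ra`; and saturating
reaction 10 with the published modifier constants yields at most two
(not three) simultaneously stable states.  The corresponding checks in
`tests/test_acceptance.py` are left failing on purpose.

## Numerical choices

* **Integration**: LSODA with `rtol = 1e-8`, `atol = 1e-10`.  The
  relaxation oscillations alternate millisecond-scale ubiquitination
  bursts with hour-scale reservoir recovery; conserved totals drift by
  less than 1e-12 (relative) over 30,000 s runs.
* **Steady states**: roots of the right-hand side in reduced coordinates
  (conservation laws eliminated, removing the neutral directions), found
  by Levenberg–Marquardt from seeded random starts on the conservation
  simplex plus corner-biased starts, deduplicated at relative distance
  1e-5.  Stability from the reduced-Jacobian spectrum (central
  differences); eigenvalue threshold ±1e-9 with a `marginal` flag.
* **Folds**: grid continuation with warm starts, fold location refined by
  bisection on the steady-state count to relative precision 1e-3 —
  robust and directly checkable against the quasi-static hysteresis
  protocol, which must and does jump within one step of each fold.
* **Excitability**: a response is "over threshold" when the peak `Zub`
  deviation exceeds the applied increment (or the sub-threshold reference
  for parameter pulses) by more than `response_excess = 0.02` (2 nM).
  A sub-threshold kick decays monotonically (peak = kick), an
  over-threshold one adds an excursion of roughly fixed size (~0.1), so
  this excess is monotone in the stimulus and bisectable; a peak-to-kick
  *ratio* rule fails for large kicks because the fixed-size excursion
  dilutes.  A state increment moves the conserved totals, so the system
  returns to the steady state of the *perturbed* totals (the pulse
  protocol, which conserves totals, returns to the original state to
  1e-4).
* **Oscillation detection**: peak analysis of `Zub` after discarding 30%
  of the trajectory; oscillation requires ≥ 5 peaks, inter-peak CV < 0.05
  and a late/early prominence ratio > 0.95 (a possibly truncated final
  peak is excluded).  Phase lags by cross-correlation at the period.
* **Long timescale**: only `Bd` and `Rd` are degraded (first order,
  `ln 2 / half-life`); complexed species are protected, which is what
  makes the complex half-life exceed the free one.  Synthesis is balanced
  against the degradation-targeted levels *averaged over the stable
  states*, so inside a bistable window neither branch is systematically
  fed.  Over the first hour the long model then deviates from the short
  model by < 0.15 normalized units and reaches the same attractor; with
  synthesis targeting abundances below the oscillatory band, oscillations
  die out over ~10 h and a unique steady state is approached.

## What the synthetic data emulate — and what they do not

`noisy_timecourse` emulates densitometry of quantified immunoblots:
composite observables (total ubiquitinated Ring1B `Rd+Ru+Ra+Zub`, total
active `Zub+Ra+Ru`, uH2A) sampled at a few dozen time points with
multiplicative lognormal noise (default CV 0.1, mean-preserving) and a
detection floor.  Real blots add gel-to-gel normalization error,
saturation of strong bands and antibody cross-reactivity, none of which is
modelled; passing recovery tests therefore show identifiability under the
stated noise model, not under every experimental artefact.  Parameter
recovery of `(k7, k6a)` needs observations at two USP7 abundances fitted
globally — at a single abundance the two constants compensate along a
ridge (removal capacity against loop gain) and the medians exceed 20%.

The dose–response of ubiquitinated Ring1B against transfected Ring1B is
emulated only qualitatively (monotone increase); no numeric dose–response
table exists to fit.

## Known limitations

* The two calibrated sets split the regime anchors between them; no single
  set covers all published coordinates (documented above).
* Bistability of the default set survives 1.25-fold random perturbation of
  all rate constants in roughly a third to a half of draws — the window
  (about 100 nM wide in Bmi1) is real but not parameter-robust in the
  strong sense.
* `qss_curves` exposes the clamped-species partition as configuration; the
  shipped default (clamp `Rd`, report `Zub`, and vice versa) makes the
  curve intersections coincide with the steady states exactly, but the
  `Zub` curve is not strictly invariant under `Bmi1_tot` changes.
* SBML export is structural Level 3 Version 2 (species, reactions, kinetic
  laws in content MathML); documents round-trip through the bundled reader
  with identical stoichiometry but are not validated against the XSD
  schema.
* No stochastic simulation, no spatial propagation, no thermodynamic
  constraints on rate constants.
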