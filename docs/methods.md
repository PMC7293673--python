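# Methods

## Model structure and assumptions

The model deliberately sits between first-principles Fenton chemistry
(dozens of elementary reactions, radiation-field modeling) and purely
empirical fits. Its assumptions:

* The radical core is reduced to the two-reaction iron cycle plus a
  first-order photo-reduction of Fe³⁺ and a first-order "inefficient
  elimination" of HO•. No HO• + H₂O₂ scavenging, no iron–organic
  complexation, no carbonate/chloride chemistry, no temperature
  dependence. The lamp irradiance is folded into k₀, so k₀ is specific
  to the plant's photo-reactor at its operating irradiance
  (36 W m⁻²-class UVA lamp); no radiation-field model is attempted.
* pH is controlled at 2.8, so [H⁺] = 10⁻²·⁸ ≈ 1.58×10⁻³ mol/L,
  [OH⁻] = Kw/[H⁺] and [H₂O] = 55.5 mol/L are clamped constants with
  zero derivatives. HO₂• (produced by the Fe³⁺ + H₂O₂ step) has no
  consuming reaction in the scheme and accumulates in an inert sink;
  dissolved O₂ is carried as an inert constant.
* The degradation mechanism is *fictitious*: fragments are bookkeeping
  species whose carbon numbers halve at each attack (FNCᵦ = NC/2ᵇ) while
  the molar amount doubles, so every breakage step conserves carbon
  exactly. Non-integer carbon numbers (14 → 7 → 3.5 → …) are weights,
  not molecules.
* A terminal step FR_F + HO• → mineralized products (rate constant
  `k_fragment`) removes the last fragment's carbon from the organic
  pool. Without it the cascade conserves organic carbon identically and
  TOC could never fall; with it, and with **all** organic species
  counted in TOC, the fragment asymptotes of the irradiated paracetamol
  run reproduce the final TOC conversion analytically
  (1 − (4·0.10 + 2·0.19 + 1·0.32)/(8·0.26) = 0.471). For a one-carbon
  target the cascade degenerates to a 1:1 attack followed by terminal
  mineralization of the single intermediate (two reactions, two rate
  constants — consistent with the two fitted constants reported for
  formic acid, although the same study prints B = 1 for it; we treat
  that count as inconsistent with its own TOC formula).
* All processes competing for HO• — elimination and every breakage
  step — are damped by the availability-controlled normalization
  r_i → r_i²/S with S = r_elim + Σ r_b. This is the literal reading of
  the published normalization; the dimensionally tidier alternative
  (proportional allocation, i.e. raw mass-action rates sharing the
  available radicals) is implemented behind
  `normalization="proportional"` but is off by default, since the
  literal form reproduces the published simulated checkpoints.
* Units are mol/L and seconds internally; mmol/L and minutes at every
  external boundary, converted exactly once. The compound-specific
  constants are taken in L mol⁻¹ s⁻¹ as tabulated in the source study
  (its running text says L (mmol s)⁻¹; the tabulated units are used
  because they reproduce the published trajectories).

## Plant and integration scheme

Four CSTRs in a cycle (9.00, 2.25, 1.50, 2.25 L; total 15.0 L) with a
12.0 L/min recirculation flow; only the 1.50-L compartment reacts
photochemically, and only in irradiated mode. Samples are taken from
the tank (compartment 1); a volume-weighted average accessor exists for
comparison.

Each fixed step does, in order: (1) reaction update per compartment with
normalized rates and the availability clamp — if a step would consume
more of a species than is present, every reaction consuming that
species is scaled by the ratio available/demanded (a reaction is scaled
by the smallest factor among its reactants); (2) H₂O₂ feed into the
tank at constant rate during the feed window; (3) cyclic advective
exchange of Q·dt·cᵢ moles computed on pre-exchange concentrations.

* **dt = 0.05 s** by default: Q·dt = 0.01 L ≪ 1.5 L (smallest
  compartment), and the fastest kinetic time constants under the
  reference conditions are of order seconds. The scheme's fixed point
  coincides with the ODE equilibrium, so quasi-steady species (HO•,
  iron redox state) track the continuous solution closely: on a 10-min
  run the scheme agrees with an adaptive stiff integration (LSODA,
  rtol 10⁻⁸) of the identical field to well under 0.5 % in all
  normalized observables. If the clamp activates on more than 1 % of
  steps, dt is halved automatically (at most three times; then the run
  aborts with a diagnostic).
* **Feed duration 30 s** by default. The dosing is only known to be
  fast but finite; `feed_sensitivity()` reports the headline
  observables across 10–60 s. Within that range the checkpoints move by
  well under a percentage point.
* Observation extraction takes the nearest recorded grid point (1-s
  recording grid by default) — no interpolation, the grid being dense
  relative to the sampling intervals.
* Initial conditions: target and Fe²⁺ uniform across the plant (they
  are premixed before the oxidant starts the run), all iron ferrous,
  no Fe³⁺, no radicals, no H₂O₂ (it arrives through the feed).
* The compiled (numba) kernel is cross-checked in the test suite
  against a pure-Python step built directly from the rate functions.

## Reference parameters

| constant | value | units | role |
|---|---|---|---|
| k₀ | 5.6×10⁻² | s⁻¹ | Fe³⁺ photo-reduction (irradiance folded in) |
| k₁ | 5.0 | L mol⁻¹ s⁻¹ | Fe³⁺ + H₂O₂ |
| k₂ | 63.0 | L mol⁻¹ s⁻¹ | Fe²⁺ + H₂O₂ (Fenton) |
| k_elim | 7.5×10⁻² | s⁻¹ | HO• inefficient elimination |
| k_target / k_fragment (PCT) | 1.5×10³ / 1.5×10² | L mol⁻¹ s⁻¹ | paracetamol cascade |
| k_target / k_fragment (SQX) | 4.5×10² / 3.5×10² | L mol⁻¹ s⁻¹ | sulfaquinoxaline cascade |
| k_target / k_fragment (FA) | 6.5×10⁻¹ / 7.5×10⁻² | L mol⁻¹ s⁻¹ | formic-acid steps |

## Calibration

Stage 1 (core) uses blank assays (Fe²⁺ + H₂O₂, no organics) and their
H₂O₂ series; stage 2 fixes the core and fits (k_target, k_fragment) per
compound on the target/TOC/H₂O₂ series. The published procedure was a
manual priority-guided search; here it is bounded multistart least
squares on log₁₀-transformed constants (scipy `least_squares`, trust
region reflective), with the priority encoded as fixed residual weights
TOC : target : H₂O₂ = 3 : 2 : 1 (configurable). Residuals are computed
on normalized series for all three observables, each series normalized
by its nominal dosed initial value (robust to noise on the t = 0
sample). Default bounds: the literature ranges for k₁ (0.1–11.7) and
k₂ (63.0–76.0 L mol⁻¹ s⁻¹), one decade around the reference values for
everything else. Standard errors come from the Gauss–Newton covariance
(pseudo-inverse of JᵀJ), so flat directions show up as very large
errors rather than failures.

Identifiability caveats, by construction of the model:

* k_elim has **zero** leverage on blank assays — the radical sink feeds
  nothing back into the iron/oxidant balance — so the core stage cannot
  determine it (a test demonstrates the exact invariance). It is kept
  in the core-stage interface for completeness, retains its starting
  value, and can be fixed explicitly.
* k₂ is only weakly identified by the slow H₂O₂ sampling grid: the
  quasi-steady consumption rate depends on the harmonic mean
  k₁k₂/(k₁+k₂), dominated by the smaller k₁. The tight literature range
  on k₂ is what keeps the estimate meaningful.
* Estimating k₀ requires at least one irradiated blank; the model
  raises an identifiability error otherwise.

Fitting simulations run at dt = 0.25 s (same scheme, coarser step,
sub-0.5 % observable differences) so that a full multistart fit takes
seconds instead of minutes.

## Synthetic data

The generator replays the study's assay structure: target sampled on
each compound's HPLC grid (paracetamol: 0–15 min, dense early;
sulfaquinoxaline: 0–120 min; formic acid followed through TOC only),
TOC every 15 min (analyzer cycle time), H₂O₂ every 5 min to 30 min then
every 15 min. Noise is multiplicative Gaussian (default σ = 5 %,
matching replicate scatter typical of these spectrophotometric and TOC
determinations), negatives truncated to zero, and target values below a
detection limit (default 10⁻³ mmol/L) dropped as a chromatograph would
drop them. Every assay draws from an independent child stream of the
master seed, so datasets are bit-reproducible.

What synthetic data do *not* emulate: real intermediate chemistry (the
generator uses the same fictitious cascade as the model, so parameter
recovery tests probe the estimation machinery, not model adequacy),
autocorrelated instrument drift, iron-series measurements, and the
model–plant mismatch a real dataset would carry. Passing recovery tests
therefore shows the pipeline is consistent and well-posed, not that the
model fits any particular real effluent.

## Problem sizes used in the shipped checks

Headline simulations run the full 120-min assays at dt = 0.05 s
(144 000 steps, four compartments). Conservation checks run every
registered assay truncated to 30 min at dt = 0.25 s; the stiff-oracle
comparison uses a 10-min run; parameter-recovery studies use 20
replicate synthetic datasets per stage at dt = 0.25 s with three
optimizer starts each.

## Known limitations

* The fragment cascade cannot represent partial mineralization routes
  (e.g. direct CO₂ loss from the parent) or refractory end products;
  TOC plateaus arise only from oxidant exhaustion.
* k₀ is plant- and lamp-specific; transferring it requires re-fitting
  against an irradiated blank on the new geometry.
* The normalization r²/S is an empirical stiffness-control device, not
  mass-action kinetics; its "proportional" alternative changes the
  elimination/breakage split and is provided for sensitivity analysis.
* Blank-assay H₂O₂ consumption is somewhat over-predicted by the core
  at the reference constants (the known bias of the published model);
  the package reproduces the model, including that bias.
* No uncertainty quantification beyond asymptotic standard errors; a
  one-at-a-time perturbation of the feed duration is the only built-in
  sensitivity diagnostic.
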