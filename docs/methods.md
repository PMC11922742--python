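# Methods

## Pump–leak energetics

The resting-cost model treats the membrane at steady state as two ohmic
leak pathways — a sodium-selective conductance g_Na and a
potassium-selective conductance g_K with g_Na + g_K = g_in = 1/R_in —
balanced by the electrogenic Na⁺/K⁺-ATPase at its canonical stoichiometry
of 3 Na⁺ extruded and 2 K⁺ imported per ATP. Setting sodium influx equal
to 3Fa and potassium efflux to 2Fa (a = pump cycle rate, F = Faraday
constant) and eliminating the conductances yields

    g_Na = 3 g_in (V − E_K) / (V + 2 E_Na − 3 E_K),
    ATP rate = g_in (E_Na − V)(V − E_K) / (F (V + 2 E_Na − 3 E_K)).

Assumptions worth keeping in mind: chloride, calcium and electro-neutral
transport are ignored; the ionic gradients (and hence E_Na, E_K) are taken
as fixed; the pump stoichiometry is voltage- and temperature-independent.
The model is undefined outside E_K < V < E_Na, where one conductance
fraction would have to be negative — such measurements raise an
`InvalidRegimeError` and are excluded (and flagged) from cohort summaries
rather than clipped, since clipping would silently bias group means.

Parameters and defaults:

| parameter | default | units | meaning |
|---|---|---|---|
| E_Na | +53.8 | mV | sodium reversal potential of the recording solutions |
| E_K | −108.4 | mV | potassium reversal potential |
| T | 296.15 | K | room-temperature recording |
| C_m | 20 | pF | typical membrane capacitance |
| ΔV_ap | 60 | mV | action-potential depolarization amplitude |
| ΔC | 20 | fF | capacitance increase per action potential |
| d | 40 | nm | dense-core vesicle diameter |
| c_spec | 1 | μF cm⁻² | specific membrane capacitance |
| ATP/vesicle | 23,400 | — | vesicle packaging cost |
| bulk rate | 20 | pmol μg⁻¹ min⁻¹ | ATP production ceiling (per μg protein) |
| cell volume / dry fraction / density | 1 pl / 0.25 / 1 g ml⁻¹ | — | protein-per-cell conversion |

The reversal potentials are used verbatim as recording-solution constants;
a `nernst()` helper is provided but deliberately not wired in, because the
defaults do not reduce to a single-ion Nernst computation on the nominal
solution compositions. Physical constants are CODATA 2018 via
`scipy.constants`, so derived figures are bit-reproducible.

Unit bookkeeping is centralized in `necell.constants`: voltages in mV,
conductances in nS (so nS·mV = pA without factors), capacitances in pF/fF,
rates stored both as mol s⁻¹ and molecules s⁻¹. Headline figures may be
rounded to one significant figure for reporting
(`round_to_sig_figs`), never in stored values.

Note an internal inconsistency of the usual headline arithmetic: ~400
vesicles at 23,400 ATP each is ≈9.3×10⁶ ATP per action potential, not
5×10⁷; the package always reports the computed product.

## Patch-clamp features

*V*<sub>rest</sub> is the median of the zero-current trace over the first
3 s after breakthrough. A median (not a mean or a point read) is used for
robustness to breakthrough transients; if the recording drifts by more
than 5 mV across the window (cytoplasm dialysis), the read falls back to
the first 0.5 s. Voltages are junction-corrected by subtracting the 10 mV
liquid junction potential of a gluconate pipette unless flagged as
prenulled (the default, matching amplifier-side nulling).

Passive properties come from per-sweep least-squares fits of
V(t) = V_base + I·R_in(1 − e^(−t/τ)) to small (2–4 pA) hyperpolarizing
steps — a single-compartment (mono-exponential) model. τ is bounded above
by a third of the step duration: the protocol presumes steps ≥ 3τ, and an
unbounded fit at low signal-to-noise can chase noise into a quasi-linear
ramp with τ → ∞. Per-sweep estimates are combined with weights ∝ I²,
since the estimator variance at fixed noise scales with the inverse
square of the voltage deflection. C = τ/R_in by construction.

Excitability is the maximum positive difference between peak voltage and
the steady-state depolarized voltage across a ladder of depolarizing
steps, with the steady state taken as the mean over the last 20% of the
step (configurable; no standard definition exists). Both the in-step peak
and a post-offset rebound window (200 ms) are searched and the larger
wins, with the rebound use recorded — rebound spikes, when present, are
typically the largest. The score is zero unless more than one sweep shows
a clear overshoot; "clear" defaults to 5 mV above steady state and is
always reported with the result.

## Calcium activity

The only supported order is complete-track filtering → per-frame
background subtraction (one scalar background per field of view) →
per-cell median normalization → peak calling, and it is recorded in every
result. Peak calling is standard topographic prominence (each peak
measured against the higher of the two lowest valleys separating it from
nearer higher terrain or the trace edge) with cutoff 0.1 on
median-normalized traces; `scipy.signal.find_peaks` provides the engine
and an exhaustive brute-force oracle in the test suite pins the exact
semantics, including plateau-midpoint indexing and the non-callability of
edge samples. No minimum peak distance or width is imposed by default. A
cell is active iff it has at least one supra-cutoff peak; cells with
non-positive median are excluded with a logged reason.

## Metabolite exchange

Growth over an incubation is a two-point exponential fit,
k = ln(N_f/N_0)/T — initial and final counts are all that is measured —
and the integrated cell-time N_0(e^{kT} − 1)/k (with the continuous limit
N_0·T below |kT| = 10⁻¹⁰) normalizes the mock-minus-sample concentration
difference into fmol cell⁻¹ h⁻¹, secretion-positive. Mock replicates are
averaged into one reference by default (pairing between mock and sample
wells is generally not meaningful), with an index-paired mode available.
The glycolysis index is the ratio of lactate secretion to glucose
consumption, defined only under net glucose consumption; 2 is the
stoichiometric ceiling for purely glucose-derived lactate and larger
values indicate other lactate sources. The titration crossover is the
smallest supplied lactate concentration with net flux ≤ 0.

## CRISPR vulnerability filter

A gene passes iff median L2FC over SCLC lines < −2 **and** (SCLC median −
LUAD/PDAC pooled median) < −1.5, both strictly, so threshold ties fail.
Even-count medians use the two-middle-values midpoint; missing values are
dropped per gene per group, and genes missing an entire group are
excluded with a count. The pooled-group median (not a mean of per-type
medians) is used for the comparison group.

## Synthetic data: what it does and does not emulate

The generators define the study conditions for every test:

* **Sweep sets** — single-compartment RC responses (R_in 500 MΩ, C 20 pF,
  V_rest −70 mV, 10 kHz sampling, 0.4 s steps, 0.5 mV noise) plus, for
  the excitable phenotype, stereotyped piecewise-linear spike templates
  (55 mV above plateau) inserted where the noiseless trajectory crosses a
  −40 mV threshold, with optional rebound templates. Templates give exact
  overshoot ground truth; they do not reproduce conductance dynamics,
  spike-frequency adaptation or channel noise, so passing tests validate
  the feature definitions, not biophysical realism of spike shapes.
* **Calcium fields** — 100 cells × 150 frames at 0.5 Hz (5 min). Active
  cells (planted fraction 0.3) receive Poisson event trains convolved
  with an instantaneous-rise, 6 s mono-exponential-decay kernel at
  amplitude 0.5 ΔF/median (a 5× margin over the 0.1 cutoff). Noise is a
  stationary AR(1) process with total sd 0.02 and frame-to-frame
  correlation 0.9 (~19 s correlation time): at 0.5 Hz the fluctuations of
  a segmented cell's mean intensity are dominated by slow sources (focus
  and illumination drift) rather than frame-independent shot noise.
  Uncorrelated noise of the same amplitude would place the extreme-value
  spread of a 150-frame trace near the prominence cutoff and is not what
  these recordings look like. No photobleaching trend, motion artefacts
  or wave propagation are simulated.
* **Flux experiments** — exact exponential growth inverted through the
  exchange arithmetic (so zero-noise recovery is exact to rounding), with
  optional relative measurement noise on concentrations and counting
  noise on the final count. Defaults: N₀ = 10⁶ cells, 24 h, 2 ml,
  DMEM-like 25 mM glucose, planted rates −290 (glucose) and +380
  (lactate) fmol cell⁻¹ h⁻¹ (index ≈ 1.31).
* **Screens** — 4,915 genes × 8 lines (4 per group), null values
  N(0, 0.3), 8 planted genes at SCLC median −3.5 vs 0 elsewhere — a 1.5
  margin beyond the −2 threshold, so exact recovery is expected and
  verified.

All generators take an integer seed and are byte-deterministic given it.

## Numerical choices and degenerate inputs

Boundary V values (exactly E_K or E_Na) are errors, not zeros, though the
ATP rate vanishes continuously toward both. The cell-time integral
branches to its k → 0 limit below |kT| = 10⁻¹⁰ and matches adaptive
quadrature to <10⁻⁸ elsewhere. Empty cohorts and empty fields of view
return explicit empty results; an empty field's active fraction is
undefined and raises rather than returning 0. Problem sizes in the test
suite (1,000 random draws for the solver-equivalence and peak-calling
oracles, 100 seeds for recovery suites, 50 fields for the binomial-CI
check) keep the full run under ten seconds while leaving Monte-Carlo
margins wide.

## Known limitations

The energetics model is a steady-state bound, not a dynamic simulation:
no Hodgkin–Huxley kinetics, chloride/calcium fluxes or temperature
dependence. The passive fit assumes one compartment; electrotonically
extended cells would need a second exponential. The calcium module calls
activity, not event rates or wave speeds. The screen filter reproduces
the selection rule only — applying it to the real external screen data is
out of scope, so the synthetic 8-of-4,915 recovery validates the filter's
behaviour, not the biological hit list.
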