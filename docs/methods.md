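# Methods

## Scope

navblock implements the in-vitro pharmacology workflow for a
state-dependent Nav-channel pore blocker: a gating-plus-binding simulator
that generates realistic automated patch-clamp peak-current tables under
six voltage protocols, and the analysis stack that turns such tables into
Boltzmann/Hill/exponential fit parameters and, ultimately, the resting and
inactivated dissociation constants `K_R` and `K_I`. The simulator is a
first-class, tested component: it defines the study conditions under which
the analyses are validated end to end.

## The channel model

Seven states: closed (C), open (O), fast-inactivated (IF), slow-inactivated
(IS) and drug-bound counterparts CB, IFB, ISB. There is deliberately no
drug-bound open state: the compound class being modelled (neutral,
ultra-lipophilic, fenestration-access) shows no effect on open-state
inactivation, so open channels neither bind nor unbind.

Equilibria are specified directly and rates are built around them:

* Activation: `O/C = exp((V - Va)/ka)` with forward/backward rates
  `act_rate·exp(±(V - Va)/2ka)`.
* Fast inactivation from closed: `IF/C` is set so that total availability
  (`C+O` vs `IF+IS`) is exactly the logistic
  `h(V) = 1/(1 + exp((V - Vs)/ks))` at equilibrium, with symmetric
  voltage-dependent rates scaled by `inact_rate`.
* Open-state inactivation: constant `O → IF` rate; the reverse `IF → O`
  rate is fixed by the C–O–IF cycle identity so the free gating graph obeys
  detailed balance.
* Slow inactivation: voltage-independent first-order `IF ↔ IS`.
* Binding: `C→CB`, `IF→IFB`, `IS→ISB` at `k_on·[C]`; unbinding at
  `k_on·K_R` (CB) and `k_on·K_I` (IFB, ISB). Bound-state gating mirrors the
  free rates scaled by `sqrt(K_R/K_I)` so every cycle has unit rate-ratio
  product.

Because the whole graph is reversible, the stationary distribution is a
Gibbs measure over explicit state weights, and the closed forms used as
oracles (availability, apparent IC50, fractional block) are exact rather
than approximations. The simulator's equilibrium block matches
`C/(C + IC50_app(V))` to a few parts in 10⁴; the test suite asserts 2%.

Propagation is exact per constant-voltage segment: state advancement uses
cached matrix exponentials (scaling-and-squaring conserves occupancy to
~1e-10 per segment; states are renormalized and a 1e-6 drift guard trips on
numerical failure), and dense open-probability traces for peak detection
use the eigendecomposition of the same generator. No ODE stepping.

## Default parameters

| parameter | value | why |
|---|---|---|
| `ssi_v_half`, `ssi_slope` | −80 mV, 8 mV | puts vehicle inactivation at −100 mV at 7.6%, inside the observed 5–10% band |
| `act_v_half`, `act_slope` | −37 mV, 7 mV | calibrated so the drug-free IV family (500 ms steps, 5 mV grid, blanked 0.5 ms) peaks at −25 mV |
| `act_rate` | 3 /ms | sub-ms activation at test potentials |
| `open_inact_rate` | 1.5 /ms | open-state decay tau ≈ 0.66 ms at −25 mV (0.5–1 ms target) |
| `inact_rate` | 0.05 /ms | fast-inactivation recovery tau ≈ 2 ms at −120 mV, ≈ 10 ms at −80 mV |
| `slow_entry`, `slow_exit` | 5e-5, 1e-3 /ms | mild slow inactivation (~5% of the inactivated pool at rest) |
| `K_R`, `K_I`, `k_on` | 108 µM, 3.6 µM, 0.002 (µM·s)⁻¹ | the study's fitted constants; equilibration tau ≈ 11 s at 30 µM/−90 mV, in the observed tens-of-seconds range |
| cell template | 50 nS, 15 pF, E_Na +68 mV | peak currents ~1–3 nA, densities ~100 pA/pF; E_Na is the Nernst potential of 145/10 mM Na⁺ at 22 °C |
| noise, rundown | σ = 5% multiplicative per peak, 1%/min | rundown is shared by vehicle and drug cells so vehicle correction is testable |

A second gating profile, `conductance_assay_gating()` (`slow_entry` 1e-3,
`slow_exit` 1e-5 /ms), is used for the maximal-conductance (IV) and
slow-SSI assays. The seconds-long depolarizations of those protocols drive
channels into deep slow-inactivated states; with drug on board the
slow-unbinding ISB pool accumulates and ~48% of maximal conductance is lost
at 30 µM while the activation midpoint of the remaining channels moves by
only ~1 mV. The split into two profiles is deliberate: a single
two-parameter modulated-receptor instance cannot simultaneously show ~25%
inhibition at −100 mV (availability ~0.92 with K_R/K_I = 30) and lose half
its conductance from a −120 mV holding, where equilibrium block is pinned
near 25% by `K_R`; the printed observations themselves are in tension, and
each analysis is validated under the profile that represents its assay.

## Protocols

Defaults reproduce the published stimulus families: 30-step activation and
SSI grids (−120…+25 mV, 5 mV, 500 ms), slow-SSI families per duration
(1/3/5/10 s, 100 ms recovery, 10 ms test), 4 × 180 pulses at 1 Hz for the
use-dependence assay (−110…−80 mV), a 12-interval log ladder (1 ms–10 s)
for recovery, and sparse 20 ms pulses every 5 s over 3 min for kinetics.
Unstated plumbing was fixed once: 5 s inter-sweep interval; a 30 s
inter-interval recovery step at −120 mV (long enough that carried bound
drug relaxes to its resting level before the next interval's first pulse);
drug application coincides with recording start for the use-dependence and
kinetics assays (initial state = drug-free gating equilibrium), while
IV/SSI/recovery assays start from the fully drug-equilibrated state after a
20 min incubation.

## Analysis choices

* **QC**: cell-level, strict inequalities (Rm > 500 MΩ, Rs < 10 MΩ,
  max |peak| > 500 pA); excluded cells are logged with the failed criteria.
* **Normalization**: each cell to its own first pulse; drug responses
  divided by the mean vehicle response at the same protocol coordinate;
  inhibition clamped to [−0.2, 1.2] with out-of-range values flagged.
* **"Last pulse"** is estimated as the mean over the final five pulses of
  each interval (all at binding equilibrium); this mirrors the
  mean-of-last-points convention used for maximal inhibition in the
  kinetics analysis and roughly halves the variance of the hyperpolarized
  IC50 estimates.
* **Hill slope rule**: free slope by default; fixed to 1 when the free fit
  leaves the slope with > 50% relative standard error (the practice used
  for extrapolated curves), or when the caller fixes it.
* **Four-state fit**: `1/IC50(V) = h(V)/K_R + (1−h(V))/K_I`, availability
  from the vehicle 500 ms SSI Boltzmann by default (options: a
  use-dependent availability curve measured at the end of vehicle trains,
  or the configured model Boltzmann). Solved by non-negative linear least
  squares with relative (fractional) weighting of the reciprocal IC50s,
  which spans two orders of magnitude across holding potentials; a
  coefficient pinned at zero sets the boundary flag. Voltages whose curves
  carry a no-inhibition flag (< 10% maximal response) are excluded; an
  optional censored mode enters them at the highest tested concentration.
  An optional duty-cycle availability correction
  (`h → (1−d)·h`, d = pulse width/period) exists but defaults off: across
  seeded round trips the plain SSI availability tracks the drug-sensed
  availability closely and the naive correction overshoots.
* **Fitters**: bounded trust-region least squares from a fixed multistart
  grid (log-spaced rate/IC50 starts; ties broken lexicographically), so
  every fit is a pure function of its inputs. Standard errors from the
  Jacobian-based covariance at the optimum. Residuals are unweighted within
  each curve fit.
* **Concentration ladder**: 1, 3, 10, 30, 100, 300 µM × 8 cells plus
  vehicle. The ladder brackets apparent IC50s from ~4 to ~90 µM; the
  published kinetics experiments used 4–30 µM, but the concentration set of
  the state-dependence figure is not stated.

## What the generator does and does not emulate

It emulates: Boltzmann-shaped availability, exponential drug equilibration,
use-dependent accumulation of block, per-cell conductance/seal variability,
single-concentration-per-cell designs, multiplicative peak noise, shared
rundown, capacitive blanking (first 0.5 ms of each measured segment). It
does not emulate: stochastic single-channel gating, series-resistance or
leak artifacts, temperature effects, liquid-junction offsets, or
instrument-specific filtering. Passing round-trip tests therefore
demonstrate estimator correctness under the stated noise model, not
robustness to every artifact of real recordings.

## Known limitations

* With a state-independent association rate, the predicted equilibration
  time constant `1/(k_on(C + IC50_app(V)))` *shortens* slightly at
  hyperpolarized holding potentials (unbinding-dominated relaxation),
  whereas state-gated access (fenestrations opening with inactivation)
  would make onset faster at depolarized potentials. The analyses do not
  depend on this trend; only the concentration dependence of tau is
  asserted.
* Because `K_R` is finite (108 µM), the model necessarily shows ~25%
  resting-state block at −120/−110 mV at equilibrium; first pulses of
  later holding intervals (minutes after drug application) therefore do
  show inhibition at the highest concentrations. The no-tonic-block
  property holds for the first interval, where the drug has had no time to
  bind.
* The use-dependence estimator inherits a small (~+10–15%) positive bias in
  the recovered fold preference from the mismatch between the 500 ms SSI
  availability and the duty-cycle-averaged availability the drug actually
  senses; it is well inside the ±30% validation band (median fold ≈ 32,
  range 28–37 over 16 seeds).

## Problem sizes

The end-to-end validation study uses 56 cells × 720 pulses (plus a 30-sweep
SSI protocol per cell) and completes in a few seconds on one CPU thanks to
propagator caching and conductance-rescaling across cells; the full test
suite runs in well under a minute.
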