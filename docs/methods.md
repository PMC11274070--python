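# Methods

## Model

Each synaptic cleft is a one-dimensional interval [0, d] with an absorbing
boundary at the post-synaptic membrane x = d.  A neurotransmitter of
charge −e released at the pre-synaptic membrane (x = 0) undergoes
overdamped Langevin dynamics

    ζ ẋ = F(x) + ξ(t),   ⟨ξ(t) ξ(t′)⟩ = 2 ζ T δ(t − t′),   D = T/ζ,

with T the thermal energy (k_B × temperature).  The force is the constant
electrostatic drift −eV/d plus the soft-wall force F_W described below.
There is no boundary condition on the negative axis other than the wall
force itself.

Two clefts are simulated with independent noise; the observable is the
distribution of ΔT = t₁ − t₂ over pairs of first-passage times, summarized
by its histogram, mean, standard deviation (unbiased sample variance) and
plain skewness g₁ = m₃/m₂^{3/2}.

At the default parameters the Péclet number v·d/D = e|V|/T ≈ 0.15, so the
transport is *diffusion-dominated*: the drift bias across the whole cleft
is small compared with thermal motion.  Two consequences run through
everything below: (i) the wall-free walk spends most of its passage time on
deep excursions into x < 0, so any effective wall shortens the mean transit
by an order of magnitude; and (ii) all first-passage distributions have
heavy right tails, so second-moment statistics need care.

## Parameters

| symbol | meaning | default | unit |
|---|---|---|---|
| d | cleft width | 20 | nm |
| D | diffusion coefficient | 0.33 | µm²/ms |
| V | trans-cleft voltage | −4 | mV |
| T | thermal energy | k_B·310 K ≈ 4.28×10⁻²¹ | J |
| F_MAX | peak wall force | 9.6×10⁻¹² | N |
| x₀ | wall region half-width | 2 | nm |
| l_C | wall steepness | −0.3 | nm |
| dt | time step | 10 | ns |
| n_runs | pairs per experiment | 50,000 | – |
| t_max | censoring horizon | 5 | ms |
| x_start | release point | 0 | m |

The temperature is not part of the published parameter set; body
temperature (310 K) is the only defensible default and is configurable.
T enters through ζ = T/D and through the closed-form ΔT width
δ = 2(T/e|V|)^{3/2}d²/D, which scales as T^{3/2}.  The charge is fixed to
−e (glutamate).  All internal computation is SI; customary units (nm,
µm²/ms, mV, ns) are converted exactly once at the config/CLI boundary.

## The soft wall

The wall is built from the even logistic bump
b(u) = exp(u/2l_C)/(exp(u/2l_C)+1)² = ¼ sech²(u/4l_C), evaluated through
cosh of the half-argument so it underflows gracefully instead of
overflowing.  Four variants are implemented:

* **anti_return** (default): F_W(x) = |4F_MAX[b(x−x₀) − b(x+x₀)]| — the
  two-bump field directed toward the post-synaptic side everywhere.
* **zero_offset**: the signed (odd) difference 4F_MAX[b(x−x₀) − b(x+x₀)].
* **literal**: the same minus a constant F_MAX everywhere.
* **off**: no wall.

Why the default is the rectified field and not one of the signed forms:
the literal variant's constant −F_MAX offset exceeds the electrostatic
drift ~300-fold and makes the cleft impassable.  The odd zero_offset field
has a saddle exactly at the release point and a potential well of ≈5 T
behind the membrane; measured at the default protocol, half of the
released particles fall behind the wall (≈98% of all trajectory time is
spent at x < −2x₀), the mean transit *triples* relative to the wall-free
walk, and halving dt changes the mean first-passage time by ~50% because
the trap-escape kinetics are unresolved.  A force whose stated role is to
prevent return to the pre-synaptic side must point toward the cleft on
both sides of the membrane; rectifying the same field achieves exactly
that with the same published magnitudes and length scales.  With the
default wall the mean transit drops from 8.1 µs (wall-free closed form) to
≈0.5 µs and the ΔT width narrows accordingly — consistent with the wall
*shortening* the diffusion time, at the cost of a quantitative offset from
the wall-free closed form that is expected, since that benchmark describes
an unconfined walk.

Softness: the per-step wall displacement F_W(x₀/2)·dt/ζ at the default
protocol is ≈3.8 nm against a per-step rms noise of ≈2.6 nm — a strong
nudge, not a hard reflection.

The wall is *not* impenetrable in the strict sense: its integrated barrier
is ≈5 T, so a particle at the membrane escapes behind the wall with
probability ~e⁻⁵ per contact, and a particle that does escape returns on
the drift time scale (microseconds), far longer than the typical transit.
These rare escape events dominate the tails of the first-passage
distribution.

## Numerical protocol

* **Integrator**: Euler–Maruyama, x′ = x + (F/ζ)dt + √(2Ddt)·z.  The noise
  is additive, so there is no Itô–Stratonovich ambiguity.
* **First passage**: declared at the first step with x ≥ d; the recorded
  time is the step-end time, or, with `interpolate_crossing`, linear
  interpolation within the final step.  No Brownian-bridge correction is
  applied, so the discrete walk carries the standard boundary-monitoring
  bias: the effective boundary sits ≈0.58·√(2Ddt) beyond d.  At dt = 10 ns
  that is 1.5 nm on a 20 nm cleft, and in the diffusion-dominated regime
  it inflates the mean transit by several percent — see "time-step
  sensitivity" below.
* **Wall resolution**: at dt = 10 ns the per-step rms displacement
  (2.6 nm) exceeds the wall steepness scale 4|l_C| = 1.2 nm, so a
  trajectory can jump the wall region in a single step.  These spurious
  jumps occur at ~10⁻³–10⁻² per pair and each costs a drift-limited return
  delay of up to hundreds of µs, which pollutes variance and skewness
  estimates.  The sweep experiments therefore shrink the step to the
  wall-resolved value dt_D = (2l_C)²/(2D) (rms step = half the wall
  scale, making single-step jumps >6σ events), capped at the protocol
  default.  Because v ∝ D at fixed T and V, scaling dt ∝ 1/D leaves the
  dimensionless problem unchanged: every sweep row runs the *same*
  discrete experiment up to a time rescaling, so ratios across D are free
  of discretization artifacts.
* **Censoring**: the default horizon is 5 ms (the wall-free tail decays on
  ~0.2 ms).  In sweeps the horizon is scaled with the slower cleft's
  diffusion time, to 20·d²/D — about 5× the 99.9% transit quantile of the
  walled dynamics — so that only detached wall-escape outliers (rate
  ~10⁻⁴/pair) are censored; censored pair counts are reported in every
  sweep row.  Censored runs are always excluded from statistics and
  counted; a warning is logged when the censored fraction exceeds 10⁻³.
* **Randomness**: one master seed; every (pair-member, run) owns a
  SeedSequence-spawned PCG64 substream, so results are bit-identical
  regardless of internal chunking, and a rerun with the same seed
  reproduces every trajectory exactly.  A `shared_noise` test hook drives
  both members with identical streams (identical clefts then give
  ΔT ≡ 0).
* **Histograms**: 101 bins over ±5 robust standard deviations
  (IQR/1.349) of the ΔT sample — wide enough to show the flanks, immune
  to the rare escape outliers.  Without crossing interpolation the samples
  live on the lattice k·dt, so the bin width is snapped up to an odd
  multiple of dt and a bin is centred on zero; otherwise the counts alias
  into a sawtooth.

## Closed-form benchmarks

`cleftsim.analytic` implements the drifted-Wiener hitting density (the
inverse-Gaussian law with mean d/v and shape d²/2D), its CDF, exact
sampling, and the ΔT variance both by quadrature of the density and in
closed form δ = 2(T/e|V|)^{3/2}d²/D; the two agree to better than 10⁻⁶
relative across a wide (D, V) grid, and the quadrature uses an upper cutoff
chosen from the survival function so the omitted tail mass is <10⁻¹².
These serve as independent oracles: the simulator with the wall off
matches the exact law to KS ≈ 0.016 at dt = 1 ns with 20,000 runs.

## Time-step sensitivity (known limitation)

Halving dt at the default protocol (wall on, dt = 10 ns) changes the mean
first-passage time by ≈8%, and even with the wall off the
boundary-monitoring bias alone implies ≈2% per halving at this step size.
The published step is simply not in the asymptotic regime for this
geometry; the bias shrinks like √dt and is ≈2% per halving at dt = 1–2 ns.
Conclusions in this package rest on ratios and shapes computed under the
scale-invariant sweep protocol (which cancels the bias across rows), not
on absolute transit times at dt = 10 ns.

## What the experiments show

* Physiological defaults: the ΔT histogram is unimodal and centred on
  zero (mean and skewness consistent with 0), with a core of width
  ~1 µs — against a wall-free closed-form width of 42 µs — so
  simultaneous release survives transit as near-simultaneous arrival.
* Symmetric D sweep: the ΔT width grows as D falls, following the 1/D law
  of the closed form; at D = 0.03 µm²/ms it is ≈11× the physiological
  width — the correlation is lost.
* Asymmetric sweep (D₂ = 0.33 µm²/ms fixed): raising D₁ above the
  physiological value does not broaden the histogram (the slower cleft
  dominates); lowering D₁ broadens it like the symmetric sweep and makes
  it visibly skewed.  Because the transit law itself is skewed, the ΔT
  skewness departs from zero as soon as the clefts differ; it is judged
  against a moment-based standard error √(m₆/(n m₂³)) rather than the
  Gaussian √(6/n), which is far too tight for these heavy-flanked samples.
* Voltage sweep (V₂ = −4 mV fixed): moderate voltage differences
  (−1 … −16 mV) leave the width essentially unchanged; asymmetry becomes
  visible only at unphysiologically large voltages.

The experiments above are statements about this one-dimensional model with
its idealized wall — not about real synapses: real clefts are
three-dimensional, transmitters are released in vesicle-sized bursts with
receptor binding and re-uptake, and the wall force is a phenomenological
stand-in for the exclusion effect of the pre-synaptic membrane.  What the
passing tests establish is internal: the simulator agrees with the exact
hitting law where one exists, and the qualitative sweep conclusions are
robust to the numerical protocol.
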