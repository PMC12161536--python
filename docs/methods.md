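# Methods

`semgsim` simulates surface EMG and muscle force with the muscle *fiber* as
the unit of activation: a fiber only fires when the acetylcholine at its
junction crosses its own threshold, so the recruited fiber fraction of a
motor unit varies with firing rate instead of being all-or-none.  This note
documents the model, its parameters, the numerical choices, and what the
synthetic inputs do and do not emulate.

## Model chain

1. **Motor control.** A desired force–time profile (normalised by maximum
   voluntary contraction, MVC) is translated per sample into a pair
   (n recruited units, mean firing rate m).  Calibration first builds an
   N×M matrix of window-averaged unit forces over the firing-rate grid
   8–42 Hz; sorting units by size (the Henneman size principle) and
   cumulating rows gives the reference matrix `M_ref`, whose entry (n, m)
   is the force of the n smallest units at rate m.  Each sample picks the
   entry within ±1% of the demanded force that lies closest to the diagonal
   from (0, 0) to (N, M) in normalised index space; an empty window falls
   back to the nearest entry, demand above the model maximum saturates at
   (N, M).  Active units fire periodically; at every change of the selected
   pair each active unit redraws its rate from a Gaussian centred on m with
   a standard deviation that grows linearly from 0 to 10 Hz with the
   recruited fraction, clamped to the rate grid.  Newly recruited units
   start with a uniform random phase; continuing units keep their phase.

2. **Motor neuron.** Each impulse releases acetylcholine with profile
   `ACh(t) = Am (1 − e^{−kr t}) e^{−kd t}`; impulses sum linearly.  A fiber
   innervates at the first sample its summed trace reaches its threshold,
   which zeroes that fiber's trace (reuptake): further innervations need
   fresh releases.  The difference-of-exponentials form admits an exact
   two-state per-sample recursion, which the implementation runs vectorised
   over all (fiber, train) pairs; an independent direct-summation oracle
   checks it in the tests.

3. **Fiber electrophysiology.** The intracellular waveform is
   `Vm(z) = A (αz)^3 e^{−αz} − B`; the transmembrane current is
   `C σ_ic π r² Vm''(z)`, a triphasic wave whose three sign lobes (bounded
   by the analytic zero crossings αz = 0, 3±√3) are collapsed to point
   charges at their charge centroids.  The middle charge is set to minus
   the sum of the outer two, so the net is exactly zero.  On innervation a
   mirrored tripole pair travels from the junction toward each tendon along
   the fiber's 3D polyline at the fiber's conduction velocity (cv·dt arc
   length per sample).  Amplitudes are jointly ramped from zero over a
   generation region at the junction and back to zero over an extinction
   region at each tendon (default length: the tripole span (3+√3)/α,
   configurable as `ramp_length_mm`); a train ends when its wavefront
   reaches the tendon.  Poles that have not yet emerged sit clamped at the
   junction, so every tripole is charge-balanced at every sample — dropping
   unemerged poles instead leaves a monopole transient that dominates the
   spectrum, which is why the clamped form was chosen.

4. **Volume conduction.** Tissues live on a regular voxel grid (air,
   fat/skin, muscle, cortical and cancellous bone with conductivities
   4.07e-2, 0.30, 2.00e-2, 7.56e-2 S/m).  Per electrode, unit current is
   injected at the electrode node (reciprocity) and
   `∇·σ∇V = 0` is solved with trilinear hexahedral finite elements,
   per-voxel constant σ, natural no-flux conditions at the skin–air
   interface and grounded planes at both ends of the z axis.  The solver
   uses a sparse LU factorisation below 50k unknowns and Jacobi-
   preconditioned conjugate gradients (relative residual 1e-8) above.
   Millimetre coordinates are converted to metres in the assembly, so h is
   in volts per ampere.  Pole positions sample h by trilinear
   interpolation.  Against an exact method-of-images solution of the
   grounded-slab problem the solver agrees to ~1% away from the source; on
   a large homogeneous cylinder it matches the free-space kernel
   1/(4πσd) to ~4% mean at 4 mm voxels, halving under refinement.  Note
   that at arm scale the insulating lateral boundary genuinely raises h by
   tens of percent relative to free space — that is physics, not error.

5. **Electrodes and signals.** An M×N grid (default 2×3, 15 mm z spacing,
   centred at 30% of the z axis) is cast from a surrounding cylinder onto
   the skin by marching each ray to its first tissue voxel.  Monopolar
   channels are sums of motor-unit potentials; bipolar channels are exact
   differences of neighbouring z rows within a theta column.  Because the
   geometry is static, each fiber's innervation waveform per electrode is a
   fixed template; the engine computes it once (pole train → lead field)
   and accumulates time-shifted copies at the innervation instants.  By
   linearity this equals the pole-by-pole sum, and the motor-unit-split
   test verifies the factorisation exactly.

6. **Force.** A twitch is
   `F_base (1 − e^{−t/τ_up}) d² e^{−t/τ_down}` (zero for t < 0; the d²
   factor is kept verbatim, so forces carry model units of mN·µm²; MVC
   normalisation removes the absolute scale).  Fiber force superposes
   twitches at innervation instants; unit and whole-muscle forces are
   sums.  Calibration averages use the closed-form twitch integral rather
   than sampled sums.

## Parameters

Fiber populations are sampled per type (I/IIa/IIx) from positive-truncated
Gaussians: radius 20±5 / 27.5±7.5 / 30±10 µm, intracellular conductivity
0.35±0.25 / 0.5±0.5 / 0.7±0.5 S/m, threshold 0.45±0.15 / 0.6±0.2 /
0.9±0.3 mM, twitch force 65±15 / 75±20 / 100±25 mN, rise 37±12 / 15±5 /
7±3 ms, decay 50±14 / 20±7 / 10±4 ms.  Conduction velocity maps the
population's r·σ_ic products affinely onto 3–5 m/s (a constant population
maps to the midpoint).  The junction sits where the fiber polyline crosses
the z plane at a Gaussian 40±5% length fraction from the upper tendon.
Membrane constants: A = 96 mV, B = 90 mV, C = 1500.  α is stored as
0.55 mm⁻¹ (550 m⁻¹): the larger unit reading would make the action
potential ~9 µm wide with MHz bandwidth; 0.55 mm⁻¹ gives a ~9 mm wave and
sEMG-band spectra.

**Acetylcholine scaling.** With Am = 1 mM, kr = 0.45 s⁻¹, kd = 30 s⁻¹ the
single-impulse peak is 0.0055 mM and the 42 Hz summed peak 0.021 mM — far
below thresholds printed in mM.  The release equation and thresholds are
implemented verbatim; `AChConfig.units` optionally reinterprets the rates
per millisecond, and `threshold_scale` globally rescales thresholds.  The
desk configuration fixes `threshold_scale = 0.012`, computed so the
threshold band (0.45–0.9) maps onto the concentration band reachable
between 8 Hz (0.0061) and 42 Hz (0.021): type-I fibers then fire from the
lowest rates while type-IIx fibers need near-maximal rates, which is the
intended recruitment gradient.

**Motor-unit pool.** Full scale is 200k fibers in 1000±250 units of
300±100 fibers; sizes are adjusted one fiber at a time on random units
(never below one fiber) until the total matches.  Unit territories
disperse as `R · N₂(0, λ)`, with R read as an area fraction (4–40% of the
muscle cross-section, converted to the radius of a disc of that area) and
λ as 20–50% of R; per-unit means scale linearly with unit size across
those bands (10% relative draw std, a choice — only proportionality is
specified).  Units are placed by re-centring each dispersed cloud on a
random unassigned cross-section point and greedily matching each dispersed
fiber to the nearest free point.  Fiber types start uniform random and are
converted one per iteration using three equal-std Gaussians over the
unit-size range (std = range/6, a choice) until realized percentages are
within ±1 point of the targets, concentrating slow fibers in small units.

**Fiber paths.** Cross-sections are paired layer to layer by recursive
bisection: split both point sets into ⌈n/2⌉/⌊n/2⌋ halves along the larger
bounding-box extent (ties split along x; the larger half takes the
lower-coordinate side), recurse to singletons, pair.  This is a bijection
at every layer interface, checked against an independent recursive
implementation.

## Synthetic inputs

The phantom is a concentric-cylinder arm (cancellous 7, cortical 12,
muscle 40, skin 45 mm) in a 100×100×150 mm box at 4 mm voxels, with a
120° muscle sector (radii 15–35 mm) holding the fiber cross-sections —
deterministic given spec and seed.  Reference profiles emulate the
laboratory tasks: smoothed isometric trapezoids (10/40% MVC) and
raised-cosine isotonic bursts (20/30% MVC) at 100 Hz, resampled to the
2 kHz simulation clock by band-limited polyphase filtering and rescaled
from participant MVC to the model MVC (`M_ref` at full recruitment and
top rate).

What the phantom does *not* emulate: real anatomy (muscle shape, tissue
heterogeneity along z, subject variation), electrode–skin impedance,
amplifier noise, movement artifacts, or fiber shortening.  Passing tests
therefore demonstrate internal consistency of the model chain and its
stated physics on idealised geometry, not agreement with any recording.

## Problem sizes

Tests and the acceptance script run desk-scale models chosen to exercise
every code path with minutes-scale turnaround: 600 fibers / 15 units for
spectral comparisons, 2000 fibers / 50 units for force tracking, 4 mm
voxels (2 mm for the refinement check).  Relative pool spreads (size
std/mean) are preserved when scaling down.  Full scale is supported but
not exercised by the suite.

## Numerical choices and edge cases

- Impulse and innervation times snap to the nearest sample of fs = 2 kHz.
- Threshold crossings are detected on the discrete trace (first sample at
  or above threshold); no sub-sample interpolation.
- Truncated Gaussians redraw up to 100 rounds, then clamp to avg/10.
- Degenerate cv range (min = max) yields a constant population; an empty
  fiber population raises.
- Twitch kernels truncate eight decay constants after onset.
- The median frequency of an all-zero signal is reported as an error, and
  similarity denominators that vanish (both means or both stds zero)
  return NaN rather than a guessed value.
- Envelope correlations of unequal lengths linearly resample to the
  shorter vector; moving averages use centred windows with edge
  truncation.
- Force tracking: the ±1% window check is a property of the planned
  recruitment (deterministic mean rates).  With the Gaussian rate
  dispersion active, plateau force fluctuates by several percent at desk
  scale simply because few units are recruited (per-unit force sensitivity
  ~8%/Hz); the dispersion's own statistics are verified separately.

## Known limitations

- Fibers do not shorten; geometry is frozen during contraction.
- The motor-unit pool model is the two-profile (count, rate) scheme; no
  physiological pool variability beyond the rate dispersion.
- The lead field treats electrodes as points (no surface averaging or
  contact impedance).
- Recruitment is open loop: no feedback from achieved force.
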