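# Methods

## Point membrane and quasi-active linearization

A membrane patch carries a leak (`g_L`, `E_L`), a static
hyperpolarization-activated conductance (`g_H`, `E_H = -43 mV`) treated
as a second leak because its intrinsic kinetics are orders of magnitude
slower than the signals of interest, and a low-threshold potassium (KLT)
current

    I_KLT = gbar * w^4 * z * (V - E_K),    E_K = -90 mV,

with fast activation `w` and slow, partial inactivation `z` (floor 0.5)
relaxing first-order toward Boltzmann steady states with bell-shaped
voltage-dependent time constants.  The exact kinetics functions of the
low-threshold channel family are parameterized in `KLTKinetics`; the
shipped numbers are a calibrated set (below), not a transcription of any
single experimental fit.

The resting potential solves the steady-state current balance by
bisection on [-120, 0] mV to 1e-12 mV.  Some strongly rectifying
parameter sets have a second, depolarized root; the solver returns the
most hyperpolarized one and warns.  Linearizing the current balance
about rest gives the quasi-active admittance per unit area

    Y(f) = i 2*pi*f C_m + G_eff + gamma_w / (1 + i 2*pi*f tau_w)
                                + gamma_z / (1 + i 2*pi*f tau_z)

with `G_eff = g_L + g_H + gbar w^4 z` the slope-free conductance,
`gamma_w > 0` the restorative activation conductance and
`gamma_z < 0` the small regenerative inactivation term.  `Y(0)` equals
the numerical slope of the steady-state I-V curve (tested to 1e-6
relative).  The `simplified` mode drops the `gamma_z` term; at the
reference point its corner sits at 12.5 Hz, far below the resonance, and
the two modes agree in peak frequency to ~0.1%.

Resonance metrics are read off `|Z| = |1/Y|` on a logarithmic grid
(0.5-2000 Hz, 2000 points) with a dense linear refinement within +-10%
of the coarse peak: the peak is parabolic-interpolated, the half-power
(`|Z|_max / sqrt(2)`) edges linearly interpolated, and
`Q = f_R / (f_+ - f_-)`.  Half power is taken on `|Z|`, not `|Z|^2`;
this convention yields Q values of order 0.5-1 for these membranes.  A
magnitude that peaks at the lowest grid frequency is non-resonant
(`f_R = 0`); an interior peak whose low-frequency side never falls to
half power keeps its `f_R` but has no `Q`.

## Cables and trees

For a uniform cylinder (diameter `d`, axial resistivity `R_a`) the
propagation constant is `gamma(f) = sqrt(4 R_a / (d z_m(f)))`
(principal branch), the space constant `lambda(f) = 1/Re(gamma)` —
chosen over `|1/gamma|` because it is the decay length of `|K|` — and
the semi-infinite input impedance `Z_in = (4 R_a / (pi d^2)) / gamma`.
The transfer impedance is `K(x, f) = Z_in e^{-gamma x}`.  Because
`lambda(f)` peaks at a higher frequency than `|Z_in|` (the mismatch
`Delta f = f_lambda - f_R`), the peak of `|K(x, .)|` climbs from the
input resonance toward `f_lambda` with distance — the spatial profile
of resonance frequencies.  Positions are path distances from the
recording electrode (x = 0).

Finite segments terminated by a lumped impedance use the standard
two-port composition; all hyperbolic ratios are computed from
exponentials with non-positive real part, so electrotonically long
segments cannot overflow, and sealed ends are symbolic rather than a
large float.  A tree is collapsed by post-order recursion — leaves
sealed, daughters combined in parallel, the soma treated as an
isopotential quasi-active sphere in parallel with all root branches —
followed by an outward attenuation pass; by reciprocity the transfer
impedance from any site to the recording node is the node input
impedance times the accumulated attenuation.  Parameter gradients along
a section are handled piecewise-uniformly with 5 um sub-segments, each
linearized about its own local resting state; halving the sub-segment
length moves profile frequencies by < 0.2 Hz on the shipped models.
The recording site is the root node (soma); transfer between two
arbitrary dendritic sites is not implemented.

## Frozen calibration

The kinetics parameters, reversal potentials and geometry are frozen
once in `dres/params/*.toml` and `builders.py`:

- Reference patch/cable (`reference_patch.toml`): `C_m = 1 uF/cm^2`,
  `g_L = 0`, `g_H = 0.3593 mS/cm^2`, `gbar = 19.73148 mS/cm^2`,
  `w^4` half-activation -62 mV (slope 4 mV), `tau_w(rest) = 0.85 ms`,
  `tau_z(rest) = 12.73 ms`; cable `d = 2 um`, `R_a = 150 Ohm cm`.
  This set places the somatic transfer resonance at 308 Hz, the 500 um
  resonance at 341.9 Hz (an 11.0% rise), patch Q = 0.84, effective
  cutoff 170 Hz, and the inactivation corner at 12.50 Hz.
- Optimized-cable endpoint (`optimized_cable.toml`): 200 um sealed
  cable, `d = 3.943 um`, uniform `gbar = 15 mS/cm^2`, constant
  `g_L = 0.25` with a linear `g_H` gradient 0.07 -> 0.75 mS/cm^2
  (total leak 0.32 -> 1.0), `E_L = -75.35 mV`; its profile spans
  292.0 - 325.0 Hz.
- Multipolar classification fixture (`builders.build_multipolar`): a
  synthetic stellate-like cell — six dendrites on a 9 um soma, four
  200 um dendrites with conductance scales 0.52 -> 0.45...0.80 of the
  reference patch, plus a 300 um (scale -> 0.95) and a 600 um
  (scale -> 1.20) dendrite.  Its transfer-resonance profile spans
  ~206-280 Hz, populating both task bands (208 +- 4, 228 +- 4 Hz), and
  the long dendrites supply distally sharpened, frequency-selective
  sites.

## Time-domain simulator

The compartmental model (centers <= 5 um apart by default, 10 um for
the classification tasks) is integrated with backward Euler on the
voltage (Hines elimination over the tree, unconditionally stable) and
staggered exact-exponential gating updates, dt <= 0.025 ms.  Synapses
are conductance-based double exponentials updated event-wise.  The ZAP
protocol injects a linear chirp; the empirical resonance is the
instantaneous chirp frequency at the maximum of the analytic-signal
envelope of the voltage (50 ms edges trimmed), cross-checked against the
FFT ratio `V(f)/I(f)`.  Desk-scale chirps of 1.5-3 s over 50-600 Hz
resolve the 200-350 Hz peaks to within the stated tolerances and keep
the default suite fast; the scheme's first-order time-constant bias
(`~dt/2tau`) and dx/dt convergence are tested explicitly.  Spiking, when
needed, is an integrate-and-fire overlay at the soma (threshold, reset,
refractory period, optional adaptive threshold); subthreshold dynamics
elsewhere are untouched.  The kernel is compiled with numba when
available and runs as plain Python otherwise.

## Evolutionary optimization

`evolve` is a (mu + lambda) evolution strategy: truncation selection,
rank-biased parent sampling, Gaussian mutation with a globally annealed
step size corrected by a 1/5-success rule, one fine-scale mutant of the
incumbent per generation, and box clipping.  Infeasible candidates
(death penalty) never outrank feasible ones.  The conductance-gradient
objective maximizes the profile range `Delta = max f_R - min f_R`
subject to `<Q> >= 0.8`; per-branch gradient endpoints, diameters
(repaired to taper non-increasingly) and the soma radius span the
search space with ranges in `builders.PARAM_RANGES`.  Defaults
(pop 24, lambda 48, 60 generations) are generic choices; tests and the
bundled benchmark run scaled-down versions.

## Classification tasks

Inputs are 25 independent inhomogeneous Poisson trains with rate
`r0 (1 + m sin(2 pi f_mod t))`, sampled by thinning; their vector
strength at `f_mod` is m/2 (tested).  Synaptic weights are normalized
inversely to each site's DC transfer gain so every synapse delivers the
same mean somatic drive and differences reflect resonance tuning rather
than proximity.  `r0` and `m` are treated as task parameters (they are
part of the task's optimization problem) and frozen per task.

*Spatial task* (`r0 = 100 sp/s`, m = 1, 1 s trials): the same spike
trains are delivered to synapses at sites whose transfer resonance
matches the 228 Hz signal (228 +- 4 Hz band) or mismatches it
(208 +- 4 Hz band); a one-sided sign test over paired seeds asks
whether the matched band drives more output spikes.  At the frozen
near-rheobase detector (threshold 0.28 mV above somatic rest) the
matched band wins ~19/20 seeds (p ~ 2e-6).

*Temporal task* (`r0 = 800 sp/s`, m = 1, 12.9 pA somatic DC): one
synapse set, locations and a shared weight optimized by the ES
(locations discretized to the profile grid, candidate sites ranked by
analytic target/null selectivity), evaluated on held-out seeds with
`S = (r_T - r_N) / (r_T + r_N)`.  Candidates whose mean target response
falls below 5 sp/s are infeasible: without that floor the search
converges on near-silent solutions whose S is determined by single
stray spikes.  The achievable selectivity on the shipped fixture is
S ~ 0.18 (target 5.3 vs null 3.7 sp/s, 13/20 paired seeds): the
differential attenuation between 228 and 208 Hz saturates at ~2.9% per
e-fold of amplitude attenuation, capping per-site amplitude margins at
~10-15%, while the per-cycle shot noise of 25 Poisson afferents at
feasible rates stays several times larger.  Single-presentation
demonstrations of sharp temporal selection are easy to produce in this
regime; a seed-averaged selectivity above 0.5 is not, and the package
reports the honest number.

## What the synthetic data do and do not show

The generators emulate the study conditions: abstract morphologies with
200 um soma-to-tip paths, linear conductance gradients, sinusoidally
modulated Poisson input.  They do not emulate reconstructed morphologies
(tapering, spines, realistic branch statistics), channel noise,
synaptic depression, inhibition, or temperature effects; passing tests
therefore validate the analytic machinery and the simulator against
each other and against the calibrated operating points, not the
biological parameter values themselves.

## Numerical choices and degenerate inputs

- Frequency grids: log-spaced 0.5-2000 Hz; refinement +-10% around
  coarse peaks; profile computations share one refined grid.
- Root finding: bisection, bracket [-120, 0] mV, 1e-12 mV tolerance;
  no root raises, multiple roots warn and take the most hyperpolarized.
- Zero-length or outward-tapering sections, disconnected trees,
  non-increasing frequency grids, and non-finite impedances raise
  immediately with specific messages.
- Sealed boundaries are symbolic; parallel combination skips them.
- All stochastic paths accept explicit seeds and are bitwise
  reproducible; the ES logs its full history.

## Known limitations

- Quasi-active profiles linearize each sub-segment about its local
  rest; with strong gradients the true coupled rest differs slightly
  (the ZAP cross-checks bound the effect at < 5% in f_R).
- The temporal-task selectivity ceiling discussed above.
- No Na+ channels, dynamic H current, axons, spines or inhibition; Q10
  handling is a single rate scale.
- SWC import attaches a uniform membrane (densities are not an SWC
  concept) and maps unknown structure types to dendrite with a warning.
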