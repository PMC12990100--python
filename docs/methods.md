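# Methods

This note documents the models, estimators and numerical choices behind
`ionflow`, what the bundled toy electrolyte does and does not emulate, and
the problem sizes the shipped analyses use.

## Field-coupled forces from atomic polar tensors

A homogeneous electric field **ε** enters perturbatively: the total force
on atom *i* is the zero-field force plus a field-induced term obtained by
contracting the atom's polar tensor (APT) with the field,

    F_i,η = F⁰_i,η + Σ_ζ P_i,η,ζ ε_ζ .

The APT is the derivative of the system dipole with respect to the atomic
position — equivalently, the derivative of the atomic force with respect
to the field — and its trace/3 is the Born effective charge. Units are
kept native throughout: tensors in e, fields in V Å⁻¹, forces in e·V Å⁻¹
(numerically identical to eV Å⁻¹); every conversion factor lives in
`ionflow.constants`.

Exact theory requires the acoustic sum rule Σ_i P_i = q_tot·I. Tabulated
or model tensors that violate it are repaired by subtracting the equal
share (Σ_i P_i − q_tot·I)/N from every atom — an even split over atoms,
not mass- or species-weighted. The correction is applied once, at table
load time, because it is a property of the tensor table rather than of
any frame. With corrected tensors the net field force on the system is
exactly q_tot·ε, so the field cannot inject spurious momentum beyond the
physical drift of the net charge.

`finite_difference_apt` provides the independent validation route: a
central difference of any force model with respect to the field, default
increment 0.0257 V Å⁻¹. Central (not forward) differences give
second-order accuracy at the same cost; for a force model linear in the
field the estimate is exact to round-off, which is what the oracle tests
assert.

## The toy electrolyte

The synthetic-data generator is a Langevin-dynamics model of one cation
in a bath of single-site solvent particles carrying rigid point dipoles.
It reproduces the *statistical structure* the transport analyses assume —
distinct, exchangeable first solvation shells with tunable stability,
dipole–field alignment, steady-state drift with Joule heat removed by a
stochastic thermostat — and nothing else. It makes no attempt to
reproduce water's chemistry or any real ion's absolute conductivity or
lifetime.

**Translations.** All particles interact by truncated Lennard-Jones pairs
(cutoff 2.5 σ, minimum image, cubic box). Positions are integrated with
the BAOAB splitting of Langevin dynamics (velocity-Verlet with an
exact Ornstein–Uhlenbeck mid-step), timestep 1 fs, friction 0.01 fs⁻¹.
The friction doubles as the heat sink for the work done by the field;
stage-mean kinetic temperatures are recorded and stay within ~1% of the
300 K target at all fields used. Positions are stored unwrapped so
displacement and velocity statistics need no unwrapping step.

**Field coupling.** The ion carries the polar tensor q·I (q = +1 e by
default), solvent atoms carry zero net Born charge, and the per-atom
field force is assembled by `field_coupling.perturbed_forces` — the same
code path the analyses use.

**Rotations.** Each solvent particle carries a unit dipole vector evolved
by overdamped rotational Langevin dynamics: drift (D_r/kT)·(μ u × E_loc)
with rotational diffusion constant D_r = 0.002 fs⁻¹, where E_loc is the
external field plus the (cutoff) Coulomb field of the ion. The stationary
distribution is Boltzmann in −μ u·E_loc, so the mean field-alignment
follows the Langevin function (verified in the tests) and first-shell
dipoles orient radially away from the cation. Dipole orientation does not
feed back on translations; the analyses only require orientational
statistics, not dipolar forces.

**Presets.** Shell stability is controlled by the ion–solvent well-depth
multiplier; three presets bracket the transport regimes:

| preset | mass (amu) | σ_is (Å) | well multiplier | regime |
|--------|-----------|----------|-----------------|--------|
| li     | 6.94      | 1.85     | 12.0            | strongly bound, vehicular |
| na     | 22.99     | 2.25     | 2.5             | intermediate |
| cs     | 132.91    | 2.25     | 0.4             | labile, structural |

The base well depth is 0.02 eV, solvent–solvent ε = 0.0067 eV and
σ = 3.0 Å; 200 solvent particles in an 18.2 Å box give a dense fluid
(ρσ³ ≈ 0.9). The multiplier is the stability dial: the continuous shell
lifetime rises strictly with it (a tested invariant). Mass sets the
rattling frequency of the caged ion. The li preset uses a smaller contact
distance; an early variant that also gave the labile preset a larger
contact distance confounded well depth with shell geometry (big shells
have long geometric residence regardless of binding) and was dropped.

**Limitations.** Single-site solvent (no hydrogen-bond network, no
molecular geometry), cutoff electrostatics (no Ewald), no counterion, no
polarizability beyond the rigid dipole, and a Langevin thermostat in
place of velocity rescaling. Consequently, passing tests demonstrate that
the *estimators* behave correctly on data with the right statistical
structure; they say nothing about any real electrolyte's numbers.

One Langevin artifact deserves emphasis: with a mass-independent friction
rate γ, the drag force is −γ m v, so diffusion scales as D = kT/(mγ) —
real liquids have nearly mass-independent D set by particle size. The
heavy labile preset therefore diffuses slowly, and its diffusion-limited
shell residence is long enough to nearly tie the intermediate preset's
lifetime even though its binding is ~5× weaker. The continuous-lifetime
ordering across binding strengths is accordingly asserted at matched
mass, where the well-depth multiplier is the only dial (the ~0.8 → 1.7 →
2.7 ps progression for multipliers 0.4 → 2.5 → 6 is robust across seeds);
the vehicular-versus-structural regime contrast between the strongly
bound and labile presets is unaffected, since it is driven by identity
churn rather than absolute residence.

**Markov coordination-state generator.** For exact-oracle tests of the
lifetime and decomposition estimators, `generate_markov_cn_series`
produces piecewise-constant integer-CN paths with exponential dwell
times, per-member Poisson identity swaps and per-state Gaussian drift
velocities. Its generating parameters are known, so survival correlations
(e^{−kτ} for swap rate k), occupancy-weighted drift mixtures and
class-mean recovery can be asserted against closed forms.

## Structure estimators

The ion–solvent RDF uses the standard pair normalization (shell volume ×
partner density × frame count), bins of 0.03 Å. The running coordination
number is the cumulative per-frame pair count on the same binning. The
first-shell radius R0 is the first local minimum after the first peak of
a Savitzky–Golay-smoothed g(r) (window 11 bins, order 3, search out to
1.8× the peak position); raw-bin argmin is noise-dominated when the
minimum flattens, exactly the labile-shell case, and when no interior
minimum survives smoothing the detector raises and a manual cutoff must
be supplied. Zero-field R0 is reused at all field strengths. Membership
uses strict inequality r < R0.

The smooth coordination number uses the rational switching function with
NN = 20, ND = 40. Because ND = 2·NN the term (1−x^NN)/(1−x^ND) reduces
algebraically to 1/(1+x^NN), which evaluates the r = R0 limit (= 1/2)
without special-casing.

The PMF along CN is −kT ln p(CN) from a histogram (bin width 0.1 CN), the
additive constant fixed by pinning the minimum to zero, empty bins
reported as NaN rather than zero. The tilt-angle analysis accumulates
(cos α, cos θ) pairs conditional on first-shell membership — cos α
between the member→ion axis and the field, cos θ between the dipole and
the field — normalized to integrate to one over [−1,1]²; conditioning on
membership avoids the solid-angle weighting a joint (α, θ) histogram
would have.

## Dynamics estimators

The continuous survival correlation is C(τ) = ⟨S(t₀,t₀+τ)/N(t₀)⟩ over
origins with N(t₀) > 0 — the per-origin-ratio reading, with origins at
every frame, restricted to t₀ ≤ T − τ_max so all lags are equally
sampled. A member counts toward S only while *continuously* inside R0;
there is no intermittent-return allowance (t* = 0), since intermittent
lifetimes are sensitive to that threshold. The lifetime τ_c is the
trapezoidal integral of C over the available lag range.

VACF and MSD use FFT-based multi-origin averages. Green–Kubo D integrates
the VACF (trapezoid) only out to where the integral has converged: 2.5 ps
by default, which suits solvents with slowly decaying correlations, but
0.75 ps in the toy-electrolyte closure study — the toy ion's VACF has an
integral timescale of ~30 fs, so 0.75 ps is ~25 integral times and
integrating further would only accumulate statistical noise in the
estimate. The Einstein cross-check fits the MSD
slope over a matched lag window (default 2.5–10 ps), where a single
trajectory still determines both estimators tightly and their statistical
fluctuations largely cancel. Diffusion errors come from segmenting the
trajectory, estimating D per segment and bootstrap-resampling the
segments (default 10,000 resamples, seeded). Finite-size extrapolation is
a weighted (1/SD²) linear fit of D against 1/L whose intercept is D_∞;
the Nernst–Einstein conversion Λ_m = F²D_∞/RT uses F = 96485.332 C mol⁻¹,
R = 8.31446 J mol⁻¹ K⁻¹.

The VDOS is computed per block (counts {24, 48, 96, 192, 384} by default;
{24, 48, 96} for the 100-ps toy runs), Hann-windowed before the
transform to limit leakage into the low-frequency band, block-averaged,
then averaged across block counts on the finest grid; per-block-count
peak positions are reported so peak stability can be checked. The
rattling frequency is the lowest interior local maximum with at least 5%
of-maximum prominence (the zero-frequency bin is excluded — drift and
diffusion contaminate ν = 0); its reciprocal is the rattling period. A
spectrum that decays monotonically from zero means no caged oscillation
exists and the detector raises; the labile preset genuinely has no caged
band, so regime analyses pass it the smallest period detected among the
other presets, which is conservative for the labile classification
(smaller thresholds over-count *vehicular* frames).

## Conduction and decomposition

The ionic current density is J_z(t) = (1/V) Σ_η P_ion,η,z v_ion,η(t); by
default the static table tensor is used for every frame (a hook accepts
per-frame tensors). Stage means discard 20 ps of equilibration by default
and carry block-averaged SEMs: block length doubles until the blocked SEM
changes by <5% over two successive doublings, with a floor of 8 blocks
(largest-block SEM plus a warning if no plateau is reached). The
conductivity is a weighted (1/SEM²) zero-intercept least-squares slope of
⟨J_z⟩ against E_z using only stages at or below the linear cutoff
(default 0.0514 V Å⁻¹); weights are relative, so jointly rescaling all
SEMs leaves the slope unchanged. Λ_m = σ/c with c the nominal molarity of
one cation in the cell volume.

Frames are partitioned into maximal segments of unchanged first-shell
identity sets — any membership change ends a segment, including
count-preserving swaps and pure entries, since stability is defined by
*which* solvent particles coordinate, not how many. Whole segments of
duration ≥ τ_rattle are stable-n (vehicular); everything else is labile
(structural). Frames near a qualifying segment's end count as stable:
segments are labeled as wholes, without frame margins. Per-class
time-weighted means reconstruct the total mean current exactly, an
algebraic identity asserted at 1e-12 relative on every input. The
sensitivity scan repeats the decomposition at scaled τ_rattle; the
vehicular weight is non-increasing in the multiplier (dwell-time
censoring), also asserted.

## Problem sizes and seeds

The shipped study conditions, chosen once as the package's own sizes:

- **Closure run**: 200 solvent particles; 250 ps zero-field (10 ps
  discard) for the Green–Kubo route with 12.5-ps segments; five field
  stages at 0.0103–0.0514 V Å⁻¹, 150 ps each (15 ps discard) — about 10⁶
  Langevin steps in total. Agreement between the two conductivity routes
  is asserted within 2 combined standard errors.
- **Regime runs**: 100 ps per preset (10 ps discard), 5 fs sampling,
  VDOS blocks {24, 48, 96}.
- **Statistical recoveries**: 10⁵-frame Markov series for the survival
  lifetime (10% tolerance at exchange rate 0.002 fs⁻¹); 10⁶
  inverse-transform samples for the double-well PMF (0.05 kT RMS over
  populated bins); 10⁶ steps for the free-particle Ornstein–Uhlenbeck
  oracles (VACF(0) = 3kT/m within 2%, D = kT/mγ within 5%).

All randomness flows from one master seed through `numpy` SeedSequence
spawning; per-stage child seeds are recorded in trajectory metadata, and
identical seed + config reproduces trajectories bit-for-bit.

## Known limitations

- Only cubic cells and single-cation systems; no ion–ion correlations, no
  solvent contribution to the current (the ionic term is what is
  regressed), no binary trajectory formats.
- The blocked-SEM plateau may not be reached on short stages; the
  largest-block SEM is then a mild underestimate of the true error,
  making the closure check slightly stricter, not looser.
- The toy simulator's linear-response window was not mapped precisely;
  the five closure fields sit where the fitted residuals show no
  curvature (R² > 0.98), inside the default cutoff.
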