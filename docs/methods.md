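# Methods

## What is simulated

The package models a double spin echo in which both refocusing pulses are
chemical-shift-selective adiabatic full passages (complex hyperbolic
secants), applied as an identical pair, and the two figures this buys at
7 T: B1-insensitive, phase-compensated refocusing restricted to a chosen
chemical-shift band, and J-difference editing obtained by acquiring the
same echo twice with two different band definitions and subtracting.

All simulations are relaxation-free.  T1/T2, macromolecular baselines,
frequency drift, eddy currents, gradient/readout encoding, coil combination
and spectral fitting are out of scope; the quantities computed here
(profiles, ratios, edited yields) are the sequence-design quantities that do
not depend on them to first order.

## Pulse model and parameter recovery

The sech pulse is `B1(t) = Ω₀ sech(βt)^(1+iμ)`.  Published protocols pin
down duration τ and sweep bandwidth BW but not (β, μ, Ω₀), so the package
recovers them:

* `β = 2 asech(s)/τ` — the envelope decays to the truncation level `s` at
  the pulse edges.  Default `s = 0.01` (1%), a common design point that
  keeps the edge discontinuity negligible while using the available
  duration; β depends only logarithmically on `s`, so the reconstruction is
  not sensitive to this choice.
* `μ = π·BW/β` — the sweep identity `BW = μβ/π`.
* `Ω₀` = 2× the adiabatic threshold, the stated operating point of the
  sequence.  The threshold itself is defined operationally: the smallest
  amplitude scale at which the on-carrier inversion reaches `Mz ≤ −0.95`
  (the criterion value is a package choice; the concept has no published
  numeric definition), located by a scan over amplitude scales with linear
  interpolation of the crossing.

With the scheme-2 editing-full numbers (τ = 24 ms, BW = 0.88 kHz) this
reconstruction reproduces the published profile anchors without further
tuning: Mz ≈ −0.82 at the 4.2 ppm passband edge (published ≈ −0.8), 90.9%
refocusing there (published > 90%), and a ≥10³ water-suppression factor at
4.7 ppm.  The 0.81 kHz / 31 ms variant used by the non-editing sequence is
registered as a separate preset; both appear in the published text and the
bandwidth ambiguity between them is left explicit rather than resolved.

The sinc-Gaussian excitation `B1(t) ∝ sin(πtf)/sin(πt)·exp(−b²t²)` is
evaluated with t in seconds on ±3 ms with the published f = 5500, b = 400;
read this way the formula is self-consistent (the only zero of the
denominator in range is the removable one at t = 0, filled with its limit
f) and yields the published 5.5 kHz excitation width.  The envelope is
rescaled to the requested flip angle, since only width and flip angle are
physically anchored.

## Propagation

Single-spin responses use piecewise-constant SU(2) propagation over the
sampled waveform (midpoint sampling, default 4096 samples — >100× the
fastest sweep frequency).  Cayley–Klein parameters give `Mz = 1 − 2|b|²`,
per-pulse refocusing `|b²|` and pair refocusing `|b²|²`.  For an identical
pulse pair the two coherence-transfer amplitudes (−1→+1 then +1→−1) are
complex conjugates, so the pair's net refocusing phase is zero by
construction; the tests compute the deviation rather than assume it.

Note the distinction between the *per-pulse* refocusing efficiency `|b²|`
(the quantity shown in published refocusing profiles, equal to `(1−Mz)/2`)
and the *pair pathway* amplitude `|b²|²` actually transferred through the
double echo.  At the 4.2 ppm band edge these are 0.91 and 0.83
respectively; both are exposed via the `pair` flag of
`refocusing_profile`.

Coupled systems (≤8 spins, dense 2ⁿ×2ⁿ matrices) evolve under the full
isotropic-coupling Hamiltonian with 297 Hz/ppm and the reference at
3.0 ppm.  Shaped pulses are applied with chemical shift and J active during
the pulse — at 24–31 ms the pulses occupy a large fraction of TE and this
evolution is not negligible (see Limitations).  Crusher pairs are modeled
as ideal coherence-pathway selection: around each refocusing pulse the
density operator is decomposed by coherence order p and only the p → −p
transfers are kept.  This is exactly what symmetric spoilers enforce, and
it is the mechanism of the implicit water/lipid suppression: spins the
pulse does not invert keep their order and are discarded.  Excitation is an
ideal 90° by default (a shaped excitation changes overall scale, not the
editing logic); detection is `Tr(ρ F⁺)`, coherence order −1.

Echo timing is symmetric (τ/2 — pulse — τ — pulse — τ/2); the actual delay
split is not published.  For an adiabatic passage the effective flip time
inside the pulse is offset-dependent, but with an identical pair that
dependence cancels in the echo condition, so the symmetric choice is not
load-bearing.  Acquisition defaults follow the sequence: 1024 complex
points, 1.28 kHz sweep.  Spectra are formed with exponential apodization
(default 2 Hz), zero-filling, and the standard half-first-point correction
(without it, the one-sided DFT's constant baseline corrupts window
integrals).

## Editing schemes and metrics

The three published schemes are registered with their carriers, bandwidths
and TEs.  For scheme 2 the published ppm band edges (full 1.6–4.2 ppm,
partial 2.7–4.2 ppm, stop band from 2.35 ppm) are stored explicitly and
used for the band-margin geometry; they are close to, but not exactly,
carrier ± BW/2 for the kHz presets, and the package does not force them to
agree.  Schemes 1 and 3 print only carriers; their edges are inferred as
carrier ± BW/2 and flagged configurable.

Editing efficiency in a window is |∫ difference| projected on the in-phase
axis defined by the partial spectrum, normalized by |∫ partial|.  The
projection discards the quadrature dispersion residue of a finite
integration window; for an ideal AX pair the measure then reproduces the
closed form `1 − cos(πJ·TE)` to <1% with a window spanning ±0.6 ppm.  B0
robustness re-runs the editing with all resonances globally shifted,
integrates in a window tracking the shifted multiplet, and normalizes by
the *zero-offset* partial reference — normalizing per-offset would divide
two quantities that fail together and mask the collapse.  For GABA/scheme 2
the edited yield is flat (≥0.96 of baseline) over ±0.3 ppm and collapses
(0.27) at +0.7 ppm, where the 1.9 ppm partner has crossed into the partial
passband and is refocused in both acquisitions.

SAR and peak power are computed only as ratios under the standard models
for similarly shaped adiabatic pulses: SAR ∝ BW at equal adiabatic
condition, and required peak B1 ∝ √(BW/τ) (threshold `Ω₀ = √μ·β`).  The
published peak-power comparison of 15.7% corresponds to this amplitude
ratio — the linear BW/τ power ratio would be 2.5% — and the package
implements the amplitude form, which also matches the published 84%
complementary reduction.  Waveform-level cross-checks (Σ|B1|²dt energies,
max|B1|²) agree with the models to better than 10% for pulses designed at
equal truncation and threshold multiple; the tests allow 25%.

## Synthetic phantom

`make_phantom("sphere_b1_dip")` builds a 24×24×8 sphere of uniform unit
creatine concentration with a transmit-field scale rising radially from 0.6
(centre) to 1.2 (rim) — a stylized standing-wave dip of a head coil at 7 T —
plus a seeded low-order perturbation (clipped to [0.5, 1.3]) and a smooth B0
map within ±0.1 ppm.  Per voxel, signal = concentration × pair refocusing
efficiency at that voxel's (B0, B1), interpolated from a precomputed
(offset × scale) Bloch table; this single-spin efficiency model is the
deliberate speed/fidelity trade for map-level statistics.  The phantom
reproduces the qualitative published contrast: the adiabatic map is uniform
(CoV ~0.01%, ≤5% asserted) while a generic amplitude-modulated π pulse
inherits the B1 dip (CoV ~8%, ≥3× the adiabatic value, across seeds).  What
this does *not* show: the real phantom's actual B1+ distribution is not
quantified, so the maps are a property check of adiabatic-vs-AM sensitivity,
not a quantitative prediction of any measured map.  The AM comparison arm is
a generic amplitude-modulated pulse, not a reconstruction of any specific
published pulse shape (whose coefficients are not printed).

## Numerical choices

* 4096 samples per pulse for single-spin profiles; 512 for spin-system runs
  (Nyquist-checked against sweep + offsets; ≥10× margin).
* Threshold search grid 0.1–3.0 in steps of 0.02 with interpolation.
* Propagators via Hermitian eigendecomposition (exact per step); unitarity
  is stress-tested to 1e-10 over 10⁴ steps.
* Degenerate inputs rejected: truncation ≥ 1, non-positive
  durations/bandwidths, TE too short for the pulse pair, Nyquist
  violations, B0 offsets beyond ±0.75 ppm.
* Problem sizes (1024-point FIDs, ≤6-spin systems, 24×24×8 phantom, 5-seed
  property sweeps) are chosen so any single check completes in seconds on
  one CPU core.

## Known limitations

* **Intra-pulse J dynamics.**  With real swept 24 ms pulses the J
  modulation deviates from the free-evolution closed form
  `cos(πJ·TE)`/`sin(πJ·TE)` by up to ~15% of the modulation at TE = 68 ms:
  during a long adiabatic passage the coupling term is partially truncated
  while the two spins follow different effective fields.  This is physics,
  not discretization (it shrinks roughly linearly with pulse duration and
  vanishes for instantaneous pulses).  Closed-form oracles are therefore
  checked in the `IdealBandPulse` limit (instantaneous, perfectly
  band-selective 180°), while real-pulse behavior is tested against its own
  invariants (selective refocusing, cancellation, B0 retention).
* **Weak-coupling oracles** are exact only to second order in J/Δν; the
  test systems use ≥2.4 ppm separations where those corrections are <1.5%.
* Slice-selection gradients, EPSI readout, parallel imaging, and absolute
  SAR (W/kg) are out of scope; all SAR statements are relative.
* Metabolite shifts and couplings are standard literature values embedded
  as constants; the glutamate set is the conventional literature fit, other
  systems use representative vicinal/geminal values.  None of the tested
  properties depend on their decimals.
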