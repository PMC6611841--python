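# Methods

## Physical model

The cerebral aqueduct is idealised as a rigid straight cylinder of radius
R = 2 mm (motivated by a median aqueduct cross-section of ~14 mm² in iNPH
patients) filled with CSF, treated as a Newtonian fluid with
ρ = 1000 kg/m³ and μ = 0.7 × 10⁻³ Pa·s (water at body temperature; CSF
properties are not pinned more precisely by the source measurements, and
results carry that uncertainty — a μ of 0.65 mPa·s changes the static
Poiseuille gradient by ~7% and the oscillatory amplitudes by less).

For axisymmetric flow driven by a spatially uniform axial pressure
gradient the Navier–Stokes equations reduce to

    ρ ∂v/∂t − (μ/r) ∂v/∂r − μ ∂²v/∂r² = −dp/dz(t),  0 ≤ r ≤ R,

with no-slip at r = R and symmetry at the axis. For dp/dz = a·sin(ωt) the
periodic solution is the Womersley flow; the package evaluates its flow
rate amplitude A = |πR²(ia/ρω)[1 − (2/Λ)J₁(Λ)/J₀(Λ)]| with Λ = α·i^{3/2}
and α = R√(ωρ/μ) via `scipy.special.jv` on the complex plane (stable to at
least α = 100, where both Bessel functions grow like e^{α/√2} but their
ratio stays O(1)).

Phase convention: the driving gradient is a sine, so the physical flow
rate is Q(t) = Im{Q̂ e^{iωt}}; velocity profiles, flow-rate series and the
finite-difference oracle share this convention, which matters only for
waveform plots — amplitudes, PVFs and volumes are phase-free. Component
phases default to zero (pure sines); relative phase does not affect any
reported quantity in the linear model.

Per-cycle volumes follow from V = A/(πf): the integral of A sin(2πft)
over a half period. This is the whole mechanism in one line — at equal
flow amplitude, volume is inversely proportional to frequency, so the
respiratory component (≈4.11× slower than cardiac) displaces ≈4.11× the
volume. The steady (third-circulation) problem uses Poiseuille's law,
dp/dz = 8μQ/(πR⁴).

Limits of the model: rigid walls, no curvature/stenosis, no entrance
effects, no net-flow superposition (window means are shifted to zero), and
an aqueduct geometry common to all patients. Changing R rescales all
amplitudes strongly (R⁴ in the viscous limit) but moves the
cardiac/respiratory *ratios* only weakly, since both Womersley numbers
shift together.

## Differential-pressure pipeline

1. **dICP**: (second channel − ventricular channel)/L, mmHg/m. The two
   sensor placements (subdural or parenchymal) are handled identically.
2. **Windows**: consecutive, non-overlapping 360 s segments (the typical
   duration of a cardiac-gated PC-MRI acquisition). A window is accepted
   iff the raw pressure difference in mmHg (before division by L) has
   max − min strictly below 2 mmHg and contains no missing samples; the
   threshold is dimensionally a pressure, so it is applied before the /L.
   Accepted windows are mean-shifted to zero, removing hydrostatic and
   other static offsets (body position was not recorded in the source
   protocol). Acceptance is evaluated on the raw difference, before any
   detrending — the simplest reading and the one that makes the rule a
   pure artifact gate.
3. **State**: a window is "sleeping" iff its start time-of-day lies in
   [00:00, 06:00), half-open so a window starting exactly at 06:00 is
   awake; windows without a wall clock are "unknown" and excluded from the
   sleep comparison.
4. **Spectra**: single-sided amplitude spectrum by real FFT, normalised so
   a stationary sinusoid of amplitude a with a whole number of periods in
   the window appears as a peak of height a (2|X_k|/N). Frequency
   resolution is 1/360 Hz. The 15 Hz low-pass acts by zeroing spectral
   bins (it is a spectrum-domain cutoff, not a time-domain filter). Head
   movement and drift concentrate below 0.1 Hz; their spectral skirt is
   removed by fitting A·e^{−bf} (linear least squares on log-amplitude
   over bins in (0, 0.7) Hz excluding the 0.15–0.4 Hz respiratory band,
   with b clamped at ≥ 0) and subtracting it, clamping the result at zero.
   Degenerate fits fall back to the identity with a warning.
5. **Band peaks**: maxima over the closed cardiac (0.7–1.6 Hz) and
   respiratory (0.15–0.4 Hz) bands, ties broken toward the lower
   frequency; a band whose maximum is numerically zero is flagged "not
   found". Peak amplitudes are multiplied by a calibration factor C,
   default 1.0: with this package's spectrum normalisation a clean
   sinusoid is recovered exactly at C = 1, which makes synthetic parameter
   recovery a sharp test. Clinical processing chains whose spectral
   normalisation under-reads time-domain amplitudes use C ≈ 7; C rescales
   both bands equally and cancels from every cardiac/respiratory ratio, so
   all ratio-type results are C-independent.

No window taper is applied. Consequently a sinusoid that does not complete
a whole number of periods in 360 s loses up to ~36% of its peak to
scalloping; with 1/360 Hz resolution, snapping a physiological rate to the
nearest bin changes it by < 0.1 beat/min, so recovery tests generate
on-bin frequencies and real-data amplitude calibration is delegated to C.

## Finite-difference oracle

An independent check of the analytical solution: Crank–Nicolson (second
order in space and time, unconditionally stable) on a uniform radial grid,
default 96 intervals and 256 time steps per period of the highest forcing
frequency. The 1/r singularity at the axis is handled by the symmetry
expansion (1/r)∂v/∂r → ∂²v/∂r² with a ghost point v(−Δr) = v(Δr). Starting
from rest, the transient decays with time constant τ = R²/(ν j₀₁²) ≈ 1 s;
whole lowest-frequency periods are simulated until at least 10τ have
elapsed before the final analysed period. Flow rate is the trapezoidal
quadrature of 2πr·v; component amplitudes are Fourier projections over a
whole number of periods. Measured agreement with the closed form is ≤
2×10⁻⁴ relative over α ∈ [1, 10], and a constant forcing relaxes to the
Poiseuille profile to ~10⁻⁹.

## Peak/valley decomposition

For a flow curve carrying both components, every adjacent peak/valley pair
of the total curve defines a midpoint ((Qp+Qv)/2 at (tp+tv)/2); the
respiratory flow Q_r(t) is a continuous interpolant of these midpoints and
the cardiac flow is the remainder. Extrema are detected with a prominence
threshold of 10% of the series range to suppress noise. The default
interpolant is a natural cubic spline: a piecewise-linear interpolant sags
between midpoints and inflates the cardiac range by 10–20% at
physiological frequency ratios, which is why linear is available but not
default.

The method has a known systematic bias: the midpoint averages the slow
component across half a cardiac period, shrinking its extremes by exactly
cos(π f_r/(2 f_c)) — about 7% at the physiological frequency ratio ~4.1
and 11% at ratio 3. The complement of that shrink leaks into the cardiac
component. Tests assert this closed-form prediction rather than pretending
the bias away; at the cohort-mean conditions the recovered PVFs are within
8% and per-cycle volumes within 7% of the analytical values. The method
assumes separated timescales and emits a warning when the detected
frequency ratio falls below 2; when the slow component's slope exceeds the
fast component's, cardiac extrema disappear and the decomposition is not
meaningful. PVFs ((max − min)/2 per component) are measured on the span
between the first and last midpoint — outside it the interpolant is a
constant extension, not a decomposition. Per-cycle volumes are trapezoidal
integrals of |Q_i|/2 between the first and last peak of each component,
divided by the number of whole cycles.

When only a cardiac gradient is known (e.g. derived from cardiac-gated
PC-MRI flow), a representative respiratory component is constructed with
the cohort ratios: amplitude /2.85, frequency /4.11.

## Cohort aggregation

Quantities are averaged per window within a patient (ratios as per-window
ratios, not ratios of means), then mean ± sample SD (n−1) across patient
means — never pooled windows. Patients with fewer than two accepted
windows are excluded (mirroring the source cohort's exclusion of one
patient). Sleep vs awake is a two-sided paired t-test per quantity on
patient sub-means, pairwise-complete, with no multiple-comparison
correction (none is implied by the source analysis); zero-variance
differences are reported as degenerate rather than given a fabricated p.

## Synthetic data

The generator emulates the *structure* of overnight dual-sensor ICP: a
large common-mode pulsatile ICP (cardiac amplitude 4.5 mmHg by default,
plus a respiratory modulation at 0.25× that amplitude — raw ICP is
cardiac-dominated) identical in both channels, a small differential signal
L × (cardiac sinusoid + respiratory sinusoid + sub-0.1 Hz drift), optional
step artifacts (posture changes) applied to the second channel, and
independent Gaussian white noise per channel (the simplest model of the
reported high-frequency sensor noise; the real noise spectrum is
uncharacterised). Defaults follow the measured cohort means: cardiac
1.46 mmHg/m at 62/min, respiratory 0.52 mmHg/m at 15/min, L = 6 cm,
200 Hz sampling. All randomness flows from an explicit seed; no global
state.

What the generator does **not** model: ICP waveform morphology
(percussion/tidal/dicrotic sub-peaks), heart-rate variability, respiratory
amplitude modulation of the cardiac peak, or correlated sensor noise.
Passing recovery tests therefore demonstrate the correctness of the
pipeline's arithmetic under the stated signal model, not robustness to
every physiological confound.

## Problem sizes and numerical choices

Synthetic analyses use 2 h recordings per patient (20 windows) at 200 Hz;
parameter-recovery suites use 50 independent 6-minute windows at in-band
SNR 5. The oracle comparisons run α ∈ {1, 3, 5.5, 10} at 96 radial points
and 256 steps/period, converged well past the 1% comparison level (grid
refinement moves amplitudes by < 0.5%). mmHg↔Pa uses the single constant
133.322 Pa/mmHg; all internal computation is SI, with mmHg/m, mL/s and μL
only at I/O boundaries.
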