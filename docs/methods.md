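# Methods

`powderid` implements a complete desk workflow for identifying crystalline
substances — seized drugs in particular — from X-ray powder diffractograms:
conditioning of the raw scan, peak-position matching against a reference
library, and a quantitative cross-correlation similarity score, validated
end to end on a built-in instrument simulator.

## Data model

A diffractogram (`Pattern`) is intensity versus scattering angle 2θ on a
strictly increasing, uniform grid. The reference unit is the `Phase`: a
named list of reflections (2θ position at a stated wavelength, relative
intensity with the strongest line scaled to 100), the same information a
Powder Diffraction File card tabulates. Positions move between wavelengths
with Bragg's law, λ = 2d·sin θ: the lattice spacing d is the invariant, so
sin θ₂ = (λ₂/λ₁)·sin θ₁.

Two numerical conventions are worth stating. Text output uses 8 significant
digits; the reader snaps grids whose per-point jitter is below 1% of a step
onto an exact uniform grid (pure text round-off cannot exceed that), and
rejects anything worse with instructions to resample explicitly. Six digits
— a more common choice — would bound the relative round-trip error only at
5·10⁻⁶, which is incompatible with the 10⁻⁶ round-trip guarantee the
package makes, and the implied grid jitter would dwarf the uniform-grid
tolerance.

## Conditioning pipeline

The fixed stage order is: resample (only if grids must be unified) →
background → smoothing → Kα2 stripping → normalization. Every stage maps a
valid pattern to a valid pattern on the same grid, and each can be toggled
off for ablation.

**Background.** Iteratively clipped polynomial (default degree 5, tolerance
10⁻⁶, ≤ 100 passes): fit, replace points above the fit by the fit, refit.
A single least-squares fit is biased upward by the peaks; clipping descends
to the peak-free envelope. The fit uses a Chebyshev basis on [−1, 1] with a
precomputed projector, so each pass is two matrix–vector products. On noisy
data the converged curve sits at the *lower envelope* of the noise (about
1–2σ below the mean background), so the subtracted pattern retains a small
positive pedestal; squaring in the similarity score suppresses it, and peak
prominence thresholds handle it in detection.

**Smoothing.** Savitzky–Golay, default 11 points / order 3 (≈ 0.2° on the
0.019° grid, below typical peak FWHM). Polynomials up to the filter order
are reproduced exactly; edges use the polynomial extrapolation of the end
fits. On narrow peaks (FWHM ≈ 5 grid steps) the filter produces faint side
lobes, which is why detection thresholds should not be set arbitrarily low
even for noise-free data.

**Kα2 stripping.** A Cu tube emits Kα1 (1.540562 Å) and Kα2 (1.544398 Å) at
a 2:1 ratio, so every reflection appears twice. Rachinger-type stripping
solves K(θ₂) = observed(θ₂) − r·K(θ₁(θ₂)), where θ₁ is the Kα1 angle whose
companion lands at θ₂; we iterate this fixed point (a contraction for
r < 1, tolerance 10⁻¹² of the maximum, ≤ 200 passes) with negative
residuals clipped at zero. Residuals at the companion position are ≤ 3% of
the companion height across 10–59° on simulated doublets. Stripping must
not be applied to data that is already Kα1-only (synthetic singlet renders,
pre-stripped exports): subtracting a shifted replica of a singlet erodes
real lines and leaves echo artifacts. Set the doublet ratio to 0 in that
case; the validation experiments that render singlets do exactly this.

**Normalization.** Unit maximum by default (the strongest point becomes 1);
unit area is available. Unit maximum is required for the windowed
similarity score to spread usefully — see below.

## Peak analysis

Peaks are local maxima of the conditioned pattern above relative height
(default 1%) and prominence (0.5%) thresholds, with the apex refined by a
three-point parabola (worst observed error on noisy isolated peaks at
SNR ≈ 30 is ~0.005°, a quarter of a grid step).

Matching is greedy nearest-neighbour within a tolerance (default 0.10°,
about five grid steps): closest pairs commit first, each peak is used once,
distance ties break toward the lower angle — deterministic and order
independent. The matched fraction counts *reference* lines found in the
sample; unmatched sample peaks are reported as possible adulterants.
Relative intensities are deliberately ignored: crystal habit, preferred
orientation and grinding reorder peak intensities freely, while positions
are the substance fingerprint. Ranking ties between candidate phases are
broken by the windowed cross-correlation score against a clean render of
the tied phase, not by intensities, for the same reason.

## Cross-correlation score

With f′ and g′ the unit-max-normalized diffractograms of standard and
sample, the patterns are squared (f = f′², g = g′²) to accentuate peaks and
attenuate background, and the score is

    CCS = Σ_τ C_fg(τ) / Σ_τ C_ff(τ),      C_fg(τ) = Δ·Σ_i f_i g_{i+τ/Δ},

integrals discretized as rectangle sums (the step Δ cancels in the ratio).
CCS(p, p) = 1 exactly in every mode.

**The full-lag form factorizes.** Over all lags, Σ_τ C_fg = (Σf)(Σg), so
the literal score collapses to Σg/Σf — a position-blind intensity ratio
that cannot distinguish substances by where their peaks sit. The package
implements this `mode="full"` for completeness and asserts the
factorization as an exact algebraic property, but the recommended score is
`mode="windowed"`: restricting to |τ| ≤ 0.5° keeps position information
while absorbing small 2θ misalignments (sample height, thermal shifts).

**Known limitation.** Squaring after unit-max normalization weights each
line by the 4th power of its relative intensity, so the windowed score is
dominated by the one to three strongest lines. Two consequences, both
visible in the validation experiments: (i) a strong habit perturbation
(lognormal σ = 0.5) that boosts one line of the *standard* inflates the
auto-correlation denominator like u⁴ and can push a genuine same-substance
score down to ~0.2; (ii) an unrelated compound whose strong line falls
within the lag window of the standard's strongest line can score ~0.5–0.9.
Same-substance scores therefore exceed unrelated-compound scores clearly
*on average* (≈ 0.69 vs ≈ 0.12 in the shipped experiment), but the strict
extreme-value separation — the minimum within-substance score above the
maximum unrelated score over a full 7 + 6 score matrix — holds in only
~10–20% of seeded repetitions under these conditions. Smaller lag windows
and milder perturbations shrink but do not eliminate the overlap. For
identification, peak matching is primary and the score is a tie-breaker,
which sidesteps the issue; for similarity screening, the score matrix
should be read as a contrast of levels, not of extremes.

## Simulator

The generator emulates a Bragg–Brentano CuKα bench instrument: 5–60° 2θ in
0.019° steps, pseudo-Voigt profiles (η = 0.5 Gaussian/Lorentzian mix,
constant FWHM 0.1° — no Caglioti angle dependence) with *area* proportional
to relative intensity, the Kα2 companion placed by Bragg's law at half the
Kα1 area, a polynomial background (default flat 50 counts), and Poisson
counting noise (`noise_scale` s: counts ~ Poisson(s × clean), so variance
equals s × level; default s = 1, giving apex SNR ≈ 30 for a strong line).
Habit effects are modelled as independent lognormal factors (median 1) on
relative intensities, positions untouched. Reference fixtures carry 8–25
lines ≥ 0.3° apart with lognormal relative intensities clipped to [10, 100]
(cards tabulate lines above a floor); phases 0 and 1 of every fixture
library share half their positions, the structural-analog stress case
typical of designer drugs.

What the simulator does *not* model: structure factors and Lorentz-
polarization (intensities are free parameters, which is the point),
hkl-dependent March–Dollase orientation (the lognormal factor is an
empirical stand-in), angle-dependent broadening, sample-height or zero
shifts, and amorphous humps. Passing the shipped experiments therefore
demonstrates the pipeline's correctness and its robustness to intensity
reordering, counting noise and smooth backgrounds — not robustness to
every artifact of real instruments.

## Experiment sizes and seeds

The shipped validation experiments (also re-run by `scripts/acceptance.py`)
use: 100 random patterns for the self-score identity; 50 random pairs of
length ≤ 256 against naive double-loop oracles; 200 repetitions of the
7-same + 6-unrelated score-matrix contrast; 100 identification trials with
a 10-phase library; 11 doublet positions across 10–59°; 100 noisy
single-peak renders; and one 0.30/0.70 two-phase mixture per seed. All
randomness flows from explicit integer seeds through
`numpy.random.default_rng`; identical seeds give bitwise-identical
patterns.
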