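# Methods

## Generative model of a scan

A scan is a time series of spectral frames produced by three particle
populations — free species A, free species B and heterodimeric A·B
complexes — diffusing in two dimensions. The model reflects diffusers
confined to a membrane plane:

* **Geometry.** Particles live in a periodic square of half-width
  `box_half_width` (default 1.0 µm, ≥ 4 beam waists so the detection
  profile is negligible at the boundary). The detection profile is a
  Gaussian `W(r) = exp(−2 r²/w²)` centered in the box, with 1/e² waist
  `w = 0.25 µm`.
* **Counts.** Particle numbers are parameterized as mean counts in the
  *effective focal area* `A_eff = π w²`, the normalization for which a
  single-species autocorrelation amplitude obeys `G₀ = 1/N_eff`
  (because `A_eff = (∫W)²/∫W²` for a 2D Gaussian profile). Box counts
  are Poisson-resampled each scan at `mean · A_box/A_eff`, emulating
  scans at different spots with varying local concentrations.
* **Dynamics.** Steps are i.i.d. Gaussian with per-axis variance
  `2 D Δt`, wrapped periodically. Defaults `D_A = D_B = 1.0 µm²/s`,
  `D_AB = 0.4 µm²/s` (complexes slower), `Δt = 1/769 s`, 25,000 frames
  per scan — the acquisition geometry of the EMCCD spectral detection
  this emulates.
* **Detection.** Molecule m contributes `brightness · W(r_m)` to its
  channel; complexes carry one fluorophore of each color and appear in
  both channels. Default brightness: 3 detected photoelectrons per
  molecule per frame at the spot center — chosen to give
  signal-to-noise comparable to published cytoplasmic FCS; the source
  study does not report molecular brightness, spot size or expression
  levels, so these defaults are stated conventions, not inferences.
* **Spectral dispersion and noise.** Expected photons per bin are
  `Σ_f I_f(t)·S_f + background` with `S_f` normalized Gaussian-shaped
  emission profiles over 16 bins (YFP-like bluer, mCherry-like
  redder, moderate overlap). Camera counts are
  `em_gain · Poisson(expected) + N(0, read_noise_sd)`, floored at 0
  (gain 250, read noise 2 counts). This is a deliberately simple EMCCD
  surrogate: the excess-noise factor of the EM register, triplet
  blinking, photobleaching, 3D diffusion and flow are *not* modeled.
  Brightness and background are specified pre-gain; since the
  correlation normalizes by channel means, the gain convention does
  not affect G.

Randomness derives from a single master seed through
`numpy.random.SeedSequence` children (one per scan, reduced mod 2³¹),
so conditions are bit-reproducible.

## Unmixing

Each frame is decomposed by least squares against the reference
spectra, with a constant offset column (default on) absorbing the
uniform background, and coefficients constrained nonnegative by
default (NNLS; intensities are physical). The unconstrained branch is
kept both as an option and as the fast path: frames whose
unconstrained solution is already nonnegative need no NNLS. Near-zero
signal makes NNLS truncation slightly positive-biased, so bias-
sensitive diagnostics use the unconstrained branch; in the pipeline
the effect on fitted amplitudes is far below the condition-level
tolerances.

## Correlation estimator

`G(τ) = ⟨δI₁(t)·δI₂(t+τ)⟩ / (⟨I₁⟩⟨I₂⟩)` with δI the deviation from the
scan-global mean and the average over all overlapping pairs at each
lag. The lag grid is multi-tau-style: every integer lag until the
geometric spacing exceeds one frame, then ≤ `points_per_octave`
(default 8) lags per doubling, capped at `n_frames/8` to bound
estimator variance. Evaluation is a vectorized direct sum — no
binning or averaging approximations — so it is numerically identical
(10⁻¹⁰) to the literal double loop, which the tests verify against an
independent brute-force implementation.

Two known finite-size effects matter for interpretation:

* **Mean-subtraction pedestal.** Estimating the mean from the same
  finite trace biases G by roughly `−(2 G₀ τ_D/T)·ln(T/τ_D)` — a small
  negative pedestal (≈ −1 % of G₀ at the defaults). Amplitude *ratios*
  (Fc, codiffusing fractions) are insensitive to it; absolute
  dwell-time estimation is best done with a free baseline, which the
  dwell-law tests and examples do.
* **Closed periodic box.** With no particle exchange, long-lag G
  deviates slightly from the ideal hyperbola (periodic images
  re-enter the spot on the box-crossing timescale). One visible
  consequence: fitted-parameter standard errors shrink a little slower
  than √k when the trace length grows k-fold.

## Diffusion fit

`G_fit(τ) = G∞ + G₀/(1 + τ/τ_D)`, the 2D Brownian shape for
membrane-bound diffusers. The baseline G∞ is fixed at 0 by default —
the internally consistent companion of the fluctuation estimator,
which decays to zero — with `fixed1` (for correlations reported on a
+1 offset convention) and `free` available. Fitting is unweighted
Levenberg–Marquardt (lmfit) with initialization
`G₀ ← G(τ_min) − G∞`, `τ_D ←` lag at half decay, a grid search over
τ_D decades as fallback, and a truthful `converged` flag — never a
silent garbage fit. Only lags with ≥ 64 overlapping samples enter the
fit. τ_D is bounded to `[τ_min/2, 2·τ_max]` of the fitted window:
dwell times outside the sampled lag range are unidentifiable, and
letting τ_D collapse below the first lag would let pure-noise cross
curves extrapolate arbitrarily large zero-lag amplitudes. Standard
errors come from the fit curvature.

## Codiffusion statistics

With ideal amplitudes `G₀ᵃᵘᵗᵒ = 1/N` (all diffusers of that color) and
`G₀ᶜʳᵒˢˢ = N_c/(N_A·N_B)`:

* `Fc = 2 G₀ᶜʳᵒˢˢ/(G₀ᴬ + G₀ᴮ) = 2 N_c/(N_A + N_B)` — the share of all
  diffusers that are two-color complexes;
* fraction of species i codiffusing `= G₀ᶜʳᵒˢˢ/G₀ʲ = N_c/N_i` (j the
  other species).

Per-scan values are kept **unclipped** — fit noise pushes individual
scans outside [0, 1], and condition means are taken over the raw
values; clipping is available but off. Scans are excluded only for
non-converged fits (flagged, never dropped silently); there is no
outlier rejection. Conditions are compared with the two-tailed
unequal-variance (Welch–Satterthwaite) t test.

## Three-filter FRET

`nFRET = I_FF − α·I_DD − β·I_AA` pixelwise, negatives retained
(clipping is a display choice). Bleed-through slopes are
through-origin least-squares fits of I_FF on the single-label
reference channel over above-threshold pixels, after subtracting each
channel's sub-threshold background pedestal (a camera offset otherwise
inflates the slope). The default threshold is background mean + 2 SD,
with background taken as the dimmest quartile of the reference image;
both the threshold and an explicit background mask can be supplied.
The synthetic scene generator realizes the exact forward model
(Poisson noise per cube) and returns ground truth for testing.

## Contact fractions

A residue contacts a lipid class in a frame when any of its particles
lies within the cutoff of any particle of that class
(minimum-image distances when per-frame box lengths are given);
fractions average this binary indicator over frames — the most common
contact-fraction convention. The default cutoff 6.0 Å is a
coarse-grained bead-scale convention (4.5 Å suggested for all-atom
heavy atoms); it is configurable and not asserted to be any published
study's value. Binding regions are maximal runs of ≥ `min_run`
consecutive residues whose maximum fraction over classes reaches the
threshold. The k-d-tree search is verified against the all-pairs
computation.

## Problem sizes used in tests and the acceptance script

Condition-level checks use 30 scans × 25,000 frames per condition
(variant-like: free-A 5.5, free-B 0.9, complexes 4.5 → 45 % of A and
~83 % of B complexed; WT-like: 9.5/0.85/3.0 → 24 %/~78 %; null: 5.5/5.4/0).
Single-species law checks use 20 scans; these run the trace-level
pipeline (the spectral stage is exercised separately by its own
round-trip and unbiasedness checks). Parameter-recovery tolerances:
amplitudes and dwell times within 15 % (median over scans), condition
mean Fc within ±0.05, codiffusing fractions within ±5 percentage
points, zero-complex null |mean Fc| < 0.05.

## Known limitations

The simulator omits EM-register excess noise, detector afterpulsing,
triplet dynamics, photobleaching, 3D diffusion, flow and vesicle
transport; real spectral calibration (prism dispersion registration)
and blind unmixing are out of scope. Passing recovery tests on this
synthetic model demonstrates the correctness of the estimator chain
under the stated assumptions — not that real cytoplasmic scans satisfy
those assumptions. Brightness heterogeneity (multiple copies per
cluster) is not modeled, although amplitude ratios would be affected
by it in real data.
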