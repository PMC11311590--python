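# Methods

This note documents the models behind each `hemekin` module, the choices
made where the procedures were genuinely open, and what the synthetic
generators do and do not emulate.

## Redox buffer design (`hemekin.redox`)

The ferro/ferricyanide couple is treated as a one-electron couple with
the Nernst relation in natural-log form, Em = E°′ + (RT/F)·ln([ox]/[red]),
RT/F = 25.693 mV at the default 298.15 K (assay temperature). The
base-10 (59.2 mV/decade) form is equivalent; the natural-log form keeps
the closed-form inverse `ratio_for_em` trivial. No activity-coefficient
or ionic-strength correction is applied: at assay ionic strengths the
correction is smaller than the 10 mV rounding used when quoting buffer
potentials, and the published design itself quotes rounded values
(374 mV → "370 mV").

## Peroxidase assay (`hemekin.assay`)

ΔA(420−500 nm) is converted to ferricyanide with Δε = 1040 M⁻¹cm⁻¹ and a
1 cm default path. Rates are ordinary least-squares slopes. Three window
modes exist because real traces differ: `full` (default — most traces are
close to linear), `final` with fraction q (default 0.5, for traces with
an initial lag, where the rate must come from the final linear section)
and `manual`. There is no automatic lag detector: the choice of window is
an experimental judgement and is reported back (window and R²) rather
than hidden. Turnover is (rate − control)/[CytC]; negative values are
flagged, not raised, since a slow variant can fall within noise of the
control. Rounding to two decimals happens only at display time.

Note one arithmetic subtlety: (6.6 − 0.77)/3 = 1.9433, which displays as
1.94; published tables sometimes carry 1.95 for this entry, consistent
with rounding from unrounded input rates. The package always reports the
exact arithmetic of its inputs.

## Band arithmetic (`hemekin.bands`)

All band amplitudes are two-point differences A(λ_a) − A(λ_b) with linear
interpolation between grid points; wavelengths outside the recorded grid
are an error, never extrapolated (scan digitization is instrument-
specific, and extrapolated band amplitudes are meaningless). Difference
spectra are computed on the intersection grid with the reference
interpolated onto the sample's points. Concentration determinations are
straight Beer–Lambert inversions: Δε(550−540) = 18.7 mM⁻¹cm⁻¹ for the
reduced-minus-oxidized protein difference, ε(240) = 40 M⁻¹cm⁻¹ for H₂O₂.
Normalized band kinetics divide by the amplitude of a reference spectrum
(the pre-perturbation oxidized spectrum ≡ 1), which is how Soret and
695 nm charge-transfer bleaching curves are conventionally presented.

## Two-state MCD decomposition (`hemekin.mcd`)

The decomposition assumes a closed two-state system: every spectrum is
f·B_c + (1−f)·B_f. Three specifics were open and are fixed as follows.

*Free basis.* The last spectrum of the series. The complex decays to
completion on the recorded timescale, so the end-of-run spectrum is the
best available free-form estimate. Any residual complex in it makes the
fitted fractions linear-affine in the true ones (same rate constant,
slightly offset plateau) — the exponential fit of the fraction trace
therefore still recovers k, which is why `decay_fit` leaves the plateau
free.

*Complex basis by symmetry restoration.* A pure MCD derivative band is
antisymmetric about its zero crossing. The candidate
B_c(λ; f) = [first(λ) − (1−f)·free(λ)]/f is scored by
Σ|B(λ₀+δ) + B(λ₀−δ)| / Σ(|B(λ₀+δ)| + |B(λ₀−δ)|) over a half-grid-step δ
lattice inside the recorded range, λ₀ being the interpolated sign change
between the extrema; f is scanned on a 10⁻³ grid over [0.5, 1] and
refined by bounded golden-section search (xatol 10⁻⁷). On noiseless
mixtures this recovers f to < 10⁻³ and the basis to machine precision;
the score of the reconstructed basis is by construction never worse than
the first spectrum's.

*Unmixing.* With the sum-to-one constraint the least-squares problem is
one-dimensional and closed-form: f* = ⟨s − B_f, B_c − B_f⟩/‖B_c − B_f‖².
Fractions are clipped to [0, 1] (the raw value is kept for diagnostics;
its residual is orthogonal to B_c − B_f). Only two components are
modeled; a per-time residual RMS above 5% of the signal range raises a
flag suggesting a third species rather than silently absorbing it.

*Isosbestic points* are local minima of the across-time standard
deviation below a threshold (default 10% of the maximum SD — at a true
crossing the SD drops to the noise floor), refined to sub-grid precision
by parabolic interpolation. A series of identical spectra is degenerate
(every wavelength qualifies) and returns empty with a warning.

## Exponential kinetics (`hemekin.kinetics`)

y(t) = y_inf + (y0 − y_inf)·exp(−kt), fitted with
`scipy.optimize.curve_fit`; initial guesses come from log-linearizing the
data against the endpoint plateau. The reported time constant is the
half-time t½ = ln2/k, i.e. the time for the reaction to progress halfway
— the convention used when quoting τ for these decays — not the
e-folding time 1/k (both are derivable from the stored k). The plateau
is free by default because the complex decays to the free-form signal,
not to zero. No weighting is applied (the instrument noise structure is
unknown); a soft-L1 robust loss is available but off by default.
Non-convergence and constant records return `converged=False` with NaN
parameters instead of raising; steps against the fitted direction larger
than ~3σ of the between-sample noise trigger a warning.

## RMSF (`hemekin.flexibility`)

Frames are superposed by iterated Kabsch fits (via
`scipy.spatial.transform.Rotation.align_vectors`) of the Cα subset onto
the running mean structure, restarting from the ensemble mean so the
procedure is idempotent, until the mean moves < 10⁻⁶ Å RMS. RMSF is then
the per-residue root-mean-square deviation from the mean over frames,
in Å. Superposition absorbs six rigid-body degrees of freedom, which
biases RMSF low by roughly a factor √(1 − 6/(3N)) for N fitted atoms
(~1% at N = 100) — negligible against the 2% Monte-Carlo tolerance used
in validation. Multi-model PDB I/O goes through biotite; models with
inconsistent atom counts are rejected, and missing residues in region
reports are skipped with a warning, never imputed.

## Synthetic generators (`hemekin.synthetic`)

The generators define the validation conditions:

* **MCD series** — Gaussian lobes (σ = 1.8 nm, unit amplitude) at
  550/555 nm (complex) and 545/550 nm (free) on a 530–565 nm grid with
  0.5 nm steps; fractions f(t) = f₀·e^(−kt) with defaults f₀ = 0.95,
  k = ln2/2.8 min⁻¹ and scan times 0.3–14.1 min every 0.8 min, matching
  the cadence of minute-interval MCD scans of the decaying complex. The
  Gaussian line shape is an assumption (only the extrema positions are
  constrained by observation); two opposite-signed Gaussians are the
  simplest shape reproducing them. Validation noise uses SNR 50
  (noise SD = peak/50).
* **Assay traces** — product concentration rising linearly at the set
  slope after a C¹-smooth quadratic onset of duration `lag` (real lag
  phases are smooth; only the "final linear section" is well defined),
  converted to ΔA via Δε = 1040 M⁻¹cm⁻¹.
* **Butterfly series** — difference spectra A_max·(1−e^(−k_on·t)) times a
  fixed butterfly shape (−lobe at 403, +lobe at 417 nm, σ = 6 nm) over
  380–440 nm; default k_on = ln2/3.3 min⁻¹.
* **Ensembles** — Cα positions on an idealized helical trace with i.i.d.
  isotropic Gaussian displacements of per-axis width σ_r, so the exact
  expected RMSF √3·σ_r is known. Validation uses 100 residues × 10⁴
  frames at σ = 0.5 Å.

Noise is additive i.i.d. Gaussian per point everywhere — the generators
do **not** emulate baseline drift, photobleaching, turbidity,
wavelength-dependent noise, or correlated MD dynamics. Passing tests
therefore demonstrate correctness of the estimators under white noise
and exact two-state behavior, not robustness to every instrumental
artifact of real spectra.

Exponential-fit validation runs 100 decays with k = 0.2 min⁻¹ sampled
every 0.1 min over 20 min (kinetic-mode cadence) at 5% additive noise;
the median |k̂/k − 1| is ~2–3%.

## Numerical conventions

Times in minutes, wavelengths in nm, pathlength 1 cm unless stated;
concentrations in µM (protein, ferricyanide) or mM (H₂O₂). Seeds drive
`numpy.random.default_rng`; identical seed and arguments give
bit-identical outputs. Degenerate inputs (flat spectra, constant traces,
identical bases, single frames) raise `ValueError` with a specific
message rather than producing NaNs, except where a flag is the specified
behavior (non-converged fits, negative turnover, degenerate isosbestic
search).

## Known limitations

* The symmetry-restoration reconstruction is one consistent realization
  of an instrument-vendor procedure that is not publicly documented;
  other objectives (e.g. penalizing specific even moments) could give
  slightly different f₀.
* Only single-exponential kinetics are modeled; multi-exponential or
  stretched decays are out of scope.
* The two-component unmixing has no provision for a third species beyond
  flagging high residuals.
* RMSF is computed globally over the supplied frames; no block averaging
  or convergence analysis of the underlying trajectory is attempted, and
  trajectory formats other than multi-model PDB are not read.
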