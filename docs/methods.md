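# Methods

## Quenching-binding model

The core model assumes a single class of equivalent, independent binding
sites and intensity-based detection. Per temperature T:

* Stern–Volmer: F₀/F = 1 + K_sv[Q]. K_sv is the OLS slope of F₀/F versus
  [Q]. By default the intercept is a free parameter and is reported —
  experimental lines rarely pass exactly through 1, and a free intercept
  keeps r² meaningful; an `anchored` option forces the theoretical
  intercept and regresses (F₀/F − 1) through the origin. K_q = K_sv/τ₀
  is stored alongside, with τ₀ defaulting to 10⁻⁸ s (the order of the
  tryptophan fluorescence lifetime); when results are quoted at the
  customary 10¹¹ M⁻¹s⁻¹ scale this default makes K_q numerically equal
  to K_sv on the 10³ M⁻¹ scale. τ₀ is a configuration parameter, never
  inferred.
* Double-log: log₁₀((F₀−F)/F) = log₁₀K_a + n·log₁₀[Q] by OLS. Points
  with F ≥ F₀ (no net quenching) have an undefined left-hand side; they
  are dropped with a warning and at least three points must survive.
  Base-10 logarithms here, natural logarithm in the Van't Hoff step.
* Van't Hoff: ln K_a regressed on 1/T; ΔH = −slope·R, ΔS = intercept·R
  with R = 8.314 J/(mol K), reported in kJ. ΔG = ΔH − TΔS per
  temperature. Two temperatures give an exact line (r² = 1 by
  construction); users should treat thermodynamics from fewer than three
  temperatures as indicative.
* All regressions are unweighted OLS with r² = 1 − SS_res/SS_tot; when
  the response is constant, a perfect fit reports r² = 1.

Temperatures are always caller-supplied. The bundled worked example uses
293/303/310 K because that triple is exactly consistent with its ΔH, ΔS
and ΔG values.

### Classification rules

Mechanism: the K_sv trend over temperature uses strict monotonicity with
a relative tie tolerance of 10⁻⁶ (ties or mixed trends → `flat`).
Increasing K_sv with every K_q above the diffusion-controlled collision
limit (2×10¹⁰ M⁻¹s⁻¹, configurable) → `combined`; increasing but below
the limit → `dynamic`; decreasing and above → `static`; anything else →
`indeterminate`.

Driving force (Ross–Subramanian): ΔH < −tol and ΔS < 0 →
hydrogen-bond/van der Waals; ΔH > tol and ΔS > 0 → hydrophobic;
|ΔH| ≤ tol, or ΔH < −tol with ΔS > 0 → electrostatic. tol = 1 kJ/mol
defines "ΔH ≈ 0"; there is no field-standard threshold, and 1 kJ/mol is
well under thermal energy at room temperature. The remaining sign
combination (ΔH > tol, ΔS < 0) lies outside the convention — binding
would be non-spontaneous at all temperatures — and falls back to
`electrostatic` rather than raising, since the label set is closed.

## Spectra

λ_max is the grid argmax (ties → shorter wavelength) refined by a
parabola through the peak and its two neighbours, which recovers
sub-grid centres on smooth bands; the raw argmax is available with
`refine=False`. A maximum on the window edge is returned unrefined with
a warning. Shift calls use a 0.5 nm tolerance — half a typical 1-nm grid
step; published shifts are ≥ 2 nm. No smoothing is applied by default; a
moving-average method is provided. The suggested emission search window
is 300–450 nm, which excludes the 280 nm excitation line.

## Assays

Ellman's sulfhydryl formula is Beer–Lambert with the standard TNB
extinction 13 600 M⁻¹cm⁻¹ and explicit dilution bookkeeping (default
factor 11 from 0.5 mL sample + 4.5 mL buffer + 0.5 mL reagent). Negative
BPB-bound masses and out-of-range calibration inversions are returned
with warnings, not clamped — downstream QC decides. The urea/thiourea
partition treats the two releases as independent measurements and calls
dominance at a 10 % relative margin.

## CD deconvolution

Fractions solve min‖Aw − y‖ subject to w ≥ 0 (scipy NNLS), then are
renormalised to the unit simplex. Because renormalisation absorbs any
overall scale of y, the result is invariant to the spectrum's
concentration/path-length normalisation, which is rarely recorded
consistently. `residual_norm` is the relative residual of the
unnormalised solution. The packaged basis is synthetic: Gaussian band
parameterisations of the canonical class shapes (helix: positive ~193 nm
band and the 208/222 nm double minimum; sheet: positive ~195, negative
~218; turn: weak positive ~205; coil: strong negative ~198). Band widths
are chosen narrow enough that the helix double minimum is resolved and
the four classes stay well-conditioned. Fractions from real spectra are
therefore indicative, not comparable to commercial deconvolution
packages with measured reference sets.

## Trajectory metrics

* RMSD: centroid removal plus the optimal rotation from the SVD of the
  cross-covariance; a reflection is corrected by flipping the smallest
  singular direction so the rotation is always proper. This matters for
  near-planar or chiral point sets, where the improper solution would
  underestimate RMSD.
* RMSF: frames are superposed onto a reference, then each atom's RMS
  deviation from its time-mean position is taken. The default reference
  is the time-mean structure after two alignment passes (first to the
  initial frame, then to the provisional mean). A `fit_subset` restricts
  the superposition to a rigid core so mobile atoms do not bias the
  alignment.
* SASA (Shrake–Rupley): each atom carries a golden-spiral lattice of
  quasi-uniform test points on its probe-inflated sphere (probe 0.14 nm,
  960 points by default — relative quadrature error < 1 %, and halving
  vs doubling the count changes 10-atom cluster totals by < 1 %); a
  point is accessible if outside every other inflated sphere. The
  hydrophobic/hydrophilic split sums per-atom areas by caller-supplied
  flags, with an element heuristic (N/O polar, C/S hydrophobic) as the
  default.
* Hydrogen bonds: donor–acceptor distance ≤ 0.35 nm and
  hydrogen–donor–acceptor angle ≤ 30°, the common geometric criterion in
  MD analysis tools; hydrogens are attached to donors by a 0.12 nm
  covalent cutoff. Each donor–acceptor pair counts at most once.
* Van der Waals radii (nm): H 0.12, C 0.17, N 0.155, O 0.152, S 0.18;
  unknown elements default to 0.17. All tables are overridable.

PDB ingestion (Biopython, multi-MODEL) converts Å → nm; a plain
multi-frame XYZ reader is included. Only post-hoc geometry is computed —
no force fields, thermostats, docking or binding-energy decomposition.

## Synthetic data

Generators are exact inverses of their analysis stages at zero noise,
which anchors the round-trip test suite. Defaults mirror the study
conditions the package targets: quencher ladder 0, 0.760, 1.520, 2.282,
3.041, 3.802 ×10⁻⁴ M; temperatures 293/303/310 K; worked-example K_sv of
750/1120/1460 M⁻¹. Fluorescence noise is multiplicative lognormal
(detector noise scales with intensity; 1 % is typical of a bench
fluorimeter), CD and absorbance noise additive Gaussian. One integer
seed drives a named, CRC-derived substream per generator, so adding a
generator never perturbs another's stream.

What the generators do *not* emulate: inner-filter effects, fluorophore
heterogeneity (multiple tryptophan environments), scattering baselines,
instrument drift, and cooperative or multi-site binding isotherms.
Passing recovery tests therefore demonstrates the estimators are
correct and stable under idealised noise, not that real spectra satisfy
the single-site model.

## Problem sizes and determinism

The recovery simulations use 200 replicates (quenching) and 100
replicates (CD) at the default six-point ladder — enough for stable
medians/means while the whole suite runs in seconds. The brute-force
RMSD oracle scans an 18³ Euler grid with a Nelder–Mead polish.
Everything random is seeded; `hypothesis` tests run derandomised.
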