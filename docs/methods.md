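# Methods

## Models

### Light-controlled dissociation (photokinetics)

Zdk unbinds from LOV2 either directly from the dark, high-affinity state
(rate `k3`, s⁻¹) or after a light-driven conformational change: photoexcitation
at rate `k1·ν` (with `k1` per µW·cm⁻²·s and ν the blue-light intensity in
µW/cm²) followed by fast unbinding from the lit state at `k2` (s⁻¹). Treating
the conformational step and lit-state unbinding as sequential first-order
events gives the apparent dissociation rate

    k_obs(ν) = k1·ν·k2 / (k1·ν + k2) + k3,

rising from `k3` in the dark and saturating at `k2 + k3`. The enforced
binding half-life is τ = ln2 / k_obs. Defaults anchor the tunable range at
τ(0) = 10 s and τ(∞) = 0.5 s, with half-saturation of the light-dependent
term at 2 µW/cm² so that the 16 µW/cm² maximum of the intensity program is
effectively saturating (τ(16) ≈ 0.56 s).

`k_obs` is measured by fitting `y(t) = p + (y0 − p)·e^(−k_obs·(t−t_on))` to
post-illumination frames. A free plateau `p` is fitted by default because
washout can be incomplete; it can be pinned to zero. The (ν, k_obs) fit is
unweighted least squares by default, with an optional 1/SE² weighting. LED
voltage→intensity calibration uses monotone piecewise-linear interpolation
and refuses to extrapolate, because LED output is non-linear at low voltages.

### Proofreading chain and saturable response

Each proofreading step is a competing-exponentials race between the forward
transition (`kp = ln2/τ_p`) and dissociation (`koff = ln2/τ_off`):
α = τ_off/(τ_off + τ_p) per step, `α^n` through the chain. In the
strong-proofreading limit (τ_p ≫ τ_off) α is proportional to τ_off, and the
productive upstream signal from `R` occupied receptors scales as `R·τ^n`.
The DAG readout is modeled as saturable in that signal:

    DAG = A·R·τ^n / (K + R·τ^n) + β.

`A` (DAG a.u.) is a free amplitude absorbing arbitrary reporter units; `K`
(units of R·τⁿ) is the half-maximal upstream signal; `β` (DAG a.u.) is basal
signaling. Because this assumes every step proofreads strongly, the fitted
`n` is a lower bound on the true number of steps.

Occupancy is recorded in arbitrary units that depend on each day's optical
path, so `(n, K, β, A)` are fitted per imaging day (datasets at different
ligand densities within a day are combined); pooling across days must be
requested explicitly. Fitted `n` is invariant to rescaling the DAG values
(normalization scheme) and to rescaling occupancy units within a day (`K`
absorbs the scale); both invariances are tested numerically.

### Amplification

Far from saturation (R·τⁿ ≪ K, β = 0), DAG ∝ R·τⁿ. At fixed occupancy a
fold-f change in half-life changes DAG by `f^n`. Comparing two ligands at
equal *density*, the longer-lived ligand also reaches f-fold higher
occupancy (equilibrium occupancy ∝ τ far from binding saturation), so the
total amplification is `f^(n+1)`: for n = 2.7 and f = 10 this is
10^3.7 ≈ 5.0×10³ — the "~5,000-fold" figure — while the proofreading steps
alone contribute 10^2.7 ≈ 5.0×10². `amplification_factor` exposes both via
`include_occupancy`.

## Fitting and uncertainty

The proofreading fit is bounded trust-region least squares
(`scipy.optimize.least_squares`, `x_scale='jac'`, tolerances 1e-14) with
n ∈ [0, 10], K, A > 0, β ≥ 0, initialized at n = 1, β = min(DAG),
A = max(DAG) − β, K = median(R·τ). A fit with `n` pinned at a bound is
flagged, not silently accepted. Degrees of freedom ≤ 4 are refused.

The 95% CI on `n` is the symmetric normal approximation n ± 1.96·sd(n).
Two variance estimators are provided:

* `ci_method='linear'`: the conventional linearized covariance
  (J'J)⁻¹·RSS/dof. The Jacobian is column-equilibrated before inversion —
  `K` is typically ~10⁶ while `n` is ~1, and without equilibration the
  pseudoinverse cutoff makes var(n) depend on the arbitrary units of the
  data. The pseudoinverse tolerates directions that are genuinely degenerate
  (e.g. `n` at a bound).
* `ci_method='bootstrap'` (default): sd(n) from case-resampling bootstrap
  refits (200 resamples, warm-started at the full-data solution, seeded).
  Under realistic multiplicative cell-to-cell noise the least-squares surface
  is curved along the correlated (n, K) ridge and the linearized variance
  understates the uncertainty of `n`; the bootstrap spread is calibrated in
  our replicate studies (~95% coverage versus ~88% for the linearized CI at
  the generator's default noise). The linearized method is retained for
  comparability with conventional `curve_fit`-style analyses.

Normal-approximation CIs presume dof well above 30; the per-day defaults give
dof = 116.

## Measurement chain (images)

Flat-field correction divides `(frame − offset)` by `(dye − offset)` and
refuses non-positive dye signal. RICM segmentation thresholds (Otsu by
default, fixed threshold optional), keeps the largest connected component,
fills holes, and flags footprints touching the frame edge. The background
ribbon is the morphological dilation by 6 px minus the dilation by 2 px —
widths are configurable; the source protocol specifies only a "thin ribbon
slightly expanded" from the footprint. Occupancy is mean(cell) −
mean(ribbon), divided by the whole-field ligand-channel intensity normalized
to its time-course mean; mean-one per-frame laser fluctuations therefore
cancel exactly, and an overall scale is part of the arbitrary units. DAG is
the mean of the last six frames minus the PP2 baseline minus drift, where
drift is the measured block's reset-pulse value minus the mean of the final
three reset values (end-anchored, where drift has stabilized). Negative
corrected values are retained unclipped so fit residuals stay unbiased.
Pixels are 0-based row-major boolean sets; no subpixel geometry. Frames are
assumed registered; the synthetic fixtures are generated aligned.

Absolute calibrations: ligand density ρ_sat = ρ_counted·DF·[Cy3]/(f·[A488])
scaled by the measured fraction of saturation; receptor counts from a log-log
OLS regression of antibody binding capacity on bead MFI, background
subtracted, reported as a (count, 2·count) range because a bivalent IgG can
engage one or two receptors.

Spearman correlations use average ranks for ties (scipy). Kernel smoothing
is a Gaussian-kernel Nadaraya–Watson estimator; fitted values are convex
combinations of the observations, and grid points farther than 8 bandwidths
from all data are returned as NaN rather than extrapolated.

## Synthetic data: what it emulates and what it does not

The generator mirrors the experimental design: per day, 4 bilayer datasets at
densities (40, 150, 450, 1200) molecules/µm² (the sensitive working range),
30 cells per dataset, each cell assigned one intensity from the program
(0, 0.1, 0.2, 0.4, 0.8, 1.6, 3.2, 16) µW/cm², producing roughly log-spaced
half-lives 10 → 0.56 s. Occupancy follows the simplest law consistent with
half-life increasing occupancy — binding equilibrium
`R = R_tot · konρ/(konρ + koff)` with `kon·ρ` = 2e-4 s⁻¹ per (molecule/µm²)
and R_tot = 1.5×10⁵ receptors — times a per-day unit scale drawn uniformly
from [0.5, 2] (emulating day-to-day optical-path changes) and a mean-one
lognormal cell factor. DAG is the saturable response evaluated at the cell's
*recorded* occupancy, times an independent mean-one lognormal factor
(CV 0.25), plus additive Gaussian noise (SD 2 a.u. = 2% of A). Ground truth
defaults: n = 2.7, K = 1e6 (placed mid-range of R·τⁿ so the response is
well identified), β = 5, A = 100.

The lognormal noise family and its CV are a stand-in — the distribution of
real cell-to-cell variability is unknown — so passing recovery tests shows
the estimator is correct and calibrated *under this generative model*, not
that real data are this well behaved. The image renderer produces a single
static disk footprint with a radial vignette and optional per-frame laser
factors and Poisson noise; it contains no PSF, evanescent-field depth,
bleaching, motility or multi-cell fields, so quantification tests validate
the measurement arithmetic, not segmentation robustness on difficult images.

For the occupancy-only null study (true n = 0) the half-max constant is set
to K = 5×10⁴ ≈ the median occupancy: with the n = 2.7 default K = 1e6 (units
R·τⁿ) an n = 0 response is essentially linear in R and (A, K) are jointly
unidentifiable, which would test parameter degeneracy rather than the null
hypothesis about `n`.

Determinism: one root seed; each generator derives an independent child
stream via `default_rng([stream_offset, seed])` with fixed offsets 1–4
(cell table, traces, events, images), so adding calls to one generator never
perturbs another.

The binding-event simulator draws per-step Bernoulli(α) outcomes and gamma/
exponential waiting times rather than a full event-loop simulation — for a
single receptor chain the embedded jump chain is exactly this process — and
serves as the stochastic oracle for `α^n`.

## Known limitations

* The fitted `n` is a lower bound tied to the strong-proofreading
  assumption; τ_p is not estimated.
* Day-level fits assume a single (n, K, β, A) per day across ligand
  densities; dataset-level β variation is not modeled.
* Bootstrap CIs cost ~200 refits per fit (~1 s per day group at the default
  study size); use `ci_method='linear'` when speed matters more than
  calibration.
* The deposited single-cell spreadsheet of the original study can be read
  via `read_cell_table` with a `column_mapping`, but is not bundled; tests
  and examples run entirely on synthetic data.
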