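# Methods

This note documents the models, estimators and numerical choices behind
resikit, in the spirit of the methods documentation of packages such as
statsmodels or msprime: what is computed, under which assumptions, and which
knobs matter.

## The RESI estimator

A localization table holds independent position measurements
x_i ± lp_i of target molecules. Under the model that the K localizations of
one target are i.i.d. normal around the true position, the
minimum-variance linear unbiased (and maximum-likelihood) estimator of the
position is the inverse-variance weighted mean with weights w_i = 1/lp_i²:

    x̄_wtd = Σ w_i x_i / Σ w_i.

Its reported precision is the weighted standard error of the mean,

    sem = sqrt(Var_wtd / K),
    Var_wtd = K/(K−1) · Σ w_i (x_i − x̄_wtd)² / Σ w_i,

which reduces to the ordinary Bessel-corrected s.e.m. for equal weights. The
lateral precision of a RESI localization is the average (not quadrature sum)
of the x and y s.e.m. The axial coordinate uses a plain unweighted mean and
its precision is taken as twice the lateral value, reflecting the roughly
twofold larger axial spread of astigmatic 3D detection; no per-localization
axial precision is stored. For equal lp the estimator obeys
σ_RESI = σ_SMLM/√K, the scaling law the precision module verifies.

Precision is quantified as the scalar spread σ = sqrt(½·tr cov(x, y))
(unbiased covariance), which equals σ for an isotropic Gaussian. The
in-silico curve draws M localizations per site, splits them into n = M/K
*disjoint* subsets (enforcing M/K ≥ 10), and measures the spread of the
subset means; disjoint partitioning rather than resampling with replacement
matches the n = M/K subset count and keeps subset means independent. The
experimental resampler applies the same procedure to a measured cluster and
extrapolates the all-M precision as (cluster spread)/√M.

## Clustering and artifact filters

Targets are found as neighbour-count local maxima: localization i is a
maximum iff no localization within radius r of it has a strictly higher
neighbour count, with exact ties broken toward the lower index — a strict
"more neighbours than all neighbours" rule would leave a flat-topped cloud
with no maximum at all, while the lowest-index preference keeps the result
deterministic and yields exactly one maximum per plateau. Maxima are
processed in decreasing-count order (ties again by index); each claims all
not-yet-assigned localizations within r, so localizations are never shared
between clusters. Clusters need *more than* n_min members to survive (the
threshold is strict). In 3D the neighbourhood is the ellipsoid
sqrt(dx² + dy² + (dz·r/r_z)²) ≤ r; r_z ≈ 2r is a sensible default given the
axial spread. A good starting radius is about twice the localization
precision: larger radii merge adjacent targets, smaller ones split single
clouds ("subclustering", visible as a spurious NND mode near 2r).

Two temporal filters remove unspecific-sticking artifacts, exploiting the
fact that genuine repetitive blinking is spread uniformly over the
acquisition so a true cluster's mean frame concentrates near the middle:

* mean-frame filter: reject if the cluster's mean frame falls within the
  first or last 20% of frames (rejection is closed at the boundaries:
  mean ≤ 0.2·n_frames or ≥ 0.8·n_frames, with 0-based frames);
* window filter: partition [0, n_frames) into 20 equal windows anchored at
  acquisition start; reject if any single window holds more than 80% of the
  cluster's localizations.

Both fractions and the window count are parameters. The size threshold is
applied before the temporal filters; since the filters are independent, the
order affects only which rejection label a doubly-bad cluster receives.
`suggest_n_min` histograms per-pick localization counts, smooths lightly,
detects modes with a prominence filter (10% of the peak) and reports the
antimode between the two dominant modes; it declares the histogram unimodal
when the valley is shallower than half the lower mode, since such dips are
binning noise rather than a background/target separation.

## Alignment

Rounds are registered in two stages. The coarse stage bins both tables into
2D histograms on a shared grid and FFT-cross-correlates them; the peak,
refined to sub-bin precision by 1D quadratic interpolation along each axis,
gives the translation. Non-overlapping fields, or a correlation with no
peak above 5 σ of the correlation map, produce a warning and a zero shift
rather than an arbitrary one. The fine stage solves the 2D orthogonal
Procrustes problem (SVD/Kabsch, no scaling) on fiducial pairs matched by
mutual nearest neighbour within a cutoff; ambiguous matches are dropped
with a warning. The rotation pivot defaults to the fiducial centroid, which
decouples rotation and translation estimates. Rotation is strictly
in-plane; z passes through untouched. Near-collinear fiducial geometry is
flagged because it conditions the rotation poorly.

## Design calculators

With on-rate k_on, imager concentration c, bright time τ_bright and
exposure t_exposure, the mean dark time is τ_dark = 1/(k_on·c) and the
expected localizations per site in time t are t·k_on·c·τ_bright/t_exposure;
inverting gives the acquisition time for a requested n_loc, and
n_loc = ⌈(σ_SMLM/σ_RESI)²⌉ (rounded up — a fractional localization cannot
be collected). Stochastic labelling with n sequences at probability 1/n
gives P(diff. seq.) = 1 − 1/n for a pair and P(m, n) = n!/((n−m)!·nᵐ) for m
molecules; the unresolved fraction for CSR-distributed targets is the
first-NND CDF F = 1 − exp(−ρπd²) at effective density ρ = density/n and
resolvability distance d = 4σ by default (stricter than the 2.35σ FWHM
criterion). A Monte-Carlo estimate of F is exposed alongside the closed
form; the two agree within sampling error. The module deliberately does not
combine the pair probability with the CSR fraction into one number — the
correct composition depends on the molecular arrangement, so the primitives
are exposed separately.

## Synthetic data

The generator emulates the statistical structure the analyses rely on, not
microscope physics. Localization clouds are isotropic Gaussians of s.d.
σ_SMLM (axial s.d. 2σ_SMLM by default) with lp = σ_SMLM per localization;
frame indices are i.i.d. uniform in the default blink mode (the idealization
of repetitive blinking; used for filter tests), or generated from a Poisson
binding-event process with τ_bright/t_exposure consecutive frames per event
in kinetic mode. Sticking artifacts are injected as extra clusters at
random positions (they arise from unspecific imager sticking, not from true
sites) with all frames inside a short consecutive span. Not modelled:
photon budgets, PSF shape and astigmatism, drift, camera noise, sequence-
specific kinetics. Consequently, passing tests demonstrate the correctness
of the estimators and filters under the stated statistical model, not
robustness to optical aberrations or residual drift in real data.

The membrane-receptor mixture draws CSR monomers and CSR dimer centres;
each dimer contributes two molecules at a *fixed* distance D in a uniformly
random orientation (the generative description specifies only the expected
distance, not a distribution; the fixed-distance choice puts all spread
into the uncertainty term). Every molecule is perturbed once by an isotropic
Gaussian of s.d. σ_label (labelling + localization variability, applied per
molecule rather than per localization) and survives detection independently
with probability equal to the labelling efficiency. Because both endpoints
are perturbed, the observed intra-dimer distance is Rician with mean
slightly above D — the fitter uses the identical generative code, so this
is self-consistent. Points are generated in a window enlarged by a 100 nm
guard band and cropped (for the CSR reference, distances of core points are
computed against all points including the guard band), eliminating
nearest-neighbour edge deflation. "Density of dimers" counts pairs per µm²,
each carrying two molecules; fit-space parameters are translated so that
observed density = (total molecule density) × labelling efficiency holds by
construction, with frac_of_dimers the percentage of molecules in dimers and
frac_of_monomers = 100 − frac_of_dimers.

## The monomer/dimer fit

The fit minimizes the sum of squared differences between the binned first-
NND histogram of the data and of simulations, over (D, σ_label,
frac_of_dimers); observed density and labelling efficiency are fixed to
their experimental values. Binning is 1 nm over 0–100 nm (configurable):
fine enough to resolve a ~13 nm dimer mode, coarse enough for stable counts
at ~2×10⁴ points. Histograms are normalized to fractions so sample sizes
need not match. Only the first NND order enters the objective; orders 2–4
serve as CSR-consistency diagnostics.

Numerically the objective is stochastic, so three devices keep the
optimization honest:

1. **Histogram averaging before squaring.** Replicate simulations are
   averaged into one histogram before the SSE is taken; this shrinks the
   shot-noise floor of the objective by the replicate count. It matters
   because the model has a partially degenerate direction — a small-D,
   large-σ_label dimer (Rayleigh-like separation) mimics a large-D,
   moderate-σ_label one (Rice-like) to within a few 10⁻⁵ in SSE.
2. **Common random numbers.** All evaluations within a stage share fixed
   simulation seeds, making the objective deterministic for the optimizer.
3. **Coarse grid → re-ranking → local refinement.** An 11×11×11 grid over
   D ∈ [1, 20] nm, σ_label ∈ [1, 20] nm, frac ∈ [0, 100] % is scored with a
   cheap reduced-window simulation (~5,000 molecules; the histogram shape
   depends on density, not count). The best ~20 grid points are re-scored
   at the data-matched window with replicated simulations — this guards
   against the cheap pass picking the wrong basin within its noise — and
   the winner seeds a Nelder–Mead refinement (clipped to the ranges,
   simplex spanning about one grid cell, up to 120 iterations) of the
   replicate-averaged objective at full window size.

Parameter uncertainties follow the refit procedure: M datasets are
simulated at the optimum with the data's molecule count, each is fine-
fitted (Nelder–Mead from the optimum, no coarse stage), and the per-
parameter standard deviation across refits is reported. M < 10 is flagged
as indicative only. Degenerate inputs (all-coincident points) return a
failed-fit flag rather than an arbitrary optimum.

## Problem sizes and defaults used in tests

The test suite and acceptance script run at desk scale: precision curves
use M = 2–3×10⁴ simulated localizations per site; geometry-recovery tests
use 50–80 localizations per site over 5–50 seeds; the mixture fit is
exercised on ~21,000-molecule datasets (420 µm² at 50 µm⁻² observed
density) with 10 independent fits, and the refit-uncertainty procedure at
M = 20 rather than 100 — a replication choice that leaves the s.d.
estimates unbiased, only noisier by √5.

## Known limitations

* The clusterer's hard radius truncates each Gaussian cloud (~86% capture
  at r = 2σ); reported K undercounts the true localization number
  accordingly, consistently with the radius-based cluster definition.
* The fiducial correspondence is mutual-nearest-neighbour after coarse
  translation; it assumes fiducials are sparser than the matching cutoff
  and does not reconstruct ROI-selection heuristics used in per-origami
  workflows.
* The window filter anchors windows at acquisition start, not at the
  cluster's first frame.
* Whether a localization within r of two maxima may be shared is resolved
  by forbidding sharing (first-processed maximum wins).
* The mixture fit assumes the monomer/dimer model; it does not test for
  higher-order oligomers (chains, hexamers), for which only the order ≥ 2
  NND CSR diagnostics give indirect evidence.
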