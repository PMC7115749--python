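# Methods

This note records the models, numerical choices and synthetic-data
assumptions behind `ramanphen`, at the level of detail a maintainer or
reviewer needs to interpret what the tests do and do not demonstrate.

## Preprocessing

Spectra pass through four steps in a fixed order: replicate averaging,
truncation to the 400–1,800 cm⁻¹ biological window (inclusive bounds),
Goldindec baseline subtraction, vector normalization. The order matters —
normalization after baselining means downstream models see pure spectral
shape — and the pipeline refuses to reorder it. Averaging before
baselining follows the conventional workflow; baselining individual
acquisitions first is defensible noise-wise and can be composed manually
from the step functions if wanted.

### Goldindec baseline

The fluorescence background is modelled as a low-order polynomial
(default degree 3) on the shift axis rescaled to [0, 1] for conditioning.
The fit minimises an asymmetric truncated-quadratic cost by iteratively
reweighted least squares: points whose residual above the current fit
exceeds a scale threshold *s* are peak candidates and drop out of the
next refit; points at or below the fit always keep full weight. The
threshold is chosen by golden-section search (40 iterations on
[1e−6, 1] of the unit-range signal) so that the resulting peak fraction
— the share of points classified above the baseline by more than *s* —
matches the user's estimated peak ratio (default 0.5). IRLS runs at most
100 iterations to a relative tolerance of 1e−6 on the baseline; failure
to converge raises a warning, never a silent pass. A constant input is
degenerate: the baseline is the input and the corrected spectrum is zero.

Pre-smoothing uses a Savitzky–Golay window (default 5 points, polynomial
order capped at the baseline order) rather than a boxcar mean. Both are
moving-window smoothers; SG was chosen because it reproduces polynomials
up to the fit order exactly, including at the window edges, so a
background-only input is recovered to machine precision — a boxcar
distorts polynomial edges by O(h²) and would leak that distortion into
the fitted baseline.

Recovery performance is assessed against construction oracles: on
generated spectra (cubic background several times the band scale,
Lorentzian bands, default parameters) the estimated background stays
within 5 % of the true background's range, and peak heights over a
constructed cubic are recovered within 5 %.

## PCA and DAPC

PCA is mean-centred SVD; `min(n − 1, p)` components are retained, which
is the full rank of the centred matrix, and explained-variance ratios
are singular values squared over total variance. Every loading (and
canonical axis) is oriented so its largest-magnitude element is
positive, making outputs reproducible across linear-algebra backends.
The test suite checks eigenvalues against a brute-force covariance
eigendecomposition and full-rank reconstruction at 1e−8.

DAPC is linear discriminant analysis on the top `n_pcs` PC scores: the
generalised eigenproblem S_b v = λ S_w v with between-class and pooled
within-class scatter. When S_w is singular — inevitable as `n_pcs`
approaches the sample count — a ridge of 1e−8 × trace/dim is added.
Axes are scaled so the pooled within-class variance of the canonical
scores is 1, which makes centroid separations directly interpretable in
within-class standard deviations. At most `min(n_pcs, k − 1)` axes are
kept. Classification is nearest group centroid in canonical space
(Euclidean); distances within 1e−9 of the minimum count as a tie, broken
toward the first label in sorted class order. Uniform priors are
assumed throughout. Class labels are ordered by sorted unique value.

"Contributions" of a DAPC model are its canonical axes back-projected
through the PC loadings onto the shift grid — the model shows which
wavenumbers drive class separation; for PCA the loading itself is used.
The table is ranked by absolute weight and annotated from a built-in
band-assignment table (nearest entry within 5 cm⁻¹).

## Validation and random chance

Leave-one-out refits PCA *and* DAPC inside every fold — the held-out
spectrum never influences the decomposition, the strict no-leakage
reading. Per-class metrics are one-vs-rest: sensitivity (TPR),
specificity (TNR) and binary accuracy; overall accuracy is the
multiclass correct fraction. Displayed percentages are rounded to one
decimal; internal values are exact.

The random-chance baseline is a predictor drawing one of the *k*
observed classes uniformly at random (not prevalence-weighted — the
uniform version uniquely yields the familiar 33/67 and 14/86/76 printed
values): sensitivity 100/k, specificity 100(1 − 1/k), one-vs-rest
accuracy 100[p/k + (1 − p)(1 − 1/k)] with class prevalence p. A
vectorised Monte-Carlo estimator cross-checks the closed forms (tested
at 10⁵ draws within 0.5 percentage points).

`pc_sweep` reports one leave-one-out result per retained-PC count and
flags the best by overall accuracy, ties toward fewer PCs; the noisy
label construction in the tests shows the expected overfitting pattern
(best performer below the largest model).

## Distance statistics

TSD, TPD and TCD sum √((x_i − ref_i)²) over, respectively, the truncated
shift grid, the first five PC scores, and the top five DAPC canonicals.
The summand reduces to |x_i − ref_i|, so as written these are L1
distances, and that is the default — despite the "multi-dimensional
distance" intuition suggesting Euclidean; an `l2` option is provided.
A model with fewer than five canonical axes (e.g. any 2-class DAPC, one
axis) sums over all available axes. The reference spectrum is the
pointwise mean of the control group's processed spectra; its definition
travels with every distance table. On unit-norm spectra TSD is bounded
by 2√(grid length) (Cauchy–Schwarz), asserted in the tests alongside the
metric axioms and a naive-loop oracle at 1e−12.

ANOVA of distances on experimental factors uses type II sums of squares
(robust to unbalanced designs); pairwise comparisons use Tukey's HSD at
α = 0.01 (99 % confidence). Regression against a numeric covariate is
OLS with the signed Pearson R; band/analyte correlation reads the
processed intensity at the nearest grid point (optionally a ± window
mean) and reports Pearson R.

## Circadian analysis

Outlier handling is two-stage and non-destructive (points are flagged,
never deleted): first the median method — |x − median| > 3 scaled MADs,
scale 1.4826, the standard reading of that named default — then a hard
TSD > 0.15 ceiling on the points still kept. Both stages compute their
statistics on the full series, so filtering is idempotent. The MAD
multiplier and ceiling are arguments. Note that on a series whose spread
puts the MAD fence below 0.15, the median stage intercepts large
excursions before the ceiling does; the ceiling is the backstop for
dispersed series.

The kept points are fitted with a least-squares quartic (numpy
`polyfit` on raw hours; the 0–24 range is well conditioned, and time-
shift equivariance holds to 1e−6). Interior extrema come from the real
roots of the cubic derivative inside the fitted window, classified by
the second derivative; a quartic admits at most two interior maxima,
which is exactly why fourth order is used — it is the lowest order able
to express a bimodal excursion. `returns_to_initial` holds when the
fitted endpoint values differ by at most 10 % (configurable) of the
fitted range — "full return" needs an operational tolerance and 10 % is
this package's choice; a numerically flat fit returns trivially and is
not bimodal. `bimodal` requires exactly two interior maxima separated by
an interior minimum.

The time-course builder holds the reference out of the series: the
earliest sample's replicate acquisitions are split in half, one half
averaged into the reference phenotype, the other standing in as the 0 h
observation. Comparing the 0 h spectrum to itself would pin TSD(0) to
exactly zero while every later point carries the acquisition-noise
floor, biasing the fitted endpoints; the split gives all points a
comparable floor.

## Synthetic data

`generate_spectrum` builds background + Σ band profiles + i.i.d.
Gaussian noise. Bands default to Lorentzian (the natural Raman line
shape; Gaussian available) with half-width 6.5 cm⁻¹ — consistent with a
13 cm⁻¹ instrument resolution — at positions and relative amplitudes
from the built-in assignment table, carotenoid bands dominant as in
cyanobacterial whole-cell spectra. The background is a cubic on the
normalised axis, several times the band scale, decreasing toward high
shifts like typical fluorescence. The default grid is 1 cm⁻¹ steps over
400–1,800 (1,401 points), finer than the instrument resolution so
interpolation cannot drop bands.

Study-level structure: per condition, `n_samples_per_condition`
biological samples (each band amplitude jittered by a lognormal with
σ = 0.05 — independent cultures differ by a few percent), each with
`n_replicates` = 20 acquisitions carrying additive noise with
σ = `noise_sd` × largest base amplitude (default 0.05). The
two-condition recovery study scales one carotenoid band (1,520 cm⁻¹) by
3× — an effect an order of magnitude above the sample-level variation,
as a strong induced phenotype is. The nitrate series raises glycogen
bands up to 2.5-fold at full deprivation while chlorophyll- and
carotenoid-associated bands fall (chlorosis). The glucose preset raises
storage-carbohydrate bands.

The circadian generator modulates the glycogen and carotenoid band pool
along a normalised trajectory m(t). For light/dark cycling, m is
0.7 × (the quartic with interior extrema exactly at 6, 12 and 18 h,
normalised to [0, 1] with zeros at 0 and 24 h) + 0.3 × sin²(πt/12):
maxima exactly at the 6 h and 18 h sampling points, a partial midday
return, full return at 24 h — and, importantly, a shape whose own
least-squares quartic has interior maxima within ±1 h of 6 and 18
(purely periodic shapes such as |sin| or sin² pull the fitted maxima to
~4.3/19.7 h). Dark mode drifts linearly without return. The preset's
noise scale differs from the classification studies: a single culture
tracked through time is far more reproducible than independent
biological samples, and because TSD accumulates |noise| over 1,401 grid
points, the observed 0–0.15 TSD working range pins the effective
post-averaging noise; the preset uses noise_sd 3e−4, sample jitter 5e−4
and modulation depth 0.02, giving a peak TSD ≈ 0.11 over a noise floor
≈ 0.02, inside the range the 0.15 exclusion ceiling leaves intact.

What the generator does **not** emulate: cosmic-ray spikes, detector
etaloning, wavenumber miscalibration between acquisitions, band-shape
changes (only amplitudes move), heteroscedastic shot noise (an i.i.d.
Gaussian is the simplest defensible model; a shot-noise mode would be a
config extension), or real covariance between molecular pools. Passing
recovery tests therefore demonstrates the correctness of the
computations under known ground truth, not instrument-grade robustness.
The published culture metrics (e.g. the 95.3 %/93.4 %/96.9 % glucose
classification or the R = 0.82/0.92 band–analyte correlations) depend on
the original acquisitions and wet-lab measurement tables and are not
reproducible from synthetic data; the pipeline recomputes the same kinds
of quantities from user-supplied spectral and metadata files via
`ramanphen run`.

## Problem sizes and determinism

All simulation entry points are driven by a single integer seed and are
bit-reproducible. The test suite and acceptance script use moderate
sizes chosen as sufficient for their statistical checks: 100 random
pairs/triples for the distance oracles, 20 random matrices for the PCA
oracle, 10 samples per condition for classification recovery with a
50-permutation null, 100 seeded replicates for circadian recovery, 10⁵
draws for the Monte-Carlo random-chance cross-check.
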