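# Methods

`rptfusion` implements a structure–behavior interaction analysis for
three-group psychiatric cohorts (healthy controls, major depressive
disorder, cocaine-dependence polysubstance use): operant-keypress
reward/aversion metrics are extracted per participant, regressed against
normalized regional brain volumes within each group, and the resulting
slope matrices are compared across groups and fused into a kNN
classifier. This note records the model, the parameter choices that
matter, and the places where the design was genuinely open.

## Keypress metrics (relative preference theory)

The behavioral task trades keypresses for picture viewing time across
4 categories × 20 pictures; approach ("inc") presses lengthen viewing,
avoidance ("dec") presses shorten it. Per participant, category and
valence we compute K (mean keypresses per responded picture), σ (their
standard deviation) and H (Shannon entropy, bits, of the normalized
count distribution over the category's pictures, so 0 ≤ H ≤ log₂20).
Three per-participant curves over the four per-category points yield the
nine RPT graph features:

- **value function** H = b·ln(K − x₀), fit on the avoidance limb by
  profiling the residual sum of squares over the offset x₀ (closed-form
  slope at each x₀; coarse 400-point grid then bounded scalar
  minimization, tolerance 1e-12). Curvature b is *loss resilience*;
  x₀ is the *negative offset*. A power law H = a·K^b is the fallback
  when the log form cannot be produced.
- **limit function** σ = aK² + bK + c (ordinary least squares).
  *Negative turning point* = −b/2a, *negative apex* = c − b²/4a,
  *negative area* = (b² − 4ac)^{3/2}/(6a²), defined only when the
  fitted parabola crosses the K axis.
- **trade-off function** over per-category (H⁺, H⁻) points:
  r = √(H⁺² + H⁻²) and θ = arctan(H⁻/H⁺) (degrees from the H⁺ axis;
  90° when H⁺ = 0), summarized by their across-category means
  (*radial distance*, *polar angle*) and sample (n−1) standard
  deviations (*radial/polar dispersion*).

With the six base variables (K±, H±, σ± averaged across categories)
these are the 15 "keypress metrics". A participant whose avoidance
value fit, avoidance limit fit, or trade-off construction cannot be
produced is flagged invalid with a reason code and excluded from all
group-level analyses — the same exclusion mechanism applied during
cohort assembly in this study design.

Choices made where the convention was open: K and σ are computed over
pictures with a nonzero count of the given valence (work actually
traded; a zero-inclusive variant is a config switch); entropy is the
within-category entropy of the participant's count distribution over
pictures; an all-zero side is undefined (NaN), not zero; the quadratic
area is reported as an absolute area.

## Regression grid

Per group, each of the 15 metrics (dependent) is regressed on each of
the 29 volumes (independent), 435 cells per group. Demographic
covariates are screened per (group, volume): ethnicity by two-sample
Wilcoxon rank-sum between the two largest strata (participants
identifying as Asian dropped), age and years of education by Spearman
correlation; a demographic enters the model only at screening p < .05.
A covariate-free variant of the grid feeds the heatmap stage.

Outliers are removed by Cook's distance, iteratively (single worst
observation per refit, capped at 20% of the sample). The removal
cutoff is the Cook–Weisberg convention — remove while max Dᵢ exceeds
the median of F(p, n−p), about 0.7 for a bivariate fit. We measured
the common 4/n flagging threshold used as a *removal* rule and found it
degenerate: on clean Gaussian data it removes ~10% of points per
regression (single pass) or cascades to the cap (iterated), inflating
the null significant-cell rate of a 435-cell grid from ~0.05 to 0.11
(single pass) or 0.22 (iterated). The F-median cutoff keeps the null
rate inside the exact binomial 99% band around 0.05 while still
removing a gross outlier and nothing else; `cooks_rule="4/n"` remains
available for sensitivity analysis. One caveat: Cook's distance is
leverage-weighted, so a gross y-outlier at the exact center of the
x range tops out near D ≈ 0.5 and survives the default cutoff.

Variables are z-scored within group over the retained observations
(categorical covariates enter as unscaled indicators), so the reported
β is standardized; with no covariates it equals the Pearson correlation
of the retained points. CIs are t-based at 95%. Regressions need
n ≥ 10 after listwise deletion; smaller cells are skipped with a
reason, never aborting the grid.

q-values are Benjamini–Hochberg, computed per (group, volume) family
across the 15 metrics. Holm's step-down is available
(`bh_method="holm"`) because published report tables of this design
sometimes carry q = p·(m − rank + 1) arithmetic despite naming BH.

Cross-group overlap counts cells significant in two groups ("common")
and those whose β signs also agree ("consistent"); the headline
fraction is 2·consistent / total significant regressions, the
"a of b" convention.

## Heatmap comparison

Per group pair, three cellwise matrices over the covariate-free grids:
valence |β_A|−|β_B| (−1..1), intensity |β_A−β_B| (0..2), and sign
agreement (+1 same, −1 opposite; undefined when either β is exactly 0).
Summary tests: one-sample t of the valence cells against 0 (an all-zero
vector is reported as t=0, p=1 rather than undefined); the sample
median of the intensities with a one-sample Wilcoxon signed-rank test
against 0 (zeros dropped) — the two-sample rank-sum variant against
another pair's intensities is available, since a rank-sum test of a
single error distribution against "median zero" is not well formed;
and a proportion test of the same-sign rate against 0.5 (normal
approximation without continuity correction by default, exact binomial
by config). All defined cells enter the comparisons, not only
significant ones; a significant-only restriction is a config switch.
Heatmaps are rendered volumes × metrics on a diverging red–blue scale
anchored at each matrix's documented range, deterministically.

## Feature selection and kNN

Candidate features (metrics and volumes) are screened with
Kruskal–Wallis plus Dunn's pairwise z tests on pooled mean ranks with
tie correction; the three pairwise p-values are BH-corrected within
each feature and the feature is selected when any pairwise q < .05.

Classification is pairwise leave-one-out kNN, k = 5. Continuous
features are whitened by the inverse principal square root of the
pooled within-group covariance (Mahalanobis transform; a small ridge
handles singular covariance), re-estimated inside every LOO fold so no
held-out information leaks into the metric (a whole-sample fit is a
config switch). One-hot demographic indicators are appended after the
transform, unscaled, and excluded from the covariance. The k nearest
training points vote; class scores are prior × vote share with priors
defaulting to training-fold class proportions; score ties resolve to
the larger prior, then lexicographically. Six feature combinations are
evaluated per group pair (metrics / volumes / demographics and their
unions), 18 models in total.

## Synthetic cohort generator

The generator emulates the cohort the analysis assumes, with planted
ground truth:

- **Sizes** default to 40 CTRL / 25 MDD / 46 CD.
- **Counts**: each picture carries a latent per-participant valence
  (approach with probability 0.5); only that side receives a count,
  drawn negative-binomial with per-category means spread over roughly
  1.3–11 keypresses/picture (mild group shifts in overall work rate),
  dispersion 8, a lognormal participant work-rate multiplier
  (σ = 0.18), and censoring at 12 keypresses — the censoring is what
  produces the rise-then-saturate variance–mean (limit) curve seen in
  real keypress behavior. About 90% of simulated participants yield
  fully fittable profiles; the rest exercise the exclusion path.
- **Volumes**: anatomically plausible baseline fractions of total brain
  volume (summing to ~0.87). A coupled (volume, metric, group, ρ) cell
  is built in z space as z_vol = ρ·z_metric + √(1−ρ²)·noise within
  that group, so the population standardized slope equals ρ; uncoupled
  volumes are independent noise around the group-free baseline; z maps
  to fractions as baseline·(1 + 0.05·z), with positivity clamps and a
  total-volume rescale that never trigger at the default spread.
- **Demographics** are sampled independently of volumes (age ~ normal
  38 ± 10.6 clipped to 18–65, education uniform 8–20, male-majority
  gender and White-majority ethnicity mixes); an optional age→volume
  slope exercises covariate screening.

What the generator does **not** emulate: anatomical covariance between
regions, task learning/fatigue within a session, demographic–behavior
correlations, and diagnosis-specific response topologies beyond rate
shifts and planted couplings. Passing recovery tests therefore shows
the estimator chain is correct and calibrated, not that real cohorts
carry effects of the planted size.

## Problem sizes and numerics

Calibration checks use 40 participants/group (one 435-cell grid per
group); recovery checks use 200/group with 27 planted cells at
|ρ| ∈ {0.5, 0.6}. All randomness flows from a single integer seed
through one `numpy` Generator; identical seed and configuration give
bit-identical outputs. Optimizer tolerances: 1e-12 for the value-fit
offset search; 1e-8 ridge relative scale for singular covariance;
quadratic fits fail when |a| < 1e-8 within the fit's scale.

## Known limitations

- The value-function curvature is heavy-tailed at four points per fit;
  occasional extreme loss-resilience values are expected and are the
  main driver of Cook's-distance removals downstream.
- Dunn's z test uses the normal approximation; at very small groups
  (< ~5) its pairwise p-values are approximate.
- The LOO-kNN prior-weighted vote is one reasonable reading of
  "priors applied"; discriminant-style implementations may weight
  differently, and exact replication of any particular statistical
  package is not attempted.
- Replication of a specific published cohort's cell-level numbers is
  sensitive to the Cook's-distance convention and to the exact entropy
  estimator; both are exposed as configuration rather than fixed.
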