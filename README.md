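# rptfusion

Structure–behavior interaction analysis for operant-keypress cohorts.

Psychiatric conditions such as major depressive disorder (MDD) and
cocaine-dependence polysubstance use (CD) are hard to separate with
either behavior or brain imaging alone. `rptfusion` implements a
pipeline for discriminating control (CTRL), MDD and CD groups through
the *interactions* between computational reward/aversion behavior and
brain structure: it extracts relative-preference-theory (RPT) metrics
from operant keypress data, regresses them on total-brain-normalized
regional volumes within each group, compares the resulting slope
matrices between groups with a heatmap framework, and fuses the
selected features into a Mahalanobis leave-one-out kNN classifier.
It is aimed at computational-psychiatry researchers who have per-picture
keypress counts and regional brain volumes per participant.

## The model in brief

From each participant's approach (inc) and avoidance (dec) keypress
counts over 4 picture categories × 20 pictures, three RPT curves are
fit across the per-category points (K = mean keypresses, H = Shannon
entropy in bits, σ = standard deviation):

- value function H = b·ln(K − x₀) (avoidance limb → loss resilience b,
  negative offset x₀),
- limit function σ = aK² + bK + c (→ negative apex, turning point
  −b/2a, quadratic area (b²−4ac)^{3/2}/6a²),
- trade-off function over (H⁺, H⁻) with r = √(H⁺²+H⁻²),
  θ = arctan(H⁻/H⁺) (→ polar angle/dispersion, radial
  distance/dispersion).

Together with K±, H±, σ± these form 15 keypress metrics. Per group,
each metric is regressed on each of 29 normalized volumes (Cook's-
distance outlier removal, screened demographic covariates, standardized
β with 95% CI, Benjamini–Hochberg q per volume family). Group pairs
are then compared cell-by-cell on β valence (|β_A|−|β_B|, t test),
intensity (|β_A−β_B|, median + Wilcoxon signed-rank) and sign agreement
(proportion test vs 0.5), and classified pairwise with k=5 LOO-kNN
after pooled within-group whitening. A synthetic cohort generator
plants known (volume, metric, group, ρ) couplings so the entire chain
can be validated against ground truth. Details and design rationale:
[docs/methods.md](docs/methods.md).

## Worked example

```python
from rptfusion import SimulationConfig, Coupling, generate_cohort, build_cohort_table
from rptfusion.association import run_grid, grid_summary, overlap_analysis
from rptfusion.heatmaps import beta_matrix, compare

cfg = SimulationConfig(
    seed=42,
    coupling_spec=(
        Coupling("Right Thalamus", "loss_resilience", "CD", -0.5),
        Coupling("Right Amygdala", "negative_offset", "MDD", -0.6),
    ),
)
ds = generate_cohort(cfg)                       # 40 CTRL / 25 MDD / 46 CD
cohort = build_cohort_table(ds.responses, ds.participants)

grids = {g: run_grid(cohort, g, with_covariates=True)
         for g in ("CTRL", "MDD", "CD")}
ov = overlap_analysis(grids)
mc = compare(beta_matrix(cohort, "MDD"), beta_matrix(cohort, "CD"))
```

Output:

```text
cohort: 111 participants, 97 with fittable profiles
CTRL: 17 of 435 cells at p<.05
MDD: 23 of 435 cells at p<.05
CD: 12 of 435 cells at p<.05
planted CD cell: std beta=-0.373, p=0.0195
cross-group consistency: 4 of 52 = 7.7%
MDD vs CD: intensity median=0.169 (p=5.2e-73), sign agreement=0.51
```

Reading this: 14 of 111 simulated participants could not produce all
required RPT fits and are excluded (flagged, not dropped from the
tables). Each group's 435-cell grid shows a modest number of
significant structure–behavior cells; the coupling planted in the CD
group is recovered with the right sign (β = −0.37). Only 4 of the 52
significant regressions are "consistent" — significant in two groups
with the same slope direction — so the groups' structure–behavior
patterns barely overlap, and the MDD/CD slope matrices differ strongly
in intensity while agreeing in sign at chance level (51%).

A full run (grids, heatmap PNG/SVGs, feature selection, 18 kNN models)
from the shell:

```bash
rptfusion all --seed 42 --out results_dir      # simulates a cohort
rptfusion all --responses responses.csv --participants participants.csv --out results_dir
```

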