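# Methods

## The experiment being modelled

The package targets a common design in plant stress ecology: offspring from
several source populations (here five, labelled NE, NW, C, SE, SW, with SE
and SW the southern pair), with seed families nested in populations, grown
in a 2×2 factorial of temperature (average ≈ 20.6 °C vs high ≈ 25.2 °C) and
watering (average vs low), in five spatial blocks per treatment. Plants sit
in 54-pot trays of which only every second pot is used — a checkerboard of
27 plants — so rosettes never touch and image analysis stays per-pot.
Rosette growth is photographed about twice a week from germination;
performance (germination day, survival, longevity, flowering) is scored
throughout; at harvest plants are separated into inflorescences, dead
leaves, living leaves and roots and weighed fresh and dry.

## Imaging

Segmentation keeps pixels whose HSV hue falls in a green window or a red
window (union of the two masks), with saturation/value floors that reject
unsaturated background. No numeric thresholds are canonical for this step,
so both windows are configuration (`SegmentationConfig`); the synthetic
fixtures draw plants in colors strictly inside the green window and
backgrounds with zero saturation, so tests do not depend on the window
edges. Pot cells are half-open pixel rectangles `[y0,y1)×[x0,x1)`, 0-based,
tiling the image exactly — per-pot counts therefore sum to the whole-mask
count with no double counting. Areas are `count × (mm/px)²` with one scalar
calibration per tray; there is no checkerboard detection and no exposure
normalization. Unused pots are reported as absent, never as zero.

## Growth models

Seven mean functions with 2 or 3 parameters (see the table in
`rosette/growth.py`). Fits minimize the residual sum of squares with
`scipy.optimize.least_squares` under box bounds that keep each model in its
valid domain (e.g. the power exponent positive so area(0)=0). Initialization:
asymptote ← 1.05·max(area), x_mid ← day nearest half-max, scal ← day
range/4; three perturbed restarts before a fit is flagged non-convergent
(AIC = +∞). Model comparison uses the Gaussian-error AIC
`n·ln(RSS/n) + 2(k+1)`, counting the error variance as a parameter and
dropping additive constants (identical across models within a plant, so
rankings are unaffected). RSS is floored at 1e-12 inside the logarithm so
exact fits remain finite; AIC ties within 1e-9 go to the model with fewer
parameters, then to a fixed model order. The two-parameter logistic fixes
its asymptote at the maximum observed area — a pragmatic convention, one of
several possible.

Growth traits are always read off the three-parameter logistic (refit if a
different model won the AIC comparison): size = A, x_mid, and growth
rate = A/(4·scal), the analytic slope at the inflection.

## Functional traits, transforms, nuisance correction

SLA = rosette area at final imaging / living-leaf dry mass (mm²/mg);
LDMC = living-leaf dry (mg) / living-leaf fresh (g); root:shoot = root dry /
(all leaves + inflorescences dry). Dead leaves never enter SLA or LDMC;
whether they count in the shoot is a flag (default: they do, matching the
"all leaves" wording of the standard definition; the generator produces zero
dead-leaf mass so both conventions coincide on synthetic data). Growth rate,
root:shoot, SLA and LDMC are log₁₀-transformed; nonpositive values exclude
the plant for that trait.

"Considerable variance" for nuisance correction is operationalized as an
ANOVA F-test at p < 0.05 per term — a threshold knob, since no canonical
value exists. Correction is sequential in the order germination day (numeric
covariate), block, tray-within-block; each passing term is removed by OLS
residualization with the grand mean re-added, so corrected and raw traits
share their mean and corrected variance never exceeds raw variance. A joint
single-regression alternative is available by flag. Factor levels emptied by
missingness are dropped from the term design; fully aliased terms are
skipped with a warning.

## Selection analysis

Standardization is within treatment ((x − mean)/sd, n−1 denominator).
Combined-stress imputation: per family, the mean of that family's trait
means under heat and under drought (the single available mean if only one
exists, flagged; plants of families absent from both drop out). It applies
only to SLA, LDMC and root:shoot in the combined treatment, on the
analysis (log) scale before standardization.

Fitness families: flowering and survival are Bernoulli, fit by logit-link
binomial GLM (statsmodels' IRLS); longevity is Gaussian, fit by OLS.
Univariate model choice is AIC between `W ~ z` and `W ~ z + z²` (the
quadratic model keeps the linear term — the standard hierarchy); ties go to
the linear model. Quadratic coefficients are reported **as fitted**, not
doubled to the Lande–Arnold γ. Complete separation in a binary fit is
detected (runaway coefficients or non-finite standard errors) and the result
marked non-estimable rather than reported. Multivariate gradients come from
a single linear model of all six traits; aliased traits are dropped from a
rank-deficient design. Wald standard errors and p-values throughout.

## Population statistics

The rank-sum contrast uses the Mann–Whitney U (scipy): exact enumeration
when the combined sample is ≤ 12 and tie-free, otherwise the normal
approximation with tie and continuity corrections; identical pooled values
return p = 1 at the null-centered statistic. Contrasts pool plants within
region group at the plant level by default (family-mean pooling by flag).
Two-sided p-values, no multiple-testing correction. Flowering is only
contrasted where flowering occurred. Correlations are pairwise-complete
Pearson with t-distribution p-values. PCA decomposes the trait correlation
matrix on complete cases (eigenvalues sum to the trait count; each
component's largest-magnitude loading is made positive). The factorial
estimator is ordinary fixed-effects OLS (logit GLM for binary outcomes) on
control-referenced coding — a deliberately simplified validator for
synthetic data, not a mixed-model analysis; random-effect structures are out
of scope.

## Synthetic-data generator

The generator's defaults are the emulated study conditions: 5 populations ×
10 families × 4 treatments × 5 blocks = 1000 plants. Growth truth is the
three-parameter logistic (a config switch generates from any of the seven
models); per-treatment parameter means follow the factorial pattern
(asymptote 1464.85 mm² at control, heat −209.25, drought −374.06,
interaction −62.10; inflection day 27.12, −1.48, −1.38, −2.30; curve scale
4–4.5 d, chosen as a realistic steepness since no reference value exists).
Observation noise is Gaussian (default sd 25 mm²), areas clipped at 0,
imaging every 3.5 days, horizon 70 days. Mortality per treatment derives
from survival logits 3.51, −1.62, −1.84 with interaction −2.71 — mild under
single stress, far worse than additive combined — plus a +1.5 survival-logit
advantage for southern plants under combined stress only. Death days of
non-survivors come from a Gaussian longevity model clipped to the
experiment; flowering is essentially restricted to benign-temperature cells.

Harvest weights are generated by inverting the trait definitions from the
plant's terminal rosette area, with Gaussian family effects (sd 10% of the
target mean) and plant noise (5%) on SLA (target 20 mm²/mg), LDMC
(250 mg/g) and root:shoot (0.5); the family and plant variabilities are
order-of-magnitude choices exposed in `SimConfig`, not calibrated values.
Weights floor at 0.1 mg so every ratio stays positive for the log transform.
Binary fitness is Bernoulli with success probability
inv-logit(base + β·z) on within-treatment standardized true traits;
longevity is Gaussian around a linear predictor. Default β mirror the
dominant gradients of the emulated experiment (control flowering: SLA 0.29,
LDMC 0.10, root:shoot −0.04; combined-stress longevity: size 0.14). SLA,
LDMC and root:shoot are deliberately withheld for plants that die under
combined stress, which is what exercises the family-mean imputation.

Reproducibility: every plant draws from a substream seeded by
`(seed, plant index)`, so identical configs give byte-identical tables and
any subset of plants is reproducible alone.

What the generator does **not** emulate: real leaf shapes (plants are
drawn as filled disks — sufficient for testing per-pot counting, silent on
segmentation of ragged rosettes), lighting/exposure variation, spatially
correlated block effects, overlap between neighbouring plants (the design
prevents it), climate at the source sites, and trait–mortality feedback on
the growth curve beyond truncation at death. Passing tests therefore
demonstrate the correctness of the computational chain under known truth,
not the field validity of any biological conclusion.

## Simulation sizes and numerical choices

Power-style checks use sizes at which the relevant asymptotics are
informative while keeping the suite quick: 200 plants per generating model
for model-selection power at 2% noise, 100 replicates of n = 2000 for
multivariate gradient recovery, 10 replicates of the full default
experiment for the qualitative stress-interaction pattern. In the
model-selection power study the linear truth carries a 50 mm² intercept
(a zero-intercept line is exactly the power model with b = 1, making the
two indistinguishable) and the von Bertalanffy truth sets t0 = 0 so the
curve is non-negative over the whole observation window (a negative pre-t0
segment is not a valid area trajectory, and clipping would distort the
generating model).

One boundary worth knowing: when the truth is purely linear, AIC still
admits the spurious quadratic term in a fraction of replicates approaching
P(χ²₁ > 2) ≈ 0.157 — an intrinsic property of AIC, not an implementation
defect — so the expected linear-pick rate tops out near 84%.

## Known limitations

- No mixed-effects growth or trait models; the factorial estimator ignores
  block/family random structure by design.
- The longevity fitness model is Gaussian with identity link (a config
  switch is the natural extension point); no variance-standardized vs
  mean-standardized gradient conversions, no correlational (z_i·z_j)
  selection terms.
- Segmentation is pure color thresholding: no instance segmentation, no
  machine learning, no handling of overlapping rosettes.
- The two-parameter logistic's fixed asymptote makes its AIC slightly
  optimistic when the observed maximum happens to sit near the true
  asymptote.
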