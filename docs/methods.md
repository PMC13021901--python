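# Methods

## Data model

An observation is a strictly positive quadruple (T [K], P [bar], y, ρ):
temperature, pressure, drug solubility as reported (the source tabulates y
without units; values are used on the printed scale, never rescaled), and
CO₂ density (kg·m⁻³ scale). Datasets are ordered; loading preserves row
order and validates every cell (numeric, > 0). The packaged fixture is the
32-row phenytoin / scCO₂ table, grouped by its four temperatures, stored
at full printed precision in `src/solubag/data/phenytoin_scco2.csv`; a
load → write → load cycle is the identity on records.

## Preprocessing

Temperature (≈313–345) and pressure (≈95–250) are on incomparable scales,
so every family z-scores the raw features with training means/SDs before
any expansion or distance computation. Scalers are fitted per training set
(for bagging, per bag), stored on the fitted model, and applied at
prediction time.

## Base learners

**Polynomial.** Design matrix = all monomials z_T^a z_P^b with a+b ≤ d
(intercept first, graded-lexicographic order, T before P within a degree
block). Coefficients solve the ridge normal equations with the intercept
unpenalized; with penalty 0 and full rank this is exactly OLS, and a
singular unpenalized system raises rather than silently pseudo-inverting.
A small default penalty (1e-8) stabilizes near-singular high-degree
expansions of 32-point data.

**Gamma GLM.** Same expansion; log link. For the gamma family with log
link the IRLS working weights are identically 1, so each iteration is one
ridge solve against the working response η + (y−μ)/μ. Iteration starts
from the least-squares fit of log y, stops when the relative deviance
change is below 1e-10, and errors (carrying the last iterate) at 100
iterations. Dispersion is the Pearson χ²/(n−p) estimate. Predictions
exp(η) are positive for any finite query.

**KNN.** Brute-force Euclidean (optionally Manhattan) distances on the
standardized features; prediction is the unweighted mean of the k nearest
targets. Ties at the k-th distance break by training-set index (stable
argsort), making predictions deterministic. All three families are
deterministic given (data, config).

## Bagging

`fit_bagged` draws B with-replacement index samples of size
round(fraction·n) (fraction 1.0 by default — classical bagging), fits one
base model per bag, and averages member predictions. The ensemble seed
spawns child seeds as seed + bag index, so a fixed seed reproduces every
member bitwise while bags stay independent. A bag whose fit fails (e.g. a
singular design) is redrawn at most 5 times. `bootstrap=False` gives every
member the identity bag, the degenerate single-model case used in tests.

## Bat-algorithm tuning

The optimizer implements exactly the two velocity/position update
equations with componentwise random frequency F ~ Uniform[0, f_max]
(f_max = 1), position clipping to the search box, and an elitist archive;
the classical loudness/pulse-rate dynamics and local random walk are
intentionally omitted. Defaults: 20 bats, 50 iterations for generic use.

Hyperparameter boxes: polynomial/gamma — degree ∈ [1,6] (integer), ridge
penalty ∈ [1e-8, 1] (log scale), B ∈ [10, 200]; KNN — k ∈ [1, min(20,
n−1)], B ∈ [10, 200]. Integer dims round to nearest on decoding.

The tuning objective is the five-fold cross-validated RMSE of the *bagged*
model: folds come from one seeded shuffle fixed across all candidate
evaluations (so the objective is a deterministic function of the
position), and squared errors are pooled over all held-out points before
taking the root — one RMSE per candidate rather than a mean of five, which
is less noisy on 6–7-point folds. Training RMSE is deliberately not the
objective: it degenerates (k = 1 and maximal degree give near-zero
training error). Inside `tune_model` the search budget is 10 bats × 15
iterations (160 evaluations); the hyperparameter boxes are small and
low-dimensional, and a full grid scan of the degree × penalty × B
landscape confirms this budget finds the CV optimum on the fixture.

## Study protocol

For each output (density, solubility) and family (PR, KNN, GR): tune with
the bat algorithm, refit the bagged model on the training data, report R²,
RMSE, AARD% and max error. The source study never states its train/test
split; Table-style metrics here are computed by default on all 32 records
after fitting on all 32 (its CV means nearly equal its full-fit metrics,
which is consistent with full-data evaluation), and `holdout_fraction`
switches to a shuffled train/test split for a stricter protocol. Under
the default protocol all three bagged families reach R² ≈ 0.98–0.99 on
the fixture, so family rankings are much closer than the published
comparison suggests — a direct consequence of evaluating on the training
records, flagged here rather than hidden.

Cross-validation of a selected configuration refits it per fold (no
nested re-tuning, matching a "CV of the selected model" reading) on a
seeded shuffle into near-equal folds, merging any fold with fewer than 2
points into its predecessor, and reports mean ± sample SD per metric.
Per-fold R² on ~6 held-out points is intrinsically harsh and
seed-sensitive; CV means here are therefore systematically below
full-data R².

Feature importance is permutation importance: the mean RMSE increase over
seeded shuffles of one feature column, floored at zero and normalized to
shares summing to 1. Effect curves fix the other input at the dataset
median by default and flag (not forbid) extrapolation beyond the training
range; the response surface evaluates the cartesian grid in long format.
Master seed 20260313 by default; all stochastic stages derive child seeds
from it deterministically.

## Synthetic data generator

`generate` emulates the statistical shape of the experimental campaign: a
full T × P grid (default 4 × 8 over 313–345 K / 95–250 bar), a polynomial
density surface in the standardized features (default signs: decreasing in
T, increasing in P, mildly saturating in P — mimicking solvent expansion
and compression), and a log-linear solubility surface increasing in both
inputs. Density noise is multiplicative Gaussian (SD = dispersion × mean,
floored to keep values positive) or gamma; solubility noise is always
gamma multiplicative with mean 1 and variance equal to the dispersion,
matching the gamma learner's assumption. Default dispersion 0.02 (≈2%
relative noise, the reproducibility one expects of densitometry; solubility
measurements are noisier but share the default for simplicity). The
generator returns the noiseless surfaces alongside the dataset so recovery
tests can score against ground truth.

What it does not emulate: equation-of-state physics (no critical-region
density cliff like the real 318 K / 95 bar corner), correlated measurement
error across a pressure series, and non-monotone solubility behaviour near
the crossover pressure (the real data decrease with T at 95 bar). Passing
synthetic-recovery tests therefore shows the pipeline recovers smooth
monotone surfaces under multiplicative noise — not that it captures
critical-region curvature.

## Numerical choices and limitations

* Ridge penalties apply to standardized-feature expansions with the
  intercept unpenalized; penalty 0 is honored exactly (OLS or error).
* IRLS tolerances: relative deviance change < 1e-10, cap 100; linear
  predictors are clipped at ±500 before exponentiation to avoid overflow
  during early iterations.
* KNN ties and all sorts use stable order; every random draw flows from an
  explicit seed; repeated runs are bitwise identical.
* Problem sizes in tests and the acceptance script (32-record fixture,
  36–64-point synthetic grids, 160-evaluation tuning budgets) are chosen
  so a full study runs in minutes on one core.
* With 32 grid points, bagged polynomial fits above degree 3 are unstable
  on held-out folds (a bootstrap bag holds ~20 unique points against 15+
  terms), so leakage-free CV tuning selects degree 2–3 surfaces. Models
  selected this way generalize better but fit the training records less
  tightly than a higher-degree surface evaluated in-sample would.
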