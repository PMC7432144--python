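# Methods

## Problem setting

Hazel (*Corylus avellana*) cell suspension cultures produce paclitaxel, and
fungal elicitors — cell extract (CE) and culture filtrate (CF) of an
endophytic fungus — strongly modulate both biomass and product formation.
The modelling task is a classic small-factorial bioprocess problem: four
inputs (CE dose, CF dose in % v/v, elicitor adding day, harvest day) and
five responses (dry weight, intracellular, extracellular and total
paclitaxel, extracellular portion), a few hundred observations, smooth but
non-linear dose–response behaviour. Two model families are fitted and
compared: first-order multiple linear regression with backward elimination,
and a single-hidden-layer perceptron whose architecture and optimal inputs
are found by a genetic algorithm (MLP-GA).

## Synthetic experiment generator

No raw measurements are available, so `datagen` emulates the experimental
design with a parametric ground-truth family. The design is a randomized
complete block factorial: 10 blend levels (CE:CF 100:0, 75:25, 50:50,
25:75, 0:100 plus the same five water:PDB sham ratios), total doses 2.5, 5
and 10 % v/v, elicitor addition on culture day 13 or 17, harvests every 2
days after elicitation up to day 23, three replicates — 720 rows. Sham
(water:PDB) blends are encoded as `ce_conc = cf_conc = 0` whatever their
nominal volume, because they deliver no microbe-associated molecular
patterns; harvest time is an absolute culture day, not days
post-elicitation.

Each simulated base response (dry weight, intracellular, extracellular) is

    baseline · (1 + a_ce·g(ce) + a_cf·g(cf) + a_int·g(ce)·g(cf))
             · (1 + s·(adding_day − 13)) · (1 − exp(−r·(clock − onset)))

with g a Gaussian dose bump re-anchored so g(0) = 0 (controls sit exactly
on the baseline kinetics) and `clock` either the absolute culture day
(biomass, saturating growth) or time since elicitation (product
accumulation). Defaults place the joint CE/CF optimum in the interior of
the dose region (so input optimization is non-trivial) and give magnitudes
a hazel-culture scientist would recognise: biomass ~8–12 g l⁻¹ dominated by
harvest time with only a mild elicitor effect, intracellular paclitaxel
rising from ~2 to ~16–18 µg g⁻¹ DW under strong CE/CF humps with synergy,
secretion CF-heavier and favoured by late addition. Total yield and the
secreted portion are derived *before* noise from the accounting identities
`total = intra·dw + extra` and `portion = 100·extra/total`; the five
reported responses then receive independent additive Gaussian measurement
noise and are clipped at zero. The default noise sd per response is 10 % of
the standard deviation of its noiseless values over the design — a
three-replicate bench experiment with good HPLC quantification plausibly
sits in that range. An optional replicate (block) offset is available and
defaults to zero.

What the generator does **not** emulate: replicate-specific trends,
heteroscedastic noise (real relative errors grow near the detection limit),
measurement error in the inputs, or any kinetic/mechanistic growth model.
Passing tests therefore demonstrate that the estimation and optimization
machinery recovers known smooth truth under honest noise — not that the
fitted surfaces describe any particular laboratory system.

`true_optimum` locates the noiseless-surface argmax by dense grid search
(default step 0.25 in every input, harvest > adding enforced) and is used
purely as an oracle for validating the stochastic optimizer.

## Train/test protocol and metrics

Observations are split 70/30 uniformly at random by row (train size is
round-half-up of 0.7·n; one shared split for all five responses). Accuracy
is summarised by R² = 1 − SS_res/SS_tot (the strict definition — possibly
negative off-training, not squared correlation), RMSE, and
MAPE = (1/n) Σ |(y_act − y_est)/y_act| × 100. The standalone MAPE raises on
zero actual values; the composite evaluator excludes zero-actual rows
(clipped noisy observations) from the MAPE average only.

## Regression

Ordinary least squares with intercept on the four raw inputs, no
interaction or polynomial terms; standard errors from the unbiased residual
variance, two-sided p-values on n − k degrees of freedom (statsmodels
supplies the fit). Backward elimination removes one term per iteration —
the non-intercept term with the largest p-value above α = 0.05 — and
refits; the intercept is never removed. Term importance is ranked by |t|,
ties keeping original column order.

## Perceptron

One tansig hidden layer, linear output, one single-output network per
response. Inputs and target are min–max scaled to [−1, 1] on the training
ranges; the scaler is stored inside the model so a saved estimator is
self-contained. Training is deterministic full-batch gradient descent on
the scaled mean-squared error with momentum 0.9 and an adaptive learning
rate (step rejected and rate ×0.7 when the error ratio exceeds 1.04,
otherwise accepted and rate ×1.05 — the classic accept/reject variant of
momentum back-propagation), weights initialized uniformly in [−0.5, 0.5]
from the seed, early stopping on a 15 % internal validation slice with
patience 400 epochs (cap 4000), returning the best-validation weights.
Analytic gradients are verified against central finite differences in the
test suite. Predictions for inputs more than 10 % of the training range
outside it emit an extrapolation warning but are not refused.

## Genetic algorithm

Real-coded chromosomes; roulette-wheel (fitness-proportional) selection on
shifted fitness; blend crossover with probability 0.85; per-gene Gaussian
mutation (probability 0.01, sd = 10 % of the gene range) clipped to the
bounds; elitism 1; population 50; 500 generations. Inequality constraints
enter as an additive penalty (coefficient 10³) proportional to the
violation. Two numerical choices matter in practice and are deliberate:

- the roulette shift point is the minimum over *feasible* individuals, with
  fitness below it clipped to a vanishing share — shifting by the global
  minimum lets one heavily-penalized outlier flatten selection pressure to
  near-uniform;
- crossover uses the extended blend range α ∈ [−0.25, 1.25], because pure
  convex averaging contracts the population toward its centroid and, at
  mutation rate 0.01, the search then commits to whichever local basin it
  first samples.

**Architecture search.** The hidden-neuron count (default range 2–10) is a
single rounded-real gene; candidate fitness is the negative RMSE on an
inner 15 % validation slice of the *training* subset (the test subset never
informs the choice), with a fixed training seed per candidate and cached
evaluations, so each count is trained at most once. The winner is retrained
on the full training subset.

**Input optimization.** The surrogate's prediction is maximized over the
box of observed input ranges subject to harvest ≥ adding day, harvest ≤
final culture day and — when the caller supplies it, as the pipeline does —
combined dose ce + cf ≤ the largest total dose actually applied. The dose
cap exists because the factorial design never samples the high-CE +
high-CF corner of the box (doses are blend-fraction × total concentration,
so ce + cf ≤ 10 % in the data) and surrogates routinely hallucinate maxima
in that unobserved corner. The GA is restarted five times from derived
seeds and the best run kept, since a low-mutation GA can converge into a
local basin the surrogate itself disprefers. Per-run elitist best-fitness
traces are monotone non-decreasing and recorded for plotting.

## Sensitivity analysis

For each input, VSE = model RMSE with that input "unavailable", implemented
as mean-substitution of the column over the evaluation rows (deterministic;
column permutation is provided as an alternative perturbation and used as a
cross-check oracle in the tests). VSR = VSE / base RMSE, computed on all
data lines (training and testing together). Rescaling to [0, 1] uses
(VSR − 1)⁺ normalized by its maximum, anchoring "no effect" at 0 and the
most influential input at 1; any strictly monotone rescaling preserves the
ranking, which is all downstream use depends on. Ties rank in input order;
a zero base RMSE is rejected as degenerate.

## Reporting arithmetic

Optimal conditions are stated as total dose (ce + cf, 2 dp), an integer
blend label (CE share = round-half-up of its percentage, CF share the
complement, so labels always sum to 100; zero dose → "control"), and the
elapsed time 24·(harvest − adding) hours rendered as "H h and M min" with
minutes rounded. Published worked examples of this arithmetic are used as
fixed test vectors; one published sentence is internally inconsistent (a
total dose printed as 11.13 % against components summing to 11.04 %) and is
excluded from the tests.

## Estimator files

A fitted surrogate exports to a versioned JSON schema (weights, scalers,
activation tags, training metadata) that reloads to bit-identical
predictions, plus a flat closed-form formula in the raw input variables
(only `tanh` appears) for spreadsheet users; the formula is checked against
the network forward pass with an independent symbolic evaluator.

## Problem sizes and determinism

The default study is the full 720-row design; test-suite simulations use
that size for end-to-end checks (20 seeds for optimizer-recovery and
sensitivity-recovery rates) and smaller constructed datasets (n = 80–400)
for unit-level properties. Every stochastic stage draws from a seed derived
from a single master seed via `numpy.random.SeedSequence`, so any report is
regenerable from its echoed configuration.

## Known limitations

- The adding-day effect is identified from only two design levels partially
  confounded with the post-elicitation harvest window; surrogates can place
  its optimum a fraction of a day off, and occasionally in the wrong half
  of the interval.
- Backward elimination inherits the usual caveats of stepwise selection
  (post-selection p-values are optimistic); it is reproduced here as the
  comparison baseline, not recommended practice.
- MAPE is scale-sensitive and undefined at zero observations; comparisons
  across responses with different zero-proximity are not meaningful.
- The GA is a global heuristic: with restarts it reliably solves this
  4-dimensional smooth problem, but no convergence guarantee exists.
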