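# Methods

## The model

`tamres` models the acquisition of tamoxifen (TAM) resistance in an initially
drug-sensitive breast cancer cell population as deterministic dynamics of four
subpopulations: sensitive cells (S), pre-resistant cells (P), and two resistant
states — one with rewired metabolism (R1) and one with an adhesive,
epigenetically altered phenotype (R2). The state vector is the four cell counts
plus the cumulative drug exposure U (µM·week), the time integral of the dose.

Twelve reactions drive the dynamics (`tamres.model`): exponential growth of
each state (v1, v5, v9, v12), TAM-induced death of S and P (v2, v6; gated by an
indicator on the current dose), forward transitions S→P (v3), P→R1 (v7) and
P→R2 (v10), and mass-action reverse transitions P→S (v4), R1→P (v8) and R2→P
(v11). Each forward transition is rate-limited by a Hill sigmoid of cumulative
exposure,

    h(U; n, K) = U^n / (K^n + U^n),

encoding the assumption that state transitions require an accumulated history
of drug-induced (epi)genetic change: the rate is negligible until U approaches
the half-effect K and saturates beyond it, with steepness n. The model has
exactly 19 free parameters — four growth rates, two death rates, three forward
rate constants with their three steepnesses and three half-effects, three
reverse rates, and the initial pre-resistant fraction f_P0. Resistant states
neither die from TAM nor transition onward; this keeps the parameter count at
19 and matches the transition graph the model encodes.

Assumptions worth stating plainly: growth is density-independent (the weekly
passaging keeps cultures sub-confluent); transitions are first-order in the
source population; the dose is constant within a condition (1 µM under TAM, 0
in control), so U(t) = dose·t exactly; and all cell-to-cell variability is
expressed through the ensemble of fitted parameter sets rather than stochastic
dynamics.

## Simulation and observables

The wet protocol reseeds 1 × 10⁶ cells weekly; the observable is the weekly
fold change F(t) = X_total(t⁻)/X_total((t−1)⁺). Because the system is linear
in cell counts, F(t) and the subpopulation fractions are invariant to the
dilution, which is kept on by default purely for numerical bounding; U is a
property of the culture's history and is never rescaled. The reference
integrator is LSODA with relative tolerance 1e−10 and absolute tolerance 1e−12
on counts normalized by the seeding size (the contract requires ≤1e−8; the
tighter default makes the closed-form exponential test pass at 1e−8 with
margin).

The summary statistic for sensitivity and intervention analyses is the
mean-over-time growth rate q: the arithmetic mean of F(4)…F(10), i.e. average
weekly growth after week 3, when resistant regrowth dominates. q ≤ 1 means the
treated population regresses on average.

A second integrator (`tamres._fast`) serves the optimizer's inner loop: since
U(t) is known in closed form, the cell subsystem is linear time-varying and a
fixed-step RK4 update is multiplication by a state-independent propagator
matrix. All step propagators for all candidate parameter sets are built
vectorized and combined by pairwise reduction, so a differential-evolution
population is simulated in a few milliseconds. At the default 40 steps/week it
matches the reference solver to ~1e−8 relative (tested at 1e−6); the global
search phase uses 12 steps/week, and every reported wSSPE is recomputed with
the reference solver.

## Fitting

The data are 38 scalars: weekly fold changes for weeks 1–11 under TAM and
control, plus the four-way composition at weeks 0, 3, 6 and 9 of the TAM arm.
The objective is the weighted sum of squared percentage errors

    wSSPE = Σ_i ((x_sim,i − x_exp,i) / (x_exp,i + 0.1))²,

whose +0.1 offset guards the zero-valued proportion entries and balances the
growth and proportion blocks; no extra block weighting is applied. Control
growth does not constrain TAM-specific parameters and each composition vector
has three degrees of freedom, so the 38 points effectively constrain the model
through 23 (`effective_constraint_count`). All 16 proportion entries still
enter the objective.

Estimation is multistart: n_starts (default 20) independent
differential-evolution runs, each from its own seed, over bounded parameters —
rates 1e−4–10 /week, steepnesses 0.5–10, half-effects 0.1–20 µM·week, f_P0
0–0.5 — searched in log10 space except f_P0. Each run is refined by a bounded
trust-region (TRF) least-squares polish on the residual vector, with the
Jacobian computed by a batched forward-difference sweep; the polish is accepted
only if it improves the loss. All starts are returned sorted by wSSPE, none
filtered, and the ensemble spread stands in for extrinsic cell-to-cell
variability. The default budget (80 DE generations, population 7×19, polish
cap 120 evaluations) fits one start in ~5 s; results are bitwise reproducible
from the seeds.

Fitted parameter distributions are compared with the paired Wilcoxon
signed-rank test (exact two-sided p for ≤25 non-zero differences; p = 1 by
convention when all differences are zero), validated in the tests against
brute-force enumeration of all 2^n sign assignments.

## Sensitivity analysis

For each reaction the flux is multiplied by (1+δ) throughout the TAM-arm
simulation — the perturbation acts on the flux as a whole, implemented via a
per-reaction scale vector in the right-hand side — and the coefficient is the
normalized log-derivative s_i = (ln q′ − ln q)/ln(1+δ) with δ = 0.01. The
log-normalized discretization (rather than the raw percent change) makes the
single-population closed form exact: with only one growth reaction g active,
q = e^g and s = g·δ/ln(1+δ). Reactions with a zero rate constant have exactly
zero sensitivity (the shortcut is explicit, so no finite-difference noise
appears). δ-robustness (0.01 vs 0.001 within 2%) is tested. Ensemble
summaries report per-reaction mean and SD (ddof = 1) across fits; undefined
coefficients propagate as NaN, not failures.

## Combination inhibition

Inhibitable processes are the growth of each resistant state (g_R1, g_R2) and
the forward transition into each (k_PR1, k_PR2). A "remaining reaction rate"
factor in [0, 1] multiplies the targeted rate constant — rate inhibition, with
the sigmoid shape untouched. For a pair of targets and an 11 × 11 factor grid
(1.0, 0.9, …, 0.0 per axis, configurable), every ensemble member is simulated
under TAM only (q is defined for treated cells) and mean and SD of q are
recorded per cell; the grid is evaluated with the vectorized propagator
integrator and cross-checked against the reference solver in the tests. The
regression boundary reports, per x-factor, the largest y-factor whose
ensemble-mean q ≤ 1. Under the default synthetic truth the
(growth_R1, growth_R2) pair does not reach q ≤ 1 even at full double
inhibition (mean q ≈ 1.03, because net pre-resistant growth remains slightly
positive), so its boundary is empty; an empty boundary is a valid outcome and
the contour machinery is exercised on scenarios with higher death rates.

## Synthetic data

The generator (`tamres.synthetic`) emulates the summarized experimental
inputs, not raw sequencing data. The documented synthetic truth is calibrated
so its noise-free simulation shows: control growth of 1.5–2.2-fold every week;
TAM growth near stasis (0.85–1.15) in weeks 2–5 recovering to ≥1.3 by week 9;
and a composition course from ≥90% sensitive at week 0, through a ≥60%
pre-resistant majority at weeks 3–6, to a resistant split at week 9 with both
R1 and R2 ≥ 20% and R2 dominant — with g_R2 > g_R1 and n_PR2 > n_PR1 built
in as the two headline orderings any recovery experiment should reproduce.

Noise: fold changes receive i.i.d. multiplicative lognormal noise with
coefficient of variation 0.05 (growth is a ratio, so noise is multiplicative;
the level is of the order of the replicate scatter such assays show);
compositions are resampled from a Dirichlet centered on the simulated
fractions with concentration 200 (≈ ±0.03 per fraction), the simplest noise
model respecting the simplex. Zero and cv→0 / concentration→∞ reproduce the
noise-free model output exactly, sharing the reference simulation code path.

What the generator does not emulate: batch effects, week-to-week correlated
noise, measurement error on the week labels, compositional bias from the
single-cell assignment step, or any feedback of density on growth. Passing
recovery tests therefore demonstrate identifiability and correctness of the
estimation machinery under the stated noise model, not robustness to real
experimental artifacts.

## Problem sizes and numerical choices

Default analysis sizes: 11-week horizons, ensembles of 20 fits, 11 × 11
intervention grids. The test suite runs the noise-free recovery at the full 20
starts and the noisy-ordering experiment as 10 repetitions × best-of-4 starts;
these sizes were chosen as the smallest that make the ordering statistics
stable. Ties in the signed-rank test fall back to scipy's exact-with-ties
handling; factor grids must be sorted descending so contour extraction can
scan columns monotonically; trajectories with non-positive total counts raise
an integration error naming the failing weekly interval.

## Known limitations

Local (one-at-a-time) sensitivity only — no Sobol/Morris global analysis; no
stochastic birth–death version, spatial structure, or cell-cycle phases; no
pharmacokinetics of actual inhibitors (inhibition is an idealized rate
scaling); constant dose per condition (no schedules); the 19-parameter model
is only weakly identified by 23 effective constraints, so individual parameter
values beyond the tested orderings should be interpreted through the ensemble
spread, not point estimates.
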