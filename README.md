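# tamres

Population-dynamics analysis of how an estrogen-receptor-positive breast
cancer cell population acquires resistance to tamoxifen (TAM) under
continuous 1 µM exposure.

Long-term TAM treatment of an initially sensitive culture produces a
characteristic course: growth stalls for several weeks, then recovers as
resistant cells take over. Single-cell profiling of such cultures resolves
the population into a sensitive state (S), a pre-resistant intermediate (P),
and two distinct resistant states — one metabolically rewired (R1), one
adhesive and epigenetically altered (R2). `tamres` is for modelers who want
to quantify that process: which transitions drive it, which rates the data
actually pin down, and which combination of interventions would stop the
regrowth.

## The model

Cell counts X_S, X_P, X_R1, X_R2 evolve by twelve reactions: exponential
growth of each state, TAM-induced death of S and P, forward transitions
S→P→{R1, R2}, and weak reverse transitions. Forward transition rates are
gated by a Hill sigmoid of the cumulative exposure U(t) = ∫dose dt:

    dX_S/dt = g_S·X_S − d_S·X_S − k_SP·h(U; n_SP, K_SP)·X_S + k_PS·X_P,
    h(U; n, K) = U^n / (K^n + U^n),

and analogously for the other states (19 free parameters in all). The
observables are the weekly fold change F(t) — total cells at the end of a
week over the 10⁶ reseeded at its start — and the subpopulation fractions.

Fitting minimizes the weighted sum of squared percentage errors over 38
observations (11 TAM + 11 control weekly fold changes, four composition
snapshots),

    wSSPE = Σ_i ((x_sim,i − x_exp,i)/(x_exp,i + 0.1))²,

by multistart differential evolution with a least-squares polish, producing
an ensemble of fitted parameter sets. Downstream analyses act on the
ensemble: local sensitivity of the mean post-week-3 growth rate
q = mean(F(4)…F(10)) to each reaction flux (s_i = ∂ln q/∂ln v_i, discretized
with a 1% flux increase), and in-silico combination inhibition of
resistant-state growth and transition over a grid of remaining-rate factors,
with the q ≤ 1 contour marking regression. See `docs/methods.md` for the
full account.

A synthetic-data module generates growth/composition datasets from a
documented synthetic truth with multiplicative lognormal noise on fold
changes and Dirichlet noise on compositions, so the entire pipeline is
testable without any download.

## Worked example

```python
from tamres import (NoiseConfig, FitConfig, assemble_observations,
                    fit_multistart, generate_dataset,
                    sensitivity_report, intervention_grid)

data = generate_dataset(noise=NoiseConfig(seed=1))          # synthetic experiment
obs = assemble_observations(data)                           # 38 labeled scalars
fits = fit_multistart(obs, FitConfig(n_starts=6, seed_base=42))
best = fits[0]
print(f"best wSSPE over {len(obs)} observations: {best.wsspe:.4f}")
print(f"g_R1 = {best.params.g_R1:.3f}, g_R2 = {best.params.g_R2:.3f}")

report = sensitivity_report(fits)
top = report.summary_frame().sort_values("mean", ascending=False).head(3)
print(top.to_string(index=False))

grid = intervention_grid(fits, "growth_R1", "growth_R2")
print(f"mean q uninhibited: {grid.mean_q[0, 0]:.3f}; "
      f"fully inhibited: {grid.mean_q[-1, -1]:.3f}")
```

prints

```
best wSSPE over 38 observations: 0.0109
g_R1 = 0.408, g_R2 = 0.627
reaction     mean       sd
     v12 0.272141 0.000637
      v5 0.258869 0.005275
      v9 0.082664 0.000357
mean q uninhibited: 1.331; fully inhibited: 1.004
```

Reading this: the best of six fits reproduces the noisy synthetic data to
about 1–2% per point (wSSPE 0.011 over 38 points); the fitted R2 growth rate
exceeds R1's, as in the generating truth. The most sensitive reaction is v12
(growth of R2, coefficient ≈ 0.27: a 1% increase in that flux raises the
mean growth rate by ≈ 0.27%), ahead of pre-resistant growth (v5) and R1
growth (v9). Fully inhibiting both resistant states' growth drops the
ensemble-mean q from 1.33 to 1.00 — to the edge of regression, since the
pre-resistant compartment still grows slightly.

The same stages are available from the shell:

```
tamres generate --seed 1 --out-growth growth.csv --out-props props.csv
tamres fit --growth growth.csv --proportions props.csv --out fits.json --seed-base 42
tamres sensitivity --fits fits.json --out sens.csv
tamres intervene --fits fits.json --pair growth_R1,growth_R2 --out grid.csv
tamres run --config run.yaml --out results/   # full pipeline from YAML
```

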