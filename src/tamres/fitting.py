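"""Parameter estimation against growth-rate and composition time courses.

The fitting data are two weekly growth-rate series (TAM-treated and untreated
control, weeks 1–11) and the four subpopulation proportions at weeks 0, 3, 6
and 9 of the TAM arm — 38 scalar observations in all.  The objective is the
weighted sum of squared percentage errors

    wSSPE = Σ_i ((x_sim,i − x_exp,i) / (x_exp,i + 0.1))²,

whose +0.1 denominator both guards against division by zero (proportions can
be 0) and balances the growth and proportion blocks, which live on different
scales.  Control growth does not constrain the TAM-specific parameters and
each proportion vector has 3 degrees of freedom, so the 38 points practically
constrain the model through 23 of them.

Estimation is multistart global optimization: ``n_starts`` independent
differential-evolution runs (rates searched in log space within broad
biologically plausible weekly-kinetics bounds), each refined by a bounded
trust-region least-squares polish, yielding an ensemble of fitted parameter
sets whose spread stands in for cell-to-cell (extrinsic) variability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from ._fast import DEFAULT_STEPS_PER_WEEK, predict_flat_batch
from .errors import (
    AlignmentError,
    InsufficientSampleError,
    InvalidParameterError,
    SchemaError,
)
from .model import PARAM_NAMES, ModelParameters
from .simulate import Condition, integrate

__all__ = [
    "SUBPOPULATIONS",
    "DEFAULT_PROPORTION_WEEKS",
    "DEFAULT_BOUNDS",
    "ExperimentDataset",
    "ObservationSet",
    "FitConfig",
    "FitResult",
    "PairedComparison",
    "assemble_observations",
    "effective_constraint_count",
    "predict_observations",
    "wsspe",
    "fit_multistart",
    "compare_parameter_distributions",
]

SUBPOPULATIONS = ("S", "P", "R1", "R2")
DEFAULT_PROPORTION_WEEKS = (0, 3, 6, 9)

#: wSSPE weighting offset (guards x_exp = 0 and balances the two data blocks)
WSSPE_OFFSET = 0.1

#: search bounds in natural units, bracketing plausible weekly kinetics
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    **{name: (1e-4, 10.0) for name in (
        "g_S", "g_P", "g_R1", "g_R2", "d_S", "d_P",
        "k_SP", "k_PR1", "k_PR2", "k_PS", "k_R1P", "k_R2P",
    )},
    **{name: (0.5, 10.0) for name in ("n_SP", "n_PR1", "n_PR2")},
    **{name: (0.1, 20.0) for name in ("K_SP", "K_PR1", "K_PR2")},
    "f_P0": (0.0, 0.5),
}

# f_P0 is searched on its natural (linear) scale; everything else in log10
_LOG_PARAMS = tuple(name for name in PARAM_NAMES if name != "f_P0")


# ---------------------------------------------------------------------------
# data containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExperimentDataset:
    """The fitting data: two growth-rate series plus composition snapshots.

    ``growth_tam``/``growth_ctrl`` are weekly fold changes for weeks
    ``1..len``; ``proportions[j]`` is the subpopulation fraction vector
    (S, P, R1, R2) at week ``proportion_weeks[j]`` of the TAM arm.
    """

    growth_tam: np.ndarray
    growth_ctrl: np.ndarray
    proportions: np.ndarray
    proportion_weeks: tuple[int, ...] = DEFAULT_PROPORTION_WEEKS

    def __post_init__(self) -> None:
        object.__setattr__(self, "growth_tam", np.asarray(self.growth_tam, dtype=float))
        object.__setattr__(self, "growth_ctrl", np.asarray(self.growth_ctrl, dtype=float))
        object.__setattr__(self, "proportions", np.asarray(self.proportions, dtype=float))
        for name in ("growth_tam", "growth_ctrl"):
            g = getattr(self, name)
            if g.ndim != 1 or g.size == 0:
                raise SchemaError(f"{name} must be a non-empty 1-D series")
            if not np.all(np.isfinite(g)) or np.any(g <= 0):
                raise SchemaError(f"{name} must contain finite values > 0")
        if len(self.growth_tam) != len(self.growth_ctrl):
            raise SchemaError(
                "growth_tam and growth_ctrl must cover the same weeks "
                f"({len(self.growth_tam)} vs {len(self.growth_ctrl)})"
            )
        P = self.proportions
        if P.ndim != 2 or P.shape != (len(self.proportion_weeks), len(SUBPOPULATIONS)):
            raise SchemaError(
                "proportions must have shape (n_weeks, 4) matching proportion_weeks, "
                f"got {P.shape}"
            )
        if np.any(P < 0) or np.any(P > 1):
            raise SchemaError("proportions entries must lie in [0, 1]")
        sums = P.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-6):
            bad = self.proportion_weeks[int(np.argmax(np.abs(sums - 1.0)))]
            raise SchemaError(f"proportions at week {bad} do not sum to 1")

    @property
    def n_weeks(self) -> int:
        return len(self.growth_tam)


@dataclass(frozen=True)
class ObservationSet:
    """Labeled scalar observations in a fixed canonical order.

    Each entry carries (kind, condition, week, subpopulation) metadata; the
    same container shape is used for experimental values and for simulated
    counterparts so the objective can align them label by label.
    """

    kinds: tuple[str, ...]
    conditions: tuple[str, ...]
    weeks: tuple[int, ...]
    subpopulations: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        n = len(self.values)
        if not (len(self.kinds) == len(self.conditions) == len(self.weeks)
                == len(self.subpopulations) == n):
            raise SchemaError("observation metadata and values must have equal length")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def labels(self) -> tuple[tuple[str, str, int, str], ...]:
        return tuple(zip(self.kinds, self.conditions, self.weeks, self.subpopulations))

    def with_values(self, values: np.ndarray) -> "ObservationSet":
        values = np.asarray(values, dtype=float)
        if values.shape != self.values.shape:
            raise SchemaError(f"expected {len(self)} values, got shape {values.shape}")
        return ObservationSet(self.kinds, self.conditions, self.weeks,
                              self.subpopulations, values)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "kind": self.kinds,
                "condition": self.conditions,
                "week": self.weeks,
                "subpopulation": self.subpopulations,
                "value": self.values,
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ObservationSet":
        required = {"kind", "condition", "week", "subpopulation", "value"}
        missing = required - set(frame.columns)
        if missing:
            raise SchemaError(f"observation table missing columns: {sorted(missing)}")
        sub = frame["subpopulation"].fillna("").astype(str)
        return cls(
            kinds=tuple(frame["kind"].astype(str)),
            conditions=tuple(frame["condition"].astype(str)),
            weeks=tuple(int(w) for w in frame["week"]),
            subpopulations=tuple(sub),
            values=frame["value"].to_numpy(dtype=float),
        )


@dataclass(frozen=True)
class FitConfig:
    """Budget and bounds of one multistart estimation campaign."""

    n_starts: int = 20
    seed_base: int = 1000
    bounds: dict[str, tuple[float, float]] = field(default_factory=lambda: dict(DEFAULT_BOUNDS))
    de_maxiter: int = 80
    de_popsize: int = 7          # scipy convention: population = popsize × 19
    polish: bool = True
    polish_max_nfev: int = 120   # least-squares iterations (jacobians counted once)
    steps_per_week: int = DEFAULT_STEPS_PER_WEEK
    de_steps_per_week: int = 12  # coarser grid for the global-search phase

    def __post_init__(self) -> None:
        if self.n_starts < 1:
            raise InvalidParameterError("n_starts must be >= 1")
        missing = set(PARAM_NAMES) - set(self.bounds)
        if missing:
            raise SchemaError(f"bounds missing for parameters: {sorted(missing)}")

    def seed_for_start(self, i: int) -> int:
        return int((self.seed_base + i) % (2**31 - 1))


@dataclass(frozen=True)
class FitResult:
    """One fitted parameter set with its loss and optimizer provenance."""

    params: ModelParameters
    wsspe: float
    seed: int
    n_iterations: int
    n_evaluations: int
    converged: bool

    def __post_init__(self) -> None:
        if self.wsspe < 0:
            raise InvalidParameterError(f"wSSPE must be >= 0, got {self.wsspe!r}")

    def to_dict(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "wsspe": float(self.wsspe),
            "seed": int(self.seed),
            "n_iterations": int(self.n_iterations),
            "n_evaluations": int(self.n_evaluations),
            "converged": bool(self.converged),
        }

    @classmethod
    def from_dict(cls, data: dict) -> "FitResult":
        return cls(
            params=ModelParameters.from_dict(data["params"]),
            wsspe=float(data["wsspe"]),
            seed=int(data["seed"]),
            n_iterations=int(data["n_iterations"]),
            n_evaluations=int(data["n_evaluations"]),
            converged=bool(data["converged"]),
        )


@dataclass(frozen=True)
class PairedComparison:
    """Wilcoxon signed-rank summary of two paired parameter (or q) vectors."""

    statistic: float
    p_value: float
    median_difference: float
    n: int


# ---------------------------------------------------------------------------
# observation assembly and the objective
# ---------------------------------------------------------------------------

def assemble_observations(data: ExperimentDataset) -> ObservationSet:
    """Flatten a dataset to labeled scalars in the canonical order.

    Ordering: TAM growth by week, control growth by week, then proportions by
    week and subpopulation (S, P, R1, R2).  The standard design (11 + 11
    growth points and four proportion snapshots) yields 38 entries.
    """
    kinds: list[str] = []
    conditions: list[str] = []
    weeks: list[int] = []
    subpops: list[str] = []
    values: list[float] = []

    for cond, series in (("tam", data.growth_tam), ("ctrl", data.growth_ctrl)):
        for week, value in enumerate(series, start=1):
            kinds.append("growth")
            conditions.append(cond)
            weeks.append(week)
            subpops.append("")
            values.append(float(value))
    for j, week in enumerate(data.proportion_weeks):
        for k, sub in enumerate(SUBPOPULATIONS):
            kinds.append("proportion")
            conditions.append("tam")
            weeks.append(int(week))
            subpops.append(sub)
            values.append(float(data.proportions[j, k]))

    return ObservationSet(tuple(kinds), tuple(conditions), tuple(weeks),
                          tuple(subpops), np.array(values))


def effective_constraint_count(obs: ObservationSet) -> int:
    """Number of data points that practically constrain the model.

    Control growth does not constrain TAM-specific parameters and each
    proportion vector has one redundant entry, so the count is
    (# TAM growth points) + (# subpopulations − 1) × (# proportion weeks).
    """
    kinds = np.asarray(obs.kinds)
    conds = np.asarray(obs.conditions)
    n_tam_growth = int(np.sum((kinds == "growth") & (conds == "tam")))
    prop_mask = kinds == "proportion"
    if not prop_mask.any():
        return n_tam_growth
    prop_weeks = {w for w, m in zip(obs.weeks, prop_mask) if m}
    n_subpops = len({s for s, m in zip(obs.subpopulations, prop_mask) if m})
    return n_tam_growth + (n_subpops - 1) * len(prop_weeks)


def _template_labels(
    n_weeks: int, proportion_weeks: tuple[int, ...]
) -> ObservationSet:
    dummy = ExperimentDataset(
        growth_tam=np.ones(n_weeks),
        growth_ctrl=np.ones(n_weeks),
        proportions=np.full((len(proportion_weeks), 4), 0.25),
        proportion_weeks=proportion_weeks,
    )
    return assemble_observations(dummy)


def predict_observations(
    params: ModelParameters,
    n_weeks: int = 11,
    proportion_weeks: tuple[int, ...] = DEFAULT_PROPORTION_WEEKS,
) -> ObservationSet:
    """Simulate both arms and extract the observations' simulated counterparts.

    Uses the reference adaptive integrator; labels and ordering match
    :func:`assemble_observations` exactly.
    """
    tam = integrate(params, Condition(tam_dose=1.0, n_weeks=n_weeks))
    ctrl = integrate(params, Condition(tam_dose=0.0, n_weeks=n_weeks))
    values = np.concatenate([
        tam.fold_change,
        ctrl.fold_change,
        np.concatenate([tam.fractions[w] for w in proportion_weeks]),
    ])
    return _template_labels(n_weeks, proportion_weeks).with_values(values)


def wsspe(sim: ObservationSet, exp: ObservationSet) -> float:
    """Weighted sum of squared percentage errors between aligned sets.

    Σ_i ((x_sim,i − x_exp,i) / (x_exp,i + 0.1))²; zero iff the sets agree
    elementwise.
    """
    if sim.labels != exp.labels:
        raise AlignmentError("simulated and experimental observation labels differ")
    r = (sim.values - exp.values) / (exp.values + WSSPE_OFFSET)
    return float(np.dot(r, r))


# ---------------------------------------------------------------------------
# multistart estimation
# ---------------------------------------------------------------------------

def _transform_bounds(bounds: dict[str, tuple[float, float]]) -> list[tuple[float, float]]:
    out = []
    for name in PARAM_NAMES:
        lo, hi = bounds[name]
        if name in _LOG_PARAMS:
            if lo <= 0:
                raise SchemaError(f"log-scale bound for {name} must be > 0")
            out.append((np.log10(lo), np.log10(hi)))
        else:
            out.append((float(lo), float(hi)))
    return out


def _to_natural(z: np.ndarray) -> np.ndarray:
    """Map search-space coordinates (S, 19) to natural parameter values."""
    theta = np.array(z, dtype=float, copy=True)
    for i, name in enumerate(PARAM_NAMES):
        if name in _LOG_PARAMS:
            theta[..., i] = 10.0 ** theta[..., i]
    return theta


def _make_residual_fn(exp_values: np.ndarray, n_weeks: int, steps_per_week: int):
    denom = exp_values + WSSPE_OFFSET

    def residuals(z2d: np.ndarray) -> np.ndarray:
        theta = _to_natural(np.atleast_2d(z2d))
        sim = predict_flat_batch(theta, n_weeks=n_weeks, steps_per_week=steps_per_week)
        return (sim - exp_values[None, :]) / denom[None, :]

    return residuals


def fit_multistart(obs: ObservationSet, config: FitConfig | None = None) -> list[FitResult]:
    """Run independent global-optimization starts and return all results.

    Each start is a differential-evolution run from its own seed over the
    bounded search space (log scale for rates and shapes), followed by a
    bounded trust-region least-squares polish on the wSSPE residual vector.
    Results are sorted by final wSSPE (recomputed with the reference
    integrator) and every start is returned — none are filtered by loss.
    Identical seeds and config reproduce identical results.
    """
    config = config or FitConfig()
    exp_values = obs.values
    n_growth = sum(1 for k, c in zip(obs.kinds, obs.conditions)
                   if k == "growth" and c == "tam")
    prop_weeks = tuple(sorted({w for k, w in zip(obs.kinds, obs.weeks)
                               if k == "proportion"}))
    if prop_weeks != DEFAULT_PROPORTION_WEEKS:
        raise SchemaError(
            f"fitting expects proportion snapshots at weeks {DEFAULT_PROPORTION_WEEKS}, "
            f"got {prop_weeks}"
        )
    n_weeks = n_growth
    residual_fn = _make_residual_fn(exp_values, n_weeks, config.steps_per_week)
    residual_fn_coarse = _make_residual_fn(exp_values, n_weeks, config.de_steps_per_week)

    def loss_batch(z: np.ndarray) -> np.ndarray:
        # scipy passes (N,) for scalar calls and (N, S) when vectorized
        z2d = z.T if z.ndim == 2 else z[None, :]
        r = residual_fn_coarse(z2d)
        out = np.einsum("ij,ij->i", r, r)
        return out if z.ndim == 2 else float(out[0])

    bounds_z = _transform_bounds(config.bounds)
    results: list[FitResult] = []

    for i in range(config.n_starts):
        seed = config.seed_for_start(i)
        de = optimize.differential_evolution(
            loss_batch,
            bounds=bounds_z,
            seed=seed,
            maxiter=config.de_maxiter,
            popsize=config.de_popsize,
            tol=0.0,
            polish=False,
            updating="deferred",
            vectorized=True,
            init="latinhypercube",
        )
        z_best = de.x
        n_evals = int(de.nfev)
        converged = bool(np.isfinite(de.fun))
        n_iter = int(de.nit)

        if config.polish:
            def res1(z: np.ndarray) -> np.ndarray:
                return residual_fn(z[None, :])[0]

            def jac(z: np.ndarray) -> np.ndarray:
                # one batched forward-difference sweep: 19 perturbed points at once
                step = 1e-6 * np.maximum(1.0, np.abs(z))
                Z = np.repeat(z[None, :], len(z), axis=0) + np.diag(step)
                r0 = residual_fn(z[None, :])[0]
                R = residual_fn(Z)
                return ((R - r0[None, :]) / step[:, None]).T

            lb = np.array([b[0] for b in bounds_z])
            ub = np.array([b[1] for b in bounds_z])
            ls = optimize.least_squares(
                res1,
                np.clip(z_best, lb, ub),
                jac=jac,
                bounds=(lb, ub),
                method="trf",
                max_nfev=config.polish_max_nfev,
            )
            r0 = res1(z_best)
            if np.isfinite(ls.cost) and 2.0 * ls.cost <= float(r0 @ r0):
                z_best = ls.x
            n_evals += int(ls.nfev)

        params = ModelParameters.from_array(_to_natural(z_best[None, :])[0])
        final = wsspe(predict_observations(params, n_weeks=n_weeks), obs)
        results.append(
            FitResult(
                params=params,
                wsspe=final,
                seed=seed,
                n_iterations=n_iter,
                n_evaluations=n_evals,
                converged=converged and np.isfinite(final),
            )
        )

    return sorted(results, key=lambda r: r.wsspe)


# ---------------------------------------------------------------------------
# ensemble statistics
# ---------------------------------------------------------------------------

def compare_parameter_distributions(
    fits: list[FitResult], param_a: str, param_b: str
) -> PairedComparison:
    """Paired Wilcoxon signed-rank comparison of two fitted parameters.

    Exact two-sided p-value for n ≤ 25 pairs (no zero differences); if every
    paired difference is zero, p = 1 by convention.
    """
    for name in (param_a, param_b):
        if name not in PARAM_NAMES:
            raise InvalidParameterError(f"unknown parameter name: {name!r}")
    if len(fits) < 6:
        raise InsufficientSampleError(
            f"paired comparison needs at least 6 fits, got {len(fits)}"
        )
    a = np.array([getattr(f.params, param_a) for f in fits])
    b = np.array([getattr(f.params, param_b) for f in fits])
    return compare_paired_values(a, b)


def compare_paired_values(a: np.ndarray, b: np.ndarray) -> PairedComparison:
    """Signed-rank comparison of two same-length paired value vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise SchemaError("paired vectors must be 1-D and of equal length")
    d = a - b
    median_diff = float(np.median(d))
    nonzero = d[d != 0]
    if nonzero.size == 0:
        return PairedComparison(0.0, 1.0, median_diff, len(d))
    method = "exact" if nonzero.size <= 25 else "approx"
    res = stats.wilcoxon(a, b, zero_method="wilcox", alternative="two-sided",
                         method=method)
    return PairedComparison(float(res.statistic), float(res.pvalue),
                            median_diff, len(d))
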