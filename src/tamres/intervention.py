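"""In-silico combination inhibition of resistant-state growth and transition.

The four inhibitable processes are the growth of each resistant state
(``growth_R1`` → g_R1, ``growth_R2`` → g_R2) and the forward transition into
each (``transition_R1`` → k_PR1, ``transition_R2`` → k_PR2).  An inhibition
is expressed as a *remaining reaction rate* factor in [0, 1] multiplying the
targeted rate constant: 1.0 means no inhibition, 0.0 complete inhibition.

For a pair of targets and a grid of factor combinations, every fitted
parameter set in the ensemble is simulated under TAM and the mean-over-time
growth rate q (weeks 4–10) is averaged across the ensemble per cell.  The
contour where mean q drops to ≤ 1 marks the combinations that drive the
treated population into regression.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._fast import simulate_batch
from .errors import InvalidParameterError, InvalidTargetError
from .fitting import FitResult, PairedComparison, compare_paired_values
from .model import ModelParameters

__all__ = [
    "INHIBITION_TARGETS",
    "apply_inhibition",
    "intervention_grid",
    "threshold_contour",
    "InterventionGrid",
]

#: inhibitable process -> the rate constant it scales (and its reaction flux)
INHIBITION_TARGETS: dict[str, str] = {
    "growth_R1": "g_R1",        # reaction v9
    "growth_R2": "g_R2",        # reaction v12
    "transition_R1": "k_PR1",   # reaction v7
    "transition_R2": "k_PR2",   # reaction v10
}

_Q_HORIZON = 10
_BATCH_ROWS = 512  # chunk size keeping the propagator arrays small

DEFAULT_FACTORS = tuple(np.round(np.linspace(1.0, 0.0, 11), 10))


def apply_inhibition(
    params: ModelParameters, target: str, factor: float
) -> ModelParameters:
    """Scale one inhibitable rate constant by the remaining-rate factor."""
    if target not in INHIBITION_TARGETS:
        raise InvalidTargetError(
            f"unknown inhibition target {target!r}; "
            f"expected one of {sorted(INHIBITION_TARGETS)}"
        )
    if not 0.0 <= factor <= 1.0:
        raise InvalidParameterError(f"factor must lie in [0, 1], got {factor!r}")
    name = INHIBITION_TARGETS[target]
    return params.replace(**{name: getattr(params, name) * factor})


def _q_batch(theta: np.ndarray) -> np.ndarray:
    """Mean-over-time growth rate q per parameter row, evaluated in chunks."""
    out = np.empty(theta.shape[0])
    for start in range(0, theta.shape[0], _BATCH_ROWS):
        chunk = theta[start : start + _BATCH_ROWS]
        folds, _ = simulate_batch(chunk, tam_dose=1.0, n_weeks=_Q_HORIZON)
        out[start : start + _BATCH_ROWS] = folds[:, 3:10].mean(axis=1)
    return out


@dataclass(frozen=True)
class InterventionGrid:
    """Ensemble-mean q over a 2-D grid of remaining-rate factors.

    ``mean_q[i, j]`` (and ``sd_q``, ``q_values[:, i, j]``) correspond to
    ``factors_x[i]`` on the first target and ``factors_y[j]`` on the second;
    factors run descending from 1.0 (untreated) to 0.0 (full inhibition).
    """

    target_x: str
    target_y: str
    factors_x: tuple[float, ...]
    factors_y: tuple[float, ...]
    q_values: np.ndarray = field(repr=False)  # (n_fits, nx, ny)
    uninhibited_mean_q: float = 0.0

    @property
    def mean_q(self) -> np.ndarray:
        return self.q_values.mean(axis=0)

    @property
    def sd_q(self) -> np.ndarray:
        if self.q_values.shape[0] < 2:
            return np.zeros_like(self.mean_q)
        return self.q_values.std(axis=0, ddof=1)

    def cell(self, factor_x: float, factor_y: float) -> np.ndarray:
        """Per-fit q vector of one grid cell (for rank-test comparisons)."""
        i = self.factors_x.index(factor_x)
        j = self.factors_y.index(factor_y)
        return self.q_values[:, i, j]

    def compare_cells(
        self, cell_a: tuple[float, float], cell_b: tuple[float, float]
    ) -> PairedComparison:
        """Paired signed-rank comparison of q between two named cells."""
        return compare_paired_values(self.cell(*cell_a), self.cell(*cell_b))

    def to_frame(self) -> pd.DataFrame:
        """Long format: one row per (factor_x, factor_y)."""
        fx, fy = np.meshgrid(self.factors_x, self.factors_y, indexing="ij")
        return pd.DataFrame(
            {
                "factor_x": fx.ravel(),
                "factor_y": fy.ravel(),
                "mean_q": self.mean_q.ravel(),
                "sd_q": self.sd_q.ravel(),
            }
        )


def _validate_factors(factors) -> tuple[float, ...]:
    factors = tuple(float(f) for f in factors)
    if not factors:
        raise InvalidParameterError("factors must be non-empty")
    if any(f < 0 or f > 1 for f in factors):
        raise InvalidParameterError("factors must lie in [0, 1]")
    if list(factors) != sorted(factors, reverse=True):
        raise InvalidParameterError("factors must be sorted descending from 1.0")
    return factors


def intervention_grid(
    fits: list[FitResult] | list[ModelParameters],
    target_x: str,
    target_y: str,
    factors=DEFAULT_FACTORS,
    factors_y=None,
) -> InterventionGrid:
    """Ensemble-mean q for every combination of two inhibitions.

    Simulates the TAM arm only — q is defined for TAM-treated cells.  The
    grid is evaluated with the vectorized propagator integrator so a full
    ensemble × 11 × 11 grid runs in seconds; results are deterministic given
    the fits and factors.
    """
    for t in (target_x, target_y):
        if t not in INHIBITION_TARGETS:
            raise InvalidTargetError(f"unknown inhibition target {t!r}")
    if target_x == target_y:
        raise InvalidTargetError("target_x and target_y must differ")
    fx = _validate_factors(factors)
    fy = _validate_factors(factors_y if factors_y is not None else factors)

    params_list = [f.params if isinstance(f, FitResult) else f for f in fits]
    if not params_list:
        raise InvalidParameterError("intervention grid needs at least one fit")
    theta0 = np.stack([p.to_array() for p in params_list])  # (n_fits, 19)
    n_fits, nx, ny = len(params_list), len(fx), len(fy)

    from .model import PARAM_NAMES

    ix = PARAM_NAMES.index(INHIBITION_TARGETS[target_x])
    iy = PARAM_NAMES.index(INHIBITION_TARGETS[target_y])

    # expand to (n_fits, nx, ny, 19) and scale the two targeted constants
    theta = np.broadcast_to(
        theta0[:, None, None, :], (n_fits, nx, ny, theta0.shape[1])
    ).copy()
    theta[..., ix] *= np.asarray(fx)[None, :, None]
    theta[..., iy] *= np.asarray(fy)[None, None, :]

    q = _q_batch(theta.reshape(-1, theta0.shape[1])).reshape(n_fits, nx, ny)
    uninhibited = float(_q_batch(theta0).mean())
    return InterventionGrid(
        target_x=target_x,
        target_y=target_y,
        factors_x=fx,
        factors_y=fy,
        q_values=q,
        uninhibited_mean_q=uninhibited,
    )


def threshold_contour(grid: InterventionGrid, level: float = 1.0) -> pd.DataFrame:
    """Regression boundary: per x-factor, the largest y-factor with mean q ≤ level.

    Returns a frame with one row per x-factor; ``boundary_factor_y`` is NaN
    where no y-factor in the grid reaches the level.
    """
    mean_q = grid.mean_q
    rows = []
    for i, f_x in enumerate(grid.factors_x):
        ok = [f_y for j, f_y in enumerate(grid.factors_y) if mean_q[i, j] <= level]
        rows.append({"factor_x": f_x, "boundary_factor_y": max(ok) if ok else np.nan})
    return pd.DataFrame(rows)
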