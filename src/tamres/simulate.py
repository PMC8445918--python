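"""Weekly-passage simulation of the subpopulation model.

The wet protocol reseeds 1 × 10^6 cells every week and measures the weekly
fold change — the total count at the end of a week divided by the reseeded
count at its start.  Because the model is linear in cell counts, the fold
changes and subpopulation fractions are identical whether or not the culture
is diluted; dilution is kept on by default purely to keep counts bounded over
long horizons.  Cumulative exposure ``U`` is a property of the culture's
history and is never rescaled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .errors import InsufficientHorizonError, IntegrationError, InvalidParameterError
from .model import CellState, ModelParameters, rhs_array

__all__ = ["Condition", "Trajectory", "integrate", "mean_growth_rate", "CONTROL", "TAM"]

#: weeks whose fold changes enter the mean-over-time growth rate q
Q_WEEKS = tuple(range(4, 11))


@dataclass(frozen=True)
class Condition:
    """A culture condition: constant TAM dose, horizon, and passaging."""

    tam_dose: float = 0.0          # µM; 0 for control, 1 for the TAM arm
    n_weeks: int = 11
    N0: float = 1e6                # reseeded cell count per week
    dilute_weekly: bool = True

    def __post_init__(self) -> None:
        if self.tam_dose < 0:
            raise InvalidParameterError(f"tam_dose must be >= 0, got {self.tam_dose!r}")
        if self.n_weeks < 1:
            raise InvalidParameterError(f"n_weeks must be >= 1, got {self.n_weeks!r}")
        if self.N0 <= 0:
            raise InvalidParameterError(f"N0 must be > 0, got {self.N0!r}")

    @property
    def label(self) -> str:
        return "tam" if self.tam_dose > 0 else "ctrl"


#: the two standard experimental arms
CONTROL = Condition(tam_dose=0.0)
TAM = Condition(tam_dose=1.0)


@dataclass(frozen=True)
class Trajectory:
    """Simulated time course sampled at integer weeks.

    ``states[w]`` holds the cell counts just before the week-``w`` dilution
    (``states[0]`` is the initial seeding); ``fold_change[w-1]`` is
    ``X_total(w⁻) / X_total((w−1)⁺)`` for weeks 1..n; ``fractions[w]`` are
    the subpopulation proportions at week ``w``.
    """

    condition: Condition
    weeks: np.ndarray = field(repr=False)
    states: np.ndarray = field(repr=False)       # (n_weeks+1, 5) counts + U
    fold_change: np.ndarray = field(repr=False)  # (n_weeks,)
    fractions: np.ndarray = field(repr=False)    # (n_weeks+1, 4)

    @property
    def n_weeks(self) -> int:
        return int(self.weeks[-1])

    def state_at(self, week: int) -> CellState:
        return CellState.from_array(np.maximum(self.states[week], 0.0))

    def to_dataframe(self) -> pd.DataFrame:
        """Tidy export: one row per week."""
        n = self.n_weeks
        return pd.DataFrame(
            {
                "week": self.weeks,
                "condition": self.condition.label,
                "X_S": self.states[:, 0],
                "X_P": self.states[:, 1],
                "X_R1": self.states[:, 2],
                "X_R2": self.states[:, 3],
                "U": self.states[:, 4],
                "fold_change": np.concatenate([[np.nan], self.fold_change]),
                "frac_S": self.fractions[:, 0],
                "frac_P": self.fractions[:, 1],
                "frac_R1": self.fractions[:, 2],
                "frac_R2": self.fractions[:, 3],
            },
            index=pd.RangeIndex(n + 1),
        )


def initial_state_array(params: ModelParameters, N0: float) -> np.ndarray:
    """Week-0 seeding: sensitive cells plus the pre-resistant fraction f_P0."""
    return np.array(
        [(1.0 - params.f_P0) * N0, params.f_P0 * N0, 0.0, 0.0, 0.0]
    )


def integrate(
    params: ModelParameters,
    condition: Condition,
    flux_scale: np.ndarray | None = None,
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> Trajectory:
    """Integrate the model week by week under a condition.

    Solves the ODE on each weekly interval with a stiff-capable solver
    (LSODA), records the fold change and fractions just before each passage,
    then — if ``condition.dilute_weekly`` — rescales the four cell counts back
    to ``N0`` (leaving ``U`` untouched).  Integration is carried out in units
    of ``N0`` so the absolute tolerance is meaningful across seeding scales.

    ``flux_scale`` (length 12) multiplies each reaction flux throughout; it is
    the perturbation hook of the sensitivity analysis.
    """
    n = condition.n_weeks
    y = initial_state_array(params, 1.0)  # normalized units: counts / N0
    states = np.empty((n + 1, 5))
    fractions = np.empty((n + 1, 4))
    fold = np.empty(n)

    states[0] = y * np.array([condition.N0] * 4 + [1.0])
    fractions[0] = y[:4] / y[:4].sum()

    for week in range(1, n + 1):
        total_start = y[:4].sum()
        sol = solve_ivp(
            rhs_array,
            (week - 1.0, float(week)),
            y,
            method="LSODA",
            args=(params, condition.tam_dose, flux_scale),
            rtol=rtol,
            atol=atol,
        )
        if not sol.success or not np.all(np.isfinite(sol.y[:, -1])):
            raise IntegrationError(
                f"ODE integration failed on week interval [{week - 1}, {week}]: "
                f"{sol.message}"
            )
        y = sol.y[:, -1]
        total_end = y[:4].sum()
        if total_end <= 0:
            raise IntegrationError(
                f"total cell count non-positive on week interval [{week - 1}, {week}]"
            )
        fold[week - 1] = total_end / total_start
        fractions[week] = y[:4] / total_end
        states[week] = y * np.array([condition.N0] * 4 + [1.0])
        if condition.dilute_weekly:
            y = y.copy()
            y[:4] /= total_end  # reseed N0 cells; exposure history persists

    return Trajectory(
        condition=condition,
        weeks=np.arange(n + 1),
        states=states,
        fold_change=fold,
        fractions=fractions,
    )


def mean_growth_rate(traj: Trajectory) -> float:
    """Mean-over-time growth rate q: the average weekly fold change of weeks 4–10.

    q = (Σ_{t=4}^{10} X_total(t)/X_total(t−1)) / 7.  This is the summary the
    sensitivity and intervention analyses act on; q ≤ 1 means the treated
    population no longer grows on average after week 3.
    """
    if traj.n_weeks < Q_WEEKS[-1]:
        raise InsufficientHorizonError(
            f"mean growth rate needs a trajectory through week {Q_WEEKS[-1]}, "
            f"got {traj.n_weeks} weeks"
        )
    return float(np.mean([traj.fold_change[t - 1] for t in Q_WEEKS]))
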