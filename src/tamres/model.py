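"""Four-subpopulation reaction network of tamoxifen (TAM) resistance acquisition.

The model tracks four cell states of an initially TAM-sensitive breast cancer
cell population:

* ``S``  — sensitive cells,
* ``P``  — pre-resistant cells,
* ``R1`` — resistant cells with rewired metabolism,
* ``R2`` — resistant cells with an adhesive, epigenetically altered phenotype,

plus ``U``, the cumulative TAM exposure (µM·week, the time integral of the
dose).  Cells grow exponentially, sensitive and pre-resistant cells die under
TAM, and forward state transitions (S→P, P→R1, P→R2) accelerate with
cumulative exposure through a Hill sigmoid of ``U``.  Reverse transitions
(P→S, R1→P, R2→P) are plain mass-action.  The twelve reaction fluxes
``v1``–``v12`` and the 19 free parameters are fixed by this module.

Reaction map
------------
=====  =======================================  =================
flux   meaning                                  rate law
=====  =======================================  =================
v1     growth of S                              g_S·X_S
v2     TAM-induced death of S                   d_S·1{dose>0}·X_S
v3     forward S→P                              k_SP·h(U; n_SP, K_SP)·X_S
v4     reverse P→S                              k_PS·X_P
v5     growth of P                              g_P·X_P
v6     TAM-induced death of P                   d_P·1{dose>0}·X_P
v7     forward P→R1                             k_PR1·h(U; n_PR1, K_PR1)·X_P
v8     reverse R1→P                             k_R1P·X_R1
v9     growth of R1                             g_R1·X_R1
v10    forward P→R2                             k_PR2·h(U; n_PR2, K_PR2)·X_P
v11    reverse R2→P                             k_R2P·X_R2
v12    growth of R2                             g_R2·X_R2
=====  =======================================  =================

where ``h(U; n, K) = U^n / (K^n + U^n)`` is the Hill activation.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

import numpy as np

from .errors import InvalidParameterError, InvalidStateError

__all__ = [
    "PARAM_NAMES",
    "STATE_FIELDS",
    "REACTION_NAMES",
    "N_PARAMETERS",
    "N_REACTIONS",
    "ModelParameters",
    "CellState",
    "ReactionRates",
    "hill_activation",
    "reaction_rates",
    "rhs",
]

#: Canonical ordering of the 19 free parameters.
PARAM_NAMES: tuple[str, ...] = (
    "g_S", "g_P", "g_R1", "g_R2",
    "d_S", "d_P",
    "k_SP", "k_PR1", "k_PR2",
    "n_SP", "n_PR1", "n_PR2",
    "K_SP", "K_PR1", "K_PR2",
    "k_PS", "k_R1P", "k_R2P",
    "f_P0",
)

#: State vector ordering used by array-based interfaces.
STATE_FIELDS: tuple[str, ...] = ("X_S", "X_P", "X_R1", "X_R2", "U")

REACTION_NAMES: tuple[str, ...] = tuple(f"v{i}" for i in range(1, 13))

N_PARAMETERS = len(PARAM_NAMES)
N_REACTIONS = len(REACTION_NAMES)

# parameters that must be strictly positive (Hill shape/scale)
_STRICT_POSITIVE = ("n_SP", "n_PR1", "n_PR2", "K_SP", "K_PR1", "K_PR2")


@dataclass(frozen=True)
class ModelParameters:
    """The 19 free parameters of the subpopulation model.

    Growth (``g_*``) and death (``d_*``) rates are per week; forward
    transition rate constants ``k_SP/k_PR1/k_PR2`` are per-week maxima reached
    at saturating cumulative exposure; ``n_*`` are dimensionless Hill
    steepnesses; ``K_*`` are half-effect cumulative exposures (µM·week);
    ``k_PS/k_R1P/k_R2P`` are per-week reverse rates; ``f_P0`` is the initial
    pre-resistant fraction at week 0.
    """

    g_S: float
    g_P: float
    g_R1: float
    g_R2: float
    d_S: float
    d_P: float
    k_SP: float
    k_PR1: float
    k_PR2: float
    n_SP: float
    n_PR1: float
    n_PR2: float
    K_SP: float
    K_PR1: float
    K_PR2: float
    k_PS: float
    k_R1P: float
    k_R2P: float
    f_P0: float

    def __post_init__(self) -> None:
        for name in PARAM_NAMES:
            value = getattr(self, name)
            if not np.isfinite(value):
                raise InvalidParameterError(f"{name} must be finite, got {value!r}")
            if name in _STRICT_POSITIVE:
                if value <= 0:
                    raise InvalidParameterError(f"{name} must be > 0, got {value!r}")
            elif value < 0:
                raise InvalidParameterError(f"{name} must be >= 0, got {value!r}")
        if not 0.0 <= self.f_P0 < 1.0:
            raise InvalidParameterError(f"f_P0 must lie in [0, 1), got {self.f_P0!r}")

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict[str, float]:
        return {name: float(getattr(self, name)) for name in PARAM_NAMES}

    @classmethod
    def from_dict(cls, data: dict[str, float]) -> "ModelParameters":
        unknown = sorted(set(data) - set(PARAM_NAMES))
        if unknown:
            raise InvalidParameterError(f"unknown parameter keys: {unknown}")
        missing = sorted(set(PARAM_NAMES) - set(data))
        if missing:
            raise InvalidParameterError(f"missing parameter keys: {missing}")
        return cls(**{name: float(data[name]) for name in PARAM_NAMES})

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=False)

    @classmethod
    def from_json(cls, text: str) -> "ModelParameters":
        return cls.from_dict(json.loads(text))

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, values: np.ndarray) -> "ModelParameters":
        values = np.asarray(values, dtype=float)
        if values.shape != (N_PARAMETERS,):
            raise InvalidParameterError(
                f"expected {N_PARAMETERS} parameters, got shape {values.shape}"
            )
        return cls(**dict(zip(PARAM_NAMES, values.tolist())))

    def replace(self, **changes: float) -> "ModelParameters":
        return dataclasses.replace(self, **changes)


@dataclass(frozen=True)
class CellState:
    """Cell counts of the four subpopulations plus cumulative TAM exposure."""

    X_S: float
    X_P: float
    X_R1: float
    X_R2: float
    U: float = 0.0

    def __post_init__(self) -> None:
        for name in STATE_FIELDS:
            value = getattr(self, name)
            if not np.isfinite(value) or value < 0:
                raise InvalidStateError(f"{name} must be finite and >= 0, got {value!r}")

    @property
    def total(self) -> float:
        return self.X_S + self.X_P + self.X_R1 + self.X_R2

    def to_array(self) -> np.ndarray:
        return np.array([self.X_S, self.X_P, self.X_R1, self.X_R2, self.U], dtype=float)

    @classmethod
    def from_array(cls, values: np.ndarray) -> "CellState":
        values = np.asarray(values, dtype=float)
        if values.shape != (5,):
            raise InvalidStateError(f"expected 5 state components, got shape {values.shape}")
        return cls(*values.tolist())


@dataclass(frozen=True)
class ReactionRates:
    """The twelve reaction fluxes (cells/week) at a given state."""

    v1: float
    v2: float
    v3: float
    v4: float
    v5: float
    v6: float
    v7: float
    v8: float
    v9: float
    v10: float
    v11: float
    v12: float

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in REACTION_NAMES], dtype=float)


def hill_activation(U: float, n: float, K: float) -> float:
    """Hill sigmoid ``U^n / (K^n + U^n)`` of cumulative exposure.

    Monotone non-decreasing in ``U``, 0 at ``U = 0``, 0.5 at ``U = K`` and
    saturating to 1.  ``n`` sets the steepness of the switch, ``K`` the
    half-effect exposure.
    """
    if n <= 0 or K <= 0:
        raise InvalidParameterError(f"Hill shape requires n > 0 and K > 0, got n={n!r}, K={K!r}")
    if U < 0:
        raise InvalidStateError(f"cumulative exposure must be >= 0, got {U!r}")
    if U == 0.0:
        return 0.0
    # logistic in log space: robust to overflow at large steepness
    t = n * (np.log(K) - np.log(U))
    if t > 700.0:
        return 0.0
    return float(1.0 / (1.0 + np.exp(t)))


def _rates_array(y: np.ndarray, params: ModelParameters, tam_dose: float) -> np.ndarray:
    """Vector of the twelve fluxes for state array ``y = (X_S, X_P, X_R1, X_R2, U)``."""
    X_S, X_P, X_R1, X_R2, U = y
    U = max(U, 0.0)  # absorb solver round-off below zero
    drug = 1.0 if tam_dose > 0 else 0.0
    h_SP = hill_activation(U, params.n_SP, params.K_SP)
    h_PR1 = hill_activation(U, params.n_PR1, params.K_PR1)
    h_PR2 = hill_activation(U, params.n_PR2, params.K_PR2)
    return np.array(
        [
            params.g_S * X_S,                  # v1
            params.d_S * drug * X_S,           # v2
            params.k_SP * h_SP * X_S,          # v3
            params.k_PS * X_P,                 # v4
            params.g_P * X_P,                  # v5
            params.d_P * drug * X_P,           # v6
            params.k_PR1 * h_PR1 * X_P,        # v7
            params.k_R1P * X_R1,               # v8
            params.g_R1 * X_R1,                # v9
            params.k_PR2 * h_PR2 * X_P,        # v10
            params.k_R2P * X_R2,               # v11
            params.g_R2 * X_R2,                # v12
        ]
    )


def reaction_rates(
    state: CellState, params: ModelParameters, tam_dose: float
) -> ReactionRates:
    """Evaluate all twelve reaction fluxes at a state.

    TAM-induced death (v2, v6) is gated by an indicator on the current dose;
    forward transitions (v3, v7, v10) are gated by the Hill sigmoid of the
    cumulative exposure ``state.U``, so both vanish in a drug-naive culture.
    """
    if tam_dose < 0:
        raise InvalidParameterError(f"tam_dose must be >= 0, got {tam_dose!r}")
    v = _rates_array(state.to_array(), params, tam_dose)
    return ReactionRates(*v.tolist())


def rhs_array(
    t: float,
    y: np.ndarray,
    params: ModelParameters,
    tam_dose: float,
    flux_scale: np.ndarray | None = None,
) -> np.ndarray:
    """ODE right-hand side on the raw state array (solver-facing).

    ``flux_scale`` optionally multiplies each of the twelve fluxes; it is the
    hook used by the sensitivity and intervention analyses to perturb one
    reaction as a whole.
    """
    v = _rates_array(y, params, tam_dose)
    if flux_scale is not None:
        v = v * flux_scale
    v1, v2, v3, v4, v5, v6, v7, v8, v9, v10, v11, v12 = v
    return np.array(
        [
            v1 - v2 - v3 + v4,
            v3 - v4 + v5 - v6 - v7 + v8 - v10 + v11,
            v7 - v8 + v9,
            v10 - v11 + v12,
            tam_dose,
        ]
    )


def rhs(
    t: float,
    state: CellState,
    params: ModelParameters,
    tam_dose: float,
    flux_scale: np.ndarray | None = None,
) -> np.ndarray:
    """Time derivative of ``(X_S, X_P, X_R1, X_R2, U)``.

    Transitions conserve cells: the sum of the four cell derivatives equals
    total growth flux minus total death flux.  ``dU/dt`` is the dose itself.
    """
    if tam_dose < 0:
        raise InvalidParameterError(f"tam_dose must be >= 0, got {tam_dose!r}")
    return rhs_array(t, state.to_array(), params, tam_dose, flux_scale)
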