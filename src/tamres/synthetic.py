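"""Synthetic experiment generator.

Every downstream stage of the package — fitting, sensitivity, intervention —
is exercised against data produced here, so the generator encodes the
qualitative biology the analysis assumes: an untreated culture that grows
close to twofold per week throughout; a TAM-treated culture whose growth is
held near stasis for the first ~5 weeks before recovering; and a composition
that moves from almost purely sensitive cells at week 0, through a
pre-resistant majority at weeks 3–6, to a split between the two resistant
states by week 9, with the adhesive/epigenetic state (R2) dominant and
faster-growing.

The "true" parameter set below is a synthetic, implementer-calibrated
constant — it is documented, fixed, and satisfies the pattern above under
noise-free simulation, including the two headline orderings ``g_R2 > g_R1``
(R2 outgrows R1) and ``n_PR2 > n_PR1`` (the P→R2 switch is steeper).

Noise model: weekly fold changes receive i.i.d. multiplicative lognormal
noise (growth is a ratio, so noise should be multiplicative); composition
vectors are resampled from a Dirichlet distribution centered on the simulated
fractions, the simplest noise respecting the simplex.  Both are configurable
and fully reproducible from a seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidParameterError
from .fitting import (
    DEFAULT_PROPORTION_WEEKS,
    ExperimentDataset,
)
from .model import ModelParameters
from .simulate import CONTROL, TAM, Condition, integrate

__all__ = ["NoiseConfig", "default_true_parameters", "generate_dataset"]

#: calibrated synthetic truth (per-week rates; exposures in µM·week)
_TRUE_PARAMS: dict[str, float] = {
    "g_S": 0.64,    # sensitive cells: ~1.9-fold/week untreated
    "g_P": 0.45,
    "g_R1": 0.25,   # metabolic resistant state grows slowly...
    "g_R2": 0.65,   # ...the adhesive state almost like untreated cells
    "d_S": 0.62,    # TAM death nearly cancels sensitive growth -> stasis
    "d_P": 0.40,
    "k_SP": 1.5,    # S->P engages within the first weeks of exposure
    "k_PR1": 0.15,  # P->R1 is a slow, gradual leak
    "k_PR2": 0.6,   # P->R2 is faster once triggered
    "n_SP": 2.0,
    "n_PR1": 2.0,   # shallow switch: R1 accumulates from early on
    "n_PR2": 8.0,   # sharp switch: R2 floods in only after ~week 6
    "K_SP": 1.5,
    "K_PR1": 5.0,
    "K_PR2": 7.0,
    "k_PS": 0.02,   # reverse transitions are weak
    "k_R1P": 0.02,
    "k_R2P": 0.02,
    "f_P0": 0.05,   # 5% of the seeding is already pre-resistant
}


@dataclass(frozen=True)
class NoiseConfig:
    """Noise levels of the synthetic experiment.

    ``growth_cv`` is the coefficient of variation of the multiplicative
    lognormal noise on fold changes; ``proportion_concentration`` scales the
    Dirichlet concentration of the composition noise (200 gives roughly ±0.03
    per fraction); ``np.inf`` concentration and zero cv reproduce the
    noise-free model output exactly.
    """

    growth_cv: float = 0.05
    proportion_concentration: float = 200.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.growth_cv < 0:
            raise InvalidParameterError(f"growth_cv must be >= 0, got {self.growth_cv!r}")
        if not self.proportion_concentration > 0:
            raise InvalidParameterError(
                f"proportion_concentration must be > 0, got {self.proportion_concentration!r}"
            )


def default_true_parameters() -> ModelParameters:
    """The fixed synthetic truth used throughout testing and examples."""
    return ModelParameters.from_dict(_TRUE_PARAMS)


def generate_dataset(
    params: ModelParameters | None = None,
    noise: NoiseConfig | None = None,
    n_weeks: int = 11,
    proportion_weeks: tuple[int, ...] = DEFAULT_PROPORTION_WEEKS,
) -> ExperimentDataset:
    """Simulate both arms and overlay measurement noise.

    Emits ``n_weeks`` growth values per arm and one composition vector per
    week in ``proportion_weeks`` (TAM arm).  With ``growth_cv = 0`` and
    infinite concentration the output equals the noise-free model prediction.
    """
    params = params or default_true_parameters()
    noise = noise or NoiseConfig()
    rng = np.random.default_rng(noise.seed)

    tam = integrate(params, Condition(tam_dose=TAM.tam_dose, n_weeks=n_weeks))
    ctrl = integrate(params, Condition(tam_dose=CONTROL.tam_dose, n_weeks=n_weeks))

    growth_tam = tam.fold_change.copy()
    growth_ctrl = ctrl.fold_change.copy()
    if noise.growth_cv > 0:
        # lognormal with unit median; sigma chosen so the cv matches
        sigma = float(np.sqrt(np.log1p(noise.growth_cv**2)))
        growth_tam *= np.exp(sigma * rng.standard_normal(n_weeks))
        growth_ctrl *= np.exp(sigma * rng.standard_normal(n_weeks))

    props = np.empty((len(proportion_weeks), 4))
    for j, week in enumerate(proportion_weeks):
        target = np.maximum(tam.fractions[week], 0.0)
        target = target / target.sum()
        if np.isinf(noise.proportion_concentration):
            props[j] = target
        else:
            alpha = np.maximum(noise.proportion_concentration * target, 1e-8)
            draw = rng.dirichlet(alpha)
            props[j] = draw / draw.sum()

    return ExperimentDataset(
        growth_tam=growth_tam,
        growth_ctrl=growth_ctrl,
        proportions=props,
        proportion_weeks=proportion_weeks,
    )
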