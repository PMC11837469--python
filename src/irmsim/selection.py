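"""Truncation selection on polygenic insecticide resistance.

One mosquito generation proceeds as follows.  The population emerges with
per-trait polygenic resistance scores (PRS) distributed normally around the
current mean with fixed phenotypic standard deviation ``sigma``.  A fraction
``x`` of females (and ``m * x`` of males) contact the deployed
insecticide(s); the rest escape selection entirely.  Among those exposed, a
fraction ``p`` survives each insecticide, where ``p`` is the expected field
survival given the population's bioassay survival and the insecticide's
current efficacy.  Survival is by truncation: exactly the top-``p`` fraction
of the trait distribution survives.  For a mixture, a mosquito must survive
both truncations in turn, so the joint exposed survival is ``p_i * p_j``.

The parental population of the next generation is the mixture of unexposed
mosquitoes (unshifted) and exposed survivors (mean shifted up by the
truncated-normal excess), which gives the within-generation selection
differential.  The between-generation response follows the sex-specific
Breeder's equation:

    R = h2 * (S_female + S_male) / 2 * beta

with heritability ``h2`` and an exposure scaling factor ``beta`` used to
calibrate simulated timescales.  Cross resistance between the two traits
enters as a correlated response with genetic correlation ``alpha``:

    R_i_total = R_i + alpha * sqrt(h2_i * h2_j) * S_bar_j * beta

(equal phenotypic standard deviations assumed).  The degree of control is the
fraction of adult females killed in the generation,
``x * (1 - joint exposed survival)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Union

import numpy as np
from scipy.special import ndtri

from .mapping import (
    FieldSurvivalParams,
    ResistanceScale,
    field_survival,
    prs_to_bioassay,
)

__all__ = [
    "PopulationState",
    "ExposureConfig",
    "ModelParams",
    "SelectionOutcome",
    "Monotherapy",
    "Mixture",
    "DegenerateExtinctionError",
    "selection_intensity",
    "mono_selection_differential",
    "mixture_selection_differentials",
    "breeders_response",
    "apply_cross_resistance",
    "degree_of_control",
    "single_generation_step",
]


class DegenerateExtinctionError(ValueError):
    """The entire population is exposed and killed: no parents remain."""


@dataclass(frozen=True)
class PopulationState:
    """Mean PRS per resistance trait, with fixed phenotypic spread.

    ``mean_prs_j`` is ``None`` for one-trait (monotherapy-only) settings.
    The phenotypic standard deviation ``sigma`` is shared by both traits and
    held constant across generations: the model tracks means only.
    """

    mean_prs_i: float
    mean_prs_j: Optional[float] = None
    sigma: float = 20.0

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError("sigma must be > 0")
        if not np.isfinite(self.mean_prs_i):
            raise ValueError("mean_prs_i must be finite")
        if self.mean_prs_j is not None and not np.isfinite(self.mean_prs_j):
            raise ValueError("mean_prs_j must be finite")


@dataclass(frozen=True)
class ExposureConfig:
    """Insecticide exposure and deme structure parameters.

    ``female_exposure`` (x) is the proportion of females contacting the
    deployed insecticide(s); males contact at ``male_ratio * x``.
    ``coverage`` (C) and ``dispersal`` (theta) are used only by the
    multi-generation strategy simulator.
    """

    female_exposure: float = 0.7
    male_ratio: float = 1.0
    coverage: float = 0.7
    dispersal: float = 0.2

    def __post_init__(self) -> None:
        if not 0 <= self.female_exposure <= 1:
            raise ValueError("female_exposure must be in [0, 1]")
        if not 0 <= self.male_ratio * self.female_exposure <= 1:
            raise ValueError("male exposure (male_ratio * female_exposure) must be in [0, 1]")
        if not 0 <= self.coverage <= 1:
            raise ValueError("coverage must be in [0, 1]")
        if not 0 <= self.dispersal <= 1:
            raise ValueError("dispersal must be in [0, 1]")

    @property
    def male_exposure(self) -> float:
        return self.male_ratio * self.female_exposure


@dataclass(frozen=True)
class ModelParams:
    """Genetic and conversion parameters of the selection model."""

    h2_i: float = 0.2
    h2_j: float = 0.2
    cross_resistance: float = 0.0
    exposure_scaling: float = 1.0
    cost_differential_i_female: float = 0.0
    cost_differential_i_male: float = 0.0
    cost_differential_j_female: float = 0.0
    cost_differential_j_male: float = 0.0
    field_params: FieldSurvivalParams = field(default_factory=FieldSurvivalParams)
    scale: ResistanceScale = field(default_factory=ResistanceScale)
    survival_floor: float = 1e-10

    def __post_init__(self) -> None:
        for name in ("h2_i", "h2_j"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if not -1 <= self.cross_resistance <= 1:
            raise ValueError("cross_resistance must be in [-1, 1]")
        if not self.exposure_scaling > 0:
            raise ValueError("exposure_scaling must be > 0")
        if not self.survival_floor > 0:
            raise ValueError("survival_floor must be > 0")


@dataclass(frozen=True)
class Monotherapy:
    """Deployment of a single insecticide at its current efficacy."""

    trait: Literal["i", "j"]
    efficacy: float


@dataclass(frozen=True)
class Mixture:
    """Co-formulated deployment: contact exposes to both insecticides."""

    efficacy_i: float
    efficacy_j: float


Deployment = Union[Monotherapy, Mixture, None]


@dataclass(frozen=True)
class SelectionOutcome:
    """Per-generation selection summary (PRS units and proportions)."""

    differential_female_i: float
    differential_male_i: float
    differential_female_j: float
    differential_male_j: float
    response_i: float
    response_j: float
    exposed_survival_i: float
    exposed_survival_j: float
    degree_of_control: float


_SQRT_2PI = np.sqrt(2.0 * np.pi)


def _norm_pdf(x):
    return np.exp(-0.5 * np.square(x)) / _SQRT_2PI


def _upper_quantile(p):
    """z such that the standard-normal upper tail beyond z has mass ``p``."""
    return -ndtri(p)


def _tail_density(p, floor: float = 1e-10):
    """Standard-normal density at the upper-tail quantile holding mass ``p``.

    Equals ``p * selection_intensity(p)``; numerically safe at both ends
    (0 at p = 0 and at p = 1).
    """
    p = np.clip(np.asarray(p, dtype=float), floor, 1.0)
    out = _norm_pdf(_upper_quantile(p))
    return out if out.ndim else float(out)


def selection_intensity(p, floor: float = 1e-10):
    """Mean excess, in standard deviations, of the top-``p`` tail of a
    standard normal: ``pdf(isf(p)) / p``.

    This is the factor by which truncation survival of a fraction ``p``
    shifts the survivors' mean.  ``p`` below ``floor`` is clamped to the
    floor; ``p <= 0`` is a domain error; ``p = 1`` gives 0 (no selection).
    """
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0):
        raise ValueError("survival proportion must be > 0")
    if np.any(p > 1):
        raise ValueError("survival proportion must be <= 1")
    p = np.maximum(p, floor)
    out = _norm_pdf(_upper_quantile(p)) / p
    return out if out.ndim else float(out)


def _exposed_survival(mean_prs: float, efficacy: float, params: ModelParams) -> float:
    return field_survival(
        prs_to_bioassay(mean_prs, params.scale), efficacy, params.field_params
    )


def mono_selection_differential(
    state: PopulationState,
    trait: Literal["i", "j"],
    efficacy: float,
    exposure: float,
    params: ModelParams = ModelParams(),
) -> tuple[float, float]:
    """Selection differential for one insecticide deployed alone.

    Returns ``(S, p)`` where ``p`` is the field survival of exposed
    mosquitoes and

        S = x * p * sigma * i(p) / ((1 - x) + x * p)

    the parental mean shift of a population in which a fraction ``1 - x``
    escaped exposure and dilutes the selected survivors.
    """
    if not 0 <= exposure <= 1:
        raise ValueError("exposure must be in [0, 1]")
    z = state.mean_prs_i if trait == "i" else state.mean_prs_j
    if z is None:
        raise ValueError(f"state has no trait {trait!r}")
    p = _exposed_survival(z, efficacy, params)
    if p == 0.0 and exposure == 1.0:
        raise DegenerateExtinctionError(
            "entire population exposed and killed (exposure = 1, survival = 0)"
        )
    if exposure == 0.0 or p in (0.0, 1.0):
        return 0.0, p
    s = (
        exposure
        * state.sigma
        * _tail_density(p, params.survival_floor)
        / ((1.0 - exposure) + exposure * p)
    )
    return float(s), p


def mixture_selection_differentials(
    state: PopulationState,
    efficacy_i: float,
    efficacy_j: float,
    exposure: float,
    params: ModelParams = ModelParams(),
) -> tuple[float, float, float, float]:
    """Selection differentials for both insecticides of a mixture.

    Exposed mosquitoes must survive both truncations; the joint exposed
    survival is ``p_i * p_j`` (truncations independent given the means).
    Returns ``(S_i, S_j, p_i, p_j)`` with

        S_i = x * p_i * p_j * sigma * i(p_i) / ((1 - x) + x * p_i * p_j)

    and symmetrically for j.  An effective partner (small ``p_j``) thins the
    trait-i survivors, so the unexposed dilute them more and S_i shrinks; at
    exposure 1 there is no unexposed pool and S_i is independent of the
    partner.
    """
    if state.mean_prs_j is None:
        raise ValueError("mixture selection requires a two-trait state")
    if not 0 <= exposure <= 1:
        raise ValueError("exposure must be in [0, 1]")
    p_i = _exposed_survival(state.mean_prs_i, efficacy_i, params)
    p_j = _exposed_survival(state.mean_prs_j, efficacy_j, params)
    joint = p_i * p_j
    if joint == 0.0 and exposure == 1.0:
        raise DegenerateExtinctionError(
            "entire population exposed and killed by the mixture"
        )
    if exposure == 0.0:
        return 0.0, 0.0, p_i, p_j
    denom = (1.0 - exposure) + exposure * joint
    floor = params.survival_floor
    s_i = exposure * state.sigma * p_j * _tail_density(p_i, floor) / denom
    s_j = exposure * state.sigma * p_i * _tail_density(p_j, floor) / denom
    return float(s_i), float(s_j), p_i, p_j


def breeders_response(
    diff_female: float, diff_male: float, h2: float, beta: float = 1.0
) -> float:
    """Sex-specific Breeder's equation: ``h2 * (S_f + S_m) / 2 * beta``."""
    return h2 * 0.5 * (diff_female + diff_male) * beta


def apply_cross_resistance(
    response_direct_i: float,
    response_direct_j: float,
    mean_diff_i: float,
    mean_diff_j: float,
    params: ModelParams,
) -> tuple[float, float]:
    """Add the correlated response from selection on the partner trait.

    ``total_i = direct_i + alpha * sqrt(h2_i * h2_j) * S_bar_j * beta``
    (standard correlated-response form with equal phenotypic SDs), and
    symmetrically for j.  ``S_bar`` are sex-averaged differentials.
    """
    alpha = params.cross_resistance
    coupling = alpha * np.sqrt(params.h2_i * params.h2_j) * params.exposure_scaling
    total_i = response_direct_i + coupling * mean_diff_j
    total_j = response_direct_j + coupling * mean_diff_i
    return float(total_i), float(total_j)


def degree_of_control(exposure: float, joint_exposed_survival: float):
    """Fraction of adult females killed: ``x * (1 - joint survival)``."""
    x = np.asarray(exposure, dtype=float)
    p = np.asarray(joint_exposed_survival, dtype=float)
    if np.any((x < 0) | (x > 1)) or np.any((p < 0) | (p > 1)):
        raise ValueError("exposure and survival must be in [0, 1]")
    out = x * (1.0 - p)
    return out if out.ndim else float(out)


def _sex_differentials(
    state: PopulationState,
    deployment: Deployment,
    exposure: float,
    params: ModelParams,
) -> tuple[float, float, float, float]:
    """Raw insecticide-selection differentials (S_i, S_j, p_i, p_j) for one sex."""
    if deployment is None:
        p_j = 1.0 if state.mean_prs_j is not None else np.nan
        return 0.0, 0.0, 1.0, p_j
    if isinstance(deployment, Monotherapy):
        s, p = mono_selection_differential(
            state, deployment.trait, deployment.efficacy, exposure, params
        )
        if deployment.trait == "i":
            return s, 0.0, p, 1.0
        return 0.0, s, 1.0, p
    return mixture_selection_differentials(
        state, deployment.efficacy_i, deployment.efficacy_j, exposure, params
    )


def single_generation_step(
    state: PopulationState,
    deployment: Deployment,
    exposure: ExposureConfig = ExposureConfig(),
    params: ModelParams = ModelParams(),
) -> tuple[SelectionOutcome, PopulationState]:
    """Advance the population mean(s) by one generation of selection.

    Computes sex-specific differentials (females exposed at ``x``, males at
    ``m * x``), subtracts fitness-cost differentials, sex-averages, applies
    the Breeder's equation and the cross-resistance correlated response, and
    returns the outcome together with the updated state.  The degree of
    control reports female kills only.
    """
    sf_i, sf_j, pf_i, pf_j = _sex_differentials(
        state, deployment, exposure.female_exposure, params
    )
    sm_i, sm_j, _, _ = _sex_differentials(
        state, deployment, exposure.male_exposure, params
    )

    df_i = sf_i - params.cost_differential_i_female
    dm_i = sm_i - params.cost_differential_i_male
    df_j = sf_j - params.cost_differential_j_female
    dm_j = sm_j - params.cost_differential_j_male

    beta = params.exposure_scaling
    direct_i = breeders_response(df_i, dm_i, params.h2_i, beta)
    direct_j = breeders_response(df_j, dm_j, params.h2_j, beta)
    mean_diff_i = 0.5 * (df_i + dm_i)
    mean_diff_j = 0.5 * (df_j + dm_j)
    total_i, total_j = apply_cross_resistance(
        direct_i, direct_j, mean_diff_i, mean_diff_j, params
    )

    has_j = state.mean_prs_j is not None
    if not has_j:
        total_j = 0.0
    joint = pf_i * (pf_j if has_j and np.isfinite(pf_j) else 1.0)
    control = degree_of_control(exposure.female_exposure, joint)

    outcome = SelectionOutcome(
        differential_female_i=df_i,
        differential_male_i=dm_i,
        differential_female_j=df_j,
        differential_male_j=dm_j,
        response_i=total_i,
        response_j=total_j,
        exposed_survival_i=pf_i,
        exposed_survival_j=pf_j,
        degree_of_control=control,
    )
    new_state = PopulationState(
        mean_prs_i=state.mean_prs_i + total_i,
        mean_prs_j=(state.mean_prs_j + total_j) if has_j else None,
        sigma=state.sigma,
    )
    return outcome, new_state
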