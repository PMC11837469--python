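"""Exhaustive single-generation parameter sweeps.

These sweeps cross insecticide efficacy (emulating any point along a decay
curve), exposure and initial resistance, and record the one-generation change
in bioassay survival and the degree of control for monotherapy and mixture
deployments.  They are the "snap-shot" view of the selection process: any
moment of a multi-generation deployment corresponds to one cell.

The sweeps are computed on numpy arrays (no per-cell Python loop) and
returned as tidy pandas DataFrames, one row per parameter combination, in
deterministic lexicographic order of the swept parameters.

Cells where the entire population is exposed and killed (exposure 1, joint
survival 0) leave no parents: the change in survival is recorded as NaN with
degree of control 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .mapping import (
    FieldSurvivalParams,
    ResistanceScale,
    bioassay_to_prs,
    field_survival,
    prs_to_bioassay,
)
from .selection import PopulationState, _tail_density

__all__ = ["GridSpec", "seed_population", "run_mono_grid", "run_mixture_grid"]

# Published PRS seeds for the standard resistance levels.  47 is the rounded
# inverse of 5% (exact 47.368...); using the rounded score keeps seeded
# populations on the operational table.
_PRINTED_PRS = {0.0: 0.0, 5.0: 47.0, 10.0: 100.0, 20.0: 225.0, 50.0: 900.0, 80.0: 3600.0}

_DEFAULT_EFFICACIES = tuple(float(v) for v in np.round(np.arange(0.0, 1.21, 0.1), 10))
_DEFAULT_EXPOSURES = tuple(float(v) for v in np.round(np.arange(0.1, 1.01, 0.1), 10))
_DEFAULT_RESISTANCE = (0.0, 5.0, 10.0, 20.0, 50.0, 80.0)


@dataclass(frozen=True)
class GridSpec:
    """Parameter ranges and fixed constants for a single-generation sweep."""

    efficacy_values: Sequence[float] = _DEFAULT_EFFICACIES
    exposure_values: Sequence[float] = _DEFAULT_EXPOSURES
    resistance_levels: Sequence[float] = _DEFAULT_RESISTANCE
    heritability: float = 0.2
    sigma: float = 20.0
    exposure_scaling: float = 1.0
    mode: Literal["monotherapy", "mixture"] = "monotherapy"
    scale: ResistanceScale = field(default_factory=ResistanceScale)
    field_params: FieldSurvivalParams = field(default_factory=FieldSurvivalParams)

    def __post_init__(self) -> None:
        for name in ("efficacy_values", "exposure_values", "resistance_levels"):
            vals = getattr(self, name)
            if len(vals) == 0:
                raise ValueError(f"{name} must be non-empty")
        if np.any(np.asarray(self.efficacy_values) < 0):
            raise ValueError("efficacy values must be >= 0")
        exp = np.asarray(self.exposure_values)
        if np.any((exp < 0) | (exp > 1)):
            raise ValueError("exposure values must be in [0, 1]")
        res = np.asarray(self.resistance_levels)
        if np.any((res < 0) | (res >= 100)):
            raise ValueError("resistance levels (bioassay %) must be in [0, 100)")
        if not 0 <= self.heritability <= 1:
            raise ValueError("heritability must be in [0, 1]")
        if not self.sigma > 0:
            raise ValueError("sigma must be > 0")
        if self.mode not in ("monotherapy", "mixture"):
            raise ValueError(f"unknown grid mode {self.mode!r}")


def seed_population(
    bioassay_percent: float,
    scale: ResistanceScale = ResistanceScale(),
    sigma: float = 20.0,
) -> PopulationState:
    """Population whose mean PRS gives the requested bioassay survival (%).

    The six standard levels (0, 5, 10, 20, 50, 80%) seed at the published
    scores (0, 47, 100, 225, 900, 3600) when the default scale is used;
    any other level inverts the Hill curve exactly.
    """
    if not 0 <= bioassay_percent < 100:
        raise ValueError("bioassay percent must be in [0, 100)")
    z = _seed_prs(bioassay_percent, scale)
    return PopulationState(mean_prs_i=z, sigma=sigma)


def _seed_prs(bioassay_percent: float, scale: ResistanceScale) -> float:
    if scale == ResistanceScale() and float(bioassay_percent) in _PRINTED_PRS:
        return _PRINTED_PRS[float(bioassay_percent)]
    return bioassay_to_prs(bioassay_percent / 100.0, scale)


def _mono_cells(spec: GridSpec, efficacy, exposure, z):
    """Vectorized monotherapy outcomes for broadcast parameter arrays."""
    k = prs_to_bioassay(z, spec.scale)
    p = field_survival(k, efficacy, spec.field_params)
    denom = (1.0 - exposure) + exposure * p
    degenerate = (exposure == 1.0) & (p == 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        s = exposure * spec.sigma * _tail_density(p) / denom
    s = np.where(p == 0.0, 0.0, s)
    response = spec.heritability * spec.exposure_scaling * s
    delta = 100.0 * (prs_to_bioassay(z + response, spec.scale) - k)
    delta = np.where(degenerate, np.nan, delta)
    control = exposure * (1.0 - p)
    return delta, control, degenerate


def run_mono_grid(spec: GridSpec = GridSpec()) -> pd.DataFrame:
    """Sweep efficacy x exposure x resistance for a single insecticide.

    Returns one row per cell with the change in bioassay survival
    (``delta_bioassay_i``, percentage points) and the degree of control.
    Male and female exposure are equal in the sweep, so a single differential
    serves both sexes.
    """
    if spec.mode != "monotherapy":
        raise ValueError("run_mono_grid requires mode='monotherapy'")
    eff, exp, res = np.meshgrid(
        np.asarray(spec.efficacy_values, dtype=float),
        np.asarray(spec.exposure_values, dtype=float),
        np.asarray(spec.resistance_levels, dtype=float),
        indexing="ij",
    )
    eff, exp, res = eff.ravel(), exp.ravel(), res.ravel()
    z = np.asarray([_seed_prs(r, spec.scale) for r in res])
    delta, control, degenerate = _mono_cells(spec, eff, exp, z)
    return pd.DataFrame(
        {
            "efficacy_i": eff,
            "exposure": exp,
            "resistance_i_percent": res,
            "mean_prs_i": z,
            "delta_bioassay_i": delta,
            "degree_of_control": control,
            "degenerate": degenerate,
        }
    )


def run_mixture_grid(spec: GridSpec) -> pd.DataFrame:
    """Sweep efficacy_i x efficacy_j x exposure x resistance_i x resistance_j
    for a two-insecticide mixture.

    Per-insecticide changes in bioassay survival and their sum (the total
    amount of selection) are recorded alongside the degree of control.
    """
    if spec.mode != "mixture":
        raise ValueError("run_mixture_grid requires mode='mixture'")
    eff_i, eff_j, exp, res_i, res_j = (
        a.ravel()
        for a in np.meshgrid(
            np.asarray(spec.efficacy_values, dtype=float),
            np.asarray(spec.efficacy_values, dtype=float),
            np.asarray(spec.exposure_values, dtype=float),
            np.asarray(spec.resistance_levels, dtype=float),
            np.asarray(spec.resistance_levels, dtype=float),
            indexing="ij",
        )
    )
    seed = {float(r): _seed_prs(r, spec.scale) for r in np.unique(res_i)}
    z_i = np.asarray([seed[r] for r in res_i])
    z_j = np.asarray([seed[r] for r in res_j])
    k_i = prs_to_bioassay(z_i, spec.scale)
    k_j = prs_to_bioassay(z_j, spec.scale)
    p_i = field_survival(k_i, eff_i, spec.field_params)
    p_j = field_survival(k_j, eff_j, spec.field_params)
    joint = p_i * p_j
    degenerate = (exp == 1.0) & (joint == 0.0)
    denom = (1.0 - exp) + exp * joint
    with np.errstate(divide="ignore", invalid="ignore"):
        s_i = exp * spec.sigma * p_j * _tail_density(p_i) / denom
        s_j = exp * spec.sigma * p_i * _tail_density(p_j) / denom
    s_i = np.where(p_i == 0.0, 0.0, s_i)
    s_j = np.where(p_j == 0.0, 0.0, s_j)
    h2b = spec.heritability * spec.exposure_scaling
    delta_i = 100.0 * (prs_to_bioassay(z_i + h2b * s_i, spec.scale) - k_i)
    delta_j = 100.0 * (prs_to_bioassay(z_j + h2b * s_j, spec.scale) - k_j)
    delta_i = np.where(degenerate, np.nan, delta_i)
    delta_j = np.where(degenerate, np.nan, delta_j)
    return pd.DataFrame(
        {
            "efficacy_i": eff_i,
            "efficacy_j": eff_j,
            "exposure": exp,
            "resistance_i_percent": res_i,
            "resistance_j_percent": res_j,
            "delta_bioassay_i": delta_i,
            "delta_bioassay_j": delta_j,
            "delta_total": delta_i + delta_j,
            "degree_of_control": exp * (1.0 - joint),
            "degenerate": degenerate,
        }
    )
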