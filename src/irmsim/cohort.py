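"""Individual-based Monte-Carlo cohort simulator.

Simulates a single cohort of mosquitoes under exactly the statistical
assumptions of the analytic selection model: per-trait resistance scores
drawn from independent normals with fixed standard deviation, Bernoulli
exposure, and deterministic top-fraction (truncation) survival of the
exposed.  The empirical selection differentials and degree of control
converge to the closed-form values as the cohort grows, so this serves as a
brute-force cross-check of the dilution/averaging algebra in
:mod:`irmsim.selection` — and as a seedable synthetic-data generator.

By default the truncation threshold is the *theoretical* normal quantile for
the intended survival fraction, so the comparison isolates the selection
algebra from finite-sample quantile noise; an empirical-quantile mode is
available for end-to-end checks.  Standard errors come from batch means
(independent blocks of the cohort), which is exact here because blocks are
i.i.d.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np
import pandas as pd

from .mapping import FieldSurvivalParams, ResistanceScale, field_survival, prs_to_bioassay
from .selection import Mixture, Monotherapy, _upper_quantile

__all__ = ["CohortSpec", "CohortResult", "simulate_cohort"]


@dataclass(frozen=True)
class CohortSpec:
    """One synthetic cohort: who is exposed and what they must survive."""

    n_individuals: int = 1_000_000
    mean_prs_i: float = 0.0
    mean_prs_j: Optional[float] = None
    sigma: float = 20.0
    exposure: float = 0.7
    deployment: Monotherapy | Mixture = Monotherapy(trait="i", efficacy=1.0)
    seed: int = 0
    threshold_mode: Literal["theoretical", "empirical"] = "theoretical"
    n_blocks: int = 50
    scale: ResistanceScale = field(default_factory=ResistanceScale)
    field_params: FieldSurvivalParams = field(default_factory=FieldSurvivalParams)

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        if not 0 <= self.exposure <= 1:
            raise ValueError("exposure must be in [0, 1]")
        if not self.sigma > 0:
            raise ValueError("sigma must be > 0")
        if isinstance(self.deployment, Mixture) and self.mean_prs_j is None:
            raise ValueError("mixture deployment requires mean_prs_j")
        if self.threshold_mode not in ("theoretical", "empirical"):
            raise ValueError(f"unknown threshold_mode {self.threshold_mode!r}")
        if not 1 <= self.n_blocks <= self.n_individuals:
            raise ValueError("n_blocks must be in [1, n_individuals]")


@dataclass(frozen=True)
class CohortResult:
    """Empirical selection outcome with batch-means standard errors."""

    differential_i: float
    differential_j: float
    se_differential_i: float
    se_differential_j: float
    degree_of_control: float
    se_degree_of_control: float
    exposed_survival_i: float
    exposed_survival_j: float
    n_parents: int
    degenerate: bool


def _intended_survival(spec: CohortSpec) -> tuple[float, float]:
    """Expected field survival per insecticide, from the cohort's mean PRS."""
    dep = spec.deployment
    if isinstance(dep, Monotherapy):
        z = spec.mean_prs_i if dep.trait == "i" else spec.mean_prs_j
        p = field_survival(
            prs_to_bioassay(z, spec.scale), dep.efficacy, spec.field_params
        )
        return (p, 1.0) if dep.trait == "i" else (1.0, p)
    p_i = field_survival(
        prs_to_bioassay(spec.mean_prs_i, spec.scale), dep.efficacy_i, spec.field_params
    )
    p_j = field_survival(
        prs_to_bioassay(spec.mean_prs_j, spec.scale), dep.efficacy_j, spec.field_params
    )
    return p_i, p_j


def _survives(values: np.ndarray, mean: float, sigma: float, p: float, mode: str) -> np.ndarray:
    """Truncation: keep the top-``p`` fraction of the trait distribution."""
    if p >= 1.0:
        return np.ones(values.shape, dtype=bool)
    if p <= 0.0:
        return np.zeros(values.shape, dtype=bool)
    if mode == "theoretical":
        threshold = mean + sigma * _upper_quantile(p)
    else:
        threshold = np.quantile(values, 1.0 - p)
    return values > threshold


def simulate_cohort(spec: CohortSpec) -> CohortResult:
    """Simulate one cohort and measure selection empirically.

    The parental population is the union of unexposed mosquitoes and exposed
    survivors of all deployed insecticides.  The differential per trait is
    the parental mean minus the cohort mean; the degree of control is the
    fraction of the cohort killed.  A fixed seed makes the output
    bit-reproducible.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_individuals
    two_traits = spec.mean_prs_j is not None

    z_i = rng.normal(spec.mean_prs_i, spec.sigma, size=n)
    z_j = rng.normal(spec.mean_prs_j, spec.sigma, size=n) if two_traits else None
    exposed = rng.random(n) < spec.exposure

    p_i, p_j = _intended_survival(spec)
    dep = spec.deployment
    alive = ~exposed
    exp_idx = np.flatnonzero(exposed)
    survivors = exp_idx
    if isinstance(dep, Monotherapy):
        vals = z_i if dep.trait == "i" else z_j
        p = p_i if dep.trait == "i" else p_j
        mean = spec.mean_prs_i if dep.trait == "i" else spec.mean_prs_j
        keep = _survives(vals[survivors], mean, spec.sigma, p, spec.threshold_mode)
        survivors = survivors[keep]
    else:
        # sequential truncation: survive insecticide i, then insecticide j
        keep = _survives(z_i[survivors], spec.mean_prs_i, spec.sigma, p_i, spec.threshold_mode)
        survivors = survivors[keep]
        keep = _survives(z_j[survivors], spec.mean_prs_j, spec.sigma, p_j, spec.threshold_mode)
        survivors = survivors[keep]
    alive[survivors] = True

    n_parents = int(alive.sum())
    if n_parents == 0:
        return CohortResult(
            differential_i=np.nan,
            differential_j=np.nan,
            se_differential_i=np.nan,
            se_differential_j=np.nan,
            degree_of_control=1.0,
            se_degree_of_control=0.0,
            exposed_survival_i=p_i,
            exposed_survival_j=p_j,
            n_parents=0,
            degenerate=True,
        )

    blocks = np.array_split(np.arange(n), spec.n_blocks)

    def _block_stats(values: Optional[np.ndarray]) -> tuple[float, float]:
        if values is None:
            return 0.0, 0.0
        per_block = np.array(
            [values[b][alive[b]].mean() - values[b].mean() for b in blocks]
        )
        est = float(values[alive].mean() - values.mean())
        se = float(per_block.std(ddof=1) / np.sqrt(len(per_block)))
        return est, se

    s_i, se_i = _block_stats(z_i)
    s_j, se_j = _block_stats(z_j)
    killed = 1.0 - n_parents / n
    per_block_kill = np.array([1.0 - alive[b].mean() for b in blocks])
    se_kill = float(per_block_kill.std(ddof=1) / np.sqrt(len(per_block_kill)))

    return CohortResult(
        differential_i=s_i,
        differential_j=s_j,
        se_differential_i=se_i,
        se_differential_j=se_j,
        degree_of_control=killed,
        se_degree_of_control=se_kill,
        exposed_survival_i=p_i,
        exposed_survival_j=p_j,
        n_parents=n_parents,
        degenerate=False,
    )


def cohort_frame(spec: CohortSpec) -> pd.DataFrame:
    """Export the raw simulated cohort (for debugging), one row per mosquito."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_individuals
    data = {"prs_i": rng.normal(spec.mean_prs_i, spec.sigma, size=n)}
    if spec.mean_prs_j is not None:
        data["prs_j"] = rng.normal(spec.mean_prs_j, spec.sigma, size=n)
    data["exposed"] = rng.random(n) < spec.exposure
    return pd.DataFrame(data)
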