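"""Multi-generation resistance-management strategy simulation.

Two demes are tracked: a treated site holding a fraction ``coverage`` of the
population, where the deployed insecticide(s) select for resistance, and
untreated refugia holding the rest, where only fitness costs (default zero)
act.  Each generation the demes exchange migrants: a fraction ``dispersal``
of each deme is replaced by the coverage-weighted pooled population, which
conserves the global mean of each trait exactly.

Two strategies are compared from identical starting conditions:

* **sequence** — one insecticide at a time.  The deployed insecticide is
  monitored in the treated deme; when its bioassay survival reaches the
  withdrawal threshold (default 10%) it is withdrawn and the next available
  insecticide is deployed fresh the following generation.  A withdrawn
  insecticide becomes available again once its survival falls below the
  return threshold (default 8%).  The strategy fails when no insecticide is
  available.
* **mixture** — both insecticides co-deployed (possibly at reduced dose).
  The strategy fails as soon as either component reaches the withdrawal
  threshold.

Deployed insecticides decay between scheduled redeployments (default every
30 generations, the standard bed-net replacement interval), which reset the
efficacy to the deployed dose.  The outcome is the strategy lifespan in
years (10 generations per year), censored at 500 generations (50 years).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace
from typing import Literal, Optional

import numpy as np
import pandas as pd

from .decay import DecayProfile, InsecticideSpec, efficacy_at
from .mapping import field_survival, prs_to_bioassay
from .selection import (
    ExposureConfig,
    Mixture,
    ModelParams,
    Monotherapy,
    PopulationState,
    single_generation_step,
)

__all__ = [
    "StrategyConfig",
    "DeploymentState",
    "StrategyOutcome",
    "disperse",
    "run_strategy",
    "compare_strategies",
    "run_scenario",
    "SCENARIO_DEFAULTS",
]

logger = logging.getLogger(__name__)

BASE_RATE_GRID = (0.005, 0.015, 0.025)
ALPHA_GRID = (-0.3, 0.0, 0.3)
MIXTURE_DOSE_GRID = (1.0, 0.75, 0.5)


@dataclass(frozen=True)
class StrategyConfig:
    """Everything needed for one multi-generation strategy run."""

    strategy: Literal["sequence", "mixture"] = "sequence"
    coverage: float = 0.7
    dispersal: float = 0.2
    female_exposure: float = 0.7
    male_ratio: float = 1.0
    withdrawal_threshold: float = 10.0  # bioassay survival, %
    return_threshold: float = 8.0
    deployment_frequency: int = 30  # generations between redeployments
    max_generations: int = 500
    generations_per_year: int = 10
    insecticide_i: InsecticideSpec = field(default_factory=lambda: InsecticideSpec("i"))
    insecticide_j: InsecticideSpec = field(default_factory=lambda: InsecticideSpec("j"))
    model_params: ModelParams = field(default_factory=ModelParams)
    initial_mean_i: float = 0.0
    initial_mean_j: float = 0.0
    sigma: float = 20.0
    monitor: Literal["treated", "global"] = "treated"
    deployment_order: tuple[str, str] = ("i", "j")
    record_trajectory: bool = True

    def __post_init__(self) -> None:
        if self.strategy not in ("sequence", "mixture"):
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if not self.return_threshold < self.withdrawal_threshold:
            raise ValueError("return_threshold must be below withdrawal_threshold")
        if self.deployment_frequency < 1:
            raise ValueError("deployment_frequency must be >= 1")
        if self.max_generations < 1:
            raise ValueError("max_generations must be >= 1")
        if self.generations_per_year < 1:
            raise ValueError("generations_per_year must be >= 1")
        if sorted(self.deployment_order) != ["i", "j"]:
            raise ValueError("deployment_order must be a permutation of ('i', 'j')")
        if self.monitor not in ("treated", "global"):
            raise ValueError(f"unknown monitor mode {self.monitor!r}")
        ExposureConfig(
            female_exposure=self.female_exposure,
            male_ratio=self.male_ratio,
            coverage=self.coverage,
            dispersal=self.dispersal,
        )


@dataclass
class DeploymentState:
    """What is currently deployed and for how long."""

    deployed: Optional[str] = None  # "i" | "j" | "mixture" | None
    tau: int = 0
    withdrawn: dict = field(default_factory=lambda: {"i": False, "j": False})


@dataclass(frozen=True)
class StrategyOutcome:
    """Result of one strategy run."""

    lifespan_generations: int
    lifespan_years: float
    censored: bool
    termination_reason: str
    trajectory: Optional[pd.DataFrame]


def disperse(
    site_means: tuple[float, float],
    refugia_means: tuple[float, float],
    coverage: float,
    dispersal: float,
) -> tuple[tuple[float, float], tuple[float, float]]:
    """Mix each deme with the coverage-weighted pooled population.

    ``pooled = C * site + (1 - C) * refugia`` per trait; each deme becomes
    ``(1 - theta) * own + theta * pooled``.  The global mean
    ``C * site' + (1 - C) * refugia'`` equals the pre-dispersal pooled mean
    exactly.
    """
    site = np.asarray(site_means, dtype=float)
    ref = np.asarray(refugia_means, dtype=float)
    pooled = coverage * site + (1.0 - coverage) * ref
    new_site = (1.0 - dispersal) * site + dispersal * pooled
    new_ref = (1.0 - dispersal) * ref + dispersal * pooled
    return tuple(new_site), tuple(new_ref)


def _survival_percent(mean_prs: float, params: ModelParams) -> float:
    return 100.0 * prs_to_bioassay(mean_prs, params.scale)


class _Run:
    """Mutable bookkeeping for one strategy simulation."""

    def __init__(self, config: StrategyConfig):
        self.cfg = config
        self.params = config.model_params
        self.exposure = ExposureConfig(
            female_exposure=config.female_exposure,
            male_ratio=config.male_ratio,
            coverage=config.coverage,
            dispersal=config.dispersal,
        )
        self.site = PopulationState(
            config.initial_mean_i, config.initial_mean_j, config.sigma
        )
        self.refugia = PopulationState(
            config.initial_mean_i, config.initial_mean_j, config.sigma
        )
        self.profiles = {
            "i": config.insecticide_i.profile,
            "j": config.insecticide_j.profile,
        }
        self.deployment = DeploymentState()
        self.rows: list[dict] = []

    def monitored_mean(self, trait: str) -> float:
        site = self.site.mean_prs_i if trait == "i" else self.site.mean_prs_j
        if self.cfg.monitor == "treated":
            return site
        ref = self.refugia.mean_prs_i if trait == "i" else self.refugia.mean_prs_j
        return self.cfg.coverage * site + (1.0 - self.cfg.coverage) * ref

    def survival(self, trait: str) -> float:
        return _survival_percent(self.monitored_mean(trait), self.params)

    def update_availability(self) -> None:
        """A withdrawn insecticide returns once below the return threshold."""
        for trait in ("i", "j"):
            if self.deployment.withdrawn[trait] and trait != self.deployment.deployed:
                if self.survival(trait) < self.cfg.return_threshold:
                    self.deployment.withdrawn[trait] = False

    def available(self) -> list[str]:
        return [
            t
            for t in self.cfg.deployment_order
            if not self.deployment.withdrawn[t]
        ]

    def step_generation(self, deployment_arm) -> None:
        """One generation: selection in the site, costs in refugia, dispersal."""
        _, self.site = single_generation_step(
            self.site, deployment_arm, self.exposure, self.params
        )
        refugia_exposure = replace(self.exposure, female_exposure=0.0)
        _, self.refugia = single_generation_step(
            self.refugia, None, refugia_exposure, self.params
        )
        (si, sj), (ri, rj) = disperse(
            (self.site.mean_prs_i, self.site.mean_prs_j),
            (self.refugia.mean_prs_i, self.refugia.mean_prs_j),
            self.cfg.coverage,
            self.cfg.dispersal,
        )
        self.site = PopulationState(si, sj, self.cfg.sigma)
        self.refugia = PopulationState(ri, rj, self.cfg.sigma)

    def record(self, generation: int, eff_i: float, eff_j: float, control: float) -> None:
        if not self.cfg.record_trajectory:
            return
        self.rows.append(
            {
                "generation": generation,
                "deployed": self.deployment.deployed,
                "tau": self.deployment.tau,
                "site_mean_i": self.site.mean_prs_i,
                "site_mean_j": self.site.mean_prs_j,
                "refugia_mean_i": self.refugia.mean_prs_i,
                "refugia_mean_j": self.refugia.mean_prs_j,
                "site_bioassay_i": _survival_percent(self.site.mean_prs_i, self.params),
                "site_bioassay_j": _survival_percent(self.site.mean_prs_j, self.params),
                "efficacy_i": eff_i,
                "efficacy_j": eff_j,
                "degree_of_control": control,
            }
        )

    def outcome(self, generations: int, reason: str, censored: bool) -> StrategyOutcome:
        traj = pd.DataFrame(self.rows) if self.cfg.record_trajectory else None
        return StrategyOutcome(
            lifespan_generations=generations,
            lifespan_years=generations / self.cfg.generations_per_year,
            censored=censored,
            termination_reason=reason,
            trajectory=traj,
        )


def _run_sequence(run: _Run) -> StrategyOutcome:
    cfg = run.cfg
    # initial availability: anything already at/above the withdrawal threshold
    # is not deployable
    for trait in ("i", "j"):
        if run.survival(trait) >= cfg.withdrawal_threshold:
            run.deployment.withdrawn[trait] = True
    avail = run.available()
    if not avail:
        logger.info("gen=0 event=terminate reason='no insecticide available'")
        return run.outcome(0, "no insecticide available", censored=False)
    run.deployment.deployed = avail[0]
    run.deployment.tau = 0
    logger.info("gen=0 event=deploy insecticide=%s", avail[0])

    for gen in range(1, cfg.max_generations + 1):
        trait = run.deployment.deployed
        eff = efficacy_at(run.profiles[trait], run.deployment.tau)
        arm = Monotherapy(trait=trait, efficacy=eff)
        run.step_generation(arm)
        # diagnostic degree of control for the deployed insecticide in the
        # treated deme (not an outcome: no population dynamics behind it)
        p = field_survival(
            prs_to_bioassay(run.site.mean_prs_i if trait == "i" else run.site.mean_prs_j,
                            run.params.scale),
            eff,
            run.params.field_params,
        )
        control = cfg.female_exposure * (1.0 - p)
        run.deployment.tau += 1
        if run.deployment.tau >= cfg.deployment_frequency:
            run.deployment.tau = 0  # scheduled redeployment refreshes efficacy
            logger.debug("gen=%d event=refresh insecticide=%s", gen, trait)
        run.record(gen, eff if trait == "i" else np.nan, eff if trait == "j" else np.nan, control)

        run.update_availability()
        if run.survival(trait) >= cfg.withdrawal_threshold:
            run.deployment.withdrawn[trait] = True
            logger.info(
                "gen=%d event=withdraw insecticide=%s survival=%.2f",
                gen, trait, run.survival(trait),
            )
            run.update_availability()
            avail = run.available()
            if not avail:
                logger.info("gen=%d event=terminate reason='no insecticide available'", gen)
                return run.outcome(gen, "no insecticide available", censored=False)
            run.deployment.deployed = avail[0]
            run.deployment.tau = 0
            logger.info("gen=%d event=deploy insecticide=%s", gen, avail[0])
    return run.outcome(cfg.max_generations, "reached maximum duration", censored=True)


def _run_mixture(run: _Run) -> StrategyOutcome:
    cfg = run.cfg
    for trait in ("i", "j"):
        if run.survival(trait) >= cfg.withdrawal_threshold:
            return run.outcome(0, "no insecticide available", censored=False)
    run.deployment.deployed = "mixture"
    run.deployment.tau = 0

    for gen in range(1, cfg.max_generations + 1):
        eff_i = efficacy_at(run.profiles["i"], run.deployment.tau)
        eff_j = efficacy_at(run.profiles["j"], run.deployment.tau)
        run.step_generation(Mixture(efficacy_i=eff_i, efficacy_j=eff_j))
        p_i = field_survival(
            prs_to_bioassay(run.site.mean_prs_i, run.params.scale), eff_i,
            run.params.field_params,
        )
        p_j = field_survival(
            prs_to_bioassay(run.site.mean_prs_j, run.params.scale), eff_j,
            run.params.field_params,
        )
        control = cfg.female_exposure * (1.0 - p_i * p_j)
        run.deployment.tau += 1
        if run.deployment.tau >= cfg.deployment_frequency:
            run.deployment.tau = 0
        run.record(gen, eff_i, eff_j, control)

        for trait in ("i", "j"):
            if run.survival(trait) >= cfg.withdrawal_threshold:
                logger.info(
                    "gen=%d event=terminate reason='mixture component %s failed'",
                    gen, trait,
                )
                return run.outcome(
                    gen, f"component {trait} reached withdrawal threshold",
                    censored=False,
                )
    return run.outcome(cfg.max_generations, "reached maximum duration", censored=True)


def run_strategy(config: StrategyConfig) -> StrategyOutcome:
    """Run one strategy to failure or to the 500-generation cap."""
    run = _Run(config)
    if config.strategy == "sequence":
        return _run_sequence(run)
    return _run_mixture(run)


def compare_strategies(
    config: StrategyConfig,
    mixture_deployed_efficacy: float = 1.0,
) -> tuple[float, StrategyOutcome, StrategyOutcome]:
    """Mixture vs sequence from identical initial conditions.

    The sequence arm deploys each insecticide at its configured (full) dose;
    the mixture arm deploys both components at ``mixture_deployed_efficacy``
    (1 = full dose, below 1 = reduced-dose mixture).  Decay rates and all
    genetic parameters are shared.  Returns
    ``(difference_years, mixture_outcome, sequence_outcome)`` where the
    difference is mixture minus sequence; censored lifespans enter at the
    cap.
    """
    seq_cfg = replace(config, strategy="sequence")
    mix_cfg = replace(
        config,
        strategy="mixture",
        insecticide_i=InsecticideSpec(
            config.insecticide_i.name,
            config.insecticide_i.profile.with_deployed_efficacy(mixture_deployed_efficacy),
        ),
        insecticide_j=InsecticideSpec(
            config.insecticide_j.name,
            config.insecticide_j.profile.with_deployed_efficacy(mixture_deployed_efficacy),
        ),
    )
    seq = run_strategy(seq_cfg)
    mix = run_strategy(mix_cfg)
    return mix.lifespan_years - seq.lifespan_years, mix, seq


SCENARIO_DEFAULTS = {
    1: {},
    2: {"initial_mean_i": 25.0, "initial_mean_j": 0.0},
    3: {"h2_i": 0.15, "h2_j": 0.25},
}


def _scenario_config(scenario_id: int, overrides: Optional[dict] = None) -> StrategyConfig:
    if scenario_id not in SCENARIO_DEFAULTS:
        raise ValueError(f"unknown scenario {scenario_id!r}; expected 1, 2 or 3")
    cfg = StrategyConfig(record_trajectory=False)
    extra = dict(SCENARIO_DEFAULTS[scenario_id])
    h2_i = extra.pop("h2_i", None)
    h2_j = extra.pop("h2_j", None)
    if h2_i is not None:
        cfg = replace(cfg, model_params=replace(cfg.model_params, h2_i=h2_i, h2_j=h2_j))
    if extra:
        cfg = replace(cfg, **extra)
    if overrides:
        cfg = replace(cfg, **overrides)
    return cfg


def run_scenario(scenario_id: int, overrides: Optional[dict] = None) -> pd.DataFrame:
    """Full factorial strategy comparison for one scenario.

    Crosses the two-stage base decay rate per insecticide
    ``{0.005, 0.015, 0.025}^2``, cross resistance ``{-0.3, 0, 0.3}`` and
    mixture deployed dose ``{1, 0.75, 0.5}`` (81 comparisons), plus a
    no-decay companion set over dose x cross resistance (9 comparisons).
    Returns one row per comparison.
    """
    base = _scenario_config(scenario_id, overrides)
    rows = []

    def _one(decay_mode, rate_i, rate_j, alpha, omega0):
        cfg = replace(
            base,
            model_params=replace(base.model_params, cross_resistance=alpha),
            insecticide_i=InsecticideSpec(
                "i",
                replace(
                    base.insecticide_i.profile,
                    mode=decay_mode,
                    base_rate=rate_i if decay_mode == "two_stage" else base.insecticide_i.profile.base_rate,
                    deployed_efficacy=1.0,
                ),
            ),
            insecticide_j=InsecticideSpec(
                "j",
                replace(
                    base.insecticide_j.profile,
                    mode=decay_mode,
                    base_rate=rate_j if decay_mode == "two_stage" else base.insecticide_j.profile.base_rate,
                    deployed_efficacy=1.0,
                ),
            ),
        )
        diff, mix, seq = compare_strategies(cfg, mixture_deployed_efficacy=omega0)
        rows.append(
            {
                "scenario": scenario_id,
                "decay_mode": decay_mode,
                "base_rate_i": rate_i if decay_mode == "two_stage" else np.nan,
                "base_rate_j": rate_j if decay_mode == "two_stage" else np.nan,
                "cross_resistance": alpha,
                "mixture_deployed_efficacy": omega0,
                "lifespan_mixture_years": mix.lifespan_years,
                "lifespan_sequence_years": seq.lifespan_years,
                "difference_years": diff,
                "mixture_censored": mix.censored,
                "sequence_censored": seq.censored,
                "mixture_termination": mix.termination_reason,
                "sequence_termination": seq.termination_reason,
            }
        )

    for rate_i, rate_j, alpha, omega0 in itertools.product(
        BASE_RATE_GRID, BASE_RATE_GRID, ALPHA_GRID, MIXTURE_DOSE_GRID
    ):
        _one("two_stage", rate_i, rate_j, alpha, omega0)
    for alpha, omega0 in itertools.product(ALPHA_GRID, MIXTURE_DOSE_GRID):
        _one("none", np.nan, np.nan, alpha, omega0)
    return pd.DataFrame(rows)
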