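"""Insecticide efficacy decay after deployment.

Deployed insecticides lose killing efficacy over time through a combination
of chemical decay and physical degradation of the substrate (netting fabric,
sprayed walls).  For long-lasting insecticidal nets this is well described by
a two-stage linear process: a slow base decay rate for the first
``threshold_generation`` generations (default 15, about 1.5 years at 10
mosquito generations per year) followed by rapid decay (default 0.08 efficacy
units per generation) for the remainder of the deployment.  A constant-rate
mode and a no-decay mode (the usual assumption in resistance-management
models) are provided for comparison.

Rates are linear (efficacy units per generation), not proportional, and
efficacy is floored at zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

__all__ = ["DecayProfile", "InsecticideSpec", "efficacy_at"]

DecayMode = Literal["two_stage", "constant", "none"]


@dataclass(frozen=True)
class DecayProfile:
    """Efficacy-over-time profile for one deployed insecticide.

    Parameters
    ----------
    deployed_efficacy : float
        Efficacy at deployment (omega_0).  1 = recommended dose; mixtures
        deployed at reduced dose use 0.75 or 0.5.
    base_rate : float
        Efficacy lost per generation during the initial slow phase (delta_b).
    threshold_generation : int
        Last generation of the slow phase (tau_b); the rapid rate applies
        strictly after it.
    rapid_rate : float
        Efficacy lost per generation in the rapid phase (delta_r).
    mode : {"two_stage", "constant", "none"}
    constant_rate : float
        Per-generation loss in ``constant`` mode.
    """

    deployed_efficacy: float = 1.0
    base_rate: float = 0.015
    threshold_generation: int = 15
    rapid_rate: float = 0.08
    mode: DecayMode = "two_stage"
    constant_rate: float = 0.015

    def __post_init__(self) -> None:
        if self.deployed_efficacy < 0:
            raise ValueError("deployed_efficacy must be >= 0")
        for name in ("base_rate", "rapid_rate", "constant_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.threshold_generation < 0:
            raise ValueError("threshold_generation must be >= 0")
        if self.mode not in ("two_stage", "constant", "none"):
            raise ValueError(f"unknown decay mode {self.mode!r}")

    def with_deployed_efficacy(self, omega0: float) -> "DecayProfile":
        """Same decay dynamics at a different deployment dose."""
        return replace(self, deployed_efficacy=omega0)


@dataclass(frozen=True)
class InsecticideSpec:
    """A named insecticide: its deployment dose and decay profile."""

    name: str = "i"
    profile: DecayProfile = field(default_factory=DecayProfile)


def efficacy_at(profile: DecayProfile, tau):
    """Efficacy ``tau`` whole generations after deployment.

    Two-stage mode:
    ``max(0, omega_0 - delta_b * min(tau, tau_b) - delta_r * max(0, tau - tau_b))``.
    The base rate applies through generation ``tau_b`` inclusive, the rapid
    rate strictly after.  Non-increasing in ``tau``; ``tau = 0`` always
    returns the deployed efficacy.
    """
    tau = np.asarray(tau)
    if np.any(tau < 0):
        raise ValueError("generations since deployment must be >= 0")
    tau = tau.astype(float)
    w0 = profile.deployed_efficacy
    if profile.mode == "none":
        out = np.broadcast_to(np.asarray(w0, dtype=float), tau.shape).copy()
    elif profile.mode == "constant":
        out = np.maximum(0.0, w0 - profile.constant_rate * tau)
    else:
        tb = profile.threshold_generation
        out = np.maximum(
            0.0,
            w0
            - profile.base_rate * np.minimum(tau, tb)
            - profile.rapid_rate * np.maximum(0.0, tau - tb),
        )
    return out if out.ndim else float(out)
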