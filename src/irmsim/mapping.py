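"""Conversions between the polygenic resistance score, bioassay survival and
field survival.

The level of insecticide resistance of a mosquito population is tracked as a
quantitative trait, the polygenic resistance score (PRS).  A PRS is not
directly observable; what is measured operationally is the proportion of a
sample surviving a standardized discriminating-dose bioassay (e.g. the WHO
tube test).  The mapping from PRS to bioassay survival is a saturating
Hill/Michaelis-Menten curve: survival = z**n / (z**n + K**n), with
half-saturation constant ``K`` (PRS units, default 900) and Hill coefficient
``n`` (default 1).  With the defaults, a mean PRS of 900 corresponds to 50%
bioassay survival, 225 to 20%, 3600 to 80%.

Bioassay survival is in turn converted to expected survival of insecticide
contact in the field, which accounts for variable contact durations and for
the current killing efficacy of the deployed insecticide.  At efficacy 1
(recommended dose, kills all fully susceptible mosquitoes in a bioassay) the
relation is the linear regression ``phi1 * k + phi2``; lower efficacies scale
the field mortality down, efficacies above 1 (above recommended dose) scale
it up and can drive susceptible field survival to zero.

All functions accept scalars or numpy arrays and broadcast.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ResistanceScale",
    "FieldSurvivalParams",
    "prs_to_bioassay",
    "bioassay_to_prs",
    "field_survival",
]


@dataclass(frozen=True)
class ResistanceScale:
    """Hill-curve constants linking mean PRS to bioassay survival.

    Parameters
    ----------
    half_saturation : float
        PRS value giving 50% bioassay survival (PRS units, > 0).
    hill_coefficient : float
        Steepness of the saturating curve (dimensionless, > 0).
    """

    half_saturation: float = 900.0
    hill_coefficient: float = 1.0

    def __post_init__(self) -> None:
        if not self.half_saturation > 0:
            raise ValueError(
                f"half_saturation must be > 0, got {self.half_saturation}"
            )
        if not self.hill_coefficient > 0:
            raise ValueError(
                f"hill_coefficient must be > 0, got {self.hill_coefficient}"
            )


@dataclass(frozen=True)
class FieldSurvivalParams:
    """Regression constants converting bioassay survival to field survival.

    ``phi1`` is the slope and ``phi2`` the intercept of the field-survival
    regression at insecticide efficacy 1; ``phi2`` is the field survival of a
    fully susceptible population facing a full-dose insecticide (not every
    contact is lethal in the field).
    """

    phi1: float = 0.48
    phi2: float = 0.15

    def __post_init__(self) -> None:
        if not 0 <= self.phi2 < 1:
            raise ValueError(f"phi2 must be in [0, 1), got {self.phi2}")
        if self.phi1 < 0:
            raise ValueError(f"phi1 must be >= 0, got {self.phi1}")
        if self.phi1 + self.phi2 > 1:
            raise ValueError(
                f"phi1 + phi2 must be <= 1, got {self.phi1 + self.phi2}"
            )


def prs_to_bioassay(z, scale: ResistanceScale = ResistanceScale()):
    """Bioassay survival proportion for a population with mean PRS ``z``.

    Negative scores (a susceptibility reserve) map to 0 survival.  Output is
    strictly within [0, 1): no finite score gives 100% survival.
    """
    z = np.maximum(np.asarray(z, dtype=float), 0.0)
    n = scale.hill_coefficient
    kn = scale.half_saturation**n
    zn = z**n
    out = zn / (zn + kn)
    return out if out.ndim else float(out)


def bioassay_to_prs(k, scale: ResistanceScale = ResistanceScale()):
    """Mean PRS whose bioassay survival is ``k`` (inverse of the Hill curve).

    Raises
    ------
    ValueError
        If ``k`` is outside [0, 1); 100% survival has no finite PRS.
    """
    k = np.asarray(k, dtype=float)
    if np.any((k < 0) | (k >= 1)):
        raise ValueError("bioassay survival must be in [0, 1)")
    out = scale.half_saturation * (k / (1.0 - k)) ** (1.0 / scale.hill_coefficient)
    return out if out.ndim else float(out)


def field_survival(
    k_bioassay,
    efficacy,
    params: FieldSurvivalParams = FieldSurvivalParams(),
):
    """Expected field survival of insecticide contact.

    ``1 - efficacy * (1 - (phi1 * k + phi2))``, clamped to [0, 1].  At
    efficacy 1 this reduces to the bioassay-to-field regression
    ``phi1 * k + phi2``; at efficacy 0 everything survives; efficacies above 1
    represent above-recommended doses and can drive survival to 0.

    Raises
    ------
    ValueError
        If any efficacy is negative.
    """
    k = np.asarray(k_bioassay, dtype=float)
    w = np.asarray(efficacy, dtype=float)
    if np.any(w < 0):
        raise ValueError("insecticide efficacy must be >= 0")
    out = np.clip(1.0 - w * (1.0 - (params.phi1 * k + params.phi2)), 0.0, 1.0)
    return out if out.ndim else float(out)
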