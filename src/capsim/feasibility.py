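"""Physical feasibility calculators for action-potential propagation.

Three back-of-envelope computations that frame the model:

* **Charge-diffusion speed limit.**  Ion channels sit 1.5–5 um apart, and a
  Na+ ion must physically diffuse from one channel to the next for charge
  to carry the threshold.  Using the 1-D mean-squared-displacement relation
  ``t = x^2 / (2 D)`` (the fastest — most conservative — spreading
  estimate), the effective charge speed ``x / t = 2 D / x`` falls orders of
  magnitude short of the ~1 m/s propagation speed, so diffusing charge
  alone cannot be the propagation mechanism.
* **Temporal accuracy.**  The threshold front advances channel-to-channel,
  so the finest temporal grain of membrane computation is
  ``spacing / velocity`` — about 1 us at 1 um and 1 m/s, versus the
  millisecond accuracy of voltage-trajectory models: a ~1000x precision
  gain.
* **Myelinated pulse-wave velocity.**  Inside a myelin sleeve the
  mechanical pulse travels as a pressure wave in an elastic tube, with the
  Moens–Korteweg velocity ``PWV = sqrt(E h / (rho d))``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "FeasibilityParams",
    "PWVParams",
    "FeasibilityReport",
    "diffusion_time",
    "charge_speed_ratio",
    "temporal_accuracy",
    "precision_gain",
    "moens_korteweg_velocity",
    "compute_feasibility_report",
    "NA_DIFFUSION_COEFF_M2_PER_S",
    "NA_IONIC_RADIUS_PM",
]

#: Diffusion coefficient of Na+ in water at 25 degC (handbook value).
NA_DIFFUSION_COEFF_M2_PER_S = 1.33e-9
#: Ionic radius of Na+ (informational).
NA_IONIC_RADIUS_PM = 116.0


@dataclass(frozen=True)
class FeasibilityParams:
    """Inputs for the charge-diffusion speed limit.

    Defaults take the upper end of the measured 1.5–5 um inter-channel
    spacing and a required propagation speed of 1 m/s (the unmyelinated
    maximum).
    """

    channel_spacing_um: float = 5.0
    diffusion_coeff_m2_per_s: float = NA_DIFFUSION_COEFF_M2_PER_S
    required_velocity_m_per_s: float = 1.0
    ionic_radius_pm: float = NA_IONIC_RADIUS_PM

    def __post_init__(self) -> None:
        if self.channel_spacing_um <= 0:
            raise ValueError("channel spacing must be > 0")
        if self.diffusion_coeff_m2_per_s <= 0:
            raise ValueError("diffusion coefficient must be > 0")
        if self.required_velocity_m_per_s <= 0:
            raise ValueError("required velocity must be > 0")


@dataclass(frozen=True)
class PWVParams:
    """Moens–Korteweg inputs: elastic tube wall around an incompressible fluid."""

    elastic_modulus_pa: float
    wall_thickness_m: float
    fluid_density_kg_per_m3: float
    diameter_m: float

    def __post_init__(self) -> None:
        for name in ("elastic_modulus_pa", "wall_thickness_m",
                     "fluid_density_kg_per_m3", "diameter_m"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass(frozen=True)
class FeasibilityReport:
    diffusion_time_s: float
    effective_charge_speed_m_per_s: float
    speed_ratio: float
    temporal_accuracy_s: float
    verdict: str
    params: FeasibilityParams

    def to_dict(self) -> dict:
        return {
            "diffusion_time_s": self.diffusion_time_s,
            "effective_charge_speed_m_per_s": self.effective_charge_speed_m_per_s,
            "speed_ratio": self.speed_ratio,
            "temporal_accuracy_s": self.temporal_accuracy_s,
            "verdict": self.verdict,
            "params": {
                "channel_spacing_um": self.params.channel_spacing_um,
                "diffusion_coeff_m2_per_s": self.params.diffusion_coeff_m2_per_s,
                "required_velocity_m_per_s": self.params.required_velocity_m_per_s,
                "ionic_radius_pm": self.params.ionic_radius_pm,
            },
        }


def diffusion_time(x_um: float, d_m2_per_s: float) -> float:
    """Time for charge to spread a distance ``x_um`` by 1-D diffusion,
    ``t = x^2 / (2 D)``."""
    if x_um < 0:
        raise ValueError("distance must be >= 0")
    if d_m2_per_s <= 0:
        raise ValueError("diffusion coefficient must be > 0")
    x_m = x_um * 1e-6
    return x_m * x_m / (2.0 * d_m2_per_s)


def charge_speed_ratio(p: FeasibilityParams) -> float:
    """Effective diffusive charge speed over required propagation speed.

    ``x / t(x) = 2 D / x``; a ratio below 1 means diffusing charge cannot
    keep up with the front.
    """
    t = diffusion_time(p.channel_spacing_um, p.diffusion_coeff_m2_per_s)
    effective = (p.channel_spacing_um * 1e-6) / t
    return effective / p.required_velocity_m_per_s


def temporal_accuracy(x_um: float, v_m_per_s: float) -> float:
    """Channel spacing over conduction velocity: the finest phase grain."""
    if x_um < 0:
        raise ValueError("spacing must be >= 0")
    if v_m_per_s <= 0:
        raise ValueError("velocity must be > 0")
    return x_um * 1e-6 / v_m_per_s


def precision_gain(coarse_accuracy_s: float, fine_accuracy_s: float) -> float:
    """Factor by which the finer temporal accuracy improves on the coarser."""
    if coarse_accuracy_s <= 0 or fine_accuracy_s <= 0:
        raise ValueError("accuracies must be > 0")
    return coarse_accuracy_s / fine_accuracy_s


def moens_korteweg_velocity(p: PWVParams) -> float:
    """Pulse-wave velocity in an elastic tube, ``sqrt(E h / (rho d))``."""
    return math.sqrt(
        p.elastic_modulus_pa * p.wall_thickness_m
        / (p.fluid_density_kg_per_m3 * p.diameter_m)
    )


def compute_feasibility_report(
    p: FeasibilityParams | None = None,
) -> FeasibilityReport:
    p = p or FeasibilityParams()
    t_diff = diffusion_time(p.channel_spacing_um, p.diffusion_coeff_m2_per_s)
    ratio = charge_speed_ratio(p)
    effective = ratio * p.required_velocity_m_per_s
    verdict = "insufficient" if ratio < 1.0 else "sufficient"
    return FeasibilityReport(
        diffusion_time_s=t_diff,
        effective_charge_speed_m_per_s=effective,
        speed_ratio=ratio,
        temporal_accuracy_s=temporal_accuracy(
            p.channel_spacing_um, p.required_velocity_m_per_s
        ),
        verdict=verdict,
        params=p,
    )
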