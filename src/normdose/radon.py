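"""Radon physics chain: exhalation, indoor accumulation and dose.

Four linked pieces:

1. **Diffusive exhalation from a thick layer** (extended-source model).
   Radon produced by Ra-226 decay inside the grains emanates into the
   pore space with probability E(Θ) and diffuses to the surface.  For a
   layer much thicker than the diffusion length (> 3 m of nodules) the
   surface flux is

       P = C_Ra-226 × E(Θ) × ρ × sqrt(D_bulk / λ) × λ      [Bq/(m²·s)]

   with D_bulk = D_MA × R_por, the molecular diffusion coefficient of
   radon in air (1e-5 m²/s) scaled by the bulk porosity.

2. **Comminution source term.**  A fraction f_com of the radon inventory
   stored in the pore space is released when the material is crushed:
   R = C_Ra-226 × f_com × pc for processing capacity pc [kg/s].

3. **Indoor mass balance.**  The indoor concentration obeys
   dC/dt = e′ + v·C_a − (λ + v)·C, with volume-specific entry rate
   e′ = P·A/V (surface exhalation) or e′ = R·f_indoor/V (comminution),
   ventilation rate v [1/s] and decay constant λ.  The steady state is
   C = e′/(λ + v) when outdoor radon is neglected; the transient solution
   is an exponential relaxation toward it and is evaluated in closed form.

4. **Dose.**  E = C_Rn × t_exp × F × DCF with equilibrium factor F
   (default 0.4) subsuming all radon-progeny behaviour, and the
   ICRP-65-consistent dose conversion factor 7.8e-6 mSv·m³/(Bq·h).

No multi-zone ventilation, progeny attachment/plate-out, or
moisture-dependent emanation curve is modelled; wet material requires a
user-supplied emanation factor (exhalation from water-saturated nodules
is about half the dry value).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .inventory import NuclideVector

#: Rn-222 decay constant [1/s] as used in the reference calculations
#: (the textbook value is 2.0993e-6; results are reported with 2.1e-6).
LAMBDA_RN222 = 2.1e-6

#: Molecular diffusion coefficient of radon in air [m²/s].
D_MOLECULAR_AIR = 1.0e-5

#: ICRP-65-consistent radon dose conversion factor [mSv·m³/(Bq·h)],
#: applied together with an explicit equilibrium factor.
DCF_RADON_ICRP65 = 7.8e-6

#: ICRP-137 alternative (~2x the ICRP-65 value; not yet adopted in the
#: regulations this assessment follows, therefore never the default).
DCF_RADON_ICRP137 = 1.6e-5

#: Default emanation factor of dry nodules.
EMANATION_DRY_DEFAULT = 0.36


@dataclass
class RadonMaterialProps:
    """Material properties controlling diffusive radon exhalation."""

    c_ra226: float                      # Ra-226 specific activity [Bq/kg]
    emanation: float = EMANATION_DRY_DEFAULT   # E(Θ), moisture dependent
    bulk_density: float = 3300.0        # ρ [kg/m³]
    porosity: float = 0.6               # R_por, bulk pore fraction
    d_ma: float = D_MOLECULAR_AIR       # molecular diffusion coeff. [m²/s]

    def __post_init__(self) -> None:
        if self.c_ra226 < 0:
            raise ValidationError(f"c_ra226 must be >= 0, got {self.c_ra226}")
        if not 0.0 <= self.emanation <= 1.0:
            raise ValidationError(f"emanation must be in [0, 1], got {self.emanation}")
        if not 0.0 < self.porosity <= 1.0:
            raise ValidationError(f"porosity must be in (0, 1], got {self.porosity}")
        if self.bulk_density <= 0 or self.d_ma <= 0:
            raise ValidationError("bulk density and diffusion coefficient must be > 0")

    @property
    def d_bulk(self) -> float:
        """Bulk diffusion coefficient D_bulk = D_MA × porosity [m²/s]."""
        return self.d_ma * self.porosity


@dataclass
class RadonEnvironment:
    """Enclosure geometry and ventilation for the indoor radon balance.

    ``exhaling_area`` is the effective area from which radon reaches the
    air volume; for a cargo hold this is the footprint of the nodule
    surface (only the top of the pile feeds the head space when diffusion
    is the sole transport mechanism in the voids below).
    """

    volume: float                       # V [m³]
    exhaling_area: float                # A [m²]
    ventilation_rate: float             # v [1/s]
    outdoor_concentration: float = 0.0  # C_a [Bq/m³]
    lambda_rn: float = LAMBDA_RN222     # λ [1/s]

    def __post_init__(self) -> None:
        if self.volume <= 0 or self.exhaling_area < 0:
            raise ValidationError("volume must be > 0 and area >= 0")
        if self.ventilation_rate < 0 or self.outdoor_concentration < 0:
            raise ValidationError("ventilation rate and outdoor concentration must be >= 0")
        if self.lambda_rn <= 0:
            raise ValidationError(f"decay constant must be > 0, got {self.lambda_rn}")


@dataclass
class ComminutionSource:
    """Radon release at crushing/milling of the material."""

    pc_kg_s: float                      # processing capacity [kg/s]
    f_com: float = 0.3                  # released fraction at comminution
    f_indoor: float = 0.5               # fraction released into the hall

    def __post_init__(self) -> None:
        if self.pc_kg_s <= 0:
            raise ValidationError(f"processing capacity must be > 0, got {self.pc_kg_s}")
        for name in ("f_com", "f_indoor"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1]")


@dataclass
class RadonDoseConfig:
    """Inputs of the radon dose formula E = C × t × F × DCF."""

    c_rn_bq_m3: float
    t_exp_h: float
    equilibrium_factor: float = 0.4
    dcf: float = DCF_RADON_ICRP65       # [mSv·m³/(Bq·h)]

    def __post_init__(self) -> None:
        for name in ("c_rn_bq_m3", "t_exp_h", "dcf"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if not 0.0 <= self.equilibrium_factor <= 1.0:
            raise ValidationError(
                f"equilibrium factor must be in [0, 1], got {self.equilibrium_factor}"
            )


def exhalation_rate(material: RadonMaterialProps, lambda_rn: float = LAMBDA_RN222) -> float:
    """Radon surface flux P [Bq/(m²·s)] of a thick layer of material.

    Valid for layers thicker than a few diffusion lengths (> 3 m of
    nodules); the caller is responsible for that geometric assumption.
    Scales with sqrt(D_bulk): quadrupling the diffusion coefficient
    doubles the flux.
    """
    if lambda_rn <= 0:
        raise ValidationError(f"decay constant must be > 0, got {lambda_rn}")
    return (
        material.c_ra226
        * material.emanation
        * material.bulk_density
        * math.sqrt(material.d_bulk / lambda_rn)
        * lambda_rn
    )


def entry_rate_surface(exhalation: float, env: RadonEnvironment) -> float:
    """Volume-specific radon entry rate e′ = P·A/V [Bq/(m³·s)]."""
    if exhalation < 0:
        raise ValidationError(f"exhalation rate must be >= 0, got {exhalation}")
    return exhalation * env.exhaling_area / env.volume


def entry_rate_comminution(
    vector: NuclideVector, source: ComminutionSource, env: RadonEnvironment
) -> tuple[float, float]:
    """Radon source term and indoor entry rate from crushing the material.

    Returns ``(R_source, e_prime)`` with R = C_Ra-226 × f_com × pc in
    Bq/s and e′ = R × f_indoor / V in Bq/(m³·s).
    """
    r_source = vector.ra226 * source.f_com * source.pc_kg_s
    e_prime = r_source * source.f_indoor / env.volume
    return r_source, e_prime


def steady_state_concentration(e_prime: float, env: RadonEnvironment) -> float:
    """Steady-state indoor radon concentration [Bq/m³].

    C = (e′ + v·C_a) / (λ + v); the outdoor term vanishes with the
    default C_a = 0.  Strictly decreasing in the ventilation rate; with
    v = 0 the maximum accumulation e′/λ is reached.
    """
    sink = env.lambda_rn + env.ventilation_rate
    if sink <= 0:
        raise ValidationError("no sink: lambda + ventilation rate must be > 0")
    return (e_prime + env.ventilation_rate * env.outdoor_concentration) / sink


def transient_concentration(
    e_prime: float,
    env: RadonEnvironment,
    c0: float,
    t_s: float | np.ndarray,
) -> float | np.ndarray:
    """Indoor radon concentration C(t) [Bq/m³] from initial value ``c0``.

    Closed-form solution of dC/dt = e′ + v·C_a − (λ + v)·C:

        C(t) = C_∞ + (c0 − C_∞) · exp(−(λ + v)·t)

    relaxing toward the steady state C_∞ with rate λ + v.  Accepts a
    scalar time or an array of times [s].
    """
    t = np.asarray(t_s, dtype=float)
    if np.any(t < 0):
        raise ValidationError("time must be >= 0")
    if c0 < 0:
        raise ValidationError(f"initial concentration must be >= 0, got {c0}")
    k = env.lambda_rn + env.ventilation_rate
    c_inf = steady_state_concentration(e_prime, env)
    result = c_inf + (c0 - c_inf) * np.exp(-k * t)
    return float(result) if np.isscalar(t_s) else result


def radon_dose(config: RadonDoseConfig) -> float:
    """Effective dose [mSv/a] from radon (and progeny, via F) inhalation."""
    return (
        config.c_rn_bq_m3
        * config.t_exp_h
        * config.equilibrium_factor
        * config.dcf
    )
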