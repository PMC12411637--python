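"""Internal exposure from inhalation of radioactive dust.

The committed effective dose from breathing dust-laden air is

    E = V̇ × t_exp × Σ_i g_inh,i × C_air,i
    C_air,i = C_dust × C_i × (1 − f_inh)

with V̇ the breathing rate (default 1.2 m³/h for light work), C_dust the
airborne dust concentration [mg/m³], C_i the specific activity of nuclide
i in the dust [Bq/mg after conversion] and f_inh the fraction of dust
removed by respiratory protection (0 = no mask; an FFP-2 mask removes up
to 94%).  The dust is assumed to carry the bulk material's nuclide
vector — no size-fraction enrichment, aerosol physics or lung-deposition
modelling beyond the fixed AMAD-5 µm coefficient table.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ValidationError
from .inventory import DoseCoefficients, NuclideVector, unit_dust_dose
from .units import bq_per_kg_to_bq_per_mg, usv_to_msv

#: Maximum allowable concentration of alveolar (A-)dust for routine work
#: areas [mg/m³] (German Technical Rules for Hazardous Substances).
MAC_A_DUST_ROUTINE = 1.25

#: Maximum shift-average A-dust concentration for workplaces with
#: occasional exposure, e.g. filter maintenance [mg/m³].
MAC_A_DUST_OCCASIONAL = 3.0

#: Default occupational breathing rate [m³/h].
BREATHING_RATE_DEFAULT = 1.2


@dataclass
class DustExposureConfig:
    """Workplace dust exposure parameters for one pathway."""

    c_dust_mg_m3: float
    t_exp_h: float
    breathing_rate_m3_h: float = BREATHING_RATE_DEFAULT
    f_inh: float = 0.0

    def __post_init__(self) -> None:
        for name in ("c_dust_mg_m3", "t_exp_h", "breathing_rate_m3_h"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0, got {getattr(self, name)}")
        if not 0.0 <= self.f_inh <= 1.0:
            raise ValidationError(f"f_inh must be in [0, 1], got {self.f_inh}")


@dataclass
class AirborneActivity:
    """Per-nuclide activity concentration in breathed air [Bq/m³]."""

    entries: dict[str, float]

    def __post_init__(self) -> None:
        for nuclide, c in self.entries.items():
            if c < 0:
                raise ValidationError(
                    f"airborne concentration must be >= 0 for {nuclide}: {c}"
                )


def airborne_activity(
    vector: NuclideVector, config: DustExposureConfig
) -> AirborneActivity:
    """Activity concentrations C_air,i [Bq/m³] of dust-borne nuclides."""
    reduction = 1.0 - config.f_inh
    return AirborneActivity(
        {
            nuclide: config.c_dust_mg_m3 * bq_per_kg_to_bq_per_mg(activity) * reduction
            for nuclide, activity in vector.items()
        }
    )


def dust_dose(
    vector: NuclideVector,
    coefficients: DoseCoefficients,
    config: DustExposureConfig,
) -> float:
    """Annual committed effective dose from dust inhalation [mSv/a].

    Factorizes exactly as V̇ × t × C_dust × (1 − f_inh) × unit dust dose,
    since every term is linear in the activities.
    """
    inhaled_dust_mg = config.breathing_rate_m3_h * config.t_exp_h * config.c_dust_mg_m3
    dose_usv = inhaled_dust_mg * (1.0 - config.f_inh) * unit_dust_dose(
        vector, coefficients
    )
    return usv_to_msv(dose_usv)
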