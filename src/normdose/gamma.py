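"""External gamma exposure from stored or handled material.

The ambient dose equivalent rate H*(10) next to bulk NORM is, for simple
geometries, proportional to the Ra-226 specific activity (Ra-226 standing
proxy for its short-lived gamma emitters Pb-214/Bi-214, with which it is
largely in secular equilibrium):

    H*(10) [µSv/h] = ADR × C_Ra-226 [Bq/g]

with ADR a tabulated geometry factor in µSv/h per Bq/g.  The effective
dose then follows as

    E = f_con × Σ_s H*(10)_s × t_exp,s × a_s

where f_con (default 0.6) converts the operational quantity H*(10) to
effective dose, t_exp is the annual exposure time and a_s ∈ [0, 1] is the
transmitted fraction after shielding (a_s = 1 means no shielding).

Gamma from the Th-232 series and from airborne radon progeny is neglected
(both are negligible for this material).  The geometry factors are data,
not computed: no photon transport is modelled beyond an inverse-square
helper for distances larger than the lateral source dimensions.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

import pandas as pd

from .errors import ValidationError
from .inventory import NuclideVector
from .units import bq_per_kg_to_bq_per_g, usv_to_msv


@dataclass(frozen=True)
class GeometryFactor:
    """Proportionality between Ra-226 specific activity and H*(10).

    ``adr_per_bq_g`` is in µSv/h per Bq/g Ra-226; ``distance_note``
    records whether the factor applies at the surface or at 1 m.
    """

    label: str
    adr_per_bq_g: float
    distance_note: str = "at surface"

    def __post_init__(self) -> None:
        if self.adr_per_bq_g < 0:
            raise ValidationError(
                f"ADR factor must be >= 0, got {self.adr_per_bq_g}"
            )


def load_geometry_factors(source: str | Path | None = None) -> pd.DataFrame:
    """The packaged geometry table (storage scenario -> ADR factor).

    Columns: ``label``, ``adr_surface_uSv_h_per_Bq_g``,
    ``adr_1m_uSv_h_per_Bq_g``.
    """
    if source is None:
        source = resources.files("normdose.data").joinpath("geometry_factors.csv")
    return pd.read_csv(source)


def geometry_factor(label: str, distance: str = "surface") -> GeometryFactor:
    """Look up a packaged storage geometry (``distance``: "surface" or "1m")."""
    table = load_geometry_factors()
    row = table[table["label"] == label]
    if row.empty:
        known = ", ".join(table["label"])
        raise ValidationError(f"unknown geometry {label!r}; known: {known}")
    if distance not in ("surface", "1m"):
        raise ValidationError(f"distance must be 'surface' or '1m', got {distance!r}")
    column = "adr_surface_uSv_h_per_Bq_g" if distance == "surface" else "adr_1m_uSv_h_per_Bq_g"
    note = "at surface" if distance == "surface" else "at 1 m"
    return GeometryFactor(label, float(row.iloc[0][column]), note)


def inverse_square_adr(adr_at_reference: float, distance_m: float,
                       reference_m: float = 1.0) -> float:
    """Scale an ADR factor to a larger distance by the inverse-square law.

    Valid only when the distance is of the order of, or larger than, the
    lateral dimensions of the source; closer in, the tabulated factors
    apply directly.
    """
    if distance_m <= 0 or reference_m <= 0:
        raise ValidationError("distances must be positive")
    return adr_at_reference * (reference_m / distance_m) ** 2


def ambient_dose_rate(vector: NuclideVector, geometry: GeometryFactor) -> float:
    """H*(10) [µSv/h] next to material with the given nuclide vector.

    Requires Ra-226 in the vector (it drives the gamma field).
    """
    c_ra226_bq_g = bq_per_kg_to_bq_per_g(vector.ra226)
    return geometry.adr_per_bq_g * c_ra226_bq_g


@dataclass
class GammaExposureConfig:
    """One gamma exposure source: geometry, time, shielding, conversion.

    ``shielding`` is the *transmitted* fraction a_s (0.5 means the
    barrier removes half of the dose rate; 1.0 means unshielded).
    """

    geometry: GeometryFactor
    t_exp_h: float
    shielding: float = 1.0
    f_con: float = 0.6

    def __post_init__(self) -> None:
        if self.t_exp_h < 0:
            raise ValidationError(f"exposure time must be >= 0, got {self.t_exp_h}")
        if not 0.0 <= self.shielding <= 1.0:
            raise ValidationError(
                f"shielding (transmitted fraction) must be in [0, 1], got {self.shielding}"
            )
        if not 0.0 < self.f_con <= 1.0:
            raise ValidationError(f"f_con must be in (0, 1], got {self.f_con}")


def gamma_dose(
    config: GammaExposureConfig | Sequence[GammaExposureConfig],
    vector: NuclideVector | Sequence[NuclideVector],
) -> float:
    """Annual effective dose [mSv/a] from one or several gamma sources.

    When sequences are given they are paired element-wise (one material
    per source) and the contributions are summed.
    """
    if isinstance(config, GammaExposureConfig):
        configs = [config]
        vectors = [vector]
    else:
        configs = list(config)
        vectors = list(vector)
        if len(configs) != len(vectors):
            raise ValidationError(
                f"{len(configs)} sources but {len(vectors)} material vectors"
            )
    total_usv = 0.0
    for cfg, vec in zip(configs, vectors):
        h10 = ambient_dose_rate(vec, cfg.geometry)
        total_usv += cfg.f_con * h10 * cfg.t_exp_h * cfg.shielding
    return usv_to_msv(total_usv)
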