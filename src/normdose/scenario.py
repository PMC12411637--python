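"""Compose exposure pathways into named occupational scenarios.

A scenario bundles gamma, dust and (optionally) radon pathway
configurations, each bound to a material, and evaluates the total annual
effective dose

    E = E_gamma + E_dust + E_radon        (ingestion excluded)

The ingestion pathway is excluded by construction, assuming compliance
with standard occupational hygiene.  The radon contribution is reported
separately from the gamma+dust subtotal because its concentration input
depends on facility design and ventilation rather than on the material
vector; the ×3 surface-layer sensitivity multiplier therefore scales the
gamma and dust pathways (which are linear in the specific activities)
while leaving a fixed radon concentration untouched.

Scenario files are TOML; the two reference scenarios (transport vessel,
processing plant) are packaged as fixtures.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Mapping

import pandas as pd

from .dust import DustExposureConfig, dust_dose
from .errors import ValidationError
from .gamma import GammaExposureConfig, GeometryFactor, gamma_dose, geometry_factor
from .inventory import DoseCoefficients, NuclideVector, load_dose_coefficients, load_materials
from .radon import RadonDoseConfig, radon_dose

#: Annual effective dose above which a worker must be classified as
#: occupationally exposed [mSv/a].
OCCUPATIONAL_THRESHOLD_MSV = 1.0

#: Annual dose limit for occupationally exposed workers [mSv/a].
OCCUPATIONAL_LIMIT_MSV = 20.0


@dataclass
class GammaPathwaySpec:
    """A gamma exposure source bound to a named material."""

    material: str
    geometry: GeometryFactor
    t_exp_h: float
    shielding: float = 1.0
    f_con: float = 0.6
    label: str = ""

    def exposure_config(self) -> GammaExposureConfig:
        return GammaExposureConfig(
            geometry=self.geometry,
            t_exp_h=self.t_exp_h,
            shielding=self.shielding,
            f_con=self.f_con,
        )


@dataclass
class DustPathwaySpec:
    """A dust inhalation pathway bound to a named material."""

    material: str
    c_dust_mg_m3: float
    t_exp_h: float
    breathing_rate_m3_h: float = 1.2
    f_inh: float = 0.0
    label: str = ""

    def exposure_config(self) -> DustExposureConfig:
        return DustExposureConfig(
            c_dust_mg_m3=self.c_dust_mg_m3,
            t_exp_h=self.t_exp_h,
            breathing_rate_m3_h=self.breathing_rate_m3_h,
            f_inh=self.f_inh,
        )


@dataclass
class Scenario:
    """A named exposure scenario: pathways plus sensitivity settings."""

    label: str
    gamma: list[GammaPathwaySpec] = field(default_factory=list)
    dust: list[DustPathwaySpec] = field(default_factory=list)
    radon: RadonDoseConfig | None = None
    surface_multiplier: float = 1.0

    def __post_init__(self) -> None:
        if not self.gamma and not self.dust and self.radon is None:
            raise ValidationError("scenario must define at least one pathway")
        if self.surface_multiplier < 1.0:
            raise ValidationError(
                f"surface multiplier must be >= 1, got {self.surface_multiplier}"
            )

    def with_multiplier(self, multiplier: float) -> "Scenario":
        return replace(self, surface_multiplier=multiplier)


@dataclass
class PathwayDose:
    label: str
    kind: str       # "gamma" | "dust" | "radon"
    dose_msv: float


@dataclass
class DoseReport:
    """Per-pathway and total annual effective doses [mSv/a].

    Raw values are kept at full precision; rounding to reporting
    precision happens only in :meth:`to_frame` / :meth:`format`.
    """

    scenario_label: str
    pathways: list[PathwayDose]

    @property
    def subtotal_excl_radon_msv(self) -> float:
        return sum(p.dose_msv for p in self.pathways if p.kind != "radon")

    @property
    def radon_msv(self) -> float:
        return sum(p.dose_msv for p in self.pathways if p.kind == "radon")

    @property
    def total_msv(self) -> float:
        return sum(p.dose_msv for p in self.pathways)

    @property
    def occupationally_exposed(self) -> bool:
        return self.total_msv >= OCCUPATIONAL_THRESHOLD_MSV

    @property
    def exceeds_limit(self) -> bool:
        return self.total_msv >= OCCUPATIONAL_LIMIT_MSV

    def to_frame(self, sig_figs: int = 2) -> pd.DataFrame:
        rows = [
            {"pathway": p.label, "kind": p.kind,
             "dose_mSv_a": _round_sig(p.dose_msv, sig_figs)}
            for p in self.pathways
        ]
        return pd.DataFrame(rows, columns=["pathway", "kind", "dose_mSv_a"])

    def format(self) -> str:
        lines = [f"Scenario: {self.scenario_label}"]
        width = max((len(p.label) for p in self.pathways), default=10)
        for p in self.pathways:
            lines.append(f"  {p.label:<{width}}  [{p.kind:>5}]  "
                         f"{_round_sig(p.dose_msv, 2):g} mSv/a")
        lines.append(f"  subtotal (gamma + dust): {_round_sig(self.subtotal_excl_radon_msv, 2):g} mSv/a")
        if self.radon_msv:
            lines.append(f"  radon:                   {_round_sig(self.radon_msv, 3):g} mSv/a")
        lines.append(f"  total:                   {_round_sig(self.total_msv, 2):g} mSv/a")
        c = classify(self)
        lines.append(
            "  classification: "
            + ("occupationally exposed" if c.occupationally_exposed else "below 1 mSv/a benchmark")
            + (", EXCEEDS 20 mSv/a LIMIT" if c.exceeds_limit else "")
        )
        return "\n".join(lines)


@dataclass(frozen=True)
class Classification:
    total_msv: float
    occupationally_exposed: bool   # total >= 1 mSv/a
    exceeds_limit: bool            # total >= 20 mSv/a


def classify(report: DoseReport) -> Classification:
    """Assess a dose report against the occupational benchmarks.

    Workers above 1 mSv/a must be classified as occupationally exposed
    (medical surveillance applies); 20 mSv/a is the annual limit for
    occupationally exposed workers.
    """
    total = report.total_msv
    return Classification(
        total_msv=total,
        occupationally_exposed=total >= OCCUPATIONAL_THRESHOLD_MSV,
        exceeds_limit=total >= OCCUPATIONAL_LIMIT_MSV,
    )


def _round_sig(value: float, sig_figs: int) -> float:
    if value == 0:
        return 0.0
    from math import floor, log10

    return round(value, -int(floor(log10(abs(value)))) + sig_figs - 1)


def run_scenario(
    scenario: Scenario,
    materials: Mapping[str, NuclideVector] | None = None,
    coefficients: DoseCoefficients | None = None,
) -> DoseReport:
    """Evaluate every pathway of a scenario and sum the effective doses.

    ``materials`` maps material labels to nuclide vectors; the packaged
    fixtures are used when omitted.  The surface multiplier scales every
    material vector before the (linear) gamma and dust pathways are
    evaluated.
    """
    if materials is None:
        materials = load_materials()
    if coefficients is None:
        coefficients = load_dose_coefficients()

    def resolve(name: str) -> NuclideVector:
        if name not in materials:
            raise ValidationError(
                f"scenario {scenario.label!r} references unknown material {name!r}; "
                f"available: {sorted(materials)}"
            )
        return materials[name].scaled(scenario.surface_multiplier)

    pathways: list[PathwayDose] = []
    for i, spec in enumerate(scenario.gamma):
        dose = gamma_dose(spec.exposure_config(), resolve(spec.material))
        pathways.append(
            PathwayDose(spec.label or f"gamma[{i}] {spec.material}", "gamma", dose)
        )
    for i, spec in enumerate(scenario.dust):
        dose = dust_dose(resolve(spec.material), coefficients, spec.exposure_config())
        pathways.append(
            PathwayDose(spec.label or f"dust[{i}] {spec.material}", "dust", dose)
        )
    if scenario.radon is not None:
        pathways.append(PathwayDose("radon", "radon", radon_dose(scenario.radon)))
    return DoseReport(scenario_label=scenario.label, pathways=pathways)


# -- scenario files -------------------------------------------------------

FIXTURE_SCENARIOS = ("transport", "processing_plant")


def list_fixture_scenarios() -> tuple[str, ...]:
    return FIXTURE_SCENARIOS


def _parse_gamma_block(block: dict) -> GammaPathwaySpec:
    if "adr_factor" in block:
        geom = GeometryFactor(
            label=block.get("geometry", "custom"),
            adr_per_bq_g=float(block["adr_factor"]),
            distance_note=block.get("distance", "custom"),
        )
    elif "geometry" in block:
        geom = geometry_factor(block["geometry"], block.get("distance", "surface"))
    else:
        raise ValidationError(
            f"gamma pathway needs 'geometry' or 'adr_factor': {block}"
        )
    return GammaPathwaySpec(
        material=block["material"],
        geometry=geom,
        t_exp_h=float(block["t_exp_h"]),
        shielding=float(block.get("shielding", 1.0)),
        f_con=float(block.get("f_con", 0.6)),
        label=block.get("label", ""),
    )


def _parse_dust_block(block: dict) -> DustPathwaySpec:
    return DustPathwaySpec(
        material=block["material"],
        c_dust_mg_m3=float(block["c_dust_mg_m3"]),
        t_exp_h=float(block["t_exp_h"]),
        breathing_rate_m3_h=float(block.get("breathing_rate_m3_h", 1.2)),
        f_inh=float(block.get("f_inh", 0.0)),
        label=block.get("label", ""),
    )


def load_scenario(source: str | Path) -> Scenario:
    """Load a scenario from a TOML file or packaged fixture name."""
    name = str(source)
    if name in FIXTURE_SCENARIOS:
        path = resources.files("normdose.data").joinpath(f"scenarios/{name}.toml")
        raw = path.read_bytes()
    else:
        raw = Path(source).read_bytes()
    try:
        doc = tomllib.loads(raw.decode("utf-8"))
    except tomllib.TOMLDecodeError as exc:
        raise ValidationError(f"invalid scenario file {source}: {exc}") from exc

    try:
        radon_cfg = None
        if "radon" in doc:
            rb = doc["radon"]
            radon_cfg = RadonDoseConfig(
                c_rn_bq_m3=float(rb["concentration_bq_m3"]),
                t_exp_h=float(rb["t_exp_h"]),
                equilibrium_factor=float(rb.get("equilibrium_factor", 0.4)),
                dcf=float(rb.get("dcf", RadonDoseConfig.__dataclass_fields__["dcf"].default)),
            )
        return Scenario(
            label=doc.get("label", Path(str(source)).stem),
            gamma=[_parse_gamma_block(b) for b in doc.get("gamma", [])],
            dust=[_parse_dust_block(b) for b in doc.get("dust", [])],
            radon=radon_cfg,
            surface_multiplier=float(doc.get("surface_multiplier", 1.0)),
        )
    except KeyError as exc:
        raise ValidationError(f"scenario file {source} is missing key {exc}") from exc
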