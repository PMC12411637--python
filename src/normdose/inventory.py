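"""Radionuclide data model: decay-series membership, specific-activity
vectors and inhalation dose coefficients.

The package ships the radiological fingerprint of deep-sea polymetallic
nodules as measured averages (bulk material) together with the derived
process streams (slag of the third pyrometallurgical reduction stage,
flue/filter dust of the first stage), and the occupational inhalation dose
coefficients for the long-lived members of the three natural decay series
(U-238, U-235, Th-232) at AMAD 5 µm.  Only nuclides with a coefficient
above 0.1 µSv/Bq are tabulated; everything below that cutoff contributes
zero by construction.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterator, Mapping

import pandas as pd

from .errors import MissingNuclideError, ValidationError
from .units import bq_per_kg_to_bq_per_mg

logger = logging.getLogger(__name__)

_NAME_ELEMENT_FIRST = re.compile(r"([A-Za-z]{1,2})-?(\d{1,3})")
_NAME_MASS_FIRST = re.compile(r"(\d{1,3})-?([A-Za-z]{1,2})")


def normalize_nuclide(name: str) -> str:
    """Normalize a nuclide identifier to canonical ``Element-Mass`` form.

    Accepts ``"Ra-226"``, ``"Ra226"``, ``"226Ra"``, ``"226-Ra"`` and
    case variants thereof.

    >>> normalize_nuclide("226Ra")
    'Ra-226'
    """
    s = str(name).strip().replace(" ", "")
    m = _NAME_ELEMENT_FIRST.fullmatch(s)
    if m:
        element, mass = m.group(1), m.group(2)
    else:
        m = _NAME_MASS_FIRST.fullmatch(s)
        if not m:
            raise ValidationError(f"unrecognized nuclide name: {name!r}")
        mass, element = m.group(1), m.group(2)
    return f"{element.capitalize()}-{mass}"


@dataclass(frozen=True)
class Nuclide:
    """A radionuclide of one of the three natural decay series.

    ``half_life_a`` (years) is informational only; no ingrowth or decay
    correction is performed anywhere in the package — specific activities
    are taken as measured.
    """

    name: str
    series: str  # parent of the natural decay series: U-238, U-235 or Th-232
    half_life_a: float


#: Known nuclides, keyed by canonical name.  Half-lives in years.
NUCLIDE_REGISTRY: Mapping[str, Nuclide] = {
    n.name: n
    for n in [
        Nuclide("U-238", "U-238", 4.468e9),
        Nuclide("U-234", "U-238", 2.455e5),
        Nuclide("Th-230", "U-238", 7.54e4),
        Nuclide("Ra-226", "U-238", 1.600e3),
        Nuclide("Rn-222", "U-238", 1.05e-2),
        Nuclide("Pb-210", "U-238", 22.3),
        Nuclide("Po-210", "U-238", 0.379),
        Nuclide("U-235", "U-235", 7.04e8),
        Nuclide("Pa-231", "U-235", 3.276e4),
        Nuclide("Ac-227", "U-235", 21.77),
        Nuclide("Th-232", "Th-232", 1.405e10),
        Nuclide("Ra-228", "Th-232", 5.75),
        Nuclide("Th-228", "Th-232", 1.912),
    ]
}

#: Packaged specific-activity tables (material label -> resource file).
FIXTURE_VECTORS = {
    "nodules_bulk": "nodules_bulk.csv",
    "slag_3rd_reduction": "slag_3rd_reduction.csv",
    "filter_dust_1st_reduction": "filter_dust_1st_reduction.csv",
}


def _data_path(resource: str):
    return resources.files("normdose.data").joinpath(resource)


@dataclass
class NuclideVector:
    """Per-nuclide specific activities of one material [Bq/kg].

    ``rel_uncertainty`` maps nuclide -> relative uncertainty in percent
    (optional per nuclide).  Activities and uncertainties must be
    non-negative; nuclide names are normalized on construction, and two
    spellings of the same nuclide are rejected as duplicates.
    """

    activities: dict[str, float]
    rel_uncertainty: dict[str, float] = field(default_factory=dict)
    material_label: str = ""

    def __post_init__(self) -> None:
        normalized: dict[str, float] = {}
        for name, activity in self.activities.items():
            canon = normalize_nuclide(name)
            if canon not in NUCLIDE_REGISTRY:
                raise ValidationError(f"unknown nuclide: {name!r}")
            if canon in normalized:
                raise ValidationError(f"duplicate nuclide entry: {canon}")
            activity = float(activity)
            if activity < 0:
                raise ValidationError(
                    f"negative specific activity for {canon}: {activity}"
                )
            normalized[canon] = activity
        self.activities = normalized

        unc: dict[str, float] = {}
        for name, pct in self.rel_uncertainty.items():
            canon = normalize_nuclide(name)
            pct = float(pct)
            if pct < 0:
                raise ValidationError(f"negative uncertainty for {canon}: {pct}")
            if canon in unc:
                raise ValidationError(f"duplicate uncertainty entry: {canon}")
            unc[canon] = pct
        self.rel_uncertainty = unc

    # -- access -----------------------------------------------------------

    def activity(self, nuclide: str, default: float = 0.0) -> float:
        """Specific activity of ``nuclide`` in Bq/kg (``default`` if absent)."""
        return self.activities.get(normalize_nuclide(nuclide), default)

    def require(self, nuclide: str) -> float:
        canon = normalize_nuclide(nuclide)
        if canon not in self.activities:
            raise MissingNuclideError(canon, self.material_label or "vector")
        return self.activities[canon]

    @property
    def ra226(self) -> float:
        """Ra-226 specific activity [Bq/kg]; raises if absent."""
        return self.require("Ra-226")

    @property
    def nuclides(self) -> tuple[str, ...]:
        return tuple(self.activities)

    @property
    def total_activity(self) -> float:
        """Sum of all specific activities [Bq/kg]."""
        return sum(self.activities.values())

    def items(self) -> Iterator[tuple[str, float]]:
        return iter(self.activities.items())

    def __len__(self) -> int:
        return len(self.activities)

    # -- algebra ----------------------------------------------------------

    def scaled(self, factor: float, label: str | None = None) -> "NuclideVector":
        """Return a copy with every activity multiplied by ``factor`` >= 0.

        Relative uncertainties are unchanged (they are scale-free).
        """
        if factor < 0:
            raise ValidationError(f"scale factor must be >= 0, got {factor}")
        return NuclideVector(
            {n: a * factor for n, a in self.activities.items()},
            dict(self.rel_uncertainty),
            self.material_label if label is None else label,
        )

    def __add__(self, other: "NuclideVector") -> "NuclideVector":
        """Nuclide-wise sum of activities (uncertainties are dropped)."""
        merged = dict(self.activities)
        for n, a in other.activities.items():
            merged[n] = merged.get(n, 0.0) + a
        return NuclideVector(merged, {}, f"{self.material_label}+{other.material_label}")

    def subset(self, nuclides, label: str | None = None) -> "NuclideVector":
        """Restrict the vector to the given nuclides (must all be present)."""
        keep = [normalize_nuclide(n) for n in nuclides]
        for n in keep:
            if n not in self.activities:
                raise MissingNuclideError(n, self.material_label or "vector")
        return NuclideVector(
            {n: self.activities[n] for n in keep},
            {n: self.rel_uncertainty[n] for n in keep if n in self.rel_uncertainty},
            self.material_label if label is None else label,
        )


@dataclass
class DoseCoefficients:
    """Inhalation dose coefficients g_inh [µSv/Bq] at a fixed AMAD.

    ``absorption_class`` records the lung absorption type (F fast, M
    moderate, S slow) each coefficient was taken for.  The packaged table
    is valid for an activity median aerodynamic diameter of 5 µm and uses
    S values for thorium isotopes, the F value for Ac-227 and M values
    otherwise.
    """

    g_inh: dict[str, float]
    absorption_class: dict[str, str] = field(default_factory=dict)
    amad_um: float = 5.0

    def __post_init__(self) -> None:
        coeffs: dict[str, float] = {}
        for name, g in self.g_inh.items():
            canon = normalize_nuclide(name)
            g = float(g)
            if g <= 0:
                raise ValidationError(f"dose coefficient must be > 0 for {canon}: {g}")
            coeffs[canon] = g
        self.g_inh = coeffs
        self.absorption_class = {
            normalize_nuclide(n): str(c) for n, c in self.absorption_class.items()
        }
        if self.amad_um <= 0:
            raise ValidationError(f"AMAD must be positive, got {self.amad_um}")

    def coefficient(self, nuclide: str) -> float | None:
        return self.g_inh.get(normalize_nuclide(nuclide))


def load_nuclide_vector(source: str | Path) -> NuclideVector:
    """Load a specific-activity vector from a CSV file or packaged fixture.

    ``source`` may be a packaged material name (see :data:`FIXTURE_VECTORS`)
    or a path to a delimited file with columns ``nuclide``,
    ``activity_Bq_per_kg`` and optionally ``uncertainty_pct``.
    """
    label = str(source)
    if label in FIXTURE_VECTORS:
        path = _data_path(FIXTURE_VECTORS[label])
    else:
        path = Path(source)
        label = path.stem
    table = pd.read_csv(path)
    required = {"nuclide", "activity_Bq_per_kg"}
    if not required.issubset(table.columns):
        raise ValidationError(
            f"{path}: expected columns {sorted(required)}, got {list(table.columns)}"
        )
    names = [normalize_nuclide(n) for n in table["nuclide"]]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValidationError(f"{path}: duplicate nuclide rows: {dupes}")
    activities = dict(zip(names, table["activity_Bq_per_kg"].astype(float)))
    uncertainties: dict[str, float] = {}
    if "uncertainty_pct" in table.columns:
        for name, pct in zip(names, table["uncertainty_pct"]):
            if pd.notna(pct):
                uncertainties[name] = float(pct)
    return NuclideVector(activities, uncertainties, material_label=label)


def load_dose_coefficients(source: str | Path | None = None) -> DoseCoefficients:
    """Load inhalation dose coefficients (packaged AMAD-5 µm table by default)."""
    path = _data_path("dose_coefficients.csv") if source is None else Path(source)
    table = pd.read_csv(path)
    names = [normalize_nuclide(n) for n in table["nuclide"]]
    classes = (
        dict(zip(names, table["absorption_class"]))
        if "absorption_class" in table.columns
        else {}
    )
    return DoseCoefficients(
        g_inh=dict(zip(names, table["g_inh_uSv_per_Bq"].astype(float))),
        absorption_class=classes,
    )


def load_materials() -> dict[str, NuclideVector]:
    """All packaged material vectors, keyed by material label."""
    return {name: load_nuclide_vector(name) for name in FIXTURE_VECTORS}


def unit_dust_dose(vector: NuclideVector, coefficients: DoseCoefficients) -> float:
    """Committed effective dose per unit mass of inhaled dust [µSv/mg].

    Sums g_inh,i × C_i over every nuclide of the vector that has a
    tabulated coefficient (Bq/kg → Bq/mg conversion applied).  Nuclides
    without a coefficient are below the 0.1 µSv/Bq relevance cutoff and
    contribute zero; they are logged for traceability.
    """
    total = 0.0
    for nuclide, activity in vector.items():
        g = coefficients.coefficient(nuclide)
        if g is None:
            if activity > 0:
                logger.debug(
                    "nuclide %s (%.3g Bq/kg) has no dose coefficient; contributes 0",
                    nuclide,
                    activity,
                )
            continue
        total += g * bq_per_kg_to_bq_per_mg(activity)
    return total
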