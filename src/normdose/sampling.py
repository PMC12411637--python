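"""Forward Monte Carlo uncertainty propagation for dose scenarios.

The measured nuclide vectors carry per-nuclide relative uncertainties
(13–45%).  These are propagated to dose distributions by sampling each
specific activity from a lognormal distribution parameterized so that the
*arithmetic mean* equals the tabulated value and the coefficient of
variation equals the tabulated relative uncertainty.  Because every
pathway is linear in the activities, this mean-preserving choice makes
the expected Monte Carlo dose converge to the deterministic result.

Activities are sampled independently per nuclide by default.  A shared
surface-layer multiplier, drawn uniformly from a bounded range (the
observed surface-to-bulk enrichment spans roughly 1–3), acts as an
optional common-mode factor for correlated enrichment.  Bounded
multiplicative perturbations of operational parameters (dust
concentration, exposure times, shielding) are supported as well.

This is forward propagation only — no calibration or inference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ValidationError
from .inventory import DoseCoefficients, NuclideVector, load_dose_coefficients, load_materials
from .scenario import DoseReport, Scenario, run_scenario

#: Observed range of the surface-layer specific-activity enhancement.
SURFACE_MULTIPLIER_STUDY_RANGE = (1.0, 3.0)

#: Scenario parameters that may be perturbed, mapped to (kind, field).
PERTURBABLE_PARAMETERS = {
    "c_dust": ("dust", "c_dust_mg_m3"),
    "t_exp_dust": ("dust", "t_exp_h"),
    "t_exp_gamma": ("gamma", "t_exp_h"),
    "shielding": ("gamma", "shielding"),
}


@dataclass
class SamplingSpec:
    """Monte Carlo configuration.

    ``parameter_perturbations`` maps a parameter name from
    :data:`PERTURBABLE_PARAMETERS` to a bounded multiplicative range
    ``(lo, hi)``; a factor is drawn uniformly per iteration and applied
    to every pathway carrying that parameter.  ``surface_multiplier_range``
    of ``None`` keeps the scenario's fixed multiplier (the deterministic
    study case); a range samples one shared multiplier per iteration.
    """

    n_draws: int
    seed: int
    activity_model: str = "lognormal"   # "lognormal" or "degenerate"
    parameter_perturbations: dict[str, tuple[float, float]] = field(default_factory=dict)
    surface_multiplier_range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.n_draws < 1:
            raise ValidationError(f"n_draws must be >= 1, got {self.n_draws}")
        if self.activity_model not in ("lognormal", "degenerate"):
            raise ValidationError(
                f"unknown activity model {self.activity_model!r}"
            )
        for name, bounds in self.parameter_perturbations.items():
            if name not in PERTURBABLE_PARAMETERS:
                raise ValidationError(
                    f"unknown perturbable parameter {name!r}; "
                    f"known: {sorted(PERTURBABLE_PARAMETERS)}"
                )
            lo, hi = bounds
            if not (0 <= lo <= hi):
                raise ValidationError(f"range for {name!r} must satisfy 0 <= lo <= hi")
        if self.surface_multiplier_range is not None:
            lo, hi = self.surface_multiplier_range
            if not (1.0 <= lo <= hi):
                raise ValidationError("surface multiplier range must satisfy 1 <= lo <= hi")


def _lognormal_params(mean: float, cv: float) -> tuple[float, float]:
    """(mu, sigma) of a lognormal with given arithmetic mean and CV."""
    sigma2 = math.log1p(cv * cv)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


def _sample_vector(
    base: NuclideVector, rng: np.random.Generator, model: str
) -> NuclideVector:
    if model == "degenerate":
        return base.scaled(1.0)
    activities = {}
    for nuclide, mean in base.items():
        if mean == 0.0:
            activities[nuclide] = 0.0
            continue
        if nuclide not in base.rel_uncertainty:
            raise ValidationError(
                f"no relative uncertainty for {nuclide} in "
                f"{base.material_label!r}; cannot sample it"
            )
        cv = base.rel_uncertainty[nuclide] / 100.0
        if cv == 0.0:
            activities[nuclide] = mean
            continue
        mu, sigma = _lognormal_params(mean, cv)
        activities[nuclide] = float(rng.lognormal(mu, sigma))
    return NuclideVector(activities, dict(base.rel_uncertainty), base.material_label)


def sample_nuclide_vectors(
    spec: SamplingSpec, base: NuclideVector
) -> list[NuclideVector]:
    """Draw ``spec.n_draws`` activity vectors around ``base``.

    Reproducible under a fixed seed; all sampled activities are positive
    (lognormal support).  With CV = 0 everywhere, or with the
    ``degenerate`` model, every draw equals the base vector.
    """
    rng = np.random.default_rng(spec.seed)
    return [_sample_vector(base, rng, spec.activity_model) for _ in range(spec.n_draws)]


@dataclass
class MonteCarloResult:
    """Per-draw dose totals with summary statistics."""

    n_draws: int
    totals_msv: np.ndarray
    subtotals_excl_radon_msv: np.ndarray

    def summary(self) -> pd.DataFrame:
        """Mean, sd and 5/50/95 percentiles of total and gamma+dust dose."""
        rows = []
        for name, values in (
            ("total", self.totals_msv),
            ("subtotal_excl_radon", self.subtotals_excl_radon_msv),
        ):
            rows.append(
                {
                    "quantity": name,
                    "mean": float(np.mean(values)),
                    "sd": float(np.std(values, ddof=1)) if len(values) > 1 else 0.0,
                    "p5": float(np.percentile(values, 5)),
                    "p50": float(np.percentile(values, 50)),
                    "p95": float(np.percentile(values, 95)),
                }
            )
        return pd.DataFrame(rows).set_index("quantity")


def _perturbed_scenario(
    scenario: Scenario, spec: SamplingSpec, rng: np.random.Generator
) -> Scenario:
    """Apply per-draw parameter perturbations and multiplier draw."""
    out = scenario
    for name in sorted(spec.parameter_perturbations):
        lo, hi = spec.parameter_perturbations[name]
        factor = float(rng.uniform(lo, hi))
        kind, attr = PERTURBABLE_PARAMETERS[name]
        if kind == "gamma":
            out = replace(
                out,
                gamma=[
                    replace(g, **{attr: min(getattr(g, attr) * factor, 1.0)
                                  if attr == "shielding"
                                  else getattr(g, attr) * factor})
                    for g in out.gamma
                ],
            )
        else:
            out = replace(
                out,
                dust=[replace(d, **{attr: getattr(d, attr) * factor}) for d in out.dust],
            )
    if spec.surface_multiplier_range is not None:
        lo, hi = spec.surface_multiplier_range
        out = out.with_multiplier(float(rng.uniform(lo, hi)))
    return out


def monte_carlo_dose(
    spec: SamplingSpec,
    scenario: Scenario,
    materials: Mapping[str, NuclideVector] | None = None,
    coefficients: DoseCoefficients | None = None,
) -> MonteCarloResult:
    """Propagate activity and parameter uncertainty to dose distributions.

    Each iteration samples one vector per material (in sorted material
    order), perturbs the scenario parameters, and calls the same
    :func:`~normdose.scenario.run_scenario` used for deterministic
    reports.  With the ``degenerate`` model, no perturbations and a fixed
    multiplier, the distribution collapses to the deterministic dose.
    """
    if materials is None:
        materials = load_materials()
    if coefficients is None:
        coefficients = load_dose_coefficients()
    rng = np.random.default_rng(spec.seed)

    totals = np.empty(spec.n_draws)
    subtotals = np.empty(spec.n_draws)
    names = sorted(materials)
    for i in range(spec.n_draws):
        sampled = {
            name: _sample_vector(materials[name], rng, spec.activity_model)
            for name in names
        }
        report: DoseReport = run_scenario(
            _perturbed_scenario(scenario, spec, rng), sampled, coefficients
        )
        totals[i] = report.total_msv
        subtotals[i] = report.subtotal_excl_radon_msv
    return MonteCarloResult(
        n_draws=spec.n_draws,
        totals_msv=totals,
        subtotals_excl_radon_msv=subtotals,
    )
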