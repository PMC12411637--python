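"""Pyrometallurgical process streams and radionuclide partitioning.

The assumed flowsheet smelts nodules in three reduction stages.  Mass is
lost at each stage, so radionuclides that report to the residue are
enriched by the ratio of input to output mass flow.  Two partitioning
assumptions are modelled, both deliberately conservative:

* all non-volatile radionuclides transfer completely into the slag of the
  *third* reduction stage (the stream with the largest mass reduction,
  input/output ≈ 2.2 for 3.0 → 1.374 Mt/a);
* the volatile nuclides Pb-210 and Po-210 leave the melt at ~1450 °C and
  are collected quantitatively in the flue/filter dust of the *first*
  stage (3.0 → 0.297 Mt/a, a ≈10.1-fold enrichment), while optionally
  being double-counted in the slag so that slag doses are not
  underestimated.

No thermochemical partitioning model is attempted; transfer fractions are
fixed assumptions of the scenario.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ValidationError
from .inventory import NuclideVector, normalize_nuclide

#: Default volatile nuclides driven into the first-stage filter dust.
VOLATILE_NUCLIDES = frozenset({"Pb-210", "Po-210"})


@dataclass
class MaterialStream:
    """A mass flow [t/a] carrying a nuclide vector."""

    mass_rate: float
    vector: NuclideVector
    stage_label: str = ""

    def __post_init__(self) -> None:
        if not self.mass_rate > 0:
            raise ValidationError(f"mass rate must be > 0, got {self.mass_rate}")


def enrichment_factor(input_stream: MaterialStream, output_mass_rate: float) -> float:
    """Specific-activity enrichment when ``input_stream`` is reduced to
    ``output_mass_rate`` [t/a] with complete radionuclide transfer.

    Equals the mass ratio input/output; e.g. 3.0 Mt/a of nodules into
    1.374 Mt/a of slag gives 2.18… (printed as 2.2).
    """
    if not output_mass_rate > 0:
        raise ValidationError(f"output mass rate must be > 0, got {output_mass_rate}")
    return input_stream.mass_rate / output_mass_rate


@dataclass
class PartitionRule:
    """How one smelting campaign splits nuclides between slag and dust.

    ``double_count_volatiles_in_slag`` keeps Pb-210/Po-210 in the slag
    vector *as well as* in the dust (the conservative default), so the sum
    of stream activities can exceed the input inventory by design.

    ``printed_rounding`` selects the reporting arithmetic used in the
    source tables: enrichment factors rounded to one decimal (2.2, 10.1)
    and resulting activities rounded to integer Bq/kg.  Full-precision
    mass-ratio arithmetic is used when it is False.
    """

    dust_mass_rate: float
    slag_mass_rate: float
    volatile_nuclides: frozenset[str] = field(default_factory=lambda: VOLATILE_NUCLIDES)
    double_count_volatiles_in_slag: bool = True
    printed_rounding: bool = True

    def __post_init__(self) -> None:
        if not self.dust_mass_rate > 0 or not self.slag_mass_rate > 0:
            raise ValidationError("partition mass rates must be > 0")
        self.volatile_nuclides = frozenset(
            normalize_nuclide(n) for n in self.volatile_nuclides
        )
        if not self.volatile_nuclides:
            raise ValidationError("volatile nuclide set must be non-empty")


def _enrich(activity: float, factor: float, printed: bool) -> float:
    if printed:
        return float(round(activity * round(factor, 1)))
    return activity * factor


def apply_flowsheet(
    nodules: MaterialStream, rule: PartitionRule
) -> tuple[MaterialStream, MaterialStream]:
    """Partition a nodule feed into third-stage slag and first-stage dust.

    Returns ``(slag_stream, filter_dust_stream)``.  The dust stream holds
    only the volatile nuclides enriched by the dust mass ratio; the slag
    stream holds all nuclides enriched by the slag mass ratio (volatiles
    included only when double-counting is enabled).  For non-volatile
    nuclides activity is conserved: C_slag × M_slag = C_nodule × M_nodule
    (exactly in full-precision mode, to integer rounding otherwise).
    """
    nodules.vector.require("Ra-226")  # sanity: feed must look like nodules
    for nuclide in sorted(rule.volatile_nuclides):
        if nuclide not in nodules.vector.activities:
            raise ValidationError(
                f"volatile nuclide {nuclide} missing from input stream "
                f"{nodules.stage_label or nodules.vector.material_label!r}"
            )

    slag_factor = enrichment_factor(nodules, rule.slag_mass_rate)
    dust_factor = enrichment_factor(nodules, rule.dust_mass_rate)
    printed = rule.printed_rounding

    slag_activities = {}
    for nuclide, activity in nodules.vector.items():
        if nuclide in rule.volatile_nuclides and not rule.double_count_volatiles_in_slag:
            continue
        slag_activities[nuclide] = _enrich(activity, slag_factor, printed)
    dust_activities = {
        n: _enrich(nodules.vector.activities[n], dust_factor, printed)
        for n in sorted(rule.volatile_nuclides)
    }

    unc = nodules.vector.rel_uncertainty
    slag = MaterialStream(
        mass_rate=rule.slag_mass_rate,
        vector=NuclideVector(
            slag_activities,
            {n: unc[n] for n in slag_activities if n in unc},
            material_label="slag_3rd_reduction",
        ),
        stage_label="slag of the 3rd reduction stage",
    )
    dust = MaterialStream(
        mass_rate=rule.dust_mass_rate,
        vector=NuclideVector(
            dust_activities,
            {n: unc[n] for n in dust_activities if n in unc},
            material_label="filter_dust_1st_reduction",
        ),
        stage_label="filter dust of the 1st reduction stage",
    )
    return slag, dust
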