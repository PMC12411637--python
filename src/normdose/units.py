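"""Central unit conversions.

Specific activities are stored in Bq/kg, inhalation dose coefficients in
µSv/Bq, doses are reported in mSv/a and rates in SI seconds.  The source
literature mixes Bq/kg, Bq/g, Bq/mg, µSv, mSv, hours and seconds, and most
reproduction errors in this domain are unit slips, so every conversion used
anywhere in the package lives here.
"""

#: Bq/kg in one Bq/g.
BQ_PER_KG_PER_BQ_PER_G = 1_000.0

#: Bq/kg in one Bq/mg.
BQ_PER_KG_PER_BQ_PER_MG = 1_000_000.0

#: µSv in one mSv.
USV_PER_MSV = 1_000.0

#: Seconds in one hour.
SECONDS_PER_HOUR = 3_600.0

#: Tonnes per year equivalent to one kg/s (for mass-flow conversions).
T_PER_A_PER_KG_PER_S = 365.25 * 24 * 3_600.0 / 1_000.0


def bq_per_kg_to_bq_per_g(activity: float) -> float:
    """Convert a specific activity from Bq/kg to Bq/g."""
    return activity / BQ_PER_KG_PER_BQ_PER_G


def bq_per_kg_to_bq_per_mg(activity: float) -> float:
    """Convert a specific activity from Bq/kg to Bq/mg."""
    return activity / BQ_PER_KG_PER_BQ_PER_MG


def usv_to_msv(dose_usv: float) -> float:
    """Convert a dose from µSv to mSv."""
    return dose_usv / USV_PER_MSV


def per_hour_to_per_second(rate: float) -> float:
    """Convert a first-order rate (e.g. an air-change rate) from 1/h to 1/s.

    The exact factor 1/3600 is used throughout; rounded per-second values
    such as 0.0003 for one air change per hour noticeably shift indoor
    steady-state radon concentrations.
    """
    return rate / SECONDS_PER_HOUR
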