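"""Standardization of sigmoid growth-model constants to comparable growth rates.

Published growth studies report the rate constant ``k`` of whichever sigmoid
model (logistic, Gompertz, von Bertalanffy) was fitted to the mass
trajectory.  Those constants are not comparable across model families
because each family places its inflection point — where absolute growth
peaks — at a different fraction of asymptotic mass.  This module converts a
raw record ``(family, k, adult mass)`` into the pair that *is* comparable:

* ``AGR``    — maximum absolute growth rate, grams/day, the peak of dM/dt;
* ``BMatMG`` — body mass at maximum growth, grams, the mass at the
  inflection point.

For asymptotic mass ``A``:

=================  ==================  =====================
family             BMatMG / A          AGR
=================  ==================  =====================
logistic           1/2                 (1/2)  * k * BMatMG
Gompertz           1/e                 k * BMatMG
von Bertalanffy    8/27                (3/2) * k * BMatMG
=================  ==================  =====================

The von Bertalanffy form used throughout is the cubed mass curve
``M(t) = A (1 - (1/3) e^{-kt})^3``, which is the parameterization consistent
with an inflection at ``(8/27) A`` and the 3/2 multiplier.
"""

from __future__ import annotations

import enum
import logging
import math
import re
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "GrowthModelFamily",
    "GrowthRecord",
    "StandardizedRecord",
    "inflection_fraction",
    "agr_multiplier",
    "bmatmg_from_adult_mass",
    "convert_rate_to_daily",
    "standardize_record",
    "standardize_table",
    "aggregate_species_means",
    "relative_growth_rate",
    "normalize_species_name",
    "read_trait_table",
    "write_standardized_table",
    "growth_curve",
    "inflection_fraction_numeric",
    "DAYS_PER_YEAR",
]

#: Days per year used when converting yearly/monthly rate constants to a
#: daily basis.  365 (not 365.25); months are 365/12 days.  Configurable via
#: the ``days_per_year`` argument of :func:`convert_rate_to_daily`.
DAYS_PER_YEAR = 365.0


class GrowthModelFamily(str, enum.Enum):
    """The three sigmoid growth-model families, plus a marker for records
    whose maximum growth rate was measured directly rather than derived
    from a fitted model."""

    LOGISTIC = "logistic"
    GOMPERTZ = "gompertz"
    VON_BERTALANFFY = "vonbertalanffy"
    DIRECT = "direct"

    @classmethod
    def parse(cls, value) -> "GrowthModelFamily":
        if isinstance(value, cls):
            return value
        key = re.sub(r"[\s_\-]+", "", str(value).strip().lower())
        aliases = {
            "logistic": cls.LOGISTIC,
            "gompertz": cls.GOMPERTZ,
            "vonbertalanffy": cls.VON_BERTALANFFY,
            "bertalanffy": cls.VON_BERTALANFFY,
            "vb": cls.VON_BERTALANFFY,
            "direct": cls.DIRECT,
        }
        try:
            return aliases[key]
        except KeyError:
            raise ValueError(f"unknown growth-model family: {value!r}") from None


_INFLECTION_FRACTION = {
    GrowthModelFamily.LOGISTIC: 0.5,
    GrowthModelFamily.GOMPERTZ: 1.0 / math.e,
    GrowthModelFamily.VON_BERTALANFFY: 8.0 / 27.0,
}

_AGR_MULTIPLIER = {
    GrowthModelFamily.LOGISTIC: 0.5,
    GrowthModelFamily.GOMPERTZ: 1.0,
    GrowthModelFamily.VON_BERTALANFFY: 1.5,
}

def inflection_fraction(family) -> float:
    """Fraction of asymptotic mass at the inflection point of ``family``.

    Exact analytic values: logistic 1/2, Gompertz 1/e, von Bertalanffy 8/27.
    """
    family = GrowthModelFamily.parse(family)
    try:
        return _INFLECTION_FRACTION[family]
    except KeyError:
        raise ValueError(
            f"family {family.value!r} has no inflection fraction; direct "
            "records need an assumed sigmoid family"
        ) from None


def agr_multiplier(family) -> float:
    """Dimensionless factor relating ``k * BMatMG`` to the peak growth rate."""
    family = GrowthModelFamily.parse(family)
    try:
        return _AGR_MULTIPLIER[family]
    except KeyError:
        raise ValueError(
            f"family {family.value!r} has no AGR multiplier; direct records "
            "carry a measured AGR instead"
        ) from None


def bmatmg_from_adult_mass(adult_mass: float, family) -> float:
    """Body mass at maximum growth: adult mass times the family's
    inflection fraction."""
    if not adult_mass > 0:
        raise ValueError(f"adult mass must be positive, got {adult_mass}")
    return adult_mass * inflection_fraction(family)


def convert_rate_to_daily(k: float, time_unit: str, days_per_year: float = DAYS_PER_YEAR) -> float:
    """Convert a growth-rate constant to a per-day basis.

    ``day`` is identity; ``year`` divides by ``days_per_year``; ``month``
    divides by ``days_per_year / 12``.
    """
    if not k > 0:
        raise ValueError(f"rate constant must be positive, got {k}")
    unit = str(time_unit).strip().lower()
    if unit == "day":
        return k
    if unit == "year":
        return k / days_per_year
    if unit == "month":
        return k / (days_per_year / 12.0)
    raise ValueError(f"unknown time unit {time_unit!r}; expected day, month or year")


_WS = re.compile(r"[\s_]+")


def normalize_species_name(name: str) -> str:
    """Canonical species-name form used to match trait tables against trees:
    trimmed, whitespace/underscores collapsed to single underscores,
    case-folded."""
    return _WS.sub("_", str(name).strip()).casefold()


@dataclass(frozen=True)
class GrowthRecord:
    """One raw observation: a species' fitted growth constant and adult mass.

    ``family = DIRECT`` means AGR was measured directly (``agr_direct``,
    g/day, as in classical fastest-interval reptile compilations); such
    records must declare ``assumed_family`` so BMatMG can still be located.
    """

    species: str
    group: str
    family: GrowthModelFamily
    k: Optional[float]  # per time_unit; None for direct records
    time_unit: str = "day"
    adult_mass: float = 0.0  # grams
    agr_direct: Optional[float] = None  # g/day
    assumed_family: Optional[GrowthModelFamily] = None

    def __post_init__(self):
        object.__setattr__(self, "family", GrowthModelFamily.parse(self.family))
        if self.assumed_family is not None:
            object.__setattr__(
                self, "assumed_family", GrowthModelFamily.parse(self.assumed_family)
            )
        if not self.adult_mass > 0:
            raise ValueError(f"{self.species}: adult mass must be positive")
        if self.family is GrowthModelFamily.DIRECT:
            if self.agr_direct is None or not self.agr_direct > 0:
                raise ValueError(f"{self.species}: direct record needs agr_direct > 0")
        else:
            if self.k is None or not self.k > 0:
                raise ValueError(f"{self.species}: model record needs k > 0")


@dataclass(frozen=True)
class StandardizedRecord:
    """Model-independent observation: peak growth rate and the mass where
    it occurs, with their base-10 logs.  The regression's observation unit."""

    species: str
    group: str
    agr: float  # g/day
    bmatmg: float  # g
    log_agr: float
    log_bm: float

    @classmethod
    def from_values(cls, species, group, agr, bmatmg) -> "StandardizedRecord":
        if not (agr > 0 and bmatmg > 0):
            raise ValueError(f"{species}: AGR and BMatMG must be positive")
        return cls(species, group, agr, bmatmg, math.log10(agr), math.log10(bmatmg))


def standardize_record(rec: GrowthRecord, days_per_year: float = DAYS_PER_YEAR) -> StandardizedRecord:
    """Convert one raw record to (AGR, BMatMG).

    For fitted-model records, ``AGR = multiplier(family) * k_daily * BMatMG``.
    For direct records the measured AGR is passed through and BMatMG is
    derived from the declared ``assumed_family`` (a von Bertalanffy
    assumption for fastest-interval reptile rates); refusing to default silently,
    a direct record without an assumed family is an error.
    """
    if rec.family is GrowthModelFamily.DIRECT:
        if rec.assumed_family is None:
            raise ValueError(
                f"{rec.species}: direct-AGR record requires an explicit "
                "assumed_family to locate BMatMG"
            )
        bmatmg = bmatmg_from_adult_mass(rec.adult_mass, rec.assumed_family)
        agr = float(rec.agr_direct)
    else:
        bmatmg = bmatmg_from_adult_mass(rec.adult_mass, rec.family)
        k_daily = convert_rate_to_daily(rec.k, rec.time_unit, days_per_year)
        agr = agr_multiplier(rec.family) * k_daily * bmatmg
    return StandardizedRecord.from_values(rec.species, rec.group, agr, bmatmg)


def aggregate_species_means(
    records: Iterable[StandardizedRecord], group: Optional[str] = None
) -> list[StandardizedRecord]:
    """Collapse repeated measurements of a species to arithmetic means of
    AGR and BMatMG on the linear scale (logs recomputed from the means).

    Dinosaur records are exempt: every (mass, rate) point from a growth
    series is an observation in its own right, so they pass through
    unchanged.
    """
    records = list(records)
    if group is None:
        groups = {r.group for r in records}
        if len(groups) > 1:
            raise ValueError("records span multiple groups; pass group explicitly")
        group = groups.pop() if groups else ""
    if _is_dinosaur_group(group):
        return records
    out: list[StandardizedRecord] = []
    seen: dict[str, list[StandardizedRecord]] = {}
    for r in records:
        seen.setdefault(normalize_species_name(r.species), []).append(r)
    for recs in seen.values():
        if len(recs) == 1:
            out.append(recs[0])
        else:
            agr = float(np.mean([r.agr for r in recs]))
            bm = float(np.mean([r.bmatmg for r in recs]))
            out.append(StandardizedRecord.from_values(recs[0].species, group, agr, bm))
    return out


def _is_dinosaur_group(group: str) -> bool:
    return "dinosaur" in str(group).casefold()


def relative_growth_rate(rec: StandardizedRecord) -> float:
    """Relative growth rate, per day: AGR / BMatMG."""
    return rec.agr / rec.bmatmg


# ---------------------------------------------------------------------------
# table I/O

_REQUIRED_COLS = ["species", "group", "model", "k", "k_unit", "adult_mass_g"]


def read_trait_table(path, sep: Optional[str] = None) -> list[GrowthRecord]:
    """Read a raw trait table (CSV or TSV, header required) into records.

    Columns: species, group, model (logistic/gompertz/vonbertalanffy/direct),
    k, k_unit (day/month/year), adult_mass_g, and optionally
    agr_direct_g_per_day and assumed_family.
    """
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    missing = [c for c in _REQUIRED_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"trait table {path} missing columns: {missing}")
    records = []
    for i, row in df.iterrows():
        fam = GrowthModelFamily.parse(row["model"])
        k = row["k"]
        records.append(
            GrowthRecord(
                species=str(row["species"]),
                group=str(row["group"]),
                family=fam,
                k=None if pd.isna(k) else float(k),
                time_unit=str(row["k_unit"]) if not pd.isna(row["k_unit"]) else "day",
                adult_mass=float(row["adult_mass_g"]),
                agr_direct=(
                    float(row["agr_direct_g_per_day"])
                    if "agr_direct_g_per_day" in df.columns
                    and not pd.isna(row.get("agr_direct_g_per_day"))
                    else None
                ),
                assumed_family=(
                    GrowthModelFamily.parse(row["assumed_family"])
                    if "assumed_family" in df.columns
                    and not pd.isna(row.get("assumed_family"))
                    else None
                ),
            )
        )
    return records


def standardize_table(
    records: Iterable[GrowthRecord],
    aggregate: bool = True,
    days_per_year: float = DAYS_PER_YEAR,
) -> pd.DataFrame:
    """Standardize raw records and (optionally) aggregate species means.

    Returns a DataFrame with columns species, group, agr_g_per_day,
    bmatmg_g, log10_agr, log10_bmatmg, rgr_per_day.
    """
    std = [standardize_record(r, days_per_year) for r in records]
    if aggregate:
        by_group: dict[str, list[StandardizedRecord]] = {}
        for r in std:
            by_group.setdefault(r.group, []).append(r)
        std = [r for g, recs in by_group.items() for r in aggregate_species_means(recs, g)]
    return pd.DataFrame(
        {
            "species": [r.species for r in std],
            "group": [r.group for r in std],
            "agr_g_per_day": [r.agr for r in std],
            "bmatmg_g": [r.bmatmg for r in std],
            "log10_agr": [r.log_agr for r in std],
            "log10_bmatmg": [r.log_bm for r in std],
            "rgr_per_day": [relative_growth_rate(r) for r in std],
        }
    )


def write_standardized_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# closed-form growth curves and a numeric inflection locator
#
# These are used to verify the analytic fractions/multipliers by locating
# the peak of dM/dt on the actual mass curves, and by the synthetic module.


def growth_curve(family):
    """Return ``M(t)`` for the given family as a callable ``f(t, A, k)``.

    logistic:        A / (1 + exp(-k (t - t0))), t0 placed so M(0) is small
    Gompertz:        A exp(-b e^{-k t})
    von Bertalanffy: A (1 - (1/3) e^{-k t})^3
    """
    family = GrowthModelFamily.parse(family)
    if family is GrowthModelFamily.LOGISTIC:

        def m(t, A=1.0, k=1.0, t0=None):
            if t0 is None:
                t0 = 5.0 / k  # start near 0.7% of A
            return A / (1.0 + np.exp(-k * (np.asarray(t) - t0)))

        return m
    if family is GrowthModelFamily.GOMPERTZ:

        def m(t, A=1.0, k=1.0, b=5.0):
            return A * np.exp(-b * np.exp(-k * np.asarray(t)))

        return m
    if family is GrowthModelFamily.VON_BERTALANFFY:

        def m(t, A=1.0, k=1.0):
            return A * (1.0 - (1.0 / 3.0) * np.exp(-k * np.asarray(t))) ** 3

        return m
    raise ValueError(f"no growth curve for family {family.value!r}")


def inflection_fraction_numeric(family, k: float = 0.01, A: float = 1.0) -> float:
    """Locate the inflection of the family's mass curve numerically and
    return the mass there as a fraction of ``A``.

    The inflection is where dM/dt peaks; it is found by maximizing a
    central-difference derivative of the closed-form curve with a bounded
    scalar optimizer.  Agreement with :func:`inflection_fraction` is a
    consistency check on the analytic constants.
    """
    from scipy.optimize import minimize_scalar

    m = growth_curve(family)
    h = 1e-4 / k

    def neg_rate(t):
        return -(m(t + h, A=A, k=k) - m(t - h, A=A, k=k)) / (2 * h)

    # growth is essentially complete by t = 20/k for all three families.  The
    # cubed von Bertalanffy curve starts at 8/27 A when t = 0 but extends back
    # to t = -ln(3)/k (where M = 0), so its search window opens below zero.
    fam = GrowthModelFamily.parse(family)
    lo = -0.98 * math.log(3.0) / k if fam is GrowthModelFamily.VON_BERTALANFFY else h
    res = minimize_scalar(neg_rate, bounds=(lo + h, 20.0 / k), method="bounded",
                          options={"xatol": 1e-10 / k})
    return float(m(res.x, A=A, k=k) / A)
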