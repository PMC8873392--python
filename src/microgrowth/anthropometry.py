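"""Sex/age-standardised BMI (zBMI) via the LMS method.

A growth reference tabulates, per sex and age in days, the Box-Cox power
``L``, the median BMI ``M`` (kg/m^2) and the coefficient of variation ``S``.
The z-score of an observed BMI is::

    z = ((BMI / M)**L - 1) / (L * S)      if L != 0
    z = ln(BMI / M) / S                   if L == 0

with (L, M, S) linearly interpolated in age between tabulated rows.  On the
standard-normal scale z = +3 corresponds to the 99.865th percentile and
z = -3 to the 0.135th; observations outside |z| > 3 in cohort data are
usually measurement or data-entry errors and are removed before analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GrowthReference",
    "bmi",
    "zbmi",
    "zbmi_table",
    "inverse_lms",
    "flag_outliers",
    "synthetic_reference",
]

_REF_COLUMNS = ["sex", "age_days", "L", "M", "S"]


@dataclass
class GrowthReference:
    """LMS lookup table keyed by (sex, age in days).

    Parameters
    ----------
    table : pandas.DataFrame
        Columns ``sex, age_days, L, M, S``.  Sex coding is free-form
        (e.g. ``"F"``/``"M"`` or ``1``/``2``) but must match the
        anthropometry records.  Within each sex, ages must be strictly
        increasing and ``M > 0``, ``S > 0`` everywhere.
    """

    table: pd.DataFrame
    _by_sex: dict = field(init=False, repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in _REF_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"growth reference missing columns: {missing}")
        tab = self.table
        if (tab["M"] <= 0).any() or (tab["S"] <= 0).any():
            raise ValueError("growth reference requires M > 0 and S > 0")
        for sex, grp in tab.groupby("sex"):
            ages = grp["age_days"].to_numpy(float)
            if not np.all(np.diff(ages) > 0):
                raise ValueError(f"ages not strictly increasing for sex {sex!r}")
            self._by_sex[sex] = (
                ages,
                grp["L"].to_numpy(float),
                grp["M"].to_numpy(float),
                grp["S"].to_numpy(float),
            )

    @classmethod
    def from_csv(cls, path) -> "GrowthReference":
        return cls(pd.read_csv(path))

    def lms_at(self, sex, age_days: float) -> tuple[float, float, float]:
        """Interpolated (L, M, S) at an exact age; no extrapolation."""
        try:
            ages, L, M, S = self._by_sex[sex]
        except KeyError:
            raise KeyError(f"sex {sex!r} not in growth reference") from None
        if age_days < ages[0] or age_days > ages[-1]:
            raise ValueError(
                f"age {age_days} d outside reference span "
                f"[{ages[0]}, {ages[-1]}] for sex {sex!r}"
            )
        return (
            float(np.interp(age_days, ages, L)),
            float(np.interp(age_days, ages, M)),
            float(np.interp(age_days, ages, S)),
        )


def bmi(weight_kg: float, length_cm: float) -> float:
    """BMI in kg/m^2 from weight in kg and length/height in cm."""
    if weight_kg <= 0 or length_cm <= 0:
        raise ValueError("weight and length must be positive")
    return weight_kg / (length_cm / 100.0) ** 2


def _lms_z(bmi_value: float, L: float, M: float, S: float) -> float:
    if L == 0.0:
        return float(np.log(bmi_value / M) / S)
    return float(((bmi_value / M) ** L - 1.0) / (L * S))


def zbmi(weight_kg, length_cm, age_days, sex, reference: GrowthReference) -> float:
    """BMI-for-age z-score for a single observation."""
    L, M, S = reference.lms_at(sex, float(age_days))
    return _lms_z(bmi(weight_kg, length_cm), L, M, S)


def inverse_lms(z: float, L: float, M: float, S: float) -> float:
    """BMI corresponding to a z-score (inverse of the LMS transform)."""
    if L == 0.0:
        return float(M * np.exp(S * z))
    return float(M * (1.0 + L * S * z) ** (1.0 / L))


def zbmi_table(records: pd.DataFrame, reference: GrowthReference) -> pd.DataFrame:
    """Add a ``zbmi`` column to a long anthropometry table.

    Expects columns ``weight_kg, length_cm, age_days, sex``; rows with any of
    these missing get a missing zbmi rather than an error.
    """
    out = records.copy()
    z = np.full(len(out), np.nan)
    for i, row in enumerate(out.itertuples(index=False)):
        w, l, a = row.weight_kg, row.length_cm, row.age_days
        if pd.isna(w) or pd.isna(l) or pd.isna(a):
            continue
        z[i] = zbmi(w, l, a, row.sex, reference)
    out["zbmi"] = z
    return out


def flag_outliers(
    records: pd.DataFrame, bound: float = 3.0, column: str = "zbmi"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split records into (kept, flagged) by the |zBMI| > bound rule.

    Values beyond the reference's +/-3 band almost always reflect entry
    errors in weight or length; they are removed observation-wise (a child
    keeps its other time points).  Missing zbmi values are kept.
    """
    z = records[column]
    is_out = z.abs() > bound
    is_out = is_out.fillna(False)
    return records.loc[~is_out].copy(), records.loc[is_out].copy()


def synthetic_reference(
    max_age_days: int = 4800, step: int = 30, sexes=("F", "M")
) -> GrowthReference:
    """A smooth synthetic LMS grid for testing and simulation.

    This is *not* a real growth standard: it is a plausible median-BMI
    trajectory (adiposity peak in infancy, rebound in mid-childhood) with
    mild skewness, so that the package can run self-contained.  Real
    reference tables in the same CSV layout drop in unchanged.
    """
    ages = np.arange(0, max_age_days + step, step, dtype=float)
    years = ages / 365.25
    # median BMI: rises to ~17.5 near 9 months, dips to ~15.3 near 5-6 y,
    # then climbs slowly (adiposity rebound)
    M = 13.5 + 4.0 * np.exp(-0.5 * ((years - 0.75) / 0.9) ** 2) + 0.35 * np.maximum(
        years - 5.0, 0.0
    )
    L = -0.5 - 0.1 * np.tanh(years - 2.0)
    S = 0.08 + 0.01 * np.tanh(years - 3.0)
    frames = []
    for k, sex in enumerate(sexes):
        frames.append(
            pd.DataFrame(
                {
                    "sex": sex,
                    "age_days": ages,
                    "L": L,
                    "M": M * (1.0 + 0.01 * k),  # small sex offset
                    "S": S,
                }
            )
        )
    return GrowthReference(pd.concat(frames, ignore_index=True))
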