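"""Radiocarbon unit conversions, error propagation, and reporting conventions.

The module converts AMS fraction-modern (Fm, a.k.a. F14C) measurements into
the two quantities radiocarbon laboratories report:

* the decay-corrected Δ14C (‰), which removes the decay that occurred
  between 1950 and the year of measurement so that samples measured in
  different years are comparable::

      Δ14C = (Fm · exp(λ·(1950 − y)) − 1) · 1000,   λ = 1/8267 yr⁻¹

* the conventional radiocarbon age (years BP), which by convention uses the
  Libby mean life::

      age = −8033 · ln(Fm),   σ_age = 8033 · σ_Fm / Fm

Samples with Fm ≥ 1 carry post-1950 "bomb pulse" carbon and receive the
label ``Modern`` (or ``>Modern`` when Fm is greater than 1 by more than one
analytical σ) instead of a numeric age.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .errors import InputIOError, InvalidMeasurementError, InvalidYearError, OutOfRangeError

__all__ = [
    "LAMBDA_14C",
    "LIBBY_MEAN_LIFE",
    "REFERENCE_YEAR",
    "FM_MIN",
    "ModernClass",
    "RadiocarbonMeasurement",
    "RadiocarbonReport",
    "fm_to_delta14c",
    "delta14c_to_fm",
    "fm_to_age",
    "classify_modern",
    "round_reported",
    "report_measurement",
    "read_measurements",
    "convert_table",
]

#: True (Cambridge) 14C decay constant, 1/yr — used for decay-corrected Δ14C.
LAMBDA_14C = 1.0 / 8267.0

#: Libby mean life (yr) — used for the conventional radiocarbon age.
LIBBY_MEAN_LIFE = 8033.0

#: Radiocarbon reference year (defines "before present").
REFERENCE_YEAR = 1950

#: Fm values below this are beyond measurement background and rejected.
FM_MIN = 1e-6

#: Default decay-correction year when a measurement does not state one
#: (the groundwater collection year).
DEFAULT_YEAR = 2011


class ModernClass(str, enum.Enum):
    """Reporting class of a radiocarbon result."""

    NUMERIC_AGE = "numeric-age"
    MODERN = "Modern"
    GREATER_THAN_MODERN = "greater-than-Modern"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


def _check_fm(fm: float) -> None:
    if not (fm > 0) or fm < FM_MIN:
        raise InvalidMeasurementError(
            f"fraction modern must be positive and >= {FM_MIN}; got {fm!r}"
        )


def _check_year(year: float) -> None:
    if year < REFERENCE_YEAR:
        raise InvalidYearError(f"measurement year must be >= {REFERENCE_YEAR}; got {year!r}")


@dataclass(frozen=True)
class RadiocarbonMeasurement:
    """One AMS result: fraction modern ± 1σ plus measurement metadata.

    ``d13c_permil`` is carried as metadata only: the −20 ± 2‰ fractionation
    correction is applied by the AMS facility upstream, so ``fraction_modern``
    is already the corrected F14C.
    """

    sample_id: str
    fraction_modern: float
    fm_sigma: float
    year_measured: int = DEFAULT_YEAR
    d13c_permil: float = -20.0
    d13c_sigma: float = 2.0
    carbon_mass_ug: Optional[float] = None
    label: str = ""

    def __post_init__(self) -> None:
        _check_fm(self.fraction_modern)
        if self.fm_sigma < 0:
            raise InvalidMeasurementError(f"fm_sigma must be >= 0; got {self.fm_sigma!r}")
        _check_year(self.year_measured)


@dataclass(frozen=True)
class RadiocarbonReport:
    """Derived reporting quantities for one measurement.

    ``age_years``/``age_sigma`` are the reporting-rounded values and are
    present iff ``modern_class`` is ``numeric-age``; the unrounded values are
    kept in ``raw_age``/``raw_age_sigma``.
    """

    delta14c_permil: float
    delta14c_sigma: float
    modern_class: ModernClass
    age_years: Optional[float] = None
    age_sigma: Optional[float] = None
    raw_age: Optional[float] = None
    raw_age_sigma: Optional[float] = None
    sample_id: str = ""

    def __post_init__(self) -> None:
        if (self.age_years is not None) != (self.modern_class is ModernClass.NUMERIC_AGE):
            raise ValueError("age_years must be present iff modern_class is numeric-age")
        if self.delta14c_sigma < 0:
            raise ValueError("delta14c_sigma must be >= 0")
        if self.age_sigma is not None and self.age_sigma < 0:
            raise ValueError("age_sigma must be >= 0")


def fm_to_delta14c(fm: float, sigma: float, year: float = DEFAULT_YEAR) -> tuple[float, float]:
    """Decay-corrected Δ14C (‰) and its 1σ from fraction modern.

    Parameters
    ----------
    fm, sigma
        Fraction modern and its 1σ analytical uncertainty.
    year
        Calendar year of the AMS measurement (>= 1950). The correction
        removes 14C decay between 1950 and this year.

    Returns
    -------
    (delta14c, delta14c_sigma) in ‰.
    """
    _check_fm(fm)
    if sigma < 0:
        raise InvalidMeasurementError(f"sigma must be >= 0; got {sigma!r}")
    _check_year(year)
    decay = math.exp(LAMBDA_14C * (REFERENCE_YEAR - year))
    return (fm * decay - 1.0) * 1000.0, 1000.0 * sigma * decay


def delta14c_to_fm(delta: float, year: float = DEFAULT_YEAR) -> float:
    """Inverse of :func:`fm_to_delta14c` (point value only)."""
    if delta <= -1000.0:
        raise OutOfRangeError(f"delta14c must be > -1000 permil; got {delta!r}")
    _check_year(year)
    decay = math.exp(LAMBDA_14C * (REFERENCE_YEAR - year))
    return (delta / 1000.0 + 1.0) / decay


def fm_to_age(
    fm: float,
    sigma: float,
    *,
    modern_sigmas: float = 1.0,
    rounding: bool = True,
) -> RadiocarbonReport:
    """Conventional radiocarbon age from fraction modern.

    age = −8033·ln(Fm); σ_age = 8033·σ_Fm/Fm. Samples with Fm ≥ 1 receive a
    Modern / >Modern class and no numeric age. The raw (unrounded) age is
    always retained; ``rounding`` controls whether the reported age is
    rounded per :func:`round_reported`.
    """
    _check_fm(fm)
    if sigma < 0:
        raise InvalidMeasurementError(f"sigma must be >= 0; got {sigma!r}")
    cls = classify_modern(fm, sigma, sigmas=modern_sigmas)
    if cls is not ModernClass.NUMERIC_AGE:
        return RadiocarbonReport(
            delta14c_permil=float("nan"), delta14c_sigma=0.0, modern_class=cls
        )
    raw_age = -LIBBY_MEAN_LIFE * math.log(fm)
    raw_sigma = LIBBY_MEAN_LIFE * sigma / fm
    if rounding:
        rep_age, rep_sigma = round_reported(raw_age, raw_sigma)
    else:
        rep_age, rep_sigma = raw_age, raw_sigma
    return RadiocarbonReport(
        delta14c_permil=float("nan"),
        delta14c_sigma=0.0,
        modern_class=cls,
        age_years=rep_age,
        age_sigma=rep_sigma,
        raw_age=raw_age,
        raw_age_sigma=raw_sigma,
    )


def classify_modern(fm: float, sigma: float, *, sigmas: float = 1.0) -> ModernClass:
    """Reporting class from Fm and its analytical σ.

    Default rule: Fm < 1 → numeric age; Fm ≥ 1 but within ``sigmas``·σ of 1 →
    Modern; Fm − ``sigmas``·σ > 1 → >Modern.
    """
    _check_fm(fm)
    if sigma < 0:
        raise InvalidMeasurementError(f"sigma must be >= 0; got {sigma!r}")
    if fm < 1.0:
        return ModernClass.NUMERIC_AGE
    if fm - sigmas * sigma > 1.0:
        return ModernClass.GREATER_THAN_MODERN
    return ModernClass.MODERN


def round_reported(
    value: float,
    sigma: float,
    *,
    coarse_threshold: float = 20000.0,
    fine_step: int = 5,
    coarse_step: int = 10,
) -> tuple[float, float]:
    """Round an age (or similar quantity) and its σ for reporting.

    Default rule: nearest ``fine_step`` (5 yr) below ``coarse_threshold``,
    nearest ``coarse_step`` (10 yr) above; σ rounded with the same step.
    Raw values should be kept alongside — this is presentation only.
    """
    if sigma < 0:
        raise InvalidMeasurementError(f"sigma must be >= 0; got {sigma!r}")
    step = fine_step if abs(value) < coarse_threshold else coarse_step
    return float(step * round(value / step)), float(step * round(sigma / step))


def report_measurement(
    m: RadiocarbonMeasurement, *, rounding: bool = True, modern_sigmas: float = 1.0
) -> RadiocarbonReport:
    """Full report (Δ14C, age, Modern class) for one measurement."""
    delta, dsigma = fm_to_delta14c(m.fraction_modern, m.fm_sigma, m.year_measured)
    age_part = fm_to_age(
        m.fraction_modern, m.fm_sigma, modern_sigmas=modern_sigmas, rounding=rounding
    )
    return RadiocarbonReport(
        delta14c_permil=delta,
        delta14c_sigma=dsigma,
        modern_class=age_part.modern_class,
        age_years=age_part.age_years,
        age_sigma=age_part.age_sigma,
        raw_age=age_part.raw_age,
        raw_age_sigma=age_part.raw_age_sigma,
        sample_id=m.sample_id,
    )


# ---------------------------------------------------------------------------
# Tabular I/O


def read_measurements(
    path: str | Path, *, default_year: int = DEFAULT_YEAR
) -> list[RadiocarbonMeasurement]:
    """Read a delimited measurement table (comma or tab separated).

    Required columns: ``sample_id, fraction_modern, fm_sigma``. Optional:
    ``year_measured`` (default ``default_year``), ``d13c``, ``carbon_ug``,
    ``label``.
    """
    path = Path(path)
    if not path.exists():
        raise InputIOError(f"measurement table not found: {path}")
    try:
        df = pd.read_csv(path, sep=None, engine="python")
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise InputIOError(f"could not parse measurement table {path}: {exc}") from exc
    required = {"sample_id", "fraction_modern", "fm_sigma"}
    missing = required - set(df.columns)
    if missing:
        raise InputIOError(f"measurement table {path} missing columns: {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        year = getattr(row, "year_measured", None)
        if year is None or pd.isna(year):
            year = default_year
        out.append(
            RadiocarbonMeasurement(
                sample_id=str(row.sample_id),
                fraction_modern=float(row.fraction_modern),
                fm_sigma=float(row.fm_sigma),
                year_measured=int(year),
                d13c_permil=float(getattr(row, "d13c", -20.0) or -20.0),
                carbon_mass_ug=(
                    float(row.carbon_ug)
                    if "carbon_ug" in df.columns and not pd.isna(row.carbon_ug)
                    else None
                ),
                label=str(getattr(row, "label", "") or ""),
            )
        )
    return out


def convert_table(
    measurements: Iterable[RadiocarbonMeasurement],
    *,
    rounding: bool = True,
    modern_sigmas: float = 1.0,
) -> pd.DataFrame:
    """Convert measurements to a report table mirroring a lab summary table.

    Columns: sample id, fraction modern ± σ, Δ14C ± σ, and either the
    conventional age ± σ or the Modern class.
    """
    rows = []
    for m in measurements:
        r = report_measurement(m, rounding=rounding, modern_sigmas=modern_sigmas)
        rows.append(
            {
                "sample_id": m.sample_id,
                "fraction_modern": m.fraction_modern,
                "fm_sigma": m.fm_sigma,
                "delta14c": r.delta14c_permil,
                "delta14c_sigma": r.delta14c_sigma,
                "age_years": r.age_years,
                "age_sigma": r.age_sigma,
                "modern_class": r.modern_class.value,
            }
        )
    return pd.DataFrame(rows)
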