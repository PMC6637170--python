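"""Two-end-member Δ14C mixing: apportioning RNA carbon between autotrophy
and heterotrophy.

Model
-----
Community RNA carbon is assumed to be a linear combination of an inorganic
pool assimilated by autotrophs (DIC) and one organic pool assimilated by
heterotrophs (DOC or SOC). Writing Δ_S for the sample RNA Δ14C, Δ_A for the
DIC end-member and Δ_B for the organic end-member, the autotrophic fraction
is::

    f = (Δ_S − Δ_B) / (Δ_A − Δ_B)

A pairing is only physically interpretable when Δ_S lies between the two
end-member means (e.g. buried plant material, more 14C-enriched than both
the DIC and the sample, cannot be paired with DIC).

Uncertainty is propagated two ways, which cross-check one another:

* first-order (delta-method) error propagation through the ratio, and
* Monte Carlo: Gaussian draws for the sample and both end-members, with the
  empirical percentile interval of the per-draw fractions.

End-member σ for sediment and plant pools is the printed between-sample SD,
treated by default as end-member heterogeneity (no √n shrinkage; set
``shrink_sigma=True`` to use standard errors instead).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DegenerateEndmembersError, InputIOError, OutOfRangeError

__all__ = [
    "EndMember",
    "Validity",
    "MixingResult",
    "mixing_fraction",
    "check_validity",
    "delta_method_sigma",
    "mc_uncertainty",
    "apportion_all_pairs",
    "infer_het_endmember",
    "read_endmembers",
    "read_sample",
    "CarbonSourceMixingModel",
    "MixingFitResults",
]

#: end-member intervals narrower than this (‰) are degenerate
_DEGENERATE_WIDTH = 1e-9


@dataclass(frozen=True)
class EndMember:
    """A carbon pool's Δ14C distribution: mean ± σ (‰), from n samples."""

    name: str
    delta14c_permil: float
    sigma_permil: float = 0.0
    n_samples: int = 1

    def __post_init__(self) -> None:
        if self.sigma_permil < 0:
            raise ValueError(f"sigma_permil must be >= 0; got {self.sigma_permil!r}")
        if self.n_samples < 1:
            raise ValueError(f"n_samples must be >= 1; got {self.n_samples!r}")


class Validity(str, enum.Enum):
    VALID = "valid"
    SAMPLE_OUTSIDE_INTERVAL = "sample-outside-interval"
    DEGENERATE_ENDMEMBERS = "degenerate-endmembers"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class MixingResult:
    """Apportioned autotrophy fraction for one end-member pairing.

    ``f_autotrophy`` is never clamped: out-of-interval samples yield a value
    outside [0, 1] together with ``validity = sample-outside-interval``.
    """

    pair_name: str
    f_autotrophy: float
    validity: Validity
    method: str  # "point" | "monte-carlo"
    sigma_f: Optional[float] = None
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    ci_level: float = 0.95
    n_draws: Optional[int] = None
    frac_draws_outside: Optional[float] = None
    mc_mean: Optional[float] = None

    def __post_init__(self) -> None:
        if self.validity is Validity.VALID and self.ci_low is not None:
            if not (self.ci_low <= self.f_autotrophy <= self.ci_high):
                raise ValueError("CI must bracket the point estimate")

    @property
    def percent(self) -> float:
        """Autotrophy as a percent, rounded to one decimal (reporting)."""
        return round(100.0 * self.f_autotrophy, 1)


def _delta(x) -> float:
    return x.delta14c_permil if isinstance(x, EndMember) else float(x)


def _sigma(x) -> float:
    return x.sigma_permil if isinstance(x, EndMember) else 0.0


def _check_distinct(dic, org) -> None:
    if abs(_delta(dic) - _delta(org)) <= _DEGENERATE_WIDTH:
        raise DegenerateEndmembersError(
            f"end-members coincide at {_delta(dic)!r} permil; fraction undefined"
        )


def mixing_fraction(sample_delta: float, dic, org) -> float:
    """Autotrophic fraction f = (Δ_S − Δ_B)/(Δ_A − Δ_B).

    ``dic``/``org`` may be :class:`EndMember` or bare ‰ values. The result is
    not clamped; pair with :func:`check_validity`.
    """
    _check_distinct(dic, org)
    return (float(sample_delta) - _delta(org)) / (_delta(dic) - _delta(org))


def check_validity(sample_delta: float, dic, org) -> Validity:
    """Whether the sample lies within the closed end-member interval."""
    a, b = _delta(dic), _delta(org)
    if abs(a - b) <= _DEGENERATE_WIDTH:
        return Validity.DEGENERATE_ENDMEMBERS
    lo, hi = min(a, b), max(a, b)
    if lo <= float(sample_delta) <= hi:
        return Validity.VALID
    return Validity.SAMPLE_OUTSIDE_INTERVAL


def delta_method_sigma(sample_delta: float, sample_sigma: float, dic: EndMember, org: EndMember) -> float:
    """First-order propagated σ of the mixing fraction.

    With f = (S−B)/(A−B):  σ_f² = σ_S²/(A−B)² + σ_A²(S−B)²/(A−B)⁴
    + σ_B²(S−A)²/(A−B)⁴.
    """
    _check_distinct(dic, org)
    if sample_sigma < 0:
        raise ValueError("sample_sigma must be >= 0")
    a, b, s = dic.delta14c_permil, org.delta14c_permil, float(sample_delta)
    w = a - b
    var = (
        (sample_sigma / w) ** 2
        + (dic.sigma_permil * (s - b) / w**2) ** 2
        + (org.sigma_permil * (s - a) / w**2) ** 2
    )
    return math.sqrt(var)


def _effective_sigma(em: EndMember, shrink: bool) -> float:
    return em.sigma_permil / math.sqrt(em.n_samples) if shrink else em.sigma_permil


def mc_uncertainty(
    sample_delta: float,
    sample_sigma: float,
    dic: EndMember,
    org: EndMember,
    *,
    n_draws: int = 100_000,
    seed: Optional[int] = None,
    ci_level: float = 0.95,
    shrink_sigma: bool = False,
    rng: Optional[np.random.Generator] = None,
) -> MixingResult:
    """Monte-Carlo mixing fraction with an empirical percentile interval.

    Gaussian draws for the sample and both end-members; the fraction is
    computed per draw. Draws falling outside [0, 1] are retained in the
    distribution (clamping would bias the interval) but their share is
    reported in ``frac_draws_outside``.
    """
    if n_draws < 1000:
        raise ValueError("n_draws must be >= 1000 for a stable percentile interval")
    _check_distinct(dic, org)
    if rng is None:
        rng = np.random.default_rng(seed)
    s = rng.normal(float(sample_delta), sample_sigma, n_draws)
    a = rng.normal(dic.delta14c_permil, _effective_sigma(dic, shrink_sigma), n_draws)
    b = rng.normal(org.delta14c_permil, _effective_sigma(org, shrink_sigma), n_draws)
    width = a - b
    ok = np.abs(width) > _DEGENERATE_WIDTH
    f = (s[ok] - b[ok]) / width[ok]
    point = mixing_fraction(sample_delta, dic, org)
    alpha = (1.0 - ci_level) / 2.0
    if sample_sigma == 0 and dic.sigma_permil == 0 and org.sigma_permil == 0:
        lo = hi = point
        sd = 0.0
        mc_mean = point
    else:
        lo, hi = np.quantile(f, [alpha, 1.0 - alpha])
        sd = float(np.std(f, ddof=1))
        mc_mean = float(np.mean(f))
    outside = float(np.mean((f < 0) | (f > 1)))
    return MixingResult(
        pair_name=f"{dic.name}-{org.name}",
        f_autotrophy=point,
        validity=check_validity(sample_delta, dic, org),
        method="monte-carlo",
        sigma_f=sd,
        ci_low=float(min(lo, point)),
        ci_high=float(max(hi, point)),
        ci_level=ci_level,
        n_draws=n_draws,
        frac_draws_outside=outside,
        mc_mean=mc_mean,
    )


def apportion_all_pairs(
    sample_delta: float,
    sample_sigma: float,
    endmembers: Sequence[EndMember],
    dic_name: str = "DIC",
    *,
    n_draws: int = 100_000,
    seed: Optional[int] = None,
    ci_level: float = 0.95,
    shrink_sigma: bool = False,
    method: str = "monte-carlo",
) -> list[MixingResult]:
    """One :class:`MixingResult` per non-DIC end-member.

    Each pairing carries its own validity (e.g. the plant pool, more
    enriched than both DIC and sample, yields ``sample-outside-interval``).
    """
    by_name = {em.name: em for em in endmembers}
    if dic_name not in by_name:
        raise ConfigurationError(
            f"DIC end-member {dic_name!r} not in table: {sorted(by_name)}"
        )
    dic = by_name[dic_name]
    rng = np.random.default_rng(seed)
    results = []
    for em in endmembers:
        if em.name == dic_name:
            continue
        if method == "monte-carlo":
            results.append(
                mc_uncertainty(
                    sample_delta,
                    sample_sigma,
                    dic,
                    em,
                    n_draws=n_draws,
                    ci_level=ci_level,
                    shrink_sigma=shrink_sigma,
                    rng=rng,
                )
            )
        else:
            f = mixing_fraction(sample_delta, dic, em)
            sd = delta_method_sigma(sample_delta, sample_sigma, dic, em)
            results.append(
                MixingResult(
                    pair_name=f"{dic.name}-{em.name}",
                    f_autotrophy=f,
                    validity=check_validity(sample_delta, dic, em),
                    method="point",
                    sigma_f=sd,
                )
            )
    return results


def infer_het_endmember(f_community: float, sample_delta: float, dic) -> float:
    """Back-solve the organic end-member Δ14C implied by a taxonomy-based
    autotrophy fraction: Δ_B = (Δ_S − f·Δ_A)/(1 − f).

    Plugging the result back into :func:`mixing_fraction` recovers
    ``f_community``.
    """
    if not (0.0 <= f_community < 1.0):
        raise OutOfRangeError(
            f"f_community must be in [0, 1); got {f_community!r} (f = 1 leaves no "
            "heterotrophic carbon to attribute)"
        )
    return (float(sample_delta) - f_community * _delta(dic)) / (1.0 - f_community)


# ---------------------------------------------------------------------------
# I/O helpers


def read_endmembers(path: str | Path) -> list[EndMember]:
    """Read an end-member table: columns ``name, delta14c, sigma, n``."""
    path = Path(path)
    if not path.exists():
        raise InputIOError(f"end-member table not found: {path}")
    df = pd.read_csv(path, sep=None, engine="python")
    missing = {"name", "delta14c"} - set(df.columns)
    if missing:
        raise InputIOError(f"end-member table {path} missing columns: {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        out.append(
            EndMember(
                name=str(row.name),
                delta14c_permil=float(row.delta14c),
                sigma_permil=float(getattr(row, "sigma", 0.0) or 0.0),
                n_samples=int(getattr(row, "n", 1) or 1),
            )
        )
    return out


def read_sample(path: str | Path) -> tuple[str, float, float]:
    """Read a one-row sample table (``name, delta14c, sigma``)."""
    path = Path(path)
    if not path.exists():
        raise InputIOError(f"sample table not found: {path}")
    df = pd.read_csv(path, sep=None, engine="python")
    if "delta14c" not in df.columns or len(df) == 0:
        raise InputIOError(f"sample table {path} needs a delta14c column and one row")
    row = df.iloc[0]
    return str(row.get("name", "sample")), float(row["delta14c"]), float(row.get("sigma", 0.0))


# ---------------------------------------------------------------------------
# Model / Results


class CarbonSourceMixingModel:
    """Two-end-member carbon-source apportionment model for one RNA sample.

    Parameters
    ----------
    sample_delta, sample_sigma
        Δ14C of the community RNA (‰) and its 1σ.
    endmembers
        Candidate carbon pools; must include the inorganic (DIC) pool named
        ``dic_name``.
    sample_name
        Label used in summaries.

    Examples
    --------
    >>> from rnacarbon import datasets, CarbonSourceMixingModel
    >>> model = CarbonSourceMixingModel.from_files(
    ...     datasets.path("rifle_sample.csv"), datasets.path("rifle_endmembers.csv"))
    >>> res = model.fit(seed=0)
    >>> print(res.summary())  # doctest: +SKIP
    """

    def __init__(
        self,
        sample_delta: float,
        sample_sigma: float,
        endmembers: Sequence[EndMember],
        dic_name: str = "DIC",
        sample_name: str = "sample",
    ) -> None:
        names = [em.name for em in endmembers]
        if len(set(names)) != len(names):
            raise ConfigurationError(f"duplicate end-member names: {names}")
        if dic_name not in names:
            raise ConfigurationError(f"DIC end-member {dic_name!r} not among {names}")
        self.sample_delta = float(sample_delta)
        self.sample_sigma = float(sample_sigma)
        self.endmembers = list(endmembers)
        self.dic_name = dic_name
        self.sample_name = sample_name

    @classmethod
    def from_files(
        cls, sample_path: str | Path, endmember_path: str | Path, dic_name: str = "DIC"
    ) -> "CarbonSourceMixingModel":
        name, delta, sigma = read_sample(sample_path)
        return cls(delta, sigma, read_endmembers(endmember_path), dic_name, sample_name=name)

    @classmethod
    def from_dataframes(
        cls, sample: pd.DataFrame, endmembers: pd.DataFrame, dic_name: str = "DIC"
    ) -> "CarbonSourceMixingModel":
        row = sample.iloc[0]
        ems = [
            EndMember(
                str(r["name"]),
                float(r["delta14c"]),
                float(r.get("sigma", 0.0)),
                int(r.get("n", 1)),
            )
            for _, r in endmembers.iterrows()
        ]
        return cls(
            float(row["delta14c"]),
            float(row.get("sigma", 0.0)),
            ems,
            dic_name,
            sample_name=str(row.get("name", "sample")),
        )

    @property
    def dic(self) -> EndMember:
        return next(em for em in self.endmembers if em.name == self.dic_name)

    def fit(
        self,
        method: str = "monte-carlo",
        *,
        n_draws: int = 100_000,
        seed: Optional[int] = None,
        ci_level: float = 0.95,
        shrink_sigma: bool = False,
    ) -> "MixingFitResults":
        """Apportion the sample against every organic end-member.

        ``method`` is ``"monte-carlo"`` (percentile CI) or ``"point"``
        (delta-method σ only).
        """
        if method not in ("monte-carlo", "point"):
            raise ConfigurationError(f"unknown method {method!r}")
        results = apportion_all_pairs(
            self.sample_delta,
            self.sample_sigma,
            self.endmembers,
            self.dic_name,
            n_draws=n_draws,
            seed=seed,
            ci_level=ci_level,
            shrink_sigma=shrink_sigma,
            method=method,
        )
        return MixingFitResults(self, results, method=method, seed=seed)


class MixingFitResults:
    """Fit results: one apportionment per DIC-organic pairing.

    Attributes
    ----------
    results : list of MixingResult
    """

    def __init__(
        self,
        model: CarbonSourceMixingModel,
        results: list[MixingResult],
        method: str,
        seed: Optional[int],
    ) -> None:
        self.model = model
        self.results = results
        self.method = method
        self.seed = seed

    def __iter__(self):
        return iter(self.results)

    def by_pair(self, pair_name: str) -> MixingResult:
        for r in self.results:
            if r.pair_name == pair_name:
                return r
        raise KeyError(pair_name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "pair": [r.pair_name for r in self.results],
                "f_autotrophy": [r.f_autotrophy for r in self.results],
                "percent": [r.percent for r in self.results],
                "sigma_f": [r.sigma_f for r in self.results],
                "ci_low": [r.ci_low for r in self.results],
                "ci_high": [r.ci_high for r in self.results],
                "validity": [r.validity.value for r in self.results],
            }
        )

    def infer_heterotroph_endmember(self, f_community: float) -> tuple[float, str]:
        """Organic-pool Δ14C implied by an independent (taxonomy-based)
        autotrophy fraction, and the name of the closest non-DIC end-member.
        """
        implied = infer_het_endmember(f_community, self.model.sample_delta, self.model.dic)
        organics = [em for em in self.model.endmembers if em.name != self.model.dic_name]
        closest = min(organics, key=lambda em: abs(em.delta14c_permil - implied))
        return implied, closest.name

    def summary(self) -> str:
        m = self.model
        lines = [
            "Two-end-member Delta14C carbon-source apportionment",
            "=" * 55,
            f"Sample: {m.sample_name}  Delta14C = {m.sample_delta:.1f} +/- {m.sample_sigma:.1f} permil",
            f"DIC end-member: {m.dic.delta14c_permil:.1f} +/- {m.dic.sigma_permil:.1f} permil",
            f"Method: {self.method}"
            + (f" (n_draws={self.results[0].n_draws}, seed={self.seed})"
               if self.results and self.results[0].n_draws else ""),
            "",
            f"{'pair':<12}{'% autotrophy':>14}{'sigma_f':>10}{'CI':>20}{'validity':>26}",
        ]
        for r in self.results:
            ci = (
                f"[{100*r.ci_low:.1f}, {100*r.ci_high:.1f}]"
                if r.ci_low is not None
                else "--"
            )
            sd = f"{100*r.sigma_f:.1f}" if r.sigma_f is not None else "--"
            lines.append(
                f"{r.pair_name:<12}{r.percent:>14.1f}{sd:>10}{ci:>20}{r.validity.value:>26}"
            )
        return "\n".join(lines)
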