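"""The paired-analysis report: isotope- and taxonomy-based autotrophy
estimates for the same RNA sample, combined.

The two estimates address the same question from independent data: the
mixing model apportions the RNA's radiocarbon between the DIC pool and each
candidate organic pool, while the community summary sums the relative
abundance of taxa annotated as lithoautotrophs. When the two agree, the
taxonomy-based fraction can be back-substituted into the mixing equation to
infer which organic pool the heterotrophs actually used: the report names
the end-member whose Δ14C lies closest to the implied value.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .community import (
    CommunitySummary,
    DenominatorMode,
    TaxonRecord,
    annotate,
    filter_min_abundance,
    top_n,
    trophic_fraction,
)
from .errors import ConfigurationError
from .mixing import CarbonSourceMixingModel, EndMember, MixingFitResults, MixingResult

__all__ = ["PairedReport", "run_paired_analysis", "render_report"]


@dataclass(frozen=True)
class PairedReport:
    """Combined isotope + taxonomy carbon-source report for one sample."""

    sample_name: str
    sample_delta14c: float
    isotope_estimates: tuple[MixingResult, ...]
    community_estimate: CommunitySummary
    inferred_het_delta14c: float
    concordant_pair: str  # organic end-member closest to the inferred value


def run_paired_analysis(
    sample_delta: float,
    sample_sigma: float,
    endmembers: Sequence[EndMember],
    records: Sequence[TaxonRecord],
    annotations: Optional[pd.DataFrame] = None,
    *,
    dic_name: str = "DIC",
    min_abundance: Optional[float] = 0.001,
    top_n_taxa: Optional[int] = None,
    denominator_mode: DenominatorMode | str = DenominatorMode.TOTAL_COMMUNITY,
    n_draws: int = 100_000,
    seed: Optional[int] = None,
    sample_name: str = "sample",
) -> PairedReport:
    """Run mixing (all pairs) + community summary and combine them.

    Taxa are selected by ``top_n_taxa`` when given, otherwise by
    ``min_abundance``; the resulting lithoautotroph fraction feeds the
    back-solved heterotroph end-member.
    """
    model = CarbonSourceMixingModel(
        sample_delta, sample_sigma, endmembers, dic_name, sample_name=sample_name
    )
    fit = model.fit(n_draws=n_draws, seed=seed)

    if annotations is not None:
        records = annotate(records, annotations)
    if top_n_taxa is not None:
        subset = top_n(records, top_n_taxa)
        selection = f"top-{top_n_taxa}"
    elif min_abundance is not None:
        subset = filter_min_abundance(records, min_abundance)
        selection = f"abundance >= {min_abundance:g}"
    else:
        raise ConfigurationError("either top_n_taxa or min_abundance must be given")
    community = trophic_fraction(subset, denominator_mode, selection=selection)

    f_comm = community.autotroph_fraction
    implied, closest = fit.infer_heterotroph_endmember(f_comm)
    return PairedReport(
        sample_name=sample_name,
        sample_delta14c=float(sample_delta),
        isotope_estimates=tuple(fit.results),
        community_estimate=community,
        inferred_het_delta14c=implied,
        concordant_pair=closest,
    )


def _report_dict(report: PairedReport) -> dict:
    return {
        "sample": report.sample_name,
        "sample_delta14c_permil": report.sample_delta14c,
        "isotope_estimates": [
            {
                "pair": r.pair_name,
                "f_autotrophy": r.f_autotrophy,
                "percent_autotrophy": r.percent,
                "sigma_f": r.sigma_f,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "ci_level": r.ci_level,
                "validity": r.validity.value,
                "method": r.method,
                "n_draws": r.n_draws,
                "frac_draws_outside": r.frac_draws_outside,
            }
            for r in report.isotope_estimates
        ],
        "community_estimate": {
            "selection": report.community_estimate.selection,
            "n_taxa": report.community_estimate.n_taxa,
            "cumulative_abundance": report.community_estimate.cumulative_abundance,
            "autotroph_fraction": report.community_estimate.autotroph_fraction,
            "autotroph_percent": report.community_estimate.autotroph_percent,
            "unknown_fraction": report.community_estimate.unknown_fraction,
            "denominator_mode": report.community_estimate.denominator_mode.value,
            "mean_identity": report.community_estimate.mean_identity,
        },
        "inferred_het_delta14c_permil": report.inferred_het_delta14c,
        "concordant_pair": report.concordant_pair,
    }


def render_report(report: PairedReport, format: str = "json") -> str:
    """Serialize a report: ``json`` (full precision) or ``text`` (rounded)."""
    if format == "json":
        return json.dumps(_report_dict(report), indent=2)
    if format == "text":
        lines = [
            f"Paired carbon-source report for {report.sample_name}",
            "=" * 60,
            f"RNA Delta14C: {report.sample_delta14c:.1f} permil",
            "",
            "Isotope-based autotrophy estimates:",
        ]
        for r in report.isotope_estimates:
            extra = (
                f"  CI [{100*r.ci_low:.1f}, {100*r.ci_high:.1f}]%"
                if r.ci_low is not None
                else ""
            )
            lines.append(f"  {r.pair_name:<12} {r.percent:6.1f}%  ({r.validity.value}){extra}")
        c = report.community_estimate
        lines += [
            "",
            f"Taxonomy-based estimate ({c.selection}, {c.denominator_mode.value}):",
            f"  lithoautotrophs: {c.autotroph_percent:.1f}% "
            f"({c.n_taxa} taxa, cumulative abundance {100*c.cumulative_abundance:.1f}%)",
            "",
            f"Heterotroph end-member implied by the taxonomy-based fraction: "
            f"{report.inferred_het_delta14c:.1f} permil",
            f"Closest organic pool: {report.concordant_pair}",
        ]
        return "\n".join(lines)
    raise ConfigurationError(f"unknown report format {format!r}")
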