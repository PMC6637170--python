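"""Trophic-fraction estimation over reconstructed-16S relative-abundance
tables.

The input is the output of a templated 16S reconstruction (one row per
reconstructed taxon with its relative abundance) plus a user-supplied
trophic annotation (taxon id → lithoautotroph / heterotroph / unknown,
optionally with the % identity to the best-matching characterized isolate).
The module selects taxa (top-N or a minimum-abundance threshold), sums
lithoautotroph abundance, and reports the autotroph fraction against either
the whole community or the selected subset — the two readings of
"fraction of the population" — together with coverage statistics and the
rank-cumulative abundance curves.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .errors import InputIOError, ValidationError

__all__ = [
    "TrophicLabel",
    "TaxonRecord",
    "CommunitySummary",
    "load_abundance_table",
    "load_annotations",
    "annotate",
    "filter_min_abundance",
    "top_n",
    "trophic_fraction",
    "cumulative_curve",
    "taxa_count_coverage",
]


class TrophicLabel(str, enum.Enum):
    LITHOAUTOTROPH = "lithoautotroph"
    HETEROTROPH = "heterotroph"
    UNKNOWN = "unknown"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class DenominatorMode(str, enum.Enum):
    TOTAL_COMMUNITY = "total-community"
    SELECTED_SUBSET = "selected-subset"


@dataclass(frozen=True)
class TaxonRecord:
    """One reconstructed 16S taxon."""

    taxon_id: str
    taxon_name: str
    relative_abundance: float
    best_match_identity: Optional[float] = None  # percent, [0, 100]
    trophic_label: TrophicLabel = TrophicLabel.UNKNOWN

    def __post_init__(self) -> None:
        if not (0.0 <= self.relative_abundance <= 1.0):
            raise ValidationError(
                f"relative abundance of {self.taxon_id!r} outside [0, 1]: "
                f"{self.relative_abundance!r}"
            )
        if self.best_match_identity is not None and not (
            0.0 <= self.best_match_identity <= 100.0
        ):
            raise ValidationError(
                f"best_match_identity of {self.taxon_id!r} outside [0, 100]"
            )


@dataclass(frozen=True)
class CommunitySummary:
    """Aggregate trophic statistics for a selected set of taxa."""

    selection: str
    n_taxa: int
    cumulative_abundance: float
    autotroph_fraction: float
    unknown_fraction: float
    denominator_mode: DenominatorMode
    mean_identity: Optional[float] = None

    @property
    def autotroph_percent(self) -> float:
        return round(100.0 * self.autotroph_fraction, 1)


def load_abundance_table(
    path: str | Path,
    fasta_path: Optional[str | Path] = None,
) -> list[TaxonRecord]:
    """Read a delimited abundance table (``taxon_id, name, relative_abundance``).

    Records are returned sorted by descending abundance. Abundances summing
    to > 1.5 are auto-detected as percentages and divided by 100 (with a
    warning). When ``fasta_path`` is given, its sequence ids must be a
    superset of the table's taxon ids; missing ids produce a warning listing
    them.
    """
    path = Path(path)
    if not path.exists():
        raise InputIOError(f"abundance table not found: {path}")
    df = pd.read_csv(path, sep=None, engine="python")
    missing = {"taxon_id", "relative_abundance"} - set(df.columns)
    if missing:
        raise InputIOError(f"abundance table {path} missing columns: {sorted(missing)}")
    if "name" not in df.columns:
        df["name"] = df["taxon_id"]
    dup = df["taxon_id"][df["taxon_id"].duplicated()]
    if len(dup):
        raise ValidationError(f"duplicate taxon ids in {path}: {sorted(set(dup.astype(str)))}")
    ab = df["relative_abundance"].astype(float)
    total = ab.sum()
    if total > 1.5:
        warnings.warn(
            f"abundances in {path} sum to {total:.3g} > 1.5; interpreting as percentages",
            stacklevel=2,
        )
        ab = ab / 100.0
        total = ab.sum()
    if total > 1.0 + 1e-6:
        raise ValidationError(f"abundances in {path} sum to {total!r} > 1")
    records = [
        TaxonRecord(str(tid), str(name), float(a))
        for tid, name, a in zip(df["taxon_id"], df["name"], ab)
    ]
    records.sort(key=lambda r: (-r.relative_abundance, r.taxon_id))
    if fasta_path is not None:
        from Bio import SeqIO

        fasta_ids = {rec.id for rec in SeqIO.parse(str(fasta_path), "fasta")}
        absent = sorted(r.taxon_id for r in records if r.taxon_id not in fasta_ids)
        if absent:
            warnings.warn(
                f"{len(absent)} taxon ids missing from FASTA {fasta_path}: {absent}",
                stacklevel=2,
            )
    return records


def load_annotations(path: str | Path) -> pd.DataFrame:
    """Read a trophic-annotation table (``taxon_id, trophic_label``,
    optional ``best_match_identity``)."""
    path = Path(path)
    if not path.exists():
        raise InputIOError(f"annotation table not found: {path}")
    df = pd.read_csv(path, sep=None, engine="python")
    missing = {"taxon_id", "trophic_label"} - set(df.columns)
    if missing:
        raise InputIOError(f"annotation table {path} missing columns: {sorted(missing)}")
    bad = set(df["trophic_label"].astype(str)) - {l.value for l in TrophicLabel}
    if bad:
        raise ValidationError(f"unknown trophic labels in {path}: {sorted(bad)}")
    return df


def annotate(records: Sequence[TaxonRecord], annotations: pd.DataFrame) -> list[TaxonRecord]:
    """Attach trophic labels (and identities) to abundance records.

    Taxa absent from the annotation table keep the ``unknown`` label; a
    warning lists them.
    """
    by_id = {
        str(r.taxon_id): (
            TrophicLabel(str(r.trophic_label)),
            None
            if "best_match_identity" not in annotations.columns or pd.isna(r.best_match_identity)
            else float(r.best_match_identity),
        )
        for r in annotations.itertuples(index=False)
    }
    out, unlabelled = [], []
    for rec in records:
        if rec.taxon_id in by_id:
            label, ident = by_id[rec.taxon_id]
            out.append(
                TaxonRecord(rec.taxon_id, rec.taxon_name, rec.relative_abundance, ident, label)
            )
        else:
            unlabelled.append(rec.taxon_id)
            out.append(rec)
    if unlabelled:
        warnings.warn(
            f"{len(unlabelled)} taxa without trophic annotation treated as unknown: "
            f"{unlabelled[:10]}{'...' if len(unlabelled) > 10 else ''}",
            stacklevel=2,
        )
    return out


def filter_min_abundance(records: Sequence[TaxonRecord], threshold: float) -> list[TaxonRecord]:
    """Taxa with relative abundance >= ``threshold`` (inclusive), order kept."""
    if not (0.0 <= threshold <= 1.0):
        raise ValidationError(f"threshold must be in [0, 1]; got {threshold!r}")
    return [r for r in records if r.relative_abundance >= threshold]


def top_n(records: Sequence[TaxonRecord], n: int) -> list[TaxonRecord]:
    """The ``n`` most abundant taxa; ties broken by taxon_id."""
    if n < 0:
        raise ValidationError(f"n must be >= 0; got {n!r}")
    ordered = sorted(records, key=lambda r: (-r.relative_abundance, r.taxon_id))
    return ordered[:n]


def trophic_fraction(
    subset: Sequence[TaxonRecord],
    denominator_mode: DenominatorMode | str = DenominatorMode.TOTAL_COMMUNITY,
    *,
    selection: str = "",
    identity_weighting: str = "unweighted",
) -> CommunitySummary:
    """Lithoautotroph abundance fraction over a selected set of taxa.

    ``denominator_mode`` chooses the denominator: 1.0 (``total-community``,
    reading "of the population" as the whole community) or the subset's
    cumulative abundance (``selected-subset``). Unknown-labelled abundance is
    reported separately; ``mean_identity`` averages best-match identity over
    the lithoautotroph records (``identity_weighting`` = ``unweighted`` or
    ``abundance``).
    """
    mode = DenominatorMode(denominator_mode)
    cum = sum(r.relative_abundance for r in subset)
    if mode is DenominatorMode.SELECTED_SUBSET and (not subset or cum == 0):
        raise ValidationError("selected-subset mode needs a non-empty subset")
    auto = [r for r in subset if r.trophic_label is TrophicLabel.LITHOAUTOTROPH]
    auto_ab = sum(r.relative_abundance for r in auto)
    unknown_ab = sum(
        r.relative_abundance for r in subset if r.trophic_label is TrophicLabel.UNKNOWN
    )
    denom = 1.0 if mode is DenominatorMode.TOTAL_COMMUNITY else cum
    idents = [(r.best_match_identity, r.relative_abundance) for r in auto
              if r.best_match_identity is not None]
    mean_ident: Optional[float] = None
    if idents:
        if identity_weighting == "abundance":
            wsum = sum(w for _, w in idents)
            mean_ident = sum(i * w for i, w in idents) / wsum if wsum else None
        else:
            mean_ident = sum(i for i, _ in idents) / len(idents)
    return CommunitySummary(
        selection=selection or f"{len(subset)} taxa",
        n_taxa=len(subset),
        cumulative_abundance=cum,
        autotroph_fraction=auto_ab / denom if denom else 0.0,
        unknown_fraction=unknown_ab / denom if denom else 0.0,
        denominator_mode=mode,
        mean_identity=mean_ident,
    )


def cumulative_curve(records: Sequence[TaxonRecord]) -> pd.DataFrame:
    """Rank-cumulative abundance of all taxa and of lithoautotrophs only.

    Expects records sorted by descending abundance (as produced by the
    loader). Returns columns ``rank, cumulative_abundance,
    cumulative_lithoautotroph_abundance``; both curves are nondecreasing and
    the lithoautotroph curve never exceeds the all-taxon curve.
    """
    rows = []
    cum = cum_auto = 0.0
    for rank, r in enumerate(records, start=1):
        cum += r.relative_abundance
        if r.trophic_label is TrophicLabel.LITHOAUTOTROPH:
            cum_auto += r.relative_abundance
        rows.append((rank, cum, cum_auto))
    return pd.DataFrame(
        rows, columns=["rank", "cumulative_abundance", "cumulative_lithoautotroph_abundance"]
    )


def taxa_count_coverage(
    records: Sequence[TaxonRecord], threshold: float
) -> tuple[int, float]:
    """Number of taxa at/above an abundance threshold and their summed
    abundance (the "N taxa covering X% of the community" statistic)."""
    if threshold > 1.0:
        return 0, 0.0
    kept = filter_min_abundance(records, threshold)
    return len(kept), sum(r.relative_abundance for r in kept)
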