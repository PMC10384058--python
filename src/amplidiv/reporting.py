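"""Summary tables: diversity counts, per-family breakdowns with
percentage shares, species-count histograms and top-N lists.

Percentages are rounded half-up to two decimals, matching the
convention of printed summary tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .clustering import ClusterAssignment
from .ecology import EcologySummary
from .records import RANKS

FAMILY_RANK = RANKS.index("family")

HISTOGRAM_BINS = ("1", "2-10", "11-50", ">=51")


@dataclass(frozen=True)
class Percentage:
    value: float
    text: str


def percentage(part: int, whole: int) -> Percentage:
    """100 * part / whole, rounded half-up to 2 decimals."""
    if whole <= 0:
        raise ValueError("percentage of a zero or negative whole is undefined")
    if not (0 <= part <= whole):
        raise ValueError(f"part {part} outside [0, {whole}]")
    value = Decimal(100 * part) / Decimal(whole)
    rounded = value.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP)
    return Percentage(value=float(rounded), text=f"{rounded}%")


@dataclass
class DiversityReport:
    """Known vs predicted counts per rank, with per-family breakdowns."""

    overall: pd.DataFrame
    genera_per_family: pd.DataFrame
    species_per_family: pd.DataFrame


def _family_of(assignment: ClusterAssignment, label: str) -> str:
    name = assignment.label_lineage.get(label, ("",) * len(RANKS))[FAMILY_RANK]
    return name if name else "Unknown families"


def diversity_table(
    assignment: ClusterAssignment,
    retained: set[str],
    known_taxa: Mapping[str, Mapping[str, Sequence[str]]] | None = None,
) -> DiversityReport:
    """Count distinct fOTU/gOTU/sOTU labels overall and restricted to
    the retained (>= abundance threshold) sOTU set, plus per-family
    genus and species breakdowns with percentage shares.

    ``known_taxa`` maps family -> genus -> list of species names of the
    described reference taxonomy; absent, known counts are zero.
    """
    known = known_taxa or {}
    fotus = sorted(set(assignment.fotu.values()))
    gotus = sorted(set(assignment.gotu.values()))
    sotus = sorted(set(assignment.sotu.values()))
    sotu_to_gotu: dict[str, str] = {}
    sotu_to_fotu: dict[str, str] = {}
    for rid, s_label in assignment.sotu.items():
        sotu_to_gotu[s_label] = assignment.gotu[rid]
        sotu_to_fotu[s_label] = assignment.fotu[rid]
    retained_sotus = [s for s in sotus if s in retained]
    retained_gotus = sorted({sotu_to_gotu[s] for s in retained_sotus})
    retained_fotus = sorted({sotu_to_fotu[s] for s in retained_sotus})

    overall = pd.DataFrame(
        {
            "known": [
                len(known),
                sum(len(g) for g in known.values()),
                sum(len(sp) for g in known.values() for sp in g.values()),
            ],
            "predicted": [len(fotus), len(gotus), len(sotus)],
            "predicted_ge_threshold": [len(retained_fotus), len(retained_gotus), len(retained_sotus)],
        },
        index=["families", "genera", "species"],
    )

    def breakdown(labels: Iterable[str], retained_labels: Iterable[str]) -> pd.DataFrame:
        labels = list(labels)
        retained_labels = set(retained_labels)
        fams = sorted({_family_of(assignment, l) for l in labels})
        rows = []
        total = len(labels)
        total_ret = len([l for l in labels if l in retained_labels])
        for fam in fams:
            in_fam = [l for l in labels if _family_of(assignment, l) == fam]
            ret = [l for l in in_fam if l in retained_labels]
            rows.append(
                {
                    "family": fam,
                    "predicted": len(in_fam),
                    "predicted_pct": percentage(len(in_fam), total).value if total else 0.0,
                    "predicted_ge_threshold": len(ret),
                    "predicted_ge_threshold_pct": (
                        percentage(len(ret), total_ret).value if total_ret else 0.0
                    ),
                }
            )
        return pd.DataFrame(
            rows,
            columns=["family", "predicted", "predicted_pct", "predicted_ge_threshold", "predicted_ge_threshold_pct"],
        )

    return DiversityReport(
        overall=overall,
        genera_per_family=breakdown(gotus, retained_gotus),
        species_per_family=breakdown(sotus, retained_sotus),
    )


def species_histogram(
    assignment: ClusterAssignment,
    level: str = "genus",
    retained: set[str] | None = None,
) -> dict[str, int]:
    """Bin species counts per genus- or family-level taxon into
    {1, 2-10, 11-50, >=51}; taxa without retained species are omitted.
    Counts of exactly 51 fall in the top bin."""
    if level not in ("genus", "family"):
        raise ValueError("level must be 'genus' or 'family'")
    parent = assignment.gotu if level == "genus" else assignment.fotu
    species_of: dict[str, set[str]] = {}
    for rid, s_label in assignment.sotu.items():
        if retained is not None and s_label not in retained:
            continue
        species_of.setdefault(parent[rid], set()).add(s_label)
    bins = dict.fromkeys(HISTOGRAM_BINS, 0)
    for taxa_species in species_of.values():
        n = len(taxa_species)
        if n == 1:
            bins["1"] += 1
        elif n <= 10:
            bins["2-10"] += 1
        elif n <= 50:
            bins["11-50"] += 1
        else:
            bins[">=51"] += 1
    return bins


def top_tables(
    summaries: Sequence[EcologySummary],
    n: int = 20,
    assignment: ClusterAssignment | None = None,
    species_names: Mapping[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Top-N sOTUs by prevalence (positive samples) and by maximum
    abundance; ties break by sOTU label."""
    if n < 1:
        raise ValueError("n must be >= 1")
    names = species_names or {}

    def row(s: EcologySummary) -> dict:
        fam = gen = ""
        if assignment is not None and s.sotu in assignment.label_lineage:
            lin = assignment.label_lineage[s.sotu]
            fam = lin[FAMILY_RANK] or ""
            gen = lin[RANKS.index("genus")] or ""
        return {
            "family": fam,
            "genus": gen,
            "species": names.get(s.sotu, "Unknown species"),
            "sOTU": s.sotu,
            "n_positive": s.n_positive,
            "n_positive_ge_threshold": s.n_positive_ge_threshold,
            "prevalence_environment": s.dominant_environment,
            "max_abundance_environment": s.max_abundance_environment,
            "max_abundance": s.max_abundance,
        }

    by_prevalence = sorted(summaries, key=lambda s: (-s.n_positive, s.sotu))[:n]
    by_abundance = sorted(summaries, key=lambda s: (-s.max_abundance, s.sotu))[:n]
    cols = [
        "family", "genus", "species", "sOTU", "n_positive", "n_positive_ge_threshold",
        "prevalence_environment", "max_abundance_environment", "max_abundance",
    ]
    return (
        pd.DataFrame([row(s) for s in by_prevalence], columns=cols),
        pd.DataFrame([row(s) for s in by_abundance], columns=cols),
    )


def render_markdown(table: pd.DataFrame) -> str:
    """Plain-text Markdown rendering of a summary table."""
    cols = [str(c) for c in table.columns]
    lines = ["| " + " | ".join(cols) + " |", "| " + " | ".join("---" for _ in cols) + " |"]
    for _, row in table.iterrows():
        lines.append("| " + " | ".join(str(v) for v in row.tolist()) + " |")
    return "\n".join(lines)
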