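"""Environment categorisation and per-sOTU ecological summaries.

Raw sample descriptions are mapped onto a fixed set of environment
categories (saline water, freshwater, soil, air, plant, host, their
saline-water counterparts, bioreactor); manually assembled laboratory
systems are excluded from every statistic.  Per sOTU the module counts
positive samples (abundance > 0), samples at or above the relative-
abundance threshold (default 0.1%), the dominant environment among
positive samples, the maximum abundance and its environment, and flags
cosmopolitan sOTUs (detected in at least ``cosmopolitan_min`` samples,
default 50).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

CATEGORY_ORDER = (
    "saline water",
    "freshwater",
    "soil",
    "air",
    "plant",
    "host",
    "plant saline water",
    "host saline water",
    "bioreactor",
    "other",
)
EXCLUDED = "excluded"

_EXCLUDED_MARKERS = ("laboratory", "lab-cultivated", "manually assembled", "polymer surface", "in vitro")
_BIOREACTOR_MARKERS = (
    "sludge", "wastewater", "bioreactor", "reactor", "digester", "fermentation", "anammox", "wwtp",
)
_SALINE_MARKERS = (
    "marine", "seawater", "sea water", "ocean", "saline", "estuar", "coastal", "beach",
    "saltern", "hypersaline", "salt marsh", "tidal",
)
_SALINE_IMPLICIT = ("sponge", "coral", "seagrass", "kelp", "macroalga", "algal mat")
_HOST_MARKERS = (
    "gut", "feces", "fecal", "faecal", "intestin", "skin", "sponge", "coral", "mussel",
    "oyster", "host", "animal", "human", "mouse", "insect", "fish", "gill", "rumen",
)
_PLANT_MARKERS = (
    "plant", "leaf", "root", "rhizosphere", "phyllosphere", "seagrass", "kelp", "macroalga",
    "algal", "algae", "moss",
)
_FRESHWATER_MARKERS = ("freshwater", "lake", "river", "pond", "stream", "groundwater", "spring water")
_SOIL_MARKERS = ("soil", "permafrost", "compost", "agricultural field", "desert")
_AIR_MARKERS = ("air", "aerosol", "dust")


@dataclass(frozen=True)
class SampleRecord:
    sample_id: str
    raw_label: str
    category: str


def categorize_environment(raw_label: str) -> str:
    """Deterministic keyword mapping from a free-text sample label to an
    environment category; unmatched labels map to ``other`` with a
    logged warning, lab-assembled systems to ``excluded``."""
    text = raw_label.lower()

    def has(markers: Iterable[str]) -> bool:
        return any(m in text for m in markers)

    if has(_EXCLUDED_MARKERS):
        return EXCLUDED
    if has(_BIOREACTOR_MARKERS):
        return "bioreactor"
    saline = has(_SALINE_MARKERS) or has(_SALINE_IMPLICIT)
    host = has(_HOST_MARKERS)
    plant = has(_PLANT_MARKERS)
    if host and saline:
        return "host saline water"
    if plant and saline:
        return "plant saline water"
    if host:
        return "host"
    if plant:
        return "plant"
    if saline:
        return "saline water"
    if has(_FRESHWATER_MARKERS):
        return "freshwater"
    if has(_SOIL_MARKERS):
        return "soil"
    if has(_AIR_MARKERS):
        return "air"
    logger.warning("unrecognised environment label %r mapped to 'other'", raw_label)
    return "other"


def categorize_samples(samples: pd.DataFrame) -> list[SampleRecord]:
    """Apply :func:`categorize_environment` to a (sample_id, raw_label)
    table."""
    return [
        SampleRecord(sample_id=str(row.sample_id), raw_label=str(row.raw_label),
                     category=categorize_environment(str(row.raw_label)))
        for row in samples.itertuples()
    ]


@dataclass
class EcologySummary:
    sotu: str
    n_positive: int
    n_positive_ge_threshold: int
    dominant_environment: str
    max_abundance: float
    max_abundance_environment: str
    cosmopolitan: bool


def _active(samples: Sequence[SampleRecord]) -> list[SampleRecord]:
    return [s for s in samples if s.category != EXCLUDED]


def compute_positivity(
    abundance: pd.DataFrame,
    samples: Sequence[SampleRecord],
    order_sotus: Iterable[str] | None = None,
) -> dict[str, float]:
    """Fraction of samples per environment category in which any target
    sOTU is present (abundance > 0).  Excluded samples are ignored,
    categories without samples are omitted; key ``overall`` covers all
    non-excluded samples."""
    cols = list(order_sotus) if order_sotus is not None else list(abundance.columns)
    cols = [c for c in cols if c in abundance.columns]
    active = [s for s in _active(samples) if s.sample_id in abundance.index]
    positive = (abundance.loc[[s.sample_id for s in active], cols] > 0).any(axis=1) if cols else pd.Series(
        False, index=[s.sample_id for s in active]
    )
    out: dict[str, float] = {}
    totals: dict[str, int] = {}
    pos: dict[str, int] = {}
    for s in active:
        totals[s.category] = totals.get(s.category, 0) + 1
        if bool(positive.loc[s.sample_id]):
            pos[s.category] = pos.get(s.category, 0) + 1
    for cat in CATEGORY_ORDER:
        if cat in totals:
            out[cat] = pos.get(cat, 0) / totals[cat]
    out["overall"] = (sum(pos.values()) / len(active)) if active else 0.0
    return out


def summarize_sotu_ecology(
    abundance: pd.DataFrame,
    samples: Sequence[SampleRecord],
    threshold: float = 0.001,
    cosmopolitan_min: int = 50,
    *,
    dominant_over_threshold_only: bool = False,
) -> list[EcologySummary]:
    """Per-sOTU prevalence and abundance summary over non-excluded
    samples.

    Dominant environment is the modal category among positive samples
    (optionally only samples at >= threshold); ties resolve to the
    category with the higher summed abundance, then fixed category
    order.  Threshold comparisons use >= ("at least 0.1%").
    """
    if threshold <= 0 or cosmopolitan_min <= 0:
        raise ValueError("threshold and cosmopolitan_min must be positive")
    active = [s for s in _active(samples) if s.sample_id in abundance.index]
    cat_of = {s.sample_id: s.category for s in active}
    sub = abundance.loc[[s.sample_id for s in active]]
    out: list[EcologySummary] = []
    for sotu in abundance.columns:
        col = sub[sotu]
        pos = col[col > 0]
        n_positive = int((col > 0).sum())
        n_ge = int((col >= threshold).sum())
        if n_positive == 0:
            out.append(EcologySummary(sotu, 0, 0, "", 0.0, "", False))
            continue
        basis = pos[pos >= threshold] if dominant_over_threshold_only else pos
        counts: dict[str, int] = {}
        sums: dict[str, float] = {}
        for sid, val in basis.items():
            cat = cat_of[sid]
            counts[cat] = counts.get(cat, 0) + 1
            sums[cat] = sums.get(cat, 0.0) + float(val)
        if counts:
            dominant = min(
                counts,
                key=lambda c: (-counts[c], -sums[c], CATEGORY_ORDER.index(c)),
            )
        else:
            dominant = ""
        # idxmax on the positive subset; ties resolve to the first sample
        # in matrix order, which is fixed by construction
        max_sid = pos.idxmax()
        out.append(
            EcologySummary(
                sotu=sotu,
                n_positive=n_positive,
                n_positive_ge_threshold=n_ge,
                dominant_environment=dominant,
                max_abundance=float(pos.loc[max_sid]),
                max_abundance_environment=cat_of[max_sid],
                cosmopolitan=n_positive >= cosmopolitan_min,
            )
        )
    return out


def filter_by_abundance(summaries: Sequence[EcologySummary], threshold: float = 0.001) -> set[str]:
    """sOTUs reaching the abundance threshold in at least one sample."""
    return {s.sotu for s in summaries if s.n_positive_ge_threshold >= 1}


def summaries_to_frame(summaries: Sequence[EcologySummary]) -> pd.DataFrame:
    rows = [
        {
            "sOTU": s.sotu,
            "n_positive": s.n_positive,
            "n_positive_ge_threshold": s.n_positive_ge_threshold,
            "dominant_environment": s.dominant_environment,
            "max_abundance": s.max_abundance,
            "max_abundance_environment": s.max_abundance_environment,
            "cosmopolitan": int(s.cosmopolitan),
        }
        for s in summaries
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "sOTU", "n_positive", "n_positive_ge_threshold", "dominant_environment",
            "max_abundance", "max_abundance_environment", "cosmopolitan",
        ],
    )
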