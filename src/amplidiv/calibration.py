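"""Similarity-cutoff calibration from described reference species.

Fixed 16S similarity cutoffs (97/95/90% for species/genus/family on the
full gene) do not transfer to arbitrary subregions.  The cutoffs used
for clustering are therefore re-derived for the selected region as the
mean pairwise identity among reference species that share a genus
(species cutoff), share a family but not a genus (genus cutoff), or
belong to different families (family cutoff), each rounded to two
decimals.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Sequence

from .identity import pairwise_identity
from .records import RANKS, Lineage

FAMILY_RANK = RANKS.index("family")
GENUS_RANK = RANKS.index("genus")


@dataclass(frozen=True)
class ReferenceSpecies:
    """A described species with its region-trimmed ungapped sequence."""

    name: str
    lineage: Lineage
    sequence: str

    def __post_init__(self) -> None:
        if not self.lineage[FAMILY_RANK] or not self.lineage[GENUS_RANK]:
            raise ValueError(f"reference {self.name!r} must be annotated to genus level")

    @property
    def family(self) -> str:
        return self.lineage[FAMILY_RANK]

    @property
    def genus(self) -> str:
        return self.lineage[GENUS_RANK]


@dataclass(frozen=True)
class CutoffSet:
    """Species/genus/family clustering cutoffs for the selected region."""

    species_cutoff: float
    genus_cutoff: float
    family_cutoff: float

    def __post_init__(self) -> None:
        if not (0 < self.family_cutoff <= self.genus_cutoff <= self.species_cutoff <= 1):
            raise ValueError(
                "cutoffs must satisfy 0 < family <= genus <= species <= 1, got "
                f"{self.family_cutoff}/{self.genus_cutoff}/{self.species_cutoff}"
            )

    def to_json(self, path: str | Path, pair_counts: dict[str, int] | None = None) -> None:
        payload = {
            "species": self.species_cutoff,
            "genus": self.genus_cutoff,
            "family": self.family_cutoff,
        }
        if pair_counts:
            payload["pair_counts"] = pair_counts
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "CutoffSet":
        payload = json.loads(Path(path).read_text())
        return cls(payload["species"], payload["genus"], payload["family"])


def _round2(x: float) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def calibrate_cutoffs(
    refs: Sequence[ReferenceSpecies],
) -> tuple[CutoffSet, dict[str, int]]:
    """Derive the three cutoffs from all reference species pairs.

    Each pair contributes to exactly one stratum according to shared
    genus / shared family / different families; the per-stratum
    unweighted mean identity, rounded to 2 decimals, is the cutoff.
    Raises when a stratum has no pairs or the means are not ordered.
    """
    sums = {"species": 0.0, "genus": 0.0, "family": 0.0}
    counts = {"species": 0, "genus": 0, "family": 0}
    for a, b in itertools.combinations(refs, 2):
        ident = pairwise_identity(a.sequence, b.sequence)
        if a.genus == b.genus and a.family == b.family:
            stratum = "species"
        elif a.family == b.family:
            stratum = "genus"
        else:
            stratum = "family"
        sums[stratum] += ident
        counts[stratum] += 1
    for stratum in ("species", "genus", "family"):
        if counts[stratum] == 0:
            raise ValueError(f"no reference pairs in the {stratum!r} stratum")
    means = {k: sums[k] / counts[k] for k in sums}
    if not (means["species"] > means["genus"] > means["family"]):
        raise ValueError(
            "reference identities are not ordered species > genus > family: "
            f"{means}"
        )
    cutoffs = CutoffSet(
        species_cutoff=_round2(means["species"]),
        genus_cutoff=_round2(means["genus"]),
        family_cutoff=_round2(means["family"]),
    )
    return cutoffs, counts
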