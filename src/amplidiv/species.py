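"""Assignment of described species names to molecular species (sOTUs).

Each reference species is mapped to its best-identity sOTU
representative; the mapping counts only when the identity reaches the
assignment threshold (default 98%).  References that are not separable
over the selected region land on the same sOTU, which then carries the
slash-merged name (e.g. ``Neolewinella marina/litorea``).  sOTUs with
no mapped reference are reported as ``Unknown species``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .calibration import ReferenceSpecies
from .identity import pairwise_identity

UNKNOWN = "Unknown species"


@dataclass(frozen=True)
class SpeciesAssignment:
    sotu: str
    assigned_name: str
    identity: float
    merged: bool


def _merge_names(names: Sequence[str]) -> str:
    """Slash-join species names in input order; when all share the
    genus word, epithets are merged under a single genus."""
    if len(names) == 1:
        return names[0]
    split = [n.split(" ", 1) for n in names]
    genera = {s[0] for s in split}
    if len(genera) == 1 and all(len(s) == 2 for s in split):
        return split[0][0] + " " + "/".join(s[1] for s in split)
    return "/".join(names)


def assign_known_species(
    representatives: Mapping[str, str],
    refs: Sequence[ReferenceSpecies],
    threshold: float = 0.98,
    *,
    strictly_above: bool = False,
) -> list[SpeciesAssignment]:
    """Name sOTUs after reference species matching at high identity.

    Every reference is assigned to at most one sOTU (its best hit; ties
    broken by sOTU label order).  ``strictly_above`` switches the
    acceptance rule from >= threshold to > threshold.
    """
    labels = sorted(representatives)
    hits: dict[str, list[tuple[str, float]]] = {}
    for ref in refs:
        best_label, best_ident = None, -1.0
        for label in labels:
            ident = pairwise_identity(ref.sequence, representatives[label])
            if ident > best_ident:
                best_label, best_ident = label, ident
        accepted = best_ident > threshold if strictly_above else best_ident >= threshold
        if best_label is not None and accepted:
            hits.setdefault(best_label, []).append((ref.name, best_ident))
    out = []
    for label in labels:
        matched = hits.get(label)
        if matched:
            names = [name for name, _ in matched]
            out.append(
                SpeciesAssignment(
                    sotu=label,
                    assigned_name=_merge_names(names),
                    identity=max(ident for _, ident in matched),
                    merged=len(matched) > 1,
                )
            )
        else:
            out.append(SpeciesAssignment(sotu=label, assigned_name=UNKNOWN, identity=math.nan, merged=False))
    return out


def assignments_to_frame(assignments: Sequence[SpeciesAssignment]) -> pd.DataFrame:
    rows = [
        {"sOTU": a.sotu, "name": a.assigned_name, "identity": a.identity, "merged": int(a.merged)}
        for a in assignments
    ]
    return pd.DataFrame(rows, columns=["sOTU", "name", "identity", "merged"])
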