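"""Taxonomy-informed hierarchical incremental clustering (fOTU/gOTU/sOTU).

Sequences are first binned by their annotated taxonomy down to genus, so
clusters can never mix sequences whose annotations disagree.  Inside
each bin a greedy incremental pass clusters sequences at the family
cutoff (fOTUs); each fOTU is re-clustered at the genus cutoff (gOTUs)
and each gOTU at the species cutoff (sOTUs).  Every cluster keeps its
founding sequence as the fixed representative, and membership requires
identity to the representative at or above the level's cutoff.

The greedy pass processes entries in a canonical order — multiplicity
descending, length descending, id ascending — and attaches each entry
to the first acceptable representative ("first match"; a best-match
variant is available), which makes the whole procedure deterministic
and invariant to input order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .calibration import CutoffSet
from .identity import pairwise_identity
from .records import RANKS, Lineage

GENUS_DEPTH = RANKS.index("genus") + 1
UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class SequenceEntry:
    """A trimmed, ungapped sequence entering clustering."""

    id: str
    bases: str
    lineage: Lineage = ("",) * len(RANKS)
    multiplicity: int = 1
    sample_abundances: Mapping[str, float] | None = None


def canonical_order(entries: Iterable[SequenceEntry]) -> list[SequenceEntry]:
    return sorted(entries, key=lambda e: (-e.multiplicity, -len(e.bases), e.id))


def bin_by_taxonomy(entries: Sequence[SequenceEntry]) -> dict[tuple[str, ...], list[SequenceEntry]]:
    """Partition entries by annotated taxonomy down to genus.

    The bin key is the lineage truncated at the deepest nonempty rank
    (at most genus); entries unannotated below that depth fall into an
    ``unclassified`` child bin of their deepest annotated ancestor, so
    novel clades cluster together without contaminating named bins.
    """
    bins: dict[tuple[str, ...], list[SequenceEntry]] = {}
    for entry in entries:
        ranks = list(entry.lineage[:GENUS_DEPTH])
        depth = 0
        for i, name in enumerate(ranks):
            if name:
                depth = i + 1
            else:
                break
        key = tuple(ranks[:depth])
        if depth < GENUS_DEPTH:
            key = key + (UNCLASSIFIED,)
        bins.setdefault(key, []).append(entry)
    return bins


@dataclass
class Cluster:
    representative: SequenceEntry
    members: list[SequenceEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.members:
            self.members = [self.representative]


def incremental_cluster(
    bin_entries: Sequence[SequenceEntry],
    cutoff: float,
    *,
    best_hit: bool = False,
) -> list[Cluster]:
    """Greedy incremental clustering of one taxonomy bin.

    Entries are processed in canonical order; each joins the first
    existing cluster whose representative it matches at >= cutoff
    (or the best-identity one with ``best_hit``), else founds a new
    cluster.
    """
    if not (0 < cutoff <= 1):
        raise ValueError("cutoff must be in (0, 1]")
    clusters: list[Cluster] = []
    for entry in canonical_order(bin_entries):
        target = None
        best = -1.0
        for cluster in clusters:
            ident = pairwise_identity(entry.bases, cluster.representative.bases)
            if ident >= cutoff:
                if not best_hit:
                    target = cluster
                    break
                if ident > best:
                    best, target = ident, cluster
        if target is None:
            clusters.append(Cluster(representative=entry))
        else:
            target.members.append(entry)
    return clusters


def oracle_cluster(bin_entries: Sequence[SequenceEntry], cutoff: float) -> list[Cluster]:
    """Reference implementation for small bins: materialise the full
    all-pairs identity matrix, then replay the greedy canonical-order
    process against it.  Must agree with :func:`incremental_cluster`."""
    if len(bin_entries) > 40:
        raise ValueError("oracle_cluster is restricted to bins of at most 40 entries")
    ordered = canonical_order(bin_entries)
    ident = {}
    for i, a in enumerate(ordered):
        for j, b in enumerate(ordered):
            if i < j:
                ident[(a.id, b.id)] = ident[(b.id, a.id)] = pairwise_identity(a.bases, b.bases)
    clusters: list[Cluster] = []
    for entry in ordered:
        target = None
        for cluster in clusters:
            if ident[(entry.id, cluster.representative.id)] >= cutoff:
                target = cluster
                break
        if target is None:
            clusters.append(Cluster(representative=entry))
        else:
            target.members.append(entry)
    return clusters


@dataclass
class ClusterAssignment:
    """Nested fOTU/gOTU/sOTU labels per sequence id."""

    fotu: dict[str, str] = field(default_factory=dict)
    gotu: dict[str, str] = field(default_factory=dict)
    sotu: dict[str, str] = field(default_factory=dict)
    representatives: dict[str, str] = field(default_factory=dict)
    label_lineage: dict[str, Lineage] = field(default_factory=dict)
    representative_bases: dict[str, str] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "id": rid,
                "fOTU": self.fotu[rid],
                "gOTU": self.gotu[rid],
                "sOTU": self.sotu[rid],
                "is_representative": int(
                    any(self.representatives.get(lbl) == rid for lbl in (self.fotu[rid], self.gotu[rid], self.sotu[rid]))
                ),
            }
            for rid in sorted(self.fotu)
        ]
        return pd.DataFrame(rows, columns=["id", "fOTU", "gOTU", "sOTU", "is_representative"])

    def n_fotus(self) -> int:
        return len(set(self.fotu.values()))

    def n_gotus(self) -> int:
        return len(set(self.gotu.values()))

    def n_sotus(self) -> int:
        return len(set(self.sotu.values()))


def _pad(prefix: str, ordinal: int) -> str:
    return f"{prefix}{ordinal:04d}"


def hierarchical_tic(
    entries: Sequence[SequenceEntry],
    cutoffs: CutoffSet,
    *,
    best_hit: bool = False,
) -> ClusterAssignment:
    """Full taxonomy-informed hierarchy: bins -> fOTUs -> gOTUs -> sOTUs.

    Labels are zero-padded ordinals (FOTU0001, ...) issued in canonical
    processing order (bins sorted by key, clusters in founding order),
    so the assignment is independent of input record order.  Each OTU
    label carries the annotated taxonomy of its bin.
    """
    assignment = ClusterAssignment()
    bins = bin_by_taxonomy(entries)
    n_f = n_g = n_s = 0
    for key in sorted(bins):
        bin_lineage = tuple(r for r in key if r != UNCLASSIFIED)
        bin_lineage = bin_lineage + ("",) * (len(RANKS) - len(bin_lineage))
        for fcluster in incremental_cluster(bins[key], cutoffs.family_cutoff, best_hit=best_hit):
            n_f += 1
            f_label = _pad("FOTU", n_f)
            assignment.representatives[f_label] = fcluster.representative.id
            assignment.representative_bases[f_label] = fcluster.representative.bases
            assignment.label_lineage[f_label] = bin_lineage
            for gcluster in incremental_cluster(fcluster.members, cutoffs.genus_cutoff, best_hit=best_hit):
                n_g += 1
                g_label = _pad("GOTU", n_g)
                assignment.representatives[g_label] = gcluster.representative.id
                assignment.representative_bases[g_label] = gcluster.representative.bases
                assignment.label_lineage[g_label] = bin_lineage
                for scluster in incremental_cluster(gcluster.members, cutoffs.species_cutoff, best_hit=best_hit):
                    n_s += 1
                    s_label = _pad("SOTU", n_s)
                    assignment.representatives[s_label] = scluster.representative.id
                    assignment.representative_bases[s_label] = scluster.representative.bases
                    assignment.label_lineage[s_label] = bin_lineage
                    for member in scluster.members:
                        assignment.fotu[member.id] = f_label
                        assignment.gotu[member.id] = g_label
                        assignment.sotu[member.id] = s_label
    return assignment


def validate_assignment(
    assignment: ClusterAssignment,
    entries: Sequence[SequenceEntry],
    cutoffs: CutoffSet,
) -> None:
    """Assert the structural invariants of a finished assignment:
    nesting of the three levels, taxonomy bounds, and member-to-
    representative identity at or above each level's cutoff."""
    by_id = {e.id: e for e in entries}
    sotu_to_gotu: dict[str, str] = {}
    gotu_to_fotu: dict[str, str] = {}
    for rid in assignment.sotu:
        s, g, f = assignment.sotu[rid], assignment.gotu[rid], assignment.fotu[rid]
        if sotu_to_gotu.setdefault(s, g) != g or gotu_to_fotu.setdefault(g, f) != f:
            raise AssertionError(f"nesting violated for {rid}")
        entry = by_id[rid]
        for label, cutoff in ((f, cutoffs.family_cutoff), (g, cutoffs.genus_cutoff), (s, cutoffs.species_cutoff)):
            rep = assignment.representative_bases[label]
            if pairwise_identity(entry.bases, rep) < cutoff:
                raise AssertionError(f"{rid} below cutoff {cutoff} to representative of {label}")
        lineage = assignment.label_lineage[f]
        for rank, name in enumerate(lineage):
            if name and entry.lineage[rank] and entry.lineage[rank] != name:
                raise AssertionError(f"taxonomy bound violated for {rid} at rank {RANKS[rank]}")
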