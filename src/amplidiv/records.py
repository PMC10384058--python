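"""Core record types and file I/O for aligned amplicon collections.

Sequences live in two representations: *gapped* rows of a fixed-width
multiple sequence alignment (characters over ``A C G T N -``) and
*ungapped* base strings obtained after trimming.  Taxonomy lineages are
tuples of rank names ordered domain -> phylum -> class -> order ->
family -> genus; trailing ranks may be empty strings when a sequence is
only partially classified.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

RANKS = ("domain", "phylum", "class", "order", "family", "genus")
GAP_CHARS = frozenset("-.")

Lineage = tuple[str, ...]


def lineage_from_string(text: str) -> Lineage:
    """Parse a semicolon-separated lineage into a six-rank tuple."""
    parts = [p.strip() for p in text.split(";")] if text else []
    parts = parts[: len(RANKS)]
    parts += [""] * (len(RANKS) - len(parts))
    return tuple(parts)


def lineage_to_string(lineage: Lineage) -> str:
    return ";".join(lineage)


@dataclass(frozen=True)
class AlignedRecord:
    """One gapped sequence row of the master alignment."""

    id: str
    columns: str
    lineage: Lineage = ("",) * len(RANKS)
    sample_id: str = ""

    def base_count(self) -> int:
        return sum(1 for c in self.columns if c not in GAP_CHARS)

    def ungapped(self) -> str:
        return "".join(c for c in self.columns if c not in GAP_CHARS)


def check_equal_width(records: Sequence[AlignedRecord]) -> int:
    """Return the shared alignment width, raising on any mismatch."""
    if not records:
        return 0
    width = len(records[0].columns)
    for rec in records:
        if len(rec.columns) != width:
            raise ValueError(
                f"alignment width mismatch: {rec.id} has {len(rec.columns)} "
                f"columns, expected {width}"
            )
    return width


# ---------------------------------------------------------------------------
# FASTA / TSV round-trips


def write_fasta(records: Iterable[AlignedRecord], path: str | Path, *, ungapped: bool = False) -> None:
    seqs = []
    for rec in records:
        seq = rec.ungapped() if ungapped else rec.columns
        seqs.append(SeqRecord(Seq(seq), id=rec.id, description=""))
    with open(path, "w") as fh:
        SeqIO.write(seqs, fh, "fasta-2line")


def read_fasta(path: str | Path, taxonomy: dict[str, Lineage] | None = None) -> list[AlignedRecord]:
    """Read (possibly gapped) FASTA; ids of the form ``seq<k>|<sample>``
    carry their source sample after the pipe."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        sample = rec.id.split("|", 1)[1] if "|" in rec.id else ""
        lin = (taxonomy or {}).get(rec.id, ("",) * len(RANKS))
        out.append(AlignedRecord(id=rec.id, columns=str(rec.seq).upper(), lineage=lin, sample_id=sample))
    return out


def write_taxonomy_tsv(records: Iterable[AlignedRecord], path: str | Path) -> None:
    rows = [{"id": r.id, "lineage": lineage_to_string(r.lineage)} for r in records]
    pd.DataFrame(rows, columns=["id", "lineage"]).to_csv(path, sep="\t", index=False)


def read_taxonomy_tsv(path: str | Path) -> dict[str, Lineage]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    return {row.id: lineage_from_string(row.lineage) for row in df.itertuples()}
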