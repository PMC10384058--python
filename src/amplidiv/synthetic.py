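"""Synthetic amplicon communities with planted hierarchical structure.

The generator emulates the inputs of an integrative 16S diversity
analysis: a family > genus > species hierarchy at controlled pairwise
identities, amplicon fragments targeting different subregions of a
common gapped alignment, variable fragment lengths, and per-sample
relative-abundance profiles over a range of environment labels.  Every
emitted fragment is traceable to exactly one planted species, giving
all downstream stages ground truth.

Mutation model
--------------
Sequences evolve by per-site substitutions on an ungapped master of
``region_length`` core bases (plus fixed flanks) embedded in a gapped
master alignment.  Each branch of the hierarchy (family, genus,
species) and each read owns a *disjoint* pool of core sites, so the
pairwise Hamming distance between any two sequences is the exact sum of
the substitution counts on their separating branches.  Two reads of the
same species differ at ~2r sites, reads of sister species at
2*k_s + ~2r, and so on; the per-branch counts r, k_s, k_g, k_f are
chosen so that those distances land on the configured identity targets.
Identity targets are therefore met exactly (up to rounding to whole
substitutions) rather than on average, and infeasible ladders are
rejected up front.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .records import RANKS, AlignedRecord, Lineage, write_fasta, write_taxonomy_tsv

BASES = np.array(list("ACGT"))
FLANK_BASES = 40
GAP_EVERY = 8  # one all-gap column after every 8 flank base columns
ORDER_LINEAGE = ("Bacteria", "Bacteroidota", "Saprospiria", "Saprospirales")

ENVIRONMENT_SYNONYMS: dict[str, tuple[str, ...]] = {
    "saline water": ("marine sediment", "seawater surface", "coastal lagoon water", "beach sand"),
    "freshwater": ("river water", "lake sediment", "pond water"),
    "soil": ("agricultural soil", "forest soil", "permafrost core"),
    "air": ("outdoor air filter", "urban aerosol"),
    "plant": ("plant leaf surface", "moss cushion"),
    "host": ("human gut metagenome", "mouse fecal pellet", "insect gut"),
    "plant saline water": ("seagrass leaf surface", "kelp blade", "marine algal mat"),
    "host saline water": ("marine sponge tissue", "coral mucus", "marine fish gill"),
    "bioreactor": ("activated sludge", "anaerobic digester", "wastewater treatment effluent"),
    "excluded": ("laboratory-cultivated photosynthetic mat", "biofilm on polymer surface in laboratory"),
}


class InfeasibleIdentityError(ValueError):
    """Raised when the identity ladder cannot be realised on
    region_length bases (targets too close or site budget exceeded)."""


@dataclass
class SimulationConfig:
    seed: int = 0
    n_families: int = 3
    genera_per_family: int = 3
    species_per_genus: int = 3
    region_length: int = 282
    within_species_identity: float = 0.99
    within_genus_identity: float = 0.96
    within_family_identity: float = 0.92
    across_family_identity: float = 0.90
    n_samples: int = 60
    environments: list[str] = field(default_factory=lambda: list(ENVIRONMENT_SYNONYMS))
    fragment_windows: list[tuple[int, int]] | None = None
    fragment_window_weights: list[float] | None = None
    short_fragment_rate: float = 0.05
    abundance_alpha: float = 0.3
    fragments_per_species: int = 18

    def __post_init__(self) -> None:
        idents = (
            self.within_species_identity,
            self.within_genus_identity,
            self.within_family_identity,
            self.across_family_identity,
        )
        if not all(0 < x <= 1 for x in idents):
            raise ValueError("identity targets must be in (0, 1]")
        if not (idents[0] > idents[1] > idents[2] > idents[3]):
            raise ValueError("identity ladder must be strictly ordered species > genus > family > across")
        for name in ("n_families", "genera_per_family", "species_per_genus", "region_length",
                     "n_samples", "fragments_per_species"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not (0 <= self.short_fragment_rate <= 1):
            raise ValueError("short_fragment_rate must be in [0, 1]")
        if self.abundance_alpha <= 0:
            raise ValueError("abundance_alpha must be positive")
        if not self.environments:
            raise ValueError("environments must be nonempty")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        if "fragment_windows" in payload and payload["fragment_windows"] is not None:
            payload["fragment_windows"] = [tuple(w) for w in payload["fragment_windows"]]
        return cls(**payload)

    def to_yaml(self, path: str | Path) -> None:
        payload = dataclasses.asdict(self)
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


@dataclass
class AlignmentLayout:
    """Column bookkeeping of the gapped master alignment."""

    width: int
    base_columns: np.ndarray  # column index of each ungapped master base
    n_core: int

    @property
    def n_bases(self) -> int:
        return int(self.base_columns.size)

    @property
    def core_slice(self) -> tuple[int, int]:
        """Half-open column interval spanned by the core region."""
        start = int(self.base_columns[FLANK_BASES])
        end = int(self.base_columns[FLANK_BASES + self.n_core - 1]) + 1
        return start, end

    def row_from_ungapped(self, seq: np.ndarray, base_mask: np.ndarray | None = None) -> str:
        row = np.full(self.width, "-", dtype="<U1")
        mask = base_mask if base_mask is not None else np.ones(self.n_bases, dtype=bool)
        row[self.base_columns[mask]] = seq[mask]
        return "".join(row)


def build_layout(region_length: int) -> AlignmentLayout:
    cols: list[int] = []
    col = 0

    def flank() -> None:
        nonlocal col
        for i in range(FLANK_BASES):
            cols.append(col)
            col += 1
            if (i + 1) % GAP_EVERY == 0:
                col += 1  # fixed all-gap column

    flank()
    for _ in range(region_length):
        cols.append(col)
        col += 1
    flank()
    return AlignmentLayout(width=col, base_columns=np.array(cols, dtype=np.int64), n_core=region_length)


def _substitution_counts(config: SimulationConfig) -> tuple[int, int, int, int]:
    """Per-branch substitution counts (read, species, genus, family)
    realising the identity ladder at the fragment level."""
    L = config.region_length
    t_s, t_g, t_f, t_x = (
        config.within_species_identity,
        config.within_genus_identity,
        config.within_family_identity,
        config.across_family_identity,
    )
    r = round(L * (1 - t_s) / 2)
    k_s = round((L * (1 - t_g) - 2 * r) / 2)
    k_g = round(L * (t_g - t_f) / 2)
    k_f = round(L * (t_f - t_x) / 2)
    if min(k_s, k_g, k_f) < 1:
        raise InfeasibleIdentityError(
            f"identity targets too close for region_length={L}: "
            f"per-branch substitution counts r={r}, k_s={k_s}, k_g={k_g}, k_f={k_f}"
        )
    # realized fragment-pair distances under disjoint site pools
    dist = {
        "species": 2 * r,
        "genus": 2 * k_s + 2 * r,
        "family": 2 * (k_s + k_g) + 2 * r,
        "across": 2 * (k_s + k_g + k_f) + 2 * r,
    }
    realized = {k: 1 - d / L for k, d in dist.items()}
    for name, target in (("species", t_s), ("genus", t_g), ("family", t_f), ("across", t_x)):
        if abs(realized[name] - target) > 0.015:
            raise InfeasibleIdentityError(
                f"cannot realise {name} identity {target} on {L} bases "
                f"(closest achievable: {realized[name]:.4f})"
            )
    budget = (
        config.n_families * k_f
        + config.n_families * config.genera_per_family * k_g
        + config.n_families * config.genera_per_family * config.species_per_genus * k_s
    )
    if budget + max(4 * r, 1) > L:
        raise InfeasibleIdentityError(
            f"hierarchy needs {budget} distinct substitution sites plus a read pool, "
            f"but the region has only {L} bases"
        )
    return r, k_s, k_g, k_f


@dataclass
class SyntheticDataset:
    """A complete planted dataset: fragments, truth labels, references,
    sample metadata and abundance profiles."""

    config: SimulationConfig
    layout: AlignmentLayout
    records: list[AlignedRecord]
    truth: dict[str, tuple[str, str, str]]
    reference_records: list[AlignedRecord]
    reference_names: dict[str, str]
    species_sequences: dict[str, np.ndarray]
    samples: pd.DataFrame | None = None
    abundance: pd.DataFrame | None = None
    read_pool: np.ndarray | None = None
    read_substitutions: int = 0

    def species_labels(self) -> list[str]:
        return sorted(self.species_sequences)


def _rng(config: SimulationConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stage])


def simulate_reference_hierarchy(config: SimulationConfig) -> SyntheticDataset:
    """Plant the family > genus > species hierarchy.

    Returns a dataset whose records are one full-length aligned row per
    planted species (these also serve as the reference set); fragments
    and abundance profiles are added by the companion operations.
    """
    r, k_s, k_g, k_f = _substitution_counts(config)
    layout = build_layout(config.region_length)
    rng = _rng(config, stage=1)

    master = rng.choice(BASES, size=layout.n_bases)
    perm = rng.permutation(config.region_length)
    cursor = 0

    def take(n: int) -> np.ndarray:
        nonlocal cursor
        sites = perm[cursor : cursor + n]
        cursor += n
        return sites

    def substitute(seq: np.ndarray, core_sites: np.ndarray) -> None:
        for site in core_sites:
            pos = FLANK_BASES + int(site)
            current = seq[pos]
            options = [b for b in "ACGT" if b != current]
            seq[pos] = options[int(rng.integers(len(options)))]

    records: list[AlignedRecord] = []
    names: dict[str, str] = {}
    species_seqs: dict[str, np.ndarray] = {}
    truth: dict[str, tuple[str, str, str]] = {}
    for fi in range(config.n_families):
        fam_label = f"F{fi + 1:02d}"
        fam_seq = master.copy()
        substitute(fam_seq, take(k_f))
        for gi in range(config.genera_per_family):
            gen_label = f"{fam_label}G{gi + 1:02d}"
            gen_seq = fam_seq.copy()
            substitute(gen_seq, take(k_g))
            for si in range(config.species_per_genus):
                sp_label = f"{gen_label}S{si + 1:02d}"
                sp_seq = gen_seq.copy()
                substitute(sp_seq, take(k_s))
                species_seqs[sp_label] = sp_seq
                ref_id = f"ref|{sp_label}"
                lineage: Lineage = ORDER_LINEAGE + (fam_label, gen_label)
                records.append(
                    AlignedRecord(id=ref_id, columns=layout.row_from_ungapped(sp_seq), lineage=lineage)
                )
                names[ref_id] = f"{gen_label} sp{si + 1:02d}"
                truth[ref_id] = (fam_label, gen_label, sp_label)

    return SyntheticDataset(
        config=config,
        layout=layout,
        records=records,
        truth=truth,
        reference_records=list(records),
        reference_names=names,
        species_sequences=species_seqs,
        read_pool=perm[cursor:].copy(),
        read_substitutions=r,
    )


def default_windows(layout: AlignmentLayout) -> list[tuple[int, int]]:
    """Two overlapping subregion windows whose intersection is the core:
    left flank + core, and core + right flank."""
    core_start, core_end = layout.core_slice
    return [(0, core_end), (core_start, layout.width)]


def simulate_abundance_profiles(
    dataset: SyntheticDataset, config: SimulationConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw per-sample environment labels and long-tailed relative
    abundances over the planted species.

    Each sample's abundances sum to below 1 (the remainder stands for
    non-target taxa).  Every fourth species is scaled to peak below the
    0.1% threshold so the abundance gate is exercised from both sides.
    """
    config = config or dataset.config
    rng = _rng(config, stage=2)
    sample_ids = [f"S{i + 1:03d}" for i in range(config.n_samples)]
    categories = [str(rng.choice(config.environments)) for _ in sample_ids]
    labels = [str(rng.choice(ENVIRONMENT_SYNONYMS.get(cat, (cat,)))) for cat in categories]
    samples = pd.DataFrame({"sample_id": sample_ids, "raw_label": labels})

    species = dataset.species_labels()
    n = len(species)
    rows = []
    for _ in sample_ids:
        total = rng.uniform(0.1, 0.7)
        weights = rng.dirichlet(np.full(n, config.abundance_alpha))
        present = rng.random(n) < 0.5
        if not present.any():
            present[int(rng.integers(n))] = True
        row = weights * present
        s = row.sum()
        rows.append(total * row / s if s > 0 else row)
    abundance = pd.DataFrame(rows, index=sample_ids, columns=species)
    for k, sp in enumerate(species):
        if k % 4 == 3:
            peak = abundance[sp].max()
            if peak > 0:
                abundance[sp] *= 0.0008 / peak  # planted rare species
    return abundance, samples


def fragment_records(
    dataset: SyntheticDataset,
    fragment_windows: list[tuple[int, int]] | None = None,
    short_fragment_rate: float | None = None,
    seed: int | None = None,
) -> list[AlignedRecord]:
    """Emit aligned fragments: per-read substitutions on the species
    sequence, restriction to one subregion window, and optional
    truncation to below the coverage-filter threshold.

    Reads are annotated only to order level — the planted families and
    genera are novel diversity for the clustering stage to recover.
    """
    config = dataset.config
    windows = fragment_windows if fragment_windows is not None else (
        config.fragment_windows or default_windows(dataset.layout)
    )
    if not windows:
        raise ValueError("fragment_windows must be nonempty")
    for start, end in windows:
        if not (0 <= start < end <= dataset.layout.width):
            raise ValueError(f"window [{start}, {end}) outside alignment of width {dataset.layout.width}")
    rate = config.short_fragment_rate if short_fragment_rate is None else short_fragment_rate
    rng = np.random.default_rng([config.seed if seed is None else seed, 3])
    weights = config.fragment_window_weights or ([0.6, 0.4] if len(windows) == 2 else None)
    if weights is not None:
        if len(weights) != len(windows):
            raise ValueError("fragment_window_weights must match fragment_windows")
        probs = np.asarray(weights, dtype=float)
        probs = probs / probs.sum()
    else:
        probs = np.full(len(windows), 1 / len(windows))

    layout = dataset.layout
    pool = dataset.read_pool
    r = dataset.read_substitutions
    sample_ids = list(dataset.samples["sample_id"]) if dataset.samples is not None else [
        f"S{i + 1:03d}" for i in range(config.n_samples)
    ]
    lineage: Lineage = ORDER_LINEAGE + ("", "")

    fragments: list[AlignedRecord] = []
    counter = 0
    for sp_label in dataset.species_labels():
        sp_seq = dataset.species_sequences[sp_label]
        if dataset.abundance is not None and sp_label in dataset.abundance.columns:
            col = dataset.abundance[sp_label].to_numpy(dtype=float)
            sample_probs = col / col.sum() if col.sum() > 0 else np.full(len(sample_ids), 1 / len(sample_ids))
        else:
            sample_probs = np.full(len(sample_ids), 1 / len(sample_ids))
        for _ in range(config.fragments_per_species):
            counter += 1
            read = sp_seq.copy()
            if r > 0 and pool is not None and pool.size > 0:
                sites = rng.choice(pool, size=min(r, pool.size), replace=False)
                for site in sites:
                    pos = FLANK_BASES + int(site)
                    options = [b for b in "ACGT" if b != read[pos]]
                    read[pos] = options[int(rng.integers(len(options)))]
            w_start, w_end = windows[int(rng.choice(len(windows), p=probs))]
            in_window = (layout.base_columns >= w_start) & (layout.base_columns < w_end)
            if rng.random() < rate:
                keep_n = int(in_window.sum()) // 2
                idx = np.flatnonzero(in_window)
                in_window = np.zeros_like(in_window)
                in_window[idx[:keep_n]] = True
            sample = sample_ids[int(rng.choice(len(sample_ids), p=sample_probs))]
            rec_id = f"seq{counter}|{sample}"
            fragments.append(
                AlignedRecord(
                    id=rec_id,
                    columns=layout.row_from_ungapped(read, in_window),
                    lineage=lineage,
                    sample_id=sample,
                )
            )
            dataset.truth[rec_id] = dataset.truth[f"ref|{sp_label}"]
    return fragments


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Full generation pass: hierarchy, abundance profiles, fragments."""
    dataset = simulate_reference_hierarchy(config)
    dataset.abundance, dataset.samples = simulate_abundance_profiles(dataset, config)
    dataset.records = fragment_records(dataset)
    return dataset


def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> None:
    """Write the dataset as plain-text files: gapped fragment FASTA,
    taxonomy/sample/abundance/truth TSVs, and the reference set."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(dataset.records, outdir / "fragments.fasta")
    write_taxonomy_tsv(dataset.records, outdir / "taxonomy.tsv")
    write_fasta(dataset.reference_records, outdir / "references.fasta")
    write_taxonomy_tsv(dataset.reference_records, outdir / "reference_taxonomy.tsv")
    pd.DataFrame(
        [{"id": rid, "name": name} for rid, name in sorted(dataset.reference_names.items())]
    ).to_csv(outdir / "reference_names.tsv", sep="\t", index=False)
    if dataset.samples is not None:
        dataset.samples.to_csv(outdir / "samples.tsv", sep="\t", index=False)
    if dataset.abundance is not None:
        dataset.abundance.to_csv(outdir / "abundance.tsv", sep="\t", index_label="sample_id")
    truth = pd.DataFrame(
        [
            {"id": rid, "family": fam, "genus": gen, "species": sp}
            for rid, (fam, gen, sp) in sorted(dataset.truth.items())
        ]
    )
    truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
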