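"""End-to-end orchestration of the amplicon diversity workflow.

``run_pipeline`` chains the stages on a synthetic dataset: dereplicate,
locate and trim the most-represented alignment region, calibrate the
species/genus/family cutoffs from the planted reference species,
cluster with the taxonomy-informed hierarchy, name sOTUs from the
references, and produce the ecological and diversity summaries.  The
result object carries every intermediate artifact plus an evaluation of
the clustering against the planted truth; ``PipelineResult.write``
persists the lot as plain-text tables, byte-identically for a fixed
configuration.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import ecology, regions, reporting, species
from .calibration import CutoffSet, ReferenceSpecies, calibrate_cutoffs
from .clustering import ClusterAssignment, SequenceEntry, hierarchical_tic
from .records import GAP_CHARS, AlignedRecord
from .synthetic import SimulationConfig, SyntheticDataset, simulate_dataset


@dataclass
class PipelineOptions:
    plateau_fraction: float = 0.8
    min_fraction: float = 0.8
    min_bases_override: int | None = None
    window_override: tuple[int, int] | None = None
    assignment_threshold: float = 0.98
    abundance_threshold: float = 0.001
    cosmopolitan_min: int = 50
    top_n: int = 20
    best_hit: bool = False
    cutoffs_override: CutoffSet | None = None


@dataclass
class TruthEvaluation:
    """Planted-truth scorecard: recovered cluster counts vs planted
    counts and the fraction of records whose sOTU is the majority
    cluster of their planted species."""

    n_fotus: int
    n_gotus: int
    n_sotus: int
    planted_families: int
    planted_genera: int
    planted_species: int
    agreement: float


@dataclass
class PipelineResult:
    dataset: SyntheticDataset
    multiplicities: regions.Multiplicities
    coverage: regions.PositionCoverage
    window: regions.RegionWindow
    kept: list[AlignedRecord]
    discard_log: pd.DataFrame
    cutoffs: CutoffSet
    pair_counts: dict[str, int]
    entries: list[SequenceEntry]
    assignment: ClusterAssignment
    species_assignments: list[species.SpeciesAssignment]
    sample_records: list[ecology.SampleRecord]
    sotu_abundance: pd.DataFrame
    summaries: list[ecology.EcologySummary]
    retained: set[str]
    positivity: dict[str, float]
    report: reporting.DiversityReport
    top_prevalent: pd.DataFrame
    top_abundant: pd.DataFrame
    truth_eval: TruthEvaluation

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.cutoffs.to_json(outdir / "cutoffs.json", self.pair_counts)
        self.assignment.to_frame().to_csv(outdir / "assignment.tsv", sep="\t", index=False)
        self.multiplicities.to_frame().to_csv(outdir / "multiplicities.tsv", sep="\t", index=False)
        self.discard_log.to_csv(outdir / "discarded.tsv", sep="\t", index=False)
        species.assignments_to_frame(self.species_assignments).to_csv(
            outdir / "species_assignments.tsv", sep="\t", index=False
        )
        ecology.summaries_to_frame(self.summaries).to_csv(outdir / "ecology.tsv", sep="\t", index=False)
        self.sotu_abundance.to_csv(outdir / "sotu_abundance.tsv", sep="\t", index_label="sample_id")
        pd.DataFrame(
            [{"category": k, "positivity": v} for k, v in self.positivity.items()]
        ).to_csv(outdir / "positivity.tsv", sep="\t", index=False)
        self.report.overall.to_csv(outdir / "diversity_overall.tsv", sep="\t", index_label="rank")
        self.report.genera_per_family.to_csv(outdir / "diversity_genera.tsv", sep="\t", index=False)
        self.report.species_per_family.to_csv(outdir / "diversity_species.tsv", sep="\t", index=False)
        self.top_prevalent.to_csv(outdir / "top_prevalent.tsv", sep="\t", index=False)
        self.top_abundant.to_csv(outdir / "top_abundant.tsv", sep="\t", index=False)
        window = self.window
        (outdir / "window.txt").write_text(
            f"start={window.start}\nend={window.end}\nexpected_bases={window.expected_bases}\n"
            f"min_fraction={window.min_fraction}\nthreshold={window.threshold}\n"
        )


def _trim_reference(rec: AlignedRecord, window: regions.RegionWindow, name: str) -> ReferenceSpecies:
    segment = rec.columns[window.start : window.end]
    bases = "".join(c for c in segment if c not in GAP_CHARS)
    return ReferenceSpecies(name=name, lineage=rec.lineage, sequence=bases)


def _map_abundance_to_sotus(
    dataset: SyntheticDataset, assignment: ClusterAssignment
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Re-key the per-species abundance matrix by recovered sOTU via the
    majority sOTU of each planted species' surviving fragments."""
    species_to_sotu: dict[str, str] = {}
    votes: dict[str, Counter] = {}
    for rid, label in assignment.sotu.items():
        truth = dataset.truth.get(rid)
        if truth is None:
            continue
        votes.setdefault(truth[2], Counter())[label] += 1
    for sp, counter in votes.items():
        species_to_sotu[sp] = counter.most_common(1)[0][0]
    if dataset.abundance is None:
        return pd.DataFrame(), species_to_sotu
    frames: dict[str, pd.Series] = {}
    for sp in dataset.abundance.columns:
        sotu = species_to_sotu.get(sp)
        if sotu is None:
            continue
        frames[sotu] = frames.get(sotu, 0) + dataset.abundance[sp]
    matrix = pd.DataFrame(frames)
    return matrix.reindex(sorted(matrix.columns), axis=1), species_to_sotu


def _evaluate_truth(dataset: SyntheticDataset, assignment: ClusterAssignment) -> TruthEvaluation:
    config = dataset.config
    majority: dict[str, str] = {}
    votes: dict[str, Counter] = {}
    for rid, label in assignment.sotu.items():
        truth = dataset.truth.get(rid)
        if truth is not None:
            votes.setdefault(truth[2], Counter())[label] += 1
    for sp, counter in votes.items():
        majority[sp] = counter.most_common(1)[0][0]
    total = correct = 0
    for rid, label in assignment.sotu.items():
        truth = dataset.truth.get(rid)
        if truth is None:
            continue
        total += 1
        if majority.get(truth[2]) == label:
            correct += 1
    return TruthEvaluation(
        n_fotus=assignment.n_fotus(),
        n_gotus=assignment.n_gotus(),
        n_sotus=assignment.n_sotus(),
        planted_families=config.n_families,
        planted_genera=config.n_families * config.genera_per_family,
        planted_species=config.n_families * config.genera_per_family * config.species_per_genus,
        agreement=(correct / total) if total else 0.0,
    )


def run_pipeline(
    sim_config: SimulationConfig,
    options: PipelineOptions | None = None,
    dataset: SyntheticDataset | None = None,
) -> PipelineResult:
    options = options or PipelineOptions()
    dataset = dataset or simulate_dataset(sim_config)

    unique, multiplicities = regions.dereplicate(dataset.records)
    coverage = regions.compute_position_coverage(unique)
    window = regions.select_represented_region(
        coverage, options.plateau_fraction, override=options.window_override
    )
    reference_row = dataset.reference_records[0]
    window.expected_bases = regions.expected_bases_in_window(reference_row, window)
    window.min_fraction = options.min_fraction
    window.min_bases_override = options.min_bases_override
    kept, discard_log = regions.trim_and_filter(unique, window)

    entries = [
        SequenceEntry(
            id=rec.id,
            bases=rec.columns,
            lineage=rec.lineage,
            multiplicity=multiplicities.counts.get(rec.id, 1),
        )
        for rec in kept
    ]

    refs = [
        _trim_reference(rec, window, dataset.reference_names[rec.id])
        for rec in dataset.reference_records
    ]
    cutoffs, pair_counts = calibrate_cutoffs(refs)
    if options.cutoffs_override is not None:
        cutoffs = options.cutoffs_override
    assignment = hierarchical_tic(entries, cutoffs, best_hit=options.best_hit)

    sotu_reps = {
        label: assignment.representative_bases[label]
        for label in set(assignment.sotu.values())
    }
    species_assignments = species.assign_known_species(
        sotu_reps, refs, threshold=options.assignment_threshold
    )

    sample_records = (
        ecology.categorize_samples(dataset.samples) if dataset.samples is not None else []
    )
    sotu_abundance, _ = _map_abundance_to_sotus(dataset, assignment)
    summaries = ecology.summarize_sotu_ecology(
        sotu_abundance,
        sample_records,
        threshold=options.abundance_threshold,
        cosmopolitan_min=options.cosmopolitan_min,
    ) if not sotu_abundance.empty else []
    retained = ecology.filter_by_abundance(summaries, options.abundance_threshold)
    positivity = (
        ecology.compute_positivity(sotu_abundance, sample_records)
        if not sotu_abundance.empty
        else {}
    )

    known_taxa: dict[str, dict[str, list[str]]] = {}
    for rec in dataset.reference_records:
        fam, gen = rec.lineage[4], rec.lineage[5]
        known_taxa.setdefault(fam, {}).setdefault(gen, []).append(dataset.reference_names[rec.id])
    report = reporting.diversity_table(assignment, retained, known_taxa)
    names = {
        a.sotu: a.assigned_name for a in species_assignments if a.assigned_name != species.UNKNOWN
    }
    top_prevalent, top_abundant = reporting.top_tables(
        summaries, options.top_n, assignment=assignment, species_names=names
    )

    return PipelineResult(
        dataset=dataset,
        multiplicities=multiplicities,
        coverage=coverage,
        window=window,
        kept=kept,
        discard_log=discard_log,
        cutoffs=cutoffs,
        pair_counts=pair_counts,
        entries=entries,
        assignment=assignment,
        species_assignments=species_assignments,
        sample_records=sample_records,
        sotu_abundance=sotu_abundance,
        summaries=summaries,
        retained=retained,
        positivity=positivity,
        report=report,
        top_prevalent=top_prevalent,
        top_abundant=top_abundant,
        truth_eval=_evaluate_truth(dataset, assignment),
    )
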