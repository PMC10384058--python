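"""Synthetic community generator: planted identity ladder, fragment
windows, abundance profiles, determinism."""

import itertools

import numpy as np
import pytest
from scipy import stats

from amplidiv import (
    RegionWindow,
    SimulationConfig,
    fragment_records,
    pairwise_identity,
    simulate_abundance_profiles,
    simulate_dataset,
    simulate_reference_hierarchy,
    trim_and_filter,
)
from amplidiv.synthetic import InfeasibleIdentityError, build_layout, default_windows


def core_window(dataset) -> RegionWindow:
    start, end = dataset.layout.core_slice
    return RegionWindow(start=start, end=end, expected_bases=dataset.config.region_length)


def trimmed_by_truth(dataset, records):
    kept, _ = trim_and_filter(records, core_window(dataset))
    return {rec.id: (rec.columns, dataset.truth[rec.id]) for rec in kept}


def test_degenerate_hierarchy_single_species():
    dataset = simulate_reference_hierarchy(
        SimulationConfig(seed=3, n_families=1, genera_per_family=1, species_per_genus=1)
    )
    assert len(dataset.reference_records) == 1
    assert len(dataset.species_sequences) == 1


def test_determinism_byte_identical():
    config = SimulationConfig(seed=19, n_families=2, genera_per_family=2, species_per_genus=2,
                              fragments_per_species=4, n_samples=8)
    d1 = simulate_dataset(config)
    d2 = simulate_dataset(config)
    assert [(r.id, r.columns, r.sample_id) for r in d1.records] == [
        (r.id, r.columns, r.sample_id) for r in d2.records
    ]
    assert d1.abundance.equals(d2.abundance)
    assert d1.samples.equals(d2.samples)


def test_realized_identity_ladder_on_fragments():
    """Mean pairwise identities over emitted fragments land within
    +/- 1.5 pp of the configured targets and are strictly ordered."""
    config = SimulationConfig(seed=7, n_families=2, genera_per_family=2, species_per_genus=2,
                              fragments_per_species=5, n_samples=10, short_fragment_rate=0.0)
    dataset = simulate_dataset(config)
    trimmed = trimmed_by_truth(dataset, dataset.records)
    strata = {"species": [], "genus": [], "family": [], "across": []}
    for (sa, ta), (sb, tb) in itertools.combinations(trimmed.values(), 2):
        ident = pairwise_identity(sa, sb)
        if ta[2] == tb[2]:
            strata["species"].append(ident)
        elif ta[1] == tb[1]:
            strata["genus"].append(ident)
        elif ta[0] == tb[0]:
            strata["family"].append(ident)
        else:
            strata["across"].append(ident)
    means = {k: float(np.mean(v)) for k, v in strata.items()}
    assert means["species"] > means["genus"] > means["family"] > means["across"]
    assert means["species"] == pytest.approx(config.within_species_identity, abs=0.015)
    assert means["genus"] == pytest.approx(config.within_genus_identity, abs=0.015)
    assert means["family"] == pytest.approx(config.within_family_identity, abs=0.015)
    assert means["across"] == pytest.approx(config.across_family_identity, abs=0.015)


def test_infeasible_ladder_rejected():
    with pytest.raises(InfeasibleIdentityError):
        simulate_reference_hierarchy(
            SimulationConfig(seed=1, within_family_identity=0.9205, across_family_identity=0.92)
        )
    with pytest.raises(InfeasibleIdentityError):
        simulate_reference_hierarchy(
            SimulationConfig(seed=1, n_families=10, genera_per_family=10, species_per_genus=10)
        )


def test_fragment_window_assignment_binomial():
    """With 60/40 window weights the per-window counts stay inside the
    binomial 99% band."""
    config = SimulationConfig(seed=23, n_families=1, genera_per_family=1, species_per_genus=1,
                              fragments_per_species=1000, n_samples=5, short_fragment_rate=0.0)
    dataset = simulate_reference_hierarchy(config)
    fragments = fragment_records(dataset)
    left_flank_col = int(dataset.layout.base_columns[0])
    in_first = sum(1 for rec in fragments if rec.columns[left_flank_col] != "-")
    lo, hi = stats.binom.ppf([0.005, 0.995], 1000, 0.6)
    assert lo <= in_first <= hi


def test_short_fragment_rate_extremes():
    config = SimulationConfig(seed=5, n_families=1, genera_per_family=1, species_per_genus=1,
                              fragments_per_species=30, n_samples=5, short_fragment_rate=0.0)
    dataset = simulate_reference_hierarchy(config)
    window = default_windows(dataset.layout)[0]
    cols = dataset.layout.base_columns
    window_bases = int(((cols >= window[0]) & (cols < window[1])).sum())
    full = fragment_records(dataset, [window], short_fragment_rate=0.0)
    assert {rec.base_count() for rec in full} == {window_bases}

    truncated = fragment_records(dataset, [window], short_fragment_rate=1.0)
    kept, log = trim_and_filter(truncated, core_window(dataset))
    assert kept == []
    assert len(log) == len(truncated)


def test_abundance_profiles_contract():
    config = SimulationConfig(seed=13, n_families=2, genera_per_family=2, species_per_genus=2,
                              n_samples=100, abundance_alpha=0.2)
    dataset = simulate_reference_hierarchy(config)
    abundance, samples = simulate_abundance_profiles(dataset, config)
    assert (abundance.sum(axis=1) <= 1.0 + 1e-12).all()
    assert (abundance.to_numpy() >= 0).all()
    assert len(samples) == 100
    maxima = abundance.max(axis=0)
    assert (maxima < 0.001).any(), "a planted rare species should stay below the 0.1% gate"
    assert (maxima >= 0.001).any()
    # every raw label belongs to the configured synonym pools
    from amplidiv.synthetic import ENVIRONMENT_SYNONYMS

    pool = {label for labels in ENVIRONMENT_SYNONYMS.values() for label in labels}
    assert set(samples["raw_label"]) <= pool


def test_every_fragment_traceable_to_one_species():
    config = SimulationConfig(seed=31, n_families=2, genera_per_family=2, species_per_genus=2,
                              fragments_per_species=6, n_samples=10)
    dataset = simulate_dataset(config)
    species = set(dataset.species_sequences)
    for rec in dataset.records:
        assert dataset.truth[rec.id][2] in species
    covered = {dataset.truth[rec.id][2] for rec in dataset.records}
    assert covered == species


def test_layout_core_is_contiguous_columns():
    layout = build_layout(282)
    start, end = layout.core_slice
    assert end - start == 282
    core_cols = layout.base_columns[40:40 + 282]
    assert (np.diff(core_cols) == 1).all()
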