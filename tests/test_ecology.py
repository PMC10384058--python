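"""Environment categorisation and ecological summaries."""

import numpy as np
import pandas as pd
import pytest

from amplidiv import (
    SampleRecord,
    categorize_environment,
    compute_positivity,
    filter_by_abundance,
    summarize_sotu_ecology,
)

from ._oracles import brute_force_summary


@pytest.mark.parametrize(
    "label,category",
    [
        ("marine sediment", "saline water"),
        ("beach sand", "saline water"),
        ("activated sludge", "bioreactor"),
        ("wastewater treatment effluent", "bioreactor"),
        ("laboratory-cultivated photosynthetic mat", "excluded"),
        ("biofilm on polymer surface in laboratory", "excluded"),
        ("river water", "freshwater"),
        ("agricultural soil", "soil"),
        ("marine sponge tissue", "host saline water"),
        ("seagrass leaf surface", "plant saline water"),
        ("human gut metagenome", "host"),
        ("moss cushion", "plant"),
        ("urban aerosol", "air"),
        ("completely cryptic description", "other"),
    ],
)
def test_categorize_environment(label, category):
    assert categorize_environment(label) == category


def sample(sid: str, category: str) -> SampleRecord:
    return SampleRecord(sample_id=sid, raw_label=category, category=category)


def random_ecology(seed: int, n_sotus: int, n_samples: int):
    rng = np.random.default_rng(seed)
    categories = ["saline water", "freshwater", "soil", "bioreactor", "host"]
    samples = [sample(f"S{i:03d}", categories[int(rng.integers(len(categories)))]) for i in range(n_samples)]
    values = rng.random((n_samples, n_sotus)) * 0.02
    values[rng.random((n_samples, n_sotus)) < 0.6] = 0.0
    abundance = pd.DataFrame(values, index=[s.sample_id for s in samples],
                             columns=[f"SOTU{j:04d}" for j in range(n_sotus)])
    return abundance, samples


class TestPositivity:
    def test_half_positive(self):
        samples = [sample(f"S{i}", "freshwater") for i in range(4)]
        abundance = pd.DataFrame(
            {"SOTU1": [0.01, 0.2, 0.0, 0.0]}, index=[s.sample_id for s in samples]
        )
        result = compute_positivity(abundance, samples)
        assert result["freshwater"] == 0.5

    def test_no_positive_samples(self):
        samples = [sample("S1", "soil")]
        abundance = pd.DataFrame({"SOTU1": [0.0]}, index=["S1"])
        result = compute_positivity(abundance, samples)
        assert result["soil"] == 0.0 and result["overall"] == 0.0

    def test_empty_category_omitted(self):
        samples = [sample("S1", "soil")]
        abundance = pd.DataFrame({"SOTU1": [0.5]}, index=["S1"])
        assert "freshwater" not in compute_positivity(abundance, samples)

    def test_matches_brute_force(self):
        abundance, samples = random_ecology(33, 20, 80)
        result = compute_positivity(abundance, samples)
        by_cat: dict[str, list[bool]] = {}
        for s in samples:
            positive = any(abundance.at[s.sample_id, c] > 0 for c in abundance.columns)
            by_cat.setdefault(s.category, []).append(positive)
        for cat, flags in by_cat.items():
            assert result[cat] == pytest.approx(sum(flags) / len(flags))
        allf = [f for flags in by_cat.values() for f in flags]
        assert result["overall"] == pytest.approx(sum(allf) / len(allf))

    def test_category_positives_sum_to_overall(self):
        abundance, samples = random_ecology(34, 10, 60)
        result = compute_positivity(abundance, samples)
        totals = {s.category: 0 for s in samples}
        for s in samples:
            totals[s.category] += 1
        total_pos = sum(result[c] * totals[c] for c in totals)
        assert total_pos == pytest.approx(result["overall"] * len(samples))


class TestSummaries:
    def test_direct_reading(self):
        samples = [sample("s1", "saline water"), sample("s2", "soil")]
        abundance = pd.DataFrame({"X": [0.002, 0.0009]}, index=["s1", "s2"])
        (summary,) = summarize_sotu_ecology(abundance, samples)
        assert summary.n_positive == 2
        assert summary.n_positive_ge_threshold == 1
        assert summary.max_abundance_environment == "saline water"
        assert summary.max_abundance == pytest.approx(0.002)

    def test_boundary_abundance_counts(self):
        samples = [sample("s1", "soil")]
        abundance = pd.DataFrame({"X": [0.001]}, index=["s1"])
        (summary,) = summarize_sotu_ecology(abundance, samples)
        assert summary.n_positive_ge_threshold == 1

    def test_cosmopolitan_iff_min_positives(self):
        samples = [sample(f"S{i:03d}", "soil") for i in range(60)]
        values = {"A": [0.01] * 50 + [0.0] * 10, "B": [0.01] * 49 + [0.0] * 11}
        abundance = pd.DataFrame(values, index=[s.sample_id for s in samples])
        summaries = {s.sotu: s for s in summarize_sotu_ecology(abundance, samples)}
        assert summaries["A"].cosmopolitan
        assert not summaries["B"].cosmopolitan

    def test_excluded_samples_influence_nothing(self):
        samples = [sample("s1", "soil"), sample("s2", "excluded")]
        abundance = pd.DataFrame({"X": [0.002, 0.9]}, index=["s1", "s2"])
        (summary,) = summarize_sotu_ecology(abundance, samples)
        assert summary.n_positive == 1
        assert summary.max_abundance == pytest.approx(0.002)
        assert summary.max_abundance_environment == "soil"

    def test_matches_brute_force(self):
        abundance, samples = random_ecology(35, 30, 120)
        summaries = summarize_sotu_ecology(abundance, samples, cosmopolitan_min=20)
        expected = brute_force_summary(abundance, samples, 0.001, 20)
        for s in summaries:
            want = expected[s.sotu]
            assert s.n_positive == want["n_positive"]
            assert s.n_positive_ge_threshold == want["n_positive_ge_threshold"]
            assert s.dominant_environment == want["dominant_environment"]
            assert s.max_abundance == pytest.approx(want["max_abundance"])
            assert s.max_abundance_environment == want["max_abundance_environment"]
            assert s.cosmopolitan == want["cosmopolitan"]


class TestAbundanceFilter:
    def test_boundary_retention(self):
        samples = [sample("s1", "soil")]
        for value, retained in ((0.0011, True), (0.0009, False)):
            abundance = pd.DataFrame({"X": [value]}, index=["s1"])
            summaries = summarize_sotu_ecology(abundance, samples)
            assert (("X" in filter_by_abundance(summaries))) is retained

    def test_retention_monotone_in_threshold(self):
        abundance, samples = random_ecology(36, 25, 60)
        sizes = []
        for threshold in (0.0005, 0.001, 0.002, 0.005, 0.01):
            summaries = summarize_sotu_ecology(abundance, samples, threshold=threshold)
            sizes.append(len(filter_by_abundance(summaries, threshold)))
        assert sizes == sorted(sizes, reverse=True)
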