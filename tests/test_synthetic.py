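"""Community generator: divergence models, marker insertion, read
simulation with ground truth, ASV tables."""

import numpy as np
import pytest

from phagetrace.synthetic import (
    ConfigurationError,
    PopulationSpec,
    SampleDesign,
    generate_asv_table,
    generate_population,
    insert_marker_gene,
    simulate_marker_reads,
    simulate_reads,
    write_fastq,
)


def _mismatch_frac(a: str, b: str) -> float:
    return np.mean([x != y for x, y in zip(a, b)])


class TestGeneratePopulation:
    def test_single_variant_identical_to_ancestor(self):
        spec = PopulationSpec("p", "viral", "single", 2000, 1)
        pop = generate_population(spec, seed=1)
        assert pop.variants[0] == pop.ancestor
        assert pop.divergence.realized_divergence.iloc[0] == 0.0

    def test_clonal_divergences_bounded_and_islands_invariant(self):
        spec = PopulationSpec(
            "p", "viral", "clonal", 20000, 5,
            divergence_params={"max_divergence": 0.02},
            conserved_islands=[(1000, 500), (9000, 800)],
        )
        pop = generate_population(spec, seed=1)
        for v in pop.variants:
            assert 0.0 <= _mismatch_frac(v, pop.ancestor) <= 0.02
            for start, ln in spec.conserved_islands:
                assert v[start:start + ln] == pop.ancestor[start:start + ln]

    def test_continuum_spans_at_least_ten_points(self):
        spec = PopulationSpec("p", "viral", "continuum", 20000, 50)
        pop = generate_population(spec, seed=3)
        div = pop.divergence.realized_divergence
        assert div.max() - div.min() >= 0.10

    def test_two_cloud_separation(self):
        spec = PopulationSpec("p", "viral", "two_cloud", 10000, 20)
        pop = generate_population(spec, seed=2)
        div = pop.divergence.realized_divergence.to_numpy()
        near, far = div[div <= 0.02], div[div >= 0.079]
        assert len(near) + len(far) == 20 and len(near) and len(far)

    def test_invalid_model_name_rejected(self):
        with pytest.raises(ConfigurationError):
            PopulationSpec("p", "viral", "blob", 2000, 1)

    def test_divergence_above_cap_rejected(self):
        with pytest.raises(ConfigurationError):
            PopulationSpec("p", "viral", "continuum", 2000, 2,
                           divergence_params={"max_divergence": 0.5})

    def test_reproducible_under_seed(self):
        spec = PopulationSpec("p", "viral", "clonal", 2000, 3)
        assert generate_population(spec, 7).variants == generate_population(spec, 7).variants


class TestInsertMarkerGene:
    def test_empty_marker_is_noop(self):
        assert insert_marker_gene("ACGTACGT", "", 3) == "ACGTACGT"

    def test_replacement_at_position(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), 8000))
        marker = "".join(rng.choice(list("ACGT"), 1083))
        out = insert_marker_gene(seq, marker, 5000)
        assert out[5000:6083] == marker
        assert len(out) == len(seq)
        assert out[:5000] == seq[:5000] and out[6083:] == seq[6083:]

    def test_overlap_with_island_is_error(self):
        with pytest.raises(ConfigurationError):
            insert_marker_gene("A" * 2000, "C" * 100, 950, [(900, 100)])

    def test_marker_past_end_is_error(self):
        with pytest.raises(ConfigurationError):
            insert_marker_gene("A" * 100, "C" * 50, 80)


def _toy_community():
    host = generate_population(PopulationSpec("h", "host", "single", 2000, 1), 1)
    phage = generate_population(PopulationSpec("v", "viral", "single", 2000, 1), 2)
    return {"h": host, "v": phage}


def _design(**kw):
    base = dict(
        sites=["S1"], dates=["d1"], seed=9,
        abundances={"h": 10.0, "v": 5.0},
        infected_fraction={"v": 0.4},
        infection_links={"v": "h"},
        n_reads=400, read_length=100,
    )
    base.update(kw)
    return SampleDesign(**base)


class TestSimulateReads:
    def test_counts_sum_to_n_reads(self):
        reads, truth = simulate_reads(_toy_community(), _design())
        assert (truth.read_counts.sum(axis=1) == 400).all()
        assert all(len(reads[s]) == 400 for s in reads)

    def test_no_infection_means_no_phage_rna(self):
        reads, truth = simulate_reads(_toy_community(), _design(infected_fraction={"v": 0.0}))
        assert truth.read_counts.loc["S1_d1_RNA", "v"] == 0
        assert not truth.activity.loc["S1_d1_RNA", "v"]

    def test_zero_reads_gives_empty_sample(self):
        reads, truth = simulate_reads(_toy_community(), _design(n_reads=0))
        assert all(len(r) == 0 for r in reads.values())
        assert (truth.read_counts.to_numpy() == 0).all()

    def test_zero_total_abundance_is_error(self):
        with pytest.raises(ConfigurationError):
            simulate_reads(_toy_community(), _design(abundances={"h": 0.0, "v": 0.0}))

    def test_expected_viral_marker_fraction_closed_form(self):
        _, truth = simulate_reads(_toy_community(), _design(infected_fraction={"v": 0.3}))
        row = truth.viral_marker_fraction
        expected = 1.0 * 0.3 / (1.0 * 0.3 + 0.7)
        assert row.loc[row.host == "h", "expected_fraction"].iloc[0] == pytest.approx(expected)

    def test_deterministic_fastq_bytes(self, tmp_path):
        out = []
        for rep in range(2):
            reads, _ = simulate_reads(_toy_community(), _design())
            p = tmp_path / f"rep{rep}.fastq"
            write_fastq(p, reads["S1_d1_DNA"])
            out.append(p.read_bytes())
        assert out[0] == out[1]


class TestMarkerReadFraction:
    def test_viral_marker_read_share_matches_closed_form(self, psba_genes):
        """alpha=1, I=0.5: viral share of 20000 marker reads within 3 SE."""
        I = 0.5
        weights = {"cyano_synechococcus": 1 - I, "T4like": I}
        genes = {g: psba_genes[g] for g in weights}
        reads = simulate_marker_reads(genes, weights, 20000, 200, 0.001, seed=4)
        viral = sum(1 for rid, _ in reads if rid.endswith("T4like"))
        p = viral / 20000
        se = np.sqrt(0.5 * 0.5 / 20000)
        assert abs(p - 0.5) <= 3 * se


class TestAsvTable:
    def test_all_absent_rows_flagged_and_zero(self):
        table, flagged = generate_asv_table({"a": {}, "b": {}}, ["s1", "s2"])
        assert flagged == ["s1", "s2"]
        assert (table.to_numpy() == 0).all()

    def test_single_asv_relative_abundance_one(self):
        table, flagged = generate_asv_table({"a": {"s1": 3.0, "s2": 7.0}}, ["s1", "s2"])
        assert flagged == []
        assert (table["a"] == 1.0).all()

    def test_rows_sum_to_one_and_absence_pattern(self):
        abund = {
            "Syn": {"POLA": 2.0, "SPOT": 2.0, "CAT": 2.0},
            "Pro": {"SPOT": 1.0, "CAT": 1.0},  # near-absent in the port
        }
        table, _ = generate_asv_table(abund, ["POLA", "SPOT", "CAT"])
        assert table.loc["POLA", "Pro"] == 0.0
        assert table.loc["POLA", "Syn"] == 1.0
        np.testing.assert_allclose(table.sum(axis=1), 1.0)
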