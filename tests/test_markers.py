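"""Marker profile construction, threshold calibration, six-frame search,
group assignment, expression partitioning and the infected-fraction
estimator."""

import numpy as np
import pytest

from phagetrace.markers import (
    MarkerAssignment,
    MarkerReferenceSet,
    build_profile,
    calibrate_threshold,
    classify_reads,
    gp23_partition,
    infected_fraction,
    partition,
    search_reads,
)
from phagetrace.synthetic import (
    MarkerSetConfig,
    back_translate,
    generate_marker_references,
    simulate_marker_reads,
)

from conftest import revcomp


def _toy_refset(col6L4V=False):
    """10 aligned sequences over 2 groups."""
    seqs = []
    for i in range(10):
        aa = "L" if (col6L4V and i < 6) else ("V" if col6L4V else "A")
        seqs.append("ACDEF" + aa + "GHIKLMNPQRSTVWYACDEF")
    ids = [f"s{i}" for i in range(10)]
    labels = {f"s{i}": ("g1" if i < 5 else "g2") for i in range(10)}
    return MarkerReferenceSet(ids=ids, sequences=seqs, labels=labels)


class TestBuildProfile:
    def test_closed_form_log_odds(self):
        profile = build_profile(_toy_refset(col6L4V=True), pseudocount=0.5)
        from phagetrace.markers import AA_CODE

        col = 5
        score_L = profile.pssm[col, AA_CODE[ord("L")]]
        assert score_L == pytest.approx(np.log2((6.5 / 20.0) / 0.05))
        score_V = profile.pssm[col, AA_CODE[ord("V")]]
        assert score_V == pytest.approx(np.log2((4.5 / 20.0) / 0.05))

    def test_conserved_column_scores_highest_for_its_residue(self):
        profile = build_profile(_toy_refset())
        col0 = profile.pssm[0, :20]
        from phagetrace.markers import AA_ORDER

        assert AA_ORDER[int(np.argmax(col0))] == "A"

    def test_mostly_gap_columns_dropped(self):
        refs = _toy_refset()
        seqs = [s[:10] + ("-" if i < 6 else s[10]) + s[11:] for i, s in enumerate(refs.sequences)]
        refs2 = MarkerReferenceSet(ids=refs.ids, sequences=seqs, labels=refs.labels)
        profile = build_profile(refs2)
        assert profile.width == refs2.n_columns - 1
        assert 10 not in profile.kept_columns

    def test_unaligned_lengths_rejected(self):
        with pytest.raises(ValueError):
            MarkerReferenceSet(ids=["a", "b"], sequences=["ACDEF", "ACDE"],
                               labels={"a": "g1", "b": "g2"})

    def test_too_few_references_rejected(self):
        refs = MarkerReferenceSet(
            ids=["a", "b"], sequences=["ACDEF", "ACDEF"], labels={"a": "g1", "b": "g2"}
        )
        with pytest.raises(ValueError):
            build_profile(refs)


class TestCalibrateThreshold:
    def test_fpr_one_accepts_everything(self, psba_profile):
        _, profile = psba_profile
        import copy

        p = copy.copy(profile)
        t_all = calibrate_threshold(p, read_length=100, n_null=300, target_fpr=1.0, seed=1)
        t_none = calibrate_threshold(p, read_length=100, n_null=300, target_fpr=1e-12, seed=1)
        assert t_all < t_none  # min vs max of the null scores

    def test_empirical_fpr_within_factor_two(self, psba_profile):
        _, profile = psba_profile
        rng = np.random.default_rng(23)
        n = 8000
        reads = [
            (f"n{i}", "".join(np.array(list("ACGT"))[rng.integers(0, 4, 200)]))
            for i in range(n)
        ]
        hits = search_reads(reads, profile)
        fpr = len(hits) / n
        assert 0.5e-3 <= fpr <= 2e-3


class TestSearchAndAssign:
    def test_marker_read_with_errors_detected(self, psba_profile, psba_genes):
        refs, profile = psba_profile
        reads = simulate_marker_reads(
            {"T4like": psba_genes["T4like"]}, {"T4like": 1.0}, 50, 200, 0.01, seed=2
        )
        assigns = classify_reads(reads, profile)
        assert len(assigns) >= 48
        assert all(a.group == "T4like" for a in assigns)

    def test_reverse_complement_detected_via_frames_4_to_6(self, psba_profile, psba_genes):
        _, profile = psba_profile
        gene = psba_genes["T4like"][0]
        fwd = [("f", gene[300:500])]
        rev = [("r", revcomp(gene[300:500]))]
        (af,) = classify_reads(fwd, profile)
        (ar,) = classify_reads(rev, profile)
        assert af.frame <= 3 < ar.frame
        assert af.group == ar.group == "T4like"
        assert af.score == pytest.approx(ar.score)

    def test_exact_reference_segment_assigned_to_its_group(self, psba_profile):
        refs, profile = psba_profile
        idx = refs.ids.index("T4like.ref00")
        gene = back_translate(refs.sequences[idx], seed=0)
        (a,) = classify_reads([("x", gene[:210])], profile)
        assert a.group == "T4like"
        assert a.identity == 1.0

    def test_group_accuracy_at_five_percent_divergence(self):
        cfg = MarkerSetConfig(
            groups=("cyano_synechococcus", "cyano_prochlorococcus", "T4like", "T7like"),
            inter_group_divergence=0.05,
            seed=31,
        )
        refs = generate_marker_references(cfg)
        profile = build_profile(refs)
        calibrate_threshold(profile, read_length=200, n_null=3000, seed=31)
        genes = {}
        for i, rid in enumerate(refs.ids):
            genes.setdefault(refs.labels[rid], []).append(
                back_translate(refs.sequences[i], seed=i)
            )
        reads = simulate_marker_reads(
            genes, {g: 1.0 for g in genes}, 3000, 200, 0.001, seed=31
        )
        assigns = classify_reads(reads, profile)
        assert len(assigns) >= 2800
        acc = np.mean([a.group == a.read_id.split("|")[1] for a in assigns])
        assert acc >= 0.90


def _mk(group, n):
    return [MarkerAssignment(f"r{group}{i}", "s", 1, 50.0, group=group) for i in range(n)]


class TestPartition:
    def test_symmetric_counts(self):
        res = partition(_mk("cyano_synechococcus", 50) + _mk("cyano_prochlorococcus", 50)
                        + _mk("T4like", 100))
        assert res.t4_fraction == pytest.approx(0.5)
        assert res.viral_host_ratio == pytest.approx(1.0)
        assert res.infected_fraction_estimate == pytest.approx(0.5)

    def test_worked_ratio_example(self):
        res = partition(_mk("cyano_synechococcus", 30) + _mk("cyano_prochlorococcus", 20)
                        + _mk("T4like", 60) + _mk("T7like", 5))
        assert res.viral_host_ratio == pytest.approx(1.2)
        assert res.t4_fraction == pytest.approx(60 / 115)
        assert sum(res.fractions.values()) == pytest.approx(1.0)

    def test_zero_viral_counts(self):
        res = partition(_mk("cyano_synechococcus", 10))
        assert res.viral_host_ratio == 0.0
        assert res.viral_fraction == 0.0

    def test_no_reads_flagged_empty(self):
        res = partition([])
        assert res.flagged == "empty"

    def test_no_host_reads_flagged(self):
        res = partition(_mk("T4like", 10))
        assert res.flagged == "no_host_reads"


class TestInfectedFraction:
    def test_closed_form_values(self):
        assert infected_fraction(1.0) == 0.5
        assert infected_fraction(0.0) == 0.0
        assert infected_fraction(1.2) == pytest.approx(0.5454545454)

    def test_monotone_in_ratio_and_alpha_pivot(self):
        rs = np.linspace(0, 5, 40)
        vals = [infected_fraction(r, alpha=2.0) for r in rs]
        assert all(a <= b for a, b in zip(vals, vals[1:]))
        assert infected_fraction(2.0, alpha=2.0) == 0.5


class TestEndToEndEstimator:
    def test_infected_fraction_recovered_from_reads(self, psba_profile, psba_genes):
        _, profile = psba_profile
        for true_i in (0.2, 0.6):
            w = {
                "cyano_synechococcus": (1 - true_i) * 0.6,
                "cyano_prochlorococcus": (1 - true_i) * 0.4,
                "T4like": true_i,
            }
            reads = simulate_marker_reads(
                {g: psba_genes[g] for g in w}, w, 6000, 200, 0.001, seed=int(true_i * 100)
            )
            res = partition(classify_reads(reads, profile))
            assert res.infected_fraction_estimate == pytest.approx(true_i, abs=0.05)

    def test_strand_symmetry_of_partition(self, psba_profile, psba_genes):
        _, profile = psba_profile
        w = {"cyano_synechococcus": 0.5, "T4like": 0.5}
        reads = simulate_marker_reads({g: psba_genes[g] for g in w}, w, 600, 200, 0.0, seed=8)
        flipped = [(rid, revcomp(seq)) for rid, seq in reads]
        res_a = partition(classify_reads(reads, profile))
        res_b = partition(classify_reads(flipped, profile))
        assert res_a.counts == res_b.counts


@pytest.fixture(scope="module")
def gp23():
    refs = generate_marker_references(
        MarkerSetConfig(groups=("cyanophage_T4like", "heterophage_T4like"), seed=41)
    )
    genes = {}
    for i, rid in enumerate(refs.ids):
        genes.setdefault(refs.labels[rid], []).append(
            back_translate(refs.sequences[i], seed=i)
        )
    return refs, genes


class TestGp23:
    def test_mixture_recovered_within_three_se(self, gp23):
        refs, genes = gp23
        n = 4000
        reads = simulate_marker_reads(
            genes, {"cyanophage_T4like": 0.2, "heterophage_T4like": 0.8}, n, 200, 0.001, seed=5
        )
        df = gp23_partition({"s1": reads}, refs, seed=5)
        se = np.sqrt(0.2 * 0.8 / n)
        assert abs(df.loc["s1", "cyanophage_T4like"] - 0.2) <= 3 * se

    def test_pure_heterophage_gives_zero_cyanophage(self, gp23):
        refs, genes = gp23
        reads = simulate_marker_reads(
            {"heterophage_T4like": genes["heterophage_T4like"]},
            {"heterophage_T4like": 1.0}, 400, 200, 0.001, seed=6,
        )
        df = gp23_partition({"s1": reads}, refs, seed=6)
        assert df.loc["s1", "cyanophage_T4like"] == 0.0

    def test_empty_read_set_flagged_nan(self, gp23):
        refs, _ = gp23
        df = gp23_partition({"s1": []}, refs, seed=7)
        assert np.isnan(df.loc["s1", "cyanophage_T4like"])
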