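import math
import re

import numpy as np
import pandas as pd
import pytest

from evotol import genotype, synth


class TestPackagedCatalogs:
    def test_table1_per_carrier_counts(self):
        counts = genotype.count_mutations(genotype.load_table1())
        assert counts["G3.2/G3.6"] == 20
        assert counts["G3.266.7"] == 8
        assert counts["X3.5"] == 11

    def test_class_totals(self):
        assert genotype.total_mutations(genotype.load_class_totals()) == 131

    def test_parallel_evolution_tallies(self):
        t2 = genotype.load_table2()
        assert genotype.parallel_evolution_tally(t2, "marC") == 6
        assert genotype.parallel_evolution_tally(t2, "acrAB", merge_acrAB=True) == 5
        assert genotype.parallel_evolution_tally(t2, "mdh") == 3
        assert genotype.parallel_evolution_tally(t2, "no_such_gene") == 0

    def test_count_by_class(self):
        by_class = genotype.count_mutations(genotype.load_table1(), by="class")
        assert sum(by_class.values()) == 39
        with pytest.raises(ValueError):
            genotype.count_mutations([], by="gene")


def test_allele_frequency():
    assert genotype.allele_frequency(1, 4) == pytest.approx(25.0)
    assert genotype.allele_frequency(2, 4) == pytest.approx(50.0)
    with pytest.raises(ValueError):
        genotype.allele_frequency(5, 4)
    with pytest.raises(ValueError):
        genotype.allele_frequency(0, 0)


class TestMutationOrder:
    def test_packaged_trajectory_order(self):
        order = genotype.mutation_order(genotype.load_x3_trajectory())
        first = order.set_index("locus")["first_detected"]
        assert first["mdtJ-tqsA"] == 180
        assert first["mdh"] == first["deaD"] == first["plsX"] == 266
        ranks = order.set_index("locus")["rank"]
        assert ranks["mdh"] == ranks["deaD"] == ranks["plsX"]  # one cluster
        assert ranks["marC"] == 1  # earliest cluster
        assert ranks["mdtJ-tqsA"] < ranks["mdh"] < ranks["acrA"]

    def test_mixed_counts_as_detection_and_nt_skipped(self):
        calls = pd.DataFrame({
            "locus": ["x", "x", "y", "y"],
            "generation": [10, 20, 10, 20],
            "state": ["Mixed", "Mut", "NT", "WT"]})
        order = genotype.mutation_order(calls).set_index("locus")
        assert order.loc["x", "first_detected"] == 10
        assert math.isnan(order.loc["y", "rank"])

    def test_matches_generator(self):
        loci = pd.DataFrame({"locus": ["a", "b"],
                             "fixation_generation": [100, 300],
                             "sweep_width": [40, 40]})
        calls = synth.gen_allele_trajectories(loci, [0, 80, 150, 280, 350])
        order = genotype.mutation_order(calls).set_index("locus")
        assert order.loc["a", "first_detected"] == 80
        assert order.loc["b", "first_detected"] == 280


def test_trajectory_join():
    order = pd.DataFrame({"locus": ["a", "b"], "first_detected": [80, 150],
                          "rank": [1, 2]})
    fit = pd.DataFrame({"generation": [0, 100, 200], "condition": ["c"] * 3,
                        "mu": [0.4, 0.5, 0.7]})
    out = genotype.trajectory_join(order, fit)
    first = out.set_index("generation_to")
    assert first.loc[100, "new_loci"] == "a"
    assert first.loc[200, "new_loci"] == "b"
    assert first.loc[200, "delta_mu"] == pytest.approx(0.2)
    assert not out["missing_fitness"].any()


class TestFilterVariants:
    def test_threshold_boundaries(self):
        cands = pd.DataFrame({
            "coordinate": [1, 2, 3, 4],
            "class": ["SNP", "SNP", "indel", "indel"],
            "quality": [150, 149, 50, 50],
            "frequency": [0.9, 0.9, 0.4, 0.39]})
        kept = genotype.filter_variants(cands)
        assert kept["coordinate"].tolist() == [1, 3]

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            genotype.filter_variants(pd.DataFrame(columns=["coordinate", "class",
                                                           "quality", "frequency"]),
                                     snp_quality_min=-1)


class TestCoverageGaps:
    def test_adjacent_runs_merge(self):
        df = pd.DataFrame({"seq": ["chr"] * 5,
                           "start": [0, 1000, 1500, 2500, 3000],
                           "end": [1000, 1500, 2500, 3000, 5000],
                           "depth": [50, 0, 0, 50, 40]})
        track = genotype.CoverageTrack(df, 5000)
        assert genotype.detect_coverage_gaps(track, min_length=1000) == [(1000, 2500)]
        assert genotype.detect_coverage_gaps(track, min_length=2000) == []

    def test_non_tiling_rejected(self):
        df = pd.DataFrame({"seq": ["chr"] * 2, "start": [0, 200],
                           "end": [100, 300], "depth": [1, 1]})
        with pytest.raises(ValueError):
            genotype.CoverageTrack(df, 300)


class TestHomopolymerFilter:
    def test_matches_regex_oracle_on_random_reads(self):
        rng = np.random.default_rng(11)
        reads = []
        for i in range(200):
            seq = "".join(rng.choice(list("ACGTN"), size=30))
            if i % 4 == 0:  # plant runs of varying length
                run_len = int(rng.integers(8, 15))
                seq = seq[:5] + "A" * run_len + seq[5 + run_len:]
            reads.append((f"r{i}", seq))
        oracle = [(rid, s) for rid, s in reads if not re.search(r"(.)\1{10,}", s)]
        assert genotype.homopolymer_filter(reads, max_run=10) == oracle

    def test_boundary_run_kept(self):
        reads = [("a", "A" * 10 + "C"), ("b", "A" * 11 + "C"), ("c", "")]
        kept = genotype.homopolymer_filter(reads, max_run=10)
        assert [r for r, _ in kept] == ["a", "c"]

    def test_invalid_bases_rejected(self):
        with pytest.raises(ValueError):
            genotype.homopolymer_filter([("a", "ACGX")])


def test_coordinate_conversion_roundtrip():
    assert genotype.to_zero_based(1) == 0
    assert genotype.to_one_based(0) == 1
    for c in (1, 7, 4_600_000):
        assert genotype.to_one_based(genotype.to_zero_based(c)) == c
    with pytest.raises(ValueError):
        genotype.to_zero_based(0)
    with pytest.raises(ValueError):
        genotype.to_one_based(-1)


def test_record_validation_and_loader_errors(tmp_path):
    with pytest.raises(ValueError):
        genotype.MutationRecord("c", "g", 1, "weird", "A>T", "-")
    with pytest.raises(ValueError):
        genotype.GenotypeCall("x", 10, "Maybe")
    with pytest.raises(ValueError):
        genotype.VariantCandidate(1, "SNP", 10, 1.5)
    bad = tmp_path / "bad.tsv"
    bad.write_text("carrier\tgene\n")
    with pytest.raises(ValueError):
        genotype.load_mutation_table(bad)
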