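import numpy as np
import pandas as pd
import pytest

from evotol import nca, synth


def test_substream_deterministic_and_label_separated():
    a = synth.substream(7, "growth").standard_normal(5)
    b = synth.substream(7, "growth").standard_normal(5)
    c = synth.substream(7, "qpcr").standard_normal(5)
    assert np.array_equal(a, b)
    assert not np.array_equal(a, c)


class TestThreePhase:
    def test_lag_then_exact_exponential(self):
        t = np.linspace(0, 10, 301)
        od = synth.three_phase_od(t, mu=0.5, lag_h=2.0, od0=0.01, capacity=5.0)
        assert np.allclose(od[t <= 2.0], 0.01)
        mid = (t > 2.0) & (od < 2.0)  # exponential segment, below half capacity
        slope = np.polyfit(t[mid], np.log(od[mid]), 1)[0]
        assert slope == pytest.approx(0.5, abs=1e-12)

    def test_saturates_below_capacity(self):
        t = np.linspace(0, 100, 500)
        od = synth.three_phase_od(t, mu=0.5, lag_h=1.0, od0=0.01, capacity=1.2)
        assert od.max() <= 1.2 + 1e-9
        assert od[-1] == pytest.approx(1.2, rel=1e-3)

    def test_invalid_parameters(self):
        t = np.linspace(0, 10, 20)
        with pytest.raises(ValueError):
            synth.three_phase_od(t, mu=-0.1, lag_h=1, od0=0.01, capacity=1.0)
        with pytest.raises(ValueError):
            synth.three_phase_od(t, mu=0.5, lag_h=1, od0=2.0, capacity=1.0)


def test_gen_growth_plate_shape_and_blanks():
    truth = pd.DataFrame({"well": ["A1", "A2"], "mu": [0.3, 0.6],
                          "lag_h": [1.0, 2.0], "od0": [0.005, 0.005],
                          "capacity": [1.2, 1.2]})
    plate, plate_map = synth.gen_growth_plate(truth, synth.SimConfig(seed=1))
    assert (plate.groupby("well").size() == 289).all()
    assert plate_map["blank"].sum() == 3
    assert set(truth["well"]) <= set(plate_map["well"])


class TestFitnessLandscape:
    def test_noiseless_multiplicative_truth(self):
        singles = {"a": 1.1, "b": 1.2}
        table, truth = synth.gen_fitness_landscape(
            singles, {("a", "b"): 1.5}, synth.SimConfig(noise_sd=0.0))
        w = table.set_index("subset")["w"]
        assert w["a;b"] == pytest.approx(1.1 * 1.2 * 1.5, abs=1e-12)
        assert w["a"] == pytest.approx(1.1)
        assert len(table) == 3  # a, b, a;b

    def test_k_cap_and_positivity(self):
        with pytest.raises(ValueError):
            synth.gen_fitness_landscape({f"m{i}": 1.0 for i in range(13)})
        with pytest.raises(ValueError):
            synth.gen_fitness_landscape({"a": -1.0})

    def test_replicate_columns_and_se(self):
        table, _ = synth.gen_fitness_landscape(
            {"a": 1.0, "b": 1.0}, None,
            synth.SimConfig(seed=2, noise_sd=0.1), n_replicates=4)
        row = table.set_index("subset").loc["a;b"]
        reps = row[["rep1", "rep2", "rep3", "rep4"]].to_numpy(dtype=float)
        assert row["w"] == pytest.approx(reps.mean())
        assert row["se"] == pytest.approx(reps.std(ddof=1) / 2.0)


def test_sample_connectivity_properties():
    Z = synth.sample_connectivity(60, ["A", "B", "C"], seed=5)
    assert ((Z.sum(axis=1) >= 1) & (Z.sum(axis=1) <= 3)).all()
    assert (Z.sum(axis=0) >= 1).all()
    Zi = synth.sample_connectivity(60, ["A", "B", "C"], seed=5,
                                   identifiable=True, n_conditions=3)
    assert nca.check_identifiability(Zi, 3).ok


def test_gen_expression_dataset_truth_roundtrip(small_connectivity):
    Z = small_connectivity
    P = pd.DataFrame(np.arange(16, dtype=float).reshape(4, 4),
                     index=Z.columns, columns=["c1", "c2", "c3", "c4"])
    cfg = synth.SimConfig(seed=9, noise_sd=0.0, n_bio_replicates=2, n_tech_replicates=2)
    spots, truth = synth.gen_expression_dataset(Z, P, cfg)
    # noiseless gene matrix equals baseline + A @ P
    expected = truth["baseline"] + truth["A"].to_numpy() @ P.to_numpy()
    assert np.allclose(truth["E"].to_numpy(), expected)
    # foreground minus background recovers expression exactly (noiseless)
    spots = spots.assign(expr=spots["fg"] - spots["bg"])
    one = spots[(spots["probe"] == f"{Z.index[0]}_p1") & (spots["sample"] == "c1_rep1")]
    assert np.allclose(one["expr"], truth["E"].iloc[0, 0])
    # support of A matches Z
    assert ((truth["A"].to_numpy() != 0) == (Z.to_numpy() != 0)).all()


def test_gen_allele_trajectories_states():
    loci = pd.DataFrame({"locus": ["x"], "fixation_generation": [200],
                         "sweep_width": [60]})
    out = synth.gen_allele_trajectories(loci, [0, 150, 199, 200, 300])
    states = out.set_index("generation")["state"]
    assert states[0] == "WT"
    assert states[150] == "Mixed"
    assert states[199] == "Mixed"
    assert states[200] == "Mut"
    assert states[300] == "Mut"
    with pytest.raises(ValueError):
        synth.gen_allele_trajectories(loci, [10, 10])


def test_gen_amplification_curves_monotone_until_plateau():
    params = pd.DataFrame({"well": ["w1"], "d0": [1e-6], "k": [2.0],
                           "plateau": [10.0]})
    out = synth.gen_amplification_curves(params, synth.SimConfig(noise_sd=0.0))
    f = out["fluorescence"].to_numpy()
    assert (np.diff(f) >= 0).all()
    assert f.max() <= 10.0


def test_gen_variant_candidates_planted_structure():
    cands, truth, coverage, reads = synth.gen_variant_candidates(
        n_true_snps=4, n_decoy_snps=4, n_true_indels=3, n_decoy_indels=3,
        cfg=synth.SimConfig(seed=3), gap_intervals=[(100, 5100)])
    snps = cands[cands["class"] == "SNP"]
    indels = cands[cands["class"] == "indel"]
    assert ((snps["quality"] >= 150) == snps["coordinate"].isin(truth)).all()
    assert ((indels["frequency"] >= 0.4) == indels["coordinate"].isin(truth)).all()
    # coverage tiles the genome with the planted zero interval
    assert (coverage["start"].iloc[1:].to_numpy()
            == coverage["end"].iloc[:-1].to_numpy()).all()
    assert ((coverage["depth"] == 0) == ((coverage["start"] == 100)
                                         & (coverage["end"] == 5100))).all()
    assert len(reads) == 10 and all(len(s) == 36 for _, s in reads)
    with pytest.raises(ValueError):
        synth.gen_variant_candidates(gap_intervals=[(0, 100), (50, 200)])
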