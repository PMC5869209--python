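import numpy as np
import pandas as pd
import pytest

from kiwisat import (
    ErrorModel,
    PopulationModel,
    PopulationSpec,
    default_standard_concentrations,
    simulate_individuals,
    simulate_populations,
    simulate_qpcr,
    simulate_replicates,
)
from kiwisat.simulate import _stutter_allele


class TestPopulations:
    def test_frequencies_normalized(self, small_panel):
        model = simulate_populations(
            small_panel, [PopulationSpec("p1", "A. mantelli")], n_alleles=2, seed=1
        )
        for locus, freqs in model.allele_freqs["p1"].items():
            assert sum(freqs.values()) == pytest.approx(1.0, abs=1e-9)
            assert all(f >= 0 for f in freqs.values())

    def test_private_alleles_disjoint(self, small_panel):
        model = simulate_populations(
            small_panel,
            [PopulationSpec("p1", "A. mantelli"), PopulationSpec("p2", "A. rowi")],
            private_allele_plan={"p1": ["L1"], "p2": ["L1"]},
            n_alleles=3,
            seed=2,
        )
        s1, s2 = model.support("p1", "L1"), model.support("p2", "L1")
        assert s1 - s2 and s2 - s1  # each has an allele the other lacks

    def test_five_species_table_sized_model(self, panel, five_species_specs):
        model = simulate_populations(panel, five_species_specs, seed=3)
        assert len(model.populations) == 5
        truth = simulate_individuals(
            model,
            {"mantelli": 23, "haastii": 9, "owenii": 7, "rowi": 3, "australis": 15},
            seed=3,
        )
        assert truth["sample"].nunique() == 23 + 9 + 7 + 3 + 15
        # every downstream count (Na etc.) derivable: all loci present
        assert truth.groupby("sample")["locus"].count().eq(len(panel)).all()

    def test_zero_allele_request_rejected(self, small_panel):
        with pytest.raises(ValueError):
            simulate_populations(
                small_panel, [PopulationSpec("p1", "A. mantelli")], n_alleles=0
            )

    def test_oversized_private_plan_rejected(self, small_panel):
        with pytest.raises(ValueError, match="ladder"):
            simulate_populations(
                small_panel,
                [PopulationSpec("p1", "A. mantelli")],
                n_alleles=11,  # L1 ladder has 11 sizes; private allele overflows
                private_allele_plan={"p1": ["L1"]},
            )

    def test_reproducible_under_seed(self, small_panel):
        specs = [PopulationSpec("p1", "A. mantelli")]
        m1 = simulate_populations(small_panel, specs, seed=9)
        m2 = simulate_populations(small_panel, specs, seed=9)
        assert m1.allele_freqs == m2.allele_freqs


def two_allele_model(small_panel, f=0.0):
    freqs = {}
    for name in ("L1", "L2", "L3"):
        lo = small_panel[name].size_range[0]
        u = small_panel[name].repeat_unit
        freqs[name] = {lo: 0.5, lo + u: 0.5}
    return PopulationModel(
        panel=small_panel,
        populations=[PopulationSpec("p1", "A. owenii")],
        allele_freqs={"p1": freqs},
        inbreeding_f={"p1": f},
    )


class TestIndividuals:
    def test_heterozygosity_matches_hwe(self, small_panel):
        truth = simulate_individuals(two_allele_model(small_panel), 1000, seed=4)
        g = truth[truth["locus"] == "L1"]
        het = (g["allele_a"] != g["allele_b"]).mean()
        se = np.sqrt(0.5 * 0.5 / 1000)
        assert het == pytest.approx(0.5, abs=3 * se)

    def test_complete_inbreeding_removes_heterozygotes(self, small_panel):
        truth = simulate_individuals(two_allele_model(small_panel, f=1.0), 100, seed=5)
        auto = truth[truth["locus"] != "Z37B"]
        assert (auto["allele_a"] == auto["allele_b"]).all()

    def test_owenii_female_sex_genotype(self, small_panel):
        truth = simulate_individuals(
            two_allele_model(small_panel), 50, sex_ratio=1.0, seed=6
        )
        sex = truth[truth["locus"] == "Z37B"]
        assert (truth["sex"] == "F").all()
        assert (sex["allele_a"] == 92).all()
        assert (sex["allele_b"] == 94).all()

    def test_males_never_carry_w(self, small_panel):
        truth = simulate_individuals(
            two_allele_model(small_panel), 50, sex_ratio=0.0, seed=7
        )
        sex = truth[truth["locus"] == "Z37B"]
        assert not ((sex["allele_a"] == 92) | (sex["allele_b"] == 92)).any()

    def test_unknown_species_rejected(self, small_panel):
        model = two_allele_model(small_panel)
        model.populations[0] = PopulationSpec("p1", "A. nullius")
        with pytest.raises(KeyError):
            simulate_individuals(model, 5)

    def test_alleles_within_population_support(self, small_panel):
        model = two_allele_model(small_panel)
        truth = simulate_individuals(model, 200, seed=8)
        auto = truth[truth["locus"] == "L1"]
        assert set(auto["allele_a"]) | set(auto["allele_b"]) <= {100, 102}


class TestReplicates:
    def test_zero_error_rates_reproduce_truth(self, small_panel):
        truth = simulate_individuals(two_allele_model(small_panel), 10, seed=9)
        reps = simulate_replicates(truth, ErrorModel(), small_panel, seed=10)
        merged = reps.merge(truth, on=["sample", "locus"])
        for r in merged.itertuples():
            assert set(r.alleles) == {r.allele_a, r.allele_b}

    def test_certain_failure_empties_everything(self, small_panel):
        truth = simulate_individuals(two_allele_model(small_panel), 5, seed=11)
        reps = simulate_replicates(
            truth, ErrorModel(fail_prob=1.0), small_panel, seed=12
        )
        assert (reps["alleles"].map(len) == 0).all()

    def test_replicate_count_and_failure_fraction(self, small_panel):
        truth = simulate_individuals(two_allele_model(small_panel), 100, seed=13)
        em = ErrorModel(fail_prob=0.25, replicates=4)
        reps = simulate_replicates(truth, em, small_panel, seed=14)
        assert len(reps) == len(truth) * 4
        frac = (reps["alleles"].map(len) == 0).mean()
        se = np.sqrt(0.25 * 0.75 / len(reps))
        assert frac == pytest.approx(0.25, abs=3 * se)

    def test_false_alleles_stay_inside_size_range(self, small_panel):
        truth = simulate_individuals(two_allele_model(small_panel), 50, seed=15)
        reps = simulate_replicates(
            truth, ErrorModel(fa_prob=1.0), small_panel, seed=16
        )
        for r in reps.itertuples():
            locus = small_panel[r.locus]
            lo, hi = locus.size_range
            assert all(lo <= a <= hi for a in r.alleles)

    def test_stutter_never_equals_true_allele(self, small_panel):
        rng = np.random.default_rng(0)
        for _ in range(50):
            fa = _stutter_allele((100, 102), small_panel["L1"], rng)
            assert fa not in (100, 102)

    def test_same_seed_identical_tables(self, small_panel):
        truth = simulate_individuals(two_allele_model(small_panel), 10, seed=17)
        em = ErrorModel(fail_prob=0.1, ado_prob=0.2, fa_prob=0.05)
        r1 = simulate_replicates(truth, em, small_panel, seed=18)
        r2 = simulate_replicates(truth, em, small_panel, seed=18)
        pd.testing.assert_frame_equal(r1, r2)

    def test_invalid_error_model_rejected(self):
        with pytest.raises(ValueError):
            ErrorModel(ado_prob=1.5)
        with pytest.raises(ValueError):
            ErrorModel(replicates=0)


class TestQPCRSimulation:
    def test_noiseless_cq_on_the_line(self):
        run = simulate_qpcr({"s1": 0.5}, slope=-3.3219, intercept=21.0, seed=1)
        std = run[run["role"] == "standard"]
        expected = 21.0 + -3.3219 * np.log10(std["concentration"].astype(float))
        np.testing.assert_allclose(std["cq"], expected)

    def test_ten_standard_dilutions_in_triplicate(self):
        run = simulate_qpcr({}, seed=2)
        std = run[run["role"] == "standard"]
        assert std["concentration"].nunique() == 10
        assert len(std) == 30
        concs = default_standard_concentrations()
        assert concs[0] == pytest.approx(5.0) and concs[-1] == pytest.approx(0.002)

    def test_inhibition_shift_moves_spiked_wells(self):
        run = simulate_qpcr(
            {"s1": 0.5, "s2": 0.5}, inhibition_shifts={"s2": 5.0}, seed=3
        )
        spiked = run[run["role"] == "spiked_sample"].groupby("sample")["cq"].mean()
        control = run[run["role"] == "positive_control"]["cq"].mean()
        assert spiked["s2"] - control == pytest.approx(5.0)
        assert spiked["s1"] - control == pytest.approx(0.0)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            simulate_qpcr({"s1": -1.0})
        with pytest.raises(ValueError):
            simulate_qpcr({}, slope=1.0)
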