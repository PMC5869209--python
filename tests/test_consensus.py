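import numpy as np
import pandas as pd
import pytest

from kiwisat import (
    ConsensusCaller,
    ErrorModel,
    call_consensus,
    classify_success,
    error_rates,
    filter_samples,
    quality_index,
    simulate_individuals,
    simulate_replicates,
)

from conftest import make_genotype_frame, make_replicate_frame

A, B, C = 100, 102, 104


def quad(sample, locus, *reps):
    return [(sample, locus, i + 1, r) for i, r in enumerate(reps)]


class TestConsensusCalling:
    def test_heterozygote_from_mixed_support(self):
        reps = make_replicate_frame(quad("s1", "L1", (A, B), (A,), (B,), (A, B)))
        cons = call_consensus(reps)
        assert (cons.allele_a.iloc[0], cons.allele_b.iloc[0]) == (A, B)
        assert cons.flag.iloc[0] == "ok"

    def test_homozygote_needs_hom_min(self):
        reps = make_replicate_frame(quad("s1", "L1", (A,), (A,), (A,), ()))
        cons = call_consensus(reps)
        assert (cons.allele_a.iloc[0], cons.allele_b.iloc[0]) == (A, A)

    def test_two_positive_replicates_alone_insufficient(self):
        reps = make_replicate_frame(quad("s1", "L1", (A,), (A, B)))
        cons = call_consensus(reps)
        assert pd.isna(cons.allele_a.iloc[0])
        assert cons.flag.iloc[0] == "low_support"

    def test_reference_overrides_thin_replicates(self):
        reps = make_replicate_frame(quad("s1", "L1", (A,), (A, B)))
        ref = make_genotype_frame([("s1", "L1", A, B)])
        cons = call_consensus(reps, reference=ref)
        assert (cons.allele_a.iloc[0], cons.allele_b.iloc[0]) == (A, B)
        assert cons.source.iloc[0] == "reference"

    def test_three_supported_alleles_flagged_conflict(self):
        reps = make_replicate_frame(
            quad("s1", "L1", (A, B), (A, C), (B, C), (A, B, C))
        )
        cons = call_consensus(reps)
        assert pd.isna(cons.allele_a.iloc[0])
        assert cons.flag.iloc[0] == "conflict"

    def test_all_failed_flag(self):
        reps = make_replicate_frame(quad("s1", "L1", (), (), (), ()))
        cons = call_consensus(reps)
        assert cons.flag.iloc[0] == "all_failed"

    def test_estimator_params_roundtrip(self):
        cc = ConsensusCaller(het_min=3, hom_min=4)
        assert cc.get_params() == {"het_min": 3, "hom_min": 4}
        cc.set_params(het_min=2)
        assert cc.het_min == 2


class TestQualityIndex:
    def test_full_concordance_gives_one(self):
        rows = quad("s1", "L1", (A, B), (A, B), (A, B), (A, B)) + quad(
            "s1", "L2", (A,), (A,), (A,), (A,)
        )
        reps = make_replicate_frame(rows)
        qi = quality_index(reps, call_consensus(reps))
        assert qi.per_sample["s1"] == pytest.approx(1.0)

    def test_partial_discordance_hand_value(self):
        # 22 perfect loci + one locus scoring 1,1,0,0 -> (22 + 0.5) / 23
        rows = []
        for i in range(22):
            rows += quad("s1", f"L{i}", (A, B), (A, B), (A, B), (A, B))
        rows += quad("s1", "L22", (A, B), (A, B), (A,), ())
        reps = make_replicate_frame(rows)
        qi = quality_index(reps, call_consensus(reps))
        assert qi.per_sample["s1"] == pytest.approx((22 + 0.5) / 23)
        assert qi.per_sample["s1"] == pytest.approx(0.9783, abs=1e-4)

    def test_all_failed_locus_scores_zero(self):
        rows = quad("s1", "L1", (A,), (A,), (A,), (A,)) + quad(
            "s1", "L2", (), (), (), ()
        )
        reps = make_replicate_frame(rows)
        qi = quality_index(reps, call_consensus(reps))
        psl = qi.per_sample_locus.set_index("locus")["qi"]
        assert psl["L2"] == 0.0
        assert qi.per_sample["s1"] == pytest.approx(0.5)

    def test_sample_without_any_consensus_is_undefined(self):
        reps = make_replicate_frame(quad("s1", "L1", (), (), (), ()))
        qi = quality_index(reps, call_consensus(reps))
        assert np.isnan(qi.per_sample["s1"])

    def test_homozygote_replicate_with_extra_allele_scores_zero(self):
        rows = quad("s1", "L1", (A,), (A,), (A,), (A, B))
        reps = make_replicate_frame(rows)
        qi = quality_index(reps, call_consensus(reps))
        assert qi.per_sample["s1"] == pytest.approx(0.75)

    def test_dropping_lowest_qi_loci_never_lowers_mean(self, noisy_dataset):
        _, _, reps = noisy_dataset
        qi = quality_index(reps, call_consensus(reps))
        per_locus = qi.per_locus.sort_values()
        for k in (1, 3, 5):
            keep = per_locus.index[k:]
            sub = reps[reps["locus"].isin(keep)]
            qi_sub = quality_index(sub, call_consensus(sub))
            assert qi_sub.dataset_mean >= qi.dataset_mean - 1e-12


class TestErrorRates:
    def test_ado_definition(self):
        # consensus A/B; positive reps {A}, {A,B}, {B} -> 2 dropouts of 3
        reps = make_replicate_frame(quad("s1", "L1", (A,), (A, B), (B,), ()))
        ref = make_genotype_frame([("s1", "L1", A, B)])
        er = error_rates(reps, ref)
        assert er.ado_by_locus["L1"] == pytest.approx(2 / 3)
        assert er.amplification_failure == pytest.approx(0.25)

    def test_fa_definition(self):
        # consensus A/B; reps {A,B}, {A,C}, {B} -> 1 of 3 positives has C
        reps = make_replicate_frame(quad("s1", "L1", (A, B), (A, C), (), (B,)))
        ref = make_genotype_frame([("s1", "L1", A, B)])
        er = error_rates(reps, ref)
        assert er.fa_by_locus["L1"] == pytest.approx(1 / 3)

    def test_fa_denominator_variant(self):
        rows = quad("s1", "L1", (A, B), (A, C), (), (B,)) + quad(
            "s1", "L2", (A,), (A,), (A,), (A,)
        )
        reps = make_replicate_frame(rows)
        ref = make_genotype_frame([("s1", "L1", A, B), ("s1", "L2", A, A)])
        er_all = error_rates(reps, ref, fa_denominator="all")
        er_het = error_rates(reps, ref, fa_denominator="het")
        assert er_all.fa_by_sample["s1"] == pytest.approx(1 / 7)
        assert er_het.fa_by_sample["s1"] == pytest.approx(1 / 3)
        with pytest.raises(ValueError):
            error_rates(reps, ref, fa_denominator="pooled")

    def test_no_heterozygous_consensus_gives_undefined_ado(self):
        reps = make_replicate_frame(quad("s1", "L1", (A,), (A,), (A,), (A,)))
        er = error_rates(reps, call_consensus(reps))
        assert np.isnan(er.ado_by_locus["L1"])

    def test_zero_error_data_gives_exact_zeros(self, small_panel):
        from kiwisat import PopulationModel, PopulationSpec

        model = PopulationModel(
            panel=small_panel,
            populations=[PopulationSpec("pop1", "A. mantelli")],
            allele_freqs={
                "pop1": {l: {100: 0.5, 102: 0.5} for l in ("L1", "L2", "L3")}
            },
        )
        truth = simulate_individuals(model, 20, seed=3)
        reps = simulate_replicates(truth, ErrorModel(), small_panel, seed=4)
        er = error_rates(reps, call_consensus(reps))
        assert er.amplification_failure == 0.0
        assert (er.ado_by_locus.dropna() == 0).all()
        assert (er.fa_by_locus == 0).all()


class TestFilters:
    def _consensus_with_missing(self, n_missing):
        rows = [("s1", f"L{i}", A, B) for i in range(23 - n_missing)]
        rows += [("s1", f"L{i}", None, None) for i in range(23 - n_missing, 23)]
        return make_genotype_frame(rows)

    @pytest.mark.parametrize("n_missing, kept", [(3, False), (2, True), (0, True)])
    def test_max_failed_loci_boundary(self, n_missing, kept):
        cons = self._consensus_with_missing(n_missing)
        out = filter_samples(cons, max_failed_loci=2)
        assert ("s1" in set(out["sample"])) is kept

    def test_complete_table_unchanged(self):
        cons = self._consensus_with_missing(0)
        out = filter_samples(cons)
        pd.testing.assert_frame_equal(out, cons)

    @pytest.mark.parametrize(
        "qi, success", [(0.88, True), (0.75, True), (0.74, False)]
    )
    def test_success_threshold_boundary_inclusive(self, qi, success):
        flags, frac = classify_success(pd.Series({"s1": qi}))
        assert bool(flags["success"].iloc[0]) is success
        assert frac == (1.0 if success else 0.0)
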