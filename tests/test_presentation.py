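"""PHBR scoring, binding calls, binding fractions and mutated-allele bias."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import hmean

from mhcescape import presentation as pres
from mhcescape.cohort_stats import ValidationError
from mhcescape.io_formats import AffinityRankTable, Patient, Group, SomaticMutation, VariantClass

from oracles import mann_whitney_exact_p, wilcoxon_exact_p

rank6 = st.lists(
    st.floats(min_value=0.01, max_value=100.0, allow_nan=False), min_size=6, max_size=6
)


def _table(rows: dict) -> AffinityRankTable:
    wide = pd.DataFrame.from_dict(rows, orient="index", columns=range(1, 7))
    wide.index.name = "mutation_id"
    return AffinityRankTable(wide)


def _mut(mid, patient="P1", vc=VariantClass.MISSENSE, rna=10):
    return SomaticMutation(mid, patient, "GENE1", vc, "1", 100, 10, 5, 50, rna)


class TestPHBR:
    def test_best_rank_is_minimum(self):
        assert pres.best_rank_per_allele([5.0, 0.3, 12.0]) == 0.3
        assert pres.best_rank_per_allele([2.0]) == 2.0
        assert pres.best_rank_per_allele([7, 7, 7]) == 7
        with pytest.raises(ValidationError):
            pres.best_rank_per_allele([])

    @pytest.mark.parametrize(
        "ranks,expected",
        [
            ([2, 2, 2, 2, 2, 2], 2.0),
            ([1, 2, 3, 4, 5, 6], 6 / (1 + 1 / 2 + 1 / 3 + 1 / 4 + 1 / 5 + 1 / 6)),
            ([0.5, 0.5, 0.5, 50, 50, 50], 6 / 6.06),
        ],
    )
    def test_known_values(self, ranks, expected):
        assert pres.phbr_score(ranks) == pytest.approx(expected, abs=1e-12)

    def test_matches_harmonic_mean_oracle_on_1000_vectors(self, rng):
        vectors = np.exp(rng.uniform(np.log(0.01), np.log(100), size=(1000, 6)))
        for v in vectors:
            assert pres.phbr_score(v) == pytest.approx(hmean(v), abs=1e-12)

    @given(rank6)
    def test_bounded_by_min_and_max(self, ranks):
        score = pres.phbr_score(ranks)
        assert min(ranks) - 1e-9 <= score <= max(ranks) + 1e-9

    @given(rank6, st.integers(min_value=0, max_value=5), st.floats(min_value=1.01, max_value=5))
    def test_strictly_increasing_in_each_argument(self, ranks, idx, factor):
        bumped = list(ranks)
        bumped[idx] = bumped[idx] * factor
        assert pres.phbr_score(bumped) > pres.phbr_score(ranks)

    def test_arity_and_positivity_enforced(self):
        with pytest.raises(ValidationError):
            pres.phbr_score([1, 2, 3])
        with pytest.raises(ValidationError):
            pres.phbr_score([1, 2, 3, 4, 5, 0])

    def test_binding_cutoff_inclusive(self):
        assert pres.is_binding(2.0)
        assert not pres.is_binding(2.0001)
        assert pres.is_binding(0.1)


class TestBindingFraction:
    def test_direct_count(self):
        # PHBRs [1.0, 3.0, 1.5, 5.0] at cutoff 2 -> 2/4
        muts = [_mut(f"M{i}") for i in range(4)]
        table = _table({f"M{i}": [v] * 6 for i, v in enumerate([1.0, 3.0, 1.5, 5.0])})
        assert pres.binding_fraction(muts, table, cutoff=2.0) == 0.5

    def test_extreme_cutoffs(self):
        muts = [_mut(f"M{i}") for i in range(3)]
        table = _table({f"M{i}": [v] * 6 for i, v in enumerate([1.0, 3.0, 9.0])})
        assert pres.binding_fraction(muts, table, cutoff=100.0) == 1.0
        assert pres.binding_fraction(muts, table, cutoff=0.5) == 0.0

    def test_empty_denominator_is_nan(self):
        silent = [_mut("M1", vc=VariantClass.SILENT), _mut("M2", rna=0)]
        table = _table({"M1": [1] * 6, "M2": [1] * 6})
        assert np.isnan(pres.binding_fraction(silent, table))

    def test_nondecreasing_in_cutoff(self, small_cohort):
        ids = small_cohort.patients["patient_id"]
        cutoffs = [0.5, 1, 2, 4, 8, 16, 100]
        prev = None
        for cut in cutoffs:
            frac = pres.binding_fractions(small_cohort.mutations, small_cohort.ranks, ids, cut)
            if prev is not None:
                assert (frac.dropna() >= prev[frac.dropna().index] - 1e-12).all()
            prev = frac

    def test_curve_single_patient_and_duplicates(self):
        muts = [_mut(f"M{i}") for i in range(4)]
        table = _table({f"M{i}": [v] * 6 for i, v in enumerate([1.0, 3.0, 1.5, 5.0])})
        frame = pd.DataFrame([m.__dict__ | {"variant_classification": m.variant_classification.value} for m in muts])
        curve = pres.binding_fraction_curve(frame, table, ["P1"], [1.0, 2.0, 10.0])
        assert curve.tolist() == [0.25, 0.5, 1.0]
        # duplicating the patient's data leaves the median curve unchanged
        muts2 = [_mut(f"M{i+4}", patient="P2") for i in range(4)]
        table2 = _table(
            {f"M{i}": [v] * 6 for i, v in enumerate([1.0, 3.0, 1.5, 5.0])}
            | {f"M{i+4}": [v] * 6 for i, v in enumerate([1.0, 3.0, 1.5, 5.0])}
        )
        frame2 = pd.concat(
            [frame, pd.DataFrame([m.__dict__ | {"variant_classification": m.variant_classification.value} for m in muts2])],
            ignore_index=True,
        )
        curve2 = pres.binding_fraction_curve(frame2, table2, ["P1", "P2"], [1.0, 2.0, 10.0])
        assert curve2.tolist() == curve.tolist()

    def test_empty_group_is_error(self, small_cohort):
        with pytest.raises(ValidationError):
            pres.binding_fraction_curve(
                small_cohort.mutations, small_cohort.ranks, ["NOBODY"], [2.0]
            )


class TestAlleleBias:
    def _patient(self, slot=1):
        return Patient("P1", "COAD", "II", ("A",) * 6, 0.1, Group.HLA_MUT, mutated_slot=slot)

    def test_allele_binding_counts(self):
        muts = [_mut("M1")]
        table = _table({"M1": [1, 50, 50, 50, 50, 50]})
        assert pres.allele_binding_counts(muts, table, 2.0).tolist() == [1, 0, 0, 0, 0, 0]
        assert pres.allele_binding_counts([], table, 2.0).tolist() == [0] * 6
        muts3 = [_mut(f"M{i}") for i in range(3)]
        all_bind = _table({f"M{i}": [1] * 6 for i in range(3)})
        assert pres.allele_binding_counts(muts3, all_bind, 2.0).tolist() == [3] * 6

    def test_bias_direction_arithmetic(self):
        muts = [_mut(f"M{i}") for i in range(4)] + [_mut("M4", rna=10)]
        # counts [4,1,1,1,1,1] at slot 1: 4 muts bind slot 1 only, one binds all
        table = _table(
            {f"M{i}": [1, 50, 50, 50, 50, 50] for i in range(3)} | {"M3": [1, 50, 50, 50, 50, 50], "M4": [1, 1, 1, 1, 1, 1]}
        )
        res = pres.mutant_allele_bias(self._patient(1), muts, table, 2.0)
        assert res.n_mut_allele == 5 and res.mean_other == 1.0
        assert res.direction is pres.BiasDirection.MUT_HIGHER

    def test_tied_and_other_higher(self):
        muts = [_mut("M1")]
        equal = _table({"M1": [1] * 6})
        assert (
            pres.mutant_allele_bias(self._patient(1), muts, equal, 2.0).direction
            is pres.BiasDirection.TIED
        )
        other = _table({"M1": [50, 1, 1, 1, 1, 1]})
        res = pres.mutant_allele_bias(self._patient(1), muts, other, 2.0)
        assert res.direction is pres.BiasDirection.OTHER_HIGHER

    def test_patient_without_mutated_slot_is_error(self):
        wt = Patient("P1", "COAD", "II", ("A",) * 6, 0.1, Group.WT)
        with pytest.raises(ValidationError):
            pres.mutant_allele_bias(wt, [], _table({"M1": [1] * 6}), 2.0)

    def test_bias_test_all_positive_differences(self):
        results = [
            pres.BiasResult(f"P{i}", 3 + i, 1.0 + 0.1 * i, pres.BiasDirection.MUT_HIGHER)
            for i in range(5)
        ]
        res = pres.bias_test(results)
        assert res.raw_p == pytest.approx(0.0625)  # 2 / 2^5, sign enumeration
        diffs = [r.n_mut_allele - r.mean_other for r in results]
        assert res.raw_p == pytest.approx(wilcoxon_exact_p(diffs))

    def test_bias_test_symmetric_differences(self):
        results = [
            pres.BiasResult("P1", 4, 1.0, pres.BiasDirection.MUT_HIGHER),
            pres.BiasResult("P2", 1, 4.0, pres.BiasDirection.OTHER_HIGHER),
        ]
        assert pres.bias_test(results).raw_p == 1.0

    def test_bias_detected_under_default_effect(self):
        """With bias_strength > 0 the paired Wilcoxon rejects in >=90% of seeds."""
        from mhcescape.synthetic_cohort import CohortConfig, generate_cohort

        hits = 0
        seeds = range(10)
        for seed in seeds:
            cohort = generate_cohort(CohortConfig(n_patients=500, seed=seed))
            bias = pres.bias_results(cohort.patients, cohort.mutations, cohort.ranks)
            hits += pres.bias_test(bias).raw_p < 0.05
        assert hits >= 9


class TestTimingBiasContrast:
    def test_exact_separated_strata(self):
        """early=[5,6,7] vs late=[1,2,3]: U=9, exact two-sided p=0.1."""
        from mhcescape.cohort_stats import mann_whitney

        res = mann_whitney([5, 6, 7], [1, 2, 3])
        assert res.statistic == 9.0
        assert res.raw_p == pytest.approx(0.1)
        assert res.raw_p == pytest.approx(mann_whitney_exact_p([5, 6, 7], [1, 2, 3]))

    def test_identical_strata_p_one(self):
        from mhcescape.cohort_stats import mann_whitney

        assert mann_whitney([1, 2, 3], [1, 2, 3]).raw_p == 1.0

    def test_empty_stratum_is_error(self, small_cohort):
        timing = pd.DataFrame(
            columns=["patient_id", "mutation_id", "gene_class", "af", "percentile", "in_cnv", "timing_class"]
        )
        with pytest.raises(ValidationError):
            pres.timing_bias_contrast(
                small_cohort.patients, small_cohort.mutations, small_cohort.ranks, timing
            )

    def test_early_mutants_carry_more_mutant_slot_binders(self):
        """Clonal (high-VAF) HLA escape couples to stronger mutated-slot
        binding, so early medians exceed late medians."""
        from mhcescape.synthetic_cohort import CohortConfig, generate_cohort
        from mhcescape.pipeline import run_pipeline

        hits = 0
        for seed in range(5):
            cohort = generate_cohort(
                CohortConfig(n_patients=1000, seed=seed, bias_strength=0.2, early_bias_multiplier=3.0)
            )
            res = run_pipeline(cohort)
            row = res["timing_tests"]
            row = row[row["label"] == "mutant-allele-binders:early-vs-late"]
            if len(row) == 1:
                n1n2 = row.iloc[0]["n1"] * row.iloc[0]["n2"]
                hits += row.iloc[0]["statistic"] > n1n2 / 2  # early stochastically larger
        assert hits >= 4


def test_hla_mutant_group_curve_dominates_wt_at_cutoff():
    """The binding bias lifts the HLA-mutant group's median binding
    fraction above the wild-type group's at the binding cutoff."""
    from mhcescape.synthetic_cohort import CohortConfig, generate_cohort
    from mhcescape.io_formats import Group

    hits = 0
    for seed in range(10):
        cohort = generate_cohort(CohortConfig(n_patients=1000, seed=300 + seed))
        patients = cohort.patients
        hla_ids = patients.loc[patients["group"] == Group.HLA_MUT.value, "patient_id"]
        wt_ids = patients.loc[patients["group"] == Group.WT.value, "patient_id"]
        hla_curve = pres.binding_fraction_curve(cohort.mutations, cohort.ranks, hla_ids, [2.0])
        wt_curve = pres.binding_fraction_curve(cohort.mutations, cohort.ranks, wt_ids, [2.0])
        hits += hla_curve.iloc[0] >= wt_curve.iloc[0]
    assert hits >= 9
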