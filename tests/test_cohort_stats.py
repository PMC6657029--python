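"""Filters, burden, MSI binarization, group assignment, cytolytic score
and the shared statistical tests (against enumeration oracles)."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mhcescape import cohort_stats as cs
from mhcescape.io_formats import Group, SomaticMutation, ValidationError, VariantClass

from oracles import bh_stepup, fisher_exact_p, mann_whitney_exact_p, wilcoxon_exact_p


def _mut(vc=VariantClass.MISSENSE, rna=10, gene="GENE1"):
    return SomaticMutation("M1", "P1", gene, vc, "1", 100, 10, 5, 50, rna)


class TestFiltersAndScores:
    @pytest.mark.parametrize("rna,expected", [(5, True), (4, False), (0, False), (50, True)])
    def test_expression_threshold_inclusive(self, rna, expected):
        assert cs.is_expressed(_mut(rna=rna)) is expected

    @pytest.mark.parametrize(
        "vc,expected",
        [
            (VariantClass.MISSENSE, True),
            (VariantClass.NONSENSE, True),
            (VariantClass.FRAMESHIFT_INDEL, True),
            (VariantClass.SPLICE, True),
            (VariantClass.SILENT, False),
            (VariantClass.NONCODING, False),
        ],
    )
    def test_nonsynonymous_filter(self, vc, expected):
        assert cs.is_nonsynonymous(_mut(vc=vc)) is expected

    def test_burden_pseudocount(self):
        assert cs.mutation_burden([_mut() for _ in range(10)]) == 11
        assert cs.mutation_burden([]) == 1
        mixed = [_mut(rna=10), _mut(rna=0), _mut(rna=2)]
        assert cs.mutation_burden(mixed) == 2

    @pytest.mark.parametrize("score,expected", [(0.55, "MSI_H"), (0.1, "MSS"), (0.4, "MSI_H")])
    def test_msi_binarization(self, score, expected):
        assert cs.msi_status(score) == expected

    def test_negative_mantis_rejected(self):
        with pytest.raises(ValidationError):
            cs.msi_status(-0.1)

    @pytest.mark.parametrize(
        "b2m,hla,expected",
        [
            ([VariantClass.MISSENSE], [], Group.B2M_MUT),
            ([], [VariantClass.SILENT], Group.SYN_ONLY),
            ([VariantClass.NONSENSE], [VariantClass.MISSENSE], Group.BOTH),
            ([], [], Group.WT),
            ([VariantClass.SILENT], [VariantClass.MISSENSE], Group.HLA_MUT),
        ],
    )
    def test_group_assignment(self, b2m, hla, expected):
        b2m_muts = [_mut(vc=v, gene="B2M") for v in b2m]
        hla_muts = [_mut(vc=v, gene="HLA-A") for v in hla]
        assert cs.assign_group(b2m_muts, hla_muts) is expected

    def test_cytolytic_score_identities(self):
        expr = pd.DataFrame(
            {
                "patient_id": ["P1", "P2", "P3"],
                "gzma_log2tpm": [4.0, 5.0, 6.0],
                "prf1_log2tpm": [1.0, 2.0, 3.0],
            }
        )
        scores = cs.cytolytic_scores(expr)
        assert scores["P2"] == pytest.approx(0.0)  # at the cohort mean
        assert scores.sum() == pytest.approx(0.0)
        sd = np.std([4.0, 5.0, 6.0])
        assert scores["P3"] == pytest.approx(2.0 * (1.0 / sd))
        one_sd_above = cs.cytolytic_score(
            cs.ImmuneProfile("P3", 6.0, 3.0),
            [cs.ImmuneProfile(p, g, f) for p, g, f in zip(expr.patient_id, expr.gzma_log2tpm, expr.prf1_log2tpm)],
        )
        assert one_sd_above == scores["P3"]

    def test_cytolytic_zero_variance_rejected(self):
        expr = pd.DataFrame(
            {"patient_id": ["P1", "P2"], "gzma_log2tpm": [1.0, 1.0], "prf1_log2tpm": [1.0, 2.0]}
        )
        with pytest.raises(ValidationError):
            cs.cytolytic_scores(expr)


class TestMannWhitney:
    def test_separated_samples_exact(self):
        res = cs.mann_whitney([1, 2, 3], [4, 5, 6])
        assert res.raw_p == pytest.approx(2 / 20)

    def test_identical_samples(self):
        assert cs.mann_whitney([1, 2, 3], [1, 2, 3]).raw_p == 1.0

    def test_two_sided_symmetry(self, rng):
        x, y = rng.normal(size=6), rng.normal(size=5)
        assert cs.mann_whitney(x, y).raw_p == pytest.approx(cs.mann_whitney(y, x).raw_p)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValidationError):
            cs.mann_whitney([], [1.0])

    @given(
        st.lists(st.integers(0, 10_000), min_size=4, max_size=12, unique=True),
        st.integers(2, 10),
    )
    def test_matches_enumeration_oracle_small_samples(self, pooled, cut):
        cut = min(cut, len(pooled) - 2)
        x, y = pooled[:cut], pooled[cut:]
        assert cs.mann_whitney(x, y).raw_p == pytest.approx(mann_whitney_exact_p(x, y))


class TestWilcoxon:
    @given(
        st.lists(st.integers(1, 10_000), min_size=3, max_size=12, unique=True),
        st.integers(0, 2**12 - 1),
    )
    def test_matches_sign_enumeration_oracle(self, magnitudes, signs):
        diffs = [m if (signs >> i) & 1 else -m for i, m in enumerate(magnitudes)]
        assert cs.wilcoxon_paired(diffs).raw_p == pytest.approx(wilcoxon_exact_p(diffs))

    def test_all_zero_differences_flagged(self):
        res = cs.wilcoxon_paired([0.0, 0.0, 0.0])
        assert res.degenerate and res.raw_p == 1.0


class TestFisher:
    def test_cross_product_odds_ratio(self):
        assert cs.fisher_exact([[10, 90], [1, 99]]).statistic == pytest.approx(11.0)
        balanced = cs.fisher_exact([[5, 5], [5, 5]])
        assert balanced.statistic == 1.0 and balanced.raw_p == 1.0

    def test_zero_cell_unbounded(self):
        res = cs.fisher_exact([[5, 0], [2, 7]])
        assert res.statistic == float("inf") and res.degenerate

    def test_degenerate_margin_flagged(self):
        res = cs.fisher_exact([[0, 0], [3, 4]])
        assert res.degenerate

    @given(
        st.integers(0, 15), st.integers(0, 15), st.integers(0, 15), st.integers(0, 15)
    )
    def test_matches_hypergeometric_oracle_margins_30(self, a, b, c, d):
        table = [[a, b], [c, d]]
        if min(a + b, c + d, a + c, b + d) == 0:
            return  # degenerate margins handled separately
        assert cs.fisher_exact(table).raw_p == pytest.approx(fisher_exact_p(table), abs=1e-9)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValidationError):
            cs.fisher_exact([[1, -2], [3, 4]])


class TestBH:
    def test_hand_computed_stepup(self):
        assert cs.bh_adjust([0.01, 0.02, 0.03]).tolist() == pytest.approx([0.03, 0.03, 0.03])
        assert cs.bh_adjust([0.2]).tolist() == [0.2]

    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=20))
    def test_matches_oracle_and_dominates_raw(self, pvalues):
        adjusted = cs.bh_adjust(pvalues)
        assert np.allclose(adjusted, bh_stepup(pvalues))
        assert (adjusted >= np.asarray(pvalues) - 1e-15).all()
        assert (adjusted <= 1.0 + 1e-15).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            cs.bh_adjust([0.5, 1.5])


class TestCohortContrasts:
    def _patients(self, rows):
        frame = pd.DataFrame(rows, columns=["patient_id", "tumor_type", "group", "mantis_score"])
        return frame

    def test_merge_then_threshold(self):
        # 3 mutated COAD + 2 mutated READ patients merge to CRC (5) and are
        # retained at min_mutated=5; a type with 4 mutated patients is not
        rows = []
        for i in range(3):
            rows.append((f"C{i}", "COAD", "B2M_MUT", 0.1))
        for i in range(2):
            rows.append((f"R{i}", "READ", "B2M_MUT", 0.1))
        for i in range(4):
            rows.append((f"L{i}", "LUAD", "B2M_MUT", 0.1))
        for i in range(20):
            rows.append((f"W{i}", "COAD" if i < 10 else "LUAD", "WT", 0.1))
        patients = self._patients(rows)
        values = pd.Series(
            np.arange(len(patients), dtype=float), index=patients["patient_id"]
        )
        results = cs.per_tumor_type_contrast(patients, values, "burden", min_mutated=5)
        labels = [r.label for r in results]
        assert labels == ["burden:B2M_MUT-vs-WT:CRC"]
        assert results[0].adjusted_p == results[0].raw_p  # BH of a single test

    def test_msi_enrichment_degenerate_without_msi_patients(self):
        patients = self._patients(
            [("P1", "COAD", "B2M_MUT", 0.1), ("P2", "COAD", "WT", 0.1), ("P3", "COAD", "WT", 0.2)]
        )
        assert cs.msi_enrichment(patients, Group.B2M_MUT).degenerate

    def test_burden_table_covers_patients_without_mutations(self):
        muts = pd.DataFrame(
            {
                "patient_id": ["P1"],
                "variant_classification": [VariantClass.MISSENSE.value],
                "rna_read_count": [9],
            }
        )
        burden = cs.burden_table(muts, ["P1", "P2"])
        assert burden.tolist() == [2, 1]
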