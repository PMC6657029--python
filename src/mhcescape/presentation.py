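"""PHBR-I presentation scoring, binding calls, binding-fraction analysis
and mutant-allele bias statistics.

The Patient Harmonic-mean Best Rank (PHBR-I) score of a mutation is the
harmonic mean, across the patient's 6 HLA class I allele slots, of the
best (minimum) binding percentile rank of the peptides covering that
mutation. Lower scores mean better predicted presentation; scores <= 2
(inclusive) are called *binding*, i.e. the mutation is a putative
neoantigen.

Allele-specific analyses (mutated-allele bias, early/late contrasts) call
a mutation binding *at a slot* when that slot's best rank is <= the same
cutoff — a per-allele call, deliberately distinct from the PHBR-level
call. Homozygous allele pairs occupy two slots and contribute two
(duplicate) values everywhere.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .cohort_stats import (
    ComparisonResult,
    ValidationError,
    is_expressed,
    mann_whitney,
    wilcoxon_paired,
)
from .io_formats import (
    AffinityRankTable,
    Group,
    N_SLOTS,
    NEOANTIGEN_SOURCE_CLASSES,
    Patient,
    SomaticMutation,
)

__all__ = [
    "PHBR_BINDING_CUTOFF",
    "PHBRResult",
    "BiasDirection",
    "BiasResult",
    "best_rank_per_allele",
    "phbr_score",
    "is_binding",
    "phbr_table",
    "binding_fraction",
    "binding_fractions",
    "binding_fraction_curve",
    "allele_binding_counts",
    "mutant_allele_bias",
    "bias_results",
    "bias_test",
    "timing_bias_contrast",
]

#: Default PHBR-I cutoff separating binding from non-binding mutations
#: (inclusive: a score of exactly 2 is binding).
PHBR_BINDING_CUTOFF = 2.0


@dataclass
class PHBRResult:
    """PHBR score and binding call for one mutation."""

    mutation_id: str
    per_slot_best_rank: tuple[float, ...]
    phbr: float
    binding: bool


class BiasDirection(str, enum.Enum):
    MUT_HIGHER = "mut_higher"   # more neoantigens bind the mutated allele
    OTHER_HIGHER = "other_higher"
    TIED = "tied"

    def __str__(self) -> str:  # pragma: no cover
        return self.value


@dataclass
class BiasResult:
    """Mutated- vs unmutated-allele neoantigen counts for one patient."""

    patient_id: str
    n_mut_allele: int
    mean_other: float
    direction: BiasDirection


# ---------------------------------------------------------------------------
# Core scores
# ---------------------------------------------------------------------------


def best_rank_per_allele(peptide_ranks: Sequence[float]) -> float:
    """Best (minimum) percentile rank among peptides at one (mutation, slot)."""
    ranks = np.asarray(peptide_ranks, dtype=float)
    if ranks.size == 0:
        raise ValidationError("best_rank_per_allele requires a nonempty list")
    if (ranks <= 0).any():
        raise ValidationError("peptide ranks must be > 0")
    return float(ranks.min())


def phbr_score(best_ranks: Sequence[float]) -> float:
    """Harmonic mean of the 6 per-slot best ranks: 6 / sum(1/r_i).

    Homozygous alleles contribute duplicate values. The result always lies
    between the minimum and maximum rank and is strictly increasing in each
    argument.
    """
    ranks = np.asarray(best_ranks, dtype=float)
    if ranks.shape != (N_SLOTS,):
        raise ValidationError(
            f"phbr_score requires exactly {N_SLOTS} best ranks, got {ranks.shape}"
        )
    if (ranks <= 0).any():
        raise ValidationError("best ranks must be > 0")
    return float(N_SLOTS / np.sum(1.0 / ranks))


def is_binding(phbr: float, cutoff: float = PHBR_BINDING_CUTOFF) -> bool:
    """Binding call at the PHBR cutoff (inclusive: phbr == cutoff binds)."""
    if phbr <= 0:
        raise ValidationError("PHBR must be > 0")
    return phbr <= cutoff


def phbr_table(
    ranks: AffinityRankTable, cutoff: float = PHBR_BINDING_CUTOFF
) -> pd.DataFrame:
    """Vectorized PHBR scores for every mutation in a rank table.

    Returns a frame indexed by mutation_id with columns ``phbr`` and
    ``binding``.
    """
    wide = ranks.wide
    phbr = N_SLOTS / (1.0 / wide.to_numpy(dtype=float)).sum(axis=1)
    return pd.DataFrame(
        {"phbr": phbr, "binding": phbr <= cutoff}, index=wide.index
    )


# ---------------------------------------------------------------------------
# Binding fractions
# ---------------------------------------------------------------------------


def _neoantigen_source_ids(mutations: pd.DataFrame) -> pd.Series:
    keep = mutations["variant_classification"].isin(
        [vc.value for vc in NEOANTIGEN_SOURCE_CLASSES]
    ) & (mutations["rna_read_count"] >= 5)
    return mutations.loc[keep, ["patient_id", "mutation_id"]]


def binding_fraction(
    patient_mutations: Iterable[SomaticMutation],
    ranks: AffinityRankTable,
    cutoff: float = PHBR_BINDING_CUTOFF,
) -> float:
    """Fraction of one patient's expressed missense/indel mutations whose
    PHBR is <= cutoff. NaN when the patient has no qualifying mutation
    (such patients are excluded from group summaries)."""
    eligible = [
        m
        for m in patient_mutations
        if m.variant_classification in NEOANTIGEN_SOURCE_CLASSES and is_expressed(m)
    ]
    if not eligible:
        return float("nan")
    n_binding = sum(
        1 for m in eligible if is_binding(phbr_score(ranks.best_ranks(m.mutation_id)), cutoff)
    )
    return n_binding / len(eligible)


def binding_fractions(
    mutations: pd.DataFrame,
    ranks: AffinityRankTable,
    patient_ids: Sequence[str] | pd.Index,
    cutoff: float = PHBR_BINDING_CUTOFF,
) -> pd.Series:
    """Vectorized per-patient binding fractions (NaN where undefined)."""
    src = _neoantigen_source_ids(mutations)
    phbr = phbr_table(ranks, cutoff)["phbr"]
    merged = src.assign(phbr=phbr.reindex(src["mutation_id"]).to_numpy())
    if merged["phbr"].isna().any():
        missing = merged.loc[merged["phbr"].isna(), "mutation_id"].head().tolist()
        raise ValidationError(f"mutations absent from rank table, e.g. {missing}")
    grouped = merged.groupby("patient_id")["phbr"]
    frac = grouped.apply(lambda s: float(np.mean(s <= cutoff)))
    return frac.reindex(pd.Index(patient_ids, name="patient_id")).rename("binding_fraction")


def binding_fraction_curve(
    mutations: pd.DataFrame,
    ranks: AffinityRankTable,
    patient_ids: Sequence[str] | pd.Index,
    cutoffs: Sequence[float],
) -> pd.Series:
    """Median-across-patients binding fraction at each PHBR cutoff.

    The per-group curve underlying the ECDF-style display: nondecreasing in
    the cutoff. Patients with no expressed missense/indel mutations are
    excluded; an empty group is an error.
    """
    src = _neoantigen_source_ids(mutations)
    src = src[src["patient_id"].isin(pd.Index(patient_ids))]
    if len(src) == 0:
        raise ValidationError("no patient in the group has a defined binding fraction")
    phbr = phbr_table(ranks)["phbr"].reindex(src["mutation_id"]).to_numpy()
    if np.isnan(phbr).any():
        raise ValidationError("mutations absent from rank table")
    df = src.assign(phbr=phbr)
    cutoffs = np.asarray(list(cutoffs), dtype=float)
    per_patient = df.groupby("patient_id")["phbr"].apply(
        lambda s: pd.Series(
            (np.sort(s.to_numpy())[None, :] <= cutoffs[:, None]).mean(axis=1), index=cutoffs
        )
    )
    medians = per_patient.groupby(level=1).median()
    return medians.reindex(cutoffs).rename("median_binding_fraction")


# ---------------------------------------------------------------------------
# Mutated-allele bias
# ---------------------------------------------------------------------------


def allele_binding_counts(
    patient_mutations: Iterable[SomaticMutation],
    ranks: AffinityRankTable,
    cutoff: float = PHBR_BINDING_CUTOFF,
) -> np.ndarray:
    """Per-slot counts of expressed missense/indel mutations whose *per-slot*
    best rank is <= cutoff (allele-specific calls, not PHBR)."""
    counts = np.zeros(N_SLOTS, dtype=np.int64)
    for m in patient_mutations:
        if m.variant_classification in NEOANTIGEN_SOURCE_CLASSES and is_expressed(m):
            counts += ranks.best_ranks(m.mutation_id) <= cutoff
    return counts


def _bias_from_counts(patient_id: str, counts: np.ndarray, mutated_slot: int) -> BiasResult:
    counts = np.asarray(counts)
    if counts.shape != (N_SLOTS,):
        raise ValidationError(f"expected {N_SLOTS} slot counts")
    idx = mutated_slot - 1
    n_mut = int(counts[idx])
    mean_other = float(np.delete(counts, idx).mean())
    if n_mut > mean_other:
        direction = BiasDirection.MUT_HIGHER
    elif n_mut < mean_other:
        direction = BiasDirection.OTHER_HIGHER
    else:
        direction = BiasDirection.TIED
    return BiasResult(str(patient_id), n_mut, mean_other, direction)


def mutant_allele_bias(
    patient: Patient,
    patient_mutations: Iterable[SomaticMutation],
    ranks: AffinityRankTable,
    cutoff: float = PHBR_BINDING_CUTOFF,
) -> BiasResult:
    """Compare neoantigen counts at the mutated slot vs the mean of the
    other five slots (unweighted arithmetic mean; duplicate slots of a
    homozygous pair count as distinct slots)."""
    if patient.mutated_slot is None:
        raise ValidationError(
            f"patient {patient.patient_id} has no mutated HLA allele slot"
        )
    counts = allele_binding_counts(patient_mutations, ranks, cutoff)
    return _bias_from_counts(patient.patient_id, counts, patient.mutated_slot)


def _allele_binding_count_frame(
    mutations: pd.DataFrame, ranks: AffinityRankTable, cutoff: float
) -> pd.DataFrame:
    """Per-patient per-slot binder counts (vectorized)."""
    src = _neoantigen_source_ids(mutations)
    binds = (ranks.wide.reindex(src["mutation_id"]) <= cutoff).to_numpy()
    out = pd.DataFrame(binds.astype(np.int64), columns=list(range(1, N_SLOTS + 1)))
    out["patient_id"] = src["patient_id"].to_numpy()
    return out.groupby("patient_id").sum()


def bias_results(
    patients: pd.DataFrame,
    mutations: pd.DataFrame,
    ranks: AffinityRankTable,
    cutoff: float = PHBR_BINDING_CUTOFF,
) -> list[BiasResult]:
    """Mutated-allele bias for every HLA_MUT patient in a cohort."""
    counts = _allele_binding_count_frame(mutations, ranks, cutoff)
    hla = patients[patients["group"] == Group.HLA_MUT.value]
    results = []
    for r in hla.itertuples(index=False):
        row = (
            counts.loc[r.patient_id].to_numpy()
            if r.patient_id in counts.index
            else np.zeros(N_SLOTS, dtype=np.int64)
        )
        results.append(_bias_from_counts(r.patient_id, row, int(r.mutated_slot)))
    return results


def bias_test(results: Sequence[BiasResult], label: str = "mutant-allele-bias") -> ComparisonResult:
    """Paired Wilcoxon signed-rank test on (n_mut_allele - mean_other)."""
    if len(results) < 2:
        raise ValidationError("bias_test requires >= 2 patients")
    diffs = [r.n_mut_allele - r.mean_other for r in results]
    return wilcoxon_paired(diffs, label=label)


def timing_bias_contrast(
    patients: pd.DataFrame,
    mutations: pd.DataFrame,
    ranks: AffinityRankTable,
    timing: pd.DataFrame,
    cutoff: float = PHBR_BINDING_CUTOFF,
    label: str = "mutant-allele-binders:early-vs-late",
) -> ComparisonResult:
    """Mann-Whitney contrast of mutated-allele binder counts between
    early (AF percentile > 60) and late (< 40) HLA-mutant patients.

    MSI-H patients and patients mutated in both B2M and HLA are excluded
    (the latter by restricting to the HLA_MUT group). ``timing`` is the
    per-escape-mutation annotation table from :mod:`mhcescape.timing`.
    """
    from .cohort_stats import msi_status

    hla = patients[patients["group"] == Group.HLA_MUT.value].copy()
    hla = hla[hla["mantis_score"].map(msi_status) == "MSS"]
    cls = (
        timing[timing["gene_class"] == "HLA"]
        .drop_duplicates("patient_id")
        .set_index("patient_id")["timing_class"]
    )
    hla["timing_class"] = cls.reindex(hla["patient_id"]).to_numpy()
    counts = _allele_binding_count_frame(mutations, ranks, cutoff)

    def _n_mut(row) -> int:
        if row.patient_id not in counts.index:
            return 0
        return int(counts.loc[row.patient_id].to_numpy()[int(row.mutated_slot) - 1])

    early = [
        _n_mut(r) for r in hla.itertuples(index=False) if r.timing_class == "early"
    ]
    late = [
        _n_mut(r) for r in hla.itertuples(index=False) if r.timing_class == "late"
    ]
    if not early or not late:
        raise ValidationError("both the early and late strata must be nonempty")
    return mann_whitney(early, late, label=label)
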