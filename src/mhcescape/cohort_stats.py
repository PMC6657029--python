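"""Filters, burden and immune scores, group assignment, and the
statistical-contrast layer shared by the burden, presentation, timing and
immune analyses.

Conventions
-----------
* A mutation counts as *expressed* when at least 5 RNA-seq reads cover the
  mutated position (inclusive threshold, configurable).
* *Nonsynonymous* = missense, nonsense, frameshift/in-frame indel or
  splice-site; silent and noncoding variants are filtered out.
* Per-patient mutation burden = expressed nonsynonymous count + 1
  (pseudocount so log-scale displays are defined for zero-count tumors).
* MANTIS microsatellite scores are binarized at 0.4 (>= 0.4 -> MSI-H).
* The cytolytic activity score is the sum of per-cohort z-scored log2 TPM
  of GZMA and PRF1; it averages 0 over the analyzed cohort by construction.
* All two-group tests are two-sided. Mann-Whitney and paired Wilcoxon use
  the exact null for small tie-free samples and the tie-corrected normal
  approximation otherwise. Multiple-comparison control is Benjamini-
  Hochberg, applied within one family per stratified analysis; pan-cancer
  single tests are reported raw.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import (
    Group,
    NONSYNONYMOUS_CLASSES,
    SomaticMutation,
    ValidationError,
    VariantClass,
)

__all__ = [
    "TestKind",
    "ComparisonResult",
    "ImmuneProfile",
    "EXPRESSION_READ_THRESHOLD",
    "MANTIS_THRESHOLD",
    "is_expressed",
    "is_nonsynonymous",
    "mutation_burden",
    "burden_table",
    "msi_status",
    "assign_group",
    "cytolytic_score",
    "cytolytic_scores",
    "mann_whitney",
    "wilcoxon_paired",
    "ks_two_sample",
    "fisher_exact",
    "bh_adjust",
    "adjust_family",
    "merge_crc",
    "per_tumor_type_contrast",
    "msi_enrichment",
]

#: RNA read-count threshold for calling a mutation expressed (inclusive).
EXPRESSION_READ_THRESHOLD = 5

#: MANTIS score threshold for MSI-H (boundary assigned to MSI-H).
MANTIS_THRESHOLD = 0.4

#: Exact-null size limit for rank tests (above, normal approximation).
_EXACT_LIMIT = 25


class TestKind(str, enum.Enum):
    MANN_WHITNEY = "mann_whitney"
    WILCOXON_PAIRED = "wilcoxon_paired"
    KS_TWO_SAMPLE = "ks_two_sample"
    FISHER_EXACT = "fisher_exact"

    def __str__(self) -> str:  # pragma: no cover
        return self.value


@dataclass
class ComparisonResult:
    """One statistical contrast.

    ``statistic`` is the test statistic (U, W, D or the sample odds ratio
    for Fisher). ``adjusted_p`` is None until BH adjustment is applied to
    the family the result belongs to. ``degenerate`` flags contrasts whose
    null is vacuous (all paired differences zero, empty table margin,
    unbounded odds ratio); such p-values should not be interpreted.
    """

    label: str
    test: TestKind
    n1: int
    n2: int
    statistic: float
    raw_p: float
    adjusted_p: float | None = None
    degenerate: bool = False
    note: str = ""

    def to_row(self) -> dict:
        return {
            "label": self.label,
            "test": self.test.value,
            "n1": self.n1,
            "n2": self.n2,
            "statistic": self.statistic,
            "raw_p": self.raw_p,
            "adjusted_p": self.adjusted_p,
            "degenerate": self.degenerate,
            "note": self.note,
        }


@dataclass
class ImmuneProfile:
    """Per-patient immune readouts (expression plus consumed deconvolution)."""

    patient_id: str
    gzma_log2tpm: float
    prf1_log2tpm: float
    cytolytic_score: float = math.nan
    cd8_level: float = math.nan
    nk_level: float = math.nan


# ---------------------------------------------------------------------------
# Filters and per-patient scores
# ---------------------------------------------------------------------------


def is_expressed(mutation, threshold: int = EXPRESSION_READ_THRESHOLD) -> bool:
    """True iff the mutated position has >= ``threshold`` RNA reads."""
    count = mutation.rna_read_count if isinstance(mutation, SomaticMutation) else int(mutation)
    if count < 0:
        raise ValidationError("rna_read_count must be >= 0")
    return count >= threshold


def is_nonsynonymous(mutation) -> bool:
    """True iff the variant class is coding and non-silent."""
    vc = (
        mutation.variant_classification
        if isinstance(mutation, SomaticMutation)
        else VariantClass(mutation)
    )
    return vc in NONSYNONYMOUS_CLASSES


def mutation_burden(
    patient_mutations: Iterable, threshold: int = EXPRESSION_READ_THRESHOLD
) -> int:
    """Expressed nonsynonymous mutation count plus a pseudocount of 1."""
    return 1 + sum(
        1
        for m in patient_mutations
        if is_nonsynonymous(m) and is_expressed(m, threshold)
    )


def burden_table(
    mutations: pd.DataFrame,
    patient_ids: Sequence[str] | pd.Index,
    threshold: int = EXPRESSION_READ_THRESHOLD,
) -> pd.Series:
    """Vectorized per-patient burden over a normalized mutation frame.

    Patients without any qualifying mutation receive the bare pseudocount.
    """
    keep = mutations["variant_classification"].isin(
        [vc.value for vc in NONSYNONYMOUS_CLASSES]
    ) & (mutations["rna_read_count"] >= threshold)
    counts = mutations.loc[keep].groupby("patient_id").size()
    return (counts.reindex(pd.Index(patient_ids, name="patient_id"), fill_value=0) + 1).rename(
        "burden"
    )


def msi_status(mantis_score: float, threshold: float = MANTIS_THRESHOLD) -> str:
    """Binarize a MANTIS score: >= threshold -> ``"MSI_H"`` else ``"MSS"``."""
    if mantis_score < 0:
        raise ValidationError("mantis_score must be >= 0")
    return "MSI_H" if mantis_score >= threshold else "MSS"


def assign_group(b2m_mutations: Iterable, hla_mutations: Iterable) -> Group:
    """Assign the escape group from a patient's B2M and HLA mutation lists.

    Nonsynonymous mutations in both genes -> BOTH; in one -> B2M_MUT /
    HLA_MUT; only synonymous (or noncoding) B2M/HLA mutations -> SYN_ONLY
    (excluded from every contrast); none at all -> WT.
    """
    b2m = list(b2m_mutations)
    hla = list(hla_mutations)
    b2m_ns = any(is_nonsynonymous(m) for m in b2m)
    hla_ns = any(is_nonsynonymous(m) for m in hla)
    if b2m_ns and hla_ns:
        return Group.BOTH
    if b2m_ns:
        return Group.B2M_MUT
    if hla_ns:
        return Group.HLA_MUT
    if b2m or hla:
        return Group.SYN_ONLY
    return Group.WT


def cytolytic_scores(expression: pd.DataFrame) -> pd.Series:
    """Cytolytic activity per patient: z(GZMA log2 TPM) + z(PRF1 log2 TPM).

    Z-scores are computed across the analyzed cohort (population SD), so
    the scores sum to zero over that cohort.
    """
    if len(expression) < 2:
        raise ValidationError("cytolytic score needs >= 2 patients")
    out = np.zeros(len(expression))
    for gene in ("gzma_log2tpm", "prf1_log2tpm"):
        vals = expression[gene].to_numpy(dtype=float)
        sd = vals.std(ddof=0)
        if sd == 0:
            raise ValidationError(f"zero variance in {gene}; cytolytic score undefined")
        out += (vals - vals.mean()) / sd
    return pd.Series(out, index=expression["patient_id"].to_numpy(), name="cytolytic_score")


def cytolytic_score(profile: ImmuneProfile, cohort_profiles: Sequence[ImmuneProfile]) -> float:
    """Scalar form of :func:`cytolytic_scores` for one patient."""
    frame = pd.DataFrame(
        {
            "patient_id": [p.patient_id for p in cohort_profiles],
            "gzma_log2tpm": [p.gzma_log2tpm for p in cohort_profiles],
            "prf1_log2tpm": [p.prf1_log2tpm for p in cohort_profiles],
        }
    )
    scores = cytolytic_scores(frame)
    if profile.patient_id not in scores.index:
        raise ValidationError(f"patient {profile.patient_id} not in cohort profiles")
    return float(scores.loc[profile.patient_id])


# ---------------------------------------------------------------------------
# Tests
# ---------------------------------------------------------------------------


def _has_ties(values: np.ndarray) -> bool:
    return len(np.unique(values)) < len(values)


def mann_whitney(x, y, label: str = "") -> ComparisonResult:
    """Two-sided unpaired Mann-Whitney U test (x is the reference sample).

    Exact null for tie-free samples with combined n <= 25, otherwise the
    tie-corrected normal approximation with continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValidationError("mann_whitney requires two nonempty samples")
    pooled = np.concatenate([x, y])
    method = (
        "exact" if len(pooled) <= _EXACT_LIMIT and not _has_ties(pooled) else "asymptotic"
    )
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return ComparisonResult(
        label=label,
        test=TestKind.MANN_WHITNEY,
        n1=len(x),
        n2=len(y),
        statistic=float(res.statistic),
        raw_p=float(min(res.pvalue, 1.0)),
    )


def wilcoxon_paired(differences, label: str = "") -> ComparisonResult:
    """Two-sided paired Wilcoxon signed-rank test on precomputed differences.

    Zero differences are dropped (Wilcoxon convention). All-zero input is
    a degenerate contrast (statistic 0, p 1, flagged).
    """
    d = np.asarray(differences, dtype=float)
    if len(d) < 2:
        raise ValidationError("wilcoxon_paired requires >= 2 pairs")
    nz = d[d != 0]
    if len(nz) == 0:
        return ComparisonResult(
            label=label,
            test=TestKind.WILCOXON_PAIRED,
            n1=len(d),
            n2=len(d),
            statistic=0.0,
            raw_p=1.0,
            degenerate=True,
            note="all paired differences zero",
        )
    method = (
        "exact"
        if len(nz) <= _EXACT_LIMIT and not _has_ties(np.abs(nz))
        else "approx"
    )
    res = stats.wilcoxon(nz, alternative="two-sided", method=method, correction=(method == "approx"))
    return ComparisonResult(
        label=label,
        test=TestKind.WILCOXON_PAIRED,
        n1=len(d),
        n2=len(d),
        statistic=float(res.statistic),
        raw_p=float(min(res.pvalue, 1.0)),
    )


def ks_two_sample(x, y, label: str = "") -> ComparisonResult:
    """Two-sample two-sided Kolmogorov-Smirnov test."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValidationError("ks_two_sample requires two nonempty samples")
    res = stats.ks_2samp(x, y, alternative="two-sided")
    return ComparisonResult(
        label=label,
        test=TestKind.KS_TWO_SAMPLE,
        n1=len(x),
        n2=len(y),
        statistic=float(res.statistic),
        raw_p=float(res.pvalue),
    )


def fisher_exact(table, label: str = "") -> ComparisonResult:
    """Two-sided Fisher exact test on a 2x2 count table.

    ``statistic`` is the sample (cross-product) odds ratio a*d / (b*c); a
    zero off-diagonal cell makes it unbounded (inf) and flags the result.
    Degenerate margins (an all-zero row or column) are flagged with p = 1.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValidationError("fisher_exact requires a 2x2 table")
    if (t < 0).any() or not np.allclose(t, np.round(t)):
        raise ValidationError("fisher_exact requires nonnegative integer counts")
    t = t.astype(np.int64)
    a, b, c, d = t[0, 0], t[0, 1], t[1, 0], t[1, 1]
    degenerate = bool(
        t.sum(axis=0).min() == 0 or t.sum(axis=1).min() == 0
    )
    if b * c == 0:
        # zero denominator: unbounded, or undefined if the numerator is
        # also zero
        odds = math.nan if a * d == 0 else math.inf
        note = "unbounded or undefined sample odds ratio (zero cell)"
    else:
        odds = (a * d) / (b * c)
        note = ""
    p = 1.0 if degenerate else float(stats.fisher_exact(t, alternative="two-sided")[1])
    return ComparisonResult(
        label=label,
        test=TestKind.FISHER_EXACT,
        n1=int(t[0].sum()),
        n2=int(t[1].sum()),
        statistic=float(odds) if not math.isnan(odds) else math.nan,
        raw_p=min(p, 1.0),
        degenerate=degenerate or not np.isfinite(odds),
        note=note,
    )


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, returned in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValidationError("p-values must lie in [0, 1]")
    return np.asarray(stats.false_discovery_control(p, method="bh"))


def adjust_family(results: Sequence[ComparisonResult]) -> list[ComparisonResult]:
    """Apply BH across one family of contrasts, filling ``adjusted_p``."""
    if not results:
        return []
    adjusted = bh_adjust([r.raw_p for r in results])
    return [replace(r, adjusted_p=float(q)) for r, q in zip(results, adjusted)]


# ---------------------------------------------------------------------------
# Cohort-level contrasts
# ---------------------------------------------------------------------------


def merge_crc(tumor_types: pd.Series) -> pd.Series:
    """Merge the COAD and READ tumor-type codes into CRC."""
    return tumor_types.replace({"COAD": "CRC", "READ": "CRC"})


def _mutant_mask(groups: pd.Series, group: Group) -> pd.Series:
    # BOTH-group patients carry the mutation of either gene and are counted
    # on both mutant sides; SYN_ONLY never enters a contrast.
    return groups.isin([group.value, Group.BOTH.value])


def per_tumor_type_contrast(
    patients: pd.DataFrame,
    values: pd.Series,
    variable: str,
    min_mutated: int = 5,
    mutant_groups: Sequence[Group] = (Group.B2M_MUT, Group.HLA_MUT),
) -> list[ComparisonResult]:
    """Per-tumor-type Mann-Whitney contrasts of ``values`` (mutant vs WT).

    COAD and READ are merged to CRC before stratification; tumor types with
    fewer than ``min_mutated`` mutated patients for a given mutant group
    are dropped; BH adjustment is applied across the emitted family.
    ``values`` must be indexed by patient_id.
    """
    df = patients[["patient_id", "tumor_type", "group"]].copy()
    df["tumor_type"] = merge_crc(df["tumor_type"])
    df["value"] = values.reindex(df["patient_id"].to_numpy()).to_numpy()
    df = df[df["value"].notna() & (df["group"] != Group.SYN_ONLY.value)]
    results: list[ComparisonResult] = []
    for g in mutant_groups:
        mut = df[_mutant_mask(df["group"], g)]
        wt = df[df["group"] == Group.WT.value]
        counts = mut.groupby("tumor_type").size()
        for tt in sorted(counts.index[counts >= min_mutated]):
            wt_tt = wt.loc[wt["tumor_type"] == tt, "value"]
            if len(wt_tt) == 0:
                continue
            results.append(
                mann_whitney(
                    mut.loc[mut["tumor_type"] == tt, "value"],
                    wt_tt,
                    label=f"{variable}:{g.value}-vs-WT:{tt}",
                )
            )
    return adjust_family(results)


def msi_enrichment(patients: pd.DataFrame, group: Group, label: str = "") -> ComparisonResult:
    """Fisher exact test for enrichment of a mutant group in MSI-H tumors.

    2x2 table: (mutant vs WT) x (MSI-H vs MSS), MSI status from MANTIS
    scores at the 0.4 threshold. SYN_ONLY patients are excluded.
    """
    df = patients[patients["group"] != Group.SYN_ONLY.value]
    msi = df["mantis_score"].map(msi_status) == "MSI_H"
    mut = _mutant_mask(df["group"], group)
    wt = df["group"] == Group.WT.value
    table = [
        [int((mut & msi).sum()), int((mut & ~msi).sum())],
        [int((wt & msi).sum()), int((wt & ~msi).sum())],
    ]
    return fisher_exact(table, label=label or f"msi-enrichment:{group.value}")
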