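"""Allelic-fraction timing of escape mutations.

A mutation's tumor allelic fraction (AF = t_alt_count / t_depth) proxies
for the fraction of tumor cells carrying it: clonal, early mutations sit
at high AF, late subclonal ones at low AF. Because absolute AF scales
differ between tumors, each escape mutation is annotated with its AF
*percentile* within the ranked list of expressed mutations of the same
tumor. Percentile > 60 is classified early, < 40 late, in between
intermediate (excluded from the early/late contrast).

Copy-number variation distorts AF; a robustness variant excludes any
mutation falling in a segment with |log2 fold-change| > 0.1 (strict).
The default analysis retains them.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort_stats import EXPRESSION_READ_THRESHOLD, ComparisonResult, ks_two_sample
from .io_formats import SomaticMutation, ValidationError

__all__ = [
    "CNV_LOG2FC_THRESHOLD",
    "EARLY_PERCENTILE",
    "LATE_PERCENTILE",
    "TimingClass",
    "TimingAnnotation",
    "allelic_fraction",
    "af_percentile",
    "af_percentiles",
    "in_cnv",
    "classify_timing",
    "timing_distribution_test",
    "annotate_cohort",
]

#: |log2 fold-change| above which (strictly) a segment counts as CNV.
CNV_LOG2FC_THRESHOLD = 0.1

#: AF percentile above which (strictly) an escape mutation is early.
EARLY_PERCENTILE = 60.0
#: AF percentile below which (strictly) an escape mutation is late.
LATE_PERCENTILE = 40.0


class TimingClass(str, enum.Enum):
    EARLY = "early"
    LATE = "late"
    INTERMEDIATE = "intermediate"

    def __str__(self) -> str:  # pragma: no cover
        return self.value


@dataclass
class TimingAnnotation:
    """Timing annotation of one escape mutation."""

    mutation_id: str
    af: float
    percentile: float
    in_cnv: bool
    timing_class: TimingClass


def allelic_fraction(t_alt_count: int, t_depth: int) -> float:
    """Tumor allelic fraction t_alt_count / t_depth."""
    if t_depth <= 0:
        raise ValidationError("t_depth must be > 0")
    if not 0 <= t_alt_count <= t_depth:
        raise ValidationError("need 0 <= t_alt_count <= t_depth")
    return t_alt_count / t_depth


def af_percentile(target_af: float, patient_afs) -> float:
    """Mid-rank percentile of one AF within a patient's AF list.

    100 * (c_below + 0.5 * c_tied_others) / (n - 1), counting over the
    *other* n-1 mutations, so a unique minimum scores exactly 0 and a
    unique maximum exactly 100, and ties are split symmetrically. The
    target must be a member of the list; a singleton list is undefined
    (the patient is excluded).
    """
    afs = np.asarray(patient_afs, dtype=float)
    matches = np.isclose(afs, target_af)
    if not matches.any():
        raise ValidationError("target AF must be a member of the patient's AF list")
    if len(afs) < 2:
        raise ValidationError("percentile undefined for a single-mutation tumor")
    c_below = int(np.sum(afs < target_af))
    c_tied_others = int(matches.sum()) - 1
    return 100.0 * (c_below + 0.5 * c_tied_others) / (len(afs) - 1)


def af_percentiles(afs) -> np.ndarray:
    """Mid-rank percentiles of every member of an AF list (vectorized).

    Equivalent to :func:`af_percentile` applied to each element:
    100 * (average_rank - 1) / (n - 1).
    """
    afs = np.asarray(afs, dtype=float)
    if len(afs) < 2:
        raise ValidationError("percentiles undefined for fewer than 2 mutations")
    order = pd.Series(afs).rank(method="average").to_numpy()
    return 100.0 * (order - 1.0) / (len(afs) - 1)


def in_cnv(mutation: SomaticMutation, segments) -> bool:
    """True iff the mutation position falls in a same-patient segment with
    |log2 fold-change| strictly greater than 0.1 (inclusive coordinates)."""
    for seg in segments:
        if seg.patient_id != mutation.patient_id or seg.chrom != mutation.chrom:
            continue
        if seg.start <= mutation.pos <= seg.end and abs(seg.log2fc) > CNV_LOG2FC_THRESHOLD:
            return True
    return False


def classify_timing(percentile: float) -> TimingClass:
    """Early (> 60), late (< 40) or intermediate classification."""
    if not 0 <= percentile <= 100:
        raise ValidationError("percentile must lie in [0, 100]")
    if percentile > EARLY_PERCENTILE:
        return TimingClass.EARLY
    if percentile < LATE_PERCENTILE:
        return TimingClass.LATE
    return TimingClass.INTERMEDIATE


def timing_distribution_test(
    b2m_percentiles, hla_percentiles, label: str = "af-percentile:B2M-vs-HLA"
) -> ComparisonResult:
    """Two-sample KS test comparing B2M vs HLA escape AF percentile
    distributions."""
    return ks_two_sample(b2m_percentiles, hla_percentiles, label=label)


# ---------------------------------------------------------------------------
# Cohort-level annotation
# ---------------------------------------------------------------------------

_ESCAPE_GENES = ("B2M", "HLA-A", "HLA-B", "HLA-C")


def _cnv_flags(mutations: pd.DataFrame, segments: pd.DataFrame) -> pd.Series:
    """Vectorized CNV membership per mutation (indexed like ``mutations``)."""
    if len(segments) == 0 or len(mutations) == 0:
        return pd.Series(False, index=mutations.index)
    cnv_segs = segments[segments["log2fc"].abs() > CNV_LOG2FC_THRESHOLD]
    if len(cnv_segs) == 0:
        return pd.Series(False, index=mutations.index)
    muts = mutations[["patient_id", "chrom", "pos"]].reset_index(names="_row")
    merged = muts.merge(
        cnv_segs[["patient_id", "chrom", "start", "end"]], on=["patient_id", "chrom"]
    )
    hit = merged[(merged["pos"] >= merged["start"]) & (merged["pos"] <= merged["end"])]
    flags = pd.Series(False, index=mutations.index)
    flags.loc[hit["_row"].unique()] = True
    return flags


def annotate_cohort(
    patients: pd.DataFrame,
    mutations: pd.DataFrame,
    segments: pd.DataFrame,
    exclude_cnv: bool = False,
    expression_threshold: int = EXPRESSION_READ_THRESHOLD,
) -> pd.DataFrame:
    """Timing-annotate every escape (B2M/HLA) mutation in a cohort.

    The percentile ranking set is the patient's expressed mutations (the
    analyzed set). With ``exclude_cnv``, mutations in CNV regions are
    removed both from the ranking set and from the annotated output (the
    robustness variant); by default they are retained and only flagged.

    Returns a frame with columns patient_id, mutation_id, gene_class
    (B2M/HLA), af, percentile, in_cnv, timing_class. Escape mutations of
    patients with fewer than two expressed mutations are omitted
    (percentile undefined).
    """
    muts = mutations[mutations["t_depth"] > 0].copy()
    muts["af"] = muts["t_alt_count"] / muts["t_depth"]
    muts["in_cnv"] = _cnv_flags(muts, segments)
    expressed = muts[muts["rna_read_count"] >= expression_threshold]
    if exclude_cnv:
        expressed = expressed[~expressed["in_cnv"]]

    expressed = expressed.copy()
    sizes = expressed.groupby("patient_id")["af"].transform("size")
    expressed = expressed[sizes >= 2]
    ranks = expressed.groupby("patient_id")["af"].rank(method="average")
    n = expressed.groupby("patient_id")["af"].transform("size")
    expressed["percentile"] = 100.0 * (ranks - 1.0) / (n - 1.0)

    is_escape = expressed["gene"].isin(_ESCAPE_GENES)
    esc = expressed[is_escape].copy()
    esc["gene_class"] = np.where(esc["gene"] == "B2M", "B2M", "HLA")
    esc["timing_class"] = [classify_timing(p).value for p in esc["percentile"]]
    out = esc[
        ["patient_id", "mutation_id", "gene_class", "af", "percentile", "in_cnv", "timing_class"]
    ].reset_index(drop=True)
    return out
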