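"""Tabular I/O for the MHC-I escape-mutation analysis pipeline.

All dialects are plain tab-delimited text with a header row. Genomic and
protein coordinates are 1-based inclusive throughout (MAF convention).

Formats
-------
MAF subset
    Minimal mutation-annotation-format columns: ``Tumor_Sample_Barcode``,
    ``Hugo_Symbol``, ``Variant_Classification``, ``Chromosome``,
    ``Start_Position``, ``Protein_position``, ``t_alt_count``, ``t_depth``,
    ``rna_read_count`` and optionally ``mutation_id``. Comment lines
    starting with ``#`` are skipped; extra columns are ignored. Full MAF
    compliance is out of scope.
rank table
    ``mutation_id``, ``slot`` (1-6), ``rank`` — per-allele binding
    percentile ranks in (0, 100], lower = stronger predicted binding.
    Duplicate (mutation, slot) rows are peptide-level ranks and are reduced
    to their minimum (best rank) at load time.
segments
    SEG-like: ``patient_id``, ``chrom``, ``start``, ``end``, ``log2fc``.
patients / expression
    Wide tables keyed by ``patient_id``.
"""

from __future__ import annotations

import enum
import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "ValidationError",
    "VariantClass",
    "Group",
    "NONSYNONYMOUS_CLASSES",
    "NEOANTIGEN_SOURCE_CLASSES",
    "SomaticMutation",
    "CNVSegment",
    "Patient",
    "AffinityRankTable",
    "read_maf_subset",
    "read_maf_frame",
    "write_maf_subset",
    "read_rank_table",
    "write_rank_table",
    "read_segments",
    "read_segments_frame",
    "write_segments",
    "read_patients",
    "read_patients_frame",
    "write_patients",
    "read_expression",
    "write_expression",
    "mutations_to_frame",
    "frame_to_mutations",
    "patients_to_frame",
    "frame_to_patients",
]


class FormatError(ValueError):
    """A file does not conform to the expected tabular dialect."""


class ValidationError(ValueError):
    """A record violates a domain invariant (e.g. alt reads > depth)."""


class VariantClass(str, enum.Enum):
    """Normalized somatic-variant consequence classes."""

    MISSENSE = "missense"
    NONSENSE = "nonsense"
    FRAMESHIFT_INDEL = "frameshift_indel"
    INFRAME_INDEL = "inframe_indel"
    SPLICE = "splice"
    SILENT = "silent"
    NONCODING = "noncoding"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Classes counted as nonsynonymous (coding, non-silent) in burden and
#: group assignment. Splice-site variants are included.
NONSYNONYMOUS_CLASSES = frozenset(
    {
        VariantClass.MISSENSE,
        VariantClass.NONSENSE,
        VariantClass.FRAMESHIFT_INDEL,
        VariantClass.INFRAME_INDEL,
        VariantClass.SPLICE,
    }
)

#: Classes that generate candidate neoantigen peptides (missense + indel);
#: the denominator of per-patient binding fractions.
NEOANTIGEN_SOURCE_CLASSES = frozenset(
    {
        VariantClass.MISSENSE,
        VariantClass.FRAMESHIFT_INDEL,
        VariantClass.INFRAME_INDEL,
    }
)

#: MAF Variant_Classification vocabulary -> normalized class. Unmappable
#: values fall back to NONCODING.
MAF_CLASS_MAP = {
    "Missense_Mutation": VariantClass.MISSENSE,
    "Nonsense_Mutation": VariantClass.NONSENSE,
    "Nonstop_Mutation": VariantClass.NONSENSE,
    "Frame_Shift_Del": VariantClass.FRAMESHIFT_INDEL,
    "Frame_Shift_Ins": VariantClass.FRAMESHIFT_INDEL,
    "In_Frame_Del": VariantClass.INFRAME_INDEL,
    "In_Frame_Ins": VariantClass.INFRAME_INDEL,
    "Splice_Site": VariantClass.SPLICE,
    "Splice_Region": VariantClass.SPLICE,
    "Translation_Start_Site": VariantClass.NONSENSE,
    "Silent": VariantClass.SILENT,
}
# Already-normalized names are accepted as-is (round-trip).
MAF_CLASS_MAP.update({vc.value: vc for vc in VariantClass})


class Group(str, enum.Enum):
    """Patient escape-mutation group."""

    WT = "WT"
    B2M_MUT = "B2M_MUT"
    HLA_MUT = "HLA_MUT"
    BOTH = "BOTH"
    SYN_ONLY = "SYN_ONLY"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


STAGES = ("I", "II", "III", "IV", "unknown")

N_SLOTS = 6
SLOTS = tuple(range(1, N_SLOTS + 1))


# ---------------------------------------------------------------------------
# Record types
# ---------------------------------------------------------------------------


@dataclass
class SomaticMutation:
    """One somatic variant in one tumor.

    ``pos`` is the 1-based genomic start; ``protein_pos`` the 1-based
    UniProt residue index (None when not applicable/known).
    """

    mutation_id: str
    patient_id: str
    gene: str
    variant_classification: VariantClass
    chrom: str
    pos: int
    protein_pos: int | None
    t_alt_count: int
    t_depth: int
    rna_read_count: int

    def __post_init__(self) -> None:
        self.variant_classification = VariantClass(self.variant_classification)
        if self.pos < 1:
            raise ValidationError(f"pos must be >= 1, got {self.pos}")
        if not 0 <= self.t_alt_count <= self.t_depth:
            raise ValidationError(
                f"need 0 <= t_alt_count <= t_depth, got "
                f"t_alt_count={self.t_alt_count}, t_depth={self.t_depth}"
            )
        if self.rna_read_count < 0:
            raise ValidationError("rna_read_count must be >= 0")
        if self.protein_pos is not None and self.protein_pos < 1:
            raise ValidationError("protein_pos must be >= 1 when present")


@dataclass
class CNVSegment:
    """A copy-number segment with its log2 fold-change."""

    patient_id: str
    chrom: str
    start: int
    end: int
    log2fc: float

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(
                f"segment start {self.start} > end {self.end}"
            )


@dataclass
class Patient:
    """One tumor sample with its HLA genotype and cohort annotations.

    ``genotype`` holds 6 allele-slot strings (slots 1-2: HLA-A, 3-4: HLA-B,
    5-6: HLA-C); duplicates encode homozygosity but slots remain distinct
    identities. ``mutated_slot`` is defined iff the patient carries a
    somatic HLA mutation (groups HLA_MUT and BOTH).
    """

    patient_id: str
    tumor_type: str
    stage: str
    genotype: tuple[str, ...]
    mantis_score: float
    group: Group
    mutated_slot: int | None = None

    def __post_init__(self) -> None:
        self.group = Group(self.group)
        self.genotype = tuple(self.genotype)
        if len(self.genotype) != N_SLOTS:
            raise ValidationError(
                f"genotype must have exactly {N_SLOTS} slots, got "
                f"{len(self.genotype)}"
            )
        if self.stage not in STAGES:
            raise ValidationError(f"unknown stage {self.stage!r}")
        if self.mantis_score < 0:
            raise ValidationError("mantis_score must be >= 0")
        needs_slot = self.group in (Group.HLA_MUT, Group.BOTH)
        if needs_slot and self.mutated_slot is None:
            raise ValidationError(
                f"group {self.group} requires a mutated_slot"
            )
        if not needs_slot and self.mutated_slot is not None:
            raise ValidationError(
                f"group {self.group} must not define mutated_slot"
            )
        if self.mutated_slot is not None and self.mutated_slot not in SLOTS:
            raise ValidationError(
                f"mutated_slot must be in 1..{N_SLOTS}, got {self.mutated_slot}"
            )


class AffinityRankTable:
    """Per-(mutation, allele-slot) best binding percentile ranks.

    Stored wide: one row per mutation, columns = the 6 allele slots. Every
    mutation present has a rank for all 6 slots, and all ranks lie in
    (0, 100]. Build from long-form rows with :meth:`from_long`, which
    reduces duplicate (mutation, slot) peptide-level rows to their minimum
    (= best rank per allele).
    """

    def __init__(self, wide: pd.DataFrame):
        wide = wide.copy()
        wide.columns = [int(c) for c in wide.columns]
        if list(wide.columns) != list(SLOTS):
            raise ValidationError(
                f"rank table must have exactly slots {SLOTS}, got "
                f"{list(wide.columns)}"
            )
        if wide.isna().any().any():
            bad = wide.index[wide.isna().any(axis=1)][:5].tolist()
            raise ValidationError(
                f"incomplete rank table: mutations missing slots, e.g. {bad}"
            )
        vals = wide.to_numpy(dtype=float)
        if (vals <= 0).any() or (vals > 100).any():
            raise ValidationError("all ranks must lie in (0, 100]")
        wide = wide.astype(float)
        wide.index = wide.index.astype(str)
        wide.index.name = "mutation_id"
        self._wide = wide.sort_index()

    @classmethod
    def from_long(cls, df: pd.DataFrame) -> "AffinityRankTable":
        for col in ("mutation_id", "slot", "rank"):
            if col not in df.columns:
                raise FormatError(f"rank table missing required column {col!r}")
        slot = pd.to_numeric(df["slot"], errors="raise")
        if not slot.isin(SLOTS).all():
            raise ValidationError("slot values must be in 1..6")
        rank = df["rank"].astype(float)  # exact string->float round-trip
        if (rank <= 0).any():
            raise ValidationError("ranks must be > 0")
        long = pd.DataFrame(
            {"mutation_id": df["mutation_id"].astype(str), "slot": slot, "rank": rank}
        )
        best = long.groupby(["mutation_id", "slot"], sort=True)["rank"].min()
        wide = best.unstack("slot")
        return cls(wide.reindex(columns=list(SLOTS)))

    # -- accessors ---------------------------------------------------------

    @property
    def wide(self) -> pd.DataFrame:
        """Wide view: index mutation_id, columns slots 1..6."""
        return self._wide

    @property
    def mutation_ids(self) -> pd.Index:
        return self._wide.index

    def __len__(self) -> int:
        return len(self._wide)

    def __contains__(self, mutation_id: str) -> bool:
        return mutation_id in self._wide.index

    def best_rank(self, mutation_id: str, slot: int) -> float:
        """Best (minimum) peptide rank for one mutation at one slot."""
        if slot not in SLOTS:
            raise ValidationError(f"slot must be in 1..{N_SLOTS}")
        return float(self._wide.at[str(mutation_id), slot])

    def best_ranks(self, mutation_id: str) -> np.ndarray:
        """All six per-slot best ranks for one mutation."""
        return self._wide.loc[str(mutation_id)].to_numpy(dtype=float)

    def subset(self, mutation_ids: Iterable[str]) -> "AffinityRankTable":
        ids = pd.Index([str(m) for m in mutation_ids]).unique()
        missing = ids.difference(self._wide.index)
        if len(missing):
            raise ValidationError(
                f"mutations absent from rank table, e.g. {missing[:5].tolist()}"
            )
        return AffinityRankTable(self._wide.loc[ids])

    def to_long(self) -> pd.DataFrame:
        long = (
            self._wide.stack()
            .rename("rank")
            .reset_index()
            .rename(columns={"level_1": "slot"})
        )
        long["slot"] = long["slot"].astype(int)
        return long.sort_values(["mutation_id", "slot"], ignore_index=True)

    def equals(self, other: "AffinityRankTable") -> bool:
        return self._wide.equals(other._wide)


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

MAF_REQUIRED_COLUMNS = (
    "Tumor_Sample_Barcode",
    "Hugo_Symbol",
    "Variant_Classification",
    "Chromosome",
    "Start_Position",
    "Protein_position",
    "t_alt_count",
    "t_depth",
    "rna_read_count",
)

_MUTATION_FRAME_COLUMNS = [
    "mutation_id",
    "patient_id",
    "gene",
    "variant_classification",
    "chrom",
    "pos",
    "protein_pos",
    "t_alt_count",
    "t_depth",
    "rna_read_count",
]


def _read_tsv(path: str | os.PathLike, required: Sequence[str], *, comment: str | None = None) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, comment=comment, float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file (no header)") from exc
    except OSError as exc:
        raise FormatError(f"{path}: {exc}") from exc
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    return df


def _to_int(series: pd.Series, name: str, path) -> pd.Series:
    out = pd.to_numeric(series, errors="coerce")
    bad = out.isna() & series.notna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0]) + 1
        raise FormatError(
            f"{path}: malformed value {series[bad].iloc[0]!r} in column "
            f"{name!r} at data row {row}"
        )
    if out.isna().any():
        row = int(np.flatnonzero(out.isna().to_numpy())[0]) + 1
        raise FormatError(f"{path}: missing value in column {name!r} at data row {row}")
    frac = out % 1
    if (frac != 0).any():
        raise FormatError(f"{path}: non-integer value in column {name!r}")
    return out.astype(np.int64)


def _parse_protein_pos(value) -> "int | None":
    """First listed protein position from a MAF Protein_position field.

    Accepts forms like ``123``, ``123/362``, ``123-125/362`` or ``p.123``;
    blank / ``.`` / ``-`` / unparsable mean "no protein position".
    """
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    text = str(value).strip()
    if text in ("", ".", "-", "NA", "nan"):
        return None
    text = text.removeprefix("p.")
    text = text.split("/")[0].split("-")[0]
    digits = "".join(ch for ch in text if ch.isdigit())
    if not digits:
        return None
    pos = int(digits)
    return pos if pos >= 1 else None


def read_maf_frame(path: str | os.PathLike) -> pd.DataFrame:
    """Read a MAF-subset file into the normalized mutation DataFrame."""
    df = _read_tsv(path, MAF_REQUIRED_COLUMNS, comment="#")
    n = len(df)
    if n == 0:
        return pd.DataFrame(columns=_MUTATION_FRAME_COLUMNS).astype(
            {"pos": np.int64, "t_alt_count": np.int64, "t_depth": np.int64,
             "rna_read_count": np.int64, "protein_pos": "Int64"}
        )
    out = pd.DataFrame(
        {
            "patient_id": df["Tumor_Sample_Barcode"].astype(str),
            "gene": df["Hugo_Symbol"].astype(str),
            "chrom": df["Chromosome"].astype(str),
            "pos": _to_int(df["Start_Position"], "Start_Position", path),
            "t_alt_count": _to_int(df["t_alt_count"], "t_alt_count", path),
            "t_depth": _to_int(df["t_depth"], "t_depth", path),
            "rna_read_count": _to_int(df["rna_read_count"], "rna_read_count", path),
        }
    )
    out["variant_classification"] = [
        MAF_CLASS_MAP.get(v, VariantClass.NONCODING).value
        for v in df["Variant_Classification"].astype(str)
    ]
    out["protein_pos"] = pd.array(
        [_parse_protein_pos(v) for v in df["Protein_position"]], dtype="Int64"
    )
    if "mutation_id" in df.columns:
        out["mutation_id"] = df["mutation_id"].astype(str)
    else:
        out["mutation_id"] = [
            f"{p}:{c}:{s}" for p, c, s in zip(out["patient_id"], out["chrom"], out["pos"])
        ]
    bad = out["t_alt_count"] > out["t_depth"]
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0]) + 1
        raise ValidationError(
            f"{path}: t_alt_count > t_depth at data row {row}"
        )
    if (out["pos"] < 1).any():
        raise ValidationError(f"{path}: Start_Position must be >= 1")
    if (out["rna_read_count"] < 0).any() or (out["t_alt_count"] < 0).any():
        raise ValidationError(f"{path}: read counts must be >= 0")
    return out[_MUTATION_FRAME_COLUMNS]


def read_maf_subset(path: str | os.PathLike) -> list[SomaticMutation]:
    """Read a MAF-subset file as a list of :class:`SomaticMutation`."""
    return frame_to_mutations(read_maf_frame(path))


def frame_to_mutations(frame: pd.DataFrame) -> list[SomaticMutation]:
    return [
        SomaticMutation(
            mutation_id=str(r.mutation_id),
            patient_id=str(r.patient_id),
            gene=str(r.gene),
            variant_classification=VariantClass(r.variant_classification),
            chrom=str(r.chrom),
            pos=int(r.pos),
            protein_pos=None if pd.isna(r.protein_pos) else int(r.protein_pos),
            t_alt_count=int(r.t_alt_count),
            t_depth=int(r.t_depth),
            rna_read_count=int(r.rna_read_count),
        )
        for r in frame.itertuples(index=False)
    ]


def mutations_to_frame(mutations: Iterable[SomaticMutation]) -> pd.DataFrame:
    rows = [
        (
            m.mutation_id,
            m.patient_id,
            m.gene,
            m.variant_classification.value,
            m.chrom,
            m.pos,
            m.protein_pos,
            m.t_alt_count,
            m.t_depth,
            m.rna_read_count,
        )
        for m in mutations
    ]
    frame = pd.DataFrame(rows, columns=_MUTATION_FRAME_COLUMNS)
    frame["protein_pos"] = frame["protein_pos"].astype("Int64")
    return frame


def write_maf_subset(mutations, path: str | os.PathLike) -> None:
    """Write mutations (records or normalized frame) as a MAF-subset file."""
    frame = mutations if isinstance(mutations, pd.DataFrame) else mutations_to_frame(mutations)
    out = pd.DataFrame(
        {
            "Tumor_Sample_Barcode": frame["patient_id"],
            "Hugo_Symbol": frame["gene"],
            "Variant_Classification": frame["variant_classification"],
            "Chromosome": frame["chrom"],
            "Start_Position": frame["pos"],
            "Protein_position": frame["protein_pos"],
            "t_alt_count": frame["t_alt_count"],
            "t_depth": frame["t_depth"],
            "rna_read_count": frame["rna_read_count"],
            "mutation_id": frame["mutation_id"],
        }
    )
    out.to_csv(path, sep="\t", index=False)


def read_rank_table(path: str | os.PathLike) -> AffinityRankTable:
    """Read a long-form rank table, reducing peptide-level duplicates by min."""
    df = _read_tsv(path, ("mutation_id", "slot", "rank"))
    if len(df) == 0:
        return AffinityRankTable(
            pd.DataFrame(columns=list(SLOTS), index=pd.Index([], name="mutation_id"))
        )
    try:
        df["slot"] = pd.to_numeric(df["slot"])
        df["rank"] = df["rank"].astype(float)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"{path}: malformed slot/rank value: {exc}") from exc
    return AffinityRankTable.from_long(df)


def write_rank_table(ranks: AffinityRankTable, path: str | os.PathLike) -> None:
    ranks.to_long().to_csv(path, sep="\t", index=False)


SEGMENT_COLUMNS = ("patient_id", "chrom", "start", "end", "log2fc")


def read_segments_frame(path: str | os.PathLike) -> pd.DataFrame:
    df = _read_tsv(path, SEGMENT_COLUMNS)
    if len(df) == 0:
        return pd.DataFrame(columns=list(SEGMENT_COLUMNS)).astype(
            {"start": np.int64, "end": np.int64, "log2fc": float}
        )
    out = pd.DataFrame(
        {
            "patient_id": df["patient_id"].astype(str),
            "chrom": df["chrom"].astype(str),
            "start": _to_int(df["start"], "start", path),
            "end": _to_int(df["end"], "end", path),
            "log2fc": df["log2fc"].astype(float),
        }
    )
    bad = out["start"] > out["end"]
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0]) + 1
        raise ValidationError(f"{path}: segment start > end at data row {row}")
    return out


def read_segments(path: str | os.PathLike) -> list[CNVSegment]:
    return [
        CNVSegment(str(r.patient_id), str(r.chrom), int(r.start), int(r.end), float(r.log2fc))
        for r in read_segments_frame(path).itertuples(index=False)
    ]


def write_segments(segments, path: str | os.PathLike) -> None:
    if isinstance(segments, pd.DataFrame):
        frame = segments[list(SEGMENT_COLUMNS)]
    else:
        frame = pd.DataFrame(
            [(s.patient_id, s.chrom, s.start, s.end, s.log2fc) for s in segments],
            columns=list(SEGMENT_COLUMNS),
        )
    frame.to_csv(path, sep="\t", index=False)


_ALLELE_COLS = [f"allele_{i}" for i in SLOTS]
PATIENT_COLUMNS = (
    ["patient_id", "tumor_type", "stage"]
    + _ALLELE_COLS
    + ["mantis_score", "group", "mutated_slot"]
)


def read_patients_frame(path: str | os.PathLike) -> pd.DataFrame:
    df = _read_tsv(path, PATIENT_COLUMNS)
    if len(df) == 0:
        out = pd.DataFrame(columns=list(PATIENT_COLUMNS))
        out["mantis_score"] = out["mantis_score"].astype(float)
        out["mutated_slot"] = out["mutated_slot"].astype("Int64")
        return out
    out = df[list(PATIENT_COLUMNS)].copy()
    for col in ["patient_id", "tumor_type", "stage", *_ALLELE_COLS, "group"]:
        out[col] = out[col].astype(str)
    out["mantis_score"] = df["mantis_score"].astype(float)
    out["mutated_slot"] = pd.array(
        pd.to_numeric(df["mutated_slot"], errors="coerce"), dtype="Int64"
    )
    # row-level invariants via the record type
    frame_to_patients(out)
    return out


def read_patients(path: str | os.PathLike) -> list[Patient]:
    return frame_to_patients(read_patients_frame(path))


def frame_to_patients(frame: pd.DataFrame) -> list[Patient]:
    patients = []
    for r in frame.itertuples(index=False):
        slot = getattr(r, "mutated_slot")
        patients.append(
            Patient(
                patient_id=str(r.patient_id),
                tumor_type=str(r.tumor_type),
                stage=str(r.stage),
                genotype=tuple(str(getattr(r, c)) for c in _ALLELE_COLS),
                mantis_score=float(r.mantis_score),
                group=Group(r.group),
                mutated_slot=None if pd.isna(slot) else int(slot),
            )
        )
    return patients


def patients_to_frame(patients: Iterable[Patient]) -> pd.DataFrame:
    rows = [
        (p.patient_id, p.tumor_type, p.stage, *p.genotype, p.mantis_score,
         p.group.value, p.mutated_slot)
        for p in patients
    ]
    frame = pd.DataFrame(rows, columns=list(PATIENT_COLUMNS))
    frame["mutated_slot"] = frame["mutated_slot"].astype("Int64")
    return frame


def write_patients(patients, path: str | os.PathLike) -> None:
    frame = patients if isinstance(patients, pd.DataFrame) else patients_to_frame(patients)
    frame.to_csv(path, sep="\t", index=False)


EXPRESSION_COLUMNS = ("patient_id", "gzma_log2tpm", "prf1_log2tpm", "cd8_level", "nk_level")


def read_expression(path: str | os.PathLike) -> pd.DataFrame:
    """Read per-patient immune expression records.

    Columns: GZMA / PRF1 log2 TPM and consumed deconvolution outputs
    (CD8+ T-cell and NK levels, nonnegative).
    """
    df = _read_tsv(path, EXPRESSION_COLUMNS)
    if len(df) == 0:
        out = pd.DataFrame(columns=list(EXPRESSION_COLUMNS))
        for c in EXPRESSION_COLUMNS[1:]:
            out[c] = out[c].astype(float)
        return out
    out = pd.DataFrame({"patient_id": df["patient_id"].astype(str)})
    for c in EXPRESSION_COLUMNS[1:]:
        out[c] = df[c].astype(float)
    if (out[["cd8_level", "nk_level"]] < 0).any().any():
        raise ValidationError(f"{path}: cd8_level/nk_level must be >= 0")
    return out


def write_expression(expression: pd.DataFrame, path: str | os.PathLike) -> None:
    expression[list(EXPRESSION_COLUMNS)].to_csv(path, sep="\t", index=False)
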