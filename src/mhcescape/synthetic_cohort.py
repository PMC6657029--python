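"""Synthetic tumor cohorts with the statistical structure the escape-
mutation analysis assumes.

The generator emulates, at configurable effect sizes, the four phenomena
the pipeline is built to detect:

* group-specific inflation of expressed nonsynonymous mutation burden in
  B2M/HLA-mutant (and MSI-H) tumors — overdispersed negative-binomial
  counts;
* enrichment of neoantigens binding the *mutated* HLA allele slot in
  HLA-mutant patients (``bias_strength``), stronger for clonal/early
  escape mutations (``early_bias_multiplier``);
* high-percentile B2M escape-mutation VAFs versus a bimodal high/low
  mixture for HLA escape mutations, against uniform passenger VAFs;
* enrichment of escape mutations among MSI-H tumors at a target odds
  ratio, drawn from Fisher's noncentral hypergeometric distribution so the
  sample odds ratio concentrates on the target.

No sequences are simulated: per-allele binding percentile ranks are drawn
directly (log-uniform), read counts are binomial draws at Poisson depth,
and the genome is an abstract 22 x 100 Mb coordinate space. Group sizes
are deterministic roundings of the configured fractions; a fixed seed
reproduces the cohort byte-identically.
"""

from __future__ import annotations

import os
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import io_formats
from .io_formats import (
    AffinityRankTable,
    Group,
    N_SLOTS,
    ValidationError,
    VariantClass,
)

__all__ = ["ConfigError", "VAFModel", "CohortConfig", "Cohort", "generate_cohort", "write_cohort", "read_cohort"]


class ConfigError(ValueError):
    """Invalid cohort configuration."""


@dataclass
class VAFModel:
    """Beta-distribution parameters for escape-mutation VAFs.

    B2M escape mutations are drawn from a single high-skewed Beta; HLA
    escape mutations from a two-component mixture (clonal high / subclonal
    low) with weight ``hla_high_weight`` on the high component. Passenger
    VAFs are uniform on (0, 1].
    """

    b2m_alpha: float = 8.0
    b2m_beta: float = 1.5
    hla_high_alpha: float = 8.0
    hla_high_beta: float = 1.5
    hla_low_alpha: float = 1.5
    hla_low_beta: float = 8.0
    hla_high_weight: float = 0.5


@dataclass
class CohortConfig:
    """All knobs of the synthetic-cohort generator.

    Fractions are of ``n_patients`` and rounded deterministically to group
    counts. Burden multipliers are fold-changes on the negative-binomial
    mean of expressed nonsynonymous counts (dispersion
    ``burden_dispersion`` = NB size parameter). ``bias_strength`` is the
    probability that an expressed missense/indel mutation of an HLA-mutant
    patient gets its mutated-slot rank redrawn below the binding cutoff;
    it is multiplied by ``early_bias_multiplier`` (capped at 1) for
    patients whose escape VAF came from the clonal high component.
    """

    n_patients: int = 500
    frac_b2m_mut: float = 0.10
    frac_hla_mut: float = 0.20
    frac_both: float = 0.01
    frac_syn_only: float = 0.02
    frac_msi: float = 0.15
    msi_enrichment_or: float = 15.0
    baseline_burden_mean: float = 50.0
    burden_dispersion: float = 10.0
    burden_multiplier_b2m: float = 2.0
    burden_multiplier_hla: float = 2.0
    burden_multiplier_msi: float = 5.0
    bias_strength: float = 0.15
    early_bias_multiplier: float = 2.0
    rank_log_min: float = 0.7
    rank_log_max: float = 100.0
    vaf_model: VAFModel = field(default_factory=VAFModel)
    depth_mean: float = 80.0
    expressed_prob: float = 0.7
    cnv_fraction: float = 0.2
    homozygous_fraction: float = 0.1
    silent_rate: float = 0.35
    immune_shift: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.vaf_model, dict):
            self.vaf_model = VAFModel(**self.vaf_model)
        self.validate()

    def validate(self) -> None:
        fracs = {
            "frac_b2m_mut": self.frac_b2m_mut,
            "frac_hla_mut": self.frac_hla_mut,
            "frac_both": self.frac_both,
            "frac_syn_only": self.frac_syn_only,
            "frac_msi": self.frac_msi,
            "expressed_prob": self.expressed_prob,
            "cnv_fraction": self.cnv_fraction,
            "homozygous_fraction": self.homozygous_fraction,
            "bias_strength": self.bias_strength,
        }
        for name, value in fracs.items():
            if not 0.0 <= value <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {value}")
        if self.frac_b2m_mut + self.frac_hla_mut + self.frac_both > 1.0:
            raise ConfigError("frac_b2m_mut + frac_hla_mut + frac_both must be <= 1")
        if self.frac_b2m_mut + self.frac_hla_mut + self.frac_both + self.frac_syn_only > 1.0:
            raise ConfigError("group fractions must sum to <= 1")
        for name in (
            "msi_enrichment_or",
            "baseline_burden_mean",
            "burden_dispersion",
            "burden_multiplier_b2m",
            "burden_multiplier_hla",
            "burden_multiplier_msi",
            "depth_mean",
        ):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        if not 0 < self.rank_log_min < self.rank_log_max <= 100.0:
            raise ConfigError("need 0 < rank_log_min < rank_log_max <= 100")
        if self.n_patients < 0:
            raise ConfigError("n_patients must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "CohortConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: expected a mapping of config fields")
        unknown = set(raw) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


@dataclass
class Cohort:
    """A generated cohort as five cross-referencing tables.

    ``patients``, ``mutations``, ``segments`` and ``expression`` are
    normalized DataFrames in the dialects of :mod:`mhcescape.io_formats`;
    ``ranks`` is an :class:`AffinityRankTable` covering every
    nonsynonymous mutation.
    """

    patients: pd.DataFrame
    mutations: pd.DataFrame
    ranks: AffinityRankTable
    segments: pd.DataFrame
    expression: pd.DataFrame

    def validate(self) -> None:
        pids = set(self.patients["patient_id"])
        if not set(self.mutations["patient_id"]).issubset(pids):
            raise ValidationError("mutation references unknown patient_id")
        if not set(self.segments["patient_id"]).issubset(pids):
            raise ValidationError("segment references unknown patient_id")
        if not set(self.ranks.mutation_ids).issubset(set(self.mutations["mutation_id"])):
            raise ValidationError("rank table references unknown mutation_id")

    def patient_records(self) -> list[io_formats.Patient]:
        return io_formats.frame_to_patients(self.patients)

    def mutation_records(self) -> list[io_formats.SomaticMutation]:
        return io_formats.frame_to_mutations(self.mutations)

    def equals(self, other: "Cohort") -> bool:
        return (
            self.patients.reset_index(drop=True).equals(other.patients.reset_index(drop=True))
            and self.mutations.reset_index(drop=True).equals(other.mutations.reset_index(drop=True))
            and self.ranks.equals(other.ranks)
            and self.segments.reset_index(drop=True).equals(other.segments.reset_index(drop=True))
            and self.expression.reset_index(drop=True).equals(other.expression.reset_index(drop=True))
        )


# ---------------------------------------------------------------------------
# Constant pools
# ---------------------------------------------------------------------------

_TUMOR_TYPES = (
    ("BRCA", 0.15), ("LUAD", 0.12), ("BLCA", 0.09), ("COAD", 0.08),
    ("READ", 0.04), ("STAD", 0.08), ("UCEC", 0.10), ("HNSC", 0.08),
    ("SKCM", 0.08), ("KIRC", 0.07), ("PRAD", 0.06), ("CESC", 0.05),
)
_STAGE_PROBS = (("I", 0.25), ("II", 0.30), ("III", 0.25), ("IV", 0.15), ("unknown", 0.05))

_ALLELE_POOL = {
    "HLA-A": ("HLA-A*01:01", "HLA-A*02:01", "HLA-A*03:01", "HLA-A*11:01", "HLA-A*24:02"),
    "HLA-B": ("HLA-B*07:02", "HLA-B*08:01", "HLA-B*15:01", "HLA-B*35:01", "HLA-B*44:02"),
    "HLA-C": ("HLA-C*03:04", "HLA-C*04:01", "HLA-C*05:01", "HLA-C*07:01", "HLA-C*07:02"),
}
#: slot (1-based) -> HLA gene
SLOT_GENE = {1: "HLA-A", 2: "HLA-A", 3: "HLA-B", 4: "HLA-B", 5: "HLA-C", 6: "HLA-C"}

# abstract genome: 22 autosomes x 100 Mb
_N_CHROM = 22
_CHROM_LEN = 100_000_000
# escape-gene loci (chrom, base position) in the abstract genome,
# numerically close to the real GRCh38 loci for readability
_GENE_LOCI = {
    "B2M": ("15", 44_711_000),
    "HLA-A": ("6", 29_942_000),
    "HLA-B": ("6", 31_353_000),
    "HLA-C": ("6", 31_268_000),
}

_PASSENGER_CLASSES = (
    (VariantClass.MISSENSE.value, 0.75),
    (VariantClass.NONSENSE.value, 0.08),
    (VariantClass.FRAMESHIFT_INDEL.value, 0.08),
    (VariantClass.INFRAME_INDEL.value, 0.04),
    (VariantClass.SPLICE.value, 0.05),
)
_B2M_ESCAPE_CLASSES = (
    (VariantClass.NONSENSE.value, 0.35),
    (VariantClass.FRAMESHIFT_INDEL.value, 0.35),
    (VariantClass.MISSENSE.value, 0.30),
)
_HLA_ESCAPE_CLASSES = (
    (VariantClass.MISSENSE.value, 0.60),
    (VariantClass.NONSENSE.value, 0.20),
    (VariantClass.FRAMESHIFT_INDEL.value, 0.20),
)

_NONSYN_VALUES = [vc.value for vc in io_formats.NONSYNONYMOUS_CLASSES]
_NEO_VALUES = [vc.value for vc in io_formats.NEOANTIGEN_SOURCE_CLASSES]


def _round(x: float) -> int:
    """Deterministic half-up rounding (no banker's rounding surprises)."""
    return int(np.floor(x + 0.5))


def _choice(rng, items, size):
    values, probs = zip(*items)
    return rng.choice(values, size=size, p=np.asarray(probs) / np.sum(probs))


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate one cohort; identical config (incl. seed) gives identical
    output."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    vm = config.vaf_model

    # --- groups (deterministic counts) -----------------------------------
    n_b2m = _round(config.frac_b2m_mut * n)
    n_hla = _round(config.frac_hla_mut * n)
    n_both = _round(config.frac_both * n)
    n_syn = _round(config.frac_syn_only * n)
    n_wt = n - n_b2m - n_hla - n_both - n_syn
    if n_wt < 0:
        raise ConfigError("group fractions leave no room for WT patients")
    groups = np.array(
        [Group.B2M_MUT.value] * n_b2m
        + [Group.HLA_MUT.value] * n_hla
        + [Group.BOTH.value] * n_both
        + [Group.SYN_ONLY.value] * n_syn
        + [Group.WT.value] * n_wt
    )
    rng.shuffle(groups)
    patient_ids = np.array([f"P{i:05d}" for i in range(1, n + 1)])

    has_b2m = np.isin(groups, [Group.B2M_MUT.value, Group.BOTH.value])
    has_hla = np.isin(groups, [Group.HLA_MUT.value, Group.BOTH.value])
    escape = has_b2m | has_hla

    # --- MSI with target enrichment odds ratio ---------------------------
    n_msi = _round(config.frac_msi * n)
    n_esc = int(escape.sum())
    lo = max(0, n_msi - (n - n_esc))
    hi = min(n_esc, n_msi)
    if lo == hi:
        x = lo
    else:
        x = int(
            stats.nchypergeom_fisher.rvs(
                n, n_esc, n_msi, config.msi_enrichment_or, random_state=rng
            )
        )
    msi = np.zeros(n, dtype=bool)
    esc_idx = np.flatnonzero(escape)
    non_idx = np.flatnonzero(~escape)
    if x > 0:
        msi[rng.choice(esc_idx, size=x, replace=False)] = True
    if n_msi - x > 0:
        msi[rng.choice(non_idx, size=n_msi - x, replace=False)] = True
    mantis = np.where(
        msi, rng.uniform(0.45, 1.10, size=n), rng.uniform(0.01, 0.35, size=n)
    )

    # --- demographics and genotypes --------------------------------------
    tumor_type = _choice(rng, _TUMOR_TYPES, n)
    stage = _choice(rng, _STAGE_PROBS, n)
    genotype = np.empty((n, N_SLOTS), dtype=object)
    for j, slot in enumerate(range(1, N_SLOTS + 1)):
        pool = _ALLELE_POOL[SLOT_GENE[slot]]
        genotype[:, j] = rng.choice(pool, size=n)
    homozygous = rng.random(n) < config.homozygous_fraction
    hom_gene = rng.integers(0, 3, size=n)  # 0: A (slots 1,2), 1: B, 2: C
    for i in np.flatnonzero(homozygous):
        j = 2 * hom_gene[i]
        genotype[i, j + 1] = genotype[i, j]

    mutated_slot = np.full(n, pd.NA, dtype=object)
    hla_slots = rng.integers(1, N_SLOTS + 1, size=n)
    mutated_slot[has_hla] = hla_slots[has_hla]

    # --- passenger mutations ---------------------------------------------
    mult = np.ones(n)
    mult[has_b2m] *= config.burden_multiplier_b2m
    mult[has_hla] *= config.burden_multiplier_hla
    mult[msi] *= config.burden_multiplier_msi
    mean_total = config.baseline_burden_mean / config.expressed_prob * mult
    r = config.burden_dispersion
    n_nonsyn = rng.negative_binomial(r, r / (r + mean_total)) if n else np.array([], dtype=int)
    n_silent = rng.poisson(config.silent_rate * mean_total) if n else np.array([], dtype=int)

    def _passengers(counts: np.ndarray, classes) -> pd.DataFrame:
        total = int(counts.sum())
        owner = np.repeat(np.arange(n), counts)
        vaf = 1.0 - rng.random(total)  # uniform on (0, 1]
        depth = np.maximum(rng.poisson(config.depth_mean, size=total), 1)
        alt = rng.binomial(depth, vaf)
        expressed = rng.random(total) < config.expressed_prob
        rna = np.where(
            expressed, 5 + rng.poisson(25.0, size=total), rng.integers(0, 5, size=total)
        )
        return pd.DataFrame(
            {
                "patient_id": patient_ids[owner],
                "gene": np.char.add(
                    "GENE", rng.integers(0, 400, size=total).astype("U4")
                ),
                "variant_classification": _choice(rng, classes, total),
                "chrom": rng.integers(1, _N_CHROM + 1, size=total).astype(str),
                "pos": rng.integers(1, _CHROM_LEN + 1, size=total),
                "protein_pos": rng.integers(1, 501, size=total),
                "t_alt_count": alt,
                "t_depth": depth,
                "rna_read_count": rna,
            }
        )

    nonsyn_df = _passengers(n_nonsyn, _PASSENGER_CLASSES)
    silent_df = _passengers(n_silent, ((VariantClass.SILENT.value, 1.0),))

    # --- escape mutations --------------------------------------------------
    def _escape_rows(idx: np.ndarray, gene_of, classes, vaf_draw) -> pd.DataFrame:
        k = len(idx)
        genes = np.array([gene_of(i) for i in idx], dtype=object)
        loci = np.array([_GENE_LOCI[g] for g in genes], dtype=object)
        chrom = np.array([c for c, _ in loci])
        base = np.array([b for _, b in loci], dtype=np.int64)
        vaf = np.clip(vaf_draw(k), 1e-6, 1.0)
        depth = np.maximum(rng.poisson(config.depth_mean, size=k), 1)
        alt = np.minimum(rng.binomial(depth, vaf), depth)
        prot = np.where(
            genes == "B2M",
            rng.integers(1, 120, size=k),
            rng.integers(25, 366, size=k),
        )
        return pd.DataFrame(
            {
                "patient_id": patient_ids[idx],
                "gene": genes,
                "variant_classification": _choice(rng, classes, k),
                "chrom": chrom,
                "pos": base + rng.integers(0, 8_000, size=k),
                "protein_pos": prot,
                "t_alt_count": alt,
                "t_depth": depth,
                # escape mutations are analyzed as expressed events
                "rna_read_count": 5 + rng.poisson(25.0, size=k),
            }
        )

    b2m_idx = np.flatnonzero(has_b2m)
    b2m_df = _escape_rows(
        b2m_idx,
        lambda i: "B2M",
        _B2M_ESCAPE_CLASSES,
        lambda k: rng.beta(vm.b2m_alpha, vm.b2m_beta, size=k),
    )

    hla_idx = np.flatnonzero(has_hla)
    hla_high = np.zeros(n, dtype=bool)
    hla_high[hla_idx] = rng.random(len(hla_idx)) < vm.hla_high_weight

    def _hla_vaf(k: int) -> np.ndarray:
        high = hla_high[hla_idx]
        out = np.empty(k)
        out[high] = rng.beta(vm.hla_high_alpha, vm.hla_high_beta, size=int(high.sum()))
        out[~high] = rng.beta(vm.hla_low_alpha, vm.hla_low_beta, size=int((~high).sum()))
        return out

    hla_df = _escape_rows(
        hla_idx,
        lambda i: SLOT_GENE[int(mutated_slot[i])],
        _HLA_ESCAPE_CLASSES,
        _hla_vaf,
    )

    syn_idx = np.flatnonzero(groups == Group.SYN_ONLY.value)
    syn_df = _escape_rows(
        syn_idx,
        lambda i: ("B2M", "HLA-A", "HLA-B", "HLA-C")[int(rng.integers(0, 4))],
        ((VariantClass.SILENT.value, 1.0),),
        lambda k: 1.0 - rng.random(k),
    )

    mutations = pd.concat(
        [nonsyn_df, silent_df, b2m_df, hla_df, syn_df], ignore_index=True
    )
    mutations.insert(
        0, "mutation_id", np.array([f"M{i:07d}" for i in range(1, len(mutations) + 1)])
    )
    mutations = mutations[
        [
            "mutation_id", "patient_id", "gene", "variant_classification",
            "chrom", "pos", "protein_pos", "t_alt_count", "t_depth", "rna_read_count",
        ]
    ].astype(
        {
            "pos": np.int64, "t_alt_count": np.int64, "t_depth": np.int64,
            "rna_read_count": np.int64,
        }
    )
    mutations["protein_pos"] = mutations["protein_pos"].astype("Int64")

    # --- binding percentile ranks ----------------------------------------
    is_nonsyn = mutations["variant_classification"].isin(_NONSYN_VALUES)
    rank_ids = mutations.loc[is_nonsyn, "mutation_id"].to_numpy()
    log_lo, log_hi = np.log(config.rank_log_min), np.log(config.rank_log_max)
    wide = np.exp(rng.uniform(log_lo, log_hi, size=(len(rank_ids), N_SLOTS)))

    # mutant-allele bias: redraw the mutated slot's rank below the binding
    # cutoff for a bias_strength fraction of expressed missense/indel
    # mutations of HLA-mutant patients (stronger for clonal escape)
    if config.bias_strength > 0 and len(rank_ids):
        eff_bias = np.zeros(n)
        eff_bias[has_hla] = config.bias_strength
        eff_bias[has_hla & hla_high] = min(
            1.0, config.bias_strength * config.early_bias_multiplier
        )
        sub = mutations.loc[is_nonsyn]
        eligible = (
            sub["variant_classification"].isin(_NEO_VALUES)
            & (sub["rna_read_count"] >= 5)
        ).to_numpy()
        owner_pos = pd.Series(np.arange(n), index=patient_ids)
        owner = owner_pos[sub["patient_id"].to_numpy()].to_numpy()
        boost = eligible & (rng.random(len(sub)) < eff_bias[owner])
        slot_idx = np.array(
            [int(s) - 1 if not pd.isna(s) else 0 for s in mutated_slot[owner]]
        )
        cutoff_hi = np.log(min(2.0, config.rank_log_max))
        new_ranks = np.exp(rng.uniform(min(log_lo, cutoff_hi), cutoff_hi, size=int(boost.sum())))
        wide[np.flatnonzero(boost), slot_idx[boost]] = new_ranks

    ranks = AffinityRankTable(
        pd.DataFrame(wide, index=pd.Index(rank_ids, name="mutation_id"),
                     columns=list(range(1, N_SLOTS + 1)))
    )

    # --- copy-number segments --------------------------------------------
    owner = np.repeat(np.arange(n), _N_CHROM)
    chrom = np.tile(np.arange(1, _N_CHROM + 1), n)
    cnv_hit = rng.random(n * _N_CHROM) < config.cnv_fraction
    neutral_hit = rng.random(n * _N_CHROM) < 0.25
    sign = rng.choice([-1.0, 1.0], size=n * _N_CHROM)
    cnv_lfc = sign * rng.uniform(0.15, 1.0, size=n * _N_CHROM)
    neutral_lfc = rng.uniform(-0.1, 0.1, size=n * _N_CHROM)
    neutral_start = rng.integers(1, _CHROM_LEN // 2, size=n * _N_CHROM)
    seg_frames = []
    if cnv_hit.any():
        seg_frames.append(
            pd.DataFrame(
                {
                    "patient_id": patient_ids[owner[cnv_hit]],
                    "chrom": chrom[cnv_hit].astype(str),
                    "start": np.ones(int(cnv_hit.sum()), dtype=np.int64),
                    "end": np.full(int(cnv_hit.sum()), _CHROM_LEN, dtype=np.int64),
                    "log2fc": cnv_lfc[cnv_hit],
                }
            )
        )
    if neutral_hit.any():
        seg_frames.append(
            pd.DataFrame(
                {
                    "patient_id": patient_ids[owner[neutral_hit]],
                    "chrom": chrom[neutral_hit].astype(str),
                    "start": neutral_start[neutral_hit].astype(np.int64),
                    "end": (neutral_start[neutral_hit] + _CHROM_LEN // 4).astype(np.int64),
                    "log2fc": neutral_lfc[neutral_hit],
                }
            )
        )
    if seg_frames:
        segments = pd.concat(seg_frames, ignore_index=True)
        segments = segments.sort_values(
            ["patient_id", "chrom", "start"], kind="stable", ignore_index=True
        )
    else:
        segments = pd.DataFrame(columns=list(io_formats.SEGMENT_COLUMNS)).astype(
            {"start": np.int64, "end": np.int64, "log2fc": float}
        )

    # --- immune expression -------------------------------------------------
    shift = config.immune_shift
    gzma = rng.normal(5.0, 1.0, size=n) + shift * escape
    prf1 = rng.normal(5.0, 1.0, size=n) + shift * escape
    cd8 = rng.gamma(2.0, 1.0, size=n) + shift * has_hla
    nk = rng.gamma(2.0, 1.0, size=n) + shift * has_b2m
    expression = pd.DataFrame(
        {
            "patient_id": patient_ids,
            "gzma_log2tpm": gzma,
            "prf1_log2tpm": prf1,
            "cd8_level": cd8,
            "nk_level": nk,
        }
    )

    patients = pd.DataFrame(
        {
            "patient_id": patient_ids,
            "tumor_type": tumor_type,
            "stage": stage,
            **{f"allele_{j + 1}": genotype[:, j] for j in range(N_SLOTS)},
            "mantis_score": mantis,
            "group": groups,
            "mutated_slot": pd.array(
                [pd.NA if pd.isna(s) else int(s) for s in mutated_slot], dtype="Int64"
            ),
        }
    )

    cohort = Cohort(
        patients=patients,
        mutations=mutations,
        ranks=ranks,
        segments=segments,
        expression=expression,
    )
    cohort.validate()
    return cohort


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------

COHORT_FILES = {
    "patients": "patients.tsv",
    "mutations": "mutations.maf",
    "ranks": "ranks.tsv",
    "segments": "segments.tsv",
    "expression": "expression.tsv",
}


def write_cohort(cohort: Cohort, directory: str | os.PathLike) -> dict[str, Path]:
    """Write the five cohort tables into ``directory`` (created if absent).

    Round-trips losslessly through :func:`read_cohort`.
    """
    directory = Path(directory)
    try:
        directory.mkdir(parents=True, exist_ok=True)
        paths = {key: directory / name for key, name in COHORT_FILES.items()}
        io_formats.write_patients(cohort.patients, paths["patients"])
        io_formats.write_maf_subset(cohort.mutations, paths["mutations"])
        io_formats.write_rank_table(cohort.ranks, paths["ranks"])
        io_formats.write_segments(cohort.segments, paths["segments"])
        io_formats.write_expression(cohort.expression, paths["expression"])
    except OSError as exc:
        raise OSError(f"failed writing cohort under {directory}: {exc}") from exc
    return paths


def read_cohort(directory: str | os.PathLike) -> Cohort:
    """Read a cohort previously written by :func:`write_cohort`."""
    directory = Path(directory)
    cohort = Cohort(
        patients=io_formats.read_patients_frame(directory / COHORT_FILES["patients"]),
        mutations=io_formats.read_maf_frame(directory / COHORT_FILES["mutations"]),
        ranks=io_formats.read_rank_table(directory / COHORT_FILES["ranks"]),
        segments=io_formats.read_segments_frame(directory / COHORT_FILES["segments"]),
        expression=io_formats.read_expression(directory / COHORT_FILES["expression"]),
    )
    cohort.validate()
    return cohort
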