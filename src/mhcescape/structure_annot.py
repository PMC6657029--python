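"""Residue-level structural annotation of B2M and HLA class I proteins.

Works from *precomputed* per-structure tables: relative solvent-accessible
surface area (RSA) per UniProt position, plus the set of positions
predicted to mediate the physical B2M-HLA interface. Per structure, a
position is labeled

* ``interface`` when it belongs to the interface set (overrides RSA),
* ``surface`` when RSA > 15 (strict),
* ``core`` when RSA < 5 (strict),
* ``ambiguous`` for RSA in [5, 15].

Across the structures available for a protein (multiple PDB entries,
multiple alleles) the final annotation is a single pooled plurality vote;
any tie for the top count, and any position with no structural
observation, resolves to ``ambiguous``.

Positions use UniProt full-length numbering (1-based, signal peptide
included); subtracting the 24-residue signal peptide maps HLA positions to
the IMGT/HLA mature-protein numbering.

The module also finds recurrently mutated hotspot positions (per-gene
count thresholds, strict) and tests domain-level mutation enrichment with
a Fisher exact test on a (mutations in/out of domain) x (residues in/out
of domain) table.
"""

from __future__ import annotations

import os
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .cohort_stats import ComparisonResult, fisher_exact
from .io_formats import FormatError, ValidationError

__all__ = [
    "RSA_SURFACE_THRESHOLD",
    "RSA_CORE_THRESHOLD",
    "SIGNAL_PEPTIDE_LENGTH",
    "PROTEINS",
    "PROTEIN_LENGTHS",
    "DEFAULT_HOTSPOT_THRESHOLDS",
    "DEFAULT_HLA_DOMAINS",
    "ResidueLabel",
    "StructureRSA",
    "ResidueAnnotation",
    "DomainMap",
    "classify_rsa",
    "annotate_structure",
    "consensus_label",
    "annotate_protein",
    "uniprot_to_imgt",
    "find_hotspots",
    "domain_enrichment",
    "read_rsa_tables",
    "read_domain_map",
    "write_annotations",
]

#: RSA strictly above this -> surface.
RSA_SURFACE_THRESHOLD = 15.0
#: RSA strictly below this -> core.
RSA_CORE_THRESHOLD = 5.0
#: Length of the HLA class I signal peptide (UniProt -> IMGT offset).
SIGNAL_PEPTIDE_LENGTH = 24

PROTEINS = ("B2M", "HLA-A", "HLA-B", "HLA-C")

#: Full-length UniProt sequence lengths (signal peptide included).
PROTEIN_LENGTHS = {"B2M": 119, "HLA-A": 365, "HLA-B": 362, "HLA-C": 366}

#: Per-gene hotspot count thresholds (strictly greater than).
DEFAULT_HOTSPOT_THRESHOLDS = {"HLA-A": 3, "HLA-B": 3, "HLA-C": 1}

INTERFACE = "interface"
CORE = "core"
SURFACE = "surface"
AMBIGUOUS = "ambiguous"
RESIDUE_LABELS = (INTERFACE, CORE, SURFACE, AMBIGUOUS)

ResidueLabel = str


@dataclass
class StructureRSA:
    """Precomputed residue annotations for one structure (one PDB entry).

    ``rsa_by_position`` maps UniProt positions to RSA values (percentage-
    like, >= 0); ``interface_positions`` lists positions predicted to form
    the B2M-HLA contact (they may lack an RSA value: structure-only
    evidence is allowed).
    """

    structure_id: str
    protein: str
    rsa_by_position: dict[int, float]
    interface_positions: frozenset[int] = frozenset()
    allele: str | None = None

    def __post_init__(self) -> None:
        if self.protein not in PROTEINS:
            raise ValidationError(f"unknown protein {self.protein!r}")
        for pos, rsa in self.rsa_by_position.items():
            if rsa < 0:
                raise ValidationError(f"negative RSA {rsa} at position {pos}")
        self.interface_positions = frozenset(int(p) for p in self.interface_positions)


@dataclass
class ResidueAnnotation:
    """Final consensus label for one (protein, position)."""

    protein: str
    position: int
    label: ResidueLabel

    def __post_init__(self) -> None:
        if self.label not in RESIDUE_LABELS:
            raise ValidationError(f"unknown residue label {self.label!r}")


@dataclass
class DomainMap:
    """Named, non-overlapping UniProt-position intervals of one protein."""

    protein: str
    intervals: dict[str, tuple[int, int]]

    def __post_init__(self) -> None:
        spans = sorted(self.intervals.values())
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if e1 >= s2:
                raise ValidationError("domain intervals must not overlap")
        for name, (s, e) in self.intervals.items():
            if s > e or s < 1:
                raise ValidationError(f"bad interval for domain {name!r}")

    def contains(self, name: str, position: int) -> bool:
        s, e = self.intervals[name]
        return s <= position <= e

    def length(self, name: str) -> int:
        s, e = self.intervals[name]
        return e - s + 1


#: HLA-A heavy-chain domain intervals in full-length UniProt numbering.
DEFAULT_HLA_DOMAINS = DomainMap(
    protein="HLA-A",
    intervals={
        "signal_peptide": (1, 24),
        "alpha1": (25, 114),
        "alpha2": (115, 206),
        "alpha3": (207, 298),
        "connecting_peptide": (299, 308),
        "transmembrane": (309, 332),
        "cytoplasmic": (333, 365),
    },
)


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------


def classify_rsa(rsa: float) -> ResidueLabel:
    """Label one RSA value: > 15 surface, < 5 core, [5, 15] ambiguous."""
    if rsa < 0:
        raise ValidationError(f"RSA must be >= 0, got {rsa}")
    if rsa > RSA_SURFACE_THRESHOLD:
        return SURFACE
    if rsa < RSA_CORE_THRESHOLD:
        return CORE
    return AMBIGUOUS


def annotate_structure(structure: StructureRSA) -> dict[int, ResidueLabel]:
    """Per-position labels of one structure; interface overrides RSA."""
    labels = {pos: classify_rsa(rsa) for pos, rsa in structure.rsa_by_position.items()}
    for pos in structure.interface_positions:
        labels[pos] = INTERFACE
    return labels


def consensus_label(labels: Iterable[ResidueLabel]) -> ResidueLabel:
    """Strict plurality over structure-level labels; ties and the empty
    multiset (no structural observation) resolve to ambiguous."""
    counts = Counter(labels)
    for lab in counts:
        if lab not in RESIDUE_LABELS:
            raise ValidationError(f"unknown residue label {lab!r}")
    if not counts:
        return AMBIGUOUS
    ranked = counts.most_common()
    if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
        return AMBIGUOUS
    return ranked[0][0]


def annotate_protein(
    structures: Sequence[StructureRSA],
    protein_length: int | None = None,
) -> list[ResidueAnnotation]:
    """Pooled consensus annotation of one protein over all its structures.

    All structure-level labels for a position (across PDB entries and
    alleles) enter a single plurality vote — order-independent, and
    consistent with two-stage consensus on the documented cases. Output
    covers positions 1..protein_length (default: the protein's UniProt
    length); positions never observed in any structure are ambiguous.
    """
    if not structures:
        raise ValidationError("annotate_protein requires >= 1 structure")
    proteins = {s.protein for s in structures}
    if len(proteins) > 1:
        raise ValidationError(f"structures from different proteins mixed: {sorted(proteins)}")
    protein = structures[0].protein
    if protein_length is None:
        protein_length = PROTEIN_LENGTHS[protein]
    votes: dict[int, list[ResidueLabel]] = {}
    for s in structures:
        for pos, lab in annotate_structure(s).items():
            votes.setdefault(int(pos), []).append(lab)
    positions = sorted(set(range(1, protein_length + 1)) | set(votes))
    return [
        ResidueAnnotation(protein, pos, consensus_label(votes.get(pos, ())))
        for pos in positions
    ]


def uniprot_to_imgt(position: int) -> int:
    """Map a full-length UniProt position to IMGT/HLA mature-protein
    numbering by subtracting the 24-residue signal peptide."""
    if position <= SIGNAL_PEPTIDE_LENGTH:
        raise ValidationError(
            f"position {position} lies within the {SIGNAL_PEPTIDE_LENGTH}-residue signal peptide"
        )
    return position - SIGNAL_PEPTIDE_LENGTH


def find_hotspots(
    position_counts: Mapping[int, int],
    gene: str,
    thresholds: Mapping[str, int] | None = None,
) -> list[int]:
    """Positions mutated strictly more often than the per-gene threshold."""
    thresholds = dict(DEFAULT_HOTSPOT_THRESHOLDS if thresholds is None else thresholds)
    if gene not in thresholds:
        raise ValidationError(f"no hotspot threshold defined for gene {gene!r}")
    cut = thresholds[gene]
    for pos, count in position_counts.items():
        if count < 0:
            raise ValidationError(f"negative count at position {pos}")
    return sorted(pos for pos, count in position_counts.items() if count > cut)


def domain_enrichment(
    mutation_positions: Sequence[int],
    domain_map: DomainMap,
    domain_name: str,
    protein_length: int | None = None,
) -> ComparisonResult:
    """Fisher exact test of mutation enrichment in one named domain.

    2x2 table rows: mutations (in domain, outside domain); residues
    (in domain, outside domain). The statistic is the sample cross-product
    odds ratio; a zero cell flags it as unbounded.
    """
    if domain_name not in domain_map.intervals:
        raise ValidationError(f"domain {domain_name!r} not defined in map")
    positions = list(mutation_positions)
    if not positions:
        raise ValidationError("domain_enrichment requires >= 1 mutation")
    if protein_length is None:
        protein_length = PROTEIN_LENGTHS[domain_map.protein]
    in_dom = sum(1 for p in positions if domain_map.contains(domain_name, p))
    out_dom = len(positions) - in_dom
    res_in = domain_map.length(domain_name)
    res_out = protein_length - res_in
    if res_out <= 0:
        raise ValidationError("domain covers the whole protein")
    return fisher_exact(
        [[in_dom, out_dom], [res_in, res_out]],
        label=f"domain-enrichment:{domain_map.protein}:{domain_name}",
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_rsa_tables(
    rsa_path: str | os.PathLike, interface_path: str | os.PathLike | None = None
) -> list[StructureRSA]:
    """Read per-structure RSA tables and optional interface lists.

    RSA table columns: structure_id, protein, position, rsa (optional
    allele). Interface list columns: structure_id, position.
    """
    rsa = pd.read_csv(rsa_path, sep="\t", dtype=str)
    for col in ("structure_id", "protein", "position", "rsa"):
        if col not in rsa.columns:
            raise FormatError(f"{rsa_path}: missing required column {col!r}")
    rsa["position"] = pd.to_numeric(rsa["position"], errors="raise").astype(int)
    rsa["rsa"] = pd.to_numeric(rsa["rsa"], errors="raise").astype(float)
    iface_by_structure: dict[str, set[int]] = {}
    if interface_path is not None:
        iface = pd.read_csv(interface_path, sep="\t", dtype=str)
        for col in ("structure_id", "position"):
            if col not in iface.columns:
                raise FormatError(f"{interface_path}: missing required column {col!r}")
        iface["position"] = pd.to_numeric(iface["position"], errors="raise").astype(int)
        for sid, grp in iface.groupby("structure_id"):
            iface_by_structure[str(sid)] = set(grp["position"])
    structures = []
    for sid, grp in rsa.groupby("structure_id", sort=True):
        proteins = grp["protein"].unique()
        if len(proteins) != 1:
            raise ValidationError(f"structure {sid}: mixed proteins {sorted(proteins)}")
        allele = None
        if "allele" in grp.columns:
            vals = grp["allele"].dropna().unique()
            allele = str(vals[0]) if len(vals) else None
        structures.append(
            StructureRSA(
                structure_id=str(sid),
                protein=str(proteins[0]),
                rsa_by_position=dict(zip(grp["position"], grp["rsa"])),
                interface_positions=frozenset(iface_by_structure.get(str(sid), set())),
                allele=allele,
            )
        )
    return structures


def read_domain_map(path: str | os.PathLike) -> DomainMap:
    """Load a DomainMap from a YAML file: ``protein`` plus
    ``domains: {name: [start, end]}``."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "protein" not in raw or "domains" not in raw:
        raise FormatError(f"{path}: expected keys 'protein' and 'domains'")
    intervals = {
        str(name): (int(span[0]), int(span[1])) for name, span in raw["domains"].items()
    }
    return DomainMap(protein=str(raw["protein"]), intervals=intervals)


def write_annotations(
    annotations: Sequence[ResidueAnnotation], path: str | os.PathLike
) -> None:
    pd.DataFrame(
        [(a.protein, a.position, a.label) for a in annotations],
        columns=["protein", "position", "label"],
    ).to_csv(path, sep="\t", index=False)
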