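"""Core domain types for the LuxR-linked BGC mining pipeline.

The pipeline operates on annotated biosynthetic gene clusters (BGCs):
each cluster is a contiguous genomic region carrying CDS features, a
product-type annotation (NRPS, PKS, ...) and organism metadata.  Protein
domain evidence arrives as HMMER hit rows; a gene qualifies as a LuxR
homolog when a single protein carries both the LuxR DNA-binding domain
(PF00196) and the autoinducer/signal-binding domain (PF03472), and as a
LuxI homolog when it carries the AHL-synthase domain (PF00765).

Coordinates are 0-based half-open throughout; conversion to GenBank's
1-based closed convention happens only at the I/O boundary.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, asdict
from typing import Mapping, Optional, Sequence

PF_LUXR_DNA_BINDING = "PF00196"
PF_LUXR_SIGNAL_BINDING = "PF03472"
PF_LUXI_SYNTHASE = "PF00765"

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
PROTEIN_ALPHABET = frozenset(AMINO_ACIDS + "X")
NUCLEOTIDES = frozenset("ACGTN")


class GeneRole(str, enum.Enum):
    """Functional role of a gene within its cluster (antiSMASH 'gene_kind')."""

    BIOSYNTHETIC = "biosynthetic"
    REGULATORY = "regulatory"
    TRANSPORT = "transport"
    OTHER = "other"
    UNKNOWN = "unknown"

    @classmethod
    def from_qualifier(cls, value: Optional[str]) -> "GeneRole":
        if value is None:
            return cls.UNKNOWN
        value = value.strip().lower()
        # antiSMASH writes e.g. "biosynthetic" or "biosynthetic-additional"
        for role in cls:
            if value == role.value or value.startswith(role.value + "-"):
                return role
        return cls.UNKNOWN


class Habitat(str, enum.Enum):
    """Curated lifestyle of the source organism."""

    PLANT_ASSOCIATED = "plant_associated"
    ENVIRONMENTAL = "environmental"
    HUMAN_ASSOCIATED = "human_associated"
    OTHER = "other"
    UNKNOWN = "unknown"

    @classmethod
    def from_qualifier(cls, value: Optional[str]) -> "Habitat":
        if value is None:
            return cls.UNKNOWN
        value = value.strip().lower()
        for habitat in cls:
            if value == habitat.value:
                return habitat
        return cls.UNKNOWN


@dataclass(frozen=True)
class GeneFeature:
    """One CDS within a cluster region.

    ``start``/``end`` are 0-based half-open nucleotide coordinates on the
    region; ``strand`` is +1/-1; ``translation`` is the uppercase protein
    sequence (20 standard residues plus X).
    """

    gene_id: str
    start: int
    end: int
    strand: int
    translation: str
    role: GeneRole = GeneRole.UNKNOWN

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"gene {self.gene_id!r}: need 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in (1, -1):
            raise ValueError(f"gene {self.gene_id!r}: strand must be +1 or -1")
        if not self.translation:
            raise ValueError(f"gene {self.gene_id!r}: empty translation")
        bad = set(self.translation) - PROTEIN_ALPHABET
        if bad:
            raise ValueError(
                f"gene {self.gene_id!r}: illegal residue(s) {sorted(bad)!r} in translation"
            )


@dataclass
class BGCRecord:
    """One annotated biosynthetic gene cluster."""

    record_id: str
    organism: str = ""
    taxonomy: Sequence[str] = ()
    habitat: Habitat = Habitat.UNKNOWN
    bgc_type: str = "other"
    genes: list[GeneFeature] = field(default_factory=list)
    region_seq: str = ""
    genome_gc: Optional[float] = None

    def __post_init__(self) -> None:
        n = len(self.region_seq)
        for g in self.genes:
            if g.end > n:
                raise ValueError(
                    f"record {self.record_id!r}: gene {g.gene_id!r} end {g.end} "
                    f"exceeds region length {n}"
                )

    @property
    def taxon_class(self) -> str:
        """Taxonomic class (2nd rank: phylum, class, order, family, genus)."""
        return self.taxonomy[1] if len(self.taxonomy) > 1 else "unknown"

    def gene(self, gene_id: str) -> GeneFeature:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)


@dataclass(frozen=True)
class DomainHit:
    """One Pfam domain match on one protein (one domtblout row)."""

    protein_id: str
    pfam_acc: str
    cond_evalue: float
    bitscore: float
    ali_from: int
    ali_to: int
    model_coverage: float

    def __post_init__(self) -> None:
        if self.cond_evalue <= 0:
            raise ValueError("cond_evalue must be > 0")
        if self.ali_from > self.ali_to:
            raise ValueError("ali_from must be <= ali_to")
        if not (0.0 <= self.model_coverage <= 1.0):
            raise ValueError("model_coverage must lie in [0, 1]")


@dataclass
class PipelineConfig:
    """Tunable thresholds for every pipeline stage.

    ``identity_cutoff`` (0.9), ``bootstrap_reps`` (1000) and
    ``support_display_min`` (50%) follow the published screen; the
    hmmsearch qualifying-hit thresholds (``evalue_max``, ``coverage_min``)
    and the GC windowing parameters are this package's own assumptions and
    are echoed into run manifests as such.
    """

    evalue_max: float = 1e-5
    coverage_min: float = 0.35
    identity_cutoff: float = 0.9
    bootstrap_reps: int = 1000
    support_display_min: float = 50.0
    gc_window: int = 500
    gc_step: int = 250
    alpha: float = 0.05
    seed: int = 0

    ASSUMED_DEFAULTS = ("evalue_max", "coverage_min", "gc_window", "gc_step", "alpha")

    def __post_init__(self) -> None:
        if not (0.0 < self.identity_cutoff <= 1.0):
            raise ValueError("identity_cutoff must lie in (0, 1]")
        if self.bootstrap_reps < 1:
            raise ValueError("bootstrap_reps must be >= 1")
        if self.gc_step < 1 or self.gc_window < 1:
            raise ValueError("gc_window and gc_step must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: Mapping) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        return cls(**{k: v for k, v in dict(data).items() if k in known})
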