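"""Synthetic BGC datasets with planted LuxR/LuxI structure and ground truth.

The generator emulates the statistical structure the screen assumes in its
real inputs: a population of annotated cluster records in which some carry
a LuxR-family regulator (a single protein with both the PF00196 DNA-binding
and PF03472 signal-binding domains), a configurable fraction of those also
carry a LuxI AHL-synthase gene (PF00765), some records are "luxI-only"
decoys whose sole biosynthetic-role gene is the synthase, and the rest are
LuxR-free negatives.  Planted LuxR proteins fall into K sequence families
with controlled within-family (> cutoff) and between-family (< cutoff)
identities, so the dereplication stage has an exactly known answer.

Domain evidence is planted as hit-table rows rather than as detectable
sequence motifs: detection in the real screen is hmmsearch-annotation
driven, and the generator mirrors that contract.  Mutations are
substitution-only so that sequence identities are exactly controllable.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .records import (
    AMINO_ACIDS,
    BGCRecord,
    DomainHit,
    GeneFeature,
    GeneRole,
    Habitat,
    PF_LUXI_SYNTHASE,
    PF_LUXR_DNA_BINDING,
    PF_LUXR_SIGNAL_BINDING,
)
from . import io as _io

#: Pfam model lengths used when planting hits and serializing domtblout.
MODEL_LENGTHS = {
    PF_LUXR_DNA_BINDING: 58,
    PF_LUXR_SIGNAL_BINDING: 160,
    PF_LUXI_SYNTHASE: 200,
}

LUXR_LENGTH = 250
MIN_REGION_LENGTH = 10_000

#: Cluster-type frequencies modelled on the screen's reported composition
#: (NRPS 26%, PKS 10%, NRPS-PKS 11%, long tail of other classes).
DEFAULT_TYPE_DISTRIBUTION = {
    "NRPS": 0.26,
    "PKS": 0.10,
    "NRPS-PKS": 0.11,
    "bacteriocin": 0.09,
    "terpene": 0.08,
    "siderophore": 0.06,
    "lanthipeptide": 0.05,
    "thiopeptide": 0.04,
    "beta-lactam": 0.03,
    "ectoine": 0.02,
    "other": 0.16,
}

#: Habitat frequencies: plant-associated most common, then environmental,
#: then human-associated, then other.
DEFAULT_HABITAT_DISTRIBUTION = {
    Habitat.PLANT_ASSOCIATED.value: 0.40,
    Habitat.ENVIRONMENTAL.value: 0.30,
    Habitat.HUMAN_ASSOCIATED.value: 0.20,
    Habitat.OTHER.value: 0.10,
}

#: Proteobacterial class frequencies (Gamma > Alpha > Beta >> Delta).
_CLASS_DISTRIBUTION = {
    "Gammaproteobacteria": 0.41,
    "Alphaproteobacteria": 0.31,
    "Betaproteobacteria": 0.26,
    "Deltaproteobacteria": 0.02,
}


@dataclass
class SynthSpec:
    """Parameters of one synthetic dataset.

    Defaults give 3 LuxR families of 4/3/2 members (9 true positives),
    2 luxI-only decoys, 5 negatives, a 47% LuxI co-occurrence rate among
    true positives, and a 0.60 region GC against a 0.67 genome background.
    """

    n_families: int = 3
    members_per_family: tuple[int, ...] = (4, 3, 2)
    within_identity: float = 0.95
    between_identity: float = 0.70
    luxi_fraction: float = 0.47
    luxi_only_decoys: int = 2
    negatives: int = 5
    type_distribution: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TYPE_DISTRIBUTION)
    )
    habitat_distribution: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_HABITAT_DISTRIBUTION)
    )
    region_gc: float = 0.60
    genome_gc: float = 0.67
    seed: int = 0

    def __post_init__(self) -> None:
        self.members_per_family = tuple(self.members_per_family)
        if len(self.members_per_family) != self.n_families:
            raise ValueError(
                f"members_per_family has {len(self.members_per_family)} entries "
                f"for n_families={self.n_families}"
            )
        if not (0.0 < self.between_identity < self.within_identity <= 1.0):
            raise ValueError("need 0 < between_identity < within_identity <= 1")
        for name, dist in (
            ("type_distribution", self.type_distribution),
            ("habitat_distribution", self.habitat_distribution),
        ):
            total = sum(dist.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{name} sums to {total}, expected 1")

    @property
    def n_planted(self) -> int:
        return sum(self.members_per_family)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["members_per_family"] = list(self.members_per_family)
        return d

    @classmethod
    def from_dict(cls, data) -> "SynthSpec":
        known = set(cls.__dataclass_fields__)
        return cls(**{k: v for k, v in dict(data).items() if k in known})


@dataclass
class GroundTruth:
    """Planted structure of a synthetic dataset."""

    family_of: dict[str, int]
    planted_luxr_bgcs: set[str]
    planted_luxi_bgcs: set[str]
    decoy_bgcs: set[str]

    def __post_init__(self) -> None:
        if self.decoy_bgcs & self.planted_luxr_bgcs:
            raise ValueError("decoy records cannot also be planted LuxR records")
        if not self.planted_luxi_bgcs <= self.planted_luxr_bgcs:
            raise ValueError("LuxI-planted records must be LuxR-planted records")

    def to_json(self, path) -> None:
        _io.write_json(
            {
                "family_of": self.family_of,
                "planted_luxr_bgcs": sorted(self.planted_luxr_bgcs),
                "planted_luxi_bgcs": sorted(self.planted_luxi_bgcs),
                "decoy_bgcs": sorted(self.decoy_bgcs),
            },
            path,
        )

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        data = json.loads(Path(path).read_text())
        return cls(
            family_of=dict(data["family_of"]),
            planted_luxr_bgcs=set(data["planted_luxr_bgcs"]),
            planted_luxi_bgcs=set(data["planted_luxi_bgcs"]),
            decoy_bgcs=set(data["decoy_bgcs"]),
        )


# ---------------------------------------------------------------------------
# sequence-level primitives

def random_protein(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def mutate_protein(parent: str, target_identity: float, rng: np.random.Generator) -> str:
    """Substitute residues so the child has exactly the target identity.

    The number of substituted positions is ``round(L * (1 - target))``;
    each substitution picks a residue different from the parent's, so the
    realized ungapped identity (identical residues / length) equals the
    target to within rounding (well inside +/-0.02 for L >= 50).
    """
    if not (0.0 < target_identity <= 1.0):
        raise ValueError("target_identity must lie in (0, 1]")
    if len(parent) < 50:
        raise ValueError("parent must be at least 50 residues")
    n_sub = round(len(parent) * (1.0 - target_identity))
    if n_sub == 0:
        return parent
    positions = rng.choice(len(parent), size=n_sub, replace=False)
    child = list(parent)
    for pos in positions:
        choices = [aa for aa in AMINO_ACIDS if aa != parent[pos]]
        child[pos] = choices[rng.integers(len(choices))]
    return "".join(child)


def random_dna(length: int, gc: float, rng: np.random.Generator) -> str:
    """Random nucleotide sequence with expected GC fraction ``gc``."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(list("AGCT"), size=length, p=p))


def _family_proteins(spec: SynthSpec, rng: np.random.Generator):
    """Plant K families with controlled pairwise identities.

    Family founders are independent mutants of a common root at identity
    ``1 - (1 - between)/2`` each, so founder pairs sit near the between
    target.  Within a family, each member substitutes ``round(L*(1-w)/2)``
    positions drawn from disjoint position sets, so member pairs differ at
    exactly the sum of their private substitutions: pairwise identity is
    ``1 - 2d/L ~ within_identity`` with zero sampling noise.
    """
    L = LUXR_LENGTH
    root = random_protein(L, rng)
    founder_identity = 1.0 - (1.0 - spec.between_identity) / 2.0
    d_within = round(L * (1.0 - spec.within_identity) / 2.0)
    proteins: dict[str, str] = {}
    family_of: dict[str, int] = {}
    for fam_idx, n_members in enumerate(spec.members_per_family):
        founder = mutate_protein(root, founder_identity, rng)
        need = d_within * n_members
        if need > L:
            raise ValueError(
                f"family of {n_members} members at within_identity "
                f"{spec.within_identity} needs {need} > {L} private positions"
            )
        pool = rng.choice(L, size=need, replace=False)
        for m_idx in range(n_members):
            member = list(founder)
            for pos in pool[m_idx * d_within : (m_idx + 1) * d_within]:
                choices = [aa for aa in AMINO_ACIDS if aa != founder[pos]]
                member[pos] = choices[rng.integers(len(choices))]
            pid = f"fam{fam_idx}_luxR{m_idx}"
            proteins[pid] = "".join(member)
            family_of[pid] = fam_idx
    return proteins, family_of


# ---------------------------------------------------------------------------
# record assembly

def _plant_domain_hits(protein_id: str, accs, rng: np.random.Generator):
    hits = []
    for acc in accs:
        qlen = MODEL_LENGTHS[acc]
        span = int(rng.integers(int(np.ceil(0.8 * qlen)), qlen + 1))
        hits.append(
            DomainHit(
                protein_id=protein_id,
                pfam_acc=acc,
                cond_evalue=float(10.0 ** rng.uniform(-30, -8)),
                bitscore=float(np.round(rng.uniform(60, 320), 1)),
                ali_from=1,
                ali_to=span,
                model_coverage=span / qlen,
            )
        )
    return hits


def _draw(dist: dict[str, float], rng: np.random.Generator) -> str:
    keys = sorted(dist)
    probs = np.array([dist[k] for k in keys])
    return keys[rng.choice(len(keys), p=probs / probs.sum())]


def _assemble_record(
    record_id: str,
    genes_spec: list[tuple[str, int, GeneRole]],
    spec: SynthSpec,
    bgc_type: str,
    rng: np.random.Generator,
) -> tuple[BGCRecord, list[GeneFeature]]:
    """Lay genes out left to right on a fresh random region."""
    features: list[GeneFeature] = []
    pos = 100
    for gene_id, prot_len, role in genes_spec:
        pos += int(rng.integers(50, 200))
        length_nt = prot_len * 3
        strand = 1 if rng.random() < 0.7 else -1
        translation = random_protein(prot_len, rng)
        features.append(
            GeneFeature(gene_id, pos, pos + length_nt, strand, translation, role)
        )
        pos += length_nt
    region_len = max(pos + 100, MIN_REGION_LENGTH)
    record = BGCRecord(
        record_id=record_id,
        organism=f"Synthoplasma sp. {record_id}",
        taxonomy=(
            "Proteobacteria",
            _draw(_CLASS_DISTRIBUTION, rng),
            "Synthetales",
            "Synthetaceae",
            "Synthoplasma",
        ),
        habitat=Habitat(_draw(spec.habitat_distribution, rng)),
        bgc_type=bgc_type,
        genes=features,
        region_seq=random_dna(region_len, spec.region_gc, rng),
        genome_gc=spec.genome_gc,
    )
    return record, features


def generate_dataset(spec: SynthSpec):
    """Generate ``(records, hits, truth)`` for one synthetic dataset.

    Deterministic in ``spec.seed``: per-record RNG streams are spawned from
    one seed sequence so the same spec always yields the same dataset.
    """
    master = np.random.SeedSequence(spec.seed)
    n_records = spec.n_planted + spec.luxi_only_decoys + spec.negatives
    streams = [np.random.default_rng(s) for s in master.spawn(n_records + 2)]
    fam_rng, shuffle_rng = streams[-2], streams[-1]

    luxr_proteins, raw_family_of = _family_proteins(spec, fam_rng)
    luxr_ids = sorted(raw_family_of, key=lambda p: (raw_family_of[p], p))

    records: list[BGCRecord] = []
    hits: list[DomainHit] = []
    family_of: dict[str, int] = {}
    planted_luxr: set[str] = set()
    planted_luxi: set[str] = set()
    decoys: set[str] = set()
    idx = 0

    # true positives: LuxR regulator + biosynthetic core, optional LuxI
    for pid in luxr_ids:
        rng = streams[idx]
        record_id = f"SYN{idx:04d}"
        with_luxi = bool(rng.random() < spec.luxi_fraction)
        luxr_gene = f"{record_id}_luxR"
        genes_spec = [(luxr_gene, LUXR_LENGTH, GeneRole.REGULATORY)]
        if with_luxi:
            genes_spec.append((f"{record_id}_luxI", 200, GeneRole.BIOSYNTHETIC))
        genes_spec += [
            (f"{record_id}_core1", 320, GeneRole.BIOSYNTHETIC),
            (f"{record_id}_core2", 280, GeneRole.BIOSYNTHETIC),
            (f"{record_id}_transp", 150, GeneRole.TRANSPORT),
        ]
        bgc_type = _draw(spec.type_distribution, rng)
        record, features = _assemble_record(record_id, genes_spec, spec, bgc_type, rng)
        # swap the planted LuxR sequence into the regulator gene
        record.genes[0] = dataclasses.replace(features[0], translation=luxr_proteins[pid])
        hits += _plant_domain_hits(
            luxr_gene, (PF_LUXR_DNA_BINDING, PF_LUXR_SIGNAL_BINDING), rng
        )
        if with_luxi:
            hits += _plant_domain_hits(f"{record_id}_luxI", (PF_LUXI_SYNTHASE,), rng)
            planted_luxi.add(record_id)
        family_of[luxr_gene] = raw_family_of[pid]
        planted_luxr.add(record_id)
        records.append(record)
        idx += 1

    # luxI-only decoys: a LuxR regulator whose record's only biosynthetic
    # gene is the AHL synthase itself
    for _ in range(spec.luxi_only_decoys):
        rng = streams[idx]
        record_id = f"SYN{idx:04d}"
        genes_spec = [
            (f"{record_id}_luxR", LUXR_LENGTH, GeneRole.REGULATORY),
            (f"{record_id}_luxI", 200, GeneRole.BIOSYNTHETIC),
            (f"{record_id}_transp", 150, GeneRole.TRANSPORT),
            (f"{record_id}_misc", 180, GeneRole.OTHER),
        ]
        record, _feats = _assemble_record(record_id, genes_spec, spec, "hserlactone", rng)
        hits += _plant_domain_hits(
            f"{record_id}_luxR", (PF_LUXR_DNA_BINDING, PF_LUXR_SIGNAL_BINDING), rng
        )
        hits += _plant_domain_hits(f"{record_id}_luxI", (PF_LUXI_SYNTHASE,), rng)
        decoys.add(record_id)
        records.append(record)
        idx += 1

    # negatives: no LuxR; one carries a lone DNA-binding-domain hit
    # (a GerE-like regulator) to exercise the dual-domain requirement
    for neg_idx in range(spec.negatives):
        rng = streams[idx]
        record_id = f"SYN{idx:04d}"
        genes_spec = [
            (f"{record_id}_core1", 320, GeneRole.BIOSYNTHETIC),
            (f"{record_id}_core2", 280, GeneRole.BIOSYNTHETIC),
            (f"{record_id}_reg", 220, GeneRole.REGULATORY),
            (f"{record_id}_transp", 150, GeneRole.TRANSPORT),
        ]
        bgc_type = _draw(spec.type_distribution, rng)
        record, _feats = _assemble_record(record_id, genes_spec, spec, bgc_type, rng)
        if neg_idx == 0:
            hits += _plant_domain_hits(f"{record_id}_reg", (PF_LUXR_DNA_BINDING,), rng)
        records.append(record)
        idx += 1

    order = shuffle_rng.permutation(len(records))
    records = [records[i] for i in order]
    truth = GroundTruth(
        family_of=family_of,
        planted_luxr_bgcs=planted_luxr,
        planted_luxi_bgcs=planted_luxi,
        decoy_bgcs=decoys,
    )
    return records, hits, truth


def write_dataset(spec: SynthSpec, outdir) -> dict[str, Path]:
    """Generate a dataset and serialize the full fixture set to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records, hits, truth = generate_dataset(spec)
    paths = {
        "genbank": outdir / "records.gbk",
        "domtblout": outdir / "hits.domtblout",
        "truth": outdir / "truth.json",
        "spec": outdir / "synth_spec.json",
    }
    _io.write_genbank(records, paths["genbank"])
    _io.write_domtblout(hits, paths["domtblout"], model_lengths=MODEL_LENGTHS)
    truth.to_json(paths["truth"])
    _io.write_json(spec.to_dict(), paths["spec"])
    return paths
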