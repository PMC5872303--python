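"""The LuxR-linked BGC screen.

A cluster is a hit when one of its proteins carries qualifying matches to
both LuxR-family Pfam domains — the DNA-binding domain (PF00196) and the
autoinducer/signal-binding domain (PF03472) — on the *same* protein.
Clusters whose only biosynthetic-role gene is the LuxI AHL synthase
(PF00765) are then removed: such records were called clusters solely
because the synthase itself is a biosynthetic gene, and carry no pathway
to regulate.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .records import (
    BGCRecord,
    DomainHit,
    GeneRole,
    PipelineConfig,
    PF_LUXI_SYNTHASE,
    PF_LUXR_DNA_BINDING,
    PF_LUXR_SIGNAL_BINDING,
)

logger = logging.getLogger(__name__)


@dataclass
class LuxRAssociation:
    """One screen hit: a cluster paired with its LuxR gene(s)."""

    record_id: str
    luxr_gene_ids: list[str]
    luxi_gene_ids: list[str] = field(default_factory=list)
    bgc_type: str = "other"

    def __post_init__(self) -> None:
        if not self.luxr_gene_ids:
            raise ValueError("a LuxR association needs at least one LuxR gene")

    @property
    def has_luxi(self) -> bool:
        return bool(self.luxi_gene_ids)


def _qualifying(hit: DomainHit, cfg: PipelineConfig) -> bool:
    return hit.cond_evalue <= cfg.evalue_max and hit.model_coverage >= cfg.coverage_min


def _hits_by_protein(hits: Iterable[DomainHit]) -> Mapping[str, list[DomainHit]]:
    index: dict[str, list[DomainHit]] = defaultdict(list)
    for h in hits:
        index[h.protein_id].append(h)
    return index


def find_luxr_genes(
    record: BGCRecord, hits: Iterable[DomainHit], cfg: PipelineConfig
) -> list[str]:
    """Genes with qualifying hits for BOTH LuxR domains on the same protein.

    A qualifying hit has conditional E-value <= ``cfg.evalue_max`` and model
    coverage >= ``cfg.coverage_min``.  Output preserves gene order.
    """
    index = _hits_by_protein(hits)
    out = []
    for gene in record.genes:
        accs = {
            h.pfam_acc for h in index.get(gene.gene_id, ()) if _qualifying(h, cfg)
        }
        if PF_LUXR_DNA_BINDING in accs and PF_LUXR_SIGNAL_BINDING in accs:
            out.append(gene.gene_id)
    return out


def find_luxi_genes(
    record: BGCRecord, hits: Iterable[DomainHit], cfg: PipelineConfig
) -> list[str]:
    """Genes with a qualifying hit to the LuxI AHL-synthase domain."""
    index = _hits_by_protein(hits)
    return [
        gene.gene_id
        for gene in record.genes
        if any(
            h.pfam_acc == PF_LUXI_SYNTHASE and _qualifying(h, cfg)
            for h in index.get(gene.gene_id, ())
        )
    ]


def filter_luxi_only(
    associations: Sequence[LuxRAssociation],
    records: Mapping[str, BGCRecord],
) -> list[LuxRAssociation]:
    """Drop hits whose record's biosynthetic genes are exactly its LuxI genes.

    Idempotent; preserves input order; never removes a record that has any
    biosynthetic-role gene beyond the synthase (or no synthase at all).
    """
    kept = []
    for assoc in associations:
        record = records[assoc.record_id]
        biosynthetic = {
            g.gene_id for g in record.genes if g.role is GeneRole.BIOSYNTHETIC
        }
        luxi = set(assoc.luxi_gene_ids)
        if biosynthetic and biosynthetic == luxi:
            logger.info(
                "%s removed: only biosynthetic gene is the luxI homolog",
                assoc.record_id,
            )
            continue
        kept.append(assoc)
    return kept


def mine(
    records: Sequence[BGCRecord],
    hits: Iterable[DomainHit],
    cfg: PipelineConfig | None = None,
) -> list[LuxRAssociation]:
    """Run the full screen over a dataset.

    Finds clusters with >= 1 dual-domain LuxR gene, attaches LuxI genes,
    then applies the luxI-only exclusion filter.  Deterministic; raises on
    duplicate record ids.
    """
    cfg = cfg or PipelineConfig()
    seen: set[str] = set()
    by_id: dict[str, BGCRecord] = {}
    for rec in records:
        if rec.record_id in seen:
            raise ValueError(f"duplicate record_id {rec.record_id!r}")
        seen.add(rec.record_id)
        by_id[rec.record_id] = rec

    hits = list(hits)
    associations = []
    for rec in records:
        luxr = find_luxr_genes(rec, hits, cfg)
        if not luxr:
            continue
        associations.append(
            LuxRAssociation(
                record_id=rec.record_id,
                luxr_gene_ids=luxr,
                luxi_gene_ids=find_luxi_genes(rec, hits, cfg),
                bgc_type=rec.bgc_type,
            )
        )
    return filter_luxi_only(associations, by_id)


def association_table(
    associations: Sequence[LuxRAssociation], records: Mapping[str, BGCRecord]
) -> list[dict]:
    """TSV-ready rows describing each screen hit."""
    rows = []
    for a in associations:
        rec = records[a.record_id]
        rows.append(
            {
                "record_id": a.record_id,
                "organism": rec.organism,
                "bgc_type": a.bgc_type,
                "luxr_gene_ids": ",".join(a.luxr_gene_ids),
                "has_luxi": a.has_luxi,
                "habitat": rec.habitat.value,
                "class": rec.taxon_class,
            }
        )
    return rows
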