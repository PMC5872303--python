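"""Readers and writers for the external formats the pipeline touches.

GenBank flat files and FASTA go through Biopython; HMMER domtblout is a
fixed-column whitespace table parsed directly.  Internally everything is
0-based half-open; GenBank's 1-based closed locations are converted here
and nowhere else.
"""

from __future__ import annotations

import csv
import json
import logging
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from .records import BGCRecord, DomainHit, GeneFeature, GeneRole, Habitat

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# GenBank

def read_genbank(path) -> list[BGCRecord]:
    """Read annotated cluster records from a GenBank flat file.

    One :class:`BGCRecord` per GenBank record.  CDS locations are converted
    from 1-based closed to 0-based half-open.  Missing qualifiers map to
    unknown/absent values; a CDS without a translation is skipped with a
    warning rather than raising.
    """
    path = Path(path)
    records: list[BGCRecord] = []
    try:
        parsed = list(SeqIO.parse(str(path), "genbank"))
    except ValueError as exc:
        raise ValueError(f"malformed GenBank record in {path}: {exc}") from exc
    for rec in parsed:
        habitat = Habitat.UNKNOWN
        genome_gc = None
        bgc_type = "other"
        genes: list[GeneFeature] = []
        for feat in rec.features:
            if feat.type == "source":
                habitat = Habitat.from_qualifier(_qual(feat, "habitat"))
                gc = _qual(feat, "genome_gc")
                genome_gc = float(gc) if gc is not None else None
            elif feat.type in ("region", "cluster"):
                product = _qual(feat, "product")
                if product is not None:
                    bgc_type = product
            elif feat.type == "CDS":
                translation = _qual(feat, "translation")
                gene_id = (
                    _qual(feat, "locus_tag")
                    or _qual(feat, "gene")
                    or _qual(feat, "protein_id")
                    or f"{rec.id}_cds{len(genes) + 1}"
                )
                if not translation:
                    logger.warning(
                        "%s: CDS %s has no translation; skipped", rec.id, gene_id
                    )
                    continue
                genes.append(
                    GeneFeature(
                        gene_id=gene_id,
                        start=int(feat.location.start),  # Biopython is already 0-based
                        end=int(feat.location.end),
                        strand=feat.location.strand or 1,
                        translation=translation.upper(),
                        role=GeneRole.from_qualifier(_qual(feat, "gene_kind")),
                    )
                )
        records.append(
            BGCRecord(
                record_id=rec.id,
                organism=rec.annotations.get("organism", ""),
                taxonomy=tuple(rec.annotations.get("taxonomy", ())),
                habitat=habitat,
                bgc_type=bgc_type,
                genes=genes,
                region_seq=str(rec.seq).upper(),
                genome_gc=genome_gc,
            )
        )
    if not records:
        raise ValueError(f"no GenBank records found in {path}")
    return records


def write_genbank(records: Iterable[BGCRecord], path) -> None:
    """Write cluster records as a multi-record GenBank flat file."""
    seqrecords = []
    for rec in records:
        sr = SeqRecord(
            Seq(rec.region_seq),
            id=rec.record_id,
            name=rec.record_id[:16],
            description=f"{rec.bgc_type} biosynthetic gene cluster",
            annotations={
                "molecule_type": "DNA",
                "organism": rec.organism,
                "source": rec.organism,
                "taxonomy": list(rec.taxonomy),
            },
        )
        source_quals = {"organism": [rec.organism], "habitat": [rec.habitat.value]}
        if rec.genome_gc is not None:
            source_quals["genome_gc"] = [f"{rec.genome_gc:.6f}"]
        sr.features.append(
            SeqFeature(
                SimpleLocation(0, len(rec.region_seq), strand=1),
                type="source",
                qualifiers=source_quals,
            )
        )
        sr.features.append(
            SeqFeature(
                SimpleLocation(0, len(rec.region_seq), strand=1),
                type="region",
                qualifiers={"product": [rec.bgc_type]},
            )
        )
        for g in rec.genes:
            sr.features.append(
                SeqFeature(
                    SimpleLocation(g.start, g.end, strand=g.strand),
                    type="CDS",
                    qualifiers={
                        "locus_tag": [g.gene_id],
                        "translation": [g.translation],
                        "gene_kind": [g.role.value],
                    },
                )
            )
        seqrecords.append(sr)
    SeqIO.write(seqrecords, str(path), "genbank")


def _qual(feat, key):
    values = feat.qualifiers.get(key)
    return values[0] if values else None


# ---------------------------------------------------------------------------
# HMMER domtblout

#: column indices (0-based) in HMMER 3 per-domain tabular output
_DOMTBL_MIN_FIELDS = 23


def read_domtblout(path) -> list[DomainHit]:
    """Parse a HMMER ``--domtblout`` table into :class:`DomainHit` rows.

    ``model_coverage`` is derived as (hmm_to - hmm_from + 1) / model_length.
    The query accession column is used for the Pfam accession, with the
    version suffix (``PF00196.20`` -> ``PF00196``) stripped.
    """
    hits: list[DomainHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < _DOMTBL_MIN_FIELDS:
                raise ValueError(
                    f"{path}: row {lineno} has {len(fields)} fields, "
                    f"expected >= {_DOMTBL_MIN_FIELDS}"
                )
            qlen = int(fields[5])
            hmm_from, hmm_to = int(fields[15]), int(fields[16])
            acc = fields[4]
            if acc == "-":
                acc = fields[3]
            hits.append(
                DomainHit(
                    protein_id=fields[0],
                    pfam_acc=acc.split(".")[0],
                    cond_evalue=float(fields[11]),
                    bitscore=float(fields[13]),
                    ali_from=int(fields[17]),
                    ali_to=int(fields[18]),
                    model_coverage=(hmm_to - hmm_from + 1) / qlen,
                )
            )
    return hits


def write_domtblout(hits: Iterable[DomainHit], path, model_lengths=None) -> None:
    """Write hits in the HMMER per-domain tabular dialect.

    ``model_lengths`` maps Pfam accession -> model length; when absent a
    length is back-computed so that re-reading reproduces the stored
    coverage exactly (coverage is rounded to the implied span).
    """
    model_lengths = dict(model_lengths or {})
    with open(path, "w") as fh:
        fh.write("# --- full sequence --- -------------- this domain --------------\n")
        fh.write("# target name | query acc | c-Evalue | score | hmm/ali coords\n")
        for h in hits:
            qlen = model_lengths.get(h.pfam_acc, 1000)
            span = max(1, round(h.model_coverage * qlen))
            hmm_from, hmm_to = 1, span
            row = [
                h.protein_id, "-", "0",
                h.pfam_acc, h.pfam_acc, str(qlen),
                f"{h.cond_evalue:.17g}", f"{h.bitscore:.17g}", "0.0",
                "1", "1",
                f"{h.cond_evalue:.17g}", f"{h.cond_evalue:.17g}",
                f"{h.bitscore:.17g}", "0.0",
                str(hmm_from), str(hmm_to),
                str(h.ali_from), str(h.ali_to),
                str(h.ali_from), str(h.ali_to),
                "0.99", "-",
            ]
            fh.write(" ".join(row) + "\n")


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path) -> dict[str, str]:
    """Read a (possibly aligned) FASTA file as an ordered id -> sequence map."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seqs[rec.id] = str(rec.seq).upper()
    return seqs


def write_fasta(seqs: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


# ---------------------------------------------------------------------------
# Newick

def write_newick(tree, path) -> None:
    """Write a phylogenetic tree as Newick.

    Branch lengths are printed to 6 decimals and integer bootstrap supports
    become internal-node labels.  Duplicate leaf names or negative branch
    lengths abort before anything is written.
    """
    leaves = tree.leaf_names()
    if len(leaves) != len(set(leaves)):
        raise ValueError("duplicate leaf names in tree")
    if len(leaves) < 2:
        raise ValueError("tree must have at least 2 leaves")
    for node, length in tree.iter_branches():
        if length is not None and length < 0:
            raise ValueError(f"negative branch length {length} on {node}")
    Path(path).write_text(tree.to_newick() + "\n")


# ---------------------------------------------------------------------------
# Tabular / JSON result helpers

def write_tsv(rows: Sequence[dict], path, columns: Sequence[str] | None = None) -> None:
    if columns is None:
        columns = list(rows[0].keys()) if rows else []
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(columns), delimiter="\t")
        writer.writeheader()
        writer.writerows(rows)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
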