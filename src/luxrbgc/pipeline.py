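"""End-to-end pipeline: mine -> dereplicate -> classify -> GC -> phylogeny.

One configuration (YAML/JSON mapping) drives a full run.  Two input modes:

- ``mode: files`` — read GenBank cluster records and a HMMER domtblout
  hit table from disk;
- ``mode: synthetic`` — generate a dataset from a ``synthetic:`` spec
  block (the generator's ground truth is serialized next to the results).

Every run writes the same artifact set (hit table, cluster table, summary
JSON, GC report, Newick tree, manifest); identical config + seed give
byte-identical artifacts.  The manifest echoes the configuration, input
digests and the stage-count funnel (input -> LuxR-positive -> post-filter
-> post-dereplication); assumed (non-published) thresholds are flagged.
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path
from typing import Mapping

import yaml

from . import gcstats, io as _io, phylogeny as phylo
from .classification import classify_luxr, tabulate
from .dereplication import cluster_table, greedy_cluster
from .mining import (
    LuxRAssociation,
    association_table,
    filter_luxi_only,
    find_luxi_genes,
    find_luxr_genes,
)
from .records import PipelineConfig
from .references import OUTGROUP_NAME, reference_panel
from .synthetic import MODEL_LENGTHS, SynthSpec, generate_dataset

logger = logging.getLogger(__name__)


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, Mapping):
        raise ValueError(f"{path}: config must be a mapping")
    return dict(cfg)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: Mapping, outdir) -> dict:
    """Execute all stages and write artifacts into ``outdir``.

    Returns the run manifest (also written as ``manifest.json``).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pcfg = PipelineConfig.from_dict(config.get("pipeline", {}))
    if "seed" in config:
        pcfg.seed = int(config["seed"])

    mode = config.get("mode", "synthetic")
    digests: dict[str, str] = {}
    truth = None
    if mode == "files":
        gbk = Path(config["inputs"]["genbank"])
        dom = Path(config["inputs"]["domtblout"])
        for p in (gbk, dom):
            if not p.exists():
                raise FileNotFoundError(f"missing input file: {p}")
        records = _io.read_genbank(gbk)
        hits = _io.read_domtblout(dom)
        digests = {"genbank": _sha256(gbk), "domtblout": _sha256(dom)}
    elif mode == "synthetic":
        spec = SynthSpec.from_dict({**config.get("synthetic", {}), "seed": pcfg.seed})
        records, hits, truth = generate_dataset(spec)
        _io.write_genbank(records, outdir / "records.gbk")
        _io.write_domtblout(hits, outdir / "hits.domtblout", MODEL_LENGTHS)
        truth.to_json(outdir / "truth.json")
        digests = {
            "genbank": _sha256(outdir / "records.gbk"),
            "domtblout": _sha256(outdir / "hits.domtblout"),
        }
    else:
        raise ValueError(f"unknown mode {mode!r}")

    by_id = {r.record_id: r for r in records}
    if len(by_id) != len(records):
        raise ValueError("duplicate record_id in input")

    # --- stage 1: the screen
    unfiltered: list[LuxRAssociation] = []
    for rec in records:
        luxr = find_luxr_genes(rec, hits, pcfg)
        if luxr:
            unfiltered.append(
                LuxRAssociation(
                    record_id=rec.record_id,
                    luxr_gene_ids=luxr,
                    luxi_gene_ids=find_luxi_genes(rec, hits, pcfg),
                    bgc_type=rec.bgc_type,
                )
            )
    associations = filter_luxi_only(unfiltered, by_id)
    logger.info(
        "screen: %d records -> %d LuxR-positive -> %d after luxI-only filter",
        len(records), len(unfiltered), len(associations),
    )
    _io.write_tsv(
        association_table(associations, by_id),
        outdir / "hits.tsv",
        columns=[
            "record_id", "organism", "bgc_type", "luxr_gene_ids",
            "has_luxi", "habitat", "class",
        ],
    )

    # --- stage 2: dereplication on the first LuxR protein of each hit
    luxr_seqs = {
        a.luxr_gene_ids[0]: by_id[a.record_id].gene(a.luxr_gene_ids[0]).translation
        for a in associations
    }
    assoc_by_luxr = {a.luxr_gene_ids[0]: a for a in associations}
    if luxr_seqs:
        clusters = greedy_cluster(luxr_seqs, pcfg.identity_cutoff)
        representatives = [assoc_by_luxr[c.representative_id] for c in clusters]
    else:
        clusters, representatives = [], []
    logger.info("dereplication: %d hits -> %d clusters", len(associations), len(clusters))
    _io.write_tsv(
        cluster_table(clusters),
        outdir / "clusters.tsv",
        columns=["cluster_index", "representative_id", "n_members",
                 "member_ids", "identities"],
    )
    rep_seqs = {c.representative_id: luxr_seqs[c.representative_id] for c in clusters}
    _io.write_fasta(rep_seqs, outdir / "representatives.fasta")

    # --- stage 3: classification & summary
    panel = reference_panel()
    summary = tabulate(representatives, by_id, n_hits_unfiltered=len(associations))
    luxr_classes = {
        rid: classify_luxr(seq, panel).value for rid, seq in rep_seqs.items()
    }
    summary_dict = summary.to_dict()
    summary_dict["luxr_classes"] = luxr_classes
    _io.write_json(summary_dict, outdir / "summary.json")

    # --- stage 4: GC anomaly per representative record
    gc_rows = []
    for a in representatives:
        rec = by_id[a.record_id]
        if rec.genome_gc is None:
            continue
        background = gcstats.binomial_background(rec.genome_gc, pcfg.gc_window)
        prof = gcstats.profile_with_anomaly(
            rec.region_seq, background, pcfg.gc_window, pcfg.gc_step, pcfg.alpha
        )
        gc_rows.append(
            {
                "record_id": rec.record_id,
                "region_max": f"{prof.region_max:.4f}",
                "region_mean": f"{prof.region_mean:.4f}",
                "region_min": f"{prof.region_min:.4f}",
                "genome_mean": "" if prof.genome_mean is None else f"{prof.genome_mean:.4f}",
                "z": "" if prof.z is None else f"{prof.z:.4f}",
                "p_value": "" if prof.p_value is None else f"{prof.p_value:.3e}",
                "anomalous": prof.anomalous,
            }
        )
    _io.write_tsv(
        gc_rows,
        outdir / "gc_report.tsv",
        columns=["record_id", "region_max", "region_mean", "region_min",
                 "genome_mean", "z", "p_value", "anomalous"],
    )

    # --- stage 5: phylogeny of representatives + reference panel
    tree_taxa = dict(rep_seqs)
    tree_taxa.update(panel.sequences)
    tree_written = False
    if len(tree_taxa) >= 4:
        msa = phylo.progressive_align(tree_taxa)
        msa = phylo.complete_deletion(msa)
        tree = phylo.neighbor_joining(phylo.p_distance(msa))
        supports = phylo.bootstrap_support(msa, pcfg.bootstrap_reps, pcfg.seed)
        rooted = phylo.root_with_outgroup(tree, OUTGROUP_NAME)
        phylo.annotate_supports(rooted, supports)
        _io.write_newick(rooted, outdir / "tree.nwk")
        tree_written = True

    manifest = {
        "config": {k: v for k, v in config.items()},
        "pipeline_config": pcfg.to_dict(),
        "assumptions": list(PipelineConfig.ASSUMED_DEFAULTS),
        "input_digests": digests,
        "seed": pcfg.seed,
        "mode": mode,
        "stage_counts": {
            "input_records": len(records),
            "luxr_positive": len(unfiltered),
            "post_luxi_only_filter": len(associations),
            "post_dereplication": len(clusters),
        },
        "tree_written": tree_written,
        "n_tree_taxa": len(tree_taxa) if tree_written else 0,
    }
    counts = manifest["stage_counts"]
    assert (
        counts["input_records"] >= counts["luxr_positive"]
        >= counts["post_luxi_only_filter"] >= counts["post_dereplication"]
    ), "stage funnel must be non-increasing"
    _io.write_json(manifest, outdir / "manifest.json")
    return manifest
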