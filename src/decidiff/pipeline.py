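"""End-to-end orchestration: formats -> deg -> setops -> enrichment ->
reduction -> clustering, with every intermediate persisted.

The pipeline is filesystem-mediated: each stage reads and writes the
documented table formats, so any stage can be re-run, swapped or
inspected in isolation, and stage-wise execution reproduces
:func:`run_all` byte for byte.  All thresholds live once in
:class:`RunConfig`; no stage hard-codes the 2.0/0.5 fold cutoffs, the
0.01 enrichment alpha or the 0.5 similarity cutoff.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .deg import (DEGSet, DEGThresholds, call_degs_bulk, call_degs_invivo,
                  pseudobulk_means)
from .errors import ConfigError
from .formats import (StudyDesign, read_annotation_tsv,
                      read_cell_matrix, read_expression_tsv, read_obo_subset,
                      write_deg_table, write_enrichment_table, write_newick,
                      write_reduced_table, write_run_summary,
                      write_venn_table)
from .setops import pairwise_overlap, shared_with_invivo, venn_partition
from .clustering import cluster_samples
from .enrichment import enrich, propagate_annotations
from .reduction import (STIMULI, call_specificity, classify_groups,
                        detections_from_classifications, information_content,
                        load_function_groups, reduce_terms)

logger = logging.getLogger(__name__)

INPUT_KEYS = ("bulk_tsv", "design_json", "mtx", "genes", "cells_meta",
              "obo", "annotation", "groups_yaml")


@dataclass
class RunConfig:
    """Validated configuration of a full pipeline run."""

    inputs: dict[str, str]
    outdir: str
    thresholds: DEGThresholds = field(default_factory=DEGThresholds)
    alpha: float = 0.01
    enrichment_method: str = "fisher"
    similarity_measure: str = "simrel"
    similarity_cutoff: float = 0.5
    marker_gene: str = "FOXO1"
    marker_min_value: float = 0.0
    log_transform: bool = True
    distance_metric: str = "euclidean"
    cluster_linkage: str = "average"
    seed: int = 0

    def __post_init__(self) -> None:
        missing = set(INPUT_KEYS) - set(self.inputs)
        if missing:
            raise ConfigError(f"missing input paths: {sorted(missing)}")
        for key in INPUT_KEYS:
            if not Path(self.inputs[key]).exists():
                raise ConfigError(
                    f"input path for {key!r} does not exist: "
                    f"{self.inputs[key]}"
                )
        if not 0 < self.alpha <= 1:
            raise ConfigError("alpha must be in (0, 1]")
        if not 0 <= self.similarity_cutoff <= 1:
            raise ConfigError("similarity_cutoff must be in [0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        thresholds = DEGThresholds(**raw.pop("thresholds", {}))
        return cls(thresholds=thresholds, **raw)

    def to_dict(self) -> dict:
        d = {
            "inputs": dict(self.inputs),
            "outdir": self.outdir,
            "thresholds": {
                "pseudocount": self.thresholds.pseudocount,
                "up_fold": self.thresholds.up_fold,
                "down_fold": self.thresholds.down_fold,
            },
            "alpha": self.alpha,
            "enrichment_method": self.enrichment_method,
            "similarity_measure": self.similarity_measure,
            "similarity_cutoff": self.similarity_cutoff,
            "marker_gene": self.marker_gene,
            "marker_min_value": self.marker_min_value,
            "log_transform": self.log_transform,
            "distance_metric": self.distance_metric,
            "cluster_linkage": self.cluster_linkage,
            "seed": self.seed,
        }
        return d

    def hash(self) -> str:
        """Digest of the analytic configuration (output location excluded)."""
        d = self.to_dict()
        d.pop("outdir")
        canon = json.dumps(d, sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def read_design_json(path: str | Path) -> StudyDesign:
    with open(path) as fh:
        raw = json.load(fh)
    return StudyDesign(tuple(raw["stimuli"]), raw["control_of"],
                       raw["protocol_days"])


def run_all(config: RunConfig) -> dict:
    """Execute every stage in order and return the run summary.

    Idempotent for identical inputs and config (the summary records a
    config hash).  Any stage failure aborts with the stage name; outputs
    written before the failure are retained next to a ``FAILED`` marker.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    try:
        return _run_stages(config, out)
    except Exception as exc:  # annotate and mark partial output
        (out / "FAILED").write_text(f"stage failed: {exc}\n")
        raise


def _run_stages(config: RunConfig, out: Path) -> dict:
    matrix = read_expression_tsv(config.inputs["bulk_tsv"])
    design = read_design_json(config.inputs["design_json"])
    cells = read_cell_matrix(config.inputs["mtx"], config.inputs["genes"],
                             config.inputs["cells_meta"])
    ontology = read_obo_subset(config.inputs["obo"])
    annotation = read_annotation_tsv(config.inputs["annotation"], ontology)
    groups = load_function_groups(config.inputs["groups_yaml"])

    # --- DEG calling -----------------------------------------------------
    bulk_degs = call_degs_bulk(matrix, design, config.thresholds)
    write_deg_table(list(bulk_degs.values()), out / "deg_bulk.tsv")
    prolif = pseudobulk_means(cells, "late_proliferative")
    secr = pseudobulk_means(cells, "late_secretory",
                            (config.marker_gene, config.marker_min_value))
    invivo = call_degs_invivo(prolif, secr, config.thresholds)
    write_deg_table(invivo, out / "deg_invivo.tsv")

    # --- set comparisons -------------------------------------------------
    stimuli = list(design.stimuli)
    pooled = venn_partition(
        [(s, bulk_degs[s].all_genes) for s in stimuli])
    write_venn_table(pooled, out / "venn_pooled.tsv")
    for direction in ("up", "down"):
        part = venn_partition(
            [(s, getattr(bulk_degs[s], direction + "_genes"))
             for s in stimuli])
        write_venn_table(part, out / f"venn_{direction}.tsv")

    overlap_rows = []
    for i, a in enumerate(stimuli):
        for b in stimuli[i + 1:]:
            tab = pairwise_overlap(bulk_degs[a], bulk_degs[b])
            for direction, row in tab.iterrows():
                overlap_rows.append((a, b, direction, row["a_only"],
                                     row["common"], row["b_only"]))
    with open(out / "pairwise_overlaps.tsv", "w") as fh:
        fh.write("a\tb\tdirection\ta_only\tcommon\tb_only\n")
        for row in overlap_rows:
            fh.write("\t".join(map(str, row)) + "\n")

    # cross-dataset comparison on the shared gene universe only
    shared_universe = set(matrix.gene_ids) & set(cells.gene_ids)
    n_excluded = (len(set(matrix.gene_ids) - shared_universe)
                  + len(set(cells.gene_ids) - shared_universe))
    if n_excluded:
        logger.info("%d gene(s) absent from one dataset excluded from "
                    "concordance", n_excluded)

    def restrict(ds: DEGSet) -> DEGSet:
        return DEGSet(
            ds.contrast_name,
            {g: f for g, f in ds.up.items() if g in shared_universe},
            {g: f for g, f in ds.down.items() if g in shared_universe},
        )

    invivo_shared = restrict(invivo)
    concordances = {}
    with open(out / "concordance.tsv", "w") as fh:
        fh.write("stimulus\tshared_up\tshared_down\tshared_total\t"
                 "invitro_total\tratio_percent\n")
        for s in stimuli:
            res = shared_with_invivo(restrict(bulk_degs[s]), invivo_shared)
            concordances[s] = res
            fh.write(f"{s}\t{len(res.shared_up)}\t{len(res.shared_down)}\t"
                     f"{res.shared_total}\t{res.invitro_total}\t"
                     f"{res.ratio_percent}\n")

    # --- enrichment / reduction / classification -------------------------
    propagated = propagate_annotations(ontology, annotation)
    ic = information_content(ontology, propagated, propagated=True)
    classified: dict[str, dict[str, dict]] = {}
    term_counts: dict[str, dict[str, dict[str, int]]] = {}
    contrasts = {s: bulk_degs[s] for s in stimuli}
    contrasts["in_vivo"] = invivo
    for cname, ds in contrasts.items():
        classified[cname] = {}
        term_counts[cname] = {}
        for direction in ("up", "down"):
            study = getattr(ds, direction + "_genes")
            report = enrich(study, propagated, ontology, config.alpha,
                            contrast_name=cname, direction=direction,
                            method=config.enrichment_method, propagated=True)
            slug = cname.replace("+", "_").replace(" ", "_")
            write_enrichment_table(report, out / f"enrich_{slug}_{direction}.tsv",
                                   ontology)
            reduced = reduce_terms(report.terms, ic, ontology,
                                   config.similarity_cutoff,
                                   config.similarity_measure)
            write_reduced_table(reduced, report.terms,
                                out / f"reduced_{slug}_{direction}.tsv",
                                ontology)
            classified[cname][direction] = classify_groups(reduced, groups,
                                                           ontology)
            term_counts[cname][direction] = {
                "enriched": len(report.terms),
                "representatives": len(reduced.representatives),
            }

    detections = detections_from_classifications(
        {s: classified[s] for s in stimuli}, groups)
    specificity = call_specificity(detections)
    with open(out / "specificity.tsv", "w") as fh:
        header = ["group", "label"]
        for s in STIMULI:
            header += [f"{s}_up", f"{s}_down"]
        fh.write("\t".join(header) + "\n")
        for group, label in specificity.labels.items():
            row = [group, label]
            for s in STIMULI:
                row += [str(int(detections[group][s]["up"])),
                        str(int(detections[group][s]["down"]))]
            fh.write("\t".join(row) + "\n")

    # --- clustering ------------------------------------------------------
    dendrogram = cluster_samples(matrix, log_transform=config.log_transform,
                                 metric=config.distance_metric,
                                 linkage=config.cluster_linkage)
    write_newick(dendrogram, out / "dendrogram.nwk")

    # --- summary ---------------------------------------------------------
    summary = {
        "version": __version__,
        "config_hash": config.hash(),
        "deg_counts": {s: {"up": len(bulk_degs[s].up),
                           "down": len(bulk_degs[s].down)} for s in stimuli},
        "invivo_counts": {"up": len(invivo.up), "down": len(invivo.down)},
        "pseudobulk_cells": {"late_proliferative": prolif.n_cells,
                             "late_secretory": secr.n_cells},
        "venn_pooled_sizes": pooled.sizes(),
        "concordance": {
            s: {"shared_up": len(c.shared_up),
                "shared_down": len(c.shared_down),
                "shared_total": c.shared_total,
                "invitro_total": c.invitro_total,
                "ratio_percent": c.ratio_percent}
            for s, c in concordances.items()},
        "term_counts": term_counts,
        "specificity": dict(specificity.labels),
        "newick": dendrogram.to_newick(),
    }
    write_run_summary(summary, out / "run_summary.json")
    failed = out / "FAILED"
    if failed.exists():
        failed.unlink()
    return summary


def verify_run(outdir: str | Path) -> list[str]:
    """Check that the persisted summary matches the persisted intermediates.

    Recomputes every count in ``run_summary.json`` from the stage output
    tables and returns a list of mismatch descriptions (empty = verified).
    """
    import pandas as pd

    from .formats import read_deg_table

    out = Path(outdir)
    summary = json.loads((out / "run_summary.json").read_text())
    problems: list[str] = []

    bulk = read_deg_table(out / "deg_bulk.tsv")
    for s, counts in summary["deg_counts"].items():
        got = {"up": len(bulk[s].up), "down": len(bulk[s].down)} \
            if s in bulk else {"up": 0, "down": 0}
        if got != counts:
            problems.append(f"deg_counts[{s}]: summary {counts}, table {got}")

    invivo = read_deg_table(out / "deg_invivo.tsv")
    ds = next(iter(invivo.values()))
    got = {"up": len(ds.up), "down": len(ds.down)}
    if got != summary["invivo_counts"]:
        problems.append(
            f"invivo_counts: summary {summary['invivo_counts']}, table {got}")

    venn = pd.read_csv(out / "venn_pooled.tsv", sep="\t", dtype=str)
    sizes = venn.groupby("label")["gene"].count().to_dict()
    for label, n in summary["venn_pooled_sizes"].items():
        if sizes.get(label, 0) != n:
            problems.append(
                f"venn[{label}]: summary {n}, table {sizes.get(label, 0)}")

    conc = pd.read_csv(out / "concordance.tsv", sep="\t", index_col=0)
    for s, c in summary["concordance"].items():
        row = conc.loc[s]
        if (int(row["shared_total"]) != c["shared_total"]
                or float(row["ratio_percent"]) != c["ratio_percent"]):
            problems.append(f"concordance[{s}] mismatch")
    return problems
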