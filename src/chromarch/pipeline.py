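"""End-to-end pipeline: ends -> clusters -> classify -> expression/marks.

``run_full_pipeline`` executes every stage that its inputs allow, writes one
TSV/BED per stage plus a consolidated ``summary.json``, and echoes the merged
configuration next to the outputs so a run is reproducible from its
artifacts alone. Stages whose inputs are missing (no FASTA, no expression
table) are marked skipped rather than failing the run.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd
import yaml

from . import annotation as ann_io
from .annotation import GenomeAnnotation, write_clusters_bed
from .clusters import (
    FamilySpec,
    GeneCluster,
    clustered_fraction,
    detect_clusters,
    detect_secretome_clusters,
    permutation_test,
)
from .ends import (
    PositionalClassConfig,
    classify_genes,
    classify_position,
    find_at_rich_segments,
    find_telomere_tracts,
    gc_disparity_curve,
    gene_end_distances,
)
from .expression import (
    ExpressionTable,
    condition_enrichment_table,
    group_mean_expression,
    induction_ratio,
    mark_counts_by_class,
    pairwise_welch,
    read_marks_tsv,
)

log = logging.getLogger("chromarch")


@dataclass
class RunConfig:
    annotation: str
    out_dir: str
    fasta: str | None = None
    labels: str | None = None
    expression: str | None = None
    expression_kind: str = "rpkm"
    marks: str | None = None
    families: list[str] = field(default_factory=list)  # empty -> auto-discover
    min_genes: int = 3
    mode: str = "max_gap"
    gap_threshold: int | None = None
    reference: str = "glucose"
    fold: float = 2.0
    at_threshold: float = 0.80
    at_min_length: int = 1000
    telomere_unit: str = "TTAGGG"
    min_copies: int = 4
    max_offset: int = 1000
    n_perm: int = 0
    seed: int = 42
    positional: PositionalClassConfig = field(default_factory=PositionalClassConfig)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        pos = raw.pop("positional", None)
        cfg = cls(**raw)
        if pos:
            cfg.positional = PositionalClassConfig(**pos)
        return cfg

    def to_yaml(self, path: str) -> None:
        raw = dataclasses.asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=True)


def cluster_positional_classes(
    clusters: list[GeneCluster],
    ann: GenomeAnnotation,
    config: PositionalClassConfig | None = None,
) -> list[GeneCluster]:
    """Assign each cluster its CEC/NCEC/MCC class from its bp envelope."""
    config = config or PositionalClassConfig()
    for c in clusters:
        chrom = ann.chromosome(c.chrom_id)
        c.positional_class = classify_position(c.span_bp, chrom.length, config)
    return clusters


def cluster_expression_groups(
    ann: GenomeAnnotation,
    clusters: list[GeneCluster],
    config: PositionalClassConfig | None = None,
) -> dict[str, str]:
    """Gene -> CEC/NCEC/MCC group of its cluster, RANDOM for unclustered genes."""
    cluster_positional_classes(clusters, ann, config)
    groups = {g.gene_id: "RANDOM" for g in ann.genes()}
    for c in clusters:
        for gid in c.member_ids:
            groups[gid] = c.positional_class
    return groups


def _clusters_frame(clusters: list[GeneCluster]) -> pd.DataFrame:
    rows = [
        {
            "family": c.family, "chrom": c.chrom_id,
            "first_ordinal": c.first_ordinal, "last_ordinal": c.last_ordinal,
            "start": c.span_bp[0], "end": c.span_bp[1],
            "n_members": c.n_members, "class": c.positional_class,
            "member_ids": ";".join(c.member_ids),
        }
        for c in sorted(clusters, key=lambda c: (c.family, c.chrom_id, c.span_bp))
    ]
    return pd.DataFrame(
        rows,
        columns=["family", "chrom", "first_ordinal", "last_ordinal", "start",
                 "end", "n_members", "class", "member_ids"],
    )


def run_full_pipeline(config: RunConfig) -> dict:
    """Run every stage and return (and write) the consolidated summary."""
    os.makedirs(config.out_dir, exist_ok=True)
    out = lambda name: os.path.join(config.out_dir, name)
    summary: dict = {"stages": {}}

    def stage(name):
        log.info("stage %s", name)
        summary["stages"][name] = "run"

    try:
        ann = ann_io.read_annotation(config.annotation, config.fasta, config.labels)
    except Exception as exc:
        raise RuntimeError(f"stage annotation failed: {exc}") from exc
    stage("annotation")
    summary["n_genes_total"] = ann.n_genes_total
    summary["genome_size"] = ann.genome_size
    summary["gene_density_per_chrom"] = {
        c.chrom_id: ann_io.gene_density(c) for c in ann.chromosomes
    }

    has_seq = all(c.sequence is not None for c in ann.chromosomes)
    if has_seq:
        stage("ends")
        telomeres, at_rows, curve_rows = [], [], []
        for chrom in ann.chromosomes:
            for t in find_telomere_tracts(
                chrom, config.telomere_unit, config.min_copies, config.max_offset
            ):
                telomeres.append(dataclasses.asdict(t))
            for seg in find_at_rich_segments(
                chrom.sequence, config.at_threshold, config.at_min_length, chrom.chrom_id
            ):
                at_rows.append(seg)
            curve = gc_disparity_curve(chrom.sequence)
            for pos in range(0, min(50_000, chrom.length), 50):
                curve_rows.append(
                    {"chrom": chrom.chrom_id, "terminus": "five_prime",
                     "offset": pos, "cumulative": int(curve[pos])}
                )
            for pos in range(0, min(50_000, chrom.length), 50):
                curve_rows.append(
                    {"chrom": chrom.chrom_id, "terminus": "three_prime",
                     "offset": pos,
                     "cumulative": int(curve[-1]) - int(curve[chrom.length - 1 - pos])}
                )
        pd.DataFrame(
            telomeres,
            columns=["chrom_id", "terminus", "unit", "n_copies", "start", "end",
                     "orientation"],
        ).to_csv(out("telomeres.tsv"), sep="\t", index=False)
        with open(out("at_segments.bed"), "w") as fh:
            fh.write("#chrom\tstart\tend\tname\tscore\n")
            for seg in at_rows:
                fh.write(
                    f"{seg.chrom_id}\t{seg.start}\t{seg.end}\tAT_rich\t"
                    f"{seg.at_fraction:.3f}\n"
                )
        pd.DataFrame(curve_rows).to_csv(out("gc_curves.tsv"), sep="\t", index=False)
        summary["n_telomere_tracts"] = len(telomeres)
        summary["n_at_segments"] = len(at_rows)
    else:
        summary["stages"]["ends"] = "skipped (no FASTA)"

    stage("classify")
    classes = classify_genes(ann, config.positional)
    distances = gene_end_distances(ann)
    rows = [
        {"gene_id": g.gene_id, "chrom": g.chrom_id,
         "distance_bp": distances[g.gene_id], "class": classes[g.gene_id]}
        for g in ann.genes()
    ]
    pd.DataFrame(rows).to_csv(out("classes.tsv"), sep="\t", index=False)
    class_counts: dict[str, int] = {}
    for cls in classes.values():
        class_counts[cls] = class_counts.get(cls, 0) + 1
    summary["gene_class_counts"] = class_counts

    stage("clusters")
    families = config.families or sorted(
        lab for lab in ann.labels()
        if len(ann.genes_with_label(lab)) >= config.min_genes
    )
    all_clusters: list[GeneCluster] = []
    summary["families"] = {}
    for label in families:
        spec = FamilySpec.from_annotation(
            ann, label, config.min_genes, config.mode, config.gap_threshold
        )
        clusters = detect_clusters(ann, spec)
        cluster_positional_classes(clusters, ann, config.positional)
        all_clusters.extend(clusters)
        fam_summary = {
            "n_members": spec.n_members,
            "D": round(spec.D, 2),
            "gap_threshold": spec.gap_threshold,
            "n_clusters": len(clusters),
            "clustered_pct": round(clustered_fraction(ann, spec, clusters), 1),
            "cluster_class_counts": {
                cls: sum(c.positional_class == cls for c in clusters)
                for cls in ("CEC", "NCEC", "MCC")
            },
        }
        log.info(
            "family %s: %d members, D=%.1f, gap=%s, %d clusters",
            label, spec.n_members, spec.D, spec.gap_threshold, len(clusters),
        )
        if config.n_perm >= 99:
            perm = permutation_test(ann, spec, config.n_perm, config.seed)
            fam_summary["permutation_p"] = perm.p_value
        summary["families"][label] = fam_summary
    if any("SECRETED" in g.labels for g in ann.genes()):
        sec = detect_secretome_clusters(ann, "SECRETED", config.min_genes)
        cluster_positional_classes(sec, ann, config.positional)
        for c in sec:
            c.family = "SECRETED_STRICT"
        all_clusters.extend(sec)
        summary["secretome_strict"] = {
            "n_clusters": len(sec),
            "n_genes": sum(c.n_members for c in sec),
        }
    _clusters_frame(all_clusters).to_csv(out("clusters.tsv"), sep="\t", index=False)
    write_clusters_bed(all_clusters, out("clusters.bed"))

    if config.expression:
        stage("expression")
        expr = ExpressionTable.read_tsv(config.expression, config.expression_kind)
        groups = cluster_expression_groups(ann, all_clusters, config.positional)
        conditions = [c for c in expr.conditions if c != config.reference]
        mean_rows, ratio_rows = [], []
        for cond in expr.conditions:
            for cls, s in group_mean_expression(expr, groups, cond).items():
                mean_rows.append(
                    {"group": cls, "condition": cond, "n": s.n,
                     "mean": s.mean, "sd": s.sd}
                )
        for cond in conditions:
            for cls, r in induction_ratio(expr, groups, cond, config.reference).items():
                ratio_rows.append({"group": cls, "condition": cond, "fold": r})
        pd.DataFrame(mean_rows).to_csv(out("group_means.tsv"), sep="\t", index=False)
        pd.DataFrame(ratio_rows).to_csv(out("induction.tsv"), sep="\t", index=False)
        enrich = condition_enrichment_table(
            expr, groups, conditions, config.reference, config.fold
        )
        enrich.to_csv(out("enrichment.tsv"), sep="\t", index=False)
        by_group: dict[str, list[float]] = {}
        for gid, cls in groups.items():
            if gid in expr.values.index:
                by_group.setdefault(cls, []).append(
                    float(expr.values.at[gid, config.reference])
                )
        welch = pairwise_welch({k: v for k, v in by_group.items() if len(v) >= 2})
        welch.to_csv(out("welch_basal.tsv"), sep="\t", index=False)
        summary["enrichment"] = {
            f"{row['class']}/{row['condition']}": {
                "n_induced": int(row["n_induced"]),
                "pct_induced": float(row["pct_induced"]),
            }
            for _, row in enrich.iterrows()
        }
    else:
        summary["stages"]["expression"] = "skipped (no expression table)"

    if config.marks:
        stage("marks")
        marks = read_marks_tsv(config.marks)
        mark_table = mark_counts_by_class(marks, classes)
        mark_table.to_csv(out("marks_by_class.tsv"), sep="\t", index=False)
        summary["marks_by_class"] = {
            f"{r['class']}/{r['mark']}": {"n_marked": int(r["n_marked"]),
                                          "pct_marked": float(r["pct_marked"])}
            for _, r in mark_table.iterrows()
        }
    else:
        summary["stages"]["marks"] = "skipped (no marks table)"

    config.to_yaml(out("run_config.yaml"))
    with open(out("summary.json"), "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return summary
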