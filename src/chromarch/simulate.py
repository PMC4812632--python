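"""Synthetic genomes with planted, manifest-recorded ground truth.

Generates multi-chromosome genomes that emulate the statistical architecture
of a compact filamentous-fungus genome: background sequence at ~51.5 % GC,
terminal (TTAGGG)_N telomere tracts on a subset of termini, terminal AT-rich
tracts of 1-2.8 kb, genes placed at ~0.28 genes/kb with planted clusters of
labeled families, a basal-expression deficit of two orders of magnitude for
chromosome-end (CEC) genes, >2-fold induction effects on inducing carbon
sources, and H3K9me3 enrichment at chromosome ends. Everything planted is
recorded in a ground-truth manifest so each downstream detector can be
scored for recovery.

Default chromosome lengths are one tenth of the 2.8-6.9 Mb range typical of
the emulated genome, keeping the full pipeline fast; ``paper_scale=True``
restores full-size chromosomes.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .annotation import (
    GeneRecord,
    GenomeAnnotation,
    build_annotation,
    write_annotation_gff3,
    write_annotation_tsv,
)
from .ends import PositionalClassConfig, classify_position, reverse_complement
from .expression import ExpressionTable, write_marks_tsv

#: termini carrying a telomere tract, with copy numbers (14<=N<=17 typical,
#: one short N=5 tract; three chromosomes have none at either terminus)
DEFAULT_TELOMERES: dict[str, dict[str, int]] = {
    "chr1": {"five_prime": 16, "three_prime": 14},
    "chr3": {"five_prime": 5},
    "chr4": {"three_prime": 16},
    "chr5": {"five_prime": 17, "three_prime": 15},
}

#: termini carrying an AT-rich tract (four chromosomes on both termini,
#: three on one terminus only)
DEFAULT_AT_TERMINI: dict[str, tuple[str, ...]] = {
    "chr1": ("five_prime", "three_prime"),
    "chr2": ("five_prime", "three_prime"),
    "chr3": ("three_prime",),
    "chr4": ("five_prime", "three_prime"),
    "chr5": ("five_prime", "three_prime"),
    "chr6": ("five_prime",),
    "chr7": ("five_prime",),
}


@dataclass
class FamilyDef:
    """A labeled gene family: total size and what gets planted as clusters."""

    label: str
    n_members: int
    n_planted_clusters: int = 0
    cluster_size: int = 3
    planted_gap: int = 0  # intervening non-family genes between adjacent members


def _default_families() -> list[FamilyDef]:
    return [
        FamilyDef("CAZYME", 23, n_planted_clusters=2, cluster_size=4, planted_gap=2),
        FamilyDef("SECRETED", 60, n_planted_clusters=4, cluster_size=4, planted_gap=0),
        FamilyDef("SSCP", 20, n_planted_clusters=2, cluster_size=3, planted_gap=0),
        FamilyDef("KOG:A", 35, n_planted_clusters=2, cluster_size=3, planted_gap=2),
        FamilyDef("KOG:J", 34, n_planted_clusters=2, cluster_size=3, planted_gap=1),
        FamilyDef("PROTEASE", 15),
        FamilyDef("ORPHAN", 30),
    ]


@dataclass
class ExpressionSpec:
    """Planted expression structure (RPKM scale).

    Basal abundance is log-normal; chromosome-end (CEC) genes carry a basal
    deficit of two orders of magnitude (``cec_basal_factor``), near-end
    (NCEC) genes a milder one. Induced genes keep their full (undeficient)
    base level times a fold draw, so end-proximal classes show the largest
    induction ratios despite comparable induced levels.
    """

    basal_meanlog: float = math.log(100.0)
    basal_sdlog: float = 0.6
    noise_sdlog: float = 0.1
    cec_basal_factor: float = 0.01
    class_basal_factors: dict = field(
        default_factory=lambda: {"NCEC": 0.3, "MCC": 1.0}
    )
    basal_conditions: tuple = ("glucose", "glycerol")
    induced_conditions: tuple = (
        "cellulose", "lactose", "sophorose", "conidiation", "confrontation",
    )
    reference: str = "glucose"
    induced_fraction: dict = field(
        default_factory=lambda: {
            "cellulose": 0.12, "lactose": 0.10, "sophorose": 0.07,
            "conidiation": 0.15, "confrontation": 0.04,
        }
    )
    induced_n: dict = field(default_factory=dict)  # exact counts, overrides fraction
    induction_fold_range: tuple = (4.0, 16.0)
    #: sampling weight multipliers making end-proximal genes likelier targets
    class_weights: dict = field(
        default_factory=lambda: {
            "conidiation": {"CEC": 4.0, "NCEC": 4.0},
            "confrontation": {"CEC": 6.0},
        }
    )

    def basal_factor(self, cls: str) -> float:
        if cls == "CEC":
            return self.cec_basal_factor
        return self.class_basal_factors.get(cls, 1.0)


@dataclass
class MarkSpec:
    """Per-class Bernoulli rates for histone-mark calls."""

    h3k9_rate_cec: float = 0.08
    h3k9_rate_other: float = 0.01
    h3k4me2_rate_cec: float = 0.115
    h3k4me2_rate_other: float = 0.48
    h3k4me3_rate_cec: float = 0.10
    h3k4me3_rate_other: float = 0.43

    def rate(self, mark: str, cls: str) -> float:
        cec = cls == "CEC"
        return {
            "H3K9me3": self.h3k9_rate_cec if cec else self.h3k9_rate_other,
            "H3K4me2": self.h3k4me2_rate_cec if cec else self.h3k4me2_rate_other,
            "H3K4me3": self.h3k4me3_rate_cec if cec else self.h3k4me3_rate_other,
        }[mark]


@dataclass
class SyntheticGenomeConfig:
    seed: int = 0
    n_chromosomes: int = 7
    chrom_lengths: tuple = (690_000, 580_000, 520_000, 470_000, 430_000, 380_000, 280_000)
    gene_density: float = 0.28  # genes per kb
    background_gc: float = 0.515
    gene_length_range: tuple = (500, 3000)
    family_defs: list = field(default_factory=_default_families)
    telomere_unit: str = "TTAGGG"
    telomere_spec: dict = field(default_factory=lambda: dict(DEFAULT_TELOMERES))
    at_tract_length_range: tuple = (1000, 2800)
    at_tract_fraction: float = 0.86
    at_tract_termini: dict = field(default_factory=lambda: dict(DEFAULT_AT_TERMINI))
    expression_spec: ExpressionSpec = field(default_factory=ExpressionSpec)
    mark_spec: MarkSpec = field(default_factory=MarkSpec)
    positional: PositionalClassConfig = field(default_factory=PositionalClassConfig)
    paper_scale: bool = False

    def lengths(self) -> list[int]:
        scale = 10 if self.paper_scale else 1
        if len(self.chrom_lengths) != self.n_chromosomes:
            raise ValueError("chrom_lengths length must equal n_chromosomes")
        return [int(L) * scale for L in self.chrom_lengths]

    def validate(self) -> None:
        for fam in self.family_defs:
            if fam.n_planted_clusters * fam.cluster_size > fam.n_members:
                raise ValueError(
                    f"family {fam.label!r}: planted genes exceed n_members"
                )
        if not (0 < self.background_gc < 1):
            raise ValueError("background_gc must be in (0,1)")
        for rates in (self.expression_spec.induced_fraction.values(),):
            if any(not 0 <= r <= 1 for r in rates):
                raise ValueError("induced fractions must be in [0,1]")


@dataclass
class SyntheticDataset:
    annotation: GenomeAnnotation
    expression: ExpressionTable
    marks: dict
    manifest: dict
    config: SyntheticGenomeConfig

    def write(self, out_dir: str) -> dict:
        """Emit FASTA, TSV+GFF3 annotation, expression and marks TSVs and the
        manifest JSON; cross-checks manifest consistency before writing."""
        self._check_consistency()
        os.makedirs(out_dir, exist_ok=True)
        paths = {
            "fasta": os.path.join(out_dir, "genome.fa"),
            "tsv": os.path.join(out_dir, "genes.tsv"),
            "gff3": os.path.join(out_dir, "genes.gff3"),
            "expression": os.path.join(out_dir, "expression.tsv"),
            "marks": os.path.join(out_dir, "marks.tsv"),
            "manifest": os.path.join(out_dir, "manifest.json"),
        }
        records = [
            SeqRecord(Seq(c.sequence), id=c.chrom_id, description="")
            for c in self.annotation.chromosomes
        ]
        SeqIO.write(records, paths["fasta"], "fasta")
        write_annotation_tsv(self.annotation, paths["tsv"])
        write_annotation_gff3(self.annotation, paths["gff3"])
        self.expression.write_tsv(paths["expression"])
        write_marks_tsv(self.marks, paths["marks"])
        with open(paths["manifest"], "w") as fh:
            json.dump(self.manifest, fh, indent=1, sort_keys=True)
            fh.write("\n")
        return paths

    def _check_consistency(self) -> None:
        man = self.manifest
        gene_ids = {g.gene_id for g in self.annotation.genes()}
        for cl in man["planted_clusters"]:
            missing = set(cl["gene_ids"]) - gene_ids
            if missing:
                raise AssertionError(f"manifest cluster genes absent: {missing}")
            fam = cl["family"]
            for gid in cl["gene_ids"]:
                if fam not in self.annotation.gene(gid).labels:
                    raise AssertionError(f"{gid} lacks planted label {fam}")
        for tel in man["planted_telomeres"]:
            chrom = self.annotation.chromosome(tel["chrom"])
            tract = chrom.sequence[tel["start"] : tel["end"]]
            unit = tel["unit"] if tel["orientation"] == "forward" else reverse_complement(tel["unit"])
            if tract != unit * tel["n_copies"]:
                raise AssertionError(f"telomere sequence mismatch on {tel['chrom']}")
        if set(man["class_of_gene"]) != gene_ids:
            raise AssertionError("manifest class map does not cover the gene set")


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return np.frombuffer(b"ACGT", dtype=np.uint8)[
        rng.choice(4, size=length, p=probs)
    ].copy()


def generate(config: SyntheticGenomeConfig | None = None) -> SyntheticDataset:
    """Generate a synthetic genome, annotation, expression and mark tables.

    Fully reproducible from ``config.seed``: the same config yields
    byte-identical output files.
    """
    config = config or SyntheticGenomeConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    lengths = config.lengths()
    chrom_ids = [f"chr{i + 1}" for i in range(config.n_chromosomes)]

    sequences: dict[str, str] = {}
    planted_telomeres = []
    planted_at_tracts = []
    feature_margin: dict[str, list[int]] = {}  # gene-free bp at [5', 3']

    unit = config.telomere_unit
    for chrom_id, L in zip(chrom_ids, lengths):
        seq = _random_sequence(rng, L, config.background_gc)
        margin5 = margin3 = 100
        for terminus, n_copies in sorted(config.telomere_spec.get(chrom_id, {}).items()):
            tract_len = n_copies * len(unit)
            if terminus == "five_prime":
                tract = (reverse_complement(unit) * n_copies).encode()
                seq[:tract_len] = np.frombuffer(tract, dtype=np.uint8)
                start, end = 0, tract_len
                margin5 = max(margin5, tract_len + 100)
            else:
                tract = (unit * n_copies).encode()
                seq[L - tract_len :] = np.frombuffer(tract, dtype=np.uint8)
                start, end = L - tract_len, L
                margin3 = max(margin3, tract_len + 100)
            planted_telomeres.append(
                {
                    "chrom": chrom_id, "terminus": terminus, "unit": unit,
                    "n_copies": int(n_copies), "start": int(start), "end": int(end),
                    "orientation": "revcomp" if terminus == "five_prime" else "forward",
                }
            )
        for terminus in config.at_tract_termini.get(chrom_id, ()):
            lo, hi = config.at_tract_length_range
            tract_len = int(rng.integers(lo, hi + 1))
            at = config.at_tract_fraction
            is_at = rng.random(tract_len) < at
            bases = np.where(
                is_at,
                np.where(rng.random(tract_len) < 0.5, ord("A"), ord("T")),
                np.where(rng.random(tract_len) < 0.5, ord("G"), ord("C")),
            ).astype(np.uint8)
            if terminus == "five_prime":
                start = margin5
                margin5 += tract_len + 100
            else:
                start = L - margin3 - tract_len
                margin3 += tract_len + 100
            seq[start : start + tract_len] = bases
            planted_at_tracts.append(
                {
                    "chrom": chrom_id, "terminus": terminus, "start": int(start),
                    "end": int(start + tract_len), "at_fraction": at,
                }
            )
        sequences[chrom_id] = seq.tobytes().decode("ascii")
        feature_margin[chrom_id] = [margin5, margin3]

    # gene placement: exponential intergenic gaps tuned to the target density
    len_lo, len_hi = config.gene_length_range
    mean_len = (len_lo + len_hi) / 2
    gap_scale = max(1000.0 / config.gene_density - mean_len, 100.0)
    genes: list[GeneRecord] = []
    counter = 0
    for chrom_id, L in zip(chrom_ids, lengths):
        pos = feature_margin[chrom_id][0]
        stop = L - feature_margin[chrom_id][1]
        while True:
            gap = rng.exponential(gap_scale)
            g_len = int(rng.integers(len_lo, len_hi + 1))
            start = int(pos + gap)
            end = start + g_len
            if end > stop:
                break
            counter += 1
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(GeneRecord(f"TR{counter:05d}", chrom_id, start, end, strand))
            pos = end

    # family labels: planted clusters first, remaining members uniform
    labels: dict[str, set[str]] = {g.gene_id: set() for g in genes}
    by_chrom: dict[str, list[GeneRecord]] = {c: [] for c in chrom_ids}
    for g in genes:
        by_chrom[g.chrom_id].append(g)  # already in start order per chromosome
    chrom_gene_counts = np.array([len(by_chrom[c]) for c in chrom_ids], dtype=float)
    planted_clusters = []
    for fam in config.family_defs:
        members: set[str] = set()
        occupied: set[tuple[str, int]] = set()  # (chrom, index) with a buffer
        for _ in range(fam.n_planted_clusters):
            step = fam.planted_gap + 1
            needed = (fam.cluster_size - 1) * step + 1
            for _attempt in range(200):
                ci = rng.choice(len(chrom_ids), p=chrom_gene_counts / chrom_gene_counts.sum())
                chrom_genes = by_chrom[chrom_ids[ci]]
                if len(chrom_genes) < needed + 10:
                    continue
                s = int(rng.integers(0, len(chrom_genes) - needed))
                idx = list(range(s, s + needed, step))
                buffer = set(
                    (chrom_ids[ci], k)
                    for k in range(s - 15, s + needed + 15)
                )
                if buffer & occupied:
                    continue
                cluster_ids = [chrom_genes[k].gene_id for k in idx]
                for gid in cluster_ids:
                    labels[gid].add(fam.label)
                members.update(cluster_ids)
                occupied |= buffer
                planted_clusters.append(
                    {"family": fam.label, "chrom": chrom_ids[ci], "gene_ids": cluster_ids}
                )
                break
            else:
                raise RuntimeError(
                    f"could not place planted cluster for {fam.label!r}"
                )
        n_extra = fam.n_members - len(members)
        pool = [g.gene_id for g in genes if fam.label not in labels[g.gene_id]]
        extra = rng.choice(len(pool), size=n_extra, replace=False)
        for k in extra:
            labels[pool[k]].add(fam.label)

    genes = [
        GeneRecord(g.gene_id, g.chrom_id, g.start, g.end, g.strand,
                   labels=frozenset(labels[g.gene_id]))
        for g in genes
    ]
    annotation = build_annotation(
        genes, dict(zip(chrom_ids, lengths)), sequences
    )

    chrom_len_map = dict(zip(chrom_ids, lengths))
    class_of_gene = {
        g.gene_id: classify_position((g.start, g.end), chrom_len_map[g.chrom_id],
                                     config.positional)
        for g in annotation.genes()
    }

    # expression matrix
    espec = config.expression_spec
    gene_ids = [g.gene_id for g in annotation.genes()]
    n_genes = len(gene_ids)
    base = rng.lognormal(espec.basal_meanlog, espec.basal_sdlog, size=n_genes)
    factors = np.array([espec.basal_factor(class_of_gene[g]) for g in gene_ids])
    induced: dict[str, list[str]] = {}
    for cond in espec.induced_conditions:
        n_ind = espec.induced_n.get(
            cond, int(round(espec.induced_fraction.get(cond, 0.0) * n_genes))
        )
        w = np.ones(n_genes)
        for cls, mult in espec.class_weights.get(cond, {}).items():
            w[[class_of_gene[g] == cls for g in gene_ids]] *= mult
        chosen = rng.choice(n_genes, size=n_ind, replace=False, p=w / w.sum())
        induced[cond] = sorted(gene_ids[k] for k in chosen)

    cols = {}
    for cond in espec.basal_conditions:
        noise = rng.lognormal(0.0, espec.noise_sdlog, size=n_genes)
        cols[cond] = base * factors * noise
    for cond in espec.induced_conditions:
        noise = rng.lognormal(0.0, espec.noise_sdlog, size=n_genes)
        folds = rng.uniform(*espec.induction_fold_range, size=n_genes)
        ind_set = set(induced[cond])
        is_ind = np.array([g in ind_set for g in gene_ids])
        cols[cond] = np.where(is_ind, base * folds, base * factors) * noise
    expr = ExpressionTable(
        pd.DataFrame(cols, index=pd.Index(gene_ids, name="gene_id")).round(4),
        value_kind="rpkm",
    )

    # histone marks
    mspec = config.mark_spec
    marks: dict[str, set[str]] = {}
    for mark in ("H3K4me2", "H3K4me3", "H3K9me3"):
        draws = rng.random(n_genes)
        for k, gid in enumerate(gene_ids):
            if draws[k] < mspec.rate(mark, class_of_gene[gid]):
                marks.setdefault(gid, set()).add(mark)

    manifest = {
        "seed": config.seed,
        "n_genes": n_genes,
        "chrom_lengths": chrom_len_map,
        "gene_density_target": config.gene_density,
        "background_gc": config.background_gc,
        "planted_clusters": planted_clusters,
        "planted_telomeres": planted_telomeres,
        "planted_at_tracts": planted_at_tracts,
        "class_of_gene": class_of_gene,
        "induced_genes": induced,
        "marks": {g: sorted(m) for g, m in sorted(marks.items())},
        "cec_basal_factor": espec.cec_basal_factor,
        "mark_rates": asdict(mspec),
    }
    return SyntheticDataset(annotation, expr, marks, manifest, config)


def emit_paper_scale_fixture(out_dir: str | None = None, seed: int = 20) -> SyntheticDataset:
    """A miniature seven-chromosome genome exercising every feature class.

    Deterministic (fixed seed): telomeres on both termini of two chromosomes,
    single-terminus tracts elsewhere and none on three chromosomes; AT tracts
    of 1-2.8 kb; planted family clusters; class-structured expression and
    marks. Written to ``out_dir`` when given.
    """
    ds = generate(SyntheticGenomeConfig(seed=seed))
    if out_dir is not None:
        ds.write(out_dir)
    return ds
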