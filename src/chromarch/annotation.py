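"""Genome annotation model: gene intervals, ordinals and functional labels.

All coordinates are 0-based, half-open (BED convention). GFF3 input/output
converts from/to the 1-based inclusive GFF convention at the boundary; TSV
input is taken to be already in the internal convention. Every downstream
analysis (cluster detection, positional classification) works off the
ordinal order of genes along each chromosome, which is assigned here once
and validated.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

log = logging.getLogger(__name__)

TSV_COLUMNS = ("gene_id", "chrom", "start", "end", "strand")


class AnnotationError(ValueError):
    """Raised when an annotation fails validation; names the offending record."""


@dataclass(frozen=True)
class GeneRecord:
    """A gene interval on a chromosome.

    ``start``/``end`` are 0-based half-open; ``ordinal`` is the gene's rank
    among all genes of its chromosome sorted by start (ties broken by end,
    then gene_id). ``labels`` holds functional category tags such as
    ``KOG:A``, ``CAZYME``, ``SECRETED``, ``SSCP``.
    """

    gene_id: str
    chrom_id: str
    start: int
    end: int
    strand: str = "."
    ordinal: int = -1
    labels: frozenset[str] = frozenset()

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class ChromosomeRecord:
    chrom_id: str
    length: int
    sequence: str | None = None
    genes: list[GeneRecord] = field(default_factory=list)

    @property
    def n_genes(self) -> int:
        return len(self.genes)


@dataclass
class GenomeAnnotation:
    """Ordered, validated per-chromosome gene intervals with labels."""

    chromosomes: list[ChromosomeRecord]

    def __post_init__(self) -> None:
        self._by_chrom = {c.chrom_id: c for c in self.chromosomes}
        self._by_gene = {g.gene_id: g for c in self.chromosomes for g in c.genes}

    @property
    def n_genes_total(self) -> int:
        return sum(c.n_genes for c in self.chromosomes)

    @property
    def genome_size(self) -> int:
        return sum(c.length for c in self.chromosomes)

    def chromosome(self, chrom_id: str) -> ChromosomeRecord:
        try:
            return self._by_chrom[chrom_id]
        except KeyError:
            raise AnnotationError(f"unknown chromosome {chrom_id!r}") from None

    def gene(self, gene_id: str) -> GeneRecord:
        try:
            return self._by_gene[gene_id]
        except KeyError:
            raise AnnotationError(f"unknown gene {gene_id!r}") from None

    def genes(self) -> Iterator[GeneRecord]:
        for chrom in self.chromosomes:
            yield from chrom.genes

    def genes_with_label(self, label: str) -> list[GeneRecord]:
        return [g for g in self.genes() if label in g.labels]

    def labels(self) -> set[str]:
        out: set[str] = set()
        for g in self.genes():
            out |= g.labels
        return out


def build_annotation(
    genes: Iterable[GeneRecord],
    chrom_lengths: Mapping[str, int],
    sequences: Mapping[str, str] | None = None,
) -> GenomeAnnotation:
    """Assemble and validate a :class:`GenomeAnnotation` from raw records.

    Assigns ordinals per chromosome by (start, end, gene_id); rejects genes on
    unknown chromosomes, duplicate gene ids, malformed coordinates and
    sequence/length mismatches.
    """
    sequences = sequences or {}
    seen: set[str] = set()
    per_chrom: dict[str, list[GeneRecord]] = {c: [] for c in chrom_lengths}
    for g in genes:
        if g.gene_id in seen:
            raise AnnotationError(f"duplicate gene_id {g.gene_id!r}")
        seen.add(g.gene_id)
        if g.chrom_id not in per_chrom:
            raise AnnotationError(
                f"gene {g.gene_id!r} on unknown chromosome {g.chrom_id!r}"
            )
        if not (0 <= g.start < g.end <= chrom_lengths[g.chrom_id]):
            raise AnnotationError(
                f"gene {g.gene_id!r}: invalid interval [{g.start}, {g.end}) on "
                f"{g.chrom_id} (length {chrom_lengths[g.chrom_id]})"
            )
        if g.strand not in ("+", "-", "."):
            raise AnnotationError(f"gene {g.gene_id!r}: invalid strand {g.strand!r}")
        per_chrom[g.chrom_id].append(g)

    chromosomes = []
    for chrom_id, length in chrom_lengths.items():
        seq = sequences.get(chrom_id)
        if seq is not None and len(seq) != length:
            raise AnnotationError(
                f"chromosome {chrom_id!r}: sequence length {len(seq)} != "
                f"declared length {length}"
            )
        ordered = sorted(per_chrom[chrom_id], key=lambda g: (g.start, g.end, g.gene_id))
        ordered = [replace(g, ordinal=i) for i, g in enumerate(ordered)]
        chromosomes.append(
            ChromosomeRecord(chrom_id=chrom_id, length=length, sequence=seq, genes=ordered)
        )
    return GenomeAnnotation(chromosomes)


def _read_fasta(path: str) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def _parse_label_field(raw: object) -> frozenset[str]:
    if raw is None or (isinstance(raw, float) and pd.isna(raw)) or raw == "":
        return frozenset()
    return frozenset(s for s in str(raw).split(";") if s)


def read_labels(path: str) -> dict[str, set[str]]:
    """Read a label table (TSV, columns gene_id and label, one row per tag)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if not {"gene_id", "label"} <= set(df.columns):
        raise AnnotationError("label table needs columns gene_id, label")
    out: dict[str, set[str]] = {}
    for gid, lab in zip(df["gene_id"], df["label"]):
        out.setdefault(gid, set()).add(lab)
    return out


def read_annotation(
    path: str,
    fasta_path: str | None = None,
    labels: str | Mapping[str, set[str]] | None = None,
    chrom_lengths: Mapping[str, int] | None = None,
) -> GenomeAnnotation:
    """Load a GFF3 or TSV annotation, optionally with chromosome sequences.

    GFF3 coordinates (1-based inclusive) are converted to the internal 0-based
    half-open convention. The TSV dialect requires header columns
    gene_id, chrom, start, end, strand (internal convention), plus an optional
    ``labels`` column of ``;``-separated tags. ``labels`` may also be given as
    a separate table path or mapping. Chromosome lengths come from the FASTA
    when given, from ``chrom_lengths`` otherwise, and as a last resort from
    the maximal gene end per chromosome.
    """
    if isinstance(labels, str):
        labels = read_labels(labels)
    labels = dict(labels or {})

    ext = os.path.splitext(path)[1].lower()
    if ext in (".gff", ".gff3"):
        rows = _read_gff3_rows(path)
    else:
        rows = _read_tsv_rows(path)

    genes = []
    for gene_id, chrom, start, end, strand, tags in rows:
        tags = set(tags) | labels.get(gene_id, set())
        genes.append(
            GeneRecord(gene_id, chrom, start, end, strand, labels=frozenset(tags))
        )

    sequences = _read_fasta(fasta_path) if fasta_path else None
    if sequences is not None:
        lengths = {c: len(s) for c, s in sequences.items()}
    elif chrom_lengths is not None:
        lengths = dict(chrom_lengths)
    else:
        lengths = {}
        for g in genes:
            lengths[g.chrom_id] = max(lengths.get(g.chrom_id, 0), g.end)
        log.info("no FASTA or lengths given; chromosome lengths inferred from genes")
    return build_annotation(genes, lengths, sequences)


def _read_tsv_rows(path: str):
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(TSV_COLUMNS) - set(df.columns)
    if missing:
        raise AnnotationError(f"TSV annotation missing columns: {sorted(missing)}")
    has_labels = "labels" in df.columns
    for row in df.itertuples(index=False):
        start, end = int(row.start), int(row.end)
        if start >= end:
            raise AnnotationError(
                f"gene {row.gene_id!r}: start {start} >= end {end}"
            )
        tags = _parse_label_field(getattr(row, "labels", None)) if has_labels else frozenset()
        yield str(row.gene_id), str(row.chrom), start, end, str(row.strand), tags


def _read_gff3_rows(path: str):
    import gffutils

    db = gffutils.create_db(
        path, ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    for feat in db.features_of_type("gene", order_by=("seqid", "start")):
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        start, end = feat.start - 1, feat.end  # 1-based inclusive -> half-open
        if start >= end:
            raise AnnotationError(f"gene {gene_id!r}: start >= end after conversion")
        tags = frozenset(feat.attributes.get("labels", [""])[0].split(";")) - {""}
        yield gene_id, feat.seqid, start, end, feat.strand or ".", tags


def write_annotation_gff3(ann: GenomeAnnotation, path: str) -> None:
    """Write genes as GFF3 (1-based inclusive), with labels in attributes."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom in ann.chromosomes:
            fh.write(f"##sequence-region {chrom.chrom_id} 1 {chrom.length}\n")
        for g in ann.genes():
            attrs = f"ID={g.gene_id}"
            if g.labels:
                attrs += ";labels=" + ";".join(sorted(g.labels))
            fh.write(
                f"{g.chrom_id}\tchromarch\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\t{attrs}\n"
            )


def write_annotation_tsv(ann: GenomeAnnotation, path: str) -> None:
    rows = [
        {
            "gene_id": g.gene_id, "chrom": g.chrom_id, "start": g.start,
            "end": g.end, "strand": g.strand, "labels": ";".join(sorted(g.labels)),
        }
        for g in ann.genes()
    ]
    pd.DataFrame(rows, columns=list(TSV_COLUMNS) + ["labels"]).to_csv(
        path, sep="\t", index=False
    )


def gene_density(chrom: ChromosomeRecord) -> float:
    """Genes per kb, reported to 2 decimals."""
    if chrom.length <= 0:
        raise AnnotationError(f"chromosome {chrom.chrom_id!r} has non-positive length")
    return round(chrom.n_genes / (chrom.length / 1000.0), 2)


def write_clusters_bed(clusters: Sequence, path: str) -> None:
    """Write cluster envelopes as BED: chrom, start, end, family, n_members."""
    rows = sorted(clusters, key=lambda c: (c.chrom_id, c.span_bp[0], c.span_bp[1]))
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tname\tscore\n")
        for c in rows:
            fh.write(
                f"{c.chrom_id}\t{c.span_bp[0]}\t{c.span_bp[1]}\t{c.family}\t{c.n_members}\n"
            )


def read_bed(path: str) -> list[tuple[str, int, int, str, int]]:
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            chrom, start, end, name, score = line.rstrip("\n").split("\t")[:5]
            out.append((chrom, int(start), int(end), name, int(score)))
    return out
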