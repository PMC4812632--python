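"""Density-based detection of functional gene clusters along chromosomes.

The rules are ordinal-based: for a gene family with n members in a genome of
N genes, the average distribution number D = N/n is the expected ordinal
spacing of family genes under uniform placement. A cluster is a run of at
least ``min_genes`` family genes whose spacing beats that expectation
fivefold — either every adjacent pair is separated by at most floor(D/5)
non-family genes (max_gap mode), or the mean separation of the run stays
below D/5 (mean_gap mode). A separate adjacency rule detects secreted-protein
clusters: at least three strictly adjacent secreted genes, or at least four
secreted genes with a single non-secreted gene interrupting the group.

Significance of an observed clustered fraction is assessed by a label-shuffle
permutation test: family membership is reassigned uniformly at random over
all ordinal positions (chromosome sizes fixed) and the clustered fraction
recomputed under the same rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .annotation import AnnotationError, GenomeAnnotation


@dataclass
class FamilySpec:
    """A gene family plus its derived clustering parameters."""

    name: str
    label: str
    n_members: int
    D: float
    gap_threshold: float
    min_genes: int = 3
    mode: str = "max_gap"  # or "mean_gap"

    @classmethod
    def from_annotation(
        cls,
        ann: GenomeAnnotation,
        label: str,
        min_genes: int = 3,
        mode: str = "max_gap",
        gap_threshold: float | None = None,
        name: str | None = None,
    ) -> "FamilySpec":
        n_members = len(ann.genes_with_label(label))
        if n_members == 0:
            raise AnnotationError(f"no genes carry label {label!r}")
        D = average_distribution_number(ann.n_genes_total, n_members)
        if gap_threshold is None:
            gap_threshold = math.floor(D / 5) if mode == "max_gap" else D / 5
        return cls(name or label, label, n_members, D, gap_threshold, min_genes, mode)


@dataclass
class GeneCluster:
    family: str
    chrom_id: str
    member_ids: list[str]
    first_ordinal: int
    last_ordinal: int
    span_bp: tuple[int, int]
    n_members: int
    positional_class: str = "UNSET"


@dataclass
class ClusterPermutationResult:
    family: str
    observed_clustered_fraction: float
    null_fractions: list[float]
    p_value: float
    n_perm: int
    seed: int


def average_distribution_number(n_genes_total: int, n_members: int) -> float:
    """Expected ordinal spacing D of family genes under uniform placement."""
    if n_members <= 0 or n_genes_total <= 0:
        raise ValueError("n_genes_total and n_members must be positive")
    return n_genes_total / n_members


def average_spacing_kb(genome_size_kb: float, n_members: int) -> float:
    """Expected physical spacing (kb) of family genes, truncated to 3 decimals."""
    if n_members <= 0 or genome_size_kb <= 0:
        raise ValueError("genome_size_kb and n_members must be positive")
    return math.floor(genome_size_kb / n_members * 1000) / 1000


def window_parameters(D: float, min_genes: int = 3) -> tuple[int, int]:
    """Gap threshold floor(D/5) and the matching sliding-window length."""
    if D <= 0 or min_genes < 2:
        raise ValueError("need D > 0 and min_genes >= 2")
    gap = math.floor(D / 5)
    return gap, min_genes * gap


def _max_gap_runs(ordinals: list[int], gap_threshold: float, min_genes: int) -> list[list[int]]:
    """Maximal runs where each adjacent pair has <= gap_threshold intervening genes."""
    runs: list[list[int]] = []
    cur: list[int] = []
    for o in ordinals:
        if cur and (o - cur[-1] - 1) > gap_threshold:
            runs.append(cur)
            cur = []
        cur.append(o)
    if cur:
        runs.append(cur)
    return [r for r in runs if len(r) >= min_genes]


def _mean_gap_runs(ordinals: list[int], mean_bound: float, min_genes: int) -> list[list[int]]:
    """Maximal runs grown greedily left-to-right while the mean gap stays < bound,
    then trimmed from whichever end has the larger gap while mean >= bound."""
    runs: list[list[int]] = []
    cur: list[int] = []
    gap_sum = 0
    for o in ordinals:
        if cur:
            g = o - cur[-1] - 1
            if (gap_sum + g) / len(cur) < mean_bound:
                gap_sum += g
                cur.append(o)
                continue
            runs.append(cur)
            cur, gap_sum = [], 0
        cur.append(o)
    if cur:
        runs.append(cur)

    trimmed = []
    for r in runs:
        while len(r) >= 2:
            gaps = [b - a - 1 for a, b in zip(r, r[1:])]
            if sum(gaps) / len(gaps) < mean_bound:
                break
            r = r[1:] if gaps[0] >= gaps[-1] else r[:-1]
        if len(r) >= min_genes:
            trimmed.append(r)
    return trimmed


def detect_clusters(ann: GenomeAnnotation, spec: FamilySpec) -> list[GeneCluster]:
    """Detect family clusters chromosome by chromosome (never across junctions)."""
    if spec.mode not in ("max_gap", "mean_gap"):
        raise ValueError(f"unknown mode {spec.mode!r}")
    if not ann.genes_with_label(spec.label):
        raise AnnotationError(f"unknown label {spec.label!r}: no gene carries it")
    clusters: list[GeneCluster] = []
    for chrom in ann.chromosomes:
        fam = [g for g in chrom.genes if spec.label in g.labels]
        ordinals = [g.ordinal for g in fam]
        by_ord = {g.ordinal: g for g in fam}
        if spec.mode == "max_gap":
            runs = _max_gap_runs(ordinals, spec.gap_threshold, spec.min_genes)
        else:
            runs = _mean_gap_runs(ordinals, spec.D / 5, spec.min_genes)
        for r in runs:
            genes = [by_ord[o] for o in r]
            clusters.append(
                GeneCluster(
                    family=spec.name,
                    chrom_id=chrom.chrom_id,
                    member_ids=[g.gene_id for g in genes],
                    first_ordinal=r[0],
                    last_ordinal=r[-1],
                    span_bp=(genes[0].start, genes[-1].end),
                    n_members=len(genes),
                )
            )
    return clusters


def detect_secretome_clusters(
    ann: GenomeAnnotation, label: str = "SECRETED", min_genes: int = 3
) -> list[GeneCluster]:
    """Secreted-protein clusters under the strict adjacency rule.

    Reports (a) maximal runs of >= min_genes strictly adjacent secreted genes
    and (b) maximal groups of >= min_genes+1 secreted genes containing exactly
    one interior non-secreted gene; group boundaries are always secreted.
    Adjacent blocks separated by one gene are merged greedily left-to-right.
    """
    clusters: list[GeneCluster] = []
    for chrom in ann.chromosomes:
        flags = [label in g.labels for g in chrom.genes]
        # maximal blocks of strictly adjacent secreted genes
        blocks: list[tuple[int, int]] = []  # ordinal [first, last]
        i = 0
        while i < len(flags):
            if flags[i]:
                j = i
                while j + 1 < len(flags) and flags[j + 1]:
                    j += 1
                blocks.append((i, j))
                i = j + 1
            else:
                i += 1
        taken: list[tuple[int, int, int]] = []  # (first, last, n_secreted)
        k = 0
        while k < len(blocks):
            a0, a1 = blocks[k]
            if k + 1 < len(blocks):
                b0, b1 = blocks[k + 1]
                n = (a1 - a0 + 1) + (b1 - b0 + 1)
                if b0 - a1 == 2 and n >= min_genes + 1:  # one interruption
                    taken.append((a0, b1, n))
                    k += 2
                    continue
            if a1 - a0 + 1 >= min_genes:
                taken.append((a0, a1, a1 - a0 + 1))
            k += 1
        for first, last, _n in taken:
            genes = [g for g in chrom.genes[first : last + 1] if label in g.labels]
            clusters.append(
                GeneCluster(
                    family=label,
                    chrom_id=chrom.chrom_id,
                    member_ids=[g.gene_id for g in genes],
                    first_ordinal=first,
                    last_ordinal=last,
                    span_bp=(chrom.genes[first].start, chrom.genes[last].end),
                    n_members=len(genes),
                )
            )
    return clusters


def clustered_fraction(
    ann: GenomeAnnotation, spec: FamilySpec, clusters: list[GeneCluster] | None = None
) -> float:
    """Percentage of family members that sit in a detected cluster."""
    if clusters is None:
        clusters = detect_clusters(ann, spec)
    n_clustered = sum(c.n_members for c in clusters)
    return 100.0 * n_clustered / spec.n_members


def _clustered_count_from_ordinals(
    ordinals_by_chrom: list[list[int]], spec: FamilySpec
) -> int:
    total = 0
    for ords in ordinals_by_chrom:
        if spec.mode == "max_gap":
            runs = _max_gap_runs(ords, spec.gap_threshold, spec.min_genes)
        else:
            runs = _mean_gap_runs(ords, spec.D / 5, spec.min_genes)
        total += sum(len(r) for r in runs)
    return total


def permutation_test(
    ann: GenomeAnnotation,
    spec: FamilySpec,
    n_perm: int = 999,
    seed: int = 0,
) -> ClusterPermutationResult:
    """Label-shuffle null for the clustered fraction.

    Family membership is reassigned uniformly over all ordinal slots with the
    chromosome structure fixed; p = (1 + #{null >= observed}) / (n_perm + 1).
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    observed = clustered_fraction(ann, spec)
    chrom_sizes = [c.n_genes for c in ann.chromosomes]
    offsets = np.cumsum([0] + chrom_sizes)
    n_total = offsets[-1]
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        slots = np.sort(rng.choice(n_total, size=spec.n_members, replace=False))
        per_chrom = []
        for c in range(len(chrom_sizes)):
            sel = slots[(slots >= offsets[c]) & (slots < offsets[c + 1])]
            per_chrom.append((sel - offsets[c]).tolist())
        count = _clustered_count_from_ordinals(per_chrom, spec)
        null[i] = 100.0 * count / spec.n_members
    p = (1 + int(np.sum(null >= observed))) / (n_perm + 1)
    return ClusterPermutationResult(
        family=spec.name,
        observed_clustered_fraction=observed,
        null_fractions=null.tolist(),
        p_value=p,
        n_perm=n_perm,
        seed=seed,
    )
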