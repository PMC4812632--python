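import math

import numpy as np
import pytest

from chromarch.annotation import GeneRecord, build_annotation
from chromarch.simulate import SyntheticGenomeConfig, generate


def toy_annotation(n_genes, labeled=None, chrom_id="chrA", spacing=1000,
                   gene_len=500, extra_chroms=None, sequence=None):
    """A single-chromosome annotation with genes at regular spacing.

    ``labeled`` maps a label to the ordinals that carry it; ``extra_chroms``
    maps further chrom_ids to gene counts (same spacing, unlabeled).
    """
    labeled = labeled or {}
    genes = []
    for i in range(n_genes):
        tags = {lab for lab, ords in labeled.items() if i in ords}
        genes.append(
            GeneRecord(f"{chrom_id}_g{i:04d}", chrom_id, i * spacing,
                       i * spacing + gene_len, "+", labels=frozenset(tags))
        )
    lengths = {chrom_id: n_genes * spacing + gene_len}
    for cid, n in (extra_chroms or {}).items():
        for i in range(n):
            genes.append(
                GeneRecord(f"{cid}_g{i:04d}", cid, i * spacing,
                           i * spacing + gene_len, "+")
            )
        lengths[cid] = n * spacing + gene_len
    seqs = {chrom_id: sequence} if sequence is not None else None
    if seqs:
        lengths[chrom_id] = len(sequence)
    return build_annotation(genes, lengths, seqs)


def brute_force_max_gap_clusters(member_ordinals, gap_threshold, min_genes=3):
    """Oracle: enumerate every contiguous window of member ordinals, keep
    windows where all adjacent gaps satisfy the bound, discard non-maximal."""
    members = sorted(member_ordinals)
    n = len(members)
    valid = []
    for i in range(n):
        for j in range(i + min_genes - 1, n):
            window = members[i : j + 1]
            if all(b - a - 1 <= gap_threshold for a, b in zip(window, window[1:])):
                valid.append((i, j))
    maximal = [
        (i, j)
        for (i, j) in valid
        if not any((a <= i and j <= b and (a, b) != (i, j)) for (a, b) in valid)
    ]
    return [tuple(members[i : j + 1]) for (i, j) in sorted(maximal)]


def brute_force_best_subsequence(scores):
    """Oracle: best-scoring contiguous subsequence over all O(n^2) windows,
    via prefix sums (max over j of S[j] - min_{i<j} S[i])."""
    cum = np.concatenate([[0.0], np.cumsum(scores)])
    best = -np.inf
    running_min = cum[0]
    for j in range(1, len(cum)):
        best = max(best, cum[j] - running_min)
        running_min = min(running_min, cum[j])
    return best


def brute_force_best_subsequence_quadratic(scores):
    cum = np.concatenate([[0.0], np.cumsum(scores)])
    best = -np.inf
    for i in range(len(scores)):
        best = max(best, np.max(cum[i + 1 :] - cum[i]))
    return best


def t_sf_by_quadrature(x, df):
    """Upper-tail t probability by numerical integration of the density
    written from log-gamma functions (independent of scipy.stats.t)."""
    from scipy.integrate import quad

    logc = (
        math.lgamma((df + 1) / 2)
        - math.lgamma(df / 2)
        - 0.5 * math.log(df * math.pi)
    )

    def pdf(u):
        return math.exp(logc - (df + 1) / 2 * math.log1p(u * u / df))

    val, _ = quad(pdf, x, np.inf)
    return val


def random_dna(rng, length, gc=0.5):
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=probs)])


@pytest.fixture(scope="session")
def dataset():
    """Default synthetic genome used across test modules."""
    return generate(SyntheticGenomeConfig(seed=1))


@pytest.fixture(scope="session")
def annotation(dataset):
    return dataset.annotation
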