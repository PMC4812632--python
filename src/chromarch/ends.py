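"""Chromosome-end characterization and positional classification.

Covers four terminal analyses of linear fungal chromosomes:

* telomere tract detection — longest exact tandem array of the telomere
  repeat unit (TTAGGG at the 3' terminus, its reverse complement CCCTAA at
  the 5' terminus) within a fixed offset of each terminus;
* a window-less cumulative AT/GC disparity curve, from which the GC content
  of any interval is recoverable without choosing a window size;
* AT-rich subtelomeric segments as maximal-scoring subsequences under
  per-base scores +(1-theta) for A/T and -theta for G/C, so that a segment
  has positive score exactly when its AT fraction exceeds theta;
* positional classes: CEC (chromosome-end cluster, within ``cec_max`` of a
  terminus), NCEC (near-chromosome-end, ``ncec_min``..``ncec_max``) and MCC
  (middle of the chromosome), measured from the feature edge nearest a
  terminus.

A random-region GC control samples fixed-length windows away from the
termini and reports their composition, mirroring the control used to show
that AT-rich tracts are a terminal phenomenon.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np

from .annotation import ChromosomeRecord, GenomeAnnotation

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")
# IUPAC ambiguity codes other than N are tolerated and scored 0, like N.
_IUPAC = set("ACGTUNRYSWKMBDHV")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class TelomereTract:
    chrom_id: str
    terminus: str  # five_prime | three_prime
    unit: str
    n_copies: int
    start: int
    end: int
    orientation: str  # forward | revcomp


@dataclass
class ATRichSegment:
    chrom_id: str
    start: int
    end: int
    at_fraction: float
    score: float

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class PositionalClassConfig:
    """Distance bands (bp from the nearest chromosome end) for CEC/NCEC/MCC.

    Features falling in the undefined band (cec_max, ncec_min) are assigned
    per ``gap_policy`` so the three classes partition the chromosome.
    """

    cec_max: int = 50_000
    ncec_min: int = 65_000
    ncec_max: int = 150_000
    gap_policy: str = "NCEC"

    def __post_init__(self) -> None:
        if not (self.cec_max <= self.ncec_min < self.ncec_max):
            raise ValueError("need cec_max <= ncec_min < ncec_max")
        if self.gap_policy not in ("CEC", "NCEC", "MCC"):
            raise ValueError("gap_policy must be CEC, NCEC or MCC")


@dataclass
class RegionGCStats:
    n_regions: int
    region_length: int
    mean_gc: float
    sd_gc: float
    fraction_at_above_threshold: float
    fraction_with_at_segment: float
    seed: int
    region_coords: list = field(default_factory=list)


def find_telomere_tracts(
    chrom: ChromosomeRecord,
    unit: str = "TTAGGG",
    min_copies: int = 4,
    max_offset: int = 1000,
) -> list[TelomereTract]:
    """Longest exact tandem array of the repeat unit at each terminus.

    The 3' terminus is scanned for forward-strand ``unit`` arrays, the 5'
    terminus for arrays of its reverse complement. A tract qualifies if its
    terminus-proximal edge lies within ``max_offset`` of the terminus and it
    has at least ``min_copies`` copies.
    """
    if chrom.sequence is None:
        raise ValueError(
            f"chromosome {chrom.chrom_id!r} has no sequence; supply a FASTA"
        )
    seq = chrom.sequence.upper()
    L = len(seq)
    tracts: list[TelomereTract] = []

    def best_array(pattern: str, terminus: str) -> tuple[int, int] | None:
        best = None
        for m in re.finditer(f"(?:{pattern})+", seq):
            n = (m.end() - m.start()) // len(pattern)
            if n < min_copies:
                continue
            dist = m.start() if terminus == "five_prime" else L - m.end()
            if dist > max_offset:
                continue
            if best is None or (m.end() - m.start()) > (best[1] - best[0]):
                best = (m.start(), m.end())
        return best

    hit5 = best_array(reverse_complement(unit), "five_prime")
    if hit5:
        tracts.append(
            TelomereTract(
                chrom.chrom_id, "five_prime", unit,
                (hit5[1] - hit5[0]) // len(unit), hit5[0], hit5[1], "revcomp",
            )
        )
    hit3 = best_array(unit, "three_prime")
    if hit3:
        tracts.append(
            TelomereTract(
                chrom.chrom_id, "three_prime", unit,
                (hit3[1] - hit3[0]) // len(unit), hit3[0], hit3[1], "forward",
            )
        )
    return tracts


_DISPARITY = np.zeros(256, dtype=np.int8)
for b in b"ATWatw":
    _DISPARITY[b] = 1
for b in b"GCSgcs":
    _DISPARITY[b] = -1
# W (A/T) and S (G/C) are unambiguous for composition; other codes stay 0.


def _validate_iupac(seq_bytes: np.ndarray) -> None:
    letters = {chr(c) for c in np.unique(seq_bytes)}
    bad = letters - _IUPAC
    if bad:
        raise ValueError(f"non-IUPAC characters in sequence: {sorted(bad)}")


def gc_disparity_curve(sequence: str) -> np.ndarray:
    """Cumulative AT/GC disparity: step +1 for A/T, -1 for G/C, 0 for N.

    The GC fraction of any interval [i, j) follows from the curve alone as
    ``(j - i - (c_j - c_i)) / 2 / (j - i)`` (N counted as half GC), which
    makes the curve a window-free substitute for sliding-window GC plots.
    """
    if not sequence:
        raise ValueError("empty sequence")
    arr = np.frombuffer(sequence.upper().encode("ascii"), dtype=np.uint8)
    _validate_iupac(arr)
    return np.cumsum(_DISPARITY[arr], dtype=np.int64)


def gc_from_curve(curve: np.ndarray, i: int, j: int) -> float:
    """GC fraction of [i, j) recovered from the disparity curve."""
    if not (0 <= i < j <= len(curve)):
        raise ValueError("invalid slice")
    ci = 0 if i == 0 else curve[i - 1]
    return (j - i - (curve[j - 1] - ci)) / 2 / (j - i)


def _maximal_scoring_subsequences(scores: np.ndarray) -> list[tuple[int, int, float]]:
    """All maximal-scoring (positive) disjoint subsequences, amortized linear
    time via back pointers. Returns (start, end, score) 5'->3'."""
    # Each kept subsequence is [Lidx, Ridx, Lcum, Rcum, prev]; Lcum is the
    # cumulative score just before the subsequence, Rcum just after; prev is
    # the index of the rightmost earlier entry with Lcum < this entry's Lcum
    # (entries in between all have Lcum >= it, so the search can hop).
    stack: list[list] = []
    pos_idx = np.flatnonzero(scores > 0)
    cumsum = np.cumsum(scores)
    for idx in pos_idx:
        idx = int(idx)
        left = cumsum[idx] - scores[idx]
        cur = [idx, idx + 1, float(left), float(cumsum[idx]), -1]
        while True:
            j = len(stack) - 1
            while j >= 0 and stack[j][2] >= cur[2]:
                j = stack[j][4]
            if j < 0 or stack[j][3] >= cur[3]:
                cur[4] = j
                stack.append(cur)
                break
            # merge stack[j] with cur, swallowing everything in between
            cur = [stack[j][0], cur[1], stack[j][2], cur[3], stack[j][4]]
            del stack[j:]
    return [(s[0], s[1], s[3] - s[2]) for s in stack]


def find_at_rich_segments(
    sequence: str,
    at_threshold: float = 0.80,
    min_length: int = 1000,
    chrom_id: str = "",
) -> list[ATRichSegment]:
    """Maximal-scoring AT-rich segments of at least ``min_length`` bp.

    Per-base scores are +(1 - at_threshold) for A/T, -at_threshold for G/C
    and 0 for N, so a segment scores positive iff its AT fraction (over
    unambiguous bases) exceeds the threshold. Segments are disjoint and
    reported 5'->3'.
    """
    arr = np.frombuffer(sequence.upper().encode("ascii"), dtype=np.uint8)
    _validate_iupac(arr)
    disp = _DISPARITY[arr].astype(np.float64)
    scores = np.where(disp > 0, 1.0 - at_threshold, np.where(disp < 0, -at_threshold, 0.0))
    segs = []
    for start, end, score in _maximal_scoring_subsequences(scores):
        if end - start < min_length:
            continue
        window = disp[start:end]
        n_at = int(np.sum(window > 0))
        n_gc = int(np.sum(window < 0))
        frac = n_at / (n_at + n_gc) if (n_at + n_gc) else 0.0
        segs.append(ATRichSegment(chrom_id, int(start), int(end), frac, float(score)))
    return segs


def classify_position(
    feature_span: tuple[int, int],
    chrom_length: int,
    config: PositionalClassConfig | None = None,
) -> str:
    """CEC/NCEC/MCC class of a feature from its nearest-terminus distance."""
    config = config or PositionalClassConfig()
    start, end = feature_span
    if not (0 <= start < end <= chrom_length):
        raise ValueError(
            f"span ({start}, {end}) outside chromosome of length {chrom_length}"
        )
    distance = min(start, chrom_length - end)
    if distance <= config.cec_max:
        return "CEC"
    if distance < config.ncec_min:
        return config.gap_policy
    if distance <= config.ncec_max:
        return "NCEC"
    return "MCC"


def classify_genes(
    ann: GenomeAnnotation, config: PositionalClassConfig | None = None
) -> dict[str, str]:
    """Positional class of every gene, keyed by gene_id."""
    config = config or PositionalClassConfig()
    out = {}
    for chrom in ann.chromosomes:
        for g in chrom.genes:
            out[g.gene_id] = classify_position((g.start, g.end), chrom.length, config)
    return out


def gene_end_distances(ann: GenomeAnnotation) -> dict[str, int]:
    out = {}
    for chrom in ann.chromosomes:
        for g in chrom.genes:
            out[g.gene_id] = min(g.start, chrom.length - g.end)
    return out


def _gc_at_counts(seq: str) -> tuple[int, int]:
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    disp = _DISPARITY[arr]
    return int(np.sum(disp < 0)), int(np.sum(disp > 0))


def sample_region_gc(
    ann: GenomeAnnotation,
    n_regions: int = 100,
    region_length: int = 20_000,
    exclude_terminal: int = 50_000,
    seed: int = 0,
    at_threshold: float = 0.80,
    min_segment_length: int = 1000,
) -> RegionGCStats:
    """GC statistics of randomly sampled non-terminal regions.

    Windows are drawn uniformly (chromosomes weighted by eligible span) from
    sequence at least ``exclude_terminal`` bp away from both termini. Two
    AT-richness readouts are reported: the fraction of regions whose overall
    AT content exceeds the threshold, and the fraction containing at least
    one AT-rich segment (threshold ``at_threshold``, length
    >= ``min_segment_length``).
    """
    eligible = []
    for chrom in ann.chromosomes:
        if chrom.sequence is None:
            raise ValueError(f"chromosome {chrom.chrom_id!r} has no sequence")
        span = chrom.length - 2 * exclude_terminal - region_length
        if span <= 0:
            warnings.warn(
                f"chromosome {chrom.chrom_id} too short for non-terminal "
                f"{region_length} bp regions; skipped"
            )
            continue
        eligible.append((chrom, span))
    if not eligible:
        raise ValueError("no chromosome long enough to sample non-terminal regions")

    rng = np.random.default_rng(seed)
    weights = np.array([s for _, s in eligible], dtype=float)
    weights /= weights.sum()
    gcs = np.empty(n_regions)
    n_whole_at = 0
    n_with_segment = 0
    coords = []
    for k in range(n_regions):
        ci = rng.choice(len(eligible), p=weights)
        chrom, span = eligible[ci]
        start = exclude_terminal + int(rng.integers(0, span + 1))
        region = chrom.sequence[start : start + region_length]
        n_gc, n_at = _gc_at_counts(region)
        gcs[k] = 100.0 * n_gc / (n_gc + n_at) if (n_gc + n_at) else np.nan
        if n_at / (n_at + n_gc) > at_threshold:
            n_whole_at += 1
        if find_at_rich_segments(region, at_threshold, min_segment_length):
            n_with_segment += 1
        coords.append((chrom.chrom_id, start, start + region_length))
    return RegionGCStats(
        n_regions=n_regions,
        region_length=region_length,
        mean_gc=float(np.mean(gcs)),
        sd_gc=float(np.std(gcs, ddof=1)) if n_regions > 1 else 0.0,
        fraction_at_above_threshold=n_whole_at / n_regions,
        fraction_with_at_segment=n_with_segment / n_regions,
        seed=seed,
        region_coords=coords,
    )
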