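"""Gene-level expression and histone-mark integration.

Consumes gene-level numbers only (log hybridization intensities or RPKM, and
per-gene histone-mark calls) and summarizes them over positional/cluster
classes: group means, induction ratios relative to a reference carbon
source, induced-gene enrichment tables, mark counts per class, and Welch's
unequal-variance t test for group-mean comparisons (with Benjamini-Hochberg
correction when many comparisons are reported together).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

SUPPORTED_MARKS = frozenset({"H3K4me2", "H3K4me3", "H3K9me3"})

#: pseudo-count (RPKM) added to both sides of a ratio when the reference is 0
ZERO_REFERENCE_PSEUDOCOUNT = 0.1


@dataclass
class ExpressionTable:
    """Gene x condition matrix of non-negative expression values.

    ``value_kind`` is ``rpkm`` (linear) or ``log_intensity`` (logarithmic;
    ratios are computed after de-logging with ``log_base``).
    """

    values: pd.DataFrame  # index gene_id, columns conditions
    value_kind: str = "rpkm"
    log_base: float = 2.0

    def __post_init__(self) -> None:
        if self.value_kind not in ("rpkm", "log_intensity"):
            raise ValueError(f"unknown value_kind {self.value_kind!r}")
        n0 = len(self.values)
        self.values = self.values.dropna()
        dropped = n0 - len(self.values)
        if dropped:
            log.info("dropped %d genes with missing expression values", dropped)
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("non-finite expression values")
        if self.value_kind == "rpkm" and (self.values.to_numpy() < 0).any():
            raise ValueError("negative RPKM values")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def conditions(self) -> list[str]:
        return list(self.values.columns)

    @classmethod
    def read_tsv(cls, path: str, value_kind: str = "rpkm", log_base: float = 2.0):
        df = pd.read_csv(path, sep="\t", index_col="gene_id")
        return cls(df.astype(float), value_kind, log_base)

    def write_tsv(self, path: str) -> None:
        self.values.to_csv(path, sep="\t", index_label="gene_id")

    def _col(self, condition: str) -> pd.Series:
        if condition not in self.values.columns:
            raise KeyError(f"unknown condition {condition!r}")
        return self.values[condition]

    def fold_change(self, condition: str, reference: str) -> pd.Series:
        """Per-gene fold change condition/reference on the linear scale."""
        c, r = self._col(condition), self._col(reference)
        if self.value_kind == "log_intensity":
            return pd.Series(
                np.power(self.log_base, c - r), index=self.values.index
            )
        num, den = c.astype(float).copy(), r.astype(float).copy()
        zero = den == 0
        if zero.any():
            log.info(
                "%d genes with reference RPKM 0; pseudo-count %.2f applied",
                int(zero.sum()), ZERO_REFERENCE_PSEUDOCOUNT,
            )
            num[zero] += ZERO_REFERENCE_PSEUDOCOUNT
            den[zero] += ZERO_REFERENCE_PSEUDOCOUNT
        return num / den


@dataclass
class GroupExpressionSummary:
    group: str
    condition: str
    n: int
    mean: float  # nan when the group is empty after exclusions
    sd: float
    excluded_genes: list[str] = field(default_factory=list)


@dataclass
class WelchResult:
    t: float
    df: float
    p_two_sided: float


def read_marks_tsv(path: str) -> dict[str, set[str]]:
    """Histone-mark call table: columns gene_id, mark; one row per call."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if not {"gene_id", "mark"} <= set(df.columns):
        raise ValueError("marks table needs columns gene_id, mark")
    bad = set(df["mark"]) - SUPPORTED_MARKS
    if bad:
        raise ValueError(f"unsupported marks: {sorted(bad)}")
    out: dict[str, set[str]] = {}
    for gid, mark in zip(df["gene_id"], df["mark"]):
        out.setdefault(gid, set()).add(mark)
    return out


def write_marks_tsv(marks: Mapping[str, Iterable[str]], path: str) -> None:
    rows = [
        {"gene_id": gid, "mark": m}
        for gid in sorted(marks) for m in sorted(marks[gid])
    ]
    pd.DataFrame(rows, columns=["gene_id", "mark"]).to_csv(path, sep="\t", index=False)


def induced_genes(
    expr: ExpressionTable, condition: str, reference: str, fold: float = 2.0
) -> set[str]:
    """Genes expressed strictly more than ``fold`` times the reference level."""
    fc = expr.fold_change(condition, reference)
    return set(fc.index[fc > fold])


def group_mean_expression(
    expr: ExpressionTable,
    class_assignment: Mapping[str, str],
    condition: str,
    exclusions: Iterable[str] = (),
) -> dict[str, GroupExpressionSummary]:
    """Per-class arithmetic mean and sd of a condition's values.

    ``exclusions`` removes named genes (e.g. extreme outliers whose induction
    values would dominate the class mean) before averaging.
    """
    exclusions = set(exclusions)
    col = expr._col(condition)
    out: dict[str, GroupExpressionSummary] = {}
    by_class: dict[str, list[str]] = {}
    for gid in expr.genes:
        cls = class_assignment.get(gid)
        if cls is not None:
            by_class.setdefault(cls, []).append(gid)
    for cls, gids in sorted(by_class.items()):
        excluded = sorted(set(gids) & exclusions)
        kept = [g for g in gids if g not in exclusions]
        vals = col.loc[kept].to_numpy(dtype=float)
        if len(vals) == 0:
            out[cls] = GroupExpressionSummary(cls, condition, 0, float("nan"), 0.0, excluded)
        else:
            sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
            out[cls] = GroupExpressionSummary(
                cls, condition, len(vals), float(np.mean(vals)), sd, excluded
            )
    return out


def induction_ratio(
    expr: ExpressionTable,
    class_assignment: Mapping[str, str],
    condition: str,
    reference: str,
    exclusions: Iterable[str] = (),
) -> dict[str, float]:
    """Class mean(condition) / class mean(reference); nan when undefined."""
    num = group_mean_expression(expr, class_assignment, condition, exclusions)
    den = group_mean_expression(expr, class_assignment, reference, exclusions)
    out = {}
    for cls in num:
        m_ref = den[cls].mean
        if den[cls].n == 0 or m_ref == 0 or math.isnan(m_ref):
            out[cls] = float("nan")
        else:
            out[cls] = num[cls].mean / m_ref
    return out


def welch_t_test(sample_a: Sequence[float], sample_b: Sequence[float]) -> WelchResult:
    """Welch's two-sample t test (unequal variances, Welch-Satterthwaite df)."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs n >= 2")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("samples must be finite")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = len(a), len(b)
    se2 = va / na + vb / nb
    if se2 == 0:
        # both samples constant: no variance to test against
        delta = a.mean() - b.mean()
        df = float(na + nb - 2)
        if delta == 0:
            return WelchResult(0.0, df, 1.0)
        return WelchResult(math.copysign(math.inf, delta), df, 0.0)
    t = (a.mean() - b.mean()) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return WelchResult(float(t), float(df), min(p, 1.0))


def pairwise_welch(
    groups: Mapping[str, Sequence[float]], fdr_threshold: int = 5
) -> pd.DataFrame:
    """Welch tests for every pair of groups, BH-adjusted when > ``fdr_threshold``
    comparisons are made in one report."""
    from statsmodels.stats.multitest import multipletests

    names = sorted(groups)
    rows = []
    for i, ga in enumerate(names):
        for gb in names[i + 1 :]:
            res = welch_t_test(groups[ga], groups[gb])
            rows.append(
                {"group_a": ga, "group_b": gb, "t": res.t, "df": res.df,
                 "p": res.p_two_sided}
            )
    df = pd.DataFrame(rows, columns=["group_a", "group_b", "t", "df", "p"])
    if len(df) > fdr_threshold:
        df["p_adj"] = multipletests(df["p"], method="fdr_bh")[1]
    else:
        df["p_adj"] = df["p"]
    return df


def mark_counts_by_class(
    marks: Mapping[str, Iterable[str]], class_assignment: Mapping[str, str]
) -> pd.DataFrame:
    """Per class and mark: gene count and percentage of class genes marked.

    Percentages are against the explicit class sizes implied by
    ``class_assignment`` (every denominator is named in the output).
    """
    class_sizes: dict[str, int] = {}
    for cls in class_assignment.values():
        class_sizes[cls] = class_sizes.get(cls, 0) + 1
    counts: dict[tuple[str, str], int] = {}
    for gid, gene_marks in marks.items():
        cls = class_assignment.get(gid)
        if cls is None:
            continue
        for m in gene_marks:
            if m not in SUPPORTED_MARKS:
                raise ValueError(f"unsupported mark {m!r}")
            counts[(cls, m)] = counts.get((cls, m), 0) + 1
    rows = []
    for cls in sorted(class_sizes):
        for mark in sorted(SUPPORTED_MARKS):
            n = counts.get((cls, mark), 0)
            rows.append(
                {
                    "class": cls, "mark": mark, "n_class_genes": class_sizes[cls],
                    "n_marked": n,
                    "pct_marked": round(100.0 * n / class_sizes[cls], 1)
                    if class_sizes[cls] else 0.0,
                }
            )
    return pd.DataFrame(rows, columns=["class", "mark", "n_class_genes", "n_marked", "pct_marked"])


def condition_enrichment_table(
    expr: ExpressionTable,
    class_assignment: Mapping[str, str],
    conditions: Sequence[str],
    reference: str,
    fold: float = 2.0,
) -> pd.DataFrame:
    """Induced-gene counts per class and condition, with percentages of the
    class total (one row per class x condition)."""
    class_members: dict[str, set[str]] = {}
    for gid in expr.genes:
        cls = class_assignment.get(gid)
        if cls is not None:
            class_members.setdefault(cls, set()).add(gid)
    rows = []
    for condition in conditions:
        ind = induced_genes(expr, condition, reference, fold)
        for cls in sorted(class_members):
            members = class_members[cls]
            n_ind = len(members & ind)
            rows.append(
                {
                    "class": cls, "condition": condition, "n_genes": len(members),
                    "n_induced": n_ind,
                    "pct_induced": round(100.0 * n_ind / len(members), 1)
                    if members else 0.0,
                }
            )
    return pd.DataFrame(
        rows, columns=["class", "condition", "n_genes", "n_induced", "pct_induced"]
    )
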