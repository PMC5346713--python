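"""Normalization, two-group differential expression and sample clustering.

The workflow mirrors common count-panel practice (NanoString-style data):
counts are scaled per sample to a common geometric mean, log2-transformed
with a pseudocount, tested per miRNA with a two-sample t-test, and corrected
with Benjamini-Hochberg FDR.  A miRNA is called significant under the dual
threshold P < 0.01 and FDR q < 0.05.  Sample structure is inspected by
average-linkage (UPGMA) clustering on 1 - Pearson correlation distances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

from .io import (NORMALIZED_LOG2, RAW_COUNTS, ExpressionMatrix,
                 ValidationError)

ALPHA_P = 0.01
ALPHA_Q = 0.05


class NormalizationError(ValueError):
    """Raised when a sample cannot be scaled (e.g. all-zero counts)."""


def normalize_geometric_mean(raw: ExpressionMatrix,
                             pseudocount: float = 1.0) -> ExpressionMatrix:
    """Scale each sample to the cohort's common geometric mean, then log2.

    The per-sample size factor is ``f_s = G / g_s`` where ``g_s`` is the
    geometric mean of ``count + pseudocount`` over all miRNAs in sample *s*
    and ``G`` is the geometric mean of the ``g_s`` across samples.  Output
    values are ``log2(count * f_s + pseudocount)``; after rescaling, the
    vector of per-sample geometric means is constant across samples (up to
    the pseudocount).
    """
    if raw.scale != RAW_COUNTS:
        raise ValidationError("normalization expects raw counts")
    counts = raw.values.to_numpy(dtype=float)
    zero = counts.sum(axis=0) == 0
    if zero.any():
        bad = raw.values.columns[np.nonzero(zero)[0][0]]
        raise NormalizationError(f"sample {bad!r} has all-zero counts")
    log_g = np.mean(np.log(counts + pseudocount), axis=0)  # ln g_s
    factors = np.exp(np.mean(log_g) - log_g)               # G / g_s
    normalized = np.log2(counts * factors + pseudocount)
    values = pd.DataFrame(normalized, index=raw.values.index,
                          columns=raw.values.columns)
    return ExpressionMatrix(values=values, groups=raw.groups.copy(),
                            scale=NORMALIZED_LOG2)


@dataclass
class DEResult:
    """Per-miRNA two-group test result.

    ``log2fc = mean_A - mean_B`` so positive values mean "up in group A".
    ``degenerate`` marks zero pooled variance (p set to 1, never significant).
    """

    mirna_id: str
    mean_log2_a: float
    mean_log2_b: float
    log2fc: float
    t_statistic: float
    p_value: float
    fdr_q: float
    significant: bool
    degenerate: bool = False

    @property
    def direction(self) -> str:
        return "up" if self.log2fc > 0 else "down"


def differential_expression(norm: ExpressionMatrix,
                            group_a: str | None = None,
                            group_b: str | None = None,
                            alpha_p: float = ALPHA_P,
                            alpha_q: float = ALPHA_Q,
                            equal_var: bool = True) -> list[DEResult]:
    """Two-sided two-sample t-test per miRNA with BH-FDR across all miRNAs.

    Group A is the reference ("up in A" gives positive log2FC); by default the
    lexicographically first group label is A.  ``equal_var=True`` gives the
    pooled-variance Student test; set False for Welch.
    """
    if norm.scale != NORMALIZED_LOG2:
        raise ValidationError("differential expression expects normalized log2 data")
    names = norm.group_names
    if group_a is None or group_b is None:
        if len(names) != 2:
            raise ValidationError(f"expected exactly 2 groups, found {names}")
        group_a, group_b = names
    a = norm.values[norm.samples_of(group_a)].to_numpy(dtype=float)
    b = norm.values[norm.samples_of(group_b)].to_numpy(dtype=float)
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValidationError("both groups need at least 2 samples")

    t, p = stats.ttest_ind(a, b, axis=1, equal_var=equal_var)
    degenerate = (a.var(axis=1) == 0) & (b.var(axis=1) == 0)
    t = np.where(degenerate, 0.0, t)
    p = np.where(degenerate, 1.0, p)
    q = multipletests(p, method="fdr_bh")[1]
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    results = []
    for i, mid in enumerate(norm.values.index):
        sig = bool(p[i] < alpha_p and q[i] < alpha_q and not degenerate[i])
        results.append(DEResult(
            mirna_id=mid, mean_log2_a=float(mean_a[i]),
            mean_log2_b=float(mean_b[i]),
            log2fc=float(mean_a[i] - mean_b[i]),
            t_statistic=float(t[i]), p_value=float(p[i]), fdr_q=float(q[i]),
            significant=sig, degenerate=bool(degenerate[i])))
    return results


def significant_results(de: list[DEResult]) -> list[DEResult]:
    return [r for r in de if r.significant]


def top_by_fold_change(de: list[DEResult], n: int = 15,
                       direction: str = "up") -> list[DEResult]:
    """Top-n significant miRNAs per direction, ranked by |log2FC|."""
    sig = [r for r in de if r.significant and r.direction == direction]
    return sorted(sig, key=lambda r: abs(r.log2fc), reverse=True)[:n]


def de_table(de: list[DEResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.mirna_id, r.log2fc, r.t_statistic, r.p_value, r.fdr_q,
          r.significant, r.degenerate) for r in de],
        columns=["mirna", "log2fc", "t", "p", "q", "significant", "degenerate"])


@dataclass
class ClusterResult:
    """UPGMA tree over samples plus the two-cluster cut and its agreement
    with the provided group labels (label permutation minimized)."""

    linkage: np.ndarray
    assignments: pd.Series  # sample -> {1, 2}
    misclassification_count: int
    mode: str


def hierarchical_cluster(norm: ExpressionMatrix, mode: str = "unsupervised",
                         de: list[DEResult] | None = None) -> ClusterResult:
    """Average-linkage clustering of samples on d = 1 - Pearson correlation.

    Supervised mode restricts the profile to the significant miRNAs of ``de``;
    unsupervised mode uses all miRNAs.  Two clusters are obtained by cutting
    the final merge; the misclassification count is minimized over the two
    cluster-to-label pairings.
    """
    if mode not in ("unsupervised", "supervised"):
        raise ValidationError(f"unknown clustering mode {mode!r}")
    values = norm.values
    if mode == "supervised":
        if de is None:
            raise ValidationError("supervised mode requires DE results")
        keep = [r.mirna_id for r in de if r.significant]
        if len(keep) < 2:
            raise ValidationError(
                "supervised mode requires >= 2 significant miRNAs")
        values = values.loc[keep]
    profiles = values.to_numpy(dtype=float).T  # samples x miRNAs
    sds = profiles.std(axis=1)
    if (sds == 0).any():
        bad = values.columns[np.nonzero(sds == 0)[0][0]]
        raise ValidationError(
            f"sample {bad!r} has a constant profile; correlation undefined")
    corr = np.corrcoef(profiles)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    linkage = hierarchy.linkage(squareform(dist, checks=False), method="average")
    flat = hierarchy.fcluster(linkage, t=2, criterion="maxclust")
    assignments = pd.Series(flat, index=values.columns)

    labels = norm.groups.loc[values.columns]
    names = sorted(labels.unique())
    if len(names) == 2:
        mism = [(assignments.map({1: names[0], 2: names[1]}) != labels).sum(),
                (assignments.map({1: names[1], 2: names[0]}) != labels).sum()]
        misclassified = int(min(mism))
    else:  # degenerate labeling; report against majority assignment
        misclassified = int(min((assignments == 1).sum(),
                                (assignments == 2).sum()))
    return ClusterResult(linkage=linkage, assignments=assignments,
                         misclassification_count=misclassified, mode=mode)
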