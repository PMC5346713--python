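"""Clinical-pathological group comparisons and per-miRNA covariate regressions.

Continuous variables reported as mean +/- SEM are compared with the
pooled-variance Student t-test reconstructed from the summary statistics;
stage/grade distributions use the Pearson chi-square test without continuity
correction; binary follow-up variables use the two-sided Fisher exact test
(minimum-likelihood rule).  Panel miRNAs are additionally regressed on
ethnicity, age, tumor size and lymph-node status by OLS, with
Benjamini-Hochberg FDR applied per covariate across the panel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ClinicalTable, ExpressionMatrix, ValidationError

REGRESSORS = ["group", "age", "tumor_size", "ln_status"]


@dataclass(frozen=True)
class SummaryGroup:
    """A group's summary statistics as printed in a clinical table:
    mean +/- SEM with sample size."""

    mean: float
    sem: float
    n: int

    def __post_init__(self) -> None:
        if self.sem <= 0:
            raise ValidationError(f"SEM must be positive, got {self.sem}")
        if self.n < 2:
            raise ValidationError(f"group size must be >= 2, got {self.n}")

    @property
    def sd(self) -> float:
        return self.sem * np.sqrt(self.n)

    @classmethod
    def from_values(cls, values) -> "SummaryGroup":
        values = np.asarray(values, dtype=float)
        values = values[~np.isnan(values)]
        return cls(mean=float(values.mean()),
                   sem=float(values.std(ddof=1) / np.sqrt(len(values))),
                   n=len(values))


def ttest_from_summary(a: SummaryGroup,
                       b: SummaryGroup) -> tuple[float, int, float]:
    """Pooled-variance two-sided Student t-test from (mean, SEM, n)."""
    res = stats.ttest_ind_from_stats(a.mean, a.sd, a.n, b.mean, b.sd, b.n,
                                     equal_var=True)
    return float(res.statistic), a.n + b.n - 2, float(res.pvalue)


def chisq_rxc(table) -> tuple[float, int, float]:
    """Pearson chi-square on an r x c contingency table, no continuity
    correction; df = (r-1)(c-1)."""
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or min(table.shape) < 2:
        raise ValidationError("contingency table needs >= 2 rows and columns")
    if (table < 0).any():
        raise ValidationError("negative cell count")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValidationError("zero marginal row or column")
    chi2, p, df, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), int(df), float(p)


def fisher_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table, summing hypergeometric
    probabilities no larger than the observed table's.

    An empty margin makes every table equally (un)informative; p = 1 by
    convention.
    """
    table = np.asarray(table, dtype=int)
    if table.shape != (2, 2) or (table < 0).any():
        raise ValidationError("Fisher test needs a non-negative 2x2 table")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return 1.0
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


@dataclass
class RegressionResult:
    """One (miRNA, covariate) association from the panel-wide OLS fits."""

    mirna_id: str
    covariate: str
    coefficient: float
    std_error: float
    p_value: float
    fdr_q: float
    significant: bool
    n_used: int


def mirna_clinical_regression(norm: ExpressionMatrix,
                              panel_ids: list[str],
                              clinical: ClinicalTable,
                              alpha_q: float = 0.05) -> list[RegressionResult]:
    """OLS of each panel miRNA's normalized expression on clinical covariates.

    Design: intercept + group (second group label coded 1) + age +
    tumor_size + ln_status (pos coded 1).  Samples with any missing regressor
    are removed listwise.  Standard errors are heteroskedasticity-robust
    (HC3), since log2-transformed count outcomes have group- and
    abundance-dependent residual variance.  BH-FDR is applied across the
    panel separately for each covariate; tumor stage and grade are not
    modeled (degenerate in the cohorts this reproduces: no stage-I or
    grade-1 cases).
    """
    missing = [m for m in panel_ids if m not in norm.values.index]
    if missing:
        raise ValidationError(f"panel miRNAs missing from matrix: {missing}")
    samples = [s for s in norm.sample_ids if s in clinical.data.index]
    if len(samples) < len(norm.sample_ids):
        raise ValidationError("clinical table missing samples from the matrix")
    cov = clinical.data.loc[samples]
    names = sorted(norm.groups.unique())
    design = pd.DataFrame(index=samples)
    design["group"] = (norm.groups.loc[samples] == names[-1]).astype(float)
    design["age"] = pd.to_numeric(cov["age"], errors="coerce")
    design["tumor_size"] = pd.to_numeric(cov["tumor_size"], errors="coerce")
    design["ln_status"] = cov["ln_status"].map({"pos": 1.0, "neg": 0.0})
    keep = design.notna().all(axis=1)
    design = design[keep]
    n_used = int(keep.sum())
    if n_used <= len(REGRESSORS) + 1:
        raise ValidationError(
            f"only {n_used} complete samples for {len(REGRESSORS)} regressors")
    # build the constant column explicitly: add_constant would silently skip
    # it when a covariate is itself constant, hiding the rank deficiency
    x = np.column_stack([np.ones(n_used),
                         design[REGRESSORS].to_numpy(dtype=float)])
    if np.linalg.matrix_rank(x) < x.shape[1]:
        sds = design[REGRESSORS].std()
        flat = list(sds.index[sds == 0])
        raise ValidationError(f"rank-deficient design; collinear columns {flat}")

    fits = {}
    for mirna in panel_ids:
        y = norm.values.loc[mirna, design.index].to_numpy(dtype=float)
        fits[mirna] = sm.OLS(y, x).fit(cov_type="HC3")

    results: list[RegressionResult] = []
    for j, covariate in enumerate(REGRESSORS, start=1):
        raw = np.array([fits[m].pvalues[j] for m in panel_ids])
        q = multipletests(raw, method="fdr_bh")[1]
        for i, mirna in enumerate(panel_ids):
            fit = fits[mirna]
            results.append(RegressionResult(
                mirna_id=mirna, covariate=covariate,
                coefficient=float(fit.params[j]), std_error=float(fit.bse[j]),
                p_value=float(raw[i]), fdr_q=float(q[i]),
                significant=bool(q[i] < alpha_q), n_used=n_used))
    return results


def regression_table(results: list[RegressionResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.mirna_id, r.covariate, r.coefficient, r.std_error, r.p_value,
          r.fdr_q, r.significant, r.n_used) for r in results],
        columns=["mirna", "covariate", "beta", "se", "p", "q", "significant",
                 "n_used"])
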