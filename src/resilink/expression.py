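"""Differential expression between AD and control brains.

Two covariate models are fitted per gene by ordinary least squares on
normalized (log-scale) expression:

* ``simple``        — diagnosis + age at death + sex + RIN + tissue source +
  flowcell;
* ``comprehensive`` — the simple model plus the expression of five CNS
  cell-type marker genes (ENO2 neurons, GFAP astrocytes, CD68 microglia,
  OLIG2 oligodendrocytes, CD34 endothelium), absorbing cell-composition
  shifts that disease pathology induces in bulk tissue.

Diagnosis is coded control = 0, AD = 1, so a positive coefficient means
up-regulation in AD.  Multiple testing is handled with Storey q-values
(Benjamini–Hochberg for small gene sets).  A log-transform ANCOVA with age
and sex covariates is provided for replication datasets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MARKER_GENES",
    "ExpressionStudy",
    "DgeResult",
    "fit_dge",
    "qvalues",
    "ancova_replication",
]

MARKER_GENES = ("ENO2", "GFAP", "CD68", "OLIG2", "CD34")


@dataclass
class ExpressionStudy:
    """Genes x samples normalized expression with sample covariates.

    ``covariates`` must contain a ``diagnosis`` column (0/1 or control/AD);
    ``marker_channels`` (samples x 5) is required only for the comprehensive
    model.
    """

    matrix: pd.DataFrame  # genes x samples
    covariates: pd.DataFrame  # samples x covariates, includes diagnosis
    marker_channels: Optional[pd.DataFrame] = None  # samples x marker genes

    def __post_init__(self):
        if "diagnosis" not in self.covariates.columns:
            raise ValueError("covariates must include a 'diagnosis' column")
        if self.covariates["diagnosis"].isna().any():
            raise ValueError("missing diagnosis labels are not allowed")
        if list(self.matrix.columns) != list(self.covariates.index):
            raise ValueError("matrix columns and covariate rows must align")

    def diagnosis_vector(self) -> np.ndarray:
        d = self.covariates["diagnosis"]
        if d.dtype == object or str(d.dtype) == "category":
            return (d.astype(str).str.upper() == "AD").to_numpy(dtype=float)
        return d.to_numpy(dtype=float)


@dataclass
class DgeResult:
    table: pd.DataFrame  # per gene: beta, se, p, q, direction, df_resid, error

    def significant(self, q_threshold: float = 0.05) -> pd.DataFrame:
        ok = self.table[self.table["error"].isna()]
        return ok[ok["q"] < q_threshold]


def _design(study: ExpressionStudy, model: str) -> pd.DataFrame:
    cov = study.covariates.drop(columns=["diagnosis"])
    parts = [pd.Series(1.0, index=study.covariates.index, name="const"),
             pd.Series(study.diagnosis_vector(), index=study.covariates.index,
                       name="diagnosis")]
    if not cov.empty:
        parts.append(pd.get_dummies(cov, drop_first=True, dtype=float))
    if model == "comprehensive":
        if study.marker_channels is None:
            raise ValueError("comprehensive model requires marker_channels")
        mc = study.marker_channels.astype(float)
        # constant channels carry no composition signal; dropping them makes
        # the comprehensive model collapse exactly onto the simple one
        mc = mc.loc[:, mc.std(ddof=1) > 0]
        if not mc.empty:
            # standardized channels: coefficient scale is per SD of marker signal
            mc = (mc - mc.mean()) / mc.std(ddof=1)
            parts.append(mc.add_prefix("marker_"))
    elif model != "simple":
        raise ValueError(f"unknown model {model!r}")
    return pd.concat(parts, axis=1).astype(float)


def fit_dge(study: ExpressionStudy, model: str = "simple") -> DgeResult:
    """Per-gene OLS of expression on diagnosis plus covariates.

    The per-gene two-sided p comes from the diagnosis coefficient's t
    statistic on n - rank(X) residual degrees of freedom.  Genes whose fit is
    impossible (rank-deficient after adding the gene, non-finite values) are
    flagged in the ``error`` column rather than aborting the study.
    """
    X = _design(study, model).to_numpy()
    n, k = X.shape
    rank = np.linalg.matrix_rank(X)
    d = study.diagnosis_vector()
    if min((d == 1).sum(), (d == 0).sum()) < 2:
        raise ValueError("need at least 2 samples per diagnosis group")
    genes = study.matrix.index
    Y = study.matrix.to_numpy(dtype=float).T  # samples x genes
    out = pd.DataFrame(
        index=genes,
        columns=["beta", "se", "p", "q", "direction", "df_resid", "error"],
        dtype=object,
    )
    if rank < k:
        # rank-deficient design (e.g. flowcell confounded with diagnosis):
        # flag every gene, never crash
        out["error"] = "rank_deficient_design"
        out["q"] = np.nan
        return DgeResult(table=out)
    df_resid = n - rank
    XtX_inv = np.linalg.inv(X.T @ X)
    H = XtX_inv @ X.T
    j = 1  # diagnosis column
    betas = H @ Y  # k x genes
    resid = Y - X @ betas
    sigma2 = (resid**2).sum(axis=0) / df_resid
    se = np.sqrt(sigma2 * XtX_inv[j, j])
    beta_dx = betas[j]
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = beta_dx / se
    p = 2 * stats.t.sf(np.abs(tstat), df_resid)
    bad = ~np.isfinite(Y).all(axis=0) | ~np.isfinite(se) | (se == 0)
    out["beta"] = beta_dx
    out["se"] = se
    out["p"] = p
    out["direction"] = np.where(beta_dx > 0, "UpInAD", "DownInAD")
    out["df_resid"] = df_resid
    out.loc[bad, "error"] = "degenerate_fit"
    out.loc[~bad, "error"] = None
    out["error"] = out["error"].where(out["error"].notna(), None)
    ok = ~bad
    q = np.full(len(genes), np.nan)
    if ok.any():
        q[ok] = qvalues(p[ok])
    out["q"] = q
    return DgeResult(table=out)


def qvalues(p_list: Sequence[float], method: str = "storey",
            lambdas: Optional[np.ndarray] = None) -> np.ndarray:
    """FDR q-values; Storey's pi0 estimate with a smoothed lambda grid.

    Falls back to Benjamini–Hochberg (pi0 = 1) for small input lists, where
    the pi0 spline is unstable, or when ``method='bh'``.  Output is invariant
    to input order and monotone in ranked p.
    """
    p = np.asarray(p_list, dtype=float)
    if p.size == 0:
        return np.array([])
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    m = p.size
    pi0 = 1.0
    if method == "storey" and m >= 100:
        lam = np.arange(0.0, 0.96, 0.05) if lambdas is None else np.asarray(lambdas)
        pi0_lam = np.array([(p > l).mean() / (1 - l) for l in lam])
        # cubic smoother in lambda, evaluated at the largest lambda
        coef = np.polyfit(lam, pi0_lam, 3)
        pi0 = float(np.clip(np.polyval(coef, lam.max()), 0.0, 1.0))
        if pi0 <= 0:
            pi0 = 1.0
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    q_ranked = pi0 * m * ranked / np.arange(1, m + 1)
    q_ranked = np.minimum.accumulate(q_ranked[::-1])[::-1]
    q_ranked = np.clip(q_ranked, 0.0, 1.0)
    q = np.empty(m)
    q[order] = q_ranked
    return q


def ancova_replication(
    expression: Sequence[float],
    diagnosis: Sequence[int],
    age: Sequence[float],
    sex: Sequence[int],
    log_offset: Optional[float] = None,
) -> tuple[float, float]:
    """Log-transform ANCOVA for replication datasets; returns (beta, p).

    Expression is log-transformed to approximate normality, then regressed on
    diagnosis with age and sex covariates; the diagnosis contrast is reported.
    Nonpositive values require an explicit ``log_offset``.
    """
    x = np.asarray(expression, dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("constant expression: no test")
    if log_offset is not None:
        x = x + log_offset
    if np.any(x <= 0):
        raise ValueError(
            "nonpositive expression values: supply log_offset to shift before the log"
        )
    ylog = np.log(x)
    cols = [np.ones_like(ylog), np.asarray(diagnosis, dtype=float)]
    # constant covariates are dropped so the model nests cleanly down to a
    # two-sample comparison
    for c in (np.asarray(age, dtype=float), np.asarray(sex, dtype=float)):
        if np.ptp(c) > 0:
            cols.append(c)
    X = np.column_stack(cols)
    beta, *_ = np.linalg.lstsq(X, ylog, rcond=None)
    resid = ylog - X @ beta
    df = len(ylog) - np.linalg.matrix_rank(X)
    sigma2 = (resid**2).sum() / df
    cov = sigma2 * np.linalg.inv(X.T @ X)
    t = beta[1] / np.sqrt(cov[1, 1])
    p = 2 * stats.t.sf(abs(t), df)
    return float(beta[1]), float(p)
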