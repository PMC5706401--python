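"""Case-control association with a one-sided protective alternative, and a
gene-based rare-variant test of the SKAT-O family with a permutation null.

The single-variant path is an additive-coding logistic regression of AD status
on genotype with age, sex and site covariates; because the design searches for
protective alleles, the reported p is the one-sided lower-tail probability
p = Phi(beta / SE), small only when the minor allele reduces risk.

The gene-based statistic mixes a burden and a variance-component (kernel)
score over a grid of mixing weights rho,

    Q_rho = (1 - rho) * sum_j w_j^2 s_j^2 + rho * (sum_j w_j s_j)^2,

with s_j the per-variant score G_j . (y - mu_0) from the covariate-only null
model and w_j Beta(MAF; 1, 25) density weights.  The observed statistic is the
minimum over rho of the permutation p of Q_rho; its overall significance is
calibrated by permuting the null-model residuals and recomputing the min-p
statistic each round, so no quadratic-form tail approximation is needed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "AssociationResult",
    "GeneTestResult",
    "MonomorphicError",
    "SeparationError",
    "allelic_or",
    "logistic_assoc",
    "gene_test",
    "beta_maf_weights",
    "DEFAULT_RHO_GRID",
]

DEFAULT_RHO_GRID = (0.0, 0.01, 0.04, 0.09, 0.16, 0.25, 0.5, 1.0)


class MonomorphicError(ValueError):
    """Genotype has no variation; no test is possible."""


class SeparationError(RuntimeError):
    """Perfect separation in the logistic fit; consider the ridge fallback."""


@dataclass
class AssociationResult:
    id: str
    beta: float  # log-odds per minor allele
    se: float
    or_: float
    ci95: tuple[float, float]
    p_one_sided: float
    n_case: int
    n_control: int
    maf_case: float
    maf_control: float
    zero_cell_corrected: bool = False


def allelic_or(
    case_alt: float, case_ref: float, control_alt: float, control_ref: float,
    variant_id: str = "",
) -> AssociationResult:
    """Crude allelic odds ratio from a 2x2 allele-count table with Woolf CI.

    Zero cells receive the Haldane–Anscombe 0.5 correction (flagged).  A fully
    empty margin is undefined and raises.
    """
    counts = np.array([case_alt, case_ref, control_alt, control_ref], dtype=float)
    if np.any(counts < 0):
        raise ValueError("allele counts must be nonnegative")
    if case_alt + case_ref == 0 or control_alt + control_ref == 0 or \
            case_alt + control_alt == 0 and case_ref + control_ref == 0:
        raise ValueError("a margin of the 2x2 table is empty; OR undefined")
    corrected = bool(np.any(counts == 0))
    if corrected:
        counts = counts + 0.5
    a, b, c, d = counts
    or_ = (a / b) / (c / d)
    se = float(np.sqrt(1 / a + 1 / b + 1 / c + 1 / d))
    beta = float(np.log(or_))
    lo, hi = np.exp(beta - 1.96 * se), np.exp(beta + 1.96 * se)
    p = float(stats.norm.cdf(beta / se))  # one-sided, protective direction
    n_case_alleles = case_alt + case_ref
    n_control_alleles = control_alt + control_ref
    return AssociationResult(
        id=variant_id,
        beta=beta,
        se=se,
        or_=float(or_),
        ci95=(float(lo), float(hi)),
        p_one_sided=p,
        n_case=int(round(n_case_alleles / 2)),
        n_control=int(round(n_control_alleles / 2)),
        maf_case=case_alt / n_case_alleles if n_case_alleles else float("nan"),
        maf_control=control_alt / n_control_alleles if n_control_alleles else float("nan"),
        zero_cell_corrected=corrected,
    )


def _maf(genotypes: np.ndarray) -> float:
    return float(np.mean(genotypes) / 2.0)


def logistic_assoc(
    genotypes: Sequence[int],
    phenotype: Sequence[int],
    covariates: Optional[pd.DataFrame] = None,
    variant_id: str = "",
    ridge: Optional[float] = None,
) -> AssociationResult:
    """Additive-coding logistic regression with a one-sided protective p.

    ``phenotype`` is 0 = control, 1 = case; ``covariates`` typically holds
    age, sex and site (categoricals are dummy-coded by the caller or passed as
    pandas categoricals).  The fit is maximum likelihood via iteratively
    reweighted least squares.  Detected separation raises
    :class:`SeparationError` unless a ridge penalty is supplied.
    """
    g = np.asarray(genotypes, dtype=float)
    y = np.asarray(phenotype, dtype=float)
    if g.std() == 0:
        raise MonomorphicError(f"variant {variant_id or '<unnamed>'} is monomorphic")
    if y.min() == y.max():
        raise ValueError("need at least one case and one control")
    # minor-allele orientation from controls: the reported effect is per minor
    # allele, so a majority coded allele is flipped before fitting
    if g[y == 0].mean() / 2.0 > 0.5:
        g = 2.0 - g
    X = pd.DataFrame({"genotype": g})
    if covariates is not None:
        cov = pd.get_dummies(covariates.reset_index(drop=True), drop_first=True, dtype=float)
        X = pd.concat([X, cov], axis=1)
    X = sm.add_constant(X.astype(float), has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            if ridge is not None:
                fit = sm.Logit(y, X).fit_regularized(
                    alpha=ridge, L1_wt=0.0, disp=0, maxiter=200
                )
                # refit-free SE from the penalized information matrix
                res = sm.Logit(y, X).fit(disp=0, start_params=fit.params, maxiter=0)
                params, bse = fit.params, res.bse
            else:
                res = sm.Logit(y, X).fit(disp=0, maxiter=100)
                params, bse = res.params, res.bse
        except Exception as exc:  # statsmodels raises PerfectSeparation variants
            raise SeparationError(
                f"logistic fit failed ({exc}); retry with ridge=<penalty>"
            ) from exc
    beta = float(params["genotype"])
    se = float(bse["genotype"])
    if not np.isfinite(beta) or not np.isfinite(se) or abs(beta) > 30:
        raise SeparationError(
            "separation detected (diverging genotype coefficient); "
            "retry with ridge=<penalty>"
        )
    p = float(stats.norm.cdf(beta / se))
    case = y == 1
    return AssociationResult(
        id=variant_id,
        beta=beta,
        se=se,
        or_=float(np.exp(beta)),
        ci95=(float(np.exp(beta - 1.96 * se)), float(np.exp(beta + 1.96 * se))),
        p_one_sided=p,
        n_case=int(case.sum()),
        n_control=int((~case).sum()),
        maf_case=_maf(g[case]),
        maf_control=_maf(g[~case]),
    )


# -- gene-based test ----------------------------------------------------------


def beta_maf_weights(mafs: np.ndarray, a: float = 1.0, b: float = 25.0) -> np.ndarray:
    """Beta(1, 25) density weights on minor allele frequency (SKAT convention)."""
    mafs = np.clip(np.asarray(mafs, dtype=float), 1e-12, 1 - 1e-12)
    return stats.beta.pdf(mafs, a, b)


@dataclass
class GeneTestResult:
    gene: str
    q_rho: dict[float, float]
    rho_grid: tuple[float, ...]
    statistic: float  # min over rho of the permutation p of Q_rho
    best_rho: float
    p_permutation: float
    n_permutations: int
    seed: int
    n_variants: int = 0


def gene_test(
    genotypes: np.ndarray,
    phenotype: Sequence[int],
    covariates: Optional[pd.DataFrame] = None,
    rho_grid: Sequence[float] = DEFAULT_RHO_GRID,
    weights: Optional[np.ndarray] = None,
    n_perm: int = 1000,
    seed: int = 0,
    gene: str = "",
) -> GeneTestResult:
    """Burden/kernel combined gene test with a permutation min-p null.

    ``genotypes`` is (n_samples, n_variants) additive dosages.  Monomorphic
    variants are dropped; if none remain the test is refused.  The permutation
    p honors its lower bound 1 / (n_perm + 1).
    """
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives a very coarse permutation p")
    G = np.asarray(genotypes, dtype=float)
    y = np.asarray(phenotype, dtype=float)
    poly = G.std(axis=0) > 0
    if not poly.any():
        raise MonomorphicError("all variants in the gene are monomorphic")
    G = G[:, poly]
    X = np.ones((len(y), 1))
    if covariates is not None:
        cov = pd.get_dummies(covariates.reset_index(drop=True), drop_first=True, dtype=float)
        X = np.column_stack([X, cov.to_numpy(dtype=float)])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        null = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    resid = y - null.fittedvalues
    if weights is None:
        w = beta_maf_weights(G.mean(axis=0) / 2.0)
    else:
        w = np.asarray(weights, dtype=float)[poly]

    rho_grid = tuple(float(r) for r in rho_grid)
    rng = np.random.default_rng(seed)
    perms = np.empty((n_perm + 1, len(y)), dtype=float)
    perms[0] = resid
    for i in range(1, n_perm + 1):
        perms[i] = resid[rng.permutation(len(y))]
    S = perms @ G  # (n_perm+1, n_variants) score vectors
    ws = S * w
    kernel = (ws**2).sum(axis=1)  # rho = 0 component
    burden = ws.sum(axis=1) ** 2  # rho = 1 component
    rhos = np.asarray(rho_grid)
    Q = (1 - rhos[:, None]) * kernel[None, :] + rhos[:, None] * burden[None, :]
    # per-rho permutation p for every row (observed is row 0), computed by rank
    order = np.argsort(-Q, axis=1, kind="stable")
    ranks = np.empty_like(order)
    rows = np.arange(Q.shape[0])[:, None]
    ranks[rows, order] = np.arange(Q.shape[1])[None, :]
    p_rho = (ranks + 1) / (n_perm + 1)  # P(Q_perm >= Q) including self
    minp = p_rho.min(axis=0)  # per row: min over rho
    obs = minp[0]
    p_final = float((1 + np.sum(minp[1:] <= obs)) / (n_perm + 1))
    best = int(np.argmin(p_rho[:, 0]))
    return GeneTestResult(
        gene=gene,
        q_rho={r: float(q) for r, q in zip(rho_grid, Q[:, 0])},
        rho_grid=rho_grid,
        statistic=float(obs),
        best_rho=rho_grid[best],
        p_permutation=p_final,
        n_permutations=n_perm,
        seed=seed,
        n_variants=int(poly.sum()),
    )
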