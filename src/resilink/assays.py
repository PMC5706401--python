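"""Statistics for the in-vitro validation assays.

Covers LDH-release cytotoxicity percentages, efficiency-corrected comparative
threshold-cycle (ddCt) relative expression with the 20% replicate-variability
exclusion, ELISA normalization to total protein, and group comparison by
one-way ANOVA gated Bonferroni-corrected t-tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "LdhMeasurement",
    "QpcrCondition",
    "cytotoxicity_pct",
    "ddct_relative_expression",
    "elisa_normalize",
    "group_compare",
    "GroupCompareResult",
]


@dataclass(frozen=True)
class LdhMeasurement:
    """Transfected / spontaneous / maximum LDH absorbances for one well set."""

    transfected: float
    spontaneous: float
    maximum: float


def cytotoxicity_pct(m: LdhMeasurement) -> float:
    """((transfected - spontaneous) / (maximum - spontaneous)) x 100."""
    if m.maximum <= m.spontaneous:
        raise ValueError("maximum LDH must exceed spontaneous LDH")
    return (m.transfected - m.spontaneous) / (m.maximum - m.spontaneous) * 100.0


@dataclass
class QpcrCondition:
    """Replicate Ct readings for target and housekeeping assays in one condition."""

    target_ct: Sequence[float]
    housekeeping_ct: Sequence[float]


def _mean_se_cv(ct: np.ndarray) -> tuple[float, float, float]:
    mean = float(np.mean(ct))
    se = float(np.std(ct, ddof=1) / np.sqrt(len(ct))) if len(ct) > 1 else 0.0
    cv = se / abs(mean) if mean else float("inf")
    return mean, se, cv


def ddct_relative_expression(
    treated: QpcrCondition,
    control: QpcrCondition,
    efficiency: float = 2.0,
    max_replicate_cv: float = 0.20,
) -> tuple[float, float]:
    """Comparative-Ct fold change of treated vs control; returns (fold, SE).

    Per condition, dCt = mean(target Ct) - mean(housekeeping Ct); the fold
    change is efficiency^(-ddCt) with ddCt = dCt_treated - dCt_control, so a
    doubling-per-cycle assay (efficiency 2) maps ddCt = 1 to fold 0.5.  The SE
    is the delta-method propagation of the four replicate-mean variances.
    Conditions whose replicate Ct standard error exceeds ``max_replicate_cv``
    of the mean are excluded; if either condition is excluded there is no
    result.
    """
    if not 1.0 < efficiency <= 2.0:
        raise ValueError("amplification efficiency must lie in (1, 2]")
    stats_ = []
    for cond in (treated, control):
        for ct in (np.asarray(cond.target_ct, float), np.asarray(cond.housekeeping_ct, float)):
            if ct.size == 0:
                raise ValueError("each condition needs at least one well")
            if np.any(ct <= 0):
                raise ValueError("Ct values must be positive")
            mean, se, cv = _mean_se_cv(ct)
            if cv > max_replicate_cv:
                raise ValueError(
                    "replicate Ct standard error exceeds the "
                    f"{max_replicate_cv:.0%} exclusion rule: no result"
                )
            stats_.append((mean, se))
    (t_mean, t_se), (h_mean, h_se), (ct_mean, ct_se), (ch_mean, ch_se) = stats_
    ddct = (t_mean - h_mean) - (ct_mean - ch_mean)
    fold = efficiency ** (-ddct)
    var_ddct = t_se**2 + h_se**2 + ct_se**2 + ch_se**2
    se_fold = abs(fold * np.log(efficiency)) * np.sqrt(var_ddct)
    return float(fold), float(se_fold)


def elisa_normalize(analyte_pg_per_ml: float, protein_ug_per_ml: float) -> float:
    """Analyte corrected for total intracellular protein, in pg/ug."""
    if protein_ug_per_ml <= 0:
        raise ValueError("total protein must be positive")
    if analyte_pg_per_ml < 0:
        raise ValueError("analyte concentration must be nonnegative")
    return analyte_pg_per_ml / protein_ug_per_ml


@dataclass
class GroupCompareResult:
    anova_p: float
    anova_f: float
    pairwise: dict[str, float]  # group -> Bonferroni-adjusted t-test p vs control
    gated: bool  # True when pairwise tests were skipped (ANOVA p >= alpha)


def group_compare(
    groups: dict[str, Sequence[float]],
    control: Optional[str] = None,
    alpha: float = 0.05,
    all_pairs: bool = False,
) -> GroupCompareResult:
    """One-way ANOVA with gated Bonferroni-corrected pairwise t-tests.

    Pairwise (equal-variance) t-tests run only when the ANOVA rejects at
    ``alpha``; by default each treatment is compared against ``control`` (the
    first group if unspecified), with the Bonferroni multiplier equal to the
    number of comparisons performed and adjusted p capped at 1.
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least two groups")
    arrays = {n: np.asarray(groups[n], dtype=float) for n in names}
    for n, a in arrays.items():
        if a.size < 2:
            raise ValueError(f"group {n!r} has fewer than 2 replicates: no test")
    f, p = stats.f_oneway(*arrays.values())
    if not np.isfinite(p):  # identical constant groups
        f, p = 0.0, 1.0
    if p >= alpha:
        return GroupCompareResult(anova_p=float(p), anova_f=float(f), pairwise={}, gated=True)
    control = control or names[0]
    if all_pairs:
        pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1 :]]
    else:
        pairs = [(control, n) for n in names if n != control]
    m = len(pairs)
    pairwise = {}
    for a, b in pairs:
        _, praw = stats.ttest_ind(arrays[a], arrays[b], equal_var=True)
        key = b if a == control and not all_pairs else f"{a}_vs_{b}"
        pairwise[key] = min(1.0, float(praw) * m)
    return GroupCompareResult(anova_p=float(p), anova_f=float(f), pairwise=pairwise, gated=False)
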