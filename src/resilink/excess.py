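"""Familial excess-AD-mortality statistics on genealogies.

Individuals are stratified into cohorts by birth year (5-year blocks), sex and
birth place; the cohort-specific AD death rate is the proportion of cohort
members whose death certificate carries an AD code.  A pedigree's expected AD
deaths E is the sum over cohorts of (descendants in cohort) x (cohort rate);
the relative risk is RR = O / E and the one-sided excess test treats the
observed count O as Poisson with mean E:

    p = P(X >= O),  X ~ Poisson(E)

which is an approximation to the sum of per-cohort binomials and conservative
for common phenotypes.  Pedigrees with RR > 1 and p below a configurable
significance cut are flagged high-risk; study pedigrees additionally require
minimum counts of resilient individuals and AD cases.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .pedigree import Individual, Pedigree

__all__ = [
    "CohortTable",
    "PedigreeRiskResult",
    "assign_cohorts",
    "cohort_rates",
    "expected_ad_deaths",
    "observed_ad_deaths",
    "poisson_tail",
    "excess_risk_test",
    "evaluate_pedigrees",
    "select_study_pedigrees",
]

UNASSIGNED = ("unassigned", "unassigned", "unassigned")


def assign_cohorts(individuals: Iterable[Individual]) -> dict[str, tuple]:
    """Stratum label (5-year birth block, sex, birth place) per individual id.

    Individuals with unknown birth year go to an explicit ``unassigned``
    bucket; they never enter rate denominators or expectations.
    """
    labels = {}
    for ind in individuals:
        if ind.birth_year is None:
            labels[ind.id] = UNASSIGNED
        else:
            block = 5 * (ind.birth_year // 5)
            labels[ind.id] = ((block, block + 4), ind.sex, ind.birth_place)
    return labels


@dataclass
class CohortTable:
    """Per-stratum member counts, AD death counts and death rates."""

    strata: dict[tuple, dict]  # label -> {n_members, n_ad_deaths, rate, zero_denominator}
    n_unassigned: int = 0

    def rate(self, label: tuple) -> float:
        return self.strata[label]["rate"]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for label, d in self.strata.items():
            block, sex, place = label
            rows.append(
                {
                    "birth_block": f"{block[0]}-{block[1]}" if isinstance(block, tuple) else block,
                    "sex": sex,
                    "birth_place": place,
                    "n_members": d["n_members"],
                    "n_ad_deaths": d["n_ad_deaths"],
                    "rate": d["rate"],
                }
            )
        return pd.DataFrame(rows)


def cohort_rates(population: Iterable[Individual]) -> CohortTable:
    """Cohort-specific AD death rates over the whole genealogy population."""
    population = list(population)
    labels = assign_cohorts(population)
    strata: dict[tuple, dict] = {}
    n_unassigned = 0
    for ind in population:
        label = labels[ind.id]
        if label == UNASSIGNED:
            n_unassigned += 1
            continue
        d = strata.setdefault(label, {"n_members": 0, "n_ad_deaths": 0})
        d["n_members"] += 1
        d["n_ad_deaths"] += int(ind.ad_death)
    for d in strata.values():
        d["zero_denominator"] = d["n_members"] == 0
        d["rate"] = 0.0 if d["zero_denominator"] else d["n_ad_deaths"] / d["n_members"]
    return CohortTable(strata=strata, n_unassigned=n_unassigned)


def expected_ad_deaths(
    ped: Pedigree, rates: CohortTable, include_marry_ins: bool = False
) -> float:
    """E = sum over cohorts of (pedigree descendants in cohort) x cohort rate."""
    members = [ped[i] for i in ped.descendant_ids(include_marry_ins)]
    labels = assign_cohorts(members)
    e = 0.0
    for ind in members:
        label = labels[ind.id]
        if label == UNASSIGNED:
            continue
        if label not in rates.strata:
            raise KeyError(
                f"descendant {ind.id} falls in stratum {label} absent from the cohort table"
            )
        e += rates.rate(label)
    return e


def observed_ad_deaths(ped: Pedigree, include_marry_ins: bool = False) -> int:
    """O = descendants with an AD code on the death certificate (known birth year)."""
    return sum(
        1
        for i in ped.descendant_ids(include_marry_ins)
        if ped[i].ad_death and ped[i].birth_year is not None
    )


def poisson_tail(observed: int, expected: float) -> float:
    """P(X >= O) for X ~ Poisson(E); O = 0 gives exactly 1."""
    if observed < 0 or expected < 0:
        raise ValueError("observed and expected must be nonnegative")
    if observed == 0:
        return 1.0
    return float(stats.poisson.sf(observed - 1, expected))


@dataclass
class PedigreeRiskResult:
    pedigree_id: str
    observed: int
    expected: float
    rr: float  # O/E; nan when E == 0
    p_one_sided: float
    high_risk: bool
    degenerate: bool = False  # E == 0 with O > 0


def excess_risk_test(
    observed: int, expected: float, pedigree_id: str = "", alpha: float = 0.05
) -> PedigreeRiskResult:
    """One-sided Poisson test of RR > 1 for a pedigree's AD death count."""
    if observed < 0 or expected < 0:
        raise ValueError("observed and expected must be nonnegative")
    degenerate = expected == 0 and observed > 0
    rr = observed / expected if expected > 0 else float("nan")
    p = 0.0 if degenerate else poisson_tail(observed, expected)
    if observed == 0:
        p = 1.0
    high_risk = (expected > 0 and rr > 1.0 or degenerate) and p < alpha
    return PedigreeRiskResult(
        pedigree_id=pedigree_id,
        observed=observed,
        expected=expected,
        rr=rr,
        p_one_sided=p,
        high_risk=high_risk,
        degenerate=degenerate,
    )


def evaluate_pedigrees(
    pedigrees: Sequence[Pedigree],
    rates: CohortTable,
    alpha: float = 0.05,
    bonferroni: bool = False,
) -> list[PedigreeRiskResult]:
    """Excess-risk test per pedigree against population cohort rates.

    No correction across pedigrees by default; ``bonferroni`` divides alpha by
    the number of pedigrees tested.
    """
    a = alpha / len(pedigrees) if bonferroni and pedigrees else alpha
    out = []
    for ped in pedigrees:
        o = observed_ad_deaths(ped)
        e = expected_ad_deaths(ped, rates)
        out.append(excess_risk_test(o, e, pedigree_id=ped.pedigree_id, alpha=a))
    return out


def select_study_pedigrees(
    results: Sequence[PedigreeRiskResult],
    pedigrees: Sequence[Pedigree],
    min_resilient: int = 4,
    min_cases: int = 4,
) -> list[str]:
    """High-risk pedigrees with at least ``min_resilient`` resilient members and
    ``min_cases`` AD cases, ranked by ascending excess-risk p."""
    by_id = {p.pedigree_id: p for p in pedigrees}
    eligible = []
    for res in results:
        if not res.high_risk:
            continue
        ped = by_id[res.pedigree_id]
        n_res = sum(1 for i in ped.members.values() if i.phenotype == "resilient")
        n_case = sum(1 for i in ped.members.values() if i.phenotype == "case")
        if n_res >= min_resilient and n_case >= min_cases:
            eligible.append(res)
    eligible.sort(key=lambda r: r.p_one_sided)
    return [r.pedigree_id for r in eligible]


def results_frame(results: Sequence[PedigreeRiskResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "pedigree_id": [r.pedigree_id for r in results],
            "observed": [r.observed for r in results],
            "expected": [r.expected for r in results],
            "rr": [r.rr for r in results],
            "p_one_sided": [r.p_one_sided for r in results],
            "high_risk": [r.high_risk for r in results],
        }
    )
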