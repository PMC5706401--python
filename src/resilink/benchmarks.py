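"""End-to-end validation benchmarks run by the acceptance machinery.

Each function regenerates its inputs from the synthetic-data module (or the
bundled candidate-variant table), runs the corresponding pipeline stage, and
returns a scalar summary.  Problem sizes are chosen to finish at desk scale;
the methods note records them.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats

from .assays import LdhMeasurement, QpcrCondition, cytotoxicity_pct, ddct_relative_expression
from .assoc import allelic_or, gene_test, logistic_assoc
from .datasets import candidate_variants
from .excess import cohort_rates, evaluate_pedigrees, poisson_tail
from .expression import fit_dge
from .linkage import (
    Marker,
    MarkerMap,
    TraitModel,
    enumerate_two_locus_loglik,
    pedigree_loglik,
    scan,
    two_point_tlod,
)
from .pedigree import Individual, Pedigree
from .simulate import (
    ExpressionEffectSpec,
    LinkageSimSpec,
    PopulationSpec,
    gen_case_control,
    gen_expression,
    gen_linkage_genotypes,
    gen_population,
    gen_variant_table,
)
from .variants import apply_filter_cascade

FULLY_PENETRANT = TraitModel(disease_allele_freq=0.005, penetrance_carrier=1.0,
                             penetrance_noncarrier=0.0)


def _subseeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31 - 1) for s in ss.generate_state(n)]


# -- pedigree factories --------------------------------------------------------


def branching_pedigree(n_branches: int, kids_per: int) -> Pedigree:
    mem = [Individual(id="F0", sex="male"), Individual(id="M0", sex="female")]
    for b in range(n_branches):
        cs = "male" if b % 2 == 0 else "female"
        mem.append(Individual(id=f"B{b}", father_id="F0", mother_id="M0", sex=cs))
        mem.append(Individual(id=f"S{b}", sex="female" if cs == "male" else "male",
                              is_marry_in=True))
        for k in range(kids_per):
            fa, mo = (f"B{b}", f"S{b}") if cs == "male" else (f"S{b}", f"B{b}")
            mem.append(Individual(id=f"K{b}_{k}", father_id=fa, mother_id=mo,
                                  sex="male" if k % 2 == 0 else "female"))
    return Pedigree("BENCH", mem)


def random_pedigree(n_members: int, seed: int) -> Pedigree:
    rng = np.random.default_rng(seed)
    mem = [Individual(id="A", sex="male"), Individual(id="B", sex="female")]
    couples = [("A", "B")]
    i = 2
    while len(mem) < n_members:
        fa, mo = couples[rng.integers(len(couples))]
        c = Individual(id=f"I{i}", father_id=fa, mother_id=mo,
                       sex="male" if rng.random() < 0.5 else "female")
        mem.append(c)
        i += 1
        if len(mem) < n_members and rng.random() < 0.5:
            sp = Individual(id=f"I{i}", sex="female" if c.sex == "male" else "male",
                            is_marry_in=True)
            mem.append(sp)
            i += 1
            couples.append((c.id, sp.id) if c.sex == "male" else (sp.id, c.id))
    return Pedigree(f"R{seed}", mem)


# -- filter-cascade worked example --------------------------------


def candidate_cascade_retained() -> int:
    """Candidate variants retained by the cascade out of the encoded eight."""
    variants = candidate_variants()
    _, retained = apply_filter_cascade(
        variants, resilient_ids=("R1", "R2", "R3", "R4"), case_ids=())
    return len(retained)


# -- Poisson excess-risk ------------------------------------------


def poisson_tail_max_abs_error() -> float:
    """Max |tail - oracle| over E <= 50, O <= 100 against a pmf accumulation."""
    worst = 0.0
    for e in np.arange(0.5, 50.5, 0.5):
        term = math.exp(-e)
        cum = term
        for o in range(1, 101):
            worst = max(worst, abs(poisson_tail(o, e) - (1 - cum)))
            term *= e / o
            cum += term
    return worst


def excess_null_type1(seed: int, n_pedigrees: int = 1000,
                      alpha: float = 0.05) -> dict[str, float]:
    """Null rejection rate of the one-sided Poisson excess test.

    Returns the empirical fraction of unspiked pedigrees with p < alpha
    together with the test's mean exact size: the one-sided Poisson test is
    discrete, so its achieved size sits below the nominal level by an amount
    that depends on each pedigree's expected count E.  Calibration means the
    empirical rate matches the exact size (and never exceeds nominal).
    """
    spec = PopulationSpec(n_pedigrees=n_pedigrees, generations=6, mean_offspring=2.7,
                          base_ad_rate_by_cohort=0.05, seed=seed)
    peds, _ = gen_population(spec)
    pool = [i for p in peds for i in p.members.values()]
    rates = cohort_rates(pool)
    results = evaluate_pedigrees(peds, rates, alpha=alpha)
    rate = float(np.mean([r.p_one_sided < alpha for r in results]))
    sizes = []
    for r in results:
        # exact size at this E: P(X >= o*) for the smallest o* rejecting
        o_grid = np.arange(0, max(20, int(r.expected * 3) + 20))
        tails = stats.poisson.sf(o_grid - 1, r.expected) if r.expected > 0 else None
        if tails is None:
            sizes.append(0.0)
            continue
        rejecting = tails < alpha
        sizes.append(float(tails[rejecting][0]) if rejecting.any() else 0.0)
    return {"empirical": rate, "exact_size": float(np.mean(sizes)),
            "n": n_pedigrees}


# -- linkage exactness --------------------------------------------


def tlod_ten_meioses() -> float:
    """TLOD of 10 phase-known non-recombinant meioses at theta 0 (10 log10 2)."""
    mem = [
        Individual(id="GF", sex="male", affection="affected", genotypes=[(2, 2)]),
        Individual(id="GM", sex="female", affection="unaffected", genotypes=[(1, 1)]),
        Individual(id="P", father_id="GF", mother_id="GM", sex="male",
                   affection="affected", genotypes=[(1, 2)]),
        Individual(id="S", sex="female", affection="unaffected", genotypes=[(1, 1)]),
    ]
    for i in range(10):
        mem.append(Individual(id=f"C{i}", father_id="P", mother_id="S",
                              affection="affected", genotypes=[(1, 2)]))
    ped = Pedigree("PK", mem)
    genos = {iid: ind.genotypes[0] for iid, ind in ped.members.items()}
    tlod, _ = two_point_tlod(ped, genos, FULLY_PENETRANT, [0.8, 0.2])
    return float(tlod)


def peeling_vs_enumeration_max_rel_error(seed: int, n_cases: int = 100) -> float:
    """Max relative disagreement between peeling and brute-force enumeration."""
    model = TraitModel(0.1, 0.8, 0.05)
    worst = 0.0
    for s in _subseeds(seed, n_cases):
        rng = np.random.default_rng(s)
        ped = random_pedigree(int(rng.integers(3, 9)), s)
        spec = LinkageSimSpec(trait_model=model, marker_alt_freqs=[0.35],
                              theta_to_trait=[float(rng.uniform(0, 0.5))], seed=s)
        gen_linkage_genotypes(ped, spec)
        genos = {iid: ind.genotypes[0] for iid, ind in ped.members.items()}
        theta = float(rng.choice([0.0, 0.05, 0.2, 0.35, 0.5]))
        a = pedigree_loglik(ped, genos, model, [0.65, 0.35], theta)[0]
        b = enumerate_two_locus_loglik(ped, genos, model, [0.65, 0.35], theta)
        if np.isinf(a) and np.isinf(b):
            continue
        worst = max(worst, abs(a - b) / abs(b))
    return worst


def lod_at_half_max_abs(seed: int, n_cases: int = 20) -> float:
    """Max |TLOD| when the grid pins theta at 0.5 (must be exactly 0)."""
    model = TraitModel(0.1, 0.8, 0.05)
    worst = 0.0
    for s in _subseeds(seed + 1, n_cases):
        ped = random_pedigree(8, s)
        spec = LinkageSimSpec(trait_model=model, marker_alt_freqs=[0.4],
                              theta_to_trait=[0.1], seed=s)
        gen_linkage_genotypes(ped, spec)
        genos = {iid: ind.genotypes[0] for iid, ind in ped.members.items()}
        tlod, _ = two_point_tlod(ped, genos, model, [0.6, 0.4], theta_grid=[0.5])
        worst = max(worst, abs(tlod))
    return worst


# -- linkage calibration and power --------------------------------


def _scan_pedigree(seed: int, n_markers: int, linked_idx: int | None,
                   branches: int = 4, kids: int = 3):
    """Gene-drop a branching pedigree; returns (pedigree, marker map, truth)."""
    thetas = [0.5] * n_markers
    if linked_idx is not None:
        thetas[linked_idx] = 0.01
    ped = branching_pedigree(branches, kids)
    spec = LinkageSimSpec(trait_model=FULLY_PENETRANT,
                          marker_alt_freqs=[0.5] * n_markers,
                          theta_to_trait=thetas,
                          carriers_seeded_in=["F0"], seed=seed)
    _, truth = gen_linkage_genotypes(ped, spec)
    mmap = MarkerMap([Marker(f"m{j}", "2", 10_000 * (j + 1)) for j in range(n_markers)])
    return ped, mmap, truth


def null_scan_significant_fraction(seed: int, n_rep: int = 200,
                                   n_markers: int = 100) -> float:
    """Fraction of unlinked scans whose max TLOD exceeds 3.30."""
    hits = 0
    for s in _subseeds(seed + 2, n_rep):
        ped, mmap, _ = _scan_pedigree(s, n_markers, linked_idx=None)
        prof = scan(ped, mmap, FULLY_PENETRANT)
        hits += prof.max_tlod > 3.30
    return hits / n_rep


def _informative_meioses(ped: Pedigree, truth, marker_idx: int) -> int:
    """Meioses from parents heterozygous at both the trait and the marker."""
    def doubly_het(iid):
        if iid is None:
            return False
        g = ped[iid].genotypes[marker_idx]
        return truth.loc[iid, "n_disease_alleles"] == 1 and g[0] != g[1]

    n = 0
    for iid in ped.members:
        f, m = ped.parents_of(iid)
        n += doubly_het(f) + doubly_het(m)
    return n


def linked_scan_localization_rate(seed: int, n_rep: int = 100,
                                  n_markers: int = 30) -> float:
    """Fraction of linked scans whose 1-LOD interval covers the true locus.

    Replicates are conditioned on the segregating variant producing at least
    10 informative meioses.
    """
    linked_idx = n_markers // 2
    hits = 0
    subs = iter(_subseeds(seed + 3, n_rep * 20))
    for _ in range(n_rep):
        while True:
            s = next(subs)
            # 30-member pedigree: large sibships give the two-point statistic
            # enough phase information per informative meiosis
            ped, mmap, truth = _scan_pedigree(s, n_markers, linked_idx,
                                              branches=4, kids=5)
            if _informative_meioses(ped, truth, linked_idx) >= 10:
                break
        prof = scan(ped, mmap, FULLY_PENETRANT)
        hits += linked_idx in prof.support_marker_indices
    return hits / n_rep


# -- association calibration --------------------------------------


def logistic_null_ks_p(seed: int, n_rep: int = 500, n: int = 2000) -> float:
    """KS uniformity p of the one-sided logistic p under the null."""
    ps = []
    for s in _subseeds(seed + 4, n_rep):
        df = gen_case_control(n // 2, n // 2, 0.2, 0.2, seed=s)
        ps.append(logistic_assoc(df["genotype"], df["phenotype"]).p_one_sided)
    return float(stats.kstest(ps, "uniform").pvalue)


def logistic_vs_2x2_max_abs_diff(seed: int, n_rep: int = 20) -> float:
    """Max |logistic beta - closed-form 2x2 log-OR| for carrier coding."""
    worst = 0.0
    for s in _subseeds(seed + 5, n_rep):
        df = gen_case_control(300, 500, 0.1, 0.2, seed=s)
        carrier = (df["genotype"] > 0).astype(int)
        if carrier.std() == 0:
            continue
        res = logistic_assoc(carrier, df["phenotype"])
        case = df["phenotype"] == 1
        a, b = carrier[case].sum(), case.sum() - carrier[case].sum()
        c, d = carrier[~case].sum(), (~case).sum() - carrier[~case].sum()
        if min(a, b, c, d) == 0:
            continue
        worst = max(worst, abs(res.beta - np.log((a / b) / (c / d))))
    return worst


def gene_test_null_ks_p(seed: int, n_rep: int = 200, n: int = 300,
                        n_perm: int = 499) -> float:
    """KS uniformity p of the gene-based permutation p under the null."""
    ps = []
    for s in _subseeds(seed + 6, n_rep):
        rng = np.random.default_rng(s)
        mafs = rng.uniform(0.02, 0.2, 5)
        G = rng.binomial(2, mafs, size=(n, 5)).astype(float)
        y = rng.binomial(1, 0.4, n)
        if G.std(axis=0).max() == 0 or y.std() == 0:
            continue
        ps.append(gene_test(G, y, n_perm=n_perm, seed=s).p_permutation)
    return float(stats.kstest(ps, "uniform").pvalue)


# -- recovery at replication scale --------------------------------


def replication_scale_or_mean(seed: int, n_rep: int = 200,
                              n_case: int = 544, n_control: int = 3605,
                              maf_case: float = 0.031,
                              maf_control: float = 0.045) -> float:
    """Mean crude allelic OR across replicates at the replication design size."""
    ors = []
    for s in _subseeds(seed + 7, n_rep):
        df = gen_case_control(n_case, n_control, maf_case, maf_control, seed=s)
        case = df["phenotype"] == 1
        a = df.loc[case, "genotype"].sum()
        b = 2 * case.sum() - a
        c = df.loc[~case, "genotype"].sum()
        d = 2 * (~case).sum() - c
        ors.append(allelic_or(a, b, c, d).or_)
    return float(np.mean(ors))


def expected_2x2_or(maf_case: float = 0.031, maf_control: float = 0.045) -> float:
    return (maf_case / (1 - maf_case)) / (maf_control / (1 - maf_control))


# -- differential expression / FDR -----------------------------------------------------


def dge_realized_fdr(seed: int, n_rep: int = 20, n_genes: int = 1000,
                     n_signal: int = 100) -> float:
    """Mean false-discovery proportion at q < 0.05 with known signals."""
    fdps = []
    for s in _subseeds(seed + 8, n_rep):
        betas = np.zeros(n_genes)
        betas[:n_signal] = 0.4
        es = ExpressionEffectSpec(disease_betas=betas, noise_sd=0.3)
        study, _ = gen_expression(n_genes, 40, 40, effect_spec=es, seed=s)
        table = fit_dge(study, model="simple").table
        called = table["q"].astype(float) < 0.05
        nulls = np.arange(n_genes) >= n_signal
        fdps.append((called.to_numpy() & nulls).sum() / max(1, called.sum()))
    return float(np.mean(fdps))


def dge_recovery_rate(seed: int, n_rep: int = 200) -> float:
    """Fraction of replicates recovering a 0.32 diagnosis effect within 3 SE
    at the 80 vs 76 design size."""
    hits = 0
    for s in _subseeds(seed + 9, n_rep):
        betas = np.zeros(50)
        betas[0] = 0.32
        es = ExpressionEffectSpec(disease_betas=betas, noise_sd=0.3)
        study, _ = gen_expression(50, 80, 76, effect_spec=es, seed=s)
        row = fit_dge(study, model="simple").table.iloc[0]
        hits += abs(float(row["beta"]) - 0.32) < 3 * float(row["se"])
    return hits / n_rep


# -- assay formula fixed points ------------------------------------


def assay_fixed_points() -> dict[str, float]:
    cyto = cytotoxicity_pct(LdhMeasurement(30.0, 10.0, 50.0))
    fold, _ = ddct_relative_expression(QpcrCondition([21.0], [18.0]),
                                       QpcrCondition([20.0], [18.0]))
    rng = np.random.default_rng(0)
    a, b = rng.normal(0, 1, 8), rng.normal(0.6, 1, 8)
    f, _ = stats.f_oneway(a, b)
    t, _ = stats.ttest_ind(a, b, equal_var=True)
    return {
        "cytotoxicity_worked_example_pct": float(cyto),
        "ddct_one_cycle_fold": float(fold),
        "anova_f_minus_t_squared": float(abs(f - t**2)),
    }
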