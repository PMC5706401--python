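"""Synthetic-data generators with machine-readable ground truth.

Every input the pipeline consumes can be generated here with known truth:
multi-generation genealogies with cohort-structured AD mortality and spiked
high-risk pedigrees; pedigree marker genotypes gene-dropped around a dominant
protective locus; annotated variant tables with per-filter pass/fail truth;
case-control genotype tables at stated carrier frequencies; and expression
matrices with covariates including the five CNS cell-marker channels.

All generators are pure functions of (spec, seed): a fixed seed reproduces
byte-identical output.  Gene dropping is forward simulation of the generative
model the likelihood integrates over, which is what makes exact recovery
tests possible downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .linkage import Marker, MarkerMap, TraitModel
from .pedigree import Individual, Pedigree
from .variants import AnnotatedVariant, FILTER_NAMES, InteractionNetwork

__all__ = [
    "PopulationSpec",
    "LinkageSimSpec",
    "CovariateSpec",
    "ExpressionEffectSpec",
    "gen_population",
    "gen_linkage_genotypes",
    "gen_variant_table",
    "gen_case_control",
    "gen_expression",
    "write_map",
    "write_vcf",
    "write_bed",
    "generate_from_config",
]


# -- population / mortality ---------------------------------------------------


@dataclass
class PopulationSpec:
    """Genealogy-simulation parameters.

    ``base_ad_rate_by_cohort`` maps a 5-year birth block start to the AD death
    probability for that cohort (a scalar applies to all cohorts).  Designated
    high-risk pedigrees have their per-cohort hazard multiplied by
    ``spiked_pedigree_rr`` (truncated at 1).
    """

    n_pedigrees: int = 100
    generations: int = 4
    mean_offspring: float = 3.0
    birth_year_range: tuple[int, int] = (1850, 1960)
    base_ad_rate_by_cohort: float | dict = 0.05
    spiked_pedigree_rr: float = 1.0
    n_spiked: int = 0
    resilient_rate: float = 0.08
    prop_in_state: float = 0.9
    seed: int = 0

    def __post_init__(self):
        if self.n_pedigrees <= 0 or self.generations <= 0:
            raise ValueError("need at least one pedigree and one generation")
        if self.spiked_pedigree_rr < 1.0:
            raise ValueError("spiked_pedigree_rr must be >= 1")
        rates = (
            self.base_ad_rate_by_cohort.values()
            if isinstance(self.base_ad_rate_by_cohort, dict)
            else [self.base_ad_rate_by_cohort]
        )
        if any(not 0.0 <= r <= 1.0 for r in rates):
            raise ValueError("cohort rates must lie in [0, 1]")

    def rate_for(self, birth_year: int) -> float:
        if isinstance(self.base_ad_rate_by_cohort, dict):
            block = 5 * (birth_year // 5)
            return self.base_ad_rate_by_cohort.get(block, 0.0)
        return self.base_ad_rate_by_cohort


def gen_population(spec: PopulationSpec) -> tuple[list[Pedigree], pd.DataFrame]:
    """Generate genealogies with cohort-structured AD mortality.

    Returns (pedigrees, truth) where truth records per pedigree whether it was
    spiked and with what rate ratio.  The first ``n_spiked`` pedigrees are the
    high-risk ones.
    """
    rng = np.random.default_rng(spec.seed)
    y0, y1 = spec.birth_year_range
    pedigrees = []
    truth_rows = []
    for p in range(spec.n_pedigrees):
        pid = f"P{p + 1:04d}"
        spiked = p < spec.n_spiked and spec.spiked_pedigree_rr > 1.0
        rr = spec.spiked_pedigree_rr if spiked else 1.0
        members: list[Individual] = []
        counter = 0

        def new_id():
            nonlocal counter
            counter += 1
            return f"{pid}_{counter}"

        def birth_place():
            return "in_state" if rng.random() < spec.prop_in_state else "out_of_state"

        f0 = Individual(id=new_id(), sex="male",
                        birth_year=int(y0 + rng.integers(0, 6)), birth_place=birth_place())
        m0 = Individual(id=new_id(), sex="female",
                        birth_year=int(y0 + rng.integers(0, 6)), birth_place=birth_place())
        members += [f0, m0]
        couples = [(f0, m0)]
        for g in range(1, spec.generations):
            next_couples = []
            last_gen = g == spec.generations - 1
            for fa, mo in couples:
                n_kids = int(rng.poisson(spec.mean_offspring))
                for _ in range(n_kids):
                    by = min(int(max(fa.birth_year, mo.birth_year)
                                 + rng.integers(20, 36)), y1)
                    child = Individual(
                        id=new_id(), father_id=fa.id, mother_id=mo.id,
                        sex="male" if rng.random() < 0.5 else "female",
                        birth_year=by, birth_place=birth_place(),
                    )
                    members.append(child)
                    if not last_gen:
                        spouse = Individual(
                            id=new_id(),
                            sex="female" if child.sex == "male" else "male",
                            birth_year=min(int(by + rng.integers(-3, 4)), y1),
                            birth_place=birth_place(), is_marry_in=True,
                        )
                        members.append(spouse)
                        pair = (child, spouse) if child.sex == "male" else (spouse, child)
                        next_couples.append(pair)
            couples = next_couples
        # AD mortality: per-cohort hazard for everyone; the pedigree-specific
        # spike multiplies the hazard of blood descendants only
        for ind in members:
            mult = 1.0 if ind.is_marry_in else rr
            hazard = min(1.0, spec.rate_for(ind.birth_year) * mult)
            if rng.random() < hazard:
                ind.ad_death = True
                ind.vital_status = "dead"
                ind.phenotype = "case"
            elif rng.random() < spec.resilient_rate:
                ind.phenotype = "resilient"
        pedigrees.append(Pedigree(pid, members))
        truth_rows.append({"pedigree_id": pid, "spiked": spiked, "rr": rr,
                           "n_members": len(members)})
    return pedigrees, pd.DataFrame(truth_rows)


# -- gene dropping ------------------------------------------------------------


@dataclass
class LinkageSimSpec:
    """Gene-drop parameters for one pedigree and a marker panel.

    Each marker is simulated at its own recombination fraction to the trait
    locus (0.5 = unlinked); marker alleles are biallelic with the given
    alt-allele frequencies.  ``carriers_seeded_in`` forces the listed founders
    to carry exactly one copy of the protective allele, guaranteeing
    segregation regardless of its population frequency.
    """

    trait_model: TraitModel = field(default_factory=TraitModel)
    marker_alt_freqs: Sequence[float] = (0.5,)
    theta_to_trait: Sequence[float] = (0.5,)
    carriers_seeded_in: Sequence[str] = ()
    marker_map: Optional[MarkerMap] = None
    seed: int = 0

    def __post_init__(self):
        if len(self.marker_alt_freqs) != len(self.theta_to_trait):
            raise ValueError("marker frequency and theta lists must have equal length")
        if any(not 0.0 <= t <= 0.5 for t in self.theta_to_trait):
            raise ValueError("recombination fractions must lie in [0, 0.5]")
        if self.marker_map is not None and len(self.marker_map) != len(self.marker_alt_freqs):
            raise ValueError("marker map does not match the simulated panel")


def gen_linkage_genotypes(
    ped: Pedigree, spec: LinkageSimSpec
) -> tuple[Pedigree, pd.DataFrame]:
    """Gene-drop marker genotypes and trait phenotypes through a pedigree.

    Founder two-locus haplotypes are drawn at linkage equilibrium; each
    meiosis picks a grandparental origin at the trait locus and recombines to
    each marker with its own theta; phenotypes are drawn from the penetrances
    given carrier status.  Fills each member's ``genotypes`` (allele codes
    1 = ref, 2 = alt) and ``affection`` in place and returns the pedigree with
    a per-individual truth table (disease-allele count, affection).
    """
    rng = np.random.default_rng(spec.seed)
    model = spec.trait_model
    q = model.disease_allele_freq
    n_mark = len(spec.marker_alt_freqs)
    freqs = np.asarray(spec.marker_alt_freqs, dtype=float)
    thetas = np.asarray(spec.theta_to_trait, dtype=float)
    seeded = set(spec.carriers_seeded_in)
    unknown = seeded - set(ped.members)
    if unknown:
        raise ValueError(f"seeded carriers not in pedigree: {sorted(unknown)}")

    # haplotype: (trait_allele, marker_alleles array) with 0 = ref/wild, 1 = alt/disease
    haps: dict[str, list[tuple[int, np.ndarray]]] = {}

    def founder_hap(force_trait: Optional[int] = None):
        t = int(rng.random() < q) if force_trait is None else force_trait
        m = (rng.random(n_mark) < freqs).astype(int)
        return (t, m)

    def meiosis(parent_haps):
        origin = int(rng.random() < 0.5)
        t = parent_haps[origin][0]
        flip = rng.random(n_mark) < thetas
        m = np.where(flip, parent_haps[1 - origin][1], parent_haps[origin][1])
        return (t, m)

    for iid in ped.topological_order():
        f, mo = ped.parents_of(iid)
        if f is None and mo is None:
            if iid in seeded:
                h = [founder_hap(force_trait=1), founder_hap(force_trait=0)]
                rng.shuffle(h)
                haps[iid] = h
            else:
                haps[iid] = [founder_hap(), founder_hap()]
        else:
            # a missing co-parent is an implicit founder drawn from the population
            pat = meiosis(haps[f]) if f is not None else founder_hap()
            mat = meiosis(haps[mo]) if mo is not None else founder_hap()
            haps[iid] = [pat, mat]

    rows = []
    for iid, ind in ped.members.items():
        h1, h2 = haps[iid]
        n_dis = h1[0] + h2[0]
        pen = model.penetrance(n_dis)
        affected = bool(rng.random() < pen)
        ind.affection = "affected" if affected else "unaffected"
        ind.genotypes = [
            (int(h1[1][j]) + 1, int(h2[1][j]) + 1) for j in range(n_mark)
        ]
        rows.append({"id": iid, "n_disease_alleles": int(n_dis), "affected": affected})
    return ped, pd.DataFrame(rows).set_index("id")


# -- annotated variant tables --------------------------------------------------


def gen_variant_table(
    n_variants: int,
    fraction_passing_each_filter: dict[str, float] | float,
    seed: int = 0,
    resilient_ids: Sequence[str] = ("R1", "R2", "R3"),
    case_ids: Sequence[str] = ("C1", "C2"),
):
    """Annotated variants whose per-filter outcomes are drawn independently.

    ``fraction_passing_each_filter`` is a scalar or a map filter-name ->
    pass probability over the seven cascade rules.  Returns a dict with the
    variants, the cascade inputs (blacklist trees, network, sample ids) and a
    truth frame holding each rule's pass/fail and the retained flag (the
    conjunction).  Each variant gets its own gene so compound-het rescue never
    blurs the single-variant truth.
    """
    if isinstance(fraction_passing_each_filter, dict):
        fracs = {n: float(fraction_passing_each_filter[n]) for n in FILTER_NAMES}
    else:
        fracs = {n: float(fraction_passing_each_filter) for n in FILTER_NAMES}
    if any(not 0.0 <= f <= 1.0 for f in fracs.values()):
        raise ValueError("pass fractions must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    resilient_ids = list(resilient_ids)
    case_ids = list(case_ids)
    passes = {n: rng.random(n_variants) < fracs[n] for n in FILTER_NAMES}

    variants = []
    window_tree = IntervalTree()
    edges = [("NEAR_HUB", "SEED")]
    seed_genes = {"SEED"}
    for i in range(n_variants):
        gene = f"G{i:05d}"
        pos = 1000 + 10 * i
        ok = {n: bool(passes[n][i]) for n in FILTER_NAMES}
        if not ok["blacklist"]:
            window_tree.addi(pos - 1, pos)
        if ok["case_network"]:
            edges.append((gene, "SEED"))
            carriers_case = set()
        else:
            if rng.random() < 0.5:
                edges.append((gene, "SEED"))
                carriers_case = {case_ids[0]}
            else:
                carriers_case = set()  # gene left far from any seed
        functional_kwargs = {}
        if ok["functional_evidence"]:
            choice = rng.integers(0, 4)
            if choice == 0:
                functional_kwargs = {"phylop_p": float(rng.uniform(0.01, 1.0))}
            elif choice == 1:
                functional_kwargs = {"consequence": "missense", "sift_benign": False}
            elif choice == 2:
                functional_kwargs = {"consequence": "utr3"}
            else:
                functional_kwargs = {"promoter": True}
        else:
            functional_kwargs = {
                "consequence": "synonymous",
                "sift_benign": True,
                "phylop_p": float(rng.uniform(0.0, 0.0099)),
            }
        variants.append(
            AnnotatedVariant(
                chrom="2",
                pos=pos,
                ref="A",
                alt="G",
                gene=gene,
                resilient_carriers=(
                    set(resilient_ids) if ok["resilient_sharing"] else {resilient_ids[0]}
                ),
                case_carriers=carriers_case,
                call_quality={
                    "resilient": float(rng.uniform(20.0, 60.0)) if ok["call_quality"]
                    else float(rng.uniform(0.0, 19.9))
                },
                panel_freqs={
                    "kg1000": float(rng.uniform(0.0, 0.0299)) if ok["panel_frequency"]
                    else float(rng.uniform(0.03, 0.5))
                },
                zygosity_class="heterozygous" if ok["zygosity_class"] else "other",
                **functional_kwargs,
            )
        )
    truth = pd.DataFrame(
        {n: passes[n] for n in FILTER_NAMES},
        index=[v.key for v in variants],
    )
    truth["retained"] = truth[list(FILTER_NAMES)].all(axis=1)
    network = InteractionNetwork.from_edges(edges, seed_genes)
    return {
        "variants": variants,
        "resilient_ids": resilient_ids,
        "case_ids": case_ids,
        "blacklist_window_trees": {"2": window_tree},
        "blacklist_genes": set(),
        "network": network,
        "truth": truth,
    }


# -- case-control genotypes ----------------------------------------------------


@dataclass
class CovariateSpec:
    """Age/sex/site covariate generation, with optional age–genotype confounding."""

    age_mean: float = 78.0
    age_sd: float = 6.0
    case_age_shift: float = 0.0
    n_sites: int = 3
    age_per_allele: float = 0.0  # > 0 switches on age–genotype confounding


def gen_case_control(
    n_case: int,
    n_control: int,
    maf_case: float,
    maf_control: float,
    covariate_spec: Optional[CovariateSpec] = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Case-control genotypes binomial(2, MAF) per group with covariates.

    Returns a frame with columns genotype, phenotype (1 = case), age, sex,
    site, plus a ``monomorphic`` attribute flag in ``DataFrame.attrs`` when
    the drawn genotype column has no variation.
    """
    for maf in (maf_case, maf_control):
        if not 0.0 <= maf <= 0.5:
            raise ValueError("MAFs must lie in [0, 0.5]")
    cs = covariate_spec or CovariateSpec()
    rng = np.random.default_rng(seed)
    n = n_case + n_control
    pheno = np.concatenate([np.ones(n_case, dtype=int), np.zeros(n_control, dtype=int)])
    geno = np.concatenate([
        rng.binomial(2, maf_case, size=n_case),
        rng.binomial(2, maf_control, size=n_control),
    ])
    age = rng.normal(cs.age_mean, cs.age_sd, size=n) + cs.case_age_shift * pheno
    age = age + cs.age_per_allele * geno
    sex = rng.integers(0, 2, size=n)
    site = rng.integers(0, max(1, cs.n_sites), size=n)
    df = pd.DataFrame({
        "genotype": geno,
        "phenotype": pheno,
        "age": age,
        "sex": sex,
        "site": pd.Categorical([f"site{s}" for s in site]),
    })
    df.attrs["monomorphic"] = bool(geno.std() == 0)
    return df


# -- expression matrices -------------------------------------------------------


@dataclass
class ExpressionEffectSpec:
    """Truth effects for the expression generator.

    ``disease_betas`` is the per-gene log-scale AD effect (scalar broadcasts);
    ``marker_loadings`` (genes x 5) routes marker-channel signal into genes,
    and ``marker_dx_effect`` shifts the marker channels themselves in AD —
    together they create diagnosis effects mediated by cell composition.
    """

    disease_betas: float | np.ndarray = 0.0
    marker_loadings: float | np.ndarray = 0.0
    marker_dx_effect: float = 0.0
    covariate_betas: dict = field(default_factory=lambda: {"age": 0.01, "sex": 0.05,
                                                           "rin": 0.1})
    noise_sd: float = 0.3


def gen_expression(
    n_genes: int,
    n_ad: int,
    n_control: int,
    effect_spec: Optional[ExpressionEffectSpec] = None,
    seed: int = 0,
):
    """Log-scale expression with diagnosis, covariate and marker-channel effects.

    Returns (ExpressionStudy, truth frame of per-gene disease betas).
    """
    from .expression import MARKER_GENES, ExpressionStudy

    if n_genes <= 0 or n_ad <= 0 or n_control <= 0:
        raise ValueError("counts must be positive")
    es = effect_spec or ExpressionEffectSpec()
    rng = np.random.default_rng(seed)
    n = n_ad + n_control
    dx = np.concatenate([np.ones(n_ad), np.zeros(n_control)])
    age = rng.normal(80, 7, size=n)
    sex = rng.integers(0, 2, size=n)
    rin = rng.normal(7.5, 0.8, size=n)
    tissue = rng.integers(0, 2, size=n)
    flowcell = rng.integers(0, 4, size=n)
    markers = rng.normal(0.0, 1.0, size=(n, len(MARKER_GENES)))
    markers = markers + es.marker_dx_effect * dx[:, None]

    betas = np.broadcast_to(np.asarray(es.disease_betas, dtype=float), (n_genes,)).copy()
    loadings = np.broadcast_to(
        np.asarray(es.marker_loadings, dtype=float), (n_genes, len(MARKER_GENES))
    ).copy()
    cb = es.covariate_betas
    base = rng.normal(5.0, 1.0, size=n_genes)
    expr = (
        base[:, None]
        + betas[:, None] * dx[None, :]
        + loadings @ markers.T
        + cb.get("age", 0.0) * (age - age.mean())[None, :]
        + cb.get("sex", 0.0) * sex[None, :]
        + cb.get("rin", 0.0) * (rin - rin.mean())[None, :]
        + rng.normal(0.0, es.noise_sd, size=(n_genes, n))
    )
    samples = [f"S{i + 1:04d}" for i in range(n)]
    genes = [f"gene{i + 1:05d}" for i in range(n_genes)]
    matrix = pd.DataFrame(expr, index=genes, columns=samples)
    covariates = pd.DataFrame(
        {
            "diagnosis": dx.astype(int),
            "age_at_death": age,
            "sex": sex,
            "rin": rin,
            "tissue_source": pd.Categorical([f"bank{t}" for t in tissue]),
            "flowcell": pd.Categorical([f"fc{f}" for f in flowcell]),
        },
        index=samples,
    )
    marker_channels = pd.DataFrame(markers, index=samples, columns=list(MARKER_GENES))
    study = ExpressionStudy(matrix=matrix, covariates=covariates,
                            marker_channels=marker_channels)
    truth = pd.DataFrame({"beta": betas}, index=genes)
    return study, truth


# -- writers -------------------------------------------------------------------


def write_map(marker_map: MarkerMap, dest) -> str:
    lines = [
        f"{m.chromosome}\t{m.name}\t0\t{m.position_bp}" for m in marker_map.markers
    ]
    text = "\n".join(lines) + "\n"
    _write_text(text, dest)
    return text


def write_vcf(
    variants: Sequence[AnnotatedVariant],
    dest,
    samples: Sequence[str] = (),
    genotypes: Optional[dict[tuple, dict[str, tuple[str, str]]]] = None,
) -> str:
    """Minimal VCF v4.2 writer (GT and AD genotype fields)."""
    out = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
    ]
    header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO"]
    if samples:
        header += ["FORMAT", *samples]
    out.append("\t".join(header))
    for v in variants:
        row = [v.chrom, str(v.pos), ".", v.ref, v.alt, ".", "PASS", f"GENE={v.gene}"]
        if samples:
            row.append("GT:AD")
            per = (genotypes or {}).get(v.key, {})
            for s in samples:
                gt, ad = per.get(s, ("./.", "."))
                row.append(f"{gt}:{ad}")
        out.append("\t".join(row))
    text = "\n".join(out) + "\n"
    _write_text(text, dest)
    return text


def write_bed(trees: dict[str, IntervalTree], dest) -> str:
    rows = []
    for chrom in sorted(trees):
        for iv in sorted(trees[chrom]):
            rows.append(f"{chrom}\t{iv.begin}\t{iv.end}")
    text = "\n".join(rows) + "\n"
    _write_text(text, dest)
    return text


def _write_text(text: str, dest) -> None:
    if dest is None:
        return
    if hasattr(dest, "write"):
        dest.write(text)
    else:
        with open(dest, "wt", encoding="utf-8") as fh:
            fh.write(text)


def generate_from_config(config, outdir) -> dict:
    """Drive every generator from one YAML-style mapping; writes files to outdir.

    Recognized sections: ``population``, ``variants``, ``case_control``,
    ``expression`` — each holding the corresponding generator's keyword
    arguments.  Returns the in-memory objects keyed by section.
    """
    import os

    import yaml

    from .pedigree import write_ped

    if not isinstance(config, dict):
        with open(config, "rt", encoding="utf-8") as fh:
            config = yaml.safe_load(fh)
    os.makedirs(outdir, exist_ok=True)
    out: dict = {}
    if "population" in config:
        spec = PopulationSpec(**config["population"])
        peds, truth = gen_population(spec)
        write_ped(peds, os.path.join(outdir, "population.ped"))
        truth.to_csv(os.path.join(outdir, "population_truth.tsv"), sep="\t", index=False)
        out["population"] = (peds, truth)
    if "variants" in config:
        bundle = gen_variant_table(**config["variants"])
        write_vcf(bundle["variants"], os.path.join(outdir, "variants.vcf"))
        bundle["truth"].to_csv(os.path.join(outdir, "variant_truth.tsv"), sep="\t")
        write_bed(bundle["blacklist_window_trees"], os.path.join(outdir, "blacklist.bed"))
        out["variants"] = bundle
    if "case_control" in config:
        df = gen_case_control(**config["case_control"])
        df.to_csv(os.path.join(outdir, "case_control.tsv"), sep="\t", index=False)
        out["case_control"] = df
    if "expression" in config:
        cfg = dict(config["expression"])
        study, truth = gen_expression(**cfg)
        study.matrix.to_csv(os.path.join(outdir, "expression.tsv"), sep="\t")
        study.covariates.to_csv(os.path.join(outdir, "expression_covariates.tsv"), sep="\t")
        truth.to_csv(os.path.join(outdir, "expression_truth.tsv"), sep="\t")
        out["expression"] = (study, truth)
    return out
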