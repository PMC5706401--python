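"""Exact pedigree likelihood, TLOD closed forms, pruning, and scan behavior."""

import numpy as np
import pytest

from resilink.linkage import (
    DEFAULT_THETA_GRID,
    LoopedPedigreeError,
    Marker,
    MarkerMap,
    TraitModel,
    classify_tlod,
    enumerate_two_locus_loglik,
    estimate_allele_freqs,
    marker_loglik,
    pedigree_loglik,
    prune_markers,
    scan,
    trait_loglik,
    two_point_tlod,
)
from resilink.pedigree import Individual, Pedigree
from resilink.simulate import LinkageSimSpec, gen_linkage_genotypes

from conftest import branching_pedigree, random_pedigree

MODEL = TraitModel(disease_allele_freq=0.1, penetrance_carrier=0.8,
                   penetrance_noncarrier=0.05)


def phase_known_pedigree(n_children: int, recombinants: int) -> Pedigree:
    """Doubly heterozygous parent with known phase and n scorable meioses.

    The affected grandfather is homozygous 2/2 at the marker and the
    unaffected grandmother 1/1, so the parent's disease allele is known to
    ride with marker allele 2; every child is a phase-known meiosis.
    """
    mem = [
        Individual(id="GF", sex="male", affection="affected", genotypes=[(2, 2)]),
        Individual(id="GM", sex="female", affection="unaffected", genotypes=[(1, 1)]),
        Individual(id="P", father_id="GF", mother_id="GM", sex="male",
                   affection="affected", genotypes=[(1, 2)]),
        Individual(id="S", sex="female", affection="unaffected", genotypes=[(1, 1)]),
    ]
    for i in range(n_children):
        rec = i < recombinants
        mem.append(Individual(
            id=f"C{i}", father_id="P", mother_id="S", affection="affected",
            genotypes=[(1, 1) if rec else (1, 2)],
        ))
    return Pedigree("PK", mem)


def genos_of(ped):
    return {iid: ind.genotypes[0] for iid, ind in ped.members.items()
            if ind.genotypes}


class TestLikelihood:
    def test_empty_evidence_gives_log_one(self):
        solo = Pedigree("S", [Individual(id="x")])
        ll = pedigree_loglik(solo, {}, MODEL, [0.6, 0.4], 0.3)
        assert ll[0] == pytest.approx(0.0, abs=1e-12)

    def test_factorizes_at_half(self):
        """At theta = 0.5 the joint equals trait-only x marker-only."""
        ped = random_pedigree(8, 7)
        spec = LinkageSimSpec(trait_model=MODEL, marker_alt_freqs=[0.4],
                              theta_to_trait=[0.2], seed=7)
        gen_linkage_genotypes(ped, spec)
        genos = genos_of(ped)
        joint = pedigree_loglik(ped, genos, MODEL, [0.6, 0.4], 0.5)[0]
        split = trait_loglik(ped, MODEL) + marker_loglik(ped, genos, [0.6, 0.4])
        assert joint == pytest.approx(split, abs=1e-10)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_enumeration(self, seed):
        """Peeling equals the brute-force genotype-assignment sum."""
        rng = np.random.default_rng(seed)
        ped = random_pedigree(int(rng.integers(3, 9)), seed + 50)
        spec = LinkageSimSpec(trait_model=MODEL, marker_alt_freqs=[0.35],
                              theta_to_trait=[float(rng.uniform(0, 0.5))],
                              seed=seed)
        gen_linkage_genotypes(ped, spec)
        genos = genos_of(ped)
        theta = float(rng.choice([0.0, 0.05, 0.2, 0.5]))
        a = pedigree_loglik(ped, genos, MODEL, [0.65, 0.35], theta)[0]
        b = enumerate_two_locus_loglik(ped, genos, MODEL, [0.65, 0.35], theta)
        assert a == pytest.approx(b, rel=1e-9)

    def test_mendelian_inconsistency_flags_zero_likelihood(self):
        mem = [
            Individual(id="F", sex="male", genotypes=[(1, 1)]),
            Individual(id="M", sex="female", genotypes=[(1, 1)]),
            Individual(id="C", father_id="F", mother_id="M", genotypes=[(2, 2)]),
        ]
        ped = Pedigree("MX", mem)
        ll = pedigree_loglik(ped, genos_of(ped), MODEL, [0.5, 0.5], 0.1)
        assert np.isneginf(ll[0])
        with pytest.raises(ValueError, match="Mendelian"):
            two_point_tlod(ped, genos_of(ped), MODEL, [0.5, 0.5])

    def test_small_loop_matches_enumeration(self, cousin_pedigree):
        spec = LinkageSimSpec(trait_model=MODEL, marker_alt_freqs=[0.4],
                              theta_to_trait=[0.1], seed=3)
        gen_linkage_genotypes(cousin_pedigree, spec)
        genos = genos_of(cousin_pedigree)
        a = pedigree_loglik(cousin_pedigree, genos, MODEL, [0.6, 0.4], 0.1)[0]
        b = enumerate_two_locus_loglik(cousin_pedigree, genos, MODEL, [0.6, 0.4], 0.1)
        assert a == pytest.approx(b, rel=1e-9)

    def test_large_looped_pedigree_unsupported(self, cousin_pedigree):
        # inflate the looped pedigree beyond the exact-evaluation cutoff
        mem = list(cousin_pedigree.members.values())
        for j in range(5):
            mem.append(Individual(id=f"extra{j}", father_id="C1", mother_id="C2"))
        big = Pedigree("BIGLOOP", mem)
        with pytest.raises(LoopedPedigreeError):
            pedigree_loglik(big, {}, MODEL, [0.5, 0.5], 0.1)


class TestTlod:
    def test_ten_nonrecombinant_phase_known_meioses(self):
        model = TraitModel(0.005, 1.0, 0.0)
        ped = phase_known_pedigree(10, 0)
        tlod, th = two_point_tlod(ped, genos_of(ped), model, [0.8, 0.2])
        assert tlod == pytest.approx(10 * np.log10(2), abs=1e-9)
        assert th == 0.0

    def test_two_recombinants_closed_form(self):
        # independent closed form: log10(theta^k (1-theta)^(n-k) / 0.5^n)
        model = TraitModel(0.005, 1.0, 0.0)
        ped = phase_known_pedigree(10, 2)
        tlod, th = two_point_tlod(ped, genos_of(ped), model, [0.8, 0.2])
        expected = np.log10(0.2**2 * 0.8**8 / 0.5**10)
        assert th == 0.2
        assert tlod == pytest.approx(expected, abs=1e-9)

    def test_uninformative_marker_gives_zero(self):
        ped = phase_known_pedigree(6, 0)
        hom = {iid: (1, 1) for iid in ped.members}
        model = TraitModel(0.005, 1.0, 0.0)
        tlod, _ = two_point_tlod(ped, hom, model, [1.0, 0.0])
        assert tlod == pytest.approx(0.0, abs=1e-9)

    def test_lod_at_half_is_exactly_zero(self):
        ped = phase_known_pedigree(8, 1)
        model = TraitModel(0.005, 1.0, 0.0)
        tlod, th = two_point_tlod(ped, genos_of(ped), model, [0.8, 0.2],
                                  theta_grid=[0.5])
        assert tlod == 0.0 and th == 0.5

    def test_grid_must_contain_half(self):
        ped = phase_known_pedigree(4, 0)
        with pytest.raises(ValueError, match="0.5"):
            two_point_tlod(ped, genos_of(ped), MODEL, [0.8, 0.2], theta_grid=[0.0, 0.1])

    @pytest.mark.parametrize(
        "tlod,expected",
        [(2.21, "suggestive"), (3.5, "significant"), (1.0, "none"), (1.86, "none"),
         (3.30, "suggestive")],
    )
    def test_threshold_classification(self, tlod, expected):
        assert classify_tlod(tlod) == expected


class TestScan:
    def test_linked_locus_in_support_interval(self):
        ped = branching_pedigree(4, 4)
        model = TraitModel(0.005, 1.0, 0.0)
        n_mark, true_idx = 20, 10
        thetas = [0.5] * n_mark
        thetas[true_idx] = 0.01
        spec = LinkageSimSpec(
            trait_model=model, marker_alt_freqs=[0.5] * n_mark,
            theta_to_trait=thetas, carriers_seeded_in=["F0"], seed=6,
        )
        gen_linkage_genotypes(ped, spec)
        mmap = MarkerMap([Marker(f"m{j}", "2", 1000 * (j + 1)) for j in range(n_mark)])
        prof = scan(ped, mmap, model)
        assert true_idx in prof.support_marker_indices
        c, s, e = prof.support_interval
        assert c == "2" and s <= 1000 * (true_idx + 1) <= e

    def test_profile_contains_argmax(self):
        ped = branching_pedigree(3, 3)
        spec = LinkageSimSpec(trait_model=MODEL, marker_alt_freqs=[0.5] * 5,
                              theta_to_trait=[0.5] * 5, seed=2)
        gen_linkage_genotypes(ped, spec)
        mmap = MarkerMap([Marker(f"m{j}", "7", 100 * (j + 1)) for j in range(5)])
        prof = scan(ped, mmap, MODEL)
        j_best = int(np.argmax([ml.tlod for ml in prof.marker_lods]))
        assert j_best in prof.support_marker_indices
        assert all(ml.tlod >= 0 for ml in prof.marker_lods)


class TestPruning:
    def test_duplicate_marker_dropped(self):
        rng = np.random.default_rng(0)
        g = rng.integers(1, 3, size=(200, 1, 2))
        pairs = np.concatenate([g, g], axis=1)  # r^2 = 1
        kept = prune_markers(pairs, min_heterozygosity=0.2, max_r2=0.5)
        assert list(kept) == [0]

    def test_monomorphic_dropped(self):
        mono = np.ones((100, 1, 2), dtype=int)
        with pytest.warns(UserWarning, match="empty panel"):
            kept = prune_markers(mono, min_heterozygosity=0.3)
        assert len(kept) == 0

    def test_independent_markers_mostly_kept(self):
        rng = np.random.default_rng(1)
        pairs = rng.integers(1, 3, size=(500, 40, 2))
        kept = prune_markers(pairs, min_heterozygosity=0.3, max_r2=0.5)
        assert len(kept) >= 38  # >= 95% of independent MAF-0.5 markers

    def test_founder_frequency_estimation(self, trio):
        trio.members["F"].genotypes = [(1, 2)]
        trio.members["M"].genotypes = [(2, 2)]
        trio.members["C"].genotypes = [(1, 2)]
        freqs = estimate_allele_freqs(trio, 0)
        assert freqs == pytest.approx([0.25, 0.75])  # founders only
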