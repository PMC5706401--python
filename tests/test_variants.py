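"""Filter cascade, network proximity, capture intersection, reassignment."""

import io

import networkx as nx
import numpy as np
import pytest
from intervaltree import IntervalTree

from resilink.datasets import candidate_variants
from resilink.simulate import gen_variant_table
from resilink.variants import (
    FILTER_NAMES,
    AnnotatedVariant,
    FilterParams,
    InteractionNetwork,
    RawRecord,
    apply_filter_cascade,
    network_proximity,
    read_bed,
    reassign_genotype,
    restrict_to_capture,
)

R = ("R1", "R2", "R3")
C = ("C1", "C2")


def passing_variant(**overrides) -> AnnotatedVariant:
    kw = dict(
        chrom="2", pos=100, ref="A", alt="G", gene="GENE",
        resilient_carriers=set(R), case_carriers=set(),
        call_quality={"resilient": 45.0}, panel_freqs={"kg1000": 0.0152},
        consequence="utr3", zygosity_class="heterozygous",
    )
    kw.update(overrides)
    return AnnotatedVariant(**kw)


def simple_network(edges=(("GENE", "SEED"),), seeds=("SEED",)):
    return InteractionNetwork.from_edges(edges, seeds)


class TestCascade:
    def test_candidate_set_fully_retained(self):
        variants = candidate_variants()
        traces, retained = apply_filter_cascade(
            variants, resilient_ids=("R1", "R2", "R3", "R4"), case_ids=())
        assert len(retained) == len(variants) == 8
        freq_verdicts = {t.verdicts["panel_frequency"] for t in traces}
        assert freq_verdicts == {"pass"}  # 0.0152 etc. all < 3%

    def test_frequency_exclusion_at_three_percent(self):
        v = passing_variant(panel_freqs={"kg1000": 0.05})
        traces, retained = apply_filter_cascade([v], R, C, network=simple_network())
        assert traces[0].verdicts["panel_frequency"] == "fail"
        assert retained == []
        # boundary: exactly 3% is excluded, just below passes
        v2 = passing_variant(panel_freqs={"esp": 0.03})
        t2, _ = apply_filter_cascade([v2], R, C)
        assert t2[0].verdicts["panel_frequency"] == "fail"
        v3 = passing_variant(panel_freqs={"esp": 0.0299})
        t3, _ = apply_filter_cascade([v3], R, C)
        assert t3[0].verdicts["panel_frequency"] == "pass"

    def test_absent_frequency_passes(self):
        v = passing_variant(panel_freqs={})
        traces, _ = apply_filter_cascade([v], R, C)
        assert traces[0].verdicts["panel_frequency"] == "pass"

    def test_generator_truth_recovered_exactly(self):
        bundle = gen_variant_table(300, 0.7, seed=21)
        traces, retained = apply_filter_cascade(
            bundle["variants"],
            bundle["resilient_ids"],
            bundle["case_ids"],
            blacklist_window_trees=bundle["blacklist_window_trees"],
            blacklist_genes=bundle["blacklist_genes"],
            network=bundle["network"],
        )
        truth = bundle["truth"]
        got = {t.variant_key: t.retained for t in traces}
        for key, row in truth.iterrows():
            assert got[key] == row["retained"], key
        # per-filter verdicts match the generator's draw too
        for t, (_, row) in zip(traces, truth.iterrows()):
            for name in FILTER_NAMES:
                assert (t.verdicts[name] == "pass") == row[name], (t.variant_key, name)

    def test_trace_accounting_invariant(self):
        bundle = gen_variant_table(100, 0.5, seed=5)
        traces, retained = apply_filter_cascade(
            bundle["variants"], bundle["resilient_ids"], bundle["case_ids"],
            blacklist_window_trees=bundle["blacklist_window_trees"],
            network=bundle["network"],
        )
        keys = {v.key for v in retained}
        for t in traces:
            assert t.retained == (t.variant_key in keys)
            assert t.retained == all(v != "fail" for v in t.verdicts.values())

    def test_compound_het_rescue(self):
        a = passing_variant(pos=100, zygosity_class="other",
                            resilient_carriers={"R1", "R2", "R3"})
        b = passing_variant(pos=200, zygosity_class="heterozygous")
        traces, retained = apply_filter_cascade([a, b], R, C)
        assert traces[0].verdicts["zygosity_class"] == "pass"  # rescued via b
        lone = passing_variant(pos=300, gene="OTHER", zygosity_class="other")
        traces2, _ = apply_filter_cascade([lone], R, C)
        assert traces2[0].verdicts["zygosity_class"] == "fail"

    def test_strict_mode_fails_unannotated(self):
        v = passing_variant(consequence="other", panel_freqs={})
        t_lenient, _ = apply_filter_cascade([v], R, C)
        assert t_lenient[0].verdicts["functional_evidence"] == "not_applicable"
        assert t_lenient[0].retained
        t_strict, retained = apply_filter_cascade(
            [v], R, C, params=FilterParams(strict=True))
        assert not t_strict[0].retained
        assert retained == []

    def test_phylop_comparator_configurable(self):
        v = passing_variant(consequence="synonymous", sift_benign=True, phylop_p=0.001)
        t1, _ = apply_filter_cascade([v], R, C)
        assert t1[0].verdicts["functional_evidence"] == "fail"
        params = FilterParams(phylop_conserved_if_geq=False)
        t2, _ = apply_filter_cascade([v], R, C, params=params)
        assert t2[0].verdicts["functional_evidence"] == "pass"


class TestNetworkProximity:
    def test_seed_itself_is_proximal_by_default(self):
        net = simple_network()
        assert network_proximity("SEED", net)
        assert not network_proximity("SEED", net, seed_is_proximal=False)

    def test_upstream_two_steps(self):
        net = simple_network(edges=[("A", "B"), ("B", "SEED"), ("C", "A")])
        assert network_proximity("A", net)       # A -> B -> SEED
        assert not network_proximity("C", net)   # 3 steps

    def test_downstream_one_step(self):
        net = simple_network(edges=[("SEED", "D"), ("D", "E")])
        assert network_proximity("D", net)
        assert not network_proximity("E", net)

    def test_absent_gene_is_not_proximal(self):
        assert not network_proximity("NOPE", simple_network())

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bfs_oracle_on_random_graphs(self, seed):
        rng = np.random.default_rng(seed)
        n = 200
        g = nx.gnp_random_graph(n, 0.02, directed=True, seed=int(seed))
        g = nx.relabel_nodes(g, {i: f"g{i}" for i in range(n)})
        seeds = {f"g{i}" for i in rng.choice(n, size=5, replace=False)}
        net = InteractionNetwork(graph=g, seed_genes=seeds)
        # brute-force oracle over explicit paths of length <= 2 up, <= 1 down
        adj = nx.to_numpy_array(g, nodelist=sorted(g.nodes))
        nodes = sorted(g.nodes)
        idx = {v: i for i, v in enumerate(nodes)}
        up2 = ((adj + adj @ adj) > 0)
        for v in rng.choice(nodes, size=40, replace=False):
            expect = v in seeds or any(
                up2[idx[v], idx[s]] or adj[idx[s], idx[v]] for s in seeds if s in idx
            )
            assert network_proximity(v, net) == expect


class TestCapture:
    def test_identical_beds_are_identity(self):
        bed = "1\t0\t1000\n2\t50\t150\n"
        trees = read_bed(io.StringIO(bed))
        vs = [passing_variant(chrom="2", pos=100)]
        assert restrict_to_capture(vs, [trees, read_bed(io.StringIO(bed))]) == vs

    def test_disjoint_beds_empty(self):
        t1 = read_bed(io.StringIO("1\t0\t100\n"))
        t2 = read_bed(io.StringIO("1\t200\t300\n"))
        vs = [passing_variant(chrom="1", pos=50), passing_variant(chrom="1", pos=250)]
        assert restrict_to_capture(vs, [t1, t2]) == []

    def test_malformed_bed_reports_line(self):
        with pytest.raises(ValueError, match="line 2"):
            read_bed(io.StringIO("1\t0\t100\n1\tfoo\t200\n"))
        with pytest.raises(ValueError, match="exceed start"):
            read_bed(io.StringIO("1\t100\t100\n"))

    def test_needs_at_least_one_region_set(self):
        with pytest.raises(ValueError):
            restrict_to_capture([], [])

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_membership_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        sets = []
        for _ in range(3):
            tree = IntervalTree()
            for _ in range(20):
                s = int(rng.integers(0, 900))
                tree.addi(s, s + int(rng.integers(1, 120)))
            sets.append({"1": tree})
        vs = [passing_variant(chrom="1", pos=int(p)) for p in rng.integers(1, 1001, 80)]
        got = restrict_to_capture(vs, sets)
        for v in vs:
            member = all(
                any(iv.begin <= v.pos - 1 < iv.end for iv in trees["1"])
                for trees in sets
            )
            assert (v in got) == member


class TestReassignment:
    def test_passing_call_kept(self):
        raw = RawRecord(present=True, ref_reads=10, alt_reads=8, passed_filters=True,
                        called_genotype="0/1")
        assert reassign_genotype("0/1", raw) == ("0/1", "rule1_as_called")

    def test_failed_filter_with_alt_reads_is_missing(self):
        raw = RawRecord(present=True, ref_reads=20, alt_reads=3, passed_filters=False)
        assert reassign_genotype(None, raw) == ("missing", "rule2_missing")

    def test_all_reference_reads_is_hom_ref(self):
        raw = RawRecord(present=True, ref_reads=25, alt_reads=0, passed_filters=False)
        assert reassign_genotype(None, raw) == ("hom_ref", "rule3_hom_ref")

    def test_absent_site_logged_separately(self):
        assert reassign_genotype(None, RawRecord(present=False)) == ("missing", "site_absent")

    @pytest.mark.parametrize("alt", range(0, 6))
    def test_hom_ref_only_with_zero_alt_reads(self, alt):
        """Reassignment never erases alternate-allele evidence."""
        raw = RawRecord(present=True, ref_reads=10, alt_reads=alt, passed_filters=False)
        geno, rule = reassign_genotype(None, raw)
        if alt == 0:
            assert geno == "hom_ref"
        else:
            assert geno == "missing"
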