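"""Variant-filter cascade, interaction-network proximity, capture harmonization,
and genotype reassignment for candidate protective variants in linkage regions.

The cascade applies seven rules in order, recording a per-variant trace:

1.  ``resilient_sharing`` — carried by the sequenced resilient members of the
    pedigree (all of them by default);
2.  ``call_quality``      — call quality >= 20.0 in cases or resilient samples;
3.  ``blacklist``         — outside the top 0.2% most exonically variable
    100-bp windows and the top 1% most variable genes of healthy public
    genomes (both supplied as inputs);
4.  ``panel_frequency``   — excluded if any reference panel (1000 Genomes,
    Complete Genomics, ESP) reports frequency >= 3%; absent frequency passes
    (a novel variant cannot be excluded on evidence it lacks);
5.  ``zygosity_class``    — gain-of-function, heterozygous, hemizygous,
    haploinsufficient, or compound heterozygous (two or more retained
    heterozygous variants in one gene in one sample; evaluated last within
    this rule, the one deliberately order-dependent step);
6.  ``functional_evidence`` — pathogenic flag, predicted gain-of-function,
    microRNA-binding site, protein-altering consequence not predicted benign,
    splice disruption up to two bases into an intron, promoter/enhancer,
    conserved region (phyloP p >= 0.01, taken literally from the source
    criterion; the comparator is configurable), or untranslated region;
7.  ``case_network``      — absent from the pedigree's AD cases and within two
    interaction connections upstream, or one downstream, of known AD
    susceptibility genes.

A variant is retained iff no rule records a fail.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import networkx as nx
from intervaltree import IntervalTree

__all__ = [
    "AnnotatedVariant",
    "FilterTrace",
    "FilterParams",
    "InteractionNetwork",
    "FILTER_NAMES",
    "apply_filter_cascade",
    "network_proximity",
    "read_bed",
    "restrict_to_capture",
    "reassign_genotype",
    "RawRecord",
]

FILTER_NAMES = (
    "resilient_sharing",
    "call_quality",
    "blacklist",
    "panel_frequency",
    "zygosity_class",
    "functional_evidence",
    "case_network",
)

PROTEIN_ALTERING = {"frameshift", "inframe_indel", "stop_loss", "missense"}
UTR = {"utr3", "utr5"}


@dataclass
class AnnotatedVariant:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    gene: str = ""
    call_quality: dict = field(default_factory=dict)  # cohort -> quality
    resilient_carriers: set = field(default_factory=set)
    case_carriers: set = field(default_factory=set)
    panel_freqs: dict = field(default_factory=dict)  # kg1000/complete_genomics/esp -> freq
    consequence: str = "other"
    splice_intron_offset: Optional[int] = None
    sift_benign: Optional[bool] = None
    bsift_gof: Optional[bool] = None
    pathogenic_flag: bool = False
    mirna_binding: bool = False
    promoter: bool = False
    enhancer: bool = False
    phylop_p: Optional[float] = None
    zygosity_class: str = "other"  # heterozygous/hemizygous/haploinsufficient_gene/other
    gain_of_function: bool = False

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError("pos is 1-based and must be >= 1")
        for f in self.panel_freqs.values():
            if f is not None and not 0.0 <= f <= 1.0:
                raise ValueError("panel frequencies must lie in [0, 1]")
        if self.splice_intron_offset is not None and self.splice_intron_offset < 0:
            raise ValueError("splice offset must be >= 0")

    @property
    def key(self) -> tuple:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class FilterTrace:
    """Ordered per-filter verdicts; retained iff no filter failed."""

    variant_key: tuple
    verdicts: dict[str, str] = field(default_factory=dict)  # pass/fail/not_applicable

    @property
    def retained(self) -> bool:
        return all(v != "fail" for v in self.verdicts.values())


@dataclass
class FilterParams:
    min_resilient_sharing: Optional[int] = None  # None -> all resilient samples
    min_call_quality: float = 20.0
    max_panel_freq: float = 0.03
    phylop_threshold: float = 0.01
    phylop_conserved_if_geq: bool = True  # literal reading of the criterion
    max_splice_intron_offset: int = 2
    seed_is_proximal: bool = True
    strict: bool = False  # not_applicable counts as fail when True


@dataclass
class InteractionNetwork:
    """Directed gene-interaction graph with AD susceptibility seed genes."""

    graph: nx.DiGraph
    seed_genes: set

    def __post_init__(self):
        self.missing_seeds = {s for s in self.seed_genes if s not in self.graph}

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str]], seed_genes: Iterable[str]):
        g = nx.DiGraph()
        g.add_edges_from(edges)
        return cls(graph=g, seed_genes=set(seed_genes))


def network_proximity(
    gene: str, network: InteractionNetwork, seed_is_proximal: bool = True
) -> bool:
    """True iff ``gene`` lies within two directed connections upstream, or one
    downstream, of a seed gene (a path gene->...->seed of length <= 2, or
    seed->gene of length <= 1).  A seed gene itself is proximal by default
    (path length 0)."""
    if gene in network.seed_genes:
        return bool(seed_is_proximal)
    if gene not in network.graph:
        return False
    reach = nx.single_source_shortest_path_length(network.graph, gene, cutoff=2)
    if any(s in reach for s in network.seed_genes):
        return True
    return any(
        network.graph.has_edge(s, gene) for s in network.seed_genes if s in network.graph
    )


def _in_blacklist_windows(v: AnnotatedVariant, trees: dict[str, IntervalTree]) -> bool:
    tree = trees.get(v.chrom)
    return bool(tree is not None and tree[v.pos - 1])


def _functional_evidence(v: AnnotatedVariant, params: FilterParams) -> Optional[bool]:
    """Disjunction of functional criteria; None when nothing is annotated."""
    conserved = None
    if v.phylop_p is not None:
        conserved = (
            v.phylop_p >= params.phylop_threshold
            if params.phylop_conserved_if_geq
            else v.phylop_p <= params.phylop_threshold
        )
    clauses: list[Optional[bool]] = [
        v.pathogenic_flag,
        v.bsift_gof,
        v.mirna_binding,
        # protein-altering and not predicted benign (no benign call counts as
        # not-benign; annotation absent iff consequence is "other")
        None if v.consequence == "other"
        else (v.consequence in PROTEIN_ALTERING and not v.sift_benign),
        None if v.splice_intron_offset is None
        else v.splice_intron_offset <= params.max_splice_intron_offset,
        v.promoter or v.enhancer,
        conserved,
        None if v.consequence == "other" else v.consequence in UTR,
    ]
    if any(c is True for c in clauses):
        return True
    nothing_annotated = (
        v.consequence == "other"
        and v.sift_benign is None
        and v.splice_intron_offset is None
        and v.phylop_p is None
        and v.bsift_gof is None
    )
    return None if nothing_annotated else False


def apply_filter_cascade(
    variants: Sequence[AnnotatedVariant],
    resilient_ids: Iterable[str],
    case_ids: Iterable[str],
    blacklist_window_trees: Optional[dict[str, IntervalTree]] = None,
    blacklist_genes: Optional[set] = None,
    network: Optional[InteractionNetwork] = None,
    params: Optional[FilterParams] = None,
) -> tuple[list[FilterTrace], list[AnnotatedVariant]]:
    """Run the seven-rule cascade; returns (traces, retained variants)."""
    params = params or FilterParams()
    resilient_ids = set(resilient_ids)
    case_ids = set(case_ids)
    blacklist_genes = blacklist_genes or set()
    blacklist_window_trees = blacklist_window_trees or {}
    need = (
        len(resilient_ids)
        if params.min_resilient_sharing is None
        else params.min_resilient_sharing
    )

    traces = [FilterTrace(variant_key=v.key) for v in variants]

    def verdict(cond: Optional[bool]) -> str:
        if cond is None:
            return "not_applicable"
        return "pass" if cond else "fail"

    for v, t in zip(variants, traces):
        shared = len(v.resilient_carriers & resilient_ids) >= need if need else True
        t.verdicts["resilient_sharing"] = verdict(shared)

        quals = [q for q in v.call_quality.values() if q is not None]
        t.verdicts["call_quality"] = verdict(
            max(quals) >= params.min_call_quality if quals else None
        )

        t.verdicts["blacklist"] = verdict(
            not _in_blacklist_windows(v, blacklist_window_trees)
            and v.gene not in blacklist_genes
        )

        freqs = [f for f in v.panel_freqs.values() if f is not None]
        t.verdicts["panel_frequency"] = verdict(
            all(f < params.max_panel_freq for f in freqs)
        )

        zyg = (
            v.gain_of_function
            or v.zygosity_class in ("heterozygous", "hemizygous", "haploinsufficient_gene")
        )
        t.verdicts["zygosity_class"] = verdict(zyg)

        t.verdicts["functional_evidence"] = verdict(_functional_evidence(v, params))

        if network is None:
            prox = None
        else:
            prox = network_proximity(v.gene, network, params.seed_is_proximal)
        absent_cases = not (v.case_carriers & case_ids)
        t.verdicts["case_network"] = verdict(
            None if prox is None else (absent_cases and prox)
        )

    # compound heterozygotes: last step of rule 5 — a heterozygous variant
    # failing the zygosity rule is rescued when some sample carries another
    # otherwise-retained heterozygous variant in the same gene
    def provisional(t: FilterTrace) -> bool:
        bad = [
            n for n, s in t.verdicts.items()
            if s == "fail" or (s == "not_applicable" and params.strict)
        ]
        return not [n for n in bad if n != "zygosity_class"]

    by_gene: dict[str, list[int]] = {}
    for i, v in enumerate(variants):
        by_gene.setdefault(v.gene, []).append(i)
    for gene, idxs in by_gene.items():
        hets = [
            i for i in idxs
            if provisional(traces[i]) and variants[i].resilient_carriers
        ]
        for i in hets:
            if traces[i].verdicts["zygosity_class"] == "pass":
                continue
            carriers = variants[i].resilient_carriers
            for j in hets:
                if j != i and carriers & variants[j].resilient_carriers:
                    traces[i].verdicts["zygosity_class"] = "pass"
                    break

    if params.strict:
        for t in traces:
            for name, s in t.verdicts.items():
                if s == "not_applicable":
                    t.verdicts[name] = "fail"

    retained = [v for v, t in zip(variants, traces) if t.retained]
    return traces, retained


# -- capture-region harmonization --------------------------------------------


def read_bed(bed_source) -> dict[str, IntervalTree]:
    """Parse a BED file (0-based half-open) into per-chromosome interval trees."""
    trees: dict[str, IntervalTree] = {}
    if hasattr(bed_source, "read"):
        lines = bed_source.read().splitlines()
    else:
        with open(bed_source, "rt", encoding="utf-8") as fh:
            lines = fh.read().splitlines()
    for lineno, line in enumerate(lines, start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) < 3:
            raise ValueError(f"BED line {lineno}: expected >= 3 columns")
        try:
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
        except ValueError as exc:
            raise ValueError(f"BED line {lineno}: {exc}") from None
        if end <= start:
            raise ValueError(f"BED line {lineno}: end must exceed start")
        trees.setdefault(chrom, IntervalTree()).addi(start, end)
    return trees


def restrict_to_capture(
    variants: Sequence[AnnotatedVariant],
    region_sets: Sequence[dict[str, IntervalTree]],
) -> list[AnnotatedVariant]:
    """Variants whose position lies inside every capture region set."""
    if not region_sets:
        raise ValueError("at least one region set is required")
    out = []
    for v in variants:
        if all(
            trees.get(v.chrom) is not None and trees[v.chrom][v.pos - 1]
            for trees in region_sets
        ):
            out.append(v)
    return out


# -- genotype reassignment ----------------------------------------------------


@dataclass
class RawRecord:
    """Per-sample raw evidence at a site: read support and filter status."""

    present: bool
    ref_reads: int = 0
    alt_reads: int = 0
    passed_filters: bool = False
    called_genotype: Optional[str] = None


def reassign_genotype(gatk_call: Optional[str], raw: RawRecord) -> tuple[str, str]:
    """Harmonize a genotype across platforms; returns (genotype, rule).

    Rule 1: a call that passed all quality filters is kept as called.
    Rule 2: no passing call but at least one alternate-supporting read ->
    genotype set to missing.  Rule 3: all reads reference -> homozygous
    reference.  A site entirely absent from the raw data is missing, logged
    under its own rule.
    """
    if not raw.present:
        return "missing", "site_absent"
    if gatk_call is not None and raw.passed_filters:
        return gatk_call, "rule1_as_called"
    if raw.alt_reads >= 1:
        return "missing", "rule2_missing"
    return "hom_ref", "rule3_hom_ref"
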