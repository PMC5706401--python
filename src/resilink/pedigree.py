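"""Genealogy data structures, LINKAGE-PED I/O, and relationship computations.

A :class:`Pedigree` is a directed acyclic genealogy: founders (individuals with
no parents inside the pedigree, including marry-in spouses) plus the descendant
closure of those founders.  All downstream stages — excess-mortality scoring,
gene dropping and parametric linkage — operate on this container.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import networkx as nx

__all__ = [
    "Individual",
    "Pedigree",
    "PedigreeError",
    "read_pedigree",
    "read_ped",
    "write_ped",
    "detect_loops",
    "kinship_coefficient",
    "inbreeding_coefficient",
]

MISSING = "0"

SEX_FROM_PED = {"1": "male", "2": "female", "0": "unknown"}
SEX_TO_PED = {"male": "1", "female": "2", "unknown": "0"}
# PED affection column: 2 = affected, 1 = unaffected, 0 = unknown.  The
# three-way study phenotype (case / resilient / unknown) cannot be expressed in
# this dialect and travels in a sidecar table instead.
AFFECTION_FROM_PED = {"2": "affected", "1": "unaffected", "0": "unknown", "-9": "unknown"}
AFFECTION_TO_PED = {"affected": "2", "unaffected": "1", "unknown": "0"}


class PedigreeError(ValueError):
    """Structural or validation error in a genealogy."""


@dataclass
class Individual:
    """One genealogy member.

    ``genotypes`` holds marker genotypes as (allele1, allele2) integer pairs
    (0 = missing), preserved verbatim from PED files for the linkage stage.
    """

    id: str
    father_id: Optional[str] = None
    mother_id: Optional[str] = None
    sex: str = "unknown"
    birth_year: Optional[int] = None
    birth_place: str = "unknown"
    ad_death: bool = False
    vital_status: str = "unknown"
    phenotype: str = "unknown"  # case / resilient / unknown (sidecar label)
    affection: str = "unknown"  # affected / unaffected / unknown (PED column)
    is_marry_in: bool = False
    genotypes: list[tuple[int, int]] = field(default_factory=list)

    @property
    def has_parents(self) -> bool:
        return self.father_id is not None or self.mother_id is not None


class Pedigree:
    """A validated genealogy: founders plus their descendant closure."""

    def __init__(self, pedigree_id: str, members: Iterable[Individual]):
        self.pedigree_id = pedigree_id
        self.members: dict[str, Individual] = {}
        for ind in members:
            if ind.id in self.members:
                raise PedigreeError(f"duplicate individual id {ind.id!r}")
            self.members[ind.id] = ind
        self._validate()

    # -- structure -----------------------------------------------------------

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, ind_id: str) -> bool:
        return ind_id in self.members

    def __getitem__(self, ind_id: str) -> Individual:
        try:
            return self.members[ind_id]
        except KeyError:
            raise KeyError(f"individual {ind_id!r} not in pedigree {self.pedigree_id!r}")

    @property
    def founder_ids(self) -> set[str]:
        """Members with neither parent inside the pedigree (marry-ins included)."""
        out = set()
        for ind in self.members.values():
            if ind.father_id not in self.members and ind.mother_id not in self.members:
                out.add(ind.id)
        return out

    def descendant_ids(self, include_marry_ins: bool = False) -> set[str]:
        """Blood members of the pedigree (descendant closure of its founders).

        Marry-in spouses carry no founder descent and are excluded from
        observed/expected mortality accounting unless requested.
        """
        if include_marry_ins:
            return set(self.members)
        return {i for i, ind in self.members.items() if not ind.is_marry_in}

    def parents_of(self, ind_id: str) -> tuple[Optional[str], Optional[str]]:
        ind = self[ind_id]
        father = ind.father_id if ind.father_id in self.members else None
        mother = ind.mother_id if ind.mother_id in self.members else None
        return father, mother

    def children_of(self, ind_id: str) -> list[str]:
        return [
            i for i, ind in self.members.items()
            if ind.father_id == ind_id or ind.mother_id == ind_id
        ]

    def topological_order(self) -> list[str]:
        """Member ids with every parent before each of its children."""
        g = self._parent_graph()
        return list(nx.topological_sort(g))

    def _parent_graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.members)
        for ind in self.members.values():
            for pid in (ind.father_id, ind.mother_id):
                if pid in self.members:
                    g.add_edge(pid, ind.id)
        return g

    def _validate(self) -> None:
        for ind in self.members.values():
            fid, mid = ind.father_id, ind.mother_id
            if fid in self.members and self.members[fid].sex == "female":
                raise PedigreeError(
                    f"{ind.id}: father {fid} is recorded as female"
                )
            if mid in self.members and self.members[mid].sex == "male":
                raise PedigreeError(
                    f"{ind.id}: mother {mid} is recorded as male"
                )
            if fid == ind.id or mid == ind.id:
                raise PedigreeError(f"{ind.id} lists itself as a parent (cycle: [{ind.id}])")
        g = self._parent_graph()
        if not nx.is_directed_acyclic_graph(g):
            cycle = [u for u, _ in nx.find_cycle(g)]
            raise PedigreeError(f"cyclic ancestry among {cycle}")
        # a parent role forces a sex
        for ind in self.members.values():
            if ind.sex == "unknown" and self.children_of(ind.id):
                raise PedigreeError(f"{ind.id} is a parent but has unknown sex")


# -- PED I/O -----------------------------------------------------------------


def _as_lines(ped_source) -> list[str]:
    if hasattr(ped_source, "read"):
        text = ped_source.read()
    else:
        with open(ped_source, "rt", encoding="utf-8") as fh:
            text = fh.read()
    return [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]


def read_ped(ped_source) -> list[Pedigree]:
    """Parse LINKAGE-style PED text (path or file object) into pedigrees.

    Columns: family, individual, father, mother, sex, affection, then optional
    genotype allele pairs.  ``0`` denotes a missing parent or allele.
    """
    families: dict[str, list[Individual]] = {}
    parent_ids: dict[str, set[str]] = {}
    for lineno, line in enumerate(_as_lines(ped_source), start=1):
        fields_ = line.split()
        if len(fields_) < 6:
            raise PedigreeError(f"PED line {lineno}: expected >= 6 columns, got {len(fields_)}")
        fam, iid, fid, mid, sex, aff = fields_[:6]
        geno_cols = fields_[6:]
        if len(geno_cols) % 2:
            raise PedigreeError(f"PED line {lineno}: odd number of genotype columns")
        genotypes = [
            (int(geno_cols[i]), int(geno_cols[i + 1])) for i in range(0, len(geno_cols), 2)
        ]
        ind = Individual(
            id=iid,
            father_id=None if fid == MISSING else fid,
            mother_id=None if mid == MISSING else mid,
            sex=SEX_FROM_PED.get(sex, "unknown"),
            affection=AFFECTION_FROM_PED.get(aff, "unknown"),
            genotypes=genotypes,
        )
        families.setdefault(fam, []).append(ind)
        parent_ids.setdefault(fam, set()).update(
            p for p in (ind.father_id, ind.mother_id) if p is not None
        )
    out = []
    for fam, members in families.items():
        known = {m.id for m in members}
        missing_parents = parent_ids[fam] - known
        if missing_parents:
            raise PedigreeError(
                f"family {fam}: parents {sorted(missing_parents)} referenced but absent"
            )
        # marry-ins: founders with a co-parent who is a non-founder, i.e. no
        # genealogy of their own but married into the descendant closure
        ped = Pedigree(fam, members)
        _flag_marry_ins(ped)
        out.append(ped)
    return out


def _flag_marry_ins(ped: Pedigree) -> None:
    """Mark founders who married into the descendant closure.

    A founder is a marry-in when every child it has was co-parented with a
    non-founder; the remaining founders are the pedigree's original couple(s).
    """
    founders = ped.founder_ids
    for fid in founders:
        kids = ped.children_of(fid)
        if not kids:
            continue
        coparents = set()
        for kid in kids:
            f, m = ped.parents_of(kid)
            coparents.update(p for p in (f, m) if p is not None and p != fid)
        if coparents and all(c not in founders for c in coparents):
            ped.members[fid].is_marry_in = True


def read_pedigree(ped_source) -> Pedigree:
    """Read a PED source expected to contain exactly one family."""
    peds = read_ped(ped_source)
    if len(peds) != 1:
        raise PedigreeError(f"expected one family, found {len(peds)}")
    return peds[0]


def write_ped(pedigrees: Sequence[Pedigree] | Pedigree, dest=None) -> str:
    """Serialize pedigrees back to LINKAGE PED text (read∘write identity)."""
    if isinstance(pedigrees, Pedigree):
        pedigrees = [pedigrees]
    buf = io.StringIO()
    for ped in pedigrees:
        for ind in ped.members.values():
            row = [
                ped.pedigree_id,
                ind.id,
                ind.father_id or MISSING,
                ind.mother_id or MISSING,
                SEX_TO_PED[ind.sex],
                AFFECTION_TO_PED[ind.affection],
            ]
            for a, b in ind.genotypes:
                row += [str(a), str(b)]
            buf.write(" ".join(row) + "\n")
    text = buf.getvalue()
    if dest is not None:
        if hasattr(dest, "write"):
            dest.write(text)
        else:
            with open(dest, "wt", encoding="utf-8") as fh:
                fh.write(text)
    return text


# -- relationship computations ----------------------------------------------


def detect_loops(ped: Pedigree) -> list[list[str]]:
    """Cycles in the marriage-node graph (consanguinity / multiple-mating loops).

    The marriage-node graph joins each mating pair through a marriage node and
    links marriage nodes to their children.  A zero-loop pedigree (a tree of
    nuclear families) returns ``[]``; each independent loop is reported as the
    list of individual ids on it.
    """
    g = nx.Graph()
    for ind in ped.members.values():
        g.add_node(("i", ind.id))
        f, m = ped.parents_of(ind.id)
        if f is not None or m is not None:
            mnode = ("m", f, m)
            g.add_node(mnode)
            if f is not None:
                g.add_edge(("i", f), mnode)
            if m is not None:
                g.add_edge(("i", m), mnode)
            g.add_edge(mnode, ("i", ind.id))
    loops = []
    for cyc in nx.cycle_basis(g):
        loops.append([n[1] for n in cyc if n[0] == "i"])
    return loops


def _depth(ped: Pedigree, memo: dict[str, int], ind_id: str) -> int:
    if ind_id in memo:
        return memo[ind_id]
    f, m = ped.parents_of(ind_id)
    d = 0 if f is None and m is None else 1 + max(
        _depth(ped, memo, p) for p in (f, m) if p is not None
    )
    memo[ind_id] = d
    return d


def kinship_coefficient(ped: Pedigree, a: str, b: str) -> float:
    """Recursive kinship coefficient phi(a, b).

    phi(a, a) = (1 + f_a) / 2 with f_a the inbreeding coefficient (parental
    kinship); parent–child and full sibs give 0.25 in a non-inbred pedigree,
    first cousins 0.0625.  Symmetric in (a, b).
    """
    if a not in ped.members or b not in ped.members:
        missing = a if a not in ped.members else b
        raise KeyError(f"individual {missing!r} not in pedigree")
    depth_memo: dict[str, int] = {}
    memo: dict[tuple[str, str], float] = {}

    def phi(x: str, y: str) -> float:
        key = (x, y) if x <= y else (y, x)
        if key in memo:
            return memo[key]
        if x == y:
            f, m = ped.parents_of(x)
            val = 0.5 if f is None or m is None else 0.5 * (1.0 + phi(f, m))
        else:
            # recurse on the individual further from the founders; it cannot
            # be an ancestor of the other, so the recursion terminates
            if _depth(ped, depth_memo, x) < _depth(ped, depth_memo, y):
                x, y = y, x
            f, m = ped.parents_of(x)
            if f is None and m is None:
                val = 0.0
            else:
                val = 0.5 * sum(phi(p, y) for p in (f, m) if p is not None)
                if f is None or m is None:
                    pass  # missing parent contributes kinship 0
        memo[key] = val
        return val

    return phi(a, b)


def inbreeding_coefficient(ped: Pedigree, a: str) -> float:
    """f_a = kinship of a's parents (0 for founders or half-known parentage)."""
    f, m = ped.parents_of(a)
    if f is None or m is None:
        return 0.0
    return kinship_coefficient(ped, f, m)
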