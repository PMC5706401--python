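"""Parametric dominant-model two-point linkage on extended pedigrees.

The likelihood is the exact joint probability of observed phenotypes and
marker genotypes under a single-locus trait model linked to one marker at
recombination fraction theta:

* founders carry two-locus haplotypes drawn at Hardy–Weinberg and linkage
  equilibrium (trait allele frequency ``q``, marker allele frequencies from
  the data or supplied);
* each meiosis transmits one parental haplotype, recombining between the two
  loci with probability theta;
* penetrance acts on the trait genotype (carrier vs non-carrier under a
  dominant model); phenotype ``unknown`` contributes a factor of one.

The joint sum over unobserved two-locus genotypes is computed by variable
elimination on the pedigree's Bayes network — a generalized Elston–Stewart
peeling that is exact for zero-loop pedigrees (and for small looped ones).
A brute-force enumeration over all genotype assignments is kept as an
independent reference path (``enumerate_two_locus_loglik``).

The TLOD is the theta-maximized log10 likelihood ratio against theta = 0.5;
scores above 1.86 are classified suggestive and above 3.30 significant, the
conventional genome-wide thresholds for this design.
"""

from __future__ import annotations

import string
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .pedigree import Pedigree, detect_loops

__all__ = [
    "TraitModel",
    "Marker",
    "MarkerMap",
    "LodProfile",
    "MarkerLod",
    "LoopedPedigreeError",
    "SUGGESTIVE_TLOD",
    "SIGNIFICANT_TLOD",
    "DEFAULT_THETA_GRID",
    "read_map",
    "prune_markers",
    "pedigree_loglik",
    "trait_loglik",
    "marker_loglik",
    "enumerate_two_locus_loglik",
    "two_point_tlod",
    "scan",
    "estimate_allele_freqs",
]

SUGGESTIVE_TLOD = 1.86
SIGNIFICANT_TLOD = 3.30
DEFAULT_THETA_GRID = (0.0, 0.01, 0.05, 0.1, 0.15, 0.2, 0.3, 0.4, 0.5)

LN10 = np.log(10.0)


class LoopedPedigreeError(ValueError):
    """Raised when exact peeling is requested on an unsupported looped pedigree."""


@dataclass(frozen=True)
class TraitModel:
    """Single-locus disease model.

    Defaults are the general dominant model used for resilience linkage:
    disease allele frequency 0.005 with carrier / non-carrier penetrances
    0.5 and 0.0005.
    """

    disease_allele_freq: float = 0.005
    penetrance_carrier: float = 0.5
    penetrance_noncarrier: float = 0.0005
    inheritance: str = "dominant"

    def __post_init__(self):
        for v in (self.disease_allele_freq, self.penetrance_carrier, self.penetrance_noncarrier):
            if not 0.0 <= v <= 1.0:
                raise ValueError("trait-model probabilities must lie in [0, 1]")
        if self.inheritance not in ("dominant", "recessive"):
            raise ValueError(f"unknown inheritance {self.inheritance!r}")

    def penetrance(self, n_disease_alleles: int) -> float:
        if self.inheritance == "dominant":
            carrier = n_disease_alleles >= 1
        else:
            carrier = n_disease_alleles == 2
        return self.penetrance_carrier if carrier else self.penetrance_noncarrier


@dataclass(frozen=True)
class Marker:
    name: str
    chromosome: str
    position_bp: int
    allele_freqs: Optional[tuple[float, ...]] = None


@dataclass
class MarkerMap:
    """Ordered marker positions; positions must increase within a chromosome."""

    markers: list[Marker]

    def __post_init__(self):
        last: dict[str, int] = {}
        for m in self.markers:
            if m.chromosome in last and m.position_bp <= last[m.chromosome]:
                raise ValueError(
                    f"marker {m.name}: positions must strictly increase within chromosome"
                )
            last[m.chromosome] = m.position_bp

    def __len__(self) -> int:
        return len(self.markers)


def read_map(map_source) -> MarkerMap:
    """Read a LINKAGE MAP file: chromosome, name, [cM,] bp position."""
    df = pd.read_csv(map_source, sep=r"\s+", header=None, comment="#", dtype=str)
    if df.shape[1] == 3:
        df.columns = ["chrom", "name", "pos"]
    elif df.shape[1] >= 4:
        df = df.iloc[:, :4]
        df.columns = ["chrom", "name", "cm", "pos"]
    else:
        raise ValueError("MAP file needs 3 or 4 columns")
    markers = [
        Marker(name=r["name"], chromosome=r["chrom"], position_bp=int(r["pos"]))
        for _, r in df.iterrows()
    ]
    return MarkerMap(markers)


# -- marker panel pruning ----------------------------------------------------


def prune_markers(
    geno_pairs: np.ndarray,
    min_heterozygosity: float = 0.3,
    max_r2: float = 0.5,
    window: int = 50,
) -> np.ndarray:
    """Greedy left-to-right panel reduction to high-heterozygosity, low-LD markers.

    ``geno_pairs``: integer array (n_individuals, n_markers, 2) of allele codes
    (0 = missing), typically founders only so LD reflects population structure
    rather than co-segregation.  A marker is kept iff its observed
    heterozygosity is at least ``min_heterozygosity`` and its squared allelic
    correlation with every already-kept marker within the trailing ``window``
    is at most ``max_r2``.  Returns the kept marker indices.
    """
    geno = np.asarray(geno_pairs)
    n_ind, n_mark, _ = geno.shape
    observed = (geno > 0).all(axis=2)
    het = np.zeros(n_mark)
    dose = np.full((n_ind, n_mark), np.nan)
    for j in range(n_mark):
        obs = observed[:, j]
        if obs.sum() == 0:
            continue
        g = geno[obs, j, :]
        het[j] = (g[:, 0] != g[:, 1]).mean()
        minor = 2  # dosage of allele code 2 ("alt") by convention
        dose[obs, j] = (g == minor).sum(axis=1)
    kept: list[int] = []
    for j in range(n_mark):
        if het[j] < min_heterozygosity:
            continue
        ok = True
        for k in reversed(kept):
            if j - k > window:
                break
            both = observed[:, j] & observed[:, k]
            if both.sum() < 3:
                continue
            a, b = dose[both, j], dose[both, k]
            if a.std() == 0 or b.std() == 0:
                continue
            r = np.corrcoef(a, b)[0, 1]
            if r * r > max_r2:
                ok = False
                break
        if ok:
            kept.append(j)
    if not kept:
        warnings.warn("all markers pruned: empty panel")
    return np.asarray(kept, dtype=int)


def estimate_allele_freqs(
    ped: Pedigree, marker_index: int, n_alleles: int = 2
) -> np.ndarray:
    """Marker allele frequencies from founder genotypes (all members as fallback)."""

    def counts(ids):
        c = np.zeros(n_alleles)
        for iid in ids:
            genos = ped[iid].genotypes
            if marker_index < len(genos):
                for a in genos[marker_index]:
                    if a > 0:
                        c[a - 1] += 1
        return c

    c = counts(ped.founder_ids)
    if c.sum() == 0:
        warnings.warn("no typed founders; estimating allele frequencies from all members")
        c = counts(ped.members)
    if c.sum() == 0:
        return np.full(n_alleles, 1.0 / n_alleles)
    return c / c.sum()


# -- exact likelihood by variable elimination --------------------------------


def _eliminate(factors, order, batch_ndim):
    """Sum-product variable elimination; returns log of the summed-out product.

    ``factors`` is a list of (vars, array) with array shape
    batch_shape + (S,) * len(vars).  Uses einsum with per-variable letters and
    an ellipsis for the batch axes; rescales after every elimination so that
    likelihoods far below float range stay representable.
    """
    letters = {v: string.ascii_letters[i] for i, v in enumerate(
        dict.fromkeys(v for vars_, _ in factors for v in vars_)
    )}
    if len(letters) > 52:
        raise ValueError("pedigree too large for the elimination engine (>52 members)")
    factors = list(factors)
    log_scale = 0.0
    for v in order:
        bucket = [f for f in factors if v in f[0]]
        if not bucket:
            continue
        factors = [f for f in factors if v not in f[0]]
        out_vars = tuple(dict.fromkeys(
            u for vars_, _ in bucket for u in vars_ if u != v
        ))
        subs = ",".join("..." + "".join(letters[u] for u in vars_) for vars_, _ in bucket)
        subs += "->..." + "".join(letters[u] for u in out_vars)
        arr = np.einsum(subs, *[a for _, a in bucket])
        state_axes = tuple(range(arr.ndim - len(out_vars), arr.ndim))
        scale = np.max(arr, axis=state_axes) if state_axes else arr
        scale = np.asarray(scale, dtype=float)
        safe = np.where(scale > 0, scale, 1.0)
        arr = arr / safe.reshape(safe.shape + (1,) * len(out_vars))
        with np.errstate(divide="ignore"):
            log_scale = log_scale + np.log(scale)
        factors.append((out_vars, arr))
    # remaining factors are batch-shaped scalars
    total = np.asarray(1.0)
    for vars_, arr in factors:
        assert not vars_
        total = total * arr
    with np.errstate(divide="ignore"):
        return np.log(total) + log_scale


def _elimination_order(ped: Pedigree) -> list[str]:
    """Min-degree greedy order on the moralized pedigree graph."""
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(ped.members)
    for iid in ped.members:
        f, m = ped.parents_of(iid)
        ps = [p for p in (f, m) if p is not None]
        for p in ps:
            g.add_edge(p, iid)
        if len(ps) == 2:
            g.add_edge(ps[0], ps[1])
    order = []
    g = g.copy()
    while g.number_of_nodes():
        v = min(g.nodes, key=lambda n: (g.degree(n), str(n)))
        nbrs = list(g.neighbors(v))
        for i in range(len(nbrs)):
            for j in range(i + 1, len(nbrs)):
                g.add_edge(nbrs[i], nbrs[j])
        g.remove_node(v)
        order.append(v)
    return order


def _two_locus_tables(model: TraitModel, marker_freqs: np.ndarray, thetas: np.ndarray):
    """Founder prior (S,), transmission (T, S, S_f, S_m), and state metadata.

    Haplotype index h = t * k + m with t in {0: wild, 1: disease} and m a
    marker allele (0-based); ordered genotype s = paternal_h * H + maternal_h.
    """
    k = len(marker_freqs)
    H = 2 * k
    q = model.disease_allele_freq
    hap_p = np.empty(H)
    for t in (0, 1):
        hap_p[t * k : (t + 1) * k] = ((1 - q), q)[t] * np.asarray(marker_freqs)
    prior = np.outer(hap_p, hap_p).reshape(-1)  # (S,)

    hap_t = np.arange(H) // k
    hap_m = np.arange(H) % k
    S = H * H
    pat = np.arange(S) // H
    mat = np.arange(S) % H
    T = len(thetas)
    th = thetas.reshape(T, 1, 1)
    # P(transmitted hap (t,m) | parent ordered genotype s)
    t1, m1 = hap_t[pat], hap_m[pat]
    t2, m2 = hap_t[mat], hap_m[mat]
    ht = hap_t.reshape(1, H, 1)
    hm = hap_m.reshape(1, H, 1)
    half = 0.5 * (
        (ht == t1) * ((1 - th) * (hm == m1) + th * (hm == m2))
        + (ht == t2) * ((1 - th) * (hm == m2) + th * (hm == m1))
    )  # (T, H, S)
    trans = np.einsum("tps,tqm->tpqsm", half, half).reshape(T, S, S, S)
    meta = {"k": k, "H": H, "S": S, "pat": pat, "mat": mat, "hap_t": hap_t, "hap_m": hap_m}
    return prior, trans, meta


def _phenotype_factor(model: TraitModel, affection: str, n_dis: np.ndarray) -> np.ndarray:
    if affection == "unknown":
        return np.ones_like(n_dis, dtype=float)
    pen = np.where(
        (n_dis >= 1) if model.inheritance == "dominant" else (n_dis == 2),
        model.penetrance_carrier,
        model.penetrance_noncarrier,
    )
    return pen if affection == "affected" else 1.0 - pen


def _marker_factor(obs: tuple[int, int], pat_m: np.ndarray, mat_m: np.ndarray) -> np.ndarray:
    a, b = obs
    if a == 0 or b == 0:
        return np.ones_like(pat_m, dtype=float)
    a -= 1
    b -= 1
    return (((pat_m == a) & (mat_m == b)) | ((pat_m == b) & (mat_m == a))).astype(float)


def pedigree_loglik(
    ped: Pedigree,
    marker_genotypes: dict[str, tuple[int, int]],
    model: TraitModel,
    marker_freqs: Sequence[float],
    theta,
    affection: Optional[dict[str, str]] = None,
    allow_loops_up_to: int = 12,
) -> np.ndarray:
    """Exact log pedigree likelihood of phenotypes and one marker, batched over theta.

    Returns an array of natural-log likelihoods, one per theta (scalar theta
    accepted).  Mendelian-inconsistent genotypes yield -inf (a zero-likelihood
    flag), never a silent underflow.  Looped pedigrees beyond
    ``allow_loops_up_to`` members raise :class:`LoopedPedigreeError`.
    """
    thetas = np.atleast_1d(np.asarray(theta, dtype=float))
    if np.any((thetas < 0) | (thetas > 0.5)):
        raise ValueError("theta must lie in [0, 0.5]")
    if detect_loops(ped) and len(ped) > allow_loops_up_to:
        raise LoopedPedigreeError(
            f"pedigree {ped.pedigree_id} has marriage loops and {len(ped)} members; "
            f"exact evaluation is only supported for looped pedigrees of "
            f"<= {allow_loops_up_to} members"
        )
    marker_freqs = np.asarray(marker_freqs, dtype=float)
    prior, trans, meta = _two_locus_tables(model, marker_freqs, thetas)
    k, H = meta["k"], meta["H"]
    pat_m = meta["hap_m"][meta["pat"]]
    mat_m = meta["hap_m"][meta["mat"]]
    n_dis = meta["hap_t"][meta["pat"]] + meta["hap_t"][meta["mat"]]

    factors = []
    for iid, ind in ped.members.items():
        f, m = ped.parents_of(iid)
        if f is None and m is None:
            factors.append(((iid,), prior))
        elif f is not None and m is not None:
            factors.append(((iid, f, m), trans))
        elif f is not None:
            # unknown mother integrated out against the founder prior
            partial = np.einsum("tcfm,m->tcf", trans, prior)
            factors.append(((iid, f), partial))
        else:
            partial = np.einsum("tcfm,f->tcm", trans, prior)
            factors.append(((iid, m), partial))
        aff = (affection or {}).get(iid, ind.affection)
        ev = _phenotype_factor(model, aff, n_dis)
        obs = marker_genotypes.get(iid, (0, 0))
        ev = ev * _marker_factor(obs, pat_m, mat_m)
        factors.append(((iid,), ev))
    order = _elimination_order(ped)
    ll = _eliminate(factors, order, batch_ndim=1)
    # pedigrees without transmissions carry no theta axis; broadcast it back
    return np.broadcast_to(np.asarray(ll, dtype=float), thetas.shape).copy()


def trait_loglik(ped: Pedigree, model: TraitModel,
                 affection: Optional[dict[str, str]] = None) -> float:
    """Log likelihood of phenotypes alone (no marker data)."""
    ll = pedigree_loglik(ped, {}, model, [1.0], 0.5, affection=affection)
    return float(np.atleast_1d(ll)[0])


def marker_loglik(
    ped: Pedigree,
    marker_genotypes: dict[str, tuple[int, int]],
    marker_freqs: Sequence[float],
) -> float:
    """Log likelihood of one marker's genotypes alone (no phenotype data)."""
    null = TraitModel(disease_allele_freq=0.0, penetrance_carrier=0.5,
                      penetrance_noncarrier=0.5)
    ll = pedigree_loglik(ped, marker_genotypes, null, marker_freqs, 0.5,
                         affection={iid: "unknown" for iid in ped.members})
    return float(np.atleast_1d(ll)[0])


# -- brute-force reference ---------------------------------------------------


def enumerate_two_locus_loglik(
    ped: Pedigree,
    marker_genotypes: dict[str, tuple[int, int]],
    model: TraitModel,
    marker_freqs: Sequence[float],
    theta: float,
    affection: Optional[dict[str, str]] = None,
) -> float:
    """Brute-force sum over all two-locus ordered genotype assignments.

    Exponential in pedigree size; kept as an independent reference path for
    validating the elimination engine on small pedigrees.  Implements the
    generative model directly with scalar arithmetic: founder haplotype priors,
    per-meiosis transmission with recombination, penetrance and genotype
    observation, accumulated over a depth-first enumeration (zero branches
    pruned).
    """
    marker_freqs = np.asarray(marker_freqs, dtype=float)
    k = len(marker_freqs)
    H = 2 * k
    q = model.disease_allele_freq

    def hap_prob(h):
        t, m = divmod(h, k)
        return (q if t else 1.0 - q) * marker_freqs[m]

    def transmit_prob(h, parent_state):
        hp, hm = divmod(parent_state, H)
        t, m = divmod(h, k)
        t1, m1 = divmod(hp, k)
        t2, m2 = divmod(hm, k)
        p = 0.0
        if t == t1:
            p += 0.5 * ((1 - theta) * (m == m1) + theta * (m == m2))
        if t == t2:
            p += 0.5 * ((1 - theta) * (m == m2) + theta * (m == m1))
        return p

    def evid(iid, s):
        ind = ped[iid]
        hp, hm = divmod(s, H)
        tp, mp = divmod(hp, k)
        tm, mm = divmod(hm, k)
        w = 1.0
        aff = (affection or {}).get(iid, ind.affection)
        if aff != "unknown":
            pen = model.penetrance(tp + tm)
            w *= pen if aff == "affected" else 1.0 - pen
        a, b = marker_genotypes.get(iid, (0, 0))
        if a and b and sorted((mp, mm)) != sorted((a - 1, b - 1)):
            return 0.0
        return w

    order = ped.topological_order()
    total = 0.0

    def rec(i, assign, weight):
        nonlocal total
        if i == len(order):
            total += weight
            return
        iid = order[i]
        f, m = ped.parents_of(iid)
        for s in range(H * H):
            hp, hm = divmod(s, H)
            w = weight
            if f is None:
                w *= hap_prob(hp)
            else:
                w *= transmit_prob(hp, assign[f])
            if w == 0.0:
                continue
            if m is None:
                w *= hap_prob(hm)
            else:
                w *= transmit_prob(hm, assign[m])
            if w == 0.0:
                continue
            w *= evid(iid, s)
            if w == 0.0:
                continue
            assign[iid] = s
            rec(i + 1, assign, w)
        assign.pop(iid, None)

    rec(0, {}, 1.0)
    with np.errstate(divide="ignore"):
        return float(np.log(total)) if total > 0 else float("-inf")


# -- TLOD scan ---------------------------------------------------------------


@dataclass
class MarkerLod:
    marker: Marker
    tlod: float
    theta_hat: float


@dataclass
class LodProfile:
    """Per-marker TLOD profile with classification and 1-LOD support interval."""

    marker_lods: list[MarkerLod]
    max_tlod: float
    best_marker: Optional[Marker]
    classification: str  # none / suggestive / significant
    support_interval: Optional[tuple[str, int, int]]  # (chrom, start_bp, end_bp)
    support_marker_indices: list[int] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "marker": [ml.marker.name for ml in self.marker_lods],
                "chrom": [ml.marker.chromosome for ml in self.marker_lods],
                "pos": [ml.marker.position_bp for ml in self.marker_lods],
                "tlod": [ml.tlod for ml in self.marker_lods],
                "theta_hat": [ml.theta_hat for ml in self.marker_lods],
            }
        )


def two_point_tlod(
    ped: Pedigree,
    marker_genotypes: dict[str, tuple[int, int]],
    model: TraitModel,
    marker_freqs: Sequence[float],
    theta_grid: Sequence[float] = DEFAULT_THETA_GRID,
    affection: Optional[dict[str, str]] = None,
) -> tuple[float, float]:
    """Theta-maximized log10 likelihood ratio against theta = 0.5.

    Returns (tlod, theta_hat).  The grid must contain 0.5, which pins the
    ratio's denominator and guarantees tlod >= 0.
    """
    grid = np.asarray(sorted(set(float(t) for t in theta_grid)))
    if 0.5 not in grid:
        raise ValueError("theta grid must contain 0.5")
    ll = pedigree_loglik(ped, marker_genotypes, model, marker_freqs, grid,
                         affection=affection)
    ll = np.atleast_1d(ll)
    ll05 = ll[grid == 0.5][0]
    if not np.isfinite(ll05):
        raise ValueError("zero likelihood at theta=0.5: Mendelian-inconsistent genotypes")
    lods = (ll - ll05) / LN10
    i = int(np.argmax(lods))
    return float(lods[i]), float(grid[i])


def classify_tlod(tlod: float) -> str:
    if tlod > SIGNIFICANT_TLOD:
        return "significant"
    if tlod > SUGGESTIVE_TLOD:
        return "suggestive"
    return "none"


def scan(
    ped: Pedigree,
    marker_map: MarkerMap,
    model: TraitModel,
    theta_grid: Sequence[float] = DEFAULT_THETA_GRID,
    marker_freqs: Optional[Sequence[Sequence[float]]] = None,
    affection: Optional[dict[str, str]] = None,
    merge_gap: int = 3,
) -> LodProfile:
    """Two-point TLOD scan over a marker panel with 1-LOD support interval.

    Marker genotypes are taken from each member's PED genotype columns, in map
    order.  The support region is the run of markers around the argmax whose
    TLOD is within 1 unit of the maximum; runs of fewer than ``merge_gap``
    sub-threshold markers are bridged, because two-point profiles are jagged —
    a marker whose key meioses are uninformative scores near zero even when it
    sits inside a linked region — and bridging merges adjacent peaks the way
    the fine-mapping step treats them.  The reported genomic interval extends
    to the first flanking marker beyond the run on each side: the 1-LOD
    crossing lies between that marker and the last in-support one.
    """
    mls: list[MarkerLod] = []
    for j, marker in enumerate(marker_map.markers):
        genos = {
            iid: ind.genotypes[j]
            for iid, ind in ped.members.items()
            if j < len(ind.genotypes)
        }
        if marker_freqs is not None:
            freqs = np.asarray(marker_freqs[j], dtype=float)
        elif marker.allele_freqs is not None:
            freqs = np.asarray(marker.allele_freqs, dtype=float)
        else:
            freqs = estimate_allele_freqs(ped, j)
        tlod, th = two_point_tlod(ped, genos, model, freqs, theta_grid, affection)
        mls.append(MarkerLod(marker, tlod, th))
    tlods = np.array([ml.tlod for ml in mls])
    i_max = int(np.argmax(tlods))
    max_tlod = float(tlods[i_max])
    in_support = tlods >= max_tlod - 1.0
    # expand around the argmax, bridging runs of < merge_gap excluded markers
    # on the same chromosome
    chrom = mls[i_max].marker.chromosome
    idx = [i_max]
    for step in (-1, 1):
        j = i_max + step
        gap = 0
        while 0 <= j < len(mls) and mls[j].marker.chromosome == chrom:
            if in_support[j]:
                idx.append(j)
                gap = 0
            else:
                gap += 1
                if gap >= max(1, merge_gap):
                    break
            j += step
    # extend to the flanking markers bounding the 1-LOD crossings
    lo, hi = min(idx), max(idx)
    if lo > 0 and mls[lo - 1].marker.chromosome == chrom:
        idx.append(lo - 1)
    if hi < len(mls) - 1 and mls[hi + 1].marker.chromosome == chrom:
        idx.append(hi + 1)
    idx.sort()
    support = (
        chrom,
        mls[idx[0]].marker.position_bp,
        mls[idx[-1]].marker.position_bp,
    )
    return LodProfile(
        marker_lods=mls,
        max_tlod=max_tlod,
        best_marker=mls[i_max].marker,
        classification=classify_tlod(max_tlod),
        support_interval=support,
        support_marker_indices=idx,
    )
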