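"""Mitochondrial-genome phylogenetics: GTR+Gamma distances, NJ, bootstrap, dating.

The pipeline mirrors the classical distance workflow for whole-mtDNA
haplotypes: maximum-likelihood pairwise distances under a single
alignment-wide GTR(+Gamma) parameterisation, neighbor-joining on the
distance matrix, nonparametric bootstrap over alignment columns, and a
relative-rate ("RelTime"-style) conversion of branch lengths into node
ages anchored on an outgroup calibration interval.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import dendropy
import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import gamma as _gamma

NUCLEOTIDES = "ACGT"
_CODE = {c: i for i, c in enumerate(NUCLEOTIDES)}
_CODE.update({c.lower(): i for i, c in enumerate(NUCLEOTIDES)})

__all__ = [
    "GtrModel",
    "discrete_gamma_rates",
    "pairwise_distances",
    "estimate_gtr_params",
    "nj_tree",
    "bipartitions",
    "bootstrap_support",
    "divergence_times",
    "relative_node_heights",
]


def discrete_gamma_rates(shape: float, n_categories: int) -> np.ndarray:
    """Mean rates of the equal-probability discrete Gamma categories.

    Yang's (1994) discretisation: the mean-1 Gamma(shape, 1/shape)
    distribution is cut at its ``i/K`` quantiles and each category is
    represented by its conditional mean. Rates are renormalised to mean 1.
    """
    if shape <= 0:
        raise ValueError("gamma shape must be positive")
    k = int(n_categories)
    if k < 1:
        raise ValueError("need at least one rate category")
    if k == 1:
        return np.ones(1)
    edges = np.concatenate(
        [[0.0], _gamma.ppf(np.arange(1, k) / k, a=shape, scale=1.0 / shape), [np.inf]]
    )
    # E[X 1(a<X<b)] for mean-1 Gamma(shape) equals the shape+1 CDF mass.
    mass = np.diff(_gamma.cdf(edges, a=shape + 1.0, scale=1.0 / shape))
    rates = k * mass
    return rates / rates.mean()


@dataclass(frozen=True)
class GtrModel:
    """General time-reversible substitution model with optional +Gamma rates.

    Parameters
    ----------
    exchangeabilities:
        Six symmetric rates in the order (AC, AG, AT, CG, CT, GT).
    base_freqs:
        Equilibrium frequencies of A, C, G, T.
    gamma_shape:
        Shape of the discrete Gamma rate distribution across sites;
        ``None`` means rate homogeneity.
    n_categories:
        Number of discrete Gamma categories (ignored when gamma_shape is None).
    """

    exchangeabilities: Tuple[float, ...] = (1.0, 1.0, 1.0, 1.0, 1.0, 1.0)
    base_freqs: Tuple[float, ...] = (0.25, 0.25, 0.25, 0.25)
    gamma_shape: Optional[float] = 0.3734
    n_categories: int = 5

    def __post_init__(self):
        ex = np.asarray(self.exchangeabilities, dtype=float)
        pi = np.asarray(self.base_freqs, dtype=float)
        if ex.shape != (6,) or np.any(ex <= 0):
            raise ValueError("need 6 positive exchangeabilities (AC,AG,AT,CG,CT,GT)")
        if pi.shape != (4,) or np.any(pi <= 0) or not np.isclose(pi.sum(), 1.0):
            raise ValueError("base frequencies must be 4 positive values summing to 1")
        if self.gamma_shape is not None and self.gamma_shape <= 0:
            raise ValueError("gamma shape must be positive or None")

    @classmethod
    def jc(cls, gamma_shape: Optional[float] = None, n_categories: int = 5) -> "GtrModel":
        """Jukes-Cantor parameterisation (equal rates and frequencies)."""
        return cls((1.0,) * 6, (0.25,) * 4, gamma_shape, n_categories)

    def rate_matrix(self) -> np.ndarray:
        """Normalised instantaneous rate matrix Q (1 expected subst/site/unit)."""
        s = np.zeros((4, 4))
        ac, ag, at, cg, ct, gt = self.exchangeabilities
        s[0, 1] = s[1, 0] = ac
        s[0, 2] = s[2, 0] = ag
        s[0, 3] = s[3, 0] = at
        s[1, 2] = s[2, 1] = cg
        s[1, 3] = s[3, 1] = ct
        s[2, 3] = s[3, 2] = gt
        pi = np.asarray(self.base_freqs)
        q = s * pi[None, :]
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        mu = -(pi * np.diag(q)).sum()
        return q / mu

    def category_rates(self) -> np.ndarray:
        if self.gamma_shape is None:
            return np.ones(1)
        return discrete_gamma_rates(self.gamma_shape, self.n_categories)


class EigenGtr:
    """Spectral decomposition of a GTR model for fast P(t) and dP/dt."""

    def __init__(self, model: GtrModel):
        self.model = model
        pi = np.asarray(model.base_freqs)
        q = model.rate_matrix()
        ps = np.sqrt(pi)
        b = ps[:, None] * q / ps[None, :]
        b = 0.5 * (b + b.T)
        lam, v = np.linalg.eigh(b)
        self.lam = lam
        self.right = v / ps[:, None]        # P(t) = right @ diag(e^{lam t}) @ left
        self.left = v.T * ps[None, :]
        self.rates = model.category_rates()
        self.pi = pi

    def prob(self, t: float) -> np.ndarray:
        """Per-category transition matrices, shape (K, 4, 4)."""
        if t == 0.0:
            return np.broadcast_to(np.eye(4), (len(self.rates), 4, 4)).copy()
        e = np.exp(np.outer(self.rates, self.lam) * t)        # (K, 4)
        p = np.einsum("aj,kj,jb->kab", self.right, e, self.left)
        p = np.clip(p, 0.0, None)
        return p / p.sum(axis=2, keepdims=True)

    def mixture_and_deriv(self, t: float) -> Tuple[np.ndarray, np.ndarray]:
        """Category-averaged P(t) and dP/dt (4x4 each)."""
        scaled = np.outer(self.rates, self.lam)               # (K, 4)
        e = np.exp(scaled * t)
        m = np.einsum("aj,kj,jb->ab", self.right, e, self.left) / len(self.rates)
        dm = np.einsum("aj,kj,jb->ab", self.right, e * scaled, self.left) / len(self.rates)
        return m, dm


def encode_sequence(seq: str) -> np.ndarray:
    """A/C/G/T (any case) -> 0..3; gaps and ambiguity codes -> -1."""
    return np.array([_CODE.get(c, -1) for c in seq], dtype=np.int64)


def _pattern_counts(ci: np.ndarray, cj: np.ndarray) -> np.ndarray:
    mask = (ci >= 0) & (cj >= 0)
    return np.bincount(ci[mask] * 4 + cj[mask], minlength=16).reshape(4, 4)


def ml_distance(counts: np.ndarray, eig: EigenGtr, t_max: float = 50.0) -> float:
    """ML evolutionary distance for one pair from its 4x4 site-pattern counts.

    Maximises the pairwise likelihood sum N_xy log(pi_x * mean_k P_k(t)[x,y])
    by solving the score equation with Brent root-finding; the pi_x factor is
    independent of t and drops out of the score. Returns +inf (with a warning)
    when the pair is saturated beyond ``t_max`` substitutions/site.
    """
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    if n <= 0:
        raise ValueError("no pairwise-complete sites")
    if counts.trace() == n:
        return 0.0

    def score(t: float) -> float:
        m, dm = eig.mixture_and_deriv(t)
        return float((counts * (dm / np.maximum(m, 1e-300))).sum())

    lo = 1e-9
    if score(lo) <= 0.0:
        return 0.0
    hi = 0.1
    while score(hi) > 0.0:
        hi *= 2.0
        if hi > t_max:
            warnings.warn("saturated pair: ML distance beyond t_max, returning inf")
            return np.inf
    return brentq(score, lo, hi, xtol=1e-14, rtol=8.9e-16, maxiter=200)


def pairwise_distances(
    alignment: Mapping[str, str],
    model: GtrModel,
    min_complete_sites: int = 100,
) -> Tuple[List[str], np.ndarray]:
    """ML pairwise distance matrix under one shared GTR(+Gamma) parameterisation.

    Model parameters are fixed alignment-wide (the composite/shared-parameter
    convention); only the branch length of each pair is optimised. Sites with
    a gap or ambiguity in either member of a pair are excluded pairwise.
    """
    labels = list(alignment)
    if len(labels) < 2:
        raise ValueError("need at least 2 taxa")
    lengths = {len(s) for s in alignment.values()}
    if len(lengths) != 1:
        raise ValueError("alignment rows must have equal length")
    codes = [encode_sequence(alignment[lab]) for lab in labels]
    eig = EigenGtr(model)
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            counts = _pattern_counts(codes[i], codes[j])
            if counts.sum() < min_complete_sites:
                warnings.warn(
                    f"pair ({labels[i]}, {labels[j]}): only {int(counts.sum())} "
                    f"pairwise-complete sites (< {min_complete_sites})"
                )
            d[i, j] = d[j, i] = ml_distance(counts, eig)
    return labels, d


def estimate_gtr_params(
    alignment: Mapping[str, str],
    gamma_shape: Optional[float] = 0.3734,
    n_categories: int = 5,
    pseudocount: float = 1.0,
) -> GtrModel:
    """Moment-style GTR parameter estimate from the full alignment.

    Base frequencies are the observed nucleotide proportions; each
    exchangeability is the pooled symmetric mismatch count over all pairs,
    scaled by 1/(pi_i pi_j) and normalised to the GT rate. A quick, documented
    heuristic (not a full ML fit) that fixes one parameterisation for all
    pairwise distances.
    """
    labels = list(alignment)
    codes = [encode_sequence(alignment[lab]) for lab in labels]
    stacked = np.concatenate(codes)
    stacked = stacked[stacked >= 0]
    if stacked.size == 0:
        raise ValueError("alignment contains no unambiguous nucleotides")
    pi = np.bincount(stacked, minlength=4).astype(float)
    pi = pi / pi.sum()
    pooled = np.zeros((4, 4))
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            pooled += _pattern_counts(codes[i], codes[j])
    sym = pooled + pooled.T
    pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
    ex = np.array([(sym[a, b] + pseudocount) / (pi[a] * pi[b]) for a, b in pairs])
    ex = ex / ex[-1]
    return GtrModel(tuple(ex), tuple(pi), gamma_shape, n_categories)


# ---------------------------------------------------------------------------
# Neighbor-joining
# ---------------------------------------------------------------------------


def nj_tree(labels: Sequence[str], matrix: np.ndarray) -> dendropy.Tree:
    """Neighbor-joining tree from a symmetric distance matrix.

    Standard Saitou-Nei agglomeration; Q-ties are broken deterministically by
    the lexicographically smallest pair of cluster labels (each cluster keyed
    by its smallest member taxon). Negative branch-length estimates are
    clamped to zero. Returns an unrooted dendropy tree.
    """
    d = np.array(matrix, dtype=float)
    labels = list(labels)
    n = len(labels)
    if d.shape != (n, n):
        raise ValueError("matrix shape does not match labels")
    if np.isnan(d).any():
        raise ValueError("distance matrix contains NaN")
    if not np.allclose(d, d.T, rtol=1e-8, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if (d < -1e-12).any():
        raise ValueError("distance matrix must be non-negative")
    if n < 2:
        raise ValueError("need at least 2 taxa")

    def fmt(x: float) -> str:
        return f"{max(x, 0.0):.17g}"

    nwk = {i: labels[i] for i in range(n)}
    key = {i: labels[i] for i in range(n)}
    active = list(range(n))
    dist = {(i, j): d[i, j] for i in range(n) for j in range(n) if i < j}

    def get(i, j):
        return dist[(i, j) if i < j else (j, i)]

    nxt = n
    while len(active) > 3:
        m = len(active)
        r = {i: sum(get(i, k) for k in active if k != i) for i in active}
        best = None
        for ii in range(m):
            for jj in range(ii + 1, m):
                i, j = active[ii], active[jj]
                q = (m - 2) * get(i, j) - r[i] - r[j]
                tie = tuple(sorted((key[i], key[j])))
                cand = (q, tie, i, j)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        _, _, i, j = best
        dij = get(i, j)
        vi = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        vj = dij - vi
        new = nxt
        nxt += 1
        nwk[new] = f"({nwk[i]}:{fmt(vi)},{nwk[j]}:{fmt(vj)})"
        key[new] = min(key[i], key[j])
        for k in active:
            if k in (i, j):
                continue
            dist[(min(new, k), max(new, k))] = 0.5 * (get(i, k) + get(j, k) - dij)
        active = [k for k in active if k not in (i, j)] + [new]

    if len(active) == 3:
        a, b, c = active
        va = 0.5 * (get(a, b) + get(a, c) - get(b, c))
        vb = 0.5 * (get(a, b) + get(b, c) - get(a, c))
        vc = 0.5 * (get(a, c) + get(b, c) - get(a, b))
        s = f"({nwk[a]}:{fmt(va)},{nwk[b]}:{fmt(vb)},{nwk[c]}:{fmt(vc)});"
    else:
        a, b = active
        half = 0.5 * get(a, b)
        s = f"({nwk[a]}:{fmt(half)},{nwk[b]}:{fmt(half)});"

    tree = dendropy.Tree.get(data=s, schema="newick")
    tree.is_rooted = False
    return tree


def bipartitions(tree: dendropy.Tree) -> set:
    """Non-trivial splits of an (unrooted) tree as canonical frozensets.

    Each split is the frozenset {side, complement} of leaf-label frozensets.
    """
    taxa = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    splits = set()
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        other = taxa - below
        if len(below) >= 2 and len(other) >= 2:
            splits.add(frozenset({below, other}))
    return splits


def bootstrap_support(
    alignment: Mapping[str, str],
    model: GtrModel,
    n_reps: int = 1000,
    seed: Optional[int] = None,
) -> Tuple[dendropy.Tree, Dict[frozenset, float]]:
    """Nonparametric bootstrap support over alignment columns.

    Columns are resampled with replacement, distances and the NJ tree are
    recomputed per replicate, and support is the percentage of replicates
    containing each split of the full-data tree. Model parameters stay fixed
    at the full-alignment values (the shared-parameter convention).
    """
    labels = list(alignment)
    codes = [encode_sequence(alignment[lab]) for lab in labels]
    nsites = len(codes[0])
    eig = EigenGtr(model)
    ntax = len(labels)

    def matrix_from_counts(counts_by_pair):
        d = np.zeros((ntax, ntax))
        for (i, j), cnt in counts_by_pair.items():
            t = ml_distance(cnt, eig)
            if not np.isfinite(t):
                t = 50.0
            d[i, j] = d[j, i] = t
        return d

    # site-pattern codes per pair; 16 marks sites invalid for that pair
    pair_codes = {}
    for i in range(ntax):
        for j in range(i + 1, ntax):
            code = codes[i] * 4 + codes[j]
            code[(codes[i] < 0) | (codes[j] < 0)] = 16
            pair_codes[(i, j)] = code

    full_counts = {
        p: np.bincount(c, minlength=17)[:16].reshape(4, 4) for p, c in pair_codes.items()
    }
    tree = nj_tree(labels, matrix_from_counts(full_counts))
    target = bipartitions(tree)
    tally = {s: 0 for s in target}

    rng = np.random.default_rng(seed)
    for _ in range(int(n_reps)):
        idx = rng.integers(0, nsites, nsites)
        counts = {
            p: np.bincount(c[idx], minlength=17)[:16].reshape(4, 4)
            for p, c in pair_codes.items()
        }
        rep_splits = bipartitions(nj_tree(labels, matrix_from_counts(counts)))
        for s in target:
            if s in rep_splits:
                tally[s] += 1

    support = (
        {s: 100.0 * c / n_reps for s, c in tally.items()} if n_reps > 0 else {}
    )
    return tree, support


# ---------------------------------------------------------------------------
# Divergence dating
# ---------------------------------------------------------------------------


def _clade_key(node) -> Tuple[str, ...]:
    return tuple(sorted(lf.taxon.label for lf in node.leaf_iter()))


def relative_node_heights(tree: dendropy.Tree, outgroup: str):
    """Relative (unitless) node heights from a relative-rate normalisation.

    The tree is rooted on the outgroup branch. The calibrated split height is
    half the mean outgroup-to-ingroup-tip path length; every other ingroup
    node's height is the recursive mean over its children of (child height +
    child branch), i.e. an average root-to-node path after per-lineage rate
    smoothing. Exact on clock-like (ultrametric) input.
    """
    tree = tree.clone(depth=1)
    og = None
    for leaf in tree.leaf_node_iter():
        if leaf.taxon.label == outgroup:
            og = leaf
            break
    if og is None:
        raise ValueError(f"outgroup taxon {outgroup!r} not found in tree")
    pdm = tree.phylogenetic_distance_matrix()
    og_taxon = og.taxon
    in_taxa = [t for t in tree.taxon_namespace if t is not og_taxon]
    root_height = float(np.mean([pdm.distance(og_taxon, t) for t in in_taxa])) / 2.0

    tree.reroot_at_edge(og.edge, update_bipartitions=False)
    ingroup_children = [c for c in tree.seed_node.child_nodes() if c is not og]
    if len(ingroup_children) != 1:
        # outgroup edge adjacent to a multifurcation at the root; treat the
        # non-outgroup children jointly
        ingroup_root_nodes = ingroup_children
    else:
        ingroup_root_nodes = ingroup_children

    heights: Dict[Tuple[str, ...], float] = {}

    def visit(node) -> float:
        if node.is_leaf():
            heights[_clade_key(node)] = 0.0
            return 0.0
        vals = []
        for child in node.child_nodes():
            h = visit(child)
            blen = child.edge.length or 0.0
            vals.append(h + blen)
        h = float(np.mean(vals))
        heights[_clade_key(node)] = h
        return h

    for node in ingroup_root_nodes:
        visit(node)

    all_key = tuple(sorted(t.label for t in tree.taxon_namespace))
    heights[all_key] = root_height
    return heights, all_key


def divergence_times(
    tree: dendropy.Tree,
    outgroup: str,
    calibration: Tuple[float, float] = (8.0, 12.0),
) -> pd.DataFrame:
    """Node ages (Mya) by scaling relative heights to a calibration interval.

    The split between the outgroup and the ingroup is anchored at the midpoint
    of ``calibration``; the interval endpoints are propagated to per-node age
    bounds. Returns a tidy table with one row per internal node (clades keyed
    by their sorted tip labels).
    """
    lo, hi = calibration
    if not (0 < lo <= hi):
        raise ValueError("calibration interval must satisfy 0 < lo <= hi")
    heights, root_key = relative_node_heights(tree, outgroup)
    root_rel = heights[root_key]
    if root_rel <= 0:
        raise ValueError("calibrated split has non-positive relative height")
    mid = 0.5 * (lo + hi)
    rows = []
    for clade, h in sorted(heights.items(), key=lambda kv: (-len(kv[0]), kv[0])):
        if len(clade) < 2:
            continue
        rows.append(
            {
                "clade": ";".join(clade),
                "rel_height": h,
                "age_mya": h * mid / root_rel,
                "age_lo_mya": h * lo / root_rel,
                "age_hi_mya": h * hi / root_rel,
                "is_calibration": clade == root_key,
            }
        )
    return pd.DataFrame(rows)
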