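"""Tamura–Nei 1993 distances and neighbor-joining trees.

This is a distance-based stand-in for full maximum-likelihood phylogenetics:
the question it answers here is topological — do the suspect paralogues form
their own clade, separate from the designated coding copy and the outgroup
species? TN93 distinguishes the two transition classes (A<->G among purines,
C<->T among pyrimidines) from transversions and uses the empirical base
composition of each pair; NJ then agglomerates with the standard Q
criterion. No invariant-sites parameter, no bootstrapping.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .io import ValidationError

__all__ = [
    "DistanceMatrix",
    "tn93_distance",
    "tn93_matrix",
    "nj_tree",
    "write_distance_matrix",
]

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")
_VALID = frozenset("ACGT")


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise distance matrix with an ordered taxon list."""

    taxa: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = self.values
        if v.shape != (len(self.taxa), len(self.taxa)):
            raise ValidationError("matrix shape does not match taxon count")
        if not np.allclose(v, v.T, equal_nan=True):
            raise ValidationError("distance matrix must be symmetric")
        if not np.all(np.diag(v) == 0):
            raise ValidationError("distance matrix diagonal must be zero")
        if np.any(v[np.isfinite(v)] < 0):
            raise ValidationError("distances must be non-negative")

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.taxa.index(a), self.taxa.index(b)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.taxa), columns=list(self.taxa))


def tn93_distance(a: str, b: str) -> float:
    """TN93 distance (substitutions/site) between two aligned DNA sequences.

    Sites where either sequence has a gap, N or other ambiguity are excluded
    pairwise. Base frequencies are the empirical frequencies of the pair
    pooled over comparable sites. Returns ``inf`` when a logarithm argument
    is non-positive (distance saturated) or when the composition is too
    degenerate to correct (a pair with no purines or no pyrimidines at all
    but observed differences).
    """
    a, b = a.upper(), b.upper()
    if len(a) != len(b):
        raise ValidationError(f"aligned sequences differ in length ({len(a)} vs {len(b)})")
    counts = {base: 0 for base in "ACGT"}
    n = 0
    transitions_ag = 0
    transitions_ct = 0
    transversions = 0
    for x, y in zip(a, b):
        if x not in _VALID or y not in _VALID:
            continue
        n += 1
        counts[x] += 1
        counts[y] += 1
        if x != y:
            pair = {x, y}
            if pair <= _PURINES:
                transitions_ag += 1
            elif pair <= _PYRIMIDINES:
                transitions_ct += 1
            else:
                transversions += 1
    if n == 0:
        raise ValidationError("no comparable (ungapped, unambiguous) sites")
    p1 = transitions_ag / n
    p2 = transitions_ct / n
    q = transversions / n
    if p1 == 0 and p2 == 0 and q == 0:
        return 0.0
    g = {base: counts[base] / (2 * n) for base in "ACGT"}
    g_r = g["A"] + g["G"]
    g_y = g["C"] + g["T"]
    if g_r == 0 or g_y == 0:
        return math.inf
    k1 = 2 * g["A"] * g["G"] / g_r
    k2 = 2 * g["T"] * g["C"] / g_y
    k3 = 2 * (g_r * g_y - g["A"] * g["G"] * g_y / g_r - g["T"] * g["C"] * g_r / g_y)
    d = 0.0
    if k1 > 0:
        w1 = 1 - p1 / k1 - q / (2 * g_r)
        if w1 <= 0:
            return math.inf
        d += -k1 * math.log(w1)
    elif p1 > 0:
        return math.inf
    if k2 > 0:
        w2 = 1 - p2 / k2 - q / (2 * g_y)
        if w2 <= 0:
            return math.inf
        d += -k2 * math.log(w2)
    elif p2 > 0:
        return math.inf
    w3 = 1 - q / (2 * g_r * g_y)
    if w3 <= 0:
        return math.inf
    d += -k3 * math.log(w3)
    return d


def tn93_matrix(sequences: Mapping[str, str]) -> DistanceMatrix:
    """Pairwise TN93 matrix over an aligned set of DNA sequences."""
    taxa = tuple(sequences)
    if len(taxa) < 2:
        raise ValidationError("need at least two sequences")
    n = len(taxa)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = tn93_distance(sequences[taxa[i]], sequences[taxa[j]])
            values[i, j] = values[j, i] = d
    return DistanceMatrix(taxa=taxa, values=values)


def write_distance_matrix(dm: DistanceMatrix, path) -> None:
    """PHYLIP-style square matrix as TSV."""
    dm.to_frame().to_csv(path, sep="\t")


class _Cluster:
    __slots__ = ("newick", "key")

    def __init__(self, newick: str, key: str):
        self.newick = newick
        self.key = key  # lexicographically smallest leaf label underneath


def _fmt(x: float) -> str:
    return f"{x:.12g}"


def nj_tree(dm: DistanceMatrix, outgroup: str | None = None) -> dendropy.Tree:
    """Canonical neighbor-joining over a distance matrix.

    Agglomerates with the standard Q criterion, Q(i,j) = (n-2)·d(i,j) − R_i
    − R_j; ties are broken deterministically by the lexicographically
    smallest (cluster, cluster) key pair, so permuting taxon order yields an
    isomorphic tree. The result is unrooted (trifurcating root node) unless
    ``outgroup`` is given, in which case the tree is rooted at the midpoint
    of the outgroup's pendant edge.
    """
    if len(dm.taxa) < 3:
        raise ValidationError("neighbor-joining needs at least 3 taxa")
    if outgroup is not None and outgroup not in dm.taxa:
        raise ValidationError(f"outgroup {outgroup!r} not among taxa")
    if not np.all(np.isfinite(dm.values)):
        raise ValidationError("cannot build a tree from saturated (infinite) distances")

    clusters: dict[str, _Cluster] = {t: _Cluster(t, t) for t in dm.taxa}
    d: dict[frozenset, float] = {}
    for i, a in enumerate(dm.taxa):
        for b in dm.taxa[i + 1 :]:
            d[frozenset((a, b))] = float(dm.get(a, b))

    def dist(x: str, y: str) -> float:
        return d[frozenset((x, y))]

    counter = 0
    while len(clusters) > 3:
        n = len(clusters)
        keys = sorted(clusters, key=lambda k: clusters[k].key)
        r = {x: sum(dist(x, y) for y in keys if y != x) for x in keys}
        best: tuple[str, str] | None = None
        best_q = math.inf
        for i, x in enumerate(keys):
            for y in keys[i + 1 :]:
                qv = (n - 2) * dist(x, y) - r[x] - r[y]
                if qv < best_q - 1e-12:
                    best_q = qv
                    best = (x, y)
        assert best is not None
        x, y = best
        dxy = dist(x, y)
        lx = dxy / 2 + (r[x] - r[y]) / (2 * (n - 2))
        ly = dxy - lx
        cx, cy = clusters.pop(x), clusters.pop(y)
        children = sorted(((cx, lx), (cy, ly)), key=lambda c: c[0].key)
        newick = "(" + ",".join(f"{c.newick}:{_fmt(l)}" for c, l in children) + ")"
        new_key = min(cx.key, cy.key)
        name = f"__u{counter}"
        counter += 1
        for z in list(clusters):
            d[frozenset((name, z))] = (dist(x, z) + dist(y, z) - dxy) / 2
        clusters[name] = _Cluster(newick, new_key)

    keys = sorted(clusters, key=lambda k: clusters[k].key)
    if len(keys) == 3:
        x, y, z = keys
        bx = (dist(x, y) + dist(x, z) - dist(y, z)) / 2
        by = (dist(x, y) + dist(y, z) - dist(x, z)) / 2
        bz = (dist(x, z) + dist(y, z) - dist(x, y)) / 2
        parts = sorted(
            ((clusters[x], bx), (clusters[y], by), (clusters[z], bz)),
            key=lambda c: c[0].key,
        )
    else:  # exactly 2 (only possible for a 3-taxon input after no joins? kept defensive)
        x, y = keys
        parts = [(clusters[x], dist(x, y) / 2), (clusters[y], dist(x, y) / 2)]
    newick = "(" + ",".join(f"{c.newick}:{_fmt(l)}" for c, l in parts) + ");"
    tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    tree.is_rooted = outgroup is not None
    if outgroup is not None:
        node = tree.find_node_with_taxon_label(outgroup)
        assert node is not None
        half = (node.edge.length or 0.0) / 2
        tree.reroot_at_edge(node.edge, length1=half, length2=half, update_bipartitions=True)
    return tree
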