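"""Population structure: PCA on standardized genotypes, identity-by-state
distances, neighbor-joining trees, outgroup rooting, and Newick I/O.

Trees are :class:`dendropy.Tree` objects; the NJ agglomeration itself is
implemented here (Saitou-Nei Q-criterion, deterministic lowest-index
tie-break, negative branch lengths clamped to zero with the excess
transferred to the sibling).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import dendropy
import numpy as np

from relictpop.variant_store.model import CohortMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "PCAResult",
    "DistanceMatrix",
    "pca",
    "ibs_distance",
    "nj_tree",
    "root_with_outgroup",
    "write_newick",
    "read_newick",
    "patristic_matrix",
]


@dataclass
class PCAResult:
    samples: list[str]
    coordinates: np.ndarray  # (n_samples, n_components)
    pct_variance: np.ndarray  # per reported component, of total nonzero variance
    eigenvalues: np.ndarray  # all nonzero eigenvalues, descending
    n_sites_used: int


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray  # symmetric, zero diagonal

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix not symmetric")
        self.values = v


def pca(m: CohortMatrix, n_components: int = 20) -> PCAResult:
    """PCA of 2p-centered, sqrt(2p(1-p))-scaled dosages (PLINK-style).

    Requires a fully-called matrix; monomorphic sites are dropped with a
    warning. The sign of each component is fixed so the first sample with a
    nonzero coordinate loads nonnegatively.
    """
    if m.n_samples < 2:
        raise ValueError("PCA needs at least 2 samples")
    if np.any(m.dosages < 0):
        raise ValueError("PCA requires a fully-called matrix (no missing dosages)")
    alt, n_alleles = m.alt_counts()
    p = alt / n_alleles
    poly = (p > 0) & (p < 1)
    n_dropped = int((~poly).sum())
    if n_dropped:
        logger.warning("dropping %d monomorphic sites before PCA", n_dropped)
    if not poly.any():
        raise ValueError("no polymorphic sites for PCA")
    pp = p[poly]
    x = (m.dosages[:, poly].astype(np.float64) - 2.0 * pp) / np.sqrt(2.0 * pp * (1.0 - pp))
    g = x @ x.T / x.shape[1]
    w, v = np.linalg.eigh(g)
    order = np.argsort(w)[::-1]
    w = w[order]
    v = v[:, order]
    tol = max(g.shape[0], 1) * np.abs(w[0]) * np.finfo(np.float64).eps if w.size else 0.0
    nonzero = w > tol
    w_nz = w[nonzero]
    k = min(n_components, m.n_samples - 1, int(nonzero.sum()))
    coords = v[:, :k] * np.sqrt(np.clip(w[:k], 0.0, None))
    for comp in range(k):
        col = coords[:, comp]
        nz = np.flatnonzero(np.abs(col) > 0)
        if nz.size and col[nz[0]] < 0:
            coords[:, comp] = -col
    pct = w[:k] / w_nz.sum() * 100.0
    return PCAResult(
        samples=list(m.samples),
        coordinates=coords,
        pct_variance=pct,
        eigenvalues=w_nz,
        n_sites_used=int(poly.sum()),
    )


def ibs_distance(m: CohortMatrix, chunk: int = 4096) -> DistanceMatrix:
    """1-IBS allele-sharing distance: mean over mutually-called sites of
    ``|d_j - d_k| / 2``. A pair with no mutually-called site is an error."""
    if m.n_samples < 2:
        raise ValueError("need at least 2 samples")
    n = m.n_samples
    num = np.zeros((n, n))
    cnt = np.zeros((n, n))
    for lo in range(0, m.n_sites, chunk):
        d = m.dosages[:, lo : lo + chunk].astype(np.float64)
        called = d >= 0
        dv = np.where(called, d, 0.0)
        diff = np.abs(dv[:, None, :] - dv[None, :, :])
        both = called[:, None, :] & called[None, :, :]
        num += np.where(both, diff, 0.0).sum(axis=2)
        cnt += both.sum(axis=2)
    off = ~np.eye(n, dtype=bool)
    if np.any(cnt[off] == 0):
        bad = np.argwhere((cnt == 0) & off)[0]
        raise ValueError(
            f"no mutually-called sites for pair ({m.samples[bad[0]]}, {m.samples[bad[1]]})"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        dist = np.where(cnt > 0, num / np.maximum(cnt, 1) / 2.0, 0.0)
    np.fill_diagonal(dist, 0.0)
    return DistanceMatrix(list(m.samples), dist)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------


def nj_tree(d: DistanceMatrix) -> dendropy.Tree:
    """Saitou-Nei neighbor joining.

    Agglomerates until three nodes remain, then resolves the final star with
    the three-point formulas. Ties on the Q criterion break to the lowest
    (creation-order) index pair. Negative two-point branch lengths are
    clamped to zero with the excess moved to the sibling branch.
    """
    labels = list(d.labels)
    r = len(labels)
    if r < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    tns = dendropy.TaxonNamespace(labels)
    nodes: list[dendropy.Node] = []
    for label in labels:
        node = dendropy.Node()
        node.taxon = tns.get_taxon(label)
        nodes.append(node)
    dist = d.values.astype(np.float64).copy()
    active = list(range(r))  # creation-order indices into `nodes`/dist rows
    # dist grows: preallocate (2r-2) square
    full = np.zeros((2 * r, 2 * r))
    full[:r, :r] = dist

    while len(active) > 3:
        k = len(active)
        sub = full[np.ix_(active, active)]
        rowsum = sub.sum(axis=1)
        q = (k - 2) * sub - rowsum[:, None] - rowsum[None, :]
        np.fill_diagonal(q, np.inf)
        # lowest creation-index tie-break: scan in index order
        best = None
        for ai in range(k):
            for aj in range(ai + 1, k):
                if best is None or q[ai, aj] < best[0] - 1e-12:
                    best = (q[ai, aj], ai, aj)
        _, ai, aj = best
        i, j = active[ai], active[aj]
        dij = full[i, j]
        li = dij / 2.0 + (rowsum[ai] - rowsum[aj]) / (2.0 * (k - 2))
        lj = dij - li
        li, lj = _clamp_transfer(li, lj)
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = li
        parent.add_child(nodes[j])
        nodes[j].edge.length = lj
        u = len(nodes)
        nodes.append(parent)
        for ak in range(k):
            if ak in (ai, aj):
                continue
            other = active[ak]
            duk = (full[i, other] + full[j, other] - dij) / 2.0
            full[u, other] = full[other, u] = duk
        active = [x for x in active if x not in (i, j)] + [u]

    # resolve the final three nodes around an unrooted central vertex
    i, j, k3 = active
    dij, dik, djk = full[i, j], full[i, k3], full[j, k3]
    li = (dij + dik - djk) / 2.0
    lj = (dij + djk - dik) / 2.0
    lk = (dik + djk - dij) / 2.0
    center = dendropy.Node()
    for node, length in ((nodes[i], li), (nodes[j], lj), (nodes[k3], lk)):
        center.add_child(node)
        node.edge.length = max(length, 0.0)
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = center
    tree.is_rooted = False
    return tree


def _clamp_transfer(li: float, lj: float) -> tuple[float, float]:
    if li < 0:
        return 0.0, lj + li if lj + li > 0 else 0.0
    if lj < 0:
        return li + lj if li + lj > 0 else 0.0, 0.0
    return li, lj


def patristic_matrix(tree: dendropy.Tree, labels: Sequence[str]) -> np.ndarray:
    """Leaf-to-leaf path-length matrix in the order of ``labels``."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    n = len(labels)
    out = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            dd = pdm.patristic_distance(taxa[labels[a]], taxa[labels[b]])
            out[a, b] = out[b, a] = dd
    return out


def root_with_outgroup(tree: dendropy.Tree, outgroup_labels: Sequence[str]) -> dendropy.Tree:
    """Root on the branch separating the outgroup from the ingroup, at its
    midpoint. The outgroup set must form one side of a bipartition of the
    unrooted topology."""
    t = tree.clone(depth=1)
    want = set(outgroup_labels)
    all_labels = {leaf.taxon.label for leaf in t.leaf_node_iter()}
    missing = want - all_labels
    if missing:
        raise ValueError(f"outgroup labels not in tree: {sorted(missing)}")
    target_edge = None
    for node in t.preorder_node_iter():
        if node is t.seed_node:
            continue
        below = {leaf.taxon.label for leaf in node.leaf_iter()}
        if below == want or (all_labels - below) == want:
            target_edge = node.edge
            break
    if target_edge is None:
        raise ValueError(
            f"outgroup {sorted(want)} is not monophyletic on the unrooted topology"
        )
    length = target_edge.length or 0.0
    t.reroot_at_edge(target_edge, length1=length / 2.0, length2=length / 2.0)
    t.is_rooted = True
    return t


def write_newick(tree: dendropy.Tree, path: str) -> None:
    """Write Newick with branch lengths; labels needing it are quoted."""
    tree.write(path=path, schema="newick", unquoted_underscores=True)


def read_newick(path: str) -> dendropy.Tree:
    return dendropy.Tree.get(path=path, schema="newick", preserve_underscores=True)
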