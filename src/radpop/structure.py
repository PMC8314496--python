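"""Population-structure inference: GRM-based PCA and a neighbour-joining tree.

PCA follows the standardized genetic-relationship-matrix route: per site,
dosages are centred at twice the pooled allele frequency, scaled by
``sqrt(2 p (1-p))``, missing values mean-imputed, and cross-products
averaged over usable sites. Scores are eigenvectors scaled by the square
root of their eigenvalues; explained-variance percentages are taken over
the positive spectrum.

The tree is individual-level neighbour joining (Saitou-Nei agglomeration
with the Studier-Keppler Q criterion) on allele-sharing distances
``mean |x_i - x_j| / 2``. NJ is exact on additive matrices; ties in Q are
broken on the smallest (row, col) index pair so the result is deterministic.
"""

from __future__ import annotations

import io as _io
import logging
from dataclasses import dataclass

import dendropy
import numpy as np

from .datamodel import MISSING, GenotypeDataset, RadpopError

logger = logging.getLogger(__name__)


@dataclass
class PCAResult:
    coordinates: np.ndarray  # samples x k
    variance_pct: np.ndarray  # length k
    k: int
    samples: list[str]


@dataclass
class NJTree:
    """Unrooted NJ tree with edge lengths; negative lengths clamped to 0."""

    tree: dendropy.Tree
    n_clamped: int
    distance_metric: str = "allele-sharing"

    def as_newick(self) -> str:
        s = self.tree.as_string(schema="newick", suppress_rooting=True).strip()
        return s if s.endswith(";") else s + ";"

    def midpoint_rooted(self) -> dendropy.Tree:
        t = self.tree.clone(depth=1)
        t.reroot_at_midpoint(update_bipartitions=True)
        return t


def grm(gd: GenotypeDataset) -> np.ndarray:
    """Standardized genetic relationship matrix over usable sites.

    Sites fixed in the pooled sample (p in {0, 1}) are skipped; missing
    dosages are mean-imputed per site (centred value 0).
    """
    if gd.n_samples < 2:
        raise RadpopError("GRM needs >= 2 samples")
    X = gd.dosages.astype(float)
    X[X == MISSING] = np.nan
    n_called = (~np.isnan(X)).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.nansum(X, axis=0) / (2.0 * n_called)
    usable = (n_called > 0) & (p > 0) & (p < 1)
    if not usable.any():
        raise RadpopError("no polymorphic sites for GRM")
    Xu = X[:, usable]
    pu = p[usable]
    Z = (Xu - 2.0 * pu) / np.sqrt(2.0 * pu * (1.0 - pu))
    Z[np.isnan(Z)] = 0.0  # mean imputation of missing dosages
    return Z @ Z.T / usable.sum()


def pca(gd: GenotypeDataset, k: int = 10) -> PCAResult:
    """Top-k eigenpairs of the GRM as sample scores and variance percentages."""
    if k >= gd.n_samples:
        raise RadpopError("k must be smaller than the number of samples")
    G = grm(gd)
    evals, evecs = np.linalg.eigh(G)  # ascending, deterministic
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos_total = evals[evals > 0].sum()
    top_vals = evals[:k]
    coords = evecs[:, :k] * np.sqrt(np.maximum(top_vals, 0.0))
    variance_pct = 100.0 * np.maximum(top_vals, 0.0) / pos_total
    return PCAResult(
        coordinates=coords, variance_pct=variance_pct, k=k, samples=list(gd.samples)
    )


def allele_sharing_distance(gd: GenotypeDataset) -> np.ndarray:
    """Pairwise ``mean |x_i - x_j| / 2`` over shared non-missing sites."""
    n = gd.n_samples
    X = gd.dosages.astype(float)
    M = X != MISSING
    X = np.where(M, X, 0.0)
    D = np.zeros((n, n))
    for i in range(n):
        shared = M[i] & M
        diff = np.abs(X[i] - X) / 2.0
        counts = shared.sum(axis=1)
        zero_pairs = np.where(counts == 0)[0]
        bad = [j for j in zero_pairs if j != i]
        if bad:
            raise RadpopError(
                f"no shared non-missing sites for pairs {[(gd.samples[i], gd.samples[j]) for j in bad]}"
            )
        with np.errstate(invalid="ignore", divide="ignore"):
            D[i] = np.where(shared, diff, 0.0).sum(axis=1) / counts
    np.fill_diagonal(D, 0.0)
    return (D + D.T) / 2.0


def nj_tree(D: np.ndarray, labels: list[str]) -> NJTree:
    """Neighbour joining on a symmetric distance matrix.

    Saitou-Nei agglomeration with the Studier-Keppler Q matrix
    ``Q(i,j) = (m-2) d(i,j) - r_i - r_j``; ties broken on the smallest
    (row, col) pair. Additive matrices are recovered exactly. Negative branch
    lengths are clamped to 0 (count reported); the topology is untouched.
    """
    D = np.asarray(D, dtype=float)
    m = D.shape[0]
    if D.shape != (m, m) or m != len(labels):
        raise RadpopError("distance matrix shape does not match labels")
    if not np.allclose(D, D.T, atol=1e-12):
        raise RadpopError("distance matrix must be symmetric")
    if m < 3:
        raise RadpopError("NJ needs >= 3 taxa")

    taxa = dendropy.TaxonNamespace(labels)
    nodes = [dendropy.Node(taxon=taxa.get_taxon(lab)) for lab in labels]
    lengths: dict[int, float] = {}
    active = list(range(m))
    dist = {(i, j): D[i, j] for i in range(m) for j in range(m) if i < j}
    next_id = m
    node_of = {i: nodes[i] for i in range(m)}

    def d(i: int, j: int) -> float:
        return dist[(i, j) if i < j else (j, i)]

    while len(active) > 2:
        mm = len(active)
        r = {i: sum(d(i, j) for j in active if j != i) for i in active}
        best = None
        for ai in range(mm):
            for aj in range(ai + 1, mm):
                i, j = active[ai], active[aj]
                q = (mm - 2) * d(i, j) - r[i] - r[j]
                key = (q, i, j)
                if best is None or key < best:
                    best = key
        _, i, j = best
        dij = d(i, j)
        li = dij / 2.0 + (r[i] - r[j]) / (2.0 * (mm - 2))
        lj = dij - li
        u = next_id
        next_id += 1
        parent = dendropy.Node()
        parent.add_child(node_of[i])
        parent.add_child(node_of[j])
        lengths[id(node_of[i])] = li
        lengths[id(node_of[j])] = lj
        node_of[u] = parent
        for k in active:
            if k in (i, j):
                continue
            dist[(min(k, u), max(k, u))] = (d(i, k) + d(j, k) - dij) / 2.0
        active = [k for k in active if k not in (i, j)] + [u]

    i, j = active
    # final join: hang the remaining leaf off the last internal node so the
    # seed is a trifurcation (standard unrooted newick shape)
    if node_of[j].taxon is None:
        i, j = j, i
    root = node_of[i]
    root.add_child(node_of[j])
    lengths[id(node_of[j])] = d(i, j)

    n_clamped = 0
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node = root
    for node in tree.preorder_node_iter():
        if node is root:
            continue
        length = lengths.get(id(node), 0.0)
        if length < 0:
            n_clamped += 1
            length = 0.0
        node.edge.length = length
    tree.is_rooted = False
    if n_clamped:
        logger.info("nj_tree: clamped %d negative branch lengths to 0", n_clamped)
    return NJTree(tree=tree, n_clamped=n_clamped)


def tree_path_lengths(njt: NJTree) -> dict[tuple[str, str], float]:
    """Leaf-to-leaf patristic distances (oracle hook for additivity checks)."""
    pdm = njt.tree.phylogenetic_distance_matrix()
    out = {}
    taxa = sorted(njt.tree.taxon_namespace, key=lambda t: t.label)
    for a in taxa:
        for b in taxa:
            if a.label < b.label:
                out[(a.label, b.label)] = pdm.patristic_distance(a, b)
    return out


def parse_newick(text_or_path: str, from_path: bool = False) -> dendropy.Tree:
    """Read a newick tree (round-trip helper for exports)."""
    if from_path:
        return dendropy.Tree.get(path=text_or_path, schema="newick")
    return dendropy.Tree.get(file=_io.StringIO(text_or_path), schema="newick")
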