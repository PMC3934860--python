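"""Phylogenies and Pagel-lambda covariance structures.

Under Brownian trait evolution the covariance between two tips is the
shared branch length from the root to their most recent common ancestor,
giving the n x n matrix C.  Pagel's lambda rescales the off-diagonal of C,
interpolating between no phylogenetic signal (lambda = 0, ordinary least
squares) and the full Brownian expectation (lambda = 1).  Lambda is allowed
to range over the whole interval on which the transformed matrix stays
positive definite, which extends below zero and above one on most trees;
negative estimates do occur in comparative data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import dendropy
import numpy as np

from .growth import normalize_species_name

log = logging.getLogger(__name__)

__all__ = [
    "Phylogeny",
    "PhyloCovariance",
    "read_newick",
    "match_and_prune",
    "vcv_from_tree",
    "pagel_transform",
    "feasible_lambda_range",
    "LAMBDA_SENTINEL",
]

#: Clip for lambda bounds when the covariance is diagonal (any lambda is
#: feasible, so the interval is reported as +/- this sentinel).
LAMBDA_SENTINEL = 10.0


@dataclass
class Phylogeny:
    """A rooted tree with branch lengths and normalization-aware tip lookup.

    Thin wrapper over a :class:`dendropy.Tree`; tip labels are matched via
    :func:`~allogrow.growth.normalize_species_name` so that e.g.
    ``Homo_sapiens`` in a Newick file matches ``homo sapiens`` in a table.
    """

    tree: dendropy.Tree
    tip_names: list[str] = field(init=False)

    def __post_init__(self):
        self.tip_names = [t.label for t in self.tree.taxon_namespace]
        normed = [normalize_species_name(n) for n in self.tip_names]
        dupes = {n for n in normed if normed.count(n) > 1}
        if dupes:
            raise ValueError(f"duplicate tip names after normalization: {sorted(dupes)}")

    @property
    def n_tips(self) -> int:
        return len(self.tip_names)

    def normalized_tip_map(self) -> dict[str, str]:
        return {normalize_species_name(n): n for n in self.tip_names}

    def as_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()


def read_newick(path_or_string, assume_unit_lengths: bool = True) -> Phylogeny:
    """Read a single Newick tree from a file path or a literal string.

    Polytomies are kept as-is.  If *every* edge lacks a branch length the
    tree is treated as a cladogram and all edges get unit length (logged);
    isolated missing lengths on an otherwise calibrated tree default to 0.
    """
    s = str(path_or_string)
    kwargs = dict(schema="newick", preserve_underscores=True)
    if s.lstrip().startswith("(") and ";" in s:
        tree = dendropy.Tree.get(data=s, **kwargs)
    else:
        tree = dendropy.Tree.get(path=s, **kwargs)
    edges = [e for e in tree.preorder_edge_iter() if e.head_node is not tree.seed_node]
    if edges and all(e.length is None for e in edges):
        if not assume_unit_lengths:
            raise ValueError("tree has no branch lengths")
        log.warning("tree has no branch lengths; assigning unit length to all edges")
        for e in edges:
            e.length = 1.0
    for e in edges:
        if e.length is None:
            e.length = 0.0
        if e.length < 0:
            raise ValueError(f"negative branch length {e.length}")
    return Phylogeny(tree)


def match_and_prune(
    phylo: Phylogeny, species: Sequence[str]
) -> tuple[Phylogeny, list[str], list[str]]:
    """Prune the tree to the species present in both tree and table.

    Returns ``(pruned_tree, matched, dropped)`` where *matched* are table
    species found in the tree (in table order, table spelling) and *dropped*
    are table species absent from the tree — those remain available for a
    non-phylogenetic (OLS) fit.  Fewer than 3 matches is an error: the
    phylogenetic regression is not identifiable.
    """
    if not len(species):
        raise ValueError("empty species list")
    tipmap = phylo.normalized_tip_map()
    matched, dropped = [], []
    for sp in species:
        (matched if normalize_species_name(sp) in tipmap else dropped).append(sp)
    if len(matched) < 3:
        raise ValueError(
            f"only {len(matched)} species shared between table and tree; "
            "at least 3 are needed for a phylogenetic fit"
        )
    keep_labels = {tipmap[normalize_species_name(sp)] for sp in matched}
    tree = dendropy.Tree(phylo.tree)  # deep clone; original untouched
    taxa = [t for t in tree.taxon_namespace if t.label in keep_labels]
    tree.retain_taxa(taxa)
    tree.purge_taxon_namespace()
    return Phylogeny(tree), matched, dropped


@dataclass
class PhyloCovariance:
    """Phylogenetic covariance: shared root-to-MRCA path lengths, with the
    current Pagel's lambda applied to the off-diagonal."""

    taxa: list[str]
    C: np.ndarray
    lam: float = 1.0

    def __post_init__(self):
        self.C = np.asarray(self.C, float)
        n = len(self.taxa)
        if self.C.shape != (n, n):
            raise ValueError("covariance shape does not match taxa")
        if not np.allclose(self.C, self.C.T):
            raise ValueError("covariance must be symmetric")

    @property
    def n(self) -> int:
        return len(self.taxa)

    def matrix(self) -> np.ndarray:
        return self.C.copy()


def vcv_from_tree(phylo: Phylogeny, taxa_order: Optional[Sequence[str]] = None) -> PhyloCovariance:
    """Brownian expectation matrix: C_ij = root-to-MRCA(i,j) path length,
    C_ii = root-to-tip distance.  Rows/columns follow ``taxa_order`` when
    given (normalized-name matching), else the tree's taxon order."""
    tree = phylo.tree
    tipmap = phylo.normalized_tip_map()
    if taxa_order is None:
        labels = list(phylo.tip_names)
    else:
        labels = []
        for sp in taxa_order:
            key = normalize_species_name(sp)
            if key not in tipmap:
                raise ValueError(f"taxon {sp!r} not in tree")
            labels.append(tipmap[key])
    index = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    C = np.zeros((n, n))
    tree.calc_node_root_distances(return_leaf_distances_only=False)
    # For each node: tips below each child subtree; tip pairs split across
    # different children share exactly this node's root distance.
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            lab = node.taxon.label
            if lab in index:
                i = index[lab]
                C[i, i] = node.root_distance
            node._tipset = [lab] if lab in index else []
            continue
        child_sets = [c._tipset for c in node.child_nodes()]
        depth = node.root_distance
        for a in range(len(child_sets)):
            for b in range(a + 1, len(child_sets)):
                for la in child_sets[a]:
                    ia = index[la]
                    for lb in child_sets[b]:
                        ib = index[lb]
                        C[ia, ib] = C[ib, ia] = depth
        node._tipset = [t for s in child_sets for t in s]
    out_taxa = list(taxa_order) if taxa_order is not None else labels
    return PhyloCovariance(out_taxa, C, lam=1.0)


def expand_duplicate_tips(
    phylo: Phylogeny,
    species: Sequence[str],
    labels: Optional[Sequence[str]] = None,
    epsilon: Optional[float] = None,
) -> Phylogeny:
    """Expand tips into one leaf per record for multi-observation taxa.

    ``species`` lists one (possibly repeated) tip name per record.  Each
    record becomes a new leaf attached under its taxon's original tip with a
    short terminal branch of length ``epsilon`` (default: 1e-6 of the tree
    height), so records of the same taxon share that taxon's full
    phylogenetic covariance while remaining distinct observations.  With
    ``epsilon = 0`` duplicate records are exact twins and the covariance is
    singular at lambda = 1, which the feasibility check rejects — keep it
    positive unless lambda is restricted below 1.

    ``labels`` names the new leaves (default ``<tip>_r<i>``); the returned
    tree's covariance should be ordered by those labels.
    """
    tipmap = phylo.normalized_tip_map()
    if labels is None:
        labels = [f"{sp}_r{i + 1}" for i, sp in enumerate(species)]
    if len(labels) != len(species):
        raise ValueError("labels must match species length")
    tree = dendropy.Tree(phylo.tree)
    tree.calc_node_root_distances(return_leaf_distances_only=False)
    height = max(leaf.root_distance for leaf in tree.leaf_node_iter())
    eps = 1e-6 * height if epsilon is None else float(epsilon)
    if eps < 0:
        raise ValueError("epsilon must be non-negative")
    leafmap = {
        normalize_species_name(leaf.taxon.label): leaf for leaf in tree.leaf_node_iter()
    }
    tns = tree.taxon_namespace
    for sp, lab in zip(species, labels):
        key = normalize_species_name(sp)
        if key not in tipmap:
            raise ValueError(f"record species {sp!r} not a tip of the tree")
        node = leafmap[key]
        taxon = dendropy.Taxon(label=lab)
        tns.add_taxon(taxon)
        node.new_child(taxon=taxon, edge_length=eps)
    for node in list(leafmap.values()):
        node.taxon = None
    tree.purge_taxon_namespace()
    return Phylogeny(tree)


def pagel_transform(cov: PhyloCovariance, lam: float, check: bool = True) -> PhyloCovariance:
    """Multiply the off-diagonal of C by lambda, leaving the diagonal fixed."""
    if check:
        lo, hi = feasible_lambda_range(cov)
        if not (lo < lam < hi):
            raise ValueError(
                f"lambda = {lam} outside the positive-definite feasible "
                f"range ({lo:.6g}, {hi:.6g})"
            )
    C = cov.C.copy()
    off = ~np.eye(cov.n, dtype=bool)
    C[off] *= lam
    return PhyloCovariance(list(cov.taxa), C, lam=lam)


def _is_pd(M: np.ndarray) -> bool:
    try:
        np.linalg.cholesky(M)
        return True
    except np.linalg.LinAlgError:
        return False


def lambda_matrix(cov: PhyloCovariance, lam: float) -> np.ndarray:
    """C with off-diagonal scaled by ``lam`` (no feasibility check)."""
    D = np.diag(np.diag(cov.C))
    return D + lam * (cov.C - D)


def feasible_lambda_range(cov: PhyloCovariance, tol: float = 1e-8) -> tuple[float, float]:
    """Largest interval of lambda keeping the transformed matrix positive
    definite, found by bisection with a Cholesky probe.

    The transformed matrix is linear in lambda (``D + lambda (C - D)``), so
    the PD region is an interval containing 0.  For valid trees it always
    contains (0, 1); bounds are clipped to +/- ``LAMBDA_SENTINEL`` when the
    off-diagonal vanishes (diagonal C: any lambda works).
    """
    D = np.diag(np.diag(cov.C))
    Off = cov.C - D
    if not np.any(np.diag(cov.C) > 0):
        raise ValueError("covariance has a non-positive diagonal")
    if np.allclose(Off, 0):
        return (-LAMBDA_SENTINEL, LAMBDA_SENTINEL)
    w_min = float(np.linalg.eigvalsh(cov.C)[0])
    if w_min <= 1e-10 * float(np.diag(cov.C).max()):
        # singular already at lambda = 1: identical-twin tips
        raise ValueError(
            "covariance is singular at lambda = 1 (tips with identical "
            "root-to-tip paths); drop one of the duplicate tips"
        )

    def bound(direction: float) -> float:
        # expand a good/bad bracket outward from 0, then bisect; ``good`` is
        # always PD, ``bad`` (once found) is not
        good, bad = 0.0, direction
        while _is_pd(lambda_matrix(cov, bad)):
            good, bad = bad, bad * 2.0
            if abs(bad) >= LAMBDA_SENTINEL:
                if _is_pd(lambda_matrix(cov, direction * LAMBDA_SENTINEL)):
                    return direction * LAMBDA_SENTINEL
                bad = direction * LAMBDA_SENTINEL
                break
        while abs(bad - good) > tol:
            mid = 0.5 * (good + bad)
            if _is_pd(lambda_matrix(cov, mid)):
                good = mid
            else:
                bad = mid
        return good

    return (bound(-1.0), bound(1.0))
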