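"""Dice similarity, distance matrices, trees with bootstrap support, PCoA.

All pairwise comparisons between dominant-marker profiles use the Dice
coefficient S = 2a / (2a + b + c), where a is the number of shared band
presences and b, c the presences exclusive to either specimen; shared
absences carry no information for dominant markers and are ignored.
Genetic distance is D = 1 - S.  Trees are built by UPGMA (rooted,
ultrametric) or neighbor joining (unrooted), with node support from
bootstrap resampling of loci.  Principal coordinate analysis is classical
scaling: double-centre the squared-distance Gower matrix and
eigendecompose; negative eigenvalues are excluded from the variance
denominator but their total mass is reported so users can judge how
non-Euclidean the distances are.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import scipy.cluster.hierarchy as sch
import scipy.linalg
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj as _skbio_nj

from .errors import HybridDetectError, UndefinedSimilarityError
from .io_matrix import MarkerMatrix

log = logging.getLogger(__name__)


# ---------------------------------------------------------------- Dice

def dice_similarity(x, y) -> float:
    """Dice similarity S = 2a/(2a+b+c) between two binary band profiles."""
    x = np.asarray(x, dtype=bool)
    y = np.asarray(y, dtype=bool)
    if x.shape != y.shape:
        raise HybridDetectError("profiles differ in length")
    a = int((x & y).sum())
    b = int((x & ~y).sum())
    c = int((~x & y).sum())
    if 2 * a + b + c == 0:
        raise UndefinedSimilarityError("both profiles are all-absent; Dice undefined")
    return 2 * a / (2 * a + b + c)


def distance_matrix(matrix: MarkerMatrix) -> DistanceMatrix:
    """Pairwise Dice distances D = 1 - S for all specimens in the matrix."""
    if matrix.n_specimens < 2:
        raise HybridDetectError("need >=2 specimens for a distance matrix")
    X = matrix.values.astype(float)
    sums = X.sum(axis=1)
    if (sums == 0).any():
        empty = [s for s, t in zip(matrix.specimen_ids, sums) if t == 0]
        raise UndefinedSimilarityError(f"all-absent specimens: {empty}")
    shared = X @ X.T
    denom = sums[:, None] + sums[None, :]
    D = 1.0 - 2.0 * shared / denom
    np.fill_diagonal(D, 0.0)
    D = (D + D.T) / 2.0  # enforce exact symmetry against float noise
    return DistanceMatrix(np.clip(D, 0.0, 1.0), list(matrix.specimen_ids))


# ---------------------------------------------------------------- trees

def _linkage_to_tree(Z: np.ndarray, ids: list[str]) -> TreeNode:
    """Convert a scipy linkage matrix into an ultrametric TreeNode.

    Linkage heights are full inter-cluster distances; tip depth below a
    merge node is half that height, matching the UPGMA convention.
    """
    n = len(ids)
    nodes: dict[int, tuple[TreeNode, float]] = {
        i: (TreeNode(name=ids[i]), 0.0) for i in range(n)
    }
    for k, (i, j, h, _) in enumerate(Z):
        hi = h / 2.0
        left, dl = nodes.pop(int(i))
        right, dr = nodes.pop(int(j))
        left.length = hi - dl
        right.length = hi - dr
        parent = TreeNode(children=[left, right])
        nodes[n + k] = (parent, hi)
    root, _ = nodes.popitem()[1]
    root.length = None
    return root


def upgma(dm: DistanceMatrix) -> TreeNode:
    """Rooted ultrametric UPGMA tree (merge heights = half average distance)."""
    if len(dm.ids) < 2:
        raise HybridDetectError("UPGMA needs >=2 specimens")
    Z = sch.linkage(dm.condensed_form(), method="average")
    return _linkage_to_tree(Z, list(dm.ids))


def nj(dm: DistanceMatrix) -> TreeNode:
    """Unrooted neighbor-joining tree; negative branch lengths clamped to 0."""
    if len(dm.ids) < 3:
        raise HybridDetectError("NJ needs >=3 specimens")
    tree = _skbio_nj(dm)
    n_clamped = 0
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
            n_clamped += 1
    if n_clamped:
        log.info("clamped %d negative NJ branch lengths to 0", n_clamped)
    return tree


def _unrooted_splits(tree: TreeNode) -> set[frozenset]:
    """Non-trivial unrooted bipartitions, each as the smaller-or-canonical side."""
    tips = frozenset(t.name for t in tree.tips())
    splits = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        other = tips - side
        if len(side) < 2 or len(other) < 2:
            continue
        splits.add(min(side, other, key=lambda s: (len(s), sorted(s))))
    return splits


def _rooted_clades(tree: TreeNode) -> set[frozenset]:
    """Non-trivial rooted clades (tip sets below internal nodes)."""
    n = len(list(tree.tips()))
    clades = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 2 <= len(side) <= n - 1:
            clades.add(side)
    return clades


def bootstrap_support(
    matrix: MarkerMatrix,
    method: str = "nj",
    n_reps: int = 1000,
    seed: int | None = None,
    stratify_by_source: bool = False,
    max_retries: int = 100,
) -> TreeNode:
    """Point-estimate tree with bootstrap node supports (percent of replicates).

    Resampling unit is the locus (columns, with replacement, same count);
    with ``stratify_by_source`` the resampling is done within each locus
    source (e.g. separately for each fingerprinting method).  Replicates
    that produce an all-absent specimen are redrawn (up to ``max_retries``
    times).  Supports are matched on unrooted splits for NJ and rooted
    clades for UPGMA, and attached as internal node names.
    """
    if n_reps < 1:
        raise HybridDetectError("n_reps must be >= 1")
    build = {"nj": nj, "upgma": upgma}.get(method)
    if build is None:
        raise HybridDetectError(f"unknown tree method {method!r}")
    splits_of = _unrooted_splits if method == "nj" else _rooted_clades

    point = build(distance_matrix(matrix))
    target = splits_of(point)
    counts = {s: 0 for s in target}
    rng = np.random.default_rng(seed)
    n_loci = matrix.n_loci

    if stratify_by_source and matrix.locus_source:
        strata = {}
        for j, s in enumerate(matrix.locus_source):
            strata.setdefault(s, []).append(j)
        strata = [np.array(v) for v in strata.values()]
    else:
        strata = [np.arange(n_loci)]

    for _ in range(n_reps):
        for attempt in range(max_retries + 1):
            cols = np.concatenate([rng.choice(s, size=len(s), replace=True) for s in strata])
            vals = matrix.values[:, cols]
            if vals.sum(axis=1).min() > 0:
                break
        else:
            raise HybridDetectError(
                f"could not draw a bootstrap replicate without an all-absent "
                f"specimen in {max_retries} retries"
            )
        rep = MarkerMatrix(
            list(matrix.specimen_ids), [f"L{j}" for j in range(len(cols))], vals
        )
        rep_splits = splits_of(build(distance_matrix(rep)))
        for s in target:
            if s in rep_splits:
                counts[s] += 1

    tips = frozenset(t.name for t in point.tips())
    for node in point.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        key = side if method == "upgma" else min(side, tips - side, key=lambda s: (len(s), sorted(s)))
        if key in counts:
            node.name = str(int(round(100 * counts[key] / n_reps)))
    return point


# ---------------------------------------------------------------- PCoA

@dataclass
class PCoAResult:
    """Classical-scaling embedding of a distance matrix."""

    specimen_ids: list[str]
    coordinates: np.ndarray          # specimens x axes
    eigenvalues: np.ndarray          # positive eigenvalues, descending
    proportion_explained: np.ndarray
    negative_eigenvalue_mass: float  # sum of |negative eigenvalues|


def pcoa(dm: DistanceMatrix, n_axes: int = 2) -> PCoAResult:
    """Principal coordinate analysis via double-centred eigendecomposition.

    Only positive eigenvalues enter the variance denominator; the absolute
    mass of negative eigenvalues is reported (no Cailliez/Lingoes
    correction is applied).
    """
    if n_axes < 1:
        raise HybridDetectError("n_axes must be >= 1")
    D = np.asarray(dm.data, dtype=float)
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    G = -0.5 * J @ (D**2) @ J
    vals, vecs = scipy.linalg.eigh(G)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    tol = max(1e-12, 1e-10 * max(abs(vals[0]), 1.0))
    pos = vals > tol
    neg_mass = float(-vals[vals < -tol].sum())
    n_pos = int(pos.sum())
    if n_axes > n_pos:
        warnings.warn(
            f"requested {n_axes} axes but only {n_pos} positive eigenvalues; truncating",
            stacklevel=2,
        )
        n_axes = max(n_pos, 1)
    pos_vals = vals[pos]
    coords = vecs[:, pos][:, :n_axes] * np.sqrt(pos_vals[:n_axes])
    prop = pos_vals[:n_axes] / pos_vals.sum() if n_pos else np.zeros(n_axes)
    return PCoAResult(
        specimen_ids=list(dm.ids),
        coordinates=coords,
        eigenvalues=pos_vals[:n_axes],
        proportion_explained=prop,
        negative_eigenvalue_mass=neg_mass,
    )


# ---------------------------------------------------------------- export

def write_newick(tree: TreeNode, path) -> None:
    """Newick with branch lengths to 6 significant digits."""
    for node in tree.traverse():
        if node.length is not None:
            node.length = float(f"{node.length:.6g}")
    tree.write(str(path))


def write_phylip(dm: DistanceMatrix, path) -> None:
    """Square PHYLIP distance matrix (for external network software)."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"{len(dm.ids)}\n")
        for sid, row in zip(dm.ids, dm.data):
            fh.write(sid + "  " + "  ".join(f"{v:.6f}" for v in row) + "\n")


def write_distances_delimited(dm: DistanceMatrix, path, sep: str = ",") -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("specimen_id" + sep + sep.join(dm.ids) + "\n")
        for sid, row in zip(dm.ids, dm.data):
            fh.write(sid + sep + sep.join(f"{v:.6f}" for v in row) + "\n")
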