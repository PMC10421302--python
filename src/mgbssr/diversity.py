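"""Diversity analysis: allele-presence 0/1 matrix, binary distances,
neighbor-joining tree and principal coordinates analysis.

SSR fragments scored across many accessions are treated as dominant bands:
each (marker, allele size) pair becomes a 0/1 column recording presence.
Jaccard distance plus Saitou-Nei neighbor joining is the default pipeline
for such matrices; PCoA (classical scaling of the double-centered squared
distances) gives the complementary ordination view.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .popgen import GenotypeTable

__all__ = [
    "to_binary_matrix",
    "distance",
    "nj_tree",
    "tree_to_newick",
    "pcoa",
    "PCoAResult",
    "cut_tree_groups",
]

METRICS = ("jaccard", "dice", "simple_matching")


def to_binary_matrix(table: GenotypeTable) -> pd.DataFrame:
    """Samples x (marker, allele) presence/absence matrix.

    Columns follow marker order then ascending allele size; a missing cell
    yields all zeros in that marker's columns; presence is scored without
    dosage (a triploid 100/100/120 marks both alleles once).
    """
    columns: list[tuple[str, int]] = []
    for m in table.markers:
        alleles = sorted({a for s in table.samples for a in table.cell(s, m)})
        columns.extend((m, a) for a in alleles)
    index = pd.MultiIndex.from_tuples(columns, names=["marker", "allele"]) if columns else None
    data = np.zeros((len(table.samples), len(columns)), dtype=np.int8)
    pos = {c: j for j, c in enumerate(columns)}
    for i, s in enumerate(table.samples):
        for m in table.markers:
            for a in set(table.cell(s, m)):
                data[i, pos[(m, a)]] = 1
    return pd.DataFrame(data, index=list(table.samples), columns=index)


def distance(matrix: pd.DataFrame, metric: str = "jaccard") -> "skbio.DistanceMatrix":
    """Pairwise binary dissimilarity between samples.

    All-zero rows are a degenerate case for jaccard/dice: two all-zero rows
    are at distance 0, an all-zero row is at distance 1 from any row with
    at least one band.
    """
    import skbio

    if metric not in METRICS:
        raise ValueError(f"metric must be one of {METRICS}")
    if len(matrix) < 2:
        raise ValueError("need at least 2 samples")
    X = matrix.to_numpy(dtype=bool)
    scipy_metric = {"jaccard": "jaccard", "dice": "dice", "simple_matching": "hamming"}[
        metric
    ]
    with np.errstate(invalid="ignore"):
        d = squareform(pdist(X, metric=scipy_metric))
    if metric in ("jaccard", "dice"):
        empty = ~X.any(axis=1)
        if empty.any():
            for i in np.flatnonzero(empty):
                d[i, :] = np.where(X.any(axis=1), 1.0, 0.0)
                d[:, i] = d[i, :]
                d[i, i] = 0.0
    np.nan_to_num(d, copy=False, nan=0.0)
    return skbio.DistanceMatrix(d, ids=list(matrix.index))


def nj_tree(dm: "skbio.DistanceMatrix") -> "skbio.TreeNode":
    """Saitou-Nei neighbor joining; returns an unrooted tree (trifurcating
    root) with exact branch lengths.

    Negative branch lengths are clamped to zero with the deficit moved to
    the adjacent branch of the joined pair, preserving their summed length.
    Serialize with :func:`tree_to_newick` for 6-significant-digit newick.
    """
    import skbio

    ids = list(dm.ids)
    n = len(ids)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 samples")
    d = np.array(dm.data, dtype=float)
    nodes: dict[int, "skbio.TreeNode"] = {
        i: skbio.TreeNode(name=ids[i]) for i in range(n)
    }
    active = list(range(n))
    next_id = n
    D = {(i, j): d[i, j] for i in range(n) for j in range(i + 1, n)}

    def dist(a: int, b: int) -> float:
        if a == b:
            return 0.0
        return D[(a, b)] if a < b else D[(b, a)]

    def setdist(a: int, b: int, v: float) -> None:
        if a < b:
            D[(a, b)] = v
        else:
            D[(b, a)] = v

    while len(active) > 3:
        m = len(active)
        r = {a: sum(dist(a, b) for b in active if b != a) for a in active}
        best = None
        for ii in range(m):
            for jj in range(ii + 1, m):
                a, b = active[ii], active[jj]
                q = (m - 2) * dist(a, b) - r[a] - r[b]
                key = (q, a, b)
                if best is None or key < best:
                    best = key
        _, a, b = best
        dab = dist(a, b)
        la = dab / 2 + (r[a] - r[b]) / (2 * (m - 2))
        lb = dab - la
        if la < 0:
            lb += la
            la = 0.0
        if lb < 0:
            la += lb
            lb = 0.0
        u = next_id
        next_id += 1
        parent = skbio.TreeNode()
        nodes[a].length = la
        nodes[b].length = lb
        parent.extend([nodes[a], nodes[b]])
        nodes[u] = parent
        for c in active:
            if c in (a, b):
                continue
            setdist(u, c, (dist(a, c) + dist(b, c) - dab) / 2)
        active = [c for c in active if c not in (a, b)] + [u]
    a, b, c = active
    # three-point formulas for the final trifurcation
    la = (dist(a, b) + dist(a, c) - dist(b, c)) / 2
    lb = (dist(a, b) + dist(b, c) - dist(a, c)) / 2
    lc = (dist(a, c) + dist(b, c) - dist(a, b)) / 2
    lengths = [la, lb, lc]
    for i in range(3):
        if lengths[i] < 0:
            j = int(np.argmax(lengths))
            lengths[j] += lengths[i]
            lengths[i] = 0.0
    root = skbio.TreeNode()
    for node_id, length in zip((a, b, c), lengths):
        nodes[node_id].length = length
        root.append(nodes[node_id])
    return root


def tree_to_newick(tree: "skbio.TreeNode", sig_digits: int = 6) -> str:
    """Newick text with branch lengths at ``sig_digits`` significant digits."""

    def fmt(node) -> str:
        if node.is_tip():
            label = node.name or ""
        else:
            label = "(" + ",".join(fmt(ch) for ch in node.children) + ")"
        if node.length is not None:
            label += f":{node.length:.{sig_digits}g}"
        return label

    return fmt(tree) + ";"


@dataclass
class PCoAResult:
    coordinates: pd.DataFrame  # samples x retained axes
    eigenvalues: np.ndarray  # all eigenvalues, descending (negatives included)
    proportion_explained: np.ndarray

    @property
    def n_axes(self) -> int:
        return self.coordinates.shape[1]


def pcoa(dm: "skbio.DistanceMatrix", k: int = 2) -> PCoAResult:
    """Classical scaling (Gower centering of -d^2/2, eigendecomposition).

    Axes are ordered by descending eigenvalue; axes with non-positive
    eigenvalues are reported in ``eigenvalues`` but never returned as
    coordinates (a warning notes when fewer than ``k`` remain). Axis signs
    are canonicalized so the largest-magnitude loading is positive.
    """
    import warnings

    from skbio.stats.ordination import pcoa as _skbio_pcoa

    if k < 1:
        raise ValueError("k must be >= 1")
    with warnings.catch_warnings():
        # all eigenvalues are wanted, and negatives (routine for Jaccard-type
        # distances) are surfaced to the caller rather than warned about
        warnings.filterwarnings("ignore", message=".*all dimensions.*")
        warnings.filterwarnings("ignore", message=".*negative eigenvalues.*")
        res = _skbio_pcoa(dm, number_of_dimensions=0)
    eig = res.eigvals.to_numpy()
    coords = res.samples.to_numpy()
    n_pos = int((eig > 1e-12).sum())
    if n_pos < k:
        warnings.warn(
            f"only {n_pos} axes have positive eigenvalues; returning {n_pos} of "
            f"the requested {k}",
            stacklevel=2,
        )
    k_eff = min(k, n_pos)
    coords = coords[:, :k_eff].copy()
    for j in range(k_eff):
        i_max = int(np.argmax(np.abs(coords[:, j])))
        if coords[i_max, j] < 0:
            coords[:, j] = -coords[:, j]
    total = eig[eig > 0].sum()
    return PCoAResult(
        coordinates=pd.DataFrame(
            coords,
            index=list(dm.ids),
            columns=[f"PCo{j + 1}" for j in range(k_eff)],
        ),
        eigenvalues=eig,
        proportion_explained=np.where(eig > 0, eig / total, 0.0),
    )


def cut_tree_groups(newick: str, k: int) -> list[list[str]]:
    """Presentation utility: split tips into k groups by removing the k-1
    longest internal edges of the tree."""
    import skbio

    tree = skbio.TreeNode.read([newick])
    internal = [
        nd
        for nd in tree.non_tips(include_self=False)
        if nd.length is not None
    ]
    internal.sort(key=lambda nd: -(nd.length or 0.0))
    cut = set(internal[: max(0, k - 1)])
    groups: list[list[str]] = []
    seen: set[str] = set()
    for nd in cut:
        tips = sorted(t.name for t in nd.tips())
        tips = [t for t in tips if t not in seen]
        if tips:
            groups.append(tips)
            seen.update(tips)
    rest = sorted(t.name for t in tree.tips() if t.name not in seen)
    if rest:
        groups.append(rest)
    return groups
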