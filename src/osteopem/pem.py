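"""Phylogenetic eigenvector maps (PEM).

A PEM turns a rooted time tree into an orthogonal regression basis.  The
construction:

1. *Influence matrix* ``B`` — a binary tips x edges matrix; ``B[i, j] = 1``
   iff edge ``j`` lies on the path from the root to tip ``i``.
2. *Edge weights* — each edge of length ``b`` (Ma) gets
   ``w = psi * b**((1 - a) / 2)`` with steepness ``a`` in [0, 1] and rate
   scale ``psi > 0``.  At ``a = 0`` the weighted influence matrix reproduces
   Brownian-motion covariance (``Bw @ Bw.T`` equals the matrix of shared
   root-to-tip path lengths); at ``a = 1`` branch lengths drop out entirely.
3. *Basis* — the weighted influence matrix is column-centred and decomposed
   by thin SVD.  The left singular vectors are the eigenvector map: mutually
   orthonormal, zero-sum columns that encode phylogenetic structure at
   decreasing scales.

Out-of-sample (fossil) tips grafted onto the tree are *scored* against a
training basis: their weighted influence row, expressed in the training
edge set, is centred with the stored column means and projected through
``V @ diag(1/d)``.  Edges touched only by target tips have identically zero
centred columns in the training matrix and hence contribute nothing to the
scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .trees import PhyloTree

_SV_RTOL = 1e-10  # singular values below _SV_RTOL * max(d) are treated as rank deficiency


@dataclass
class InfluenceMatrix:
    """Binary tips x edges path-membership matrix with recorded orderings."""

    matrix: np.ndarray  # (n_tips, n_edges), float 0/1
    tip_labels: list[str]
    edge_lengths: np.ndarray  # (n_edges,) branch lengths in Ma, preorder

    @property
    def n_tips(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_edges(self) -> int:
        return self.matrix.shape[1]


@dataclass
class EdgeWeights:
    """Power-weighted branch lengths: ``w = psi * b**((1-a)/2)``."""

    a: float
    psi: float
    weights: np.ndarray


@dataclass
class PEMBasis:
    """Centred-SVD basis of the weighted influence matrix.

    ``U`` columns are orthonormal and sum to zero; ``d`` holds the retained
    singular values in descending order; ``V`` maps edge space to component
    space; ``col_means`` are the column means removed before the SVD.
    """

    U: np.ndarray  # (n, r)
    d: np.ndarray  # (r,)
    V: np.ndarray  # (m, r)
    col_means: np.ndarray  # (m,)
    weights: EdgeWeights
    tip_labels: list[str]

    @property
    def rank(self) -> int:
        return self.d.shape[0]

    def to_frame(self):
        """Eigenvectors as a DataFrame indexed by tip label (debug/export)."""
        import pandas as pd

        cols = [f"V{k + 1}" for k in range(self.rank)]
        return pd.DataFrame(self.U, index=self.tip_labels, columns=cols)


def build_influence(tree: PhyloTree) -> InfluenceMatrix:
    """Root-to-tip path membership matrix with deterministic preorder edge order."""
    tips = tree.tips()
    if len(tips) < 2:
        raise ValueError("influence matrix requires a tree with at least 2 tips")
    edges = tree.edges()
    edge_index = {id(node): j for j, node in enumerate(edges)}
    B = np.zeros((len(tips), len(edges)))
    for i, tip in enumerate(tips):
        node = tip
        while node.parent is not None:
            B[i, edge_index[id(node)]] = 1.0
            node = node.parent
    lengths = np.array([float(e.length) for e in edges])
    return InfluenceMatrix(B, [t.label for t in tips], lengths)


def compute_edge_weights(
    tree_or_lengths, a: float, psi: float = 1.0
) -> EdgeWeights:
    """Per-edge weights ``w = psi * b**((1-a)/2)``.

    ``a`` interpolates between Brownian-motion weighting (0, ``w = psi*sqrt(b)``)
    and branch-length independence (1, ``w = psi``).  Zero-length edges get
    weight 0 whenever ``a < 1``.
    """
    if not (0.0 <= a <= 1.0):
        raise ValueError(f"steepness a must lie in [0, 1], got {a}")
    if psi <= 0:
        raise ValueError(f"rate scale psi must be > 0, got {psi}")
    if isinstance(tree_or_lengths, PhyloTree):
        lengths = np.array([float(e.length) for e in tree_or_lengths.edges()])
    elif isinstance(tree_or_lengths, InfluenceMatrix):
        lengths = tree_or_lengths.edge_lengths
    else:
        lengths = np.asarray(tree_or_lengths, dtype=float)
    expo = (1.0 - a) / 2.0
    if expo == 0.0:
        w = np.full(lengths.shape, psi)
    else:
        w = psi * np.power(lengths, expo)
    return EdgeWeights(a=a, psi=psi, weights=w)


def build_pem(B: InfluenceMatrix, W: EdgeWeights) -> PEMBasis:
    """Column-centre the weighted influence matrix and take its thin SVD.

    Singular values below ``1e-10 * max(d)`` are dropped as numerical rank
    deficiency.  Each retained eigenvector has its first nonzero entry (in
    tip order) made positive so bases are reproducible across platforms.
    """
    if B.n_edges != W.weights.shape[0]:
        raise ValueError(
            f"dimension mismatch: {B.n_edges} edges vs {W.weights.shape[0]} weights"
        )
    Bw = B.matrix * W.weights
    col_means = Bw.mean(axis=0)
    X = Bw - col_means
    U, d, Vt = np.linalg.svd(X, full_matrices=False)
    if d.size == 0 or d[0] <= 0.0:
        raise ValueError("weighted influence matrix has rank 0 after centring")
    keep = d > _SV_RTOL * d[0]
    U, d, V = U[:, keep], d[keep], Vt[keep].T
    # deterministic sign convention
    for k in range(U.shape[1]):
        col = U[:, k]
        nz = np.flatnonzero(np.abs(col) > 1e-12 * np.abs(col).max())
        if nz.size and col[nz[0]] < 0:
            U[:, k] = -col
            V[:, k] = -V[:, k]
    return PEMBasis(
        U=U, d=d, V=V, col_means=col_means, weights=W, tip_labels=list(B.tip_labels)
    )


def target_scores(basis: PEMBasis, target_row: np.ndarray) -> np.ndarray:
    """Score an out-of-sample tip against a training basis.

    ``target_row`` is the tip's *weighted* influence row over the same edge
    set and weights the basis was built with.  Scores are
    ``(row - col_means) @ V @ diag(1/d)``; a training tip's own row maps back
    to its row of ``U`` exactly.
    """
    row = np.asarray(target_row, dtype=float)
    if row.shape != basis.col_means.shape:
        raise ValueError(
            f"target row has {row.shape[0]} entries; basis expects "
            f"{basis.col_means.shape[0]} edges"
        )
    return ((row - basis.col_means) @ basis.V) / basis.d


def training_basis_with_targets(
    tree: PhyloTree,
    training_labels: list[str],
    target_labels: list[str],
    a: float,
    psi: float = 1.0,
) -> tuple[PEMBasis, dict[str, np.ndarray]]:
    """Build a training basis on the full analysis tree and score target tips.

    The analysis tree carries both training (extant) and target (fossil)
    tips.  The basis uses only the training rows of the full tree's weighted
    influence matrix — edges private to target tips end up with zero centred
    columns and do not enter the basis — and each target tip is scored from
    its own weighted row.
    """
    infl = build_influence(tree)
    index = {lab: i for i, lab in enumerate(infl.tip_labels)}
    missing = [l for l in list(training_labels) + list(target_labels) if l not in index]
    if missing:
        raise KeyError(f"labels not found as tips: {missing}")
    W = compute_edge_weights(infl, a=a, psi=psi)
    rows_train = [index[l] for l in training_labels]
    B_train = InfluenceMatrix(
        infl.matrix[rows_train], list(training_labels), infl.edge_lengths
    )
    basis = build_pem(B_train, W)
    weighted = infl.matrix * W.weights
    scores = {lab: target_scores(basis, weighted[index[lab]]) for lab in target_labels}
    return basis, scores
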