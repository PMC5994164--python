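"""Ancestral state reconstruction under Brownian motion.

Internal-node values are the maximum-likelihood states: the values that
minimise the Brownian deviance sum((x_child - x_parent)^2 / b) over all
edges.  That minimisation is a sparse linear system — the tree's weighted
Laplacian with conductance 1/b per edge — solved here directly, which is
both fast and numerically transparent.  The same states are the GLS
conditional expectations given the tips (the tests check this equivalence
against an explicit-covariance oracle).

Estimates are convex combinations of the tip values, so every internal
state lies within the observed tip range.  Zero-length branches are
contracted before the solve; nodes joined by them share one state.

Reconstruction is done on the log10 response scale, consistent with the
regression; exports carry both log and back-transformed values.  Fossil
tips enter with their *predicted* values treated as known — prediction
uncertainty is not propagated (a recorded limitation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trees import Node, PhyloTree


@dataclass
class AncestralStates:
    """Per-node state estimates on the scale of the input tip values.

    ``values``/``variances`` are indexed by preorder node position;
    ``node_ids`` gives a stable string id per node (tip label, or ``node<k>``
    for unlabelled internal nodes).
    """

    node_ids: list[str]
    values: np.ndarray
    variances: np.ndarray
    sigma2: float  # ML Brownian rate estimated from the tips (per Ma)

    def value_of(self, node_id: str) -> float:
        return float(self.values[self.node_ids.index(node_id)])


def _node_ids(tree: PhyloTree) -> tuple[list[Node], list[str]]:
    nodes = list(tree.preorder())
    ids = []
    k = 0
    for node in nodes:
        if node.label:
            ids.append(node.label)
        else:
            ids.append(f"node{k}")
            k += 1
    return nodes, ids


def _shared_path_matrix(tree: PhyloTree) -> tuple[np.ndarray, list[str]]:
    """BM covariance structure of the tips: shared root-to-tip path lengths."""
    tips = tree.tips()
    paths = []
    for tip in tips:
        edges = set()
        node = tip
        while node.parent is not None:
            edges.add(id(node))
            node = node.parent
        paths.append(edges)
    lengths = {id(n): float(n.length) for n in tree.edges()}
    n = len(tips)
    C = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            C[i, j] = sum(lengths[e] for e in paths[i] & paths[j])
    return C, [t.label for t in tips]


def _ml_rate(tree: PhyloTree, tip_values: dict[str, float]) -> float:
    """ML Brownian rate sigma^2 from the tips via GLS on the tip covariance."""
    C, labels = _shared_path_matrix(tree)
    x = np.array([tip_values[l] for l in labels])
    if np.allclose(x, x[0]):
        return 0.0
    # guard against a singular covariance (e.g. all-zero branch lengths)
    C = C + 1e-12 * np.eye(len(x))
    Cinv = np.linalg.inv(C)
    ones = np.ones(len(x))
    mu = float(ones @ Cinv @ x) / float(ones @ Cinv @ ones)
    resid = x - mu
    return float(resid @ Cinv @ resid) / len(x)


def bm_ancestral_states(
    tree: PhyloTree, tip_values: dict[str, float]
) -> AncestralStates:
    """ML ancestral states under Brownian motion for every node of the tree.

    Tip values are reproduced exactly; each internal node gets the deviance-
    minimising estimate and its conditional variance ``sigma2 * (L_uu)^-1``
    (zero when all tips are identical).
    """
    nodes, ids = _node_ids(tree)
    tips = tree.tips()
    tip_labels = {t.label for t in tips}
    missing = sorted(set(tip_values) ^ tip_labels)
    if set(tip_values) - tip_labels or tip_labels - set(tip_values):
        raise ValueError(f"tip values do not match tree tips; mismatch: {missing}")

    # contract zero-length edges: union-find over preorder indices (index-based
    # so the group layout, and hence float rounding, is run-deterministic)
    pos = {id(n): k for k, n in enumerate(nodes)}
    group = list(range(len(nodes)))

    def find(i):
        while group[i] != i:
            group[i] = group[group[i]]
            i = group[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            group[max(ri, rj)] = min(ri, rj)

    for node in nodes:
        if node.parent is not None and node.length == 0.0:
            union(pos[id(node)], pos[id(node.parent)])

    groups = sorted({find(k) for k in range(len(nodes))})
    gindex = {g: k for k, g in enumerate(groups)}
    of_node = {id(n): gindex[find(pos[id(n)])] for n in nodes}
    G = len(groups)

    # known groups: contain >= 1 tip; value = mean of member tip values
    known_vals: dict[int, list[float]] = {}
    for tip in tips:
        known_vals.setdefault(of_node[id(tip)], []).append(tip_values[tip.label])
    known = sorted(known_vals)
    unknown = [g for g in range(G) if g not in known_vals]

    # weighted Laplacian over groups, conductance 1/b per (non-contracted) edge
    L = np.zeros((G, G))
    for node in nodes:
        if node.parent is None or node.length == 0.0:
            continue
        gi, gj = of_node[id(node)], of_node[id(node.parent)]
        c = 1.0 / node.length
        L[gi, gi] += c
        L[gj, gj] += c
        L[gi, gj] -= c
        L[gj, gi] -= c

    gvals = np.zeros(G)
    for g, vals in known_vals.items():
        gvals[g] = float(np.mean(vals))
    if unknown:
        Luu = L[np.ix_(unknown, unknown)]
        Luk = L[np.ix_(unknown, known)]
        xk = gvals[known]
        gvals[np.array(unknown)] = np.linalg.solve(Luu, -Luk @ xk)

    sigma2 = _ml_rate(tree, tip_values)
    gvars = np.zeros(G)
    if unknown and sigma2 > 0:
        gvars[np.array(unknown)] = sigma2 * np.diag(np.linalg.inv(Luu))

    values = np.array([gvals[of_node[id(n)]] for n in nodes])
    variances = np.array([gvars[of_node[id(n)]] for n in nodes])
    for k, node in enumerate(nodes):
        if node.is_tip:
            values[k] = tip_values[node.label]  # tips exact, even if contracted
            variances[k] = 0.0
    return AncestralStates(node_ids=ids, values=values, variances=variances, sigma2=sigma2)


def export_tree_map(
    tree: PhyloTree,
    states: AncestralStates,
    n_samples: int = 9,
    back_transform_base: float | None = 10.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Node-value and edge-gradient tables for colour-coded tree plots.

    The node table lists every node with its height (time from the root,
    Ma), state and variance; the edge table samples a linear interpolation
    along each edge (endpoints included) for continuous colour mapping.
    When ``back_transform_base`` is set, a natural-unit column is added.
    """
    nodes, ids = _node_ids(tree)
    if len(ids) != len(states.node_ids):
        raise ValueError("states do not cover this tree")
    heights = [tree.depth(n) for n in nodes]
    node_df = pd.DataFrame(
        {
            "node_id": ids,
            "is_tip": [n.is_tip for n in nodes],
            "height": heights,
            "value": states.values,
            "variance": states.variances,
        }
    )
    if back_transform_base is not None:
        node_df["value_natural"] = np.power(back_transform_base, node_df["value"])

    index = {id(n): k for k, n in enumerate(nodes)}
    rows = []
    ts = np.linspace(0.0, 1.0, n_samples)
    for node in nodes:
        if node.parent is None:
            continue
        k_child, k_parent = index[id(node)], index[id(node.parent)]
        v0, v1 = states.values[k_parent], states.values[k_child]
        h0 = heights[k_parent]
        for t in ts:
            rows.append(
                {
                    "parent_id": ids[k_parent],
                    "child_id": ids[k_child],
                    "fraction": float(t),
                    "height": h0 + t * node.length,
                    "value": float(v0 + t * (v1 - v0)),
                }
            )
    edge_df = pd.DataFrame(rows)
    if back_transform_base is not None and len(edge_df):
        edge_df["value_natural"] = np.power(back_transform_base, edge_df["value"])
    return node_df, edge_df


def plot_tree_map(tree: PhyloTree, states: AncestralStates, path=None, cmap="viridis"):
    """Convenience rendering of the colour-coded tree (not part of the tested core)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.collections import LineCollection

    nodes, ids = _node_ids(tree)
    index = {id(n): k for k, n in enumerate(nodes)}
    tips = tree.tips()
    ypos = {id(t): i for i, t in enumerate(tips)}

    def assign_y(node):
        if node.is_tip:
            return ypos[id(node)]
        ys = [assign_y(c) for c in node.children]
        ypos[id(node)] = sum(ys) / len(ys)
        return ypos[id(node)]

    assign_y(tree.root)
    segs, vals = [], []
    for node in nodes:
        if node.parent is None:
            continue
        x1 = tree.depth(node)
        x0 = x1 - node.length
        y = ypos[id(node)]
        segs.append([(x0, y), (x1, y)])
        vals.append(states.values[index[id(node)]])
        segs.append([(x0, ypos[id(node.parent)]), (x0, y)])
        vals.append(states.values[index[id(node.parent)]])
    fig, ax = plt.subplots(figsize=(7, 0.35 * len(tips) + 1))
    lc = LineCollection(segs, cmap=cmap)
    lc.set_array(np.array(vals))
    ax.add_collection(lc)
    for t in tips:
        ax.text(tree.depth(t) + 0.01, ypos[id(t)], t.label, va="center", fontsize=8)
    ax.autoscale()
    ax.set_xlabel("time from root (Ma)")
    ax.set_yticks([])
    fig.colorbar(lc, ax=ax, label="log10 response")
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
        return None
    return fig
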