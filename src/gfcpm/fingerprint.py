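"""Stable-edge "fingerprints" of a CPM run and their network attribution.

Edges selected in at least a given fraction of LOOCV folds (default 90%) form
the fingerprint.  Each edge maps back to its node pair and network pair;
network weights are sums of node degrees, and network-pair strength matrices
sum the group-mean Fisher-z of the fingerprint edges connecting each pair of
networks.  The threshold-sensitivity analysis repeats the attribution at
85/95/100% occurrence and compares pair matrices to the 90% reference by
Spearman rank correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .connectivity import edge_count, edge_pairs
from .synthetic_cohort import ParcellationScheme


def stable_edges(fold_masks: np.ndarray, occurrence_threshold: float = 0.9) -> np.ndarray:
    """Edge indices selected in at least ``occurrence_threshold`` of folds."""
    if not 0.0 < occurrence_threshold <= 1.0:
        raise ValueError("occurrence threshold must be in (0, 1]")
    M = np.asarray(fold_masks, dtype=bool)
    freq = M.mean(axis=0)
    return np.flatnonzero(freq >= occurrence_threshold - 1e-12)


def edge_fraction(n_stable: int, n_nodes: int) -> float:
    """Stable edges as a percentage of all edges, to 3 decimals."""
    total = edge_count(n_nodes)
    if n_stable > total:
        raise ValueError("more stable edges than edges exist")
    return round(100.0 * n_stable / total, 3)


def classify_edges(edge_set: np.ndarray, scheme: ParcellationScheme) -> pd.DataFrame:
    """Map edge indices to node pairs, network pairs and intra/inter labels."""
    edge_set = np.asarray(edge_set, dtype=int)
    n = scheme.n_nodes
    total = edge_count(n)
    if edge_set.size and (edge_set.min() < 0 or edge_set.max() >= total):
        raise IndexError(f"edge index out of range for {n} nodes")
    ii, jj = edge_pairs(n)
    i = ii[edge_set]
    j = jj[edge_set]
    net_i = scheme.network_labels[i]
    net_j = scheme.network_labels[j]
    return pd.DataFrame(
        {
            "edge": edge_set,
            "node_i": i,
            "node_j": j,
            "network_i": net_i,
            "network_j": net_j,
            "kind": np.where(net_i == net_j, "intra", "inter"),
        }
    )


def network_weights(edge_set: np.ndarray, scheme: ParcellationScheme) -> pd.Series:
    """Per-network weight: sum of node degrees over the network's nodes.

    Degrees count fingerprint edges incident to each node, so the weights sum
    to twice the number of edges (handshake identity).
    """
    info = classify_edges(edge_set, scheme)
    degree = np.zeros(scheme.n_nodes, dtype=int)
    np.add.at(degree, info["node_i"].to_numpy(), 1)
    np.add.at(degree, info["node_j"].to_numpy(), 1)
    nets = scheme.networks
    weights = {
        net: int(degree[scheme.network_labels == net].sum()) for net in nets
    }
    return pd.Series(weights, name="weight")


def network_pair_matrix(
    edge_set: np.ndarray,
    gfc_stack: np.ndarray,
    scheme: ParcellationScheme,
) -> pd.DataFrame:
    """K x K symmetric matrix of summed connectivity strength between networks.

    Entry (A, B) sums, over fingerprint edges joining A and B, the group-mean
    Fisher z of the edge (mean across the subjects of ``gfc_stack``); the
    mean-then-sum aggregation keeps the scale stable across cohort sizes.
    """
    gfc_stack = np.atleast_2d(np.asarray(gfc_stack, dtype=float))
    if gfc_stack.shape[1] != edge_count(scheme.n_nodes):
        raise ValueError("GFC stack width must equal the edge count")
    nets = scheme.networks
    idx = {net: k for k, net in enumerate(nets)}
    M = np.zeros((len(nets), len(nets)))
    info = classify_edges(edge_set, scheme)
    group_mean = gfc_stack.mean(axis=0)
    for _, row in info.iterrows():
        a, b = idx[row["network_i"]], idx[row["network_j"]]
        z = group_mean[row["edge"]]
        M[a, b] += z
        if a != b:
            M[b, a] += z
    return pd.DataFrame(M, index=list(nets), columns=list(nets))


@dataclass
class SensitivityEntry:
    threshold: float
    n_pos: int
    n_neg: int
    rho_pos: float = float("nan")
    rho_neg: float = float("nan")
    p_pos: float = float("nan")
    p_neg: float = float("nan")
    computable_pos: bool = True
    computable_neg: bool = True


def _pair_vector(M: pd.DataFrame) -> np.ndarray:
    """Upper triangle including the diagonal (intra-network cells)."""
    A = M.to_numpy()
    return A[np.triu_indices(A.shape[0])]


def _spearman_vs(ref: np.ndarray, other: np.ndarray) -> tuple[float, float, bool]:
    if np.count_nonzero(other) < 3 or np.count_nonzero(ref) < 3:
        return float("nan"), float("nan"), False
    rho, p = stats.spearmanr(ref, other)
    return float(rho), float(p), bool(np.isfinite(rho))


def threshold_sensitivity(
    pos_masks: np.ndarray,
    neg_masks: np.ndarray,
    gfc_stack: np.ndarray,
    scheme: ParcellationScheme,
    thresholds: tuple[float, ...] = (0.85, 0.95, 1.0),
    reference: float = 0.9,
) -> dict[float, SensitivityEntry]:
    """Stable-edge counts and pair-matrix similarity across occurrence thresholds.

    For each threshold, reports (n_pos, n_neg) and the Spearman correlation
    between the vectorized network-pair matrices at that threshold and at the
    reference (computed separately for the positive and negative sets).  A
    pair matrix with fewer than 3 nonzero cells is flagged not-computable.
    """
    out: dict[float, SensitivityEntry] = {}
    ref_pos = network_pair_matrix(stable_edges(pos_masks, reference), gfc_stack, scheme)
    ref_neg = network_pair_matrix(stable_edges(neg_masks, reference), gfc_stack, scheme)
    vref_pos, vref_neg = _pair_vector(ref_pos), _pair_vector(ref_neg)
    for thr in sorted(set(thresholds) | {reference}):
        ep = stable_edges(pos_masks, thr)
        en = stable_edges(neg_masks, thr)
        entry = SensitivityEntry(threshold=thr, n_pos=len(ep), n_neg=len(en))
        vp = _pair_vector(network_pair_matrix(ep, gfc_stack, scheme))
        vn = _pair_vector(network_pair_matrix(en, gfc_stack, scheme))
        entry.rho_pos, entry.p_pos, entry.computable_pos = _spearman_vs(vref_pos, vp)
        entry.rho_neg, entry.p_neg, entry.computable_neg = _spearman_vs(vref_neg, vn)
        out[thr] = entry
    return out


# ---------------------------------------------------------------------------
# exports
# ---------------------------------------------------------------------------

def fingerprint_summary(
    pos_masks: np.ndarray,
    neg_masks: np.ndarray,
    gfc_stack: np.ndarray,
    scheme: ParcellationScheme,
    occurrence_threshold: float = 0.9,
) -> dict:
    """JSON-ready fingerprint description (edges, networks, weights, fractions)."""
    out: dict = {
        "occurrence_threshold": occurrence_threshold,
        "pair_matrix_aggregation": "group-mean z per edge, summed per network pair",
    }
    for name, masks in (("positive", pos_masks), ("negative", neg_masks)):
        edges = stable_edges(masks, occurrence_threshold)
        info = classify_edges(edges, scheme)
        freq = np.asarray(masks, dtype=bool).mean(axis=0)
        out[name] = {
            "n_edges": int(len(edges)),
            "percent_of_all_edges": edge_fraction(len(edges), scheme.n_nodes),
            "edges": [
                {
                    "edge": int(row["edge"]),
                    "nodes": [int(row["node_i"]), int(row["node_j"])],
                    "networks": [str(row["network_i"]), str(row["network_j"])],
                    "kind": str(row["kind"]),
                    "occurrence": float(freq[row["edge"]]),
                }
                for _, row in info.iterrows()
            ],
            "network_weights": network_weights(edges, scheme).to_dict(),
        }
    return out


def export_brainnet(
    edge_set: np.ndarray,
    scheme: ParcellationScheme,
    node_path,
    edge_path,
    edge_values: np.ndarray | None = None,
) -> None:
    """Write BrainNet Viewer text files.

    ``.node``: one row per node — x y z color size label, with color = network
    index (1-based) and size = fingerprint degree.  ``.edge``: n x n weighted
    adjacency over the fingerprint edges (weight 1, or the supplied per-edge
    values in canonical edge order).
    """
    n = scheme.n_nodes
    ii, jj = edge_pairs(n)
    A = np.zeros((n, n))
    for e in np.asarray(edge_set, dtype=int):
        w = 1.0 if edge_values is None else float(edge_values[e])
        A[ii[e], jj[e]] = A[jj[e], ii[e]] = w
    degree = (A != 0).sum(axis=0)
    nets = scheme.networks
    color = np.array([nets.index(l) + 1 for l in scheme.network_labels])
    with open(node_path, "w") as fh:
        for k in range(n):
            x, y, z = scheme.coordinates[k]
            fh.write(
                f"{x:.2f}\t{y:.2f}\t{z:.2f}\t{color[k]}\t{degree[k]}\t"
                f"{scheme.network_labels[k]}_{k}\n"
            )
    np.savetxt(edge_path, A, delimiter="\t", fmt="%.6f")
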