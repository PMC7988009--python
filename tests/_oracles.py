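"""Independent brute-force oracles for the lineage model tests.

These enumerate all hidden internal-state assignments explicitly (as a
2^k x k bit table) and stay independent of the pruning/Fitch
implementations they check.
"""

from __future__ import annotations

import numpy as np

from episwitch.lineage import R, LineageTree


def _assignments(k: int) -> np.ndarray:
    """(2^k, k) array of all binary assignments."""
    idx = np.arange(2**k, dtype=np.uint32)
    return (idx[:, None] >> np.arange(k)) & 1


def _edges(tree: LineageTree):
    internal = [i for i in range(tree.n_nodes) if tree.fate[i] == "divided"]
    pos = {n: j for j, n in enumerate(internal)}
    int_edges = [
        (pos[int(tree.parent[i])], pos[i])
        for i in internal
        if tree.parent[i] >= 0
    ]
    leaf_edges = [
        (pos[int(tree.parent[leaf])], int(tree.status[leaf]))
        for leaf in tree.observed_leaves
        if tree.parent[leaf] >= 0
    ]
    root_pos = pos.get(tree.root)
    return internal, int_edges, leaf_edges, root_pos


def brute_force_log_likelihood(
    tree: LineageTree, p_on: float, p_off: float, root_prob: float
) -> float:
    """Sum the joint probability over all internal-node state assignments.

    Censored leaves are dropped (their edge marginalizes to 1); observed
    leaves contribute their transition probability from the assigned parent
    state.
    """
    T = np.array([[1.0 - p_on, p_on], [p_off, 1.0 - p_off]])
    internal, int_edges, leaf_edges, root_pos = _edges(tree)
    if not internal:  # the root is itself a leaf
        root = tree.root
        if tree.fate[root] == "terminal_observed":
            pr = root_prob if tree.status[root] == R else 1.0 - root_prob
            return float(np.log(pr)) if pr > 0 else -np.inf
        return 0.0
    A = _assignments(len(internal))
    pr = np.where(A[:, root_pos] == 1, root_prob, 1.0 - root_prob).astype(float)
    for p, c in int_edges:
        pr *= T[A[:, p], A[:, c]]
    for p, s in leaf_edges:
        pr *= T[A[:, p], s]
    total = pr.sum()
    return float(np.log(total)) if total > 0 else -np.inf


def brute_force_min_switches(tree: LineageTree) -> int:
    """Exhaustive minimum state-change count over internal labelings.

    Censored leaves are free (cost 0 by copying the parent); observed leaves
    are fixed.
    """
    internal, int_edges, leaf_edges, _ = _edges(tree)
    if not internal:
        return 0
    A = _assignments(len(internal))
    cost = np.zeros(len(A), dtype=np.int64)
    for p, c in int_edges:
        cost += A[:, p] != A[:, c]
    for p, s in leaf_edges:
        cost += A[:, p] != s
    return int(cost.min())


def count_switches(tree: LineageTree, assignment: np.ndarray) -> int:
    """Parent->child state changes implied by a full assignment (all nodes)."""
    cost = 0
    for i in range(tree.n_nodes):
        par = tree.parent[i]
        if par >= 0:
            cost += assignment[int(par)] != assignment[i]
    return int(cost)
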