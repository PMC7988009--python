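from __future__ import annotations

import numpy as np
import pytest

from episwitch.lineage import LineageTree, SwitchingRates, simulate_lineages


@pytest.fixture
def paper_rates() -> SwitchingRates:
    """The fitted per-generation switching probabilities."""
    return SwitchingRates(0.01, 0.055)


def make_tree(leaf_statuses, tree_id="toy") -> LineageTree:
    """Complete binary tree of depth ceil(log2(len(leaves))) from leaf labels.

    ``leaf_statuses`` is a sequence over {"R", "N"} of length a power of two.
    """
    n_leaves = len(leaf_statuses)
    depth = int(np.log2(n_leaves))
    assert 2**depth == n_leaves
    records = []
    # heap layout: node k at depth d has children 2k+1, 2k+2
    n_nodes = 2 ** (depth + 1) - 1
    for k in range(n_nodes):
        d = int(np.floor(np.log2(k + 1)))
        parent = "ROOT" if k == 0 else f"n{(k - 1) // 2}"
        if d < depth:
            records.append(
                dict(node_id=f"n{k}", parent_id=parent, generation=d,
                     fate="divided", leaf_status="NA")
            )
        else:
            records.append(
                dict(node_id=f"n{k}", parent_id=parent, generation=d,
                     fate="terminal_observed",
                     leaf_status=leaf_statuses[k - (2**depth - 1)])
            )
    return LineageTree.from_records(records, tree_id=tree_id)


def cherry(status_a="R", status_b="R") -> LineageTree:
    return make_tree([status_a, status_b], tree_id="cherry")


def random_trees(n, seed, max_generations=4, death_prob=0.25):
    """Censored random trees spanning a range of shapes, for oracle checks."""
    rng = np.random.default_rng(seed)
    out = []
    while len(out) < n:
        rates = SwitchingRates(rng.uniform(0, 0.5), rng.uniform(0, 0.5))
        batch = simulate_lineages(
            rates,
            rng.uniform(0.1, 0.9),
            4,
            int(rng.integers(1, max_generations + 1)),
            death_prob=death_prob,
            seed=int(rng.integers(2**31)),
        )
        for t in batch:
            if len(t.observed_leaves) >= 1:
                out.append(t)
    return out[:n]
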