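import itertools

import numpy as np
import pytest
from hypothesis import settings

from pbnet.rules import ProbabilisticRule

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture
def worked_rule() -> ProbabilisticRule:
    """Deterministic rule f(A, B, C) = A or (B and C) for target D."""
    table = [
        1.0 if (a or (b and c)) else 0.0
        for a, b, c in itertools.product((0, 1), repeat=3)
    ]
    return ProbabilisticRule.from_truth_table("D", ("A", "B", "C"), table)


def brute_force_attractors(reduced):
    """Independent terminal-SCC oracle for a reduced deterministic system.

    Structurally different from the package route: builds an explicit sparse
    adjacency matrix of the asynchronous state graph and uses scipy's
    strongly-connected-components labelling; terminal SCCs are those with no
    outgoing cross-component edge. Returns a set of frozensets of
    (node, value) pairs — fixed nodes carry 0/1, oscillating nodes 'osc'.
    """
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import connected_components

    free = sorted(reduced.rules)
    n = len(free)
    if n == 0:
        return {frozenset((k, v) for k, v in sorted(reduced.constants.items()))}
    n_states = 2**n
    rows, cols = [], []
    for s in range(n_states):
        state = dict(reduced.constants)
        for i, node in enumerate(free):
            state[node] = (s >> i) & 1
        for i, node in enumerate(free):
            regs, table = reduced.rules[node]
            idx = 0
            for r in regs:
                idx = (idx << 1) | state[r]
            new_bit = int(table[idx])
            succ = (s & ~(1 << i)) | (new_bit << i)
            if succ != s:
                rows.append(s)
                cols.append(succ)
    mat = csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(n_states, n_states)
    )
    n_comp, labels = connected_components(mat, directed=True, connection="strong")
    terminal = set(range(n_comp))
    for s, t in zip(rows, cols):
        if labels[s] != labels[t]:
            terminal.discard(labels[s])
    out = set()
    for comp in terminal:
        states = np.nonzero(labels == comp)[0]
        entry = dict(reduced.constants)
        for i, node in enumerate(free):
            bits = {(int(s) >> i) & 1 for s in states}
            entry[node] = bits.pop() if len(bits) == 1 else "osc"
        out.add(frozenset(entry.items()))
    return out


def attractor_set(attractors):
    """Normalize package PseudoAttractors to the oracle's representation."""
    out = set()
    for a in attractors:
        entry = dict(a.fixed_states)
        for node in a.oscillating_nodes:
            entry[node] = "osc"
        out.add(frozenset(entry.items()))
    return out
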