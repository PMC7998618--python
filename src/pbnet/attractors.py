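"""Pseudo-attractor identification for probabilistic Boolean systems.

A pseudo-attractor of a probabilistic Boolean system is a set of states that
the dynamics enter with higher probability than they leave along every axis.
Because forward and backward single-node transition probabilities sum to 1,
these are exactly the attracting strongly connected components of the state
transition graph after removing every transition with probability below 0.5 —
equivalently, the attractors of the nearest deterministic system obtained by
rounding each rule probability to 0 or 1.

The workflow here: round the inferred probabilistic rules, pin the system's
source nodes to their condition-specific Boolean state (averaged over
replicates), propagate the resulting constants to a reduced free-node system,
then exhaustively build the general-asynchronous state transition graph of
the reduced system and report its terminal SCCs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .rules import NormalizedExpressionMatrix, ProbabilisticRule, config_index

logger = logging.getLogger("pbnet")

#: Largest number of free (unpinned, unforced) nodes for which the exhaustive
#: state-transition-graph search is attempted (2^bound states).
EXHAUSTIVE_BOUND = 20


@dataclass
class DeterministicRuleSet:
    """Rounded Boolean system: per-node 0/1 truth tables plus constants.

    ``rules`` maps each regulated node to ``(regulators, table)`` with
    ``table[config_index(c)] in {0, 1}``; ``constants`` holds source
    assignments and any values forced by propagation.
    """

    rules: dict[str, tuple[tuple[str, ...], np.ndarray]]
    constants: dict[str, int] = field(default_factory=dict)

    @property
    def source_nodes(self) -> set[str]:
        """Nodes referenced as regulators (or declared constant) without a rule."""
        referenced = {r for regs, _ in self.rules.values() for r in regs}
        return (referenced | set(self.constants)) - set(self.rules)

    @property
    def nodes(self) -> list[str]:
        return sorted(set(self.rules) | self.source_nodes)

    def evaluate(self, node: str, state: dict[str, int]) -> int:
        if node in self.constants:
            return self.constants[node]
        regs, table = self.rules[node]
        return int(table[config_index(state[r] for r in regs)])


@dataclass
class ConditionPinning:
    condition: str
    source_values: dict[str, int]


@dataclass
class PseudoAttractor:
    """One attractor of the rounded system under a given pinning: fixed node
    values plus the set of nodes that oscillate within the attracting SCC."""

    condition: str
    fixed_states: dict[str, int]
    oscillating_nodes: frozenset[str] = frozenset()

    @property
    def is_steady_state(self) -> bool:
        return not self.oscillating_nodes

    def value(self, node: str) -> float:
        """Node activation within the attractor; oscillating nodes count 0.5."""
        if node in self.oscillating_nodes:
            return 0.5
        return float(self.fixed_states[node])


# ---------------------------------------------------------------------------
# rounding and pinning
# ---------------------------------------------------------------------------

def round_to_deterministic(rules: dict[str, ProbabilisticRule]) -> DeterministicRuleSet:
    """Round each rule probability to the nearest Boolean value.

    Probabilities >= 0.5 round to 1 (transitions with probability below 0.5
    are the ones absent from the pseudo-attractor graph, so exact 0.5
    persists); exact ties are logged because the deterministic approximation
    is ill-defined there.
    """
    out: dict[str, tuple[tuple[str, ...], np.ndarray]] = {}
    for node, rule in rules.items():
        ties = int((rule.table == 0.5).sum())
        if ties and not rule.deterministic:
            logger.warning(
                "rule for %s has %d entries exactly at 0.5; rounded to 1", node, ties
            )
        out[node] = (rule.regulators, (rule.table >= 0.5).astype(np.uint8))
    return DeterministicRuleSet(rules=out)


def pin_source_nodes(
    normalized: NormalizedExpressionMatrix, condition: str, source_nodes
) -> ConditionPinning:
    """Pin each source node ON iff its mean normalized value over the
    condition's replicates exceeds 0.5 (exact ties pin OFF, logged)."""
    samples = normalized.condition_samples(condition)
    values = {}
    for node in sorted(source_nodes):
        row = node if node in normalized.values.index else node.removesuffix("_T")
        if row not in normalized.values.index:
            raise KeyError(f"no expression row for source node {node!r}")
        mean = float(normalized.values.loc[row, samples].mean())
        if mean == 0.5:
            logger.warning("source %s averages exactly 0.5 in %s; pinned OFF", node, condition)
        values[node] = int(mean > 0.5)
    return ConditionPinning(condition=condition, source_values=values)


# ---------------------------------------------------------------------------
# constant propagation
# ---------------------------------------------------------------------------

def _restrict_table(
    regs: tuple[str, ...], table: np.ndarray, known: dict[str, int]
) -> tuple[tuple[str, ...], np.ndarray]:
    fixed = [(i, known[r]) for i, r in enumerate(regs) if r in known]
    if not fixed:
        return regs, table
    cube = table.reshape((2,) * len(regs))
    # index highest axes first so earlier axis numbers stay valid
    for i, v in sorted(fixed, reverse=True):
        cube = np.take(cube, v, axis=i)
    new_regs = tuple(r for r in regs if r not in known)
    return new_regs, cube.reshape(-1)


def propagate_constants(
    ruleset: DeterministicRuleSet, pinning: ConditionPinning | dict[str, int]
) -> DeterministicRuleSet:
    """Substitute pinned values and iterate: any rule that becomes constant
    fixes its node, and the fix is propagated until nothing changes.

    Substitution is confluent — the reduced free system and the forced
    assignments do not depend on the order constants are applied.
    """
    known = dict(pinning.source_values if isinstance(pinning, ConditionPinning) else pinning)
    known.update(ruleset.constants)
    missing = ruleset.source_nodes - set(known)
    if missing:
        raise ValueError(f"pinning does not cover source nodes: {sorted(missing)}")
    rules = {n: (regs, tab.copy()) for n, (regs, tab) in ruleset.rules.items()}
    changed = True
    while changed:
        changed = False
        for node in list(rules):
            regs, tab = _restrict_table(*rules[node], known)
            # a node already forced keeps its constant regardless of its rule
            if node in known:
                del rules[node]
                changed = True
                continue
            if tab.min() == tab.max():
                known[node] = int(tab[0])
                del rules[node]
                changed = True
            else:
                rules[node] = (regs, tab)
    return DeterministicRuleSet(rules=rules, constants=known)


# ---------------------------------------------------------------------------
# exhaustive attractor search
# ---------------------------------------------------------------------------

def _async_transition_graph(
    free: list[str], rules: dict[str, tuple[tuple[str, ...], np.ndarray]],
    constants: dict[str, int],
) -> nx.DiGraph:
    """General-asynchronous STG over the free nodes: from each state, one
    transition per node whose update changes it (self-loops omitted)."""
    n = len(free)
    pos = {node: i for i, node in enumerate(free)}
    compiled = []
    for node in free:
        regs, tab = rules[node]
        bits = []
        consts = []
        for r in regs:
            if r in pos:
                bits.append(pos[r])
                consts.append(None)
            else:
                bits.append(None)
                consts.append(constants[r])
        compiled.append((pos[node], bits, consts, tab))
    g = nx.DiGraph()
    g.add_nodes_from(range(2**n))
    for state in range(2**n):
        for i, bits, consts, tab in compiled:
            idx = 0
            for b, c in zip(bits, consts):
                idx = (idx << 1) | ((state >> b) & 1 if c is None else c)
            new_bit = int(tab[idx])
            succ = (state & ~(1 << i)) | (new_bit << i)
            if succ != state:
                g.add_edge(state, succ)
    return g


def find_pseudo_attractors(
    reduced: DeterministicRuleSet,
    condition: str = "",
    bound: int = EXHAUSTIVE_BOUND,
) -> list[PseudoAttractor]:
    """Terminal SCCs of the reduced system's asynchronous state graph.

    Singleton terminal SCCs are steady states; larger ones are complex
    attractors whose varying nodes are reported as oscillating. Forced and
    pinned values are merged back into each attractor. Raises if the free
    node count exceeds ``bound`` (pin more sources, or raise the bound at
    your own peril: the search enumerates 2^n states).
    """
    free = sorted(reduced.rules)
    n = len(free)
    if n > bound:
        raise ValueError(
            f"{n} free nodes exceed the exhaustive search bound ({bound}); "
            "pin additional source nodes to reduce the system"
        )
    if n == 0:
        return [PseudoAttractor(condition=condition, fixed_states=dict(reduced.constants))]
    stg = _async_transition_graph(free, reduced.rules, reduced.constants)
    cond = nx.condensation(stg)
    attractors = []
    for comp in sorted(cond.nodes):
        if cond.out_degree(comp) != 0:
            continue
        states = sorted(cond.nodes[comp]["members"])
        fixed = dict(reduced.constants)
        oscillating = set()
        for i, node in enumerate(free):
            values = {(s >> i) & 1 for s in states}
            if len(values) == 1:
                fixed[node] = values.pop()
            else:
                oscillating.add(node)
                fixed[node] = states[0] >> i & 1  # representative value
        for node in oscillating:
            fixed.pop(node, None)
        attractors.append(
            PseudoAttractor(
                condition=condition,
                fixed_states=fixed,
                oscillating_nodes=frozenset(oscillating),
            )
        )
    # deterministic report order: by sorted fixed-state tuple
    attractors.sort(key=lambda a: tuple(sorted(a.fixed_states.items())))
    return attractors


def condition_attractors(
    rules: dict[str, ProbabilisticRule],
    source_nodes,
    normalized: NormalizedExpressionMatrix,
    bound: int = EXHAUSTIVE_BOUND,
) -> dict[str, list[PseudoAttractor]]:
    """Round once, then pin/propagate/search per experimental condition."""
    det = round_to_deterministic(rules)
    out = {}
    for condition in normalized.conditions:
        pinning = pin_source_nodes(normalized, condition, set(source_nodes) | det.source_nodes)
        reduced = propagate_constants(det, pinning)
        out[condition] = find_pseudo_attractors(reduced, condition, bound=bound)
    return out


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def attractor_module_summary(
    attractors: dict[str, list[PseudoAttractor]] | list[PseudoAttractor],
    modules: dict[str, str],
    source_nodes,
):
    """Mean module activation per condition over pseudo-attractors.

    Activation of a module in one attractor is the fraction of its non-source
    member nodes that are ON (oscillating nodes count 0.5); conditions are
    averaged over their attractors.
    """
    import pandas as pd

    if isinstance(attractors, list):
        grouped: dict[str, list[PseudoAttractor]] = {}
        for a in attractors:
            grouped.setdefault(a.condition, []).append(a)
        attractors = grouped
    source_nodes = set(source_nodes)
    labels = sorted({m for m in modules.values() if m != "unassigned"})
    rows = {}
    for label in labels:
        members = [
            g for g, m in modules.items() if m == label and g not in source_nodes
        ]
        rows[label] = {}
        for condition, atts in attractors.items():
            if not members or not atts:
                rows[label][condition] = np.nan
                continue
            fracs = [np.mean([a.value(g) for g in members]) for a in atts]
            rows[label][condition] = float(np.mean(fracs))
    return pd.DataFrame(rows).T


def average_start_state(attractors: list[PseudoAttractor]) -> dict[str, int]:
    """Average the attractors of one condition into a Boolean start state:
    per node, mean activation (oscillating = 0.5) thresholded at > 0.5
    (exact ties resolve OFF)."""
    if not attractors:
        raise ValueError("need at least one attractor")
    nodes = set()
    for a in attractors:
        nodes |= set(a.fixed_states) | set(a.oscillating_nodes)
    return {
        node: int(np.mean([a.value(node) for a in attractors]) > 0.5)
        for node in sorted(nodes)
    }


def attractors_to_frame(attractors: dict[str, list[PseudoAttractor]]):
    """Long-format table: one row per attractor, one column per node, values
    0/1/'osc'."""
    import pandas as pd

    rows = []
    for condition, atts in attractors.items():
        for k, a in enumerate(atts):
            row = {"condition": condition, "attractor": k}
            for node in sorted(set(a.fixed_states) | a.oscillating_nodes):
                row[node] = "osc" if node in a.oscillating_nodes else a.fixed_states[node]
            rows.append(row)
    return pd.DataFrame(rows)
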