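"""In-silico intervention analysis of a probabilistic Boolean system.

Two halves. First, static prioritization: every edge gets four scores
quantifying how likely the regulator is necessary or sufficient for its
target to be ON or OFF (NON, SON, NOFF, SOFF), computed from the target
rule's mean output with the regulator held ON (avgON) versus OFF (avgOFF);
an *influence index* then aggregates the scores of a node's out-edges into a
module to rank knockout (KO, node held OFF) and constitutive-activation
(CA, node held ON) candidates for up- or down-regulating that module.

Second, dynamic validation: general-asynchronous random walks (one randomly
chosen node updated per step, ON with the rule's probability) are run from a
condition's average start state, with and without the intervention; the
number of steps until a module's activation fraction first crosses between
the low (< 1/4 of non-source members ON) and intermediate (1/4..3/4) bands
is recorded over many walks, censored at ``n_steps + 1``, and intervention
vs wild-type switching-time distributions are compared by a two-sided
Mann-Whitney U test with Benjamini-Hochberg correction across the whole
batch of tests.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .rules import ProbabilisticRule, RuleSet

#: Default walk configuration.
N_WALKS = 100
N_STEPS = 5000
ALPHA = 0.05
#: Module-activation band edges (fractions of non-source module nodes ON).
BAND_LOW = 0.25
BAND_HIGH = 0.75


# ---------------------------------------------------------------------------
# necessary / sufficient edge profiles
# ---------------------------------------------------------------------------

@dataclass
class EdgeRegulationProfile:
    source: str
    target: str
    avg_on: float
    avg_off: float
    sign: str  # positive | negative | none
    non: float
    son: float
    noff: float
    soff: float


def edge_regulation_profile(rule: ProbabilisticRule, source: str) -> EdgeRegulationProfile:
    """NON/SON/NOFF/SOFF for the edge ``source -> rule.target``.

    avgON/avgOFF are unweighted means of the rule table over the co-regulator
    contexts. A positive edge (avgON > avgOFF) gets NON = 1 - avgOFF,
    SON = avgON, NOFF = SOFF = 0; a negative edge gets NOFF = avgOFF,
    SOFF = 1 - avgON, NON = SON = 0. When avgON equals avgOFF the edge has no
    net direction and all four scores are 0.
    """
    if source not in rule.regulators:
        raise KeyError(f"{source!r} does not regulate {rule.target!r}")
    axis = rule.regulators.index(source)
    cube = rule.table.reshape((2,) * rule.n_regulators)
    avg_on = float(np.take(cube, 1, axis=axis).mean())
    avg_off = float(np.take(cube, 0, axis=axis).mean())
    non = son = noff = soff = 0.0
    if avg_on > avg_off:
        sign = "positive"
        non, son = 1.0 - avg_off, avg_on
    elif avg_on < avg_off:
        sign = "negative"
        noff, soff = avg_off, 1.0 - avg_on
    else:
        sign = "none"
    return EdgeRegulationProfile(
        source=source, target=rule.target, avg_on=avg_on, avg_off=avg_off,
        sign=sign, non=non, son=son, noff=noff, soff=soff,
    )


def influence_index(
    node: str,
    mode: str,
    goal: str,
    module: str,
    rules: dict[str, ProbabilisticRule] | RuleSet,
    modules: dict[str, str],
) -> float:
    """Rank how well intervening on ``node`` serves a module goal.

    Sums, over the node's targets inside the module, a weighted combination
    of the target edges' necessary/sufficient scores. KO interventions weigh
    necessity double (turning OFF a necessary regulator suffices to turn the
    target OFF); CA interventions weigh sufficiency double::

        KO,DOWN: (NON - NOFF) + 0.5 (SON - SOFF)
        KO,UP:   (NOFF - NON) + 0.5 (SOFF - SON)
        CA,DOWN: (SOFF - SON) + 0.5 (NOFF - NON)
        CA,UP:   (SON - SOFF) + 0.5 (NON - NOFF)

    A node with no targets in the module scores 0.
    """
    if mode not in ("KO", "CA"):
        raise ValueError("mode must be 'KO' or 'CA'")
    if goal not in ("UP", "DOWN"):
        raise ValueError("goal must be 'UP' or 'DOWN'")
    if isinstance(rules, RuleSet):
        rules = rules.rules
    total = 0.0
    for target, rule in rules.items():
        if node not in rule.regulators or modules.get(target) != module:
            continue
        p = edge_regulation_profile(rule, node)
        if mode == "KO" and goal == "DOWN":
            total += (p.non - p.noff) + 0.5 * (p.son - p.soff)
        elif mode == "KO" and goal == "UP":
            total += (p.noff - p.non) + 0.5 * (p.soff - p.son)
        elif mode == "CA" and goal == "DOWN":
            total += (p.soff - p.son) + 0.5 * (p.noff - p.non)
        else:
            total += (p.son - p.soff) + 0.5 * (p.non - p.noff)
    return total


def influence_index_table(
    rules: dict[str, ProbabilisticRule] | RuleSet, modules: dict[str, str]
) -> pd.DataFrame:
    """Influence index of every (node, mode, module, goal) combination."""
    if isinstance(rules, RuleSet):
        rules = rules.rules
    nodes = sorted({r for rule in rules.values() for r in rule.regulators})
    labels = sorted({m for m in modules.values() if m != "unassigned"})
    rows = []
    for node in nodes:
        for mode in ("KO", "CA"):
            for module in labels:
                for goal in ("UP", "DOWN"):
                    rows.append(
                        {
                            "node": node, "mode": mode, "module": module, "goal": goal,
                            "index": influence_index(node, mode, goal, module, rules, modules),
                        }
                    )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# interventions
# ---------------------------------------------------------------------------

@dataclass
class InterventionSpec:
    """Nodes to hold constant: mode 'KO' pins OFF, 'CA' pins ON; applied to
    both the _T and _A forms of split genes."""

    targets: tuple[tuple[str, str], ...] = ()
    name: str = ""

    def __post_init__(self) -> None:
        self.targets = tuple((str(n), str(m).upper()) for n, m in self.targets)
        seen = set()
        for node, mode in self.targets:
            if mode not in ("KO", "CA"):
                raise ValueError(f"unknown intervention mode {mode!r}")
            if node in seen:
                raise ValueError(f"node {node!r} listed twice in intervention")
            seen.add(node)
        if not self.name:
            self.name = "+".join(f"{n}:{m}" for n, m in self.targets) or "WT"

    def held_values(self, all_nodes) -> dict[str, int]:
        """Expand to node -> held value, covering _T/_A forms."""
        all_nodes = set(all_nodes)
        held = {}
        for node, mode in self.targets:
            value = 0 if mode == "KO" else 1
            forms = [n for n in (node, f"{node}_T", f"{node}_A") if n in all_nodes]
            if not forms:
                raise KeyError(f"intervention names unknown node {node!r}")
            for f in forms:
                held[f] = value
        return held


def apply_intervention(ruleset: RuleSet, spec: InterventionSpec) -> tuple[RuleSet, dict[str, int]]:
    """Replace the held nodes' rules with constants; everything else updates
    as in the wild-type system. Returns the constrained rule set and the
    held-value map."""
    held = spec.held_values(ruleset.nodes)
    rules = dict(ruleset.rules)
    sources = set(ruleset.source_nodes)
    for node, value in held.items():
        rules[node] = ProbabilisticRule.from_truth_table(node, (), [float(value)])
        sources.discard(node)
    return RuleSet(rules=rules, source_nodes=sources), held


# ---------------------------------------------------------------------------
# random-walk simulation
# ---------------------------------------------------------------------------

class _CompiledSystem:
    """Index-compiled rule set for the walk inner loop (plain-Python ints)."""

    def __init__(self, ruleset: RuleSet, held: dict[str, int]):
        self.nodes = ruleset.nodes
        self.index = {n: i for i, n in enumerate(self.nodes)}
        self.held = dict(held)
        # source nodes hold their start value: they have no update rule
        self.static = set(held) | set(ruleset.source_nodes)
        self.free = [self.index[n] for n in self.nodes if n not in self.static]
        self.regs: list[tuple[int, ...]] = []
        self.tables: list[list[float]] = []
        for n in self.nodes:
            rule = ruleset.rules.get(n)
            if rule is None or n in self.static:
                self.regs.append(())
                self.tables.append([0.5])
            else:
                self.regs.append(tuple(self.index[r] for r in rule.regulators))
                self.tables.append([float(p) for p in rule.table])

    def initial_state(self, start_state: dict[str, int]) -> list[int]:
        state = []
        for n in self.nodes:
            if n in self.held:
                state.append(self.held[n])
            elif n in start_state:
                state.append(int(start_state[n]))
            else:
                raise KeyError(f"start state misses node {n!r}")
        return state


def simulate_walk(
    ruleset: RuleSet,
    start_state: dict[str, int],
    n_steps: int = N_STEPS,
    rng_seed: int = 0,
    held: dict[str, int] | None = None,
) -> pd.DataFrame:
    """One general-asynchronous random walk; returns the full trajectory.

    Each step picks one non-held, non-source node uniformly at random and
    sets it ON with its rule's probability at the current regulator states.
    Row 0 is the start state; row k the state after k update attempts.
    """
    sys = _CompiledSystem(ruleset, held or {})
    state = sys.initial_state(start_state)
    rng = random.Random(rng_seed)
    free, regs, tables = sys.free, sys.regs, sys.tables
    traj = np.empty((n_steps + 1, len(state)), dtype=np.uint8)
    traj[0] = state
    for step in range(1, n_steps + 1):
        i = free[rng.randrange(len(free))]
        cfg = 0
        for j in regs[i]:
            cfg = (cfg << 1) | state[j]
        state[i] = 1 if rng.random() < tables[i][cfg] else 0
        traj[step] = state
    return pd.DataFrame(traj, columns=sys.nodes)


# ---------------------------------------------------------------------------
# module activation and switching times
# ---------------------------------------------------------------------------

def module_activation(state: dict[str, int], module_nodes, source_nodes) -> tuple[float, str]:
    """Fraction of the module's non-source nodes that are ON, plus its band.

    Bands: low (< 1/4), intermediate (1/4..3/4 inclusive), high (> 3/4).
    Source nodes are excluded — they cannot respond to interventions.
    """
    members = [n for n in module_nodes if n not in set(source_nodes)]
    if not members:
        raise ValueError("module has no non-source nodes")
    frac = sum(int(state[n]) for n in members) / len(members)
    if frac < BAND_LOW:
        band = "low"
    elif frac <= BAND_HIGH:
        band = "intermediate"
    else:
        band = "high"
    return frac, band


def first_switch_time(
    walk: pd.DataFrame, module_nodes, source_nodes, start_band: str,
) -> int:
    """First step at which a trajectory's module band crosses the scored
    boundary: low -> (intermediate or higher), or intermediate -> low;
    censored at ``len(walk)`` (i.e. n_steps + 1) if it never does."""
    if start_band not in ("low", "intermediate"):
        raise ValueError("start_band must be 'low' or 'intermediate'")
    members = [n for n in module_nodes if n not in set(source_nodes)]
    counts = walk[members].sum(axis=1).to_numpy()
    frac = counts / len(members)
    if start_band == "low":
        hits = np.nonzero(frac[1:] >= BAND_LOW)[0]
    else:
        hits = np.nonzero(frac[1:] < BAND_LOW)[0]
    return int(hits[0]) + 1 if hits.size else len(walk)


@dataclass
class SwitchTimeDistribution:
    module: str
    direction: str  # 'low->intermediate' or 'intermediate->low'
    times: list[int]
    n_steps: int = N_STEPS
    intervention: str = "WT"
    condition: str = ""

    @property
    def mean(self) -> float:
        return float(np.mean(self.times))


def measure_switch_times(
    ruleset: RuleSet,
    start_state: dict[str, int],
    module_nodes,
    source_nodes,
    n_walks: int = N_WALKS,
    n_steps: int = N_STEPS,
    master_seed: int = 0,
    held: dict[str, int] | None = None,
    module: str = "",
    intervention: str = "WT",
    condition: str = "",
) -> SwitchTimeDistribution:
    """Switching-time distribution of one module over repeated walks.

    Each walk gets an independent RNG seeded from ``(master_seed, walk)``
    and stops early at its first band switch; walks that never switch within
    ``n_steps`` record the censored value ``n_steps + 1``. Modules starting
    in the high band are not scored (crossings of the 3/4 boundary are rare
    and excluded by design); this raises so callers can skip them.
    """
    sys = _CompiledSystem(ruleset, held or {})
    # non-source module members (held nodes still count toward activation)
    members_idx = [sys.index[n] for n in module_nodes if n not in set(source_nodes)]
    if not members_idx:
        raise ValueError("module has no non-source nodes")
    member_set = set(members_idx)
    n_members = len(members_idx)
    low_cut = BAND_LOW * n_members  # count < low_cut  <=> low band
    state0 = sys.initial_state(start_state)
    count0 = sum(state0[i] for i in members_idx)
    frac0 = count0 / n_members
    if frac0 < BAND_LOW:
        start_band, direction = "low", "low->intermediate"
    elif frac0 <= BAND_HIGH:
        start_band, direction = "intermediate", "intermediate->low"
    else:
        raise ValueError("module starts in the high band; this crossing is not scored")
    free, regs, tables = sys.free, sys.regs, sys.tables
    times = []
    for walk in range(n_walks):
        rng = random.Random(master_seed * 1_000_003 + walk)
        state = list(state0)
        count = count0
        t = n_steps + 1  # censored unless a switch happens
        for step in range(1, n_steps + 1):
            i = free[rng.randrange(len(free))]
            cfg = 0
            for j in regs[i]:
                cfg = (cfg << 1) | state[j]
            new = 1 if rng.random() < tables[i][cfg] else 0
            if new != state[i]:
                state[i] = new
                if i in member_set:
                    count += 1 if new else -1
                    if start_band == "low":
                        if count >= low_cut:
                            t = step
                            break
                    elif count < low_cut:
                        t = step
                        break
        times.append(t)
    return SwitchTimeDistribution(
        module=module, direction=direction, times=times, n_steps=n_steps,
        intervention=intervention, condition=condition,
    )


# ---------------------------------------------------------------------------
# statistical comparison
# ---------------------------------------------------------------------------

@dataclass
class InterventionResult:
    intervention: str
    module: str
    direction: str
    p_raw: float
    p_adjusted: float = float("nan")
    mean_shift: float = float("nan")  # mean(intervention) / mean(WT)
    classification: str = "none"
    condition: str = ""


def _mwu_p(a, b) -> float:
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
        return 1.0  # identical constant samples: no evidence of a shift
    return float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)


def compare_interventions(
    wt_times: list[SwitchTimeDistribution],
    intervention_times: list[SwitchTimeDistribution],
    alpha: float = ALPHA,
) -> list[InterventionResult]:
    """Mann-Whitney U + BH classification of every intervention distribution
    against its matching wild-type distribution.

    Matching is on (condition, module): the WT list must contain exactly one
    distribution per key. Classification logic: a module starting low that
    switches *slower* under intervention was stabilized low (downregulating),
    *faster* means destabilized (upregulating); a module starting
    intermediate that switches slower was stabilized up (upregulating),
    faster means downregulating. Only BH-adjusted p < alpha classifies.
    """
    wt_by_key: dict[tuple[str, str], SwitchTimeDistribution] = {}
    for d in wt_times:
        key = (d.condition, d.module)
        if key in wt_by_key:
            raise ValueError(f"duplicate wild-type distribution for {key}")
        wt_by_key[key] = d
    results = []
    for d in intervention_times:
        wt = wt_by_key.get((d.condition, d.module))
        if wt is None:
            raise ValueError(f"no wild-type distribution for {(d.condition, d.module)}")
        if len(wt.times) != len(d.times):
            raise ValueError("mismatched walk counts between WT and intervention")
        results.append(
            InterventionResult(
                intervention=d.intervention,
                module=d.module,
                direction=d.direction,
                condition=d.condition,
                p_raw=_mwu_p(d.times, wt.times),
                mean_shift=d.mean / wt.mean if wt.mean else float("nan"),
            )
        )
    if results:
        adjusted = multipletests([r.p_raw for r in results], method="fdr_bh")[1]
        for r, p in zip(results, adjusted):
            r.p_adjusted = float(p)
            if p < alpha:
                slower = r.mean_shift > 1.0
                faster = r.mean_shift < 1.0
                if r.direction == "low->intermediate":
                    r.classification = (
                        "downregulating" if slower else "upregulating" if faster else "none"
                    )
                else:  # intermediate->low
                    r.classification = (
                        "upregulating" if slower else "downregulating" if faster else "none"
                    )
    return results


def results_to_frame(results: list[InterventionResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "intervention": r.intervention,
                "condition": r.condition,
                "module": r.module,
                "direction": r.direction,
                "p_raw": r.p_raw,
                "p_adjusted": r.p_adjusted,
                "mean_shift": r.mean_shift,
                "classification": r.classification,
            }
            for r in results
        ]
    )


def switch_times_to_frame(dists: list[SwitchTimeDistribution]) -> pd.DataFrame:
    rows = []
    for d in dists:
        for k, t in enumerate(d.times):
            rows.append(
                {
                    "intervention": d.intervention,
                    "condition": d.condition,
                    "module": d.module,
                    "direction": d.direction,
                    "walk": k,
                    "time": t,
                }
            )
    return pd.DataFrame(rows)
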