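"""Probabilistic Boolean rule inference from steady-state expression.

This module covers the inference half of the pipeline: transforming and
normalizing expression, splitting post-translationally regulated genes into
transcript (``X_T``) and active-protein (``X_A``) forms, solving the
sloppy-logic activation system for per-sample ``X_A`` values, and inferring a
probabilistic Boolean update rule for every regulated node, with iterative
removal of insignificant regulators.

The estimator is BooleaBayes-style: for a target with regulators
``r_1 .. r_N`` each sample ``s`` contributes weight
``w_{s,c} = prod_i (x_{i,s} if c_i else 1 - x_{i,s})`` to each regulator
configuration ``c in {0,1}^N``, and the rule's ON-probability at ``c`` is the
weighted mean of the target's normalized value, shrunk toward 0.5 by a single
pseudo-observation::

    f(c) = (0.5 * prior_weight + sum_s w_{s,c} y_s) / (prior_weight + sum_s w_{s,c})

so a configuration supported by no data returns exactly 0.5 — the rule is
maximally uncertain where the steady states say nothing.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger("pbnet")

#: In-degree above which rule inference is close to unconstrained by data
#: (2^N configurations vs a handful of steady-state samples).
MAX_RELIABLE_REGULATORS = 6

#: Default regulator-significance threshold for pruning.
SIGNIFICANCE_THRESHOLD = 0.1

#: Default percentiles for expression normalization.
PERCENTILE_LOW = 20.0
PERCENTILE_HIGH = 80.0


# ---------------------------------------------------------------------------
# configuration indexing
# ---------------------------------------------------------------------------

def config_index(bits) -> int:
    """Index of a regulator configuration; the first regulator is the most
    significant bit, so ``(1, 0, 0) -> 4`` for a 3-regulator rule."""
    idx = 0
    for b in bits:
        idx = (idx << 1) | int(b)
    return idx


def enumerate_configs(n_regulators: int):
    """All configurations of ``n_regulators`` Boolean inputs in index order."""
    return itertools.product((0, 1), repeat=n_regulators)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class NormalizedExpressionMatrix:
    """Gene-by-sample expression scaled to [0, 1].

    ``values`` rows are genes (including any solved ``X_A`` rows appended
    later), columns are samples; ``sample_conditions`` maps every column to
    its experimental condition.
    """

    values: pd.DataFrame
    sample_conditions: dict[str, str]
    raw_transform: str = "log1p_fpkm"

    def __post_init__(self) -> None:
        v = self.values.to_numpy(dtype=float)
        if v.size and (v.min() < -1e-12 or v.max() > 1 + 1e-12):
            raise ValueError("normalized expression must lie in [0, 1]")
        missing = set(self.values.columns) - set(self.sample_conditions)
        if missing:
            raise ValueError(f"samples without a condition label: {sorted(missing)}")

    def condition_samples(self, condition: str) -> list[str]:
        cols = [s for s in self.values.columns if self.sample_conditions[s] == condition]
        if not cols:
            raise KeyError(f"unknown condition {condition!r}")
        return cols

    @property
    def conditions(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.values.columns:
            seen.setdefault(self.sample_conditions[s], None)
        return list(seen)


@dataclass
class ProbabilisticRule:
    """One node's probabilistic Boolean update function.

    ``table[config_index(c)]`` is the probability that the target is ON given
    regulator configuration ``c``; ``support`` is the total sample weight that
    informed each entry (0 means the entry is pure prior).
    """

    target: str
    regulators: tuple[str, ...]
    table: np.ndarray
    support: np.ndarray
    deterministic: bool = False

    def __post_init__(self) -> None:
        self.regulators = tuple(self.regulators)
        self.table = np.asarray(self.table, dtype=float)
        self.support = np.asarray(self.support, dtype=float)
        n = len(self.regulators)
        if self.table.shape != (2**n,):
            raise ValueError(
                f"rule for {self.target}: table length {self.table.shape} "
                f"does not match {n} regulators"
            )
        if self.table.min() < 0 or self.table.max() > 1:
            raise ValueError(f"rule for {self.target}: probabilities outside [0, 1]")

    @property
    def n_regulators(self) -> int:
        return len(self.regulators)

    def probability(self, bits) -> float:
        return float(self.table[config_index(bits)])

    @classmethod
    def from_truth_table(cls, target: str, regulators, table) -> "ProbabilisticRule":
        """Wrap a deterministic 0/1 truth table as a (degenerate) rule."""
        table = np.asarray(table, dtype=float)
        return cls(
            target=target,
            regulators=tuple(regulators),
            table=table,
            support=np.zeros_like(table),
            deterministic=True,
        )


@dataclass
class ActivationEquation:
    """Sloppy-logic activation of one split node:
    ``X_A = X_T * min(sum(activators), 1) * max(1 - sum(inhibitors), 0)``,
    with the activator factor omitted when the node has no activators (a node
    nobody activates is active unless deactivated)."""

    node: str
    transcript_var: str
    activators: tuple[str, ...]
    inhibitors: tuple[str, ...]
    active_var: str

    def rhs(self, values: dict[str, float]) -> float:
        x_t = values[self.transcript_var]
        act = 1.0
        if self.activators:
            act = min(sum(values[a] for a in self.activators), 1.0)
        inh = max(1.0 - sum(values[i] for i in self.inhibitors), 0.0)
        return x_t * act * inh


@dataclass
class RegulatorSignificance:
    regulator: str
    value: float


# ---------------------------------------------------------------------------
# expression preprocessing and normalization
# ---------------------------------------------------------------------------

def preprocess_expression(
    raw: pd.DataFrame, symbol_whitelist: set[str] | None = None
) -> pd.DataFrame:
    """log(1 + FPKM) transform, optionally restricted to a symbol whitelist.

    Rows are genes, columns samples. Negative input values are rejected; an
    absent whitelist keeps every row.
    """
    values = raw.to_numpy(dtype=float)
    if values.size and values.min() < 0:
        raise ValueError("FPKM values must be nonnegative")
    out = pd.DataFrame(np.log1p(values), index=raw.index, columns=raw.columns)
    if symbol_whitelist is not None:
        out = out.loc[[g for g in out.index if g in symbol_whitelist]]
    return out


def normalize_expression(
    matrix: pd.DataFrame,
    sample_conditions: dict[str, str] | None = None,
    *,
    p_low: float = PERCENTILE_LOW,
    p_high: float = PERCENTILE_HIGH,
    raw_transform: str = "log1p_fpkm",
) -> NormalizedExpressionMatrix:
    """Scale each gene to [0, 1] between its 20th and 80th percentiles.

    Values at or below the low percentile map to 0, at or above the high
    percentile to 1, and values in between are linearly interpolated.
    Percentiles use numpy's linear-interpolation convention. A gene whose two
    percentiles coincide is uninformative and is set to 0.5 everywhere (with a
    warning): it cannot be said to be ON or OFF from these data.
    """
    if matrix.shape[1] < 2:
        raise ValueError("normalization needs at least 2 samples")
    values = matrix.to_numpy(dtype=float)
    lo = np.percentile(values, p_low, axis=1, keepdims=True)
    hi = np.percentile(values, p_high, axis=1, keepdims=True)
    span = hi - lo
    degenerate = span[:, 0] <= 0
    span[degenerate] = 1.0  # avoid divide-by-zero; rows overwritten below
    normed = np.clip((values - lo) / span, 0.0, 1.0)
    if degenerate.any():
        genes = list(matrix.index[degenerate])
        logger.warning(
            "%d gene(s) with coincident %gth/%gth percentiles set to 0.5: %s",
            len(genes), p_low, p_high, genes[:10],
        )
        normed[degenerate] = 0.5
    if sample_conditions is None:
        sample_conditions = {s: "all" for s in matrix.columns}
    return NormalizedExpressionMatrix(
        values=pd.DataFrame(normed, index=matrix.index, columns=matrix.columns),
        sample_conditions=dict(sample_conditions),
        raw_transform=raw_transform,
    )


# ---------------------------------------------------------------------------
# edge typing and transcript/active splitting
# ---------------------------------------------------------------------------

def classify_edge_types(network: nx.DiGraph, tf_flags: dict[str, bool] | set) -> nx.DiGraph:
    """Partition edges into transcriptional vs post-translational.

    An edge is transcriptional iff its source is a transcription factor; all
    other edges are post-translational and carry an activating/deactivating
    sign (edges without annotation default to activating).
    """
    if not isinstance(tf_flags, dict):
        tf_flags = {n: True for n in tf_flags}
    g = network.copy()
    for u, v, data in g.edges(data=True):
        is_tf = bool(tf_flags.get(u, False))
        data["regulation_type"] = "transcriptional" if is_tf else "post_translational"
        sign = data.get("sign")
        if sign not in ("positive", "negative"):
            sign = "positive"  # unannotated regulation assumed activating
        data["sign"] = sign
        g.nodes[u]["tf"] = bool(tf_flags.get(u, False))
    for n in g.nodes:
        g.nodes[n].setdefault("tf", bool(tf_flags.get(n, False)))
        g.nodes[n].setdefault("role", "plain")
    return g


def split_post_translational_nodes(network: nx.DiGraph) -> nx.DiGraph:
    """Split every post-translationally regulated node X into X_T and X_A.

    X_T keeps the transcriptional in-edges; X_A receives the
    post-translational in-edges plus a dependency edge X_T -> X_A; every
    out-edge of X is re-sourced to X_A. Purely transcriptionally regulated
    nodes are unchanged (active as long as transcribed).
    """
    split = {
        n
        for n in network.nodes
        if any(
            d.get("regulation_type") == "post_translational"
            for _, _, d in network.in_edges(n, data=True)
        )
    }
    g = nx.DiGraph()
    for n, data in network.nodes(data=True):
        if n in split:
            g.add_node(f"{n}_T", **{**data, "role": "transcript", "base": n})
            g.add_node(f"{n}_A", **{**data, "role": "active", "base": n})
            g.add_edge(f"{n}_T", f"{n}_A", regulation_type="transcript_dependency",
                       sign="positive")
        else:
            g.add_node(n, **{**data, "role": "plain", "base": n})
    for u, v, data in network.edges(data=True):
        src = f"{u}_A" if u in split else u
        if v in split:
            tgt = f"{v}_T" if data.get("regulation_type") == "transcriptional" else f"{v}_A"
        else:
            tgt = v
        g.add_edge(src, tgt, **data)
    return g


def build_activation_equations(split_network: nx.DiGraph) -> list[ActivationEquation]:
    """One sloppy-logic equation per active-protein node of the split network."""
    equations = []
    for n, data in split_network.nodes(data=True):
        if data.get("role") != "active":
            continue
        base = data["base"]
        activators, inhibitors = [], []
        for u, _, edata in split_network.in_edges(n, data=True):
            if edata.get("regulation_type") == "transcript_dependency":
                continue
            if edata.get("sign") == "negative":
                inhibitors.append(u)
            else:
                activators.append(u)
        equations.append(
            ActivationEquation(
                node=base,
                transcript_var=f"{base}_T",
                activators=tuple(sorted(activators)),
                inhibitors=tuple(sorted(inhibitors)),
                active_var=n,
            )
        )
    return equations


def solve_protein_activation(
    normalized: NormalizedExpressionMatrix,
    equations: list[ActivationEquation],
    tol: float = 1e-8,
    max_iter: int = 2000,
) -> NormalizedExpressionMatrix:
    """Solve the coupled activation equations per sample and append X_A rows.

    The nonlinear system ``X_A - F(X_A) = 0`` is solved with scipy's hybrid
    Powell root finder started from ``X_A = X_T``; when that does not reach
    the residual tolerance (e.g. on singular systems with a continuum of
    fixed points), a damped fixed-point iteration ``x <- (x + F(x)) / 2``
    takes over. Every factor of F maps into [0, 1], so solutions are clipped
    only to guard float error. Row names ``<gene>_T`` alias the gene's own
    row so both spellings resolve during training.
    """
    from scipy import optimize

    if tol <= 0:
        raise ValueError("tol must be positive")
    values = normalized.values
    transcript_rows = {}
    for eq in equations:
        if eq.node not in values.index:
            raise KeyError(f"no expression row for split node {eq.node!r}")
        transcript_rows[eq.transcript_var] = values.loc[eq.node]
    active_rows = {eq.active_var: [] for eq in equations}
    for sample in values.columns:
        state: dict[str, float] = {g: float(values.at[g, sample]) for g in values.index}
        for eq in equations:
            state[eq.transcript_var] = state[eq.node]
            state[eq.active_var] = state[eq.node]  # initial guess X_A = X_T

        def _residuals(x):
            for eq, v in zip(equations, x):
                state[eq.active_var] = float(v)
            return [state[eq.active_var] - eq.rhs(state) for eq in equations]

        def _max_residual():
            return max(
                (abs(state[eq.active_var] - eq.rhs(state)) for eq in equations),
                default=0.0,
            )

        if equations:
            x0 = [state[eq.active_var] for eq in equations]
            sol = optimize.root(_residuals, x0, method="hybr")
            _residuals(sol.x)
        if _max_residual() >= tol:
            # fallback: damped fixed point from X_A = X_T (robust on singular
            # systems, linear convergence otherwise)
            for eq in equations:
                state[eq.active_var] = state[eq.node]
            for _ in range(max_iter):
                for eq in equations:
                    state[eq.active_var] = 0.5 * (state[eq.active_var] + eq.rhs(state))
                if _max_residual() < tol:
                    break
        if _max_residual() >= tol:
            bad = [
                eq.active_var
                for eq in equations
                if abs(state[eq.active_var] - eq.rhs(state)) >= tol
            ]
            raise RuntimeError(
                f"activation solve did not converge in sample {sample!r} "
                f"for nodes {bad}"
            )
        for eq in equations:
            active_rows[eq.active_var].append(min(max(state[eq.active_var], 0.0), 1.0))
    extra = pd.DataFrame(
        {s: [active_rows[v][k] for v in active_rows] for k, s in enumerate(values.columns)},
        index=list(active_rows),
    )
    alias = pd.DataFrame(
        {s: [transcript_rows[v][s] for v in transcript_rows] for s in values.columns},
        index=list(transcript_rows),
    )
    combined = pd.concat([values, alias, extra])
    return NormalizedExpressionMatrix(
        values=combined,
        sample_conditions=normalized.sample_conditions,
        raw_transform=normalized.raw_transform,
    )


# ---------------------------------------------------------------------------
# rule inference
# ---------------------------------------------------------------------------

def infer_probabilistic_rule(
    target: str,
    regulators,
    training: NormalizedExpressionMatrix,
    prior_weight: float = 1.0,
) -> ProbabilisticRule:
    """Fit the probabilistic update rule of one target from steady states.

    See the module docstring for the estimator. With no regulators the rule
    is the uninformative constant 0.5 (the node becomes a source for later
    analyses). More than 6 regulators triggers a warning: the table is then
    dominated by the prior almost everywhere.
    """
    regulators = tuple(regulators)
    n = len(regulators)
    if n == 0:
        return ProbabilisticRule(target, (), np.array([0.5]), np.array([0.0]))
    if n > MAX_RELIABLE_REGULATORS:
        warnings.warn(
            f"rule for {target!r} has {n} regulators; inference with more than "
            f"{MAX_RELIABLE_REGULATORS} inputs is nearly unconstrained by data",
            stacklevel=2,
        )
    values = training.values
    for name in (target, *regulators):
        if name not in values.index:
            raise KeyError(f"no training row for {name!r}")
    x = values.loc[list(regulators)].to_numpy(dtype=float)  # N x S
    y = values.loc[target].to_numpy(dtype=float)
    table = np.empty(2**n)
    support = np.empty(2**n)
    for idx, bits in enumerate(enumerate_configs(n)):
        w = np.ones_like(y)
        for i, b in enumerate(bits):
            w = w * (x[i] if b else 1.0 - x[i])
        s = w.sum()
        table[idx] = (0.5 * prior_weight + w @ y) / (prior_weight + s)
        support[idx] = s
    return ProbabilisticRule(target, regulators, table, support)


def regulator_significance(rule: ProbabilisticRule, regulator: str) -> RegulatorSignificance:
    """Maximum absolute change in the rule's output the regulator can cause
    by switching OFF -> ON, over all configurations of the other regulators."""
    if regulator not in rule.regulators:
        raise KeyError(f"{regulator!r} is not a regulator of {rule.target!r}")
    axis = rule.regulators.index(regulator)
    cube = rule.table.reshape((2,) * rule.n_regulators)
    diff = np.abs(np.take(cube, 1, axis=axis) - np.take(cube, 0, axis=axis))
    return RegulatorSignificance(regulator=regulator, value=float(diff.max()))


def prune_insignificant_regulators(
    target: str,
    regulators,
    training: NormalizedExpressionMatrix,
    threshold: float = SIGNIFICANCE_THRESHOLD,
    prior_weight: float = 1.0,
) -> ProbabilisticRule:
    """Iteratively refit the rule, dropping the least significant regulator.

    While any regulator's significance falls below ``threshold``, the single
    lowest-significance regulator is removed (ties broken lexicographically by
    id) and the rule re-inferred on the survivors. If no regulator survives,
    the returned rule is the constant-0.5 source prior.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    regs = list(regulators)
    while True:
        rule = infer_probabilistic_rule(target, regs, training, prior_weight)
        if not regs:
            return rule
        sigs = {r: regulator_significance(rule, r).value for r in regs}
        if min(sigs.values()) >= threshold:
            return rule
        worst = min(sigs.values())
        victim = min(r for r, v in sigs.items() if v == worst)
        logger.debug("pruning %s from rule of %s (significance %.4f)", victim, target, worst)
        regs.remove(victim)


# ---------------------------------------------------------------------------
# whole-network inference
# ---------------------------------------------------------------------------

@dataclass
class RuleSet:
    """Inferred rules for a whole network plus its effective source nodes."""

    rules: dict[str, ProbabilisticRule]
    source_nodes: set[str] = field(default_factory=set)

    @property
    def nodes(self) -> list[str]:
        return sorted(set(self.rules) | self.source_nodes)


def _deterministic_activation_rule(eq: ActivationEquation) -> ProbabilisticRule:
    """Inhibitory-dominant Boolean update for an active-protein node:
    ``X_A = X_T and (or activators) and not (or inhibitors)`` (the activator
    clause is dropped when there are none)."""
    regs = (eq.transcript_var, *eq.activators, *eq.inhibitors)
    n_act = len(eq.activators)
    table = []
    for bits in enumerate_configs(len(regs)):
        x_t = bits[0]
        acts = bits[1 : 1 + n_act]
        inhs = bits[1 + n_act :]
        on = x_t and (any(acts) if acts else True) and not any(inhs)
        table.append(1.0 if on else 0.0)
    return ProbabilisticRule.from_truth_table(eq.active_var, regs, table)


def infer_network_rules(
    network: nx.DiGraph,
    normalized: NormalizedExpressionMatrix,
    tf_flags: dict[str, bool] | set,
    threshold: float = SIGNIFICANCE_THRESHOLD,
    prior_weight: float = 1.0,
    activation_tol: float = 1e-8,
) -> tuple[RuleSet, nx.DiGraph, NormalizedExpressionMatrix]:
    """Run the full inference stage on an assembled network.

    Classifies edge types, splits post-translationally regulated nodes,
    solves the activation system, then infers and prunes a rule for every
    node with regulators. Active-protein nodes get the deterministic
    inhibitory-dominant rule; training targets use ``X_A`` rows where they
    exist. Returns the rule set, the split network, and the extended
    training matrix.
    """
    typed = classify_edge_types(network, tf_flags)
    split = split_post_translational_nodes(typed)
    equations = build_activation_equations(split)
    training = solve_protein_activation(normalized, equations, tol=activation_tol)
    rules: dict[str, ProbabilisticRule] = {}
    sources: set[str] = set()
    eq_by_var = {eq.active_var: eq for eq in equations}
    for node in sorted(split.nodes):
        data = split.nodes[node]
        if data.get("role") == "active":
            rules[node] = _deterministic_activation_rule(eq_by_var[node])
            continue
        regs = sorted(split.predecessors(node))
        if not regs:
            sources.add(node)
            continue
        row = node if node in training.values.index else data.get("base")
        if row is None or row not in training.values.index:
            raise KeyError(f"no training row for network node {node!r}")
        local = training
        if row != node:
            # target spelled differently from its expression row (split _T form)
            extra = training.values.loc[[row]].rename(index={row: node})
            local = NormalizedExpressionMatrix(
                pd.concat([training.values, extra]),
                training.sample_conditions,
                training.raw_transform,
            )
        rule = prune_insignificant_regulators(
            node, regs, local, threshold=threshold, prior_weight=prior_weight
        )
        if rule.n_regulators == 0:
            sources.add(node)
        else:
            rules[node] = rule
    return RuleSet(rules=rules, source_nodes=sources), split, training


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def rule_to_frame(rule: ProbabilisticRule) -> pd.DataFrame:
    """One row per regulator configuration: regulator bits, probability, support."""
    rows = []
    for idx, bits in enumerate(enumerate_configs(rule.n_regulators)):
        row = {r: b for r, b in zip(rule.regulators, bits)}
        row["probability"] = rule.table[idx]
        row["support"] = rule.support[idx]
        rows.append(row)
    return pd.DataFrame(rows)


def write_ruleset(ruleset: RuleSet, outdir) -> None:
    """Write per-node rule CSVs plus a manifest JSON."""
    import json
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"sources": sorted(ruleset.source_nodes), "nodes": {}}
    for node, rule in sorted(ruleset.rules.items()):
        safe = node.replace("/", "_")
        rule_to_frame(rule).to_csv(outdir / f"rule_{safe}.csv", index=False)
        manifest["nodes"][node] = {
            "regulators": list(rule.regulators),
            "deterministic": rule.deterministic,
            "file": f"rule_{safe}.csv",
        }
    (outdir / "rules_manifest.json").write_text(json.dumps(manifest, indent=2))


def read_ruleset(indir) -> RuleSet:
    import json
    from pathlib import Path

    indir = Path(indir)
    manifest = json.loads((indir / "rules_manifest.json").read_text())
    rules = {}
    for node, meta in manifest["nodes"].items():
        frame = pd.read_csv(indir / meta["file"])
        regs = tuple(meta["regulators"])
        order = np.array([config_index(row) for row in frame[list(regs)].to_numpy()])
        table = np.empty(len(frame))
        support = np.empty(len(frame))
        table[order] = frame["probability"].to_numpy()
        support[order] = frame["support"].to_numpy()
        rules[node] = ProbabilisticRule(
            node, regs, table, support, deterministic=bool(meta["deterministic"])
        )
    return RuleSet(rules=rules, source_nodes=set(manifest["sources"]))
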