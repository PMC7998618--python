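"""Synthetic ground truth for exercising the whole pipeline offline.

Real inputs to the pipeline are an RNAseq-derived expression matrix
(conditions x replicates), a stack of curated interaction databases with
inconsistent gene naming, alias tables, and a transcription-factor list.
This module fabricates all of them from a known Boolean model so that every
downstream stage — assembly, rule inference, attractor search, intervention
simulation — has fixtures with a recoverable ground truth.

Defaults mirror the study design the pipeline assumes: 6 experimental
conditions measured in triplicate (18 samples), FPKM-like ON values drawn
from [20, 200] and OFF values from [0, 2] with lognormal replicate noise, so
the downstream 20th/80th-percentile normalization cleanly separates states
whenever a gene differs across conditions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .rules import ProbabilisticRule, config_index, enumerate_configs

_MAX_FAMILY_INPUTS = 3  # rule family spans 1..3 inputs


@dataclass
class BoolRule:
    """Deterministic truth table over named regulators (ground truth)."""

    regulators: tuple[str, ...]
    table: np.ndarray  # 0/1, length 2**len(regulators)

    def evaluate(self, values: dict[str, int]) -> int:
        return int(self.table[config_index(values[r] for r in self.regulators)])

    def as_probabilistic(self, target: str) -> ProbabilisticRule:
        return ProbabilisticRule.from_truth_table(target, self.regulators, self.table)


@dataclass
class GroundTruthModel:
    nodes: list[str]
    modules: dict[str, str]
    tf_flags: dict[str, bool]
    rules: dict[str, BoolRule]  # non-source nodes only
    source_nodes: list[str]
    seed: int

    def __post_init__(self) -> None:
        node_set = set(self.nodes)
        for tgt, rule in self.rules.items():
            unknown = set(rule.regulators) - node_set
            if unknown:
                raise ValueError(f"rule for {tgt} names non-nodes {sorted(unknown)}")
        if set(self.rules) & set(self.source_nodes):
            raise ValueError("source nodes must not carry rules")
        if not set(self.source_nodes) <= node_set:
            raise ValueError("source nodes must be nodes of the model")
        if set(self.modules) != node_set:
            raise ValueError("module labels must partition the node set")

    @property
    def edges(self) -> set[tuple[str, str]]:
        return {(r, t) for t, rule in self.rules.items() for r in rule.regulators}

    def edge_sign(self, source: str, target: str) -> str:
        """'+', '-' or '?' from the truth table: sign of the mean output
        change when the regulator flips OFF -> ON."""
        rule = self.rules[target]
        axis = rule.regulators.index(source)
        cube = rule.table.reshape((2,) * len(rule.regulators))
        delta = float(np.take(cube, 1, axis=axis).mean() - np.take(cube, 0, axis=axis).mean())
        if delta > 0:
            return "+"
        if delta < 0:
            return "-"
        return "?"


@dataclass
class SyntheticExpressionSpec:
    n_conditions: int = 6
    n_replicates: int = 3
    high_range: tuple[float, float] = (20.0, 200.0)
    low_range: tuple[float, float] = (0.0, 2.0)
    noise_sd: float = 0.2
    dropout_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.high_range[0] <= self.low_range[1]:
            raise ValueError("high_range must lie strictly above low_range")
        if self.n_conditions * self.n_replicates < 2:
            raise ValueError("need at least 2 samples")
        if self.noise_sd < 0 or not 0 <= self.dropout_rate <= 1:
            raise ValueError("invalid noise_sd or dropout_rate")


# ---------------------------------------------------------------------------
# ground-truth network generation
# ---------------------------------------------------------------------------

def _sample_rule(rng: np.random.Generator, regulators: tuple[str, ...]) -> BoolRule:
    """Draw a rule from the generator family for the given regulators:
    identity/negation (1 input), AND/OR with random literal signs (2 inputs),
    or the inhibitory-dominant form (activators OR'd, then AND NOT inhibitor;
    3 inputs)."""
    k = len(regulators)
    table = np.zeros(2**k, dtype=np.uint8)
    if k == 1:
        negate = bool(rng.integers(2))
        for idx, (b,) in enumerate(enumerate_configs(1)):
            table[idx] = (1 - b) if negate else b
    elif k == 2:
        use_and = bool(rng.integers(2))
        signs = rng.integers(2, size=2)  # 1 = negated literal
        for idx, bits in enumerate(enumerate_configs(2)):
            lits = [b ^ s for b, s in zip(bits, signs)]
            table[idx] = (lits[0] & lits[1]) if use_and else (lits[0] | lits[1])
    elif k == 3:
        inhibitor = int(rng.integers(3))
        for idx, bits in enumerate(enumerate_configs(3)):
            acts = [b for i, b in enumerate(bits) if i != inhibitor]
            table[idx] = int(any(acts) and not bits[inhibitor])
    else:  # pragma: no cover - family capped at 3 inputs
        raise ValueError("rule family spans 1..3 inputs")
    return BoolRule(regulators=regulators, table=table)


def _try_generate(
    rng: np.random.Generator, n_nodes: int, n_modules: int, max_in_degree: int
) -> GroundTruthModel | None:
    nodes = [f"G{i + 1:02d}" for i in range(n_nodes)]
    n_sources = max(1, round(0.2 * n_nodes))
    source_idx = rng.choice(n_nodes, size=n_sources, replace=False)
    sources = sorted(nodes[i] for i in source_idx)
    regulated = [n for n in nodes if n not in sources]
    max_k = min(max_in_degree, _MAX_FAMILY_INPUTS)
    rules: dict[str, BoolRule] = {}
    for node in regulated:
        k = int(rng.integers(1, max_k + 1))
        pool = [n for n in nodes if n != node]
        regs = tuple(sorted(rng.choice(pool, size=min(k, len(pool)), replace=False)))
        rules[node] = _sample_rule(rng, regs)

    import networkx as nx

    g = nx.DiGraph()
    g.add_nodes_from(nodes)
    g.add_edges_from((r, t) for t, rule in rules.items() for r in rule.regulators)
    if not nx.is_weakly_connected(g):
        return None
    try:
        next(nx.simple_cycles(g))
    except StopIteration:
        return None  # no feedback loop

    labels = [f"m{i + 1}" for i in range(n_modules)]
    order = list(rng.permutation(nodes))
    modules = {}
    for i, node in enumerate(order):
        if i < n_modules:
            modules[node] = labels[i]  # every label gets at least one node
        else:
            modules[node] = (
                "unassigned" if rng.random() < 0.15 else labels[int(rng.integers(n_modules))]
            )
    tf_flags = {n: bool(rng.random() < 0.5) for n in nodes}
    return GroundTruthModel(
        nodes=nodes, modules=modules, tf_flags=tf_flags, rules=rules,
        source_nodes=sources, seed=0,
    )


def generate_ground_truth_network(
    n_nodes: int, n_modules: int, max_in_degree: int, seed: int
) -> GroundTruthModel:
    """Random connected Boolean model with at least one source node and one
    feedback loop; rules drawn from the 1-to-3-input family. Deterministic
    given the seed (rejection sampling over derived streams)."""
    if n_nodes < 4:
        raise ValueError("need at least 4 nodes")
    if not 1 <= max_in_degree <= 5:
        raise ValueError("max_in_degree must lie in 1..5")
    if n_modules < 1 or n_modules > n_nodes:
        raise ValueError("n_modules must lie in 1..n_nodes")
    for attempt in range(500):
        rng = np.random.default_rng(np.random.SeedSequence([seed, attempt]))
        model = _try_generate(rng, n_nodes, n_modules, max_in_degree)
        if model is not None:
            model.seed = seed
            return model
    raise RuntimeError("could not generate a connected model with feedback")  # pragma: no cover


# ---------------------------------------------------------------------------
# expression generation
# ---------------------------------------------------------------------------

def _condition_attractor_state(model: GroundTruthModel, pinning: dict[str, int]) -> dict[str, float]:
    """Relax the deterministic model under a source pinning to its first
    pseudo-attractor; oscillating nodes get activation 0.5."""
    from .attractors import DeterministicRuleSet, find_pseudo_attractors, propagate_constants

    det = DeterministicRuleSet(
        rules={t: (r.regulators, r.table) for t, r in model.rules.items()}
    )
    reduced = propagate_constants(det, pinning)
    attractor = find_pseudo_attractors(reduced)[0]
    return {n: attractor.value(n) for n in model.nodes}


def generate_expression(
    model: GroundTruthModel, spec: SyntheticExpressionSpec, seed: int
) -> tuple[pd.DataFrame, dict[str, str]]:
    """FPKM-like expression for ``n_conditions x n_replicates`` samples.

    Each condition pins the model's source nodes to a distinct Boolean
    pattern and relaxes the system to an attractor; ON genes draw a base
    level from ``high_range``, OFF genes from ``low_range`` (oscillating
    genes from the gap in between), shared by the condition's replicates.
    Replicates multiply the base by lognormal noise ``exp(noise_sd * z)`` and
    zero out entries with probability ``dropout_rate``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 104729]))
    n_sources = len(model.source_nodes)
    n_patterns = 2**n_sources
    if n_patterns >= spec.n_conditions:
        patterns = rng.choice(n_patterns, size=spec.n_conditions, replace=False)
    else:
        patterns = rng.integers(0, n_patterns, size=spec.n_conditions)
    columns: dict[str, np.ndarray] = {}
    condition_map: dict[str, str] = {}
    for c, pattern in enumerate(patterns):
        condition = f"C{c + 1}"
        pinning = {
            s: (int(pattern) >> i) & 1 for i, s in enumerate(model.source_nodes)
        }
        state = _condition_attractor_state(model, pinning)
        base = np.empty(len(model.nodes))
        for i, node in enumerate(model.nodes):
            v = state[node]
            if v == 1:
                base[i] = rng.uniform(*spec.high_range)
            elif v == 0:
                base[i] = rng.uniform(*spec.low_range)
            else:  # oscillating: intermediate level between the two ranges
                base[i] = rng.uniform(spec.low_range[1], spec.high_range[0])
        for r in range(spec.n_replicates):
            sample = f"{condition}_r{r + 1}"
            noise = (
                np.exp(spec.noise_sd * rng.standard_normal(len(base)))
                if spec.noise_sd > 0
                else 1.0
            )
            col = base * noise
            if spec.dropout_rate > 0:
                col = np.where(rng.random(len(col)) < spec.dropout_rate, 0.0, col)
            columns[sample] = col
            condition_map[sample] = condition
    frame = pd.DataFrame(columns, index=model.nodes)
    return frame, condition_map


def rule_training_matrix(model_or_rule, target: str | None = None):
    """Noiseless normalized training data covering every regulator
    configuration of one rule: one sample per configuration, regulator rows
    set to the configuration bits and the target row to the rule's output.

    Accepts either a :class:`GroundTruthModel` plus target name, or a
    ``(regulators, table)``-style :class:`BoolRule` with an explicit target.
    Returns a :class:`~pbnet.rules.NormalizedExpressionMatrix`.
    """
    from .rules import NormalizedExpressionMatrix

    if isinstance(model_or_rule, GroundTruthModel):
        rule = model_or_rule.rules[target]
    else:
        rule = model_or_rule
    if target is None:
        raise ValueError("target name required")
    regs = list(rule.regulators)
    data = {}
    for idx, bits in enumerate(enumerate_configs(len(regs))):
        col = {r: float(b) for r, b in zip(regs, bits)}
        col[target] = float(rule.table[idx])
        data[f"cfg{idx}"] = col
    frame = pd.DataFrame(data).loc[regs + [target]]
    return NormalizedExpressionMatrix(
        values=frame,
        sample_conditions={s: "cfg" for s in frame.columns},
        raw_transform="none",
    )


# ---------------------------------------------------------------------------
# interaction databases, aliases, TF list
# ---------------------------------------------------------------------------

@dataclass
class SyntheticDatabases:
    """Interaction tables with internally labeled decoys, alias tables, and
    the TF list, as produced by :func:`generate_interaction_databases`."""

    interaction_tables: list[pd.DataFrame]  # includes boolean column is_decoy
    alias_tables: list[pd.DataFrame]
    tf_list: list[str]
    decoy_edges: set[tuple[str, str]] = field(default_factory=set)


def _stylize(name: str, rng: np.random.Generator) -> str:
    """Case/punctuation variant recoverable by canonicalization
    ('G01' -> 'g-01' style)."""
    chars = [c.lower() if rng.random() < 0.5 else c for c in name]
    pos = int(rng.integers(1, len(chars)))
    chars.insert(pos, str(rng.choice(["-", "_", "."])))
    return "".join(chars)


def generate_interaction_databases(
    model: GroundTruthModel,
    n_resources: int,
    alias_noise: float,
    decoy_edge_rate: float,
    seed: int,
) -> SyntheticDatabases:
    """Noisy multi-resource interaction tables for the model's edge set.

    Every true edge appears in at least one resource. With probability
    ``alias_noise`` an endpoint name is replaced by a registered alias, and
    independently by a case/punctuation variant; both are recoverable via the
    emitted alias tables plus canonicalization. Decoy edges (false
    interactions at ``decoy_edge_rate`` per true edge) carry reference count
    1 and confidence 0 so downstream score pruning can remove them; they are
    flagged in the ``is_decoy`` column for test assertions only.
    """
    if n_resources < 1:
        raise ValueError("need at least one resource")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7919]))
    aliases = {n: f"{n}ALT" for n in model.nodes}
    alias_pairs = sorted(aliases.items())
    half = len(alias_pairs) // 2 or 1
    alias_tables = [
        pd.DataFrame(alias_pairs[:half], columns=["name", "alias"]),
        pd.DataFrame(alias_pairs[half:], columns=["name", "alias"]),
    ]
    resource_names = [f"resource{k + 1}" for k in range(n_resources)]
    has_confidence = {name: k % 2 == 0 for k, name in enumerate(resource_names)}

    def emit_name(node: str) -> str:
        name = node
        if rng.random() < alias_noise:
            name = aliases[node]
        if rng.random() < alias_noise:
            name = _stylize(name, rng)
        return name

    records: dict[str, list[dict]] = {r: [] for r in resource_names}
    true_edges = sorted(model.edges)
    for src, tgt in true_edges:
        member = rng.random(n_resources) < 0.6
        if not member.any():
            member[int(rng.integers(n_resources))] = True
        sign = model.edge_sign(src, tgt)
        for k, resource in enumerate(resource_names):
            if not member[k]:
                continue
            conf = float(rng.uniform(0.3, 1.0)) if has_confidence[resource] else 0.0
            records[resource].append(
                {
                    "source": emit_name(src),
                    "target": emit_name(tgt),
                    "effect": sign,
                    "n_references": int(1 + rng.poisson(2)),
                    "confidence": round(conf, 3),
                    "resource": resource,
                    "is_decoy": False,
                }
            )
    decoy_edges: set[tuple[str, str]] = set()
    n_decoys = int(round(decoy_edge_rate * len(true_edges)))
    guard = 0
    while len(decoy_edges) < n_decoys and guard < 50 * max(n_decoys, 1):
        guard += 1
        src, tgt = (str(x) for x in rng.choice(model.nodes, size=2, replace=False))
        if (src, tgt) in model.edges or (src, tgt) in decoy_edges:
            continue
        decoy_edges.add((src, tgt))
        resource = resource_names[int(rng.integers(n_resources))]
        records[resource].append(
            {
                "source": emit_name(src),
                "target": emit_name(tgt),
                "effect": "?",
                "n_references": 1,
                "confidence": 0.0,
                "resource": resource,
                "is_decoy": True,
            }
        )
    tables = [
        pd.DataFrame(
            records[r],
            columns=["source", "target", "effect", "n_references", "confidence",
                     "resource", "is_decoy"],
        )
        for r in resource_names
    ]
    tf_list = sorted(n for n, f in model.tf_flags.items() if f)
    return SyntheticDatabases(
        interaction_tables=tables,
        alias_tables=alias_tables,
        tf_list=tf_list,
        decoy_edges=decoy_edges,
    )


# ---------------------------------------------------------------------------
# writers / readers (plain-text external formats)
# ---------------------------------------------------------------------------

def write_fixture_set(
    outdir,
    model: GroundTruthModel,
    expression: pd.DataFrame,
    condition_map: dict[str, str],
    databases: SyntheticDatabases,
) -> dict[str, str]:
    """Write the full synthetic fixture set as TSV/text/JSON; returns the
    path map. Decoy labels are dropped from the interaction TSVs (they are
    internal ground truth, not database content)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}
    for k, table in enumerate(databases.interaction_tables):
        p = outdir / f"interactions_{k + 1}.tsv"
        table.drop(columns=["is_decoy"]).to_csv(p, sep="\t", index=False)
        paths[f"interactions_{k + 1}"] = str(p)
    for k, table in enumerate(databases.alias_tables):
        p = outdir / f"aliases_{k + 1}.tsv"
        table.to_csv(p, sep="\t", index=False, header=False)
        paths[f"aliases_{k + 1}"] = str(p)
    p = outdir / "tfs.txt"
    p.write_text("\n".join(databases.tf_list) + "\n")
    paths["tfs"] = str(p)
    p = outdir / "expression.tsv"
    expression.to_csv(p, sep="\t", index_label="gene")
    paths["expression"] = str(p)
    p = outdir / "conditions.tsv"
    pd.DataFrame(sorted(condition_map.items()), columns=["sample", "condition"]).to_csv(
        p, sep="\t", index=False
    )
    paths["conditions"] = str(p)
    p = outdir / "modules.tsv"
    pd.DataFrame(sorted(model.modules.items()), columns=["gene", "module"]).to_csv(
        p, sep="\t", index=False
    )
    paths["modules"] = str(p)
    p = outdir / "ground_truth.json"
    p.write_text(model_to_json(model))
    paths["ground_truth"] = str(p)
    return paths


def model_to_json(model: GroundTruthModel) -> str:
    return json.dumps(
        {
            "nodes": model.nodes,
            "modules": model.modules,
            "tf_flags": model.tf_flags,
            "source_nodes": model.source_nodes,
            "seed": model.seed,
            "rules": {
                t: {"regulators": list(r.regulators), "table": r.table.tolist()}
                for t, r in model.rules.items()
            },
        },
        indent=2,
    )


def model_from_json(text: str) -> GroundTruthModel:
    raw = json.loads(text)
    return GroundTruthModel(
        nodes=raw["nodes"],
        modules=raw["modules"],
        tf_flags={k: bool(v) for k, v in raw["tf_flags"].items()},
        rules={
            t: BoolRule(tuple(r["regulators"]), np.array(r["table"], dtype=np.uint8))
            for t, r in raw["rules"].items()
        },
        source_nodes=raw["source_nodes"],
        seed=raw["seed"],
    )
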