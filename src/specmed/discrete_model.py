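"""Discrete causal Bayesian networks with exact enumeration-based inference.

A :class:`CausalModel` is a DAG over finitely-supported categorical variables
together with one conditional probability distribution (CPD) per node.  The
joint distribution factorizes according to the causal Markov condition, and
interventions follow the truncated-factorization (do-operator) semantics:
``do(X=x)`` removes the edges into ``X`` and replaces its CPD with a point
mass at ``x``.

Intended scale is small models (roughly up to ten variables with small
alphabets); all queries enumerate the joint support exactly.  There is no
approximate inference.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import yaml

CPD_ROW_TOL = 1e-12   # tolerance for a CPD row summing to one
PMF_TOL = 1e-10       # tolerance for a derived pmf summing to one

Label = object  # category labels are arbitrary hashables (strings, ints, ...)


class ModelError(ValueError):
    """A structurally invalid model, query, or label."""


class UnsupportedEvidenceError(ModelError):
    """Conditioning on an event of probability zero."""


@dataclass(frozen=True)
class Variable:
    """A named categorical variable with an ordered finite alphabet."""

    name: str
    alphabet: tuple

    def __post_init__(self):
        object.__setattr__(self, "alphabet", tuple(self.alphabet))
        if len(self.alphabet) == 0:
            raise ModelError(f"variable {self.name!r}: empty alphabet")
        if len(set(self.alphabet)) != len(self.alphabet):
            raise ModelError(f"variable {self.name!r}: duplicate labels")

    def index(self, label: Label) -> int:
        try:
            return self.alphabet.index(label)
        except ValueError:
            raise ModelError(
                f"label {label!r} not in alphabet of {self.name!r}"
            ) from None


@dataclass(frozen=True)
class Dag:
    """A directed acyclic graph over named nodes."""

    nodes: frozenset
    edges: frozenset

    def __init__(self, nodes: Iterable[str], edges: Iterable[tuple[str, str]]):
        object.__setattr__(self, "nodes", frozenset(nodes))
        object.__setattr__(self, "edges", frozenset(tuple(e) for e in edges))
        for a, b in self.edges:
            if a not in self.nodes or b not in self.nodes:
                raise ModelError(f"edge ({a!r}, {b!r}) references undeclared node")
        if not nx.is_directed_acyclic_graph(self.graph()):
            raise ModelError("graph contains a directed cycle")

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    def parents(self, node: str) -> tuple[str, ...]:
        if node not in self.nodes:
            raise ModelError(f"unknown node {node!r}")
        return tuple(sorted(a for a, b in self.edges if b == node))

    def topological_order(self) -> list[str]:
        return list(nx.lexicographical_topological_sort(self.graph()))


def cut_outgoing(dag: Dag, x: str) -> Dag:
    """The DAG with all outgoing arrows from ``x`` removed."""
    if x not in dag.nodes:
        raise ModelError(f"unknown node {x!r}")
    return Dag(dag.nodes, {e for e in dag.edges if e[0] != x})


def d_separated(dag: Dag, a: Iterable[str], b: Iterable[str], c: Iterable[str]) -> bool:
    """Standard d-separation of node sets ``a`` and ``b`` given ``c``."""
    a, b, c = set(a), set(b), set(c)
    unknown = (a | b | c) - dag.nodes
    if unknown:
        raise ModelError(f"unknown nodes {sorted(map(repr, unknown))}")
    if (a & b) or (a & c) or (b & c):
        raise ModelError("d-separation query requires disjoint node sets")
    return nx.is_d_separator(dag.graph(), a, b, c)


@dataclass(frozen=True)
class Cpd:
    """Conditional distribution of ``child`` given an ordered parent list.

    ``table`` maps each parent-value tuple to a probability vector over the
    child alphabet (in alphabet order).
    """

    child: str
    parents: tuple[str, ...]
    table: Mapping[tuple, np.ndarray]

    def __init__(self, child, parents, table):
        object.__setattr__(self, "child", child)
        object.__setattr__(self, "parents", tuple(parents))
        object.__setattr__(
            self,
            "table",
            {tuple(k): np.asarray(v, dtype=float) for k, v in dict(table).items()},
        )

    @staticmethod
    def point_mass(child: str, variable: Variable, label: Label) -> "Cpd":
        vec = np.zeros(len(variable.alphabet))
        vec[variable.index(label)] = 1.0
        return Cpd(child, (), {(): vec})


@dataclass(frozen=True)
class Intervention:
    """An assignment set for the do-operator."""

    assignments: Mapping[str, Label]

    def __init__(self, assignments: Mapping[str, Label] | None = None, **kw):
        merged = dict(assignments or {})
        merged.update(kw)
        object.__setattr__(self, "assignments", merged)

    def __bool__(self):
        return bool(self.assignments)


class Pmf:
    """Exact probability mass function over a finite joint support.

    Stored densely as an ndarray with one axis per variable, axis order
    matching ``variables`` and axis coordinates matching each variable's
    alphabet order.
    """

    def __init__(self, variables: Sequence[Variable], array: np.ndarray,
                 check: bool = True):
        self.variables = tuple(variables)
        self.array = np.asarray(array, dtype=float)
        expected = tuple(len(v.alphabet) for v in self.variables)
        if self.array.shape != expected:
            raise ModelError(
                f"pmf shape {self.array.shape} does not match alphabets {expected}"
            )
        if check:
            if np.any(self.array < -PMF_TOL):
                raise ModelError("pmf has negative probabilities")
            total = float(self.array.sum())
            if abs(total - 1.0) > PMF_TOL:
                raise ModelError(f"pmf mass {total} is not 1 within {PMF_TOL}")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(v.name for v in self.variables)

    def variable(self, name: str) -> Variable:
        for v in self.variables:
            if v.name == name:
                return v
        raise ModelError(f"unknown variable {name!r}")

    def support(self):
        """Iterate ``(assignment_tuple, probability)`` over the full support."""
        alphabets = [v.alphabet for v in self.variables]
        for idx, labels in zip(np.ndindex(self.array.shape),
                               itertools.product(*alphabets)):
            yield labels, float(self.array[idx])

    def prob(self, assignment: Mapping[str, Label]) -> float:
        idx = tuple(self.variable(n).index(assignment[n]) for n in self.names)
        return float(self.array[idx])

    def reorder(self, names: Sequence[str]) -> "Pmf":
        if set(names) != set(self.names):
            raise ModelError("reorder must use the same variable set")
        perm = [self.names.index(n) for n in names]
        return Pmf([self.variables[i] for i in perm],
                   np.transpose(self.array, perm), check=False)

    def same_support(self, other: "Pmf") -> bool:
        try:
            other = other.reorder(self.names)
        except ModelError:
            return False
        return all(a.alphabet == b.alphabet
                   for a, b in zip(self.variables, other.variables))


def marginal(pmf: Pmf, keep: Sequence[str]) -> Pmf:
    """Sum out every variable not in ``keep`` (order follows ``keep``)."""
    keep = list(keep)
    unknown = set(keep) - set(pmf.names)
    if unknown:
        raise ModelError(f"unknown variables {sorted(map(repr, unknown))}")
    drop_axes = tuple(i for i, n in enumerate(pmf.names) if n not in keep)
    arr = pmf.array.sum(axis=drop_axes) if drop_axes else pmf.array
    kept_vars = [v for v in pmf.variables if v.name in keep]
    out = Pmf(kept_vars, arr, check=False)
    return out.reorder(keep)


def condition(pmf: Pmf, evidence: Mapping[str, Label]) -> Pmf:
    """Renormalized restriction of ``pmf`` to the evidence event.

    Raises :class:`UnsupportedEvidenceError` when the event has probability
    zero; callers that average over contexts are expected to skip such
    contexts explicitly rather than receive NaN.
    """
    if not evidence:
        return pmf
    index = []
    kept = []
    for v in pmf.variables:
        if v.name in evidence:
            index.append(v.index(evidence[v.name]))
        else:
            index.append(slice(None))
            kept.append(v)
    restricted = pmf.array[tuple(index)]
    mass = float(np.asarray(restricted).sum())
    if mass <= 0.0:
        raise UnsupportedEvidenceError(
            f"evidence {dict(evidence)!r} has probability zero"
        )
    arr = np.asarray(restricted) / mass
    if not kept:  # evidence on all variables: scalar point mass
        return Pmf([], arr.reshape(()), check=False)
    return Pmf(kept, arr, check=False)


@dataclass(frozen=True)
class CausalModel:
    """DAG + one CPD per node; the joint pmf of the causal Markov factorization.

    ``covariate_roles`` optionally records which covariate nodes belong to
    UX / UY / UZ (overlap allowed); it is carried through interventions
    untouched and only interpreted by callers.
    """

    variables: Mapping[str, Variable]
    dag: Dag
    cpds: Mapping[str, Cpd]
    covariate_roles: Mapping[str, frozenset] = field(default_factory=dict)

    def __init__(self, variables, dag, cpds, covariate_roles=None):
        if not isinstance(variables, Mapping):
            variables = {v.name: v for v in variables}
        object.__setattr__(self, "variables", dict(variables))
        object.__setattr__(self, "dag", dag)
        object.__setattr__(self, "cpds", dict(cpds))
        object.__setattr__(
            self,
            "covariate_roles",
            {k: frozenset(v) for k, v in (covariate_roles or {}).items()},
        )

    def variable(self, name: str) -> Variable:
        try:
            return self.variables[name]
        except KeyError:
            raise ModelError(f"unknown variable {name!r}") from None


def validate_model(model: CausalModel) -> list[str]:
    """Check every structural invariant; one diagnostic string per violation."""
    diags: list[str] = []
    if set(model.variables) != model.dag.nodes:
        diags.append("variable set does not match DAG nodes")
    if set(model.cpds) != model.dag.nodes:
        diags.append("every node must have exactly one CPD")
    for name in sorted(model.dag.nodes & set(model.cpds)):
        cpd = model.cpds[name]
        dag_parents = model.dag.parents(name)
        if len(set(cpd.parents)) != len(cpd.parents) or \
                tuple(sorted(cpd.parents)) != dag_parents:
            diags.append(
                f"{name}: CPD parents {cpd.parents} != DAG parents {dag_parents}"
            )
            continue
        child_var = model.variables.get(name)
        if child_var is None:
            continue
        parent_alpha = [model.variables[p].alphabet for p in cpd.parents
                        if p in model.variables]
        if len(parent_alpha) != len(cpd.parents):
            continue
        expected_keys = set(itertools.product(*parent_alpha))
        if set(cpd.table) != expected_keys:
            diags.append(f"{name}: CPD table does not cover all parent combinations")
        for key, vec in cpd.table.items():
            if vec.shape != (len(child_var.alphabet),):
                diags.append(f"{name}: row {key} has wrong length")
                continue
            if np.any(vec < 0):
                diags.append(f"{name}: row {key} has negative probabilities")
            if abs(float(vec.sum()) - 1.0) > CPD_ROW_TOL:
                diags.append(f"{name}: row {key} not normalized (sum={vec.sum()})")
    return diags


def _require_valid(model: CausalModel):
    diags = validate_model(model)
    if diags:
        raise ModelError("invalid model: " + "; ".join(diags))


def joint_pmf(model: CausalModel, check: bool = True) -> Pmf:
    """The exact joint distribution by multiplying broadcast CPD factors."""
    if check:
        _require_valid(model)
    order = model.dag.topological_order()
    vars_ = [model.variables[n] for n in order]
    shape = tuple(len(v.alphabet) for v in vars_)
    joint = np.ones(shape)
    axis_of = {n: i for i, n in enumerate(order)}
    for name in order:
        cpd = model.cpds[name]
        # factor array with axes (parent_1, ..., parent_k, child)
        par_vars = [model.variables[p] for p in cpd.parents]
        fac = np.empty(tuple(len(v.alphabet) for v in par_vars)
                       + (len(model.variables[name].alphabet),))
        for key, vec in cpd.table.items():
            idx = tuple(v.index(l) for v, l in zip(par_vars, key))
            fac[idx] = vec
        # broadcast into the full joint shape: permute factor axes into
        # ascending joint-axis order, then reshape with singleton axes
        full_axes = [axis_of[p] for p in cpd.parents] + [axis_of[name]]
        perm = np.argsort(full_axes)
        fac_sorted = np.transpose(fac, perm)
        reshape = [1] * len(order)
        for joint_axis, size in zip(sorted(full_axes), fac_sorted.shape):
            reshape[joint_axis] = size
        joint = joint * fac_sorted.reshape(reshape)
    pmf = Pmf(vars_, joint, check=False)
    total = float(joint.sum())
    if check and abs(total - 1.0) > PMF_TOL:
        raise ModelError(f"joint mass {total} is not 1 within {PMF_TOL}")
    return pmf


def intervene(model: CausalModel, do: Intervention) -> CausalModel:
    """Truncated factorization: drop incoming edges, CPDs become point masses."""
    if not do:
        return model
    for name, label in do.assignments.items():
        model.variable(name).index(label)  # raises on unknown name or label
    new_edges = {e for e in model.dag.edges if e[1] not in do.assignments}
    new_dag = Dag(model.dag.nodes, new_edges)
    new_cpds = dict(model.cpds)
    for name, label in do.assignments.items():
        new_cpds[name] = Cpd.point_mass(name, model.variables[name], label)
    return CausalModel(model.variables, new_dag, new_cpds, model.covariate_roles)


def interventional_query(
    model: CausalModel,
    target: str | Sequence[str],
    do: Intervention | Mapping[str, Label] | None = None,
    given: Mapping[str, Label] | None = None,
) -> Pmf:
    """p(target | do, given): intervene, enumerate, condition, marginalize."""
    targets = [target] if isinstance(target, str) else list(target)
    if do is not None and not isinstance(do, Intervention):
        do = Intervention(do)
    m = intervene(model, do) if do else model
    joint = joint_pmf(m, check=False)
    given = dict(given or {})
    keep = targets + [g for g in given if g not in targets]
    pmf = marginal(joint, keep)
    pmf = condition(pmf, given)
    return pmf.reorder(targets)


@dataclass(frozen=True)
class IdentifiabilityResult:
    identifiable: bool
    witness_u1: frozenset | None = None
    witness_u2: frozenset | None = None


def _subsets_in_order(items: Iterable[str]):
    """Subsets by increasing cardinality, then lexicographic by sorted names."""
    items = sorted(items)
    for r in range(len(items) + 1):
        yield from (frozenset(c) for c in itertools.combinations(items, r))


def check_identifiability(dag: Dag, x: str, z: str, y: str,
                          observed: Iterable[str] = ()) -> IdentifiabilityResult:
    """Observational identifiability of the specific effects of ``x`` on ``y``.

    Searches subsets of the observed covariates for witnesses U1, U2 such
    that X is d-separated from Y given U1, and from Z given U2, in the graph
    with X's outgoing edges removed.  Witnesses are minimal in cardinality
    with ties broken by the deterministic subset order of
    :func:`_subsets_in_order`.
    """
    if len({x, z, y}) != 3:
        raise ModelError("x, z, y must be three distinct nodes")
    observed = set(observed) - {x, z, y}
    g_cut = cut_outgoing(dag, x)
    w1 = next((s for s in _subsets_in_order(observed)
               if d_separated(g_cut, {x}, {y}, s)), None)
    w2 = next((s for s in _subsets_in_order(observed)
               if d_separated(g_cut, {x}, {z}, s)), None)
    if w1 is None or w2 is None:
        return IdentifiabilityResult(False)
    return IdentifiabilityResult(True, w1, w2)


# ---------------------------------------------------------------------------
# model spec I/O


def model_to_dict(model: CausalModel) -> dict:
    return {
        "variables": {n: list(v.alphabet) for n, v in sorted(model.variables.items())},
        "edges": sorted([list(e) for e in model.dag.edges]),
        "cpds": {
            n: {
                "parents": list(c.parents),
                "table": {
                    ",".join(str(l) for l in key): [float(p) for p in vec]
                    for key, vec in sorted(c.table.items(), key=lambda kv: str(kv[0]))
                },
            }
            for n, c in sorted(model.cpds.items())
        },
        "roles": {k: sorted(v) for k, v in sorted(model.covariate_roles.items())},
    }


def model_from_dict(spec: Mapping) -> CausalModel:
    variables = {n: Variable(n, tuple(a)) for n, a in spec["variables"].items()}
    dag = Dag(variables, [tuple(e) for e in spec.get("edges", [])])
    cpds = {}
    for name, entry in spec["cpds"].items():
        parents = tuple(entry.get("parents", ()))
        table = {}
        for key, vec in entry["table"].items():
            if parents:
                parts = [p.strip() for p in str(key).split(",")]
                if len(parts) != len(parents):
                    raise ModelError(
                        f"{name}: key {key!r} does not match parents {parents}"
                    )
                tup = tuple(
                    _coerce_label(part, variables[p].alphabet)
                    for part, p in zip(parts, parents)
                )
            else:
                tup = ()
            table[tup] = np.asarray(vec, dtype=float)
        cpds[name] = Cpd(name, parents, table)
    roles = {k: frozenset(v) for k, v in (spec.get("roles") or {}).items()}
    return CausalModel(variables, dag, cpds, roles)


def _coerce_label(text: str, alphabet: tuple):
    """Match a serialized label back to the declared alphabet."""
    for label in alphabet:
        if str(label) == text:
            return label
    raise ModelError(f"label {text!r} not in alphabet {alphabet}")


def load_model(path: str | Path) -> CausalModel:
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in {".yaml", ".yml"}:
        spec = yaml.safe_load(text)
    else:
        spec = json.loads(text)
    return model_from_dict(spec)


def save_model(model: CausalModel, path: str | Path):
    path = Path(path)
    spec = model_to_dict(model)
    if path.suffix.lower() in {".yaml", ".yml"}:
        path.write_text(yaml.safe_dump(spec, sort_keys=False))
    else:
        path.write_text(json.dumps(spec, indent=2))
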