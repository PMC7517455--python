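"""Baseline information-theoretic causal measures.

Ay–Polani information flow (plain and conditional, node-centric) and the
Janzing et al. causal strength (edge-centric, via the post-cutting
distribution).  These serve both as standalone measures and as independent
oracles for the equivalence theorems linking them to the expected specific
effects.
"""

from __future__ import annotations

import math
from typing import Iterable

import numpy as np

from . import information as info
from .discrete_model import (
    CausalModel,
    Cpd,
    Dag,
    ModelError,
    Pmf,
    Variable,
    interventional_query,
    joint_pmf,
    marginal,
)


def information_flow(model: CausalModel, x: str, y: str) -> float:
    """Ay–Polani information flow I(X -> Y).

    sum_x p(x) sum_y p(y|x^) log [ p(y|x^) / sum_x' p(x') p(y|x^') ].
    Interventional throughout, so confounder-induced dependence is removed.
    """
    p_x = marginal(joint_pmf(model), [x])
    branches = []  # (weight, interventional pmf of y)
    for (x_val,), w in p_x.support():
        p_y = interventional_query(model, y, do={x: x_val})
        branches.append((w, p_y))
    mix_arr = np.zeros_like(branches[0][1].array)
    for w, p_y in branches:
        mix_arr += w * p_y.array
    mix = Pmf(branches[0][1].variables, mix_arr, check=False)
    total = 0.0
    for w, p_y in branches:
        if w <= 0:
            continue
        term = info.kl(p_y, mix)
        if math.isinf(term):
            return math.inf
        total += w * term
    return total


def conditional_information_flow(model: CausalModel, x: str, y: str,
                                 imposed: Iterable[str]) -> float:
    """Information flow from x to y imposing V (every member intervened).

    sum_v p(v) sum_x p(x|v^) sum_y p(y|x^,v^) log
        [ p(y|x^,v^) / sum_x' p(x'|v^) p(y|x^',v^) ].
    """
    imposed = sorted(set(imposed))
    if not imposed:
        return information_flow(model, x, y)
    if x in imposed or y in imposed:
        raise ModelError("imposed set must exclude the cause and the effect")
    p_v = marginal(joint_pmf(model), imposed)
    total = 0.0
    for v_labels, w_v in p_v.support():
        if w_v <= 0:
            continue
        v_do = dict(zip(imposed, v_labels))
        # interventional conditioning: p(x | v^) in the v-intervened model
        p_x = interventional_query(model, x, do=v_do)
        branches = []
        for (x_val,), w_x in p_x.support():
            p_y = interventional_query(model, y, do={x: x_val, **v_do})
            branches.append((w_x, p_y))
        mix_arr = np.zeros_like(branches[0][1].array)
        for w_x, p_y in branches:
            mix_arr += w_x * p_y.array
        mix = Pmf(branches[0][1].variables, mix_arr, check=False)
        for w_x, p_y in branches:
            if w_x <= 0:
                continue
            term = info.kl(p_y, mix)
            if math.isinf(term):
                return math.inf
            total += w_v * w_x * term
    return total


def post_cutting(model: CausalModel, cut: Iterable[tuple[str, str]]) -> Pmf:
    """The post-cutting distribution for a set of severed edges.

    Computed by explicit augmentation: for each cut edge (p, c), the child c
    is rewired to an independent "marginal copy" of p (a fresh parentless
    node carrying p's observational marginal), and the copies are then
    marginalized out.  Each cut edge gets its own copy, so two children cut
    from the same parent receive independent draws.
    """
    cut = {tuple(e) for e in cut}
    bad = cut - model.dag.edges
    if bad:
        raise ModelError(f"cut edges not in model: {sorted(bad)}")
    if not cut:
        return joint_pmf(model)
    original = sorted(model.variables)
    joint = joint_pmf(model)

    variables = dict(model.variables)
    cpds = dict(model.cpds)
    edges = set(model.dag.edges) - cut
    for parent, child in sorted(cut):
        copy_name = f"{parent}__cut__{child}"
        p_marg = marginal(joint, [parent])
        variables[copy_name] = Variable(copy_name, model.variables[parent].alphabet)
        cpds[copy_name] = Cpd(copy_name, (), {(): p_marg.array})
        old = cpds[child]
        new_parents = tuple(copy_name if q == parent else q for q in old.parents)
        cpds[child] = Cpd(child, new_parents, old.table)
        edges.add((copy_name, child))
    augmented = CausalModel(variables, Dag(variables, edges), cpds)
    return marginal(joint_pmf(augmented), original)


def causal_strength(model: CausalModel, cut: Iterable[tuple[str, str]]) -> float:
    """Janzing et al. causal strength of an edge set: D(p || p_cut)."""
    cut = list(cut)
    if not cut:
        raise ModelError("causal strength requires a non-empty edge set")
    p = joint_pmf(model)
    p_cut = post_cutting(model, cut)
    return info.kl(p.reorder(sorted(p.names)), p_cut.reorder(sorted(p_cut.names)))
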