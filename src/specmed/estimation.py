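"""Plug-in (maximum-likelihood) estimation of the specific measures from
categorical observational samples.

Every distribution entering a measure is replaced by its empirical
frequency estimate; the measure's formula is then evaluated verbatim.  Pure
ML (pseudocount 0) is the default; an optional pseudocount is available
because the mixtures of the natural direct/indirect estimators touch every
(x', z') cell and sparse cells are inevitable on small data.  Zero-count
cells that carry positive mixture weight raise :class:`InestimableError`
rather than being silently smoothed.

Estimation of an interventional quantity from observational frequencies is
gated by a graphical identifiability check (d-separation in the graph with
the cause's outgoing edges removed); ``assume_identifiable=True`` overrides
the gate explicitly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import information as info
from .discrete_model import (
    CausalModel,
    Cpd,
    Dag,
    ModelError,
    Variable,
    cut_outgoing,
    d_separated,
    joint_pmf,
)
from .effects import EffectValue, MediationSpec

WEIGHT_COLUMN = "weight"


class InestimableError(ValueError):
    """A required empirical cell is empty (and no pseudocount was given)."""


class IdentifiabilityError(ValueError):
    """Observational estimation requested without graphical identifiability."""


class SampleTable:
    """Categorical observational records with an optional weight column.

    Integer-coded columns are cached so resampling-heavy callers (bootstrap,
    permutation) can recount cells cheaply.  An optional ``weight`` column
    supports the exact-enumeration pathway, where rows are a model's full
    support weighted by exact probabilities.
    """

    def __init__(self, df: pd.DataFrame, _codes=None, _cats=None):
        if len(df) < 1:
            raise ModelError("sample table must have at least one row")
        self.df = df.reset_index(drop=True)
        self.columns = tuple(c for c in self.df.columns if c != WEIGHT_COLUMN)
        if WEIGHT_COLUMN in self.df.columns:
            w = np.asarray(self.df[WEIGHT_COLUMN], dtype=float)
            if np.any(w < 0):
                raise ModelError("weights must be non-negative")
            self.weights = w
        else:
            self.weights = np.ones(len(self.df))
        self._codes = dict(_codes or {})
        self._cats = dict(_cats or {})

    @property
    def n(self) -> int:
        return len(self.df)

    def categories(self, col: str) -> np.ndarray:
        self._ensure(col)
        return self._cats[col]

    def codes(self, col: str) -> np.ndarray:
        self._ensure(col)
        return self._codes[col]

    def _ensure(self, col: str):
        if col in self._codes:
            return
        if col not in self.columns:
            raise ModelError(f"unknown column {col!r}")
        cats, codes = np.unique(np.asarray(self.df[col]), return_inverse=True)
        self._cats[col] = cats
        self._codes[col] = codes

    def code_of(self, col: str, label) -> int:
        cats = self.categories(col)
        hits = np.flatnonzero(cats == label)
        if hits.size == 0:
            raise InestimableError(
                f"value {label!r} of {col!r} does not occur in the sample"
            )
        return int(hits[0])

    def take(self, idx: np.ndarray) -> "SampleTable":
        """Row subset/resample; reuses cached category codings."""
        codes = {c: v[idx] for c, v in self._codes.items()}
        return SampleTable(self.df.iloc[idx], _codes=codes, _cats=self._cats)

    def permuted_within(self, col: str, strata_col: str,
                        rng: np.random.Generator) -> "SampleTable":
        """Permute ``col`` within strata of ``strata_col`` (unit weights only)."""
        if not np.all(self.weights == 1.0):
            raise ModelError("stratified permutation requires unit weights")
        values = np.asarray(self.df[col]).copy()
        strata = self.codes(strata_col)
        for s in np.unique(strata):
            rows = np.flatnonzero(strata == s)
            values[rows] = values[rows[rng.permutation(rows.size)]]
        df = self.df.copy()
        df[col] = values
        cats = {c: v for c, v in self._cats.items() if c != col}
        codes = {c: v for c, v in self._codes.items() if c != col}
        return SampleTable(df, _codes=codes, _cats=cats)

    # ---------------- I/O ----------------

    @classmethod
    def read_csv(cls, path: str | Path, sep: str | None = None) -> "SampleTable":
        path = Path(path)
        if sep is None:
            sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
        return cls(pd.read_csv(path, sep=sep))

    def to_csv(self, path: str | Path, sep: str | None = None):
        path = Path(path)
        if sep is None:
            sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
        self.df.to_csv(path, sep=sep, index=False)

    @classmethod
    def from_model(cls, model: CausalModel) -> "SampleTable":
        """Full-support enumeration weighted by exact probabilities.

        Plug-in estimators evaluated on this table reproduce the exact
        measures as an algebraic identity (weighted frequencies equal the
        model probabilities by construction).
        """
        pmf = joint_pmf(model)
        rows = [labels + (p,) for labels, p in pmf.support()]
        df = pd.DataFrame(rows, columns=list(pmf.names) + [WEIGHT_COLUMN])
        return cls(df)


# ---------------------------------------------------------------------------
# empirical model fitting


@dataclass(frozen=True)
class EmpiricalModel:
    """A CausalModel with frequency-estimated CPDs plus the parent
    configurations that were never observed (inestimable at pseudocount 0;
    their filler rows are uniform and must not be queried)."""

    model: CausalModel
    inestimable: frozenset  # of (child, parent_value_tuple)

    def require_estimable(self):
        if self.inestimable:
            raise InestimableError(
                f"unobserved parent configurations: {sorted(self.inestimable, key=str)}"
            )


def fit_empirical(samples: SampleTable, dag: Dag, pseudocount: float = 0.0,
                  alphabets: Mapping[str, Sequence] | None = None) -> EmpiricalModel:
    """Maximum-likelihood CPDs given a declared DAG.

    Each CPD row is (count + pseudocount) / (total + pseudocount * |alphabet|).
    Alphabets default to the observed unique values per column.
    """
    missing = set(dag.nodes) - set(samples.columns)
    if missing:
        raise ModelError(f"sample columns missing DAG nodes {sorted(missing)}")
    alphabets = dict(alphabets or {})
    variables = {}
    for node in dag.nodes:
        alpha = tuple(alphabets.get(node, samples.categories(node).tolist()))
        variables[node] = Variable(node, alpha)
    cpds = {}
    flagged = set()
    for node in sorted(dag.nodes):
        parents = dag.parents(node)
        child_alpha = variables[node].alphabet
        k = len(child_alpha)
        table = {}
        for key in _product([variables[p].alphabet for p in parents]):
            mask = np.ones(samples.n, dtype=bool)
            ok = True
            for p, val in zip(parents, key):
                cats = samples.categories(p)
                hit = np.flatnonzero(cats == val)
                if hit.size == 0:
                    ok = False
                    break
                mask &= samples.codes(p) == hit[0]
            counts = np.zeros(k)
            if ok:
                for j, val in enumerate(child_alpha):
                    cats = samples.categories(node)
                    hit = np.flatnonzero(cats == val)
                    if hit.size:
                        sel = mask & (samples.codes(node) == hit[0])
                        counts[j] = samples.weights[sel].sum()
            total = counts.sum()
            if total == 0 and pseudocount == 0:
                flagged.add((node, key))
                table[key] = np.full(k, 1.0 / k)  # filler; flagged
            else:
                table[key] = (counts + pseudocount) / (total + pseudocount * k)
        cpds[node] = Cpd(node, parents, table)
    model = CausalModel(variables, dag, cpds)
    return EmpiricalModel(model, frozenset(flagged))


def _product(alphabets: Sequence[Sequence]):
    import itertools
    return itertools.product(*alphabets)


# ---------------------------------------------------------------------------
# count-based conditional distributions


def _conditional(samples: SampleTable, target: str, given: Mapping,
                 pseudocount: float) -> np.ndarray:
    """p-hat(target | given) over the table-wide alphabet of ``target``."""
    k = len(samples.categories(target))
    mask = np.ones(samples.n, dtype=bool)
    for col, val in given.items():
        mask &= samples.codes(col) == samples.code_of(col, val)
    counts = np.bincount(samples.codes(target)[mask],
                         weights=samples.weights[mask], minlength=k)
    total = counts.sum()
    if total == 0 and pseudocount == 0:
        raise InestimableError(f"empty cell for context {dict(given)!r}")
    return (counts + pseudocount) / (total + pseudocount * k)


def _kl_vec(p: np.ndarray, q: np.ndarray) -> float:
    mask = p > 0
    if np.any(q[mask] == 0):
        return math.inf
    value = float((p[mask] * info._log(p[mask] / q[mask])).sum())
    return 0.0 if -1e-12 < value < 0 else value


def _entropy_vec(p: np.ndarray) -> float:
    nz = p[p > 0]
    return float(-(nz * info._log(nz)).sum())


# ---------------------------------------------------------------------------
# identifiability gate


def _gate(dag: Dag, cause: str, effect: str, given: frozenset | set = frozenset(),
          assume_identifiable: bool = False, also_mediator: str | None = None):
    if assume_identifiable:
        return
    g_cut = cut_outgoing(dag, cause)
    conds = [(effect, given)]
    if also_mediator is not None:
        conds.append((also_mediator, given))
    for other, ctx in conds:
        if not d_separated(g_cut, {cause}, {other}, set(ctx)):
            raise IdentifiabilityError(
                f"{cause} is not d-separated from {other} given {sorted(ctx)} "
                f"after removing {cause}'s outgoing edges; observational "
                "plug-in estimation is not licensed "
                "(pass assume_identifiable=True to override)"
            )


# ---------------------------------------------------------------------------
# estimators


def estimate_ste(samples: SampleTable, dag: Dag, x_var: str, y_var: str, x,
                 pseudocount: float = 0.0,
                 assume_identifiable: bool = False) -> EffectValue:
    """Plug-in STE: D(p-hat(Y|x) || p-hat(Y))."""
    _gate(dag, x_var, y_var, assume_identifiable=assume_identifiable)
    p_cond = _conditional(samples, y_var, {x_var: x}, pseudocount)
    p_marg = _conditional(samples, y_var, {}, pseudocount)
    return EffectValue("ste", x_var, x, _kl_vec(p_cond, p_marg))


def _natural_weights(samples: SampleTable, x_var: str,
                     pseudocount: float) -> np.ndarray:
    return _conditional(samples, x_var, {}, pseudocount)


def estimate_snde(samples: SampleTable, dag: Dag, spec: MediationSpec, x,
                  pseudocount: float = 0.0,
                  assume_identifiable: bool = False) -> EffectValue:
    """Plug-in SNDE: D(p-hat(Y|x) || sum_{x',z'} p-hat(x') p-hat(z'|x) p-hat(Y|x',z'))."""
    if not isinstance(spec.z, str):
        raise ModelError("plug-in SNDE/SNIE expect a single mediator column")
    _gate(dag, spec.x, spec.y, assume_identifiable=assume_identifiable,
          also_mediator=spec.z)
    return _nested_plugin(samples, spec, x, pseudocount, direct=True)


def estimate_snie(samples: SampleTable, dag: Dag, spec: MediationSpec, x,
                  pseudocount: float = 0.0,
                  assume_identifiable: bool = False) -> EffectValue:
    """Plug-in SNIE: D(p-hat(Y|x) || sum_{x',z'} p-hat(x') p-hat(z'|x') p-hat(Y|x,z'))."""
    if not isinstance(spec.z, str):
        raise ModelError("plug-in SNDE/SNIE expect a single mediator column")
    _gate(dag, spec.x, spec.y, assume_identifiable=assume_identifiable,
          also_mediator=spec.z)
    return _nested_plugin(samples, spec, x, pseudocount, direct=False)


def _nested_plugin(samples: SampleTable, spec: MediationSpec, x,
                   pseudocount: float, direct: bool) -> EffectValue:
    x_cats = samples.categories(spec.x)
    z_cats = samples.categories(spec.z)
    p_first = _conditional(samples, spec.y, {spec.x: x}, pseudocount)
    p_x = _natural_weights(samples, spec.x, pseudocount)
    mix = np.zeros_like(p_first)
    for i, x_prime in enumerate(x_cats):
        if p_x[i] <= 0:
            continue
        z_context = x if direct else x_prime
        y_context = x_prime if direct else x
        p_z = _conditional(samples, spec.z, {spec.x: z_context}, pseudocount)
        for j, z_prime in enumerate(z_cats):
            w = p_x[i] * p_z[j]
            if w <= 0:
                continue
            p_y = _conditional(samples, spec.y,
                               {spec.x: y_context, spec.z: z_prime}, pseudocount)
            mix += w * p_y
    name = "snde" if direct else "snie"
    return EffectValue(name, spec.x, x, _kl_vec(p_first, mix))


def estimate_conditional_ste(samples: SampleTable, dag: Dag, cause: str,
                             effect: str, condition_var: str, s, e,
                             pseudocount: float = 0.0,
                             assume_identifiable: bool = False) -> EffectValue:
    """Plug-in conditional STE: D(p-hat(Y|e,s) || p-hat(Y|e)) for cause value
    ``s`` in covariate context ``condition_var = e``."""
    _gate(dag, cause, effect, given={condition_var},
          assume_identifiable=assume_identifiable)
    p_cond = _conditional(samples, effect, {cause: s, condition_var: e},
                          pseudocount)
    p_base = _conditional(samples, effect, {condition_var: e}, pseudocount)
    return EffectValue("conditional_ste", cause, s, _kl_vec(p_cond, p_base),
                       condition={condition_var: e})


def estimate_normalized(samples: SampleTable, dag: Dag, measure: str,
                        x_var: str, y_var: str, x,
                        z_var: str | None = None,
                        condition_var: str | None = None,
                        condition_value=None,
                        pseudocount: float = 0.0,
                        assume_identifiable: bool = False) -> float:
    """Plug-in normalized measure: value / (value + H-hat(Y | x-stratum
    [and condition]))."""
    if measure == "ste":
        ev = estimate_ste(samples, dag, x_var, y_var, x, pseudocount,
                          assume_identifiable)
        context = {x_var: x}
    elif measure in ("snde", "snie"):
        spec = MediationSpec(x=x_var, z=z_var, y=y_var)
        fn = estimate_snde if measure == "snde" else estimate_snie
        ev = fn(samples, dag, spec, x, pseudocount, assume_identifiable)
        context = {x_var: x}
    elif measure == "conditional_ste":
        ev = estimate_conditional_ste(samples, dag, x_var, y_var,
                                      condition_var, x, condition_value,
                                      pseudocount, assume_identifiable)
        context = {x_var: x, condition_var: condition_value}
    else:
        raise ModelError(f"unknown measure {measure!r}")
    value = ev.value
    if value == 0.0:
        return 0.0
    if math.isinf(value):
        return 1.0
    h = _entropy_vec(_conditional(samples, y_var, context, pseudocount))
    if h == 0.0:
        return 1.0
    return value / (value + h)
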