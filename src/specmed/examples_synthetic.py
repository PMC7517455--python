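"""Worked-example models with closed-form effect values, and a seeded
synthetic mediation-data generator.

The three analytic constructions — the binary chain reaction, the
caused-uncertainty collider, and the shared-responsibility inhibitor model —
come with closed-form specific-effect formulas that serve as independent
oracles for the generic effect engine.

The mediation generator emulates the structure of an ENSO-style case study:
a three-state climate driver E, a persistence mediator S (past anomaly
category), and an outcome T (current anomaly category), wired E -> S -> T
with a direct E -> T link.  It emits categorical records directly, or, in
continuous mode, latent anomaly series quantized at empirical terciles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .discrete_model import CausalModel, Cpd, Dag, ModelError, Variable
from .information import bernoulli_kl
from .estimation import SampleTable


def _bern(p1: float) -> np.ndarray:
    """Probability vector over alphabet (0, 1)."""
    return np.array([1.0 - p1, p1])


def example1_model() -> CausalModel:
    """Two-node model X -> Y with X~Bern(1/7), Y|X=0~Bern(1/10), Y|X=1~Bern(8/10).

    The marginal of Y is Bern(2/10), so H(Y) = H(Y|X=1) even though the
    distribution of Y depends strongly on X — the construction separating
    the two candidate specific informations.
    """
    variables = {"X": Variable("X", (0, 1)), "Y": Variable("Y", (0, 1))}
    dag = Dag(variables, [("X", "Y")])
    cpds = {
        "X": Cpd("X", (), {(): _bern(1 / 7)}),
        "Y": Cpd("Y", ("X",), {(0,): _bern(1 / 10), (1,): _bern(8 / 10)}),
    }
    return CausalModel(variables, dag, cpds)


# ---------------------------------------------------------------------------
# chain reaction


@dataclass(frozen=True)
class ChainParams:
    """Binary message chain X -> Z -> Y with per-hop flip probability epsilon."""

    epsilon: float = 0.1

    def __post_init__(self):
        if not 0.0 <= self.epsilon <= 0.5:
            raise ModelError("epsilon must lie in [0, 0.5]")


def chain_model(params: ChainParams) -> CausalModel:
    """X~Bern(0.5); Z copies X, Y copies Z, each flipped with prob epsilon."""
    e = params.epsilon
    variables = {n: Variable(n, (0, 1)) for n in ("X", "Z", "Y")}
    dag = Dag(variables, [("X", "Z"), ("Z", "Y")])
    flip = {(0,): _bern(e), (1,): _bern(1.0 - e)}
    cpds = {
        "X": Cpd("X", (), {(): _bern(0.5)}),
        "Z": Cpd("Z", ("X",), flip),
        "Y": Cpd("Y", ("Z",), flip),
    }
    return CausalModel(variables, dag, cpds)


@dataclass(frozen=True)
class ChainClosedForms:
    ste: float                  # STE(x -> Y), same for both x
    conditional_ste: float      # STE(z -> Y | x) for the given (x, z)


def chain_closed_forms(params: ChainParams, x: int, z: int) -> ChainClosedForms:
    """Closed forms: STE(x->Y) = D(2e(1-e) || 0.5); STE(z->Y|x) is
    D(e || 2e(1-e)) when x == z and D(e || e^2 + (1-e)^2) otherwise."""
    e = params.epsilon
    total = bernoulli_kl(2 * e * (1 - e), 0.5)
    if x == z:
        cond = bernoulli_kl(e, 2 * e * (1 - e))
    else:
        cond = bernoulli_kl(e, e ** 2 + (1 - e) ** 2)
    return ChainClosedForms(ste=total, conditional_ste=cond)


# ---------------------------------------------------------------------------
# caused uncertainty


def caused_uncertainty_model() -> CausalModel:
    """Collider X -> Y <- Z with X~Bern(0.5), Z~Bern(0.1) and

    Y | X,Z ~ Bern(0.5) if Z=1, Bern(0.1) if (X,Z)=(0,0), Bern(0.9) if (1,0).

    When z=1 the value of X is irrelevant, yet z=1 shifts the distribution
    of Y — Z causes uncertainty in Y without predicting its value.
    """
    variables = {n: Variable(n, (0, 1)) for n in ("X", "Z", "Y")}
    dag = Dag(variables, [("X", "Y"), ("Z", "Y")])
    cpds = {
        "X": Cpd("X", (), {(): _bern(0.5)}),
        "Z": Cpd("Z", (), {(): _bern(0.1)}),
        "Y": Cpd("Y", ("X", "Z"), {
            (0, 0): _bern(0.1),
            (1, 0): _bern(0.9),
            (0, 1): _bern(0.5),
            (1, 1): _bern(0.5),
        }),
    }
    return CausalModel(variables, dag, cpds)


# ---------------------------------------------------------------------------
# shared responsibility


@dataclass(frozen=True)
class SharedResponsibilityParams:
    """n iid Bern(epsilon) inhibitors X_i jointly influencing Y."""

    n: int = 4
    epsilon: float = 0.1

    def __post_init__(self):
        if self.n < 1:
            raise ModelError("n must be >= 1")
        if self.n > 12:
            raise ModelError("n > 12 exceeds the intended enumeration scale")
        if not 0.0 < self.epsilon < 1.0:
            raise ModelError("epsilon must lie in (0, 1)")


def shared_responsibility_model(params: SharedResponsibilityParams) -> CausalModel:
    """X_i ~ iid Bern(epsilon), i=1..n; Y | X ~ Bern(2^-k) with k = sum x_i."""
    names = [f"X{i}" for i in range(1, params.n + 1)]
    variables = {n: Variable(n, (0, 1)) for n in names}
    variables["Y"] = Variable("Y", (0, 1))
    dag = Dag(variables, [(n, "Y") for n in names])
    cpds = {n: Cpd(n, (), {(): _bern(params.epsilon)}) for n in names}
    table = {}
    parent_order = tuple(sorted(names))
    for bits in np.ndindex(*(2,) * params.n):
        k = int(sum(bits))
        table[tuple(bits)] = _bern(2.0 ** (-k))
    cpds["Y"] = Cpd("Y", parent_order, table)
    return CausalModel(variables, dag, cpds)


def shared_responsibility_closed_form(params: SharedResponsibilityParams,
                                      x1: int, k1: int) -> float:
    """Closed form for STE(x1 -> Y | k1), the conditional STE of one
    inhibitor given that k1 of the others are active:

    D(2^-k1 || e/2^(k1+1) + (1-e)/2^k1)   when x1 = 0,
    D(2^-(k1+1) || e/2^(k1+1) + (1-e)/2^k1) when x1 = 1.
    """
    if not 0 <= k1 <= params.n - 1:
        raise ModelError("k1 must lie in [0, n-1]")
    e = params.epsilon
    mix = e / 2.0 ** (k1 + 1) + (1.0 - e) / 2.0 ** k1
    forced = 2.0 ** (-(k1 + x1))
    return bernoulli_kl(forced, mix)


# ---------------------------------------------------------------------------
# synthetic mediation generator


def _default_p_s_given_e() -> dict:
    # cold phase favors cold anomalies, warm phase warm ones
    return {
        (-1,): np.array([0.45, 0.35, 0.20]),
        (0,): np.array([0.30, 0.40, 0.30]),
        (1,): np.array([0.20, 0.35, 0.45]),
    }


def _default_p_t_given_es() -> dict:
    # persistence kernel (weight on repeating the past category) blended
    # with the direct driver effect; direct link stronger than indirect
    direct = _default_p_s_given_e()
    pers = {
        -1: np.array([0.60, 0.25, 0.15]),
        0: np.array([0.20, 0.60, 0.20]),
        1: np.array([0.15, 0.25, 0.60]),
    }
    table = {}
    for e in (-1, 0, 1):
        for s in (-1, 0, 1):
            table[(e, s)] = 0.55 * pers[s] + 0.45 * direct[(e,)]
    return table


@dataclass(frozen=True)
class MediationGenParams:
    """Generator for categorical (e, s, t) mediation records.

    Defaults emulate a three-phase driver with a rarer-than-neutral active
    phase, a persistent mediator, and a direct link stronger than the
    indirect one.  In continuous mode, latent anomalies are drawn per
    category and re-quantized at the empirical terciles of each raw series
    (ties assigned to the lower bin).
    """

    alphabet: tuple = (-1, 0, 1)
    p_e: np.ndarray = field(default_factory=lambda: np.array([0.25, 0.5, 0.25]))
    p_s_given_e: Mapping = field(default_factory=_default_p_s_given_e)
    p_t_given_es: Mapping = field(default_factory=_default_p_t_given_es)
    n: int = 10_000
    seed: int = 0
    continuous: bool = False
    anomaly_means: Mapping[int, float] = field(
        default_factory=lambda: {-1: -1.5, 0: 0.0, 1: 1.8})
    persistence_coef: float = 0.6
    noise_sd: float = 1.0


def mediation_model(params: MediationGenParams) -> CausalModel:
    """The exact categorical E -> S -> T (+ E -> T) model the generator samples."""
    a = params.alphabet
    variables = {n: Variable(n, a) for n in ("E", "S", "T")}
    dag = Dag(variables, [("E", "S"), ("E", "T"), ("S", "T")])
    cpds = {
        "E": Cpd("E", (), {(): np.asarray(params.p_e, dtype=float)}),
        "S": Cpd("S", ("E",), {tuple(k) if isinstance(k, tuple) else (k,): v
                               for k, v in params.p_s_given_e.items()}),
        "T": Cpd("T", ("E", "S"), dict(params.p_t_given_es)),
    }
    return CausalModel(variables, dag, cpds)


def sample_model(model: CausalModel, n: int, seed: int) -> SampleTable:
    """n iid ancestral-sampling draws from any CausalModel, as a SampleTable."""
    rng = np.random.default_rng(seed)
    order = model.dag.topological_order()
    idx_draws: dict[str, np.ndarray] = {}
    for name in order:
        var = model.variables[name]
        cpd = model.cpds[name]
        k = len(var.alphabet)
        if not cpd.parents:
            idx = rng.choice(k, size=n, p=cpd.table[()])
        else:
            # group rows by parent configuration and draw each block at once
            shape = tuple(len(model.variables[p].alphabet) for p in cpd.parents)
            codes = np.ravel_multi_index(
                tuple(idx_draws[p] for p in cpd.parents), shape)
            idx = np.empty(n, dtype=int)
            for code in np.unique(codes):
                key = tuple(
                    model.variables[p].alphabet[i]
                    for p, i in zip(cpd.parents,
                                    np.unravel_index(code, shape)))
                rows = np.flatnonzero(codes == code)
                idx[rows] = rng.choice(k, size=rows.size, p=cpd.table[key])
        idx_draws[name] = idx
    df = pd.DataFrame({
        name: [model.variables[name].alphabet[i] for i in idx_draws[name]]
        for name in order
    })
    return SampleTable(df)


def _tercile_bins(series: np.ndarray) -> np.ndarray:
    """Quantize at the empirical terciles of the raw series; ties to the
    lower bin.  Returns categories in {-1, 0, 1}."""
    lo, hi = np.quantile(series, [1 / 3, 2 / 3])
    return np.where(series <= lo, -1, np.where(series <= hi, 0, 1))


def generate_mediation_samples(params: MediationGenParams) -> SampleTable:
    """Seeded iid (e, s, t) records from the mediation model.

    Categorical mode samples the CPDs directly.  Continuous mode emits
    latent anomaly values (driver-phase mean + persistence + Gaussian
    noise) and quantizes each raw series at its empirical terciles before
    any other processing, so each bin holds one third of records up to
    rounding.
    """
    if not params.continuous:
        return sample_model(mediation_model(params), params.n, params.seed)
    rng = np.random.default_rng(params.seed)
    a = params.alphabet
    e_idx = rng.choice(len(a), size=params.n, p=np.asarray(params.p_e, float))
    e = np.asarray(a, dtype=object)[e_idx].astype(int)
    means = np.array([params.anomaly_means[v] for v in e])
    s_raw = means + rng.normal(0.0, params.noise_sd, params.n)
    t_raw = (means + params.persistence_coef * (s_raw - means)
             + rng.normal(0.0, params.noise_sd, params.n))
    df = pd.DataFrame({
        "E": e,
        "S": _tercile_bins(s_raw),
        "T": _tercile_bins(t_raw),
    })
    return SampleTable(df)
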