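"""Information-theoretic primitives on exact pmfs.

Entropy, KL divergence, conditional entropy (averaged and value-specific),
and (conditional) mutual information, all evaluated exactly on :class:`Pmf`
objects.  Quantities are reported in bits by default; the log base is a
single module-level configuration (:func:`set_units`) rather than a per-call
argument.

Conventions: ``0 log 0 := 0`` and ``0 log(0/0) := 0``.  KL divergence is
``+inf`` whenever the first argument puts mass where the second does not;
infinity is a first-class value propagated through downstream normalization
and reporting.
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

import numpy as np

from .discrete_model import Pmf, ModelError, condition, marginal

_LOG_BASE = 2.0  # bits


def set_units(units: str):
    """Configure the global log base: ``"bits"`` (default) or ``"nats"``."""
    global _LOG_BASE
    if units == "bits":
        _LOG_BASE = 2.0
    elif units == "nats":
        _LOG_BASE = math.e
    else:
        raise ValueError(f"unknown units {units!r}; expected 'bits' or 'nats'")


def get_units() -> str:
    return "bits" if _LOG_BASE == 2.0 else "nats"


def _log(x: np.ndarray) -> np.ndarray:
    return np.log(x) / math.log(_LOG_BASE)


def entropy(p: Pmf) -> float:
    """Shannon entropy -sum p log p, with 0 log 0 = 0."""
    a = np.ravel(p.array)
    nz = a[a > 0]
    return float(-(nz * _log(nz)).sum())


def kl(p: Pmf, q: Pmf) -> float:
    """KL divergence D(p || q); +inf iff p puts mass where q has none."""
    if not p.same_support(q):
        raise ModelError("KL divergence requires identical variables and alphabets")
    q = q.reorder(p.names)
    pa, qa = np.ravel(p.array), np.ravel(q.array)
    mask = pa > 0
    if np.any(qa[mask] == 0):
        return math.inf
    value = float((pa[mask] * _log(pa[mask] / qa[mask])).sum())
    # p == q up to float rounding can leave a ~1e-16 negative residue
    return 0.0 if -1e-12 < value < 0 else value


def bernoulli_kl(alpha: float, beta: float) -> float:
    """D(Bern(alpha) || Bern(beta)): the scalar shorthand D(a || b)."""
    total = 0.0
    for p_, q_ in ((alpha, beta), (1.0 - alpha, 1.0 - beta)):
        if p_ > 0:
            if q_ == 0:
                return math.inf
            total += p_ * math.log(p_ / q_) / math.log(_LOG_BASE)
    return total


def conditional_entropy(joint: Pmf, target: str | Sequence[str],
                        given: Sequence[str]) -> float:
    """H(target | given): expected entropy of the conditional distribution."""
    targets = [target] if isinstance(target, str) else list(target)
    given = list(given)
    sub = marginal(joint, targets + [g for g in given if g not in targets])
    if not given:
        return entropy(sub)
    g_marg = marginal(sub, given)
    total = 0.0
    for labels, pg in g_marg.support():
        if pg <= 0:
            continue
        cond = condition(sub, dict(zip(given, labels)))
        total += pg * entropy(marginal(cond, targets))
    return total


def specific_conditional_entropy(joint: Pmf, target: str | Sequence[str],
                                 evidence: Mapping) -> float:
    """H(target | evidence values): entropy at one specific conditioning value.

    Not to be confused with the averaged conditional entropy.
    """
    targets = [target] if isinstance(target, str) else list(target)
    sub = marginal(joint, targets + [e for e in evidence if e not in targets])
    return entropy(marginal(condition(sub, evidence), targets))


def mutual_information(joint: Pmf, a: str | Sequence[str],
                       b: str | Sequence[str],
                       given: Sequence[str] | None = None) -> float:
    """I(a; b) or conditional I(a; b | given), via entropy differences."""
    a_list = [a] if isinstance(a, str) else list(a)
    given = list(given or [])
    h1 = conditional_entropy(joint, a_list, given)
    b_list = [b] if isinstance(b, str) else list(b)
    h2 = conditional_entropy(joint, a_list, b_list + given)
    value = h1 - h2
    # exact arithmetic can leave a tiny negative residue
    return 0.0 if -1e-12 < value < 0 else value
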