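"""Specific causal effect measures on discrete causal models.

All measures compare interventional distributions of the effect variable by
KL divergence, evaluated exactly on a :class:`CausalModel`:

* STE — specific total effect: distribution of Y under do(X=x) versus the
  mixture of Y-distributions under naturally occurring X.
* SCDE — specific controlled direct effect: the same comparison with the
  mediator clamped to a fixed z by intervention.
* SNDE / SNIE — specific natural direct / indirect effects: either the value
  of X fed to Y's mechanism, or the mediator's distribution, is swapped
  between "forced x" and "natural X".
* Conditional variants condition every distribution on a covariate context
  u~; normalized variants map bits to [0, 1].

Every measure is computed from exact interventional queries — never from
observational shortcuts — so the values are correct in confounded models.
Observational identification belongs to the estimation module.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from . import information as info
from .discrete_model import (
    CausalModel,
    ModelError,
    Pmf,
    UnsupportedEvidenceError,
    interventional_query,
    joint_pmf,
    marginal,
)


@dataclass(frozen=True)
class MediationSpec:
    """Role declaration for the mediation DAG: cause x, mediator(s) z, effect y,
    and (possibly empty) covariates u."""

    x: str
    z: str | tuple[str, ...] | None
    y: str
    u: tuple[str, ...] = ()

    def __post_init__(self):
        z = self.z
        if z is not None and not isinstance(z, str):
            object.__setattr__(self, "z", tuple(z))
        object.__setattr__(self, "u", tuple(self.u))
        roles = [self.x, self.y, *self.mediators, *self.u]
        if len(set(roles)) != len(roles):
            raise ModelError("mediation roles must be disjoint")

    @property
    def mediators(self) -> tuple[str, ...]:
        if self.z is None:
            return ()
        return (self.z,) if isinstance(self.z, str) else self.z


@dataclass(frozen=True)
class EffectValue:
    """One computed measure: value in the configured units (may be +inf),
    plus the context it was computed in."""

    measure: str
    cause: str
    cause_value: object
    value: float
    mediator_value: object = None
    condition: Mapping | None = None
    normalized: float | None = None

    def to_dict(self) -> dict:
        rec = {
            "measure": self.measure,
            "cause": self.cause,
            "cause_value": self.cause_value,
            "bits": "inf" if math.isinf(self.value) else self.value,
        }
        if self.mediator_value is not None:
            rec["mediator_value"] = self.mediator_value
        if self.condition:
            rec["condition"] = dict(self.condition)
        if self.normalized is not None:
            rec["normalized"] = self.normalized
        return rec


def _mixture(terms: list[tuple[float, Pmf]]) -> Pmf:
    """Probability-weighted mixture of pmfs over the same support."""
    total = sum(w for w, _ in terms)
    if not terms or abs(total - 1.0) > 1e-9:
        raise ModelError(f"mixture weights sum to {total}, expected 1")
    ref = terms[0][1]
    arr = np.zeros_like(ref.array)
    for w, pmf in terms:
        arr += w * pmf.reorder(ref.names).array
    return Pmf(ref.variables, arr, check=False)


def _observational(model: CausalModel, target: str | Sequence[str],
                   given: Mapping | None = None) -> Pmf:
    return interventional_query(model, target, do=None, given=given)


# ---------------------------------------------------------------------------
# specific mutual information (observational; two-node setting)


def smi_i1(model: CausalModel, spec: MediationSpec, x) -> EffectValue:
    """Specific mutual information I1(x;Y) = D(p(Y|X=x) || p(Y)).

    Observational: requires p(x) > 0, unlike the interventional measures.
    """
    px = _observational(model, spec.x)
    if px.prob({spec.x: x}) <= 0:
        raise UnsupportedEvidenceError(f"p({spec.x}={x!r}) = 0; SMI undefined")
    p_cond = _observational(model, spec.y, given={spec.x: x})
    p_marg = _observational(model, spec.y)
    return EffectValue("smi_i1", spec.x, x, info.kl(p_cond, p_marg))


def smi_i2(model: CausalModel, spec: MediationSpec, x) -> EffectValue:
    """Second candidate I2(x;Y) = H(Y|X=x) - H(Y); may be negative.

    Implemented exactly as printed; note E[I2] = -I(X;Y) under this sign.
    """
    joint = joint_pmf(model)
    px = marginal(joint, [spec.x])
    if px.prob({spec.x: x}) <= 0:
        raise UnsupportedEvidenceError(f"p({spec.x}={x!r}) = 0; SMI undefined")
    h_spec = info.specific_conditional_entropy(joint, spec.y, {spec.x: x})
    h_marg = info.entropy(marginal(joint, [spec.y]))
    return EffectValue("smi_i2", spec.x, x, h_spec - h_marg)


# ---------------------------------------------------------------------------
# unconditional specific effects


def ste(model: CausalModel, spec: MediationSpec, x) -> EffectValue:
    """Specific total effect D(p(Y|x^) || sum_x' p(x') p(Y|x^'))."""
    p_do = interventional_query(model, spec.y, do={spec.x: x})
    mix = _natural_mixture(model, spec, extra_do={}, given={})
    return EffectValue("ste", spec.x, x, info.kl(p_do, mix))


def scde(model: CausalModel, spec: MediationSpec, x, z) -> EffectValue:
    """Specific controlled direct effect with the mediator clamped at z."""
    z_assign = _mediator_assignment(spec, z)
    p_do = interventional_query(model, spec.y, do={spec.x: x, **z_assign})
    mix = _natural_mixture(model, spec, extra_do=z_assign, given={})
    return EffectValue("scde", spec.x, x, info.kl(p_do, mix), mediator_value=z)


def snde(model: CausalModel, spec: MediationSpec, x) -> EffectValue:
    """Specific natural direct effect: natural x' fed to Y's mechanism while
    the mediator follows its distribution under do(X=x)."""
    p_do = interventional_query(model, spec.y, do={spec.x: x})
    mix = _nested_mixture(model, spec, x, mediator_under=x, given={})
    return EffectValue("snde", spec.x, x, info.kl(p_do, mix))


def snie(model: CausalModel, spec: MediationSpec, x) -> EffectValue:
    """Specific natural indirect effect: forced x fed to Y's mechanism while
    the mediator follows its distribution under naturally occurring X."""
    p_do = interventional_query(model, spec.y, do={spec.x: x})
    mix = _nested_mixture(model, spec, x, mediator_under=None, given={})
    return EffectValue("snie", spec.x, x, info.kl(p_do, mix))


# ---------------------------------------------------------------------------
# conditional variants (covariate context u~)


def conditional_ste(model: CausalModel, spec: MediationSpec, x,
                    u_tilde: Mapping) -> EffectValue:
    """STE conditioned on a covariate context: every distribution, including
    the natural-X weights, is conditioned on u~."""
    u_tilde = dict(u_tilde)
    if not u_tilde:
        return ste(model, spec, x)
    p_do = interventional_query(model, spec.y, do={spec.x: x}, given=u_tilde)
    mix = _natural_mixture(model, spec, extra_do={}, given=u_tilde)
    val = info.kl(p_do, mix)
    return EffectValue("conditional_ste", spec.x, x, val, condition=u_tilde)


def conditional_scde(model: CausalModel, spec: MediationSpec, x, z,
                     u_tilde: Mapping) -> EffectValue:
    u_tilde = dict(u_tilde)
    if not u_tilde:
        return scde(model, spec, x, z)
    z_assign = _mediator_assignment(spec, z)
    p_do = interventional_query(model, spec.y, do={spec.x: x, **z_assign},
                                given=u_tilde)
    mix = _natural_mixture(model, spec, extra_do=z_assign, given=u_tilde)
    return EffectValue("conditional_scde", spec.x, x, info.kl(p_do, mix),
                       mediator_value=z, condition=u_tilde)


def conditional_snde(model: CausalModel, spec: MediationSpec, x,
                     u_tilde: Mapping) -> EffectValue:
    u_tilde = dict(u_tilde)
    if not u_tilde:
        return snde(model, spec, x)
    p_do = interventional_query(model, spec.y, do={spec.x: x}, given=u_tilde)
    mix = _nested_mixture(model, spec, x, mediator_under=x, given=u_tilde)
    return EffectValue("conditional_snde", spec.x, x, info.kl(p_do, mix),
                       condition=u_tilde)


def conditional_snie(model: CausalModel, spec: MediationSpec, x,
                     u_tilde: Mapping) -> EffectValue:
    u_tilde = dict(u_tilde)
    if not u_tilde:
        return snie(model, spec, x)
    p_do = interventional_query(model, spec.y, do={spec.x: x}, given=u_tilde)
    mix = _nested_mixture(model, spec, x, mediator_under=None, given=u_tilde)
    return EffectValue("conditional_snie", spec.x, x, info.kl(p_do, mix),
                       condition=u_tilde)


def normalized(model: CausalModel, spec: MediationSpec,
               measure: EffectValue, x, u_tilde: Mapping | None = None) -> float:
    """Normalize a measure into [0, 1] as value / (value + H(Y | do, u~)).

    The denominator entropy is that of Y in the context the measure's first
    argument was computed in: do(X=x) (plus do(Z=z) for the controlled
    direct effect) conditioned on u~.  A zero measure normalizes to 0; a
    positive measure with a deterministic intervened Y (entropy 0), or an
    infinite measure, normalizes to 1.
    """
    u_tilde = dict(u_tilde or {})
    if measure.value == 0.0:
        return 0.0
    if math.isinf(measure.value):
        return 1.0
    do = {spec.x: x}
    if measure.measure in ("scde", "conditional_scde"):
        do.update(_mediator_assignment(spec, measure.mediator_value))
    p_do = interventional_query(model, spec.y, do=do, given=u_tilde)
    h = info.entropy(p_do)
    if h == 0.0:
        return 1.0
    return measure.value / (measure.value + h)


def with_normalized(model: CausalModel, spec: MediationSpec,
                    measure: EffectValue, x,
                    u_tilde: Mapping | None = None) -> EffectValue:
    """Attach the normalized value to an EffectValue record."""
    nrm = normalized(model, spec, measure, x, u_tilde)
    return EffectValue(measure.measure, measure.cause, measure.cause_value,
                       measure.value, measure.mediator_value,
                       measure.condition, nrm)


# ---------------------------------------------------------------------------
# mixture plumbing


def _mediator_assignment(spec: MediationSpec, z) -> dict:
    meds = spec.mediators
    if not meds:
        raise ModelError("spec declares no mediator")
    if isinstance(spec.z, str):
        return {spec.z: z}
    if not isinstance(z, (tuple, list)) or len(z) != len(meds):
        raise ModelError(f"mediator value {z!r} does not match mediators {meds}")
    return dict(zip(meds, z))


def _natural_mixture(model: CausalModel, spec: MediationSpec,
                     extra_do: Mapping, given: Mapping) -> Pmf:
    """sum_x' p(x' | u~) p(Y | x^', [z^], u~); zero-weight contexts skipped."""
    p_x = _observational(model, spec.x, given=given or None)
    terms = []
    for (x_val,), w in p_x.support():
        if w <= 0:
            continue
        p_y = interventional_query(model, spec.y,
                                   do={spec.x: x_val, **extra_do},
                                   given=given or None)
        terms.append((w, p_y))
    return _mixture(terms)


def _nested_mixture(model: CausalModel, spec: MediationSpec, x,
                    mediator_under, given: Mapping) -> Pmf:
    """sum_{x',z'} p(x'|u~) p(z'|x^?,u~) p(Y|x^?,z',u~).

    ``mediator_under=x`` gives the natural-direct mixture (mediator drawn
    under do(X=x), Y's mechanism fed the natural x'); ``mediator_under=None``
    gives the natural-indirect mixture (mediator drawn under do(X=x'), Y's
    mechanism fed the forced x).
    """
    meds = spec.mediators
    if not meds:
        raise ModelError("SNDE/SNIE require a declared mediator")
    p_x = _observational(model, spec.x, given=given or None)
    terms = []
    for (x_prime,), w_x in p_x.support():
        if w_x <= 0:
            continue
        z_source = x if mediator_under is not None else x_prime
        y_source = x_prime if mediator_under is not None else x
        p_z = interventional_query(model, list(meds), do={spec.x: z_source},
                                   given=given or None)
        for z_labels, w_z in p_z.support():
            if w_z <= 0:
                continue
            p_y = interventional_query(
                model, spec.y, do={spec.x: y_source},
                given={**dict(zip(meds, z_labels)), **given},
            )
            terms.append((w_x * w_z, p_y))
    return _mixture(terms)
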