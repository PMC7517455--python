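"""Specific total/direct/indirect effect measures against closed forms and
independent brute-force enumeration oracles."""

import itertools
import math

import numpy as np
import pytest

import specmed as sm
from specmed.discrete_model import Cpd, Dag, UnsupportedEvidenceError, Variable
from conftest import random_mediation_model

XY = sm.MediationSpec(x="X", z=None, y="Y")
XZY = sm.MediationSpec(x="X", z="Z", y="Y")


# ---------------------------------------------------------------------------
# independent oracle: truncated-factorization enumeration with plain dicts


def brute_joint(model, do=None):
    """Joint distribution as a dict, overriding intervened CPDs in place."""
    do = do or {}
    names = sorted(model.variables)
    out = {}
    for assignment in itertools.product(
            *[model.variables[n].alphabet for n in names]):
        ctx = dict(zip(names, assignment))
        p = 1.0
        for n in names:
            if n in do:
                p *= 1.0 if ctx[n] == do[n] else 0.0
            else:
                cpd = model.cpds[n]
                key = tuple(ctx[q] for q in cpd.parents)
                p *= cpd.table[key][model.variables[n].index(ctx[n])]
        out[assignment] = p
    return names, out


def brute_dist(model, target, do=None, given=None):
    """p(target | do, given) over the target alphabet, by raw summation."""
    given = given or {}
    names, joint = brute_joint(model, do)
    alpha = model.variables[target].alphabet
    num = {y: 0.0 for y in alpha}
    den = 0.0
    for assignment, p in joint.items():
        ctx = dict(zip(names, assignment))
        if any(ctx[k] != v for k, v in given.items()):
            continue
        den += p
        num[ctx[target]] += p
    return np.array([num[y] / den for y in alpha])


def brute_kl(p, q):
    total = 0.0
    for a, b in zip(p, q):
        if a > 0:
            if b == 0:
                return math.inf
            total += a * math.log2(a / b)
    return total


def brute_snde(model, x):
    """Eq-by-term evaluation of the natural direct mixture."""
    p_first = brute_dist(model, "Y", do={"X": x})
    p_x = brute_dist(model, "X")
    p_z = brute_dist(model, "Z", do={"X": x})
    x_alpha = model.variables["X"].alphabet
    z_alpha = model.variables["Z"].alphabet
    mix = np.zeros_like(p_first)
    for i, xp in enumerate(x_alpha):
        for j, zp in enumerate(z_alpha):
            w = p_x[i] * p_z[j]
            if w > 0:
                mix += w * brute_dist(model, "Y", do={"X": xp}, given={"Z": zp})
    return brute_kl(p_first, mix)


def brute_snie(model, x):
    p_first = brute_dist(model, "Y", do={"X": x})
    p_x = brute_dist(model, "X")
    x_alpha = model.variables["X"].alphabet
    z_alpha = model.variables["Z"].alphabet
    mix = np.zeros_like(p_first)
    for i, xp in enumerate(x_alpha):
        p_z = brute_dist(model, "Z", do={"X": xp})
        for j, zp in enumerate(z_alpha):
            w = p_x[i] * p_z[j]
            if w > 0:
                mix += w * brute_dist(model, "Y", do={"X": x}, given={"Z": zp})
    return brute_kl(p_first, mix)


# ---------------------------------------------------------------------------


class TestSpecificMutualInformation:
    def test_example1_i1_is_specific_information(self, example1):
        assert sm.smi_i1(example1, XY, 1).value == pytest.approx(1.2)

    def test_example1_i2_vanishes_despite_dependence(self, example1):
        assert sm.smi_i2(example1, XY, 1).value == pytest.approx(0.0, abs=1e-12)

    def test_expectation_of_i1_is_mutual_information(self, rng):
        for _ in range(10):
            m = random_mediation_model(rng, max_alphabet=3)
            joint = sm.joint_pmf(m)
            p_x = sm.marginal(joint, ["X"])
            e_i1 = sum(w * sm.smi_i1(m, XZY, x[0]).value
                       for x, w in p_x.support() if w > 0)
            assert e_i1 == pytest.approx(
                sm.mutual_information(joint, "X", "Y"), abs=1e-10)

    def test_deterministic_copy_i2_is_minus_entropy(self):
        v = {"X": Variable("X", (0, 1)), "Y": Variable("Y", (0, 1))}
        m = sm.CausalModel(v, Dag(v, [("X", "Y")]), {
            "X": Cpd("X", (), {(): [0.5, 0.5]}),
            "Y": Cpd("Y", ("X",), {(0,): [1, 0], (1,): [0, 1]}),
        })
        assert sm.smi_i2(m, XY, 1).value == pytest.approx(-1.0)

    def test_zero_probability_cause_value(self):
        v = {"X": Variable("X", (0, 1)), "Y": Variable("Y", (0, 1))}
        m = sm.CausalModel(v, Dag(v, [("X", "Y")]), {
            "X": Cpd("X", (), {(): [1.0, 0.0]}),
            "Y": Cpd("Y", ("X",), {(0,): [0.9, 0.1], (1,): [0.2, 0.8]}),
        })
        # interventional STE is still defined; observational SMI is not
        assert sm.ste(m, XY, 1).value == pytest.approx(
            sm.bernoulli_kl(0.8, 0.1))
        with pytest.raises(UnsupportedEvidenceError):
            sm.smi_i1(m, XY, 1)


class TestSte:
    def test_chain_closed_form(self):
        m = sm.chain_model(sm.ChainParams(0.1))
        expected = sm.bernoulli_kl(2 * 0.1 * 0.9, 0.5)  # 0.320 bits
        for x in (0, 1):
            assert sm.ste(m, XZY, x).value == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.320, abs=5e-4)

    def test_chain_limit_one_bit(self):
        m = sm.chain_model(sm.ChainParams(1e-8))
        assert sm.ste(m, XZY, 0).value == pytest.approx(1.0, abs=1e-3)

    def test_no_directed_path_gives_zero(self, caused_uncertainty):
        # Z -> Y <- X: X has no path to Z, so STE(x -> Z) = 0
        spec = sm.MediationSpec(x="X", z=None, y="Z")
        for x in (0, 1):
            assert sm.ste(caused_uncertainty, spec, x).value == pytest.approx(
                0.0, abs=1e-12)

    def test_two_node_equals_smi_and_reverse_is_zero(self, example1):
        for x in (0, 1):
            assert sm.ste(example1, XY, x).value == pytest.approx(
                sm.smi_i1(example1, XY, x).value, abs=1e-12)
        reverse = sm.MediationSpec(x="Y", z=None, y="X")
        for y in (0, 1):
            assert sm.ste(example1, reverse, y).value == pytest.approx(
                0.0, abs=1e-12)


class TestScde:
    def test_caused_uncertainty_parentless_mediator(self, caused_uncertainty):
        spec = sm.MediationSpec(x="X", z="Z", y="Y")
        assert sm.scde(caused_uncertainty, spec, 0, 0).value == pytest.approx(
            0.53, abs=5e-3)
        # z=1 severs the X -> Y mechanism entirely
        assert sm.scde(caused_uncertainty, spec, 0, 1).value == pytest.approx(
            0.0, abs=1e-12)

    def test_pure_chain_has_no_direct_effect(self, chain01):
        for x in (0, 1):
            for z in (0, 1):
                assert sm.scde(chain01, XZY, x, z).value == pytest.approx(
                    0.0, abs=1e-12)


class TestSndeSnie:
    def test_pure_chain_snde_zero_snie_equals_ste(self, chain01):
        for x in (0, 1):
            assert sm.snde(chain01, XZY, x).value == pytest.approx(0, abs=1e-12)
            assert sm.snie(chain01, XZY, x).value == pytest.approx(
                sm.ste(chain01, XZY, x).value, abs=1e-12)

    def test_removing_mediator_to_effect_edge_collapses_snde_to_ste(self, rng):
        m = random_mediation_model(rng, max_alphabet=3)
        # rebuild with Z -> Y removed: Y keeps only X as parent
        variables = m.variables
        dag = Dag(variables, [("X", "Z"), ("X", "Y")])
        y_cpd = m.cpds["Y"]
        ky = len(variables["Y"].alphabet)
        table = {}
        for (xv,) in itertools.product(variables["X"].alphabet):
            # average old rows over z with any fixed weights; use z marginal
            row = np.zeros(ky)
            zw = np.ones(len(variables["Z"].alphabet))
            zw /= zw.sum()
            for j, zv in enumerate(variables["Z"].alphabet):
                key = tuple(xv if q == "X" else zv for q in y_cpd.parents)
                row += zw[j] * y_cpd.table[key]
            table[(xv,)] = row
        cpds = dict(m.cpds)
        cpds["Y"] = Cpd("Y", ("X",), table)
        m2 = sm.CausalModel(variables, dag, cpds)
        for x in variables["X"].alphabet:
            assert sm.snde(m2, XZY, x).value == pytest.approx(
                sm.ste(m2, XZY, x).value, abs=1e-10)
            assert sm.snie(m2, XZY, x).value == pytest.approx(0.0, abs=1e-10)

    def test_removing_cause_to_mediator_edge_zeroes_snie(self, rng):
        m = random_mediation_model(rng, max_alphabet=3)
        variables = m.variables
        dag = Dag(variables, [("X", "Y"), ("Z", "Y")])
        kz = len(variables["Z"].alphabet)
        cpds = dict(m.cpds)
        cpds["Z"] = Cpd("Z", (), {(): rng.dirichlet(np.ones(kz))})
        m2 = sm.CausalModel(variables, dag, cpds)
        for x in variables["X"].alphabet:
            assert sm.snie(m2, XZY, x).value == pytest.approx(0.0, abs=1e-10)

    def test_random_models_match_brute_force_oracle(self, rng):
        for _ in range(8):
            m = random_mediation_model(rng, confounded=bool(rng.integers(2)),
                                       max_alphabet=3)
            for x in m.variables["X"].alphabet:
                assert sm.snde(m, XZY, x).value == pytest.approx(
                    brute_snde(m, x), abs=1e-10)
                assert sm.snie(m, XZY, x).value == pytest.approx(
                    brute_snie(m, x), abs=1e-10)


class TestConditionalSte:
    def test_chain_closed_form_matches(self):
        params = sm.ChainParams(0.1)
        m = sm.chain_model(params)
        spec = sm.MediationSpec(x="Z", z=None, y="Y", u=("X",))
        got = sm.conditional_ste(m, spec, 0, {"X": 0}).value
        expected = sm.bernoulli_kl(0.1, 2 * 0.1 * 0.9)
        assert got == pytest.approx(expected, abs=1e-12)
        # frozen from an independent evaluation (scipy.special.rel_entr)
        assert got == pytest.approx(0.0360713, abs=5e-7)

    def test_caused_uncertainty_table(self, caused_uncertainty):
        spec = sm.MediationSpec(x="Z", z=None, y="Y", u=("X",))
        vals = {z: sm.conditional_ste(caused_uncertainty, spec, z,
                                      {"X": 0}).value for z in (0, 1)}
        assert vals[0] == pytest.approx(0.01, abs=5e-3)
        assert vals[1] == pytest.approx(0.52, abs=1e-2)

    def test_empty_context_reduces_to_ste(self, chain01):
        for x in (0, 1):
            assert sm.conditional_ste(chain01, XZY, x, {}).value == \
                sm.ste(chain01, XZY, x).value

    def test_full_covariate_context_matches_factored_form(self, rng):
        # with all covariates observed, p(x'|u) reduces to p(x'|uX): check
        # the general computation against the explicitly factored evaluation
        m = random_mediation_model(rng, confounded=True, max_alphabet=3)
        spec = sm.MediationSpec(x="X", z="Z", y="Y", u=("U",))
        for u in m.variables["U"].alphabet:
            for x in m.variables["X"].alphabet:
                general = sm.conditional_ste(m, spec, x, {"U": u}).value
                # factored: weights from the X CPD row at uX = u directly
                w = m.cpds["X"].table[(u,)]
                first = sm.interventional_query(m, "Y", do={"X": x},
                                                given={"U": u})
                mix = np.zeros_like(first.array)
                for i, xp in enumerate(m.variables["X"].alphabet):
                    if w[i] > 0:
                        mix += w[i] * sm.interventional_query(
                            m, "Y", do={"X": xp}, given={"U": u}).array
                expected = sm.kl(first, sm.Pmf(first.variables, mix,
                                               check=False))
                assert general == pytest.approx(expected, abs=1e-10)


class TestConditionalVariants:
    def test_empty_context_equals_unconditional(self, rng):
        m = random_mediation_model(rng, max_alphabet=3)
        x = m.variables["X"].alphabet[0]
        z = m.variables["Z"].alphabet[0]
        assert sm.conditional_scde(m, XZY, x, z, {}).value == \
            sm.scde(m, XZY, x, z).value
        assert sm.conditional_snde(m, XZY, x, {}).value == \
            sm.snde(m, XZY, x).value
        assert sm.conditional_snie(m, XZY, x, {}).value == \
            sm.snie(m, XZY, x).value

    def test_context_forcing_the_cause_zeroes_its_effects(self):
        # U copies into X deterministically; conditioning on U leaves a
        # single-term mixture, so every measure of the forced value is 0
        v = {n: Variable(n, (0, 1)) for n in ("U", "X", "Z", "Y")}
        dag = Dag(v, [("U", "X"), ("X", "Z"), ("X", "Y"), ("Z", "Y")])
        rng = np.random.default_rng(7)
        cpds = {
            "U": Cpd("U", (), {(): [0.4, 0.6]}),
            "X": Cpd("X", ("U",), {(0,): [1, 0], (1,): [0, 1]}),
            "Z": Cpd("Z", ("X",), {(0,): [0.8, 0.2], (1,): [0.3, 0.7]}),
            "Y": Cpd("Y", ("X", "Z"), {
                k: rng.dirichlet(np.ones(2))
                for k in itertools.product((0, 1), repeat=2)
            }),
        }
        m = sm.CausalModel(v, dag, cpds)
        spec = sm.MediationSpec(x="X", z="Z", y="Y", u=("U",))
        for u in (0, 1):
            assert sm.conditional_ste(m, spec, u, {"U": u}).value == \
                pytest.approx(0.0, abs=1e-12)
            assert sm.conditional_snde(m, spec, u, {"U": u}).value == \
                pytest.approx(0.0, abs=1e-12)
            assert sm.conditional_snie(m, spec, u, {"U": u}).value == \
                pytest.approx(0.0, abs=1e-12)

    def test_nonnegativity_on_random_models(self, rng):
        for _ in range(6):
            m = random_mediation_model(rng, confounded=True, max_alphabet=3)
            spec = sm.MediationSpec(x="X", z="Z", y="Y", u=("U",))
            for u in m.variables["U"].alphabet:
                for x in m.variables["X"].alphabet:
                    assert sm.conditional_ste(m, spec, x, {"U": u}).value >= 0
                    assert sm.conditional_snde(m, spec, x, {"U": u}).value >= 0
                    assert sm.conditional_snie(m, spec, x, {"U": u}).value >= 0


class TestMarginalizationInvariance:
    def test_snde_same_for_last_state_and_full_history_mediator(self):
        # E -> T0 -> T1 -> T2 with E -> Ti: when the persistence chain is
        # Markov given E, the SNDE of e on T2 is the same whether the
        # mediator is T1 or the full history (T0, T1)
        gen = sm.MediationGenParams()
        a = gen.alphabet
        v = {"E": Variable("E", a), "T0": Variable("T0", a),
             "T1": Variable("T1", a), "T2": Variable("T2", a)}
        dag = Dag(v, [("E", "T0"), ("E", "T1"), ("E", "T2"),
                      ("T0", "T1"), ("T1", "T2")])
        trans = gen.p_t_given_es
        cpds = {
            "E": Cpd("E", (), {(): gen.p_e}),
            "T0": Cpd("T0", ("E",), dict(gen.p_s_given_e)),
            "T1": Cpd("T1", ("E", "T0"), dict(trans)),
            "T2": Cpd("T2", ("E", "T1"), dict(trans)),
        }
        m = sm.CausalModel(v, dag, cpds)
        spec_last = sm.MediationSpec(x="E", z="T1", y="T2")
        spec_hist = sm.MediationSpec(x="E", z=("T0", "T1"), y="T2")
        for e in a:
            assert sm.snde(m, spec_last, e).value == pytest.approx(
                sm.snde(m, spec_hist, e).value, abs=1e-10)


class TestNormalized:
    def test_deterministic_intervention_normalizes_to_one(self):
        m = sm.chain_model(sm.ChainParams(0.0))
        ev = sm.ste(m, XZY, 1)
        assert ev.value > 0
        assert sm.normalized(m, XZY, ev, 1) == 1.0

    def test_zero_measure_normalizes_to_zero(self, chain01):
        ev = sm.snde(chain01, XZY, 0)
        assert ev.value == pytest.approx(0.0, abs=1e-12)
        assert sm.normalized(chain01, XZY, ev, 0) == 0.0

    def test_measure_equal_to_entropy_gives_half(self, chain01):
        ev = sm.ste(chain01, XZY, 0)
        h = sm.entropy(sm.interventional_query(chain01, "Y", do={"X": 0}))
        expected = ev.value / (ev.value + h)
        assert sm.normalized(chain01, XZY, ev, 0) == pytest.approx(expected)
        synthetic = sm.EffectValue("ste", "X", 0, h)
        assert sm.normalized(chain01, XZY, synthetic, 0) == pytest.approx(0.5)

    def test_infinite_measure_normalizes_to_one(self):
        inf_ev = sm.EffectValue("ste", "X", 0, math.inf)
        m = sm.chain_model(sm.ChainParams(0.1))
        assert sm.normalized(m, XZY, inf_ev, 0) == 1.0
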