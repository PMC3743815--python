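"""Rate laws, stoichiometric semantics and structural validation."""

import numpy as np
import pytest

from coxflux import (
    Component,
    ComponentKind,
    ModelIntegrityError,
    Modifier,
    ModifierRole,
    NetworkModel,
    RateParameters,
    Reaction,
    ReactionType,
    StateError,
    consumed_ids,
    reaction_rate,
    validate_model,
)

from _oracles import symbolic_rate

P = RateParameters()


def _rxn(rtype, subs=(), prods=(), mods=()):
    return Reaction("r", rtype, tuple(subs), tuple(prods), tuple(mods))


class TestRateLaws:
    @pytest.mark.parametrize("rtype,subs,prods,mods,state,expected", [
        # direct evaluations of the kinetic law table
        (ReactionType.TRANSCRIPTION, ["G"], ["m"], [], {"G": 1.0, "m": 0.0}, 0.25),
        (ReactionType.TRANSLATION, ["m"], ["p"], [], {"m": 2.0, "p": 0.0}, 0.7),
        (ReactionType.DECAY, ["S"], [], [], {"S": 0.0}, 0.0),
        (ReactionType.DECAY, ["S"], [], [], {"S": 3.0}, 0.3),
        (ReactionType.COMPLEX_FORMATION, ["A", "B"], ["AB"], [],
         {"A": 2.0, "B": 3.0, "AB": 0.0}, 4.2),
        (ReactionType.TRANSLOCATION, ["X"], ["Xn"], [], {"X": 2.0, "Xn": 1.0}, 0.5),
        (ReactionType.TRANSLOCATION, ["X"], ["Xn"], [], {"X": 0.0, "Xn": 1.0}, -0.5),
        (ReactionType.MIRNA_BINDING, ["m"], [], [Modifier("mi", ModifierRole.MIRNA)],
         {"m": 4.0, "mi": 5.0}, 0.2),
    ])
    def test_direct_evaluation(self, rtype, subs, prods, mods, state, expected):
        assert reaction_rate(_rxn(rtype, subs, prods, mods), state, P) == pytest.approx(expected)

    def test_inhibited_phosphorylation(self):
        """[P]=2,[E]=1,k_e=0.35,[I]=1,k_i=0.2 -> 2*1*0.35/(1+0.2) = 0.5833..."""
        r = _rxn(ReactionType.PHOSPHORYLATION, ["P"], ["pP"],
                 [Modifier("E", ModifierRole.ENZYME), Modifier("I", ModifierRole.INHIBITOR)])
        state = {"P": 2.0, "E": 1.0, "I": 1.0, "pP": 0.0}
        assert reaction_rate(r, state, P) == pytest.approx(2 * 1 * 0.35 / 1.2)
        # absent inhibitor recovers plain enzymatic mass action
        r0 = _rxn(ReactionType.PHOSPHORYLATION, ["P"], ["pP"],
                  [Modifier("E", ModifierRole.ENZYME)])
        assert reaction_rate(r0, state, P) == pytest.approx(0.7)

    def test_tf_modifiers_scale_transcription(self):
        r = _rxn(ReactionType.TRANSCRIPTION, ["G"], ["m"],
                 [Modifier("TFp", ModifierRole.TF_PROMOTE),
                  Modifier("TFr", ModifierRole.TF_REPRESS)])
        state = {"G": 1.0, "m": 0.0, "TFp": 3.0, "TFr": 1.0}
        assert reaction_rate(r, state, P) == pytest.approx(0.25 * 4 / 2)
        # no TFs -> reduces to the bare law
        state0 = {"G": 1.0, "m": 0.0, "TFp": 0.0, "TFr": 0.0}
        assert reaction_rate(r, state0, P) == pytest.approx(0.25)

    def test_unresolved_id_raises(self):
        with pytest.raises(ModelIntegrityError):
            reaction_rate(_rxn(ReactionType.DECAY, ["nope"]), {"S": 1.0}, P)

    def test_negative_concentration_raises(self):
        with pytest.raises(StateError):
            reaction_rate(_rxn(ReactionType.DECAY, ["S"]), {"S": -0.1}, P)


def _random_reaction_and_state(rng):
    """A random reaction of each type with a random positive state."""
    cases = []
    state = {cid: float(rng.uniform(0.0, 5.0))
             for cid in ("G", "m", "p", "A", "B", "AB", "X", "Xn", "E", "I", "mi",
                         "TFp", "TFr")}
    cases.append(_rxn(ReactionType.TRANSCRIPTION, ["G"], ["m"],
                      [Modifier("TFp", ModifierRole.TF_PROMOTE),
                       Modifier("TFr", ModifierRole.TF_REPRESS)]))
    cases.append(_rxn(ReactionType.TRANSLATION, ["m"], ["p"]))
    cases.append(_rxn(ReactionType.DECAY, ["p"]))
    cases.append(_rxn(ReactionType.COMPLEX_FORMATION, ["A", "B"], ["AB"]))
    cases.append(_rxn(ReactionType.TRANSLOCATION, ["X"], ["Xn"]))
    cases.append(_rxn(ReactionType.PHOSPHORYLATION, ["p"], ["X"],
                      [Modifier("E", ModifierRole.ENZYME),
                       Modifier("I", ModifierRole.INHIBITOR)]))
    cases.append(_rxn(ReactionType.DEPHOSPHORYLATION, ["X"], ["p"],
                      [Modifier("E", ModifierRole.ENZYME)]))
    cases.append(_rxn(ReactionType.ACTIVATION, ["p"], ["X"],
                      [Modifier("E", ModifierRole.ENZYME),
                       Modifier("I", ModifierRole.INHIBITOR)]))
    cases.append(_rxn(ReactionType.MIRNA_BINDING, ["m"], [],
                      [Modifier("mi", ModifierRole.MIRNA)]))
    return cases, state


def test_agrees_with_symbolic_oracle_on_random_states():
    """Every rate law matches an independent symbolic evaluation (100 states)."""
    rng = np.random.default_rng(42)
    for _ in range(100):
        cases, state = _random_reaction_and_state(rng)
        for r in cases:
            assert reaction_rate(r, state, P) == pytest.approx(
                symbolic_rate(r, state, P), rel=1e-12, abs=1e-12)


def test_rates_homogeneous_in_their_constant():
    """Doubling the named rate constant doubles the rate, for every type."""
    rng = np.random.default_rng(7)
    cases, state = _random_reaction_and_state(rng)
    for r in cases:
        v1 = reaction_rate(r, state, P)
        doubled = P.copy()
        doubled.overrides[r.id] = 2 * P.primary(r)
        v2 = reaction_rate(r, state, doubled)
        assert v2 == pytest.approx(2 * v1, rel=1e-12, abs=1e-15)


def test_rates_finite_and_nonnegative_except_translocation():
    rng = np.random.default_rng(3)
    for _ in range(50):
        cases, state = _random_reaction_and_state(rng)
        for r in cases:
            v = reaction_rate(r, state, P)
            assert np.isfinite(v)
            if r.rtype is not ReactionType.TRANSLOCATION:
                assert v >= 0


def test_template_semantics():
    """Transcription/translation consume nothing; miRNA binding eats the mRNA."""
    assert consumed_ids(_rxn(ReactionType.TRANSCRIPTION, ["G"], ["m"])) == ()
    assert consumed_ids(_rxn(ReactionType.TRANSLATION, ["m"], ["p"])) == ()
    assert consumed_ids(_rxn(ReactionType.DECAY, ["S"])) == ("S",)
    mb = _rxn(ReactionType.MIRNA_BINDING, ["m"], [], [Modifier("mi", ModifierRole.MIRNA)])
    assert consumed_ids(mb) == ("m",)


class TestValidation:
    def test_fixture_is_valid(self, mini_cox):
        assert validate_model(mini_cox) == []

    def test_dangling_product(self):
        m = NetworkModel.build(
            [Component("G", ComponentKind.GENE), Component("m", ComponentKind.MRNA)],
            [Reaction("tx", ReactionType.TRANSCRIPTION, ("G",), ("ghost",))])
        diags = validate_model(m)
        assert any(d.rule == "dangling" and d.subject == "tx" for d in diags)

    def test_transcription_arity(self):
        m = NetworkModel.build(
            [Component("G", ComponentKind.GENE),
             Component("m1", ComponentKind.MRNA), Component("m2", ComponentKind.MRNA)],
            [Reaction("tx", ReactionType.TRANSCRIPTION, ("G",), ("m1", "m2"))])
        assert any(d.rule == "arity" for d in validate_model(m))

    def test_clamped_only_for_compound_or_gene(self):
        m = NetworkModel.build(
            [Component("p", ComponentKind.PROTEIN, clamped=True)], [])
        assert any(d.rule == "clamped" for d in validate_model(m))

    def test_translocation_same_compartment_flagged(self):
        from coxflux import Compartment
        m = NetworkModel.build(
            [Component("a", ComponentKind.PROTEIN),
             Component("b", ComponentKind.PROTEIN)],
            [Reaction("tr", ReactionType.TRANSLOCATION, ("a",), ("b",))])
        assert any(d.rule == "compartment" for d in validate_model(m))


class TestHypothesisProperties:
    """Randomized law properties (derandomized for reproducibility)."""

    from hypothesis import given, settings, strategies as st

    conc = st.floats(min_value=0.0, max_value=1e6, allow_nan=False)

    @given(g=conc, tf=conc)
    @settings(deadline=None, derandomize=True, max_examples=50)
    def test_promoting_tf_never_lowers_transcription(self, g, tf):
        r = _rxn(ReactionType.TRANSCRIPTION, ["G"], ["m"],
                 [Modifier("TF", ModifierRole.TF_PROMOTE)])
        base = reaction_rate(_rxn(ReactionType.TRANSCRIPTION, ["G"], ["m"]),
                             {"G": g, "m": 0.0}, P)
        with_tf = reaction_rate(r, {"G": g, "m": 0.0, "TF": tf}, P)
        assert with_tf >= base

    @given(p=conc, e=conc, i=conc)
    @settings(deadline=None, derandomize=True, max_examples=50)
    def test_inhibitor_never_raises_enzymatic_rate(self, p, e, i):
        r = _rxn(ReactionType.PHOSPHORYLATION, ["P"], ["pP"],
                 [Modifier("E", ModifierRole.ENZYME), Modifier("I", ModifierRole.INHIBITOR)])
        free = reaction_rate(r, {"P": p, "E": e, "I": 0.0, "pP": 0.0}, P)
        held = reaction_rate(r, {"P": p, "E": e, "I": i, "pP": 0.0}, P)
        assert held <= free
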