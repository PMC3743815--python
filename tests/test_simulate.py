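"""Flux propagation: single steps, steady states, conservation, consistency."""

import numpy as np
import pytest

from coxflux import (
    Component,
    ComponentKind,
    Compartment,
    Modifier,
    ModifierRole,
    NetworkModel,
    RateParameters,
    Reaction,
    ReactionType,
    SimulationError,
    SimulationSettings,
    StateVector,
    initialize,
    run_to_steady_state,
    step,
)
from coxflux import ExpressionTable

from _oracles import ode_steady_state


def chain_model(clamp_gene_at=1.0):
    """gene -> mRNA -> protein with decays; the gene is a clamped source."""
    return NetworkModel.build(
        [Component("G", ComponentKind.GENE, clamped=True, fixed_value=clamp_gene_at),
         Component("m", ComponentKind.MRNA),
         Component("p", ComponentKind.PROTEIN)],
        [Reaction("tx", ReactionType.TRANSCRIPTION, ("G",), ("m",)),
         Reaction("tl", ReactionType.TRANSLATION, ("m",), ("p",)),
         Reaction("dm", ReactionType.DECAY, ("m",)),
         Reaction("dp", ReactionType.DECAY, ("p",))])


class TestStep:
    def test_decay_only_depletes_substrate(self):
        m = NetworkModel.build([Component("A", ComponentKind.PROTEIN)],
                               [Reaction("d", ReactionType.DECAY, ("A",))])
        s = step(m, StateVector({"A": 1.0}), SimulationSettings(step_size=1.0))
        assert s["A"] == pytest.approx(0.9)
        assert s.step == 1

    def test_clamped_compound_never_moves(self):
        m = NetworkModel.build(
            [Component("ADP", ComponentKind.COMPOUND, clamped=True, fixed_value=1.0),
             Component("X", ComponentKind.COMPLEX)],
            [Reaction("cf", ReactionType.COMPLEX_FORMATION, ("ADP", "ADP"), ("X",))])
        s = StateVector({"ADP": 1.0, "X": 0.0})
        for _ in range(5):
            s = step(m, s, SimulationSettings(step_size=0.5))
        assert s["ADP"] == 1.0
        assert s["X"] > 0

    def test_empty_reaction_set_is_identity(self):
        m = NetworkModel.build([Component("A", ComponentKind.PROTEIN)], [])
        s0 = StateVector({"A": 2.5})
        assert step(m, s0).values == s0.values

    def test_negative_clip(self):
        # translocation with empty source pulls the sink negative in one
        # coarse step; the clip floors it at zero
        m = NetworkModel.build(
            [Component("a", ComponentKind.PROTEIN),
             Component("b", ComponentKind.PROTEIN, compartment=Compartment.NUCLEOPLASM)],
            [Reaction("tr", ReactionType.TRANSLOCATION, ("a",), ("b",))])
        s = step(m, StateVector({"a": 0.0, "b": 1.0}), SimulationSettings(step_size=3.0))
        assert s["b"] == 0.0
        assert s["a"] == pytest.approx(1.5)


class TestSteadyState:
    def test_single_stage_balance(self):
        """Clamped gene source: steady mRNA = k_transcription/k_decay = 2.5."""
        m = chain_model()
        res = run_to_steady_state(m, initialize(m, ExpressionTable({})),
                                  SimulationSettings(convergence_tol=1e-10))
        assert res.converged
        assert res.state["m"] == pytest.approx(2.5, rel=1e-4)

    def test_two_stage_chain(self):
        """Steady protein = (0.25/0.1)*(0.35/0.1) = 8.75."""
        m = chain_model()
        res = run_to_steady_state(m, initialize(m, ExpressionTable({})),
                                  SimulationSettings(convergence_tol=1e-10))
        assert res.state["p"] == pytest.approx(8.75, rel=1e-4)

    def test_all_zero_initial_state_stays_zero(self):
        m = chain_model(clamp_gene_at=0.0)
        res = run_to_steady_state(m, StateVector({"G": 0.0, "m": 0.0, "p": 0.0}))
        assert res.converged
        assert all(v == 0.0 for v in res.state.values.values())

    def test_divergence_names_runaway_component(self):
        # autocatalytic activation: d[P]/dt = k*[P]^2 blows up
        m = NetworkModel.build(
            [Component("S", ComponentKind.COMPOUND, clamped=True, fixed_value=1.0),
             Component("P", ComponentKind.PROTEIN)],
            [Reaction("auto", ReactionType.ACTIVATION, ("S",), ("P",),
                      (Modifier("P", ModifierRole.ENZYME),))])
        with pytest.raises(SimulationError, match="P"):
            run_to_steady_state(m, StateVector({"S": 1.0, "P": 2.0}),
                                SimulationSettings(step_size=1.0, overflow_guard=1e3))

    def test_non_converged_reported(self):
        m = chain_model()
        res = run_to_steady_state(m, initialize(m, ExpressionTable({})),
                                  SimulationSettings(max_steps=2))
        assert not res.converged
        assert res.steps_used == 2

    def test_step_size_halving_leaves_steady_state_unchanged(self):
        m = chain_model()
        s0 = initialize(m, ExpressionTable({}))
        a = run_to_steady_state(m, s0, SimulationSettings(step_size=0.1, convergence_tol=1e-9))
        b = run_to_steady_state(m, s0, SimulationSettings(step_size=0.05, convergence_tol=1e-9))
        for cid in a.state.values:
            assert a.state[cid] == pytest.approx(b.state[cid], rel=1e-4, abs=1e-9)

    def test_matches_ode_integration_on_small_random_models(self):
        from coxflux import FixtureSpec, generate_random_model
        for seed in (0, 1, 2):
            m = generate_random_model(FixtureSpec(
                n_genes=2, n_pathways=1, wiring_density=1.0, seed=seed, include_mirnas=1))
            assert len(m.components) <= 12
            genes = ExpressionTable({c.id: 1.0 + 0.5 * i for i, c in
                                     enumerate(m.components_of_kind(ComponentKind.GENE))})
            mirnas = ExpressionTable({c.id: 0.8 for c in
                                      m.components_of_kind(ComponentKind.MIRNA)},
                                     id_namespace="mirbase")
            s0 = initialize(m, genes, mirnas)
            euler = run_to_steady_state(m, s0, SimulationSettings(convergence_tol=1e-10))
            assert euler.converged
            ode = ode_steady_state(m, s0.values)
            for cid in m.components:
                assert euler.state[cid] == pytest.approx(ode[cid], rel=1e-3, abs=1e-8)


class TestConservation:
    """Mass bookkeeping per reaction type with clipping off and nothing clamped."""

    settings = SimulationSettings(step_size=0.1, negative_clip=False)

    def test_complex_formation_conserves_constituent_weighted_mass(self):
        m = NetworkModel.build(
            [Component("A", ComponentKind.PROTEIN), Component("B", ComponentKind.PROTEIN),
             Component("AB", ComponentKind.COMPLEX)],
            [Reaction("cf", ReactionType.COMPLEX_FORMATION, ("A", "B"), ("AB",))])
        s = StateVector({"A": 2.0, "B": 1.0, "AB": 0.0})
        weighted = lambda st: st["A"] + st["B"] + 2 * st["AB"]
        before = weighted(s)
        for _ in range(20):
            s = step(m, s, self.settings)
        assert weighted(s) == pytest.approx(before, rel=1e-12)

    def test_translocation_conserves_plain_mass(self):
        m = NetworkModel.build(
            [Component("a", ComponentKind.PROTEIN),
             Component("an", ComponentKind.PROTEIN, compartment=Compartment.NUCLEOPLASM)],
            [Reaction("tr", ReactionType.TRANSLOCATION, ("a",), ("an",))])
        s = StateVector({"a": 3.0, "an": 0.5})
        for _ in range(150):
            s = step(m, s, self.settings)
        assert s["a"] + s["an"] == pytest.approx(3.5, rel=1e-12)
        # net flow settles at the k_in/k_out balance point
        assert s["a"] * 0.5 == pytest.approx(s["an"] * 0.5, rel=1e-3)

    def test_decay_strictly_decreases_mass(self):
        m = NetworkModel.build([Component("S", ComponentKind.PROTEIN)],
                               [Reaction("d", ReactionType.DECAY, ("S",))])
        s = StateVector({"S": 1.0})
        prev = 1.0
        for _ in range(10):
            s = step(m, s, self.settings)
            assert s["S"] < prev
            prev = s["S"]

    def test_phosphorylation_conserves_mass(self):
        m = NetworkModel.build(
            [Component("p", ComponentKind.PROTEIN), Component("pp", ComponentKind.PROTEIN),
             Component("E", ComponentKind.PROTEIN)],
            [Reaction("ph", ReactionType.PHOSPHORYLATION, ("p",), ("pp",),
                      (Modifier("E", ModifierRole.ENZYME),))])
        s = StateVector({"p": 2.0, "pp": 0.0, "E": 1.0})
        for _ in range(20):
            s = step(m, s, self.settings)
        assert s["p"] + s["pp"] == pytest.approx(2.0, rel=1e-12)
        assert s["E"] == 1.0  # enzyme recycled


def test_stiffness_warning():
    m = chain_model()
    with pytest.warns(UserWarning, match="unstable"):
        run_to_steady_state(m, initialize(m, ExpressionTable({})),
                            SimulationSettings(step_size=2.0, max_steps=5))


def test_determinism_bit_identical():
    m = chain_model()
    s0 = initialize(m, ExpressionTable({}))
    r1 = run_to_steady_state(m, s0, SimulationSettings(max_steps=500))
    r2 = run_to_steady_state(m, s0, SimulationSettings(max_steps=500))
    assert r1.state.values == r2.state.values


def test_trajectory_recording_and_dump(tmp_path):
    import pandas as pd
    from coxflux import write_trajectory

    m = chain_model()
    res = run_to_steady_state(m, initialize(m, ExpressionTable({})),
                              SimulationSettings(max_steps=50, record_trajectory=True))
    assert res.trajectory is not None
    assert res.trajectory.shape == (res.steps_used + 1, 3)
    out = tmp_path / "traj.tsv"
    write_trajectory(res, out)
    df = pd.read_csv(out, sep="\t")
    assert list(df.columns) == ["step", "G", "m", "p"]
    assert len(df) == res.steps_used + 1
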