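"""Declarative therapeutic perturbations of a network model.

Four intervention mechanisms are supported, each a pure function returning
a fresh model (or state) and leaving its input untouched:

* siRNA knockdown — the translation rate of the target mRNA is divided by
  the siRNA level (``v = [mRNA]·k_translation/[siRNA]``); a siRNA species
  pinned at that level is added to the model for bookkeeping.
* degradation-promoting drug — the decay rate of each listed protein is
  multiplied by an inhibitor level ≥ 1 (``v = [P]·k_decay·[Inhibit]``).
  The bundled NS-398 preset targets COX-2, VEGFA, IL1 and TNF
  simultaneously.
* kinase inhibition — the target protein's enzymatic contributions to
  phosphorylation/activation reactions are nullified or scaled, modelling
  small-molecule kinase inhibitors orthogonally to expression knockdown.
* miRNA overexpression — the miRNA's initial concentration is multiplied
  by a fold factor (default 100); absent miRNAs are raised from a small
  documented floor so the protocol is never a silent no-op.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple, Union

import yaml

from .io import StateVector
from .model import (
    Component,
    ComponentKind,
    ModifierRole,
    NetworkModel,
    ReactionType,
)


class PerturbationError(Exception):
    pass


@dataclass(frozen=True)
class SirnaAction:
    target_mrna: str
    sirna_level: float = 10.0

    def __post_init__(self) -> None:
        if self.sirna_level <= 0:
            raise PerturbationError("sirna_level must be > 0 (rate law divides by it)")


@dataclass(frozen=True)
class DegradationDrugAction:
    #: (target protein id, inhibitor level >= 1)
    targets: Tuple[Tuple[str, float], ...]

    def __post_init__(self) -> None:
        for cid, level in self.targets:
            if level < 1:
                raise PerturbationError(
                    f"inhibitor level for {cid!r} must be >= 1 (degradation promotion)")


@dataclass(frozen=True)
class KinaseInhibition:
    target: str
    mode: str = "zero_activity"       # "zero_activity" | "scale"
    factor: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in ("zero_activity", "scale"):
            raise PerturbationError(f"unknown kinase inhibition mode {self.mode!r}")
        if not 0.0 <= self.factor <= 1.0:
            raise PerturbationError("kinase inhibition factor must be in [0, 1]")


@dataclass(frozen=True)
class MirnaOverexpression:
    mirna: str
    fold: float = 100.0
    floor: float = 0.01

    def __post_init__(self) -> None:
        if self.fold <= 0:
            raise PerturbationError("fold must be > 0")


Action = Union[SirnaAction, DegradationDrugAction, KinaseInhibition, MirnaOverexpression]


@dataclass
class PerturbationSpec:
    name: str
    actions: List[Action] = field(default_factory=list)

    def model_actions(self) -> List[Action]:
        return [a for a in self.actions if not isinstance(a, MirnaOverexpression)]

    def state_actions(self) -> List[MirnaOverexpression]:
        return [a for a in self.actions if isinstance(a, MirnaOverexpression)]


# ---------------------------------------------------------------------------
# individual mechanisms
# ---------------------------------------------------------------------------

def apply_sirna(m: NetworkModel, action: SirnaAction) -> NetworkModel:
    """Divide the target mRNA's translation rate(s) by the siRNA level."""
    target = action.target_mrna
    if target not in m.components:
        raise PerturbationError(f"siRNA target {target!r} not in model")
    out = m.copy()
    hit = False
    for r in out.reactions_of_type(ReactionType.TRANSLATION):
        if r.substrates[0] == target:
            out.params.overrides[r.id] = out.params.primary(r) / action.sirna_level
            hit = True
    if not hit:
        raise PerturbationError(f"{target!r} has no translation reaction to knock down")
    sid = f"siRNA:{target}"
    if sid not in out.components:
        out.components[sid] = Component(sid, ComponentKind.SIRNA,
                                        fixed_value=action.sirna_level)
    return out


def apply_degradation_drug(m: NetworkModel, action: DegradationDrugAction) -> NetworkModel:
    """Multiply the decay rate of each target protein by its inhibitor level."""
    out = m.copy()
    for target, level in action.targets:
        if target not in m.components:
            raise PerturbationError(f"degradation target {target!r} not in model")
        hit = False
        for r in out.reactions_of_type(ReactionType.DECAY):
            if r.substrates[0] == target:
                out.params.overrides[r.id] = out.params.primary(r) * level
                hit = True
        if not hit:
            raise PerturbationError(
                f"{target!r} has no decay reaction; degradation promotion impossible")
    return out


def apply_kinase_inhibition(m: NetworkModel, action: KinaseInhibition) -> NetworkModel:
    """Null or scale the target's enzymatic rate contributions."""
    if action.target not in m.components:
        raise PerturbationError(f"kinase target {action.target!r} not in model")
    factor = 0.0 if action.mode == "zero_activity" else action.factor
    out = m.copy()
    hit = False
    for r in out.reactions.values():
        if r.rtype in (ReactionType.PHOSPHORYLATION, ReactionType.DEPHOSPHORYLATION,
                       ReactionType.ACTIVATION):
            if action.target in r.modifier_ids(ModifierRole.ENZYME):
                out.params.overrides[r.id] = out.params.primary(r) * factor
                hit = True
    if not hit:
        raise PerturbationError(
            f"{action.target!r} never acts as enzyme in a phosphorylation/activation reaction")
    return out


def apply_mirna_overexpression(m: NetworkModel, s0: StateVector,
                               action: MirnaOverexpression) -> StateVector:
    """Multiply the miRNA's initial concentration by ``fold``.

    A zero baseline becomes ``fold * floor`` so that overexpressing an
    unexpressed miRNA still injects signal.
    """
    mid = action.mirna
    if mid not in m.components:
        raise PerturbationError(f"miRNA {mid!r} not in model")
    if m.components[mid].kind != ComponentKind.MIRNA:
        raise PerturbationError(f"{mid!r} is not a miRNA component")
    out = s0.copy()
    baseline = out.values[mid]
    out.values[mid] = baseline * action.fold if baseline > 0 else action.fold * action.floor
    return out


def apply_spec(m: NetworkModel, s0: StateVector,
               spec: PerturbationSpec) -> Tuple[NetworkModel, StateVector]:
    """Apply all actions of a spec; returns (new model, new initial state).

    The state is re-derived for the returned model: components added by
    model-level actions (the bookkeeping siRNA species) are inserted at
    their fixed value.
    """
    model = m
    for action in spec.model_actions():
        if isinstance(action, SirnaAction):
            model = apply_sirna(model, action)
        elif isinstance(action, DegradationDrugAction):
            model = apply_degradation_drug(model, action)
        elif isinstance(action, KinaseInhibition):
            model = apply_kinase_inhibition(model, action)
    state = s0.copy()
    for cid, comp in model.components.items():
        if cid not in state.values:
            state.values[cid] = comp.fixed_value if comp.fixed_value is not None else 0.0
    for action in spec.state_actions():
        state = apply_mirna_overexpression(model, state, action)
    return model, state


# ---------------------------------------------------------------------------
# YAML serialization
# ---------------------------------------------------------------------------

_ACTION_TAGS = {
    "sirna": SirnaAction,
    "degradation_drug": DegradationDrugAction,
    "kinase_inhibition": KinaseInhibition,
    "mirna_overexpression": MirnaOverexpression,
}


def _action_to_dict(a: Action) -> Dict:
    if isinstance(a, SirnaAction):
        return {"type": "sirna", "target_mrna": a.target_mrna, "sirna_level": a.sirna_level}
    if isinstance(a, DegradationDrugAction):
        return {"type": "degradation_drug",
                "targets": [{"protein": cid, "inhibitor_level": lvl} for cid, lvl in a.targets]}
    if isinstance(a, KinaseInhibition):
        return {"type": "kinase_inhibition", "target": a.target,
                "mode": a.mode, "factor": a.factor}
    if isinstance(a, MirnaOverexpression):
        return {"type": "mirna_overexpression", "mirna": a.mirna,
                "fold": a.fold, "floor": a.floor}
    raise TypeError(f"unknown action {a!r}")


def _action_from_dict(d: Dict) -> Action:
    kind = d.get("type")
    if kind == "sirna":
        return SirnaAction(d["target_mrna"], float(d.get("sirna_level", 10.0)))
    if kind == "degradation_drug":
        return DegradationDrugAction(tuple(
            (t["protein"], float(t.get("inhibitor_level", 10.0))) for t in d["targets"]))
    if kind == "kinase_inhibition":
        return KinaseInhibition(d["target"], d.get("mode", "zero_activity"),
                                float(d.get("factor", 0.0)))
    if kind == "mirna_overexpression":
        return MirnaOverexpression(d["mirna"], float(d.get("fold", 100.0)),
                                   float(d.get("floor", 0.01)))
    raise PerturbationError(f"unknown perturbation action type {kind!r}")


def save_spec(spec: PerturbationSpec, path) -> None:
    doc = {"name": spec.name, "actions": [_action_to_dict(a) for a in spec.actions]}
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_spec(path) -> PerturbationSpec:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return PerturbationSpec(doc.get("name", "perturbation"),
                            [_action_from_dict(d) for d in doc.get("actions", [])])


# ---------------------------------------------------------------------------
# presets (wired to the mini-COX fixture ids)
# ---------------------------------------------------------------------------

#: NS-398 degradation targets: COX-2 plus the co-inhibited cytokines.
NS398_TARGETS = ("PTGS2_prot", "VEGFA_prot", "IL1B_prot", "TNF_prot")

#: Default inhibitor level; the drug-strength scale is a repository choice
#: (documented in docs/methods.md), not a measured quantity.
DEFAULT_INHIBITOR_LEVEL = 10.0


def cox2_sirna(level: float = 10.0) -> PerturbationSpec:
    return PerturbationSpec("cox2_sirna", [SirnaAction("PTGS2_mRNA", level)])


def ns398(level: float = DEFAULT_INHIBITOR_LEVEL) -> PerturbationSpec:
    return PerturbationSpec("ns398", [DegradationDrugAction(
        tuple((cid, level) for cid in NS398_TARGETS))])


def cox2_only(level: float = DEFAULT_INHIBITOR_LEVEL) -> PerturbationSpec:
    """Single COX-2 inhibition comparator: degradation promotion on COX-2 only."""
    return PerturbationSpec("cox2_only", [DegradationDrugAction((("PTGS2_prot", level),))])


def cox2_plus_rtk(rtk: str, level: float = DEFAULT_INHIBITOR_LEVEL,
                  mode: str = "zero_activity", factor: float = 0.0) -> PerturbationSpec:
    """Combined inhibition: COX-2 degradation promotion plus kinase inhibition."""
    return PerturbationSpec(f"cox2_plus_{rtk}", [
        DegradationDrugAction((("PTGS2_prot", level),)),
        KinaseInhibition(rtk, mode, factor),
    ])


def mir_overexpress(mirna: str, fold: float = 100.0) -> PerturbationSpec:
    return PerturbationSpec(f"overexpress_{mirna}", [MirnaOverexpression(mirna, fold)])


PRESETS = {
    "cox2_sirna": cox2_sirna,
    "ns398": ns398,
    "cox2_only": cox2_only,
}
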