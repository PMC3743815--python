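"""Typed in-memory representation of a three-layer signaling network.

The model follows the layered discipline of literature-curated signaling
networks: a gene layer, an RNA layer (mRNA and miRNA) and a third layer
holding proteins, complexes and small-molecule compounds.  Genes act as
templates (transcription does not consume them), mRNAs are templates for
translation, and signal is carried downward by mass-action rate laws
attached to a small taxonomy of reaction types.

All rate constants live in :class:`RateParameters`; a per-reaction override
map lets perturbations rewrite the effective constant of a single reaction
without touching the shared defaults.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple


class ModelIntegrityError(Exception):
    """A reaction references an id that does not resolve in the model/state."""


class StateError(Exception):
    """A state holds an invalid (negative or non-finite) concentration."""


class ComponentKind(str, enum.Enum):
    GENE = "gene"
    MRNA = "mRNA"
    PROTEIN = "protein"
    COMPLEX = "complex"
    COMPOUND = "compound"
    MIRNA = "miRNA"
    PSEUDO = "pseudo"
    SIRNA = "siRNA"


class Compartment(str, enum.Enum):
    DEFAULT = "default"
    NUCLEOPLASM = "nucleoplasm"
    MEMBRANE = "membrane"
    EXTRACELLULAR = "extracellular"


class ReactionType(str, enum.Enum):
    TRANSCRIPTION = "transcription"
    TRANSLATION = "translation"
    DECAY = "decay"
    COMPLEX_FORMATION = "complex_formation"
    TRANSLOCATION = "translocation"
    PHOSPHORYLATION = "phosphorylation"
    DEPHOSPHORYLATION = "dephosphorylation"
    ACTIVATION = "activation"
    MIRNA_BINDING = "mirna_binding"


class ModifierRole(str, enum.Enum):
    ENZYME = "enzyme"
    INHIBITOR = "inhibitor"
    TF_PROMOTE = "transcription_factor_promote"
    TF_REPRESS = "transcription_factor_repress"
    MIRNA = "mirna"


#: kinds that may be concentration-clamped during simulation (metabolic
#: byproducts held constant to prevent signal drop-down, plus genes which
#: are constant anyway under template semantics).
CLAMPABLE_KINDS = frozenset({ComponentKind.COMPOUND, ComponentKind.GENE})


@dataclass(frozen=True)
class Component:
    """A typed model species.

    ``id`` is an opaque namespaced string (Ensembl for gene/mRNA, UniProt
    for protein, ChEBI for compound, miRBase for miRNA, internal otherwise);
    no id-mapping is performed here.  ``fixed_value`` is the concentration a
    clamped species (or an added siRNA) is pinned to at initialization.
    """

    id: str
    kind: ComponentKind
    compartment: Compartment = Compartment.DEFAULT
    clamped: bool = False
    fixed_value: Optional[float] = None


@dataclass(frozen=True)
class Modifier:
    component_id: str
    role: ModifierRole


@dataclass(frozen=True)
class Reaction:
    id: str
    rtype: ReactionType
    substrates: Tuple[str, ...] = ()
    products: Tuple[str, ...] = ()
    modifiers: Tuple[Modifier, ...] = ()

    def modifier_ids(self, role: ModifierRole) -> Tuple[str, ...]:
        return tuple(m.component_id for m in self.modifiers if m.role == role)


@dataclass
class RateParameters:
    """Shared kinetic constants plus per-reaction overrides.

    Defaults are the empirical mass-action constants used throughout the
    model: transcription 0.25, translation 0.35, decay 0.1, complex
    formation 0.7, translocation 0.5/0.5, phosphorylation 0.35 (enzyme) /
    0.2 (inhibitor), activation 0.4/0.2, miRNA binding 0.01.
    Dephosphorylation has no constant of its own and shares the
    phosphorylation pair.
    """

    k_transcription: float = 0.25
    k_translation: float = 0.35
    k_decay: float = 0.1
    k_complex: float = 0.7
    k_in: float = 0.5
    k_out: float = 0.5
    k_e_phos: float = 0.35
    k_i_phos: float = 0.2
    k_e_act: float = 0.4
    k_i_act: float = 0.2
    k_mi: float = 0.01
    #: reaction id -> effective primary constant for that reaction
    overrides: Dict[str, float] = field(default_factory=dict)

    _PRIMARY = {
        ReactionType.TRANSCRIPTION: "k_transcription",
        ReactionType.TRANSLATION: "k_translation",
        ReactionType.DECAY: "k_decay",
        ReactionType.COMPLEX_FORMATION: "k_complex",
        ReactionType.PHOSPHORYLATION: "k_e_phos",
        ReactionType.DEPHOSPHORYLATION: "k_e_phos",
        ReactionType.ACTIVATION: "k_e_act",
        ReactionType.MIRNA_BINDING: "k_mi",
        ReactionType.TRANSLOCATION: "k_in",
    }

    def primary(self, r: Reaction) -> float:
        """The constant multiplying the rate law of ``r`` (override-aware).

        For translocation the override, if any, replaces both ``k_in`` and
        ``k_out`` (a single shared net constant).
        """
        if r.id in self.overrides:
            return self.overrides[r.id]
        return getattr(self, self._PRIMARY[r.rtype])

    def inhibition(self, r: Reaction) -> float:
        if r.rtype in (ReactionType.PHOSPHORYLATION, ReactionType.DEPHOSPHORYLATION):
            return self.k_i_phos
        if r.rtype == ReactionType.ACTIVATION:
            return self.k_i_act
        return 0.0

    def translocation_pair(self, r: Reaction) -> Tuple[float, float]:
        if r.id in self.overrides:
            k = self.overrides[r.id]
            return k, k
        return self.k_in, self.k_out

    def copy(self) -> "RateParameters":
        return replace(self, overrides=dict(self.overrides))

    def constants(self) -> Dict[str, float]:
        return {
            name: getattr(self, name)
            for name in (
                "k_transcription", "k_translation", "k_decay", "k_complex",
                "k_in", "k_out", "k_e_phos", "k_i_phos", "k_e_act",
                "k_i_act", "k_mi",
            )
        }


class HallmarkName(str, enum.Enum):
    EVADING_APOPTOSIS = "evading_apoptosis"
    PROLIFERATION = "proliferation"
    SUSTAINED_ANGIOGENESIS = "sustained_angiogenesis"
    TISSUE_INVASION = "tissue_invasion"


@dataclass(frozen=True)
class HallmarkDefinition:
    """A cancer-hallmark readout: an algebraic combination of concentrations.

    Value is ``sum(numerator) / (denominator_offset + sum(denominator))``;
    the ratio hallmarks (evading apoptosis, sustained angiogenesis) carry a
    ``1 +`` offset in the denominator, the sum hallmarks (proliferation,
    tissue invasion) have no denominator terms and offset 0, in which case
    the denominator is taken as 1 (a pure sum).  All coefficients default
    to 1: relative influence degrees of individual components are not
    weighted.
    """

    name: HallmarkName
    numerator_terms: Tuple[Tuple[str, float], ...] = ()
    denominator_terms: Tuple[Tuple[str, float], ...] = ()
    denominator_offset: float = 0.0


@dataclass
class NetworkModel:
    components: Dict[str, Component] = field(default_factory=dict)
    reactions: Dict[str, Reaction] = field(default_factory=dict)
    params: RateParameters = field(default_factory=RateParameters)
    hallmark_definitions: List[HallmarkDefinition] = field(default_factory=list)
    name: str = "model"

    @classmethod
    def build(
        cls,
        components: Iterable[Component],
        reactions: Iterable[Reaction],
        params: Optional[RateParameters] = None,
        hallmarks: Iterable[HallmarkDefinition] = (),
        name: str = "model",
    ) -> "NetworkModel":
        comp_map: Dict[str, Component] = {}
        for c in components:
            if c.id in comp_map:
                raise ModelIntegrityError(f"duplicate component id {c.id!r}")
            comp_map[c.id] = c
        rxn_map: Dict[str, Reaction] = {}
        for r in reactions:
            if r.id in rxn_map:
                raise ModelIntegrityError(f"duplicate reaction id {r.id!r}")
            rxn_map[r.id] = r
        return cls(comp_map, rxn_map, params or RateParameters(),
                   list(hallmarks), name)

    def copy(self) -> "NetworkModel":
        """Shallow-safe copy: components/reactions are immutable and shared."""
        return NetworkModel(dict(self.components), dict(self.reactions),
                            self.params.copy(), list(self.hallmark_definitions),
                            self.name)

    def components_of_kind(self, kind: ComponentKind) -> List[Component]:
        return [c for c in self.components.values() if c.kind == kind]

    def reactions_of_type(self, rtype: ReactionType) -> List[Reaction]:
        return [r for r in self.reactions.values() if r.rtype == rtype]


# ---------------------------------------------------------------------------
# stoichiometry (template semantics)
# ---------------------------------------------------------------------------

def consumed_ids(r: Reaction) -> Tuple[str, ...]:
    """Component ids depleted by one firing of ``r``.

    Transcription and translation are template reactions: the gene/mRNA
    substrate is read, not consumed; signal is only generated at the
    transcriptional level and forwarded downward.  miRNA binding consumes
    the target mRNA (repression by degradation) while the miRNA modifier is
    recycled.
    """
    if r.rtype in (ReactionType.TRANSCRIPTION, ReactionType.TRANSLATION):
        return ()
    return r.substrates


def produced_ids(r: Reaction) -> Tuple[str, ...]:
    return r.products


# ---------------------------------------------------------------------------
# rate laws
# ---------------------------------------------------------------------------

def _conc(state: Mapping[str, float], cid: str) -> float:
    try:
        v = state[cid]
    except KeyError:
        raise ModelIntegrityError(f"component {cid!r} not present in state")
    if not math.isfinite(v):
        raise StateError(f"non-finite concentration for {cid!r}")
    if v < 0:
        raise StateError(f"negative concentration {v} for {cid!r}")
    return v


def reaction_rate(r: Reaction, state: Mapping[str, float],
                  params: RateParameters) -> float:
    """Instantaneous mass-action flux of ``r`` at ``state``.

    Laws per reaction type (k is the override-aware primary constant):

    ==================  ====================================================
    transcription       [G]·k · (1+Σ[TF+]) / (1+Σ[TF−])
    translation         [m]·k
    decay               [S]·k
    complex formation   (∏ substrates)·k
    translocation       [S(A)]·k_in − [S(B)]·k_out   (signed net flow)
    (de)phos/activation [P]·(∏ enzymes)·k_e / (1 + k_i·Σ[inhibitors])
    miRNA binding       [m]·(∏ miRNA modifiers)·k
    ==================  ====================================================

    Transcription-factor control is multiplicative and reduces to the bare
    law when no TF modifier is attached; the enzymatic law reduces to plain
    mass action when no inhibitor is attached.
    """
    rt = r.rtype
    if rt == ReactionType.TRANSCRIPTION:
        v = _conc(state, r.substrates[0]) * params.primary(r)
        promote = sum(_conc(state, cid) for cid in r.modifier_ids(ModifierRole.TF_PROMOTE))
        repress = sum(_conc(state, cid) for cid in r.modifier_ids(ModifierRole.TF_REPRESS))
        return v * (1.0 + promote) / (1.0 + repress)
    if rt in (ReactionType.TRANSLATION, ReactionType.DECAY):
        return _conc(state, r.substrates[0]) * params.primary(r)
    if rt == ReactionType.COMPLEX_FORMATION:
        v = params.primary(r)
        for cid in r.substrates:
            v *= _conc(state, cid)
        return v
    if rt == ReactionType.TRANSLOCATION:
        k_in, k_out = params.translocation_pair(r)
        return _conc(state, r.substrates[0]) * k_in - _conc(state, r.products[0]) * k_out
    if rt in (ReactionType.PHOSPHORYLATION, ReactionType.DEPHOSPHORYLATION,
              ReactionType.ACTIVATION):
        v = _conc(state, r.substrates[0]) * params.primary(r)
        for cid in r.modifier_ids(ModifierRole.ENZYME):
            v *= _conc(state, cid)
        inhib = sum(_conc(state, cid) for cid in r.modifier_ids(ModifierRole.INHIBITOR))
        return v / (1.0 + params.inhibition(r) * inhib)
    if rt == ReactionType.MIRNA_BINDING:
        v = _conc(state, r.substrates[0]) * params.primary(r)
        for cid in r.modifier_ids(ModifierRole.MIRNA):
            v *= _conc(state, cid)
        return v
    raise ModelIntegrityError(f"unknown reaction type {rt!r}")


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Diagnostic:
    subject: str          # component or reaction id
    rule: str             # short rule name, e.g. "arity", "dangling"
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.rule}] {self.subject}: {self.message}"


_ARITY: Dict[ReactionType, Tuple[Tuple[int, Optional[int]], Tuple[int, Optional[int]]]] = {
    # rtype -> ((min_sub, max_sub), (min_prod, max_prod)); None = unbounded
    ReactionType.TRANSCRIPTION: ((1, 1), (1, 1)),
    ReactionType.TRANSLATION: ((1, 1), (1, 1)),
    ReactionType.DECAY: ((1, 1), (0, 0)),
    ReactionType.COMPLEX_FORMATION: ((2, None), (1, 1)),
    ReactionType.TRANSLOCATION: ((1, 1), (1, 1)),
    ReactionType.PHOSPHORYLATION: ((1, 1), (1, 1)),
    ReactionType.DEPHOSPHORYLATION: ((1, 1), (1, 1)),
    ReactionType.ACTIVATION: ((1, 1), (1, 1)),
    ReactionType.MIRNA_BINDING: ((1, 1), (0, 0)),
}

_KIND_EXPECTATIONS: Dict[ReactionType, Tuple[Optional[ComponentKind], Optional[ComponentKind]]] = {
    # rtype -> (expected substrate kind, expected product kind); None = any
    ReactionType.TRANSCRIPTION: (ComponentKind.GENE, ComponentKind.MRNA),
    ReactionType.TRANSLATION: (ComponentKind.MRNA, ComponentKind.PROTEIN),
    ReactionType.COMPLEX_FORMATION: (None, ComponentKind.COMPLEX),
    ReactionType.MIRNA_BINDING: (ComponentKind.MRNA, None),
}


def validate_model(m: NetworkModel) -> List[Diagnostic]:
    """Structural diagnostics; empty list iff all type invariants hold."""
    out: List[Diagnostic] = []

    for c in m.components.values():
        if c.clamped and c.kind not in CLAMPABLE_KINDS:
            out.append(Diagnostic(c.id, "clamped",
                                  f"clamped is only allowed for compound/gene, not {c.kind.value}"))
        if c.fixed_value is not None and c.fixed_value < 0:
            out.append(Diagnostic(c.id, "fixed_value", "fixed value must be nonnegative"))

    for kname, kval in m.params.constants().items():
        if kval < 0:
            out.append(Diagnostic(kname, "parameter", f"rate constant {kname} is negative"))
    for rid, kval in m.params.overrides.items():
        if rid not in m.reactions:
            out.append(Diagnostic(rid, "dangling", "rate override for unknown reaction"))
        if kval < 0:
            out.append(Diagnostic(rid, "parameter", "override constant is negative"))

    for r in m.reactions.values():
        for cid in (*r.substrates, *r.products, *(mod.component_id for mod in r.modifiers)):
            if cid not in m.components:
                out.append(Diagnostic(r.id, "dangling", f"references unknown component {cid!r}"))
        (smin, smax), (pmin, pmax) = _ARITY[r.rtype]
        ns, np_ = len(r.substrates), len(r.products)
        if ns < smin or (smax is not None and ns > smax):
            out.append(Diagnostic(r.id, "arity",
                                  f"{r.rtype.value} expects {smin}{'+' if smax is None else ''} substrate(s), got {ns}"))
        if np_ < pmin or (pmax is not None and np_ > pmax):
            out.append(Diagnostic(r.id, "arity",
                                  f"{r.rtype.value} expects {pmin}{'+' if pmax is None else ''} product(s), got {np_}"))
        sub_kind, prod_kind = _KIND_EXPECTATIONS.get(r.rtype, (None, None))
        if sub_kind is not None:
            for cid in r.substrates:
                c = m.components.get(cid)
                if c is not None and c.kind != sub_kind:
                    out.append(Diagnostic(r.id, "kind",
                                          f"{r.rtype.value} substrate {cid!r} should be {sub_kind.value}, is {c.kind.value}"))
        if prod_kind is not None:
            for cid in r.products:
                c = m.components.get(cid)
                if c is not None and c.kind != prod_kind:
                    out.append(Diagnostic(r.id, "kind",
                                          f"{r.rtype.value} product {cid!r} should be {prod_kind.value}, is {c.kind.value}"))
        if r.rtype == ReactionType.TRANSLOCATION and ns == 1 and np_ == 1:
            a = m.components.get(r.substrates[0])
            b = m.components.get(r.products[0])
            if a is not None and b is not None:
                if a.compartment == b.compartment:
                    out.append(Diagnostic(r.id, "compartment",
                                          "translocation endpoints share a compartment"))
                if a.kind != b.kind:
                    out.append(Diagnostic(r.id, "kind",
                                          "translocation endpoints must be the same species kind"))
        if r.rtype == ReactionType.MIRNA_BINDING and not r.modifier_ids(ModifierRole.MIRNA):
            out.append(Diagnostic(r.id, "arity", "mirna_binding needs a miRNA modifier"))
        # a clamped species may appear as substrate only if declared clamped
        # (clamped substrates are templates/never depleted); nothing to flag
        # beyond the clamped-kind rule above.

    for hd in m.hallmark_definitions:
        if hd.denominator_offset < 0:
            out.append(Diagnostic(hd.name.value, "hallmark", "denominator offset must be >= 0"))
        if hd.denominator_terms and hd.denominator_offset <= 0:
            out.append(Diagnostic(hd.name.value, "hallmark",
                                  "ratio hallmark needs a positive denominator offset"))
    return out
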