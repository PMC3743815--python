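"""Bundled miniature COX-pathway model and synthetic input generators.

Everything here is generated programmatically and deterministically, so the
whole pipeline — model I/O, initialization, simulation, perturbation,
hallmark readouts, FCA and miRNA scoring — is testable without any
external download.

The mini-COX model is a desk-scale (106-component) caricature of the
prostaglandin signaling network:

* COX-1/COX-2 gene→mRNA→protein chains; clamped arachidonic-acid and O₂
  pools; the two-step enzymatic conversion AA → PGG₂ → PGH₂ catalyzed by
  the COX proteins; PGH₂ branching into PGE₂/PGI₂/PGD₂/PGF₂/TXA₂ via their
  tissue-specific synthases.
* PGE₂ binding its four receptors EP1–4 (weakly, so receptor occupancy
  tracks the ligand); the receptor complexes activate a PKA-like branch
  that promotes anti-apoptotic and pro-angiogenic transcription, while a
  COX-independent EGF→EGFR→MAPK1→MYC cascade (with phospho-MYC
  translocating to the nucleoplasm) drives the proliferation markers.
* an NFκB-like arm activated by IL1β and TNF, promoting proliferative and
  anti-apoptotic transcription; VEGFA binding a KDR-like receptor for the
  angiogenesis readout; MMPs for the invasion readout.
* all four hallmark readouts wired to fixture species, and three miRNAs
  whose validated target is the COX-2 mRNA.

The wiring is deliberately sparse enough that the qualitative contrasts of
interest hold structurally: with EP1–4 weakly expressed, COX-2 knockdown
barely touches proliferation (the markers are driven by the EGF and
IL1/TNF arms), while the NS-398-style degradation drug also pulls down
VEGFA/IL1/TNF signaling and therefore proliferation, evading-apoptosis and
sustained-angiogenesis readouts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .io import ExpressionTable
from .model import (
    Compartment,
    Component,
    ComponentKind,
    HallmarkDefinition,
    HallmarkName,
    Modifier,
    ModifierRole,
    NetworkModel,
    RateParameters,
    Reaction,
    ReactionType,
    validate_model,
)
from .simulate import SimulationSettings


class FixtureError(Exception):
    pass


# ---------------------------------------------------------------------------
# mini-COX fixture
# ---------------------------------------------------------------------------

#: genes with a full gene→mRNA→protein chain, in construction order
MINI_COX_GENES: Tuple[str, ...] = (
    "PTGS1", "PTGS2",                                  # COX-1 / COX-2
    "PTGES", "PTGIS", "PTGDS", "PTGFS", "TBXAS1",      # prostaglandin synthases
    "PTGER1", "PTGER2", "PTGER3", "PTGER4",            # EP1-4 receptors
    "EGFR", "MAPK1", "MYC", "NFKB1", "PRKACA",         # signaling cascades
    "VEGFA", "IL1B", "TNF", "KDR",                     # cytokines + VEGF receptor
    "BCL2", "BAX",                                     # apoptosis regulators
    "MKI67", "URGCP", "IL8",                           # proliferation / angiogenesis markers
    "MMP2", "MMP9",                                    # invasion markers
)

EP_GENES: Tuple[str, ...] = ("PTGER1", "PTGER2", "PTGER3", "PTGER4")
MINI_COX_MIRNAS: Tuple[str, ...] = ("mir-101", "mir-199a", "mir-16")

_PROSTAGLANDINS: Tuple[Tuple[str, str], ...] = (
    ("PGE2", "PTGES"), ("PGI2", "PTGIS"), ("PGD2", "PTGDS"),
    ("PGF2", "PTGFS"), ("TXA2", "TBXAS1"),
)

#: transcription-factor wiring: gene -> list of (modifier id, role)
_TF_WIRING: Dict[str, Tuple[Tuple[str, ModifierRole], ...]] = {
    "BCL2": (("A_NFKB1", ModifierRole.TF_PROMOTE), ("P_PKA", ModifierRole.TF_PROMOTE)),
    "MKI67": (("A_NFKB1", ModifierRole.TF_PROMOTE),),
    "URGCP": (("A_NFKB1", ModifierRole.TF_PROMOTE),),
    "IL8": (("P_PKA", ModifierRole.TF_PROMOTE),),
    "BAX": (("A_NFKB1", ModifierRole.TF_REPRESS),),
}

#: EP receptor binding is weak relative to ligand turnover so that receptor
#: occupancy tracks the PGE2 level instead of being capped by receptor
#: synthesis; realized as per-reaction rate overrides on the cf_EP* laws.
EP_BINDING_K = 0.001

#: frozen component/reaction census of the fixture, checked by tests
MINI_COX_MANIFEST: Dict[str, Dict[str, int]] = {
    "components": {
        "gene": 27, "mRNA": 27, "protein": 33, "compound": 11,
        "complex": 5, "miRNA": 3,
    },
    "reactions": {
        "transcription": 27, "translation": 27, "decay": 72,
        "activation": 12, "phosphorylation": 6, "dephosphorylation": 1,
        "complex_formation": 5, "translocation": 1, "mirna_binding": 3,
    },
}


def build_mini_cox_model() -> NetworkModel:
    """Deterministic construction of the miniature COX-pathway model."""
    components: List[Component] = []
    reactions: List[Reaction] = []

    def comp(cid: str, kind: ComponentKind, **kw) -> str:
        components.append(Component(cid, kind, **kw))
        return cid

    def rxn(rid: str, rtype: ReactionType, subs: Sequence[str] = (),
            prods: Sequence[str] = (), mods: Sequence[Modifier] = ()) -> None:
        reactions.append(Reaction(rid, rtype, tuple(subs), tuple(prods), tuple(mods)))

    # clamped small-molecule pools
    for cid in ("AA", "O2", "EGF", "PP2A"):
        comp(cid, ComponentKind.COMPOUND, clamped=True, fixed_value=1.0)

    # gene -> mRNA -> protein chains
    for g in MINI_COX_GENES:
        comp(f"{g}_gene", ComponentKind.GENE)
        comp(f"{g}_mRNA", ComponentKind.MRNA)
        comp(f"{g}_prot", ComponentKind.PROTEIN)
        tf_mods = tuple(Modifier(cid, role) for cid, role in _TF_WIRING.get(g, ()))
        rxn(f"tx_{g}", ReactionType.TRANSCRIPTION, [f"{g}_gene"], [f"{g}_mRNA"], tf_mods)
        rxn(f"tl_{g}", ReactionType.TRANSLATION, [f"{g}_mRNA"], [f"{g}_prot"])
        rxn(f"dec_{g}_mRNA", ReactionType.DECAY, [f"{g}_mRNA"])
        rxn(f"dec_{g}_prot", ReactionType.DECAY, [f"{g}_prot"])

    # prostaglandin backbone: AA --COX--> PGG2 --COX--> PGH2 --synthase--> PGx
    for cid in ("PGG2", "PGH2", "PGE2", "PGI2", "PGD2", "PGF2", "TXA2"):
        comp(cid, ComponentKind.COMPOUND)
        rxn(f"dec_{cid}", ReactionType.DECAY, [cid])
    for cox in ("PTGS1", "PTGS2"):
        rxn(f"act_PGG2_via_{cox}", ReactionType.ACTIVATION, ["AA"], ["PGG2"],
            [Modifier(f"{cox}_prot", ModifierRole.ENZYME),
             Modifier("O2", ModifierRole.ENZYME)])
        rxn(f"act_PGH2_via_{cox}", ReactionType.ACTIVATION, ["PGG2"], ["PGH2"],
            [Modifier(f"{cox}_prot", ModifierRole.ENZYME)])
    for pg, synthase in _PROSTAGLANDINS:
        rxn(f"act_{pg}", ReactionType.ACTIVATION, ["PGH2"], [pg],
            [Modifier(f"{synthase}_prot", ModifierRole.ENZYME)])

    # PGE2 receptor binding (weak, see EP_BINDING_K)
    ep_overrides: Dict[str, float] = {}
    for ep in EP_GENES:
        cid = comp(f"PGE2_{ep}", ComponentKind.COMPLEX)
        rxn(f"cf_{ep}", ReactionType.COMPLEX_FORMATION,
            ["PGE2", f"{ep}_prot"], [cid])
        ep_overrides[f"cf_{ep}"] = EP_BINDING_K
        rxn(f"dec_PGE2_{ep}", ReactionType.DECAY, [cid])

    # VEGF receptor binding (angiogenesis readout)
    comp("KDR_VEGFA", ComponentKind.COMPLEX)
    rxn("cf_KDR_VEGFA", ReactionType.COMPLEX_FORMATION,
        ["VEGFA_prot", "KDR_prot"], ["KDR_VEGFA"])
    rxn("dec_KDR_VEGFA", ReactionType.DECAY, ["KDR_VEGFA"])

    # growth-factor MAPK cascade and PGE2-gated PKA branch
    for cid in ("P_EGFR", "P_MAPK1", "P_MYC", "A_NFKB1", "P_PKA"):
        comp(cid, ComponentKind.PROTEIN)
        rxn(f"dec_{cid}", ReactionType.DECAY, [cid])
    comp("P_MYC_nuc", ComponentKind.PROTEIN, compartment=Compartment.NUCLEOPLASM)
    rxn("dec_P_MYC_nuc", ReactionType.DECAY, ["P_MYC_nuc"])

    rxn("act_P_EGFR", ReactionType.ACTIVATION, ["EGFR_prot"], ["P_EGFR"],
        [Modifier("EGF", ModifierRole.ENZYME)])
    rxn("ph_MAPK1_via_EGFR", ReactionType.PHOSPHORYLATION,
        ["MAPK1_prot"], ["P_MAPK1"], [Modifier("P_EGFR", ModifierRole.ENZYME)])
    for ep in EP_GENES:
        rxn(f"ph_PKA_via_{ep}", ReactionType.PHOSPHORYLATION,
            ["PRKACA_prot"], ["P_PKA"],
            [Modifier(f"PGE2_{ep}", ModifierRole.ENZYME)])
    rxn("deph_MAPK1", ReactionType.DEPHOSPHORYLATION, ["P_MAPK1"], ["MAPK1_prot"],
        [Modifier("PP2A", ModifierRole.ENZYME)])
    rxn("ph_MYC", ReactionType.PHOSPHORYLATION, ["MYC_prot"], ["P_MYC"],
        [Modifier("P_MAPK1", ModifierRole.ENZYME)])
    rxn("tr_P_MYC", ReactionType.TRANSLOCATION, ["P_MYC"], ["P_MYC_nuc"])

    # NFkB-like arm fed by the cytokines
    for cytokine in ("IL1B", "TNF"):
        rxn(f"act_NFKB_via_{cytokine}", ReactionType.ACTIVATION,
            ["NFKB1_prot"], ["A_NFKB1"],
            [Modifier(f"{cytokine}_prot", ModifierRole.ENZYME)])

    # miRNA repression of COX-2 mRNA
    for mir in MINI_COX_MIRNAS:
        comp(mir, ComponentKind.MIRNA)
        rxn(f"mb_{mir}_PTGS2", ReactionType.MIRNA_BINDING, ["PTGS2_mRNA"], [],
            [Modifier(mir, ModifierRole.MIRNA)])

    hallmarks = [
        HallmarkDefinition(
            HallmarkName.EVADING_APOPTOSIS,
            numerator_terms=(("BCL2_prot", 1.0),),
            denominator_terms=(("BAX_prot", 1.0),),
            denominator_offset=1.0),
        HallmarkDefinition(
            HallmarkName.PROLIFERATION,
            numerator_terms=(("MKI67_prot", 1.0), ("URGCP_prot", 1.0),
                             ("P_MYC_nuc", 1.0))),
        HallmarkDefinition(
            HallmarkName.SUSTAINED_ANGIOGENESIS,
            numerator_terms=(("VEGFA_prot", 1.0), ("KDR_VEGFA", 1.0),
                             ("IL8_prot", 1.0)),
            denominator_offset=1.0),
        HallmarkDefinition(
            HallmarkName.TISSUE_INVASION,
            numerator_terms=(("MMP2_prot", 1.0), ("MMP9_prot", 1.0))),
    ]

    m = NetworkModel.build(components, reactions,
                           RateParameters(overrides=ep_overrides), hallmarks,
                           name="mini-cox")
    diags = validate_model(m)
    if diags:  # construction bug, not user error
        raise FixtureError("mini-COX fixture invalid: " + "; ".join(map(str, diags)))
    return m


def recommended_settings(**overrides) -> SimulationSettings:
    """Simulation settings sized for fixture-scale steady-state runs.

    The enzyme cascades reach total outflow coefficients of order 100 for
    strongly expressed profiles, so the explicit update needs a finer step
    than the generic default to stay well inside its stability region; the
    tight tolerance makes steady-state ratios accurate to ~1e-6.
    """
    kw = dict(step_size=0.01, max_steps=60000, convergence_tol=1e-9)
    kw.update(overrides)
    return SimulationSettings(**kw)


# ---------------------------------------------------------------------------
# random layered models
# ---------------------------------------------------------------------------

@dataclass
class FixtureSpec:
    n_genes: int
    n_pathways: int = 0
    wiring_density: float = 0.5
    seed: int = 0
    include_hallmarks: bool = False
    include_mirnas: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise FixtureError("n_genes must be >= 1")
        if not 0 < self.wiring_density <= 1:
            raise FixtureError("wiring_density must be in (0, 1]")


def generate_random_model(spec: FixtureSpec) -> NetworkModel:
    """Seeded random layered model honoring all arity invariants.

    Base: ``n_genes`` independent gene→mRNA→protein chains with decays.
    ``n_pathways`` activation cascades (random protein substrate, random
    protein enzyme, new active species with decay) are added on top, then
    complex-formation links between random protein pairs at
    ``wiring_density``, then ``include_mirnas`` miRNA species each
    repressing a random mRNA.  Identical specs yield identical models.
    """
    rng = np.random.default_rng(spec.seed)
    components: List[Component] = []
    reactions: List[Reaction] = []
    proteins: List[str] = []
    mrnas: List[str] = []

    for i in range(spec.n_genes):
        g = f"G{i:03d}"
        components += [
            Component(f"{g}_gene", ComponentKind.GENE),
            Component(f"{g}_mRNA", ComponentKind.MRNA),
            Component(f"{g}_prot", ComponentKind.PROTEIN),
        ]
        reactions += [
            Reaction(f"tx_{g}", ReactionType.TRANSCRIPTION, (f"{g}_gene",), (f"{g}_mRNA",)),
            Reaction(f"tl_{g}", ReactionType.TRANSLATION, (f"{g}_mRNA",), (f"{g}_prot",)),
            Reaction(f"dec_{g}_mRNA", ReactionType.DECAY, (f"{g}_mRNA",)),
            Reaction(f"dec_{g}_prot", ReactionType.DECAY, (f"{g}_prot",)),
        ]
        mrnas.append(f"{g}_mRNA")
        proteins.append(f"{g}_prot")

    for j in range(spec.n_pathways):
        if len(proteins) < 2:
            raise FixtureError("n_pathways needs at least 2 proteins to wire a cascade")
        sub, enz = rng.choice(len(proteins), size=2, replace=False)
        active = f"A{j:03d}"
        components.append(Component(active, ComponentKind.PROTEIN))
        reactions += [
            Reaction(f"act_{active}", ReactionType.ACTIVATION,
                     (proteins[sub],), (active,),
                     (Modifier(proteins[enz], ModifierRole.ENZYME),)),
            Reaction(f"dec_{active}", ReactionType.DECAY, (active,)),
        ]

    n_pairs = 0
    if spec.n_genes >= 2:
        for i in range(spec.n_genes - 1):
            if rng.random() < spec.wiring_density:
                a, b = proteins[i], proteins[i + 1]
                cx = f"CX{n_pairs:03d}"
                components.append(Component(cx, ComponentKind.COMPLEX))
                reactions += [
                    Reaction(f"cf_{cx}", ReactionType.COMPLEX_FORMATION, (a, b), (cx,)),
                    Reaction(f"dec_{cx}", ReactionType.DECAY, (cx,)),
                ]
                n_pairs += 1

    for k in range(spec.include_mirnas):
        mid = f"mir{k:03d}"
        components.append(Component(mid, ComponentKind.MIRNA))
        target = mrnas[int(rng.integers(len(mrnas)))]
        reactions.append(Reaction(f"mb_{mid}", ReactionType.MIRNA_BINDING,
                                  (target,), (), (Modifier(mid, ModifierRole.MIRNA),)))

    hallmarks: List[HallmarkDefinition] = []
    if spec.include_hallmarks:
        pool = list(proteins)
        rng.shuffle(pool)
        quarter = max(1, len(pool) // 4)
        hallmarks = [
            HallmarkDefinition(HallmarkName.EVADING_APOPTOSIS,
                               numerator_terms=tuple((p, 1.0) for p in pool[:quarter]),
                               denominator_terms=tuple((p, 1.0) for p in pool[quarter:2 * quarter]),
                               denominator_offset=1.0),
            HallmarkDefinition(HallmarkName.PROLIFERATION,
                               numerator_terms=tuple((p, 1.0) for p in pool[:quarter])),
            HallmarkDefinition(HallmarkName.SUSTAINED_ANGIOGENESIS,
                               numerator_terms=tuple((p, 1.0) for p in pool[-quarter:]),
                               denominator_offset=1.0),
            HallmarkDefinition(HallmarkName.TISSUE_INVASION,
                               numerator_terms=tuple((p, 1.0) for p in pool[-quarter:])),
        ]

    m = NetworkModel.build(components, reactions, RateParameters(), hallmarks,
                           name=f"random-{spec.seed}")
    diags = validate_model(m)
    if diags:
        raise FixtureError("generated model invalid: " + "; ".join(map(str, diags)))
    return m


# ---------------------------------------------------------------------------
# synthetic expression profiles
# ---------------------------------------------------------------------------

def generate_expression_profiles(m: NetworkModel, n_samples: int, seed: int = 0,
                                 scale: str = "linear", low_ep: bool = False,
                                 kind: str = "gene") -> List[ExpressionTable]:
    """Seeded synthetic expression tables for the model's genes (or miRNAs).

    Linear-scale values are log-normal(μ=0, σ=1) truncated at ±2σ (keeping
    the explicit flux-propagation update comfortably stable for any
    sample); log-ratio values are the corresponding base-2 logs.  With
    ``low_ep`` the EP1–4 receptor genes are forced two orders of magnitude
    below the smallest other value, emulating cell lines whose PGE₂
    receptors are barely expressed.
    """
    if kind == "gene":
        ids = [c.id for c in m.components_of_kind(ComponentKind.GENE)]
        namespace = "ensembl"
    elif kind == "mirna":
        ids = [c.id for c in m.components_of_kind(ComponentKind.MIRNA)]
        namespace = "mirbase"
    else:
        raise ValueError(f"unknown profile kind {kind!r}")
    if not ids:
        raise FixtureError(f"model has no {kind} components to profile")

    rng = np.random.default_rng(seed)
    ep_ids = {f"{g}_gene" for g in EP_GENES}
    tables: List[ExpressionTable] = []
    for _ in range(n_samples):
        z = np.clip(rng.normal(0.0, 1.0, size=len(ids)), -2.0, 2.0)
        linear = dict(zip(ids, np.exp(z)))
        if low_ep and kind == "gene":
            others = [v for cid, v in linear.items() if cid not in ep_ids]
            floor = 0.01 * min(others) if others else 0.01
            for cid in ep_ids & set(linear):
                linear[cid] = floor
        if scale == "linear":
            tables.append(ExpressionTable(linear, "linear", namespace))
        elif scale == "log_ratio":
            tables.append(ExpressionTable(
                {cid: float(np.log2(v)) for cid, v in linear.items()},
                "log_ratio", namespace))
        else:
            raise ValueError(f"unknown scale {scale!r}")
    return tables
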