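"""Model and expression-table I/O plus expression-based initialization.

Two on-disk model dialects are supported:

* a versioned XML schema (``<coxflux-model version="1">``) holding
  parameters, typed components, typed reactions with modifier roles, and
  hallmark definitions;
* a three-file tabular dialect (``components.tsv``, ``reactions.tsv``,
  ``hallmarks.tsv``, optional ``parameters.tsv``) that is diff-friendly.

Expression tables are TSV with an ``id<TAB>value`` header.  Microarray-style
log-ratio tables must be exponentiated (:func:`linearize`) before
initialization because negative values are not meaningful concentrations
for flux propagation.
"""

from __future__ import annotations

import logging
import math
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Tuple

import pandas as pd
from lxml import etree

from .model import (
    CLAMPABLE_KINDS,
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

log = logging.getLogger(__name__)

MODEL_XML_VERSION = "1"


class ModelFormatError(Exception):
    """The on-disk model could not be parsed into a valid network model."""


# ---------------------------------------------------------------------------
# expression tables
# ---------------------------------------------------------------------------

@dataclass
class ExpressionTable:
    """id -> expression value, with an explicit scale."""

    values: Dict[str, float]
    scale: str = "linear"            # "linear" | "log_ratio"
    id_namespace: str = "ensembl"    # "ensembl" | "mirbase"

    def __post_init__(self) -> None:
        if self.scale not in ("linear", "log_ratio"):
            raise ValueError(f"unknown expression scale {self.scale!r}")


def read_expression_table(path: os.PathLike, scale: str = "linear",
                          id_namespace: str = "ensembl") -> ExpressionTable:
    df = pd.read_csv(path, sep="\t")
    if list(df.columns[:2]) != ["id", "value"]:
        raise ModelFormatError(
            f"{path}: expression tables need an 'id<TAB>value' header, got {list(df.columns)}")
    ids = df["id"].astype(str)
    if ids.duplicated().any():
        dup = ids[ids.duplicated()].iloc[0]
        raise ModelFormatError(f"{path}: duplicate identifier {dup!r}")
    return ExpressionTable(dict(zip(ids, df["value"].astype(float))),
                           scale=scale, id_namespace=id_namespace)


def write_expression_table(t: ExpressionTable, path: os.PathLike) -> None:
    pd.DataFrame({"id": list(t.values), "value": list(t.values.values())}) \
        .to_csv(path, sep="\t", index=False)


def linearize(t: ExpressionTable, base: float = 2.0) -> ExpressionTable:
    """Convert a log-ratio table to linear scale by exponentiation.

    Negative log-ratios are not usable as initial concentrations, so each
    value x becomes ``base**x`` (default base 2).  Linear tables pass
    through unchanged.
    """
    if t.scale == "linear":
        return ExpressionTable(dict(t.values), "linear", t.id_namespace)
    out = {}
    for cid, x in t.values.items():
        if not math.isfinite(x):
            raise ValueError(f"non-finite expression value for {cid!r}")
        out[cid] = float(base) ** x
    return ExpressionTable(out, "linear", t.id_namespace)


# ---------------------------------------------------------------------------
# state vectors
# ---------------------------------------------------------------------------

@dataclass
class StateVector:
    """Concentration per component (arbitrary units) at a simulation step."""

    values: Dict[str, float]
    step: int = 0

    def __getitem__(self, cid: str) -> float:
        return self.values[cid]

    def __contains__(self, cid: str) -> bool:
        return cid in self.values

    def get(self, cid: str, default: float = 0.0) -> float:
        return self.values.get(cid, default)

    def copy(self) -> "StateVector":
        return StateVector(dict(self.values), self.step)

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, name="concentration")


def initialize(m: NetworkModel, genes: Optional[ExpressionTable] = None,
               mirnas: Optional[ExpressionTable] = None,
               unmatched_default: float = 0.0) -> StateVector:
    """Build the initial state from expression data.

    Gene components take their expression value (matched by id); miRNA
    components likewise when a miRNA table is given.  Every other species
    (mRNA, protein, complex, pseudo) starts at zero: signal is generated
    only at the transcriptional level and propagates downward.  Clamped
    species and species carrying a declared ``fixed_value`` are pinned to
    that value (clamped compounds default to 1.0).  Unmatched genes/miRNAs
    get ``unmatched_default`` and are reported via logging.
    """
    if genes is not None and genes.scale != "linear":
        raise ValueError("gene expression table must be linear scale; apply linearize() first")
    if mirnas is not None and mirnas.scale != "linear":
        raise ValueError("miRNA expression table must be linear scale; apply linearize() first")

    values: Dict[str, float] = {}
    unmatched: List[str] = []
    for c in m.components.values():
        if c.fixed_value is not None:
            values[c.id] = float(c.fixed_value)
        elif c.clamped:
            values[c.id] = 1.0
        elif c.kind == ComponentKind.GENE:
            table = genes.values if genes is not None else {}
            if c.id in table:
                values[c.id] = float(table[c.id])
            else:
                values[c.id] = unmatched_default
                unmatched.append(c.id)
        elif c.kind == ComponentKind.MIRNA:
            table = mirnas.values if mirnas is not None else {}
            if c.id in table:
                values[c.id] = float(table[c.id])
            else:
                values[c.id] = unmatched_default
                if mirnas is not None:
                    unmatched.append(c.id)
        else:
            values[c.id] = 0.0
    if unmatched:
        log.warning("%d component(s) without expression data set to %g: %s",
                    len(unmatched), unmatched_default,
                    ", ".join(unmatched[:8]) + ("..." if len(unmatched) > 8 else ""))
    return StateVector(values, step=0)


# ---------------------------------------------------------------------------
# XML dialect
# ---------------------------------------------------------------------------

def _model_to_xml(m: NetworkModel) -> etree._Element:
    root = etree.Element("coxflux-model", version=MODEL_XML_VERSION, name=m.name)
    params = etree.SubElement(root, "parameters")
    for kname, kval in m.params.constants().items():
        params.set(kname, repr(kval))
    for rid, kval in sorted(m.params.overrides.items()):
        etree.SubElement(params, "override", reaction=rid, value=repr(kval))
    comps = etree.SubElement(root, "components")
    for c in m.components.values():
        el = etree.SubElement(comps, "component", id=c.id, kind=c.kind.value,
                              compartment=c.compartment.value)
        if c.clamped:
            el.set("clamped", "true")
        if c.fixed_value is not None:
            el.set("fixed-value", repr(c.fixed_value))
    rxns = etree.SubElement(root, "reactions")
    for r in m.reactions.values():
        el = etree.SubElement(rxns, "reaction", id=r.id, type=r.rtype.value)
        for cid in r.substrates:
            etree.SubElement(el, "substrate", ref=cid)
        for cid in r.products:
            etree.SubElement(el, "product", ref=cid)
        for mod in r.modifiers:
            etree.SubElement(el, "modifier", ref=mod.component_id, role=mod.role.value)
    hms = etree.SubElement(root, "hallmarks")
    for hd in m.hallmark_definitions:
        el = etree.SubElement(hms, "hallmark", name=hd.name.value)
        el.set("denominator-offset", repr(hd.denominator_offset))
        for cid, coef in hd.numerator_terms:
            etree.SubElement(el, "numerator", ref=cid, coefficient=repr(coef))
        for cid, coef in hd.denominator_terms:
            etree.SubElement(el, "denominator", ref=cid, coefficient=repr(coef))
    return root


def _enum_lookup(enum_cls, raw: str, what: str, el) -> object:
    try:
        return enum_cls(raw)
    except ValueError:
        line = getattr(el, "sourceline", "?")
        raise ModelFormatError(
            f"line {line}: unknown {what} {raw!r} "
            f"(expected one of {[e.value for e in enum_cls]})")


def _model_from_xml(root: etree._Element, path: str) -> NetworkModel:
    if root.tag != "coxflux-model":
        raise ModelFormatError(f"{path}: root element is <{root.tag}>, expected <coxflux-model>")
    if root.get("version") != MODEL_XML_VERSION:
        raise ModelFormatError(f"{path}: unsupported model schema version {root.get('version')!r}")
    params = RateParameters()
    pel = root.find("parameters")
    if pel is not None:
        for kname in params.constants():
            if pel.get(kname) is not None:
                setattr(params, kname, float(pel.get(kname)))
        for ov in pel.findall("override"):
            params.overrides[ov.get("reaction")] = float(ov.get("value"))
    components = []
    for el in root.findall("components/component"):
        components.append(Component(
            id=el.get("id"),
            kind=_enum_lookup(ComponentKind, el.get("kind"), "component kind", el),
            compartment=_enum_lookup(Compartment, el.get("compartment", "default"),
                                     "compartment", el),
            clamped=el.get("clamped", "false") == "true",
            fixed_value=float(el.get("fixed-value")) if el.get("fixed-value") else None,
        ))
    reactions = []
    for el in root.findall("reactions/reaction"):
        reactions.append(Reaction(
            id=el.get("id"),
            rtype=_enum_lookup(ReactionType, el.get("type"), "reaction type", el),
            substrates=tuple(s.get("ref") for s in el.findall("substrate")),
            products=tuple(s.get("ref") for s in el.findall("product")),
            modifiers=tuple(Modifier(s.get("ref"),
                                     _enum_lookup(ModifierRole, s.get("role"), "modifier role", s))
                            for s in el.findall("modifier")),
        ))
    hallmarks = []
    for el in root.findall("hallmarks/hallmark"):
        hallmarks.append(HallmarkDefinition(
            name=_enum_lookup(HallmarkName, el.get("name"), "hallmark", el),
            numerator_terms=tuple((t.get("ref"), float(t.get("coefficient", "1")))
                                  for t in el.findall("numerator")),
            denominator_terms=tuple((t.get("ref"), float(t.get("coefficient", "1")))
                                    for t in el.findall("denominator")),
            denominator_offset=float(el.get("denominator-offset", "0")),
        ))
    return NetworkModel.build(components, reactions, params, hallmarks,
                              name=root.get("name", "model"))


# ---------------------------------------------------------------------------
# tabular dialect
# ---------------------------------------------------------------------------

_COMPONENT_COLUMNS = ["id", "kind", "compartment", "clamped", "fixed_value"]
_REACTION_COLUMNS = ["id", "type", "substrates", "products", "modifiers", "rate_override"]
_HALLMARK_COLUMNS = ["hallmark", "denominator_offset", "side", "component", "coefficient"]


def _write_tabular(m: NetworkModel, directory: Path) -> None:
    directory.mkdir(parents=True, exist_ok=True)
    comp_rows = [{
        "id": c.id, "kind": c.kind.value, "compartment": c.compartment.value,
        "clamped": int(c.clamped),
        "fixed_value": "" if c.fixed_value is None else repr(c.fixed_value),
    } for c in m.components.values()]
    pd.DataFrame(comp_rows, columns=_COMPONENT_COLUMNS).to_csv(
        directory / "components.tsv", sep="\t", index=False)

    rxn_rows = [{
        "id": r.id, "type": r.rtype.value,
        "substrates": ";".join(r.substrates),
        "products": ";".join(r.products),
        "modifiers": ";".join(f"{mod.component_id}:{mod.role.value}" for mod in r.modifiers),
        "rate_override": ("" if r.id not in m.params.overrides
                          else repr(m.params.overrides[r.id])),
    } for r in m.reactions.values()]
    pd.DataFrame(rxn_rows, columns=_REACTION_COLUMNS).to_csv(
        directory / "reactions.tsv", sep="\t", index=False)

    hm_rows = []
    for hd in m.hallmark_definitions:
        for side, terms in (("numerator", hd.numerator_terms),
                            ("denominator", hd.denominator_terms)):
            for cid, coef in terms:
                hm_rows.append({"hallmark": hd.name.value,
                                "denominator_offset": repr(hd.denominator_offset),
                                "side": side, "component": cid, "coefficient": repr(coef)})
        if not hd.numerator_terms and not hd.denominator_terms:
            hm_rows.append({"hallmark": hd.name.value,
                            "denominator_offset": repr(hd.denominator_offset),
                            "side": "numerator", "component": "", "coefficient": "1"})
    pd.DataFrame(hm_rows, columns=_HALLMARK_COLUMNS).to_csv(
        directory / "hallmarks.tsv", sep="\t", index=False)

    prm_rows = [{"parameter": k, "value": repr(v)} for k, v in m.params.constants().items()]
    pd.DataFrame(prm_rows).to_csv(directory / "parameters.tsv", sep="\t", index=False)


def _read_tabular(directory: Path) -> NetworkModel:
    def _load(name: str) -> pd.DataFrame:
        p = directory / name
        if not p.exists():
            raise ModelFormatError(f"{directory}: missing {name}")
        return pd.read_csv(p, sep="\t", dtype=str, keep_default_na=False)

    comp_df = _load("components.tsv")
    components = []
    for _, row in comp_df.iterrows():
        try:
            kind = ComponentKind(row["kind"])
        except ValueError:
            raise ModelFormatError(f"components.tsv: unknown component kind {row['kind']!r}")
        components.append(Component(
            id=row["id"], kind=kind,
            compartment=Compartment(row.get("compartment", "default") or "default"),
            clamped=row.get("clamped", "0") in ("1", "true", "True"),
            fixed_value=float(row["fixed_value"]) if row.get("fixed_value") else None,
        ))

    rxn_df = _load("reactions.tsv")
    reactions = []
    overrides: Dict[str, float] = {}
    for _, row in rxn_df.iterrows():
        try:
            rtype = ReactionType(row["type"])
        except ValueError:
            raise ModelFormatError(f"reactions.tsv: unknown reaction type {row['type']!r}")
        mods = []
        for token in filter(None, row.get("modifiers", "").split(";")):
            cid, _, role = token.rpartition(":")
            try:
                mods.append(Modifier(cid, ModifierRole(role)))
            except ValueError:
                raise ModelFormatError(f"reactions.tsv: unknown modifier role {role!r}")
        reactions.append(Reaction(
            id=row["id"], rtype=rtype,
            substrates=tuple(filter(None, row.get("substrates", "").split(";"))),
            products=tuple(filter(None, row.get("products", "").split(";"))),
            modifiers=tuple(mods),
        ))
        if row.get("rate_override"):
            overrides[row["id"]] = float(row["rate_override"])

    params = RateParameters(overrides=overrides)
    pfile = directory / "parameters.tsv"
    if pfile.exists():
        prm_df = pd.read_csv(pfile, sep="\t", dtype=str)
        for _, row in prm_df.iterrows():
            if row["parameter"] in params.constants():
                setattr(params, row["parameter"], float(row["value"]))

    hallmarks: List[HallmarkDefinition] = []
    hm_df = _load("hallmarks.tsv")
    by_name: Dict[str, Dict] = {}
    for _, row in hm_df.iterrows():
        try:
            name = HallmarkName(row["hallmark"])
        except ValueError:
            raise ModelFormatError(f"hallmarks.tsv: unknown hallmark {row['hallmark']!r}")
        acc = by_name.setdefault(name.value, {
            "name": name, "offset": float(row["denominator_offset"] or 0),
            "num": [], "den": []})
        if row["component"]:
            term = (row["component"], float(row["coefficient"] or 1))
            acc["num" if row["side"] == "numerator" else "den"].append(term)
    for acc in by_name.values():
        hallmarks.append(HallmarkDefinition(
            name=acc["name"], numerator_terms=tuple(acc["num"]),
            denominator_terms=tuple(acc["den"]), denominator_offset=acc["offset"]))

    return NetworkModel.build(components, reactions, params, hallmarks,
                              name=directory.name)


# ---------------------------------------------------------------------------
# entry points
# ---------------------------------------------------------------------------

def _infer_format(path: Path, fmt: Optional[str]) -> str:
    if fmt is not None:
        return fmt
    if path.is_dir():
        return "tabular"
    return "xml"


def read_model(path: os.PathLike, format: Optional[str] = None,
               check: bool = True) -> NetworkModel:
    """Read a model from XML (single file) or the tabular dialect (directory).

    With ``check=True`` the model is validated and any integrity diagnostic
    is raised as :class:`ModelFormatError`.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "xml":
        if not path.exists():
            raise ModelFormatError(f"{path}: no such file")
        try:
            tree = etree.parse(str(path))
        except etree.XMLSyntaxError as exc:
            raise ModelFormatError(f"{path}: XML parse error: {exc}") from exc
        m = _model_from_xml(tree.getroot(), str(path))
    elif fmt == "tabular":
        if not path.is_dir():
            raise ModelFormatError(f"{path}: tabular models are directories")
        m = _read_tabular(path)
    else:
        raise ValueError(f"unknown model format {fmt!r}")
    if check:
        diags = validate_model(m)
        if diags:
            raise ModelFormatError(
                f"{path}: model fails validation: " + "; ".join(str(d) for d in diags[:5]))
    return m


def write_model(m: NetworkModel, path: os.PathLike, format: Optional[str] = None) -> None:
    path = Path(path)
    fmt = format or ("tabular" if path.suffix == "" else "xml")
    if fmt == "xml":
        root = _model_to_xml(m)
        path.parent.mkdir(parents=True, exist_ok=True)
        etree.ElementTree(root).write(str(path), pretty_print=True,
                                      xml_declaration=True, encoding="utf-8")
    elif fmt == "tabular":
        _write_tabular(m, path)
    else:
        raise ValueError(f"unknown model format {fmt!r}")


def write_state(s: StateVector, path: os.PathLike) -> None:
    pd.DataFrame({"component": list(s.values), "concentration": list(s.values.values())}) \
        .to_csv(path, sep="\t", index=False)
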