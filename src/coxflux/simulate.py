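"""Continuous-valued synchronous flux propagation to steady state.

The update discipline is forward-Euler on the mass-action system defined by
the model's rate laws: at each step every reaction rate is evaluated on the
*current* state and all components are updated simultaneously.  Clamped
species never change; negative excursions (possible for the signed
translocation law at coarse steps) are clipped to zero by default, since
negative token counts are meaningless for flux propagation.

The model is compiled once into index arrays and a sparse stoichiometry
matrix so that a step is a handful of vectorized numpy operations; this is
what makes steady-state runs on fixture-scale models (hundreds of species,
tens of thousands of steps) fast enough for interactive use.  There is no
randomness anywhere: identical inputs give bit-identical trajectories.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy import sparse

from .io import StateVector
from .model import (
    ModifierRole,
    NetworkModel,
    ReactionType,
    consumed_ids,
    produced_ids,
)

log = logging.getLogger(__name__)


class SimulationError(Exception):
    pass


@dataclass
class SimulationSettings:
    step_size: float = 0.1
    max_steps: int = 10000
    convergence_tol: float = 1e-6     # relative, per component per step
    negative_clip: bool = True
    record_trajectory: bool = False
    overflow_guard: float = 1e12
    persistence: int = 3              # consecutive quiet steps required

    def __post_init__(self) -> None:
        if self.step_size <= 0 or self.max_steps <= 0 or self.convergence_tol <= 0:
            raise ValueError("step_size, max_steps and convergence_tol must be positive")


@dataclass
class SteadyStateResult:
    state: StateVector
    converged: bool
    steps_used: int
    residual: float
    model: NetworkModel
    trajectory: Optional[np.ndarray] = None      # (steps+1, n_components)
    component_order: Tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# compilation
# ---------------------------------------------------------------------------

def _segments(index_lists: List[List[int]]) -> Tuple[np.ndarray, np.ndarray]:
    """Flatten ragged index lists into (concatenated, segment starts)."""
    flat = np.array([i for lst in index_lists for i in lst], dtype=np.intp)
    starts = np.zeros(len(index_lists), dtype=np.intp)
    pos = 0
    for j, lst in enumerate(index_lists):
        starts[j] = pos
        pos += len(lst)
    return flat, starts


def _seg_product(values: np.ndarray, flat: np.ndarray, starts: np.ndarray) -> np.ndarray:
    if len(starts) == 0:
        return np.empty(0)
    return np.multiply.reduceat(values[flat], starts)


class CompiledModel:
    """Index-array form of a model for vectorized rate evaluation."""

    def __init__(self, m: NetworkModel):
        self.model = m
        self.order: Tuple[str, ...] = tuple(m.components)
        self.index: Dict[str, int] = {cid: i for i, cid in enumerate(self.order)}
        self.clamped = np.array([m.components[cid].clamped for cid in self.order])
        self.rxn_order: Tuple[str, ...] = tuple(m.reactions)

        idx = self.index
        n_rxn = len(self.rxn_order)
        params = m.params

        # per-group scratch
        simple_sub: List[int] = []          # transcription/translation/decay/enzymatic/mirna...
        groups: Dict[str, dict] = {}

        def grp(name: str) -> dict:
            return groups.setdefault(name, {
                "cols": [], "sub": [], "k": [], "ki": [],
                "factors": [], "prom": [], "repr": [], "inhib": [],
                "a": [], "b": [], "k_in": [], "k_out": []})

        for col, rid in enumerate(self.rxn_order):
            r = m.reactions[rid]
            rt = r.rtype
            if rt == ReactionType.TRANSCRIPTION:
                g = grp("tx")
                g["cols"].append(col)
                g["sub"].append(idx[r.substrates[0]])
                g["k"].append(params.primary(r))
                g["prom"].append([idx[c] for c in r.modifier_ids(ModifierRole.TF_PROMOTE)])
                g["repr"].append([idx[c] for c in r.modifier_ids(ModifierRole.TF_REPRESS)])
            elif rt in (ReactionType.TRANSLATION, ReactionType.DECAY):
                g = grp("linear")
                g["cols"].append(col)
                g["sub"].append(idx[r.substrates[0]])
                g["k"].append(params.primary(r))
            elif rt == ReactionType.COMPLEX_FORMATION:
                g = grp("complex")
                g["cols"].append(col)
                g["k"].append(params.primary(r))
                g["factors"].append([idx[c] for c in r.substrates])
            elif rt == ReactionType.TRANSLOCATION:
                g = grp("transloc")
                g["cols"].append(col)
                k_in, k_out = params.translocation_pair(r)
                g["a"].append(idx[r.substrates[0]])
                g["b"].append(idx[r.products[0]])
                g["k_in"].append(k_in)
                g["k_out"].append(k_out)
            elif rt in (ReactionType.PHOSPHORYLATION, ReactionType.DEPHOSPHORYLATION,
                        ReactionType.ACTIVATION):
                g = grp("enzymatic")
                g["cols"].append(col)
                g["sub"].append(idx[r.substrates[0]])
                g["k"].append(params.primary(r))
                g["ki"].append(params.inhibition(r))
                g["factors"].append([idx[c] for c in r.modifier_ids(ModifierRole.ENZYME)])
                g["inhib"].append([idx[c] for c in r.modifier_ids(ModifierRole.INHIBITOR)])
            elif rt == ReactionType.MIRNA_BINDING:
                g = grp("mirna")
                g["cols"].append(col)
                g["sub"].append(idx[r.substrates[0]])
                g["k"].append(params.primary(r))
                g["factors"].append([idx[c] for c in r.modifier_ids(ModifierRole.MIRNA)])

        self.groups: Dict[str, dict] = {}
        for name, g in groups.items():
            cg: dict = {"cols": np.array(g["cols"], dtype=np.intp)}
            if g["sub"]:
                cg["sub"] = np.array(g["sub"], dtype=np.intp)
            if g["k"]:
                cg["k"] = np.array(g["k"])
            if g["ki"]:
                cg["ki"] = np.array(g["ki"])
            if name == "tx":
                cg["prom"] = _segments(g["prom"])
                cg["repr"] = _segments(g["repr"])
                cg["prom_counts"] = np.array([len(x) for x in g["prom"]])
                cg["repr_counts"] = np.array([len(x) for x in g["repr"]])
            if name in ("complex", "enzymatic", "mirna"):
                cg["factors"] = _segments(g["factors"])
                cg["factor_counts"] = np.array([len(x) for x in g["factors"]])
            if name == "enzymatic":
                cg["inhib"] = _segments(g["inhib"])
                cg["inhib_counts"] = np.array([len(x) for x in g["inhib"]])
            if name == "transloc":
                cg["a"] = np.array(g["a"], dtype=np.intp)
                cg["b"] = np.array(g["b"], dtype=np.intp)
                cg["k_in"] = np.array(g["k_in"])
                cg["k_out"] = np.array(g["k_out"])
            self.groups[name] = cg

        # stoichiometry: net change per component per reaction firing,
        # with clamped rows zeroed so clamped species never move.
        rows, cols, data = [], [], []
        for col, rid in enumerate(self.rxn_order):
            r = m.reactions[rid]
            for cid in consumed_ids(r):
                if not m.components[cid].clamped:
                    rows.append(idx[cid]); cols.append(col); data.append(-1.0)
            for cid in produced_ids(r):
                if not m.components[cid].clamped:
                    rows.append(idx[cid]); cols.append(col); data.append(1.0)
        self.stoich = sparse.csr_matrix(
            (data, (rows, cols)), shape=(len(self.order), n_rxn))
        self.n_reactions = n_rxn

    # -- rate evaluation ----------------------------------------------------

    def rates(self, s: np.ndarray) -> np.ndarray:
        v = np.zeros(self.n_reactions)
        g = self.groups.get("linear")
        if g is not None:
            v[g["cols"]] = s[g["sub"]] * g["k"]
        g = self.groups.get("tx")
        if g is not None:
            base = s[g["sub"]] * g["k"]
            prom = np.zeros(len(g["cols"]))
            mask = g["prom_counts"] > 0
            if mask.any():
                flat, starts = g["prom"]
                sums = np.add.reduceat(s[flat], starts[mask]) if flat.size else prom[mask]
                prom[mask] = sums
            repr_ = np.zeros(len(g["cols"]))
            mask = g["repr_counts"] > 0
            if mask.any():
                flat, starts = g["repr"]
                repr_[mask] = np.add.reduceat(s[flat], starts[mask])
            v[g["cols"]] = base * (1.0 + prom) / (1.0 + repr_)
        g = self.groups.get("complex")
        if g is not None:
            flat, starts = g["factors"]
            v[g["cols"]] = g["k"] * _seg_product(s, flat, starts)
        g = self.groups.get("enzymatic")
        if g is not None:
            base = s[g["sub"]] * g["k"]
            enz = np.ones(len(g["cols"]))
            mask = g["factor_counts"] > 0
            if mask.any():
                flat, starts = g["factors"]
                enz[mask] = np.multiply.reduceat(s[flat], starts[mask])
            inhib = np.zeros(len(g["cols"]))
            mask = g["inhib_counts"] > 0
            if mask.any():
                flat, starts = g["inhib"]
                inhib[mask] = np.add.reduceat(s[flat], starts[mask])
            v[g["cols"]] = base * enz / (1.0 + g["ki"] * inhib)
        g = self.groups.get("mirna")
        if g is not None:
            flat, starts = g["factors"]
            v[g["cols"]] = s[g["sub"]] * g["k"] * _seg_product(s, flat, starts)
        g = self.groups.get("transloc")
        if g is not None:
            v[g["cols"]] = s[g["a"]] * g["k_in"] - s[g["b"]] * g["k_out"]
        return v

    def state_to_array(self, s: StateVector) -> np.ndarray:
        missing = [cid for cid in self.order if cid not in s.values]
        if missing:
            raise SimulationError(f"state lacks component(s): {missing[:5]}")
        return np.array([s.values[cid] for cid in self.order])

    def array_to_state(self, arr: np.ndarray, step: int) -> StateVector:
        return StateVector({cid: float(x) for cid, x in zip(self.order, arr)}, step)


def compile_model(m: NetworkModel) -> CompiledModel:
    """Compile ``m``, memoizing on the model instance.

    Perturbations return fresh model objects, so the cache is safe as long
    as a model's parameters are not mutated in place after first use.
    """
    cached = getattr(m, "_compiled", None)
    if cached is None:
        cached = CompiledModel(m)
        m._compiled = cached   # type: ignore[attr-defined]
    return cached


def _check_rates_finite(cm: CompiledModel, v: np.ndarray) -> None:
    if not np.all(np.isfinite(v)):
        bad = int(np.flatnonzero(~np.isfinite(v))[0])
        raise SimulationError(f"non-finite rate in reaction {cm.rxn_order[bad]!r}")


def _warn_if_stiff(m: NetworkModel, settings: SimulationSettings) -> None:
    kmax = max(m.params.constants().values())
    if m.params.overrides:
        kmax = max(kmax, max(m.params.overrides.values()))
    if settings.step_size * kmax >= 1.0:
        warnings.warn(
            f"step_size {settings.step_size} times largest rate constant {kmax} "
            "is >= 1; the explicit update may be unstable", stacklevel=3)


def step(m: NetworkModel, s: StateVector,
         settings: Optional[SimulationSettings] = None) -> StateVector:
    """One synchronous update of every component."""
    settings = settings or SimulationSettings()
    cm = compile_model(m)
    arr = cm.state_to_array(s)
    v = cm.rates(arr)
    _check_rates_finite(cm, v)
    new = arr + settings.step_size * (cm.stoich @ v)
    if settings.negative_clip:
        np.maximum(new, 0.0, out=new)
        new[cm.clamped] = arr[cm.clamped]
    return cm.array_to_state(new, s.step + 1)


def run_to_steady_state(m: NetworkModel, s0: StateVector,
                        settings: Optional[SimulationSettings] = None) -> SteadyStateResult:
    """Iterate the synchronous update until concentrations settle.

    Convergence requires the maximum relative per-step change over all
    unclamped components to stay below ``convergence_tol`` for
    ``persistence`` consecutive steps (robust against slow oscillatory
    transients).  Divergence past ``overflow_guard`` raises with the
    runaway component named.
    """
    settings = settings or SimulationSettings()
    _warn_if_stiff(m, settings)
    cm = compile_model(m)
    arr = cm.state_to_array(s0)
    unclamped = ~cm.clamped
    dt = settings.step_size
    quiet = 0
    residual = np.inf
    traj = [arr.copy()] if settings.record_trajectory else None

    n = 0
    for n in range(1, settings.max_steps + 1):
        v = cm.rates(arr)
        _check_rates_finite(cm, v)
        new = arr + dt * (cm.stoich @ v)
        if settings.negative_clip:
            np.maximum(new, 0.0, out=new)
        new[cm.clamped] = arr[cm.clamped]
        delta = np.abs(new - arr)[unclamped]
        scale = np.maximum(np.abs(arr)[unclamped], 1e-12)
        residual = float((delta / scale).max()) if delta.size else 0.0
        arr = new
        if traj is not None:
            traj.append(arr.copy())
        peak = float(np.abs(arr).max()) if arr.size else 0.0
        if peak > settings.overflow_guard:
            runaway = cm.order[int(np.abs(arr).argmax())]
            raise SimulationError(
                f"simulation diverged: component {runaway!r} exceeded "
                f"{settings.overflow_guard:g} at step {n}")
        quiet = quiet + 1 if residual <= settings.convergence_tol else 0
        if quiet >= settings.persistence:
            break

    converged = quiet >= settings.persistence
    if not converged:
        log.warning("steady state not reached in %d steps (residual %.3g)",
                    n, residual)
    return SteadyStateResult(
        state=cm.array_to_state(arr, s0.step + n),
        converged=converged, steps_used=n, residual=residual, model=m,
        trajectory=np.array(traj) if traj is not None else None,
        component_order=cm.order)


def write_trajectory(result: SteadyStateResult, path) -> None:
    """Dump a recorded trajectory as TSV (one row per step, one column per
    component); requires ``record_trajectory=True`` on the run."""
    import pandas as pd

    if result.trajectory is None:
        raise ValueError("run was not recorded; set record_trajectory=True")
    df = pd.DataFrame(result.trajectory, columns=list(result.component_order))
    df.insert(0, "step", range(len(df)))
    df.to_csv(path, sep="\t", index=False)
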