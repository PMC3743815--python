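"""Cancer-hallmark readouts and Flux-Comparative Analysis (FCA).

FCA compares the steady state of a perturbed model run against the steady
state of a control run of the same model under identical initialization:
each component gets the ratio perturbed/control, and the four hallmark
pseudo-readouts (evading apoptosis, proliferation, sustained angiogenesis,
tissue invasion) are evaluated on both states and compared the same way.
Ratios are kept at full precision internally; rounding (2 decimals by
default) happens only when writing tables.

Components at exactly zero concentration in the control state get no ratio
(a dead subnetwork has no meaningful fold change); they are collected in
``undefined_set`` instead.
"""

from __future__ import annotations

import logging
import math
import os
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set

import pandas as pd

from .io import StateVector
from .model import HallmarkDefinition, HallmarkName
from .simulate import SteadyStateResult

log = logging.getLogger(__name__)


class FcaError(Exception):
    pass


@dataclass
class FcaResult:
    ratios: Dict[str, float]
    hallmark_ratios: Dict[HallmarkName, float]
    undefined_set: Set[str]
    control: StateVector
    perturbed: StateVector
    hallmark_control: Dict[HallmarkName, float] = field(default_factory=dict)
    hallmark_perturbed: Dict[HallmarkName, float] = field(default_factory=dict)


def evaluate_hallmark(d: HallmarkDefinition, s: Mapping[str, float] | StateVector) -> float:
    """Value of one hallmark readout on a state.

    ``sum(coef*conc)`` over the numerator divided by
    ``denominator_offset + sum(coef*conc)`` over the denominator; a sum
    hallmark (no denominator terms, offset 0) divides by 1.  Ids missing
    from the state resolve to 0 with a warning.
    """
    values = s.values if isinstance(s, StateVector) else s

    def term_sum(terms) -> float:
        total = 0.0
        for cid, coef in terms:
            if cid not in values:
                log.warning("hallmark %s references missing component %r (treated as 0)",
                            d.name.value, cid)
                continue
            total += coef * values[cid]
        return total

    num = term_sum(d.numerator_terms)
    if not d.denominator_terms and d.denominator_offset == 0:
        return num
    den = d.denominator_offset + term_sum(d.denominator_terms)
    if den == 0:
        raise FcaError(f"hallmark {d.name.value}: zero denominator with zero offset")
    return num / den


def fca(control: SteadyStateResult, perturbed: SteadyStateResult,
        readouts: Optional[Sequence[str]] = None,
        zero_tol: float = 1e-12) -> FcaResult:
    """Per-component and per-hallmark perturbation/control ratios.

    Both runs must come from the same component universe; non-converged
    inputs are accepted with a warning.  ``readouts`` restricts the
    per-component table to a subset of ids (hallmarks are always computed
    from the control model's hallmark definitions).
    """
    missing = set(control.state.values) - set(perturbed.state.values)
    if missing:
        raise FcaError(f"perturbation state lacks control components: {sorted(missing)[:5]}")
    extra = set(perturbed.state.values) - set(control.state.values)
    if extra:
        # intervention bookkeeping species (e.g. the added siRNA) carry no
        # control baseline and are excluded from the comparison
        log.debug("ignoring %d perturbation-only component(s): %s",
                  len(extra), sorted(extra)[:5])
    for name, res in (("control", control), ("perturbation", perturbed)):
        if not res.converged:
            log.warning("%s state did not converge (residual %.3g); FCA may be unreliable",
                        name, res.residual)

    ids = list(readouts) if readouts is not None else list(control.state.values)
    unknown = [cid for cid in ids if cid not in control.state.values]
    if unknown:
        raise FcaError(f"readout ids not in model: {unknown[:5]}")

    ratios: Dict[str, float] = {}
    undefined: Set[str] = set()
    for cid in ids:
        c = control.state.values[cid]
        p = perturbed.state.values[cid]
        if abs(c) <= zero_tol:
            undefined.add(cid)
        else:
            ratios[cid] = p / c

    hm_control: Dict[HallmarkName, float] = {}
    hm_perturbed: Dict[HallmarkName, float] = {}
    hm_ratio: Dict[HallmarkName, float] = {}
    for hd in control.model.hallmark_definitions:
        hc = evaluate_hallmark(hd, control.state)
        hp = evaluate_hallmark(hd, perturbed.state)
        hm_control[hd.name] = hc
        hm_perturbed[hd.name] = hp
        hm_ratio[hd.name] = hp / hc if abs(hc) > zero_tol else math.nan

    return FcaResult(ratios=ratios, hallmark_ratios=hm_ratio, undefined_set=undefined,
                     control=control.state, perturbed=perturbed.state,
                     hallmark_control=hm_control, hallmark_perturbed=hm_perturbed)


# ---------------------------------------------------------------------------
# presentation
# ---------------------------------------------------------------------------

def fca_table(result: FcaResult, decimals: int = 2) -> pd.DataFrame:
    rows = []
    for cid in result.control.values:
        c = result.control.values[cid]
        p = result.perturbed.values[cid]
        if cid in result.ratios:
            rows.append({"component": cid, "control": c, "perturbed": p,
                         "ratio": round(result.ratios[cid], decimals)})
        elif cid in result.undefined_set:
            rows.append({"component": cid, "control": c, "perturbed": p,
                         "ratio": math.nan})
    return pd.DataFrame(rows, columns=["component", "control", "perturbed", "ratio"])


def hallmark_table(result: FcaResult, decimals: int = 2) -> pd.DataFrame:
    rows = [{"hallmark": name.value,
             "control": result.hallmark_control.get(name, math.nan),
             "perturbed": result.hallmark_perturbed.get(name, math.nan),
             "ratio": round(ratio, decimals) if math.isfinite(ratio) else ratio}
            for name, ratio in result.hallmark_ratios.items()]
    return pd.DataFrame(rows, columns=["hallmark", "control", "perturbed", "ratio"])


def write_fca_tsv(result: FcaResult, path: os.PathLike, decimals: int = 2) -> None:
    fca_table(result, decimals).to_csv(path, sep="\t", index=False)


def write_hallmark_tsv(result: FcaResult, path: os.PathLike, decimals: int = 2) -> None:
    hallmark_table(result, decimals).to_csv(path, sep="\t", index=False)


def plot_fca_heatmap(results: Mapping[str, FcaResult], path: os.PathLike) -> None:
    """Hallmark-ratio heatmap across comparisons (presentation only)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    names = [h.value for h in HallmarkName]
    rows = list(results)
    data = [[results[r].hallmark_ratios.get(HallmarkName(h), math.nan) for h in names]
            for r in rows]
    fig, ax = plt.subplots(figsize=(1.6 * len(names) + 2, 0.6 * len(rows) + 1.5))
    im = ax.imshow(data, cmap="RdYlGn", vmin=0.0, vmax=2.0, aspect="auto")
    ax.set_xticks(range(len(names)), names, rotation=30, ha="right")
    ax.set_yticks(range(len(rows)), rows)
    for i, row in enumerate(data):
        for j, val in enumerate(row):
            if math.isfinite(val):
                ax.text(j, i, f"{val:.2f}", ha="center", va="center", fontsize=8)
    fig.colorbar(im, ax=ax, label="perturbation / control")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
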