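"""Independent reference implementations used only as test oracles.

Everything here is deliberately written from the rate-law table and the
reaction semantics directly, sharing no code path with the package, so
agreement is evidence rather than tautology.
"""

from __future__ import annotations

from itertools import product
from typing import Dict, Mapping

import numpy as np
import sympy
from scipy.integrate import solve_ivp
from scipy.stats import rankdata

from coxflux.model import ModifierRole, NetworkModel, ReactionType


# ---------------------------------------------------------------------------
# symbolic per-reaction rate oracle
# ---------------------------------------------------------------------------

def symbolic_rate(r, state: Mapping[str, float], params) -> float:
    """Evaluate the rate law of ``r`` via sympy expressions built per type."""
    sym = {cid: sympy.Symbol(f"c_{i}") for i, cid in enumerate(state)}
    subs = {sym[cid]: val for cid, val in state.items()}

    def S(cid):
        return sym[cid]

    rt = r.rtype
    if rt == ReactionType.TRANSCRIPTION:
        prom = sum((S(c) for c in r.modifier_ids(ModifierRole.TF_PROMOTE)), sympy.Integer(0))
        repr_ = sum((S(c) for c in r.modifier_ids(ModifierRole.TF_REPRESS)), sympy.Integer(0))
        expr = S(r.substrates[0]) * params.primary(r) * (1 + prom) / (1 + repr_)
    elif rt in (ReactionType.TRANSLATION, ReactionType.DECAY):
        expr = S(r.substrates[0]) * params.primary(r)
    elif rt == ReactionType.COMPLEX_FORMATION:
        expr = sympy.Integer(1) * params.primary(r)
        for c in r.substrates:
            expr *= S(c)
    elif rt == ReactionType.TRANSLOCATION:
        k_in, k_out = params.translocation_pair(r)
        expr = S(r.substrates[0]) * k_in - S(r.products[0]) * k_out
    elif rt in (ReactionType.PHOSPHORYLATION, ReactionType.DEPHOSPHORYLATION,
                ReactionType.ACTIVATION):
        enz = sympy.Integer(1)
        for c in r.modifier_ids(ModifierRole.ENZYME):
            enz *= S(c)
        inhib = sum((S(c) for c in r.modifier_ids(ModifierRole.INHIBITOR)), sympy.Integer(0))
        expr = S(r.substrates[0]) * enz * params.primary(r) / (1 + params.inhibition(r) * inhib)
    elif rt == ReactionType.MIRNA_BINDING:
        expr = S(r.substrates[0]) * params.primary(r)
        for c in r.modifier_ids(ModifierRole.MIRNA):
            expr *= S(c)
    else:  # pragma: no cover
        raise ValueError(rt)
    return float(expr.subs(subs))


# ---------------------------------------------------------------------------
# mass-action ODE oracle
# ---------------------------------------------------------------------------

def ode_steady_state(m: NetworkModel, s0: Mapping[str, float],
                     t_final: float = 2000.0) -> Dict[str, float]:
    """Integrate the mass-action ODE system with a stiff solver.

    The right-hand side is rebuilt here from the reaction list: template
    reactions (transcription/translation) consume nothing, decay and miRNA
    binding are pure sinks, clamped species have zero derivative.
    """
    order = list(m.components)
    index = {cid: i for i, cid in enumerate(order)}
    clamped = np.array([m.components[cid].clamped for cid in order])

    def rhs(_t, y):
        state = {cid: max(val, 0.0) for cid, val in zip(order, y)}
        dy = np.zeros(len(order))
        for r in m.reactions.values():
            v = symbolic_rate_fast(r, state, m.params)
            if r.rtype not in (ReactionType.TRANSCRIPTION, ReactionType.TRANSLATION):
                for cid in r.substrates:
                    dy[index[cid]] -= v
            for cid in r.products:
                dy[index[cid]] += v
        dy[clamped] = 0.0
        return dy

    y0 = np.array([s0[cid] for cid in order])
    sol = solve_ivp(rhs, (0.0, t_final), y0, method="LSODA",
                    rtol=1e-10, atol=1e-12)
    assert sol.success, sol.message
    return dict(zip(order, sol.y[:, -1]))


def symbolic_rate_fast(r, state: Mapping[str, float], params) -> float:
    """Plain-python rate evaluation (kept separate from the package)."""
    rt = r.rtype
    if rt == ReactionType.TRANSCRIPTION:
        prom = sum(state[c] for c in r.modifier_ids(ModifierRole.TF_PROMOTE))
        rep = sum(state[c] for c in r.modifier_ids(ModifierRole.TF_REPRESS))
        return state[r.substrates[0]] * params.primary(r) * (1 + prom) / (1 + rep)
    if rt in (ReactionType.TRANSLATION, ReactionType.DECAY):
        return state[r.substrates[0]] * params.primary(r)
    if rt == ReactionType.COMPLEX_FORMATION:
        v = params.primary(r)
        for c in r.substrates:
            v *= state[c]
        return v
    if rt == ReactionType.TRANSLOCATION:
        k_in, k_out = params.translocation_pair(r)
        return state[r.substrates[0]] * k_in - state[r.products[0]] * k_out
    if rt in (ReactionType.PHOSPHORYLATION, ReactionType.DEPHOSPHORYLATION,
              ReactionType.ACTIVATION):
        v = state[r.substrates[0]] * params.primary(r)
        for c in r.modifier_ids(ModifierRole.ENZYME):
            v *= state[c]
        inhib = sum(state[c] for c in r.modifier_ids(ModifierRole.INHIBITOR))
        return v / (1 + params.inhibition(r) * inhib)
    if rt == ReactionType.MIRNA_BINDING:
        v = state[r.substrates[0]] * params.primary(r)
        for c in r.modifier_ids(ModifierRole.MIRNA):
            v *= state[c]
        return v
    raise ValueError(rt)  # pragma: no cover


# ---------------------------------------------------------------------------
# exhaustive signed-rank oracle
# ---------------------------------------------------------------------------

def wilcoxon_enumeration_p(c, c_prime) -> float:
    """Two-sided signed-rank p by enumerating all sign assignments.

    Zero differences are dropped; |differences| are midranked; under the
    null every sign vector is equally likely and the two-sided p is twice
    the smaller tail of the positive-rank-sum distribution, capped at 1.
    """
    d = np.asarray(c_prime, dtype=float) - np.asarray(c, dtype=float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return 1.0
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    w_values = [np.sum(ranks[list(signs)]) if any(signs) else 0.0
                for signs in product([False, True], repeat=n)]
    w_values = np.array(w_values)
    n_total = len(w_values)
    cdf = np.sum(w_values <= w_obs + 1e-9) / n_total
    sf = np.sum(w_values >= w_obs - 1e-9) / n_total
    return min(1.0, 2.0 * min(cdf, sf))
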