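"""miRNA influence scoring via the Wilcoxon signed-rank statistic.

The influence of a miRNA is measured system-wide: the concentrations of
*all* model components in a control steady state are paired with the same
concentrations in a steady state reached after overexpressing the miRNA,
and a two-sided Wilcoxon signed-rank test is applied to the pairs.  The
score is

    MIS = -log10(p)

so an intervention that moves many components far from their control
values yields a small p and a large score.  The p-value is a heuristic
impact measure here, not a hypothesis test: the pairs are deterministic
model outputs, not a random sample, so no sampling-based inference is
implied.

The signed-rank p-value is computed exactly (shifted-rank-sum distribution
via dynamic programming, midranks for ties) for up to 25 nonzero
differences, and by the normal approximation with tie correction above
that.  Zero differences are dropped before ranking (the classical
convention; model-wide comparisons typically contain large unchanged
subnetworks, and keeping zeros would systematically deflate p).  The Pratt
variant that keeps zeros is available via ``zero_method="pratt"``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import SteadyStateResult

EXACT_LIMIT = 25
_P_FLOOR = 1e-300


class MisError(Exception):
    pass


def _exact_signed_rank_p(ranks: np.ndarray, w_plus: float) -> float:
    """Exact two-sided p for the positive-rank sum given midranks.

    All 2^n sign assignments are equally likely under the null; the
    distribution of W+ over assignments is built by convolution over the
    doubled (hence integer) midranks, and the two-sided p is twice the
    smaller tail, capped at 1.
    """
    scaled = np.rint(2 * ranks).astype(np.int64)
    total = int(scaled.sum())
    # counts[s] = number of sign assignments with doubled rank sum s
    counts = np.zeros(total + 1, dtype=np.float64)
    counts[0] = 1.0
    for r in scaled:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: counts.size - r]
        counts = counts + shifted
    n_assign = 2.0 ** len(ranks)
    w2 = int(np.rint(2 * w_plus))
    cdf = counts[: w2 + 1].sum() / n_assign
    sf = counts[w2:].sum() / n_assign
    return min(1.0, 2.0 * min(cdf, sf))


def _approx_signed_rank_p(d: np.ndarray, ranks: np.ndarray, w_plus: float) -> float:
    """Normal approximation with tie correction (no continuity correction)."""
    n = len(d)
    mu = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var -= (tie_counts ** 3 - tie_counts).sum() / 48.0
    if var <= 0:
        return 1.0
    z = (w_plus - mu) / math.sqrt(var)
    return float(2.0 * stats.norm.sf(abs(z)))


def wilcoxon_signed_rank(c: Sequence[float], c_prime: Sequence[float],
                         zero_method: str = "wilcox",
                         mode: str = "auto") -> float:
    """Two-sided signed-rank p-value for paired vectors.

    ``mode`` is ``"auto"`` (exact up to 25 nonzero differences, normal
    approximation beyond), ``"exact"`` or ``"approx"``.  If every
    difference is zero the test carries no signal and p = 1 is returned.
    """
    c = np.asarray(c, dtype=float)
    c_prime = np.asarray(c_prime, dtype=float)
    if c.shape != c_prime.shape or c.ndim != 1:
        raise MisError("paired vectors must be one-dimensional and equal length")
    if len(c) < 2:
        raise MisError("need at least 2 pairs")
    if zero_method not in ("wilcox", "pratt"):
        raise MisError(f"unknown zero_method {zero_method!r}")

    d = c_prime - c
    if zero_method == "wilcox":
        d = d[d != 0]
    if d.size == 0 or not np.any(d):
        return 1.0

    ranks = stats.rankdata(np.abs(d))
    if zero_method == "pratt":
        # zeros get the lowest ranks but contribute to neither tail
        keep = d != 0
        ranks = ranks[keep]
        d = d[keep]
        if d.size == 0:
            return 1.0
    w_plus = float(ranks[d > 0].sum())

    if mode == "exact" or (mode == "auto" and d.size <= EXACT_LIMIT):
        return _exact_signed_rank_p(ranks, w_plus)
    return _approx_signed_rank_p(d, ranks, w_plus)


@dataclass
class MisResult:
    mirna: str
    p_value: float
    score: float
    n_components: int
    tumor_type_tag: Optional[str] = None


def mis(control: SteadyStateResult, perturbed: SteadyStateResult,
        mirna: str = "", tumor_type_tag: Optional[str] = None,
        zero_method: str = "wilcox", mode: str = "auto") -> MisResult:
    """Influence score of a miRNA-overexpression run against its control.

    The paired vectors are the steady concentrations of all model
    components (component order is irrelevant to the statistic).
    """
    ids = sorted(control.state.values)
    missing = [cid for cid in ids if cid not in perturbed.state.values]
    if missing:
        raise MisError(f"perturbation state lacks control components: {missing[:5]}")
    c = [control.state.values[cid] for cid in ids]
    c_prime = [perturbed.state.values[cid] for cid in ids]
    p = wilcoxon_signed_rank(c, c_prime, zero_method=zero_method, mode=mode)
    score = -math.log10(max(p, _P_FLOOR))
    return MisResult(mirna=mirna, p_value=p, score=score,
                     n_components=len(ids), tumor_type_tag=tumor_type_tag)


def rank_and_average(results: Sequence[MisResult],
                     high_cutoff: float = 20.0,
                     low_cutoff: float = 3.0) -> pd.DataFrame:
    """Group-wise mean influence score per miRNA, ranked descending.

    Results are grouped by ``tumor_type_tag`` (untagged results fall into
    the group ``"all"``).  Scores above ``high_cutoff`` are flagged
    ``high``, below ``low_cutoff`` flagged ``low`` — the narrative cutoffs
    used to call extreme (biomarker-candidate) miRNAs.
    """
    if not results:
        return pd.DataFrame(columns=["mirna", "group", "mean_score", "n", "flag"])
    rows = [{"mirna": r.mirna, "group": r.tumor_type_tag or "all", "score": r.score}
            for r in results]
    df = pd.DataFrame(rows)
    agg = (df.groupby(["group", "mirna"], as_index=False)
             .agg(mean_score=("score", "mean"), n=("score", "size")))
    agg["flag"] = ""
    agg.loc[agg["mean_score"] > high_cutoff, "flag"] = "high"
    agg.loc[agg["mean_score"] < low_cutoff, "flag"] = "low"
    return (agg.sort_values(["group", "mean_score"], ascending=[True, False])
               .reset_index(drop=True)[["mirna", "group", "mean_score", "n", "flag"]])


def read_mirna_targets(path) -> pd.DataFrame:
    """miRNA→target lists as CSV with columns (mirna, target, pubmed)."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise MisError(f"{path}: expected at least (miRNA id, target id) columns")
    df.columns = ["mirna", "target", "pubmed"][: df.shape[1]]
    return df
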