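"""Group-comparison statistics and crosslink-per-collagen normalization.

The comparison protocol is a classical one-way ANOVA across treatment groups
followed by post hoc two-tailed two-sample Student's t-tests (pooled variance)
at α = 0.05, with configurable significance stars. Statistics are computed
directly from sums of squares so each step is testable against textbook values;
only the F and t tail probabilities come from scipy's distribution CDFs. No
multiple-testing correction is applied by default; Holm adjustment is available
behind a flag.

Crosslink biochemistry: total mature pyridinoline crosslinks (PYD + DPD, from
ELISA) are normalized to collagen content estimated from hydroxyproline, using
300 hydroxyprolines per triple helix and a molecular weight of 300 kDa per
triple helix (so 1 nmol of collagen ≡ 300 µg).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist
from scipy.stats import t as t_dist

from .errors import ParameterError

__all__ = [
    "collagen_from_hyp",
    "CrosslinkQuant",
    "crosslink_density",
    "one_way_anova",
    "posthoc_ttests",
    "significance_stars",
    "AnovaResult",
]

HYP_PER_TRIPLE_HELIX = 300.0
COLLAGEN_KDA = 300.0

DEFAULT_STARS = ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*"))


def collagen_from_hyp(hyp_nmol: float) -> tuple[float, float]:
    """Collagen (nmol, µg) from hydroxyproline content.

    nmol = Hyp/300; µg = nmol × 300 (1 nmol × 300 kDa = 300 µg).
    """
    if hyp_nmol < 0:
        raise ParameterError("hydroxyproline amount must be ≥ 0")
    collagen_nmol = hyp_nmol / HYP_PER_TRIPLE_HELIX
    collagen_ug = collagen_nmol * COLLAGEN_KDA
    return collagen_nmol, collagen_ug


@dataclass
class CrosslinkQuant:
    """Mature pyridinium crosslinks (PYD + DPD) and collagen content for one sample."""

    pyd_dpd_nmol: float
    hyp_nmol: float

    def __post_init__(self):
        if self.pyd_dpd_nmol < 0 or self.hyp_nmol < 0:
            raise ParameterError("amounts must be ≥ 0")

    @property
    def collagen_nmol(self) -> float:
        return collagen_from_hyp(self.hyp_nmol)[0]

    @property
    def collagen_ug(self) -> float:
        return collagen_from_hyp(self.hyp_nmol)[1]


def crosslink_density(q: CrosslinkQuant) -> float:
    """Crosslinks per collagen triple helix (mol/mol); NaN (flagged) when Hyp is zero."""
    if q.hyp_nmol == 0:
        warnings.warn("crosslink density undefined: zero hydroxyproline")
        return float("nan")
    return q.pyd_dpd_nmol / q.collagen_nmol


def _group_values(table: pd.DataFrame, metric: str) -> dict[str, np.ndarray]:
    sub = table[table["metric"] == metric]
    groups = {g: np.asarray(v["value"], dtype=float)
              for g, v in sub.groupby("group", sort=False)}
    if len(groups) < 2:
        raise ParameterError(f"metric {metric!r} needs ≥ 2 groups")
    for g, v in groups.items():
        if len(v) < 2:
            raise ParameterError(f"group {g!r} has fewer than 2 samples")
        if not np.all(np.isfinite(v)):
            raise ParameterError(f"group {g!r} contains non-finite values")
    return groups


@dataclass
class AnovaResult:
    f_stat: float
    p_value: float
    df_between: int
    df_within: int


def one_way_anova(table: pd.DataFrame, metric: str) -> AnovaResult:
    """Classical one-way ANOVA from sums of squares.

    ``table`` has columns ``sample_id, group, metric, value`` (one row per
    sample per metric). F = MS_between / MS_within on (k−1, N−k) degrees of
    freedom; with zero within- and between-group variance F is 0 and p is 1.
    """
    groups = _group_values(table, metric)
    all_vals = np.concatenate(list(groups.values()))
    grand = all_vals.mean()
    ss_between = sum(len(v) * (v.mean() - grand) ** 2 for v in groups.values())
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in groups.values())
    df_b = len(groups) - 1
    df_w = len(all_vals) - len(groups)
    ms_b = ss_between / df_b
    ms_w = ss_within / df_w
    if ms_w == 0:
        f_stat = 0.0 if ms_b == 0 else float("inf")
        p = 1.0 if ms_b == 0 else 0.0
    else:
        f_stat = ms_b / ms_w
        p = float(f_dist.sf(f_stat, df_b, df_w))
    return AnovaResult(float(f_stat), p, df_b, df_w)


def pooled_ttest(x: np.ndarray, y: np.ndarray) -> tuple[float, float, int, bool]:
    """Two-sample pooled-variance Student's t; returns (t, two-sided p, df, degenerate)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n1, n2 = len(x), len(y)
    df = n1 + n2 - 2
    sp2 = (((x - x.mean()) ** 2).sum() + ((y - y.mean()) ** 2).sum()) / df
    diff = x.mean() - y.mean()
    if sp2 == 0:
        if diff == 0:
            return 0.0, 1.0, df, False
        return float(np.sign(diff) * np.inf), 0.0, df, True
    t = diff / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    p = 2.0 * float(t_dist.sf(abs(t), df))
    return float(t), p, df, False


def significance_stars(p: float, thresholds=DEFAULT_STARS) -> str:
    for thr, stars in sorted(thresholds):
        if p < thr:
            return stars
    return "ns"


def _holm(pvals: list[float]) -> list[float]:
    order = np.argsort(pvals)
    m = len(pvals)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * pvals[idx])
        adj[idx] = min(running, 1.0)
    return adj.tolist()


def posthoc_ttests(table: pd.DataFrame, metric: str, alpha: float = 0.05,
                   star_thresholds=DEFAULT_STARS,
                   holm: bool = False) -> pd.DataFrame:
    """All pairwise Student's t-tests for one metric.

    Returns a DataFrame with one row per group pair: t, df, p, significance flag
    at ``alpha``, star annotation, and a ``degenerate`` flag for the
    zero-pooled-variance / unequal-means case. Holm step-down adjustment is
    optional and off by default.
    """
    groups = _group_values(table, metric)
    rows = []
    for g1, g2 in itertools.combinations(groups, 2):
        t, p, df, degen = pooled_ttest(groups[g1], groups[g2])
        rows.append({"metric": metric, "group1": g1, "group2": g2,
                     "t": t, "df": df, "p": p, "degenerate": degen})
    out = pd.DataFrame(rows)
    if holm:
        out["p_adj"] = _holm(out["p"].tolist())
        pcol = "p_adj"
    else:
        pcol = "p"
    out["significant"] = out[pcol] < alpha
    out["stars"] = [significance_stars(p, star_thresholds) for p in out[pcol]]
    return out
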