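"""Group-comparison statistics used in the reports.

Two groups -> Mann–Whitney U (two-sided); three or more -> Kruskal–Wallis H
followed by Dunn's pairwise post-hoc test with Holm (default) or Bonferroni
multiplicity adjustment.  Nonparametric throughout, matching how per-sample
morphometric quantities (layer fractions, diameters, densities) are
compared between developmental stages.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["compare_groups", "dunn_test", "density_check"]


def _holm(p: np.ndarray) -> np.ndarray:
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * p[i])
        adj[i] = min(running, 1.0)
    return adj


def dunn_test(groups: dict[str, np.ndarray], p_adjust: str = "holm") -> pd.DataFrame:
    """Dunn's rank-based pairwise comparisons after Kruskal–Wallis.

    z for pair (i, j) uses the pooled mid-ranks with tie correction:
    ``z = (R̄_i − R̄_j) / sqrt((N(N+1)/12 − T) (1/n_i + 1/n_j))`` with
    ``T = Σ(t³ − t) / (12(N − 1))`` over tied-value groups; two-sided normal
    p-values, then Holm or Bonferroni adjustment.
    """
    names = list(groups)
    values = [np.asarray(groups[n], dtype=float) for n in names]
    pooled = np.concatenate(values)
    N = len(pooled)
    ranks = sps.rankdata(pooled)
    _, tie_counts = np.unique(pooled, return_counts=True)
    T = float(((tie_counts**3 - tie_counts).sum()) / (12.0 * (N - 1))) if N > 1 else 0.0

    mean_ranks = {}
    start = 0
    for n, v in zip(names, values):
        mean_ranks[n] = ranks[start : start + len(v)].mean()
        start += len(v)

    rows = []
    var_base = N * (N + 1) / 12.0 - T
    raw = []
    for a, b in combinations(names, 2):
        na, nb = len(groups[a]), len(groups[b])
        se = np.sqrt(var_base * (1.0 / na + 1.0 / nb))
        z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else 0.0
        p = 2.0 * sps.norm.sf(abs(z))
        raw.append(p)
        rows.append({"group_a": a, "group_b": b, "z": z, "p_raw": p})
    raw = np.asarray(raw)
    if p_adjust == "holm":
        adj = _holm(raw)
    elif p_adjust == "bonferroni":
        adj = np.minimum(raw * len(raw), 1.0)
    else:
        raise ValueError(f"unknown p_adjust {p_adjust!r}; use 'holm' or 'bonferroni'")
    for row, pa in zip(rows, adj):
        row["p_adjusted"] = float(pa)
    return pd.DataFrame(rows)


def compare_groups(values_by_group: dict[str, np.ndarray], p_adjust: str = "holm") -> dict:
    """Nonparametric comparison report for two or more groups.

    Returns a dict with per-group n and median, the omnibus test name,
    statistic and p-value, and (for >= 3 groups) Dunn's pairwise table.
    For two groups the Mann–Whitney U reported is ``min(U1, U2)``, the
    classic tabled statistic (0 for complete separation).
    """
    names = list(values_by_group)
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    for n in names:
        if len(np.asarray(values_by_group[n])) < 2:
            raise ValueError(f"group {n!r} has fewer than 2 values")
    report: dict = {
        "groups": {
            n: {"n": int(len(values_by_group[n])), "median": float(np.median(values_by_group[n]))}
            for n in names
        }
    }
    if len(names) == 2:
        a, b = (np.asarray(values_by_group[n], dtype=float) for n in names)
        res = sps.mannwhitneyu(a, b, alternative="two-sided")
        u1 = float(res.statistic)
        u2 = len(a) * len(b) - u1
        report.update(test="mann-whitney", U=min(u1, u2), p_value=float(res.pvalue))
    else:
        res = sps.kruskal(*[np.asarray(values_by_group[n], dtype=float) for n in names])
        report.update(test="kruskal-wallis", H=float(res.statistic), p_value=float(res.pvalue))
        report["posthoc"] = dunn_test(values_by_group, p_adjust=p_adjust)
    return report


def density_check(counts_by_class: dict[str, int], region_volume_um3: float, unit: float = 1e5) -> dict[str, float]:
    """Cells per 10⁵ µm³ per class — the simple density sanity check."""
    if region_volume_um3 <= 0:
        raise ValueError("region volume must be > 0")
    return {c: n / region_volume_um3 * unit for c, n in counts_by_class.items()}
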