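"""Rank-based group comparison: Kruskal-Wallis plus Dunn's post-hoc.

Kruskal-Wallis uses pooled mid-ranks with the standard tie correction
and a chi-square approximation by default; an exact permutation p-value
(full enumeration of group assignments) is available for small samples.

The post-hoc is Dunn's rank-based z test, many-to-one against a
reference (control) group, with Bonferroni (default) or Holm adjustment
over the performed comparisons. Note Dunn's, not Dunnett's: the latter
is a parametric procedure and does not follow a rank-based omnibus test.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .imaging_io import atomic_write_bytes

__all__ = [
    "KWResult",
    "DunnComparison",
    "kruskal_wallis",
    "dunn_many_to_one",
    "assign_stars",
    "write_stats_report",
]

ADJUSTMENTS = ("bonferroni", "holm")

# star thresholds, most significant first; strict inequalities
_STAR_LEVELS = [(1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*")]


@dataclass(frozen=True)
class KWResult:
    H: float
    df: int
    p_value: float
    n_total: int


@dataclass(frozen=True)
class DunnComparison:
    group: str
    reference: str
    n_group: int
    n_reference: int
    z: float
    p_raw: float
    p_adjusted: float
    stars: str


def _tie_term(pooled: np.ndarray) -> float:
    """Sum of t^3 - t over tied value groups."""
    _, counts = np.unique(pooled, return_counts=True)
    return float(np.sum(counts.astype(np.float64) ** 3 - counts))


def _h_statistic(ranks: np.ndarray, sizes: Sequence[int], tie_sum: float) -> float:
    n_total = len(ranks)
    h = 0.0
    start = 0
    for n in sizes:
        r = ranks[start : start + n].sum()
        h += r * r / n
        start += n
    h = 12.0 / (n_total * (n_total + 1)) * h - 3.0 * (n_total + 1)
    correction = 1.0 - tie_sum / (n_total**3 - n_total)
    if correction <= 0:
        raise ValueError("all pooled values identical; statistic undefined")
    return h / correction


def kruskal_wallis(
    groups: Sequence[Sequence[float]], p_method: str = "chi2"
) -> KWResult:
    """Tie-corrected Kruskal-Wallis test over ``groups``.

    ``p_method='chi2'`` uses the chi-square approximation with k-1
    degrees of freedom. ``p_method='exact'`` enumerates every assignment
    of the pooled values to groups of the observed sizes (feasible for
    small total n) and reports the exact permutation p-value for the
    same H statistic.
    """
    if len(groups) < 2:
        raise ValueError("kruskal_wallis requires at least 2 groups")
    arrays = [np.asarray(g, dtype=np.float64) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValueError("every group must contain at least one value")
    pooled = np.concatenate(arrays)
    if np.unique(pooled).size < 2:
        raise ValueError("all pooled values identical; statistic undefined")
    sizes = [a.size for a in arrays]
    ranks = sps.rankdata(pooled)  # mid-ranks for ties
    tie_sum = _tie_term(pooled)
    h = _h_statistic(ranks, sizes, tie_sum)
    df = len(groups) - 1

    if p_method == "chi2":
        p = float(sps.chi2.sf(h, df))
    elif p_method == "exact":
        p = _exact_permutation_p(ranks, sizes, tie_sum, h)
    else:
        raise ValueError(f"unknown p_method {p_method!r}")
    return KWResult(H=float(h), df=df, p_value=p, n_total=int(pooled.size))


def _exact_permutation_p(
    ranks: np.ndarray, sizes: Sequence[int], tie_sum: float, h_obs: float
) -> float:
    """Exact p by full enumeration of assignments of the pooled ranks to
    groups of the observed sizes. Only the rank multiset matters, so the
    enumeration runs over index subsets."""
    n_total = len(ranks)
    if n_total > 12:
        raise ValueError("exact enumeration limited to total n <= 12")
    count = 0
    total = 0
    eps = 1e-12

    def recurse(remaining: tuple[int, ...], depth: int, chosen_ranks: list):
        nonlocal count, total
        if depth == len(sizes) - 1:
            arrangement = chosen_ranks + [ranks[list(remaining)]]
            h = _h_statistic(np.concatenate(arrangement), sizes, tie_sum)
            total += 1
            if h >= h_obs - eps:
                count += 1
            return
        for subset in combinations(range(len(remaining)), sizes[depth]):
            picked = [remaining[i] for i in subset]
            rest = tuple(i for j, i in enumerate(remaining) if j not in set(subset))
            recurse(rest, depth + 1, chosen_ranks + [ranks[picked]])

    recurse(tuple(range(n_total)), 0, [])
    return count / total


def dunn_many_to_one(
    groups: Mapping[str, Sequence[float]],
    reference_label: str,
    adjustment: str = "bonferroni",
) -> list[DunnComparison]:
    """Dunn's rank-based z tests of every group against the reference.

    z = (meanrank_i - meanrank_ref) / sqrt(sigma2 * (1/n_i + 1/n_ref))
    with sigma2 = N(N+1)/12 - sum(t^3 - t) / (12 (N - 1)) on pooled
    mid-ranks; two-sided p from the standard normal; adjusted over the
    k-1 comparisons by the configured method.
    """
    if reference_label not in groups:
        raise ValueError(f"reference {reference_label!r} not among groups")
    if len(groups) < 2:
        raise ValueError("dunn_many_to_one requires at least 2 groups")
    if adjustment not in ADJUSTMENTS:
        raise ValueError(
            f"unknown adjustment {adjustment!r}; choose from {ADJUSTMENTS}"
        )
    labels = list(groups)
    arrays = [np.asarray(groups[lbl], dtype=np.float64) for lbl in labels]
    if any(a.size == 0 for a in arrays):
        raise ValueError("every group must contain at least one value")
    pooled = np.concatenate(arrays)
    n_total = pooled.size
    ranks = sps.rankdata(pooled)
    sigma2 = n_total * (n_total + 1) / 12.0 - _tie_term(pooled) / (
        12.0 * (n_total - 1)
    )
    mean_ranks = {}
    start = 0
    for lbl, a in zip(labels, arrays):
        mean_ranks[lbl] = ranks[start : start + a.size].mean()
        start += a.size
    sizes = {lbl: a.size for lbl, a in zip(labels, arrays)}

    others = [lbl for lbl in labels if lbl != reference_label]
    zs, p_raws = [], []
    for lbl in others:
        se = np.sqrt(sigma2 * (1.0 / sizes[lbl] + 1.0 / sizes[reference_label]))
        z = (mean_ranks[lbl] - mean_ranks[reference_label]) / se if se > 0 else 0.0
        zs.append(float(z))
        p_raws.append(float(2.0 * sps.norm.sf(abs(z))))
    p_adj = _adjust(np.array(p_raws), adjustment)

    return [
        DunnComparison(
            group=lbl,
            reference=reference_label,
            n_group=sizes[lbl],
            n_reference=sizes[reference_label],
            z=z,
            p_raw=p,
            p_adjusted=pa,
            stars=assign_stars(pa),
        )
        for lbl, z, p, pa in zip(others, zs, p_raws, p_adj)
    ]


def _adjust(p_raw: np.ndarray, method: str) -> np.ndarray:
    m = len(p_raw)
    if m == 0:
        return p_raw
    if method == "bonferroni":
        return np.minimum(1.0, m * p_raw)
    # holm: step-down
    order = np.argsort(p_raw)
    adj = np.empty_like(p_raw)
    running = 0.0
    for i, idx in enumerate(order):
        running = max(running, (m - i) * p_raw[idx])
        adj[idx] = min(1.0, running)
    return adj


def assign_stars(p_adjusted: float) -> str:
    """Map an adjusted p-value to the conventional star code
    (ns / * / ** / *** / ****), strict thresholds."""
    if not 0.0 <= p_adjusted <= 1.0:
        raise ValueError(f"p-value {p_adjusted} outside [0, 1]")
    for threshold, code in _STAR_LEVELS:
        if p_adjusted < threshold:
            return code
    return "ns"


def write_stats_report(
    kw: KWResult, comparisons: Sequence[DunnComparison], path: str | Path
) -> pd.DataFrame:
    """CSV report: a comment header with the omnibus result, then one row
    per Dunn comparison."""
    df = pd.DataFrame(
        [
            {
                "group": c.group,
                "reference": c.reference,
                "n_group": c.n_group,
                "n_reference": c.n_reference,
                "z": c.z,
                "p_raw": c.p_raw,
                "p_adjusted": c.p_adjusted,
                "stars": c.stars,
            }
            for c in comparisons
        ],
        columns=[
            "group",
            "reference",
            "n_group",
            "n_reference",
            "z",
            "p_raw",
            "p_adjusted",
            "stars",
        ],
    )
    header = (
        f"# kruskal_wallis H={kw.H!r} df={kw.df} p={kw.p_value!r} "
        f"n={kw.n_total}\n"
    )
    atomic_write_bytes(path, (header + df.to_csv(index=False)).encode("utf-8"))
    return df
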