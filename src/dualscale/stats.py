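"""Nonparametric group comparisons: Kruskal-Wallis omnibus followed by
Dunn's pairwise test with Bonferroni correction (two-sided, alpha = 0.05 on
the adjusted p-values)."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["GroupComparison", "kruskal_wallis", "dunn_bonferroni"]

ALPHA = 0.05


@dataclass
class GroupComparison:
    labels: list[str]
    H: float
    p_omnibus: float
    pairs: list[tuple[str, str]]
    z: np.ndarray
    p_raw: np.ndarray
    p_adjusted: np.ndarray
    significant: np.ndarray = field(init=False)

    def __post_init__(self):
        self.significant = self.p_adjusted < ALPHA

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "group_a": [a for a, _ in self.pairs],
            "group_b": [b for _, b in self.pairs],
            "z": self.z,
            "p_raw": self.p_raw,
            "p_adj": self.p_adjusted,
            "significant": self.significant,
        })


def _check_groups(groups):
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    groups = [np.asarray(g, dtype=float) for g in groups]
    for g in groups:
        if g.size == 0:
            raise ValueError("groups must be nonempty")
    return groups


def kruskal_wallis(groups) -> tuple[float, float]:
    """Rank-based H with tie correction; p from chi-square with k-1 df.

    Degenerate input (all values identical across groups) returns (0, 1)
    rather than raising.
    """
    groups = _check_groups(groups)
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    H, p = sps.kruskal(*groups)
    return float(H), float(p)


def dunn_bonferroni(groups, labels=None) -> GroupComparison:
    """Dunn's post hoc test on pooled ranks with tie-corrected variance.

    z_ab = (rbar_a - rbar_b) / sqrt(Vtie * (1/n_a + 1/n_b)) with
    Vtie = N(N+1)/12 - T/(12(N-1)), T = sum(t^3 - t) over tie groups.
    Two-sided p-values are multiplied by k(k-1)/2 and capped at 1.
    """
    groups = _check_groups(groups)
    k = len(groups)
    if labels is None:
        labels = [f"group{i + 1}" for i in range(k)]
    H, p_omni = kruskal_wallis(groups)

    pooled = np.concatenate(groups)
    N = pooled.size
    ranks = sps.rankdata(pooled)
    sizes = [g.size for g in groups]
    bounds = np.cumsum([0] + sizes)
    mean_ranks = [ranks[bounds[i]:bounds[i + 1]].mean() for i in range(k)]

    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts ** 3 - counts)
    var = N * (N + 1) / 12.0
    if N > 1:
        var -= tie_term / (12.0 * (N - 1))

    pairs, zs, ps = [], [], []
    n_comparisons = k * (k - 1) // 2
    for a in range(k):
        for b in range(a + 1, k):
            pairs.append((labels[a], labels[b]))
            se = np.sqrt(var * (1.0 / sizes[a] + 1.0 / sizes[b]))
            z = 0.0 if se == 0.0 else (mean_ranks[a] - mean_ranks[b]) / se
            zs.append(z)
            ps.append(2.0 * sps.norm.sf(abs(z)))
    z = np.array(zs)
    p_raw = np.array(ps)
    p_adj = np.minimum(1.0, p_raw * n_comparisons)
    return GroupComparison(labels=list(labels), H=H, p_omnibus=p_omni,
                           pairs=pairs, z=z, p_raw=p_raw, p_adjusted=p_adj)
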