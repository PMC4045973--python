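"""Doubled-haploid linkage mapping: distortion screen, two-point
recombination/LOD, LOD-threshold grouping, heuristic ordering and
Kosambi map distances.

The population model is a doubled-haploid (DH) cross: every individual
carries one fully homozygous recombinant gamete, so genotypes segregate
1:1 and a recombinant between two markers is simply a disagreement of
parental alleles.  Ordering within a linkage group uses a greedy
nearest-neighbour chain refined by 2-opt on the sum of adjacent
recombination fractions — a documented heuristic replacement for a
multipoint regression mapper, so map lengths are comparable rather than
identical to those of such software.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats


class LinkageError(ValueError):
    pass


def validate_genotypes(matrix: pd.DataFrame) -> pd.DataFrame:
    """Check a markers x individuals matrix of a/b/- calls."""
    bad = set(np.asarray(matrix, dtype=object).ravel()) - {"a", "b", "-"}
    if bad:
        raise LinkageError(f"invalid genotype calls: {sorted(map(str, bad))}")
    non_missing = (matrix.values != "-").sum(axis=1)
    if (non_missing < 2).any():
        low = matrix.index[non_missing < 2].tolist()
        raise LinkageError(f"markers with <2 non-missing calls: {low}")
    return matrix


def segregation_test(genotypes, alpha: float = 0.05) -> tuple:
    """Chi-square test of the DH 1:1 segregation expectation.

    Returns ``(status, statistic, p_value)`` with status ``distorted``
    when p < alpha.
    """
    arr = np.asarray(genotypes, dtype=object)
    n_a = int((arr == "a").sum())
    n_b = int((arr == "b").sum())
    n = n_a + n_b
    if n == 0:
        raise LinkageError("all calls missing")
    stat, p = stats.chisquare([n_a, n_b], [n / 2, n / 2])
    return ("distorted" if p < alpha else "ok", float(stat), float(p))


def estimate_rf_dh(g1, g2) -> tuple:
    """Two-point recombination fraction and LOD for DH genotypes.

    r is the recombinant share of pairwise-complete individuals, capped
    at 0.5; LOD is the log10 likelihood ratio of the binomial DH model
    at the uncapped estimate against free recombination (r = 0.5).
    """
    a1 = np.asarray(g1, dtype=object)
    a2 = np.asarray(g2, dtype=object)
    ok = (a1 != "-") & (a2 != "-")
    n = int(ok.sum())
    if n < 2:
        raise LinkageError("fewer than 2 pairwise-complete individuals")
    k = int((a1[ok] != a2[ok]).sum())
    r_hat = k / n
    r = min(r_hat, 0.5)
    # constrained MLE: r >= 0.5 carries no linkage evidence in a
    # phase-known DH cross, so the likelihood ratio is 1 (LOD 0)
    if r_hat >= 0.5:
        lod = 0.0
    elif r_hat == 0:
        lod = n * math.log10(2.0)
    else:
        lod = k * math.log10(2 * r_hat) + (n - k) * math.log10(2 * (1 - r_hat))
    return r, lod, n


def kosambi_cm(r: float) -> float:
    """Kosambi map distance in cM: d = 25 ln((1+2r)/(1-2r))."""
    if not 0.0 <= r < 0.5:
        raise LinkageError("r must be in [0, 0.5)")
    return 25.0 * math.log((1 + 2 * r) / (1 - 2 * r))


def kosambi_inverse(d_cm: float) -> float:
    """Inverse Kosambi: r = 0.5 tanh(d/50) for d in cM."""
    if d_cm < 0:
        raise LinkageError("distance must be >= 0")
    return 0.5 * math.tanh(d_cm / 50.0)


def pairwise_rf(matrix: pd.DataFrame) -> tuple:
    """Vectorized all-pairs (r, LOD, n) over a genotype matrix.

    Returns three square DataFrames indexed by marker.  Pairs with fewer
    than two complete individuals get NaN and are excluded from grouping.
    """
    markers = matrix.index
    G = np.where(matrix.values == "a", 0, np.where(matrix.values == "b", 1, -1))
    A = (G == 1).astype(np.float64)
    B = (G == 0).astype(np.float64)
    V = (G >= 0).astype(np.float64)
    n = V @ V.T
    k = A @ B.T + B @ A.T         # disagreements among complete pairs
    with np.errstate(divide="ignore", invalid="ignore"):
        r_hat = np.where(n > 0, k / n, np.nan)
        lod = np.where(
            r_hat >= 0.5, 0.0,
            np.where(
                r_hat > 0,
                k * np.log10(np.maximum(2 * r_hat, 1e-300))
                + (n - k) * np.log10(np.maximum(2 * (1 - r_hat), 1e-300)),
                n * math.log10(2.0)))
    r = np.minimum(r_hat, 0.5)
    invalid = n < 2
    r[invalid] = np.nan
    lod[invalid] = np.nan
    return (pd.DataFrame(r, index=markers, columns=markers),
            pd.DataFrame(lod, index=markers, columns=markers),
            pd.DataFrame(n, index=markers, columns=markers))


def group_markers(lod: pd.DataFrame, lod_threshold: float = 4.0) -> list:
    """Connected components of the graph with edges where LOD >= threshold."""
    g = nx.Graph()
    g.add_nodes_from(lod.index)
    arr = lod.values
    idx = lod.index
    ii, jj = np.where(np.triu(np.nan_to_num(arr, nan=-np.inf), k=1) >= lod_threshold)
    g.add_edges_from((idx[i], idx[j]) for i, j in zip(ii, jj))
    comps = [sorted(c) for c in nx.connected_components(g)]
    return sorted(comps, key=lambda c: (-len(c), c[0]))


@dataclass
class LinkageGroupMap:
    lg_id: str
    marker_ids: list
    positions_cm: list
    rf_adjacent: list = field(default_factory=list)

    def __post_init__(self):
        if self.positions_cm and self.positions_cm[0] != 0.0:
            raise LinkageError("first map position must be 0")
        if any(b < a for a, b in zip(self.positions_cm, self.positions_cm[1:])):
            raise LinkageError("map positions must be non-decreasing")

    @property
    def length_cm(self) -> float:
        return self.positions_cm[-1] if self.positions_cm else 0.0


def order_and_space(markers: list, r: pd.DataFrame, lg_id: str = "LG") -> LinkageGroupMap:
    """Order one linkage group and assign cumulative Kosambi positions.

    Greedy nearest-neighbour chain seeded at the most distal pair,
    refined by 2-opt on the sum of adjacent recombination fractions.
    Orientation is canonicalized so the lexicographically smaller end
    marker comes first.
    """
    markers = list(markers)
    if len(markers) == 1:
        return LinkageGroupMap(lg_id, markers, [0.0])
    sub = r.loc[markers, markers].values.astype(float)
    sub = np.where(np.isnan(sub), 0.5, sub)
    m = len(markers)

    # seed at one end of the most distal (largest-rf) pair
    i0, j0 = np.unravel_index(np.argmax(sub), sub.shape)
    order = [int(i0)]
    remaining = set(range(m)) - {int(i0)}
    while remaining:
        last = order[-1]
        nxt = min(remaining, key=lambda j: (sub[last, j], markers[j]))
        order.append(nxt)
        remaining.discard(nxt)

    # 2-opt with O(1) delta per candidate reversal
    improved = True
    while improved:
        improved = False
        for i in range(m - 1):
            for j in range(i + 1, m):
                delta = 0.0
                if i > 0:
                    delta += sub[order[i - 1], order[j]] - sub[order[i - 1], order[i]]
                if j < m - 1:
                    delta += sub[order[i], order[j + 1]] - sub[order[j], order[j + 1]]
                if delta < -1e-12:
                    order[i:j + 1] = order[i:j + 1][::-1]
                    improved = True
    if markers[order[-1]] < markers[order[0]]:
        order = order[::-1]
    ids = [markers[i] for i in order]
    rf_adj = [min(sub[a, b], 0.4999999) for a, b in zip(order, order[1:])]
    pos, cum = [0.0], 0.0
    for rf in rf_adj:
        cum += kosambi_cm(rf)
        pos.append(cum)
    return LinkageGroupMap(lg_id, ids, pos, rf_adj)


def build_map(matrix: pd.DataFrame, lod_threshold: float = 4.0,
              alpha: float = 0.05, max_missing: float = 0.5) -> dict:
    """Full mapping pipeline from a genotype matrix.

    Distorted markers (chi-square p < alpha against 1:1) and markers
    with more than ``max_missing`` missing calls are excluded before
    grouping; exclusions are reported alongside the maps.
    """
    validate_genotypes(matrix)
    excluded = {}
    keep = []
    for marker in matrix.index:
        row = matrix.loc[marker]
        missing_frac = float((row == "-").mean())
        if missing_frac > max_missing:
            excluded[marker] = "missing"
            warnings.warn(f"{marker}: dropped ({missing_frac:.0%} missing)")
            continue
        status, stat, p = segregation_test(row, alpha=alpha)
        if status == "distorted":
            excluded[marker] = "distorted"
            continue
        keep.append(marker)
    kept = matrix.loc[keep]
    r, lod, n = pairwise_rf(kept)
    groups = group_markers(lod, lod_threshold)
    maps = [order_and_space(grp, r, lg_id=f"LG{k + 1}")
            for k, grp in enumerate(groups)]
    return {"maps": maps, "excluded": excluded, "rf": r, "lod": lod,
            "n_markers_used": len(keep)}


def map_to_frame(maps: list) -> pd.DataFrame:
    rows = [(m.lg_id, mid, round(pos, 3))
            for m in maps for mid, pos in zip(m.marker_ids, m.positions_cm)]
    return pd.DataFrame(rows, columns=["lg_id", "marker_id", "position_cM"])
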