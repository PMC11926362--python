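"""Interregional co-activation: Pearson matrices, Ward dendrograms and
rank-based group comparisons of correlation values.

For each group x marker, regional percent-positive values across animals
give a 14x14 Pearson correlation matrix — the co-activation object.  Ward
hierarchical clustering on the dissimilarity d = 1 - r summarises its
modular structure, and two-sided Mann-Whitney tests compare r-value
collections between groups, either over all 91 region pairs or over the
pairs touching one anatomical group.

The Mann-Whitney test is implemented with an exact, tie-aware null
distribution (dynamic programming over the multiset of midranks,
equivalent to enumerating every assignment of pooled values to the two
samples) whenever n_x * n_y <= 400, and a tie-corrected normal
approximation with continuity correction otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .data import (
    ComparisonResult,
    CorrelationMatrix,
    RegionPanel,
    ValidationError,
    default_panel,
)

EXACT_LIMIT = 400  # exact null distribution up to n_x * n_y of this size


# ---------------------------------------------------------------------------
# Pearson correlation matrices


def pearson_matrix(
    activation: pd.DataFrame,
    group: str,
    marker: str,
    panel: RegionPanel | None = None,
    min_pairs: int = 3,
) -> CorrelationMatrix:
    """Across-animal Pearson correlations between all region pairs.

    Uses pairwise-complete animals per region pair (missing animal x
    region cells are tolerated); a pair with fewer than ``min_pairs``
    shared animals, or a region with zero across-animal variance, yields
    an undefined (NaN) entry.  The diagonal is fixed at 1.
    """
    panel = panel or default_panel()
    sub = activation.query("group == @group and marker == @marker")
    if sub.empty:
        raise ValidationError(f"no activation rows for ({group}, {marker})")
    wide = sub.pivot(index="animal_id", columns="region", values="pct_positive")
    wide = wide.reindex(columns=list(panel.region_ids))
    corr = wide.corr(method="pearson", min_periods=min_pairs)
    np.fill_diagonal(corr.values, 1.0)
    corr.index.name = corr.columns.name = None
    return CorrelationMatrix(
        group=group, marker=marker, matrix=corr, n_animals=len(wide)
    )


# ---------------------------------------------------------------------------
# Ward clustering


@dataclass
class Dendrogram:
    """Ward merge tree over the region panel.

    ``merges`` is a scipy-format linkage matrix (13 rows for 14 leaves:
    merged cluster indices, merge height, new cluster size); ``labels``
    are the leaf region ids in input order.
    """

    merges: np.ndarray
    labels: tuple[str, ...]

    @property
    def leaf_order(self) -> tuple[str, ...]:
        return tuple(self.labels[i] for i in hierarchy.leaves_list(self.merges))

    def cut(self, k: int) -> dict[str, int]:
        """Flat clustering into k clusters; region -> cluster id (1..k)."""
        flat = hierarchy.fcluster(self.merges, t=k, criterion="maxclust")
        return dict(zip(self.labels, (int(c) for c in flat)))


def ward_cluster(matrix: CorrelationMatrix) -> Dendrogram:
    """Agglomerative Ward clustering on the dissimilarity d = 1 - r.

    Uses the Lance-Williams Ward update on the precomputed dissimilarity
    (Ward.D2 convention).  Undefined r entries must be resolved upstream.
    """
    m = matrix.matrix.to_numpy(float)
    if np.isnan(m).any():
        raise ValidationError(
            "correlation matrix has undefined entries; impute or exclude "
            "the affected regions before clustering"
        )
    d = 1.0 - m
    np.fill_diagonal(d, 0.0)
    z = hierarchy.linkage(squareform(d, checks=False), method="ward")
    return Dendrogram(merges=z, labels=matrix.regions)


# ---------------------------------------------------------------------------
# Mann-Whitney U


def _exact_two_sided_p(x: np.ndarray, y: np.ndarray, u_obs: float) -> float:
    """Exact two-sided p by DP over the tie-aware permutation null.

    Counts, for every way of assigning the pooled multiset to the two
    samples, the rank-sum U; equivalent to full enumeration of all
    C(n, n_x) assignments.  Works with doubled midranks so all sums are
    integers; exact rational arithmetic via Python ints.
    """
    nx, ny = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks2 = np.rint(2 * stats.rankdata(pooled)).astype(int)
    values, counts = np.unique(pooled, return_counts=True)
    # doubled midrank per distinct value
    rank2_of = {}
    for v in values:
        rank2_of[v] = int(ranks2[pooled == v][0])
    # ways[j] maps doubled rank-sum -> number of assignments using j items
    ways: list[dict[int, int]] = [dict() for _ in range(nx + 1)]
    ways[0][0] = 1
    for v, c in zip(values, counts):
        r2 = rank2_of[v]
        new: list[dict[int, int]] = [dict() for _ in range(nx + 1)]
        for j in range(nx + 1):
            for s, w in ways[j].items():
                for k in range(0, min(int(c), nx - j) + 1):
                    coeff = math.comb(int(c), k)
                    d = new[j + k]
                    key = s + k * r2
                    d[key] = d.get(key, 0) + w * coeff
        ways = new
    total = math.comb(nx + ny, nx)
    center2 = nx * ny  # doubled U center = 2 * nx*ny/2
    thr = abs(2 * u_obs - center2)
    hits = 0
    offset = nx * (nx + 1)  # doubled U = doubled rank sum - nx(nx+1)
    for s, w in ways[nx].items():
        if abs((s - offset) - center2) >= thr - 1e-9:
            hits += w
    return min(1.0, hits / total)


def mann_whitney(
    x: Sequence[float], y: Sequence[float], label: str = ""
) -> ComparisonResult:
    """Two-sided Mann-Whitney U test.

    U is the rank-sum form for the first sample (U_x = R_x - n_x(n_x+1)/2,
    midranks for ties); p is exact (tie-aware permutation null) when
    n_x * n_y <= 400, otherwise a tie-corrected normal approximation with
    continuity correction.  Direction reports the median shift of the
    second sample relative to the first.
    """
    x = np.asarray(list(x), float)
    y = np.asarray(list(y), float)
    if len(x) == 0 or len(y) == 0:
        raise ValidationError("both samples must be non-empty")
    nx, ny = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    u_x = float(ranks[:nx].sum() - nx * (nx + 1) / 2)
    n = nx + ny
    _, tie_counts = np.unique(pooled, return_counts=True)
    if nx * ny <= EXACT_LIMIT:
        p = _exact_two_sided_p(x, y, u_x)
    else:
        tie_term = float(((tie_counts**3 - tie_counts).sum()) / (n * (n - 1)))
        var = nx * ny / 12.0 * ((n + 1) - tie_term)
        if var <= 0:
            p = 1.0
        else:
            mu = nx * ny / 2.0
            z = (abs(u_x - mu) - 0.5) / math.sqrt(var)
            p = min(1.0, 2.0 * stats.norm.sf(max(z, 0.0)))
    shift = float(np.median(y) - np.median(x))
    if shift == 0:
        shift = float(np.mean(y) - np.mean(x))
    direction = "none" if (p >= 0.05 or shift == 0) else (
        "increase" if shift > 0 else "decrease"
    )
    from .activation import arrow_code  # local import avoids a cycle

    return ComparisonResult(
        label=label, statistic=u_x, p_value=float(p),
        direction=direction, arrow_code=arrow_code(float(p), direction),
        stat_name="U",
    )


# ---------------------------------------------------------------------------
# r-value group comparisons


def select_pairs(
    panel: RegionPanel, pair_set: str = "all"
) -> list[tuple[str, str]]:
    """Unordered region pairs for an r-value comparison.

    ``all`` gives the C(14,2) = 91 pairs; an anatomical-group name gives
    every pair with at least one endpoint in that group.
    """
    regions = panel.region_ids
    pairs = [
        (a, b) for i, a in enumerate(regions) for b in regions[i + 1:]
    ]
    if pair_set == "all":
        return pairs
    members = set(panel.regions_in(pair_set))
    if not members:
        raise ValidationError(f"empty pair set {pair_set!r}")
    return [(a, b) for a, b in pairs if a in members or b in members]


def rvalue_compare(
    matrix_a: CorrelationMatrix,
    matrix_b: CorrelationMatrix,
    pair_set: str = "all",
    panel: RegionPanel | None = None,
) -> ComparisonResult:
    """Mann-Whitney comparison of r values between two matrices.

    Collects the r value of every selected pair from each matrix
    (undefined entries dropped) and tests the two collections.
    """
    panel = panel or default_panel()
    pairs = select_pairs(panel, pair_set)
    if not pairs:
        raise ValidationError(f"empty pair set {pair_set!r}")

    def collect(m: CorrelationMatrix) -> list[float]:
        vals = [m.matrix.at[a, b] for a, b in pairs]
        return [v for v in vals if not np.isnan(v)]

    xa, xb = collect(matrix_a), collect(matrix_b)
    label = (
        f"r[{pair_set}]:{matrix_b.group}/{matrix_b.marker}"
        f"_vs_{matrix_a.group}/{matrix_a.marker}"
    )
    return mann_whitney(xa, xb, label=label)
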