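"""Correlation thresholding and functional-network construction.

A functional network keeps only the strongest co-activations: the cutoff
is the global mean plus one standard deviation of all pairwise r values
within a group x marker combination, and every pair whose r strictly
exceeds it becomes an edge weighted by that r.  All 14 regions remain
nodes regardless of degree, so isolated regions stay visible downstream.
"""

from __future__ import annotations

import math

import networkx as nx
import numpy as np

from .data import CorrelationMatrix, FunctionalNetwork, ValidationError


def threshold_value(matrix: CorrelationMatrix, ddof: int = 1) -> float:
    """Mean + 1 SD of the defined upper-triangle r values.

    ``ddof=1`` (sample SD) by default; ``ddof=0`` gives the population
    SD.  Undefined (NaN) entries are excluded.  Raises when fewer than
    two defined values remain.
    """
    vals = matrix.upper_triangle(dropna=True).to_numpy(float)
    if vals.size < 2:
        raise ValidationError("need >= 2 defined off-diagonal r values")
    return float(vals.mean() + vals.std(ddof=ddof))


def build_network(
    matrix: CorrelationMatrix, cutoff: float | None = None, ddof: int = 1
) -> FunctionalNetwork:
    """Thresholded weighted network from a correlation matrix.

    An edge joins every unordered region pair with r strictly greater
    than ``cutoff`` (default: :func:`threshold_value`); ties at exactly
    the cutoff are dropped.  Undefined entries never form edges.
    """
    if cutoff is None:
        cutoff = threshold_value(matrix, ddof=ddof)
    if not math.isfinite(cutoff):
        raise ValidationError(f"cutoff must be finite, got {cutoff}")
    g = nx.Graph()
    g.add_nodes_from(matrix.regions)
    for (a, b), r in matrix.upper_triangle(dropna=True).items():
        if r > cutoff:
            g.add_edge(a, b, weight=float(r))
    return FunctionalNetwork(
        group=matrix.group, marker=matrix.marker, graph=g,
        threshold=float(cutoff),
    )
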