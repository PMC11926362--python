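"""Per-region activation statistics: percent-positive nuclei and
three-group contrasts (one-way ANOVA with Tukey HSD post hoc).

Percent-positive values are the pipeline's basic measurements.  Two
conventions are supported: *inclusive* (a double-labeled nucleus counts
toward both markers — the default, standard in catFISH reporting) and
*exclusive* (only-counts).  Group contrasts per region x marker mirror
the study design: vehicle vs home cage, iso vs home cage, iso vs vehicle,
each summarised with an arrow code (one/two/three arrows for p < 0.05 /
0.01 / 0.001, ``=`` otherwise, oriented by the sign of the difference).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import (
    GROUPS,
    MARKERS,
    ComparisonResult,
    RegionPanel,
    ValidationError,
    default_panel,
)

#: Ordered pairwise contrasts; direction is for the *second* group
#: relative to the first (the reference).
CONTRASTS = (
    ("home_cage", "vehicle"),
    ("home_cage", "iso"),
    ("vehicle", "iso"),
)


def percent_positive(
    counts: pd.DataFrame, convention: str = "inclusive"
) -> pd.DataFrame:
    """Long-format activation table from a validated counts table.

    Returns one row per animal x region x marker with ``pct_positive``
    in [0, 100].  Inclusive: pct(H1a) = 100 * (n_h1a_only + n_double) /
    n_total (likewise Arc); pct(double) = 100 * n_double / n_total.
    Exclusive uses the only-counts for H1a and Arc.
    """
    if convention not in ("inclusive", "exclusive"):
        raise ValueError(f"unknown convention {convention!r}")
    if (counts["n_total"] == 0).any():
        bad = counts.loc[counts["n_total"] == 0].iloc[0]
        raise ValidationError(
            f"n_total = 0 for ({bad['animal_id']!r}, {bad['region']!r}): "
            "region unquantifiable"
        )
    total = counts["n_total"].to_numpy(float)
    double = counts["n_double"].to_numpy(float)
    h1a = counts["n_h1a_only"].to_numpy(float)
    arc = counts["n_arc_only"].to_numpy(float)
    if convention == "inclusive":
        h1a, arc = h1a + double, arc + double
    frames = []
    for marker, num in (("H1a", h1a), ("Arc", arc), ("double", double)):
        frames.append(pd.DataFrame({
            "animal_id": counts["animal_id"],
            "group": counts["group"],
            "region": counts["region"],
            "marker": marker,
            "pct_positive": 100.0 * num / total,
        }))
    return pd.concat(frames, ignore_index=True)


def arrow_code(p: float, direction: str) -> str:
    """Arrow-coded significance: ``=`` for p >= 0.05, else 1/2/3 arrows
    at the strict thresholds 0.05, 0.01, 0.001, oriented by direction."""
    if not 0 <= p <= 1:
        raise ValueError(f"p-value {p} outside [0, 1]")
    if p >= 0.05 or direction == "none":
        return "="
    head = {"increase": "↑", "decrease": "↓"}[direction]
    n = 3 if p < 0.001 else 2 if p < 0.01 else 1
    return head * n


def _direction(diff: float, p: float) -> str:
    if p >= 0.05 or diff == 0:
        return "none"
    return "increase" if diff > 0 else "decrease"


@dataclass
class AnovaResult:
    """One-way ANOVA across groups for one region x marker, with Tukey
    HSD pairwise contrasts (Tukey-Kramer for unequal group sizes)."""

    region: str
    marker: str
    f_statistic: float
    df_between: int
    df_within: int
    p_value: float
    tukey: list[ComparisonResult]


def anova_tukey(
    activation: pd.DataFrame, region: str, marker: str
) -> AnovaResult:
    """One-way ANOVA on percent-positive across groups, then Tukey HSD.

    Requires >= 2 groups with >= 2 animals each; raises on degenerate
    input (zero within-group variance everywhere).
    """
    sub = activation.query("region == @region and marker == @marker")
    samples = [
        sub.loc[sub["group"] == g, "pct_positive"].to_numpy(float)
        for g in GROUPS
        if (sub["group"] == g).any()
    ]
    labels = [g for g in GROUPS if (sub["group"] == g).any()]
    if len(samples) < 2 or any(len(s) < 2 for s in samples):
        raise ValidationError(
            f"need >= 2 groups with >= 2 animals for ({region}, {marker})"
        )
    if all(np.var(s) == 0 for s in samples):
        raise ValidationError(
            f"zero within-group variance for ({region}, {marker})"
        )
    f_stat, p = stats.f_oneway(*samples)
    hsd = stats.tukey_hsd(*samples)
    means = {g: s.mean() for g, s in zip(labels, samples)}
    tukey = []
    for ref, other in CONTRASTS:
        if ref not in labels or other not in labels:
            continue
        i, j = labels.index(ref), labels.index(other)
        p_pair = float(hsd.pvalue[i, j])
        diff = means[other] - means[ref]
        direction = _direction(diff, p_pair)
        tukey.append(ComparisonResult(
            label=f"{region}:{marker}:{other}_vs_{ref}",
            statistic=float(hsd.statistic[j, i]),
            p_value=p_pair,
            direction=direction,
            arrow_code=arrow_code(p_pair, direction),
            stat_name="mean_diff",
        ))
    n = sum(len(s) for s in samples)
    return AnovaResult(
        region=region, marker=marker,
        f_statistic=float(f_stat), p_value=float(p),
        df_between=len(samples) - 1, df_within=n - len(samples),
        tukey=tukey,
    )


def activation_contrast_table(
    activation: pd.DataFrame, panel: RegionPanel | None = None
) -> pd.DataFrame:
    """All region x marker ANOVA + Tukey contrasts as one tidy table,
    mirroring the arrow-coded group-comparison tables."""
    panel = panel or default_panel()
    rows = []
    for region in panel.region_ids:
        for marker in MARKERS:
            res = anova_tukey(activation, region, marker)
            for comp in res.tukey:
                contrast = comp.label.split(":", 2)[2]
                rows.append({
                    "region": region, "marker": marker, "contrast": contrast,
                    "anova_F": res.f_statistic, "anova_p": res.p_value,
                    "tukey_p": comp.p_value, "direction": comp.direction,
                    "arrow_code": comp.arrow_code,
                })
    return pd.DataFrame(rows)
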