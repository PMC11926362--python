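"""Synthetic nucleus-counts generator with planted co-activation structure.

The generator emulates the statistical structure the downstream analysis
assumes: three treatment groups of ~10 animals, 14 brain regions, several
hundred DAPI nuclei per sampled field, group-dependent mean activation,
and across-animal interregional covariance with a planted block
(anatomical-module) structure.

Model (per animal): one latent Gaussian vector per marker epoch,

    z_epoch ~ MVN(mu[group, marker, :], Sigma),    Sigma from the block model,

is pushed through the logistic function to per-region marker probabilities
p_early, p_late.  Joint nucleus-class probabilities couple the two epochs
through a single additive dependence knob ``delta_double``:

    p11 = p_early * p_late + delta_double      (independence at 0)
    p10 = p_early - p11,  p01 = p_late - p11,  p00 = remainder

and the four class counts are a multinomial draw over n_total nuclei,
with n_total uniform on ``nuclei_range``.  Identical seeds give
byte-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .data import GROUPS, RegionPanel, default_panel, validate_counts

#: Baseline activation logit: ~10% marker-positive nuclei, typical of
#: home-cage IEG expression.
BASELINE_LOGIT = -2.2
#: Group-effect increment on the logit scale (~10% -> ~27%).
EFFECT_LOGIT = 1.2


def default_mu(panel: RegionPanel) -> dict[tuple[str, str, str], float]:
    """Default mean-activation logits per (group, marker, region).

    Qualitative pattern: home-cage low everywhere; vehicle elevated in
    hippocampus and RSC; iso elevated in the thalamus.  Both marker
    epochs share the group effect.
    """
    mu: dict[tuple[str, str, str], float] = {}
    elevated = {
        "home_cage": frozenset(),
        "vehicle": frozenset(
            panel.regions_in("hippocampus") + panel.regions_in("RSC")
        ),
        "iso": frozenset(panel.regions_in("thalamus")),
    }
    for group in GROUPS:
        for marker in ("H1a", "Arc"):
            for region in panel.region_ids:
                bump = EFFECT_LOGIT if region in elevated.get(group, ()) else 0.0
                mu[(group, marker, region)] = BASELINE_LOGIT + bump
    return mu


def build_latent_cov(
    blocks: Sequence[Sequence[str]],
    rho_within: float,
    rho_between: float,
    sigma: float,
    region_ids: Sequence[str],
) -> np.ndarray:
    """Block-structured latent covariance over the region panel.

    Entry (i, j) is ``sigma**2 * rho_within`` when i != j share a block,
    ``sigma**2 * rho_between`` otherwise, and ``sigma**2`` on the
    diagonal.  Raises if the parameters give a non-PSD matrix.
    """
    if not (0 <= rho_within < 1 and 0 <= rho_between < 1):
        raise ValueError("rho_within and rho_between must be in [0, 1)")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    block_of: dict[str, int] = {}
    for k, block in enumerate(blocks):
        for r in block:
            if r in block_of:
                raise ValueError(f"region {r!r} appears in two blocks")
            block_of[r] = k
    missing = [r for r in region_ids if r not in block_of]
    if missing:
        raise ValueError(f"regions not assigned to any block: {missing}")
    labels = np.array([block_of[r] for r in region_ids])
    same = labels[:, None] == labels[None, :]
    cov = np.where(same, rho_within, rho_between) * sigma**2
    np.fill_diagonal(cov, sigma**2)
    w = np.linalg.eigvalsh(cov)
    if w.min() < -1e-10:
        raise ValueError(
            f"latent covariance is not positive semi-definite "
            f"(min eigenvalue {w.min():.3g})"
        )
    return cov


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic counts generator.

    Defaults describe the emulated study design: 3 groups x 10 animals x
    14 regions, 300-800 nuclei per field, moderate across-animal latent
    variation (sigma = 0.5 on the logit scale), stronger within-module
    than between-module latent correlation, and a small positive marker
    dependence (delta_double = 0.01, roughly doubling baseline double
    labeling relative to independence).
    """

    n_animals: int = 10
    panel: RegionPanel = field(default_factory=default_panel)
    nuclei_range: tuple[int, int] = (300, 800)
    mu: Mapping[tuple[str, str, str], float] | None = None
    blocks: tuple[tuple[str, ...], ...] | None = None
    rho_within: float = 0.5
    rho_between: float = 0.1
    sigma: float = 0.5
    delta_double: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mu is None:
            self.mu = default_mu(self.panel)
        if self.blocks is None:
            self.blocks = tuple(
                self.panel.regions_in(g) for g in self.panel.anatomical_groups
            )
        lo, hi = self.nuclei_range
        if not (0 < lo <= hi):
            raise ValueError("nuclei_range must satisfy 0 < min <= max")
        # PSD check happens here; mean-level class probabilities must be valid
        self.latent_cov()
        for group in GROUPS:
            for region in self.panel.region_ids:
                pe = expit(self.mu[(group, "H1a", region)])
                pl = expit(self.mu[(group, "Arc", region)])
                _joint_probs(
                    np.array([pe]), np.array([pl]), self.delta_double,
                    strict=True,
                )

    def latent_cov(self) -> np.ndarray:
        return build_latent_cov(
            self.blocks, self.rho_within, self.rho_between,
            self.sigma, self.panel.region_ids,
        )


def _joint_probs(
    p_early: np.ndarray, p_late: np.ndarray, delta_double: float,
    strict: bool = False,
) -> np.ndarray:
    """Four nucleus-class probabilities (p00, p10, p01, p11) per region.

    ``p11`` is the product baseline plus ``delta_double``, clamped into
    the Frechet-feasible interval [max(0, pe+pl-1), min(pe, pl)] so the
    only- and negative-class probabilities stay non-negative.  With
    ``strict=True`` (used to vet a configuration's mean-level
    probabilities) an out-of-bounds request raises instead of clamping.
    """
    lo = np.maximum(0.0, p_early + p_late - 1.0)
    hi = np.minimum(p_early, p_late)
    p11_raw = p_early * p_late + delta_double
    if strict and ((p11_raw > hi + 1e-12).any() or (p11_raw < lo - 1e-12).any()):
        raise ValueError(
            "marker dependence too strong for the marginal probabilities "
            "(negative only-class probability); use a smaller delta_double"
        )
    p11 = np.clip(p11_raw, lo, hi)
    p10 = p_early - p11
    p01 = p_late - p11
    p00 = 1.0 - p11 - p10 - p01
    return np.stack([p00, p10, p01, p11], axis=-1)


def simulate_dataset(config: SyntheticConfig) -> pd.DataFrame:
    """Draw a full counts table under the latent-Gaussian block model.

    Returns a validated long-format DataFrame with one row per
    animal x region (columns ``animal_id, group, region, n_total,
    n_h1a_only, n_arc_only, n_double``).  Deterministic given
    ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    panel = config.panel
    cov = config.latent_cov()
    regions = list(panel.region_ids)
    rows = []
    for group in GROUPS:
        mu_early = np.array([config.mu[(group, "H1a", r)] for r in regions])
        mu_late = np.array([config.mu[(group, "Arc", r)] for r in regions])
        for i in range(config.n_animals):
            animal = f"{group}_{i + 1:02d}"
            z_early = rng.multivariate_normal(mu_early, cov, method="cholesky")
            z_late = rng.multivariate_normal(mu_late, cov, method="cholesky")
            probs = _joint_probs(expit(z_early), expit(z_late), config.delta_double)
            totals = rng.integers(
                config.nuclei_range[0], config.nuclei_range[1] + 1, len(regions)
            )
            for j, region in enumerate(regions):
                n00, n10, n01, n11 = rng.multinomial(totals[j], probs[j])
                rows.append(
                    (animal, group, region, int(totals[j]),
                     int(n10), int(n01), int(n11))
                )
    df = pd.DataFrame(
        rows,
        columns=["animal_id", "group", "region",
                 "n_total", "n_h1a_only", "n_arc_only", "n_double"],
    )
    return validate_counts(df, panel)
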