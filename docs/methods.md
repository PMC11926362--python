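# Methods

`iegnet` turns per-region immediate-early-gene (IEG) nucleus counts from a
three-group rat experiment into activation statistics, interregional
co-activation matrices, thresholded functional brain networks, and
graph-centrality contrasts. This note documents the models and procedures
the package implements, the choices made where the analysis convention was
genuinely open, and what the synthetic-data generator does and does not
emulate.

## Study design and data model

The experimental design the package assumes is catFISH (cellular
compartment analysis of temporal activity by FISH) over two IEG markers
with distinct somatic-expression delays — Homer1a (H1a), time-stamping an
early behavioral epoch (~35–40 min before sacrifice), and Arc,
time-stamping a late epoch (~5–6 min) — quantified in 14 brain areas: six
dorsal-hippocampal subfields (upDG, lowDG, pCA3, dCA3, pCA1, dCA1), two
retrosplenial areas (gRSC, dRSC), three prefrontal areas (Cg1, PL, IL),
and three thalamic nuclei (PV, LDDM, LDVL). Three treatment groups
(`home_cage`, `vehicle`, `iso` for the β-adrenergic agonist
isoproterenol), roughly 9–10 animals each.

The raw input is one row per animal × region with the total DAPI nucleus
count and the three mutually exclusive label classes (H1a-only, Arc-only,
double-labeled); the DAPI-only remainder is implicit. Storing exclusive
classes is lossless; marker-inclusive percentages are derived, never
stored. Missing animal × region cells are permitted (histology sections
fail) and propagate as missing values; correlations use pairwise-complete
animals.

## Activation statistics

Percent-positive per animal × region × marker defaults to the *inclusive*
convention — a double-labeled nucleus counts toward both markers, the
standard in catFISH reporting — with the *exclusive* (only-counts)
convention available via config, since published percent-positive figures
do not always state which was used. For each region × marker, groups are
compared with a classical one-way ANOVA (no Welch correction) followed by
Tukey HSD post hoc tests, using the Tukey–Kramer adjustment because group
sizes of 9 vs 10 are unbalanced. Results carry an arrow code: `=` for
p ≥ 0.05, one/two/three arrows for p < 0.05 / 0.01 / 0.001, oriented by
the sign of the group-mean difference. The thresholds are strict
inequalities, so p = 0.05 exactly codes as `=`.

Tukey HSD p values are conservative relative to *unadjusted* pairwise
testing on the same pooled error term (Fisher LSD: same MSE, df = N − k);
they are **not** uniformly larger than a two-sample t that ignores the
third group's variance, because pooling can shrink the error estimate.
The test suite checks conservativeness against the LSD oracle.

## Co-activation and clustering

For each group × marker, the 14×14 Pearson matrix correlates regional
percent-positive values across the animals of that group. A region with
zero across-animal variance yields undefined (NaN) entries, which are
excluded from pooled r statistics and flagged for the user; pairs with
fewer than 3 shared animals are likewise undefined.

Ward hierarchical clustering runs on the dissimilarity d = 1 − r, the
standard co-activation dissimilarity, with the Lance–Williams Ward update
on the precomputed d (the Ward.D2 convention). Merge heights are
non-decreasing; a 3- or 4-cluster cut of the tree gives flat modules.

Between-group comparisons of r values use a two-sided Mann–Whitney U
test, either over all C(14,2) = 91 pairs or over every pair with at least
one endpoint in a named anatomical group (hippocampus 63 pairs, RSC 25,
PFC 36, thalamus 36). No Fisher z-transform is applied first: a
rank-based test is invariant under monotone transforms, so it would not
change the result.

### Mann–Whitney implementation

U is reported in rank-sum form for the first sample (midranks under
ties). The p value is exact whenever n_x·n_y ≤ 400: a dynamic program
over the multiset of (doubled) midranks counts, for every one of the
C(n, n_x) assignments of pooled values to the samples, the resulting U —
i.e. the tie-aware permutation null, computed in integer arithmetic. The
two-sided p is the null mass at least as far from n_x·n_y/2 as the
observed U. Above the exact limit a tie-corrected normal approximation
with continuity correction is used. All-tied input gives p = 1.

## Network construction

Within each group × marker, the edge threshold τ is the global mean plus
one standard deviation of the 91 pairwise r values. The SD is the sample
SD (ddof = 1), the default of `sd()` in most statistical environments;
population SD is available via config since the convention is rarely
stated. Every pair with r **strictly** above τ becomes an edge weighted
by r; ties at τ are dropped (measure-zero in practice). Negative r values
participate in the mean/SD and may in principle survive a negative τ; no
absolute-value transform is applied. All 14 regions remain nodes
regardless of degree.

Under the null of i.i.d. normal r values, the surviving fraction
approaches the one-sided one-SD tail mass Φ(−1) ≈ 0.159; the acceptance
suite verifies this at 1,000 Monte-Carlo replicates (the mean fraction
over replicates of 91 values sits within 0.01 of 0.1587).

## Graph measures

- **Giant component**: node count of the largest connected component;
  an edgeless graph has giant component 1.
- **Degree**: unweighted edge count per node.
- **Local transitivity**: 2·T(v)/(k(v)(k(v)−1)); nodes of degree 0 *or* 1
  score 0 (the 0/0 case for degree 1 is resolved to 0, consistent with
  the isolated-node convention).
- **Nodal efficiency**: mean inverse shortest-path length to all other
  nodes, unreachable nodes contributing 0. Paths default to unweighted
  hop counts — r-weights are similarities, not costs — with an optional
  weighted mode using distance 1/weight.
- **Hub score**: eigenvector centrality of the weighted adjacency,
  normalized so the maximum is 1. Computed by power iteration on
  A + sI with s the largest |weight| — the shift leaves eigenvectors
  unchanged but prevents oscillation on bipartite components — with an
  extrapolated stopping rule (successive-change ratio estimates the
  convergence factor) so the tolerance of 1e−10 bounds the actual
  eigenvector error. Isolated nodes score exactly 0. On disconnected
  graphs the dominant component carries the score mass.

Nodewise degree, clustering and efficiency are compared between groups
with the same Mann–Whitney test (14 vs 14 values, hence always in the
exact regime; maximum possible U is 196).

## Synthetic-data generator

The generator exists so that every downstream stage is testable without
the original histology. Per animal it draws one latent Gaussian vector
per marker epoch, `z ~ MVN(mu[group, marker, ·], Σ)`, where Σ has a
planted block structure over the region panel: σ²·ρ_within inside a
block, σ²·ρ_between across blocks, σ² on the diagonal (positive
semi-definiteness is checked at construction). Logistic transforms give
per-region marker probabilities; the two epochs couple through one knob,
p₁₁ = p_early·p_late + δ_double (independence at δ = 0), and the four
nucleus classes are a multinomial over n_total ~ Uniform{300, …, 800}
nuclei. Identical seeds give byte-identical tables.

Draw-level joint probabilities are clamped into the Fréchet-feasible
interval [max(0, p_e+p_l−1), min(p_e, p_l)]: a valid configuration can
still produce tail latent draws for which the additive δ would otherwise
make an only-class probability negative, and clamping (rather than
failing) is the behaviour a simulation user needs. A configuration whose
*mean-level* probabilities are infeasible is rejected at construction
with a message to reduce δ_double.

Defaults (chosen once as a realistic emulation of the study conditions):
10 animals per group; baseline activation logit −2.2 (≈10% positive,
typical of home-cage IEG expression) with a +1.2 logit group effect
(≈27%) — vehicle elevated in hippocampus and RSC, iso in the thalamus;
latent SD σ = 0.5 on the logit scale (across-animal spread of roughly
5–19% around a 10% mean, and small enough that near-tail class
probabilities stay Fréchet-feasible at δ_double = 0.01); ρ_within = 0.5,
ρ_between = 0.1; δ_double = 0.01 (roughly doubling baseline double
labeling relative to independence); blocks default to the four
anatomical groups.

What the generator does **not** emulate: IEG transcription kinetics,
within-animal spatial correlation between sampled fields, segmentation
and classification error in the imaging pipeline, overdispersion beyond
the latent-logit level, or group differences in covariance structure
(covariance is shared across groups unless configured otherwise).
Passing tests on synthetic data therefore demonstrate the *pipeline's*
correctness and sensitivity under controlled structure, not properties
of any real dataset.

### Planted-structure recovery

With ρ_within = 0.8, ρ_between = 0 and 50 animals per group over a
3-block partition (hippocampus / RSC+PFC / thalamus), the full chain —
simulate → percent-positive → Pearson → mean+SD threshold → network, and
Ward 3-cluster cut — recovered the planted partition perfectly in an
independent 1,000-replicate calibration run (intra-block edge fraction
and adjusted Rand index both 1.0 in every replicate). The regression
tests assert the frozen bounds 0.9 for both quantities, far above the
chance levels (~0.36 intra-block fraction for random edges; ARI ≈ 0).

## Pipeline and reproducibility

`run_all` executes activation stats → correlation matrices and
dendrograms → r comparisons → networks → metrics → metric comparisons
for every group × marker present, skipping contrast stages (with a
logged notice) when only one group is supplied. Every output directory
contains a `summary.json` embedding the resolved configuration; outputs
contain no timestamps, so identical configurations reproduce
byte-identical tables and summaries. Figures (correlation heatmaps with
dendrograms; force-directed network diagrams with edge width ∝ r, node
size ∝ hub score, node color by anatomical group, fixed layout seed) are
conveniences, not analysis surfaces.

Problem sizes used by the test and acceptance runs — 10 animals/group for
pipeline checks, 200 animals/group for marginal calibration, 50/group for
planted-structure recovery, 1,000 Monte-Carlo replicates for the
threshold-rule null — were chosen to give stable Monte-Carlo estimates at
interactive runtimes.

## Known limitations

- Group-level statistics on real data depend on raw per-animal counts;
  the package validates its procedures on synthetic structure, not on
  the original study's numbers.
- Correlation matrices at n ≈ 10 animals are noisy; the mean+SD
  threshold is a pragmatic sparsification, not an inferential edge test
  (no permutation null or density matching is provided, by design).
- The exact Mann–Whitney regime is capped at n_x·n_y ≤ 400; beyond it
  the tie-corrected normal approximation applies.
- Eigenvector centrality on graphs with mixed-sign edge weights is not
  meaningful; hub scores are intended for thresholded networks whose
  surviving weights share a sign.
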