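# Methods

## Scope and data model

The package analyses task-driven functional connectivity between
activation-defined ROIs. Its unit of data is a per-subject,
per-condition ROI × scan matrix of BOLD values (the "average time
series", AVT): all scans belonging to one task condition, concatenated
across runs. Everything upstream of that matrix — image reconstruction,
realignment, normalisation, GLM-based ROI definition — is out of scope;
everything downstream (connectivity, graph metrics, group statistics) is
implemented and tested here.

## Node atlases

Two node tables are packaged as TSV: `N1` (21 ROIs common to both age
groups) and `N2` (12 ROIs over-activated in the old group). Hemisphere
assignment comes from the table's side column, never from the sign of
the x coordinate: near-midline nodes (cerebellar vermis at x = ±2) keep
their printed labels, which matters for the interhemispheric analysis
(N1 has 10 L × 11 R = 110 crossing pairs). Row order is graph vertex
order and is stable across save/load.

ROI spheres have radius 6 mm. The rasterisation grid was never part of
the published description, so `sphere_voxel_indices` exposes voxel size
and origin as parameters, uses 0-based indices with voxel-center
coordinates, and includes a voxel iff its center lies within the radius
(strict ≤). This is the simplest convention that is exactly testable by
brute-force enumeration.

## Synthetic cohorts

### Generative model

Each (group, condition) cell has a sparse precision matrix Ω built from
an edge support and target partial correlations; data are drawn from the
corresponding multivariate normal. With unit diagonal, Ω = I − R gives
partial correlations exactly equal to R's entries, so ground truth is
exact on support and exactly zero off support. Scans receive AR(1)
filtering (x_t = φ x_{t−1} + √(1−φ²) ε_t), which leaves the
contemporaneous covariance — and therefore the true partial
correlations — untouched while adding realistic temporal smoothness,
plus a constant task offset during task epochs. The model is
deliberately not an HRF-convolved biophysical simulation: the
connectivity analysis consumes only the second-order structure of
condition epochs, and this is the minimal model that exercises it.

### Feasibility of the target structure

Realistic edge strengths (|r| ≈ 0.3–0.45) at realistic densities are
not positive-definite for arbitrary supports: a random-sign random
support at mean degree ~4 has spectral radius well above 1. The default
support is therefore structured: edges are drawn from ring bands
(nearest neighbours with positive r, second neighbours negative, third
neighbours positive in a spread-out order), whose alternating signs keep
the spectral radius low. Nesting is built in: all four cells take
prefixes of one deterministic edge order, so young ⊂ old and IP ⊂ AP.
`build_precision` verifies the eigenvalue floor (0.05); if a model is
slightly infeasible it uniformly shrinks the off-diagonals (equivalent
to diagonal loading plus renormalisation) and errors out — never clips
silently — if that moves any partial correlation by more than 0.02.

### Default parameters

| parameter | default | rationale |
| --- | --- | --- |
| n per group | 16 | the study design this emulates |
| design | 4 runs × 6 blocks × 3 conditions × 7 scans, TR 3 s | 378 s runs; 168 scans per condition |
| young baseline density | 2.4/(N−1) | mean true degree 2.4; keeps the densest cell feasible at all atlas sizes |
| young partial r | 0.30 | near the detection limit at α = 0.001 with 168 scans, so young networks are realistically incompletely detected |
| age increment | +0.10 density, +0.10 r | the old-vs-young effect, sized to be detectable at n = 16/group |
| phase increment | +0.02 density, +0.02 r | AP harder than IP in both groups |
| AR(1) φ | 0.3 | moderate BOLD autocorrelation at TR 3 s |
| noise_sd | 1.0 | overall BOLD scale; partial correlations are scale-invariant |
| task amplitude | 1.0 | mean offset only; removed by covariance centering |

Kinematics are drawn per subject with condition-dependent population
parameters (AP: 16° ± 4° phase error, 20° ± 5° phase SD; IP: 7° ± 2°,
10° ± 3°) identical across groups, emulating performance-matched
cohorts; an optional linear coupling to a connectivity summary supports
correlation analyses.

Seeding is counter-based: every subject × condition stream derives from
`SeedSequence(master_seed, group, subject, condition)`, so cohorts are
reproducible and subjects independent.

### What the generator does not emulate

No voxel-level images, motion or physiological artifacts, HRF dynamics,
per-subject frequency titration, or session/run drift beyond what the
detrending stage can remove. Passing recovery tests therefore shows the
*estimators* are correct under the model's assumptions, not that real
BOLD data meet those assumptions.

## Extraction

Two AVT definitions exist in the literature for the same quantity and
both are implemented: the element-wise voxel mean (default) and the
first eigenvariate (first left singular direction, scaled to the matrix
RMS and sign-aligned with the voxel mean). Whether a published analysis
averaged before or after the eigenvariate step is generally ambiguous;
the choice here is explicit, recorded in run metadata, and switchable.
Epoch selection concatenates condition scans across runs without
boundary tapering; detrending is per-ROI linear (order 0 = none).

## Connectivity

Partial correlations come from the inverse sample covariance. Scans
within concatenated epochs are treated as exchangeable samples — no
autocorrelation correction — matching common practice for this design;
the AR(1) induced by the generator slightly widens the null, which is
visible (and tolerated) in the significance tests. Edge significance
uses `t = ρ√(df/(1−ρ²))` with df = n − N, the standard df for a
correlation controlling N−2 covariates, validated against a permutation
oracle. Tests are two-sided; negative partial correlations form edges
and keep their sign in the weights (a config switch flips to unsigned).
Ridge loading of the covariance exists only as an opt-in for
near-singular inputs and is always logged. No multiplicity correction is
applied across edges: robustness is assessed by sweeping the five
thresholds instead, and edge sets are provably nested across them.

## Graph metrics

All metrics are computed on the binary adjacency except strength, which
sums signed weights. Conventions where the literature is loose:

* clustering and local efficiency are 0 for nodes of degree < 2 (avoids 0/0);
* nodal path length averages over reachable peers only; isolated nodes
  are missing (NaN) and excluded from the network mean; global
  efficiency (mean 1/d, 1/∞ = 0) is reported alongside as the
  disconnection-robust integration measure;
* betweenness uses Brandes accumulation, counts unordered pairs, and is
  unnormalised — the magnitudes (≈ N for these network sizes) match the
  reporting convention of the toolbox literature;
* the small-world ratios divide the observed mean clustering and path
  length by C_rand = k/N and L_rand = ((ln N − γ)/ln k) + 0.5; they are
  computed per subject and then averaged, and are NaN when mean degree
  ≤ 1 (estimate undefined).

Every metric is verified against exhaustive brute-force oracles
(explicit BFS, enumeration of all shortest paths) on hundreds of random
graphs, and against networkx independently.

## Group statistics

The 2 × 2 ANOVA is a split-plot: AGE (different people) is tested
against the subjects-within-groups stratum, PHASE and AGE × PHASE
against the subject × phase stratum. For the balanced design the sums
of squares are exact and the decomposition SS_total = SS_between +
SS_within holds to machine precision (property-tested). A degenerate
noiseless denominator is reported as an infinite-F flag rather than an
exception-free wrong number. With 16 + 16 subjects the AGE test has
df = (1, 30).

Tukey HSD over the four cell means uses the studentized range with
k = 4. The error term follows the design: within-group comparisons use
the subject × phase stratum; between-group comparisons use the Winer
pooled mean square (MS_subjects + MS_within)/2 with Satterthwaite
degrees of freedom. This matches R's `aov` + `emmeans` on a fixture to
four decimals.

Brain–behaviour correlations are Pearson R over pairwise-complete
subjects, flagged at P < 0.01; zero-variance inputs are reported as
missing with a reason. No correction across the correlation family is
applied, but the number of evaluated correlations is part of the output
so readers can apply their own.

## Pipeline

One YAML config drives simulate → connect → measure → test → report.
Unknown keys are rejected, alphas are normalised ascending with a
warning, and every output table carries a hash of the canonical config
in a header comment; identical configs reproduce identical bytes.
Input can be the built-in generator or a directory of ROI × scan TSV
files with a JSON manifest (the same format `write_cohort` emits).

## Problem sizes in tests and the acceptance script

Recovery and calibration suites run at sizes chosen for tight Monte
Carlo error at desk scale: estimator consistency at 10–20 k scans,
oracle equivalence on 200 random graphs of ≤ 9 nodes, small-world
self-consistency on 100 Erdős–Rényi graphs of 50 nodes, AGE-detection
power over 100 (tests) / 50 (script) cohorts of 16 + 16 subjects on the
12-node atlas, and ANOVA type-I calibration over 5000 null replicates.

## Known limitations

* Published group-level values from the original cohort are not
  reproducible (raw scans undeposited); validation is by parameter
  recovery on synthetic data instead.
* The significance test assumes exchangeable scans; with autocorrelated
  epochs it is mildly anticonservative. An effective-sample-size
  correction would be the natural extension.
* Weighted variants of clustering/path metrics are intentionally absent:
  the metric set mirrors binary-graph definitions, with strength as the
  only weighted quantity.
* No modularity, hub, or rich-club analysis — network-mean comparisons
  across non-matched densities do not license topological claims.
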