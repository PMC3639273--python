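"""Synthetic block-design BOLD cohorts with known connectivity structure.

Generates ROI time series whose second-order structure follows a Gaussian
graphical model: each (group, condition) cell has a sparse precision matrix
whose off-diagonal support defines the true functional edges, with exact
target partial correlations on that support and zeros elsewhere.  Scans are
AR(1)-filtered so the series carry realistic temporal autocorrelation while
keeping the contemporaneous covariance (and hence the true partial
correlations) unchanged, and a boxcar task mean is added during task blocks.

The default cohort mirrors a two-group aging study design: 16 subjects per
group, four runs of six 21-s blocks per condition (AP / IP / REST) at
TR = 3 s, with the old group's networks denser (+0.10 edge density) and
stronger (+0.10 partial r) than the young group's, and the harder AP
condition slightly denser/stronger than IP in both groups.  Ground truth
(support and targets per cell) is exposed for parameter-recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .extraction import SubjectConditionSeries

__all__ = [
    "DesignSpec",
    "PrecisionModel",
    "CohortSpec",
    "make_design",
    "build_precision",
    "implied_partial_correlations",
    "model_covariance",
    "default_cohort",
    "simulate_subject",
    "simulate_kinematics",
    "write_cohort",
    "GROUPS",
    "TASK_CONDITIONS",
]

GROUPS = ("old", "young")
TASK_CONDITIONS = ("AP", "IP")

_GROUP_CODE = {"old": 0, "young": 1}
_CONDITION_CODE = {"AP": 0, "IP": 1, "REST": 2}

#: kinematic population parameters (degrees): mean / between-subject SD of
#: phase error and of phase variability, per condition.  AP (anti-phase) is
#: harder than IP, so both accuracy and stability are worse; the parameters
#: are identical across age groups, emulating performance-matched cohorts.
KINEMATIC_PARAMS = {
    "AP": {"error_mean": 16.0, "error_sd": 4.0, "sd_mean": 20.0, "sd_sd": 5.0},
    "IP": {"error_mean": 7.0, "error_sd": 2.0, "sd_mean": 10.0, "sd_sd": 3.0},
}


@dataclass(frozen=True)
class DesignSpec:
    """Block design of one scanning session.

    Defaults reproduce the study design this package emulates: 4 runs, each
    holding 6 blocks of every condition, 7 scans per 21-s block at TR = 3 s,
    i.e. 126 scans (378 s) per run and 168 scans per condition in total.
    """

    n_runs: int = 4
    blocks_per_condition_per_run: int = 6
    scans_per_block: int = 7
    tr: float = 3.0
    conditions: tuple[str, ...] = ("AP", "IP", "REST")
    block_order_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_runs", "blocks_per_condition_per_run", "scans_per_block"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if len(set(self.conditions)) != len(self.conditions):
            raise ValueError("conditions must be unique")

    @property
    def scans_per_run(self) -> int:
        return (
            self.blocks_per_condition_per_run
            * len(self.conditions)
            * self.scans_per_block
        )

    @property
    def run_duration_s(self) -> float:
        return self.scans_per_run * self.tr

    @property
    def scans_per_condition_per_run(self) -> int:
        return self.blocks_per_condition_per_run * self.scans_per_block

    @property
    def scans_per_condition(self) -> int:
        """Scans per condition over the whole session (all runs)."""
        return self.scans_per_condition_per_run * self.n_runs


def make_design(spec: DesignSpec) -> list[list[str]]:
    """Build the scan-to-condition schedule, one list of labels per run.

    Within every block cycle the order of conditions is shuffled
    (deterministically from ``block_order_seed``), so each condition occurs
    exactly ``blocks_per_condition_per_run`` times per run and the schedule
    is balanced across runs and subjects.
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.block_order_seed))
    schedule: list[list[str]] = []
    for _ in range(spec.n_runs):
        run: list[str] = []
        for _ in range(spec.blocks_per_condition_per_run):
            order = rng.permutation(len(spec.conditions))
            for idx in order:
                run.extend([spec.conditions[idx]] * spec.scans_per_block)
        schedule.append(run)
    return schedule


@dataclass(frozen=True)
class PrecisionModel:
    """Sparse Gaussian-graphical target for one (group, condition) cell.

    ``support`` lists the unordered node pairs carrying true edges and
    ``target_partial_r`` the partial correlation each edge should have
    (a scalar applies to every pair).  Off-support partial correlations
    are exactly zero by construction.
    """

    n_nodes: int
    support: tuple[tuple[int, int], ...]
    target_partial_r: float | tuple[float, ...] = 0.3
    diagonal: float = 1.0

    def __post_init__(self) -> None:
        if self.diagonal <= 0:
            raise ValueError("diagonal must be positive")
        seen = set()
        for i, j in self.support:
            if not (0 <= i < self.n_nodes and 0 <= j < self.n_nodes) or i == j:
                raise ValueError(f"invalid support pair ({i}, {j})")
            key = (min(i, j), max(i, j))
            if key in seen:
                raise ValueError(f"duplicate support pair ({i}, {j})")
            seen.add(key)
        for r in self.targets():
            if not -1 < r < 1:
                raise ValueError(f"target partial r {r} outside (-1, 1)")

    def targets(self) -> tuple[float, ...]:
        if isinstance(self.target_partial_r, (int, float)):
            return tuple(float(self.target_partial_r) for _ in self.support)
        if len(self.target_partial_r) != len(self.support):
            raise ValueError("one target per support pair required")
        return tuple(float(r) for r in self.target_partial_r)


class InfeasiblePrecisionError(ValueError):
    """Targets cannot be realised as a positive-definite precision matrix."""


def build_precision(
    model: PrecisionModel,
    min_eigenvalue: float = 0.05,
    tolerance: float = 0.02,
) -> np.ndarray:
    """Construct an SPD precision matrix realising the model's targets.

    With unit diagonal, a precision ``Omega = I - R`` implies partial
    correlations ``rho_ij = -Omega_ij = R_ij``, so targets are met exactly
    whenever ``I - R`` already has smallest eigenvalue >= ``min_eigenvalue``.
    Otherwise the off-diagonals are uniformly shrunk by the largest factor
    ``s`` keeping the eigenvalue floor (equivalent to diagonal loading
    followed by renormalisation); if the implied partial correlations then
    deviate from their targets by more than ``tolerance`` the model is
    rejected with an explicit error rather than silently clipped.
    """
    n = model.n_nodes
    R = np.zeros((n, n))
    targets = model.targets()
    for (i, j), r in zip(model.support, targets):
        R[i, j] = R[j, i] = r

    if not model.support:
        return np.eye(n) * model.diagonal

    lam_max = float(np.linalg.eigvalsh(R)[-1])
    if lam_max <= 1.0 - min_eigenvalue:
        scale = 1.0
    else:
        scale = (1.0 - min_eigenvalue) / lam_max
        deviation = (1.0 - scale) * max(abs(r) for r in targets)
        if deviation > tolerance:
            raise InfeasiblePrecisionError(
                f"targets infeasible: uniform shrinkage to {scale:.3f} needed "
                f"for positive definiteness moves partial correlations by "
                f"{deviation:.3f} (> {tolerance})"
            )
    omega = (np.eye(n) - scale * R) * model.diagonal
    return omega


def implied_partial_correlations(omega: np.ndarray) -> np.ndarray:
    """Partial correlations of a precision matrix: -O_ij / sqrt(O_ii O_jj)."""
    d = np.sqrt(np.diag(omega))
    rho = -omega / np.outer(d, d)
    np.fill_diagonal(rho, 0.0)
    return rho


def model_covariance(model: PrecisionModel) -> np.ndarray:
    """Covariance implied by the model (inverse of its precision)."""
    return np.linalg.inv(build_precision(model))


@dataclass(frozen=True)
class CohortSpec:
    """Full two-group cohort: design, generative models, noise, and seed."""

    group_models: dict[tuple[str, str], PrecisionModel] = field(repr=False)
    n_per_group: int = 16
    design: DesignSpec = field(default_factory=DesignSpec)
    noise_sd: float = 1.0
    ar1_coefficient: float = 0.3
    task_amplitude: float = 1.0
    master_seed: int = 0
    node_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not 0 <= self.ar1_coefficient < 1:
            raise ValueError("ar1_coefficient must be in [0, 1)")
        sizes = {m.n_nodes for m in self.group_models.values()}
        if len(sizes) != 1:
            raise ValueError("all group models must share n_nodes")
        for group, condition in self.group_models:
            if group not in GROUPS:
                raise ValueError(f"unknown group '{group}'")
            if condition not in self.design.conditions:
                raise ValueError(f"condition '{condition}' not in design")

    @property
    def n_nodes(self) -> int:
        return next(iter(self.group_models.values())).n_nodes

    def conditions(self, group: str) -> list[str]:
        return sorted(
            {c for g, c in self.group_models if g == group},
            key=_CONDITION_CODE.get,
        )


def _ordered_support(n_nodes: int) -> list[tuple[tuple[int, int], int]]:
    """Deterministic edge order with SPD-friendly geometry.

    Edges are taken from ring bands: nearest neighbours first (positive
    sign), then second neighbours (negative sign), then third neighbours in
    a stride-3 rotation (positive sign).  Alternating band signs keep the
    spectral radius of the partial-correlation pattern low, so prefixes of
    this list stay feasible at realistic edge strengths (|r| ~ 0.3-0.45) up
    to roughly three bands of density.
    """
    out: list[tuple[tuple[int, int], int]] = []
    seen: set[tuple[int, int]] = set()

    def add(i: int, j: int, sign: int) -> None:
        key = (min(i % n_nodes, j % n_nodes), max(i % n_nodes, j % n_nodes))
        if key[0] != key[1] and key not in seen:
            seen.add(key)
            out.append((key, sign))

    for i in range(n_nodes):
        add(i, i + 1, +1)
    for i in range(n_nodes):
        add(i, i + 2, -1)
    stride_order: list[int] = []
    seen_start: set[int] = set()
    offset = 0
    while len(stride_order) < n_nodes:
        v = offset
        while v not in seen_start:
            seen_start.add(v)
            stride_order.append(v)
            v = (v + 3) % n_nodes
        offset += 1
    for i in stride_order:
        add(i, i + 3, +1)
    return out


def default_cohort(
    n_nodes: int = 12,
    master_seed: int = 0,
    n_per_group: int = 16,
    young_density: float | None = None,
    young_partial_r: float = 0.30,
    age_density_increment: float = 0.10,
    age_r_increment: float = 0.10,
    phase_density_increment: float = 0.02,
    phase_r_increment: float = 0.02,
    design: DesignSpec | None = None,
    noise_sd: float = 1.0,
    ar1_coefficient: float = 0.3,
    task_amplitude: float = 1.0,
    node_labels: tuple[str, ...] | None = None,
) -> CohortSpec:
    """Build the default aging-study cohort for a network of ``n_nodes``.

    Edge supports are nested prefixes of a single deterministic edge order
    (young subset of old, IP subset of AP), so the old group's networks have
    strictly larger support and |partial r| than the young group's.  The
    young baseline density defaults to a mean true degree of 2.4
    (``2.4 / (n_nodes - 1)``), which keeps the densest cell (old AP, at
    baseline + 0.12) inside the feasible region of the banded support
    geometry at the default edge strengths.
    """
    if young_density is None:
        young_density = 2.4 / (n_nodes - 1)
    order = _ordered_support(n_nodes)
    n_pairs_total = n_nodes * (n_nodes - 1) // 2

    def model(density: float, r: float) -> PrecisionModel:
        k = round(density * n_pairs_total)
        if k > len(order):
            raise InfeasiblePrecisionError(
                f"density {density:.3f} needs {k} edges; banded support "
                f"geometry provides only {len(order)} for n={n_nodes}"
            )
        pairs = tuple(p for p, _ in order[:k])
        signs = tuple(s for _, s in order[:k])
        return PrecisionModel(
            n_nodes=n_nodes,
            support=pairs,
            target_partial_r=tuple(s * r for s in signs),
        )

    cells = {
        ("young", "IP"): (young_density, young_partial_r),
        ("young", "AP"): (
            young_density + phase_density_increment,
            young_partial_r + phase_r_increment,
        ),
        ("old", "IP"): (
            young_density + age_density_increment,
            young_partial_r + age_r_increment,
        ),
        ("old", "AP"): (
            young_density + age_density_increment + phase_density_increment,
            young_partial_r + age_r_increment + phase_r_increment,
        ),
    }
    group_models = {key: model(d, r) for key, (d, r) in cells.items()}
    # fail fast if any cell's precision is infeasible
    for m in group_models.values():
        build_precision(m)
    return CohortSpec(
        group_models=group_models,
        n_per_group=n_per_group,
        design=design if design is not None else DesignSpec(),
        noise_sd=noise_sd,
        ar1_coefficient=ar1_coefficient,
        task_amplitude=task_amplitude,
        master_seed=master_seed,
        node_labels=node_labels,
    )


def _subject_rng(
    cohort: CohortSpec, group: str, subject_index: int, *extra: int
) -> np.random.Generator:
    """Counter-based per-subject stream: SeedSequence(master, group, subject)."""
    seq = np.random.SeedSequence(
        cohort.master_seed,
        spawn_key=(_GROUP_CODE[group], subject_index, *extra),
    )
    return np.random.default_rng(seq)


def simulate_subject(
    cohort: CohortSpec, group: str, subject_index: int
) -> dict[str, SubjectConditionSeries]:
    """Simulate one subject's per-condition concatenated epoch series.

    For each task condition the returned matrix holds the condition's
    epochs concatenated across runs (ROI x scan).  Within a run the series
    is a stationary AR(1)-filtered multivariate normal whose marginal
    covariance equals ``noise_sd^2`` times the inverse of the cell's
    precision matrix, plus a constant task offset of ``task_amplitude``.
    The AR(1) filter uses innovations scaled by ``sqrt(1 - phi^2)`` so
    temporal smoothing leaves the contemporaneous covariance (and thus the
    true partial correlations) untouched.
    """
    if group not in GROUPS:
        raise ValueError(f"unknown group '{group}'")
    if not 0 <= subject_index < cohort.n_per_group:
        raise ValueError(
            f"subject_index {subject_index} outside 0..{cohort.n_per_group - 1}"
        )
    phi = cohort.ar1_coefficient
    innov_scale = np.sqrt(1.0 - phi**2)
    n = cohort.n_nodes
    m = cohort.design.scans_per_condition_per_run
    subject_id = f"{group}{subject_index:02d}"

    out: dict[str, SubjectConditionSeries] = {}
    for condition in cohort.conditions(group):
        omega = build_precision(cohort.group_models[(group, condition)])
        sigma = np.linalg.inv(omega) * cohort.noise_sd**2
        chol = np.linalg.cholesky(sigma)
        rng = _subject_rng(
            cohort, group, subject_index, _CONDITION_CODE[condition]
        )
        runs = []
        for _ in range(cohort.design.n_runs):
            eps = chol @ rng.standard_normal((n, m))
            x = np.empty((n, m))
            x[:, 0] = eps[:, 0]
            for t in range(1, m):
                x[:, t] = phi * x[:, t - 1] + innov_scale * eps[:, t]
            runs.append(x)
        matrix = np.concatenate(runs, axis=1)
        if condition != "REST":
            matrix = matrix + cohort.task_amplitude
        out[condition] = SubjectConditionSeries(
            subject_id=subject_id,
            group=group,
            condition=condition,
            matrix=matrix,
            node_labels=list(cohort.node_labels)
            if cohort.node_labels is not None
            else None,
        )
    return out


def simulate_kinematics(
    cohort: CohortSpec,
    group: str,
    subject_index: int,
    condition: str,
    connectivity_summary: float | None = None,
    coupling: float = 0.0,
) -> tuple[float, float]:
    """Draw (phase error, SD of relative phase) in degrees for one subject.

    Population parameters depend only on the condition (AP harder than IP),
    never on the group — the cohorts are performance-matched by design.  If
    ``connectivity_summary`` is given, ``coupling`` times that value is
    added to both outcomes, providing a linear brain-behaviour link for
    correlation analyses (coupling 0 leaves the outcomes independent of
    connectivity).
    """
    if condition not in KINEMATIC_PARAMS:
        raise ValueError(f"condition must be one of {TASK_CONDITIONS}")
    params = KINEMATIC_PARAMS[condition]
    rng = _subject_rng(
        cohort, group, subject_index, 7, _CONDITION_CODE[condition]
    )
    shift = 0.0
    if connectivity_summary is not None:
        shift = coupling * float(connectivity_summary)
    error = params["error_mean"] + shift + params["error_sd"] * rng.standard_normal()
    sd = params["sd_mean"] + shift + params["sd_sd"] * rng.standard_normal()
    return float(error), float(sd)


def write_cohort(cohort: CohortSpec, out_dir: str | Path) -> Path:
    """Write the cohort as per-subject TSV matrices plus a JSON manifest.

    Each subject x condition series goes to
    ``<group><idx>_<condition>.tsv`` (ROI x scan, node labels as header);
    the manifest records the design, seeds, and ground-truth support so
    recovery analyses can be run against the emitted files alone.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    labels = (
        list(cohort.node_labels)
        if cohort.node_labels is not None
        else [f"roi{i:02d}" for i in range(cohort.n_nodes)]
    )
    files = []
    for group in GROUPS:
        if not cohort.conditions(group):
            continue
        for idx in range(cohort.n_per_group):
            for condition, series in simulate_subject(cohort, group, idx).items():
                name = f"{series.subject_id}_{condition}.tsv"
                header = "\t".join(labels)
                np.savetxt(
                    out_dir / name,
                    series.matrix,
                    delimiter="\t",
                    header=header,
                    comments="",
                    fmt="%.6f",
                )
                files.append(name)
    manifest = {
        "master_seed": cohort.master_seed,
        "n_per_group": cohort.n_per_group,
        "noise_sd": cohort.noise_sd,
        "ar1_coefficient": cohort.ar1_coefficient,
        "task_amplitude": cohort.task_amplitude,
        "design": asdict(cohort.design),
        "node_labels": labels,
        "files": files,
        "ground_truth": {
            f"{group}:{condition}": {
                "support": [list(p) for p in model.support],
                "target_partial_r": list(model.targets()),
            }
            for (group, condition), model in sorted(cohort.group_models.items())
        },
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out_dir / "manifest.json"


def read_cohort(cohort_dir: str | Path) -> tuple[CohortSpec, dict[tuple[str, int, str], np.ndarray]]:
    """Load a cohort written by :func:`write_cohort`.

    Returns the reconstructed :class:`CohortSpec` (ground-truth models
    included) and a mapping ``(group, subject_index, condition) -> matrix``
    of the stored ROI x scan series.
    """
    cohort_dir = Path(cohort_dir)
    manifest = json.loads((cohort_dir / "manifest.json").read_text())
    models = {}
    for key, truth in manifest["ground_truth"].items():
        group, condition = key.split(":")
        models[(group, condition)] = PrecisionModel(
            n_nodes=len(manifest["node_labels"]),
            support=tuple(tuple(p) for p in truth["support"]),
            target_partial_r=tuple(truth["target_partial_r"]),
        )
    spec = CohortSpec(
        group_models=models,
        n_per_group=manifest["n_per_group"],
        design=DesignSpec(**manifest["design"]),
        noise_sd=manifest["noise_sd"],
        ar1_coefficient=manifest["ar1_coefficient"],
        task_amplitude=manifest["task_amplitude"],
        master_seed=manifest["master_seed"],
        node_labels=tuple(manifest["node_labels"]),
    )
    series: dict[tuple[str, int, str], np.ndarray] = {}
    for name in manifest["files"]:
        stem = Path(name).stem  # e.g. old03_AP
        subject_id, condition = stem.rsplit("_", 1)
        group = "old" if subject_id.startswith("old") else "young"
        idx = int(subject_id[len(group):])
        series[(group, idx, condition)] = np.loadtxt(
            cohort_dir / name, delimiter="\t", skiprows=1
        )
    return spec, series
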