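"""Group-level statistics: split-plot ANOVA, interhemispheric strength,
Tukey post hoc tests, and brain-behaviour correlations.

The central test is a 2 x 2 mixed (split-plot) ANOVA with a
between-subjects factor AGE (old / young — different people) and a
within-subjects factor PHASE (AP / IP — both performed by every subject).
AGE is tested against the between-subject error stratum
(subjects-within-groups), PHASE and the AGE x PHASE interaction against
the subject x phase stratum.  Sums of squares are computed exactly for
the balanced design and the decomposition
``SS_total = SS_between_subjects + SS_within`` holds to machine precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .connectivity import NetworkGraph
from .node_atlas import NodeTable, interhemispheric_pairs

__all__ = [
    "AnovaResult",
    "SplitPlotAnova",
    "split_plot_anova",
    "mixed_anova",
    "interhemispheric_strength",
    "tukey_posthoc",
    "kinematics_correlations",
]

EFFECTS = ("AGE", "PHASE", "AGE:PHASE")


@dataclass(frozen=True)
class AnovaResult:
    """One tested effect: F ratio, degrees of freedom, and p-value."""

    effect: str
    F: float
    df_num: int
    df_den: int
    p: float


@dataclass(frozen=True)
class SplitPlotAnova:
    """Full split-plot decomposition of one measure.

    Holds the three effect tests plus the two error strata (needed by the
    Tukey post hoc machinery) and the cell means.
    """

    results: dict[str, AnovaResult]
    ms_subjects_within: float
    df_subjects_within: int
    ms_error_within: float
    df_error_within: int
    cell_means: dict[tuple[str, str], float]
    n_per_group: int
    ss_components: dict[str, float]

    def __getitem__(self, effect: str) -> AnovaResult:
        return self.results[effect]


def _f_test(ss_num: float, df_num: int, ms_den: float, df_den: int, effect: str
            ) -> AnovaResult:
    ms_num = ss_num / df_num
    if ms_den <= 0:
        # degenerate noiseless design: flag as infinite F unless the
        # numerator is also null
        if math.isclose(ms_num, 0.0, abs_tol=1e-12):
            return AnovaResult(effect, 0.0, df_num, df_den, 1.0)
        return AnovaResult(effect, float("inf"), df_num, df_den, 0.0)
    F = ms_num / ms_den
    p = float(stats.f.sf(F, df_num, df_den))
    return AnovaResult(effect, float(F), df_num, df_den, p)


def split_plot_anova(values: np.ndarray,
                     groups: tuple[str, ...] = ("old", "young"),
                     conditions: tuple[str, ...] = ("AP", "IP"),
                     ) -> SplitPlotAnova:
    """Split-plot ANOVA on a (group x subject x condition) value array.

    ``values[g, s, c]`` is subject ``s`` of group ``g`` under condition
    ``c``; the design must be complete and balanced (equal subjects per
    group, every subject measured in every condition).
    """
    y = np.asarray(values, dtype=float)
    if y.ndim != 3:
        raise ValueError("values must be (group, subject, condition)")
    a, n, b = y.shape
    if a != len(groups) or b != len(conditions):
        raise ValueError("array shape does not match factor levels")
    if a < 2 or b < 2 or n < 2:
        raise ValueError("need >= 2 groups, >= 2 conditions, >= 2 subjects")
    if not np.all(np.isfinite(y)):
        raise ValueError("missing or non-finite cells in the design")

    grand = y.mean()
    ss_total = float(((y - grand) ** 2).sum())

    subj_means = y.mean(axis=2)                       # (a, n)
    ss_between_subj = float(b * ((subj_means - grand) ** 2).sum())
    group_means = y.mean(axis=(1, 2))                 # (a,)
    ss_age = float(n * b * ((group_means - grand) ** 2).sum())
    ss_subj_within = ss_between_subj - ss_age
    df_subj_within = a * (n - 1)

    cond_means = y.mean(axis=(0, 1))                  # (b,)
    ss_phase = float(a * n * ((cond_means - grand) ** 2).sum())
    cell_means = y.mean(axis=1)                       # (a, b)
    interaction = (
        cell_means
        - group_means[:, None]
        - cond_means[None, :]
        + grand
    )
    ss_interaction = float(n * (interaction ** 2).sum())
    ss_error_within = (
        ss_total - ss_between_subj - ss_phase - ss_interaction
    )
    df_error_within = a * (n - 1) * (b - 1)

    ms_subj = ss_subj_within / df_subj_within
    ms_err = ss_error_within / df_error_within

    results = {
        "AGE": _f_test(ss_age, a - 1, ms_subj, df_subj_within, "AGE"),
        "PHASE": _f_test(ss_phase, b - 1, ms_err, df_error_within, "PHASE"),
        "AGE:PHASE": _f_test(
            ss_interaction, (a - 1) * (b - 1), ms_err, df_error_within,
            "AGE:PHASE",
        ),
    }
    return SplitPlotAnova(
        results=results,
        ms_subjects_within=ms_subj,
        df_subjects_within=df_subj_within,
        ms_error_within=ms_err,
        df_error_within=df_error_within,
        cell_means={
            (g, c): float(cell_means[gi, ci])
            for gi, g in enumerate(groups)
            for ci, c in enumerate(conditions)
        },
        n_per_group=n,
        ss_components={
            "total": ss_total,
            "between_subjects": ss_between_subj,
            "AGE": ss_age,
            "subjects_within_groups": ss_subj_within,
            "PHASE": ss_phase,
            "AGE:PHASE": ss_interaction,
            "error_within": ss_error_within,
        },
    )


def _records_to_array(records: pd.DataFrame,
                      groups: tuple[str, ...],
                      conditions: tuple[str, ...]) -> np.ndarray:
    required = {"subject", "group", "condition", "value"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"records missing columns {sorted(missing)}")
    dup = records.duplicated(subset=["subject", "condition"])
    if dup.any():
        raise ValueError(
            "duplicate (subject, condition) rows: "
            f"{records.loc[dup, 'subject'].tolist()}"
        )
    wide = records.pivot(index="subject", columns="condition", values="value")
    incomplete = wide[wide[list(conditions)].isna().any(axis=1)].index.tolist() \
        if set(conditions) <= set(wide.columns) else wide.index.tolist()
    if incomplete:
        raise ValueError(f"subjects with missing cells: {incomplete}")
    subj_group = records.groupby("subject")["group"].agg(set)
    if any(len(g) != 1 for g in subj_group):
        raise ValueError("a subject appears in more than one group")
    subj_group = subj_group.map(lambda s: next(iter(s)))
    counts = subj_group.value_counts()
    if set(counts.index) != set(groups):
        raise ValueError(f"expected groups {groups}, found {list(counts.index)}")
    if counts.nunique() != 1:
        raise ValueError(f"unbalanced groups: {counts.to_dict()}")
    n = int(counts.iloc[0])
    y = np.empty((len(groups), n, len(conditions)))
    for gi, g in enumerate(groups):
        subjects = sorted(subj_group[subj_group == g].index)
        for si, subj in enumerate(subjects):
            for ci, c in enumerate(conditions):
                y[gi, si, ci] = wide.loc[subj, c]
    return y


def mixed_anova(records: pd.DataFrame,
                groups: tuple[str, ...] = ("old", "young"),
                conditions: tuple[str, ...] = ("AP", "IP"),
                ) -> SplitPlotAnova:
    """Split-plot ANOVA from long-format records.

    ``records`` needs columns ``subject, group, condition, value`` with one
    row per subject x condition; the design must be complete and balanced.
    """
    y = _records_to_array(records, groups, conditions)
    return split_plot_anova(y, groups=groups, conditions=conditions)


def interhemispheric_strength(graph: NetworkGraph, table: NodeTable) -> float:
    """Mean weight of valid edges crossing between the hemispheres.

    Considers only node pairs whose endpoints carry different hemisphere
    labels; returns NaN (missing, not zero) when no crossing edge exists.
    """
    if graph.n_nodes != table.n_nodes:
        raise ValueError(
            f"graph has {graph.n_nodes} nodes, table {table.n_nodes}"
        )
    pairs = interhemispheric_pairs(table)
    weights = [
        graph.weights[i, j] for i, j in pairs if graph.binary[i, j]
    ]
    if not weights:
        return float("nan")
    return float(np.mean(weights))


def tukey_posthoc(records: pd.DataFrame,
                  comparisons: list[tuple[tuple[str, str], tuple[str, str]]]
                  | None = None,
                  groups: tuple[str, ...] = ("old", "young"),
                  conditions: tuple[str, ...] = ("AP", "IP"),
                  ) -> pd.DataFrame:
    """Tukey HSD over the four AGE x PHASE cell means.

    Studentized-range p-values with k = 4 means.  Within-group comparisons
    (same subjects under two conditions) use the subject x phase error
    stratum; between-group comparisons use the Winer pooled error
    ``(MS_subjects + MS_within) / 2`` with Satterthwaite degrees of
    freedom, since they mix both variance components.
    """
    anova = mixed_anova(records, groups=groups, conditions=conditions)
    cells = [(g, c) for g in groups for c in conditions]
    if comparisons is None:
        comparisons = [
            (cells[i], cells[j])
            for i in range(len(cells))
            for j in range(i + 1, len(cells))
        ]
    k = len(cells)
    n = anova.n_per_group
    ms_w, df_w = anova.ms_error_within, anova.df_error_within
    ms_s, df_s = anova.ms_subjects_within, anova.df_subjects_within

    rows = []
    for cell_a, cell_b in comparisons:
        for cell in (cell_a, cell_b):
            if cell not in anova.cell_means:
                raise ValueError(f"unknown cell {cell}")
        diff = anova.cell_means[cell_a] - anova.cell_means[cell_b]
        if cell_a[0] == cell_b[0]:  # same group: pure within-subject contrast
            ms_err, df_err = ms_w, df_w
        else:
            ms_err = (ms_s + ms_w) / 2.0
            if ms_s > 0 or ms_w > 0:
                df_err = (ms_s + ms_w) ** 2 / (
                    ms_s**2 / df_s + ms_w**2 / df_w
                )
            else:
                df_err = df_s + df_w
        se = math.sqrt(ms_err / n)
        if se == 0:
            q = 0.0 if math.isclose(diff, 0.0, abs_tol=1e-12) else float("inf")
            p = 1.0 if q == 0.0 else 0.0
        else:
            q = abs(diff) / se
            p = float(stats.studentized_range.sf(q, k, df_err))
        rows.append(
            {
                "cell_a": f"{cell_a[0]}/{cell_a[1]}",
                "cell_b": f"{cell_b[0]}/{cell_b[1]}",
                "mean_diff": diff,
                "q": q,
                "df": df_err,
                "p_adj": min(p, 1.0),
            }
        )
    return pd.DataFrame(rows)


def kinematics_correlations(metrics: pd.DataFrame,
                            kinematics: pd.DataFrame,
                            alpha_sig: float = 0.01) -> pd.DataFrame:
    """Pearson correlations between network measures and kinematic outcomes.

    ``metrics`` is long format (``subject, group, condition, measure,
    value``); ``kinematics`` has one row per subject x condition with
    columns ``phase_error`` and ``phase_sd``.  One correlation is computed
    per (measure, kinematic, group, condition) over pairwise-complete
    subjects; correlations with p below ``alpha_sig`` are flagged.  The
    number of evaluated correlations is implicit in the row count, so
    readers can apply their own multiplicity correction.
    """
    kin_cols = ["phase_error", "phase_sd"]
    merged = metrics.merge(
        kinematics, on=["subject", "group", "condition"], how="inner"
    )
    rows = []
    for (measure, group, condition), chunk in merged.groupby(
        ["measure", "group", "condition"], sort=True
    ):
        for kin in kin_cols:
            sub = chunk[["value", kin]].dropna()
            note = ""
            if len(sub) < 3:
                r, p = float("nan"), float("nan")
                note = "fewer than 3 complete pairs"
            elif sub["value"].nunique() == 1 or sub[kin].nunique() == 1:
                r, p = float("nan"), float("nan")
                note = "zero variance"
            else:
                r, p = stats.pearsonr(sub["value"], sub[kin])
            rows.append(
                {
                    "measure": measure,
                    "kinematic": kin,
                    "group": group,
                    "condition": condition,
                    "n": len(sub),
                    "R": float(r),
                    "p": float(p),
                    "significant": bool(p < alpha_sig)
                    if np.isfinite(p)
                    else False,
                    "note": note,
                }
            )
    return pd.DataFrame(rows)
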