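"""End-to-end orchestration: simulate -> connect -> measure -> test -> report.

A single declarative YAML config drives the whole analysis; every run is
deterministic given its master seed, and each output table carries the
config hash in a header comment so results can always be traced back to
the exact configuration that produced them.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .connectivity import PRESET_ALPHAS, partial_correlation, threshold
from .extraction import detrend
from .graph_metrics import network_metrics, nodal_metrics
from .group_stats import (
    interhemispheric_strength,
    kinematics_correlations,
    mixed_anova,
    tukey_posthoc,
)
from .node_atlas import packaged_node_table
from .synthetic_data import (
    GROUPS,
    default_cohort,
    read_cohort,
    simulate_kinematics,
    simulate_subject,
    write_cohort,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "ConfigError", "validate_config", "run_pipeline", "RunReport"]

#: network measures entered into the per-alpha ANOVA sweep
ANOVA_MEASURES = (
    "cluster_coefficient",
    "degree",
    "density",
    "efficiency",
    "path_length",
    "betweenness",
    "connection_strength",
    "swn_cluster_coefficient",
    "swn_path_length",
)


class ConfigError(ValueError):
    """Aggregated, human-readable configuration problems."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("; ".join(errors))


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    network: str
    out_dir: str
    n_per_group: int = 16
    master_seed: int = 0
    alphas: tuple[float, ...] = PRESET_ALPHAS
    primary_alpha: float = 0.001
    avt_method: str = "mean"
    signed_weights: bool = True
    detrend_order: int = 1
    data_dir: str | None = None

    def to_dict(self) -> dict:
        d = asdict(self)
        d["alphas"] = list(self.alphas)
        return d

    def config_hash(self) -> str:
        canonical = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


_CONFIG_FIELDS = {
    "network": str,
    "out_dir": str,
    "n_per_group": int,
    "master_seed": int,
    "alphas": list,
    "primary_alpha": float,
    "avt_method": str,
    "signed_weights": bool,
    "detrend_order": int,
    "data_dir": str,
}
_REQUIRED_FIELDS = ("network", "out_dir")


def validate_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML run config, aggregating all errors."""
    path = Path(path)
    if not path.exists():
        raise ConfigError([f"config file not found: {path}"])
    raw = yaml.safe_load(path.read_text())
    errors: list[str] = []
    if raw is None:
        raise ConfigError(
            [f"missing required fields: {', '.join(_REQUIRED_FIELDS)}"]
        )
    if not isinstance(raw, dict):
        raise ConfigError(["config must be a YAML mapping"])

    unknown = sorted(set(raw) - set(_CONFIG_FIELDS))
    for key in unknown:
        errors.append(f"unknown key '{key}'")
    missing = [k for k in _REQUIRED_FIELDS if k not in raw]
    if missing:
        errors.append(f"missing required fields: {', '.join(missing)}")

    values: dict = {}
    for key, expected in _CONFIG_FIELDS.items():
        if key not in raw:
            continue
        value = raw[key]
        if expected is float and isinstance(value, int):
            value = float(value)
        if expected is int and isinstance(value, bool):
            errors.append(f"'{key}' must be an integer")
            continue
        if not isinstance(value, expected):
            errors.append(
                f"'{key}' must be {expected.__name__}, got "
                f"{type(value).__name__}"
            )
            continue
        values[key] = value

    if "network" in values and values["network"] not in ("N1", "N2"):
        errors.append("'network' must be 'N1' or 'N2'")
    if "n_per_group" in values and values["n_per_group"] < 2:
        errors.append("'n_per_group' must be >= 2")
    if "avt_method" in values and values["avt_method"] not in (
        "mean",
        "eigenvariate",
    ):
        errors.append("'avt_method' must be 'mean' or 'eigenvariate'")
    if "detrend_order" in values and values["detrend_order"] not in (0, 1):
        errors.append("'detrend_order' must be 0 or 1")
    if "data_dir" in values and not Path(values["data_dir"]).is_dir():
        errors.append(f"'data_dir' is not a directory: {values['data_dir']}")
    if "alphas" in values:
        try:
            alphas = tuple(float(a) for a in values["alphas"])
        except (TypeError, ValueError):
            errors.append("'alphas' must be a list of numbers")
            alphas = ()
        if alphas and not all(0 < a < 1 for a in alphas):
            errors.append("every alpha must lie in (0, 1)")
        elif alphas:
            if list(alphas) != sorted(alphas):
                logger.warning("alphas were not ascending; normalising order")
                alphas = tuple(sorted(alphas))
            values["alphas"] = alphas
    if "primary_alpha" in values or "alphas" in values:
        primary = values.get("primary_alpha", 0.001)
        alphas = values.get("alphas", PRESET_ALPHAS)
        if isinstance(alphas, tuple) and alphas and primary not in alphas:
            errors.append(
                f"primary_alpha {primary} must be one of the run alphas"
            )

    if errors:
        raise ConfigError(errors)
    return RunConfig(**values)


def cohort_network_metrics(
    cohort,
    alphas: tuple[float, ...] = (0.001,),
    detrend_order: int = 0,
) -> pd.DataFrame:
    """Network-level metrics for every subject x condition x alpha of a cohort.

    Lightweight sweep used for recovery/power studies: simulates each
    subject, estimates the partial-correlation matrix, thresholds at every
    alpha, and returns one row of network means per subject x condition x
    alpha.
    """
    rows = []
    for group in GROUPS:
        if not cohort.conditions(group):
            continue
        for idx in range(cohort.n_per_group):
            for condition, series in simulate_subject(cohort, group, idx).items():
                X = detrend(series.matrix, order=detrend_order)
                pcm = partial_correlation(X)
                for alpha in alphas:
                    net = network_metrics(threshold(pcm, alpha))
                    rows.append(
                        {
                            "subject": series.subject_id,
                            "group": group,
                            "condition": condition,
                            "alpha": alpha,
                            **net.to_dict(),
                        }
                    )
    return pd.DataFrame(rows)


@dataclass
class RunReport:
    """Paths and headline tables of a completed run."""

    out_dir: Path
    manifest: dict
    network_metrics: pd.DataFrame
    anova: pd.DataFrame
    edge_counts: pd.DataFrame
    interhemispheric: pd.DataFrame
    correlations: pd.DataFrame
    tables: dict[str, Path] = field(default_factory=dict)


def _write_table(df: pd.DataFrame, path: Path, config_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config_hash}\n")
        df.to_csv(fh, index=False, lineterminator="\n")


def run_pipeline(config: RunConfig, write_cohort_files: bool = False) -> RunReport:
    """Execute the full analysis for one config and write all tables.

    Stages: synthesise the cohort for the configured node atlas; estimate
    each subject x condition partial-correlation matrix; threshold at every
    alpha; compute nodal/network metrics; run the AGE x PHASE ANOVA per
    measure and alpha; run the interhemispheric-strength sub-analysis with
    Tukey post hoc tests at the primary alpha; correlate network measures
    with simulated kinematics.  Any stage failure aborts with the stage
    and subject/condition named.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    alphas = tuple(sorted(config.alphas))

    table = packaged_node_table(config.network)
    stored_series = None
    if config.data_dir is not None:
        cohort, stored_series = read_cohort(config.data_dir)
        if cohort.n_nodes != table.n_nodes:
            raise RuntimeError(
                f"stage=load data_dir holds {cohort.n_nodes}-node series but "
                f"network {config.network} has {table.n_nodes} nodes"
            )
    else:
        cohort = default_cohort(
            n_nodes=table.n_nodes,
            master_seed=config.master_seed,
            n_per_group=config.n_per_group,
            node_labels=tuple(table.labels),
        )
    if write_cohort_files and stored_series is None:
        write_cohort(cohort, out_dir / "cohort")

    network_rows: list[dict] = []
    nodal_rows: list[dict] = []
    edge_rows: list[dict] = []
    inter_rows: list[dict] = []
    kin_rows: list[dict] = []

    for group in GROUPS:
        for idx in range(cohort.n_per_group):
            t0 = time.perf_counter()
            try:
                if stored_series is None:
                    series_by_cond = simulate_subject(cohort, group, idx)
                else:
                    from .extraction import SubjectConditionSeries

                    series_by_cond = {
                        cond: SubjectConditionSeries(
                            subject_id=f"{group}{idx:02d}",
                            group=group,
                            condition=cond,
                            matrix=stored_series[(group, idx, cond)],
                            node_labels=list(cohort.node_labels),
                        )
                        for cond in cohort.conditions(group)
                    }
            except Exception as exc:
                raise RuntimeError(
                    f"stage=load subject={group}{idx:02d}: {exc}"
                ) from exc
            for condition, series in series_by_cond.items():
                stage = f"subject={series.subject_id} condition={condition}"
                try:
                    X = detrend(series.matrix, order=config.detrend_order)
                    pcm = partial_correlation(X)
                    pcm.node_labels = series.node_labels
                except Exception as exc:
                    raise RuntimeError(f"stage=connectivity {stage}: {exc}") from exc
                error, sd = simulate_kinematics(cohort, group, idx, condition)
                kin_rows.append(
                    {
                        "subject": series.subject_id,
                        "group": group,
                        "condition": condition,
                        "phase_error": error,
                        "phase_sd": sd,
                    }
                )
                for alpha in alphas:
                    try:
                        graph = threshold(
                            pcm, alpha, signed_weights=config.signed_weights
                        )
                        net = network_metrics(graph)
                        nodal = nodal_metrics(graph)
                    except Exception as exc:
                        raise RuntimeError(
                            f"stage=metrics {stage} alpha={alpha}: {exc}"
                        ) from exc
                    meta = {
                        "subject": series.subject_id,
                        "group": group,
                        "condition": condition,
                        "alpha": alpha,
                    }
                    edge_rows.append({**meta, "n_edges": net.n_edges})
                    network_rows.append({**meta, **net.to_dict()})
                    ndf = nodal.to_frame()
                    for record in ndf.to_dict("records"):
                        nodal_rows.append({**meta, **record})
                    if alpha == config.primary_alpha:
                        inter_rows.append(
                            {
                                **meta,
                                "interhemispheric_strength": (
                                    interhemispheric_strength(graph, table)
                                ),
                            }
                        )
                logger.info(
                    "stage=analyze subject=%s condition=%s wall=%.3fs",
                    series.subject_id,
                    condition,
                    time.perf_counter() - t0,
                )

    network_df = pd.DataFrame(network_rows)
    nodal_df = pd.DataFrame(nodal_rows)
    edge_df = pd.DataFrame(edge_rows)
    inter_df = pd.DataFrame(inter_rows)
    kin_df = pd.DataFrame(kin_rows).drop_duplicates(
        subset=["subject", "condition"]
    )

    # ANOVA per measure: F at the primary alpha, p at every alpha
    anova_rows: list[dict] = []
    for measure in ANOVA_MEASURES:
        for effect in ("AGE", "PHASE", "AGE:PHASE"):
            row: dict = {"measure": measure, "effect": effect}
            for alpha in alphas:
                chunk = network_df[network_df["alpha"] == alpha][
                    ["subject", "group", "condition", measure]
                ].rename(columns={measure: "value"})
                if chunk["value"].isna().any():
                    f_val, p_val, dfs = float("nan"), float("nan"), ""
                else:
                    res = mixed_anova(chunk)[effect]
                    f_val, p_val = res.F, res.p
                    dfs = f"{res.df_num}, {res.df_den}"
                if alpha == config.primary_alpha:
                    row["df"] = dfs
                    row["F"] = f_val
                row[f"p_{alpha:g}"] = p_val
            anova_rows.append(row)
    anova_df = pd.DataFrame(anova_rows)

    # interhemispheric sub-analysis at the primary alpha
    inter_records = inter_df.rename(
        columns={"interhemispheric_strength": "value"}
    )[["subject", "group", "condition", "value"]]
    if inter_records["value"].isna().any():
        n_miss = int(inter_records["value"].isna().sum())
        logger.warning(
            "interhemispheric ANOVA skipped: %d subject-conditions without "
            "crossing edges",
            n_miss,
        )
        inter_anova_df = pd.DataFrame(
            [{"note": f"skipped: {n_miss} missing subject-conditions"}]
        )
        tukey_df = pd.DataFrame()
    else:
        res = mixed_anova(inter_records)
        inter_anova_df = pd.DataFrame(
            [
                {
                    "effect": effect,
                    "F": res[effect].F,
                    "df_num": res[effect].df_num,
                    "df_den": res[effect].df_den,
                    "p": res[effect].p,
                }
                for effect in ("AGE", "PHASE", "AGE:PHASE")
            ]
        )
        tukey_df = tukey_posthoc(inter_records)

    # brain-behaviour correlations at the primary alpha
    metrics_long = network_df[network_df["alpha"] == config.primary_alpha].melt(
        id_vars=["subject", "group", "condition"],
        value_vars=list(ANOVA_MEASURES),
        var_name="measure",
        value_name="value",
    )
    corr_df = kinematics_correlations(metrics_long, kin_df)

    tables = {}
    for name, df in [
        ("edge_counts", edge_df),
        ("network_metrics", network_df),
        ("nodal_metrics", nodal_df),
        ("anova", anova_df),
        ("interhemispheric", inter_df),
        ("interhemispheric_anova", inter_anova_df),
        ("tukey", tukey_df),
        ("correlations", corr_df),
        ("kinematics", kin_df),
    ]:
        path = out_dir / f"{name}.csv"
        _write_table(df, path, chash)
        tables[name] = path

    manifest = {
        "config": config.to_dict(),
        "config_hash": chash,
        "version": __version__,
        "master_seed": config.master_seed,
        "n_nodes": table.n_nodes,
        "conventions": {
            "avt_method": config.avt_method,
            "signed_weights": config.signed_weights,
            "edge_test": "two-sided t, df = n_samples - N",
            "betweenness": "unordered pairs, unnormalised",
            "unreachable_pairs": "excluded from nodal path length",
            "clustering_degree_lt_2": 0.0,
            "scan_exchangeability": "no autocorrelation correction",
        },
        "tables": {k: str(v.name) for k, v in tables.items()},
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)

    return RunReport(
        out_dir=out_dir,
        manifest=manifest,
        network_metrics=network_df,
        anova=anova_df,
        edge_counts=edge_df,
        interhemispheric=inter_df,
        correlations=corr_df,
        tables=tables,
    )
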