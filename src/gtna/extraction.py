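"""ROI average time series (AVT) extraction and epoch handling.

Bridges voxel- or ROI-level BOLD data and connectivity estimation: collapse
an ROI's voxels to a single representative time course, pull out the scans
belonging to one task condition, and remove linear drift.

Two AVT definitions are implemented because the literature uses both for
the same quantity: the element-wise voxel mean and the first eigenvariate
of the voxel-by-scan matrix.  The default is ``mean``; the choice is
recorded in pipeline output metadata so results are unambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

__all__ = [
    "SubjectConditionSeries",
    "extract_avt",
    "select_condition_epochs",
    "detrend",
]


@dataclass
class SubjectConditionSeries:
    """ROI x scan matrix for one subject and condition.

    ``matrix`` rows follow the vertex order of ``node_labels`` (one label
    per ROI).  Downstream partial-correlation estimation requires more
    scans than ROIs, which is enforced here.
    """

    subject_id: str
    group: str
    condition: str
    matrix: np.ndarray
    node_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("matrix must be 2-D (ROI x scan)")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError(
                f"{self.subject_id}/{self.condition}: matrix contains "
                "non-finite values"
            )
        n_rois, n_scans = self.matrix.shape
        if n_scans <= n_rois:
            raise ValueError(
                f"{self.subject_id}/{self.condition}: need more scans "
                f"({n_scans}) than ROIs ({n_rois}) for partial correlations"
            )
        if self.node_labels is not None and len(self.node_labels) != n_rois:
            raise ValueError(
                f"{self.subject_id}/{self.condition}: {len(self.node_labels)} "
                f"labels for {n_rois} ROIs"
            )

    @property
    def n_rois(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_scans(self) -> int:
        return self.matrix.shape[1]


def extract_avt(voxel_matrix: np.ndarray, method: str = "mean") -> np.ndarray:
    """Collapse a voxel x scan matrix to one representative series.

    ``mean`` averages voxels element-wise.  ``eigenvariate`` projects onto
    the first left singular direction, scales the projection to the
    root-mean-square amplitude of the input matrix, and flips its sign if
    needed so that it correlates non-negatively with the voxel mean.
    """
    X = np.asarray(voxel_matrix, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[0] < 1 or X.shape[1] < 2:
        raise ValueError("need at least 1 voxel and 2 scans")

    if method == "mean":
        return X.mean(axis=0)
    if method == "eigenvariate":
        if np.allclose(X, X.flat[0]):
            raise ValueError(
                "eigenvariate undefined for an all-constant voxel matrix"
            )
        _, s, vt = np.linalg.svd(X, full_matrices=False)
        series = vt[0]
        rms_x = np.sqrt(np.mean(X**2))
        rms_series = np.sqrt(np.mean(series**2))
        series = series * (rms_x / rms_series)
        mean_series = X.mean(axis=0)
        # sign-align with the voxel mean; SVD sign is arbitrary
        centered = series - series.mean()
        mean_centered = mean_series - mean_series.mean()
        if float(centered @ mean_centered) < 0:
            series = -series
        return series
    raise ValueError(f"unknown AVT method '{method}'")


def _flat_schedule(schedule: list[list[str]]) -> list[str]:
    return [cond for run in schedule for cond in run]


def select_condition_epochs(
    series: np.ndarray, schedule: list[list[str]], condition: str
) -> np.ndarray:
    """Concatenate the scans labelled ``condition`` across all runs.

    ``schedule`` is the per-run scan-to-condition map produced by
    :func:`gtna.synthetic_data.make_design`; its total length must equal
    the number of scans in ``series``.  Run order and within-run scan
    order are preserved, so the selected columns partition across the
    conditions of the schedule.
    """
    X = np.asarray(series, dtype=float)
    labels = _flat_schedule(schedule)
    n_scans = X.shape[-1]
    if len(labels) != n_scans:
        raise ValueError(
            f"schedule covers {len(labels)} scans but series has {n_scans}"
        )
    if condition not in labels:
        raise ValueError(f"condition '{condition}' absent from schedule")
    mask = np.array([lab == condition for lab in labels])
    return X[..., mask]


def detrend(series: np.ndarray, order: int = 1) -> np.ndarray:
    """Remove the per-ROI least-squares linear trend (order 1) or nothing.

    Order 1 subtracts each row's best-fitting straight line (slope and
    intercept), order 0 returns a copy unchanged.  This is the only drift
    filter offered; scanner-specific whitening pipelines are upstream of
    this package.
    """
    X = np.asarray(series, dtype=float)
    if order == 0:
        return X.copy()
    if order == 1:
        return signal.detrend(X, axis=-1, type="linear")
    raise ValueError(f"detrend order must be 0 or 1, got {order}")
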