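"""Temporal conditioning of ROI time series and motion-based quality control.

The pipeline consumes node-by-time signal matrices already extracted from a
parcellation; everything spatial (realignment, normalisation, smoothing)
happens upstream and is out of scope here.  This module covers the temporal
part of a standard resting-state preprocessing chain:

* discarding initial volumes acquired before magnetisation equilibrium,
* Friston-24 expansion of rigid-body motion parameters,
* ordinary-least-squares nuisance regression,
* zero-phase Butterworth band-pass filtering,
* Power-style frame-wise displacement and mean-FD subject exclusion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal as sps
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import ConfigError, InputError

logger = logging.getLogger(__name__)

DEFAULT_HEAD_RADIUS_MM = 50.0


@dataclass
class RoiTimeSeries:
    """One subject's node-by-time signal matrix.

    Parameters
    ----------
    subject_id : str
        Cohort-unique identifier.
    data : ndarray of shape (n_nodes, n_timepoints)
        Regional signal values; rows follow ``node_ids``.
    tr_seconds : float
        Sampling interval (repetition time) in seconds.
    node_ids : list of str
        Ordered node identifiers, one per row of ``data``.
    """

    subject_id: str
    data: np.ndarray
    tr_seconds: float
    node_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise InputError("data must be a 2-D node-by-time matrix")
        if not self.node_ids:
            self.node_ids = [f"n{i}" for i in range(self.data.shape[0])]
        if len(self.node_ids) != self.data.shape[0]:
            raise InputError(
                f"node_ids length {len(self.node_ids)} does not match "
                f"node count {self.data.shape[0]}"
            )
        if not np.all(np.isfinite(self.data)):
            raise InputError("data contains missing or non-finite values")
        if not self.tr_seconds > 0:
            raise ConfigError("tr_seconds must be positive")

    @property
    def n_nodes(self) -> int:
        return self.data.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]


@dataclass
class MotionParams:
    """Rigid-body realignment parameters for one subject.

    ``data`` has one row per acquired volume and six columns: three
    translations in millimetres followed by three rotations in radians.
    """

    subject_id: str
    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[1] != 6:
            raise InputError(
                f"motion parameters must have exactly 6 columns, got shape "
                f"{self.data.shape}"
            )
        if not np.all(np.isfinite(self.data)):
            raise InputError("motion parameters contain non-finite values")


def discard_initial_volumes(ts: RoiTimeSeries, n_discard: int) -> RoiTimeSeries:
    """Drop the first ``n_discard`` time points (equilibration volumes)."""
    if n_discard < 0:
        raise InputError("n_discard must be non-negative")
    if n_discard >= ts.n_timepoints:
        raise InputError(
            f"n_discard={n_discard} >= available time points {ts.n_timepoints}"
        )
    return replace(ts, data=ts.data[:, n_discard:].copy())


def framewise_displacement(
    motion: MotionParams, head_radius_mm: float = DEFAULT_HEAD_RADIUS_MM
) -> np.ndarray:
    """Per-frame head displacement (Power backward-difference formula).

    FD(t) = sum of absolute translation differences plus ``head_radius_mm``
    times the sum of absolute rotation differences between frames t-1 and t;
    the first frame has FD 0 by convention.  Rotations are converted to arc
    length on a sphere of the given radius (50 mm default).
    """
    if motion.data.shape[0] < 2:
        raise InputError("need at least 2 frames to compute displacement")
    diffs = np.abs(np.diff(motion.data, axis=0))
    fd = diffs[:, :3].sum(axis=1) + head_radius_mm * diffs[:, 3:].sum(axis=1)
    return np.concatenate([[0.0], fd])


def exclude_high_motion(
    manifest: pd.DataFrame,
    fd_summaries: dict[str, float],
    threshold_mm: float = 1.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition a cohort manifest by the mean-FD exclusion rule.

    Subjects whose mean frame-wise displacement exceeds ``threshold_mm``
    (1 mm default) are excluded.  Returns ``(retained, excluded)``; the
    excluded frame gains ``mean_fd`` and ``exclusion_reason`` columns.
    """
    missing = [s for s in manifest["subject_id"] if s not in fd_summaries]
    if missing:
        raise InputError(f"missing FD summary for subject(s): {missing}")
    mean_fd = manifest["subject_id"].map(fd_summaries)
    mask = mean_fd > threshold_mm
    excluded = manifest[mask].copy()
    excluded["mean_fd"] = mean_fd[mask]
    excluded["exclusion_reason"] = [
        f"mean FD {v:.3f} mm > {threshold_mm:g} mm" for v in mean_fd[mask]
    ]
    for sid, reason in zip(excluded["subject_id"], excluded["exclusion_reason"]):
        logger.warning("excluding %s: %s", sid, reason)
    return manifest[~mask].copy(), excluded


def friston24(motion: MotionParams) -> np.ndarray:
    """Expand 6 rigid-body parameters into the Friston 24-regressor set.

    Column blocks: [P, P^2, P_lag1, P_lag1^2], six columns each, with the
    lag-1 block zero-padded at the first frame.
    """
    p = motion.data
    if p.shape[0] < 2:
        raise InputError("need at least 2 frames for the lag-1 expansion")
    lag = np.vstack([np.zeros(6), p[:-1]])
    return np.hstack([p, p**2, lag, lag**2])


def nuisance_regress(ts: RoiTimeSeries, regressors: np.ndarray | None) -> RoiTimeSeries:
    """Regress nuisance signals out of every node's series (OLS residuals).

    The design is ``[intercept | regressors]``; an empty regressor set thus
    reduces to per-node demeaning.  A rank-deficient design is solved in the
    least-norm sense with a logged warning; residual orthogonality to the
    design columns holds either way.
    """
    t = ts.n_timepoints
    if regressors is None or (hasattr(regressors, "size") and regressors.size == 0):
        design = np.ones((t, 1))
    else:
        regressors = np.asarray(regressors, dtype=float)
        if regressors.ndim == 1:
            regressors = regressors[:, None]
        if regressors.shape[0] != t:
            raise InputError(
                f"regressor rows {regressors.shape[0]} != time points {t}"
            )
        if not np.all(np.isfinite(regressors)):
            raise InputError("regressors contain non-finite values")
        design = np.column_stack([np.ones(t), regressors])
    coef, _, rank, _ = np.linalg.lstsq(design, ts.data.T, rcond=None)
    if rank < design.shape[1]:
        logger.warning(
            "rank-deficient nuisance design for %s (rank %d < %d); "
            "using least-norm solution",
            ts.subject_id, rank, design.shape[1],
        )
    resid = ts.data.T - design @ coef
    return replace(ts, data=resid.T)


def bandpass(ts: RoiTimeSeries, low_hz: float, high_hz: float) -> RoiTimeSeries:
    """Zero-phase Butterworth band-pass, applied forward-backward per node.

    A 4th-order design run through ``filtfilt`` (no phase distortion, the
    effective magnitude response is squared).  ``low_hz = 0`` degrades to a
    low-pass; the DC component is removed in every case.
    """
    nyquist = 0.5 / ts.tr_seconds
    if not (0 <= low_hz < high_hz < nyquist):
        raise ConfigError(
            f"band ({low_hz}, {high_hz}) Hz invalid for Nyquist {nyquist} Hz"
        )
    demeaned = ts.data - ts.data.mean(axis=1, keepdims=True)
    if low_hz == 0:
        sos = sps.butter(4, high_hz, btype="lowpass", fs=1.0 / ts.tr_seconds,
                         output="sos")
    else:
        sos = sps.butter(4, [low_hz, high_hz], btype="bandpass",
                         fs=1.0 / ts.tr_seconds, output="sos")
    filtered = sps.sosfiltfilt(sos, demeaned, axis=1)
    filtered = filtered - filtered.mean(axis=1, keepdims=True)
    return replace(ts, data=filtered)


class SignalConditioner(BaseEstimator, TransformerMixin):
    """Temporal-conditioning transformer: discard, nuisance-regress, filter.

    Stateless in the sklearn sense (``fit`` only validates); ``transform``
    maps a list of :class:`RoiTimeSeries` to conditioned copies.  Motion
    regressors (Friston-24) and extra nuisance columns (global/CSF/WM) are
    supplied per subject at transform time.

    Parameters
    ----------
    n_discard : int, default 4
        Initial volumes dropped before any other step.
    low_hz, high_hz : float, defaults 0.01 and 0.10
        Band-pass edges in Hz.
    order : tuple of str
        Step order among {"discard", "regress", "bandpass"}; the default
        regresses before filtering so filtered-out nuisance variance is not
        reintroduced.
    """

    def __init__(
        self,
        n_discard: int = 4,
        low_hz: float = 0.01,
        high_hz: float = 0.10,
        order: tuple[str, ...] = ("discard", "regress", "bandpass"),
    ):
        self.n_discard = n_discard
        self.low_hz = low_hz
        self.high_hz = high_hz
        self.order = order

    def fit(self, X, y=None):
        allowed = {"discard", "regress", "bandpass"}
        if set(self.order) - allowed or len(set(self.order)) != len(self.order):
            raise ConfigError(f"order must be a permutation drawn from {allowed}")
        self.n_features_in_ = len(X) if hasattr(X, "__len__") else 0
        return self

    def transform_one(
        self,
        ts: RoiTimeSeries,
        motion: MotionParams | None = None,
        extra_regressors: np.ndarray | None = None,
    ) -> RoiTimeSeries:
        """Condition a single subject's series."""
        out = ts
        for step in self.order:
            if step == "discard":
                out = discard_initial_volumes(out, self.n_discard)
            elif step == "regress":
                out = nuisance_regress(
                    out, self._build_design(out, ts, motion, extra_regressors)
                )
            elif step == "bandpass":
                out = bandpass(out, self.low_hz, self.high_hz)
        return out

    def transform(self, X, motions=None, extra_regressors=None):
        motions = motions or [None] * len(X)
        extras = extra_regressors or [None] * len(X)
        return [
            self.transform_one(ts, m, e) for ts, m, e in zip(X, motions, extras)
        ]

    def _build_design(self, current, original, motion, extra):
        cols = []
        if motion is not None:
            cols.append(friston24(motion))
        if extra is not None:
            cols.append(np.asarray(extra, dtype=float))
        if not cols:
            return None
        design = np.hstack(cols)
        if design.shape[0] == original.n_timepoints != current.n_timepoints:
            # regressors were tabulated per acquired volume; align them with
            # the post-discard series
            design = design[original.n_timepoints - current.n_timepoints:]
        if design.shape[0] != current.n_timepoints:
            raise InputError(
                f"regressor rows {design.shape[0]} do not match the "
                f"{current.n_timepoints}-point series for {current.subject_id}"
            )
        return design
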