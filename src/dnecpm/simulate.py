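"""Synthetic cohorts with a known, planted connectivity-score relation.

Real resting-state cohorts of this kind are rarely shared, so every stage of
the pipeline is exercised against generated data whose ground truth is known
exactly.  Two generation modes are provided:

``generate_dne_direct``
    Samples dnE matrices directly.  Entries are drawn in Fisher-z space,
    ``z = mu + b * s_i + eps`` for planted node pairs (``eps ~ N(0, sigma^2)``,
    ``s_i`` the subject's standardised score) and ``z = mu + eps`` otherwise,
    then mapped through ``tanh`` so every entry respects the correlation
    range by construction.  This isolates the prediction stage: the planted
    slope is recoverable in closed form (the dnE-score correlation is
    ``b / sqrt(b^2 + sigma^2)``).

``generate_cohort_timeseries``
    Builds node-by-time series whose *windowed* connectivity co-fluctuates:
    each planted pair gets two slow latent modulators; one node's coupling
    to a shared community signal follows the first modulator and the other
    node's follows a score-dependent mixture of both, so the synchrony of
    their efficiency fluctuations — hence the dnE entry — increases with the
    subject's score.  This exercises the full window/graph/correlation path.

Reproducibility: a single cohort seed is expanded into independent
substreams — ``default_rng([seed, 0])`` for the score draw and
``default_rng([seed, 1, i])`` for subject i — so any subject can be
regenerated in isolation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

from .conditioning import RoiTimeSeries
from .errors import ConfigError
from .network import DnEMatrix

# depth of the coupling-amplitude modulation around its unit baseline; the
# clip floor keeps couplings positive when a modulator swings low
_MODULATION_DEPTH = 1.5
_COUPLING_FLOOR = 0.05


@dataclass(frozen=True)
class SyntheticConfig:
    """Cohort-generation settings.

    Defaults emulate the acquisition the pipeline targets: 62 subjects,
    246 nodes, 240 time points at TR = 2 s, scores on a UPDRS-III-like
    0-70 scale.  ``effect_size`` is the planted slope in Fisher-z units per
    standardised score unit; ``baseline_z_mean``/``noise_sd`` set the
    Fisher-z location and dispersion of ordinary (non-planted) entries;
    ``modulator_smoothness`` is the low-pass cutoff (Hz) of the latent
    modulators in the time-series mode — the 0.005 Hz default gives
    connectivity states lasting a few minutes, slower than the 100 s
    analysis window, as sliding-window estimation requires.
    """

    n_subjects: int = 62
    n_nodes: int = 246
    n_timepoints: int = 240
    tr_seconds: float = 2.0
    score_range: tuple[float, float] = (10.0, 70.0)
    signal_pairs: tuple[tuple[int, int], ...] = ()
    effect_size: float = 0.0
    baseline_z_mean: float = 0.3
    noise_sd: float = 0.3
    modulator_smoothness: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ConfigError("n_subjects must be >= 1")
        if self.n_nodes < 3:
            raise ConfigError("n_nodes must be >= 3")
        if self.n_timepoints < 8:
            raise ConfigError("n_timepoints must be >= 8")
        if self.tr_seconds <= 0:
            raise ConfigError("tr_seconds must be positive")
        lo, hi = self.score_range
        if not lo < hi:
            raise ConfigError("score_range min must be < max")
        for p, q in self.signal_pairs:
            if not (0 <= p < q < self.n_nodes):
                raise ConfigError(
                    f"signal_pairs entry ({p}, {q}) invalid: need 0 <= i < j < n_nodes"
                )
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be positive")
        if self.modulator_smoothness <= 0:
            raise ConfigError("modulator_smoothness must be positive")
        nyq = 0.5 / self.tr_seconds
        if self.modulator_smoothness >= nyq:
            raise ConfigError(
                f"modulator_smoothness must be below the Nyquist rate {nyq} Hz"
            )


@dataclass
class SyntheticTruth:
    """Planted ground truth accompanying a generated cohort.

    ``scores`` has one column per prediction target (``medication_off``
    drawn uniformly over the configured range; ``medication_on`` its halved
    counterpart, emulating the typical post-levodopa improvement); both
    standardise to the same latent ``standardized_score`` the plant used.
    """

    scores: pd.DataFrame
    standardized_score: np.ndarray
    signal_pairs: tuple[tuple[int, int], ...]
    effect_size: float
    seed: int


def _score_rng(config: SyntheticConfig) -> np.random.Generator:
    return np.random.default_rng([config.seed, 0])

def _subject_rng(config: SyntheticConfig, i: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, 1, i])


def _draw_truth(config: SyntheticConfig) -> SyntheticTruth:
    rng = _score_rng(config)
    lo, hi = config.score_range
    off = rng.uniform(lo, hi, config.n_subjects)
    sd = off.std()
    s_tilde = (off - off.mean()) / sd if sd > 0 else np.zeros_like(off)
    scores = pd.DataFrame({
        "medication_off": off,
        "medication_on": 0.5 * off,
    })
    return SyntheticTruth(scores=scores, standardized_score=s_tilde,
                          signal_pairs=tuple(config.signal_pairs),
                          effect_size=config.effect_size, seed=config.seed)


def generate_dne_direct(config: SyntheticConfig) -> tuple[list[DnEMatrix], SyntheticTruth]:
    """Sample per-subject dnE matrices with the plant applied in Fisher-z space."""
    truth = _draw_truth(config)
    n = config.n_nodes
    iu, ju = np.triu_indices(n, k=1)
    pair_pos = {(p, q): k for k, (p, q) in enumerate(zip(iu.tolist(), ju.tolist()))}
    signal_idx = [pair_pos[pq] for pq in config.signal_pairs]
    node_ids = [f"n{i}" for i in range(n)]
    mats = []
    for i in range(config.n_subjects):
        rng = _subject_rng(config, i)
        z = config.baseline_z_mean + rng.normal(0.0, config.noise_sd, iu.size)
        if signal_idx:
            z[signal_idx] += config.effect_size * truth.standardized_score[i]
        mat = np.eye(n)
        vals = np.tanh(z)
        mat[iu, ju] = vals
        mat[ju, iu] = vals
        mats.append(DnEMatrix(data=mat, node_ids=list(node_ids)))
    return mats, truth


def _smooth_modulator(rng: np.random.Generator, n: int, cutoff_hz: float,
                      tr: float) -> np.ndarray:
    """Unit-variance low-pass-filtered Gaussian noise (a slow latent drive)."""
    raw = rng.standard_normal(n)
    sos = sps.butter(4, cutoff_hz, btype="lowpass", fs=1.0 / tr, output="sos")
    m = sps.sosfiltfilt(sos, raw)
    m = m - m.mean()
    sd = m.std()
    return m / sd if sd > 0 else m


def generate_cohort_timeseries(
    config: SyntheticConfig, window_length_hint: int = 50
) -> tuple[list[RoiTimeSeries], SyntheticTruth]:
    """Build node-by-time series whose windowed connectivity carries the plant.

    ``window_length_hint`` is the window length intended downstream; the
    series must span at least two windows for dynamics to be estimable.
    """
    if config.n_timepoints < 2 * window_length_hint:
        raise ConfigError(
            f"n_timepoints={config.n_timepoints} too small: need at least "
            f"2 x window length ({2 * window_length_hint})"
        )
    truth = _draw_truth(config)
    T, n = config.n_timepoints, config.n_nodes
    alpha = (1.0 + np.tanh(config.effect_size * truth.standardized_score)) / 2.0
    signal_nodes = {node for pq in config.signal_pairs for node in pq}
    subjects = []
    for i in range(config.n_subjects):
        rng = _subject_rng(config, i)
        community = rng.standard_normal(T)
        coupling = np.empty((n, T))
        # static community coupling for ordinary nodes
        static_w = rng.uniform(0.4, 0.8, n)
        coupling[:] = static_w[:, None]
        for p, q in config.signal_pairs:
            m1 = _smooth_modulator(rng, T, config.modulator_smoothness,
                                   config.tr_seconds)
            m2 = _smooth_modulator(rng, T, config.modulator_smoothness,
                                   config.tr_seconds)
            mq = alpha[i] * m1 + np.sqrt(max(0.0, 1.0 - alpha[i] ** 2)) * m2
            coupling[p] = np.clip(1.0 + _MODULATION_DEPTH * m1,
                                  _COUPLING_FLOOR, None)
            coupling[q] = np.clip(1.0 + _MODULATION_DEPTH * mq,
                                  _COUPLING_FLOOR, None)
        noise = rng.standard_normal((n, T))
        data = coupling * community[None, :] + noise
        # ordinary nodes keep unit total variance: w*c + sqrt(1-w^2)*eta
        ordinary = np.array([j not in signal_nodes for j in range(n)])
        data[ordinary] = (
            static_w[ordinary, None] * community[None, :]
            + np.sqrt(1.0 - static_w[ordinary, None] ** 2) * noise[ordinary]
        )
        subjects.append(RoiTimeSeries(
            subject_id=f"sub-{i:03d}", data=data, tr_seconds=config.tr_seconds,
            node_ids=[f"n{k}" for k in range(n)],
        ))
    return subjects, truth


def write_cohort(out_dir: str | Path, subjects: list[RoiTimeSeries],
                 truth: SyntheticTruth) -> Path:
    """Write a generated cohort in the formats the real pipeline reads.

    Produces one time-series TSV per subject, a cohort manifest CSV with
    both score columns, and a truth JSON; returns the manifest path.
    """
    from .io import write_timeseries

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for ts, (_, score_row) in zip(subjects, truth.scores.iterrows()):
        path = out_dir / f"{ts.subject_id}_timeseries.tsv"
        write_timeseries(path, ts)
        rows.append({
            "subject_id": ts.subject_id,
            "timeseries_path": path.name,
            "motion_path": "",
            "updrs_off": score_row["medication_off"],
            "updrs_on": score_row["medication_on"],
        })
    manifest_path = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest_path, index=False)
    truth_path = out_dir / "truth.json"
    truth_path.write_text(json.dumps({
        "signal_pairs": [list(pq) for pq in truth.signal_pairs],
        "effect_size": truth.effect_size,
        "seed": truth.seed,
        "scores": {c: truth.scores[c].tolist() for c in truth.scores.columns},
    }, indent=2, sort_keys=True))
    return manifest_path
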