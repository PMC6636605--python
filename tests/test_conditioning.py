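"""Temporal conditioning and motion quality control."""

import numpy as np
import pandas as pd
import pytest

from dnecpm import (InputError, MotionParams, SignalConditioner, bandpass,
                    discard_initial_volumes, exclude_high_motion,
                    framewise_displacement, friston24, nuisance_regress)
from dnecpm.errors import ConfigError
from tests.conftest import make_ts


class TestDiscardInitialVolumes:
    def test_removes_leading_volumes(self, rng):
        ts = make_ts(rng.standard_normal((4, 240)))
        out = discard_initial_volumes(ts, 4)
        assert out.n_timepoints == 236
        assert np.array_equal(out.data, ts.data[:, 4:])
        assert out.node_ids == ts.node_ids

    def test_zero_discard_is_identity(self, random_ts):
        out = discard_initial_volumes(random_ts, 0)
        assert np.array_equal(out.data, random_ts.data)

    def test_discarding_everything_is_an_error(self, rng):
        ts = make_ts(rng.standard_normal((3, 5)))
        with pytest.raises(InputError):
            discard_initial_volumes(ts, 5)


class TestFramewiseDisplacement:
    def test_constant_motion_gives_zero(self):
        motion = MotionParams("s", np.ones((50, 6)) * 0.3)
        assert np.all(framewise_displacement(motion) == 0)

    def test_translation_step(self):
        data = np.zeros((10, 6))
        data[5:, 0] = 1.0  # 1 mm x-translation from frame 5 on
        fd = framewise_displacement(MotionParams("s", data))
        assert fd[5] == pytest.approx(1.0)
        assert fd[0] == 0.0
        assert np.all(np.delete(fd, 5) == 0)

    def test_rotation_step_scales_with_head_radius(self):
        data = np.zeros((10, 6))
        data[5:, 4] = 0.02  # 0.02 rad about one axis
        fd = framewise_displacement(MotionParams("s", data), head_radius_mm=50.0)
        assert fd[5] == pytest.approx(1.0)  # 50 mm * 0.02 rad

    def test_invariant_to_constant_offset(self, rng):
        base = rng.normal(0, 0.1, (40, 6))
        shifted = base + rng.normal(0, 1, 6)
        fd0 = framewise_displacement(MotionParams("s", base))
        fd1 = framewise_displacement(MotionParams("s", shifted))
        assert np.allclose(fd0, fd1)

    def test_wrong_column_count_rejected(self):
        with pytest.raises(InputError):
            MotionParams("s", np.zeros((10, 5)))


class TestExcludeHighMotion:
    @staticmethod
    def _manifest(n):
        return pd.DataFrame({
            "subject_id": [f"sub-{i:03d}" for i in range(n)],
            "timeseries_path": [f"sub-{i:03d}.tsv" for i in range(n)],
            "updrs_off": 40.0, "updrs_on": 20.0,
        })

    def test_cohort_partition(self):
        manifest = self._manifest(62)
        fd = {s: 0.33 for s in manifest["subject_id"]}
        for s in list(fd)[:4]:
            fd[s] = 1.5
        retained, excluded = exclude_high_motion(manifest, fd, 1.0)
        assert len(retained) == 58
        assert len(excluded) == 4
        assert all("mean FD" in r for r in excluded["exclusion_reason"])

    def test_infinite_threshold_retains_all(self):
        manifest = self._manifest(5)
        fd = {s: 10.0 for s in manifest["subject_id"]}
        retained, excluded = exclude_high_motion(manifest, fd, np.inf)
        assert len(retained) == 5 and len(excluded) == 0

    def test_typical_cohort_motion_not_excluded(self):
        manifest = self._manifest(10)
        fd = {s: 0.33 for s in manifest["subject_id"]}
        retained, _ = exclude_high_motion(manifest, fd, 1.0)
        assert len(retained) == 10

    def test_missing_summary_names_subject(self):
        manifest = self._manifest(3)
        fd = {"sub-000": 0.1, "sub-002": 0.1}
        with pytest.raises(InputError, match="sub-001"):
            exclude_high_motion(manifest, fd, 1.0)


class TestFriston24:
    def test_block_structure(self, rng):
        p = rng.standard_normal((30, 6))
        out = friston24(MotionParams("s", p))
        assert out.shape == (30, 24)
        assert np.array_equal(out[:, :6], p)
        assert np.array_equal(out[:, 6:12], p**2)
        assert np.array_equal(out[1:, 12:18], p[:-1])
        assert np.all(out[0, 12:] == 0)

    def test_zero_motion_gives_zero_regressors(self):
        out = friston24(MotionParams("s", np.zeros((10, 6))))
        assert np.all(out == 0)

    def test_single_value_placement(self):
        p = np.zeros((10, 6))
        p[3, 2] = 0.5
        out = friston24(MotionParams("s", p))
        assert out[3, 2 + 6] == pytest.approx(0.25)
        assert out[4, 2 + 12] == pytest.approx(0.5)
        assert out[4, 2 + 18] == pytest.approx(0.25)


class TestNuisanceRegress:
    def test_no_regressors_demeans(self, random_ts):
        out = nuisance_regress(random_ts, None)
        assert np.allclose(out.data, random_ts.data
                           - random_ts.data.mean(axis=1, keepdims=True))

    def test_perfect_fit_gives_zero_residual(self, rng):
        reg = rng.standard_normal((80, 1))
        ts = make_ts(np.tile(reg.T, (3, 1)))
        out = nuisance_regress(ts, reg)
        assert np.allclose(out.data, 0, atol=1e-10)

    def test_residuals_orthogonal_to_design(self, rng):
        ts = make_ts(rng.standard_normal((5, 100)))
        reg = rng.standard_normal((100, 7))
        out = nuisance_regress(ts, reg)
        inner = out.data @ reg
        scale = np.linalg.norm(out.data) * np.linalg.norm(reg)
        assert np.max(np.abs(inner)) / scale < 1e-8

    def test_idempotent(self, rng):
        ts = make_ts(rng.standard_normal((4, 90)))
        reg = rng.standard_normal((90, 5))
        once = nuisance_regress(ts, reg)
        twice = nuisance_regress(once, reg)
        assert np.allclose(once.data, twice.data, atol=1e-10)

    def test_row_mismatch_rejected(self, random_ts, rng):
        with pytest.raises(InputError):
            nuisance_regress(random_ts, rng.standard_normal((50, 2)))


class TestBandpass:
    def test_removes_dc(self):
        ts = make_ts(np.full((3, 200), 7.5))
        out = bandpass(ts, 0.01, 0.10)
        assert np.allclose(out.data, 0, atol=1e-8)

    def test_passband_sinusoid_preserved(self):
        t = np.arange(400) * 2.0
        sine = np.sin(2 * np.pi * 0.05 * t)
        out = bandpass(make_ts(sine[None, :]), 0.01, 0.10)
        # compare amplitude away from filter edge effects
        mid = slice(50, 350)
        ratio = out.data[0, mid].std() / sine[mid].std()
        assert abs(ratio - 1.0) < 0.05

    def test_stopband_sinusoid_attenuated(self):
        t = np.arange(400) * 2.0
        sine = np.sin(2 * np.pi * 0.2 * t)
        out = bandpass(make_ts(sine[None, :]), 0.01, 0.10)
        assert out.data[0].std() / sine.std() < 0.2

    def test_band_must_respect_nyquist(self, random_ts):
        with pytest.raises(ConfigError):
            bandpass(random_ts, 0.01, 0.30)  # Nyquist at TR=2 s is 0.25 Hz
        with pytest.raises(ConfigError):
            bandpass(random_ts, 0.10, 0.05)


def test_full_chain_preserves_node_order(rng):
    ts = make_ts(rng.standard_normal((8, 160)), subject_id="sub-007")
    motion = MotionParams("sub-007", rng.normal(0, 0.05, (160, 6)))
    out = SignalConditioner(n_discard=4).transform_one(ts, motion)
    assert out.node_ids == ts.node_ids
    assert out.n_nodes == ts.n_nodes
    assert out.n_timepoints == 156
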