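"""Task design, driving inputs and GLM regressors."""

import numpy as np
import pandas as pd
import pytest

import bidcm
from bidcm.paradigm import (CONDITIONS, DesignConfig, TaskDesign, Trial,
                            canonical_hrf, dct_highpass_basis)


class TestBuildDesign:
    @pytest.mark.parametrize("seed", [0, 1, 17, 202])
    def test_condition_counts_and_counterbalancing(self, seed):
        d = bidcm.build_design(seed=seed)
        assert len(d.trials) == 16
        assert all(n == 4 for n in d.condition_counts().values())
        # each block of four trials holds each condition exactly once
        for b in range(4):
            block = {t.condition for t in d.trials[4 * b:4 * b + 4]}
            assert block == set(CONDITIONS)

    def test_timings_match_the_paradigm(self):
        d = bidcm.build_design(seed=1)
        for t in d.trials:
            assert t.encoding_duration == 3.5
            assert t.probe_duration == 1.4
            assert t.fixation_duration == 0.8
            assert t.isi in (0.358, 0.716, 1.074, 1.432, 1.790)
            # the probe train spans 10 x (1.4 + 0.8) = 22 s
            assert t.retrieval_duration == pytest.approx(22.0)
        assert d.tr == 1.79

    def test_deterministic_for_fixed_seed(self):
        a = bidcm.build_design(seed=9)
        b = bidcm.build_design(seed=9)
        assert a == b
        assert a != bidcm.build_design(seed=10)

    def test_events_strictly_increasing_and_non_overlapping(self):
        d = bidcm.build_design(seed=4)
        ev = d.events_frame()
        onsets = ev["onset"].to_numpy()
        ends = onsets + ev["duration"].to_numpy()
        assert np.all(np.diff(onsets) > 0)
        assert np.all(ends[:-1] <= onsets[1:] + 1e-9)

    def test_session_too_short_raises_naming_trial(self):
        with pytest.raises(ValueError, match="trial"):
            bidcm.build_design(seed=1, n_scans=100)

    def test_events_tsv_round_trip(self, tmp_path):
        d = bidcm.build_design(seed=2)
        d.to_tsv(tmp_path / "events.tsv")
        ev = pd.read_csv(tmp_path / "events.tsv", sep="\t")
        assert list(ev.columns) == ["onset", "duration", "trial_type"]
        assert set(ev["trial_type"]) <= {
            "novel_enc", "novel_ret", "practiced_enc", "practiced_ret",
            "control_enc", "control_ret", "rest"}
        assert (ev["trial_type"] == "novel_enc").sum() == 4


def _single_trial_design(condition="novel", n_scans=40):
    cfg = DesignConfig()
    trial = Trial(condition=condition, encoding_onset=3.58,
                  encoding_duration=3.5, isi=1.074,
                  probe_onsets=tuple(3.58 + 3.5 + 1.074 + k * 2.2
                                     for k in range(10)),
                  probe_duration=1.4, fixation_duration=0.8)
    return TaskDesign(trials=(trial,), tr=1.79, n_scans=n_scans, seed=0,
                      config=cfg)


class TestDesignToInputs:
    def test_rest_only_design_has_zero_inputs(self):
        d = _single_trial_design("rest")
        u = bidcm.design_to_inputs(d).u
        assert not np.any(u)

    def test_on_time_matches_event_durations(self):
        d = _single_trial_design("novel")
        inp = bidcm.design_to_inputs(d)
        assert abs(inp.on_time("EN") - 3.5) <= inp.dt
        assert abs(inp.on_time("RN") - 22.0) <= inp.dt
        assert inp.on_time("EP") == 0.0
        assert inp.on_time("RP") == 0.0

    @pytest.mark.parametrize("seed", [0, 3, 11])
    def test_on_time_full_design(self, seed):
        d = bidcm.build_design(seed=seed)
        inp = bidcm.design_to_inputs(d)
        for name, total in [("EN", 14.0), ("EP", 14.0),
                            ("RN", 88.0), ("RP", 88.0)]:
            assert abs(inp.on_time(name) - total) <= 4 * inp.dt

    def test_phases_are_disjoint(self, inputs):
        u = inputs.u
        assert not np.any(u[:, 0] * u[:, 2])  # EN and RN
        assert not np.any(u[:, 1] * u[:, 3])  # EP and RP

    def test_binary_values_and_default_dt(self, design, inputs):
        assert set(np.unique(inputs.u)) <= {0.0, 1.0}
        assert inputs.dt == pytest.approx(design.tr / 16)
        assert inputs.bins_per_scan == 16

    def test_dt_not_dividing_tr_raises(self, design):
        with pytest.raises(ValueError, match="divide"):
            bidcm.design_to_inputs(design, dt=0.5)


class TestRegressors:
    def test_eight_task_columns(self, design):
        R = bidcm.build_regressors(design)
        assert R.n_task == 8
        assert [n for n in R.names[:8]] == [
            "novel_enc", "novel_ret", "practiced_enc", "practiced_ret",
            "control_enc", "control_ret", "rest_enc", "rest_ret"]
        assert np.all(np.isfinite(R.X))
        assert R.names[-1] == "constant"

    def test_empty_design_gives_constant_only(self):
        d = TaskDesign(trials=(), tr=1.79, n_scans=20, seed=0)
        R = bidcm.build_regressors(d, include_confounds=False)
        assert R.n_task == 0
        assert R.names == ("constant",)

    def test_shift_invariance_by_whole_scans(self):
        k = 4
        d0 = _single_trial_design("novel", n_scans=60)
        t = d0.trials[0]
        shifted = Trial(condition=t.condition,
                        encoding_onset=t.encoding_onset + k * d0.tr,
                        encoding_duration=t.encoding_duration, isi=t.isi,
                        probe_onsets=tuple(p + k * d0.tr
                                           for p in t.probe_onsets),
                        probe_duration=t.probe_duration,
                        fixation_duration=t.fixation_duration)
        d1 = TaskDesign(trials=(shifted,), tr=d0.tr, n_scans=60, seed=0,
                        config=d0.config)
        X0 = bidcm.build_regressors(d0, include_confounds=False).X
        X1 = bidcm.build_regressors(d1, include_confounds=False).X
        np.testing.assert_allclose(X1[k:, :2], X0[:-k, :2], atol=1e-12)

    def test_retrieval_boxcar_support_matches_inputs(self):
        """The pre-convolution support of the RN regressor equals the RN
        input-column support."""
        d = _single_trial_design("novel")
        inp = bidcm.design_to_inputs(d)
        t = d.trials[0]
        mid = (np.arange(inp.n_bins) + 0.5) * inp.dt
        expected = ((mid >= t.retrieval_onset)
                    & (mid < t.retrieval_end)).astype(float)
        np.testing.assert_array_equal(inp.u[:, 2], expected)

    def test_dct_basis_spans_long_periods_only(self, design):
        dct = dct_highpass_basis(design.n_scans, design.tr, cutoff=128.0)
        total = design.n_scans * design.tr
        k_max = dct.shape[1]
        assert 2 * total / k_max > 128.0
        assert 2 * total / (k_max + 1) <= 128.0

    def test_hrf_against_nilearn_oracle(self):
        from nilearn.glm.first_level import spm_hrf
        dt = 0.1
        t = np.arange(0, 32, dt)
        mine = canonical_hrf(t)
        ref = spm_hrf(dt, oversampling=1, time_length=32.0)
        ref = ref / ref.max()
        n = min(mine.size, ref.size)
        r = np.corrcoef(mine[:n], ref[:n])[0, 1]
        assert r > 0.999
        assert abs(t[np.argmax(mine)] - 5.0) < 1.0  # peak near 5 s
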