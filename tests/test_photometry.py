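"""Photometry processing: detrending, alignment, binning, z-scoring, AUC, QC."""

import dataclasses

import numpy as np
import pytest

from socialfp import (
    AnimalResponse,
    EventList,
    PhotometryTrace,
    SimConfig,
    align_events,
    animal_mean_trace,
    area_under_curve,
    build_heatmap,
    detrend_isosbestic,
    extract_peri_event,
    qc_session,
    simulate_photometry_trace,
    zscore_peri_event,
)
from socialfp.photometry import PeriEventMatrix, PhotometryError


def make_trace(dff=None, fs=100.0, dur=30.0, t0=0.0):
    n = int(dur * fs)
    t = np.arange(n) / fs + t0
    s405 = 80.0 + 0.1 * np.sin(t)
    s465 = 2.0 * s405
    tr = PhotometryTrace(t=t, s465=s465, s405=s405, fs=fs)
    if dff is not None:
        tr = dataclasses.replace(tr, dff=np.broadcast_to(dff, t.shape).astype(float))
    return tr


def sim_trace(amps, cfg, bouts, seed=0):
    t, s465, s405, _ = simulate_photometry_trace(
        bouts, amps, cfg, np.random.default_rng(seed)
    )
    return PhotometryTrace(t=t, s465=s465, s405=s405, fs=cfg.fs_photo)


class TestDetrend:
    def test_perfect_fit_residual_zero(self):
        tr = detrend_isosbestic(make_trace())
        assert np.max(np.abs(tr.dff)) < 1e-12
        a, b = tr.fit_coef
        assert a == pytest.approx(2.0) and b == pytest.approx(0.0, abs=1e-9)

    def test_constant_control_rejected(self):
        t = np.arange(100) / 100.0
        tr = PhotometryTrace(t=t, s465=np.ones(100), s405=np.ones(100), fs=100.0)
        with pytest.raises(PhotometryError, match="degenerate"):
            detrend_isosbestic(tr)

    def test_removes_shared_motion_artifact(self, sim_config):
        """With zero transients, regressing out the 405 channel beats naive
        mean-normalization by at least the artifact/noise sd ratio."""
        cfg = dataclasses.replace(sim_config, motion_sd=4.0, noise_sd=0.5)
        tr = sim_trace({}, cfg, [], seed=5)
        det = detrend_isosbestic(tr)
        naive = (tr.s465 - tr.s465.mean()) / tr.s465.mean()
        ratio = np.std(naive) / np.std(det.dff)
        assert ratio >= cfg.motion_sd / cfg.noise_sd

    def test_recovers_transient_peak(self, quiet_config):
        """Noise-free single transient: post-fit peak dF/F within 5% of the
        injected peak amplitude."""
        amp = 1.3
        bouts = [{"stimulus": "social", "start": 150.0, "end": 155.0}]
        det = detrend_isosbestic(sim_trace({"social": amp}, quiet_config, bouts))
        assert np.max(det.dff) == pytest.approx(amp, rel=0.05)


class TestAlignEvents:
    def ev(self, onsets):
        onsets = np.asarray(onsets, dtype=float)
        return EventList(onsets, onsets + 1.0,
                         np.array(["social"] * len(onsets), dtype=object))

    def test_identity_and_pure_shift(self):
        tr = make_trace(dff=0.0)
        ev = self.ev([1.0, 5.0, 20.0])
        same = align_events(ev, tr)
        np.testing.assert_array_equal(same.onsets, ev.onsets)
        shifted = align_events(ev, tr, clock_offset=3.0)
        np.testing.assert_allclose(shifted.onsets, ev.onsets + 3.0)

    def test_out_of_range_events_dropped_and_counted(self):
        tr = make_trace(dff=0.0, dur=10.0)
        out = align_events(self.ev([1.0, 9.0, 50.0]), tr)
        assert out.onsets.size == 2 and out.n_dropped == 1
        with pytest.raises(PhotometryError):
            align_events(self.ev([50.0, 60.0]), tr)

    def test_generator_offset_round_trip(self, quiet_config):
        """A clock offset injected by the generator is undone by alignment:
        the peri-event peak lands in the same bin as with zero offset."""
        bouts = [{"stimulus": "social", "start": 100.0, "end": 106.0}]
        peaks = []
        for offset in (0.0, 2.5):
            cfg = dataclasses.replace(quiet_config, clock_offset=offset)
            det = detrend_isosbestic(sim_trace({"social": 2.0}, cfg, bouts))
            ev = align_events(self.ev([100.0]), det, clock_offset=offset)
            mat = extract_peri_event(det, ev)
            peaks.append(np.argmax(mat.values[0]))
        assert peaks[0] == peaks[1]


class TestExtractPeriEvent:
    def test_constant_dff_rows_constant(self):
        tr = make_trace(dff=0.7)
        mat = extract_peri_event(tr, TestAlignEvents().ev([5.0, 10.0]))
        assert mat.values.shape == (2, 70)
        np.testing.assert_allclose(mat.values, 0.7, atol=1e-12)
        np.testing.assert_allclose(mat.centers[0], -1.95)
        np.testing.assert_allclose(mat.centers[-1], 4.95)

    def test_incomplete_baseline_excluded(self):
        tr = make_trace(dff=0.0, dur=30.0)
        mat = extract_peri_event(tr, TestAlignEvents().ev([1.0, 10.0]))
        assert mat.values.shape[0] == 1
        assert mat.n_excluded_window == 1

    def test_empty_event_list(self):
        tr = make_trace(dff=0.0)
        mat = extract_peri_event(tr, EventList(np.array([]), np.array([]),
                                               np.array([], dtype=object)))
        assert mat.values.shape == (0, 70)

    def test_matches_direct_summation_oracle(self, rng):
        fs = 100.0
        n = int(40 * fs)
        t = np.arange(n) / fs
        dff = rng.standard_normal(n)
        tr = dataclasses.replace(make_trace(dur=40.0), dff=dff)
        onsets = np.sort(rng.uniform(3.0, 34.0, 12))
        ev = EventList(onsets, onsets + 1.0,
                       np.array(["social"] * 12, dtype=object))
        mat = extract_peri_event(tr, ev)
        for row, onset in zip(mat.values, mat.onsets):
            for j in range(70):
                lo = onset - 2.0 + 0.1 * j
                sel = (t >= lo - 1e-9) & (t < lo + 0.1 - 1e-9)
                assert row[j] == pytest.approx(dff[sel].mean(), abs=1e-9)

    def test_baseline_overlap_flagged_not_dropped(self):
        tr = make_trace(dff=0.0)
        onsets = np.array([10.0, 11.0])
        ev = EventList(onsets, onsets + 0.5,
                       np.array(["social", "social"], dtype=object))
        mat = extract_peri_event(tr, ev)
        assert mat.values.shape[0] == 2
        assert list(mat.baseline_overlap) == [False, True]


class TestZScore:
    def make_matrix(self, values):
        values = np.atleast_2d(values)
        n = values.shape[1]
        centers = -2.0 + 0.05 + 0.1 * np.arange(n)
        return PeriEventMatrix(
            values=values, centers=centers,
            labels=np.array(["social"] * values.shape[0], dtype=object),
            onsets=np.zeros(values.shape[0]),
            kept=np.ones(values.shape[0], dtype=bool),
            baseline_overlap=np.zeros(values.shape[0], dtype=bool),
        )

    def test_arithmetic(self):
        """Baseline mean 5, sd 2 -> a post-onset value of 9 maps to z = 2."""
        base = np.array([5.0 - 2.0, 5.0 + 2.0] * 10)  # mean 5, sd(n-1) ~2.05
        row = np.concatenate([base, [9.0] * 50])
        z = zscore_peri_event(self.make_matrix(row))
        sd = base.std(ddof=1)
        assert z.values[0, -1] == pytest.approx((9.0 - 5.0) / sd)

    def test_constant_row_flagged_degenerate(self):
        z = zscore_peri_event(self.make_matrix(np.full(70, 3.14)))
        assert not z.kept[0]

    def test_self_normalization_random_rows(self, rng):
        mat = self.make_matrix(rng.standard_normal((500, 70)))
        z = zscore_peri_event(mat)
        base = z.values[:, z.baseline_cols]
        np.testing.assert_allclose(base.mean(axis=1), 0.0, atol=1e-9)
        np.testing.assert_allclose(base.std(axis=1, ddof=1), 1.0, atol=1e-9)


class TestResponsesAndAUC:
    def resp(self, trace, centers=None):
        trace = np.asarray(trace, dtype=float)
        if centers is None:
            centers = -2.0 + 0.05 + 0.1 * np.arange(trace.size)
        return AnimalResponse("social", trace, centers, n_events=1)

    def test_mean_trace_identity_symmetry_idempotence(self, rng):
        m = TestZScore().make_matrix(rng.standard_normal((1, 70)))
        r = animal_mean_trace(m)["social"]
        np.testing.assert_array_equal(r.mean_trace, m.values[0])
        row = rng.standard_normal(70)
        m2 = TestZScore().make_matrix(np.vstack([row, -row]))
        np.testing.assert_allclose(
            animal_mean_trace(m2)["social"].mean_trace, 0.0, atol=1e-12
        )
        m5 = TestZScore().make_matrix(np.tile(row, (5, 1)))
        np.testing.assert_allclose(
            animal_mean_trace(m5)["social"].mean_trace, row, atol=1e-12
        )

    def test_absent_stimulus_absent_record(self, rng):
        m = TestZScore().make_matrix(rng.standard_normal((2, 70)))
        assert "empty" not in animal_mean_trace(m)

    def test_auc_constant_rectangle(self):
        assert area_under_curve(self.resp(np.ones(70))) == pytest.approx(5.0)
        assert area_under_curve(self.resp(np.zeros(70))) == 0.0

    def test_auc_linearity(self, rng):
        y = rng.standard_normal(70)
        a1 = area_under_curve(self.resp(y))
        a3 = area_under_curve(self.resp(3.0 * y))
        assert a3 == pytest.approx(3.0 * a1)

    def test_auc_recomputable_and_interval_checked(self, rng):
        y = rng.standard_normal(70)
        r = self.resp(y)
        assert area_under_curve(r) == pytest.approx(area_under_curve(r), abs=1e-9)
        with pytest.raises(ValueError):
            area_under_curve(r, interval=(0.0, 9.0))


class TestQC:
    def test_flat_noise_stability_pass(self, rng):
        tr = make_trace(dur=180.0, t0=-120.0)
        tr = dataclasses.replace(tr, dff=rng.normal(0, 0.01, tr.t.size))
        rec = qc_session(tr, stimulus_intro_time=0.0)
        assert rec["complete"] and rec["stability_pass"]

    def test_imposed_drift_fails_stability(self, rng):
        tr = make_trace(dur=180.0, t0=-120.0)
        drift = 0.1 * tr.t / 60.0  # 0.1 dF/F per minute
        tr = dataclasses.replace(tr, dff=drift + rng.normal(0, 0.001, tr.t.size))
        rec = qc_session(tr, stimulus_intro_time=0.0)
        assert rec["complete"] and not rec["stability_pass"]

    def test_missing_pre_period_incomplete(self, rng):
        tr = make_trace(dur=120.0, t0=-10.0)
        tr = dataclasses.replace(tr, dff=rng.normal(0, 0.01, tr.t.size))
        rec = qc_session(tr, stimulus_intro_time=0.0)
        assert not rec["complete"] and rec["pass"] is None

    def test_snr_monotone_in_transient_amplitude(self, sim_config):
        """The tail/noise SNR metric grows with generator amplitude."""
        bouts = [{"stimulus": "social", "start": float(s), "end": s + 6.0}
                 for s in np.arange(5.0, 290.0, 15.0)]
        snrs = []
        for amp in (0.0, 1.0, 2.0, 4.0):
            det = detrend_isosbestic(sim_trace({"social": amp}, sim_config, bouts))
            snrs.append(qc_session(det, stimulus_intro_time=0.0)["snr"])
        assert all(a < b for a, b in zip(snrs, snrs[1:]))


class TestHeatmap:
    def make_resp(self, animal, genotype, rng):
        return AnimalResponse("social", rng.standard_normal(70),
                              -2.0 + 0.05 + 0.1 * np.arange(70), 3,
                              animal_id=animal, genotype=genotype)

    def test_single_animal_shape(self, rng):
        mat, meta = build_heatmap([self.make_resp("a1", "WT", rng)])
        assert mat.shape == (1, 70)

    def test_row_order_invariant_and_rows_identical(self, rng):
        resps = [self.make_resp(a, g, rng)
                 for g in ("KO", "WT", "HET") for a in ("a2", "a1")]
        mat1, meta1 = build_heatmap(resps)
        mat2, meta2 = build_heatmap(list(reversed(resps)))
        np.testing.assert_array_equal(mat1, mat2)
        assert [m["genotype"] for m in meta1] == ["WT", "WT", "HET", "HET", "KO", "KO"]
        by_key = {(r.genotype, r.animal_id): r for r in resps}
        for row, m in zip(mat1, meta1):
            np.testing.assert_array_equal(
                row, by_key[(m["genotype"], m["animal_id"])].mean_trace
            )

    def test_inconsistent_bins_rejected(self, rng):
        r1 = self.make_resp("a1", "WT", rng)
        r2 = AnimalResponse("social", np.zeros(50),
                            np.linspace(-2, 5, 50), 1, "a2", "WT")
        with pytest.raises(ValueError):
            build_heatmap([r1, r2])
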