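"""ALEX demultiplexing, corrections, bleach detection, selection gate."""

import numpy as np
import pandas as pd
import pytest

import flipkin as fk
from flipkin.preprocess import (
    compute_fret,
    correct_bleedthrough,
    demultiplex,
    detect_photobleach,
    select_and_truncate,
)
from flipkin.simulate import OpticsConfig, StatePath
from flipkin.traceio import Trace


def _make_trace(donor, acceptor, red=None, excitation=None, frame_time=0.1, meta=None):
    n = len(donor)
    exc = excitation if excitation is not None else np.full(n, "G")
    frames = pd.DataFrame(
        {
            "frame": np.arange(n),
            "time_s": np.arange(n) * frame_time,
            "excitation": exc,
            "donor": donor,
            "acceptor": acceptor,
            "red": red if red is not None else np.full(n, np.nan),
        }
    )
    return Trace("test", frames, meta or {"frame_time": frame_time})


class TestDemultiplex:
    def test_alternating_splits_evenly(self):
        optics = OpticsConfig(excitation_schedule="alternating_1Hz")
        labels = optics.excitation_labels(200)
        tr = _make_trace(np.ones(200), np.ones(200), np.ones(200), excitation=labels)
        ch = demultiplex(tr)
        assert len(ch["donor"]) == 100 and len(ch["red"]) == 100

    def test_green_only_has_empty_red_series(self):
        tr = _make_trace(np.ones(100), np.ones(100))
        ch = demultiplex(tr)
        assert len(ch["red"]) == 0 and len(ch["donor"]) == 100

    def test_red_block_confined_to_start(self):
        optics = OpticsConfig(excitation_schedule="red_block_then_green")
        labels = optics.excitation_labels(600)
        tr = _make_trace(np.ones(600), np.ones(600), np.ones(600), excitation=labels)
        ch = demultiplex(tr)
        assert len(ch["red"]) == 150  # 15 s at 100 ms/frame
        assert ch["red_time"].max() < 15.0 <= ch["fret_time"].min()


class TestCorrections:
    def test_zero_beta_is_identity(self):
        a = np.array([1.0, 2.0, 3.0])
        assert np.array_equal(correct_bleedthrough(np.ones(3), a, 0.0), a)

    def test_inverts_render_model(self, noiseless_optics):
        noiseless_optics.bleedthrough_beta = 0.08
        path = StatePath(np.array([0.0]), np.array([0]), 20.0)
        trace, _ = fk.render_trace(path, [0.35], noiseless_optics, seed=0)
        a = correct_bleedthrough(trace.frames["donor"], trace.frames["acceptor"], 0.08)
        assert np.allclose(a, 350.0)

    def test_compute_fret_examples(self):
        E, valid = compute_fret(np.array([1.0, 1.0, 0.0]), np.array([1.0, 0.0, 0.0]),
                                min_total=0.5)
        assert E[0] == pytest.approx(0.5)
        assert E[1] == pytest.approx(0.0)
        assert not valid[2] and np.isnan(E[2])

    def test_recovered_fret_on_simulated_static_level(self):
        optics = OpticsConfig(excitation_schedule="green_only",
                              bleach_rate_donor=0.0, bleach_rate_acceptor=0.0)
        path = StatePath(np.array([0.0]), np.array([0]), 100.0)
        trace, _ = fk.render_trace(path, [0.4], optics, seed=1)
        d = trace.frames["donor"].to_numpy() - optics.background
        a = correct_bleedthrough(d, trace.frames["acceptor"].to_numpy() - optics.background,
                                 optics.bleedthrough_beta)
        E, valid = compute_fret(d, a, min_total=200.0)
        assert np.nanmean(E[valid]) == pytest.approx(0.4, abs=0.02)


class TestDetectPhotobleach:
    def _noisy(self, x, rng, sd=60.0):
        return x + rng.normal(0, sd, len(x))

    def test_clean_donor_bleach_located(self):
        rng = np.random.default_rng(0)
        donor = np.concatenate([np.full(800, 700.0), np.full(400, 0.0)]) + 100
        acceptor = np.concatenate([np.full(800, 300.0), np.full(400, 0.0)]) + 100
        res = detect_photobleach(self._noisy(donor, rng), self._noisy(acceptor, rng),
                                 background=100.0, noise_sd=60.0)
        assert res["kind"] == "donor"
        assert abs(res["bleach_frame"] - 800) <= 2
        assert res["single_step"]

    def test_no_bleach_flags_false_at_end(self):
        rng = np.random.default_rng(1)
        donor = self._noisy(np.full(600, 800.0), rng)
        acceptor = self._noisy(np.full(600, 300.0), rng)
        res = detect_photobleach(donor, acceptor, background=100.0, noise_sd=60.0)
        assert res["kind"] is None and not res["single_step"]
        assert res["bleach_frame"] == 600

    def test_acceptor_then_donor_returns_earliest(self):
        # acceptor dies at 500 (FRET -> 0, donor rises), donor at 900
        rng = np.random.default_rng(2)
        donor = np.concatenate([np.full(500, 600.0), np.full(400, 1000.0), np.full(300, 0.0)])
        acceptor = np.concatenate([np.full(500, 400.0), np.full(400, 0.0), np.full(300, 0.0)])
        res = detect_photobleach(self._noisy(donor + 100, rng), self._noisy(acceptor + 100, rng),
                                 background=100.0, noise_sd=60.0)
        assert res["kind"] == "acceptor"
        assert abs(res["bleach_frame"] - 500) <= 10

    def test_multi_substep_loss_is_not_single_step(self):
        # an aggregate: donor decays to background through a half plateau
        rng = np.random.default_rng(3)
        donor = np.concatenate([np.full(400, 900.0), np.full(300, 450.0), np.full(300, 0.0)])
        acceptor = np.full(1000, 0.0)
        res = detect_photobleach(self._noisy(donor + 100, rng), self._noisy(acceptor + 100, rng),
                                 background=100.0, noise_sd=60.0)
        assert res["kind"] == "donor"
        assert not res["single_step"]


class TestSelectionGate:
    def test_most_dynamic_molecules_accepted_at_defaults(self):
        params = fk.FlippingParams()
        traces, man = fk.simulate_flipping_ensemble(params, n_traces=80, duration=500.0, seed=11)
        series = [select_and_truncate(t) for t in traces]
        dyn = [s.accepted for s, m in zip(series, man.molecules) if m["class"] == "dynamic"]
        assert np.mean(dyn) >= 0.80

    def test_truncation_matches_manifest_bleach_frame(self):
        traces, man = fk.simulate_flipping_ensemble(fk.FlippingParams(), n_traces=40,
                                                    duration=500.0, seed=12)
        checked = 0
        for tr, m in zip(traces, man.molecules):
            s = select_and_truncate(tr)
            bt = [v for v in m["bleach_times"].values() if v is not None]
            if not s.accepted or not bt:
                continue
            true_frame = int(min(bt) / 0.1) - 150  # green frames only
            assert abs(s.qc["bleach_frame"] - true_frame) <= 10
            checked += 1
        assert checked >= 10

    def test_unstable_red_rejected(self):
        # acceptor dye dead during the localization block: no red signal
        optics = OpticsConfig(excitation_schedule="red_block_then_green")
        path = StatePath(np.array([0.0]), np.array([0]), 120.0)
        trace, _ = fk.render_trace(
            path, [0.4], optics, seed=0,
            bleach_times={"donor": np.inf, "acceptor": 5.0, "red": 5.0},
        )
        s = select_and_truncate(trace)
        assert not s.accepted and s.qc["reason"] == "unstable_acceptor"

    def test_two_dye_simultaneous_dropout_rejected(self):
        # both dyes vanish inside the red block: fails the red-presence gate
        optics = OpticsConfig(excitation_schedule="red_block_then_green")
        path = StatePath(np.array([0.0]), np.array([0]), 120.0)
        trace, _ = fk.render_trace(
            path, [0.4], optics, seed=0,
            bleach_times={"donor": 8.0, "acceptor": 8.0, "red": 8.0},
        )
        s = select_and_truncate(trace)
        assert not s.accepted

    def test_accepted_series_ends_before_bleach(self, small_flipping_ensemble):
        _, traces, _ = small_flipping_ensemble
        for tr in traces:
            s = select_and_truncate(tr)
            if s.accepted:
                assert len(s.E) <= s.qc["bleach_frame"]
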