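"""Step detection, binding detection, event pairing, exchange kinetics."""

import numpy as np
import pytest

import flipkin as fk
from flipkin.exchange import (
    Step,
    detect_binding,
    detect_steps,
    intermediate_histogram,
    pair_events,
    processive_fraction,
)


def _times(n):
    return np.arange(n) * 0.1


class TestDetectSteps:
    def test_noiseless_single_step_located_exactly(self):
        E = np.concatenate([np.zeros(100), np.full(200, 0.4)])
        steps = detect_steps(_times(300), E, noise_sd=0.01)
        assert len(steps) == 1
        assert steps[0].time == pytest.approx(10.0, abs=0.1)
        assert steps[0].amplitude == pytest.approx(0.4, abs=0.01)

    def test_two_step_staircase_levels(self):
        rng = np.random.default_rng(0)
        E = np.concatenate([np.zeros(150), np.full(200, 0.6), np.full(150, 0.8)])
        E = E + rng.normal(0, 0.05, len(E))
        steps = detect_steps(_times(500), E)
        assert len(steps) == 2
        assert steps[0].level_after == pytest.approx(0.6, abs=0.03)
        assert steps[1].level_after == pytest.approx(0.8, abs=0.03)

    def test_false_positive_rate_on_flat_noise(self):
        rng = np.random.default_rng(1)
        n_fp = sum(
            bool(detect_steps(_times(2000), rng.normal(0, 0.05, 2000)))
            for _ in range(1000)
        )
        assert n_fp <= 10  # >= 99% of flat traces yield zero steps

    def test_negative_steps_ignored(self):
        E = np.concatenate([np.full(150, 0.6), np.zeros(150)])
        assert detect_steps(_times(300), E, noise_sd=0.01) == []

    def test_sensitivity_to_large_steps(self):
        """Steps of amplitude >= 0.3 with >= 5-s dwells are nearly always found."""
        rng = np.random.default_rng(2)
        found = 0
        for i in range(100):
            E = np.concatenate([np.zeros(80), np.full(80, 0.4)])
            E = E + rng.normal(0, 0.05, len(E))
            steps = detect_steps(_times(160), E)
            found += any(abs(s.time - 8.0) < 1.0 for s in steps)
        assert found >= 95


class TestDetectBinding:
    def test_interval_recovered(self):
        rng = np.random.default_rng(3)
        t = _times(6000)
        red = np.where((t >= 50) & (t < 400), 800.0, 0.0) + 100 + rng.normal(0, 60, 6000)
        iv = detect_binding(t, red, background=100.0, noise_sd=60.0)
        assert len(iv) == 1
        assert iv[0][0] == pytest.approx(50.0, abs=2.0)
        assert iv[0][1] == pytest.approx(400.0, abs=2.0)

    def test_never_bound_is_empty(self):
        rng = np.random.default_rng(4)
        red = 100 + rng.normal(0, 60, 3000)
        assert detect_binding(_times(3000), red, 100.0, 60.0) == []

    def test_two_bindings_with_gap(self):
        rng = np.random.default_rng(5)
        t = _times(3000)
        red = np.where(((t >= 20) & (t < 100)) | ((t >= 130) & (t < 250)), 800.0, 0.0)
        red = red + 100 + rng.normal(0, 60, 3000)
        iv = detect_binding(t, red, 100.0, 60.0)
        assert len(iv) == 2

    def test_brief_blips_removed_by_hysteresis(self):
        red = np.full(500, 100.0)
        red[200:202] = 900.0  # 2-frame blip below the 3-frame hysteresis
        assert detect_binding(_times(500), red, 100.0, 60.0) == []


class TestPairEvents:
    def test_double_within_one_interval(self):
        steps = [Step(60.0, 0.0, 0.6), Step(200.0, 0.6, 0.8)]
        ev = pair_events("m", steps, [(40.0, 500.0)], 600.0)
        assert ev.classification == "double"
        assert ev.tau1 == pytest.approx(20.0)
        assert ev.tau2 == pytest.approx(140.0)
        assert not ev.tau2_censored

    def test_distributive_across_intervals(self):
        steps = [Step(60.0, 0.0, 0.4), Step(400.0, 0.4, 0.8)]
        ev = pair_events("m", steps, [(40.0, 100.0), (380.0, 500.0)], 600.0)
        assert ev.classification == "double_distributive"
        # exposure: censored in interval 1, event in interval 2
        assert ev.tau2_exposures[0] == (pytest.approx(40.0), True)
        assert ev.tau2_exposures[-1][1] is False

    def test_single_with_red_loss_is_censored(self):
        ev = pair_events("m", [Step(60.0, 0.0, 0.6)], [(40.0, 300.0)], 600.0)
        assert ev.classification == "single"
        assert ev.loss_cause == "red_vanished"
        assert ev.tau2_censored and ev.tau2 == pytest.approx(240.0)

    def test_single_truncated_by_trace_end(self):
        ev = pair_events("m", [Step(60.0, 0.0, 0.6)], [(40.0, 599.0)], 600.0)
        assert ev.loss_cause == "trace_end"

    def test_unpaired_step_flagged_and_excluded(self):
        ev = pair_events("m", [Step(350.0, 0.0, 0.6)], [(40.0, 100.0)], 600.0)
        assert ev.paired == [-1]
        assert ev.classification == "none"

    def test_binding_without_step_is_censored_attempt(self):
        ev = pair_events("m", [], [(40.0, 140.0)], 600.0)
        assert ev.classification == "none"
        assert ev.tau1_attempts == [(pytest.approx(100.0), True)]


class TestKinetics:
    def test_equal_rates_give_equal_taus(self):
        rng = np.random.default_rng(6)
        events = []
        for i in range(300):
            t1, t2 = rng.exponential(50.0), rng.exponential(50.0)
            if t1 + t2 > 900:
                continue
            steps = [Step(10.0 + t1, 0.0, 0.5), Step(10.0 + t1 + t2, 0.5, 0.8)]
            events.append(pair_events(f"m{i}", steps, [(10.0, 1000.0)], 1000.0))
        f1, f2 = fk.fit_exchange_times(events)
        assert f1.tau1 == pytest.approx(f2.tau1, rel=0.2)
        assert f1.tau1 == pytest.approx(50.0, rel=0.15)

    def test_processive_fraction_no_loss(self):
        events = [
            pair_events("m", [Step(10.0, 0, 0.5), Step(50.0, 0.5, 0.8)], [(0.0, 500.0)], 600.0)
            for _ in range(10)
        ]
        res = processive_fraction(events)
        assert res["processive_fraction"] == 1.0
        assert res["distributive_fraction"] == 0.0

    def test_processivity_denominator_counts_all_exchangers(self):
        evs = []
        evs.append(pair_events("a", [Step(10, 0, 0.5), Step(50, 0.5, 0.8)], [(0, 500)], 600))
        evs.append(pair_events("b", [Step(10, 0, 0.5)], [(0, 200)], 600))
        evs.append(pair_events("c", [Step(10, 0, 0.5), Step(400, 0.5, 0.8)],
                               [(0, 100), (380, 500)], 600))
        evs.append(pair_events("d", [], [(0, 100)], 600))
        res = processive_fraction(evs)
        assert res["n_single"] == 1 and res["n_double"] == 1 and res["n_distributive"] == 1
        assert res["processive_fraction"] == pytest.approx(1 / 3)


class TestIntermediateHistogram:
    def _events(self, values):
        evs = []
        for i, v in enumerate(values):
            ev = pair_events(f"m{i}", [Step(10.0, 0.0, v)], [(0.0, 500.0)], 600.0,
                             E=np.full(100, v), time_s=np.linspace(10, 500, 100))
            evs.append(ev)
        return evs

    def test_two_faces_resolved(self):
        rng = np.random.default_rng(7)
        vals = np.concatenate([rng.normal(0.4, 0.03, 55), rng.normal(0.6, 0.03, 45)])
        res = intermediate_histogram(self._events(vals), seed=0)
        assert res["means"][0] == pytest.approx(0.4, abs=0.03)
        assert res["means"][1] == pytest.approx(0.6, abs=0.03)
        assert res["weights"][1] == pytest.approx(0.45, abs=0.1)
        assert not res["degenerate"]

    def test_single_face_is_degenerate(self):
        rng = np.random.default_rng(8)
        vals = rng.normal(0.6, 0.03, 80)
        res = intermediate_histogram(self._events(vals), seed=0)
        assert res["degenerate"]

    def test_too_few_events_rejected(self):
        with pytest.raises(ValueError):
            intermediate_histogram(self._events([0.4, 0.6]))


def test_end_to_end_classification_confusion(small_exchange_ensemble):
    """Detected single/double/none labels agree with the manifest truth."""
    _, traces, man = small_exchange_ensemble
    rep = fk.analyze_exchange_ensemble(traces, man, True, seed=0)
    truth = {m["molecule_id"]: m["class"] for m in man.molecules}
    agree = [e.classification == truth[e.molecule_id] for e in rep["events"]]
    assert np.mean(agree) >= 0.85
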