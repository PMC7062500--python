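"""Spike detection, waveform metrics, SPIKE-synchronization, statistics."""

import subprocess

import numpy as np
import pytest

from ca1sim.errors import MetricError
from ca1sim.metrics import (SpikeTrain, all_half_widths, compare_groups,
                            depolarization_time, detect_spikes, half_width,
                            mean_firing_rate, peak_amplitude,
                            potentiation_index, spike_sync_matrix,
                            spike_sync_pair)
from ca1sim.synthetic import canned_spike_trains


def spike_sync_reference(x, y, window):
    """Independent brute-force SPIKE-synchronization (naive double loop).

    Follows the published adaptive-coincidence definition: spike x_i is
    coincident if its nearest partner spike y_j satisfies |x_i - y_j| <
    0.5 * min(neighbouring ISIs of x_i and y_j); boundary spikes use the
    ISIs that exist, and a train without ISIs falls back to the partner's
    (then to half the window).
    """
    def isis_around(train, i):
        out = []
        if i > 0:
            out.append(train[i] - train[i - 1])
        if i + 1 < len(train):
            out.append(train[i + 1] - train[i])
        return out

    def count(a, b):
        total = 0
        for i in range(len(a)):
            best_j, best_d = None, None
            for j in range(len(b)):
                d = abs(a[i] - b[j])
                if best_d is None or d < best_d:
                    best_j, best_d = j, d
            isis = isis_around(a, i) + isis_around(b, best_j)
            tau = 0.5 * min(isis) if isis else 0.5 * (window[1] - window[0])
            if best_d < tau:
                total += 1
        return total

    if len(x) == 0 and len(y) == 0:
        return 1.0
    if len(x) == 0 or len(y) == 0:
        return 0.0
    return (count(x, y) + count(y, x)) / (len(x) + len(y))


def uniform_trace(duration=200.0, dt=0.1, baseline=-65.0):
    t = np.arange(0.0, duration + dt / 2, dt)
    return t, np.full_like(t, baseline)


class TestDetectSpikes:
    def test_flat_trace_is_empty(self):
        t, v = uniform_trace()
        assert len(detect_spikes(t, v)) == 0

    def test_constructed_crossings(self):
        t, v = uniform_trace()
        for t0 in (100.0, 150.0):
            sel = (t >= t0) & (t < t0 + 2.0)
            v[sel] = 40.0
        train = detect_spikes(t, v)
        assert len(train) == 2
        assert train.times == pytest.approx([100.0, 150.0], abs=0.05)

    def test_interpolated_crossing_time(self):
        t = np.array([0.0, 1.0, 2.0, 3.0])
        v = np.array([-65.0, -65.0, 85.0, -65.0])
        # linear rise from -65 at t=1 to 85 at t=2 crosses 10 mV at t=1.5
        train = detect_spikes(t, v)
        assert train.times[0] == pytest.approx(1.5)

    def test_nonuniform_sampling_rejected(self):
        with pytest.raises(MetricError):
            detect_spikes(np.array([0.0, 1.0, 3.0]), np.zeros(3))


class TestHalfWidth:
    def test_triangular_pulse(self):
        t = np.arange(0.0, 12.0, 0.01)
        v = np.full_like(t, -65.0)
        # rise at 75 mV/ms from (4.0,-65): crosses 10 mV at 5.0, peaks at
        # (5.3, 32.5); falls at 25 mV/ms: crosses 10 mV at 6.2 -> 1.2 ms
        up = (t >= 4.0) & (t < 5.3)
        dn = (t >= 5.3) & (t < 9.2)
        v[up] = -65.0 + (t[up] - 4.0) * 75.0
        v[dn] = np.maximum(32.5 - (t[dn] - 5.3) * 25.0, -65.0)
        assert half_width(t, v) == pytest.approx(1.2, abs=0.02)

    def test_monotone_under_amplitude_scaling(self):
        t = np.arange(0.0, 20.0, 0.01)
        base = np.exp(-0.5 * ((t - 10.0) / 1.5) ** 2)
        widths = [half_width(t, -65.0 + a * base) for a in (90.0, 120.0, 150.0)]
        assert widths[0] <= widths[1] <= widths[2]

    def test_no_crossing_is_error(self):
        t, v = uniform_trace()
        with pytest.raises(MetricError):
            half_width(t, v)

    def test_every_detected_spike_has_positive_width(self, wildtype_cell):
        from ca1sim.engine import CurrentClamp, run_simulation

        tr = run_simulation(wildtype_cell, 60.0, clamps=[
            CurrentClamp(wildtype_cell.soma_compartment, 2.0, 10.0, 2.0)],
            record_currents=False, sample_every_ms=0.05)
        widths = all_half_widths(tr.t, tr.soma())
        assert len(widths) >= 1 and np.all(widths > 0)


class TestPeakAndDepolarizationTime:
    def test_monotone_decay_peaks_at_onset(self):
        t = np.arange(0.0, 50.0, 0.1)
        v = -65.0 + 20.0 * np.exp(-t / 5.0)
        assert peak_amplitude(v) == pytest.approx(-45.0)
        assert depolarization_time(t, v, 0.0) == 0.0

    def test_single_bump(self):
        t = np.arange(0.0, 50.0, 0.1)
        onset = 20.0
        v = -65.0 + 128.0 * np.exp(-0.5 * ((t - onset - 12.5) / 2.0) ** 2)
        assert peak_amplitude(v) == pytest.approx(63.0)
        assert depolarization_time(t, v, onset) == pytest.approx(12.5, abs=0.1)

    def test_threshold_mode(self):
        t = np.arange(0.0, 50.0, 0.1)
        v = np.full_like(t, -65.0)
        v[(t >= 30.0) & (t < 32.0)] = 40.0
        assert depolarization_time(t, v, 20.0, mode="threshold") == \
            pytest.approx(10.0, abs=0.1)


class TestMeanFiringRate:
    def test_count_over_window(self):
        train = SpikeTrain(np.linspace(10, 900, 15), (0.0, 1000.0))
        assert mean_firing_rate(train) == pytest.approx(15.0)

    def test_empty_train(self):
        assert mean_firing_rate(SpikeTrain(np.array([]), (0.0, 500.0))) == 0.0

    def test_window_concatenation_averages(self):
        a = SpikeTrain(np.linspace(10, 490, 10), (0.0, 500.0))
        b = SpikeTrain(np.linspace(510, 990, 20), (500.0, 1000.0))
        both = SpikeTrain(np.concatenate([a.times, b.times]), (0.0, 1000.0))
        assert mean_firing_rate(both) == pytest.approx(
            (mean_firing_rate(a) + mean_firing_rate(b)) / 2.0)


class TestSpikeSync:
    def test_identical_pair_is_one(self):
        trains, w = canned_spike_trains("identical_pair")
        assert spike_sync_pair(SpikeTrain(trains[0], w),
                               SpikeTrain(trains[1], w)) == 1.0

    def test_disjoint_pair_is_zero(self):
        trains, w = canned_spike_trains("disjoint_pair")
        assert spike_sync_pair(SpikeTrain(trains[0], w),
                               SpikeTrain(trains[1], w)) == 0.0

    def test_small_jitter_keeps_full_sync(self):
        trains, w = canned_spike_trains("jittered_pair", seed=4)
        assert spike_sync_pair(SpikeTrain(trains[0], w),
                               SpikeTrain(trains[1], w)) == 1.0

    def test_matrix_properties_on_random_sets(self, rng):
        for _ in range(5):
            trains = [SpikeTrain(np.unique(rng.uniform(0, 1000,
                                                       rng.integers(3, 30))),
                                 (0.0, 1000.0)) for _ in range(4)]
            m = spike_sync_matrix(trains)
            np.testing.assert_array_equal(m, m.T)
            np.testing.assert_array_equal(np.diag(m), np.ones(4))
            assert np.all((m >= 0) & (m <= 1))

    def test_matches_independent_reference(self, rng):
        for _ in range(10):
            x = np.unique(rng.uniform(0, 1000, rng.integers(2, 40)))
            y = np.unique(rng.uniform(0, 1000, rng.integers(2, 40)))
            mine = spike_sync_pair(SpikeTrain(x, (0.0, 1000.0)),
                                   SpikeTrain(y, (0.0, 1000.0)))
            ref = spike_sync_reference(x, y, (0.0, 1000.0))
            assert mine == pytest.approx(ref, abs=1e-12)

    def test_single_spike_train_uses_partner_window(self):
        x = np.array([500.0])
        y = np.array([490.0, 510.0, 530.0])
        mine = spike_sync_pair(SpikeTrain(x, (0.0, 1000.0)),
                               SpikeTrain(y, (0.0, 1000.0)))
        assert mine == pytest.approx(
            spike_sync_reference(x, y, (0.0, 1000.0)))


class TestPotentiationIndex:
    def _pairing(self, paired_ca, epsp_ca, paired_v=10.0, epsp_v=5.0,
                 bap_v=5.0):
        return {"paired": dict(peak_ca=paired_ca, peak_v_dep=paired_v),
                "epsp": dict(peak_ca=epsp_ca, peak_v_dep=epsp_v),
                "bap": dict(peak_ca=epsp_ca, peak_v_dep=bap_v)}

    def test_identical_conditions_give_unity(self):
        assert potentiation_index(self._pairing(1e-3, 1e-3)) == 1.0
        assert potentiation_index(self._pairing(1e-3, 1e-3), "voltage") == 1.0

    def test_missing_condition_is_error(self):
        with pytest.raises(MetricError):
            potentiation_index({"paired": {}, "epsp": {}})

    def test_separation_limit_near_unity(self, wildtype_cell):
        from ca1sim.protocols import STDPPairingSpec, run_stdp_pairing

        pr = run_stdp_pairing(wildtype_cell,
                              STDPPairingSpec(delta_t_ms=500.0,
                                              tail_ms=250.0))
        # with no bAP/EPSP interaction the voltage readout equals the
        # saturation-free ratio peak/(epsp+bap)
        v = potentiation_index(pr, "voltage")
        c = pr.conditions
        assert v == pytest.approx(
            max(c["epsp"]["peak_v_dep"], c["bap"]["peak_v_dep"])
            / (c["epsp"]["peak_v_dep"] + c["bap"]["peak_v_dep"]), rel=0.02)


class TestCompareGroups:
    def test_complete_separation(self):
        out = compare_groups({"a": np.array([1.0, 2, 3]),
                              "b": np.array([4.0, 5, 6])})
        row = out.iloc[0]
        assert row.u_stat == 0.0
        assert row.p_mwu < 0.2  # smallest attainable two-sided p at n=3

    def test_identical_groups_not_significant(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        out = compare_groups({"a": x, "b": x.copy()})
        assert out.iloc[0].p_mwu == pytest.approx(1.0, abs=0.05)
        assert not out.iloc[0].significant

    def test_degenerate_constant_groups_reported(self):
        out = compare_groups({"a": np.ones(4), "b": np.ones(4)})
        assert out.iloc[0].p_mwu == 1.0
        assert not out.iloc[0].significant

    def test_p_value_matches_r_wilcox(self, tmp_path):
        # cross-check against an independent statistics package (R)
        x = [1.1, 2.3, 3.1, 4.8, 5.2]
        y = [2.9, 4.4, 6.1, 7.0, 8.5]
        out = compare_groups({"x": np.array(x), "y": np.array(y)})
        script = tmp_path / "mwu.R"
        script.write_text(
            f"cat(sprintf('%.10f', wilcox.test(c({','.join(map(str, x))}),"
            f" c({','.join(map(str, y))}), exact=TRUE)$p.value))\n")
        res = subprocess.run(["Rscript", "--vanilla", str(script)],
                             capture_output=True, text=True, timeout=120)
        assert res.returncode == 0, res.stderr
        p_r = float(res.stdout.strip())
        assert out.iloc[0].p_mwu == pytest.approx(p_r, abs=1e-6)

    def test_tukey_columns_present(self):
        out = compare_groups({"a": [1.0, 2, 3, 2.5], "b": [4.0, 5, 6, 5.5],
                              "c": [1.2, 2.2, 3.2, 2.2]})
        assert {"tukey_low", "tukey_high", "tukey_reject"} <= set(out.columns)
        assert len(out) == 3
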