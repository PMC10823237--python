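import numpy as np
import pytest

from tangentia.connectivity import (
    CorrectedCCG,
    compute_ccg,
    connectivity_map,
    detect_connection,
    detection_probability_pct,
    efficacy,
    jitter_correct,
    mean_connections_per_recording,
    pair_distance,
)
from tangentia.probe_io import make_probe_layout
from tangentia.synth import ConnectionSpec, simulate_trains


def brute_force_ccg(pre, post, bin_ms=0.1, max_lag_ms=10.0):
    """All-pairs lag histogram, the independent oracle."""
    d = ((np.asarray(post)[None, :] - np.asarray(pre)[:, None]) * 1e3).ravel()
    n_bins = int(round(2 * max_lag_ms / bin_ms))
    idx = np.floor((d + max_lag_ms) / bin_ms).astype(int)
    ok = (idx >= 0) & (idx < n_bins)
    return np.bincount(idx[ok], minlength=n_bins).astype(float)


def _flat_ccg(corrected, baseline_sd, bin_ms=0.1, n_pre=1000):
    n = corrected.size
    lags = -10.0 + (np.arange(n) + 0.5) * bin_ms
    return CorrectedCCG(lags, corrected.copy(), np.zeros(n), corrected,
                        baseline_sd, n_pre, n_pre, bin_ms, 10.0)


class TestComputeCcg:
    def test_single_pair_lands_in_2ms_bin(self):
        ccg = compute_ccg(np.array([1.000]), np.array([1.002]))
        assert ccg.counts.sum() == 1
        bin_of_2ms = int(np.floor((2.0 + 10.0) / 0.1))
        assert ccg.counts[bin_of_2ms] == 1
        assert ccg.lags_ms[bin_of_2ms] == pytest.approx(2.05)

    def test_reversal_symmetry(self):
        rng = np.random.default_rng(4)
        a = np.sort(rng.uniform(0, 20, 300))
        b = np.sort(rng.uniform(0, 20, 250))
        ab = compute_ccg(a, b)
        ba = compute_ccg(b, a)
        assert np.array_equal(ab.counts, ba.counts[::-1])

    def test_matches_bruteforce_exactly(self):
        rng = np.random.default_rng(5)
        a = np.sort(rng.uniform(0, 50, 1000))
        b = np.sort(rng.uniform(0, 50, 800))
        ccg = compute_ccg(a, b)
        assert np.array_equal(ccg.counts, brute_force_ccg(a, b))

    def test_poisson_chance_level(self):
        # E[count/bin] = r_a * r_b * T * delta = 10*10*100*1e-4 = 1.0
        rng = np.random.default_rng(6)
        a = np.sort(rng.uniform(0, 100, rng.poisson(1000)))
        b = np.sort(rng.uniform(0, 100, rng.poisson(1000)))
        ccg = compute_ccg(a, b)
        assert ccg.counts.mean() == pytest.approx(1.0, abs=0.3)

    def test_empty_pre_warns_and_zeroes(self):
        with pytest.warns(UserWarning):
            ccg = compute_ccg(np.empty(0), np.array([1.0]))
        assert not np.any(ccg.counts)


class TestJitterCorrect:
    def test_decomposition_identity_exact(self):
        rng = np.random.default_rng(7)
        a = np.sort(rng.uniform(0, 60, 600))
        b = np.sort(rng.uniform(0, 60, 600))
        cc = jitter_correct(a, b, seed=1)
        assert np.array_equal(cc.corrected + cc.jitter_mean, cc.raw_counts)
        assert np.array_equal(cc.raw_counts, compute_ccg(a, b).counts)

    def test_independent_pairs_center_on_zero(self):
        means = []
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            a = np.sort(rng.uniform(0, 120, rng.poisson(1200)))
            b = np.sort(rng.uniform(0, 120, rng.poisson(1200)))
            cc = jitter_correct(a, b, seed=rng)
            means.append(cc.corrected.mean())
        m = np.mean(means)
        se = np.std(means, ddof=1) / np.sqrt(len(means))
        assert abs(m) < 3 * se + 1e-3

    def test_injected_mass_after_self_subtraction(self):
        # interval jitter re-spreads the connection's own evoked pairs at
        # density 1/W, so a fixed window of width w retains (1 - w/W) of
        # the evoked mass: over 1-3 ms that is 0.8 x n_transmitted
        units, gt = simulate_trains({0: 8.0, 1: 6.0}, 1200.0,
                                    [ConnectionSpec(0, 1, 0.1, 2.0, 0.2)],
                                    seed=8)
        ntr = gt.connections[0].n_transmitted
        cc = jitter_correct(units.by_id(0).spike_times_s,
                            units.by_id(1).spike_times_s, seed=9)
        win = (cc.lags_ms >= 1.0) & (cc.lags_ms < 3.0)
        got = cc.corrected[win].sum()
        assert got == pytest.approx(0.8 * ntr, abs=4 * np.sqrt(ntr))

    def test_empty_post_gives_zero_corrected(self):
        cc = jitter_correct(np.array([1.0, 2.0]), np.empty(0), seed=0)
        assert not np.any(cc.corrected)

    def test_window_must_exceed_bin(self):
        with pytest.raises(ValueError):
            jitter_correct(np.array([1.0]), np.array([1.0]),
                           jitter_window_ms=0.05, bin_ms=0.1, seed=0)

    def test_seed_determinism(self):
        rng = np.random.default_rng(10)
        a = np.sort(rng.uniform(0, 30, 300))
        b = np.sort(rng.uniform(0, 30, 300))
        c1 = jitter_correct(a, b, seed=42)
        c2 = jitter_correct(a, b, seed=42)
        assert np.array_equal(c1.corrected, c2.corrected)


class TestDetectConnection:
    def test_flat_zero_gives_none(self):
        assert detect_connection(_flat_ccg(np.zeros(200), 0.0)) is None

    def test_three_significant_bins_insufficient(self):
        rng = np.random.default_rng(11)
        corrected = rng.normal(0, 1.0, 200)
        sd = float(np.std(corrected[(np.arange(200) >= 55)
                                    & (np.arange(200) < 105)], ddof=1))
        corrected[125:128] = 10.0  # 3 consecutive bins at 2.5-2.8 ms
        assert detect_connection(_flat_ccg(corrected, sd)) is None
        corrected[128] = 10.0  # the fourth bin completes the run
        conn = detect_connection(_flat_ccg(corrected, sd))
        assert conn is not None
        assert conn.significant_bins.size >= 4

    def test_peak_outside_monosynaptic_window_ignored(self):
        corrected = np.zeros(200)
        corrected[60:70] = 50.0  # around -3.5 ms: acausal, not monosynaptic
        assert detect_connection(_flat_ccg(corrected, 1.0)) is None

    def test_simulated_pair_detected_at_planted_delay(self):
        units, _ = simulate_trains({0: 12.0, 1: 10.0}, 1800.0,
                                   [ConnectionSpec(0, 1, 0.05, 2.0, 0.2)],
                                   seed=12)
        assert units.by_id(0).n_spikes >= 20000
        cc = jitter_correct(units.by_id(0).spike_times_s,
                            units.by_id(1).spike_times_s, seed=13)
        conn = detect_connection(cc)
        assert conn is not None
        assert conn.peak_lag_ms == pytest.approx(2.0, abs=0.3)
        assert conn.peak_height_sd > 3.0

    def test_degenerate_nonzero_ccg_refused(self):
        corrected = np.zeros(200)
        corrected[130] = 5.0
        with pytest.raises(ValueError):
            detect_connection(_flat_ccg(corrected, 0.0))


class TestEfficacy:
    def test_zero_peak_clipped_to_zero(self):
        corrected = np.full(200, -0.5)
        conn_bins = np.arange(125, 129)
        from tangentia.connectivity import Connection
        conn = Connection(-1, -1, 2.5, 5.0, conn_bins)
        assert efficacy(_flat_ccg(corrected, 1.0), conn) == 0.0

    @pytest.mark.parametrize("p,duration", [(0.02, 3600.0), (0.5, 1800.0)])
    def test_planted_probability_recovered(self, p, duration):
        units, gt = simulate_trains({0: 12.0, 1: 10.0}, duration,
                                    [ConnectionSpec(0, 1, p, 2.0, 0.2)],
                                    seed=14)
        cc = jitter_correct(units.by_id(0).spike_times_s,
                            units.by_id(1).spike_times_s, seed=15)
        conn = detect_connection(cc)
        eff = efficacy(cc, conn)
        # binomial oracle: the realised transmitted fraction
        true_frac = gt.connections[0].n_transmitted / units.by_id(0).n_spikes
        assert eff == pytest.approx(true_frac, rel=0.1)

    def test_empty_pre_undefined(self):
        from tangentia.connectivity import Connection
        cc = _flat_ccg(np.zeros(200), 1.0)
        cc.n_pre = 0
        conn = Connection(-1, -1, 2.0, 5.0, np.arange(120, 124))
        assert efficacy(cc, conn) is None


class TestPairDistance:
    def test_same_channel_zero(self):
        layout = make_probe_layout(64)
        assert pair_distance(layout, 10, 10) == 0.0

    def test_ten_rows_same_column(self):
        layout = make_probe_layout(64, "four-column")
        # channels 0 and 40 sit in the same column, 10 rows = 200 µm apart
        assert layout.x[0] == layout.x[40]
        assert pair_distance(layout, 0, 40) == pytest.approx(200.0)

    def test_symmetry_and_validation(self):
        layout = make_probe_layout(64)
        assert pair_distance(layout, 3, 40) == pair_distance(layout, 40, 3)
        with pytest.raises(ValueError):
            pair_distance(layout, 0, 64)


class TestConnectivityMap:
    def test_planted_graph_recovered_exactly(self):
        # 3 TCAs diverging onto 3 V1Ns each; every V1N converges from one TCA
        conns = [ConnectionSpec(pre, 10 + 3 * pre + k, 0.2, 2.0, 0.2)
                 for pre in range(3) for k in range(3)]
        rates = {i: 10.0 for i in range(3)}
        rates.update({j: 5.0 for j in range(10, 19)})
        units, gt = simulate_trains(rates, 900.0, conns, seed=16)
        detected, summary = connectivity_map(units, seed=17)
        assert {(c.pre_id, c.post_id) for c in detected} == gt.edge_set()
        assert summary["n_tested"] == 27
        assert summary["n_detected"] == 9
        assert summary["mean_divergence"] == pytest.approx(3.0)
        assert summary["mean_convergence"] == pytest.approx(1.0)
        assert all(summary["divergence"][p] == 3 for p in range(3))
        assert summary["detection_pct"] == pytest.approx(100 * 9 / 27)

    def test_no_tca_units_yields_empty_result(self):
        units, _ = simulate_trains({0: 5.0}, 10.0, seed=0,
                                   labels={0: "V1N"})
        with pytest.warns(UserWarning):
            detected, summary = connectivity_map(units, seed=0)
        assert detected == [] and summary["n_detected"] == 0


class TestSummaryArithmetic:
    def test_detection_probability(self):
        assert detection_probability_pct(1, 4) == 25.0
        with pytest.raises(ValueError):
            detection_probability_pct(1, 0)

    def test_mean_per_recording(self):
        assert mean_connections_per_recording(10, 4) == 2.5


class TestFalsePositiveControl:
    def test_rate_comodulation_rejected(self):
        # common 1 Hz rate modulation without a connection: the 10-ms
        # interval jitter preserves the slow co-modulation in the surrogate,
        # so it must not produce detections
        n_det = 0
        n_seeds = 100
        for seed in range(n_seeds):
            rng = np.random.default_rng(2000 + seed)
            t = np.arange(0, 600.0, 1e-3)
            lam = 15.0 * (1 + 0.8 * np.sin(2 * np.pi * t)) * 1e-3
            a = t[rng.random(t.size) < lam]
            b = t[rng.random(t.size) < lam]
            cc = jitter_correct(a, b, seed=rng)
            try:
                conn = detect_connection(cc)
            except ValueError:
                conn = None
            n_det += conn is not None
        assert n_det <= 0.05 * n_seeds
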