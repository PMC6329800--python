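"""Encoding classifier: correlation maps, run detection, feature specificity."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats as st

from fsrpe import encoding as enc
from fsrpe import ephys

from conftest import planted_neuron

BC = enc.BinningConfig()
CC = enc.ClassifierConfig()


class TestBinRates:
    def test_25ms_config_yields_73_bins(self):
        cfg = enc.BinningConfig(step=0.025)
        assert cfg.n_bins == 73
        assert cfg.starts[0] == pytest.approx(-0.5)
        assert cfg.starts[-1] == pytest.approx(1.3)

    def test_empty_spike_train_all_zero(self, neural_session):
        rec = ephys.NeuronRecording(
            neuron_id=0, area="ACC",
            spikes={"outcome": [np.empty(0)] * neural_session.n_trials},
            waveform=np.empty(0), session=neural_session)
        assert enc.bin_rates(rec, BC).sum() == 0

    def test_single_spike_hits_exactly_covering_windows(self, neural_session):
        spikes = [np.empty(0)] * neural_session.n_trials
        spikes[0] = np.array([0.1])
        rec = ephys.NeuronRecording(neuron_id=0, area="ACC",
                                    spikes={"outcome": spikes},
                                    waveform=np.empty(0),
                                    session=neural_session)
        rates = enc.bin_rates(rec, BC)
        covering = (BC.starts <= 0.1) & (0.1 < BC.starts + BC.window)
        np.testing.assert_array_equal(rates[0] > 0, covering)
        assert rates[0, covering].max() == pytest.approx(1.0 / BC.window)


class TestCorrelationMaps:
    def test_matches_scipy_spearman_per_bin(self):
        rng = np.random.default_rng(0)
        rates = rng.poisson(3.0, size=(40, 12)).astype(float)
        x = rng.normal(size=40)
        m = enc.rank_correlation_map(rates, x)
        for b in range(12):
            rho, p = st.spearmanr(rates[:, b], x)
            assert m.r[b] == pytest.approx(rho, abs=1e-12)
            assert m.p[b] == pytest.approx(p, abs=1e-10)

    def test_rank_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(1)
        rates = rng.gamma(2.0, size=(30, 5))
        x = rng.normal(size=30)
        a = enc.rank_correlation_map(rates, x)
        b = enc.rank_correlation_map(np.exp(3 * rates) + 7, x)
        np.testing.assert_allclose(a.r, b.r, atol=1e-12)

    def test_monotone_rate_gives_unit_correlation(self):
        x = np.linspace(0, 1, 25)
        rates = np.tile((x ** 3)[:, None], (1, 4))
        m = enc.rank_correlation_map(rates, x)
        np.testing.assert_allclose(m.r, 1.0)

    def test_partial_matches_pingouin_oracle(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(2)
        n = 50
        z = np.where(rng.random(n) > 0.5, 1.0, -1.0)
        x = np.abs(rng.normal(size=n)) + 0.3 * z
        rates = rng.poisson(4 + 2 * x, size=(3, n)).T.astype(float)
        m = enc.partial_rank_correlation_map(rates, x, z)
        for b in range(3):
            df = pd.DataFrame({"y": rates[:, b], "x": x, "z": z})
            res = pingouin.partial_corr(df, x="x", y="y", covar="z",
                                        method="spearman")
            assert m.r[b] == pytest.approx(float(res["r"].iloc[0]), abs=1e-10)

    def test_partial_removes_pure_sign_coding(self):
        """A neuron driven only by outcome sign shows ~zero partial
        correlation with |RPE| — the point of the partialization."""
        rng = np.random.default_rng(3)
        n = 400
        sign = np.where(rng.random(n) > 0.5, 1.0, -1.0)
        mag = np.where(sign > 0, np.abs(rng.normal(0.2, 0.1, n)),
                       np.abs(rng.normal(0.6, 0.2, n)))
        rates = rng.poisson(5 + 3 * (sign > 0), size=(5, n)).T.astype(float)
        plain = enc.rank_correlation_map(rates, mag)
        part = enc.partial_rank_correlation_map(rates, mag, sign)
        assert np.abs(plain.r).mean() > 3 * np.abs(part.r).mean()

    def test_constant_covariate_falls_back(self):
        rng = np.random.default_rng(4)
        rates = rng.poisson(3.0, size=(30, 2)).astype(float)
        x = rng.normal(size=30)
        m = enc.partial_rank_correlation_map(rates, x, np.ones(30))
        assert "constant covariate" in m.note


class TestFisherZ:
    def test_equal_correlations_give_zero(self):
        assert enc.fisher_z_compare(0.4, 50, 0.4, 80) == pytest.approx(0.0)

    def test_closed_form_value(self):
        z = enc.fisher_z_compare(0.5, 103, 0.0, 103)
        assert z == pytest.approx(np.arctanh(0.5) / np.sqrt(2 / 100), abs=1e-9)

    def test_antisymmetry(self):
        a = enc.fisher_z_compare(0.3, 40, -0.2, 60)
        b = enc.fisher_z_compare(-0.2, 60, 0.3, 40)
        assert a == pytest.approx(-b)

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            enc.fisher_z_compare(0.5, 3, 0.0, 50)


class TestDetectEncoding:
    def _map(self, sig_bins, n_bins=None, r_val=0.5):
        n_bins = n_bins or BC.n_bins
        r = np.zeros(n_bins)
        p = np.ones(n_bins)
        r[sig_bins] = r_val
        p[sig_bins] = 0.001
        return enc.EncodingMap(r=r, p=p, n=100, regressor="pRPE")

    def test_four_consecutive_post_bins_flagged(self):
        post0 = int(np.where(BC.post_mask)[0][0])
        win = self._map([post0 + 2, post0 + 3, post0 + 4, post0 + 5])
        w = enc.detect_encoding(win, BC, CC, positive=True)
        assert w is not None
        assert w.start_bin == post0 + 2 and w.length == 4

    def test_three_bins_not_flagged(self):
        post0 = int(np.where(BC.post_mask)[0][0])
        w = enc.detect_encoding(self._map([post0, post0 + 1, post0 + 2]),
                                BC, CC, positive=True)
        assert w is None

    def test_pre_outcome_run_vetoes(self):
        post0 = int(np.where(BC.post_mask)[0][0])
        bins = [0, 1, 2, post0 + 1, post0 + 2, post0 + 3, post0 + 4]
        w = enc.detect_encoding(self._map(bins), BC, CC, positive=True)
        assert w is None

    def test_two_pre_bins_allowed(self):
        post0 = int(np.where(BC.post_mask)[0][0])
        bins = [0, 1, post0 + 1, post0 + 2, post0 + 3, post0 + 4]
        w = enc.detect_encoding(self._map(bins), BC, CC, positive=True)
        assert w is not None

    def test_wrong_sign_ignored(self):
        post0 = int(np.where(BC.post_mask)[0][0])
        m = self._map([post0, post0 + 1, post0 + 2, post0 + 3], r_val=-0.5)
        assert enc.detect_encoding(m, BC, CC, positive=True) is None
        assert enc.detect_encoding(m, BC, CC, positive=False) is not None


class TestInclusion:
    def test_low_rate_neuron_excluded(self, neural_session, neural_trace):
        prof = ephys.NeuronProfile(baseline_hz=0.4)
        rec = ephys.simulate_neuron(prof, neural_session, neural_trace,
                                    seed=0)
        ok, reasons, _ = enc.include_neuron(rec, neural_trace)
        assert not ok and "rate" in reasons

    def test_too_few_usable_trials_excluded(self, reference_spec):
        from fsrpe import rl, task
        cfg = task.TaskConfig()
        s = task.generate_session(cfg, rl.RLAgent(reference_spec), seed=21,
                                  n_blocks=1)
        s.annotate_learning()
        trace = rl.rpe_trace(reference_spec, s)
        rec = ephys.simulate_neuron(ephys.NeuronProfile(), s, trace, seed=0)
        ok, reasons, usable = enc.include_neuron(rec, trace)
        if s.learned_blocks():
            assert usable.sum() <= 40 or ok
        else:
            assert not ok

    def test_under_15_trials_not_evaluable(self, neural_trace):
        rng = np.random.default_rng(0)
        rates = rng.poisson(3.0, size=(len(neural_trace), 5)).astype(float)
        m, _ = enc.signal_map(rates[:14], neural_trace.iloc[:14], "pRPE", CC)
        assert not m.evaluable


class TestClassifier:
    def test_planted_color_specific_neuron_recovered(self, neural_session,
                                                     neural_trace):
        rec = planted_neuron(neural_session, neural_trace, "pRPE", 20.0,
                             seed=6, duration=0.6)
        lab = enc.classify_neuron(rec, neural_trace)
        fs = lab.feature_specific[("pRPE", "color")]
        assert fs is not None
        feat, win = fs
        assert feat == "c1"
        # encoding window overlaps the planted [0.2, 0.8) s interval
        assert 0.0 <= win.bin_times[0] <= 0.8

    def test_equal_coding_for_both_colors_is_nonspecific(self, neural_session,
                                                         neural_trace):
        # plant the same pRPE signal without feature condition
        prof = ephys.NeuronProfile(baseline_hz=5.0, signals=(
            ephys.PlantedSignal("pRPE", 20.0, latency=0.2, duration=0.6),))
        rec = ephys.simulate_neuron(prof, neural_session, neural_trace,
                                    seed=8)
        lab = enc.classify_neuron(rec, neural_trace)
        assert lab.nonspecific["pRPE"] is not None
        assert lab.feature_specific[("pRPE", "color")] is None

    def test_multiple_signal_types_coexist(self, neural_session,
                                           neural_trace):
        prof = ephys.NeuronProfile(baseline_hz=5.0, signals=(
            ephys.PlantedSignal("pRPE", 20.0, latency=0.2, duration=0.6,
                                dimension="color", feature="c1"),
            ephys.PlantedSignal("nRPE", 20.0, latency=0.2, duration=0.6,
                                dimension="location", feature="L"),
        ))
        rec = ephys.simulate_neuron(prof, neural_session, neural_trace,
                                    seed=12)
        lab = enc.classify_neuron(rec, neural_trace)
        assert lab.feature_specific[("pRPE", "color")] is not None
        assert lab.feature_specific[("nRPE", "location")] is not None

    def test_exclusive_nonspecific_flag(self, neural_session, neural_trace):
        rec = planted_neuron(neural_session, neural_trace, "pRPE", 20.0,
                             seed=6, duration=0.6)
        lab = enc.classify_neuron(rec, neural_trace)
        # a feature-specific neuron may also trip the pooled test, but it is
        # never counted nonspecific-only for that signal
        assert lab.is_feature_specific("pRPE")
        assert not lab.nonspecific_only("pRPE")

    def test_outcome_encoding_power_and_null(self, neural_session,
                                             neural_trace):
        prof = ephys.NeuronProfile(baseline_hz=5.0, signals=(
            ephys.PlantedSignal("outcome", 5.0, latency=0.1, duration=0.6),))
        flags = wins = 0
        for k in range(20):
            rec = ephys.simulate_neuron(prof, neural_session, neural_trace,
                                        seed=300 + k)
            lab = enc.classify_neuron(rec, neural_trace)
            flags += lab.outcome_flag
            wins += lab.outcome is not None
        assert flags >= 18  # epoch regression power > 0.9 at 5 Hz gain
        assert wins >= 15   # run-based latency window found in most

    def test_labels_table_roundtrip(self, neural_session, neural_trace):
        rec = planted_neuron(neural_session, neural_trace, "pRPE", 20.0,
                             seed=6, duration=0.6)
        table = enc.labels_table([enc.classify_neuron(rec, neural_trace)])
        assert (table["included"]).all()
        assert "pRPE" in set(table["signal"].dropna())
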