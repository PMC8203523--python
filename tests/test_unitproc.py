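"""Epoch modulation, optotagging, CCG detection, waveform features, classifiers."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from bfnet import synth, unitproc
from bfnet.unitproc import SpikeUnit


def _unit(times, uid=0, region="BF", duration=None, waveform=None):
    return SpikeUnit(id=uid, region=region, spike_times=np.asarray(times, float),
                     mean_waveform=waveform, session_duration=duration)


def _epochs(n_trials, epoch_s=2.0, base_s=2.0):
    rows = []
    t = 0.0
    for tr in range(n_trials):
        rows.append((tr, "center", t, t + base_s)); t += base_s
        rows.append((tr, "decision", t, t + epoch_s)); t += epoch_s
    return pd.DataFrame(rows, columns=["trial", "label", "t_start_s", "t_end_s"])


# ---------------------------------------------------------------------------
# epoch modulation
# ---------------------------------------------------------------------------


class TestEpochModulation:
    def test_identical_rates_nonsignificant_zero_z(self):
        # one spike per second everywhere
        ep = _epochs(8)
        times = np.arange(0.5, 32.0, 1.0)
        r = unitproc.epoch_rate_modulation(_unit(times), ep, "decision")
        assert r.p_value == 1.0
        assert np.allclose(r.z_per_trial[~np.isnan(r.z_per_trial)], 0.0)

    def test_rank_sum_p_matches_exhaustive_enumeration(self):
        # 4 vs 4 integer per-trial counts; oracle enumerates all C(8,4)=70
        # group assignments of the pooled values
        ep = _epochs(4, epoch_s=1.0, base_s=1.0)
        epoch_counts = [1, 5, 7, 9]
        base_counts = [2, 3, 4, 6]
        times = []
        for tr, (ce, cb) in enumerate(zip(epoch_counts, base_counts)):
            b0 = ep[(ep.trial == tr) & (ep.label == "center")].iloc[0]
            e0 = ep[(ep.trial == tr) & (ep.label == "decision")].iloc[0]
            times += list(b0.t_start_s + (np.arange(cb) + 0.5) / cb * 0.99)
            times += list(e0.t_start_s + (np.arange(ce) + 0.5) / ce * 0.99)
        r = unitproc.epoch_rate_modulation(_unit(sorted(times)), ep, "decision",
                                           min_trials=4)
        pooled = np.array(epoch_counts + base_counts, float)
        obs = sum(stats.rankdata(pooled)[:4])
        null = [
            sum(stats.rankdata(pooled)[list(c)])
            for c in itertools.combinations(range(8), 4)
        ]
        mu = np.mean(null)
        p_oracle = np.mean(np.abs(np.array(null) - mu) >= abs(obs - mu) - 1e-12)
        assert r.p_value == pytest.approx(p_oracle)

    def test_rate_doubled_during_decision_detected(self):
        hits = 0
        n_runs = 12
        for seed in range(n_runs):
            cfg = synth.SynthConfig(
                seed=seed, n_trials=30, probes=[synth.ProbeLayout("BF", 1, 2)],
                units=[synth.UnitSpec(0, mean_rate_hz=5.0,
                                      epoch_rate_gain=(("decision", 2.0),))],
            )
            ep = synth.make_epoch_table(cfg)
            units, _ = synth.generate_units(cfg, ep, synth.make_light_events(cfg))
            r = unitproc.epoch_rate_modulation(units[0], ep, "decision")
            hits += (r.p_value < 0.05) and (np.nanmean(r.z_per_trial) > 0)
        assert hits >= int(0.9 * n_runs)

    def test_too_few_trials_rejected(self):
        ep = _epochs(3)
        with pytest.raises(ValueError, match="trials"):
            unitproc.epoch_rate_modulation(_unit(np.arange(1.0, 10.0)), ep,
                                           "decision")

    def test_feature_scaled_rates_in_unit_interval(self):
        ep = _epochs(6)
        g = np.random.default_rng(0)
        r = unitproc.epoch_rate_modulation(
            _unit(np.sort(g.uniform(0, 24, 120))), ep, "decision")
        assert 0.0 <= r.norm_epoch_mean <= 1.0
        assert 0.0 <= r.norm_baseline_mean <= 1.0


# ---------------------------------------------------------------------------
# optotagging
# ---------------------------------------------------------------------------


def _light(n_trains=15, gap=3.0, period=0.1, train_s=2.0, width=0.01):
    t, rows = gap, []
    for _ in range(n_trains):
        for p in range(int(train_s / period)):
            rows.append((t + p * period, width))
        t += train_s + gap
    return pd.DataFrame(rows, columns=["t_s", "duration_s"])


class TestOptotag:
    def test_insufficient_stimuli_error(self, rng):
        le = _light(n_trains=4)  # 80 pulses < 100
        with pytest.raises(unitproc.InsufficientStimuliError, match="insufficient"):
            unitproc.optotag(_unit(np.sort(rng.uniform(0, 80, 200))), le)

    def test_responsive_unit_tagged_up(self, small_session):
        le = small_session["light"]
        chol = [u for u in small_session["units"] if u.is_cholinergic][0]
        r = unitproc.optotag(chol, le)
        assert r.responsive and r.direction == "up"
        assert r.evoked_rate_hz > r.control_mean_hz + 2 * r.control_sd_hz

    def test_nonresponsive_unit_passes(self, small_session):
        le = small_session["light"]
        other = [u for u in small_session["units"]
                 if u.region == "BF" and not u.is_cholinergic][0]
        r = unitproc.optotag(other, le)
        assert not r.responsive and r.direction == "none"

    def test_null_specificity_near_nominal(self):
        # homogeneous Poisson units, no injected response: the 2 SD rule
        # should flag only a small fraction
        le = _light()
        dur = le["t_s"].max() + 5.0
        flags = 0
        n_units = 60
        for seed in range(n_units):
            g = np.random.default_rng(20_000 + seed)
            u = _unit(synth.poisson_train(2.0, dur, g))
            flags += unitproc.optotag(u, le).responsive
        assert flags / n_units < 0.15

    def test_time_rescaling_invariance(self, rng):
        # compressing time by c scales every rate by c; with windows
        # scaled alike the criterion compares the same counts
        le = _light()
        dur = le["t_s"].max() + 5.0
        times = synth.poisson_train(3.0, dur, rng)
        r1 = unitproc.optotag(_unit(times), le)
        c = 4.0
        le2 = le.copy()
        le2["t_s"] /= c
        le2["duration_s"] /= c
        r2 = unitproc.optotag(_unit(times / c), le2, pulse_width_s=0.01 / c,
                              control_window_s=2.0 / c)
        assert r1.responsive == r2.responsive
        assert r2.evoked_rate_hz == pytest.approx(c * r1.evoked_rate_hz)


# ---------------------------------------------------------------------------
# CCG detection
# ---------------------------------------------------------------------------


class TestCCG:
    def test_threshold_matches_brute_force_poisson_quantile(self, rng):
        # oracle: sum the pmf until the CDF reaches the quantile
        lambdas = rng.uniform(0.01, 30.0, 200)
        for lam in lambdas:
            k, c = 0, np.exp(-lam)
            term = np.exp(-lam)
            while c < 0.9999:
                k += 1
                term *= lam / k
                c += term
            assert unitproc.poisson_threshold(lam, 0.9999) == k

    def test_symmetry_forward_reverse(self, rng):
        a = np.sort(rng.uniform(0, 100, 500))
        b = np.sort(rng.uniform(0, 100, 400))
        cab, _ = unitproc.cross_correlogram(a, b)
        cba, _ = unitproc.cross_correlogram(b, a)
        assert np.array_equal(cab, cba[::-1])

    def test_injected_excitatory_coupling_detected(self, rng):
        pre = synth.poisson_train(5.0, 700.0, rng)
        post = synth.poisson_train(5.0, 700.0, rng)
        c = synth.CouplingSpec(pre=0, post=1, efficacy=0.2, lag_ms=2.5,
                               jitter_ms=0.5)
        post2, _ = synth.apply_coupling(pre, post, c, 700.0, rng)
        r = unitproc.ccg_detect(pre, post2)
        assert r.detected and r.sign == "excitatory"
        sig_lags = [lag for lag, _, _ in r.significant_bins]
        assert any(2.0 <= lag <= 3.0 for lag in sig_lags)

    def test_inhibitory_coupling_detected(self, rng):
        pre = synth.poisson_train(10.0, 900.0, rng)
        post = synth.poisson_train(30.0, 900.0, rng)
        c = synth.CouplingSpec(pre=0, post=1, sign="inhibitory", efficacy=1.0,
                               lag_ms=3.0, jitter_ms=1.5)
        post2, _ = synth.apply_coupling(pre, post, c, 900.0, rng)
        r = unitproc.ccg_detect(pre, post2)
        assert r.detected and r.sign == "inhibitory"

    def test_independent_pairs_rarely_detected(self):
        detections = 0
        n_pairs = 60
        for seed in range(n_pairs):
            g = np.random.default_rng(31_000 + seed)
            a = synth.poisson_train(5.0, 600.0, g)
            b = synth.poisson_train(5.0, 600.0, g)
            detections += unitproc.ccg_detect(a, b).detected
        assert detections <= 1  # >= 2 consecutive 1e-4 tails: ~never

    def test_min_spike_requirement(self, rng):
        with pytest.raises(ValueError, match="spikes"):
            unitproc.ccg_detect(np.sort(rng.uniform(0, 10, 50)),
                                np.sort(rng.uniform(0, 10, 500)))

    def test_disjoint_spans_rejected(self):
        a = np.linspace(0, 10, 200)
        b = np.linspace(20, 30, 200)
        with pytest.raises(ValueError, match="overlap"):
            unitproc.ccg_detect(a, b)


# ---------------------------------------------------------------------------
# waveform features
# ---------------------------------------------------------------------------


class TestWaveformFeatures:
    def test_template_tp_latency(self):
        wide = _unit(np.arange(1.0, 400.0), waveform=synth._template("wide"))
        narrow = _unit(np.arange(1.0, 400.0), waveform=synth._template("narrow"))
        assert unitproc.tp_latency_ms(wide.peak_channel_waveform()) == pytest.approx(0.6)
        assert unitproc.tp_latency_ms(narrow.peak_channel_waveform()) == pytest.approx(0.25)

    def test_burst_index_uniform_acg_is_one(self, monkeypatch):
        counts = np.full(300, 17)
        edges = 1e-3 * np.arange(301)
        monkeypatch.setattr(unitproc, "autocorrelogram",
                            lambda *a, **k: (counts, edges))
        assert unitproc.burst_index(np.arange(10.0)) == pytest.approx(1.0)

    def test_burst_index_doubled_short_lags_is_two(self, monkeypatch):
        counts = np.full(300, 10)
        edges = 1e-3 * np.arange(301)
        centers = edges[:-1] + 5e-4
        counts[(centers >= 3e-3) & (centers < 5e-3)] = 20
        monkeypatch.setattr(unitproc, "autocorrelogram",
                            lambda *a, **k: (counts, edges))
        assert unitproc.burst_index(np.arange(10.0)) == pytest.approx(2.0)

    def test_burst_index_empty_denominator_missing(self):
        # three spikes closer than 200 ms: no 200-300 ms lags at all
        assert np.isnan(unitproc.burst_index(np.array([0.0, 0.004, 0.008])))

    def test_pca_identical_waveforms_zero_scores(self):
        units = [_unit(np.arange(1.0, 50.0), uid=i,
                       waveform=synth._template("wide")) for i in range(5)]
        scores = unitproc.waveform_pca(units)
        assert np.allclose(scores, 0.0)

    def test_pca_separates_template_families(self):
        g = np.random.default_rng(3)
        units = []
        for i in range(10):
            kind = "wide" if i < 5 else "narrow"
            w = synth._template(kind) + 0.5 * g.standard_normal(32)
            units.append(_unit(np.arange(1.0, 50.0), uid=i, waveform=w))
        scores = unitproc.waveform_pca(units)
        side = np.sign(scores[:, 0])
        assert len(set(side[:5])) == 1 and len(set(side[5:])) == 1
        assert side[0] != side[-1]

    def test_pca_matches_eigendecomposition_oracle(self):
        units = [_unit(np.arange(1.0, 50.0), uid=0, waveform=synth._template("wide")),
                 _unit(np.arange(1.0, 50.0), uid=1, waveform=synth._template("narrow"))]
        scores = unitproc.waveform_pca(units)
        # brute-force oracle: rebuild the cropped second-derivative matrix
        from scipy.interpolate import CubicSpline

        rows = []
        for u in units:
            w = u.peak_channel_waveform()
            xf = np.arange(0, 31 + 1e-9, 0.2)
            wf = CubicSpline(np.arange(32), w)(xf)
            d2 = np.diff(wf, n=2)
            tr = int(np.argmin(wf))
            rows.append(d2[tr : tr + int(round(0.8e-3 * 100_000))])
        m = np.asarray(rows) - np.mean(rows, axis=0)
        cov = m @ m.T  # Gram matrix shares nonzero eigenvalues with the cov
        evals, evecs = np.linalg.eigh(cov)
        pc1 = evecs[:, -1] * np.sqrt(evals[-1])
        assert np.allclose(np.abs(scores[:, 0]), np.abs(pc1), rtol=1e-6)
        assert np.allclose(scores[:, 1], 0.0, atol=1e-6)

    def test_window_beyond_waveform_rejected(self):
        w = np.zeros(32)
        w[30] = -1.0  # trough at the very end
        units = [_unit(np.arange(1.0, 50.0), uid=i, waveform=w) for i in range(3)]
        with pytest.raises(ValueError, match="window"):
            unitproc.waveform_pca(units)


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------


def _gaussian_clusters(rng, k=6, n_per=20, sep=5.0):
    # unit-SD clusters whose centres are pairwise at least `sep` apart
    centers = []
    while len(centers) < k:
        c = rng.uniform(-4 * sep, 4 * sep, 3)
        if all(np.linalg.norm(c - o) >= sep for o in centers):
            centers.append(c)
    x = np.vstack([c + rng.standard_normal((n_per, 3)) for c in centers])
    y = np.repeat(np.arange(k), n_per)
    return x, y


class TestClassification:
    def test_six_cluster_recovery(self, rng):
        x, y = _gaussian_clusters(rng)
        labels, _ = unitproc.classify_units(x, k=6, seed=0)
        assert adjusted_rand_score(y, labels) >= 0.95

    def test_order_invariance(self, rng):
        x, _ = _gaussian_clusters(rng)
        labels, _ = unitproc.classify_units(x, k=6, seed=0)
        perm = rng.permutation(len(x))
        labels_p, _ = unitproc.classify_units(x[perm], k=6, seed=0)
        assert adjusted_rand_score(labels[perm], labels_p) == 1.0

    def test_determinism_same_seed(self, rng):
        x, _ = _gaussian_clusters(rng)
        l1, _ = unitproc.classify_units(x, k=6, seed=3)
        l2, _ = unitproc.classify_units(x, k=6, seed=3)
        assert np.array_equal(l1, l2)

    def test_k_exceeding_units_rejected(self, rng):
        with pytest.raises(ValueError, match="exceeds"):
            unitproc.classify_units(rng.standard_normal((4, 3)), k=6)

    def test_bagged_tree_separable_high_oob(self, rng):
        x, y = _gaussian_clusters(rng, n_per=30)
        x4 = np.hstack([x, rng.standard_normal((len(x), 1))])
        chol = np.zeros(len(x), bool)
        oob, _ = unitproc.crossvalidate_bagged_tree(x4, y, chol, seed=0)
        assert oob >= 0.95

    def test_bagged_tree_shuffled_labels_chance(self, rng):
        x, y = _gaussian_clusters(rng, n_per=30)
        x4 = np.hstack([x, rng.standard_normal((len(x), 1))])
        y_sh = rng.permutation(y)
        chol = np.zeros(len(x), bool)
        oob, _ = unitproc.crossvalidate_bagged_tree(x4, y_sh, chol, seed=0)
        se = np.sqrt((1 / 6) * (5 / 6) / len(x))
        assert abs(oob - 1 / 6) < 5 * se

    def test_cholinergic_predicted_into_wide_cluster(self):
        # full pipeline on synthetic units: wide-template "cholinergic"
        # units must be predicted into a cluster dominated by wide units
        g = np.random.default_rng(8)
        units = []
        for i in range(40):
            kind = "wide" if i % 2 == 0 else "narrow"
            w = synth._template(kind) + 0.8 * g.standard_normal(32)
            rate = float(5.0 * np.exp(0.6 * g.standard_normal()))
            t = synth.poisson_train(rate, 400.0, g)
            units.append(SpikeUnit(id=i, region="OFC", spike_times=t,
                                   mean_waveform=w, session_duration=400.0,
                                   is_cholinergic=False))
        for i in range(40, 43):  # held-out cholinergic cells, wide waveform
            w = synth._template("wide") + 0.8 * g.standard_normal(32)
            t = synth.poisson_train(2.0, 400.0, g)
            units.append(SpikeUnit(id=i, region="BF", spike_times=t,
                                   mean_waveform=w, session_duration=400.0,
                                   is_cholinergic=True))
        feats = unitproc.feature_table(units)
        labels, _ = unitproc.classify_units(feats, k=6, seed=0)
        chol = feats["is_cholinergic"].to_numpy()
        oob, pred = unitproc.crossvalidate_bagged_tree(feats, labels, chol, seed=0)
        tp = feats["tp_latency_ms"].to_numpy()
        for lab in pred:
            members = tp[(labels == lab) & ~chol]
            assert members.size and np.median(members) > unitproc.TP_SPLIT_MS

    def test_preliminary_split_rule(self):
        tp = np.array([0.6, 0.3, 0.3, 0.5])
        fr = np.array([2.0, 2.0, 10.0, 8.0])
        assert unitproc.preliminary_split(tp, fr).tolist() == [
            True, True, False, True]


@given(st.integers(0, 5000))
def test_ccg_time_reversal_property(seed):
    g = np.random.default_rng(seed)
    a = np.sort(g.uniform(0, 20, 60))
    b = np.sort(g.uniform(0, 20, 60))
    cab, _ = unitproc.cross_correlogram(a, b, bin_s=1e-3, window_s=0.02)
    cba, _ = unitproc.cross_correlogram(b, a, bin_s=1e-3, window_s=0.02)
    assert np.array_equal(cab, cba[::-1])
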