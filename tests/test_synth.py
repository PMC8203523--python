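"""Synthetic-session generator: determinism, injected effects, bookkeeping."""

import numpy as np
import pytest

from bfnet import cohmap, lfpproc, synth
from bfnet.io import load_session


class TestConfig:
    def test_default_probe_geometry(self):
        cfg = synth.SynthConfig()
        counts = {p.region: p.n_sites for p in cfg.probes}
        assert counts == {"BF": 64, "OFC": 32, "V2": 32}
        assert all(
            p.vertical_pitch_um == 100.0 for p in cfg.probes if p.region != "BF"
        )

    def test_cue_duration_default_4s(self):
        assert synth.SynthConfig().epoch_durations["cue"] == 4.0

    def test_band_outside_nyquist_rejected(self):
        with pytest.raises(ValueError, match="f_lo < f_hi"):
            synth.SynthConfig(gamma_bands={"bad": (100.0, 700.0)})

    def test_nonpositive_epoch_duration_rejected(self):
        durs = dict(synth.DEFAULT_EPOCH_DURATIONS, cue=0.0)
        with pytest.raises(ValueError, match="duration"):
            synth.SynthConfig(epoch_durations=durs)

    def test_invalid_efficacy_rejected(self):
        with pytest.raises(ValueError, match="efficacy"):
            synth.CouplingSpec(pre=0, post=1, efficacy=0.0)

    def test_coupling_lag_outside_detector_window_rejected(self):
        with pytest.raises(ValueError, match="lag"):
            synth.CouplingSpec(pre=0, post=1, lag_ms=0.5)


class TestEpochs:
    def test_epochs_tile_session_without_overlap(self):
        cfg = synth.SynthConfig(n_trials=5, probes=[synth.ProbeLayout("OFC", 1, 2)],
                                light=synth.LightSpec(n_trains=3))
        ep = synth.make_epoch_table(cfg).sort_values("t_start_s")
        starts = ep["t_start_s"].to_numpy()
        ends = ep["t_end_s"].to_numpy()
        assert starts[0] == 0.0
        assert np.allclose(starts[1:], ends[:-1])
        assert ends[-1] == pytest.approx(cfg.session_duration)

    def test_six_epoch_labels_per_trial(self):
        ep = synth.make_epoch_table(synth.SynthConfig(n_trials=3))
        per_trial = ep[ep["trial"] == 1]["label"].tolist()
        assert per_trial == list(synth.EPOCH_LABELS)

    def test_light_events_inside_optostim_epoch(self):
        cfg = synth.SynthConfig(n_trials=2, light=synth.LightSpec())
        ep = synth.make_epoch_table(cfg)
        le = synth.make_light_events(cfg)
        o = ep[ep["label"] == synth.OPTOSTIM_LABEL].iloc[0]
        assert (le["t_s"] >= o["t_start_s"]).all()
        assert (le["t_s"] + le["duration_s"] <= o["t_end_s"] + 1e-9).all()
        assert len(le) >= 100


class TestLFP:
    def _tiny(self, seed=0, **kw):
        kw.setdefault("probes", [synth.ProbeLayout("OFC", 1, 2),
                                 synth.ProbeLayout("V2", 1, 2)])
        kw.setdefault("n_trials", 4)
        return synth.SynthConfig(seed=seed, **kw)

    def test_seed_determinism_bitwise(self):
        cfg = self._tiny(seed=42)
        ep = synth.make_epoch_table(cfg)
        a = synth.generate_lfp(cfg, ep)
        b = synth.generate_lfp(cfg, ep)
        assert np.array_equal(a.samples, b.samples)

    def test_different_seeds_differ(self):
        cfg = self._tiny()
        ep = synth.make_epoch_table(cfg)
        a = synth.generate_lfp(cfg, ep, seed=1)
        b = synth.generate_lfp(cfg, ep, seed=2)
        assert not np.array_equal(a.samples, b.samples)

    def test_output_rate_and_shape(self):
        cfg = self._tiny()
        rec = synth.generate_lfp(cfg, synth.make_epoch_table(cfg))
        assert rec.rate == cfg.lfp_rate
        assert rec.n_samples == int(cfg.session_duration * cfg.lfp_rate)
        assert rec.samples.shape[1] == 4

    def test_hotspot_raises_epoch_coherence_over_center(self):
        cfg = self._tiny(seed=7, hotspots=[synth.HotspotSpec(
            channel_pairs=((0, 2),), band="low_gamma", epoch="decision",
            coupling=0.9)])
        ep = synth.make_epoch_table(cfg)
        rec = synth.generate_lfp(cfg, ep)
        ve, vb, _, _ = cohmap.trial_coherence_samples(
            rec, ep, "OFC", "V2", "low_gamma", "decision")
        assert ve[0, 0].mean() > vb[0, 0].mean() + 0.1

    def test_no_coupling_channels_independent(self):
        cfg = self._tiny(seed=3)
        ep = synth.make_epoch_table(cfg)
        rec = synth.generate_lfp(cfg, ep)
        ve, vb, _, _ = cohmap.trial_coherence_samples(
            rec, ep, "OFC", "V2", "low_gamma", "decision")
        assert ve.mean() < 0.05 and vb.mean() < 0.05


class TestCoherenceMonotonicInCoupling:
    def test_band_coherence_increases_with_coupling(self):
        means = {}
        for c in (0.2, 0.5, 0.9):
            vals = []
            for seed in range(20):
                cfg = synth.SynthConfig(
                    seed=seed, n_trials=3,
                    probes=[synth.ProbeLayout("OFC", 1, 1),
                            synth.ProbeLayout("V2", 1, 1)],
                    hotspots=[synth.HotspotSpec(channel_pairs=((0, 1),),
                                                band="low_gamma",
                                                epoch="decision", coupling=c)],
                )
                ep = synth.make_epoch_table(cfg)
                rec = synth.generate_lfp(cfg, ep)
                ve, _, _, _ = cohmap.trial_coherence_samples(
                    rec, ep, "OFC", "V2", "low_gamma", "decision")
                vals.append(ve.mean())
            means[c] = np.mean(vals)
        assert means[0.2] < means[0.5] < means[0.9]


class TestUnits:
    def _cfg(self, **kw):
        kw.setdefault("probes", [synth.ProbeLayout("BF", 2, 4)])
        kw.setdefault("n_trials", 40)  # >= 600 s session
        return synth.SynthConfig(**kw)

    def test_rate_fidelity_within_3_se(self):
        cfg = self._cfg(seed=9, units=[synth.UnitSpec(0, mean_rate_hz=5.0),
                                       synth.UnitSpec(1, mean_rate_hz=2.16)])
        ep = synth.make_epoch_table(cfg)
        units, _ = synth.generate_units(cfg, ep, synth.make_light_events(cfg))
        t_total = cfg.session_duration
        assert t_total >= 600
        for u, spec in zip(units, cfg.units):
            se = np.sqrt(spec.mean_rate_hz / t_total)
            assert abs(u.mean_rate - spec.mean_rate_hz) < 3 * se

    def test_excitatory_insertion_count_matches_log(self, rng):
        # ~50,000 pre spikes at efficacy 0.2 -> ~10,000 logged insertions
        pre = synth.poisson_train(50.0, 1000.0, rng)
        post = synth.poisson_train(5.0, 1000.0, rng)
        c = synth.CouplingSpec(pre=0, post=1, efficacy=0.2, lag_ms=2.5)
        merged, n_ins = synth.apply_coupling(pre, post, c, 1000.0, rng)
        expect = 0.2 * pre.size
        sd = np.sqrt(pre.size * 0.2 * 0.8)
        assert abs(n_ins - expect) < 4 * sd
        assert merged.size == post.size + n_ins

    def test_inhibitory_full_efficacy_empties_deletion_window(self, rng):
        pre = synth.poisson_train(10.0, 300.0, rng)
        post = synth.poisson_train(30.0, 300.0, rng)
        c = synth.CouplingSpec(pre=0, post=1, sign="inhibitory", efficacy=1.0,
                               lag_ms=3.0, jitter_ms=1.0)
        new_post, n_del = synth.apply_coupling(pre, post, c, 300.0, rng)
        assert n_del > 0
        idx = np.searchsorted(pre, new_post)
        prev = np.where(idx > 0, new_post - pre[np.maximum(idx - 1, 0)], np.inf)
        assert not np.any((prev > 0.002) & (prev < 0.004))

    def test_zero_light_probability_flat_psth(self):
        from bfnet import unitproc

        cfg = self._cfg(seed=4, n_trials=2,
                        units=[synth.UnitSpec(0, mean_rate_hz=20.0)],
                        light=synth.LightSpec())
        ep = synth.make_epoch_table(cfg)
        le = synth.make_light_events(cfg)
        units, truth = synth.generate_units(cfg, ep, le)
        assert truth.tagged_units == []
        res = unitproc.optotag(units[0], le)
        # PSTH flat: in-pulse bin counts comparable to off-pulse bins
        counts = res.psth_counts
        assert counts.sum() > 0
        centers = (res.psth_edges[:-1] + res.psth_edges[1:]) / 2
        inside = counts[(centers > 0) & (centers < 0.01)].mean()
        outside = counts[centers < 0].mean()
        assert inside < 3 * max(outside, 0.5)

    def test_waveform_templates_tp_latency(self):
        wide = synth._template("wide")
        narrow = synth._template("narrow")
        assert int(np.argmin(wide)) == 10
        assert int(np.argmin(narrow)) == 10
        assert int(np.argmax(wide[10:])) == 12  # 0.6 ms at 20 kHz
        assert int(np.argmax(narrow[10:])) == 5  # 0.25 ms


class TestDataset:
    def test_default_config_channel_counts(self, tmp_path):
        cfg = synth.SynthConfig(seed=0, n_trials=1)
        lfp, *_ = synth.generate_dataset(cfg, tmp_path / "d")
        regions = [c.region for c in lfp.channels]
        assert regions.count("BF") == 64
        assert regions.count("OFC") == 32
        assert regions.count("V2") == 32

    def test_round_trip_equals_in_memory(self, small_session):
        s = load_session(small_session["dir"])
        assert np.allclose(
            s.lfp.samples, small_session["lfp"].samples, atol=1e-4
        )
        assert s.lfp.channels == small_session["lfp"].channels
        assert len(s.units) == len(small_session["units"])
        for a, b in zip(s.units, small_session["units"]):
            assert a.id == b.id and a.region == b.region
            assert np.allclose(a.spike_times, b.spike_times, atol=1e-9)
            assert a.is_cholinergic == b.is_cholinergic
        assert s.epochs.equals(small_session["epochs"])
        assert s.ground_truth is not None
        assert s.ground_truth.tagged_units == small_session["truth"].tagged_units

    def test_empty_trial_count_still_valid(self, tmp_path):
        cfg = synth.SynthConfig(seed=1, n_trials=0,
                                probes=[synth.ProbeLayout("OFC", 1, 2)])
        synth.generate_dataset(cfg, tmp_path / "e")
        s = load_session(tmp_path / "e")
        assert len(s.epochs) == 0 and s.lfp.n_samples == 0

    def test_ground_truth_bookkeeping(self, small_session):
        truth = small_session["truth"]
        cfg = small_session["config"]
        assert len(truth.hotspots) == len(cfg.hotspots) == 1
        assert len(truth.couplings) == len(cfg.couplings) == 1
        assert len(truth.sta_effects) == len(cfg.sta_effects) == 1
        assert truth.tagged_units == [0]
        assert truth.couplings[0]["n_changed"] > 0

    def test_empty_injections_empty_truth(self):
        cfg = synth.SynthConfig(seed=0, n_trials=1,
                                probes=[synth.ProbeLayout("BF", 1, 2)],
                                units=[synth.UnitSpec(0)])
        ep = synth.make_epoch_table(cfg)
        _, truth = synth.generate_units(cfg, ep, synth.make_light_events(cfg))
        assert truth.hotspots == [] and truth.couplings == []
        assert truth.tagged_units == [] and truth.sta_effects == []

    def test_sta_effect_requires_spikes(self):
        cfg = synth.SynthConfig(
            seed=0, n_trials=1, probes=[synth.ProbeLayout("V2", 1, 2)],
            sta_effects=[synth.StaEffectSpec(trigger_unit=0, target_channels=(0,))],
        )
        with pytest.raises(ValueError, match="unit_spikes"):
            synth.generate_lfp(cfg, synth.make_epoch_table(cfg))
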