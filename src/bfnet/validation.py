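"""Parameter-recovery and calibration batteries on synthetic sessions.

Each function regenerates its inputs from a seed, runs the analysis
exactly as a user would, and scores the result against the generator's
ground truth: map sensitivity/false-discovery, CCG detection and false-
alarm rates, optotag hit rate and specificity, STA selectivity and null
calibration, and classifier recovery.  These are the quantitative
checks behind the package's claims about its own statistical behaviour.
"""

from __future__ import annotations

import numpy as np
from sklearn.metrics import adjusted_rand_score

from . import cohmap, stamod, synth, unitproc


def _spawn(seed: int, n: int) -> list[int]:
    """Independent child seeds below 2**31."""
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


# ---------------------------------------------------------------------------
# coherence change maps
# ---------------------------------------------------------------------------


def map_recovery_experiment(
    seed: int = 0,
    n_seeds: int = 20,
    n_trials: int = 20,
    coupling: float = 0.8,
    alpha: float = 0.01,
    n_perm: int = 1000,
) -> dict:
    """Hotspot recovery on full 32x32 cortico-cortical maps.

    Each session injects one shared low-gamma source across an 8x8 block
    of OFC x V2 contact pairs (64 of 1024 voxels) during the decision
    epoch.  Returns mean sensitivity and false-discovery proportion of
    the significant-and-positive voxel set against ground truth.
    """
    ofc = list(range(0, 8))
    v2 = list(range(32, 40))
    pairs = tuple((a, b) for a in ofc for b in v2)
    sens, fdp = [], []
    for s in _spawn(seed, n_seeds):
        cfg = synth.SynthConfig(
            seed=s, n_trials=n_trials,
            probes=[synth.ProbeLayout("OFC", 4, 8), synth.ProbeLayout("V2", 4, 8)],
            hotspots=[synth.HotspotSpec(channel_pairs=pairs, band="low_gamma",
                                        epoch="decision", coupling=coupling)],
        )
        ep = synth.make_epoch_table(cfg)
        rec = synth.generate_lfp(cfg, ep)
        m = cohmap.build_change_map(rec, ep, "OFC", "V2", "low_gamma",
                                    "decision", alpha=alpha, n_perm=n_perm,
                                    seed=s)
        truth = np.zeros(m.scores.shape, bool)
        ia = {c: i for i, c in enumerate(m.channels_a)}
        ib = {c: i for i, c in enumerate(m.channels_b)}
        for a, b in pairs:
            truth[ia[a], ib[b]] = True
        detected = m.mask & (m.scores > 0)
        tp = int((detected & truth).sum())
        fp = int((detected & ~truth).sum())
        sens.append(tp / truth.sum())
        fdp.append(fp / max(int(detected.sum()), 1))
    return {"sensitivity": float(np.mean(sens)), "fdp": float(np.mean(fdp)),
            "n_seeds": n_seeds, "n_voxels": 1024}


def null_map_calibration(
    seed: int = 0, n_seeds: int = 6, alpha: float = 0.05, n_perm: int = 500,
    n_trials: int = 12,
) -> dict:
    """Significant-voxel rate on coupling-free sessions (should be ~alpha)."""
    flags, total = 0, 0
    for s in _spawn(seed, n_seeds):
        cfg = synth.SynthConfig(
            seed=s, n_trials=n_trials,
            probes=[synth.ProbeLayout("OFC", 2, 4), synth.ProbeLayout("V2", 2, 4)],
        )
        ep = synth.make_epoch_table(cfg)
        rec = synth.generate_lfp(cfg, ep)
        m = cohmap.build_change_map(rec, ep, "OFC", "V2", "low_gamma",
                                    "decision", alpha=alpha, n_perm=n_perm,
                                    seed=s)
        flags += int(m.mask.sum())
        total += m.n_voxels
    return {"rate": flags / total, "n_tests": total}


# ---------------------------------------------------------------------------
# CCG detector
# ---------------------------------------------------------------------------


def poisson_threshold_oracle_agreement(seed: int = 0, n_rates: int = 1000) -> dict:
    """Fraction of random predicted rates where the per-bin threshold
    equals direct summation of the Poisson pmf up to the 0.9999 quantile."""
    rng = np.random.default_rng(seed)
    rates = rng.uniform(0.005, 40.0, n_rates)
    agree = 0
    for lam in rates:
        k, cdf, term = 0, np.exp(-lam), np.exp(-lam)
        while cdf < 0.9999:
            k += 1
            term *= lam / k
            cdf += term
        agree += int(unitproc.poisson_threshold(lam, 0.9999)) == k
    return {"agreement": agree / n_rates, "n": n_rates}


def ccg_detection_experiment(
    seed: int = 0, n_seeds: int = 20, efficacy: float = 0.2,
    lag_ms: float = 2.5, duration_s: float = 700.0, rate_hz: float = 5.0,
) -> dict:
    """Detection rate for injected excitatory couplings (>=3000 pre spikes)."""
    hits = 0
    for s in _spawn(seed, n_seeds):
        rng = np.random.default_rng(s)
        pre = synth.poisson_train(rate_hz, duration_s, rng)
        post = synth.poisson_train(rate_hz, duration_s, rng)
        c = synth.CouplingSpec(pre=0, post=1, efficacy=efficacy, lag_ms=lag_ms,
                               jitter_ms=0.5)
        post2, _ = synth.apply_coupling(pre, post, c, duration_s, rng)
        r = unitproc.ccg_detect(pre, post2)
        hits += r.detected and r.sign == "excitatory"
    return {"rate": hits / n_seeds, "n_seeds": n_seeds}


def ccg_false_detection_experiment(
    seed: int = 0, n_pairs: int = 300, duration_s: float = 600.0,
    rate_hz: float = 5.0,
) -> dict:
    """False-detection rate on independent Poisson pairs.

    The analytic null: each bin exceeds the 99.99th Poisson percentile
    with probability < 1e-4, and a detection needs two consecutive such
    bins among the 7 in-window bins, so false detections are ~never.
    """
    det = 0
    for s in _spawn(seed, n_pairs):
        rng = np.random.default_rng(s)
        a = synth.poisson_train(rate_hz, duration_s, rng)
        b = synth.poisson_train(rate_hz, duration_s, rng)
        det += unitproc.ccg_detect(a, b).detected
    return {"rate": det / n_pairs, "n_pairs": n_pairs}


# ---------------------------------------------------------------------------
# optotagging
# ---------------------------------------------------------------------------


def optotag_battery(seed: int = 0, n_units: int = 100,
                    evoked_prob: float = 0.8) -> dict:
    """Hit rate on light-responsive units and specificity on null units.

    Each simulated unit fires at ~2 Hz; responsive units emit an extra
    spike on 80% of the 10 ms pulses.  The 2 SD criterion should flag
    every responsive unit (direction up) and pass null units at its
    nominal specificity.
    """
    light = synth.LightSpec()
    hits = flags = 0
    for i, s in enumerate(_spawn(seed, 2 * n_units)):
        responsive = i < n_units
        cfg = synth.SynthConfig(
            seed=s, n_trials=0, probes=[synth.ProbeLayout("BF", 1, 2)],
            units=[synth.UnitSpec(0, mean_rate_hz=2.16, is_cholinergic=responsive,
                                  light_response_prob=evoked_prob if responsive else 0.0)],
            light=light,
        )
        ep = synth.make_epoch_table(cfg)
        le = synth.make_light_events(cfg)
        units, _ = synth.generate_units(cfg, ep, le)
        r = unitproc.optotag(units[0], le)
        if responsive:
            hits += r.responsive and r.direction == "up"
        else:
            flags += r.responsive
    return {"hit_rate": hits / n_units, "specificity": 1.0 - flags / n_units,
            "n_units": n_units}


# ---------------------------------------------------------------------------
# spike-triggered gamma
# ---------------------------------------------------------------------------


def sta_battery(seed: int = 0, n_seeds: int = 50, gain: float = 2.0,
                alpha: float = 0.05) -> dict:
    """Single-channel STA-effect selectivity and null-site calibration.

    Each session carries one cholinergic-like 2.16 Hz trigger and a
    post-spike low-gamma gain on channel 0 of an 8-site probe; the other
    7 sites (both bands) are null tests.  Null flag rates are reported
    at the requested alpha and at 0.01.  The KS null runs slightly
    conservative at alpha=0.05 (spike-triggered windows of one session
    are weakly dependent); see the methods note for the calibration
    contract.
    """
    target_hits, null_n = 0, 0
    null_p: list[float] = []
    for s in _spawn(seed, n_seeds):
        cfg = synth.SynthConfig(
            seed=s, n_trials=10, probes=[synth.ProbeLayout("V2", 1, 8)],
            units=[synth.UnitSpec(0, region="V2", mean_rate_hz=2.16,
                                  is_cholinergic=True)],
            sta_effects=[synth.StaEffectSpec(trigger_unit=0, target_channels=(0,),
                                             band="low_gamma", gain=gain)],
        )
        ep = synth.make_epoch_table(cfg)
        units, _ = synth.generate_units(cfg, ep, synth.make_light_events(cfg))
        rec = synth.generate_lfp(cfg, ep, unit_spikes={0: units[0].spike_times})
        res = stamod.sta_scan(units[0], rec, channels=list(range(8)), alpha=alpha)
        tgt = res[(res.channel == 0) & (res.band == "low_gamma")]
        target_hits += int(tgt.iloc[0]["significant"])
        null = res[res.channel != 0]
        null_p += list(null["p_value"])
        null_n += len(null)
    null_p_arr = np.asarray(null_p)
    return {"target_rate": target_hits / n_seeds,
            "null_rate": float((null_p_arr < alpha).mean()),
            "null_rate_alpha01": float((null_p_arr < 0.01).mean()),
            "n_null_tests": null_n, "n_seeds": n_seeds}


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------


def _separated_clusters(rng, k=6, n_per=20, sep=5.0, dim=3):
    centers = []
    while len(centers) < k:
        c = rng.uniform(-4 * sep, 4 * sep, dim)
        if all(np.linalg.norm(c - o) >= sep for o in centers):
            centers.append(c)
    x = np.vstack([c + rng.standard_normal((n_per, dim)) for c in centers])
    y = np.repeat(np.arange(k), n_per)
    return x, y


def classifier_battery(seed: int = 0) -> dict:
    """Six-cluster recovery, bagged-tree OOB accuracy, chance on shuffled
    labels, and prediction of wide-waveform cholinergic units."""
    rng = np.random.default_rng(seed)
    x, y = _separated_clusters(rng)
    labels, _ = unitproc.classify_units(x, k=6, seed=seed)
    ari = adjusted_rand_score(y, labels)

    x4 = np.hstack([x, rng.standard_normal((len(x), 1))])
    chol = np.zeros(len(x), bool)
    oob_sep, _ = unitproc.crossvalidate_bagged_tree(x4, y, chol, seed=seed)
    oob_shuf, _ = unitproc.crossvalidate_bagged_tree(
        x4, rng.permutation(y), chol, seed=seed)

    # full waveform pipeline: wide-template cholinergic cells land in
    # wide-waveform clusters.  Training rates are heterogeneous
    # (lognormal around 5 Hz) as in real unit populations, so the
    # cholinergic cells' low rates are not outside the training support;
    # the score is the population-level fraction predicted into clusters
    # whose members have wide (TP > 0.485 ms) waveforms.
    units = []
    for i in range(80):
        kind = "wide" if i % 2 == 0 else "narrow"
        w = synth._template(kind) + 0.8 * rng.standard_normal(32)
        rate = float(5.0 * np.exp(0.6 * rng.standard_normal()))
        units.append(unitproc.SpikeUnit(
            id=i, region="OFC", spike_times=synth.poisson_train(rate, 400.0, rng),
            mean_waveform=w, session_duration=400.0))
    for i in range(80, 88):
        w = synth._template("wide") + 0.8 * rng.standard_normal(32)
        units.append(unitproc.SpikeUnit(
            id=i, region="BF", spike_times=synth.poisson_train(2.16, 400.0, rng),
            mean_waveform=w, session_duration=400.0, is_cholinergic=True))
    feats = unitproc.feature_table(units)
    klabels, _ = unitproc.classify_units(feats, k=6, seed=seed)
    mask = feats["is_cholinergic"].to_numpy()
    _, pred = unitproc.crossvalidate_bagged_tree(feats, klabels, mask, seed=seed)
    tp = feats["tp_latency_ms"].to_numpy()
    wide_frac = float(np.mean([
        np.median(tp[(klabels == lab) & ~mask]) > unitproc.TP_SPLIT_MS
        for lab in pred
    ]))
    return {"ari": float(ari), "oob_separated": float(oob_sep),
            "oob_shuffled": float(oob_shuf),
            "cholinergic_wide_fraction": wide_frac,
            "n_cholinergic": int(mask.sum())}
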