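"""Seeded synthetic recordings with the statistical structure the analysis assumes.

The generator emulates the study conditions: a 64-site / 8-shank basal
forebrain probe plus two 32-site / 4-shank cortical probes (OFC, V2),
epoch-structured trials (center/rest, 4-s cue, decision, approach,
consume, return), gamma-band coherence hotspots between designated
contact pairs, low-rate light-responsive ("cholinergic") units,
excitatory/inhibitory spike couplings at millisecond lags, and
multiplicative post-spike gamma-amplitude modulation at designated
cortical sites.  It is statistical, not biophysical: 1/f-shaped Gaussian
background plus narrowband Gaussian gamma components and Poisson spike
trains.  Every injected effect is recorded in a :class:`GroundTruth`
object so recovery can be scored exactly.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .lfpproc import DEFAULT_BANDS, LFP_RATE, ChannelInfo, LFPRecording
from .unitproc import SpikeUnit

EPOCH_LABELS = ("center", "cue", "decision", "approach", "consume", "return")
OPTOSTIM_LABEL = "optostim"

#: Default epoch durations (s).  The cue is 4 s by experimental design; the
#: center/rest baseline matches it; locomotor epochs are shorter.
DEFAULT_EPOCH_DURATIONS = {
    "center": 4.0,
    "cue": 4.0,
    "decision": 2.0,
    "approach": 2.0,
    "consume": 2.0,
    "return": 2.0,
}

WAVEFORM_RATE = 20_000.0
WAVEFORM_SAMPLES = 32


# ---------------------------------------------------------------------------
# configuration types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ProbeLayout:
    """Silicon-probe geometry for one region."""

    region: str
    n_shanks: int = 4
    sites_per_shank: int = 8
    vertical_pitch_um: float = 100.0
    shank_pitch_um: float = 200.0

    @property
    def n_sites(self) -> int:
        return self.n_shanks * self.sites_per_shank


def default_probes() -> list[ProbeLayout]:
    """BF 8x8 plus two cortical 4x8 probes with 100 um vertical pitch."""
    return [
        ProbeLayout("BF", n_shanks=8, sites_per_shank=8, vertical_pitch_um=20.0),
        ProbeLayout("OFC", n_shanks=4, sites_per_shank=8, vertical_pitch_um=100.0),
        ProbeLayout("V2", n_shanks=4, sites_per_shank=8, vertical_pitch_um=100.0),
    ]


@dataclass(frozen=True)
class HotspotSpec:
    """A shared narrowband source injected into a set of channel pairs.

    ``coupling`` is the amplitude fraction of the shared source in each
    channel's band component during ``epoch`` (0 elsewhere, so the
    coupling is strictly greater in its epoch than at rest).
    """

    channel_pairs: tuple[tuple[int, int], ...]
    band: str = "low_gamma"
    epoch: str = "decision"
    coupling: float = 0.8
    lag_ms: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.coupling <= 1.0:
            raise ValueError("coupling must lie in [0, 1]")


@dataclass(frozen=True)
class UnitSpec:
    """One synthetic spike unit."""

    unit_id: int
    region: str = "BF"
    mean_rate_hz: float = 5.0
    template: str = "wide"  # "wide" or "narrow"
    is_cholinergic: bool = False
    light_response_prob: float = 0.0  # extra-spike probability per pulse
    epoch_rate_gain: tuple[tuple[str, float], ...] = ()

    def __post_init__(self) -> None:
        if self.mean_rate_hz < 0:
            raise ValueError("mean rate must be non-negative")
        if self.template not in ("wide", "narrow"):
            raise ValueError("template must be 'wide' or 'narrow'")


def cholinergic_unit(unit_id: int, rate_hz: float = 2.16,
                     light_response_prob: float = 0.8) -> UnitSpec:
    """A BF cholinergic unit: low rate (~2 Hz), wide waveform, light-responsive."""
    return UnitSpec(unit_id, region="BF", mean_rate_hz=rate_hz, template="wide",
                    is_cholinergic=True, light_response_prob=light_response_prob)


@dataclass(frozen=True)
class CouplingSpec:
    """Directed short-latency spike coupling between two units."""

    pre: int
    post: int
    sign: str = "excitatory"  # or "inhibitory"
    efficacy: float = 0.2
    lag_ms: float = 2.5
    jitter_ms: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 < self.efficacy <= 1.0:
            raise ValueError("efficacy must lie in (0, 1]")
        if self.sign not in ("excitatory", "inhibitory"):
            raise ValueError("sign must be 'excitatory' or 'inhibitory'")
        if not 1.5 <= self.lag_ms <= 5.0:
            raise ValueError("lag must lie inside the detector window [1.5, 5] ms")


@dataclass(frozen=True)
class StaEffectSpec:
    """Multiplicative gamma-amplitude gain after each trigger spike."""

    trigger_unit: int
    target_channels: tuple[int, ...] = ()
    band: str = "low_gamma"
    gain: float = 2.0
    window_s: float = 0.5  # gain applies on (spike, spike + window_s]

    def __post_init__(self) -> None:
        if self.gain <= 0:
            raise ValueError("gain must be positive")


@dataclass(frozen=True)
class LightSpec:
    """Optotagging pulse-train protocol: 10 ms pulses in 2-s trains.

    The within-train inter-pulse interval is not pinned down by the
    protocol description; it is a free parameter here (default 100 ms
    period, i.e. 20 pulses per train).
    """

    n_trains: int = 15
    train_duration_s: float = 2.0
    pulse_width_s: float = 0.010
    pulse_period_s: float = 0.100
    inter_train_gap_s: float = 3.0

    @property
    def pulses_per_train(self) -> int:
        return int(self.train_duration_s / self.pulse_period_s)

    @property
    def n_pulses(self) -> int:
        return self.n_trains * self.pulses_per_train


@dataclass
class SynthConfig:
    """Full description of one synthetic session."""

    seed: int = 0
    n_trials: int = 20
    epoch_durations: dict = field(default_factory=lambda: dict(DEFAULT_EPOCH_DURATIONS))
    probes: list[ProbeLayout] = field(default_factory=default_probes)
    lfp_rate: float = LFP_RATE
    noise_exponent: float = 1.0
    background_rms_uv: float = 30.0
    band_rms_uv: float = 15.0
    gamma_bands: dict = field(default_factory=lambda: dict(DEFAULT_BANDS))
    hotspots: list[HotspotSpec] = field(default_factory=list)
    units: list[UnitSpec] = field(default_factory=list)
    couplings: list[CouplingSpec] = field(default_factory=list)
    sta_effects: list[StaEffectSpec] = field(default_factory=list)
    light: LightSpec | None = None

    def __post_init__(self) -> None:
        for label, d in self.epoch_durations.items():
            if d <= 0:
                raise ValueError(f"epoch {label!r} duration must be > 0")
        for label, (lo, hi) in self.gamma_bands.items():
            if not 0 < lo < hi < self.lfp_rate / 2:
                raise ValueError(
                    f"band {label!r} edges must satisfy 0 < f_lo < f_hi < rate/2"
                )

    @property
    def trial_duration(self) -> float:
        return float(sum(self.epoch_durations.values()))

    @property
    def session_duration(self) -> float:
        dur = self.n_trials * self.trial_duration
        if self.light is not None:
            dur += self.light.n_trains * (
                self.light.train_duration_s + self.light.inter_train_gap_s
            )
        return dur

    def channel_table(self) -> list[ChannelInfo]:
        chans: list[ChannelInfo] = []
        next_id = 0
        for probe in self.probes:
            for shank in range(probe.n_shanks):
                for site in range(probe.sites_per_shank):
                    chans.append(
                        ChannelInfo(
                            id=next_id, region=probe.region, shank=shank,
                            site=site, depth_um=site * probe.vertical_pitch_um,
                        )
                    )
                    next_id += 1
        return chans


@dataclass
class GroundTruth:
    """Record of every injected effect; the recovery oracle."""

    hotspots: list[dict] = field(default_factory=list)
    couplings: list[dict] = field(default_factory=list)
    tagged_units: list[int] = field(default_factory=list)
    sta_effects: list[dict] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        return cls(**d)


# ---------------------------------------------------------------------------
# epochs and light events
# ---------------------------------------------------------------------------


def make_epoch_table(config: SynthConfig) -> pd.DataFrame:
    """Tile the session with per-trial epochs plus a final optostim block.

    Columns: trial, label, t_start_s, t_end_s (half-open intervals).  The
    optostim block, if any, carries trial = -1.
    """
    rows = []
    t = 0.0
    for trial in range(config.n_trials):
        for label in EPOCH_LABELS:
            d = config.epoch_durations[label]
            rows.append((trial, label, t, t + d))
            t += d
    if config.light is not None:
        end = config.session_duration
        rows.append((-1, OPTOSTIM_LABEL, t, end))
    return pd.DataFrame(rows, columns=["trial", "label", "t_start_s", "t_end_s"])


def make_light_events(config: SynthConfig) -> pd.DataFrame:
    """Pulse onset times within the optostim block.  Columns: t_s, duration_s."""
    if config.light is None:
        return pd.DataFrame(columns=["t_s", "duration_s"])
    spec = config.light
    t0 = config.n_trials * config.trial_duration
    times = []
    t = t0 + spec.inter_train_gap_s
    for _ in range(spec.n_trains):
        for p in range(spec.pulses_per_train):
            times.append(t + p * spec.pulse_period_s)
        t += spec.train_duration_s + spec.inter_train_gap_s
    return pd.DataFrame({"t_s": times, "duration_s": spec.pulse_width_s})


def _epoch_intervals(epochs: pd.DataFrame, label: str) -> list[tuple[float, float]]:
    sel = epochs[epochs["label"] == label]
    return list(zip(sel["t_start_s"], sel["t_end_s"]))


# ---------------------------------------------------------------------------
# LFP synthesis
# ---------------------------------------------------------------------------


def _one_over_f(n: int, rate: float, exponent: float, rms: float,
                rng: np.random.Generator) -> np.ndarray:
    """Spectrally shaped Gaussian noise: power ~ 1/f^exponent."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / rate)
    shape = np.ones_like(f)
    nz = f > 0
    shape[nz] = f[nz] ** (-exponent / 2.0)
    shape[0] = 0.0  # no DC
    x = np.fft.irfft(spec * shape, n)
    return x * (rms / max(x.std(), 1e-30))


def _band_noise(n: int, rate: float, band: tuple[float, float],
                rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS Gaussian noise band-limited to [f_lo, f_hi]."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / rate)
    mask = (f >= band[0]) & (f <= band[1])
    x = np.fft.irfft(spec * mask, n)
    return x / max(x.std(), 1e-30)


def _ramped_indicator(n: int, rate: float, intervals, ramp_s: float = 0.05) -> np.ndarray:
    """0/1 envelope over the given intervals with cosine ramps at the edges."""
    env = np.zeros(n)
    nr = max(int(round(ramp_s * rate)), 1)
    ramp = 0.5 * (1 - np.cos(np.linspace(0, math.pi, nr)))
    for t0, t1 in intervals:
        s0, s1 = int(round(t0 * rate)), int(round(t1 * rate))
        s0, s1 = max(s0, 0), min(s1, n)
        if s1 <= s0:
            continue
        env[s0:s1] = 1.0
        m = min(nr, (s1 - s0) // 2)
        env[s0 : s0 + m] = ramp[:m]
        env[s1 - m : s1] = ramp[:m][::-1]
    return env


def generate_lfp(
    config: SynthConfig,
    epochs: pd.DataFrame,
    seed: int | None = None,
    unit_spikes: dict[int, np.ndarray] | None = None,
) -> LFPRecording:
    """Synthesize the multichannel LFP.

    Per channel: 1/f background plus one independent narrowband component
    per configured gamma band.  Each hotspot mixes a shared narrowband
    source into its channels with amplitude fraction ``coupling`` during
    its epoch only (channel = sqrt(1-c^2) * own + c * shared inside the
    band component, cosine-ramped at epoch edges).  STA effects multiply
    the band component of their target channels by ``gain`` in the window
    after each trigger spike, which requires ``unit_spikes``.
    """
    if seed is None:
        seed = config.seed
    rate = config.lfp_rate
    channels = config.channel_table()
    n = int(round(config.session_duration * rate))
    if n == 0:  # degenerate but valid: an empty session
        return LFPRecording(samples=np.empty((0, len(channels)), np.float32),
                            rate=rate, channels=channels)

    if config.sta_effects and unit_spikes is None:
        raise ValueError("sta_effects require unit spike trains (unit_spikes)")

    ss = np.random.SeedSequence([int(seed), 0x1F9])
    rng_bg, rng_band, rng_shared = [np.random.default_rng(s) for s in ss.spawn(3)]

    # shared hotspot sources, one per hotspot
    shared = {
        i: _band_noise(n, rate, config.gamma_bands[h.band], rng_shared)
        for i, h in enumerate(config.hotspots)
    }
    # per-channel hotspot membership: channel -> (hotspot idx)
    member: dict[int, list[int]] = {}
    for i, h in enumerate(config.hotspots):
        for a, b in h.channel_pairs:
            member.setdefault(a, []), member.setdefault(b, [])
            if i not in member[a]:
                member[a].append(i)
            if i not in member[b]:
                member[b].append(i)
    sta_by_channel: dict[int, list[StaEffectSpec]] = {}
    for eff in config.sta_effects:
        for ch in eff.target_channels:
            sta_by_channel.setdefault(ch, []).append(eff)

    samples = np.empty((n, len(channels)), dtype=np.float32)
    for col, ch in enumerate(channels):
        x = _one_over_f(n, rate, config.noise_exponent,
                        config.background_rms_uv, rng_bg)
        for blabel, bedges in config.gamma_bands.items():
            own = _band_noise(n, rate, bedges, rng_band)
            comp = own
            for i in member.get(ch.id, []):
                h = config.hotspots[i]
                if h.band != blabel:
                    continue
                w = h.coupling * _ramped_indicator(
                    n, rate, _epoch_intervals(epochs, h.epoch)
                )
                comp = np.sqrt(np.clip(1.0 - w**2, 0.0, None)) * comp + w * shared[i]
            comp = comp * config.band_rms_uv
            for eff in sta_by_channel.get(ch.id, []):
                if eff.band != blabel:
                    continue
                gain_env = np.ones(n)
                spikes = np.asarray(unit_spikes[eff.trigger_unit])
                for t in spikes:
                    s0 = int(round(t * rate)) + 1
                    s1 = int(round((t + eff.window_s) * rate)) + 1
                    gain_env[max(s0, 0) : min(s1, n)] = eff.gain
                comp = comp * gain_env
            x = x + comp
        samples[:, col] = x
    return LFPRecording(samples=samples, rate=rate, channels=channels)


# ---------------------------------------------------------------------------
# spike-train synthesis
# ---------------------------------------------------------------------------


def poisson_train(rate_hz: float, duration_s: float,
                  rng: np.random.Generator, t0: float = 0.0) -> np.ndarray:
    """Homogeneous Poisson spike train on [t0, t0 + duration)."""
    if rate_hz <= 0 or duration_s <= 0:
        return np.empty(0)
    count = rng.poisson(rate_hz * duration_s)
    return np.sort(t0 + rng.random(count) * duration_s)


def apply_coupling(
    pre: np.ndarray,
    post: np.ndarray,
    coupling: CouplingSpec,
    duration_s: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, int]:
    """Insert (excitatory) or delete (inhibitory) post spikes around pre spikes.

    Excitatory: each pre spike inserts a post spike at lag +- jitter with
    probability ``efficacy``.  Inhibitory: post spikes falling in
    (lag - jitter, lag + jitter) after a pre spike are deleted with
    probability ``efficacy`` (thinning).  Returns the modified post train
    and the number of inserted/deleted spikes.
    """
    lag = coupling.lag_ms / 1000.0
    jit = coupling.jitter_ms / 1000.0
    if coupling.sign == "excitatory":
        hit = rng.random(pre.size) < coupling.efficacy
        extra = pre[hit] + lag + rng.uniform(-jit, jit, int(hit.sum()))
        extra = extra[(extra >= 0) & (extra < duration_s)]
        merged = np.sort(np.concatenate([post, extra]))
        return np.unique(merged), extra.size
    # inhibitory: deletion windows
    if post.size == 0 or pre.size == 0:
        return post, 0
    idx = np.searchsorted(pre, post)
    prev = np.where(idx > 0, post - pre[np.maximum(idx - 1, 0)], np.inf)
    in_window = (prev > lag - jit) & (prev < lag + jit)
    doomed = in_window & (rng.random(post.size) < coupling.efficacy)
    return post[~doomed], int(doomed.sum())


def _template(kind: str) -> np.ndarray:
    """Biphasic waveform template at 20 kHz, 32 samples, trough at sample 10.

    Wide: peak at sample 22 (trough-to-peak 0.6 ms); narrow: peak at
    sample 15 (0.25 ms).
    """
    t = np.arange(WAVEFORM_SAMPLES, dtype=float)
    trough_at = 10.0
    peak_at = 22.0 if kind == "wide" else 15.0
    trough_w = 2.0 if kind == "wide" else 1.3
    peak_w = 5.0 if kind == "wide" else 2.5
    w = -100.0 * np.exp(-0.5 * ((t - trough_at) / trough_w) ** 2)
    w += 45.0 * np.exp(-0.5 * ((t - peak_at) / peak_w) ** 2)
    # ensure the global extrema sit exactly on the nominal samples
    return w


def generate_units(
    config: SynthConfig,
    epochs: pd.DataFrame,
    light_events: pd.DataFrame,
    seed: int | None = None,
) -> tuple[list[SpikeUnit], GroundTruth]:
    """Generate spike units, apply couplings and light responses.

    Base trains are Poisson at the unit's rate (piecewise-constant when
    ``epoch_rate_gain`` multipliers are present).  Light-responsive units
    emit one extra spike per pulse with the configured probability.
    Couplings are applied after base generation; insertion/deletion
    counts are logged in the returned :class:`GroundTruth`.
    """
    if seed is None:
        seed = config.seed
    duration = config.session_duration
    ss = np.random.SeedSequence([int(seed), 0x5B1])
    rngs = {u.unit_id: np.random.default_rng(s)
            for u, s in zip(config.units, ss.spawn(len(config.units)))}
    rng_coup = np.random.default_rng(np.random.SeedSequence([int(seed), 0xC0]))
    rng_wave = np.random.default_rng(np.random.SeedSequence([int(seed), 0x3A]))

    trains: dict[int, np.ndarray] = {}
    truth = GroundTruth()
    for u in config.units:
        rng = rngs[u.unit_id]
        gains = dict(u.epoch_rate_gain)
        if gains:
            parts = [
                poisson_train(
                    u.mean_rate_hz * gains.get(row["label"], 1.0),
                    row["t_end_s"] - row["t_start_s"], rng, row["t_start_s"],
                )
                for _, row in epochs.iterrows()
            ]
            train = np.sort(np.concatenate(parts)) if parts else np.empty(0)
        else:
            train = poisson_train(u.mean_rate_hz, duration, rng)
        if u.light_response_prob > 0 and len(light_events):
            hit = rng.random(len(light_events)) < u.light_response_prob
            onsets = light_events["t_s"].to_numpy()[hit]
            widths = light_events["duration_s"].to_numpy()[hit]
            extra = onsets + rng.random(onsets.size) * widths
            train = np.unique(np.concatenate([train, extra]))
            truth.tagged_units.append(u.unit_id)
        trains[u.unit_id] = train

    for c in config.couplings:
        if c.pre not in trains or c.post not in trains:
            raise ValueError(f"coupling references unknown unit ({c.pre}->{c.post})")
        new_post, n_changed = apply_coupling(
            trains[c.pre], trains[c.post], c, duration, rng_coup
        )
        trains[c.post] = new_post
        truth.couplings.append(
            {**dataclasses.asdict(c), "n_pre_spikes": int(trains[c.pre].size),
             "n_changed": n_changed}
        )

    for h_i, h in enumerate(config.hotspots):
        truth.hotspots.append({**dataclasses.asdict(h), "index": h_i})
    for eff in config.sta_effects:
        truth.sta_effects.append(dataclasses.asdict(eff))

    channels = config.channel_table()
    units: list[SpikeUnit] = []
    for u in config.units:
        region_chans = [c for c in channels if c.region == u.region]
        if not region_chans:
            raise ValueError(f"no channels in region {u.region!r}")
        peak = region_chans[int(rng_wave.integers(len(region_chans)))]
        base = _template(u.template)
        wf = np.zeros((len(region_chans), WAVEFORM_SAMPLES))
        for row, c in enumerate(region_chans):
            dist = abs(c.site - peak.site) + 4 * abs(c.shank - peak.shank)
            atten = math.exp(-0.5 * (dist / 1.5) ** 2)
            noise = rng_wave.standard_normal(WAVEFORM_SAMPLES)
            noise = np.convolve(noise, np.ones(3) / 3, mode="same")
            wf[row] = base * atten + 2.0 * noise
        units.append(
            SpikeUnit(
                id=u.unit_id, region=u.region, spike_times=trains[u.unit_id],
                mean_waveform=wf, waveform_rate=WAVEFORM_RATE,
                waveform_channels=[c.id for c in region_chans],
                peak_channel=peak.id, is_cholinergic=u.is_cholinergic,
                session_duration=duration,
            )
        )
    return units, truth


# ---------------------------------------------------------------------------
# whole dataset
# ---------------------------------------------------------------------------


def generate_dataset(config: SynthConfig, out_dir: str | Path):
    """Generate and write a full session to ``out_dir``.

    Files: lfp.h5, spikes.csv, waveforms.h5, epochs.csv, light.csv,
    ground_truth.json, manifest.json.  Returns the loaded-equivalent
    in-memory objects ``(lfp, units, epochs, light, truth)``.
    """
    from . import io as _io  # deferred: io imports nothing from synth

    epochs = make_epoch_table(config)
    light = make_light_events(config)
    units, truth = generate_units(config, epochs, light)
    spikes = {u.id: u.spike_times for u in units}
    lfp = generate_lfp(config, epochs, unit_spikes=spikes)
    _io.save_session(Path(out_dir), lfp, units, epochs, light, truth)
    return lfp, units, epochs, light, truth
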