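"""Cholinergic spike-triggered spatial analysis of cortical gamma power.

For each (trigger unit, cortical channel, gamma band) the band power from
the continuous wavelet transform is averaged over the 500 ms before and
the 500 ms after every trigger spike, yielding two per-spike sample sets.
Their empirical cumulative distributions are compared with a two-sample
Kolmogorov-Smirnov test, the normalised difference score
(mean_after - mean_before)/(mean_after + mean_before) quantifies the
direction, and per-cell summaries report the percentage of a probe's
sites with a significant change.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import lfpproc
from .lfpproc import LFPRecording
from .unitproc import SpikeUnit


# ---------------------------------------------------------------------------
# band power
# ---------------------------------------------------------------------------


def band_power_timeseries(rec: LFPRecording, channel: int, band,
                          voices: int = lfpproc.DEFAULT_VOICES) -> np.ndarray:
    """Time series of normalised Morlet power averaged over a band."""
    _, edges = lfpproc.resolve_band(band)
    freqs = lfpproc.band_freq_grid(edges, voices)
    coef = lfpproc._cwt(rec.get(channel), freqs, rec.rate)
    scales = lfpproc._FC * rec.rate / freqs
    return (np.abs(coef) ** 2 / scales[:, None]).mean(axis=0)


# ---------------------------------------------------------------------------
# spike-triggered windows
# ---------------------------------------------------------------------------


@dataclass
class StaWindows:
    before: np.ndarray
    after: np.ndarray
    n_spikes_used: int
    status: str = "ok"


def _thin_spikes(times: np.ndarray, min_separation: float) -> np.ndarray:
    """Greedy selection keeping spikes at least ``min_separation`` apart."""
    if min_separation <= 0 or times.size == 0:
        return times
    kept = [times[0]]
    for t in times[1:]:
        if t - kept[-1] >= min_separation:
            kept.append(t)
    return np.asarray(kept)


def spike_triggered_power(
    spike_times: np.ndarray | SpikeUnit,
    power: np.ndarray,
    rate: float,
    half_window_s: float = 0.5,
    min_spikes: int = 50,
    min_separation_s: float | None = None,
) -> StaWindows:
    """Mean band power in the 500 ms before vs. after each trigger spike.

    ``power`` is a band-power time series at ``rate`` (see
    :func:`band_power_timeseries`).  Spikes closer than the half-window
    to the session edges are dropped.  By default spikes are greedily
    thinned to a minimum separation of twice the half-window so that
    windows from consecutive triggers never overlap (keeps the before and
    after sample sets mutually independent); pass 0 to disable.
    """
    times = (spike_times.spike_times if isinstance(spike_times, SpikeUnit)
             else np.asarray(spike_times, float))
    if min_separation_s is None:
        min_separation_s = 2.0 * half_window_s
    n = power.size
    nw = int(round(half_window_s * rate))
    duration = n / rate
    valid = times[(times >= half_window_s) & (times <= duration - half_window_s)]
    valid = _thin_spikes(valid, min_separation_s)
    if valid.size < min_spikes:
        return StaWindows(before=np.empty(0), after=np.empty(0),
                          n_spikes_used=int(valid.size),
                          status="insufficient spikes")
    csum = np.concatenate([[0.0], np.cumsum(power, dtype=float)])
    s = np.clip(np.round(valid * rate).astype(int), nw, n - nw - 1)
    before = (csum[s] - csum[s - nw]) / nw            # [-500 ms, 0)
    after = (csum[s + 1 + nw] - csum[s + 1]) / nw     # (0, +500 ms]
    return StaWindows(before=before, after=after, n_spikes_used=int(valid.size))


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------


@dataclass
class KSResult:
    d_statistic: float
    p_value: float
    significant: bool
    status: str = "ok"


def ks_before_after(before, after, alpha: float = 0.05) -> KSResult:
    """Two-sample Kolmogorov-Smirnov comparison of the power ECDFs."""
    b = np.asarray(before, float)
    a = np.asarray(after, float)
    if b.size < 10 or a.size < 10:
        return KSResult(float("nan"), float("nan"), False, "insufficient events")
    d, p = stats.ks_2samp(b, a)
    return KSResult(float(d), float(p), bool(p < alpha))


def sta_difference_score(before, after) -> float:
    """(mean_after - mean_before) / (mean_after + mean_before) in [-1, 1]."""
    b = np.asarray(before, float)
    a = np.asarray(after, float)
    if b.size == 0 or a.size == 0:
        raise ValueError("both sample sets must be non-empty")
    ma, mb = a.mean(), b.mean()
    denom = ma + mb
    if denom == 0:
        return float("nan")
    return float((ma - mb) / denom)


# ---------------------------------------------------------------------------
# scans and summaries
# ---------------------------------------------------------------------------


@dataclass
class STAResult:
    trigger_unit: int
    channel: int
    region: str
    band: str
    n_spikes: int
    d_statistic: float
    p_value: float
    significant: bool
    diff_score: float
    before_mean: float
    after_mean: float
    status: str = "ok"


def sta_scan(
    trigger: SpikeUnit,
    rec: LFPRecording,
    channels: list[int] | None = None,
    bands=("low_gamma", "high_gamma"),
    alpha: float = 0.05,
    half_window_s: float = 0.5,
    min_spikes: int = 50,
    min_separation_s: float | None = None,
) -> pd.DataFrame:
    """KS test + difference score per (channel, band) for one trigger unit."""
    if channels is None:
        channels = [c.id for c in rec.channels if c.region != "BF"]
    region_of = {c.id: c.region for c in rec.channels}
    rows = []
    for band in bands:
        label, _ = lfpproc.resolve_band(band)
        for ch in channels:
            power = band_power_timeseries(rec, ch, band)
            win = spike_triggered_power(
                trigger, power, rec.rate, half_window_s=half_window_s,
                min_spikes=min_spikes, min_separation_s=min_separation_s,
            )
            if win.status != "ok":
                rows.append(STAResult(trigger.id, ch, region_of[ch], label,
                                      win.n_spikes_used, float("nan"),
                                      float("nan"), False, float("nan"),
                                      float("nan"), float("nan"), win.status))
                continue
            ks = ks_before_after(win.before, win.after, alpha=alpha)
            rows.append(
                STAResult(
                    trigger_unit=trigger.id, channel=ch, region=region_of[ch],
                    band=label, n_spikes=win.n_spikes_used,
                    d_statistic=ks.d_statistic, p_value=ks.p_value,
                    significant=ks.significant,
                    diff_score=sta_difference_score(win.before, win.after),
                    before_mean=float(win.before.mean()),
                    after_mean=float(win.after.mean()), status=ks.status,
                )
            )
    return pd.DataFrame([r.__dict__ for r in rows])


def summarize_percent_significant(
    results: pd.DataFrame,
    expected_sites: int = 32,
) -> pd.DataFrame:
    """Per (trigger unit, region, band): percent of sites with a significant
    before/after gamma change — the per-cell summary table.

    Expects the long frame from :func:`sta_scan` (columns trigger_unit,
    region, band, channel, significant).  When a group has fewer sites
    than ``expected_sites`` the percent is computed over the available
    sites and flagged incomplete.
    """
    rows = []
    for (unit, region, band), g in results.groupby(
        ["trigger_unit", "region", "band"], sort=True
    ):
        n_sites = g["channel"].nunique()
        n_sig = int(g["significant"].sum())
        rows.append(
            dict(trigger_unit=unit, region=region, band=band,
                 n_sites=n_sites, n_significant=n_sig,
                 percent_significant=100.0 * n_sig / n_sites if n_sites else float("nan"),
                 complete=n_sites == expected_sites)
        )
    return pd.DataFrame(rows)
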