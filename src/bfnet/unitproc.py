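"""Spike-unit physiology.

Epoch firing-rate modulation (rank-sum vs. the center/rest baseline),
optogenetic tagging (light-evoked rate beyond 2 SD of the pre-stimulus
control), cross-correlogram detection of putative monosynaptic
connections (Poisson-tail threshold on a Gaussian-smoothed predictor),
waveform features (trough-to-peak latency, burst index, waveform PCA),
k-means cell classification and its bagged-decision-tree cross
validation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import CubicSpline
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.ensemble import BaggingClassifier
from sklearn.tree import DecisionTreeClassifier

#: Preliminary excitatory/inhibitory split: wide waveform or low rate.
TP_SPLIT_MS = 0.485
RATE_SPLIT_HZ = 6.0


class InsufficientStimuliError(ValueError):
    """Raised when fewer light stimuli than required are available."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class SpikeUnit:
    """A sorted unit: spike times (s), mean waveform at 20 kHz, metadata."""

    id: int
    region: str
    spike_times: np.ndarray
    mean_waveform: np.ndarray | None = None  # [channel x sample] or [sample]
    waveform_rate: float = 20_000.0
    waveform_channels: list[int] | None = None
    peak_channel: int | None = None
    is_cholinergic: bool = False
    session_duration: float | None = None

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        if self.spike_times.size > 1 and np.any(np.diff(self.spike_times) <= 0):
            raise ValueError("spike times must be strictly increasing")
        if self.mean_waveform is not None:
            self.mean_waveform = np.atleast_2d(np.asarray(self.mean_waveform, float))

    @property
    def n_spikes(self) -> int:
        return self.spike_times.size

    @property
    def mean_rate(self) -> float:
        if self.session_duration is None or self.session_duration <= 0:
            raise ValueError("session_duration unknown; cannot compute mean rate")
        return self.n_spikes / self.session_duration

    def peak_channel_waveform(self) -> np.ndarray:
        """Waveform on the site with maximum deviation from its own baseline."""
        if self.mean_waveform is None:
            raise ValueError("unit has no waveform")
        w = self.mean_waveform
        dev = np.abs(w - w.mean(axis=1, keepdims=True)).max(axis=1)
        return w[int(np.argmax(dev))]


@dataclass
class UnitFeatures:
    """Physiological feature vector for one unit."""

    unit_id: int
    tp_latency_ms: float
    burst_index: float
    w_pca1: float = np.nan
    w_pca2: float = np.nan
    mean_rate_hz: float = np.nan
    kmeans_label: int | None = None
    predicted_label: int | None = None
    is_cholinergic: bool = False


@dataclass
class OptotagResult:
    unit_id: int
    evoked_rate_hz: float
    control_mean_hz: float
    control_sd_hz: float
    responsive: bool
    direction: str  # "up", "down" or "none"
    n_events: int
    n_control: int
    psth_counts: np.ndarray = field(repr=False, default=None)  # type: ignore
    psth_edges: np.ndarray = field(repr=False, default=None)  # type: ignore


@dataclass
class ConnectionResult:
    pre_id: int
    post_id: int
    sign: str | None  # "excitatory", "inhibitory" or None
    detected: bool
    significant_bins: list[tuple[float, int, float]]  # (lag ms, count, threshold)
    lags_ms: np.ndarray = field(repr=False, default=None)  # type: ignore
    counts: np.ndarray = field(repr=False, default=None)  # type: ignore
    predictor: np.ndarray = field(repr=False, default=None)  # type: ignore


@dataclass
class ModulationResult:
    unit_id: int
    epoch: str
    p_value: float
    z_per_trial: np.ndarray
    z_timecourse: np.ndarray
    timecourse_bins: np.ndarray
    epoch_rates: np.ndarray
    baseline_rates: np.ndarray
    norm_epoch_mean: float
    norm_baseline_mean: float


# ---------------------------------------------------------------------------
# correlograms
# ---------------------------------------------------------------------------


def cross_correlogram(
    pre: np.ndarray,
    post: np.ndarray,
    bin_s: float = 5e-4,
    window_s: float = 0.05,
    same_unit: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of (post - pre) spike lags.  Returns (counts, bin edges).

    With ``same_unit`` the zero-lag self pairs are excluded (for
    autocorrelograms).
    """
    pre = np.asarray(pre, float)
    post = np.asarray(post, float)
    nbins = int(round(2 * window_s / bin_s))
    edges = -window_s + bin_s * np.arange(nbins + 1)
    diffs = []
    lo = np.searchsorted(post, pre - window_s)
    hi = np.searchsorted(post, pre + window_s)
    for t, a, b in zip(pre, lo, hi):
        diffs.append(post[a:b] - t)
    if diffs:
        d = np.concatenate(diffs)
    else:
        d = np.empty(0)
    if same_unit:
        d = d[d != 0.0]
    counts, _ = np.histogram(d, bins=edges)
    return counts, edges


def autocorrelogram(times: np.ndarray, bin_s: float = 1e-3,
                    window_s: float = 0.3) -> tuple[np.ndarray, np.ndarray]:
    """Positive-lag autocorrelogram with ``bin_s`` bins up to ``window_s``."""
    times = np.asarray(times, float)
    nbins = int(round(window_s / bin_s))
    edges = bin_s * np.arange(nbins + 1)
    hi = np.searchsorted(times, times + window_s)
    diffs = [times[i + 1 : h] - times[i] for i, h in enumerate(hi)]
    d = np.concatenate(diffs) if diffs else np.empty(0)
    counts, _ = np.histogram(d, bins=edges)
    return counts, edges


def burst_index(times: np.ndarray, bin_s: float = 1e-3) -> float:
    """Mean autocorrelogram count in 3-5 ms lags over the mean in 200-300 ms.

    Uses 1-ms bins; the numerator covers lags [3, 5) ms, the denominator
    [200, 300) ms.  NaN when the denominator is empty.
    """
    counts, edges = autocorrelogram(times, bin_s=bin_s, window_s=0.3)
    centers = edges[:-1] + bin_s / 2
    num = counts[(centers >= 3e-3) & (centers < 5e-3)]
    den = counts[(centers >= 0.2) & (centers < 0.3)]
    if den.size == 0 or den.mean() == 0:
        return float("nan")
    return float(num.mean() / den.mean())


# ---------------------------------------------------------------------------
# waveform features
# ---------------------------------------------------------------------------


def tp_latency_ms(waveform: np.ndarray, rate: float = 20_000.0) -> float:
    """Trough-to-peak latency: global trough to the subsequent maximum (ms)."""
    w = np.asarray(waveform, float)
    trough = int(np.argmin(w))
    if trough >= w.size - 1:
        raise ValueError("waveform has no samples after its trough")
    peak = trough + int(np.argmax(w[trough:]))
    if peak == trough:
        raise ValueError("no peak after the waveform trough")
    return (peak - trough) / rate * 1e3


def waveform_features(unit: SpikeUnit, acg_bin_s: float = 1e-3) -> tuple[float, float]:
    """(trough-to-peak latency ms, burst index) for one unit."""
    w = unit.peak_channel_waveform()
    tp = tp_latency_ms(w, unit.waveform_rate)
    bi = burst_index(unit.spike_times, bin_s=acg_bin_s)
    return tp, bi


def waveform_pca(
    units: list[SpikeUnit],
    window_ms: tuple[float, float] = (0.0, 0.8),
    upsample: int = 5,
) -> np.ndarray:
    """First two PCs of the second derivative of the up-sampled waveforms.

    Each unit's peak-channel mean waveform is cubic-upsampled by
    ``upsample``, differentiated twice (second finite difference), aligned
    at its global trough, and cropped to ``window_ms`` relative to the
    trough; the stacked matrix is mean-centred and projected on its first
    two principal axes.  Returns an (n_units, 2) score array.
    """
    if len(units) < 2:
        raise ValueError("waveform PCA needs at least 2 units")
    rows = []
    for u in units:
        w = u.peak_channel_waveform()
        rate = u.waveform_rate * upsample
        x = np.arange(w.size)
        xf = np.arange(0, w.size - 1 + 1e-9, 1.0 / upsample)
        wf = CubicSpline(x, w)(xf)
        d2 = np.diff(wf, n=2)
        trough = int(np.argmin(wf))
        i0 = trough + int(round(window_ms[0] * 1e-3 * rate))
        i1 = trough + int(round(window_ms[1] * 1e-3 * rate))
        if i1 > d2.size or i0 < 0:
            raise ValueError(
                f"PCA window {window_ms} ms exceeds the waveform span for unit {u.id}"
            )
        rows.append(d2[i0:i1])
    mat = np.asarray(rows)
    if np.allclose(mat.std(axis=0), 0.0):
        return np.zeros((len(units), 2))
    pca = PCA(n_components=2, svd_solver="full")
    return pca.fit_transform(mat)


def feature_table(units: list[SpikeUnit], window_ms=(0.0, 0.8), upsample=5) -> pd.DataFrame:
    """Assemble the per-unit feature table used by the classifiers."""
    scores = waveform_pca(units, window_ms=window_ms, upsample=upsample)
    rows = []
    for u, (p1, p2) in zip(units, scores):
        tp, bi = waveform_features(u)
        rows.append(
            dict(unit_id=u.id, region=u.region, tp_latency_ms=tp, burst_index=bi,
                 w_pca1=p1, w_pca2=p2, mean_rate_hz=u.mean_rate,
                 is_cholinergic=u.is_cholinergic)
        )
    return pd.DataFrame(rows)


def preliminary_split(tp_ms: np.ndarray, rate_hz: np.ndarray) -> np.ndarray:
    """Putative excitatory (True) vs inhibitory: TP > 0.485 ms or rate < 6 Hz."""
    return (np.asarray(tp_ms) > TP_SPLIT_MS) | (np.asarray(rate_hz) < RATE_SPLIT_HZ)


# ---------------------------------------------------------------------------
# epoch modulation
# ---------------------------------------------------------------------------


def _count_in(times: np.ndarray, t0: float, t1: float) -> int:
    return int(np.searchsorted(times, t1) - np.searchsorted(times, t0))


def epoch_rate_modulation(
    unit: SpikeUnit,
    epochs: pd.DataFrame,
    epoch_label: str,
    baseline_label: str = "center",
    min_trials: int = 5,
    psth_bin_s: float = 0.1,
) -> ModulationResult:
    """Firing-rate modulation of one unit in an epoch vs. the rest baseline.

    Per-trial rates in the epoch and in the same trial's baseline are
    compared with the two-sided Wilcoxon rank-sum (Mann-Whitney) test —
    exact for small tie-free samples, normal approximation with tie
    correction otherwise.  Per-trial Z uses the baseline mean/SD; rates
    are also min-max feature-scaled across the session.
    """
    trials = sorted(
        set(epochs.loc[epochs["label"] == epoch_label, "trial"])
        & set(epochs.loc[epochs["label"] == baseline_label, "trial"])
    )
    if len(trials) < min_trials:
        raise ValueError(
            f"need >= {min_trials} trials with both {epoch_label!r} and baseline"
        )
    ep = epochs.set_index(["trial", "label"])
    er, br = [], []
    for tr in trials:
        t0, t1 = ep.loc[(tr, epoch_label), ["t_start_s", "t_end_s"]]
        b0, b1 = ep.loc[(tr, baseline_label), ["t_start_s", "t_end_s"]]
        er.append(_count_in(unit.spike_times, t0, t1) / (t1 - t0))
        br.append(_count_in(unit.spike_times, b0, b1) / (b1 - b0))
    er, br = np.asarray(er), np.asarray(br)

    p = float(stats.mannwhitneyu(er, br, alternative="two-sided", method="auto").pvalue)
    bsd = br.std(ddof=1)
    z = (er - br.mean()) / bsd if bsd > 0 else np.full(er.size, np.nan)

    pooled = np.concatenate([er, br])
    span = pooled.max() - pooled.min()
    norm = (pooled - pooled.min()) / span if span > 0 else np.zeros_like(pooled)
    n_e = norm[: er.size].mean()
    n_b = norm[er.size :].mean()

    # trial-averaged time-resolved Z across the epoch
    dur = min(
        float(ep.loc[(tr, epoch_label), "t_end_s"] - ep.loc[(tr, epoch_label), "t_start_s"])
        for tr in trials
    )
    nb = max(int(dur / psth_bin_s), 1)
    psth = np.zeros(nb)
    for tr in trials:
        t0 = float(ep.loc[(tr, epoch_label), "t_start_s"])
        rel = unit.spike_times[
            (unit.spike_times >= t0) & (unit.spike_times < t0 + nb * psth_bin_s)
        ] - t0
        psth += np.histogram(rel, bins=nb, range=(0, nb * psth_bin_s))[0]
    psth_rate = psth / (len(trials) * psth_bin_s)
    zt = (psth_rate - br.mean()) / bsd if bsd > 0 else np.full(nb, np.nan)
    return ModulationResult(
        unit_id=unit.id, epoch=epoch_label, p_value=p, z_per_trial=z,
        z_timecourse=zt, timecourse_bins=psth_bin_s * (np.arange(nb) + 0.5),
        epoch_rates=er, baseline_rates=br,
        norm_epoch_mean=float(n_e), norm_baseline_mean=float(n_b),
    )


# ---------------------------------------------------------------------------
# optotagging
# ---------------------------------------------------------------------------


def optotag(
    unit: SpikeUnit,
    light_events: pd.DataFrame,
    pulse_width_s: float = 0.010,
    response_window_s: float | None = None,
    control_window_s: float = 2.0,
    min_stimuli: int = 100,
    sd_threshold: float = 2.0,
    psth_window_s: float = 0.05,
    psth_bin_s: float = 0.001,
) -> OptotagResult:
    """Tag a unit as light-responsive by the 2-SD rate criterion.

    The evoked rate is counted in the response window (default: the pulse
    width) after every pulse.  Control rates come from the
    ``control_window_s`` preceding events whose gap to the previous event
    is at least the control window — otherwise the control would overlap
    earlier pulses of the same train.  Responsive iff
    |evoked - control mean| > ``sd_threshold`` x control SD.
    """
    t = np.asarray(light_events["t_s"], float)
    if t.size < min_stimuli:
        raise InsufficientStimuliError(
            f"insufficient stimuli: {t.size} < {min_stimuli}"
        )
    win = response_window_s if response_window_s is not None else pulse_width_s
    spikes = unit.spike_times

    evoked_counts = np.searchsorted(spikes, t + win) - np.searchsorted(spikes, t)
    evoked_rate = evoked_counts.sum() / (t.size * win)

    gap = np.diff(t, prepend=-np.inf)
    ctrl_onsets = t[(gap >= control_window_s) & (t >= control_window_s)]
    ctrl_counts = np.searchsorted(spikes, ctrl_onsets) - np.searchsorted(
        spikes, ctrl_onsets - control_window_s
    )
    ctrl_rates = ctrl_counts / control_window_s
    c_mean = float(ctrl_rates.mean()) if ctrl_rates.size else float("nan")
    c_sd = float(ctrl_rates.std(ddof=1)) if ctrl_rates.size > 1 else float("nan")

    responsive = bool(abs(evoked_rate - c_mean) > sd_threshold * c_sd)
    if responsive:
        direction = "up" if evoked_rate > c_mean else "down"
    else:
        direction = "none"

    nb = int(round(2 * psth_window_s / psth_bin_s))
    edges = -psth_window_s + psth_bin_s * np.arange(nb + 1)
    rel = []
    for onset in t:
        a = np.searchsorted(spikes, onset - psth_window_s)
        b = np.searchsorted(spikes, onset + psth_window_s)
        rel.append(spikes[a:b] - onset)
    counts = np.histogram(np.concatenate(rel) if rel else np.empty(0), bins=edges)[0]

    return OptotagResult(
        unit_id=unit.id, evoked_rate_hz=float(evoked_rate),
        control_mean_hz=c_mean, control_sd_hz=c_sd,
        responsive=responsive, direction=direction,
        n_events=int(t.size), n_control=int(ctrl_rates.size),
        psth_counts=counts, psth_edges=edges,
    )


# ---------------------------------------------------------------------------
# cross-correlogram connection detection
# ---------------------------------------------------------------------------


def poisson_threshold(rate: np.ndarray | float, quantile: float = 0.9999) -> np.ndarray:
    """Smallest k with Poisson CDF(k; rate) >= quantile, per element."""
    return stats.poisson.ppf(quantile, np.asarray(rate, float))


def ccg_detect(
    pre: SpikeUnit | np.ndarray,
    post: SpikeUnit | np.ndarray,
    bin_s: float = 5e-4,
    window_s: float = 0.05,
    gaussian_sd_s: float = 0.010,
    quantile: float = 0.9999,
    hollow_fraction: float = 0.0,
    lag_window_ms: tuple[float, float] = (1.5, 5.0),
    min_spikes: int = 100,
    min_consecutive: int = 2,
    pre_id: int | None = None,
    post_id: int | None = None,
) -> ConnectionResult:
    """Detect a putative monosynaptic connection from the cross-correlogram.

    The CCG (0.5-ms bins, +-50 ms) convolved with a 10-ms-SD Gaussian is
    the baseline predictor; each bin's upper threshold is the 99.99th
    percentile of the Poisson distribution at the predicted rate (lower
    threshold at 1 - quantile).  An excitatory (inhibitory) connection
    requires at least ``min_consecutive`` consecutive bins above (below)
    threshold with lags inside [+1.5, +5] ms.  ``hollow_fraction``
    down-weights the kernel centre (0 = the plain Gaussian).
    """
    pre_t = pre.spike_times if isinstance(pre, SpikeUnit) else np.asarray(pre, float)
    post_t = post.spike_times if isinstance(post, SpikeUnit) else np.asarray(post, float)
    if pre_id is None:
        pre_id = pre.id if isinstance(pre, SpikeUnit) else -1
    if post_id is None:
        post_id = post.id if isinstance(post, SpikeUnit) else -1
    if pre_t.size < min_spikes or post_t.size < min_spikes:
        raise ValueError(f"both trains need >= {min_spikes} spikes")
    if pre_t.size and post_t.size:
        if min(pre_t[-1], post_t[-1]) <= max(pre_t[0], post_t[0]):
            raise ValueError("spike trains do not overlap in time")

    counts, edges = cross_correlogram(pre_t, post_t, bin_s=bin_s, window_s=window_s)
    centers_ms = (edges[:-1] + bin_s / 2) * 1e3

    half = int(np.ceil(4 * gaussian_sd_s / bin_s))
    k = np.exp(-0.5 * ((np.arange(-half, half + 1) * bin_s) / gaussian_sd_s) ** 2)
    k[half] *= 1.0 - hollow_fraction
    k /= k.sum()
    predictor = np.convolve(counts.astype(float), k, mode="same")
    # compensate truncation at the correlogram edges
    norm = np.convolve(np.ones_like(counts, float), k, mode="same")
    predictor = predictor / norm

    thr_hi = poisson_threshold(predictor, quantile)
    thr_lo = stats.poisson.ppf(1.0 - quantile, predictor)

    in_window = (centers_ms >= lag_window_ms[0] - 1e-9) & (
        centers_ms <= lag_window_ms[1] + 1e-9
    )
    above = (counts > thr_hi) & in_window
    below = (counts < thr_lo) & in_window

    def _runs(mask: np.ndarray) -> bool:
        run = 0
        for m in mask[in_window]:
            run = run + 1 if m else 0
            if run >= min_consecutive:
                return True
        return False

    exc = _runs(above)
    inh = _runs(below)
    sign = "excitatory" if exc else ("inhibitory" if inh else None)
    sig_mask = above | below
    sig_bins = [
        (float(centers_ms[i]), int(counts[i]),
         float(thr_hi[i] if above[i] else thr_lo[i]))
        for i in np.flatnonzero(sig_mask)
    ]
    return ConnectionResult(
        pre_id=pre_id, post_id=post_id, sign=sign, detected=bool(exc or inh),
        significant_bins=sig_bins, lags_ms=centers_ms, counts=counts,
        predictor=predictor,
    )


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------


def _zscore_columns(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (x - mu) / sd


def classify_units(
    features: np.ndarray | pd.DataFrame,
    k: int = 6,
    seed: int = 0,
    n_init: int = 10,
) -> tuple[np.ndarray, float]:
    """K-means (z-scored TP latency, w-PCA1, w-PCA2); labels 1..k + inertia."""
    if isinstance(features, pd.DataFrame):
        features = features[["tp_latency_ms", "w_pca1", "w_pca2"]].to_numpy()
    x = np.asarray(features, float)
    if x.ndim != 2:
        raise ValueError("features must be 2-D [units x features]")
    if not np.isfinite(x).all():
        raise ValueError("features must be complete (finite) for clustering")
    if k > x.shape[0]:
        raise ValueError(f"k={k} exceeds the number of units ({x.shape[0]})")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    labels = km.fit_predict(_zscore_columns(x))
    return labels + 1, float(km.inertia_)


def crossvalidate_bagged_tree(
    features: np.ndarray | pd.DataFrame,
    labels: np.ndarray,
    cholinergic_mask: np.ndarray,
    seed: int = 0,
    n_estimators: int = 100,
) -> tuple[float, np.ndarray]:
    """Bagged decision trees on (TP, w-PCA1, w-PCA2, mean rate).

    Trained on non-cholinergic units only; returns the out-of-bag
    accuracy and predicted cluster labels for the held-out cholinergic
    units (empty array if there are none).
    """
    if isinstance(features, pd.DataFrame):
        features = features[
            ["tp_latency_ms", "w_pca1", "w_pca2", "mean_rate_hz"]
        ].to_numpy()
    x = np.asarray(features, float)
    y = np.asarray(labels)
    chol = np.asarray(cholinergic_mask, bool)
    xt, yt = x[~chol], y[~chol]
    classes, counts = np.unique(yt, return_counts=True)
    if classes.size < 2:
        raise ValueError("need at least 2 classes in the training labels")
    if (counts < 2).any():
        warnings.warn("a training class has a single member", stacklevel=2)
    model = BaggingClassifier(
        estimator=DecisionTreeClassifier(random_state=seed),
        n_estimators=n_estimators, oob_score=True, random_state=seed,
    )
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="Some inputs do not have OOB")
        model.fit(xt, yt)
        oob = float(model.oob_score_)
    pred = model.predict(x[chol]) if chol.any() else np.empty(0, dtype=y.dtype)
    return oob, pred
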