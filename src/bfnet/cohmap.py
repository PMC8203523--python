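"""Behaviour-epoch coherence statistics.

The coherence change score between a behavioural epoch and the
center/rest baseline,

    score = (mean(CWC_behavior) - mean(CWC_rest))
            / (mean(CWC_behavior) + mean(CWC_rest)),

its Monte-Carlo permutation significance, full contact-pair change maps
(e.g. 32 x 32 = 1024 voxels for a cortico-cortical region pair), and
epoch-level one-way ANOVA with Tukey HSD comparisons of baseline-relative
coherence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from . import lfpproc
from .lfpproc import LFPRecording


# ---------------------------------------------------------------------------
# change score
# ---------------------------------------------------------------------------


def coherence_change_score(behavior, resting) -> float:
    """Normalised difference of mean coherence, bounded in [-1, 1].

    NaN when both means are zero (the voxel is reported missing by map
    builders rather than propagating NaN into statistics).
    """
    b = np.asarray(behavior, float)
    r = np.asarray(resting, float)
    if b.size == 0 or r.size == 0:
        raise ValueError("both sample lists must be non-empty")
    for name, v in (("behavior", b), ("resting", r)):
        if np.any((v < 0) | (v > 1)):
            raise ValueError(f"{name} coherence values must lie in [0, 1]")
    mb, mr = b.mean(), r.mean()
    denom = mb + mr
    if denom == 0:
        return float("nan")
    return float((mb - mr) / denom)


# ---------------------------------------------------------------------------
# permutation significance
# ---------------------------------------------------------------------------


@dataclass
class PermutationTest:
    score: float
    observed_diff: float
    p_value: float
    significant: bool
    alpha: float
    n_perm: int
    alternative: str


def _resolve_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _perm_pvalues(
    samples: np.ndarray,
    n_behavior: int,
    n_perm: int,
    rng: np.random.Generator,
    alternative: str = "two-sided",
    method: str = "permutation",
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised permutation p-values for rows of pooled samples.

    ``samples`` is (n_rows, n_total) with the first ``n_behavior`` columns
    the behaviour group.  One shared set of label permutations (or, with
    ``method='bootstrap'``, with-replacement resamples) is applied to all
    rows.  Returns (p_values, observed difference of means).
    """
    samples = np.asarray(samples, float)
    n_total = samples.shape[1]
    nb, nr = n_behavior, n_total - n_behavior
    obs = samples[:, :nb].mean(axis=1) - samples[:, nb:].mean(axis=1)

    if method == "permutation":
        idx = np.argsort(rng.random((n_perm, n_total)), axis=1)
    elif method == "bootstrap":
        idx = rng.integers(0, n_total, size=(n_perm, n_total))
    else:
        raise ValueError(f"unknown resampling method {method!r}")
    w = np.zeros((n_perm, n_total))
    rows = np.arange(n_perm)
    if method == "permutation":
        w[rows[:, None], idx[:, :nb]] = 1.0 / nb
        w[rows[:, None], idx[:, nb:]] = -1.0 / nr
    else:
        # bootstrap draws may repeat columns; accumulate weights
        for j in range(nb):
            np.add.at(w, (rows, idx[:, j]), 1.0 / nb)
        for j in range(nb, n_total):
            np.add.at(w, (rows, idx[:, j]), -1.0 / nr)
    null = samples @ w.T  # (n_rows, n_perm)

    eps = 1e-12
    if alternative == "two-sided":
        ge = (np.abs(null) >= np.abs(obs)[:, None] - eps).sum(axis=1)
    elif alternative == "greater":
        ge = (null >= obs[:, None] - eps).sum(axis=1)
    elif alternative == "less":
        ge = (null <= obs[:, None] + eps).sum(axis=1)
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    p = (1.0 + ge) / (n_perm + 1.0)
    return p, obs


def permutation_significance(
    behavior,
    resting,
    alpha: float,
    n_perm: int = 3000,
    seed=None,
    alternative: str = "two-sided",
    method: str = "permutation",
) -> PermutationTest:
    """Monte-Carlo permutation test of the difference of mean coherence.

    Both groups are pooled ("merged distribution"); each resample draws
    label-permuted groups of the original sizes and recomputes the
    difference of means; the observed difference is referred to that null
    distribution.  ``method='bootstrap'`` resamples with replacement
    instead.  ``alpha`` is required — the per-analysis level is a
    deliberate, explicit choice.
    """
    b = np.asarray(behavior, float)
    r = np.asarray(resting, float)
    if b.size < 2 or r.size < 2:
        raise ValueError("both groups need at least 2 observations")
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is very small", stacklevel=2)
    pooled = np.concatenate([b, r])
    score = coherence_change_score(np.clip(b, 0, 1), np.clip(r, 0, 1)) if (
        (b >= 0).all() and (b <= 1).all() and (r >= 0).all() and (r <= 1).all()
    ) else float("nan")
    if np.ptp(pooled) == 0:
        return PermutationTest(score=score, observed_diff=0.0, p_value=1.0,
                               significant=False, alpha=alpha, n_perm=n_perm,
                               alternative=alternative)
    rng = _resolve_rng(seed)
    p, obs = _perm_pvalues(pooled[None, :], b.size, n_perm, rng,
                           alternative=alternative, method=method)
    return PermutationTest(
        score=score, observed_diff=float(obs[0]), p_value=float(p[0]),
        significant=bool(p[0] <= alpha), alpha=alpha, n_perm=n_perm,
        alternative=alternative,
    )


# ---------------------------------------------------------------------------
# change maps
# ---------------------------------------------------------------------------


@dataclass
class CoherenceChangeMap:
    """Pairwise change scores with a per-voxel significance mask."""

    scores: np.ndarray
    p_values: np.ndarray
    mask: np.ndarray
    missing: np.ndarray
    channels_a: list[int]
    channels_b: list[int]
    region_a: str
    region_b: str
    band_label: str
    epoch: str
    alpha: float
    n_trials: int
    status: str = "ok"

    @property
    def n_voxels(self) -> int:
        return self.scores.size

    def to_long_frame(self) -> pd.DataFrame:
        rows = []
        for i, ca in enumerate(self.channels_a):
            for j, cb in enumerate(self.channels_b):
                rows.append(
                    dict(channel_a=ca, channel_b=cb, score=self.scores[i, j],
                         p_value=self.p_values[i, j],
                         significant=bool(self.mask[i, j]),
                         missing=bool(self.missing[i, j]))
                )
        df = pd.DataFrame(rows)
        df["region_a"] = self.region_a
        df["region_b"] = self.region_b
        df["band"] = self.band_label
        df["epoch"] = self.epoch
        return df


def trial_coherence_samples(
    rec: LFPRecording,
    epochs: pd.DataFrame,
    region_a: str,
    region_b: str,
    band,
    epoch: str,
    baseline: str = "center",
) -> tuple[np.ndarray, np.ndarray, list[int], list[int]]:
    """Per-trial band/interval-averaged CWC for every cross-region pair.

    Returns (behaviour values, baseline values) each shaped
    (n_a, n_b, n_trials), plus the two channel-id lists.  Only trials
    containing both the epoch and the baseline contribute.

    Within each trial both intervals are truncated to their common
    minimum duration: the coherence estimator's bias floor scales
    inversely with the averaging window, so unmatched windows would bias
    the change score away from zero even without any true coupling.
    With matched windows the two groups are exchangeable under the null.
    """
    chans_a = [c.id for c in rec.region_channels(region_a)]
    chans_b = [c.id for c in rec.region_channels(region_b)]
    if not chans_a or not chans_b:
        raise ValueError(f"regions {region_a!r}/{region_b!r} not both present")
    trials = sorted(
        set(epochs.loc[epochs["label"] == epoch, "trial"])
        & set(epochs.loc[epochs["label"] == baseline, "trial"])
    )
    ep = epochs.set_index(["trial", "label"])
    iv_e, iv_b = [], []
    for t in trials:
        e0, e1 = ep.loc[(t, epoch), ["t_start_s", "t_end_s"]]
        b0, b1 = ep.loc[(t, baseline), ["t_start_s", "t_end_s"]]
        dur = min(e1 - e0, b1 - b0)
        iv_e.append((float(e0), float(e0 + dur)))
        iv_b.append((float(b0), float(b0 + dur)))
    if not trials:
        return (np.empty((len(chans_a), len(chans_b), 0)),) * 2 + (chans_a, chans_b)
    vals_e = lfpproc.pairwise_band_coherence(rec, chans_a, chans_b, band, iv_e)
    vals_b = lfpproc.pairwise_band_coherence(rec, chans_a, chans_b, band, iv_b)
    return vals_e, vals_b, chans_a, chans_b


def build_change_map(
    rec: LFPRecording,
    epochs: pd.DataFrame,
    region_a: str,
    region_b: str,
    band,
    epoch: str,
    alpha: float,
    n_perm: int = 1000,
    seed=None,
    baseline: str = "center",
    alternative: str = "two-sided",
) -> CoherenceChangeMap:
    """Coherence change score + permutation significance for every voxel.

    For a pair of 32-site cortical probes this is the 1024-voxel map; the
    mask marks voxels whose permutation p-value is at most ``alpha``
    (two-sided by default, so both increases and decreases are flagged).
    """
    band_label, _ = lfpproc.resolve_band(band)
    vals_e, vals_b, chans_a, chans_b = trial_coherence_samples(
        rec, epochs, region_a, region_b, band, epoch, baseline
    )
    na, nb_ch, n_trials = vals_e.shape
    shape = (na, nb_ch)
    if n_trials == 0:
        z = np.zeros(shape)
        return CoherenceChangeMap(
            scores=np.full(shape, np.nan), p_values=np.full(shape, np.nan),
            mask=np.zeros(shape, bool), missing=np.ones(shape, bool),
            channels_a=chans_a, channels_b=chans_b, region_a=region_a,
            region_b=region_b, band_label=band_label, epoch=epoch,
            alpha=alpha, n_trials=0, status="no trials with both epochs",
        )
    me = vals_e.mean(axis=2)
    mb = vals_b.mean(axis=2)
    denom = me + mb
    missing = denom == 0
    scores = np.full(shape, np.nan)
    np.divide(me - mb, denom, out=scores, where=~missing)

    samples = np.concatenate([vals_e, vals_b], axis=2).reshape(-1, 2 * n_trials)
    rng = _resolve_rng(seed)
    p, _ = _perm_pvalues(samples, n_trials, n_perm, rng, alternative=alternative)
    p_values = p.reshape(shape)
    mask = (p_values <= alpha) & ~missing
    return CoherenceChangeMap(
        scores=scores, p_values=p_values, mask=mask, missing=missing,
        channels_a=chans_a, channels_b=chans_b, region_a=region_a,
        region_b=region_b, band_label=band_label, epoch=epoch, alpha=alpha,
        n_trials=n_trials,
    )


# ---------------------------------------------------------------------------
# relative coherence and epoch-level ANOVA / Tukey
# ---------------------------------------------------------------------------


def relative_coherence_table(
    rec: LFPRecording,
    epochs: pd.DataFrame,
    region_a: str,
    region_b: str,
    band,
    conditions: list[str],
    baseline: str = "center",
) -> pd.DataFrame:
    """Per-trial coherence as a proportion of the same trial's baseline.

    The coherence is averaged across all cross-region channel pairings
    before forming the ratio.  Columns: condition, trial, relative.
    """
    rows = []
    for cond in conditions:
        vals_e, vals_b, _, _ = trial_coherence_samples(
            rec, epochs, region_a, region_b, band, cond, baseline
        )
        trials = sorted(
            set(epochs.loc[epochs["label"] == cond, "trial"])
            & set(epochs.loc[epochs["label"] == baseline, "trial"])
        )
        for k, tr in enumerate(trials):
            base = vals_b[:, :, k].mean()
            if base > 0:
                rows.append(dict(condition=cond, trial=tr,
                                 relative=vals_e[:, :, k].mean() / base))
    return pd.DataFrame(rows, columns=["condition", "trial", "relative"])


@dataclass
class EpochComparison:
    f_statistic: float
    p_value: float
    p_value_bonferroni: float
    tukey: pd.DataFrame
    dropped: list[str] = field(default_factory=list)


def compare_epoch_coherence(
    groups: dict[str, np.ndarray] | pd.DataFrame,
    alpha: float = 0.05,
    n_families: int = 1,
) -> EpochComparison:
    """One-way ANOVA over conditions followed by Tukey HSD pairwise tests.

    ``groups`` maps condition label to relative-coherence observations
    (or a DataFrame with 'condition'/'relative' columns).  Conditions
    with fewer than 2 observations are dropped with a warning.  The
    family-level alpha is additionally Bonferroni-divided by
    ``n_families`` (the number of band x region-pair analyses run).
    """
    if isinstance(groups, pd.DataFrame):
        groups = {
            str(c): g["relative"].to_numpy()
            for c, g in groups.groupby("condition")
        }
    dropped = [k for k, v in groups.items() if np.asarray(v).size < 2]
    if dropped:
        warnings.warn(f"dropping conditions with < 2 observations: {dropped}",
                      stacklevel=2)
    kept = {k: np.asarray(v, float) for k, v in groups.items() if k not in dropped}
    if len(kept) < 2:
        raise ValueError("need at least 2 conditions with >= 2 observations")

    f_stat, p = stats.f_oneway(*kept.values())
    adj_alpha = alpha / max(n_families, 1)
    values = np.concatenate(list(kept.values()))
    labels = np.concatenate([[k] * v.size for k, v in kept.items()])
    res = pairwise_tukeyhsd(values, labels, alpha=adj_alpha)
    tukey = pd.DataFrame(
        res.summary().data[1:], columns=res.summary().data[0]
    )
    return EpochComparison(
        f_statistic=float(f_stat), p_value=float(p),
        p_value_bonferroni=float(min(p * max(n_families, 1), 1.0)),
        tukey=tukey, dropped=dropped,
    )


# ---------------------------------------------------------------------------
# calibration utility
# ---------------------------------------------------------------------------


def permutation_type_i_error(
    alphas=(0.05, 0.01),
    n_reps: int = 500,
    n_perm: int = 1000,
    group_size: int = 20,
    seed=None,
    alternative: str = "two-sided",
) -> dict[float, float]:
    """Empirical null rejection rate of the permutation test.

    Draws ``n_reps`` pairs of same-distribution groups (standard normal)
    and reports, for each alpha, the fraction rejected — the type-I error
    the permutation machinery actually delivers.
    """
    rng = _resolve_rng(seed)
    data = rng.standard_normal((n_reps, 2 * group_size))
    p, _ = _perm_pvalues(data, group_size, n_perm, rng, alternative=alternative)
    return {float(a): float((p <= a).mean()) for a in alphas}
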