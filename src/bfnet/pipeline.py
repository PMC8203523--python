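"""End-to-end analysis pipeline over one session.

Runs, in order: unit features and k-means classification with bagged-tree
cross-validation, optotagging, pairwise CCG connection detection,
relative-coherence ANOVA, coherence change maps, and the spike-triggered
gamma scan for cholinergic-tagged units.  All stages are deterministic
given the configured seeds; every stage writes CSV (plus PNG heatmaps
for maps) into the results directory together with a machine-readable
run report and a log of the parameters actually used.
"""

from __future__ import annotations

import itertools
import json
import logging
import traceback
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cohmap, stamod, unitproc
from .io import Session, load_session
from .lfpproc import DEFAULT_BANDS

log = logging.getLogger("bfnet")


@dataclass
class PipelineConfig:
    """Validated knobs of the end-to-end run."""

    bands: list[str] = field(default_factory=lambda: list(DEFAULT_BANDS))
    map_alpha: float = 0.01
    sta_alpha: float = 0.05
    n_perm: int = 1000
    seed: int = 0
    epochs_of_interest: list[str] = field(default_factory=lambda: ["decision"])
    map_region_pairs: list[tuple[str, str]] = field(
        default_factory=lambda: [("OFC", "V2")]
    )
    baseline_label: str = "center"
    run_maps: bool = True
    run_units: bool = True
    run_sta: bool = True
    run_anova: bool = True
    min_trials: int = 5

    def validate(self) -> None:
        for b in self.bands:
            if b not in DEFAULT_BANDS:
                raise ValueError(f"unknown band label {b!r}")
        for a in (self.map_alpha, self.sta_alpha):
            if not 0 < a < 1:
                raise ValueError("alpha values must lie in (0, 1)")
        if self.n_perm < 100:
            raise ValueError("n_perm must be >= 100")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**raw)
        cfg.validate()
        return cfg


def _save_heatmap(map_obj: cohmap.CoherenceChangeMap, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(9, 4))
    im = axes[0].imshow(map_obj.scores, cmap="RdBu_r", vmin=-1, vmax=1)
    axes[0].set_title(f"change score {map_obj.epoch} {map_obj.band_label}")
    fig.colorbar(im, ax=axes[0])
    shown = np.where(map_obj.mask, map_obj.scores, np.nan)
    im2 = axes[1].imshow(shown, cmap="RdBu_r", vmin=-1, vmax=1)
    axes[1].set_title(f"significant (alpha={map_obj.alpha})")
    fig.colorbar(im2, ax=axes[1])
    for ax in axes:
        ax.set_xlabel(map_obj.region_b)
        ax.set_ylabel(map_obj.region_a)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def run_pipeline(session: Session | str | Path, config: PipelineConfig,
                 out_dir: str | Path) -> dict:
    """Run all configured stages; returns the run report dictionary.

    On a stage failure the partial results are preserved, the stage is
    named in the log and report, and a RuntimeError is raised.
    """
    config.validate()
    if not isinstance(session, Session):
        session = load_session(session)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    log.info("parameters: %s", json.dumps(config.__dict__, default=str))

    report: dict = {"session_id": session.session_id, "stages": {},
                    "parameters": {k: (list(v) if isinstance(v, tuple) else v)
                                   for k, v in config.__dict__.items()}}
    failed = None
    try:
        if config.run_units and session.units:
            _stage_units(session, config, out, report)
        if config.run_anova:
            _stage_anova(session, config, out, report)
        if config.run_maps:
            _stage_maps(session, config, out, report)
        if config.run_sta and session.units:
            _stage_sta(session, config, out, report)
    except Exception as exc:  # noqa: BLE001 - stage name must reach the report
        failed = report.get("current_stage", "unknown")
        log.error("stage %s failed: %s", failed, exc)
        report["failed_stage"] = failed
        report["error"] = "".join(traceback.format_exception_only(exc)).strip()
    finally:
        (out / "run_report.json").write_text(json.dumps(report, indent=2, default=str))
        log.removeHandler(handler)
        handler.close()
    if failed is not None:
        raise RuntimeError(f"pipeline stage {failed!r} failed; see run.log")
    return report


def _stage_units(session: Session, config: PipelineConfig, out: Path,
                 report: dict) -> None:
    report["current_stage"] = "units"
    units = session.units
    feats = unitproc.feature_table(units)
    if len(feats) >= 6 and feats[["tp_latency_ms", "w_pca1", "w_pca2"]].notna().all().all():
        labels, inertia = unitproc.classify_units(feats, k=min(6, len(feats)),
                                                  seed=config.seed)
        feats["kmeans_label"] = labels
        chol = feats["is_cholinergic"].to_numpy()
        n_classes = len(set(labels[~chol]))
        # OOB scoring needs enough non-cholinergic units to be meaningful
        if chol.any() and (~chol).sum() >= 10 and n_classes >= 2:
            oob, pred = unitproc.crossvalidate_bagged_tree(
                feats, labels, chol, seed=config.seed
            )
            feats.loc[chol, "predicted_label"] = pred
            report["stages"]["units"] = {"oob_accuracy": oob,
                                         "kmeans_inertia": inertia}
    feats.to_csv(out / "unit_features.csv", index=False)

    if len(session.light):
        rows = []
        for u in units:
            try:
                r = unitproc.optotag(u, session.light)
            except unitproc.InsufficientStimuliError:
                continue
            rows.append(dict(unit_id=r.unit_id, evoked_rate_hz=r.evoked_rate_hz,
                             control_mean_hz=r.control_mean_hz,
                             control_sd_hz=r.control_sd_hz,
                             responsive=r.responsive, direction=r.direction))
        pd.DataFrame(rows).to_csv(out / "optotags.csv", index=False)

    rows = []
    for a, b in itertools.permutations(units, 2):
        if a.n_spikes < 100 or b.n_spikes < 100:
            continue
        r = unitproc.ccg_detect(a, b)
        if r.detected:
            rows.append(dict(pre_id=r.pre_id, post_id=r.post_id, sign=r.sign,
                             n_significant_bins=len(r.significant_bins)))
    pd.DataFrame(rows, columns=["pre_id", "post_id", "sign",
                                "n_significant_bins"]).to_csv(
        out / "connections.csv", index=False
    )
    report["stages"].setdefault("units", {})["n_connections"] = len(rows)


def _stage_anova(session: Session, config: PipelineConfig, out: Path,
                 report: dict) -> None:
    report["current_stage"] = "anova"
    frames = []
    results = {}
    conditions = [
        lbl for lbl in session.epochs["label"].unique()
        if lbl != config.baseline_label
    ]
    pairs = config.map_region_pairs
    n_families = max(len(pairs) * len(config.bands), 1)
    for (ra, rb) in pairs:
        for band in config.bands:
            tbl = cohmap.relative_coherence_table(
                session.lfp, session.epochs, ra, rb, band, conditions,
                baseline=config.baseline_label,
            )
            tbl["region_pair"] = f"{ra}x{rb}"
            tbl["band"] = band
            frames.append(tbl)
            counts = tbl.groupby("condition").size()
            if (counts >= 2).sum() >= 2:
                cmp_res = cohmap.compare_epoch_coherence(
                    tbl, alpha=0.05, n_families=n_families
                )
                results[f"{ra}x{rb}/{band}"] = {
                    "F": cmp_res.f_statistic, "p": cmp_res.p_value,
                    "p_bonferroni": cmp_res.p_value_bonferroni,
                }
    if frames:
        pd.concat(frames).to_csv(out / "relative_coherence.csv", index=False)
    report["stages"]["anova"] = results


def _stage_maps(session: Session, config: PipelineConfig, out: Path,
                report: dict) -> None:
    report["current_stage"] = "maps"
    info = {}
    for (ra, rb) in config.map_region_pairs:
        for band in config.bands:
            for epoch in config.epochs_of_interest:
                m = cohmap.build_change_map(
                    session.lfp, session.epochs, ra, rb, band, epoch,
                    alpha=config.map_alpha, n_perm=config.n_perm,
                    seed=config.seed, baseline=config.baseline_label,
                )
                stem = f"map_{ra}x{rb}_{band}_{epoch}"
                m.to_long_frame().to_csv(out / f"{stem}.csv", index=False)
                _save_heatmap(m, out / f"{stem}.png")
                info[stem] = {"status": m.status, "n_trials": m.n_trials,
                              "n_significant": int(m.mask.sum()),
                              "n_voxels": int(m.n_voxels)}
    report["stages"]["maps"] = info


def _stage_sta(session: Session, config: PipelineConfig, out: Path,
               report: dict) -> None:
    report["current_stage"] = "sta"
    triggers = [u for u in session.units if u.is_cholinergic]
    frames = []
    for u in triggers:
        frames.append(stamod.sta_scan(u, session.lfp, bands=config.bands,
                                      alpha=config.sta_alpha))
    if frames:
        res = pd.concat(frames)
        res.to_csv(out / "sta_results.csv", index=False)
        summary = stamod.summarize_percent_significant(res)
        summary.to_csv(out / "sta_summary.csv", index=False)
        report["stages"]["sta"] = {"n_triggers": len(triggers),
                                   "n_tests": len(res)}
    else:
        report["stages"]["sta"] = {"n_triggers": 0}
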