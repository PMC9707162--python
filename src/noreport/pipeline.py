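"""End-to-end orchestration: simulate -> calibrate -> classify -> erp -> fmri.

A single YAML-serializable RunConfig drives all stages; every stochastic
stage derives its generator from the top-level seed via named substreams
(stable under stage toggling).  Each run writes its artifacts plus a
manifest listing every file with a SHA-256 content hash, so identical
configs reproduce identical manifests.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import classify as clf
from . import clusterstat as cs
from . import erp as erp_mod
from . import eyeproc, fmri, io, paradigm
from ._rng import spawn_seed
from .synth import (
    EyeDynamicsParams,
    ObserverModel,
    apply_overt_reports,
    default_bold_templates,
    default_erp_templates,
    generate_eeg_epochs,
    generate_eye_session,
    generate_fmri_session,
    generate_isi_segments,
    generate_observer_responses,
)

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "StageError", "ConfigError"]


class ConfigError(ValueError):
    pass


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    seed: int = 0
    observer_threshold: float = 0.10
    observer_slope: float = 40.0
    n_testing_runs: int = 2
    relevant_set: str = "quadrant"
    n_eeg_participants: int = 8
    n_eeg_trials_per_cell: int = 20
    n_fmri_participants: int = 12
    n_fmri_events: int = 20
    n_perm: int = 300
    alpha: float = 0.05
    stages: dict = field(
        default_factory=lambda: {
            "simulate": True,
            "calibrate": True,
            "classify": True,
            "erp": True,
            "fmri": True,
        }
    )
    overwrite: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = io.read_config_yaml(path) or {}
        unknown = set(raw) - set(cls().__dict__)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Run the enabled stages, returning the manifest dict.

    The manifest records the config, its hash, the seed, and every artifact
    with a content hash; it is written to ``manifest.json`` in ``out_dir``.
    Existing artifacts are never overwritten unless ``config.overwrite``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_dict = asdict(config)
    cfg_hash = hashlib.sha256(
        json.dumps(cfg_dict, sort_keys=True).encode()
    ).hexdigest()
    manifest: dict = {
        "config": cfg_dict,
        "config_hash": cfg_hash,
        "seed": config.seed,
        "artifacts": {},
    }
    state: dict = {}

    def _register(path: Path) -> None:
        manifest["artifacts"][str(path.relative_to(out))] = _sha256(path)

    def _target(name: str) -> Path:
        p = out / name
        if p.exists() and not config.overwrite:
            raise FileExistsError(f"{p} exists; pass overwrite to replace it")
        return p

    stage_order = ["simulate", "calibrate", "classify", "erp", "fmri"]
    try:
        for stage in stage_order:
            if not config.stages.get(stage, False):
                continue
            log.info("running stage %s (config %s, seed %d)", stage, cfg_hash[:8], config.seed)
            globals()[f"_stage_{stage}"](config, out, state, _register, _target)
    except FileExistsError:
        raise
    except Exception as exc:  # record which stage died, keep partial manifest
        manifest["failed_stage"] = getattr(exc, "stage", stage)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise StageError(stage, exc) from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    manifest["artifacts"]["manifest.json"] = "-"
    return manifest


def _stage_simulate(config, out, state, register, target):
    p = target("run_config.yaml")
    io.write_config_yaml(asdict(config), p)
    register(p)

    pcfg = paradigm.ParadigmConfig()
    observer = ObserverModel(config.observer_threshold, config.observer_slope)
    seed = config.seed

    cal = paradigm.build_calibration_schedule(pcfg, seed=spawn_seed(seed, "cal"))
    cal_resp = generate_observer_responses(cal, observer, seed=spawn_seed(seed, "cal_resp"))
    state["calibration"] = cal_resp
    for e, s in cal_resp:
        e.response_seen = bool(s)
    p = target("calibration_events.tsv")
    io.write_events_tsv(cal, p)
    register(p)

    fits = {}
    for ls in paradigm.LOCATION_SETS:
        fits[ls] = paradigm.fit_psychometric(
            [(e.opacity, s) for e, s in cal_resp if e.location_set == ls], pcfg
        )
    state["fits"] = fits

    trials = paradigm.build_testing_schedule(
        pcfg, fits, config.relevant_set, config.n_testing_runs,
        seed=spawn_seed(seed, "testing"),
    )
    events = paradigm.events_of(trials)
    labeled = generate_observer_responses(
        events, observer, seed=spawn_seed(seed, "test_resp")
    )
    apply_overt_reports(labeled, seed=spawn_seed(seed, "reports"))
    state["trials"] = trials
    state["labeled_events"] = labeled
    p = target("testing_events.tsv")
    io.write_events_tsv(events, p)
    register(p)

    rec = generate_eye_session(
        events, [s for _, s in labeled], EyeDynamicsParams(),
        seed=spawn_seed(seed, "eye"),
    )
    state["eye_recording"] = rec
    p = target("eye_samples.tsv")
    io.write_eye_tsv(rec, p)
    register(p)


def _stage_calibrate(config, out, state, register, target):
    fits = state["fits"]
    summary = {
        ls: {
            "threshold_opacity": f.threshold_opacity,
            "slope": f.slope,
            "converged": f.converged,
        }
        for ls, f in fits.items()
    }
    summary["behavior"] = paradigm.score_behavior(state.get("trials", []))
    p = target("calibration_fit.json")
    p.write_text(json.dumps(summary, indent=2))
    register(p)


def _stage_classify(config, out, state, register, target):
    rec = state["eye_recording"]
    labeled = state["labeled_events"]
    blinks, _ = eyeproc.detect_blinks(rec)
    interp = eyeproc.interpolate_artifacts(rec, blinks)
    msaccs = eyeproc.detect_microsaccades(
        interp, exclude_mask=interp.info["artifact_valid"]
    )
    bt = [b[0] for b in blinks]
    mt = [m.onset for m in msaccs]
    events = [e for e, _ in labeled]
    epochs = eyeproc.epoch_eye(
        interp, [e.onset for e in events], blink_times=bt, msacc_times=mt
    )
    # epoch_eye drops edge anchors; align labels with the surviving epochs
    by_anchor = {e.onset: (e, lab) for e, lab in labeled}
    triples = [(ep, *by_anchor[ep.anchor]) for ep in epochs]
    report_idx = [i for i, (_, e, _) in enumerate(triples) if e.relevance == "report"]
    noreport_idx = [i for i, (_, e, _) in enumerate(triples) if e.relevance == "no_report"]
    X = clf.feature_matrix([ep for ep, _, _ in triples])
    y = np.array([lab for _, _, lab in triples])
    pipe = clf.train_pipeline(
        X[report_idx], y[report_idx], seed=spawn_seed(config.seed, "clf")
    )
    p = target("classifier.json")
    p.write_text(pipe.to_json())
    register(p)
    outputs = clf.classify(pipe, X[noreport_idx])
    import pandas as pd

    p = target("noreport_predictions.tsv")
    pd.DataFrame(
        {
            "score": [o.score for o in outputs],
            "label": [o.label for o in outputs],
            "true_seen": y[noreport_idx],
        }
    ).to_csv(p, sep="\t", index=False)
    register(p)

    isi = generate_isi_segments(
        events, rec, seed=spawn_seed(config.seed, "isi")
    )
    if isi:
        isi_out = clf.classify_isi(pipe, [e for _, e in isi])
        p = target("isi_predictions.tsv")
        pd.DataFrame(
            {
                "center_time": [c for c, _ in isi],
                "score": [o.score for o in isi_out],
                "label": [o.label for o in isi_out],
            }
        ).to_csv(p, sep="\t", index=False)
        register(p)


def _stage_erp(config, out, state, register, target):
    templates = default_erp_templates()
    sets = generate_eeg_epochs(
        config.n_eeg_participants, config.n_eeg_trials_per_cell, templates,
        "no_report", seed=spawn_seed(config.seed, "eeg"),
    )
    p = target("eeg_participant01.h5")
    io.write_eeg_h5(sets[0], p)
    register(p)
    res = erp_mod.erp_cluster_contrast(
        sets, None,
        config=cs.ClusterTestConfig(
            alpha=config.alpha, n_perm=config.n_perm,
            seed=spawn_seed(config.seed, "erp_perm"),
        ),
    )
    p = target("erp_contrast.json")
    p.write_text(json.dumps(res.summary(), indent=2))
    register(p)


def _stage_fmri(config, out, state, register, target):
    templates = default_bold_templates()
    sess = generate_fmri_session(
        config.n_fmri_participants, config.n_fmri_events, templates,
        "report", seed=spawn_seed(config.seed, "fmri"),
    )
    res = fmri.group_contrast_map(
        sess.perceived, sess.not_perceived,
        cs.ClusterTestConfig(
            alpha=config.alpha, n_perm=config.n_perm,
            seed=spawn_seed(config.seed, "fmri_perm"),
        ),
    )
    p = target("fmri_contrast.json")
    p.write_text(json.dumps(res.summary(), indent=2))
    register(p)

    grid = templates.grid_dims
    sig_any = res.significant_mask.any(axis=1).reshape(grid).astype(np.float32)
    p = target("fmri_significant_mask.nii.gz")
    io.write_nifti(sig_any, p, voxel_size=templates.voxel_size)
    register(p)

    sel = fmri.select_network_voxels(res)
    if sel.sum() >= 3:
        tt = templates.times
        win = (tt > 0) & (tt <= 10)
        diff = sess.difference.mean(axis=0)
        part = fmri.kmeans_networks(
            diff[sel][:, win], tt[win], voxel_indices=np.flatnonzero(sel),
            seed=spawn_seed(config.seed, "kmeans"),
        )
        p = target("network_partition.nii.gz")
        io.write_nifti(
            part.label_image(grid).astype(np.float32), p, templates.voxel_size
        )
        register(p)
        p = target("network_timecourses.json")
        p.write_text(
            json.dumps(
                {k: v.tolist() for k, v in part.cluster_timecourses.items()},
                indent=2,
            )
        )
        register(p)
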