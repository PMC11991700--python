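"""Reproducible end-to-end runs: generator -> trajectory -> hierarchical fit,
and generator -> calcium analysis.

A :class:`RunConfig` (YAML-serialisable, explicit seeds per stage) drives
:func:`run_behavior` and :func:`run_calcium`; each produces a fixed artifact
set plus a manifest recording package versions, seeds, per-session QC
outcomes and sampler diagnostics.  With identical config and seeds all
non-MCMC artifacts are byte-identical across reruns; MCMC artifacts are
identical under a pinned environment.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import calcium as ca
from . import inference, synthetic, trajectory

__all__ = ["RunConfig", "StageError", "run_behavior", "run_calcium"]

BEHAVIOR_ARTIFACTS = ["visits.csv", "summary.csv", "posterior.nc", "comparison.csv", "contrasts.csv"]
CALCIUM_ARTIFACTS = ["dff.h5", "responders.csv", "onsets.csv", "fov_stats.csv"]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and offending ids."""

    def __init__(self, stage: str, message: str, session_ids=()):
        self.stage = stage
        self.session_ids = list(session_ids)
        super().__init__(f"stage {stage!r} failed: {message}" + (f" (sessions: {self.session_ids})" if session_ids else ""))


@dataclass
class RunConfig:
    """Configuration of one pipeline run (round-trips through YAML)."""

    out_dir: str = "runs/out"
    stages: tuple[str, ...] = ("simulate", "behavior", "fit", "compare", "contrasts")
    profile: str = "scaled"  # "scaled": 2 chains x 500/500; "full": 4 x 2000/2000
    seed_simulate: int = 0
    seed_fit: int = 1
    behavior: synthetic.BehaviorSimConfig = field(default_factory=synthetic.BehaviorSimConfig)
    calcium: synthetic.CalciumSimConfig = field(default_factory=synthetic.CalciumSimConfig)

    def sampler_settings(self) -> dict:
        if self.profile == "full":
            return {"chains": 4, "tune": 2000, "draws": 2000}
        if self.profile == "smoke":
            return {"chains": 2, "tune": 150, "draws": 150}
        return {"chains": 2, "tune": 500, "draws": 500}

    # -- serialisation -------------------------------------------------------

    def to_dict(self) -> dict:
        return json.loads(json.dumps(dataclasses.asdict(self), default=list))

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "behavior" in d and isinstance(d["behavior"], dict):
            b = dict(d["behavior"])
            if "geometry" in b and isinstance(b["geometry"], dict):
                b["geometry"] = trajectory.ChamberGeometry(**{k: tuple(v) for k, v in b["geometry"].items()})
            if "genotypes" in b:
                b["genotypes"] = {g: {c: tuple(p) for c, p in ch.items()} for g, ch in b["genotypes"].items()}
            d["behavior"] = synthetic.BehaviorSimConfig(**b)
        if "calcium" in d and isinstance(d["calcium"], dict):
            c = dict(d["calcium"])
            if "stimulus_plateaus" in c:
                c["stimulus_plateaus"] = tuple(c["stimulus_plateaus"])
            d["calcium"] = synthetic.CalciumSimConfig(**c)
        if "stages" in d:
            d["stages"] = tuple(d["stages"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _versions() -> dict:
    import arviz
    import scipy

    import thermodrift

    return {
        "thermodrift": thermodrift.__version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "arviz": arviz.__version__,
    }


def _write_manifest(outdir: Path, config: RunConfig, extra: dict) -> None:
    manifest = {"versions": _versions(), "config": config.to_dict(), **extra}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))


def run_behavior(config: RunConfig) -> dict:
    """Generate sessions, process tracks, fit and compare models.

    Artifacts in ``config.out_dir``: visits.csv (recovered visits),
    summary.csv (per-session preference bins and rolling statistics),
    posterior.nc, comparison.csv, contrasts.csv, manifest.json.  Returns the
    manifest dictionary.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = set(config.stages)
    qc_log: list[dict] = []
    diagnostics: dict = {}

    sim_cfg = dataclasses.replace(config.behavior, seed=config.seed_simulate)
    try:
        sample = synthetic.gen_behavior_sessions(sim_cfg, make_tracks="behavior" in stages)
    except Exception as e:  # pragma: no cover - config errors surface here
        raise StageError("simulate", str(e)) from e
    meta = sample.visits[["animal", "genotype", "temp_combo"]].drop_duplicates("animal").set_index("animal")

    if "behavior" in stages:
        visit_frames, summary_frames = [], []
        for animal, track in sample.tracks.items():
            try:
                cleaned = trajectory.clean_track(track)
                if trajectory.qc_climbing(cleaned):
                    qc_log.append({"animal": animal, "rejected": True, "reason": "climbing"})
                    continue
                pos = trajectory.to_position(cleaned, session_length=sim_cfg.session_length)
                visits = trajectory.segment_visits(pos, sim_cfg.geometry)
                summ = trajectory.summarize_session(visits, session_length=sim_cfg.session_length)
            except trajectory.SessionRejected as e:
                qc_log.append({"animal": animal, "rejected": True, "reason": e.reason})
                continue
            except Exception as e:
                raise StageError("behavior", str(e), [animal]) from e
            qc_log.append({"animal": animal, "rejected": False, "reason": ""})
            v = visits.copy()
            v.insert(0, "animal", animal)
            v.insert(1, "genotype", meta.loc[animal, "genotype"])
            v.insert(2, "temp_combo", meta.loc[animal, "temp_combo"])
            visit_frames.append(v)
            s = summ.preference.copy()
            s.insert(0, "animal", animal)
            s["crossings_total"] = summ.crossings
            summary_frames.append(s)
        if not visit_frames:
            raise StageError("behavior", "all sessions rejected by QC", [q["animal"] for q in qc_log])
        visits_df = pd.concat(visit_frames, ignore_index=True)
        visits_df.to_csv(out / "visits.csv", index=False)
        pd.concat(summary_frames, ignore_index=True).to_csv(out / "summary.csv", index=False)
    else:
        visits_df = sample.visits[["animal", "genotype", "temp_combo", "chamber", "start", "end", "duration", "censored"]]
        visits_df.to_csv(out / "visits.csv", index=False)
        if "fit" in stages or "compare" in stages:
            pass

    table = visits_df[["animal", "genotype", "temp_combo", "chamber", "duration", "censored"]]
    settings = config.sampler_settings()
    post = None
    if "fit" in stages:
        try:
            spec = inference.ModelSpec(a_value=sim_cfg.a, z=sim_cfg.z, name="v+sv predictors")
            model = inference.build_model(table, spec)
            post = inference.sample_posterior(model, seed=config.seed_fit, **settings)
            post.idata.to_netcdf(str(out / "posterior.nc"))
            diagnostics["fit"] = post.diagnostics
        except Exception as e:
            raise StageError("fit", str(e)) from e
    if "compare" in stages:
        try:
            specs = [
                inference.ModelSpec(a_value=sim_cfg.a, z=sim_cfg.z, name="v+sv predictors"),
                inference.ModelSpec(sv="floating", a_value=sim_cfg.a, z=sim_cfg.z, name="constant sv"),
            ]
            comparison = inference.rank_models(specs, table, seed=config.seed_fit, require_reliable=False, **settings)
            comparison.to_csv(out / "comparison.csv", index=False)
        except Exception as e:
            raise StageError("compare", str(e)) from e
    if "contrasts" in stages:
        try:
            if post is None:
                model = inference.build_model(table, inference.ModelSpec(a_value=sim_cfg.a, z=sim_cfg.z))
                post = inference.sample_posterior(model, seed=config.seed_fit, **settings)
            inference.contrasts(post).to_csv(out / "contrasts.csv", index=False)
        except Exception as e:
            raise StageError("contrasts", str(e)) from e

    _write_manifest(out, config, {"qc": qc_log, "diagnostics": diagnostics, "n_visits": int(len(visits_df))})
    return json.loads((out / "manifest.json").read_text())


def run_calcium(config: RunConfig) -> dict:
    """Generate a recording and run the trace pipeline.

    Artifacts: dff.h5 (session-convention dF/F0), responders.csv,
    onsets.csv, fov_stats.csv, manifest.json.
    """
    import h5py

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cal_cfg = dataclasses.replace(config.calcium, seed=config.seed_simulate)
    try:
        sample = synthetic.gen_calcium_dataset(cal_cfg)
        fset = sample.fset
        corrected = ca.neuropil_correct(fset.F, fset.Fneu, cal_cfg.neuropil_gain)
        session = ca.dff(corrected, fset.sample_rate, "first-10-s", clip_percentiles=ca.DEFAULT_CLIP_PERCENTILES)
        by_epoch = ca.dff(corrected, fset.sample_rate, "first-10-frames-per-stimulus", epochs=fset.epochs)
    except Exception as e:
        raise StageError("calcium-preprocess", str(e)) from e
    try:
        splits = ca.segment_phases(fset.stim, fset.epochs)
        X, y, rate = synthetic.labelled_training_set(seed=config.seed_fit, noise_sd=cal_cfg.noise_sd)
        clf = ca.ResponderClassifier().fit(X, y, rate)
        table = ca.build_responder_table(by_epoch, fset.epochs, clf, splits)
        n_viable = int(sample.truth["viable"].sum()) if cal_cfg.include_agonists else cal_cfg.n_cells
        stats = ca.fov_stats(table, n_viable, by_epoch, fset.epochs)
    except Exception as e:
        raise StageError("calcium-analysis", str(e)) from e

    with h5py.File(out / "dff.h5", "w") as h5:
        h5.create_dataset("dff", data=session.data)
        h5.create_dataset("time", data=session.time)
        h5.create_dataset("valid", data=session.valid)
        h5.attrs["convention"] = session.convention
    table.to_csv(out / "responders.csv", index=False)
    table[table["responder"]][["cell", "stimulus", "onset", "onset_phase"]].to_csv(out / "onsets.csv", index=False)
    per_stim = stats.per_stimulus.copy()
    per_stim.insert(0, "n_viable", stats.n_viable)
    per_stim.insert(1, "prop_warm", stats.prop_warm)
    per_stim.to_csv(out / "fov_stats.csv", index=False)
    _write_manifest(out, config, {"n_cells": cal_cfg.n_cells, "phase_boundaries": [s.boundary for s in splits]})
    return json.loads((out / "manifest.json").read_text())
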