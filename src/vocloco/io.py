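"""Study loading, model-table assembly, and the end-to-end pipeline driver.

Conventions used throughout: times are seconds from session start, event
intervals are half-open [onset, offset), and 1 Hz series are anchored at
bin centers t = 0.5, 1.5, ... s.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import ecg as ecg_mod
from . import maturity as mat_mod
from . import mixedmodels as mm
from . import motion as motion_mod
from . import perievent as pe
from .study import SessionBundle

log = logging.getLogger("vocloco")

__all__ = ["PipelineConfig", "load_study", "assemble_call_table",
           "assemble_locomotor_table", "run_pipeline"]

MANIFEST_COLUMNS = ["subject", "pnd", "session_id", "duration_s"]


@dataclass
class PipelineConfig:
    """Stage parameters; defaults are the analysis' canonical values."""

    activity_p: float = 0.10
    trajectory_p_individual: float = 0.03
    trajectory_p_population: float = 0.01
    perievent_p_session: float = 0.1
    perievent_p_population: float = 0.3
    developmental_p: float = 0.0001
    n_rep: int = 1000
    k_per_session: int = 10
    seed: int = 0
    alpha: float = 0.05
    min_hr_coverage: float = 0.5

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        return cls(**json.loads(text))

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


def load_study(manifest_path) -> list:
    """Read a study directory's manifest into SessionBundles.

    Dangling per-modality paths are flagged in the bundle QC dict and the
    load continues; missing required manifest columns raise.
    """
    manifest_path = Path(manifest_path)
    root = manifest_path.parent
    man = pd.read_csv(manifest_path, keep_default_na=False)
    missing = [c for c in MANIFEST_COLUMNS if c not in man.columns]
    if missing:
        raise ValueError(f"manifest missing required columns: {missing}")
    if len(man) == 0:
        log.warning("empty manifest %s", manifest_path)
    bundles = []
    for _, row in man.iterrows():
        b = SessionBundle(subject=str(row["subject"]), pnd=int(row["pnd"]),
                          session_id=str(row["session_id"]),
                          duration_s=float(row["duration_s"]))
        if not (1 <= b.pnd <= 61):
            raise ValueError(f"session {b.session_id}: pnd {b.pnd} outside [1, 61]")

        def _path(col):
            v = str(row.get(col, "") or "")
            if not v:
                return None
            p = root / v
            if not p.exists():
                b.qc[f"dangling_{col}"] = v
                return None
            return p

        p = _path("calls")
        if p:
            b.calls = pd.read_csv(p)
        p = _path("behaviors")
        if p:
            b.behaviors = pd.read_csv(p)
        p = _path("motion")
        if p:
            b.motion_raw = pd.read_csv(p)["raw"].to_numpy(float)
        p = _path("ecg")
        if p:
            with np.load(p) as z:
                b.beat_times = z["beat_times"]
                if "artifact_mask" in z and z["artifact_mask"].size:
                    b.qc["artifact_mask"] = [tuple(iv) for iv in z["artifact_mask"]]
        p = _path("audio")
        if p:
            from scipy.io import wavfile
            fs, wav = wavfile.read(p)
            b.audio = (np.asarray(wav, float), fs)
        bundles.append(b)
    return bundles


def _session_activity(bundle, cfg: PipelineConfig):
    if bundle.motion_raw is None:
        return None
    try:
        return motion_mod.activity_pipeline(bundle.motion_raw,
                                            session=bundle.session_id,
                                            p=cfg.activity_p)
    except ValueError:
        return None


def _session_heart_rate(bundle, cfg: PipelineConfig):
    """Arousal percentiles from observed beats (or a raw ECG recording)."""
    if bundle.ecg is not None:
        hr, qc = ecg_mod.heart_rate_pipeline(bundle.ecg)
        return hr if qc["included"] else None
    if bundle.beat_times is None:
        return None
    beats = ecg_mod.correct_intervals(bundle.beat_times)
    hr = ecg_mod.rate_from_beats(beats, bundle.duration_s)
    if not ecg_mod.coverage_ok(hr):
        return None
    return ecg_mod.to_percentiles(hr)


def _mean_in_interval(series, onset, offset):
    if series is None:
        return np.nan
    vals = pe._event_means(np.asarray(series, float),
                           np.array([onset]), np.array([offset]))
    return float(vals[0])


def assemble_call_table(bundles, activity_by_session, hr_by_session) -> pd.DataFrame:
    """Per-call model rows: acoustics plus within-call activity and arousal."""
    rows = []
    for b in bundles:
        if b.calls is None or not len(b.calls):
            continue
        act = activity_by_session.get(b.session_id)
        act = act.activity if act is not None else None
        hr = hr_by_session.get(b.session_id)
        hr = hr.percentile if hr is not None else None
        for _, c in b.calls.iterrows():
            rows.append({
                "subject": b.subject, "pnd": b.pnd, "session": b.session_id,
                "call_type": c["call_type"],
                "duration_s": c.get("duration_s", c["offset_s"] - c["onset_s"]),
                "wiener_entropy": c.get("wiener_entropy", np.nan),
                "locomotor_activity": _mean_in_interval(act, c["onset_s"], c["offset_s"]),
                "heart_rate": _mean_in_interval(hr, c["onset_s"], c["offset_s"]),
            })
    return pd.DataFrame(rows)


def assemble_locomotor_table(bundles, hr_by_session) -> pd.DataFrame:
    """Per-locomotor-bout model rows with within-bout arousal."""
    rows = []
    for b in bundles:
        if b.behaviors is None or not len(b.behaviors):
            continue
        loco = b.behaviors[b.behaviors["category"] == "locomotor"]
        hr = hr_by_session.get(b.session_id)
        hr = hr.percentile if hr is not None else None
        for _, e in loco.iterrows():
            rows.append({
                "subject": b.subject, "pnd": b.pnd, "session": b.session_id,
                "event": "locomotor", "behavior": e["behavior"],
                "heart_rate": _mean_in_interval(hr, e["onset_s"], e["offset_s"]),
            })
    return pd.DataFrame(rows)


HOLM_FAMILIES = {"1.5": "acoustic~activity", "1.6": "acoustic~activity"}


def _fit_suite(call_table, loco_table, maturity_pts, proportions, cfg) -> pd.DataFrame:
    """Fit every suite model whose inputs exist; Holm-adjust within families."""
    frames = []
    for spec in mm.build_suite():
        try:
            if spec.name in ("1.1", "1.2", "1.3"):
                cat = spec.subset["category"]
                sub = proportions[proportions["category"] == cat]
                parts = []
                for beh, grp in sub.groupby("behavior"):
                    r = mm.fit_model(mm.ModelSpec(spec.name, "proportion", "pnd",
                                                  spec.random), grp)
                    r["term"] = f"pnd[{beh}]"
                    parts.append(r)
                if parts:
                    frames.append(pd.concat(parts, ignore_index=True))
                continue
            if spec.name == "1.4":
                data = maturity_pts
            elif spec.name == "1.11":
                data = loco_table
            else:
                data = call_table
            if data is None or not len(data):
                continue
            if spec.response in data.columns and data[spec.response].notna().sum() == 0:
                continue
            frames.append(mm.fit_model(spec, data))
        except ValueError as exc:
            log.warning("model %s skipped: %s", spec.name, exc)
    if not frames:
        return pd.DataFrame()
    out = pd.concat(frames, ignore_index=True)
    fam = out["model_id"].map(lambda a: HOLM_FAMILIES.get(a, a))
    out["p_adj"] = np.nan
    for _, idx in out.groupby(fam).groups.items():
        ok = out.loc[idx, "p_raw"].notna()
        if ok.any():
            out.loc[idx[ok], "p_adj"] = mm.holm_adjust(out.loc[idx[ok], "p_raw"])
    return out


def run_pipeline(bundles, config: PipelineConfig | None = None, outdir=None,
                 force=False) -> dict:
    """Execute acoustics -> motion -> ecg -> maturity -> peri-event -> models.

    Returns a dict of result tables/objects; when ``outdir`` is given, CSVs
    and a provenance record (config hash, seed, stage counts) are written.
    Re-running into an outdir holding the same config hash reuses it unless
    ``force``.
    """
    cfg = config or PipelineConfig()
    if outdir is not None:
        outdir = Path(outdir)
        prov_path = outdir / "provenance.json"
        if prov_path.exists() and not force:
            prov = json.loads(prov_path.read_text())
            if prov.get("config_hash") == cfg.config_hash:
                log.info("outputs for config %s already present; reusing",
                         cfg.config_hash)
                return {"cached": True, "outdir": outdir}
        outdir.mkdir(parents=True, exist_ok=True)

    counts = {"sessions": len(bundles)}
    activity = {b.session_id: _session_activity(b, cfg) for b in bundles}
    activity = {k: v for k, v in activity.items() if v is not None}
    counts["motion_sessions"] = len(activity)

    hr = {b.session_id: _session_heart_rate(b, cfg) for b in bundles}
    counts["ecg_sessions"] = sum(b.has_ecg for b in bundles)
    hr = {k: v for k, v in hr.items() if v is not None}
    counts["ecg_sessions_included"] = len(hr)

    proportions = mat_mod.category_proportions(bundles)
    classification = mat_mod.classify_behaviors(proportions, alpha=cfg.alpha)
    points = mat_mod.maturity_points(bundles, classification)
    trajectories = {}
    for cat, grp in points.groupby("category"):
        try:
            fit = mat_mod.fit_trajectory(grp, level="population",
                                         p_population=cfg.trajectory_p_population,
                                         category=cat)
            trajectories[cat] = fit
        except ValueError as exc:
            log.warning("trajectory for %s skipped: %s", cat, exc)
    counts["calls"] = int(sum(len(b.calls) for b in bundles if b.calls is not None))
    counts["behavior_instances"] = int(sum(len(b.behaviors) for b in bundles
                                           if b.behaviors is not None))

    call_table = assemble_call_table(bundles, activity, hr)
    loco_table = assemble_locomotor_table(bundles, hr)
    models = _fit_suite(call_table, loco_table, points, proportions, cfg)

    # peri-event bands: arousal around phee onsets; locomotion around call onsets
    hr_sessions, act_sessions = [], []
    for b in bundles:
        if b.calls is None or not len(b.calls):
            continue
        phees = b.calls[b.calls["call_type"] == "phee"]
        if b.session_id in hr and len(phees):
            hr_sessions.append(pe.SessionSignal(hr[b.session_id].percentile, phees,
                                                b.duration_s, b.pnd, b.session_id))
        if b.session_id in activity and len(b.calls):
            act_sessions.append(pe.SessionSignal(activity[b.session_id].activity,
                                                 b.calls, b.duration_s, b.pnd,
                                                 b.session_id))
    bands = {}
    if hr_sessions:
        bands["heartrate_phee_onset"] = pe.perievent_band(
            hr_sessions, kind="heartrate", anchor="onset", n_rep=cfg.n_rep,
            k_per_session=cfg.k_per_session, seed=cfg.seed,
            p_session=cfg.perievent_p_session,
            p_population=cfg.perievent_p_population)
    if act_sessions:
        bands["locomotor_call_onset"] = pe.perievent_band(
            act_sessions, kind="locomotor", anchor="onset", n_rep=cfg.n_rep,
            k_per_session=cfg.k_per_session, seed=cfg.seed,
            p_session=cfg.perievent_p_session,
            p_population=cfg.perievent_p_population)

    results = {
        "activity": activity, "heart_rate": hr, "proportions": proportions,
        "classification": classification, "maturity_points": points,
        "trajectories": trajectories,
        "transition_days": {c: t.transition_day for c, t in trajectories.items()},
        "call_table": call_table, "locomotor_table": loco_table,
        "models": models, "bands": bands, "counts": counts,
    }

    if outdir is not None:
        proportions.to_csv(outdir / "proportions.csv", index=False)
        classification.to_csv(outdir / "classification.csv", index=False)
        points.to_csv(outdir / "maturity.csv", index=False)
        if len(models):
            models.to_csv(outdir / "models.csv", index=False)
        if len(call_table):
            call_table.to_csv(outdir / "calls_model_table.csv", index=False)
        for name, band in bands.items():
            band.to_frame().to_csv(outdir / f"perievent_{name}.csv", index=False)
        traj = {c: {"knots": t.spline.knots.tolist(),
                    "values": t.spline.values.tolist(),
                    "p": t.p, "transition_day": t.transition_day}
                for c, t in trajectories.items()}
        (outdir / "trajectories.json").write_text(json.dumps(traj, indent=2))
        (outdir / "provenance.json").write_text(json.dumps(
            {"config_hash": cfg.config_hash, "config": json.loads(cfg.to_json()),
             "counts": counts, "schema_version": 1}, indent=2))
    return results
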