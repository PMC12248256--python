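"""Session readers/writers, GeoJSON export, and the pipeline driver.

Flat-file layout of a session directory::

    env.csv            environmental stream (ISO-8601 UTC timestamps)
    physio.csv         physiological stream
    segment_plan.json  ordered static intervals [label, arrive_s, leave_s]
    profile.json       participant biometrics

Every file written here starts with ``#``-prefixed metadata lines (tool
version, seed, config hash) so a result can always be traced to the run
that produced it; readers skip them.  Timestamps are stored as ISO-8601
UTC alongside the relative seconds used internally.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from datetime import datetime, timedelta, timezone
from pathlib import Path

import pandas as pd

from . import __version__
from .compare import MethodComparison
from .exposure import (DOSE_POLLUTANTS, ExposureTable, StandardInputs,
                       session_exposure, standard_dose)
from .preprocess import preprocess_session
from .synthetic import (ParticipantProfile, ScenarioConfig, SensorSession,
                        generate_profile, generate_session)
from .ventilation import vm_series

__all__ = [
    "RunConfig",
    "write_session",
    "read_session",
    "export_geojson",
    "run_pipeline",
]

log = logging.getLogger(__name__)

# fixed epoch for relative->ISO conversion; morning sessions start at 10:00,
# afternoon at 14:30 (the campaign's two daily slots)
_SLOT_START = {"morning": datetime(2022, 11, 7, 10, 0, tzinfo=timezone.utc),
               "afternoon": datetime(2022, 11, 7, 14, 30, tzinfo=timezone.utc)}


@dataclasses.dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    scenario: ScenarioConfig
    standard_inputs: StandardInputs
    n_participants: int = 1
    sex_ratio: float = 0.7
    seed: int = 0
    out_dir: str = "pape_run"
    env_factor: str = "minute_means"
    ventilation_mode: str = "nodes"   # or "segment_median"
    pollutant: str = "pm2_5"

    def config_hash(self) -> str:
        payload = json.dumps({
            "scenario": dataclasses.asdict(self.scenario),
            "standard_inputs": dataclasses.asdict(self.standard_inputs),
            "n_participants": self.n_participants, "sex_ratio": self.sex_ratio,
            "seed": self.seed, "env_factor": self.env_factor,
            "ventilation_mode": self.ventilation_mode, "pollutant": self.pollutant,
        }, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _metadata_header(seed, config_hash: str = "") -> str:
    return (f"# pape {__version__}\n# seed: {seed}\n"
            f"# config_hash: {config_hash}\n")


def _write_csv(df: pd.DataFrame, path: Path, seed, config_hash: str = "") -> None:
    with open(path, "w", newline="") as fh:
        fh.write(_metadata_header(seed, config_hash))
        df.to_csv(fh, index=False)


def write_session(session: SensorSession, out_dir, seed="", config_hash="") -> Path:
    """Persist a session directory (env.csv, physio.csv, plan, profile)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    base = _SLOT_START[session.time_of_day]
    for name, df in (("env.csv", session.env_stream), ("physio.csv", session.physio_stream)):
        df = df.copy()
        iso = [(base + timedelta(seconds=float(s))).isoformat().replace("+00:00", "Z")
               for s in df["timestamp"]]
        df.insert(0, "time_utc", iso)
        _write_csv(df, out / name, seed, config_hash)
    (out / "segment_plan.json").write_text(json.dumps({
        "time_of_day": session.time_of_day,
        "segments": [[label, a, b] for label, a, b in session.segment_plan],
    }, indent=1))
    (out / "profile.json").write_text(json.dumps(
        dataclasses.asdict(session.profile), indent=1))
    return out


def _read_stream_csv(path: Path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, comment="#")
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path.name}: malformed CSV ({exc})") from exc
    if "timestamp" not in df.columns:
        raise ValueError(f"{path.name}: missing required column 'timestamp'")
    if df.isna().any().any():
        col = df.columns[df.isna().any()][0]
        line = int(df[col].isna().idxmax())
        raise ValueError(f"{path.name}: missing value in column {col!r} at data row {line}")
    return df


def read_session(session_dir) -> SensorSession:
    """Load and validate a session directory written by :func:`write_session`.

    Every session invariant (monotone timestamps, non-negative
    concentrations, PM size-fraction ordering, plan containment) is
    enforced on load; violations raise ``ValueError`` naming the file and
    offending row.
    """
    d = Path(session_dir)
    for required in ("env.csv", "physio.csv", "segment_plan.json", "profile.json"):
        if not (d / required).exists():
            raise FileNotFoundError(f"session directory {d} lacks {required}")
    env = _read_stream_csv(d / "env.csv").drop(columns=["time_utc"], errors="ignore")
    physio = _read_stream_csv(d / "physio.csv").drop(columns=["time_utc"], errors="ignore")
    plan_doc = json.loads((d / "segment_plan.json").read_text())
    plan = [(str(label), float(a), float(b)) for label, a, b in plan_doc["segments"]]
    profile = ParticipantProfile(**json.loads((d / "profile.json").read_text()))
    session = SensorSession(profile=profile, env_stream=env, physio_stream=physio,
                            segment_plan=plan,
                            time_of_day=plan_doc.get("time_of_day", "morning"))
    try:
        return session.validate()
    except ValueError as exc:
        raise ValueError(f"{d / 'env.csv'}: {exc}") from exc


def export_geojson(session: SensorSession, exposure: ExposureTable | None = None) -> dict:
    """GeoJSON FeatureCollection: the walked track as a LineString plus one
    Point per static segment carrying per-pollutant median concentrations
    and, when an exposure table is supplied, the segment doses."""
    env = session.env_stream
    if "lat" not in env.columns or "lon" not in env.columns:
        raise ValueError("session has no coordinates to export")
    coords = [[round(float(lon), 6), round(float(lat), 6)]
              for lat, lon in zip(env["lat"], env["lon"])]
    features = [{
        "type": "Feature",
        "geometry": {"type": "LineString", "coordinates": coords},
        "properties": {"participant": session.profile.participant_id,
                       "time_of_day": session.time_of_day},
    }]
    t = env["timestamp"].to_numpy(float)
    for label, arrive, leave in session.segment_plan:
        mask = (t >= arrive) & (t < leave)
        sub = env.loc[mask]
        props = {"label": label, "arrive_s": arrive, "leave_s": leave}
        for pol in DOSE_POLLUTANTS:
            if pol in sub.columns and mask.any():
                props[f"{pol}_median"] = float(sub[pol].median())
        if exposure is not None:
            seg_rows = exposure.rows[exposure.rows["segment"] == label]
            for row in seg_rows.itertuples():
                props[f"{row.pollutant}_pape"] = row.pape
        lat = float(sub["lat"].median()) if mask.any() else None
        lon = float(sub["lon"].median()) if mask.any() else None
        features.append({
            "type": "Feature",
            "geometry": {"type": "Point", "coordinates": [round(lon, 6), round(lat, 6)]},
            "properties": props,
        })
    return {"type": "FeatureCollection", "features": features}


def run_pipeline(config: RunConfig) -> dict:
    """Simulate -> preprocess -> ventilation -> exposure -> compare.

    Persists all intermediates under ``config.out_dir`` and returns a
    manifest (also written as ``manifest.json``) with the seed, config
    hash and SHA-256 of every output, so identical configurations yield
    byte-identical runs.
    """
    if config.standard_inputs is None:
        raise ValueError("run requires standard_inputs (fixed-station concentrations)")
    if config.pollutant not in config.standard_inputs.c_std:
        raise ValueError(f"standard_inputs lacks pollutant {config.pollutant!r}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    stage = "simulate"
    doses_new, doses_std, outputs = [], [], []
    try:
        for i in range(config.n_participants):
            pseed = config.seed * 100003 + i
            profile = generate_profile(pseed, config.sex_ratio, f"P{i + 1:02d}")
            session = generate_session(profile, config.scenario, pseed + 1)
            sdir = write_session(session, out / f"P{i + 1:02d}", config.seed, chash)
            outputs += [sdir / "env.csv", sdir / "physio.csv",
                        sdir / "segment_plan.json", sdir / "profile.json"]

            stage = "preprocess"
            channels = preprocess_session(session)

            stage = "ventilation"
            vm = vm_series(channels["pr"], channels["rr"], profile,
                           per_segment_median=(config.ventilation_mode == "segment_median"))

            stage = "exposure"
            table = session_exposure(channels, vm, env_factor=config.env_factor)
            _write_csv(table.to_frame().round(6), sdir / "exposure.csv",
                       config.seed, chash)
            outputs.append(sdir / "exposure.csv")
            track = export_geojson(session, table)
            (sdir / "track.geojson").write_text(json.dumps(track))
            outputs.append(sdir / "track.geojson")

            doses_new.append(table.total(config.pollutant))
            doses_std.append(standard_dose(config.standard_inputs, config.pollutant))
            log.info("participant %s: ID_NEW=%.2f ID_STD=%.2f",
                     profile.participant_id, doses_new[-1], doses_std[-1])

        stage = "compare"
        report: dict = {"id_new": doses_new, "id_std": doses_std}
        if config.n_participants >= 3:
            res = MethodComparison(doses_new, doses_std).fit()
            report["comparison"] = {k: v for k, v in res.as_dict().items()}
            (out / "comparison.txt").write_text(res.summary() + "\n")
            outputs.append(out / "comparison.txt")
        (out / "doses.json").write_text(json.dumps(report, indent=1, default=float))
        outputs.append(out / "doses.json")
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    manifest = {
        "tool": f"pape {__version__}",
        "seed": config.seed,
        "config_hash": chash,
        "outputs": {str(p.relative_to(out)): hashlib.sha256(p.read_bytes()).hexdigest()
                    for p in outputs},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
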