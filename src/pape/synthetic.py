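"""Seeded generation of synthetic body-sensor-network (BSN) sessions.

A session emulates the walking protocol used to evaluate personal air
pollution exposure: seven static acquisition points (labelled A..G, each a
distinct microenvironment — A is the only indoor one, a laboratory) joined
by walking transits, with an environmental monitor sampling every 24 s
(PM1/PM2.5/PM10, CO2, tVOC, CO, NO2, temperature, humidity, pressure, GPS)
and a physiological node sampling pulse rate and respiratory rate at 10 Hz.

Default regime parameters (per-label medians and IQR-like spreads) follow
the published per-point summaries of the pilot campaign: indoor air shows
high CO2/tVOC and low particulate matter, outdoor points the reverse, with
a marked CO2 excess indoors (~1010 ppm vs ~620 ppm outside).  CO and NO2
stayed below the 20 ppb detection limit throughout that campaign, so both
channels are generated left-censored at the limit of detection.

Everything is driven by :class:`numpy.random.Generator` seeded explicitly;
identical (profile, config, seed) triples produce identical sessions.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ScenarioConfig",
    "ParticipantProfile",
    "SensorSession",
    "STATIC_LABELS",
    "default_regimes",
    "default_physio",
    "default_waypoints",
    "predict_fvc",
    "generate_profile",
    "generate_session",
    "simulate_point_summaries",
]

STATIC_LABELS = ("A", "B", "C", "D", "E", "F", "G")

#: Pollutant / atmosphere channels carried by the environmental stream.
ENV_CHANNELS = ("pm1", "pm2_5", "pm10", "co2", "tvoc", "co", "no2", "temp", "rh", "pressure")

# Per-point (median, spread) for each channel. Spreads are IQRs; the AR(1)
# noise converts them to a Gaussian sigma via IQR / 1.349. Values mirror the
# campaign's per-point summary table; CO/NO2 are sub-LOD everywhere.
_REGIMES = {
    "A": {"co2": (1010.4, 214.2), "tvoc": (586.1, 207.5), "pm1": (8.4, 7.8),
          "pm2_5": (9.9, 8.6), "pm10": (10.4, 8.9), "co": (8.0, 6.0), "no2": (8.0, 6.0),
          "temp": (21.0, 1.0), "rh": (45.0, 5.0), "pressure": (1013.0, 1.0)},
    "B": {"co2": (615.9, 56.3), "tvoc": (167.7, 215.0), "pm1": (22.7, 22.8),
          "pm2_5": (24.2, 16.0), "pm10": (24.6, 16.9), "co": (8.0, 6.0), "no2": (8.0, 6.0),
          "temp": (14.0, 1.5), "rh": (60.0, 6.0), "pressure": (1013.0, 1.0)},
    "C": {"co2": (628.7, 73.5), "tvoc": (161.8, 254.2), "pm1": (19.7, 23.3),
          "pm2_5": (23.0, 17.5), "pm10": (23.3, 17.3), "co": (8.0, 6.0), "no2": (8.0, 6.0),
          "temp": (14.0, 1.5), "rh": (60.0, 6.0), "pressure": (1013.0, 1.0)},
    "D": {"co2": (619.4, 74.7), "tvoc": (160.4, 259.9), "pm1": (21.5, 24.8),
          "pm2_5": (21.7, 16.9), "pm10": (22.0, 18.9), "co": (8.0, 6.0), "no2": (8.0, 6.0),
          "temp": (14.0, 1.5), "rh": (60.0, 6.0), "pressure": (1013.0, 1.0)},
    "E": {"co2": (628.5, 72.0), "tvoc": (86.1, 134.7), "pm1": (20.7, 23.5),
          "pm2_5": (23.3, 21.9), "pm10": (23.7, 21.6), "co": (8.0, 6.0), "no2": (8.0, 6.0),
          "temp": (14.0, 1.5), "rh": (60.0, 6.0), "pressure": (1013.0, 1.0)},
    "F": {"co2": (626.6, 64.6), "tvoc": (134.5, 319.6), "pm1": (21.7, 20.2),
          "pm2_5": (21.8, 17.0), "pm10": (22.1, 17.1), "co": (8.0, 6.0), "no2": (8.0, 6.0),
          "temp": (14.0, 1.5), "rh": (60.0, 6.0), "pressure": (1013.0, 1.0)},
    "G": {"co2": (650.0, 79.1), "tvoc": (205.8, 440.0), "pm1": (24.4, 17.8),
          "pm2_5": (26.2, 15.1), "pm10": (26.6, 15.1), "co": (8.0, 6.0), "no2": (8.0, 6.0),
          "temp": (14.0, 1.5), "rh": (60.0, 6.0), "pressure": (1013.0, 1.0)},
}

_PHYSIO = {
    "A": {"rr": (24.0, 16.9), "pr": (86.7, 13.1)},
    "B": {"rr": (17.1, 16.6), "pr": (98.8, 19.2)},
    "C": {"rr": (14.3, 9.67), "pr": (98.1, 18.6)},
    "D": {"rr": (14.6, 9.6), "pr": (97.7, 19.0)},
    "E": {"rr": (14.3, 9.7), "pr": (105.1, 21.0)},
    "F": {"rr": (11.1, 8.6), "pr": (99.0, 21.5)},
    "G": {"rr": (11.3, 9.6), "pr": (101.0, 25.0)},
}

# Waypoints along a ~4.5 km loop in the Città Studi university area of Milan
# (lab -> gas station -> park -> traffic-light intersection -> train station
# -> small park with the regional fixed station -> low-traffic street).
_WAYPOINTS = {
    "A": (45.4785, 9.2272),
    "B": (45.4809, 9.2245),
    "C": (45.4838, 9.2266),
    "D": (45.4850, 9.2320),
    "E": (45.4860, 9.2372),
    "F": (45.4829, 9.2385),
    "G": (45.4797, 9.2330),
}


def default_regimes() -> dict:
    return {k: dict(v) for k, v in _REGIMES.items()}


def default_physio() -> dict:
    return {k: dict(v) for k, v in _PHYSIO.items()}


def default_waypoints() -> dict:
    return dict(_WAYPOINTS)


@dataclass
class ScenarioConfig:
    """Parameters of a synthetic acquisition scenario.

    ``regime_params[label][channel] = (median, iqr)`` and
    ``physio_params[label] = {"rr": (median, iqr), "pr": (median, iqr)}``
    must cover every label in the segment plan.  ``tod_shift`` applies a
    multiplicative factor to PM/tVOC and an additive offset to CO2 for
    afternoon sessions (afternoon PM is higher, afternoon CO2 lower, as in
    the campaign).  The within-segment noise is AR(1); ``ar_coef`` sets its
    lag-1 correlation (a documented stand-in — the underlying study reports
    only per-point medians and IQRs, not temporal autocorrelation).
    """

    env_period_s: float = 24.0
    physio_rate_hz: float = 10.0
    static_dwell_min: float = 5.0
    transit_min: float = 6.0
    segment_plan_template: tuple = STATIC_LABELS
    regime_params: dict = field(default_factory=default_regimes)
    physio_params: dict = field(default_factory=default_physio)
    waypoints: dict = field(default_factory=default_waypoints)
    time_of_day: str = "morning"
    tod_pm_factor: float = 1.35      # afternoon multiplicative shift on PM & tVOC
    tod_co2_offset: float = -40.0    # afternoon additive shift on CO2 (ppm)
    lod_ppb: float = 20.0
    ar_coef: float = 0.8
    ar_coef_physio: float = 0.95
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.env_period_s <= 0 or self.physio_rate_hz <= 0:
            raise ValueError("sampling cadences must be positive")
        if self.static_dwell_min <= 0 or self.transit_min <= 0:
            raise ValueError("dwell and transit durations must be positive")
        if self.lod_ppb < 0:
            raise ValueError("lod_ppb must be non-negative")
        if self.time_of_day not in ("morning", "afternoon"):
            raise ValueError(f"time_of_day must be morning|afternoon, got {self.time_of_day!r}")
        for label in self.segment_plan_template:
            if label not in self.regime_params:
                raise ValueError(f"no regime_params for segment label {label!r}")
            if label not in self.physio_params:
                raise ValueError(f"no physio_params for segment label {label!r}")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ScenarioConfig":
        raw = json.loads(text)
        raw["segment_plan_template"] = tuple(raw.get("segment_plan_template", STATIC_LABELS))
        for key in ("regime_params", "physio_params"):
            raw[key] = {lbl: {ch: tuple(v) for ch, v in d.items()} for lbl, d in raw[key].items()}
        raw["waypoints"] = {lbl: tuple(v) for lbl, v in raw["waypoints"].items()}
        return cls(**raw)


@dataclass(frozen=True)
class ParticipantProfile:
    """Biometrics feeding the ventilation model and the Standard Method.

    ``sex_code`` uses the ventilation model's coding: 1 = man, 2 = woman.
    """

    participant_id: str
    sex_code: int
    age: float
    height: float  # cm
    weight: float  # kg
    fvc: float     # litres

    def __post_init__(self) -> None:
        if self.sex_code not in (1, 2):
            raise ValueError(f"sex_code must be 1 (man) or 2 (woman), got {self.sex_code}")
        if not 18 <= self.age <= 75:
            raise ValueError(f"age {self.age} outside the 18-75 y eligibility window")
        if self.height <= 0 or self.weight <= 0 or self.fvc <= 0:
            raise ValueError("height, weight and FVC must be positive")


@dataclass
class SensorSession:
    """A participant's synchronized environmental + physiological streams.

    ``env_stream`` and ``physio_stream`` are DataFrames with a ``timestamp``
    column in seconds from session start; ``segment_plan`` is an ordered
    list of ``(label, arrive_ts, leave_ts)`` for the static points, dynamic
    segments being the gaps between consecutive static intervals.
    """

    profile: ParticipantProfile
    env_stream: pd.DataFrame
    physio_stream: pd.DataFrame
    segment_plan: list
    time_of_day: str = "morning"

    def validate(self) -> "SensorSession":
        for name, df in (("env", self.env_stream), ("physio", self.physio_stream)):
            ts = df["timestamp"].to_numpy(float)
            if len(ts) and not np.all(np.diff(ts) > 0):
                i = int(np.argmin(np.diff(ts) > 0))
                raise ValueError(f"{name} stream: timestamps not strictly increasing at row {i + 1}")
        conc = [c for c in ("pm1", "pm2_5", "pm10", "co2", "tvoc", "co", "no2")
                if c in self.env_stream.columns]
        bad = self.env_stream[conc].lt(0).any(axis=1)
        if bad.any():
            raise ValueError(f"negative concentration at env row {int(bad.idxmax())}")
        pm = self.env_stream[["pm1", "pm2_5", "pm10"]].to_numpy(float)
        viol = (pm[:, 0] > pm[:, 1]) | (pm[:, 1] > pm[:, 2])
        if viol.any():
            raise ValueError(f"PM size-fraction ordering violated at env row {int(np.argmax(viol))}")
        t0 = float(self.env_stream["timestamp"].iloc[0])
        t1 = float(self.env_stream["timestamp"].iloc[-1])
        prev_leave = -math.inf
        for label, arrive, leave in self.segment_plan:
            if not (arrive < leave):
                raise ValueError(f"segment {label}: arrive must precede leave")
            if arrive < prev_leave:
                raise ValueError(f"segment {label} overlaps the previous segment")
            if arrive < t0 or leave > t1 + 1e-9:
                raise ValueError(f"segment {label} outside the stream span [{t0}, {t1}]")
            prev_leave = leave
        return self


# -- forced vital capacity -------------------------------------------------

# Linear adult spirometry reference (stand-in, not the GLI-2012 splines):
# FVC = a*height_cm + b*age_years + c, per sex.
FVC_COEFFS = {
    1: (0.0576, -0.026, -4.34),   # men
    2: (0.0443, -0.026, -2.89),   # women
}


def predict_fvc(sex_code: int, age: float, height: float, coeffs: dict | None = None) -> float:
    """Predict forced vital capacity (L) from sex, age (y) and height (cm).

    A linear reference of the form ``a*height + b*age + c`` per sex — a
    documented stand-in for a full spirometry reference; override ``coeffs``
    (mapping sex_code -> (a, b, c)) to substitute another equation.
    """
    if sex_code not in (1, 2):
        raise ValueError(f"sex_code must be 1 or 2, got {sex_code}")
    if height <= 0:
        raise ValueError("height must be positive")
    if age <= 0:
        raise ValueError("age must be positive")
    a, b, c = (coeffs or FVC_COEFFS)[sex_code]
    fvc = a * height + b * age + c
    if fvc <= 0:
        raise ValueError(f"non-physiological FVC {fvc:.2f} L for inputs "
                         f"(sex={sex_code}, age={age}, height={height})")
    return fvc


def generate_profile(seed: int, sex_ratio: float = 0.7,
                     participant_id: str | None = None) -> ParticipantProfile:
    """Draw one participant profile.

    ``sex_ratio`` is the probability of drawing a man (the pilot cohort was
    14 men / 6 women).  Ages centre near 25.5 y with a small fraction of
    older adults; heights and weights follow sex-specific normals near the
    cohort medians (179 cm, 70 kg).  FVC is filled from :func:`predict_fvc`.
    """
    if not 0.0 <= sex_ratio <= 1.0:
        raise ValueError("sex_ratio must be in [0, 1]")
    rng = np.random.default_rng(seed)
    sex_code = 1 if rng.random() < sex_ratio else 2
    if rng.random() < 0.15:  # occasional older participants (outliers in the cohort)
        age = float(rng.uniform(30.0, 60.0))
    else:
        age = float(np.clip(rng.normal(25.5, 2.2), 20.0, 32.0))
    if sex_code == 1:
        height = float(np.clip(rng.normal(179.0, 6.0), 160.0, 200.0))
        weight = float(np.clip(rng.normal(74.0, 8.0), 50.0, 110.0))
    else:
        height = float(np.clip(rng.normal(166.0, 6.0), 148.0, 185.0))
        weight = float(np.clip(rng.normal(62.0, 7.0), 42.0, 95.0))
    pid = participant_id or f"S{seed:04d}"
    return ParticipantProfile(pid, sex_code, round(age, 1), round(height, 1),
                              round(weight, 1), round(predict_fvc(sex_code, age, height), 3))


# -- session generation ----------------------------------------------------

def _ar1(rng: np.random.Generator, n: int, sigma: float, phi: float) -> np.ndarray:
    """Stationary AR(1) noise with marginal sd ``sigma``."""
    if n <= 0:
        return np.empty(0)
    if sigma == 0.0:
        return np.zeros(n)
    x = np.empty(n)
    innov = rng.normal(0.0, 1.0, n)
    x[0] = innov[0] * sigma
    scale = sigma * math.sqrt(1.0 - phi * phi)
    for i in range(1, n):
        x[i] = phi * x[i - 1] + scale * innov[i]
    return x

_IQR_TO_SD = 1.0 / 1.3489795003921634  # Gaussian IQR -> sigma


def _build_plan(config: ScenarioConfig) -> list:
    """Static intervals (label, arrive, leave) in seconds; transits between."""
    plan, t = [], 0.0
    dwell = config.static_dwell_min * 60.0
    transit = config.transit_min * 60.0
    for label in config.segment_plan_template:
        plan.append((label, t, t + dwell))
        t += dwell + transit  # after the final point: transit back to start
    return plan


def _segment_medians(config: ScenarioConfig, channel: str) -> dict:
    """Per-label medians with the time-of-day shift applied."""
    out = {}
    for label in config.segment_plan_template:
        med, iqr = config.regime_params[label][channel]
        if config.time_of_day == "afternoon":
            if channel in ("pm1", "pm2_5", "pm10", "tvoc"):
                med = med * config.tod_pm_factor
            elif channel == "co2":
                med = med + config.tod_co2_offset
        out[label] = (med, iqr)
    return out


def _label_profile(times: np.ndarray, plan: list, med_by_label: dict,
                   session_end: float) -> np.ndarray:
    """Piecewise median profile: constant inside a static dwell, linear blend
    between consecutive dwell medians during transits (wrap back to the first
    label after the last point)."""
    meds = np.empty_like(times, dtype=float)
    labels = [p[0] for p in plan]
    for i, (label, arrive, leave) in enumerate(plan):
        m = med_by_label[label][0]
        meds[(times >= arrive) & (times < leave)] = m
        nxt_label = labels[(i + 1) % len(labels)]
        nxt_arrive = plan[i + 1][1] if i + 1 < len(plan) else session_end
        m_next = med_by_label[nxt_label][0]
        in_transit = (times >= leave) & (times < nxt_arrive)
        if in_transit.any() and nxt_arrive > leave:
            frac = (times[in_transit] - leave) / (nxt_arrive - leave)
            meds[in_transit] = m + frac * (m_next - m)
    # the sample landing exactly on session_end closes the loop at the start
    meds[times >= session_end] = med_by_label[labels[0]][0]
    return meds


def _spread_profile(times: np.ndarray, plan: list, med_by_label: dict,
                    session_end: float) -> np.ndarray:
    sig = np.empty_like(times, dtype=float)
    labels = [p[0] for p in plan]
    for i, (label, arrive, leave) in enumerate(plan):
        s = med_by_label[label][1] * _IQR_TO_SD
        nxt_arrive = plan[i + 1][1] if i + 1 < len(plan) else session_end
        s_next = med_by_label[labels[(i + 1) % len(labels)]][1] * _IQR_TO_SD
        sig[(times >= arrive) & (times < leave)] = s
        in_transit = (times >= leave) & (times < nxt_arrive)
        if in_transit.any() and nxt_arrive > leave:
            frac = (times[in_transit] - leave) / (nxt_arrive - leave)
            sig[in_transit] = s + frac * (s_next - s)
    sig[times >= session_end] = med_by_label[labels[0]][1] * _IQR_TO_SD
    return sig


def _gps_track(times: np.ndarray, plan: list, waypoints: dict,
               session_end: float) -> tuple[np.ndarray, np.ndarray]:
    """Piecewise-linear position: parked at a waypoint during a dwell,
    straight-line walk between waypoints during transits."""
    knots_t, knots_lat, knots_lon = [], [], []
    for label, arrive, leave in plan:
        lat, lon = waypoints[label]
        knots_t += [arrive, leave]
        knots_lat += [lat, lat]
        knots_lon += [lon, lon]
    lat0, lon0 = waypoints[plan[0][0]]
    knots_t.append(session_end)
    knots_lat.append(lat0)
    knots_lon.append(lon0)
    return (np.interp(times, knots_t, knots_lat),
            np.interp(times, knots_t, knots_lon))


def generate_session(profile: ParticipantProfile, config: ScenarioConfig,
                     seed: int) -> SensorSession:
    """Generate one full BSN session for a participant.

    Environmental records are spaced ``env_period_s`` apart from t=0 to the
    end of the final transit; physiological records run at
    ``physio_rate_hz``.  Each channel follows its label's regime — AR(1)
    fluctuations around the configured median, blended linearly across
    transits — with PM size-fraction ordering enforced and CO/NO2 reported
    left-censored at ``lod_ppb`` (flag columns ``co_censored`` /
    ``no2_censored``).
    """
    rng = np.random.default_rng(seed)
    plan = _build_plan(config)
    session_end = plan[-1][2] + config.transit_min * 60.0

    t_env = np.arange(0.0, session_end + 1e-9, config.env_period_s)
    env = {"timestamp": t_env}
    for channel in ENV_CHANNELS:
        med = _segment_medians(config, channel)
        base = _label_profile(t_env, plan, med, session_end)
        sig = _spread_profile(t_env, plan, med, session_end)
        # AR(1) with a slowly varying scale; spread -> 0 recovers the median
        noise = _ar1(rng, len(t_env), 1.0, config.ar_coef) * sig
        env[channel] = np.maximum(base + noise, 0.0)
    # enforce pm1 <= pm2_5 <= pm10 record-wise (medians are already ordered;
    # noise may locally swap fractions)
    pm = np.maximum.accumulate(np.column_stack([env["pm1"], env["pm2_5"], env["pm10"]]), axis=1)
    env["pm1"], env["pm2_5"], env["pm10"] = pm[:, 0], pm[:, 1], pm[:, 2]
    # left-censor the electrochemical gas channels at the detection limit
    for gas in ("co", "no2"):
        raw = env[gas]
        censored = raw < config.lod_ppb
        env[gas] = np.where(censored, config.lod_ppb, raw)
        env[f"{gas}_censored"] = censored
    lat, lon = _gps_track(t_env, plan, config.waypoints, session_end)
    env["lat"], env["lon"] = lat, lon
    env_df = pd.DataFrame(env)

    t_phys = np.arange(0.0, session_end + 1e-9, 1.0 / config.physio_rate_hz)
    physio = {"timestamp": t_phys}
    for channel in ("pr", "rr"):
        med = {lbl: config.physio_params[lbl][channel]
               for lbl in config.segment_plan_template}
        base = _label_profile(t_phys, plan, med, session_end)
        sig = _spread_profile(t_phys, plan, med, session_end)
        noise = _ar1(rng, len(t_phys), 1.0, config.ar_coef_physio) * sig
        floor = 4.0 if channel == "rr" else 35.0  # physiological floors
        physio[channel] = np.maximum(base + noise, floor)
    physio_df = pd.DataFrame(physio)

    return SensorSession(profile=profile, env_stream=env_df, physio_stream=physio_df,
                         segment_plan=plan, time_of_day=config.time_of_day).validate()


# -- summary-level simulation (for statistical calibration studies) --------

def simulate_point_summaries(n_participants: int, seed: int,
                             channel: str = "co2",
                             point_offsets: dict | None = None,
                             between_sd: float = 30.0,
                             within_sd: float = 25.0,
                             base_level: float = 620.0) -> pd.DataFrame:
    """Simulate per-participant per-point summary values (one number per
    participant per static point), for power / type-I-error studies of the
    location test battery.

    Under the null every point shares ``base_level``; ``point_offsets``
    (label -> additive offset) injects location effects, e.g. the indoor
    CO2 excess at point A.  ``between_sd`` is a participant random effect,
    ``within_sd`` the residual.  Returns a participants x points DataFrame.
    """
    rng = np.random.default_rng(seed)
    offs = {lbl: 0.0 for lbl in STATIC_LABELS}
    offs.update(point_offsets or {})
    part = rng.normal(0.0, between_sd, size=(n_participants, 1))
    resid = rng.normal(0.0, within_sd, size=(n_participants, len(STATIC_LABELS)))
    level = np.array([base_level + offs[lbl] for lbl in STATIC_LABELS])
    data = level[None, :] + part + resid
    return pd.DataFrame(data, columns=list(STATIC_LABELS),
                        index=[f"S{i:02d}" for i in range(n_participants)])
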