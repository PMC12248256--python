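"""Exposure aggregation and inhaled-dose computation.

The dose metric (personal air pollution exposure, PAPE) is the product of
a time-aggregated concentration and minute ventilation:

    PAPE = SZ * V'm / 1000

where SZ is the trapezoidal time integral of the concentration over the
period (concentration x minutes) and V'm is converted from L/min to
m3/min.  For particulate matter in ug/m3 the dose comes out in ug; for
gases the dose stays in mixing-ratio volume units (ppm*m3 for CO2,
ppb*m3 for tVOC) — no conversion to mass is attempted.

The comparator "Standard Method" replaces personal data with a fixed
monitoring station's daily concentration and a sex-tabulated ventilation,
over the same 7 x 5 min static exposure window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import SegmentedChannel
from .ventilation import VentilationSeries, tabulated_vm

__all__ = [
    "MAX_GAP_MIN",
    "DOSE_POLLUTANTS",
    "StandardInputs",
    "ExposureTable",
    "aggregate_sz",
    "compute_pape",
    "compute_pape_series",
    "standard_dose",
    "session_exposure",
]

#: Eq.-style constraint on the aggregation: consecutive samples must be
#: closer than this, otherwise the trapezoid would bridge an unobserved gap.
MAX_GAP_MIN = 10.0

#: pollutants carried into dose tables (CO and NO2 are excluded: readings
#: are censored at the detection limit throughout the emulated campaign)
DOSE_POLLUTANTS = ("pm1", "pm2_5", "pm10", "co2", "tvoc")


@dataclass
class StandardInputs:
    """Inputs of the Standard Method: fixed-station daily concentrations
    (per pollutant), a tabulated ventilation, and the total static
    exposure duration (7 points x 5 min = 35 min by default)."""

    c_std: dict
    vm_std_lpm: float
    duration_min: float = 35.0

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.c_std.values()):
            raise ValueError("fixed-station concentrations must be non-negative")
        if self.vm_std_lpm <= 0 or self.duration_min <= 0:
            raise ValueError("ventilation and duration must be positive")

    @classmethod
    def for_sex(cls, sex_code: int, c_std: dict, duration_min: float = 35.0) -> "StandardInputs":
        return cls(c_std=c_std, vm_std_lpm=tabulated_vm(sex_code), duration_min=duration_min)


@dataclass
class ExposureTable:
    """Per-segment aggregated concentrations (SZ) and doses for one session.

    ``rows`` holds one record per (segment, pollutant) with columns
    ``segment, pollutant, duration_min, sz, pape``; SZ is concentration x
    minutes, PAPE is the dose.  ``id_new`` maps pollutant -> total dose
    over the static points (the wearable-system inhaled dose).
    """

    participant_id: str
    rows: pd.DataFrame
    id_new: dict = field(default_factory=dict)

    def total(self, pollutant: str = "pm2_5") -> float:
        """Session inhaled dose for one pollutant (static points only)."""
        return self.id_new[pollutant]

    def to_frame(self) -> pd.DataFrame:
        df = self.rows.copy()
        df.insert(0, "participant", self.participant_id)
        return df


def aggregate_sz(values, times_min) -> float:
    """Trapezoidal time-aggregation of a concentration series.

    ``times_min`` must be strictly increasing and expressed in minutes with
    every gap below 10 minutes; the result has units concentration x min.
    """
    z = np.asarray(values, dtype=float)
    t = np.asarray(times_min, dtype=float)
    if len(z) != len(t):
        raise ValueError("values and times must have equal length")
    if len(z) < 2:
        raise ValueError("need at least 2 samples to aggregate")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValueError("times must be strictly increasing")
    if np.any(dt >= MAX_GAP_MIN):
        raise ValueError(f"sampling gap of {dt.max():.1f} min violates the "
                         f"< {MAX_GAP_MIN:.0f} min aggregation constraint")
    return float(np.trapezoid(z, t))


def compute_pape(sz: float, vm_lpm: float) -> float:
    """Dose from an aggregated concentration and a constant ventilation.

    ``sz`` must come from minute-based aggregation; ``vm_lpm`` (L/min) is
    converted to m3/min internally.
    """
    if vm_lpm <= 0:
        raise ValueError("vm_lpm must be positive")
    return sz * (vm_lpm / 1000.0)


def compute_pape_series(values, vm_lpm, times_min) -> float:
    """Dose with time-varying ventilation: trapezoidal integral of
    Z(t) * V'm(t) / 1000 over minutes.  Degenerates to
    ``compute_pape(aggregate_sz(z, t), vm)`` when V'm is constant."""
    z = np.asarray(values, dtype=float)
    vm = np.broadcast_to(np.asarray(vm_lpm, dtype=float), z.shape)
    if np.any(vm <= 0):
        raise ValueError("ventilation must be positive everywhere")
    return aggregate_sz(z * vm / 1000.0, times_min)


def standard_dose(inputs: StandardInputs, pollutant: str = "pm2_5") -> float:
    """Standard Method dose: C_std x (V'm_std / 1000) x duration."""
    if pollutant not in inputs.c_std:
        raise KeyError(f"no fixed-station concentration for pollutant {pollutant!r}")
    return inputs.c_std[pollutant] * (inputs.vm_std_lpm / 1000.0) * inputs.duration_min


def _minute_means(arr: np.ndarray, spm: int) -> np.ndarray:
    """Collapse a node array (spm nodes/min, endpoint-inclusive grid) to
    per-minute means: nodes are binned by the minute their time falls in."""
    n = len(arr)
    duration_min = max(int(round(n / spm)), 1)
    # node k sits at time (k / (n-1)) * duration; bin by floor(minute)
    t_min = np.linspace(0.0, duration_min, n)
    bins = np.minimum(np.floor(t_min).astype(int), duration_min - 1)
    sums = np.bincount(bins, weights=arr, minlength=duration_min)
    counts = np.bincount(bins, minlength=duration_min)
    return sums / counts


def session_exposure(segments: dict, vm: VentilationSeries,
                     pollutants=DOSE_POLLUTANTS,
                     env_factor: str = "minute_means") -> ExposureTable:
    """Per-segment SZ and dose for one session's static points.

    ``env_factor`` selects how the concentration nodes of a 5-min dwell
    become the environmental factor:

    - ``"minute_means"`` (default): the nodes of each minute are averaged
      to one value per minute and SZ is the duration-weighted sum of those
      means (the trapezoidal integral of the minute-mean step profile over
      the full dwell), so a constant concentration c over T minutes gives
      exactly SZ = c*T.  Ventilation is collapsed the same way and the
      dose is the per-minute sum of z_mean * vm_mean / 1000.
    - ``"nodes"``: trapezoid directly on the node grid (spanning
      (n-1)/spm minutes, slightly less than the nominal dwell).

    ``id_new[pollutant]`` totals the static-point doses; dynamic transits
    carry no physiological data in the emulated protocol and are excluded.
    """
    if env_factor not in ("minute_means", "nodes"):
        raise ValueError(f"unknown env_factor mode {env_factor!r}")
    first = next(iter(segments.values()))
    spm = first.samples_per_minute
    static_keys = list(first.static_segments)
    records = []
    totals = {p: 0.0 for p in pollutants}
    for key in static_keys:
        if key not in vm.segments:
            raise KeyError(f"ventilation series lacks segment {key!r}")
        vm_nodes = np.asarray(vm.segments[key], dtype=float)
        for pol in pollutants:
            if pol not in segments:
                raise KeyError(f"missing segmented channel {pol!r}")
            seg = segments[pol]
            if key not in seg.static_segments:
                raise KeyError(f"channel {pol!r} lacks static segment {key!r}")
            z_nodes = np.asarray(seg.static_segments[key], dtype=float)
            if len(z_nodes) != len(vm_nodes):
                raise ValueError(f"node grids differ for segment {key!r}")
            if env_factor == "minute_means":
                z_m = _minute_means(z_nodes, spm)
                vm_m = _minute_means(vm_nodes, spm)
                duration = float(len(z_m))  # one mean per minute
                sz = float(z_m.sum())       # x 1 min each
                pape = float(np.sum(z_m * vm_m / 1000.0))
            else:
                t = np.linspace(0.0, (len(z_nodes) - 1) / spm, len(z_nodes))
                duration = float(t[-1])
                sz = aggregate_sz(z_nodes, t)
                pape = compute_pape_series(z_nodes, vm_nodes, t)
            records.append((key, pol, duration, sz, pape))
            totals[pol] += pape
    rows = pd.DataFrame(records, columns=["segment", "pollutant",
                                          "duration_min", "sz", "pape"])
    return ExposureTable(participant_id=vm.participant_id, rows=rows, id_new=totals)
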