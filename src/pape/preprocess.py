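"""Stream preprocessing: 1 Hz resampling, segmentation, length normalization.

The chain mirrors the comparative-analysis protocol of the walking study:
every environmental channel is linearly resampled to 1 Hz, the session is
cut on the arrive/leave timestamps of the seven static points into 7 static
+ 7 dynamic arrays, and each array is length-normalized by linear
interpolation onto an even grid of 3 samples per minute so that segments
are directly comparable across participants.

Physiological channels (10 Hz) pass through the same path after
block-averaging to 1 Hz, giving a single downstream representation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic import SensorSession

__all__ = [
    "UniformSeries",
    "SegmentedChannel",
    "resample_to_1hz",
    "segment",
    "normalize_length",
    "block_average",
    "preprocess_session",
    "segmented_to_frame",
]

log = logging.getLogger(__name__)

#: channels forwarded from a session into the segmented representation
DEFAULT_ENV_CHANNELS = ("pm1", "pm2_5", "pm10", "co2", "tvoc")
DEFAULT_PHYSIO_CHANNELS = ("pr", "rr")


@dataclass
class UniformSeries:
    """A uniformly sampled channel (values at ``start_ts + k / rate_hz``)."""

    start_ts: float
    rate_hz: float
    values: np.ndarray
    channel: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"non-finite values in series {self.channel!r}")

    @property
    def times(self) -> np.ndarray:
        return self.start_ts + np.arange(len(self.values)) / self.rate_hz

    @property
    def end_ts(self) -> float:
        return self.start_ts + (len(self.values) - 1) / self.rate_hz


@dataclass
class SegmentedChannel:
    """One channel cut into static (A..G) and dynamic (A->B ...) segments.

    After :func:`normalize_length` every static array holds
    ``dwell_minutes * samples_per_minute`` values (15 for the 5-minute
    dwells of the study protocol), so arrays are length-aligned across
    participants.
    """

    channel: str
    static_segments: dict = field(default_factory=dict)
    dynamic_segments: dict = field(default_factory=dict)
    samples_per_minute: int = 3
    #: duration (min) of each static segment, keyed like static_segments
    static_durations: dict = field(default_factory=dict)


def resample_to_1hz(timestamps, values, channel: str = "") -> UniformSeries:
    """Linearly resample an irregular record stream to 1 Hz.

    Output values sit at the integer seconds contained in
    ``[first_ts, last_ts]``; when the stream starts/ends on a whole second
    (the usual case for logger output) the endpoints are preserved exactly.
    """
    t = np.asarray(timestamps, dtype=float)
    v = np.asarray(values, dtype=float)
    if len(t) < 2:
        raise ValueError(f"channel {channel!r}: need at least 2 records to resample")
    if not np.all(np.diff(t) > 0):
        raise ValueError(f"channel {channel!r}: timestamps must be strictly increasing")
    gaps = np.diff(t)
    big = gaps > 3 * np.median(gaps)
    if big.any():
        log.warning("channel %s: %d sampling gap(s) above 3x the median period "
                    "(max %.1f s) bridged by linear interpolation",
                    channel, int(big.sum()), float(gaps.max()))
    start = math.ceil(t[0] - 1e-9)
    stop = math.floor(t[-1] + 1e-9)
    grid = np.arange(start, stop + 1, dtype=float)
    return UniformSeries(start_ts=float(start), rate_hz=1.0,
                         values=np.interp(grid, t, v), channel=channel)


def segment(series: UniformSeries, plan) -> tuple[dict, dict]:
    """Cut a uniform series on the segment plan.

    Returns ``(static, dynamic)``: static arrays are the samples with
    ``arrive <= t < leave`` (half-open, so adjacent segments never share a
    sample); dynamic arrays cover the gaps between consecutive static
    intervals plus the tail after the final point.
    """
    t = series.times
    static, dynamic = {}, {}
    labels = [p[0] for p in plan]
    for label, arrive, leave in plan:
        if arrive < series.start_ts - 1e-9 or leave > series.end_ts + 1 + 1e-9:
            raise ValueError(f"segment {label!r} [{arrive}, {leave}) outside series span "
                             f"[{series.start_ts}, {series.end_ts}]")
        static[label] = series.values[(t >= arrive) & (t < leave)]
    for i, (label, _, leave) in enumerate(plan):
        if i + 1 < len(plan):
            nxt_label, nxt_arrive = plan[i + 1][0], plan[i + 1][1]
        else:  # tail transit back towards the start of the loop
            nxt_label, nxt_arrive = "end", series.end_ts + 1.0
        dynamic[f"{label}->{nxt_label}"] = series.values[(t >= leave) & (t < nxt_arrive)]
    assert len(static) == len(labels)
    return static, dynamic


def normalize_length(values, rate_hz: float = 1.0,
                     samples_per_minute: int = 3) -> np.ndarray:
    """Resample one segment onto an even grid of ``samples_per_minute``.

    The output holds ``round(duration_minutes * samples_per_minute)`` nodes
    evenly spaced over the segment's time span, both endpoints included,
    values linearly interpolated.  Duration is ``len(values) / rate_hz``
    (the half-open segment window), so a 300-sample 1 Hz dwell maps to 15
    nodes.
    """
    v = np.asarray(values, dtype=float)
    if len(v) < 2:
        raise ValueError("cannot length-normalize a segment with fewer than 2 samples")
    duration_min = len(v) / rate_hz / 60.0
    n_out = int(round(duration_min * samples_per_minute))
    if n_out < 2:
        raise ValueError(f"segment too short: {duration_min:.2f} min at "
                         f"{samples_per_minute}/min yields {n_out} node(s)")
    t_in = np.arange(len(v)) / rate_hz
    t_out = np.linspace(0.0, t_in[-1], n_out)
    return np.interp(t_out, t_in, v)


def block_average(timestamps, values, block_s: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Average a fast stream into consecutive ``block_s`` windows.

    Used to bring 10 Hz physiological streams onto the 1 Hz grid before
    segmentation; block k covers ``[k*block_s, (k+1)*block_s)`` relative to
    the first timestamp and is stamped at its left edge.
    """
    t = np.asarray(timestamps, dtype=float)
    v = np.asarray(values, dtype=float)
    if len(t) < 2:
        raise ValueError("need at least 2 records")
    idx = np.floor((t - t[0]) / block_s).astype(int)
    n = idx[-1] + 1
    sums = np.bincount(idx, weights=v, minlength=n)
    counts = np.bincount(idx, minlength=n)
    keep = counts > 0
    out_t = t[0] + np.flatnonzero(keep) * block_s
    return out_t, sums[keep] / counts[keep]


def _segment_and_normalize(series: UniformSeries, plan, spm: int) -> SegmentedChannel:
    static_raw, dynamic_raw = segment(series, plan)
    out = SegmentedChannel(channel=series.channel, samples_per_minute=spm)
    for key, arr in static_raw.items():
        out.static_segments[key] = normalize_length(arr, series.rate_hz, spm)
        out.static_durations[key] = len(arr) / series.rate_hz / 60.0
    for key, arr in dynamic_raw.items():
        if len(arr) >= 2:
            out.dynamic_segments[key] = normalize_length(arr, series.rate_hz, spm)
        else:  # degenerate transit (e.g. back-to-back points): keep raw
            out.dynamic_segments[key] = np.asarray(arr, dtype=float)
    return out


def preprocess_session(session: SensorSession,
                       env_channels=DEFAULT_ENV_CHANNELS,
                       physio_channels=DEFAULT_PHYSIO_CHANNELS,
                       samples_per_minute: int = 3) -> dict:
    """Run the full chain on a session; returns {channel: SegmentedChannel}.

    Environmental channels are resampled to 1 Hz; physiological channels
    are block-averaged to 1 Hz first.  All channels then share the same
    segmentation and length normalization, so their node grids align.
    """
    out: dict[str, SegmentedChannel] = {}
    env_t = session.env_stream["timestamp"].to_numpy(float)
    for ch in env_channels:
        series = resample_to_1hz(env_t, session.env_stream[ch].to_numpy(float), ch)
        out[ch] = _segment_and_normalize(series, session.segment_plan, samples_per_minute)
    phys_t = session.physio_stream["timestamp"].to_numpy(float)
    for ch in physio_channels:
        bt, bv = block_average(phys_t, session.physio_stream[ch].to_numpy(float))
        series = resample_to_1hz(bt, bv, ch)
        out[ch] = _segment_and_normalize(series, session.segment_plan, samples_per_minute)
    return out


def segmented_to_frame(channels: dict, participant_id: str = "") -> pd.DataFrame:
    """Flatten {channel: SegmentedChannel} into a tidy frame
    (participant, channel, segment, kind, node_index, value)."""
    rows = []
    for name, seg in channels.items():
        for kind, d in (("static", seg.static_segments), ("dynamic", seg.dynamic_segments)):
            for key, arr in d.items():
                for i, val in enumerate(np.asarray(arr, dtype=float)):
                    rows.append((participant_id, name, key, kind, i, val))
    return pd.DataFrame(rows, columns=["participant", "channel", "segment",
                                       "kind", "node_index", "value"])
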