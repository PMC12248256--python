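"""Minute-ventilation estimation.

Personalized minute ventilation (V'm, L/min) comes from a published
power-law model driven by heart rate (the wrist pulse rate is used as its
proxy), respiratory rate, age, sex and forced vital capacity:

    V'm = exp(-8.75) * HR^1.72 * RR^0.611 * age^0.298 * sex^(-0.206) * FVC^0.614

with sex coded 1 for men and 2 for women.  The comparator ("Standard
Method") instead uses sex-tabulated values for a light activity level
(METs ~2-4): 15.14 L/min for men, 13.26 L/min for women.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocess import SegmentedChannel
from .synthetic import ParticipantProfile

__all__ = [
    "VM_COEFFS",
    "TABULATED_VM_LPM",
    "VentilationSeries",
    "compute_vm",
    "vm_series",
    "tabulated_vm",
]

#: (intercept on the log scale, and exponents of HR, RR, age, sex, FVC)
VM_COEFFS = {"intercept": -8.75, "hr": 1.72, "rr": 0.611,
             "age": 0.298, "sex": -0.206, "fvc": 0.614}

#: sex-tabulated minute ventilation (L/min) for activity level 3
TABULATED_VM_LPM = {1: 15.14, 2: 13.26}


@dataclass
class VentilationSeries:
    """Per-segment minute-ventilation nodes for one participant.

    ``segments`` maps a segment key to an array of V'm values (L/min) on
    the same node grid as the segmented concentration channels.
    ``source`` is ``"model"`` (power law) or ``"tabulated"``.
    """

    participant_id: str
    segments: dict = field(default_factory=dict)
    samples_per_minute: int = 3
    source: str = "model"

    def __post_init__(self) -> None:
        for key, arr in self.segments.items():
            if np.any(np.asarray(arr, dtype=float) <= 0):
                raise ValueError(f"non-positive V'm in segment {key!r}")


def compute_vm(hr, rr, age, sex_code, fvc):
    """Minute ventilation (L/min) from the power-law model.

    Accepts scalars or arrays for ``hr`` and ``rr``.  All inputs must be
    strictly positive (the power law is undefined otherwise) and
    ``sex_code`` must be 1 (man) or 2 (woman).
    """
    hr = np.asarray(hr, dtype=float)
    rr = np.asarray(rr, dtype=float)
    if np.any(hr <= 0) or np.any(rr <= 0):
        raise ValueError("hr and rr must be strictly positive")
    if age <= 0 or fvc <= 0:
        raise ValueError("age and fvc must be strictly positive")
    if int(sex_code) not in (1, 2):
        raise ValueError(f"sex_code must be 1 or 2, got {sex_code}")
    c = VM_COEFFS
    out = (np.exp(c["intercept"]) * hr ** c["hr"] * rr ** c["rr"]
           * age ** c["age"] * float(sex_code) ** c["sex"] * fvc ** c["fvc"])
    return out if out.ndim else float(out)


def vm_series(pr: SegmentedChannel, rr: SegmentedChannel,
              profile: ParticipantProfile, static_only: bool = True,
              per_segment_median: bool = False) -> VentilationSeries:
    """Evaluate the model at every node of matched PR/RR segments.

    The pulse-rate and respiratory-rate channels must share segment keys
    and per-segment node counts (they do when produced by the same
    preprocessing run).  With ``per_segment_median=True`` each segment is
    collapsed to the V'm of its median PR and RR (a coarser sensitivity
    mode); the default evaluates node-wise.
    """
    keys = list(pr.static_segments)
    if not static_only:
        keys += list(pr.dynamic_segments)
    out = VentilationSeries(participant_id=profile.participant_id,
                            samples_per_minute=pr.samples_per_minute, source="model")
    for key in keys:
        p = pr.static_segments.get(key, pr.dynamic_segments.get(key))
        r = rr.static_segments.get(key, rr.dynamic_segments.get(key))
        if r is None or len(r) != len(p):
            raise ValueError(f"PR/RR node grids differ for segment {key!r}")
        if per_segment_median:
            vm = np.full(len(p), compute_vm(np.median(p), np.median(r),
                                            profile.age, profile.sex_code, profile.fvc))
        else:
            vm = compute_vm(p, r, profile.age, profile.sex_code, profile.fvc)
        out.segments[key] = vm
    return out


def tabulated_vm(sex_code: int) -> float:
    """Sex-tabulated minute ventilation (L/min) for the Standard Method."""
    try:
        return TABULATED_VM_LPM[int(sex_code)]
    except (KeyError, ValueError, TypeError):
        raise ValueError(f"sex_code must be 1 (man) or 2 (woman), got {sex_code!r}") from None
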