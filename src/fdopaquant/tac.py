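"""Dynamic-frame handling, decay correction, SUV normalization and VOI extraction.

A dynamic PET acquisition is histogrammed into contiguous time frames; every
regional quantity downstream (Patlak transform included) is computed on the
frame mid-times.  The default framing is the 90-min, 41-frame scheme
``6x10,6x30,11x60,15x180,3x600`` (counts x seconds).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "F18_HALF_LIFE_MIN",
    "DEFAULT_FRAMING",
    "FramingScheme",
    "TimeActivityCurve",
    "DoseInfo",
    "SUVCurve",
    "build_framing",
    "decay_correct",
    "decay_uncorrect",
    "to_suv",
    "extract_voi_tac",
]

#: Physical half-life of fluorine-18 in minutes.
F18_HALF_LIFE_MIN = 109.77

#: 41-frame, 90-min dynamic scheme used throughout as the default acquisition.
DEFAULT_FRAMING = "6x10,6x30,11x60,15x180,3x600"

_FRAME_SPEC_RE = re.compile(r"^\s*(\d+)\s*[x×]\s*(\d+(?:\.\d+)?)\s*$")


@dataclass(frozen=True)
class FramingScheme:
    """Ordered, contiguous list of dynamic frames.

    Parameters
    ----------
    starts_s, durations_s
        Frame start times and durations in seconds.  Frames must tile the
        acquisition: the first frame starts at 0 and each subsequent frame
        starts where the previous one ends.
    """

    starts_s: tuple[float, ...]
    durations_s: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.starts_s) != len(self.durations_s) or not self.starts_s:
            raise ValueError("starts and durations must be non-empty and equal length")
        if self.starts_s[0] != 0:
            raise ValueError("first frame must start at t=0")
        if any(d <= 0 for d in self.durations_s):
            raise ValueError("frame durations must be positive")
        for i in range(1, len(self.starts_s)):
            expected = self.starts_s[i - 1] + self.durations_s[i - 1]
            if not math.isclose(self.starts_s[i], expected, rel_tol=0, abs_tol=1e-9):
                raise ValueError(
                    f"frames must be contiguous: frame {i} starts at "
                    f"{self.starts_s[i]} s, expected {expected} s"
                )

    @property
    def n_frames(self) -> int:
        return len(self.starts_s)

    @property
    def total_duration_s(self) -> float:
        return self.starts_s[-1] + self.durations_s[-1]

    @property
    def mid_times_min(self) -> np.ndarray:
        """Frame mid-times in minutes post-injection."""
        s = np.asarray(self.starts_s, dtype=float)
        d = np.asarray(self.durations_s, dtype=float)
        return (s + d / 2.0) / 60.0

    @property
    def edges_min(self) -> np.ndarray:
        """Frame boundary times (length ``n_frames + 1``) in minutes."""
        s = np.asarray(self.starts_s, dtype=float)
        return np.concatenate([s, [self.total_duration_s]]) / 60.0

    @property
    def durations_min(self) -> np.ndarray:
        return np.asarray(self.durations_s, dtype=float) / 60.0


def build_framing(spec_string: str) -> FramingScheme:
    """Expand a compact ``"count x seconds"`` list into a :class:`FramingScheme`.

    ``"6x10,6x30,11x60,15x180,3x600"`` yields 41 contiguous frames totalling
    5400 s (90 min).

    Raises
    ------
    ValueError
        On malformed items, zero counts or non-positive durations.
    """
    durations: list[float] = []
    items = [s for s in spec_string.split(",") if s.strip()]
    if not items:
        raise ValueError(f"empty framing spec: {spec_string!r}")
    for item in items:
        m = _FRAME_SPEC_RE.match(item)
        if m is None:
            raise ValueError(f"malformed framing item {item!r} (expected 'COUNTxSECONDS')")
        count, dur = int(m.group(1)), float(m.group(2))
        if count == 0:
            raise ValueError(f"zero frame count in {item!r}")
        if dur <= 0:
            raise ValueError(f"non-positive frame duration in {item!r}")
        durations.extend([dur] * count)
    starts = [0.0]
    for d in durations[:-1]:
        starts.append(starts[-1] + d)
    return FramingScheme(tuple(starts), tuple(durations))


@dataclass(frozen=True)
class TimeActivityCurve:
    """Per-frame mean activity concentration for one region.

    ``values`` are in kBq/mL (or arbitrary concentration units, as long as
    target and reference share them — the Patlak slope is invariant to a
    common scale).
    """

    scheme: FramingScheme
    values: np.ndarray
    decay_corrected: bool = False
    region: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size != self.scheme.n_frames:
            raise ValueError(
                f"values length {v.size} does not match scheme with "
                f"{self.scheme.n_frames} frames"
            )
        object.__setattr__(self, "values", v)

    @property
    def mid_times_min(self) -> np.ndarray:
        return self.scheme.mid_times_min


@dataclass(frozen=True)
class DoseInfo:
    """Injected activity (MBq, at injection time) and body weight (g)."""

    injected_activity_mbq: float
    body_weight_g: float

    def __post_init__(self) -> None:
        if self.injected_activity_mbq <= 0 or self.body_weight_g <= 0:
            raise ValueError("injected activity and body weight must be positive")


@dataclass(frozen=True)
class SUVCurve:
    """Unitless standardized-uptake-value curve."""

    scheme: FramingScheme
    values: np.ndarray
    region: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.size != self.scheme.n_frames:
            raise ValueError("values length does not match scheme")
        object.__setattr__(self, "values", v)


def _decay_factors(
    scheme: FramingScheme, half_life_min: float, reference_time_min: float
) -> np.ndarray:
    if half_life_min <= 0:
        raise ValueError("half-life must be positive")
    t = scheme.mid_times_min
    return np.exp(math.log(2.0) * (t - reference_time_min) / half_life_min)


def decay_correct(
    tac: TimeActivityCurve,
    half_life_min: float = F18_HALF_LIFE_MIN,
    reference_time_min: float = 0.0,
) -> TimeActivityCurve:
    """Correct measured frame activities for physical decay.

    Each frame value is multiplied by ``2**((t_mid - t_ref)/T_half)`` so that
    all frames are expressed at the activity scale of ``reference_time_min``
    (default: injection time, which coincides with scan start).
    """
    if tac.decay_corrected:
        raise ValueError("TAC is already decay-corrected")
    f = _decay_factors(tac.scheme, half_life_min, reference_time_min)
    return replace(tac, values=tac.values * f, decay_corrected=True)


def decay_uncorrect(
    tac: TimeActivityCurve,
    half_life_min: float = F18_HALF_LIFE_MIN,
    reference_time_min: float = 0.0,
) -> TimeActivityCurve:
    """Inverse of :func:`decay_correct` (restores as-measured activities)."""
    if not tac.decay_corrected:
        raise ValueError("TAC is not decay-corrected")
    f = _decay_factors(tac.scheme, half_life_min, reference_time_min)
    return replace(tac, values=tac.values / f, decay_corrected=False)


def to_suv(tac: TimeActivityCurve, dose: DoseInfo) -> SUVCurve:
    """Normalize a decay-corrected TAC to standardized uptake value.

    SUV(t) = C(t) [kBq/mL] * body weight [g] / injected activity [kBq],
    assuming tissue density 1 g/mL.  A uniform whole-body distribution of the
    dose therefore maps to SUV 1.
    """
    if not tac.decay_corrected:
        raise ValueError("SUV conversion requires a decay-corrected TAC")
    injected_kbq = dose.injected_activity_mbq * 1000.0
    return SUVCurve(tac.scheme, tac.values * dose.body_weight_g / injected_kbq, tac.region)


def extract_voi_tac(phantom, label: int) -> TimeActivityCurve:
    """Mean time-activity curve over all voxels carrying ``label``.

    ``phantom`` is any object exposing ``frames`` (4D array, time last),
    ``mask`` (3D integer array on the same grid) and ``scheme``.  The VOI mean
    is the plain unweighted arithmetic mean per frame.

    Raises
    ------
    ValueError
        If the label is absent from the mask.
    """
    mask = np.asarray(phantom.mask)
    sel = mask == label
    n = int(sel.sum())
    if n == 0:
        raise ValueError(f"label {label} not present in mask")
    frames = np.asarray(phantom.frames, dtype=float)
    values = frames[sel].mean(axis=0)
    return TimeActivityCurve(
        phantom.scheme, values, decay_corrected=True, region=f"label{label}"
    )
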