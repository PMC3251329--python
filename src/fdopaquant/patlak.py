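"""Reference-tissue Patlak graphical analysis.

For a tracer that is irreversibly trapped in the target tissue, plotting

    y(t) = C_tissue(t) / C_ref(t)    against    x(t) = int_0^t C_ref(u) du / C_ref(t)

becomes linear once the free compartment has equilibrated; the slope of the
late-time line is the net influx constant K_i (1/min) and the intercept the
initial distribution volume V.  The reference region (cerebellum for FDOPA)
must be devoid of specific trapping — its activity replaces the arterial
plasma input.

Conventions (recorded in all output metadata): frame mid-times represent
frames; the running integral is the trapezoidal rule on mid-times with an
initial triangle from the origin; the fit window is a closed interval on
mid-times; ordinary (unweighted) least squares.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as _st

from .tac import TimeActivityCurve

__all__ = [
    "DEFAULT_WINDOW_MIN",
    "PatlakPoints",
    "PatlakResult",
    "cumulative_trapezoid_from_origin",
    "patlak_transform",
    "fit_patlak",
    "ki_ratio",
]

#: Default fit window in minutes post-injection.
DEFAULT_WINDOW_MIN = (10.0, 60.0)


def cumulative_trapezoid_from_origin(times: np.ndarray, values: np.ndarray) -> np.ndarray:
    """Running trapezoidal integral of ``values`` over ``times``, anchored at 0.

    The first segment is the triangle from (0, 0) to the first sample — the
    curve is a bolus response that rises from zero, so this is the natural
    closure of the quadrature at the origin.  The synthetic exact-identity
    generator shares this rule, which is what makes its round trips exact.
    """
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    out = np.empty_like(v)
    out[0] = 0.5 * t[0] * v[0]
    if v.size > 1:
        out[1:] = out[0] + np.cumsum(0.5 * (v[1:] + v[:-1]) * np.diff(t))
    return out


@dataclass(frozen=True)
class PatlakPoints:
    """Transformed coordinates of the Patlak plot.

    ``x`` is the normalized ("stretched") time in minutes, ``y`` the unitless
    tissue/reference ratio; ``mid_times_min`` keeps the source frame mid-times
    so the fit window can be applied in real time.
    """

    x: np.ndarray
    y: np.ndarray
    mid_times_min: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.x) == len(self.y) == len(self.mid_times_min)):
            raise ValueError("x, y and mid_times_min must have equal length")


@dataclass(frozen=True)
class PatlakResult:
    """Slope/intercept of the Patlak fit with diagnostics.

    ``ki`` is the influx constant (1/min), ``v`` the initial distribution
    volume (unitless); ``window_min`` is the closed mid-time interval used.
    """

    ki: float
    v: float
    r_squared: float
    n_points: int
    window_min: tuple[float, float]

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ValueError("a Patlak fit needs at least 2 points")
        if not self.window_min[0] < self.window_min[1]:
            raise ValueError("window start must precede window end")


def patlak_transform(
    target: TimeActivityCurve, reference: TimeActivityCurve
) -> PatlakPoints:
    """Map a (target, reference) TAC pair to Patlak coordinates.

    Raises
    ------
    ValueError
        If framing schemes differ, or the reference is not strictly positive
        (the transform divides by it); the offending frame is named.
    """
    if target.scheme != reference.scheme:
        raise ValueError("target and reference TACs must share a framing scheme")
    ref = reference.values
    bad = np.flatnonzero(ref <= 0)
    if bad.size:
        raise ValueError(
            f"reference TAC must be strictly positive; frame {bad[0]} "
            f"has value {ref[bad[0]]:g}"
        )
    t = target.scheme.mid_times_min
    x = cumulative_trapezoid_from_origin(t, ref) / ref
    y = target.values / ref
    return PatlakPoints(x=x, y=y, mid_times_min=t)


def fit_patlak(
    points: PatlakPoints,
    window_min: tuple[float, float] = DEFAULT_WINDOW_MIN,
) -> PatlakResult:
    """Ordinary least squares of y on x over frames whose mid-time lies in
    the closed interval ``window_min``.

    Raises
    ------
    ValueError
        If fewer than 2 frame mid-times fall inside the window.
    """
    lo, hi = float(window_min[0]), float(window_min[1])
    if not lo < hi:
        raise ValueError("window start must precede window end")
    sel = (points.mid_times_min >= lo) & (points.mid_times_min <= hi)
    n = int(sel.sum())
    if n < 2:
        raise ValueError(
            f"Patlak window [{lo}, {hi}] min contains {n} frame mid-times; need >= 2"
        )
    res = _st.linregress(points.x[sel], points.y[sel])
    return PatlakResult(
        ki=float(res.slope),
        v=float(res.intercept),
        r_squared=float(res.rvalue) ** 2,
        n_points=n,
        window_min=(lo, hi),
    )


def ki_ratio(ipsi, contra) -> float:
    """Ipsilateral/contralateral influx ratio in percent, 100 * Ki_R / Ki_L.

    Accepts :class:`PatlakResult` objects or bare K_i floats.  The
    contralateral (intact-side) K_i must be positive.
    """
    ki_i = float(getattr(ipsi, "ki", ipsi))
    ki_c = float(getattr(contra, "ki", contra))
    if ki_c <= 0:
        raise ValueError("contralateral K_i must be positive")
    return 100.0 * ki_i / ki_c
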