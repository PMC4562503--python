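"""Three-stage linear-system impulse response and its offset calibration.

The persistence trace is modelled as the impulse response of three cascaded
first-order (leaky-integrator) stages with distinct decay rates a, b, c
(per second):

    f(t) = D * [ (c - b) e^{-a t} + (b - a) e^{-c t} - (c - a) e^{-b t} ]

with D = D(a, b, c) a norming constant chosen so that max_t f(t) = 1.  Up to
normalization this is the hypoexponential density (the distribution of a sum
of three independent exponential stage delays), hence f(t) >= 0, f(0) = 0,
a single interior peak, and a strictly decreasing tail.

Calibration: a single constraint -- the normalized response first falls
through an offset threshold (default 0.01) at a target time t_off -- cannot
pin down both free rates b and c, so c is tied to b by a fixed ratio
(default c = 1.2 b) and b is solved for by bracketing/bisection.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy import optimize

__all__ = [
    "DecayParams",
    "impulse_response",
    "normalize",
    "calibrate_offset",
    "persistence_duration",
]

_REL_DISTINCT = 1e-9  # relative tolerance below which rates count as coincident


@dataclass(frozen=True)
class DecayParams:
    """Rates of the three stages plus normalization/calibration metadata.

    ``norm_const`` scales the raw response; after :func:`normalize` the peak
    of the scaled response is 1 and ``peak_time_s`` records where.  After
    :func:`calibrate_offset`, ``offset_threshold`` and ``t_off_s`` record the
    calibration target actually met.
    """

    a_rate: float
    b_rate: float
    c_rate: float
    norm_const: float = 1.0
    peak_time_s: Optional[float] = None
    offset_threshold: Optional[float] = None
    t_off_s: Optional[float] = None

    def __post_init__(self) -> None:
        rates = (self.a_rate, self.b_rate, self.c_rate)
        if any(r <= 0 or not np.isfinite(r) for r in rates):
            raise ValueError(f"decay rates must be positive and finite, got {rates}")
        pairs = [(self.a_rate, self.b_rate), (self.a_rate, self.c_rate),
                 (self.b_rate, self.c_rate)]
        for x, y in pairs:
            if abs(x - y) <= _REL_DISTINCT * max(x, y):
                raise ValueError(
                    f"decay rates must be pairwise distinct; got {rates} "
                    "(the closed form degenerates for coincident rates)"
                )

    @property
    def is_normalized(self) -> bool:
        return self.peak_time_s is not None


def _raw(t: np.ndarray, a: float, b: float, c: float) -> np.ndarray:
    return ((c - b) * np.exp(-a * t)
            + (b - a) * np.exp(-c * t)
            - (c - a) * np.exp(-b * t))


def impulse_response(t, p: DecayParams):
    """Evaluate norm_const * raw response at time(s) t (seconds, t >= 0)."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    out = p.norm_const * _raw(t, p.a_rate, p.b_rate, p.c_rate)
    return float(out) if out.ndim == 0 else out


def _find_peak(a: float, b: float, c: float) -> tuple[float, float]:
    """Peak time and signed raw extremum, by 1-ms grid scan plus refinement.

    The closed form is antisymmetric under reordering the rates, so the raw
    response may be single-signed negative; the extremum of |f| is located and
    returned with its sign (renormalization cancels the sign).
    """
    # the slowest stage bounds how far out the peak can sit
    t_max = 10.0 / min(a, b, c)
    grid = np.arange(0.0, t_max, 1e-3)
    vals = np.abs(_raw(grid, a, b, c))
    i = int(np.argmax(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(
        lambda t: -abs(_raw(t, a, b, c)), bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-12},
    )
    return float(res.x), float(_raw(res.x, a, b, c))


def normalize(p: DecayParams) -> DecayParams:
    """Return params with norm_const set so the peak response equals 1."""
    t_peak, v_peak = _find_peak(p.a_rate, p.b_rate, p.c_rate)
    if v_peak == 0 or not np.isfinite(v_peak):
        raise ValueError("response has degenerate peak; rates invalid")
    return replace(p, norm_const=1.0 / v_peak, peak_time_s=t_peak)


def _crossing_time(p: DecayParams, threshold: float) -> float:
    """First time after the peak at which the normalized response < threshold."""
    if not p.is_normalized:
        raise ValueError("params must be normalized first")
    if not (0 < threshold <= 1):
        raise ValueError(
            "threshold must be in (0, 1]; the tail is a sum of decaying "
            "exponentials and only reaches 0 asymptotically"
        )
    if threshold == 1.0:
        return p.peak_time_s
    # march outward from the peak until below threshold, then refine
    t_lo = p.peak_time_s
    step = max(p.peak_time_s, 1e-3)
    t_hi = t_lo + step
    for _ in range(200):
        if impulse_response(t_hi, p) < threshold:
            break
        t_lo = t_hi
        t_hi += step
        step *= 1.5
    else:  # pragma: no cover - tail always decays to 0
        raise RuntimeError("failed to bracket the threshold crossing")
    return float(optimize.brentq(
        lambda t: impulse_response(t, p) - threshold, t_lo, t_hi, xtol=1e-12))


def calibrate_offset(
    a_rate: float = 50.0,
    t_off: float = 0.6,
    threshold: float = 0.01,
    rate_ratio: float = 1.2,
    *,
    b_bracket: tuple[float, float] | None = None,
) -> DecayParams:
    """Solve for b (with c = rate_ratio * b) so the normalized response first
    falls through ``threshold`` exactly at ``t_off`` seconds.

    Returns calibrated, peak-normalized parameters.  Raises if no b in the
    bracket produces a crossing at t_off (with diagnostics).
    """
    if a_rate <= 0:
        raise ValueError("a_rate must be positive")
    if t_off <= 0:
        raise ValueError("t_off must be positive")
    if not (0 < threshold < 1):
        raise ValueError("threshold must be in (0, 1)")
    if rate_ratio <= 0 or abs(rate_ratio - 1.0) < 1e-9:
        raise ValueError("rate_ratio must be positive and != 1")

    def params_for(b: float) -> DecayParams:
        # nudge b off the degenerate lines b = a and ratio*b = a
        for bad in (a_rate, a_rate / rate_ratio):
            if abs(b - bad) <= 1e-7 * bad:
                b = bad * (1 + 2e-7)
        return normalize(DecayParams(a_rate, b, rate_ratio * b))

    def gap(b: float) -> float:
        return _crossing_time(params_for(b), threshold) - t_off

    if b_bracket is not None:
        segments = [b_bracket]
    else:
        # the crossing time is decreasing in b on each segment between the
        # degenerate rate coincidences, so search the segments in turn
        delta = 1e-4 * a_rate
        cuts = sorted({a_rate, a_rate / rate_ratio})
        edges = [1e-3]
        for cut in cuts:
            edges += [cut - delta, cut + delta]
        edges.append(100.0 * a_rate)
        segments = [(edges[i], edges[i + 1]) for i in range(0, len(edges), 2)]

    gaps = {}
    for lo, hi in segments:
        if hi <= lo:
            continue
        g_lo = gaps.setdefault(lo, gap(lo))
        g_hi = gaps.setdefault(hi, gap(hi))
        if g_lo == 0.0 or g_hi == 0.0:
            b = lo if g_lo == 0.0 else hi
            break
        if g_lo * g_hi < 0:
            b = float(optimize.brentq(gap, lo, hi, xtol=1e-12, rtol=1e-14))
            break
    else:
        diag = {f"gap({k:.4g})": f"{v:.4g} s" for k, v in gaps.items()}
        raise RuntimeError(
            f"no b produces a crossing at t_off={t_off} s (threshold="
            f"{threshold}, ratio={rate_ratio}, a={a_rate}/s); bracket "
            f"diagnostics: {diag}"
        )
    p = params_for(b)
    return replace(p, offset_threshold=threshold, t_off_s=t_off)


def persistence_duration(p: DecayParams, criterion: float) -> float:
    """First time (s) after the peak at which the normalized response falls
    below ``criterion``; criterion = 1 returns the peak time itself."""
    if not p.is_normalized:
        raise ValueError("persistence_duration requires normalized params")
    if not (0 < criterion <= 1):
        raise ValueError("criterion must be in (0, 1]")
    if criterion == 1.0:
        return p.peak_time_s
    if p.offset_threshold is not None and criterion == p.offset_threshold:
        return p.t_off_s
    return _crossing_time(p, criterion)
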