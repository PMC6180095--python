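"""Height-velocity conversion and critical fall height of a surfacing.

The critical height of a playground surface is the highest drop height from
which it still meets the impact-attenuation performance criterion
(HIC = 1000 for the hemispherical missile).  It is found by simulating
headform drops from a ladder of heights, pairing each with its HIC, and
bisecting the monotone height-HIC response.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

from .constants import GRAVITY, HIC_FILTER_HZ, HIC_LIMIT
from .errors import BracketError, InvalidParameterError
from .signal_metrics import HICResult, butterworth_filtfilt, hic
from .surface_model import DropResult, Headform, HystereticMaterial, SurfaceLayer, simulate_drop

__all__ = [
    "CriticalHeightResult",
    "height_to_velocity",
    "velocity_to_height",
    "drop_hic",
    "find_critical_height",
]


def height_to_velocity(h: float) -> float:
    """Free-fall impact velocity from height ``h``: v = sqrt(2 g h), m/s."""
    if h < 0:
        raise InvalidParameterError(f"height must be >= 0, got {h}")
    return math.sqrt(2.0 * GRAVITY * h)


def velocity_to_height(v: float) -> float:
    """Free-fall height giving impact velocity ``v``: h = v^2 / (2 g), m."""
    if v < 0:
        raise InvalidParameterError(f"velocity must be >= 0, got {v}")
    return v * v / (2.0 * GRAVITY)


@dataclass(frozen=True)
class CriticalHeightResult:
    """Critical height with the HIC achieved there and search diagnostics."""

    height: float
    hic_at_height: float
    iterations: int
    bracket: tuple[float, float]


def drop_hic(
    mat: HystereticMaterial,
    head: Headform,
    layer: SurfaceLayer,
    drop_height: float,
    dt: float = 1e-6,
    output_dt: float = 5e-5,
) -> tuple[HICResult, DropResult]:
    """One standard-procedure evaluation: drop, 2077.5 Hz filtfilt, HIC.

    The acceleration trace is produced on a 20 kHz output grid (well above
    the 2077.5 Hz cutoff) to keep the exact pair-scan HIC cheap.
    """
    res = simulate_drop(head, layer, mat, drop_height=drop_height, dt=dt, output_dt=output_dt)
    filtered = butterworth_filtfilt(res.accel, HIC_FILTER_HZ)
    return hic(filtered), res


def find_critical_height(
    mat: HystereticMaterial,
    head: Headform,
    layer: SurfaceLayer,
    hic_target: float = HIC_LIMIT,
    tol_m: float = 0.005,
    hic_fn: Callable[[float], float] | None = None,
    start_height: float = 0.5,
    max_expansions: int = 8,
    dt: float = 1e-6,
    output_dt: float = 5e-5,
) -> CriticalHeightResult:
    """Bisection for the height at which the drop-test HIC hits the target.

    The high bracket end grows geometrically from ``start_height`` until its
    HIC exceeds the target (and the low end shrinks likewise if needed);
    monotonicity over the bracket is checked on its ends.  ``hic_fn`` may
    replace the full drop+filter+HIC pipeline (e.g. for stubbing).

    Raises
    ------
    BracketError
        If the response cannot bracket the target or is not increasing over
        the bracket; the probed (height, HIC) pairs are reported.
    """
    if not tol_m > 0:
        raise InvalidParameterError("tol_m must be > 0")

    if hic_fn is None:
        def hic_fn(h: float) -> float:
            return drop_hic(mat, head, layer, h, dt=dt, output_dt=output_dt)[0].value

    probed: list[tuple[float, float]] = []

    def f(h: float) -> float:
        val = hic_fn(h)
        probed.append((h, val))
        return val

    evals = 0
    h_hi = start_height
    f_hi = f(h_hi)
    evals += 1
    h_lo, f_lo = 0.0, 0.0
    if f_hi < hic_target:
        h_lo, f_lo = h_hi, f_hi
        for _ in range(max_expansions):
            h_hi *= 2.0
            f_hi = f(h_hi)
            evals += 1
            if f_hi >= hic_target:
                break
            h_lo, f_lo = h_hi, f_hi
        else:
            raise BracketError(
                f"HIC never exceeded {hic_target:g} up to {h_hi:g} m; probed {probed}"
            )
    else:
        for _ in range(max_expansions):
            h_lo = h_hi / 2.0
            f_lo = f(h_lo)
            evals += 1
            if f_lo < hic_target:
                break
            h_hi, f_hi = h_lo, f_lo
        else:
            raise BracketError(
                f"HIC stayed above {hic_target:g} down to {h_lo:g} m; probed {probed}"
            )

    if not f_lo < f_hi:
        raise BracketError(
            f"height-HIC response not increasing over bracket ({h_lo:g}, {h_hi:g}); "
            f"probed {probed}"
        )

    f_mid = f_hi
    h_mid = h_hi
    while h_hi - h_lo > tol_m:
        h_mid = 0.5 * (h_lo + h_hi)
        f_mid = f(h_mid)
        evals += 1
        if f_mid < hic_target:
            h_lo = h_mid
        else:
            h_hi = h_mid

    return CriticalHeightResult(
        height=h_mid,
        hic_at_height=f_mid,
        iterations=evals,
        bracket=(h_lo, h_hi),
    )
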