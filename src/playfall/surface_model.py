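"""Reduced-order headform drop onto hysteretic rubber surfacing.

A rigid hemispherical headform (the 4.6 kg missile of the impact-attenuation
standard) is dropped onto a rubber-composite tile modelled as a single degree
of freedom: indentation ``x`` of the headform into a layer of thickness
``h``.  The layer pushes back with

    F(x) = scale * sigma(x / h) * A(x),        A(x) = min(pi (2 R x - x^2), A_cap)

where ``sigma`` is the material's uniaxial loading stress-strain curve
(linear interpolation, linear extrapolation of the last segment) and ``A``
the spherical-cap contact area.  Unloading is hysteretic: the force is
multiplied by

    s = 1 - (1 - hu) * (1 - W / W_max)^shape

with ``W`` the strain energy stored at the current indentation and ``W_max``
its running maximum since first contact.  ``s`` is 1 at the unloading onset
(force continuity) and tends to the hysteretic-unloading factor ``hu`` as the
layer relaxes, so ``hu`` is the fraction of force retained at full unload and
``shape`` controls the curvature of the hysteresis loop (defaults 0.5 and
2.0, the values used for rubber playground tiles).  Reloading before
separation follows the same energy-based scale back up until the stored
energy re-attains ``W_max``.

The equation of motion  m x'' = m g - F(x, x')  is integrated from first
contact with classical fixed-step 4th-order Runge-Kutta until the headform
separates (x back to 0 while moving upward).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .constants import GRAVITY
from .errors import (
    BottomOutError,
    CalibrationError,
    DivergenceError,
    InvalidParameterError,
)
from .signal_metrics import UniformSignal

__all__ = [
    "MaterialCurve",
    "HystereticMaterial",
    "Headform",
    "SurfaceLayer",
    "ContactState",
    "DropResult",
    "scale_material",
    "contact_force",
    "simulate_drop",
    "calibrate_scale",
    "baseline_material",
]

# Parametric baseline loading curve sigma(eps) = E1*eps + E3*eps^3, Pa.
# Chosen so that the default geometry below gives a critical height
# (HIC = 1000) near 1.59 m, the value a standard playground tile meets.
BASELINE_E1 = 0.24e6
BASELINE_E3 = 2.7e6

#: Default surfacing-layer thickness, m (a thick rubber tile).
DEFAULT_THICKNESS = 0.10
#: Default headform radius, m.
DEFAULT_RADIUS = 0.08
#: Default headform mass, kg (hemispherical missile of the testing standard).
DEFAULT_MASS = 4.6

#: Resolution of the precomputed force/energy lookup grid.
_GRID_POINTS = 2048


@dataclass(frozen=True)
class MaterialCurve:
    """Uniaxial loading stress-strain curve starting at (0, 0).

    ``strain`` must be strictly increasing and ``stress`` (Pa)
    non-decreasing.
    """

    strain: np.ndarray
    stress: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "strain", np.asarray(self.strain, dtype=float))
        object.__setattr__(self, "stress", np.asarray(self.stress, dtype=float))
        if self.strain.ndim != 1 or self.strain.size < 2 or self.stress.shape != self.strain.shape:
            raise InvalidParameterError("curve needs >= 2 matching (strain, stress) points")
        if self.strain[0] != 0.0 or self.stress[0] != 0.0:
            raise InvalidParameterError("loading curve must start at (0, 0)")
        if not np.all(np.diff(self.strain) > 0):
            raise InvalidParameterError("strain must be strictly increasing")
        if np.any(np.diff(self.stress) < 0):
            raise InvalidParameterError("stress must be non-decreasing")

    @classmethod
    def parametric(
        cls,
        e1: float = BASELINE_E1,
        e3: float = BASELINE_E3,
        max_strain: float = 1.0,
        n: int = 201,
    ) -> "MaterialCurve":
        """Convex polynomial family sigma = e1*eps + e3*eps^3, tabulated."""
        if e1 < 0 or e3 < 0 or (e1 == 0 and e3 == 0):
            raise InvalidParameterError("e1, e3 must be non-negative and not both zero")
        eps = np.linspace(0.0, max_strain, n)
        return cls(eps, e1 * eps + e3 * eps**3)

    def stress_at(self, strain: float | np.ndarray) -> float | np.ndarray:
        """Interpolated stress; the last segment extrapolates linearly."""
        eps = np.asarray(strain, dtype=float)
        out = np.interp(eps, self.strain, self.stress)
        slope = (self.stress[-1] - self.stress[-2]) / (self.strain[-1] - self.strain[-2])
        out = np.where(eps > self.strain[-1], self.stress[-1] + slope * (eps - self.strain[-1]), out)
        return float(out) if np.isscalar(strain) else out


@dataclass(frozen=True)
class HystereticMaterial:
    """Loading curve plus hysteretic-unloading parameters.

    hu in (0, 1] is the force fraction retained at full unload; shape > 0
    the hysteresis curvature; scale > 0 a multiplier on the stress ordinates
    (used to make stiffer/softer variants of a family).
    """

    curve: MaterialCurve
    hu: float = 0.5
    shape: float = 2.0
    scale: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.hu <= 1:
            raise InvalidParameterError(f"hu must be in (0, 1], got {self.hu}")
        if not self.shape > 0:
            raise InvalidParameterError(f"shape must be > 0, got {self.shape}")
        if not self.scale > 0:
            raise InvalidParameterError(f"scale must be > 0, got {self.scale}")


def baseline_material(hu: float = 0.5, shape: float = 2.0, scale: float = 1.0) -> HystereticMaterial:
    """The default parametric rubber-composite family."""
    return HystereticMaterial(MaterialCurve.parametric(), hu=hu, shape=shape, scale=scale)


@dataclass(frozen=True)
class Headform:
    """Rigid hemispherical drop mass."""

    mass: float = DEFAULT_MASS
    radius: float = DEFAULT_RADIUS

    def __post_init__(self) -> None:
        if not self.mass > 0:
            raise InvalidParameterError("headform mass must be > 0")
        if not self.radius > 0:
            raise InvalidParameterError("headform radius must be > 0")


@dataclass(frozen=True)
class SurfaceLayer:
    """Surfacing layer geometry; plan_area_cap defaults to pi*R^2 at use."""

    thickness: float = DEFAULT_THICKNESS
    plan_area_cap: float | None = None

    def __post_init__(self) -> None:
        if not self.thickness > 0:
            raise InvalidParameterError("layer thickness must be > 0")
        if self.plan_area_cap is not None and not self.plan_area_cap > 0:
            raise InvalidParameterError("plan_area_cap must be > 0")


def scale_material(m: HystereticMaterial, factor: float) -> HystereticMaterial:
    """Multiply the stress ordinates by ``factor`` (e.g. 5x stiffer, 0.2x softer)."""
    if not factor > 0:
        raise InvalidParameterError(f"scale factor must be > 0, got {factor}")
    return replace(m, scale=m.scale * factor)


class _ContactLaw:
    """Precomputed loading force F(x) and strain energy W(x) on a uniform grid.

    The stored strain energy is a state function of indentation only (the
    integral of the loading force), which makes the hysteretic scale factor
    well defined at every Runge-Kutta stage without extra ODE state.
    """

    def __init__(self, mat: HystereticMaterial, head: Headform, layer: SurfaceLayer):
        self.mat = mat
        self.head = head
        self.layer = layer
        cap = layer.plan_area_cap if layer.plan_area_cap is not None else math.pi * head.radius**2
        x = np.linspace(0.0, layer.thickness, _GRID_POINTS)
        area = np.minimum(math.pi * (2.0 * head.radius * x - x**2), cap)
        np.maximum(area, 0.0, out=area)
        sigma = mat.curve.stress_at(x / layer.thickness)
        f = mat.scale * sigma * area
        w = np.empty_like(f)
        w[0] = 0.0
        np.cumsum(0.5 * (f[1:] + f[:-1]) * (x[1] - x[0]), out=w[1:])
        self._dx = float(x[1] - x[0])
        self._f = f
        self._w = w
        self.thickness = layer.thickness

    def _interp(self, table: np.ndarray, x: float) -> float:
        if x <= 0.0:
            return 0.0
        if x >= self.thickness:
            raise BottomOutError(
                f"indentation {x:.4g} m reached the layer thickness "
                f"{self.thickness:.4g} m; use a stiffer curve or a thicker layer"
            )
        pos = x / self._dx
        i = int(pos)
        frac = pos - i
        return table[i] * (1.0 - frac) + table[i + 1] * frac

    def loading_force(self, x: float) -> float:
        return self._interp(self._f, x)

    def stored_energy(self, x: float) -> float:
        return self._interp(self._w, x)

    def hysteretic_scale(self, w: float, w_max: float) -> float:
        if w_max <= 0.0:
            return 1.0
        frac = min(w, w_max) / w_max
        return 1.0 - (1.0 - self.mat.hu) * (1.0 - frac) ** self.mat.shape

    def force(self, x: float, w_max: float) -> float:
        f = self.loading_force(x)
        if f <= 0.0:
            return 0.0
        return f * self.hysteretic_scale(self.stored_energy(x), w_max)


@dataclass(frozen=True)
class ContactState:
    """Instantaneous contact state for a force query."""

    indentation: float
    indentation_rate: float
    peak_energy: float = 0.0
    current_energy: float | None = None


def contact_force(
    state: ContactState,
    mat: HystereticMaterial,
    head: Headform,
    layer: SurfaceLayer,
) -> float:
    """Contact force for an instantaneous state, N.

    Loading at the energy envelope (``current_energy >= peak_energy``)
    returns the full curve force; below the envelope the hysteretic scale
    applies regardless of rate direction, which makes unloading continuous at
    its onset and reloading retrace the unloading branch.
    """
    law = _ContactLaw(mat, head, layer)
    x = state.indentation
    if x < 0:
        raise InvalidParameterError("indentation must be >= 0")
    if x > layer.thickness:
        raise BottomOutError(
            f"indentation {x:.4g} m exceeds layer thickness {layer.thickness:.4g} m"
        )
    w = state.current_energy if state.current_energy is not None else law.stored_energy(x)
    f = law.loading_force(x)
    return f * law.hysteretic_scale(w, state.peak_energy)


@dataclass(frozen=True)
class DropResult:
    """Outcome of one simulated headform drop."""

    accel: UniformSignal
    max_indentation: float
    impact_velocity: float
    rebound_velocity: float
    energy_in: float
    energy_returned: float
    energy_dissipated: float
    contact_time: float = 0.0


def _static_rest(law: _ContactLaw, head: Headform, dt: float) -> DropResult:
    """Degenerate zero-velocity drop: static equilibrium, no impact."""
    weight = head.mass * GRAVITY
    lo, hi = 0.0, law.thickness * (1 - 1e-9)
    if law.loading_force(hi) < weight:
        raise BottomOutError("layer cannot support the headform weight")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if law.loading_force(mid) < weight:
            lo = mid
        else:
            hi = mid
    accel = UniformSignal(0.0, dt, np.zeros(2), unit="g")
    return DropResult(
        accel=accel,
        max_indentation=0.5 * (lo + hi),
        impact_velocity=0.0,
        rebound_velocity=0.0,
        energy_in=0.0,
        energy_returned=0.0,
        energy_dissipated=0.0,
        contact_time=0.0,
    )


def simulate_drop(
    head: Headform,
    layer: SurfaceLayer,
    mat: HystereticMaterial,
    drop_height: float | None = None,
    impact_velocity: float | None = None,
    dt: float = 1e-6,
    output_dt: float | None = None,
    max_time: float = 0.2,
) -> DropResult:
    """Integrate one headform drop from first contact to separation.

    Exactly one of ``drop_height`` / ``impact_velocity`` must be given; the
    other follows from free fall under g = 9.81 m/s^2.  The acceleration
    trace is what the missile accelerometer would read — contact force over
    mass, in g — sampled at ``output_dt`` (default: the integration step,
    which must divide ``output_dt`` to within rounding).

    A zero impact velocity is degenerate (no impact): the result is the
    static equilibrium where the contact force balances the weight, with a
    zero acceleration trace and zero energy flow.

    Raises
    ------
    BottomOutError
        If the indentation reaches the layer thickness.
    DivergenceError
        If no separation occurs within ``max_time`` seconds of contact.
    """
    if (drop_height is None) == (impact_velocity is None):
        raise InvalidParameterError("give exactly one of drop_height or impact_velocity")
    if not dt > 0:
        raise InvalidParameterError("dt must be > 0")
    if drop_height is not None:
        if drop_height < 0:
            raise InvalidParameterError("drop_height must be >= 0")
        v0 = math.sqrt(2.0 * GRAVITY * drop_height)
    else:
        if impact_velocity < 0:
            raise InvalidParameterError("impact_velocity must be >= 0")
        v0 = float(impact_velocity)

    law = _ContactLaw(mat, head, layer)
    out_dt = dt if output_dt is None else output_dt
    stride = max(1, round(out_dt / dt))
    if abs(stride * dt - out_dt) > 1e-9 * out_dt:
        raise InvalidParameterError("output_dt must be an integer multiple of dt")

    if v0 < 1e-9:
        return _static_rest(law, head, out_dt)

    m = head.mass
    inv_m = 1.0 / m
    g = GRAVITY

    # ODE state: x (indentation, +down), v (velocity, +down).
    x, v = 0.0, v0
    w_peak = 0.0
    e_in = 0.0
    e_ret = 0.0
    accel_g: list[float] = [0.0]
    n_steps = int(math.ceil(max_time / dt))
    t = 0.0
    separated = False

    force = law.force
    for step in range(1, n_steps + 1):
        f1 = force(x, w_peak)
        # RK4 stages on (x, v)
        a1 = g - f1 * inv_m
        x2, v2 = x + 0.5 * dt * v, v + 0.5 * dt * a1
        a2 = g - force(max(x2, 0.0), w_peak) * inv_m
        x3, v3 = x + 0.5 * dt * v2, v + 0.5 * dt * a2
        a3 = g - force(max(x3, 0.0), w_peak) * inv_m
        x4, v4 = x + dt * v3, v + dt * a3
        a4 = g - force(max(x4, 0.0), w_peak) * inv_m
        x_new = x + dt * (v + 2.0 * v2 + 2.0 * v3 + v4) / 6.0
        v_new = v + dt * (a1 + 2.0 * a2 + 2.0 * a3 + a4) / 6.0

        f2 = force(max(x_new, 0.0), w_peak)
        # force-displacement work split into compression / restitution
        dx = x_new - x
        f_mid = 0.5 * (f1 + f2)
        if dx >= 0.0:
            e_in += f_mid * dx
        else:
            e_ret -= f_mid * dx

        x, v = x_new, v_new
        t = step * dt
        w_here = law.stored_energy(max(x, 0.0))
        if w_here > w_peak:
            w_peak = w_here
        if step % stride == 0:
            accel_g.append(force(max(x, 0.0), w_peak) * inv_m / g)
        if x <= 0.0 and v < 0.0:
            separated = True
            break

    if not separated:
        raise DivergenceError(f"no headform separation within {max_time:g} s of contact")

    if len(accel_g) < 2:
        accel_g.append(0.0)
    # recover max indentation from the stored-energy peak (monotone map)
    max_x = float(np.interp(w_peak, law._w, np.linspace(0.0, law.thickness, law._w.size)))
    e_diss = max(e_in - e_ret, 0.0)
    return DropResult(
        accel=UniformSignal(0.0, out_dt, np.asarray(accel_g), unit="g"),
        max_indentation=max_x,
        impact_velocity=v0,
        rebound_velocity=max(-v, 0.0),
        energy_in=e_in,
        energy_returned=e_ret,
        energy_dissipated=e_diss,
        contact_time=t,
    )


def calibrate_scale(
    mat_family: HystereticMaterial,
    head: Headform,
    layer: SurfaceLayer,
    target_height: float,
    target_hic: float = 1000.0,
    rel_tol: float = 0.005,
    dt: float = 1e-6,
    output_dt: float = 5e-5,
    max_expansions: int = 14,
) -> float:
    """Scale factor anchoring a material family to a drop-test HIC.

    Finds ``s`` such that the unbounded HIC (2077.5 Hz zero-phase filtered)
    of a drop from ``target_height`` onto ``scale_material(mat_family, s)``
    equals ``target_hic`` within ``rel_tol``, by bisection on log-scale.
    Stiffer surfacing gives a higher HIC, so the response is increasing in
    ``s`` over any physical bracket.
    """
    from .constants import HIC_FILTER_HZ
    from .signal_metrics import butterworth_filtfilt, hic as _hic

    if not target_height > 0:
        raise InvalidParameterError("target_height must be > 0")

    def response(s: float) -> float:
        res = simulate_drop(
            head, layer, scale_material(mat_family, s),
            drop_height=target_height, dt=dt, output_dt=output_dt,
        )
        filtered = butterworth_filtfilt(res.accel, HIC_FILTER_HZ)
        return _hic(filtered).value

    lo = hi = 1.0
    f_lo = f_hi = response(1.0)
    seen = [(1.0, f_lo)]
    for _ in range(max_expansions):
        if f_lo <= target_hic <= f_hi:
            break
        if f_hi < target_hic:
            lo, f_lo = hi, f_hi
            hi *= 2.0
            f_hi = response(hi)
            seen.append((hi, f_hi))
        else:
            hi, f_hi = lo, f_lo
            lo /= 2.0
            f_lo = response(lo)
            seen.append((lo, f_lo))
    else:
        rng = (min(v for _, v in seen), max(v for _, v in seen))
        raise CalibrationError(
            f"could not bracket target HIC {target_hic:g}; achieved HIC range {rng}"
        )

    for _ in range(60):
        mid = math.exp(0.5 * (math.log(lo) + math.log(hi)))
        f_mid = response(mid)
        if abs(f_mid - target_hic) <= rel_tol * target_hic:
            return mid
        if f_mid < target_hic:
            lo = mid
        else:
            hi = mid
    raise CalibrationError(
        f"bisection did not reach HIC {target_hic:g} within {rel_tol:.1%}"
    )
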