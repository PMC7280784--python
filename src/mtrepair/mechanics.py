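"""Planar elastica mechanics of a flow-loaded microtubule.

A microtubule is modelled as an inextensible slender elastic rod of contour
length L and bending rigidity kappa (pN*um^2), clamped at the GMPCPP seed
(fixed position and tangent at s = 0) and free at s = L.  A fluid flow exerts
an anisotropic slender-body drag per unit length

    f(s) = g * mu * (I - 1/2 t(s) (x) t(s)) . v(r(s)),

where t is the unit tangent, v the local flow velocity, mu the viscosity and
g a dimensionless geometric factor of order one.  The drag perpendicular to
the filament is exactly twice the parallel drag.

Equilibrium shapes solve the force/moment balance of the rod under this
distributed load.  In the tangent-angle parameterization theta(s), with
internal force N(s) = int_s^L f ds' (the free end carries no force), moment
balance reads

    kappa * theta''(s) = -(t x N)_z ,   theta(0) = clamp angle,
                                        theta'(L) = 0 (moment-free end).

The angle parameterization enforces |dr/ds| = 1 exactly, so inextensibility
is built in.  The boundary-value problem is discretized by second-order
finite differences and solved by Newton-type root finding with continuation
in flow magnitude from the unloaded straight state, which selects the
physically connected solution branch.

Units are pN / um / s throughout; k_B = 1.380649e-5 pN*um/K.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import interpolate, optimize

__all__ = [
    "K_B",
    "FilamentShape",
    "FlowField",
    "UniformFlow",
    "GridFlow",
    "MechanicalParams",
    "ElasticaSolution",
    "SolverError",
    "hydrodynamic_load",
    "equilibrium_shape",
    "shape_distance",
]

#: Boltzmann constant in pN*um/K.
K_B = 1.380649e-5


class SolverError(RuntimeError):
    """Raised when the elastica boundary-value solver fails to converge."""

    def __init__(self, message: str, residual_norm: float = np.nan):
        super().__init__(message)
        self.residual_norm = residual_norm


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FilamentShape:
    """Ordered, uniformly arc-length-sampled planar curve of one filament.

    Parameters
    ----------
    points
        (n, 2) array of coordinates in um.
    segment_length
        Nominal arc-length spacing Delta-s between consecutive points (um).
    rtol
        Relative tolerance on the inextensibility check.  Model-generated
        shapes satisfy it at 1e-6; measured shapes should be resampled with
        :meth:`from_points_resampled` first.
    """

    points: np.ndarray
    segment_length: float
    rtol: float = 1e-6

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError("points must be an (n, 2) array")
        if pts.shape[0] < 3:
            raise ValueError("a filament shape needs at least 3 points")
        if not np.all(np.isfinite(pts)):
            raise ValueError("coordinates must be finite")
        if not self.segment_length > 0:
            raise ValueError("segment_length must be positive")
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        err = np.max(np.abs(seg - self.segment_length)) / self.segment_length
        if err > self.rtol:
            raise ValueError(
                f"shape violates inextensibility: max relative segment-length "
                f"deviation {err:.3g} exceeds rtol={self.rtol:.3g}; resample "
                f"measured shapes with FilamentShape.from_points_resampled"
            )
        object.__setattr__(self, "points", pts)

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    @property
    def contour_length(self) -> float:
        """Total contour length L = (n_points - 1) * segment_length (um)."""
        return (self.n_points - 1) * self.segment_length

    @property
    def arc_lengths(self) -> np.ndarray:
        return np.arange(self.n_points) * self.segment_length

    def tangents(self) -> np.ndarray:
        """Unit tangents: one-sided at the endpoints, central elsewhere."""
        pts = self.points
        t = np.empty_like(pts)
        t[0] = pts[1] - pts[0]
        t[-1] = pts[-1] - pts[-2]
        t[1:-1] = pts[2:] - pts[:-2]
        t /= np.linalg.norm(t, axis=1, keepdims=True)
        return t

    @classmethod
    def from_tangent_angles(
        cls, theta: np.ndarray, segment_length: float, origin=(0.0, 0.0)
    ) -> "FilamentShape":
        """Integrate tangent angles into a shape with exact segment lengths.

        Each segment is laid down along the mid-angle (theta_i + theta_{i+1})/2
        so every chord has length exactly ``segment_length``.
        """
        theta = np.asarray(theta, dtype=float)
        mid = 0.5 * (theta[:-1] + theta[1:])
        steps = segment_length * np.column_stack([np.cos(mid), np.sin(mid)])
        pts = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)]) + np.asarray(
            origin, dtype=float
        )
        return cls(pts, segment_length)

    @classmethod
    def from_points_resampled(
        cls,
        points: np.ndarray,
        n_points: int | None = None,
        smoothing: float | None = None,
    ) -> "FilamentShape":
        """Resample an arbitrary ordered polyline to uniform arc length.

        Measured (digitized) shapes carry coordinate noise that both breaks
        the uniform-spacing invariant and inflates the apparent contour
        length; a smoothing spline removes most of that inflation before
        resampling.

        Parameters
        ----------
        points
            (m, 2) ordered coordinates, m >= 4.
        n_points
            Number of nodes in the resampled shape (default: keep m).
        smoothing
            ``splprep`` smoothing budget, roughly
            ``2 * m * sigma_noise**2`` for Gaussian coordinate noise of
            standard deviation sigma_noise per axis.  ``None`` or 0 gives an
            interpolating spline.
        """
        pts = np.asarray(points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 4:
            raise ValueError("need an (m, 2) array with m >= 4 to resample")
        if n_points is None:
            n_points = pts.shape[0]
        s = smoothing if smoothing is not None else 0.0
        k = min(3, pts.shape[0] - 1)
        (tck, _) = interpolate.splprep([pts[:, 0], pts[:, 1]], s=s, k=k)
        # densely sample, then reparameterize by arc length
        u = np.linspace(0.0, 1.0, max(20 * n_points, 400))
        x, y = interpolate.splev(u, tck)
        fine = np.column_stack([x, y])
        seg = np.linalg.norm(np.diff(fine, axis=0), axis=1)
        arc = np.concatenate([[0.0], np.cumsum(seg)])
        length = arc[-1]
        s_target = np.linspace(0.0, length, n_points)
        xi = np.interp(s_target, arc, fine[:, 0])
        yi = np.interp(s_target, arc, fine[:, 1])
        ds = length / (n_points - 1)
        out = np.column_stack([xi, yi])
        # chord lengths of the resampled polyline deviate from ds only at
        # curvature scale; renormalize segment-by-segment to restore the
        # inextensibility invariant exactly
        vec = np.diff(out, axis=0)
        vec *= ds / np.linalg.norm(vec, axis=1, keepdims=True)
        out = np.vstack([out[:1], out[:1] + np.cumsum(vec, axis=0)])
        return cls(out, ds)


class FlowField:
    """Base class: maps positions (um) to fluid velocities (um/s)."""

    def velocity(self, points: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def scaled(self, factor: float) -> "FlowField":  # pragma: no cover
        raise NotImplementedError


@dataclass(frozen=True)
class UniformFlow(FlowField):
    """Spatially uniform flow (vx, vy) in um/s."""

    vx: float
    vy: float

    def __post_init__(self):
        if not (np.isfinite(self.vx) and np.isfinite(self.vy)):
            raise ValueError("flow velocity must be finite")

    def velocity(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(np.asarray(points, dtype=float))
        return np.broadcast_to([self.vx, self.vy], (points.shape[0], 2)).copy()

    def scaled(self, factor: float) -> "UniformFlow":
        return UniformFlow(self.vx * factor, self.vy * factor)

    @property
    def speed(self) -> float:
        return float(np.hypot(self.vx, self.vy))


class GridFlow(FlowField):
    """Flow tabulated on a rectangular grid, e.g. from bead tracking.

    Positions outside the grid raise a ``ValueError`` (domain error).
    """

    def __init__(self, x, y, vx, vy, scale: float = 1.0):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        vx = np.asarray(vx, dtype=float)
        vy = np.asarray(vy, dtype=float)
        if np.any(np.diff(x) <= 0) or np.any(np.diff(y) <= 0):
            raise ValueError("grid axes must be strictly increasing")
        if vx.shape != (x.size, y.size) or vy.shape != (x.size, y.size):
            raise ValueError("velocity grids must have shape (len(x), len(y))")
        if not (np.all(np.isfinite(vx)) and np.all(np.isfinite(vy))):
            raise ValueError("velocities must be finite")
        self._x, self._y, self._vx, self._vy = x, y, vx, vy
        self._scale = float(scale)
        self._ivx = interpolate.RegularGridInterpolator((x, y), vx)
        self._ivy = interpolate.RegularGridInterpolator((x, y), vy)

    def velocity(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(np.asarray(points, dtype=float))
        try:
            v = np.column_stack([self._ivx(points), self._ivy(points)])
        except ValueError as exc:
            raise ValueError(f"flow field undefined at queried point: {exc}")
        return self._scale * v

    def scaled(self, factor: float) -> "GridFlow":
        return GridFlow(self._x, self._y, self._vx, self._vy,
                        scale=self._scale * factor)


@dataclass(frozen=True)
class MechanicalParams:
    """Mechanical and geometric parameters of one bending experiment.

    kappa : bending rigidity (pN*um^2)
    mu : fluid viscosity (pN*s/um^2); water at room temperature is 1e-3
    g : dimensionless slender-body geometric factor, order 1
    clamp_point : seed position (um)
    clamp_angle : tangent direction at s = 0 (radians)
    temperature : K, used only for the kappa -> Lp conversion
    """

    kappa: float
    mu: float = 1e-3
    g: float = 1.0
    clamp_point: tuple = (0.0, 0.0)
    clamp_angle: float = 0.0
    temperature: float = 308.15

    def __post_init__(self):
        for name in ("kappa", "mu", "g", "temperature"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")

    def with_kappa(self, kappa: float) -> "MechanicalParams":
        return replace(self, kappa=kappa)


@dataclass(frozen=True)
class ElasticaSolution:
    """Converged (or not) equilibrium solution of the elastica BVP."""

    shape: FilamentShape
    tangent_angles: np.ndarray
    internal_tension: np.ndarray
    converged: bool
    residual_norm: float


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def hydrodynamic_load(
    shape: FilamentShape, flow: FlowField, params: MechanicalParams
) -> np.ndarray:
    """Slender-body drag force density (pN/um) at each node of ``shape``.

    Applies the anisotropic projection g*mu*(I - 1/2 t(x)t) to the local
    flow velocity: drag perpendicular to the filament is twice the parallel
    drag.
    """
    t = shape.tangents()
    v = flow.velocity(shape.points)
    if not np.all(np.isfinite(v)):
        raise ValueError("flow velocity is not finite along the shape")
    tv = np.sum(t * v, axis=1, keepdims=True)
    return params.g * params.mu * (v - 0.5 * tv * t)


def _load_from_angles(theta, ds, flow, params, origin):
    """Tangents, positions and drag density for a tangent-angle state."""
    t = np.column_stack([np.cos(theta), np.sin(theta)])
    mid = 0.5 * (theta[:-1] + theta[1:])
    steps = ds * np.column_stack([np.cos(mid), np.sin(mid)])
    r = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)]) + origin
    v = flow.velocity(r)
    if not np.all(np.isfinite(v)):
        raise ValueError("NaN/inf in flow velocity along the filament")
    tv = np.sum(t * v, axis=1, keepdims=True)
    f = params.g * params.mu * (v - 0.5 * tv * t)
    return t, r, f


def _internal_force(f, ds):
    """N(s_i) = int_{s_i}^L f ds' by reverse cumulative trapezoid."""
    n = f.shape[0]
    N = np.zeros_like(f)
    incr = 0.5 * ds * (f[:-1] + f[1:])
    N[: n - 1] = np.cumsum(incr[::-1], axis=0)[::-1]
    return N


def _residual(theta_free, clamp_angle, ds, kappa, flow, params, origin):
    """Discrete moment balance; unknowns are theta at nodes 1..n-1.

    Residuals are scaled to angle units (multiplied by ds^2/kappa) so the
    root-finder tolerance is dimensionless.
    """
    theta = np.concatenate([[clamp_angle], theta_free])
    n = theta.size
    t, _, f = _load_from_angles(theta, ds, flow, params, origin)
    N = _internal_force(f, ds)
    cross = t[:, 0] * N[:, 1] - t[:, 1] * N[:, 0]
    res = np.empty(n - 1)
    res[: n - 2] = (theta[2:] - 2.0 * theta[1:-1] + theta[:-2]) + (
        ds * ds / kappa
    ) * cross[1:-1]
    # moment-free end: theta'(L) = 0, second-order one-sided difference
    res[n - 2] = 0.5 * (3.0 * theta[-1] - 4.0 * theta[-2] + theta[-3])
    return res


def equilibrium_shape(
    params: MechanicalParams,
    length: float,
    flow: FlowField,
    n_nodes: int = 61,
    tol: float = 1e-10,
    n_continuation: int = 10,
    theta_init: np.ndarray | None = None,
) -> ElasticaSolution:
    """Equilibrium shape of the clamped filament under flow loading.

    Continuation ramps the flow magnitude from zero (straight filament) to
    its target value in ``n_continuation`` steps, which keeps the solver on
    the physically connected branch of the multi-branched elastica problem.
    A ``theta_init`` warm start (e.g. the solution at a nearby kappa) skips
    continuation when it already converges at full flow.

    Raises
    ------
    SolverError
        if the root-finder does not reach ``tol`` at full flow magnitude.
    """
    if not length > 0:
        raise ValueError("length must be positive")
    if n_nodes < 11:
        raise ValueError("n_nodes must be at least 11")
    ds = length / (n_nodes - 1)
    origin = np.asarray(params.clamp_point, dtype=float)
    alpha = params.clamp_angle

    def solve_at(scale, start):
        sol = optimize.root(
            _residual,
            start,
            args=(alpha, ds, params.kappa, flow.scaled(scale), params, origin),
            method="hybr",
            tol=tol * 1e-2,
        )
        return sol.x, float(np.max(np.abs(sol.fun)))

    theta0 = np.full(n_nodes - 1, alpha)
    # trivial case: zero uniform flow -> straight filament
    if isinstance(flow, UniformFlow) and flow.speed == 0.0:
        theta = np.full(n_nodes, alpha)
        shape = FilamentShape.from_tangent_angles(theta, ds, origin)
        return ElasticaSolution(shape, theta, np.zeros(n_nodes), True, 0.0)

    best = None
    if theta_init is not None:
        start = np.asarray(theta_init, dtype=float)[1:]
        if start.size == n_nodes - 1:
            x, rn = solve_at(1.0, start)
            if rn < tol:
                best = (x, rn)
    if best is None:
        x = theta0
        for scale in np.linspace(0.0, 1.0, n_continuation + 1)[1:]:
            x, rn = solve_at(scale, x)
        if rn >= tol:
            raise SolverError(
                f"elastica solver did not converge (residual {rn:.3g} >= "
                f"tol {tol:.3g})",
                residual_norm=rn,
            )
        best = (x, rn)

    x, rn = best
    theta = np.concatenate([[alpha], x])
    t, _, f = _load_from_angles(theta, ds, flow, params, origin)
    N = _internal_force(f, ds)
    tension = np.sum(t * N, axis=1)
    shape = FilamentShape.from_tangent_angles(theta, ds, origin)
    return ElasticaSolution(shape, theta, tension, True, rn)


def _resample_to_n(shape: FilamentShape, n: int) -> FilamentShape:
    return FilamentShape.from_points_resampled(shape.points, n_points=n)


def shape_distance(model: FilamentShape, measured: FilamentShape) -> float:
    """Mean squared pointwise distance between two shapes (um^2).

    omega^2 = (1/L) int_0^L |r_R(s) - r(s)|^2 ds, evaluated by the trapezoid
    rule on the common uniform arc-length grid.  Shapes whose contour lengths
    differ by more than 1% are rejected; a shorter mismatch is absorbed by
    resampling the model onto the measured grid size.
    """
    Lm, Lr = model.contour_length, measured.contour_length
    if abs(Lm - Lr) / max(Lm, Lr) > 0.01:
        raise ValueError(
            f"contour lengths differ by more than 1%: {Lm:.4g} vs {Lr:.4g} um"
        )
    if model.n_points != measured.n_points:
        n = max(model.n_points, measured.n_points)
        model = _resample_to_n(model, n)
        measured = _resample_to_n(measured, n)
    d2 = np.sum((model.points - measured.points) ** 2, axis=1)
    s = measured.arc_lengths
    return float(np.trapezoid(d2, s) / s[-1])
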