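"""Parametric Gaussian feature models and forward rendering.

A fluorescently labelled microtubule structure is modelled as a sum of a
uniform background and a small number of parametric Gaussian intensity
sources:

* a **spot** — a 3D anisotropic Gaussian, used for a spindle pole body or an
  unresolved assembly of short microtubules (7 free parameters);
* a **line** — a point Gaussian integrated along a straight segment, used
  for a straight microtubule or bundle (10 free parameters);
* a **curve** — a point Gaussian integrated along a bent centerline whose
  planar curvature is expanded in a truncated Fourier series; the centerline
  is reconstructed by tangent stepping from an origin and an initial unit
  tangent (15 free parameters for two Fourier terms, the curve length being
  carried as a separately optimized shape parameter).

All geometric parameters are in micrometres.  Voxel ``(k, j, i)`` of a stack
with voxel size ``(dx, dy, dz)`` has its physical centre at
``((i + 0.5) dx, (j + 0.5) dy, (k + 0.5) dz)``; arrays are indexed
``(z, y, x)`` as read from multi-page TIFF.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numpy.polynomial import Polynomial
from scipy.special import erf

from .errors import (
    DegenerateTangentError,
    InvalidParameterError,
    StepTooLargeError,
    UnderDeterminedError,
)

__all__ = [
    "ImageStack",
    "Grid",
    "Spot",
    "LineFeature",
    "CurveFeature",
    "FourierCurvature",
    "CompositeModel",
    "render_spot",
    "render_line",
    "render_curve",
    "render_model",
    "local_curvature",
    "fit_curvature_fourier",
    "reconstruct_curve",
    "feature_from_dict",
]


# ---------------------------------------------------------------------------
# image container and geometry
# ---------------------------------------------------------------------------


@dataclass
class ImageStack:
    """A 3D fluorescence image with physical voxel sizes.

    Parameters
    ----------
    intensities
        Array of shape ``(nz, ny, nx)``, finite, arbitrary fluorescence units.
    voxel_size
        ``(dx, dy, dz)`` in µm per voxel, all positive.
    """

    intensities: np.ndarray
    voxel_size: tuple[float, float, float] = (0.1, 0.1, 0.5)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 3 or self.intensities.size == 0:
            raise InvalidParameterError("intensities must be a non-empty 3D array")
        if not np.all(np.isfinite(self.intensities)):
            raise InvalidParameterError("intensities must be finite")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)  # type: ignore[assignment]
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise InvalidParameterError("voxel sizes must be three positive numbers")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape  # type: ignore[return-value]

    @property
    def grid(self) -> "Grid":
        return Grid.from_shape(self.shape, self.voxel_size)

    def mip(self) -> np.ndarray:
        """Maximum-intensity projection along Z, shape ``(ny, nx)``."""
        return self.intensities.max(axis=0)


@dataclass(frozen=True)
class Grid:
    """Render target geometry: physical voxel-centre coordinates.

    ``xs``, ``ys``, ``zs`` are 1D arrays of voxel-centre coordinates in µm;
    a cropped grid keeps the coordinates of the parent stack, so features
    render identically on a crop and on the matching region of the full grid.
    """

    xs: np.ndarray
    ys: np.ndarray
    zs: np.ndarray
    voxel_size: tuple[float, float, float]

    @classmethod
    def from_shape(
        cls, shape: tuple[int, int, int], voxel_size: Sequence[float]
    ) -> "Grid":
        nz, ny, nx = shape
        dx, dy, dz = voxel_size
        return cls(
            xs=(np.arange(nx) + 0.5) * dx,
            ys=(np.arange(ny) + 0.5) * dy,
            zs=(np.arange(nz) + 0.5) * dz,
            voxel_size=(float(dx), float(dy), float(dz)),
        )

    @property
    def shape(self) -> tuple[int, int, int]:
        return (len(self.zs), len(self.ys), len(self.xs))

    @property
    def n_voxels(self) -> int:
        return len(self.zs) * len(self.ys) * len(self.xs)

    def crop(self, zsl: slice, ysl: slice, xsl: slice) -> "Grid":
        return Grid(self.xs[xsl], self.ys[ysl], self.zs[zsl], self.voxel_size)

    def extent(self) -> tuple[float, float, float]:
        """Physical size (µm) of the full field of view along x, y, z."""
        dx, dy, dz = self.voxel_size
        return (len(self.xs) * dx, len(self.ys) * dy, len(self.zs) * dz)


def _check_widths(widths: np.ndarray) -> None:
    if widths.shape != (3,) or not np.all(np.isfinite(widths)) or np.any(widths <= 0):
        raise InvalidParameterError(f"widths must be 3 positive finite numbers, got {widths}")


def _check_finite(name: str, value: np.ndarray) -> None:
    if not np.all(np.isfinite(value)):
        raise InvalidParameterError(f"{name} must be finite, got {value}")


# ---------------------------------------------------------------------------
# features
# ---------------------------------------------------------------------------


@dataclass(eq=False)
class Spot:
    """Anisotropic 3D Gaussian point source (7 free parameters)."""

    amplitude: float
    center: np.ndarray  # (x0, y0, z0) µm
    widths: np.ndarray  # (σx, σy, σz) µm

    N_PARAMS = 7

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        self.widths = np.asarray(self.widths, dtype=float)
        _check_finite("center", self.center)
        _check_widths(self.widths)
        if not np.isfinite(self.amplitude) or self.amplitude <= 0:
            raise InvalidParameterError("amplitude must be positive and finite")

    # -- parameter-vector packing ------------------------------------------
    def to_vector(self) -> np.ndarray:
        return np.concatenate([[self.amplitude], self.center, self.widths])

    @classmethod
    def from_vector(cls, v: np.ndarray) -> "Spot":
        v = np.asarray(v, dtype=float)
        return cls(amplitude=v[0], center=v[1:4], widths=v[4:7])

    @property
    def n_params(self) -> int:
        return self.to_vector().size

    @property
    def tip(self) -> np.ndarray:
        return self.center

    def render(self, grid: Grid) -> np.ndarray:
        return render_spot(self, grid)

    def to_dict(self) -> dict:
        return {
            "type": "spot",
            "parameters": {
                "amplitude": float(self.amplitude),
                "center": list(map(float, self.center)),
                "widths": list(map(float, self.widths)),
            },
            "units": "um",
        }


@dataclass(eq=False)
class LineFeature:
    """Gaussian intensity integrated along a straight segment (10 parameters)."""

    amplitude: float
    start: np.ndarray
    end: np.ndarray
    widths: np.ndarray

    N_PARAMS = 10

    def __post_init__(self) -> None:
        self.start = np.asarray(self.start, dtype=float)
        self.end = np.asarray(self.end, dtype=float)
        self.widths = np.asarray(self.widths, dtype=float)
        _check_finite("start", self.start)
        _check_finite("end", self.end)
        _check_widths(self.widths)
        if not np.isfinite(self.amplitude) or self.amplitude <= 0:
            raise InvalidParameterError("amplitude must be positive and finite")

    def to_vector(self) -> np.ndarray:
        return np.concatenate([[self.amplitude], self.start, self.end, self.widths])

    @classmethod
    def from_vector(cls, v: np.ndarray) -> "LineFeature":
        v = np.asarray(v, dtype=float)
        return cls(amplitude=v[0], start=v[1:4], end=v[4:7], widths=v[7:10])

    @property
    def n_params(self) -> int:
        return self.to_vector().size

    @property
    def length(self) -> float:
        return float(np.linalg.norm(self.end - self.start))

    @property
    def tip(self) -> np.ndarray:
        """Free (plus) end of the microtubule; the start is anchored at a pole."""
        return self.end

    def point_at(self, t: np.ndarray) -> np.ndarray:
        """Centerline point(s) at normalized arc length t ∈ [0, 1], shape (..., 3)."""
        t = np.asarray(t, dtype=float)[..., None]
        return self.start + (self.end - self.start) * t

    def render(self, grid: Grid, method: str = "erf") -> np.ndarray:
        return render_line(self, grid, method=method)

    def to_dict(self) -> dict:
        return {
            "type": "line",
            "parameters": {
                "amplitude": float(self.amplitude),
                "start": list(map(float, self.start)),
                "end": list(map(float, self.end)),
                "widths": list(map(float, self.widths)),
            },
            "units": "um",
        }


@dataclass(eq=False)
class FourierCurvature:
    """Truncated Fourier model of planar curvature over t ∈ [0, 1].

    ``K(t) = k0 + Σ_{i=1..N} p_i cos(i w t) + q_i sin(i w t)``,
    with ``k0``, ``p_i``, ``q_i`` in 1/µm and ``w`` a dimensionless angular
    frequency over the normalized arc length.
    """

    k0: float
    w: float
    p: np.ndarray
    q: np.ndarray

    def __post_init__(self) -> None:
        self.p = np.atleast_1d(np.asarray(self.p, dtype=float))
        self.q = np.atleast_1d(np.asarray(self.q, dtype=float))
        if self.p.shape != self.q.shape:
            raise InvalidParameterError("p and q must have the same number of terms")

    @property
    def n_terms(self) -> int:
        return self.p.size

    def __call__(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        k = np.full_like(t, self.k0, dtype=float)
        for i in range(1, self.n_terms + 1):
            k = k + self.p[i - 1] * np.cos(i * self.w * t)
            k = k + self.q[i - 1] * np.sin(i * self.w * t)
        return k

    def to_vector(self) -> np.ndarray:
        return np.concatenate([[self.k0, self.w], self.p, self.q])

    @classmethod
    def from_vector(cls, v: np.ndarray, n_terms: int = 2) -> "FourierCurvature":
        v = np.asarray(v, dtype=float)
        return cls(k0=v[0], w=v[1], p=v[2 : 2 + n_terms], q=v[2 + n_terms : 2 + 2 * n_terms])


def _tangent_from_angles(azimuth: float, polar: float) -> np.ndarray:
    """Unit tangent from spherical angles (polar measured from +z)."""
    st = np.sin(polar)
    return np.array([st * np.cos(azimuth), st * np.sin(azimuth), np.cos(polar)])


def _angles_from_tangent(t: np.ndarray) -> tuple[float, float]:
    t = np.asarray(t, dtype=float)
    n = np.linalg.norm(t)
    if n == 0 or not np.all(np.isfinite(t)):
        raise InvalidParameterError("tangent must be a non-zero finite vector")
    t = t / n
    return float(np.arctan2(t[1], t[0])), float(np.arccos(np.clip(t[2], -1, 1)))


@dataclass(eq=False)
class CurveFeature:
    """Gaussian intensity along a curved centerline (15 free parameters, N=2).

    The centerline is defined by an origin, an initial unit tangent stored as
    two angles, and a Fourier curvature model; the arc length ``length`` is a
    shape parameter carried outside the 15-vector and optionally optimized
    separately.
    """

    amplitude: float
    origin: np.ndarray
    azimuth: float
    polar: float
    curvature: FourierCurvature
    length: float
    widths: np.ndarray

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.widths = np.asarray(self.widths, dtype=float)
        _check_finite("origin", self.origin)
        _check_widths(self.widths)
        if not np.isfinite(self.amplitude) or self.amplitude <= 0:
            raise InvalidParameterError("amplitude must be positive and finite")
        if not np.isfinite(self.length) or self.length <= 0:
            raise InvalidParameterError("length must be positive and finite")

    @classmethod
    def n_params_for(cls, n_terms: int) -> int:
        # amplitude (1) + origin (3) + tangent angles (2)
        # + curvature {k0, w, p_i, q_i} (2 + 2N) + widths (3)
        return 1 + 3 + 2 + 2 + 2 * n_terms + 3

    @property
    def n_params(self) -> int:
        return self.to_vector().size

    @property
    def initial_tangent(self) -> np.ndarray:
        return _tangent_from_angles(self.azimuth, self.polar)

    def to_vector(self) -> np.ndarray:
        return np.concatenate(
            [
                [self.amplitude],
                self.origin,
                [self.azimuth, self.polar],
                self.curvature.to_vector(),
                self.widths,
            ]
        )

    @classmethod
    def from_vector(cls, v: np.ndarray, length: float, n_terms: int = 2) -> "CurveFeature":
        v = np.asarray(v, dtype=float)
        nk = 2 + 2 * n_terms
        return cls(
            amplitude=v[0],
            origin=v[1:4],
            azimuth=float(v[4]),
            polar=float(v[5]),
            curvature=FourierCurvature.from_vector(v[6 : 6 + nk], n_terms=n_terms),
            length=float(length),
            widths=v[6 + nk : 9 + nk],
        )

    def centerline(self, step: float | None = None) -> np.ndarray:
        if step is None:
            step = self.length / 512.0
        return reconstruct_curve(
            self.origin, self.initial_tangent, self.curvature, self.length, step
        )

    @property
    def tip(self) -> np.ndarray:
        return self.centerline()[-1]

    def render(self, grid: Grid, order: int = 32) -> np.ndarray:
        return render_curve(self, grid, order=order)

    def to_dict(self) -> dict:
        return {
            "type": "curve",
            "parameters": {
                "amplitude": float(self.amplitude),
                "origin": list(map(float, self.origin)),
                "azimuth": float(self.azimuth),
                "polar": float(self.polar),
                "curvature": {
                    "k0": float(self.curvature.k0),
                    "w": float(self.curvature.w),
                    "p": list(map(float, self.curvature.p)),
                    "q": list(map(float, self.curvature.q)),
                },
                "length": float(self.length),
                "widths": list(map(float, self.widths)),
            },
            "units": "um",
        }


Feature = Spot | LineFeature | CurveFeature


@dataclass(eq=False)
class CompositeModel:
    """Uniform background plus an ordered collection of features.

    ``topology`` tags the biological organization (monopolar, bipolar,
    astral, or free) and ``attachments`` records which line/curve start
    points were seeded at which spot centre (feature index → spot index).
    """

    background: float
    features: list  # list[Feature]
    topology: str = "free"
    attachments: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.isfinite(self.background) or self.background < 0:
            raise InvalidParameterError("background must be non-negative and finite")
        if self.topology not in ("monopolar", "bipolar", "astral", "free"):
            raise InvalidParameterError(f"unknown topology {self.topology!r}")

    @property
    def n_params(self) -> int:
        """Free parameters including the background level."""
        return 1 + sum(f.n_params for f in self.features)

    def render(self, grid: Grid) -> np.ndarray:
        return render_model(self, grid)

    def copy(self) -> "CompositeModel":
        return CompositeModel(
            background=self.background,
            features=[dataclasses.replace(f) for f in self.features],
            topology=self.topology,
            attachments=dict(self.attachments),
        )

    def microtubules(self) -> list:
        """Line/curve features (the microtubule-like sources)."""
        return [f for f in self.features if isinstance(f, (LineFeature, CurveFeature))]

    def to_dict(self) -> dict:
        return {
            "background": float(self.background),
            "topology": self.topology,
            "attachments": {str(k): v for k, v in self.attachments.items()},
            "features": [f.to_dict() for f in self.features],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CompositeModel":
        return cls(
            background=d["background"],
            features=[feature_from_dict(fd) for fd in d["features"]],
            topology=d.get("topology", "free"),
            attachments={int(k): v for k, v in d.get("attachments", {}).items()},
        )


def feature_from_dict(d: dict) -> Feature:
    p = d["parameters"]
    if d["type"] == "spot":
        return Spot(amplitude=p["amplitude"], center=p["center"], widths=p["widths"])
    if d["type"] == "line":
        return LineFeature(
            amplitude=p["amplitude"], start=p["start"], end=p["end"], widths=p["widths"]
        )
    if d["type"] == "curve":
        c = p["curvature"]
        return CurveFeature(
            amplitude=p["amplitude"],
            origin=p["origin"],
            azimuth=p["azimuth"],
            polar=p["polar"],
            curvature=FourierCurvature(k0=c["k0"], w=c["w"], p=c["p"], q=c["q"]),
            length=p["length"],
            widths=p["widths"],
        )
    raise InvalidParameterError(f"unknown feature type {d['type']!r}")


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def render_spot(spot: Spot, grid: Grid) -> np.ndarray:
    """Evaluate the spot Gaussian at every voxel centre (no normalization)."""
    _check_widths(spot.widths)
    x0, y0, z0 = spot.center
    sx, sy, sz = spot.widths
    ex = np.exp(-(((grid.xs - x0) / sx) ** 2))[None, None, :]
    ey = np.exp(-(((grid.ys - y0) / sy) ** 2))[None, :, None]
    ez = np.exp(-(((grid.zs - z0) / sz) ** 2))[:, None, None]
    return spot.amplitude * ez * ey * ex


_DEGENERATE_A = 1e-12


def render_line(line: LineFeature, grid: Grid, method: str = "erf") -> np.ndarray:
    """Integrate a point Gaussian along the segment over normalized arc length.

    ``method='erf'`` reduces the quadratic-in-t exponent to error functions
    (exact); ``method='quadrature'`` uses composite Gauss–Legendre panels.
    A degenerate line (start == end) renders identically to a spot.
    """
    if method == "quadrature":
        pts = line.point_at  # t -> (..., 3)
        return _integrate_gaussian_along(
            pts, line.amplitude, line.widths, grid, arc_length=line.length, order=32
        )
    if method != "erf":
        raise InvalidParameterError(f"unknown line render method {method!r}")

    d = line.end - line.start
    sig2 = line.widths**2
    a = float(np.sum(d**2 / sig2))

    rx = grid.xs - line.start[0]
    ry = grid.ys - line.start[1]
    rz = grid.zs - line.start[2]
    # exponent E(t) = a t² − 2 b t + c with separable fields b and c
    bx = rx * (d[0] / sig2[0])
    by = ry * (d[1] / sig2[1])
    bz = rz * (d[2] / sig2[2])
    cx = rx * rx / sig2[0]
    cy = ry * ry / sig2[1]
    cz = rz * rz / sig2[2]
    b = bx[None, None, :] + by[None, :, None] + bz[:, None, None]
    c = cx[None, None, :] + cy[None, :, None] + cz[:, None, None]

    if a < _DEGENERATE_A:
        return line.amplitude * np.exp(-c)

    sqa = np.sqrt(a)
    # b²/a − c ≤ 0 by Cauchy–Schwarz, so the exponential cannot overflow
    e = b * b
    e *= 1.0 / a
    e -= c
    np.exp(e, out=e)
    b *= 1.0 / sqa
    t2 = erf(b)
    b -= sqa
    np.negative(b, out=b)
    t2 += erf(b)
    e *= t2
    e *= line.amplitude * (np.sqrt(np.pi) / (2.0 * sqa))
    return e


def _gauss_panels(order: int, n_panels: int) -> tuple[np.ndarray, np.ndarray]:
    """Gauss–Legendre nodes/weights for [0,1] split into equal panels."""
    nodes, weights = np.polynomial.legendre.leggauss(order)
    edges = np.linspace(0.0, 1.0, n_panels + 1)
    half = np.diff(edges) / 2.0
    mid = (edges[:-1] + edges[1:]) / 2.0
    t = (mid[:, None] + half[:, None] * nodes[None, :]).ravel()
    w = (half[:, None] * weights[None, :]).ravel()
    return t, w


def _integrate_gaussian_along(
    points_of_t,
    amplitude: float,
    widths: np.ndarray,
    grid: Grid,
    arc_length: float,
    order: int = 32,
) -> np.ndarray:
    """Gauss-quadrature line integral of point Gaussians along a centerline.

    The panel count scales with arc length over the narrowest transverse
    width so the integrand is well resolved regardless of feature size.
    """
    n_panels = max(1, int(np.ceil(arc_length / (2.0 * float(np.min(widths))))))
    n_panels = min(n_panels, 64)
    t, w = _gauss_panels(order, n_panels)
    pts = points_of_t(t)  # (n_nodes, 3)
    sx, sy, sz = widths
    ex = np.exp(-(((grid.xs[None, :] - pts[:, 0:1]) / sx) ** 2))
    ey = np.exp(-(((grid.ys[None, :] - pts[:, 1:2]) / sy) ** 2))
    ez = np.exp(-(((grid.zs[None, :] - pts[:, 2:3]) / sz) ** 2))
    out = np.einsum("tz,ty,tx->zyx", ez * w[:, None], ey, ex, optimize=True)
    return amplitude * out


def render_curve(curve: CurveFeature, grid: Grid, order: int = 32) -> np.ndarray:
    """Line-type Gaussian integral along the reconstructed curved centerline."""
    path = curve.centerline()
    s = np.linspace(0.0, 1.0, len(path))

    def pts(t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return np.stack([np.interp(t, s, path[:, i]) for i in range(3)], axis=-1)

    return _integrate_gaussian_along(
        pts, curve.amplitude, curve.widths, grid, arc_length=curve.length, order=order
    )


def render_model(model: CompositeModel, grid: Grid) -> np.ndarray:
    """Background plus the sum of per-feature renders (exact additivity)."""
    out = np.full((len(grid.zs), len(grid.ys), len(grid.xs)), float(model.background))
    for f in model.features:
        out += f.render(grid)
    return out


# ---------------------------------------------------------------------------
# curve geometry engine
# ---------------------------------------------------------------------------


def _as_poly(p) -> Polynomial:
    if isinstance(p, Polynomial):
        return p
    return Polynomial(np.asarray(p, dtype=float))


def local_curvature(x, y, t: float) -> float:
    """Signed planar curvature of a parametric curve (x(t), y(t)) at t.

    ``x`` and ``y`` are polynomials (``numpy.polynomial.Polynomial`` or
    ascending coefficient sequences).  K = (x'y'' − y'x'') / (x'² + y'²)^{3/2}.
    """
    xp, yp = _as_poly(x), _as_poly(y)
    x1, y1 = xp.deriv()(t), yp.deriv()(t)
    x2, y2 = xp.deriv(2)(t), yp.deriv(2)(t)
    speed2 = x1 * x1 + y1 * y1
    if not speed2 > 0:
        raise DegenerateTangentError(f"vanishing XY speed at t={t}")
    return float((x1 * y2 - y1 * x2) / speed2**1.5)


def curvature_from_path(points_xy: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Finite-difference curvature of a sampled XY centerline at parameters t.

    ``points_xy`` is (n, 2) sampled uniformly in t on [0, 1].
    """
    pts = np.asarray(points_xy, dtype=float)
    n = len(pts)
    dt = 1.0 / (n - 1)
    d1 = np.gradient(pts, dt, axis=0)
    d2 = np.gradient(d1, dt, axis=0)
    speed2 = d1[:, 0] ** 2 + d1[:, 1] ** 2
    if np.any(speed2 <= 0):
        raise DegenerateTangentError("vanishing XY speed along the path")
    k = (d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0]) / speed2**1.5
    ts = np.linspace(0.0, 1.0, n)
    return np.interp(np.asarray(t, dtype=float), ts, k)


def fit_curvature_fourier(
    t: np.ndarray, k: np.ndarray, n_terms: int = 2, w_grid: int = 128
) -> FourierCurvature:
    """Least-squares Fourier fit of sampled curvature K(t).

    For each trial angular frequency ``w`` on a grid the remaining
    coefficients are linear and solved in closed form; the best ``w`` is then
    polished by bounded scalar minimization.  Deterministic.
    """
    t = np.asarray(t, dtype=float)
    k = np.asarray(k, dtype=float)
    if n_terms < 1:
        raise InvalidParameterError("n_terms must be >= 1")
    if t.size < 2 * n_terms + 2:
        raise UnderDeterminedError(
            f"need at least {2 * n_terms + 2} samples for N={n_terms}, got {t.size}"
        )

    def linear_fit(w: float):
        cols = [np.ones_like(t)]
        for i in range(1, n_terms + 1):
            cols.append(np.cos(i * w * t))
            cols.append(np.sin(i * w * t))
        a = np.stack(cols, axis=1)
        coef, *_ = np.linalg.lstsq(a, k, rcond=None)
        rss = float(np.sum((a @ coef - k) ** 2))
        return coef, rss

    ws = np.linspace(0.05, 4.0 * np.pi, w_grid)
    rss_ws = [linear_fit(w)[1] for w in ws]
    i_best = int(np.argmin(rss_ws))

    from scipy.optimize import minimize_scalar

    lo = ws[max(i_best - 1, 0)]
    hi = ws[min(i_best + 1, len(ws) - 1)]
    res = minimize_scalar(
        lambda w: linear_fit(w)[1], bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-12},
    )
    w_best = float(res.x) if res.fun <= rss_ws[i_best] else float(ws[i_best])
    coef, _ = linear_fit(w_best)
    return FourierCurvature(
        k0=float(coef[0]), w=w_best, p=coef[1::2], q=coef[2::2]
    )


# π/2 rotation in the XY plane: (Tx, Ty, Tz) → (−Ty, Tx, Tz)
_ROT_XY = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])


def reconstruct_curve(
    origin: np.ndarray,
    initial_tangent: np.ndarray,
    curvature: FourierCurvature,
    length: float,
    step: float,
) -> np.ndarray:
    """Tangent-stepping reconstruction of the curve centerline.

    Starting from ``origin`` with unit tangent T, iterate
    ``T ← T + (R̄ T̂) K(t) ds`` and ``x ← x + ds T``, renormalizing T after
    each step so the arc-length parameterization stays valid; ``t = s / L``
    indexes the curvature model.  Returns ``(n+1, 3)`` points, the first
    being the origin, with cumulative arc length equal to ``length``.
    """
    if not (step > 0):
        raise InvalidParameterError("step must be positive")
    if step >= length:
        raise StepTooLargeError(f"step {step} must be smaller than length {length}")
    tangent = np.asarray(initial_tangent, dtype=float)
    norm = np.linalg.norm(tangent)
    if norm == 0 or not np.all(np.isfinite(tangent)):
        raise InvalidParameterError("initial tangent must be a non-zero finite vector")
    tangent = tangent / norm

    n_steps = int(np.round(length / step))
    ds = length / n_steps
    kvals = (curvature(np.arange(n_steps) * ds / length) * ds).tolist()

    pts = np.empty((n_steps + 1, 3))
    pts[0] = np.asarray(origin, dtype=float)
    # scalar arithmetic: the sequential update is much faster outside numpy
    x, y, z = map(float, pts[0])
    tx, ty, tz = map(float, tangent)
    for j, kds in enumerate(kvals):
        x += ds * tx
        y += ds * ty
        z += ds * tz
        pts[j + 1] = (x, y, z)
        # R̄T = (−Ty, Tx, Tz): a π/2 rotation in the XY plane
        tx, ty, tz = tx - ty * kds, ty + tx * kds, tz + tz * kds
        norm = (tx * tx + ty * ty + tz * tz) ** 0.5
        tx, ty, tz = tx / norm, ty / norm, tz / norm
    return pts
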