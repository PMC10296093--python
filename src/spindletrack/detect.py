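"""Initial feature guesses from an image stack.

Detection turns a 3D stack into typed feature guesses that seed the
non-linear fit: the spindle pole body (SPB) is found on the Z
maximum-intensity projection (MIP) by Otsu thresholding followed by an
extended-maxima H-transform; straight microtubules radiating from a pole
are found by scanning a polar-coordinate angular intensity profile; a
bipolar spindle is found from the principal axis of the largest bright
connected component; curved filaments are traced by stepping along the
local ridge orientation of the smoothed image.

Detectors work in MIP pixel coordinates internally and emit features in
physical micrometres.  All detectors are deterministic: ties between equal
maxima are broken toward the lowest linear index / lowest angle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops
from skimage.morphology import h_maxima

from .errors import (
    EmptyPathError,
    InvalidPoleError,
    NoPoleError,
    NoSpindleError,
)
from .features import (
    CurveFeature,
    FourierCurvature,
    ImageStack,
    LineFeature,
    Spot,
    curvature_from_path,
    fit_curvature_fourier,
)

__all__ = [
    "DetectionConfig",
    "InitialGuess",
    "preprocess",
    "find_pole",
    "estimate_background",
    "angular_intensity",
    "detect_lines_from_pole",
    "detect_bipolar",
    "trace_curve",
    "detect_structure",
]


@dataclass
class DetectionConfig:
    """Tunable thresholds of the detection stage.

    Lengths are in µm, raster quantities in voxels of the XY plane.
    ``stop_factor`` implements "intensity comparable to the background" as
    ``I < stop_factor × background``; ``hmax_height`` of ``None`` uses three
    times the robust noise scale (1.4826 × MAD) of the MIP.
    """

    gaussian_sigma: float = 1.5  # voxels (XY); ≈ the PSF width (matched filter)
    hmax_height: float | None = None
    phi_bin: float = np.deg2rad(2.0)  # radians
    r_bin: float = 0.5  # voxels
    peak_prominence_frac: float = 0.15
    max_initial_lines: int = 8
    min_length: float = 0.3  # µm
    max_length: float | None = None  # None → image diagonal
    min_spindle_length: float = 1.0  # µm
    steerable_scale: float = 1.5  # voxels
    trace_step: float = 1.0  # voxels
    stop_factor: float = 1.2
    sigma_guess: tuple[float, float, float] = (0.15, 0.15, 0.4)  # µm
    r_min: float = 2.0  # voxels, excluded disk around the pole
    min_peak_snr: float = 3.0  # ray peak must exceed this × robust MIP noise
    r_scales_um: tuple[float, ...] = (1.0, 2.0)  # short angular-scan radii

    def max_length_for(self, stack: ImageStack) -> float:
        if self.max_length is not None:
            return self.max_length
        ex, ey, ez = stack.grid.extent()
        return float(np.sqrt(ex**2 + ey**2))


@dataclass
class InitialGuess:
    """Typed feature guesses with provenance and an estimated background."""

    features: list
    background: float
    provenance: list[str] = field(default_factory=list)
    topology: str = "free"
    attachments: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------


def estimate_background(stack: ImageStack) -> float:
    """Background level := median intensity of the (unfiltered) image."""
    return float(np.median(stack.intensities))


def preprocess(stack: ImageStack, cfg: DetectionConfig) -> tuple[ImageStack, np.ndarray]:
    """3D Gaussian smoothing plus the Z maximum-intensity projection.

    The filter sigma is ``gaussian_sigma`` XY voxels, scaled per axis so the
    physical smoothing length is isotropic.  The input is not modified.
    """
    dx, dy, dz = stack.voxel_size
    sig_phys = cfg.gaussian_sigma * dx
    sigma = (sig_phys / dz, sig_phys / dy, sig_phys / dx)  # (z, y, x) voxels
    filtered = ndimage.gaussian_filter(stack.intensities, sigma=sigma, mode="nearest")
    fstack = ImageStack(filtered, stack.voxel_size)
    return fstack, fstack.mip()


def _robust_noise(img: np.ndarray) -> float:
    med = np.median(img)
    return float(1.4826 * np.median(np.abs(img - med)))


def _weighted_centroid_z(stack: ImageStack, ix: int, iy: int, background: float) -> float:
    """Intensity-weighted centroid (µm) of the z-column at pixel (ix, iy)."""
    nz = stack.shape[0]
    col = stack.intensities[:, iy, ix] - background
    col = np.clip(col, 0.0, None)
    dz = stack.voxel_size[2]
    if col.sum() <= 0:
        return (nz / 2.0) * dz
    zs = (np.arange(nz) + 0.5) * dz
    return float(np.sum(col * zs) / np.sum(col))


def find_pole(
    mip: np.ndarray, cfg: DetectionConfig, stack: ImageStack | None = None
) -> np.ndarray:
    """Locate the SPB on the MIP: Otsu foreground, H-maxima, brightest peak.

    Returns ``(x, y)`` in sub-pixel MIP coordinates, or ``(x, y, z)`` with z
    in voxel units from the intensity-weighted z-column centroid when the
    stack is supplied.  Ties between equally bright maxima break toward the
    lowest linear index.
    """
    mip = np.asarray(mip, dtype=float)
    if mip.max() <= mip.min():
        raise NoPoleError("image has no dynamic range")
    thr = threshold_otsu(mip)
    fg = mip > thr
    if not fg.any():
        raise NoPoleError("empty foreground after Otsu thresholding")
    h = cfg.hmax_height if cfg.hmax_height is not None else 3.0 * _robust_noise(mip)
    h = max(h, 1e-12 * (mip.max() - mip.min()), 1e-30)
    maxima = h_maxima(mip, h) & fg
    if not maxima.any():
        maxima = fg
    masked = np.where(maxima, mip, -np.inf)
    iy, ix = np.unravel_index(int(np.argmax(masked)), mip.shape)

    # sub-pixel refinement: log-parabolic interpolation (exact for a
    # Gaussian peak), falling back to a windowed centroid near borders or
    # when noise makes the log ill-defined
    cx, cy = _log_parabolic_refine(mip, ix, iy)

    if stack is None:
        return np.array([cx, cy])
    cz_um = _weighted_centroid_z(stack, ix, iy, estimate_background(stack))
    return np.array([cx, cy, cz_um / stack.voxel_size[2] - 0.5])


def _log_parabolic_refine(mip: np.ndarray, ix: int, iy: int) -> tuple[float, float]:
    bg = float(np.median(mip))

    def axis_offset(vm: float, vc: float, vp: float) -> float | None:
        if min(vm, vc, vp) <= bg:
            return None
        lm, lc, lp = np.log(vm - bg), np.log(vc - bg), np.log(vp - bg)
        denom = lm - 2 * lc + lp
        if denom >= -1e-12:
            return None
        off = 0.5 * (lm - lp) / denom
        return off if abs(off) <= 1.0 else None

    ny, nx = mip.shape
    if 1 <= ix < nx - 1 and 1 <= iy < ny - 1:
        ox = axis_offset(mip[iy, ix - 1], mip[iy, ix], mip[iy, ix + 1])
        oy = axis_offset(mip[iy - 1, ix], mip[iy, ix], mip[iy + 1, ix])
        if ox is not None and oy is not None:
            return ix + ox, iy + oy
    return _centroid_refine(mip, ix, iy)


def _centroid_refine(mip: np.ndarray, ix: int, iy: int, r: int = 2) -> tuple[float, float]:
    """Background-subtracted intensity centroid in a (2r+1)² window."""
    y0, y1 = max(iy - r, 0), min(iy + r + 1, mip.shape[0])
    x0, x1 = max(ix - r, 0), min(ix + r + 1, mip.shape[1])
    win = np.clip(mip[y0:y1, x0:x1] - np.median(mip), 0.0, None)
    if win.sum() <= 0:
        return float(ix), float(iy)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    return float(np.sum(win * xx) / win.sum()), float(np.sum(win * yy) / win.sum())


def _bilinear(img: np.ndarray, xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
    """Bilinear samples at pixel coordinates; zero outside the image."""
    return ndimage.map_coordinates(
        img, np.stack([ys, xs]), order=1, mode="constant", cval=0.0
    )


def angular_intensity(
    mip: np.ndarray, pole: np.ndarray, cfg: DetectionConfig, r_max: float | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Radially integrated, background-subtracted intensity I(φ) on [0, 2π).

    For each angular bin the (bilinearly interpolated) polar intensity
    ``I(r, φ)`` is summed from ``r_min`` to the image border (or to
    ``r_max`` pixels when given).  Returns the bin-centre angles and the
    periodic profile.
    """
    mip = np.asarray(mip, dtype=float)
    ny, nx = mip.shape
    px, py = float(pole[0]), float(pole[1])
    if not (0 <= px < nx and 0 <= py < ny):
        raise InvalidPoleError(f"pole ({px:.1f}, {py:.1f}) outside {nx}×{ny} image")
    n_phi = max(8, int(np.round(2.0 * np.pi / cfg.phi_bin)))
    phis = (np.arange(n_phi) + 0.5) * (2.0 * np.pi / n_phi)
    if r_max is None:
        r_max = float(np.hypot(nx, ny))
    rs = np.arange(cfg.r_min, r_max, cfg.r_bin)
    bg = float(np.median(mip))
    xs = px + rs[None, :] * np.cos(phis[:, None])
    ys = py + rs[None, :] * np.sin(phis[:, None])
    inside = (xs >= 0) & (xs <= nx - 1) & (ys >= 0) & (ys <= ny - 1)
    vals = _bilinear(mip, xs.ravel(), ys.ravel()).reshape(xs.shape)
    vals = np.where(inside, np.clip(vals - bg, 0.0, None), 0.0)
    # a tempered polar area weight (√r, capped) sharpens the angular
    # resolution of the blurry near-pole region without letting long bright
    # rays or far-field noise dominate the profile
    w = np.sqrt(np.minimum(rs, 30.0))
    return phis, (vals * w[None, :]).sum(axis=1)


def _angular_peaks(profile: np.ndarray, cfg: DetectionConfig) -> list[int]:
    """Indices of prominent local maxima of a periodic profile (lowest-angle ties)."""
    from scipy.signal import find_peaks

    n = len(profile)
    if profile.max() <= 0:
        return []
    # light circular smoothing stabilizes peaks against noise
    kernel = np.array([0.25, 0.5, 0.25])
    sm = np.convolve(np.concatenate([profile[-1:], profile, profile[:1]]), kernel, "same")[1:-1]
    ext = np.concatenate([sm, sm, sm])
    prom = cfg.peak_prominence_frac * sm.max()
    idx, _ = find_peaks(ext, prominence=prom)
    peaks = sorted({i - n for i in idx if n <= i < 2 * n})
    # absolute criterion: a peak must rise clear of the profile's noise.
    # The noise scale comes from bin-to-bin differences of the raw profile
    # (the ray signal is smooth in angle) and the base level from a low
    # percentile (the valleys between rays), so a profile rich in real rays
    # does not inflate its own threshold.
    d = np.diff(np.concatenate([profile, profile[:1]]))
    sigma = 1.4826 * np.median(np.abs(d - np.median(d))) / np.sqrt(2.0)
    floor = np.percentile(sm, 25) + 3.0 * sigma
    return [i for i in peaks if sm[i] >= floor]


def _radial_profile(
    mip: np.ndarray, pole: np.ndarray, phi: float, cfg: DetectionConfig
) -> tuple[np.ndarray, np.ndarray]:
    ny, nx = np.asarray(mip).shape
    r_max = float(np.hypot(nx, ny))
    rs = np.arange(cfg.r_min, r_max, cfg.r_bin)
    xs = pole[0] + rs * np.cos(phi)
    ys = pole[1] + rs * np.sin(phi)
    inside = (xs >= 0) & (xs <= nx - 1) & (ys >= 0) & (ys <= ny - 1)
    vals = _bilinear(np.asarray(mip, dtype=float), xs, ys)
    vals[~inside] = 0.0
    return rs, vals


def _stop_threshold(background: float, signal_max: float, cfg: DetectionConfig) -> float:
    """Intensity below which a ray/trace is "comparable to the background".

    Multiplicative in the background level, with a small signal-relative
    floor so the criterion stays meaningful when the background is ~zero.
    """
    return cfg.stop_factor * max(background, 0.05 * (signal_max - background))


def _line_length_along(
    mip: np.ndarray, pole: np.ndarray, phi: float, background: float, cfg: DetectionConfig
) -> tuple[float, float]:
    """Radius (px) where I(r, φ) first becomes comparable to background.

    Returns ``(radius, peak)`` with ``peak`` the profile maximum inside the
    accepted radius (an amplitude guess before background subtraction).
    """
    rs, vals = _radial_profile(mip, pole, phi, cfg)
    thr = _stop_threshold(background, float(vals.max(initial=0.0)), cfg)
    above = vals >= thr
    if not above.any():
        return 0.0, 0.0
    # contiguous above-threshold run containing the brightest sample,
    # bridging dips of up to one voxel (the pole region of a residual image
    # is already fitted away, so the run need not start at r_min)
    gap = max(1, int(np.ceil(1.0 / cfg.r_bin)))
    imax = int(np.argmax(vals))
    j1 = imax
    while j1 < len(rs) - 1:
        nxt = above[j1 + 1 : j1 + 1 + gap]
        if not nxt.any():
            break
        j1 += 1 + int(np.argmax(nxt))
    return float(rs[j1] + cfg.r_bin / 2.0), float(vals[: j1 + 1].max())


def _subtract_spot_mip(
    mip: np.ndarray, pole_xy: np.ndarray, cfg: DetectionConfig, dx: float
) -> np.ndarray:
    """MIP with the pole spot's (smoothed) in-plane Gaussian removed.

    The bright pole dominates the polar scan near the origin; subtracting
    an isotropic Gaussian of the spot's smoothed width removes the shoulder
    artifacts without touching the microtubule rays.
    """
    mip = np.asarray(mip, dtype=float)
    bg = float(np.median(mip))
    peak = float(
        _bilinear(mip, np.array([pole_xy[0]]), np.array([pole_xy[1]]))[0] - bg
    )
    if peak <= 0:
        return mip
    # render convention exp(−r²/σ²); smoothing adds 2·σ_f² to σ²
    sig2 = (cfg.sigma_guess[0] / dx) ** 2 + 2.0 * cfg.gaussian_sigma**2
    yy, xx = np.mgrid[0 : mip.shape[0], 0 : mip.shape[1]]
    r2 = (xx - pole_xy[0]) ** 2 + (yy - pole_xy[1]) ** 2
    return mip - peak * np.exp(-r2 / sig2)


def detect_lines_from_pole(
    mip: np.ndarray,
    stack: ImageStack,
    pole: np.ndarray,
    cfg: DetectionConfig,
    exclude_phis: list[float] | None = None,
    background: float | None = None,
) -> list[LineFeature]:
    """One line guess per prominent angular-intensity peak at the pole.

    ``pole`` is (x, y[, z]) in MIP pixel coordinates (z in voxels).  Each
    guess starts at the pole and ends where the radial profile first drops
    to the background level; guesses outside the length cutoffs are
    discarded.  ``exclude_phis`` suppresses peaks within ±3 angular bins of
    the given angles (e.g. a bipolar spindle axis).
    """
    dx, dy, dz = stack.voxel_size
    if background is None:
        background = estimate_background(stack)
    # the bright pole spot itself dominates the polar scan near the origin;
    # remove its smoothed in-plane Gaussian first
    mip = _subtract_spot_mip(np.asarray(mip, dtype=float), pole[:2], cfg, dx)
    # multi-scale angular scan: short integration radii make short
    # microtubules stand out that a border-length integral would drown
    phis = None
    peak_bins: list[int] = []
    n_phi = max(8, int(np.round(2.0 * np.pi / cfg.phi_bin)))
    for scale_um in (None, *sorted(cfg.r_scales_um, reverse=True)):
        r_cap = None if scale_um is None else scale_um / dx
        phis, prof = angular_intensity(mip, pole, cfg, r_max=r_cap)
        for i in _angular_peaks(prof, cfg):
            if all(min(abs(i - j), n_phi - abs(i - j)) > 3 for j in peak_bins):
                peak_bins.append(i)
    peaks = sorted(peak_bins)
    # the Z projection raises the intensity floor, so radial stopping uses
    # the MIP's own median; the 3D stack median stays the model background
    bg_mip = float(np.median(np.asarray(mip, dtype=float)))
    noise_mip = _robust_noise(np.asarray(mip, dtype=float))
    if pole.shape[0] > 2:
        pz_um = (float(pole[2]) + 0.5) * dz
    else:
        pz_um = _weighted_centroid_z(
            stack, int(round(pole[0])), int(round(pole[1])), background
        )
    lines: list[LineFeature] = []
    max_len = cfg.max_length_for(stack)
    for i in peaks:
        phi = phis[i]
        if exclude_phis and any(
            min(abs(phi - e) % (2 * np.pi), 2 * np.pi - abs(phi - e) % (2 * np.pi))
            < 3 * cfg.phi_bin
            for e in exclude_phis
        ):
            continue
        r_px, ray_peak = _line_length_along(mip, pole, phi, bg_mip, cfg)
        length = r_px * dx  # assumes square XY pixels
        if length < cfg.min_length or length > max_len:
            continue
        # matched-filter detection criterion: the ray must rise clear of the
        # projection's robust noise floor
        if ray_peak - bg_mip < cfg.min_peak_snr * noise_mip:
            continue
        tip_px = np.array([pole[0] + r_px * np.cos(phi), pole[1] + r_px * np.sin(phi)])
        ix = int(np.clip(round(tip_px[0]), 0, stack.shape[2] - 1))
        iy = int(np.clip(round(tip_px[1]), 0, stack.shape[1] - 1))
        tip_z_um = _weighted_centroid_z(stack, ix, iy, background)
        start = np.array([(pole[0] + 0.5) * dx, (pole[1] + 0.5) * dy, pz_um])
        end = np.array([(tip_px[0] + 0.5) * dx, (tip_px[1] + 0.5) * dy, tip_z_um])
        # amplitude guess: the ray's peak brightness above the MIP floor,
        # converted to the line model's amplitude convention (the normalized
        # arc-length integral dilutes peak brightness by ≈ √π·σ∥/L)
        peak = max(ray_peak - bg_mip, 0.05 * max(ray_peak, 1e-6))
        amp = peak * length / (np.sqrt(np.pi) * cfg.sigma_guess[0])
        lines.append(
            (ray_peak, LineFeature(amplitude=amp, start=start, end=end, widths=np.array(cfg.sigma_guess)))
        )
    lines.sort(key=lambda t: -t[0])
    return [ln for _, ln in lines[: cfg.max_initial_lines]]


def detect_bipolar(
    mip: np.ndarray, stack: ImageStack, cfg: DetectionConfig,
    background: float | None = None,
) -> InitialGuess:
    """Bipolar spindle: two SPB spots plus the connecting line, plus polar lines.

    The largest bright connected component gives the spindle orientation via
    its principal axis; the SPBs are the maximally distant high-intensity
    pixels of the component along that axis.
    """
    mip = np.asarray(mip, dtype=float)
    dx, dy, dz = stack.voxel_size
    if mip.max() <= mip.min():
        raise NoSpindleError("image has no dynamic range")
    thr = threshold_otsu(mip)
    mask = mip > thr
    if not mask.any():
        raise NoSpindleError("no foreground component")
    lab = label(mask)
    props = regionprops(lab, intensity_image=mip)
    comp = max(props, key=lambda p: p.area)
    ys, xs = np.nonzero(lab == comp.label)
    weights = mip[ys, xs] - np.median(mip)
    weights = np.clip(weights, 0.0, None)
    centre = np.array([np.average(xs, weights=weights), np.average(ys, weights=weights)])
    pts = np.stack([xs - centre[0], ys - centre[1]], axis=1).astype(float)
    cov = (pts * weights[:, None]).T @ pts / max(weights.sum(), 1e-12)
    evals, evecs = np.linalg.eigh(cov)
    axis = evecs[:, int(np.argmax(evals))]

    # high-intensity pixels: top half of the component's dynamic range
    hi = weights >= 0.5 * weights.max()
    proj = pts[hi] @ axis
    order = np.argsort(proj)
    p_lo = pts[hi][order[0]] + centre
    p_hi = pts[hi][order[-1]] + centre
    # the extreme above-half-maximum pixels overshoot the pole centres by
    # roughly the smoothing width; centroid refinement pulls them back
    p_lo = np.array(_centroid_refine(mip, int(round(p_lo[0])), int(round(p_lo[1]))))[[0, 1]]
    p_hi = np.array(_centroid_refine(mip, int(round(p_hi[0])), int(round(p_hi[1]))))[[0, 1]]
    sep_um = float(np.hypot(*(p_hi - p_lo))) * dx
    if sep_um < cfg.min_spindle_length:
        raise NoSpindleError(
            f"endpoint separation {sep_um:.2f} µm below minimum spindle length"
        )

    if background is None:
        background = estimate_background(stack)
    widths = np.array(cfg.sigma_guess)

    def to_um(p_px: np.ndarray) -> np.ndarray:
        ix = int(np.clip(round(p_px[0]), 0, stack.shape[2] - 1))
        iy = int(np.clip(round(p_px[1]), 0, stack.shape[1] - 1))
        z_um = _weighted_centroid_z(stack, ix, iy, background)
        return np.array([(p_px[0] + 0.5) * dx, (p_px[1] + 0.5) * dy, z_um])

    s1, s2 = to_um(p_lo), to_um(p_hi)
    amp_spot = max(float(mip[int(round(p_lo[1])), int(round(p_lo[0]))] - background), 1e-6)
    amp_line = max(float(mip[int(round(centre[1])), int(round(centre[0]))] - background), 1e-6)
    features: list = [
        Spot(amplitude=amp_spot, center=s1, widths=widths),
        Spot(amplitude=amp_spot, center=s2, widths=widths),
        LineFeature(amplitude=amp_line, start=s1, end=s2, widths=widths),
    ]
    provenance = ["bipolar:spb", "bipolar:spb", "bipolar:spindle"]
    attachments = {2: 0}
    spindle_phi = float(np.arctan2(axis[1], axis[0]))
    for spot_idx, pole_px in ((0, p_lo), (1, p_hi)):
        # remove the far pole's spot; the near one is handled by the scan
        other = p_hi if spot_idx == 0 else p_lo
        mip_lines = _subtract_spot_mip(mip, other, cfg, dx)
        toward_other = spindle_phi + (np.pi if spot_idx == 1 else 0.0)
        polar_lines = detect_lines_from_pole(
            mip_lines, stack, pole_px, cfg,
            exclude_phis=[toward_other],  # suppress the spindle direction
            background=background,
        )
        for ln in polar_lines:
            ln.start = features[spot_idx].center.copy()
            features.append(ln)
            provenance.append(f"bipolar:polar_line:{spot_idx}")
            attachments[len(features) - 1] = spot_idx
    return InitialGuess(
        features=features,
        background=background,
        provenance=provenance,
        topology="bipolar",
        attachments=attachments,
    )


# ---------------------------------------------------------------------------
# ridge tracing for curved filaments
# ---------------------------------------------------------------------------


def _ridge_orientation(mip_s: np.ndarray, x: float, y: float, scale: float) -> np.ndarray:
    """Local ridge direction from eigen-analysis of the smoothed Hessian."""
    # second derivatives by finite differences of the pre-smoothed image
    def s(xx, yy):
        return _bilinear(mip_s, np.atleast_1d(xx), np.atleast_1d(yy))[0]

    h = max(1.0, scale / 2.0)
    hxx = (s(x + h, y) - 2 * s(x, y) + s(x - h, y)) / h**2
    hyy = (s(x, y + h) - 2 * s(x, y) + s(x, y - h)) / h**2
    hxy = (s(x + h, y + h) - s(x + h, y - h) - s(x - h, y + h) + s(x - h, y - h)) / (4 * h**2)
    hess = np.array([[hxx, hxy], [hxy, hyy]])
    evals, evecs = np.linalg.eigh(hess)
    # ridge: most negative curvature across the filament; tangent is the
    # eigenvector of the *larger* (less negative) eigenvalue
    return evecs[:, int(np.argmax(evals))]


def trace_curve(
    mip: np.ndarray,
    stack: ImageStack,
    start: np.ndarray,
    initial_direction: np.ndarray,
    cfg: DetectionConfig,
    n_terms: int = 2,
) -> tuple[np.ndarray, CurveFeature]:
    """Step along the local ridge orientation from a start point.

    Returns the traced XY pixel path and a curve guess built by fitting a
    degree-4 polynomial in XY (degree 1 in Z), sampling its planar
    curvature, and fitting the Fourier curvature model.
    """
    mip = np.asarray(mip, dtype=float)
    ny, nx = mip.shape
    dx, dy, dz = stack.voxel_size
    background = estimate_background(stack)
    d = np.asarray(initial_direction[:2], dtype=float)
    if np.linalg.norm(d) == 0:
        raise EmptyPathError("zero initial direction")
    d = d / np.linalg.norm(d)
    mip_s = ndimage.gaussian_filter(mip, cfg.steerable_scale, mode="nearest")
    bg_mip = float(np.median(mip))
    thr = _stop_threshold(bg_mip, float(mip.max()), cfg)

    p = np.asarray(start[:2], dtype=float).copy()
    if _bilinear(mip, np.array([p[0]]), np.array([p[1]]))[0] < thr:
        raise EmptyPathError("start point lies in background")

    path = [p.copy()]
    max_steps = int(2 * np.hypot(nx, ny) / cfg.trace_step)
    offsets = np.linspace(-2.0, 2.0, 9)
    for _ in range(max_steps):
        o = _ridge_orientation(mip_s, p[0], p[1], cfg.steerable_scale)
        if o @ d < 0:
            o = -o
        d = o
        p_next = p + cfg.trace_step * d
        if not (0 <= p_next[0] <= nx - 1 and 0 <= p_next[1] <= ny - 1):
            break
        # snap to the ridge: intensity-weighted centroid along the normal,
        # countering the flattening drift of pure orientation stepping
        normal = np.array([-d[1], d[0]])
        sx = p_next[0] + offsets * normal[0]
        sy = p_next[1] + offsets * normal[1]
        vals = np.clip(_bilinear(mip_s, sx, sy) - np.median(mip_s), 0.0, None)
        if vals.sum() > 0:
            shift = float(np.sum(vals * offsets) / vals.sum())
            p_next = p_next + np.clip(shift, -1.0, 1.0) * normal
        if _bilinear(mip, np.array([p_next[0]]), np.array([p_next[1]]))[0] < thr:
            break
        p = p_next
        path.append(p.copy())
    path_arr = np.asarray(path)
    if len(path_arr) < 3:
        raise EmptyPathError("trace terminated immediately")

    return path_arr, curve_from_path(path_arr, stack, cfg, n_terms=n_terms)


def curve_from_path(
    path_px: np.ndarray, stack: ImageStack, cfg: DetectionConfig, n_terms: int = 2
) -> CurveFeature:
    """Convert a traced pixel path into a curve guess.

    Fits x(t), y(t) with degree-4 polynomials and z(t) with degree 1 over
    normalized arc length, samples the analytic planar curvature, and fits
    the truncated Fourier curvature model.
    """
    dx, dy, dz = stack.voxel_size
    background = estimate_background(stack)
    xy_um = (path_px + 0.5) * np.array([dx, dy])
    seg = np.linalg.norm(np.diff(xy_um, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    length = float(s[-1])
    t = s / length

    deg_xy = min(4, len(path_px) - 1)
    px = np.polynomial.Polynomial.fit(t, xy_um[:, 0], deg_xy).convert()
    py = np.polynomial.Polynomial.fit(t, xy_um[:, 1], deg_xy).convert()
    zcol = np.array(
        [
            _weighted_centroid_z(
                stack,
                int(np.clip(round(p[0]), 0, stack.shape[2] - 1)),
                int(np.clip(round(p[1]), 0, stack.shape[1] - 1)),
                background,
            )
            for p in path_px
        ]
    )
    pz = np.polynomial.Polynomial.fit(t, zcol, min(1, len(path_px) - 1)).convert()

    ts = np.linspace(0.0, 1.0, max(32, 2 * len(path_px)))
    sampled = np.stack([px(ts), py(ts)], axis=1)
    kt = curvature_from_path(sampled, ts)
    # curvature model is indexed by normalized arc length; convert planar
    # parametric curvature (already 1/µm since x, y are in µm)
    fourier = fit_curvature_fourier(ts, kt, n_terms=n_terms)

    t0 = np.array([px.deriv()(0.0), py.deriv()(0.0), pz.deriv()(0.0) * 0.0])
    azim = float(np.arctan2(t0[1], t0[0]))
    origin = np.array([px(0.0), py(0.0), pz(0.0)])
    mid_idx = len(path_px) // 2
    peak = max(
        float(
            np.asarray(stack.mip())[
                int(np.clip(round(path_px[mid_idx][1]), 0, stack.shape[1] - 1)),
                int(np.clip(round(path_px[mid_idx][0]), 0, stack.shape[2] - 1)),
            ]
        )
        - background,
        1e-6,
    )
    amp = peak * length / (np.sqrt(np.pi) * cfg.sigma_guess[0])
    return CurveFeature(
        amplitude=amp,
        origin=origin,
        azimuth=azim,
        polar=np.pi / 2.0,
        curvature=fourier,
        length=length,
        widths=np.array(cfg.sigma_guess),
    )


# ---------------------------------------------------------------------------


def detect_structure(
    stack: ImageStack, structure: str, cfg: DetectionConfig | None = None
) -> InitialGuess:
    """Structure-specific detection entry point used by the pipeline.

    ``monopolar``: pole spot + radiating lines; ``bipolar``: two SPBs and
    the spindle line (+ polar lines); ``astral``: bipolar plus traced
    curves from each pole.
    """
    cfg = cfg or DetectionConfig()
    fstack, mip = preprocess(stack, cfg)
    background = estimate_background(stack)

    if structure == "monopolar":
        pole = find_pole(mip, cfg, stack=fstack)
        dx, dy, dz = stack.voxel_size
        pole_um = np.array([(pole[0] + 0.5) * dx, (pole[1] + 0.5) * dy, (pole[2] + 0.5) * dz])
        amp = max(float(_bilinear(mip, pole[:1], pole[1:2])[0]) - background, 1e-6)
        spot = Spot(amplitude=amp, center=pole_um, widths=np.array(cfg.sigma_guess))
        lines = detect_lines_from_pole(mip, fstack, pole, cfg, background=background)
        for ln in lines:
            ln.start = pole_um.copy()
        features = [spot] + lines
        return InitialGuess(
            features=features,
            background=background,
            provenance=["monopolar:spb"] + ["monopolar:line"] * len(lines),
            topology="monopolar",
            attachments={i: 0 for i in range(1, len(features))},
        )
    if structure == "bipolar":
        return detect_bipolar(mip, fstack, cfg, background=background)
    if structure == "astral":
        guess = detect_bipolar(mip, fstack, cfg, background=background)
        guess.topology = "astral"
        # try tracing a curved filament outward from each SPB
        dx = stack.voxel_size[0]
        spb1, spb2 = guess.features[0].center, guess.features[1].center
        axis_xy = (spb2 - spb1)[:2]
        axis_xy = axis_xy / max(np.linalg.norm(axis_xy), 1e-12)
        for idx, (spb, outward) in enumerate(((spb1, -axis_xy), (spb2, axis_xy))):
            start_px = np.array(
                [spb[0] / stack.voxel_size[0] - 0.5, spb[1] / stack.voxel_size[1] - 0.5]
            )
            # fan search: the filament leaves the pole at an unknown angle
            # on the outward side; pick the brightest departure direction,
            # starting clear of the bright SPB
            base = np.arctan2(outward[1], outward[0])
            best_dir, best_val = None, -np.inf
            mm = np.asarray(mip, dtype=float)
            for off in np.linspace(-np.pi / 3, np.pi / 3, 13):
                d = np.array([np.cos(base + off), np.sin(base + off)])
                probe = start_px + 4.0 * d
                if not (0 <= probe[0] < mm.shape[1] and 0 <= probe[1] < mm.shape[0]):
                    continue
                val = float(_bilinear(mm, probe[:1], probe[1:2])[0])
                if val > best_val:
                    best_val, best_dir = val, d
            if best_dir is None:
                continue
            start = start_px + 3.0 * best_dir
            try:
                _, curve = trace_curve(mip, fstack, start, best_dir, cfg)
            except EmptyPathError:
                continue
            if curve.length < cfg.min_length:
                continue
            curve.origin = spb.copy()
            guess.features.append(curve)
            guess.provenance.append(f"astral:curve:{idx}")
            guess.attachments[len(guess.features) - 1] = idx
        return guess
    raise InvalidPoleError(f"unknown structure {structure!r}")
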