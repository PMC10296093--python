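"""Scoring detections against ground truth and dynamic-instability analysis.

Detection scoring follows the tip-distance criterion: a detected
microtubule whose (free-end) tip lies within ``match_radius`` (default
0.5 µm) of an unmatched true tip is *correct*; detections matching no true
tip are *spurious*; true microtubules matched by no detection are
*missed*.  Localization errors of correct detections are reported per axis
in µm and in per-axis pixel units, with the 3D error defined as the
Euclidean norm of the pixel-normalized per-axis errors (sub-pixel accuracy
means this norm is below one).

Dynamic-instability events are maximal contiguous runs of a length-vs-time
series with at least three points, a linear-fit coefficient of
determination of at least 0.8, and a total length change of at least
0.5 µm; the slope sign distinguishes polymerization from depolymerization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import linregress

from .errors import InvalidParameterError
from .simulate import GroundTruth, SimulationConfig, simulate_image

__all__ = [
    "DetectionReport",
    "DynamicEvent",
    "classify_detections",
    "position_errors",
    "snr_sweep",
    "detect_dynamic_events",
    "summarize_dynamics",
]


@dataclass
class DetectionReport:
    """Per-microtubule correct/spurious/missed bookkeeping for one image."""

    truth_labels: list[str]  # per true MT: "correct" | "missed"
    detection_labels: list[str]  # per detected MT: "correct" | "spurious"
    matches: list[tuple[int, int]]  # (detection index, truth index)
    errors_um: np.ndarray  # (n_matches, 3) signed per-axis tip errors, µm
    truth_lengths: np.ndarray
    detected_lengths: np.ndarray

    @property
    def n_truth(self) -> int:
        return len(self.truth_labels)

    @property
    def n_detected(self) -> int:
        return len(self.detection_labels)

    @property
    def n_correct(self) -> int:
        return len(self.matches)

    @property
    def n_missed(self) -> int:
        return self.n_truth - self.n_correct

    @property
    def n_spurious(self) -> int:
        return self.n_detected - self.n_correct


def classify_detections(
    detected_features: list,
    truth: GroundTruth,
    match_radius: float = 0.5,
) -> DetectionReport:
    """Greedy nearest-first one-to-one tip matching within ``match_radius`` µm.

    A detected microtubule farther than the radius from every (unmatched)
    true tip is spurious; unmatched truths are missed.  Conservation holds:
    correct + missed = #truth and correct + spurious = #detections.
    """
    if match_radius <= 0:
        raise InvalidParameterError("match radius must be positive")
    det_mts = [
        f for f in detected_features if hasattr(f, "tip") and not _is_spot(f)
    ]
    true_mts = truth.microtubules
    det_tips = np.array([f.tip for f in det_mts]).reshape(-1, 3)
    true_tips = truth.tips().reshape(-1, 3)

    matches: list[tuple[int, int]] = []
    if len(det_mts) and len(true_mts):
        d = np.linalg.norm(det_tips[:, None, :] - true_tips[None, :, :], axis=2)
        d = d.copy()
        while True:
            i, j = np.unravel_index(int(np.argmin(d)), d.shape)
            if not np.isfinite(d[i, j]) or d[i, j] > match_radius:
                break
            matches.append((int(i), int(j)))
            d[i, :] = np.inf
            d[:, j] = np.inf
            if not np.isfinite(d).any():
                break
    matched_d = {i for i, _ in matches}
    matched_t = {j for _, j in matches}
    errors = np.array(
        [det_tips[i] - true_tips[j] for i, j in matches], dtype=float
    ).reshape(-1, 3)
    return DetectionReport(
        truth_labels=[
            "correct" if j in matched_t else "missed" for j in range(len(true_mts))
        ],
        detection_labels=[
            "correct" if i in matched_d else "spurious" for i in range(len(det_mts))
        ],
        matches=matches,
        errors_um=errors,
        truth_lengths=np.array([mt.length for mt in true_mts], dtype=float),
        detected_lengths=np.array([mt.length for mt in det_mts], dtype=float),
    )


def _is_spot(f) -> bool:
    from .features import Spot

    return isinstance(f, Spot)


def position_errors(
    report: DetectionReport, voxel_size: tuple[float, float, float]
) -> pd.DataFrame:
    """Per-match localization errors in µm and pixel units.

    Columns: absolute per-axis errors (µm and pixels) and the 3D error,
    the Euclidean norm of pixel-normalized per-axis errors.  Empty (flagged
    by zero rows) when there is no correct match.
    """
    err = np.abs(report.errors_um)
    vox = np.asarray(voxel_size, dtype=float)
    px = report.errors_um / vox
    return pd.DataFrame(
        {
            "err_x_um": err[:, 0],
            "err_y_um": err[:, 1],
            "err_z_um": err[:, 2],
            "err_x_px": np.abs(px[:, 0]),
            "err_y_px": np.abs(px[:, 1]),
            "err_z_px": np.abs(px[:, 2]),
            "err_3d_px": np.linalg.norm(px, axis=1),
        }
    )


def snr_sweep(
    sim_cfg: SimulationConfig,
    snr_levels: list[float],
    reps_per_level: int,
    base_seed: int = 1,
    match_radius: float = 0.5,
    detection_cfg=None,
    optimizer_cfg=None,
    records: list | None = None,
) -> pd.DataFrame:
    """Run simulate → detect → fit → classify over an SNR grid.

    Per-image seeds are ``base_seed + rep`` so the sweep is reproducible
    and trivially resumable.  Per-image failures are logged into the record
    list (``status='failed'``) and never abort the sweep.  Returns one row
    per SNR level with detection rates (percent) and mean localization
    errors; per-image records accumulate into ``records`` when given.
    """
    from dataclasses import replace as _replace

    from .pipeline import analyze_frame

    if reps_per_level < 1:
        raise InvalidParameterError("need at least one repetition per level")
    rows = []
    for snr in snr_levels:
        n_true = n_correct = n_spur = n_det = n_fail = 0
        err3d: list[float] = []
        errxy: list[float] = []
        errz: list[float] = []
        missed_len: list[float] = []
        correct_len: list[float] = []
        for rep in range(reps_per_level):
            cfg = _replace(sim_cfg, target_snr=snr, seed=base_seed + rep)
            stack, truth = simulate_image(cfg)
            try:
                fit = analyze_frame(
                    stack,
                    structure=cfg.structure,
                    detection_cfg=detection_cfg,
                    optimizer_cfg=optimizer_cfg,
                )
                detected = fit.model.features
            except Exception as exc:  # detector found nothing usable
                detected = []
                n_fail += 1
                if records is not None:
                    records.append(
                        {"snr": snr, "seed": cfg.seed, "status": "failed", "error": str(exc)}
                    )
            report = classify_detections(detected, truth, match_radius)
            n_true += report.n_truth
            n_correct += report.n_correct
            n_spur += report.n_spurious
            n_det += report.n_detected
            pe = position_errors(report, cfg.voxel_size)
            err3d.extend(pe["err_3d_px"].tolist())
            errxy.extend(np.hypot(pe["err_x_px"], pe["err_y_px"]).tolist())
            errz.extend(pe["err_z_px"].tolist())
            for lbl, ln in zip(report.truth_labels, report.truth_lengths):
                (correct_len if lbl == "correct" else missed_len).append(float(ln))
            if records is not None:
                records.append(
                    {
                        "snr": snr,
                        "seed": cfg.seed,
                        "status": "ok",
                        "n_truth": report.n_truth,
                        "n_correct": report.n_correct,
                        "n_spurious": report.n_spurious,
                    }
                )
        rows.append(
            {
                "snr": snr,
                "n_images": reps_per_level,
                "n_true_mts": n_true,
                "n_detections": n_det,
                "n_failed": n_fail,
                "correct_pct": 100.0 * n_correct / n_true if n_true else np.nan,
                "missed_pct": 100.0 * (n_true - n_correct) / n_true if n_true else np.nan,
                "spurious_pct": 100.0 * n_spur / n_det if n_det else 0.0,
                "mean_err_xy_px": float(np.mean(errxy)) if errxy else np.nan,
                "mean_err_z_px": float(np.mean(errz)) if errz else np.nan,
                "mean_err_3d_px": float(np.mean(err3d)) if err3d else np.nan,
                "mean_len_correct": float(np.mean(correct_len)) if correct_len else np.nan,
                "mean_len_missed": float(np.mean(missed_len)) if missed_len else np.nan,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# dynamic instability
# ---------------------------------------------------------------------------


@dataclass
class DynamicEvent:
    """One polymerization or depolymerization run in a length time-series."""

    kind: str  # "polymerization" | "depolymerization"
    t_start: float
    t_end: float
    delta_um: float  # signed length change over the run
    speed_um_per_s: float  # linear-fit slope
    r_squared: float
    n_points: int

    @property
    def speed_um_per_min(self) -> float:
        return self.speed_um_per_s * 60.0


def _linfit(t: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Slope and R² of a least-squares line; R²=1 for an exact fit."""
    res = linregress(t, y)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        return float(res.slope), 1.0
    return float(res.slope), float(res.rvalue**2)


def detect_dynamic_events(
    times: np.ndarray,
    lengths: np.ndarray,
    min_points: int = 3,
    min_delta: float = 0.5,
    min_r2: float = 0.8,
) -> list[DynamicEvent]:
    """Call growth/shrinkage events on a length-vs-time series.

    Maximal contiguous runs are grown greedily from the left while the
    linear fit keeps R² ≥ ``min_r2``; a finished run qualifies as an event
    when it has ≥ ``min_points`` points and a total length change of at
    least ``min_delta`` µm.  The boundary point shared by two adjacent runs
    belongs to the earlier event.  Adding a constant to all lengths changes
    nothing; reversing time swaps polymerization and depolymerization.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(lengths, dtype=float)
    if t.ndim != 1 or t.shape != y.shape:
        raise InvalidParameterError("times and lengths must be 1D and equal length")
    n = len(t)
    events: list[DynamicEvent] = []
    i = 0
    while i <= n - min_points:
        j = i + min_points - 1
        slope, r2 = _linfit(t[i : j + 1], y[i : j + 1])
        if r2 >= min_r2:
            while j + 1 < n:
                slope2, r22 = _linfit(t[i : j + 2], y[i : j + 2])
                if r22 >= min_r2:
                    j += 1
                    slope, r2 = slope2, r22
                else:
                    break
            # a run may absorb a point past a switch before R² drops; end
            # the run at its extremal length so adjacent events split at
            # the catastrophe/rescue point
            seg = y[i : j + 1]
            j_ext = i + int(np.argmax(seg) if slope > 0 else np.argmin(seg))
            if j_ext >= i + min_points - 1:
                j = j_ext
                slope, r2 = _linfit(t[i : j + 1], y[i : j + 1])
            delta = float(y[j] - y[i])
            if abs(delta) >= min_delta and slope != 0.0:
                events.append(
                    DynamicEvent(
                        kind="polymerization" if slope > 0 else "depolymerization",
                        t_start=float(t[i]),
                        t_end=float(t[j]),
                        delta_um=delta,
                        speed_um_per_s=slope,
                        r_squared=r2,
                        n_points=j - i + 1,
                    )
                )
                i = j  # shared boundary point goes to the earlier event
                continue
        i += 1
    return events


@dataclass
class DynamicsSummary:
    """Speed distributions and catastrophe-preceding growth lengths."""

    polymerization_speeds: list[float] = field(default_factory=list)  # µm/min
    depolymerization_speeds: list[float] = field(default_factory=list)  # µm/min
    growth_before_catastrophe: list[float] = field(default_factory=list)  # µm


def summarize_dynamics(events_per_track: dict[int, list[DynamicEvent]]) -> DynamicsSummary:
    """Pool event speeds per kind; record growth lengths before catastrophes.

    For every polymerization event that is followed (within the same track)
    by a depolymerization event, its total length change is recorded as the
    polymerized length preceding that catastrophe.
    """
    out = DynamicsSummary()
    for events in events_per_track.values():
        ordered = sorted(events, key=lambda e: e.t_start)
        for k, ev in enumerate(ordered):
            if ev.kind == "polymerization":
                out.polymerization_speeds.append(ev.speed_um_per_min)
                if k + 1 < len(ordered) and ordered[k + 1].kind == "depolymerization":
                    out.growth_before_catastrophe.append(ev.delta_um)
            else:
                out.depolymerization_speeds.append(ev.speed_um_per_min)
    return out
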