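"""Time linking of per-frame features and pruning of short-lived tracks.

Features fitted independently in each frame are linked into tracks with a
two-stage linear-assignment approach: first an optimal frame-to-frame
assignment on Euclidean distance between feature anchor points (spot
centres; the free-end tip for lines and curves) with births and deaths
allowed at cost ``max_link_cost``, then a gap-closing stage that joins a
track's end to a later track's start across up to ``max_gap`` missing
frames.  Tracks shorter than a minimum number of frames are discarded as
spurious single-time detections.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .features import CurveFeature, LineFeature, Spot

__all__ = ["Track", "feature_anchor", "link_features", "prune_short_tracks"]


def feature_anchor(feature) -> np.ndarray:
    """Anchor point used for linking: spot centre, or the line/curve tip."""
    if isinstance(feature, Spot):
        return np.asarray(feature.center, dtype=float)
    if isinstance(feature, (LineFeature, CurveFeature)):
        return np.asarray(feature.tip, dtype=float)
    raise TypeError(f"cannot compute anchor for {type(feature)!r}")


@dataclass
class Track:
    """An ordered sequence of (frame index, feature) pairs."""

    track_id: int
    items: list = field(default_factory=list)  # [(frame, feature), ...]
    frame_interval: float = 1.0  # seconds

    def __post_init__(self) -> None:
        frames = [f for f, _ in self.items]
        if any(b <= a for a, b in zip(frames, frames[1:])):
            raise ValueError("frame indices must be strictly increasing")

    @property
    def frames(self) -> list[int]:
        return [f for f, _ in self.items]

    @property
    def n_frames(self) -> int:
        """Number of linked (observed) frames, gaps excluded."""
        return len(self.items)

    @property
    def gap_frames(self) -> int:
        f = self.frames
        return (f[-1] - f[0] + 1 - len(f)) if f else 0

    @property
    def lifetime(self) -> float:
        """(last − first + 1) × frame interval, in seconds."""
        f = self.frames
        return (f[-1] - f[0] + 1) * self.frame_interval if f else 0.0

    def anchors(self) -> np.ndarray:
        return np.stack([feature_anchor(feat) for _, feat in self.items])


def _frame_assignment(
    a: np.ndarray, b: np.ndarray, max_cost: float
) -> list[tuple[int, int]]:
    """Optimal one-to-one matching between two point sets with birth/death.

    Uses the standard augmented cost matrix: links cost their Euclidean
    distance, unmatched points cost ``max_cost``.  Links with distance
    greater than ``max_cost`` are forbidden.
    """
    n1, n2 = len(a), len(b)
    if n1 == 0 or n2 == 0:
        return []
    big = 1e9
    d = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=2)
    top_left = np.where(d <= max_cost, d, big)
    top_right = np.full((n1, n1), big)
    np.fill_diagonal(top_right, max_cost)
    bottom_left = np.full((n2, n2), big)
    np.fill_diagonal(bottom_left, max_cost)
    bottom_right = top_left.T.copy()
    bottom_right[bottom_right < big] = 0.0
    cost = np.block([[top_left, top_right], [bottom_left, bottom_right]])
    rows, cols = linear_sum_assignment(cost)
    return [
        (int(r), int(c))
        for r, c in zip(rows, cols)
        if r < n1 and c < n2 and d[r, c] <= max_cost
    ]


def link_features(
    per_frame_features: list[list],
    max_link_cost: float = 1.0,
    max_gap: int = 1,
    frame_interval: float = 1.0,
) -> list[Track]:
    """Link per-frame features into tracks (frame-to-frame LAP + gap closing).

    ``per_frame_features[f]`` is the feature list of frame ``f``.  Returns
    tracks sorted by first frame; every linked pair's anchor distance is at
    most ``max_link_cost`` (per link, also across gaps).
    """
    if len(per_frame_features) < 1:
        raise ValueError("need at least one frame")

    # stage 1: frame-to-frame linking into segments
    segments: list[list[tuple[int, object]]] = []
    open_by_feature: dict[tuple[int, int], int] = {}  # (frame, idx) -> segment id
    for fi, feats in enumerate(per_frame_features):
        for idx in range(len(feats)):
            open_by_feature.setdefault((fi, idx), -1)
    for fi in range(len(per_frame_features) - 1):
        cur, nxt = per_frame_features[fi], per_frame_features[fi + 1]
        if not cur or not nxt:
            continue
        a = np.stack([feature_anchor(f) for f in cur])
        b = np.stack([feature_anchor(f) for f in nxt])
        for r, c in _frame_assignment(a, b, max_link_cost):
            seg_id = open_by_feature[(fi, r)]
            if seg_id < 0:
                segments.append([(fi, cur[r])])
                seg_id = len(segments) - 1
                open_by_feature[(fi, r)] = seg_id
            segments[seg_id].append((fi + 1, nxt[c]))
            open_by_feature[(fi + 1, c)] = seg_id
    # singletons: features never linked
    for (fi, idx), seg_id in open_by_feature.items():
        if seg_id < 0:
            segments.append([(fi, per_frame_features[fi][idx])])

    # stage 2: gap closing between segment ends and later segment starts
    if max_gap >= 1 and len(segments) > 1:
        merged = True
        while merged:
            merged = False
            ends = [(i, s[-1]) for i, s in enumerate(segments)]
            starts = [(i, s[0]) for i, s in enumerate(segments)]
            pairs = []
            for ei, (si, (ef, efeat)) in enumerate(ends):
                for sj, (tj, (sf, sfeat)) in enumerate(starts):
                    if si == tj:
                        continue
                    gap = sf - ef - 1
                    if 1 <= gap <= max_gap:
                        dist = float(
                            np.linalg.norm(feature_anchor(efeat) - feature_anchor(sfeat))
                        )
                        if dist <= max_link_cost:
                            pairs.append((dist, si, tj))
            if pairs:
                # greedily close the cheapest feasible gap, then re-scan
                pairs.sort(key=lambda t: t[0])
                _, si, tj = pairs[0]
                segments[si] = segments[si] + segments[tj]
                del segments[tj]
                merged = True

    segments.sort(key=lambda s: s[0][0])
    return [
        Track(track_id=i, items=s, frame_interval=frame_interval)
        for i, s in enumerate(segments)
    ]


def prune_short_tracks(tracks: list[Track], min_frames: int = 3) -> list[Track]:
    """Keep exactly the tracks observed in at least ``min_frames`` frames."""
    if min_frames < 1:
        raise ValueError("min_frames must be >= 1")
    return [t for t in tracks if t.n_frames >= min_frames]
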