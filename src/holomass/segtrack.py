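"""Cell detection, segmentation, tracking and division calling on phase images.

Mirrors the stages of a LAP-style single-particle tracker: blob
detection (Laplacian of Gaussian at the expected cell scale), seeded
region growing controlled by a single phase threshold, frame-to-frame
linking by optimal bipartite assignment with a distance cutoff, gap
closing across short detection dropouts, and a minimum-length track
filter.  Defaults match the reference configuration: blob diameter
~15 px, detector threshold 0.7, linking and gap-closing maximum
distance 15 px, maximum frame gap 5, minimum 10 spots per track.

A division is declared when a track's dry mass drops abruptly while a
new track is born nearby — the signature of mitosis in a label-free
time lapse.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import linear_sum_assignment
from skimage.segmentation import watershed

__all__ = [
    "SpotDetection",
    "LinkingConfig",
    "Track",
    "DivisionEvent",
    "detect_spots",
    "segment_cell",
    "segment_cells",
    "link_tracks",
    "detect_divisions",
    "evaluate_tracking",
    "write_spots_csv",
    "read_spots_csv",
]

_FOUR_CONN = [[0, 1, 0], [1, 1, 1], [0, 1, 0]]


@dataclass
class SpotDetection:
    """One detected cell center (0-based pixel-center coordinates)."""

    frame: int
    y: float
    x: float
    quality: float = 0.0


@dataclass
class LinkingConfig:
    blob_diameter_px: float = 15.0
    detector_threshold: float = 0.7
    max_link_px: float = 15.0
    gap_close_px: float = 15.0
    max_frame_gap: int = 5
    min_spots: int = 10
    #: minimum raw LoG response for an image to contain detections at all
    min_response: float = 1e-3

    def __post_init__(self) -> None:
        for name in ("blob_diameter_px", "detector_threshold", "max_link_px",
                     "gap_close_px", "max_frame_gap", "min_spots"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass
class Track:
    track_id: int
    spots: list = field(default_factory=list)
    division_events: list = field(default_factory=list)

    @property
    def frames(self) -> np.ndarray:
        return np.array([s.frame for s in self.spots])

    @property
    def positions(self) -> np.ndarray:
        return np.array([[s.y, s.x] for s in self.spots])

    def position_at(self, frame: int) -> np.ndarray | None:
        for s in self.spots:
            if s.frame == frame:
                return np.array([s.y, s.x])
        return None


@dataclass
class DivisionEvent:
    frame: int
    parent_track: int
    daughter_track: int


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------

def _log_calibration(sigma: float) -> float:
    """Peak scale-normalized LoG response of a unit-height Gaussian blob."""
    n = int(8 * sigma) | 1
    yy, xx = np.mgrid[0:n, 0:n] - n // 2
    blob = np.exp(-(yy ** 2 + xx ** 2) / (2 * sigma ** 2))
    resp = -sigma ** 2 * ndimage.gaussian_laplace(blob, sigma)
    return float(resp.max())


def detect_spots(phase, cfg: LinkingConfig | None = None) -> list[SpotDetection]:
    """Laplacian-of-Gaussian blob detection on one phase image.

    The detection scale is ``blob_diameter / (2 sqrt(2))`` so a blob of
    the configured diameter is matched.  Responses are normalized so an
    ideal Gaussian blob of unit (radian) height scores 1.0; local maxima
    with quality >= ``detector_threshold`` are kept, with sub-pixel
    refinement by a quadratic fit.  Pass ``frame`` positions via the
    caller; the returned detections carry frame 0.
    """
    cfg = cfg or LinkingConfig()
    values = np.asarray(getattr(phase, "values", phase), dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("phase image must be finite")
    sigma = cfg.blob_diameter_px / (2.0 * np.sqrt(2.0))
    resp = -sigma ** 2 * ndimage.gaussian_laplace(values, sigma)
    if resp.max() < cfg.min_response:
        return []
    quality = resp / _log_calibration(sigma)
    # local maxima over a neighborhood of the blob scale
    size = max(3, int(sigma))
    maxima = (quality == ndimage.maximum_filter(quality, size=size))
    maxima &= quality >= cfg.detector_threshold
    out: list[SpotDetection] = []
    for y, x in np.argwhere(maxima):
        dy = dx = 0.0
        if 0 < y < quality.shape[0] - 1:
            denom = quality[y - 1, x] - 2 * quality[y, x] + quality[y + 1, x]
            if denom < 0:
                dy = 0.5 * (quality[y - 1, x] - quality[y + 1, x]) / denom
        if 0 < x < quality.shape[1] - 1:
            denom = quality[y, x - 1] - 2 * quality[y, x] + quality[y, x + 1]
            if denom < 0:
                dx = 0.5 * (quality[y, x - 1] - quality[y, x + 1]) / denom
        out.append(SpotDetection(0, y + np.clip(dy, -1, 1),
                                 x + np.clip(dx, -1, 1), float(quality[y, x])))
    out.sort(key=lambda s: (-s.quality, s.y, s.x))
    return out


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def segment_cell(phase, seed: SpotDetection, phase_threshold: float) -> np.ndarray:
    """Region grown from one seed over 4-connected pixels above threshold.

    Returns a boolean mask; an all-False mask signals a seed below the
    threshold (no cell).
    """
    values = np.asarray(getattr(phase, "values", phase), dtype=float)
    sy, sx = int(round(seed.y)), int(round(seed.x))
    if not (0 <= sy < values.shape[0] and 0 <= sx < values.shape[1]):
        raise ValueError("seed outside the image")
    above = values >= phase_threshold
    if not above[sy, sx]:
        return np.zeros_like(above)
    labels, _ = ndimage.label(above, structure=_FOUR_CONN)
    return labels == labels[sy, sx]


def segment_cells(phase, seeds: list[SpotDetection],
                  phase_threshold: float) -> list[np.ndarray]:
    """Segment several seeds jointly, watershed-splitting shared components.

    Seeds falling in the same above-threshold component are separated on
    the watershed line of the inverted phase, so touching cells receive
    disjoint masks.
    """
    values = np.asarray(getattr(phase, "values", phase), dtype=float)
    above = values >= phase_threshold
    labels, _ = ndimage.label(above, structure=_FOUR_CONN)
    seed_labels = []
    for s in seeds:
        sy, sx = int(round(s.y)), int(round(s.x))
        seed_labels.append(labels[sy, sx] if above[sy, sx] else 0)
    masks: list[np.ndarray] = [np.zeros_like(above)] * len(seeds)
    for comp in set(seed_labels) - {0}:
        idx = [i for i, l in enumerate(seed_labels) if l == comp]
        comp_mask = labels == comp
        if len(idx) == 1:
            masks[idx[0]] = comp_mask
            continue
        markers = np.zeros(values.shape, dtype=int)
        for rank, i in enumerate(idx, start=1):
            markers[int(round(seeds[i].y)), int(round(seeds[i].x))] = rank
        ws = watershed(-values, markers=markers, mask=comp_mask,
                       connectivity=1)
        for rank, i in enumerate(idx, start=1):
            masks[i] = ws == rank
    return masks


# ---------------------------------------------------------------------------
# linking
# ---------------------------------------------------------------------------

def _assign(cost: np.ndarray, cutoff_cost: float) -> list[tuple[int, int]]:
    """LAP with a no-link alternative: pads the cost matrix so every row
    and column can opt out at ``cutoff_cost``; returns accepted pairs."""
    n, m = cost.shape
    if n == 0 or m == 0:
        return []
    big = cutoff_cost * 1.0001
    full = np.full((n + m, n + m), 2 * big)
    full[:n, :m] = np.where(cost <= cutoff_cost, cost, 2 * big)
    full[:n, m:] = np.where(np.eye(n, dtype=bool), big, 2 * big)
    full[n:, :m] = np.where(np.eye(m, dtype=bool), big, 2 * big)
    full[n:, m:] = 0.0
    rows, cols = linear_sum_assignment(full)
    return [(r, c) for r, c in zip(rows, cols)
            if r < n and c < m and cost[r, c] <= cutoff_cost]


def link_tracks(detections_by_frame: dict[int, list[SpotDetection]],
                cfg: LinkingConfig | None = None) -> list[Track]:
    """Link detections into tracks: frame-to-frame LAP then gap closing.

    Frame-to-frame assignment minimizes total squared displacement with
    a hard distance cutoff; remaining track ends are joined to later
    track starts within ``gap_close_px`` and ``max_frame_gap`` (ties
    resolved by smaller distance, then smaller frame gap).  Tracks
    shorter than ``min_spots`` are discarded.
    """
    cfg = cfg or LinkingConfig()
    frames = sorted(detections_by_frame)
    # canonical in-frame ordering makes linking independent of input order
    dets = {f: sorted(detections_by_frame[f], key=lambda s: (s.y, s.x))
            for f in frames}
    segments: list[list[SpotDetection]] = []
    open_by_index: dict[int, list[SpotDetection]] = {}
    prev_frame = None
    for f in frames:
        cur = [SpotDetection(f, s.y, s.x, s.quality) for s in dets[f]]
        new_open: dict[int, list[SpotDetection]] = {}
        if prev_frame is not None and prev_frame == f - 1 and open_by_index:
            keys = sorted(open_by_index)
            prev_pos = np.array([[open_by_index[k][-1].y, open_by_index[k][-1].x]
                                 for k in keys])
            cur_pos = np.array([[s.y, s.x] for s in cur]) if cur else np.empty((0, 2))
            if cur_pos.size:
                d2 = ((prev_pos[:, None, :] - cur_pos[None, :, :]) ** 2).sum(-1)
                pairs = _assign(d2, cfg.max_link_px ** 2)
            else:
                pairs = []
            used = set()
            for r, c in pairs:
                seg = open_by_index[keys[r]]
                seg.append(cur[c])
                new_open[id(seg)] = seg
                used.add(c)
            for k in keys:
                if id(open_by_index[k]) not in new_open:
                    segments.append(open_by_index[k])
            for c, s in enumerate(cur):
                if c not in used:
                    seg = [s]
                    new_open[id(seg)] = seg
        else:
            segments.extend(open_by_index.values())
            for s in cur:
                seg = [s]
                new_open[id(seg)] = seg
        # re-key by stable index
        open_by_index = {i: seg for i, seg in enumerate(
            sorted(new_open.values(), key=lambda g: (g[0].frame, g[0].y, g[0].x)))}
        prev_frame = f
    segments.extend(open_by_index.values())
    segments.sort(key=lambda g: (g[0].frame, g[0].y, g[0].x))

    # gap closing: join segment ends to later segment starts
    ends = [(i, seg[-1]) for i, seg in enumerate(segments)]
    starts = [(j, seg[0]) for j, seg in enumerate(segments)]
    cost = np.full((len(ends), len(starts)), np.inf)
    for a, (i, e) in enumerate(ends):
        for b, (j, s) in enumerate(starts):
            gap = s.frame - e.frame
            if i == j or gap < 1 or gap > cfg.max_frame_gap:
                continue
            d = np.hypot(e.y - s.y, e.x - s.x)
            if d <= cfg.gap_close_px:
                cost[a, b] = d ** 2 + 1e-6 * gap  # tie-break on frame gap
    pairs = _assign(cost, cfg.gap_close_px ** 2 + 1e-3)
    # merge chains deterministically
    succ = {ends[a][0]: starts[b][0] for a, b in pairs}
    merged_into = set(succ.values())
    tracks: list[Track] = []
    tid = 0
    for i, seg in enumerate(segments):
        if i in merged_into:
            continue
        chain = list(seg)
        k = i
        while k in succ:
            k = succ[k]
            chain.extend(segments[k])
        if len(chain) >= cfg.min_spots:
            tracks.append(Track(tid, chain))
            tid += 1
    return tracks


# ---------------------------------------------------------------------------
# divisions
# ---------------------------------------------------------------------------

def detect_divisions(tracks: list[Track], traces: dict[int, np.ndarray],
                     cfg: LinkingConfig | None = None,
                     drop_fraction: float = 0.30,
                     window: int = 2) -> list[DivisionEvent]:
    """Declare divisions from abrupt mass drops coinciding with track births.

    A division is recorded at frame ``f`` of track ``P`` when the
    track's mass drops by at least ``drop_fraction`` between ``f`` and
    ``f + window`` and some other track is born within ``gap_close_px``
    of ``P`` around that time.  A mass drop with no nearby birth is not
    a division.

    Because single-frame masses of touching siblings are noisy right at
    cytokinesis, the before/after levels are taken as 3-sample medians
    and the birth window is extended by one frame on each side; the
    reported frame is the largest single-step drop inside the window.
    """
    cfg = cfg or LinkingConfig()
    births = [(tr.track_id, tr.spots[0]) for tr in tracks]
    events: list[DivisionEvent] = []
    for tr in tracks:
        m = traces.get(tr.track_id)
        if m is None:
            continue
        frames = tr.frames
        n = len(frames)
        claimed = -100
        for i in range(n):
            f = int(frames[i])
            before = m[max(i - window, 0):i + 1]
            # an extended baseline guards against transient elevations
            # (two cells crossing) relaxing back and mimicking a drop
            baseline = m[max(i - 2 * (window + 2), 0):i + 1]
            after = m[i + 1:i + window + 2]
            before = before[np.isfinite(before)]
            baseline = baseline[np.isfinite(baseline)]
            after = after[np.isfinite(after)]
            if before.size == 0 or after.size == 0:
                continue
            lvl_before = float(np.median(before))
            lvl_after = float(np.median(after))
            if lvl_before <= 0 or lvl_after > (1.0 - drop_fraction) * lvl_before:
                continue
            # a crossing shows up as a transient elevation over the
            # cell's own growth trend that then relaxes; a division
            # drops from the trend itself
            if baseline.size >= 4:
                xb = np.arange(baseline.size, dtype=float)
                cb = np.polyfit(xb, baseline, 1)
                predicted = float(np.polyval(cb, baseline.size - 1))
                if predicted > 0 and lvl_before > 1.25 * predicted:
                    continue
            if f - claimed <= window:
                continue
            # a new track must appear near P around the drop; the birth
            # radius allows for the detector's resolution — two cells
            # closer than about a blob diameter are seen as one, so the
            # daughter's first own detection sits up to a blob radius
            # beyond her actual appearance distance
            lo_f, hi_f = f - 1, f + window + 1
            radius = cfg.gap_close_px + cfg.blob_diameter_px / 2.0
            track_pos = {int(ff): np.array([s.y, s.x])
                         for ff, s in zip(frames, tr.spots)
                         if lo_f <= ff <= hi_f}
            hit = None
            for tid, birth in births:
                if tid == tr.track_id or not (lo_f <= birth.frame <= hi_f):
                    continue
                d = min((np.hypot(birth.y - p[0], birth.x - p[1])
                         for p in track_pos.values()), default=np.inf)
                if d <= radius:
                    hit = tid
                    break
            if hit is None:
                continue
            # localize at the sharpest single-step drop near the trigger;
            # the division frame is the first frame at the reduced mass
            lo_i, hi_i = max(i - 4, 0), min(i + window + 1, n - 1)
            seg = m[lo_i:hi_i + 1]
            steps = np.diff(seg)
            f_loc = f
            if steps.size and np.any(np.isfinite(steps)):
                f_loc = int(frames[lo_i + int(np.nanargmin(steps)) + 1])
            events.append(DivisionEvent(f_loc, tr.track_id, hit))
            claimed = f
    # merge repeated triggers of the same event (same track, frames
    # localized within one detection window)
    merged: list[DivisionEvent] = []
    for e in sorted(events, key=lambda e: (e.parent_track, e.frame)):
        if merged and merged[-1].parent_track == e.parent_track \
                and e.frame - merged[-1].frame <= window + 2:
            continue
        merged.append(e)
    return sorted(merged, key=lambda e: (e.frame, e.parent_track))


def interphase_intervals(track: Track, events: list[DivisionEvent]) -> list[tuple[int, int]]:
    """Tile a track's lifetime into intervals bounded by its divisions."""
    frames = track.frames
    bounds = sorted({e.frame for e in events if e.parent_track == track.track_id})
    edges = [frames[0]] + [b for b in bounds if frames[0] < b < frames[-1]] \
        + [frames[-1]]
    return [(edges[i], edges[i + 1]) for i in range(len(edges) - 1)]


# ---------------------------------------------------------------------------
# evaluation against ground truth
# ---------------------------------------------------------------------------

def evaluate_tracking(tracks: list[Track], truth_positions: dict[int, np.ndarray],
                      truth_frames: dict[int, np.ndarray],
                      match_radius: float = 8.0) -> dict:
    """Purity and completeness of tracks against ground-truth trajectories.

    Every spot is attributed to the nearest ground-truth cell within
    ``match_radius`` at its frame.  A track's purity is the fraction of
    its spots attributed to its majority cell; a cell's completeness is
    the fraction of its frames covered by the track that claims it.
    """
    purities, completeness = [], []
    claims: dict[int, tuple[int, int]] = {}
    for tr in tracks:
        votes: dict[int, int] = {}
        for s in tr.spots:
            best, best_d = None, match_radius
            for cid, pos in truth_positions.items():
                fr = truth_frames[cid]
                sel = np.where(fr == s.frame)[0]
                if sel.size == 0:
                    continue
                d = np.hypot(*(pos[sel[0]] - (s.y, s.x)))
                if d <= best_d:
                    best, best_d = cid, d
            if best is not None:
                votes[best] = votes.get(best, 0) + 1
        if not votes:
            purities.append(0.0)
            continue
        major = max(votes, key=votes.get)
        purities.append(votes[major] / len(tr.spots))
        n_cov = votes[major]
        prev = claims.get(major)
        if prev is None or n_cov > prev[1]:
            claims[major] = (tr.track_id, n_cov)
    for cid, (tid, n_cov) in claims.items():
        completeness.append(n_cov / len(truth_frames[cid]))
    return {
        "purity": float(np.mean(purities)) if purities else 0.0,
        "completeness": float(np.mean(completeness)) if completeness else 0.0,
        "n_tracks": len(tracks),
        "n_matched_cells": len(claims),
    }


# ---------------------------------------------------------------------------
# TrackMate-compatible CSV
# ---------------------------------------------------------------------------

def write_spots_csv(tracks: list[Track], path) -> None:
    """Emit a 'spots in tracks statistics' table (TRACK_ID, POSITION_X,
    POSITION_Y, FRAME, QUALITY)."""
    rows = [(tr.track_id, s.x, s.y, s.frame, s.quality)
            for tr in tracks for s in tr.spots]
    pd.DataFrame(rows, columns=["TRACK_ID", "POSITION_X", "POSITION_Y",
                                "FRAME", "QUALITY"]).to_csv(path, index=False)


def read_spots_csv(path) -> list[Track]:
    df = pd.read_csv(path)
    tracks = []
    for tid, grp in df.groupby("TRACK_ID", sort=True):
        grp = grp.sort_values("FRAME")
        spots = [SpotDetection(int(r.FRAME), float(r.POSITION_Y),
                               float(r.POSITION_X), float(r.QUALITY))
                 for r in grp.itertuples()]
        tracks.append(Track(int(tid), spots))
    return tracks
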