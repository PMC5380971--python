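"""Time-lapse droplet tracking, association dynamics and marker scoring.

The live-imaging analysis follows droplets across frames (minimum-cost
bipartite matching of centroids per frame pair), derives per-pair
association state series from the boundary-gap criterion, classifies
clustered pairs as static (associated throughout a 5-min window) or
dynamic, detects persistent dissociation events, and scores a marker
channel at the dissociation site for co-occurrence and its
before/during timing.  Intensity line profiles support kymograph-style
inspection of individual events.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import ndimage
from scipy.optimize import linear_sum_assignment
from scipy.spatial import cKDTree

from .clustering import DEFAULT_THRESHOLD_PX, boundary_gap
from .io import DEFAULT_PIXEL_SIZE_UM
from .segmentation import DropletRecord

__all__ = [
    "Track",
    "PairStateSeries",
    "PairClassification",
    "DissociationEvent",
    "track_droplets",
    "pair_state_series",
    "classify_pair",
    "detect_dissociations",
    "count_persistent_dissociations",
    "score_marker",
    "line_profile",
    "static_markov_prediction",
]

ASSOCIATED, DISSOCIATED, UNKNOWN = "associated", "dissociated", "unknown"


@dataclass
class Track:
    """One droplet followed over time; gaps up to ``max_missing`` frames."""

    id: int
    frames: list[int] = field(default_factory=list)
    records: list[DropletRecord] = field(default_factory=list)
    fused_into: int | None = None  # track id this one merged into, if any

    def observation(self, frame: int) -> DropletRecord | None:
        try:
            return self.records[self.frames.index(frame)]
        except ValueError:
            return None

    @property
    def last_frame(self) -> int:
        return self.frames[-1]

    @property
    def last_centroid(self) -> tuple[float, float]:
        return self.records[-1].centroid


@dataclass
class PairStateSeries:
    """Association state of a droplet pair on frames where both exist."""

    pair: tuple[int, int]  # track ids, sorted
    frames: np.ndarray
    states: np.ndarray  # array of ASSOCIATED/DISSOCIATED strings

    def state_at(self, frame: int) -> str:
        idx = np.searchsorted(self.frames, frame)
        if idx < len(self.frames) and self.frames[idx] == frame:
            return str(self.states[idx])
        return UNKNOWN


@dataclass
class PairClassification:
    pair: tuple[int, int]
    label: str  # "static" | "dynamic"
    truncated: bool = False


@dataclass
class DissociationEvent:
    """First frame of a persistent dissociated run of a tracked pair."""

    pair: tuple[int, int]
    t_event: int  # frame index
    run_end: int  # last frame (inclusive) of the dissociated run
    site: tuple[float, float]  # midpoint of the pair at t_event - 1
    marker_positive: bool | None = None
    marker_timing: str = "none"  # "before" | "during" | "none"


# ---------------------------------------------------------------------------
# tracking
# ---------------------------------------------------------------------------

def track_droplets(
    frame_droplets: Sequence[Sequence[DropletRecord]],
    max_displacement_um: float = 0.8,
    max_missing: int = 2,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
) -> list[Track]:
    """Link per-frame detections into tracks.

    Each consecutive frame pair is solved as a minimum-cost bipartite
    matching on centroid displacement, gated at ``max_displacement_um``;
    unmatched detections open new tracks and tracks unseen for more than
    ``max_missing`` consecutive frames terminate.  Every detection in
    every frame belongs to exactly one track.  When two tracks merge
    into one detection whose area is close to the sum of theirs, the
    ending track is annotated as fused into the surviving one.
    """
    if len(frame_droplets) < 2:
        raise ValueError("tracking requires at least two frames")
    gate_px = max_displacement_um / pixel_size_um
    tracks: list[Track] = []
    open_tracks: list[Track] = []

    for t, dets in enumerate(frame_droplets):
        dets = list(dets)
        assigned = [False] * len(dets)
        if open_tracks and dets:
            cost = np.full((len(open_tracks), len(dets)), 1e9)
            for i, tr in enumerate(open_tracks):
                cr, cc = tr.last_centroid
                for j, d in enumerate(dets):
                    dist = np.hypot(d.centroid[0] - cr, d.centroid[1] - cc)
                    if dist <= gate_px:
                        cost[i, j] = dist
            rows, cols = linear_sum_assignment(cost)
            for i, j in zip(rows, cols):
                if cost[i, j] < 1e9:
                    open_tracks[i].frames.append(t)
                    open_tracks[i].records.append(dets[j])
                    assigned[j] = True
        # close stale tracks, annotating fusions
        still_open: list[Track] = []
        for tr in open_tracks:
            if tr.last_frame == t or t - tr.last_frame <= max_missing:
                still_open.append(tr)
            else:
                _annotate_fusion(tr, open_tracks, t)
        open_tracks = still_open
        for j, d in enumerate(dets):
            if not assigned[j]:
                tr = Track(id=len(tracks) + 1, frames=[t], records=[d])
                tracks.append(tr)
                open_tracks.append(tr)
    return tracks


def _annotate_fusion(ended: Track, open_tracks: list[Track], t: int) -> None:
    """If ``ended``'s last position fell inside another track's current
    mask and that mask's area is close to the sum of both, mark a fusion."""
    r, c = ended.last_centroid
    a_end = ended.records[-1].area_um2
    for other in open_tracks:
        if other is ended or other.last_frame != t:
            continue
        rec = other.records[-1]
        inside = np.any(
            (rec.rows == int(round(r))) & (rec.cols == int(round(c)))
        )
        if not inside:
            continue
        prev = other.records[-2].area_um2 if len(other.records) > 1 else rec.area_um2
        if abs(rec.area_um2 - (prev + a_end)) <= 0.35 * (prev + a_end):
            ended.fused_into = other.id
            return


# ---------------------------------------------------------------------------
# pair states
# ---------------------------------------------------------------------------

def pair_state_series(
    tracks: Sequence[Track],
    threshold_px: float = DEFAULT_THRESHOLD_PX,
    candidate_radius_px: float = 25.0,
    hysteresis_px: float = 2.5,
    smooth_frames: int = 5,
) -> list[PairStateSeries]:
    """Association state series for all track pairs that ever come close.

    Candidate pairs are those whose centroids come within
    ``candidate_radius_px`` in at least one common frame; the state on a
    frame where both are observed is associated iff the boundary gap is
    at most ``threshold_px``.  Two debouncing devices suppress
    segmentation flicker (a droplet boundary wobbling by a pixel from
    frame to frame): leaving the associated state requires the gap to
    exceed ``threshold_px + hysteresis_px``, and the state sequence is
    median-filtered over ``smooth_frames`` frames (set ``hysteresis_px=0``
    and ``smooth_frames=1`` for the raw per-frame criterion).
    """
    n_frames = max((tr.last_frame for tr in tracks), default=-1) + 1
    per_frame: dict[int, list[tuple[Track, DropletRecord]]] = {t: [] for t in range(n_frames)}
    for tr in tracks:
        for f, rec in zip(tr.frames, tr.records):
            per_frame[f].append((tr, rec))

    candidates: set[tuple[int, int]] = set()
    for t, items in per_frame.items():
        if len(items) < 2:
            continue
        pts = np.array([rec.centroid for _, rec in items])
        tree = cKDTree(pts)
        for i, j in tree.query_pairs(candidate_radius_px):
            a, b = items[i][0].id, items[j][0].id
            if a != b:
                candidates.add((min(a, b), max(a, b)))

    by_id = {tr.id: tr for tr in tracks}
    series: list[PairStateSeries] = []
    for a, b in sorted(candidates):
        ta, tb = by_id[a], by_id[b]
        common = sorted(set(ta.frames) & set(tb.frames))
        if not common:
            continue
        gaps = np.array(
            [boundary_gap(ta.observation(f), tb.observation(f)) for f in common]
        )
        assoc = np.empty(len(common), dtype=bool)
        prev = gaps[0] <= threshold_px
        for i, g in enumerate(gaps):
            if prev:
                prev = g <= threshold_px + hysteresis_px
            else:
                prev = g <= threshold_px
            assoc[i] = prev
        if smooth_frames > 1 and assoc.size >= smooth_frames:
            assoc = (
                ndimage.median_filter(
                    assoc.astype(np.int8), size=smooth_frames, mode="nearest"
                )
                > 0
            )
        states = np.where(assoc, ASSOCIATED, DISSOCIATED)
        series.append(
            PairStateSeries(
                pair=(a, b), frames=np.array(common), states=states
            )
        )
    return series


# ---------------------------------------------------------------------------
# classification and events
# ---------------------------------------------------------------------------

def classify_pair(
    series: PairStateSeries,
    window_s: float = 300.0,
    frame_interval_s: float = 2.0,
) -> PairClassification:
    """Static vs dynamic over the observation window.

    A pair that is associated in *every* observed frame of the window is
    static; any dissociated frame makes it dynamic.  The pair must be
    associated at the window start (its first observed frame).  A series
    shorter than the window is evaluated on the available frames and
    flagged truncated.
    """
    if series.frames.size == 0:
        raise ValueError("empty state series")
    if series.states[0] != ASSOCIATED:
        raise ValueError("classify_pair requires association at the window start")
    window_frames = int(round(window_s / frame_interval_s))
    first = int(series.frames[0])
    in_window = series.frames < first + window_frames
    observed_span = int(series.frames[-1]) - first + 1
    truncated = observed_span < window_frames
    label = (
        "static"
        if np.all(series.states[in_window] == ASSOCIATED)
        else "dynamic"
    )
    return PairClassification(pair=series.pair, label=label, truncated=truncated)


def detect_dissociations(
    series_set: Iterable[PairStateSeries],
    persistence_frames: int = 3,
    track_lookup: Mapping[int, Track] | None = None,
) -> list[DissociationEvent]:
    """Persistent associated→dissociated transitions.

    An event starts at the first frame of a dissociated run of length at
    least ``persistence_frames`` that follows an associated run of at
    least ``persistence_frames``; re-association afterwards is allowed
    and can yield further events.  The event site is the centroid
    midpoint at the last associated frame (when track records are
    available through ``track_lookup``).
    """
    if persistence_frames < 1:
        raise ValueError("persistence_frames must be >= 1")
    events: list[DissociationEvent] = []
    for s in series_set:
        runs = _runs(s.states)
        for k, (state, start, length) in enumerate(runs):
            if state != DISSOCIATED or length < persistence_frames:
                continue
            if k == 0:
                continue
            prev_state, prev_start, prev_len = runs[k - 1]
            if prev_state != ASSOCIATED or prev_len < persistence_frames:
                continue
            t_event = int(s.frames[start])
            run_end = int(s.frames[start + length - 1])
            site = (np.nan, np.nan)
            if track_lookup is not None:
                last_assoc = int(s.frames[start - 1])
                ra = track_lookup[s.pair[0]].observation(last_assoc)
                rb = track_lookup[s.pair[1]].observation(last_assoc)
                if ra is not None and rb is not None:
                    site = (
                        0.5 * (ra.centroid[0] + rb.centroid[0]),
                        0.5 * (ra.centroid[1] + rb.centroid[1]),
                    )
            events.append(
                DissociationEvent(pair=s.pair, t_event=t_event, run_end=run_end, site=site)
            )
    return events


def count_persistent_dissociations(
    state_matrix: np.ndarray, persistence_frames: int = 3
) -> int:
    """Count dissociations meeting the event definition on a ground-truth
    frame-resolution state matrix (rows = pairs, entries "A"/"D"/"F").

    An entry counts when a run of at least ``persistence_frames``
    associated frames is followed by a dissociated run of at least
    ``persistence_frames`` — the same operational definition
    ``detect_dissociations`` applies to measured series.
    """
    total = 0
    for row in np.asarray(state_matrix):
        runs = _runs(np.where(row == "A", ASSOCIATED, DISSOCIATED))
        for k in range(1, len(runs)):
            state, _, length = runs[k]
            prev_state, _, prev_len = runs[k - 1]
            if (
                state == DISSOCIATED
                and length >= persistence_frames
                and prev_state == ASSOCIATED
                and prev_len >= persistence_frames
            ):
                total += 1
    return total


def _runs(states: np.ndarray) -> list[tuple[str, int, int]]:
    """Run-length encode a state sequence: (state, start index, length)."""
    runs: list[tuple[str, int, int]] = []
    start = 0
    for i in range(1, len(states) + 1):
        if i == len(states) or states[i] != states[start]:
            runs.append((str(states[start]), start, i - start))
            start = i
    return runs


# ---------------------------------------------------------------------------
# marker scoring
# ---------------------------------------------------------------------------

def score_marker(
    events: Sequence[DissociationEvent],
    marker_frames: np.ndarray,
    roi_radius_um: float = 0.3,
    pre_window_frames: int = 5,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
    ld_frames_shape: tuple[int, int] | None = None,
) -> tuple[list[DissociationEvent], dict[str, float]]:
    """Score marker co-occurrence at each dissociation site.

    An event is marker positive when the mean marker intensity in a disc
    of ``roi_radius_um`` at the event site exceeds the frame background
    mean + 3 x background s.d. (robust: median and 1.4826 x MAD) in any
    frame from ``t_event - pre_window_frames`` to the end of the
    dissociated run.  Timing is "before" when the first exceedance
    precedes ``t_event``, otherwise "during".

    Returns updated events plus summary fractions
    (``fraction_positive``, ``fraction_before_of_positive``).
    """
    marker = np.asarray(marker_frames, dtype=float)
    if marker.ndim != 3:
        raise ValueError("marker_frames must be (T, H, W)")
    if ld_frames_shape is not None and marker.shape[-2:] != ld_frames_shape:
        raise ValueError("marker channel is not registered with the LD channel")
    radius_px = roi_radius_um / pixel_size_um
    h, w = marker.shape[-2:]

    bg_mean = np.median(marker, axis=(1, 2))
    bg_sd = 1.4826 * np.median(
        np.abs(marker - bg_mean[:, None, None]), axis=(1, 2)
    )

    out: list[DissociationEvent] = []
    n_pos = 0
    n_before = 0
    for ev in events:
        r, c = ev.site
        if not np.isfinite(r):
            out.append(ev)
            continue
        rr, cc = np.ogrid[:h, :w]
        roi = (rr - r) ** 2 + (cc - c) ** 2 <= radius_px**2
        t0 = max(ev.t_event - pre_window_frames, 0)
        t1 = min(ev.run_end, marker.shape[0] - 1)
        first_hit: int | None = None
        for t in range(t0, t1 + 1):
            if marker[t][roi].mean() > bg_mean[t] + 3.0 * bg_sd[t]:
                first_hit = t
                break
        positive = first_hit is not None
        timing = "none"
        if positive:
            timing = "before" if first_hit < ev.t_event else "during"
            n_pos += 1
            n_before += timing == "before"
        out.append(
            DissociationEvent(
                pair=ev.pair,
                t_event=ev.t_event,
                run_end=ev.run_end,
                site=ev.site,
                marker_positive=positive,
                marker_timing=timing,
            )
        )
    summary = {
        "fraction_positive": n_pos / len(events) if events else np.nan,
        "fraction_before_of_positive": n_before / n_pos if n_pos else np.nan,
    }
    return out, summary


# ---------------------------------------------------------------------------
# profiles and closed forms
# ---------------------------------------------------------------------------

def line_profile(
    image: np.ndarray,
    p0: tuple[float, float],
    p1: tuple[float, float],
    n_samples: int = 100,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
) -> tuple[np.ndarray, np.ndarray]:
    """Bilinear intensity profile along the segment ``p0 -> p1``.

    Returns ``(positions_um, intensities)`` at ``n_samples`` equally
    spaced points.  Endpoints must lie inside the image.
    """
    image = np.asarray(image, dtype=float)
    for p in (p0, p1):
        if not (0 <= p[0] <= image.shape[0] - 1 and 0 <= p[1] <= image.shape[1] - 1):
            raise ValueError(f"profile endpoint {p} outside image {image.shape}")
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    rr = np.linspace(p0[0], p1[0], n_samples)
    cc = np.linspace(p0[1], p1[1], n_samples)
    vals = ndimage.map_coordinates(image, np.vstack([rr, cc]), order=1)
    length_um = float(np.hypot(p1[0] - p0[0], p1[1] - p0[1])) * pixel_size_um
    return np.linspace(0.0, length_um, n_samples), vals


def static_markov_prediction(k_dissoc: float, window_s: float) -> float:
    """Probability that an associated pair never dissociates in the window.

    For two-state Markov kinetics the first dissociation time is
    exponential with rate ``k_dissoc``, so the static fraction is
    ``exp(-k_dissoc * window_s)`` independent of the re-association
    rate.
    """
    return float(np.exp(-k_dissoc * window_s))
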