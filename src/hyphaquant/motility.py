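"""Kymographs, puncta tracking, directed-run detection, flux, and comigration.

Conventions: the hyphal axis is parameterized by arclength from the tip, so
anterograde (tipward) motion decreases arclength; signed displacements are
positive for anterograde runs.  A punctum is scored as moving when it shows a
directed run — a monotone, pause-free excursion — longer than 3 um; run speed
is the inverse chord slope of the kymograph trace (run length / duration).
Comigration is scored for runs longer than 2 um, as in the manual protocol.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.optimize import linear_sum_assignment

from hyphaquant.errors import AlignmentError, InvalidGeometryError
from hyphaquant.segcoloc import (
    CooccurrenceRule,
    SegmentationParams,
    estimate_background,
    preprocess,
    score_cooccurrence,
    segment_puncta,
)

#: Published motility thresholds.
RUN_MIN_UM = 3.0
COMIG_MIN_UM = 2.0
FLUX_LINE_UM = 10.0
FLUX_WINDOW_S = 30.0


@dataclass
class TrackingParams:
    """Frame-to-frame linking and pause-rule parameters.

    ``pause_speed_um_s``/``pause_max_frames`` implement the "no pauses" run
    criterion: instantaneous motion below the pause speed for more than the
    tolerated number of consecutive frames terminates a run.
    """

    max_step_um_per_frame: float = 1.5
    min_track_len_frames: int = 3
    pause_speed_um_s: float = 0.2
    pause_max_frames: int = 2
    max_gap_frames: int = 3  # frames a track may coast unmatched (merged/missed spots)

    def __post_init__(self):
        for name in ("max_step_um_per_frame", "min_track_len_frames", "pause_speed_um_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.pause_max_frames < 0 or self.max_gap_frames < 0:
            raise ValueError("frame tolerances must be >= 0")


@dataclass
class Kymograph:
    """Distance-time reslice of a movie along a traced path (tip end first)."""

    data: np.ndarray  # (n_frames, n_arclength_px)
    path_um: np.ndarray
    line_width_px: int
    channel: str
    pixel_size_um: float
    frame_interval_s: float

    @property
    def arclength_um(self):
        return np.arange(self.data.shape[1]) * self.pixel_size_um

    def to_tiff(self, path):
        """Export the distance-time image (rows = frames) as a TIFF."""
        import tifffile

        tifffile.imwrite(path, self.data.astype(np.float32))


@dataclass
class Run:
    """One detected directed run; displacement_um > 0 means anterograde."""

    track_id: int
    t_start_s: float
    t_end_s: float
    displacement_um: float
    speed_um_s: float
    channel: str = ""
    frame_start: int = 0
    frame_end: int = 0

    def __post_init__(self):
        dur = self.t_end_s - self.t_start_s
        if dur <= 0:
            raise ValueError("run must have positive duration")
        if abs(self.speed_um_s - abs(self.displacement_um) / dur) > 1e-6:
            raise ValueError("speed must equal |displacement| / duration")

    @property
    def run_length_um(self):
        return abs(self.displacement_um)

    @property
    def anterograde(self):
        return self.displacement_um > 0


@dataclass
class FluxCount:
    """Sustained line crossings per window, split by direction."""

    anterograde: int
    retrograde: int
    line_distance_um: float = FLUX_LINE_UM
    window_s: float = FLUX_WINDOW_S

    def __post_init__(self):
        if self.anterograde < 0 or self.retrograde < 0:
            raise ValueError("flux counts must be >= 0")


@dataclass
class Track:
    """A linked punctum trajectory in arclength coordinates."""

    id: int
    channel: str
    frames: np.ndarray
    s_um: np.ndarray
    centroids_px: np.ndarray
    frame_interval_s: float
    puncta: list = field(default_factory=list)

    @property
    def t_s(self):
        return self.frames * self.frame_interval_s

    def __len__(self):
        return len(self.frames)


# ---------------------------------------------------------------------------
# Kymograph construction
# ---------------------------------------------------------------------------


def _resample_path(path_um, pixel_size_um):
    """Resample a polyline at exactly 1-px arclength steps; returns points (px)."""
    pts = np.asarray(path_um, dtype=float) / pixel_size_um
    seg = np.diff(pts, axis=0)
    seglen = np.hypot(seg[:, 0], seg[:, 1])
    cum = np.concatenate([[0.0], np.cumsum(seglen)])
    total = cum[-1]
    if total < 2:
        raise InvalidGeometryError("path shorter than 2 px")
    n = int(np.floor(total)) + 1
    samples = np.arange(n, dtype=float)
    y = np.interp(samples, cum, pts[:, 0])
    x = np.interp(samples, cum, pts[:, 1])
    return np.stack([y, x], axis=1)


def build_kymograph(movie, channel, path_um, line_width_px=1):
    """Reslice a movie along a path: rows are frames, columns arclength (px).

    Each kymograph pixel is the mean of ``line_width_px`` bilinearly
    interpolated samples taken perpendicular to the path at unit-pixel
    arclength steps; column 0 is the start (tip end) of the trace.
    """
    pts = _resample_path(path_um, movie.pixel_size_um)
    # unit tangents -> unit normals per sample
    tangents = np.gradient(pts, axis=0)
    norms = np.linalg.norm(tangents, axis=1, keepdims=True)
    tangents /= np.where(norms == 0, 1.0, norms)
    normals = np.stack([-tangents[:, 1], tangents[:, 0]], axis=1)
    offsets = np.arange(line_width_px, dtype=float) - (line_width_px - 1) / 2

    n_s = len(pts)
    data = np.empty((movie.n_frames, n_s), dtype=float)
    # (width, n_s) sampling grids perpendicular to the path
    ys = pts[:, 0][None, :] + offsets[:, None] * normals[:, 0][None, :]
    xs = pts[:, 1][None, :] + offsets[:, None] * normals[:, 1][None, :]
    for t in range(movie.n_frames):
        frame = movie.frame(t, channel)
        vals = ndimage.map_coordinates(frame, [ys, xs], order=1, mode="nearest")
        data[t] = vals.mean(axis=0)
    return Kymograph(
        data, np.asarray(path_um, dtype=float), int(line_width_px), str(channel),
        movie.pixel_size_um, movie.frame_interval_s,
    )


# ---------------------------------------------------------------------------
# Tracking
# ---------------------------------------------------------------------------


def track_puncta(movie, channel, hypha_or_path, seg=None, tp=None):
    """Detect puncta per frame and link them into tracks by nearest neighbor.

    Detections are linked frame to frame with a gated optimal assignment
    (Hungarian) on 2-D centroid distance; unmatched detections start new
    tracks and a track may coast up to ``max_gap_frames`` frames through
    missed or merged detections.  Centroids are projected onto the traced
    axis to give arclength-from-tip coordinates.
    """
    from hyphaquant.synthio import HyphaModel

    # per-frame segmentation: the exact rolling ball is too slow for movies,
    # a flat top-hat removes the same smooth background in milliseconds
    seg = seg or SegmentationParams(background_method="tophat")
    tp = tp or TrackingParams()
    if isinstance(hypha_or_path, HyphaModel):
        hypha = hypha_or_path
    else:
        hypha = HyphaModel(np.asarray(hypha_or_path, dtype=float), width_um=2.5)

    px = movie.pixel_size_um
    gate = tp.max_step_um_per_frame

    active = []  # dicts: frames, pos_um (2-D), centroids, puncta, missed
    done = []
    for t in range(movie.n_frames):
        detections, _ = segment_puncta(movie.frame(t, channel), seg, channel=channel)
        det_pos = np.array([np.asarray(p.centroid_px) * px for p in detections]).reshape(-1, 2)
        n_det, n_tr = len(detections), len(active)
        assigned_det = set()
        if n_det and n_tr:
            # constant-velocity prediction keeps identities through passes and
            # short merges; stationary tracks predict (almost) their own spot
            preds = []
            for tr in active:
                p_last = tr["pos"][-1]
                v = tr["pos"][-1] - tr["pos"][-2] if len(tr["pos"]) >= 2 else 0.0
                preds.append(p_last + v * (tr["missed"] + 1))
            cost = np.linalg.norm(
                np.array(preds)[:, None, :] - det_pos[None, :, :], axis=2
            )
            gates = np.array([gate * (tr["missed"] + 1) for tr in active])
            big = 1e6
            cmat = np.where(cost <= gates[:, None], cost, big)
            rows, cols = linear_sum_assignment(cmat)
            for r, c in zip(rows, cols):
                if cmat[r, c] >= big:
                    continue
                tr = active[r]
                tr["frames"].append(t)
                tr["pos"].append(det_pos[c])
                tr["puncta"].append(detections[c])
                tr["missed"] = 0
                assigned_det.add(c)
        for tr in active:
            if not tr["frames"] or tr["frames"][-1] != t:
                tr["missed"] += 1
        still = []
        for tr in active:
            (done if tr["missed"] > tp.max_gap_frames else still).append(tr)
        active = still
        for c in range(n_det):
            if c not in assigned_det:
                active.append(
                    {"frames": [t], "pos": [det_pos[c]], "puncta": [detections[c]], "missed": 0}
                )
    done.extend(active)

    tracks = []
    for raw in done:
        if len(raw["frames"]) < tp.min_track_len_frames:
            continue
        pos = np.array(raw["pos"])
        s_um = hypha.arclength_of(pos)
        tracks.append(
            Track(
                id=len(tracks),
                channel=str(channel),
                frames=np.asarray(raw["frames"]),
                s_um=np.asarray(s_um, dtype=float),
                centroids_px=pos / px,
                frame_interval_s=movie.frame_interval_s,
                puncta=raw["puncta"],
            )
        )
    return tracks


# ---------------------------------------------------------------------------
# Run detection
# ---------------------------------------------------------------------------


def detect_runs(track, run_min_um=RUN_MIN_UM, tp=None):
    """Find maximal monotone, pause-free segments longer than ``run_min_um``.

    A segment keeps a single displacement sign; steps slower than
    ``pause_speed_um_s`` are tolerated for at most ``pause_max_frames``
    consecutive frames.  Speed is the run-average |displacement| / duration
    (the inverse chord slope of the kymograph trace).
    """
    tp = tp or TrackingParams()
    s = np.asarray(track.s_um, dtype=float)
    t = np.asarray(track.t_s, dtype=float)
    if len(s) < max(2, tp.min_track_len_frames):
        return []
    ds = np.diff(s)
    dt = np.diff(t)
    moving = np.abs(ds) / dt >= tp.pause_speed_um_s
    sign = np.sign(ds)

    runs = []

    step_speed = np.abs(ds) / dt

    def _emit(i0, i1):
        # trim trailing/leading paused steps
        while i0 < i1 and not moving[i0]:
            i0 += 1
        while i1 > i0 and not moving[i1 - 1]:
            i1 -= 1
        if i1 <= i0:
            return
        # Positional jitter occasionally exceeds the pause speed and extends a
        # segment through stationary frames; trim the boundaries to "strong"
        # steps, at least half the segment's median moving-step speed.
        seg_spd = step_speed[i0:i1][moving[i0:i1]]
        v_ref = 0.5 * float(np.median(seg_spd))
        while i0 < i1 and not (moving[i0] and step_speed[i0] >= v_ref):
            i0 += 1
        while i1 > i0 and not (moving[i1 - 1] and step_speed[i1 - 1] >= v_ref):
            i1 -= 1
        if i1 <= i0:
            return
        disp_axis = s[i1] - s[i0]
        disp = -disp_axis  # + = anterograde (arclength decreased)
        if abs(disp) <= run_min_um:
            return
        # Trace the ridge the way a manual kymograph line is drawn: fit the
        # interior samples (which lie on the moving ridge; the two boundary
        # samples sit on the stationary shoulders) and take the times where
        # the fitted line meets the shoulders as the run endpoints.  This
        # removes the up-to-one-frame dead time at each end of the chord.
        t_start, t_end = float(t[i0]), float(t[i1])
        interior_t, interior_s = t[i0 + 1 : i1], s[i0 + 1 : i1]
        for _ in range(2):
            if len(interior_t) < 2:
                break
            b, a = np.polyfit(interior_t, interior_s, 1)
            resid = interior_s - (a + b * interior_t)
            keep = np.abs(resid) <= max(2.5 * float(np.std(resid)), 0.12)
            if keep.all() or keep.sum() < 2:
                break
            interior_t, interior_s = interior_t[keep], interior_s[keep]
        if len(interior_t) >= 2:
            b, a = np.polyfit(interior_t, interior_s, 1)
            if np.sign(b) == np.sign(disp_axis) and abs(b) > 1e-9:
                t0f, t1f = (s[i0] - a) / b, (s[i1] - a) / b
                if t0f < t1f and t[i0] - dt[0] <= t0f and t1f <= t[i1] + dt[-1]:
                    t_start, t_end = float(t0f), float(t1f)
        speed = abs(disp) / (t_end - t_start)
        runs.append(
            Run(
                track_id=track.id,
                t_start_s=t_start,
                t_end_s=t_end,
                displacement_um=float(disp),
                speed_um_s=speed,
                channel=track.channel,
                frame_start=int(track.frames[i0]),
                frame_end=int(track.frames[i1]),
            )
        )

    i = 0
    n = len(ds)
    while i < n:
        if not moving[i]:
            i += 1
            continue
        run_sign = sign[i]
        j = i + 1
        pauses = 0
        while j < n:
            if moving[j]:
                if sign[j] != run_sign:
                    break
                pauses = 0
            else:
                pauses += 1
                if pauses > tp.pause_max_frames:
                    j -= pauses - 1
                    break
            j += 1
        _emit(i, min(j, n))
        i = max(j, i + 1)
    return runs


def detect_runs_in_movie(movie, channel, hypha_or_path, seg=None, tp=None,
                         run_min_um=RUN_MIN_UM):
    """Track a movie and detect directed runs; returns (tracks, runs)."""
    tracks = track_puncta(movie, channel, hypha_or_path, seg=seg, tp=tp)
    runs = [r for tr in tracks for r in detect_runs(tr, run_min_um, tp)]
    return tracks, runs


def directed_run_percentage(n_directed, n_total):
    """Percent of scored movements that are long-distance directed runs."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    return 100.0 * n_directed / n_total


# ---------------------------------------------------------------------------
# Flux
# ---------------------------------------------------------------------------


def count_flux(tracks, line_distance_um=FLUX_LINE_UM, window_s=FLUX_WINDOW_S,
               sustain_frames=2, hypha_length_um=None):
    """Count sustained crossings of a line ``line_distance_um`` from the tip.

    A crossing counts when a track passes the line with at least
    ``sustain_frames`` consecutive frames strictly on each side; anterograde
    crossings go from beyond the line toward the tip.  Oscillations across
    the line without sustained residence are not counted.
    """
    if hypha_length_um is not None and hypha_length_um < line_distance_um:
        raise InvalidGeometryError(
            f"hypha ({hypha_length_um} um) shorter than the flux line ({line_distance_um} um)"
        )
    antero = retro = 0
    for tr in tracks:
        in_window = tr.t_s <= window_s + 1e-9
        d = tr.s_um[in_window] - line_distance_um
        side = np.sign(d)
        n = len(side)
        i = 0
        while i < n - 1:
            if side[i] != 0 and side[i + 1] != 0 and side[i] != side[i + 1]:
                before_ok = i - sustain_frames + 1 >= 0 and np.all(
                    side[i - sustain_frames + 1 : i + 1] == side[i]
                )
                after_ok = i + sustain_frames < n and np.all(
                    side[i + 1 : i + 1 + sustain_frames] == side[i + 1]
                )
                if before_ok and after_ok:
                    if side[i] > 0:  # from beyond the line toward the tip
                        antero += 1
                    else:
                        retro += 1
                    i += sustain_frames
                    continue
            i += 1
    return FluxCount(antero, retro, line_distance_um, window_s)


# ---------------------------------------------------------------------------
# Comigration and movement-aligned profiles
# ---------------------------------------------------------------------------


def comigration_fraction(
    runs_a,
    tracks_a,
    movie,
    other_channel,
    seg=None,
    rule=None,
    comig_min_um=COMIG_MIN_UM,
    min_frame_fraction=0.8,
):
    """Fraction of runs (> ``comig_min_um``) with a co-moving opposite punctum.

    For every frame of each qualifying run, the running punctum is tested
    against the opposite channel with the co-occurrence counting rule; the
    run comigrates when the rule holds in at least ``min_frame_fraction`` of
    its frames.
    """
    if not runs_a:
        raise ValueError("comigration_fraction needs at least one run")
    seg = seg or SegmentationParams(background_method="tophat")
    rule = rule or CooccurrenceRule()
    tracks_by_id = {tr.id: tr for tr in tracks_a}

    cache = {}

    def _other(t):
        if t not in cache:
            img = movie.frame(t, other_channel)
            puncta, mask = segment_puncta(img, seg, channel=other_channel)
            filtered = preprocess(img, seg)
            cache[t] = (puncta, filtered, estimate_background(filtered, mask))
        return cache[t]

    qualifying = [r for r in runs_a if r.run_length_um > comig_min_um]
    if not qualifying:
        raise ValueError("no runs exceed the comigration length threshold")
    n_comig = 0
    for run in qualifying:
        tr = tracks_by_id[run.track_id]
        idx = np.flatnonzero((tr.frames >= run.frame_start) & (tr.frames <= run.frame_end))
        hits = 0
        for i in idx:
            punct = tr.puncta[i]
            puncta_b, filtered_b, bg_b = _other(int(tr.frames[i]))
            if not puncta_b:
                continue
            _, flags = score_cooccurrence([punct], puncta_b, filtered_b, bg_b, rule)
            hits += flags[0]
        if len(idx) and hits / len(idx) >= min_frame_fraction:
            n_comig += 1
    return n_comig / len(qualifying)


def aligned_profile(kymo_a, kymo_b, trace, window_um=2.0):
    """Movement-aligned intensity profiles of both channels around a run.

    ``trace`` is a sequence of (frame, arclength_um) points along a run.  At
    each point a 1-px line scan of both kymographs is extracted in a window
    around the punctum; the offset origin is set at the maximum of channel B
    (the reference/561 channel) and the aligned scans are averaged.

    Returns (offsets_um, mean_profile_a, mean_profile_b).
    """
    if kymo_a.data.shape != kymo_b.data.shape:
        raise ValueError("kymographs must share shape (same path and time)")
    px = kymo_a.pixel_size_um
    half = int(round(window_um / px))
    offsets = np.arange(-half, half + 1)
    prof_a, prof_b = [], []
    for frame, s_um in trace:
        col = int(round(s_um / px))
        row_a = kymo_a.data[int(frame)]
        row_b = kymo_b.data[int(frame)]
        lo, hi = col - half, col + half + 1
        if lo < 0 or hi > row_a.size:
            continue
        win_b = row_b[lo:hi]
        if np.ptp(win_b) == 0:
            raise AlignmentError("flat reference-channel profile; cannot align")
        center = lo + int(np.argmax(win_b))
        lo2, hi2 = center - half, center + half + 1
        if lo2 < 0 or hi2 > row_a.size:
            continue
        prof_a.append(row_a[lo2:hi2])
        prof_b.append(row_b[lo2:hi2])
    if not prof_a:
        raise AlignmentError("no usable trace points inside the kymograph")
    return offsets * px, np.mean(prof_a, axis=0), np.mean(prof_b, axis=0)


def runs_frame(runs):
    """Tabulate detected runs as a DataFrame (CSV-ready)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "track_id": r.track_id,
                "channel": r.channel,
                "t_start_s": r.t_start_s,
                "t_end_s": r.t_end_s,
                "displacement_um": r.displacement_um,
                "run_length_um": r.run_length_um,
                "speed_um_s": r.speed_um_s,
                "direction": "anterograde" if r.anterograde else "retrograde",
            }
            for r in runs
        ]
    )
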