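"""Synthetic hyphal movies with known ground truth, and all on-disk artifact I/O.

The generator emulates the two-channel spinning-disk acquisitions the pipeline
is built to analyze: a germling or adult hypha traced tip-first, a population
of peroxisomes (561 channel) a fraction of which carry an attached Woronin
body (488 channel) at a sub-resolution offset, infrequent bidirectional
directed runs with Gaussian-distributed speeds and run lengths superposed on
stationary jittering puncta, and realistic rendering (Gaussian PSF, tilted
background, Poisson + read noise, 16-bit quantization).

All randomness is driven by explicit integer seeds; identical seeds yield
bit-identical output.
"""

from __future__ import annotations

import json
import shutil
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from hyphaquant.errors import (
    BlindingError,
    InvalidGeometryError,
    MovieFormatError,
    OutOfFieldError,
)

# Physical defaults: 100x objective on an 11-um sensor -> 0.11 um/px;
# 300 ms frame interval and 0.2 um z-steps as in the acquisitions emulated.
DEFAULT_PIXEL_SIZE_UM = 0.11
DEFAULT_FRAME_INTERVAL_S = 0.3
DEFAULT_Z_STEP_UM = 0.2


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class Movie:
    """A calibrated 5-D (t, z, c, y, x) intensity stack.

    Intensities live in the 16-bit range [0, 65535]; noiseless renders are
    stored as floats, noisy renders are quantized to uint16.
    """

    data: np.ndarray
    pixel_size_um: float
    frame_interval_s: float = DEFAULT_FRAME_INTERVAL_S
    z_step_um: float = DEFAULT_Z_STEP_UM
    channel_names: tuple = ("488", "561")

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 5:
            raise ValueError(f"movie data must be 5-D (t,z,c,y,x), got {self.data.ndim}-D")
        if self.data.size and (self.data.min() < 0 or self.data.max() > 65535):
            raise ValueError("movie intensities must lie in [0, 65535]")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be positive")
        self.channel_names = tuple(self.channel_names)
        if len(self.channel_names) != self.data.shape[2] or not self.channel_names:
            raise ValueError("channel_names must match the channel axis")

    @property
    def n_frames(self):
        return self.data.shape[0]

    @property
    def shape_yx(self):
        return self.data.shape[3], self.data.shape[4]

    def channel_index(self, channel):
        try:
            return self.channel_names.index(str(channel))
        except ValueError:
            raise KeyError(f"no channel {channel!r} in {self.channel_names}") from None

    def frame(self, t, channel):
        """Single-z 2-D frame; multi-z stacks are max-projected."""
        c = self.channel_index(channel)
        return np.asarray(self.data[t, :, c].max(axis=0), dtype=float)

    def max_z(self, channel, t=0):
        return self.frame(t, channel)

    def sum_z(self, channel, t=0):
        c = self.channel_index(channel)
        return np.asarray(self.data[t, :, c].sum(axis=0), dtype=float)


@dataclass
class HyphaModel:
    """A hyphal axis traced tip-first, with width and optional septa.

    ``centerline`` is an (n, 2) array of (y, x) points in micrometres; its
    first vertex is the hyphal tip, so arclength ``s`` measures distance from
    the tip and anterograde motion decreases ``s``.
    """

    centerline: np.ndarray
    width_um: float = 2.5
    septa_arclengths_um: tuple = ()

    def __post_init__(self):
        self.centerline = np.asarray(self.centerline, dtype=float)
        if self.centerline.ndim != 2 or self.centerline.shape[0] < 2 or self.centerline.shape[1] != 2:
            raise InvalidGeometryError("centerline must be an (n>=2, 2) array of (y, x) um points")
        seg = np.diff(self.centerline, axis=0)
        seglen = np.hypot(seg[:, 0], seg[:, 1])
        if np.any(seglen <= 0):
            raise InvalidGeometryError("centerline has coincident consecutive vertices")
        self._cum_s = np.concatenate([[0.0], np.cumsum(seglen)])
        if self.length_um <= 0:
            raise InvalidGeometryError("hypha length must be positive")
        if self.width_um <= 0:
            raise InvalidGeometryError("width_um must be positive")
        self.septa_arclengths_um = tuple(float(s) for s in self.septa_arclengths_um)
        for s in self.septa_arclengths_um:
            if not 0 < s < self.length_um:
                raise InvalidGeometryError(f"septum arclength {s} outside (0, {self.length_um})")

    @property
    def length_um(self):
        return float(self._cum_s[-1])

    @property
    def tip_xy(self):
        return tuple(self.centerline[0])

    def point_at(self, s):
        """(y, x) um position at arclength ``s`` from the tip (clipped to ends)."""
        s = np.clip(np.asarray(s, dtype=float), 0.0, self.length_um)
        y = np.interp(s, self._cum_s, self.centerline[:, 0])
        x = np.interp(s, self._cum_s, self.centerline[:, 1])
        return np.stack([y, x], axis=-1)

    def normal_at(self, s):
        """Unit normal (y, x) to the centerline at arclength ``s``."""
        s = np.asarray(s, dtype=float)
        eps = min(1e-3, self.length_um / 10)
        p0 = self.point_at(np.clip(s - eps, 0, self.length_um))
        p1 = self.point_at(np.clip(s + eps, 0, self.length_um))
        tan = p1 - p0
        norm = np.linalg.norm(tan, axis=-1, keepdims=True)
        tan = tan / np.where(norm == 0, 1.0, norm)
        # rotate tangent by 90 degrees: (ty, tx) -> (-tx, ty)
        return np.stack([-tan[..., 1], tan[..., 0]], axis=-1)

    def arclength_of(self, points_um, n_samples=2000):
        """Project (y, x) um points onto the centerline; returns arclengths."""
        grid = np.linspace(0.0, self.length_um, n_samples)
        ref = self.point_at(grid)
        pts = np.atleast_2d(np.asarray(points_um, dtype=float))
        d2 = ((pts[:, None, :] - ref[None, :, :]) ** 2).sum(axis=2)
        return grid[np.argmin(d2, axis=1)]


def straight_hypha(length_um, width_um=2.5, tip_yx_um=None, septa_arclengths_um=()):
    """A straight horizontal hypha with the tip on the left, growing to +x."""
    if tip_yx_um is None:
        tip_yx_um = (width_um, 1.0)
    y0, x0 = tip_yx_um
    line = np.array([[y0, x0], [y0, x0 + float(length_um)]])
    return HyphaModel(line, width_um=width_um, septa_arclengths_um=septa_arclengths_um)


@dataclass
class MotilityParams:
    """Parameters of the punctum motility model (one simulated cell).

    Speeds and run lengths are drawn from Gaussians truncated below at
    ``0`` and ``runlen_trunc_um`` respectively; defaults reproduce the
    published wild-type peroxisome (PTS1-channel) statistics.
    """

    n_puncta: int = 6
    frac_paired: float = 0.87
    pair_offset_um: float = 0.15
    run_init_rate_per_s: float = 0.05
    speed_mean_um_s: float = 1.72
    speed_sd_um_s: float = 0.79
    runlen_mean_um: float = 4.01
    runlen_sd_um: float = 0.96
    runlen_trunc_um: float = 0.0
    p_anterograde: float = 0.5
    jitter_sd_um: float = 0.03
    min_pause_s: float = 1.5  # refractory stationary interval between runs
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.frac_paired <= 1:
            raise ValueError("frac_paired must be in [0, 1]")
        if not 0 <= self.p_anterograde <= 1:
            raise ValueError("p_anterograde must be in [0, 1]")
        if self.speed_mean_um_s <= 0:
            raise ValueError("speed_mean_um_s must be positive")
        if self.run_init_rate_per_s < 0:
            raise ValueError("run_init_rate_per_s must be >= 0")
        if self.n_puncta < 0:
            raise ValueError("n_puncta must be >= 0")


@dataclass
class OpticsParams:
    """Rendering model: Gaussian PSF, tilted background, Poisson + read noise."""

    psf_sigma_um: float = 0.15
    background_level: float = 100.0
    background_tilt: float = 1.0  # counts per um along x
    photon_scale: float = 6000.0  # integrated counts per unit source brightness
    read_noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if self.psf_sigma_um <= 0:
            raise ValueError("psf_sigma_um must be positive")
        if self.read_noise_sd < 0:
            raise ValueError("read_noise_sd must be >= 0")


@dataclass
class TrueRun:
    """One ground-truth directed run.  displacement_um > 0 means anterograde."""

    punctum_id: int
    t_start_s: float
    t_end_s: float
    displacement_um: float
    speed_um_s: float
    clipped: bool = False  # cut short by a hypha end or the end of the movie

    def __post_init__(self):
        dur = self.t_end_s - self.t_start_s
        if dur <= 0:
            raise ValueError("run must have positive duration")
        if abs(abs(self.displacement_um) - self.speed_um_s * dur) > 1e-6:
            raise ValueError("|displacement| must equal speed x duration")

    @property
    def run_length_um(self):
        return abs(self.displacement_um)

    @property
    def anterograde(self):
        return self.displacement_um > 0


@dataclass
class TrackTruth:
    """Ground-truth trajectory of one punctum, in arclength-from-tip coordinates."""

    punctum_id: int
    channel: str
    t_s: np.ndarray
    s_um: np.ndarray
    lateral_um: float = 0.0
    brightness: float = 1.0

    def __post_init__(self):
        self.t_s = np.asarray(self.t_s, dtype=float)
        self.s_um = np.asarray(self.s_um, dtype=float)
        if self.t_s.shape != self.s_um.shape:
            raise ValueError("t_s and s_um must have the same shape")


@dataclass
class GroundTruth:
    """Everything the simulator knows: tracks, true runs, pairing, annotations."""

    tracks: list
    true_runs: list = field(default_factory=list)
    pair_map: dict = field(default_factory=dict)  # 488 punctum id -> 561 punctum id
    annotations: dict = field(default_factory=dict)

    def __post_init__(self):
        targets = list(self.pair_map.values())
        if len(targets) != len(set(targets)):
            raise ValueError("pair_map must be injective")

    def track(self, punctum_id):
        for tr in self.tracks:
            if tr.punctum_id == punctum_id:
                return tr
        raise KeyError(punctum_id)

    def runs_frame(self):
        return pd.DataFrame(
            [
                {
                    "punctum_id": r.punctum_id,
                    "t_start_s": r.t_start_s,
                    "t_end_s": r.t_end_s,
                    "displacement_um": r.displacement_um,
                    "speed_um_s": r.speed_um_s,
                    "clipped": r.clipped,
                }
                for r in self.true_runs
            ]
        )

    def tracks_frame(self):
        rows = []
        for tr in self.tracks:
            for t, s in zip(tr.t_s, tr.s_um):
                rows.append(
                    {
                        "punctum_id": tr.punctum_id,
                        "channel": tr.channel,
                        "t_s": t,
                        "s_um": s,
                        "lateral_um": tr.lateral_um,
                    }
                )
        return pd.DataFrame(rows)

    def write(self, out_dir):
        """Write tracks/runs CSVs and a JSON annotation file to ``out_dir``."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.tracks_frame().to_csv(out / "truth_tracks.csv", index=False)
        self.runs_frame().to_csv(out / "truth_runs.csv", index=False)
        ann = dict(self.annotations)
        ann["pair_map"] = {str(k): v for k, v in self.pair_map.items()}
        with open(out / "truth_annotations.json", "w") as fh:
            json.dump(ann, fh, indent=2, default=float)


# ---------------------------------------------------------------------------
# Motility simulation
# ---------------------------------------------------------------------------


def _truncated_normal(rng, mean, sd, low):
    """Rejection-sample a Gaussian truncated to (low, inf)."""
    if sd == 0:
        if mean <= low:
            raise ValueError("degenerate truncated normal: mean <= low with sd=0")
        return mean
    for _ in range(10000):
        x = rng.normal(mean, sd)
        if x > low:
            return x
    raise RuntimeError("truncated-normal rejection sampling failed")


def simulate_motility(hypha, params, duration_s, dt_s=DEFAULT_FRAME_INTERVAL_S):
    """Simulate punctum trajectories on a hyphal centerline.

    Each 561-channel punctum alternates between stationary phases (iid
    Gaussian positional jitter of ``jitter_sd_um``) and directed runs started
    at rate ``run_init_rate_per_s``, with speed and run length drawn from
    truncated Gaussians and direction anterograde (toward the tip, decreasing
    arclength) with probability ``p_anterograde``.  Runs end early at a hypha
    end or the end of the movie and are then flagged ``clipped``.  A fraction
    ``frac_paired`` of puncta carry an attached 488-channel punctum that
    shares the trajectory, offset by ``pair_offset_um`` along the axis while
    stationary and coincident during runs.
    """
    if dt_s <= 0:
        raise ValueError("dt_s must be positive")
    if duration_s < dt_s:
        raise ValueError("duration_s must be >= dt_s")
    if not isinstance(hypha, HyphaModel) or hypha.length_um <= 0:
        raise InvalidGeometryError("simulate_motility needs a hypha of positive length")

    rng = np.random.default_rng(params.seed)
    L = hypha.length_um
    margin = min(0.2, 0.05 * L)
    n_frames = int(np.floor(duration_s / dt_s + 1e-9)) + 1
    t_grid = np.arange(n_frames) * dt_s

    tracks, true_runs, pair_map = [], [], {}
    next_partner_id = params.n_puncta

    for pid in range(params.n_puncta):
        s0 = rng.uniform(0.15 * L, 0.85 * L)
        lateral = rng.uniform(-hypha.width_um / 3, hypha.width_um / 3)
        brightness = rng.uniform(0.8, 1.3)
        bp_t, bp_s = [0.0], [s0]
        run_intervals = []
        t, s = 0.0, s0
        while params.run_init_rate_per_s > 0:
            # refractory minimum pause keeps successive runs distinct events
            wait = params.min_pause_s + rng.exponential(1.0 / params.run_init_rate_per_s)
            t_run = t + wait
            if t_run >= duration_s:
                break
            speed = _truncated_normal(rng, params.speed_mean_um_s, params.speed_sd_um_s, 0.0)
            length = _truncated_normal(rng, params.runlen_mean_um, params.runlen_sd_um, params.runlen_trunc_um)
            antero = rng.random() < params.p_anterograde
            clipped = False
            # anterograde = toward the tip = decreasing arclength
            direction = -1.0 if antero else 1.0
            s_target = s + direction * length
            lo, hi = margin, L - margin
            if s_target < lo:
                s_target, clipped = lo, True
            elif s_target > hi:
                s_target, clipped = hi, True
            run_dur = abs(s_target - s) / speed
            if t_run + run_dur > duration_s:
                run_dur = duration_s - t_run
                s_target = s + direction * speed * run_dur
                clipped = True
            if run_dur > 1e-9:
                # displacement > 0 means anterograde (s decreased)
                disp = -direction * speed * run_dur
                s_target = s - disp
                true_runs.append(
                    TrueRun(pid, t_run, t_run + run_dur, disp, speed, clipped=clipped)
                )
                bp_t += [t_run, t_run + run_dur]
                bp_s += [s, s_target]
                run_intervals.append((t_run, t_run + run_dur))
            t, s = t_run + run_dur, s_target
        bp_t.append(duration_s + dt_s)
        bp_s.append(s)

        s_samp = np.interp(t_grid, bp_t, bp_s)
        in_run = np.zeros(n_frames, dtype=bool)
        for a, b in run_intervals:
            in_run |= (t_grid >= a - 1e-9) & (t_grid <= b + 1e-9)
        jitter = rng.normal(0.0, params.jitter_sd_um, n_frames)
        s_samp = np.where(in_run, s_samp, np.clip(s_samp + jitter, 0.0, L))
        tracks.append(TrackTruth(pid, "561", t_grid.copy(), s_samp, lateral, brightness))

        if rng.random() < params.frac_paired:
            # attached Woronin body: coincident during runs, offset while stationary
            sign = 1.0 if rng.random() < 0.5 else -1.0
            offset = np.where(in_run, 0.0, sign * params.pair_offset_um)
            s_partner = np.clip(s_samp + offset, 0.0, L)
            partner = TrackTruth(
                next_partner_id, "488", t_grid.copy(), s_partner, lateral,
                brightness * rng.uniform(0.7, 1.1),
            )
            tracks.append(partner)
            pair_map[next_partner_id] = pid
            next_partner_id += 1

    ann = {
        "duration_s": float(duration_s),
        "dt_s": float(dt_s),
        "hypha_length_um": L,
        "n_puncta": params.n_puncta,
    }
    return GroundTruth(tracks, true_runs, pair_map, ann)


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------


def _add_gaussian_spot(img, y_px, x_px, sigma_px, total_counts):
    """Accumulate an integral-normalized 2-D Gaussian into ``img`` in place."""
    ny, nx = img.shape
    r = int(np.ceil(4.5 * sigma_px)) + 2
    y0, y1 = int(np.floor(y_px)) - r, int(np.floor(y_px)) + r + 1
    x0, x1 = int(np.floor(x_px)) - r, int(np.floor(x_px)) + r + 1
    y0c, y1c = max(y0, 0), min(y1, ny)
    x0c, x1c = max(x0, 0), min(x1, nx)
    if y0c >= y1c or x0c >= x1c:
        return
    yy = np.arange(y0c, y1c)[:, None] - y_px
    xx = np.arange(x0c, x1c)[None, :] - x_px
    g = np.exp(-(yy**2 + xx**2) / (2 * sigma_px**2))
    img[y0c:y1c, x0c:x1c] += total_counts / (2 * np.pi * sigma_px**2) * g


def render_movie(
    hypha,
    truth,
    optics,
    shape_yx,
    pixel_size_um=DEFAULT_PIXEL_SIZE_UM,
    frame_interval_s=None,
    channel_names=("488", "561"),
    apply_poisson=True,
    extra_sources=None,
):
    """Render a ground-truth scene into a calibrated movie.

    Each punctum becomes a 2-D Gaussian of width ``psf_sigma_um`` whose
    integrated above-background signal is ``photon_scale x brightness``.  A
    planar background (level + tilt along x) is added, then Poisson shot noise
    (disabled with ``apply_poisson=False``) and Gaussian read noise; noisy
    output is quantized to uint16, noiseless output stays float32.

    ``extra_sources`` maps channel name -> static 2-D intensity image added to
    every frame before noise (used for septum/leakage scenes).
    """
    ny, nx = shape_yx
    channel_names = tuple(channel_names)
    if not truth.tracks:
        t_grid = np.array([0.0])
    else:
        t_grid = truth.tracks[0].t_s
    if frame_interval_s is None:
        frame_interval_s = (
            float(t_grid[1] - t_grid[0]) if len(t_grid) > 1
            else truth.annotations.get("dt_s", DEFAULT_FRAME_INTERVAL_S)
        )
    nt, nc = len(t_grid), len(channel_names)

    x_um = np.arange(nx) * pixel_size_um
    background = optics.background_level + optics.background_tilt * x_um
    background = np.broadcast_to(background, (ny, nx)).astype(float)

    sigma_px = optics.psf_sigma_um / pixel_size_um
    signal = np.zeros((nt, 1, nc, ny, nx), dtype=float)

    out_of_field = []
    for tr in truth.tracks:
        if tr.channel not in channel_names:
            raise ValueError(f"track channel {tr.channel!r} not among {channel_names}")
        c = channel_names.index(tr.channel)
        pos = hypha.point_at(tr.s_um) + tr.lateral_um * hypha.normal_at(tr.s_um)
        pos_px = pos / pixel_size_um
        if np.any(pos_px[:, 0] < 0) or np.any(pos_px[:, 0] > ny - 1) or np.any(
            pos_px[:, 1] < 0
        ) or np.any(pos_px[:, 1] > nx - 1):
            out_of_field.append(tr.punctum_id)
            continue
        total = optics.photon_scale * tr.brightness
        for ti in range(nt):
            _add_gaussian_spot(signal[ti, 0, c], pos_px[ti, 0], pos_px[ti, 1], sigma_px, total)
    if out_of_field:
        raise OutOfFieldError(out_of_field)

    if extra_sources:
        for ch, img in extra_sources.items():
            signal[:, 0, channel_names.index(ch)] += np.asarray(img, dtype=float)

    data = signal + background[None, None, None]
    rng = np.random.default_rng(optics.seed)
    noisy = False
    if apply_poisson:
        data = rng.poisson(np.clip(data, 0, None)).astype(float)
        noisy = True
    if optics.read_noise_sd > 0:
        data = data + rng.normal(0.0, optics.read_noise_sd, data.shape)
        noisy = True
    data = np.clip(data, 0, 65535)
    data = np.round(data).astype(np.uint16) if noisy else data.astype(np.float32)
    return Movie(data, pixel_size_um, frame_interval_s, DEFAULT_Z_STEP_UM, channel_names)


# ---------------------------------------------------------------------------
# Scene builders
# ---------------------------------------------------------------------------


def _static_truth(entries, annotations):
    """Build a single-frame GroundTruth from (id, channel, s, lateral, brightness)."""
    tracks = [
        TrackTruth(pid, ch, np.array([0.0]), np.array([s]), lat, b)
        for pid, ch, s, lat, b in entries
    ]
    return tracks, annotations


def make_coloc_field(
    n_primary=18,
    primary_channel="488",
    frac_paired=0.87,
    n_unpaired_other=6,
    pair_offset_um=0.15,
    min_sep_um=1.1,
    field_length_um=45.0,
    field_width_um=4.0,
    optics=None,
    pixel_size_um=DEFAULT_PIXEL_SIZE_UM,
    apply_poisson=True,
    seed=0,
):
    """A single-frame two-channel germling field with a known pairing fraction.

    ``n_primary`` puncta are placed in ``primary_channel``; each independently
    carries an attached punctum in the other channel with probability
    ``frac_paired`` at a sub-resolution offset.  ``n_unpaired_other`` solitary
    puncta of the other channel act as distractors.  Distinct objects are kept
    ``min_sep_um`` apart so the true pairing is unambiguous.

    Returns (movie, truth); ``truth.annotations['true_paired_fraction']`` is
    the realized fraction.
    """
    rng = np.random.default_rng(seed)
    optics = optics if optics is not None else OpticsParams(seed=seed + 1)
    other_channel = "561" if primary_channel == "488" else "488"
    hypha = straight_hypha(
        length_um=field_length_um, width_um=field_width_um,
        tip_yx_um=(field_width_um, 1.0),
    )
    L, w = hypha.length_um, hypha.width_um

    placed = []

    def _place():
        for _ in range(5000):
            s = rng.uniform(0.03 * L, 0.97 * L)
            lat = rng.uniform(-w / 2.5, w / 2.5)
            p = np.array([s, lat])
            if all(np.linalg.norm(p - q) > min_sep_um for q in placed):
                placed.append(p)
                return s, lat
        raise RuntimeError("could not place puncta with the requested separation")

    entries, pair_map = [], {}
    n_paired = 0
    pid = 0
    for _ in range(n_primary):
        s, lat = _place()
        b = rng.uniform(0.8, 1.3)
        primary_id = pid
        entries.append((primary_id, primary_channel, s, lat, b))
        pid += 1
        if rng.random() < frac_paired:
            ang = rng.uniform(0, 2 * np.pi)
            ds, dl = pair_offset_um * np.cos(ang), pair_offset_um * np.sin(ang)
            entries.append((pid, other_channel, s + ds, lat + dl, rng.uniform(0.8, 1.3)))
            g, r = (primary_id, pid) if primary_channel == "488" else (pid, primary_id)
            pair_map[g] = r
            n_paired += 1
            pid += 1
    for _ in range(n_unpaired_other):
        s, lat = _place()
        entries.append((pid, other_channel, s, lat, rng.uniform(0.8, 1.3)))
        pid += 1

    ann = {
        "scene": "coloc_field",
        "primary_channel": primary_channel,
        "n_primary": n_primary,
        "n_paired": n_paired,
        "true_paired_fraction": n_paired / n_primary if n_primary else float("nan"),
    }
    tracks, ann = _static_truth(entries, ann)
    truth = GroundTruth(tracks, [], pair_map, ann)
    ny = int(np.ceil((2 * hypha.tip_xy[0]) / pixel_size_um)) + 1
    nx = int(np.ceil((L + 2.0) / pixel_size_um)) + 1
    movie = render_movie(
        hypha, truth, optics, (ny, nx), pixel_size_um,
        channel_names=("488", "561"), apply_poisson=apply_poisson,
    )
    return movie, truth


def make_septum_scene(
    class_label,
    optics=None,
    pixel_size_um=DEFAULT_PIXEL_SIZE_UM,
    apply_poisson=True,
    seed=0,
):
    """A single-frame septal crop with Woronin bodies on both/one/neither side.

    The hypha runs horizontally (tip to the left); a membrane-dye ridge marks
    the septal plane at the crop center.  488 puncta are placed within 1 um of
    the plane according to ``class_label`` in {"both", "one", "none"}.
    """
    if class_label not in ("both", "one", "none"):
        raise ValueError("class_label must be 'both', 'one' or 'none'")
    rng = np.random.default_rng(seed)
    optics = optics if optics is not None else OpticsParams(seed=seed + 1)
    hypha = straight_hypha(length_um=8.0, width_um=2.5, tip_yx_um=(2.5, 0.5),
                           septa_arclengths_um=(4.0,))
    s_sep = hypha.septa_arclengths_um[0]

    sides = {"both": (-1, +1), "one": (rng.choice([-1, 1]),), "none": ()}[class_label]
    entries = []
    pid = 0
    lat_sign = rng.choice([-1.0, 1.0])
    for sign in sides:
        d = rng.uniform(0.45, 0.85)
        # opposite-side puncta get opposite lateral offsets so the two
        # organelles stay optically resolvable across the septal plane
        lat = lat_sign * rng.uniform(0.25, 0.6)
        lat_sign = -lat_sign
        entries.append((pid, "488", s_sep + sign * d, lat, rng.uniform(0.9, 1.3)))
        pid += 1

    ny = int(np.ceil(2 * hypha.tip_xy[0] / pixel_size_um)) + 1
    nx = int(np.ceil((hypha.length_um + 1.0) / pixel_size_um)) + 1
    # membrane-dye septum: a Gaussian ridge across the hyphal width
    x_sep_px = (hypha.tip_xy[1] + s_sep) / pixel_size_um
    yy = np.arange(ny)[:, None] * pixel_size_um
    xx = np.arange(nx)[None, :]
    y_c = hypha.tip_xy[0]
    in_band = np.abs(yy - y_c) <= hypha.width_um / 2
    ridge = 900.0 * np.exp(-((xx - x_sep_px) ** 2) / (2 * (0.12 / pixel_size_um) ** 2))
    septum_img = np.where(in_band, ridge, 0.0)

    ann = {
        "scene": "septum",
        "class": class_label,
        "septum_arclength_um": s_sep,
        "septum_x_um": hypha.tip_xy[1] + s_sep,
        "n_left": sum(1 for sg in sides if sg < 0),
        "n_right": sum(1 for sg in sides if sg > 0),
    }
    tracks, ann = _static_truth(entries, ann)
    truth = GroundTruth(tracks, [], {}, ann)
    movie = render_movie(
        hypha, truth, optics, (ny, nx), pixel_size_um,
        channel_names=("488", "CFW"), apply_poisson=apply_poisson,
        extra_sources={"CFW": septum_img},
    )
    return movie, truth


def disk_mask(shape_yx, center_yx_px, radius_px):
    """Boolean disk by pixel-center distance; used for puddle ROIs."""
    yy, xx = np.ogrid[: shape_yx[0], : shape_yx[1]]
    return (yy - center_yx_px[0]) ** 2 + (xx - center_yx_px[1]) ** 2 <= radius_px**2


def make_leakage_scene(
    total_leaked_signal,
    puddle_radius_um=2.0,
    optics=None,
    pixel_size_um=DEFAULT_PIXEL_SIZE_UM,
    apply_poisson=True,
    seed=0,
):
    """A burst-tip scene with a disk-shaped cytoplasmic puddle.

    The puddle's background-corrected integrated signal equals
    ``total_leaked_signal`` exactly in a noiseless render; the true value and
    the puddle geometry are recorded in the annotations.
    """
    if total_leaked_signal < 0:
        raise ValueError("total_leaked_signal must be >= 0")
    optics = optics if optics is not None else OpticsParams(seed=seed + 1)
    fov_um = (14.0, 18.0)
    ny = int(np.ceil(fov_um[0] / pixel_size_um))
    nx = int(np.ceil(fov_um[1] / pixel_size_um))
    hypha = straight_hypha(length_um=8.0, width_um=2.5, tip_yx_um=(fov_um[0] / 2, 9.5))

    # burst hypha body: uniform cytoplasmic marker in the band, fading at the tip
    yy = np.arange(ny)[:, None] * pixel_size_um
    xx = np.arange(nx)[None, :] * pixel_size_um
    y_c, x_tip = hypha.tip_xy
    body = ((np.abs(yy - y_c) <= hypha.width_um / 2) & (xx >= x_tip)) * 350.0

    center_um = (y_c, x_tip - puddle_radius_um - 1.0)
    center_px = (center_um[0] / pixel_size_um, center_um[1] / pixel_size_um)
    mask = disk_mask((ny, nx), center_px, puddle_radius_um / pixel_size_um)
    puddle = np.zeros((ny, nx))
    if mask.sum() and total_leaked_signal > 0:
        puddle[mask] = total_leaked_signal / mask.sum()

    ann = {
        "scene": "leakage",
        "total_leaked_signal": float(total_leaked_signal),
        "puddle_center_um": [float(c) for c in center_um],
        "puddle_radius_um": float(puddle_radius_um),
    }
    truth = GroundTruth([], [], {}, ann)
    movie = render_movie(
        hypha, truth, optics, (ny, nx), pixel_size_um,
        channel_names=("488",), apply_poisson=apply_poisson,
        extra_sources={"488": body + puddle},
    )
    return movie, truth


def make_flux_cell(
    n_anterograde=1,
    n_retrograde=1,
    line_um=10.0,
    window_s=30.0,
    dt_s=DEFAULT_FRAME_INTERVAL_S,
    speed_mean_um_s=1.72,
    speed_sd_um_s=0.79,
    n_stationary=3,
    hypha_length_um=22.0,
    channel="561",
    jitter_sd_um=0.03,
    seed=0,
):
    """A cell whose ground-truth crossing counts at ``line_um`` are set exactly.

    Each crossing punctum performs one directed run that traverses the line
    with randomized speed, extent and timing; ``n_stationary`` immobile puncta
    are added away from the line.  Used to tune the simulated flux to a target
    rate by construction.
    """
    rng = np.random.default_rng(seed)
    hypha = straight_hypha(length_um=hypha_length_um)
    n_frames = int(np.floor(window_s / dt_s + 1e-9)) + 1
    t_grid = np.arange(n_frames) * dt_s

    # distinct organelles start optically resolvable: keep all initial
    # positions >= 1.2 um apart in the (arclength, lateral) plane
    starts = []

    def _start(draw_s0):
        for _ in range(5000):
            s0 = draw_s0()
            lat = rng.uniform(-hypha.width_um / 3, hypha.width_um / 3)
            if all(np.hypot(s0 - s, lat - l) > 1.2 for s, l in starts):
                starts.append((s0, lat))
                return s0, lat
        raise RuntimeError("could not place flux-cell puncta resolvably")

    tracks, runs = [], []
    pid = 0
    directions = [+1] * n_anterograde + [-1] * n_retrograde
    n_cross = len(directions)
    slot = (window_s - 3.0) / max(n_cross, 1)  # one crossing per time slot
    # crossers occupy two zones (above/below the line); stagger each zone's
    # occupants axially so starts AND landing points all stay resolvable
    occupancy = {+1: 0, -1: 0}  # points above / below the line

    def _zone_band(side):
        # disjoint 1-um axial bands separated by 1.4 um per zone occupant
        lo = 1.8 + 2.4 * occupancy[side]
        occupancy[side] += 1
        return lo, lo + 1.0

    for k, direction in enumerate(directions):
        # direction +1 = anterograde = s decreasing through the line
        speed = _truncated_normal(rng, speed_mean_um_s, speed_sd_um_s, 0.8)
        lo_b, hi_b = _zone_band(direction)
        s_start, lat = _start(lambda: line_um + direction * rng.uniform(lo_b, hi_b))
        # the landing position must stay resolvable from every other punctum,
        # otherwise the runner fuses with a neighbor right after crossing
        lo_a, hi_a = _zone_band(-direction)
        s_end = line_um - direction * rng.uniform(lo_a, hi_a)
        starts.append((s_end, lat))
        run_dur = abs(s_end - s_start) / speed
        t0 = 1.5 + k * slot + rng.uniform(0.0, max(0.3, slot - run_dur - 0.5))
        bp_t = [0.0, t0, t0 + run_dur, window_s + dt_s]
        bp_s = [s_start, s_start, s_end, s_end]
        s_samp = np.interp(t_grid, bp_t, bp_s)
        in_run = (t_grid >= t0 - 1e-9) & (t_grid <= t0 + run_dur + 1e-9)
        s_samp = np.where(
            in_run, s_samp,
            np.clip(s_samp + rng.normal(0, jitter_sd_um, n_frames), 0, hypha.length_um),
        )
        tracks.append(TrackTruth(pid, channel, t_grid.copy(), s_samp, lat, rng.uniform(0.9, 1.3)))
        disp = float(s_start - s_end)
        runs.append(TrueRun(pid, t0, t0 + run_dur, disp, speed))
        pid += 1
    def _stationary_s0():
        while True:  # keep immobile puncta off the counting line
            s0 = rng.uniform(2.0, hypha.length_um - 2.0)
            if abs(s0 - line_um) >= 1.5:
                return s0

    for _ in range(n_stationary):
        s0, lat = _start(_stationary_s0)
        s_samp = np.clip(s0 + rng.normal(0, jitter_sd_um, n_frames), 0, hypha.length_um)
        tracks.append(TrackTruth(pid, channel, t_grid.copy(), s_samp, lat, rng.uniform(0.8, 1.2)))
        pid += 1

    ann = {
        "scene": "flux_cell",
        "dt_s": float(dt_s),
        "line_um": float(line_um),
        "window_s": float(window_s),
        "n_anterograde": n_anterograde,
        "n_retrograde": n_retrograde,
        "hypha_length_um": hypha.length_um,
    }
    return hypha, GroundTruth(tracks, runs, {}, ann)


# Simulation presets mirroring the genotypes contrasted in the study.
PRESETS = {
    "wildtype": MotilityParams(),
    "motility-null": MotilityParams(run_init_rate_per_s=0.0),
}


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def write_movie(movie, path):
    """Write a Movie to an OME-TIFF with full calibration metadata."""
    path = Path(path)
    data = movie.data
    data = data.astype(np.uint16) if np.issubdtype(data.dtype, np.integer) else data.astype(np.float32)
    tifffile.imwrite(
        path,
        data,
        ome=True,
        metadata={
            "axes": "TZCYX",
            "PhysicalSizeX": movie.pixel_size_um,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeY": movie.pixel_size_um,
            "PhysicalSizeYUnit": "µm",
            "PhysicalSizeZ": movie.z_step_um,
            "PhysicalSizeZUnit": "µm",
            "TimeIncrement": movie.frame_interval_s,
            "TimeIncrementUnit": "s",
            "Channel": {"Name": list(movie.channel_names)},
        },
    )


def _strip_ns(tag):
    return tag.rsplit("}", 1)[-1]


def read_movie(path):
    """Read an OME-TIFF written by :func:`write_movie` (lossless round trip).

    Calibration metadata (pixel size, frame interval) is required; a missing
    tag raises :class:`MovieFormatError` rather than assuming a default.
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tif:
            series = tif.series[0]
            data = series.asarray()
            axes = series.axes
            ome = tif.ome_metadata
    except (tifffile.TiffFileError, ValueError, OSError) as exc:
        raise MovieFormatError(f"cannot read {path}: {exc}") from exc
    if ome is None:
        raise MovieFormatError(f"{path} has no OME metadata")

    # expand to the full TZCYX order, inserting singleton axes as needed
    order = "TZCYX"
    axes = axes.replace("S", "C").replace("Q", "T")
    for ax in axes:
        if ax not in order:
            raise MovieFormatError(f"unsupported axis {ax!r} in {path}")
    for ax in order:
        if ax not in axes:
            data = np.expand_dims(data, axis=0)
            axes = ax + axes
    data = np.moveaxis(data, [axes.index(a) for a in order], range(5))

    root = ET.fromstring(ome)
    pixels = None
    for el in root.iter():
        if _strip_ns(el.tag) == "Pixels":
            pixels = el
            break
    if pixels is None:
        raise MovieFormatError(f"{path}: OME metadata lacks a Pixels element")
    if "PhysicalSizeX" not in pixels.attrib:
        raise MovieFormatError(f"{path}: missing PhysicalSizeX (pixel size) metadata")
    if "TimeIncrement" not in pixels.attrib:
        raise MovieFormatError(f"{path}: missing TimeIncrement (frame interval) metadata")
    pixel_size = float(pixels.attrib["PhysicalSizeX"])
    frame_interval = float(pixels.attrib["TimeIncrement"])
    z_step = float(pixels.attrib.get("PhysicalSizeZ", DEFAULT_Z_STEP_UM))
    names = [
        el.attrib.get("Name", str(i))
        for i, el in enumerate(e for e in pixels.iter() if _strip_ns(e.tag) == "Channel")
    ]
    if len(names) != data.shape[2]:
        names = [str(i) for i in range(data.shape[2])]
    return Movie(data, pixel_size, frame_interval, z_step, tuple(names))


def write_trace(path_um, csv_path):
    """Write a tip-first polyline of (y, x) um points to CSV."""
    arr = np.asarray(path_um, dtype=float)
    pd.DataFrame({"y_um": arr[:, 0], "x_um": arr[:, 1]}).to_csv(csv_path, index=False)


def read_trace(csv_path):
    df = pd.read_csv(csv_path)
    if not {"y_um", "x_um"} <= set(df.columns):
        raise MovieFormatError(f"{csv_path}: trace CSV needs y_um,x_um columns")
    return df[["y_um", "x_um"]].to_numpy()


def blind_dataset(paths, out_dir, seed=0):
    """Copy files under random opaque names and return the blinding key.

    The key (a DataFrame with columns blinded, original) is also written to
    ``out_dir/blinding_key.csv``.  The mapping is bijective and seeded.
    """
    paths = [Path(p) for p in paths]
    if not paths:
        raise BlindingError("blind_dataset needs at least one file")
    for p in paths:
        if not p.exists():
            raise BlindingError(f"no such file: {p}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    names = [f"blind_{rng.integers(0, 16**8):08x}{p.suffix}" for p in paths]
    if len(set(names)) != len(names):
        raise BlindingError("blinded name collision; use a different seed")
    for p, name in zip(paths, names):
        shutil.copyfile(p, out / name)
    key = pd.DataFrame({"blinded": names, "original": [str(p) for p in paths]})
    key.to_csv(out / "blinding_key.csv", index=False)
    return key
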