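"""Movement/sleep annotation of positional traces and per-fly features.

Raw frame-level positions are reduced to a 10-s interval grid: an interval is
*moving* if any frame-to-frame Euclidean displacement within it reaches the
0.25 mm threshold, otherwise immobile.  Maximal immobile runs strictly longer
than 5 min are sleep bouts (the whole run counts as sleep, including its
first 5 min).  Flies immobile continuously from some onset to the end of the
recording for at least 24 h are flagged dead and censored from the onset; the
first recording day is always excluded (habituation).

Frame velocities use the empirically calibrated correction
``v = 10^(d/1000) / (dt * fps * a)`` with ``d = 1000 * log10(displacement)``
and ``a = 0.0042``, which reduces to ``displacement / (dt * fps * a)`` for a
positive displacement; a zero displacement maps to velocity 0 by convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: empirically defined velocity correction factor (mm per dimensionless unit)
VELOCITY_CORRECTION = 0.0042
#: immobility threshold on frame-to-frame displacement (mm)
MOVE_THRESHOLD = 0.25
#: annotator resolution (s)
INTERVAL = 10.0
#: minimum immobility-run duration counted as sleep (s); strictly longer
MIN_SLEEP = 300.0


@dataclass
class FlyTrack:
    """One fly's positional time series plus schedule metadata."""

    fly_id: str
    genotype: str
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    fps: float
    zt0_offset: float = 0.0
    photoperiod: float = 12.0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.fps <= 0:
            raise ValueError("fps must be strictly positive")
        if self.t.size >= 2 and not np.all(np.diff(self.t) > 0):
            raise ValueError("timestamps must be strictly increasing")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, fps: float, fly_id: str | None = None,
                   genotype: str | None = None, **kw) -> "FlyTrack":
        return cls(
            fly_id=fly_id if fly_id is not None else str(df["fly_id"].iloc[0]),
            genotype=genotype if genotype is not None else str(df["genotype"].iloc[0]),
            t=df["t"].to_numpy(), x=df["x"].to_numpy(), y=df["y"].to_numpy(),
            fps=fps, **kw)


@dataclass
class FlyFeatures:
    """Sleep-architecture and activity summary for one fly."""

    fly_id: str
    genotype: str
    sleep_fraction_day: float
    sleep_fraction_night: float
    latency_longest_bout: float      # minutes from ZT12
    mean_bout_length_night: float    # minutes
    n_bouts_night: float             # per night
    morning_anticipation: float
    velocity_if_awake: float         # mm/s
    total_distance: float            # mm per 24 h

    FIELDS = ("sleep_fraction_day", "sleep_fraction_night",
              "latency_longest_bout", "mean_bout_length_night",
              "n_bouts_night", "morning_anticipation",
              "velocity_if_awake", "total_distance")


@dataclass
class QCResult:
    """Death call and excluded recording days for one fly."""

    fly_id: str
    dead: bool
    death_onset: float | None = None
    excluded_days: list[int] = field(default_factory=lambda: [0])


def corrected_velocity(displacement, dt, fps: float,
                       a: float = VELOCITY_CORRECTION):
    """Dimensionless corrected velocity of a frame-to-frame displacement.

    Zero displacements return 0 (the log-distance is undefined for a
    stationary fly).  Accepts scalars or arrays.
    """
    displacement = np.asarray(displacement, dtype=float)
    dt = np.asarray(dt, dtype=float)
    if np.any(displacement < 0):
        raise ValueError("displacement must be non-negative")
    if np.any(dt <= 0) or fps <= 0 or a <= 0:
        raise ValueError("dt, fps and a must be strictly positive")
    with np.errstate(divide="ignore"):
        d = 1000.0 * np.log10(displacement)
    v = np.where(displacement > 0,
                 np.power(10.0, d / 1000.0) / (dt * fps * a), 0.0)
    return float(v) if v.ndim == 0 else v


def annotate_intervals(track: FlyTrack,
                       move_threshold: float = MOVE_THRESHOLD) -> pd.DataFrame:
    """Annotate a track on the contiguous 10-s grid anchored at its start.

    Returns one row per window ``[start, start + 10 s)`` with columns
    ``interval_start, moving, max_displacement, corrected_velocity,
    log_distance, distance, missing``.  Windows with no frame-to-frame step
    (recording gaps longer than one interval) are flagged missing rather than
    interpolated.
    """
    if track.t.size < 2:
        raise ValueError("track must contain at least one full interval")
    disp = np.hypot(np.diff(track.x), np.diff(track.y))
    dt = np.diff(track.t)
    # corrected_velocity reduces to disp / (dt * fps * a) for disp > 0
    vel = np.where(disp > 0, disp / (dt * track.fps * VELOCITY_CORRECTION), 0.0)

    fpw = int(round(INTERVAL * track.fps))
    regular = (fpw > 0
               and np.allclose(dt, dt[0])
               and abs(dt[0] * fpw - INTERVAL) < 1e-9
               and track.t.size % fpw == 0)
    if regular:
        # fast path: fixed frames-per-window, reshape instead of scatter
        n_win = track.t.size // fpw
        padded = np.zeros(track.t.size)
        padded[1:] = disp
        block = padded.reshape(n_win, fpw)
        max_disp = block.max(axis=1)
        total_dist = block.sum(axis=1)
        vpad = np.zeros(track.t.size)
        vpad[1:] = vel
        vel_sum = vpad.reshape(n_win, fpw).sum(axis=1)
        counts = np.full(n_win, fpw)
        counts[0] = fpw - 1     # first window lacks the step into frame 0
    else:
        # displacement i belongs to the window containing the later frame
        win = np.floor((track.t[1:] - track.t[0]) / INTERVAL).astype(int)
        n_win = int(win.max()) + 1
        max_disp = np.zeros(n_win)
        np.maximum.at(max_disp, win, disp)
        total_dist = np.zeros(n_win)
        np.add.at(total_dist, win, disp)
        counts = np.bincount(win, minlength=n_win)
        vel_sum = np.zeros(n_win)
        np.add.at(vel_sum, win, vel)
    with np.errstate(invalid="ignore"):
        vel_mean = np.where(counts > 0, vel_sum / np.maximum(counts, 1), np.nan)

    missing = counts == 0
    moving = max_disp >= move_threshold
    with np.errstate(divide="ignore"):
        log_d = np.where(max_disp > 0, 1000.0 * np.log10(max_disp), 0.0)
    return pd.DataFrame({
        "interval_start": track.t[0] + INTERVAL * np.arange(n_win),
        "moving": moving & ~missing,
        "max_displacement": max_disp,
        "corrected_velocity": vel_mean,
        "log_distance": log_d,
        "distance": total_dist,
        "missing": missing,
    })


def _immobile_runs(immobile: np.ndarray) -> list[tuple[int, int]]:
    """(start, stop) index pairs of maximal True runs, stop exclusive."""
    padded = np.concatenate([[False], immobile, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    return list(zip(edges[::2], edges[1::2]))


def score_sleep(annotations: pd.DataFrame,
                min_sleep: float = MIN_SLEEP) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the 5-min rule; returns (annotations + asleep column, bouts).

    A maximal run of immobile (non-missing) intervals whose total duration
    exceeds ``min_sleep`` seconds is a sleep bout; all of its intervals are
    marked asleep, including the first five minutes.
    """
    ann = annotations.copy()
    immobile = (~ann["moving"].to_numpy()) & (~ann["missing"].to_numpy())
    asleep = np.zeros(len(ann), dtype=bool)
    bouts = []
    for start, stop in _immobile_runs(immobile):
        duration = (stop - start) * INTERVAL
        if duration > min_sleep:
            asleep[start:stop] = True
            bouts.append((ann["interval_start"].iloc[start], duration))
    ann["asleep"] = asleep
    bout_df = pd.DataFrame(bouts, columns=["onset", "duration"])
    return ann, bout_df


def detect_death(annotations: pd.DataFrame, fly_id: str = "",
                 window: float = 24.0) -> QCResult:
    """Flag a fly dead if immobile continuously through the final ``window`` hours.

    The onset of the terminal immobile run is the death onset; data from the
    onset onward are censored by the caller.  The first recording day is
    always excluded (habituation).
    """
    immobile = (~annotations["moving"].to_numpy()) & (~annotations["missing"].to_numpy())
    runs = _immobile_runs(immobile)
    dead = False
    onset = None
    if runs and runs[-1][1] == len(annotations):
        start, stop = runs[-1]
        if (stop - start) * INTERVAL >= window * 3600.0:
            dead = True
            onset = float(annotations["interval_start"].iloc[start])
    return QCResult(fly_id=fly_id, dead=dead, death_onset=onset, excluded_days=[0])


def _zt(interval_start: np.ndarray, zt0_offset: float) -> np.ndarray:
    """Zeitgeber time (h) of each interval start."""
    return ((interval_start - zt0_offset) % 86400.0) / 3600.0


def _retained_mask(ann: pd.DataFrame, qc: QCResult, zt0_offset: float) -> np.ndarray:
    day_index = np.floor((ann["interval_start"].to_numpy() - zt0_offset) / 86400.0)
    keep = ~np.isin(day_index, qc.excluded_days)
    if qc.dead and qc.death_onset is not None:
        keep &= ann["interval_start"].to_numpy() < qc.death_onset
    keep &= ~ann["missing"].to_numpy()
    return keep


def morning_anticipation(ann: pd.DataFrame, zt0_offset: float = 0.0,
                         photoperiod: float = 12.0,
                         retained: np.ndarray | None = None) -> float:
    """Activity ratio (last 3 h of dark) / (last 6 h of dark), meaned over nights.

    0.5 means flat late-night activity; values above 0.5 indicate an
    anticipatory ramp before lights-on.  NaN when no activity occurred in the
    final 6 h of any retained night.
    """
    zt = _zt(ann["interval_start"].to_numpy(), zt0_offset)
    if retained is None:
        retained = ~ann["missing"].to_numpy()
    moving = ann["moving"].to_numpy() & retained
    night_idx = np.floor((ann["interval_start"].to_numpy() - zt0_offset) / 86400.0)
    last6 = (zt >= 18.0) & retained
    last3 = (zt >= 21.0) & retained
    ratios = []
    for night in np.unique(night_idx[last6]):
        sel = night_idx == night
        a6 = np.sum(moving[sel & last6])
        a3 = np.sum(moving[sel & last3])
        if a6 > 0:
            ratios.append(a3 / a6)
    return float(np.mean(ratios)) if ratios else math.nan


def extract_features(track: FlyTrack, annotations: pd.DataFrame,
                     bouts: pd.DataFrame, qc: QCResult) -> FlyFeatures:
    """Per-fly sleep-architecture features averaged over retained days.

    Day/night assignment: ZT in [0, photoperiod) is light, the remainder is
    dark.  Latency is the weighted mean over nights of (onset of the night's
    longest bout − ZT12), with nights weighted by the retained fraction of
    their dark phase; bout statistics are restricted to the dark phase.
    """
    ann = annotations
    keep = _retained_mask(ann, qc, track.zt0_offset)
    if not keep.any():
        raise ValueError(f"{track.fly_id}: no retained data after QC")
    zt = _zt(ann["interval_start"].to_numpy(), track.zt0_offset)
    light = zt < track.photoperiod
    asleep = ann["asleep"].to_numpy()

    day_sel = keep & light
    night_sel = keep & ~light
    sf_day = float(asleep[day_sel].mean()) if day_sel.any() else math.nan
    sf_night = float(asleep[night_sel].mean()) if night_sel.any() else math.nan

    # per-night bout statistics on the dark phase
    starts = ann["interval_start"].to_numpy()
    night_index = np.floor((starts - track.zt0_offset) / 86400.0)
    lat_vals, lat_w, blen, bnum = [], [], [], []
    b_on = bouts["onset"].to_numpy() if len(bouts) else np.empty(0)
    b_end = b_on + (bouts["duration"].to_numpy() if len(bouts) else np.empty(0))
    for night in np.unique(night_index[night_sel]):
        sel = night_sel & (night_index == night)
        weight = sel.sum() / (((24.0 - track.photoperiod) * 3600.0) / INTERVAL)
        zt12 = track.zt0_offset + night * 86400.0 + track.photoperiod * 3600.0
        night_end = track.zt0_offset + (night + 1) * 86400.0
        # bouts clipped to this night's dark window
        on = np.maximum(b_on, zt12)
        off = np.minimum(b_end, night_end)
        dur = off - on
        in_night = dur > 0
        bnum.append(int(in_night.sum()))
        if in_night.any():
            blen.append(dur[in_night].mean() / 60.0)
            longest_on = on[in_night][np.argmax(dur[in_night])]
            lat_vals.append((longest_on - zt12) / 60.0)
            lat_w.append(weight)

    latency = (float(np.average(lat_vals, weights=lat_w))
               if lat_vals else math.nan)
    mean_blen = float(np.mean(blen)) if blen else 0.0
    n_bouts = float(np.mean(bnum)) if bnum else 0.0

    moving = ann["moving"].to_numpy() & keep
    vel = ann["corrected_velocity"].to_numpy()
    # corrected velocity is dimensionless; rescale to mm/s via the correction
    v_awake = (float(np.nanmean(vel[moving])) * VELOCITY_CORRECTION * track.fps
               if moving.any() else 0.0)
    n_days_kept = keep.sum() * INTERVAL / 86400.0
    total_dist = float(ann["distance"].to_numpy()[keep].sum() / max(n_days_kept, 1e-9))

    return FlyFeatures(
        fly_id=track.fly_id, genotype=track.genotype,
        sleep_fraction_day=sf_day, sleep_fraction_night=sf_night,
        latency_longest_bout=max(latency, 0.0) if not math.isnan(latency) else math.nan,
        mean_bout_length_night=mean_blen, n_bouts_night=n_bouts,
        morning_anticipation=morning_anticipation(
            ann, track.zt0_offset, track.photoperiod, retained=keep),
        velocity_if_awake=v_awake, total_distance=total_dist)


def annotate_fly(track: FlyTrack, move_threshold: float = MOVE_THRESHOLD,
                 min_sleep: float = MIN_SLEEP) -> tuple[pd.DataFrame, pd.DataFrame, QCResult]:
    """Convenience chain: intervals → sleep scoring → death QC."""
    ann = annotate_intervals(track, move_threshold)
    ann, bouts = score_sleep(ann, min_sleep)
    qc = detect_death(ann, fly_id=track.fly_id)
    return ann, bouts, qc


def features_table(feature_list: list[FlyFeatures]) -> pd.DataFrame:
    """Stack per-fly features into one row per fly."""
    rows = [{"fly_id": f.fly_id, "genotype": f.genotype,
             **{k: getattr(f, k) for k in FlyFeatures.FIELDS}}
            for f in feature_list]
    return pd.DataFrame(rows)
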