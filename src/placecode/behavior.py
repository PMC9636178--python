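"""Lap segmentation and behavioral readouts of reward expectation.

Segments a session into track traversals (laps), detects the lap on which
anticipatory licking stops after reward removal (the RE_high / RE_low
boundary), classifies lap-wise engagement with the environment from
approach behavior (deceleration toward the track end) or pupil-area
dynamics, and provides the small helpers used throughout (approach ratio,
matched-velocity lap split, trailing rolling average).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .session import SessionRecord, BinningSpec

NEVER = "never"           # sentinel: licking never stopped
RE_HIGH = "RE_HIGH"
RE_LOW = "RE_LOW"
ENGAGED = "ENGAGED"
DISENGAGED = "DISENGAGED"
NOT_CLASSIFIED = "not-classified"
NOT_APPLICABLE = "not-applicable"


@dataclass
class Lap:
    """One traversal of the track (teleportation to teleportation)."""

    lap_index: int                 # 1-based within condition
    start_frame: int
    end_frame: int                 # half-open
    condition: str
    duration_s: float
    velocity_by_position: np.ndarray
    approach_ratio: float          # nan when undefined
    anticipatory_lick_count: int = 0
    partial: bool = False
    re_label: str = NOT_APPLICABLE
    engagement: str = NOT_CLASSIFIED


@dataclass
class LapTable:
    laps: list[Lap] = field(default_factory=list)

    def __iter__(self):
        return iter(self.laps)

    def __len__(self):
        return len(self.laps)

    def select(self, condition: str | None = None, re_label: str | None = None,
               engagement: str | None = None, complete: bool = True) -> list[Lap]:
        out = []
        for lap in self.laps:
            if complete and lap.partial:
                continue
            if condition is not None and lap.condition != condition:
                continue
            if re_label is not None and lap.re_label != re_label:
                continue
            if engagement is not None and lap.engagement != engagement:
                continue
            out.append(lap)
        return out

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "lap_index": l.lap_index,
                    "condition": l.condition,
                    "start_frame": l.start_frame,
                    "end_frame": l.end_frame,
                    "duration_s": l.duration_s,
                    "approach_ratio": l.approach_ratio,
                    "anticipatory_lick_count": l.anticipatory_lick_count,
                    "re_label": l.re_label,
                    "engagement": l.engagement,
                    "partial": l.partial,
                }
                for l in self.laps
            ]
        )


def _binned_velocity(session: SessionRecord, start: int, end: int,
                     spec: BinningSpec) -> np.ndarray:
    """Mean instantaneous velocity per 5 cm position bin for one lap."""
    pos = session.position[start:end]
    vel = session.velocity[start:end]
    moving = vel > 0
    bins = spec.bin_of(pos[moving])
    sums = np.bincount(bins, weights=vel[moving], minlength=spec.n_bins)
    counts = np.bincount(bins, minlength=spec.n_bins)
    with np.errstate(invalid="ignore"):
        out = np.divide(sums, counts, out=np.full(spec.n_bins, np.nan),
                        where=counts > 0)
    return out


def approach_ratio(velocity_by_position: np.ndarray,
                   spec: BinningSpec | None = None) -> float:
    """Mid-track (100-150 cm) over end-track (175-200 cm) mean velocity.

    Values above 1 mean the animal decelerates approaching the track end;
    nan when the end-track velocity is unavailable or zero.
    """
    spec = spec or BinningSpec()
    mid = velocity_by_position[spec.bins_covering(100.0, 150.0)]
    end = velocity_by_position[spec.bins_covering(175.0, 200.0)]
    mid_mean = np.nanmean(mid) if np.any(np.isfinite(mid)) else np.nan
    end_mean = np.nanmean(end) if np.any(np.isfinite(end)) else np.nan
    if not np.isfinite(end_mean) or end_mean <= 0:
        return float("nan")
    return float(mid_mean / end_mean)


def segment_laps(session: SessionRecord, spec: BinningSpec | None = None) -> LapTable:
    """Split the session into laps.

    A lap starts at the first frame whose position is below the previous
    frame's position (teleportation wrap) or at a session/condition start;
    a condition change mid-track splits the lap and flags both parts
    partial.  Every frame belongs to exactly one lap.  The final lap is
    flagged partial unless the track was completed (a wrap or session end
    at the track end).
    """
    spec = spec or BinningSpec()
    pos = session.position
    cond = session.condition
    T = session.n_frames
    if T == 0:
        return LapTable([])

    wrap = np.zeros(T, dtype=bool)
    wrap[1:] = pos[1:] < pos[:-1] - session.track_length / 2
    cond_change = np.zeros(T, dtype=bool)
    cond_change[1:] = cond[1:] != cond[:-1]
    starts = np.flatnonzero(wrap | cond_change)
    boundaries = np.concatenate([[0], starts, [T]])
    boundaries = np.unique(boundaries)

    laps: list[Lap] = []
    counters: dict[str, int] = {}
    for a, b in zip(boundaries[:-1], boundaries[1:]):
        a, b = int(a), int(b)
        c = cond[a]
        counters[c] = counters.get(c, 0) + 1
        started_mid_track = pos[a] > spec.bin_width
        ended_mid_track = pos[b - 1] < session.track_length - 4 * spec.bin_width \
            and not (b < T and wrap[b])
        # a lap that starts or ends because the condition changed mid-track,
        # or the trailing remainder of the session, is partial
        partial = bool(started_mid_track or ended_mid_track)
        vbp = _binned_velocity(session, a, b, spec)
        # traversal duration excludes the post-reward/teleportation pause
        moving = np.flatnonzero(session.velocity[a:b] > 0)
        last_moving = moving[-1] if moving.size else b - 1 - a
        laps.append(
            Lap(
                lap_index=counters[c],
                start_frame=a,
                end_frame=b,
                condition=c,
                duration_s=float(session.time[a + last_moving] - session.time[a]
                                 + 1.0 / session.frame_rate),
                velocity_by_position=vbp,
                approach_ratio=approach_ratio(vbp, spec),
                partial=partial,
            )
        )

    conditions_seen = set(cond)
    for c in conditions_seen:
        if not any(l.condition == c and not l.partial for l in laps):
            warnings.warn(f"condition {c!r} contains no complete lap")
    return LapTable(laps)


def anticipation_zone(session: SessionRecord, lap_table: LapTable) -> float:
    """Start (cm) of the anticipatory-licking zone.

    Mean over rewarded-condition laps of the position of the first lick in
    each licking lap; lick-free laps are ignored.  The zone runs from this
    position to the track end and through the post-teleportation pause.
    """
    first_lick_positions = []
    for lap in lap_table.select(condition="R"):
        licks = np.flatnonzero(session.lick[lap.start_frame:lap.end_frame])
        if licks.size:
            first_lick_positions.append(
                session.position[lap.start_frame + licks[0]])
    if not first_lick_positions:
        raise ValueError(
            "no licks in rewarded laps; reward-expectation analysis undefined")
    return float(np.mean(first_lick_positions))


def count_anticipatory_licks(session: SessionRecord, lap: Lap,
                             zone_start_cm: float) -> int:
    """Licks within the anticipation zone (zone start to teleportation,
    pause included) during one lap."""
    sl = slice(lap.start_frame, lap.end_frame)
    in_zone = session.position[sl] >= zone_start_cm
    return int(np.count_nonzero(session.lick[sl] & in_zone))


def detect_lick_stop_lap(session: SessionRecord, lap_table: LapTable,
                         zone_start_cm: float, k_consecutive: int = 2):
    """Find the UR lap where anticipatory licking has stopped.

    The stop lap is the lap following the *first* run of ``k_consecutive``
    UR laps with zero anticipatory licks; isolated licks on later laps do
    not relabel (first-occurrence rule).  UR laps before the stop lap are
    labeled RE_HIGH, from it onward RE_LOW (written into the lap table).
    Returns the 1-based UR lap index, or the sentinel ``"never"``.
    """
    ur_laps = lap_table.select(condition="UR")
    if not ur_laps:
        raise ValueError("session has no UR laps")
    for lap in ur_laps:
        lap.anticipatory_lick_count = count_anticipatory_licks(
            session, lap, zone_start_cm)

    stop: int | str = NEVER
    silent_run = 0
    for lap in ur_laps:
        if lap.anticipatory_lick_count == 0:
            silent_run += 1
            if silent_run == k_consecutive:
                stop = lap.lap_index + 1
                break
        else:
            silent_run = 0

    for lap in ur_laps:
        if stop == NEVER or lap.lap_index < stop:
            lap.re_label = RE_HIGH
        else:
            lap.re_label = RE_LOW
    return stop


def classify_engagement_approach(lap_table: LapTable,
                                 sd_mult: float = 1.5) -> None:
    """Label RE_LOW laps ENGAGED / DISENGAGED from approach behavior.

    A lap is ENGAGED when its approach ratio is at least
    ``mean_R - sd_mult * sd_R`` of the rewarded-condition ratios (i.e. not
    unusually flat); the threshold is scale-invariant in velocity.
    """
    r_ratios = np.array([l.approach_ratio for l in lap_table.select(condition="R")
                         if np.isfinite(l.approach_ratio)])
    if r_ratios.size < 2:
        raise ValueError("need at least 2 rewarded laps to set the "
                         "engagement threshold")
    threshold = r_ratios.mean() - sd_mult * r_ratios.std(ddof=1)
    for lap in lap_table.select(condition="UR", re_label=RE_LOW):
        if not np.isfinite(lap.approach_ratio):
            warnings.warn(f"UR lap {lap.lap_index}: approach ratio undefined, "
                          "lap not classified")
            continue
        lap.engagement = ENGAGED if lap.approach_ratio >= threshold else DISENGAGED


def pupil_engagement(session: SessionRecord, lap_table: LapTable,
                     sd_mult: float = 1.5, spec: BinningSpec | None = None) -> dict:
    """Per-lap pupil-area correlation with the rewarded-lap template.

    Blink frames (blink area below mean minus two standard deviations) are
    removed and linearly interpolated; immobile frames are excluded; the
    pupil trace is binned into 40 position bins per lap; the template is
    the mean over rewarded laps.  Laps whose Pearson correlation with the
    template falls below ``mean_R - sd_mult * sd_R`` of rewarded-lap
    correlations are labeled DISENGAGED.

    Also reports the three per-lap nuisance summaries: mean eye movement is
    not computed here (no pupil-center channel in the data model), blink
    ratio and freezing ratio are flagged-frame fractions.
    """
    spec = spec or BinningSpec()
    if session.pupil_area is None:
        raise ValueError("pupil channel not present in this session")
    pupil = session.pupil_area.astype(float).copy()

    blink_ratio_flags = np.zeros(session.n_frames, dtype=bool)
    if session.blink_area is not None:
        blink = session.blink_area
        blink_thresh = blink.mean() - 2.0 * blink.std()
        blink_frames = blink < blink_thresh
        blink_ratio_flags = blink_frames
        if blink_frames.any() and not blink_frames.all():
            good = np.flatnonzero(~blink_frames)
            pupil[blink_frames] = np.interp(np.flatnonzero(blink_frames),
                                            good, pupil[good])

    run = session.run_mask

    def lap_curve(lap: Lap) -> np.ndarray:
        sl = slice(lap.start_frame, lap.end_frame)
        sel = run[sl]
        bins = spec.bin_of(session.position[sl][sel])
        sums = np.bincount(bins, weights=pupil[sl][sel], minlength=spec.n_bins)
        counts = np.bincount(bins, minlength=spec.n_bins)
        return np.divide(sums, counts, out=np.full(spec.n_bins, np.nan),
                         where=counts > 0)

    r_laps = lap_table.select(condition="R")
    if not r_laps:
        raise ValueError("no rewarded laps to build the pupil template")
    template = np.nanmean(np.stack([lap_curve(l) for l in r_laps]), axis=0)

    def corr_with_template(curve: np.ndarray) -> float:
        ok = np.isfinite(curve) & np.isfinite(template)
        if ok.sum() < 3 or curve[ok].std() == 0 or template[ok].std() == 0:
            return float("nan")
        return float(np.corrcoef(curve[ok], template[ok])[0, 1])

    report: dict = {"template": template, "laps": []}
    r_corrs = []
    for lap in r_laps:
        r_corrs.append(corr_with_template(lap_curve(lap)))
    r_corrs = np.array([c for c in r_corrs if np.isfinite(c)])
    threshold = r_corrs.mean() - sd_mult * r_corrs.std(ddof=1) if r_corrs.size >= 2 \
        else -np.inf
    report["threshold"] = float(threshold)

    for lap in lap_table:
        sl = slice(lap.start_frame, lap.end_frame)
        n = lap.end_frame - lap.start_frame
        corr = corr_with_template(lap_curve(lap))
        label = NOT_CLASSIFIED
        if np.isfinite(corr):
            label = ENGAGED if corr >= threshold else DISENGAGED
        report["laps"].append(
            {
                "condition": lap.condition,
                "lap_index": lap.lap_index,
                "pupil_correlation": corr,
                "engagement": label,
                "blink_ratio": float(blink_ratio_flags[sl].mean()) if n else 0.0,
                "freezing_ratio": float((~run[sl]).mean()) if n else 0.0,
            }
        )
    return report


def match_velocity_laps(r_durations, ur_durations, method: str = "range",
                        bin_width_s: float = 1.0):
    """Split UR laps into matched-velocity and slower sets.

    ``method="range"``: a UR lap is matched when its duration falls within
    [min, max] of the rewarded-lap durations.  ``method="histogram"``: a
    UR lap is matched when it falls in a nonempty bin of the rewarded-lap
    duration histogram (``bin_width_s`` bins).
    """
    r = np.asarray(r_durations, dtype=float)
    ur = np.asarray(ur_durations, dtype=float)
    if r.size == 0 or ur.size == 0:
        raise ValueError("both duration sets must be nonempty")
    if method == "range":
        matched = (ur >= r.min()) & (ur <= r.max())
    elif method == "histogram":
        edges = np.arange(0.0, max(r.max(), ur.max()) + 2 * bin_width_s,
                          bin_width_s)
        occupied = np.histogram(r, bins=edges)[0] > 0
        idx = np.clip(np.digitize(ur, edges) - 1, 0, occupied.size - 1)
        matched = occupied[idx]
    else:
        raise ValueError(f"unknown method {method!r}")
    matched_idx = np.flatnonzero(matched)
    slower_idx = np.flatnonzero(~matched)
    return matched_idx, slower_idx


def rolling_average(series, window: int = 3) -> np.ndarray:
    """Trailing (causal) rolling mean; each output averages the last
    ``min(window, available)`` points, so output length equals input."""
    x = np.asarray(series, dtype=float)
    out = np.empty_like(x)
    for i in range(x.size):
        out[i] = x[max(0, i - window + 1): i + 1].mean()
    return out
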