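"""Dopaminergic-axon trace preprocessing and ramp-to-reward metrics.

Axon ROIs whose traces are highly correlated are merged; dF/F uses a wide
sliding-percentile baseline (2000 frames) appropriate for slowly varying
neuropil-scale signals.  Each lap's fluorescence is aligned to reward
delivery and divided into 34 pre-reward + 6 post-reward time bins (per-lap
equal fractions of the pre-reward span so laps of different duration align
bin-wise), min-subtracted per lap and max-normalized per session.  The
ramp is quantified per lap by the maximum binned value, the slope of a
line fit between the located minimum (near lap start) and maximum (near
lap end), and their product slope*max; all three are normalized by their
rewarded-condition lap means, so the R means are exactly 1.  A
motion-initiation-aligned view supports checking for velocity- rather than
reward-coupled axons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .session import SessionRecord, BinningSpec
from .behavior import Lap

N_PRE_BINS = 34
N_POST_BINS = 6
POST_REWARD_S = 2.0


def merge_correlated_rois(traces: np.ndarray, threshold: float = 0.7) -> np.ndarray:
    """Merge ROI traces whose Pearson correlation is >= ``threshold``.

    Merging follows connected components of the correlation graph (a chain
    A~B~C merges even if A and C correlate weakly); each merged trace is
    the mean of its members.  Returns merged traces in order of first
    member.
    """
    traces = np.atleast_2d(np.asarray(traces, dtype=float))
    n = traces.shape[0]
    if n <= 1:
        return traces.copy()
    corr = np.corrcoef(traces)
    adj = csr_matrix(np.nan_to_num(corr) >= threshold)
    n_comp, labels = connected_components(adj, directed=False)
    order = []
    seen = set()
    for lab in labels:
        if lab not in seen:
            seen.add(lab)
            order.append(lab)
    return np.stack([traces[labels == lab].mean(axis=0) for lab in order])


def axon_dff(raw: np.ndarray, window: int = 2000,
             percentile: float = 8.0) -> np.ndarray:
    """dF/F with a wide sliding-percentile baseline.

    F0 is the centered rolling ``percentile`` of the raw trace over
    ``window`` frames (edge-truncated); traces shorter than the window use
    the full trace with a warning.  Raw fluorescence must be positive.
    """
    import pandas as pd

    f = np.asarray(raw, dtype=float)
    if f.size < window:
        warnings.warn(f"trace ({f.size} frames) shorter than baseline window "
                      f"({window}); using full-trace window")
        window = f.size
    f0 = (pd.Series(f).rolling(window, center=True, min_periods=1)
          .quantile(percentile / 100.0).to_numpy())
    if np.any(f0 <= 0):
        raise ValueError("nonpositive baseline; raw fluorescence must be positive")
    return (f - f0) / f0


@dataclass
class RampProfile:
    """Reward-aligned binned fluorescence and per-lap ramp metrics."""

    time_binned: np.ndarray          # laps x 40 (34 pre + 6 post), normalized
    position_binned: np.ndarray      # laps x 40 position bins, normalized
    lap_conditions: list[str]
    lap_indices: list[int]
    lap_re_keys: list[str]           # R / RE_HIGH / RE_LOW / RR ...
    post_missing: np.ndarray         # laps lacking complete post-reward bins
    slope: np.ndarray = field(default=None)      # per lap, R-normalized
    max: np.ndarray = field(default=None)
    slope_max: np.ndarray = field(default=None)
    excluded: np.ndarray = field(default=None)   # degenerate-fit laps
    max_range: tuple[int, int] | None = None     # R-derived search ranges
    min_range: tuple[int, int] | None = None

    def condition_mean(self, metric: str, key: str) -> float:
        values = getattr(self, metric)
        sel = np.array([k == key for k in self.lap_re_keys]) & ~self.excluded
        return float(values[sel].mean()) if sel.any() else float("nan")


def _alignment_frame(session: SessionRecord, lap: Lap) -> int:
    """Reward-delivery frame, or the teleportation (end-of-running) frame
    for unrewarded laps where reward previously occurred."""
    sl = slice(lap.start_frame, lap.end_frame)
    rew = np.flatnonzero(session.reward[sl])
    if rew.size:
        return lap.start_frame + int(rew[0])
    moving = np.flatnonzero(session.velocity[sl] > 0)
    last = int(moving[-1]) if moving.size else lap.end_frame - 1 - lap.start_frame
    return lap.start_frame + last


def _re_key(lap: Lap) -> str:
    if lap.condition == "UR" and lap.re_label in ("RE_HIGH", "RE_LOW"):
        return lap.re_label
    return lap.condition


def bin_by_time_to_reward(trace: np.ndarray, session: SessionRecord,
                          laps: list[Lap]) -> tuple[np.ndarray, np.ndarray]:
    """Laps x 40 reward-aligned time-binned fluorescence.

    The pre-reward span of each lap is divided into 34 equal time bins and
    the 2 s after reward into 6 bins; each lap's row is min-subtracted and
    the whole session is divided by its maximum bin value.  Returns
    ``(matrix, post_missing)`` where ``post_missing`` flags laps whose
    post-reward span is truncated (those bins carry nan).
    """
    n_post_frames = int(round(POST_REWARD_S * session.frame_rate))
    rows = []
    post_missing = np.zeros(len(laps), dtype=bool)
    for li, lap in enumerate(laps):
        align = _alignment_frame(session, lap)
        pre = trace[lap.start_frame:align + 1]
        edges = np.linspace(0, pre.size, N_PRE_BINS + 1).astype(int)
        row = [pre[a:b].mean() if b > a else np.nan
               for a, b in zip(edges[:-1], edges[1:])]
        post = trace[align + 1: align + 1 + n_post_frames]
        if post.size < n_post_frames:
            post_missing[li] = True
        if post.size:
            pedges = np.linspace(0, post.size, N_POST_BINS + 1).astype(int)
            row += [post[a:b].mean() if b > a else np.nan
                    for a, b in zip(pedges[:-1], pedges[1:])]
        else:
            row += [np.nan] * N_POST_BINS
        rows.append(row)
    matrix = np.asarray(rows, dtype=float)
    matrix = matrix - np.nanmin(matrix, axis=1, keepdims=True)
    peak = np.nanmax(matrix)
    if peak > 1e-12:        # flat signals stay at zero
        matrix = matrix / peak
    else:
        matrix = np.where(np.isnan(matrix), matrix, 0.0)
    return matrix, post_missing


def bin_by_position(trace: np.ndarray, session: SessionRecord,
                    laps: list[Lap], spec: BinningSpec | None = None
                    ) -> np.ndarray:
    """Laps x 40 position-binned fluorescence, min-subtracted per lap and
    max-normalized per session (mirror of the time-binned path)."""
    spec = spec or BinningSpec()
    rows = []
    for lap in laps:
        sl = slice(lap.start_frame, lap.end_frame)
        moving = session.velocity[sl] > 0
        bins = spec.bin_of(session.position[sl][moving])
        sums = np.bincount(bins, weights=trace[sl][moving], minlength=spec.n_bins)
        counts = np.bincount(bins, minlength=spec.n_bins)
        rows.append(np.divide(sums, counts, out=np.full(spec.n_bins, np.nan),
                              where=counts > 0))
    matrix = np.asarray(rows)
    matrix = matrix - np.nanmin(matrix, axis=1, keepdims=True)
    peak = np.nanmax(matrix)
    if peak > 1e-12:        # flat signals stay at zero
        matrix = matrix / peak
    else:
        matrix = np.where(np.isnan(matrix), matrix, 0.0)
    return matrix


def ramp_slope_max(time_binned: np.ndarray, re_keys: list[str],
                   max_window: int = 15, min_window: int = 25):
    """Per-lap ramp metrics: maximum, slope, and slope*max.

    On rewarded (R) laps the maximum is located within ``max_window``
    pre-reward bins of lap end and the minimum within ``min_window`` bins
    of lap start; in every other condition the search ranges are restricted
    to the nearest and furthest bins where the R maxima/minima were found.
    The slope is the least-squares line over the bins between the located
    minimum and maximum (inclusive).  Each metric is divided by its R-lap
    mean, making the R means exactly 1.  Laps whose located minimum bin is
    at or beyond their maximum bin are flagged excluded.
    Returns ``(slope, max, slope_max, excluded, max_range, min_range)``.
    """
    pre = time_binned[:, :N_PRE_BINS]
    L = pre.shape[0]
    is_r = np.array([k == "R" for k in re_keys])
    if not is_r.any():
        raise ValueError("rewarded laps are required to fix search ranges")

    max_lo_r = N_PRE_BINS - max_window
    r_max_bins = max_lo_r + np.nanargmax(pre[is_r, max_lo_r:], axis=1)
    r_min_bins = np.nanargmin(pre[is_r, :min_window], axis=1)
    max_range = (int(r_max_bins.min()), int(r_max_bins.max()))
    min_range = (int(r_min_bins.min()), int(r_min_bins.max()))

    slope = np.full(L, np.nan)
    vmax = np.full(L, np.nan)
    excluded = np.zeros(L, dtype=bool)
    for i in range(L):
        row = pre[i]
        if is_r[i]:
            mx = max_lo_r + int(np.nanargmax(row[max_lo_r:]))
            mn = int(np.nanargmin(row[:min_window]))
        else:
            a, b = max_range
            mx = a + int(np.nanargmax(row[a:b + 1]))
            a, b = min_range
            mn = a + int(np.nanargmin(row[a:b + 1]))
        vmax[i] = np.nanmax(row)
        if mn >= mx:
            excluded[i] = True
            continue
        xs = np.arange(mn, mx + 1)
        ys = row[mn:mx + 1]
        ok = np.isfinite(ys)
        if ok.sum() < 2:
            excluded[i] = True
            continue
        slope[i] = np.polyfit(xs[ok], ys[ok], 1)[0]

    def normalize(v):
        sel = is_r & ~excluded & np.isfinite(v)
        mean_r = v[sel].mean() if sel.any() else np.nan
        return v / mean_r if mean_r and np.isfinite(mean_r) and mean_r != 0 else v

    slope_n = normalize(slope)
    max_n = normalize(vmax)
    product = slope_n * max_n
    slope_max = normalize(product)
    return slope_n, max_n, slope_max, excluded, max_range, min_range


def ramp_profile(trace: np.ndarray, session: SessionRecord,
                 laps: list[Lap], spec: BinningSpec | None = None) -> RampProfile:
    """Full ramp quantification of one axon over the given laps."""
    time_binned, post_missing = bin_by_time_to_reward(trace, session, laps)
    position_binned = bin_by_position(trace, session, laps, spec)
    re_keys = [_re_key(l) for l in laps]
    slope, vmax, slope_max, excluded, max_rng, min_rng = ramp_slope_max(
        time_binned, re_keys)
    return RampProfile(
        time_binned=time_binned,
        position_binned=position_binned,
        lap_conditions=[l.condition for l in laps],
        lap_indices=[l.lap_index for l in laps],
        lap_re_keys=re_keys,
        post_missing=post_missing,
        slope=slope,
        max=vmax,
        slope_max=slope_max,
        excluded=excluded,
        max_range=max_rng,
        min_range=min_rng,
    )


def motion_aligned_activity(trace: np.ndarray, velocity: np.ndarray,
                            frame_rate: float = 30.0, pre_s: float = 2.0,
                            post_s: float = 8.0, speed_threshold: float = 1.0,
                            min_epoch_s: float = 1.0) -> dict:
    """Motion-initiation-aligned mean dF/F and normalized velocity.

    Motion epochs are runs with velocity >= ``speed_threshold`` lasting at
    least ``min_epoch_s``; windows from ``pre_s`` before to ``post_s``
    after initiation are extracted (edge-truncated windows dropped) and
    velocity is max-normalized per epoch.
    """
    v = np.asarray(velocity, dtype=float)
    x = np.asarray(trace, dtype=float)
    moving = v >= speed_threshold
    edges = np.diff(moving.astype(int))
    onsets = np.flatnonzero(edges == 1) + 1
    offsets = np.flatnonzero(edges == -1) + 1
    if moving[0]:
        onsets = np.r_[0, onsets]
    if moving[-1]:
        offsets = np.r_[offsets, v.size]
    min_len = int(round(min_epoch_s * frame_rate))
    pre_f = int(round(pre_s * frame_rate))
    post_f = int(round(post_s * frame_rate))

    dff_windows, vel_windows = [], []
    for a, b in zip(onsets, offsets):
        if b - a < min_len:
            continue
        lo, hi = a - pre_f, a + post_f
        if lo < 0 or hi > v.size:
            continue
        dff_windows.append(x[lo:hi])
        vel = v[lo:hi]
        vmax = vel.max()
        vel_windows.append(vel / vmax if vmax > 0 else vel)
    if not dff_windows:
        warnings.warn("no motion epochs found")
        return {"n_epochs": 0, "dff": np.empty((0, pre_f + post_f)),
                "velocity": np.empty((0, pre_f + post_f)),
                "mean_dff": None, "mean_velocity": None,
                "time_s": (np.arange(pre_f + post_f) - pre_f) / frame_rate}
    dff = np.stack(dff_windows)
    vel = np.stack(vel_windows)
    return {"n_epochs": dff.shape[0], "dff": dff, "velocity": vel,
            "mean_dff": dff.mean(axis=0), "mean_velocity": vel.mean(axis=0),
            "time_s": (np.arange(pre_f + post_f) - pre_f) / frame_rate}
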