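"""Place-field detection, characterization and fate tracking.

Activity of each cell is binned into a laps x 40 rate map of mean dF/F per
5 cm bin over running frames.  Candidate fields are contiguous runs of the
mean tuning curve above its baseline; a candidate becomes a place field
only if it passes six criteria: width above 10 cm, in-field mean dF/F above
0.10, in-field mean more than 4x the out-of-field mean, in-field calcium
transients on more than 30% of laps, a rising phase located on the track,
and a circular-shuffle bootstrap p-value below 0.05.

Field parameters follow the standard definitions: center of mass
``COM = sum(F_i x_i) / sum(F_i)`` with x_i the bin centers, the
trial-to-trial reliability index (mean lap-by-lap correlation of in-field
activity times the fraction of laps with an in-field transient),
out-of-field over in-field firing ratio, width, and firing intensity (peak
of the mean curve).  Field fate across conditions (stable / remapped /
disappeared / new) is classified by bin-interval overlap, reward-end
over-representation is quantified from the distribution of field centers,
and reward cells are identified by peri-reward firing in two distinct
environments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .session import SessionRecord, BinningSpec
from .behavior import Lap

QUARTERS = ((0.0, 50.0), (50.0, 100.0), (100.0, 150.0), (150.0, 200.0))


@dataclass
class FieldConfig:
    """Detection thresholds (defaults are the standard six criteria)."""

    min_width_cm: float = 10.0        # criterion 1 (exclusive)
    min_mean_dff: float = 0.10        # criterion 2
    in_out_ratio: float = 4.0         # criterion 3 (exclusive)
    min_lap_fraction: float = 0.30    # criterion 4 (exclusive)
    p_threshold: float = 0.05         # criterion 6
    n_shuffles: int = 1000
    baseline_percentile: float = 25.0
    candidate_rel_floor: float = 0.05
    # transient detection
    transient_sigma_mult: float = 2.0
    transient_min_duration_s: float = 0.33
    transient_min_peak: float = 0.10


@dataclass
class BinnedRateMap:
    """Laps x 40 matrix of mean dF/F per spatial bin (run-filtered)."""

    cell: int
    condition: str
    matrix: np.ndarray
    laps: list
    empty_bins: np.ndarray          # bins with no running frames in some lap

    @property
    def mean_curve(self) -> np.ndarray:
        return self.matrix.mean(axis=0)


@dataclass
class PlaceField:
    cell: int
    condition: str
    start_bin: int
    end_bin: int                    # inclusive
    clipped: bool
    com: float                      # cm
    width: float                    # cm
    reliability: float
    out_in_ratio: float
    intensity: float
    p_boot: float
    lap_hit_fraction: float

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start_bin, self.end_bin)


@dataclass
class Rejection:
    cell: int
    condition: str
    start_bin: int
    end_bin: int
    criterion: int                  # first failed criterion, 1..6
    detail: str


# --------------------------------------------------------------------------
# binning and transients


def baseline_dff(trace: np.ndarray, window: int = 500,
                 percentile: float = 8.0) -> np.ndarray:
    """Somatic dF/F from raw fluorescence via a rolling-percentile baseline:
    ``(F - F0) / F0`` with F0 the centered rolling 8th percentile."""
    import pandas as pd

    f = np.asarray(trace, dtype=float)
    f0 = (pd.Series(f).rolling(window, center=True, min_periods=1)
          .quantile(percentile / 100.0).to_numpy())
    if np.any(f0 <= 0):
        raise ValueError("nonpositive baseline; raw fluorescence must be positive")
    return (f - f0) / f0


def bin_activity(session: SessionRecord, laps: list[Lap], cell: int,
                 spec: BinningSpec | None = None,
                 baseline_percentile: float = 25.0,
                 activity_mask: np.ndarray | None = None) -> BinnedRateMap:
    """Laps x 40 rate map of one cell over the given laps.

    Bin value = mean dF/F over running frames of that lap in that bin;
    bins without running frames are zero and flagged.  When
    ``activity_mask`` is given (the significant-transient mask), activity
    outside it is zeroed before binning, so out-of-field bins reflect real
    transients rather than measurement noise.  The per-cell baseline
    (percentile of all bin means) is subtracted and negatives are clipped
    to zero, so the matrix is nonnegative.
    """
    spec = spec or BinningSpec()
    if not laps:
        raise ValueError("no laps passed the filter")
    trace = session.dff[cell]
    if activity_mask is not None:
        trace = np.where(activity_mask, trace, 0.0)
    run = session.run_mask
    L = len(laps)
    matrix = np.zeros((L, spec.n_bins))
    empty = np.zeros(spec.n_bins, dtype=bool)
    for i, lap in enumerate(laps):
        sl = slice(lap.start_frame, lap.end_frame)
        sel = run[sl]
        bins = spec.bin_of(session.position[sl][sel])
        sums = np.bincount(bins, weights=trace[sl][sel], minlength=spec.n_bins)
        counts = np.bincount(bins, minlength=spec.n_bins)
        empty |= counts == 0
        matrix[i] = np.divide(sums, counts, out=np.zeros(spec.n_bins),
                              where=counts > 0)
    baseline = np.percentile(matrix.mean(axis=0), baseline_percentile)
    matrix = np.clip(matrix - baseline, 0.0, None)
    return BinnedRateMap(cell, laps[0].condition if laps else "", matrix,
                         laps, empty)


def detect_transients(trace: np.ndarray, frame_rate: float = 30.0,
                      sigma_mult: float = 2.0, min_duration_s: float = 0.33,
                      min_peak: float = 0.10) -> list[tuple[int, int]]:
    """Significant calcium transients in a dF/F trace.

    Noise is estimated from below-median residuals; a transient is a
    maximal run above ``median + sigma_mult * sigma`` lasting at least
    ``min_duration_s`` with peak dF/F of at least ``min_peak``.  Returns
    half-open (onset, offset) frame intervals.
    """
    x = np.asarray(trace, dtype=float)
    med = np.median(x)
    below = x[x < med] - med
    sigma = float(np.sqrt(np.mean(below ** 2))) if below.size else 0.0
    thresh = med + sigma_mult * sigma
    above = x > thresh
    if not above.any():
        return []
    edges = np.diff(above.astype(int))
    onsets = np.flatnonzero(edges == 1) + 1
    offsets = np.flatnonzero(edges == -1) + 1
    if above[0]:
        onsets = np.r_[0, onsets]
    if above[-1]:
        offsets = np.r_[offsets, x.size]
    min_len = max(1, int(round(min_duration_s * frame_rate)))
    out = []
    for a, b in zip(onsets, offsets):
        if b - a >= min_len and x[a:b].max() >= min_peak:
            out.append((int(a), int(b)))
    return out


def transient_mask(trace: np.ndarray, frame_rate: float = 30.0,
                   **kwargs) -> np.ndarray:
    """Boolean per-frame mask of significant-transient membership."""
    mask = np.zeros(np.asarray(trace).shape[0], dtype=bool)
    for a, b in detect_transients(trace, frame_rate, **kwargs):
        mask[a:b] = True
    return mask


# --------------------------------------------------------------------------
# candidates and criteria


def candidate_fields(mean_curve: np.ndarray,
                     baseline_percentile: float = 25.0,
                     already_subtracted: bool = True,
                     rel_floor: float = 0.05) -> list[tuple[int, int, bool]]:
    """Candidate field intervals from a 40-bin mean tuning curve.

    After subtracting the baseline (the given percentile of bin means),
    candidates are the maximal runs of bins above the noise floor
    (``rel_floor`` times the curve peak; 0 means strictly positive), each
    containing its run's local peak; a run touching the final bin is
    marked clipped at the track end.  The floor keeps residual bin noise —
    which is positive in half the bins by chance — from fusing separate
    fields into one track-wide run.  Returns
    ``(start_bin, end_bin_inclusive, clipped)`` triples.
    """
    curve = np.asarray(mean_curve, dtype=float)
    if not already_subtracted:
        curve = curve - np.percentile(curve, baseline_percentile)
    floor = rel_floor * curve.max() if curve.max() > 0 else 0.0
    positive = curve > floor
    if not positive.any():
        return []
    edges = np.diff(positive.astype(int))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1)
    if positive[0]:
        starts = np.r_[0, starts]
    if positive[-1]:
        ends = np.r_[ends, curve.size - 1]
    return [(int(a), int(b), bool(b == curve.size - 1))
            for a, b in zip(starts, ends)]


def lap_hit_fraction(session: SessionRecord, laps: list[Lap],
                     interval: tuple[int, int], tmask: np.ndarray,
                     spec: BinningSpec) -> float:
    """Fraction of laps with a significant transient inside the field."""
    s, e = interval
    hits = 0
    for lap in laps:
        sl = slice(lap.start_frame, lap.end_frame)
        bins = spec.bin_of(session.position[sl])
        infield = (bins >= s) & (bins <= e) & session.run_mask[sl]
        if np.any(tmask[sl] & infield):
            hits += 1
    return hits / len(laps)


def bootstrap_pvalue(matrix: np.ndarray, interval: tuple[int, int],
                     n_shuffles: int = 1000,
                     rng: np.random.Generator | None = None) -> float:
    """Circular-shuffle bootstrap p-value of a candidate interval.

    Each shuffle rotates every lap's 40-bin row by an independent uniform
    offset; the statistic is the in/out mean ratio of the interval; the
    p-value uses the add-one estimator ``(1 + #{shuffle >= observed}) /
    (1 + n_shuffles)``.
    """
    rng = rng or np.random.default_rng(0)
    L, n_bins = matrix.shape
    s, e = interval
    inmask = np.zeros(n_bins, dtype=bool)
    inmask[s:e + 1] = True
    eps = 1e-9

    def statistic(m3):
        in_mean = m3[..., inmask].mean(axis=-1)
        out_mean = m3[..., ~inmask].mean(axis=-1) if (~inmask).any() else 0.0
        return in_mean / np.maximum(out_mean, eps)

    observed = float(statistic(matrix[None]).mean())
    offsets = rng.integers(0, n_bins, size=(n_shuffles, L))
    cols = (np.arange(n_bins)[None, None, :] - offsets[:, :, None]) % n_bins
    shuffled = matrix[np.arange(L)[None, :, None], cols]
    shuffle_stats = statistic(shuffled).mean(axis=-1)
    return float((1 + np.sum(shuffle_stats >= observed)) / (1 + n_shuffles))


def field_com(matrix: np.ndarray, interval: tuple[int, int],
              spec: BinningSpec | None = None):
    """Center of mass of a field: per-lap ``sum(F_i x_i)/sum(F_i)`` over the
    field bins (x_i = bin centers), averaged over laps with nonzero
    in-field activity.  Returns ``(field_com, per_lap_coms)``; nan when the
    field is silent on every lap."""
    spec = spec or BinningSpec()
    s, e = interval
    sub = matrix[:, s:e + 1]
    x = spec.centers[s:e + 1]
    sums = sub.sum(axis=1)
    per_lap = np.full(matrix.shape[0], np.nan)
    active = sums > 0
    per_lap[active] = (sub[active] * x).sum(axis=1) / sums[active]
    if not active.any():
        return float("nan"), per_lap
    return float(per_lap[active].mean()), per_lap


def field_reliability(matrix: np.ndarray, interval: tuple[int, int],
                      hit_fraction: float) -> float:
    """Trial-to-trial reliability index.

    Out-of-field bins are zeroed, the L x L lap-by-lap Pearson matrix is
    computed over laps with in-field variance, and the mean off-diagonal
    correlation is multiplied by the fraction of laps with an in-field
    transient.  1.0 = fires identically every lap; 0.5 = same place but
    only half the laps.
    """
    s, e = interval
    zeroed = np.zeros_like(matrix)
    zeroed[:, s:e + 1] = matrix[:, s:e + 1]
    keep = zeroed.std(axis=1) > 0
    sub = zeroed[keep]
    if sub.shape[0] < 2:
        return 0.0
    corr = np.corrcoef(sub)
    off = corr[~np.eye(sub.shape[0], dtype=bool)]
    return float(np.clip(off.mean(), 0.0, 1.0) * hit_fraction)


def field_params(matrix: np.ndarray, interval: tuple[int, int],
                 clipped: bool, spec: BinningSpec | None = None):
    """Out/in firing ratio, width (cm) and intensity of a field.

    Clipped fields use the track end as the field end.  The out/in ratio is
    mean dF/F outside the field over mean inside (lower = cleaner field);
    intensity is the peak of the mean curve within the field.
    """
    spec = spec or BinningSpec()
    s, e = interval
    mean_curve = matrix.mean(axis=0)
    inmask = np.zeros(spec.n_bins, dtype=bool)
    inmask[s:e + 1] = True
    in_mean = mean_curve[inmask].mean()
    out_mean = mean_curve[~inmask].mean() if (~inmask).any() else 0.0
    out_in = float(out_mean / in_mean) if in_mean > 0 else float("nan")
    width = (e - s + 1) * spec.bin_width
    intensity = float(mean_curve[inmask].max())
    return out_in, width, intensity


def apply_field_criteria(candidate: tuple[int, int, bool],
                         rate_map: BinnedRateMap, session: SessionRecord,
                         tmask: np.ndarray, config: FieldConfig,
                         rng: np.random.Generator,
                         spec: BinningSpec | None = None):
    """Evaluate the six criteria in order on one candidate.

    Returns a :class:`PlaceField` or a :class:`Rejection` carrying the
    first failed criterion.
    """
    spec = spec or BinningSpec()
    s, e, clipped = candidate
    cell, cond = rate_map.cell, rate_map.condition
    matrix = rate_map.matrix
    mean_curve = rate_map.mean_curve

    width = (e - s + 1) * spec.bin_width
    if width <= config.min_width_cm and not clipped:
        return Rejection(cell, cond, s, e, 1,
                         f"width {width:g} cm not > {config.min_width_cm:g}")

    in_mean = float(mean_curve[s:e + 1].mean())
    if in_mean <= config.min_mean_dff:
        return Rejection(cell, cond, s, e, 2,
                         f"in-field mean {in_mean:.3f} not > "
                         f"{config.min_mean_dff:g} above baseline")

    outmask = np.ones(spec.n_bins, dtype=bool)
    outmask[s:e + 1] = False
    out_mean = float(mean_curve[outmask].mean()) if outmask.any() else 0.0
    if out_mean > 0 and in_mean <= config.in_out_ratio * out_mean:
        return Rejection(cell, cond, s, e, 3,
                         f"in/out ratio {in_mean / out_mean:.2f} not > "
                         f"{config.in_out_ratio:g}")

    hit_frac = lap_hit_fraction(session, rate_map.laps, (s, e), tmask, spec)
    if hit_frac <= config.min_lap_fraction:
        return Rejection(cell, cond, s, e, 4,
                         f"in-field transients on {hit_frac:.0%} of laps, "
                         f"need > {config.min_lap_fraction:.0%}")

    if not _rising_phase_on_track(candidate, rate_map, session, tmask, spec):
        return Rejection(cell, cond, s, e, 5,
                         "rising phase at/after reward delivery")

    p = bootstrap_pvalue(matrix, (s, e), config.n_shuffles, rng)
    if p >= config.p_threshold:
        return Rejection(cell, cond, s, e, 6,
                         f"bootstrap p {p:.3f} not < {config.p_threshold:g}")

    com, _ = field_com(matrix, (s, e), spec)
    out_in, width, intensity = field_params(matrix, (s, e), clipped, spec)
    reliability = field_reliability(matrix, (s, e), hit_frac)
    return PlaceField(cell, cond, s, e, clipped, com, width, reliability,
                      out_in, intensity, p, hit_frac)


def _rising_phase_on_track(candidate, rate_map: BinnedRateMap,
                           session: SessionRecord, tmask: np.ndarray,
                           spec: BinningSpec) -> bool:
    """Criterion 5: the field must begin firing on the track, not at or
    after reward delivery / during the teleportation pause.

    A field confined to the final bin fails; otherwise in-field transient
    onsets must predominantly occur during running, not during the
    post-traversal pause.
    """
    s, e, clipped = candidate
    if s == spec.n_bins - 1:
        return False
    onsets_run, onsets_pause = 0, 0
    run = session.run_mask
    for lap in rate_map.laps:
        sl = slice(lap.start_frame, lap.end_frame)
        bins = spec.bin_of(session.position[sl])
        infield = (bins >= s) & (bins <= e)
        lap_mask = tmask[sl] & infield
        if not lap_mask.any():
            continue
        onset = np.flatnonzero(lap_mask)[0]
        if run[lap.start_frame + onset]:
            onsets_run += 1
        else:
            onsets_pause += 1
    if onsets_run + onsets_pause == 0:
        return True
    return onsets_run >= onsets_pause


def detect_place_fields(session: SessionRecord, laps: list[Lap],
                        cells=None, config: FieldConfig | None = None,
                        rng: np.random.Generator | None = None,
                        spec: BinningSpec | None = None,
                        return_rejections: bool = False):
    """Run the full detector on a set of laps (one condition).

    Returns ``{cell: [PlaceField, ...]}`` (cells without fields map to an
    empty list), plus the rejection list when requested.
    """
    config = config or FieldConfig()
    rng = rng or np.random.default_rng(0)
    spec = spec or BinningSpec()
    cells = range(session.n_cells) if cells is None else cells

    fields: dict[int, list[PlaceField]] = {}
    rejections: list[Rejection] = []
    for cell in cells:
        tmask = transient_mask(
            session.dff[cell], session.frame_rate,
            sigma_mult=config.transient_sigma_mult,
            min_duration_s=config.transient_min_duration_s,
            min_peak=config.transient_min_peak)
        rate_map = bin_activity(session, laps, cell, spec,
                                config.baseline_percentile,
                                activity_mask=tmask)
        fields[cell] = []
        for cand in candidate_fields(rate_map.mean_curve,
                                     rel_floor=config.candidate_rel_floor):
            result = apply_field_criteria(cand, rate_map, session, tmask,
                                          config, rng, spec)
            if isinstance(result, PlaceField):
                fields[cell].append(result)
            else:
                rejections.append(result)
    if return_rejections:
        return fields, rejections
    return fields


# --------------------------------------------------------------------------
# spatial correlation


def spatial_correlation(curve_a: np.ndarray, curve_b: np.ndarray) -> float:
    """Pearson correlation between two 40-bin mean activity curves; nan
    when either curve has zero variance."""
    a = np.asarray(curve_a, dtype=float)
    b = np.asarray(curve_b, dtype=float)
    if a.std() == 0 or b.std() == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def spatial_correlation_by_cell(session: SessionRecord, r_laps: list[Lap],
                                other_laps: list[Lap], cells,
                                spec: BinningSpec | None = None) -> dict:
    """Per-cell correlation of the R mean curve with another condition's
    mean curve (out-of-field activity retained), for cells with R fields."""
    spec = spec or BinningSpec()
    out = {}
    for cell in cells:
        a = bin_activity(session, r_laps, cell, spec).mean_curve
        b = bin_activity(session, other_laps, cell, spec).mean_curve
        out[cell] = spatial_correlation(a, b)
    return out


def within_condition_correlation(session: SessionRecord, laps: list[Lap],
                                 cells, spec: BinningSpec | None = None) -> dict:
    """Half-split control: correlation between the mean curves of the two
    halves of the lap set."""
    spec = spec or BinningSpec()
    half = len(laps) // 2
    first, second = laps[:half], laps[half:]
    out = {}
    for cell in cells:
        a = bin_activity(session, first, cell, spec).mean_curve
        b = bin_activity(session, second, cell, spec).mean_curve
        out[cell] = spatial_correlation(a, b)
    return out


# --------------------------------------------------------------------------
# fate classification


def _overlaps(f1: PlaceField, f2: PlaceField) -> bool:
    return f1.start_bin <= f2.end_bin and f2.start_bin <= f1.end_bin


def _fate_of(field_: PlaceField, later: list[PlaceField]) -> str:
    if not later:
        return "disappeared"
    if any(_overlaps(field_, g) for g in later):
        return "stable"
    return "remapped"


def round1(x: float) -> float:
    """Percentage to one decimal, round-half-away-from-zero."""
    return math.floor(abs(x) * 10 + 0.5) / 10 * (1 if x >= 0 else -1)


def classify_fate(fields_by_condition: dict, track_length: float = 200.0) -> dict:
    """Track the fate of every field across R -> RE_low -> RR.

    ``fields_by_condition`` maps a condition key (``"R"``, ``"RE_LOW"``,
    ``"RR"``) to the detector output ``{cell: [PlaceField, ...]}``.  An R
    field is STABLE in a later condition when the cell has a field there
    overlapping its bin interval by at least one bin, REMAPPED when the
    cell has only non-overlapping fields, DISAPPEARED when the cell has no
    field; later-condition fields with no overlapping earlier field are
    NEW.  Returns per-field fate records and the summary count ledger.
    """
    r_fields = fields_by_condition.get("R", {})
    relow = fields_by_condition.get("RE_LOW", {})
    rr = fields_by_condition.get("RR", {})

    records = []
    for cell, flds in r_fields.items():
        for f in flds:
            rec = {"cell": cell, "field": f, "com": f.com,
                   "fate_relow": _fate_of(f, relow.get(cell, [])) if relow
                   is not None else None}
            if rr:
                rec["fate_rr"] = _fate_of(f, rr.get(cell, []))
            records.append(rec)

    def all_fields(d):
        return [f for flds in d.values() for f in flds]

    def is_new(f, cell, earlier_maps):
        return not any(_overlaps(f, g)
                       for em in earlier_maps
                       for g in em.get(cell, []))

    new_relow = [(cell, f) for cell, flds in relow.items() for f in flds
                 if is_new(f, cell, [r_fields])]
    new_rr = [(cell, f) for cell, flds in rr.items() for f in flds
              if is_new(f, cell, [r_fields, relow])]

    counts = {
        "r_total": len([f for flds in r_fields.values() for f in flds]),
        "relow_total": len(all_fields(relow)),
        "rr_total": len(all_fields(rr)),
        "stable": sum(r["fate_relow"] == "stable" for r in records),
        "disappear": sum(r["fate_relow"] == "disappeared" for r in records),
        "remap": sum(r["fate_relow"] == "remapped" for r in records),
        "new_relow": len(new_relow),
        "new_rr": len(new_rr),
    }
    if rr:
        counts["rr_stable"] = sum(r.get("fate_rr") == "stable" for r in records)
        counts["rr_remap"] = sum(r.get("fate_rr") == "remapped" for r in records)
        counts["stable_throughout"] = sum(
            r["fate_relow"] == "stable" and r.get("fate_rr") == "stable"
            for r in records)
        counts["reappear_rr"] = sum(
            r["fate_relow"] == "disappeared" and r.get("fate_rr") == "stable"
            for r in records)
        # fate of fields newly formed in RE_low
        stable_new, gone_new = 0, 0
        for cell, f in new_relow:
            fate = _fate_of(f, rr.get(cell, []))
            stable_new += fate == "stable"
            gone_new += fate == "disappeared"
        counts["new_relow_stable_rr"] = stable_new
        counts["new_relow_gone_rr"] = gone_new

    # positional breakdown of disappearance and new-field formation
    quarter_edges = np.array([q[0] for q in QUARTERS] + [track_length])

    def quarter_counts(coms):
        return np.histogram(coms, bins=quarter_edges)[0].tolist()

    counts["disappear_by_quarter"] = quarter_counts(
        [r["com"] for r in records if r["fate_relow"] == "disappeared"])
    counts["new_relow_by_quarter"] = quarter_counts([f.com for _, f in new_relow])
    counts["new_rr_by_quarter"] = quarter_counts([f.com for _, f in new_rr])

    return {"records": records, "new_relow": new_relow, "new_rr": new_rr,
            "counts": counts, "summary": summarize_fates(counts)}


def summarize_fates(counts: dict) -> dict:
    """One-decimal percentage ledger from fate counts.

    Percentages of R fields that are stable / disappeared / remapped in
    RE_low and stable / remapped in RR; stable throughout; new fields as a
    share of each condition's total; reappearance of disappeared fields;
    survival of newly formed fields.
    """
    def pct(num, den):
        return round1(100.0 * num / den) if den else float("nan")

    r = counts.get("r_total", 0)
    out = {
        "stable_pct": pct(counts.get("stable", 0), r),
        "disappear_pct": pct(counts.get("disappear", 0), r),
        "remap_pct": pct(counts.get("remap", 0), r),
        "new_relow_pct": pct(counts.get("new_relow", 0),
                             counts.get("relow_total", 0)),
    }
    if "rr_stable" in counts:
        out.update({
            "stable_throughout_pct": pct(counts.get("stable_throughout", 0), r),
            "rr_stable_pct": pct(counts.get("rr_stable", 0), r),
            "rr_remap_pct": pct(counts.get("rr_remap", 0), r),
            "reappear_rr_pct": pct(counts.get("reappear_rr", 0),
                                   counts.get("disappear", 0)),
            "new_relow_stable_rr_pct": pct(counts.get("new_relow_stable_rr", 0),
                                           counts.get("new_relow", 0)),
            "new_relow_gone_rr_pct": pct(counts.get("new_relow_gone_rr", 0),
                                         counts.get("new_relow", 0)),
            "new_rr_pct": pct(counts.get("new_rr", 0),
                              counts.get("rr_total", 0)),
        })
    return out


# --------------------------------------------------------------------------
# reward over-representation


def field_density(coms, track_length: float = 200.0) -> dict:
    """Reward-end over-representation statistics from field centers.

    Fits a Gaussian (maximum likelihood) to the centers, compares the
    observed distribution with uniform (KS test), and reports the
    over-representation delta: the percentage of fields in the final 50 cm
    minus the mean percentage per 50 cm bin over the middle of the track
    (50-150 cm).  The uniform expectation per 50 cm bin is 25%.
    """
    coms = np.asarray(list(coms), dtype=float)
    n = coms.size
    if n < 20:
        raise ValueError(f"need at least 20 field centers, have {n}")
    mean, sd = float(coms.mean()), float(coms.std())
    ks = stats.kstest(coms, stats.uniform(0, track_length).cdf)

    end_pct = 100.0 * np.mean((coms >= 150.0) & (coms <= track_length))
    mid_bins = [(50.0, 100.0), (100.0, 150.0)]
    mid_pcts = [100.0 * np.mean((coms >= a) & (coms < b)) for a, b in mid_bins]
    delta = end_pct - float(np.mean(mid_pcts))
    quarter_edges = np.array([q[0] for q in QUARTERS] + [track_length])
    density_pct = 100.0 * np.histogram(coms, bins=quarter_edges)[0] / n
    return {
        "n": int(n),
        "gauss_mean_cm": mean,
        "gauss_sd_cm": sd,
        "ks_stat": float(ks.statistic),
        "ks_p": float(ks.pvalue),
        "end_pct": float(end_pct),
        "mid_mean_pct": float(np.mean(mid_pcts)),
        "overrep_delta": float(delta),
        "uniform_expectation_pct": 25.0,
        "density_by_quarter_pct": density_pct.tolist(),
    }


# --------------------------------------------------------------------------
# reward cells


def identify_reward_cells(session_r: SessionRecord, session_n: SessionRecord,
                          laps_r: list[Lap], laps_n: list[Lap],
                          zone_cm: float = 40.0, peri_s: float = 2.0,
                          min_lap_fraction: float = 0.30,
                          config: FieldConfig | None = None,
                          time_bins: int = 40) -> dict:
    """Reward cells: fire at the reward zone and around reward delivery in
    both a familiar and a novel rewarded environment.

    A cell qualifies when significant transients occur within the final
    ``zone_cm`` of the track and within ``peri_s`` seconds of reward
    delivery on more than ``min_lap_fraction`` of laps in BOTH sessions
    (cells are matched across sessions by row index).  Returns the cell
    set plus lap x time-bin peri-reward profiles and their time COM.
    """
    config = config or FieldConfig()
    if session_r.n_cells != session_n.n_cells:
        raise ValueError("sessions must share a matched cell set")

    def qualifies(session: SessionRecord, laps: list[Lap], cell: int):
        tmask = transient_mask(session.dff[cell], session.frame_rate,
                               sigma_mult=config.transient_sigma_mult,
                               min_duration_s=config.transient_min_duration_s,
                               min_peak=config.transient_min_peak)
        peri_frames = int(round(peri_s * session.frame_rate))
        zone_hits = peri_hits = n_laps = 0
        for lap in laps:
            sl = slice(lap.start_frame, lap.end_frame)
            rew = np.flatnonzero(session.reward[sl])
            n_laps += 1
            in_zone = session.position[sl] >= session.track_length - zone_cm
            if np.any(tmask[sl] & in_zone):
                zone_hits += 1
            if rew.size:
                r = lap.start_frame + rew[0]
                a = max(0, r - peri_frames)
                b = min(session.n_frames, r + peri_frames + 1)
                if tmask[a:b].any():
                    peri_hits += 1
        if n_laps == 0:
            return False
        return (zone_hits / n_laps > min_lap_fraction
                and peri_hits / n_laps > min_lap_fraction)

    cells = [c for c in range(session_r.n_cells)
             if qualifies(session_r, laps_r, c) and qualifies(session_n, laps_n, c)]

    def profile(session: SessionRecord, laps: list[Lap], cell: int):
        peri_frames = int(round(peri_s * session.frame_rate))
        rows = []
        for lap in laps:
            sl = slice(lap.start_frame, lap.end_frame)
            rew = np.flatnonzero(session.reward[sl])
            if not rew.size:
                continue
            r = lap.start_frame + rew[0]
            a, b = r - peri_frames, r + peri_frames + 1
            if a < 0 or b > session.n_frames:
                continue
            seg = session.dff[cell, a:b]
            edges = np.linspace(0, seg.size, time_bins + 1).astype(int)
            rows.append([seg[i:j].mean() for i, j in zip(edges[:-1], edges[1:])])
        return np.asarray(rows)

    profiles = {}
    for cell in cells:
        mat = profile(session_r, laps_r, cell)
        t_centers = np.linspace(-peri_s, peri_s, time_bins)
        mean_prof = mat.mean(axis=0) if mat.size else np.zeros(time_bins)
        shifted = mean_prof - mean_prof.min()
        com_t = (float((shifted * t_centers).sum() / shifted.sum())
                 if shifted.sum() > 0 else float("nan"))
        profiles[cell] = {"matrix": mat, "time_com_s": com_t}
    return {"cells": cells, "profiles": profiles,
            "fraction": len(cells) / max(session_r.n_cells, 1)}
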