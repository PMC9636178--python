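"""Naive-Bayes position decoding on the circular track.

A Gaussian naive-Bayes classifier predicts the animal's 5 cm position bin
from the population dF/F vector, trained on running frames only.  Because
the end of the track teleports back to the start, residuals are circular:
the decoding error between true position and predicted bin center is
wrapped to at most half the track.  Decoder quality per lap is summarized
by the coefficient of determination R^2, and the lap-wise R^2 series in UR
is fit with a reverse Boltzmann sigmoid to locate the lap on which spatial
coding abruptly degrades.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from sklearn.naive_bayes import GaussianNB

from .session import SessionRecord, BinningSpec
from .behavior import Lap, LapTable, rolling_average


class CircularPositionDecoder:
    """Gaussian naive-Bayes position decoder (sklearn-style estimator).

    Parameters
    ----------
    spec : BinningSpec
        Spatial discretization (40 x 5 cm bins by default).
    var_floor : float
        Variance floor applied per cell per bin, guarding against
        zero-variance features in noiseless data.
    circular : bool
        Score with circular residuals (default) or raw linear residuals.
    """

    def __init__(self, spec: BinningSpec | None = None, var_floor: float = 1e-6,
                 circular: bool = True):
        self.spec = spec or BinningSpec()
        self.var_floor = var_floor
        self.circular = circular

    def get_params(self, deep: bool = True) -> dict:
        return {"spec": self.spec, "var_floor": self.var_floor,
                "circular": self.circular}

    def set_params(self, **params) -> "CircularPositionDecoder":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, X: np.ndarray, position: np.ndarray) -> "CircularPositionDecoder":
        """Fit on frames x cells activity and per-frame positions (cm).

        Caller is responsible for restricting to running frames.
        """
        X = np.asarray(X, dtype=float)
        if X.shape[0] == 0:
            raise ValueError("no frames to train on (is the run mask empty?)")
        y = self.spec.bin_of(position)
        present = np.unique(y)
        missing = sorted(set(range(self.spec.n_bins)) - set(present.tolist()))
        if missing:
            warnings.warn(f"position bins absent from training data: {missing}")
        self.missing_bins_ = missing
        self.nb_ = GaussianNB(priors=np.full(present.size, 1.0 / present.size),
                              var_smoothing=0.0)
        self.nb_.fit(X, y)
        self.nb_.var_ = np.maximum(self.nb_.var_, self.var_floor)
        self.classes_ = self.nb_.classes_
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Posterior-argmax bin per frame; ties break toward lower bins."""
        jll = self.nb_._joint_log_likelihood(np.asarray(X, dtype=float))
        return self.classes_[np.argmax(jll, axis=1)]

    def score(self, X: np.ndarray, position: np.ndarray) -> float:
        """R^2 between true position and predicted bin center."""
        return decoder_r2(position, self.predict(X), self.spec, self.circular)


def circular_residual(true_cm: np.ndarray, pred_cm: np.ndarray,
                      track_length: float) -> np.ndarray:
    """Signed position error wrapped to (-track_length/2, track_length/2]."""
    d = np.asarray(true_cm, dtype=float) - np.asarray(pred_cm, dtype=float)
    return (d + track_length / 2) % track_length - track_length / 2


def decoder_r2(position: np.ndarray, pred_bins: np.ndarray,
               spec: BinningSpec, circular: bool = True) -> float:
    """Coefficient of determination of the decoded position.

    Residuals are circular by default (teleportation is not an error of
    half a track); the total sum of squares is about the arithmetic mean of
    the true positions.
    """
    pred_cm = spec.centers[np.asarray(pred_bins, dtype=int)]
    pos = np.asarray(position, dtype=float)
    if circular:
        resid = circular_residual(pos, pred_cm, spec.track_length)
    else:
        resid = pos - pred_cm
    ss_tot = np.sum((pos - pos.mean()) ** 2)
    if ss_tot == 0:
        return float("nan")
    return float(1.0 - np.sum(resid ** 2) / ss_tot)


@dataclass
class DecoderResult:
    """Decoding evaluation over a set of test laps."""

    predicted_bins: dict            # lap key -> per-frame predicted bin
    lap_r2: dict                    # lap key -> R^2
    error_by_position: np.ndarray   # 40-bin mean |circular error| in cm
    train_laps: list = field(default_factory=list)
    test_laps: list = field(default_factory=list)


def _lap_key(lap: Lap):
    return (lap.condition, lap.lap_index)


def _lap_frames(session: SessionRecord, lap: Lap) -> np.ndarray:
    idx = np.arange(lap.start_frame, lap.end_frame)
    return idx[session.run_mask[idx]]


def train_decoder(session: SessionRecord, train_laps: list[Lap],
                  spec: BinningSpec | None = None) -> CircularPositionDecoder:
    """Train the decoder on the running frames of the given laps."""
    spec = spec or BinningSpec()
    frames = np.concatenate([_lap_frames(session, lap) for lap in train_laps]) \
        if train_laps else np.array([], dtype=int)
    if frames.size == 0:
        raise ValueError("no running frames available for training")
    decoder = CircularPositionDecoder(spec)
    decoder.fit(session.dff[:, frames].T, session.position[frames])
    return decoder


def decode_and_score(decoder: CircularPositionDecoder, session: SessionRecord,
                     test_laps: list[Lap], train_laps: list[Lap] | None = None
                     ) -> DecoderResult:
    """Decode the running frames of each test lap and score lap-wise R^2
    plus the 40-bin profile of mean absolute (circular) error."""
    spec = decoder.spec
    predicted, lap_r2 = {}, {}
    err_sum = np.zeros(spec.n_bins)
    err_count = np.zeros(spec.n_bins)
    for lap in test_laps:
        frames = _lap_frames(session, lap)
        if frames.size == 0:
            continue
        pred = decoder.predict(session.dff[:, frames].T)
        pos = session.position[frames]
        predicted[_lap_key(lap)] = pred
        lap_r2[_lap_key(lap)] = decoder_r2(pos, pred, spec, decoder.circular)
        abs_err = np.abs(circular_residual(pos, spec.centers[pred],
                                           spec.track_length))
        true_bins = spec.bin_of(pos)
        err_sum += np.bincount(true_bins, weights=abs_err, minlength=spec.n_bins)
        err_count += np.bincount(true_bins, minlength=spec.n_bins)
    error_by_position = np.divide(err_sum, err_count,
                                  out=np.full(spec.n_bins, np.nan),
                                  where=err_count > 0)
    return DecoderResult(predicted, lap_r2, error_by_position,
                         train_laps=[_lap_key(l) for l in (train_laps or [])],
                         test_laps=[_lap_key(l) for l in test_laps])


def train_test_decode(session: SessionRecord, lap_table: LapTable,
                      train_frac: float = 0.6,
                      spec: BinningSpec | None = None) -> DecoderResult:
    """Protocol of the cross-condition evaluation: train on the first
    ``train_frac`` of rewarded laps, test on the remaining R laps and on
    every UR / RR lap."""
    r_laps = lap_table.select(condition="R")
    n_train = max(1, int(round(train_frac * len(r_laps))))
    train_laps = r_laps[:n_train]
    test_laps = r_laps[n_train:] + lap_table.select(condition="UR") \
        + lap_table.select(condition="RR")
    decoder = train_decoder(session, train_laps, spec)
    return decode_and_score(decoder, session, test_laps, train_laps)


def crossval_within_condition(session: SessionRecord, lap_table: LapTable,
                              conditions: list[str] | None = None,
                              test_frac: float = 0.2,
                              rng: np.random.Generator | None = None,
                              spec: BinningSpec | None = None) -> dict:
    """Sliding cross-validation within each condition.

    Down-samples every condition to the smallest condition lap count
    (random subset without replacement), then slides a test window of
    ``test_frac`` of the laps by one lap per fold, training on the rest;
    per-lap R^2 is averaged over the folds testing that lap.
    Returns ``{condition: {lap_index: mean R^2}}``.
    """
    rng = rng or np.random.default_rng(0)
    spec = spec or BinningSpec()
    conditions = conditions or sorted({l.condition for l in lap_table
                                       if not l.partial})
    by_cond = {c: lap_table.select(condition=c) for c in conditions}
    n_min = min(len(v) for v in by_cond.values())
    if n_min < 5:
        raise ValueError(f"need at least 5 laps per condition, have {n_min}")

    results: dict = {}
    for cond, laps in by_cond.items():
        if len(laps) > n_min:
            keep = np.sort(rng.choice(len(laps), size=n_min, replace=False))
            laps = [laps[i] for i in keep]
        n_test = max(1, int(round(test_frac * n_min)))
        sums: dict[int, float] = {}
        counts: dict[int, int] = {}
        for start in range(n_min):
            test_idx = [(start + j) % n_min for j in range(n_test)]
            test = [laps[j] for j in test_idx]
            train = [laps[j] for j in range(n_min) if j not in test_idx]
            decoder = train_decoder(session, train, spec)
            res = decode_and_score(decoder, session, test)
            for lap in test:
                r2 = res.lap_r2.get(_lap_key(lap))
                if r2 is None:
                    continue
                sums[lap.lap_index] = sums.get(lap.lap_index, 0.0) + r2
                counts[lap.lap_index] = counts.get(lap.lap_index, 0) + 1
        results[cond] = {k: sums[k] / counts[k] for k in sorted(sums)}
    return results


# --------------------------------------------------------------------------
# reverse Boltzmann sigmoid fit of lap-wise R^2


@dataclass
class SigmoidFit:
    """Reverse Boltzmann sigmoid fit of a lap-wise series.

    ``f(x) = A2 + (A1 - A2) / (1 + exp((x - x0) / dx))`` with early plateau
    A1, late plateau A2, midpoint x0 (laps) and slope scale dx (laps).
    """

    a1: float
    a2: float
    x0: float
    dx: float
    r2: float
    inflection_lap: int | None
    degenerate: bool = False


def reverse_boltzmann(x, a1, a2, x0, dx):
    z = np.clip((np.asarray(x, dtype=float) - x0) / dx, -700, 700)
    return a2 + (a1 - a2) / (1.0 + np.exp(z))


def fit_inflection(lapwise_r2, laps=None, smooth_window: int = 3,
                   presmoothed: bool = False) -> SigmoidFit:
    """Fit the (rolling-averaged) lap-wise R^2 to a reverse Boltzmann
    sigmoid and locate the inflection lap.

    The inflection lap is the first point, on a 0.01-lap grid, where the
    discrete second derivative of the fit changes sign, rounded to the
    nearest integer lap.  A fit whose plateaus are indistinguishable is
    flagged degenerate with no inflection.
    """
    y = np.asarray(lapwise_r2, dtype=float)
    if y.size < 6:
        raise ValueError(f"need at least 6 laps to fit, have {y.size}")
    x = np.asarray(laps, dtype=float) if laps is not None \
        else np.arange(1, y.size + 1, dtype=float)
    if not presmoothed:
        y = rolling_average(y, smooth_window)

    a1_0, a2_0 = float(y.max()), float(y.min())
    x0_0 = float(x[np.argmin(np.diff(y))] if y.size > 1 else x[y.size // 2])
    p0 = [a1_0, a2_0, x0_0, 1.0]
    span = x.max() - x.min()
    bounds = ([a2_0 - 1.0, a2_0 - 1.0, x.min() - span, 1e-3],
              [a1_0 + 1.0, a1_0 + 1.0, x.max() + span, span])
    try:
        popt, _ = curve_fit(reverse_boltzmann, x, y, p0=p0, bounds=bounds,
                            maxfev=20000)
    except RuntimeError as exc:
        raise RuntimeError(
            f"sigmoid fit failed to converge (initial values {p0}): {exc}"
        ) from exc
    a1, a2, x0, dx = (float(v) for v in popt)
    yhat = reverse_boltzmann(x, *popt)
    ss_tot = np.sum((y - y.mean()) ** 2)
    fit_r2 = float(1.0 - np.sum((y - yhat) ** 2) / ss_tot) if ss_tot > 0 else np.nan

    degenerate = abs(a1 - a2) < 1e-3 * max(abs(a1), abs(a2), 1.0)
    inflection = None
    if not degenerate:
        grid = np.arange(x.min(), x.max() + 0.01, 0.01)
        f = reverse_boltzmann(grid, *popt)
        d2 = np.diff(f, 2)
        sign_change = np.flatnonzero(np.sign(d2[:-1]) != np.sign(d2[1:]))
        if sign_change.size:
            inflection = int(round(grid[sign_change[0] + 1]))
        inflection = inflection if inflection is not None else int(round(x0))
        inflection = int(np.clip(inflection, x.min(), x.max()))
    return SigmoidFit(a1, a2, x0, dx, fit_r2, inflection, degenerate)
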