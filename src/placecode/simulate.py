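"""Synthetic session generator with known ground truth.

Emulates the statistical structure of head-fixed VR sessions on a 2 m
linear track sampled at 30 Hz: rewarded (R), unrewarded (UR) and
re-rewarded (RR) lap blocks; anticipatory licking that extinguishes a few
laps after reward removal; engaged laps that decelerate on approach to the
track end versus disengaged laps with a flat velocity profile; place cells
with Gaussian spatial tuning, lap-wise Bernoulli reliability, calcium
transient kinetics, out-of-field nuisance events and an over-representation
of the reward end; condition-dependent field fate (stable / remap /
disappear / new), with the map switch tied to the lap licking stops rather
than to reward removal itself; a dopaminergic-axon signal ramping with
proximity to reward whose amplitude depends on reward expectation; and an
optional pupil channel whose within-lap dynamics flatten on disengaged laps.

Every sampled latent is recorded in a JSON-serializable ground-truth
dictionary so each downstream analysis stage can be tested by parameter
recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace

import numpy as np
from scipy.signal import fftconvolve

from .session import SessionRecord, BinningSpec


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class SimConfig:
    """Study conditions for one synthetic session.

    Defaults encode the observed scale of the emulated experiment: lap
    counts 34/28/27 for R/UR/RR, matched-lap median duration 7.3 s,
    approach ratio 1.3 on engaged laps, anticipatory licking ceasing around
    UR lap 5, 30% of low-expectation laps disengaged, field fate fractions
    0.367/0.412/0.221 (stable/disappear/remap), reward-end center-of-mass
    over-representation as a Gaussian at 114 +/- 55 cm, and axon ramp
    amplitudes 1.0/0.57/0.24/1.0 for R / RE_high / RE_low / RR.
    """

    n_cells: int = 200
    place_cell_fraction: float = 0.45
    laps: dict = field(default_factory=lambda: {"R": 34, "UR": 28, "RR": 27})
    frame_rate: float = 30.0
    track_length: float = 200.0

    # behavior
    lap_duration_median_s: float = 7.3
    lap_duration_sigma: float = 0.12      # lognormal shape
    disengaged_duration_factor: float = 1.6
    approach_ratio: float = 1.3
    approach_ratio_sd: float = 0.04
    disengaged_fraction: float = 0.30
    pause_s: float = 1.5
    lick_zone_start_cm: float = 180.0
    lick_rate_hz: float = 8.0
    lick_stop_lap_mean: float = 5.0
    lick_stop_lap_sd: float = 1.0
    random_relick: bool = False
    relick_lap_prob: float = 0.15

    # place cells
    field_sigma_cm: float = 10.0
    reliability_p: float = 0.8
    amplitude_mean: float = 0.6
    amplitude_sigma: float = 0.2          # lognormal shape
    reward_overrep_weight: float = 0.5
    reward_gauss_mean_cm: float = 114.0
    reward_gauss_sd_cm: float = 55.0
    fate_fractions: dict = field(
        default_factory=lambda: {"stable": 0.367, "disappear": 0.412, "remap": 0.221}
    )
    rr_transition: dict = field(
        default_factory=lambda: {
            # P(fate in RR | fate in RE_low) for fields defined in R
            "stable": {"stable": 0.761, "remap": 0.100, "disappear": 0.139},
            "disappear": {"stable": 0.506, "remap": 0.100, "disappear": 0.394},
            "remap": {"stable": 0.120, "remap": 0.450, "disappear": 0.430},
        }
    )
    new_field_rate_relow: float = 0.49    # new RE_low fields per R field
    new_field_rate_rr: float = 0.23
    new_field_stable_rr: float = 0.216    # P(new RE_low field survives into RR)
    remap_min_shift_cm: float = 25.0

    # calcium kinetics / noise
    transient_rise_s: float = 0.05
    transient_decay_s: float = 0.5
    out_of_field_rate_hz: float = 0.02    # stray transients per cell per second
    noise_sd: float = 0.05

    # dopaminergic axon
    ramp_amplitudes: dict = field(
        default_factory=lambda: {"R": 1.0, "RE_HIGH": 0.57, "RE_LOW": 0.24, "RR": 1.0}
    )
    ramp_exponent: float = 2.0
    ramp_amplitude_jitter: float = 0.05
    axon_noise_sd: float = 0.02

    # pupil
    with_pupil: bool = False
    pupil_bump: float = 0.4
    pupil_noise_sd: float = 0.03
    blink_prob: float = 0.005

    seed: int = 0

    def validate(self) -> None:
        total = sum(self.fate_fractions.values())
        if abs(total - 1.0) > 1e-6:
            raise ConfigError(f"fate fractions sum to {total:g}, expected 1")
        for name in ("reliability_p", "disengaged_fraction", "reward_overrep_weight"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v:g} outside [0, 1]")
        if any(n < 1 for n in self.laps.values()):
            raise ConfigError("each condition needs at least one lap")


# --------------------------------------------------------------------------
# behavior


@dataclass
class _LapPlan:
    condition: str
    lap: int              # 1-based within condition
    engaged: bool
    licking: bool
    rewarded: bool
    duration_s: float
    approach_ratio: float


def _plan_laps(config: SimConfig, rng: np.random.Generator) -> tuple[list[_LapPlan], dict]:
    """Sample per-lap latents (engagement, licking, duration)."""
    n_ur = config.laps.get("UR", 0)

    # lap on which anticipatory licking ceases (first silent UR lap); the
    # k=2 consecutive-silent-laps rule places the RE boundary two laps later
    first_silent = max(2, int(round(rng.normal(config.lick_stop_lap_mean,
                                               config.lick_stop_lap_sd))))
    if n_ur:
        first_silent = min(first_silent, max(2, n_ur - 6))
    lick_stop_lap = first_silent + 2

    lick_laps = set(range(1, first_silent))
    if config.random_relick:
        for lap in range(lick_stop_lap, n_ur + 1):
            if rng.random() < config.relick_lap_prob:
                lick_laps.add(lap)

    plans: list[_LapPlan] = []
    per_lap = []
    for cond, n_laps in config.laps.items():
        for lap in range(1, n_laps + 1):
            rewarded = cond in ("R", "RR", "N")
            licking = rewarded or (cond == "UR" and lap in lick_laps)
            if cond == "UR" and lap >= lick_stop_lap:
                engaged = rng.random() >= config.disengaged_fraction
            elif cond == "DARK":
                engaged = False
            else:
                engaged = True
            dur = rng.lognormal(np.log(config.lap_duration_median_s),
                                config.lap_duration_sigma)
            if not engaged:
                dur *= config.disengaged_duration_factor
            ratio = (rng.normal(config.approach_ratio, config.approach_ratio_sd)
                     if engaged else rng.normal(1.0, 0.02))
            plans.append(_LapPlan(cond, lap, engaged, licking, rewarded,
                                  dur, max(ratio, 1.01)))
            per_lap.append({"condition": cond, "lap": lap, "engaged": bool(engaged),
                            "licking_on": bool(licking)})

    lick_meta = {
        "last_lick_lap": first_silent - 1,
        "first_silent_lap": int(first_silent),
        "lick_stop_lap": int(lick_stop_lap),
        "relick_laps": sorted(l for l in lick_laps if l >= first_silent),
    }
    return plans, {"laps": per_lap, "lick": lick_meta}


def _lap_velocity_profile(plan: _LapPlan, track_length: float):
    """Velocity as a function of position for one lap.

    Engaged laps run flat until 150 cm then decelerate linearly so that the
    mid-track (100-150 cm) to end-track (175-200 cm) velocity ratio matches
    the planned approach ratio; disengaged laps are nearly flat.  The
    profile is scaled so the traversal takes the planned duration.
    """
    r = plan.approach_ratio
    # end-segment velocity fraction so that mean v over [175, 200] = v0 / r
    ve_frac = max((1.0 / r - 0.25) / 0.75, 0.05)

    def v_of_x(x, v0):
        x = np.asarray(x, dtype=float)
        v = np.full_like(x, v0)
        tail = x >= 150.0
        v[tail] = v0 * (1.0 + (ve_frac - 1.0) * (x[tail] - 150.0)
                        / (track_length - 150.0))
        return v

    xs = np.linspace(0, track_length - 1e-6, 2001)
    t_unit = np.trapezoid(1.0 / v_of_x(xs, 1.0), xs)   # traversal time at v0=1
    v0 = t_unit / plan.duration_s
    return lambda x: v_of_x(x, v0)


def generate_behavior(config: SimConfig, rng: np.random.Generator):
    """Generate per-frame behavior channels and the per-lap ground truth.

    Returns ``(frames, truth)`` where ``frames`` holds per-frame arrays
    plus lap bookkeeping (slices, reward/teleport alignment frames, plans)
    consumed by the trace generators.
    """
    config.validate()
    plans, truth = _plan_laps(config, rng)
    dt = 1.0 / config.frame_rate
    pause_frames = int(round(config.pause_s * config.frame_rate))
    lick_p = min(config.lick_rate_hz * dt, 1.0)

    pos_parts, vel_parts, lick_parts, rew_parts, cond_parts = [], [], [], [], []
    lap_slices: list[tuple[int, int]] = []
    lap_reward_frame: list[int] = []
    cursor = 0

    for plan in plans:
        v_of_x = _lap_velocity_profile(plan, config.track_length)
        pos, vel = [], []
        x = 0.0
        while x < config.track_length:
            v = float(v_of_x(x))
            pos.append(x)
            vel.append(v)
            x += v * dt
        n_run = len(pos)
        # consumption / teleportation pause at the end of the track
        hold = min(pos[-1], config.track_length - 1e-3)
        pos.extend([hold] * pause_frames)
        vel.extend([0.0] * pause_frames)
        n = len(pos)
        pos = np.asarray(pos)

        lick = np.zeros(n, dtype=bool)
        if plan.licking:
            zone = pos >= config.lick_zone_start_cm
            lick[zone] = rng.random(int(zone.sum())) < lick_p
            zone_run = np.flatnonzero(zone[:n_run])
            if zone_run.size and not lick[zone_run].any():
                lick[zone_run[0]] = True   # licking laps always lick pre-reward
        reward = np.zeros(n, dtype=bool)
        if plan.rewarded:
            reward[n_run - 1] = True

        pos_parts.append(pos)
        vel_parts.append(np.asarray(vel))
        lick_parts.append(lick)
        rew_parts.append(reward)
        cond_parts.append(np.full(n, plan.condition, dtype=object))
        lap_slices.append((cursor, cursor + n))
        lap_reward_frame.append(cursor + n_run - 1)
        cursor += n

    position = np.concatenate(pos_parts)
    T = position.shape[0]
    frames = {
        "time": np.arange(T) * dt,
        "position": position,
        "velocity": np.concatenate(vel_parts),
        "lick": np.concatenate(lick_parts),
        "reward": np.concatenate(rew_parts),
        "condition": np.concatenate(cond_parts),
        "lap_slices": lap_slices,
        "lap_reward_frame": lap_reward_frame,
        "plans": plans,
    }
    return frames, truth


# --------------------------------------------------------------------------
# place cells


def _transient_kernel(config: SimConfig) -> np.ndarray:
    """Difference-of-exponentials calcium kernel (rise 50 ms, decay 500 ms),
    normalized to unit area so convolution preserves sustained amplitudes."""
    dt = 1.0 / config.frame_rate
    t = np.arange(0, config.transient_decay_s * 6, dt)
    k = np.exp(-t / config.transient_decay_s) - np.exp(-t / config.transient_rise_s)
    return k / k.sum()


def _draw_com(config: SimConfig, rng: np.random.Generator) -> float:
    """Field center from the uniform + reward-end Gaussian mixture."""
    margin = 2.0
    if rng.random() < config.reward_overrep_weight:
        while True:
            c = rng.normal(config.reward_gauss_mean_cm, config.reward_gauss_sd_cm)
            if margin < c < config.track_length - margin:
                return float(c)
    return float(rng.uniform(margin, config.track_length - margin))


def _draw_remapped_com(config: SimConfig, old: float, rng: np.random.Generator) -> float:
    while True:
        c = _draw_com(config, rng)
        if abs(c - old) > config.remap_min_shift_cm:
            return float(c)


def _assign_cell_maps(config: SimConfig, rng: np.random.Generator) -> list[dict]:
    """Sample per-cell tuning and condition-dependent fate.

    ``com`` maps a *map key* to a field center: "R" (expressed in R laps
    and UR laps before licking stops), "UR" (expressed in RE_low laps),
    "RR", "N".  Absent key = no field on that map.
    """
    n = config.n_cells
    n_place = int(round(n * config.place_cell_fraction))
    fates = list(config.fate_fractions)
    probs = np.array([config.fate_fractions[f] for f in fates])

    cells: list[dict] = []
    for i in range(n):
        rec = {
            "cell": i,
            "reliability_p": config.reliability_p,
            "amplitude": float(rng.lognormal(np.log(config.amplitude_mean),
                                             config.amplitude_sigma)),
            "com": {},
            "fate_relow": None,
            "fate_rr": None,
            "new_in": None,
        }
        if i < n_place:
            com_r = _draw_com(config, rng)
            rec["com"]["R"] = com_r
            if "N" in config.laps:
                rec["com"]["N"] = _draw_com(config, rng)
            fate = str(rng.choice(fates, p=probs))
            rec["fate_relow"] = fate
            if fate == "stable":
                rec["com"]["UR"] = com_r
            elif fate == "remap":
                rec["com"]["UR"] = _draw_remapped_com(config, com_r, rng)
            if "RR" in config.laps:
                trans = config.rr_transition[fate]
                keys = list(trans)
                p = np.array([trans[k] for k in keys], dtype=float)
                rr_fate = str(rng.choice(keys, p=p / p.sum()))
                rec["fate_rr"] = rr_fate
                if rr_fate == "stable":
                    rec["com"]["RR"] = com_r
                elif rr_fate == "remap":
                    rec["com"]["RR"] = _draw_remapped_com(config, com_r, rng)
        cells.append(rec)

    # new fields form in previously silent cells
    silent = [c for c in cells if "R" not in c["com"]]
    rng.shuffle(silent)
    n_new_relow = (min(int(round(config.new_field_rate_relow * n_place)), len(silent))
                   if "UR" in config.laps else 0)
    for rec in silent[:n_new_relow]:
        rec["com"]["UR"] = _draw_com(config, rng)
        rec["new_in"] = "UR"
        if "RR" in config.laps and rng.random() < config.new_field_stable_rr:
            rec["com"]["RR"] = rec["com"]["UR"]
    if "RR" in config.laps:
        remaining = silent[n_new_relow:]
        n_new_rr = min(int(round(config.new_field_rate_rr * n_place)), len(remaining))
        for rec in remaining[:n_new_rr]:
            rec["com"]["RR"] = _draw_com(config, rng)
            rec["new_in"] = "RR"
    return cells


def _lap_map_key(plan: _LapPlan, lick_stop_lap: int) -> str:
    """Which tuning map a lap expresses: UR laps keep the R map until
    licking stops, then switch to the RE_low map."""
    if plan.condition == "UR":
        return "R" if plan.lap < lick_stop_lap else "UR"
    return plan.condition


def generate_place_cell_traces(config: SimConfig, frames: dict, truth: dict,
                               rng: np.random.Generator) -> np.ndarray:
    """Synthesize the cells x frames dF/F matrix from sampled latents.

    In-field activity on a lap is Bernoulli(``reliability_p``): on hit laps
    the cell emits a Gaussian spatial rate centered on the lap's map,
    convolved with the calcium kernel.  Out-of-field stray transients occur
    as a Poisson process and white measurement noise is added last.  The
    ground truth gains per-cell maps, per-lap hit records and the
    noise-free (calcium-space) center of mass of each realized field.
    """
    cells = _assign_cell_maps(config, rng)
    lick_stop = truth["lick"]["lick_stop_lap"]
    plans = frames["plans"]
    lap_slices = frames["lap_slices"]
    position = frames["position"]
    velocity = frames["velocity"]
    T = position.shape[0]
    kernel = _transient_kernel(config)
    impulse_kernel = kernel / kernel.max()
    sig2 = config.field_sigma_cm ** 2
    spec = BinningSpec()
    run = velocity >= spec.speed_threshold

    # per-frame map key, for ground-truth center-of-mass computation
    map_key_frames: dict[str, np.ndarray] = {}
    for plan, (a, b) in zip(plans, lap_slices):
        key = _lap_map_key(plan, lick_stop)
        mask = map_key_frames.setdefault(key, np.zeros(T, dtype=bool))
        mask[a:b] = True

    dff = np.zeros((config.n_cells, T))
    for rec in cells:
        field_signal = np.zeros(T)
        lap_hits = []
        for plan, (a, b) in zip(plans, lap_slices):
            key = _lap_map_key(plan, lick_stop)
            com = rec["com"].get(key)
            if com is None:
                continue
            hit = rng.random() < rec["reliability_p"]
            lap_hits.append({"condition": plan.condition, "lap": plan.lap,
                             "map": key, "hit": bool(hit)})
            if not hit:
                continue
            seg = position[a:b]
            rate = rec["amplitude"] * np.exp(-((seg - com) ** 2) / (2 * sig2))
            rate[~run[a:b]] = 0.0
            field_signal[a:b] += rate
        clean = fftconvolve(field_signal, kernel)[:T]
        rec["lap_hits"] = lap_hits

        rec["true_com"] = {}
        for key, mask in map_key_frames.items():
            if key not in rec["com"]:
                continue
            sel = mask & run
            if not sel.any():
                continue
            bins = spec.bin_of(position[sel])
            sums = np.bincount(bins, weights=clean[sel], minlength=spec.n_bins)
            counts = np.bincount(bins, minlength=spec.n_bins)
            curve = np.divide(sums, counts, out=np.zeros(spec.n_bins),
                              where=counts > 0)
            if curve.sum() > 0:
                # center of mass of the realized calcium field's core: the
                # contiguous run of bins above 5% of the noise-free peak
                peak = int(np.argmax(curve))
                floor = 0.05 * curve[peak]
                lo = peak
                while lo > 0 and curve[lo - 1] > floor:
                    lo -= 1
                hi = peak
                while hi < spec.n_bins - 1 and curve[hi + 1] > floor:
                    hi += 1
                core = curve[lo:hi + 1]
                rec["true_com"][key] = float(
                    (core * spec.centers[lo:hi + 1]).sum() / core.sum())

        noisy = clean
        n_events = rng.poisson(config.out_of_field_rate_hz * T / config.frame_rate)
        if n_events:
            impulses = np.zeros(T)
            idx = rng.integers(0, T, n_events)
            impulses[idx] += rec["amplitude"] * rng.uniform(0.5, 1.0, n_events)
            noisy = noisy + fftconvolve(impulses, impulse_kernel)[:T]
        if config.noise_sd > 0:
            noisy = noisy + rng.normal(0.0, config.noise_sd, T)
        dff[rec["cell"]] = noisy

    truth["cells"] = cells
    truth["lick_stop_lap"] = int(lick_stop)
    return dff


# --------------------------------------------------------------------------
# dopaminergic axon


def generate_da_axon(config: SimConfig, frames: dict, truth: dict,
                     rng: np.random.Generator) -> np.ndarray:
    """Reward-proximity ramping axon signal.

    Within each lap the signal is ``amplitude(condition) * g(f)`` where
    ``f`` is the fraction of the pre-reward span elapsed and
    ``g(f) = f**ramp_exponent`` (monotone, g(0)=0, g(1)=1); it decays back
    to baseline within 2 s after reward.  UR laps align to the
    teleportation frame where reward previously occurred.  Amplitude
    depends on reward expectation (R / RE_high / RE_low / RR).

    ``ramp_amplitudes`` are expressed on the slope*max readout scale:
    because both the fitted slope and the maximum scale linearly with the
    fluorescence scale, slope*max scales quadratically, so the underlying
    signal is scaled by the square root of the configured level.  A
    configured level of 0.57 is then recovered as a mean slope*max of 0.57
    relative to the rewarded condition.
    """
    lick_stop = truth["lick"]["lick_stop_lap"]
    T = frames["position"].shape[0]
    signal = np.zeros(T)
    lap_amp = []
    for plan, (a, b), rf in zip(frames["plans"], frames["lap_slices"],
                                frames["lap_reward_frame"]):
        if plan.condition == "UR":
            key = "RE_HIGH" if plan.lap < lick_stop else "RE_LOW"
        else:
            key = plan.condition
        base = config.ramp_amplitudes.get(key, config.ramp_amplitudes.get("R", 1.0))
        amp = (float(np.sqrt(base) * rng.lognormal(0.0, config.ramp_amplitude_jitter))
               if base > 0 else 0.0)
        lap_amp.append({"condition": plan.condition, "lap": plan.lap,
                        "re_key": key, "amplitude": amp})
        pre = np.arange(a, rf + 1)
        f = (pre - a) / max(rf - a, 1)
        signal[pre] = amp * f ** config.ramp_exponent
        post = np.arange(rf + 1, b)
        if post.size:
            tau = 0.5 * config.frame_rate   # frames; back to baseline < 2 s
            signal[post] = amp * np.exp(-(post - rf) / tau)
    if config.axon_noise_sd > 0:
        signal = signal + rng.normal(0.0, config.axon_noise_sd, T)
    truth["axon"] = {"laps": lap_amp,
                     "amplitudes": dict(config.ramp_amplitudes),
                     "exponent": config.ramp_exponent}
    return signal


# --------------------------------------------------------------------------
# pupil


def _generate_pupil(config: SimConfig, frames: dict, rng: np.random.Generator):
    """Pupil-area trace: a bump over the final 25 cm, flattened when
    disengaged, plus white noise; blink dips mark the blink channel."""
    position = frames["position"]
    T = position.shape[0]
    bump = np.clip((position - (config.track_length - 25.0)) / 25.0, 0.0, 1.0)
    pupil = np.ones(T)
    for plan, (a, b) in zip(frames["plans"], frames["lap_slices"]):
        scale = config.pupil_bump if plan.engaged else 0.05 * config.pupil_bump
        pupil[a:b] += scale * bump[a:b]
    pupil += rng.normal(0.0, config.pupil_noise_sd, T)
    blink = np.ones(T) + rng.normal(0.0, 0.02, T)
    blink_frames = rng.random(T) < config.blink_prob
    blink[blink_frames] = 0.3
    pupil[blink_frames] = 0.1
    return pupil, blink


# --------------------------------------------------------------------------
# top level


def generate_session(config: SimConfig | None = None, seed: int | None = None,
                     with_axon: bool = False):
    """Generate a full synthetic session.

    Returns ``(session, truth)``; ``truth`` is JSON-serializable and records
    every sampled latent.  With ``with_axon=True`` the axon signal is
    appended as the final row of ``dff`` and flagged in the ground truth.
    Identical config and seed give bit-identical output.
    """
    config = config or SimConfig()
    if seed is not None:
        config = replace(config, seed=seed)
    config.validate()
    rng = np.random.default_rng(config.seed)

    frames, truth = generate_behavior(config, rng)
    dff = generate_place_cell_traces(config, frames, truth, rng)
    if with_axon:
        axon = generate_da_axon(config, frames, truth, rng)
        dff = np.vstack([dff, axon[None, :]]) if dff.size else axon[None, :]
        truth["axon_row"] = int(dff.shape[0] - 1)

    pupil = blink = None
    if config.with_pupil:
        pupil, blink = _generate_pupil(config, frames, rng)

    session = SessionRecord(
        time=frames["time"],
        position=frames["position"],
        velocity=frames["velocity"],
        lick=frames["lick"],
        reward=frames["reward"],
        condition=frames["condition"],
        dff=dff,
        frame_rate=config.frame_rate,
        track_length=config.track_length,
        pupil_area=pupil,
        blink_area=blink,
        animal_id=f"sim{config.seed}",
    )
    truth["seed"] = int(config.seed)
    truth["n_cells"] = int(config.n_cells)
    truth["lap_counts"] = dict(config.laps)
    return session, truth


def generate_axon_session(config: SimConfig | None = None, seed: int | None = None):
    """Axon-imaging session: behavior plus a single ramping-axon dF/F row."""
    if config is None:
        config = SimConfig(n_cells=0, place_cell_fraction=0.0)
    elif config.n_cells:
        config = replace(config, n_cells=0, place_cell_fraction=0.0)
    return generate_session(config, seed=seed, with_axon=True)
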