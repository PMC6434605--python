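"""Synthetic biologger deployments with realistic class structure.

The generator produces, for one simulated bird, a hidden per-second
behavior sequence (:func:`simulate_states`), a matching 25 Hz tri-axial
acceleration trace with depth (:func:`simulate_accel`), and a GPS track
whose kinematics are consistent with the behavior sequence
(:func:`simulate_gps`).

Behavior sequences are semi-Markov: explicit bout durations are drawn
per behavior (log-normal), and bouts are arranged in central-place
foraging trips -- colony, outbound flight, a period on the water
(swimming, with dives embedded inside swimming for murres), inbound
flight, colony -- so that the behavioral adjacency constraints hold by
construction: no direct colony-swimming, colony-diving or flying-diving
transitions, and every change between the colony and the water passes
through flight.

The acceleration signal model inverts the feature definitions used for
classification: body posture sets the static (gravity) component via the
bout's pitch angle, band-limited body-motion noise (resonant AR(2),
0.6-1.5 Hz depending on behavior) scaled to the behavior's activity
level provides the dynamic component, and flight adds a heave (Z) axis
sinusoid at the species wing-beat frequency.  A random
mounting-pitch offset (within +/-15 degrees) is applied per deployment to
exercise the pitch calibration step.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .config import SpeciesConfig
from .io import AccelTrace, GpsTrack

__all__ = [
    "BehaviorSignal", "BehaviorParams", "StateSequence",
    "default_params", "simulate_states", "simulate_accel", "simulate_gps",
    "simulate_deployment",
]

MIN_BOUT_S = 10.0          # generator never emits a bout shorter than this
DIVE_SPEED = 1.0           # m/s vertical during descent/ascent


@dataclass
class BehaviorSignal:
    """Class-conditional signal parameters for one behavior."""

    pitch_mean: float          # degrees
    pitch_sd: float
    activity_mean: float       # g, on the species activity metric
    activity_sd: float
    bout_median: float         # s, log-normal median bout duration
    bout_sigma: float          # log-scale SD of bout duration
    noise_f0: float = 1.0      # Hz, center of the dynamic-noise band
    # flight only
    wbf_hz: float = 0.0        # flapping frequency, Hz
    wbf_bout_sd: float = 0.0   # between-bout frequency SD, Hz
    wbf_jitter_sd: float = 0.0  # slow within-bout frequency jitter SD, Hz
    flap_amplitude: float = 0.0  # g, heave-axis sinusoid amplitude
    # diving only (murre)
    depth_mean: float = 0.0    # m (negative below surface)
    depth_sd: float = 0.0
    # GPS kinematics
    speed_mean: float = 0.0    # m/s
    speed_sd: float = 0.0


@dataclass
class BehaviorParams:
    """Per-behavior signal parameters plus deployment-level settings."""

    behaviors: dict[str, BehaviorSignal]
    noise_damping: float = 0.92      # AR(2) pole radius of dynamic noise
    sensor_noise: float = 0.01       # g, white measurement noise
    mounting_offset_range: float = 15.0   # deg, uniform +/- range
    colony_scatter: float = 10.0     # m, positional jitter at the nest
    swim_drift_sd: float = 60.0      # m, OU positional SD while on water
    dives_per_visit: float = 3.0     # mean extra dives per water visit (murre)

    def __getitem__(self, behavior: str) -> BehaviorSignal:
        return self.behaviors[behavior]


def default_params(config: SpeciesConfig) -> BehaviorParams:
    """Default class-conditional parameters for a species/stage preset.

    The pitch, activity, wing-beat frequency and dive-depth distributions
    reproduce the per-behavior summary statistics of the two study
    species; incubation presets differ from chick-rearing only in bout
    durations and colony activity (incubating birds sit longer and, for
    kittiwakes, shuffle more on the nest).
    """
    egg = config.stage == "egg"
    if config.species == "murre":
        b = {
            "colony": BehaviorSignal(37.6, 6.1, 0.05, 0.02,
                                     bout_median=4800 if egg else 2400,
                                     bout_sigma=0.5, noise_f0=0.6),
            "flying": BehaviorSignal(0.0, 1.0, 0.10, 0.03,
                                     bout_median=480, bout_sigma=0.35,
                                     noise_f0=1.0,
                                     wbf_hz=8.1, wbf_bout_sd=0.1,
                                     wbf_jitter_sd=0.15, flap_amplitude=1.0,
                                     speed_mean=12.0, speed_sd=1.5),
            "swimming": BehaviorSignal(-7.4, 2.5, 0.28, 0.08,
                                       bout_median=300, bout_sigma=0.5,
                                       noise_f0=1.3,
                                       speed_mean=0.5, speed_sd=0.2),
            "diving": BehaviorSignal(-5.0, 15.0, 0.20, 0.05,
                                     bout_median=60, bout_sigma=0.3,
                                     noise_f0=1.5,
                                     depth_mean=-20.5, depth_sd=9.0),
        }
        return BehaviorParams(behaviors=b)
    b = {
        "colony": BehaviorSignal(29.9, 11.7,
                                 0.06 if egg else 0.04, 0.02,
                                 bout_median=3600 if egg else 1800,
                                 bout_sigma=0.5, noise_f0=0.6),
        "flying": BehaviorSignal(0.0, 1.0, 0.08, 0.02,
                                 bout_median=480, bout_sigma=0.35,
                                 noise_f0=1.0,
                                 wbf_hz=4.16, wbf_bout_sd=0.1,
                                 wbf_jitter_sd=0.12, flap_amplitude=0.85,
                                 speed_mean=8.0, speed_sd=1.0),
        "swimming": BehaviorSignal(5.7, 2.9, 0.18, 0.04,
                                   bout_median=420, bout_sigma=0.5,
                                   noise_f0=1.3,
                                   speed_mean=0.5, speed_sd=0.2),
    }
    return BehaviorParams(behaviors=b)


@dataclass
class StateSequence:
    """Hidden per-second behavior labels plus the generating bout table."""

    bird_id: str
    states: np.ndarray                 # per-second labels, length = seconds
    bout_table: pd.DataFrame           # behavior, start, end, dive_depth

    def __len__(self) -> int:
        return self.states.size

    @property
    def duration(self) -> float:
        return float(self.states.size)


def _lognormal_duration(rng, sig: BehaviorSignal, floor: float = MIN_BOUT_S) -> float:
    d = sig.bout_median * np.exp(sig.bout_sigma * rng.standard_normal())
    return float(max(d, floor))


def simulate_states(config: SpeciesConfig, params: Optional[BehaviorParams],
                    duration_hours: float, seed) -> StateSequence:
    """Draw a semi-Markov behavior sequence starting at the colony."""
    if duration_hours <= 0:
        raise ValueError("duration must be positive")
    if params is None:
        params = default_params(config)
    rng = np.random.default_rng(seed)
    total = int(round(duration_hours * 3600))
    murre = config.species == "murre"

    bouts: list[tuple[str, float, float]] = []   # behavior, duration, dive depth
    elapsed = 0.0

    def add(behavior: str, dur: float, depth: float = np.nan) -> None:
        nonlocal elapsed
        bouts.append((behavior, dur, depth))
        elapsed += dur

    while elapsed < total:
        add("colony", _lognormal_duration(rng, params["colony"], 60.0))
        if elapsed >= total:
            break
        # foraging trip: out-flight, water period, in-flight
        out_dur = _lognormal_duration(rng, params["flying"], 60.0)
        add("flying", out_dur)
        add("swimming", _lognormal_duration(rng, params["swimming"]))
        if murre:
            n_dives = 1 + rng.poisson(params.dives_per_visit)
            for _ in range(n_dives):
                sig = params["diving"]
                depth = min(rng.normal(sig.depth_mean, sig.depth_sd), -3.0)
                dur = 2.0 * abs(depth) / DIVE_SPEED + rng.uniform(10.0, 30.0)
                add("diving", max(dur, MIN_BOUT_S + 2), depth)
                add("swimming", _lognormal_duration(rng, params["swimming"]))
        # return leg mirrors the outbound commute so the bird lands at the nest
        add("flying", max(out_dur * rng.uniform(0.92, 1.08), 60.0))

    # integer-second bout boundaries, truncated to the deployment
    rows = []
    t = 0
    for behavior, dur, depth in bouts:
        end = min(t + int(round(dur)), total)
        if end > t:
            rows.append((behavior, t, end, depth))
        t = end
        if t >= total:
            break
    table = pd.DataFrame(rows, columns=["behavior", "start", "end", "dive_depth"])
    states = np.empty(total, dtype="<U8")
    for behavior, start, end, _ in table.itertuples(index=False):
        states[start:end] = behavior
    return StateSequence(bird_id=f"sim_{seed}" if np.isscalar(seed) else "sim",
                         states=states, bout_table=table)


def _ar1(rng, n: int, phi: float) -> np.ndarray:
    """Unit-marginal-variance AR(1) noise (slow drift processes)."""
    white = rng.standard_normal(n)
    return lfilter([np.sqrt(1.0 - phi ** 2)], [1.0, -phi], white)


def _body_noise(rng, n: int, f0: float, r: float, rate: float) -> np.ndarray:
    """Band-limited body-motion noise: resonant AR(2) centered at f0 Hz.

    Real non-flight body movement (shuffling, paddling strokes, wave
    action) concentrates between roughly 0.5 and 2 Hz, well above the
    passband of the 2-s moving mean that defines static acceleration --
    so it registers as dynamic acceleration without corrupting the
    posture estimate, and gives non-flight windows their low dominant
    frequencies.
    """
    theta = 2.0 * np.pi * f0 / rate
    a = [1.0, -2.0 * r * np.cos(theta), r * r]
    return lfilter([1.0], a, rng.standard_normal(n))


def _metric_mean(axes: list, metric: str, window: int) -> float:
    """Mean activity metric of a noise sample, via the feature pipeline."""
    def dyn(x):
        s = pd.Series(x).rolling(window, center=True, min_periods=1)
        return x - s.mean().to_numpy()

    if metric == "SD_Z":
        d = dyn(axes[2])
        return float(np.nanmean(pd.Series(d).rolling(
            window, center=True, min_periods=1).std(ddof=0).to_numpy()))
    odba = np.abs(dyn(axes[0])) + np.abs(dyn(axes[1])) + np.abs(dyn(axes[2]))
    return float(np.nanmean(pd.Series(odba).rolling(
        window, center=True, min_periods=1).std(ddof=0).to_numpy()))


def _activity_factors(rng, params: BehaviorParams, metric: str,
                      rate: int) -> dict:
    """Per-behavior activity-metric response of unit-scale body noise."""
    n = 120 * rate
    window = 2 * rate
    out = {}
    for behavior, sig in params.behaviors.items():
        axes = [_body_noise(rng, n, sig.noise_f0, params.noise_damping, rate)
                for _ in range(3)]
        out[behavior] = _metric_mean(axes, metric, window)
    return out


def simulate_accel(states: StateSequence, config: SpeciesConfig,
                   params: Optional[BehaviorParams], seed) -> AccelTrace:
    """Render a 25 Hz tri-axial trace (plus depth for murres) from states."""
    if params is None:
        params = default_params(config)
    rng = np.random.default_rng(seed)
    rate = int(round(config.sampling_rate))
    seconds = len(states)
    n = seconds * rate
    t = np.arange(n) / rate

    offset = rng.uniform(-params.mounting_offset_range,
                         params.mounting_offset_range)
    factors = _activity_factors(rng, params, config.activity_metric, rate)

    theta = np.empty(n)        # measured pitch, deg
    depth_sec = np.zeros(seconds) if config.has_depth else None
    noise = np.zeros((3, n))   # per-axis dynamic body noise

    table = states.bout_table
    for behavior, start, end, dive_depth in table.itertuples(index=False):
        sig = params[behavior]
        i0, i1 = start * rate, end * rate
        theta[i0:i1] = rng.normal(sig.pitch_mean, sig.pitch_sd) + offset
        act = max(rng.normal(sig.activity_mean, sig.activity_sd),
                  0.25 * sig.activity_mean, 0.005)
        scale = act / factors[behavior]
        for ax in range(3):
            noise[ax, i0:i1] = scale * _body_noise(
                rng, i1 - i0, sig.noise_f0, params.noise_damping, rate)
        if behavior == "diving" and depth_sec is not None:
            dur = end - start
            target = dive_depth if np.isfinite(dive_depth) else -0.35 * dur
            # V/U profile: 1 m/s descent, bottom phase, 1 m/s ascent,
            # clipped so every second of the dive sits below -1 m
            leg = min(int(np.ceil(abs(target) / DIVE_SPEED)), dur // 2)
            prof = np.full(dur, float(target))
            if leg > 0:
                ramp = -DIVE_SPEED * np.arange(1, leg + 1)
                prof[:leg] = np.maximum(ramp, target)
                prof[dur - leg:] = np.maximum(ramp[::-1], target)
            depth_sec[start:end] = np.minimum(prof, -1.5)

    # slow postural wander within bouts (birds shift position); without it
    # segment-mean pitch would cluster at the per-bout draws
    wander_phi = np.exp(-1.0 / (30.0 * rate))
    theta += 2.0 * _ar1(rng, n, wander_phi)

    rad = np.radians(theta)
    X = np.sin(rad) + noise[0]
    Y = noise[1]
    Z = np.cos(rad) + noise[2]
    del noise

    # flapping-flight sinusoid on the heave axis, phase-continuous per bout
    jitter_phi = np.exp(-1.0 / (10.0 * rate))   # ~10 s correlation time
    for behavior, start, end, _ in table.itertuples(index=False):
        if behavior != "flying":
            continue
        sig = params[behavior]
        i0, i1 = start * rate, end * rate
        m = i1 - i0
        f = (sig.wbf_hz + rng.normal(0.0, sig.wbf_bout_sd)
             + sig.wbf_jitter_sd * _ar1(rng, m, jitter_phi))
        phase = 2.0 * np.pi * np.cumsum(f) / rate + rng.uniform(0, 2 * np.pi)
        Z[i0:i1] += sig.flap_amplitude * np.sin(phase)

    if params.sensor_noise > 0:
        X += params.sensor_noise * rng.standard_normal(n)
        Y += params.sensor_noise * rng.standard_normal(n)
        Z += params.sensor_noise * rng.standard_normal(n)

    depth = None
    if depth_sec is not None:
        depth = np.repeat(depth_sec, rate)   # 1 Hz channel, step-filled
    return AccelTrace(bird_id=states.bird_id, t=t, X=X, Y=Y, Z=Z, depth=depth)


def _ou_walk(rng, n: int, sd: float, tau: float) -> np.ndarray:
    """Mean-reverting positional noise (per-second), starting at zero."""
    phi = np.exp(-1.0 / tau)
    step = sd * np.sqrt(1.0 - phi ** 2)
    return lfilter([step], [1.0, -phi], rng.standard_normal(n))


def simulate_gps(states: StateSequence, config: SpeciesConfig,
                 params: Optional[BehaviorParams], seed) -> GpsTrack:
    """Planar nest-centered GPS track consistent with the behavior states.

    Colony positions jitter within tens of meters of the origin, flight
    legs are straight commutes at species-typical ground speed, and time
    on the water is a mean-reverting drift around the trip's offshore
    anchor.  The inbound flight speed is set by the distance home and the
    bout duration, which the state generator matched to the outbound leg.
    """
    if params is None:
        params = default_params(config)
    rng = np.random.default_rng(seed)
    seconds = len(states)
    pos = np.zeros((seconds, 2))
    here = np.zeros(2)

    table = states.bout_table
    rows = list(table.itertuples(index=False))
    for k, (behavior, start, end, _) in enumerate(rows):
        m = end - start
        if behavior == "colony":
            tau = 60.0
            pos[start:end, 0] = params.colony_scatter * _ou_walk(rng, m, 1.0, tau)
            pos[start:end, 1] = params.colony_scatter * _ou_walk(rng, m, 1.0, tau)
            here = pos[end - 1].copy()
        elif behavior == "flying":
            nxt = rows[k + 1][0] if k + 1 < len(rows) else None
            sig = params["flying"]
            if nxt in (None, "colony"):
                # head home; speed is fixed by distance and duration
                dist = float(np.hypot(*here))
                speed = dist / m if m > 0 else sig.speed_mean
                lo = 1.5 * config.gps_flight_speed
                hi = 0.8 * config.gps_speed_error_cutoff
                speed = float(np.clip(speed, lo, hi))
                direction = (-here / dist) if dist > 1 else np.array([1.0, 0.0])
            else:
                speed = float(np.clip(rng.normal(sig.speed_mean, sig.speed_sd),
                                      0.6 * sig.speed_mean, 1.6 * sig.speed_mean))
                if np.hypot(*here) < 100:
                    ang = rng.uniform(0, 2 * np.pi)
                    direction = np.array([np.cos(ang), np.sin(ang)])
                else:
                    direction = here / np.hypot(*here)
            steps = speed * np.arange(1, m + 1)
            pos[start:end] = here + steps[:, None] * direction
            here = pos[end - 1].copy()
        else:   # swimming or diving: drift around the current anchor
            anchor = here.copy()
            pos[start:end, 0] = anchor[0] + _ou_walk(rng, m, params.swim_drift_sd, 300.0)
            pos[start:end, 1] = anchor[1] + _ou_walk(rng, m, params.swim_drift_sd, 300.0)
            here = pos[end - 1].copy()

    fix_t = np.arange(0.0, seconds, config.fix_interval)
    idx = fix_t.astype(int)
    noise = rng.normal(0.0, 2.0, size=(idx.size, 2))
    return GpsTrack(bird_id=states.bird_id, t=fix_t,
                    x=pos[idx, 0] + noise[:, 0], y=pos[idx, 1] + noise[:, 1],
                    fix_interval=config.fix_interval)


def simulate_deployment(config: SpeciesConfig, duration_hours: float, seed,
                        params: Optional[BehaviorParams] = None):
    """Simulate one bird end to end: states, accelerometer trace, GPS track."""
    if params is None:
        params = default_params(config)
    ss = np.random.SeedSequence(seed)
    s_states, s_accel, s_gps = ss.spawn(3)
    states = simulate_states(config, params, duration_hours, s_states)
    states.bird_id = f"bird{seed}"
    trace = simulate_accel(states, config, params, s_accel)
    gps = simulate_gps(states, config, params, s_gps)
    return states, trace, gps
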