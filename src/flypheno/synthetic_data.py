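"""Synthetic cohorts with known ground truth.

Two generators back the whole pipeline:

* :func:`generate_tracks` emulates multi-day single-fly video tracking in
  glass tubes (positions sampled at a fixed frame rate under a 12:12
  light:dark schedule).  Each fly alternates between an *asleep* state with
  sub-threshold jitter and an *awake* state with genotype-dependent speed,
  driven by a two-state semi-Markov process whose sleep-entry hazard is
  modulated over clock time by an archetype's sleep-intensity curve,
  lights-off latency and morning-anticipation parameters.
* :func:`generate_erg` emulates electroretinogram depolarization replicate
  tables for single and double heterozygous mutants, with per-batch controls
  and a multiplicative non-interacting expectation plus an optional additive
  interaction term per gene pair.

Both are deterministic for a fixed seed; per-fly streams are spawned from
``(seed, fly index)`` so cohorts are reproducible regardless of chunking.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MINUTES_PER_DAY = 1440
SECONDS_PER_DAY = 86400
#: step (s) of the underlying state process; one state per annotator interval
STATE_STEP = 10.0


@dataclass(frozen=True)
class ArchetypeSpec:
    """Genotype-level behavioral phenotype used to drive the simulator.

    Parameters
    ----------
    genotype_label:
        Name carried through to every downstream table.
    sleep_intensity_curve:
        1440 per-minute weights in [0, 1] multiplying the sleep-entry hazard
        at the corresponding clock minute (ZT0 = lights on at minute 0).
    mean_bout_length_night:
        Mean sleep-bout duration (s) during the dark phase.
    bout_rate_night:
        Sleep-bout initiation rate (bouts/h of awake time) at intensity 1.
    latency_lights_off:
        Mean delay (s) from lights-off until sleep pressure is fully engaged;
        the hazard ramps up as ``1 - exp(-t/latency)`` after ZT12.
    anticipation_ramp:
        Fraction in [0, 1] by which the sleep hazard is suppressed, ramping
        linearly over the final 3 h of night, producing a morning activity
        rise.
    awake_speed_mean, awake_speed_sd:
        Per-fly walking speed distribution (mm/s) while awake.
    day_sleep_scale:
        Multiplier on mean bout length during the light phase.
    """

    genotype_label: str
    sleep_intensity_curve: np.ndarray
    mean_bout_length_night: float = 1200.0
    bout_rate_night: float = 4.0
    latency_lights_off: float = 1800.0
    anticipation_ramp: float = 0.0
    awake_speed_mean: float = 2.5
    awake_speed_sd: float = 0.5
    day_sleep_scale: float = 0.5

    def __post_init__(self) -> None:
        curve = np.asarray(self.sleep_intensity_curve, dtype=float)
        object.__setattr__(self, "sleep_intensity_curve", curve)
        if curve.shape != (MINUTES_PER_DAY,):
            raise ValueError(
                f"sleep_intensity_curve must have {MINUTES_PER_DAY} entries, "
                f"got {curve.shape}"
            )
        if curve.min() < 0 or curve.max() > 1:
            raise ValueError("sleep_intensity_curve values must lie in [0, 1]")
        for name in ("mean_bout_length_night", "bout_rate_night",
                     "latency_lights_off", "awake_speed_mean", "day_sleep_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not 0.0 <= self.anticipation_ramp <= 1.0:
            raise ValueError("anticipation_ramp must lie in [0, 1]")
        if self.awake_speed_sd < 0:
            raise ValueError("awake_speed_sd must be non-negative")


@dataclass(frozen=True)
class SimulationConfig:
    """Recording-session parameters (frame rate, duration, photoperiod)."""

    n_flies_per_genotype: int = 20
    n_days: int = 6
    fps: float = 2.0
    photoperiod: float = 12.0
    seed: int = 0
    tube_length: float = 65.0

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError("fps must be strictly positive")
        if self.n_days < 2:
            raise ValueError("n_days must be at least 2 (first day is discarded)")
        if not 0 < self.photoperiod < 24:
            raise ValueError("photoperiod must lie in (0, 24) hours")
        if self.n_flies_per_genotype < 1:
            raise ValueError("n_flies_per_genotype must be at least 1")
        if self.tube_length <= 0:
            raise ValueError("tube_length must be strictly positive")


@dataclass(frozen=True)
class ERGSimSpec:
    """Ground-truth specification of an ERG interaction screen.

    ``single_effect`` maps each genotype to its depolarization amplitude as a
    fraction of control; ``interaction_term`` maps unordered gene pairs to an
    additive deviation from the multiplicative expectation (the ground-truth
    analogue of the Bayesian model's interaction term).
    """

    control_mean: float = 8.0
    single_effect: dict = field(default_factory=dict)
    interaction_term: dict = field(default_factory=dict)
    replicate_sd: float = 0.05
    n_replicates_per_genotype: int = 10
    n_batches: int = 3
    seed: int = 0
    batch_cv: float = 0.05

    def __post_init__(self) -> None:
        if self.n_replicates_per_genotype < 5:
            raise ValueError("n_replicates_per_genotype must be >= 5")
        if self.replicate_sd <= 0:
            raise ValueError("replicate_sd must be strictly positive")
        if self.control_mean <= 0:
            raise ValueError("control_mean must be strictly positive")
        for g, e in self.single_effect.items():
            if not 0 < e <= 1.05:
                raise ValueError(f"single effect for {g} must lie in (0, 1.05]")
        genes = set(self.single_effect)
        for pair in self.interaction_term:
            for g in pair:
                if g not in genes:
                    raise ValueError(f"interaction term references unknown genotype {g!r}")

    def pairs(self) -> list[tuple[str, str]]:
        """All unordered pairs of the specified genotypes, sorted."""
        genes = sorted(self.single_effect)
        return [(a, b) for i, a in enumerate(genes) for b in genes[i + 1:]]

    def iota(self, a: str, b: str) -> float:
        return self.interaction_term.get(frozenset((a, b)), self.interaction_term.get((a, b), self.interaction_term.get((b, a), 0.0)))


@dataclass(frozen=True)
class GroundTruth:
    """Planted group memberships and interaction classes for scoring recovery."""

    genotype_groups: dict
    interaction_calls: dict


def _fly_rng(seed: int, fly_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((seed, fly_index)))


def _hazard_profiles(arch: ArchetypeSpec, config: SimulationConfig) -> tuple[np.ndarray, np.ndarray]:
    """Per-state-step sleep-entry and wake probabilities over one day."""
    n_steps = int(round(SECONDS_PER_DAY / STATE_STEP))
    t = np.arange(n_steps) * STATE_STEP  # seconds since lights-on
    minute = (t // 60).astype(int) % MINUTES_PER_DAY
    intensity = arch.sleep_intensity_curve[minute].copy()

    lights_off = config.photoperiod * 3600.0
    night = t >= lights_off
    # latency: sleep pressure engages gradually after lights-off
    since_off = np.where(night, t - lights_off, 0.0)
    ramp = 1.0 - np.exp(-since_off / max(arch.latency_lights_off, 1e-9))
    intensity[night] *= ramp[night]
    # morning anticipation: hazard suppressed linearly over the last 3 h of night
    antic_start = SECONDS_PER_DAY - 3 * 3600.0
    antic = t >= antic_start
    frac = (t - antic_start) / (3 * 3600.0)
    intensity[antic] *= 1.0 - arch.anticipation_ramp * frac[antic]

    p_sleep = 1.0 - np.exp(-(arch.bout_rate_night / 3600.0) * STATE_STEP * intensity)
    mean_bout = np.where(night, arch.mean_bout_length_night,
                         arch.mean_bout_length_night * arch.day_sleep_scale)
    p_wake = 1.0 - np.exp(-STATE_STEP / mean_bout)
    return p_sleep, p_wake


def simulate_states(arch: ArchetypeSpec, config: SimulationConfig,
                    rng: np.random.Generator) -> np.ndarray:
    """Boolean asleep/awake sequence on the 10-s state grid for one fly."""
    p_sleep_day, p_wake_day = _hazard_profiles(arch, config)
    steps_per_day = p_sleep_day.size
    n_steps = steps_per_day * config.n_days
    u = rng.random(n_steps).tolist()
    p_on = np.tile(p_sleep_day, config.n_days).tolist()
    p_off = np.tile(p_wake_day, config.n_days).tolist()
    asleep = [False] * n_steps
    state = False
    for i in range(n_steps):
        if state:
            if u[i] < p_off[i]:
                state = False
        elif u[i] < p_on[i]:
            state = True
        asleep[i] = state
    return np.asarray(asleep, dtype=bool)


def _frames_from_states(asleep: np.ndarray, arch: ArchetypeSpec,
                        config: SimulationConfig,
                        rng: np.random.Generator) -> pd.DataFrame:
    """Expand a 10-s state sequence into frame-level positions."""
    frames_per_step = int(round(STATE_STEP * config.fps))
    n_frames = asleep.size * frames_per_step
    asleep_f = np.repeat(asleep, frames_per_step)

    speed = max(rng.normal(arch.awake_speed_mean, arch.awake_speed_sd), 0.3)
    step_mag = np.where(
        asleep_f,
        rng.uniform(0.0, 0.1, n_frames),            # always below 0.25 mm
        np.abs(rng.normal(speed / config.fps, 0.3 * speed / config.fps, n_frames)),
    )
    # keep awake steps above the immobility threshold so states are recoverable
    step_mag[~asleep_f] = np.maximum(step_mag[~asleep_f], 0.3)
    direction = rng.integers(0, 2, n_frames) * 2.0 - 1.0
    x = np.empty(n_frames)
    x0 = rng.uniform(0, config.tube_length)
    np.cumsum(step_mag * direction, out=x)
    x += x0
    # reflecting boundary on [0, tube_length] via triangle-wave folding
    L = config.tube_length
    x = np.abs(np.mod(x, 2 * L) - L) * -1 + L
    # transverse jitter kept tiny so it never lifts a sleeping fly above the
    # 0.25 mm immobility threshold
    y = np.clip(rng.normal(1.5, 0.02, n_frames), 0.0, 3.0)
    t = np.arange(n_frames, dtype=float) / config.fps
    return pd.DataFrame({"t": t, "x": x, "y": y})


def generate_tracks(config: SimulationConfig,
                    archetypes: list[ArchetypeSpec]) -> pd.DataFrame:
    """Long-format track table for a full cohort.

    Returns a DataFrame with columns ``fly_id, genotype, t, x, y`` at 1/fps
    spacing; deterministic for a fixed ``config.seed``.
    """
    frames = [df.assign(fly_id=fid, genotype=g)
              for fid, g, df in iter_tracks(config, archetypes)]
    out = pd.concat(frames, ignore_index=True)
    return out[["fly_id", "genotype", "t", "x", "y"]]


def iter_tracks(config: SimulationConfig, archetypes: list[ArchetypeSpec]):
    """Yield ``(fly_id, genotype, frame table)`` one fly at a time.

    Streaming counterpart of :func:`generate_tracks`; multi-day frame tables
    are large, so downstream pipelines annotate each fly as it is produced
    instead of stacking the whole cohort.
    """
    if not archetypes:
        raise ValueError("at least one archetype is required")
    fly_index = 0
    for arch in archetypes:
        for _ in range(config.n_flies_per_genotype):
            rng = _fly_rng(config.seed, fly_index)
            asleep = simulate_states(arch, config, rng)
            frames = _frames_from_states(asleep, arch, config, rng)
            yield f"fly{fly_index:04d}", arch.genotype_label, frames
            fly_index += 1


def generate_erg(spec: ERGSimSpec) -> pd.DataFrame:
    """ERG replicate table with per-batch controls.

    Columns: ``batch, genotype_a, genotype_b, amplitude, is_control``
    (``genotype_b`` empty for singles and controls).  Double-mutant replicate
    means converge to ``control_mean * (eA * eB + interaction)``; amplitudes
    are in mV on the raw scale so downstream per-batch normalization is
    exercised (each batch's control mean is drawn around ``control_mean``).
    """
    rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 977)))
    genes = sorted(spec.single_effect)
    pairs = spec.pairs()
    rows: list[tuple] = []
    n_rep = spec.n_replicates_per_genotype

    # round-robin assignment of measurements to batches
    units = [(g, "", spec.single_effect[g]) for g in genes]
    units += [(a, b, spec.single_effect[a] * spec.single_effect[b] + spec.iota(a, b))
              for a, b in pairs]

    batch_ctrl = rng.normal(spec.control_mean, spec.batch_cv * spec.control_mean,
                            spec.n_batches)
    batch_ctrl = np.maximum(batch_ctrl, 0.1 * spec.control_mean)
    for bi in range(spec.n_batches):
        ctrl = rng.normal(batch_ctrl[bi], spec.replicate_sd * batch_ctrl[bi],
                          max(n_rep, 5))
        for amp in ctrl:
            rows.append((f"batch{bi}", "control", "", float(amp), True))
    for ui, (a, b, frac) in enumerate(units):
        bi = ui % spec.n_batches
        amps = batch_ctrl[bi] * (frac + rng.normal(0.0, spec.replicate_sd, n_rep))
        amps = np.maximum(amps, 1e-3)
        for amp in amps:
            rows.append((f"batch{bi}", a, b, float(amp), False))
    return pd.DataFrame(rows, columns=["batch", "genotype_a", "genotype_b",
                                       "amplitude", "is_control"])


def flat_curve(level: float = 0.5) -> np.ndarray:
    """Constant sleep-intensity curve."""
    return np.full(MINUTES_PER_DAY, float(level))


def archetype_low_sleep(label: str = "groupA") -> ArchetypeSpec:
    """Reduced-sleep phenotype: low hazard throughout, long latency."""
    curve = np.concatenate([np.full(720, 0.10), np.full(720, 0.30)])
    return ArchetypeSpec(label, curve, mean_bout_length_night=700.0,
                         bout_rate_night=2.0, latency_lights_off=5400.0,
                         anticipation_ramp=0.0, awake_speed_mean=3.0)


def archetype_morning_sleep(label: str = "groupB") -> ArchetypeSpec:
    """High-sleep phenotype: short lights-off latency plus a morning sleep bump."""
    curve = np.concatenate([
        np.linspace(0.9, 0.4, 240),         # morning sleep bout after lights-on
        np.full(480, 0.25),
        np.full(720, 0.9),                  # strong night sleep
    ])
    return ArchetypeSpec(label, curve, mean_bout_length_night=2400.0,
                         bout_rate_night=8.0, latency_lights_off=400.0,
                         anticipation_ramp=0.0, awake_speed_mean=2.0)


def write_tracks(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tracks(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_erg(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_erg(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    df["is_control"] = df["is_control"].astype(bool)
    return df
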