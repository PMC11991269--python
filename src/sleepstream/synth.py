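"""Synthetic overnight recordings with stage-conditional physiology.

The generator has two layers.  :func:`simulate_hypnogram` draws a semi-Markov
stage sequence: after a wake prologue, episodes alternate with stage weights
tilted across the night (deep sleep concentrated early, REM late, light sleep
about half of sleep) and episode lengths drawn from stage-specific
exponential laws.  :func:`simulate_signals` then renders 1 Hz heart rate, RR
intervals and 3-axis acceleration conditioned on the stage sequence:

* HR is lowest and most stable in deep sleep, wake-like and variable in REM,
  with AR(1) noise and a smooth cross-fade at stage boundaries;
* RR follows ``60000 / HR`` plus beat-to-beat jitter whose scale sets the
  measured SDNN regime (highest in REM);
* acceleration is a constant gravity vector plus sensor noise and
  Poisson-timed movement bursts, frequent in wake and absent in REM (atonia).

Everything is deterministic given a seed.  The generator targets the feature
space the rule cascade reads; it does not model respiratory sinus arrhythmia
spectra or other fine HRV structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter1d

from .errors import ConfigError, DataError
from .signal_io import STAGES, Hypnogram, Recording

_STAGE_SET = set(STAGES)


@dataclass(frozen=True)
class NightConfig:
    """Stage-architecture parameters of a simulated night.

    Targets follow adult sleep structure: stage fractions are occupancies of
    the post-prologue period, chosen so that as fractions *of sleep* light is
    about half, deep lands in 15-20% (concentrated early in the night) and
    REM in 20-25% (concentrated late); the remainder is intra-sleep wake.
    """

    duration: int = 8 * 3600  # s
    light_frac: float = 0.51
    deep_frac: float = 0.17
    rem_frac: float = 0.22
    wake_prologue: int = 900  # s awake before sleep onset
    mean_episode: dict[str, float] = field(
        default_factory=lambda: {"WAKE": 180.0, "LIGHT": 1200.0, "DEEP": 900.0, "REM": 1080.0}
    )
    min_episode: int = 60  # s
    deep_early_bias: float = 1.0  # 0 = flat, 1 = weight 2(1-u) across sleep
    rem_late_bias: float = 1.0  # 0 = flat, 1 = weight 2u

    def __post_init__(self) -> None:
        if self.duration < 600:
            raise ConfigError("duration must be >= 600 s")
        fracs = (self.light_frac, self.deep_frac, self.rem_frac)
        if any(not 0.0 <= f <= 1.0 for f in fracs) or sum(fracs) > 1.0:
            raise ConfigError("stage fractions must lie in [0, 1] and sum to <= 1")
        if not 0 <= self.wake_prologue < self.duration:
            raise ConfigError("wake_prologue must fit inside the night")
        if set(self.mean_episode) != _STAGE_SET:
            raise ConfigError(f"mean_episode must cover exactly {sorted(_STAGE_SET)}")

    @property
    def wake_frac(self) -> float:
        return 1.0 - self.light_frac - self.deep_frac - self.rem_frac


@dataclass(frozen=True)
class PhysioConfig:
    """Stage-conditional signal parameters.

    Defaults are simulator conventions consistent with the qualitative
    physiology the cascade exploits (deep HR lowest and most stable, REM HR
    wake-like with the highest SDNN, movement essentially absent in REM),
    not measurements of any real cohort.
    """

    hr_mean: dict[str, float] = field(
        default_factory=lambda: {"WAKE": 72.0, "LIGHT": 60.0, "DEEP": 52.0, "REM": 68.0}
    )
    hr_sd: dict[str, float] = field(
        default_factory=lambda: {"WAKE": 6.0, "LIGHT": 3.0, "DEEP": 1.5, "REM": 5.0}
    )
    sdnn: dict[str, float] = field(
        default_factory=lambda: {"WAKE": 30.0, "LIGHT": 40.0, "DEEP": 20.0, "REM": 90.0}
    )
    movement_rate: dict[str, float] = field(  # bursts per minute
        default_factory=lambda: {"WAKE": 6.0, "LIGHT": 0.5, "DEEP": 0.1, "REM": 0.02}
    )
    ar_coef: float = 0.9  # AR(1) coefficient of the HR noise
    crossfade: int = 30  # s of physiological blending at stage boundaries
    acc_noise_sd: float = 0.005  # g per axis
    burst_amp: float = 0.3  # g per axis during a movement burst
    burst_len: tuple[int, int] = (2, 6)  # s, inclusive-exclusive range

    def __post_init__(self) -> None:
        for name in ("hr_mean", "hr_sd", "sdnn", "movement_rate"):
            if set(getattr(self, name)) != _STAGE_SET:
                raise ConfigError(f"{name} must cover exactly {sorted(_STAGE_SET)}")
        hm = self.hr_mean
        if not hm["DEEP"] < hm["LIGHT"] < hm["REM"] < hm["WAKE"]:
            raise ConfigError("need hr_mean DEEP < LIGHT < REM < WAKE")
        if self.hr_sd["DEEP"] > min(self.hr_sd.values()):
            raise ConfigError("DEEP must have the smallest hr_sd")
        if self.movement_rate["REM"] > min(self.movement_rate.values()):
            raise ConfigError("REM movement rate must be the minimum (atonia)")
        if not 0.0 <= self.ar_coef < 1.0:
            raise ConfigError("ar_coef must lie in [0, 1)")

    @classmethod
    def default(cls) -> "PhysioConfig":
        return cls()

    @classmethod
    def exaggerated(cls) -> "PhysioConfig":
        """Widely separated stage regimes: HR means >= 4 sd apart, REM SDNN at
        least twice any non-REM SDNN, and movement confined to wake.  Used to
        test that the cascade recovers the generating hypnogram when the
        feature space is cleanly separable."""
        return cls(
            hr_mean={"WAKE": 80.0, "LIGHT": 64.0, "DEEP": 50.0, "REM": 72.0},
            hr_sd={"WAKE": 2.0, "LIGHT": 2.0, "DEEP": 1.0, "REM": 2.0},
            sdnn={"WAKE": 30.0, "LIGHT": 35.0, "DEEP": 15.0, "REM": 100.0},
            movement_rate={"WAKE": 6.0, "LIGHT": 0.0, "DEEP": 0.0, "REM": 0.0},
        )


def simulate_hypnogram(cfg: NightConfig, seed) -> Hypnogram:
    """Draw one night's stage sequence as a semi-Markov chain.

    Episode stages are sampled with weights proportional to
    ``target_fraction / mean_episode`` so long-run occupancy matches the
    configured proportions, tilted linearly across the sleep period so deep
    sleep concentrates early and REM late.  A draw equal to the current
    stage simply extends the ongoing episode, which keeps the occupancy
    targets unbiased.
    """
    rng = np.random.default_rng(seed)
    order = ("WAKE", "LIGHT", "DEEP", "REM")
    base = {
        "WAKE": cfg.wake_frac / cfg.mean_episode["WAKE"],
        "LIGHT": cfg.light_frac / cfg.mean_episode["LIGHT"],
        "DEEP": cfg.deep_frac / cfg.mean_episode["DEEP"],
        "REM": cfg.rem_frac / cfg.mean_episode["REM"],
    }
    stages = ["WAKE"] * cfg.wake_prologue
    sleep_len = cfg.duration - cfg.wake_prologue
    t = cfg.wake_prologue
    while t < cfg.duration:
        u = (t - cfg.wake_prologue) / sleep_len
        tilt = {
            "WAKE": 1.0,
            "LIGHT": 1.0,
            "DEEP": max(0.0, 1.0 + cfg.deep_early_bias * (1.0 - 2.0 * u)),
            "REM": max(0.0, 1.0 + cfg.rem_late_bias * (2.0 * u - 1.0)),
        }
        weights = np.array([base[s] * tilt[s] for s in order])
        if weights.sum() <= 0:
            raise ConfigError("stage weights vanished; infeasible proportions")
        stage = order[rng.choice(4, p=weights / weights.sum())]
        length = max(cfg.min_episode, int(rng.exponential(cfg.mean_episode[stage])))
        stages.extend([stage] * min(length, cfg.duration - t))
        t += length
    return Hypnogram(start_time=0, stages=np.asarray(stages), source="medical")


def _stage_series(stages: np.ndarray, table: dict[str, float]) -> np.ndarray:
    out = np.empty(stages.size)
    for s, v in table.items():
        out[stages == s] = v
    return out


def simulate_signals(hyp: Hypnogram, cfg: PhysioConfig, seed) -> Recording:
    """Render stage-conditional 1 Hz HR / RR / acceleration for a hypnogram."""
    unknown = set(np.unique(hyp.stages)) - _STAGE_SET
    if unknown:
        raise DataError(f"unknown stage labels {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    stages = hyp.stages
    n = stages.size

    mean = _stage_series(stages, cfg.hr_mean)
    sd = _stage_series(stages, cfg.hr_sd)
    sdnn = _stage_series(stages, cfg.sdnn)
    if cfg.crossfade > 1 and n > 1:
        mean = uniform_filter1d(mean, cfg.crossfade, mode="nearest")
        sd = uniform_filter1d(sd, cfg.crossfade, mode="nearest")
        sdnn = uniform_filter1d(sdnn, cfg.crossfade, mode="nearest")

    # AR(1) noise with stationary per-second sd tracking the stage regime
    z = rng.standard_normal(n)
    noise = np.empty(n)
    noise[0] = sd[0] * z[0]
    scale = np.sqrt(1.0 - cfg.ar_coef**2)
    for t in range(1, n):
        noise[t] = cfg.ar_coef * noise[t - 1] + scale * sd[t] * z[t]
    hr = np.clip(mean + noise, 25.0, 240.0)

    rr = np.clip(60000.0 / hr + rng.standard_normal(n) * sdnn, 250.0, 2900.0)

    acc = np.array([0.0, 0.0, 1.0]) + rng.normal(0.0, cfg.acc_noise_sd, size=(n, 3))
    rate_per_s = _stage_series(stages, cfg.movement_rate) / 60.0
    starts = rng.random(n) < rate_per_s
    lengths = rng.integers(cfg.burst_len[0], cfg.burst_len[1], size=n)
    burst = np.zeros(n, dtype=bool)
    for t in np.flatnonzero(starts):
        # bursts never cross a stage boundary (atonia stages stay still)
        end = min(n, t + int(lengths[t]))
        for s in range(t, end):
            if stages[s] != stages[t]:
                break
            burst[s] = True
    n_burst = int(np.count_nonzero(burst))
    acc[burst] += rng.normal(0.0, cfg.burst_amp, size=(n_burst, 3))

    return Recording(
        start_time=hyp.start_time,
        hr=hr,
        rr=rr,
        acc=acc,
        subject_id="synthetic",
    )


def simulate_night(
    night_cfg: NightConfig, physio_cfg: PhysioConfig, seed
) -> tuple[Recording, Hypnogram]:
    """Simulate one full night: (Recording, reference Hypnogram), shared seed."""
    ss = np.random.SeedSequence(seed)
    hyp_seed, sig_seed = ss.spawn(2)
    hyp = simulate_hypnogram(night_cfg, hyp_seed)
    rec = simulate_signals(hyp, physio_cfg, sig_seed)
    return rec, hyp
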