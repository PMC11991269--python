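"""The two on-the-fly sleep-stage classifiers.

Both variants share the same skeleton: the subject is assumed awake when the
recording starts; the algorithm watches for the physiological heart-rate fall
and subsequent stabilization that marks sleep onset; from the onset second
onward a short-circuiting rule cascade labels every second as WAKE, DEEP, REM
or LIGHT from causal window statistics:

    IF   a large enough portion of HR is above hr_th
         AND a large enough portion of RR is below rr_th
         AND (motion-aware only) there are enough movements      -> WAKE
    ELIF the std of smoothed HR inside the window is below std_th -> DEEP
    ELIF the SDNN clause fires AND movements are minimal          -> REM
    ELSE                                                          -> LIGHT

The motion-aware variant's REM clause requires a large enough portion of the
per-second SDNN above one threshold together with near-absent movement
(muscle atonia); the accelerometer-free variant replaces it with a
two-threshold SDNN clause.  DEEP and REM transitions are guarded by dwell
times (``x3`` / ``x5``): the candidate rule must have held for that many
consecutive seconds before the transition is admitted, otherwise the previous
label is held.

Two execution paths are provided: :func:`score_recording` (vectorized batch
features + sequential cascade) and the incremental :func:`step` /
:class:`ScorerState` interface.  Both evaluate identical window statistics,
so folding ``step`` over a recording reproduces ``score_recording``
element-wise.
"""

from __future__ import annotations

import dataclasses
import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import yaml

from .errors import ConfigError, DataError
from .features import (
    FeatureFrame,
    extract_features,
    moving_average,
    trailing_std,
)
from .signal_io import HR_RANGE, RR_RANGE, STAGES, Hypnogram, Recording, align_hypnograms

logger = logging.getLogger(__name__)

W, L, D, R = 0, 1, 2, 3
_STAGE_ARRAY = np.asarray(STAGES)

VARIANTS = ("motion_aware", "hr_only")


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class OnsetConfig:
    """Sleep-onset detector parameters.

    The wake baseline is the median smoothed HR over the first
    ``baseline_win`` seconds; onset is the first second where smoothed HR has
    fallen ``drop_delta`` bpm below that baseline *and* the sample std of
    smoothed HR over the trailing ``stab_dur`` seconds is below ``stab_tol``
    (the "following HR stabilization").
    """

    baseline_win: int = 300  # s
    drop_delta: float = 8.0  # bpm
    stab_tol: float = 1.5  # bpm
    stab_dur: int = 120  # s

    def __post_init__(self) -> None:
        if min(self.baseline_win, self.drop_delta, self.stab_tol, self.stab_dur) <= 0:
            raise ConfigError("all OnsetConfig fields must be positive")


def _check_common(cfg) -> None:
    if cfg.win_size < 2:
        raise ConfigError("win_size must be >= 2")
    if cfg.smooth_win < 1 or cfg.sdnn_win < 2:
        raise ConfigError("smooth_win must be >= 1 and sdnn_win >= 2")
    for name in ("hr_th", "rr_th", "std_th"):
        if getattr(cfg, name) <= 0:
            raise ConfigError(f"{name} must be > 0")
    for name in ("x1", "x2"):
        if not 0.0 <= getattr(cfg, name) <= 1.0:
            raise ConfigError(f"{name} must lie in [0, 1]")


@dataclass(frozen=True)
class StagingConfig:
    """Parameters of the motion-aware cascade.

    ``win_size``, ``hr_th``, ``rr_th``, ``acc_th``, ``std_th`` and the five
    ``x`` parameters are the cascade's conventional tunables: ``x1``/``x2``
    the required HR/RR exceedance fractions for WAKE, ``x3``/``x5`` the
    minimum dwell (s) before a DEEP/REM transition, ``x4`` the required SDNN
    exceedance fraction for REM.  ``sdnn_th`` is the SDNN magnitude the REM
    rule compares against, ``movement_min``/``movement_max`` the movement
    counts meaning "enough movements" (WAKE) and "movements minimized" (REM).

    The shipped default values are calibration artifacts: they were produced
    by :func:`calibrate` on synthetic nights with the default physiology and
    carry no claim about any real cohort.  Re-calibrate on labelled data
    before use on real recordings.
    """

    win_size: int = 90  # s, evaluation window
    hr_th: float = 64.0  # bpm
    rr_th: float = 900.0  # ms
    acc_th: float = 0.05  # g, per-second first-difference magnitude
    std_th: float = 2.0  # bpm, smoothed-HR std below which DEEP fires
    x1: float = 0.3  # fraction of window with hr > hr_th
    x2: float = 0.4  # fraction of window with rr < rr_th
    x3: int = 30  # s, DEEP dwell
    x4: float = 0.4  # fraction of window with sdnn > sdnn_th
    x5: int = 30  # s, REM dwell
    smooth_win: int = 3  # s, HR moving-average span
    sdnn_win: int = 60  # s, per-second SDNN support
    sdnn_th: float = 65.0  # ms
    movement_min: int = 3  # counts, WAKE "enough movements"
    movement_max: int = 1  # counts, REM "movements minimized"
    onset: OnsetConfig = field(default_factory=OnsetConfig)

    def __post_init__(self) -> None:
        _check_common(self)
        if self.acc_th <= 0 or self.sdnn_th <= 0:
            raise ConfigError("acc_th and sdnn_th must be > 0")
        if not 0.0 <= self.x4 <= 1.0:
            raise ConfigError("x4 must lie in [0, 1]")
        if self.x3 < 0 or self.x5 < 0:
            raise ConfigError("dwell times x3/x5 must be >= 0")
        if self.movement_min < 0 or self.movement_max < 0:
            raise ConfigError("movement counts must be >= 0")


@dataclass(frozen=True)
class HrOnlyConfig:
    """Parameters of the accelerometer-free cascade.

    The WAKE rule drops the movement clause; the REM rule requires a large
    enough portion of the SDNN above ``sdnn_th1`` *and* a large enough
    portion above ``sdnn_th2`` (fractions ``f1`` / ``f2``).  Defaults are
    synthetic-night calibration artifacts, as for :class:`StagingConfig`.
    """

    win_size: int = 90
    hr_th: float = 68.0
    rr_th: float = 900.0
    std_th: float = 2.0
    x1: float = 0.5
    x2: float = 0.4
    smooth_win: int = 5
    sdnn_win: int = 60
    sdnn_th1: float = 50.0  # ms
    sdnn_th2: float = 70.0  # ms
    f1: float = 0.4
    f2: float = 0.3
    min_dwell_deep: int = 60  # s
    min_dwell_rem: int = 60  # s
    onset: OnsetConfig = field(default_factory=OnsetConfig)

    def __post_init__(self) -> None:
        _check_common(self)
        if not 0.0 < self.sdnn_th1 <= self.sdnn_th2:
            raise ConfigError("need 0 < sdnn_th1 <= sdnn_th2")
        for name in ("f1", "f2"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1]")
        if self.min_dwell_deep < 0 or self.min_dwell_rem < 0:
            raise ConfigError("dwell times must be >= 0")


def _variant_of(cfg) -> str:
    return "motion_aware" if isinstance(cfg, StagingConfig) else "hr_only"


def _check_variant(cfg, variant: str) -> None:
    if variant not in VARIANTS:
        raise ConfigError(f"variant must be one of {VARIANTS}, got {variant!r}")
    if _variant_of(cfg) != variant:
        raise ConfigError(
            f"config of type {type(cfg).__name__} does not match variant {variant!r}"
        )


def _dwells(cfg) -> tuple[int, int]:
    if isinstance(cfg, StagingConfig):
        return cfg.x3, cfg.x5
    return cfg.min_dwell_deep, cfg.min_dwell_rem


def save_config(cfg, path) -> None:
    """Write a staging config as YAML (nested onset block, variant tag)."""
    payload = dataclasses.asdict(cfg)
    payload["variant"] = _variant_of(cfg)
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)


def load_config(path):
    """Load a YAML staging config written by :func:`save_config`."""
    with open(path, encoding="utf-8") as fh:
        payload = yaml.safe_load(fh)
    if not isinstance(payload, dict):
        raise ConfigError(f"config file {path} does not hold a mapping")
    variant = payload.pop("variant", None)
    onset = OnsetConfig(**payload.pop("onset", {}))
    cls = {"motion_aware": StagingConfig, "hr_only": HrOnlyConfig}.get(
        variant, StagingConfig if "acc_th" in payload else HrOnlyConfig
    )
    try:
        return cls(onset=onset, **payload)
    except TypeError as exc:
        raise ConfigError(f"bad config file {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# sleep onset


def _onset_from_smoothed(smoothed: np.ndarray, ocfg: OnsetConfig) -> int | None:
    n = smoothed.size
    start = max(ocfg.baseline_win, ocfg.stab_dur - 1)
    if n <= start:
        return None
    baseline = np.median(smoothed[: ocfg.baseline_win])
    stab = trailing_std(smoothed, ocfg.stab_dur)
    cond = (smoothed <= baseline - ocfg.drop_delta) & (stab < ocfg.stab_tol)
    cond[:start] = False
    hits = np.flatnonzero(cond)
    return int(hits[0]) if hits.size else None


def detect_sleep_onset(hr_prefix, cfg: OnsetConfig, smooth_win: int) -> int | None:
    """Find the sleep-onset second in a causal HR prefix, or ``None``.

    Onset is the first second ``t`` at which the moving-average HR has
    dropped ``drop_delta`` bpm below the wake baseline (median smoothed HR
    over the first ``baseline_win`` seconds) and the smoothed HR has
    stabilized: its sample std over the trailing ``stab_dur`` seconds is
    below ``stab_tol``.  A prefix shorter than the baseline window yields
    ``None`` (insufficient evidence), not an error.
    """
    hr = np.asarray(hr_prefix, dtype=float)
    if hr.size == 0:
        raise DataError("empty HR prefix")
    if hr.size < cfg.baseline_win:
        return None
    return _onset_from_smoothed(moving_average(hr, smooth_win), cfg)


# ---------------------------------------------------------------------------
# cascade state machine


@dataclass
class ScorerState:
    """Mutable state of the streaming scorer.

    Holds the current stage, onset status, dwell run-lengths and the sample
    history buffers needed to recompute every window statistic causally.
    """

    asleep: bool = False
    onset_index: int | None = None
    stage: int = W
    seconds_in_stage: int = 0
    deep_run: int = 0
    rem_run: int = 0
    n: int = 0
    baseline: float | None = None
    last_frame: FeatureFrame | None = None
    _hr: list = field(default_factory=list, repr=False)
    _rr: list = field(default_factory=list, repr=False)
    _smoothed: list = field(default_factory=list, repr=False)
    _sdnn: list = field(default_factory=list, repr=False)
    _moveflags: list = field(default_factory=list, repr=False)
    _acc_prev: np.ndarray | None = field(default=None, repr=False)

    @property
    def current_stage(self) -> str:
        return STAGES[self.stage]


def _advance(state: ScorerState, wake: bool, deep: bool, rem: bool, x3: int, x5: int) -> int:
    """One cascade decision with dwell hysteresis; updates ``state`` in place."""
    state.deep_run = state.deep_run + 1 if deep else 0
    state.rem_run = state.rem_run + 1 if rem else 0
    prev = state.stage
    if wake:
        new = W
    elif deep:
        new = D if (prev == D or state.deep_run >= x3) else prev
    elif rem:
        new = R if (prev == R or state.rem_run >= x5) else prev
    else:
        new = L
    if new == prev:
        state.seconds_in_stage += 1
    else:
        logger.debug(
            "t=%d transition %s -> %s", state.n - 1, STAGES[prev], STAGES[new]
        )
        state.seconds_in_stage = 1
    state.stage = new
    return new


def classify_second_motion_aware(
    frame: FeatureFrame, state: ScorerState, cfg: StagingConfig
) -> str:
    """Label one second with the motion-aware cascade (subject already asleep)."""
    wake = (
        frame.frac_hr_above >= cfg.x1
        and frame.frac_rr_below >= cfg.x2
        and frame.movement_count >= cfg.movement_min
    )
    deep = frame.smoothed_hr_std < cfg.std_th
    rem = frame.frac_sdnn_above >= cfg.x4 and frame.movement_count <= cfg.movement_max
    return STAGES[_advance(state, wake, deep, rem, cfg.x3, cfg.x5)]


def classify_second_hr_only(
    frame: FeatureFrame, state: ScorerState, cfg: HrOnlyConfig
) -> str:
    """Label one second with the accelerometer-free cascade."""
    wake = frame.frac_hr_above >= cfg.x1 and frame.frac_rr_below >= cfg.x2
    deep = frame.smoothed_hr_std < cfg.std_th
    rem = frame.frac_sdnn_above_1 >= cfg.f1 and frame.frac_sdnn_above_2 >= cfg.f2
    return STAGES[
        _advance(state, wake, deep, rem, cfg.min_dwell_deep, cfg.min_dwell_rem)
    ]


# ---------------------------------------------------------------------------
# incremental interface


def _validate_sample(hr: float, rr: float) -> None:
    if not HR_RANGE[0] < hr < HR_RANGE[1]:
        raise DataError(f"hr sample {hr!r} outside {HR_RANGE}")
    if not RR_RANGE[0] < rr < RR_RANGE[1]:
        raise DataError(f"rr sample {rr!r} outside {RR_RANGE}")


def step(state: ScorerState, sample, cfg, variant: str = "motion_aware") -> tuple[ScorerState, str]:
    """Consume one second of data and emit exactly one stage label.

    ``sample`` is ``(hr_bpm, rr_ms, acc_xyz)``; the acceleration vector is
    ignored by the ``hr_only`` variant but may still be supplied.  The state
    is updated in place and returned for fold-style use.  Labels already
    emitted are never revised — the window statistics evaluated here are
    identical to the batch path's, so folding ``step`` over a recording
    reproduces :func:`score_recording` element-wise.
    """
    _check_variant(cfg, variant)
    hr, rr, acc = float(sample[0]), float(sample[1]), sample[2]
    _validate_sample(hr, rr)
    t = state.n
    state._hr.append(hr)
    state._rr.append(rr)
    hr_arr = np.asarray(state._hr)
    rr_arr = np.asarray(state._rr)

    sw = cfg.smooth_win
    state._smoothed.append(float(np.mean(hr_arr[max(0, t - sw + 1) :])))
    if t == 0:
        state._sdnn.append(0.0)
    else:
        lo = max(0, t - cfg.sdnn_win + 1)
        state._sdnn.append(float(np.std(rr_arr[lo:], ddof=1)))
    if variant == "motion_aware":
        a = np.asarray(acc, dtype=float)
        if state._acc_prev is None:
            state._moveflags.append(False)
        else:
            d = a - state._acc_prev
            state._moveflags.append(bool(np.sqrt((d * d).sum()) > cfg.acc_th))
        state._acc_prev = a
    state.n = t + 1

    smoothed = np.asarray(state._smoothed)
    if not state.asleep:
        ocfg = cfg.onset
        start = max(ocfg.baseline_win, ocfg.stab_dur - 1)
        if state.baseline is None and t + 1 >= ocfg.baseline_win:
            state.baseline = float(np.median(smoothed[: ocfg.baseline_win]))
        if (
            t >= start
            and state.baseline is not None
            and smoothed[t] <= state.baseline - ocfg.drop_delta
            and np.std(smoothed[t - ocfg.stab_dur + 1 :], ddof=1) < ocfg.stab_tol
        ):
            state.asleep = True
            state.onset_index = t
            logger.debug("t=%d sleep onset detected", t)
        else:
            state.last_frame = None
            return state, STAGES[W]

    win = cfg.win_size
    lo = max(0, t - win + 1)
    wl = t + 1 - lo
    if t == 0:
        smoothed_std = 0.0
    else:
        slo = max(0, t - win + 1)
        smoothed_std = float(np.std(smoothed[slo:], ddof=1))
    frame = FeatureFrame(
        t=t,
        smoothed_hr_std=smoothed_std,
        frac_hr_above=int(np.count_nonzero(hr_arr[lo:] > cfg.hr_th)) / wl,
        frac_rr_below=int(np.count_nonzero(rr_arr[lo:] < cfg.rr_th)) / wl,
        hr_window=hr_arr[lo:],
        rr_window=rr_arr[lo:],
        sdnn_window=np.asarray(state._sdnn[lo:]),
    )
    sdnn_win_vals = frame.sdnn_window
    if variant == "motion_aware":
        frame.movement_count = int(np.count_nonzero(state._moveflags[lo:]))
        frame.frac_sdnn_above = int(np.count_nonzero(sdnn_win_vals > cfg.sdnn_th)) / wl
        label = classify_second_motion_aware(frame, state, cfg)
    else:
        frame.frac_sdnn_above_1 = int(np.count_nonzero(sdnn_win_vals > cfg.sdnn_th1)) / wl
        frame.frac_sdnn_above_2 = int(np.count_nonzero(sdnn_win_vals > cfg.sdnn_th2)) / wl
        label = classify_second_hr_only(frame, state, cfg)
    state.last_frame = frame
    return state, label


def stream_score(rec: Recording, cfg, variant: str = "motion_aware") -> Hypnogram:
    """Score a recording by folding :func:`step` over its samples."""
    state = ScorerState()
    labels = np.empty(len(rec), dtype=object)
    for t in range(len(rec)):
        state, labels[t] = step(state, (rec.hr[t], rec.rr[t], rec.acc[t]), cfg, variant)
    return Hypnogram(rec.start_time, labels.astype("U5"), source="algorithm")


# ---------------------------------------------------------------------------
# batch interface


def score_recording(rec: Recording, cfg, variant: str = "motion_aware") -> Hypnogram:
    """Score a full recording; the label at ``t`` uses samples up to ``t`` only."""
    _check_variant(cfg, variant)
    if len(rec) < 1:
        raise DataError("cannot score an empty recording")
    feats = extract_features(rec, cfg)
    labels = np.full(len(rec), W, dtype=np.int64)
    onset = _onset_from_smoothed(feats["smoothed_hr"], cfg.onset)
    if onset is None:
        return Hypnogram(rec.start_time, _STAGE_ARRAY[labels], source="algorithm")

    x3, x5 = _dwells(cfg)
    if variant == "motion_aware":
        wake_arr = (
            (feats["frac_hr_above"] >= cfg.x1)
            & (feats["frac_rr_below"] >= cfg.x2)
            & (feats["movement_count"] >= cfg.movement_min)
        )
        rem_arr = (feats["frac_sdnn_above"] >= cfg.x4) & (
            feats["movement_count"] <= cfg.movement_max
        )
    else:
        wake_arr = (feats["frac_hr_above"] >= cfg.x1) & (feats["frac_rr_below"] >= cfg.x2)
        rem_arr = (feats["frac_sdnn_above_1"] >= cfg.f1) & (
            feats["frac_sdnn_above_2"] >= cfg.f2
        )
    deep_arr = feats["smoothed_hr_std"] < cfg.std_th

    state = ScorerState(asleep=True, onset_index=onset)
    wake_l, deep_l, rem_l = wake_arr.tolist(), deep_arr.tolist(), rem_arr.tolist()
    for t in range(onset, len(rec)):
        state.n = t + 1
        labels[t] = _advance(state, wake_l[t], deep_l[t], rem_l[t], x3, x5)
    return Hypnogram(rec.start_time, _STAGE_ARRAY[labels], source="algorithm")


# ---------------------------------------------------------------------------
# calibration


def balanced_accuracy(truth: Hypnogram, pred: Hypnogram) -> float:
    """Mean per-stage recall over the stages present in the truth hypnogram."""
    t, p = align_hypnograms(truth, pred)
    recalls = []
    for s in STAGES:
        mask = t.stages == s
        total = int(np.count_nonzero(mask))
        if total:
            recalls.append(int(np.count_nonzero(p.stages[mask] == s)) / total)
    return float(np.mean(recalls))


def config_grid(base, grid: dict[str, list]) -> list:
    """Expand a base config with per-field value lists into a full grid.

    Iteration order follows ``itertools.product`` over the dict's insertion
    order, which fixes the deterministic tie-break order of :func:`calibrate`.
    """
    if not grid:
        return [base]
    keys = list(grid)
    return [
        dataclasses.replace(base, **dict(zip(keys, combo)))
        for combo in itertools.product(*(grid[k] for k in keys))
    ]


def default_grid(base=None, variant: str = "motion_aware") -> list:
    """A modest starting grid around the shipped defaults.

    Sweeps the parameters that move recognition the most on synthetic nights:
    the moving-average span, the evaluation window, the DEEP std threshold,
    and (motion-aware) the REM SDNN fraction with both dwell times.
    """
    if base is None:
        base = StagingConfig() if variant == "motion_aware" else HrOnlyConfig()
    common = {
        "smooth_win": [3, 5, 15],
        "win_size": [90, 150],
        "std_th": [0.9, 1.2, 1.6, 2.0],
        "hr_th": [64.0, 68.0],
    }
    if variant == "motion_aware":
        return config_grid(base, {**common, "x4": [0.4], "x3": [30], "x5": [15, 30]})
    return config_grid(base, {**common, "f1": [0.4, 0.6], "min_dwell_rem": [15, 60]})


def calibrate(labelled, space, seed: int = 0, variant: str = "motion_aware"):
    """Pick the grid point with the highest mean balanced accuracy.

    ``labelled`` is a sequence of ``(Recording, Hypnogram)`` nights; ``space``
    a finite iterable of config objects.  The search is an exhaustive,
    fully deterministic sweep (``seed`` is accepted for API stability); ties
    resolve to the first grid point in iteration order.
    """
    nights = list(labelled)
    if not nights:
        raise ConfigError("calibrate needs at least one labelled night")
    space = list(space)
    if not space:
        raise ConfigError("empty parameter grid")
    best_cfg, best_score = None, -np.inf
    for cfg in space:
        scores = [
            balanced_accuracy(truth, score_recording(rec, cfg, variant))
            for rec, truth in nights
        ]
        mean_score = float(np.mean(scores))
        logger.debug("grid point %s -> balanced accuracy %.4f", cfg, mean_score)
        if mean_score > best_score:
            best_cfg, best_score = cfg, mean_score
    return best_cfg
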