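"""Causal feature extractors feeding the rule cascade.

Every extractor here is *trailing*: the value at second ``t`` depends only on
samples up to and including ``t``, with windows shrinking during warm-up.
This is what makes the classifier usable on-the-fly — output at ``t`` never
changes when later samples arrive.

The cascade consumes five per-second statistics:

* fraction of the last ``win_size`` HR samples strictly above ``hr_th``;
* fraction of the last ``win_size`` RR samples strictly below ``rr_th``;
* sample std of moving-average-smoothed HR over the last ``win_size`` s;
* fraction of the last ``win_size`` per-second SDNN values strictly above an
  SDNN threshold, where per-second SDNN is the sample std of the last
  ``sdnn_win`` RR values;
* number of "moving" seconds in the window, a second being moving when the
  first-difference magnitude of the acceleration vector exceeds ``acc_th``.

Standard deviations are sample (n-1) standard deviations throughout; SDNN is
conventionally a sample std.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from .errors import ConfigError, DataError
from .signal_io import Recording


@dataclass
class FeatureFrame:
    """Per-second feature snapshot consumed by the stage rules.

    Fraction fields for the motion-aware variant use ``frac_sdnn_above``; the
    accelerometer-free variant uses the two-threshold pair
    ``frac_sdnn_above_1`` / ``frac_sdnn_above_2`` and ignores movement.
    """

    t: int
    smoothed_hr_std: float
    frac_hr_above: float
    frac_rr_below: float
    movement_count: int = 0
    frac_sdnn_above: float = 0.0
    frac_sdnn_above_1: float = 0.0
    frac_sdnn_above_2: float = 0.0
    hr_window: np.ndarray | None = None
    rr_window: np.ndarray | None = None
    sdnn_window: np.ndarray | None = None


def _as_series(series) -> np.ndarray:
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise DataError("expected a non-empty 1-D sequence")
    return x


def moving_average(series, smooth_win: int) -> np.ndarray:
    """Trailing moving average with a shrinking warm-up window.

    ``out[t] = mean(series[max(0, t - smooth_win + 1) .. t])``.
    """
    x = _as_series(series)
    if smooth_win < 1:
        raise ConfigError("smooth_win must be >= 1")
    n = x.size
    out = np.empty(n)
    for t in range(min(smooth_win, n) - 1):
        out[t] = np.mean(x[: t + 1])
    if n >= smooth_win:
        out[smooth_win - 1 :] = sliding_window_view(x, smooth_win).mean(axis=-1)
    else:
        out[n - 1] = np.mean(x)
    return out


def trailing_std(series, win_size: int) -> np.ndarray:
    """Trailing sample standard deviation; ``out[0] = 0`` by convention."""
    x = _as_series(series)
    if win_size < 2:
        raise ConfigError("win_size must be >= 2")
    n = x.size
    out = np.empty(n)
    out[0] = 0.0
    for t in range(1, min(win_size, n) - 1):
        out[t] = np.std(x[: t + 1], ddof=1)
    if n >= win_size:
        out[win_size - 1 :] = sliding_window_view(x, win_size).std(axis=-1, ddof=1)
    elif n > 1:
        out[n - 1] = np.std(x, ddof=1)
    return out


def sdnn(rr_values) -> float:
    """SDNN: sample standard deviation of a block of RR (NN) intervals, ms."""
    x = _as_series(rr_values)
    if x.size < 2:
        raise DataError("SDNN requires at least two RR values")
    return float(np.std(x, ddof=1))


def exceedance_fraction(values, threshold: float, direction: str) -> float:
    """Fraction of values strictly above/below ``threshold``.

    Values exactly equal to the threshold are never counted.
    """
    x = _as_series(values)
    if direction == "above":
        count = int(np.count_nonzero(x > threshold))
    elif direction == "below":
        count = int(np.count_nonzero(x < threshold))
    else:
        raise ConfigError(f"direction must be 'above' or 'below', got {direction!r}")
    return count / x.size


def movement_flags(acc, acc_th: float) -> np.ndarray:
    """Boolean per-second movement flags for an ``(n, 3)`` acceleration array.

    Second ``t`` is moving when the Euclidean norm of ``acc[t] - acc[t-1]``
    strictly exceeds ``acc_th``; the first second has no predecessor and is
    never moving.  The first difference makes the statistic independent of
    wrist orientation (the static gravity component cancels).
    """
    a = np.asarray(acc, dtype=float)
    if a.ndim != 2 or a.shape[1] != 3 or a.shape[0] == 0:
        raise DataError("expected a non-empty (n, 3) acceleration array")
    d = np.diff(a, axis=0)
    mag = np.sqrt((d * d).sum(axis=1))
    return np.concatenate([[False], mag > acc_th])


def movement_activity(acc_window, acc_th: float) -> int:
    """Count of moving seconds within an acceleration window (>= 2 samples)."""
    a = np.asarray(acc_window, dtype=float)
    if a.ndim != 2 or a.shape[0] < 2:
        raise DataError("movement_activity requires at least two samples")
    return int(np.count_nonzero(movement_flags(a, acc_th)))


def _trailing_count(mask: np.ndarray, win_size: int) -> np.ndarray:
    """Trailing count of True values over a (shrinking at warm-up) window."""
    c = np.cumsum(mask.astype(np.int64))
    out = c.copy()
    if mask.size > win_size:
        out[win_size:] = c[win_size:] - c[:-win_size]
    return out


def _window_lengths(n: int, win_size: int) -> np.ndarray:
    return np.minimum(np.arange(n) + 1, win_size)


def extract_features(rec: Recording, cfg) -> dict[str, np.ndarray]:
    """Compute the full per-second feature set for a recording, vectorized.

    ``cfg`` is a staging config; the presence of an ``acc_th`` attribute
    selects the motion-aware feature set, otherwise the accelerometer-free
    set with its two SDNN thresholds.  This is the definitional
    recompute-from-window implementation against which the incremental
    scorer state is validated.
    """
    n = len(rec)
    wl = _window_lengths(n, cfg.win_size).astype(float)
    smoothed = moving_average(rec.hr, cfg.smooth_win)
    feats: dict[str, np.ndarray] = {
        "smoothed_hr": smoothed,
        "smoothed_hr_std": trailing_std(smoothed, cfg.win_size),
        "sdnn": trailing_std(rec.rr, cfg.sdnn_win),
        "frac_hr_above": _trailing_count(rec.hr > cfg.hr_th, cfg.win_size) / wl,
        "frac_rr_below": _trailing_count(rec.rr < cfg.rr_th, cfg.win_size) / wl,
    }
    if hasattr(cfg, "acc_th"):
        flags = movement_flags(rec.acc, cfg.acc_th)
        feats["movement_count"] = _trailing_count(flags, cfg.win_size)
        feats["frac_sdnn_above"] = (
            _trailing_count(feats["sdnn"] > cfg.sdnn_th, cfg.win_size) / wl
        )
    else:
        feats["frac_sdnn_above_1"] = (
            _trailing_count(feats["sdnn"] > cfg.sdnn_th1, cfg.win_size) / wl
        )
        feats["frac_sdnn_above_2"] = (
            _trailing_count(feats["sdnn"] > cfg.sdnn_th2, cfg.win_size) / wl
        )
    return feats


def features_to_frame(feats: dict[str, np.ndarray]) -> pd.DataFrame:
    """Debug dump of a feature dict as a DataFrame with a ``t`` column."""
    n = len(next(iter(feats.values())))
    out = pd.DataFrame({"t": np.arange(n)})
    for key, values in feats.items():
        if key != "smoothed_hr":
            out[key] = values
    return out
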