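"""Second-by-second evaluation of a predicted hypnogram against a reference.

The evaluation suite mirrors how wearable sleep stagers are validated against
PSG: a 4x4 confusion matrix column-normalized per true stage, the binary
sleep--wake triple (sensitivity / precision / accuracy with SLEEP = LIGHT u
DEEP u REM as the positive class), signed sleep--wake pattern deltas (sleep
onset, final awakening, TST, WASO), and per-stage recognition latency.

Sign conventions: *advances* are positive when the algorithm event occurs
earlier than the medical one; latencies are reported as
``time(medical) - time(algorithm)``, so a positive latency also means the
algorithm anticipated the stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import AlignmentError, DataError, ParameterError
from .signal_io import STAGES, Hypnogram

SLEEP_STAGES = ("LIGHT", "DEEP", "REM")

#: How far (s) before a true episode start a matching predicted label may lie.
DEFAULT_MATCH_BACK = 300


def _stage_arrays(truth: Hypnogram, pred: Hypnogram) -> tuple[np.ndarray, np.ndarray]:
    if len(truth) != len(pred) or truth.start_time != pred.start_time:
        raise AlignmentError(
            "hypnograms must be aligned (same start and length) before evaluation; "
            "use align_hypnograms()"
        )
    return truth.stages, pred.stages


@dataclass
class StageConfusion:
    """4x4 stage confusion holding raw second counts (rows = predicted,
    columns = true stage); percentages are column-normalized so each defined
    column sums to 100."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (4, 4) or np.any(self.counts < 0):
            raise DataError("counts must be a non-negative 4x4 matrix")

    @property
    def column_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def defined_columns(self) -> np.ndarray:
        """Mask of true stages that actually occur; undefined columns are
        flagged here and hold NaN percentages, never silent zeros."""
        return self.column_totals > 0

    @property
    def percentages(self) -> np.ndarray:
        totals = self.column_totals.astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = 100.0 * self.counts / totals
        pct[:, ~self.defined_columns] = np.nan
        return pct

    def recall(self, stage: str) -> float:
        """Diagonal entry (%) for one true stage; NaN when the stage never occurs."""
        i = STAGES.index(stage)
        return float(self.percentages[i, i])

    def __add__(self, other: "StageConfusion") -> "StageConfusion":
        return StageConfusion(self.counts + other.counts)


@dataclass
class SleepWakeSummary:
    """Binary sleep--wake metrics (%) and signed pattern deltas (s)."""

    sensitivity: float
    precision: float
    accuracy: float
    onset_advance: float
    wake_advance: float
    tst_diff: float
    waso_diff: float


@dataclass
class StageLatency:
    """Per-stage mean recognition latency, ``time(medical) - time(algorithm)``.

    Stages with no matched episode carry NaN and a zero matched count —
    undefined, never silently zero.
    """

    mean_latency: dict[str, float] = field(default_factory=dict)
    episodes_matched: dict[str, int] = field(default_factory=dict)
    episodes_total: dict[str, int] = field(default_factory=dict)


def confusion_matrix(truth: Hypnogram, pred: Hypnogram) -> StageConfusion:
    """Count prediction/truth stage pairs second by second."""
    t, p = _stage_arrays(truth, pred)
    counts = np.zeros((4, 4), dtype=np.int64)
    for ci, cs in enumerate(STAGES):
        mask = t == cs
        for ri, rs in enumerate(STAGES):
            counts[ri, ci] = np.count_nonzero(p[mask] == rs)
    return StageConfusion(counts)


def _binary_counts(t: np.ndarray, p: np.ndarray) -> tuple[int, int, int, int]:
    t_sleep = np.isin(t, SLEEP_STAGES)
    p_sleep = np.isin(p, SLEEP_STAGES)
    tp = int(np.count_nonzero(t_sleep & p_sleep))
    fn = int(np.count_nonzero(t_sleep & ~p_sleep))
    fp = int(np.count_nonzero(~t_sleep & p_sleep))
    tn = int(np.count_nonzero(~t_sleep & ~p_sleep))
    return tp, fn, fp, tn


def sleep_wake_metrics(truth: Hypnogram, pred: Hypnogram) -> tuple[float, float, float]:
    """Sensitivity, precision and accuracy (%) with SLEEP as positive class.

    Undefined ratios (no sleep in truth, or no sleep predicted) come back as
    NaN with a warning rather than a silent zero.
    """
    t, p = _stage_arrays(truth, pred)
    tp, fn, fp, tn = _binary_counts(t, p)
    if tp + fn == 0:
        warnings.warn("no sleep seconds in truth: sensitivity undefined", stacklevel=2)
        sens = float("nan")
    else:
        sens = 100.0 * tp / (tp + fn)
    if tp + fp == 0:
        warnings.warn("no sleep seconds predicted: precision undefined", stacklevel=2)
        prec = float("nan")
    else:
        prec = 100.0 * tp / (tp + fp)
    acc = 100.0 * (tp + tn) / (tp + fn + fp + tn)
    return sens, prec, acc


def _onset_wakeup(stages: np.ndarray, side: str) -> tuple[int, int]:
    sleep = np.flatnonzero(np.isin(stages, SLEEP_STAGES))
    if sleep.size == 0:
        raise ParameterError(f"{side} hypnogram contains no sleep seconds")
    return int(sleep[0]), int(sleep[-1] + 1)


def sleep_wake_parameters(
    truth: Hypnogram, pred: Hypnogram
) -> tuple[float, float, float, float]:
    """Signed deltas (s): onset advance, wake-up advance, TST diff, WASO diff.

    Advances are ``truth_time - pred_time`` (positive = algorithm earlier);
    TST/WASO diffs are ``pred - truth``.
    """
    t, p = _stage_arrays(truth, pred)
    t_on, t_up = _onset_wakeup(t, "truth")
    p_on, p_up = _onset_wakeup(p, "pred")
    tst_t = int(np.count_nonzero(np.isin(t, SLEEP_STAGES)))
    tst_p = int(np.count_nonzero(np.isin(p, SLEEP_STAGES)))
    waso_t = int(np.count_nonzero(t[t_on:t_up] == "WAKE"))
    waso_p = int(np.count_nonzero(p[p_on:p_up] == "WAKE"))
    return (
        float(t_on - p_on),
        float(t_up - p_up),
        float(tst_p - tst_t),
        float(waso_p - waso_t),
    )


def _episodes(stages: np.ndarray, stage: str) -> list[tuple[int, int]]:
    """Maximal runs of ``stage`` as half-open ``(start, end)`` second spans."""
    mask = np.concatenate([[False], stages == stage, [False]])
    edges = np.flatnonzero(np.diff(mask.astype(np.int8)))
    return [(int(edges[i]), int(edges[i + 1])) for i in range(0, edges.size, 2)]


def stage_latency(
    truth: Hypnogram, pred: Hypnogram, match_back: int = DEFAULT_MATCH_BACK
) -> StageLatency:
    """Mean per-stage recognition latency over matched truth episodes.

    For each maximal truth episode of stage ``S`` starting at ``t0``, the
    first predicted ``S`` second inside ``[t0 - match_back, episode_end)`` is
    taken as the recognition time ``t1``; the episode contributes
    ``t0 - t1`` (positive = algorithm anticipated).  Episodes with no
    predicted ``S`` second in that span are excluded and counted.
    """
    t, p = _stage_arrays(truth, pred)
    out = StageLatency()
    for stage in STAGES:
        eps = _episodes(t, stage)
        latencies = []
        for t0, t_end in eps:
            lo = max(0, t0 - match_back)
            hits = np.flatnonzero(p[lo:t_end] == stage)
            if hits.size:
                latencies.append(t0 - (lo + int(hits[0])))
        out.episodes_total[stage] = len(eps)
        out.episodes_matched[stage] = len(latencies)
        out.mean_latency[stage] = (
            float(np.mean(latencies)) if latencies else float("nan")
        )
    return out


@dataclass
class NightReport:
    """Full evaluation of one night."""

    confusion: StageConfusion
    summary: SleepWakeSummary
    latency: StageLatency

    def to_dict(self) -> dict:
        return {
            "confusion_counts": self.confusion.counts.tolist(),
            "confusion_pct": self.confusion.percentages.tolist(),
            "stage_order": list(STAGES),
            "sleep_wake": vars(self.summary),
            "latency": {
                "mean_s": self.latency.mean_latency,
                "episodes_matched": self.latency.episodes_matched,
                "episodes_total": self.latency.episodes_total,
            },
        }


def evaluate_night(
    truth: Hypnogram, pred: Hypnogram, match_back: int = DEFAULT_MATCH_BACK
) -> NightReport:
    """Confusion matrix, sleep--wake triple, pattern deltas and latency."""
    sens, prec, acc = sleep_wake_metrics(truth, pred)
    on_adv, up_adv, tst_d, waso_d = sleep_wake_parameters(truth, pred)
    return NightReport(
        confusion=confusion_matrix(truth, pred),
        summary=SleepWakeSummary(sens, prec, acc, on_adv, up_adv, tst_d, waso_d),
        latency=stage_latency(truth, pred, match_back),
    )


def aggregate_nights(
    reports: list[NightReport],
) -> tuple[SleepWakeSummary, StageConfusion]:
    """Average sleep--wake summaries arithmetically; pool confusion counts.

    Confusion matrices are pooled by summing raw second counts *before*
    normalization, so long nights weigh proportionally to their duration.
    """
    if not reports:
        raise DataError("aggregate_nights needs at least one night")
    fields_ = (
        "sensitivity",
        "precision",
        "accuracy",
        "onset_advance",
        "wake_advance",
        "tst_diff",
        "waso_diff",
    )
    means = {
        f: float(np.mean([getattr(r.summary, f) for r in reports])) for f in fields_
    }
    pooled = StageConfusion(np.sum([r.confusion.counts for r in reports], axis=0))
    return SleepWakeSummary(**means), pooled
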