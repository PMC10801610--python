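"""Sequence-method baroreflex sensitivity and effectiveness.

The spontaneous sequence method scans the beat series for SBP *ramps*:
runs of three or more consecutive beats in which systolic pressure rises
(up ramp) or falls (down ramp) by at least a per-beat threshold.  A ramp
is an *effective* baroreflex event when the RR intervals, at some lag of
0-2 beats, change concordantly (lengthening for rising pressure,
shortening for falling) by at least an RR threshold per beat.

Baroreflex sensitivity (BRS, ms/mmHg) is the mean over effective
sequences of the least-squares slope of RR on SBP; the baroreflex
effectiveness index (BEI) is the fraction of ramps that are effective.
The per-beat thresholds (1 mmHg, 4 ms) follow common sequence-method
practice and are exposed as parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .beats import BeatSeries

DEFAULT_SBP_DELTA = 1.0   # mmHg per beat
DEFAULT_RR_DELTA = 4.0    # ms per beat
DEFAULT_MAX_LAG = 2       # beats
DEFAULT_MIN_LEN = 3       # beats per ramp


@dataclass
class Ramp:
    """A monotone SBP run of ``min_len`` or more consecutive beats."""

    direction: str                  # "up" or "down"
    beat_indices: np.ndarray        # consecutive, length >= 3
    sbp_values: np.ndarray

    def __post_init__(self) -> None:
        self.beat_indices = np.asarray(self.beat_indices, dtype=int)
        self.sbp_values = np.asarray(self.sbp_values, dtype=float)
        if self.direction not in ("up", "down"):
            raise ValueError("direction must be 'up' or 'down'")
        if len(self.beat_indices) < 3:
            raise ValueError("a ramp spans at least 3 beats")
        if np.any(np.diff(self.beat_indices) != 1):
            raise ValueError("ramp beats must be consecutive")
        d = np.diff(self.sbp_values)
        if self.direction == "up" and np.any(d <= 0):
            raise ValueError("up ramp must have strictly increasing SBP")
        if self.direction == "down" and np.any(d >= 0):
            raise ValueError("down ramp must have strictly decreasing SBP")


@dataclass
class ClassifiedRamp:
    """A ramp together with its effectiveness classification."""

    ramp: Ramp
    effective: bool
    lag: int | None = None          # lag of the matched RR response
    rr_values: np.ndarray | None = None
    slope: float | None = None      # ms/mmHg, filled by sequence_brs
    reason: str | None = None       # why ineffective, when applicable


@dataclass
class BaroreflexResult:
    """Sequence-method indices of one recording.

    BRS fields are NaN when no effective sequence exists in that
    direction; BEI fields are NaN when no ramps were detected in that
    direction.
    """

    brs_up: float = float("nan")
    brs_down: float = float("nan")
    brs_mean: float = float("nan")
    bei_up: float = float("nan")
    bei_down: float = float("nan")
    br_up: int = 0
    br_down: int = 0
    brx_up: int = 0
    brx_down: int = 0
    ramps: list = field(default_factory=list, repr=False)

    @property
    def defined(self) -> bool:
        """True when at least one ramp was found."""
        return (self.br_up + self.br_down + self.brx_up + self.brx_down) > 0


def detect_ramps(
    sbp: np.ndarray,
    min_len: int = DEFAULT_MIN_LEN,
    delta_thresh: float = DEFAULT_SBP_DELTA,
) -> list[Ramp]:
    """Find maximal monotone SBP runs with per-beat change >= threshold.

    Each beat-to-beat step of an up ramp satisfies
    ``sbp[i+1] - sbp[i] >= delta_thresh`` (``<= -delta_thresh`` for down
    ramps).  Ramps never share beats: when an up run turns directly into a
    down run, the turning beat belongs to the earlier ramp and the later
    run is trimmed, surviving only if it still spans ``min_len`` beats.
    """
    sbp = np.asarray(sbp, dtype=float)
    n = len(sbp)
    if n < min_len:
        return []
    steps = np.diff(sbp)
    labels = np.where(steps >= delta_thresh, 1, np.where(steps <= -delta_thresh, -1, 0))
    ramps: list[Ramp] = []
    last_used = -1  # last beat index already owned by a ramp
    i = 0
    while i < n - 1:
        lab = labels[i]
        if lab == 0:
            i += 1
            continue
        j = i
        while j < n - 1 and labels[j] == lab:
            j += 1
        # candidate spans beats [i, j]; trim the start past used beats
        start = max(i, last_used + 1)
        if j - start + 1 >= min_len:
            idx = np.arange(start, j + 1)
            ramps.append(Ramp(
                direction="up" if lab == 1 else "down",
                beat_indices=idx,
                sbp_values=sbp[idx],
            ))
            last_used = j
        i = j
    return ramps


def classify_ramp(
    ramp: Ramp,
    rr: np.ndarray,
    max_lag: int = DEFAULT_MAX_LAG,
    rr_delta_thresh: float = DEFAULT_RR_DELTA,
) -> ClassifiedRamp:
    """Decide whether the RR intervals respond concordantly to a ramp.

    For each lag ``k = 0..max_lag`` (first qualifying lag wins) the RR
    values at the ramp's beat indices shifted by ``k`` must change by at
    least ``rr_delta_thresh`` per beat in the ramp's direction.  A ramp
    whose shifted window runs past the end of the series at every lag is
    ineffective with reason ``"truncated"``.
    """
    rr = np.asarray(rr, dtype=float)
    n = len(rr)
    sign = 1.0 if ramp.direction == "up" else -1.0
    truncated_all = True
    for k in range(max_lag + 1):
        idx = ramp.beat_indices + k
        if idx[-1] >= n:
            continue
        truncated_all = False
        d = sign * np.diff(rr[idx])
        if np.all(d >= rr_delta_thresh):
            return ClassifiedRamp(ramp=ramp, effective=True, lag=k, rr_values=rr[idx])
    return ClassifiedRamp(
        ramp=ramp, effective=False,
        reason="truncated" if truncated_all else "discordant",
    )


def _slope(sbp: np.ndarray, rr: np.ndarray) -> float:
    """Least-squares slope of RR (ms) on SBP (mmHg)."""
    x = sbp - sbp.mean()
    denom = float(np.dot(x, x))
    if denom == 0.0:
        return float("nan")
    return float(np.dot(x, rr - rr.mean()) / denom)


def sequence_brs(
    classified: list[ClassifiedRamp],
    slope_method: str = "least_squares",
    min_correlation: float | None = None,
) -> BaroreflexResult:
    """Aggregate effective sequences into BRS/BEI indices.

    Per-sequence slope is the least-squares slope of the matched RR values
    on the ramp's SBP values (``slope_method="endpoint"`` uses the
    endpoint ratio instead; the two agree on collinear data).  BRS per
    direction is the mean of per-sequence slopes; ``brs_mean`` averages
    the directions that exist.  An optional minimum SBP-RR correlation
    filter (off by default) drops weakly linear sequences.
    """
    if slope_method not in ("least_squares", "endpoint"):
        raise ValueError("slope_method must be 'least_squares' or 'endpoint'")
    slopes: dict[str, list[float]] = {"up": [], "down": []}
    counts = {"up": [0, 0], "down": [0, 0]}  # [effective, ineffective]
    for cr in classified:
        direction = cr.ramp.direction
        if not cr.effective:
            counts[direction][1] += 1
            continue
        counts[direction][0] += 1
        sbp, rr = cr.ramp.sbp_values, cr.rr_values
        if min_correlation is not None:
            r = np.corrcoef(sbp, rr)[0, 1]
            if not np.isfinite(r) or abs(r) < min_correlation:
                continue
        if slope_method == "endpoint":
            cr.slope = float((rr[-1] - rr[0]) / (sbp[-1] - sbp[0]))
        else:
            cr.slope = _slope(sbp, rr)
        if np.isfinite(cr.slope):
            slopes[direction].append(cr.slope)

    def mean_or_nan(v: list[float]) -> float:
        return float(np.mean(v)) if v else float("nan")

    brs_up = mean_or_nan(slopes["up"])
    brs_down = mean_or_nan(slopes["down"])
    directional = [b for b in (brs_up, brs_down) if np.isfinite(b)]
    brs_mean = float(np.mean(directional)) if directional else float("nan")

    def bei(eff: int, ineff: int) -> float:
        total = eff + ineff
        return eff / total if total > 0 else float("nan")

    return BaroreflexResult(
        brs_up=brs_up, brs_down=brs_down, brs_mean=brs_mean,
        bei_up=bei(*counts["up"]), bei_down=bei(*counts["down"]),
        br_up=counts["up"][0], br_down=counts["down"][0],
        brx_up=counts["up"][1], brx_down=counts["down"][1],
        ramps=classified,
    )


def baroreflex_indices(
    series: BeatSeries,
    min_len: int = DEFAULT_MIN_LEN,
    delta_sbp: float = DEFAULT_SBP_DELTA,
    delta_rr: float = DEFAULT_RR_DELTA,
    max_lag: int = DEFAULT_MAX_LAG,
    slope_method: str = "least_squares",
    min_correlation: float | None = None,
) -> BaroreflexResult:
    """Full sequence-method analysis of one (spontaneous-breathing) recording.

    Composes ramp detection, effectiveness classification and slope
    aggregation.  When the recording contains no ramps at all, every index
    is NaN and ``result.defined`` is False.
    """
    ramps = detect_ramps(series.sbp, min_len=min_len, delta_thresh=delta_sbp)
    classified = [
        classify_ramp(r, series.rr, max_lag=max_lag, rr_delta_thresh=delta_rr)
        for r in ramps
    ]
    return sequence_brs(classified, slope_method=slope_method,
                        min_correlation=min_correlation)
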