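"""Reading, writing and artifact screening of beat-series files.

File format: delimited text with a ``#``-prefixed key/value metadata block
followed by the header ``time_s,rr_ms,sbp_mmhg,dbp_mmhg`` and one row per
beat.  Floats are written with shortest round-trip precision so that
``read(write(x)) == x`` exactly for finite values.

Artifact handling in the original protocol was manual; here an explicit
two-rule automated surrogate is used (absolute RR bounds plus deviation
from a local running median) so that the pipeline is reproducible.  Both
thresholds are exposed as parameters.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

from .beats import BeatSeries

HEADER = "time_s,rr_ms,sbp_mmhg,dbp_mmhg"

#: Default absolute physiologic RR bounds (ms).
DEFAULT_ABS_BOUNDS = (300.0, 2000.0)
#: Default relative deviation from the local median that flags a beat.
DEFAULT_REL_THRESHOLD = 0.20
#: Width (beats) of the running-median window used by the relative rule.
MEDIAN_WINDOW = 11
#: A recording with at least this fraction of flagged beats is unusable.
MAX_FLAGGED_FRACTION = 0.20


class BeatSeriesParseError(ValueError):
    """Raised when a beat-series file violates the format or its invariants."""


@dataclass
class ArtifactReport:
    """Outcome of screening one recording for artifacts."""

    flagged_indices: np.ndarray
    rules_fired: dict  # beat index -> list of rule names
    fraction_flagged: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction_flagged <= 1.0:
            raise ValueError("fraction_flagged must lie in [0, 1]")


def write_beat_series(series: BeatSeries, path: str | os.PathLike) -> None:
    """Write a :class:`BeatSeries` to a delimited-text file."""
    with open(path, "w") as fh:
        fh.write(f"# subject_id: {series.subject_id}\n")
        fh.write(f"# protocol: {series.protocol}\n")
        fh.write(f"# n_beats: {len(series)}\n")
        fh.write(HEADER + "\n")
        for t, rr, s, d in zip(series.t, series.rr, series.sbp, series.dbp):
            fh.write(f"{float(t)!r},{float(rr)!r},{float(s)!r},{float(d)!r}\n")


def read_beat_series(path: str | os.PathLike) -> BeatSeries:
    """Read a beat-series file, validating format and physiologic invariants.

    Raises
    ------
    BeatSeriesParseError
        On missing/malformed columns, non-monotone times, non-positive RR
        or inconsistent pressures; the message names the offending line.
    """
    meta: dict[str, str] = {}
    rows: list[tuple[float, float, float, float]] = []
    header_seen = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                if ":" in line:
                    key, _, value = line[1:].partition(":")
                    meta[key.strip()] = value.strip()
                continue
            if not header_seen:
                if line != HEADER:
                    raise BeatSeriesParseError(
                        f"{path}:{lineno}: expected header {HEADER!r}, got {line!r}"
                    )
                header_seen = True
                continue
            parts = line.split(",")
            if len(parts) != 4:
                raise BeatSeriesParseError(
                    f"{path}:{lineno}: expected 4 columns, got {len(parts)}"
                )
            try:
                rows.append(tuple(float(p) for p in parts))  # type: ignore[arg-type]
            except ValueError as exc:
                raise BeatSeriesParseError(f"{path}:{lineno}: {exc}") from None
    if not header_seen:
        raise BeatSeriesParseError(f"{path}: no column header found")
    arr = np.array(rows, dtype=float).reshape(-1, 4)
    try:
        return BeatSeries(
            subject_id=meta.get("subject_id", "unknown"),
            protocol=meta.get("protocol", "SR"),
            t=arr[:, 0],
            rr=arr[:, 1],
            sbp=arr[:, 2],
            dbp=arr[:, 3],
        )
    except ValueError as exc:
        raise BeatSeriesParseError(f"{path}: {exc}") from None


def _running_median(rr: np.ndarray, window: int) -> np.ndarray:
    """Centered running median; the window shrinks at the edges (and for
    series shorter than the window) instead of failing."""
    n = len(rr)
    half = window // 2
    out = np.empty(n)
    for i in range(n):
        lo = max(0, i - half)
        hi = min(n, i + half + 1)
        out[i] = np.median(rr[lo:hi])
    return out


def screen_artifacts(
    series: BeatSeries,
    abs_bounds: tuple[float, float] = DEFAULT_ABS_BOUNDS,
    rel_threshold: float = DEFAULT_REL_THRESHOLD,
    window: int = MEDIAN_WINDOW,
) -> ArtifactReport:
    """Flag implausible beats without modifying the series.

    A beat is flagged iff its RR interval falls outside ``abs_bounds``
    (rule ``"abs"``) or deviates from the median of a centered
    ``window``-beat neighbourhood by more than ``rel_threshold`` times
    that median (rule ``"rel"``).
    """
    if len(series) == 0:
        raise ValueError("cannot screen an empty series")
    lo, hi = abs_bounds
    rr = series.rr
    med = _running_median(rr, window)
    abs_bad = (rr < lo) | (rr > hi)
    rel_bad = np.abs(rr - med) > rel_threshold * med
    flagged = np.flatnonzero(abs_bad | rel_bad)
    rules: dict[int, list[str]] = {}
    for i in flagged:
        fired = []
        if abs_bad[i]:
            fired.append("abs")
        if rel_bad[i]:
            fired.append("rel")
        rules[int(i)] = fired
    return ArtifactReport(
        flagged_indices=flagged,
        rules_fired=rules,
        fraction_flagged=len(flagged) / len(series),
    )


class RecordingRejected(ValueError):
    """Raised when a recording has too many artifacts to be usable."""


def interpolate_artifacts(series: BeatSeries, report: ArtifactReport) -> BeatSeries:
    """Replace flagged RR intervals by linear interpolation between the
    nearest clean neighbours and rebuild beat times cumulatively.

    Flagged beats at the edges take the value of the nearest clean beat.
    Raises :class:`RecordingRejected` when ``report.fraction_flagged``
    reaches ``MAX_FLAGGED_FRACTION``.
    """
    if report.fraction_flagged >= MAX_FLAGGED_FRACTION:
        raise RecordingRejected(
            f"{series.subject_id}/{series.protocol}: "
            f"{report.fraction_flagged:.0%} of beats flagged "
            f"(limit {MAX_FLAGGED_FRACTION:.0%}); recording unusable"
        )
    if len(report.flagged_indices) == 0:
        return series
    rr = series.rr.copy()
    bad = np.zeros(len(rr), dtype=bool)
    bad[report.flagged_indices] = True
    clean_idx = np.flatnonzero(~bad)
    if len(clean_idx) == 0:
        raise RecordingRejected("no clean beats to interpolate from")
    rr[bad] = np.interp(np.flatnonzero(bad), clean_idx, rr[clean_idx])
    return series.replace_rr(rr, flags=np.zeros(len(rr), dtype=bool))
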