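"""Frequency-domain analysis of beat-to-beat series.

Heart-rate variability (HRV) and blood-pressure variability (BPV) are
quantified as power in standard short-term bands: very-low frequency
(VLF, 0-0.04 Hz), low frequency (LF, 0.04-0.15 Hz, containing the ~0.1 Hz
Mayer-wave rhythm) and high frequency (HF, 0.15-0.4 Hz, containing
respiratory sinus arrhythmia at normal breathing rates).  Total power (TP)
is the integral over 0-0.4 Hz.

The beat series is unevenly sampled by nature, so it is first interpolated
with a cubic spline and resampled on a uniform grid (4 Hz by default).
Five-minute recordings use a Welch estimate (120-s Hann segments, 50%
overlap); two-minute paced recordings use a single Hann-tapered
periodogram, and their VLF estimate is marked invalid (a 2-min record
cannot resolve the VLF band meaningfully).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.interpolate import CubicSpline

from .beats import BeatSeries

DEFAULT_FS = 4.0
MIN_DURATION_S = 60.0
#: Recordings at least this long are treated as long-term (Welch, valid VLF).
LONG_RECORDING_S = 240.0
WELCH_SEGMENT_S = 120.0


@dataclass(frozen=True)
class BandScheme:
    """Contiguous, ordered frequency bands, half-open on the upper edge."""

    vlf: tuple[float, float] = (0.0, 0.04)
    lf: tuple[float, float] = (0.04, 0.15)
    hf: tuple[float, float] = (0.15, 0.4)

    def __post_init__(self) -> None:
        bands = [self.vlf, self.lf, self.hf]
        for lo, hi in bands:
            if not 0.0 <= lo < hi:
                raise ValueError(f"invalid band ({lo}, {hi})")
        for (a, b), (c, d) in zip(bands, bands[1:]):
            if b != c:
                raise ValueError("bands must be contiguous and ordered")

    @property
    def total(self) -> tuple[float, float]:
        return (self.vlf[0], self.hf[1])


@dataclass
class SpectralResult:
    """Band powers of one signal under one protocol.

    Powers are ms^2 for RR and mmHg^2 for pressures.  ``lf_hf_ratio`` is
    NaN when HF power is zero; ``vlf_valid`` is False for short (2-min)
    recordings, where the VLF figure is reported but not interpretable.
    """

    signal: str
    protocol: str
    tp: float
    vlf: float
    lf: float
    hf: float
    lf_hf_ratio: float
    vlf_valid: bool

    def __post_init__(self) -> None:
        if min(self.tp, self.vlf, self.lf, self.hf) < 0:
            raise ValueError("band powers must be non-negative")


def resample_tachogram(
    series: BeatSeries,
    fs: float = DEFAULT_FS,
    signal: str = "RR",
) -> tuple[np.ndarray, np.ndarray]:
    """Cubic-spline resampling of a per-beat signal onto a uniform grid.

    Returns ``(times, values)``; the grid spans the recording and never
    extrapolates beyond the first/last beat.  Refuses recordings shorter
    than 60 s, where the band structure cannot be resolved.
    """
    if len(series) < 2:
        raise ValueError("need at least 2 beats to resample")
    if series.duration < MIN_DURATION_S:
        raise ValueError(
            f"recording of {series.duration:.1f}s is too short for spectral "
            f"analysis (minimum {MIN_DURATION_S:.0f}s)"
        )
    values = series.signal(signal)
    spline = CubicSpline(series.t, values)
    n = int(math.floor(series.duration * fs)) + 1
    grid = series.t[0] + np.arange(n) / fs
    return grid, spline(grid)


def band_powers(
    x: np.ndarray,
    fs: float,
    scheme: BandScheme | None = None,
    detrend: str = "linear",
    signal: str = "RR",
    protocol: str = "SR",
) -> SpectralResult:
    """Band powers of an evenly sampled signal.

    Welch PSD (120-s Hann segments, 50% overlap) for recordings of at
    least 240 s, a single Hann-tapered periodogram otherwise.  Power in a
    band ``[lo, hi)`` is the PSD integral over the frequency bins falling
    in the band; TP integrates 0-0.4 Hz.
    """
    scheme = scheme or BandScheme()
    x = np.asarray(x, dtype=float)
    duration = len(x) / fs
    if duration < MIN_DURATION_S:
        raise ValueError("signal shorter than 60 s")
    if fs / 2.0 < scheme.hf[1]:
        raise ValueError(
            f"sampling rate {fs} Hz cannot resolve the HF band "
            f"(needs fs >= {2 * scheme.hf[1]} Hz)"
        )
    if detrend not in ("mean", "linear"):
        raise ValueError("detrend must be 'mean' or 'linear'")
    det = "constant" if detrend == "mean" else "linear"
    long_record = duration >= LONG_RECORDING_S
    if long_record:
        nperseg = min(len(x), int(WELCH_SEGMENT_S * fs))
        f, pxx = sps.welch(
            x, fs=fs, window="hann", nperseg=nperseg,
            noverlap=nperseg // 2, detrend=det,
        )
    else:
        f, pxx = sps.periodogram(x, fs=fs, window="hann", detrend=det)
    df = f[1] - f[0]

    def integrate(lo: float, hi: float) -> float:
        mask = (f >= lo) & (f < hi)
        return float(np.sum(pxx[mask]) * df)

    vlf = integrate(*scheme.vlf)
    lf = integrate(*scheme.lf)
    hf = integrate(*scheme.hf)
    tp = integrate(*scheme.total)
    ratio = lf / hf if hf > 1e-12 else float("nan")
    return SpectralResult(
        signal=signal, protocol=protocol,
        tp=tp, vlf=vlf, lf=lf, hf=hf,
        lf_hf_ratio=ratio, vlf_valid=long_record,
    )


def analyze_recording(
    series: BeatSeries,
    scheme: BandScheme | None = None,
    fs: float = DEFAULT_FS,
    detrend: str = "linear",
) -> dict[str, SpectralResult]:
    """Band powers of all three per-beat signals of one recording.

    Returns a mapping ``{"RR": ..., "SBP": ..., "DBP": ...}``; RR powers
    in ms^2, pressure powers in mmHg^2.  The series is expected to have
    been screened/interpolated beforehand.
    """
    out = {}
    for name in ("RR", "SBP", "DBP"):
        _, x = resample_tachogram(series, fs=fs, signal=name)
        out[name] = band_powers(
            x, fs=fs, scheme=scheme, detrend=detrend,
            signal=name, protocol=series.protocol,
        )
    return out


def spectra_frame(results: dict) -> pd.DataFrame:
    """Flatten ``{subject_id: {protocol: {signal: SpectralResult}}}`` into a
    tidy table with one row per subject x protocol x signal."""
    rows = []
    for sid, by_protocol in results.items():
        for protocol, by_signal in by_protocol.items():
            for name, res in by_signal.items():
                rows.append({
                    "subject_id": sid, "protocol": protocol, "signal": name,
                    "tp": res.tp, "vlf": res.vlf, "lf": res.lf, "hf": res.hf,
                    "lf_hf": res.lf_hf_ratio, "vlf_valid": res.vlf_valid,
                })
    return pd.DataFrame(rows)


def protocol_contrast(
    spectra: pd.DataFrame,
    signal: str = "RR",
    baseline: str = "SR",
    bands: tuple[str, ...] = ("tp", "lf", "hf"),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-subject band-power changes of paced protocols against baseline.

    Parameters
    ----------
    spectra : DataFrame
        Tidy table as produced by :func:`spectra_frame` (columns
        ``subject_id, protocol, signal`` plus band columns).

    Returns
    -------
    (per_subject, summary)
        ``per_subject`` holds one row per subject x paced protocol with
        signed differences ``<band>_diff``; subjects missing a protocol
        are excluded.  ``summary`` gives, per protocol and band, the
        median difference and the fraction of subjects with an increase.
    """
    sub = spectra[spectra["signal"] == signal]
    wide = sub.pivot_table(index="subject_id", columns="protocol",
                           values=list(bands), aggfunc="first")
    rows = []
    for protocol in ("BR12", "BR6"):
        if protocol == baseline:
            continue
        for sid in wide.index:
            rec = {"subject_id": sid, "protocol": protocol}
            ok = True
            for band in bands:
                try:
                    a = wide.loc[sid, (band, protocol)]
                    b = wide.loc[sid, (band, baseline)]
                except KeyError:
                    ok = False
                    break
                if pd.isna(a) or pd.isna(b):
                    ok = False
                    break
                rec[f"{band}_diff"] = a - b
            if ok:
                rows.append(rec)
    per_subject = pd.DataFrame(rows)
    summary_rows = []
    for protocol, grp in per_subject.groupby("protocol"):
        for band in bands:
            d = grp[f"{band}_diff"]
            summary_rows.append({
                "protocol": protocol, "band": band,
                "median_diff": float(d.median()),
                "fraction_increased": float((d > 0).mean()),
            })
    return per_subject, pd.DataFrame(summary_rows)
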