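"""Per-beat cardiovascular series.

The elementary data object of the package: one recording of a subject under
one breathing protocol, as beat-by-beat triplets of RR interval (ms) and
systolic/diastolic arterial pressure (mmHg), with the onset time of each
beat.  Beat times and RR intervals are redundant by construction
(``t[n+1] = t[n] + rr[n] / 1000``) and the container enforces that
consistency.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Recognised breathing protocols: spontaneous respiration (5 min),
#: paced breathing at 12 breaths/min (2 min) and at 6 breaths/min (2 min).
PROTOCOLS = ("SR", "BR12", "BR6")

#: Breathing frequency implied by each paced protocol (Hz).
PROTOCOL_FREQ_HZ = {"BR12": 0.2, "BR6": 0.1}

_TIME_ATOL = 1e-9


@dataclass
class BeatSeries:
    """Beat-by-beat RR/SBP/DBP series for one subject and protocol.

    Parameters
    ----------
    subject_id : str
        Identifier of the subject the recording belongs to.
    protocol : str
        One of ``"SR"`` (spontaneous), ``"BR12"`` (12 breaths/min) or
        ``"BR6"`` (6 breaths/min).
    t : ndarray of float
        Beat onset times in seconds, strictly increasing.
    rr : ndarray of float
        RR intervals in milliseconds, all positive.  ``t[n+1] - t[n]``
        must equal ``rr[n] / 1000``.
    sbp, dbp : ndarray of float
        Systolic and diastolic pressure per beat, mmHg, with
        ``sbp > dbp > 0``.
    artifact_flags : ndarray of bool, optional
        Per-beat artifact marks; defaults to all-clean.
    """

    subject_id: str
    protocol: str
    t: np.ndarray
    rr: np.ndarray
    sbp: np.ndarray
    dbp: np.ndarray
    artifact_flags: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.rr = np.asarray(self.rr, dtype=float)
        self.sbp = np.asarray(self.sbp, dtype=float)
        self.dbp = np.asarray(self.dbp, dtype=float)
        if self.artifact_flags is None:
            self.artifact_flags = np.zeros(self.t.shape, dtype=bool)
        else:
            self.artifact_flags = np.asarray(self.artifact_flags, dtype=bool)
        if self.protocol not in PROTOCOLS:
            raise ValueError(
                f"unknown protocol {self.protocol!r}; expected one of {PROTOCOLS}"
            )
        n = len(self.t)
        for name in ("rr", "sbp", "dbp", "artifact_flags"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"length mismatch: t has {n} beats, "
                                 f"{name} has {len(getattr(self, name))}")
        if n == 0:
            return
        if np.any(self.rr <= 0):
            bad = int(np.argmax(self.rr <= 0))
            raise ValueError(f"non-positive RR interval at beat {bad}")
        if np.any(~np.isfinite(self.t)) or np.any(np.diff(self.t) <= 0):
            raise ValueError("beat times must be finite and strictly increasing")
        if np.any(self.sbp <= self.dbp) or np.any(self.dbp <= 0):
            raise ValueError("pressures must satisfy sbp > dbp > 0")
        if n > 1 and not np.allclose(
            np.diff(self.t), self.rr[:-1] / 1000.0, rtol=0.0, atol=_TIME_ATOL
        ):
            raise ValueError("beat times inconsistent with RR intervals")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def duration(self) -> float:
        """Recording span in seconds (first to last beat onset)."""
        if len(self.t) < 2:
            return 0.0
        return float(self.t[-1] - self.t[0])

    def signal(self, name: str) -> np.ndarray:
        """Return one of the per-beat signals by name (``RR``/``SBP``/``DBP``)."""
        try:
            return {"RR": self.rr, "SBP": self.sbp, "DBP": self.dbp}[name]
        except KeyError:
            raise KeyError(f"unknown signal {name!r}; expected RR, SBP or DBP") from None

    def replace_rr(self, rr: np.ndarray, flags: np.ndarray | None = None) -> "BeatSeries":
        """Return a copy with new RR intervals and beat times rebuilt cumulatively."""
        rr = np.asarray(rr, dtype=float)
        t = np.empty_like(rr)
        if len(rr):
            t[0] = self.t[0]
            np.cumsum(rr[:-1] / 1000.0, out=t[1:])
            t[1:] += t[0]
        return BeatSeries(
            subject_id=self.subject_id,
            protocol=self.protocol,
            t=t,
            rr=rr,
            sbp=self.sbp.copy(),
            dbp=self.dbp.copy(),
            artifact_flags=(self.artifact_flags.copy() if flags is None else flags),
        )
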