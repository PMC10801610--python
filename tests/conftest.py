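import numpy as np
import pytest

import autonomics as au


def make_series(rr, sbp=None, dbp=None, protocol="SR", subject_id="s1", t0=0.0):
    """Build a consistent BeatSeries from RR intervals (ms)."""
    rr = np.asarray(rr, dtype=float)
    n = len(rr)
    sbp = np.full(n, 120.0) if sbp is None else np.asarray(sbp, dtype=float)
    dbp = sbp - 50.0 if dbp is None else np.asarray(dbp, dtype=float)
    t = np.empty(n)
    if n:
        t[0] = t0
        t[1:] = t0 + np.cumsum(rr[:-1] / 1000.0)
    return au.BeatSeries(subject_id=subject_id, protocol=protocol,
                         t=t, rr=rr, sbp=sbp, dbp=dbp)


@pytest.fixture(scope="session")
def presets():
    """Calibrated group presets (calibration is deterministic and cached)."""
    return au.make_group_presets()


@pytest.fixture(scope="session")
def small_cohort(presets):
    """A small full cohort (all three protocols) shared across tests."""
    return au.simulate_cohort(12, presets, seed=0)


@pytest.fixture(scope="session")
def small_cohort_spectra(small_cohort):
    results = {}
    for (sid, proto), series in small_cohort.recordings.items():
        results.setdefault(sid, {})[proto] = au.analyze_recording(series)
    frame = au.spectra_frame(results)
    frame["group"] = frame.subject_id.str.rsplit("_", n=1).str[0]
    return frame
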