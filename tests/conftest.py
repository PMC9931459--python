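import numpy as np
import pytest

from ildgapc import PatientRecord


@pytest.fixture
def make_record():
    """Factory for a valid patient record with overridable fields."""

    def _make(**kw):
        base = dict(
            patient_id="P1",
            diagnosis="IPF",
            sex="male",
            age=70.0,
            fvc_pct=80.0,
            dlco_pct=60.0,
            ccis=1,
            followup_days=1000.0,
        )
        base.update(kw)
        return PatientRecord(**base)

    return _make


@pytest.fixture
def censored_survival_sample():
    """Small mixed censored/uncensored sample with a prognostic score."""
    rng = np.random.default_rng(42)
    n = 80
    score = rng.normal(size=n)
    t = rng.exponential(100 * np.exp(-0.8 * score))
    c = rng.exponential(150, n)
    time = np.minimum(t, c)
    event = (t <= c).astype(int)
    return time, event, score
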