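import numpy as np
import pytest

from erpstates.containers import GrandAverage, SubjectERP
from erpstates.simulate import make_montage


@pytest.fixture(scope="session")
def montage16():
    return make_montage(16)


@pytest.fixture(scope="session")
def montage32():
    return make_montage(32)


def make_ga(data, sfreq=512.0, condition="ST", alignment="stimulus", t0=0.0,
            subjects=("S01", "S02"), mean_rt_ms=None):
    data = np.asarray(data, dtype=float)
    dt = 1000.0 / sfreq
    return GrandAverage(
        condition=condition,
        alignment=alignment,
        sfreq=sfreq,
        data=data,
        times=t0 + np.arange(data.shape[1]) * dt,
        subjects=list(subjects),
        mean_rt_ms=mean_rt_ms,
    )


def make_subject_erp(data, subject, condition, sfreq=512.0, alignment="stimulus",
                     t0=0.0, n_epochs=40, mean_rt_ms=800.0):
    data = np.asarray(data, dtype=float)
    dt = 1000.0 / sfreq
    return SubjectERP(
        subject=subject,
        condition=condition,
        alignment=alignment,
        sfreq=sfreq,
        data=data,
        times=t0 + np.arange(data.shape[1]) * dt,
        n_epochs=n_epochs,
        mean_rt_ms=mean_rt_ms,
    )
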