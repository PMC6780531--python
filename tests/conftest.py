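"""Shared fixtures: printed per-frequency calibration values and cohorts.

The per-rate QT means frozen here are the study's printed values; tests
use them both as generator calibration and as inputs to independent
desk-oracle arithmetic.
"""

from __future__ import annotations

import pytest
from hypothesis import HealthCheck, settings

from qtdyn import Cohort, GeneratorConfig, PacingBurst, PatientRecord, Phase, Sex, generate_cohort

settings.register_profile(
    "ci", derandomize=True, max_examples=60,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

#: Printed per-frequency QT means (ms), baseline and released phases.
QT_BASELINE_MEANS = {
    50: 469.33, 60: 448.53, 70: 432.44, 80: 417.37,
    90: 401.60, 100: 382.22, 110: 368.67, 120: 359.67,
}
QT_RELEASED_MEANS = {
    50: 520.0, 60: 477.16, 70: 468.0, 80: 454.48,
    90: 435.60, 100: 417.33, 110: 404.67, 120: 388.0,
}

#: Noise-free study conditions: every patient sits exactly on the
#: configured per-rate means.
def noise_free_config(**overrides) -> GeneratorConfig:
    base = dict(
        n_patients=1,
        qt_sd_by_rate={r: 0.0 for r in QT_BASELINE_MEANS},
        qrs_baseline_sd=0.0,
        delta_qrs_sd=0.0,
        tpe_burst_sd=0.0,
        seed=0,
    )
    base.update(overrides)
    return GeneratorConfig(**base)


def make_burst(
    patient_id="P001", phase=Phase.BASELINE, rate_bpm=60,
    qrs_ms=100.0, qrsend_tpeak_ms=220.0, tpeak_tend_ms=80.0, qt_ms=400.0,
) -> PacingBurst:
    return PacingBurst(
        patient_id=patient_id, phase=phase, rate_bpm=rate_bpm,
        rr_s=60.0 / rate_bpm, qrs_ms=qrs_ms, qrsend_tpeak_ms=qrsend_tpeak_ms,
        tpeak_tend_ms=tpeak_tend_ms, qt_ms=qt_ms)


@pytest.fixture(scope="session")
def default_cohort() -> Cohort:
    """One default 23-patient two-phase cohort."""
    return generate_cohort(GeneratorConfig(seed=42))


@pytest.fixture(scope="session")
def table_means_patient() -> PatientRecord:
    """A deterministic patient lying exactly on the printed per-rate means."""
    cohort = generate_cohort(noise_free_config())
    return cohort.patients[0]


@pytest.fixture
def two_patient_cohort() -> Cohort:
    """Tiny hand-built cohort: two patients, both phases at 60 and 80 bpm."""
    patients = []
    for pid, sex, qt_shift in (("A", Sex.MALE, 0.0), ("B", Sex.FEMALE, 12.0)):
        bursts = []
        for phase, widen in ((Phase.BASELINE, 0.0), (Phase.RELEASED, 30.0)):
            for rate in (60, 80):
                bursts.append(make_burst(
                    patient_id=pid, phase=phase, rate_bpm=rate,
                    qrs_ms=100.0 + widen,
                    qrsend_tpeak_ms=220.0 - rate / 4 + qt_shift,
                    tpeak_tend_ms=80.0,
                    qt_ms=400.0 - rate / 4 + widen + qt_shift))
        patients.append(PatientRecord(
            patient_id=pid, sex=sex,
            wenckebach_bpm={Phase.BASELINE: 120, Phase.RELEASED: 120},
            bursts=bursts))
    return Cohort(patients=patients, provenance="hand-built")
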