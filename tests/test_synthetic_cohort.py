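"""Generator: calibration, determinism, correlation structure, attrition."""

from __future__ import annotations

import numpy as np
import pytest

from qtdyn import (
    GeneratorConfig,
    GeneratorConfigError,
    Phase,
    apply_attrition,
    generate_cohort,
    pearson,
    phase_contrast,
    write_cohort,
)
from conftest import QT_BASELINE_MEANS, QT_RELEASED_MEANS, noise_free_config


@pytest.fixture(scope="module")
def big_cohort():
    """One large cohort for law-of-large-numbers checks."""
    return generate_cohort(GeneratorConfig(n_patients=2000, seed=11))


def paired_deltas(cohort):
    a = phase_contrast(cohort, "qt").to_frame().rename(columns={"delta_ms": "dqt"})
    b = phase_contrast(cohort, "qrs").to_frame().rename(columns={"delta_ms": "dqrs"})
    return a.merge(b[["patient_id", "rate_bpm", "dqrs"]], on=["patient_id", "rate_bpm"])


class TestNoiseFreeLimit:
    def test_every_patient_sits_on_configured_means(self):
        cohort = generate_cohort(noise_free_config(n_patients=3))
        for patient in cohort:
            for burst in patient.bursts:
                expected = (QT_BASELINE_MEANS if burst.phase is Phase.BASELINE
                            else QT_RELEASED_MEANS)[burst.rate_bpm]
                assert burst.qt_ms == pytest.approx(expected, abs=1e-9)
                assert burst.qrs_ms == pytest.approx(
                    98.50 + (32.5 if burst.phase is Phase.RELEASED else 0.0))

    def test_rho_one_flat_means_gives_delta_qt_equal_delta_qrs(self):
        """With rho → 1 and a flat released shift, the QT prolongation is
        the QRS widening patientwise."""
        config = GeneratorConfig(
            n_patients=6, seed=5, rho_dqt_dqrs=1.0,
            qt_released_mean={r: m + 32.5 for r, m in QT_BASELINE_MEANS.items()},
            delta_qst_highrate_mean={}, delta_tpe_highrate_mean={},
        )
        m = paired_deltas(generate_cohort(config))
        assert np.allclose(m["dqt"], m["dqrs"], atol=1e-9)


class TestDeterminism:
    def test_same_seed_byte_identical(self, tmp_path):
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        write_cohort(generate_cohort(GeneratorConfig(seed=17)), p1)
        write_cohort(generate_cohort(GeneratorConfig(seed=17)), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_different_seeds_differ(self):
        c1 = generate_cohort(GeneratorConfig(seed=1))
        c2 = generate_cohort(GeneratorConfig(seed=2))
        assert c1.patients[0].bursts[0].qt_ms != c2.patients[0].bursts[0].qt_ms

    def test_attrition_toggle_does_not_perturb_interval_draws(self):
        plain = generate_cohort(GeneratorConfig(seed=13))
        dropped = generate_cohort(GeneratorConfig(seed=13, p_av_block=0.3))
        for p_plain, p_drop in zip(plain, dropped):
            base_plain = {b.rate_bpm: b.qt_ms for b in p_plain.phase_bursts(Phase.BASELINE)}
            base_drop = {b.rate_bpm: b.qt_ms for b in p_drop.phase_bursts(Phase.BASELINE)}
            assert base_plain == base_drop


class TestLargeSampleRecovery:
    def test_delta_qrs_mean_recovered(self, big_cohort):
        m = paired_deltas(big_cohort)
        per_patient = m.groupby("patient_id")["dqrs"].mean()
        se = 13.774 / np.sqrt(len(per_patient))
        assert abs(per_patient.mean() - 32.5) < 3 * se

    def test_correlation_recovered(self, big_cohort):
        m = paired_deltas(big_cohort)
        assert pearson(m["dqt"], m["dqrs"]) == pytest.approx(0.79, abs=0.03)

    def test_per_rate_baseline_qt_means_converge(self, big_cohort):
        frames = {}
        for patient in big_cohort:
            for b in patient.phase_bursts(Phase.BASELINE):
                frames.setdefault(b.rate_bpm, []).append(b.qt_ms)
        for rate, values in frames.items():
            sd = GeneratorConfig().qt_sd_by_rate[rate]
            se = sd / np.sqrt(len(values))
            assert abs(np.mean(values) - QT_BASELINE_MEANS[rate]) < 3 * se + 1e-9


class TestInternalConsistency:
    def test_sum_decomposition_exact_on_generated_truth(self, default_cohort):
        for patient in default_cohort:
            for b in patient.bursts:
                assert b.qt_ms == pytest.approx(
                    b.qrs_ms + b.qrsend_tpeak_ms + b.tpeak_tend_ms, abs=1e-6)

    def test_component_deltas_sum_to_overall_qt_delta(self):
        """Configured widening + sub-interval phase shifts reproduce the
        calibrated mean QT prolongation: 32.5 − 1.18 + 4.07 ≈ 35.7."""
        config = GeneratorConfig()
        d = config.derived_parameters()["delta_qt_rate"]
        mean_dqt = np.mean(list(d.values()))
        component_sum = (config.delta_qrs_mean + config.delta_qst_mean
                         + config.delta_tpe_mean)
        assert component_sum == pytest.approx(mean_dqt, abs=1.0)

    def test_extra_sd_reduces_to_simple_formula_for_flat_means(self):
        config = GeneratorConfig(
            qt_released_mean={r: m + 30.0 for r, m in QT_BASELINE_MEANS.items()})
        der = config.derived_parameters()
        rho = config.rho_dqt_dqrs
        expected = config.delta_qrs_sd * np.sqrt(1.0 / rho**2 - 1.0)
        assert der["var_rate"] == 0.0
        assert der["extra_sd"] == pytest.approx(expected)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "overrides, match",
        [
            (dict(n_patients=0), "n_patients"),
            (dict(rates=(80, 60)), "sorted"),
            (dict(rates=(55,)), "ladder"),
            (dict(rho_dqt_dqrs=0.0), "rho"),
            (dict(rho_dqt_dqrs=1.5), "rho"),
            (dict(p_av_block=1.2), "p_av_block"),
            (dict(qrs_baseline_sd=-1.0), "SD"),
        ],
    )
    def test_invalid_config_rejected(self, overrides, match):
        with pytest.raises(GeneratorConfigError, match=match):
            GeneratorConfig(**overrides).validate()

    def test_infeasible_partition_names_rate_and_phase(self):
        config = GeneratorConfig(tpe_baseline_mean=400.0)
        with pytest.raises(GeneratorConfigError, match="baseline phase, 50 bpm"):
            config.validate()

    def test_mapping_round_trip(self):
        config = GeneratorConfig(seed=5, n_patients=7)
        assert GeneratorConfig.from_mapping(config.to_mapping()) == config

    def test_unknown_key_rejected(self):
        with pytest.raises(GeneratorConfigError, match="unknown config keys"):
            GeneratorConfig.from_mapping({"qt_mean": 400})


class TestAttrition:
    def test_zero_probabilities_identity(self, default_cohort):
        config = GeneratorConfig(seed=42)
        out = apply_attrition(default_cohort, config)
        assert out.n_bursts == default_cohort.n_bursts

    def test_full_av_block_removes_all_released_bursts(self):
        config = GeneratorConfig(seed=8, p_av_block=1.0)
        cohort = generate_cohort(config)
        for patient in cohort:
            assert not patient.phase_bursts(Phase.RELEASED)
            assert len(patient.phase_bursts(Phase.BASELINE)) == 8

    def test_baseline_never_altered(self):
        config = GeneratorConfig(seed=21, p_av_block=0.3,
                                 wenckebach_released_drop=0.5)
        cohort = generate_cohort(config)
        for patient in cohort:
            assert len(patient.phase_bursts(Phase.BASELINE)) == 8
            patient.validate(tol=1e-6)

    def test_mean_excluded_count_matches_binomial_expectation(self):
        """p = 5/28 on 28 patients loses ≈ 5 patients on average."""
        base = generate_cohort(GeneratorConfig(n_patients=28, seed=1))
        excluded = []
        for seed in range(400):
            config = GeneratorConfig(n_patients=28, seed=seed, p_av_block=5 / 28)
            out = apply_attrition(base, config)
            excluded.append(sum(not p.phase_bursts(Phase.RELEASED) for p in out))
        se = np.sqrt(28 * (5 / 28) * (23 / 28) / 400)
        assert np.mean(excluded) == pytest.approx(5.0, abs=3 * se)
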