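"""Synthetic two-phase paced cohorts with controlled QRS widening.

Emulates the statistical structure of an atrial-pacing (AAI) protocol run
twice in the same patients — once at baseline and once immediately after
deployment of a self-expanding aortic valve prosthesis, which typically
produces left-bundle-branch-block-like QRS widening. Pacing steps through
50–120 bpm in 10-bpm increments; each burst yields averaged QT, QRS,
QRSend-Tpeak and Tpeak-Tend durations.

Generative model (per patient i, rate r):

* ``QRS_base_i ~ N(mu_qrs, sd_qrs)``, constant across rates and bursts
  within a phase (depolarization time is rate-invariant in this range).
* Widening ``dQRS_i ~ N(mu_dqrs, sd_dqrs)``; released QRS =
  ``QRS_base_i + dQRS_i`` at every rate.
* Baseline QT(i, r) = ``mu_qt[r] + sqrt(f)·s[r]·z_i + sqrt(1-f)·s[r]·eps``,
  with a shared patient z-score so per-rate totals match the configured
  SDs while patients keep their rank across rates (f = between-patient
  variance fraction, default 0.7).
* Released QT(i, r) = baseline QT(i, r) + ``dQRS_i`` + ``extra_i`` + c[r],
  where ``extra_i`` is an independent patient-level normal capturing QT
  prolongation beyond the QRS widening, and c[r] is a deterministic
  calibration offset pinning the released per-rate expectation to the
  configured released means.
* Tpeak-Tend is generated around its phase/rate mean (with a high-rate
  rise in the released phase); QRSend-Tpeak is the remainder
  ``qt − qrs − tpe``, so the sum decomposition is exact by construction.

The variance of ``extra_i`` is sized so the pooled per-burst Pearson
correlation between released-minus-baseline δ-QT and δ-QRS equals
``rho_dqt_dqrs`` in expectation, *including* the deterministic
between-rate spread introduced by the calibration offsets (see
docs/methods.md for the derivation).
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field, fields
from typing import Any, Mapping

import numpy as np

from .data_model import (
    GENERATED_TOL_MS,
    PACING_RATES_BPM,
    Cohort,
    PacingBurst,
    PatientRecord,
    Phase,
    Sex,
)

__all__ = [
    "GeneratorConfig",
    "GeneratorConfigError",
    "generate_cohort",
    "apply_attrition",
    "DEFAULT_QT_BASELINE_MEAN_MS",
    "DEFAULT_QT_RELEASED_MEAN_MS",
    "DEFAULT_QT_BASELINE_SD_MS",
]

# Per-frequency QT calibration (ms): mean baseline / released QT and the
# baseline total SD at each pacing rate, from the reference TAVI pacing
# cohort (n = 23) this generator emulates.
DEFAULT_QT_BASELINE_MEAN_MS: dict[int, float] = {
    50: 469.33, 60: 448.53, 70: 432.44, 80: 417.37,
    90: 401.60, 100: 382.22, 110: 368.67, 120: 359.67,
}
DEFAULT_QT_RELEASED_MEAN_MS: dict[int, float] = {
    50: 520.0, 60: 477.16, 70: 468.0, 80: 454.48,
    90: 435.60, 100: 417.33, 110: 404.67, 120: 388.0,
}
DEFAULT_QT_BASELINE_SD_MS: dict[int, float] = {
    50: 27.09, 60: 26.44, 70: 22.96, 80: 24.59,
    90: 19.53, 100: 2.08, 110: 20.60, 120: 17.31,
}

DEFAULT_QRS_BASELINE_MEAN_MS = 98.50
DEFAULT_QRS_BASELINE_SD_MS = 21.78
DEFAULT_DELTA_QRS_MEAN_MS = 32.5
# Widening treated as independent patient-level variance on top of the
# baseline QRS spread: sd_released^2 = sd_baseline^2 + sd_widening^2.
DEFAULT_DELTA_QRS_SD_MS = (25.77**2 - 21.78**2) ** 0.5  # ≈ 13.77

DEFAULT_TPE_BASELINE_MEAN_MS = 87.0
DEFAULT_TPE_BURST_SD_MS = 8.0
DEFAULT_DELTA_TPE_MEAN_MS = 4.07
DEFAULT_DELTA_QST_MEAN_MS = -1.18
# High-rate released-phase additions (ms): repolarization intervals are
# unchanged below 100 bpm but lengthen progressively at 100-120 bpm.
DEFAULT_QST_HIGHRATE_MS: dict[int, float] = {100: 3.0, 110: 5.0, 120: 7.0}
DEFAULT_TPE_HIGHRATE_MS: dict[int, float] = {100: 6.0, 110: 10.0, 120: 14.0}

DEFAULT_RHO_DQT_DQRS = 0.79
DEFAULT_SEX_RATIO = 0.48

_MIN_SUBINTERVAL_MS = 0.5
# Spawn keys for RNG substreams that must not perturb per-patient
# interval draws when toggled.
_SEX_STREAM_KEY = 0x5E
_ATTRITION_STREAM_KEY = 0xA7


class GeneratorConfigError(ValueError):
    """Invalid or infeasible generator configuration."""


@dataclass
class GeneratorConfig:
    """Study conditions for :func:`generate_cohort`.

    Defaults reproduce the two-phase pacing protocol they were calibrated
    to: 23 patients, rate ladder 50–120 bpm, per-frequency QT means of
    both phases, ~32.5 ms mean QRS widening, and a δ-QT/δ-QRS coupling
    of 0.79.
    """

    n_patients: int = 23
    rates: tuple[int, ...] = PACING_RATES_BPM
    qt_baseline_mean: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_QT_BASELINE_MEAN_MS))
    #: Released per-rate QT targets; ``None`` disables calibration and the
    #: released means follow mechanistically from the widening terms.
    qt_released_mean: dict[int, float] | None = field(
        default_factory=lambda: dict(DEFAULT_QT_RELEASED_MEAN_MS))
    qt_sd_by_rate: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_QT_BASELINE_SD_MS))
    #: Fraction of per-rate QT variance that is between-patient.
    qt_between_frac: float = 0.7
    #: Optional flat within-patient burst SD (ms); overrides the
    #: ``sqrt(1 - qt_between_frac)·qt_sd_by_rate`` rule when set.
    qt_burst_sd: float | None = None
    qrs_baseline_mean: float = DEFAULT_QRS_BASELINE_MEAN_MS
    qrs_baseline_sd: float = DEFAULT_QRS_BASELINE_SD_MS
    delta_qrs_mean: float = DEFAULT_DELTA_QRS_MEAN_MS
    delta_qrs_sd: float = DEFAULT_DELTA_QRS_SD_MS
    tpe_baseline_mean: float = DEFAULT_TPE_BASELINE_MEAN_MS
    tpe_burst_sd: float = DEFAULT_TPE_BURST_SD_MS
    #: Overall released-minus-baseline phase means (ms) of the two
    #: repolarization sub-intervals, averaged over the rate ladder.
    delta_tpe_mean: float = DEFAULT_DELTA_TPE_MEAN_MS
    delta_qst_mean: float = DEFAULT_DELTA_QST_MEAN_MS
    delta_qst_highrate_mean: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_QST_HIGHRATE_MS))
    delta_tpe_highrate_mean: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_TPE_HIGHRATE_MS))
    rho_dqt_dqrs: float = DEFAULT_RHO_DQT_DQRS
    p_av_block: float = 0.0
    wenckebach_released_drop: float = 0.0
    sex_ratio: float = DEFAULT_SEX_RATIO
    seed: int = 0

    # -- validation ---------------------------------------------------

    def validate(self) -> None:
        if self.n_patients < 1:
            raise GeneratorConfigError("n_patients must be >= 1")
        if list(self.rates) != sorted(self.rates):
            raise GeneratorConfigError("rates must be sorted ascending")
        unknown = [r for r in self.rates if r not in PACING_RATES_BPM]
        if unknown:
            raise GeneratorConfigError(
                f"rates must lie on the protocol ladder {PACING_RATES_BPM}, "
                f"got {unknown}")
        for name in ("qt_baseline_mean", "qt_sd_by_rate"):
            table = getattr(self, name)
            missing = [r for r in self.rates if r not in table]
            if missing:
                raise GeneratorConfigError(f"{name} missing rates {missing}")
        if self.qt_released_mean is not None:
            missing = [r for r in self.rates if r not in self.qt_released_mean]
            if missing:
                raise GeneratorConfigError(
                    f"qt_released_mean missing rates {missing}")
        sds = [self.qrs_baseline_sd, self.delta_qrs_sd, self.tpe_burst_sd]
        sds += [self.qt_sd_by_rate[r] for r in self.rates]
        if self.qt_burst_sd is not None:
            sds.append(self.qt_burst_sd)
        if any(s < 0 for s in sds):
            raise GeneratorConfigError("all SDs must be >= 0")
        if not 0.0 < self.rho_dqt_dqrs <= 1.0:
            raise GeneratorConfigError("rho_dqt_dqrs must be in (0, 1]")
        if not 0.0 <= self.qt_between_frac <= 1.0:
            raise GeneratorConfigError("qt_between_frac must be in [0, 1]")
        for name in ("p_av_block", "wenckebach_released_drop", "sex_ratio"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise GeneratorConfigError(f"{name} must be in [0, 1]")
        positive = {
            "qrs_baseline_mean": self.qrs_baseline_mean,
            "tpe_baseline_mean": self.tpe_baseline_mean,
        }
        positive.update({f"qt_baseline_mean[{r}]": self.qt_baseline_mean[r]
                         for r in self.rates})
        for name, value in positive.items():
            if not value > 0:
                raise GeneratorConfigError(f"{name} must be > 0, got {value!r}")
        self._check_partition_feasible()

    def _check_partition_feasible(self) -> None:
        """Expected sub-intervals must stay positive at every rate/phase."""
        der = self.derived_parameters()
        for r in self.rates:
            qst_base = (self.qt_baseline_mean[r] - self.qrs_baseline_mean
                        - self.tpe_baseline_mean)
            if qst_base <= 0:
                raise GeneratorConfigError(
                    f"baseline phase, {r} bpm: expected QRSend-Tpeak "
                    f"{qst_base:.1f} ms is not positive")
            tpe_rel = (self.tpe_baseline_mean + der["delta_tpe_base"]
                       + self.delta_tpe_highrate_mean.get(r, 0.0))
            qt_rel = self.qt_baseline_mean[r] + der["delta_qt_rate"][r]
            qst_rel = qt_rel - (self.qrs_baseline_mean + self.delta_qrs_mean) - tpe_rel
            for name, value in (("Tpeak-Tend", tpe_rel), ("QRSend-Tpeak", qst_rel)):
                if value <= 0:
                    raise GeneratorConfigError(
                        f"released phase, {r} bpm: expected {name} "
                        f"{value:.1f} ms is not positive")

    # -- derived quantities -------------------------------------------

    def derived_parameters(self) -> dict[str, Any]:
        """Deterministic quantities implied by the configuration.

        Returns a dict with:

        * ``delta_tpe_base`` / ``delta_qst_base``: rate-independent parts
          of the released-phase sub-interval shifts, chosen so the means
          over the rate ladder equal ``delta_tpe_mean`` / ``delta_qst_mean``.
        * ``delta_qt_rate``: deterministic per-rate δ-QT expectation.
        * ``extra_sd``: SD of the patient-level QT prolongation beyond the
          QRS widening, sized for the target δ-QT/δ-QRS correlation.
        """
        n = len(self.rates)
        hr_tpe = {r: self.delta_tpe_highrate_mean.get(r, 0.0) for r in self.rates}
        hr_qst = {r: self.delta_qst_highrate_mean.get(r, 0.0) for r in self.rates}
        delta_tpe_base = self.delta_tpe_mean - sum(hr_tpe.values()) / n
        delta_qst_base = self.delta_qst_mean - sum(hr_qst.values()) / n
        if self.qt_released_mean is not None:
            delta_qt_rate = {
                r: self.qt_released_mean[r] - self.qt_baseline_mean[r]
                for r in self.rates}
        else:
            delta_qt_rate = {
                r: (self.delta_qrs_mean + delta_tpe_base + hr_tpe[r]
                    + delta_qst_base + hr_qst[r])
                for r in self.rates}
        # Pooled per-burst corr(δ-QT, δ-QRS) mixes the patient-level
        # variance with the deterministic between-rate spread of the
        # δ-QT expectations; subtract the latter when sizing extra_i.
        d = np.array([delta_qt_rate[r] for r in self.rates])
        var_rate = float(d.var())  # equal weights over the ladder
        rho = self.rho_dqt_dqrs
        extra_var = self.delta_qrs_sd**2 * (1.0 / rho**2 - 1.0) - var_rate
        return {
            "delta_tpe_base": delta_tpe_base,
            "delta_qst_base": delta_qst_base,
            "delta_qt_rate": delta_qt_rate,
            "var_rate": var_rate,
            "extra_sd": math.sqrt(max(extra_var, 0.0)),
        }

    # -- (de)serialization --------------------------------------------

    def to_mapping(self) -> dict[str, Any]:
        out: dict[str, Any] = {}
        for f in fields(self):
            value = getattr(self, f.name)
            if isinstance(value, tuple):
                value = list(value)
            out[f.name] = value
        return out

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Any]) -> "GeneratorConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise GeneratorConfigError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(mapping)
        if "rates" in kwargs:
            kwargs["rates"] = tuple(int(r) for r in kwargs["rates"])
        for key in ("qt_baseline_mean", "qt_released_mean", "qt_sd_by_rate",
                    "delta_qst_highrate_mean", "delta_tpe_highrate_mean"):
            if kwargs.get(key) is not None:
                kwargs[key] = {int(r): float(v) for r, v in kwargs[key].items()}
        return cls(**kwargs)

    def config_hash(self) -> str:
        payload = repr(sorted(self.to_mapping().items())).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def _partition(qt: float, qrs: float, tpe: float) -> tuple[float, float]:
    """Split qt − qrs into (qrsend_tpeak, tpeak_tend), keeping both positive.

    tpe is nudged into range in the (rare) tail where the remainder would
    go non-positive.
    """
    lo, hi = _MIN_SUBINTERVAL_MS, qt - qrs - _MIN_SUBINTERVAL_MS
    if hi <= lo:
        raise GeneratorConfigError(
            f"cannot partition qt={qt:.1f} ms with qrs={qrs:.1f} ms")
    tpe = min(max(tpe, lo), hi)
    return qt - qrs - tpe, tpe


def generate_cohort(config: GeneratorConfig) -> Cohort:
    """Generate a validated two-phase cohort under the configured conditions.

    Deterministic given ``config.seed``; each patient consumes an
    independent RNG substream, and the sex and attrition draws use
    separate streams so toggling one knob never perturbs another
    patient's intervals.
    """
    config.validate()
    der = config.derived_parameters()
    f_between = config.qt_between_frac
    root = np.random.SeedSequence(config.seed)
    patient_seeds = root.spawn(config.n_patients)
    sex_rng = np.random.default_rng(
        np.random.SeedSequence(config.seed, spawn_key=(_SEX_STREAM_KEY,)))

    patients: list[PatientRecord] = []
    max_rate = max(config.rates)
    for i in range(config.n_patients):
        rng = np.random.default_rng(patient_seeds[i])
        pid = f"P{i + 1:03d}"
        sex = Sex.MALE if sex_rng.random() < config.sex_ratio else Sex.FEMALE
        z = rng.standard_normal()
        qrs_base = config.qrs_baseline_mean + config.qrs_baseline_sd * rng.standard_normal()
        qrs_base = max(qrs_base, _MIN_SUBINTERVAL_MS)
        dqrs = config.delta_qrs_mean + config.delta_qrs_sd * rng.standard_normal()
        extra = der["extra_sd"] * rng.standard_normal()

        bursts: list[PacingBurst] = []
        for r in config.rates:
            s_r = config.qt_sd_by_rate[r]
            within_sd = (config.qt_burst_sd if config.qt_burst_sd is not None
                         else math.sqrt(1.0 - f_between) * s_r)
            qt_base = (config.qt_baseline_mean[r]
                       + math.sqrt(f_between) * s_r * z
                       + within_sd * rng.standard_normal())
            qt_rel = qt_base + dqrs + extra + (der["delta_qt_rate"][r]
                                               - config.delta_qrs_mean)
            rr = 60.0 / r
            # Truncation guard for extreme tails (keeps QT < RR).
            qt_base = min(qt_base, rr * 1000.0 - 1.0)
            qt_rel = min(qt_rel, rr * 1000.0 - 1.0)

            tpe_b = (config.tpe_baseline_mean
                     + config.tpe_burst_sd * rng.standard_normal())
            qst_b, tpe_b = _partition(qt_base, qrs_base, tpe_b)
            bursts.append(PacingBurst(
                patient_id=pid, phase=Phase.BASELINE, rate_bpm=r, rr_s=rr,
                qrs_ms=qrs_base, qrsend_tpeak_ms=qst_b,
                tpeak_tend_ms=tpe_b, qt_ms=qt_base))

            tpe_mean_rel = (config.tpe_baseline_mean + der["delta_tpe_base"]
                            + config.delta_tpe_highrate_mean.get(r, 0.0))
            tpe_r = tpe_mean_rel + config.tpe_burst_sd * rng.standard_normal()
            qst_r, tpe_r = _partition(qt_rel, qrs_base + dqrs, tpe_r)
            bursts.append(PacingBurst(
                patient_id=pid, phase=Phase.RELEASED, rate_bpm=r, rr_s=rr,
                qrs_ms=qrs_base + dqrs, qrsend_tpeak_ms=qst_r,
                tpeak_tend_ms=tpe_r, qt_ms=qt_rel))

        patients.append(PatientRecord(
            patient_id=pid, sex=sex,
            wenckebach_bpm={Phase.BASELINE: max_rate, Phase.RELEASED: max_rate},
            bursts=bursts))

    cohort = Cohort(patients=patients,
                    provenance=f"qtdyn.generate_cohort seed={config.seed} "
                               f"config={config.config_hash()}")
    if config.p_av_block > 0 or config.wenckebach_released_drop > 0:
        cohort = apply_attrition(cohort, config)
    cohort.validate(tol=GENERATED_TOL_MS)
    return cohort


def apply_attrition(cohort: Cohort, config: GeneratorConfig) -> Cohort:
    """Apply post-release patient losses to the released phase only.

    With probability ``p_av_block`` a patient develops third-degree AV
    block after valve release and loses the whole released phase;
    otherwise, with probability ``wenckebach_released_drop`` the released
    Wenckebach point falls and the released rate ladder is truncated at a
    random lower cap. Baseline bursts are never altered. Decisions come
    from a dedicated RNG substream of ``config.seed`` with a fixed number
    of draws per patient, so they are stable across unrelated config
    changes.
    """
    for name in ("p_av_block", "wenckebach_released_drop"):
        if not 0.0 <= getattr(config, name) <= 1.0:
            raise GeneratorConfigError(f"{name} must be in [0, 1]")
    rng = np.random.default_rng(
        np.random.SeedSequence(config.seed, spawn_key=(_ATTRITION_STREAM_KEY,)))
    rates = sorted(config.rates)
    patients: list[PatientRecord] = []
    for patient in cohort.patients:
        u_block = rng.random()
        u_drop = rng.random()
        cap_idx = int(rng.integers(0, max(len(rates) - 1, 1)))
        released_cap: int | None = patient.wenckebach_bpm.get(Phase.RELEASED)
        if u_block < config.p_av_block:
            released_cap = None
        elif u_drop < config.wenckebach_released_drop:
            released_cap = rates[cap_idx]
        kept = [b for b in patient.bursts
                if b.phase is Phase.BASELINE
                or (released_cap is not None and b.rate_bpm <= released_cap)]
        wenckebach = dict(patient.wenckebach_bpm)
        if released_cap is None:
            wenckebach.pop(Phase.RELEASED, None)
        else:
            wenckebach[Phase.RELEASED] = released_cap
        patients.append(PatientRecord(
            patient_id=patient.patient_id, sex=patient.sex,
            wenckebach_bpm=wenckebach, bursts=kept))
    return Cohort(patients=patients,
                  provenance=cohort.provenance + " +attrition")
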