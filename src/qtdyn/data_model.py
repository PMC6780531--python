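"""Domain types, invariant checking and tidy-CSV serialization.

The unit conventions are fixed once here and used everywhere else:
all ECG interval durations are stored in **milliseconds**; the cycle
length (RR) is carried in **seconds** next to the pacing rate in bpm.
Mixing the two is the classic source of silent bugs with the linear
rate-correction formulas, so no other module converts units on its own.
"""

from __future__ import annotations

import enum
import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd

__all__ = [
    "Phase",
    "Sex",
    "PacingBurst",
    "PatientRecord",
    "Cohort",
    "ValidationError",
    "CohortParseError",
    "PACING_RATES_BPM",
    "CSV_COLUMNS",
    "read_cohort",
    "write_cohort",
    "average_burst",
]

#: Pacing-rate ladder of the two-phase AAI protocol: 50-120 bpm in 10-bpm steps.
PACING_RATES_BPM: tuple[int, ...] = tuple(range(50, 121, 10))

#: Fixed tidy-CSV header (one row per pacing burst).
CSV_COLUMNS: tuple[str, ...] = (
    "patient_id",
    "sex",
    "phase",
    "rate_bpm",
    "rr_s",
    "qrs_ms",
    "qrsend_tpeak_ms",
    "tpeak_tend_ms",
    "qt_ms",
)

#: Default sum-decomposition tolerance for manually measured data, ms.
MEASURED_TOL_MS = 5.0
#: Tolerance for generator output, where qt = qrs + qrsend_tpeak + tpeak_tend
#: holds by construction.
GENERATED_TOL_MS = 1e-6

_RR_TOL_S = 1e-9


class ValidationError(ValueError):
    """A burst or cohort violates a structural invariant."""


class CohortParseError(ValueError):
    """A cohort CSV is malformed (bad header, unparseable row)."""


class Phase(str, enum.Enum):
    """Protocol phase: before (baseline) vs immediately after (released)
    deployment of the self-expanding aortic prosthesis."""

    BASELINE = "baseline"
    RELEASED = "released"


class Sex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"


@dataclass(frozen=True)
class PacingBurst:
    """Averaged interval measurements for one stimulation burst.

    One burst = continuous AAI pacing at a fixed rate; the stored values
    are means over a few stabilized beats (see :func:`average_burst`).
    """

    patient_id: str
    phase: Phase
    rate_bpm: int
    rr_s: float
    qrs_ms: float
    qrsend_tpeak_ms: float
    tpeak_tend_ms: float
    qt_ms: float

    def validate(self, tol: float = MEASURED_TOL_MS) -> None:
        """Raise :class:`ValidationError` on any invariant violation.

        tol is the allowed mismatch (ms) between qt and the sum of its
        three sub-intervals; manual caliper measurements are not exactly
        additive, generated truth is.
        """
        ctx = f"patient {self.patient_id!r}, {self.phase.value}, {self.rate_bpm} bpm"
        if self.rate_bpm not in PACING_RATES_BPM:
            raise ValidationError(
                f"{ctx}: rate_bpm must be one of {PACING_RATES_BPM}"
            )
        if abs(self.rr_s - 60.0 / self.rate_bpm) > _RR_TOL_S:
            raise ValidationError(
                f"{ctx}: rr_s={self.rr_s!r} inconsistent with 60/rate_bpm"
            )
        for name in ("qrs_ms", "qrsend_tpeak_ms", "tpeak_tend_ms", "qt_ms"):
            value = getattr(self, name)
            if not value > 0:
                raise ValidationError(f"{ctx}: {name}={value!r} must be > 0")
        if not self.qt_ms < self.rr_s * 1000.0:
            raise ValidationError(
                f"{ctx}: qt_ms={self.qt_ms!r} must be shorter than the cycle "
                f"length ({self.rr_s * 1000.0:.1f} ms)"
            )
        mismatch = abs(
            self.qt_ms - (self.qrs_ms + self.qrsend_tpeak_ms + self.tpeak_tend_ms)
        )
        if mismatch > tol:
            raise ValidationError(
                f"{ctx}: qt differs from qrs + qrsend_tpeak + tpeak_tend by "
                f"{mismatch:.3f} ms (tol {tol} ms)"
            )


@dataclass
class PatientRecord:
    """One patient's paired burst sets across the two protocol phases.

    wenckebach_bpm maps each phase to the highest pacing rate with 1:1
    atrio-ventricular conduction; bursts never exceed it.
    """

    patient_id: str
    sex: Sex
    wenckebach_bpm: dict[Phase, int]
    bursts: list[PacingBurst] = field(default_factory=list)

    def validate(self, tol: float = MEASURED_TOL_MS) -> None:
        seen: set[tuple[Phase, int]] = set()
        for burst in self.bursts:
            if burst.patient_id != self.patient_id:
                raise ValidationError(
                    f"patient {self.patient_id!r}: burst carries foreign id "
                    f"{burst.patient_id!r}"
                )
            key = (burst.phase, burst.rate_bpm)
            if key in seen:
                raise ValidationError(
                    f"patient {self.patient_id!r}: duplicate burst at "
                    f"{burst.phase.value}/{burst.rate_bpm} bpm"
                )
            seen.add(key)
            cap = self.wenckebach_bpm.get(burst.phase)
            if cap is not None and burst.rate_bpm > cap:
                raise ValidationError(
                    f"patient {self.patient_id!r}: {burst.phase.value} burst at "
                    f"{burst.rate_bpm} bpm exceeds Wenckebach point {cap} bpm"
                )
            burst.validate(tol=tol)

    def phase_bursts(self, phase: Phase) -> list[PacingBurst]:
        return [b for b in self.bursts if b.phase is phase]

    def burst_at(self, phase: Phase, rate_bpm: int) -> PacingBurst | None:
        for b in self.bursts:
            if b.phase is phase and b.rate_bpm == rate_bpm:
                return b
        return None


@dataclass
class Cohort:
    """A collection of patients plus free-text provenance metadata."""

    patients: list[PatientRecord]
    provenance: str = ""

    def __iter__(self) -> Iterator[PatientRecord]:
        return iter(self.patients)

    def __len__(self) -> int:
        return len(self.patients)

    @property
    def n_bursts(self) -> int:
        return sum(len(p.bursts) for p in self.patients)

    def validate(self, tol: float = MEASURED_TOL_MS) -> None:
        if not self.patients:
            raise ValidationError("cohort has no patients")
        ids = [p.patient_id for p in self.patients]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate patient ids: {dupes}")
        for patient in self.patients:
            patient.validate(tol=tol)

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format view, one row per burst, deterministic order."""
        rows = []
        for patient in self.patients:
            for b in patient.bursts:
                rows.append(
                    {
                        "patient_id": patient.patient_id,
                        "sex": patient.sex.value,
                        "phase": b.phase.value,
                        "rate_bpm": b.rate_bpm,
                        "rr_s": b.rr_s,
                        "qrs_ms": b.qrs_ms,
                        "qrsend_tpeak_ms": b.qrsend_tpeak_ms,
                        "tpeak_tend_ms": b.tpeak_tend_ms,
                        "qt_ms": b.qt_ms,
                    }
                )
        frame = pd.DataFrame(rows, columns=list(CSV_COLUMNS))
        if not frame.empty:
            frame = frame.sort_values(
                ["patient_id", "phase", "rate_bpm"], kind="mergesort"
            ).reset_index(drop=True)
        return frame


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def read_cohort(path: str | Path, tol: float = MEASURED_TOL_MS) -> Cohort:
    """Read a tidy burst-level CSV into a validated :class:`Cohort`.

    Each row becomes one :class:`PacingBurst`. The Wenckebach point is not
    a CSV column; it is inferred per phase as the highest rate present.

    Raises :class:`CohortParseError` for malformed input (naming the
    offending line) and :class:`ValidationError` for invariant violations.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, dtype={"patient_id": str},
                            float_precision="round_trip")
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise CohortParseError(f"{path}: {exc}") from exc
    if list(frame.columns) != list(CSV_COLUMNS):
        raise CohortParseError(
            f"{path}: header must be {','.join(CSV_COLUMNS)!r}, "
            f"got {','.join(map(str, frame.columns))!r}"
        )

    patients: dict[str, PatientRecord] = {}
    for idx, row in frame.iterrows():
        line_no = idx + 2  # header is line 1
        try:
            sex = Sex(str(row["sex"]))
            phase = Phase(str(row["phase"]))
            burst = PacingBurst(
                patient_id=str(row["patient_id"]),
                phase=phase,
                rate_bpm=int(row["rate_bpm"]),
                rr_s=float(row["rr_s"]),
                qrs_ms=float(row["qrs_ms"]),
                qrsend_tpeak_ms=float(row["qrsend_tpeak_ms"]),
                tpeak_tend_ms=float(row["tpeak_tend_ms"]),
                qt_ms=float(row["qt_ms"]),
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise CohortParseError(f"{path}, line {line_no}: {exc}") from exc
        record = patients.get(burst.patient_id)
        if record is None:
            record = PatientRecord(
                patient_id=burst.patient_id, sex=sex, wenckebach_bpm={}, bursts=[]
            )
            patients[record.patient_id] = record
        elif record.sex is not sex:
            raise CohortParseError(
                f"{path}, line {line_no}: patient {burst.patient_id!r} changes sex"
            )
        record.bursts.append(burst)

    for record in patients.values():
        record.wenckebach_bpm = {
            phase: max(b.rate_bpm for b in record.phase_bursts(phase))
            for phase in Phase
            if record.phase_bursts(phase)
        }
    cohort = Cohort(patients=list(patients.values()), provenance=str(path))
    cohort.validate(tol=tol)
    return cohort


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort as tidy CSV with deterministic row order.

    Rows are sorted by (patient_id, phase, rate_bpm); floats keep full
    round-trip precision, so writing the same cohort twice is
    byte-identical and read∘write is the identity.
    """
    frame = cohort.to_frame()
    buf = io.StringIO()
    frame.to_csv(buf, index=False, lineterminator="\n")
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


# ---------------------------------------------------------------------------
# Burst averaging
# ---------------------------------------------------------------------------

def average_burst(
    beat_intervals: Sequence[Mapping[str, float]],
    n_skip: int = 10,
    n_avg: int = 3,
) -> dict[str, float]:
    """Average per-beat interval measurements into burst-level values.

    The first ``n_skip`` beats of a pacing burst are discarded so ECG
    intervals stabilize at the new rate, then the next ``n_avg``
    consecutive beats are averaged (defaults: skip 10, average 3).

    Parameters
    ----------
    beat_intervals
        Ordered per-beat measurements; each element maps interval names
        (e.g. ``qt_ms``) to values. All beats must share the same keys.

    Returns
    -------
    dict mapping each interval name to the arithmetic mean over beats
    ``n_skip + 1 .. n_skip + n_avg``.
    """
    if n_skip < 0 or n_avg < 1:
        raise ValueError("need n_skip >= 0 and n_avg >= 1")
    required = n_skip + n_avg
    if len(beat_intervals) < required:
        raise ValueError(
            f"need at least {required} beats (n_skip={n_skip} + n_avg={n_avg}), "
            f"got {len(beat_intervals)}"
        )
    window = beat_intervals[n_skip : n_skip + n_avg]
    keys = window[0].keys()
    for beat in window:
        if beat.keys() != keys:
            raise ValueError("beats carry inconsistent interval names")
    return {k: sum(beat[k] for beat in window) / n_avg for k in keys}
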