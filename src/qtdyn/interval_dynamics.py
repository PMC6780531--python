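"""Derived interval statistics: the QT60 reference, QTc deviations and
paired released-minus-baseline (δ) contrasts.

The accuracy of a rate-correction formula is judged against QT60 — the QT
actually measured while pacing at 60 bpm — via

    qtc_deviation = QT60 − QTc,

so negative values mean the formula overestimates relative to the 60-bpm
reference. δ quantities are released-phase minus baseline-phase values
matched within patient at the same pacing rate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterator

import pandas as pd

from .data_model import Cohort, PacingBurst, PatientRecord, Phase
from .qtc_formulas import RATE_FORMULAS, Formula, correct_burst

__all__ = [
    "DeviationRecord",
    "PhaseContrast",
    "ContrastResult",
    "qt60_reference",
    "qtc_deviation",
    "phase_contrast",
    "deltas_frame",
    "CONTRAST_QUANTITIES",
]

logger = logging.getLogger("qtdyn")

_RAW_QUANTITIES = {
    "qt": "qt_ms",
    "qrs": "qrs_ms",
    "qrsend_tpeak": "qrsend_tpeak_ms",
    "tpeak_tend": "tpeak_tend_ms",
}
_FORMULA_SHORT = {
    Formula.BAZETT: "bzt",
    Formula.FRIDERICIA: "frd",
    Formula.FRAMINGHAM: "frm",
    Formula.HODGES: "hdg",
    Formula.RAUTAHARJU: "rau",
}
_SHORT_TO_FORMULA = {v: k for k, v in _FORMULA_SHORT.items()}

#: Every quantity :func:`phase_contrast` understands.
CONTRAST_QUANTITIES: tuple[str, ...] = tuple(
    list(_RAW_QUANTITIES)
    + [f"qtc_{s}" for s in _SHORT_TO_FORMULA]
    + [f"qtc_deviation_{_FORMULA_SHORT[f]}" for f in RATE_FORMULAS]
)


@dataclass(frozen=True)
class DeviationRecord:
    """QT60 − QTc for one burst under one correction formula."""

    patient_id: str
    phase: Phase
    formula: Formula
    rate_bpm: int
    qtc_deviation_ms: float


@dataclass(frozen=True)
class PhaseContrast:
    """Released − baseline difference of a quantity, within patient/rate."""

    patient_id: str
    rate_bpm: int
    quantity: str
    delta_ms: float


@dataclass
class ContrastResult:
    """Phase contrasts plus a log of unpaired (skipped) patient/rates."""

    contrasts: list[PhaseContrast]
    skipped: list[tuple[str, int, str]]

    def __iter__(self) -> Iterator[PhaseContrast]:
        return iter(self.contrasts)

    def __len__(self) -> int:
        return len(self.contrasts)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "patient_id": c.patient_id,
                    "rate_bpm": c.rate_bpm,
                    "quantity": c.quantity,
                    "delta_ms": c.delta_ms,
                }
                for c in self.contrasts
            ],
            columns=["patient_id", "rate_bpm", "quantity", "delta_ms"],
        )


def qt60_reference(
    patient: PatientRecord, phase: Phase, interpolate: bool = False
) -> float:
    """The patient's measured QT at 60 bpm in the given phase, ms.

    If several 60-bpm bursts exist their mean is returned. When the
    60-bpm rung is missing and ``interpolate`` is true, QT60 is linearly
    interpolated from the 50- and 70-bpm bursts; otherwise an error names
    the patient and phase.
    """
    bursts = [b for b in patient.phase_bursts(phase) if b.rate_bpm == 60]
    if bursts:
        return sum(b.qt_ms for b in bursts) / len(bursts)
    if interpolate:
        lo = patient.burst_at(phase, 50)
        hi = patient.burst_at(phase, 70)
        if lo is not None and hi is not None:
            return 0.5 * (lo.qt_ms + hi.qt_ms)
    raise ValueError(
        f"patient {patient.patient_id!r} has no 60-bpm burst in the "
        f"{phase.value} phase (interpolation "
        f"{'failed: need 50- and 70-bpm bursts' if interpolate else 'disabled'})"
    )


def qtc_deviation(
    patient: PatientRecord,
    phase: Phase,
    formula: Formula | str,
    interpolate: bool = False,
) -> list[DeviationRecord]:
    """QT60 − QTc for every burst of one patient-phase.

    For the rate-only formulas the record at 60 bpm is identically zero.
    """
    formula = Formula(formula)
    qt60 = qt60_reference(patient, phase, interpolate=interpolate)
    records = []
    for burst in patient.phase_bursts(phase):
        qtc = correct_burst(burst, formula, sex=patient.sex).qtc_ms
        records.append(
            DeviationRecord(
                patient_id=patient.patient_id,
                phase=phase,
                formula=formula,
                rate_bpm=burst.rate_bpm,
                qtc_deviation_ms=qt60 - qtc,
            )
        )
    return records


def _burst_quantity(burst: PacingBurst, patient: PatientRecord, quantity: str) -> float:
    if quantity in _RAW_QUANTITIES:
        return getattr(burst, _RAW_QUANTITIES[quantity])
    if quantity.startswith("qtc_deviation_"):
        formula = _SHORT_TO_FORMULA[quantity.removeprefix("qtc_deviation_")]
        qt60 = qt60_reference(patient, burst.phase)
        return qt60 - correct_burst(burst, formula, sex=patient.sex).qtc_ms
    if quantity.startswith("qtc_"):
        formula = _SHORT_TO_FORMULA[quantity.removeprefix("qtc_")]
        return correct_burst(burst, formula, sex=patient.sex).qtc_ms
    raise ValueError(
        f"unknown quantity {quantity!r}; expected one of {CONTRAST_QUANTITIES}"
    )


def phase_contrast(cohort: Cohort, quantity: str) -> ContrastResult:
    """Released − baseline contrasts of a quantity, matched within patient
    at the same pacing rate.

    Patient/rates lacking either phase are skipped, logged and counted in
    the result's ``skipped`` list — never silently dropped. For the
    deviation quantities, patients missing a 60-bpm rung in a phase skip
    all of that phase's rates.
    """
    if quantity not in CONTRAST_QUANTITIES:
        raise ValueError(
            f"unknown quantity {quantity!r}; expected one of {CONTRAST_QUANTITIES}"
        )
    contrasts: list[PhaseContrast] = []
    skipped: list[tuple[str, int, str]] = []
    for patient in cohort:
        rates = sorted(
            {b.rate_bpm for b in patient.bursts}
        )
        for rate in rates:
            base = patient.burst_at(Phase.BASELINE, rate)
            rel = patient.burst_at(Phase.RELEASED, rate)
            if base is None or rel is None:
                missing = Phase.BASELINE if base is None else Phase.RELEASED
                skipped.append(
                    (patient.patient_id, rate, f"no {missing.value} burst")
                )
                continue
            try:
                delta = _burst_quantity(rel, patient, quantity) - _burst_quantity(
                    base, patient, quantity
                )
            except ValueError as exc:  # e.g. missing QT60 rung
                skipped.append((patient.patient_id, rate, str(exc)))
                continue
            contrasts.append(
                PhaseContrast(
                    patient_id=patient.patient_id,
                    rate_bpm=rate,
                    quantity=quantity,
                    delta_ms=delta,
                )
            )
    for pid, rate, reason in skipped:
        logger.info("phase_contrast(%s): skipped %s @ %d bpm (%s)",
                    quantity, pid, rate, reason)
    return ContrastResult(contrasts=contrasts, skipped=skipped)


def deltas_frame(cohort: Cohort, quantities: tuple[str, ...] | None = None) -> pd.DataFrame:
    """Long-format table of phase contrasts for several quantities.

    Columns: patient_id, rate_bpm, quantity, delta_ms.
    """
    quantities = quantities or CONTRAST_QUANTITIES
    frames = [phase_contrast(cohort, q).to_frame() for q in quantities]
    return pd.concat(frames, ignore_index=True)


def mean_delta(result: ContrastResult, patient_first: bool = False) -> float:
    """Cohort mean of a contrast, burst-level by default.

    ``patient_first`` switches to patient-mean-of-means averaging (each
    patient weighted equally regardless of ladder length).
    """
    frame = result.to_frame()
    if frame.empty:
        raise ValueError("no paired contrasts to average")
    if patient_first:
        return float(frame.groupby("patient_id")["delta_ms"].mean().mean())
    return float(frame["delta_ms"].mean())
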