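"""QT rate-correction formulas, plus the Rautaharju dual rate+QRS correction.

All functions take QT in milliseconds and the cycle length RR in seconds
and return a corrected QT in milliseconds. The linear formulas are often
quoted with second-based constants (0.154, 0.00175); dimensional analysis
shows those coefficients pair with QT in seconds, so with millisecond QT
they become 154 ms per second of RR shortening (Framingham) and 1.75 ms
per bpm above 60 (Hodges). All four rate-only corrections are the identity
at 60 bpm (RR = 1 s) by construction.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from .data_model import PacingBurst, Sex

__all__ = [
    "Formula",
    "CorrectionResult",
    "RATE_FORMULAS",
    "bazett",
    "fridericia",
    "framingham",
    "hodges",
    "rautaharju_dual",
    "correct_burst",
]


class Formula(str, enum.Enum):
    BAZETT = "bazett"
    FRIDERICIA = "fridericia"
    FRAMINGHAM = "framingham"
    HODGES = "hodges"
    RAUTAHARJU = "rautaharju"


#: The four heart-rate-only corrections (no QRS term).
RATE_FORMULAS: tuple[Formula, ...] = (
    Formula.BAZETT,
    Formula.FRIDERICIA,
    Formula.FRAMINGHAM,
    Formula.HODGES,
)

#: Rautaharju sex constant k, ms.
RAUTAHARJU_K_MS = {Sex.MALE: 22.0, Sex.FEMALE: 34.0}


@dataclass(frozen=True)
class CorrectionResult:
    """A corrected QT value together with the inputs that produced it."""

    formula: Formula
    qtc_ms: float
    qt_ms: float
    rr_s: float
    qrs_ms: float | None = None
    sex: Sex | None = None

    def __post_init__(self) -> None:
        if not self.qtc_ms > 0:
            raise ValueError(f"qtc_ms must be > 0, got {self.qtc_ms!r}")
        dual = self.formula is Formula.RAUTAHARJU
        if dual and (self.qrs_ms is None or self.sex is None):
            raise ValueError("rautaharju result requires qrs_ms and sex")
        if not dual and (self.qrs_ms is not None or self.sex is not None):
            raise ValueError(
                f"{self.formula.value} result must not carry qrs_ms/sex"
            )


def _check_positive(qt_ms: float, rr_s: float) -> None:
    if not qt_ms > 0:
        raise ValueError(f"qt_ms must be > 0, got {qt_ms!r}")
    if not rr_s > 0:
        raise ValueError(f"rr_s must be > 0, got {rr_s!r}")


def bazett(qt_ms: float, rr_s: float) -> float:
    """QTc = QT / RR^(1/2)."""
    _check_positive(qt_ms, rr_s)
    return qt_ms / rr_s ** 0.5


def fridericia(qt_ms: float, rr_s: float) -> float:
    """QTc = QT / RR^(1/3)."""
    _check_positive(qt_ms, rr_s)
    return qt_ms / rr_s ** (1.0 / 3.0)


def framingham(qt_ms: float, rr_s: float) -> float:
    """QTc = QT + 154·(1 − RR), RR in seconds, QT in ms."""
    _check_positive(qt_ms, rr_s)
    return qt_ms + 154.0 * (1.0 - rr_s)


def hodges(qt_ms: float, rr_s: float) -> float:
    """QTc = QT + 1.75·(HR − 60) with HR = 60/RR in bpm."""
    _check_positive(qt_ms, rr_s)
    return qt_ms + 1.75 * (60.0 / rr_s - 60.0)


def rautaharju_dual(
    qt_ms: float, rate_bpm: float, qrs_ms: float, sex: Sex | str
) -> float:
    """Dual rate + QRS adjustment for prolonged ventricular depolarization.

    QT_RR,QRS = QT − 155·(60/HR − 1) − 0.93·(QRS − 139) + k,
    with k = 22 ms for men and 34 ms for women. Both adjustment terms
    vanish at 60 bpm with a 139-ms QRS.
    """
    if not qt_ms > 0 or not qrs_ms > 0:
        raise ValueError("qt_ms and qrs_ms must be > 0")
    if not rate_bpm > 0:
        raise ValueError(f"rate_bpm must be > 0, got {rate_bpm!r}")
    try:
        k = RAUTAHARJU_K_MS[Sex(sex)]
    except ValueError as exc:
        raise ValueError(f"unknown sex label {sex!r}") from exc
    return qt_ms - 155.0 * (60.0 / rate_bpm - 1.0) - 0.93 * (qrs_ms - 139.0) + k


_RATE_DISPATCH = {
    Formula.BAZETT: bazett,
    Formula.FRIDERICIA: fridericia,
    Formula.FRAMINGHAM: framingham,
    Formula.HODGES: hodges,
}


def correct_burst(
    burst: PacingBurst,
    formula: Formula | str,
    sex: Sex | str | None = None,
) -> CorrectionResult:
    """Apply a correction formula to one pacing burst.

    For the Rautaharju dual correction the heart rate is taken as
    60/rr_s of the burst itself (never supplied independently) and
    ``sex`` is required.
    """
    formula = Formula(formula)
    if formula is Formula.RAUTAHARJU:
        if sex is None:
            raise ValueError("rautaharju correction requires the patient's sex")
        sex = Sex(sex)
        qtc = rautaharju_dual(
            burst.qt_ms, 60.0 / burst.rr_s, burst.qrs_ms, sex
        )
        return CorrectionResult(
            formula=formula,
            qtc_ms=qtc,
            qt_ms=burst.qt_ms,
            rr_s=burst.rr_s,
            qrs_ms=burst.qrs_ms,
            sex=sex,
        )
    qtc = _RATE_DISPATCH[formula](burst.qt_ms, burst.rr_s)
    return CorrectionResult(
        formula=formula, qtc_ms=qtc, qt_ms=burst.qt_ms, rr_s=burst.rr_s
    )
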