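"""End-to-end study orchestration and report generation.

``run_study`` composes the full pipeline — simulate → correct → contrast
→ infer — and assembles three analogues of the study's summary outputs:

* an interval table (per-quantity baseline/released means ± SD and the
  paired δ with cluster-bootstrap CI95),
* a formula-accuracy table (per-formula QTc deviation from QT60 in both
  phases, with CI95 and the correlation of QTc with QT60),
* rate-trend tables (linear slope of δ quantities and QTc deviations on
  pacing rate).

``equal_weight_table2_oracle`` is an independent desk check: it applies
each formula directly to printed per-rate QT means with equal weights,
bypassing the generator and the pipeline entirely.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd

from . import __version__
from .data_model import Cohort, Phase, write_cohort
from .interval_dynamics import deltas_frame, phase_contrast, qt60_reference, qtc_deviation
from .cluster_inference import (
    BootstrapSummary,
    _pearson_statistic,
    cluster_bootstrap,
    rate_trend,
)
from .qtc_formulas import RATE_FORMULAS, Formula, correct_burst
from .synthetic_cohort import GeneratorConfig, generate_cohort

__all__ = [
    "StudyReport",
    "run_study",
    "corrections_frame",
    "equal_weight_table2_oracle",
    "equal_weight_deviation_oracle",
]

_TABLE2_QUANTITIES = (
    "qrs", "qt", "qrsend_tpeak", "tpeak_tend",
    "qtc_bzt", "qtc_frd", "qtc_frm", "qtc_hdg",
)
_FORMULA_SHORT = {
    Formula.BAZETT: "bzt", Formula.FRIDERICIA: "frd",
    Formula.FRAMINGHAM: "frm", Formula.HODGES: "hdg",
}


@dataclass
class StudyReport:
    """All study-level outputs plus reproducibility metadata."""

    table2_analogue: pd.DataFrame
    table4_analogue: pd.DataFrame
    trend_tables: pd.DataFrame
    metadata: dict[str, Any] = field(default_factory=dict)

    def to_markdown(self) -> str:
        """Human-readable report, intervals rounded to 0.1 ms."""
        def fmt(frame: pd.DataFrame) -> str:
            shown = frame.copy()
            for col in shown.columns:
                if shown[col].dtype.kind == "f":
                    shown[col] = shown[col].round(1)
            return shown.to_string(index=False)

        meta = "\n".join(f"- {k}: {v}" for k, v in sorted(self.metadata.items()))
        return (
            "# Paced-cohort QT dynamics report\n\n"
            f"## Run metadata\n\n{meta}\n\n"
            "## Interval summary (baseline vs released)\n\n"
            f"{fmt(self.table2_analogue)}\n\n"
            "## Formula accuracy vs QT60\n\n"
            "qtc_deviation = QT60 - QTc; negative values mean the formula\n"
            "overestimates relative to the 60-bpm reference.\n\n"
            f"{fmt(self.table4_analogue)}\n\n"
            "## Rate trends\n\n"
            f"{fmt(self.trend_tables)}\n"
        )


def corrections_frame(
    cohort: Cohort,
    formulas: tuple[Formula | str, ...] = RATE_FORMULAS,
) -> pd.DataFrame:
    """Long-format corrected QT table: one row per burst × formula."""
    rows = []
    for patient in cohort:
        for burst in patient.bursts:
            for formula in formulas:
                result = correct_burst(burst, Formula(formula), sex=patient.sex)
                rows.append({
                    "patient_id": patient.patient_id,
                    "phase": burst.phase.value,
                    "rate_bpm": burst.rate_bpm,
                    "formula": result.formula.value,
                    "qt_ms": burst.qt_ms,
                    "rr_s": burst.rr_s,
                    "qtc_ms": result.qtc_ms,
                })
    return pd.DataFrame(rows, columns=[
        "patient_id", "phase", "rate_bpm", "formula", "qt_ms", "rr_s", "qtc_ms"])


def _delta_bootstrap(cohort: Cohort, quantity: str, n_boot: int, seed: int):
    result = phase_contrast(cohort, quantity)
    frame = result.to_frame()
    clusters = {pid: grp["delta_ms"].to_numpy()
                for pid, grp in frame.groupby("patient_id")}
    summary = cluster_bootstrap(
        clusters, "mean", n_boot=n_boot, seed=seed,
        statistic_label=f"mean_delta_{quantity}")
    return result, summary


def _phase_values(cohort: Cohort, quantity_col: str, phase: Phase) -> pd.Series:
    rows = []
    for patient in cohort:
        for burst in patient.phase_bursts(phase):
            rows.append(getattr(burst, quantity_col))
    return pd.Series(rows, dtype=float)


def run_study(
    config: GeneratorConfig,
    n_boot: int = 2000,
    seed: int | None = None,
    outdir: str | Path | None = None,
    patient_first: bool = False,
) -> StudyReport:
    """Run the full pipeline on one synthetic cohort.

    ``seed`` drives the inference resampling (defaults to
    ``config.seed``); the cohort itself is generated from
    ``config.seed``. Deterministic given both. When ``outdir`` is set,
    writes ``cohort.csv``, ``qtc.csv``, ``deltas.csv``, ``inference.csv``
    and ``report.md`` there.

    ``patient_first`` switches the phase-contrast means from burst-level
    averaging (every paired tracing counts once) to patient-first
    averaging (every patient counts once).
    """
    if seed is None:
        seed = config.seed
    seed_counter = iter(range(seed, seed + 10_000))

    cohort = generate_cohort(config)
    qtc = corrections_frame(cohort)
    deltas = deltas_frame(cohort)

    # Interval summary with paired deltas ------------------------------
    raw_cols = {"qt": "qt_ms", "qrs": "qrs_ms",
                "qrsend_tpeak": "qrsend_tpeak_ms", "tpeak_tend": "tpeak_tend_ms"}
    table2_rows = []
    inference_rows = []
    for quantity in _TABLE2_QUANTITIES:
        result, summary = _delta_bootstrap(cohort, quantity, n_boot, next(seed_counter))
        frame = result.to_frame()
        if patient_first:
            delta_mean = float(frame.groupby("patient_id")["delta_ms"].mean().mean())
        else:
            delta_mean = float(frame["delta_ms"].mean())
        if quantity in raw_cols:
            base = _phase_values(cohort, raw_cols[quantity], Phase.BASELINE)
            rel = _phase_values(cohort, raw_cols[quantity], Phase.RELEASED)
        else:
            short = quantity.removeprefix("qtc_")
            sel = qtc[qtc["formula"].map(
                lambda f: _FORMULA_SHORT[Formula(f)] == short)]
            base = sel.loc[sel["phase"] == "baseline", "qtc_ms"]
            rel = sel.loc[sel["phase"] == "released", "qtc_ms"]
        table2_rows.append({
            "quantity": quantity,
            "baseline_mean_ms": base.mean(), "baseline_sd_ms": base.std(ddof=1),
            "released_mean_ms": rel.mean(), "released_sd_ms": rel.std(ddof=1),
            "delta_ms": delta_mean,
            "delta_ci_low": summary.ci_low, "delta_ci_high": summary.ci_high,
            "delta_p": summary.p_value,
            "n_pairs": len(result), "n_skipped": len(result.skipped),
        })
        inference_rows.append({
            "statistic": summary.statistic_label, "estimate": summary.estimate,
            "ci_low": summary.ci_low, "ci_high": summary.ci_high,
            "p_value": summary.p_value, "n_boot": summary.n_boot,
            "seed": summary.seed,
        })
    table2 = pd.DataFrame(table2_rows)

    # Formula accuracy vs QT60 -----------------------------------------
    table4_rows = []
    for formula in RATE_FORMULAS:
        for phase in Phase:
            dev_clusters: dict[str, list[float]] = {}
            corr_clusters: dict[str, list[tuple[float, float]]] = {}
            for patient in cohort:
                if not patient.phase_bursts(phase):
                    continue
                try:
                    qt60 = qt60_reference(patient, phase)
                except ValueError:
                    continue  # no 60-bpm rung (e.g. Wenckebach truncation)
                records = qtc_deviation(patient, phase, formula)
                dev_clusters[patient.patient_id] = [
                    r.qtc_deviation_ms for r in records]
                corr_clusters[patient.patient_id] = [
                    (correct_burst(b, formula, sex=patient.sex).qtc_ms, qt60)
                    for b in patient.phase_bursts(phase)]
            dev_summary = cluster_bootstrap(
                dev_clusters, "mean", n_boot=n_boot, seed=next(seed_counter),
                statistic_label=f"qtc_deviation_{_FORMULA_SHORT[formula]}_{phase.value}")
            corr_label = f"corr_qtc_qt60_{_FORMULA_SHORT[formula]}_{phase.value}"
            corr_seed = next(seed_counter)
            try:
                corr_summary = cluster_bootstrap(
                    corr_clusters, _pearson_statistic, n_boot=n_boot,
                    seed=corr_seed, statistic_label=corr_label)
            except (ValueError, RuntimeError):
                # degenerate cohort (e.g. QT60 constant across patients)
                nan = float("nan")
                corr_summary = BootstrapSummary(
                    estimate=nan, ci_low=nan, ci_high=nan, p_value=nan,
                    n_boot=n_boot, seed=corr_seed, statistic_label=corr_label)
            table4_rows.append({
                "formula": formula.value, "phase": phase.value,
                "qtc_deviation_ms": dev_summary.estimate,
                "dev_ci_low": dev_summary.ci_low,
                "dev_ci_high": dev_summary.ci_high,
                "corr_qt60": corr_summary.estimate,
                "corr_ci_low": corr_summary.ci_low,
                "corr_ci_high": corr_summary.ci_high,
            })
            for summary in (dev_summary, corr_summary):
                inference_rows.append({
                    "statistic": summary.statistic_label,
                    "estimate": summary.estimate, "ci_low": summary.ci_low,
                    "ci_high": summary.ci_high, "p_value": summary.p_value,
                    "n_boot": summary.n_boot, "seed": summary.seed,
                })
    table4 = pd.DataFrame(table4_rows)

    # Rate trends ------------------------------------------------------
    trend_rows = []
    trend_quantities = ["qrs", "qrsend_tpeak", "tpeak_tend"] + [
        f"qtc_deviation_{_FORMULA_SHORT[f]}" for f in RATE_FORMULAS]
    for quantity in trend_quantities:
        frame = phase_contrast(cohort, quantity).to_frame()
        trend = rate_trend(frame, n_boot=n_boot, seed=next(seed_counter))
        trend_rows.append({
            "quantity": f"delta_{quantity}",
            "slope_ms_per_bpm": trend.slope, "p_value": trend.p_value,
            "ci_low": trend.ci_low, "ci_high": trend.ci_high,
        })
        inference_rows.append({
            "statistic": f"trend_delta_{quantity}", "estimate": trend.slope,
            "ci_low": trend.ci_low, "ci_high": trend.ci_high,
            "p_value": trend.p_value, "n_boot": trend.n_boot,
            "seed": trend.seed,
        })
    trends = pd.DataFrame(trend_rows)

    report = StudyReport(
        table2_analogue=table2,
        table4_analogue=table4,
        trend_tables=trends,
        metadata={
            "qtdyn_version": __version__,
            "generator_seed": config.seed,
            "inference_seed": seed,
            "config_hash": config.config_hash(),
            "n_patients": len(cohort),
            "n_bursts": cohort.n_bursts,
            "n_boot": n_boot,
            "averaging": "patient_first" if patient_first else "burst_level",
        },
    )

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_cohort(cohort, outdir / "cohort.csv")
        qtc.to_csv(outdir / "qtc.csv", index=False, lineterminator="\n")
        deltas.to_csv(outdir / "deltas.csv", index=False, lineterminator="\n")
        pd.DataFrame(inference_rows).to_csv(
            outdir / "inference.csv", index=False, lineterminator="\n")
        (outdir / "report.md").write_text(report.to_markdown(), encoding="utf-8")
    return report


# ---------------------------------------------------------------------------
# Equal-weight desk oracles
# ---------------------------------------------------------------------------

def _check_full_ladder(means: Mapping[int, float], label: str) -> None:
    missing = [r for r in range(50, 121, 10) if r not in means]
    if missing:
        raise ValueError(f"{label}: missing per-rate means for {missing} bpm")


def equal_weight_table2_oracle(
    baseline_means: Mapping[int, float],
    released_means: Mapping[int, float],
) -> dict[str, float]:
    """Per-formula δ-QTc from per-rate QT means alone, equal weights.

    Applies each rate-correction formula to the per-rate mean QT of each
    phase, averages over the eight rates with equal weights and returns
    released − baseline. Independent of the generator and the cohort
    pipeline; formulas are linear in QT, so applying them to means is
    exact.
    """
    _check_full_ladder(baseline_means, "baseline_means")
    _check_full_ladder(released_means, "released_means")
    out = {}
    for formula in RATE_FORMULAS:
        short = _FORMULA_SHORT[formula]
        phase_means = []
        for means in (baseline_means, released_means):
            qtcs = [
                _apply(formula, means[r], 60.0 / r) for r in range(50, 121, 10)]
            phase_means.append(sum(qtcs) / len(qtcs))
        out[short] = phase_means[1] - phase_means[0]
    return out


def equal_weight_deviation_oracle(
    means: Mapping[int, float],
) -> dict[str, float]:
    """Per-formula mean QTc deviation (QT60 − QTc) from per-rate QT means.

    QT60 is the 60-bpm entry of ``means``; the deviation is averaged over
    the eight rates with equal weights.
    """
    _check_full_ladder(means, "means")
    qt60 = means[60]
    out = {}
    for formula in RATE_FORMULAS:
        short = _FORMULA_SHORT[formula]
        devs = [qt60 - _apply(formula, means[r], 60.0 / r)
                for r in range(50, 121, 10)]
        out[short] = sum(devs) / len(devs)
    return out


def _apply(formula: Formula, qt_ms: float, rr_s: float) -> float:
    from . import qtc_formulas

    return getattr(qtc_formulas, formula.value)(qt_ms, rr_s)


def plot_deviation_by_rate(report: StudyReport, cohort: Cohort, path: str | Path) -> None:
    """Optional diagnostic figure: per-formula QTc deviation vs pacing rate.

    Requires matplotlib (``pip install qtdyn[plot]``); nothing else in the
    package depends on it.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(2, 2, figsize=(9, 7), sharex=True, sharey=True)
    for ax, formula in zip(axes.ravel(), RATE_FORMULAS):
        for phase, color in ((Phase.BASELINE, "tab:blue"), (Phase.RELEASED, "tab:red")):
            points: dict[int, list[float]] = {}
            for patient in cohort:
                if not patient.phase_bursts(phase):
                    continue
                for rec in qtc_deviation(patient, phase, formula):
                    points.setdefault(rec.rate_bpm, []).append(rec.qtc_deviation_ms)
            rates = sorted(points)
            means = [sum(points[r]) / len(points[r]) for r in rates]
            ax.plot(rates, means, "o-", color=color, label=phase.value)
        ax.axhline(0.0, color="gray", lw=0.8)
        ax.set_title(formula.value)
    axes[0, 0].legend()
    for ax in axes[1, :]:
        ax.set_xlabel("pacing rate (bpm)")
    for ax in axes[:, 0]:
        ax.set_ylabel("QT60 − QTc (ms)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
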