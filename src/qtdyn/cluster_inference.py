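"""Subject-resampling (cluster) bootstrap inference and related statistics.

ECG burst measurements arrive in clusters — several bursts per patient —
so naive resampling of bursts would understate uncertainty. All
confidence intervals and tests here resample *patients* with replacement;
a resampled patient brings every one of their observations along, which
preserves the within-subject correlation structure.

Conventions:

* CI95 is the percentile interval of the bootstrap distribution
  (bias-corrected-accelerated available via ``ci_method="bca"``).
* Two-sided p-values for H0: statistic = 0 use the recentred bootstrap
  distribution: p = P(|statistic* − observed| ≥ |observed|), with the
  (1 + count)/(1 + B) finite-sample correction so p is never exactly 0.
* Every inference call takes an explicit seed, which the returned
  summary embeds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BootstrapSummary",
    "TrendResult",
    "cluster_bootstrap",
    "pearson",
    "paired_test",
    "rate_trend",
    "bonferroni",
]

#: A degenerate replicate (statistic undefined) is redrawn; after this
#: many total attempts the call errors out.
_REDRAW_FACTOR = 10


@dataclass(frozen=True)
class BootstrapSummary:
    estimate: float
    ci_low: float
    ci_high: float
    p_value: float
    n_boot: int
    seed: int
    statistic_label: str


@dataclass(frozen=True)
class TrendResult:
    """Least-squares slope of a quantity on pacing rate, ms per bpm."""

    slope: float
    p_value: float
    rate_range: tuple[int, ...]
    ci_low: float
    ci_high: float
    n_boot: int
    seed: int


Statistic = Callable[[np.ndarray], float]


def _pooled_mean(data: np.ndarray) -> float:
    return float(np.mean(data))


_STATISTIC_REGISTRY: dict[str, Statistic] = {"mean": _pooled_mean}


def _as_cluster_arrays(
    values: Mapping[object, Sequence[float] | np.ndarray]
) -> list[np.ndarray]:
    arrays = []
    for key, obs in values.items():
        arr = np.atleast_1d(np.asarray(obs, dtype=float))
        if arr.size == 0:
            raise ValueError(f"patient {key!r} has no observations")
        arrays.append(arr)
    return arrays


def _percentile_ci(boots: np.ndarray) -> tuple[float, float]:
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return float(lo), float(hi)


def _bca_ci(boots: np.ndarray, estimate: float, jackknife: np.ndarray) -> tuple[float, float]:
    # Bias correction from the bootstrap distribution, acceleration from
    # the delete-one-patient jackknife.
    prop = np.clip(np.mean(boots < estimate), 1e-9, 1 - 1e-9)
    z0 = stats.norm.ppf(prop)
    centered = jackknife.mean() - jackknife
    denom = np.sum(centered**2) ** 1.5
    accel = np.sum(centered**3) / (6.0 * denom) if denom > 0 else 0.0
    alphas = []
    for z_alpha in (stats.norm.ppf(0.025), stats.norm.ppf(0.975)):
        adj = z0 + (z0 + z_alpha) / (1.0 - accel * (z0 + z_alpha))
        alphas.append(stats.norm.cdf(adj))
    lo, hi = np.percentile(boots, [100 * alphas[0], 100 * alphas[1]])
    return float(lo), float(hi)


def cluster_bootstrap(
    values: Mapping[object, Sequence[float] | np.ndarray],
    statistic: str | Statistic = "mean",
    n_boot: int = 2000,
    seed: int = 0,
    statistic_label: str | None = None,
    ci_method: str = "percentile",
) -> BootstrapSummary:
    """Bootstrap a statistic by resampling patients with replacement.

    Parameters
    ----------
    values
        Mapping of patient id to that patient's observations — a 1-D
        array of scalars, or a 2-D (n_obs, k) array for statistics that
        need paired columns. All of a patient's rows travel together in
        every resample.
    statistic
        ``"mean"`` (pooled mean over all observations, with a vectorized
        fast path) or a callable receiving the vertically stacked
        observation array of one resample and returning a float. A
        replicate on which the callable raises or returns NaN is redrawn
        (capped at 10× n_boot attempts).
    """
    if len(values) < 2:
        raise ValueError("cluster bootstrap needs at least 2 patients")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if isinstance(statistic, str):
        label = statistic_label or statistic
        try:
            stat_fn = _STATISTIC_REGISTRY[statistic]
        except KeyError:
            raise ValueError(
                f"unknown statistic label {statistic!r}; "
                f"known: {sorted(_STATISTIC_REGISTRY)}") from None
    else:
        stat_fn = statistic
        label = statistic_label or getattr(statistic, "__name__", "statistic")

    arrays = _as_cluster_arrays(values)
    n_pat = len(arrays)
    stacked = np.concatenate([a.reshape(a.shape[0], -1) for a in arrays])
    observed = float(stat_fn(stacked if stacked.shape[1] > 1 else stacked[:, 0]))
    if not np.isfinite(observed):
        raise ValueError(f"statistic {label!r} undefined on the observed sample")
    rng = np.random.default_rng(seed)

    if stat_fn is _pooled_mean and stacked.shape[1] == 1:
        # Vectorized fast path: the pooled mean only needs per-patient
        # sums and counts.
        sums = np.array([a.sum() for a in arrays])
        counts = np.array([a.size for a in arrays], dtype=float)
        idx = rng.integers(0, n_pat, size=(n_boot, n_pat))
        boots = sums[idx].sum(axis=1) / counts[idx].sum(axis=1)
        jack = (sums.sum() - sums) / (counts.sum() - counts)
    else:
        boots = np.empty(n_boot)
        attempts = 0
        max_attempts = _REDRAW_FACTOR * n_boot
        filled = 0
        while filled < n_boot:
            if attempts >= max_attempts:
                raise RuntimeError(
                    f"statistic {label!r} degenerate on too many resamples "
                    f"({attempts} attempts for {n_boot} replicates)")
            attempts += 1
            idx = rng.integers(0, n_pat, size=n_pat)
            sample = np.concatenate(
                [arrays[j].reshape(arrays[j].shape[0], -1) for j in idx])
            try:
                value = float(stat_fn(sample if sample.shape[1] > 1 else sample[:, 0]))
            except (ValueError, ZeroDivisionError, FloatingPointError):
                continue
            if not np.isfinite(value):
                continue
            boots[filled] = value
            filled += 1
        jack = np.empty(n_pat)
        for j in range(n_pat):
            sample = np.concatenate(
                [arrays[k].reshape(arrays[k].shape[0], -1)
                 for k in range(n_pat) if k != j])
            try:
                jack[j] = float(
                    stat_fn(sample if sample.shape[1] > 1 else sample[:, 0]))
            except (ValueError, ZeroDivisionError, FloatingPointError):
                jack[j] = observed

    if ci_method == "percentile":
        ci_low, ci_high = _percentile_ci(boots)
    elif ci_method == "bca":
        ci_low, ci_high = _bca_ci(boots, observed, jack)
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")

    shifts = np.abs(boots - observed)
    p_value = (1.0 + np.sum(shifts >= abs(observed))) / (n_boot + 1.0)
    return BootstrapSummary(
        estimate=observed,
        ci_low=ci_low,
        ci_high=ci_high,
        p_value=float(min(p_value, 1.0)),
        n_boot=n_boot,
        seed=seed,
        statistic_label=label,
    )


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation of two paired vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    if x.size < 3:
        raise ValueError("pearson needs at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("pearson undefined for a constant vector")
    return float(stats.pearsonr(x, y).statistic)


def _pearson_statistic(data: np.ndarray) -> float:
    if np.ptp(data[:, 0]) == 0 or np.ptp(data[:, 1]) == 0:
        return float("nan")  # degenerate resample: redraw
    return float(stats.pearsonr(data[:, 0], data[:, 1]).statistic)


def paired_test(
    before: Mapping[object, Sequence[float]] | Sequence[float],
    after: Mapping[object, Sequence[float]] | Sequence[float],
    n_boot: int = 2000,
    seed: int = 0,
) -> BootstrapSummary:
    """Cluster-bootstrap test of a paired before/after shift.

    The statistic is the mean paired difference (after − before);
    inference comes from :func:`cluster_bootstrap` on the per-patient
    differences, so H0 is "no shift". Inputs are either mappings of
    patient id to matched observation arrays, or two flat sequences of
    per-patient values.
    """
    if isinstance(before, Mapping) != isinstance(after, Mapping):
        raise ValueError("before and after must be of the same kind")
    diffs: dict[object, np.ndarray] = {}
    if isinstance(before, Mapping):
        if set(before) != set(after):
            raise ValueError("before and after must cover the same patients")
        for key in before:
            b = np.atleast_1d(np.asarray(before[key], dtype=float))
            a = np.atleast_1d(np.asarray(after[key], dtype=float))
            if a.shape != b.shape:
                raise ValueError(f"patient {key!r}: unmatched before/after lengths")
            diffs[key] = a - b
    else:
        b = np.asarray(before, dtype=float)
        a = np.asarray(after, dtype=float)
        if a.shape != b.shape:
            raise ValueError("unmatched before/after lengths")
        diffs = {i: np.array([d]) for i, d in enumerate(a - b)}
    return cluster_bootstrap(
        diffs, "mean", n_boot=n_boot, seed=seed,
        statistic_label="mean_paired_difference")


def _slope(data: np.ndarray) -> float:
    x, y = data[:, 0], data[:, 1]
    var = np.var(x)
    if var == 0:
        return float("nan")
    return float(np.cov(x, y, bias=True)[0, 1] / var)


def rate_trend(
    values: pd.DataFrame,
    n_boot: int = 2000,
    seed: int = 0,
) -> TrendResult:
    """Linear trend of a quantity across pacing rates.

    ``values`` is a long-format frame with columns ``patient_id``,
    ``rate_bpm`` and ``value`` (``delta_ms`` is accepted as an alias).
    The point estimate is the Gaussian identity-link (ordinary
    least-squares) slope of value on rate, in ms per bpm; the p-value
    and CI95 come from the cluster bootstrap of the slope, so no
    parametric error assumption is leaned on. Requires observations at
    ≥ 3 distinct rates.
    """
    frame = values.rename(columns={"delta_ms": "value"})
    required = {"patient_id", "rate_bpm", "value"}
    if not required.issubset(frame.columns):
        raise ValueError(f"values must have columns {sorted(required)}")
    rates = tuple(sorted(frame["rate_bpm"].unique()))
    if len(rates) < 3:
        raise ValueError(
            f"rate trend needs >= 3 distinct rates, got {len(rates)}")

    import statsmodels.api as sm

    exog = sm.add_constant(frame["rate_bpm"].to_numpy(dtype=float))
    fit = sm.OLS(frame["value"].to_numpy(dtype=float), exog).fit()
    slope = float(fit.params[1])

    clusters = {
        pid: grp[["rate_bpm", "value"]].to_numpy(dtype=float)
        for pid, grp in frame.groupby("patient_id")
    }
    summary = cluster_bootstrap(
        clusters, _slope, n_boot=n_boot, seed=seed, statistic_label="ols_slope")
    return TrendResult(
        slope=slope,
        p_value=summary.p_value,
        rate_range=rates,
        ci_low=summary.ci_low,
        ci_high=summary.ci_high,
        n_boot=n_boot,
        seed=seed,
    )


def bonferroni(p_values: Sequence[float], m: int | None = None) -> list[float]:
    """Bonferroni adjustment: min(1, p·m) elementwise.

    ``m`` defaults to the number of p-values and may exceed it (when only
    a subset of the family is being adjusted).
    """
    p = list(p_values)
    if m is None:
        m = len(p)
    if m < len(p):
        raise ValueError(f"m={m} smaller than the number of p-values ({len(p)})")
    for value in p:
        if not 0.0 <= value <= 1.0:
            raise ValueError(f"p-value {value!r} outside [0, 1]")
    return [min(1.0, value * m) for value in p]
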