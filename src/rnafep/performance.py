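"""Predicted-vs-experimental performance metrics with bootstrap CIs.

Point metrics: MAE, RMSE, Pearson's r, Kendall's tau-b, Spearman's rho.
Uncertainty: ligand systems are resampled with replacement (paired
values) n_boot times; each metric is summarized by its bootstrap mean
and percentile 95% CI.  With the six-ligand panel this mirrors the
standard small-n evaluation protocol for affinity prediction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

METRIC_NAMES = ("mae", "rmse", "pearson_r", "kendall_tau", "spearman_rho")


@dataclass
class PerformanceReport:
    mae: float
    rmse: float
    pearson_r: float
    kendall_tau: float
    spearman_rho: float
    n: int
    ci95: dict = field(default_factory=dict)
    boot_mean: dict = field(default_factory=dict)
    n_boot: Optional[int] = None
    seed: Optional[int] = None
    n_degenerate: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {m: getattr(self, m) for m in METRIC_NAMES}
        out["n"] = self.n
        if self.n_boot is not None:
            out.update(
                {
                    "n_boot": self.n_boot,
                    "seed": self.seed,
                    "ci95": self.ci95,
                    "boot_mean": self.boot_mean,
                    "n_degenerate": self.n_degenerate,
                }
            )
        return out


def _paired(predicted, experimental) -> tuple[np.ndarray, np.ndarray]:
    pred = np.asarray(predicted, dtype=float)
    expt = np.asarray(experimental, dtype=float)
    if pred.shape != expt.shape or pred.ndim != 1:
        raise ValueError(
            f"predicted and experimental must be equal-length vectors, "
            f"got shapes {pred.shape} and {expt.shape}"
        )
    if pred.size < 2:
        raise ValueError("need at least two paired values")
    return pred, expt


def compute_metrics(
    predicted: Sequence[float], experimental: Sequence[float]
) -> PerformanceReport:
    """Point estimates of all five metrics on paired dG vectors.

    Spearman's rho is Pearson on average ranks; Kendall's tau is the
    tie-corrected tau-b (identical to tau-a when all values are
    distinct).  Raises if either vector has zero variance, since the
    correlations are then undefined.
    """
    pred, expt = _paired(predicted, experimental)
    if np.ptp(pred) == 0 or np.ptp(expt) == 0:
        raise ValueError("zero variance in a vector: correlations undefined")
    err = pred - expt
    return PerformanceReport(
        mae=float(np.mean(np.abs(err))),
        rmse=float(np.sqrt(np.mean(err**2))),
        pearson_r=float(stats.pearsonr(pred, expt).statistic),
        kendall_tau=float(stats.kendalltau(pred, expt, variant="b").statistic),
        spearman_rho=float(stats.spearmanr(pred, expt).statistic),
        n=pred.size,
    )


def bootstrap_metrics(
    predicted: Sequence[float],
    experimental: Sequence[float],
    n_boot: int = 1000,
    seed: int = 0,
    metrics: Sequence[str] = METRIC_NAMES,
) -> PerformanceReport:
    """Point metrics plus bootstrap mean and percentile 95% CI.

    Ligand systems (paired values) are resampled with replacement.
    Resamples where a metric is degenerate (zero variance in either
    vector) are dropped from that metric's bootstrap distribution and
    counted in ``n_degenerate``; if every resample is degenerate the CI
    is reported as None.  Deterministic for a fixed seed.  ``metrics``
    restricts which metrics get a bootstrap distribution (the point
    estimates are always all computed).
    """
    pred, expt = _paired(predicted, experimental)
    if pred.size < 3:
        raise ValueError("bootstrap needs at least three ligand systems")
    unknown = set(metrics) - set(METRIC_NAMES)
    if unknown:
        raise ValueError(f"unknown metrics: {sorted(unknown)}")
    report = compute_metrics(pred, expt)
    rng = np.random.default_rng(seed)
    n = pred.size
    want_rank = bool({"pearson_r", "kendall_tau", "spearman_rho"} & set(metrics))

    samples: dict[str, list[float]] = {m: [] for m in metrics}
    degenerate = {m: 0 for m in metrics}
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        p, e = pred[idx], expt[idx]
        err = p - e
        if "mae" in samples:
            samples["mae"].append(float(np.mean(np.abs(err))))
        if "rmse" in samples:
            samples["rmse"].append(float(np.sqrt(np.mean(err**2))))
        if not want_rank:
            continue
        if np.ptp(p) == 0 or np.ptp(e) == 0:
            for m in ("pearson_r", "kendall_tau", "spearman_rho"):
                if m in degenerate:
                    degenerate[m] += 1
        else:
            if "pearson_r" in samples:
                samples["pearson_r"].append(float(stats.pearsonr(p, e).statistic))
            # ties in a resample can still degenerate the rank metrics
            if "kendall_tau" in samples:
                tau = stats.kendalltau(p, e, variant="b").statistic
                if np.isnan(tau):
                    degenerate["kendall_tau"] += 1
                else:
                    samples["kendall_tau"].append(float(tau))
            if "spearman_rho" in samples:
                rho = stats.spearmanr(p, e).statistic
                if np.isnan(rho):
                    degenerate["spearman_rho"] += 1
                else:
                    samples["spearman_rho"].append(float(rho))

    for m in metrics:
        vals = np.array(samples[m])
        if vals.size == 0:
            report.ci95[m] = None
            report.boot_mean[m] = None
        else:
            lo, hi = np.percentile(vals, [2.5, 97.5])
            report.ci95[m] = (float(lo), float(hi))
            report.boot_mean[m] = float(vals.mean())
    report.n_boot = n_boot
    report.seed = seed
    report.n_degenerate = degenerate
    return report
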