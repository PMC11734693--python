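"""Lambda-window overlap diagnostics.

For every window the forward and (sign-aligned) backward dU
distributions are histogrammed on shared bins and compared with a
Kullback-Leibler divergence; windows above a divergence threshold are
classified "low" overlap for reporting (the green/red bar charts used
to spot problematic alchemical transitions).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from rnafep.types import TransformationLeg, as_float_array

DEFAULT_BINS = 100
DEFAULT_THRESHOLD = 0.5  # nats


@dataclass
class WindowOverlap:
    lambda_start: float
    lambda_end: float
    kl_divergence: float
    classification: str  # "sufficient" | "low"


@dataclass
class OverlapReport:
    per_window: list[WindowOverlap]
    threshold: float

    def to_dict(self) -> dict:
        return {
            "threshold_nats": self.threshold,
            "windows": [
                {
                    "lambda_start": w.lambda_start,
                    "lambda_end": w.lambda_end,
                    "kl_divergence_nats": w.kl_divergence,
                    "classification": w.classification,
                }
                for w in self.per_window
            ],
        }


def kl_divergence(
    samples_p: Sequence[float],
    samples_q: Sequence[float],
    n_bins: int = DEFAULT_BINS,
) -> float:
    """Histogram KL divergence D(p||q) in nats.

    Both sample sets are binned on shared equal-width bins spanning the
    union range; a pseudo-count of 1/n (n = that set's sample count) is
    added to every bin before normalizing, which regularizes empty bins
    and caps the divergence of disjoint distributions.  Nonnegative by
    Gibbs' inequality.
    """
    if n_bins < 2:
        raise ValueError(f"n_bins must be >= 2, got {n_bins}")
    p = as_float_array(samples_p, "samples_p")
    q = as_float_array(samples_q, "samples_q")
    lo = min(p.min(), q.min())
    hi = max(p.max(), q.max())
    if lo == hi:  # all samples identical: distributions coincide
        return 0.0
    edges = np.linspace(lo, hi, n_bins + 1)
    cp = np.histogram(p, bins=edges)[0].astype(float) + 1.0 / p.size
    cq = np.histogram(q, bins=edges)[0].astype(float) + 1.0 / q.size
    cp /= cp.sum()
    cq /= cq.sum()
    return float(np.sum(cp * np.log(cp / cq)))


def window_overlap_report(
    fwd_leg: TransformationLeg,
    bwd_leg: TransformationLeg,
    threshold: float = DEFAULT_THRESHOLD,
    n_bins: int = DEFAULT_BINS,
) -> OverlapReport:
    """Per-window KL overlap between a forward leg and its backward
    partner.

    Backward dU samples are negated before comparison so both
    distributions describe the same transformation; window (a, b)
    forward is paired with window (b, a) backward.  A window is
    "sufficient" when KL <= threshold, else "low".
    """
    if fwd_leg.step_id != bwd_leg.step_id:
        raise ValueError("legs describe different steps")
    if fwd_leg.n_windows != bwd_leg.n_windows:
        raise ValueError(
            f"window count mismatch: {fwd_leg.n_windows} forward vs "
            f"{bwd_leg.n_windows} backward"
        )
    per_window = []
    for fw, bw in zip(fwd_leg.windows, reversed(bwd_leg.windows)):
        if not (
            math.isclose(fw.lambda_start, bw.lambda_end, abs_tol=1e-9)
            and math.isclose(fw.lambda_end, bw.lambda_start, abs_tol=1e-9)
        ):
            raise ValueError(
                f"grid mismatch at forward window "
                f"({fw.lambda_start}, {fw.lambda_end}): backward partner is "
                f"({bw.lambda_start}, {bw.lambda_end})"
            )
        kl = kl_divergence(fw.delta_u, -bw.delta_u, n_bins=n_bins)
        per_window.append(
            WindowOverlap(
                lambda_start=fw.lambda_start,
                lambda_end=fw.lambda_end,
                kl_divergence=kl,
                classification="sufficient" if kl <= threshold else "low",
            )
        )
    return OverlapReport(per_window=per_window, threshold=threshold)


def plot_overlap_report(report: OverlapReport, path, title: Optional[str] = None) -> None:
    """Green/red bar chart of per-window KL divergence."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    centers = [0.5 * (w.lambda_start + w.lambda_end) for w in report.per_window]
    values = [w.kl_divergence for w in report.per_window]
    colors = [
        "tab:green" if w.classification == "sufficient" else "tab:red"
        for w in report.per_window
    ]
    width = min(
        abs(w.lambda_end - w.lambda_start) for w in report.per_window
    ) * 0.8
    fig, ax = plt.subplots(figsize=(8, 3))
    ax.bar(centers, values, width=width, color=colors)
    ax.axhline(report.threshold, ls="--", color="k", lw=0.8)
    ax.set_xlabel("lambda (window center)")
    ax.set_ylabel("KL divergence (nats)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
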