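"""Free energy estimators: exponential-averaging FEP, the acceptance-ratio
(BAR) cross-check, TI quadrature, and bidirectional combination.

Per window, FEP computes dG = -kT ln <exp(-dU/kT)> over the retained
samples.  The standard error is the larger of (a) first-order
propagation of the sample variance of exp(-dU/kT) and (b) a 10-block
block-average, which softens correlation bias.  A leg's dG is the sum
over its windows.  A bidirectional pair is combined as
(dG_fwd - dG_bwd)/2 with hysteresis |dG_fwd + dG_bwd|: the backward
transformation estimates the reverse process, so under perfect
reversibility dG_bwd = -dG_fwd.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
from scipy.special import expit, logsumexp

from rnafep.constants import kt
from rnafep.types import (
    Direction,
    LambdaWindow,
    StepEstimate,
    TIProfile,
    TransformationLeg,
    as_float_array,
)

N_BLOCKS = 10


def _exp_average(delta_u: np.ndarray, temperature: float) -> float:
    """dG = -kT ln mean(exp(-beta dU)), computed via logsumexp."""
    beta = 1.0 / kt(temperature)
    n = delta_u.size
    return -(logsumexp(-beta * delta_u) - math.log(n)) / beta


def fep_window_estimate(window: LambdaWindow) -> tuple[float, float]:
    """Exponential-average free energy of one window after discarding
    the equilibration fraction.

    Returns (delta_g, stderr) in kcal/mol.  Raises if fewer than two
    samples remain or any dU is non-finite.
    """
    retained = window.retained()
    if retained.size == 0:
        raise ValueError("no samples remain after applying discard_fraction")
    if retained.size < 2:
        raise ValueError("need at least 2 retained samples for an estimate")
    if not np.all(np.isfinite(retained)):
        bad = np.flatnonzero(~np.isfinite(retained)).tolist()
        raise ValueError(f"non-finite dU at retained indices {bad}")

    kbt = kt(window.temperature)
    delta_g = _exp_average(retained, window.temperature)

    # First-order propagation through dG = -kT ln(mean x), x = exp(-beta dU):
    # sd(dG) = kT * sd(x) / (mean(x) * sqrt(n)).  Work with shifted x for
    # numerical stability; the mean-normalized ratio is shift-invariant.
    beta = 1.0 / kbt
    shift = retained.min()
    x = np.exp(-beta * (retained - shift))
    n = retained.size
    stderr_prop = kbt * x.std(ddof=1) / (x.mean() * math.sqrt(n))

    stderr_block = _block_stderr(retained, window.temperature)
    return delta_g, max(stderr_prop, stderr_block)


def _block_stderr(delta_u: np.ndarray, temperature: float) -> float:
    """Standard error from block averaging of per-block FEP estimates."""
    n = delta_u.size
    if n < 2 * N_BLOCKS:
        return 0.0
    usable = n - (n % N_BLOCKS)
    blocks = delta_u[:usable].reshape(N_BLOCKS, -1)
    estimates = np.array([_exp_average(b, temperature) for b in blocks])
    return float(estimates.std(ddof=1) / math.sqrt(N_BLOCKS))


def leg_estimate(leg: TransformationLeg) -> StepEstimate:
    """Sum window free energies over a contiguous leg.

    stderr is the root-sum-square of window stderrs (windows are sampled
    independently); per_window records (lambda_start, lambda_end, dG, se).
    """
    per_window = []
    total = 0.0
    var = 0.0
    for w in leg.windows:
        dg, se = fep_window_estimate(w)
        per_window.append((w.lambda_start, w.lambda_end, dg, se))
        total += dg
        var += se * se
    return StepEstimate(
        step_id=leg.step_id,
        delta_g=total,
        stderr=math.sqrt(var),
        per_window=per_window,
        temperature=leg.temperature,
    )


def combine_bidirectional(fwd: StepEstimate, bwd: StepEstimate) -> StepEstimate:
    """Combine a forward/backward pair of estimates for the same step.

    combined dG = (dG_fwd - dG_bwd) / 2, since the backward run estimates
    the reverse process; hysteresis = |dG_fwd + dG_bwd| measures the
    deviation from perfect reversibility and feeds replicate QC.
    """
    if fwd.step_id != bwd.step_id:
        raise ValueError(f"step mismatch: {fwd.step_id} vs {bwd.step_id}")
    if (
        fwd.temperature is not None
        and bwd.temperature is not None
        and not math.isclose(fwd.temperature, bwd.temperature)
    ):
        raise ValueError(
            f"temperature mismatch: {fwd.temperature} K vs {bwd.temperature} K"
        )
    delta_g = 0.5 * (fwd.delta_g - bwd.delta_g)
    hysteresis = abs(fwd.delta_g + bwd.delta_g)
    stderr = 0.5 * math.hypot(fwd.stderr, bwd.stderr)

    per_window = []
    if fwd.per_window and len(fwd.per_window) == len(bwd.per_window):
        # Backward windows traverse lambda in reverse order; window
        # (a, b) forward pairs with (b, a) backward.
        for (fs, fe, fdg, fse), (bs, be, bdg, bse) in zip(
            fwd.per_window, reversed(bwd.per_window)
        ):
            if math.isclose(fs, be, abs_tol=1e-9) and math.isclose(fe, bs, abs_tol=1e-9):
                per_window.append(
                    (fs, fe, 0.5 * (fdg - bdg), 0.5 * math.hypot(fse, bse))
                )
            else:
                per_window = []
                break

    return StepEstimate(
        step_id=fwd.step_id,
        delta_g=delta_g,
        stderr=stderr,
        hysteresis=hysteresis,
        per_window=per_window,
        temperature=fwd.temperature,
    )


def bar_estimate(
    fwd_samples: Sequence[float],
    bwd_samples: Sequence[float],
    temperature: float,
    tol: float = 1e-8,
    max_iter: int = 200,
) -> float:
    """Bennett acceptance-ratio free energy from a bidirectional pair.

    Solves the self-consistency condition

        sum_i f(ln(nF/nB) + beta (W_F,i - dG))
            = sum_j f(ln(nB/nF) + beta (W_B,j + dG)),

    with f the Fermi function, by bisection.  W_F are forward work
    samples (A -> B) and W_B backward work samples (B -> A), both in
    kcal/mol.  Serves as an independent cross-check on the FEP path.
    """
    w_f = as_float_array(fwd_samples, "fwd_samples")
    w_b = as_float_array(bwd_samples, "bwd_samples")
    beta = 1.0 / kt(temperature)
    log_ratio = math.log(w_f.size / w_b.size)

    def residual(dg: float) -> float:
        # expit(-x) = 1/(1+e^x); residual is monotone increasing in dg.
        lhs = expit(-(log_ratio + beta * (w_f - dg))).sum()
        rhs = expit(-(-log_ratio + beta * (w_b + dg))).sum()
        return lhs - rhs

    # Bracket the root around the FEP estimates from both directions.
    lo = min(_exp_average(w_f, temperature), -_exp_average(w_b, temperature)) - 1.0
    hi = max(_exp_average(w_f, temperature), -_exp_average(w_b, temperature)) + 1.0
    for _ in range(60):
        if residual(lo) < 0:
            break
        lo -= max(1.0, hi - lo)
    for _ in range(60):
        if residual(hi) > 0:
            break
        hi += max(1.0, hi - lo)
    if residual(lo) >= 0 or residual(hi) <= 0:
        raise RuntimeError("failed to bracket the BAR self-consistency root")

    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        r = residual(mid)
        if abs(r) < tol or (hi - lo) < 1e-12:
            return mid
        if r < 0:
            lo = mid
        else:
            hi = mid
    raise RuntimeError(f"BAR bisection did not converge in {max_iter} iterations")


def ti_estimate(profile: TIProfile) -> tuple[float, float]:
    """Trapezoidal integral of <dU/dlambda> over lambda with error
    propagation through the trapezoid weights."""
    if not np.all(np.isfinite(profile.mean_dudl)):
        raise ValueError("TI profile contains non-finite mean values")
    lam = profile.lambda_grid
    weights = np.zeros_like(lam)
    dx = np.diff(lam)
    weights[:-1] += 0.5 * dx
    weights[1:] += 0.5 * dx
    delta_g = float(np.dot(weights, profile.mean_dudl))
    stderr = float(np.sqrt(np.sum((weights * profile.sem_dudl) ** 2)))
    return delta_g, stderr


def ti_step_estimate(
    fwd: TIProfile, bwd: TIProfile, step_id, temperature: float | None = None
) -> StepEstimate:
    """Bidirectional TI: estimate each direction by quadrature and
    combine with the same convention as FEP legs."""
    fdg, fse = ti_estimate(fwd)
    bdg, bse = ti_estimate(bwd)
    f = StepEstimate(step_id=step_id, delta_g=fdg, stderr=fse, temperature=temperature,
                     per_window=[(0.0, 1.0, fdg, fse)])
    b = StepEstimate(step_id=step_id, delta_g=bdg, stderr=bse, temperature=temperature,
                     per_window=[(1.0, 0.0, bdg, bse)])
    return combine_bidirectional(f, b)


def estimate_step(
    fwd_leg: TransformationLeg, bwd_leg: TransformationLeg
) -> StepEstimate:
    """End-to-end FEP step estimate from a bidirectional leg pair."""
    if fwd_leg.direction != Direction.FORWARD or bwd_leg.direction != Direction.BACKWARD:
        raise ValueError("expected one forward and one backward leg, in that order")
    return combine_bidirectional(leg_estimate(fwd_leg), leg_estimate(bwd_leg))
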