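"""A-priori replicate rejection.

Two indicators, both computed purely from simulation output (no
experimental values enter the decision):

1. the cycle's total hysteresis error must be strictly less than
   10 kcal/mol;
2. the replicate's restraint contribution (step 1 by default) must not
   exceed 2.5x the magnitude of the pool median, where the pool is all
   replicates of all ligands run under the same condition.

Rejected replicates are flagged, never deleted; aggregation ignores
them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np

from rnafep.types import BindingEstimate, QCDecision, StepId

HYSTERESIS_THRESHOLD = 10.0
RESTRAINT_MULTIPLIER = 2.5
DEFAULT_RESTRAINT_STEP = StepId.STEP1


@dataclass
class ReplicateRecord:
    """One independent end-to-end replicate entering QC."""

    replicate_id: str
    ligand_id: str
    estimate: BindingEstimate

    def restraint_delta_g(self, step: StepId) -> float:
        try:
            return self.estimate.step_delta_g[step.value]
        except KeyError as exc:
            raise ValueError(
                f"replicate {self.replicate_id} has no {step.value} estimate"
            ) from exc


def check_hysteresis(
    replicate: BindingEstimate, threshold: float = HYSTERESIS_THRESHOLD
) -> tuple[bool, float]:
    """Pass iff total cycle hysteresis is strictly below the threshold.

    Returns (passed, hysteresis_value).
    """
    h = replicate.total_hysteresis
    if h is None or not np.isfinite(h):
        raise ValueError("replicate has no finite total_hysteresis")
    return h < threshold, float(h)


def check_restraint_outlier(
    replicate_restraint_dg: float,
    pool: Sequence[float],
    multiplier: float = RESTRAINT_MULTIPLIER,
) -> tuple[bool, float]:
    """Pass iff |dG_restraint| <= multiplier * |median(pool)|.

    ``pool`` holds the restraint-step dG of every replicate of every
    ligand in the same condition (the candidate included).  Returns
    (passed, pool_median).
    """
    pool = np.asarray(pool, dtype=float)
    if pool.size < 3:
        raise ValueError(f"restraint pool needs >= 3 replicates, got {pool.size}")
    med = float(np.median(pool))
    passed = abs(replicate_restraint_dg) <= multiplier * abs(med)
    return passed, med


def apply_rejection(
    study: Sequence[ReplicateRecord],
    hysteresis_threshold: float = HYSTERESIS_THRESHOLD,
    restraint_multiplier: float = RESTRAINT_MULTIPLIER,
    restraint_step: Union[str, StepId] = DEFAULT_RESTRAINT_STEP,
) -> list[QCDecision]:
    """Apply both checks to every replicate of a study.

    The pool median is computed once over all replicates of all ligands
    (deterministic and order-invariant); decisions are returned in the
    input order.
    """
    restraint_step = StepId(restraint_step)
    pool = [r.restraint_delta_g(restraint_step) for r in study]
    decisions = []
    for rec in study:
        reasons = []
        h_ok, h_val = check_hysteresis(rec.estimate, hysteresis_threshold)
        if not h_ok:
            reasons.append("hysteresis_exceeded")
        r_val = rec.restraint_delta_g(restraint_step)
        r_ok, med = check_restraint_outlier(r_val, pool, restraint_multiplier)
        if not r_ok:
            reasons.append("restraint_outlier")
        decisions.append(
            QCDecision(
                replicate_id=rec.replicate_id,
                accepted=not reasons,
                reasons=reasons,
                hysteresis_value=h_val,
                restraint_value=r_val,
                pool_median=med,
            )
        )
    return decisions
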