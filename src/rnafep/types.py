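"""Domain containers for alchemical free energy post-processing.

All energies are in kcal/mol, temperatures in kelvin, and coupling
parameters (lambda) in [0, 1].  A *forward* transformation runs the
process as simulated (decoupling for alchemical steps, restraint release
for TI steps); a *backward* transformation samples the reverse process,
so its own free energy estimate approximates minus the forward value.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np


class Direction(str, enum.Enum):
    FORWARD = "forward"
    BACKWARD = "backward"


class StepId(str, enum.Enum):
    """The legs of the double-decoupling cycle.

    step1: bulk restraint contribution, dG(bulk,rest)
    step2: bulk alchemical decoupling, dG(bulk,alch)
    step3: complex alchemical decoupling, dG(complex,alch)
    step4: complex restraint contribution, dG(complex,rest)
    step5: apo-target backbone restraint (restrained cycle variant only)
    """

    STEP1 = "step1"
    STEP2 = "step2"
    STEP3 = "step3"
    STEP4 = "step4"
    STEP5 = "step5"


class Environment(str, enum.Enum):
    BULK = "bulk"
    COMPLEX = "complex"
    APO_TARGET = "apo_target"


@dataclass
class LambdaWindow:
    """One alchemical window: samples of the potential-energy difference
    dU between adjacent lambda states.

    ``discard_fraction`` marks the leading fraction of samples as
    equilibration; it is recorded here but applied only at estimation
    time so diagnostics can inspect the raw stream.
    """

    lambda_start: float
    lambda_end: float
    direction: Direction
    delta_u: np.ndarray
    temperature: float
    discard_fraction: float = 0.0

    def __post_init__(self) -> None:
        self.delta_u = np.asarray(self.delta_u, dtype=float)
        for lam, name in ((self.lambda_start, "lambda_start"), (self.lambda_end, "lambda_end")):
            if not (0.0 <= lam <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {lam}")
        if self.lambda_start == self.lambda_end:
            raise ValueError("lambda_start and lambda_end must differ")
        if self.temperature <= 0:
            raise ValueError(f"temperature must be positive, got {self.temperature}")
        if not (0.0 <= self.discard_fraction < 1.0):
            raise ValueError(f"discard_fraction must be in [0, 1), got {self.discard_fraction}")
        self.direction = Direction(self.direction)

    @property
    def n_samples(self) -> int:
        return int(self.delta_u.size)

    def retained(self) -> np.ndarray:
        """Samples remaining after discarding the equilibration fraction."""
        n_skip = int(math.floor(self.discard_fraction * self.delta_u.size))
        return self.delta_u[n_skip:]


@dataclass
class TransformationLeg:
    """An ordered, contiguous set of lambda windows covering [0, 1]."""

    step_id: StepId
    environment: Environment
    direction: Direction
    windows: list[LambdaWindow]

    def __post_init__(self) -> None:
        self.step_id = StepId(self.step_id)
        self.environment = Environment(self.environment)
        self.direction = Direction(self.direction)
        if not self.windows:
            raise ValueError("a transformation leg needs at least one window")
        temps = {w.temperature for w in self.windows}
        if len(temps) > 1:
            raise ValueError(f"windows mix temperatures: {sorted(temps)}")
        dirs = {w.direction for w in self.windows}
        if dirs != {self.direction}:
            raise ValueError("window directions disagree with the leg direction")
        for prev, nxt in zip(self.windows, self.windows[1:]):
            if not math.isclose(prev.lambda_end, nxt.lambda_start, abs_tol=1e-12):
                raise ValueError(
                    f"gap in lambda coverage: window ends at {prev.lambda_end} "
                    f"but next starts at {nxt.lambda_start}"
                )

    @property
    def temperature(self) -> float:
        return self.windows[0].temperature

    @property
    def n_windows(self) -> int:
        return len(self.windows)


@dataclass
class TIProfile:
    """Mean coupling derivative <dU/dlambda> on a lambda grid, with
    standard errors, as produced by a restraint-release TI run."""

    lambda_grid: np.ndarray
    mean_dudl: np.ndarray
    sem_dudl: np.ndarray
    n_samples: np.ndarray

    def __post_init__(self) -> None:
        self.lambda_grid = np.asarray(self.lambda_grid, dtype=float)
        self.mean_dudl = np.asarray(self.mean_dudl, dtype=float)
        self.sem_dudl = np.asarray(self.sem_dudl, dtype=float)
        self.n_samples = np.asarray(self.n_samples, dtype=int)
        n = self.lambda_grid.size
        if not (self.mean_dudl.size == self.sem_dudl.size == self.n_samples.size == n):
            raise ValueError("TI profile arrays must have equal length")
        if n < 2:
            raise ValueError("TI profile needs at least two grid points")
        if np.any(np.diff(self.lambda_grid) <= 0):
            raise ValueError("lambda grid must be strictly increasing")
        if not math.isclose(self.lambda_grid[0], 0.0, abs_tol=1e-12):
            raise ValueError("lambda grid must start at 0")
        if not math.isclose(self.lambda_grid[-1], 1.0, abs_tol=1e-12):
            raise ValueError("lambda grid must end at 1")


@dataclass
class StepEstimate:
    """Free energy estimate for one cycle step, possibly combined from a
    bidirectional pair (then ``hysteresis`` measures the deviation from
    perfect reversibility, |dG_fwd + dG_bwd|)."""

    step_id: StepId
    delta_g: float
    stderr: float
    hysteresis: float = 0.0
    per_window: list[tuple[float, float, float, float]] = field(default_factory=list)
    temperature: Optional[float] = None

    def __post_init__(self) -> None:
        self.step_id = StepId(self.step_id)
        if not math.isfinite(self.delta_g):
            raise ValueError("delta_g must be finite")
        if self.hysteresis < 0:
            raise ValueError("hysteresis must be nonnegative")


@dataclass
class BindingEstimate:
    """Standard-state binding free energy assembled from one replicate's
    cycle steps."""

    delta_g_bind: float
    stderr: float
    total_hysteresis: float
    standard_state_term: float
    variant: str
    replicate_id: Optional[str] = None
    step_delta_g: dict = field(default_factory=dict)


@dataclass
class QCDecision:
    """Outcome of the a-priori replicate rejection protocol."""

    replicate_id: str
    accepted: bool
    reasons: list[str]
    hysteresis_value: float
    restraint_value: float
    pool_median: float

    def __post_init__(self) -> None:
        if self.accepted != (len(self.reasons) == 0):
            raise ValueError("accepted must be True exactly when reasons is empty")


@dataclass
class LigandResult:
    """Aggregate over a ligand's accepted replicates."""

    ligand_id: str
    replicate_estimates: list[BindingEstimate]
    mean: float
    sd: Optional[float]
    rejected: list[QCDecision] = field(default_factory=list)


def as_float_array(values: Sequence[float], name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError(f"{name} must be nonempty")
    if not np.all(np.isfinite(arr)):
        bad = np.flatnonzero(~np.isfinite(arr)).tolist()
        raise ValueError(f"{name} contains non-finite values at indices {bad}")
    return arr
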