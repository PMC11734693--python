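"""Readers and writers for alchemical window samples and TI profiles.

Two on-disk representations are supported:

* the legacy "fepout" text dialect (NAMD-style): window headers of the
  form ``#NEW FEP WINDOW: LAMBDA SET TO <x> LAMBDA2 <y>`` followed by
  sample lines starting with ``FepEnergy:``, with dU taken from a fixed
  numeric field (the 6th by default; producers differ, so the position
  is overridable);
* a canonical delimited window table, which is the interchange format
  for everything downstream.

Both round-trip losslessly: parse -> write -> parse is the identity on
dU sequences and lambda bounds.
"""

from __future__ import annotations

import io
import re
from pathlib import Path
from typing import Iterable, TextIO, Union

import numpy as np
import pandas as pd

from rnafep.constants import DEFAULT_DISCARD_FRACTION
from rnafep.types import (
    Direction,
    Environment,
    LambdaWindow,
    StepId,
    TIProfile,
    TransformationLeg,
)

WINDOW_TABLE_COLUMNS = [
    "step_id",
    "environment",
    "direction",
    "lambda_start",
    "lambda_end",
    "sample_index",
    "delta_u_kcal_mol",
    "temperature_K",
]

TI_TABLE_COLUMNS = ["lambda", "mean_dudl_kcal_mol", "sem_dudl_kcal_mol", "n_samples"]

#: dU is the 6th numeric field after the ``FepEnergy:`` token by default.
DEFAULT_DELTA_U_FIELD = 6

_HEADER_RE = re.compile(
    r"#NEW FEP WINDOW:\s+LAMBDA SET TO\s+(?P<l1>[-+0-9.eE]+)\s+LAMBDA2\s+(?P<l2>[-+0-9.eE]+)"
)


class FepoutParseError(ValueError):
    """Raised when the legacy dialect stream is malformed."""


def parse_fep_output(
    stream: Union[str, TextIO],
    direction: Union[str, Direction],
    temperature: float,
    discard_fraction: float = DEFAULT_DISCARD_FRACTION,
    step_id: Union[str, StepId] = StepId.STEP3,
    environment: Union[str, Environment] = Environment.COMPLEX,
    delta_u_field: int = DEFAULT_DELTA_U_FIELD,
) -> TransformationLeg:
    """Parse a legacy fepout stream into a transformation leg.

    Lambda bounds come from the window headers, never from the samples.
    ``discard_fraction`` is recorded on each window but not applied.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    direction = Direction(direction)

    windows: list[LambdaWindow] = []
    current_bounds: tuple[float, float] | None = None
    current_samples: list[float] = []

    def flush(line_no: int) -> None:
        nonlocal current_bounds, current_samples
        if current_bounds is None:
            return
        if not current_samples:
            raise FepoutParseError(
                f"window {current_bounds[0]} -> {current_bounds[1]} declared before "
                f"line {line_no} contains no FepEnergy records"
            )
        windows.append(
            LambdaWindow(
                lambda_start=current_bounds[0],
                lambda_end=current_bounds[1],
                direction=direction,
                delta_u=np.array(current_samples),
                temperature=temperature,
                discard_fraction=discard_fraction,
            )
        )
        current_bounds = None
        current_samples = []

    for line_no, line in enumerate(stream, start=1):
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith("#"):
            if "NEW FEP WINDOW" in stripped:
                m = _HEADER_RE.search(stripped)
                if m is None:
                    raise FepoutParseError(
                        f"malformed window header at line {line_no}: {stripped!r}"
                    )
                flush(line_no)
                current_bounds = (float(m.group("l1")), float(m.group("l2")))
            continue
        if stripped.startswith("FepEnergy:"):
            if current_bounds is None:
                raise FepoutParseError(
                    f"FepEnergy record at line {line_no} precedes any window header"
                )
            fields = stripped.split()[1:]
            if len(fields) < delta_u_field:
                raise FepoutParseError(
                    f"FepEnergy record at line {line_no} has {len(fields)} numeric "
                    f"fields, need at least {delta_u_field}"
                )
            try:
                value = float(fields[delta_u_field - 1])
            except ValueError as exc:
                raise FepoutParseError(
                    f"non-numeric dU field at line {line_no}: {fields[delta_u_field - 1]!r}"
                ) from exc
            current_samples.append(value)

    flush(line_no=-1)
    if not windows:
        raise FepoutParseError("stream declares no FEP windows")

    # The dialect writes windows in traversal order; lambda must move
    # monotonically along the transformation.
    starts = [w.lambda_start for w in windows]
    diffs = np.diff(starts)
    if len(starts) > 1 and not (np.all(diffs > 0) or np.all(diffs < 0)):
        raise FepoutParseError(f"non-monotone lambda sequence in headers: {starts}")

    return TransformationLeg(
        step_id=StepId(step_id),
        environment=Environment(environment),
        direction=direction,
        windows=windows,
    )


def write_window_table(legs: Iterable[TransformationLeg], path: Union[str, Path]) -> None:
    """Write legs to the canonical window table.

    Rows are ordered deterministically (step, environment, direction,
    window order, sample index) and numbers are serialized with full
    round-trip precision, so identical inputs give byte-identical files.
    """
    records = []
    for leg in sorted(
        legs, key=lambda l: (l.step_id.value, l.environment.value, l.direction.value)
    ):
        for w in leg.windows:
            for i, du in enumerate(w.delta_u):
                records.append(
                    (
                        leg.step_id.value,
                        leg.environment.value,
                        leg.direction.value,
                        repr(float(w.lambda_start)),
                        repr(float(w.lambda_end)),
                        i,
                        repr(float(du)),
                        repr(float(w.temperature)),
                    )
                )
    df = pd.DataFrame(records, columns=WINDOW_TABLE_COLUMNS)
    df.to_csv(path, index=False)


def read_window_table(
    path: Union[str, Path], discard_fraction: float = DEFAULT_DISCARD_FRACTION
) -> list[TransformationLeg]:
    """Read the canonical window table back into transformation legs.

    Legs are grouped by (step_id, environment, direction); sample order
    within each window is preserved.  An empty table yields no legs.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in WINDOW_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"window table missing columns: {missing}")
    if df.empty:
        return []

    legs = []
    for (step, env, direction), group in df.groupby(
        ["step_id", "environment", "direction"], sort=True
    ):
        temps = group["temperature_K"].unique()
        if temps.size > 1:
            raise ValueError(
                f"leg ({step}, {direction}) mixes temperatures: {sorted(temps)}"
            )
        windows = []
        for (ls, le), wgroup in group.groupby(["lambda_start", "lambda_end"], sort=False):
            wgroup = wgroup.sort_values("sample_index")
            windows.append(
                LambdaWindow(
                    lambda_start=float(ls),
                    lambda_end=float(le),
                    direction=Direction(direction),
                    delta_u=wgroup["delta_u_kcal_mol"].to_numpy(),
                    temperature=float(temps[0]),
                    discard_fraction=discard_fraction,
                )
            )
        windows.sort(key=lambda w: w.lambda_start, reverse=Direction(direction) == Direction.BACKWARD)
        legs.append(
            TransformationLeg(
                step_id=StepId(step),
                environment=Environment(env),
                direction=Direction(direction),
                windows=windows,
            )
        )
    return legs


def write_ti_profile(profile: TIProfile, path: Union[str, Path]) -> None:
    """Write a TI profile to its canonical table at full precision."""
    df = pd.DataFrame(
        {
            "lambda": [repr(float(x)) for x in profile.lambda_grid],
            "mean_dudl_kcal_mol": [repr(float(x)) for x in profile.mean_dudl],
            "sem_dudl_kcal_mol": [repr(float(x)) for x in profile.sem_dudl],
            "n_samples": profile.n_samples,
        }
    )
    df.to_csv(path, index=False)


def read_ti_profile(path: Union[str, Path]) -> TIProfile:
    """Read and validate a TI profile table."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in TI_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"TI profile table missing columns: {missing}")
    return TIProfile(
        lambda_grid=df["lambda"].to_numpy(dtype=float),
        mean_dudl=df["mean_dudl_kcal_mol"].to_numpy(dtype=float),
        sem_dudl=df["sem_dudl_kcal_mol"].to_numpy(dtype=float),
        n_samples=df["n_samples"].to_numpy(dtype=int),
    )
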