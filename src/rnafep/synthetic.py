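"""Ground-truth-known synthetic alchemical datasets.

Window samples are drawn from the unique Gaussian work-distribution
pair consistent with the Crooks fluctuation theorem for a given window
free energy dG and work spread sigma_W:

    forward  dU ~ N(dG + sigma^2 / 2kT, sigma^2)
    backward dU ~ N(-dG + sigma^2 / 2kT, sigma^2)

so exponential averaging, BAR, and the closed form all agree on dG in
expectation -- estimator acceptance is analytic rather than circular.
Restraint TI profiles come from the exact harmonic-coupling law
<dU/dlambda> = (k/2) sigma_cv^2 / (1 + beta lambda k sigma_cv^2), whose
integral is (kT/2) ln(1 + beta k sigma_cv^2).

``gen_study`` builds full multi-ligand, multi-replicate studies with
every cycle step generated self-consistently from a decomposition of
the true binding free energy, plus optional planted pathologies
(hysteresis bursts; restraint outliers) for QC calibration.  Everything
is deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from rnafep.constants import DEFAULT_DISCARD_FRACTION, kt
from rnafep.cycle import RestraintScheme, standard_state_correction
from rnafep.types import (
    Direction,
    Environment,
    LambdaWindow,
    StepId,
    TIProfile,
    TransformationLeg,
)

#: Study shape mirroring the source protocol: complex-side legs use 40
#: lambda windows, bulk-side legs 30; first 20% of each window's
#: samples treated as equilibration.
N_WINDOWS_COMPLEX = 40
N_WINDOWS_BULK = 30

#: Default ligand panel: six congeneric binders spanning a 5.5 kcal/mol
#: affinity range (the realistic spread for a theophylline-analog set).
DEFAULT_LIGANDS = (
    ("lig1", -9.0),
    ("lig2", -7.9),
    ("lig3", -6.8),
    ("lig4", -5.7),
    ("lig5", -4.6),
    ("lig6", -3.5),
)


def gen_fep_window(
    delta_g_true: float,
    sigma_w: float,
    n_fwd: int,
    n_bwd: int,
    temperature: float,
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Bidirectional dU samples for one window (see module docstring).

    With sigma_w = 0 every forward sample equals dG_true exactly (and
    every backward sample equals -dG_true).
    """
    if sigma_w < 0:
        raise ValueError("sigma_w must be nonnegative")
    rng = np.random.default_rng(seed)
    dissipation = sigma_w**2 / (2.0 * kt(temperature))
    fwd = rng.normal(delta_g_true + dissipation, sigma_w, size=n_fwd)
    bwd = rng.normal(-delta_g_true + dissipation, sigma_w, size=n_bwd)
    return fwd, bwd


def gen_ti_profile(
    force_constant: float,
    cv_sd: float,
    lambda_grid: Sequence[float],
    noise_sem: float,
    seed: int,
    temperature: float = 298.0,
    n_samples_per_point: int = 1000,
    negate: bool = False,
) -> tuple[TIProfile, float]:
    """Harmonic restraint-coupling TI profile with closed-form truth.

    Returns (profile, dG_true) with dG_true = (kT/2) ln(1 + beta k
    sigma^2), the work of turning the restraint ON.  ``negate=True``
    yields the reverse (turn-OFF) profile whose integral is -dG_true.
    """
    if force_constant <= 0:
        raise ValueError("force_constant must be positive")
    if cv_sd <= 0:
        raise ValueError("cv_sd must be positive")
    rng = np.random.default_rng(seed)
    lam = np.asarray(lambda_grid, dtype=float)
    beta = 1.0 / kt(temperature)
    var = cv_sd**2

    coupling = lam if not negate else 1.0 - lam
    mean = 0.5 * force_constant * var / (1.0 + beta * coupling * force_constant * var)
    if negate:
        mean = -mean
    if noise_sem > 0:
        mean = mean + rng.normal(0.0, noise_sem, size=lam.size)
    profile = TIProfile(
        lambda_grid=lam,
        mean_dudl=mean,
        sem_dudl=np.full(lam.size, max(noise_sem, 1e-12)),
        n_samples=np.full(lam.size, n_samples_per_point),
    )
    dg_true = 0.5 * kt(temperature) * math.log(1.0 + beta * force_constant * var)
    return profile, dg_true


def gen_step_legs(
    step_id: StepId,
    environment: Environment,
    delta_g_true: float,
    n_windows: int,
    sigma_w: float,
    n_samples: int,
    temperature: float,
    seed: int,
    discard_fraction: float = DEFAULT_DISCARD_FRACTION,
    hysteresis_offset: float = 0.0,
) -> tuple[TransformationLeg, TransformationLeg]:
    """A bidirectional pair of FEP legs whose window truths sum to
    ``delta_g_true`` (split evenly across windows).

    ``hysteresis_offset`` is a pathology hook: it shifts every forward
    window's samples by offset/n_windows, breaking reversibility by
    exactly ``offset`` in expectation while moving the combined
    estimate by offset/2.
    """
    edges = np.linspace(0.0, 1.0, n_windows + 1)
    per_window_dg = delta_g_true / n_windows
    per_window_offset = hysteresis_offset / n_windows
    fwd_windows = []
    bwd_windows = []
    for i in range(n_windows):
        f, b = gen_fep_window(
            per_window_dg, sigma_w, n_samples, n_samples, temperature, seed + i
        )
        fwd_windows.append(
            LambdaWindow(
                lambda_start=edges[i],
                lambda_end=edges[i + 1],
                direction=Direction.FORWARD,
                delta_u=f + per_window_offset,
                temperature=temperature,
                discard_fraction=discard_fraction,
            )
        )
        bwd_windows.append(
            LambdaWindow(
                lambda_start=edges[i + 1],
                lambda_end=edges[i],
                direction=Direction.BACKWARD,
                delta_u=b,
                temperature=temperature,
                discard_fraction=discard_fraction,
            )
        )
    fwd = TransformationLeg(step_id, environment, Direction.FORWARD, fwd_windows)
    bwd = TransformationLeg(
        step_id, environment, Direction.BACKWARD, list(reversed(bwd_windows))
    )
    return fwd, bwd


def gen_restraint_step_profiles(
    delta_g_true: float,
    noise_sem: float,
    seed: int,
    temperature: float = 298.0,
    force_constant: float = 10.0,
    cv_sd: float = 0.5,
    n_points: int = 101,
) -> tuple[TIProfile, TIProfile]:
    """Bidirectional TI profile pair for a restraint step whose forward
    integral equals ``delta_g_true``.

    The harmonic-coupling law fixes the profile shape; it is scaled so
    its integral matches the step truth (restraint steps bundle several
    CV restraints, so the net work is a free parameter of the study).
    The backward profile is the negated, lambda-reversed shape, as a
    turn-on/turn-off pair produces.
    """
    lam = np.linspace(0.0, 1.0, n_points)
    base_fwd, dg_on = gen_ti_profile(
        force_constant, cv_sd, lam, 0.0, seed, temperature=temperature
    )
    scale = delta_g_true / dg_on
    rng = np.random.default_rng(seed)
    sem = max(noise_sem, 1e-12)
    fwd_mean = base_fwd.mean_dudl * scale + rng.normal(0.0, sem, size=lam.size)
    bwd_mean = -(base_fwd.mean_dudl * scale)[::-1] + rng.normal(0.0, sem, size=lam.size)
    fwd = TIProfile(lam, fwd_mean, np.full(lam.size, sem), base_fwd.n_samples)
    bwd = TIProfile(lam, bwd_mean, np.full(lam.size, sem), base_fwd.n_samples)
    return fwd, bwd


@dataclass
class Pathology:
    replicate_index: int  # flat index: ligand_index * n_replicates + replicate
    kind: str  # "hysteresis_burst" | "restraint_outlier"
    magnitude: float  # kcal/mol offset for bursts; scale factor for outliers

    def __post_init__(self) -> None:
        if self.kind not in ("hysteresis_burst", "restraint_outlier"):
            raise ValueError(f"unknown pathology kind: {self.kind}")


@dataclass
class StudySpec:
    """Shape and ground truth of a synthetic multi-replicate study."""

    ligands: Sequence[tuple[str, float]] = DEFAULT_LIGANDS
    n_replicates: int = 3
    n_samples: int = 1000
    sigma_w: float = 0.5
    temperature: float = 298.0
    seed: int = 0
    variant: str = "standard"
    scheme: RestraintScheme = field(default_factory=RestraintScheme)
    n_windows_complex: int = N_WINDOWS_COMPLEX
    n_windows_bulk: int = N_WINDOWS_BULK
    discard_fraction: float = DEFAULT_DISCARD_FRACTION
    ti_noise_sem: float = 0.05
    pathologies: Sequence[Pathology] = ()
    # decomposition rule: fixed truths for steps 1, 2, 4 (and 5 when the
    # backbone-restrained variant is generated); step 3 is solved so the
    # assembled cycle returns the ligand's true dG_bind.
    step1_dg: float = -2.5
    step2_dg: float = 4.0
    step4_dg: float = -3.0
    step5_dg: float = 1.5

    def __post_init__(self) -> None:
        if self.sigma_w <= 0:
            raise ValueError("sigma_w must be positive")
        if self.variant not in ("standard", "backbone_restrained"):
            raise ValueError(f"unknown variant: {self.variant}")
        if self.variant == "backbone_restrained" and not self.scheme.restrained_variant:
            self.scheme = RestraintScheme(backbone_rmsd=10.0)
        n_total = len(self.ligands) * self.n_replicates
        for p in self.pathologies:
            if not (0 <= p.replicate_index < n_total):
                raise ValueError(
                    f"pathology replicate index {p.replicate_index} out of "
                    f"range for {n_total} replicates"
                )


@dataclass
class ReplicateData:
    """All generated legs and profiles for one replicate of one ligand."""

    ligand_id: str
    replicate_id: str
    fep_legs: dict  # StepId -> (fwd TransformationLeg, bwd TransformationLeg)
    ti_profiles: dict  # StepId -> (fwd TIProfile, bwd TIProfile)
    truth: dict  # StepId -> true step dG (forward convention)


@dataclass
class StudyData:
    spec: StudySpec
    replicates: list[ReplicateData]
    manifest: dict  # ground truths for assertions


def _decompose(spec: StudySpec, dg_bind: float, ss_term: float) -> dict[StepId, float]:
    """Solve the per-step truths so that the cycle assembly recovers
    dg_bind exactly (see rnafep.cycle for the sign convention)."""
    g = {
        StepId.STEP1: spec.step1_dg,
        StepId.STEP2: spec.step2_dg,
        StepId.STEP4: spec.step4_dg,
    }
    g[StepId.STEP3] = (
        g[StepId.STEP4] + ss_term + g[StepId.STEP2] - g[StepId.STEP1] - dg_bind
    )
    if spec.variant == "backbone_restrained":
        # the backbone-restraint work enters step 4 and step 5 equally,
        # cancelling in the assembly
        g[StepId.STEP5] = spec.step5_dg
        g[StepId.STEP4] = g[StepId.STEP4] + spec.step5_dg
    return g


def gen_study(spec: StudySpec) -> StudyData:
    """Generate a full study: per ligand x replicate, bidirectional FEP
    legs for the alchemical steps (2, 3), bidirectional TI profile
    pairs for the restraint steps (1, 4, and 5 when backbone-restrained),
    and a manifest of all ground truths.

    Pathologies: ``hysteresis_burst`` adds its magnitude (kcal/mol) to
    the forward direction of step 3; ``restraint_outlier`` multiplies
    the replicate's step-1 truth by its magnitude.
    """
    ss_term = standard_state_correction(spec.scheme, spec.temperature)
    replicates = []
    manifest = {
        "variant": spec.variant,
        "temperature": spec.temperature,
        "standard_state_term": ss_term,
        "ligands": {},
        "pathologies": [
            {"replicate_index": p.replicate_index, "kind": p.kind, "magnitude": p.magnitude}
            for p in spec.pathologies
        ],
    }
    pathology_by_index: dict[int, list[Pathology]] = {}
    for p in spec.pathologies:
        pathology_by_index.setdefault(p.replicate_index, []).append(p)

    flat = 0
    for lig_idx, (ligand_id, dg_bind) in enumerate(spec.ligands):
        manifest["ligands"][ligand_id] = {"delta_g_bind": dg_bind, "replicates": {}}
        for rep in range(spec.n_replicates):
            rep_id = f"{ligand_id}_r{rep + 1}"
            truths = _decompose(spec, dg_bind, ss_term)
            burst = 0.0
            for p in pathology_by_index.get(flat, []):
                if p.kind == "restraint_outlier":
                    truths[StepId.STEP1] = truths[StepId.STEP1] * p.magnitude
                    # keep the cycle self-consistent: step 3 absorbs the shift
                    truths[StepId.STEP3] = (
                        truths[StepId.STEP4]
                        - (truths.get(StepId.STEP5, 0.0) if spec.variant == "backbone_restrained" else 0.0)
                        + ss_term
                        + truths[StepId.STEP2]
                        - truths[StepId.STEP1]
                        - dg_bind
                    )
                elif p.kind == "hysteresis_burst":
                    burst = p.magnitude

            base_seed = (spec.seed * 1_000_003 + flat * 7919) % (2**31)
            fep_steps = {
                StepId.STEP2: (Environment.BULK, spec.n_windows_bulk),
                StepId.STEP3: (Environment.COMPLEX, spec.n_windows_complex),
            }
            ti_steps = [StepId.STEP1, StepId.STEP4]
            if spec.variant == "backbone_restrained":
                ti_steps.append(StepId.STEP5)

            fep_legs = {}
            for k, (step_id, (env, n_win)) in enumerate(fep_steps.items()):
                fwd, bwd = gen_step_legs(
                    step_id,
                    env,
                    truths[step_id],
                    n_win,
                    spec.sigma_w,
                    spec.n_samples,
                    spec.temperature,
                    seed=base_seed + 101 * k,
                    discard_fraction=spec.discard_fraction,
                    hysteresis_offset=burst if step_id == StepId.STEP3 else 0.0,
                )
                fep_legs[step_id] = (fwd, bwd)

            ti_profiles = {}
            for k, step_id in enumerate(ti_steps):
                ti_profiles[step_id] = gen_restraint_step_profiles(
                    truths[step_id],
                    spec.ti_noise_sem,
                    seed=base_seed + 100_000 + 211 * k,
                    temperature=spec.temperature,
                )

            replicates.append(
                ReplicateData(
                    ligand_id=ligand_id,
                    replicate_id=rep_id,
                    fep_legs=fep_legs,
                    ti_profiles=ti_profiles,
                    truth=dict(truths),
                )
            )
            manifest["ligands"][ligand_id]["replicates"][rep_id] = {
                s.value: truths[s] for s in truths
            }
            flat += 1

    return StudyData(spec=spec, replicates=replicates, manifest=manifest)
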