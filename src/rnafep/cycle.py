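"""Thermodynamic-cycle assembly for absolute binding free energies.

The cycle follows the double-decoupling scheme with seven harmonic
restraints on the ligand (conformation RMSD, polar/azimuthal position
angles, three quaternion-based Euler angles, COM distance) and, in the
backbone-restrained variant, an eighth RMSD restraint on the RNA
backbone plus an extra apo-target step.

Sign convention (pinned by the generator-recovery tests): every step's
delta_g is the forward-as-simulated work -- restraints are turned OFF in
steps 1/4/5, the ligand is decoupled in steps 2/3.  The assembly is

    dG_bind = dG4 - dG3 + dG_ss + dG2 - dG1        (standard)
    dG_bind = dG4 - dG3 + dG_ss + dG2 - dG1 - dG5  (backbone-restrained)

where dG_ss > 0 is the analytic work of imposing the positional and
orientational restraints on a noninteracting ligand at standard
concentration.  Step 5 cancels the backbone-restraint work between the
holo and apo ends of the cycle, which is exactly why the two variants
agree on the same underlying system.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from rnafep.constants import STANDARD_VOLUME_A3, kt
from rnafep.types import BindingEstimate, LigandResult, QCDecision, StepEstimate, StepId

DEG = math.pi / 180.0


@dataclass
class RestraintScheme:
    """Force constants of the harmonic CV restraints.

    Distance-like constants (ligand_rmsd, com_distance, backbone_rmsd)
    are in kcal/mol/A^2; angular constants are in kcal/mol/deg^2 by
    default (set ``angle_units='rad'`` if a producer reports them per
    squared radian).  ``reference_values`` holds the restraint centers:
    com_distance in angstroms, angles in degrees.
    """

    ligand_rmsd: float = 10.0
    polar_angle: float = 0.1
    azimuthal_angle: float = 0.1
    euler_q1: float = 0.1
    euler_q2: float = 0.1
    euler_q3: float = 0.1
    com_distance: float = 10.0
    backbone_rmsd: Optional[float] = None
    angle_units: str = "deg"
    reference_values: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in (
            "ligand_rmsd",
            "polar_angle",
            "azimuthal_angle",
            "euler_q1",
            "euler_q2",
            "euler_q3",
            "com_distance",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"force constant {name} must be nonnegative")
        if self.backbone_rmsd is not None and self.backbone_rmsd <= 0:
            raise ValueError("backbone_rmsd force constant must be positive when present")
        if self.angle_units not in ("deg", "rad"):
            raise ValueError(f"angle_units must be 'deg' or 'rad', got {self.angle_units}")
        defaults = {
            "com_distance": 5.0,
            "polar_angle": 90.0,
            "azimuthal_angle": 0.0,
            "euler_q1": 90.0,
            "euler_q2": 0.0,
            "euler_q3": 0.0,
        }
        self.reference_values = {**defaults, **self.reference_values}

    @property
    def restrained_variant(self) -> bool:
        return self.backbone_rmsd is not None

    def angular_k_rad(self, name: str) -> float:
        """Angular force constant converted to kcal/mol/rad^2."""
        k = getattr(self, name)
        if self.angle_units == "deg":
            return k / (DEG * DEG)
        return k


class QuadratureError(RuntimeError):
    pass


def _converging_quad(integrand, lo: float, hi: float, rtol: float = 1e-6) -> float:
    """Trapezoidal quadrature with grid doubling until the relative
    change on doubling drops below ``rtol``."""
    n = 257
    prev = None
    for _ in range(18):
        x = np.linspace(lo, hi, n)
        val = float(np.trapezoid(integrand(x), x))
        if prev is not None and val != 0.0 and abs(val - prev) <= rtol * abs(val):
            return val
        prev = val
        n = 2 * n - 1
    raise QuadratureError("quadrature did not converge on grid doubling")


def standard_state_correction(
    scheme: RestraintScheme,
    temperature: float,
    standard_volume: float = STANDARD_VOLUME_A3,
) -> float:
    """Work (kcal/mol) of imposing the positional and orientational
    restraints on a noninteracting ligand at standard concentration.

    The unrestrained reference confines the ligand COM to the
    standard-state volume V° (a sphere of radius (3V°/4pi)^(1/3) around
    the receptor) with free orientation over 8pi^2.  Each restrained
    coordinate is integrated by 1-D quadrature with its Jacobian (r^2
    for the COM distance, sin(theta) for the polar and first Euler
    angle); no narrow-trap Gaussian approximation is substituted.
    Positive for any finite force constants, and exactly 0 when all
    positional/orientational force constants are 0.
    """
    beta = 1.0 / kt(temperature)
    ref = scheme.reference_values
    r_cap = (3.0 * standard_volume / (4.0 * math.pi)) ** (1.0 / 3.0)

    def boltz(k_rad_or_a2, center, x):
        return np.exp(-0.5 * beta * k_rad_or_a2 * (x - center) ** 2)

    k_r = scheme.com_distance
    if k_r < 0:
        raise ValueError("com_distance force constant must be nonnegative")
    i_r = _converging_quad(lambda r: r * r * boltz(k_r, ref["com_distance"], r), 0.0, r_cap)

    k_th = scheme.angular_k_rad("polar_angle")
    th0 = ref["polar_angle"] * DEG
    i_th = _converging_quad(lambda t: np.sin(t) * boltz(k_th, th0, t), 0.0, math.pi)

    k_ph = scheme.angular_k_rad("azimuthal_angle")
    ph0 = ref["azimuthal_angle"] * DEG
    i_ph = _converging_quad(lambda p: boltz(k_ph, ph0, p), ph0 - math.pi, ph0 + math.pi)

    k_e1 = scheme.angular_k_rad("euler_q1")
    e1 = ref["euler_q1"] * DEG
    i_e1 = _converging_quad(lambda t: np.sin(t) * boltz(k_e1, e1, t), 0.0, math.pi)
    k_e2 = scheme.angular_k_rad("euler_q2")
    e2 = ref["euler_q2"] * DEG
    i_e2 = _converging_quad(lambda p: boltz(k_e2, e2, p), e2 - math.pi, e2 + math.pi)
    k_e3 = scheme.angular_k_rad("euler_q3")
    e3 = ref["euler_q3"] * DEG
    i_e3 = _converging_quad(lambda p: boltz(k_e3, e3, p), e3 - math.pi, e3 + math.pi)

    kbt = kt(temperature)
    positional = -kbt * math.log(i_r * i_th * i_ph / standard_volume)
    orientational = -kbt * math.log(i_e1 * i_e2 * i_e3 / (8.0 * math.pi**2))
    return positional + orientational


def isotropic_trap_correction(
    force_constant: float,
    temperature: float,
    standard_volume: float = STANDARD_VOLUME_A3,
) -> float:
    """Standard-state work of a pure 3-D isotropic Cartesian trap,
    computed by quadrature of [integral exp(-beta k x^2/2) dx]^3.

    Closed form: kT ln[ V° / (2 pi kT / k)^(3/2) ]; used as the
    quadrature cross-check where no Jacobian enters.
    """
    if force_constant <= 0:
        raise ValueError("force constant must be positive")
    kbt = kt(temperature)
    sigma = math.sqrt(kbt / force_constant)
    half = 15.0 * sigma
    i_x = _converging_quad(
        lambda x: np.exp(-0.5 * force_constant * x * x / kbt), -half, half
    )
    return -kbt * math.log(i_x**3 / standard_volume)


_STANDARD_STEPS = (StepId.STEP1, StepId.STEP2, StepId.STEP3, StepId.STEP4)


def assemble_cycle(
    steps: dict[StepId, StepEstimate],
    scheme: RestraintScheme,
    temperature: float,
    variant: str = "standard",
    replicate_id: Optional[str] = None,
    standard_volume: float = STANDARD_VOLUME_A3,
) -> BindingEstimate:
    """Assemble the standard-state binding free energy from step
    estimates (see module docstring for the sign convention).

    ``variant`` is 'standard' (steps 1-4) or 'backbone_restrained'
    (steps 1-5; step 5's apo-target restraint work is subtracted so the
    backbone-restraint device cancels between holo and apo states).
    """
    if variant not in ("standard", "backbone_restrained"):
        raise ValueError(f"unknown cycle variant: {variant}")
    steps = {StepId(k): v for k, v in steps.items()}
    required = _STANDARD_STEPS + ((StepId.STEP5,) if variant == "backbone_restrained" else ())
    missing = [s.value for s in required if s not in steps]
    if missing:
        raise ValueError(f"variant '{variant}' is missing steps: {missing}")
    if variant == "backbone_restrained" and not scheme.restrained_variant:
        raise ValueError("backbone_restrained variant needs scheme.backbone_rmsd set")
    for s in required:
        t = steps[s].temperature
        if t is not None and not math.isclose(t, temperature):
            raise ValueError(f"{s.value} temperature {t} K != cycle temperature {temperature} K")

    ss = standard_state_correction(scheme, temperature, standard_volume)
    g = {s: steps[s].delta_g for s in required}
    delta_g_bind = g[StepId.STEP4] - g[StepId.STEP3] + ss + g[StepId.STEP2] - g[StepId.STEP1]
    if variant == "backbone_restrained":
        delta_g_bind -= g[StepId.STEP5]

    stderr = math.sqrt(sum(steps[s].stderr ** 2 for s in required))
    total_hysteresis = sum(steps[s].hysteresis for s in required)
    return BindingEstimate(
        delta_g_bind=delta_g_bind,
        stderr=stderr,
        total_hysteresis=total_hysteresis,
        standard_state_term=ss,
        variant=variant,
        replicate_id=replicate_id,
        step_delta_g={s.value: g[s] for s in required},
    )


def aggregate_replicates(
    ligand_id: str,
    estimates: list[BindingEstimate],
    qc_decisions: Optional[list[QCDecision]] = None,
) -> LigandResult:
    """Mean and standard deviation of the binding free energy over the
    accepted replicates; rejected replicates are kept, flagged, and
    excluded from the statistics.
    """
    if qc_decisions is None:
        accepted = list(estimates)
        rejected: list[QCDecision] = []
    else:
        if len(qc_decisions) != len(estimates):
            raise ValueError("one QC decision per replicate estimate is required")
        accepted = [e for e, d in zip(estimates, qc_decisions) if d.accepted]
        rejected = [d for d in qc_decisions if not d.accepted]
    if not accepted:
        raise ValueError(
            f"ligand {ligand_id}: all replicates rejected by QC; "
            "run replacement replicates before aggregating"
        )
    values = np.array([e.delta_g_bind for e in accepted])
    mean = float(values.mean())
    sd = float(values.std(ddof=1)) if values.size >= 2 else None
    return LigandResult(
        ligand_id=ligand_id,
        replicate_estimates=accepted,
        mean=mean,
        sd=sd,
        rejected=rejected,
    )
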