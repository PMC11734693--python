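"""Ionic strength of a buffer and ion-count planning for a simulation box.

Ionic strength is I = 1/2 sum_i c_i z_i^2 over all charged species.
Fully dissociating salts expand stoichiometrically; weak acids (e.g.
the HEPES sulfonate/piperazinium system near neutral pH) are split by
Henderson-Hasselbalch at the stated pH.  Whether the titration
counterion of a buffering species (the Na+ brought in by titrating
HEPES free acid with NaOH) is counted toward I is a convention choice;
it is off by default and exposed as a flag.

Ion planning converts a target salt concentration and box volume into
co-ion/counterion pair counts, then adds neutralizing counterions so
the final system is exactly electroneutral.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

AVOGADRO = 6.02214076e23

#: HEPES sulfonic-acid pKa2 at 25 C.
HEPES_PKA = 7.48


@dataclass
class IonSpecies:
    name: str
    concentration_mM: float
    charge: int

    def __post_init__(self) -> None:
        if self.concentration_mM < 0:
            raise ValueError(f"negative concentration for {self.name}")


@dataclass
class Salt:
    """A fully dissociating salt: ions as (name, formal charge, stoichiometry)."""

    name: str
    concentration_mM: float
    ions: Sequence[tuple[str, int, int]]

    def __post_init__(self) -> None:
        net = sum(z * nu for _, z, nu in self.ions)
        if net != 0:
            raise ValueError(f"salt {self.name} is not charge-balanced (net {net:+d})")


@dataclass
class WeakAcid:
    """A weak acid/base buffering species split by Henderson-Hasselbalch.

    The deprotonated form carries ``deprotonated_charge`` (default -1,
    the sulfonate of a Good's buffer); the protonated form is neutral.
    ``counterion`` optionally names the titration counterion released
    alongside the charged form.
    """

    name: str
    concentration_mM: float
    pka: float
    ph: float
    deprotonated_charge: int = -1
    counterion: Optional[tuple[str, int]] = None

    @property
    def ionized_fraction(self) -> float:
        frac = 1.0 / (1.0 + 10.0 ** (self.pka - self.ph))
        if not (0.0 < frac < 1.0):
            raise ValueError(f"ionized fraction of {self.name} must be in (0, 1)")
        return frac


@dataclass
class BufferSpec:
    salts: list[Salt] = field(default_factory=list)
    weak_acids: list[WeakAcid] = field(default_factory=list)


def species_concentrations(
    spec: BufferSpec, include_titration_counterion: bool = False
) -> list[IonSpecies]:
    """Expand a buffer spec into its charged species.

    Salts expand stoichiometrically; weak acids contribute their
    ionized fraction at the stated pH.  The titration counterion of a
    weak acid is included only on request (convention flag).
    """
    out: list[IonSpecies] = []
    for salt in spec.salts:
        for ion, z, nu in salt.ions:
            out.append(IonSpecies(ion, salt.concentration_mM * nu, z))
    for wa in spec.weak_acids:
        if wa.pka is None:
            raise ValueError(f"weak acid {wa.name} has no pKa")
        ionized = wa.concentration_mM * wa.ionized_fraction
        out.append(IonSpecies(f"{wa.name}{wa.deprotonated_charge:+d}", ionized, wa.deprotonated_charge))
        if include_titration_counterion:
            if wa.counterion is None:
                raise ValueError(f"weak acid {wa.name} has no titration counterion defined")
            cname, cz = wa.counterion
            out.append(IonSpecies(cname, ionized * abs(wa.deprotonated_charge) / abs(cz), cz))
    return out


def ionic_strength(ions: Sequence[IonSpecies] | Sequence[tuple[float, int]]) -> float:
    """I = 1/2 sum c_i z_i^2, in mM for concentrations in mM."""
    if not ions:
        raise ValueError("ion list must be nonempty")
    total = 0.0
    for ion in ions:
        if isinstance(ion, IonSpecies):
            c, z = ion.concentration_mM, ion.charge
        else:
            c, z = ion
        if c < 0:
            raise ValueError("negative concentration")
        total += c * z * z
    return 0.5 * total


def experimental_buffer() -> BufferSpec:
    """The affinity-assay buffer: 50 mM NaCl, 5 mM MgCl2, 100 mM HEPES
    titrated to pH 7.3."""
    return BufferSpec(
        salts=[
            Salt("NaCl", 50.0, [("Na+", 1, 1), ("Cl-", -1, 1)]),
            Salt("MgCl2", 5.0, [("Mg2+", 2, 1), ("Cl-", -1, 2)]),
        ],
        weak_acids=[
            WeakAcid("HEPES", 100.0, pka=HEPES_PKA, ph=7.3, counterion=("Na+", 1))
        ],
    )


@dataclass
class IonPlan:
    box_volume_A3: float
    salt: tuple[str, str]
    cation_charge: int
    anion_charge: int
    n_pairs: int
    n_neutralizing: int
    neutralizing_ion: str
    system_charge: int
    achieved_mM: float
    residual_mM: float

    @property
    def net_charge(self) -> int:
        # salt pairs are charge-balanced; only neutralizers shift the total
        if self.system_charge == 0:
            return 0
        z = self.cation_charge if self.system_charge < 0 else self.anion_charge
        return self.system_charge + self.n_neutralizing * z


def plan_ions(
    box_volume_A3: float,
    target_salt_mM: float,
    salt: tuple[str, str] = ("Na+", "Cl-"),
    system_charge: int = 0,
    cation_charge: int = 1,
    anion_charge: int = -1,
) -> IonPlan:
    """Plan ion counts for a box: co-ion/counterion pairs to hit the
    target concentration, then neutralizing counterions.

    Pair count = round(c * N_A * V); the residual concentration error
    from rounding is reported.  Neutralization uses the salt ion of
    sign opposite to the system charge; an error is raised if the
    system charge is not an integer multiple of that ion's charge.
    """
    if box_volume_A3 <= 0:
        raise ValueError("box volume must be positive")
    if target_salt_mM < 0:
        raise ValueError("target concentration must be nonnegative")
    liters = box_volume_A3 * 1e-27
    exact = target_salt_mM * 1e-3 * AVOGADRO * liters
    n_pairs = int(round(exact))
    achieved = n_pairs / (AVOGADRO * liters) * 1e3

    if system_charge == 0:
        n_neutral = 0
        neutralizing = salt[0]
    elif system_charge < 0:
        if cation_charge <= 0:
            raise ValueError("cannot neutralize a negative system with a non-cation")
        if (-system_charge) % cation_charge:
            raise ValueError(
                f"system charge {system_charge} is not a multiple of the "
                f"cation charge {cation_charge:+d}"
            )
        n_neutral = (-system_charge) // cation_charge
        neutralizing = salt[0]
    else:
        if anion_charge >= 0:
            raise ValueError("cannot neutralize a positive system with a non-anion")
        if system_charge % (-anion_charge):
            raise ValueError(
                f"system charge {system_charge} is not a multiple of the "
                f"anion charge {anion_charge:+d}"
            )
        n_neutral = system_charge // (-anion_charge)
        neutralizing = salt[1]

    return IonPlan(
        box_volume_A3=box_volume_A3,
        salt=salt,
        cation_charge=cation_charge,
        anion_charge=anion_charge,
        n_pairs=n_pairs,
        n_neutralizing=n_neutral,
        neutralizing_ion=neutralizing,
        system_charge=system_charge,
        achieved_mM=achieved,
        residual_mM=achieved - target_salt_mM,
    )
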