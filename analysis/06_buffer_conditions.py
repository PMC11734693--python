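"""Buffer chemistry: ionic strength of the assay buffer and the ion
plan that approximates it in a simulation box.

Writes results/buffer.json.  The assay buffer (50 mM NaCl, 5 mM MgCl2,
100 mM HEPES at pH 7.3) works out to an ionic strength of 85 mM; a
68 A cubic box at 55 mM NaCl needs 10 co-ion/counterion pairs before
neutralizing counterions are added.
"""

import dataclasses
import json

from common import RESULTS
from rnafep.buffer import (
    experimental_buffer,
    ionic_strength,
    plan_ions,
    species_concentrations,
)


def main() -> None:
    RESULTS.mkdir(parents=True, exist_ok=True)
    ions = species_concentrations(experimental_buffer())
    strength = ionic_strength(ions)
    print("assay buffer ion species:")
    for ion in ions:
        print(f"  {ion.name:>8s}  {ion.concentration_mM:7.1f} mM  z = {ion.charge:+d}")
    print(f"ionic strength I = {strength:.1f} mM")

    # a typical RNA-ligand box: 68 A cube, 55 mM NaCl, net charge -32
    plan = plan_ions(68.0**3, 55.0, system_charge=-32)
    print(f"ion plan: {plan.n_pairs} Na+/Cl- pairs "
          f"({plan.achieved_mM:.1f} mM achieved) + "
          f"{plan.n_neutralizing} neutralizing {plan.neutralizing_ion}")

    out = {
        "ions": [dataclasses.asdict(i) for i in ions],
        "ionic_strength_mM": strength,
        "ion_plan": dataclasses.asdict(plan),
    }
    (RESULTS / "buffer.json").write_text(json.dumps(out, indent=2) + "\n")


if __name__ == "__main__":
    main()
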