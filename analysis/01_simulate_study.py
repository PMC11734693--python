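"""Generate the reference synthetic study and write its raw data.

Emits, per replicate: the canonical window table for the alchemical
steps and TI profile tables for the restraint steps, plus the
ground-truth manifest -- the same artifact layout a post-processed
simulation campaign would produce.
"""

import json

from common import RESULTS, reference_spec
from rnafep import alchemy_io
from rnafep.synthetic import gen_study


def main() -> None:
    outdir = RESULTS / "study"
    outdir.mkdir(parents=True, exist_ok=True)
    study = gen_study(reference_spec())
    for rep in study.replicates:
        legs = [leg for pair in rep.fep_legs.values() for leg in pair]
        alchemy_io.write_window_table(legs, outdir / f"{rep.replicate_id}_windows.csv")
        for step_id, (fwd, bwd) in rep.ti_profiles.items():
            alchemy_io.write_ti_profile(fwd, outdir / f"{rep.replicate_id}_{step_id.value}_ti_forward.csv")
            alchemy_io.write_ti_profile(bwd, outdir / f"{rep.replicate_id}_{step_id.value}_ti_backward.csv")
    (outdir / "manifest.json").write_text(json.dumps(study.manifest, indent=2) + "\n")
    n_path = len(study.manifest["pathologies"])
    print(f"generated {len(study.replicates)} replicates "
          f"({n_path} with planted pathologies) under {outdir}")


if __name__ == "__main__":
    main()
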