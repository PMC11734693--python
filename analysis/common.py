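"""Shared configuration for the analysis drivers.

All drivers regenerate the same deterministic reference study, so each
script can be run standalone in any order.  Outputs go to results/.
"""

from pathlib import Path

from rnafep.synthetic import Pathology, StudySpec

RESULTS = Path(__file__).resolve().parent.parent / "results"
STUDY_SEED = 2026

#: The reference study: six congeneric ligands, three replicates each,
#: 40 complex / 30 bulk windows, with two planted pathological
#: replicates to exercise the rejection protocol.
def reference_spec(variant: str = "standard") -> StudySpec:
    return StudySpec(
        seed=STUDY_SEED,
        variant=variant,
        n_samples=1000,
        pathologies=[
            Pathology(1, "hysteresis_burst", 15.0),
            Pathology(8, "restraint_outlier", 4.0),
        ],
    )
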