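"""End-to-end orchestration: study data -> step estimates -> assembled
cycles -> replicate QC -> per-ligand aggregates."""

from __future__ import annotations

from dataclasses import dataclass

from rnafep.cycle import aggregate_replicates, assemble_cycle
from rnafep.estimators import estimate_step, ti_step_estimate
from rnafep.qc import ReplicateRecord, apply_rejection
from rnafep.synthetic import ReplicateData, StudyData
from rnafep.types import BindingEstimate, LigandResult, QCDecision, StepEstimate


def estimate_replicate_steps(rep: ReplicateData, temperature: float) -> dict:
    """Per-step estimates for one replicate: FEP for the alchemical
    legs, bidirectional TI for the restraint legs."""
    steps: dict = {}
    for step_id, (fwd, bwd) in rep.fep_legs.items():
        steps[step_id] = estimate_step(fwd, bwd)
    for step_id, (fwd, bwd) in rep.ti_profiles.items():
        steps[step_id] = ti_step_estimate(fwd, bwd, step_id, temperature=temperature)
    return steps


@dataclass
class StudyResult:
    records: list[ReplicateRecord]
    decisions: list[QCDecision]
    ligand_results: list[LigandResult]

    @property
    def predictions(self) -> dict[str, float]:
        return {r.ligand_id: r.mean for r in self.ligand_results}


def process_study(
    study: StudyData,
    hysteresis_threshold: float = 10.0,
    restraint_multiplier: float = 2.5,
) -> StudyResult:
    """Run estimation, cycle assembly, QC, and aggregation for a study."""
    spec = study.spec
    records = []
    for rep in study.replicates:
        steps = estimate_replicate_steps(rep, spec.temperature)
        estimate = assemble_cycle(
            steps,
            spec.scheme,
            spec.temperature,
            variant=spec.variant,
            replicate_id=rep.replicate_id,
        )
        records.append(
            ReplicateRecord(
                replicate_id=rep.replicate_id,
                ligand_id=rep.ligand_id,
                estimate=estimate,
            )
        )

    decisions = apply_rejection(
        records,
        hysteresis_threshold=hysteresis_threshold,
        restraint_multiplier=restraint_multiplier,
    )

    ligand_results = []
    for ligand_id, _ in spec.ligands:
        reps = [
            (rec.estimate, dec)
            for rec, dec in zip(records, decisions)
            if rec.ligand_id == ligand_id
        ]
        estimates = [e for e, _ in reps]
        decs = [d for _, d in reps]
        ligand_results.append(aggregate_replicates(ligand_id, estimates, decs))

    return StudyResult(records=records, decisions=decisions, ligand_results=ligand_results)
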