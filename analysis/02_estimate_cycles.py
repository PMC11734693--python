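"""Estimate every cycle step and assemble per-replicate binding free
energies for the reference study.

Writes results/cycle_estimates.csv with one row per replicate: the
assembled dG_bind, its propagated standard error, the total cycle
hysteresis, and the per-step contributions.
"""

import pandas as pd

from common import RESULTS, reference_spec
from rnafep.cycle import assemble_cycle
from rnafep.pipeline import estimate_replicate_steps
from rnafep.synthetic import gen_study


def main() -> None:
    RESULTS.mkdir(parents=True, exist_ok=True)
    spec = reference_spec()
    study = gen_study(spec)
    rows = []
    for rep in study.replicates:
        steps = estimate_replicate_steps(rep, spec.temperature)
        est = assemble_cycle(steps, spec.scheme, spec.temperature,
                             variant=spec.variant, replicate_id=rep.replicate_id)
        truth = dict(spec.ligands)[rep.ligand_id]
        rows.append({
            "ligand_id": rep.ligand_id,
            "replicate_id": rep.replicate_id,
            "delta_g_bind_kcal_mol": round(est.delta_g_bind, 4),
            "stderr_kcal_mol": round(est.stderr, 4),
            "total_hysteresis_kcal_mol": round(est.total_hysteresis, 4),
            "standard_state_term_kcal_mol": round(est.standard_state_term, 4),
            "truth_kcal_mol": truth,
            **{f"{k}_kcal_mol": round(v, 4) for k, v in est.step_delta_g.items()},
        })
    df = pd.DataFrame(rows)
    out = RESULTS / "cycle_estimates.csv"
    df.to_csv(out, index=False)
    healthy = df[df.total_hysteresis_kcal_mol < 10.0]
    err = (healthy.delta_g_bind_kcal_mol - healthy.truth_kcal_mol).abs()
    print(f"wrote {len(df)} replicate estimates to {out}")
    print(f"low-hysteresis replicates track truth to "
          f"{err.mean():.3f} kcal/mol on average (max {err.max():.3f})")


if __name__ == "__main__":
    main()
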