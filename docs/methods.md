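# Methods

This note documents the models, conventions, and numerical choices
behind `rnafep`, and what the synthetic validation does and does not
demonstrate about real simulation data.

## Free energy estimators

**FEP (exponential averaging).** For a window with potential-energy
differences ΔU between adjacent λ states,
ΔG = −kT·ln⟨e^(−ΔU/kT)⟩ over the retained samples, computed via
log-sum-exp for numerical stability (k_B = 0.0019872 kcal/mol/K). The
leading `discard_fraction` of each window (default 0.2, mirroring a
200 ps equilibration discard from 1 ns windows) is stored on the window
and applied only at estimation time, so diagnostics always see the raw
stream.

The standard error is the larger of two estimates: first-order
propagation of the sample variance of e^(−ΔU/kT)
(kT·sd(x)/(mean(x)·√n)), and the standard error over 10 contiguous
block estimates. Block averaging partially compensates for sample
autocorrelation, which is otherwise ignored; for the i.i.d. synthetic
data the two agree.

**Bidirectional combination.** A backward leg samples the reverse
process, so its own estimate approximates −ΔG. The combined estimate is
(ΔG_fwd − ΔG_bwd)/2 and the hysteresis |ΔG_fwd + ΔG_bwd| measures the
deviation from perfect reversibility. Cycle-level hysteresis is the sum
over steps (the per-step quadrature alternative is a one-line change;
the sum is the stricter and simpler convention).

A note on antisymmetry: exponential averaging satisfies
g(ΔU) + g(−ΔU) ≤ 0 with equality only for constant ΔU (a Jensen-gap
inequality). Negating a finite noisy sample set therefore flips the
estimate only up to a gap of order σ²/kT, which closes quadratically as
the spread shrinks. This is a property of the estimator, not a bug; the
tests pin both the exact constant-ΔU case and the asymptotic behaviour.

**BAR.** The Bennett acceptance-ratio estimate solves

    Σᵢ f(ln(n_F/n_B) + β(W_F,i − ΔG)) = Σⱼ f(ln(n_B/n_F) + β(W_B,j + ΔG))

with f the Fermi function, by bisection (residual monotone in ΔG;
bracketed from the two one-sided FEP estimates; tolerance 1e-8, max 200
iterations). BAR is kept strictly as an independent cross-check on the
FEP path — the two must agree within 3 combined SE on Crooks-consistent
data — never as the production estimator, so the check is not circular.

**TI.** Trapezoidal quadrature of ⟨∂U/∂λ⟩ on the given grid, with the
SEM propagated through the trapezoid weights. No spline fitting: the
restraint-coupling integrand is smooth and monotone, and the trapezoid
error at 101 points is far below the sampling noise.

## Thermodynamic cycle and sign convention

Every step's ΔG is stored as the **forward-as-simulated work**:
restraints are turned *off* in steps 1 (bulk), 4 (complex) and 5 (apo
RNA); the ligand is decoupled in steps 2 (bulk) and 3 (complex). The
assembly is

    ΔG_bind = ΔG₄ − ΔG₃ + ΔG_ss + ΔG₂ − ΔG₁            (standard)
    ΔG_bind = ΔG₄ − ΔG₃ + ΔG_ss + ΔG₂ − ΔG₁ − ΔG₅      (backbone-restrained)

This is pinned by generator-recovery tests rather than prose: any
consistent decomposition of a known ΔG_bind must be recovered by the
assembly, and the two variants must agree on the same ground truth
(step 5 is exactly the term that makes the backbone-restraint work
cancel between holo and apo states). Uncertainties combine as
root-sum-square; hysteresis adds.

## Standard-state correction

ΔG_ss is the work of imposing the positional (COM distance r, polar θ,
azimuthal φ) and orientational (three Euler angles) restraints on a
noninteracting ligand at standard concentration. Each coordinate is
integrated by 1-D trapezoidal quadrature with grid doubling until the
relative change is below 1e-6, with its Jacobian (r² for the distance,
sin θ for the polar and first Euler angle); the positional reference is
the standard-state volume V° = 1661 Å³ (a sphere around the receptor)
and the orientational reference is free rotation, 8π². No narrow-trap
Gaussian approximation is substituted silently; the Gaussian closed
form is used only as a test oracle (the pure Cartesian isotropic trap,
kT·ln[V°/(2πkT/k)^{3/2}] = 5.27 kcal/mol at k = 10 kcal/mol/Å²,
T = 298 K, matched by quadrature to 1e-3).

Conventions worth stating:

- Angular force constants are interpreted in kcal/mol/deg² (the values
  0.1 kcal/mol printed per squared ångström in upstream configs cannot
  be literal for angles); a `angle_units="rad"` switch is provided.
  Degrees are converted exactly at the quadrature boundary.
- A force constant of 0 means "no restraint on that coordinate", and
  with all constants 0 the correction is exactly 0 (the restrained
  integrals collapse to the free references). Negative constants are
  errors.
- Default restraint centers put the trap well inside the integration
  domains (r₀ = 5 Å against the V° sphere radius 7.35 Å; angle centers
  at 90°/0°). A trap centered near a domain edge degrades the
  approximation; the quadrature will still converge but the result then
  reflects the truncated geometry.
- The correction is monotone increasing in every force constant and
  gains exactly kT·ln 2 when V° doubles (tight-trap regime).

Defaults mirror the production restraint scheme: 10 kcal/mol/Å² for
ligand RMSD and COM distance, 0.1 for the angles, and 10 for the
optional backbone RMSD restraint (present iff the backbone-restrained
variant is used).

## Replicate rejection (QC)

Two indicators, both computed from simulation output only:

1. **Hysteresis:** total cycle hysteresis must be strictly less than
   10 kcal/mol (a value of exactly 10 fails).
2. **Restraint outlier:** |ΔG_restraint| must not exceed 2.5× the
   magnitude of the pool median, the pool being the restraint-step ΔG
   of *all* replicates of *all* ligands in the same condition,
   candidate included (inclusion keeps the decision deterministic and
   order-invariant). The screened step defaults to step 1; the
   production protocol's wording is ambiguous between the bulk and
   complex restraint arms, so the step is configurable rather than
   resolved silently.

Rejected replicates are flagged, never deleted; aggregation (mean ± sd
over ≥ 2 accepted replicates) ignores them, and zero accepted
replicates is an error instructing the user to run replacements.

## Overlap diagnostics

Backward ΔU samples are negated so both directions describe the same
transformation, then both sets are histogrammed on shared equal-width
bins spanning the union range; a pseudo-count of 1/n per bin
regularizes empty bins (capping the divergence of disjoint
distributions) and D(p‖q) = Σ p·ln(p/q) ≥ 0 in nats. Defaults: 100
bins, threshold 0.5 nats for the sufficient/low classification — the
threshold is a report field so plots are self-describing, and both are
configurable.

Two facts matter for interpretation. First, Crooks-consistent
bidirectional pairs have an *intrinsic* mean separation of σ²/kT
between the forward and sign-aligned backward distributions, so the
true KL is σ²/(2(kT)²) ≈ 0.36 nats already at σ_W = 0.5 kcal/mol —
a healthy window is not at KL = 0. Second, the histogram estimator is
biased upward when bins outnumber what the samples populate; a bin
count near √n is appropriate (the analysis driver uses this for
1000-sample windows, while the 100-bin default targets 10⁴+ samples).

## Performance metrics

MAE, RMSE, Pearson r on values, Spearman ρ (Pearson on average ranks),
and Kendall τ-b (tie-corrected; identical to τ-a for distinct values).
Uncertainty by resampling ligand systems (paired values) with
replacement, 1000 times by default, summarizing each metric by its
bootstrap mean and percentile 2.5/97.5 interval. Degenerate resamples
(zero variance) are dropped from the affected metric's distribution
with a recorded count. The percentile interval is the simplest method
consistent with the protocol; with only six ligand systems it
undercovers noticeably (empirically ~83% instead of 95% for MAE under
unit-normal errors) — small-n bootstrap intervals should be read as
stability indicators, not calibrated confidence statements.

## Buffer chemistry

I = ½·Σ cᵢzᵢ² over all charged species. Fully dissociating salts expand
stoichiometrically; weak acids split by Henderson–Hasselbalch at the
stated pH. HEPES uses pKa 7.48 (sulfonic pKa₂ at 25 °C), giving 39.8 mM
HEPES⁻ at pH 7.3 and I = 84.9 ≈ 85 mM for the assay buffer; whether the
titration counterion counts toward I is a convention flag (off by
default — including it would give ~105 mM, inconsistent with the
reported value). Ion planning rounds pair counts to the nearest integer
(residual concentration reported) and then neutralizes exactly,
erroring if the system charge is not a multiple of the counterion
charge.

## Synthetic data generator

Window samples come from the unique Gaussian pair satisfying the
Crooks fluctuation relation for a given window free energy ΔG and work
spread σ_W: forward ΔU ~ N(ΔG + σ²/2kT, σ²), backward
ΔU ~ N(−ΔG + σ²/2kT, σ²). This makes estimator validation analytic
(closed forms exist for FEP, BAR, and the KL between directions) rather
than circular. Restraint TI profiles follow the exact harmonic-coupling
law ⟨∂U/∂λ⟩ = (k/2)σ_cv²/(1 + βλkσ_cv²), whose integral is
(kT/2)·ln(1 + βkσ_cv²); step-level profiles are scaled so the integral
matches the step's decomposed truth (a restraint step bundles several
CVs, so its net work is a study parameter).

Default study shape mirrors the production protocol: 6 ligands spanning
−9.0 … −3.5 kcal/mol (the realistic affinity range of a congeneric
theophylline-analog panel), 3 replicates, 40 complex / 30 bulk
λ-windows, discard fraction 0.2, σ_W = 0.5 kcal/mol, 1000 samples per
window per direction, T = 298 K. The step decomposition fixes
ΔG₁ = −2.5 (matching the typical pool median of bulk restraint
contributions), ΔG₂ = 4.0, ΔG₄ = −3.0 (ΔG₅ = 1.5 for the restrained
variant, injected equally into steps 4 and 5 so it cancels) and solves
ΔG₃ so the assembly returns the ligand's true ΔG_bind.

Pathology hooks: `hysteresis_burst` shifts one direction of the complex
decoupling step by a fixed offset (breaking reversibility by exactly
that amount in expectation); `restraint_outlier` scales the screened
restraint step's truth. Everything, pathologies included, is
deterministic under a fixed seed.

**What this does not emulate:** autocorrelated MD time series (beyond
what block averaging would soften), non-Gaussian work distributions,
conformational drift and other nonstationarity, finite-overlap bias
between adjacent windows, or force-field/solvent sensitivity. Passing
the synthetic suite demonstrates the post-processing is correct and
calibrated, not that a given simulation campaign is converged.

## Problem sizes used in validation

Closed-form estimator checks run at 10⁵ samples; cycle-closure checks
at 10⁴ samples per window on a 10/8-window cycle (3 replicates); the QC
calibration uses 100 seeded studies of 4 ligands × 3 replicates at 200
samples per window with 10/8 windows — the rejection decision depends
only on step-level scalars, so the calibration is insensitive to window
count and sample depth, and the planted-pathology magnitudes and
thresholds are the protocol's values throughout. The reference analysis
study uses the full default shape.
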