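"""Model evaluation: visual predictive check and nonparametric bootstrap.

Runs a VPC (how well do simulated replicate studies bracket the observed
medians?) and a small arm-stratified bootstrap on a paper-sized synthetic
study.
"""

from clozapk import (
    GeneratorConfig,
    ModelStructureConfig,
    REFERENCE_RANDOM_EFFECTS,
    REFERENCE_RAT_ESTIMATES,
    REFERENCE_RESIDUALS,
    bootstrap,
    default_rat_design,
    generate_study,
    vpc,
    weighted_residuals,
)
from clozapk.estimation import FitResult

dataset = generate_study(default_rat_design(), GeneratorConfig(seed=11))
fit = FitResult(
    fixed_effects=REFERENCE_RAT_ESTIMATES,
    random_effects=REFERENCE_RANDOM_EFFECTS,
    residual=REFERENCE_RESIDUALS,
    ofv=float("nan"),
    method="laplace",
    structure=ModelStructureConfig(),
)

res = weighted_residuals(dataset, fit)
print(f"residuals: n={len(res)}, CWRES mean {res.CWRES.mean():+.3f}, "
      f"SD {res.CWRES.std():.3f} (well-specified model: ~0 and ~1)")

check = vpc(dataset, fit, n_replicates=500, seed=42)
print(f"VPC ({check.n_replicates} replicates): observed median inside the "
      f"90% interval at {100 * check.coverage():.0f}% of timepoints")

boot = bootstrap(dataset, fit, n_replicates=50, seed=7, method="pooled", maxiter=80)
row = boot.summary("cl_clo")
print("bootstrap (50 replicates, pooled refits), clozapine clearance CL/F:")
print(f"  point {row['estimate']:.3f}  median {row['median']:.3f}  "
      f"90% interval [{row['p5']:.3f}, {row['p95']:.3f}] L/min")
print(f"  failed replicates: {boot.n_failed}")
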