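"""Human translation and receptor-occupancy prediction.

Scales the rat brain-ECF disposition to a 70 kg human (clearance W^0.75,
volume W^1, rate constants W^-0.25), links it to a human plasma model and
predicts steady-state receptor occupancy.

The human plasma constants and receptor dissociation constants below are
SYNTHETIC stand-ins: the real values are literature inputs the user must
supply (the workflow is conditional on them).
"""

import numpy as np

from clozapk import (
    HumanPKConfig,
    Receptor,
    ReceptorPanel,
    REFERENCE_RAT_ESTIMATES,
    build_human_model,
    occupancy_time_course,
    scale_brain_parameters,
    simulate_human_steady_state,
)

human = HumanPKConfig(
    cl_clo_plasma=0.7,    # L/min total CL/F  (synthetic example value)
    v_clo_plasma=500.0,   # L                 (synthetic example value)
    ka_clo=0.012,         # 1/min             (synthetic example value)
    cl_met_plasma=0.5,    # L/min             (synthetic example value)
    v_met_plasma=400.0,   # L                 (synthetic example value)
    fm=0.5,               # half of clozapine clearance forms norclozapine
    fu=0.03,              # 3% unbound in plasma
)
panel = ReceptorPanel(
    receptors=(
        Receptor("D2", "clozapine", 120.0, "synthetic-example"),
        Receptor("5HT2A", "clozapine", 8.0, "synthetic-example"),
        Receptor("D2", "norclozapine", 180.0, "synthetic-example"),
    )
)

scaled = scale_brain_parameters(REFERENCE_RAT_ESTIMATES)
print("allometrically scaled brain parameters (0.35 kg rat -> 70 kg human):")
for name, value in scaled.items():
    print(f"  {name:8s} {getattr(REFERENCE_RAT_ESTIMATES, name):9.4g} -> {value:9.4g}")

model = build_human_model(REFERENCE_RAT_ESTIMATES, human)
sims = {
    dose: simulate_human_steady_state(model, dose, n_subjects=200, seed=1)
    for dose in (200.0, 300.0, 400.0)
}
for dose, sim in sims.items():
    med = np.median(sim.profiles["parent_brain"], axis=0)
    print(f"{dose:.0f} mg/day: median unbound brain-ECF clozapine "
          f"{1000 * med.min():.2f}-{1000 * med.max():.2f} ug/L over the interval")

profile = occupancy_time_course(sims, panel)
print("predicted median occupancy range, 6-24 h after dose:")
for (receptor, compound, dose), grp in profile.table.groupby(
    ["receptor", "compound", "dose_mg"]
):
    print(f"  {compound:13s} {receptor:6s} {dose:3.0f} mg: "
          f"{grp['median'].min():5.1f}-{grp['median'].max():5.1f} %")
print("(occupancy values are conditional on the synthetic Kd/plasma constants)")
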