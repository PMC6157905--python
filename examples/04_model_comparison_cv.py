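"""Compare the Siamese model against the four reference classifiers.

Runs the cross-validated factorial design (feature sets × timepoint sets)
on a synthetic labeled cohort and prints mean accuracy/AUC per design
cell, plus the Mann-Whitney contrast of the Siamese model against each
baseline on the two-timepoint CA+CT cell.
"""

import numpy as np

from cogtraj import SimulationConfig, filter_eligible, mmse_two_class_spec, simulate_cohort
from cogtraj.evaluate import build_prediction_inputs, run_experiment
from cogtraj.lsn import LSNConfig
from cogtraj.reference import FAST_GRIDS
from cogtraj.trajectory import label_cohort, model_trajectories

config = SimulationConfig(n_subjects=250, class_spec=mmse_two_class_spec(),
                          scale="mmse", visit_missing_prob=0.1, seed=3)
cohort, _ = simulate_cohort(config)
template, _ = model_trajectories(cohort, "mmse", k=2, months=config.visit_grid)
assignments, _ = label_cohort(filter_eligible(cohort, "mmse"), template)
label_of = {a.subject_id: a.label for a in assignments}

inputs, ids, _ = build_prediction_inputs(cohort, "mmse")
keep = [i for i, s in enumerate(ids) if s in label_of]
inputs, ids = [inputs[i] for i in keep], [ids[i] for i in keep]
y = np.array([template.class_labels.index(label_of[s]) for s in ids])

report = run_experiment(
    inputs, ids, y, template.class_labels, "mmse",
    models=("LR", "SVM", "RF", "ANN", "LSN"), k=5, inner_folds=0, seed=0,
    grids=FAST_GRIDS, lsn_config=LSNConfig(seed=0, max_epochs=150),
)

print(f"{'cell':<28}{'mean acc':>10}{'mean AUC':>10}")
for key, cell in sorted(report.cells.items()):
    aucs = [a for a in cell.fold_auc if a is not None]
    print(f"{key:<28}{np.mean(cell.fold_accuracy):>10.3f}"
          f"{np.mean(aucs) if aucs else float('nan'):>10.3f}")
print("\nMann-Whitney p-values, Siamese vs baseline (two-timepoint CA+CT):")
for name, p in sorted(report.comparisons.items()):
    print(f"  {name}: p = {p:.3f}")
print("\nTrajectory labels here derive largely from the score curves, so")
print("clinical attributes already separate the classes well; the Siamese")
print("model's edge appears when the signal sits in structural change")
print("(see example 03).")
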