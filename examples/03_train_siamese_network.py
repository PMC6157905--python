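"""Train the Longitudinal Siamese Network on two-timepoint inputs.

Builds a cohort whose classes differ only in the rate of cortical
thinning in a 12-ROI signature (clinical scores are identically
distributed), trains the Siamese model on baseline + follow-up data, and
shows that it recovers the class from structural change alone — then
inspects the distance embedding's antisymmetry.
"""

import numpy as np

from cogtraj import SimulationConfig, ct_signal_only_spec, simulate_cohort
from cogtraj.evaluate import build_prediction_inputs
from cogtraj.lsn import LSNConfig, distance_embedding, predict_proba, train_lsn

config = SimulationConfig(n_subjects=300, class_spec=ct_signal_only_spec(),
                          scale="mmse", seed=11)
cohort, truth = simulate_cohort(config)
inputs, ids, excluded = build_prediction_inputs(cohort, "mmse")
y = np.array([["stable", "decline"].index(truth[s]) for s in ids])

split = int(0.8 * len(inputs))
params, history = train_lsn(inputs[:split], y[:split],
                            LSNConfig(n_classes=2, seed=1, max_epochs=200),
                            class_labels=["stable", "decline"])
probs = predict_proba(params, inputs[split:])
acc = np.mean(np.argmax(probs, axis=1) == y[split:])

print(f"training subjects: {split}   held-out: {len(inputs) - split}")
print(f"epochs run: {history['epochs_run']}  best validation loss: "
      f"{history['best_val_loss']:.3f}")
print(f"held-out accuracy from CT change alone: {acc:.2f}")

x = inputs[0]
e_fwd = distance_embedding(params, x.ct_t0, x.ct_t1)
e_rev = distance_embedding(params, x.ct_t1, x.ct_t0)
print(f"\ndistance embedding (first 4 dims): {np.round(e_fwd[:4], 3)}")
print(f"reversed timepoints:               {np.round(e_rev[:4], 3)}")
print("\nThe embedding is the difference of the shared branch outputs, so")
print("swapping the two scans negates it exactly — direction of change is")
print("preserved, and identical scans map to the zero vector.")
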